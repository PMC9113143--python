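"""Synthetic single-cell mtDNA cohort generator with known ground truth.

Emulates the count-table structure of mtscATAC-seq-derived per-cell mtDNA
pileups: germline variants near VAF 1 shared by every cell, somatic variants
whose per-cell VAF comes either from an explicit table or from the
Wright-Fisher dilution model, homopolymer-artifact sites, strand-asymmetric
oxidative-damage errors (G>T / C>A), and negative-binomial per-(cell, site)
depth variation. Every planted signal is recorded in a truth table so the
downstream filter cascade can be scored against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import MtGenomeAnnotation, load_annotation
from .counts import AlleleCountMatrix
from .wrightfisher import MT_GENOME_LENGTH, SimParams, simulate_cellset

_BASES = ("A", "C", "G", "T")

#: default artifact positions: the homopolymer/misalignment blacklist
DEFAULT_ARTIFACT_SITES = (
    "302A/C", "309C/T", "311C/T", "312C/T", "313C/T", "316G/C",
    "514C/A", "515A/G", "523A/C", "524C/G",
    "3106C/A", "3109T/C", "3110C/A",
)


class CohortConfigError(ValueError):
    """A CohortSpec field violates its constraints."""


def parse_variant_token(token: str) -> tuple[int, str, str]:
    """Parse '3243A/G'-style notation into (site, ref, alt)."""
    i = 0
    while i < len(token) and token[i].isdigit():
        i += 1
    site, rest = token[:i], token[i:]
    if not site or len(rest) != 3 or rest[1] != "/":
        raise ValueError(f"cannot parse variant token {token!r}")
    return int(site), rest[0].upper(), rest[2].upper()


def variant_token(site: int, ref: str, alt: str) -> str:
    return f"{site}{ref}/{alt}"


@dataclass
class CellTypeSpec:
    label: str
    n_cells: int
    baseline_copy_number: int = 500


@dataclass
class CohortSpec:
    """Configuration of one synthetic cohort.

    somatic_source maps a cell-type label to either a SimParams (per-cell
    VAFs produced by the Wright-Fisher dilution model) or an explicit
    per-cell VAF table (DataFrame with columns cell_index, site, ref, alt,
    true_vaf). error_rates are per-read substitution error probabilities
    keyed "G>T"-style; artifact_sites are seeded with spurious alt reads.
    """

    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [CellTypeSpec("B", 100)]
    )
    depth_mean: float = 50.0
    depth_dispersion: float = 5.0
    germline_variants: list[str | tuple[int, str, str]] = field(default_factory=list)
    somatic_source: dict = field(default_factory=dict)
    error_rates: dict[str, float] = field(default_factory=dict)
    artifact_sites: list[str | tuple[int, str, str]] = field(default_factory=list)
    artifact_vaf: float = 0.15
    artifact_cell_fraction: float = 0.3
    damage_strand_bias: float = 0.9
    strand_fwd_fraction: float = 0.5
    strand_noise: float = 0.02
    n_background_sites: int = 200
    total_reads_mean: float = 50_000.0
    reads_per_copy: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if not self.cell_types:
            problems.append("cell_types: at least one cell type required")
        for ct in self.cell_types:
            if ct.n_cells <= 0:
                problems.append(f"cell_types[{ct.label}].n_cells: must be > 0")
            if ct.baseline_copy_number <= 0:
                problems.append(
                    f"cell_types[{ct.label}].baseline_copy_number: must be > 0"
                )
        if self.depth_mean <= 0:
            problems.append("depth_mean: must be > 0")
        if self.depth_dispersion <= 0:
            problems.append("depth_dispersion: must be > 0")
        for key, rate in self.error_rates.items():
            if not 0.0 <= rate <= 1.0:
                problems.append(f"error_rates[{key}]: {rate} outside [0, 1]")
        for name in ("artifact_vaf", "artifact_cell_fraction",
                     "damage_strand_bias", "strand_fwd_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                problems.append(f"{name}: {v} outside [0, 1]")
        for source in (self.germline_variants, self.artifact_sites):
            for item in source:
                site, _, _ = self._as_variant(item)
                if not 1 <= site <= MT_GENOME_LENGTH:
                    problems.append(
                        f"variant site {site}: outside 1..{MT_GENOME_LENGTH}"
                    )
        if problems:
            raise CohortConfigError("; ".join(problems))

    @staticmethod
    def _as_variant(item) -> tuple[int, str, str]:
        if isinstance(item, str):
            return parse_variant_token(item)
        site, ref, alt = item
        return int(site), str(ref).upper(), str(alt).upper()

    def germline(self) -> list[tuple[int, str, str]]:
        return [self._as_variant(v) for v in self.germline_variants]

    def artifacts(self) -> list[tuple[int, str, str]]:
        return [self._as_variant(v) for v in self.artifact_sites]


@dataclass
class TruthTable:
    """Ground truth of a synthetic cohort.

    variants: one row per planted variant (site, ref, alt, class with
    mutually exclusive classes germline | somatic | artifact | damage_error).
    cell_vafs: per (cell, variant) true VAF in [0, 1] (absent rows mean 0).
    """

    variants: pd.DataFrame
    cell_vafs: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.variants):
            dup = self.variants.duplicated(["site", "ref", "alt"])
            if dup.any():
                raise ValueError("planted variants must be unique")

    def of_class(self, cls: str) -> pd.DataFrame:
        return self.variants[self.variants["class"] == cls]

    def write(self, directory) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "truth_variants": directory / "truth_variants.tsv",
            "truth_cell_vafs": directory / "truth_cell_vafs.tsv",
        }
        self.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
        self.cell_vafs.to_csv(paths["truth_cell_vafs"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, directory) -> "TruthTable":
        directory = Path(directory)
        return cls(
            variants=pd.read_csv(directory / "truth_variants.tsv", sep="\t"),
            cell_vafs=pd.read_csv(directory / "truth_cell_vafs.tsv", sep="\t"),
        )


def simulate_site_counts(
    true_vaf: float,
    depth: int,
    strand_fwd_fraction: float = 0.5,
    error_rate: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[int, int, int, int]:
    """Sample (ref_fwd, ref_rev, alt_fwd, alt_rev) for one (cell, site).

    Alt reads ~ binomial(depth, p) with p the true VAF perturbed by the
    per-read error rate (errors convert ref reads to alt and vice versa);
    each read is assigned to the forward strand with probability
    strand_fwd_fraction.
    """
    if not 0.0 <= true_vaf <= 1.0:
        raise ValueError(f"true_vaf must be in [0, 1], got {true_vaf}")
    if depth < 0:
        raise ValueError(f"depth must be >= 0, got {depth}")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError(f"error_rate must be in [0, 1], got {error_rate}")
    rng = rng or np.random.default_rng()
    p_alt = true_vaf * (1 - error_rate) + (1 - true_vaf) * error_rate
    alt = int(rng.binomial(depth, p_alt))
    ref = depth - alt
    alt_fwd = int(rng.binomial(alt, strand_fwd_fraction))
    ref_fwd = int(rng.binomial(ref, strand_fwd_fraction))
    return ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd


def generate_cohort(
    spec: CohortSpec, ann: MtGenomeAnnotation | None = None
) -> tuple[AlleleCountMatrix, TruthTable]:
    """Generate a cohort per the spec; bit-identical for identical seeds."""
    ann = ann or load_annotation()
    rng = np.random.default_rng(spec.seed)

    cells = _make_cells(spec, rng)
    planted, cell_vafs = _plan_variants(spec, ann, cells, rng)
    bg_sites = _background_sites(spec, ann, planted, rng)

    count_rows = []
    damage_hits: dict[tuple[int, str, str], bool] = {}
    vaf_lookup = {
        (r.cell_id, r.site): r.true_vaf for r in cell_vafs.itertuples()
    }
    site_plan = planted.set_index("site")[["ref", "alt", "class"]]

    all_sites = list(site_plan.index) + list(bg_sites)
    n_sites = len(all_sites)
    for cell_id in cells["cell_id"]:
        depths = _nb_depths(spec, n_sites, rng)
        p_fwd = np.clip(
            rng.normal(spec.strand_fwd_fraction, spec.strand_noise, n_sites), 0, 1
        )
        for j, site in enumerate(all_sites):
            depth = int(depths[j])
            if depth == 0:
                continue
            if site in site_plan.index:
                ref, alt, cls = site_plan.loc[site]
                true_vaf = vaf_lookup.get((cell_id, site), 0.0)
                row = _sample_counts(depth, true_vaf, p_fwd[j], p_fwd[j], rng)
            else:
                ref = ann.base_at(site)
                alt, cls = ".", None
                row = (int(rng.binomial(depth, p_fwd[j])), 0, 0, 0)
                row = (row[0], depth - row[0], 0, 0)
                # strand-asymmetric damage errors at eligible background sites
                err_alt, err_rate = _error_target(spec, ref)
                if err_alt is not None and err_rate > 0:
                    n_err = rng.binomial(depth, err_rate)
                    if n_err:
                        ref_total = depth - n_err
                        ref_fwd = int(rng.binomial(ref_total, p_fwd[j]))
                        err_fwd = int(rng.binomial(n_err, spec.damage_strand_bias))
                        row = (ref_fwd, ref_total - ref_fwd, err_fwd, n_err - err_fwd)
                        alt = err_alt
                        damage_hits[(site, ref, err_alt)] = True
            count_rows.append(
                (cell_id, site, ref, alt, row[0], row[1], row[2], row[3])
            )

    counts = pd.DataFrame(
        count_rows,
        columns=[
            "cell_id", "site", "ref", "alt",
            "ref_fwd", "ref_rev", "alt_fwd", "alt_rev",
        ],
    )
    damage = pd.DataFrame(
        [
            {"site": s, "ref": r, "alt": a, "class": "damage_error"}
            for (s, r, a) in sorted(damage_hits)
        ]
    )
    variants = pd.concat([planted, damage], ignore_index=True)
    truth = TruthTable(variants=variants, cell_vafs=cell_vafs)
    return AlleleCountMatrix(counts=counts, cells=cells), truth


def write_cohort(matrix: AlleleCountMatrix, truth: TruthTable, directory) -> dict:
    """Write counts + cell metadata + truth tables; round-trips losslessly
    through :func:`read_cohort`."""
    paths = matrix.write(directory)
    paths.update(truth.write(directory))
    return paths


def read_cohort(directory) -> tuple[AlleleCountMatrix, TruthTable]:
    return AlleleCountMatrix.read(directory), TruthTable.read(directory)


# -- internals ---------------------------------------------------------------


def _make_cells(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for ct in spec.cell_types:
        total = rng.poisson(spec.total_reads_mean, ct.n_cells) + 1
        mito = rng.binomial(
            total,
            np.clip(
                ct.baseline_copy_number * spec.reads_per_copy / spec.total_reads_mean,
                0,
                1,
            ),
        )
        for i in range(ct.n_cells):
            rows.append(
                {
                    "cell_id": f"{ct.label}_{i:04d}",
                    "cell_type": ct.label,
                    "mito_reads": int(mito[i]),
                    "total_reads": int(total[i]),
                }
            )
    return pd.DataFrame(rows)


def _plan_variants(spec, ann, cells, rng):
    """Assemble the planted variant plan and per-cell true VAFs."""
    rows = []
    vaf_rows = []
    used_sites: set[int] = set()

    for site, ref, alt in spec.germline():
        rows.append({"site": site, "ref": ref, "alt": alt, "class": "germline"})
        used_sites.add(site)
        for cell_id in cells["cell_id"]:
            vaf_rows.append(
                {"cell_id": cell_id, "site": site, "ref": ref, "alt": alt,
                 "true_vaf": 1.0}
            )

    for site, ref, alt in spec.artifacts():
        rows.append({"site": site, "ref": ref, "alt": alt, "class": "artifact"})
        used_sites.add(site)
        for cell_id in cells["cell_id"]:
            if rng.random() < spec.artifact_cell_fraction:
                vaf_rows.append(
                    {"cell_id": cell_id, "site": site, "ref": ref, "alt": alt,
                     "true_vaf": spec.artifact_vaf}
                )

    for ct in spec.cell_types:
        source = spec.somatic_source.get(ct.label)
        if source is None:
            continue
        ct_cells = cells.loc[cells["cell_type"] == ct.label, "cell_id"].to_numpy()
        if isinstance(source, SimParams):
            entries = _wf_somatic_entries(source, ct_cells, ann, rng)
        else:
            entries = [
                (ct_cells[int(r["cell_index"])], int(r["site"]),
                 str(r["ref"]).upper(), str(r["alt"]).upper(), float(r["true_vaf"]))
                for _, r in pd.DataFrame(source).iterrows()
            ]
        for cell_id, site, ref, alt, vaf in entries:
            if site not in used_sites:
                rows.append(
                    {"site": site, "ref": ref, "alt": alt, "class": "somatic"}
                )
                used_sites.add(site)
            vaf_rows.append(
                {"cell_id": cell_id, "site": site, "ref": ref, "alt": alt,
                 "true_vaf": vaf}
            )

    planted = pd.DataFrame(
        rows, columns=["site", "ref", "alt", "class"]
    ).drop_duplicates(["site", "ref", "alt"])
    cell_vafs = pd.DataFrame(
        vaf_rows, columns=["cell_id", "site", "ref", "alt", "true_vaf"]
    )
    return planted, cell_vafs


def _wf_somatic_entries(params: SimParams, ct_cells, ann, rng):
    """Per-cell somatic VAFs from the Wright-Fisher dilution model, with
    uniformly drawn (unique) genomic positions per mutation."""
    params = params.with_(
        n_cells=len(ct_cells), seed=int(rng.integers(0, 2**31))
    )
    cellset = simulate_cellset(params)
    ann_bases = ann.sequence
    entries = []
    taken: set[int] = set()
    for cell_idx, vaf in zip(cellset.cell_index, cellset.vaf):
        while True:
            site = int(rng.integers(1, MT_GENOME_LENGTH + 1))
            if site not in taken:
                taken.add(site)
                break
        ref = ann_bases[site - 1]
        alt = str(rng.choice([b for b in _BASES if b != ref]))
        entries.append((ct_cells[int(cell_idx)], site, ref, alt, float(vaf)))
    return entries


def _background_sites(spec, ann, planted, rng) -> np.ndarray:
    taken = set(planted["site"].tolist())
    pool = rng.choice(
        MT_GENOME_LENGTH, size=min(spec.n_background_sites * 3, MT_GENOME_LENGTH),
        replace=False,
    ) + 1
    sites = [s for s in pool.tolist() if s not in taken][: spec.n_background_sites]
    return np.array(sorted(sites), dtype=int)


def _nb_depths(spec, n, rng) -> np.ndarray:
    r = spec.depth_dispersion
    p = r / (r + spec.depth_mean)
    return rng.negative_binomial(r, p, size=n)


def _sample_counts(depth, true_vaf, p_fwd_ref, p_fwd_alt, rng):
    alt = int(rng.binomial(depth, true_vaf))
    ref = depth - alt
    alt_fwd = int(rng.binomial(alt, p_fwd_alt))
    ref_fwd = int(rng.binomial(ref, p_fwd_ref))
    return (ref_fwd, ref - ref_fwd, alt_fwd, alt - alt_fwd)


def _error_target(spec: CohortSpec, ref: str):
    """The configured error substitution applying at a site with this ref."""
    for key, rate in spec.error_rates.items():
        r, a = key.split(">")
        if r.upper() == ref:
            return a.upper(), rate
    return None, 0.0
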