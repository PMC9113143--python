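"""Somatic mtDNA variant identification: the five-step filter cascade.

Candidate calls are made per cell (depth >= 8, alt reads >= 2, VAF >= 0.01)
and unioned; then, in order: (1) germline variants removed (pooled VAF >
90%, or VAF > 90% shared by > 90% of covered cells); (2) homopolymer /
misalignment site blacklist and the G>T / C>A oxidative-damage substitution
blacklist; (3) confidence filters (site depth >= 20, alt reads >= 2,
forward-strand fraction of alt reads strictly between 30% and 70% in at
least one cell); (4) VAF recount in every cell of the cell types where the
variant was confidently seen, defined only at >= 8x depth; (5) cells with
mean mtDNA depth <= 10x dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import AlleleCountMatrix

DEFAULT_SITE_BLACKLIST = (
    # misalignment around the 302-315 homopolymer
    "302A/C", "309C/T", "311C/T", "312C/T", "313C/T", "316G/C",
    # misalignment around the 513-525 repeat
    "514C/A", "515A/G", "523A/C", "524C/G",
    # misalignment around the 3107N reference placeholder
    "3106C/A", "3109T/C", "3110C/A",
)
DEFAULT_SUBSTITUTION_BLACKLIST = ("G>T", "C>A")


@dataclass
class FilterConfig:
    """Thresholds of the filter cascade (defaults per the published
    protocol; see module docstring)."""

    candidate_min_vaf: float = 0.01
    candidate_min_depth: int = 8
    candidate_min_alt_reads: int = 2
    bulk_germline_vaf: float = 0.90
    shared_cell_fraction: float = 0.90
    site_blacklist: tuple[str, ...] = DEFAULT_SITE_BLACKLIST
    substitution_blacklist: tuple[str, ...] = DEFAULT_SUBSTITUTION_BLACKLIST
    min_site_depth: int = 20
    min_alt_reads: int = 2
    strand_low: float = 0.30
    strand_high: float = 0.70
    recount_min_depth: int = 8
    min_cell_mean_depth: float = 10.0

    def __post_init__(self) -> None:
        for name in ("candidate_min_vaf", "bulk_germline_vaf",
                     "shared_cell_fraction", "strand_low", "strand_high"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.strand_low >= self.strand_high:
            raise ValueError(
                f"strand_low ({self.strand_low}) must be < strand_high "
                f"({self.strand_high})"
            )


@dataclass
class VariantCallSet:
    """Set of (site, ref, alt) calls with filter provenance flags."""

    variants: pd.DataFrame  # columns: site, ref, alt (+ provenance flags)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        cols = {"site", "ref", "alt"}
        if not cols <= set(self.variants.columns):
            raise ValueError(f"variant table needs columns {sorted(cols)}")
        self.variants = self.variants.drop_duplicates(
            ["site", "ref", "alt"]
        ).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.variants)

    def keys(self) -> set[tuple[int, str, str]]:
        return {
            (int(r.site), r.ref, r.alt) for r in self.variants.itertuples()
        }

    def labels(self) -> list[str]:
        return [f"{int(r.site)}{r.ref}/{r.alt}" for r in self.variants.itertuples()]

    def _stamped(self, mask: pd.Series, step: str) -> "VariantCallSet":
        kept = self.variants[mask].reset_index(drop=True)
        return VariantCallSet(kept, self.provenance + [step])


@dataclass
class CellVariantMatrix:
    """Cell x variant VAF matrix (NaN = undefined, depth < recount floor)
    plus per-cell mean mtDNA depth and cell types."""

    vaf: pd.DataFrame  # index cell_id, one column per variant label
    mean_depth: pd.Series
    cell_types: pd.Series

    @property
    def n_cells(self) -> int:
        return len(self.vaf)


def _derived(matrix: AlleleCountMatrix) -> pd.DataFrame:
    df = matrix.with_derived()
    return df[df["alt"] != "."]


def call_candidates(matrix: AlleleCountMatrix, cfg: FilterConfig) -> VariantCallSet:
    """Candidate variants: any cell with site depth >= 8, >= 2 alt reads and
    alt fraction >= 1%; candidates are unioned over cells."""
    df = _derived(matrix)
    ok = (
        (df["depth"] >= cfg.candidate_min_depth)
        & (df["alt_reads"] >= cfg.candidate_min_alt_reads)
        & (df["vaf"] >= cfg.candidate_min_vaf)
    )
    calls = df.loc[ok, ["site", "ref", "alt"]].drop_duplicates()
    return VariantCallSet(calls.reset_index(drop=True), ["candidates"])


def identify_germline(matrix: AlleleCountMatrix, cfg: FilterConfig) -> set:
    """Germline variants: pooled (all-cell) VAF > 90%, or per-cell VAF > 90%
    in > 90% of cells covered at >= 8x at the site."""
    df = _derived(matrix)
    if df.empty:
        return set()
    pooled = df.groupby(["site", "ref", "alt"], observed=True).agg(
        alt_total=("alt_reads", "sum"), depth_total=("depth", "sum")
    )
    bulk = pooled[
        pooled["alt_total"] > cfg.bulk_germline_vaf * pooled["depth_total"]
    ].index

    covered = df[df["depth"] >= cfg.recount_min_depth]
    shared = covered.groupby(["site", "ref", "alt"], observed=True)["vaf"].agg(
        frac_high=lambda v: (v > cfg.bulk_germline_vaf).mean()
    )
    shared_idx = shared[shared["frac_high"] > cfg.shared_cell_fraction].index
    return {(int(s), r, a) for s, r, a in set(bulk) | set(shared_idx)}


def remove_germline(
    calls: VariantCallSet, germline: set
) -> VariantCallSet:
    mask = ~calls.variants.apply(
        lambda r: (int(r["site"]), r["ref"], r["alt"]) in germline, axis=1
    )
    if calls.variants.empty:
        mask = pd.Series(dtype=bool)
    return calls._stamped(mask, "germline_removed")


def apply_blacklists(calls: VariantCallSet, cfg: FilterConfig) -> VariantCallSet:
    """Remove homopolymer/misalignment blacklist sites and blacklisted
    substitution types (oxidative-damage G>T / C>A)."""
    from .cohort import parse_variant_token

    site_bl = {parse_variant_token(t) for t in cfg.site_blacklist}
    sub_bl = {tuple(s.split(">")) for s in cfg.substitution_blacklist}
    v = calls.variants
    if v.empty:
        return calls._stamped(pd.Series(dtype=bool), "blacklists")
    in_site_bl = v.apply(
        lambda r: (int(r["site"]), r["ref"], r["alt"]) in site_bl, axis=1
    )
    in_sub_bl = v.apply(lambda r: (r["ref"], r["alt"]) in sub_bl, axis=1)
    return calls._stamped(~(in_site_bl | in_sub_bl), "blacklists")


def apply_confidence_filters(
    calls: VariantCallSet, matrix: AlleleCountMatrix, cfg: FilterConfig
) -> VariantCallSet:
    """Keep a variant only if some cell has site depth >= 20, >= 2 alt reads
    and a strictly strand-balanced alt allele (0.30 < fwd fraction < 0.70)."""
    df = _derived(matrix)
    ok = df[
        (df["depth"] >= cfg.min_site_depth)
        & (df["alt_reads"] >= cfg.min_alt_reads)
        & (df["alt_fwd_frac"] > cfg.strand_low)
        & (df["alt_fwd_frac"] < cfg.strand_high)
    ]
    confident = {
        (int(r.site), r.ref, r.alt) for r in ok.itertuples()
    }
    v = calls.variants
    if v.empty:
        return calls._stamped(pd.Series(dtype=bool), "confidence")
    mask = v.apply(
        lambda r: (int(r["site"]), r["ref"], r["alt"]) in confident, axis=1
    )
    return calls._stamped(mask, "confidence")


def confident_cell_types(
    calls: VariantCallSet, matrix: AlleleCountMatrix, cfg: FilterConfig
) -> dict[tuple[int, str, str], set[str]]:
    """Cell types in which each final variant passed the confidence rule."""
    df = _derived(matrix).merge(
        matrix.cells[["cell_id", "cell_type"]], on="cell_id"
    )
    ok = df[
        (df["depth"] >= cfg.min_site_depth)
        & (df["alt_reads"] >= cfg.min_alt_reads)
        & (df["alt_fwd_frac"] > cfg.strand_low)
        & (df["alt_fwd_frac"] < cfg.strand_high)
    ]
    out: dict[tuple[int, str, str], set[str]] = {}
    for r in ok.itertuples():
        out.setdefault((int(r.site), r.ref, r.alt), set()).add(r.cell_type)
    return {k: v for k, v in out.items() if k in calls.keys()}


def recount_vaf(
    calls: VariantCallSet,
    matrix: AlleleCountMatrix,
    cfg: FilterConfig,
    within_cell_types: bool = True,
) -> CellVariantMatrix:
    """Recount each final variant's VAF in all individual cells.

    VAF = alt/(alt+ref) where the site is covered at >= 8x, else missing
    (NaN). With within_cell_types=True (default) the recount is restricted
    to cells of the cell types where the variant passed the confidence
    filters, mirroring per-cell-type recounting.
    """
    df = matrix.with_derived()
    cells = matrix.cells.set_index("cell_id")
    labels = calls.labels()
    vaf = pd.DataFrame(
        np.nan, index=cells.index, columns=labels, dtype=float
    )
    scope = (
        confident_cell_types(calls, matrix, cfg) if within_cell_types else None
    )
    by_site = {
        site: grp for site, grp in df.groupby("site", observed=True)
    }
    for (site, ref, alt), label in zip(
        [(int(r.site), r.ref, r.alt) for r in calls.variants.itertuples()], labels
    ):
        grp = by_site.get(site)
        if grp is None:
            continue
        covered = grp[grp["depth"] >= cfg.recount_min_depth]
        for r in covered.itertuples():
            if scope is not None:
                allowed = scope.get((site, ref, alt), set())
                if cells.loc[r.cell_id, "cell_type"] not in allowed:
                    continue
            alt_reads = r.alt_reads if r.alt == alt else 0
            vaf.loc[r.cell_id, label] = alt_reads / r.depth
    return CellVariantMatrix(
        vaf=vaf,
        mean_depth=matrix.mean_depth_per_cell(),
        cell_types=cells["cell_type"],
    )


def filter_cells(cvm: CellVariantMatrix, cfg: FilterConfig) -> CellVariantMatrix:
    """Drop cells whose mean mtDNA site depth is <= 10x."""
    keep = cvm.mean_depth > cfg.min_cell_mean_depth
    if not keep.any():
        warnings.warn("all cells dropped by the mean-depth filter", stacklevel=2)
    return CellVariantMatrix(
        vaf=cvm.vaf.loc[keep],
        mean_depth=cvm.mean_depth.loc[keep],
        cell_types=cvm.cell_types.loc[keep],
    )


@dataclass
class CascadeResult:
    candidates: VariantCallSet
    germline: set
    somatic: VariantCallSet
    cell_variant_matrix: CellVariantMatrix


def run_cascade(
    matrix: AlleleCountMatrix, cfg: FilterConfig | None = None
) -> CascadeResult:
    """The full five-step cascade in the published order."""
    cfg = cfg or FilterConfig()
    candidates = call_candidates(matrix, cfg)
    germline = identify_germline(matrix, cfg)
    calls = remove_germline(candidates, germline)
    calls = apply_blacklists(calls, cfg)
    calls = apply_confidence_filters(calls, matrix, cfg)
    cvm = recount_vaf(calls, matrix, cfg)
    cvm = filter_cells(cvm, cfg)
    _assert_disjoint(calls, germline, cfg)
    return CascadeResult(
        candidates=candidates,
        germline=germline,
        somatic=calls,
        cell_variant_matrix=cvm,
    )


def _assert_disjoint(calls: VariantCallSet, germline: set, cfg: FilterConfig):
    from .cohort import parse_variant_token

    final = calls.keys()
    site_bl = {parse_variant_token(t) for t in cfg.site_blacklist}
    sub_bl = {tuple(s.split(">")) for s in cfg.substitution_blacklist}
    assert not (final & germline), "somatic set overlaps germline set"
    assert not (final & site_bl), "somatic set overlaps site blacklist"
    assert not {k for k in final if (k[1], k[2]) in sub_bl}, (
        "somatic set contains blacklisted substitution types"
    )


def write_vcf(calls: VariantCallSet, path, contig: str = "chrM") -> None:
    """Write final variants as a minimal VCF (one record per variant, filter
    provenance in INFO)."""
    prov = ",".join(calls.provenance) or "none"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length=16569>\n")
        fh.write(
            '##INFO=<ID=STEPS,Number=.,Type=String,'
            'Description="Filter cascade steps passed">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        v = calls.variants.sort_values("site")
        for r in v.itertuples():
            fh.write(
                f"{contig}\t{int(r.site)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"STEPS={prov}\n"
            )
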