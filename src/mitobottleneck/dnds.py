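"""Selection statistics on mtDNA substitutions: dN/dS by substitution-site
enumeration.

Potential sites are counted by enumerating, for every codon of every CDS,
all 9 single-nucleotide substitutions and classifying each as synonymous
(SY) or nonsynonymous (NS) under the vertebrate mitochondrial code (stop
gain/loss counts as NS), giving genome-wide totals N and S with
N + S = 9 * (number of codons). Observed substitutions are classified the
same way; dN = n/N, dS = s/S, and their ratio is ~1 under neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import MtGenomeAnnotation, translate_codon

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SubstitutionCall:
    """Classification of one substitution in one gene context."""

    site: int
    ref: str
    alt: str
    region: str  # loop | tRNA | rRNA | coding
    gene: str | None = None
    effect: str | None = None  # SY | NS | None for non-coding
    aa_ref: str | None = None
    aa_alt: str | None = None
    overlapping: bool = False


@dataclass
class DnDsResult:
    """Observed and potential substitution counts for one stratum."""

    stratum: str
    n: int  # observed NS
    s: int  # observed SY
    N: int  # potential NS sites
    S: int  # potential SY sites

    @property
    def dN(self) -> float:
        return self.n / self.N if self.N > 0 else np.nan

    @property
    def dS(self) -> float:
        return self.s / self.S if self.S > 0 else np.nan

    @property
    def ratio(self) -> float:
        """dN/dS; undefined (NaN) when s = 0 or N or S is 0."""
        if self.s == 0 or self.S == 0 or self.N == 0:
            return np.nan
        return self.dN / self.dS

    def as_dict(self) -> dict:
        return {
            "stratum": self.stratum,
            "n": self.n,
            "s": self.s,
            "N": self.N,
            "S": self.S,
            "dN": self.dN,
            "dS": self.dS,
            "dnds": self.ratio,
        }


def classify_substitution(
    site: int, ref: str, alt: str, ann: MtGenomeAnnotation
) -> list[SubstitutionCall]:
    """Classify a substitution by region and coding effect.

    Returns one entry per overlapping gene context (a single entry for
    non-coding sites or sites inside exactly one CDS). Light-strand genes
    are classified on the reverse complement. The reference base must match
    the annotation genome at the site.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    genome_ref = ann.base_at(site)
    if genome_ref != ref:
        raise ValueError(
            f"reference mismatch at site {site}: annotation has {genome_ref}, "
            f"variant says {ref}"
        )
    genes = ann.cds_at(site)
    if genes.empty:
        return [
            SubstitutionCall(site=site, ref=ref, alt=alt, region=ann.region_at(site))
        ]
    out = []
    overlapping = len(genes) > 1
    for _, g in genes.iterrows():
        call = _classify_in_gene(site, ref, alt, g, ann)
        call.overlapping = overlapping
        out.append(call)
    return out


def _classify_in_gene(
    site: int, ref: str, alt: str, gene: pd.Series, ann: MtGenomeAnnotation
) -> SubstitutionCall:
    if gene["strand"] == "-":
        pos = gene["end"] - site  # 0-based position in coding sequence
        c_ref, c_alt = ref.translate(_COMPLEMENT), alt.translate(_COMPLEMENT)
    else:
        pos = site - gene["start"]
        c_ref, c_alt = ref, alt
    cds = ann.cds_sequence(gene["name"])
    if pos >= len(cds):
        # trailing base of an incomplete stop codon: no codon to classify
        return SubstitutionCall(
            site=site, ref=ref, alt=alt, region="coding", gene=gene["name"], effect=None
        )
    codon_i, offset = divmod(pos, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    assert codon[offset] == c_ref
    mutated = codon[:offset] + c_alt + codon[offset + 1 :]
    aa_ref = translate_codon(codon)
    aa_alt = translate_codon(mutated)
    return SubstitutionCall(
        site=site,
        ref=ref,
        alt=alt,
        region="coding",
        gene=gene["name"],
        effect="SY" if aa_ref == aa_alt else "NS",
        aa_ref=aa_ref,
        aa_alt=aa_alt,
    )


def codon_site_counts(codon: str) -> tuple[int, int]:
    """(NS, SY) counts among the 9 single-base substitutions of one codon."""
    aa = translate_codon(codon)
    ns = sy = 0
    for i in range(3):
        for b in _BASES:
            if b == codon[i]:
                continue
            if translate_codon(codon[:i] + b + codon[i + 1 :]) == aa:
                sy += 1
            else:
                ns += 1
    return ns, sy


def count_potential_sites(cds_sequences) -> tuple[int, int]:
    """Genome-wide potential (N, S): enumerate all 9 substitutions of every
    codon of every CDS. Accepts a dict of name->sequence or an iterable of
    sequences; sequences must be unambiguous and whole-codon length.
    """
    if isinstance(cds_sequences, dict):
        cds_sequences = cds_sequences.values()
    N = S = 0
    for seq in cds_sequences:
        seq = seq.upper()
        if set(seq) - set(_BASES):
            raise ValueError("CDS contains ambiguous bases")
        if len(seq) % 3:
            raise ValueError("CDS length not divisible by 3")
        for i in range(0, len(seq), 3):
            ns, sy = codon_site_counts(seq[i : i + 3])
            N += ns
            S += sy
    return N, S


def annotate_variants(variants: pd.DataFrame, ann: MtGenomeAnnotation) -> pd.DataFrame:
    """Annotate a variant table (columns site, ref, alt) with region, gene
    and coding effect; one output row per gene context at overlaps."""
    rows = []
    for _, v in variants.iterrows():
        for call in classify_substitution(int(v["site"]), v["ref"], v["alt"], ann):
            rec = dict(v)
            rec.update(
                region=call.region,
                gene=call.gene,
                effect=call.effect,
                overlapping=call.overlapping,
            )
            rows.append(rec)
    return pd.DataFrame(rows)


def compute_dnds(
    variants: pd.DataFrame,
    ann: MtGenomeAnnotation,
    strata: list[tuple[float, float]] | None = None,
    vaf_column: str = "vaf",
) -> pd.DataFrame:
    """dN/dS per VAF stratum.

    ``variants`` needs columns site, ref, alt and (when strata are given) a
    VAF column; strata are (low, high] intervals partitioning (0, 1], with
    the first interval also closed at its low edge. Overlap contexts count
    once per variant: NS if nonsynonymous in any overlapping gene.
    """
    annotated = annotate_variants(variants, ann)
    N, S = count_potential_sites(ann.all_cds_sequences())
    if annotated.empty:
        effect = pd.DataFrame(columns=["site", "ref", "alt", "effect", vaf_column])
    else:
        keys = [c for c in ("site", "ref", "alt", vaf_column) if c in annotated.columns]
        effect = (
            annotated.groupby(keys, dropna=False)["effect"]
            .agg(lambda e: "NS" if (e == "NS").any() else ("SY" if (e == "SY").any() else None))
            .reset_index()
        )
    if strata is None:
        strata = [(0.0, 1.0)]
    rows = []
    for lo, hi in strata:
        if vaf_column in effect.columns and effect[vaf_column].notna().any():
            vaf = effect[vaf_column]
            sel = effect[(vaf > lo) & (vaf <= hi) | ((vaf == lo) & (lo == strata[0][0]))]
        else:
            sel = effect
        res = DnDsResult(
            stratum=f"{lo:g}-{hi:g}",
            n=int((sel["effect"] == "NS").sum()),
            s=int((sel["effect"] == "SY").sum()),
            N=N,
            S=S,
        )
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def vaf_by_region(
    variant_vafs: pd.DataFrame, ann: MtGenomeAnnotation
) -> pd.DataFrame:
    """VAF observations keyed by genomic region and, for coding variants,
    by SY/NS - the per-region VAF distribution comparison.

    ``variant_vafs`` needs columns site, ref, alt, vaf (one row per defined
    cell-level VAF observation). Coding variants appear under their effect
    key ("NS"/"SY"); non-coding under their region label, so the keys
    partition the input rows.
    """
    annotated = annotate_variants(
        variant_vafs[["site", "ref", "alt"]].drop_duplicates(), ann
    )
    if annotated.empty:
        return pd.DataFrame(columns=["site", "ref", "alt", "vaf", "key"])
    key = (
        annotated.groupby(["site", "ref", "alt"], dropna=False)
        .apply(_context_key, include_groups=False)
        .rename("key")
        .reset_index()
    )
    return variant_vafs.merge(key, on=["site", "ref", "alt"], how="left")


def _context_key(group: pd.DataFrame) -> str:
    if (group["region"] == "coding").any():
        return "NS" if (group["effect"] == "NS").any() else "SY"
    return group["region"].iloc[0]


def random_coding_substitutions(
    ann: MtGenomeAnnotation, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw substitutions uniformly over all possible single-base changes in
    coding regions - the neutral null for dN/dS checks (expected ratio 1).
    """
    genes = ann.cds_genes()
    sites = []
    for _, g in genes.iterrows():
        length = g["end"] - g["start"] + 1
        usable = length - (length % 3)
        if g["strand"] == "-":
            span = np.arange(g["start"] + (length % 3), g["end"] + 1)
        else:
            span = np.arange(g["start"], g["start"] + usable)
        sites.append(span)
    sites = np.unique(np.concatenate(sites))
    pick = rng.choice(sites, size=n, replace=True)
    rows = []
    for site in pick:
        ref = ann.base_at(int(site))
        alt = rng.choice([b for b in _BASES if b != ref])
        rows.append({"site": int(site), "ref": ref, "alt": alt})
    return pd.DataFrame(rows)
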