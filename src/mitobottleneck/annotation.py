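"""Mitochondrial genome annotation: rCRS region map, CDS handling, and the
vertebrate mitochondrial codon table.

The bundled table carries the standard rCRS (16,569 bp) gene coordinates:
control-region/loop intervals, 22 tRNAs, 2 rRNAs and the 13 protein-coding
genes (including the ATP8/ATP6 and ND4L/ND4 overlaps; ND6 and eight tRNAs
on the light strand). No reference nucleotide sequence ships with the
package: by default a synthetic genome consistent with those coordinates is
generated deterministically, which is sufficient for site-count enumeration
and for all simulation-based analyses; supply the real rCRS FASTA to
annotate real variant calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .wrightfisher import MT_GENOME_LENGTH

#: NCBI translation table 2, "Vertebrate Mitochondrial": TGA = Trp,
#: AGA/AGG = stop, ATA = Met.
MITO_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

REGION_LABELS = ("loop", "tRNA", "rRNA", "coding")

# base composition roughly matching the mtDNA heavy strand
_SYNTHETIC_BASE_P = {"A": 0.31, "C": 0.31, "G": 0.13, "T": 0.25}
_SYNTHETIC_SEED = 16569

#: rCRS reference bases pinned in the synthetic genome so position-anchored
#: defaults (the homopolymer blacklist, well-known variant sites) carry
#: their real reference alleles.
_LANDMARK_BASES = {
    302: "A", 309: "C", 311: "C", 312: "C", 313: "C", 316: "G",
    514: "C", 515: "A", 523: "A", 524: "C",
    3106: "C", 3109: "T", 3110: "C",
    2636: "G", 3209: "A", 3243: "A", 10304: "G", 16356: "T",
}


@dataclass
class MtGenomeAnnotation:
    """Region map + genome sequence + mitochondrial codon table."""

    regions: pd.DataFrame  # columns: name, region, start, end, strand
    sequence: str
    synthetic: bool = True

    def __post_init__(self) -> None:
        if len(self.sequence) != MT_GENOME_LENGTH:
            raise ValueError(
                f"genome must be {MT_GENOME_LENGTH} bp, got {len(self.sequence)}"
            )
        r = self.regions
        if (r["start"] < 1).any() or (r["end"] > MT_GENOME_LENGTH).any():
            raise ValueError("region intervals outside 1..16569")
        if not set(r["region"]) <= set(REGION_LABELS):
            raise ValueError(f"unknown region labels: {set(r['region']) - set(REGION_LABELS)}")

    @property
    def codon_table(self) -> CodonTable.CodonTable:
        return MITO_CODON_TABLE

    def base_at(self, site: int) -> str:
        self._check_site(site)
        return self.sequence[site - 1]

    def region_at(self, site: int) -> str:
        """Region label at a 1-based rCRS position.

        Sites in no annotated interval (short intergenic spacers and the
        control region) are labeled "loop". Sites inside a coding interval
        return "coding" even where a tRNA overlaps, matching a
        coding-effect-first annotation.
        """
        self._check_site(site)
        hits = self._intervals_at(site)
        if hits.empty:
            return "loop"
        for label in ("coding", "rRNA", "tRNA", "loop"):
            if (hits["region"] == label).any():
                return label
        return "loop"  # unreachable

    def cds_at(self, site: int) -> pd.DataFrame:
        """All coding genes containing the site (>1 row at gene overlaps)."""
        hits = self._intervals_at(site)
        return hits[hits["region"] == "coding"].reset_index(drop=True)

    def gene(self, name: str) -> pd.Series:
        match = self.regions[self.regions["name"] == name]
        if match.empty:
            raise KeyError(f"no gene named {name!r}")
        return match.iloc[0]

    def cds_genes(self) -> pd.DataFrame:
        return self.regions[self.regions["region"] == "coding"].reset_index(drop=True)

    def cds_sequence(self, name: str) -> str:
        """Coding-strand CDS sequence trimmed to whole codons.

        Light-strand genes are reverse-complemented; mitochondrial genes
        with incomplete 3' stop codons are trimmed of their 1-2 trailing
        bases so the length is divisible by 3.
        """
        g = self.gene(name)
        seq = self.sequence[g["start"] - 1 : g["end"]]
        if g["strand"] == "-":
            seq = str(Seq(seq).reverse_complement())
        trim = len(seq) % 3
        return seq[: len(seq) - trim] if trim else seq

    def all_cds_sequences(self) -> dict[str, str]:
        return {name: self.cds_sequence(name) for name in self.cds_genes()["name"]}

    def _intervals_at(self, site: int) -> pd.DataFrame:
        r = self.regions
        return r[(r["start"] <= site) & (site <= r["end"])]

    def _check_site(self, site: int) -> None:
        if not 1 <= site <= MT_GENOME_LENGTH:
            raise ValueError(f"site {site} outside 1..{MT_GENOME_LENGTH}")


def _bundled_regions() -> pd.DataFrame:
    with resources.files("mitobottleneck.data").joinpath("mt_annotation.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def _synthetic_genome(regions: pd.DataFrame, seed: int = _SYNTHETIC_SEED) -> str:
    """Deterministic synthetic 16,569-bp genome consistent with the region
    table (stand-in for the rCRS nucleotide sequence; see module docstring).
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list(_SYNTHETIC_BASE_P))
    seq = rng.choice(bases, size=MT_GENOME_LENGTH, p=list(_SYNTHETIC_BASE_P.values()))
    for site, base in _LANDMARK_BASES.items():
        seq[site - 1] = base
    return "".join(seq)


def load_annotation(fasta_path=None, seed: int = _SYNTHETIC_SEED) -> MtGenomeAnnotation:
    """Load the bundled region map with either a user-supplied genome FASTA
    (e.g. the real rCRS) or the deterministic synthetic genome."""
    regions = _bundled_regions()
    if fasta_path is not None:
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        seq = str(record.seq).upper()
        if len(seq) != MT_GENOME_LENGTH:
            raise ValueError(
                f"expected a {MT_GENOME_LENGTH} bp genome, got {len(seq)}"
            )
        return MtGenomeAnnotation(regions=regions, sequence=seq, synthetic=False)
    return MtGenomeAnnotation(
        regions=regions, sequence=_synthetic_genome(regions, seed), synthetic=True
    )


def write_cds_fasta(ann: MtGenomeAnnotation, path) -> None:
    """Write per-gene coding-strand CDS sequences (trimmed to codons)."""
    with open(path, "w") as fh:
        for name, seq in ann.all_cds_sequences().items():
            origin = "synthetic" if ann.synthetic else "provided"
            fh.write(f">{name} {origin}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def translate_codon(codon: str) -> str:
    """Amino acid (one-letter) or '*' for a stop, vertebrate mito code."""
    codon = codon.upper()
    if codon in MITO_CODON_TABLE.stop_codons:
        return "*"
    try:
        return MITO_CODON_TABLE.forward_table[codon]
    except KeyError:
        raise ValueError(f"ambiguous or invalid codon {codon!r}") from None
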