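"""Per-cell, per-site, strand-resolved mtDNA allele-count container.

The observed-data object every pipeline stage consumes. Counts live in a
long-format table with one row per (cell, site): reference reads split by
strand plus, where the site carries an alternate allele, alt reads split by
strand (single alternate allele per site; ``alt == "."`` marks ref-only
coverage rows).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .wrightfisher import MT_GENOME_LENGTH

COUNT_COLUMNS = [
    "cell_id", "site", "ref", "alt", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev",
]
CELL_COLUMNS = ["cell_id", "cell_type", "mito_reads", "total_reads"]


@dataclass
class AlleleCountMatrix:
    """Strand-resolved allele counts plus per-cell metadata."""

    counts: pd.DataFrame
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(COUNT_COLUMNS) - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns {sorted(missing)}")
        missing = set(CELL_COLUMNS) - set(self.cells.columns)
        if missing:
            raise ValueError(f"cell table missing columns {sorted(missing)}")
        if self.cells["cell_id"].duplicated().any():
            raise ValueError("cell_ids must be unique")
        if len(self.counts):
            sites = self.counts["site"]
            if sites.min() < 1 or sites.max() > MT_GENOME_LENGTH:
                raise ValueError(f"sites must lie in 1..{MT_GENOME_LENGTH}")
            for col in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
                if (self.counts[col] < 0).any():
                    raise ValueError(f"negative read counts in {col}")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def with_derived(self) -> pd.DataFrame:
        """Counts plus depth / alt_reads / vaf / alt forward-fraction."""
        df = self.counts.copy()
        df["depth"] = df[["ref_fwd", "ref_rev", "alt_fwd", "alt_rev"]].sum(axis=1)
        df["alt_reads"] = df["alt_fwd"] + df["alt_rev"]
        df["vaf"] = (df["alt_reads"] / df["depth"]).where(df["depth"] > 0)
        df["alt_fwd_frac"] = (df["alt_fwd"] / df["alt_reads"]).where(df["alt_reads"] > 0)
        return df

    def mean_depth_per_cell(self) -> pd.Series:
        """Mean mtDNA site depth per cell over its covered sites."""
        df = self.with_derived()
        by_cell = df.groupby("cell_id", observed=True)["depth"].mean()
        return by_cell.reindex(self.cells["cell_id"], fill_value=0.0)

    def write(self, directory) -> dict[str, Path]:
        """Write counts (gzip TSV), cell metadata (TSV); returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": directory / "counts.tsv.gz",
            "cells": directory / "cells.tsv",
        }
        # fixed mtime keeps gzip output byte-identical for identical data
        self.counts.to_csv(
            paths["counts"], sep="\t", index=False,
            compression={"method": "gzip", "mtime": 0},
        )
        self.cells.to_csv(paths["cells"], sep="\t", index=False)
        return paths

    @classmethod
    def read(cls, directory) -> "AlleleCountMatrix":
        directory = Path(directory)
        counts_path = directory / "counts.tsv.gz"
        if not counts_path.exists():
            counts_path = directory / "counts.tsv"
        counts = pd.read_csv(
            counts_path, sep="\t", dtype={"ref": "string", "alt": "string"}
        )
        counts["ref"] = counts["ref"].fillna(".").astype(str)
        counts["alt"] = counts["alt"].fillna(".").astype(str)
        cells = pd.read_csv(directory / "cells.tsv", sep="\t")
        return cls(counts=counts, cells=cells)
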