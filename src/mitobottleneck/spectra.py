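"""Descriptive statistics of somatic mtDNA heteroplasmy.

VAF spectra (the 19-bin summary vector used for ABC), per-cell mutational
burden, homoplasmic/dominant cell fractions, the relative copy-number proxy
(mito reads / total reads), and removal of variants already fixed in the
progenitor pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Bin edges 0.05, 0.10, ..., 1.00 - 20 edges, 19 bins. Bins are
#: left-closed/right-open except the last, which is closed at 1.0 so
#: homoplasmic variants (VAF = 1) are counted.
SPECTRUM_EDGES = np.round(np.arange(1, 21) * 0.05, 10)
N_BINS = 19


@dataclass
class VAFSpectrum:
    """19-bin VAF spectrum for one cell population."""

    counts: np.ndarray
    n_cells: int
    cell_type: str = ""
    normalization: str = "raw"  # "raw" | "per_cell_mean"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"spectrum must have {N_BINS} bins")
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")

    @property
    def bin_edges(self) -> np.ndarray:
        return SPECTRUM_EDGES

    def per_cell_mean(self) -> "VAFSpectrum":
        if self.normalization == "per_cell_mean":
            return self
        if self.n_cells == 0:
            raise ValueError("cannot normalize per cell with n_cells = 0")
        return VAFSpectrum(
            self.counts / self.n_cells,
            self.n_cells,
            self.cell_type,
            "per_cell_mean",
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": SPECTRUM_EDGES[:-1],
                "bin_high": SPECTRUM_EDGES[1:],
                "count": self.counts,
                "cell_type": self.cell_type,
            }
        )


def vaf_spectrum(
    vafs,
    n_cells: int,
    normalization: str = "raw",
    cell_type: str = "",
) -> VAFSpectrum:
    """Bin VAFs into the 19-bin spectrum.

    Bin i (1-based) holds VAFs in [0.05 i, 0.05 (i+1)) for i < 19 and
    [0.95, 1.0] for i = 19; VAFs below 0.05 are excluded (detection floor).
    """
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size and (vafs.min() < 0 or vafs.max() > 1):
        raise ValueError("VAFs must lie in [0, 1]")
    if normalization not in ("raw", "per_cell_mean"):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts, _ = np.histogram(vafs, bins=SPECTRUM_EDGES)
    spec = VAFSpectrum(counts.astype(float), n_cells, cell_type, "raw")
    return spec.per_cell_mean() if normalization == "per_cell_mean" else spec


def per_cell_burden(cvm: pd.DataFrame) -> pd.Series:
    """Somatic variants per cell: count of defined VAFs > 0.

    ``cvm`` is a cell x variant VAF table (NaN marks undefined entries,
    i.e. insufficient depth), as produced by the variant pipeline.
    """
    return (cvm > 0).sum(axis=1).astype(int)


def homoplasmic_dominant_fractions(
    cvm: pd.DataFrame,
    cell_types: pd.Series,
    homoplasmic_threshold: float = 0.95,
    dominant_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per cell type: fraction of cells carrying >= 1 homoplasmic variant
    (VAF >= homoplasmic_threshold) and >= 1 dominant variant
    (VAF > dominant_threshold, i.e. VAF > 50% in a single cell).
    """
    for name, thr in (
        ("homoplasmic_threshold", homoplasmic_threshold),
        ("dominant_threshold", dominant_threshold),
    ):
        if not 0.0 < thr <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {thr}")
    cell_types = cell_types.reindex(cvm.index)
    has_homo = (cvm >= homoplasmic_threshold).any(axis=1)
    has_dom = (cvm > dominant_threshold).any(axis=1)
    out = pd.DataFrame(
        {
            "cell_type": cell_types,
            "homoplasmic": has_homo,
            "dominant": has_dom,
        }
    )
    agg = out.groupby("cell_type", observed=True).agg(
        n_cells=("homoplasmic", "size"),
        homoplasmic_fraction=("homoplasmic", "mean"),
        dominant_fraction=("dominant", "mean"),
    )
    return agg.reset_index()


def relative_copy_number(cells: pd.DataFrame) -> pd.DataFrame:
    """mtDNA copy-number proxy per cell: mito_reads / total_reads.

    ``cells`` needs columns cell_id, cell_type, mito_reads, total_reads.
    Returns the per-cell proxy with a per-cell-type median attached.
    """
    if (cells["total_reads"] <= 0).any():
        bad = cells.loc[cells["total_reads"] <= 0, "cell_id"].tolist()
        raise ValueError(f"total_reads must be > 0; offending cells: {bad[:5]}")
    out = cells[["cell_id", "cell_type"]].copy()
    out["mito_fraction"] = cells["mito_reads"] / cells["total_reads"]
    medians = out.groupby("cell_type", observed=True)["mito_fraction"].median()
    out["cell_type_median"] = out["cell_type"].map(medians)
    return out


def exclude_early_fixed(
    cvm: pd.DataFrame,
    cell_types: pd.Series,
    progenitor_types: set[str] | list[str],
    fixed_vaf: float = 0.90,
    fixed_cell_fraction: float = 0.50,
) -> pd.DataFrame:
    """Drop variants fixed early in development.

    A variant homoplasmic (VAF > fixed_vaf) in more than fixed_cell_fraction
    of progenitor cells (among those where its VAF is defined) was fixed
    before lineage commitment and is excluded from spectrum analysis.
    """
    cell_types = cell_types.reindex(cvm.index)
    prog = cvm.loc[cell_types.isin(set(progenitor_types))]
    if prog.empty:
        warnings.warn(
            "no progenitor cells present; early-fixed exclusion is a no-op",
            stacklevel=2,
        )
        return cvm
    n_defined = prog.notna().sum(axis=0)
    n_fixed = (prog > fixed_vaf).sum(axis=0)
    with np.errstate(invalid="ignore"):
        frac = np.where(n_defined > 0, n_fixed / n_defined.replace(0, 1), 0.0)
    keep = cvm.columns[frac <= fixed_cell_fraction]
    return cvm[keep]
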