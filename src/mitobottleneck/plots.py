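"""Figure helpers: VAF-spectrum bars and posterior histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .abc import Posterior
from .spectra import SPECTRUM_EDGES, VAFSpectrum


def plot_spectrum(spectra: VAFSpectrum | list[VAFSpectrum], path=None):
    """Bar plot per 0.05-wide VAF bin, one panel per cell type."""
    if isinstance(spectra, VAFSpectrum):
        spectra = [spectra]
    fig, axes = plt.subplots(
        1, len(spectra), figsize=(4 * len(spectra), 3), squeeze=False, sharey=True
    )
    centers = (SPECTRUM_EDGES[:-1] + SPECTRUM_EDGES[1:]) / 2
    for ax, spec in zip(axes[0], spectra):
        ax.bar(centers, spec.counts, width=0.045)
        ax.set_xlabel("VAF")
        ax.set_ylabel(
            "mutations" if spec.normalization == "raw" else "mutations / cell"
        )
        ax.set_title(spec.cell_type or "spectrum")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_posterior(posterior: Posterior, path=None):
    """Histogram of each inferred parameter (alpha, Td, Ta, Nb)."""
    fig, axes = plt.subplots(1, 4, figsize=(14, 3))
    for ax, name in zip(axes, ("alpha", "Td", "Ta", "Nb")):
        x = posterior.draws[name].to_numpy(dtype=float)
        ax.hist(x, bins=30)
        lo, hi = np.percentile(x, [2.5, 97.5])
        ax.axvline(x.mean(), color="k", lw=1)
        ax.set_title(f"{name}: {x.mean():.2f} [{lo:.2f}, {hi:.2f}]")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
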