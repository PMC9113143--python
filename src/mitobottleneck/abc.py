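"""Rejection-sampling ABC for the dilution-bottleneck parameters.

Infers (alpha, Td, Ta) from an observed 19-bin VAF spectrum. Each prior
draw simulates a cohort, summarizes it as the 19-bin spectrum, and computes
the Euclidean distance to the observed spectrum; the draws with the
smallest 100*eta percent of distances form the posterior (sorted-distance
variant of rejection ABC, so with K = 1e6 and eta = 0.001 the posterior
holds exactly 1,000 draws). Summaries are compared as per-cell means so the
distance is insensitive to cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .spectra import N_BINS, VAFSpectrum
from .wrightfisher import MT_GENOME_LENGTH, SimParams, bottleneck_size, simulate_cellset

_PRIOR_BATCH = 8192
_MAX_PRIOR_TRIES = 1000


@dataclass
class PriorSpec:
    """Joint prior over (alpha, Td, Ta).

    alpha ~ U(alpha_range), Td ~ U{td_range}, Ta ~ U{ta_range} (integer,
    inclusive bounds), subject to the retention constraint
    Nb = N0 * alpha**Td > nb_min and the ordering constraint Ta >= Td;
    draws violating either are resampled.
    """

    alpha_range: tuple[float, float] = (0.0, 1.0)
    td_range: tuple[int, int] = (0, 30)
    ta_range: tuple[int, int] = (10, 40)
    N0: int = 500
    nb_min: float = 10.0

    def __post_init__(self) -> None:
        lo, hi = self.alpha_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid alpha_range {self.alpha_range}")
        if self.td_range[0] > self.td_range[1] or self.td_range[0] < 0:
            raise ValueError(f"invalid td_range {self.td_range}")
        if self.ta_range[0] > self.ta_range[1]:
            raise ValueError(f"invalid ta_range {self.ta_range}")


@dataclass
class ABCConfig:
    """Rejection-ABC run configuration.

    K prior draws; the floor(K * eta) smallest-distance draws are accepted.
    n_cells is the simulated cohort size per draw (per-cell-mean summaries
    make the distance insensitive to the observed cohort size).
    """

    K: int = 1_000_000
    eta: float = 0.001
    n_cells: int = 200
    mu: float = 1e-7
    L: int = MT_GENOME_LENGTH
    mu_candidates: tuple[float, ...] = (1e-8, 1e-7)
    detection_floor: float = 0.05
    ancestral_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must be in (0, 1], got {self.eta}")
        if self.K < 1 or self.K * self.eta < 1:
            raise ValueError("K * eta must be >= 1 (no draws would be accepted)")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def n_accept(self) -> int:
        return int(np.floor(self.K * self.eta))


@dataclass
class Posterior:
    """Accepted ABC draws plus run metadata."""

    draws: pd.DataFrame  # columns: alpha, Td, Ta, Nb, distance
    config: ABCConfig
    prior: PriorSpec
    max_rejected_distance_below: float = field(default=np.inf)

    def __len__(self) -> int:
        return len(self.draws)

    def summary(self) -> pd.DataFrame:
        return posterior_summary(self)

    def mean_params(self) -> SimParams:
        """SimParams at the posterior mean (Td, Ta rounded to integers)."""
        m = self.draws.mean()
        return SimParams(
            N0=self.prior.N0,
            alpha=float(m["alpha"]),
            Td=int(round(m["Td"])),
            Ta=max(int(round(m["Ta"])), int(round(m["Td"]))),
            mu=self.config.mu,
            L=self.config.L,
            n_cells=self.config.n_cells,
            detection_floor=self.config.detection_floor,
            ancestral_generations=self.config.ancestral_generations,
        )


def sample_prior(
    spec: PriorSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw parameters from the constrained prior (resampling rejected
    draws until Nb > nb_min and Ta >= Td hold).

    With size=None returns a single (alpha, Td, Ta) tuple; otherwise three
    arrays of length ``size``.
    """
    n = 1 if size is None else int(size)
    alphas = np.empty(n)
    tds = np.empty(n, np.int64)
    tas = np.empty(n, np.int64)
    filled = 0
    for _ in range(_MAX_PRIOR_TRIES):
        m = max(n - filled, _PRIOR_BATCH if size is not None else 64)
        a = rng.uniform(*spec.alpha_range, m)
        td = rng.integers(spec.td_range[0], spec.td_range[1] + 1, m)
        ta = rng.integers(spec.ta_range[0], spec.ta_range[1] + 1, m)
        ok = (spec.N0 * a**td > spec.nb_min) & (ta >= td)
        k = min(int(ok.sum()), n - filled)
        if k:
            idx = np.flatnonzero(ok)[:k]
            alphas[filled:filled + k] = a[idx]
            tds[filled:filled + k] = td[idx]
            tas[filled:filled + k] = ta[idx]
            filled += k
        if filled == n:
            if size is None:
                return float(alphas[0]), int(tds[0]), int(tas[0])
            return alphas, tds, tas
    raise RuntimeError(
        "prior has no feasible region under the Nb > "
        f"{spec.nb_min} and Ta >= Td constraints"
    )


def summarize_observed(observed: VAFSpectrum, n_cells: int | None = None) -> np.ndarray:
    """Observed spectrum as a per-cell-mean 19-vector."""
    if observed.counts.shape != (N_BINS,):
        raise ValueError(f"observed spectrum must have {N_BINS} bins")
    if observed.normalization == "per_cell_mean":
        return observed.counts.astype(float)
    n = observed.n_cells if n_cells is None else n_cells
    if n < 1:
        raise ValueError("observed cohort size must be >= 1 for normalization")
    return observed.counts / n


def abc_reject(
    observed: VAFSpectrum,
    cfg: ABCConfig,
    prior: PriorSpec | None = None,
    return_all_distances: bool = False,
) -> Posterior:
    """Run rejection ABC and return the accepted draws.

    The posterior is the floor(K * eta) draws with smallest Euclidean
    distance between simulated and observed per-cell-mean spectra; ties at
    the cutoff are broken by draw order (stable sort).
    """
    prior = prior or PriorSpec()
    rng = np.random.default_rng(cfg.seed)
    obs = summarize_observed(observed)

    alphas, tds, tas = sample_prior(prior, rng, size=cfg.K)
    # per-draw kernel seeds from the run seed; kernel takes 32-bit seeds
    seeds = rng.integers(0, 2**32, size=cfg.K).astype(np.int64)
    dists = _kernels.abc_distance_kernel(
        alphas,
        tds,
        tas,
        seeds,
        obs,
        cfg.n_cells,
        prior.N0,
        cfg.mu * cfg.L,
        cfg.detection_floor,
        cfg.ancestral_generations,
    )
    order = np.argsort(dists, kind="stable")
    acc = order[: cfg.n_accept]
    draws = pd.DataFrame(
        {
            "alpha": alphas[acc],
            "Td": tds[acc],
            "Ta": tas[acc],
            "Nb": prior.N0 * alphas[acc] ** tds[acc],
            "distance": dists[acc],
        }
    )
    rejected = dists[order[cfg.n_accept:]]
    post = Posterior(
        draws=draws,
        config=cfg,
        prior=prior,
        max_rejected_distance_below=float(rejected.min()) if rejected.size else np.inf,
    )
    if return_all_distances:
        post.all_distances = dists  # diagnostic attribute
    return post


def posterior_summary(posterior: Posterior) -> pd.DataFrame:
    """Mean and 95% CI (2.5/97.5 percentiles) per parameter, incl. Nb."""
    if len(posterior) == 0:
        raise ValueError("empty posterior")
    rows = []
    for name in ("alpha", "Td", "Ta", "Nb"):
        x = posterior.draws[name].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [2.5, 97.5])
        rows.append(
            {"parameter": name, "mean": x.mean(), "ci_low": lo, "ci_high": hi}
        )
    return pd.DataFrame(rows)


def model_select_mu(
    observed: VAFSpectrum,
    cfg: ABCConfig,
    prior: PriorSpec | None = None,
) -> tuple[float, pd.DataFrame]:
    """Run ABC once per candidate mutation rate and pick the best fit.

    The fit score is the mean accepted distance; the mu with the smallest
    score is selected. Returns (chosen_mu, score table).
    """
    if not cfg.mu_candidates:
        raise ValueError("mu_candidates is empty")
    ss = np.random.SeedSequence(cfg.seed)
    sub = ss.spawn(len(cfg.mu_candidates))
    rows = []
    for mu, child in zip(cfg.mu_candidates, sub):
        run_cfg = ABCConfig(
            K=cfg.K,
            eta=cfg.eta,
            n_cells=cfg.n_cells,
            mu=mu,
            L=cfg.L,
            mu_candidates=cfg.mu_candidates,
            detection_floor=cfg.detection_floor,
            ancestral_generations=cfg.ancestral_generations,
            seed=int(child.generate_state(1)[0] % 2**31),
        )
        post = abc_reject(observed, run_cfg, prior)
        rows.append({"mu": mu, "mean_accepted_distance": post.draws["distance"].mean()})
    scores = pd.DataFrame(rows)
    chosen = float(scores.loc[scores["mean_accepted_distance"].idxmin(), "mu"])
    return chosen, scores


def posterior_predictive(
    posterior: Posterior | None = None,
    n_reps: int = 100,
    n_cells: int | None = None,
    seed: int | None = None,
    params: SimParams | None = None,
) -> tuple[VAFSpectrum, np.ndarray]:
    """Average spectrum of n_reps cohorts at the posterior-mean parameters.

    Returns (mean spectrum over replicates as raw per-cohort counts, per-bin
    standard deviation across replicates). ``params`` overrides the
    posterior mean, e.g. for a matched no-bottleneck (alpha = 1) control or
    when checking a point hypothesis without a posterior.
    """
    if params is None:
        if posterior is None or len(posterior) == 0:
            raise ValueError("need a nonempty posterior or explicit params")
        params = posterior.mean_params()
    if n_cells is not None:
        params = params.with_(n_cells=n_cells)
    if seed is None:
        base_seed = posterior.config.seed if posterior is not None else 0
    else:
        base_seed = seed
    seeds = np.random.SeedSequence(base_seed).generate_state(n_reps)
    from .wrightfisher import cohort_spectrum_counts

    reps = np.stack(
        [cohort_spectrum_counts(params, seed=int(s)) for s in seeds]
    ).astype(float)
    mean = VAFSpectrum(reps.mean(axis=0), params.n_cells, normalization="raw")
    return mean, reps.std(axis=0)


def simulate_observed_cohort(params: SimParams) -> VAFSpectrum:
    """Simulate a cohort at known parameters and summarize it as a raw
    spectrum - the standard way to build synthetic 'observed' data for
    parameter-recovery experiments.
    """
    cells = simulate_cellset(params)
    from .spectra import vaf_spectrum

    return vaf_spectrum(cells.detected_vafs(), params.n_cells)
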