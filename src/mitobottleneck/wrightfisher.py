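"""Wright-Fisher dilution-bottleneck model of mtDNA heteroplasmy.

Models lymphoid development from the LMPP stage as a haploid Wright-Fisher
population of mtDNA molecules inside one cell. During the bottleneck only a
fraction ``alpha`` of molecules replicates per cell division, so the copy
number shrinks geometrically for ``Td`` divisions, reaching a minimum of

    Nb = N0 * alpha**Td

after which it recovers to the baseline ``N0`` in a single resampling
generation and stays constant until ``Ta`` total divisions have elapsed.
New mutations enter each generation as a Poisson influx with genome-wide
rate ``u = mu * L`` per copy (infinite-sites bookkeeping: every mutation is
a fresh allele; copy counts drift by binomial resampling and variants at
count 0 are pruned).

An optional ancestral phase (``ancestral_generations`` at constant ``N0``)
models standing heteroplasmy accumulated through the donor's lifetime of
relaxed mtDNA turnover before lymphoid commitment; it defaults to 0, i.e.
a mutation-free LMPP founder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from . import _kernels

MT_GENOME_LENGTH = 16_569


class ExtinctionError(RuntimeError):
    """Raised when the mtDNA copy number of a lineage reaches zero."""


@dataclass
class SimParams:
    """Parameters of the dilution-bottleneck simulation.

    Attributes
    ----------
    N0 : baseline mtDNA copies per cell (500 for B/T lineages, 300 for NK).
    alpha : dilution rate per division, in (0, 1]; alpha = 1 disables the
        bottleneck.
    Td : number of dilution divisions (>= 0).
    Ta : total divisions from LMPP to mature lymphocyte (>= Td).
    mu : per-site per-division mutation rate (default 1e-7).
    L : mitochondrial genome length in bp.
    n_cells : independent lineages per simulated cohort.
    detection_floor : VAFs below this are treated as undetectable.
    ancestral_generations : constant-N0 generations run before the
        dilution phase to build standing heteroplasmy (default 0).
    seed : RNG seed for cohort simulation.
    """

    N0: int = 500
    alpha: float = 1.0
    Td: int = 0
    Ta: int = 10
    mu: float = 1e-7
    L: int = MT_GENOME_LENGTH
    n_cells: int = 500
    detection_floor: float = 0.05
    ancestral_generations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError(f"N0 must be >= 1, got {self.N0}")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.Td < 0:
            raise ValueError(f"Td must be >= 0, got {self.Td}")
        if self.Ta < self.Td:
            raise ValueError(f"Ta ({self.Ta}) must be >= Td ({self.Td})")
        if self.mu < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu}")
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.ancestral_generations < 0:
            raise ValueError("ancestral_generations must be >= 0")

    @property
    def u(self) -> float:
        """Genome-wide mutation rate per copy per division, u = mu * L."""
        return self.mu * self.L

    @property
    def Nb(self) -> float:
        """Minimal copy number through the bottleneck, N0 * alpha**Td."""
        return bottleneck_size(self.N0, self.alpha, self.Td)

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


def nk_baseline(N0: int = 500, relative_copy_number: float = 0.6) -> int:
    """Baseline mtDNA copies for the NK lineage.

    NK cells carry ~60% of the mtDNA copy number of B/T cells, so the NK
    cohort baseline is 500 * 0.6 = 300 copies.
    """
    return int(round(N0 * relative_copy_number))


def nk_params(**kwargs) -> SimParams:
    """Preset SimParams for the NK lineage (N0 = 300)."""
    kwargs.setdefault("N0", nk_baseline())
    return SimParams(**kwargs)


def bottleneck_size(N0: float, alpha: float, Td: int) -> float:
    """Minimal mtDNA copy number through the bottleneck: N0 * alpha**Td.

    Real-valued closed form; the simulated integer trajectory follows it
    within rounding (see :func:`copy_number_schedule`).
    """
    if N0 < 1:
        raise ValueError("N0 must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    if Td < 0:
        raise ValueError("Td must be >= 0")
    return N0 * alpha**Td


def mutation_pmf(u: float, k) -> float | np.ndarray:
    """P(k new mutations per genome per division) = u^k e^-u / k!."""
    if u < 0:
        raise ValueError("u must be >= 0")
    return stats.poisson.pmf(k, u)


def copy_number_schedule(params: SimParams) -> np.ndarray:
    """Integer copy numbers N_1..N_Ta of the developmental phase.

    Dilution applies N_{t+1} = round(alpha * N_t) for Td generations; the
    recovery generation and all later generations are at N0.
    """
    out = np.empty(params.Ta, dtype=np.int64)
    N = params.N0
    for t in range(params.Ta):
        if t < params.Td:
            N = int(np.round(params.alpha * N))
            if N < 1:
                raise ExtinctionError(
                    f"copy number reached 0 at dilution generation {t + 1} "
                    f"(alpha={params.alpha}, Td={params.Td})"
                )
        else:
            N = params.N0
        out[t] = N
    return out


@dataclass
class LineageState:
    """Mutation registry of a single lineage at one generation.

    ``ids[i]`` is the (arbitrary, unique) identifier of a segregating
    mutation present in ``counts[i]`` of the ``N`` mtDNA copies. Mutations
    at count 0 are pruned; fixed mutations stay at count N.
    """

    N: int
    ids: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    counts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    generation: int = 0
    next_id: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.ids.shape != self.counts.shape:
            raise ValueError("ids and counts must have equal length")
        if np.any(self.counts < 0) or np.any(self.counts > self.N):
            raise ValueError("mutation counts must lie in [0, N]")
        if self.next_id <= (self.ids.max() if self.ids.size else -1):
            self.next_id = int(self.ids.max()) + 1 if self.ids.size else 0

    @property
    def registry(self) -> dict[int, int]:
        return dict(zip(self.ids.tolist(), self.counts.tolist()))

    def vafs(self) -> np.ndarray:
        return self.counts / self.N


def evolve_generation(
    state: LineageState, next_N: int, u: float, rng: np.random.Generator
) -> LineageState:
    """One Wright-Fisher generation: resample to next_N copies, then add
    Poisson(u * next_N) new single-copy mutations.

    Each existing mutation's offspring count is binomial(next_N, c/N); lost
    mutations are pruned, and each new mutation gets a fresh id.
    """
    if next_N < 1:
        raise ExtinctionError("next_N < 1: mtDNA population extinct")
    counts = rng.binomial(next_N, state.counts / state.N)
    keep = counts > 0
    ids = state.ids[keep]
    counts = counts[keep]
    k = rng.poisson(u * next_N)
    if k:
        ids = np.concatenate([ids, np.arange(state.next_id, state.next_id + k)])
        counts = np.concatenate([counts, np.ones(k, np.int64)])
    return LineageState(
        N=next_N,
        ids=ids,
        counts=counts,
        generation=state.generation + 1,
        next_id=state.next_id + k,
    )


def simulate_lineage(
    params: SimParams, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Simulate one lineage; returns the final VAFs (count / N_final).

    Pure-numpy reference path built on :func:`evolve_generation`; cohort
    simulation uses the compiled kernel instead (see
    :func:`simulate_cellset`), and the two paths are cross-checked in the
    test suite.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(params.seed if rng is None else rng)
    state = LineageState(N=params.N0)
    for _ in range(params.ancestral_generations):
        state = evolve_generation(state, params.N0, params.u, rng)
    schedule = copy_number_schedule(params)
    for next_N in schedule:
        state = evolve_generation(state, int(next_N), params.u, rng)
    return state.vafs()


@dataclass
class SimulatedCellSet:
    """Final-generation mutations of a simulated cohort.

    ``cell_index[i]`` and ``vaf[i]`` give, for each segregating mutation,
    the cell carrying it and its heteroplasmy (copy count / N_final).
    """

    cell_index: np.ndarray
    vaf: np.ndarray
    n_cells: int
    N_final: int
    params: SimParams

    def per_cell(self) -> list[np.ndarray]:
        """VAF array per cell (empty array for mutation-free cells)."""
        order = np.argsort(self.cell_index, kind="stable")
        cells = self.cell_index[order]
        vafs = self.vaf[order]
        bounds = np.searchsorted(cells, np.arange(self.n_cells + 1))
        return [vafs[bounds[i]:bounds[i + 1]] for i in range(self.n_cells)]

    def detected_vafs(self) -> np.ndarray:
        """VAFs at or above the detection floor."""
        return self.vaf[self.vaf >= self.params.detection_floor]


def simulate_cellset(params: SimParams) -> SimulatedCellSet:
    """Simulate ``params.n_cells`` independent lineages (compiled kernel)."""
    cell, cnt, n_final, status = _kernels.simulate_cohort_kernel(
        params.n_cells,
        params.N0,
        params.alpha,
        params.Td,
        params.Ta,
        params.u,
        _as_kernel_seed(params.seed),
        params.ancestral_generations,
    )
    if status == _kernels.EXTINCT:
        raise ExtinctionError(
            f"mtDNA copy number reached 0 (alpha={params.alpha}, Td={params.Td}); "
            "the Nb > 10 retention rule prevents this region upstream"
        )
    return SimulatedCellSet(
        cell_index=cell,
        vaf=cnt / n_final,
        n_cells=params.n_cells,
        N_final=int(n_final),
        params=params,
    )


def cohort_spectrum_counts(params: SimParams, seed: int | None = None) -> np.ndarray:
    """Raw 19-bin VAF spectrum of one simulated cohort (compiled kernel).

    Bin i (1-based) covers [0.05 i, 0.05 (i+1)), the last bin closed at 1.
    """
    counts, status = _kernels.cohort_spectrum_kernel(
        params.n_cells,
        params.N0,
        params.alpha,
        params.Td,
        params.Ta,
        params.u,
        _as_kernel_seed(params.seed if seed is None else seed),
        params.detection_floor,
        params.ancestral_generations,
    )
    if status == _kernels.EXTINCT:
        raise ExtinctionError(
            f"mtDNA copy number reached 0 (alpha={params.alpha}, Td={params.Td})"
        )
    return counts


def drift_replicates(
    N: int, c0: int, n_gen: int, n_reps: int, seed: int = 0
) -> np.ndarray:
    """Final copy counts of n_reps independent mutations starting at count
    c0 in a constant-N population after n_gen generations (no new
    mutations). Convenience wrapper for drift-theory checks.
    """
    counts = np.full(n_reps, c0, dtype=np.int64)
    return _kernels.constant_n_counts_kernel(counts, N, n_gen, _as_kernel_seed(seed))


def _as_kernel_seed(seed: int) -> int:
    """Map an arbitrary integer seed into the kernel's legal seed range."""
    return int(np.uint32(seed))
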