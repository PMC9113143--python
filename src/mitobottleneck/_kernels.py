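"""Numba-accelerated inner loops for the Wright-Fisher dilution model.

These kernels use numba's legacy (Mersenne-Twister) RNG, seeded explicitly
per call, so results are reproducible for a fixed seed. The public API in
:mod:`mitobottleneck.wrightfisher` and :mod:`mitobottleneck.abc` wraps them.
"""

import numpy as np
from numba import njit

# status codes returned by the cohort kernel
OK = 0
EXTINCT = 1


@njit(cache=True)
def simulate_cohort_kernel(n_cells, N0, alpha, Td, Ta, u, seed, t_pre):
    """Simulate n_cells independent mtDNA lineages through the bottleneck.

    Each lineage runs t_pre ancestral generations at constant N0 (standing
    heteroplasmy), then Td dilution generations (N multiplied by alpha,
    rounded), a single recovery generation resampling to N0, and constant-N0
    generations until Ta post-ancestral generations have elapsed.

    Returns (cell_index, copy_count, N_final, status). Mutations follow
    infinite-sites bookkeeping: each row is one segregating mutation in one
    cell; copy_count is its number of mtDNA copies at the final generation.
    """
    np.random.seed(seed)
    cap = 1024
    cell = np.empty(cap, np.int64)
    cnt = np.empty(cap, np.int64)
    n_mut = 0
    N_cur = N0
    for t in range(t_pre + Ta):
        if t < t_pre:
            N_next = N0
        elif t - t_pre < Td:
            N_next = int(np.round(alpha * N_cur))
        else:
            N_next = N0
        if N_next < 1:
            return cell[:0], cnt[:0], 0, EXTINCT
        # binomial resampling of every segregating mutation; lost ones pruned
        m = 0
        for i in range(n_mut):
            c = np.random.binomial(N_next, cnt[i] / N_cur)
            if c > 0:
                cell[m] = cell[i]
                cnt[m] = c
                m += 1
        n_mut = m
        # Poisson influx of new single-copy mutations across the cohort
        k = np.random.poisson(u * N_next * n_cells)
        while n_mut + k > cap:
            cap *= 2
            new_cell = np.empty(cap, np.int64)
            new_cnt = np.empty(cap, np.int64)
            new_cell[:n_mut] = cell[:n_mut]
            new_cnt[:n_mut] = cnt[:n_mut]
            cell = new_cell
            cnt = new_cnt
        for _ in range(k):
            cell[n_mut] = np.random.randint(0, n_cells)
            cnt[n_mut] = 1
            n_mut += 1
        N_cur = N_next
    return cell[:n_mut].copy(), cnt[:n_mut].copy(), N_cur, OK


@njit(cache=True)
def cohort_spectrum_kernel(n_cells, N0, alpha, Td, Ta, u, seed, floor, t_pre):
    """Simulate a cohort and bin final VAFs into the 19-bin spectrum.

    Bin i (0-based) covers [0.05*(i+1), 0.05*(i+2)), the last bin closed at
    1.0; VAFs below `floor` (detection floor) are dropped. Returns
    (counts[19], status).
    """
    counts = np.zeros(19, np.int64)
    cell, cnt, N_final, status = simulate_cohort_kernel(
        n_cells, N0, alpha, Td, Ta, u, seed, t_pre
    )
    if status != OK:
        return counts, status
    for i in range(cnt.shape[0]):
        vaf = cnt[i] / N_final
        if vaf < floor or vaf < 0.05:
            continue
        b = int(vaf / 0.05 + 1e-9) - 1
        if b > 18:
            b = 18
        counts[b] = counts[b] + 1
    return counts, status


@njit(cache=True)
def abc_distance_kernel(alphas, tds, tas, seeds, observed_per_cell,
                        n_cells, N0, u, floor, t_pre):
    """Euclidean distance between each draw's simulated per-cell-mean
    spectrum and the observed per-cell-mean spectrum.

    Draws whose lineages go extinct (N < 1) get distance +inf.
    """
    K = alphas.shape[0]
    dists = np.empty(K, np.float64)
    for i in range(K):
        counts, status = cohort_spectrum_kernel(
            n_cells, N0, alphas[i], tds[i], tas[i], u, seeds[i], floor, t_pre
        )
        if status != OK:
            dists[i] = np.inf
            continue
        d = 0.0
        for b in range(19):
            diff = counts[b] / n_cells - observed_per_cell[b]
            d += diff * diff
        dists[i] = np.sqrt(d)
    return dists


@njit(cache=True)
def constant_n_counts_kernel(counts, N, n_gen, seed):
    """Evolve independent single-mutation copy counts for n_gen generations
    at constant population size N (no new mutations).

    Used by drift-theory checks (heterozygosity decay, fixation probability).
    """
    np.random.seed(seed)
    out = counts.copy()
    for t in range(n_gen):
        for i in range(out.shape[0]):
            c = out[i]
            if c > 0 and c < N:
                out[i] = np.random.binomial(N, c / N)
    return out
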