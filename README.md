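# mitobottleneck

Quantifying the somatic mitochondrial-DNA genetic bottleneck of human
lymphocyte development from single-cell data.

Single-cell assays that retain mitochondrial fragments (mtscATAC-seq,
scRNA-seq) let heteroplasmy — the fraction of a cell's mtDNA copies
carrying a variant (VAF) — be genotyped cell by cell. Mature B, T and NK
lymphocytes show a distinctive pattern: fewer detectable somatic mtDNA
mutations per cell than hematopoietic progenitors, yet an *excess* of
homoplasmic mutations (VAF ≈ 1). Both follow from a transient reduction in
mtDNA copy number during lymphoid development: if only a fraction α of
molecules replicates per division, the copy number shrinks from `N0` to

    Nb = N0 · α^Td

over `Td` divisions before recovering, and the amplified genetic drift
drives standing heteroplasmy to loss (lower burden) or fixation
(homoplasmy). This package implements that analysis end to end, for
computational biologists who want to simulate, detect and quantify
somatic mtDNA bottlenecks:

- **`mitobottleneck.cohort`** — synthetic single-cell allele-count cohorts
  with known ground truth (germline variants, Wright–Fisher somatic
  variants, homopolymer artifacts, strand-biased G>T/C>A damage errors,
  negative-binomial depth).
- **`mitobottleneck.pipeline`** — the five-step somatic-variant filter
  cascade over per-cell strand-resolved counts (candidates → germline
  removal → blacklists → depth/strand confidence → VAF recount → cell
  filter).
- **`mitobottleneck.spectra`** — the 19-bin VAF spectrum (bins of width
  0.05 from 0.05 to 1.0), per-cell burden, homoplasmic/dominant cell
  fractions, and the mito-reads/total-reads copy-number proxy.
- **`mitobottleneck.wrightfisher`** — the dilution-bottleneck Wright–Fisher
  simulator (numba-compiled cohort kernel plus a pure-numpy reference
  path).
- **`mitobottleneck.abc`** — rejection ABC over (α, Td, Ta) with uniform
  priors (`Td ~ U{0..30}`, `Ta ~ U{10..40}`), the retention rule
  `Nb > 10`, Euclidean distance between per-cell-mean spectra, and
  smallest-`K·η` acceptance; posterior summaries, mutation-rate model
  selection, posterior predictive spectra.
- **`mitobottleneck.dnds`** — dN/dS by exhaustive substitution enumeration
  under the vertebrate mitochondrial code, over the bundled rCRS gene map.

See `docs/methods.md` for the model, its assumptions and the numerical
choices, and `examples/` for one narrative script per capability.

## Worked example

Infer the bottleneck size from a simulated 500-cell cohort
(`examples/04_abc_inference.py`):

```python
from mitobottleneck import (ABCConfig, PriorSpec, SimParams, abc_reject,
                            posterior_summary, simulate_observed_cohort)

truth = SimParams(alpha=0.85, Td=15, Ta=25, n_cells=500, seed=3)  # Nb ~ 43.7
observed = simulate_observed_cohort(truth)
posterior = abc_reject(observed, ABCConfig(K=50_000, eta=0.002, n_cells=200, seed=5),
                       PriorSpec())
print(posterior_summary(posterior))
```

which prints

```
accepted draws: 100 of 50000
parameter      mean    ci_low    ci_high
    alpha  0.811625  0.442008   0.965418
       Td 12.990000  1.475000  22.000000
       Ta 28.730000 17.000000  37.000000
       Nb 82.514258 14.247051 376.352263
```

The `Nb` row is the estimate of the minimal mtDNA copy number through the
bottleneck: its 95% credible interval [14.2, 376] brackets the true 43.7
(individual parameters are only weakly identified from one cohort — many
(α, Td) pairs give similar spectra — which is why the experiments track CI
coverage of `Nb` rather than point error). The 100 accepted draws are the
`K·η` prior draws whose simulated 19-bin VAF spectra lie closest to the
observed one.

The qualitative signature itself (`examples/03_vaf_spectrum.py`): averaging
100 cohorts at a deep bottleneck (Nb ≈ 15) acting on standing heteroplasmy
gives a last-bin (homoplasmic) excess over the mid bins and a lower total
detectable burden than a matched constant-copy-number control, which
declines monotonically with VAF.

A one-command synthetic end-to-end run (cohort → variant calling →
spectrum → ABC → dN/dS, with a checksummed manifest):

```bash
mitobottleneck run --config examples/pipeline.yaml --out demo_run
```

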