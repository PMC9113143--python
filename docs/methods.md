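# Methods

## The model

Each cell's mitochondrial genomes are modeled as a haploid Wright–Fisher
population of `N` copies with discrete, non-overlapping generations (one
generation per cell division). A generation consists of (i) binomial
resampling: a mutation present in `c` of `N` copies is carried by
`Binomial(N', c/N)` of the `N'` copies of the next generation, mutations at
count 0 being pruned and fixed mutations staying fixed; and (ii) mutation
influx: the number of new mutations per genome copy per division is
Poisson with mean `u = μ · L` (`μ` the per-site rate, `L = 16,569` bp), so
a cohort of `n` cells at copy number `N'` gains `Poisson(u · N' · n)` new
single-copy mutations per generation. Bookkeeping is infinite-sites: every
mutation is a new allele at a previously unmutated position; with
`u·N ≪ L` recurrent mutation is negligible. Genomic positions are attached
only when annotated output is requested, drawn uniformly.

The dilution bottleneck is a deterministic copy-number schedule. From the
lymphoid-primed progenitor (LMPP) stage, only a fraction `α` of molecules
replicates per division, so `N_{t+1} = round(α · N_t)` for `T_d`
divisions, reaching the minimum

    Nb = N0 · α^Td .

The copy number then recovers to the baseline `N0` in a single resampling
generation and stays constant until `T_a` total divisions complete the
transition to a mature lymphocyte. The rounding schedule tracks the closed
form within `T_d/2` copies; the recovery generation counts toward `T_a`.
Selection on mtDNA variants is deliberately absent: the model is neutral,
and the bottleneck acts purely by amplifying drift while `N` is small.

### Parameters

| parameter | meaning | default |
|---|---|---|
| `N0` | baseline mtDNA copies per cell | 500 (300 for NK cells, which carry ~60% of the B/T copy number) |
| `α` | fraction of molecules replicating per division during the bottleneck | free, in (0, 1] |
| `T_d` | dilution divisions | free, 0–30 |
| `T_a` | total divisions LMPP → mature cell | free, 10–40, `T_a ≥ T_d` |
| `μ` | per-site per-division mutation rate | 1e-7 (1e-8 as model-selection alternative) |
| `L` | genome length | 16,569 bp |
| detection floor | smallest reportable heteroplasmy | 0.05 |
| `ancestral_generations` | constant-`N0` generations before LMPP | 0 |

### Standing heteroplasmy (`ancestral_generations`)

With a mutation-free founder, neutral fixation within ≤ 40 divisions is
essentially unobservable: conditional fixation of a neutral allele takes on
the order of `2N` generations, far longer than the developmental window, so
a bare dilution run produces almost no homoplasmic (VAF ≈ 1) mutations.
Real donors, however, enter lymphopoiesis with decades of standing
heteroplasmy: mtDNA turns over continuously (half-life of weeks) in
long-lived stem cells, so the effective number of ancestral mtDNA
generations in a middle-aged donor is in the hundreds. The simulator
therefore accepts an `ancestral_generations` phase at constant `N0` that
builds this standing variation before the dilution schedule starts. It
defaults to 0 (the bare developmental model, which is also what ABC uses by
default); donor-like cohort emulation and the bottleneck-vs-control
spectrum comparison set it to 400, at which the characteristic signature —
homoplasmic excess plus reduced detectable burden under a deep bottleneck —
is robust (it appears gradually between ~200 and ~400 generations as
mid-frequency standing variants accumulate on the ~`N0`-generation
timescale).

## Summary statistic and ABC

The summary of a cohort is the 19-bin VAF spectrum: mutation counts in
bins `[0.05·i, 0.05·(i+1))` for `i = 1..19`, the last bin closed at 1.0 so
homoplasmic variants are counted; VAFs below 0.05 fall under the detection
floor and are excluded. Spectra are compared as per-cell means (counts
divided by cohort size), which makes the Euclidean distance insensitive to
the observed cohort's size and lets ABC simulate smaller cohorts per draw.

Rejection ABC draws `(α, T_d, T_a)` from independent uniform priors
(`α ~ U(0,1)`, `T_d ~ U{0..30}`, `T_a ~ U{10..40}`), resampling any draw
violating the retention rule `Nb > 10` (which excludes extinction) or the
ordering `T_a ≥ T_d`. Each of `K` draws simulates a cohort, and the
`⌊K·η⌋` draws with the smallest Euclidean distances form the posterior
(the sorted-distance variant of rejection sampling; with `K = 1e6`,
`η = 0.001` the posterior holds exactly 1,000 draws). Ties at the cutoff
are broken by draw order; with continuous distances they have measure
zero. Posterior summaries are arithmetic means and 2.5/97.5-percentile
intervals per parameter, including the derived `Nb`. Mutation-rate model
selection runs the full procedure per candidate `μ` and picks the smaller
mean accepted distance — a pragmatic criterion, chosen here because the
acceptance threshold is itself quantile-defined.

Defaults: 200 simulated cells per draw (per-cell-mean summaries make the
distance cohort-size-insensitive; 200 balances summary noise against the
per-draw cost), `K = 1e6`, `η = 0.001`. The `α` prior spans all of (0, 1)
— the retention rule prunes the infeasible region — and `T_d`, `T_a` are
integers, since cell divisions are discrete events.

## Variant identification

The filter cascade over per-cell, strand-resolved allele counts follows a
fixed order. Candidates require, in at least one cell, site depth ≥ 8,
≥ 2 alt reads and VAF ≥ 1%, and are unioned over cells. Germline variants
are removed: pooled (all-cell) VAF > 90%, or per-cell VAF > 90% in > 90%
of covered cells (cells with ≥ 8× depth at the site; undefined-VAF cells
do not vote). Two blacklists follow: thirteen homopolymer/misalignment
positions around rCRS 302–316, 513–525 and 3105–3110, and the
oxidative-damage substitution types G>T and C>A. Confidence filters then
require, in at least one cell, depth ≥ 20, ≥ 2 alt reads, and a
forward-strand fraction of alt reads strictly between 30% and 70%
(boundary values fail). Surviving variants have their VAF recounted in
every cell of the cell types where they were confidently seen, defined
only where depth ≥ 8; finally, cells with mean mtDNA depth ≤ 10× are
dropped. "More than 20 reads" is read as depth ≥ 20 and "more than two
reads" as alt ≥ 2, matching the candidate caller's explicit minimum of 2
alt reads. The final somatic set is asserted disjoint from the germline
set and both blacklists on every run.

## Synthetic cohorts

The generator emulates the count-table structure of mtscATAC-seq-derived
per-cell mtDNA pileups: per-(cell, site) depths are negative-binomial
(mean 50, dispersion 5 by default), capturing coverage overdispersion
without claiming a specific protocol model; reads split between strands
around a configurable forward fraction. Planted signals: germline variants
at true VAF 1 in every cell; somatic variants with per-cell VAFs from an
explicit table or from the Wright–Fisher model (positions drawn uniformly,
one alternate allele per site); homopolymer artifacts seeded with spurious
alt reads at the blacklisted positions; and damage errors (G>T / C>A)
planted strand-asymmetrically (90% of error reads on one strand) so the
strand-balance filter has real work to do. Coordinates are 1-based rCRS
positions and substitutions are written `REF>ALT` / `302A/C`-style
throughout.

What the generator does not emulate: alignment artifacts beyond the listed
blacklist, doublets, index hopping, platform-specific error catalogues,
per-region coverage structure, or linkage between variants within a cell
beyond what the lineage simulation produces. Passing the planted-truth
tests therefore shows the cascade implements its rules correctly and
recovers signals under idealized noise — not that it is robust to every
real-data failure mode.

## Genome annotation and dN/dS

A bundled table carries the standard rCRS gene coordinates (control
region, 22 tRNAs, 2 rRNAs, 13 protein-coding genes, including the
ATP8/ATP6 and ND4L/ND4 overlaps; ND6 and eight tRNAs on the light
strand). The package does not ship the rCRS nucleotide sequence; by
default a deterministic synthetic genome consistent with those coordinates
is generated (with the real reference bases pinned at the handful of
positions the blacklist and well-known variants name), which is sufficient
for site-count enumeration, simulation-based analyses and tests. Real
variant annotation should supply the actual rCRS FASTA.

Potential sites are counted by substitution enumeration: for every codon
of every CDS, all 9 single-base changes are classified under the
vertebrate mitochondrial code (TGA = Trp, AGA/AGG = stop, ATA = Met), so
NS + SY = 9 per codon; genes with incomplete 3' stop codons are trimmed to
whole codons, and light-strand genes are classified on the reverse
complement. Stop gain/loss counts as nonsynonymous. Overlapping-gene sites
are classified per gene context and flagged; an observed variant counts as
NS if nonsynonymous in any context. `dN = n/N`, `dS = s/S`, and the ratio
is reported as undefined (NaN, never infinity) when `s = 0`. This is
deliberate substitution counting, not fractional Nei–Gojobori site
counting, and no maximum-likelihood machinery is involved.

## Numerical choices

- The cohort simulator is a compiled (numba) kernel over a flat
  (cell, copy-count) mutation array; a pure-numpy lineage path
  (`simulate_lineage` / `evolve_generation`) exists independently and the
  two are cross-checked in the tests.
- Kernel RNG is the legacy Mersenne-Twister seeded per call with 32-bit
  seeds derived from `numpy.random.SeedSequence`; identical seeds give
  bit-identical cohorts. Pipeline stages draw their seeds from one global
  seed via spawned substreams, so stages rerun independently with
  identical results, and gzip outputs are written with a fixed mtime so
  checksums are stable.
- Spectrum binning uses half-open bins with the last bin closed
  (`numpy.histogram` semantics), so VAF = 1.0 lands in bin 19.
- Draws whose lineages would go extinct (`N < 1`, unreachable under the
  retention rule) get infinite ABC distance rather than aborting a run.
- Degenerate inputs: empty count tables yield empty call sets (not
  errors); an all-cells-dropped depth filter warns and returns an empty
  matrix; `s = 0` gives an undefined dN/dS ratio; an empty posterior
  refuses to summarize.

## Problem sizes

Default study sizes used by the tests and the reproduction script:
ABC bookkeeping at `K = 1e6` with 2-cell simulated cohorts; parameter
recovery at `K = 5e4`, `η = 0.002`, 500-cell observed and 200-cell
simulated cohorts, 10 repetitions; spectrum-signature comparison averaged
over 100 cohorts of 500 cells; drift-theory oracles at `N = 20–50` with
1e4 Monte Carlo replicates; filter-cascade scoring on a 60-cell cohort at
~60× depth.

## Known limitations

- The model is neutral and single-lineage: clonal selection during B/T
  maturation, mitophagy, organelle-level population structure and
  selection coefficients on variants are out of scope.
- `ancestral_generations` is an effective-time knob, not a measured donor
  age; inferences about its absolute scale should not be read off the
  default.
- The retention rule `Nb > 10` truncates the prior near deep bottlenecks,
  so posterior lower CI bounds can hug the cutoff when data favor extreme
  dilution.
- Multi-allelic sites, indels and alignment-level artifacts are not
  modeled; the candidate caller consumes count tables, not reads.
- With few observed cells the per-cell-mean spectrum is noisy and ABC
  posteriors widen accordingly; the recovery experiment quantifies this at
  its stated sizes only.
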