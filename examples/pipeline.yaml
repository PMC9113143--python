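# Demo configuration for `mitobottleneck run`: a 200-cell synthetic cohort
# (bottlenecked B cells vs constant-copy-number progenitors) pushed through
# variant calling, spectrum summarization, ABC and dN/dS.
seed: 7
outdir: pipeline_demo
cohort:
  cell_types:
    - {label: B, n_cells: 100}
    - {label: HSC, n_cells: 100}
  depth_mean: 50
  germline_variants: ["3243A/G"]
  somatic_source:
    B:   {alpha: 0.89, Td: 30, Ta: 32, ancestral_generations: 400}
    HSC: {alpha: 1.0,  Td: 0,  Ta: 32, ancestral_generations: 400}
  error_rates: {"G>T": 0.003, "C>A": 0.003}
  artifact_sites: ["302A/C", "309C/T"]
abc:
  K: 10000
  eta: 0.01
  n_cells: 100
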