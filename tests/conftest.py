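import numpy as np
import pandas as pd
import pytest

import mitobottleneck as mb
from mitobottleneck.cohort import DEFAULT_ARTIFACT_SITES, CellTypeSpec, CohortSpec


@pytest.fixture(scope="session")
def ann():
    return mb.load_annotation()


def _somatic_table(ann, rng, n_cells=60, n_variants=20):
    """Explicit per-cell somatic VAF plan spanning VAFs 0.03..1.0.

    Variants avoid the blacklisted G>T / C>A substitution types so the
    cascade should recover every variant detectable above the VAF floor.
    """
    rows = []
    sites = rng.choice(np.arange(2000, 16000), n_variants, replace=False)
    vaf_cycle = [0.03, 0.05, 0.1, 0.3, 0.6, 1.0]
    for k, site in enumerate(sites):
        ref = ann.base_at(int(site))
        choices = [
            b for b in "ACGT"
            if b != ref and (ref, b) not in {("G", "T"), ("C", "A")}
        ]
        alt = str(rng.choice(choices))
        vaf = vaf_cycle[k % len(vaf_cycle)]
        for ci in rng.choice(n_cells, 25, replace=False):
            rows.append(
                {"cell_index": int(ci), "site": int(site), "ref": ref,
                 "alt": alt, "true_vaf": vaf}
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def cohort_spec(ann):
    rng = np.random.default_rng(5)
    gref = ann.base_at(1000)
    galt = [b for b in "ACGT" if b != gref][0]
    return CohortSpec(
        cell_types=[CellTypeSpec("B", 60)],
        depth_mean=60,
        germline_variants=[(1000, gref, galt)],
        somatic_source={"B": _somatic_table(ann, rng)},
        error_rates={"G>T": 0.004, "C>A": 0.004},
        artifact_sites=list(DEFAULT_ARTIFACT_SITES),
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(cohort_spec, ann):
    return mb.generate_cohort(cohort_spec, ann)


@pytest.fixture(scope="session")
def cascade(cohort):
    matrix, _ = cohort
    return mb.run_cascade(matrix)


def variant_keys(frame: pd.DataFrame) -> set:
    return {(int(r.site), r.ref, r.alt) for r in frame.itertuples()}
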