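"""End-to-end pipeline runs: stage chaining, seed management, manifest.

Executes synth -> callvars -> spectrum -> abc -> dnds, each stage consuming
the previous stage's outputs. One global seed deterministically spawns
per-stage substreams, so identical config + seed gives identical output
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc import abc_reject, posterior_summary
from .annotation import load_annotation
from .cohort import generate_cohort, write_cohort
from .config import PipelineConfig, config_digest
from .counts import AlleleCountMatrix
from .dnds import compute_dnds
from .pipeline import run_cascade, write_vcf
from .spectra import vaf_spectrum

log = logging.getLogger("mitobottleneck")

STAGES = ("synth", "callvars", "spectrum", "abc", "dnds")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def write(self, path) -> None:
        """Atomic write (temp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, default=str))
        tmp.replace(path)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage substream seeds from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % 2**31)
        for stage, child in zip(STAGES, children)
    }


def run_pipeline(config: PipelineConfig, outdir=None) -> RunManifest:
    """Run all five stages; halts at the failing stage (partial outputs are
    retained for debugging)."""
    outdir = Path(outdir or config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = RunManifest(
        config_hash=config_digest(config),
        seed=config.seed,
        package_version=__version__,
    )
    state: dict = {"ann": load_annotation()}
    for stage in STAGES:
        t0 = time.perf_counter()
        log.info("stage %s starting", stage)
        try:
            outputs = _STAGE_FNS[stage](config, seeds[stage], outdir, state)
        except Exception as exc:  # noqa: BLE001 - report failing stage
            manifest.write(outdir / "manifest.json")
            raise StageError(stage, exc) from exc
        manifest.stages[stage] = {
            "seed": seeds[stage],
            "wall_clock_s": round(time.perf_counter() - t0, 3),
            "outputs": {name: _sha256(p) for name, p in outputs.items()},
        }
    manifest.write(outdir / "manifest.json")
    return manifest


def _stage_synth(config, seed, outdir, state):
    spec = config.cohort
    spec = type(spec)(**{**spec.__dict__, "seed": seed})
    matrix, truth = generate_cohort(spec, ann=state["ann"])
    state["matrix"], state["truth"] = matrix, truth
    paths = write_cohort(matrix, truth, outdir)
    return paths


def _stage_callvars(config, seed, outdir, state):
    matrix: AlleleCountMatrix = state.get("matrix") or AlleleCountMatrix.read(outdir)
    result = run_cascade(matrix, config.filters)
    state["cascade"] = result
    vcf = outdir / "somatic_variants.vcf"
    write_vcf(result.somatic, vcf)
    cvm_path = outdir / "cell_variant_vaf.tsv"
    result.cell_variant_matrix.vaf.to_csv(cvm_path, sep="\t")
    return {"vcf": vcf, "cell_variant_vaf": cvm_path}


def _stage_spectrum(config, seed, outdir, state):
    cvm = state["cascade"].cell_variant_matrix
    vafs = cvm.vaf.to_numpy().ravel()
    vafs = vafs[~np.isnan(vafs)]
    vafs = vafs[vafs > 0]
    spec = vaf_spectrum(vafs, n_cells=max(cvm.n_cells, 1))
    state["spectrum"] = spec
    path = outdir / "vaf_spectrum.tsv"
    spec.to_frame().to_csv(path, sep="\t", index=False)
    return {"spectrum": path}


def _stage_abc(config, seed, outdir, state):
    cfg = type(config.abc)(**{**config.abc.__dict__, "seed": seed})
    posterior = abc_reject(state["spectrum"], cfg, config.prior)
    state["posterior"] = posterior
    draws_path = outdir / "posterior_draws.tsv"
    posterior.draws.to_csv(draws_path, sep="\t", index=False)
    summary_path = outdir / "posterior_summary.json"
    summary_path.write_text(
        posterior_summary(posterior).to_json(orient="records", indent=2)
    )
    return {"posterior_draws": draws_path, "posterior_summary": summary_path}


def _stage_dnds(config, seed, outdir, state):
    somatic = state["cascade"].somatic
    cvm = state["cascade"].cell_variant_matrix
    mean_vaf = cvm.vaf.mean(axis=0, skipna=True)
    variants = somatic.variants.copy()
    variants["vaf"] = [
        mean_vaf.get(label, np.nan) for label in somatic.labels()
    ]
    strata = [tuple(s) for s in config.dnds.strata]
    table = compute_dnds(variants, state["ann"], strata=strata)
    path = outdir / "dnds.tsv"
    table.to_csv(path, sep="\t", index=False)
    return {"dnds": path}


_STAGE_FNS = {
    "synth": _stage_synth,
    "callvars": _stage_callvars,
    "spectrum": _stage_spectrum,
    "abc": _stage_abc,
    "dnds": _stage_dnds,
}
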