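"""Pipeline configuration: YAML loading, defaults, validation.

A config file has per-stage sections (cohort, filters, simulation, abc,
dnds) plus global keys (seed, outdir, log_level). Unknown keys are rejected
and every violation is reported at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .abc import ABCConfig, PriorSpec
from .cohort import CellTypeSpec, CohortSpec
from .pipeline import FilterConfig
from .wrightfisher import SimParams


class ConfigError(ValueError):
    """One or more configuration violations (all listed in the message)."""


_GLOBAL_KEYS = {"seed", "outdir", "log_level"}
_SECTIONS = {"cohort", "filters", "simulation", "abc", "prior", "dnds"}


@dataclass
class DnDsConfig:
    strata: list = field(default_factory=lambda: [[0.0, 0.1], [0.1, 0.9], [0.9, 1.0]])


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "mitobottleneck_run"
    log_level: str = "INFO"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    filters: FilterConfig = field(default_factory=FilterConfig)
    simulation: SimParams = field(default_factory=SimParams)
    abc: ABCConfig = field(default_factory=ABCConfig)
    prior: PriorSpec = field(default_factory=PriorSpec)
    dnds: DnDsConfig = field(default_factory=DnDsConfig)


def _build_section(cls, data: dict, section: str, problems: list):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        problems.append(f"{section}: unknown keys {sorted(unknown)}")
        data = {k: v for k, v in data.items() if k in known}
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        problems.append(f"{section}: {exc}")
        return cls()


def _coerce_cohort(data: dict) -> dict:
    data = dict(data)
    if "cell_types" in data:
        data["cell_types"] = [
            ct if isinstance(ct, CellTypeSpec) else CellTypeSpec(**ct)
            for ct in data["cell_types"]
        ]
    if "somatic_source" in data:
        data["somatic_source"] = {
            label: (src if not isinstance(src, dict) else SimParams(**src))
            for label, src in data["somatic_source"].items()
        }
    for key in ("site_blacklist", "substitution_blacklist", "artifact_sites"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key]) if key != "artifact_sites" else data[key]
    return data


def validate_config(source) -> PipelineConfig:
    """Build a PipelineConfig from a YAML file path, a YAML string or a
    dict; defaults fill anything unspecified. Raises ConfigError listing
    every violation at once.
    """
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        raw = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(str(source)) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")

    problems: list[str] = []
    unknown = set(raw) - _GLOBAL_KEYS - _SECTIONS
    if unknown:
        problems.append(f"unknown top-level keys {sorted(unknown)}")

    kwargs = {}
    for key in _GLOBAL_KEYS & set(raw):
        kwargs[key] = raw[key]
    if "seed" in kwargs and not isinstance(kwargs["seed"], int):
        problems.append(f"seed: must be an integer, got {kwargs['seed']!r}")
        kwargs.pop("seed")

    section_cls = {
        "cohort": CohortSpec,
        "filters": FilterConfig,
        "simulation": SimParams,
        "abc": ABCConfig,
        "prior": PriorSpec,
        "dnds": DnDsConfig,
    }
    for section, cls in section_cls.items():
        data = raw.get(section, {})
        if not isinstance(data, dict):
            problems.append(f"{section}: must be a mapping")
            continue
        if section == "cohort":
            data = _coerce_cohort(data)
        if section == "prior":
            data = {
                k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
            }
        kwargs[section] = _build_section(cls, data, section, problems)

    if problems:
        raise ConfigError("; ".join(problems))
    return PipelineConfig(**kwargs)


def config_digest(config: PipelineConfig) -> str:
    """Stable hash of the full config (for the run manifest)."""
    import hashlib
    import json

    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()
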