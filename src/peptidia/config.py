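"""Pipeline configuration: YAML in, validated dataclasses out.

Unknown keys are rejected (typos must not silently fall back to
defaults) and the fully-defaulted configuration is echoed into the run
log so every run records the values it actually used.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from peptidia.cohort import CohortConfig
from peptidia.containers import ValidationError
from peptidia.models import FAMILIES, ModelSpec
from peptidia.nested import SelectionSettings
from peptidia.preprocess import PreprocessConfig

KNOWN_BLOCKS = ("input", "cohort", "preprocess", "selection", "models", "evaluation", "interpret")


@dataclass
class InputConfig:
    """Optional ingest block; when absent the cohort is simulated."""

    matrix: str | None = None
    samples: str | None = None
    features: str | None = None
    dialect: str = "wide_tsv"
    log2_scale: bool = False


@dataclass
class EvaluationConfig:
    k_outer: int = 5
    k_inner: int = 5


@dataclass
class InterpretConfig:
    enabled: bool = True


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "peptidia_run"
    input: InputConfig = field(default_factory=InputConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionSettings = field(default_factory=SelectionSettings)
    models: tuple[str, ...] = FAMILIES
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    interpret: InterpretConfig = field(default_factory=InterpretConfig)

    def model_specs(self) -> list[ModelSpec]:
        return [ModelSpec(f) for f in self.models]


def _build(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown key(s) in {context!r}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(tuple(e) if isinstance(e, list) else e for e in v)
        coerced[f.name] = v
    return cls(**coerced)


def load_config(source) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML path or a dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source or {})
    if not isinstance(data, dict):
        raise ValidationError("top-level config must be a mapping")
    unknown = set(data) - set(KNOWN_BLOCKS) - {"seed", "out_dir"}
    if unknown:
        raise ValidationError(f"unknown top-level config key(s): {sorted(unknown)}")

    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "peptidia_run")),
        input=_build(InputConfig, data.get("input") or {}, "input"),
        cohort=_build(CohortConfig, data.get("cohort") or {}, "cohort"),
        preprocess=_build(PreprocessConfig, data.get("preprocess") or {}, "preprocess"),
        selection=_build(SelectionSettings, data.get("selection") or {}, "selection"),
        models=tuple(data.get("models") or FAMILIES),
        evaluation=_build(EvaluationConfig, data.get("evaluation") or {}, "evaluation"),
        interpret=_build(InterpretConfig, data.get("interpret") or {}, "interpret"),
    )
    bad = set(cfg.models) - set(FAMILIES)
    if bad:
        raise ValidationError(f"unknown model families: {sorted(bad)}")
    cfg.preprocess.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path) -> None:
    """Echo the fully-defaulted configuration (every value the run used)."""

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(cfg), fh, sort_keys=False)
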