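"""Pipeline configuration: one flat YAML file, every analysis threshold a
named key with its standard default."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml


@dataclass
class PipelineConfig:
    outdir: str = "splicescape_out"
    seed: int = 0

    # synthetic-data scenario (used when simulate=True)
    simulate: bool = True
    n_per_arm: int = 40
    timepoints: tuple[str, ...] = ("Pre", "P15M")
    n_events: int = 200
    n_das: int = 30
    delta: float = 1.5
    das_arm: str = "EE"
    noise_sd: float = 0.5
    rand_intercept_sd: float = 0.3
    mean_depth: float = 50.0

    # explicit input paths (used when simulate=False)
    inputs: dict = field(default_factory=dict)

    # analysis thresholds
    alpha: float = 0.05
    junction_cutoff: float = 5.0
    tpm_cutoff: float = 0.5
    min_sample_fraction: float = 0.2
    logit_adjust: float = 0.001
    rbp_window: int = 100
    bonferroni_alpha: float = 0.05
    fold_change_min: float = 1.5
    candidate_window: int = 200_000
    candidate_p_cutoff: float = 0.005
    looping_threshold: float = 0.9
    binding_threshold: float = 0.9
    n_draws: int = 1000

    # per-tissue covariate lists (tissue -> covariates kept in the model)
    covariates_by_tissue: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "alpha",
            "junction_cutoff",
            "tpm_cutoff",
            "min_sample_fraction",
            "logit_adjust",
            "candidate_p_cutoff",
            "looping_threshold",
            "binding_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "timepoints" in raw:
            raw["timepoints"] = tuple(raw["timepoints"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["timepoints"] = list(d["timepoints"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)
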