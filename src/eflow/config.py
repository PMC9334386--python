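"""Run configuration: schema-validated settings for the whole pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Every knob of a pipeline run, with documented defaults.

    The synthetic-network sizes and disturbance/noise settings define the
    study conditions; stage toggles let precomputed inputs stand in for
    earlier stages.  Unknown keys in a YAML file are a schema error raised
    before any compute.
    """

    seed: int = 0

    # synthetic network
    n_gauges: int = 200
    n_reaches: int = 1000
    n_regions: int = 4
    n_classes: int = 3
    reference_fraction: float = 0.4
    huc4_per_region: int = 2
    n_years: int = 15
    covariate_noise_sd: float = 0.1
    write_flows: bool = False
    flow_dialect: str = "csv"  # or "nwis-rdb"

    # metric engine
    water_year_start_month: int = 10
    colwell_states: int = 11

    # alteration
    unreliable_metrics: tuple[str, ...] = ("TA1", "TA2")
    seasonality_signed: bool = False
    reference_model_trees: int = 200

    # forest models
    n_trees: int = 200
    min_gauges_per_scope: int = 20
    scope_policy: str = "regional"  # or "us"
    model_mode: str = "regression"
    importance_us_only: bool = True  # permutation importance is the slow part

    # flow-ecology
    taus: tuple[float, ...] = (0.50, 0.75, 0.95)
    min_n_quantile: int = 30
    fish_true_threshold: float = 0.4
    fish_max_loss: float = 5.0
    fish_wedge_depth: float = 2.0

    # uncertainty
    use_rmse_bounds: bool = False
    literal_bound_rule: bool = False

    # stage toggles
    stages: tuple[str, ...] = (
        "synth", "metrics", "alter", "model", "ecology", "uncertainty"
    )

    def __post_init__(self) -> None:
        if self.scope_policy not in ("regional", "us"):
            raise ValueError("scope_policy must be 'regional' or 'us'")
        if not (0 < self.reference_fraction < 1):
            raise ValueError("reference_fraction must be in (0, 1)")
        if any(not (0 < t < 1) for t in self.taus):
            raise ValueError("taus must lie in (0, 1)")
        self.taus = tuple(float(t) for t in self.taus)
        self.stages = tuple(self.stages)
        self.unreliable_metrics = tuple(self.unreliable_metrics)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["taus"] = list(self.taus)
        data["stages"] = list(self.stages)
        data["unreliable_metrics"] = list(self.unreliable_metrics)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def config_hash(self) -> str:
        import hashlib

        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
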