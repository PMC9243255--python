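"""Pipeline configuration: a single validated YAML schema.

Every run resolves one :class:`PipelineConfig`; the resolved model (with
the seed) is written next to the outputs so any result can be traced back
to its inputs.  Validation happens before any computation and reports
offending field paths.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

__all__ = ["PipelineConfig", "load_config"]


class GeometryConfig(BaseModel):
    n_nodes: int = 100
    layout: str = "uniform_ball"
    radius_mm: float = 70.0
    n_networks: int = 4
    lambda_c: float = 0.18  # structural EDR decay, 1/mm


class StateConfig(BaseModel):
    label: str
    n_subjects: int = 5
    G: float = 1.0


class CohortConfig(BaseModel):
    regime: str = "hopf_forward"
    tr: float = 2.0
    duration_volumes: int = 200
    states: list[StateConfig] = Field(
        default_factory=lambda: [
            StateConfig(label="stateA", n_subjects=5, G=2.0),
            StateConfig(label="stateB", n_subjects=5, G=0.5),
        ]
    )

    @model_validator(mode="after")
    def _distinct_labels(self):
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("cohort.states: duplicate state labels")
        return self


class SignalConfig(BaseModel):
    low_hz: float = 0.008
    high_hz: float = 0.08
    order: int = 2
    edge_discard: int = 10


class TurbulenceConfig(BaseModel):
    lambda_min: float = 0.01
    lambda_max: float = 0.30
    lambda_step: float = 0.03
    dt_steps: int = 1
    r_min_mm: float = 8.0
    r_max_mm: float = 34.0
    n_bins: int = 20


class HopfConfig(BaseModel):
    a: float = -0.02
    noise_sd: float = 0.01
    dt: float = 0.1
    g_min: float = 0.0
    g_max: float = 3.0
    g_step: float = 0.25
    n_reps: int = 5
    duration_volumes: int = 200


class PerturbationConfig(BaseModel):
    kind: str = "periodic_force"
    F0: float = 5e-4
    a_low: float = -0.02
    a_high: float = 0.0
    n_trials: int = 10
    lambda_s: float = 0.12


class StatsConfig(BaseModel):
    q: float = 0.05
    top_q: float = 0.15


class PipelineConfig(BaseModel):
    seed: int = 0
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    signal: SignalConfig = Field(default_factory=SignalConfig)
    turbulence: TurbulenceConfig = Field(default_factory=TurbulenceConfig)
    hopf: HopfConfig = Field(default_factory=HopfConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @model_validator(mode="after")
    def _band_below_nyquist(self):
        nyquist = 0.5 / self.cohort.tr
        if self.signal.high_hz >= nyquist:
            raise ValueError(
                f"signal.high_hz={self.signal.high_hz} must be below the "
                f"Nyquist frequency {nyquist} implied by cohort.tr={self.cohort.tr}"
            )
        if not (0 < self.signal.low_hz < self.signal.high_hz):
            raise ValueError("signal.low_hz must satisfy 0 < low_hz < high_hz")
        return self

    def lambdas(self):
        from .turbulence import lambda_grid

        return lambda_grid(
            self.turbulence.lambda_min,
            self.turbulence.lambda_max,
            self.turbulence.lambda_step,
        )

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate the YAML config; ``overrides`` merge on top."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    for key, value in (overrides or {}).items():
        node = data
        *parents, leaf = key.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = value
    return PipelineConfig.model_validate(data)
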