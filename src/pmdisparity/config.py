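"""Configuration objects: subgroup scheme, simulation, buffer policy, run config."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

#: Partition -> ordered subgroup labels. Each partition's fractions sum to 1
#: within every cluster. Caste merges Scheduled Castes and Scheduled Tribes.
DEFAULT_SCHEME: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "wealth": ("richest", "richer", "middle", "poorer", "poorest"),
    "caste": ("general", "obc", "sc_st"),
}

#: Reference subgroup for each partition used in disparity comparisons.
DEFAULT_REFERENCES: dict[str, str] = {
    "gender": "male",
    "wealth": "richest",
    "caste": "general",
}

#: Baseline expected composition shares used by the synthetic generator.
DEFAULT_BASELINE_SHARES: dict[str, tuple[float, ...]] = {
    "gender": (0.5, 0.5),
    "wealth": (0.2, 0.2, 0.2, 0.2, 0.2),
    "caste": (0.3, 0.4, 0.3),
}

#: Settlement-class marginal proportions (classes 1..7: city, dense town,
#: semi-dense town, suburban/peri-urban, village, dispersed rural, no
#: settlement). First four collapse to urban (~30% of cells).
DEFAULT_SETTLEMENT_PROPS: tuple[float, ...] = (0.04, 0.05, 0.06, 0.15, 0.30, 0.30, 0.10)


def subgroup_columns(scheme: Mapping[str, tuple[str, ...]] | None = None) -> list[str]:
    scheme = scheme or DEFAULT_SCHEME
    return [g for groups in scheme.values() for g in groups]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey + concentration-field generator.

    Defaults emulate the study conditions: an annual-mean fine-particulate
    field with mean 51.5, sd 16.7 and range 28.6-86 ug/m3 at 1-km cells;
    survey clusters nested in districts within states carrying log-normal
    expansion weights around 5e5; Dirichlet subgroup compositions over
    gender, wealth-quintile and caste partitions.
    """

    n_states: int = 10
    districts_per_state: int = 5
    clusters_per_district: int = 20
    grid_shape: tuple[int, int] = (200, 200)
    cell_size_km: float = 1.0
    conc_mean: float = 51.5
    conc_sd: float = 16.7
    conc_range: tuple[float, float] = (28.6, 86.0)
    correlation_length_km: float = 15.0
    weight_lognormal_params: tuple[float, float] = (math.log(5e5), 0.5)
    dirichlet_concentration: float = 50.0
    tilt: float = 0.0
    tilt_partition: str = "wealth"
    tilt_subgroup: str = "richest"
    tilt_stratum: str | None = None  # None = both strata
    stratum_flip_rate: float = 0.28
    settlement_props: tuple[float, ...] = DEFAULT_SETTLEMENT_PROPS
    sdi_values: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_states", "districts_per_state", "clusters_per_district"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.conc_mean <= 0:
            raise ValueError("conc_mean must be positive")
        if self.conc_sd < 0:
            raise ValueError("conc_sd must be non-negative")
        lo, hi = self.conc_range
        if lo <= 0 or hi <= lo:
            raise ValueError("conc_range must satisfy 0 < min < max")
        if self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValueError("grid_shape must be positive")
        if self.cell_size_km <= 0 or self.correlation_length_km < 0:
            raise ValueError("cell sizes must be positive")
        if not 0.0 <= self.stratum_flip_rate < 1.0:
            raise ValueError("stratum_flip_rate must be in [0, 1)")
        if abs(sum(self.settlement_props) - 1.0) > 1e-9:
            raise ValueError("settlement_props must sum to 1")
        if self.tilt_partition not in DEFAULT_SCHEME:
            raise ValueError(f"unknown partition {self.tilt_partition!r}")
        if self.tilt_subgroup not in DEFAULT_SCHEME[self.tilt_partition]:
            raise ValueError(
                f"subgroup {self.tilt_subgroup!r} not in partition {self.tilt_partition!r}"
            )
        if self.sdi_values is not None and len(self.sdi_values) != self.n_states:
            raise ValueError("sdi_values must have one entry per state")

    @property
    def n_districts(self) -> int:
        return self.n_states * self.districts_per_state

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plainify(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**_tuplify(data, cls))


@dataclass(frozen=True)
class BufferPolicy:
    """Stratum-dependent circular buffer radii for exposure extraction.

    The survey convention is 2 km around urban clusters and 5 km around
    rural clusters; uniform 2-km and uniform 5-km variants serve as
    sensitivity settings.
    """

    urban_radius_km: float = 2.0
    rural_radius_km: float = 5.0
    empty_buffer_rule: str = "error"  # or "nearest_cell"
    name: str = "baseline"

    def __post_init__(self) -> None:
        if self.urban_radius_km <= 0 or self.rural_radius_km <= 0:
            raise ValueError("buffer radii must be positive")
        if self.empty_buffer_rule not in ("error", "nearest_cell"):
            raise ValueError("empty_buffer_rule must be 'error' or 'nearest_cell'")

    def radius_for(self, stratum: str) -> float:
        if stratum == "urban":
            return self.urban_radius_km
        if stratum == "rural":
            return self.rural_radius_km
        raise ValueError(f"unknown stratum {stratum!r}")


#: The baseline + two sensitivity settings used throughout.
DEFAULT_POLICIES: tuple[BufferPolicy, ...] = (
    BufferPolicy(2.0, 5.0, name="baseline"),
    BufferPolicy(2.0, 2.0, name="uniform2"),
    BufferPolicy(5.0, 5.0, name="uniform5"),
)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration for a two-round synthetic run."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    round2_tilt: float | None = None  # None = same tilt as round 1
    round2_conc_mean: float | None = None
    round2_conc_sd: float | None = None
    policies: tuple[BufferPolicy, ...] = DEFAULT_POLICIES
    baseline_policy: str = "baseline"
    references: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REFERENCES))
    alpha: float = 0.1
    negligible_threshold: float = 0.01
    levels: tuple[str, ...] = ("national", "sdi_region", "state")
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.policies]
        if names.count(self.baseline_policy) != 1:
            raise ValueError("exactly one policy must match baseline_policy")
        for partition, ref in self.references.items():
            if ref not in DEFAULT_SCHEME.get(partition, ()):
                raise ValueError(f"reference {ref!r} not in partition {partition!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @property
    def baseline(self) -> BufferPolicy:
        return next(p for p in self.policies if p.name == self.baseline_policy)


def _plainify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _plainify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plainify(v) for v in obj]
    return obj


def _tuplify(data: dict, cls: type) -> dict:
    tuple_fields = {
        "grid_shape", "conc_range", "weight_lognormal_params",
        "settlement_props", "sdi_values",
    }
    out = {}
    for k, v in data.items():
        if k in tuple_fields and isinstance(v, list):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out
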