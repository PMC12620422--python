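"""Run configuration for the end-to-end pipeline (JSON round-trippable)."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, in one serialisable object.

    The named constants surface the conventions that change results:
    covariance normalisation (1/N), the per-coordinate vs per-node error
    metric, the cortical density threshold (g/cm^3), the element erosion
    strain, the HU calibration reference densities and the trendline
    significance threshold.  ``grid_overrides`` pins individual anthropometric
    grid cells, keyed "predictor:level" (e.g. ``"stature:-2"``).
    """

    cohort_dir: str = "."
    output_dir: str = "out"
    seed: int = 0
    align: bool = True
    covariance_convention: str = "1/N"
    per_node_error_metric: bool = False
    cortical_threshold: float = 1.4
    erosion_strain: float = 0.2
    significance_threshold: float = 0.01
    hu_reference_densities: tuple[float, float, float] = (-840.0, -80.0, 30.0)
    modulus_law: tuple[float, float] = (6850.0, 1.49)
    yield_law: tuple[float, float] = (38.5, 1.48)
    ultimate_law: tuple[float, float] = (42.9, 1.56)
    grid_overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.cortical_threshold <= 0:
            raise ValueError("cortical_threshold must be > 0")
        if self.erosion_strain <= 0:
            raise ValueError("erosion_strain must be > 0")
        if not 0 < self.significance_threshold < 1:
            raise ValueError("significance_threshold must be in (0, 1)")
        if self.covariance_convention not in ("1/N", "1/(N-1)"):
            raise ValueError("covariance_convention must be '1/N' or '1/(N-1)'")

    # -- (de)serialisation ---------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["hu_reference_densities"] = list(self.hu_reference_densities)
        d["modulus_law"] = list(self.modulus_law)
        d["yield_law"] = list(self.yield_law)
        d["ultimate_law"] = list(self.ultimate_law)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("hu_reference_densities", "modulus_law", "yield_law", "ultimate_law"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def digest(self) -> str:
        """Stable hash stamped onto every artifact of a run."""
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def parsed_grid_overrides(self) -> dict[tuple[str, int], float]:
        out: dict[tuple[str, int], float] = {}
        for key, value in self.grid_overrides.items():
            name, level = key.split(":")
            out[(name, int(level))] = float(value)
        return out
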