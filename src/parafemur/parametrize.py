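"""Anthropometric parametrization: multilinear regression of principal values
on (stature, BMI, age) and generation of new femur instances.

Each mode's principal values are regressed independently by ordinary least
squares on an explicit intercept plus the three raw predictors — an
unregularized convex problem, so refits are deterministic and any two
well-posed solvers agree.  Predicted contribution factors b then synthesise a
new instance s_new = s_mean + sum_j b_j pc_j per channel.

The 13-row anthropometric grid varies one predictor at a time to mean and
+/-1, +/-2 cohort SD while holding the others at their means.  Individual
cells can be pinned to explicit values through a clamp-override map (for
reproducing published grids whose extreme cells were clamped to cohort
bounds); overrides are always explicit, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .mesh import AnthropometricRecord, CorrespondenceError, FemurSample
from .ssam import StatisticalModel, devectorize, reconstruct

__all__ = [
    "RegressionModel",
    "PredictorStats",
    "AnthroGrid",
    "RegressionError",
    "fit_regression",
    "predict_contribution",
    "generate_instance",
    "build_anthro_grid",
]

PREDICTORS = ("stature", "bmi", "age")


class RegressionError(ValueError):
    """Raised when the anthropometric design matrix is unusable."""


@dataclass(frozen=True)
class PredictorStats:
    """Cohort mean and SD per predictor (SD is the sample SD, ddof=1)."""

    mean: dict[str, float]
    sd: dict[str, float]

    @classmethod
    def from_records(cls, records: Sequence[AnthropometricRecord]) -> "PredictorStats":
        X = np.array([[r.stature, r.bmi, r.age] for r in records], dtype=np.float64)
        return cls(mean={k: float(m) for k, m in zip(PREDICTORS, X.mean(axis=0))},
                   sd={k: float(s) for k, s in zip(PREDICTORS, X.std(axis=0, ddof=1))})


@dataclass(frozen=True)
class RegressionModel:
    """Per-mode OLS coefficients B (K, 4): intercept, stature, bmi, age."""

    coefficients: np.ndarray
    predictor_stats: PredictorStats
    channel: str = "shape"

    @property
    def n_modes(self) -> int:
        return self.coefficients.shape[0]


def _design_matrix(records: Sequence[AnthropometricRecord]) -> np.ndarray:
    X = np.array([[1.0, r.stature, r.bmi, r.age] for r in records], dtype=np.float64)
    return X


def fit_regression(pv_matrix: np.ndarray, anthro_records: Sequence[AnthropometricRecord],
                   channel: str = "shape", standardize: bool = False) -> RegressionModel:
    """Fit the multilinear pv ~ 1 + stature + bmi + age regression per mode.

    ``standardize=True`` centers/scales predictors before fitting and folds
    the scaling back into raw-unit coefficients; the fitted values are
    identical either way (offered for numerical comparability only).
    """
    pv = np.asarray(pv_matrix, dtype=np.float64)
    if pv.ndim != 2 or pv.shape[0] != len(anthro_records):
        raise ValueError("pv_matrix must be (N, K) matching the anthropometric records")
    N = pv.shape[0]
    if N < 5:
        raise RegressionError(f"need N >= 5 subjects to fit 4 coefficients, got {N}")
    X = _design_matrix(anthro_records)
    for col, name in zip(X[:, 1:].T, PREDICTORS):
        if np.ptp(col) == 0:
            raise RegressionError(f"predictor {name!r} is constant; design is rank-deficient")
    if np.linalg.matrix_rank(X) < 4:
        raise RegressionError("anthropometric design matrix is rank-deficient")
    stats_ = PredictorStats.from_records(anthro_records)
    if standardize:
        mu = np.array([stats_.mean[k] for k in PREDICTORS])
        sd = np.array([stats_.sd[k] for k in PREDICTORS])
        Z = X.copy()
        Z[:, 1:] = (X[:, 1:] - mu) / sd
        coef_z, *_ = np.linalg.lstsq(Z, pv, rcond=None)
        coef = coef_z.copy()
        coef[1:, :] = coef_z[1:, :] / sd[:, None]
        coef[0, :] = coef_z[0, :] - (mu / sd) @ coef_z[1:, :]
    else:
        coef, *_ = np.linalg.lstsq(X, pv, rcond=None)
    return RegressionModel(coefficients=coef.T, predictor_stats=stats_, channel=channel)


def predict_contribution(model: RegressionModel, stature: float, bmi: float,
                         age: float) -> np.ndarray:
    """Contribution factors b = B @ (1, stature, bmi, age)."""
    x = np.array([1.0, stature, bmi, age], dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("anthropometric inputs must be finite")
    return model.coefficients @ x


def generate_instance(shape_model: StatisticalModel, appearance_model: StatisticalModel,
                      shape_reg: RegressionModel, appearance_reg: RegressionModel,
                      anthro: AnthropometricRecord, template: FemurSample) -> FemurSample:
    """Synthesize a parametric femur for the given anthropometrics.

    Both channels are reconstructed from their regression-predicted
    contribution factors and devectorized onto the template's topology; the
    returned sample carries ``anthro``.
    """
    if (shape_model.topology_hash and appearance_model.topology_hash
            and shape_model.topology_hash != appearance_model.topology_hash):
        raise CorrespondenceError("shape and appearance models disagree in topology")
    if (shape_model.topology_hash
            and shape_model.topology_hash != template.mesh.topology_hash):
        raise CorrespondenceError("template topology differs from the model's")
    b_shape = predict_contribution(shape_reg, anthro.stature, anthro.bmi, anthro.age)
    b_app = predict_contribution(appearance_reg, anthro.stature, anthro.bmi, anthro.age)
    s_new = reconstruct(b_shape, shape_model)
    d_new = reconstruct(b_app, appearance_model)
    sample = devectorize(s_new, template, "shape")
    sample = devectorize(d_new, sample, "appearance")
    return replace(sample, anthro=anthro)


@dataclass(frozen=True)
class AnthroGrid:
    """The 13 one-at-a-time anthropometric targets: cohort mean plus
    {-2, -1, +1, +2} SD per predictor, off-varied predictors at their means."""

    records: tuple[AnthropometricRecord, ...]
    overrides: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) != 13:
            raise ValueError(f"anthropometric grid must have 13 rows, got {len(self.records)}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return 13

    def value(self, predictor: str, level: int) -> float:
        """Grid value of ``predictor`` at ``level`` in {-2,-1,0,+1,+2}."""
        label = "mean" if level == 0 else f"{predictor}{level:+d}sd"
        for r in self.records:
            if r.subject_id == label:
                return float(getattr(r, predictor))
        raise KeyError(label)


def build_anthro_grid(predictor_stats: PredictorStats,
                      overrides: Mapping[tuple[str, int], float] | None = None) -> AnthroGrid:
    """Construct the 13-row grid from cohort predictor means/SDs.

    Values follow the pure formula mean + level*SD.  ``overrides`` maps
    (predictor, level) -> value to pin individual cells (e.g. clamping an
    extreme cell to a cohort bound); levels are in {-2, -1, +1, +2}.
    """
    overrides = dict(overrides or {})
    means = predictor_stats.mean
    sds = predictor_stats.sd
    for name in PREDICTORS:
        if sds[name] <= 0:
            raise ValueError(f"predictor {name!r} has SD <= 0")
    for (name, level) in overrides:
        if name not in PREDICTORS or level not in (-2, -1, 1, 2):
            raise KeyError(f"invalid override target ({name!r}, {level})")

    def rec(label: str, **kw) -> AnthropometricRecord:
        vals = {k: means[k] for k in PREDICTORS}
        vals.update(kw)
        return AnthropometricRecord(subject_id=label, **vals)

    records = [rec("mean")]
    for name in PREDICTORS:
        for level in (-2, -1, 1, 2):
            value = overrides.get((name, level), means[name] + level * sds[name])
            records.append(rec(f"{name}{level:+d}sd", **{name: value}))
    return AnthroGrid(records=tuple(records), overrides=overrides)
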