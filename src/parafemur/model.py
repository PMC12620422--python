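"""The parametric femur model: cohort in, fitted shape/appearance PCA +
anthropometric regressions out.

:class:`ParametricFemurModel` is constructed from a corresponded cohort and
``fit()`` returns a :class:`ParametricFemurResults` carrying both channel
models, the multilinear regressions, compactness diagnostics and a
``summary()``; instance generation, the anthropometric grid, morphometric
evaluation against the training cohort (weighted sum of differences) and the
leave-one-out redundancy analysis hang off the results object.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from . import evaluation as ev
from .material import MaterialLawConfig, classify_tissue
from .mesh import AnthropometricRecord, CorrespondenceError, FemurSample, align_cohort
from .morphometrics import AxisLandmarks, Trendline, fit_trendline, measure_sample
from .parametrize import (
    AnthroGrid,
    PredictorStats,
    RegressionModel,
    build_anthro_grid,
    fit_regression,
    generate_instance,
)
from .ssam import (
    CompactnessCurve,
    StatisticalModel,
    build_model,
    compactness,
    pv_anthro_correlations,
    vectorize,
)

__all__ = ["ParametricFemurModel", "ParametricFemurResults", "LeaveOneOutResult"]

#: the morphological trendline pairs used in the evaluation statistic:
#: (label, measure attribute, predictor, predictor transform)
MORPHOLOGY_PAIRS = (
    ("femur_length~stature", "femur_length", "stature", 0.01),  # stature in m
    ("ccd_angle~age", "ccd_angle", "age", 1.0),
    ("cortical_thickness~age", "anterior_midshaft_cortical_thickness", "age", 1.0),
)


class ParametricFemurModel:
    """Statistical shape+appearance model parametrized by stature, BMI, age.

    Parameters
    ----------
    samples : corresponded cohort (identical topology, one density field and
        one anthropometric record per subject).
    align : rigidly co-align the cohort to ``reference_index`` before
        modelling.  Disable for cohorts that are already co-registered
        (e.g. synthetically generated in a common frame).
    """

    def __init__(self, samples: Sequence[FemurSample], *, align: bool = True,
                 reference_index: int = 0):
        samples = list(samples)
        if len(samples) < 2:
            raise ValueError("need a cohort of at least 2 samples")
        hashes = {s.mesh.topology_hash for s in samples}
        if len(hashes) != 1:
            raise CorrespondenceError("cohort meshes do not share a topology")
        self.samples = samples
        self.align = align
        self.reference_index = reference_index

    @property
    def anthro(self) -> list[AnthropometricRecord]:
        return [s.anthro for s in self.samples]

    def fit(self) -> "ParametricFemurResults":
        samples = (align_cohort(self.samples, self.reference_index)
                   if self.align else self.samples)
        topo = samples[0].mesh.topology_hash
        shape_vectors = np.array([vectorize(s, "shape") for s in samples])
        app_vectors = np.array([vectorize(s, "appearance") for s in samples])
        shape_model = build_model(shape_vectors, "shape", topology_hash=topo)
        app_model = build_model(app_vectors, "appearance", topology_hash=topo)
        anthro = [s.anthro for s in samples]
        shape_reg = fit_regression(shape_model.pv_matrix, anthro, channel="shape")
        app_reg = fit_regression(app_model.pv_matrix, anthro, channel="appearance")
        return ParametricFemurResults(
            model=self,
            aligned_samples=samples,
            shape_model=shape_model,
            appearance_model=app_model,
            shape_regression=shape_reg,
            appearance_regression=app_reg,
            compactness_shape=compactness(shape_model, shape_vectors),
            compactness_appearance=compactness(app_model, app_vectors),
        )


@dataclass
class LeaveOneOutResult:
    max_mean_abs_coordinate_error: float  # mm
    max_mean_abs_density_error: float  # g/cm^3
    per_fold: "pd.DataFrame"


@dataclass
class ParametricFemurResults:
    """Fitted models + regressions; generation and diagnostics live here."""

    model: ParametricFemurModel
    aligned_samples: list[FemurSample]
    shape_model: StatisticalModel
    appearance_model: StatisticalModel
    shape_regression: RegressionModel
    appearance_regression: RegressionModel
    compactness_shape: CompactnessCurve
    compactness_appearance: CompactnessCurve

    # -- basic accessors ----------------------------------------------------
    @property
    def predictor_stats(self) -> PredictorStats:
        return self.shape_regression.predictor_stats

    @property
    def template(self) -> FemurSample:
        return self.aligned_samples[0]

    def pv_correlations(self, channel: str = "shape"):
        model = self.shape_model if channel == "shape" else self.appearance_model
        return pv_anthro_correlations(model, [s.anthro for s in self.aligned_samples])

    # -- generation -----------------------------------------------------------
    def generate(self, stature: float, bmi: float, age: float,
                 subject_id: str = "parametric") -> FemurSample:
        anthro = AnthropometricRecord(subject_id=subject_id, stature=stature,
                                      bmi=bmi, age=age)
        return generate_instance(self.shape_model, self.appearance_model,
                                 self.shape_regression, self.appearance_regression,
                                 anthro, self.template)

    def anthro_grid(self, overrides: Mapping[tuple[str, int], float] | None = None
                    ) -> AnthroGrid:
        return build_anthro_grid(self.predictor_stats, overrides)

    def generate_grid(self, grid: AnthroGrid | Sequence[AnthropometricRecord] | None = None
                      ) -> list[FemurSample]:
        records = list(grid) if grid is not None else list(self.anthro_grid())
        return [generate_instance(self.shape_model, self.appearance_model,
                                  self.shape_regression, self.appearance_regression,
                                  rec, self.template) for rec in records]

    # -- morphometrics + evaluation -------------------------------------------
    def _classes(self, sample: FemurSample, shell_element_ids,
                 config: MaterialLawConfig) -> np.ndarray:
        return classify_tissue(sample.density, shell_element_ids, config)

    def morphometrics_table(self, samples: Sequence[FemurSample],
                            landmarks: AxisLandmarks, shell_element_ids,
                            config: MaterialLawConfig | None = None):
        import pandas as pd

        config = config or MaterialLawConfig()
        rows = []
        for s in samples:
            classes = self._classes(s, shell_element_ids, config)
            rec = measure_sample(s.mesh, classes, landmarks)
            rows.append((s.anthro.subject_id, s.anthro.stature, s.anthro.bmi,
                         s.anthro.age, rec.femur_length, rec.ccd_angle,
                         rec.anterior_midshaft_cortical_thickness,
                         rec.midshaft_cortical_area))
        return pd.DataFrame(rows, columns=[
            "subject_id", "stature", "bmi", "age", "femur_length", "ccd_angle",
            "cortical_thickness", "midshaft_cortical_area"])

    def morphology_trendlines(self, table) -> dict[str, Trendline]:
        """The three evaluation trendlines from a morphometrics table."""
        out = {}
        for label, attr_col, predictor, xscale in MORPHOLOGY_PAIRS:
            col = {"femur_length": "femur_length", "ccd_angle": "ccd_angle",
                   "anterior_midshaft_cortical_thickness": "cortical_thickness"}[attr_col]
            x = table[predictor].to_numpy() * xscale
            y = table[col].to_numpy()
            out[label] = fit_trendline(x, y)
        return out

    def evaluate_morphology(self, landmarks: AxisLandmarks, shell_element_ids,
                            config: MaterialLawConfig | None = None,
                            grid: AnthroGrid | None = None) -> ev.EvaluationReport:
        """Weighted-sum-of-differences comparison of the parametric model's
        morphological trends against the training cohort's.

        Reference slopes come from univariate trendlines over the training
        samples; parametric slopes from trendlines over the grid instances
        that vary the pair's predictor (the other predictors held at cohort
        means).  Normalisation ranges are the reference cohort's observed
        predictor and measure ranges.
        """
        grid = grid or self.anthro_grid()
        ref_table = self.morphometrics_table(self.aligned_samples, landmarks,
                                             shell_element_ids, config)
        instances = self.generate_grid(grid)
        par_table = self.morphometrics_table(instances, landmarks,
                                             shell_element_ids, config)
        ref_lines = self.morphology_trendlines(ref_table)

        pairs = []
        for label, attr_col, predictor, xscale in MORPHOLOGY_PAIRS:
            col = {"femur_length": "femur_length", "ccd_angle": "ccd_angle",
                   "anterior_midshaft_cortical_thickness": "cortical_thickness"}[attr_col]
            varied = par_table[par_table["subject_id"].str.startswith(predictor)
                               | (par_table["subject_id"] == "mean")]
            par_line = fit_trendline(varied[predictor].to_numpy() * xscale,
                                     varied[col].to_numpy())
            x_ref = ref_table[predictor].to_numpy() * xscale
            y_ref = ref_table[col].to_numpy()
            pairs.append(ev.SlopePair(
                label=label,
                reference_slope=ref_lines[label].slope,
                parametric_slope=par_line.slope,
                x_ref_range=(float(x_ref.min()), float(x_ref.max())),
                y_ref_range=(float(y_ref.min()), float(y_ref.max())),
            ))
        return ev.wsd(pairs)

    # -- redundancy -----------------------------------------------------------
    def leave_one_out(self, grid: AnthroGrid | Sequence[AnthropometricRecord] | None = None
                      ) -> LeaveOneOutResult:
        """Rebuild the whole parametrization N times leaving one subject out.

        The held-out rebuilds regenerate the same fixed anthropometric
        targets (default: the mean and +/-1 SD one-at-a-time rows of the
        full-cohort grid, 7 instances) and are compared against the
        full-cohort instances; reported are the maximum mean absolute nodal
        coordinate error and density error over all folds and targets.
        """
        import pandas as pd

        if grid is None:
            full = self.anthro_grid()
            records = [r for r in full
                       if r.subject_id == "mean" or r.subject_id.endswith("1sd")]
        else:
            records = list(grid)
        if not records:
            raise ValueError("empty anthropometric target list")
        reference_instances = self.generate_grid(records)
        samples = self.aligned_samples
        if len(samples) < 3:
            raise ValueError("leave-one-out needs a cohort of at least 3")
        rows = []
        for i in range(len(samples)):
            reduced = samples[:i] + samples[i + 1:]
            res = ParametricFemurModel(reduced, align=False).fit()
            fold_geo = 0.0
            fold_den = 0.0
            for rec, full_inst in zip(records, reference_instances):
                inst = res.generate(rec.stature, rec.bmi, rec.age, rec.subject_id)
                geo = float(np.abs(inst.mesh.nodes - full_inst.mesh.nodes).mean())
                den = float(np.abs(inst.density.values - full_inst.density.values).mean())
                fold_geo = max(fold_geo, geo)
                fold_den = max(fold_den, den)
            rows.append((samples[i].anthro.subject_id, fold_geo, fold_den))
        df = pd.DataFrame(rows, columns=["held_out", "max_mae_coords", "max_mae_density"])
        return LeaveOneOutResult(
            max_mean_abs_coordinate_error=float(df["max_mae_coords"].max()),
            max_mean_abs_density_error=float(df["max_mae_density"].max()),
            per_fold=df,
        )

    # -- reporting -----------------------------------------------------------
    def summary(self) -> str:
        sm, am = self.shape_model, self.appearance_model
        stats = self.predictor_stats
        var_share = sm.singular_values / sm.singular_values.sum()
        var_share_a = am.singular_values / am.singular_values.sum()
        lines = [
            "Parametric femur model (statistical shape + appearance)",
            "=" * 60,
            f"cohort size:             {sm.cohort_size}",
            f"shape dimension:         {sm.dim} (3 x nodes)",
            f"appearance dimension:    {am.dim} (elements)",
            f"retained modes:          {sm.n_modes} shape / {am.n_modes} appearance",
            f"covariance convention:   1/N",
            f"aligned:                 {self.model.align}",
            "",
            "predictors (cohort mean +/- SD):",
        ]
        for name in ("stature", "bmi", "age"):
            lines.append(f"  {name:<8} {stats.mean[name]:8.2f} +/- {stats.sd[name]:.2f}")
        lines.append("")
        lines.append("variance share of leading modes (shape | appearance):")
        for j in range(min(5, sm.n_modes)):
            va = var_share_a[j] if j < am.n_modes else float("nan")
            lines.append(f"  PC{j + 1}: {var_share[j]:6.1%} | {va:6.1%}")
        lines.append("")
        lines.append(f"full-rank reconstruction error (shape):      "
                     f"{self.compactness_shape.errors[-1]:.2e} mm")
        lines.append(f"full-rank reconstruction error (appearance): "
                     f"{self.compactness_appearance.errors[-1]:.2e} g/cm^3")
        return "\n".join(lines)
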