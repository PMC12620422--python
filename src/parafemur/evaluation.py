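"""Weighted-sum-of-differences comparison of trendline slopes.

To compare how a parametric model and a reference cohort respond to the same
predictor, the trendline slopes of matching (output, input) pairs are first
min-max normalised with the ranges observed in the reference set,

    k_norm = k * (x_ref_max - x_ref_min) / (y_ref_max - y_ref_min),

which removes units so heterogeneous pairs (mm per m of stature, degrees per
year of age, ...) become commensurable.  Per pair, the absolute difference of
normalised slopes is weighted by that pair's share of the largest absolute
normalised slope (reference or parametric, whichever is larger), the weights
summing to one, and the weighted differences are summed into the WSD.  The
weighting penalises disagreement on strong trends over disagreement on weak
ones and avoids the blow-up of naive percentage differences when a reference
slope is near zero.  Finally

    Diff% = 100 * WSD / (max - min of the reference normalised slopes).

All computation is in full precision; ``render_table`` offers a 3-decimal
display for publication-style tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SlopePair",
    "EvaluationReport",
    "EvaluationError",
    "normalize_slope",
    "wsd",
    "percent_diff",
    "render_table",
]


class EvaluationError(ValueError):
    """Raised when the comparison statistic is undefined on the input."""


@dataclass(frozen=True)
class SlopePair:
    """One matched (output y, input x) trendline pair.

    Ranges are those observed in the reference femur set; when slopes are
    supplied already normalised, ranges may be omitted (left at the unit
    ratio).
    """

    label: str
    reference_slope: float
    parametric_slope: float
    x_ref_range: tuple[float, float] = (0.0, 1.0)
    y_ref_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if not self.x_ref_range[1] > self.x_ref_range[0]:
            raise EvaluationError(f"{self.label}: degenerate x reference range")
        if not self.y_ref_range[1] > self.y_ref_range[0]:
            raise EvaluationError(f"{self.label}: degenerate (zero) y reference range")


def normalize_slope(pair: SlopePair) -> tuple[float, float]:
    """Min-max normalised (reference, parametric) slopes of one pair."""
    ratio = ((pair.x_ref_range[1] - pair.x_ref_range[0])
             / (pair.y_ref_range[1] - pair.y_ref_range[0]))
    return pair.reference_slope * ratio, pair.parametric_slope * ratio


@dataclass(frozen=True)
class EvaluationReport:
    labels: tuple[str, ...]
    reference_norm: np.ndarray
    parametric_norm: np.ndarray
    diff_norm: np.ndarray  # |ref - par| per pair
    max_norm: np.ndarray  # per-pair max(|ref|, |par|)
    weights: np.ndarray  # max_norm normalised to sum 1
    weighted_diff: np.ndarray
    wsd: float
    ref_norm_range: tuple[float, float]  # (min, max) of reference_norm
    diff_percent: float


def wsd(pairs: Sequence[SlopePair], pre_normalized: bool = False) -> EvaluationReport:
    """Weighted sum of differences over matched trendline-slope pairs.

    With ``pre_normalized=True`` the pairs' slopes are taken as already
    min-max normalised and the stored ranges are ignored.
    """
    if len(pairs) == 0:
        raise EvaluationError("need at least one slope pair")
    if pre_normalized:
        ref = np.array([p.reference_slope for p in pairs], dtype=np.float64)
        par = np.array([p.parametric_slope for p in pairs], dtype=np.float64)
    else:
        norms = [normalize_slope(p) for p in pairs]
        ref = np.array([r for r, _ in norms])
        par = np.array([q for _, q in norms])
    diff = np.abs(ref - par)
    max_norm = np.maximum(np.abs(ref), np.abs(par))
    total = max_norm.sum()
    if total == 0:
        raise EvaluationError("all normalised slopes are zero; weights undefined")
    weights = max_norm / total
    weighted = diff * weights
    ref_min, ref_max = float(ref.min()), float(ref.max())
    wsd_value = float(weighted.sum())
    if ref_max > ref_min:
        diff_percent = 100.0 * wsd_value / (ref_max - ref_min)
    else:
        diff_percent = float("nan")
    return EvaluationReport(
        labels=tuple(p.label for p in pairs),
        reference_norm=ref, parametric_norm=par, diff_norm=diff,
        max_norm=max_norm, weights=weights, weighted_diff=weighted,
        wsd=wsd_value, ref_norm_range=(ref_min, ref_max),
        diff_percent=diff_percent,
    )


def percent_diff(report: EvaluationReport) -> float:
    """100 * WSD / (max - min of the *reference* normalised slopes)."""
    ref_min, ref_max = report.ref_norm_range
    if not ref_max > ref_min:
        raise EvaluationError("degenerate reference normalised-slope range")
    return 100.0 * report.wsd / (ref_max - ref_min)


def render_table(report: EvaluationReport, decimals: int = 3) -> str:
    """Publication-style text table (values rounded to ``decimals``)."""
    header = f"{'pair':<18}{'ref':>9}{'par':>9}{'w':>9}{'w.err':>9}"
    lines = [header]
    for i, label in enumerate(report.labels):
        lines.append(
            f"{label:<18}"
            f"{report.reference_norm[i]:>9.{decimals}f}"
            f"{report.parametric_norm[i]:>9.{decimals}f}"
            f"{report.weights[i]:>9.{decimals}f}"
            f"{report.weighted_diff[i]:>9.{decimals}f}"
        )
    lines.append(f"WSD = {report.wsd:.{decimals}f}")
    lines.append(f"Diff% = {report.diff_percent:.{decimals}f}")
    return "\n".join(lines)
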