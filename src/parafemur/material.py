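"""QCT density calibration and density-to-material-property mapping.

Hounsfield units are calibrated to equivalent hydroxyapatite density with the
phantomless muscle-adipose-air strategy: the median HU of three soft-tissue
reference regions is regressed against their published equivalent densities
(air -840, adipose -80, muscle 30 mgHA/cm^3).  Per-element mechanical
properties then follow configurable power laws E = a * rho^b (and likewise for
yield and ultimate stress), with a density threshold separating cortical from
trabecular tissue and a surface-shell override that forces thin outer-surface
elements to cortical regardless of density.

The power-law coefficients shipped as defaults are commonly used femoral
density-property relations; they are configuration, not ground truth, and are
expected to be overridden to match whichever constitutive chain a study uses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mesh import DensityField

__all__ = [
    "CalibrationLine",
    "MaterialLawConfig",
    "MaterialCard",
    "CalibrationError",
    "fit_hu_calibration",
    "check_stitch_continuity",
    "classify_tissue",
    "compute_material",
    "export_material_csv",
    "export_lsdyna_cards",
    "HU_REFERENCE_DENSITIES",
]

#: Equivalent hydroxyapatite densities (mg/cm^3) of the three calibration
#: tissues: air, adipose, muscle.
HU_REFERENCE_DENSITIES = np.array([-840.0, -80.0, 30.0])


class CalibrationError(ValueError):
    """Raised when the HU calibration inputs are inconsistent."""


@dataclass(frozen=True)
class CalibrationLine:
    """HU -> mgHA/cm^3 least-squares line through the three tissue medians."""

    slope: float  # (mg/cm^3) per HU
    intercept: float  # mg/cm^3
    roi_medians: tuple[float, float, float]  # air, adipose, muscle (HU)
    residuals: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __call__(self, hu: np.ndarray | float) -> np.ndarray | float:
        return self.slope * np.asarray(hu, dtype=np.float64) + self.intercept


def fit_hu_calibration(roi_medians) -> CalibrationLine:
    """Fit the muscle-adipose-air HU calibration line.

    Parameters
    ----------
    roi_medians : sequence of 3 floats
        Median HU of the air, adipose and muscle ROIs, in that order.
        They must be finite and strictly increasing (air < adipose < muscle);
        anything else indicates mislabeled ROIs.
    """
    medians = np.asarray(roi_medians, dtype=np.float64)
    if medians.shape != (3,) or not np.all(np.isfinite(medians)):
        raise CalibrationError("need exactly three finite ROI medians (air, adipose, muscle)")
    if not (medians[0] < medians[1] < medians[2]):
        raise CalibrationError(
            f"ROI medians must increase air < adipose < muscle, got {medians.tolist()}"
        )
    # Least squares of a line through 3 (HU, mgHA) points.
    A = np.column_stack([medians, np.ones(3)])
    coef, *_ = np.linalg.lstsq(A, HU_REFERENCE_DENSITIES, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = HU_REFERENCE_DENSITIES - (slope * medians + intercept)
    return CalibrationLine(slope=slope, intercept=intercept,
                           roi_medians=tuple(medians.tolist()),
                           residuals=tuple(resid.tolist()))


def check_stitch_continuity(slab_mean_hu, threshold_hu: float = 30.0) -> tuple[float, bool]:
    """Max absolute HU deviation between adjacent stitched scan slabs.

    Returns ``(max_deviation, passed)`` where ``passed`` is True when the
    deviation does not exceed ``threshold_hu``.
    """
    slabs = np.asarray(slab_mean_hu, dtype=np.float64)
    if slabs.ndim != 1 or slabs.size < 2:
        raise ValueError("need mean HU for at least two adjacent slabs")
    deviation = float(np.max(np.abs(np.diff(slabs))))
    return deviation, deviation <= threshold_hu


@dataclass(frozen=True)
class PowerLaw:
    """property = a * rho^b, rho in g/cm^3."""

    a: float
    b: float

    def __call__(self, rho: np.ndarray) -> np.ndarray:
        return self.a * np.power(rho, self.b)


@dataclass(frozen=True)
class MaterialLawConfig:
    """Density-property laws and classification constants.

    Defaults: E = 6850 * rho^1.49 MPa (a widely used femoral apparent-density
    modulus relation), yield 38.5 * rho^1.48 MPa, ultimate 42.9 * rho^1.56
    MPa, cortical/trabecular threshold 1.4 g/cm^3, element-erosion first
    principal strain 0.2.  All editable.  ``strain_rate_dependent_trabecular``
    is pass-through metadata for downstream solvers; nothing here computes
    rate effects.
    """

    density_to_modulus: PowerLaw = field(default_factory=lambda: PowerLaw(6850.0, 1.49))
    density_to_yield: PowerLaw = field(default_factory=lambda: PowerLaw(38.5, 1.48))
    density_to_ultimate: PowerLaw = field(default_factory=lambda: PowerLaw(42.9, 1.56))
    cortical_threshold: float = 1.4  # g/cm^3
    erosion_strain: float = 0.2
    strain_rate_dependent_trabecular: bool = True

    def __post_init__(self) -> None:
        for law in (self.density_to_modulus, self.density_to_yield, self.density_to_ultimate):
            if law.a <= 0:
                raise ValueError("power-law coefficient a must be > 0")
        if self.cortical_threshold <= 0:
            raise ValueError("cortical_threshold must be > 0")
        if self.erosion_strain <= 0:
            raise ValueError("erosion_strain must be > 0")


CORTICAL = "cortical"
TRABECULAR = "trabecular"


def classify_tissue(density: DensityField, surface_shell_ids,
                    config: MaterialLawConfig | None = None) -> np.ndarray:
    """Cortical/trabecular partition of the elements.

    An element is cortical iff its density is >= the threshold (inclusive at
    exactly the threshold) OR it belongs to the outer-surface shell — shell
    elements are cortical regardless of density.  Returns an array of
    ``"cortical"`` / ``"trabecular"`` labels, one per element.
    """
    config = config or MaterialLawConfig()
    values = density.values
    m = values.shape[0]
    shell = np.asarray(sorted(set(int(i) for i in np.asarray(surface_shell_ids).ravel()))
                       if np.asarray(surface_shell_ids).size else [], dtype=np.int64)
    if shell.size and (shell.min() < 0 or shell.max() >= m):
        raise IndexError("surface shell element ids out of range")
    cortical = values >= config.cortical_threshold
    cortical[shell] = True
    return np.where(cortical, CORTICAL, TRABECULAR)


@dataclass(frozen=True)
class MaterialCard:
    """Per-element material parameters plus the erosion-strain constant."""

    elastic_modulus: np.ndarray  # MPa
    yield_stress: np.ndarray  # MPa
    ultimate_stress: np.ndarray  # MPa
    tissue_class: np.ndarray  # 'cortical' | 'trabecular'
    erosion_strain: float
    density_basis: str = "apparent"


def compute_material(density: DensityField, classes: np.ndarray,
                     config: MaterialLawConfig | None = None) -> MaterialCard:
    """Map per-element density to E / yield / ultimate via the configured laws."""
    config = config or MaterialLawConfig()
    rho = density.values
    if np.any(rho < 0):
        raise ValueError("negative density encountered")
    if classes.shape[0] != rho.shape[0]:
        raise ValueError("tissue classes and density field disagree in length")
    return MaterialCard(
        elastic_modulus=config.density_to_modulus(rho),
        yield_stress=config.density_to_yield(rho),
        ultimate_stress=config.density_to_ultimate(rho),
        tissue_class=np.asarray(classes),
        erosion_strain=config.erosion_strain,
        density_basis=density.basis,
    )


def export_material_csv(path: str | Path, density: DensityField, card: MaterialCard) -> None:
    import pandas as pd

    pd.DataFrame({
        "element_id": np.arange(len(density)),
        "density": density.values,
        "class": card.tissue_class,
        "E": card.elastic_modulus,
        "yield": card.yield_stress,
        "ultimate": card.ultimate_stress,
    }).to_csv(path, index=False)


def export_lsdyna_cards(path: str | Path, elements: np.ndarray, card: MaterialCard) -> None:
    """EXPERIMENTAL: LS-DYNA-keyword-style *ELEMENT_SOLID listing with part
    assignment by tissue class (part 1 cortical, part 2 trabecular).  Node
    and element ids are written 1-based as the keyword format expects."""
    parts = np.where(card.tissue_class == CORTICAL, 1, 2)
    with Path(path).open("w") as f:
        f.write("*KEYWORD\n$ experimental export: part 1 cortical, part 2 trabecular\n")
        f.write(f"$ erosion first principal strain: {card.erosion_strain}\n")
        f.write("*ELEMENT_SOLID\n")
        for eid, (part, conn) in enumerate(zip(parts, elements), start=1):
            nodes = "".join(f"{int(nid) + 1:8d}" for nid in conn)
            f.write(f"{eid:8d}{part:8d}{nodes}\n")
        f.write("*END\n")
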