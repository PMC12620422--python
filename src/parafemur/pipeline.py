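"""End-to-end workflow: align -> PCA (both channels) -> compactness ->
regressions -> grid generation -> morphometrics -> trendlines -> WSD report.

Artifacts are written under ``config.output_dir`` and stamped with the config
digest and seed; re-running with the same config overwrites identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import RunConfig
from .evaluation import render_table
from .io import load_cohort, read_landmarks, write_vtk
from .material import MaterialLawConfig, PowerLaw
from .model import ParametricFemurModel
from .ssam import save_model

__all__ = ["run_pipeline", "material_config_from_run_config"]


def material_config_from_run_config(config: RunConfig) -> MaterialLawConfig:
    return MaterialLawConfig(
        density_to_modulus=PowerLaw(*config.modulus_law),
        density_to_yield=PowerLaw(*config.yield_law),
        density_to_ultimate=PowerLaw(*config.ultimate_law),
        cortical_threshold=config.cortical_threshold,
        erosion_strain=config.erosion_strain,
    )


def run_pipeline(config: RunConfig, run_loo: bool = True) -> dict:
    """Run the full workflow on the cohort directory; returns the report dict.

    The cohort directory must contain the mesh files (``*.vtk`` or ``*.npz``),
    ``anthro.csv`` and ``landmarks.json`` (node-index sets + shell element
    ids, e.g. as written by the ``synth`` subcommand).
    """
    cohort_dir = Path(config.cohort_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_digest": config.digest(), "seed": config.seed}

    mesh_paths = sorted(cohort_dir.glob("*.vtk")) or sorted(cohort_dir.glob("*.npz"))
    if not mesh_paths:
        raise FileNotFoundError(f"no mesh files in {cohort_dir}")
    samples = load_cohort(mesh_paths, cohort_dir / "anthro.csv")
    landmarks, shell_ids = read_landmarks(cohort_dir / "landmarks.json")
    mat_config = material_config_from_run_config(config)

    results = ParametricFemurModel(samples, align=config.align).fit()

    save_model(out / "shape_model.npz", results.shape_model)
    save_model(out / "appearance_model.npz", results.appearance_model)
    np.savetxt(out / "shape_regression.csv", results.shape_regression.coefficients,
               delimiter=",", header="intercept,stature,bmi,age", comments="")
    np.savetxt(out / "appearance_regression.csv",
               results.appearance_regression.coefficients,
               delimiter=",", header="intercept,stature,bmi,age", comments="")

    grid = results.anthro_grid(config.parsed_grid_overrides())
    instances = results.generate_grid(grid)
    for rec, inst in zip(grid, instances):
        write_vtk(out / f"instance_{rec.subject_id}.vtk", inst.mesh, inst.density)

    ref_table = results.morphometrics_table(results.aligned_samples, landmarks,
                                            shell_ids, mat_config)
    par_table = results.morphometrics_table(instances, landmarks, shell_ids, mat_config)
    ref_table.to_csv(out / "morphometrics_reference.csv", index=False)
    par_table.to_csv(out / "morphometrics_parametric.csv", index=False)

    report = results.evaluate_morphology(landmarks, shell_ids, mat_config, grid)

    payload = {
        **stamp,
        "cohort_size": len(samples),
        "n_modes_shape": results.shape_model.n_modes,
        "n_modes_appearance": results.appearance_model.n_modes,
        "align": config.align,
        "compactness_shape_final": float(results.compactness_shape.errors[-1]),
        "compactness_appearance_final": float(results.compactness_appearance.errors[-1]),
        "pairs": {
            label: {
                "reference_norm": float(report.reference_norm[i]),
                "parametric_norm": float(report.parametric_norm[i]),
                "weight": float(report.weights[i]),
                "weighted_diff": float(report.weighted_diff[i]),
            }
            for i, label in enumerate(report.labels)
        },
        "wsd": report.wsd,
        "diff_percent": report.diff_percent,
    }
    if run_loo:
        loo = results.leave_one_out()
        payload["loo_max_mae_coords_mm"] = loo.max_mean_abs_coordinate_error
        payload["loo_max_mae_density"] = loo.max_mean_abs_density_error
    for key, value in payload.items():
        if isinstance(value, float) and not np.isfinite(value):
            raise RuntimeError(f"non-finite report field {key!r}")
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "evaluation.txt").write_text(render_table(report) + "\n")
    config.save(out / "run_config.json")
    return payload
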