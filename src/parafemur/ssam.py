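"""Statistical shape and appearance models of corresponded femur cohorts.

Given N corresponded samples, the shape channel stacks nodal coordinates into
vectors s_i = (x_1, y_1, z_1, ..., x_n, y_n, z_n) and the appearance channel
stacks per-element densities s_i = (d_1, ..., d_m).  The model is the PCA of
the 1/N-normalised empirical covariance

    D = (1/N) sum_i ds_i ds_i^T,    ds_i = s_i - s_mean,

whose eigenvectors are the principal components pc_j and whose eigenvalues
are the retained singular values.  Each subject's principal values are
pv_i = U^T ds_i.  For efficiency the decomposition is computed from the thin
SVD of the centered data matrix, which is algebraically identical to the
dense covariance eigendecomposition (a property the test-suite checks against
a dense oracle).

Convention notes
----------------
* The covariance uses 1/N (not 1/(N-1)); per-mode pv standard deviations
  SD_j follow the same convention, so SD_j = sqrt(lambda_j).  Switching to
  1/(N-1) would scale SD_j by sqrt(N/(N-1)).
* Component signs are canonicalised so the largest-magnitude entry of each
  pc_j is positive, making pv signs reproducible across platforms.
* All nonzero modes are retained (K <= N-1 after centering); numerically
  zero modes (eigenvalue below 1e-12 of the largest) are dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .mesh import CorrespondenceError, DensityField, FemurSample

__all__ = [
    "StatisticalModel",
    "CompactnessCurve",
    "vectorize",
    "devectorize",
    "build_model",
    "project",
    "reconstruct",
    "compactness",
    "mode_variation",
    "pv_anthro_correlations",
    "save_model",
    "load_model",
]

Channel = Literal["shape", "appearance"]


def vectorize(sample: FemurSample, channel: Channel) -> np.ndarray:
    """Flatten one sample into the channel's model vector.

    shape -> interleaved (x, y, z) per node, length 3n;
    appearance -> per-element densities, length m.
    """
    if channel == "shape":
        return sample.mesh.nodes.reshape(-1).copy()
    if channel == "appearance":
        return sample.density.values.copy()
    raise ValueError(f"unknown channel {channel!r}; expected 'shape' or 'appearance'")


def devectorize(vector: np.ndarray, template: FemurSample, channel: Channel) -> FemurSample:
    """Inverse of :func:`vectorize`: pour a model vector back into a sample
    structured like ``template`` (anthro metadata copied from the template)."""
    vector = np.asarray(vector, dtype=np.float64)
    if channel == "shape":
        if vector.shape[0] != 3 * template.mesh.n_nodes:
            raise ValueError("shape vector length does not match template node count")
        mesh = template.mesh.with_nodes(vector.reshape(-1, 3))
        return replace(template, mesh=mesh)
    if channel == "appearance":
        if vector.shape[0] != template.mesh.n_elements:
            raise ValueError("appearance vector length does not match template element count")
        density = DensityField(values=np.clip(vector, 0.0, None), basis=template.density.basis)
        return replace(template, density=density)
    raise ValueError(f"unknown channel {channel!r}")


@dataclass(frozen=True)
class StatisticalModel:
    """PCA model of one channel.

    Attributes
    ----------
    mean_vector : (d,) cohort mean s_mean.
    components : (d, K) orthonormal principal components (columns).
    singular_values : (K,) eigenvalues of the 1/N covariance.
    pv_matrix : (N, K) per-subject principal values.
    pv_sd : (K,) per-mode SD of the pv columns (1/N convention).
    """

    channel: Channel
    mean_vector: np.ndarray
    components: np.ndarray
    singular_values: np.ndarray
    pv_matrix: np.ndarray
    pv_sd: np.ndarray
    cohort_size: int
    topology_hash: str = ""

    @property
    def n_modes(self) -> int:
        return self.components.shape[1]

    @property
    def dim(self) -> int:
        return self.mean_vector.shape[0]


def _canonicalize_signs(components: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive (first
    such entry breaks ties)."""
    out = components.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        idx = int(np.argmax(np.abs(col)))
        if col[idx] < 0:
            out[:, j] = -col
    return out


def build_model(vectors: Sequence[np.ndarray], channel: Channel = "shape",
                topology_hash: str = "") -> StatisticalModel:
    """Build the PCA model from the cohort's channel vectors.

    Uses the thin SVD of the centered (N, d) data matrix X: if
    X = A S B^T then D = (1/N) X^T X = B (S^2/N) B^T, so the components are
    the columns of B and the covariance eigenvalues are S^2/N.
    """
    lengths = {np.asarray(v).shape for v in vectors}
    if len(lengths) != 1 or next(iter(lengths)).__len__() != 1:
        raise CorrespondenceError("cohort vectors differ in length")
    X = np.asarray(vectors, dtype=np.float64)
    N, d = X.shape
    if N < 2:
        raise ValueError("degenerate cohort: need at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD; rank <= N-1 after centering
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / N
    if eigenvalues.size and eigenvalues[0] > 0:
        keep = eigenvalues > eigenvalues[0] * 1e-12
    else:
        keep = np.zeros(eigenvalues.shape, dtype=bool)
    keep &= np.arange(eigenvalues.size) < N - 1  # centering removes one dof
    U = _canonicalize_signs(Vt[keep].T)
    lam = eigenvalues[keep]
    pv = Xc @ U
    pv_sd = np.sqrt(np.mean(pv**2, axis=0))  # 1/N convention == sqrt(lam)
    return StatisticalModel(
        channel=channel, mean_vector=mean, components=U, singular_values=lam,
        pv_matrix=pv, pv_sd=pv_sd, cohort_size=N, topology_hash=topology_hash,
    )


def project(vector: np.ndarray, model: StatisticalModel) -> np.ndarray:
    """pv = U^T (s - s_mean)."""
    vector = np.asarray(vector, dtype=np.float64)
    if vector.shape != model.mean_vector.shape:
        raise ValueError(f"vector length {vector.shape} != model dimension "
                         f"{model.mean_vector.shape}")
    return model.components.T @ (vector - model.mean_vector)


def reconstruct(b: np.ndarray, model: StatisticalModel, k: int | None = None) -> np.ndarray:
    """s = s_mean + sum_{j<=k} b_j pc_j (k defaults to all retained modes)."""
    b = np.asarray(b, dtype=np.float64)
    K = model.n_modes
    if k is None:
        k = min(K, b.shape[0])
    if k > K:
        raise ValueError(f"k={k} exceeds the model's {K} retained modes")
    if b.shape[0] < k:
        raise ValueError(f"need at least {k} contribution factors, got {b.shape[0]}")
    return model.mean_vector + model.components[:, :k] @ b[:k]


@dataclass(frozen=True)
class CompactnessCurve:
    """Mean absolute training-set reconstruction error as a function of the
    number of retained modes; mm for shape, g/cm^3 for appearance."""

    channel: Channel
    errors: np.ndarray  # (K,) error using k = 1..K components

    def __len__(self) -> int:
        return self.errors.shape[0]


def compactness(model: StatisticalModel, vectors: Sequence[np.ndarray],
                per_node: bool = False) -> CompactnessCurve:
    """Reconstruct every training member with k = 1..K modes.

    The error at each k is the mean over subjects of the mean absolute
    per-entry error (per scalar coordinate for shape).  With
    ``per_node=True`` the shape error is instead the mean per-node Euclidean
    distance.
    """
    X = np.asarray(vectors, dtype=np.float64)
    pv = (X - model.mean_vector) @ model.components  # (N, K)
    K = model.n_modes
    errors = np.empty(K)
    for k in range(1, K + 1):
        recon = model.mean_vector + pv[:, :k] @ model.components[:, :k].T
        diff = X - recon
        if per_node and model.channel == "shape":
            d = np.linalg.norm(diff.reshape(diff.shape[0], -1, 3), axis=2)
            errors[k - 1] = float(d.mean())
        else:
            errors[k - 1] = float(np.abs(diff).mean())
    return CompactnessCurve(channel=model.channel, errors=errors)


def mode_variation(model: StatisticalModel, j: int, n_sd: float = 1.0,
                   include_mean: bool = True) -> np.ndarray:
    """Instance illustrating mode j at ``n_sd`` standard deviations.

    ``include_mean=True`` gives s_mean + n_sd*SD_j*pc_j (the geometry
    convention); ``include_mean=False`` gives the bare delta n_sd*SD_j*pc_j
    (the density-variation convention, a change over the mean distribution).
    ``j`` is 1-based, matching the usual mode numbering.
    """
    if not 1 <= j <= model.n_modes:
        raise ValueError(f"mode index {j} out of range 1..{model.n_modes}")
    delta = n_sd * model.pv_sd[j - 1] * model.components[:, j - 1]
    return model.mean_vector + delta if include_mean else delta


def pv_anthro_correlations(model: StatisticalModel, anthro_records) -> "pd.DataFrame":
    """Pearson R and two-sided p between each mode's pv column and each
    anthropometric predictor.

    Returns a tidy DataFrame with columns (mode, predictor, r, p).  A
    zero-variance predictor is reported explicitly (r and p = NaN with
    ``defined = False``) rather than silently propagating NaNs.
    """
    import pandas as pd

    if len(anthro_records) != model.cohort_size:
        raise ValueError("anthropometric records do not match the model cohort")
    if model.cohort_size < 3:
        raise ValueError("need at least 3 subjects for correlations")
    predictors = {
        "stature": np.array([r.stature for r in anthro_records], dtype=np.float64),
        "bmi": np.array([r.bmi for r in anthro_records], dtype=np.float64),
        "age": np.array([r.age for r in anthro_records], dtype=np.float64),
    }
    rows = []
    for j in range(model.n_modes):
        pv_col = model.pv_matrix[:, j]
        for name, x in predictors.items():
            if np.ptp(x) == 0 or np.ptp(pv_col) == 0:
                rows.append((j + 1, name, np.nan, np.nan, False))
                continue
            r, p = stats.pearsonr(x, pv_col)
            rows.append((j + 1, name, float(r), float(p), True))
    return pd.DataFrame(rows, columns=["mode", "predictor", "r", "p", "defined"])


def save_model(path: str | Path, model: StatisticalModel) -> None:
    """Single-file archive: named arrays + JSON metadata."""
    meta = dict(channel=model.channel, cohort_size=model.cohort_size,
                topology_hash=model.topology_hash, covariance_convention="1/N")
    np.savez(path,
             mean=model.mean_vector, components=model.components,
             singular_values=model.singular_values, pv_matrix=model.pv_matrix,
             pv_sd=model.pv_sd, metadata=np.array(json.dumps(meta)))


def load_model(path: str | Path) -> StatisticalModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["metadata"]))
        return StatisticalModel(
            channel=meta["channel"], mean_vector=data["mean"],
            components=data["components"], singular_values=data["singular_values"],
            pv_matrix=data["pv_matrix"], pv_sd=data["pv_sd"],
            cohort_size=int(meta["cohort_size"]), topology_hash=meta["topology_hash"],
        )
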