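"""Euler characteristic curves of superlevel-set filtrations and their FPCA.

The topology of an image is summarized by thresholding: the excursion set
``A_u = {s : I(s) > u}`` shrinks as the threshold *u* rises, and its Euler
characteristic chi traces a curve over *u*.  On an adequate liver image the
dark vessels punch tubes through the bright parenchyma, creating handles
(negative chi contributions) at intermediate thresholds; on a suboptimal
image the excursion sets stay blob-like.  chi is computed on the cubical
complex whose 3-cells are the foreground voxels together with all of their
faces, edges and vertices:

    chi = V - E + F - C,

the alternating sum of cell counts by dimension, which for well-behaved
solids equals components - handles + voids.

Curves are normalized by the liver voxel count (masks differ in size),
smoothed into continuous functions by integrating from right to left, and
reduced to their first three functional principal component (FPC) scores via
the Karhunen-Loeve expansion of the sample covariance on the common
threshold grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import StandardizedVolume

__all__ = [
    "ECCurve",
    "SmoothedECCurve",
    "FPCModel",
    "excursion_set",
    "euler_characteristic",
    "ecc_curve",
    "smooth_ecc",
    "fit_fpca",
    "fpc_scores",
    "default_thresholds",
]


def default_thresholds(lo: float = -3.0, hi: float = 3.0, n: int = 101) -> np.ndarray:
    """Equispaced threshold grid in standardized intensity units."""
    return np.linspace(lo, hi, n)


def excursion_set(v: StandardizedVolume, u: float) -> np.ndarray:
    """Binary superlevel set: in-mask voxels with intensity strictly > u."""
    with np.errstate(invalid="ignore"):
        return v.mask & (v.intensity > u)


def euler_characteristic(b: np.ndarray) -> int:
    """Euler characteristic of the cubical complex spanned by the
    foreground voxels of a binary 3D grid.

    Counts vertices, edges, faces and 3-cells of the complex by logical-OR
    pooling of the voxel grid over the incident offsets; chi = V - E + F - C.
    An empty grid has chi = 0.
    """
    b = np.asarray(b).astype(bool)
    if b.ndim != 3:
        raise ValueError("expected a 3D binary grid")
    if not b.any():
        return 0
    n0, n1, n2 = b.shape

    def pooled(offsets_shape, axes):
        """OR of the voxel grid over unit offsets along *axes*."""
        out = np.zeros(offsets_shape, dtype=bool)
        n_ax = len(axes)
        for bits in range(1 << n_ax):
            sl = [slice(0, n0), slice(0, n1), slice(0, n2)]
            for j, ax in enumerate(axes):
                off = (bits >> j) & 1
                sl[ax] = slice(off, off + b.shape[ax])
            out[tuple(sl)] |= b
        return out

    C = int(b.sum())
    # faces: between-voxel planes in each orientation; a face exists if
    # either incident voxel is foreground
    F = 0
    F += int(pooled((n0 + 1, n1, n2), axes=(0,)).sum())
    F += int(pooled((n0, n1 + 1, n2), axes=(1,)).sum())
    F += int(pooled((n0, n1, n2 + 1), axes=(2,)).sum())
    # edges: shared by up to 4 voxels in the perpendicular plane
    E = 0
    E += int(pooled((n0, n1 + 1, n2 + 1), axes=(1, 2)).sum())
    E += int(pooled((n0 + 1, n1, n2 + 1), axes=(0, 2)).sum())
    E += int(pooled((n0 + 1, n1 + 1, n2), axes=(0, 1)).sum())
    # vertices: shared by up to 8 voxels
    V = int(pooled((n0 + 1, n1 + 1, n2 + 1), axes=(0, 1, 2)).sum())
    return V - E + F - C


@dataclass
class ECCurve:
    """chi(A_u) over an ascending threshold grid, normalized by the liver
    voxel count."""

    thresholds: np.ndarray
    chi: np.ndarray          # integer-valued
    n_liver_voxels: int

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.chi = np.asarray(self.chi)
        if self.thresholds.shape != self.chi.shape:
            raise ValueError("thresholds / chi length mismatch")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly ascending")

    @property
    def chi_norm(self) -> np.ndarray:
        return self.chi / self.n_liver_voxels


@dataclass
class SmoothedECCurve:
    """Right-to-left integral of the normalized step curve:
    S(u) = integral_u^{u_m} chi_norm(v) dv; continuous piecewise-linear
    with S(u_m) = 0."""

    thresholds: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, float)
        self.values = np.asarray(self.values, float)
        if self.thresholds.shape != self.values.shape:
            raise ValueError("thresholds / values length mismatch")


def ecc_curve(v: StandardizedVolume, thresholds: np.ndarray | None = None,
              slicewise: bool = False) -> ECCurve:
    """Euler characteristic curve of the superlevel filtration.

    With ``slicewise=True`` chi is summed over 2D slice complexes instead of
    the full 3D complex (an option for very large stacks); the default is 3D.
    """
    if not v.mask.any():
        raise ValueError("empty mask")
    thresholds = default_thresholds() if thresholds is None else np.asarray(thresholds, float)
    chi = np.empty(len(thresholds), dtype=int)
    for i, u in enumerate(thresholds):
        ex = excursion_set(v, float(u))
        if slicewise:
            chi[i] = sum(euler_characteristic(ex[:, :, k:k + 1])
                         for k in range(ex.shape[2]))
        else:
            chi[i] = euler_characteristic(ex)
    return ECCurve(thresholds=thresholds, chi=chi,
                   n_liver_voxels=v.n_liver_voxels)


def smooth_ecc(c: ECCurve) -> SmoothedECCurve:
    """Integrate the piecewise-constant normalized curve from the right
    (step convention: the value on [u_j, u_{j+1}) is chi_norm(u_j))."""
    u = c.thresholds
    y = c.chi_norm
    widths = np.diff(u)
    seg = y[:-1] * widths                       # integral over [u_j, u_{j+1})
    s = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return SmoothedECCurve(thresholds=u.copy(), values=s)


@dataclass
class FPCModel:
    """Mean curve and top-K eigenpairs of the quadrature-weighted sample
    covariance of smoothed curves on a common grid."""

    thresholds: np.ndarray
    mean: np.ndarray
    eigenfunctions: np.ndarray   # (K, m), orthonormal under the quadrature
    eigenvalues: np.ndarray      # (K,), descending, >= 0
    quad_weights: np.ndarray
    total_variance: float

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        if self.total_variance <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.total_variance


def _trapezoid_weights(u: np.ndarray) -> np.ndarray:
    w = np.zeros_like(u)
    d = np.diff(u)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def fit_fpca(curves: list[SmoothedECCurve], K: int = 3) -> FPCModel:
    """Functional PCA of smoothed curves sharing a common threshold grid.

    Eigenpairs come from the symmetrized discretized covariance
    W^{1/2} G W^{1/2} with trapezoid quadrature weights W; eigenfunctions
    are normalized to unit quadrature norm and signed so their integral is
    >= 0 (tie: first nonzero coordinate positive).
    """
    if len(curves) < K + 1:
        raise ValueError(f"need at least {K + 1} curves, got {len(curves)}")
    u = curves[0].thresholds
    for c in curves[1:]:
        if not np.allclose(c.thresholds, u):
            raise ValueError("curves must share a common threshold grid")
    X = np.stack([c.values for c in curves])         # (n, m)
    n, m = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    w = _trapezoid_weights(u)
    G = (Xc.T @ Xc) / (n - 1)                        # pointwise covariance
    sw = np.sqrt(w)
    A = sw[:, None] * G * sw[None, :]
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    phis = np.empty((K, m))
    with np.errstate(divide="ignore", invalid="ignore"):
        for k in range(K):
            phi = evecs[:, k] / np.where(sw > 0, sw, 1.0)
            nrm = np.sqrt(np.sum(w * phi ** 2))
            if nrm > 0:
                phi = phi / nrm
            integral = np.sum(w * phi)
            if integral < 0 or (integral == 0 and _first_nonzero_sign(phi) < 0):
                phi = -phi
            phis[k] = phi
    total_var = float(np.sum(w * np.diag(G)))        # integral of Var(X(u))
    return FPCModel(thresholds=u.copy(), mean=mean,
                    eigenfunctions=phis, eigenvalues=evals[:K],
                    quad_weights=w, total_variance=total_var)


def _first_nonzero_sign(phi: np.ndarray) -> float:
    nz = phi[np.abs(phi) > 1e-12]
    return float(np.sign(nz[0])) if len(nz) else 1.0


def fpc_scores(model: FPCModel, c: SmoothedECCurve) -> np.ndarray:
    """Scores xi_k = integral (X(u) - mean(u)) phi_k(u) du via the model's
    quadrature."""
    if not np.allclose(c.thresholds, model.thresholds):
        raise ValueError("curve grid does not match the FPC model grid")
    dev = c.values - model.mean
    return model.eigenfunctions @ (model.quad_weights * dev)


def reconstruct(model: FPCModel, scores: np.ndarray) -> np.ndarray:
    """Mean plus the truncated Karhunen-Loeve expansion."""
    return model.mean + scores @ model.eigenfunctions


def curve_to_csv(c: ECCurve, path: str,
                 smoothed: SmoothedECCurve | None = None) -> None:
    """Write (threshold, chi, chi_norm[, smoothed]) columns as CSV."""
    import pandas as pd
    data = {"threshold": c.thresholds, "chi": c.chi, "chi_norm": c.chi_norm}
    if smoothed is not None:
        data["smoothed"] = smoothed.values
    pd.DataFrame(data).to_csv(path, index=False)


def fpc_model_to_json(model: FPCModel, path: str) -> None:
    """Serialize the FPC model (grid, mean, eigenfunctions, eigenvalues)."""
    import json
    with open(path, "w") as fh:
        json.dump({
            "thresholds": model.thresholds.tolist(),
            "mean": model.mean.tolist(),
            "eigenfunctions": model.eigenfunctions.tolist(),
            "eigenvalues": model.eigenvalues.tolist(),
            "quad_weights": model.quad_weights.tolist(),
            "total_variance": model.total_variance,
        }, fh)
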