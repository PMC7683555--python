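"""Gray-level co-occurrence matrix (GLCM) and four Haralick statistics.

The in-mask intensities are quantized to ``N_g`` equal-width gray levels,
pairs of in-mask voxels at offset distance *d* along the 13 unique 3D
directions are tallied into a symmetric matrix of relative frequencies
``P[k, l]``, and four second-order statistics are read off:

    energy   = sum P^2                      (angular second moment)
    corr     = (sum k*l*P - mu_k mu_l) / (sd_k sd_l)
    entropy  = -sum P log P                 (natural log; 0 log 0 = 0)
    idm      = sum P / (1 + |k - l|^2)      (inverse difference moment)

where mu/sd are the marginal means and standard deviations of the level
indices under P.  The correlation denominator uses the square roots of the
marginal second central moments so the statistic is a Pearson correlation
bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import StandardizedVolume

__all__ = [
    "QuantizedVolume",
    "CooccurrenceMatrix",
    "TextureFeatures",
    "UndefinedFeature",
    "quantize",
    "glcm",
    "haralick",
    "texture_features",
    "DIRECTIONS_13",
]

#: the 13 unique 3D offset directions (one of each +/- pair)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class QuantizedVolume:
    levels: np.ndarray       # int grid; 1..n_levels inside mask, 0 outside
    mask: np.ndarray
    n_levels: int
    bin_edges: np.ndarray


@dataclass
class CooccurrenceMatrix:
    P: np.ndarray            # (N_g, N_g) relative frequencies, symmetric
    distance: int
    directions: tuple[tuple[int, int, int], ...]


@dataclass(frozen=True)
class UndefinedFeature:
    """Marker for a statistic that is undefined on this matrix (e.g.
    correlation when a marginal variance is zero)."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class TextureFeatures:
    energy: float
    correlation: float | UndefinedFeature
    entropy: float
    idm: float

    def as_dict(self) -> dict[str, float]:
        corr = self.correlation
        return {
            "glcm_energy": self.energy,
            "glcm_correlation": float("nan") if isinstance(corr, UndefinedFeature) else corr,
            "glcm_entropy": self.entropy,
            "glcm_idm": self.idm,
        }


def quantize(v: StandardizedVolume, n_levels: int = 32) -> QuantizedVolume:
    """Equal-width quantization of in-mask intensities to levels 1..n_levels
    over [in-mask min, in-mask max]; the maximum maps to level n_levels."""
    vals = v.in_mask()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise ValueError("in-mask intensity range is degenerate")
    edges = np.linspace(lo, hi, n_levels + 1)
    levels = np.zeros(v.intensity.shape, dtype=np.int32)
    idx = np.clip(
        np.floor((vals - lo) / (hi - lo) * n_levels).astype(int), 0, n_levels - 1
    )
    levels[v.mask] = idx + 1
    return QuantizedVolume(levels=levels, mask=v.mask.copy(),
                           n_levels=n_levels, bin_edges=edges)


def glcm(q: QuantizedVolume, d: int = 1,
         directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
         ) -> CooccurrenceMatrix:
    """Symmetric co-occurrence matrix pooled over *directions* at offset
    distance *d*; only pairs with both voxels in the mask count."""
    if d < 1:
        raise ValueError("d must be >= 1")
    ng = q.n_levels
    counts = np.zeros((ng, ng), dtype=np.int64)
    shape = np.array(q.levels.shape)
    for direction in directions:
        off = d * np.array(direction)
        src = [slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)]
        dst = [slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)]
        a = q.levels[tuple(src)]
        b = q.levels[tuple(dst)]
        valid = q.mask[tuple(src)] & q.mask[tuple(dst)]
        if not valid.any():
            continue
        pair = (a[valid] - 1) * ng + (b[valid] - 1)
        counts += np.bincount(pair, minlength=ng * ng).reshape(ng, ng)
    counts = counts + counts.T        # symmetrize: count both directions
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pairs for this offset")
    return CooccurrenceMatrix(P=counts / total, distance=d,
                              directions=tuple(directions))


def haralick(P: CooccurrenceMatrix | np.ndarray) -> TextureFeatures:
    """The four Haralick statistics of a co-occurrence matrix."""
    M = P.P if isinstance(P, CooccurrenceMatrix) else np.asarray(P, float)
    ng = M.shape[0]
    k = np.arange(1, ng + 1)
    energy = float((M ** 2).sum())
    nz = M[M > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    kk, ll = np.meshgrid(k, k, indexing="ij")
    idm = float((M / (1.0 + (kk - ll) ** 2)).sum())
    pk = M.sum(axis=1)
    pl = M.sum(axis=0)
    mu_k = float(k @ pk)
    mu_l = float(k @ pl)
    var_k = float(((k - mu_k) ** 2) @ pk)
    var_l = float(((k - mu_l) ** 2) @ pl)
    if var_k <= 0 or var_l <= 0:
        corr: float | UndefinedFeature = UndefinedFeature(
            "zero marginal variance: correlation undefined")
    else:
        cross = float((kk * ll * M).sum())
        corr = (cross - mu_k * mu_l) / np.sqrt(var_k * var_l)
    return TextureFeatures(energy=energy, correlation=corr,
                           entropy=entropy, idm=idm)


def texture_features(v: StandardizedVolume, n_levels: int = 32, d: int = 1,
                     directions: tuple[tuple[int, int, int], ...] = DIRECTIONS_13
                     ) -> TextureFeatures:
    """quantize -> glcm -> haralick composite on a standardized volume."""
    return haralick(glcm(quantize(v, n_levels), d=d, directions=directions))
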