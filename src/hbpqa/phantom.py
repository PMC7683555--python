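"""Synthetic liver phantoms with controllable vessel-to-parenchyma contrast.

Real hepatobiliary-phase (HBP) series show two phenotypes: on an *adequate*
exam the parenchyma retains contrast agent and vessels appear dark against a
bright background; on a *suboptimal* exam uptake is impaired and vessels are
nearly isointense with the parenchyma.  The phantom emulates exactly that
contrast phenomenology — an ellipsoidal "liver" of parenchyma intensity 1.0
carved by dark random-walk tubes at intensity ``1 - contrast`` — plus
additive Gaussian noise and a smooth multiplicative bias field.  It makes no
attempt at anatomical realism; its job is to give the downstream feature
pipeline two classes whose separability is governed by a single knob.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy import ndimage
from skimage.morphology import ball

from .volume import MaskedVolume, save_labels, save_nifti_pair

__all__ = ["PhantomSpec", "LabeledCohort", "generate_phantom", "generate_cohort"]

ADEQUATE = "adequate"
SUBOPTIMAL = "suboptimal"

#: default contrast gap used for cohorts: adequate exams have dark vessels,
#: suboptimal exams near-isointense ones.
DEFAULT_ADEQUATE_CONTRAST = 0.8
DEFAULT_SUBOPTIMAL_CONTRAST = 0.02


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters for a single phantom volume.

    ``contrast`` is the parenchyma-minus-vessel intensity gap before noise
    (parenchyma sits at 1.0, vessels at ``1.0 - contrast``); absolute scale
    is irrelevant after standardization.
    """

    grid_shape: tuple[int, int, int] = (40, 40, 14)
    liver_axes: tuple[float, float, float] = (15.0, 13.0, 6.0)
    n_vessels: int = 6
    vessel_radius_range: tuple[int, int] = (2, 3)
    contrast: float = DEFAULT_ADEQUATE_CONTRAST
    noise_sd: float = 0.05
    bias_amplitude: float = 0.1
    label: str = ADEQUATE
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.contrast < 0 or self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("contrast, noise_sd and bias_amplitude must be >= 0")
        if self.label not in (ADEQUATE, SUBOPTIMAL):
            raise ValueError(f"label must be '{ADEQUATE}' or '{SUBOPTIMAL}'")
        if self.vessel_radius_range[1] >= min(self.liver_axes):
            raise ValueError(
                f"vessel radius {self.vessel_radius_range[1]} >= min liver "
                f"semi-axis {min(self.liver_axes)}"
            )

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in self.__dict__.items()},
                fh,
            )


@dataclass
class LabeledCohort:
    """A list of phantom volumes with per-volume class labels."""

    volumes: list[MaskedVolume]
    labels: list[str]
    specs: list[PhantomSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.volumes) != len(self.labels):
            raise ValueError("volumes and labels length mismatch")

    @property
    def class_counts(self) -> tuple[int, int]:
        return (self.labels.count(ADEQUATE), self.labels.count(SUBOPTIMAL))

    def __len__(self) -> int:
        return len(self.volumes)

    def save(self, directory: str) -> None:
        for v in self.volumes:
            save_nifti_pair(v, directory)
        save_labels([v.id for v in self.volumes], self.labels,
                    f"{directory}/labels.csv")


def _ellipsoid_mask(shape, axes) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    return r2 <= 1.0


def _vessel_tubes(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Random-walk tube centerlines (3-6 steps) dilated by a ball.

    Short jittered walks dilated to a small radius produce tubes that may
    pierce the liver, branch past each other and form handles — enough
    topology to make the Euler curve informative.
    """
    shape = mask.shape
    vessels = np.zeros(shape, dtype=bool)
    inner = np.argwhere(ndimage.binary_erosion(mask, iterations=2)) if mask.any() else None
    if inner is None or len(inner) == 0:
        inner = np.argwhere(mask)
    for _ in range(spec.n_vessels):
        start = inner[rng.integers(len(inner))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        n_steps = int(rng.integers(3, 7))
        step_len = max(2.0, min(spec.liver_axes) / 2.0)
        pts = [start]
        for _ in range(n_steps):
            direction = direction + 0.6 * rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pts.append(pts[-1] + step_len * direction)
        # rasterize the polyline densely
        line = np.zeros(shape, dtype=bool)
        for a, b in zip(pts[:-1], pts[1:]):
            t = np.linspace(0.0, 1.0, int(np.ceil(np.linalg.norm(b - a) * 4)) + 2)
            xyz = np.round(a[None, :] + t[:, None] * (b - a)[None, :]).astype(int)
            keep = np.all((xyz >= 0) & (xyz < np.array(shape)), axis=1)
            xyz = xyz[keep]
            line[xyz[:, 0], xyz[:, 1], xyz[:, 2]] = True
        radius = int(rng.integers(spec.vessel_radius_range[0],
                                  spec.vessel_radius_range[1] + 1))
        if radius > 0:
            line = ndimage.binary_dilation(line, structure=ball(radius))
        vessels |= line
    return vessels & mask


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-frequency field: exp of a product of cosine modes."""
    if amplitude == 0:
        return np.ones(shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    phases = rng.uniform(0, 2 * np.pi, size=3)
    modes = [np.cos(np.pi * g / s + p) for g, s, p in zip(grids, shape, phases)]
    return np.exp(amplitude * modes[0] * modes[1] * modes[2])


def generate_phantom(spec: PhantomSpec) -> MaskedVolume:
    """Generate one phantom volume; deterministic given ``spec.seed``.

    Parenchyma voxels take intensity 1.0 and vessel voxels
    ``1.0 - contrast``; a multiplicative bias field and additive Gaussian
    noise are applied inside the mask only, and everything outside the mask
    is exactly zero.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.grid_shape, spec.liver_axes)
    if not mask.any():
        raise ValueError("liver mask has zero volume for this grid/axes choice")

    intensity = np.zeros(spec.grid_shape, dtype=float)
    intensity[mask] = 1.0
    if spec.n_vessels > 0:
        vessels = _vessel_tubes(mask, spec, rng)
        intensity[vessels] = 1.0 - spec.contrast

    intensity *= _bias_field(spec.grid_shape, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        # magnitude-style noise: MR magnitude images are nonnegative, and the
        # log-domain bias correction needs strictly positive intensities
        intensity[mask] = np.abs(
            intensity[mask] + rng.normal(0.0, spec.noise_sd, size=int(mask.sum()))
        )
    intensity[~mask] = 0.0
    return MaskedVolume(intensity=intensity, mask=mask,
                        id=f"{spec.label}_{spec.seed}")


def generate_cohort(
    n_adequate: int,
    n_suboptimal: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    suboptimal_contrast: float = DEFAULT_SUBOPTIMAL_CONTRAST,
    contrast_jitter: float = 0.2,
) -> LabeledCohort:
    """Generate a labeled two-class cohort.

    Adequate members use ``base_spec.contrast``, suboptimal members
    ``suboptimal_contrast``, each jittered per-subject by a uniform
    multiplicative factor of ±``contrast_jitter``.  Per-subject seeds are
    derived deterministically from the master seed.
    """
    if n_adequate < 0 or n_suboptimal < 0:
        raise ValueError("counts must be >= 0")
    if n_adequate + n_suboptimal == 0:
        raise ValueError("cohort must contain at least one volume")
    base = base_spec or PhantomSpec()
    master = np.random.default_rng(seed)
    volumes, labels, specs = [], [], []
    plan = [(ADEQUATE, base.contrast)] * n_adequate + \
           [(SUBOPTIMAL, suboptimal_contrast)] * n_suboptimal
    for i, (label, contrast) in enumerate(plan):
        jitter = float(master.uniform(1 - contrast_jitter, 1 + contrast_jitter))
        sub_seed = int(master.integers(0, 2**31 - 1))
        spec = replace(base, label=label, contrast=contrast * jitter, seed=sub_seed)
        vol = generate_phantom(spec)
        vol.id = f"{label}_{i:04d}"
        volumes.append(vol)
        labels.append(label)
        specs.append(spec)
    return LabeledCohort(volumes=volumes, labels=labels, specs=specs)
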