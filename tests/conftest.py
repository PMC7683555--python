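import numpy as np
import pytest

from hbpqa.phantom import PhantomSpec, generate_phantom
from hbpqa.volume import MaskedVolume, StandardizedVolume


@pytest.fixture(scope="session")
def clean_phantom() -> MaskedVolume:
    """A noise- and bias-free adequate phantom: two-point intensity."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, bias_amplitude=0.0,
                                        seed=11))


@pytest.fixture(scope="session")
def noisy_phantom() -> MaskedVolume:
    """A default adequate phantom with noise and bias."""
    return generate_phantom(PhantomSpec(seed=12))


def make_standardized(values: np.ndarray, mask: np.ndarray | None = None
                      ) -> StandardizedVolume:
    """Wrap a 3D array as a StandardizedVolume without re-standardizing."""
    values = np.asarray(values, float)
    if mask is None:
        mask = np.ones(values.shape, bool)
    out = np.where(mask, values, np.nan)
    return StandardizedVolume(intensity=out, mask=mask)


def brute_force_chi(grid: np.ndarray) -> int:
    """Independent Euler characteristic oracle by explicit cell enumeration.

    Every cell of the cubical complex is identified by its center in
    doubled coordinates; the cell dimension is the number of odd
    coordinates, and chi is the alternating sum over the deduplicated set.
    """
    grid = np.asarray(grid).astype(bool)
    cells: set[tuple[int, int, int]] = set()
    for x, y, z in np.argwhere(grid):
        for dx in (0, 1, 2):
            for dy in (0, 1, 2):
                for dz in (0, 1, 2):
                    cells.add((2 * x + dx, 2 * y + dy, 2 * z + dz))
    return sum((-1) ** sum(c % 2 for c in cell) for cell in cells)
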