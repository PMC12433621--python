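"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from btd import PhantomSpec, generate_phantom


def gauss_seidel_reference(
    f: np.ndarray, mask: np.ndarray, tol: float = 1e-12, max_sweeps: int = 200_000
) -> np.ndarray:
    """Brute-force Gauss-Seidel solve of the masked Dirichlet problem.

    Pixel-by-pixel sweeps of T(p) <- mean of 4 neighbours, boundary
    values frozen at f (edge-replicated at the raster border), run until
    the largest per-sweep update falls below ``tol``.  Deliberately
    naive and independent of the package's sparse assembly; only usable
    on small masks.
    """
    f = np.asarray(f, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    t = np.pad(f, 1, mode="edge")
    m = np.pad(mask, 1, mode="constant", constant_values=False)
    rows, cols = np.nonzero(m)
    for _ in range(max_sweeps):
        delta = 0.0
        for r, c in zip(rows, cols):
            new = 0.25 * (t[r - 1, c] + t[r + 1, c] + t[r, c - 1] + t[r, c + 1])
            delta = max(delta, abs(new - t[r, c]))
            t[r, c] = new
        if delta < tol:
            break
    return t[1:-1, 1:-1]


@pytest.fixture(scope="session")
def harmonic_sample():
    """Noiseless phantom whose true tissue is harmonic inside the mask."""
    return generate_phantom(
        PhantomSpec(tissue_kind="harmonic_in_mask", seed=7, alpha_true=1.7)
    )


@pytest.fixture(scope="session")
def smooth_sample():
    """Noiseless phantom with a generic (non-harmonic) tissue field."""
    return generate_phantom(PhantomSpec(tissue_kind="smooth", seed=3, alpha_true=2.0))
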