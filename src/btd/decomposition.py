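"""The bone-and-tissue decomposition model.

A radiograph f in [0, 1] (bones bright) is modelled as a nonlinear
composition of a smooth soft-tissue image T and a bone image B scaled
by a global contrast parameter alpha:

    f = (1/alpha) * B * (1 - T) + T

Given T (the harmonic interpolant of f across the bone mask), the model
is closed in one pass: the bone ratio r = (f - T) / (1 - T) lies in
[0, 1], alpha is the reciprocal of its maximum — hence alpha >= 1 —
and B = alpha * r, which makes max(B) exactly 1.  Because alpha >= 1
and 1 - T <= 1, the bone image has at least the gradient magnitude of
f wherever the tissue is locally flat: decomposition doubles as
guaranteed contrast enhancement of the bone content.

Four model assumptions are enforced rather than hoped for: T <= f
(pixelwise clamp after the solve, guaranteeing B >= 0), T < 1 (the
epsilon clamp guarding the denominator), T smooth (it is harmonic
inside the mask by construction), and max(B) = 1 (the alpha
definition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import laplace
from .exceptions import DegeneratePixelError, NoBoneSignalError, ShapeMismatchError
from .image_io import validate_radiograph
from .laplace import SolverConfig, solve_tissue
from .masking import validate_user_mask

__all__ = [
    "Decomposition",
    "ContrastReport",
    "compute_alpha",
    "compute_bone",
    "recompose",
    "tissue_from_bone",
    "linear_tissue",
    "contrast_report",
    "decompose",
]

#: default cutoff below which the tissue gradient counts as flat
FLAT_THRESHOLD = 1e-3


@dataclass(frozen=True)
class ContrastReport:
    """Gradient-based check of the bone-contrast guarantee.

    Forward-difference gradient magnitudes of f, B and T are compared
    on mask pixels where the tissue is locally flat
    (|grad T| <= flat_tissue_threshold).  ``fraction_enhanced`` is the
    fraction of those pixels with |grad B| >= |grad f|; it is reported
    as 1.0 (vacuously) when no pixel passes the flat-tissue filter.
    """

    grad_f: np.ndarray
    grad_b: np.ndarray
    grad_t: np.ndarray
    fraction_enhanced: float
    flat_tissue_threshold: float
    n_evaluated: int


@dataclass
class Decomposition:
    """Bundle of decomposition outputs and diagnostics."""

    tissue: np.ndarray
    bone: np.ndarray
    alpha: float
    mask: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ShapeMismatchError(f"arrays must share one shape, got {shapes}")


def compute_alpha(f: np.ndarray, t: np.ndarray, eps_alpha: float = 1e-6) -> float:
    """Closed-form contrast parameter: alpha = 1 / max_p r(p).

    The bone ratio r(p) = max(0, f(p) - T(p)) / (1 - T(p)) never
    exceeds 1 for f <= 1, so the returned alpha is always >= 1.

    Raises
    ------
    NoBoneSignalError
        When max r < ``eps_alpha``, i.e. f and T agree everywhere and
        the image carries no bone component.
    """
    f = np.asarray(f, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_shapes(f, t)
    r_max = float((np.maximum(f - t, 0.0) / (1.0 - t)).max())
    if r_max < eps_alpha:
        raise NoBoneSignalError(
            f"max bone ratio {r_max:.3g} < {eps_alpha:.3g}: f matches the "
            "tissue estimate everywhere, no bones in the image"
        )
    return 1.0 / r_max


def compute_bone(f: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    """Bone image B = alpha * max(0, f - T) / (1 - T).

    With alpha from :func:`compute_alpha` on the same pair this lands in
    [0, 1] with maximum exactly 1, and vanishes wherever f = T (in
    particular everywhere outside the mask).
    """
    f = np.asarray(f, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_shapes(f, t)
    return alpha * np.maximum(f - t, 0.0) / (1.0 - t)


def recompose(b: np.ndarray, t: np.ndarray, alpha: float) -> np.ndarray:
    """Forward composition f = (1/alpha) * B * (1 - T) + T.

    The exact algebraic inverse of :func:`compute_bone` wherever
    f >= T.  Values are clipped to [0, 1] only to absorb rounding at
    the 1e-12 level; genuine violations are left visible.
    """
    b = np.asarray(b, dtype=np.float64)
    t = np.asarray(t, dtype=np.float64)
    _check_shapes(b, t)
    if not alpha > 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    f = b * (1.0 - t) / alpha + t
    tiny = 1e-12
    f[(f < 0) & (f > -tiny)] = 0.0
    f[(f > 1) & (f < 1 + tiny)] = 1.0
    return f


def tissue_from_bone(
    f: np.ndarray, b: np.ndarray, alpha: float, epsilon: float = 1e-6
) -> np.ndarray:
    """Nonlinear bone suppression: T = (f - B/alpha) / (1 - B/alpha).

    This inverts the composition for T given the bone image, and is the
    model's counterpart of the classical linear subtraction
    (:func:`linear_tissue`).  Output is clipped to [0, 1 - epsilon].

    Raises
    ------
    DegeneratePixelError
        If B/alpha >= 1 - epsilon anywhere (vanishing denominator),
        listing the offending positions.
    """
    f = np.asarray(f, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    _check_shapes(f, b)
    scaled = b / alpha
    bad = scaled >= 1.0 - epsilon
    if bad.any():
        raise DegeneratePixelError(np.argwhere(bad))
    t = (f - scaled) / (1.0 - scaled)
    return np.clip(t, 0.0, 1.0 - epsilon)


def linear_tissue(f: np.ndarray, f_bone: np.ndarray) -> np.ndarray:
    """Classical linear bone suppression: f_tissue = f - f_bone, clipped."""
    f = np.asarray(f, dtype=np.float64)
    f_bone = np.asarray(f_bone, dtype=np.float64)
    _check_shapes(f, f_bone)
    return np.clip(f - f_bone, 0.0, 1.0)


def gradient_magnitude(img: np.ndarray) -> np.ndarray:
    """Forward-difference gradient magnitude, zero-padded at far edges."""
    img = np.asarray(img, dtype=np.float64)
    gy = np.zeros_like(img)
    gx = np.zeros_like(img)
    gy[:-1, :] = img[1:, :] - img[:-1, :]
    gx[:, :-1] = img[:, 1:] - img[:, :-1]
    return np.hypot(gy, gx)


def contrast_report(
    f: np.ndarray,
    b: np.ndarray,
    t: np.ndarray,
    mask: np.ndarray,
    flat_threshold: float = FLAT_THRESHOLD,
) -> ContrastReport:
    """Check the contrast-enhancement guarantee on flat-tissue pixels.

    The guarantee grad B ≈ alpha * grad f / (1 - T) >= grad f holds
    where grad T ≈ 0; evaluation is therefore restricted to mask pixels
    with |grad T| <= ``flat_threshold``.
    """
    _check_shapes(f, b, t, mask)
    mask = np.asarray(mask, dtype=bool)
    grad_f = gradient_magnitude(f)
    grad_b = gradient_magnitude(b)
    grad_t = gradient_magnitude(t)
    evaluated = mask & (grad_t <= flat_threshold)
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        fraction = 1.0
    else:
        fraction = float(np.mean(grad_b[evaluated] >= grad_f[evaluated]))
    return ContrastReport(
        grad_f=grad_f,
        grad_b=grad_b,
        grad_t=grad_t,
        fraction_enhanced=fraction,
        flat_tissue_threshold=flat_threshold,
        n_evaluated=n_eval,
    )


def decompose(
    f: np.ndarray,
    mask: np.ndarray,
    cfg: SolverConfig | None = None,
    flat_threshold: float = FLAT_THRESHOLD,
) -> Decomposition:
    """Run the full decomposition: solve T, clamp, close alpha and B.

    Steps: harmonic tissue estimate inside the mask; pixelwise clamp
    T <- min(T, f) (the harmonic interpolant can overshoot f at
    isolated pixels, and T <= f is what guarantees B >= 0); closed-form
    alpha; bone image.  Diagnostics record the solver residual, the
    number of clamped pixels and a contrast-report summary.
    """
    cfg = cfg or SolverConfig()
    f = validate_radiograph(f)
    mask = validate_user_mask(mask, f)

    t = solve_tissue(f, mask, cfg)
    clamped = int(np.count_nonzero(t > f))
    residual = laplace.max_residual(t, mask, f)  # pre-clamp harmonicity is t's own
    np.minimum(t, f, out=t)

    alpha = compute_alpha(f, t)
    bone = compute_bone(f, t, alpha)
    report = contrast_report(f, bone, t, mask, flat_threshold)
    diagnostics = {
        "max_residual": residual,
        "clamped_pixels": clamped,
        "fraction_enhanced": report.fraction_enhanced,
        "n_contrast_evaluated": report.n_evaluated,
        "solver_mode": cfg.mode,
    }
    return Decomposition(tissue=t, bone=bone, alpha=alpha, mask=mask, diagnostics=diagnostics)
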