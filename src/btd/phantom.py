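"""Synthetic radiograph phantoms with exact ground truth.

Real paired ground truth (a radiograph together with its true tissue
and bone components) does not exist, so every stage of the pipeline is
exercised on phantoms built by running the composition model forward:

    f = (1/alpha_true) * B_true * (1 - T_true) + T_true  (+ noise)

The tissue field is a sum of a few low-frequency cosine modes — the
smooth, slowly varying background that scattered soft-tissue signal
produces.  Bones are random ellipses with a smooth dome profile and a
cosine ripple (trabecular-like texture) so gradient-based contrast
checks are non-degenerate; the union is rescaled so its global maximum
is exactly 1.  The true mask is the bone support dilated by 3 px,
mirroring the over-covering masks the pipeline expects.

Three tissue kinds tune how faithfully the pipeline can recover the
truth: ``smooth`` leaves the cosine field as is (recovery is
approximate, since the field is not harmonic); ``harmonic_in_mask``
replaces the field inside the mask by the discrete-harmonic interpolant
of its own boundary values, making recovery exact up to solver
tolerance by uniqueness of the Dirichlet solution;
``constant_in_mask`` replaces it by the boundary mean, the flat-tissue
limit in which the contrast guarantee becomes exact.

At zero noise every generated sample is machine-checked against the
four model assumptions (T <= f, T < 1, smooth T, max B = 1).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from skimage.morphology import dilation, disk

from .decomposition import Decomposition, contrast_report, recompose
from .exceptions import PhantomPlacementError
from .laplace import SolverConfig, solve_tissue
from .masking import extract_boundary

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "evaluate_recovery",
    "sweep_specs",
]

TISSUE_KINDS = ("smooth", "harmonic_in_mask", "constant_in_mask")

#: dilation radius turning the bone support into the over-covering mask
MASK_DILATION = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic radiograph.

    height, width : pixels.
    alpha_true : contrast parameter used in the forward composition,
        >= 1 (dimensionless).
    tissue_kind : one of ``smooth``, ``harmonic_in_mask``,
        ``constant_in_mask``.
    tissue_max : peak tissue intensity, in [0, 1); the cosine field is
        rescaled to [0, tissue_max].
    n_bones : number of elliptical bone blobs (0 gives a bone-free
        image on which decomposition must report no bone signal).
    bone_texture_amp : relative amplitude of the intra-bone ripple.
    noise_sigma : additive Gaussian sensor noise on f only (ground
        truth stays exact).
    seed : PRNG seed; the sample is a pure function of the spec.
    """

    height: int = 128
    width: int = 128
    alpha_true: float = 1.5
    tissue_kind: str = "smooth"
    tissue_max: float = 0.6
    n_bones: int = 2
    bone_texture_amp: float = 0.2
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_true < 1.0:
            raise ValueError("alpha_true must be >= 1")
        if not 0.0 <= self.tissue_max < 1.0:
            raise ValueError("tissue_max must lie in [0, 1)")
        if self.n_bones < 0:
            raise ValueError("n_bones must be >= 0")
        if self.tissue_kind not in TISSUE_KINDS:
            raise ValueError(f"tissue_kind must be one of {TISSUE_KINDS}")


@dataclass
class PhantomSample:
    """A synthetic radiograph with its generating ground truth."""

    f: np.ndarray
    T_true: np.ndarray
    B_true: np.ndarray
    alpha_true: float
    M_true: np.ndarray
    spec: PhantomSpec


def _cosine_field(rng: np.random.Generator, h: int, w: int, vmax: float) -> np.ndarray:
    """Low-frequency random field: <= 4 cosine modes, rescaled to [0, vmax]."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    field = np.zeros((h, w))
    n_modes = int(rng.integers(2, 5))
    for _ in range(n_modes):
        # periods comparable to the image size keep the field smooth
        ky = rng.uniform(0.5, 2.0) * 2.0 * np.pi / h
        kx = rng.uniform(0.5, 2.0) * 2.0 * np.pi / w
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(0.5, 1.0)
        field += amp * np.cos(ky * yy + kx * xx + phase)
    lo, hi = field.min(), field.max()
    if hi > lo:
        field = (field - lo) / (hi - lo) * vmax
    else:  # vmax == 0 or degenerate draw: constant field
        field = np.full((h, w), 0.0)
    return field


def _bone_field(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Union of random ellipses with smooth dome profiles plus ripple."""
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    bone = np.zeros((h, w))
    margin = MASK_DILATION + 2
    max_semi = max(min(h, w) / 6.0, 4.0)
    min_semi = max(min(h, w) / 16.0, 2.0)
    for _ in range(spec.n_bones):
        for _attempt in range(50):
            a = rng.uniform(min_semi, max_semi)
            b = rng.uniform(min_semi, max_semi)
            reach = max(a, b)
            if (h - 2 * (margin + reach) <= 0) or (w - 2 * (margin + reach) <= 0):
                continue
            cy = rng.uniform(margin + reach, h - margin - reach)
            cx = rng.uniform(margin + reach, w - margin - reach)
            break
        else:
            raise PhantomPlacementError(
                f"cannot place an ellipse of reach {reach:.1f} in a "
                f"{h}x{w} grid with margin {margin}"
            )
        theta = rng.uniform(0.0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        rho2 = (u / a) ** 2 + (v / b) ** 2
        dome = np.maximum(1.0 - rho2, 0.0)
        ripple_k = rng.uniform(0.2, 0.6)
        ripple_phase = rng.uniform(0.0, 2.0 * np.pi)
        ripple = 1.0 + spec.bone_texture_amp * np.cos(ripple_k * u + ripple_phase)
        bone = np.maximum(bone, dome * ripple)
    if spec.n_bones > 0:
        peak = bone.max()
        if peak <= 0:
            raise PhantomPlacementError("bone field degenerated to zero")
        bone = bone / peak  # global maximum exactly 1 at the argmax
    return bone


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate a synthetic radiograph; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    tissue = _cosine_field(rng, h, w, spec.tissue_max)
    bone = _bone_field(rng, spec)
    if spec.n_bones > 0:
        mask = dilation(bone > 0, disk(MASK_DILATION))
    else:
        mask = np.zeros((h, w), dtype=bool)

    if spec.n_bones > 0 and spec.tissue_kind == "harmonic_in_mask":
        tissue = solve_tissue(tissue, mask, SolverConfig(mode="exact"))
    elif spec.n_bones > 0 and spec.tissue_kind == "constant_in_mask":
        boundary = extract_boundary(mask, tissue)
        tissue = tissue.copy()
        tissue[mask] = float(boundary.values.mean())

    f = recompose(bone, tissue, spec.alpha_true)
    if spec.noise_sigma > 0:
        f = np.clip(f + rng.normal(0.0, spec.noise_sigma, size=f.shape), 0.0, 1.0)
    else:
        _check_assumptions(f, tissue, bone, spec)

    return PhantomSample(
        f=f, T_true=tissue, B_true=bone, alpha_true=spec.alpha_true,
        M_true=mask, spec=spec,
    )


def _check_assumptions(
    f: np.ndarray, tissue: np.ndarray, bone: np.ndarray, spec: PhantomSpec
) -> None:
    """Machine-check the four model assumptions on a noiseless sample."""
    assert np.all(tissue <= f + 1e-12), "assumption violated: T > f somewhere"
    assert tissue.max() < 1.0, "assumption violated: T reaches 1"
    assert bone.min() >= 0.0, "bone field went negative"
    if spec.n_bones > 0:
        assert abs(bone.max() - 1.0) < 1e-12, "assumption violated: max(B) != 1"


def evaluate_recovery(sample: PhantomSample, result: Decomposition) -> dict[str, float]:
    """Quantify how well a decomposition recovered the ground truth.

    Returns root-mean-square errors of T and B over the whole image,
    the relative alpha error, and the contrast-report fraction of
    flat-tissue pixels whose bone gradient at least matches the input's.
    """
    t_err = result.tissue - sample.T_true
    b_err = result.bone - sample.B_true
    report = contrast_report(sample.f, result.bone, result.tissue, result.mask)
    return {
        "rmse_T": float(np.sqrt(np.mean(t_err**2))),
        "rmse_B": float(np.sqrt(np.mean(b_err**2))),
        "max_abs_T": float(np.abs(t_err).max()),
        "max_abs_B": float(np.abs(b_err).max()),
        "alpha_rel_error": float(abs(result.alpha - sample.alpha_true) / sample.alpha_true),
        "fraction_enhanced": report.fraction_enhanced,
    }


def sweep_specs(
    n: int = 100, base_seed: int = 0, height: int = 128, width: int = 128
) -> list[PhantomSpec]:
    """Standard randomized phantom population for guarantee sweeps.

    ``n`` noiseless specs cycling through the three tissue kinds and
    1-3 bones, with the contrast parameter drawn uniformly from [1, 4].
    Both the draws and the per-phantom seeds derive from ``base_seed``.
    """
    rng = np.random.default_rng(base_seed)
    return [
        PhantomSpec(
            height=height,
            width=width,
            alpha_true=float(rng.uniform(1.0, 4.0)),
            tissue_kind=TISSUE_KINDS[i % 3],
            n_bones=1 + i % 3,
            noise_sigma=0.0,
            seed=base_seed + i,
        )
        for i in range(n)
    ]


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a spec, for JSON sidecars."""
    return asdict(spec)
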