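# Methods

## Model and procedure

The package decomposes a single grayscale radiograph `f` with
intensities in [0, 1], bones-bright polarity, into a soft-tissue image
`T` and a bone image `B` under

    f = (1/α) · B · (1 − T) + T,    α ≥ 1 scalar.

The model is the atmospheric-scattering (dehazing) composition
specialised to transmission radiography: the "airlight" level is 1
because X-ray sensors receive no other light source, and the bone term
is linearly rescaled by a single global α so pixel intensity keeps its
linear relation to dose. A spatially varying α could look better but
would break that linearity and can introduce artifacts, so it is
deliberately excluded.

The inverse problem is closed by four assumptions, each enforced in
code rather than assumed:

1. `T ≤ f` — enforced by a pixelwise clamp `T ← min(T, f)` after the
   Laplace solve (the harmonic interpolant can overshoot `f` at
   isolated pixels). The clamp guarantees `B ≥ 0` and makes the
   recomposition identity exact; the number of clamped pixels is
   reported in diagnostics.
2. `0 ≤ T < 1` — enforced by clamping `T ≤ 1 − ε` (default
   `ε = 1e−6`), protecting the denominator `1 − T`. The clamp applies
   to the whole grid, including outside the mask; this matters only
   for images containing exact 1.0 there.
3. `T` smooth — holds by construction: inside the mask `T` is the
   minimiser of the Dirichlet energy, i.e. the discrete-harmonic
   interpolant.
4. `max B = 1` — holds by construction of α (below).

Procedure: estimate or accept a bone-covering mask `M`; solve
`ΔT = 0` in `M` with `T = f` on `∂M`; clamp; set
`α = 1 / max_p [(f−T)/(1−T)]` and `B = α·(f−T)/(1−T)`. Since
`(f−T)/(1−T) ≤ 1` whenever `f ≤ 1`, α ≥ 1 is structural, and the
maximum of `B` is exactly 1 at the pixel attaining the max ratio.
Negative `f − T` cannot survive the assumption-1 clamp; the ratio
additionally floors `f − T` at 0 for robustness when the functions are
called with unclamped inputs.

## Mask

The default mask recipe is: binarise `f ≥ Otsu`, morphological closing
(disk radius 3), hole filling, removal of components smaller than 64
px (8-connectivity), dilation by a disk of radius 5. The dilation is
what makes the mask a *cover*: the decomposition only needs every
bone-carrying pixel inside `M`, not an aligned segmentation, and
different reasonable masks give similar decompositions. Masks touching
the image border are allowed; the missing outside neighbours are
synthesised by replicating the edge values of `f` (a logged warning
notes that those Dirichlet data are synthetic). Multiple connected
components decouple exactly in the linear system.

## Laplace solver

Standard 5-point stencil on the pixel grid — each interior pixel
equals the mean of its 4 neighbours — assembled once over all mask
pixels in row-major order. The system is block-diagonal across
connected components, so a single sparse factorisation solves all
components independently and deterministically; no per-component loop
is needed. Exact mode uses SuperLU (`scipy.sparse.linalg.spsolve`) and
is the reference path: residuals are at rounding level (~1e−15 even at
1024², far below the 1e−8 contract) and the discrete maximum principle
holds per component. Fast mode runs Jacobi-preconditioned conjugate
gradients to a loose relative tolerance (1e−5) for large images where
a factorisation is unnecessary; its accuracy is reported, never
asserted, and nothing downstream depends on it. The residual reporter
recomputes `|4T(p) − ΣT(q)|` as a sum of neighbour differences so
constant fields give exactly zero; for border-touching masks it takes
the off-raster neighbour values from `f`'s edge replication, matching
the solve.

## Contrast guarantee

From `B = α(f−T)/(1−T)`,
`∇B = α[∇f/(1−T) − (1−f)/(1−T)² ∇T]`; wherever `∇T ≈ 0` this gives
`|∇B| ≈ α|∇f|/(1−T) ≥ |∇f|` since α ≥ 1 and `1−T ≤ 1`. The report
implements the check with forward differences (zero-padded at the far
edges; the gradient operator is otherwise unconstrained, and forward
differences keep ties exact), restricted to mask pixels with
`|∇T| ≤ 1e−3` intensity/pixel (the operational meaning of "locally
flat"), and counts the fraction with `|∇B| ≥ |∇f|`. An empty
evaluation set reports fraction 1.0 (vacuous) with `n_evaluated = 0`
rather than erroring.

In the exactly flat limit (`T` globally constant) the fraction is 1.0
at every pixel, including across mask edges. On generic phantoms the
misses concentrate in the over-coverage annulus of the mask where
`B ≈ 0` and both gradients are within rounding of zero — pixels where
the approximation behind the guarantee degenerates to a near-tie.
Because a single phantom contributes only tens of flat-tissue pixels,
the meaningful statistic is pooled over the standard phantom sweep
(below), where it is ≈ 0.97.

## Synthetic phantoms

The generator runs the composition forward so every stage has exact
ground truth. Tissue is a sum of 2–4 cosine modes with random
frequencies of 0.5–2 cycles per image side and random phases, rescaled
to `[0, tissue_max]` (default 0.6) — a smooth, slowly varying
background. Bones are `n_bones` random ellipses (semi-axes between
1/16 and 1/6 of the short side, random orientation) with a parabolic
dome profile times a cosine ripple of relative amplitude
`bone_texture_amp` (default 0.2, so gradient-based checks are
non-degenerate); the union is rescaled to a global maximum of exactly
1. The mask is the bone support dilated by 3 px, mirroring deliberate
over-coverage. Optional Gaussian noise applies to `f` only; ground
truth stays exact. At zero noise the generator machine-checks all four
model assumptions. All randomness flows from one recorded seed
(`numpy` PCG64); identical specs give bit-identical samples.

Tissue kinds: `smooth` (as above; recovery is approximate because the
field is not harmonic), `harmonic_in_mask` (field inside the mask
replaced by the discrete-harmonic interpolant of its own boundary
values; recovery is then exact up to solver tolerance by uniqueness of
the Dirichlet solution), `constant_in_mask` (replaced by the boundary
mean; the flat-tissue limit of the contrast theorem).

What the phantoms do not emulate: Beer–Lambert ray physics, scatter,
detector blur, anatomy-shaped bones, and the heavy-tailed gradient
statistics of real tissue backgrounds (the cosine field's gradient is
spread broadly rather than concentrated near zero, which makes the
flat-tissue evaluation set small at 128² and is why the contrast
statistic is pooled). Passing tests therefore demonstrate the model's
internal guarantees and exact-recovery regime, not clinical image
quality.

The standard sweep (`phantom.sweep_specs`) is 100 noiseless 128×128
phantoms cycling the three tissue kinds and 1–3 bones, with true α
drawn uniformly from [1, 4]. 128² keeps a 100-phantom sweep around a
second while leaving every guarantee scale-independent; a 1024²
feasibility run is exercised separately.

## Numerical choices

- Integer images normalise by the dtype's full-scale maximum (not the
  per-image max) to preserve the intensity–dose relation; per-image
  rescaling is an explicit opt-in flag, as is polarity inversion (no
  auto-detection).
- Integer saving quantises round-half-up; float TIFF round trips are
  lossless. Out-of-range values are rejected on save, never silently
  clipped.
- `α`'s maximum is a plain global max — ties need no breaking because
  only the value enters the formula.
- No-bone detection: `max (f−T)/(1−T) < 1e−6` raises a distinct error.
  This triggers exactly when `f` equals its own harmonic completion
  inside the mask (e.g. constant or affine bone-free images); a
  non-harmonic bone-free background leaves an interpolation gap that
  reads as signal, which is a model limitation, not a bug.
- `tissue_from_bone` guards its denominator with the same ε and lists
  degenerate pixel positions in the raised error. Its output clip to
  `1 − ε` can shave the `f = 1` equality edge of the
  nonlinear-vs-linear dominance by at most ε.
- Raster conventions everywhere: top-left origin, 0-based (row, col),
  4-adjacency for stencils/boundaries, 8-adjacency only inside
  morphology.

## Limitations

Single global α trades local optimality for dose linearity. The
Dirichlet tissue estimate is only as good as the mask's boundary
values — overlapping dense soft tissue at `∂M` biases `T` upward.
DICOM windowing, display transforms, registration and color input are
out of scope; convert to PNG/TIFF first. The fast solver mode has no
accuracy contract.
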