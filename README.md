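# btd — bone-and-tissue decomposition of single radiographs

`btd` splits a single grayscale X-ray image into two co-registered
components: a smooth **soft-tissue image** `T` and a contrast-enhanced
**bone image** `B`. Unlike bone *suppression* (which only removes bone)
or bone *segmentation* (which only labels pixels), the decomposition
returns both components on the same raster, with the bone image
guaranteed to have at least the input's local contrast. It is intended
for researchers and tool builders working on radiograph enhancement,
bone-fracture reading aids, or soft-tissue diagnosis pipelines.

## The model

A radiograph `f ∈ [0,1]` (bones-bright convention) is modelled as a
nonlinear composition, structurally analogous to the atmospheric
scattering model used in natural-image dehazing:

```
f(x,y) = (1/α) · B(x,y) · (1 − T(x,y)) + T(x,y)
```

Solving it uses four assumptions: `T ≤ f`, `0 ≤ T < 1`, `T` is smooth,
and `max B = 1`. The pipeline is then closed-form after one linear
solve:

1. **Mask** — obtain a loose bone-covering mask `M` (Otsu threshold +
   morphology by default, or user-supplied). `M` only needs to *cover*
   bone, not trace it.
2. **Tissue** — solve the Laplace equation `ΔT = 0` inside `M` with
   Dirichlet data `T = f` on `∂M` (5-point stencil, sparse direct
   solve), i.e. harmonically interpolate the background across the
   bones. Clamp `T ← min(T, f)`.
3. **Contrast parameter** — `α = 1 / max_p [(f−T)/(1−T)]`. Because the
   ratio never exceeds 1, **α ≥ 1 always**.
4. **Bone** — `B = α·(f−T)/(1−T)`, so `B ∈ [0,1]` with `max B = 1`,
   and `B = 0` wherever `f = T`.

Differentiating step 4 gives `∇B ≈ α·∇f/(1−T) ≥ ∇f` wherever
`∇T ≈ 0`: the bone image is a guaranteed local-contrast enhancement of
the input at flat-tissue pixels.

## Worked example

Every capability has a narrative script under `examples/`. The
end-to-end one (`python examples/decompose_phantom.py`) builds a
synthetic radiograph whose true tissue field is harmonic inside the
bone mask — the regime where the decomposition is mathematically exact
— and prints:

```
true alpha        : 1.700000
recovered alpha   : 1.700000
max |T - T_true|  : 0
max |B - B_true|  : 2.22e-16
max(B)            : 1.000000000000
solver residual   : 7.77e-16
```

The true contrast parameter and both component images are recovered to
machine precision (uniqueness of the Dirichlet solution), the bone
image's maximum is exactly 1, and the tissue solution satisfies the
discrete Laplace equation to ~1e-15. `examples/contrast_guarantee.py`
measures the enhancement theorem (fraction of flat-tissue pixels whose
bone gradient dominates the input's: 1.000 in the constant-tissue
limit, 0.977 pooled over a 30-phantom sweep), and
`examples/bone_suppression_comparison.py` shows the nonlinear
suppression `T = (f−b)/(1−b)` dominating the classical subtraction
`f − b` pixelwise while tracking the true tissue more closely (RMS
0.042 vs 0.072).

## Command line

```
btd decompose INPUT.png --out-tissue T.tif --out-bone B.tif --report report.json
btd decompose INPUT.png --mask MASK.png ...      # user-supplied mask
btd recompose --tissue T.tif --bone B.tif --alpha 1.7 --out F.tif
btd phantom --seed 3 --out-prefix scratch/ph     # synthetic ground truth
btd selftest                                     # fixed-seed guarantee checks
```

Exit codes: 2 unreadable input, 3 empty mask, 4 no bone signal.

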