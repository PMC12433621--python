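"""The bone-contrast guarantee, measured on gradients.

Since alpha >= 1 and 1 - T <= 1, the bone image's gradient dominates
the input's wherever the tissue is locally flat.  With globally
constant tissue the relation |grad B| >= |grad f| is exact at every
pixel; on a generic phantom it holds at almost all flat-tissue pixels.
"""

import numpy as np

from btd import PhantomSpec, contrast_report, decompose, generate_phantom, recompose

# exact limit: constant tissue
sample = generate_phantom(PhantomSpec(seed=9, n_bones=2))
t_flat = np.full_like(sample.T_true, 0.3)
f_flat = recompose(sample.B_true, t_flat, sample.alpha_true)
result = decompose(f_flat, sample.M_true)
report = contrast_report(f_flat, result.bone, result.tissue, result.mask)
print("constant tissue:")
print(f"  evaluated pixels  : {report.n_evaluated}")
print(f"  fraction enhanced : {report.fraction_enhanced:.3f}")

# generic phantoms: pool flat-tissue pixels over the standard mixed
# sweep, since a single phantom contributes only a few dozen of them
from btd.phantom import sweep_specs

enhanced = evaluated = 0
for spec in sweep_specs(n=30, base_seed=0):
    sample = generate_phantom(spec)
    result = decompose(sample.f, sample.M_true)
    report = contrast_report(sample.f, result.bone, result.tissue, result.mask)
    ev = result.mask & (report.grad_t <= report.flat_tissue_threshold)
    enhanced += int((ev & (report.grad_b >= report.grad_f)).sum())
    evaluated += int(ev.sum())
print("mixed sweep, 30 phantoms pooled:")
print(f"  evaluated pixels  : {evaluated}")
print(f"  fraction enhanced : {enhanced / evaluated:.3f}")

# the enhanced fraction is 1.0 in the exact limit and stays high on
# generic phantoms; the few misses sit where bone and tissue gradients
# are both within rounding of zero.
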