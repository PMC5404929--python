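"""Staged parameter fitting demonstrated on self-generated curves.

Reference free-energy curves are produced by the model itself with known
parameters (one SNARE-free, one with the full 15-SNARE load, one with 4
SNAREs for the torque region).  The staged recipe — hydration length from
the minimum position, tension from the slope past the minimum, zippering
energy from the mid-range slope, scaffold torque from the large-pore
slope — should recover each value.
"""

from snarepore import ModelParams, fit_all_stages
from snarepore.synth import synth_profile_curves

truth = ModelParams()
refs = synth_profile_curves(truth, N_values=(0, 15, 4), offset_kT=3.0)

fits = fit_all_stages(refs[0], refs[15], refs[4], truth)

print(f"{'parameter':<10}{'true':>10}{'fitted':>12}{'units':>8}")
for name, true_val in [
    ("lam_hyd", truth.lam_hyd),
    ("gamma", truth.gamma),
    ("eps_zip", truth.eps_zip),
    ("tau", truth.tau),
]:
    fit = fits[name]
    print(f"{name:<10}{true_val:>10.3f}{fit.value:>12.3f}{fit.units:>8}")

print(
    "\nEach stage matches a distinct curve feature, so the +3 kT offset "
    "added to the\nreference curves (an arbitrary empirical constant) has "
    "no effect on the fits."
)
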