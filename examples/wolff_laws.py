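"""Effective Wolff's laws F(L): homeostatic force vs bone wall width.

Setting the steady surface flux equal to the reference value J0 turns the
signalling model into a force-length relation.  Its shape depends on what
the osteocytes sense: under the stress stimulus F(L) has a nonzero minimum
F(0) (a disuse threshold below which no width survives); under the
strain-energy stimulus F ~ sqrt(L) near zero, so any load retains bone.
"""

from osteonet import (
    ModelParams,
    force_length_sed,
    force_length_stress,
    full_resorption_threshold,
    invert_force_length,
    validate_params,
)

p = validate_params(ModelParams())

print(" L (um)   F_stress (N)   F_sed (N)")
for L in (50, 100, 150, 200, 300, 400):
    print(f"{L:7.0f}   {force_length_stress(L, p):.5f}        {force_length_sed(L, p):.5f}")

thr = full_resorption_threshold(p)
print(f"\nstress-mode full-resorption threshold F(0) = {thr:.4f} N")

F = 0.02
print(f"\ninverting the laws at F = {F} N:")
L_stress = invert_force_length(F, "stress", p)
L_sed = invert_force_length(F, "sed", p)
print(f"  stress stimulus : {'no solution -- full resorption' if L_stress is None else L_stress}")
print(f"  strain-energy   : L = {L_sed:.1f} um (bone survives at reduced width)")
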