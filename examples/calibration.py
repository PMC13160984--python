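"""Derive the continuum-limit transport and reference quantities.

The model's primitive inputs are the osteocyte spacing, the per-step jump
fractions of the signalling molecules, and their creation/degradation
rates.  Everything else -- diffusivity D, diffusion length Lambda_D, the
reference boundary flux J0 at which bone is stationary -- is derived.
"""

from osteonet import ModelParams, derived_parameter_table, validate_params

params = validate_params(ModelParams())
for name, value in derived_parameter_table(params).items():
    print(f"{name:26s} {value:.10g}")

print()
print(
    "D = 3.2 mm^2/day means a molecule diffuses ~9 um in a second\n"
    "(rms_displacement_1s_um), comparable to calcium-wave speeds in bone.\n"
    "Lambda_D = 100 um is the mean distance travelled before degradation:\n"
    "osteocytes deeper than ~Lambda_D contribute little surface signal.\n"
    "J0 ~ 8.42e7 molecules/day is the surface flux balancing formation\n"
    "and resorption for a 200 um wall under the 0.04 N reference force."
)
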