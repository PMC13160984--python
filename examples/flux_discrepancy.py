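"""Fixed-boundary steady state: discrete lattice vs continuum closed form.

With boundaries pinned at +-100 um and the reference force, the 19-site
lattice is iterated to its steady state and its outgoing molecule flux is
compared with the continuum prediction.  The gap is a pure lattice effect
(the absorbing ghost sites sit one spacing beyond the extreme osteocytes)
and shrinks roughly linearly as the spacing is refined at fixed diffusion
length.
"""

from osteonet import ModelParams, flux_discrepancy_experiment, validate_params

for dx in (10.0, 5.0, 2.5):
    p = validate_params(ModelParams(dx=dx, dt=1e-5 * (dx / 10.0) ** 2))
    d = flux_discrepancy_experiment(p)
    print(f"dx = {dx:5.1f} um  ->  flux discrepancy {d:.3f} %")

print(
    "\nAt the reference spacing (10 um) the discrete surface flux is ~6.5%\n"
    "below the continuum value, which is why the moving-boundary model\n"
    "settles at a slightly shorter wall than the continuum Wolff law predicts."
)
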