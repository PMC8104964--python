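"""Fit a 4PL ELISA standard curve and invert sample absorbances.

Duplicate standards from 31.25 to 2000 pg/mL (twofold dilutions) are
fitted with the four-parameter logistic model; sample concentrations are
then read off the inverse curve, with an in-range flag marking absorbances
outside the fitted asymptotes.
"""

import numpy as np

from ampscreen import fit_four_pl, four_pl

rng = np.random.default_rng(31)
concentrations = np.repeat([31.25, 62.5, 125, 250, 500, 1000, 2000], 2)
absorbances = four_pl(concentrations, 0.05, 3.0, 250.0, 1.2)
absorbances = absorbances * (1 + rng.normal(0, 0.02, absorbances.size))

fit = fit_four_pl(concentrations, absorbances)
print(f"lower/upper asymptotes: {fit.lower_asymptote:.3f} / "
      f"{fit.upper_asymptote:.3f}")
print(f"inflection (EC50): {fit.inflection:.1f} pg/mL (true: 250)")
print(f"RMSE: {fit.rmse:.4f} over {fit.n_points} standard wells")

print("\nsample absorbance -> concentration:")
for absorbance in (0.4, 1.5, 2.8, 3.2):
    value, in_range = fit.concentration(absorbance)
    note = f"{value:8.1f} pg/mL" if in_range else "  out of range"
    print(f"  A = {absorbance:.2f} -> {note}")
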