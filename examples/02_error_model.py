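"""Assay error polynomial: fit, selection and variance composition.

Reconstructs nominal concentration / replicate-SD calibration pairs on a
20-level grid from the piperacillin HPLC-UV cubic, refits polynomials of
degree 1-3, and shows how the observation variance used in fitting is
composed from the assay SD plus proportional noise terms.
"""

import numpy as np

from quasipk import (
    NoiseSettings,
    PIPERACILLIN_CUBIC,
    fit_error_polynomial,
    observation_variance,
    sd_at,
)

levels = [(c, sd_at(PIPERACILLIN_CUBIC, c)) for c in np.arange(0.0, 200.0, 10.0)]
result = fit_error_polynomial(levels, max_degree=3)

for fit in result.fits:
    c = fit.coefficients
    print(f"degree {fit.degree}: SD(c) = {c[0]:.6f} + {c[1]:.6f} c "
          f"+ {c[2]:.6f} c^2 + {c[3]:.6f} c^3   (r^2 = {fit.r_squared:.4f})")
print(f"selected degree: {result.selected.degree}")

# SD at the blank and at a mid-range concentration:
print(f"SD(0)   = {sd_at(PIPERACILLIN_CUBIC, 0.0):.6f} mg/L")
print(f"SD(100) = {sd_at(PIPERACILLIN_CUBIC, 100.0):.6f} mg/L")

# Total observation variance with 1% dosing/model/timing error each:
noise = NoiseSettings(0.01, 0.01, 0.01)
v = observation_variance(PIPERACILLIN_CUBIC, 100.0, noise)
print(f"observation variance at 100 mg/L with 1% noise terms: {v:.4f} (mg/L)^2")
# = SD(100)^2 + 3 * (1 mg/L)^2: the proportional terms add in quadrature.
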