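"""Fit the 3D-PLI sinusoid of a single pixel and read off its physics.

Builds an 18-angle intensity profile for a fiber at 30 degrees with 50%
retardation, fits I(rho) = I0 + dI*sin(2 rho - 2 phi), and derives
transmittance, retardation, and the inclination estimate.
"""

import numpy as np

from scatpol import estimate_inclination, fit_pli_profile

angles = np.arange(0.0, 180.0, 10.0)          # polarizer azimuths, degrees
i0, retardation, phi = 1000.0, 0.5, 30.0
profile = i0 * (1 + retardation * np.sin(2 * np.deg2rad(angles - phi) ))

I0, dI, phi_fit = fit_pli_profile(profile, angles)
tau = I0 / 2
ret = dI / I0
alpha, bin_label = estimate_inclination(ret)

print(f"fitted mean I0        = {I0:.1f} a.u.")
print(f"fitted amplitude dI   = {dI:.1f} a.u.")
print(f"fiber direction phi   = {phi_fit:.2f} deg")
print(f"transmittance tau     = {tau:.1f} a.u.   (I0/2)")
print(f"retardation |sin d|   = {ret:.3f}        (dI/I0)")
print(f"inclination estimate  = {alpha:.1f} deg  ({bin_label} bin)")
# The direction is the sinusoid phase; the retardation of 0.5 falls in the
# 'inclined' bin (between the 0.17 steep and 0.68 in-plane thresholds).
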