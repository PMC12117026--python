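"""Independent brute-force oracles used to validate the analysis paths.

These deliberately avoid the implementation's algorithms: the sinusoid fit
uses generic nonlinear least squares, and the circular peak oracle tests
every sample for being a circular local maximum and computes topographic
prominence by exhaustive path search around the circle.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares


def lsq_sinusoid_fit(intensities, angles_deg):
    """Nonlinear least-squares fit of I = I0 + dI*sin(2 rho - 2 phi) with
    free (I0, dI, phi); returns (I0, dI, phi_deg in [0, 180))."""
    I = np.asarray(intensities, float)
    rho = np.deg2rad(np.asarray(angles_deg, float))

    def residual(p):
        i0, a, b = p
        return i0 + a * np.sin(2 * rho) + b * np.cos(2 * rho) - I

    # linear parametrization keeps the problem convex; phase from (a, b)
    sol = least_squares(residual, x0=[I.mean(), 1.0, 1.0], xtol=1e-15, ftol=1e-15)
    i0, a, b = sol.x
    di = np.hypot(a, b)
    phi = np.degrees(0.5 * np.arctan2(-b, a)) % 180.0
    return i0, di, phi


def circular_peaks_bruteforce(profile):
    """All circular local maxima of a tie-free profile with their circular
    topographic prominences, found by exhaustive path search.

    For each peak, walk the circle in both directions until a strictly
    higher sample appears (or the walk returns), tracking the minimum along
    each path; the prominence is the peak height minus the higher of the two
    path minima. Returns (indices, prominences), indices ascending.
    """
    x = np.asarray(profile, float)
    n = x.size
    peaks, proms = [], []
    for i in range(n):
        if not (x[i] > x[(i - 1) % n] and x[i] > x[(i + 1) % n]):
            continue
        path_mins = []
        for step in (1, -1):
            lo = x[i]
            found_higher = False
            for k in range(1, n):
                v = x[(i + step * k) % n]
                if v > x[i]:
                    found_higher = True
                    break
                lo = min(lo, v)
            path_mins.append(lo if found_higher else x.min())
        peaks.append(i)
        proms.append(x[i] - max(path_mins))
    return np.array(peaks), np.array(proms)


def best_pairing_bruteforce(positions, tolerance_deg=35.0):
    """Maximum number of disjoint peak pairs with circular separation within
    180 +/- tolerance, by exhaustive enumeration of matchings."""
    m = len(positions)

    def dev(i, j):
        d = abs(positions[i] - positions[j]) % 360.0
        return abs(d - 180.0)

    best = 0

    def recurse(avail, count):
        nonlocal best
        best = max(best, count)
        if not avail:
            return
        i = avail[0]
        rest = avail[1:]
        recurse(rest, count)  # leave i unpaired
        for j in rest:
            if dev(i, j) <= tolerance_deg:
                recurse([k for k in rest if k != j], count + 1)

    recurse(list(range(m)), 0)
    return best
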