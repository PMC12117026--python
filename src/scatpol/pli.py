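"""Per-pixel analysis of the 3D-PLI sinusoidal signal.

In 3D-PLI a brain section is imaged between a rotating linear polarizer
(azimuth rho) and a circular analyzer. Myelin birefringence turns each pixel's
intensity profile into a sinusoid with period 90 degrees in rho,

    I(rho) = I0 + dI * sin(2*rho - 2*phi),

whose mean I0 gives the transmittance tau = I0/2, whose normalized amplitude
|sin(delta)| = dI/I0 is the retardation (decreasing with out-of-plane fiber
inclination alpha), and whose phase phi is the in-plane fiber direction.
Direction angles are in degrees with 0 along the positive x-axis and 90 along
the positive y-axis; the signal is maximal at rho = phi + 45 degrees.

The fit is a discrete Fourier coefficient fit: for n equidistant angles
covering [0, 180) the second-harmonic Fourier coefficients are the exact
least-squares solution of the three-parameter sinusoid model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import AngularStack, require_modality

__all__ = [
    "PLIMaps",
    "PLIModelParams",
    "fit_pli_profile",
    "compute_pli_maps",
    "normalize_retardation",
    "estimate_inclination",
]


@dataclass
class PLIMaps:
    """Per-pixel 3D-PLI parameter maps.

    ``transmittance`` is tau = I0/2 (half the fitted mean signal, following
    the field's convention), ``retardation`` is |sin delta| = dI/I0 clipped to
    [0, 1], ``direction_deg`` the in-plane fiber direction in [0, 180) or NaN
    where invalid or where the amplitude vanishes, and ``valid`` marks pixels
    with sufficient mean signal.
    """

    transmittance: np.ndarray
    retardation: np.ndarray
    direction_deg: np.ndarray
    valid: np.ndarray


@dataclass
class PLIModelParams:
    """Parameters of the retardation-inclination model r(alpha).

    ``delta0_rad`` is the retardance of in-plane fibers (the model assumes
    r(alpha) = sin(delta0 * cos^2 alpha) / sin(delta0), normalized so that
    in-plane fibers have r = 1). The retardation bin boundaries correspond to
    the inclination bins: r >= 0.68 <-> alpha <= 30 deg (in-plane),
    r <= 0.17 <-> alpha >= 65 deg (steep).
    """

    delta0_rad: float = np.pi / 2
    inplane_ref_retardation: float = 1.0
    alpha_bins_deg: tuple[float, float] = (30.0, 65.0)
    inplane_ret_min: float = 0.68
    steep_ret_max: float = 0.17

    def __post_init__(self) -> None:
        if self.delta0_rad <= 0:
            raise ValueError("delta0_rad must be positive")
        lo, hi = self.alpha_bins_deg
        if not (0 < lo < hi < 90):
            raise ValueError("inclination bin boundaries must be strictly increasing in (0, 90)")
        if not (0 < self.inplane_ref_retardation <= 1):
            raise ValueError("inplane_ref_retardation must be in (0, 1]")


def _fourier_sinusoid_fit(intensities: np.ndarray, angles_deg: np.ndarray):
    """Vectorized sinusoid fit over leading angle axis.

    ``intensities`` has shape (n, ...); returns (I0, dI, phi_deg) arrays of
    shape (...). Equidistant angle grids over [0, 180) use the closed-form
    discrete Fourier coefficients; other grids fall back to linear least
    squares on the basis {1, sin 2rho, cos 2rho} (identical result on
    equidistant grids).
    """
    rho = np.deg2rad(np.asarray(angles_deg, dtype=float))
    n = rho.size
    sin2, cos2 = np.sin(2 * rho), np.cos(2 * rho)

    steps = np.diff(np.asarray(angles_deg, dtype=float))
    equidistant = steps.size > 0 and np.allclose(steps, 180.0 / n, rtol=0, atol=1e-9)
    flat = intensities.reshape(n, -1)
    if equidistant:
        i0 = flat.mean(axis=0)
        s = (2.0 / n) * sin2 @ flat
        c = (2.0 / n) * cos2 @ flat
    else:
        design = np.column_stack([np.ones(n), sin2, cos2])
        coef, *_ = np.linalg.lstsq(design, flat, rcond=None)
        i0, s, c = coef
    di = np.hypot(s, c)
    # amplitudes at round-off level (relative to the signal scale) are true
    # zeros: a constant profile must report no direction, not noise phase
    tiny = 64 * np.finfo(float).eps * np.maximum(np.abs(i0), np.abs(flat).max(axis=0))
    di = np.where(di <= tiny, 0.0, di)
    phi = np.degrees(0.5 * np.arctan2(-c, s)) % 180.0
    phi = np.where(di == 0, np.nan, phi)
    shape = intensities.shape[1:]
    return i0.reshape(shape), di.reshape(shape), phi.reshape(shape)


def fit_pli_profile(intensities, angles_deg) -> tuple[float, float, float]:
    """Fit I(rho) = I0 + dI*sin(2 rho - 2 phi) to one pixel's profile.

    Returns ``(I0, dI, phi_deg)`` with phi in [0, 180); phi is NaN when the
    amplitude is exactly zero. Requires at least three finite samples.
    """
    intensities = np.asarray(intensities, dtype=float)
    angles_deg = np.asarray(angles_deg, dtype=float)
    if intensities.ndim != 1 or angles_deg.shape != intensities.shape:
        raise ValueError("profile and angles must be 1-D arrays of equal length")
    if intensities.size < 3:
        raise ValueError("insufficient sampling: need at least 3 angles")
    if not (np.all(np.isfinite(intensities)) and np.all(np.isfinite(angles_deg))):
        raise ValueError("non-finite values in profile or angles")
    i0, di, phi = _fourier_sinusoid_fit(intensities[:, None], angles_deg)
    return float(i0[0]), float(di[0]), float(phi[0])


def compute_pli_maps(stack: AngularStack, i0_min_frac: float = 1e-6) -> PLIMaps:
    """Per-pixel 3D-PLI parameter maps from a PLI stack.

    tau = I0/2, retardation = clip(dI/I0, 0, 1). Pixels whose mean signal I0
    falls at or below ``i0_min_frac`` times the stack maximum are marked
    invalid; their transmittance/retardation/direction are NaN ("no light" is
    distinguished from "no birefringence").
    """
    require_modality(stack, "pli")
    i0, di, phi = _fourier_sinusoid_fit(stack.intensities, stack.angles_deg)
    eps = i0_min_frac * float(stack.intensities.max(initial=0.0))
    valid = i0 > eps
    with np.errstate(divide="ignore", invalid="ignore"):
        retardation = np.clip(di / i0, 0.0, 1.0)
    transmittance = np.where(valid, i0 / 2.0, np.nan)
    retardation = np.where(valid, retardation, np.nan)
    direction = np.where(valid, phi, np.nan)
    return PLIMaps(transmittance=transmittance, retardation=retardation,
                   direction_deg=direction, valid=valid)


def normalize_retardation(retardation_map: np.ndarray, reference="auto") -> np.ndarray:
    """Normalize retardation with the retardation of in-plane parallel fibers.

    ``reference`` is either a positive scalar or ``"auto"``, which uses the
    99th percentile of the retardation over valid (finite) pixels as a robust
    stand-in for the in-plane parallel-fiber reference. The result is clipped
    to [0, 1]; NaNs are preserved.
    """
    retardation_map = np.asarray(retardation_map, dtype=float)
    if isinstance(reference, str):
        if reference != "auto":
            raise ValueError("reference must be a positive number or 'auto'")
        finite = retardation_map[np.isfinite(retardation_map)]
        if finite.size == 0:
            raise ValueError("cannot auto-normalize: no valid pixels")
        reference = float(np.percentile(finite, 99))
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError("normalization reference must be > 0")
    out = retardation_map / reference
    return np.clip(out, 0.0, 1.0)


def estimate_inclination(retardation, params: PLIModelParams | None = None):
    """Out-of-plane inclination estimate and bin from normalized retardation.

    The bins follow the printed retardation thresholds: r >= 0.68 -> in-plane
    (alpha <= 30 deg), r <= 0.17 -> steep (alpha >= 65 deg), else inclined.
    The continuous alpha inverts the configured model
    r(alpha) = sin(delta0 cos^2 alpha)/sin(delta0); only the bin labels are
    normative, the continuous estimate is model-dependent.

    Accepts scalars or arrays; returns ``(alpha_deg, bin)`` where the bin is
    one of ``"inplane"``, ``"inclined"``, ``"steep"`` (an object array for
    array input).
    """
    params = params or PLIModelParams()
    r = np.asarray(retardation, dtype=float)
    if np.any((r < 0) | (r > 1) | ~np.isfinite(r)):
        raise ValueError("retardation must lie in [0, 1]")
    d0 = params.delta0_rad
    # invert r = sin(d0*cos^2 a)/sin(d0): cos^2 a = arcsin(r*sin d0)/d0
    arg = np.clip(r * np.sin(d0), -1.0, 1.0)
    cos2a = np.clip(np.arcsin(arg) / d0, 0.0, 1.0)
    alpha = np.degrees(np.arccos(np.sqrt(cos2a)))
    bins = np.where(r >= params.inplane_ret_min, "inplane",
                    np.where(r <= params.steep_ret_max, "steep", "inclined"))
    if np.isscalar(retardation) or np.ndim(retardation) == 0:
        return float(alpha), str(bins)
    return alpha, bins
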