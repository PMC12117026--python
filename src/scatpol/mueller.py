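"""Per-pixel Mueller-matrix estimation and Lu-Chipman decomposition.

A Mueller polarimeter probes the sample with a sequence of polarization
states: the polarization state generator (PSG) prepares a Stokes vector g_s,
the polarization state analyzer (PSA) projects onto an analyzer row vector
a_s, and the measured intensity is I_s = a_s . M . g_s. With at least 16
well-chosen states the 16 elements of M follow from a linear least-squares
solve per pixel. The Lu-Chipman polar decomposition then factors
M = M_depol . M_ret . M_diat, yielding the scalar summaries
diattenuation D, retardance R, depolarization, and the linear-retardance
fast-axis orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .stack import AngularStack

__all__ = [
    "PolarimetricSequence",
    "MuellerMaps",
    "polarimetric_states",
    "forward_simulate",
    "solve_mueller",
    "lu_chipman",
    "lu_chipman_maps",
    "linear_retarder",
    "diattenuator",
]

_BASIS_STOKES = {
    "H": (1.0, 1.0, 0.0, 0.0),
    "V": (1.0, -1.0, 0.0, 0.0),
    "P": (1.0, 0.0, 1.0, 0.0),
    "M": (1.0, 0.0, -1.0, 0.0),
    "R": (1.0, 0.0, 0.0, 1.0),
    "L": (1.0, 0.0, 0.0, -1.0),
}


def polarimetric_states(scheme: str = "6x6"):
    """Standard (psg_stokes, psa_rows) state sequences.

    ``"6x6"`` combines the six canonical polarization states (H, V, +45, -45,
    right/left circular) on both generator and analyzer (36 states);
    ``"4x4"`` uses the H, V, +45, R subset (16 states, minimal). The analyzer
    row of an ideal polarizer for state s is a = (1, s1, s2, s3)/2.
    """
    keys = {"6x6": "HVPMRL", "4x4": "HVPR"}.get(scheme)
    if keys is None:
        raise ValueError("scheme must be '6x6' or '4x4'")
    basis = np.array([_BASIS_STOKES[k] for k in keys])
    psg = np.repeat(basis, len(basis), axis=0)
    psa = 0.5 * np.tile(basis, (len(basis), 1))
    return psg, psa


@dataclass
class PolarimetricSequence:
    """Intensity frames with their generated Stokes vectors and analyzer rows.

    ``intensities`` has shape (n_states, H, W); ``psg_stokes`` and
    ``psa_rows`` are (n_states, 4). The Kronecker design matrix built from
    them must have full column rank (16).
    """

    intensities: np.ndarray
    psg_stokes: np.ndarray
    psa_rows: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.psg_stokes = np.asarray(self.psg_stokes, dtype=float)
        self.psa_rows = np.asarray(self.psa_rows, dtype=float)
        n = self.intensities.shape[0]
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have shape (n_states, H, W)")
        if self.psg_stokes.shape != (n, 4) or self.psa_rows.shape != (n, 4):
            raise ValueError("psg_stokes and psa_rows must have shape (n_states, 4)")
        if n < 16:
            raise ValueError("need at least 16 polarization states")

    @property
    def design_matrix(self) -> np.ndarray:
        """(n_states, 16) matrix with row s = kron(psa_row_s, psg_stokes_s),
        so that I_s = design . vec(M) for row-major vec."""
        return np.einsum("si,sj->sij", self.psa_rows,
                         self.psg_stokes).reshape(-1, 16)

    @classmethod
    def from_stack(cls, stack: AngularStack, psg_stokes, psa_rows):
        return cls(stack.intensities, psg_stokes, psa_rows)


@dataclass
class MuellerMaps:
    """Per-pixel Mueller matrices with Lu-Chipman scalar summaries."""

    M: np.ndarray
    diattenuation: np.ndarray
    retardance_deg: np.ndarray
    depolarization: np.ndarray
    linear_ret_orientation_deg: np.ndarray


def forward_simulate(M: np.ndarray, psg_stokes, psa_rows) -> np.ndarray:
    """Intensities I_s = a_s . M . g_s for one matrix (4,4) or a map
    (H, W, 4, 4); returns (n_states,) or (n_states, H, W)."""
    M = np.asarray(M, dtype=float)
    psg = np.asarray(psg_stokes, dtype=float)
    psa = np.asarray(psa_rows, dtype=float)
    if M.ndim == 2:
        return np.einsum("si,ij,sj->s", psa, M, psg)
    return np.einsum("si,hwij,sj->shw", psa, M, psg)


def solve_mueller(seq: PolarimetricSequence) -> np.ndarray:
    """Per-pixel least-squares Mueller matrix, shape (H, W, 4, 4).

    Raises if the state sequence is rank deficient, naming the unresolvable
    Mueller-matrix elements.
    """
    design = seq.design_matrix
    rank = np.linalg.matrix_rank(design)
    if rank < 16:
        _, _, piv = scipy.linalg.qr(design, pivoting=True)
        bad = sorted(piv[rank:])
        names = [f"m{i // 4}{i % 4}" for i in bad]
        raise ValueError(
            f"rank-deficient state sequence (rank {rank} < 16); "
            f"unresolvable elements: {', '.join(names)}")
    n, h, w = seq.intensities.shape
    flat = seq.intensities.reshape(n, -1)
    m, *_ = np.linalg.lstsq(design, flat, rcond=None)
    return m.T.reshape(h, w, 4, 4)


def linear_retarder(retardance_deg: float, orientation_deg: float) -> np.ndarray:
    """Mueller matrix of an ideal linear retarder (fast axis at the given
    orientation)."""
    d = np.deg2rad(retardance_deg)
    c, s = np.cos(2 * np.deg2rad(orientation_deg)), np.sin(2 * np.deg2rad(orientation_deg))
    cd, sd = np.cos(d), np.sin(d)
    return np.array([
        [1, 0, 0, 0],
        [0, c * c + s * s * cd, s * c * (1 - cd), -s * sd],
        [0, s * c * (1 - cd), s * s + c * c * cd, c * sd],
        [0, s * sd, -c * sd, cd],
    ])


def diattenuator(q: float, r: float, orientation_deg: float = 0.0) -> np.ndarray:
    """Mueller matrix of a linear diattenuator with principal intensity
    transmittances q >= r along/across the given axis."""
    c, s = np.cos(2 * np.deg2rad(orientation_deg)), np.sin(2 * np.deg2rad(orientation_deg))
    a, b, g = (q + r) / 2, (q - r) / 2, np.sqrt(q * r)
    return np.array([
        [a, b * c, b * s, 0],
        [b * c, a * c * c + g * s * s, (a - g) * s * c, 0],
        [b * s, (a - g) * s * c, a * s * s + g * c * c, 0],
        [0, 0, 0, g],
    ])


def lu_chipman_factors(M: np.ndarray):
    """Full Lu-Chipman factorization M/m00 = M_depol @ M_ret @ M_diat.

    Returns the three 4x4 factors (depolarizer, retarder, diattenuator) of
    the normalized matrix; multiplying them and scaling by m00 reproduces M
    for physical inputs.
    """
    M = np.asarray(M, dtype=float)
    m00 = M[0, 0]
    if not np.isfinite(m00) or m00 <= 0:
        raise ValueError("m00 must be positive")
    Mh = M / m00
    dvec = Mh[0, 1:]
    D = float(np.linalg.norm(dvec))
    if D >= 1:
        raise ValueError("non-physical Mueller matrix: diattenuation >= 1")
    if D > 1e-12:
        dhat = dvec / D
        mD = np.sqrt(1 - D**2) * np.eye(3) + (1 - np.sqrt(1 - D**2)) * np.outer(dhat, dhat)
    else:
        mD = np.eye(3)
    MD = np.eye(4)
    MD[0, 1:] = dvec
    MD[1:, 0] = dvec
    MD[1:, 1:] = mD

    Mp = Mh @ np.linalg.inv(MD)
    mp = Mp[1:, 1:]
    mmT = mp @ mp.T
    lam = np.clip(np.linalg.eigvalsh(mmT), 0.0, None)
    sq = np.sqrt(lam)
    if sq.max() < 1e-12:
        m_delta = np.zeros((3, 3))
        m_R = np.eye(3)
    else:
        sign = np.sign(np.linalg.det(mp)) or 1.0
        a = sq[0] * sq[1] + sq[1] * sq[2] + sq[0] * sq[2]
        m_delta = sign * np.linalg.solve(mmT + a * np.eye(3),
                                         sq.sum() * mmT + sq.prod() * np.eye(3))
        m_R = np.linalg.pinv(m_delta) @ mp
    Mdelta = np.eye(4)
    Mdelta[1:, 0] = Mp[1:, 0]
    Mdelta[1:, 1:] = m_delta
    MR = np.eye(4)
    MR[1:, 1:] = m_R
    return Mdelta, MR, MD


def lu_chipman(M: np.ndarray) -> tuple[float, float, float, float]:
    """Lu-Chipman polar decomposition scalar summaries of one Mueller matrix.

    Returns ``(D, R_deg, depol, orientation_deg)``: diattenuation
    D = ||(m01, m02, m03)|| / m00; retardance R = arccos(tr(M_R)/2 - 1) of the
    retarder factor; depolarization index 1 - |tr(M_depol) - 1| / 3; and the
    fast-axis orientation of the linear retardance component in [0, 180)
    (NaN when the retardance vanishes or is purely circular).
    Raises for m00 <= 0 or non-physical matrices (diattenuation >= 1).
    """
    M = np.asarray(M, dtype=float)
    if M.shape != (4, 4):
        raise ValueError("M must be 4x4")
    Mdelta, MR, MD = lu_chipman_factors(M)
    D = float(np.linalg.norm(MD[0, 1:]))
    m_delta = Mdelta[1:, 1:]
    m_R = MR[1:, 1:]

    depol = float(1 - abs(np.trace(m_delta)) / 3)
    cosR = np.clip((np.trace(m_R) - 1) / 2, -1.0, 1.0)
    R = float(np.degrees(np.arccos(cosR)))

    sinR = np.sin(np.deg2rad(R))
    if sinR > 1e-9:
        a1 = (m_R[1, 2] - m_R[2, 1]) / (2 * sinR)
        a2 = (m_R[2, 0] - m_R[0, 2]) / (2 * sinR)
        if abs(a1) < 1e-12 and abs(a2) < 1e-12:
            orientation = np.nan  # purely circular retardance
        else:
            orientation = float(np.degrees(0.5 * np.arctan2(a2, a1)) % 180.0)
    else:
        orientation = np.nan
    return D, R, depol, orientation


def lu_chipman_maps(M_maps: np.ndarray) -> MuellerMaps:
    """Lu-Chipman summaries per pixel; pixels where the decomposition fails
    (non-positive m00, non-physical matrix) yield NaN instead of aborting."""
    M_maps = np.asarray(M_maps, dtype=float)
    h, w = M_maps.shape[:2]
    out = {k: np.full((h, w), np.nan) for k in ("D", "R", "depol", "ori")}
    for i in range(h):
        for j in range(w):
            try:
                d, r, p, o = lu_chipman(M_maps[i, j])
            except ValueError:
                continue
            out["D"][i, j], out["R"][i, j] = d, r
            out["depol"][i, j], out["ori"][i, j] = p, o
    return MuellerMaps(M=M_maps, diattenuation=out["D"],
                       retardance_deg=out["R"], depolarization=out["depol"],
                       linear_ret_orientation_deg=out["ori"])
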