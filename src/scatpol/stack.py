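"""Angular image stacks: the common container for 3D-PLI and ComSLI acquisitions.

An acquisition is a sequence of camera frames, one per polarizer azimuth
(3D-PLI) or per azimuthal illumination angle (ComSLI). The stack stores the
frames as a single ``(n_angles, H, W)`` array together with the angle list and
a modality tag, and validates the geometric conventions of each modality on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

MODALITIES = ("pli", "comsli", "mueller")


@dataclass
class AngularStack:
    """A 3-D intensity array (angles x rows x cols) with its angle list.

    Parameters
    ----------
    intensities
        Non-negative, finite intensities in arbitrary units, shape
        ``(n_angles, H, W)``.
    angles_deg
        Strictly increasing azimuths in degrees; length must equal the number
        of frames. 3D-PLI angles live in [0, 180), ComSLI angles in [0, 360).
    modality
        One of ``"pli"``, ``"comsli"``, ``"mueller"``.
    meta
        Free-form acquisition metadata (exposure, wavelength, repetitions...).
    """

    intensities: np.ndarray
    angles_deg: np.ndarray
    modality: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must have shape (n_angles, H, W)")
        if self.angles_deg.ndim != 1 or len(self.angles_deg) != self.intensities.shape[0]:
            raise ValueError("angles_deg length must match the number of frames")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}, expected one of {MODALITIES}")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise ValueError("angles_deg must be strictly increasing")
        if self.modality == "pli":
            if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 180:
                raise ValueError("pli angles must lie in [0, 180)")
        elif self.modality == "comsli":
            if self.angles_deg[0] < 0 or self.angles_deg[-1] >= 360:
                raise ValueError("comsli angles must lie in [0, 360)")

    @property
    def n_angles(self) -> int:
        return self.intensities.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Image shape (H, W)."""
        return self.intensities.shape[1:]


def require_modality(stack: AngularStack, modality: str) -> None:
    if stack.modality != modality:
        raise ValueError(f"expected a {modality!r} stack, got {stack.modality!r}")
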