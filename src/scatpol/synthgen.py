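"""Ground-truth fiber phantoms and forward simulation of 3D-PLI / ComSLI stacks.

The phantom emulates the tissue geometries used to validate correlative
polarimetric/scattering measurements of brain sections: a background frame,
a gray-matter band, and white-matter regions with in-plane, inclined, and
steep parallel fibers plus two- and three-way crossings (mirroring corpus
callosum, fornix, cingulum, and corona radiata architectures).

Forward models
--------------
3D-PLI: per pixel an incoherent weighted sum of population sinusoids,

    I(rho) = I_base * (1 + sum_p w_p * sin(delta(alpha_p)) * sin(2(rho - phi_p)))

with delta(alpha) = delta0 * cos^2(alpha); equal populations 90 degrees apart
therefore cancel, reproducing PLI's blindness to orthogonal crossings.

ComSLI: per pixel a baseline plus, per population, a pair of wrapped-Gaussian
peaks whose mid-position mod 180 equals phi (peaks perpendicular to the fiber
axis) and whose separation shrinks with inclination as d(alpha) =
180 - kappa*alpha. Steep-fiber pixels get a broad, low-contrast profile on an
elevated baseline (strong average scattering without reliable peaks); gray
matter gets flat low profiles; background a constant low level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion import Architecture, Tissue
from .stack import AngularStack

__all__ = [
    "Region",
    "FiberPhantom",
    "NoiseSpec",
    "make_phantom",
    "simulate_pli_stack",
    "simulate_comsli_stack",
    "inject_artifacts",
]

MAX_POPULATIONS = 3


@dataclass
class Region:
    """A rectangular phantom region: pixel rows/cols (half-open slices),
    tissue and architecture labels, and its fiber populations as
    (direction_deg, inclination_deg, weight) triples."""

    name: str
    rows: tuple[int, int]
    cols: tuple[int, int]
    tissue: Tissue
    architecture: Architecture = Architecture.NONE
    populations: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        if len(self.populations) > MAX_POPULATIONS:
            raise ValueError("at most 3 fiber populations per region")
        if self.tissue == Tissue.BACKGROUND and self.populations:
            raise ValueError("background regions carry no fiber populations")
        if sum(w for _, _, w in self.populations) > 1 + 1e-12:
            raise ValueError("population weights must sum to <= 1")
        for d, a, w in self.populations:
            if not (0 <= d < 180 and 0 <= a <= 90 and 0 < w <= 1):
                raise ValueError("populations must satisfy 0<=dir<180, 0<=incl<=90, 0<w<=1")


@dataclass
class NoiseSpec:
    """Additive Gaussian noise (a.u.) and optional Poisson shot noise on the
    expected counts; identical seeds give identical stacks."""

    gaussian_sigma: float = 0.0
    poisson: bool = False
    seed: int = 0


@dataclass
class FiberPhantom:
    """Per-pixel ground truth: up to three fiber populations (direction,
    inclination, weight; NaN/0-padded) plus tissue and architecture labels."""

    directions_deg: np.ndarray      # (H, W, 3), NaN where absent
    inclinations_deg: np.ndarray    # (H, W, 3)
    weights: np.ndarray             # (H, W, 3), 0 where absent
    tissue_truth: np.ndarray        # (H, W) uint8, Tissue values
    architecture_truth: np.ndarray  # (H, W) uint8, Architecture values
    regions: tuple[Region, ...] = ()

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_truth.shape

    def n_populations(self) -> np.ndarray:
        return (self.weights > 0).sum(axis=2)

    def pli_signal_coefficients(self, delta0_rad: float = np.pi / 2):
        """Complex per-pixel birefringence signal z = sum_p w_p sin(delta_p)
        exp(2i phi_p); |z| is the expected retardation and angle(z)/2 mod 180
        the expected fitted direction."""
        sin_delta = np.sin(delta0_rad * np.cos(np.deg2rad(self.inclinations_deg)) ** 2)
        term = np.where(self.weights > 0,
                        self.weights * sin_delta
                        * np.exp(2j * np.deg2rad(self.directions_deg)), 0.0)
        return term.sum(axis=2)

    def expected_retardation(self, delta0_rad: float = np.pi / 2) -> np.ndarray:
        r = np.abs(self.pli_signal_coefficients(delta0_rad))
        return np.where(self.tissue_truth == Tissue.BACKGROUND, 0.0, r)

    def expected_direction(self, delta0_rad: float = np.pi / 2) -> np.ndarray:
        z = self.pli_signal_coefficients(delta0_rad)
        phi = np.degrees(np.angle(z) / 2.0) % 180.0
        return np.where((np.abs(z) == 0) | (self.tissue_truth == Tissue.BACKGROUND),
                        np.nan, phi)


def _vervet_like_regions(shape: tuple[int, int]) -> list[Region]:
    """Background frame around a gray-matter band, three parallel-fiber bands
    (in-plane / inclined / steep), and 2-/3-way crossing blocks.

    Inclination values are chosen so that, under the default model
    delta0 = pi/2, each band's retardation falls inside its classification
    bin (in-plane: 1.0; inclined at 50 deg: ~0.60; steep at 75 deg: ~0.105);
    crossing weights are unequal so that the residual sinusoid amplitude
    stays above the gray-matter threshold.
    """
    h, w = shape
    b = max(2, h // 8)
    if h - 2 * b < 6 or w - 2 * b < 1:
        raise ValueError("phantom too small for the vervet-like layout")
    frame = [
        Region("background_top", (0, b), (0, w), Tissue.BACKGROUND),
        Region("background_bottom", (h - b, h), (0, w), Tissue.BACKGROUND),
        Region("background_left", (b, h - b), (0, b), Tissue.BACKGROUND),
        Region("background_right", (b, h - b), (w - b, w), Tissue.BACKGROUND),
    ]
    edges = np.linspace(b, h - b, 7).astype(int)
    c0, c1 = b, w - b
    bands = [
        Region("gray_matter", (edges[0], edges[1]), (c0, c1), Tissue.GRAY,
               Architecture.NONE, ((20.0, 0.0, 0.04),)),
        Region("inplane", (edges[1], edges[2]), (c0, c1), Tissue.WHITE,
               Architecture.PARALLEL_INPLANE, ((30.0, 0.0, 1.0),)),
        Region("inclined", (edges[2], edges[3]), (c0, c1), Tissue.WHITE,
               Architecture.PARALLEL_INCLINED, ((120.0, 50.0, 1.0),)),
        Region("steep", (edges[3], edges[4]), (c0, c1), Tissue.WHITE,
               Architecture.PARALLEL_STEEP, ((60.0, 75.0, 1.0),)),
        Region("crossing_2way", (edges[4], edges[5]), (c0, c1), Tissue.WHITE,
               Architecture.CROSSING, ((0.0, 0.0, 0.56), (90.0, 0.0, 0.44))),
        Region("crossing_3way", (edges[5], edges[6]), (c0, c1), Tissue.WHITE,
               Architecture.CROSSING,
               ((0.0, 0.0, 0.40), (60.0, 0.0, 0.33), (120.0, 0.0, 0.27))),
    ]
    return frame + bands


def make_phantom(layout: str | list[Region] = "vervet-like",
                 shape: tuple[int, int] = (64, 64), seed: int = 0,
                 direction_jitter_deg: float = 0.0) -> FiberPhantom:
    """Build a ground-truth phantom from a named layout or a region list.

    Regions must tile the image exactly; overlapping or uncovered pixels
    raise. ``direction_jitter_deg`` adds seeded, per-pixel uniform jitter
    within +/- that value to all population directions (reproducible for a
    given seed).
    """
    if isinstance(layout, str):
        if layout != "vervet-like":
            raise ValueError(f"unknown layout {layout!r}")
        regions = _vervet_like_regions(shape)
    else:
        regions = list(layout)

    h, w = shape
    coverage = np.zeros(shape, dtype=int)
    directions = np.full((h, w, MAX_POPULATIONS), np.nan)
    inclinations = np.full((h, w, MAX_POPULATIONS), np.nan)
    weights = np.zeros((h, w, MAX_POPULATIONS))
    tissue = np.zeros(shape, dtype=np.uint8)
    arch = np.zeros(shape, dtype=np.uint8)
    for reg in regions:
        sl = (slice(*reg.rows), slice(*reg.cols))
        coverage[sl] += 1
        tissue[sl] = reg.tissue
        arch[sl] = reg.architecture
        for p, (d, a, wt) in enumerate(reg.populations):
            directions[sl + (p,)] = d
            inclinations[sl + (p,)] = a
            weights[sl + (p,)] = wt
    if np.any(coverage > 1):
        raise ValueError("overlapping phantom regions")
    if np.any(coverage == 0):
        raise ValueError("phantom regions do not tile the image")

    if direction_jitter_deg > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-direction_jitter_deg, direction_jitter_deg,
                             size=directions.shape)
        directions = np.where(np.isnan(directions), np.nan,
                              (directions + jitter) % 180.0)
    return FiberPhantom(directions_deg=directions, inclinations_deg=inclinations,
                        weights=weights, tissue_truth=tissue,
                        architecture_truth=arch, regions=tuple(regions))


def _apply_noise(stack: np.ndarray, noise: NoiseSpec | None) -> np.ndarray:
    if noise is None or (noise.gaussian_sigma == 0 and not noise.poisson):
        return stack
    rng = np.random.default_rng(noise.seed)
    out = stack
    if noise.poisson:
        out = rng.poisson(np.clip(out, 0, None)).astype(float)
    if noise.gaussian_sigma > 0:
        # same seed -> same standard-normal draws, scaled by sigma
        out = out + noise.gaussian_sigma * rng.standard_normal(out.shape)
    return np.clip(out, 0.0, None)


def simulate_pli_stack(phantom: FiberPhantom, n_angles: int = 18,
                       base_intensity: float = 1000.0,
                       background_intensity: float = 10.0,
                       delta0_rad: float = np.pi / 2,
                       noise: NoiseSpec | None = None) -> AngularStack:
    """Forward-simulate an n-frame 3D-PLI stack (default 18 frames, 10-degree
    polarizer steps over [0, 180))."""
    if n_angles < 3:
        raise ValueError("need at least 3 polarizer angles")
    angles = np.arange(n_angles) * 180.0 / n_angles
    rho = np.deg2rad(angles)
    z = phantom.pli_signal_coefficients(delta0_rad)
    # I = base*(1 + Re(z) sin 2rho - Im(z) cos 2rho)
    stack = base_intensity * (1.0
                              + np.sin(2 * rho)[:, None, None] * z.real[None]
                              - np.cos(2 * rho)[:, None, None] * z.imag[None])
    bg = phantom.tissue_truth == Tissue.BACKGROUND
    stack[:, bg] = background_intensity
    stack = _apply_noise(stack, noise)
    return AngularStack(stack, angles, "pli",
                        meta={"simulated": True, "base_intensity": base_intensity})


def _wrapped_gaussian(angles_deg: np.ndarray, center_deg: float,
                      sigma_deg: float) -> np.ndarray:
    d = (angles_deg - center_deg + 180.0) % 360.0 - 180.0
    return np.exp(-0.5 * (d / sigma_deg) ** 2)


@dataclass
class ComSLIModel:
    """Scattering-profile model constants (arbitrary units, degrees)."""

    baseline: float = 300.0
    peak_amplitude: float = 200.0
    peak_sigma_deg: float = 20.0
    background_level: float = 5.0
    gray_level: float = 100.0
    steep_baseline: float = 1500.0
    steep_amplitude: float = 2.0
    steep_sigma_deg: float = 60.0
    kappa: float = 0.5  # pair-distance law d(alpha) = 180 - kappa*alpha


def simulate_comsli_stack(phantom: FiberPhantom, n_angles: int = 24,
                          noise: NoiseSpec | None = None,
                          model: ComSLIModel | None = None) -> AngularStack:
    """Forward-simulate an n-frame ComSLI stack (default 24 frames, 15-degree
    azimuthal illumination steps over [0, 360)).

    Each fiber population contributes a wrapped-Gaussian peak pair centered
    at phi + 180 +/- d(alpha)/2 with amplitude proportional to its weight, so
    the pair mid-position mod 180 equals phi and in-plane fibers reach the
    maximum pair distance of 180 degrees. Steep-fiber pixels get a broad,
    low-contrast profile on an elevated baseline; gray matter a flat low
    profile; background a constant low level.
    """
    if n_angles < 8:
        raise ValueError("need at least 8 illumination angles")
    model = model or ComSLIModel()
    angles = np.arange(n_angles) * 360.0 / n_angles
    h, w = phantom.shape
    stack = np.zeros((n_angles, h, w))

    tissue, arch = phantom.tissue_truth, phantom.architecture_truth
    stack[:, tissue == Tissue.BACKGROUND] = model.background_level
    stack[:, tissue == Tissue.GRAY] = model.gray_level

    white = tissue == Tissue.WHITE
    steep = white & (arch == Architecture.PARALLEL_STEEP)
    normal = white & ~steep
    for mask, baseline, amplitude, sigma in (
            (normal, model.baseline, model.peak_amplitude, model.peak_sigma_deg),
            (steep, model.steep_baseline, model.steep_amplitude, model.steep_sigma_deg)):
        if not mask.any():
            continue
        idx = np.argwhere(mask)
        dirs = phantom.directions_deg[mask]
        incl = phantom.inclinations_deg[mask]
        wts = phantom.weights[mask]
        profiles = np.full((idx.shape[0], n_angles), baseline)
        for p in range(MAX_POPULATIONS):
            present = wts[:, p] > 0
            if not present.any():
                continue
            d_pair = 180.0 - model.kappa * incl[present, p]
            center = dirs[present, p] + 180.0
            amp = (amplitude * wts[present, p])[:, None]
            for sign in (-1.0, 1.0):
                c = (center + sign * d_pair / 2)[:, None]
                profiles[present] += amp * _wrapped_gaussian(angles[None], c, sigma)
        stack[:, idx[:, 0], idx[:, 1]] = profiles.T

    stack = _apply_noise(stack, noise)
    return AngularStack(stack, angles, "comsli", meta={"simulated": True})


@dataclass
class ArtifactSpec:
    """A deterministic acquisition artifact overlay.

    ``kind`` is ``"gain_gradient"`` (multiplicative linear gain ramp from
    1 - magnitude to 1 + magnitude across the image, emulating transmittance
    asymmetry) or ``"wheel"`` (localized radial artifact for ComSLI stacks:
    an additive azimuthal modulation whose phase rotates around ``center``,
    producing spurious direction 'wheels'). Ground truth is unchanged.
    """

    kind: str
    magnitude: float = 0.0
    axis: int = 1                      # gain_gradient: 0 = rows, 1 = cols
    center: tuple[int, int] = (0, 0)   # wheel
    radius: float = 0.0                # wheel


def inject_artifacts(stack: AngularStack, specs) -> AngularStack:
    """Apply deterministic artifact overlays to a copy of the stack."""
    if isinstance(specs, ArtifactSpec):
        specs = [specs]
    data = stack.intensities.copy()
    n, h, w = data.shape
    for spec in specs:
        if spec.magnitude == 0:
            continue
        if spec.kind == "gain_gradient":
            size = (h, w)[spec.axis]
            ramp = 1.0 + spec.magnitude * (2.0 * np.arange(size) / max(size - 1, 1) - 1.0)
            shape = [1, 1, 1]
            shape[1 + spec.axis] = size
            data *= ramp.reshape(shape)
        elif spec.kind == "wheel":
            rr, cc = np.mgrid[0:h, 0:w]
            dr, dc = rr - spec.center[0], cc - spec.center[1]
            dist = np.hypot(dr, dc)
            inside = dist <= spec.radius
            theta = np.degrees(np.arctan2(dr, dc))
            rho = stack.angles_deg[:, None, None]
            mod = spec.magnitude * (1.0 + np.cos(np.deg2rad(2 * (rho - theta[None]))))
            data += np.where(inside[None], mod, 0.0)
        else:
            raise ValueError(f"unknown artifact kind {spec.kind!r}")
    return AngularStack(np.clip(data, 0.0, None), stack.angles_deg,
                        stack.modality, dict(stack.meta))
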