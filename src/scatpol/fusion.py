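"""Tissue/fiber-architecture classification and multimodal map fusion.

3D-PLI is robust but blind to fiber crossings (it averages over crossing
bundles); ComSLI resolves up to three crossing directions but is noisier.
This module classifies every pixel from the joint parameter maps and then
assembles a multimodal fiber direction map that keeps, per pixel, the most
reliable direction(s) from either modality:

tissue:   background  <=> mean scattering Ibar <= bg_avg_max (no scattering)
          gray matter <=> not background and retardation < gm_ret_max
          white matter otherwise
architecture (within white matter):
          in-plane parallel  <=> retardation >= 0.68  (inclination <= 30 deg)
          inclined parallel  <=> 0.17 < r < 0.68 and peak prominence high
          steep parallel     <=> r <= 0.17 and strong average scattering
          crossing           <=> the remaining white-matter pixels
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np
import yaml

from .comsli import SLIMaps
from .pli import PLIMaps

__all__ = [
    "Tissue",
    "Architecture",
    "Source",
    "FusionConfig",
    "TissueClassMap",
    "MultimodalMap",
    "angular_difference",
    "pli_sli_difference_map",
    "classify_tissue",
    "classify_architecture",
    "apply_direction_offset",
    "build_multimodal_map",
]


class Tissue(enum.IntEnum):
    BACKGROUND = 0
    GRAY = 1
    WHITE = 2


class Architecture(enum.IntEnum):
    NONE = 0
    PARALLEL_INPLANE = 1
    PARALLEL_INCLINED = 2
    PARALLEL_STEEP = 3
    CROSSING = 4


class Source(enum.IntEnum):
    NONE = 0
    PLI = 1
    SLI = 2


#: classification thresholds per sample preset (peak prominence and average
#: scattering are in raw camera units and therefore sample-dependent)
PRESETS = {
    "human": dict(prominence_min=0.3, steep_avg_min=1200.0),
    "vervet": dict(prominence_min=1.0, steep_avg_min=430.0),
}


@dataclass
class FusionConfig:
    """Thresholds for classification and fusion.

    All intensity-like values (``bg_avg_max``, ``steep_avg_min``,
    ``prominence_min``) are in the arbitrary units of the ComSLI acquisition;
    retardation thresholds are on the normalized retardation in [0, 1];
    ``agree_tol_deg`` is the angular tolerance deciding whether the PLI and
    ComSLI directions "agree"; ``phi_off_deg`` a global direction offset.
    """

    bg_avg_max: float = 20.0
    gm_ret_max: float = 0.07
    inplane_ret_min: float = 0.68
    steep_ret_max: float = 0.17
    prominence_min: float = 0.3
    steep_avg_min: float = 1200.0
    agree_tol_deg: float = 25.0
    phi_off_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.steep_ret_max < self.inplane_ret_min <= 1):
            raise ValueError("require 0 < steep_ret_max < inplane_ret_min <= 1")
        if not (0 < self.agree_tol_deg < 90):
            raise ValueError("agree_tol_deg must lie in (0, 90)")

    @classmethod
    def preset(cls, name: str, **overrides) -> "FusionConfig":
        try:
            values = PRESETS[name]
        except KeyError:
            raise ValueError(f"unknown preset {name!r}, expected one of {sorted(PRESETS)}")
        return cls(**{**values, **overrides})

    @classmethod
    def from_yaml(cls, path) -> "FusionConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        preset = data.pop("preset", None)
        if preset is not None:
            return cls.preset(preset, **data)
        return cls(**data)

    def with_offset(self, phi_off_deg: float) -> "FusionConfig":
        return replace(self, phi_off_deg=phi_off_deg)


@dataclass
class TissueClassMap:
    """Per-pixel tissue labels and, within white matter, fiber architecture."""

    tissue: np.ndarray
    architecture: np.ndarray


@dataclass
class MultimodalMap:
    """Fused fiber direction map: up to three directions per pixel plus the
    per-channel provenance (none / pli / sli)."""

    directions_deg: np.ndarray
    source: np.ndarray


def angular_difference(a_deg, b_deg):
    """Absolute difference between two axial directions, in [0, 90] degrees.

    Directions are 180-degree periodic; NaN inputs propagate to NaN.
    """
    a = np.asarray(a_deg, dtype=float)
    b = np.asarray(b_deg, dtype=float)
    d = np.abs(a - b) % 180.0
    out = np.minimum(d, 180.0 - d)
    if out.ndim == 0:
        return float(out)
    return out


def pli_sli_difference_map(pli: PLIMaps, sli: SLIMaps) -> np.ndarray:
    """Per pixel, the absolute difference between the PLI direction and the
    closest of the ComSLI directions; NaN where either side has none."""
    phi = pli.direction_deg
    if phi.shape != sli.directions_deg.shape[:2]:
        raise ValueError("PLI and SLI maps must share the image shape")
    diffs = angular_difference(phi[..., None], sli.directions_deg)
    with np.errstate(all="ignore"):
        all_nan = np.all(np.isnan(diffs), axis=2)
        out = np.where(all_nan, np.nan,
                       np.nanmin(np.where(np.isnan(diffs), np.inf, diffs), axis=2))
    return out


def classify_tissue(avg: np.ndarray, retardation: np.ndarray,
                    cfg: FusionConfig) -> np.ndarray:
    """Background / gray / white labels from mean scattering and retardation.

    NaN retardation (invalid PLI pixel) on a non-background pixel counts as
    zero retardation, i.e. gray matter.
    """
    avg = np.asarray(avg, dtype=float)
    ret = np.asarray(retardation, dtype=float)
    if avg.shape != ret.shape:
        raise ValueError("maps must share shape")
    ret = np.where(np.isnan(ret), 0.0, ret)
    tissue = np.full(avg.shape, Tissue.WHITE, dtype=np.uint8)
    tissue[ret < cfg.gm_ret_max] = Tissue.GRAY
    tissue[avg <= cfg.bg_avg_max] = Tissue.BACKGROUND
    return tissue


def classify_architecture(tissue: np.ndarray, retardation: np.ndarray,
                          max_prominence: np.ndarray, avg: np.ndarray,
                          cfg: FusionConfig) -> np.ndarray:
    """Fiber-architecture labels within white matter.

    Parallel fibers are identified per inclination bin (in-plane via high
    retardation; inclined via mid retardation plus a comparatively high peak
    prominence; steep via low retardation plus strong average scattering);
    white-matter pixels matching none of these are classified as crossing.
    """
    ret = np.where(np.isnan(retardation), 0.0, np.asarray(retardation, dtype=float))
    white = np.asarray(tissue) == Tissue.WHITE
    arch = np.full(ret.shape, Architecture.NONE, dtype=np.uint8)
    inplane = ret >= cfg.inplane_ret_min
    inclined = (ret > cfg.steep_ret_max) & (ret < cfg.inplane_ret_min) \
        & (max_prominence >= cfg.prominence_min)
    steep = (ret <= cfg.steep_ret_max) & (avg > cfg.steep_avg_min)
    arch[white] = Architecture.CROSSING
    arch[white & inplane] = Architecture.PARALLEL_INPLANE
    arch[white & inclined] = Architecture.PARALLEL_INCLINED
    arch[white & steep] = Architecture.PARALLEL_STEEP
    return arch


def classify(pli: PLIMaps, sli: SLIMaps, cfg: FusionConfig) -> TissueClassMap:
    """Tissue plus architecture classification from the two map sets."""
    tissue = classify_tissue(sli.average, pli.retardation, cfg)
    arch = classify_architecture(tissue, pli.retardation, sli.max_prominence,
                                 sli.average, cfg)
    return TissueClassMap(tissue=tissue, architecture=arch)


def apply_direction_offset(directions, phi_off_deg: float):
    """Add a global direction offset (mod 180) to all non-NaN entries."""
    d = np.asarray(directions, dtype=float)
    return np.where(np.isnan(d), np.nan, (d + phi_off_deg) % 180.0)


def build_multimodal_map(pli: PLIMaps, sli: SLIMaps, classes: TissueClassMap,
                         cfg: FusionConfig) -> MultimodalMap:
    """Assemble the multimodal fiber direction map.

    Per pixel, the first matching rule wins:

    1. crossing pixels take all ComSLI directions (PLI cannot separate them);
    2. other white-matter pixels where the modalities disagree (closest-
       direction difference above ``agree_tol_deg``), or where no valid PLI
       direction exists, take the ComSLI directions;
    3. white parallel pixels where the PLI direction agrees with some ComSLI
       direction take the (more stable) PLI direction in channel 1 and keep
       the remaining ComSLI directions;
    4. gray-matter pixels take ComSLI channel 1 if present, else the PLI
       direction; further ComSLI channels are kept;
    5. background pixels, and white pixels without any ComSLI direction, stay
       empty — an unsupported PLI direction is not considered reliable there.
    """
    h, w = pli.direction_deg.shape
    if sli.directions_deg.shape[:2] != (h, w):
        raise ValueError("PLI and SLI maps must share the image shape")
    k = sli.directions_deg.shape[2]

    phi_pli = pli.direction_deg
    sli_dirs = sli.directions_deg
    has_sli = ~np.all(np.isnan(sli_dirs), axis=2)
    has_pli = ~np.isnan(phi_pli)
    diff = pli_sli_difference_map(pli, sli)

    tissue, arch = classes.tissue, classes.architecture
    white = tissue == Tissue.WHITE
    gray = tissue == Tissue.GRAY
    crossing = arch == Architecture.CROSSING

    with np.errstate(invalid="ignore"):
        disagree = diff > cfg.agree_tol_deg
        agree = diff <= cfg.agree_tol_deg
    rule1 = white & crossing
    rule2 = white & ~crossing & has_sli & (~has_pli | disagree)
    rule3 = white & ~crossing & has_sli & has_pli & agree & ~rule2

    directions = np.full((h, w, k), np.nan)
    source = np.full((h, w, k), Source.NONE, dtype=np.uint8)

    take_sli = rule1 | rule2
    directions[take_sli] = sli_dirs[take_sli]
    source[take_sli] = np.where(np.isnan(sli_dirs[take_sli]), Source.NONE, Source.SLI)

    directions[rule3, 0] = phi_pli[rule3]
    source[rule3, 0] = Source.PLI
    directions[rule3, 1:] = sli_dirs[rule3, 1:]
    source[rule3, 1:] = np.where(np.isnan(sli_dirs[rule3, 1:]), Source.NONE, Source.SLI)

    g_sli1 = gray & ~np.isnan(sli_dirs[..., 0])
    g_pli = gray & np.isnan(sli_dirs[..., 0]) & has_pli
    directions[g_sli1, 0] = sli_dirs[g_sli1, 0]
    source[g_sli1, 0] = Source.SLI
    directions[g_pli, 0] = phi_pli[g_pli]
    source[g_pli, 0] = Source.PLI
    directions[gray, 1:] = sli_dirs[gray, 1:]
    source[gray, 1:] = np.where(np.isnan(sli_dirs[gray, 1:]), Source.NONE, Source.SLI)

    return MultimodalMap(directions_deg=directions, source=source)
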