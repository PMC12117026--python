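"""Tissue/architecture classification and multimodal fusion tests."""

import numpy as np
import pytest

from scatpol import (Architecture, FusionConfig, PLIMaps, Source, Tissue,
                     TissueClassMap, angular_difference, apply_direction_offset,
                     build_multimodal_map, classify, classify_architecture,
                     classify_tissue, pli_sli_difference_map)
from scatpol.comsli import SLIMaps


def make_pli(direction, retardation=0.5, shape=None):
    d = np.asarray(direction, dtype=float)
    shape = shape or d.shape
    ret = np.broadcast_to(np.asarray(retardation, float), shape).copy()
    return PLIMaps(transmittance=np.full(shape, 100.0), retardation=ret,
                   direction_deg=np.broadcast_to(d, shape).copy(),
                   valid=~np.isnan(np.broadcast_to(d, shape)))


def make_sli(directions, average=500.0, prominence=5.0):
    d = np.asarray(directions, dtype=float)
    h, w = d.shape[:2]
    return SLIMaps(average=np.full((h, w), float(average)),
                   directions_deg=d,
                   n_directions=np.sum(~np.isnan(d), axis=2).astype(int),
                   max_prominence=np.full((h, w), float(prominence)),
                   dominant_pair_distance_deg=np.full((h, w), 180.0))


class TestAngularDifference:
    @pytest.mark.parametrize("a,b,expected", [
        (30, 30, 0), (5, 175, 10), (0, 90, 90), (170, 10, 20), (179, 1, 2),
    ])
    def test_wraparound_examples(self, a, b, expected):
        assert angular_difference(a, b) == pytest.approx(expected)

    def test_nan_propagates(self):
        assert np.isnan(angular_difference(np.nan, 30))

    def test_symmetric_and_bounded(self, rng):
        a, b = rng.uniform(0, 180, 100), rng.uniform(0, 180, 100)
        d = angular_difference(a, b)
        assert np.allclose(d, angular_difference(b, a))
        assert np.all((d >= 0) & (d <= 90))


class TestDifferenceMap:
    def test_takes_closest_sli_direction(self):
        pli = make_pli([[40.0]])
        sli = make_sli(np.array([[[10.0, 100.0, np.nan]]]))
        assert pli_sli_difference_map(pli, sli)[0, 0] == pytest.approx(30.0)

    def test_nan_when_no_sli_direction(self):
        pli = make_pli([[40.0]])
        sli = make_sli(np.full((1, 1, 3), np.nan))
        assert np.isnan(pli_sli_difference_map(pli, sli)[0, 0])

    def test_zero_when_directions_match(self):
        pli = make_pli([[40.0]])
        sli = make_sli(np.array([[[40.0, np.nan, np.nan]]]))
        assert pli_sli_difference_map(pli, sli)[0, 0] == 0.0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            pli_sli_difference_map(make_pli([[40.0]]),
                                   make_sli(np.full((2, 2, 3), np.nan)))


class TestClassifyTissue:
    def test_low_scattering_dominates_as_background(self, human_cfg):
        t = classify_tissue(np.array([[15.0]]), np.array([[0.5]]), human_cfg)
        assert t[0, 0] == Tissue.BACKGROUND

    def test_low_retardation_is_gray(self, human_cfg):
        t = classify_tissue(np.array([[100.0]]), np.array([[0.05]]), human_cfg)
        assert t[0, 0] == Tissue.GRAY

    def test_remainder_is_white(self, human_cfg):
        t = classify_tissue(np.array([[100.0]]), np.array([[0.5]]), human_cfg)
        assert t[0, 0] == Tissue.WHITE

    def test_nan_retardation_counts_as_gray(self, human_cfg):
        t = classify_tissue(np.array([[100.0]]), np.array([[np.nan]]), human_cfg)
        assert t[0, 0] == Tissue.GRAY

    def test_raising_thresholds_grows_their_classes(self, rng, human_cfg):
        avg = rng.uniform(0, 200, (40, 40))
        ret = rng.uniform(0, 1, (40, 40))
        base = classify_tissue(avg, ret, human_cfg)
        wider_bg = classify_tissue(avg, ret, FusionConfig.preset("human", bg_avg_max=60.0))
        wider_gm = classify_tissue(avg, ret, FusionConfig.preset("human", gm_ret_max=0.3))
        assert np.all((base == Tissue.BACKGROUND) <= (wider_bg == Tissue.BACKGROUND))
        assert np.all((base == Tissue.GRAY) <= (wider_gm == Tissue.GRAY))


class TestClassifyArchitecture:
    def run(self, ret, prom, avg, cfg):
        tissue = np.full((1, 1), Tissue.WHITE, dtype=np.uint8)
        return classify_architecture(tissue, np.array([[ret]]),
                                     np.array([[prom]]), np.array([[avg]]), cfg)[0, 0]

    def test_high_retardation_is_inplane(self, human_cfg):
        assert self.run(0.7, 0.0, 500, human_cfg) == Architecture.PARALLEL_INPLANE

    def test_mid_retardation_needs_prominence(self, human_cfg):
        assert self.run(0.4, 0.35, 500, human_cfg) == Architecture.PARALLEL_INCLINED
        assert self.run(0.4, 0.2, 500, human_cfg) == Architecture.CROSSING

    def test_low_retardation_needs_strong_scattering(self, human_cfg):
        assert self.run(0.1, 0.0, 1300, human_cfg) == Architecture.PARALLEL_STEEP
        assert self.run(0.1, 0.0, 1000, human_cfg) == Architecture.CROSSING

    def test_vervet_preset_thresholds(self):
        cfg = FusionConfig.preset("vervet")
        assert self.run(0.4, 0.9, 500, cfg) == Architecture.CROSSING
        assert self.run(0.1, 0.0, 500, cfg) == Architecture.PARALLEL_STEEP

    def test_architecture_none_outside_white_matter(self, human_cfg):
        tissue = np.array([[Tissue.GRAY, Tissue.BACKGROUND]], dtype=np.uint8)
        arch = classify_architecture(tissue, np.full((1, 2), 0.9),
                                     np.full((1, 2), 5.0), np.full((1, 2), 2000.0),
                                     human_cfg)
        assert np.all(arch == Architecture.NONE)


class TestOffset:
    def test_wraparound(self):
        assert apply_direction_offset(np.array([170.0]), 20.0)[0] == pytest.approx(10.0)

    def test_zero_and_full_period_are_identity(self, rng):
        d = rng.uniform(0, 180, 20)
        assert np.allclose(apply_direction_offset(d, 0.0), d)
        assert np.allclose(apply_direction_offset(d, 180.0), d)

    def test_nan_preserved(self):
        assert np.isnan(apply_direction_offset(np.array([np.nan]), 30.0))[0]


def fuse_single(tissue, arch, phi_pli, sli_dirs, cfg, avg=500.0):
    pli = make_pli([[phi_pli]], retardation=0.5)
    sli = make_sli(np.array([[sli_dirs]], dtype=float), average=avg)
    classes = TissueClassMap(
        tissue=np.array([[tissue]], dtype=np.uint8),
        architecture=np.array([[arch]], dtype=np.uint8))
    mm = build_multimodal_map(pli, sli, classes, cfg)
    return mm.directions_deg[0, 0], mm.source[0, 0]


class TestMultimodalRules:
    def test_crossing_pixel_takes_all_sli_directions(self, human_cfg):
        d, s = fuse_single(Tissue.WHITE, Architecture.CROSSING, 40.0,
                           [10.0, 100.0, np.nan], human_cfg)
        assert d[0] == 10.0 and d[1] == 100.0 and np.isnan(d[2])
        assert list(s) == [Source.SLI, Source.SLI, Source.NONE]

    def test_agreeing_parallel_pixel_takes_pli_first_channel(self, human_cfg):
        d, s = fuse_single(Tissue.WHITE, Architecture.PARALLEL_INPLANE, 42.0,
                           [45.0, np.nan, np.nan], human_cfg)
        assert d[0] == 42.0 and s[0] == Source.PLI
        assert np.isnan(d[1]) and s[1] == Source.NONE

    def test_disagreeing_parallel_pixel_falls_back_to_sli(self, human_cfg):
        d, s = fuse_single(Tissue.WHITE, Architecture.PARALLEL_INPLANE, 42.0,
                           [135.0, np.nan, np.nan], human_cfg)
        assert d[0] == 135.0 and s[0] == Source.SLI

    def test_gray_pixel_without_sli_takes_pli(self, human_cfg):
        d, s = fuse_single(Tissue.GRAY, Architecture.NONE, 80.0,
                           [np.nan, np.nan, np.nan], human_cfg)
        assert d[0] == 80.0 and s[0] == Source.PLI
        assert np.isnan(d[1:]).all()

    def test_gray_pixel_prefers_sli_first_channel(self, human_cfg):
        d, s = fuse_single(Tissue.GRAY, Architecture.NONE, 80.0,
                           [70.0, 160.0, np.nan], human_cfg)
        assert d[0] == 70.0 and s[0] == Source.SLI
        assert d[1] == 160.0 and s[1] == Source.SLI

    def test_steep_pixel_without_sli_stays_black(self, human_cfg):
        d, s = fuse_single(Tissue.WHITE, Architecture.PARALLEL_STEEP, 60.0,
                           [np.nan, np.nan, np.nan], human_cfg)
        assert np.isnan(d).all()
        assert np.all(s == Source.NONE)

    def test_background_stays_empty(self, human_cfg):
        d, s = fuse_single(Tissue.BACKGROUND, Architecture.NONE, np.nan,
                           [np.nan, np.nan, np.nan], human_cfg)
        assert np.isnan(d).all() and np.all(s == Source.NONE)

    def test_white_pixel_without_pli_uses_sli(self, human_cfg):
        d, s = fuse_single(Tissue.WHITE, Architecture.PARALLEL_INPLANE, np.nan,
                           [33.0, np.nan, np.nan], human_cfg)
        assert d[0] == 33.0 and s[0] == Source.SLI


class TestPhantomFusion:
    def test_partition_every_pixel_gets_one_tissue_label(self, pli_maps64,
                                                         sli_maps64, human_cfg):
        classes = classify(pli_maps64, sli_maps64, human_cfg)
        assert set(np.unique(classes.tissue)) <= {int(t) for t in Tissue}
        white = classes.tissue == Tissue.WHITE
        assert np.all((classes.architecture != Architecture.NONE) == white)

    def test_noiseless_phantom_classified_100_percent(self, phantom64, pli_maps64,
                                                      sli_maps64, human_cfg):
        classes = classify(pli_maps64, sli_maps64, human_cfg)
        assert np.array_equal(classes.tissue, phantom64.tissue_truth)
        assert np.array_equal(classes.architecture, phantom64.architecture_truth)

    def test_provenance_every_direction_comes_verbatim_from_inputs(
            self, pli_maps64, sli_maps64, human_cfg):
        classes = classify(pli_maps64, sli_maps64, human_cfg)
        mm = build_multimodal_map(pli_maps64, sli_maps64, classes, human_cfg)
        assert np.all((mm.source == Source.NONE) == np.isnan(mm.directions_deg))
        pli_src = mm.source == Source.PLI
        sli_src = mm.source == Source.SLI
        phi = np.broadcast_to(pli_maps64.direction_deg[..., None], mm.source.shape)
        assert np.array_equal(mm.directions_deg[pli_src], phi[pli_src])
        for i, j, c in np.argwhere(sli_src):
            assert mm.directions_deg[i, j, c] in sli_maps64.directions_deg[i, j]

    def test_crossing_output_ignores_pli_perturbation(self, phantom64, pli_maps64,
                                                      sli_maps64, human_cfg):
        classes = classify(pli_maps64, sli_maps64, human_cfg)
        mm = build_multimodal_map(pli_maps64, sli_maps64, classes, human_cfg)
        perturbed = PLIMaps(pli_maps64.transmittance, pli_maps64.retardation,
                            (pli_maps64.direction_deg + 41.0) % 180.0,
                            pli_maps64.valid)
        mm2 = build_multimodal_map(perturbed, sli_maps64, classes, human_cfg)
        crossing = classes.architecture == Architecture.CROSSING
        assert np.array_equal(mm.directions_deg[crossing],
                              mm2.directions_deg[crossing], equal_nan=True)

    def test_steep_band_renders_black_despite_valid_pli(self, phantom64, pli_maps64,
                                                        sli_maps64, human_cfg):
        # the "black cingulum": steep fibers have a valid PLI direction but no
        # reliable ComSLI peaks, so the fused map stays empty there
        classes = classify(pli_maps64, sli_maps64, human_cfg)
        mm = build_multimodal_map(pli_maps64, sli_maps64, classes, human_cfg)
        steep = phantom64.architecture_truth == Architecture.PARALLEL_STEEP
        assert np.all(~np.isnan(pli_maps64.direction_deg[steep]))
        assert np.isnan(mm.directions_deg[steep]).all()


class TestConfig:
    def test_preset_values(self):
        human, vervet = FusionConfig.preset("human"), FusionConfig.preset("vervet")
        assert (human.prominence_min, human.steep_avg_min) == (0.3, 1200.0)
        assert (vervet.prominence_min, vervet.steep_avg_min) == (1.0, 430.0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            FusionConfig.preset("macaque")

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            FusionConfig(steep_ret_max=0.8, inplane_ret_min=0.5)
        with pytest.raises(ValueError):
            FusionConfig(agree_tol_deg=120.0)

    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("preset: vervet\nagree_tol_deg: 30\n")
        cfg = FusionConfig.from_yaml(p)
        assert cfg.prominence_min == 1.0 and cfg.agree_tol_deg == 30.0
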