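"""Background ROI, ratio thresholding, components, exclusions, full pipeline."""

import numpy as np
import pytest

from fetquant import (BackgroundROI, background_mean, build_domain, delineate,
                      dsc, generate_static, label_components,
                      threshold_delineate, default_background_roi)
from fetquant.delineation import apply_exclusions, min_volume_filter
from fetquant.masking import DomainMask
from fetquant.phantom import ConfounderSpec, LesionSpec

from conftest import (flood_fill_components, loop_threshold, make_mask,
                      make_volume, small_spec)


def _full_domain(shape=(8, 8, 8)):
    return DomainMask(make_mask(np.ones(shape, bool)))


class TestBackgroundROI:
    def test_uniform_image_mean(self):
        img = make_volume(np.ones((8, 8, 8)))
        roi = BackgroundROI.from_mask(make_mask(np.ones((8, 8, 8), bool)))
        assert background_mean(img, roi) == 1.0

    def test_two_level_mean(self):
        data = np.ones((8, 8, 8))
        data[:4] = 3.0
        img = make_volume(data)
        roi = BackgroundROI.from_mask(make_mask(np.ones((8, 8, 8), bool)))
        assert background_mean(img, roi) == 2.0

    def test_sphere_rasterization_matches_distance_oracle(self):
        img = make_volume(np.ones((16, 16, 16)))
        center, radius = (14.0, 16.0, 15.0), 10.0
        roi = BackgroundROI.sphere(center, radius)
        sel = roi.rasterize(img)
        count = 0  # voxel centres within radius, exhaustively
        for i in range(16):
            for j in range(16):
                for k in range(16):
                    d2 = (2 * i - center[0]) ** 2 + (2 * j - center[1]) ** 2 \
                        + (2 * k - center[2]) ** 2
                    count += d2 <= radius ** 2
        assert int(sel.sum()) == count

    def test_small_roi_rejected_by_floor(self):
        img = make_volume(np.ones((8, 8, 8)))
        roi = BackgroundROI.sphere((8, 8, 8), 2.5)  # a handful of voxels
        with pytest.raises(ValueError, match="floor"):
            background_mean(img, roi)

    def test_nonpositive_mean_rejected(self):
        img = make_volume(np.zeros((8, 8, 8)))
        roi = BackgroundROI.from_mask(make_mask(np.ones((8, 8, 8), bool)))
        with pytest.raises(ValueError, match="positive"):
            background_mean(img, roi)


class TestThreshold:
    def test_uniform_background_below_cut_is_empty(self):
        img = make_volume(np.ones((8, 8, 8)))
        out = threshold_delineate(img, 1.0, ratio=1.6, domain=_full_domain())
        assert out.is_empty()

    def test_noiseless_cube_recovered_exactly(self):
        data = np.ones((10, 10, 10))
        data[3:6, 3:6, 3:6] = 2.0
        out = threshold_delineate(make_volume(data), 1.0, 1.6,
                                  _full_domain((10, 10, 10)))
        expected = data >= 1.6
        assert np.array_equal(out.data, expected)

    def test_at_threshold_inclusive_vs_strict(self):
        data = np.full((8, 8, 8), 1.6)
        img = make_volume(data)
        dom = _full_domain()
        assert threshold_delineate(img, 1.0, 1.6, dom).n_voxels == 8 ** 3
        assert threshold_delineate(img, 1.0, 1.6, dom, strict=True).is_empty()

    def test_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 8, 8)) + 0.5
        dom = _full_domain()
        a = threshold_delineate(make_volume(data), 1.0, 1.6, dom)
        b = threshold_delineate(make_volume(data * 7.3), 7.3, 1.6, dom)
        assert np.array_equal(a.data, b.data)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.random((12, 12, 12)) * 3
        dom_data = rng.random((12, 12, 12)) < 0.7
        out = threshold_delineate(make_volume(data), 1.0, 1.6,
                                  DomainMask(make_mask(dom_data)))
        assert np.array_equal(out.data, loop_threshold(data, 1.6, dom_data))


class TestComponents:
    def test_single_cube_one_component(self):
        data = np.zeros((8, 8, 8), bool)
        data[2:4, 2:4, 2:4] = True
        comps = label_components(make_mask(data))
        assert len(comps) == 1 and comps[0].n_voxels == 8

    def test_corner_touching_cubes_merge_under_26_connectivity(self):
        data = np.zeros((8, 8, 8), bool)
        data[2:4, 2:4, 2:4] = True
        data[4:6, 4:6, 4:6] = True  # touches only at the (4,4,4) corner
        assert len(label_components(make_mask(data))) == 1

    def test_random_masks_match_flood_fill_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            data = rng.random((10, 10, 10)) < 0.15
            comps = label_components(make_mask(data))
            oracle = flood_fill_components(data)
            assert len(comps) == len(oracle)
            got = {frozenset(zip(*np.nonzero(c.data))) for c in comps}
            want = {frozenset(c) for c in oracle}
            assert got == want

    def test_sorted_by_descending_volume(self):
        data = np.zeros((12, 12, 12), bool)
        data[0:2, 0:2, 0:2] = True      # 8 voxels
        data[8:12, 8:12, 8:12] = True   # 64 voxels
        comps = label_components(make_mask(data))
        assert [c.n_voxels for c in comps] == [64, 8]

    def test_empty_mask_no_components(self):
        assert label_components(make_mask(np.zeros((4, 4, 4), bool))) == []


class TestExclusionsAndFilter:
    def test_empty_exclusion_list_identity(self):
        m = make_mask(np.ones((4, 4, 4), bool))
        out, removed = apply_exclusions(m, [])
        assert np.array_equal(out.data, m.data) and removed == 0.0

    def test_total_exclusion_empties_mask(self):
        m = make_mask(np.ones((4, 4, 4), bool))
        out, removed = apply_exclusions(m, [m])
        assert out.is_empty()
        assert removed == pytest.approx(m.volume_ml)

    def test_min_volume_strict_boundary(self):
        small = np.zeros((10, 10, 10), bool)
        small.ravel()[:5] = True        # 5 voxels x 8 mm3 = 0.04 ml
        big = np.zeros((10, 10, 10), bool)
        big[5:, 5:, 5:] = True          # 1.0 ml
        comps = [make_mask(big), make_mask(small)]
        kept, removed = min_volume_filter(comps, min_ml=0.1)
        assert len(kept) == 1 and kept[0].n_voxels == 125
        assert removed == pytest.approx(0.04)
        # exactly at the limit -> removed (strict >)
        kept_at, _ = min_volume_filter(comps, min_ml=1.0)
        assert kept_at == []
        kept_all, _ = min_volume_filter(comps, min_ml=0.0)
        assert len(kept_all) == 2


class TestFullDelineation:
    def test_noiseless_phantom_recovered_exactly(self, clean_spec):
        ph = generate_static(clean_spec)
        res = delineate(ph.image, default_background_roi(clean_spec),
                        build_domain([ph.brain_mask], 4))
        assert dsc(res.btv_mask, ph.lesion_union) == 1.0
        assert res.background_mean == pytest.approx(1.0)

    def test_subthreshold_lesion_yields_empty_btv(self):
        spec = small_spec(lesions=(LesionSpec(center_mm=(20.0, 10.0, 5.0),
                                              semi_axes_mm=(8.0, 8.0, 8.0),
                                              tbr_true=1.5),))
        ph = generate_static(spec)
        res = delineate(ph.image, default_background_roi(spec),
                        build_domain([ph.brain_mask], 4))
        assert res.btv_mask.is_empty() and res.n_components == 0

    def test_two_lesions_one_filtered_by_volume(self):
        spec = small_spec(lesions=(
            LesionSpec(center_mm=(20.0, 10.0, 5.0), semi_axes_mm=(8.0, 8.0, 8.0)),
            LesionSpec(center_mm=(-20.0, -15.0, 0.0),
                       semi_axes_mm=(2.0, 2.0, 2.0)),  # ~0.03 ml < 0.1
        ))
        ph = generate_static(spec)
        roi = BackgroundROI.sphere((-24.0, 25.0, 0.0), 10.0)
        res = delineate(ph.image, roi, build_domain([ph.brain_mask], 4))
        assert res.n_components == 1
        assert res.filtered_volume_ml > 0

    def test_confounder_removed_by_exclusion_mask(self):
        spec = small_spec(confounders=(ConfounderSpec("pituitary", 2.5),))
        ph = generate_static(spec)
        dom = build_domain([ph.brain_mask], 4)
        roi = default_background_roi(spec)
        with_conf = delineate(ph.image, roi, dom)
        assert with_conf.n_components == 2
        cleaned = delineate(ph.image, roi, dom,
                            exclusions=[ph.confounder_mask])
        assert cleaned.n_components == 1
        assert dsc(cleaned.btv_mask, ph.lesion_union) == 1.0
        assert cleaned.excluded_volume_ml > 0

    def test_btv_monotone_in_threshold_ratio(self, clean_spec):
        ph = generate_static(small_spec(noise_sigma=0.05, psf_fwhm_mm=5.0))
        roi = default_background_roi(clean_spec)
        dom = build_domain([ph.brain_mask], 4)
        bg = background_mean(ph.image, roi)
        volumes = [threshold_delineate(ph.image, bg, r, dom).volume_ml
                   for r in np.arange(1.2, 2.51, 0.1)]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))

    def test_global_rescaling_leaves_delineation_unchanged(self, clean_spec):
        ph = generate_static(clean_spec)
        roi = default_background_roi(clean_spec)
        dom = build_domain([ph.brain_mask], 4)
        a = delineate(ph.image, roi, dom)
        scaled = type(ph.image)(ph.image.data * 11.0, ph.image.affine)
        b = delineate(scaled, roi, dom)
        assert np.array_equal(a.btv_mask.data, b.btv_mask.data)
        assert b.background_mean == pytest.approx(11.0 * a.background_mean)

    def test_every_output_voxel_satisfies_threshold(self):
        ph = generate_static(small_spec(noise_sigma=0.05, psf_fwhm_mm=5.0, seed=9))
        spec = ph.spec
        roi = default_background_roi(spec)
        res = delineate(ph.image, roi, build_domain([ph.brain_mask], 4))
        cut = res.threshold_ratio * res.background_mean
        assert np.all(ph.image.data[res.btv_mask.data] >= cut)
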