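"""Measurement chain: ABD closed forms, feret oracles, segmentation and
the antenna-robustness property of the ABD biovolume."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from copemorph.morphometrics import (
    Morphometrics,
    ParticleImage,
    ParticleMask,
    abd_diameter,
    abd_volume,
    feret_dimensions,
    manual_biovolume,
    measure,
    segment,
)
from copemorph.shapes import ShapeSpec, generate_particle


from conftest import exhaustive_feret  # noqa: E402  independent feret oracle


class TestAbdClosedForms:
    @pytest.mark.parametrize(
        "area,expected",
        [
            (math.pi, 2.0),  # unit circle
            (100.0, 11.283791670955126),  # 2 sqrt(100/pi)
            (math.pi * 400.0 * 100.0 / 4.0, 200.0),  # L=400 W=100 ellipse: sqrt(LW)
        ],
    )
    def test_abd_diameter_values(self, area, expected):
        assert abd_diameter(area) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "d,expected",
        [(1.0, math.pi / 6.0), (200.0, math.pi / 6.0 * 200.0**3)],
    )
    def test_abd_volume_values(self, d, expected):
        assert abd_volume(d) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty particle"):
            abd_diameter(0.0)
        with pytest.raises(ValueError):
            abd_volume(-1.0)

    @given(st.floats(min_value=1e-3, max_value=1e9))
    def test_volume_diameter_roundtrip(self, area):
        d = abd_diameter(area)
        # V = (pi/6) d^3 with d = 2 sqrt(A/pi) collapses to A^{3/2} * 4/(3 sqrt(pi))
        assert abd_volume(d) == pytest.approx(
            area**1.5 * 4.0 / (3.0 * math.sqrt(math.pi)), rel=1e-12
        )

    @given(
        st.floats(min_value=1.0, max_value=1e7),
        st.floats(min_value=1e-3, max_value=1.0),
    )
    def test_added_area_scales_v_abd_exactly(self, area, eps):
        """Appendage pixels of relative area eps scale the ABD by sqrt(1+eps)
        and V_ABD by (1+eps)^1.5, exactly."""
        d0, d1 = abd_diameter(area), abd_diameter(area * (1 + eps))
        assert d1 / d0 == pytest.approx(math.sqrt(1 + eps), rel=1e-12)
        assert abd_volume(d1) / abd_volume(d0) == pytest.approx(
            (1 + eps) ** 1.5, rel=1e-12
        )

    def test_doubling_area_multiplies_volume_by_2_pow_1p5(self):
        v1 = abd_volume(abd_diameter(1234.5))
        v2 = abd_volume(abd_diameter(2469.0))
        assert v2 / v1 == pytest.approx(2.0**1.5, rel=1e-12)


class TestManualBiovolume:
    def test_unit_case(self):
        assert manual_biovolume(1.0, 1.0) == 1.0

    def test_prosome_target_dimensions(self):
        # 400.1 x 102.9^2: the uncontaminated prosome reading
        assert manual_biovolume(400.1, 102.9) == pytest.approx(4.2365e6, rel=1e-4)

    def test_antenna_contaminated_dimensions(self):
        # 690.6 x 477.8^2: the same animal as read with extended antennae;
        # a ~37-fold inflation of the L x W^2 biovolume
        v = manual_biovolume(690.6, 477.8)
        assert v == pytest.approx(1.5765e8, rel=1e-4)
        assert v / manual_biovolume(400.1, 102.9) > 35

    def test_width_above_length_warns(self):
        with pytest.warns(UserWarning, match="width exceeds length"):
            manual_biovolume(100.0, 200.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            manual_biovolume(0.0, 10.0)


class TestSegment:
    def test_blank_image_yields_no_particles(self):
        img = ParticleImage(np.full((64, 64), 220, dtype=np.uint8), 1.0)
        assert segment(img) == []

    def test_single_ellipse_segmented_with_correct_area(self, plain_spec):
        img, _ = generate_particle(plain_spec)
        masks = segment(img, min_esd_um=None, max_esd_um=None)
        assert len(masks) == 1
        assert masks[0].area_um2 == pytest.approx(math.pi * 400 * 100 / 4, rel=0.02)

    def test_two_separated_particles(self):
        grid = np.full((60, 120), 220, dtype=np.uint8)
        grid[20:40, 10:40] = 40
        grid[20:40, 60:100] = 40
        masks = segment(ParticleImage(grid, 1.0), min_esd_um=None, max_esd_um=None)
        assert len(masks) == 2

    def test_size_gate_drops_out_of_window_particles(self):
        grid = np.full((80, 80), 220, dtype=np.uint8)
        grid[38:42, 38:42] = 40  # 4x4 px -> ESD ~4.5 um, below a 30 um gate
        assert segment(ParticleImage(grid, 1.0), min_esd_um=30.0, max_esd_um=300.0) == []
        assert len(segment(ParticleImage(grid, 1.0), min_esd_um=None, max_esd_um=None)) == 1

    def test_border_touching_particle_flagged(self):
        grid = np.full((60, 60), 220, dtype=np.uint8)
        grid[0:20, 10:40] = 40
        masks = segment(ParticleImage(grid, 1.0), min_esd_um=None, max_esd_um=None)
        assert len(masks) == 1 and masks[0].touches_border

    def test_otsu_threshold_option(self, plain_spec):
        img, _ = generate_particle(plain_spec)
        masks = segment(img, threshold_method="otsu", min_esd_um=None, max_esd_um=None)
        assert len(masks) == 1


class TestFeret:
    def test_disk_is_isotropic(self, disk_mask_factory):
        mask = disk_mask_factory(120.0)
        fmax, fmin = feret_dimensions(mask)
        assert fmax == pytest.approx(120.0, abs=2.0)
        assert fmin == pytest.approx(120.0, abs=2.0)

    def test_rectangle_extents(self):
        mask = ParticleMask(np.ones((100, 300), dtype=bool), 1.0)
        fmax, fmin = feret_dimensions(mask)
        assert fmax == pytest.approx(math.hypot(300, 100), abs=2.0)
        assert fmin == pytest.approx(100.0, abs=2.0)

    def test_rotation_invariance(self):
        from copemorph.shapes import render_mask

        specs = [
            ShapeSpec("calanoid_copepodite", 300.0, 100.0, orientation=o)
            for o in (0.0, 37.0)
        ]
        f0, f1 = (feret_dimensions(ParticleMask(render_mask(s), 1.0)) for s in specs)
        assert f1[0] == pytest.approx(f0[0], rel=0.03)
        assert f1[1] == pytest.approx(f0[1], rel=0.03)

    def test_matches_exhaustive_oracle_on_random_masks(self, random_blob_factory):
        for seed in range(40):
            mask = random_blob_factory(seed)
            fmax, fmin = feret_dimensions(mask)
            emax, emin = exhaustive_feret(mask)
            assert abs(fmax - emax) <= 1.0
            assert abs(fmin - emin) <= 1.0

    def test_rejects_too_few_angles(self, disk_mask_factory):
        with pytest.raises(ValueError):
            feret_dimensions(disk_mask_factory(50.0), n_angles=10)

    def test_single_pixel_minimum_extent(self):
        fmax, fmin = feret_dimensions(ParticleMask(np.ones((1, 1), bool), 2.5))
        assert fmin == pytest.approx(2.5, rel=1e-9)
        assert fmax == pytest.approx(2.5 * math.sqrt(2), rel=1e-6)


class TestMeasure:
    def test_disk_v_abd_matches_sphere(self, disk_mask_factory):
        rec = measure(disk_mask_factory(100.0))
        assert rec.v_abd_um3 == pytest.approx(math.pi / 6 * 100.0**3, rel=0.03)

    def test_antenna_fixture_feret_contaminated_v_abd_robust(self, antenna_spec):
        img, truth = generate_particle(antenna_spec)
        rec = measure(segment(img, min_esd_um=None, max_esd_um=None)[0])
        bare = ShapeSpec("calanoid_copepodite", 400.0, 100.0, pixel_size=1.0)
        img0, _ = generate_particle(bare)
        rec0 = measure(segment(img0, min_esd_um=None, max_esd_um=None)[0])
        assert rec.feret_max_um > truth.true_length
        assert rec.length_um == rec.feret_max_um  # instrument-style length
        assert abs(rec.v_abd_um3 / rec0.v_abd_um3 - 1) < 0.15

    def test_measure_is_pure(self, disk_mask_factory):
        mask = disk_mask_factory(80.0)
        assert measure(mask) == measure(mask)

    def test_isoperimetric_sanity_bounds(self, disk_mask_factory, random_blob_factory):
        """feret_max >= abd_diameter >= area / feret_max for any silhouette."""
        masks = [disk_mask_factory(60.0)] + [random_blob_factory(s) for s in range(10)]
        for mask in masks:
            rec = measure(mask)
            assert rec.feret_max_um >= rec.abd_diameter_um * (1 - 1e-9)
            assert rec.abd_diameter_um >= rec.area_um2 / rec.feret_max_um

    def test_record_units_consistent(self, disk_mask_factory):
        rec = measure(disk_mask_factory(50.0, pixel_size=0.5))
        assert rec.area_um2 == pytest.approx(rec.area_px * 0.25)
        assert rec.v_lw_um3 == pytest.approx(rec.length_um * rec.width_um**2)


class TestParticleImageValidation:
    def test_too_small_frame_rejected(self):
        with pytest.raises(ValueError):
            ParticleImage(np.zeros((2, 2)), 1.0)

    def test_nonpositive_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            ParticleImage(np.zeros((10, 10)), 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ParticleMask(np.zeros((5, 5), dtype=bool), 1.0)
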