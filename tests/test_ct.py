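import numpy as np
import pandas as pd
import pytest

from rumigen.ct import (
    SegmentationConfig,
    area_weighted_hu,
    assemble_composition,
    process_raster_stack,
    segment_slice,
    tissue_volume,
    volume_to_mass,
)


@pytest.fixture()
def seg_config():
    return SegmentationConfig()


class TestSegmentSlice:
    def test_uniform_fat_raster(self, seg_config):
        raster = np.full((10, 10), 80.0)
        seg = segment_slice(raster, seg_config, pixel_area_mm2=4.0)
        assert seg["fat"]["pixels"] == 100
        assert seg["fat"]["area_mm2"] == pytest.approx(400.0)
        assert seg["lean"]["pixels"] == seg["bone"]["pixels"] == 0

    @pytest.mark.parametrize(
        "value,tissue",
        [(40, "fat"), (115, "fat"), (116, "lean"), (200, "lean"), (201, "bone"), (255, "bone")],
    )
    def test_band_edges_inclusive(self, seg_config, value, tissue):
        seg = segment_slice(np.array([[float(value)]]), seg_config, 1.0)
        assert seg[tissue]["pixels"] == 1

    def test_known_counts_on_constructed_raster(self, seg_config):
        raster = np.array(
            [[50, 50, 120, 120], [50, 210, 210, 0], [120, 120, 0, 0], [210, 50, 120, 0]],
            dtype=float,
        )
        seg = segment_slice(raster, seg_config, 2.0)
        assert seg["fat"]["pixels"] == 4
        assert seg["lean"]["pixels"] == 5
        assert seg["bone"]["pixels"] == 3
        assert seg["background"]["pixels"] == 4

    def test_partition_is_exact(self, seg_config, rng):
        raster = rng.uniform(-50, 300, size=(32, 32))
        seg = segment_slice(raster, seg_config, 1.0)
        total = sum(seg[t]["pixels"] for t in ("fat", "lean", "bone", "background"))
        assert total == raster.size

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            SegmentationConfig(hu_fat=(40, 120), hu_lean=(116, 200))


class TestVolumeAndMass:
    def test_single_slice(self):
        assert tissue_volume([10_000.0], 30.0) == pytest.approx(300.0)

    def test_zero_areas(self):
        assert tissue_volume([0.0, 0.0], 30.0) == 0.0

    def test_ramp_hand_sum(self):
        # 10, 20, 30 cm^2 at 3 cm spacing: (10+20+30)*3 = 180 cm^3
        assert tissue_volume([1000.0, 2000.0, 3000.0], 30.0) == pytest.approx(180.0)

    def test_mass_at_unit_density(self):
        cfg = SegmentationConfig(density_coeffs=(1.0, 0.0))
        assert volume_to_mass(1000.0, 100.0, cfg) == pytest.approx(1.0)

    def test_mass_linear_in_volume(self, seg_config):
        m1 = volume_to_mass(500.0, 90.0, seg_config)
        m2 = volume_to_mass(1000.0, 90.0, seg_config)
        assert m2 == pytest.approx(2 * m1)

    def test_nonpositive_density_rejected(self):
        cfg = SegmentationConfig(density_coeffs=(0.0, 0.0))
        with pytest.raises(ValueError):
            volume_to_mass(100.0, 50.0, cfg)

    def test_area_weighted_hu(self):
        assert area_weighted_hu([100.0, 300.0], [60.0, 100.0]) == pytest.approx(90.0)


class TestAssembleComposition:
    def test_reference_scale_identities(self):
        rec = assemble_composition(
            {
                "subcutaneous_fat": 5.51,
                "intermuscular_fat": 2.29,
                "visceral_fat": 5.13,
                "carcass_lean": 19.10,
                "total_bone": 4.36,
                "nonfat_visceral": 10.76,
            }
        )
        assert rec.carcass_fat == pytest.approx(7.80)
        assert rec.total_fat == pytest.approx(12.93)
        assert rec.carcass_weight == pytest.approx(31.26)
        assert rec.ct_weight == pytest.approx(31.26 + 5.13 + 10.76)
        assert 0 < rec.dressing_out_pct < 100

    def test_lean_only_animal(self):
        rec = assemble_composition(
            {
                "subcutaneous_fat": 0.0,
                "intermuscular_fat": 0.0,
                "visceral_fat": 0.0,
                "carcass_lean": 10.0,
                "total_bone": 0.0,
                "nonfat_visceral": 0.0,
            }
        )
        assert rec.carcass_weight == pytest.approx(10.0)
        assert rec.fat_lean_ratio == 0.0

    def test_missing_depot_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_composition({"carcass_lean": 10.0})


class TestRasterStack:
    def test_round_trip_with_masks(self, seg_config, rng):
        # one carcass slice with subcutaneous/intermuscular fat split and
        # one visceral slice with rumen contents to exclude
        size = 16
        pixel_area = 25.0
        carc = np.zeros((size, size))
        sub_mask = np.zeros((size, size), dtype=bool)
        carc[0, :8] = 80.0
        sub_mask[0, :8] = True       # 8 subcutaneous fat pixels
        carc[1, :4] = 80.0           # 4 intermuscular fat pixels
        carc[2, :10] = 150.0         # 10 lean
        carc[3, :5] = 220.0          # 5 bone
        visc = np.zeros((size, size))
        rumen = np.zeros((size, size), dtype=bool)
        visc[0, :6] = 80.0           # visceral fat
        visc[1, :7] = 150.0          # organs (non-fat visceral)
        visc[2, :9] = 150.0
        rumen[2, :9] = True          # excluded rumen contents
        masses, rec = process_raster_stack(
            [
                {"raster": carc, "compartment": "carcass", "pixel_area_mm2": pixel_area,
                 "subcutaneous_mask": sub_mask},
                {"raster": visc, "compartment": "viscera", "pixel_area_mm2": pixel_area,
                 "rumen_mask": rumen},
            ],
            seg_config,
            spacing_mm=30.0,
        )
        dens80 = seg_config.density(80.0)
        expect_sub = 8 * pixel_area * 30.0 / 1000.0 * dens80 / 1000.0
        assert masses["subcutaneous_fat"] == pytest.approx(expect_sub)
        assert masses["intermuscular_fat"] == pytest.approx(expect_sub / 2.0)
        # rumen-content pixels contribute nothing
        dens150 = seg_config.density(150.0)
        expect_organs = 7 * pixel_area * 30.0 / 1000.0 * dens150 / 1000.0
        assert masses["nonfat_visceral"] == pytest.approx(expect_organs)
        assert rec.carcass_weight > 0
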