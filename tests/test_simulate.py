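import numpy as np
import pandas as pd
import pytest

from rumigen.ct import SegmentationConfig, process_stack
from rumigen.gas import process_pac_table
from rumigen.intake import daily_intake, interpolate_growth
from rumigen.pedigree import build_A, read_pedigree, pedigree_to_frame
from rumigen.simulate import (
    CTSpec,
    FeederSpec,
    PACSpec,
    SimulationConfig,
    default_trait_table,
    simulate_breeding_values,
    simulate_cohort,
    simulate_pedigree,
)


@pytest.fixture(scope="module")
def small_cohort():
    return simulate_cohort(SimulationConfig(seed=12, n_sires=10))


@pytest.fixture(scope="module")
def noiseless_cohort():
    cfg = SimulationConfig(
        seed=13,
        n_sires=6,
        weighing_noise_sd=0.0,
        ultrasound_noise_sd=0.0,
        pac=PACSpec(lot_sd=0.0, conc_noise_frac=0.0),
        feeder=FeederSpec(day_cv=0.0, duration_noise_frac=0.0),
    )
    return simulate_cohort(cfg)


class TestPedigreeGeneration:
    def test_progeny_count_arithmetic(self, rng):
        cfg = SimulationConfig(n_sires=100, dams_per_sire=5, progeny_per_dam=2)
        records, meta = simulate_pedigree(cfg, np.random.default_rng(0))
        assert len(meta) == 1000  # 100 sires x 10 progeny

    def test_link_sires_span_cohorts(self):
        cfg = SimulationConfig(n_sires=50, sire_link_frac=0.2)
        _, meta = simulate_pedigree(cfg, np.random.default_rng(1))
        cohorts_per_sire = meta.groupby("sire")["cohort"].nunique()
        assert (cohorts_per_sire >= 2).mean() >= 0.2

    def test_every_phenotyped_animal_has_a_dam(self):
        cfg = SimulationConfig(n_sires=20)
        records, meta = simulate_pedigree(cfg, np.random.default_rng(2))
        by_id = {r.animal_id: r for r in records}
        assert all(by_id[a].dam_id is not None for a in meta["animal"])

    def test_same_seed_reproduces_output(self):
        cfg = SimulationConfig(seed=99, n_sires=8)
        a = simulate_cohort(cfg)
        b = simulate_cohort(cfg)
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.feeder_events, b.feeder_events)
        pd.testing.assert_frame_equal(a.pac, b.pac)

    def test_generated_pedigree_round_trips_through_reader(self, small_cohort):
        frame = pedigree_to_frame(small_cohort.pedigree)
        reread = read_pedigree(frame)
        assert {r.animal_id for r in reread} == {r.animal_id for r in small_cohort.pedigree}


class TestBreedingValues:
    def test_zero_covariance_gives_zero_values(self, trio_pedigree, rng):
        bv, _ = simulate_breeding_values(trio_pedigree, np.zeros((2, 2)), rng=rng)
        np.testing.assert_allclose(bv, 0.0)

    def test_non_psd_covariance_rejected(self, trio_pedigree, rng):
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_breeding_values(trio_pedigree, [[1.0, 2.0], [2.0, 1.0]], rng=rng)

    def test_founder_variance_matches_target(self):
        ped = read_pedigree(
            pd.DataFrame({"animal": [f"f{i}" for i in range(5000)], "sire": "0", "dam": "0"})
        )
        bv, _ = simulate_breeding_values(ped, [[1.0]], rng=np.random.default_rng(4))
        assert np.var(bv) == pytest.approx(1.0, abs=0.1)

    def test_parent_offspring_covariance(self):
        # 2000 sire-offspring pairs: Cov(a_s, a_o) = 0.5 sigma2_a
        rows = [{"animal": f"s{i}", "sire": "0", "dam": "0"} for i in range(2000)]
        rows += [{"animal": f"o{i}", "sire": f"s{i}", "dam": "0"} for i in range(2000)]
        ped = read_pedigree(pd.DataFrame(rows))
        bv, _ = simulate_breeding_values(ped, [[1.0]], rng=np.random.default_rng(5))
        pos = {r.animal_id: i for i, r in enumerate(ped)}
        s = np.array([bv[pos[f"s{i}"], 0] for i in range(2000)])
        o = np.array([bv[pos[f"o{i}"], 0] for i in range(2000)])
        assert np.cov(s, o)[0, 1] == pytest.approx(0.5, abs=0.06)

    def test_realised_genetic_covariance_structure(self, half_sib_design):
        # paternal half sibs: Cov = 0.25 G between sibs
        ped, A, pos = half_sib_design
        G = np.array([[1.0, 0.5], [0.5, 1.0]])
        bv, _ = simulate_breeding_values(ped, G, rng=np.random.default_rng(6))
        prog = [i for i, r in enumerate(ped) if r.sire_id is not None]
        emp = np.cov(bv[prog].T)
        np.testing.assert_allclose(emp, G, atol=0.12)


class TestTruthBookkeeping:
    def test_phenotype_is_exact_sum_of_components(self, small_cohort):
        truth = small_cohort.truth
        for t in ("mmwt", "rfi", "visceral_fat"):
            recon = (
                truth[f"{t}_mu"] + truth[f"{t}_fixed"] + truth[f"{t}_bv"]
                + truth[f"{t}_mat"] + truth[f"{t}_pe"] + truth[f"{t}_resid"]
            )
            np.testing.assert_allclose(recon, truth[t], atol=1e-12)

    def test_trait_table_defaults_are_reference_seeded(self):
        tt = default_trait_table()
        assert tt.loc["ch4", "mean"] == pytest.approx(17.2)
        assert tt.loc["mmwt", "h2"] == pytest.approx(0.44)


class TestStreamRoundTrips:
    def test_feeder_daily_sums_equal_latent_intake(self, noiseless_cohort):
        coh = noiseless_cohort
        di = daily_intake(coh.feeder_events)
        assert di.to_numpy().sum() == pytest.approx(coh.feeder_events["grams"].sum())
        # with zero day-to-day noise every day equals the latent daily grams
        truth = coh.truth.set_index("animal")
        from rumigen.simulate import FEED_BY_YEAR

        for animal in di.index[:5]:
            dm, me = FEED_BY_YEAR[truth.loc[animal, "birth_year"]]
            latent = truth.loc[animal, "energy_intake"] / (dm * me) * 1000.0
            np.testing.assert_allclose(di.loc[animal], latent, rtol=1e-9)

    def test_noiseless_weights_interpolate_exactly(self, noiseless_cohort):
        coh = noiseless_cohort
        truth = coh.truth.set_index("animal")
        lw = coh.liveweights
        for animal, grp in list(lw.groupby("animal"))[:5]:
            g = interpolate_growth(grp[["day", "kg"]])
            w21_latent = truth.loc[animal, "mmwt"] ** (4.0 / 3.0)
            assert g.day21_weight == pytest.approx(w21_latent, rel=1e-9)
            assert g.adg == pytest.approx(truth.loc[animal, "adg"], rel=1e-6)

    def test_pac_round_trip_recovers_latent_emission(self, noiseless_cohort):
        # zero lot nuisance and zero reading noise: derived g/day within 2%
        coh = noiseless_cohort
        gt = process_pac_table(coh.pac, body_weight=coh.pac_body_weight)
        truth = coh.truth.set_index("animal")
        for rnd, col in ((1, "ch4"), (2, "ch4_r2")):
            sub = gt[gt["round"] == rnd].set_index("animal")
            rel = sub["ch4_g_day"] / truth.loc[sub.index, col]
            assert np.abs(rel - 1.0).max() < 0.02

    def test_zero_emission_gives_flat_profile(self):
        cfg = SimulationConfig(seed=3, n_sires=4, pac=PACSpec(lot_sd=0.0, conc_noise_frac=0.0))
        coh = simulate_cohort(cfg)
        pac = coh.pac
        animal = coh.animals["animal"].iloc[0]
        sub = pac[(pac["animal"] == animal) & (pac["gas"] == "ch4") & (pac["round"] == 1)]
        truth = coh.truth.set_index("animal")
        slope = np.polyfit(sub["minutes"], sub["concentration_ppm"], 1)[0]
        # slope scales with the latent emission; tiny emission -> near-flat
        assert slope > 0  # sanity on the forward model

    def test_ct_stack_recovers_depot_masses(self, small_cohort):
        coh = small_cohort
        seg = SegmentationConfig()
        truth = coh.truth.set_index("animal")
        for animal in coh.animals["animal"].iloc[:5]:
            grp = coh.ct_stacks[coh.ct_stacks["animal"] == animal]
            masses, _ = process_stack(grp, seg, spacing_mm=30.0)
            for depot in ("visceral_fat", "carcass_lean", "total_bone"):
                assert masses[depot] == pytest.approx(
                    max(truth.loc[animal, depot], 0.05), rel=0.05
                )

    def test_raster_mode_matches_area_mode(self, small_cohort, rng):
        from rumigen.ct import process_raster_stack
        from rumigen.simulate import raster_stack_for_animal

        coh = small_cohort
        animal = coh.animals["animal"].iloc[0]
        seg = SegmentationConfig()
        slices = raster_stack_for_animal(coh, animal, rng)
        masses_r, _ = process_raster_stack(slices, seg, spacing_mm=30.0)
        masses_a, _ = process_stack(
            coh.ct_stacks[coh.ct_stacks["animal"] == animal], seg, spacing_mm=30.0
        )
        for depot in ("subcutaneous_fat", "carcass_lean", "visceral_fat"):
            assert masses_r[depot] == pytest.approx(masses_a[depot], rel=0.08)
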