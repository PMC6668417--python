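"""Generators: determinism, truth bookkeeping, and closed-loop recovery."""

import numpy as np
import pytest

from lipoglo import synthetic as syn
from lipoglo.electrophoresis import locate_standard, quantify_subclasses
from lipoglo.gradient import density_profile, ri_to_density
from lipoglo.microscopy import quantify_larva
from lipoglo.pipeline import analyze_gel_image
from lipoglo.presets import Band, GenotypePreset


def lu_fraction(profile, standard_px, lo_lu, hi_lu):
    lu = np.arange(profile.intensities.size) / standard_px
    sel = (lu >= lo_lu) & (lu < hi_lu)
    return profile.intensities[sel].sum() / profile.intensities.sum()


class TestLaneProfile:
    def test_apoc2_profile_is_vldl_dominant(self, apoc2):
        prof, _ = syn.make_lane_profile(apoc2, 260, 100.0, noise_sd=0.0)
        assert lu_fraction(prof, 100.0, 0.3, 1.0) >= 0.60

    def test_pure_ldl_preset_confined_to_ldl_bin(self):
        preset = GenotypePreset(
            "ldl_only",
            {"ZM": 0.0, "VLDL": 0.0, "IDL": 0.0, "LDL": 1.0},
            (Band("LDL", 2.05, 0.05, 1.0),),
            {"viscera": 1.0, "trunk": 0.0, "head": 0.0},
        )
        prof, _ = syn.make_lane_profile(preset, 260, 100.0)
        assert lu_fraction(prof, 100.0, 1.7, 2.4001) > 0.999

    def test_seed_determinism(self, wt):
        a, _ = syn.make_lane_profile(wt, 260, 100.0, noise_sd=5.0, seed=7)
        b, _ = syn.make_lane_profile(wt, 260, 100.0, noise_sd=5.0, seed=7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_axis_too_short_rejected(self, wt):
        with pytest.raises(ValueError, match="axis too short"):
            syn.make_lane_profile(wt, 200, 100.0)


class TestGelImage:
    def test_noiseless_closed_loop_recovers_weights(self, wt):
        gel, truth = syn.make_gel_image([wt], seed=0)
        res = analyze_gel_image(
            gel.lipo_channel, gel.dii_channel, gel.lane_bounds,
            "standard", origin_px=gel.origin_px,
        )
        ab = res.abundances[0]
        true_w = truth.data["class_weights"][ab.lane_id]
        for sub, pct in ab.percent.items():
            assert abs(pct / 100 - true_w[sub]) < 0.01

    def test_no_sample_lanes_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            syn.make_gel_image([])

    def test_standard_plus_nine_samples_gives_ten_lanes(self, presets):
        lanes = [presets["WT"]] * 9
        gel, truth = syn.make_gel_image(lanes, standard_lane=True, seed=0)
        assert truth.data["n_lanes"] == 10
        assert truth.data["lane_order"][0] == "standard"

    def test_determinism(self, wt, mtp):
        g1, _ = syn.make_gel_image([wt, mtp], noise_sd=10.0, seed=3)
        g2, _ = syn.make_gel_image([wt, mtp], noise_sd=10.0, seed=3)
        np.testing.assert_array_equal(g1.lipo_channel, g2.lipo_channel)
        np.testing.assert_array_equal(g1.dii_channel, g2.dii_channel)


class TestPlateTimecourse:
    def test_noiseless_dosage_is_exactly_two(self):
        reads, _ = syn.make_plate_timecourse(
            {"het": 1, "hom": 2}, timepoints=[3], n_per_cell=4, cv=0.0
        )
        hom = reads.loc[reads.group == "hom", "rlu"].mean()
        het = reads.loc[reads.group == "het", "rlu"].mean()
        assert hom / het == pytest.approx(2.0)

    def test_noisy_dosage_ratio_near_two(self):
        reads, _ = syn.make_plate_timecourse(
            {"het": 1, "hom": 2}, timepoints=[3], n_per_cell=24, cv=0.2, seed=11
        )
        ratio = (
            reads.loc[reads.group == "hom", "rlu"].mean()
            / reads.loc[reads.group == "het", "rlu"].mean()
        )
        assert 1.8 <= ratio <= 2.2

    def test_determinism(self):
        a, _ = syn.make_plate_timecourse({"het": 1}, n_per_cell=4, cv=0.3, seed=5)
        b, _ = syn.make_plate_timecourse({"het": 1}, n_per_cell=4, cv=0.3, seed=5)
        assert a.equals(b)

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            syn.make_plate_timecourse({"het": 1}, per_allele_signal=-1.0)

    def test_small_cell_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            syn.make_plate_timecourse({"het": 1}, n_per_cell=1)


class TestGradientRun:
    def test_fraction_one_is_densest(self, presets):
        for preset in presets.values():
            run, _ = syn.make_gradient_run(preset, seed=0)
            dens = ri_to_density(run.refractive_index)
            assert dens[0] > dens[-1]

    def test_ri_round_trip_reproduces_ladder(self, wt):
        run, truth = syn.make_gradient_run(wt, seed=0)
        np.testing.assert_allclose(
            ri_to_density(run.refractive_index), truth.data["densities"], atol=1e-6
        )

    def test_apoc2_signal_peaks_in_buoyant_fractions(self, apoc2):
        run, _ = syn.make_gradient_run(apoc2, seed=0)
        assert run.fraction_index[np.argmax(run.signal)] >= 8

    def test_too_few_fractions_rejected(self, wt):
        with pytest.raises(ValueError, match="at least 2"):
            syn.make_gradient_run(wt, n_fractions=1)

    def test_inverted_density_range_rejected(self, wt):
        with pytest.raises(ValueError, match="bottom density"):
            syn.make_gradient_run(wt, density_range=(1.02, 1.10))


class TestParticleSample:
    def test_mean_within_clt_bound(self):
        pop = syn.make_particle_sample(24.7, 5.6, 170, seed=42)
        se = 5.6 / np.sqrt(170)
        assert abs(pop.diameters_nm.mean() - 24.7) < 3 * se

    def test_zero_sd_gives_constant(self):
        pop = syn.make_particle_sample(10.0, 0.0, 5)
        np.testing.assert_array_equal(pop.diameters_nm, np.full(5, 10.0))

    def test_all_diameters_positive_even_with_wide_sd(self):
        pop = syn.make_particle_sample(5.0, 10.0, 500, seed=0)
        assert np.all(pop.diameters_nm > 0)

    @pytest.mark.parametrize(
        "kwargs", [dict(mean_nm=-1, sd_nm=1, n=5), dict(mean_nm=10, sd_nm=-1, n=5),
                   dict(mean_nm=10, sd_nm=1, n=0)]
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            syn.make_particle_sample(**kwargs)


class TestLarvaImage:
    FRACTIONS = {"viscera": 0.6, "trunk": 0.25, "head": 0.15}

    def test_noiseless_closed_loop_is_exact(self):
        stack, masks, truth = syn.make_larva_image(self.FRACTIONS, noise_sd=0.0)
        quant = quantify_larva(stack, masks)
        for region, frac in truth.data["region_fractions"].items():
            assert quant.fractions[region] == pytest.approx(frac, abs=1e-12)

    def test_saturate_long_puts_pixels_at_ceiling(self):
        stack, masks, _ = syn.make_larva_image(self.FRACTIONS, saturate_long=True)
        assert np.any(stack.long_exposure == stack.bit_ceiling)
        assert np.all(stack.short_exposure < stack.bit_ceiling)

    def test_masks_disjoint_and_cover_silhouette(self):
        masks = syn.make_larva_masks()
        # label image: disjoint by construction; all three regions non-empty
        assert set(np.unique(masks)) == {0, 1, 2, 3}
        assert all((masks == lab).sum() > 0 for lab in (1, 2, 3))

    def test_long_is_triple_of_short_before_clipping(self):
        stack, _, _ = syn.make_larva_image(self.FRACTIONS, noise_sd=0.0)
        np.testing.assert_allclose(
            stack.long_exposure, syn.EXPOSURE_RATIO * stack.short_exposure
        )

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            syn.make_larva_image({"viscera": 0.5, "trunk": 0.3, "head": 0.1})

    def test_overlapping_custom_masks_rejected(self):
        # a mask lacking one region is as invalid as an overlapping one
        bad = np.zeros(syn.LarvaGeometry().shape, dtype=np.uint8)
        bad[:10, :10] = 1
        with pytest.raises(ValueError, match="non-empty"):
            syn.make_larva_image(self.FRACTIONS, masks=bad)


def test_gradient_generator_truth_matches_density_profile(wt):
    run, truth = syn.make_gradient_run(wt, seed=2)
    prof = density_profile(run)
    assert not prof["inverted"].any()
    np.testing.assert_allclose(prof["density_g_ml"], truth.data["densities"], atol=1e-6)


def test_groundtruth_sidecar_round_trips(tmp_path, wt):
    _, truth = syn.make_gel_image([wt], seed=1)
    path = tmp_path / "truth.json"
    truth.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["kind"] == "gel_image"
    assert data["seed"] == 1
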