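"""Generator contracts: geometry, spectra, kinetics, and self-consistency."""

import numpy as np
import pytest

from cannaspec import synthetic_data as sd
from cannaspec.labeling import assign_quality_classes, compute_rwc
from cannaspec.modeling import make_classifier, spectral_matrix, split_dataset
from cannaspec.preprocessing import apply_msc, fit_msc, fit_preprocess, apply_pipeline
from cannaspec.segmentation import compute_nbd, extract_patches, threshold_roi


def regime_mean(spectrum, wavelengths, regime):
    lo, hi = sd.REGIMES_NM[regime]
    band = (wavelengths >= lo) & (wavelengths <= hi)
    return spectrum[band].mean()


class TestFlowerMask:
    def test_fixed_seed_reproducible(self):
        m1 = sd.generate_flower_mask((120, 120), seed=3)
        m2 = sd.generate_flower_mask((120, 120), seed=3)
        assert np.array_equal(m1, m2)
        assert not np.array_equal(m1, sd.generate_flower_mask((120, 120), seed=4))

    @pytest.mark.parametrize("seed", range(5))
    def test_default_patch_count_in_reference_range(self, seed):
        # per-sample data-point counts observed on real tray images: 27-73
        mask = sd.generate_flower_mask((300, 300), seed=seed)
        assert 27 <= len(extract_patches(mask)) <= 73

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError, match="60 x 60"):
            sd.generate_flower_mask((30, 30))


class TestEndmember:
    def test_fresh_state_shared_between_methods(self, wavelengths):
        hot = sd.endmember_spectrum(0.0, "hot_air", wavelengths)
        cool = sd.endmember_spectrum(0.0, "cool_air", wavelengths)
        assert np.array_equal(hot, cool)

    @pytest.mark.parametrize("d", [0.3, 0.7, 1.0])
    def test_regime_orderings(self, wavelengths, d):
        fresh = sd.endmember_spectrum(0.0, "hot_air", wavelengths)
        hot = sd.endmember_spectrum(d, "hot_air", wavelengths)
        cool = sd.endmember_spectrum(d, "cool_air", wavelengths)
        # below 552.61 nm: hot-dried lower than fresh and cool-dried
        assert regime_mean(hot, wavelengths, "blue_green") < regime_mean(fresh, wavelengths, "blue_green")
        assert regime_mean(hot, wavelengths, "blue_green") < regime_mean(cool, wavelengths, "blue_green")
        # 556.61-612.65 nm: cool-dried highest
        assert regime_mean(cool, wavelengths, "green_yellow") > regime_mean(hot, wavelengths, "green_yellow")
        assert regime_mean(cool, wavelengths, "green_yellow") > regime_mean(fresh, wavelengths, "green_yellow")
        # 616.65-708.7 nm: cool > hot > fresh
        assert (
            regime_mean(cool, wavelengths, "red")
            > regime_mean(hot, wavelengths, "red")
            > regime_mean(fresh, wavelengths, "red")
        )
        # 720.71-884.81 nm: both drop below fresh, hot drops faster
        assert regime_mean(hot, wavelengths, "nir") < regime_mean(cool, wavelengths, "nir")
        assert regime_mean(cool, wavelengths, "nir") < regime_mean(fresh, wavelengths, "nir")

    def test_drying_state_bounds(self):
        with pytest.raises(ValueError):
            sd.endmember_spectrum(1.2, "hot_air")
        with pytest.raises(ValueError):
            sd.endmember_spectrum(0.5, "vacuum")


class TestKinetics:
    def test_initial_state(self):
        rec, prof, d = sd.simulate_kinetics("hot_air", 0.0)
        assert d == 0.0
        rwc = compute_rwc(rec)
        assert rwc == pytest.approx(78.106, abs=1e-3)
        label = assign_quality_classes(rwc, prof)
        assert (label.dryness, label.cbda_conversion, label.thca_conversion,
                label.cbd_thc) == ("fresh", "low", "low", "extreme_high")

    def test_cool_air_conversion_stays_below_6_percent(self):
        _, prof, _ = sd.simulate_kinetics("cool_air", 9.0)
        assert prof.c_tc < 6.0
        assert prof.t_tt < 6.0

    def test_hot_air_day9_conversion_matches_closed_form(self):
        params = sd.GeneratorParams()
        _, prof, _ = sd.simulate_kinetics("hot_air", 9.0, params)
        c0 = params.baseline_conversion
        expected = 100 * (c0 + (1 - c0) * (1 - np.exp(-params.k_cbd["hot_air"] * 9.0)))
        assert prof.c_tc == pytest.approx(expected)
        assert prof.c_tc > 60.0  # high-conversion class

    def test_hot_air_ratio_drops_below_20(self):
        _, prof, _ = sd.simulate_kinetics("hot_air", 9.0)
        assert prof.c_t < 20.0
        _, prof0, _ = sd.simulate_kinetics("cool_air", 9.0)
        assert prof0.c_t >= 20.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_kinetics("hot_air", -1.0)


class TestGenerateCube:
    def test_fixed_seed_bit_identical(self):
        c1, t1 = sd.generate_cube(seed=11, method="cool_air", day=4.0)
        c2, t2 = sd.generate_cube(seed=11, method="cool_air", day=4.0)
        assert np.array_equal(c1.reflectance, c2.reflectance)
        assert t1.label == t2.label

    def test_noiseless_cube_separates_exactly(self):
        params = sd.GeneratorParams(
            noise_sd=0.0, gain_range=(1.0, 1.0), offset_range=(0.0, 0.0)
        )
        cube, truth = sd.generate_cube(params, seed=2, method="hot_air", day=9.0)
        nbd = compute_nbd(cube)
        assert nbd.values[truth.flower_mask].min() > 0.3
        assert nbd.values[~truth.flower_mask].max() <= 0.3

    @pytest.mark.parametrize("method,day", [("hot_air", 9.0), ("cool_air", 2.0)])
    def test_roi_mask_covers_flower_at_default_noise(self, method, day):
        cube, truth = sd.generate_cube(seed=6, method=method, day=day)
        mask = threshold_roi(compute_nbd(cube))
        assert (truth.flower_mask & ~mask).sum() == 0

    def test_msc_inverts_the_generating_scatter_model(self, wavelengths):
        """With scatter on but band noise off, MSC against the pixel mean
        collapses every flower pixel onto the reference, itself an affine
        image of the endmember."""
        params = sd.GeneratorParams(
            noise_sd=0.0, d_noise_sd=0.0, striping_sd=0.0, component_amplitude=0.0
        )
        cube, truth = sd.generate_cube(params, seed=4, method="cool_air", day=7.0)
        pixels = cube.reflectance[truth.flower_mask]
        state = fit_msc(pixels)
        corrected = apply_msc(pixels, state)
        assert np.abs(corrected - state.reference_spectrum).max() < 1e-8
        endmember = sd.endmember_spectrum(truth.d_spectral, "cool_air", wavelengths)
        rho = np.corrcoef(state.reference_spectrum, endmember)[0, 1]
        assert rho > 0.999999

    def test_ground_truth_labels_self_consistent(self):
        for seed, method, day in [(1, "hot_air", 2.0), (2, "cool_air", 9.0), (3, "hot_air", 0.0)]:
            _, truth = sd.generate_cube(seed=seed, method=method, day=day)
            relabelled = assign_quality_classes(compute_rwc(truth.record), truth.profile)
            assert truth.label == relabelled


class TestDataset:
    def test_mini_benchmark_covers_every_class(self, mini_benchmark):
        _, truths = mini_benchmark
        coverage = sd.class_coverage(truths)  # raises on under-filled classes
        assert (coverage["count"] >= 2).all()

    def test_per_condition_counts(self, mini_benchmark):
        _, truths = mini_benchmark
        counts = truths.groupby(["drying_method", "day"]).size()
        assert (counts == 2).all()
        assert len(counts) == 10

    def test_fixed_seed_identical_truth_tables(self):
        import pandas as pd

        gen = lambda: sd.truth_table(
            [t for _, t in sd.generate_dataset(1, days=(0, 9), params=sd.GeneratorParams(shape=(80, 80)), seed=5)]
        )
        pd.testing.assert_frame_equal(gen(), gen())

    def test_scatter_drives_the_msc_advantage(self, mini_benchmark):
        """With the scatter fields disabled, the raw-vs-MSC accuracy gap for
        dryness collapses (the ablation that justifies the noise model)."""
        table_scatter, _ = mini_benchmark
        no_scatter = sd.GeneratorParams(gain_range=(1.0, 1.0), offset_range=(0.0, 0.0))
        table_clean, _ = sd.benchmark_spectrum_table(
            n_per_condition=2, params=no_scatter, seed=42
        )
        gaps = {}
        for name, table in [("scatter", table_scatter), ("clean", table_clean)]:
            cal, pred = split_dataset(table, 0.2, seed=0)
            X, Xv = spectral_matrix(cal), spectral_matrix(pred)
            accs = {}
            for method in ("raw", "msc"):
                state = fit_preprocess(method, X)
                clf = make_classifier("LR", seed=0)
                clf.fit(apply_pipeline(method, X, state), cal["dryness"])
                accs[method] = float(
                    np.mean(clf.predict(apply_pipeline(method, Xv, state)) == pred["dryness"])
                )
            gaps[name] = accs["msc"] - accs["raw"]
        assert gaps["clean"] < 0.02
        assert gaps["scatter"] > gaps["clean"]
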