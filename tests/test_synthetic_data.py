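"""Synthetic flow-cytometry dataset and dye-curve generation."""


import numpy as np
import pytest

from il4redox.datasets import ExperimentDataset
from il4redox.synthetic_data import (GeneratorSpec, generate_dataset,
                                     generate_dye_curves, normalize_mfi)


class TestNormalizeMfi:
    def test_printed_formula_example(self):
        assert normalize_mfi(10.0, 2.0, 6.0) == pytest.approx(2.0)

    def test_self_normalization_is_one(self):
        assert normalize_mfi(6.0, 2.0, 6.0) == pytest.approx(1.0)

    def test_background_maps_to_zero(self):
        assert normalize_mfi(2.0, 2.0, 6.0) == pytest.approx(0.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            normalize_mfi(5.0, 2.0, 2.0)


@pytest.fixture(scope="module")
def noiseless():
    return generate_dataset(GeneratorSpec(noise_cv=0.0, seed=0))


@pytest.fixture(scope="module")
def noisy():
    return generate_dataset(GeneratorSpec(noise_cv=0.05, seed=1))


class TestGenerateDataset:
    def test_schema_and_conditions(self, noisy):
        t = noisy.table
        assert list(t.columns) == ["condition", "species", "time_min",
                                   "mean", "sem"]
        assert set(t["condition"]) == {"untreated", "IL4", "IL4+DPI",
                                       "IL4+H2O2", "IL4+CHX", "IL4+MG132"}
        assert set(t["species"]) == {"pSTAT6", "STAT6", "SOCS3"}
        assert (t["sem"] > 0).all()

    def test_untreated_normalizes_to_one(self, noiseless):
        # the scaling is anchored so the untreated readout sits at 1.0,
        # like MFIs normalized by the untreated sample
        t, m, _ = noiseless.series("untreated", "pSTAT6")
        np.testing.assert_allclose(m, 1.0, rtol=1e-4)

    def test_zero_noise_means_are_deterministic_scaled_truth(self):
        a = generate_dataset(GeneratorSpec(noise_cv=0.0, seed=0))
        b = generate_dataset(GeneratorSpec(noise_cv=0.0, seed=999))
        np.testing.assert_allclose(a.table["mean"], b.table["mean"],
                                   rtol=1e-12)

    def test_fixed_seed_gives_byte_identical_csv(self, tmp_path):
        for name in ("a.csv", "b.csv"):
            generate_dataset(GeneratorSpec(seed=42)).to_csv(tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == \
            (tmp_path / "b.csv").read_bytes()

    def test_raw_mfi_triples_invert_to_normalized_means(self, noisy):
        raw = noisy.raw_mfi
        renorm = [normalize_mfi(r.mfi_sample, r.mfi_bk, r.mfi_untreat)
                  for r in raw.itertuples()]
        np.testing.assert_allclose(renorm, noisy.table["mean"], rtol=1e-9)

    def test_sem_scales_with_cv_over_sqrt_replicates(self):
        # empirical SEM over many seeds ~ cv * mean / sqrt(n)
        sems, means = [], []
        for seed in range(12):
            ds = generate_dataset(GeneratorSpec(noise_cv=0.08, seed=seed,
                                                conditions=("IL4",)))
            s = ds.slice("IL4", "pSTAT6")
            sems.append(s["sem"].to_numpy())
            means.append(s["mean"].to_numpy())
        ratio = np.mean(np.concatenate(sems)) / np.mean(
            0.08 * np.concatenate(means) / np.sqrt(3))
        assert 0.7 < ratio < 1.3

    def test_round_trip_through_csv(self, tmp_path, noisy):
        path = tmp_path / "ds.csv"
        noisy.to_csv(path)
        clone = ExperimentDataset.from_csv(path)
        np.testing.assert_allclose(clone.table["mean"], noisy.table["mean"])

    def test_truth_pstat6_has_two_peaks_in_observed_windows(self, noiseless):
        # the generator enforces this; the spline pipeline must agree
        from il4redox.peaks import fit_smoothing_spline
        t, m, _ = noiseless.series("IL4", "pSTAT6")
        _, _, _, feats = fit_smoothing_spline(t, m)
        assert feats.n_peaks == 2
        assert 0 < feats.t1 <= 25
        assert 25 < feats.t2 <= 120


class TestGenerateDyeCurves:
    def test_schema_and_monotone_means(self):
        df = generate_dye_curves(GeneratorSpec(noise_cv=0.0, seed=0))
        assert list(df.columns) == ["condition", "time_min",
                                    "mean_fluorescence", "sem"]
        for cond, sub in df.groupby("condition"):
            y = sub.sort_values("time_min")["mean_fluorescence"].to_numpy()
            assert np.all(np.diff(y) >= -1e-9), f"{cond} not cumulative"

    def test_dpi_curve_pointwise_below_il4(self):
        df = generate_dye_curves(GeneratorSpec(noise_cv=0.0, seed=0))
        il4 = df[df.condition == "IL4"].sort_values("time_min")
        dpi = df[df.condition == "IL4+DPI"].sort_values("time_min")
        assert np.all(dpi["mean_fluorescence"].to_numpy()
                      <= il4["mean_fluorescence"].to_numpy())

    def test_untreated_curve_is_linear_in_time(self):
        # constant baseline ROS integrates to a straight line
        df = generate_dye_curves(GeneratorSpec(noise_cv=0.0, seed=0),
                                 conditions=("untreated",))
        sub = df.sort_values("time_min")
        coeffs = np.polyfit(sub["time_min"], sub["mean_fluorescence"], 1)
        fitted = np.polyval(coeffs, sub["time_min"])
        np.testing.assert_allclose(sub["mean_fluorescence"], fitted,
                                   rtol=1e-6, atol=1e-9)

    def test_hill_fit_roundtrip_recovers_ros_peak_time(self):
        # fit the noiseless IL-4 dye curve and compare the derivative peak
        # with the generating profile's transient peak
        from il4redox.ros_input import fit_hill
        from il4redox.systems_model import default_il4_ros_profile
        df = generate_dye_curves(GeneratorSpec(noise_cv=0.0, seed=0),
                                 conditions=("IL4",))
        sub = df.sort_values("time_min")
        curve = fit_hill(sub["time_min"].to_numpy(),
                         sub["mean_fluorescence"].to_numpy())
        profile = default_il4_ros_profile()
        t = np.linspace(0.5, 120, 2000)
        truth_peak_t = t[np.argmax(profile(t) - profile.a)]
        assert curve.derivative_peak_time() == pytest.approx(truth_peak_t,
                                                             rel=0.10)
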