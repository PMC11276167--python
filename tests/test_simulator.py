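"""Paired-spectrum simulator: closed forms, determinism, class structure."""

import numpy as np
import pytest

import lvdlnet as lv
from lvdlnet.simulate import (
    LibsSimParams,
    VnirSimParams,
    _gauss_profiles,
    _lorentz_profiles,
)


def single_line_params(registry, line_idx, amp, baseline=0.0):
    a = np.zeros(len(registry))
    a[line_idx] = amp
    return LibsSimParams(
        base_amp=a, frac_coef=np.zeros_like(a), gamma=0.05, baseline=baseline
    )


class TestLibsSimulation:
    def test_noise_free_spectrum_matches_closed_form(self, libs_axis, registry):
        libs_p, _ = lv.load_preset("easy")
        libs_p.sigma_mult = 0.0
        libs_p.sigma_add = 0.0
        f = 0.4
        s = lv.simulate_libs_spectrum(f, libs_p, np.random.default_rng(0), axis=libs_axis)
        # independent template recomputation
        lam = libs_axis.values
        expected = np.full_like(lam, libs_p.baseline)
        for e, c in enumerate(registry.centers):
            g = libs_p.gamma[e]
            amp = libs_p.base_amp[e] + libs_p.frac_coef[e] * f
            expected += amp * g**2 / ((lam - c) ** 2 + g**2)
        np.testing.assert_allclose(s.intensities, expected, atol=1e-9)

    def test_intensity_at_line_center_increases_with_fraction(self, libs_axis, registry):
        p = single_line_params(registry, 7, amp=100.0)
        p.frac_coef[7] = 50.0
        i_near = np.argmin(np.abs(libs_axis.values - registry.centers[7]))
        vals = [
            lv.simulate_libs_spectrum(f, p, np.random.default_rng(0), axis=libs_axis)
            .intensities[i_near]
            for f in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert np.all(np.diff(vals) > 0)

    def test_monte_carlo_mean_matches_noiseless_value(self, libs_axis, registry):
        p = single_line_params(registry, 7, amp=100.0, baseline=20.0)
        p.sigma_mult = 0.05
        p.sigma_add = 5.0
        i_near = np.argmin(np.abs(libs_axis.values - registry.centers[7]))
        noiseless = (
            20.0
            + 100.0
            * 0.05**2
            / ((libs_axis.values[i_near] - registry.centers[7]) ** 2 + 0.05**2)
        )
        rng = np.random.default_rng(42)
        n = 500
        draws = np.array(
            [
                lv.simulate_libs_spectrum(0.0, p, rng, axis=libs_axis).intensities[i_near]
                for _ in range(n)
            ]
        )
        se = np.sqrt((100.0 * 0.05) ** 2 + 5.0**2) / np.sqrt(n)
        assert abs(draws.mean() - noiseless) < 3 * se

    def test_fraction_bounds_enforced(self, libs_axis):
        libs_p, _ = lv.load_preset("easy")
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            lv.simulate_libs_spectrum(1.2, libs_p, np.random.default_rng(0), axis=libs_axis)

    def test_negative_amplitude_combination_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            LibsSimParams(base_amp=[10.0], frac_coef=[-20.0], gamma=0.05)


class TestVnirSimulation:
    def test_fraction_effect_localized_at_bands(self, vnir_axis):
        _, p = lv.load_preset("easy")
        p.sigma_add = 0.0
        rng = np.random.default_rng(0)
        s0 = lv.simulate_vnir_spectrum(0.0, p, rng, axis=vnir_axis)
        s1 = lv.simulate_vnir_spectrum(1.0, p, rng, axis=vnir_axis)
        diff = np.abs(s0.intensities - s1.intensities)
        # far from every band (> 8 widths, where Gaussian tails are ~1e-14)
        # the two spectra agree
        lam = vnir_axis.values
        far = np.all(
            np.abs(lam[None, :] - p.band_centers[:, None]) > 8 * p.widths[:, None],
            axis=0,
        )
        assert far.sum() > 50
        assert diff[far].max() < 1e-9
        assert diff.max() > 0.01  # and the bands did move

    def test_band_depth_at_center(self, vnir_axis):
        _, p = lv.load_preset("easy")
        p.sigma_add = 0.0
        f = 0.6
        s = lv.simulate_vnir_spectrum(f, p, np.random.default_rng(0), axis=vnir_axis)
        i670 = np.argmin(np.abs(vnir_axis.values - 670.0))
        lam = vnir_axis.values[i670]
        base = p.baseline_fn()(lam)
        depths = p.depth0 + p.depth_slope * f
        expected = base - depths @ _gauss_profiles(
            np.array([lam]), p.band_centers, p.widths
        )[:, 0]
        assert s.intensities[i670] == pytest.approx(float(expected), abs=1e-9)

    def test_same_seed_gives_identical_spectra(self, vnir_axis):
        _, p = lv.load_preset("hard")
        s1 = lv.simulate_vnir_spectrum(0.4, p, np.random.default_rng(9), axis=vnir_axis)
        s2 = lv.simulate_vnir_spectrum(0.4, p, np.random.default_rng(9), axis=vnir_axis)
        assert np.array_equal(s1.intensities, s2.intensities)

    def test_reflectance_range_validated(self, vnir_axis):
        _, p = lv.load_preset("easy")
        p.depth0 = p.depth0 + 2.0  # drives reflectance negative
        with pytest.raises(ValueError, match="reflectance"):
            p.validate_reflectance(vnir_axis)


class TestPairedDataset:
    def test_minimal_dataset_has_one_sample_per_level(self):
        ds = lv.generate_preset_dataset("null", 1, seed=3)
        assert ds.n_samples == 6
        assert sorted(ds.labels.tolist()) == [0, 1, 2, 3, 4, 5]
        assert np.allclose(sorted(ds.fractions), [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])

    def test_same_seed_regenerates_identical_dataset(self):
        d1 = lv.generate_preset_dataset("hard", 2, seed=5)
        d2 = lv.generate_preset_dataset("hard", 2, seed=5)
        assert d1.equals(d2, atol=0.0)
        d3 = lv.generate_preset_dataset("hard", 2, seed=6)
        assert not np.array_equal(d1.libs, d3.libs)

    def test_dataset_rows_match_single_spectrum_api(self, tiny_ds):
        """Row i is exactly what the per-spectrum simulator produces for the
        i-th spawned seed stream (partial regeneration contract)."""
        libs_p, vnir_p = lv.load_preset(tiny_ds.manifest.preset)
        child = np.random.SeedSequence(tiny_ds.manifest.seed).spawn(tiny_ds.n_samples)[3]
        ss_libs, ss_vnir = child.spawn(2)
        s = lv.simulate_libs_spectrum(
            tiny_ds.fractions[3], libs_p, np.random.default_rng(ss_libs),
            axis=tiny_ds.libs_axis,
        )
        np.testing.assert_array_equal(s.intensities, tiny_ds.libs[3])

    def test_nearest_centroid_separates_easy_preset(self, small_ds, small_split):
        """The generator is not degenerate: raw spectra are separable."""
        from sklearn.neighbors import NearestCentroid

        for X in (small_ds.libs, small_ds.vnir):
            nc = NearestCentroid().fit(
                X[small_split.train], small_ds.labels[small_split.train]
            )
            acc = nc.score(X[small_split.test], small_ds.labels[small_split.test])
            assert acc > 0.95

    def test_null_preset_carries_no_class_signal(self):
        from sklearn.neighbors import NearestCentroid

        ds = lv.generate_preset_dataset("null", 30, seed=21)
        split = lv.split_dataset(ds.labels, seed=21)
        nc = NearestCentroid().fit(ds.vnir[split.train], ds.labels[split.train])
        acc = nc.score(ds.vnir[split.test], ds.labels[split.test])
        assert 0.0 <= acc < 0.45  # chance is 1/6; sampling error on 36 rows
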