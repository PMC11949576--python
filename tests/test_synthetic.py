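"""Twin-cohort generator: determinism, geometry coverage, coupling
signatures, leakage mixing and the phase-shuffling surrogate."""

import numpy as np
import pytest

from crossconn.metrics import aec, plv, wpli_star
from crossconn.resampling import extract_template
from crossconn.connectome import enumerate_channel_pairs
from crossconn.spectral import bandpass_analytic
from crossconn.synthetic import (SyntheticConfig, apply_leakage,
                                 generate_geometry, generate_twin_cohorts,
                                 phase_shuffle_surrogate)


class TestDeterminism:
    def test_same_config_gives_bit_identical_cohorts(self, small_config):
        r1, t1, g1 = generate_twin_cohorts(small_config)
        r2, t2, g2 = generate_twin_cohorts(small_config)
        assert r1.channels.equals(r2.channels)
        assert t1.channels.equals(t2.channels)
        for s in r1.signals:
            assert np.array_equal(r1.signals[s], r2.signals[s])
        for s in t1.signals:
            assert np.array_equal(t1.signals[s], t2.signals[s])
        assert g1.coupling == g2.coupling

    def test_different_seeds_differ(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        r1, _, _ = generate_twin_cohorts(small_config)
        r2, _, _ = generate_twin_cohorts(other)
        s = sorted(r1.signals)[0]
        assert not np.array_equal(r1.signals[s], r2.signals.get(s, 0))


class TestGeometry:
    def test_full_roi_allocation_limiting_case(self):
        cfg = SyntheticConfig(n_rois=5, n_subjects_reference=3,
                              rois_per_reference_subject=5,
                              n_couplings=4, seed=0)
        ref, _ = generate_geometry(cfg)
        for _, grp in ref.groupby("subject_id"):
            assert set(grp["roi_id"].astype(int)) == {1, 2, 3, 4, 5}

    def test_zero_scatter_puts_channels_on_centroids(self):
        cfg = SyntheticConfig(channel_scatter=0.0, seed=1)
        ref, _ = generate_geometry(cfg)
        from crossconn.synthetic import resolve
        cents, _ = resolve(cfg)
        for rec in ref.itertuples(index=False):
            assert np.allclose([rec.x_mm, rec.y_mm, rec.z_mm],
                               cents[int(rec.roi_id) - 1])

    def test_test_cohort_replicates_all_reference_positions(self):
        cfg = SyntheticConfig(seed=2)
        ref, test = generate_geometry(cfg)
        ref_set = set(map(tuple, ref[["channel_id", "x_mm", "y_mm",
                                      "z_mm"]].itertuples(index=False)))
        for _, grp in test.groupby("subject_id"):
            got = set(map(tuple, grp[["channel_id", "x_mm", "y_mm",
                                      "z_mm"]].itertuples(index=False)))
            assert got == ref_set

    def test_every_coupled_pair_covered_brute_force_recount(self,
                                                            small_cohorts):
        reference, _, gt = small_cohorts
        tpl = extract_template(enumerate_channel_pairs(reference.channels))
        for pair in gt.coupling:
            assert pair in tpl.slots
            assert len(tpl.slots[pair]) >= 1

    def test_impossible_coverage_raises_listing_pairs(self):
        cfg = SyntheticConfig(n_rois=8, n_subjects_reference=1,
                              rois_per_reference_subject=2,
                              n_couplings=8, seed=3)
        with pytest.raises(ValueError, match="uncovered"):
            generate_geometry(cfg)

    def test_template_satisfies_resampling_invariants(self, small_cohorts):
        reference, _, _ = small_cohorts
        tpl = extract_template(enumerate_channel_pairs(reference.channels))
        tpl.validate()  # raises on any violated invariant


class TestSignals:
    def _cross_roi_metrics(self, cfg):
        ref, _, gt = generate_twin_cohorts(cfg)
        band = cfg.band
        subj = sorted(ref.signals)[0]
        arr = ref.signals[subj]
        rois = ref.channels[ref.channels.subject_id == subj][
            "roi_id"].astype(int).tolist()
        i = rois.index(1)
        j = rois.index(2)
        ax = bandpass_analytic(arr[i], band, cfg.fs)
        ay = bandpass_analytic(arr[j], band, cfg.fs)
        return (aec(ax, ay).value, plv(ax, ay, 6.0).value,
                wpli_star(ax, ay, 6.0).value)

    def test_perfect_zero_lag_coupling(self):
        cfg = SyntheticConfig(n_rois=4, n_subjects_reference=2,
                              n_subjects_test=1,
                              rois_per_reference_subject=4,
                              channels_per_roi=1, duration=30.0,
                              coupling_graph=[(1, 2, 1.0, 0.0)],
                              noise_level=0.0, leakage_strength=0.0, seed=4)
        a, p, w = self._cross_roi_metrics(cfg)
        assert a == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)
        assert w == pytest.approx(0.0, abs=1e-9)  # exact zero lag

    def test_uncoupled_rois_near_zero_over_seeds(self):
        vals_a, vals_p = [], []
        for seed in range(20):
            cfg = SyntheticConfig(n_rois=4, n_subjects_reference=2,
                                  n_subjects_test=1,
                                  rois_per_reference_subject=4,
                                  channels_per_roi=1, duration=30.0,
                                  coupling_graph=[(3, 4, 0.8, 0.01)],
                                  leakage_strength=0.0, seed=seed)
            a, p, _ = self._cross_roi_metrics(cfg)  # ROIs 1-2 uncoupled
            vals_a.append(a)
            vals_p.append(p)
        assert abs(np.mean(vals_a)) < 0.05
        # PLV has a positive finite-sample floor; it must stay near it
        assert np.mean(vals_p) < 0.2

    def test_quarter_period_lag_elevates_wpli_star(self):
        lagged, floor = [], []
        for seed in range(10):
            cfg = dict(n_rois=4, n_subjects_reference=2, n_subjects_test=1,
                       rois_per_reference_subject=4, channels_per_roi=1,
                       duration=30.0, noise_level=0.3,
                       leakage_strength=0.0, seed=seed)
            # quarter period of the 10.5-Hz alpha center ~ 0.025 s
            cfg_l = SyntheticConfig(coupling_graph=[(1, 2, 1.0, 0.025)],
                                    **cfg)
            cfg_0 = SyntheticConfig(coupling_graph=[(3, 4, 1.0, 0.025)],
                                    **cfg)
            lagged.append(self._cross_roi_metrics(cfg_l)[2])
            floor.append(self._cross_roi_metrics(cfg_0)[2])
        assert np.mean(lagged) > np.mean(floor) + 0.2

    def test_band_limited_power(self, small_cohorts):
        reference, _, _ = small_cohorts
        subj = sorted(reference.signals)[0]
        x = reference.signals[subj][0]
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(len(x), 1 / 200.0)
        outside = (freqs < 0.5) | (freqs > 80.0)
        assert spec[outside].sum() / spec.sum() < 0.01


class TestLeakage:
    def test_zero_strength_is_bitwise_identity(self):
        rng = np.random.default_rng(5)
        sig = rng.standard_normal((4, 100))
        pos = rng.uniform(-50, 50, (4, 3))
        out = apply_leakage(sig, pos, 0.0, 20.0)
        assert out is sig or np.array_equal(out, sig)

    def test_mixing_weight_formula_at_lambda(self):
        sig = np.vstack([np.zeros(50), np.ones(50)])
        pos = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        out = apply_leakage(sig, pos, 0.3, 20.0)
        assert np.allclose(out[0], 0.3 * np.exp(-1.0))

    def test_leakage_component_peaks_at_zero_lag(self):
        rng = np.random.default_rng(6)
        n = 2000
        freqs = np.fft.rfftfreq(n, 1 / 200.0)
        sig = np.fft.irfft(np.fft.rfft(rng.standard_normal((2, n)))
                           * ((freqs > 0.5) & (freqs < 80)), n=n)
        pos = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.0]])
        out = apply_leakage(sig, pos, 0.4, 20.0)
        added = out[0] - sig[0]  # the leaked copy of channel 1
        xc = np.correlate(added, sig[1], mode="full")
        assert np.argmax(np.abs(xc)) == n - 1  # lag 0

    def test_leakage_raises_aec_not_wpli_star(self):
        """Independent nearby sources: mixing inflates AEC while the
        wPLI* change stays within +/- 0.05 — the zero-lag signature."""
        from crossconn.spectral import band_by_name
        band = band_by_name("alpha")
        d_aec, d_wps = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 4000
            freqs = np.fft.rfftfreq(n, 1 / 200.0)
            sig = np.fft.irfft(np.fft.rfft(rng.standard_normal((2, n)))
                               * ((freqs > 0.5) & (freqs < 80)), n=n)
            pos = np.array([[0.0, 0.0, 0.0], [15.0, 0.0, 0.0]])
            mixed = apply_leakage(sig, pos, 0.5, 20.0)
            a0 = [bandpass_analytic(s, band, 200.0) for s in sig]
            a1 = [bandpass_analytic(s, band, 200.0) for s in mixed]
            d_aec.append(aec(a1[0], a1[1]).value - aec(a0[0], a0[1]).value)
            d_wps.append(wpli_star(a1[0], a1[1], 6.0).value
                         - wpli_star(a0[0], a0[1], 6.0).value)
        assert np.mean(d_aec) > 0.1
        assert abs(np.mean(d_wps)) < 0.05


class TestPhaseShuffleSurrogate:
    def test_amplitude_spectrum_preserved_exactly(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1024)
        y = phase_shuffle_surrogate(x, np.random.default_rng(8))
        ax = np.abs(np.fft.rfft(x))
        ay = np.abs(np.fft.rfft(y))
        assert np.max(np.abs(ax - ay)) / np.max(ax) < 1e-9

    def test_autocovariance_preserved(self):
        rng = np.random.default_rng(9)
        n = 4096
        freqs = np.fft.rfftfreq(n, 1 / 200.0)
        x = np.fft.irfft(np.fft.rfft(rng.standard_normal(n))
                         * ((freqs > 1) & (freqs < 30)), n=n)
        y = phase_shuffle_surrogate(x, np.random.default_rng(10))
        # Wiener-Khinchin: matched power spectra imply matched (circular)
        # autocovariance
        acx = np.fft.irfft(np.abs(np.fft.rfft(x)) ** 2, n=n) / n
        acy = np.fft.irfft(np.abs(np.fft.rfft(y)) ** 2, n=n) / n
        assert np.allclose(acx, acy, atol=1e-9 * max(1.0, acx[0]))

    def test_independently_shuffled_copies_uncorrelated(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2048)
        rs = []
        for seed in range(20):
            y1 = phase_shuffle_surrogate(x, np.random.default_rng(100 + seed))
            y2 = phase_shuffle_surrogate(x, np.random.default_rng(200 + seed))
            rs.append(np.corrcoef(y1, y2)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_output_is_real_and_same_length(self):
        x = np.random.default_rng(12).standard_normal(999)  # odd length
        y = phase_shuffle_surrogate(x, np.random.default_rng(13))
        assert y.shape == x.shape and np.isrealobj(y)
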