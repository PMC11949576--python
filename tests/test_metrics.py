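"""Connectivity metrics: worked examples, form equivalences, bounds,
symmetry, amplitude invariance and the zero-lag leakage trade-off."""

import numpy as np
import pytest

from conftest import make_analytic

from crossconn.metrics import (METRICS, aec, compute_metric,
                               compute_metric_analytic, oaec, orthogonalize,
                               plv, wpli, wpli_star)
from crossconn.spectral import band_by_name, bandpass_analytic

FS = 200.0


def _random_pair(rng, n=1200):
    return (make_analytic(rng.standard_normal(n) + 1j * rng.standard_normal(n),
                          fs=float(n)),
            make_analytic(rng.standard_normal(n) + 1j * rng.standard_normal(n),
                          fs=float(n)))


class TestAEC:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x, _ = _random_pair(rng)
        assert aec(x, x).value == pytest.approx(1.0)

    def test_anticorrelated_envelopes(self):
        rng = np.random.default_rng(1)
        amp = 1.0 + rng.random(500)
        phase = rng.uniform(-np.pi, np.pi, 500)
        x = make_analytic(amp * np.exp(1j * phase))
        y = make_analytic((3.0 - amp) * np.exp(1j * phase))
        assert aec(x, y).value == pytest.approx(-1.0)

    def test_small_example_against_brute_force_pearson(self):
        x = make_analytic(np.array([1, 2, 3, 4], float) + 0j, fs=4.0)
        y = make_analytic(np.array([1, 3, 2, 4], float) + 0j, fs=4.0)
        # brute-force Pearson of the envelopes, term by term
        ax, ay = np.abs(x.values), np.abs(y.values)
        num = sum((a - ax.mean()) * (b - ay.mean()) for a, b in zip(ax, ay))
        den = np.sqrt(sum((a - ax.mean()) ** 2 for a in ax)
                      * sum((b - ay.mean()) ** 2 for b in ay))
        assert num / den == pytest.approx(0.8)
        assert aec(x, y).value == pytest.approx(0.8)

    def test_zero_variance_envelope_is_missing(self):
        x = make_analytic(np.exp(1j * np.linspace(0, 6, 100)))  # |x| = 1
        y = make_analytic(np.random.default_rng(2).standard_normal(100) + 0j)
        assert aec(x, y).missing


class TestOrthogonalize:
    def test_collinear_annihilation(self):
        rng = np.random.default_rng(3)
        x, _ = _random_pair(rng)
        y = make_analytic(2.5 * x.values, fs=x.sampling_rate)
        assert np.allclose(orthogonalize(y, x), 0.0, atol=1e-12)

    def test_quarter_cycle_preserves_envelope(self):
        rng = np.random.default_rng(4)
        x, _ = _random_pair(rng)
        y = make_analytic(1j * x.values, fs=x.sampling_rate)
        assert np.allclose(orthogonalize(y, x), np.abs(x.values), atol=1e-12)

    def test_single_sample_hand_computation(self):
        x = make_analytic([3 + 4j], fs=1.0)
        y = make_analytic([1 + 2j], fs=1.0)
        # imag((1+2j)(3-4j)) / 5 = imag(11+2j)/5 = 0.4
        assert orthogonalize(y, x)[0] == pytest.approx(0.4)

    def test_zero_modulus_guard(self):
        x = make_analytic([0j, 1 + 0j], fs=1.0)
        y = make_analytic([1 + 1j, 1 + 1j], fs=1.0)
        out = orthogonalize(y, x)
        assert out[0] == 0.0 and out[1] == pytest.approx(1.0)


class TestOAEC:
    def test_symmetric_by_construction(self):
        rng = np.random.default_rng(5)
        x, y = _random_pair(rng)
        assert oaec(x, y).value == pytest.approx(oaec(y, x).value, abs=1e-12)

    def test_collinear_pair_is_missing(self):
        rng = np.random.default_rng(6)
        x, _ = _random_pair(rng)
        y = make_analytic(1.7 * x.values, fs=x.sampling_rate)
        assert oaec(x, y).missing

    def test_matches_independent_reimplementation(self):
        """Sample-by-sample re-statement of the orthogonalization plus
        Pearson agrees to 1e-10; independent noise stays near zero."""
        vals = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 2000
            x = bandpass_analytic(rng.standard_normal(n),
                                  band_by_name("alpha"), FS)
            y = bandpass_analytic(rng.standard_normal(n),
                                  band_by_name("alpha"), FS)

            def ortho(a, b):
                return np.array([
                    ((av * np.conj(bv)).imag / abs(bv)) if abs(bv) > 0 else 0.0
                    for av, bv in zip(a, b)])

            def pear(u, v):
                u = u - u.mean(); v = v - v.mean()
                return (u @ v) / np.sqrt((u @ u) * (v @ v))

            expect = 0.5 * (pear(np.abs(x.values),
                                 np.abs(ortho(y.values, x.values)))
                            + pear(np.abs(y.values),
                                   np.abs(ortho(x.values, y.values))))
            got = oaec(x, y).value
            assert got == pytest.approx(expect, abs=1e-10)
            vals.append(got)
        assert abs(np.mean(vals)) < 0.05


class TestPhaseMetrics:
    def _phases(self, dphi, n=None, fs=1.0):
        dphi = np.asarray(dphi, float)
        n = len(dphi)
        x = make_analytic(np.exp(1j * dphi), fs=float(n))
        y = make_analytic(np.ones(n, complex), fs=float(n))
        return x, y, float(n)

    def test_plv_constant_phase_difference(self):
        x, y, n = self._phases(np.full(100, 0.7))
        assert plv(x, y, epoch_length=100 / n).value == pytest.approx(1.0)

    def test_plv_cancelling_resultant(self):
        x, y, n = self._phases([0, np.pi / 2, np.pi, 3 * np.pi / 2] * 25)
        assert plv(x, y, epoch_length=100 / n).value == pytest.approx(
            0.0, abs=1e-12)

    def test_plv_half_zero_half_quarter(self):
        x, y, n = self._phases([0.0] * 50 + [np.pi / 2] * 50)
        assert plv(x, y, epoch_length=100 / n).value == pytest.approx(
            np.sqrt(2) / 2)

    def test_plv_epoch_averaging(self):
        # two epochs with PLV 1 each but different mean phase: average 1
        dphi = np.r_[np.full(50, 0.0), np.full(50, np.pi / 2)]
        x, y, n = self._phases(dphi)
        assert plv(x, y, epoch_length=50 / n).value == pytest.approx(1.0)

    def test_wpli_constant_quarter_lag(self):
        x, y, n = self._phases(np.full(60, np.pi / 2))
        assert wpli(x, y, epoch_length=60 / n).value == pytest.approx(1.0)

    def test_wpli_zero_lag_convention(self):
        x, y, n = self._phases(np.zeros(60))
        assert wpli(x, y, epoch_length=60 / n).value == 0.0
        assert wpli_star(x, y, epoch_length=60 / n).value == 0.0

    def test_wpli_sign_mix_brute_force(self):
        # unit amplitudes, sin(dphi) = [1, 1, -1] -> |1+1-1| / 3 = 1/3
        x, y, n = self._phases([np.pi / 2, np.pi / 2, -np.pi / 2])
        assert wpli(x, y, epoch_length=3 / n).value == pytest.approx(1 / 3)
        assert wpli_star(x, y, epoch_length=3 / n).value == pytest.approx(1 / 3)

    def test_wpli_star_alternating_cancels(self):
        x, y, n = self._phases([np.pi / 2, -np.pi / 2] * 30)
        assert wpli_star(x, y, epoch_length=60 / n).value == pytest.approx(
            0.0, abs=1e-12)


class TestDispatch:
    def test_record_length_conventions(self, alpha):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal((2, 12000))
        mv = compute_metric("AEC", x, y, alpha, FS)
        assert mv.n_epochs == 1 and mv.n_samples == 12000
        mv = compute_metric("PLV", x, y, alpha, FS)
        assert mv.n_epochs == 10 and mv.n_samples == 1200

    def test_identical_signals_zero_wpli_star(self, alpha):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(12000)
        assert compute_metric("WPLI_STAR", x, x, alpha, FS).value == 0.0

    def test_unknown_metric_rejected(self, alpha):
        with pytest.raises(ValueError, match="unknown metric"):
            compute_metric("COHERENCE", np.zeros(2000), np.zeros(2000),
                           alpha, FS)

    def test_edge_discard_shrinks_record(self, alpha):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal((2, 12000))
        mv = compute_metric("AEC", x, y, alpha, FS, edge_discard_s=1.0)
        assert mv.n_samples == 11600


class TestInvariants:
    def test_direct_and_normalized_product_plv_forms_agree(self):
        """Eq-equivalence: |mean exp(j dphi)| computed directly from phases
        matches the normalized-analytic-product implementation to 1e-10."""
        rng = np.random.default_rng(10)
        for _ in range(200):
            x, y = _random_pair(rng, n=128)
            direct = abs(np.mean(np.exp(1j * (np.angle(x.values)
                                              - np.angle(y.values)))))
            got = plv(x, y, epoch_length=128 / x.sampling_rate).value
            assert got == pytest.approx(direct, abs=1e-10)

    def test_bounds_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            x, y = _random_pair(rng, n=64)
            el = 64 / x.sampling_rate
            assert -1.0 <= aec(x, y).value <= 1.0
            assert -1.0 <= oaec(x, y).value <= 1.0
            assert 0.0 <= plv(x, y, el).value <= 1.0
            assert 0.0 <= wpli(x, y, el).value <= 1.0
            assert 0.0 <= wpli_star(x, y, el).value <= 1.0

    def test_all_metrics_symmetric(self):
        rng = np.random.default_rng(12)
        x, y = _random_pair(rng, n=600)
        el = 600 / x.sampling_rate
        assert aec(x, y).value == pytest.approx(aec(y, x).value, abs=1e-12)
        assert oaec(x, y).value == pytest.approx(oaec(y, x).value, abs=1e-12)
        assert plv(x, y, el).value == pytest.approx(plv(y, x, el).value,
                                                    abs=1e-12)
        assert wpli(x, y, el).value == pytest.approx(wpli(y, x, el).value,
                                                     abs=1e-12)
        assert wpli_star(x, y, el).value == pytest.approx(
            wpli_star(y, x, el).value, abs=1e-12)

    def test_phase_metrics_amplitude_invariant(self):
        rng = np.random.default_rng(13)
        x, y = _random_pair(rng, n=600)
        el = 600 / x.sampling_rate
        xs = make_analytic(7.3 * x.values, fs=x.sampling_rate)
        assert plv(xs, y, el).value == pytest.approx(plv(x, y, el).value,
                                                     abs=1e-12)
        assert wpli_star(xs, y, el).value == pytest.approx(
            wpli_star(x, y, el).value, abs=1e-12)

    def test_zero_lag_mixing_inflates_aec_plv_not_oaec_wpli_star(self):
        """Instantaneous mixing of independent sources inflates AEC and PLV
        while OAEC and wPLI* stay near zero — the leakage trade-off."""
        band = band_by_name("alpha")
        raw_aec, raw_plv, raw_wps = [], [], []
        mix_aec, mix_plv, mix_oaec, mix_wps = [], [], [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            s1, s2 = rng.standard_normal((2, 4000))
            ax, ay = (bandpass_analytic(s1, band, FS),
                      bandpass_analytic(s2, band, FS))
            raw_aec.append(aec(ax, ay).value)
            raw_plv.append(plv(ax, ay, 6.0).value)
            raw_wps.append(wpli_star(ax, ay, 6.0).value)
            mx = bandpass_analytic(s1 + 0.5 * s2, band, FS)
            my = bandpass_analytic(s2 + 0.5 * s1, band, FS)
            mix_aec.append(aec(mx, my).value)
            mix_plv.append(plv(mx, my, 6.0).value)
            mix_oaec.append(oaec(mx, my).value)
            mix_wps.append(wpli_star(mx, my, 6.0).value)
        assert np.mean(mix_aec) > np.mean(raw_aec) + 0.2
        assert np.mean(mix_plv) > np.mean(raw_plv) + 0.2
        # metrics that discount zero-lag coupling stay at their floors:
        # OAEC near zero, wPLI* at its (positive) finite-sample noise floor
        assert abs(np.mean(mix_oaec)) < 0.05
        assert abs(np.mean(mix_wps) - np.mean(raw_wps)) < 0.05
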