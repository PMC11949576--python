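"""Pairwise band-limited connectivity metrics.

Five metrics over a pair of analytic signals X, Y with envelopes A and
phases phi:

* ``AEC`` — Pearson correlation of the amplitude envelopes, over the full
  record.
* ``OAEC`` — AEC after pairwise orthogonalization: each signal's
  instantaneous (zero-lag) component collinear with the other is removed via
  ``imag(Y X* / |X|)`` before correlating, and the two directions are
  averaged.  Discounts source-leakage-induced zero-lag correlation.
* ``PLV`` — modulus of the time-averaged unit phasor of the phase
  difference, per 6-s epoch, averaged over epochs.
* ``WPLI`` — amplitude-weighted phase lag index
  ``|sum A_X A_Y sin(dphi)| / sum |A_X A_Y sin(dphi)|`` per epoch.
* ``WPLI_STAR`` — the amplitude-free variant using ``sin(dphi)`` alone;
  strictly phase-driven, blind to zero-lag coupling.

Record-length conventions: the amplitude metrics (AEC, OAEC) use the whole
record; the phase metrics (PLV, wPLI, wPLI*) are computed per 6-s epoch and
averaged across epochs.  Degenerate pairs (zero-variance envelope) yield a
missing value (NaN) rather than a silent zero, so connectome averages are
not biased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectral import AnalyticSignal, BandSpec, bandpass_analytic, epoch_analytic

__all__ = [
    "METRICS",
    "MetricValue",
    "aec",
    "orthogonalize",
    "oaec",
    "plv",
    "wpli",
    "wpli_star",
    "compute_metric",
    "compute_metric_analytic",
]

#: Metric labels, in the order the analysis matrix reports them.
METRICS = ("AEC", "OAEC", "PLV", "WPLI", "WPLI_STAR")

#: Epoch length (s) for the phase metrics.
DEFAULT_EPOCH_S = 6.0


@dataclass
class MetricValue:
    """One connectivity value for one channel pair, metric and band."""

    metric: str
    band: BandSpec | None
    value: float
    n_epochs: int
    #: samples per averaging segment: the full record for AEC/OAEC, one
    #: epoch for the phase metrics
    n_samples: int = 0

    @property
    def missing(self) -> bool:
        return bool(np.isnan(self.value))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when either input has zero variance."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da = a - a.mean()
    db = b - b.mean()
    va = float(da @ da)
    vb = float(db @ db)
    # a variance at machine-noise level is degenerate, not signal
    tol_a = (1e-10 * max(1.0, abs(float(a.mean())))) ** 2 * a.size
    tol_b = (1e-10 * max(1.0, abs(float(b.mean())))) ** 2 * b.size
    if va <= tol_a or vb <= tol_b:
        return float("nan")
    return float((da @ db) / np.sqrt(va * vb))


def _signed_sine_part(prod: np.ndarray) -> np.ndarray:
    """imag of a conjugate product with machine-noise residue zeroed.

    For exactly collinear inputs the true imaginary part is zero but
    floating-point complex multiplication leaves O(eps) residue; values
    below a relative threshold are snapped to 0 so the 0/0 zero-lag
    convention can actually trigger.
    """
    im = np.imag(prod)
    return np.where(np.abs(im) < 1e-12 * np.abs(prod), 0.0, im)


def aec(x: AnalyticSignal, y: AnalyticSignal) -> MetricValue:
    """Amplitude envelope correlation over the full record."""
    _check_pair(x, y)
    r = _pearson(x.amplitude, y.amplitude)
    return MetricValue("AEC", x.band, r, n_epochs=1, n_samples=x.n_samples)


def orthogonalize(y: AnalyticSignal, x: AnalyticSignal) -> np.ndarray:
    """Component of ``y`` orthogonal to ``x``: ``imag(y conj(x) / |x|)``.

    Real-valued, same length as the inputs.  Samples where ``|x| = 0`` are
    set to 0 (division guard).  Orthogonalizing a real multiple of ``x``
    against ``x`` yields the all-zero sequence.
    """
    _check_pair(y, x)
    ax = np.abs(x.values)
    im = _signed_sine_part(y.values * np.conj(x.values))
    out = np.where(ax > 0, im / np.where(ax > 0, ax, 1.0), 0.0)
    return out


def oaec(x: AnalyticSignal, y: AnalyticSignal) -> MetricValue:
    """Orthogonalized amplitude envelope correlation, symmetrized.

    Correlates ``A_X`` with the envelope of Y-orthogonalized-to-X and vice
    versa; the final value is the mean of the two signed correlations.  The
    envelope of the (real-valued) orthogonalized sequence is its absolute
    value.  Either direction degenerate (zero-variance envelope, e.g. when
    the signals are collinear and the orthogonalized residual vanishes)
    makes the pair missing.
    """
    _check_pair(x, y)
    r1 = _pearson(x.amplitude, np.abs(orthogonalize(y, x)))
    r2 = _pearson(y.amplitude, np.abs(orthogonalize(x, y)))
    val = float("nan") if (np.isnan(r1) or np.isnan(r2)) else 0.5 * (r1 + r2)
    return MetricValue("OAEC", x.band, val, n_epochs=1, n_samples=x.n_samples)


def _unit_phasors(v: np.ndarray) -> np.ndarray:
    """v / |v| with zero-modulus samples excluded (set to 0, hence dropped
    from sums) — the division guard of the normalized-product PLV form."""
    mod = np.abs(v)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / np.where(mod > 0, mod, 1.0)
    return np.where(mod > 0, u, 0.0)


def plv(x: AnalyticSignal, y: AnalyticSignal,
        epoch_length: float = DEFAULT_EPOCH_S) -> MetricValue:
    """Phase locking value, per-epoch and averaged over epochs.

    Implemented in the normalized-analytic-product form: per epoch,
    ``| mean_t  (x/|x|) conj(y/|y|) |``, identical to the direct
    ``| mean_t exp(j (phi_x - phi_y)) |`` form.
    """
    _check_pair(x, y)
    ex = epoch_analytic(x, epoch_length)
    ey = epoch_analytic(y, epoch_length)
    vals = []
    for sx, sy in zip(ex, ey):
        ux = _unit_phasors(sx.values)
        uy = _unit_phasors(sy.values)
        valid = (np.abs(sx.values) > 0) & (np.abs(sy.values) > 0)
        n = int(valid.sum())
        if n == 0:
            vals.append(np.nan)
            continue
        vals.append(abs(np.sum(ux * np.conj(uy))) / n)
    return MetricValue("PLV", x.band, float(np.nanmean(vals)), len(vals),
                       n_samples=ex.epochs[0].n_samples)


def _pli_ratio(s: np.ndarray) -> float:
    """|sum s| / sum |s| with the 0/0 (exact zero-lag) case defined as 0."""
    den = float(np.sum(np.abs(s)))
    if den == 0.0:
        return 0.0
    return float(abs(np.sum(s)) / den)


def wpli(x: AnalyticSignal, y: AnalyticSignal,
         epoch_length: float = DEFAULT_EPOCH_S) -> MetricValue:
    """Amplitude-weighted phase lag index, epoch-averaged.

    ``A_X A_Y sin(phi_x - phi_y)`` equals ``imag(x conj(y))``, so the metric
    is the ratio of the imaginary cross-spectral term's signed sum to its
    absolute sum.  An exact zero-lag pair (all sines zero) scores 0 by
    convention — zero-lag coupling is precisely what the index discounts.
    """
    _check_pair(x, y)
    ex = epoch_analytic(x, epoch_length)
    ey = epoch_analytic(y, epoch_length)
    vals = [_pli_ratio(_signed_sine_part(sx.values * np.conj(sy.values)))
            for sx, sy in zip(ex, ey)]
    return MetricValue("WPLI", x.band, float(np.mean(vals)), len(vals),
                       n_samples=ex.epochs[0].n_samples)


def wpli_star(x: AnalyticSignal, y: AnalyticSignal,
              epoch_length: float = DEFAULT_EPOCH_S) -> MetricValue:
    """Amplitude-free phase lag index ``|sum sin dphi| / sum |sin dphi|``.

    Assumes envelopes are not part of the coupling, so synchrony is carried
    by a stable phase shift alone; invariant to any positive rescaling of
    either envelope.  0/0 (exact zero lag) is defined as 0.
    """
    _check_pair(x, y)
    ex = epoch_analytic(x, epoch_length)
    ey = epoch_analytic(y, epoch_length)
    vals = []
    for sx, sy in zip(ex, ey):
        prod = sx.values * np.conj(sy.values)
        mod = np.abs(prod)
        sines = np.where(mod > 0,
                         _signed_sine_part(prod) / np.where(mod > 0, mod, 1.0),
                         0.0)
        vals.append(_pli_ratio(sines))
    return MetricValue("WPLI_STAR", x.band, float(np.mean(vals)), len(vals),
                       n_samples=ex.epochs[0].n_samples)


def _check_pair(x: AnalyticSignal, y: AnalyticSignal) -> None:
    if x.n_samples != y.n_samples:
        raise ValueError(
            f"signal lengths differ: {x.n_samples} vs {y.n_samples}")
    if x.sampling_rate != y.sampling_rate:
        raise ValueError("sampling rates differ")


def compute_metric_analytic(
    metric: str,
    x: AnalyticSignal,
    y: AnalyticSignal,
    epoch_length: float = DEFAULT_EPOCH_S,
    edge_discard_s: float = 0.0,
) -> MetricValue:
    """Dispatch a metric on precomputed analytic signals.

    AEC/OAEC run on the full record; PLV/wPLI/wPLI* on ``epoch_length``
    epochs averaged.  ``edge_discard_s`` seconds are trimmed from each end
    before computation (filter edge-artifact guard; default 0 keeps the
    printed full-record sample-count convention).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; known: {METRICS}")
    if edge_discard_s > 0:
        x = x.trimmed(edge_discard_s)
        y = y.trimmed(edge_discard_s)
    if metric == "AEC":
        return aec(x, y)
    if metric == "OAEC":
        return oaec(x, y)
    if metric == "PLV":
        return plv(x, y, epoch_length)
    if metric == "WPLI":
        return wpli(x, y, epoch_length)
    return wpli_star(x, y, epoch_length)


def compute_metric(
    metric: str,
    x: np.ndarray,
    y: np.ndarray,
    band: BandSpec,
    fs: float,
    epoch_length: float = DEFAULT_EPOCH_S,
    edge_discard_s: float = 0.0,
) -> MetricValue:
    """Band-limit two real signals and compute one connectivity metric."""
    ax = bandpass_analytic(x, band, fs)
    ay = bandpass_analytic(y, band, fs)
    return compute_metric_analytic(metric, ax, ay, epoch_length,
                                   edge_discard_s)
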