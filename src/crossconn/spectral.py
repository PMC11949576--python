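"""Band-limited analytic-signal decomposition.

Real-valued channel signals are decomposed into narrow 0.5-Hz sub-bands,
each sub-band is converted to its analytic (Hilbert) signal, and the complex
analytic signals are averaged across sub-bands to yield one analytic signal
per canonical frequency band.  The analytic signal's modulus is the
instantaneous amplitude envelope A(t) and its argument the instantaneous
phase phi(t); every connectivity metric downstream operates on these.

Filtering is zero-phase by construction: each sub-band response is specified
directly in the frequency domain (unit passband, raised-cosine transitions)
and applied by FFT multiplication, which is equivalent to circular
convolution with a finite, length-n, symmetric impulse response.  Zero phase
distortion is required because half of the metrics are phase metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BandSpec",
    "AnalyticSignal",
    "EpochSet",
    "canonical_bands",
    "subband_grid",
    "bandpass_analytic",
    "epoch_analytic",
    "SignalTooShortError",
]

#: Transition width (Hz) of the raised-cosine edges of every sub-band filter.
TRANSITION_HZ = 0.25


class SignalTooShortError(ValueError):
    """Raised when a signal is too short for stable band-pass filtering."""


@dataclass(frozen=True)
class BandSpec:
    """A canonical frequency band tiled by fixed-width sub-bands.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"alpha"``.
    f_lo, f_hi : float
        Band edges in Hz, ``0 < f_lo < f_hi``.
    subband_width : float
        Width of the sub-bands tiling ``[f_lo, f_hi]``; the band span must be
        an integer multiple of this width.  Default 0.5 Hz.
    """

    name: str
    f_lo: float
    f_hi: float
    subband_width: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.f_lo < self.f_hi:
            raise ValueError(
                f"band {self.name!r}: need 0 < f_lo < f_hi, got "
                f"({self.f_lo}, {self.f_hi})"
            )
        span = self.f_hi - self.f_lo
        n = span / self.subband_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"band {self.name!r}: span {span} Hz is not an integer "
                f"multiple of subband_width {self.subband_width} Hz"
            )

    @property
    def n_subbands(self) -> int:
        return round((self.f_hi - self.f_lo) / self.subband_width)


def canonical_bands() -> list[BandSpec]:
    """The six canonical frequency bands of resting-state electrophysiology.

    delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, low gamma 30-55 and
    high gamma 55-80 Hz, each tiled by 0.5-Hz sub-bands.
    """
    edges = [
        ("delta", 0.5, 4.0),
        ("theta", 4.0, 8.0),
        ("alpha", 8.0, 13.0),
        ("beta", 13.0, 30.0),
        ("low_gamma", 30.0, 55.0),
        ("high_gamma", 55.0, 80.0),
    ]
    return [BandSpec(name, lo, hi) for name, lo, hi in edges]


def band_by_name(name: str) -> BandSpec:
    """Look up a canonical band by its label."""
    for b in canonical_bands():
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: "
                   f"{[b.name for b in canonical_bands()]}")


def subband_grid(band: BandSpec) -> list[tuple[float, float]]:
    """Contiguous, non-overlapping sub-band intervals tiling [f_lo, f_hi].

    Sub-bands are half-open [lo, hi) with the final sub-band closed; since
    the intervals share edges exactly, the union equals the band span with
    no gaps or overlaps.
    """
    k = band.n_subbands
    edges = band.f_lo + band.subband_width * np.arange(k + 1)
    # guard against float drift at the top edge
    edges[-1] = band.f_hi
    return [(float(edges[i]), float(edges[i + 1])) for i in range(k)]


@dataclass
class AnalyticSignal:
    """Complex band-limited analytic signal of one channel.

    ``values`` holds the sub-band-averaged analytic signal; ``amplitude`` is
    its modulus (the envelope) and ``phase`` its argument in (-pi, pi].
    """

    band: BandSpec
    sampling_rate: float
    values: np.ndarray

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[-1]

    def trimmed(self, margin_s: float) -> "AnalyticSignal":
        """Copy with ``margin_s`` seconds discarded from each end."""
        if margin_s <= 0:
            return self
        m = int(round(margin_s * self.sampling_rate))
        if 2 * m >= self.n_samples:
            raise SignalTooShortError(
                f"edge margin {margin_s} s x2 consumes the whole "
                f"{self.n_samples}-sample signal"
            )
        return AnalyticSignal(self.band, self.sampling_rate,
                              self.values[..., m:self.n_samples - m])


@dataclass
class EpochSet:
    """Equal-length consecutive segments of one analytic signal."""

    epochs: list[AnalyticSignal]
    epoch_length: float

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)


def _zero_phase_response(freqs: np.ndarray, lo: float, hi: float,
                         transition: float = TRANSITION_HZ) -> np.ndarray:
    """Real, non-negative band-pass response with raised-cosine edges.

    Unit gain on [lo + t/2, hi - t/2], cosine-squared ramps of width
    ``transition`` centred on each edge, zero outside.  Adjacent sub-bands
    sharing an edge therefore sum to exactly one across the joint.
    """
    f = np.abs(freqs)
    h = np.zeros_like(f)
    t2 = transition / 2.0
    flat = (f >= lo + t2) & (f <= hi - t2)
    h[flat] = 1.0
    ramp_up = (f > lo - t2) & (f < lo + t2)
    h[ramp_up] = np.sin(np.pi / 2 * (f[ramp_up] - (lo - t2)) / transition) ** 2
    ramp_dn = (f > hi - t2) & (f < hi + t2)
    h[ramp_dn] = np.cos(np.pi / 2 * (f[ramp_dn] - (hi - t2)) / transition) ** 2
    return h


def _min_length(band: BandSpec, fs: float) -> int:
    # at least two cycles of the lowest frequency, and enough samples that a
    # sub-band spans at least one FFT bin
    return int(np.ceil(max(2.0 * fs / band.f_lo, fs / band.subband_width)))


def bandpass_analytic(
    x: np.ndarray,
    band: BandSpec,
    fs: float,
    subband_average: str = "complex",
) -> AnalyticSignal:
    """Band-limit ``x`` and return its sub-band-averaged analytic signal.

    For every sub-band of ``band`` the signal is zero-phase band-pass
    filtered and converted to its analytic signal (negative frequencies
    zeroed, positive doubled); the complex analytic signals are then
    averaged pointwise across sub-bands.  ``subband_average="envelope_phase"``
    instead averages the sub-band envelopes and takes the circular-mean
    phase, provided as an alternative convention.

    ``x`` may be 1-D (samples,) or 2-D (channels, samples); time is the last
    axis and the output length equals the input length.

    Raises
    ------
    SignalTooShortError
        If the signal is shorter than the documented minimum
        (two cycles of ``f_lo``), never silently truncating.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if band.f_hi >= fs / 2:
        raise ValueError(f"band {band.name!r} upper edge {band.f_hi} Hz "
                         f"requires fs > {2 * band.f_hi} Hz, got {fs}")
    nmin = _min_length(band, fs)
    if n < nmin:
        raise SignalTooShortError(
            f"signal of {n} samples is shorter than the minimum {nmin} "
            f"required for stable filtering in band {band.name!r}"
        )
    if subband_average not in ("complex", "envelope_phase"):
        raise ValueError(f"unknown subband_average {subband_average!r}")

    freqs = np.fft.fftfreq(n, d=1.0 / fs)
    X = np.fft.fft(x, axis=-1)
    analytic_gain = np.where(freqs > 0, 2.0, 0.0)
    analytic_gain[freqs == 0] = 1.0

    subs = subband_grid(band)
    if subband_average == "complex":
        # averaging commutes with the linear filter + Hilbert operator, so a
        # single averaged transfer function gives the identical result in
        # one inverse FFT
        h_sum = np.zeros(n)
        for lo, hi in subs:
            h_sum += _zero_phase_response(freqs, lo, hi)
        h_avg = h_sum / len(subs)
        values = np.fft.ifft(X * (h_avg * analytic_gain), axis=-1)
    else:
        amps = np.zeros(x.shape)
        phasors = np.zeros(x.shape, dtype=complex)
        for lo, hi in subs:
            h = _zero_phase_response(freqs, lo, hi)
            a_k = np.fft.ifft(X * (h * analytic_gain), axis=-1)
            mod = np.abs(a_k)
            amps += mod
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(mod > 0, a_k / np.where(mod > 0, mod, 1.0), 0)
            phasors += unit
        amps /= len(subs)
        ang = np.angle(phasors)
        values = amps * np.exp(1j * ang)
    return AnalyticSignal(band=band, sampling_rate=fs, values=values)


def epoch_analytic(a: AnalyticSignal, epoch_length: float) -> EpochSet:
    """Cut an analytic signal into consecutive non-overlapping epochs.

    The epoch count is ``floor(T / (epoch_length * fs))``; a trailing partial
    segment is dropped.  Epoching happens on the band-limited analytic
    signal computed over the full record, never by re-filtering per epoch.
    """
    samples = epoch_length * a.sampling_rate
    if abs(samples - round(samples)) > 1e-9:
        raise ValueError(
            f"epoch_length {epoch_length} s x fs {a.sampling_rate} Hz is not "
            f"an integer number of samples"
        )
    per = int(round(samples))
    n_epochs = a.n_samples // per
    if n_epochs == 0:
        raise ValueError(
            f"epoch of {per} samples exceeds signal of {a.n_samples} samples"
        )
    epochs = [
        AnalyticSignal(a.band, a.sampling_rate,
                       a.values[..., i * per:(i + 1) * per])
        for i in range(n_epochs)
    ]
    return EpochSet(epochs=epochs, epoch_length=epoch_length)
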