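"""Band-limited analytic signals and the five connectivity metrics.

Builds two 60-s signals sharing a lagged latent source, decomposes them
into the alpha band with the 0.5-Hz sub-band Hilbert convention, and
prints all five metrics under their record-length conventions (AEC/OAEC on
the full 12,000-sample record, phase metrics on ten 6-s epochs).
"""

import numpy as np

from crossconn import band_by_name, bandpass_analytic, compute_metric

fs = 200.0
n = 12000  # 60 s
rng = np.random.default_rng(0)


def bandlimited(rng, n, fs):
    freqs = np.fft.rfftfreq(n, 1 / fs)
    z = np.fft.rfft(rng.standard_normal(n))
    return np.fft.irfft(z * ((freqs > 0.5) & (freqs < 80)), n=n)


latent = bandlimited(rng, n, fs)
lag = int(0.025 * fs)  # 25 ms, a quarter period at 10 Hz
x = 0.8 * latent + 0.6 * bandlimited(rng, n, fs)
y = 0.8 * np.roll(latent, lag) + 0.6 * bandlimited(rng, n, fs)

alpha = band_by_name("alpha")
ax = bandpass_analytic(x, alpha, fs)
print(f"alpha band: {alpha.f_lo}-{alpha.f_hi} Hz, "
      f"{alpha.n_subbands} sub-bands of {alpha.subband_width} Hz")
print(f"analytic signal: {ax.n_samples} samples, "
      f"mean envelope {ax.amplitude.mean():.4f}")

print("\nmetric   value    segments")
for metric in ("AEC", "OAEC", "PLV", "WPLI", "WPLI_STAR"):
    mv = compute_metric(metric, x, y, alpha, fs)
    print(f"{metric:9s} {mv.value:+.3f}   {mv.n_epochs} x {mv.n_samples}")

print("""
The pair shares a 25-ms-lagged source: AEC and PLV detect the coupling
directly; OAEC keeps most of it (the lag survives orthogonalization);
wPLI* is driven only by the consistent phase lead, so it is well above
its noise floor but below PLV.""")
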