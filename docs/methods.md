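# Methods

## Spectral decomposition

Channel signals are decomposed per canonical band (δ 0.5–4, θ 4–8, α 8–13,
β 13–30, low γ 30–55, high γ 55–80 Hz) by tiling the band with 0.5-Hz
sub-bands, band-pass filtering each sub-band with zero phase, taking the
analytic (Hilbert) signal of each, and averaging the complex analytic
signals pointwise into one transform per band. The transform is computed
once over the full record; epochs are cut from it afterwards, never by
re-filtering per epoch.

**Filter design.** Each sub-band's zero-phase response is specified
directly on the FFT grid: unit gain inside the sub-band with
cosine-squared transitions of 0.25 Hz centred on each edge, applied by
frequency-domain multiplication. This is a frequency-sampling FIR design —
the impulse response is finite (length n) and exactly symmetric — chosen
over windowed time-domain kernels because 0.5-Hz-wide passbands at
200 Hz sampling would need >2,600-tap kernels per sub-band while the
frequency-sampled response is exactly flat in the passband and exactly
zero-phase, which the phase metrics require. Adjacent sub-bands share
edges, so their transitions sum to one across each joint.

**Sub-band averaging convention.** Averaging the *complex* analytic
signals preserves the linear algebra every metric operates on; because the
sub-band responses tile the band, the complex average equals the band's
own analytic signal scaled by 1/K (K = number of sub-bands). All five
metrics are invariant to that scale. An alternative convention —
averaging envelopes and circular-averaging phases — is available via
`subband_average="envelope_phase"` for sensitivity analyses; it is
nonlinear and not the default.

**Edge handling.** The circular filtering and the Hilbert transform leave
artifacts within roughly one envelope correlation time of the record ends.
A configurable edge-discard margin is excluded from metric computation:
0 s at the metric level (`compute_metric`), so the printed record-length
conventions hold exactly — a 60-s record at 200 Hz enters AEC/OAEC as
T = 12,000 samples and each 6-s epoch enters the phase metrics as
T = 1,200 samples — and 1 s per end at the pipeline level
(`RunConfig.edge_discard_s`), where whole-study robustness matters more
than the sample-count convention.

**Minimum length.** `bandpass_analytic` refuses signals shorter than two
cycles of the band's lower edge or shorter than one FFT bin per sub-band
(whichever is larger) rather than silently truncating.

## Metrics: conventions and degenerate cases

- AEC/OAEC use the whole record; PLV/wPLI/wPLI* are computed per 6-s epoch
  and averaged (unweighted — epochs have equal length by construction).
- OAEC keeps the *signed* mean of the two directed correlations; a
  rectified variant is available (`RunConfig.oaec_absolute`). The envelope
  of the (real-valued) orthogonalized sequence is its absolute value.
- 0/0 in wPLI and wPLI* — every sin Δφ exactly zero, i.e. exact zero-lag
  collinearity — is defined as 0: zero-lag coupling is precisely what
  these indices discount. Because floating-point complex multiplication
  leaves O(machine-eps) imaginary residue on exactly collinear products,
  imaginary parts below 1e-12 of the product modulus are snapped to zero
  so this convention can actually trigger.
- Degenerate pairs (an envelope whose variance is at machine-noise level,
  e.g. after orthogonalizing collinear signals) yield NaN, are excluded
  from ROI-pair averages, and are counted per entry — silent zeros would
  bias connectome means downward.
- wPLI* and PLV have positive finite-sample floors (≈ 0.15 and ≈ 0.17 for
  6-s alpha epochs); "no coupling" means sitting at the floor, not at zero.
  Tests therefore compare against the floor, not against zero.

## Connectome assembly

Edges exist only where at least one same-subject channel pair connects two
different ROIs; within-ROI and cross-subject pairs never contribute. The
edge value is the flat mean over all contributing channel-pair values
irrespective of subject — deliberately *not* a mean of per-subject means.
Coverage is reported against a declared universe of possible ROI pairs
(default: all pairs of the ROIs present in the input), rounded to a whole
percentage. Stratifications: hemisphere labels from the ROI table;
depth via per-channel eccentricity (Euclidean distance from a configurable
head centre, default the coordinate origin) with an 85-mm threshold —
superficial if all member channels exceed it, deep if all are below,
mixed (and excluded from the two-group comparison) otherwise, including
channels exactly on the boundary; ROI-pair distance as the Euclidean
distance between the member channels' per-ROI centroids (stable under
varying channel counts; a mean-over-channel-pairs alternative is kept
behind `distance_method="mean_pairwise"`).

## Bootstrap, null and ROPE

The contribution template records, per ROI pair, the ordered subject slots
of the reference cohort and each slot's channel pairs. One bootstrap
iteration draws, independently per slot and ROI pair, a test subject
uniformly with replacement; the drawn subject supplies *all* channel pairs
of that slot, preserving within-subject structure; the edge value is the
flat mean over the pair's channel pairs. The spatial null permutes each
bootstrapped connectome's values across its ROI-pair labels — preserving
the value multiset exactly — and correlates the permuted connectome with
the reference; one permutation per bootstrap iteration, paired by index.

The ROPE (region of practical equivalence) is the equal-tailed central 95%
interval of the null sample (empirical quantiles with linear
interpolation). The observed distribution is significant iff strictly less
than 2.5% of it falls inside the interval, bounds inclusive — equivalent
to a 5% two-tailed test. Summaries are reported as median ± median
absolute deviation (raw MAD, unscaled), both for the observed distribution
and for its offset from the null median. Iteration counts, coverage and
threshold default to 5,000 / 5,000 / 0.95 / 0.025 and are configuration
values; the bundled examples and the reproduction script use 150–500
iterations, which this study size does not distinguish from the full count.

Per metric × band cell the pipeline derives an independent seed from
(run seed, band index, metric index), so results are invariant to
execution order and reproducible bit-for-bit.

## Synthetic twin cohorts

The generator emulates the two-cohort experimental contrast on a common
anatomy, not any particular dataset:

- **Geometry.** ROI centroids on MNI-like millimetre coordinates (random
  directions, radii spread over 45–90 mm so both deep and superficial ROIs
  exist; hemisphere from the sign of x). Reference subjects receive
  channels (centroid + 5-mm isotropic scatter) in a small random ROI
  subset; because a random assignment would routinely leave some coupled
  ROI pairs without any same-subject coverage at the default sizes, the
  coupled pairs are first placed greedily onto subjects with capacity and
  the remaining capacity is filled randomly — coverage is then validated,
  and an explicit error lists uncovered pairs when the configuration makes
  coverage impossible. Test subjects receive channels at *all* reference
  positions under the same channel ids, so the contribution template
  transfers directly.
- **Signals.** Each coupled ROI pair owns a unit-variance latent source
  (Gaussian noise band-limited to 0.5–80 Hz); the pair's second ROI
  receives it delayed by the pair's lag (integer-sample circular shift —
  lags of tens of ms are negligible against a 60-s record). A channel is
  the strength-weighted sum of its ROI's latents plus independent
  band-limited channel noise. Latents are shared across subjects *and*
  cohorts, so cross-cohort spatial correlation is meaningful; channel
  noise is independent everywhere.
- **Leakage.** The test cohort only is mixed instantaneously:
  out_i = s_i + ε Σ_{j≠i} e^(−d_ij/λ) s_j. The mixing is strictly
  zero-lag — the defining signature of source leakage.
- **Defaults.** 12 ROIs, 10 reference subjects × 4 ROIs, 8 test subjects,
  2 channels/ROI, 20 coupled pairs, 60 s at 200 Hz, alpha band. Coupling
  strengths uniform on [0.3, 1.0] (heterogeneous edges, as in real
  connectomes), lags 5–25 ms (sub-cycle at alpha), channel noise 0.7 of
  latent amplitude (in-situ recordings are not noise-dominated), ε = 0.2
  with λ = 20 mm (a leakage admixture of tens of percent of signal
  variance at neighbouring channels — strong but not signal-swamping,
  consistent with the centimetre scale of source-reconstruction point
  spreads). These sizes keep a full validation run under a minute on one
  CPU.

**What the generator does not emulate:** 1/f spectral shape, biophysical
forward fields (leakage here is isotropic-exponential rather than
lead-field-structured), sensor noise, inter-subject anatomical
variability, or non-stationarity. Passing tests therefore demonstrate the
*machinery* — conventions, assembly rules, resampling, inference — under a
controlled leakage model, not performance on real recordings.

## Numerical choices

- All randomness flows through `numpy` Generators seeded from explicit
  `SeedSequence`s; identical configurations give bit-identical outputs.
- Pearson correlations treat variances at machine-noise level
  (std ≤ 1e-10 relative) as zero, returning the degenerate-pair marker.
- Cross-modal correlation requires ≥ 3 common ROI pairs and nonzero
  variance on both sides; violations raise rather than returning NaN.
- Connectome ROI-pair keys are stored as (min, max) of the ROI ids.

## Known limitations

- The demo-scale connectome (≈ 40–48 covered pairs of 66) produces a wide
  permutation null (±≈0.3); effects must be large to clear the ROPE, which
  the default generator operating point is designed to allow. Real-scale
  connectomes (thousands of pairs) have much tighter nulls.
- The frequency-sampled filters are circular; the edge-discard margin, not
  padding, handles wrap-around artifacts.
- `wPLI` (amplitude-weighted) is implemented and tested but the validation
  experiments focus on AEC/OAEC/PLV/wPLI*, mirroring the analysis matrix
  the pipeline defaults to.
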