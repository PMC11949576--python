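"""Twin synthetic cohorts and the zero-lag leakage signature.

Generates the default twin-cohort study — a sparse-coverage reference
cohort with clean signals and a full-coverage test cohort whose channels
are mixed instantaneously with distance-dependent weights — and compares
mean connectivity over the ROI pairs both cohorts can see.
"""

from crossconn import SyntheticConfig, generate_twin_cohorts
from crossconn.experiments import cohort_connectome_values

import numpy as np

cfg = SyntheticConfig(seed=0)
reference, test, truth = generate_twin_cohorts(cfg)
print(f"reference: {len(reference.signals)} subjects, "
      f"{len(reference.channels)} channel placements over {cfg.n_rois} ROIs")
print(f"test:      {len(test.signals)} subjects x "
      f"{len(test.channels) // len(test.signals)} channels (full coverage), "
      f"leakage eps={cfg.leakage_strength}, lambda={cfg.leakage_scale} mm")
print(f"ground truth: {len(truth.coupling)} coupled ROI pairs\n")

print("metric  reference  leaky-test")
diffs = {}
for metric in ("AEC", "PLV", "OAEC"):
    ref_vals, _, test_means, _ = cohort_connectome_values(
        reference, test, cfg.band, metric)
    keys = sorted(set(ref_vals) & set(test_means))
    r = float(np.mean([ref_vals[k] for k in keys]))
    t = float(np.mean([test_means[k] for k in keys]))
    diffs[metric] = (r, t)
    print(f"{metric:6s}  {r:+.4f}    {t:+.4f}")

d_ref = diffs["OAEC"][0] - diffs["AEC"][0]
d_test = diffs["OAEC"][1] - diffs["AEC"][1]
print(f"\nOAEC - AEC: reference {d_ref:+.4f}, test {d_test:+.4f}")
print("""
Zero-lag mixing inflates AEC and PLV in the test cohort only.  The
orthogonalized metric strips that inflation, so OAEC - AEC is clearly
more negative for the leaky cohort — the leakage trade-off.""")
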