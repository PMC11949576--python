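"""Bootstrap resampling, spatial-permutation null and ROPE inference.

A reference cohort (sparse, multi-subject coverage) and a test cohort
(every subject covers all channels) differ in how subjects contribute to a
connectome.  The bootstrap makes test-cohort connectomes mimic the
reference cohort's subject-contribution structure: for each ROI pair, each
reference subject's slot of channel pairs is filled by one test subject
drawn uniformly with replacement, so the bootstrapped connectome pools
subjects exactly the way the reference connectome does.

Significance of the cross-modal spatial correlation is assessed against an
empirical null built by permuting ROI-pair labels of the bootstrapped
connectomes (destroying spatial structure while preserving the value
distribution), using a region of practical equivalence (ROPE): the central
95% of the null around its median.  The observed correlation distribution
is significant when less than 2.5% of it falls inside that range.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .connectome import ChannelPair, Connectome

__all__ = [
    "ContributionTemplate",
    "CorrelationDistribution",
    "SignificanceResult",
    "extract_template",
    "bootstrap_connectome",
    "cross_modal_correlation",
    "draw_bootstrap_connectomes",
    "bootstrap_distribution",
    "spatial_permutation_null",
    "rope_test",
    "summarize",
]

#: Default iteration counts and ROPE parameters.
DEFAULT_N_BOOTSTRAP = 5000
DEFAULT_N_PERMUTATION = 5000
DEFAULT_COVERAGE = 0.95
DEFAULT_THRESHOLD = 0.025


@dataclass
class ContributionTemplate:
    """Per-ROI-pair subject slots of channel pairs, from a reference cohort.

    ``slots[(roi_a, roi_b)]`` is an ordered list of
    ``(reference_subject_id, [(ch_a, ch_b), ...])`` — the channel pairs that
    reference subject contributed to the ROI pair.  Every channel pair of an
    ROI pair belongs to exactly one slot.
    """

    slots: dict[tuple[int, int], list[tuple[str, list[tuple[str, str]]]]]

    def validate(self) -> None:
        for key, slot_list in self.slots.items():
            if not slot_list:
                raise ValueError(f"ROI pair {key} has no subject slots")
            seen: set[tuple[str, str]] = set()
            for _, cps in slot_list:
                if not cps:
                    raise ValueError(f"empty slot in ROI pair {key}")
                dup = seen.intersection(cps)
                if dup:
                    raise ValueError(
                        f"channel pair(s) {sorted(dup)} appear in more than "
                        f"one slot of ROI pair {key}")
                seen.update(cps)

    @property
    def n_pairs(self) -> int:
        return len(self.slots)


def extract_template(pairs: Sequence[ChannelPair]) -> ContributionTemplate:
    """Build the subject-contribution template of a reference cohort.

    Groups each ROI pair's channel pairs by the contributing subject; slot
    order follows sorted subject ids for determinism.
    """
    grouped: dict[tuple[int, int], dict[str, list[tuple[str, str]]]] = {}
    for p in pairs:
        grouped.setdefault(p.roi_key, {}).setdefault(
            p.subject_id, []).append(p.channel_key)
    slots = {
        key: [(subj, by_subj[subj]) for subj in sorted(by_subj)]
        for key, by_subj in sorted(grouped.items())
    }
    tpl = ContributionTemplate(slots=slots)
    tpl.validate()
    return tpl


@dataclass
class CorrelationDistribution:
    """An ordered sample of Pearson correlations (one per iteration)."""

    values: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_iterations(self) -> int:
        return self.values.size

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def mad(self) -> float:
        """Median absolute deviation (raw, unscaled)."""
        return float(np.median(np.abs(self.values - self.median)))


@dataclass
class SignificanceResult:
    """Outcome of the ROPE test of an actual vs a null distribution."""

    median: float
    mad: float
    null_range: tuple[float, float]
    overlap_fraction: float
    significant: bool
    median_offset: float = float("nan")  # median(actual) - median(null)
    mad_offset: float = float("nan")


def bootstrap_connectome(
    template: ContributionTemplate,
    test_values: Mapping[str, Mapping[tuple[str, str], float]],
    rng: np.random.Generator,
) -> dict[tuple[int, int], float]:
    """One bootstrapped test-cohort connectome mimicking the template.

    For every ROI pair and every subject slot, one test subject is drawn
    uniformly with replacement; that subject supplies the values of ALL
    channel pairs in the slot (the slot's pairs stay together, preserving
    the within-subject structure).  The ROI-pair value is the flat mean over
    all channel pairs.  Draws are independent across slots and ROI pairs.

    Raises
    ------
    KeyError
        Naming the channel pair, if a drawn subject lacks a value for it.
    """
    subjects = sorted(test_values)
    if not subjects:
        raise ValueError("empty test cohort")
    out: dict[tuple[int, int], float] = {}
    for key, slot_list in template.slots.items():
        vals: list[float] = []
        for _, channel_pairs in slot_list:
            subj = subjects[int(rng.integers(len(subjects)))]
            per_subj = test_values[subj]
            for cp in channel_pairs:
                try:
                    vals.append(float(per_subj[cp]))
                except KeyError as exc:
                    raise KeyError(
                        f"test subject {subj!r} has no value for channel "
                        f"pair {cp} (ROI pair {key})") from exc
        out[key] = float(np.mean(vals))
    return out


def _as_values(c) -> dict[tuple[int, int], float]:
    return c.values() if isinstance(c, Connectome) else dict(c)


def cross_modal_correlation(a, b) -> float:
    """Spatial Pearson correlation between two connectomes.

    Accepts ``Connectome`` objects or plain ``{roi_pair: value}`` maps; the
    correlation runs over the intersection of ROI-pair keys, aligned.

    Raises
    ------
    ValueError
        With fewer than 3 common pairs, or when either aligned vector has
        zero variance.
    """
    va, vb = _as_values(a), _as_values(b)
    common = sorted(set(va) & set(vb))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} common ROI pairs; need at least 3")
    xa = np.array([va[k] for k in common])
    xb = np.array([vb[k] for k in common])
    sa, sb = xa.std(), xb.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(xa, xb)[0, 1])


def draw_bootstrap_connectomes(
    template: ContributionTemplate,
    test_values: Mapping[str, Mapping[tuple[str, str], float]],
    n: int,
    rng: np.random.Generator,
) -> list[dict[tuple[int, int], float]]:
    """``n`` independent bootstrapped connectomes, in iteration order."""
    return [bootstrap_connectome(template, test_values, rng)
            for _ in range(n)]


def bootstrap_distribution(
    template: ContributionTemplate,
    test_values: Mapping[str, Mapping[tuple[str, str], float]],
    reference,
    n: int = DEFAULT_N_BOOTSTRAP,
    rng: np.random.Generator | None = None,
    return_connectomes: bool = False,
):
    """Correlate ``n`` bootstrapped connectomes with the reference.

    Returns a :class:`CorrelationDistribution`; with
    ``return_connectomes=True`` also the list of bootstrapped connectomes
    (needed to build the paired permutation null).
    """
    rng = np.random.default_rng() if rng is None else rng
    boots = draw_bootstrap_connectomes(template, test_values, n, rng)
    ref = _as_values(reference)
    vals = np.array([cross_modal_correlation(ref, b) for b in boots])
    dist = CorrelationDistribution(values=vals)
    return (dist, boots) if return_connectomes else dist


def spatial_permutation_null(
    bootstraps: Sequence[Mapping[tuple[int, int], float]],
    reference,
    rng: np.random.Generator,
) -> CorrelationDistribution:
    """Empirical null by permuting ROI-pair labels of each bootstrap.

    Iteration ``i`` permutes the i-th bootstrapped connectome's values
    across its ROI-pair labels — preserving the multiset of values exactly
    while destroying the spatial correlation structure — and correlates the
    permuted connectome with the reference.  One permutation per bootstrap
    iteration, paired by index.
    """
    ref = _as_values(reference)
    vals = []
    for boot in bootstraps:
        keys = sorted(boot)
        perm = rng.permutation(len(keys))
        shuffled = {keys[i]: boot[keys[int(j)]]
                    for i, j in enumerate(perm)}
        vals.append(cross_modal_correlation(ref, shuffled))
    return CorrelationDistribution(values=np.array(vals))


def rope_test(
    actual: CorrelationDistribution,
    null: CorrelationDistribution,
    coverage: float = DEFAULT_COVERAGE,
    threshold: float = DEFAULT_THRESHOLD,
) -> SignificanceResult:
    """Region-of-practical-equivalence significance test.

    The null range is the central ``coverage`` interval of the null sample
    (equal-tailed empirical quantiles around the median, linear
    interpolation).  ``overlap_fraction`` is the share of actual values
    falling inside the range, bounds inclusive.  The actual distribution is
    significant iff the overlap is strictly below ``threshold`` —
    equivalent, at the defaults, to a 5% two-tailed test with 2.5% in each
    tail.
    """
    if actual.n_iterations == 0 or null.n_iterations == 0:
        raise ValueError("empty distribution")
    tail = (1.0 - coverage) / 2.0
    lo = float(np.quantile(null.values, tail))
    hi = float(np.quantile(null.values, 1.0 - tail))
    inside = (actual.values >= lo) & (actual.values <= hi)
    overlap = float(np.mean(inside))
    return SignificanceResult(
        median=actual.median,
        mad=actual.mad,
        null_range=(lo, hi),
        overlap_fraction=overlap,
        significant=bool(overlap < threshold),
        median_offset=float(actual.median - null.median),
        mad_offset=float(np.median(np.abs(
            (actual.values - null.median)
            - np.median(actual.values - null.median)))),
    )


def summarize(
    dist: CorrelationDistribution,
    null: CorrelationDistribution | None = None,
) -> dict[str, float]:
    """Median +/- MAD of a distribution and of its offset from a null.

    The offset series ``dist - median(null)`` mirrors how differences
    between observed cross-modal correlations and their null distributions
    are reported (median +/- median absolute deviation).
    """
    if dist.n_iterations == 0:
        raise ValueError("empty distribution")
    out = {"median": dist.median, "mad": dist.mad}
    if null is not None:
        offset = CorrelationDistribution(dist.values - null.median)
        out["median_offset"] = offset.median
        out["mad_offset"] = offset.mad
    return out
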