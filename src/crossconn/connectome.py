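"""ROI-pair connectome assembly from multi-subject channel contributions.

A connectome edge between two regions of interest (ROIs) exists when at
least one same-subject pair of channels connects them; within-ROI pairs and
cross-subject pairs never contribute.  Every contributing channel-pair value
is averaged flat — irrespective of which subject supplied it — into a single
value per ROI pair.  Entries carry contribution metadata (channel pairs,
distinct subjects) plus hemispheric, depth (eccentricity) and distance
stratification labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .spectral import BandSpec

__all__ = [
    "CHANNEL_TABLE_COLUMNS",
    "ChannelPair",
    "ROIPairEntry",
    "Connectome",
    "enumerate_channel_pairs",
    "assemble_connectome",
    "filter_min_subjects",
    "classify_hemisphere",
    "eccentricity",
    "classify_depth",
    "roi_pair_distance",
    "connectome_to_frame",
]

#: Exact channel-table header (TSV), column order not significant.
CHANNEL_TABLE_COLUMNS = (
    "subject_id", "channel_id", "x_mm", "y_mm", "z_mm",
    "roi_id", "roi_name", "hemisphere",
)

#: Eccentricity threshold (mm) splitting superficial from deep channels.
DEFAULT_ECCENTRICITY_MM = 85.0


class ChannelPair(NamedTuple):
    """A same-subject, cross-ROI channel pairing; ``roi_a < roi_b``."""

    subject_id: str
    ch_a: str
    ch_b: str
    roi_a: int
    roi_b: int

    @property
    def roi_key(self) -> tuple[int, int]:
        return (self.roi_a, self.roi_b)

    @property
    def channel_key(self) -> tuple[str, str]:
        return (self.ch_a, self.ch_b)


@dataclass
class ROIPairEntry:
    """One connectome edge with its contribution metadata."""

    roi_a: int
    roi_b: int
    channel_pairs: list[ChannelPair]
    contributing_subjects: int
    value: float
    n_missing: int = 0
    distance: float = float("nan")
    depth_class: str = ""
    hemi_class: str = ""

    @property
    def n_channel_pairs(self) -> int:
        return len(self.channel_pairs)


@dataclass
class Connectome:
    """Map from (roi_a, roi_b) to an averaged connectivity entry.

    ``n_possible`` is the declared universe of ROI pairs used as the
    coverage denominator; it is taken from the input data's ROI table (or
    given explicitly) rather than hard-coded.
    """

    metric: str
    band: BandSpec | None
    entries: dict[tuple[int, int], ROIPairEntry]
    n_possible: int

    @property
    def coverage(self) -> float:
        return len(self.entries) / self.n_possible

    @property
    def coverage_percent(self) -> int:
        """Coverage as a whole-number percentage (rounded for reporting)."""
        return round(100.0 * self.coverage)

    def values(self) -> dict[tuple[int, int], float]:
        """Plain {roi_pair: value} view used by the resampling machinery."""
        return {k: e.value for k, e in self.entries.items()}


def _validate_channel_table(channels: pd.DataFrame,
                            roi_ids: Iterable[int] | None) -> None:
    missing = set(CHANNEL_TABLE_COLUMNS) - set(channels.columns)
    if missing:
        raise ValueError(f"channel table missing columns: {sorted(missing)}")
    if roi_ids is not None:
        known = set(int(r) for r in roi_ids)
        unknown = set(channels["roi_id"].astype(int)) - known
        if unknown:
            raise ValueError(f"unknown ROI ids in channel table: "
                             f"{sorted(unknown)}")


def enumerate_channel_pairs(
    channels: pd.DataFrame,
    roi_ids: Iterable[int] | None = None,
) -> list[ChannelPair]:
    """All same-subject, cross-ROI channel pairs of a channel table.

    Within-ROI pairs are discarded (local connections) and channels from
    different subjects are never paired — connectivity cannot be computed
    across subjects.  ``roi_ids``, when given, is the known ROI universe
    used for validation.
    """
    _validate_channel_table(channels, roi_ids)
    pairs: list[ChannelPair] = []
    for subject, grp in channels.groupby("subject_id", sort=True):
        recs = list(grp[["channel_id", "roi_id"]].itertuples(index=False))
        for (ch1, r1), (ch2, r2) in itertools.combinations(recs, 2):
            r1, r2 = int(r1), int(r2)
            if r1 == r2:
                continue
            if r1 > r2:
                (ch1, r1), (ch2, r2) = (ch2, r2), (ch1, r1)
            pairs.append(ChannelPair(str(subject), str(ch1), str(ch2), r1, r2))
    return pairs


def assemble_connectome(
    pairs: Sequence[ChannelPair],
    values: Mapping[tuple[str, str, str], float],
    metric: str,
    band: BandSpec | None = None,
    n_possible: int | None = None,
) -> Connectome:
    """Average channel-pair metric values into one value per ROI pair.

    ``values`` maps ``(subject_id, ch_a, ch_b)`` to a metric value; NaN
    marks a degenerate (missing) pair, excluded from the average with a
    count kept.  The entry value is the flat mean over all non-missing
    channel pairs regardless of subject grouping — a mean of per-subject
    means is deliberately NOT used.  ROI pairs whose values are all missing
    are dropped.  ``n_possible`` defaults to C(n_rois, 2) over the ROIs seen
    in ``pairs``.
    """
    grouped: dict[tuple[int, int], list[ChannelPair]] = {}
    for p in pairs:
        grouped.setdefault(p.roi_key, []).append(p)

    if n_possible is None:
        rois = {p.roi_a for p in pairs} | {p.roi_b for p in pairs}
        n_possible = len(rois) * (len(rois) - 1) // 2 if len(rois) > 1 else 1

    entries: dict[tuple[int, int], ROIPairEntry] = {}
    for key in sorted(grouped):
        members = grouped[key]
        vals, missing = [], 0
        for p in members:
            try:
                v = values[(p.subject_id, p.ch_a, p.ch_b)]
            except KeyError as exc:
                raise KeyError(
                    f"no metric value for channel pair {p}") from exc
            if v is None or np.isnan(v):
                missing += 1
            else:
                vals.append(float(v))
        if not vals:
            continue  # every contribution degenerate: drop the pair
        subjects = {p.subject_id for p in members}
        entries[key] = ROIPairEntry(
            roi_a=key[0], roi_b=key[1], channel_pairs=members,
            contributing_subjects=len(subjects),
            value=float(np.mean(vals)), n_missing=missing,
        )
    return Connectome(metric=metric, band=band, entries=entries,
                      n_possible=int(n_possible))


def filter_min_subjects(c: Connectome, k: int) -> Connectome:
    """Retain ROI pairs contributed by at least ``k`` distinct subjects.

    Raising ``k`` trades connectome coverage for per-edge averaging depth;
    coverage is recomputed against the same declared universe.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    kept = {key: e for key, e in c.entries.items()
            if e.contributing_subjects >= k}
    return Connectome(metric=c.metric, band=c.band, entries=kept,
                      n_possible=c.n_possible)


def classify_hemisphere(hemi_a: str, hemi_b: str) -> str:
    """``intra-L`` / ``intra-R`` when both ROIs share a hemisphere, else
    ``inter``."""
    if hemi_a == hemi_b == "L":
        return "intra-L"
    if hemi_a == hemi_b == "R":
        return "intra-R"
    return "inter"


def eccentricity(position: Sequence[float],
                 center: Sequence[float] = (0.0, 0.0, 0.0)) -> float:
    """Euclidean distance (mm) of a channel position from the head center.

    Deep channels have low eccentricity, superficial channels high.  The
    head center defaults to the origin of the MNI frame.
    """
    return float(np.linalg.norm(np.asarray(position, float)
                                - np.asarray(center, float)))


def _member_positions(entry: ROIPairEntry, channels: pd.DataFrame,
                      roi: int) -> np.ndarray:
    chans = {p.ch_a if p.roi_a == roi else p.ch_b
             for p in entry.channel_pairs}
    sel = channels[channels["channel_id"].isin(chans)
                   & (channels["roi_id"].astype(int) == roi)]
    return sel[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)


def classify_depth(
    entry: ROIPairEntry,
    channels: pd.DataFrame,
    threshold: float = DEFAULT_ECCENTRICITY_MM,
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> str:
    """``superficial`` if every member channel lies beyond ``threshold`` mm
    from the head center, ``deep`` if every one lies within, else ``mixed``.

    Mixed pairs (and channels exactly on the boundary, which satisfy
    neither strict inequality) are excluded from the two-group superficial
    versus deep comparison.
    """
    pos = np.vstack([_member_positions(entry, channels, entry.roi_a),
                     _member_positions(entry, channels, entry.roi_b)])
    ecc = np.linalg.norm(pos - np.asarray(center, float), axis=1)
    if np.all(ecc > threshold):
        return "superficial"
    if np.all(ecc < threshold):
        return "deep"
    return "mixed"


def roi_pair_distance(
    entry: ROIPairEntry,
    channels: pd.DataFrame,
    method: str = "centroid",
) -> float:
    """Distance (mm) between the two ROIs of an entry.

    ``"centroid"`` (default): Euclidean distance between the centroids of
    the member channels' positions per ROI — stable under varying channel
    counts.  ``"mean_pairwise"``: mean distance over the entry's channel
    pairs, kept as an alternative definition.
    """
    pos_a = _member_positions(entry, channels, entry.roi_a)
    pos_b = _member_positions(entry, channels, entry.roi_b)
    if method == "centroid":
        return float(np.linalg.norm(pos_a.mean(axis=0) - pos_b.mean(axis=0)))
    if method == "mean_pairwise":
        by_id_a = {str(r.channel_id): np.array([r.x_mm, r.y_mm, r.z_mm])
                   for r in channels.itertuples()
                   if int(r.roi_id) == entry.roi_a}
        by_id_b = {str(r.channel_id): np.array([r.x_mm, r.y_mm, r.z_mm])
                   for r in channels.itertuples()
                   if int(r.roi_id) == entry.roi_b}
        dists = [np.linalg.norm(by_id_a[p.ch_a] - by_id_b[p.ch_b])
                 for p in entry.channel_pairs]
        return float(np.mean(dists))
    raise ValueError(f"unknown distance method {method!r}")


def annotate(
    c: Connectome,
    channels: pd.DataFrame,
    eccentricity_threshold: float = DEFAULT_ECCENTRICITY_MM,
    head_center: Sequence[float] = (0.0, 0.0, 0.0),
    distance_method: str = "centroid",
) -> Connectome:
    """Fill distance, depth and hemisphere labels on every entry in place."""
    dedup = channels.drop_duplicates("roi_id")
    hemi_of = dict(zip(dedup["roi_id"].astype(int), dedup["hemisphere"]))
    for entry in c.entries.values():
        entry.distance = roi_pair_distance(entry, channels, distance_method)
        entry.depth_class = classify_depth(entry, channels,
                                           eccentricity_threshold,
                                           head_center)
        entry.hemi_class = classify_hemisphere(hemi_of[entry.roi_a],
                                               hemi_of[entry.roi_b])
    return c


def connectome_to_frame(c: Connectome) -> pd.DataFrame:
    """Long-format table of a connectome (one row per ROI pair)."""
    rows = []
    for (a, b), e in sorted(c.entries.items()):
        rows.append({
            "roi_a": a, "roi_b": b, "metric": c.metric,
            "band": c.band.name if c.band is not None else "",
            "value": e.value, "n_channel_pairs": e.n_channel_pairs,
            "n_subjects": e.contributing_subjects,
            "distance_mm": e.distance, "hemi_class": e.hemi_class,
            "depth_class": e.depth_class,
        })
    return pd.DataFrame(rows, columns=[
        "roi_a", "roi_b", "metric", "band", "value", "n_channel_pairs",
        "n_subjects", "distance_mm", "hemi_class", "depth_class"])
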