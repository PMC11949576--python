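"""End-to-end orchestration of the cross-modal validation analysis.

``run_validation`` executes, for every configured metric x band cell:
spectral decomposition -> channel-pair metrics -> reference connectome
assembly -> contribution-template extraction -> bootstrap distribution ->
spatial-permutation null -> ROPE test, then repeats the inference on
hemispheric (intra-L / intra-R / inter), depth (superficial / deep) and
minimum-subject strata.  Cells are computed with per-cell derived seeds so
results are invariant to execution order, and the report is a plain dict
(JSON-serializable) with a flat CSV twin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .spectral import BandSpec, band_by_name, bandpass_analytic
from .metrics import METRICS, compute_metric_analytic
from .connectome import (Connectome, annotate, assemble_connectome,
                         enumerate_channel_pairs, filter_min_subjects)
from .resampling import (bootstrap_distribution, cross_modal_correlation,
                         extract_template, rope_test,
                         spatial_permutation_null,
                         CorrelationDistribution)
from .synthetic import Cohort, SyntheticConfig, generate_twin_cohorts
from .io import read_channel_table, read_signals_h5

__all__ = ["RunConfig", "run_validation", "report_to_frame"]


@dataclass
class RunConfig:
    """Analysis-matrix configuration.

    Either ``synthetic`` is set (twin cohorts are generated) or the four
    input paths point at TSV channel tables and HDF5 signal containers for
    the reference and test cohorts.
    """

    bands: tuple[str, ...] = ("alpha",)
    metrics: tuple[str, ...] = METRICS
    epoch_length: float = 6.0
    n_bootstrap: int = 5000
    n_permutation: int = 5000
    rope_coverage: float = 0.95
    significance_threshold: float = 0.025
    min_subjects_sweep: tuple[int, ...] = (1, 2, 3, 4, 5)
    eccentricity_threshold: float = 85.0
    head_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    edge_discard_s: float = 1.0
    oaec_absolute: bool = False  # rectify OAEC correlations if True
    distance_method: str = "centroid"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    reference_channels_path: str | None = None
    reference_signals_path: str | None = None
    test_channels_path: str | None = None
    test_signals_path: str | None = None

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        if not 0.0 < self.significance_threshold < 0.5:
            raise ValueError("significance_threshold must be in (0, 0.5)")
        for count in (self.n_bootstrap, self.n_permutation):
            if count < 1:
                raise ValueError("iteration counts must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        return cfg

    def band_specs(self) -> list[BandSpec]:
        return [band_by_name(b) if isinstance(b, str) else b
                for b in self.bands]


def _load_cohorts(config: RunConfig) -> tuple[Cohort, Cohort]:
    if config.synthetic is not None:
        ref, test, _ = generate_twin_cohorts(config.synthetic)
        return ref, test
    paths = (config.reference_channels_path, config.reference_signals_path,
             config.test_channels_path, config.test_signals_path)
    if any(p is None for p in paths):
        raise ValueError("RunConfig needs either a synthetic block or all "
                         "four input paths")
    rc = read_channel_table(paths[0])
    rs, rids, rfs = read_signals_h5(paths[1])
    tc = read_channel_table(paths[2])
    ts, tids, tfs = read_signals_h5(paths[3])
    if rfs != tfs:
        raise ValueError("cohorts have different sampling rates")
    return (Cohort("reference", rc, rs, rids, rfs),
            Cohort("test", tc, ts, tids, tfs))


def _decompose(cohort: Cohort, band: BandSpec
               ) -> dict[str, dict[str, np.ndarray]]:
    """subject -> channel_id -> complex analytic row, for one band."""
    out: dict[str, dict[str, np.ndarray]] = {}
    for subj, arr in cohort.signals.items():
        a = bandpass_analytic(arr, band, cohort.fs)
        out[subj] = {cid: a.values[i]
                     for i, cid in enumerate(cohort.channel_ids[subj])}
    return out


def _pair_metric(metric: str, band: BandSpec, fs: float,
                 va: np.ndarray, vb: np.ndarray, config: RunConfig) -> float:
    from .spectral import AnalyticSignal
    x = AnalyticSignal(band, fs, va)
    y = AnalyticSignal(band, fs, vb)
    mv = compute_metric_analytic(metric, x, y, config.epoch_length,
                                 config.edge_discard_s)
    if metric == "OAEC" and config.oaec_absolute and not mv.missing:
        return abs(mv.value)
    return mv.value


def _stratum_rope(
    ref_values: Mapping[tuple[int, int], float],
    boots: Sequence[Mapping[tuple[int, int], float]],
    keys: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    config: RunConfig,
) -> dict:
    """ROPE inference restricted to a subset of ROI-pair keys.

    The same bootstrapped connectomes are reused; both the actual and the
    paired permutation-null correlations run over ``keys`` only.
    """
    keys = sorted(keys)
    if len(keys) < 3:
        return {"skipped": f"only {len(keys)} ROI pairs in stratum"}
    sub_ref = {k: ref_values[k] for k in keys}
    sub_boots = [{k: b[k] for k in keys} for b in boots]
    try:
        actual = CorrelationDistribution(np.array(
            [cross_modal_correlation(sub_ref, b) for b in sub_boots]))
        null = spatial_permutation_null(sub_boots[:config.n_permutation],
                                        sub_ref, rng)
    except ValueError as exc:
        return {"skipped": str(exc)}
    res = rope_test(actual, null, config.rope_coverage,
                    config.significance_threshold)
    return {
        "median": res.median, "mad": res.mad,
        "median_offset": res.median_offset, "mad_offset": res.mad_offset,
        "null_range": list(res.null_range),
        "overlap_fraction": res.overlap_fraction,
        "significant": res.significant,
        "n_roi_pairs": len(keys),
        "n_iterations": len(sub_boots),
    }


def run_validation(config: RunConfig) -> dict:
    """Run the full analysis matrix and return the report dict.

    The report carries one cell per metric x band x stratum (each with
    median/MAD, null range, overlap fraction and significance flag), the
    minimum-subject coverage sweep, distance summaries and provenance;
    every configured cell is present or explicitly marked skipped.
    """
    reference, test = _load_cohorts(config)
    ref_pairs = enumerate_channel_pairs(reference.channels)
    if not ref_pairs:
        raise ValueError("reference cohort yields no cross-ROI channel pairs")
    template = extract_template(ref_pairs)
    template_cps = sorted({cp for slots in template.slots.values()
                           for _, cps in slots for cp in cps})
    rois = sorted(set(reference.channels["roi_id"].astype(int)))
    n_possible = len(rois) * (len(rois) - 1) // 2
    test_subjects = sorted(test.signals)

    report: dict = {
        "cells": {}, "min_subjects": {}, "summaries": {},
        "provenance": {
            "package_version": __version__,
            "seed": config.seed,
            "n_bootstrap": config.n_bootstrap,
            "n_permutation": config.n_permutation,
            "rope_coverage": config.rope_coverage,
            "significance_threshold": config.significance_threshold,
            "edge_discard_s": config.edge_discard_s,
            "oaec_absolute": config.oaec_absolute,
            "distance_method": config.distance_method,
            "quantile_rule": "equal-tailed empirical quantiles, linear "
                             "interpolation",
            "n_reference_subjects": len(reference.signals),
            "n_test_subjects": len(test_subjects),
            "n_possible_roi_pairs": n_possible,
        },
    }

    for bi, band in enumerate(config.band_specs()):
        ref_an = _decompose(reference, band)
        test_an = _decompose(test, band)
        report["cells"][band.name] = {}
        report["min_subjects"][band.name] = {}
        report["summaries"][band.name] = {}
        connectomes: dict[str, Connectome] = {}
        test_mean_values: dict[str, dict] = {}

        for mi, metric in enumerate(config.metrics):
            rng = np.random.default_rng(
                np.random.SeedSequence((config.seed, bi, mi)))

            ref_values = {
                (p.subject_id, p.ch_a, p.ch_b): _pair_metric(
                    metric, band, reference.fs,
                    ref_an[p.subject_id][p.ch_a],
                    ref_an[p.subject_id][p.ch_b], config)
                for p in ref_pairs
            }
            ref_conn = assemble_connectome(ref_pairs, ref_values, metric,
                                           band, n_possible)
            annotate(ref_conn, reference.channels,
                     config.eccentricity_threshold, config.head_center,
                     config.distance_method)
            connectomes[metric] = ref_conn

            test_values = {
                subj: {cp: _pair_metric(metric, band, test.fs,
                                        test_an[subj][cp[0]],
                                        test_an[subj][cp[1]], config)
                       for cp in template_cps}
                for subj in test_subjects
            }
            test_mean_values[metric] = {
                k: float(np.nanmean([
                    np.nanmean([test_values[s][p.channel_key]
                                for s in test_subjects])
                    for p in e.channel_pairs]))
                for k, e in ref_conn.entries.items()
            }

            ref_vals = ref_conn.values()
            actual, boots = bootstrap_distribution(
                template, test_values, ref_vals,
                n=config.n_bootstrap, rng=rng, return_connectomes=True)
            null = spatial_permutation_null(
                boots[:config.n_permutation], ref_vals, rng)
            res = rope_test(actual, null, config.rope_coverage,
                            config.significance_threshold)
            cell: dict = {
                "all": {
                    "median": res.median, "mad": res.mad,
                    "median_offset": res.median_offset,
                    "mad_offset": res.mad_offset,
                    "null_range": list(res.null_range),
                    "overlap_fraction": res.overlap_fraction,
                    "significant": res.significant,
                    "n_roi_pairs": len(ref_vals),
                    "n_iterations": actual.n_iterations,
                    "coverage_percent": ref_conn.coverage_percent,
                },
            }
            by_hemi: dict[str, list] = {"intra-L": [], "intra-R": [],
                                        "inter": []}
            by_depth: dict[str, list] = {"superficial": [], "deep": []}
            for k, e in ref_conn.entries.items():
                by_hemi[e.hemi_class].append(k)
                if e.depth_class in by_depth:
                    by_depth[e.depth_class].append(k)
            for name, keys in {**by_hemi, **by_depth}.items():
                cell[name] = _stratum_rope(ref_vals, boots, keys, rng,
                                           config)
            report["cells"][band.name][metric] = cell

            sweep = {}
            for k in config.min_subjects_sweep:
                filtered = filter_min_subjects(ref_conn, k)
                entry = _stratum_rope(ref_vals, boots,
                                      list(filtered.entries), rng, config)
                entry["coverage_percent"] = filtered.coverage_percent
                entry["n_roi_pairs_retained"] = len(filtered.entries)
                sweep[str(k)] = entry
            report["min_subjects"][band.name][metric] = sweep

            dists = np.array([e.distance
                              for e in ref_conn.entries.values()])
            vals = np.array([e.value for e in ref_conn.entries.values()])
            ok = np.isfinite(dists) & np.isfinite(vals)
            r = (float(np.corrcoef(dists[ok], vals[ok])[0, 1])
                 if ok.sum() >= 3 and vals[ok].std() > 0 else float("nan"))
            report["summaries"][band.name][metric] = {
                "reference_mean": float(np.mean(vals)),
                "test_mean": float(np.mean(
                    list(test_mean_values[metric].values()))),
                "value_vs_distance_r": r,
            }

        if {"AEC", "OAEC"} <= set(config.metrics):
            a = connectomes["AEC"].values()
            o = connectomes["OAEC"].values()
            shared = sorted(set(a) & set(o))
            ta = test_mean_values["AEC"]
            to = test_mean_values["OAEC"]
            shared_t = sorted(set(ta) & set(to))
            report["summaries"][band.name]["oaec_minus_aec"] = {
                "reference": float(np.mean([o[k] - a[k] for k in shared])),
                "test": float(np.mean([to[k] - ta[k] for k in shared_t])),
            }
    return report


def report_to_frame(report: dict) -> pd.DataFrame:
    """Flat CSV twin of the per-cell inference results."""
    rows = []
    for band, metrics in report["cells"].items():
        for metric, strata in metrics.items():
            for stratum, cell in strata.items():
                row = {"band": band, "metric": metric, "stratum": stratum}
                if "skipped" in cell:
                    row["skipped"] = cell["skipped"]
                else:
                    row.update({k: v for k, v in cell.items()
                                if not isinstance(v, (list, dict))})
                rows.append(row)
    return pd.DataFrame(rows)
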