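"""One-call orchestration of the full analysis, in the reporting order:
whole-phase condition contrasts, block-wise progressions, group changepoint
analysis per phase, per-participant changepoints, and the six-correlation
individual-differences suite — emitted as one deterministic JSON-ready
report bundle plus CSV tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .association import run_correlation_suite
from .changepoint import (
    GROUP_MEAN,
    find_changepoints,
    individual_changepoints,
    ownership_effect,
    rate_of_change_report,
    result_landmarks,
    smooth_moving_average,
)
from .data_model import (
    PHASES,
    POST,
    RH_ASYNC,
    RH_SYNC,
    STIM,
    WOOD_ASYNC,
    WOOD_SYNC,
    StudyDataset,
    describe,
    exclude_nonresponders,
    mask_dataset_post_gap,
    phase_average,
    proprioceptive_drift,
    score_questionnaire,
    default_component_map,
)
from .estimation import AUTO, DEFAULT_LABEL_THRESHOLDS, compare_conditions

log = logging.getLogger("ownflow.pipeline")

CONTRASTS = [(RH_SYNC, RH_ASYNC), (WOOD_SYNC, WOOD_ASYNC)]


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis knobs; echoed into every report for provenance."""

    gap_s: int = 10
    window_s: int = 5
    k: int = 2
    min_segment_length: int = 3
    n_boot: int = 5000
    level: float = 95.0
    seed: int = 0
    statistic: str = AUTO
    bonferroni_m: int = 6
    label_thresholds: tuple = DEFAULT_LABEL_THRESHOLDS
    smooth_individual: bool = True

    def __post_init__(self) -> None:
        if self.gap_s < 0:
            raise ValueError("gap_s must be >= 0")
        if self.window_s < 1 or self.window_s % 2 == 0:
            raise ValueError("window_s must be odd and >= 1")
        if self.k not in (1, 2):
            raise ValueError("k must be 1 or 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if not (0 < self.level < 100):
            raise ValueError("level must lie in (0, 100)")
        if self.bonferroni_m < 1:
            raise ValueError("bonferroni_m must be >= 1")


def run_full_analysis(dataset: StudyDataset, config: AnalysisConfig | None = None) -> dict:
    """Run every stage on an already-ingested dataset; returns the report bundle."""
    cfg = config or AnalysisConfig()

    dataset, excluded = exclude_nonresponders(dataset)
    log.info("stage=exclusion excluded=%d retained=%d", len(excluded),
             len(dataset.participants()))
    dataset = mask_dataset_post_gap(dataset, cfg.gap_s)
    log.info("stage=masking gap_s=%d", cfg.gap_s)

    report: dict = {
        "config": _jsonable(asdict(cfg)),
        "version": __version__,
        "exclusions": {
            "excluded_ids": excluded,
            "n_excluded": len(excluded),
            "n_retained": len(dataset.participants()),
        },
    }

    # whole-phase and block-wise condition contrasts
    contrasts_out = []
    blocks_out = []
    for pi, phase in enumerate(PHASES):
        contrasts_out += compare_conditions(
            dataset, phase, CONTRASTS, "phase_average",
            statistic=cfg.statistic, n_boot=cfg.n_boot, level=cfg.level,
            seed=cfg.seed + 10_000 * pi, thresholds=cfg.label_thresholds,
        )
        blocks_out += compare_conditions(
            dataset, phase, CONTRASTS, "block_average",
            statistic=cfg.statistic, n_boot=cfg.n_boot, level=cfg.level,
            seed=cfg.seed + 10_000 * pi + 5_000, thresholds=cfg.label_thresholds,
        )
    report["whole_phase_contrasts"] = [_jsonable(asdict(e)) for e in contrasts_out]
    report["block_contrasts"] = [_jsonable(asdict(e)) for e in blocks_out]
    log.info("stage=contrasts whole_phase=%d blocks=%d",
             len(contrasts_out), len(blocks_out))

    # group changepoints per phase, with landmark rate-of-change tables
    group_cp = {}
    for phase in PHASES:
        eff = ownership_effect(dataset, GROUP_MEAN, phase)
        eff = smooth_moving_average(eff, cfg.window_s)
        res = find_changepoints(eff, cfg.k, cfg.min_segment_length)
        landmarks = result_landmarks(eff, res)
        group_cp[phase] = {
            "changepoint_times": res.changepoint_times,
            "total_sse": res.total_sse,
            "k": res.k_requested,
            "segments": [_jsonable(asdict(s)) for s in res.segments],
            "landmarks": [list(p) for p in landmarks],
            "rate_of_change": rate_of_change_report(landmarks),
        }
        log.info("stage=group_changepoints phase=%s times=%s",
                 phase, res.changepoint_times)
    report["group_changepoints"] = group_cp

    # per-participant changepoints
    indiv = {}
    for phase in PHASES:
        results = individual_changepoints(
            dataset, phase, cfg.k, cfg.min_segment_length,
            smooth=cfg.smooth_individual, window_s=cfg.window_s,
        )
        indiv[phase] = results
        report.setdefault("individual_changepoints", {})[phase] = {
            pid: (None if r is None else {
                "changepoint_times": r.changepoint_times,
                "total_sse": r.total_sse,
            })
            for pid, r in results.items()
        }
        n_none = sum(1 for r in results.values() if r is None)
        log.info("stage=individual_changepoints phase=%s stationary=%d",
                 phase, n_none)

    # correlation suite
    correlations = run_correlation_suite(
        dataset, indiv[STIM], indiv[POST],
        n_boot=cfg.n_boot, level=cfg.level, seed=cfg.seed + 50_000,
        m=cfg.bonferroni_m,
    )
    report["correlations"] = [_jsonable(asdict(c)) for c in correlations]
    log.info("stage=correlations n=%d", len(correlations))

    # classical-measure summaries
    drift_summary = {}
    quest_summary = {}
    cmap = default_component_map()
    for cond in (RH_SYNC, RH_ASYNC, WOOD_SYNC, WOOD_ASYNC):
        drifts = [
            proprioceptive_drift(j) for j in dataset.judgments if j.condition == cond
        ]
        if drifts:
            drift_summary[cond] = _jsonable(asdict(describe(drifts)))
        scores = [
            score_questionnaire(q, cmap)
            for q in dataset.questionnaires
            if q.condition == cond
        ]
        if scores:
            quest_summary[cond] = {
                comp: _jsonable(asdict(describe([s[comp] for s in scores])))
                for comp in sorted(scores[0])
            }
    report["proprioceptive_drift"] = drift_summary
    report["questionnaire_scores"] = quest_summary

    # whole-phase descriptives per condition
    report["condition_summaries"] = {
        phase: {
            cond: _jsonable(asdict(describe([
                phase_average(dataset.get(pid, cond), phase)
                for pid in dataset.participants()
            ])))
            for cond in (RH_SYNC, RH_ASYNC, WOOD_SYNC, WOOD_ASYNC)
        }
        for phase in PHASES
    }
    return report


def report_to_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a report bundle."""
    return json.dumps(report, indent=1, sort_keys=True, allow_nan=True)


def write_report(report: dict, out_dir) -> None:
    """Write the JSON bundle and the CSV tables mirroring the report."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_to_json(report))

    rows = []
    for e in report["whole_phase_contrasts"] + report["block_contrasts"]:
        rows.append(
            {
                "contrast": e["contrast"],
                "block": e["block"],
                "statistic": e["statistic"],
                "point": e["point"],
                "ci_low": e["ci_low"],
                "ci_high": e["ci_high"],
                "label": e["label"],
                "n": e["n_pairs"],
                "median_a": e["summary_a"]["median"],
                "iqr_a": e["summary_a"]["iqr"],
                "median_b": e["summary_b"]["median"],
                "iqr_b": e["summary_b"]["iqr"],
            }
        )
    pd.DataFrame(rows).to_csv(out / "contrasts.csv", index=False)

    rows = []
    for phase, per_pid in report["individual_changepoints"].items():
        for pid, rec in sorted(per_pid.items()):
            if rec is None:
                continue
            for i, t in enumerate(rec["changepoint_times"]):
                rows.append(
                    {
                        "participant_id": pid,
                        "phase": phase,
                        "cp_index": i,
                        "cp_time_s": t,
                        "total_sse": rec["total_sse"],
                    }
                )
    pd.DataFrame(rows).to_csv(out / "individual_changepoints.csv", index=False)

    rows = []
    for c in report["correlations"]:
        rows.append(
            {
                "correlation": c["name"],
                "n": c["n_after_outliers"],
                "rho": c["rho"],
                "ci_low": c["ci_low"],
                "ci_high": c["ci_high"],
                "p_uncorrected": c["p_uncorrected"],
                "p_corrected": c["p_corrected"],
                "outliers_removed": len(c["outlier_ids"]),
            }
        )
    pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)


def checksum_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    """Recursively coerce numpy scalars/arrays and tuples for JSON export."""
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj
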