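"""Individual-differences layer: outlier filtering, Spearman correlations with
BCa bootstrap intervals, and family-wise Bonferroni reporting.

Each correlation is preceded by a boxplot-style interquartile outlier filter
applied independently per correlation; a pair is removed when either of its
two values lies outside its own variable's 1.5*IQR fences. Bonferroni
correction multiplies the uncorrected p by the family size and is UNCAPPED
by default (corrected values above 1 are reported as-is); a cap-at-1 option
exists for conventional reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .data_model import (
    RH_SYNC,
    STIM,
    DescriptiveSummary,
    StudyDataset,
    default_component_map,
    describe,
    phase_average,
    proprioceptive_drift,
    score_questionnaire,
    window_average,
)
from .changepoint import INDIVIDUAL, onset_changepoint, ownership_effect
from .estimation import bca_ci


@dataclass(frozen=True)
class CorrelationResult:
    name: str
    n_after_outliers: int
    rho: float
    ci_low: float
    ci_high: float
    p_uncorrected: float
    p_corrected: float | None
    m_comparisons: int | None
    outlier_ids: list
    summary_x: DescriptiveSummary | None
    summary_y: DescriptiveSummary | None
    computable: bool = True
    reason: str = ""


def iqr_outlier_filter(x, y, ids=None):
    """Boxplot-criterion pair filter.

    A pair is dropped when its x OR its y lies outside
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR] of that variable, with quartiles computed
    once on the full sample (no re-iteration). Returns
    ``(x_kept, y_kept, ids_kept, outlier_ids)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be the same length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if ids is None:
        ids = list(range(x.size))
    keep = _inside_fences(x) & _inside_fences(y)
    outliers = [ids[i] for i in range(x.size) if not keep[i]]
    kept_ids = [ids[i] for i in range(x.size) if keep[i]]
    return x[keep], y[keep], kept_ids, outliers


def _inside_fences(v: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)


def spearman_bca(
    x,
    y,
    name: str = "",
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rho (average ranks) with two-sided p and a BCa CI from
    resampling pairs jointly. Outlier filtering must already be applied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined: zero variance in one variable")
    res = sps.spearmanr(x, y)
    rho, p = float(res.statistic), float(res.pvalue)

    pair_idx = np.arange(x.size)

    def stat(idx, axis=None):
        idx = np.asarray(idx, dtype=int)
        if axis is None:
            return _safe_spearman(x[idx], y[idx], rho)
        return np.array([_safe_spearman(x[row], y[row], rho) for row in idx])

    ci_low, ci_high = bca_ci(pair_idx, stat, n_boot, level, seed)
    return CorrelationResult(
        name=name,
        n_after_outliers=int(x.size),
        rho=rho,
        ci_low=ci_low,
        ci_high=ci_high,
        p_uncorrected=p,
        p_corrected=None,
        m_comparisons=None,
        outlier_ids=[],
        summary_x=describe(x),
        summary_y=describe(y),
    )


def _safe_spearman(xs, ys, fallback: float) -> float:
    # a bootstrap resample can be degenerate (all-tied variable); score it at
    # the observed rho so it neither drags the distribution nor crashes
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return fallback
    return float(sps.spearmanr(xs, ys).statistic)


def bonferroni_adjust(results, m: int, cap: bool = False) -> list:
    """Set ``p_corrected = m * p_uncorrected`` on each result (uncapped by
    default; ``cap=True`` clips at 1)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    n_real = sum(1 for r in results if r.computable)
    if m < n_real:
        raise ValueError(f"family size {m} smaller than number of results {n_real}")
    out = []
    for r in results:
        if not r.computable:
            out.append(replace(r, m_comparisons=m))
            continue
        p = m * r.p_uncorrected
        if cap:
            p = min(p, 1.0)
        out.append(replace(r, p_corrected=p, m_comparisons=m))
    return out


def correlate_with_outlier_filter(
    x,
    y,
    ids,
    name: str,
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
) -> CorrelationResult:
    """IQR-filter the pairs, then Spearman+BCa; not-computable below n=4."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        return _not_computable(name, f"only {x.size} usable pairs")
    xk, yk, _, outliers = iqr_outlier_filter(x, y, ids)
    if xk.size < 4:
        return _not_computable(name, f"only {xk.size} pairs after outlier removal")
    if np.ptp(xk) == 0 or np.ptp(yk) == 0:
        return _not_computable(name, "zero variance after outlier removal")
    res = spearman_bca(xk, yk, name, n_boot, level, seed)
    return replace(res, outlier_ids=outliers)


def _not_computable(name: str, reason: str) -> CorrelationResult:
    return CorrelationResult(
        name=name,
        n_after_outliers=0,
        rho=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_uncorrected=float("nan"),
        p_corrected=None,
        m_comparisons=None,
        outlier_ids=[],
        summary_x=None,
        summary_y=None,
        computable=False,
        reason=reason,
    )


def run_correlation_suite(
    dataset: StudyDataset,
    onset_results: dict,
    fading_results: dict,
    component_map=None,
    questionnaire_component: str = "embodiment",
    potentiometer_component: str = "ownership",
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
    m: int = 6,
    cap: bool = False,
) -> list:
    """The study's six-correlation family.

    1. onset changepoint vs fading changepoint
    2. onset changepoint vs stimulation-phase mean ownership effect
    3. onset changepoint vs questionnaire score (embodiment by default)
    4. onset changepoint vs proprioceptive drift
    5. whole-stimulation rh_sync rating vs questionnaire ownership
    6. last-30-s (90-120 s) rh_sync rating vs questionnaire ownership

    Participants without a changepoint (stationary signals) are dropped
    before outlier filtering; outlier filtering is independent per
    correlation; the family-wise Bonferroni factor is ``m``.
    """
    cmap = component_map or default_component_map()
    pids = dataset.participants()

    onset = {p: onset_changepoint(onset_results.get(p)) for p in pids}
    fading = {p: onset_changepoint(fading_results.get(p)) for p in pids}

    def paired(values_a: dict, values_b: dict):
        common = [
            p
            for p in pids
            if values_a.get(p) is not None and values_b.get(p) is not None
        ]
        return (
            np.array([values_a[p] for p in common], dtype=float),
            np.array([values_b[p] for p in common], dtype=float),
            common,
        )

    mean_effect = {}
    for p in pids:
        eff = ownership_effect(dataset, INDIVIDUAL, STIM, participant_id=p)
        mean_effect[p] = float(eff.values.mean())

    quest_scores: dict = {}
    for p in pids:
        resp = dataset.questionnaire(p, RH_SYNC)
        quest_scores[p] = score_questionnaire(resp, cmap) if resp else None

    def quest(p: str, component: str):
        s = quest_scores.get(p)
        return None if s is None else s.get(component)

    drifts = {}
    for p in pids:
        j = dataset.judgment(p, RH_SYNC)
        drifts[p] = proprioceptive_drift(j) if j else None

    stim_rating = {p: phase_average(dataset.get(p, RH_SYNC), STIM) for p in pids}
    late_rating = {p: window_average(dataset.get(p, RH_SYNC), 90, 120) for p in pids}

    seeds = [None] * 6 if seed is None else [seed + i for i in range(6)]
    specs = [
        ("onset_vs_fading", onset, fading),
        ("onset_vs_mean_effect", onset, mean_effect),
        (
            "onset_vs_questionnaire",
            onset,
            {p: quest(p, questionnaire_component) for p in pids},
        ),
        ("onset_vs_drift", onset, drifts),
        (
            "stim_rating_vs_ownership",
            stim_rating,
            {p: quest(p, potentiometer_component) for p in pids},
        ),
        (
            "late_rating_vs_ownership",
            late_rating,
            {p: quest(p, potentiometer_component) for p in pids},
        ),
    ]
    results = []
    for (name, a, b), s in zip(specs, seeds):
        x, y, common = paired(a, b)
        results.append(
            correlate_with_outlier_filter(x, y, common, name, n_boot, level, s)
        )
    return bonferroni_adjust(results, m, cap)
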