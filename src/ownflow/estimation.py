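"""Paired-difference estimation statistics with BCa bootstrap intervals.

Inference is estimation-based: each condition contrast is summarised by a
paired mean or median difference with a 95% bias-corrected-and-accelerated
(BCa) bootstrap confidence interval (default 5000 resamples), plus a
qualitative evidence label. The resampling unit is always the participant:
paired differences are resampled jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .data_model import (
    DescriptiveSummary,
    StudyDataset,
    block_average,
    describe,
    phase_average,
)

MEAN = "mean"
MEDIAN = "median"
AUTO = "auto"

LABEL_NONE = "none"
LABEL_WEAK = "weak"
LABEL_MODERATE = "moderate"
LABEL_STRONG = "strong"

#: |point estimate| thresholds (rating points) splitting weak / moderate / strong.
DEFAULT_LABEL_THRESHOLDS = (100.0, 250.0)


@dataclass(frozen=True)
class PairedEstimate:
    statistic: str
    point: float
    ci_low: float
    ci_high: float
    level: float
    n_boot: int
    n_pairs: int
    seed: int
    label: str
    summary_a: DescriptiveSummary
    summary_b: DescriptiveSummary
    contrast: str = ""
    block: int | None = None


def paired_difference(x, y, statistic: str = AUTO, alpha: float = 0.05):
    """Point estimate of the paired difference x - y.

    ``auto`` picks the mean when the paired differences pass a Shapiro-Wilk
    normality test at ``alpha``, else the median. Returns
    ``(statistic_used, point, diffs)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be aligned on the same participants")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = x - y
    if statistic == AUTO:
        statistic = MEAN if _is_normalish(diffs, alpha) else MEDIAN
    if statistic == MEAN:
        return MEAN, float(diffs.mean()), diffs
    if statistic == MEDIAN:
        return MEDIAN, float(np.median(diffs)), diffs
    raise ValueError(f"unknown statistic {statistic!r}")


def _is_normalish(diffs: np.ndarray, alpha: float) -> bool:
    if np.ptp(diffs) == 0:  # Shapiro is undefined for constant input
        return True
    if diffs.size < 3:
        return True
    return sps.shapiro(diffs).pvalue > alpha


def _stat_fn(name: str):
    return {MEAN: np.mean, MEDIAN: np.median}[name]


def bca_ci(
    sample,
    stat_fn,
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
) -> tuple:
    """Bias-corrected-and-accelerated bootstrap CI for ``stat_fn(sample)``.

    ``stat_fn`` must be a deterministic numpy-style reducer accepting an
    ``axis`` keyword (e.g. ``np.mean``). Bias correction comes from the
    proportion of bootstrap statistics below the observed one, acceleration
    from jackknife skewness. A degenerate bootstrap distribution collapses to
    a zero-width interval at the statistic; zero jackknife variance falls
    back to the percentile interval.
    """
    v = np.asarray(sample, dtype=float)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if v.size < 2:
        raise ValueError("need at least 2 observations")
    theta = float(stat_fn(v))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    thetas = np.asarray(stat_fn(v[idx], axis=1), dtype=float)

    if np.ptp(thetas) == 0 and thetas[0] == theta:
        return theta, theta

    alpha = (1 - level / 100.0) / 2

    # acceleration via jackknife skewness
    jack = np.array(
        [stat_fn(np.delete(v, i)) for i in range(v.size)], dtype=float
    )
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    if denom == 0:
        lo, hi = np.percentile(thetas, [100 * alpha, 100 * (1 - alpha)])
        return float(lo), float(hi)
    a = np.sum(dev**3) / (6.0 * denom)

    prop = np.mean(thetas < theta)
    prop = min(max(prop, 1.0 / (n_boot + 1)), n_boot / (n_boot + 1.0))
    z0 = sps.norm.ppf(prop)
    z_lo, z_hi = sps.norm.ppf(alpha), sps.norm.ppf(1 - alpha)
    a1 = sps.norm.cdf(z0 + (z0 + z_lo) / (1 - a * (z0 + z_lo)))
    a2 = sps.norm.cdf(z0 + (z0 + z_hi) / (1 - a * (z0 + z_hi)))
    lo, hi = np.percentile(thetas, [100 * a1, 100 * a2])
    return float(lo), float(hi)


def classify_effect(
    point: float,
    ci_low: float,
    ci_high: float,
    thresholds: tuple = DEFAULT_LABEL_THRESHOLDS,
) -> str:
    """Qualitative evidence label for a paired estimate.

    ``none`` when the CI strictly contains 0 or the estimate is 0 with a
    zero-width CI; otherwise weak / moderate / strong by |point| against
    ``thresholds`` (a documented heuristic on the 0-1000 rating scale).
    """
    if ci_low < 0 < ci_high:
        return LABEL_NONE
    if point == 0 and ci_high == ci_low:
        return LABEL_NONE
    weak_max, moderate_max = thresholds
    mag = abs(point)
    if mag < weak_max:
        return LABEL_WEAK
    if mag <= moderate_max:
        return LABEL_MODERATE
    return LABEL_STRONG


def estimate_pair(
    x,
    y,
    statistic: str = AUTO,
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
    thresholds: tuple = DEFAULT_LABEL_THRESHOLDS,
    contrast: str = "",
    block: int | None = None,
) -> PairedEstimate:
    """Full paired estimate: point, BCa CI, evidence label, group summaries."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    stat_name, point, diffs = paired_difference(x, y, statistic)
    ci_low, ci_high = bca_ci(diffs, _stat_fn(stat_name), n_boot, level, seed)
    return PairedEstimate(
        statistic=f"{stat_name}_diff",
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        level=level,
        n_boot=n_boot,
        n_pairs=int(diffs.size),
        seed=-1 if seed is None else int(seed),
        label=classify_effect(point, ci_low, ci_high, thresholds),
        summary_a=describe(x),
        summary_b=describe(y),
        contrast=contrast,
        block=block,
    )


def compare_conditions(
    dataset: StudyDataset,
    phase: str,
    contrasts,
    measure: str = "phase_average",
    block_s: int = 30,
    statistic: str = AUTO,
    n_boot: int = 5000,
    level: float = 95.0,
    seed: int | None = None,
    thresholds: tuple = DEFAULT_LABEL_THRESHOLDS,
) -> list:
    """Batch paired estimates for condition contrasts over a phase.

    ``measure='phase_average'`` yields one estimate per contrast;
    ``measure='block_average'`` yields one per 30-s block per contrast
    (the progression-over-time layout). Participants contribute only when
    the measure is computable in both conditions of the contrast.
    """
    if not contrasts:
        raise ValueError("contrast list is empty")
    out = []
    for ci, (cond_a, cond_b) in enumerate(contrasts):
        name = f"{cond_a}_vs_{cond_b}_{phase}"
        pair_seed = None if seed is None else seed + 1000 * ci
        if measure == "phase_average":
            xs, ys = [], []
            for pid in dataset.participants():
                xs.append(phase_average(dataset.get(pid, cond_a), phase))
                ys.append(phase_average(dataset.get(pid, cond_b), phase))
            out.append(
                estimate_pair(
                    xs, ys, statistic, n_boot, level, pair_seed, thresholds,
                    contrast=name,
                )
            )
        elif measure == "block_average":
            per_pid_a, per_pid_b = [], []
            for pid in dataset.participants():
                per_pid_a.append(block_average(dataset.get(pid, cond_a), phase, block_s))
                per_pid_b.append(block_average(dataset.get(pid, cond_b), phase, block_s))
            n_blocks = len(per_pid_a[0])
            for b in range(n_blocks):
                xs = [row[b] for row in per_pid_a]
                ys = [row[b] for row in per_pid_b]
                block_seed = None if pair_seed is None else pair_seed + b
                out.append(
                    estimate_pair(
                        xs, ys, statistic, n_boot, level, block_seed, thresholds,
                        contrast=name, block=b + 1,
                    )
                )
        else:
            raise ValueError(f"unknown measure {measure!r}")
    return out


def relabel(est: PairedEstimate, thresholds: tuple) -> PairedEstimate:
    """Recompute the evidence label of an estimate under other thresholds."""
    return replace(
        est, label=classify_effect(est.point, est.ci_low, est.ci_high, thresholds)
    )
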