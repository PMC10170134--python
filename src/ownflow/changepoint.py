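"""Effect-signal construction and exact piecewise-linear changepoint detection.

The illusion-magnitude signal ("ownership effect") is the per-second
difference between synchronous and asynchronous rubber-hand ratings, either
of the group means or per participant. Changepoints are found by minimising
the total error sum of squares (SSE) of independent least-squares lines
fitted within each segment, over every admissible placement of exactly k
changepoints — an exact search rather than iterative refinement, which is
affordable at <= 120 samples and makes brute-force oracle checks meaningful.

A changepoint time is reported as the phase-relative second of the LAST
sample of the earlier segment: a changepoint "at 19 s" means seconds 1-19
form the first segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    POST,
    RH_ASYNC,
    RH_SYNC,
    STIM,
    STIM_END_S,
    RatingSeries,
    StudyDataset,
)

GROUP_MEAN = "group_mean"
INDIVIDUAL = "individual"


@dataclass(frozen=True)
class EffectSeries:
    """Sync-minus-async effect signal over one phase, on phase-relative seconds."""

    level: str
    phase: str
    times: np.ndarray
    values: np.ndarray
    participant_id: str | None = None
    smoothed: bool = False
    window_s: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=int)
        v = np.asarray(self.values, dtype=float)
        if len(t) != len(v):
            raise ValueError("times and values must have equal length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("effect values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SegmentFit:
    """Least-squares line over an inclusive index range of an effect series."""

    start_idx: int
    end_idx: int
    slope: float
    intercept: float
    sse: float

    def predict(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class ChangepointResult:
    """SSE-optimal segmentation of an effect series into k+1 linear pieces."""

    changepoint_times: list
    segments: list
    total_sse: float
    k_requested: int
    fitted_values_at_changepoints: list = field(default_factory=list)

    @property
    def changepoint_indices(self) -> list:
        return [seg.end_idx for seg in self.segments[:-1]]


# ---------------------------------------------------------------------------
# effect construction
# ---------------------------------------------------------------------------


def _phase_relative(series: RatingSeries, phase: str):
    sel = series.phase_index(phase) & series.usable()
    t = series.time_s[sel]
    if phase == POST:
        t = t - STIM_END_S
    return t, series.rating[sel]


def ownership_effect(
    dataset: StudyDataset,
    level: str = GROUP_MEAN,
    phase: str = STIM,
    participant_id: str | None = None,
) -> EffectSeries:
    """Build the sync-minus-async effect signal for one phase.

    Group level: per-second mean over participants of rh_sync minus the
    per-second mean of rh_async (each second averaged over the participants
    with a usable sample at that second). Individual level: one
    participant's rh_sync minus rh_async, seconds present in both.
    Masked seconds are absent from the result.
    """
    if level == INDIVIDUAL:
        if participant_id is None:
            raise ValueError("individual level requires a participant_id")
        pids = [participant_id]
    elif level == GROUP_MEAN:
        pids = dataset.participants()
    else:
        raise ValueError(f"unknown level {level!r}")

    per_second_sync: dict = {}
    per_second_async: dict = {}
    for pid in pids:
        for cond, store in ((RH_SYNC, per_second_sync), (RH_ASYNC, per_second_async)):
            if not dataset.has(pid, cond):
                raise ValueError(f"participant {pid!r} lacks condition {cond!r}")
            t, v = _phase_relative(dataset.get(pid, cond), phase)
            for ti, vi in zip(t, v):
                store.setdefault(int(ti), []).append(vi)

    common = sorted(set(per_second_sync) & set(per_second_async))
    if not common:
        raise ValueError("no overlapping usable seconds between conditions")
    times = np.array(common, dtype=int)
    values = np.array(
        [np.mean(per_second_sync[t]) - np.mean(per_second_async[t]) for t in common]
    )
    return EffectSeries(
        level=level,
        phase=phase,
        times=times,
        values=values,
        participant_id=participant_id,
    )


def smooth_moving_average(series: EffectSeries, window_s: int = 5) -> EffectSeries:
    """Centered moving average with window truncation at the signal edges.

    The window is clipped to the available samples, so the first output value
    averages the first ceil(window/2) samples. Output length equals input
    length. ``window_s`` must be odd (a centered window is otherwise
    undefined); 1 is the identity.
    """
    if window_s < 1 or window_s % 2 == 0:
        raise ValueError("window_s must be odd and >= 1")
    half = window_s // 2
    v = series.values
    n = len(v)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = v[lo:hi].mean()
    return replace(series, values=out, smoothed=True, window_s=window_s)


# ---------------------------------------------------------------------------
# segment least squares
# ---------------------------------------------------------------------------


class _PrefixStats:
    """Prefix sums enabling O(1) least-squares SSE over any index range."""

    def __init__(self, x: np.ndarray, y: np.ndarray) -> None:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])

    def fit(self, i: int, j: int):
        """Slope, intercept, SSE of the OLS line over samples i..j inclusive."""
        n = j - i + 1
        sx = self.sx[j + 1] - self.sx[i]
        sy = self.sy[j + 1] - self.sy[i]
        sxx = self.sxx[j + 1] - self.sxx[i]
        syy = self.syy[j + 1] - self.syy[i]
        sxy = self.sxy[j + 1] - self.sxy[i]
        cxx = sxx - sx * sx / n
        cyy = syy - sy * sy / n
        cxy = sxy - sx * sy / n
        if cxx <= 0:  # duplicate abscissae cannot occur on a strict time grid
            return 0.0, sy / n, max(cyy, 0.0)
        slope = cxy / cxx
        intercept = (sy - slope * sx) / n
        return slope, intercept, max(cyy - cxy * cxy / cxx, 0.0)


def segment_sse(times, values, start_idx: int, end_idx: int) -> SegmentFit:
    """Least-squares line and SSE over an inclusive index range (>= 2 points)."""
    if end_idx - start_idx + 1 < 2:
        raise ValueError("a segment needs at least 2 points")
    stats = _PrefixStats(times, values)
    slope, intercept, sse = stats.fit(start_idx, end_idx)
    return SegmentFit(start_idx, end_idx, float(slope), float(intercept), float(sse))


# ---------------------------------------------------------------------------
# changepoint search
# ---------------------------------------------------------------------------


def find_changepoints(
    series: EffectSeries,
    k: int = 2,
    min_segment_length: int = 3,
) -> ChangepointResult:
    """Globally SSE-optimal placement of exactly ``k`` changepoints.

    Exhaustive search over all admissible placements subject to
    ``min_segment_length``. SSE ties (within 1e-9 relative) are broken toward
    the lexicographically LARGEST changepoint tuple, so that the sample at a
    continuous knee — which lies on both adjacent segment lines — is assigned
    to the earlier segment and a breakpoint "at 19 s" means seconds 1-19 form
    the first segment. Supports k in {1, 2}.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > 2:
        raise ValueError("only k <= 2 is supported")
    n = len(series.values)
    msl = min_segment_length
    if n < (k + 1) * msl:
        raise ValueError(
            f"series of length {n} too short for {k} changepoints with "
            f"min_segment_length {msl}"
        )
    stats = _PrefixStats(series.times, series.values)

    best_sse = np.inf
    best_cuts: tuple = ()
    # prefix-sum cancellation error scales with the total sum of squares, so
    # the tie tolerance must too, or exact ties (SSE 0) are broken by noise
    tie_tol = 1e3 * np.finfo(float).eps * max(float(np.sum(series.values**2)), 1.0)

    def consider(sse: float, cuts: tuple) -> None:
        # ascending iteration + accept-on-tie => lexicographically largest tie
        nonlocal best_sse, best_cuts
        if not np.isfinite(best_sse):
            best_sse, best_cuts = sse, cuts
            return
        tol = max(1e-9 * best_sse, tie_tol)
        if sse < best_sse - tol:
            best_sse, best_cuts = sse, cuts
        elif sse < best_sse + tol:
            best_sse, best_cuts = min(best_sse, sse), cuts

    if k == 1:
        for c in range(msl - 1, n - msl):
            consider(stats.fit(0, c)[2] + stats.fit(c + 1, n - 1)[2], (c,))
    else:
        for c1 in range(msl - 1, n - 2 * msl):
            left = stats.fit(0, c1)[2]
            for c2 in range(c1 + msl, n - msl):
                consider(
                    left + stats.fit(c1 + 1, c2)[2] + stats.fit(c2 + 1, n - 1)[2],
                    (c1, c2),
                )

    bounds = [-1, *best_cuts, n - 1]
    segments = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        slope, intercept, sse = stats.fit(s + 1, e)
        segments.append(SegmentFit(s + 1, e, float(slope), float(intercept), float(sse)))
    cp_times = [int(series.times[c]) for c in best_cuts]
    fitted = [
        float(seg.predict(series.times[c]))
        for seg, c in zip(segments[:-1], best_cuts)
    ]
    return ChangepointResult(
        changepoint_times=cp_times,
        segments=segments,
        total_sse=float(best_sse),
        k_requested=k,
        fitted_values_at_changepoints=fitted,
    )


def best_line_sse(series: EffectSeries) -> float:
    """SSE of the single best-fit line (the k = 0 baseline)."""
    stats = _PrefixStats(series.times, series.values)
    return float(stats.fit(0, len(series.values) - 1)[2])


def individual_changepoints(
    dataset: StudyDataset,
    phase: str = STIM,
    k: int = 2,
    min_segment_length: int = 3,
    smooth: bool = True,
    window_s: int = 5,
    stationary_rel_tol: float = 1e-9,
) -> dict:
    """Per-participant changepoint results; ``None`` for stationary signals.

    A participant yields ``None`` when their effect signal has zero variance
    or when the optimal k-changepoint fit fails to reduce SSE relative to the
    best single-line fit by more than ``stationary_rel_tol`` (relative).
    The first changepoint per phase is the onset (stim) / fading (post) time.
    """
    out = {}
    for pid in dataset.participants():
        eff = ownership_effect(dataset, INDIVIDUAL, phase, participant_id=pid)
        if smooth:
            eff = smooth_moving_average(eff, window_s)
        if np.ptp(eff.values) == 0:
            out[pid] = None
            continue
        sse0 = best_line_sse(eff)
        result = find_changepoints(eff, k, min_segment_length)
        if sse0 <= 0 or (sse0 - result.total_sse) / sse0 <= stationary_rel_tol:
            out[pid] = None
        else:
            out[pid] = result
    return out


def onset_changepoint(result: ChangepointResult | None):
    """First changepoint time of a result, or None for stationary signals."""
    if result is None or not result.changepoint_times:
        return None
    return result.changepoint_times[0]


# ---------------------------------------------------------------------------
# landmark deltas
# ---------------------------------------------------------------------------


def rate_of_change_report(landmarks) -> list:
    """Per-interval change of a signal between consecutive (time, value) landmarks.

    Each entry reports the interval bounds, its duration, the signed change
    ``delta`` and its magnitude — the "how much did the effect move between
    changepoints" table.
    """
    pts = [(float(t), float(v)) for t, v in landmarks]
    if len(pts) < 2:
        raise ValueError("need at least two landmarks")
    if any(t1 >= t2 for (t1, _), (t2, _) in zip(pts[:-1], pts[1:])):
        raise ValueError("landmark times must be strictly increasing")
    report = []
    for (t0, v0), (t1, v1) in zip(pts[:-1], pts[1:]):
        report.append(
            {
                "t_start": t0,
                "t_end": t1,
                "duration_s": t1 - t0,
                "delta": v1 - v0,
                "magnitude": abs(v1 - v0),
            }
        )
    return report


def result_landmarks(series: EffectSeries, result: ChangepointResult) -> list:
    """(time, fitted value) landmarks: segment start, each changepoint, phase end.

    Values are taken from the per-segment fits: the first landmark is the
    first segment's fit at the first sample, each changepoint landmark is the
    earlier segment's fit at the changepoint, and the last landmark is the
    final segment's fit at the last sample.
    """
    t = series.times
    first = result.segments[0]
    last = result.segments[-1]
    marks = [(float(t[0]), float(first.predict(t[0])))]
    for seg, cp in zip(result.segments[:-1], result.changepoint_indices):
        marks.append((float(t[cp]), float(seg.predict(t[cp]))))
    marks.append((float(t[-1]), float(last.predict(t[-1]))))
    return marks
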