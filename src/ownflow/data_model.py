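"""Typed containers, ingestion, validation, and preprocessing for ownership-rating studies.

A study records a continuous 0-1000 ownership rating at 1 Hz for 240 s per
trial (120 s of visuo-tactile stimulation followed by 120 s post-stimulation)
in four conditions (rubber hand / wooden object x synchronous / asynchronous
stroking), plus per-trial proprioceptive position judgements (cm) and
per-trial Likert questionnaire responses (-3..+3).

Time is 1-indexed in integer seconds: the stimulation phase is seconds
1..120, the post-stimulation phase is seconds 121..240. Missing ratings are
carried as NaN; they are never imputed and are excluded from every average.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

RH_SYNC = "rh_sync"
RH_ASYNC = "rh_async"
WOOD_SYNC = "wood_sync"
WOOD_ASYNC = "wood_async"
CONDITIONS = (RH_SYNC, RH_ASYNC, WOOD_SYNC, WOOD_ASYNC)

TRIAL_LEN_S = 240
STIM_END_S = 120
SCALE_MIN = 0.0
SCALE_MAX = 1000.0

STIM = "stim"
POST = "post"
PHASES = (STIM, POST)


class ValidationError(ValueError):
    """Raised when an input table or record violates a study invariant."""


# ---------------------------------------------------------------------------
# rating series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RatingSeries:
    """One participant x condition rating trajectory on the full 240-s grid.

    ``rating`` is float with NaN for missing seconds; ``masked`` marks
    samples excluded from analysis (the post-stimulation gap).
    """

    participant_id: str
    condition: str
    time_s: np.ndarray
    rating: np.ndarray
    masked: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=int)
        r = np.asarray(self.rating, dtype=float)
        m = np.asarray(self.masked, dtype=bool)
        if self.condition not in CONDITIONS:
            raise ValidationError(f"unknown condition {self.condition!r}")
        if not (len(t) == len(r) == len(m)):
            raise ValidationError("time_s, rating, masked must have equal length")
        if len(t) and (t[0] < 1 or t[-1] > TRIAL_LEN_S):
            raise ValidationError("time_s must lie in [1, 240]")
        if np.any(np.diff(t) != 1):
            raise ValidationError("time_s must be strictly increasing with unit spacing")
        finite = r[np.isfinite(r)]
        if np.any(finite < SCALE_MIN) or np.any(finite > SCALE_MAX):
            raise ValidationError(
                f"rating outside [0, 1000] for participant {self.participant_id!r}, "
                f"condition {self.condition!r}"
            )
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "rating", r)
        object.__setattr__(self, "masked", m)

    @property
    def complete(self) -> bool:
        return len(self.time_s) == TRIAL_LEN_S and self.time_s[0] == 1

    def phase_index(self, phase: str) -> np.ndarray:
        """Boolean index of samples belonging to ``phase``."""
        if phase == STIM:
            return self.time_s <= STIM_END_S
        if phase == POST:
            return self.time_s > STIM_END_S
        raise ValueError(f"unknown phase {phase!r}")

    def usable(self) -> np.ndarray:
        """Samples that are present and not masked."""
        return np.isfinite(self.rating) & ~self.masked


def series_from_values(
    participant_id: str,
    condition: str,
    ratings,
    start_s: int = 1,
) -> RatingSeries:
    """Build a series from a plain rating sequence starting at ``start_s``."""
    r = np.asarray(ratings, dtype=float)
    t = np.arange(start_s, start_s + len(r))
    return RatingSeries(participant_id, condition, t, r, np.zeros(len(r), bool))


# ---------------------------------------------------------------------------
# auxiliary measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProprioceptivePair:
    """Baseline and post-stimulation felt-position judgement for one trial."""

    participant_id: str
    condition: str
    baseline_cm: float
    post_cm: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.baseline_cm) and np.isfinite(self.post_cm)):
            raise ValidationError(
                f"non-finite proprioceptive judgement for {self.participant_id!r}"
            )


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Per-trial Likert item responses on the -3..+3 agreement scale."""

    participant_id: str
    condition: str
    responses: dict

    def __post_init__(self) -> None:
        for item, value in self.responses.items():
            if not (-3 <= value <= 3):
                raise ValidationError(
                    f"response {value!r} for item {item!r} outside [-3, 3]"
                )


@dataclass(frozen=True)
class ComponentMap:
    """Mapping from questionnaire component names to item-id lists.

    ``components`` are the disjoint top-level composites; ``subcomponents``
    nest under a top-level component (keyed by subcomponent name) and may
    reuse its items.
    """

    components: dict
    subcomponents: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for name, items in self.components.items():
            if not items:
                raise ValidationError(f"component {name!r} has no items")
            overlap = seen & set(items)
            if overlap:
                raise ValidationError(
                    f"items {sorted(overlap)} appear in more than one component"
                )
            seen |= set(items)
        for name, items in self.subcomponents.items():
            if not items:
                raise ValidationError(f"subcomponent {name!r} has no items")

    def all_scales(self) -> dict:
        out = dict(self.components)
        out.update(self.subcomponents)
        return out

    @classmethod
    def from_yaml(cls, source) -> "ComponentMap":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        return cls(doc.get("components", {}), doc.get("subcomponents", {}))

    def to_yaml(self, path) -> None:
        doc = {"components": self.components, "subcomponents": self.subcomponents}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def default_component_map() -> ComponentMap:
    """Default 24-item map: embodiment (10), loss (5), movement (3),
    deafference (3), affect (3); embodiment splits into ownership /
    location / agency subcomponents."""
    emb = [f"emb{i:02d}" for i in range(1, 11)]
    return ComponentMap(
        components={
            "embodiment": emb,
            "loss": [f"loss{i:02d}" for i in range(1, 6)],
            "movement": [f"mov{i:02d}" for i in range(1, 4)],
            "deafference": [f"deaf{i:02d}" for i in range(1, 4)],
            "affect": [f"aff{i:02d}" for i in range(1, 4)],
        },
        subcomponents={
            "ownership": emb[0:4],
            "location": emb[4:7],
            "agency": emb[7:10],
        },
    )


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------


@dataclass
class StudyDataset:
    """All measurements for a cohort, keyed by (participant, condition)."""

    series: dict
    judgments: list = field(default_factory=list)
    questionnaires: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for (pid, cond), s in self.series.items():
            if (pid, cond) != (s.participant_id, s.condition):
                raise ValidationError(f"series key {(pid, cond)} does not match record")

    def participants(self) -> list:
        return sorted({pid for pid, _ in self.series})

    def get(self, participant_id: str, condition: str) -> RatingSeries:
        return self.series[(participant_id, condition)]

    def has(self, participant_id: str, condition: str) -> bool:
        return (participant_id, condition) in self.series

    def conditions_of(self, participant_id: str) -> list:
        return sorted(c for p, c in self.series if p == participant_id)

    def judgment(self, participant_id: str, condition: str):
        for j in self.judgments:
            if (j.participant_id, j.condition) == (participant_id, condition):
                return j
        return None

    def questionnaire(self, participant_id: str, condition: str):
        for q in self.questionnaires:
            if (q.participant_id, q.condition) == (participant_id, condition):
                return q
        return None


def read_ratings(
    ratings,
    judgments=None,
    questionnaires=None,
) -> StudyDataset:
    """Ingest long-format tables into a validated :class:`StudyDataset`.

    ``ratings`` is a CSV path / file object / DataFrame with columns
    ``participant_id, condition, time_s, rating``. Rows with unknown
    condition labels are dropped; missing seconds become NaN samples on the
    full 1..240 grid. Duplicate ``(participant, condition, time_s)`` rows and
    out-of-range ratings are hard errors.
    """
    df = _as_frame(ratings)
    required = {"participant_id", "condition", "time_s", "rating"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ratings table missing columns {sorted(missing)}")
    df = df[df["condition"].isin(CONDITIONS)].copy()
    df["participant_id"] = df["participant_id"].astype(str)
    df["time_s"] = df["time_s"].astype(int)

    dup = df.duplicated(subset=["participant_id", "condition", "time_s"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate rating row for participant "
            f"{row['participant_id']!r}, condition {row['condition']!r}, "
            f"time_s {int(row['time_s'])}"
        )
    bad_t = (df["time_s"] < 1) | (df["time_s"] > TRIAL_LEN_S)
    if bad_t.any():
        row = df[bad_t].iloc[0]
        raise ValidationError(f"time_s {int(row['time_s'])} outside [1, 240]")
    rated = df["rating"].notna()
    bad_r = rated & ((df["rating"] < SCALE_MIN) | (df["rating"] > SCALE_MAX))
    if bad_r.any():
        row = df[bad_r].iloc[0]
        raise ValidationError(
            f"rating {row['rating']!r} outside [0, 1000] "
            f"(participant {row['participant_id']!r}, condition "
            f"{row['condition']!r}, time_s {int(row['time_s'])})"
        )

    series = {}
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        full = np.full(TRIAL_LEN_S, np.nan)
        full[grp["time_s"].to_numpy() - 1] = grp["rating"].to_numpy(dtype=float)
        series[(pid, cond)] = RatingSeries(
            pid, cond, np.arange(1, TRIAL_LEN_S + 1), full, np.zeros(TRIAL_LEN_S, bool)
        )

    pairs = []
    if judgments is not None:
        jdf = _as_frame(judgments)
        for _, row in jdf.iterrows():
            pairs.append(
                ProprioceptivePair(
                    str(row["participant_id"]),
                    str(row["condition"]),
                    float(row["baseline_cm"]),
                    float(row["post_cm"]),
                )
            )
    quests = []
    if questionnaires is not None:
        qdf = _as_frame(questionnaires)
        for (pid, cond), grp in qdf.groupby(["participant_id", "condition"], sort=True):
            responses = {
                str(r["item_id"]): int(r["response"]) for _, r in grp.iterrows()
            }
            quests.append(QuestionnaireResponse(str(pid), str(cond), responses))
    return StudyDataset(series, pairs, quests)


def write_ratings(dataset: StudyDataset, path) -> None:
    """Emit the long-format ratings CSV (inverse of :func:`read_ratings`)."""
    rows = []
    for (pid, cond) in sorted(dataset.series):
        s = dataset.series[(pid, cond)]
        present = np.isfinite(s.rating)
        for t, r in zip(s.time_s[present], s.rating[present]):
            rows.append((pid, cond, int(t), float(r)))
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "time_s", "rating"]
    ).to_csv(path, index=False)


def write_judgments(dataset: StudyDataset, path) -> None:
    rows = [
        (j.participant_id, j.condition, j.baseline_cm, j.post_cm)
        for j in dataset.judgments
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "baseline_cm", "post_cm"]
    ).to_csv(path, index=False)


def write_questionnaires(dataset: StudyDataset, path) -> None:
    rows = []
    for q in dataset.questionnaires:
        for item, resp in sorted(q.responses.items()):
            rows.append((q.participant_id, q.condition, item, resp))
    pd.DataFrame(
        rows, columns=["participant_id", "condition", "item_id", "response"]
    ).to_csv(path, index=False)


def _as_frame(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        return pd.read_csv(source)
    if isinstance(source, io.IOBase):
        return pd.read_csv(source)
    try:
        import os

        if isinstance(source, os.PathLike):
            return pd.read_csv(source)
    except TypeError:
        pass
    raise TypeError(f"cannot read table from {type(source)!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def exclude_nonresponders(dataset: StudyDataset):
    """Drop participants whose rubber-hand-synchronous ratings never rise
    above 0 during the 120 s of stimulation.

    Returns ``(filtered_dataset, excluded_ids)``. Missing samples count as
    not-above-zero. Applied to every table of the dataset.
    """
    excluded = []
    for pid in dataset.participants():
        if not dataset.has(pid, RH_SYNC):
            raise ValidationError(f"participant {pid!r} lacks an rh_sync series")
        s = dataset.get(pid, RH_SYNC)
        stim = s.rating[s.phase_index(STIM)]
        if not np.any(stim[np.isfinite(stim)] > 0):
            excluded.append(pid)
    keep = set(dataset.participants()) - set(excluded)
    return (
        StudyDataset(
            {k: v for k, v in dataset.series.items() if k[0] in keep},
            [j for j in dataset.judgments if j.participant_id in keep],
            [q for q in dataset.questionnaires if q.participant_id in keep],
        ),
        sorted(excluded),
    )


def mask_post_gap(series: RatingSeries, gap_s: int = 10) -> RatingSeries:
    """Flag the first ``gap_s`` post-stimulation seconds as masked.

    Masked samples are excluded (never zero-filled) from all downstream
    averages and from post-phase changepoint input. Idempotent.
    """
    if gap_s < 0:
        raise ValueError("gap_s must be >= 0")
    in_gap = (series.time_s > STIM_END_S) & (series.time_s <= STIM_END_S + gap_s)
    return replace(series, masked=series.masked | in_gap)


def mask_dataset_post_gap(dataset: StudyDataset, gap_s: int = 10) -> StudyDataset:
    """Apply :func:`mask_post_gap` to every series of the dataset."""
    return StudyDataset(
        {k: mask_post_gap(s, gap_s) for k, s in dataset.series.items()},
        dataset.judgments,
        dataset.questionnaires,
    )


def phase_average(series: RatingSeries, phase: str) -> float:
    """Arithmetic mean of usable (unmasked, non-missing) ratings in a phase."""
    sel = series.phase_index(phase) & series.usable()
    if not sel.any():
        raise ValueError(
            f"no usable samples in phase {phase!r} for {series.participant_id!r}"
        )
    return float(series.rating[sel].mean())


def window_average(series: RatingSeries, start_s: int, end_s: int) -> float:
    """Mean of usable ratings with ``start_s <= time_s <= end_s``."""
    sel = (series.time_s >= start_s) & (series.time_s <= end_s) & series.usable()
    if not sel.any():
        raise ValueError(f"no usable samples in [{start_s}, {end_s}]")
    return float(series.rating[sel].mean())


def block_average(series: RatingSeries, phase: str, block_s: int = 30) -> list:
    """Per-block means over a phase, blocks anchored at the phase start.

    Masked and missing samples are excluded from their block's mean; a block
    with no usable samples yields NaN (never zero).
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    sel = series.phase_index(phase)
    n = int(sel.sum())
    if n % block_s:
        raise ValueError(f"phase length {n} not divisible by block_s {block_s}")
    ratings = series.rating[sel]
    usable = series.usable()[sel]
    out = []
    for b in range(n // block_s):
        chunk = ratings[b * block_s : (b + 1) * block_s]
        ok = usable[b * block_s : (b + 1) * block_s]
        out.append(float(chunk[ok].mean()) if ok.any() else float("nan"))
    return out


def percent_of_scale(value: float, scale_min: float = SCALE_MIN,
                     scale_max: float = SCALE_MAX) -> float:
    """Express a value as percent of the span of its rating scale."""
    if scale_max <= scale_min:
        raise ValueError("scale_max must exceed scale_min")
    if not (scale_min <= value <= scale_max):
        raise ValueError(f"value {value} outside [{scale_min}, {scale_max}]")
    return 100.0 * (value - scale_min) / (scale_max - scale_min)


def proprioceptive_drift(pair: ProprioceptivePair) -> float:
    """Post-stimulation minus baseline felt position, in cm.

    Sign convention: positive means the post judgement moved in the
    direction of increasing ruler reading (toward the viewed object under
    the study's setup); the convention is fixed here, not inferred from data.
    """
    return pair.post_cm - pair.baseline_cm


def score_questionnaire(resp: QuestionnaireResponse, cmap: ComponentMap) -> dict:
    """Per-component (and subcomponent) mean of Likert item responses."""
    scores = {}
    for name, items in cmap.all_scales().items():
        vals = []
        for item in items:
            if item not in resp.responses:
                raise ValidationError(
                    f"missing item {item!r} for participant "
                    f"{resp.participant_id!r}, condition {resp.condition!r}"
                )
            vals.append(resp.responses[item])
        scores[name] = float(np.mean(vals))
    return scores


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptiveSummary:
    n: int
    median: float
    iqr: float
    mean: float
    sd: float


def describe(values) -> DescriptiveSummary:
    """n / median / IQR / mean / sd of a sample (linear-interpolated quartiles)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    q1, q3 = np.percentile(v, [25, 75])
    return DescriptiveSummary(
        n=int(v.size),
        median=float(np.median(v)),
        iqr=float(q3 - q1),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
    )
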