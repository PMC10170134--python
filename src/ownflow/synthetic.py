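"""Synthetic study generator with stored ground truth for recovery testing.

Each participant's latent ownership trajectory is a piecewise-linear
template: zero until stimulation starts, a fast rise to a first breakpoint
(onset), slower growth to a second breakpoint (plateau), a flat plateau to
the end of stimulation, then a two-rate decay (fast until a fading
breakpoint, slow toward zero). Condition gains scale the template per
condition; i.i.d. Gaussian observation noise is added, and the readout is
clipped to [0, 1000] and optionally quantized to integers.

The piecewise-linear template (rather than a smooth saturating curve) is
deliberate: it lies inside the changepoint model class, so breakpoint
recovery errors are interpretable. Default calibration places group-level
landmarks near the reference values used throughout the test-suite
(onset ~19 s, plateau ~87 s, effect levels ~180 and ~320 points; post-phase
fading breakpoints ~17 and ~66 s).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .data_model import (
    CONDITIONS,
    RH_ASYNC,
    RH_SYNC,
    SCALE_MAX,
    SCALE_MIN,
    STIM_END_S,
    TRIAL_LEN_S,
    WOOD_ASYNC,
    WOOD_SYNC,
    ProprioceptivePair,
    QuestionnaireResponse,
    RatingSeries,
    StudyDataset,
    default_component_map,
)

#: gains chosen so (rh_sync - rh_async) reproduces the template amplitude x 0.85
DEFAULT_GAINS = {RH_SYNC: 1.0, RH_ASYNC: 0.15, WOOD_SYNC: 0.12, WOOD_ASYNC: 0.03}


@dataclass(frozen=True)
class TrajectoryParams:
    """Latent-trajectory shape for one participant (template units)."""

    onset_latency_s: float = 19.0
    rise_rate: float = 11.17  # template points/s during the fast rise
    slow_rate: float = 2.41  # template points/s between onset and plateau
    plateau_time_s: float = 87.0
    fade_fast_s: float = 17.0
    fade_fast_rate: float = 7.48
    fade_slow_rate: float = 3.70
    noise_sd: float = 25.0
    quantize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.onset_latency_s < self.plateau_time_s < STIM_END_S):
            raise ValueError("need 0 < onset_latency_s < plateau_time_s < 120")
        if self.fade_fast_s <= 0 or self.fade_fast_s >= STIM_END_S:
            raise ValueError("fade_fast_s must lie inside the post phase")
        if min(self.rise_rate, self.fade_fast_rate, self.fade_slow_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def onset_level(self) -> float:
        return self.rise_rate * self.onset_latency_s

    @property
    def plateau_level(self) -> float:
        return self.onset_level + self.slow_rate * (
            self.plateau_time_s - self.onset_latency_s
        )

    def fading_end_s(self) -> float:
        """Post-phase time at which the slow decay reaches zero."""
        level_at_break = max(
            self.plateau_level - self.fade_fast_rate * self.fade_fast_s, 0.0
        )
        if self.fade_slow_rate <= 0:
            return float(STIM_END_S)
        return min(
            self.fade_fast_s + level_at_break / self.fade_slow_rate,
            float(STIM_END_S),
        )

    def template(self, time_s: np.ndarray) -> np.ndarray:
        """Noiseless latent trajectory over absolute seconds 1..240, gain 1."""
        t = np.asarray(time_s, dtype=float)
        out = np.empty_like(t)
        stim = t <= STIM_END_S
        ts = t[stim]
        out[stim] = np.where(
            ts <= self.onset_latency_s,
            self.rise_rate * ts,
            np.where(
                ts <= self.plateau_time_s,
                self.onset_level + self.slow_rate * (ts - self.onset_latency_s),
                self.plateau_level,
            ),
        )
        tp = t[~stim] - STIM_END_S
        level_at_break = self.plateau_level - self.fade_fast_rate * self.fade_fast_s
        out[~stim] = np.where(
            tp <= self.fade_fast_s,
            self.plateau_level - self.fade_fast_rate * tp,
            level_at_break - self.fade_slow_rate * (tp - self.fade_fast_s),
        )
        return np.clip(out, 0.0, None)


@dataclass
class ParticipantTruth:
    params: TrajectoryParams
    gains: dict
    is_nonresponder: bool
    stim_breakpoints: tuple  # (onset, plateau) seconds
    post_breakpoints: tuple  # (fading fast->slow, decay end) seconds
    drift_cm: float
    ownership_score: float


@dataclass
class SyntheticTruth:
    """Ground truth for every generated participant, keyed by id."""

    master_seed: int
    participants: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = {
            "master_seed": self.master_seed,
            "participants": {
                pid: {
                    "params": asdict(t.params),
                    "gains": t.gains,
                    "is_nonresponder": t.is_nonresponder,
                    "stim_breakpoints": list(t.stim_breakpoints),
                    "post_breakpoints": list(t.post_breakpoints),
                    "drift_cm": t.drift_cm,
                    "ownership_score": t.ownership_score,
                }
                for pid, t in self.participants.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        truth = cls(master_seed=doc["master_seed"])
        for pid, rec in doc["participants"].items():
            truth.participants[pid] = ParticipantTruth(
                params=TrajectoryParams(**rec["params"]),
                gains=rec["gains"],
                is_nonresponder=rec["is_nonresponder"],
                stim_breakpoints=tuple(rec["stim_breakpoints"]),
                post_breakpoints=tuple(rec["post_breakpoints"]),
                drift_cm=rec["drift_cm"],
                ownership_score=rec["ownership_score"],
            )
        return truth


def trajectory(
    params: TrajectoryParams,
    condition: str,
    seed=None,
    participant_id: str = "sim",
    gain: float | None = None,
    gains: dict | None = None,
) -> RatingSeries:
    """One noisy, bounded, optionally quantized rating series.

    The latent signal is ``gain x template``; Gaussian noise of
    ``params.noise_sd`` is added per second, the result is clipped to the
    0-1000 readout range and rounded to integers when ``params.quantize``.
    Seconds 121-130 are emitted like any others (masking happens downstream).
    """
    if gain is None:
        gain = (gains or DEFAULT_GAINS)[condition]
    if not (0.0 <= gain <= 1.0):
        raise ValueError("condition gain must lie in [0, 1]")
    t = np.arange(1, TRIAL_LEN_S + 1)
    latent = gain * params.template(t)
    rng = np.random.default_rng(seed)
    if params.noise_sd > 0:
        latent = latent + rng.normal(0.0, params.noise_sd, size=latent.size)
    latent = np.clip(latent, SCALE_MIN, SCALE_MAX)
    if params.quantize:
        latent = np.round(latent)
    return RatingSeries(
        participant_id, condition, t, latent, np.zeros(t.size, bool)
    )


@dataclass(frozen=True)
class CohortConfig:
    """Population distributions for per-participant trajectory parameters."""

    n_participants: int = 30
    nonresponder_fraction: float = 0.1
    onset_mean_s: float = 19.0
    onset_log_sd: float = 0.12  # lognormal spread of onset latency
    plateau_mean_s: float = 87.0
    plateau_sd_s: float = 5.0
    onset_level_mean: float = 212.3  # template units; x0.85 net gain ~ 180
    onset_level_sd: float = 45.0
    plateau_level_mean: float = 376.3  # x0.85 net gain ~ 320
    plateau_level_sd: float = 70.0
    fade_fast_mean_s: float = 17.0
    fade_fast_sd_s: float = 3.0
    fade_level_mean: float = 225.0  # template level at the fading breakpoint
    fade_level_sd: float = 40.0
    decay_end_mean_s: float = 66.0
    decay_end_sd_s: float = 6.0
    noise_sd: float = 25.0
    quantize: bool = True
    gains: dict = field(default_factory=lambda: dict(DEFAULT_GAINS))
    drift_per_point: float = 0.01  # cm of drift per point of mean effect
    drift_noise_cm: float = 1.0
    ownership_per_point: float = 0.008  # Likert units per point of mean effect
    ownership_noise: float = 0.5

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        if not (0 <= self.nonresponder_fraction < 1):
            raise ValueError("nonresponder_fraction must lie in [0, 1)")
        unknown = set(self.gains) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"gains for unknown conditions {sorted(unknown)}")


def _draw_params(cfg: CohortConfig, rng: np.random.Generator) -> TrajectoryParams:
    onset = float(
        np.clip(
            cfg.onset_mean_s * rng.lognormal(0.0, cfg.onset_log_sd), 5.0, 60.0
        )
    )
    plateau_t = float(
        np.clip(rng.normal(cfg.plateau_mean_s, cfg.plateau_sd_s), onset + 15.0, 115.0)
    )
    onset_level = float(
        np.clip(rng.normal(cfg.onset_level_mean, cfg.onset_level_sd), 40.0, 800.0)
    )
    plateau_level = float(
        np.clip(
            rng.normal(cfg.plateau_level_mean, cfg.plateau_level_sd),
            onset_level + 20.0,
            990.0,
        )
    )
    fade_fast_s = float(
        np.clip(rng.normal(cfg.fade_fast_mean_s, cfg.fade_fast_sd_s), 6.0, 40.0)
    )
    fade_level = float(
        np.clip(
            rng.normal(cfg.fade_level_mean, cfg.fade_level_sd),
            10.0,
            plateau_level - 10.0,
        )
    )
    decay_end = float(
        np.clip(
            rng.normal(cfg.decay_end_mean_s, cfg.decay_end_sd_s),
            fade_fast_s + 10.0,
            115.0,
        )
    )
    return TrajectoryParams(
        onset_latency_s=onset,
        rise_rate=onset_level / onset,
        slow_rate=(plateau_level - onset_level) / (plateau_t - onset),
        plateau_time_s=plateau_t,
        fade_fast_s=fade_fast_s,
        fade_fast_rate=(plateau_level - fade_level) / fade_fast_s,
        fade_slow_rate=fade_level / (decay_end - fade_fast_s),
        noise_sd=cfg.noise_sd,
        quantize=cfg.quantize,
    )


def generate_study(
    n_participants: int | None = None,
    config: CohortConfig | None = None,
    master_seed: int = 0,
):
    """Generate a full study and its ground truth.

    Per-participant parameters are drawn from the population distributions in
    ``config``; a ``nonresponder_fraction`` of the cohort is generated as
    non-responders (all-zero rubber-hand-synchronous ratings). Drift and
    questionnaire ownership are noisy increasing functions of each
    participant's mean effect. Fully reproducible from ``master_seed``.

    Returns ``(StudyDataset, SyntheticTruth)``.
    """
    cfg = config or CohortConfig()
    if n_participants is not None:
        cfg = CohortConfig(**{**asdict(cfg), "n_participants": n_participants})
    root = np.random.SeedSequence(master_seed)
    n = cfg.n_participants
    n_nonresp = int(round(cfg.nonresponder_fraction * n))

    series: dict = {}
    judgments = []
    questionnaires = []
    truth = SyntheticTruth(master_seed=master_seed)
    cmap = default_component_map()

    child_seqs = root.spawn(n)
    for i, seq in enumerate(child_seqs):
        pid = f"p{i + 1:03d}"
        rng = np.random.default_rng(seq)
        is_nonresp = i < n_nonresp
        params = _draw_params(cfg, rng)
        gains = dict(cfg.gains)
        if is_nonresp:
            gains = {c: 0.0 for c in CONDITIONS}

        for cond in CONDITIONS:
            if is_nonresp:
                # never above zero anywhere: identically-zero readout
                s = RatingSeries(
                    pid,
                    cond,
                    np.arange(1, TRIAL_LEN_S + 1),
                    np.zeros(TRIAL_LEN_S),
                    np.zeros(TRIAL_LEN_S, bool),
                )
            else:
                s = trajectory(
                    params,
                    cond,
                    seed=rng.integers(2**63),
                    participant_id=pid,
                    gain=gains[cond],
                )
            series[(pid, cond)] = s

        net_gain = gains[RH_SYNC] - gains[RH_ASYNC]
        mean_effect = float(
            net_gain * params.template(np.arange(1, STIM_END_S + 1)).mean()
        )
        drift = cfg.drift_per_point * mean_effect + float(
            rng.normal(0.0, cfg.drift_noise_cm)
        )
        ownership = float(
            np.clip(
                -1.0
                + cfg.ownership_per_point * mean_effect
                + rng.normal(0.0, cfg.ownership_noise),
                -3.0,
                3.0,
            )
        )
        for cond in CONDITIONS:
            scale = 1.0 if cond == RH_SYNC else 0.25
            baseline = float(np.round(rng.normal(15.0, 1.0), 1))
            judgments.append(
                ProprioceptivePair(
                    pid, cond, baseline, float(np.round(baseline + scale * drift, 1))
                )
            )
            responses = {}
            for comp, items in cmap.components.items():
                center = ownership if comp == "embodiment" else ownership - 1.0
                if cond != RH_SYNC:
                    center = center - 1.0
                for item in items:
                    responses[item] = int(
                        np.clip(np.round(center + rng.normal(0.0, 0.8)), -3, 3)
                    )
            questionnaires.append(QuestionnaireResponse(pid, cond, responses))

        truth.participants[pid] = ParticipantTruth(
            params=params,
            gains=gains,
            is_nonresponder=is_nonresp,
            stim_breakpoints=(params.onset_latency_s, params.plateau_time_s),
            post_breakpoints=(params.fade_fast_s, params.fading_end_s()),
            drift_cm=drift,
            ownership_score=ownership,
        )

    return StudyDataset(series, judgments, questionnaires), truth


def recovery_report(dataset: StudyDataset, truth: SyntheticTruth,
                    individual_results: dict, phase: str = "stim") -> dict:
    """Absolute breakpoint-recovery errors against stored ground truth.

    ``individual_results`` maps participant id to a ChangepointResult (or
    None for stationary signals). Errors are reported for the first
    breakpoint of the requested phase. Raises if the result keys are not all
    present in the truth (dataset/truth mismatch guard).
    """
    unknown = set(individual_results) - set(truth.participants)
    if unknown:
        raise ValueError(f"results for participants not in truth: {sorted(unknown)}")
    errors = {}
    for pid, res in individual_results.items():
        t = truth.participants[pid]
        true_first = (
            t.stim_breakpoints[0] if phase == "stim" else t.post_breakpoints[0]
        )
        if res is None or not res.changepoint_times:
            errors[pid] = None
        else:
            errors[pid] = abs(res.changepoint_times[0] - true_first)
    found = [e for e in errors.values() if e is not None]
    return {
        "phase": phase,
        "n": len(errors),
        "n_detected": len(found),
        "per_participant_abs_error_s": errors,
        "median_abs_error_s": float(np.median(found)) if found else None,
        "max_abs_error_s": float(max(found)) if found else None,
    }
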