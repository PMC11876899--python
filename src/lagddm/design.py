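"""Experimental-design generation and fully synthetic cohorts.

Reproduces the statistical structure of the two-stage status/dictator-game
task: a fixed performance-feedback schedule (60 both-correct, 60 both-wrong,
90 subject-better, 90 subject-worse, collapsing to better/equal/worse =
90/120/90), dictator-game option pairs with integer payoffs in [1, 20] under
|correlation| <= 0.1 constraints, dot-stimulus metadata, and subjects whose
choices and RTs are generated from the onset-lag DDM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ddm import (
    DDMParams,
    ModelVariant,
    OptionPair,
    VARIANTS,
    simulate_trial,
)

__all__ = [
    "FEEDBACK_COUNTS",
    "STATUS_BY_FEEDBACK",
    "N_SESSIONS_STUDY1",
    "TRIALS_PER_SESSION",
    "FeedbackSchedule",
    "TrialRecord",
    "CohortSpec",
    "OptionSetError",
    "generate_option_set",
    "generate_feedback_schedule",
    "generate_dot_counts",
    "generate_synthetic_subject",
    "generate_cohort",
    "records_to_frame",
    "session_of_trial",
]

FEEDBACK_COUNTS = {"BC": 60, "BW": 60, "SC": 90, "SW": 90}
STATUS_BY_FEEDBACK = {"BC": "equal", "BW": "equal", "SC": "better", "SW": "worse"}
N_SESSIONS_STUDY1 = 5
TRIALS_PER_SESSION = 60


class OptionSetError(RuntimeError):
    """Raised when the payoff-correlation constraints cannot be met."""


@dataclass(frozen=True)
class FeedbackSchedule:
    """Ordered feedback codes with their derived status labels."""

    trial_feedback: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = {k: self.trial_feedback.count(k) for k in FEEDBACK_COUNTS}
        n = len(self.trial_feedback)
        if n % 10 != 0 or any(
            counts[k] * 300 != FEEDBACK_COUNTS[k] * n for k in FEEDBACK_COUNTS
        ):
            raise ValueError(
                f"feedback counts {counts} do not follow the 60:60:90:90 proportions"
            )

    @property
    def status_labels(self) -> tuple[str, ...]:
        return tuple(STATUS_BY_FEEDBACK[f] for f in self.trial_feedback)

    def __len__(self) -> int:
        return len(self.trial_feedback)


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    trial_index: int
    status: str
    options: OptionPair
    choice: int | None = None
    rt: float | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.rt is not None and not self.rt > 0:
            raise ValueError("rt must be positive when present")
        if self.status not in ("better", "equal", "worse"):
            raise ValueError(f"unknown status {self.status!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: per-group sizes and generating parameter presets."""

    n_subjects: int
    group_params: Mapping[str, DDMParams]
    seed: int
    variant_id: int = 2
    n_trials: int = 300
    t_max: float = 10.0


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def generate_option_set(
    n_trials: int, seed: int | np.random.Generator, max_tries: int = 10_000
) -> list[OptionPair]:
    """Rejection-sample a dictator-game option set.

    Payoffs are uniform integers on [1, 20].  Whole candidate sets are
    resampled until, after relabelling options so the larger-self-payoff
    option comes first, |corr(self, other)| <= 0.1 within each option and
    |corr(delta_ms, delta_mo)| <= 0.1.  Resampling whole sets (rather than
    repairing single trials) keeps the marginal payoff distribution uniform.
    """
    if n_trials < 10:
        raise ValueError("n_trials must be >= 10 for the correlation constraints to be meaningful")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    last_violation = "no attempt made"
    for _ in range(max_tries):
        pay = rng.integers(1, 21, size=(n_trials, 4))
        ms1, mo1, ms2, mo2 = pay.T.copy()
        # resample ties in self-payoff so the delta_ms > 0 relabelling exists
        ties = ms1 == ms2
        while np.any(ties):
            ms2[ties] = rng.integers(1, 21, size=int(ties.sum()))
            ties = ms1 == ms2
        flip = ms1 < ms2
        ms1[flip], ms2[flip] = ms2[flip], ms1[flip].copy()
        mo1[flip], mo2[flip] = mo2[flip], mo1[flip].copy()
        r1 = _corr(ms1, mo1)
        r2 = _corr(ms2, mo2)
        rd = _corr(ms1 - ms2, mo1 - mo2)
        if abs(r1) > 0.1:
            last_violation = f"|corr(ms1, mo1)| = {abs(r1):.3f} > 0.1"
        elif abs(r2) > 0.1:
            last_violation = f"|corr(ms2, mo2)| = {abs(r2):.3f} > 0.1"
        elif abs(rd) > 0.1:
            last_violation = f"|corr(delta_ms, delta_mo)| = {abs(rd):.3f} > 0.1"
        else:
            return [
                OptionPair(int(a), int(b), int(c), int(d))
                for a, b, c, d in zip(ms1, mo1, ms2, mo2)
            ]
    raise OptionSetError(
        f"option-set constraints not satisfied in {max_tries} tries; last: {last_violation}"
    )


def generate_feedback_schedule(seed: int | np.random.Generator) -> FeedbackSchedule:
    """Random permutation of the fixed feedback multiset (60/60/90/90)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = np.array(
        ["BC"] * FEEDBACK_COUNTS["BC"]
        + ["BW"] * FEEDBACK_COUNTS["BW"]
        + ["SC"] * FEEDBACK_COUNTS["SC"]
        + ["SW"] * FEEDBACK_COUNTS["SW"]
    )
    rng.shuffle(codes)
    return FeedbackSchedule(trial_feedback=tuple(codes.tolist()))


def generate_dot_counts(
    n_trials: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Dot-stimulus metadata: two unequal counts per trial, uniform on [32, 34].

    The stimulus is metadata only (never rendered); the covert feedback
    schedule overrides actual dot accuracy downstream.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = rng.integers(32, 35, size=(n_trials, 2))
    ties = counts[:, 0] == counts[:, 1]
    while np.any(ties):
        counts[ties, 1] = rng.integers(32, 35, size=int(ties.sum()))
        ties = counts[:, 0] == counts[:, 1]
    return counts


def session_of_trial(trial_index: int) -> int:
    """Study-1 session block (0-based) for a 0-based trial index."""
    return trial_index // TRIALS_PER_SESSION


def generate_synthetic_subject(
    params: DDMParams,
    schedule: FeedbackSchedule,
    options: Sequence[OptionPair],
    seed: int | np.random.Generator,
    subject_id: str = "s0",
    variant: ModelVariant | None = None,
    t_max: float = 10.0,
) -> list[TrialRecord]:
    """Play every trial of a design through the onset-lag DDM.

    Censored simulations (no boundary hit within ``t_max``) are kept and
    flagged, never dropped.
    """
    if len(schedule) != len(options):
        raise ValueError(
            f"design length mismatch: {len(schedule)} feedback trials vs {len(options)} option pairs"
        )
    variant = variant if variant is not None else VARIANTS[2]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    records: list[TrialRecord] = []
    for i, (status, pair) in enumerate(zip(schedule.status_labels, options)):
        out = simulate_trial(params, variant, status, pair, rng, t_max=t_max)
        records.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=i,
                status=status,
                options=pair,
                choice=out.choice,
                rt=out.rt,
                censored=out.censored,
            )
        )
    return records


def records_to_frame(records: Sequence[TrialRecord], group: str | None = None) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "group": group,
                "trial_index": r.trial_index,
                "status": r.status,
                "ms1": r.options.ms1,
                "mo1": r.options.mo1,
                "ms2": r.options.ms2,
                "mo2": r.options.mo2,
                "choice": r.choice,
                "rt": r.rt,
                "censored": r.censored,
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a full synthetic cohort, one independent design per subject.

    Every subject gets an independent RNG stream spawned from the cohort
    seed, so the output is bit-identical across runs with the same spec.
    """
    variant = VARIANTS[spec.variant_id]
    root = np.random.SeedSequence(spec.seed)
    frames: list[pd.DataFrame] = []
    idx = 0
    for group, params in spec.group_params.items():
        for j in range(spec.n_subjects):
            ss = root.spawn(1)[0]
            design_rng, sim_rng = (np.random.default_rng(s) for s in ss.spawn(2))
            options = generate_option_set(spec.n_trials, design_rng)
            schedule = _schedule_for_length(spec.n_trials, design_rng)
            sid = f"{group[:4]}{j:02d}"
            recs = generate_synthetic_subject(
                params, schedule, options, sim_rng, subject_id=sid,
                variant=variant, t_max=spec.t_max,
            )
            frames.append(records_to_frame(recs, group=group))
            idx += 1
    return pd.concat(frames, ignore_index=True)


def _schedule_for_length(n_trials: int, rng: np.random.Generator) -> FeedbackSchedule:
    """Full 300-trial schedule, or a proportionally scaled one for short designs."""
    if n_trials == 300:
        return generate_feedback_schedule(rng)
    if n_trials % 10 != 0:
        raise ValueError("n_trials must be a multiple of 10 to keep the 2:2:3:3 feedback ratio")
    k = n_trials // 10
    codes = ["BC"] * (2 * k) + ["BW"] * (2 * k) + ["SC"] * (3 * k) + ["SW"] * (3 * k)
    arr = np.array(codes)
    rng.shuffle(arr)
    return FeedbackSchedule(trial_feedback=tuple(arr.tolist()))
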