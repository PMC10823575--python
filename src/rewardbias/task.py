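"""Trial-level handling of the probabilistic reward task (PRT).

The task presents, in each of three 100-trial blocks, 50 "long" and 50
"short" mouth stimuli; one stimulus type (the *rich* role) is rewarded three
times as often as the other (*lean*).  The signal-detection response bias

    RB = 1/2 * ln( (rich_correct * lean_incorrect) / (rich_incorrect * lean_correct) )

measures the drift of the decision criterion toward the rich response,
regardless of accuracy.  This module owns the trial-log schema, reaction-time
and exclusion filtering, the 2x2 count tabulation per block, and the RB
statistic itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "BlockCounts",
    "ResponseBias",
    "ExclusionReason",
    "ExclusionReport",
    "validate_trials",
    "read_trials",
    "write_trials",
    "filter_trials",
    "tabulate_block",
    "response_bias",
]

#: Exact column order of the trial-log CSV dialect.
TRIAL_COLUMNS = [
    "participant_id",
    "session",
    "stimulation",
    "phase",
    "block",
    "trial",
    "stimulus",
    "role",
    "response",
    "correct",
    "rewarded",
    "rt_ms",
]

_ENUMS = {
    "stimulation": {"active", "sham"},
    "phase": {"pre", "post"},
    "stimulus": {"long", "short"},
    "role": {"rich", "lean"},
    "response": {"long", "short", "none"},
}


class TrialValidationError(ValueError):
    pass


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial log against the schema; returns a normalized copy.

    Checks column presence, enumeration values, index ranges (block 1-3,
    trial 1-100), boolean coding, non-negative RTs, the reward-implies-
    correct invariant, and that the rich/lean role is a fixed function of
    the stimulus within one (participant, session, phase).
    """
    if len(trials) == 0:
        raise TrialValidationError("empty trial log: no data to analyse")
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise TrialValidationError(f"trial log is missing columns: {missing}")
    out = trials[TRIAL_COLUMNS].copy()
    for col in ("session", "block", "trial"):
        out[col] = pd.to_numeric(out[col], errors="raise").astype(int)
    for col in ("correct", "rewarded"):
        vals = set(pd.unique(out[col].astype(int)))
        if not vals <= {0, 1}:
            raise TrialValidationError(f"column {col!r} must be 0/1, found {vals}")
        out[col] = out[col].astype(int).astype(bool)
    out["rt_ms"] = pd.to_numeric(out["rt_ms"], errors="raise").astype(float)
    for col, allowed in _ENUMS.items():
        out[col] = out[col].astype(str).str.lower()
        bad = set(out[col].unique()) - allowed
        if bad:
            raise TrialValidationError(f"column {col!r} has invalid values {bad}")
    if not out["session"].isin([1, 2]).all():
        raise TrialValidationError("session must be 1 or 2")
    if not out["block"].between(1, 3).all():
        raise TrialValidationError("block indices must lie in 1..3")
    if not out["trial"].between(1, 100).all():
        raise TrialValidationError("trial indices must lie in 1..100")
    if (out["rt_ms"] < 0).any():
        raise TrialValidationError("rt_ms must be non-negative")
    if (out["rewarded"] & ~out["correct"]).any():
        raise TrialValidationError("rewarded trials must be correct")
    role_map = out.groupby(
        ["participant_id", "session", "phase", "stimulus"], observed=True
    )["role"].nunique()
    if (role_map > 1).any():
        raise TrialValidationError(
            "role must be a fixed function of stimulus within (participant, session, phase)"
        )
    return out


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV."""
    return validate_trials(pd.read_csv(path))


def write_trials(trials: pd.DataFrame, path) -> None:
    out = trials[TRIAL_COLUMNS].copy()
    out["correct"] = out["correct"].astype(int)
    out["rewarded"] = out["rewarded"].astype(int)
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class BlockCounts:
    """The 2x2 rich/lean x correct/incorrect table of retained trials in one block."""

    rich_correct: int
    rich_incorrect: int
    lean_correct: int
    lean_incorrect: int

    def __post_init__(self) -> None:
        counts = self.as_tuple()
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if sum(counts) > 100:
            raise ValueError("a block holds at most 100 trials")
        if self.rich_correct + self.rich_incorrect > 50 or self.lean_correct + self.lean_incorrect > 50:
            raise ValueError("each role contributes at most 50 trials per block")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.rich_correct, self.rich_incorrect, self.lean_correct, self.lean_incorrect)

    @property
    def total(self) -> int:
        return sum(self.as_tuple())

    def swapped(self) -> "BlockCounts":
        """Rich and lean labels exchanged (negates the response bias)."""
        return BlockCounts(self.lean_correct, self.lean_incorrect,
                           self.rich_correct, self.rich_incorrect)


@dataclass(frozen=True)
class ResponseBias:
    """RB in natural-log units; ``corrected`` marks the zero-cell +0.5 adjustment."""

    value: float
    corrected: bool = False


class ExclusionReason(str, Enum):
    ONE_KEY_RESPONDER = "one_key_responder"
    RT_VIOLATION_RATE = "rt_violation_rate"
    INCOMPLETE_SESSIONS = "incomplete_sessions"
    TECHNICAL = "technical"
    NONE = "none"


@dataclass(frozen=True)
class ExclusionReport:
    participant_id: str
    excluded: bool
    reason: ExclusionReason
    rt_violation_fraction: float

    def __post_init__(self) -> None:
        if self.excluded != (self.reason is not ExclusionReason.NONE):
            raise ValueError("excluded flag must agree with the reason")


def filter_trials(
    trials: pd.DataFrame,
    rt_low: float = 200.0,
    rt_high: float = 2000.0,
    violation_threshold: float = 0.10,
) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Drop unusable trials and flag participants for exclusion.

    A trial is retained when ``rt_low <= rt_ms <= rt_high`` and a response was
    made.  Missing responses count toward the violation budget alongside
    out-of-range RTs.  A participant is flagged when the violating fraction
    exceeds ``violation_threshold`` (10%), when all responses within a session
    used one key, or when a session is missing entirely.  Retained trials are
    returned for *all* participants; callers drop flagged participants using
    the reports.
    """
    if not rt_low < rt_high:
        raise ValueError("rt_low must be below rt_high")
    trials = validate_trials(trials)
    ok_rt = trials["rt_ms"].between(rt_low, rt_high)
    responded = trials["response"] != "none"
    retained = trials[ok_rt & responded].copy()

    reports: list[ExclusionReport] = []
    for pid, sub in trials.groupby("participant_id", sort=True, observed=True):
        frac = float((~(sub["rt_ms"].between(rt_low, rt_high)) | (sub["response"] == "none")).mean())
        sessions = set(sub["session"].unique())
        one_key = any(
            sess_sub.loc[sess_sub["response"] != "none", "response"].nunique() <= 1
            for _, sess_sub in sub.groupby("session", observed=True)
        )
        if sessions != {1, 2}:
            reason = ExclusionReason.INCOMPLETE_SESSIONS
        elif one_key:
            reason = ExclusionReason.ONE_KEY_RESPONDER
        elif frac > violation_threshold:
            reason = ExclusionReason.RT_VIOLATION_RATE
        else:
            reason = ExclusionReason.NONE
        reports.append(
            ExclusionReport(
                participant_id=str(pid),
                excluded=reason is not ExclusionReason.NONE,
                reason=reason,
                rt_violation_fraction=frac,
            )
        )
    return retained, reports


def tabulate_block(trials: pd.DataFrame) -> BlockCounts:
    """Partition one participant-block of retained trials by role x correctness."""
    keys = trials[["participant_id", "session", "phase", "block"]].drop_duplicates()
    if len(keys) != 1:
        raise TrialValidationError(
            "tabulate_block expects trials from a single (participant, session, phase, block)"
        )
    rich = trials["role"] == "rich"
    correct = trials["correct"].astype(bool)
    return BlockCounts(
        rich_correct=int((rich & correct).sum()),
        rich_incorrect=int((rich & ~correct).sum()),
        lean_correct=int((~rich & correct).sum()),
        lean_incorrect=int((~rich & ~correct).sum()),
    )


def response_bias(counts: BlockCounts) -> ResponseBias:
    """Signal-detection response bias of one block's 2x2 count table.

    ``RB = 0.5 * ln((rich_correct * lean_incorrect) / (rich_incorrect * lean_correct))``,
    with 0.5 added to all four cells when any is zero (the standard log-linear
    correction), flagged via ``corrected``.
    """
    rc, ri, lc, li = (float(c) for c in counts.as_tuple())
    if rc + ri + lc + li == 0:
        raise ValueError("empty block: all four counts are zero")
    corrected = min(rc, ri, lc, li) == 0
    if corrected:
        rc, ri, lc, li = rc + 0.5, ri + 0.5, lc + 0.5, li + 0.5
    return ResponseBias(value=0.5 * math.log((rc * li) / (ri * lc)), corrected=corrected)
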