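"""Reduction of factorial repeated-measures designs to one-df effect summaries.

Every Bayes test in the analysis consumes an ``EffectSummary`` — a mean
difference with its standard error and df.  The reductions here turn
per-participant cell tables (response bias by stimulation/phase/block, or
questionnaire scores by stimulation/timepoint) into such summaries:

* a paired difference between two cells,
* the double-baselined mood index ``(post - pre)_active - (post - pre)_sham``,
* the linear contrast ``(A1-S1) - .5(A2-S2) - .5(A3-S3)`` reducing the
  2 (stimulation) x 3 (block) interaction,
* the same contrast differenced across pre/post for the three-way
  interaction, optionally on covariate-adjusted cell values.

The unit of analysis is the per-participant contrast score, so the standard
error and ``df = n - 1`` of each summary are those of an ordinary paired
t-style test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import EffectSummary

__all__ = [
    "ContrastSpec",
    "DegenerateContrastError",
    "pivot_cells",
    "summarize_scores",
    "paired_difference",
    "double_baseline_index",
    "interaction_contrast_2x3",
    "interaction_contrast_2x2x3",
    "ancova_adjusted_cells",
]


class DegenerateContrastError(ValueError):
    """Raised when per-participant scores have zero variance (SE would be 0)."""


@dataclass(frozen=True)
class ContrastSpec:
    """Named weights over cells; difference contrasts must have zero-sum weights."""

    name: str
    weights: dict

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError("contrast weights must be non-empty")


#: Linear contrast isolating block 1 against the mean of blocks 2 and 3.
BLOCK_CONTRAST = {1: 1.0, 2: -0.5, 3: -0.5}


def pivot_cells(
    df: pd.DataFrame, value: str, cell_cols: list[str], index: str = "participant_id"
) -> pd.DataFrame:
    """Wide per-participant cell table; raises if any participant misses a cell."""
    wide = df.pivot_table(index=index, columns=cell_cols, values=value, aggfunc="mean")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise ValueError(f"incomplete cell table; missing values in cells {missing}")
    return wide


def summarize_scores(scores: np.ndarray, allow_degenerate: bool = False) -> EffectSummary:
    """Per-participant scores -> EffectSummary(mean, sd/sqrt(n), df=n-1, n)."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 2:
        raise ValueError("at least two participants are required")
    se = float(np.std(scores, ddof=1) / math.sqrt(n))
    if se == 0 and not allow_degenerate:
        raise DegenerateContrastError(
            "per-participant scores are constant; SE = 0 cannot feed a Bayes test"
        )
    return EffectSummary(mean=float(np.mean(scores)), se=max(se, np.finfo(float).tiny),
                         df=n - 1, n=n)


def _column(wide: pd.DataFrame, key) -> np.ndarray:
    if key not in wide.columns:
        raise KeyError(f"cell {key!r} missing from the cell table")
    return wide[key].to_numpy(dtype=float)


def paired_difference(wide: pd.DataFrame, a, b) -> EffectSummary:
    """Within-participant difference between cells ``a`` and ``b``."""
    return summarize_scores(_column(wide, a) - _column(wide, b))


def double_baseline_index(
    wide: pd.DataFrame,
    active_post,
    active_pre,
    sham_post,
    sham_pre,
    sign_flip: bool = False,
) -> EffectSummary:
    """Double-baselined change index: (post-pre under active) - (post-pre under sham).

    ``sign_flip`` negates the index, for measures where the hypothesised
    benefit is a *decrease* (e.g. reading a drop in negative affect as a
    positive treatment effect).  The default orientation matches the raw
    active-minus-sham change difference.
    """
    idx = (_column(wide, active_post) - _column(wide, active_pre)) - (
        _column(wide, sham_post) - _column(wide, sham_pre)
    )
    if sign_flip:
        idx = -idx
    return summarize_scores(idx)


def _stim_block_contrast(
    wide: pd.DataFrame, key, weights: dict[int, float]
) -> np.ndarray:
    """Per-participant sum of w_b * (active_b - sham_b) given a cell-key factory."""
    score = np.zeros(len(wide))
    for block, w in weights.items():
        score += w * (_column(wide, key("active", block)) - _column(wide, key("sham", block)))
    return score


def interaction_contrast_2x3(
    wide: pd.DataFrame, key=None, weights: dict[int, float] | None = None
) -> EffectSummary:
    """Reduce the stimulation x block interaction to one df.

    Per participant: ``(A1-S1) - .5*(A2-S2) - .5*(A3-S3)`` where ``A_b``/``S_b``
    are the active/sham cell values in block ``b``.  ``key(stimulation, block)``
    maps to the cell-table column (default: the tuple itself).
    """
    key = key or (lambda stim, block: (stim, block))
    weights = weights if weights is not None else BLOCK_CONTRAST
    if not math.isclose(sum(weights.values()), 0.0, abs_tol=1e-12):
        raise ValueError("difference-contrast weights must sum to zero")
    return summarize_scores(_stim_block_contrast(wide, key, weights))


def interaction_contrast_2x2x3(
    wide: pd.DataFrame, key=None, weights: dict[int, float] | None = None
) -> EffectSummary:
    """Reduce the time x stimulation x block interaction to one df.

    Per participant: ``L(post) - L(pre)`` where ``L(t)`` is the 2x3 contrast
    at time ``t``.  ``key(phase, stimulation, block)`` maps to the cell
    column (default: the tuple itself).
    """
    key = key or (lambda phase, stim, block: (phase, stim, block))
    weights = weights if weights is not None else BLOCK_CONTRAST
    if not math.isclose(sum(weights.values()), 0.0, abs_tol=1e-12):
        raise ValueError("difference-contrast weights must sum to zero")
    post = _stim_block_contrast(wide, lambda s, b: key("post", s, b), weights)
    pre = _stim_block_contrast(wide, lambda s, b: key("pre", s, b), weights)
    return summarize_scores(post - pre)


def ancova_adjusted_cells(wide: pd.DataFrame, covariate: pd.Series) -> pd.DataFrame:
    """Covariate-adjusted per-participant cell values.

    Within each cell the value is regressed on the grand-mean-centred
    covariate; the adjusted value removes the fitted covariate component,
    ``y_i - b_cell * (x_i - mean(x))``, i.e. each participant's value is
    evaluated at the grand covariate mean.  Cell means are unchanged in a
    fully-within design (every participant sits in every cell); what changes
    is the participant-level spread feeding downstream contrast SEs.
    """
    cov = covariate.reindex(wide.index)
    if cov.isna().any():
        raise ValueError("covariate missing for some participants in the cell table")
    x = cov.to_numpy(dtype=float)
    xc = x - x.mean()
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("constant covariate: adjustment is undefined")
    adjusted = {}
    for col in wide.columns:
        y = wide[col].to_numpy(dtype=float)
        slope = float(np.sum(xc * (y - y.mean())) / sxx)
        adjusted[col] = y - slope * xc
    out = pd.DataFrame(adjusted, index=wide.index)
    out.columns = wide.columns
    return out
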