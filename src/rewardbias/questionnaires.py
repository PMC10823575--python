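"""Scoring of the PANAS and TEPS questionnaires, and floor-effect detection.

PANAS: 20 adjectives rated 1-5; ten positive-affect (PA) and ten
negative-affect (NA) items, each subscale the plain sum (range 10-50).
TEPS: 18 items split into anticipatory (TEPS-ANT, 10 items) and
consummatory (TEPS-CON, 8 items) pleasure; their sum indexes hedonic
capacity.  Item-to-subscale maps are configuration; the shipped defaults
follow the published instruments (1-based item positions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PANAS_PA_ITEMS",
    "PANAS_NA_ITEMS",
    "TEPS_ANT_ITEMS",
    "TEPS_CON_ITEMS",
    "QuestionnaireScore",
    "score_panas",
    "score_teps",
    "floor_effect_rate",
    "read_questionnaires",
]

# Standard published item assignments (1-based positions on the form).
PANAS_PA_ITEMS = (1, 3, 5, 9, 10, 12, 14, 16, 17, 19)
PANAS_NA_ITEMS = (2, 4, 6, 7, 8, 11, 13, 15, 18, 20)
TEPS_ANT_ITEMS = (1, 4, 6, 8, 10, 11, 12, 15, 16, 18)
TEPS_CON_ITEMS = (2, 3, 5, 7, 9, 13, 14, 17)


@dataclass(frozen=True)
class QuestionnaireScore:
    panas_pa: int
    panas_na: int
    teps_ant: int
    teps_con: int

    @property
    def teps_total(self) -> int:
        return self.teps_ant + self.teps_con


def _check_items(items, n_expected: int, low: int, high: int, name: str) -> np.ndarray:
    arr = np.asarray(list(items))
    if arr.shape != (n_expected,):
        raise ValueError(f"{name} expects exactly {n_expected} items, got {arr.shape}")
    if not np.issubdtype(arr.dtype, np.number) or np.any(arr != np.round(arr)):
        raise ValueError(f"{name} items must be integers")
    arr = arr.astype(int)
    if arr.min() < low or arr.max() > high:
        raise ValueError(f"{name} items must lie in {low}..{high}")
    return arr


def score_panas(
    items,
    pa_items: tuple[int, ...] = PANAS_PA_ITEMS,
    na_items: tuple[int, ...] = PANAS_NA_ITEMS,
) -> tuple[int, int]:
    """Sum the 20 PANAS responses into (PA, NA) using the declared item map."""
    arr = _check_items(items, 20, 1, 5, "PANAS")
    if sorted(pa_items + na_items) != list(range(1, 21)):
        raise ValueError("PA and NA item maps must partition items 1..20")
    pa = int(arr[[i - 1 for i in pa_items]].sum())
    na = int(arr[[i - 1 for i in na_items]].sum())
    return pa, na


def score_teps(
    items,
    ant_items: tuple[int, ...] = TEPS_ANT_ITEMS,
    con_items: tuple[int, ...] = TEPS_CON_ITEMS,
) -> tuple[int, int]:
    """Sum the 18 TEPS responses into (anticipatory, consummatory) subscales."""
    arr = _check_items(items, 18, 1, 6, "TEPS")
    if sorted(ant_items + con_items) != list(range(1, 19)):
        raise ValueError("ANT and CON item maps must partition items 1..18")
    ant = int(arr[[i - 1 for i in ant_items]].sum())
    con = int(arr[[i - 1 for i in con_items]].sum())
    return ant, con


def floor_effect_rate(
    scores, scale_minimum: float, threshold: float = 0.15
) -> tuple[float, bool]:
    """Fraction of measures pinned at the scale minimum; flagged above ``threshold``.

    A measure sitting at the lowest possible value carries no downward
    sensitivity; once more than 15% of measures do so the scale is considered
    floor-limited.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("floor_effect_rate requires a non-empty list of measures")
    rate = float(np.mean(arr == scale_minimum))
    return rate, rate > threshold


def read_questionnaires(path) -> pd.DataFrame:
    """Read the long-format questionnaire CSV.

    Columns: participant_id, timepoint, instrument, item_index, response.
    ``timepoint`` encodes (stimulation, pre/post) as e.g. ``active_pre``;
    ``instrument`` is ``panas`` or ``teps``.
    """
    df = pd.read_csv(path)
    required = {"participant_id", "timepoint", "instrument", "item_index", "response"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"questionnaire file is missing columns: {sorted(missing)}")
    df["instrument"] = df["instrument"].astype(str).str.lower()
    df["item_index"] = df["item_index"].astype(int)
    df["response"] = df["response"].astype(int)
    return df


def score_panas_table(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Score every (participant, timepoint) PANAS administration.

    Returns a frame with columns participant_id, timepoint, pa, na.
    """
    rows = []
    panas = questionnaires[questionnaires["instrument"] == "panas"]
    for (pid, tp), sub in panas.groupby(["participant_id", "timepoint"], observed=True):
        items = sub.sort_values("item_index")["response"].to_numpy()
        pa, na = score_panas(items)
        rows.append({"participant_id": pid, "timepoint": tp, "pa": pa, "na": na})
    return pd.DataFrame(rows)


def score_teps_table(questionnaires: pd.DataFrame) -> pd.DataFrame:
    """Score every participant's TEPS; returns participant_id, teps_ant, teps_con, teps_total."""
    rows = []
    teps = questionnaires[questionnaires["instrument"] == "teps"]
    for pid, sub in teps.groupby("participant_id", observed=True):
        items = sub.sort_values("item_index")["response"].to_numpy()
        ant, con = score_teps(items)
        rows.append(
            {"participant_id": pid, "teps_ant": ant, "teps_con": con, "teps_total": ant + con}
        )
    return pd.DataFrame(rows)
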