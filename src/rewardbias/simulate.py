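"""Generative model of a two-session stimulation study on the probabilistic reward task.

The simulator emulates the registered study design: 30 participants, two
sessions (active and sham stimulation, order counterbalanced), a pre- and a
post-stimulation task administration per session, each of three 100-trial
blocks under the asymmetric 30/10 reward schedule (50 long and 50 short
stimuli per block, 40 planned rewards of which 30 fall on the rich role).

Responders are criterion-learning signal-detection agents: the probability
of responding "long" is a logistic function of ``dprime * stimulus + c``,
where the criterion ``c`` drifts by ``learn_rate`` toward the rich response
after every delivered reward (saturating at +/-3 log-odds).  A lapse
parameter mixes in uniform guessing; reaction times are lognormal.  The
``stim_effect`` parameter injects a known criterion shift in post-active
administrations only, giving every downstream analysis a recoverable ground
truth.  PANAS/TEPS item responses are generated from latent normal mood
with declared condition shifts, rounded and clipped to the Likert range.

All randomness flows from a single root seed; each participant owns a
spawned stream, so any participant can be re-simulated independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .questionnaires import PANAS_NA_ITEMS, PANAS_PA_ITEMS
from .task import TRIAL_COLUMNS, write_trials

__all__ = [
    "ScheduleSpec",
    "StudyDesign",
    "AgentParams",
    "PopulationParams",
    "MoodEffects",
    "build_schedule",
    "simulate_participant",
    "simulate_study",
    "StudyData",
    "generate_fixture",
]


@dataclass(frozen=True)
class ScheduleSpec:
    """The asymmetric reinforcement schedule of one task administration."""

    n_blocks: int = 3
    trials_per_block: int = 100
    long_per_block: int = 50
    short_per_block: int = 50
    rewards_per_block: int = 40
    rich_rewards: int = 30
    lean_rewards: int = 10

    def __post_init__(self) -> None:
        if self.long_per_block + self.short_per_block != self.trials_per_block:
            raise ValueError("long + short stimuli must fill the block")
        if self.rich_rewards + self.lean_rewards != self.rewards_per_block:
            raise ValueError("rich + lean rewards must sum to rewards_per_block")
        if self.rich_rewards > min(self.long_per_block, self.short_per_block):
            raise ValueError("infeasible schedule: more rich rewards than rich-role trials")
        if self.lean_rewards > min(self.long_per_block, self.short_per_block):
            raise ValueError("infeasible schedule: more lean rewards than lean-role trials")


@dataclass(frozen=True)
class StudyDesign:
    """Participants, sessions, and counterbalancing of the simulated study."""

    n_participants: int = 30
    n_cap: int = 30

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least two participants")

    def stimulation_order(self, i: int) -> tuple[str, str]:
        """Session-1/session-2 stimulation for participant ``i``; half active-first."""
        return ("active", "sham") if i % 2 == 0 else ("sham", "active")


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated responder."""

    dprime: float = 1.2
    criterion0: float = 0.0
    learn_rate: float = 0.005
    lapse: float = 0.05
    stim_effect: float = 0.0
    rt_meanlog: float = 6.1
    rt_sdlog: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dprime < 0:
            raise ValueError("dprime must be non-negative")
        if not 0 <= self.lapse <= 1:
            raise ValueError("lapse must lie in [0, 1]")
        if self.rt_sdlog <= 0:
            raise ValueError("rt_sdlog must be positive")


@dataclass(frozen=True)
class PopulationParams:
    """Between-participant distribution from which agents are drawn.

    Means match a typical healthy PRT sample: ~77% accuracy (dprime 1.2),
    a per-reward criterion drift that accumulates to a block-3 response bias
    of roughly 0.2 log-units, a small lapse rate and ~450 ms median RTs.
    ``criterion_sd`` jitters the starting criterion of each administration.
    """

    dprime_mean: float = 1.2
    dprime_sd: float = 0.25
    learn_rate_mean: float = 0.002
    learn_rate_sd: float = 0.001
    criterion_sd: float = 0.15
    lapse: float = 0.05
    stim_effect: float = 0.0
    rt_meanlog: float = 6.1
    rt_sdlog: float = 0.35


@dataclass(frozen=True)
class MoodEffects:
    """Latent post-minus-pre shifts (PANAS sum-score units) per condition."""

    pa_active: float = 0.0
    pa_sham: float = 0.0
    na_active: float = 0.0
    na_sham: float = 0.0


_CRITERION_BOUND = 3.0
_PHASES = ("pre", "post")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _schedule_arrays(
    spec: ScheduleSpec, rng: np.random.Generator, rich_sign: float
) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus signs (+1 long / -1 short) and planned-reward flags for one administration."""
    T = spec.n_blocks * spec.trials_per_block
    stim_sign = np.empty(T)
    planned = np.zeros(T, dtype=bool)
    for b in range(spec.n_blocks):
        sl = slice(b * spec.trials_per_block, (b + 1) * spec.trials_per_block)
        stims = np.concatenate(
            [np.ones(spec.long_per_block), -np.ones(spec.short_per_block)]
        )
        rng.shuffle(stims)
        stim_sign[sl] = stims
        block_planned = np.zeros(spec.trials_per_block, dtype=bool)
        rich_idx = np.flatnonzero(stims == rich_sign)
        lean_idx = np.flatnonzero(stims != rich_sign)
        block_planned[rng.choice(rich_idx, size=spec.rich_rewards, replace=False)] = True
        block_planned[rng.choice(lean_idx, size=spec.lean_rewards, replace=False)] = True
        planned[sl] = block_planned
    return stim_sign, planned


def build_schedule(
    spec: ScheduleSpec, rng: np.random.Generator, rich_stimulus: str = "long"
) -> pd.DataFrame:
    """Trial list for one task administration: stimulus, role and planned rewards.

    Each block holds a shuffled sequence of 50 long and 50 short stimuli;
    the ``rich_stimulus`` carries 30 planned rewards per block and the other
    10, assigned to uniformly random trials of the matching role.
    """
    if rich_stimulus not in ("long", "short"):
        raise ValueError("rich_stimulus must be 'long' or 'short'")
    rich_sign = 1.0 if rich_stimulus == "long" else -1.0
    stim_sign, planned = _schedule_arrays(spec, rng, rich_sign)
    return pd.DataFrame({
        "block": np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block),
        "trial": np.tile(np.arange(1, spec.trials_per_block + 1), spec.n_blocks),
        "stimulus": np.where(stim_sign > 0, "long", "short"),
        "role": np.where(stim_sign == rich_sign, "rich", "lean"),
        "reward_planned": planned,
    })


@dataclass
class _ParticipantDraws:
    """All randomness of one participant, pre-drawn for the vectorized stepper."""

    stim_sign: np.ndarray      # (4, n_trials) +1 long / -1 short
    rich_sign: np.ndarray      # (4,) +1 if long is rich
    planned: np.ndarray        # (4, n_trials) planned-reward flags
    u_choice: np.ndarray       # (4, n_trials)
    rt_ms: np.ndarray          # (4, n_trials)
    c0: np.ndarray             # (4,) starting criterion per administration
    order: tuple[str, str]


def _draw_participant(
    agent: AgentParams,
    order: tuple[str, str],
    spec: ScheduleSpec,
    rng: np.random.Generator,
    criterion_jitter_sd: float = 0.0,
) -> _ParticipantDraws:
    n_trials = spec.n_blocks * spec.trials_per_block
    stim_sign = np.empty((4, n_trials))
    rich_sign = np.empty(4)
    planned = np.empty((4, n_trials), dtype=bool)
    c0 = np.empty(4)
    a = 0
    for s, stim_label in enumerate(order):
        rich_pre_sign = 1.0 if rng.random() < 0.5 else -1.0
        for phase in _PHASES:
            rs = rich_pre_sign if phase == "pre" else -rich_pre_sign
            stim_sign[a], planned[a] = _schedule_arrays(spec, rng, rs)
            rich_sign[a] = rs
            c = agent.criterion0 + criterion_jitter_sd * rng.standard_normal()
            if phase == "post" and stim_label == "active":
                # the stimulation effect is a reward-responsiveness shift:
                # oriented toward whichever stimulus is rich in this administration
                c += agent.stim_effect * rs
            c0[a] = c
            a += 1
    u_choice = rng.random((4, n_trials))
    rt = np.exp(agent.rt_meanlog + agent.rt_sdlog * rng.standard_normal((4, n_trials)))
    rt = np.clip(rt, 1.0, 5000.0)
    return _ParticipantDraws(
        stim_sign=stim_sign, rich_sign=rich_sign, planned=planned,
        u_choice=u_choice, rt_ms=rt, c0=c0, order=order,
    )


def _step_trials(
    draws: list[_ParticipantDraws],
    dprime: np.ndarray,
    learn_rate: np.ndarray,
    lapse: np.ndarray,
    spec: ScheduleSpec,
) -> dict[str, np.ndarray]:
    """Run all agents through all four administrations; returns trial arrays.

    The choice rule mixes uniform guessing (probability ``lapse``) with a
    logistic discrimination rule; a planned reward that lands on an
    incorrect trial is re-queued to the next correct same-role trial of the
    block and dropped at block end.
    """
    P = len(draws)
    n_trials = spec.n_blocks * spec.trials_per_block
    stim_sign = np.stack([d.stim_sign for d in draws])        # (P, 4, T)
    rich_sign = np.stack([d.rich_sign for d in draws])        # (P, 4)
    planned = np.stack([d.planned for d in draws])
    u_choice = np.stack([d.u_choice for d in draws])
    c0 = np.stack([d.c0 for d in draws])

    resp_sign = np.empty((P, 4, n_trials))
    rewarded = np.zeros((P, 4, n_trials), dtype=bool)
    criterion = np.empty((P, 4, n_trials))

    dp = dprime[:, None]
    lr = learn_rate[:, None]
    lp = lapse[:, None]
    for a in range(4):
        c = c0[:, a].copy()
        pending_rich = np.zeros(P, dtype=int)
        pending_lean = np.zeros(P, dtype=int)
        for t in range(n_trials):
            if t % spec.trials_per_block == 0:
                pending_rich[:] = 0
                pending_lean[:] = 0
            x = stim_sign[:, a, t]
            p_long = lp[:, 0] * 0.5 + (1 - lp[:, 0]) * _sigmoid(dp[:, 0] * x + c)
            r = np.where(u_choice[:, a, t] < p_long, 1.0, -1.0)
            resp_sign[:, a, t] = r
            correct = r == x
            is_rich = x == rich_sign[:, a]
            pl = planned[:, a, t]
            deliver = correct & pl
            # re-queued rewards land on correct, unplanned, same-role trials
            use_pending_rich = correct & ~pl & is_rich & (pending_rich > 0)
            use_pending_lean = correct & ~pl & ~is_rich & (pending_lean > 0)
            pending_rich[use_pending_rich] -= 1
            pending_lean[use_pending_lean] -= 1
            missed = ~correct & pl
            pending_rich[missed & is_rich] += 1
            pending_lean[missed & ~is_rich] += 1
            got = deliver | use_pending_rich | use_pending_lean
            rewarded[:, a, t] = got
            c = np.clip(c + np.where(got, lr[:, 0] * rich_sign[:, a], 0.0),
                        -_CRITERION_BOUND, _CRITERION_BOUND)
            criterion[:, a, t] = c
    correct = resp_sign == stim_sign
    return {
        "stim_sign": stim_sign, "resp_sign": resp_sign, "correct": correct,
        "rewarded": rewarded, "rich_sign": rich_sign, "criterion": criterion,
        "planned": planned,
    }


def _administration_meta(order: tuple[str, str]):
    """(session, stimulation, phase) for administrations 0..3."""
    meta = []
    for s, stim in enumerate(order):
        for phase in _PHASES:
            meta.append((s + 1, stim, phase))
    return meta


def _trials_frame(
    pid: str,
    draws: _ParticipantDraws,
    sim: dict[str, np.ndarray],
    i: int,
    spec: ScheduleSpec,
) -> pd.DataFrame:
    n_trials = spec.n_blocks * spec.trials_per_block
    frames = []
    meta = _administration_meta(draws.order)
    blocks = np.repeat(np.arange(1, spec.n_blocks + 1), spec.trials_per_block)
    trials = np.tile(np.arange(1, spec.trials_per_block + 1), spec.n_blocks)
    for a, (session, stim_label, phase) in enumerate(meta):
        x = sim["stim_sign"][i, a]
        r = sim["resp_sign"][i, a]
        frames.append(pd.DataFrame({
            "participant_id": pid,
            "session": session,
            "stimulation": stim_label,
            "phase": phase,
            "block": blocks,
            "trial": trials,
            "stimulus": np.where(x > 0, "long", "short"),
            "role": np.where(x == sim["rich_sign"][i, a], "rich", "lean"),
            "response": np.where(r > 0, "long", "short"),
            "correct": sim["correct"][i, a].astype(bool),
            "rewarded": sim["rewarded"][i, a].astype(bool),
            "rt_ms": np.round(draws.rt_ms[a], 1),
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def simulate_participant(
    agent: AgentParams,
    order: tuple[str, str] = ("active", "sham"),
    spec: ScheduleSpec = ScheduleSpec(),
    participant_id: str = "p01",
    criterion_jitter_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate one participant's four task administrations as a trial log."""
    rng = np.random.default_rng(agent.seed)
    draws = _draw_participant(agent, order, spec, rng, criterion_jitter_sd)
    sim = _step_trials(
        [draws],
        dprime=np.array([agent.dprime]),
        learn_rate=np.array([agent.learn_rate]),
        lapse=np.array([agent.lapse]),
        spec=spec,
    )
    return _trials_frame(participant_id, draws, sim, 0, spec)


def rb_from_sim(sim: dict[str, np.ndarray], spec: ScheduleSpec) -> np.ndarray:
    """Response bias per (agent, administration, block) from stepped trial arrays.

    Applies the same 2x2 tabulation and zero-cell-corrected RB statistic as
    :func:`rewardbias.task.response_bias`, vectorized over cells.
    """
    P = sim["correct"].shape[0]
    T = spec.trials_per_block
    is_rich = sim["stim_sign"] == sim["rich_sign"][:, :, None]
    correct = sim["correct"]
    shape = (P, 4, spec.n_blocks, T)
    rc = (is_rich & correct).reshape(shape).sum(axis=3).astype(float)
    ri = (is_rich & ~correct).reshape(shape).sum(axis=3).astype(float)
    lc = (~is_rich & correct).reshape(shape).sum(axis=3).astype(float)
    li = (~is_rich & ~correct).reshape(shape).sum(axis=3).astype(float)
    needs = (np.minimum(np.minimum(rc, ri), np.minimum(lc, li)) == 0)
    adj = np.where(needs, 0.5, 0.0)
    return 0.5 * np.log(
        ((rc + adj) * (li + adj)) / ((ri + adj) * (lc + adj))
    )


def _draw_study(
    design: StudyDesign,
    population: PopulationParams,
    spec: ScheduleSpec,
    seed: int,
) -> tuple[list[AgentParams], list[_ParticipantDraws], np.random.Generator]:
    """Draw agents and their pre-committed randomness; returns a spare mood RNG."""
    root = np.random.SeedSequence(seed)
    child = root.spawn(design.n_participants + 1)
    seeds = [int(s.generate_state(1)[0] >> 1) for s in child]
    agents: list[AgentParams] = []
    draws: list[_ParticipantDraws] = []
    for i in range(design.n_participants):
        rng = np.random.default_rng(seeds[i])
        agent = AgentParams(
            dprime=max(0.0, population.dprime_mean + population.dprime_sd * rng.standard_normal()),
            criterion0=0.0,
            learn_rate=max(0.0, population.learn_rate_mean + population.learn_rate_sd * rng.standard_normal()),
            lapse=population.lapse,
            stim_effect=population.stim_effect,
            rt_meanlog=population.rt_meanlog,
            rt_sdlog=population.rt_sdlog,
            seed=seeds[i],
        )
        agents.append(agent)
        draws.append(
            _draw_participant(agent, design.stimulation_order(i), spec, rng,
                              population.criterion_sd)
        )
    return agents, draws, np.random.default_rng(seeds[-1])


def _run_study(agents, draws, spec) -> dict[str, np.ndarray]:
    return _step_trials(
        draws,
        dprime=np.array([a.dprime for a in agents]),
        learn_rate=np.array([a.learn_rate for a in agents]),
        lapse=np.array([a.lapse for a in agents]),
        spec=spec,
    )


def simulate_rb_cells(
    design: StudyDesign = StudyDesign(),
    population: PopulationParams = PopulationParams(),
    seed: int = 0,
    spec: ScheduleSpec = ScheduleSpec(),
    return_agents: bool = False,
):
    """Fast path: per-participant response-bias cell table, no trial log.

    Returns a long frame (participant_id, stimulation, phase, block, rb)
    equal to tabulating the full trial log before reaction-time filtering
    (RTs are independent of accuracy in this generator, so the filter only
    thins trials at random); used for simulation studies where only the RB
    cells matter.
    """
    agents, draws, _ = _draw_study(design, population, spec, seed)
    sim = _run_study(agents, draws, spec)
    rb = rb_from_sim(sim, spec)
    rows = []
    for i in range(design.n_participants):
        meta = _administration_meta(draws[i].order)
        for a, (session, stim_label, phase) in enumerate(meta):
            for b in range(spec.n_blocks):
                rows.append({
                    "participant_id": f"p{i + 1:02d}", "session": session,
                    "stimulation": stim_label, "phase": phase,
                    "block": b + 1, "rb": rb[i, a, b],
                })
    out = pd.DataFrame(rows)
    return (out, agents) if return_agents else out


def _likert_items(
    rng: np.random.Generator, target_sum: float, n_items: int, item_sd: float,
    low: int = 1, high: int = 5,
) -> np.ndarray:
    raw = np.round(target_sum / n_items + item_sd * rng.standard_normal(n_items))
    return np.clip(raw, low, high).astype(int)


@dataclass
class StudyData:
    """One simulated study: trial log, questionnaire responses, ground truth."""

    trials: pd.DataFrame
    questionnaires: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trials(self.trials, out / "trials.csv")
        self.questionnaires.to_csv(out / "questionnaires.csv", index=False)
        (out / "ground_truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True))


def simulate_study(
    design: StudyDesign = StudyDesign(),
    population: PopulationParams = PopulationParams(),
    mood: MoodEffects = MoodEffects(),
    seed: int = 0,
    spec: ScheduleSpec = ScheduleSpec(),
    pa_baseline: float = 28.0,
    pa_between_sd: float = 6.0,
    na_baseline: float = 5.0,
    na_between_sd: float = 4.0,
    occasion_sd: float = 3.0,
    item_sd: float = 0.8,
) -> StudyData:
    """Simulate a complete study: trial logs, questionnaires and ground truth.

    Mood baselines emulate a healthy sample: positive affect around 28 with
    real between-participant spread; the *latent* negative affect sits below
    the scale floor (sum-score floor 10), so realized NA scores cluster at
    the minimum — the strongly floor-limited NA distributions healthy
    samples show (observed means just above 10, a large share of
    administrations exactly at it).
    """
    agents, draws_list, mood_rng = _draw_study(design, population, spec, seed)
    pids = [f"p{i + 1:02d}" for i in range(design.n_participants)]
    sim = _run_study(agents, draws_list, spec)
    trials = pd.concat(
        [_trials_frame(pids[i], draws_list[i], sim, i, spec) for i in range(design.n_participants)],
        ignore_index=True,
    )

    # questionnaires: PANAS at the four (stimulation, pre/post) timepoints + TEPS once
    q_rows = []
    for i, pid in enumerate(pids):
        pa_base = pa_baseline + pa_between_sd * mood_rng.standard_normal()
        na_base = na_baseline + na_between_sd * mood_rng.standard_normal()
        for stim in ("active", "sham"):
            for phase in _PHASES:
                pa_shift = getattr(mood, f"pa_{stim}") if phase == "post" else 0.0
                na_shift = getattr(mood, f"na_{stim}") if phase == "post" else 0.0
                pa_latent = pa_base + pa_shift + occasion_sd * mood_rng.standard_normal()
                na_latent = na_base + na_shift + occasion_sd * mood_rng.standard_normal()
                pa_items = _likert_items(mood_rng, pa_latent, 10, item_sd)
                na_items = _likert_items(mood_rng, na_latent, 10, item_sd)
                responses = np.empty(20, dtype=int)
                for j, pos in enumerate(PANAS_PA_ITEMS):
                    responses[pos - 1] = pa_items[j]
                for j, pos in enumerate(PANAS_NA_ITEMS):
                    responses[pos - 1] = na_items[j]
                for idx, resp in enumerate(responses, start=1):
                    q_rows.append({
                        "participant_id": pid, "timepoint": f"{stim}_{phase}",
                        "instrument": "panas", "item_index": idx, "response": int(resp),
                    })
        teps_latent = 76.0 + 8.0 * mood_rng.standard_normal()
        teps_items = _likert_items(mood_rng, teps_latent, 18, 0.9, low=1, high=6)
        for idx, resp in enumerate(teps_items, start=1):
            q_rows.append({
                "participant_id": pid, "timepoint": "baseline",
                "instrument": "teps", "item_index": idx, "response": int(resp),
            })
    questionnaires = pd.DataFrame(q_rows)

    truth = {
        "seed": seed,
        "design": asdict(design),
        "population": asdict(population),
        "mood_effects": asdict(mood),
        "participants": [
            {"participant_id": pids[i], "order": list(design.stimulation_order(i)),
             "seed": agents[i].seed, "dprime": agents[i].dprime,
             "learn_rate": agents[i].learn_rate, "stim_effect": agents[i].stim_effect}
            for i in range(design.n_participants)
        ],
    }
    return StudyData(trials=trials, questionnaires=questionnaires, truth=truth)


_FIXTURE_KINDS = {
    "null": {},
    "effectful": {"population": PopulationParams(stim_effect=0.3)},
    "paper_like": {
        "population": PopulationParams(),
        "mood": MoodEffects(pa_active=-2.9, pa_sham=-1.6, na_active=0.0, na_sham=0.0),
    },
}


def generate_fixture(kind: str, seed: int, out_dir=None) -> StudyData:
    """Preset study bundles: ``null`` (all effects zero), ``effectful``
    (criterion shift +0.3 in post-active), ``paper_like`` (no task effect,
    positive affect dropping after stimulation, NA floor-limited)."""
    if kind not in _FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {sorted(_FIXTURE_KINDS)}")
    data = simulate_study(seed=seed, **_FIXTURE_KINDS[kind])
    if out_dir is not None:
        data.write(out_dir)
    return data
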