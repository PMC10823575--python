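"""End-to-end analysis of a reward-responsiveness stimulation study.

``RewardResponsivenessStudy`` is the model object: it is built from a
trial log and questionnaire responses (plus an ``AnalysisConfig``), and its
``fit()`` runs the registered analysis suite in order — exclusions,
response-bias cells, the primary one-df active-vs-sham block-1 Bayes test,
the double-baselined mood indices, both interaction replications (the 2x3
stimulation-by-block contrast and the covariate-adjusted 2x2x3 contrast),
the block-3 manipulation checks, the floor-effect screen, and the
sequential stopping rule — returning a ``StudyResults`` carrying every
effect summary, Bayes factor, and frequentist companion, with a
``summary()`` rendering and a flat machine-readable ``metrics`` map.

Every Bayes test is also invocable directly from a ``(mean, se, df)``
triple through :mod:`rewardbias.bayes`; the trial-level path here exists so
synthetic studies exercise the whole chain.

Priors are registered per source study.  Two scale conventions are carried:
``prior()`` uses the source study's *SD* (the convention under which the
informed Bayes factors of the replication report reproduce), while
``design_prior()`` uses the source *SE* (the convention of the sequential
design analysis).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import contrasts, questionnaires, task
from .bayes import (
    BayesFactorResult,
    Direction,
    EffectSummary,
    PriorModel,
    default_onesample_bf,
    expected_bf_under_null,
    informed_bf,
    scale_se,
    stopping_rule,
    StoppingDecision,
)
from .frequentist import TTestResult, one_sample_t, paired_t, rm_ancova, rm_anova

__all__ = [
    "SourceStudy",
    "SOURCE_STUDIES",
    "AnalysisConfig",
    "RewardResponsivenessStudy",
    "StudyResults",
]


@dataclass(frozen=True)
class SourceStudy:
    """A published one-df effect used as an informed prior: mean, SE, SD, n."""

    name: str
    mean: float
    se: float
    n: int
    sd: float | None = None

    @property
    def df(self) -> int:
        return self.n - 1

    @property
    def sd_(self) -> float:
        return self.sd if self.sd is not None else self.se * math.sqrt(self.n)

    def prior(self, direction: str | Direction = Direction.TWO_SIDED) -> PriorModel:
        """Reporting-convention prior: shifted t at the source SD scale."""
        return PriorModel(family="shifted_t", location=self.mean, scale=self.sd_,
                          df=self.df, direction=direction)

    def design_prior(self, direction: str | Direction = Direction.TWO_SIDED) -> PriorModel:
        """Design-analysis prior: shifted t at the source SE scale."""
        return PriorModel(family="shifted_t", location=self.mean, scale=self.se,
                          df=self.df, direction=direction)


#: Source effects behind the registered priors.  RB effects are in response-bias
#: log-units; mood effects in PANAS sum-score points.
SOURCE_STUDIES: dict[str, SourceStudy] = {
    "primary_ahn": SourceStudy("primary_ahn", mean=0.14, se=0.063, n=18, sd=0.26),
    "interaction_ahn": SourceStudy("interaction_ahn", mean=0.16, se=0.08, n=18),
    "interaction_duprat": SourceStudy("interaction_duprat", mean=0.14, se=0.07, n=21, sd=0.33),
    "manipulation_ahn": SourceStudy("manipulation_ahn", mean=0.19, se=0.061, n=18, sd=0.26),
    "manipulation_duprat": SourceStudy("manipulation_duprat", mean=0.26, se=0.070, n=21, sd=0.32),
    "pa_forbes": SourceStudy("pa_forbes", mean=4.91, se=0.82, n=96),
    "na_forbes": SourceStudy("na_forbes", mean=5.92, se=0.94, n=96),
}


@dataclass
class AnalysisConfig:
    """Tunable settings of the registered analysis suite."""

    rt_low: float = 200.0
    rt_high: float = 2000.0
    rt_violation_threshold: float = 0.10
    floor_threshold: float = 0.15
    cauchy_scale: float = math.sqrt(2) / 2
    stopping_upper: float = 6.0
    stopping_lower: float = 1.0 / 6.0
    n_cap: int = 30
    sources: dict[str, SourceStudy] = field(default_factory=lambda: dict(SOURCE_STUDIES))
    seed: int = 0

    def __post_init__(self) -> None:
        required = set(SOURCE_STUDIES)
        missing = required - set(self.sources)
        if missing:
            raise ValueError(f"prior registry is missing entries: {sorted(missing)}")

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        sources = dict(SOURCE_STUDIES)
        for name, spec in (raw.pop("sources", None) or {}).items():
            sources[name] = SourceStudy(name=name, **spec)
        return cls(sources=sources, **raw)


def _cells_key(phase: str, stim: str, block: int):
    return (phase, stim, block)


class RewardResponsivenessStudy:
    """Model object for one study's trial log and questionnaires."""

    def __init__(
        self,
        trials: pd.DataFrame,
        questionnaires_df: pd.DataFrame | None = None,
        config: AnalysisConfig | None = None,
    ) -> None:
        self.config = config or AnalysisConfig()
        self.trials = task.validate_trials(trials)
        self.questionnaires = questionnaires_df
        self.log: list[dict] = []
        self._log("load", trials=self.trials, questionnaires=questionnaires_df)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_csv(
        cls, trials_path, questionnaires_path=None, config: AnalysisConfig | None = None
    ) -> "RewardResponsivenessStudy":
        trials = task.read_trials(trials_path)
        q = questionnaires.read_questionnaires(questionnaires_path) if questionnaires_path else None
        return cls(trials, q, config)

    @classmethod
    def from_frames(cls, trials, questionnaires_df=None, config=None):
        return cls(trials, questionnaires_df, config)

    # -- provenance ------------------------------------------------------
    def _log(self, stage: str, **inputs) -> None:
        digest = {}
        for k, v in inputs.items():
            if v is None:
                continue
            if isinstance(v, pd.DataFrame):
                payload = v.to_csv(index=False).encode()
            else:
                payload = repr(v).encode()
            digest[k] = hashlib.sha256(payload).hexdigest()[:16]
        self.log.append({"stage": stage, "inputs": digest})

    # -- pipeline --------------------------------------------------------
    def fit(self) -> "StudyResults":
        cfg = self.config
        retained, reports = task.filter_trials(
            self.trials, cfg.rt_low, cfg.rt_high, cfg.rt_violation_threshold
        )
        excluded = {r.participant_id for r in reports if r.excluded}
        retained = retained[~retained["participant_id"].astype(str).isin(excluded)]
        if retained["participant_id"].nunique() < 2:
            raise ValueError("fewer than two participants retained after exclusions")
        self._log("filter_trials", retained=retained)

        rb_cells = self._response_bias_cells(retained)
        wide = contrasts.pivot_cells(
            rb_cells, value="rb", cell_cols=["phase", "stimulation", "block"]
        )
        n = len(wide)
        self._log("response_bias_cells", cells=rb_cells)

        effects: dict[str, EffectSummary] = {}
        bayes: dict[str, BayesFactorResult] = {}
        ttests: dict[str, TTestResult] = {}
        src = cfg.sources

        # primary: post active block 1 vs post sham block 1
        primary = contrasts.paired_difference(
            wide, _cells_key("post", "active", 1), _cells_key("post", "sham", 1)
        )
        effects["primary"] = primary
        bayes["primary"] = informed_bf(primary, src["primary_ahn"].prior())
        bayes["primary_directional"] = informed_bf(
            primary, src["primary_ahn"].prior(Direction.POSITIVE)
        )
        ttests["primary"] = paired_t(primary)

        # exploratory: post-active block-1 RB against zero, default Cauchy prior
        pa_b1 = wide[_cells_key("post", "active", 1)].to_numpy()
        post_active_b1 = contrasts.summarize_scores(pa_b1)
        effects["post_active_block1"] = post_active_b1
        ttests["post_active_block1"] = one_sample_t(pa_b1)
        bayes["post_active_block1_cauchy"] = default_onesample_bf(
            post_active_b1.t, n, cfg.cauchy_scale
        )

        # 2x3 stimulation-by-block interaction contrast (post-stimulation cells)
        inter23 = contrasts.interaction_contrast_2x3(
            wide, key=lambda s, b: _cells_key("post", s, b)
        )
        effects["interaction_2x3"] = inter23
        bayes["interaction_2x3"] = informed_bf(inter23, src["interaction_ahn"].prior())
        ttests["interaction_2x3"] = paired_t(inter23)

        post_long = rb_cells[rb_cells["phase"] == "post"]
        anova = rm_anova(
            post_long, dv="rb", within=["stimulation", "block"],
            subject="participant_id", posthoc_factor="block",
        )

        # manipulation checks: post-sham block-3 RB against zero
        ps_b3 = wide[_cells_key("post", "sham", 3)].to_numpy()
        manip = contrasts.summarize_scores(ps_b3)
        effects["manipulation"] = manip
        ttests["manipulation"] = one_sample_t(ps_b3)
        bayes["manipulation_ahn"] = informed_bf(manip, src["manipulation_ahn"].prior())
        bayes["manipulation_duprat"] = informed_bf(manip, src["manipulation_duprat"].prior())

        # mood analyses
        mood = self._mood_analyses(effects, bayes, ttests) if self.questionnaires is not None else None

        # covariate-adjusted 2x2x3 contrast + RM-ANCOVA (needs TEPS)
        ancova = None
        if mood is not None and mood["teps"] is not None:
            teps_con = mood["teps"].set_index("participant_id")["teps_con"]
            teps_con = teps_con.reindex(wide.index)
            if not teps_con.isna().any() and teps_con.nunique() > 1:
                adjusted = contrasts.ancova_adjusted_cells(wide, teps_con)
                inter223 = contrasts.interaction_contrast_2x2x3(adjusted)
                effects["interaction_2x2x3_adjusted"] = inter223
                bayes["interaction_2x2x3_adjusted"] = informed_bf(
                    inter223, src["interaction_duprat"].prior()
                )
                ttests["interaction_2x2x3_adjusted"] = paired_t(inter223)
                ancova = rm_ancova(
                    rb_cells, dv="rb", within=["phase", "stimulation", "block"],
                    covariate=teps_con, subject="participant_id",
                )

        # design analysis: expected BFs at the planned n under a true null
        design = self._design_analysis(n_target=cfg.n_cap)

        # sequential stopping rule over the registered decision statistics
        monitored = [bayes["primary"].bf10]
        for key in ("pa_index", "na_index"):
            if key in bayes:
                monitored.append(bayes[key].bf10)
        decision = stopping_rule(
            monitored, n_collected=n, n_cap=cfg.n_cap,
            upper=cfg.stopping_upper, lower=cfg.stopping_lower,
        )
        self._log("analyses", effects=sorted(effects), bayes=sorted(bayes))

        return StudyResults(
            config=cfg,
            exclusions=reports,
            n_included=n,
            rb_cells=rb_cells,
            cell_table=wide,
            effects=effects,
            bayes=bayes,
            ttests=ttests,
            anova=anova,
            ancova=ancova,
            mood=mood,
            design_analysis=design,
            stopping=decision,
            log=list(self.log),
        )

    # -- helpers ---------------------------------------------------------
    def _response_bias_cells(self, retained: pd.DataFrame) -> pd.DataFrame:
        rows = []
        keys = ["participant_id", "stimulation", "phase", "block"]
        for (pid, stim, phase, block), sub in retained.groupby(keys, observed=True):
            counts = task.tabulate_block(sub)
            rb = task.response_bias(counts)
            rows.append({
                "participant_id": pid, "stimulation": stim, "phase": phase,
                "block": int(block), "rb": rb.value, "rb_corrected": rb.corrected,
                "n_trials": counts.total,
            })
        return pd.DataFrame(rows)

    def _mood_analyses(self, effects, bayes, ttests) -> dict:
        cfg = self.config
        q = self.questionnaires
        panas = questionnaires.score_panas_table(q)
        teps = questionnaires.score_teps_table(q)
        out = {"panas": panas, "teps": teps if len(teps) else None}
        if len(panas) == 0:
            return out

        split = panas["timepoint"].str.split("_", expand=True)
        panas = panas.assign(stimulation=split[0], phase=split[1])
        for measure in ("pa", "na"):
            wide = contrasts.pivot_cells(
                panas, value=measure, cell_cols=["stimulation", "phase"]
            )
            index = contrasts.double_baseline_index(
                wide, ("active", "post"), ("active", "pre"),
                ("sham", "post"), ("sham", "pre"),
            )
            source = self.config.sources["pa_forbes" if measure == "pa" else "na_forbes"]
            effects[f"{measure}_index"] = index
            bayes[f"{measure}_index"] = informed_bf(index, source.prior())
            ttests[f"{measure}_post"] = paired_t(
                contrasts.paired_difference(wide, ("active", "post"), ("sham", "post"))
            )
            # exploratory: per-condition post-minus-pre change
            for stim in ("active", "sham"):
                change = contrasts.summarize_scores(
                    wide[(stim, "post")].to_numpy() - wide[(stim, "pre")].to_numpy()
                )
                effects[f"{measure}_change_{stim}"] = change
                bayes[f"{measure}_change_{stim}"] = informed_bf(change, source.prior())
                ttests[f"{measure}_change_{stim}"] = paired_t(change)

        na_scores = panas["na"].to_numpy()
        rate, flagged = questionnaires.floor_effect_rate(
            na_scores, scale_minimum=10, threshold=cfg.floor_threshold
        )
        out["na_floor_rate"] = rate
        out["na_floor_flagged"] = flagged
        return out

    def _design_analysis(self, n_target: int) -> dict[str, dict]:
        """SE-scaled expected Bayes factors under the null at the planned n."""
        out = {}
        for name in ("primary_ahn", "interaction_ahn", "interaction_duprat",
                     "manipulation_ahn", "manipulation_duprat", "pa_forbes", "na_forbes"):
            s = self.config.sources[name]
            da = scale_se(s.se, s.n, n_target)
            bf_null = expected_bf_under_null(s.design_prior(), da.se_scaled, n_target - 1)
            out[name] = {
                "se_original": s.se, "n_original": s.n, "n_target": n_target,
                "se_scaled": da.se_scaled, "expected_bf_under_null": bf_null,
            }
        return out


@dataclass
class StudyResults:
    """Everything ``RewardResponsivenessStudy.fit`` computed, with reporting helpers."""

    config: AnalysisConfig
    exclusions: list
    n_included: int
    rb_cells: pd.DataFrame
    cell_table: pd.DataFrame
    effects: dict[str, EffectSummary]
    bayes: dict[str, BayesFactorResult]
    ttests: dict[str, TTestResult]
    anova: object
    ancova: object
    mood: dict | None
    design_analysis: dict
    stopping: StoppingDecision
    log: list

    @property
    def metrics(self) -> dict[str, float]:
        """Flat map of every reported number, keyed by analysis name."""
        m: dict[str, float] = {"n_included": self.n_included}
        for name, e in self.effects.items():
            m[f"{name}.mean"] = e.mean
            m[f"{name}.se"] = e.se
            m[f"{name}.df"] = e.df
        for name, b in self.bayes.items():
            m[f"{name}.bf10"] = b.bf10
            m[f"{name}.bf01"] = b.bf01
        for name, t in self.ttests.items():
            m[f"{name}.t"] = t.t
            m[f"{name}.p"] = t.p
            if t.cohens_d is not None:
                m[f"{name}.d"] = t.cohens_d
        if self.anova is not None:
            for ename, eff in self.anova.effects.items():
                key = f"anova.{ename.replace(' x ', '_x_')}"
                m[f"{key}.F"] = eff.F
                m[f"{key}.p"] = eff.p_reported
                m[f"{key}.eta_p_sq"] = eff.partial_eta_sq
                m[f"{key}.d"] = eff.cohens_d_equiv
        if self.ancova is not None:
            for ename, eff in self.ancova.effects.items():
                key = f"ancova.{ename.replace(' x ', '_x_')}"
                m[f"{key}.F"] = eff.F
                m[f"{key}.p"] = eff.p_reported
        if self.mood is not None and "na_floor_rate" in self.mood:
            m["na_floor_rate"] = self.mood["na_floor_rate"]
            m["na_floor_flagged"] = float(self.mood["na_floor_flagged"])
        for name, da in self.design_analysis.items():
            m[f"design.{name}.se_scaled"] = da["se_scaled"]
            m[f"design.{name}.expected_bf_under_null"] = da["expected_bf_under_null"]
        m["stopping_decision"] = self.stopping.value
        m["n_excluded"] = sum(r.excluded for r in self.exclusions)
        return m

    def to_json(self, path=None) -> str:
        payload = {
            "metrics": {k: (v if isinstance(v, str) else float(v))
                        for k, v in sorted(self.metrics.items())},
            "exclusions": [
                {"participant_id": r.participant_id, "excluded": r.excluded,
                 "reason": r.reason.value,
                 "rt_violation_fraction": r.rt_violation_fraction}
                for r in self.exclusions
            ],
            "log": self.log,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        lines = [
            "Reward responsiveness study — registered analysis suite",
            "=" * 58,
            f"participants included: {self.n_included} "
            f"(excluded: {sum(r.excluded for r in self.exclusions)})",
            "",
            f"{'analysis':34s} {'M':>8s} {'SE':>7s} {'BF10':>8s} {'BF01':>8s}",
        ]
        for name, e in self.effects.items():
            bf = self.bayes.get(name) or self.bayes.get(f"{name}_ahn")
            bf10 = f"{bf.bf10:8.3f}" if bf else "       -"
            bf01 = f"{bf.bf01:8.3f}" if bf else "       -"
            lines.append(f"{name:34s} {e.mean:8.3f} {e.se:7.3f} {bf10} {bf01}")
        lines.append("")
        for name, t in self.ttests.items():
            d = f", d = {t.cohens_d:.3f}" if t.cohens_d is not None else ""
            lines.append(f"t-test {name:27s} t({t.df}) = {t.t:7.3f}, p = {t.p:.3f}{d}")
        if self.anova is not None:
            lines.append("")
            lines.append("RM-ANOVA (post stimulation x block):")
            for eff in self.anova.effects.values():
                lines.append(
                    f"  {eff.name:24s} F({eff.df1},{eff.df2}) = {eff.F:6.3f}, "
                    f"p = {eff.p_reported:.3f}, eta_p^2 = {eff.partial_eta_sq:.3f}"
                )
        if self.mood is not None and "na_floor_rate" in self.mood:
            lines.append("")
            lines.append(
                f"PANAS NA floor: {100 * self.mood['na_floor_rate']:.0f}% of measures at "
                f"scale minimum (flagged: {self.mood['na_floor_flagged']})"
            )
        lines.append("")
        lines.append(f"stopping rule: {self.stopping.value}")
        return "\n".join(lines)

    def plot_response_bias(self, ax=None):
        """Point-range plot of mean RB per (phase, stimulation, block) cell."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        stats_df = (
            self.rb_cells.groupby(["phase", "stimulation", "block"], observed=True)["rb"]
            .agg(["mean", "sem"]).reset_index()
        )
        offsets = {("pre", "active"): -0.15, ("pre", "sham"): -0.05,
                   ("post", "active"): 0.05, ("post", "sham"): 0.15}
        for (phase, stim), sub in stats_df.groupby(["phase", "stimulation"], observed=True):
            xs = sub["block"] + offsets[(phase, stim)]
            ax.errorbar(xs, sub["mean"], yerr=sub["sem"], marker="o", linestyle="-",
                        capsize=3, label=f"{phase} {stim}")
        ax.axhline(0.0, color="grey", lw=0.8, ls=":")
        ax.set_xticks([1, 2, 3])
        ax.set_xlabel("block")
        ax.set_ylabel("response bias (log units)")
        ax.legend(frameon=False, fontsize=8)
        return ax
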