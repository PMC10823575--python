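"""Frequentist companions to the Bayes tests: t-tests, effect sizes, RM-ANOVA/ANCOVA.

The repeated-measures ANOVA is a fully-within-subject sums-of-squares
partition (balanced designs, one observation per subject and cell); each
within effect is tested against its interaction with subjects.  Sphericity
is assessed per multi-df effect with Mauchly's test on the orthonormalized
contrast covariance, and the Greenhouse-Geisser correction is applied when
violated.  The ANCOVA variant regresses each effect's per-subject contrast
scores on a grand-mean-centred between-subject covariate, testing the
effect (intercept) and its covariate interaction against the pooled
residual.

Effect sizes follow the reporting conventions of the PRT literature:
partial eta-squared ``F*df1 / (F*df1 + df2)`` and the equivalent Cohen's d
``2*sqrt(eta2 / (1 - eta2))``; for paired/one-sample t-tests ``d = t/sqrt(n)``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bayes import EffectSummary

__all__ = [
    "TTestResult",
    "AnovaEffect",
    "RMAnovaResults",
    "paired_t",
    "one_sample_t",
    "eta_p_sq_from_f",
    "d_from_eta",
    "rm_anova",
    "rm_ancova",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    cohens_d: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def paired_t(effect: EffectSummary) -> TTestResult:
    """Two-sided paired/one-sample t-test from an effect summary; d = t/sqrt(n)."""
    t = effect.mean / effect.se
    p = float(2 * stats.t.sf(abs(t), effect.df))
    d = t / math.sqrt(effect.n) if effect.n else t / math.sqrt(effect.df + 1)
    return TTestResult(t=float(t), df=effect.df, p=max(p, np.finfo(float).tiny), cohens_d=float(d))


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """One-sample t-test of ``values`` against ``mu0``."""
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < 2:
        raise ValueError("one_sample_t requires at least two values")
    sd = float(np.std(arr, ddof=1))
    if sd == 0:
        raise ValueError("degenerate sample: zero variance")
    eff = EffectSummary(mean=float(np.mean(arr) - mu0), se=sd / math.sqrt(n), df=n - 1, n=n)
    return paired_t(eff)


def eta_p_sq_from_f(F: float, df1: int, df2: int) -> float:
    """Partial eta-squared from an F ratio: F*df1 / (F*df1 + df2)."""
    if F < 0:
        raise ValueError("F must be non-negative")
    return F * df1 / (F * df1 + df2)


def d_from_eta(eta_sq: float) -> float:
    """Cohen's d equivalent of a partial eta-squared: 2*sqrt(eta2/(1-eta2))."""
    if not 0 <= eta_sq <= 1:
        raise ValueError("eta squared must lie in [0, 1]")
    if eta_sq == 1:
        raise ValueError("eta squared of 1 maps to an infinite d")
    return 2.0 * math.sqrt(eta_sq / (1.0 - eta_sq))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    ss: float
    ss_error: float
    partial_eta_sq: float
    cohens_d_equiv: float
    gg_epsilon: float | None = None
    sphericity_w: float | None = None
    sphericity_p: float | None = None
    corrected: bool = False
    p_gg: float | None = None

    @property
    def p_reported(self) -> float:
        """GG-corrected p when sphericity was violated, otherwise the raw p."""
        return self.p_gg if (self.corrected and self.p_gg is not None) else self.p


@dataclass
class RMAnovaResults:
    effects: dict[str, AnovaEffect]
    ss_components: dict[str, float]
    ss_total: float
    n_subjects: int
    posthoc: pd.DataFrame | None = None

    def __getitem__(self, name: str) -> AnovaEffect:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append({
                "effect": e.name, "F": e.F, "df1": e.df1, "df2": e.df2, "p": e.p,
                "partial_eta_sq": e.partial_eta_sq, "d": e.cohens_d_equiv,
                "gg_epsilon": e.gg_epsilon, "sphericity_p": e.sphericity_p,
                "sphericity_corrected": e.corrected, "p_gg": e.p_gg,
            })
        return pd.DataFrame(rows)


def _check_balanced(df: pd.DataFrame, within: list[str], subject: str) -> None:
    counts = df.groupby([subject] + within, observed=True).size()
    if counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError("unbalanced design: need exactly one observation per subject and cell")
    n_cells = int(np.prod([df[f].nunique() for f in within]))
    per_subject = df.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1 or per_subject.iloc[0] != n_cells:
        raise ValueError("unbalanced design: every subject must contribute every cell")


def _effect_estimate(df: pd.DataFrame, dv: str, factors: tuple[str, ...]) -> np.ndarray:
    """Per-row inclusion-exclusion estimate of the ``factors`` effect."""
    est = np.zeros(len(df))
    for r in range(len(factors) + 1):
        for sub in itertools.combinations(factors, r):
            sign = (-1) ** (len(factors) - len(sub))
            if sub:
                m = df.groupby(list(sub), observed=True)[dv].transform("mean").to_numpy()
            else:
                m = df[dv].mean()
            est += sign * m
    return est


def _orthonormal_contrast(k: int) -> np.ndarray:
    """(k-1) x k orthonormal rows spanning deviations from the level mean."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1)
        h[i] /= np.linalg.norm(h[i])
    return h


def _effect_contrast_scores(
    df: pd.DataFrame, dv: str, effect: tuple[str, ...], within: list[str], subject: str
) -> np.ndarray:
    """n_subjects x df_effect matrix of orthonormal contrast scores."""
    wide = df.pivot_table(index=subject, columns=list(effect), values=dv, aggfunc="mean")
    wide = wide.sort_index(axis=1)
    mats = []
    for f in effect:
        k = df[f].nunique()
        mats.append(_orthonormal_contrast(k))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return wide.to_numpy() @ C.T


def _mauchly_gg(Z: np.ndarray, resid_df: int) -> tuple[float, float, float]:
    """Mauchly W, its chi-square p, and Greenhouse-Geisser epsilon for contrast scores Z."""
    n, d = Z.shape
    S = np.cov(Z, rowvar=False, ddof=1).reshape(d, d)
    eig = np.linalg.eigvalsh(S)
    eig = np.clip(eig, 0.0, None)
    tr = eig.sum()
    gg = (tr**2) / (d * np.sum(eig**2)) if tr > 0 else 1.0 / d
    if np.any(eig <= 0) or tr <= 0:
        return 0.0, 0.0, float(gg)
    W = float(np.prod(eig) / (tr / d) ** d)
    f = 1.0 - (2.0 * d**2 + d + 2.0) / (6.0 * d * resid_df)
    chi2 = -f * resid_df * math.log(max(W, np.finfo(float).tiny))
    ddof = d * (d + 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, ddof))
    return W, p, float(gg)


def _gg_p(F: float, df1: int, df2: int, eps: float) -> float:
    return float(stats.f.sf(F, eps * df1, eps * df2))


def rm_anova(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str = "participant_id",
    sphericity_alpha: float = 0.05,
    posthoc_factor: str | None = None,
) -> RMAnovaResults:
    """Fully-within repeated-measures ANOVA on a long table.

    Each within effect is tested against its subject interaction.  Effects
    with more than one df carry Mauchly's sphericity test; when its p falls
    below ``sphericity_alpha`` the Greenhouse-Geisser corrected p is reported.
    ``posthoc_factor`` requests Bonferroni-adjusted pairwise paired t-tests
    between that factor's levels (collapsed over the others).
    """
    df = df.copy()
    _check_balanced(df, within, subject)
    n = df[subject].nunique()
    levels = {f: df[f].nunique() for f in within}

    grand = df[dv].mean()
    ss_total = float(np.sum((df[dv].to_numpy() - grand) ** 2))
    ss: dict[str, float] = {}

    # all effects over within factors and the subject factor
    all_factors = within + [subject]
    for r in range(1, len(all_factors) + 1):
        for combo in itertools.combinations(all_factors, r):
            est = _effect_estimate(df, dv, combo)
            ss[" x ".join(combo)] = float(np.sum(est**2))

    effects: dict[str, AnovaEffect] = {}
    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            name = " x ".join(combo)
            df1 = int(np.prod([levels[f] - 1 for f in combo]))
            df2 = df1 * (n - 1)
            ss_eff = ss[name]
            ss_err = ss[" x ".join(combo + (subject,))]
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else 0.0
            p = float(stats.f.sf(F, df1, df2)) if ss_err > 0 else 1.0
            eta = eta_p_sq_from_f(F, df1, df2)
            gg_eps = w = w_p = p_gg = None
            corrected = False
            if df1 > 1:
                Z = _effect_contrast_scores(df, dv, combo, within, subject)
                w, w_p, gg_eps = _mauchly_gg(Z, n - 1)
                p_gg = _gg_p(F, df1, df2, gg_eps)
                corrected = w_p < sphericity_alpha
            effects[name] = AnovaEffect(
                name=name, F=float(F), df1=df1, df2=df2, p=p, ss=ss_eff, ss_error=ss_err,
                partial_eta_sq=eta, cohens_d_equiv=d_from_eta(min(eta, 1 - 1e-15)),
                gg_epsilon=gg_eps, sphericity_w=w, sphericity_p=w_p,
                corrected=corrected, p_gg=p_gg,
            )

    posthoc = None
    if posthoc_factor is not None:
        posthoc = _bonferroni_pairwise(df, dv, posthoc_factor, subject)

    return RMAnovaResults(
        effects=effects, ss_components=ss, ss_total=ss_total, n_subjects=n, posthoc=posthoc
    )


def _bonferroni_pairwise(
    df: pd.DataFrame, dv: str, factor: str, subject: str
) -> pd.DataFrame:
    """Pairwise paired t-tests between factor levels, Bonferroni-adjusted."""
    wide = df.pivot_table(index=subject, columns=factor, values=dv, aggfunc="mean")
    lvls = list(wide.columns)
    pairs = list(itertools.combinations(lvls, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = wide[a].to_numpy() - wide[b].to_numpy()
        res = one_sample_t(diff)
        rows.append({
            "level_a": a, "level_b": b,
            "mean_a": float(wide[a].mean()), "mean_b": float(wide[b].mean()),
            "t": res.t, "df": res.df, "p_uncorrected": res.p,
            "p_bonferroni": min(1.0, res.p * m),
        })
    return pd.DataFrame(rows)


def rm_ancova(
    df: pd.DataFrame,
    dv: str,
    within: list[str],
    covariate: pd.Series,
    subject: str = "participant_id",
    sphericity_alpha: float = 0.05,
) -> RMAnovaResults:
    """Repeated-measures ANCOVA: within factors with a between-subject covariate.

    For every within effect, the per-subject orthonormal contrast scores are
    regressed on the grand-mean-centred covariate; the effect tests the
    pooled intercept, its ``x covariate`` companion tests the pooled slope,
    both against the pooled residual on ``df_effect * (n - 2)`` error df.
    The between-subject part tests the covariate against the subject-mean
    residual.  Constant covariates are rejected.
    """
    df = df.copy()
    _check_balanced(df, within, subject)
    n = df[subject].nunique()
    levels = {f: df[f].nunique() for f in within}
    subjects = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean").index
    x = covariate.reindex(subjects)
    if x.isna().any():
        raise ValueError("covariate missing for some subjects")
    xc = x.to_numpy(dtype=float)
    xc = xc - xc.mean()
    sxx = float(np.sum(xc**2))
    if sxx == 0:
        raise ValueError("constant covariate: ANCOVA is undefined")

    effects: dict[str, AnovaEffect] = {}
    ss: dict[str, float] = {}

    # between-subject part: subject means on the covariate
    subj_means = df.groupby(subject, observed=True)[dv].mean().reindex(subjects).to_numpy()
    n_cells = int(np.prod(list(levels.values())))
    b1 = float(np.sum(xc * subj_means) / sxx)
    resid_b = subj_means - subj_means.mean() - b1 * xc
    ss_cov = n_cells * b1**2 * sxx
    ss_err_b = n_cells * float(np.sum(resid_b**2))
    F_cov = (ss_cov / 1) / (ss_err_b / (n - 2)) if ss_err_b > 0 else 0.0
    p_cov = float(stats.f.sf(F_cov, 1, n - 2)) if ss_err_b > 0 else 1.0
    eta = eta_p_sq_from_f(F_cov, 1, n - 2)
    effects["covariate"] = AnovaEffect(
        name="covariate", F=F_cov, df1=1, df2=n - 2, p=p_cov, ss=ss_cov, ss_error=ss_err_b,
        partial_eta_sq=eta, cohens_d_equiv=d_from_eta(min(eta, 1 - 1e-15)),
    )
    ss["covariate"] = ss_cov

    for r in range(1, len(within) + 1):
        for combo in itertools.combinations(within, r):
            name = " x ".join(combo)
            d1 = int(np.prod([levels[f] - 1 for f in combo]))
            scale = int(np.prod([levels[f] for f in within if f not in combo]))
            Z = _effect_contrast_scores(df, dv, combo, within, subject) * math.sqrt(scale)
            zbar = Z.mean(axis=0)
            slopes = (xc @ Z) / sxx
            resid = Z - zbar - np.outer(xc, slopes)
            ss_eff = float(n * np.sum(zbar**2))
            ss_slope = float(np.sum(slopes**2) * sxx)
            ss_err = float(np.sum(resid**2))
            d2 = d1 * (n - 2)
            denom = ss_err / d2 if ss_err > 0 else 0.0
            F_eff = (ss_eff / d1) / denom if denom > 0 else 0.0
            F_int = (ss_slope / d1) / denom if denom > 0 else 0.0
            gg_eps = w = w_p = None
            p_eff = float(stats.f.sf(F_eff, d1, d2)) if denom > 0 else 1.0
            p_int = float(stats.f.sf(F_int, d1, d2)) if denom > 0 else 1.0
            p_gg_eff = p_gg_int = None
            corrected = False
            if d1 > 1:
                w, w_p, gg_eps = _mauchly_gg(resid, n - 2)
                p_gg_eff = _gg_p(F_eff, d1, d2, gg_eps)
                p_gg_int = _gg_p(F_int, d1, d2, gg_eps)
                corrected = w_p < sphericity_alpha
            for label, F_, p_, ss_, pgg in (
                (name, F_eff, p_eff, ss_eff, p_gg_eff),
                (f"{name} x covariate", F_int, p_int, ss_slope, p_gg_int),
            ):
                eta = eta_p_sq_from_f(F_, d1, d2)
                effects[label] = AnovaEffect(
                    name=label, F=F_, df1=d1, df2=d2, p=p_, ss=ss_, ss_error=ss_err,
                    partial_eta_sq=eta, cohens_d_equiv=d_from_eta(min(eta, 1 - 1e-15)),
                    gg_epsilon=gg_eps, sphericity_w=w, sphericity_p=w_p,
                    corrected=corrected, p_gg=pgg,
                )
                ss[label] = ss_

    grand = df[dv].mean()
    ss_total = float(np.sum((df[dv].to_numpy() - grand) ** 2))
    return RMAnovaResults(
        effects=effects, ss_components=ss, ss_total=ss_total, n_subjects=n
    )
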