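"""t-tests, effect-size conversions, and the repeated-measures ANOVA/ANCOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rewardbias.bayes import EffectSummary
from rewardbias.frequentist import (
    d_from_eta,
    eta_p_sq_from_f,
    one_sample_t,
    paired_t,
    rm_ancova,
    rm_anova,
)


def rm_frame(rng, n=12, block_effect=0.0, stim_effect=0.0, noise=0.5,
             factors=("stimulation", "block")):
    rows = []
    subj = rng.normal(0, 1, n)
    blocks = (1, 2, 3)
    stims = ("active", "sham")
    phases = ("pre", "post") if "phase" in factors else (None,)
    for i in range(n):
        for ph in phases:
            for s in stims:
                for b in blocks:
                    val = (
                        subj[i]
                        + block_effect * (b - 2)
                        + (stim_effect if s == "active" else 0.0)
                        + rng.normal(0, noise)
                    )
                    row = {"participant_id": f"p{i:02d}", "stimulation": s,
                           "block": b, "y": val}
                    if ph is not None:
                        row["phase"] = ph
                    rows.append(row)
    return pd.DataFrame(rows)


class TestTTests:
    def test_paired_t_from_summary(self):
        res = paired_t(EffectSummary(mean=-0.253, se=0.187, df=29, n=30))
        assert res.t == pytest.approx(-0.253 / 0.187, abs=1e-12)
        assert res.cohens_d == pytest.approx(res.t / math.sqrt(30), abs=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(res.t), 29), abs=1e-15)

    def test_zero_mean_gives_p_one(self):
        res = paired_t(EffectSummary(mean=0.0, se=0.1, df=20))
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_one_sample_matches_scipy(self, rng):
        x = rng.normal(0.4, 1.0, 25)
        mine = one_sample_t(x, mu0=0.1)
        ref = stats.ttest_1samp(x, 0.1)
        assert mine.t == pytest.approx(ref.statistic, abs=1e-10)
        assert mine.p == pytest.approx(ref.pvalue, abs=1e-10)
        assert mine.cohens_d == pytest.approx(mine.t / 5.0, abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            one_sample_t([2.0, 2.0, 2.0], mu0=2.0)


class TestEffectSizeConversions:
    @pytest.mark.parametrize(
        "F, df1, df2, eta3, d2",
        [(4.808, 2, 58, 0.142, 0.81), (2.331, 1, 29, 0.074, 0.57), (0.0, 2, 58, 0.0, 0.0)],
    )
    def test_eta_and_d_chain(self, F, df1, df2, eta3, d2):
        eta = eta_p_sq_from_f(F, df1, df2)
        assert round(eta, 3) == pytest.approx(eta3, abs=5e-4)
        if eta > 0:
            assert round(d_from_eta(round(eta, 3)), 2) == pytest.approx(d2, abs=5e-3)
        else:
            assert d_from_eta(eta) == 0.0

    def test_eta_of_one_maps_to_infinite_d(self):
        with pytest.raises(ValueError):
            d_from_eta(1.0)


class TestRMAnova:
    def test_identical_cells_give_zero_f(self, rng):
        rows = []
        vals = rng.normal(0, 1, 8)
        for i in range(8):
            for s in ("active", "sham"):
                for b in (1, 2, 3):
                    rows.append({"participant_id": f"p{i}", "stimulation": s,
                                 "block": b, "y": vals[i]})
        res = rm_anova(pd.DataFrame(rows), "y", ["stimulation", "block"])
        for eff in res.effects.values():
            # all within-cell variation is zero: every effect SS vanishes
            assert eff.ss == pytest.approx(0.0, abs=1e-18)

    def test_matches_pingouin_and_statsmodels(self, rng):
        pg = pytest.importorskip("pingouin")
        from statsmodels.stats.anova import AnovaRM

        df = rm_frame(rng, n=12, block_effect=0.15, stim_effect=0.2)
        mine = rm_anova(df, "y", ["stimulation", "block"], subject="participant_id")
        ref = pg.rm_anova(data=df, dv="y", within=["stimulation", "block"],
                          subject="participant_id", detailed=True)
        names = {"stimulation": "stimulation", "block": "block",
                 "stimulation x block": "stimulation * block"}
        for mine_name, ref_name in names.items():
            row = ref[ref["Source"] == ref_name].iloc[0]
            assert mine[mine_name].F == pytest.approx(row["F"], rel=1e-8)
            assert mine[mine_name].p == pytest.approx(row["p_unc"], rel=1e-8)
            assert mine[mine_name].ss == pytest.approx(row["SS"], rel=1e-8)
        sm = AnovaRM(df, "y", "participant_id", within=["stimulation", "block"]).fit()
        for mine_name, sm_name in (("stimulation", "stimulation"), ("block", "block"),
                                   ("stimulation x block", "stimulation:block")):
            assert mine[mine_name].F == pytest.approx(
                sm.anova_table.loc[sm_name, "F Value"], rel=1e-8
            )

    def test_sphericity_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        df = rm_frame(rng, n=14, block_effect=0.1)
        df = df[df["stimulation"] == "active"]
        mine = rm_anova(df, "y", ["block"], subject="participant_id")
        sph = pg.sphericity(df, dv="y", within="block", subject="participant_id")
        eps = pg.epsilon(df.pivot_table(index="participant_id", columns="block", values="y"),
                         correction="gg")
        assert mine["block"].sphericity_w == pytest.approx(sph.W, rel=1e-8)
        assert mine["block"].sphericity_p == pytest.approx(sph.pval, rel=1e-8)
        assert mine["block"].gg_epsilon == pytest.approx(eps, rel=1e-8)

    def test_ss_partition_is_exact(self, rng):
        df = rm_frame(rng, n=9, block_effect=0.2, stim_effect=0.1,
                      factors=("phase", "stimulation", "block"))
        res = rm_anova(df, "y", ["phase", "stimulation", "block"])
        assert sum(res.ss_components.values()) == pytest.approx(res.ss_total, rel=1e-9)

    def test_brute_force_ss_on_toy_data(self, rng):
        """SS of each effect agrees with explicit marginal-mean formulas at n=8."""
        df = rm_frame(rng, n=8, block_effect=0.3)
        res = rm_anova(df, "y", ["stimulation", "block"])
        grand = df["y"].mean()
        n, ks, kb = 8, 2, 3
        ss_stim = n * kb * sum(
            (df[df["stimulation"] == s]["y"].mean() - grand) ** 2 for s in ("active", "sham")
        )
        ss_block = n * ks * sum(
            (df[df["block"] == b]["y"].mean() - grand) ** 2 for b in (1, 2, 3)
        )
        cell = df.groupby(["stimulation", "block"])["y"].mean()
        ss_inter = n * sum(
            (cell[(s, b)]
             - df[df["stimulation"] == s]["y"].mean()
             - df[df["block"] == b]["y"].mean() + grand) ** 2
            for s, b in itertools.product(("active", "sham"), (1, 2, 3))
        )
        assert res["stimulation"].ss == pytest.approx(ss_stim, rel=1e-9)
        assert res["block"].ss == pytest.approx(ss_block, rel=1e-9)
        assert res["stimulation x block"].ss == pytest.approx(ss_inter, rel=1e-9)

    def test_posthoc_bonferroni_scales_p(self, rng):
        df = rm_frame(rng, n=10, block_effect=0.4)
        res = rm_anova(df, "y", ["stimulation", "block"], posthoc_factor="block")
        assert len(res.posthoc) == 3
        for _, row in res.posthoc.iterrows():
            assert row["p_bonferroni"] == pytest.approx(
                min(1.0, row["p_uncorrected"] * 3), abs=1e-12
            )

    def test_unbalanced_data_rejected(self, rng):
        df = rm_frame(rng, n=6).iloc[:-1]
        with pytest.raises(ValueError):
            rm_anova(df, "y", ["stimulation", "block"])


class TestRMAncova:
    def test_orthogonal_covariate_reduces_to_anova(self, rng):
        n = 16
        df = rm_frame(rng, n=n, block_effect=0.2)
        cov_raw = rng.normal(0, 1, n)
        # orthogonalize the covariate against every cell column
        wide = df.pivot_table(index="participant_id", columns=["stimulation", "block"],
                              values="y")
        X = wide.to_numpy() - wide.to_numpy().mean(axis=0)
        proj = X @ np.linalg.lstsq(X, cov_raw - cov_raw.mean(), rcond=None)[0]
        cov = pd.Series(cov_raw - cov_raw.mean() - proj, index=wide.index)
        base = rm_anova(df, "y", ["stimulation", "block"])
        anc = rm_ancova(df, "y", ["stimulation", "block"], covariate=cov)
        for name in ("stimulation", "block", "stimulation x block"):
            # same SS; F differs only through the error df (n-2 vs n-1)
            assert anc[name].ss == pytest.approx(base[name].ss, rel=1e-8)
            assert anc[name].F == pytest.approx(
                base[name].F * (n - 2) / (n - 1), rel=1e-8
            )
            assert anc[f"{name} x covariate"].F == pytest.approx(0.0, abs=1e-16)

    def test_covariate_moderated_interaction_detected(self, rng):
        n = 20
        df = rm_frame(rng, n=n, noise=0.3)
        cov = pd.Series(rng.normal(0, 1, n),
                        index=[f"p{i:02d}" for i in range(n)])
        # moderate the stimulation effect by the covariate
        boost = df.apply(
            lambda r: cov[r["participant_id"]] * (0.8 if r["stimulation"] == "active" else 0.0),
            axis=1,
        )
        df = df.assign(y=df["y"] + boost)
        anc = rm_ancova(df, "y", ["stimulation", "block"], covariate=cov)
        base = rm_anova(df, "y", ["stimulation", "block"])
        assert anc["stimulation x covariate"].p < 0.001
        # removing covariate-carried variance sharpens the within error
        assert anc["stimulation"].ss_error < base["stimulation"].ss_error

    def test_constant_covariate_rejected(self, rng):
        df = rm_frame(rng, n=6)
        cov = pd.Series(1.0, index=[f"p{i:02d}" for i in range(6)])
        with pytest.raises(ValueError):
            rm_ancova(df, "y", ["stimulation", "block"], covariate=cov)

    def test_null_p_values_uniform(self, rng):
        """Under a pure-noise model the within-effect p-values are uniform."""
        pvals = []
        for _ in range(300):
            n = 10
            vals = rng.normal(0, 1, (n, 6))
            rows = []
            for i in range(n):
                k = 0
                for s in ("a", "b"):
                    for b in (1, 2, 3):
                        rows.append({"participant_id": f"p{i:02d}", "stimulation": s,
                                     "block": b, "y": vals[i, k]})
                        k += 1
            df = pd.DataFrame(rows)
            cov = pd.Series(rng.normal(0, 1, n), index=[f"p{i:02d}" for i in range(n)])
            anc = rm_ancova(df, "y", ["stimulation", "block"], covariate=cov)
            pvals.append(anc["stimulation"].p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
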