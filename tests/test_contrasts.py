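"""One-df reductions: paired differences, mood indices, interaction contrasts, ANCOVA adjustment."""

import numpy as np
import pandas as pd
import pytest

from rewardbias.contrasts import (
    DegenerateContrastError,
    ancova_adjusted_cells,
    double_baseline_index,
    interaction_contrast_2x3,
    interaction_contrast_2x2x3,
    paired_difference,
    pivot_cells,
    summarize_scores,
)


def wide_frame(rng, cells, n=12, scale=1.0):
    data = {c: rng.normal(0, scale, n) for c in cells}
    df = pd.DataFrame(data, index=[f"p{i:02d}" for i in range(n)])
    df.columns = pd.MultiIndex.from_tuples(cells) if isinstance(cells[0], tuple) else cells
    return df


class TestSummarize:
    def test_matches_naive_recomputation(self, rng):
        x = rng.normal(0, 2, 30)
        eff = summarize_scores(x)
        assert eff.mean == pytest.approx(x.sum() / 30, abs=1e-12)
        sd = np.sqrt(((x - x.mean()) ** 2).sum() / 29)
        assert eff.se == pytest.approx(sd / np.sqrt(30), abs=1e-12)
        assert eff.df == 29 and eff.n == 30

    def test_degenerate_scores_flagged(self):
        with pytest.raises(DegenerateContrastError):
            summarize_scores(np.ones(10))


class TestPairedDifference:
    def test_matches_hand_computation(self, rng):
        cells = [("post", "active", 1), ("post", "sham", 1)]
        wide = wide_frame(rng, cells)
        eff = paired_difference(wide, cells[0], cells[1])
        d = wide[cells[0]].to_numpy() - wide[cells[1]].to_numpy()
        assert eff.mean == pytest.approx(d.mean(), abs=1e-12)
        assert eff.se == pytest.approx(d.std(ddof=1) / np.sqrt(len(d)), abs=1e-12)

    def test_identical_cells_degenerate(self, rng):
        wide = wide_frame(rng, ["a", "b"])
        wide["b"] = wide["a"]
        with pytest.raises(DegenerateContrastError):
            paired_difference(wide, "a", "b")


class TestDoubleBaseline:
    CELLS = [("active", "post"), ("active", "pre"), ("sham", "post"), ("sham", "pre")]

    def test_group_mean_identity(self, rng):
        """Index mean equals the difference of the two mean changes."""
        wide = wide_frame(rng, self.CELLS, n=30)
        eff = double_baseline_index(wide, *self.CELLS)
        act = (wide[self.CELLS[0]] - wide[self.CELLS[1]]).mean()
        sham = (wide[self.CELLS[2]] - wide[self.CELLS[3]]).mean()
        assert eff.mean == pytest.approx(act - sham, abs=1e-12)

    def test_example_change_means(self):
        """Changes of -2.900 (active) and -1.567 (sham) give an index of -1.333."""
        n = 30
        rng = np.random.default_rng(5)
        noise = rng.normal(0, 1, n)
        wide = pd.DataFrame(
            {
                self.CELLS[0]: noise - 2.900, self.CELLS[1]: noise,
                self.CELLS[2]: noise - 1.567, self.CELLS[3]: noise + rng.normal(0, 1, n) * 0,
            }
        )
        wide.columns = pd.MultiIndex.from_tuples(self.CELLS)
        # perturb so the SE is nonzero but means are exact
        bump = rng.normal(0, 0.5, n)
        bump -= bump.mean()
        wide[self.CELLS[0]] += bump
        eff = double_baseline_index(wide, *self.CELLS)
        assert eff.mean == pytest.approx(-2.900 - (-1.567), abs=1e-9)

    def test_session_constant_invariance(self, rng):
        wide = wide_frame(rng, self.CELLS)
        base = double_baseline_index(wide, *self.CELLS)
        shifted = wide + 17.3
        eff = double_baseline_index(shifted, *self.CELLS)
        assert eff.mean == pytest.approx(base.mean, abs=1e-9)
        assert eff.se == pytest.approx(base.se, abs=1e-9)

    def test_sign_flip(self, rng):
        wide = wide_frame(rng, self.CELLS)
        a = double_baseline_index(wide, *self.CELLS)
        b = double_baseline_index(wide, *self.CELLS, sign_flip=True)
        assert b.mean == pytest.approx(-a.mean, abs=1e-12)

    def test_matches_per_participant_arithmetic(self, rng):
        wide = wide_frame(rng, self.CELLS, n=8)
        eff = double_baseline_index(wide, *self.CELLS)
        idx = [
            (wide.loc[p, self.CELLS[0]] - wide.loc[p, self.CELLS[1]])
            - (wide.loc[p, self.CELLS[2]] - wide.loc[p, self.CELLS[3]])
            for p in wide.index
        ]
        assert eff.mean == pytest.approx(np.mean(idx), abs=1e-12)


class TestInteraction2x3:
    CELLS = [(s, b) for s in ("active", "sham") for b in (1, 2, 3)]

    def test_weight_arithmetic(self, rng):
        wide = wide_frame(rng, self.CELLS, n=10)
        eff = interaction_contrast_2x3(wide)
        manual = np.zeros(10)
        for b, w in {1: 1.0, 2: -0.5, 3: -0.5}.items():
            manual += w * (wide[("active", b)].to_numpy() - wide[("sham", b)].to_numpy())
        assert eff.mean == pytest.approx(manual.mean(), abs=1e-12)
        assert eff.se == pytest.approx(manual.std(ddof=1) / np.sqrt(10), abs=1e-12)

    def test_constant_per_block_differences_degenerate(self, rng):
        """Differences (.3, .1, .1) give a constant score .3 - .5*.1 - .5*.1 = .2.

        A constant per-participant score has SE 0, which is flagged rather
        than passed to a Bayes test.
        """
        base = {c: rng.integers(-4, 5, 6).astype(float) for c in self.CELLS}
        wide = pd.DataFrame(base, index=[f"p{i}" for i in range(6)])
        wide.columns = pd.MultiIndex.from_tuples(self.CELLS)
        for b, d in zip((1, 2, 3), (0.5, 0.25, 0.25)):  # dyadic: exact in floats
            wide[("active", b)] = wide[("sham", b)] + d
        with pytest.raises(DegenerateContrastError):
            interaction_contrast_2x3(wide)
        manual = np.zeros(6)
        for b, w in {1: 1.0, 2: -0.5, 3: -0.5}.items():
            manual += w * (wide[("active", b)].to_numpy() - wide[("sham", b)].to_numpy())
        assert np.allclose(manual, 0.5 - 0.5 * 0.25 - 0.5 * 0.25)

    def test_identical_profiles_vanish(self, rng):
        wide = wide_frame(rng, self.CELLS, n=8)
        for b in (1, 2, 3):
            wide[("sham", b)] = wide[("active", b)]
        with pytest.raises(DegenerateContrastError):
            # all scores are exactly zero: degenerate, and the mean is 0
            interaction_contrast_2x3(wide)
        diffs = [wide[("active", b)] - wide[("sham", b)] for b in (1, 2, 3)]
        assert all(np.allclose(d, 0) for d in diffs)

    def test_participant_constant_cancels(self, rng):
        wide = wide_frame(rng, self.CELLS, n=15)
        base = interaction_contrast_2x3(wide)
        shift = rng.normal(0, 3, 15)
        shifted = wide.add(pd.Series(shift, index=wide.index), axis=0)
        eff = interaction_contrast_2x3(shifted)
        assert eff.mean == pytest.approx(base.mean, abs=1e-9)
        assert eff.se == pytest.approx(base.se, abs=1e-9)

    def test_nonzero_sum_weights_rejected(self, rng):
        wide = wide_frame(rng, self.CELLS)
        with pytest.raises(ValueError):
            interaction_contrast_2x3(wide, weights={1: 1.0, 2: 1.0, 3: 1.0})


class TestInteraction2x2x3:
    CELLS = [
        (ph, s, b) for ph in ("pre", "post") for s in ("active", "sham") for b in (1, 2, 3)
    ]

    def test_time_invariant_profiles_vanish(self, rng):
        wide = wide_frame(rng, [(s, b) for s in ("active", "sham") for b in (1, 2, 3)], n=9)
        full = {}
        for ph in ("pre", "post"):
            for s, b in wide.columns:
                full[(ph, s, b)] = wide[(s, b)].to_numpy()
        full_wide = pd.DataFrame(full)
        full_wide.columns = pd.MultiIndex.from_tuples(full_wide.columns)
        # every per-participant score is exactly zero -> degenerate (SE 0)
        with pytest.raises(DegenerateContrastError):
            interaction_contrast_2x2x3(full_wide)
        post = interaction_contrast_2x3(full_wide, key=lambda s, b: ("post", s, b))
        pre = interaction_contrast_2x3(full_wide, key=lambda s, b: ("pre", s, b))
        assert post.mean == pytest.approx(pre.mean, abs=1e-12)

    def test_known_injected_interaction_recovered(self, rng):
        n = 40
        wide = wide_frame(rng, self.CELLS, n=n, scale=0.3)
        # add +delta to post-active block 1 only: contrast recovers delta
        delta = 0.45
        wide[("post", "active", 1)] += delta
        eff = interaction_contrast_2x2x3(wide)
        assert eff.mean == pytest.approx(delta, abs=4 * eff.se)


class TestAncovaAdjustment:
    CELLS = [(s, b) for s in ("active", "sham") for b in (1, 2, 3)]

    def test_uncorrelated_covariate_leaves_cells(self, rng):
        wide = wide_frame(rng, self.CELLS, n=20)
        cov = pd.Series(np.tile([1.0, -1.0], 10), index=wide.index)
        # force exact orthogonality per cell
        for c in wide.columns:
            y = wide[c].to_numpy()
            slope = np.sum((cov - cov.mean()) * (y - y.mean())) / np.sum((cov - cov.mean()) ** 2)
            wide[c] = y - slope * (cov - cov.mean())
        adjusted = ancova_adjusted_cells(wide, cov)
        pd.testing.assert_frame_equal(adjusted, wide, atol=1e-10, rtol=0)

    def test_slope_one_fixture_matches_hand_calculation(self):
        idx = [f"p{i}" for i in range(4)]
        cov = pd.Series([1.0, 2.0, 3.0, 4.0], index=idx)
        y = cov + 10.0  # slope exactly 1
        wide = pd.DataFrame({("active", 1): y}, index=idx)
        wide.columns = pd.MultiIndex.from_tuples([("active", 1)])
        adjusted = ancova_adjusted_cells(wide, cov)
        # residualized at the grand mean: everyone sits at the cell mean
        assert np.allclose(adjusted[("active", 1)], 12.5)

    def test_cell_means_preserved(self, rng):
        wide = wide_frame(rng, self.CELLS, n=16)
        cov = pd.Series(rng.normal(50, 6, 16), index=wide.index)
        adjusted = ancova_adjusted_cells(wide, cov)
        assert np.allclose(adjusted.mean(), wide.mean(), atol=1e-10)

    def test_constant_covariate_rejected(self, rng):
        wide = wide_frame(rng, self.CELLS)
        cov = pd.Series(3.0, index=wide.index)
        with pytest.raises(ValueError):
            ancova_adjusted_cells(wide, cov)


class TestPivot:
    def test_missing_cell_rejected(self):
        df = pd.DataFrame({
            "participant_id": ["p1", "p1", "p2"],
            "stimulation": ["active", "sham", "active"],
            "rb": [0.1, 0.2, 0.3],
        })
        with pytest.raises(ValueError):
            pivot_cells(df, "rb", ["stimulation"])
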