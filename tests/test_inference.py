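import numpy as np
import pandas as pd
import pytest

from crrtpk.inference import (
    FactorialDesign,
    backward_stepwise,
    factorial_anova,
    tukey_hsd,
    two_sample_t,
)


def design_from(df, response="y", factors=("a", "b")):
    return FactorialDesign(data=df, response=response, factors=factors)


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # pooled s² = 1, se = √(2/3), t = −3/se = −3.674, df = 4 → p = 0.0213
        t, p = two_sample_t([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=5e-4)
        assert p == pytest.approx(0.0213, abs=5e-5)

    def test_antisymmetry(self):
        t1, p1 = two_sample_t([1, 2, 3], [4, 5, 6])
        t2, p2 = two_sample_t([4, 5, 6], [1, 2, 3])
        assert t1 == -t2 and p1 == p2

    def test_zero_variance_degenerate_cases(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)
        t, p = two_sample_t([1.0, 1.0], [2.0, 2.0])
        assert p == 0.0 and t == -np.inf


class TestFactorialAnova:
    def two_group_frame(self):
        rng = np.random.default_rng(5)
        return pd.DataFrame(
            {
                "a": np.repeat(["g1", "g2"], 6),
                "y": np.concatenate([rng.normal(10, 1, 6), rng.normal(12, 1, 6)]),
            }
        )

    def test_one_factor_F_equals_t_squared(self):
        df = self.two_group_frame()
        res = factorial_anova(design_from(df, factors=("a",)))
        t, p_t = two_sample_t(df.y[df.a == "g1"], df.y[df.a == "g2"])
        F = res.table.loc["C(a)", "F"]
        assert F == pytest.approx(t**2, rel=1e-10)
        assert res.table.loc["C(a)", "PR(>F)"] == pytest.approx(p_t, rel=1e-10)

    def test_constant_response_gives_zero_F(self):
        df = pd.DataFrame({"a": ["g1", "g2"] * 4, "y": [5.0] * 8})
        res = factorial_anova(design_from(df, factors=("a",)))
        assert res.table.loc["C(a)", "F"] == pytest.approx(0.0, abs=1e-20)
        assert res.adjusted_r2 == 0.0

    def test_balanced_2x2_single_active_factor(self):
        # cell means {10,10,20,20}: pure A effect; B and A:B vanish
        rows = []
        for a, b in [(0, 0), (0, 1), (1, 0), (1, 1)]:
            for rep in range(3):
                rows.append({"a": a, "b": b, "y": 10.0 + 10.0 * a + 1e-9 * rep})
        res = factorial_anova(design_from(pd.DataFrame(rows)), interactions=2)
        assert res.table.loc["C(a)", "PR(>F)"] < 1e-10
        assert res.table.loc["C(b)", "F"] == pytest.approx(0.0, abs=1e-3)
        assert res.table.loc["C(a):C(b)", "F"] == pytest.approx(0.0, abs=1e-3)

    def test_marginal_mean_equals_cell_mean_in_balanced_design(self):
        rng = np.random.default_rng(11)
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                for _ in range(4):
                    rows.append({"a": a, "b": b, "y": rng.normal(5 + a - 2 * b, 1)})
        df = pd.DataFrame(rows)
        res = factorial_anova(design_from(df), interactions=2)
        for _, row in res.marginal_means.iterrows():
            cell = df[(df.a == row.a) & (df.b == row.b)]
            assert row.emmean == pytest.approx(cell.y.mean(), rel=1e-10)
            assert row.ci_lower < row.emmean < row.ci_upper

    def test_saturated_model_rejected(self):
        df = pd.DataFrame({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1], "y": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="saturated"):
            factorial_anova(design_from(df), interactions=2)

    def test_adjusted_r2_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {"a": np.repeat([0, 1, 2], 5), "y": rng.normal(0, 1, 15) + np.repeat([0, 1, 3], 5)}
        )
        res = factorial_anova(design_from(df, factors=("a",)))
        # brute force: R² from residuals of cell-mean fit, adjusted by formula
        fitted = df.groupby("a").y.transform("mean")
        ss_res = ((df.y - fitted) ** 2).sum()
        ss_tot = ((df.y - df.y.mean()) ** 2).sum()
        r2 = 1 - ss_res / ss_tot
        n, p = 15, 2
        assert res.r2 == pytest.approx(r2, rel=1e-12)
        assert res.adjusted_r2 == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p - 1), rel=1e-12)


class TestTukey:
    def test_p_monotone_in_mean_difference(self):
        # fixed error term and group sizes: p must fall as |diff| grows
        values = np.array([0.0, 0.0, 1.0, 1.0, 3.0, 3.0, 6.0, 6.0])
        groups = np.repeat(list("abcd"), 2)
        tk = tukey_hsd(values, groups, mse=1.0, df_resid=10.0)
        tk = tk.assign(absdiff=tk["diff"].abs()).sort_values("absdiff")
        assert (np.diff(tk.p.to_numpy()) <= 1e-12).all()

    def test_identical_groups_have_p_one(self):
        tk = tukey_hsd(np.array([1.0, 1.0, 1.0, 1.0]), np.array(["a", "a", "b", "b"]),
                       mse=1.0, df_resid=8.0)
        assert tk.p.iloc[0] == pytest.approx(1.0)


class TestBackwardStepwise:
    def synth(self, n_per_cell=2, noise_sd=1e-8, seed=0):
        """Response generated exactly from filter + flow; mode and dilution
        carry no signal."""
        rng = np.random.default_rng(seed)
        rows = []
        for mode in (0, 1):
            for filt in (1, 2):
                for flow in (2.0, 4.0):
                    for dil in (0.0, 0.5):
                        for _ in range(n_per_cell):
                            y = 1.469 - 0.821 * filt + 0.612 * flow
                            rows.append(
                                {
                                    "mode": mode, "filter": filt, "flow": flow,
                                    "dilution": dil,
                                    "y": y + rng.normal(0, noise_sd),
                                }
                            )
        return pd.DataFrame(rows)

    def test_recovers_generating_model(self):
        df = self.synth()
        fit = backward_stepwise(
            FactorialDesign(df, "y", ("mode", "filter", "flow", "dilution"))
        )
        assert fit.retained == ["filter", "flow"]
        assert set(fit.dropped) == {"mode", "dilution"}
        assert fit.params["const"] == pytest.approx(1.469, abs=1e-6)
        assert fit.params["filter"] == pytest.approx(-0.821, abs=1e-6)
        assert fit.params["flow"] == pytest.approx(0.612, abs=1e-6)
        assert fit.adjusted_r2 > 0.999
        assert (fit.pvalues.drop("const") <= 0.05).all()
        assert (fit.vif < 5).all()
        assert np.allclose(fit.tolerance * fit.vif, 1.0)

    def test_response_as_its_own_candidate(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 30)
        df = pd.DataFrame({"y": y, "x": y})
        fit = backward_stepwise(FactorialDesign(df, "y", ("x",)), candidates=["x"])
        assert fit.retained == ["x"]
        assert fit.r2 == pytest.approx(1.0)

    def test_pure_noise_candidates_mostly_all_removed(self):
        # Monte-Carlo: with α=0.05, the intercept-only outcome dominates
        outcomes = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "y": rng.normal(0, 1, 24),
                    "a": rng.normal(0, 1, 24),
                    "b": rng.normal(0, 1, 24),
                    "c": rng.normal(0, 1, 24),
                }
            )
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = backward_stepwise(FactorialDesign(df, "y", ("a", "b", "c")))
            outcomes.append(len(fit.retained) == 0)
        assert np.mean(outcomes) > 0.5

    def test_adjusted_r2_consistency(self):
        df = self.synth(noise_sd=0.3, seed=2)
        fit = backward_stepwise(
            FactorialDesign(df, "y", ("mode", "filter", "flow", "dilution"))
        )
        n, p = fit.nobs, len(fit.retained)
        assert fit.adjusted_r2 == pytest.approx(
            1 - (1 - fit.r2) * (n - 1) / (n - p - 1), rel=1e-12
        )
        assert fit.adjusted_r2 <= fit.r2

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "a": [1.0, 2, 3], "b": [0.0, 1, 0]})
        with pytest.raises(ValueError):
            backward_stepwise(FactorialDesign(df, "y", ("a", "b")))
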