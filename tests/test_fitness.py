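import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from siderotrait.fitness import (
    CompetitionAssay,
    GrowthAssay,
    cohens_d,
    factorial_lm,
    genus_effect_sizes,
    malthusian,
    relative_fitness,
    selection_rate,
    spearman_rho,
)

finite = st.floats(-5.0, 5.0, allow_nan=False)
positive = st.floats(1e-3, 1e6, allow_nan=False)


class TestMalthusian:
    def test_no_net_growth(self):
        assert malthusian(100, 100, 10) == 0.0

    def test_growth(self):
        assert malthusian(1e2, 1e6, 48) == pytest.approx(math.log(1e4) / 48)

    def test_decline(self):
        assert malthusian(1e6, 1e5, 24) == pytest.approx(math.log(0.1) / 24)

    @pytest.mark.parametrize("args", [(0, 1, 1), (1, 0, 1), (1, 1, 0), (-1, 1, 1)])
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            malthusian(*args)

    @given(n0=positive, n1=positive, n2=positive,
           t1=st.floats(0.5, 100), t2=st.floats(0.5, 100))
    def test_time_weighted_additivity(self, n0, n1, n2, t1, t2):
        m01 = malthusian(n0, n1, t1)
        m12 = malthusian(n1, n2, t2)
        m02 = malthusian(n0, n2, t1 + t2)
        assert m02 == pytest.approx((m01 * t1 + m12 * t2) / (t1 + t2), abs=1e-9)


class TestRelativeFitnessAndSelectionRate:
    def test_equal_rates(self):
        assert relative_fitness(1.5, 1.5) == 1.0
        assert selection_rate(1.5, 1.5) == 0.0

    def test_growth_means_ratio(self):
        assert relative_fitness(1.98, 1.88) == pytest.approx(1.0532, abs=1e-4)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError, match="selection_rate"):
            relative_fitness(1.0, 0.0)

    def test_selection_rate_values(self):
        assert selection_rate(1.3, 1.0) == pytest.approx(0.3)
        assert selection_rate(-0.2, 0.1) == pytest.approx(-0.3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            selection_rate(float("nan"), 1.0)

    @given(a=finite, b=finite)
    def test_antisymmetry(self, a, b):
        assert selection_rate(a, b) == pytest.approx(-selection_rate(b, a))

    @given(a=st.floats(0.1, 5), b=st.floats(0.1, 5))
    def test_reciprocal(self, a, b):
        assert relative_fitness(a, b) == pytest.approx(1.0 / relative_fitness(b, a))

    def test_assay_records(self):
        g = GrowthAssay("wt", True, 1e2, 1e6, 48)
        assert g.m == pytest.approx(math.log(1e4) / 48)
        comp = CompetitionAssay("p", "np", 1e3, 1e5, 1e3, 1e4, 24)
        assert comp.s == pytest.approx(comp.m_a - comp.m_b)
        with pytest.raises(ValueError):
            CompetitionAssay("p", "np", 1e3, 1e5, 1e3, 1e4, 24, initial_frequency_a=1.0)


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_computed(self):
        # means 0.5 vs 1.5; each var 0.5 -> pooled SD sqrt(0.5)
        assert cohens_d([0, 1], [1, 2]) == pytest.approx(-1 / math.sqrt(0.5))

    def test_scale_invariance(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.5, 1, 25)
        d = cohens_d(a, b)
        for c in (0.1, 3.0, 100.0):
            assert cohens_d(c * a, c * b) == pytest.approx(d)

    def test_unbalanced_pooling_weights(self):
        a = np.array([0.0, 2.0])          # var 2
        b = np.array([1.0, 1.0, 1.0, 3.0])  # var 1
        pooled = math.sqrt((1 * 2.0 + 3 * 1.0) / 4)
        assert cohens_d(a, b) == pytest.approx((1.0 - 1.5) / pooled)

    def test_degenerate_variance(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])


def _brute_force_spearman(x, y):
    """Independent midrank + explicit-sum Pearson oracle."""
    def midranks(v):
        out = []
        for vi in v:
            less = sum(1 for vj in v if vj < vi)
            equal = sum(1 for vj in v if vj == vi)
            out.append(less + (equal + 1) / 2.0)
        return out

    rx, ry = midranks(x), midranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    S = sum((a - b) ** 2 for a, b in zip(rx, ry))
    return S, num / den


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)
        assert res.S == 0.0

    def test_reversed_ranks(self):
        res = spearman_rho([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.rho == pytest.approx(-1.0)
        assert res.S == pytest.approx(4 * (16 - 1) / 3)  # n(n^2-1)/3 = 20

    def test_ties_match_brute_force(self):
        x, y = [1, 2, 2, 4], [1, 3, 2, 4]
        res = spearman_rho(x, y)
        S, rho = _brute_force_spearman(x, y)
        assert res.S == pytest.approx(S)
        assert res.rho == pytest.approx(rho)

    def test_matches_scipy_rho(self, rng):
        from scipy import stats

        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        res = spearman_rho(x, y)
        ref = stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)
        assert res.method == "t-approximation"

    def test_exact_permutation_p(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        res = spearman_rho(x, y)
        # direct enumeration of all 5! permutations
        _, obs = _brute_force_spearman(x, y)
        count = 0
        for perm in itertools.permutations(y):
            _, r = _brute_force_spearman(x, list(perm))
            if abs(r) >= abs(obs) - 1e-12:
                count += 1
        assert res.method == "exact-permutation"
        assert res.pvalue == pytest.approx(count / math.factorial(5))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])

    def test_too_short(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [1, 2])


def _random_factorial_table(rng, reps=4):
    rows = []
    for a in (0, 1):
        for b in ("x", "y"):
            for r in range(reps):
                rows.append({"copper": a, "ctx": b,
                             "resp": rng.normal(a * 0.4 + (b == "y") * 0.2, 0.3)})
    return pd.DataFrame(rows)


class TestFactorialLM:
    def test_balanced_marginal_means_average_cells(self, rng):
        df = _random_factorial_table(rng)
        res = factorial_lm(df, "resp", "copper", "ctx", reduce=False)
        cells = df.groupby(["copper", "ctx"])["resp"].mean()
        mm = res.marginal_means
        for level in (0, 1):
            expect = (cells[level]["x"] + cells[level]["y"]) / 2
            got = mm[(mm.factor == "copper") & (mm.level == level)]["mean"].iloc[0]
            assert got == pytest.approx(expect)

    def test_constant_response_zero_f(self):
        df = _random_factorial_table(np.random.default_rng(0))
        df["resp"] = 2.5
        res = factorial_lm(df, "resp", "copper", "ctx")
        assert (res.anova["F"] == 0).all()

    def test_normal_equations_oracle(self, rng):
        for _ in range(5):
            df = _random_factorial_table(rng, reps=3)
            res = factorial_lm(df, "resp", "copper", "ctx", reduce=False)
            a = (df["copper"] == 1).to_numpy(float)
            b = (df["ctx"] == "y").to_numpy(float)
            X = np.column_stack([np.ones(len(df)), a, b, a * b])
            beta = np.linalg.solve(X.T @ X, X.T @ df["resp"].to_numpy())
            np.testing.assert_allclose(res.coef_vector(), beta, atol=1e-10)

    def test_sequential_f_matches_statsmodels(self, rng):
        smf = pytest.importorskip("statsmodels.formula.api")
        import statsmodels.api as sm

        df = _random_factorial_table(rng)
        fit = smf.ols("resp ~ C(copper) * C(ctx)", data=df).fit()
        table = sm.stats.anova_lm(fit, typ=1)
        res = factorial_lm(df, "resp", "copper", "ctx", reduce=False)
        np.testing.assert_allclose(
            res.anova["F"].to_numpy(),
            table["F"].to_numpy()[:3],
            rtol=1e-8,
        )

    def test_empty_cell_raises(self, rng):
        df = _random_factorial_table(rng)
        df = df[~((df.copper == 1) & (df.ctx == "y"))]
        with pytest.raises(ValueError, match="cell"):
            factorial_lm(df, "resp", "copper", "ctx")

    def test_missing_column(self, rng):
        with pytest.raises(ValueError, match="nope"):
            factorial_lm(_random_factorial_table(rng), "nope", "copper", "ctx")


class TestGenusEffectSizes:
    @staticmethod
    def _panel(rng, effects):
        rows = []
        for genus, (baseline, d_shift) in effects.items():
            for copper in (0, 1):
                for i in range(10):
                    rows.append({
                        "genus": genus,
                        "copper": copper,
                        "isolate_type": "community",
                        "siderophore": rng.normal(baseline + copper * d_shift, 0.1),
                    })
        return pd.DataFrame(rows)

    def test_global_null_degenerate_spearman(self):
        rows = []
        values = [0.1, 0.2, 0.3, 0.4]
        for genus in ("A", "B", "C"):
            for copper in (0, 1):
                for v in values:
                    rows.append({"genus": genus, "copper": copper,
                                 "isolate_type": "community", "siderophore": v})
        records, summary = genus_effect_sizes(pd.DataFrame(rows))
        assert all(r.cohens_d == 0 for r in records)
        assert math.isnan(summary.rho) and summary.method == "degenerate"

    def test_constructed_monotonicity(self, rng):
        effects = {"A": (0.2, 0.3), "B": (0.4, 0.1), "C": (0.6, -0.1),
                   "D": (0.8, -0.3), "E": (1.0, -0.5)}
        records, summary = genus_effect_sizes(self._panel(rng, effects))
        assert summary.rho == pytest.approx(-1.0)

    def test_compositional_oracle(self, rng):
        from siderotrait.fitness import spearman_rho as sr

        effects = {"A": (0.2, 0.15), "B": (0.5, 0.0), "C": (0.7, -0.2), "D": (0.3, 0.1)}
        panel = self._panel(rng, effects)
        records, summary = genus_effect_sizes(panel)
        for rec in records:
            sub = panel[panel.genus == rec.genus]
            cu = sub[sub.copper == 1]["siderophore"]
            ctrl = sub[sub.copper == 0]["siderophore"]
            assert rec.cohens_d == pytest.approx(cohens_d(cu, ctrl))
            assert rec.baseline_mean == pytest.approx(ctrl.mean())
        ref = sr([r.cohens_d for r in records], [r.baseline_mean for r in records])
        assert summary.rho == pytest.approx(ref.rho)
        assert summary.S == pytest.approx(ref.S)

    def test_min_n_filtering_and_error(self, rng):
        panel = self._panel(rng, {"A": (0.2, 0.1), "B": (0.5, 0.0)})
        with pytest.raises(ValueError, match="genera"):
            genus_effect_sizes(panel)

    def test_baseline_flag(self, rng):
        effects = {"A": (0.2, 0.0), "B": (0.9, 0.0), "C": (0.5, 0.0)}
        records, _ = genus_effect_sizes(self._panel(rng, effects), baseline_threshold=0.55)
        flags = {r.genus: r.high_baseline for r in records}
        assert flags["B"] and not flags["A"]
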