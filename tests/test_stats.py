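"""Group-statistics protocol: omnibus/pairwise gating, ANCOVA, percent change."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gaitfusion.matrix import ALL_FEATURES, FeatureMatrix
from gaitfusion.stats import (
    ancova_adjust,
    compare_groups,
    fisher_exact_mc,
    percent_change,
    side_adjusted_ancova,
)


def _matrix(values: dict[str, np.ndarray], groups, covariates=None, sides=None):
    n = len(groups)
    data = {"group": list(groups)}
    data.update({k: np.asarray(v, float) for k, v in values.items()})
    cov = covariates or {}
    data["age"] = np.asarray(cov.get("age", np.full(n, 60.0)), float)
    data["sex"] = cov.get("sex", ["F"] * n)
    data["bmi"] = np.asarray(cov.get("bmi", np.full(n, 25.0)), float)
    data["side_category"] = sides if sides is not None else ["none"] * n
    df = pd.DataFrame(data, index=pd.Index([f"S{i}" for i in range(n)],
                                           name="subject_id"))
    return FeatureMatrix(df)


class TestCompareGroups:
    def test_strong_shift_flags_all_pairs(self, rng):
        groups = ["Healthy"] * 20 + ["KOA"] * 20 + ["TKA"] * 20
        base = rng.normal(size=60)
        shift = np.repeat([0.0, 3.0, 6.0], 20)  # 3 pooled SDs apart
        m = _matrix({"knee_rom": base + shift}, groups)
        row = compare_groups(m, features=["knee_rom"])[0]
        assert row.omnibus_p < 0.001
        assert set(row.pairwise_p) == {"HvsK", "HvsT", "KvsT"}
        assert all(row.significant.values())
        assert set(row.shapiro_p) == {"Healthy", "KOA", "TKA"}

    def test_identical_groups_skip_pairwise(self):
        groups = ["Healthy"] * 5 + ["KOA"] * 5 + ["TKA"] * 5
        m = _matrix({"knee_rom": np.tile(np.arange(5.0), 3)}, groups)
        row = compare_groups(m, features=["knee_rom"])[0]
        assert row.omnibus_p > 0.9
        assert row.pairwise_p == {}

    def test_null_rejection_rate_matches_alpha(self):
        # omnibus type-I error ~ alpha over 1000 null replicates
        rng = np.random.default_rng(2024)
        groups = ["Healthy"] * 15 + ["KOA"] * 15 + ["TKA"] * 15
        n_reps, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_reps):
            m = _matrix({"f": rng.normal(size=45)}, groups)
            row = compare_groups(m, features=["f"])[0]
            rejections += row.omnibus_p < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert abs(rejections / n_reps - alpha) < 3 * se + 1e-9

    def test_small_group_skipped_with_note(self):
        groups = ["Healthy"] * 6 + ["KOA"] * 2 + ["TKA"] * 6
        m = _matrix({"f": np.arange(14.0)}, groups)
        row = compare_groups(m, features=["f"])[0]
        assert "skipped" in row.note

    def test_categorical_feature_uses_fisher(self, rng):
        groups = ["Healthy"] * 10 + ["KOA"] * 10 + ["TKA"] * 10
        m = _matrix({"knee_rom": rng.normal(size=30)}, groups)
        m.data["sex"] = ["F", "M"] * 15
        rows = compare_groups(m, features=["sex"])
        assert rows[0].omnibus_test == "fisher_exact"
        assert 0.0 <= rows[0].omnibus_p <= 1.0


class TestFisherExact:
    def test_2x2_matches_scipy_exact(self):
        from scipy.stats import fisher_exact

        table = np.array([[8, 2], [1, 5]])
        assert fisher_exact_mc(table) == pytest.approx(
            fisher_exact(table)[1], abs=1e-12
        )

    def test_monte_carlo_close_to_exact_on_2x3(self):
        # compare against the exhaustive exact p-value computed by
        # enumerating all tables with the observed margins
        from math import comb
        from itertools import product

        table = np.array([[6, 1, 2], [2, 5, 4]])
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        n = table.sum()

        def prob(t):
            # margins-conditioned probability (multivariate hypergeometric)
            num = np.prod([comb(int(col[j]), int(t[0, j])) for j in range(3)])
            return num / comb(int(n), int(row[0]))

        obs_p = prob(table)
        total = 0.0
        for a, b in product(range(min(row[0], col[0]) + 1),
                            range(min(row[0], col[1]) + 1)):
            c = row[0] - a - b
            if c < 0 or c > col[2]:
                continue
            t = np.array([[a, b, c], [col[0] - a, col[1] - b, col[2] - c]])
            if (t >= 0).all():
                p = prob(t)
                if p <= obs_p + 1e-12:
                    total += p
        got = fisher_exact_mc(table, n_resamples=40000, seed=5)
        assert got == pytest.approx(total, abs=0.02)


class TestAncova:
    def test_no_covariates_reduces_to_anova(self, rng):
        from scipy.stats import f_oneway

        groups = ["Healthy"] * 12 + ["KOA"] * 12 + ["TKA"] * 12
        y = rng.normal(size=36) + np.repeat([0, 1.0, 2.0], 12)
        m = _matrix({"f": y}, groups)
        row = ancova_adjust(m, covariates=[], features=["f"])[0]
        F, p = f_oneway(y[:12], y[12:24], y[24:])
        assert row.ancova_F == pytest.approx(F, rel=1e-10)
        assert row.ancova_p == pytest.approx(p, rel=1e-10)

    def test_matches_hand_computed_sums_of_squares(self, rng):
        # n = 12, 3 groups, 1 numeric covariate: brute-force OLS oracle
        groups = ["Healthy"] * 4 + ["KOA"] * 4 + ["TKA"] * 4
        age = rng.uniform(50, 80, size=12)
        y = 0.3 * age + np.repeat([0.0, 1.0, 2.5], 4) + rng.normal(size=12)
        m = _matrix({"f": y}, groups, covariates={"age": age})
        row = ancova_adjust(m, covariates=["age"], features=["f"])[0]

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return float(np.sum((y - X @ beta) ** 2))

        ones = np.ones(12)
        g1 = np.repeat([0.0, 1.0, 0.0], 4)
        g2 = np.repeat([0.0, 0.0, 1.0], 4)
        full = np.column_stack([ones, g1, g2, age])
        reduced = np.column_stack([ones, age])  # group dropped
        ss_group = rss(reduced) - rss(full)
        ss_resid = rss(full)
        df_group, df_resid = 2, 12 - 4
        F = (ss_group / df_group) / (ss_resid / df_resid)
        assert row.ancova_F == pytest.approx(F, abs=1e-8)
        assert row.partial_eta_sq == pytest.approx(
            ss_group / (ss_group + ss_resid), abs=1e-8
        )

    def test_pure_covariate_effect_gives_null_eta(self):
        # response driven only by the covariate: group effect ~ null;
        # over replicates the mean partial eta^2 sits near its null
        # expectation E[eta2] ~ df_group / (df_group + df_resid)
        rng = np.random.default_rng(99)
        groups = ["Healthy"] * 10 + ["KOA"] * 10 + ["TKA"] * 10
        etas, ps = [], []
        for _ in range(300):
            age = rng.uniform(50, 80, size=30)
            y = 0.5 * age + rng.normal(size=30)
            m = _matrix({"f": y}, groups, covariates={"age": age})
            row = ancova_adjust(m, covariates=["age"], features=["f"])[0]
            etas.append(row.partial_eta_sq)
            ps.append(row.ancova_p)
        expected = 2 / (2 + 26)
        assert np.mean(etas) == pytest.approx(expected, abs=0.025)
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_constant_covariate_dropped(self, rng, caplog):
        groups = ["Healthy"] * 5 + ["KOA"] * 5 + ["TKA"] * 5
        m = _matrix({"f": rng.normal(size=15)}, groups,
                    covariates={"age": np.full(15, 60.0)})
        with_cov = ancova_adjust(m, covariates=["age"], features=["f"])[0]
        without = ancova_adjust(m, covariates=[], features=["f"])[0]
        assert with_cov.ancova_F == pytest.approx(without.ancova_F, rel=1e-12)

    def test_tukey_runs_on_significant_effects(self, rng):
        groups = ["Healthy"] * 10 + ["KOA"] * 10 + ["TKA"] * 10
        y = rng.normal(size=30) + np.repeat([0.0, 5.0, 10.0], 10)
        m = _matrix({"f": y}, groups)
        row = ancova_adjust(m, covariates=[], features=["f"])[0]
        assert row.tukey is not None and len(row.tukey) == 3


class TestSideAdjustedAncova:
    def test_uniform_side_reduces_to_plain_ancova(self, rng):
        groups = ["Healthy"] * 8 + ["KOA"] * 8 + ["TKA"] * 8
        y = rng.normal(size=24) + np.repeat([0, 1.0, 2.0], 8)
        m = _matrix({"f": y}, groups, sides=["none"] * 24)
        side_row = side_adjusted_ancova(m, covariates=[], features=["f"])[0]
        plain_row = ancova_adjust(m, covariates=[], features=["f"])[0]
        assert side_row.ancova_F == pytest.approx(plain_row.ancova_F, rel=1e-12)

    def test_side_explaining_variance_kills_group_effect(self, rng):
        # side alone drives the response (side assignment crossed with
        # group); after adjustment the group effect is negligible
        groups = ["Healthy"] * 10 + ["KOA"] * 10 + ["TKA"] * 10
        sides = ["bilateral", "unilateral_left"] * 15
        side_effect = {"bilateral": 5.0, "unilateral_left": 10.0}
        y = np.array([side_effect[s] for s in sides]) + 0.1 * rng.normal(size=30)
        m = _matrix({"f": y}, groups, sides=sides)
        row = side_adjusted_ancova(m, covariates=[], features=["f"])[0]
        assert row.partial_eta_sq < 0.2

    def test_singleton_category_merged(self, rng, caplog):
        groups = ["Healthy"] * 6 + ["KOA"] * 6 + ["TKA"] * 6
        sides = ["none"] * 17 + ["bilateral"]
        m = _matrix({"f": rng.normal(size=18)}, groups, sides=sides)
        rows = side_adjusted_ancova(m, covariates=[], features=["f"])
        assert rows[0].ancova_F is not None  # model stayed full rank


class TestSummaryTable:
    def test_layout_mean_sd_and_pvalues(self, rng):
        from gaitfusion.stats import summary_table

        groups = ["Healthy"] * 10 + ["KOA"] * 10 + ["TKA"] * 10
        y = rng.normal(size=30) + np.repeat([0.0, 4.0, 8.0], 10)
        m = _matrix({"knee_rom": y}, groups)
        rows = compare_groups(m, features=["knee_rom"])
        table = summary_table(m, rows)
        rec = table[table.feature == "knee_rom"].iloc[0]
        assert "±" in rec["Healthy"]
        assert rec["P-value"] < 0.05
        assert rec["HvsK"] is not None


class TestPercentChange:
    @pytest.mark.parametrize(
        "ref,comp,expected",
        [
            (34.40, 21.08, -38.7),   # swing perimeter, disease vs healthy
            (0.24, 0.30, 25.0),      # hip entropy rise
            (930.89, 593.51, -36.2),
            (550.93, 398.02, -27.8),
            (138.32, 114.09, -17.5),
            (1481.91, 996.28, -32.8),
            (1481.91, 1023.51, -30.9),
            (0.30, 0.21, -30.0),
            (0.28, 0.38, 35.7),
            (0.38, 0.30, -21.1),
            (0.20, 0.24, 20.0),
            (5.0, 5.0, 0.0),
        ],
    )
    def test_reference_values(self, ref, comp, expected):
        assert percent_change(ref, comp) == pytest.approx(expected, abs=1e-9)

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
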