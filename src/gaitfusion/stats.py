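"""Group statistics for the gait feature matrix.

Protocol per feature: Shapiro–Wilk normality screening per group; a
Kruskal–Wallis omnibus test across the three groups; if the omnibus test
is significant, all three pairwise Mann–Whitney U tests with significance
declared at the Bonferroni-corrected fixed threshold p < 0.017 (0.05/3,
applied as a threshold rather than as adjusted p-values, mirroring the
protocol this package implements).  Categorical variables are tested with
a (Monte-Carlo, margins-conditioned) Fisher exact test.  Covariate
adjustment uses ANCOVA — an OLS model ``feature ~ group + covariates`` —
with the group main effect's F, p and partial η² = SS_group /
(SS_group + SS_residual) (Type-II sums of squares by default), and
Tukey HSD post-hoc comparisons on significant main effects.  A variant
additionally enters the affected/operated-side category as a dummy-coded
covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .matrix import FeatureMatrix

logger = logging.getLogger("gaitfusion.stats")

PAIR_LABELS = {
    frozenset({"Healthy", "KOA"}): "HvsK",
    frozenset({"Healthy", "TKA"}): "HvsT",
    frozenset({"KOA", "TKA"}): "KvsT",
}


@dataclass
class FeatureStatRow:
    """All test results for one feature."""

    feature: str
    shapiro_p: dict[str, float] = field(default_factory=dict)
    omnibus_p: float | None = None
    omnibus_test: str = "kruskal"
    pairwise_p: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)
    ancova_F: float | None = None
    ancova_p: float | None = None
    partial_eta_sq: float | None = None
    tukey: pd.DataFrame | None = None
    note: str = ""


def _pair_label(g1: str, g2: str) -> str:
    return PAIR_LABELS.get(frozenset({g1, g2}), f"{g1}vs{g2}")


def fisher_exact_mc(
    table: np.ndarray, n_resamples: int = 10000, seed: int | np.random.Generator = 0
) -> float:
    """Monte-Carlo Fisher exact test for an r × c contingency table.

    Conditions on both margins (Patefield sampling) and estimates
    P(table at least as extreme as observed) by the table probability
    ordering, the same scheme R's ``fisher.test(simulate.p.value=TRUE)``
    uses.  Exact for 2×2 via scipy.
    """
    table = np.asarray(table, dtype=int)
    if table.shape == (2, 2):
        return float(sps.fisher_exact(table)[1])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dist = sps.random_table(table.sum(axis=1), table.sum(axis=0))
    obs_logp = dist.logpmf(table)
    samples = dist.rvs(size=n_resamples, random_state=rng)
    logp = dist.logpmf(samples)
    hits = int(np.count_nonzero(logp <= obs_logp + 1e-9))
    return (hits + 1) / (n_resamples + 1)


def compare_groups(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    pairwise_alpha: float = 0.017,
    features: list[str] | None = None,
    min_group_size: int = 3,
    seed: int = 0,
) -> list[FeatureStatRow]:
    """Normality screening + omnibus + gated pairwise tests per feature.

    Pairwise Mann–Whitney tests run only when the omnibus test rejects at
    ``alpha``; their significance is declared at ``pairwise_alpha``.
    Non-numeric features are tested with the Fisher exact test on the
    group × level contingency table.
    """
    df = matrix.data
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    features = features if features is not None else matrix.feature_names
    rows: list[FeatureStatRow] = []
    for feat in features:
        col = df[feat]
        row = FeatureStatRow(feature=feat)
        if not pd.api.types.is_numeric_dtype(col):
            tab = pd.crosstab(df["group"], col).to_numpy()
            row.omnibus_test = "fisher_exact"
            row.omnibus_p = fisher_exact_mc(tab, seed=seed)
            rows.append(row)
            continue
        samples = {g: col[df["group"] == g].dropna().to_numpy() for g in groups}
        if any(len(v) < min_group_size for v in samples.values()):
            logger.warning("feature %s skipped: a group has < %d observations",
                           feat, min_group_size)
            row.note = "skipped: insufficient group size"
            rows.append(row)
            continue
        for g, v in samples.items():
            # Shapiro-Wilk needs >= 3 observations and nonzero variance
            row.shapiro_p[g] = (
                float(sps.shapiro(v).pvalue) if np.ptp(v) > 0 else 1.0
            )
        if all(np.ptp(v) == 0 for v in samples.values()) and len(
            {v[0] for v in samples.values()}
        ) == 1:
            row.omnibus_p = 1.0
        else:
            row.omnibus_p = float(
                sps.kruskal(*[samples[g] for g in groups]).pvalue
            )
        if row.omnibus_p < alpha:
            for g1, g2 in combinations(groups, 2):
                p = float(
                    sps.mannwhitneyu(
                        samples[g1], samples[g2], alternative="two-sided"
                    ).pvalue
                )
                label = _pair_label(g1, g2)
                row.pairwise_p[label] = p
                row.significant[label] = p < pairwise_alpha
        rows.append(row)
    return rows


def _partial_eta_group(
    df: pd.DataFrame, feature: str, covariates: list[str], ss_type: int
) -> tuple[float, float, float]:
    """Fit feature ~ C(group) + covariates, return (F, p, partial η²)."""
    terms = ["C(group)"] + covariates
    formula = f"Q('{feature}') ~ " + " + ".join(terms)
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=ss_type)
    ss_group = float(anova.loc["C(group)", "sum_sq"])
    f_val = float(anova.loc["C(group)", "F"])
    p_val = float(anova.loc["C(group)", "PR(>F)"])
    ss_resid = float(anova.loc["Residual", "sum_sq"])
    eta = ss_group / (ss_group + ss_resid)
    return f_val, p_val, eta


def ancova_adjust(
    matrix: FeatureMatrix,
    covariates: list[str],
    features: list[str] | None = None,
    alpha: float = 0.05,
    ss_type: int = 2,
) -> list[FeatureStatRow]:
    """Covariate-adjusted group comparison per feature.

    Fits ``feature ~ group + covariates`` by OLS, reports the group main
    effect (F, p) and partial η²; runs Tukey HSD when the main effect is
    significant.  Constant (rank-deficient) covariates are dropped with a
    warning.  Categorical covariates (e.g. sex) are dummy-coded.
    """
    df = matrix.data.copy()
    features = features if features is not None else matrix.feature_names
    usable: list[str] = []
    for cov in covariates:
        if df[cov].nunique(dropna=True) < 2:
            logger.warning("covariate %s is constant; dropped from the model", cov)
            continue
        usable.append(cov)
    terms = [
        f"C(Q('{c}'))" if not pd.api.types.is_numeric_dtype(df[c]) else f"Q('{c}')"
        for c in usable
    ]
    rows: list[FeatureStatRow] = []
    for feat in features:
        sub = df[[feat, "group"] + usable].dropna()
        f_val, p_val, eta = _partial_eta_group(sub, feat, terms, ss_type)
        row = FeatureStatRow(
            feature=feat, ancova_F=f_val, ancova_p=p_val, partial_eta_sq=eta
        )
        if p_val < alpha:
            tk = pairwise_tukeyhsd(sub[feat].to_numpy(), sub["group"].to_numpy())
            row.tukey = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0]
            )
        rows.append(row)
    return rows


def side_adjusted_ancova(
    matrix: FeatureMatrix,
    covariates: list[str] = (),
    features: list[str] | None = None,
    alpha: float = 0.05,
    ss_type: int = 2,
) -> list[FeatureStatRow]:
    """ANCOVA with the side category dummy-coded among the covariates.

    Side categories with a single subject are merged into the largest
    category (with a warning) so the design stays full rank.
    """
    df = matrix.data.copy()
    if "side_category" not in df.columns:
        raise ValueError("matrix lacks a side_category column")
    counts = df["side_category"].value_counts()
    if counts.nunique() == 0:
        raise ValueError("side_category is empty")
    singletons = counts[counts < 2].index.tolist()
    if singletons and len(counts) > 1:
        target = counts.idxmax()
        logger.warning(
            "side categories %s have a single subject; merged into %r",
            singletons, target,
        )
        df.loc[df["side_category"].isin(singletons), "side_category"] = target
    m2 = FeatureMatrix(df, categories=matrix.categories)
    covs = list(covariates)
    if df["side_category"].nunique() > 1:
        covs = covs + ["side_category"]
    return ancova_adjust(m2, covs, features=features, alpha=alpha, ss_type=ss_type)


def percent_change(reference_mean: float, comparison_mean: float) -> float:
    """Signed percent change of ``comparison`` relative to ``reference``.

    Rounded to one decimal for reporting.
    """
    if reference_mean == 0:
        raise ValueError("reference mean must be nonzero")
    return round(100.0 * (comparison_mean - reference_mean) / reference_mean, 1)


def group_summary(matrix: FeatureMatrix) -> pd.DataFrame:
    """Mean ± SD per group per feature (long format)."""
    df = matrix.data
    records = []
    for feat in matrix.feature_names:
        for g, sub in df.groupby("group"):
            v = sub[feat].dropna()
            records.append(
                {"feature": feat, "group": g,
                 "mean": float(v.mean()), "sd": float(v.std(ddof=1))}
            )
    return pd.DataFrame(records)


def summary_table(matrix: FeatureMatrix, rows: list[FeatureStatRow]) -> pd.DataFrame:
    """Report table: mean ± SD per group, omnibus P, pairwise columns.

    One row per feature, mirroring the conventional clinical-table layout.
    """
    summary = group_summary(matrix)
    by_feature = {r.feature: r for r in rows}
    groups = sorted(matrix.data["group"].unique())
    records = []
    for feat in matrix.feature_names:
        rec: dict = {"feature": feat}
        sub = summary[summary.feature == feat].set_index("group")
        for g in groups:
            rec[g] = f"{sub.loc[g, 'mean']:.2f} ± {sub.loc[g, 'sd']:.2f}"
        r = by_feature.get(feat)
        if r is not None:
            rec["P-value"] = r.omnibus_p
            for label in ("HvsK", "HvsT", "KvsT"):
                rec[label] = r.pairwise_p.get(label)
        records.append(rec)
    return pd.DataFrame(records)


def rows_to_frame(rows: list[FeatureStatRow]) -> pd.DataFrame:
    """Flatten stat rows into a report table."""
    records = []
    for r in rows:
        rec: dict = {"feature": r.feature, "omnibus_test": r.omnibus_test,
                     "omnibus_p": r.omnibus_p}
        for g, p in r.shapiro_p.items():
            rec[f"shapiro_p_{g}"] = p
        for label in ("HvsK", "HvsT", "KvsT"):
            rec[f"p_{label}"] = r.pairwise_p.get(label)
            rec[f"sig_{label}"] = r.significant.get(label)
        rec["ancova_F"] = r.ancova_F
        rec["ancova_p"] = r.ancova_p
        rec["partial_eta_sq"] = r.partial_eta_sq
        rec["note"] = r.note
        records.append(rec)
    return pd.DataFrame(records)
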