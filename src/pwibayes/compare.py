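"""Frequentist comparators: split-plot ANOVA, effect t-tests, error rates.

These reproduce the classical analysis that accompanies the Bayesian
estimation: a two-factor split-plot (mixed) repeated-measures ANOVA with
group as the between-participant factor and distractor condition as the
within-participant factor; one-sample t-tests of each distractor effect
against zero within each group; Welch unequal-variance t-tests comparing
effect magnitudes between groups (with Welch-Satterthwaite fractional df);
and a per-condition logistic-regression comparison of error proportions.

No multiple-comparison correction is applied, and sphericity is not
corrected by default (a Greenhouse-Geisser option exists); both match the
reporting conventions this analysis mirrors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import EFFECT_NAMES
from .simulate import STATUS_ERROR

__all__ = ["AnovaTable", "splitplot_anova", "effect_ttests", "error_rate_comparison"]


@dataclass
class AnovaTable:
    """Omnibus split-plot ANOVA results plus the underlying sums of squares."""

    omnibus: pd.DataFrame  # term, ss, df1, df2, F, p
    sums_of_squares: dict[str, float]
    n_per_group: dict[str, int]
    gg_epsilon: float | None = None
    dropped_participants: list[str] = field(default_factory=list)

    def __getitem__(self, term: str) -> pd.Series:
        return self.omnibus.set_index("term").loc[term]


def _gg_epsilon(wide_vals: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    a = wide_vals.shape[1]
    pooled = np.zeros((a, a))
    dof = 0
    for g in np.unique(groups):
        sub = wide_vals[groups == g]
        if len(sub) >= 2:
            pooled += np.cov(sub, rowvar=False) * (len(sub) - 1)
            dof += len(sub) - 1
    pooled /= max(dof, 1)
    centered = pooled - pooled.mean(axis=0) - pooled.mean(axis=1)[:, None] + pooled.mean()
    num = np.trace(centered) ** 2
    den = (a - 1) * np.sum(centered * centered)
    return float(num / den) if den > 0 else 1.0


def splitplot_anova(
    medians: pd.DataFrame,
    conditions: tuple[str, ...] | None = None,
    greenhouse_geisser: bool = False,
) -> AnovaTable:
    """Two-factor split-plot ANOVA on the wide per-participant median table.

    Decomposition: the group main effect is tested against the
    between-participant error (participants within groups); the distractor
    main effect and the group x distractor interaction are tested against
    the within-participant residual. Participants with any missing condition
    are dropped (with a warning recorded in ``dropped_participants``).
    With two groups of sizes n1, n2 and C conditions the dfs are
    (1, n1+n2-2) for group and (C-1, (C-1)(n1+n2-2)) for the within terms.
    """
    if conditions is None:
        conditions = tuple(
            c for c in medians.columns if c not in ("participant_id", "group")
        )
    complete = medians.dropna(subset=list(conditions))
    dropped = sorted(set(medians["participant_id"]) - set(complete["participant_id"]))
    if complete["group"].nunique() < 2:
        raise ValueError("need two groups with complete data")

    vals = complete[list(conditions)].to_numpy(dtype=float)  # (N, C)
    groups = complete["group"].to_numpy()
    n_subj, a = vals.shape
    grand = vals.mean()
    glevels = sorted(set(groups))
    n_per_group = {g: int((groups == g).sum()) for g in glevels}

    subj_means = vals.mean(axis=1)
    group_means = {g: subj_means[groups == g].mean() for g in glevels}
    cond_means = vals.mean(axis=0)

    ss_total = float(((vals - grand) ** 2).sum())
    ss_group = float(a * sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in glevels))
    ss_subj_within = float(
        a * sum(((subj_means[groups == g] - group_means[g]) ** 2).sum() for g in glevels)
    )
    ss_cond = float(n_subj * ((cond_means - grand) ** 2).sum())
    cell_means = np.array([vals[groups == g].mean(axis=0) for g in glevels])  # (G, C)
    ss_cells = float(
        sum(
            n_per_group[g] * ((cell_means[j] - grand) ** 2).sum()
            for j, g in enumerate(glevels)
        )
    )
    ss_inter = ss_cells - ss_group - ss_cond
    ss_error = ss_total - ss_group - ss_subj_within - ss_cond - ss_inter

    n_groups = len(glevels)
    df_group = n_groups - 1
    df_subj = n_subj - n_groups
    df_cond = a - 1
    df_inter = (n_groups - 1) * (a - 1)
    df_err = (a - 1) * (n_subj - n_groups)

    eps = 1.0
    if greenhouse_geisser:
        eps = _gg_epsilon(vals, groups)

    rows = []
    ms_subj = ss_subj_within / df_subj
    f_group = (ss_group / df_group) / ms_subj if ms_subj > 0 else np.nan
    rows.append(
        {
            "term": "group",
            "ss": ss_group,
            "df1": df_group,
            "df2": df_subj,
            "F": f_group,
            "p": float(stats.f.sf(f_group, df_group, df_subj)) if np.isfinite(f_group) else np.nan,
        }
    )
    ms_err = ss_error / df_err if df_err > 0 else np.nan
    for term, ss, df1 in (("distractor", ss_cond, df_cond), ("interaction", ss_inter, df_inter)):
        f = (ss / df1) / ms_err if ms_err and ms_err > 0 else np.nan
        d1, d2 = df1 * eps, df_err * eps
        rows.append(
            {
                "term": term,
                "ss": ss,
                "df1": d1,
                "df2": d2,
                "F": f,
                "p": float(stats.f.sf(f, d1, d2)) if np.isfinite(f) else np.nan,
            }
        )
    ss_dict = {
        "total": ss_total,
        "group": ss_group,
        "subjects_within_groups": ss_subj_within,
        "distractor": ss_cond,
        "interaction": ss_inter,
        "error_within": ss_error,
    }
    return AnovaTable(
        omnibus=pd.DataFrame(rows),
        sums_of_squares=ss_dict,
        n_per_group=n_per_group,
        gg_epsilon=eps if greenhouse_geisser else None,
        dropped_participants=dropped,
    )


def _one_sample_row(group: str, effect: str, vals: np.ndarray) -> dict:
    n = len(vals)
    mean = float(vals.mean()) if n else np.nan
    if n < 2 or np.std(vals, ddof=1) == 0:
        return {
            "comparison": f"{group}: {effect}", "group": group, "effect": effect,
            "mean": mean, "t": np.nan, "df": n - 1 if n else np.nan, "p": np.nan,
            "ci_low": np.nan, "ci_high": np.nan, "note": "undefined (zero variance or n < 2)",
        }
    res = stats.ttest_1samp(vals, 0.0)
    ci = res.confidence_interval(0.95)
    return {
        "comparison": f"{group}: {effect}", "group": group, "effect": effect,
        "mean": mean, "t": float(res.statistic), "df": float(n - 1), "p": float(res.pvalue),
        "ci_low": float(ci.low), "ci_high": float(ci.high), "note": "",
    }


def effect_ttests(effects: pd.DataFrame) -> pd.DataFrame:
    """Per-group one-sample t-tests of each effect against zero, plus Welch
    unequal-variance between-group comparisons (patient - control) with
    Welch-Satterthwaite fractional df and 95% CIs."""
    groups = sorted(effects["group"].unique())
    if any((effects["group"] == g).sum() < 2 for g in groups):
        raise ValueError("need >= 2 participants per group")
    rows = []
    for effect in EFFECT_NAMES:
        col = f"{effect}_ms"
        for group in groups:
            vals = effects.loc[effects["group"] == group, col].dropna().to_numpy()
            rows.append(_one_sample_row(group, effect, vals))
    for effect in EFFECT_NAMES:
        col = f"{effect}_ms"
        pat = effects.loc[effects["group"] == "patient", col].dropna().to_numpy()
        con = effects.loc[effects["group"] == "control", col].dropna().to_numpy()
        mean_diff = float(pat.mean() - con.mean()) if len(pat) and len(con) else np.nan
        if len(pat) < 2 or len(con) < 2 or (np.std(pat, ddof=1) == 0 and np.std(con, ddof=1) == 0):
            rows.append(
                {
                    "comparison": f"patients vs. controls: {effect}", "group": "between",
                    "effect": effect, "mean": mean_diff, "t": np.nan, "df": np.nan,
                    "p": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                    "note": "undefined (zero variance or n < 2)",
                }
            )
            continue
        res = stats.ttest_ind(pat, con, equal_var=False)
        ci = res.confidence_interval(0.95)
        rows.append(
            {
                "comparison": f"patients vs. controls: {effect}", "group": "between",
                "effect": effect, "mean": mean_diff, "t": float(res.statistic),
                "df": float(res.df), "p": float(res.pvalue),
                "ci_low": float(ci.low), "ci_high": float(ci.high), "note": "",
            }
        )
    return pd.DataFrame(rows)


def error_rate_comparison(trials: pd.DataFrame) -> pd.DataFrame:
    """Group comparison of error proportions, per distractor condition.

    Fits a binomial GLM (logit link) of the error indicator on group within
    each condition and reports the Wald p-value of the group term. A
    condition without errors in one or both groups is flagged degenerate
    (the logit contrast is not estimable there).
    """
    import statsmodels.api as sm

    rows = []
    for condition, sub in trials.groupby("condition", sort=True):
        is_err = (sub["status"] == STATUS_ERROR).to_numpy(dtype=float)
        is_pat = (sub["group"] == "patient").to_numpy(dtype=float)
        n_pat, n_con = int(is_pat.sum()), int((1 - is_pat).sum())
        err_pat = int(is_err[is_pat == 1].sum())
        err_con = int(is_err[is_pat == 0].sum())
        row = {
            "condition": condition,
            "n_control": n_con, "n_patient": n_pat,
            "errors_control": err_con, "errors_patient": err_pat,
            "rate_control": err_con / n_con if n_con else np.nan,
            "rate_patient": err_pat / n_pat if n_pat else np.nan,
        }
        if err_con == 0 or err_pat == 0 or err_con == n_con or err_pat == n_pat:
            row.update({"coef": np.nan, "p": np.nan, "degenerate": True})
        else:
            X = sm.add_constant(is_pat)
            fit = sm.GLM(is_err, X, family=sm.families.Binomial()).fit()
            row.update(
                {"coef": float(fit.params[1]), "p": float(fit.pvalues[1]), "degenerate": False}
            )
        rows.append(row)
    return pd.DataFrame(rows)
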