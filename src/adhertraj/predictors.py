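"""Characterising trajectory groups: bivariate tests and multinomial regression.

Two stages, mirroring the usual reporting of trajectory analyses:

* a bivariate table — per-group counts/percentages with Pearson chi-square
  p-values for categorical covariates, group means/SDs with one-way ANOVA
  for continuous ones;
* a multinomial logistic regression of hard trajectory assignment on all
  covariates simultaneously, with the adherent group as the reference
  outcome, reported as adjusted odds ratios with Wald 95% CIs and p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError


@dataclass
class MNLogitResult:
    """Tidy multinomial regression output.

    ``table`` has one row per (non-reference group, covariate contrast):
    coef, se, odds_ratio, ci_low, ci_high, p.
    """

    table: pd.DataFrame
    loglik: float
    converged: bool
    n_used: int
    n_dropped: int
    reference_group: int
    group_labels: Mapping[int, str]
    separation_terms: list[str]


def encode_design(
    covariates: pd.DataFrame,
    reference_levels: Mapping[str, object] | None = None,
    continuous: Sequence[str] = (),
) -> pd.DataFrame:
    """Dummy-code covariates with explicit reference levels.

    Every categorical covariate contributes one column per non-reference
    level, named ``cov[level vs ref]``. Binary 0/1 columns default to
    reference level 0. Continuous columns pass through unchanged. A constant
    column is prepended.
    """
    reference_levels = dict(reference_levels or {})
    cols: dict[str, np.ndarray] = {}
    for name in covariates.columns:
        if name == "patient_id":
            continue
        series = covariates[name]
        if name in continuous:
            cols[name] = series.to_numpy(dtype=float)
            continue
        levels = sorted(series.dropna().unique().tolist(), key=str)
        if len(levels) < 2:
            raise ValueError(f"covariate {name!r} has a single level; drop it")
        ref = reference_levels.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not found in {name!r}")
        for lev in levels:
            if lev == ref:
                continue
            cols[f"{name}[{lev} vs {ref}]"] = (series == lev).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=covariates.index)
    X.insert(0, "const", 1.0)
    return X


def bivariate_table(
    covariates: pd.DataFrame,
    assignments: np.ndarray,
    continuous: Sequence[str] = (),
    group_labels: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptive statistics with chi-square / ANOVA p-values."""
    assignments = np.asarray(assignments)
    groups = np.unique(assignments)
    if len(groups) < 2:
        raise ValueError("need at least two groups for bivariate comparisons")
    labels = {g: (group_labels or {}).get(g, f"group{g}") for g in groups}
    rows = []
    for name in covariates.columns:
        if name == "patient_id":
            continue
        series = covariates[name]
        if name in continuous:
            x = series.to_numpy(dtype=float)
            samples = [x[assignments == g] for g in groups]
            variances = [np.var(s) for s in samples if len(s) > 1]
            flag = ""
            if not variances or max(variances) == 0.0:
                stat_val, p = np.nan, np.nan
                flag = "zero variance: F undefined"
            else:
                stat_val, p = stats.f_oneway(*samples)
            row = {
                "variable": name, "level": "(mean, sd)", "test": "anova",
                "statistic": stat_val, "df": len(groups) - 1, "p_value": p,
                "flag": flag,
            }
            for g, s in zip(groups, samples):
                row[labels[g]] = f"{s.mean():.2f} ({s.std(ddof=1):.2f})"
            rows.append(row)
        else:
            ct = pd.crosstab(series, assignments)
            chi2, p, dof, expected = stats.chi2_contingency(ct, correction=False)
            flag = "low expected counts" if expected.min() < 5 else ""
            col_totals = ct.sum(axis=0)
            for i, (lev, counts) in enumerate(ct.iterrows()):
                row = {
                    "variable": name, "level": str(lev), "test": "chi-square",
                    "statistic": chi2 if i == 0 else np.nan,
                    "df": dof if i == 0 else np.nan,
                    "p_value": p if i == 0 else np.nan,
                    "flag": flag if i == 0 else "",
                }
                for g in groups:
                    n = counts.get(g, 0)
                    row[labels[g]] = f"{n} ({100 * n / col_totals[g]:.2f})"
                rows.append(row)
    return pd.DataFrame(rows)


def fit_multinomial(
    covariates: pd.DataFrame,
    assignments: np.ndarray,
    reference_group: int = 0,
    reference_levels: Mapping[str, object] | None = None,
    continuous: Sequence[str] = (),
    group_labels: Mapping[int, str] | None = None,
) -> MNLogitResult:
    """Multinomial logistic regression of trajectory membership on covariates.

    Newton-Raphson ML fit; the reference trajectory is the base outcome, so
    each coefficient is a log-odds ratio of membership in a non-reference
    group versus the reference.  Missing covariate values are handled
    complete-case with a logged count; perfect separation is flagged (with
    the offending terms named), not raised.
    """
    assignments = np.asarray(assignments)
    if len(covariates) != len(assignments):
        raise ValueError("covariates and assignments have different lengths")
    groups = np.unique(assignments)
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group} is empty or absent")
    labels = {g: (group_labels or {}).get(g, f"group{g}") for g in groups}

    X = encode_design(covariates, reference_levels, continuous)
    keep = ~X.isna().any(axis=1).to_numpy()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} patient(s) with missing covariates "
            "(complete-case analysis)",
            UserWarning,
            stacklevel=2,
        )
    X = X.loc[keep]
    y_groups = assignments[keep]

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify aliased columns by pivoting through QR
        _, R = np.linalg.qr(X.to_numpy())
        aliased = [
            X.columns[j] for j in range(X.shape[1]) if abs(R[min(j, R.shape[0] - 1), j]) < 1e-10
        ]
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    # recode outcome: reference -> 0, others in ascending group order
    others = [g for g in groups if g != reference_group]
    code = {reference_group: 0, **{g: j + 1 for j, g in enumerate(others)}}
    endog = np.array([code[g] for g in y_groups])

    model = sm.MNLogit(endog, X)
    converged = True
    separation_terms: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=200, disp=0)
            converged = bool(res.mle_retvals.get("converged", True))
        except (PerfectSeparationError, np.linalg.LinAlgError):
            res = model.fit(method="lbfgs", maxiter=500, disp=0)
            converged = False

    params = np.asarray(res.params)          # K x (J-1)
    bse = np.asarray(res.bse)
    pvals = np.asarray(res.pvalues)
    if not converged or np.abs(params).max() > 10:
        big = np.abs(params).max(axis=1) > 10
        separation_terms = [c for c, b in zip(X.columns, big) if b]
        if separation_terms:
            converged = False

    rows = []
    with np.errstate(over="ignore"):  # inf CI bounds under separation
        for j, g in enumerate(others):
            for i, term in enumerate(X.columns):
                if term == "const":
                    continue
                coef = params[i, j]
                se = bse[i, j]
                rows.append(
                    {
                        "group": g,
                        "group_label": labels[g],
                        "vs": labels[reference_group],
                        "term": term,
                        "coef": coef,
                        "se": se,
                        "odds_ratio": np.exp(coef),
                        "ci_low": np.exp(coef - 1.96 * se),
                        "ci_high": np.exp(coef + 1.96 * se),
                        "p_value": pvals[i, j],
                    }
                )
    return MNLogitResult(
        table=pd.DataFrame(rows),
        loglik=float(res.llf),
        converged=converged,
        n_used=int(keep.sum()),
        n_dropped=n_dropped,
        reference_group=reference_group,
        group_labels=labels,
        separation_terms=separation_terms,
    )


def format_or_table(result: MNLogitResult) -> pd.DataFrame:
    """Publication-style table: one row per contrast, per-group OR/CI/p columns."""
    tab = result.table
    if tab.empty:
        return pd.DataFrame(columns=["term"])
    out = None
    for g, sub in tab.groupby("group", sort=True):
        lab = sub["group_label"].iloc[0]
        block = pd.DataFrame(
            {
                "term": sub["term"].to_numpy(),
                f"{lab}: OR": [f"{v:.2f}" for v in sub["odds_ratio"]],
                f"{lab}: 95% CI": [
                    f"{lo:.2f}–{hi:.2f}"
                    for lo, hi in zip(sub["ci_low"], sub["ci_high"])
                ],
                f"{lab}: p": [
                    f"{p:.4f} *" if p < 0.05 else f"{p:.4f}"
                    for p in sub["p_value"]
                ],
            }
        )
        out = block if out is None else out.merge(block, on="term", how="outer")
    return out


__all__ = [
    "MNLogitResult",
    "encode_design",
    "bivariate_table",
    "fit_multinomial",
    "format_or_table",
]
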