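"""Univariate cohort statistics.

Clinical-table style group comparisons: pooled-variance two-sample
Student's t tests (raw-vector and summary-statistic variants that agree
exactly), Pearson chi-square on 2x2 proportions without continuity
correction, per-metabolite univariate AUC/p tables, and severity /
survival contrasts across the enrolment subgroups with the usual
star coding (*P<0.05, **P<0.01, ***P<0.001, ****P<0.0001).

Student's (pooled) t is the default to match the clinical-table
convention; Welch's variant is available by flag. No multiple-testing
correction is applied by default; Benjamini-Hochberg adjusted p values
can be requested alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classifier import _labels_to_binary, auroc
from .cohortsim import ROLE_STUDY, SUBGROUPS

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def stars(p: float) -> str:
    for thr, code in STAR_THRESHOLDS:
        if p < thr:
            return code
    return "ns"


# ---------------------------------------------------------------------------
# two-sample tests

def two_sample_t(x1, x2, welch: bool = False) -> tuple[float, float]:
    """Two-tailed two-sample t test; pooled-variance Student's by default."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    if len(x1) < 2 or len(x2) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not welch and x1.var(ddof=1) == 0 and x2.var(ddof=1) == 0:
        if x1.mean() == x2.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind(x1, x2, equal_var=not welch)
    return float(t), float(p)


def two_sample_t_from_summary(mean1: float, sd1: float, n1: int,
                              mean2: float, sd2: float, n2: int,
                              welch: bool = False) -> tuple[float, float]:
    """Summary-statistic variant; agrees exactly with the raw-vector test
    when the summaries are computed from the raw vectors."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if not welch and sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=not welch)
    return float(t), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on [[a, b], [c, d]], df=1, no continuity correction."""
    tbl = np.array([[a, b], [c, d]], dtype=float)
    if (tbl < 0).any():
        raise ValueError("counts must be non-negative")
    if (tbl.sum(axis=0) == 0).any() or (tbl.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    chi2, p, dof, _ = stats.chi2_contingency(tbl, correction=False)
    assert dof == 1
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# group summaries (clinical-table style)

def group_summary(samples: pd.DataFrame, variables: list[str],
                  by: str = "label") -> pd.DataFrame:
    """Mean +/- SD per variable per group with the pooled-t p value."""
    study = samples[samples["role"] == ROLE_STUDY] if "role" in samples.columns else samples
    groups = sorted(study[by].dropna().unique())
    rows = []
    for var in variables:
        row: dict = {"variable": var}
        vecs = []
        for g in groups:
            v = study.loc[study[by] == g, var].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            vecs.append(v)
            row[f"{g}_n"] = len(v)
            row[f"{g}_mean"] = v.mean() if len(v) else np.nan
            row[f"{g}_sd"] = v.std(ddof=1) if len(v) > 1 else np.nan
        if len(vecs) == 2 and all(len(v) >= 2 for v in vecs):
            _, row["p"] = two_sample_t(vecs[0], vecs[1])
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")


# ---------------------------------------------------------------------------
# per-metabolite univariate diagnostics

def univariate_marker_table(X: pd.DataFrame, y) -> pd.DataFrame:
    """Per-feature univariate AUC (orientation-corrected) and t-test p.

    AUC is reported as max(AUC, 1-AUC) with a direction flag ('up' when the
    raw value is higher in the positive class). Constant features get
    AUC 0.5, p 1.0 and a 'constant' flag. Sorted by AUC descending.
    """
    yv = _labels_to_binary(y)
    if len(np.unique(yv)) < 2:
        raise ValueError("both classes must be present")
    rows = []
    for f in X.columns:
        v = X[f].to_numpy(dtype=float)
        ok = np.isfinite(v)
        row = {"feature_id": f}
        if len(np.unique(v[ok])) <= 1 or min((yv[ok] == 1).sum(), (yv[ok] == 0).sum()) < 2:
            row.update(auc=0.5, direction="constant", p=1.0)
        else:
            a = auroc(v[ok], yv[ok])
            row["direction"] = "up" if a >= 0.5 else "down"
            row["auc"] = max(a, 1 - a)
            _, row["p"] = two_sample_t(v[ok & (yv == 1)], v[ok & (yv == 0)])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature_id")
    return out.sort_values("auc", ascending=False)


# ---------------------------------------------------------------------------
# severity and survival contrasts

def severity_and_survival_contrasts(
    X: pd.DataFrame,
    samples: pd.DataFrame,
    panel: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """All pairwise severity-subgroup t tests plus the survival contrast.

    One row per (panel feature, contrast): the 6 subgroup pairs over
    control/infection/sepsis/shock and dead-vs-alive, each with t, p and
    the star code. Empty or singleton groups skip the contrast with a
    warning. ``adjust=True`` appends Benjamini-Hochberg adjusted p values.
    """
    study = samples[samples["role"] == ROLE_STUDY]
    pairs = [(SUBGROUPS[i], SUBGROUPS[j])
             for i in range(len(SUBGROUPS)) for j in range(i + 1, len(SUBGROUPS))]
    rows = []
    for f in panel:
        if f not in X.columns:
            raise KeyError(f"panel feature {f!r} not in X")
        vals = X[f]
        for g1, g2 in pairs:
            v1 = vals.reindex(study.index[study["subgroup"] == g1]).dropna()
            v2 = vals.reindex(study.index[study["subgroup"] == g2]).dropna()
            rows.append(_contrast_row(f, f"{g1}_vs_{g2}", v1, v2))
        dead = vals.reindex(study.index[study["survival28"] == "dead"]).dropna()
        alive = vals.reindex(study.index[study["survival28"] == "alive"]).dropna()
        rows.append(_contrast_row(f, "dead_vs_alive", dead, alive))
    out = pd.DataFrame(rows)
    if adjust and out["p"].notna().any():
        mask = out["p"].notna()
        out.loc[mask, "p_adj"] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
    return out


def _contrast_row(feature: str, contrast: str, v1: pd.Series, v2: pd.Series) -> dict:
    row = {"feature_id": feature, "contrast": contrast,
           "n1": len(v1), "n2": len(v2),
           "mean1": v1.mean() if len(v1) else np.nan,
           "mean2": v2.mean() if len(v2) else np.nan}
    if len(v1) < 2 or len(v2) < 2:
        warnings.warn(f"contrast {contrast} skipped for {feature}: group too small")
        row.update(t=np.nan, p=np.nan, stars="")
    else:
        t, p = two_sample_t(v1, v2)
        row.update(t=t, p=p, stars=stars(p))
    return row
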