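"""Group comparisons, correlations, ROC cutoffs, odds ratios and logistic fits.

Mirrors a standard cross-sectional ophthalmic analysis: Kruskal-Wallis
across the three groups with pairwise Mann-Whitney U tests, Pearson
correlations between image-derived and structural measures, ROC curves
with Youden-index cutoffs for separating diabetic from control eyes, a
2x2 crude odds ratio for the two-threshold impaired-flow rule, and
age-adjusted logistic regression of impaired flow on each systemic
exposure (one exposure at a time, as a small-n design demands).

All tests are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "NotAValue",
    "RocResult",
    "OddsRatioResult",
    "LogisticResult",
    "SchemaError",
    "group_compare",
    "pearson_r",
    "roc_auc",
    "odds_ratio_2x2",
    "fit_logistic",
    "build_report",
]


class SchemaError(KeyError):
    """An expected column is missing from an input table."""


@dataclass
class NotAValue:
    """Explicit undefined-result marker carrying the reason."""

    reason: str

    def __bool__(self) -> bool:
        return False


@dataclass
class GroupComparison:
    variable: str
    groups: dict  # name -> {n, mean, sd, min, max}
    kruskal_h: Optional[float]
    kruskal_p: Optional[float]
    pairwise: dict  # (g1, g2) -> {u, p, method}
    skipped: Optional[str] = None


@dataclass
class RocResult:
    auc: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # "low" or "high" flags disease


@dataclass
class OddsRatioResult:
    a: float
    b: float
    c: float
    d: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    haldane_corrected: bool = False
    p_method: str = "chi2"


@dataclass
class LogisticResult:
    term: str
    coef: float
    odds_ratio: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    p: Optional[float]
    converged: bool
    separation: bool


def group_compare(
    table: pd.DataFrame, variable: str, group_column: str = "group"
) -> GroupComparison:
    """Kruskal-Wallis across all groups plus pairwise two-sided Mann-Whitney U.

    Pairwise tests use exact enumeration when both samples have n <= 8 (and
    no ties across the pooled sample), otherwise the normal approximation
    with continuity and tie correction.  A group with fewer than 2 values
    flags the comparison as skipped.
    """
    if variable not in table.columns:
        raise SchemaError(variable)
    if group_column not in table.columns:
        raise SchemaError(group_column)
    sub = table[[group_column, variable]].dropna()
    samples = {g: v[variable].to_numpy(dtype=float) for g, v in sub.groupby(group_column, sort=False)}
    desc = {
        g: {
            "n": int(len(x)),
            "mean": float(np.mean(x)) if len(x) else float("nan"),
            "sd": float(np.std(x, ddof=1)) if len(x) > 1 else float("nan"),
            "min": float(np.min(x)) if len(x) else float("nan"),
            "max": float(np.max(x)) if len(x) else float("nan"),
        }
        for g, x in samples.items()
    }
    degenerate = [g for g, x in samples.items() if len(x) < 2]
    if len(samples) < 2 or degenerate:
        return GroupComparison(
            variable, desc, None, None, {},
            skipped=f"degenerate groups: {degenerate or 'fewer than 2 groups'}",
        )
    groups = list(samples)
    if all(np.ptp(x) == 0 for x in samples.values()) and len({x[0] for x in samples.values()}) == 1:
        h, hp = 0.0, 1.0
    else:
        h, hp = sps.kruskal(*samples.values())
    pairwise = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            x, y = samples[groups[i]], samples[groups[j]]
            pooled = np.concatenate([x, y])
            exact = len(x) <= 8 and len(y) <= 8 and len(np.unique(pooled)) == len(pooled)
            method = "exact" if exact else "asymptotic"
            u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
            pairwise[(groups[i], groups[j])] = {"u": float(u), "p": float(p), "method": method}
    return GroupComparison(variable, desc, float(h), float(hp), pairwise)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float] | NotAValue:
    """Product-moment correlation with the t-transform p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and equal length")
    if len(x) < 3:
        raise ValueError("pearson_r requires n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return NotAValue("zero_variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def roc_auc(
    values: Sequence[float], labels: Sequence[bool], direction: str = "low"
) -> RocResult:
    """AUC via the Mann-Whitney U identity, with a Youden-index cutoff.

    ``direction="low"`` means low values flag disease (as for the CCFA
    ratio); ``"high"`` the opposite (as for the tile CV).  Tied
    value-pairs count 1/2 in the AUC.  The Youden cutoff maximizes
    sensitivity + specificity - 1 over observed values; ties between
    cutoffs break toward the less extreme one (the one deeper inside the
    healthy range).
    """
    if direction not in ("low", "high"):
        raise ValueError("direction must be 'low' or 'high'")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    score = -values if direction == "low" else values
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = sps.rankdata(score)
    u = float(ranks[labels].sum() - n1 * (n1 + 1) / 2.0)
    auc = u / (n1 * n0)

    # Youden scan over observed cutoffs: disease call is value < c (low) or
    # value >= c (high); candidates are the observed values plus an
    # all-negative sentinel.
    cand = np.unique(values)
    best = None
    for c in cand:
        flag = values < c if direction == "low" else values >= c
        sens = float((flag & labels).sum()) / n1
        spec = float((~flag & ~labels).sum()) / n0
        youden = sens + spec - 1.0
        # tie-break toward the less extreme cutoff: larger c for "low"
        # (retreats from the low tail), smaller c for "high"
        better = best is None or youden > best[0] + 1e-12
        tie = best is not None and abs(youden - best[0]) <= 1e-12
        prefer = tie and ((c > best[1]) if direction == "low" else (c < best[1]))
        if better or prefer:
            best = (youden, float(c), sens, spec)
    return RocResult(
        auc=float(auc),
        youden_cutoff=best[1],
        sensitivity=best[2],
        specificity=best[3],
        direction=direction,
    )


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """Crude odds ratio of a 2x2 table with Woolf CI.

    Layout: rows exposed/unexposed, columns case/control -> OR = ad / bc.
    A zero cell triggers the Haldane-Anscombe +0.5 correction (flagged).
    The p-value is Pearson chi-square without continuity correction, or
    Fisher's exact test when any expected cell is below 5.
    """
    cells = [a, b, c, d]
    if any((not float(x).is_integer()) or x < 0 for x in cells):
        raise ValueError("cells must be nonnegative integers")
    if sum(cells) == 0:
        raise ValueError("empty table")
    a, b, c, d = (float(x) for x in cells)
    corrected = False
    aa, bb, cc, dd = a, b, c, d
    if min(cells) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = math.exp(math.log(or_) - 1.96 * se)
    ci_high = math.exp(math.log(or_) + 1.96 * se)
    table = np.array([[a, b], [c, d]])
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if (expected < 5).any():
        _, p = sps.fisher_exact(table)
        method = "fisher"
    else:
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        method = "chi2"
    return OddsRatioResult(a, b, c, d, float(or_), ci_low, ci_high, float(p), corrected, method)


def fit_logistic(
    outcome: Sequence[bool],
    covariates: pd.DataFrame,
    maxiter: int = 100,
) -> list[LogisticResult]:
    """Maximum-likelihood logistic regression with Wald CIs per covariate.

    An intercept is added.  Complete/quasi-separation (divergent
    coefficients, |coef| > 15, or a failed fit) sets the separation flag
    and suppresses the CI.  Rank-deficient designs raise.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    X = pd.DataFrame(covariates).astype(float)
    if y.ndim != 1 or len(y) != len(X):
        raise ValueError("outcome and covariates must align")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design")
    results: list[LogisticResult] = []
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=maxiter, method="newton")
        converged = bool(fit.mle_retvals.get("converged", False))
        params = fit.params
        bse = fit.bse
        pvals = fit.pvalues
        separated = (np.abs(params.drop("const")) > 15).any() or not converged
    except Exception:
        converged = False
        separated = True
        params = bse = pvals = None
    for term in X.columns:
        if params is None:
            results.append(LogisticResult(term, float("nan"), float("nan"), None, None, None, False, True))
            continue
        coef = float(params[term])
        if separated:
            results.append(
                LogisticResult(term, coef, math.exp(min(coef, 500)), None, None, None, converged, True)
            )
        else:
            se = float(bse[term])
            results.append(
                LogisticResult(
                    term,
                    coef,
                    math.exp(coef),
                    math.exp(coef - 1.96 * se),
                    math.exp(coef + 1.96 * se),
                    float(pvals[term]),
                    converged,
                    False,
                )
            )
    return results


# ---------------------------------------------------------------------------
# report assembly


_FLOW_VARS = ("ccfa_ratio", "cv_ccfa", "vld")
_MORPH_VARS = ("pros_length", "rpe_volume")
_CHAR_VARS = ("age", "bcva_logmar", "central_retinal_thickness")


def _cmp_to_dict(cmp_: GroupComparison) -> dict:
    return {
        "variable": cmp_.variable,
        "groups": cmp_.groups,
        "kruskal_h": cmp_.kruskal_h,
        "kruskal_p": cmp_.kruskal_p,
        "pairwise": {f"{a}|{b}": v for (a, b), v in cmp_.pairwise.items()},
        "skipped": cmp_.skipped,
    }


def build_report(
    cohort: pd.DataFrame,
    metrics: pd.DataFrame,
    cutoffs: tuple[float, float] = (65.9, 0.140),
    exposures: Sequence[str] = ("hba1c", "systolic_bp", "diastolic_bp", "hdl_c", "ldl_c", "triglyceride"),
) -> dict:
    """Assemble the full statistical report from cohort + per-eye metrics.

    Sections: group characteristics, flow-metric group comparisons, flow vs
    flow and flow vs outer-retina correlations, ROC cutoffs for separating
    diabetic from control eyes, the 2x2 two-threshold classification odds
    ratio, and age-adjusted logistic models of impaired flow on each
    available systemic exposure.  Deterministic given its inputs.
    """
    for col in ("eye_id", "group"):
        if col not in cohort.columns:
            raise SchemaError(col)
        if col not in metrics.columns:
            raise SchemaError(col)
    merged = cohort.merge(metrics.drop(columns=["group"]), on="eye_id", how="inner")

    report: dict = {"n": {g: int((merged["group"] == g).sum()) for g in merged["group"].unique()}}

    report["characteristics"] = [
        _cmp_to_dict(group_compare(merged, v)) for v in _CHAR_VARS if v in merged.columns
    ]
    report["flow_group_stats"] = [
        _cmp_to_dict(group_compare(merged, v)) for v in _FLOW_VARS if v in merged.columns
    ]
    report["morphology_group_stats"] = [
        _cmp_to_dict(group_compare(merged, v)) for v in _MORPH_VARS if v in merged.columns
    ]

    def corr(xcol, ycol):
        sub = merged[[xcol, ycol]].dropna()
        if len(sub) < 3:
            return {"x": xcol, "y": ycol, "r": None, "p": None, "reason": "too_few"}
        res = pearson_r(sub[xcol], sub[ycol])
        if isinstance(res, NotAValue):
            return {"x": xcol, "y": ycol, "r": None, "p": None, "reason": res.reason}
        return {"x": xcol, "y": ycol, "r": res[0], "p": res[1], "n": int(len(sub))}

    pairs = [
        ("ccfa_ratio", "vld"),
        ("cv_ccfa", "vld"),
        ("ccfa_ratio", "pros_length"),
        ("ccfa_ratio", "rpe_volume"),
        ("vld", "pros_length"),
        ("vld", "rpe_volume"),
    ]
    report["correlations"] = [
        corr(x, y) for x, y in pairs if x in merged.columns and y in merged.columns
    ]

    diabetic = merged["group"].isin(["dm_no_dr", "dr"])
    roc_section = {}
    ok = merged["ccfa_ratio"].notna() & merged["cv_ccfa"].notna()
    if diabetic[ok].nunique() == 2 if len(merged[ok]) else False:
        for col, direction in (("ccfa_ratio", "low"), ("cv_ccfa", "high")):
            res = roc_auc(merged.loc[ok, col], diabetic[ok], direction)
            roc_section[col] = {
                "auc": res.auc,
                "youden_cutoff": res.youden_cutoff,
                "sensitivity": res.sensitivity,
                "specificity": res.specificity,
                "direction": res.direction,
            }
    report["roc"] = roc_section or {"skipped": "need both diabetic and control eyes"}

    if ok.any() and diabetic[ok].nunique() == 2:
        impaired = (merged["ccfa_ratio"] < cutoffs[0]) & (merged["cv_ccfa"] >= cutoffs[1])
        a = int((impaired & diabetic & ok).sum())
        b = int((impaired & ~diabetic & ok).sum())
        c = int((~impaired & diabetic & ok).sum())
        d = int((~impaired & ~diabetic & ok).sum())
        orr = odds_ratio_2x2(a, b, c, d)
        report["classification"] = {
            "cutoffs": {"ccfa_lt": cutoffs[0], "cv_ge": cutoffs[1]},
            "table": {"a": a, "b": b, "c": c, "d": d},
            "odds_ratio": orr.odds_ratio,
            "ci": [orr.ci_low, orr.ci_high],
            "p": orr.p,
            "haldane_corrected": orr.haldane_corrected,
        }
    else:
        report["classification"] = {"skipped": "need both diabetic and control eyes"}

    logistic_section = []
    if "age" in merged.columns and ok.any():
        impaired = (
            (merged["ccfa_ratio"] < cutoffs[0]) & (merged["cv_ccfa"] >= cutoffs[1])
        ).astype(float)
        for exp_col in exposures:
            flag_col = f"{exp_col}_exceed"
            if flag_col not in merged.columns:
                continue
            X = pd.DataFrame(
                {flag_col: merged[flag_col].astype(float), "age": merged["age"]}
            )
            try:
                fits = fit_logistic(impaired[ok], X[ok])
            except ValueError as err:
                logistic_section.append({"exposure": exp_col, "skipped": str(err)})
                continue
            res = fits[0]
            logistic_section.append(
                {
                    "exposure": exp_col,
                    "odds_ratio": None if math.isnan(res.odds_ratio) else res.odds_ratio,
                    "ci": [res.ci_low, res.ci_high],
                    "p": res.p,
                    "separation": res.separation,
                    "converged": res.converged,
                }
            )
    report["logistic"] = logistic_section
    return report
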