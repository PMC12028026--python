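"""Epidemiological gold standards and performance evaluation.

A comorbidity gold standard is built from a cohort diagnosis matrix: for
each disease pair, the relative risk (RR) of carrying disease B given
disease A is estimated from the 2x2 exposure/outcome table, with a Wald
95% confidence interval and a Pearson chi-square p-value. A pair is
labelled comorbid when its p-value survives Bonferroni correction over
all tested pairs AND its RR exceeds a threshold (1, 5 or 10 — stricter
thresholds define stronger comorbidity).

Candidate similarity measures are then scored by rank-based AUC against
those labels, and combinations of measures are assessed with an
unregularised logistic regression whose best subset is chosen by AUC.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geneset_io import CohortTable

__all__ = [
    "RRResult",
    "ComorbidityLabel",
    "ROCResult",
    "LRResult",
    "relative_risk",
    "bonferroni_threshold",
    "label_pairs",
    "auc",
    "lr_combine",
]


@dataclass(frozen=True)
class RRResult:
    """Relative risk of disease B given disease A, from a 2x2 table.

    ``a`` = A+B+, ``b`` = A+B-, ``c`` = A-B+, ``d`` = A-B-. The p-value
    is from the Pearson chi-square test without continuity correction on
    the uncorrected counts.
    """

    disease_a: str
    disease_b: str
    a: int
    b: int
    c: int
    d: int
    rr: float
    ci_low: float
    ci_high: float
    p: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class ComorbidityLabel:
    disease_a: str
    disease_b: str
    rr_threshold: float
    label: int


@dataclass(frozen=True)
class ROCResult:
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class LRResult:
    """Best logistic-regression combination of measures, chosen by AUC."""

    best_measures: tuple[str, ...]
    best_auc: float
    per_subset: dict[tuple[str, ...], float]
    coefficients: dict[str, float]
    flags: tuple[str, ...] = ()


def relative_risk(
    cohort: CohortTable, disease_a: str, disease_b: str
) -> RRResult:
    """Estimate the relative risk of B given A from cohort diagnoses.

    RR = P(B | A=1) / P(B | A=0). The Wald CI is
    exp(ln RR +/- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d))). When an
    outcome count is zero in either arm, 0.5 is added to every cell for
    the RR and CI (flagged ``continuity_corrected``); the chi-square
    p-value always uses the raw counts.
    """
    exp_vec = cohort.status(disease_a)
    out_vec = cohort.status(disease_b)
    a = int(np.sum(exp_vec & out_vec))
    b = int(np.sum(exp_vec & ~out_vec))
    c = int(np.sum(~exp_vec & out_vec))
    d = int(np.sum(~exp_vec & ~out_vec))
    if a + b == 0 or c + d == 0:
        raise ValueError(
            f"disease {disease_a!r}: exposed or unexposed group is empty"
        )

    flags: list[str] = []
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if a == 0 or c == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        flags.append("continuity_corrected")
    rr = (aa / (aa + bb)) / (cc / (cc + dd))
    se = np.sqrt(1.0 / aa - 1.0 / (aa + bb) + 1.0 / cc - 1.0 / (cc + dd))
    ci_low = float(rr * np.exp(-1.96 * se))
    ci_high = float(rr * np.exp(1.96 * se))

    table = np.array([[a, b], [c, d]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        p = 1.0
        flags.append("degenerate_margin")
    else:
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        p = float(p)
    return RRResult(
        disease_a=disease_a,
        disease_b=disease_b,
        a=a,
        b=b,
        c=c,
        d=d,
        rr=float(rr),
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        flags=tuple(flags),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m over m tested pairs."""
    if m < 1:
        raise ValueError("number of tested pairs must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / m


def label_pairs(
    rr_results: list[RRResult],
    alpha: float = 0.05,
    thresholds: tuple[float, ...] = (1.0, 5.0, 10.0),
) -> dict[float, list[ComorbidityLabel]]:
    """Binary comorbidity labels at each RR threshold.

    A pair is comorbid (label 1) when its chi-square p-value is at most
    the Bonferroni threshold alpha/M over the M tested pairs AND its RR
    strictly exceeds the threshold.
    """
    m = len(rr_results)
    thr_p = bonferroni_threshold(alpha, m)
    out: dict[float, list[ComorbidityLabel]] = {}
    for t in thresholds:
        out[t] = [
            ComorbidityLabel(
                disease_a=r.disease_a,
                disease_b=r.disease_b,
                rr_threshold=t,
                label=int(r.p <= thr_p and r.rr > t),
            )
            for r in rr_results
        ]
    return out


def auc(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """Rank-based AUC (Mann-Whitney statistic, half credit for ties).

    Equivalent to the trapezoidal area under the ROC curve over all
    thresholds. Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = stats.rankdata(scores)  # average ranks handle ties with half credit
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return ROCResult(auc=float(u / (n_pos * n_neg)), n_pos=n_pos, n_neg=n_neg)


def _fit_logit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    """Unregularised ML logistic fit; on separation or non-convergence the
    (possibly diverging) direction is still returned, flagged — it orders
    cases perfectly, which is all AUC needs."""
    design = sm.add_constant(X, has_constant="add")
    flags: tuple[str, ...] = ()
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
            params = np.asarray(res.params, dtype=float)
            if not res.mle_retvals.get("converged", True):
                flags = ("not_converged",)
        except Exception:
            # perfect separation (or a singular design): the ML estimate
            # diverges, but any separating direction yields the same ROC
            # ordering — use the standardized class-mean difference
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (X - X.mean(axis=0)) / sd
            direction = Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)
            params = np.concatenate([[0.0], direction / sd])
            flags = ("separation_fallback",)
    if not np.all(np.isfinite(params)):
        params = np.nan_to_num(params, nan=0.0, posinf=0.0, neginf=0.0)
        flags = flags + ("nonfinite_params",)
    return params, flags


def lr_combine(
    score_matrix: pd.DataFrame,
    labels: np.ndarray,
    model_spec: list[tuple[str, ...]] | None = None,
) -> LRResult:
    """Search logistic-regression combinations of measures by in-sample AUC.

    ``score_matrix`` has one row per disease pair and one column per
    measure; missing scores are set to zero (a pair with no computable
    score carries no evidence). ``model_spec`` lists the measure subsets
    to try; by default every non-empty subset of the columns is
    enumerated. For each subset a maximum-likelihood logistic model is
    fit and the AUC of its fitted linear predictor on the same pairs is
    recorded; the subset with the highest AUC wins (ties break toward
    the smaller, lexicographically first subset).
    """
    X_full = score_matrix.fillna(0.0)
    y = np.asarray(labels, dtype=int)
    if len(X_full) != len(y):
        raise ValueError("score matrix and labels disagree in length")
    cols = list(X_full.columns)
    if model_spec is None:
        model_spec = [
            subset
            for r in range(1, len(cols) + 1)
            for subset in itertools.combinations(cols, r)
        ]
    if not model_spec:
        raise ValueError("model_spec must contain at least one subset")

    per_subset: dict[tuple[str, ...], float] = {}
    best_key: tuple[str, ...] | None = None
    best_auc = -np.inf
    best_params: np.ndarray | None = None
    best_flags: tuple[str, ...] = ()
    for subset in model_spec:
        subset = tuple(subset)
        missing = set(subset) - set(cols)
        if missing:
            raise ValueError(f"unknown measure(s) in model_spec: {sorted(missing)}")
        X = X_full[list(subset)].to_numpy(dtype=float)
        params, flags = _fit_logit(X, y)
        linear = params[0] + X @ params[1:]
        subset_auc = auc(linear, y).auc
        per_subset[subset] = subset_auc
        if subset_auc > best_auc:
            best_key, best_auc, best_params, best_flags = subset, subset_auc, params, flags
    assert best_key is not None and best_params is not None
    coef = {"intercept": float(best_params[0])}
    coef.update({m: float(v) for m, v in zip(best_key, best_params[1:])})
    return LRResult(
        best_measures=best_key,
        best_auc=float(best_auc),
        per_subset=per_subset,
        coefficients=coef,
        flags=best_flags,
    )
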