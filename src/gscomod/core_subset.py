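"""Core gene-set extraction via a two-component mixture of regressions.

When a disease pair shows a substantial similarity score, part of that
signal may be carried by a subset of functional gene sets whose paired
p-values track each other much more tightly than the rest. To find that
subset, the paired (transformed) p-values are modelled as a mixture of
two Gaussian linear regressions

    y_i | component k  ~  N(b0_k + b1_k * x_i, sigma2_k),   k in {1, 2}

fit by expectation-maximisation. The E-step computes posterior component
memberships (responsibilities); the M-step refits each line by
responsibility-weighted least squares and updates the noise variances
and mixing weights. EM is run from several random initialisations and
the best log-likelihood fit is kept; the log-likelihood is guaranteed
non-decreasing within a run.

The component whose members yield the larger within-component Pearson
similarity is declared the *core* gene-set subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .measures import pearson
from .ora import SemanticProfile, transform_profile

__all__ = ["MMRFit", "CoreSubsetResult", "mmr_fit", "extract_core"]

_VAR_FLOOR = 1e-10


@dataclass
class MMRFit:
    """Parameters and memberships of a two-component regression mixture."""

    intercepts: np.ndarray  # shape (2,)
    slopes: np.ndarray  # shape (2,)
    variances: np.ndarray  # shape (2,)
    weights: np.ndarray  # shape (2,), sums to 1
    responsibilities: np.ndarray  # shape (n, 2), rows sum to 1
    assignments: np.ndarray  # shape (n,), hard labels in {0, 1}
    loglik_trace: np.ndarray  # best restart's per-iteration log-likelihood
    loglik: float
    converged: bool
    degenerate: bool  # single-line fallback was taken
    seed: int
    n_restarts: int


def _weighted_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares line y = b0 + b1*x; falls back to a flat
    line through the weighted mean when x has no weighted spread."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    if sxx <= 0:
        return my, 0.0
    b1 = (w * (x - mx) * (y - my)).sum() / sxx
    return my - b1 * mx, b1


def _log_gauss(y: np.ndarray, mu: np.ndarray, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (y - mu) ** 2 / var)


def _em_once(
    x: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[dict, np.ndarray, bool]:
    n = len(x)
    # random soft start: symmetric Dirichlet responsibilities per point
    resp = rng.dirichlet((1.0, 1.0), size=n)
    b0 = np.zeros(2)
    b1 = np.zeros(2)
    var = np.ones(2)
    pi = np.full(2, 0.5)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M-step
        for k in range(2):
            w = np.maximum(resp[:, k], 1e-12)
            b0[k], b1[k] = _weighted_line(x, y, w)
            resid = y - (b0[k] + b1[k] * x)
            var[k] = max((w * resid**2).sum() / w.sum(), _VAR_FLOOR)
        pi = np.maximum(resp.mean(axis=0), 1e-12)
        pi = pi / pi.sum()
        # E-step
        log_comp = np.column_stack(
            [np.log(pi[k]) + _log_gauss(y, b0[k] + b1[k] * x, var[k]) for k in range(2)]
        )
        norm = logsumexp(log_comp, axis=1)
        resp = np.exp(log_comp - norm[:, None])
        ll = float(norm.sum())
        trace.append(ll)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    params = {
        "intercepts": b0.copy(),
        "slopes": b1.copy(),
        "variances": var.copy(),
        "weights": pi.copy(),
        "responsibilities": resp,
        "loglik": trace[-1],
    }
    return params, np.asarray(trace), converged


def mmr_fit(
    x: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> MMRFit:
    """Fit the two-component regression mixture by EM with restarts.

    ``x`` and ``y`` are the two diseases' transformed p-value vectors
    (same collection, same order). At least 10 paired observations are
    required. When all points are collinear to machine precision a
    mixture cannot be identified; the fit then degenerates to a single
    line with every point in component 0 and is flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 10:
        raise ValueError(f"need at least 10 paired observations, got {n}")

    # degenerate input: a single OLS line explains everything exactly
    b0s, b1s = _weighted_line(x, y, np.ones(n))
    resid = y - (b0s + b1s * x)
    scale = max(np.abs(y).max(), np.abs(x).max(), 1.0)
    if np.abs(resid).max() <= 1e-12 * scale:
        resp = np.zeros((n, 2))
        resp[:, 0] = 1.0
        return MMRFit(
            intercepts=np.array([b0s, b0s]),
            slopes=np.array([b1s, b1s]),
            variances=np.full(2, _VAR_FLOOR),
            weights=np.array([1.0, 0.0]),
            responsibilities=resp,
            assignments=np.zeros(n, dtype=int),
            loglik_trace=np.array([]),
            loglik=float("nan"),
            converged=False,
            degenerate=True,
            seed=seed,
            n_restarts=0,
        )

    rng = np.random.default_rng(seed)
    best: tuple[dict, np.ndarray, bool] | None = None
    for _ in range(n_restarts):
        params, trace, conv = _em_once(x, y, rng, max_iter, tol)
        if best is None or params["loglik"] > best[0]["loglik"]:
            best = (params, trace, conv)
    assert best is not None
    params, trace, conv = best
    return MMRFit(
        intercepts=params["intercepts"],
        slopes=params["slopes"],
        variances=params["variances"],
        weights=params["weights"],
        responsibilities=params["responsibilities"],
        assignments=params["responsibilities"].argmax(axis=1).astype(int),
        loglik_trace=trace,
        loglik=params["loglik"],
        converged=conv,
        degenerate=False,
        seed=seed,
        n_restarts=n_restarts,
    )


@dataclass
class CoreSubsetResult:
    """The core gene-set subset of a comorbid pair and its similarity scores."""

    core_set_names: tuple[str, ...]
    rest_set_names: tuple[str, ...]
    core_gs_sim: float
    rest_gs_sim: float
    #: per core member: does either disease's raw p pass Bonferroni alpha/n?
    significance_labels: dict[str, bool]
    bonferroni_threshold: float
    flags: tuple[str, ...] = ()


def _subset_similarity(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> float:
    if idx.sum() < 2:
        return float("nan")
    r = pearson(x[idx], y[idx])
    return r


def extract_core(
    fit: MMRFit,
    profile_a: SemanticProfile,
    profile_b: SemanticProfile,
    alpha: float = 0.05,
    transform: str = "exp",
) -> CoreSubsetResult:
    """Select the higher-similarity mixture component as the core subset.

    The within-component Pearson similarity is computed on the same
    transformed vectors the mixture was fit to; the component with the
    larger value is the core. Components with fewer than 3 members
    cannot carry a meaningful correlation, so the other component is
    taken as core (flagged). Significance labels mark core members whose
    raw p-value in either disease passes the Bonferroni threshold
    alpha/n over the n functional sets.
    """
    if profile_a.set_names != profile_b.set_names:
        raise ValueError("profiles have mismatched functional set order")
    names = np.asarray(profile_a.set_names)
    n = len(names)
    thr = alpha / n
    x = transform_profile(profile_a, transform)
    y = transform_profile(profile_b, transform)

    if fit.degenerate:
        sig = {
            str(nm): bool(min(pa, pb) <= thr)
            for nm, pa, pb in zip(names, profile_a.pvalues, profile_b.pvalues)
        }
        return CoreSubsetResult(
            core_set_names=tuple(names),
            rest_set_names=(),
            core_gs_sim=pearson(x, y),
            rest_gs_sim=float("nan"),
            significance_labels=sig,
            bonferroni_threshold=thr,
            flags=("degenerate_single_line",),
        )

    labels = fit.assignments
    flags: list[str] = []
    in0 = labels == 0
    in1 = labels == 1
    sim0 = _subset_similarity(x, y, in0)
    sim1 = _subset_similarity(x, y, in1)

    if in0.sum() < 3:
        core_mask, core_sim, rest_sim = in1, sim1, sim0
        flags.append("small_component")
    elif in1.sum() < 3:
        core_mask, core_sim, rest_sim = in0, sim0, sim1
        flags.append("small_component")
    else:
        # NaN similarity (zero variance inside a component) loses the contest
        s0 = -np.inf if np.isnan(sim0) else sim0
        s1 = -np.inf if np.isnan(sim1) else sim1
        if s0 >= s1:
            core_mask, core_sim, rest_sim = in0, sim0, sim1
        else:
            core_mask, core_sim, rest_sim = in1, sim1, sim0

    core_names = tuple(names[core_mask])
    rest_names = tuple(names[~core_mask])
    sig = {
        str(nm): bool(min(pa, pb) <= thr)
        for nm, pa, pb in zip(
            names[core_mask],
            profile_a.pvalues[core_mask],
            profile_b.pvalues[core_mask],
        )
    }
    return CoreSubsetResult(
        core_set_names=core_names,
        rest_set_names=rest_names,
        core_gs_sim=core_sim,
        rest_gs_sim=rest_sim,
        significance_labels=sig,
        bonferroni_threshold=thr,
        flags=tuple(flags),
    )
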