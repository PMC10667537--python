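"""Stratified splitting, outcome-based dichotomization, Kaplan-Meier /
log-rank, and Cox proportional-hazards fitting.

The dichotomization emulates outcome-based cut-point software: the
maximally selected log-rank statistic over an explicit candidate grid with
a minimum group-size constraint.  Cut-points are derived on the discovery
set and applied unchanged to held-out data; discovery-set p-values at the
selected cut carry an explicit uncorrected-maximum caveat (no
Miller-Siegmund correction is applied — the held-out set is the guard).

The Cox model maximizes the partial likelihood by Newton iteration with
Efron (default) or Breslow handling of tied event times; hazard ratios are
``exp(beta)`` with Wald confidence intervals from the observed information.
The log-rank statistic uses the observed-minus-expected form with
hypergeometric variance summed over distinct event times.  For tie-free
data the Cox score test at ``beta = 0`` under Breslow ties coincides with
the log-rank chi-square.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalData",
    "CutpointResult",
    "SurvivalResult",
    "stratified_split",
    "km_estimate",
    "logrank_test",
    "optimal_cutpoint",
    "apply_cutpoint",
    "cox_fit",
    "cox_score_test",
    "hr_per_k_units",
]

CUTPOINT_CAVEAT = (
    "p-value at the selected cut-point is an uncorrected maximum over the "
    "candidate grid; validate on held-out data"
)


@dataclass
class SurvivalData:
    """Right-censored follow-up: time in months (> 0) and event indicator."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=bool)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if not np.isfinite(self.time).all() or (self.time <= 0).any():
            raise ValueError("follow-up times must be finite and > 0 (time-0 subjects are rejected)")


@dataclass
class CutpointResult:
    feature_name: str
    cutoff: float
    chi_square_at_cutoff: float
    p_uncorrected: float
    n_low: int
    n_high: int
    grid_policy: str
    derived_on: str = "discovery"
    caveat: str = CUTPOINT_CAVEAT


@dataclass
class SurvivalResult:
    covariate: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    n_events: int
    model: Literal["univariate_km_logrank", "cox_uni", "cox_multi"]
    covariates: list[str]
    beta: float = float("nan")
    se: float = float("nan")


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def stratified_split(
    cohort: pd.DataFrame, test_fraction: float, seed: int, stratify_on: str = "event"
) -> pd.DataFrame:
    """Assign discovery/test split labels, stratified on the event indicator
    so both sets carry the same event proportion (within rounding).
    Deterministic for a fixed seed."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    labels = np.full(len(out), "discovery", dtype=object)
    pos = np.arange(len(out))
    for _, idx in pd.Series(pos).groupby(out[stratify_on].to_numpy()):
        idx = idx.to_numpy()
        if idx.size < 2:
            raise ValueError(f"stratum of size {idx.size} is too small to split")
        n_test = int(round(test_fraction * idx.size))
        chosen = rng.permutation(idx)[:n_test]
        labels[chosen] = "test"
    out["split_label"] = labels
    return out


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

def km_estimate(surv: SurvivalData) -> pd.DataFrame:
    """Product-limit survival curve as a step-function table
    (t, survival, at_risk, events), starting at S(0) = 1.  Subjects censored
    at an event time are counted at risk at that time."""
    if surv.time.size == 0:
        raise ValueError("empty survival data")
    kmf = KaplanMeierFitter()
    kmf.fit(surv.time, surv.event)
    tab = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    df = pd.DataFrame(
        {
            "t": tab.index.to_numpy(dtype=float),
            "survival": sf.reindex(tab.index).to_numpy(dtype=float),
            "at_risk": tab["at_risk"].to_numpy(dtype=int),
            "events": tab["observed"].to_numpy(dtype=int),
        }
    ).reset_index(drop=True)
    if df.loc[0, "t"] != 0.0:
        first = pd.DataFrame(
            {"t": [0.0], "survival": [1.0], "at_risk": [int(surv.time.size)], "events": [0]}
        )
        df = pd.concat([first, df], ignore_index=True)
    return df


def logrank_test(surv: SurvivalData, group: Sequence) -> tuple[float, float]:
    """Two-group log-rank test: (chi_square, p) with 1 df.

    Observed-minus-expected statistic with hypergeometric variance summed
    over distinct event times.  Zero total events yields (nan, nan) with a
    warning (undefined, not significant).  Symmetric in the group labels.
    """
    g = np.asarray(group)
    labels = np.unique(g)
    if labels.size != 2:
        raise ValueError(f"log-rank needs exactly two nonempty groups, got {labels.size}")
    chi2 = _logrank_chi2(surv.time, surv.event, g == labels[1])
    if np.isnan(chi2):
        return float("nan"), float("nan")
    return chi2, float(stats.chi2.sf(chi2, df=1))


def _logrank_chi2(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    event_t = time[event]
    if event_t.size == 0:
        logger.warning("log-rank undefined: zero events")
        return float("nan")
    tk, d = np.unique(event_t, return_counts=True)
    e1 = event & in_group1
    d1 = np.zeros_like(d)
    if e1.any():
        t1k, d1k = np.unique(time[e1], return_counts=True)
        d1[np.searchsorted(tk, t1k)] = d1k
    all_sorted = np.sort(time)
    g1_sorted = np.sort(time[in_group1])
    n_at = time.size - np.searchsorted(all_sorted, tk, side="left")
    n1_at = in_group1.sum() - np.searchsorted(g1_sorted, tk, side="left")
    frac = n1_at / n_at
    expected = d * frac
    with np.errstate(invalid="ignore", divide="ignore"):
        var = np.where(n_at > 1, d * frac * (1 - frac) * (n_at - d) / (n_at - 1), 0.0)
    v = var.sum()
    if v <= 0:
        return 0.0
    o_minus_e = d1.sum() - expected.sum()
    return float(o_minus_e**2 / v)


# ---------------------------------------------------------------------------
# Cut-point selection
# ---------------------------------------------------------------------------

def optimal_cutpoint(
    feature_values: Sequence[float],
    surv: SurvivalData,
    feature_name: str = "feature",
    grid_policy: Literal["percentile", "unique"] = "percentile",
    min_group_fraction: float = 0.1,
) -> CutpointResult:
    """Outcome-based dichotomization: the cut maximizing the log-rank
    chi-square over the candidate grid, subject to a minimum group size on
    both sides; ties break toward the cut nearest the median.

    ``percentile`` evaluates the 5th-95th percentiles in steps of 1;
    ``unique`` evaluates every distinct feature value.  High means
    strictly greater than the cut-off.
    """
    v = np.asarray(feature_values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("feature must take at least 2 distinct values")
    if not surv.event.any():
        raise ValueError("cut-point selection needs at least one event")
    n = v.size
    if grid_policy == "percentile":
        candidates = np.unique(np.percentile(v, np.arange(5, 96)))
    elif grid_policy == "unique":
        candidates = np.unique(v)
    else:
        raise ValueError(f"unknown grid_policy {grid_policy!r}")
    min_n = min_group_fraction * n
    median = float(np.median(v))
    best = None
    for cut in candidates:
        high = v > cut
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < min_n or n_low < min_n:
            continue
        chi2 = _logrank_chi2(surv.time, surv.event, high)
        if np.isnan(chi2):
            continue
        key = (chi2, -abs(cut - median))
        if best is None or key > best[0]:
            best = (key, float(cut), chi2, n_low, n_high)
    if best is None:
        raise ValueError(
            "no candidate cut satisfies the minimum group-size constraint "
            f"(min_group_fraction={min_group_fraction})"
        )
    _, cutoff, chi2, n_low, n_high = best
    return CutpointResult(
        feature_name=feature_name,
        cutoff=cutoff,
        chi_square_at_cutoff=chi2,
        p_uncorrected=float(stats.chi2.sf(chi2, df=1)),
        n_low=n_low,
        n_high=n_high,
        grid_policy=grid_policy,
    )


def apply_cutpoint(feature_values: Sequence[float], cutoff: float) -> np.ndarray:
    """Binary high/low labels: high iff value > cutoff (the discovery-set
    cut-off is reused unchanged on held-out data)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    v = np.asarray(feature_values, dtype=float)
    high = v > cutoff
    if high.all() or not high.any():
        logger.warning(
            "degenerate dichotomization: all %d subjects on one side of cutoff %g",
            v.size,
            cutoff,
        )
    return high


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _cox_ll_grad_info(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray, ties: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Partial log-likelihood, score and observed information."""
    order = np.argsort(-time, kind="mergesort")
    Xs = X[order]
    ts = time[order]
    es = event[order]
    n, p = Xs.shape
    eta = Xs @ beta
    shift = eta.max()  # partial likelihood is invariant to this shift
    w = np.exp(eta - shift)
    cw = np.cumsum(w)
    cxw = np.cumsum(w[:, None] * Xs, axis=0)
    cxxw = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)

    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        dsel = es[i:j]
        d = int(dsel.sum())
        if d > 0:
            XD = Xs[i:j][dsel]
            wD = w[i:j][dsel]
            s = cw[j - 1]
            xs = cxw[j - 1]
            xxs = cxxw[j - 1]
            ll += float((eta[i:j][dsel] - shift).sum())
            grad += XD.sum(axis=0)
            if ties == "breslow":
                ll -= d * np.log(s)
                grad -= d * xs / s
                info += d * (xxs / s - np.outer(xs, xs) / s**2)
            else:  # efron
                swD = wD.sum()
                xwD = (wD[:, None] * XD).sum(axis=0)
                xxwD = (wD[:, None, None] * (XD[:, :, None] * XD[:, None, :])).sum(axis=0)
                for l in range(d):
                    f = l / d
                    denom = s - f * swD
                    xn = xs - f * xwD
                    xxn = xxs - f * xxwD
                    ll -= np.log(denom)
                    grad -= xn / denom
                    info += xxn / denom - np.outer(xn, xn) / denom**2
        i = j
    return ll, grad, info


def _as_design(covariate_matrix) -> tuple[np.ndarray, list[str]]:
    if isinstance(covariate_matrix, pd.DataFrame):
        return covariate_matrix.to_numpy(dtype=float), [str(c) for c in covariate_matrix.columns]
    X = np.asarray(covariate_matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def cox_fit(
    covariate_matrix,
    surv: SurvivalData,
    ties: Literal["efron", "breslow"] = "efron",
    tol: float = 1e-9,
    max_iter: int = 100,
) -> list[SurvivalResult]:
    """Fit a Cox proportional-hazards model; one result row per covariate.

    Newton iteration on the partial likelihood until the log-likelihood
    changes by less than ``tol``; 95% Wald confidence intervals from the
    observed information.  Raises on constant covariates, too few events,
    and on non-convergence / monotone likelihood (perfect separation).
    """
    X, names = _as_design(covariate_matrix)
    if X.shape[0] != surv.time.size:
        raise ValueError("covariate matrix and survival data lengths differ")
    n_events = int(surv.event.sum())
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"constant covariate: {name!r}")
    if n_events < X.shape[1]:
        raise ValueError(f"{n_events} events < {X.shape[1]} covariates")

    beta = np.zeros(X.shape[1])
    ll, grad, info = _cox_ll_grad_info(X, surv.time, surv.event, beta, ties)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise RuntimeError("Cox fit failed: singular information matrix") from exc
        # step halving keeps the likelihood ascending
        for _ in range(30):
            cand = beta + step
            ll_new, grad_new, info_new = _cox_ll_grad_info(X, surv.time, surv.event, cand, ties)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        else:
            raise RuntimeError("Cox fit failed: step halving did not ascend")
        delta = ll_new - ll
        beta, ll, grad, info = cand, ll_new, grad_new, info_new
        # scale-aware divergence guard: linear predictor spread beyond ~200
        # means the likelihood is monotone in some direction
        if (np.abs(beta) * np.ptp(X, axis=0)).max() > 200:
            raise RuntimeError(
                "Cox fit diverged (monotone likelihood / perfect separation suspected)"
            )
        if abs(delta) < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"Cox fit did not converge in {max_iter} iterations")

    cov = np.linalg.inv(info)
    diag = np.diag(cov)
    if not np.isfinite(diag).all() or (diag <= 0).any():
        raise RuntimeError(
            "Cox fit produced a degenerate information matrix "
            "(monotone likelihood / perfect separation suspected)"
        )
    se = np.sqrt(diag)
    z975 = stats.norm.ppf(0.975)
    model = "cox_uni" if X.shape[1] == 1 else "cox_multi"
    results = []
    for j, name in enumerate(names):
        b, s = float(beta[j]), float(se[j])
        with np.errstate(over="ignore"):  # an unbounded Wald CI is reported as inf
            lo, hi = float(np.exp(b - z975 * s)), float(np.exp(b + z975 * s))
        results.append(
            SurvivalResult(
                covariate=name,
                hr=float(np.exp(b)),
                ci_low=lo,
                ci_high=hi,
                p_value=float(2 * stats.norm.sf(abs(b / s))),
                n_events=n_events,
                model=model,
                covariates=list(names),
                beta=b,
                se=s,
            )
        )
    return results


def cox_score_test(
    covariate_matrix, surv: SurvivalData, ties: Literal["breslow", "efron"] = "breslow"
) -> tuple[float, float]:
    """Cox score test at beta = 0: (chi_square, p).

    Under Breslow ties and tie-free data this equals the log-rank
    chi-square for a binary covariate.
    """
    X, _ = _as_design(covariate_matrix)
    beta = np.zeros(X.shape[1])
    _, grad, info = _cox_ll_grad_info(X, surv.time, surv.event, beta, ties)
    chi2 = float(grad @ np.linalg.solve(info, grad))
    return chi2, float(stats.chi2.sf(chi2, df=X.shape[1]))


def hr_per_k_units(beta: float, k: float = 1000.0, se: float | None = None):
    """Rescale a per-unit log-hazard to a per-``k``-units hazard ratio.

    With ``se`` given, returns ``(hr, ci_low, ci_high)`` with the CI
    endpoints transformed identically (exp(k * (beta +/- 1.96 se)));
    otherwise the scalar ``exp(k * beta)``.
    """
    hr = float(np.exp(k * beta))
    if se is None:
        return hr
    z975 = stats.norm.ppf(0.975)
    return hr, float(np.exp(k * (beta - z975 * se))), float(np.exp(k * (beta + z975 * se)))
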