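"""Cox proportional hazards core.

Fits h(t|X) = h0(t) exp(X beta) by Newton-Raphson maximization of the
partial likelihood with the Breslow convention for tied event times,
estimates the Breslow baseline cumulative hazard H0(t) (so the baseline
survival S0(t) = exp(-H0(t)) is anchored at the all-reference covariate
pattern), and predicts individual survival as S(t|X) = S0(t)**exp(X beta).

All covariates enter dummy-encoded: a categorical variable with levels
(l0, l1, l2) and reference l0 contributes indicator columns ``var=l1`` and
``var=l2``; the reference pattern maps to the zero vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Cohort

__all__ = [
    "CoxError",
    "ConvergenceError",
    "IdentifiabilityError",
    "CoxFit",
    "ScreenResult",
    "encode_design",
    "encode_row",
    "fit_cox",
    "breslow_baseline",
    "predict_survival",
    "hazard_ratios",
    "univariate_screen",
]

GRAD_TOL = 1e-8
MAX_ITER = 100
#: |beta| beyond which the partial likelihood is treated as monotone
#: (complete separation); exp(10) already exceeds any realistic hazard ratio.
DIVERGE_BETA = 10.0


class CoxError(RuntimeError):
    pass


class ConvergenceError(CoxError):
    pass


class IdentifiabilityError(CoxError):
    pass


@dataclass
class CoxFit:
    """Estimated Cox model: coefficients plus Breslow baseline.

    ``encoding`` maps each covariate to its (level, column-index) pairs;
    ``baseline_times``/``H0``/``S0`` describe the step-function baseline,
    populated by :func:`breslow_baseline`.
    """

    covariates: list[str]
    encoding: dict[str, list[tuple[str, int]]]
    reference: dict[str, str]
    column_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_events: int
    N: int
    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    H0: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def p(self) -> int:
        return len(self.beta)

    @property
    def S0(self) -> np.ndarray:
        return np.exp(-self.H0)

    def linear_predictor(self, x: dict[str, str]) -> float:
        """X beta for one covariate assignment (reference pattern -> 0)."""
        return float(self.beta @ encode_row(self, x))

    def baseline_survival(self, t) -> np.ndarray:
        """S0 evaluated at time(s) t; right-continuous step function, 1 before
        the first event time."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.baseline_times, t, side="right")
        H = np.concatenate([[0.0], self.H0])[idx]
        return np.exp(-H)


def encode_design(cohort: Cohort, covariates: list[str]) -> tuple[np.ndarray, dict, dict, list[str]]:
    """Dummy design matrix over complete rows of the listed covariates."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    encoding: dict[str, list[tuple[str, int]]] = {}
    reference: dict[str, str] = {}
    for name in covariates:
        spec = cohort.spec(name)
        if spec.kind != "categorical":
            raise CoxError(f"{name}: covariates must be categorical (discretize first)")
        values = cohort.df[name]
        if values.isna().any():
            raise CoxError(f"{name}: missing values present; fit on complete cases")
        values = values.astype(str)
        ref = spec.reference
        reference[name] = ref
        pairs = []
        for level in spec.levels:
            if level == ref:
                continue
            pairs.append((level, len(names)))
            names.append(f"{name}={level}")
            cols.append((values == level).to_numpy(dtype=float))
        encoding[name] = pairs
    X = np.column_stack(cols) if cols else np.empty((cohort.N, 0))
    return X, encoding, reference, names


def encode_row(fit: CoxFit, x: dict[str, str]) -> np.ndarray:
    v = np.zeros(fit.p)
    for name in fit.covariates:
        if name not in x:
            raise CoxError(f"covariate {name!r} absent from assignment")
        level = str(x[name])
        if level == fit.reference[name]:
            continue
        for lev, j in fit.encoding[name]:
            if lev == level:
                v[j] = 1.0
                break
        else:
            raise CoxError(f"unknown level {level!r} for covariate {name!r}")
    return v


def _tie_first(ts: np.ndarray) -> np.ndarray:
    """Index of the first member of each tie group in a sorted time vector."""
    if len(ts) == 0:
        return np.empty(0, dtype=int)
    starts = np.concatenate([[0], np.flatnonzero(np.diff(ts) != 0) + 1])
    sizes = np.diff(np.concatenate([starts, [len(ts)]]))
    return np.repeat(starts, sizes)


def _breslow_quantities(X, t, e, beta):
    """Log partial likelihood, gradient and Hessian (Breslow ties).

    Rows are processed in decreasing time order so that suffix sums in the
    original (increasing) order are risk-set sums.
    """
    order = np.argsort(t, kind="stable")
    Xs, ts, es = X[order], t[order], e[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # reverse cumulative sums: entry i sums over all j with t_j >= t_i
    # (after tie grouping below)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]

    # first index of each tie group, so denominators cover the full group
    first = _tie_first(ts)

    ev = np.flatnonzero(es == 1)
    # group events by distinct event time
    uniq, counts = np.unique(first[ev], return_counts=True)
    d = counts.astype(float)
    S0 = s0[uniq]
    S1u = s1[uniq]
    mu = S1u / S0[:, None]
    ll = eta[ev].sum() - float(d @ np.log(S0))
    grad = Xs[ev].sum(axis=0) - d @ mu
    # Hessian without any N x p x p intermediate: the first Breslow term
    # telescopes to X' diag(w * Lambda) X with Lambda_i the cumulative
    # baseline-hazard increments up to t_i
    n = len(ts)
    pos = np.searchsorted(uniq, np.arange(n), side="right")
    lam_i = np.concatenate([[0.0], np.cumsum(d / S0)])[pos]
    H1 = (Xs.T * (w * lam_i)) @ Xs
    H2 = (S1u.T * (d / S0**2)) @ S1u
    hess = -(H1 - H2)
    return ll, grad, hess


def fit_cox(cohort: Cohort, covariates: list[str]) -> CoxFit:
    """Maximize the Breslow partial likelihood by Newton-Raphson.

    Uses step-halving when a step fails to increase the log partial
    likelihood; converges when the score max-norm drops below 1e-8 per
    event (the score is a sum of one O(1) term per event, so the
    tolerance scales with the event count).

    Raises
    ------
    IdentifiabilityError
        If a dummy column is constant (level never / always observed).
    ConvergenceError
        On monotone likelihood (complete separation) or iteration cap.
    """
    X, encoding, reference, names = encode_design(cohort, covariates)
    t, e = cohort.time, cohort.event
    if e.sum() < 1:
        raise CoxError("cohort contains no events")
    for j, nm in enumerate(names):
        if np.all(X[:, j] == X[0, j]):
            raise IdentifiabilityError(f"covariate column {nm!r} is constant")
    p = X.shape[1]
    beta = np.zeros(p)
    # score tolerance scales with the number of events: each event adds an
    # O(1) term to the score, and the risk-set cumulative sums carry the
    # matching rounding noise
    tol = GRAD_TOL * max(1.0, float(e.sum()))
    ll, grad, hess = _breslow_quantities(X, t, e, beta)
    for _ in range(MAX_ITER):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as err:
            raise IdentifiabilityError(f"singular information matrix: {err}") from err
        new_beta = beta + step
        new_ll, new_grad, new_hess = _breslow_quantities(X, t, e, new_beta)
        halvings = 0
        stalled = False
        while not np.isfinite(new_ll) or new_ll < ll - 1e-12:
            halvings += 1
            if halvings > 30:
                # likelihood already flat to rounding precision
                if np.max(np.abs(grad)) < 1e-5:
                    stalled = True
                    break
                raise ConvergenceError("step-halving failed to increase likelihood")
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _breslow_quantities(X, t, e, new_beta)
        if stalled:
            break
        converged_step = np.max(np.abs(new_beta - beta)) < 1e-10
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > DIVERGE_BETA:
            worst = names[int(np.argmax(np.abs(beta)))]
            raise ConvergenceError(
                f"monotone likelihood: coefficient for {worst!r} diverges "
                "(complete separation)"
            )
        if converged_step:
            break
    else:
        raise ConvergenceError(f"no convergence in {MAX_ITER} iterations")
    if p and np.max(np.abs(beta)) > DIVERGE_BETA:
        worst = names[int(np.argmax(np.abs(beta)))]
        raise ConvergenceError(
            f"monotone likelihood: coefficient for {worst!r} diverges "
            "(complete separation)"
        )
    try:
        with np.errstate(invalid="ignore"):
            cov = np.linalg.inv(-hess) if p else np.empty((0, 0))
    except np.linalg.LinAlgError as err:
        raise IdentifiabilityError(f"singular information matrix: {err}") from err
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf)) if p else np.empty(0)
    fit = CoxFit(
        covariates=list(covariates),
        encoding=encoding,
        reference=reference,
        column_names=names,
        beta=beta,
        se=se,
        loglik=float(ll),
        n_events=int(e.sum()),
        N=cohort.N,
    )
    return breslow_baseline(fit, cohort)


def breslow_baseline(fit: CoxFit, cohort: Cohort) -> CoxFit:
    """Populate H0/S0: H0(t) = sum over event times t_i <= t of
    d_i / sum_{j in R(t_i)} exp(X_j beta)."""
    X, _, _, _ = encode_design(cohort, fit.covariates)
    t, e = cohort.time, cohort.event
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    w = np.exp(X[order] @ fit.beta)
    s0 = np.cumsum(w[::-1])[::-1]
    first = _tie_first(ts)
    ev = np.flatnonzero(es == 1)
    uniq, counts = np.unique(first[ev], return_counts=True)
    times = ts[uniq]
    increments = counts / s0[uniq]
    return replace(fit, baseline_times=times, H0=np.cumsum(increments))


def predict_survival(fit: CoxFit, x: dict[str, str], t) -> float | np.ndarray:
    """S(t|x) = S0(t) ** exp(x beta); scalar t gives a scalar."""
    lp = fit.linear_predictor(x)
    s = fit.baseline_survival(t) ** np.exp(lp)
    return float(s[0]) if np.isscalar(t) or np.asarray(t).ndim == 0 else s


def hazard_ratios(fit: CoxFit, alpha: float = 0.05) -> pd.DataFrame:
    """Coefficient table: beta, HR = exp(beta), Wald CI and p-value."""
    z = stats.norm.ppf(1 - alpha / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        zstat = np.where(fit.se > 0, fit.beta / fit.se, np.inf)
    pvals = 2 * stats.norm.sf(np.abs(zstat))
    return pd.DataFrame(
        {
            "term": fit.column_names,
            "beta": fit.beta,
            "HR": np.exp(fit.beta),
            "ci_low": np.exp(fit.beta - z * fit.se),
            "ci_high": np.exp(fit.beta + z * fit.se),
            "p": pvals,
        }
    )


@dataclass
class ScreenResult:
    """Univariate screen outcome for one candidate variable."""

    variable: str
    p_value: float
    table: pd.DataFrame | None
    kept: bool
    error: str | None = None


def univariate_screen(
    cohort: Cohort, candidates: list[str], threshold: float = 0.05
) -> list[ScreenResult]:
    """One single-covariate Cox fit per candidate.

    A variable is kept when the smallest Wald p-value across its non-
    reference levels is below ``threshold`` (default 0.05). Per-variable
    fit failures drop the variable with a warning instead of aborting the
    screen.
    """
    results = []
    for name in candidates:
        try:
            fit = fit_cox(cohort, [name])
            table = hazard_ratios(fit)
            pmin = float(table["p"].min())
            results.append(ScreenResult(name, pmin, table, kept=pmin < threshold))
        except CoxError as err:
            warnings.warn(f"univariate screen: dropping {name!r}: {err}")
            results.append(ScreenResult(name, np.nan, None, kept=False, error=str(err)))
    return results
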