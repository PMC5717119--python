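"""Prognostic survival modelling.

The centrepiece is a Cox proportional-hazards fit maximising the partial
likelihood by Newton's method, with Breslow handling of tied event times
(Efron available behind a flag), and on top of it:

* backward elimination by exact likelihood-ratio tests,
* hazard ratios with 95% confidence intervals,
* the prognostic score — the sum of each retained variable times its
  coefficient — with the published six-variable weights as defaults,
* rank-based quartile stratification with frozen cutoffs,
* Kaplan-Meier estimation and log-rank testing (via lifelines),
* a treatment-interaction likelihood-ratio test,
* AIC comparison of the three nested candidate models, and
* application of a frozen model to a validation cohort.

Natural logarithms are used throughout, so hazard ratios are exp(beta).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats

from .exceptions import (
    ConvergenceError,
    DegenerateInputError,
    SeparationError,
    ValidationError,
)
from .synthetic import MODEL_VARIABLES, PUBLISHED_COEFFICIENTS, _model_matrix

#: Features entering the model on the natural-log scale (long right tails).
LOG_TRANSFORMED = {
    "tlg": "log_tlg",
    "hist_energy": "log_hist_energy",
    "ngtdm_coarseness": "log_ngtdm_coarseness",
    "glcm_homogeneity": "log_glcm_homogeneity",
}

#: The three nested candidate models compared by AIC: clinical covariates
#: only; plus conventional PET measures; plus the full texture panel.
NESTED_MODELS: dict[str, tuple[str, ...]] = {
    "clinical": ("age", "stage_group", "treatment"),
    "clinical+suv": (
        "age", "stage_group", "treatment", "suv_max", "suv_mean", "mtv_ml",
    ),
    "clinical+suv+texture": MODEL_VARIABLES,
}


@dataclass(frozen=True)
class CoxFit:
    """A converged Cox partial-likelihood fit."""

    variables: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    n_events: int
    ties: str
    iterations: int
    converged: bool

    @property
    def k(self) -> int:
        return len(self.variables)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with median and 95% CI."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float
    median_ci: tuple[float, float]


def transform_features(table: pd.DataFrame) -> pd.DataFrame:
    """Add natural-log columns for the four long-tailed metrics.

    Originals are retained; non-positive values are flagged missing (NaN in
    the log column) with per-variable row ids recorded in
    ``result.attrs['transform_flags']`` — never silently dropped.
    """
    out = table.copy()
    flags: dict[str, list] = {}
    for raw, logname in LOG_TRANSFORMED.items():
        if raw not in out.columns:
            continue
        x = out[raw].astype(float)
        bad = x <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            out[logname] = np.where(bad | x.isna(), np.nan, np.log(x.where(x > 0)))
        flagged = out.loc[bad.fillna(False), "id"].tolist() if "id" in out else []
        if flagged:
            flags[logname] = flagged
    out.attrs["transform_flags"] = flags
    return out


def _risk_block_ends(t_sorted: np.ndarray) -> np.ndarray:
    """For each sorted position, the last index sharing its time value."""
    neg = -t_sorted
    return np.searchsorted(neg, neg, side="right") - 1


def _loglik_grad_hess(x, t, d, beta, ties):
    """Partial log-likelihood, score and observed information.

    ``x`` (n,k), ``t`` times sorted descending, ``d`` event indicators.
    Breslow: every event in a tie block shares the full risk-set sums.
    Efron: the l-th of m tied events downweights the tied contributions
    by l/m.
    """
    n, k = x.shape
    eta = x @ beta
    eta_c = eta - eta.max()  # guards overflow; cancels in ratios and is
    theta = np.exp(eta_c)  # restored in the log-likelihood below
    s0 = np.cumsum(theta)
    s1 = np.cumsum(theta[:, None] * x, axis=0)
    s2 = np.cumsum(theta[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)

    ends = _risk_block_ends(t)
    ev = np.flatnonzero(d == 1)
    loglik = float(np.sum(eta[ev]))
    grad = x[ev].sum(axis=0)
    hess = np.zeros((k, k))

    if ties == "breslow":
        e = ends[ev]
        den = s0[e]
        loglik -= float(np.sum(np.log(den) + eta.max()))
        xbar = s1[e] / den[:, None]
        grad -= xbar.sum(axis=0)
        hess = np.einsum("i,ijk->jk", 1.0 / den, s2[e]) - np.einsum(
            "ij,ik->jk", xbar, xbar
        )
    elif ties == "efron":
        for end in np.unique(ends[ev]):
            block = ev[ends[ev] == end]
            m = block.size
            td0 = theta[block].sum()
            td1 = (theta[block, None] * x[block]).sum(axis=0)
            td2 = (theta[block, None, None] * (x[block, :, None] * x[block, None, :])).sum(axis=0)
            for l in range(m):
                f = l / m
                den = s0[end] - f * td0
                num1 = s1[end] - f * td1
                num2 = s2[end] - f * td2
                loglik -= float(np.log(den) + eta.max())
                xbar = num1 / den
                grad -= xbar
                hess += num2 / den - np.outer(xbar, xbar)
    else:  # pragma: no cover
        raise ValidationError(f"unknown ties method {ties!r}")
    return loglik, grad, hess


def _null_loglik(t, d, ties):
    n = t.size
    beta0 = np.zeros(1)
    x0 = np.zeros((n, 1))
    ll, _, _ = _loglik_grad_hess(x0, t, d, beta0, ties)
    return ll


def fit_cox(
    table: pd.DataFrame,
    variables: list[str] | tuple[str, ...],
    duration_col: str = "os_months",
    event_col: str = "event",
    ties: str = "breslow",
    tol_grad: float = 1e-8,
    tol_loglik: float = 1e-9,
    max_iter: int = 60,
    min_events: int = 10,
) -> CoxFit:
    """Maximise the Cox partial likelihood by Newton iterations.

    Rows with missing values in the requested variables are removed
    (complete-case analysis); convergence requires the maximum score
    component below ``tol_grad`` or a relative log-likelihood change below
    ``tol_loglik``.  Standard errors come from the observed information.
    """
    variables = tuple(variables)
    cols = list(variables) + [duration_col, event_col]
    missing_cols = [c for c in cols if c not in table.columns]
    if missing_cols:
        raise ValidationError(f"cohort table lacks columns {missing_cols}")
    sub = table[cols].dropna()
    t_raw = sub[duration_col].to_numpy(dtype=float)
    d_raw = sub[event_col].to_numpy(dtype=int)
    n = t_raw.size
    n_events = int(d_raw.sum())
    if n_events < min_events:
        raise ValidationError(f"need >= {min_events} events, got {n_events}")

    order = np.argsort(-t_raw, kind="stable")
    t, d = t_raw[order], d_raw[order]
    ll_null = _null_loglik(t, d, ties)

    if not variables:
        return CoxFit((), np.zeros(0), np.zeros(0), ll_null, ll_null,
                      n, n_events, ties, 0, True)

    x = sub[list(variables)].to_numpy(dtype=float)[order]
    if np.any(x.std(axis=0) == 0):
        const = [v for v, s in zip(variables, x.std(axis=0)) if s == 0]
        raise DegenerateInputError(f"constant covariate(s): {const}")

    # centre covariates for conditioning; beta is unaffected
    centre = x.mean(axis=0)
    xc = x - centre

    beta = np.zeros(len(variables))
    ll, grad, hess = _loglik_grad_hess(xc, t, d, beta, ties)
    trace = [ll]
    converged = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the likelihood non-decreasing
        alpha = 1.0
        for _ in range(30):
            ll_new, g_new, h_new = _loglik_grad_hess(xc, t, d, beta + alpha * step, ties)
            if ll_new >= ll - 1e-12:
                break
            alpha /= 2.0
        beta = beta + alpha * step
        trace.append(ll_new)
        if np.any(np.abs(beta) > 20):
            raise SeparationError(
                f"diverging coefficients {dict(zip(variables, beta.round(2)))}; "
                "likely separation or monotone likelihood"
            )
        rel = abs(ll_new - ll) / max(abs(ll), 1.0)
        ll, grad, hess = ll_new, g_new, h_new
        if np.max(np.abs(grad)) < tol_grad or rel < tol_loglik:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"Cox fit did not converge in {max_iter} iterations; "
            f"log-likelihood trace tail {trace[-3:]}"
        )
    se = np.sqrt(np.diag(np.linalg.inv(hess)))
    return CoxFit(variables, beta, se, ll, ll_null, n, n_events, ties, it, True)


def events_per_variable(events, n_variables: int) -> float:
    """Events per candidate variable (EPV), to one decimal.

    ``events`` may be an event count or a cohort table.  Model stability
    guidance recommends EPV of at least 10; below that a warning is issued.
    """
    if n_variables < 1:
        raise ValidationError("n_variables must be >= 1")
    if isinstance(events, pd.DataFrame):
        events = int(events["event"].sum())
    epv = round(events / n_variables, 1)
    if epv < 10:
        warnings.warn(f"EPV {epv} below the recommended minimum of 10", stacklevel=2)
    return epv


@dataclass(frozen=True)
class EliminationResult:
    fit: CoxFit
    removed: tuple[tuple[str, float], ...]  # (variable, LR p at removal)


def backward_eliminate(
    table: pd.DataFrame,
    start_variables,
    alpha_remove: float = 0.05,
    ties: str = "breslow",
    **fit_kwargs,
) -> EliminationResult:
    """Backward elimination by exact likelihood-ratio tests.

    At each step the current model is refit without each variable in turn;
    the variable with the largest LR p-value (2*delta-logL on 1 df) above
    ``alpha_remove`` is dropped.  Stops when every retained variable tests
    at or below the threshold, or the model is empty.  Complete cases over
    the starting variable set are used throughout, so likelihoods stay
    comparable.
    """
    current = list(start_variables)
    sub = table[list(current) + ["os_months", "event"]].dropna()
    removed: list[tuple[str, float]] = []
    fit = fit_cox(sub, current, ties=ties, **fit_kwargs)
    while current:
        worst_var, worst_p = None, -1.0
        for v in current:
            reduced = [w for w in current if w != v]
            red_fit = fit_cox(sub, reduced, ties=ties, **fit_kwargs)
            lr = 2.0 * (fit.loglik - red_fit.loglik)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            if p > worst_p:
                worst_var, worst_p, worst_fit = v, p, red_fit
        if worst_p > alpha_remove:
            current.remove(worst_var)
            removed.append((worst_var, worst_p))
            fit = worst_fit
        else:
            break
    return EliminationResult(fit, tuple(removed))


def hazard_ratios(fit: CoxFit, z: float = 1.959963984540054) -> pd.DataFrame:
    """HR = exp(beta) with 95% CI exp(beta -/+ z*SE) and Wald p-values."""
    if not fit.converged:
        raise ValidationError("hazard ratios require a converged fit")
    wald = fit.beta / fit.se if fit.k else np.zeros(0)
    return pd.DataFrame(
        {
            "variable": fit.variables,
            "coef": fit.beta,
            "se": fit.se,
            "hr": np.exp(fit.beta),
            "ci_lower": np.exp(fit.beta - z * fit.se),
            "ci_upper": np.exp(fit.beta + z * fit.se),
            "p": 2 * stats.norm.sf(np.abs(wald)),
        }
    )


@dataclass(frozen=True)
class PrognosticModel:
    """Frozen score weights, transform spec and development quartile cutoffs."""

    weights: dict = field(default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    cutoffs: tuple[float, float, float] | None = None
    transforms: dict = field(default_factory=lambda: dict(LOG_TRANSFORMED))

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValidationError("score weights must be finite")
        if self.cutoffs is not None and not (
            self.cutoffs[0] < self.cutoffs[1] < self.cutoffs[2]
        ):
            raise ValidationError(f"cutoffs must increase strictly: {self.cutoffs}")

    def with_cutoffs(self, cutoffs) -> "PrognosticModel":
        return PrognosticModel(dict(self.weights), tuple(cutoffs), dict(self.transforms))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "format": "petprog-prognostic-model-v1",
                    "weights": self.weights,
                    "cutoffs": list(self.cutoffs) if self.cutoffs else None,
                    "transforms": self.transforms,
                },
                fh,
                indent=1,
            )

    @classmethod
    def load(cls, path) -> "PrognosticModel":
        with open(path) as fh:
            payload = json.load(fh)
        cutoffs = payload["cutoffs"]
        return cls(
            payload["weights"],
            tuple(cutoffs) if cutoffs else None,
            payload["transforms"],
        )


def prognostic_score(table: pd.DataFrame, model: PrognosticModel) -> pd.Series:
    """Per-patient score: sum of model weight x variable value.

    Transformed variables (``log_*``) are derived from the raw columns when
    absent.  Patients missing any model variable get a NaN score.
    """
    work = table.copy()
    needed = set(model.weights)
    derived = _model_matrix(work)
    for name in needed:
        if name not in work.columns:
            if name in derived.columns:
                work[name] = derived[name]
            else:
                raise ValidationError(f"score variable {name!r} unavailable")
    score = pd.Series(np.zeros(len(work)), index=work.index, name="prognostic_score")
    for name, w in model.weights.items():
        score = score + w * work[name].astype(float)
    return score


def assign_quartiles(scores) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Split scores into Q1 (lowest) .. Q4 (highest) quarters by rank.

    Group sizes follow the near-equal quartering that puts the larger groups
    first (76/76/75/75 at n=302); the returned cutoffs are the highest score
    in each of Q1..Q3, and any score tied with a cutoff falls in the lower
    quartile.
    """
    s = np.asarray(scores, dtype=float)
    valid = np.isfinite(s)
    if valid.sum() < 8:
        raise ValidationError("quartile assignment needs >= 8 non-missing scores")
    sv = np.sort(s[valid])
    n = sv.size
    sizes = [len(part) for part in np.array_split(np.arange(n), 4)]
    bounds = np.cumsum(sizes)[:3]
    cutoffs = tuple(float(sv[b - 1]) for b in bounds)
    _, counts = np.unique(sv, return_counts=True)
    if counts.max() > 0.25 * n:
        warnings.warn(
            "more than 25% of scores are identical; quartiles are unbalanced",
            stacklevel=2,
        )
    labels = label_by_cutoffs(s, cutoffs)
    return labels, cutoffs


def label_by_cutoffs(scores, cutoffs) -> np.ndarray:
    """Quartile labels 1-4 from frozen cutoffs; ties go to the lower group.

    NaN scores get label 0 (unassignable)."""
    s = np.asarray(scores, dtype=float)
    labels = np.zeros(s.size, dtype=int)
    valid = np.isfinite(s)
    c1, c2, c3 = cutoffs
    labels[valid] = 4
    labels[valid & (s <= c3)] = 3
    labels[valid & (s <= c2)] = 2
    labels[valid & (s <= c1)] = 1
    return labels


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate with log-log median 95% CI."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, float), np.asarray(events, int))
    sf = kmf.survival_function_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy()
    median = float(kmf.median_survival_time_)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    return KMCurve(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(),
        at_risk=at_risk,
        median=median,
        median_ci=(lo, hi),
    )


def logrank_test(times, events, groups) -> TestResult:
    """k-sample log-rank test; statistic ~ chi-square on k-1 df."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValidationError("log-rank test needs >= 2 non-empty groups")
    if events.sum() < 1:
        raise ValidationError("log-rank test needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return TestResult(float(res.test_statistic), int(uniq.size - 1), float(res.p_value))


def interaction_test(
    table: pd.DataFrame, scores, ties: str = "breslow", **fit_kwargs
) -> TestResult:
    """LR test (1 df) for a score x treatment interaction.

    Compares Cox models {score, treatment} and {score, treatment,
    score*treatment}; a small p-value means the score performs differently
    under curative vs palliative treatment.
    """
    work = pd.DataFrame(
        {
            "os_months": table["os_months"].to_numpy(dtype=float),
            "event": table["event"].to_numpy(dtype=int),
            "score": np.asarray(scores, dtype=float),
            "treatment": table["treatment"].to_numpy(dtype=float),
        }
    )
    if work["treatment"].nunique() < 2:
        raise ValidationError("both treatment groups must be non-empty")
    work["score_x_treatment"] = work["score"] * work["treatment"]
    base = fit_cox(work, ["score", "treatment"], ties=ties, **fit_kwargs)
    full = fit_cox(work, ["score", "treatment", "score_x_treatment"], ties=ties, **fit_kwargs)
    lr = max(2.0 * (full.loglik - base.loglik), 0.0)
    return TestResult(lr, 1, float(stats.chi2.sf(lr, df=1)))


def aic(fit: CoxFit) -> float:
    """Akaike information criterion: -2 log(L) + 2k."""
    return -2.0 * fit.loglik + 2.0 * fit.k


def compare_models(
    table: pd.DataFrame, ties: str = "breslow", **fit_kwargs
) -> pd.DataFrame:
    """AIC for the three nested models on one complete-case patient set.

    All three fits share the complete cases of the largest variable set, so
    their partial likelihoods (and hence AICs) are directly comparable; the
    lowest AIC marks the preferred model.
    """
    all_vars = list(NESTED_MODELS["clinical+suv+texture"])
    sub = table[all_vars + ["os_months", "event"]].dropna()
    rows = []
    for name, variables in NESTED_MODELS.items():
        fit = fit_cox(sub, variables, ties=ties, **fit_kwargs)
        if fit.n != len(sub):  # pragma: no cover - guarded by shared subset
            raise ValidationError("nested models fitted on differing case sets")
        rows.append(
            {"model": name, "k": fit.k, "loglik": fit.loglik, "aic": aic(fit)}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidationReport:
    """Result of applying a frozen prognostic model to a new cohort."""

    labels: np.ndarray
    n_missing_score: int
    km_by_group: dict[int, KMCurve]
    logrank: TestResult


def validate_model(model: PrognosticModel, table: pd.DataFrame) -> ValidationReport:
    """Score a validation cohort with frozen weights and cutoffs; no refit.

    Patients whose score cannot be computed are flagged and excluded from the
    stratified analysis, with the count reported.
    """
    if model.cutoffs is None:
        raise ValidationError("model has no frozen cutoffs; develop it first")
    scores = prognostic_score(table, model)
    labels = label_by_cutoffs(scores.to_numpy(), model.cutoffs)
    ok = labels > 0
    n_missing = int((~ok).sum())
    km = {
        int(q): km_estimate(
            table.loc[ok & (labels == q), "os_months"],
            table.loc[ok & (labels == q), "event"],
        )
        for q in np.unique(labels[ok])
    }
    lr = logrank_test(
        table.loc[ok, "os_months"], table.loc[ok, "event"], labels[ok]
    )
    return ValidationReport(labels, n_missing, km, lr)
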