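"""Working-independence GEE for the harmonic-seasonal produce-trend model.

The marginal model for household i in study month t is

    logit E[Y_it / n_it] = b0 + bS1 sin(2*pi*t/12) + bS2 cos(2*pi*t/12)
                           + bL t + bX X_i + bXL (X_i * t)

with Y_it produce items out of n_it food items, X_i demographic group
indicators (age, income, or their full interaction) and group-by-time
products carrying group-specific linear trends.  Under a working
independence correlation the estimating equations coincide with the
weighted-logistic normal equations, solved here by iteratively reweighted
least squares; inference uses the cluster-robust empirical sandwich
covariance with households as clusters.

Outcome-scale summaries are linear contrasts mapped through the inverse
logit with delta-method intervals: the baseline percent (fitted percent at
t = 1, i.e. January 2016, seasonal terms included) and the annual change
in percent produce purchased (the 12-month difference of seasonal-free
fitted percents anchored at the study-window midpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .labels import AGE_LABELS, INCOME_LABELS

__all__ = [
    "ModelSpec",
    "Design",
    "FitResult",
    "ContrastResult",
    "build_design",
    "design_row",
    "fit_gee",
    "sandwich_covariance",
    "baseline_percent",
    "annual_change_contrast",
    "fitted_percent_curve",
    "wald_ci",
]

_Z95 = 1.959964
_GROUPINGS = ("none", "age", "income", "age_by_income")


@dataclass(frozen=True)
class ModelSpec:
    """Which demographic grouping the trend model stratifies by.

    ``age_by_income`` fits the full 5 x 6 cell structure (main effects,
    two-way cell interactions, and all group-by-time products), giving
    cell-specific intercepts and slopes with shared seasonal terms.
    """

    grouping: str = "none"
    include_seasonal: bool = True
    include_group_by_time: bool = True
    ref_age: str = AGE_LABELS[0]
    ref_income: str = INCOME_LABELS[0]
    period: int = 12

    def __post_init__(self) -> None:
        if self.grouping not in _GROUPINGS:
            raise ValueError(f"grouping must be one of {_GROUPINGS}")
        if self.ref_age not in AGE_LABELS or self.ref_income not in INCOME_LABELS:
            raise ValueError("reference levels must be collapsed group labels")


@dataclass
class Design:
    """Design matrix with response pairs and cluster labels."""

    X: np.ndarray
    names: list[str]
    y: np.ndarray
    n: np.ndarray
    clusters: np.ndarray
    spec: ModelSpec
    t_max: int


@dataclass
class FitResult:
    """Coefficients and cluster-robust covariance of one model fit."""

    params: np.ndarray
    names: list[str]
    cov: np.ndarray
    model_cov: np.ndarray
    n_clusters: int
    n_rows: int
    iterations: int
    converged: bool
    separation: bool
    spec: ModelSpec
    t_max: int

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.params, "robust_se": self.se},
            index=pd.Index(self.names, name="term"),
        )


@dataclass(frozen=True)
class ContrastResult:
    """An outcome-scale quantity with a 95% CI for one demographic cell."""

    label: str
    quantity: str
    estimate: float
    ci_low: float
    ci_high: float
    se: float

    def __str__(self) -> str:
        return f"{self.estimate:.1f}% (CI {self.ci_low:.1f}; {self.ci_high:.1f})"


def _cell_parts(spec: ModelSpec, cell) -> tuple[str | None, str | None]:
    if cell is None:
        age = income = None
    elif isinstance(cell, str):
        age = cell if spec.grouping == "age" else None
        income = cell if spec.grouping == "income" else None
    else:
        age, income = cell
    if spec.grouping in ("age", "age_by_income"):
        if age not in AGE_LABELS:
            raise KeyError(f"unknown age group {age!r}")
    if spec.grouping in ("income", "age_by_income"):
        if income not in INCOME_LABELS:
            raise KeyError(f"unknown income group {income!r}")
    return age, income


def _design_columns(
    spec: ModelSpec,
    age: np.ndarray,
    income: np.ndarray,
    t: np.ndarray,
    seasonal_on: bool = True,
) -> tuple[np.ndarray, list[str]]:
    n = t.size
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["const"]
    if spec.include_seasonal:
        w = 2 * np.pi * t / spec.period
        scale = 1.0 if seasonal_on else 0.0
        cols += [scale * np.sin(w), scale * np.cos(w)]
        names += ["sin", "cos"]
    cols.append(t.astype(float))
    names.append("t")

    group: list[tuple[str, np.ndarray]] = []
    if spec.grouping in ("age", "age_by_income"):
        for a in AGE_LABELS:
            if a != spec.ref_age:
                group.append((f"age[{a}]", (age == a).astype(float)))
    if spec.grouping in ("income", "age_by_income"):
        for i in INCOME_LABELS:
            if i != spec.ref_income:
                group.append((f"income[{i}]", (income == i).astype(float)))
    if spec.grouping == "age_by_income":
        for a in AGE_LABELS:
            if a == spec.ref_age:
                continue
            am = (age == a).astype(float)
            for i in INCOME_LABELS:
                if i == spec.ref_income:
                    continue
                group.append(
                    (f"age[{a}]:income[{i}]", am * (income == i).astype(float))
                )
    for nm, v in group:
        cols.append(v)
        names.append(nm)
    if spec.include_group_by_time:
        for nm, v in group:
            cols.append(v * t)
            names.append(f"{nm}:t")
    return np.column_stack(cols), names


def build_design(panel: pd.DataFrame, spec: ModelSpec) -> Design:
    """Build the model design from a household-month panel.

    One row per panel row; dummy coding against the spec's reference
    levels with a documented, stable column order (const, sin, cos, t,
    group mains, group-by-time products).
    """
    t = panel["month"].to_numpy(float)
    age = panel.get("age_group", pd.Series([""] * len(panel))).to_numpy(object)
    income = panel.get("income_group", pd.Series([""] * len(panel))).to_numpy(object)
    if spec.grouping in ("age", "age_by_income"):
        unseen = set(age) - set(AGE_LABELS)
        if unseen:
            raise ValueError(f"panel has age labels outside the model: {unseen}")
    if spec.grouping in ("income", "age_by_income"):
        unseen = set(income) - set(INCOME_LABELS)
        if unseen:
            raise ValueError(f"panel has income labels outside the model: {unseen}")
    X, names = _design_columns(spec, age, income, t)
    return Design(
        X=X,
        names=names,
        y=panel["produce"].to_numpy(float),
        n=panel["total"].to_numpy(float),
        clusters=panel["household_id"].to_numpy(),
        spec=spec,
        t_max=int(t.max()),
    )


def design_row(
    spec: ModelSpec, cell, t: float, seasonal: bool = True
) -> np.ndarray:
    """Design vector for one demographic cell at (possibly fractional) time t."""
    age, income = _cell_parts(spec, cell)
    X, _ = _design_columns(
        spec,
        np.array([age], dtype=object),
        np.array([income], dtype=object),
        np.array([float(t)]),
        seasonal_on=seasonal,
    )
    return X[0]


def fit_gee(
    design: Design, max_iter: int = 100, tol: float = 1e-8
) -> FitResult:
    """Solve the working-independence estimating equations by IRLS.

    Deterministic given the input.  Non-convergence within ``max_iter``
    and separation (monotone likelihood; diverging linear predictor or a
    degenerate all-0/all-n response) are flagged on the result rather than
    raised, with the partial estimate returned.
    """
    X, y, n = design.X, design.y, design.n
    if X.shape[0] == 0:
        raise ValueError("empty design")
    separation = bool(y.sum() == 0 or (y == n).all())
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        if np.max(np.abs(eta)) > 30:
            separation = True
            break
        mu = expit(eta)
        w = n * mu * (1 - mu)
        z = eta + (y / n - mu) / (mu * (1 - mu))
        try:
            beta_new = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * z))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular information matrix (collinear design?): {e}"
            ) from e
        delta = np.max(np.abs(beta_new - beta)) / max(1.0, np.max(np.abs(beta)))
        beta = beta_new
        if delta < tol:
            converged = True
            break
    result = FitResult(
        params=beta,
        names=list(design.names),
        cov=np.full((X.shape[1], X.shape[1]), np.nan),
        model_cov=np.full((X.shape[1], X.shape[1]), np.nan),
        n_clusters=len(np.unique(design.clusters)),
        n_rows=X.shape[0],
        iterations=it,
        converged=converged and not separation,
        separation=separation,
        spec=design.spec,
        t_max=design.t_max,
    )
    if result.converged:
        result.cov, result.model_cov = sandwich_covariance(design, beta)
    return result


def sandwich_covariance(
    design: Design, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-robust sandwich A^-1 B A^-1 and the model-based A^-1.

    A is the working-model information X'WX with W = n mu (1-mu); B sums,
    over household clusters, the outer products of the cluster score
    contributions X_c'(y_c - n_c mu_c).  No small-sample correction is
    applied (cluster counts here are thousands and up).
    """
    X, y, n = design.X, design.y, design.n
    mu = expit(X @ beta)
    w = n * mu * (1 - mu)
    A = X.T @ (w[:, None] * X)
    try:
        A_inv = np.linalg.inv(A)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular information matrix: {e}") from e
    resid = y - n * mu
    codes, _ = pd.factorize(design.clusters)
    scores = np.zeros((codes.max() + 1, X.shape[1]))
    np.add.at(scores, codes, X * resid[:, None])
    B = scores.T @ scores
    cov = A_inv @ B @ A_inv
    cov = (cov + cov.T) / 2
    model_cov = (A_inv + A_inv.T) / 2
    return cov, model_cov


def wald_ci(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided 95% Wald interval, estimate +/- 1.959964 * se."""
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    return estimate - _Z95 * se, estimate + _Z95 * se


def _delta_interval(
    fit: FitResult, estimate: float, grad: np.ndarray
) -> tuple[float, float, float]:
    var = float(grad @ fit.cov @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    lo, hi = wald_ci(estimate, se)
    return lo, hi, se


def _require_converged(fit: FitResult) -> None:
    if not fit.converged:
        raise ValueError("model fit did not converge; contrasts unavailable")


def _cell_label(spec: ModelSpec, cell) -> str:
    age, income = _cell_parts(spec, cell)
    return " x ".join(x for x in (age, income) if x is not None) or "overall"


def baseline_percent(
    fit: FitResult, cell=None, t: float = 1.0, include_seasonal: bool = True
) -> ContrastResult:
    """Expected percent produce purchased for a cell at baseline.

    Baseline means t = 1 (January 2016) with seasonal terms included — a
    calendar instant, not a deseasonalised level; pass
    ``include_seasonal=False`` for the latter.  Delta-method CI on the
    percent scale using the robust covariance.
    """
    _require_converged(fit)
    x = design_row(fit.spec, cell, t, seasonal=include_seasonal)
    mu = float(expit(x @ fit.params))
    est = 100.0 * mu
    grad = 100.0 * mu * (1 - mu) * x
    lo, hi, se = _delta_interval(fit, est, grad)
    return ContrastResult(_cell_label(fit.spec, cell), "baseline_percent", est, lo, hi, se)


def annual_change_contrast(fit: FitResult, cell=None) -> ContrastResult:
    """Average annual change in percent produce purchased for a cell.

    The cell's per-month logit slope (bL plus its group-by-time terms) is
    rescaled to the percent-per-year scale as the 12-month difference of
    seasonal-free fitted percents anchored at the study-window midpoint;
    delta-method CI with the robust covariance.
    """
    _require_converged(fit)
    if not (fit.spec.grouping == "none" or fit.spec.include_group_by_time):
        raise ValueError("model lacks group-by-time terms for cell-specific slopes")
    t_mid = (1 + fit.t_max) / 2
    x0 = design_row(fit.spec, cell, t_mid, seasonal=False)
    c = design_row(fit.spec, cell, 1.0, seasonal=False) - design_row(
        fit.spec, cell, 0.0, seasonal=False
    )  # d eta / d t: the cell's per-month slope contrast
    x1 = x0 + 12.0 * c
    mu0 = float(expit(x0 @ fit.params))
    mu1 = float(expit(x1 @ fit.params))
    est = 100.0 * (mu1 - mu0)
    grad = 100.0 * (mu1 * (1 - mu1) * x1 - mu0 * (1 - mu0) * x0)
    lo, hi, se = _delta_interval(fit, est, grad)
    return ContrastResult(
        _cell_label(fit.spec, cell), "annual_change_percent", est, lo, hi, se
    )


def fitted_percent_curve(
    fit: FitResult, cell=None, months: np.ndarray | None = None
) -> pd.DataFrame:
    """Fitted percent produce purchased over study months for one cell."""
    _require_converged(fit)
    if months is None:
        months = np.arange(1, fit.t_max + 1)
    rows = np.vstack([design_row(fit.spec, cell, float(t)) for t in months])
    pct = 100.0 * expit(rows @ fit.params)
    return pd.DataFrame({"month": months, "fitted_percent": pct})
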