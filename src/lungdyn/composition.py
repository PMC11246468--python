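"""Cell-type composition trends over gestational week.

For each cell type, per-sample counts (n_type out of n_total cells) are
modelled as binomial with a logit link and constant, linear, or quadratic
dependence on gestational week. Coefficients carry zero-centred normal
priors with sd 2.5 on the centred, unit-sd week covariate; fits are MAP
(penalised Newton) with Laplace 95% intervals, and the trend family is
selected by exact leave-one-out cross-validation (refit on every n-1
subset, sum of held-out binomial log predictive densities), with a
parsimony margin so a more complex family must beat a simpler one by a
clear score difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .datatypes import LungdynError

FAMILIES = ("constant", "linear", "quadratic")
_NCOEF = {"constant": 1, "linear": 2, "quadratic": 3}


class FitError(LungdynError):
    pass


@dataclass
class CompositionData:
    """Per-sample counts of one focal type."""

    week: np.ndarray
    n_type: np.ndarray
    n_total: np.ndarray

    def __post_init__(self) -> None:
        self.week = np.asarray(self.week, dtype=float)
        self.n_type = np.asarray(self.n_type, dtype=int)
        self.n_total = np.asarray(self.n_total, dtype=int)
        if len(self.week) < 3:
            raise ValueError("composition data needs >= 3 samples")
        if np.any(self.n_type < 0) or np.any(self.n_type > self.n_total):
            raise ValueError("counts must satisfy 0 <= n_type <= n_total")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CompositionData":
        return cls(df["gestational_week"].to_numpy(),
                   df["n_type"].to_numpy(), df["n_total"].to_numpy())

    @property
    def n_samples(self) -> int:
        return len(self.week)


@dataclass
class CompositionFit:
    family: str
    coef: np.ndarray            # on the standardised-week scale
    coef_cov: np.ndarray        # Laplace covariance at the MAP
    prior_sd: float
    center: float               # week standardisation
    scale: float
    loo_score: float
    grid: pd.DataFrame          # gestational_week, p_hat, lo, hi

    def design(self, week: np.ndarray) -> np.ndarray:
        return _design(np.asarray(week, dtype=float), self.family,
                       self.center, self.scale)

    def predict(self, week: np.ndarray) -> np.ndarray:
        return expit(self.design(week) @ self.coef)


def _design(week: np.ndarray, family: str, center: float, scale: float
            ) -> np.ndarray:
    z = (week - center) / scale
    cols = [np.ones_like(z)]
    if family in ("linear", "quadratic"):
        cols.append(z)
    if family == "quadratic":
        cols.append(z ** 2)
    return np.column_stack(cols)


def _map_fit(X: np.ndarray, y: np.ndarray, n: np.ndarray, prior_sd: float,
             max_iter: int = 100, tol: float = 1e-10
             ) -> tuple[np.ndarray, np.ndarray]:
    """Penalised Newton MAP of a binomial-logit model; returns (beta, H)."""
    p_prec = 0.0 if np.isinf(prior_sd) else 1.0 / prior_sd ** 2
    beta = np.zeros(X.shape[1])

    def neg_post(b):
        eta = X @ b
        # log binomial likelihood up to the constant binomial coefficient
        ll = float(y @ eta - n @ np.logaddexp(0.0, eta))
        return -ll + 0.5 * p_prec * float(b @ b)

    f = neg_post(beta)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        grad = X.T @ (y - n * p) - p_prec * beta
        W = n * p * (1 - p)
        H = X.T @ (X * W[:, None]) + p_prec * np.eye(X.shape[1])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as err:
            raise FitError(f"singular Hessian during Newton fit: {err}") from err
        # backtracking line search on the negative log posterior
        t = 1.0
        for _ in range(50):
            cand = beta + t * step
            fc = neg_post(cand)
            if fc <= f + 1e-12:
                break
            t /= 2.0
        else:
            raise FitError("line search failed to improve the posterior")
        moved = np.max(np.abs(cand - beta))
        beta, f = cand, fc
        if moved < tol:
            break
    else:
        raise FitError(f"Newton fit did not converge in {max_iter} iterations "
                       f"(last step {moved:.3g})")
    p = expit(X @ beta)
    W = n * p * (1 - p)
    H = X.T @ (X * W[:, None]) + p_prec * np.eye(X.shape[1])
    return beta, H


def _loo_score(data: CompositionData, family: str, prior_sd: float,
               center: float, scale: float) -> float:
    """Exact refit leave-one-out sum of log predictive densities."""
    X = _design(data.week, family, center, scale)
    total = 0.0
    for i in range(data.n_samples):
        mask = np.ones(data.n_samples, dtype=bool)
        mask[i] = False
        beta, _ = _map_fit(X[mask], data.n_type[mask].astype(float),
                           data.n_total[mask].astype(float), prior_sd)
        p_i = float(expit(X[i] @ beta))
        total += float(stats.binom.logpmf(data.n_type[i], data.n_total[i], p_i))
    return total


def fit_family(data: CompositionData, family: str, prior_sd: float = 2.5,
               gw_grid: np.ndarray | None = None,
               compute_loo: bool = True) -> CompositionFit:
    """MAP fit of one trend family with Laplace intervals and LOO score."""
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "quadratic" and len(np.unique(data.week)) < 4:
        warnings.warn("quadratic fit with < 4 distinct weeks is weakly identified")
    center = float(data.week.mean())
    scale = float(data.week.std())
    if scale == 0:
        scale = 1.0
        warnings.warn("all samples share one gestational week; slope unidentified")
    X = _design(data.week, family, center, scale)
    beta, H = _map_fit(X, data.n_type.astype(float), data.n_total.astype(float),
                       prior_sd)
    cov = np.linalg.inv(H)
    if gw_grid is None:
        gw_grid = np.arange(data.week.min(), data.week.max() + 1)
    Xg = _design(np.asarray(gw_grid, dtype=float), family, center, scale)
    eta = Xg @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", Xg, cov, Xg))
    grid = pd.DataFrame({
        "gestational_week": gw_grid,
        "p_hat": expit(eta),
        "lo": expit(eta - 1.96 * se),
        "hi": expit(eta + 1.96 * se)})
    loo = _loo_score(data, family, prior_sd, center, scale) if compute_loo \
        else float("nan")
    return CompositionFit(family, beta, cov, prior_sd, center, scale, loo, grid)


@dataclass
class ModelSelection:
    best_family: str
    fits: dict[str, CompositionFit]
    margin: float

    @property
    def best(self) -> CompositionFit:
        return self.fits[self.best_family]

    def loo_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "family": list(self.fits),
            "loo_score": [f.loo_score for f in self.fits.values()]})


def select_model(data: CompositionData, prior_sd: float = 2.5,
                 margin: float = 0.5) -> ModelSelection:
    """Fit all three families and pick one by LOO with a parsimony margin.

    The winner is the simplest family whose LOO score is within ``margin``
    (log-density units) of the best score; a more complex family must
    therefore beat every simpler one by more than the margin. Families whose
    LOO refits fail are disqualified with a warning.
    """
    fits: dict[str, CompositionFit] = {}
    for fam in FAMILIES:
        try:
            fits[fam] = fit_family(data, fam, prior_sd=prior_sd)
        except FitError as err:
            warnings.warn(f"family {fam!r} disqualified: {err}")
    if not fits:
        raise FitError("no composition family could be fitted")
    best_score = max(f.loo_score for f in fits.values())
    for fam in FAMILIES:  # ordered simple -> complex
        if fam in fits and fits[fam].loo_score >= best_score - margin:
            return ModelSelection(fam, fits, margin)
    raise AssertionError("unreachable: some family attains the best score")


def fit_all_types(counts_by_sample: pd.DataFrame, prior_sd: float = 2.5,
                  margin: float = 0.5) -> pd.DataFrame:
    """Model selection per cell type from a long table.

    Expects columns (sample_id, gestational_week, type, count, total);
    returns one row per type with the selected family, standardised-scale
    coefficients and LOO scores.
    """
    rows = []
    for ctype, sub in counts_by_sample.groupby("type", sort=True):
        data = CompositionData(sub["gestational_week"].to_numpy(),
                               sub["count"].to_numpy(), sub["total"].to_numpy())
        sel = select_model(data, prior_sd=prior_sd, margin=margin)
        coef = np.zeros(3)
        coef[: len(sel.best.coef)] = sel.best.coef
        rows.append({
            "type": ctype, "family": sel.best_family,
            "beta0": coef[0], "beta1": coef[1], "beta2": coef[2],
            **{f"loo_{fam}": sel.fits[fam].loo_score if fam in sel.fits
               else np.nan for fam in FAMILIES}})
    return pd.DataFrame(rows)
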