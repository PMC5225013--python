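"""Jackknife (leave-one-out) generalization error and pseudo-value inference.

The search's fitness is not the training error: each model is scored by the
leave-one-out cross-validation error

    GE_JK = sum_i g( yhat_i^(-i) - y_i )

where ``yhat_i^(-i)`` is the prediction for observation ``i`` by the model
refit on the N-1 remaining observations, and ``g`` is the squared (default,
matching the L2 objective) or absolute residual.  The same N refits give the
pseudo-value parameter estimates

    pv_{i,k}   = N * beta_k^MSE - (N - 1) * beta_{i,k}
    beta*_k    = mean_i pv_{i,k}
    se(beta*)  = sqrt( sum_i (pv_{i,k} - beta*_k)^2 / (N (N - 1)) )

with confidence intervals ``beta* +- t_{alpha, N-k} * se`` and two-sided
t-tests of ``beta* = 0`` on ``N - k`` degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import UptakeDataset
from .exceptions import FitError, InsufficientDataError
from .fitting import ArrayDataset, FitResult, PredictiveModel, fit

__all__ = ["JackknifeReport", "jackknife", "fitness", "WORST_FITNESS"]

#: Sentinel fitness for models that are non-finite on the data.
WORST_FITNESS = float("inf")


@dataclass
class JackknifeReport:
    mse_jk: float
    beta_mse: np.ndarray
    beta_star: np.ndarray
    se_star: np.ndarray
    ci_halfwidth: np.ndarray
    p_values: np.ndarray
    replications: np.ndarray          # (N, k) beta_{i,k}
    loo_predictions: np.ndarray       # yhat_i^(-i)
    t_crit: float
    alpha: float
    dof: int
    param_names: tuple
    objective: str
    failed_iterations: list = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        """Parameter table shaped like a published jackknife summary."""
        return pd.DataFrame({
            "parameter": list(self.param_names),
            "beta_mse": self.beta_mse,
            "beta_star": self.beta_star,
            "se": self.se_star,
            "ci_halfwidth": self.ci_halfwidth,
            "p_value": self.p_values,
        })


def jackknife(model: PredictiveModel, dataset: UptakeDataset,
              objective: str = "l2", aggregation: str | None = None,
              alpha: float = 0.05, restarts: int = 5,
              rng: np.random.Generator | None = None,
              fit_result: FitResult | None = None,
              max_nfev: int | None = None) -> JackknifeReport:
    """Run the full leave-one-out analysis for one model.

    ``aggregation`` chooses how held-out residuals combine into the
    generalization error (``"l2"``: squared, ``"l1"``: absolute); by default
    it follows ``objective``.  Each leave-one-out refit warm-starts from the
    full-data optimum and falls back to perturbed restarts on failure.
    """
    dataset = ArrayDataset.from_dataset(dataset)
    k = model.n_params
    N = dataset.n
    if N <= k:
        raise InsufficientDataError(
            f"need more observations ({N}) than parameters ({k})")
    aggregation = aggregation or objective
    rng = rng or np.random.default_rng()

    if fit_result is None:
        fit_result = fit(model, dataset, objective=objective,
                         restarts=restarts, rng=rng, max_nfev=max_nfev)
    beta_mse = np.asarray(fit_result.beta_mse, float)

    replications = np.empty((N, k))
    loo_pred = np.empty(N)
    failed: list[int] = []

    class _Warm(PredictiveModel):
        def __init__(self):
            self.param_names = model.param_names
            self.beta0 = beta_mse
        def predict(self, beta, c0, t):
            return model.predict(beta, c0, t)

    warm = _Warm()
    for i in range(N):
        subset = dataset.drop_row(i) if k > 0 else None
        if k == 0:
            beta_i = beta_mse
        else:
            try:
                res_i = fit(warm, subset, objective=objective, restarts=0,
                            rng=rng, max_nfev=max_nfev)
            except FitError:
                res_i = None
            if res_i is None:
                try:
                    res_i = fit(model, subset, objective=objective,
                                restarts=restarts, rng=rng,
                                max_nfev=max_nfev)
                except FitError:
                    failed.append(i)
                    replications[i] = np.nan
                    loo_pred[i] = np.nan
                    continue
            beta_i = res_i.beta_mse
        replications[i] = beta_i
        loo_pred[i] = float(np.asarray(
            model.predict(beta_i, dataset.c0[i], dataset.t[i])))

    with np.errstate(all="ignore"):
        err = loo_pred - dataset.y
        finite = np.isfinite(err)
        if aggregation == "l2":
            mse_jk = (float(np.sum(err[finite] ** 2)) if finite.any()
                      else WORST_FITNESS)
        else:
            mse_jk = (float(np.sum(np.abs(err[finite]))) if finite.any()
                      else WORST_FITNESS)
        if not np.isfinite(mse_jk):
            mse_jk = WORST_FITNESS
    if not finite.all():
        mse_jk = WORST_FITNESS  # any non-finite held-out prediction disqualifies

    dof = N - k
    t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, dof))
    if k:
        pv = N * beta_mse[None, :] - (N - 1) * replications
        ok = np.isfinite(pv).all(axis=1)
        pv_ok = pv[ok]
        n_ok = len(pv_ok)
        beta_star = pv_ok.mean(axis=0) if n_ok else np.full(k, np.nan)
        if n_ok > 1:
            se = np.sqrt(np.sum((pv_ok - beta_star) ** 2, axis=0)
                         / (n_ok * (n_ok - 1)))
        else:
            se = np.zeros(k)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, beta_star / se, np.inf * np.sign(beta_star))
        p = 2.0 * stats.t.sf(np.abs(tstat), dof)
        p = np.where((se == 0) & (beta_star == 0), 1.0, p)
    else:
        beta_star = np.zeros(0)
        se = np.zeros(0)
        p = np.zeros(0)

    return JackknifeReport(
        mse_jk=mse_jk, beta_mse=beta_mse, beta_star=beta_star, se_star=se,
        ci_halfwidth=t_crit * se, p_values=p, replications=replications,
        loo_predictions=loo_pred, t_crit=t_crit, alpha=alpha, dof=dof,
        param_names=tuple(model.param_names), objective=aggregation,
        failed_iterations=failed)


def fitness(model: PredictiveModel, dataset: UptakeDataset,
            objective: str = "l2", **kwargs) -> float:
    """Jackknife generalization error as a scalar fitness (lower is better).

    Non-finite models receive the worst-rank sentinel instead of raising, so
    a population evaluation never aborts.
    """
    try:
        return jackknife(model, dataset, objective=objective, **kwargs).mse_jk
    except (FitError, InsufficientDataError):
        return WORST_FITNESS
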