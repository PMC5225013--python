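"""Lamarckian parameter refitting: local optimization of lifted constants.

Every candidate expression has its numeric constants lifted to a parameter
vector ``beta`` and refit to the training data before its fitness is judged;
the improved constants are written back into the genotype (the "Lamarckian"
step of the search).  Two objective forms are supported:

* ``"l2"`` -- sum of squared residuals (default),
* ``"l1"`` -- sum of absolute residuals.

Both are exposed because the field's conventions genuinely differ here and
the choice changes fitted parameters for asymmetric noise; see
``docs/methods.md``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from . import expressions as ex
from .exceptions import FitError

__all__ = ["PredictiveModel", "TreeModel", "ArrayDataset", "FitResult",
           "fit", "objective_value"]

# Residual sentinel for non-finite predictions: large enough to dominate any
# physical residual, small enough that squares / finite-difference Jacobians
# stay inside float64.
_BIG = 1e20


class ArrayDataset:
    """Lightweight (c0, t, y) view used in hot loops (leave-one-out refits).

    Exposes the same ``c0``/``t``/``y``/``n``/``drop_row`` surface as
    :class:`~gpkin.datasets.UptakeDataset` without table validation costs.
    """

    __slots__ = ("c0", "t", "y")

    def __init__(self, c0, t, y):
        self.c0 = np.asarray(c0, float)
        self.t = np.asarray(t, float)
        self.y = np.asarray(y, float)

    @classmethod
    def from_dataset(cls, dataset) -> "ArrayDataset":
        return cls(dataset.c0, dataset.t, dataset.y)

    @property
    def n(self) -> int:
        return self.y.size

    def drop_row(self, i: int) -> "ArrayDataset":
        return ArrayDataset(np.delete(self.c0, i), np.delete(self.t, i),
                            np.delete(self.y, i))


class PredictiveModel:
    """Minimal protocol for anything the fitter / jackknife can handle.

    Subclasses define ``param_names``, a default start vector ``beta0``, and
    ``predict(beta, c0, t)`` returning predictions in the dataset's units.
    """

    param_names: Sequence[str] = ()
    beta0: np.ndarray = np.zeros(0)

    def predict(self, beta, c0, t) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return len(self.param_names)


class TreeModel(PredictiveModel):
    """An expression tree with its constants lifted to parameters.

    ``tree`` may already carry parameter slots (then ``beta0`` must be
    given), or be a plain constant-bearing tree (then it is parameterized
    here and the original constants become the start vector).
    """

    def __init__(self, tree: ex.Node, beta0=None):
        names = ex.param_names(tree)
        if names and beta0 is None:
            raise ValueError("tree has parameter slots; beta0 is required")
        if not names and beta0 is None:
            tree, beta0 = ex.parameterize(tree)
            names = ex.param_names(tree)
        self.tree = tree
        self.param_names = list(names)
        self.beta0 = np.asarray(list(beta0), dtype=float)
        if len(self.beta0) != len(self.param_names):
            raise ValueError("beta0 length does not match parameter slots")
        self._fn = ex.compile_evaluator(tree, self.param_names)

    def predict(self, beta, c0, t):
        out = self._fn(np.asarray(c0, float), np.asarray(t, float),
                       np.asarray(beta, float))
        return np.broadcast_to(np.asarray(out, float),
                               np.broadcast(np.asarray(c0),
                                            np.asarray(t)).shape)

    def with_constants(self, beta) -> ex.Node:
        """The genotype with fitted constants written back (Lamarckian)."""
        return ex.substitute(self.tree, dict(zip(self.param_names, beta)))


@dataclass
class FitResult:
    beta_mse: np.ndarray
    objective_value: float
    converged: bool
    n_restarts_used: int
    objective: str = "l2"
    param_names: tuple = ()


def _residuals(model: PredictiveModel, dataset, beta):
    with np.errstate(all="ignore"):
        pred = model.predict(beta, dataset.c0, dataset.t)
        res = np.asarray(pred, float) - dataset.y
    bad = ~np.isfinite(res)
    if bad.any():
        res = np.where(bad, _BIG, res)
    return res


def objective_value(model: PredictiveModel, dataset, beta,
                    objective: str = "l2") -> float:
    res = _residuals(model, dataset, beta)
    with np.errstate(all="ignore"):
        if objective == "l2":
            return float(np.dot(res, res))
        if objective == "l1":
            return float(np.sum(np.abs(res)))
    raise ValueError(f"unknown objective {objective!r}")


def _local_fit(model, dataset, start, objective, max_nfev):
    k, m = len(start), dataset.n
    resid = lambda b: _residuals(model, dataset, b)
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        if objective == "l2":
            try:
                if m > k:
                    x, _, info, _, ier = optimize.leastsq(
                        resid, start, full_output=True,
                        maxfev=(max_nfev or 200) * (k + 1),
                        ftol=1e-12, xtol=1e-10)
                    fvec = info["fvec"]
                    return x, float(np.dot(fvec, fvec)), ier in (1, 2, 3, 4)
                sol = optimize.least_squares(
                    resid, start, method="trf", ftol=1e-12, xtol=1e-10,
                    gtol=1e-12, max_nfev=max_nfev)
                return (sol.x, float(np.dot(sol.fun, sol.fun)),
                        bool(sol.status > 0))
            except Exception:
                return None
        sol = optimize.minimize(
            lambda b: float(np.sum(np.abs(resid(b)))), start,
            method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-8,
                     "maxfev": (max_nfev or 400) * (k + 1)})
        return sol.x, float(sol.fun), bool(sol.success)


def fit(model: PredictiveModel, dataset,
        objective: str = "l2", restarts: int = 5,
        rng: np.random.Generator | None = None,
        max_nfev: int | None = None) -> FitResult:
    """Minimize the configured objective over ``beta``.

    Optimization starts from the model's own start vector (a tree's original
    constants) plus ``restarts`` log-uniformly perturbed starts; the best
    local optimum wins.  With zero parameter slots the fixed model's
    objective is returned directly.  Raises :class:`FitError` when every
    start is non-finite.
    """
    if objective not in ("l2", "l1"):
        raise ValueError(f"unknown objective {objective!r}")
    beta0 = np.asarray(model.beta0, dtype=float)
    if beta0.size == 0:
        val = objective_value(model, dataset, beta0, objective)
        return FitResult(beta0, val, True, 0, objective,
                         tuple(model.param_names))
    rng = rng or np.random.default_rng()

    starts = [beta0]
    for _ in range(restarts):
        scale = 10.0 ** rng.uniform(-1.0, 1.0, size=beta0.size)
        jitter = np.where(beta0 == 0.0, rng.normal(0.0, 1.0, beta0.size),
                          beta0 * scale)
        starts.append(jitter)

    best = None
    used = 0
    for idx, start in enumerate(starts):
        out = _local_fit(model, dataset, start, objective, max_nfev)
        if out is None:
            continue
        beta, val, ok = out
        if not np.isfinite(val):
            continue
        if best is None or val < best[1]:
            best = (beta, val, ok)
            used = idx
    if best is None:
        raise FitError("no optimization start yielded a finite objective")
    beta, val, ok = best
    # never report worse than the unfitted start
    val0 = objective_value(model, dataset, beta0, objective)
    if np.isfinite(val0) and val0 < val:
        beta, val, ok = beta0, val0, True
    return FitResult(np.asarray(beta, float), val, ok, used, objective,
                     tuple(model.param_names))
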