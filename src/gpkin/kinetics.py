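"""Michaelis-Menten and Hill transport baselines.

The saturable-carrier rate law, referred to the cellular+basolateral
compartment, is

    d[Fe_in]/dt = Vmax * C^n / (Km^n + C^n) * (Va / Vcb) + b        [uM/min]

with ``n = 1`` for Michaelis-Menten.  ``Va`` (apical volume, 200 uL) and
``Vcb`` (cellular + basolateral volume, 1000 uL) rescale the rate because
transported iron dilutes into a different volume than it left.  ``b`` is an
optional additive basal-leak rate, 0 by default.

Because apical depletion is negligible over the 15-min assays, the substrate
concentration is held at its initial value ``C0`` and the uptake curve is
linear in time:

    uptake(C0, t) = rate(C0) * t * Vcb        [pmol/insert]

(1 uM in 1000 uL is 1000 pmol).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import (APICAL_VOLUME_UL, CELL_BASOLATERAL_VOLUME_UL,
                       UptakeDataset)
from .exceptions import ValidationError
from .fitting import FitResult, PredictiveModel, fit
from .jackknife import JackknifeReport, jackknife

__all__ = ["KineticModel", "KineticVariantModel", "fit_variant",
           "MichaelisMentenRegressor", "HillRegressor", "VARIANTS"]


@dataclass(frozen=True)
class KineticModel:
    """A fully specified saturable-transport model."""

    km: float                      # Michaelis constant [uM]
    vmax: float                    # maximum velocity [uM/min]
    n: float = 1.0                 # Hill coefficient (1 = MM)
    v_apical: float = APICAL_VOLUME_UL
    v_cb: float = CELL_BASOLATERAL_VOLUME_UL
    b: float = 0.0                 # basal rate offset [uM/min]

    def __post_init__(self):
        if self.km <= 0:
            raise ValidationError("km must be > 0")
        if self.vmax < 0:
            raise ValidationError("vmax must be >= 0")
        if self.n <= 0:
            raise ValidationError("Hill coefficient must be > 0")
        if self.v_apical <= 0 or self.v_cb <= 0:
            raise ValidationError("volumes must be > 0")

    def rate(self, c_out):
        """Transport rate [uM/min] at apical concentration ``c_out`` [uM]."""
        c = np.asarray(c_out, dtype=float)
        cn = c ** self.n
        return (self.vmax * cn / (self.km ** self.n + cn)
                * (self.v_apical / self.v_cb) + self.b)

    def uptake(self, c0, t):
        """Apical uptake [pmol/insert]: constant-substrate integration."""
        return self.rate(c0) * np.asarray(t, dtype=float) * self.v_cb


class KineticVariantModel(PredictiveModel):
    """Adapter exposing a kinetic model's *free* parameters to the fitter.

    ``free`` lists which of ``("km", "vmax", "n")`` are optimized; the rest
    are pinned at ``fixed`` values.  ``kind`` selects the prediction units:
    uptake (pmol/insert, needs c0 and t) or rate (uM/min).
    """

    _STARTS = {"km": 10.0, "vmax": 1e-2, "n": 1.0}

    def __init__(self, free: Sequence[str], fixed: dict | None = None,
                 kind: str = "uptake",
                 v_apical: float = APICAL_VOLUME_UL,
                 v_cb: float = CELL_BASOLATERAL_VOLUME_UL,
                 b: float = 0.0):
        unknown = set(free) - {"km", "vmax", "n"}
        if unknown:
            raise ValueError(f"unknown free parameters {sorted(unknown)}")
        self.free = tuple(free)
        self.fixed = dict(fixed or {})
        self.kind = kind
        self.v_apical, self.v_cb, self.b = v_apical, v_cb, b
        self.param_names = list(self.free)
        self.beta0 = np.array([self.fixed.get(p, self._STARTS[p])
                               for p in self.free], dtype=float)

    def _model(self, beta) -> KineticModel | None:
        values = {"n": 1.0, **self.fixed,
                  **dict(zip(self.free, np.asarray(beta, float)))}
        try:
            return KineticModel(km=values["km"], vmax=values["vmax"],
                                n=values["n"], v_apical=self.v_apical,
                                v_cb=self.v_cb, b=self.b)
        except ValidationError:
            return None

    def predict(self, beta, c0, t):
        model = self._model(beta)
        if model is None:
            shape = np.broadcast(np.asarray(c0), np.asarray(t)).shape
            return np.full(shape if shape else (), np.nan)
        if self.kind == "rate":
            return model.rate(c0)
        return model.uptake(c0, t)


#: The four fitting variants compared against the symbolic search.
VARIANTS = {
    "mm_fit": dict(free=("km", "vmax")),
    "mm_linder": dict(free=("vmax",), fixed={"km": 7.0}),
    "mm_exp": dict(free=("vmax",)),        # km fixed at a measured value
    "hill": dict(free=("km", "vmax", "n")),
}


def fit_variant(dataset: UptakeDataset, variant: str,
                fixed: dict | None = None, objective: str = "l2",
                restarts: int = 5, rng: np.random.Generator | None = None,
                ) -> tuple[KineticModel, FitResult, JackknifeReport]:
    """Fit one named variant and jackknife its free parameters.

    ``fixed`` supplies / overrides pinned values (e.g. ``{"km": 10.36}`` for
    the ``mm_exp`` variant, where Km comes from an initial-rate experiment).
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {sorted(VARIANTS)}")
    spec = VARIANTS[variant]
    fixed_all = {**spec.get("fixed", {}), **(fixed or {})}
    if variant == "mm_exp" and "km" not in fixed_all:
        raise ValueError("mm_exp requires fixed={'km': <measured value>}")
    adapter = KineticVariantModel(spec["free"], fixed=fixed_all,
                                  kind=dataset.kind)
    rng = rng or np.random.default_rng()
    res = fit(adapter, dataset, objective=objective, restarts=restarts,
              rng=rng)
    report = jackknife(adapter, dataset, objective=objective,
                       restarts=restarts, rng=rng, fit_result=res)
    model = adapter._model(res.beta_mse)
    return model, res, report


# ---------------------------------------------------------------------------
# sklearn estimators
# ---------------------------------------------------------------------------

class _KineticRegressorBase(RegressorMixin, BaseEstimator):
    """Shared fit/predict plumbing for the MM and Hill estimators.

    ``X`` is ``(n_samples, 2)`` with columns ``(c0 [uM], t [min])``; ``y``
    is uptake in pmol/insert (``kind="uptake"``) or rate in uM/min
    (``kind="rate"``, where the time column is ignored).
    """

    _free: tuple = ()

    def __init__(self, km=None, vmax=None, kind="uptake", objective="l2",
                 restarts=5, random_state=None):
        self.km = km
        self.vmax = vmax
        self.kind = kind
        self.objective = objective
        self.restarts = restarts
        self.random_state = random_state

    def _fixed(self) -> dict:
        return {p: getattr(self, p) for p in ("km", "vmax")
                if getattr(self, p) is not None}

    def _free_params(self) -> tuple:
        return tuple(p for p in self._free if getattr(self, p, None) is None)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must have two columns: (c0, t)")
        frame = pd.DataFrame({
            "c0_uM": X[:, 0], "t_min": X[:, 1], "value": y,
            "replicate": np.ones(len(y), dtype=int)})
        dataset = UptakeDataset(frame, kind=self.kind)
        adapter = KineticVariantModel(self._free_params(),
                                      fixed=self._fixed(), kind=self.kind)
        rng = np.random.default_rng(self.random_state)
        res = fit(adapter, dataset, objective=self.objective,
                  restarts=self.restarts, rng=rng)
        self.fit_result_ = res
        self.jackknife_ = jackknife(adapter, dataset,
                                    objective=self.objective,
                                    restarts=self.restarts, rng=rng,
                                    fit_result=res)
        self.model_ = adapter._model(res.beta_mse)
        self.km_ = self.model_.km
        self.vmax_ = self.model_.vmax
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if self.kind == "rate":
            return self.model_.rate(X[:, 0])
        return self.model_.uptake(X[:, 0], X[:, 1])


class MichaelisMentenRegressor(_KineticRegressorBase):
    """Michaelis-Menten transport fit; fix ``km``/``vmax`` to pin them."""

    _free = ("km", "vmax")


class HillRegressor(_KineticRegressorBase):
    """Hill transport fit with free cooperativity ``n`` (unless fixed)."""

    _free = ("km", "vmax", "n")

    def __init__(self, km=None, vmax=None, n=None, kind="uptake",
                 objective="l2", restarts=5, random_state=None):
        super().__init__(km=km, vmax=vmax, kind=kind, objective=objective,
                         restarts=restarts, random_state=random_state)
        self.n = n

    def _fixed(self):
        fixed = super()._fixed()
        if self.n is not None:
            fixed["n"] = self.n
        return fixed

    def fit(self, X, y):
        super().fit(X, y)
        self.hill_n_ = self.model_.n
        return self
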