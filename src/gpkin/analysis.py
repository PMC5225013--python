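"""Model assessment, curation, term decomposition, and domain scanning.

This module hosts everything that happens *after* the search: scoring
candidate models (R^2, AICc, generalization error), discarding candidates
that misbehave inside the experimental domain, picking the best survivor,
splitting a model into additive components to weigh their contributions,
and scanning the initial-rate curve outside the measured concentration
range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy import optimize

from . import expressions as ex
from .datasets import CELL_BASOLATERAL_VOLUME_UL, UptakeDataset
from .exceptions import (DecompositionError, NoModelError,
                         UndefinedRSquaredError)

__all__ = ["r_squared", "aicc", "AssessmentReport", "assess",
           "CurationRules", "CandidateVerdict", "curate", "select_best",
           "Component", "DecompositionReport", "decompose",
           "DomainScanResult", "domain_scan"]


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------

def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SSE/SST``; may be negative.

    SST is taken about the mean of the observations, so a model worse than
    the constant mean predictor scores below zero.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must share a length >= 2")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0.0:
        raise UndefinedRSquaredError("observations are all identical")
    sse = float(np.sum((obs - pred) ** 2))
    return 1.0 - sse / sst


def aicc(observed, predicted, n_params: int) -> float:
    """Small-sample corrected Akaike criterion, least-squares form:

        AICc = N ln(SSE/N) + 2k + 2k(k+1)/(N-k-1)

    Comparable only within a cohort scored by this same formula.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    n = obs.size
    k = int(n_params)
    if n - k - 1 <= 0:
        raise ValueError("AICc needs N - k - 1 > 0")
    sse = float(np.sum((obs - pred) ** 2))
    return n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class AssessmentReport:
    r2_train: float
    r2_test: float | None
    aicc_train: float
    aicc_test: float | None
    ge: float | None
    n_params: int


def assess(predict_train, train: UptakeDataset, predict_test=None,
           test: UptakeDataset | None = None, n_params: int = 0,
           ge: float | None = None) -> AssessmentReport:
    """Score one model on the training table and optionally a test table.

    ``predict_train``/``predict_test`` are callables ``(c0, t) -> value`` in
    each table's units.
    """
    yhat = np.asarray(predict_train(train.c0, train.t), float)
    report = AssessmentReport(
        r2_train=r_squared(train.y, yhat),
        r2_test=None,
        aicc_train=aicc(train.y, yhat, n_params),
        aicc_test=None, ge=ge, n_params=n_params)
    if test is not None:
        fn = predict_test or predict_train
        yhat_t = np.asarray(fn(test.c0, test.t), float)
        report.r2_test = r_squared(test.y, yhat_t)
        report.aicc_test = aicc(test.y, yhat_t, n_params)
    return report


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CurationRules:
    """Screening rules applied to every candidate on a declared domain grid.

    * ``min_r2`` -- training R^2 must reach the threshold (default 0.8);
    * ``nonnegativity`` -- predicted uptake must be >= 0 on the grid
      (negative transported amounts contradict the assay);
    * ``singularity`` -- the model must be finite on the grid (models whose
      expressions blow up inside the domain are discarded rather than
      "protected" during evaluation).

    The grid covers t in [t_range] step ``grid_step``, C0 in [c0_range] step
    ``grid_step``, plus ``n_random_probes`` uniform interior points drawn
    from ``seed``.
    """

    min_r2: float = 0.8
    c0_range: tuple = (0.0, 20.0)
    t_range: tuple = (0.0, 15.0)
    grid_step: float = 0.1
    n_random_probes: int = 10_000
    seed: int = 0

    def probe_points(self) -> tuple[np.ndarray, np.ndarray]:
        c0 = np.arange(self.c0_range[0], self.c0_range[1] + 1e-9,
                       self.grid_step)
        t = np.arange(self.t_range[0], self.t_range[1] + 1e-9,
                      self.grid_step)
        c0g, tg = np.meshgrid(c0, t, indexing="ij")
        pts_c0, pts_t = [c0g.ravel()], [tg.ravel()]
        if self.n_random_probes:
            rng = np.random.default_rng(self.seed)
            pts_c0.append(rng.uniform(*self.c0_range, self.n_random_probes))
            pts_t.append(rng.uniform(*self.t_range, self.n_random_probes))
        return np.concatenate(pts_c0), np.concatenate(pts_t)


@dataclass
class CandidateVerdict:
    index: int
    passed: bool
    first_violation: str | None = None


def curate(candidates, rules: CurationRules | None = None,
           data: UptakeDataset | None = None):
    """Screen candidates; returns ``(survivors, verdicts)``.

    Each candidate is ``(tree, beta, r2_train)`` or an object with
    ``tree``/``beta``/``r2_train`` attributes (``r2_train`` may be None to
    recompute from ``data``).  Verdicts state the first violated rule, in
    the order min_r2, singularity, nonnegativity.
    """
    rules = rules or CurationRules()
    c0p, tp = rules.probe_points()
    survivors, verdicts = [], []
    for idx, cand in enumerate(candidates):
        tree, beta, r2 = _unpack_candidate(cand)
        if r2 is None:
            if data is None:
                raise ValueError("r2_train missing and no data provided")
            yhat = ex.evaluate(tree, data.c0, data.t, beta)
            r2 = (r_squared(data.y, yhat)
                  if np.isfinite(yhat).all() else -np.inf)
        violation = None
        if r2 < rules.min_r2:
            violation = "min_r2"
        else:
            vals = ex.evaluate(tree, c0p, tp, beta)
            if not np.isfinite(vals).all():
                violation = "singularity"
            elif (vals < 0).any():
                violation = "nonnegativity"
        verdicts.append(CandidateVerdict(idx, violation is None, violation))
        if violation is None:
            survivors.append(cand)
    return survivors, verdicts


def _unpack_candidate(cand):
    if isinstance(cand, tuple):
        tree, beta, r2 = (list(cand) + [None])[:3]
        return tree, beta, r2
    return cand.tree, getattr(cand, "beta", None), getattr(cand, "r2_train",
                                                           None)


def select_best(candidates, ges=None, r2s=None, n_params=None,
                criterion: str = "min_ge") -> int:
    """Index of the selected model among ``candidates``.

    ``criterion="min_ge"`` minimizes the generalization error;
    ``"max_r2_train"`` maximizes training R^2.  Ties break toward higher
    training R^2 (respectively lower GE), then fewer parameters, then the
    earliest candidate.
    """
    n = len(candidates)
    if n == 0:
        raise NoModelError("no surviving candidates")
    ges = np.asarray(ges if ges is not None else np.zeros(n), float)
    r2s = np.asarray(r2s if r2s is not None else np.zeros(n), float)
    ks = np.asarray(n_params if n_params is not None else np.zeros(n), float)
    if criterion == "min_ge":
        keys = list(zip(ges, -r2s, ks, range(n)))
    elif criterion == "max_r2_train":
        keys = list(zip(-r2s, ges, ks, range(n)))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return min(range(n), key=lambda i: keys[i])


# ---------------------------------------------------------------------------
# Additive decomposition
# ---------------------------------------------------------------------------

@dataclass
class Component:
    label: str
    expr: "sp.Expr"

    def __call__(self, x, dps: int = 50) -> float:
        free = list(self.expr.free_symbols)
        if not free:
            return float(sp.N(self.expr, dps))
        return float(sp.N(self.expr.subs(free[0],
                                         sp.Rational(repr(float(x)))), dps))


@dataclass
class DecompositionReport:
    """Additive split of a model after fixing one variable.

    Component values are evaluated in arbitrary precision (printed decimal
    constants treated as exact) because symbolic models routinely nest huge
    arguments inside ``sin``/``cos``, where float64 argument reduction is
    meaningless; see docs/methods.md.
    """

    fixed_var: str
    fixed_value: float
    free_var: str
    components: list = field(default_factory=list)
    dps: int = 50

    def total(self, x) -> float:
        return float(sum(c(x, self.dps) for c in self.components))

    def values(self, x) -> dict[str, float]:
        return {c.label: c(x, self.dps) for c in self.components}

    def shares(self, x) -> dict[str, float]:
        """|component| / |total| at the query point (fractions)."""
        vals = self.values(x)
        tot = abs(sum(vals.values()))
        if tot == 0.0:
            raise DecompositionError("total is zero at the query point")
        return {k: abs(v) / tot for k, v in vals.items()}

    def coefficients(self) -> dict[str, "sp.Expr"]:
        """Lumped coefficient of each component after factoring out the
        free variable's monomial, when the component has that shape."""
        x = sp.Symbol(self.free_var)
        out = {}
        for c in self.components:
            poly_part = c.expr
            coeff = sp.simplify(poly_part / x ** sp.degree(poly_part, x)) \
                if poly_part.is_polynomial(x) else None
            out[c.label] = coeff
        return out


def _classify(term: "sp.Expr", x: "sp.Symbol") -> str:
    if term.has(sp.sin) or term.has(sp.cos):
        # oscillatory only if the trig argument involves the free variable
        for f in term.atoms(sp.sin, sp.cos):
            if x in f.free_symbols:
                return "sinusoidal"
    if term.is_polynomial(x):
        deg = sp.degree(term, x)
        return {0: "constant", 1: "linear", 2: "quadratic"}.get(
            int(deg), f"degree-{deg}")
    if term.has(sp.exp) or (term.has(sp.Pow) and any(
            x in p.exp.free_symbols for p in term.atoms(sp.Pow))):
        return "exponential"
    return "other"


def decompose(tree: ex.Node, beta, fixed_var: str, fixed_value: float,
              dps: int = 50) -> DecompositionReport:
    """Split a model into additive components of the remaining variable.

    The tree (with ``beta`` substituted) is converted to an exact symbolic
    expression, the fixed variable is pinned, products are expanded over
    sums, and the top-level additive terms become labelled components whose
    values sum to the full model at every query point.
    """
    if fixed_var not in ex.VARIABLES:
        raise ValueError(f"fixed_var must be one of {ex.VARIABLES}")
    free_var = "t" if fixed_var == "C0" else "C0"
    expr = ex.to_sympy(tree, beta=beta, exact_constants=True)
    expr = expr.subs(sp.Symbol(fixed_var),
                     sp.Rational(repr(float(fixed_value))))
    x = sp.Symbol(free_var)
    try:
        expanded = sp.expand(expr)
    except Exception as err:  # pragma: no cover - sympy internals
        raise DecompositionError(f"cannot expand expression: {err}") from err
    terms = list(expanded.args) if isinstance(expanded, sp.Add) else [expanded]

    # merge terms of the same class so e.g. several linear pieces lump into
    # one component with a single lumped coefficient
    grouped: dict[str, sp.Expr] = {}
    for term in terms:
        label = _classify(term, x)
        grouped[label] = grouped.get(label, sp.S.Zero) + term
    components = [Component(lbl, e) for lbl, e in grouped.items()]
    return DecompositionReport(fixed_var=fixed_var, fixed_value=fixed_value,
                               free_var=free_var, components=components,
                               dps=dps)


# ---------------------------------------------------------------------------
# Domain-of-validity scan
# ---------------------------------------------------------------------------

@dataclass
class DomainScanResult:
    argmax_c0: float
    max_rate: float
    zero_crossing_c0: float | None
    t_fixed: float


def domain_scan(uptake_fn, c0_range=(0.0, 100.0), t_fixed: float = 3.0,
                v_cb_ul: float = CELL_BASOLATERAL_VOLUME_UL,
                n_grid: int = 4001) -> DomainScanResult:
    """Scan the initial-rate curve over a concentration range.

    ``uptake_fn(c0, t)`` returns uptake in pmol/insert; the initial rate is
    uptake(t_fixed)/t_fixed converted to uM/min via the cellular+basolateral
    volume.  A dense grid locates the maximum, a bounded scalar refinement
    polishes it, and the first downward zero crossing beyond the maximum is
    bracketed and solved (``None`` if the rate stays positive).
    """
    lo, hi = float(c0_range[0]), float(c0_range[1])
    grid = np.linspace(lo, hi, int(n_grid))

    def rate(c0):
        return np.asarray(uptake_fn(c0, t_fixed), float) / t_fixed / v_cb_ul

    vals = rate(grid)
    i = int(np.nanargmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if b > a:
        res = optimize.minimize_scalar(lambda c: -float(rate(c)),
                                       bounds=(a, b), method="bounded",
                                       options={"xatol": 1e-8})
        argmax = float(res.x)
        vmax = float(rate(argmax))
        if vmax < vals[i]:
            argmax, vmax = float(grid[i]), float(vals[i])
    else:
        argmax, vmax = float(grid[i]), float(vals[i])

    zero = None
    after = np.where((grid > argmax) & (vals <= 0.0))[0]
    if after.size:
        j = int(after[0])
        lo_b, hi_b = grid[j - 1], grid[j]
        if rate(lo_b) > 0 >= rate(hi_b):
            zero = float(optimize.brentq(lambda c: float(rate(c)),
                                         lo_b, hi_b, xtol=1e-10))
        else:
            zero = float(grid[j])
    return DomainScanResult(argmax_c0=argmax, max_rate=vmax,
                            zero_crossing_c0=zero, t_fixed=t_fixed)
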