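"""Published reference models for short-term apical iron uptake.

These are the two symbolic models (and the companion kinetic constants)
reported for iron uptake in Caco-2 bicameral inserts, reproduced here from
their printed equations and parameter tables so the package's analysis
tooling can be exercised on them without rerunning the search:

* the **best search model** -- selected from 50 independent runs by
  generalization error and curation:

      ApUp(C0, t) = b1*C0 - sin(b6)*t*C0*(C0 + b3 + sin(C0*exp(b2))
                                          - b5*t*b4^t)

* the **pruned model** -- the same tree with the concentration-sinusoid
  branch removed after decomposition showed it contributes under 1% of the
  3-min absorption velocity at 20 uM:

      ApUp(C0, t) = b1*C0 - sin(b6)*t*C0*(C0 + b3 - b5*t*b4^t)

``ApUp`` is apical uptake in pmol/insert, ``C0`` the initial apical iron
concentration in uM, ``t`` time in minutes.

.. warning::
   The parameter values below are transcribed at 3 printed significant
   figures, and two of them sit in catastrophically sensitive positions:
   ``b6`` multiplies the whole nonlinear branch through ``sin(b6)`` and lies
   next to a zero of sine (32*pi = 100.531 also prints as 1.01e2), and
   ``b2`` appears as ``sin(C0*exp(b2))`` with ``exp(b2) ~ 1e93``.  Analyses
   that depend on ``sin(b6)`` or ``sin(C0*exp(b2))`` — absolute uptake
   scale, rate-maximum location, sinusoid share — are therefore *not*
   recoverable to full accuracy from the printed digits; see
   docs/methods.md for the quantitative analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import expressions as ex

__all__ = ["ReferenceModel", "BEST_MODEL", "PRUNED_MODEL",
           "KM_EXP_UM", "VMAX_EXP_UM_PER_MIN", "KM_LINDER_UM",
           "sinusoid_branch_path"]

#: Michaelis constant measured from the 3-min initial-rate assay [uM].
KM_EXP_UM = 10.36
#: Maximum velocity from the same assay [uM/min].
VMAX_EXP_UM_PER_MIN = 0.0145
#: Literature Michaelis constant for the iron importer at pH 7 [uM].
KM_LINDER_UM = 7.0


@dataclass(frozen=True)
class ReferenceModel:
    """A fixture: expression string plus jackknife-validated parameters."""

    name: str
    expression: str
    beta_mse: dict
    beta_star: dict
    ci_halfwidth: dict
    p_values: dict
    stats: dict = field(default_factory=dict)

    def __post_init__(self):
        tree = ex.parse(self.expression)
        slots = set(ex.param_names(tree))
        if slots != set(self.beta_mse):
            raise ValueError(
                f"{self.name}: parameter table {sorted(self.beta_mse)} does "
                f"not match expression slots {sorted(slots)}")

    @property
    def tree(self) -> ex.Node:
        return ex.parse(self.expression)

    def uptake(self, c0, t, beta: dict | None = None):
        """Apical uptake [pmol/insert] at (c0 [uM], t [min]), float64."""
        return ex.evaluate(self.tree, c0, t, beta or self.beta_mse)

    def uptake_exact(self, c0, t, beta: dict | None = None,
                     dps: int = 50) -> float:
        """Arbitrary-precision evaluation (printed decimals taken exact)."""
        return ex.evaluate_exact(self.tree, c0, t, beta or self.beta_mse,
                                 dps=dps)


BEST_MODEL = ReferenceModel(
    name="best",
    expression=("b1*C0 - sin(b6)*t*C0*"
                "((C0 + b3 + sin(C0*exp(b2))) - b5*t*b4^t)"),
    beta_mse={"b1": -7.93e-3, "b2": 2.15e2, "b3": -6.25e1,
              "b4": 4.39e-1, "b5": 1.39e2, "b6": 1.01e2},
    beta_star={"b1": -7.10e-3, "b2": 2.15e2, "b3": -8.57e1,
               "b4": 4.34e-1, "b5": 1.76e2, "b6": 1.01e2},
    ci_halfwidth={"b1": 1.38e-3, "b2": 4.06e-5, "b3": 1.15e1,
                  "b4": 5.03e-3, "b5": 2.24e1, "b6": 3.85e-4},
    p_values={"b1": 6.11e-85, "b2": 0.0, "b3": 5.76e-85,
              "b4": 2.17e-138, "b5": 1.64e-86, "b6": 8.09e-295},
    stats={"r2_train": 0.849, "r2_train_star": 0.382,
           "r2_test": 0.561, "r2_test_star": 0.432, "ge": 1.46},
)

PRUNED_MODEL = ReferenceModel(
    name="pruned",
    expression="b1*C0 - sin(b6)*t*C0*(C0 + b3 - b5*t*b4^t)",
    beta_mse={"b1": 8.79e-3, "b3": -5.40e1, "b4": 4.39e-1,
              "b5": 1.48e2, "b6": 1.01e2},
    beta_star={"b1": 9.03e-3, "b3": -4.88e1, "b4": 4.46e-1,
               "b5": 4.133e1, "b6": 1.01e2},
    ci_halfwidth={"b1": 6.75e-2, "b3": 2.28e1, "b4": 1.75e-1,
                  "b5": 2.48e2, "b6": 9.12e-4},
    p_values={"b1": 1.73e-15, "b3": 3.52e-74, "b4": 2.22e-75,
              "b5": 1.28e-44, "b6": 1.65e-307},
    stats={"r2_train": 0.854, "r2_train_star": 0.646,
           "r2_test": 0.575, "r2_test_star": 0.610, "ge": 1.57},
)


def sinusoid_branch_path(tree: ex.Node) -> tuple[int, ...]:
    """Path of the concentration-sinusoid branch ``sin(C0*exp(b2))``.

    This is the branch whose removal turns the best model into the pruned
    model: a ``sin`` node whose argument contains both the concentration
    variable and an ``exp``-wrapped parameter.
    """
    for path, node in tree.iter_paths():
        if node.kind == "func" and node.value == "sin":
            arg = node.children[0]
            symbols = {n.value for _, n in arg.iter_paths() if n.kind == "var"}
            has_exp = any(n.kind == "func" and n.value == "exp"
                          for _, n in arg.iter_paths())
            if "C0" in symbols and has_exp:
                return path
    raise ValueError("no concentration-sinusoid branch found")
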