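"""Uptake / initial-rate tables and synthetic experimental designs.

The package works with two kinds of tabular data, mirroring the short-term
iron-flux assays in Caco-2 bicameral inserts that motivate it:

* ``kind="uptake"`` -- apical uptake time courses: the amount of iron in the
  cell plus the basolateral compartment (pmol/insert) at time ``t`` (min)
  after an apical challenge at concentration ``c0`` (uM).  This is the
  training response.
* ``kind="rate"`` -- initial transport rates (uM/min, concentration referred
  to the cellular+basolateral volume) estimated from the first 3 minutes of
  uptake.  This is the held-out test response.

The canonical on-disk format is delimited text with header columns
``c0_uM, t_min, value, replicate, kind``; spreadsheet input is also accepted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import (EmptyInputError, EvaluationError, SchemaError,
                         ValidationError)

__all__ = [
    "APICAL_VOLUME_UL",
    "CELL_BASOLATERAL_VOLUME_UL",
    "ColumnLayout",
    "UptakeDataset",
    "ExperimentDesign",
    "TRAINING_DESIGN",
    "RATE_DESIGN",
    "read_table",
    "write_table",
    "generate_uptake",
    "summarize",
    "uptake_to_rate",
    "initial_rates_from_uptake",
]

#: Apical compartment volume (uL).
APICAL_VOLUME_UL = 200.0
#: Cellular + basolateral compartment volume (uL).  1 uM in 1000 uL = 1000 pmol.
CELL_BASOLATERAL_VOLUME_UL = 1000.0

_KINDS = ("uptake", "rate")
_CANONICAL_COLUMNS = ("c0_uM", "t_min", "value", "replicate")


@dataclass(frozen=True)
class ColumnLayout:
    """Declares which input columns play which role (and the kind column)."""

    c0: str = "c0_uM"
    t: str = "t_min"
    value: str = "value"
    replicate: str = "replicate"
    kind: str | None = "kind"  # None: take kind from the reader argument


class UptakeDataset:
    """Immutable table of observations with replicate structure.

    Rows hold ``(c0 [uM], t [min], value, replicate)``; ``kind`` is fixed for
    the whole dataset and decides the value units (pmol/insert for uptake,
    uM/min for rates).
    """

    def __init__(self, frame: pd.DataFrame, kind: str = "uptake"):
        if kind not in _KINDS:
            raise ValidationError(f"kind must be one of {_KINDS}, got {kind!r}")
        missing = [c for c in _CANONICAL_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"missing column(s) {missing}")
        frame = frame.loc[:, list(_CANONICAL_COLUMNS)].reset_index(drop=True)
        if len(frame) == 0:
            raise EmptyInputError("dataset has no data rows")
        frame = frame.astype({"c0_uM": float, "t_min": float,
                              "value": float, "replicate": int})
        if (frame["c0_uM"] < 0).any():
            raise ValidationError("negative c0")
        if (frame["t_min"] < 0).any():
            raise ValidationError("negative t")
        if (frame["replicate"] < 1).any():
            raise ValidationError("replicate ids must be >= 1")
        self._frame = frame
        self.kind = kind

    # -- views -------------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def n(self) -> int:
        return len(self._frame)

    @property
    def c0(self) -> np.ndarray:
        return self._frame["c0_uM"].to_numpy()

    @property
    def t(self) -> np.ndarray:
        return self._frame["t_min"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self._frame["value"].to_numpy()

    @property
    def replicate(self) -> np.ndarray:
        return self._frame["replicate"].to_numpy()

    def __len__(self) -> int:
        return self.n

    def __eq__(self, other):
        return (isinstance(other, UptakeDataset) and self.kind == other.kind
                and self._frame.equals(other._frame))

    def drop_row(self, i: int) -> "UptakeDataset":
        """Leave-one-out helper: the dataset without row ``i``."""
        return UptakeDataset(self._frame.drop(index=self._frame.index[i]),
                             self.kind)

    def __repr__(self):
        return (f"UptakeDataset(kind={self.kind!r}, n={self.n}, "
                f"c0 levels={sorted(set(self.c0))})")


@dataclass(frozen=True)
class ExperimentDesign:
    """A synthetic experimental design emulating the insert assays.

    ``noise_cv`` is the coefficient of variation of multiplicative Gaussian
    replicate noise: observed = prediction * (1 + eps), eps ~ N(0, noise_cv).
    """

    concentrations: tuple[float, ...]
    timepoints: tuple[float, ...]
    replicates: int = 3
    noise_cv: float = 0.2
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "concentrations",
                           tuple(float(c) for c in self.concentrations))
        object.__setattr__(self, "timepoints",
                           tuple(float(t) for t in self.timepoints))
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("negative concentration in design")
        if any(t < 0 for t in self.timepoints):
            raise ValidationError("negative timepoint in design")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


#: Training design: uptake time courses at 5/10/20 uM, 3-15 min, triplicate.
TRAINING_DESIGN = ExperimentDesign(
    concentrations=(5.0, 10.0, 20.0),
    timepoints=(3.0, 6.0, 9.0, 12.0, 15.0),
    replicates=3,
)

#: Test design: 3-min initial rates at 3/5/7/10/20 uM, triplicate.
RATE_DESIGN = ExperimentDesign(
    concentrations=(3.0, 5.0, 7.0, 10.0, 20.0),
    timepoints=(3.0,),
    replicates=3,
)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_table(path, layout: ColumnLayout | None = None,
               kind: str | None = None) -> UptakeDataset:
    """Read a delimited-text (CSV/TSV) or spreadsheet uptake table.

    ``layout`` maps file columns to roles; with the default layout the file
    must carry the canonical header.  ``kind`` overrides / supplies the
    dataset kind when the file has no kind column.
    """
    layout = layout or ColumnLayout()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        # round_trip: the default float parser can be off by one ulp
        raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    raw.columns = [str(c).strip() for c in raw.columns]
    roles = {layout.c0: "c0_uM", layout.t: "t_min",
             layout.value: "value", layout.replicate: "replicate"}
    missing = [c for c in roles if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing column(s) {missing} in {path.name}")
    frame = raw.rename(columns=roles)
    if len(frame) == 0:
        raise EmptyInputError(f"{path.name} contains no data rows")
    if kind is None:
        if layout.kind and layout.kind in raw.columns:
            kinds = set(raw[layout.kind].astype(str))
            if len(kinds) != 1:
                raise ValidationError(f"mixed kinds {sorted(kinds)} in table")
            kind = kinds.pop()
        else:
            kind = "uptake"
    frame = frame.dropna(subset=["c0_uM", "t_min", "value", "replicate"])
    if len(frame) == 0:
        raise EmptyInputError(f"{path.name} contains no data rows")
    return UptakeDataset(frame, kind=kind)


def write_table(dataset: UptakeDataset, path) -> None:
    """Write a dataset as delimited text, lossless for float64 values."""
    path = Path(path)
    frame = dataset.frame
    frame["kind"] = dataset.kind
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    # repr round-trips float64 exactly
    with open(path, "w") as fh:
        fh.write(sep.join(frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(sep.join(
                repr(v) if isinstance(v, float) else str(v) for v in row)
                + "\n")


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

def _as_predictor(model) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """Accept a callable(c0, t), a kinetic model, or a fitted tree model."""
    if callable(model) and not hasattr(model, "uptake"):
        return model
    if hasattr(model, "uptake"):
        return lambda c0, t: model.uptake(c0, t)
    raise TypeError(f"cannot evaluate model of type {type(model)!r}")


def generate_uptake(model, design: ExperimentDesign,
                    kind: str = "uptake",
                    rng: np.random.Generator | None = None) -> UptakeDataset:
    """Simulate a dataset from ``model`` under the given design.

    Every grid cell gets ``design.replicates`` observations with
    multiplicative Gaussian noise; ``design.seed`` (or ``rng``) makes the
    draw bitwise reproducible.
    """
    predict = _as_predictor(model)
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    for c0 in design.concentrations:
        for t in design.timepoints:
            mu = float(predict(c0, t))
            if not np.isfinite(mu):
                raise EvaluationError(
                    f"model is non-finite at c0={c0}, t={t}")
            for rep in range(1, design.replicates + 1):
                eps = rng.normal(0.0, design.noise_cv) if design.noise_cv else 0.0
                rows.append((c0, t, mu * (1.0 + eps), rep))
    frame = pd.DataFrame(rows, columns=list(_CANONICAL_COLUMNS))
    return UptakeDataset(frame, kind=kind)


def summarize(dataset: UptakeDataset) -> pd.DataFrame:
    """Per-(c0, t) mean and sample standard deviation (ddof=1)."""
    g = dataset.frame.groupby(["c0_uM", "t_min"])["value"]
    out = g.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
    out["sd"] = out["sd"].fillna(0.0)
    return out.reset_index()


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def uptake_to_rate(uptake_pmol, t_min,
                   v_cb_ul: float = CELL_BASOLATERAL_VOLUME_UL):
    """Convert uptake (pmol/insert over ``t_min``) to a rate in uM/min.

    1 uM in ``v_cb_ul`` uL equals ``v_cb_ul`` pmol, so
    rate = uptake / t / v_cb.
    """
    return np.asarray(uptake_pmol, float) / np.asarray(t_min, float) / v_cb_ul


def initial_rates_from_uptake(dataset: UptakeDataset, t_min: float = 3.0,
                              v_cb_ul: float = CELL_BASOLATERAL_VOLUME_UL
                              ) -> UptakeDataset:
    """Derive an initial-rate dataset from the ``t = t_min`` uptake rows."""
    if dataset.kind != "uptake":
        raise ValidationError("initial rates derive from an uptake dataset")
    frame = dataset.frame
    sel = frame[np.isclose(frame["t_min"], t_min)].copy()
    if len(sel) == 0:
        raise EmptyInputError(f"no rows at t = {t_min} min")
    sel["value"] = uptake_to_rate(sel["value"], t_min, v_cb_ul)
    return UptakeDataset(sel, kind="rate")
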