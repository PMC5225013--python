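"""Shared fixtures: small synthetic datasets and deterministic RNGs."""

import numpy as np
import pandas as pd
import pytest

from gpkin import UptakeDataset, evaluate, generate_uptake, parse
from gpkin.datasets import ExperimentDesign


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


def make_dataset(rows, kind="uptake"):
    """rows: iterable of (c0, t, value, replicate)."""
    frame = pd.DataFrame(rows, columns=["c0_uM", "t_min", "value",
                                        "replicate"])
    return UptakeDataset(frame, kind=kind)


@pytest.fixture
def planted_tree():
    """A bilinear uptake law: value = 2 * C0 * t."""
    return parse("(2.0*C0)*t")


@pytest.fixture
def planted_data(planted_tree):
    """Noise-free observations of the planted law on a 3x3 design."""
    design = ExperimentDesign((5.0, 10.0, 20.0), (3.0, 9.0, 15.0),
                              replicates=1, noise_cv=0.0, seed=1)
    return generate_uptake(
        lambda c0, t: float(evaluate(planted_tree, c0, t)), design)


@pytest.fixture
def noisy_training_data():
    """Triplicate training-style data from a saturating model, 10% CV."""
    from gpkin import KineticModel
    from gpkin.datasets import TRAINING_DESIGN
    from dataclasses import replace
    model = KineticModel(km=10.0, vmax=0.015)
    design = replace(TRAINING_DESIGN, noise_cv=0.1, seed=7)
    return generate_uptake(model, design)
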