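"""Shared fixtures: small hand-built tables plus seeded simulations.

The expensive negative-binomial fits are session-scoped so that the
statistical checks (type-I error, parameter recovery, sensitivity)
share one fit each instead of re-running it per test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trex.diffexp import NBDiffExp
from trex.io_formats import ExpressionTable
from trex.simulate import SyntheticSpec, generate

SEED = 20150903


@pytest.fixture
def small_table() -> ExpressionTable:
    return ExpressionTable(
        pd.DataFrame(
            {"s1": [10.0, 0.0, 1.0], "s2": [20.0, 5.0, 1.0]},
            index=["g1", "g2", "g3"],
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """Desk-scale 5-condition dataset with spiked DE genes and classes."""
    return generate(SyntheticSpec(seed=SEED))


@pytest.fixture(scope="session")
def null_fit():
    """Null NB simulation (no DE, phi=0.1, 3+3) with a fitted tester."""
    spec = SyntheticSpec(
        n_genes=2000,
        conditions=("WT", "Mut"),
        n_reps=3,
        dispersion=0.1,
        de_fraction=0.0,
        seed=SEED,
    )
    table, factors, contrasts, _, truth = generate(spec)
    de = NBDiffExp().fit(table.values, factors.condition.to_numpy())
    result = de.test_contrast("Mut", "WT")
    return {"table": table, "factors": factors, "de": de, "result": result}


@pytest.fixture(scope="session")
def spiked_fit():
    """3+3 NB simulation, phi=0.1, 10% of genes at true |log2FC| = 2."""
    spec = SyntheticSpec(
        n_genes=2000,
        conditions=("WT", "Mut"),
        n_reps=3,
        dispersion=0.1,
        de_fraction=0.10,
        de_log2fc=(2.0, -2.0),
        seed=SEED + 1,
    )
    table, factors, contrasts, _, truth = generate(spec)
    de = NBDiffExp().fit(table.values, factors.condition.to_numpy())
    result = de.test_contrast("Mut", "WT")
    return {"table": table, "truth": truth, "de": de, "result": result}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)
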