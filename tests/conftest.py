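"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from hystecon.defaults import (
    default_calibration,
    default_cohort_config,
    default_model_parameters,
)
from hystecon.methods import SurgicalMethod
from hystecon.tree import ChanceNode, DecisionTree, TerminalNode, build_tree

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def params():
    """Decision-model parameters at the published point estimates."""
    return default_model_parameters()


@pytest.fixture(scope="session")
def tree(params):
    return build_tree(params)


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (73/118/43 patients) at a fixed seed."""
    from hystecon.cohort import generate_cohort

    return generate_cohort(default_cohort_config(seed=7))


# ---------------------------------------------------------------------------
# Independent oracles


def enumerate_paths(node):
    """Exhaustive root-to-leaf path enumeration: [(probability, cost), ...].

    Deliberately independent of the rollback implementation under test.
    """
    if isinstance(node, TerminalNode):
        return [(1.0, node.cost)]
    out = []
    for p, child in node.branches:
        out.extend((p * q, c) for q, c in enumerate_paths(child))
    return out


def path_expected_cost(node) -> float:
    return float(sum(p * c for p, c in enumerate_paths(node)))


def random_chance_tree(rng: np.random.Generator, depth: int):
    """Random chance/terminal tree of the given maximum depth."""
    if depth == 0 or rng.random() < 0.2:
        return TerminalNode(
            label="leaf",
            lnd=False,
            conversion=False,
            hemorrhage=False,
            or_time=float(rng.uniform(30, 400)),
            cost=float(rng.uniform(0, 1e5)),
        )
    k = int(rng.integers(2, 4))
    probs = rng.dirichlet(np.ones(k))
    branches = tuple(
        (float(p), random_chance_tree(rng, depth - 1)) for p in probs
    )
    return ChanceNode(label=f"chance-d{depth}", branches=branches)


def wrap_tree(node) -> DecisionTree:
    return DecisionTree(subtrees={SurgicalMethod.TAH: node}).validate()
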