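"""Shared fixtures: small synthetic cohorts and helper constructions."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # local test helpers

from coexnet.containers import ExpressionMatrix, Module, ModuleHierarchy
from coexnet.simulate import ModuleSpec, SimConfig, simulate_cohort


SMALL_SIM = dict(
    n_genes=240, n_samples=200,
    modules=tuple(ModuleSpec(40, (20, 20), 0.35, 0.65) for _ in range(4)),
    n_mutation_targets=20, n_cis_probes=10, n_null_probes=10,
)


def small_config(seed: int = 0, **overrides) -> SimConfig:
    return SimConfig(seed=seed, **{**SMALL_SIM, **overrides})


def truth_hierarchy(truth: dict, include_parents: bool = True) -> ModuleHierarchy:
    """Build a ModuleHierarchy from a cohort's truth manifest."""
    all_genes = frozenset(g for gs in truth["modules"].values() for g in gs)
    mods = [Module("root", None, 1.0, all_genes)]
    for mid, gs in truth["modules"].items():
        if "." not in mid and include_parents:
            mods.append(Module(mid, "root", 1.0, frozenset(gs)))
    for mid, gs in truth["modules"].items():
        if "." in mid:
            parent = mid.split(".")[0] if include_parents else "root"
            mods.append(Module(mid.replace(".", "_"), parent, 1.0, frozenset(gs)))
    return ModuleHierarchy(mods)


def logged_matrix(cohort) -> ExpressionMatrix:
    """The cohort's expression on the log2 scale, tagged as normalized."""
    return ExpressionMatrix(cohort.expression.gene_ids, cohort.expression.sample_ids,
                            cohort.logged, "normalized")


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(small_config(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_expression():
    rng = np.random.default_rng(5)
    v = rng.normal(5, 1, (30, 12))
    return ExpressionMatrix([f"g{i:02d}" for i in range(30)],
                            [f"s{j:02d}" for j in range(12)], v, "normalized")
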