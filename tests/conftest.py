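from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracle.py importable

from pygsva import ExpressionMatrix, GeneSet, GeneSetCollection


def make_expr(rng, p, n, value_kind="continuous"):
    if value_kind == "continuous":
        values = rng.normal(6, 2, size=(p, n))
    else:
        values = rng.poisson(rng.uniform(1, 100, size=p)[:, None], size=(p, n)).astype(float)
    return ExpressionMatrix(
        values=values,
        gene_ids=[f"g{i}" for i in range(p)],
        sample_ids=[f"s{j}" for j in range(n)],
        value_kind=value_kind,
    )


def make_sets(rng, gene_ids, n_sets, min_size=5, max_size=20):
    sets = []
    p = len(gene_ids)
    for k in range(n_sets):
        size = int(rng.integers(min_size, min(max_size, p - 1) + 1))
        members = tuple(np.asarray(gene_ids)[rng.choice(p, size=size, replace=False)])
        sets.append(GeneSet(f"set{k}", "", members))
    return GeneSetCollection(sets=sets)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    return make_expr(rng, p=50, n=8)


@pytest.fixture
def small_sets(rng, small_expr):
    return make_sets(rng, small_expr.gene_ids, n_sets=5)
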