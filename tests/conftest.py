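"""Shared fixtures: synthetic families/counts and additive-distance oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stemwall import SimConfig, generate
from stemwall.expression import INTERNODES, InternodeCountMatrix


def random_additive_distances(n: int, rng: np.random.Generator) -> np.ndarray:
    """Leaf-to-leaf path distances of a random binary tree with random
    positive branch lengths — the independent oracle for neighbor joining
    (NJ recovers additive matrices exactly)."""
    dist = np.zeros((n, n))
    # each active subtree tracked as {leaf: distance to subtree root}
    active: list[dict[int, float]] = [{i: 0.0} for i in range(n)]
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), 2, replace=False))
        da, db = active[i], active[j]
        la, lb = rng.uniform(0.05, 1.0, 2)
        for x, dx in da.items():
            for y, dy in db.items():
                dist[x, y] = dist[y, x] = dx + la + dy + lb
        merged = {x: dx + la for x, dx in da.items()}
        merged.update({y: dy + lb for y, dy in db.items()})
        active = [a for k, a in enumerate(active) if k not in (i, j)] + [merged]
    return dist


def make_matrix(counts: dict, lib_sizes=None, ambiguous=None) -> InternodeCountMatrix:
    """Small InternodeCountMatrix from {gene: (c4, c5, c6, c8)}."""
    df = pd.DataFrame(counts, index=list(INTERNODES)).T
    libs = pd.Series(
        lib_sizes if lib_sizes is not None else [20_000_000] * 4,
        index=list(INTERNODES),
    )
    amb = pd.DataFrame(
        ambiguous or [], columns=["gene_a", "gene_b", "internode", "count"]
    )
    return InternodeCountMatrix(counts=df, lib_sizes=libs, ambiguous=amb)


@pytest.fixture(scope="session")
def small_sim():
    """Three 12-gene families with duplicates and known classes."""
    config = SimConfig(n_families=3, genes_per_family=12, seed=11)
    alignments, truth, icm = generate(config)
    return config, alignments, truth, icm


@pytest.fixture(scope="session")
def recovery_sim():
    """~200 query genes at the study's default noise and effect size."""
    config = SimConfig(n_families=17, genes_per_family=12, seed=7)
    alignments, truth, icm = generate(config)
    return config, alignments, truth, icm
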