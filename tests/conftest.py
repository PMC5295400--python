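"""Shared fixtures: toy ontologies, random generators, brute-force oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from irwrlda.ontology import DiseaseOntology


@pytest.fixture
def toy_ontology() -> DiseaseOntology:
    """Four diseases: root R; R->A, R->B, B->C (all four are diseases)."""
    parents = {
        "A": frozenset({"R"}),
        "B": frozenset({"R"}),
        "C": frozenset({"B"}),
    }
    return DiseaseOntology(parents=parents, diseases=("R", "A", "B", "C"))


def brute_force_semantic_similarity(ont: DiseaseOntology, a: str, b: str) -> float:
    """Independent enumeration oracle for the semantic similarity ratio.

    Recomputes D(.), DAG counts and contributions from scratch with
    explicit loops, sharing no code path with the implementation.
    """

    def closure(term: str) -> frozenset[str]:
        out: set[str] = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in ont.parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    frontier.append(p)
        return frozenset(out)

    dags = {d: closure(d) for d in ont.diseases}

    def contrib(t: str) -> float:
        count = sum(1 for dag in dags.values() if t in dag)
        return -math.log(count / len(ont.diseases))

    da, db = dags[a], dags[b]
    total = sum(contrib(t) for t in da) + sum(contrib(t) for t in db)
    if total == 0.0:
        return 1.0 if da == db else 0.0
    return sum(contrib(t) + contrib(t) for t in da & db) / total


def random_ontology(rng: np.random.Generator, n_diseases: int = 8) -> DiseaseOntology:
    """A random rooted tree whose nodes are all diseases."""
    names = [f"d{i}" for i in range(n_diseases)]
    parents: dict[str, frozenset[str]] = {}
    for i in range(1, n_diseases):
        parents[names[i]] = frozenset({names[int(rng.integers(0, i))]})
    return DiseaseOntology(parents=parents, diseases=tuple(names))


def random_column_stochastic(rng: np.random.Generator, n: int) -> np.ndarray:
    w = rng.random((n, n)) + 1e-3
    return w / w.sum(axis=0, keepdims=True)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160809)
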