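"""Disease semantic similarity from MeSH-style disease DAGs.

Each disease ``A`` has a DAG whose node set ``D(A)`` is the disease
itself plus all of its ancestor terms. A term's contribution is a global
information-content-like weight

    C(t) = -log( #disease DAGs containing t / #diseases ),

so rare (specific) terms contribute more than terms shared by many
diseases. The semantic value of a disease is ``C(A) = sum_{t in D(A)} C(t)``
and the similarity between two diseases is the contribution of their
shared terms relative to their total contributions:

    SS(A, B) = sum_{t in D(A) ∩ D(B)} (C(t) + C(t)) / (C(A) + C(B)).

Because SS is a ratio of sums of logarithms, its value is independent of
the logarithm base; the natural log is used for intermediate values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import networkx as nx
import pandas as pd

from .io import ParseError

__all__ = [
    "DiseaseOntology",
    "read_ontology",
    "dag_count",
    "term_contribution",
    "semantic_value",
    "semantic_similarity",
    "semantic_matrix",
]


@dataclass(frozen=True)
class DiseaseOntology:
    """A disease term DAG plus the set of diseases carrying a DAG.

    Parameters
    ----------
    parents
        Map ``term -> set of parent terms``. Terms without parents are
        roots. The relation must be acyclic.
    diseases
        The disease ids (each a term) whose DAGs are defined. A disease
        absent from `parents` is a single-node DAG.
    """

    parents: dict[str, frozenset[str]]
    diseases: tuple[str, ...]

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for child, pars in self.parents.items():
            for p in pars:
                g.add_edge(p, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent relation contains a cycle; a DAG is required")
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease ids")

    @cached_property
    def terms(self) -> frozenset[str]:
        """All known terms: every node of the parent relation plus all diseases."""
        out = set(self.diseases)
        for child, pars in self.parents.items():
            out.add(child)
            out.update(pars)
        return frozenset(out)

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestor closure of `term` including the term itself."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        closure: set[str] = set()
        stack = [term]
        while stack:
            t = stack.pop()
            if t in closure:
                continue
            closure.add(t)
            stack.extend(self.parents.get(t, ()))
        return frozenset(closure)

    @cached_property
    def disease_dag(self) -> dict[str, frozenset[str]]:
        """``D(A)`` for every disease A: the disease plus all its ancestors."""
        return {a: self.ancestors(a) for a in self.diseases}

    @cached_property
    def _dag_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for dag in self.disease_dag.values():
            for t in dag:
                counts[t] = counts.get(t, 0) + 1
        return counts


def read_ontology(path: str | Path, diseases: list[str]) -> DiseaseOntology:
    """Read a ``child<TAB>parent`` edge TSV and attach the disease set.

    Diseases are the subset of terms named in the association data; a
    disease missing from the edge file gets a single-node DAG.
    """
    path = Path(path)
    parents: dict[str, set[str]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'child<TAB>parent', got {len(fields)} fields"
                )
            child, parent = fields[0].strip(), fields[1].strip()
            if not child or not parent:
                raise ParseError(f"{path}:{lineno}: empty term")
            parents.setdefault(child, set()).add(parent)
    frozen = {c: frozenset(p) for c, p in parents.items()}
    return DiseaseOntology(parents=frozen, diseases=tuple(diseases))


def write_ontology(ont: DiseaseOntology, path: str | Path) -> None:
    """Write the parent relation as a ``child<TAB>parent`` edge TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# child\tparent\n")
        for child in sorted(ont.parents):
            for parent in sorted(ont.parents[child]):
                fh.write(f"{child}\t{parent}\n")


def dag_count(ont: DiseaseOntology, term: str) -> int:
    """Number of disease DAGs whose node set contains `term`."""
    if term not in ont.terms:
        raise KeyError(f"unknown term {term!r}")
    return ont._dag_counts.get(term, 0)


def term_contribution(ont: DiseaseOntology, term: str, base: float | None = None) -> float:
    """Contribution ``-log(dag_count(t) / n_diseases)`` of a term.

    `base` selects the logarithm base (natural log by default); the
    downstream similarity is base-invariant.
    """
    count = dag_count(ont, term)
    if count == 0:
        raise ValueError(f"term {term!r} appears in no disease DAG; contribution undefined")
    frac = count / ont.n_diseases
    return -math.log(frac) if base is None else -math.log(frac, base)


def semantic_value(ont: DiseaseOntology, disease: str, base: float | None = None) -> float:
    """Semantic value ``C(A)``: the summed contribution over D(A)."""
    if disease not in ont.disease_dag:
        raise KeyError(f"unknown disease {disease!r}")
    return sum(term_contribution(ont, t, base=base) for t in ont.disease_dag[disease])


def semantic_similarity(
    ont: DiseaseOntology, a: str, b: str, base: float | None = None
) -> float:
    """Semantic similarity ``SS(A, B)`` in [0, 1].

    The shared-term contributions of both DAGs relative to the total
    ``C(A) + C(B)``. When both DAGs carry zero total contribution (all
    terms universally shared), the limit convention is 1 for identical
    node sets and 0 otherwise.
    """
    for d in (a, b):
        if d not in ont.disease_dag:
            raise KeyError(f"unknown disease {d!r}")
    da, db = ont.disease_dag[a], ont.disease_dag[b]
    denom = semantic_value(ont, a, base=base) + semantic_value(ont, b, base=base)
    if denom == 0.0:
        return 1.0 if da == db else 0.0
    shared = da & db
    num = sum(2.0 * term_contribution(ont, t, base=base) for t in shared)
    return num / denom


def semantic_matrix(
    ont: DiseaseOntology, order: list[str], base: float | None = None
) -> pd.DataFrame:
    """The symmetric disease semantic similarity matrix SS over `order`."""
    n = len(order)
    ss = pd.DataFrame(0.0, index=list(order), columns=list(order))
    for i in range(n):
        ss.iloc[i, i] = 1.0
        for j in range(i + 1, n):
            v = semantic_similarity(ont, order[i], order[j], base=base)
            ss.iloc[i, j] = v
            ss.iloc[j, i] = v
    return ss
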