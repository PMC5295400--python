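"""Synthetic lncRNA-disease benchmark data with planted block structure.

The method's working assumption is that lncRNAs with similar functions
associate with similar diseases. The generator makes that assumption
true by construction: lncRNAs and diseases are partitioned into
matching blocks, and

* **associations** occur at a high density inside a block and a low
  background density elsewhere;
* the **disease ontology** is a rooted tree in which diseases of a
  block share a recent ancestor, so within-block semantic similarity
  exceeds between-block similarity;
* **expression profiles** of a block share a latent tissue profile, so
  within-block Spearman correlation exceeds between-block correlation.

Turning the planting off (equal densities, zero expression
correlation) yields a structureless negative control. All randomness
is governed by a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AssociationList, to_matrix, write_associations, write_matrix
from .lnc_similarity import ExpressionProfiles, expression_matrix
from .ontology import DiseaseOntology, semantic_matrix, write_ontology

__all__ = [
    "SynthConfig",
    "make_ontology",
    "make_associations",
    "make_expression",
    "build_dataset",
    "simulate",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the planted-block generator.

    Defaults emulate a small association study: 80 lncRNAs x 20
    diseases in 4 co-association blocks, dense (0.6) inside a block
    over a sparse (0.02) background, expression profiles over 22
    tissues with strong (0.8) within-block correlation, and 80% of
    lncRNAs flagged as lincRNAs (those with usable expression data).
    """

    n_lncrnas: int = 80
    n_diseases: int = 20
    n_tissues: int = 22
    n_blocks: int = 4
    assoc_density_in_block: float = 0.6
    assoc_density_background: float = 0.02
    expr_block_correlation: float = 0.8
    ontology_branching: int = 3
    lincrna_fraction: float = 0.8
    seed: int = 0
    allow_orphans: bool = False

    def __post_init__(self) -> None:
        for name in ("assoc_density_in_block", "assoc_density_background",
                     "expr_block_correlation", "lincrna_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ontology_branching < 1:
            raise ValueError("ontology_branching must be >= 1")
        if min(self.n_lncrnas, self.n_diseases, self.n_blocks) < 1:
            raise ValueError("counts must be positive")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues for rank correlation")

    @property
    def lnc_ids(self) -> list[str]:
        return [f"lnc{i:03d}" for i in range(self.n_lncrnas)]

    @property
    def disease_ids(self) -> list[str]:
        return [f"disease{j:02d}" for j in range(self.n_diseases)]

    def lnc_blocks(self) -> np.ndarray:
        """Block index per lncRNA (contiguous, near-equal split)."""
        return np.arange(self.n_lncrnas) * self.n_blocks // self.n_lncrnas

    def disease_blocks(self) -> np.ndarray:
        return np.arange(self.n_diseases) * self.n_blocks // self.n_diseases

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def make_ontology(cfg: SynthConfig) -> DiseaseOntology:
    """A rooted disease-term tree with one shared recent ancestor per block.

    Diseases of a block hang (possibly via up to `ontology_branching`
    intermediate terms) below a block term; block terms hang below a
    common root. The root lies in every disease's DAG so it contributes
    nothing; the block terms are what separate within-block from
    between-block similarity. Deterministic given the config.
    """
    diseases = cfg.disease_ids
    if cfg.n_diseases == 1:
        return DiseaseOntology(parents={}, diseases=tuple(diseases))
    parents: dict[str, frozenset[str]] = {}
    blocks = cfg.disease_blocks()
    for b in range(cfg.n_blocks):
        block_term = f"group{b}"
        members = [diseases[j] for j in range(cfg.n_diseases) if blocks[j] == b]
        if not members:
            continue
        parents[block_term] = frozenset({"root"})
        if len(members) <= cfg.ontology_branching:
            for m in members:
                parents[m] = frozenset({block_term})
        else:
            n_mid = cfg.ontology_branching
            for k in range(n_mid):
                parents[f"group{b}.{k}"] = frozenset({block_term})
            for pos, m in enumerate(members):
                parents[m] = frozenset({f"group{b}.{pos % n_mid}"})
    return DiseaseOntology(parents=parents, diseases=tuple(diseases))


def make_associations(cfg: SynthConfig) -> AssociationList:
    """Bernoulli associations: in-block density inside, background outside.

    Unless ``allow_orphans`` is set, every disease is guaranteed at
    least one association (a random same-block lncRNA is attached),
    and at least one association exists overall.
    """
    rng = cfg._rng(1)
    lnc_ids, dis_ids = cfg.lnc_ids, cfg.disease_ids
    lb, db = cfg.lnc_blocks(), cfg.disease_blocks()
    same = lb[:, None] == db[None, :]
    p = np.where(same, cfg.assoc_density_in_block, cfg.assoc_density_background)
    hits = rng.random((cfg.n_lncrnas, cfg.n_diseases)) < p
    if not cfg.allow_orphans:
        for j in range(cfg.n_diseases):
            if not hits[:, j].any():
                pool = np.nonzero(same[:, j])[0]
                if len(pool) == 0:
                    pool = np.arange(cfg.n_lncrnas)
                hits[rng.choice(pool), j] = True
    pairs = [(lnc_ids[i], dis_ids[j]) for i, j in zip(*np.nonzero(hits))]
    return AssociationList(pairs, provenance=f"synthetic(seed={cfg.seed})")


def make_expression(cfg: SynthConfig) -> ExpressionProfiles:
    """Expression profiles sharing a latent tissue profile per block.

    Profile of lncRNA i in block b is ``rho * z_b + sqrt(1 - rho^2) * eps``
    with standard-normal latent ``z_b`` and noise, so the within-block
    Pearson (and, monotonically, Spearman) correlation is ~``rho`` =
    ``expr_block_correlation``. A ``lincrna_fraction`` share of lncRNAs
    (chosen at random) is flagged lincRNA.
    """
    rng = cfg._rng(2)
    rho = cfg.expr_block_correlation
    latent = rng.standard_normal((cfg.n_blocks, cfg.n_tissues))
    noise = rng.standard_normal((cfg.n_lncrnas, cfg.n_tissues))
    x = rho * latent[cfg.lnc_blocks()] + np.sqrt(1.0 - rho**2) * noise
    profiles = pd.DataFrame(
        x, index=cfg.lnc_ids, columns=[f"tissue{k:02d}" for k in range(cfg.n_tissues)]
    )
    n_flag = int(round(cfg.lincrna_fraction * cfg.n_lncrnas))
    flagged = rng.permutation(cfg.n_lncrnas)[:n_flag]
    flags = pd.Series(False, index=cfg.lnc_ids)
    flags.iloc[flagged] = True
    return ExpressionProfiles(profiles=profiles, linc_flags=flags)


@dataclass
class SyntheticDataset:
    """All derived artifacts of one generated benchmark."""

    cfg: SynthConfig
    ontology: DiseaseOntology
    associations: AssociationList
    profiles: ExpressionProfiles
    assoc_matrix: pd.DataFrame
    ss: pd.DataFrame
    es: pd.DataFrame


def build_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate all inputs and assemble the matrices the pipeline needs."""
    ont = make_ontology(cfg)
    assoc = make_associations(cfg)
    prof = make_expression(cfg)
    a = to_matrix(assoc, cfg.lnc_ids, cfg.disease_ids)
    ss = semantic_matrix(ont, cfg.disease_ids)
    es = expression_matrix(prof, order=cfg.lnc_ids)
    return SyntheticDataset(cfg, ont, assoc, prof, a, ss, es)


def simulate(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write pairs.tsv, edges.tsv, expr.tsv and flags.tsv to `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ont = make_ontology(cfg)
    assoc = make_associations(cfg)
    prof = make_expression(cfg)
    paths = {
        "pairs": out / "pairs.tsv",
        "edges": out / "edges.tsv",
        "expr": out / "expr.tsv",
        "flags": out / "flags.tsv",
    }
    write_associations(assoc, paths["pairs"])
    write_ontology(ont, paths["edges"])
    write_matrix(prof.profiles, paths["expr"])
    with paths["flags"].open("w") as fh:
        fh.write("# lncRNA\tis_lincRNA\n")
        for lnc, flag in prof.linc_flags.items():
            fh.write(f"{lnc}\t{int(flag)}\n")
    return paths
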