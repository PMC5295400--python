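"""Random walk with restart with similarity-derived seed probabilities.

The walk runs on the lncRNA integrated-similarity network. For a query
disease ``d`` the seed (initial probability) vector is

* 1 for every lncRNA with a known association to ``d``;
* otherwise ``max(score1, score2)`` clamped to [0, 1], where *score1*
  is the best expression similarity between the lncRNA and the known
  lncRNAs of ``d``, and *score2* is the best semantic similarity
  between ``d`` and the diseases known for that lncRNA.

Because the seeds can be built purely from similarity, a disease with
no known lncRNA can still be scored — the point of the method. The walk
iterates ``p_{t+1} = (1 - r) W p_t + r p_0`` on the column-normalized
similarity matrix ``W`` until the L1 change drops below a cutoff; the
stationary vector ranks the candidate lncRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .lnc_similarity import gaussian_kernel_matrix, integrated_similarity

__all__ = [
    "WalkConfig",
    "WalkState",
    "score1",
    "score2",
    "initial_probability",
    "column_normalize",
    "walk",
    "rank_candidates",
    "predict",
]


@dataclass(frozen=True)
class WalkConfig:
    """Restart probability, L1 convergence cutoff and iteration cap.

    The restart probability defaults to 0.9, the convention of the
    random-walk prioritization lineage this model extends.
    """

    restart: float = 0.9
    cutoff: float = 1e-10
    max_iter: int = 10000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart <= 1.0):
            raise ValueError("restart probability must be in (0, 1]")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class WalkState:
    """Inputs and outcome of one walk: p0, W, p_inf and convergence info."""

    p0: pd.Series
    w: pd.DataFrame
    p_inf: pd.Series
    iterations_used: int
    converged: bool


def _known_lncrnas(assoc: pd.DataFrame, disease: str) -> pd.Index:
    if disease not in assoc.columns:
        raise KeyError(f"unknown disease {disease!r}")
    return assoc.index[assoc[disease] > 0]


def _known_diseases(assoc: pd.DataFrame, lnc: str) -> pd.Index:
    if lnc not in assoc.index:
        raise KeyError(f"unknown lncRNA {lnc!r}")
    return assoc.columns[assoc.loc[lnc] > 0]


def score1(disease: str, lnc: str, es: pd.DataFrame, assoc: pd.DataFrame) -> float:
    """Best expression similarity to the known lncRNAs of `disease`.

    Max over ``l_i in L(d)`` of ``ES(l, l_i)``; 0 when the disease has
    no known lncRNAs (no evidence, no seed mass).
    """
    known = _known_lncrnas(assoc, disease)
    if len(known) == 0:
        return 0.0
    return float(es.loc[lnc, known].max())


def score2(disease: str, lnc: str, ss: pd.DataFrame, assoc: pd.DataFrame) -> float:
    """Best semantic similarity of `disease` to the known diseases of `lnc`.

    Max over ``d_j in D(l)`` of ``SS(d, d_j)``; 0 when the lncRNA has no
    known diseases.
    """
    known = _known_diseases(assoc, lnc)
    if len(known) == 0:
        return 0.0
    return float(ss.loc[disease, known].max())


def initial_probability(
    disease: str, es: pd.DataFrame, ss: pd.DataFrame, assoc: pd.DataFrame
) -> pd.Series:
    """Seed vector p0 over the lncRNAs of `assoc` for one disease.

    Known associated lncRNAs get exactly 1; the rest get
    ``max(score1, score2)`` clamped to [0, 1] (Spearman similarity can
    be negative, and seeds are probabilities). The vector can be all
    zero when no similarity evidence exists — the degenerate case
    handled downstream by the tie-rank convention.
    """
    lncs = assoc.index
    missing_es = set(lncs) - set(es.index)
    if missing_es:
        raise KeyError(f"ES matrix missing lncRNAs: {sorted(missing_es)[:5]}")
    if disease not in ss.index:
        raise KeyError(f"SS matrix missing disease {disease!r}")
    known = _known_lncrnas(assoc, disease)

    if len(known) > 0:
        s1 = es.loc[lncs, known].to_numpy(dtype=float).max(axis=1)
    else:
        s1 = np.zeros(len(lncs))

    a = assoc.to_numpy(dtype=float) > 0
    ss_row = ss.loc[disease, assoc.columns].to_numpy(dtype=float)
    masked = np.where(a, ss_row[None, :], -np.inf)
    s2 = masked.max(axis=1)
    s2[~a.any(axis=1)] = 0.0

    p0 = np.clip(np.maximum(s1, s2), 0.0, 1.0)
    p0[np.isin(lncs, known)] = 1.0
    return pd.Series(p0, index=lncs, name=disease)


def column_normalize(ls: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize a nonnegative similarity matrix to W.

    Every nonzero column sums to 1; all-zero columns stay zero (with a
    warning) rather than being filled uniformly — the similarity data
    supports no edges there.
    """
    vals = ls.to_numpy(dtype=float)
    if (vals < 0).any():
        i, j = np.unravel_index(np.argmin(vals), vals.shape)
        raise ValueError(
            f"negative similarity at ({ls.index[i]!r}, {ls.columns[j]!r}): {vals[i, j]}"
        )
    colsums = vals.sum(axis=0)
    zero = colsums == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} all-zero column(s) left unnormalized", stacklevel=2
        )
    safe = np.where(zero, 1.0, colsums)
    return pd.DataFrame(vals / safe, index=ls.index, columns=ls.columns)


def walk(p0: pd.Series, w: pd.DataFrame, cfg: WalkConfig | None = None) -> WalkState:
    """Iterate ``p_{t+1} = (1-r) W p_t + r p0`` to the stationary vector.

    Stops when the L1 change falls below ``cfg.cutoff`` or after
    ``cfg.max_iter`` steps (flagged as unconverged). For a
    column-stochastic W the iteration is an L1 contraction with factor
    ``1 - r`` and conserves total mass.
    """
    cfg = cfg or WalkConfig()
    if list(p0.index) != list(w.index):
        raise ValueError("p0 and W must share the same lncRNA order")
    r = cfg.restart
    wv = w.to_numpy(dtype=float)
    p0v = p0.to_numpy(dtype=float)
    p = p0v.copy()
    converged = False
    its = 0
    for its in range(1, cfg.max_iter + 1):
        p_next = (1.0 - r) * (wv @ p) + r * p0v
        if not np.all(np.isfinite(p_next)):
            raise FloatingPointError("non-finite values during walk; check W")
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < cfg.cutoff:
            converged = True
            break
    return WalkState(
        p0=p0,
        w=w,
        p_inf=pd.Series(p, index=p0.index, name=p0.name),
        iterations_used=its,
        converged=converged,
    )


def rank_candidates(
    state_or_scores: WalkState | pd.Series, disease: str, assoc: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank candidate lncRNAs (those without a known association) by p_inf.

    Returns ``(candidates, known)``: candidates carry descending scores
    and average-tie ranks (all-equal scores all get rank (N+1)/2); known
    lncRNAs are excluded from the ranking and reported separately.
    """
    scores = state_or_scores.p_inf if isinstance(state_or_scores, WalkState) else state_or_scores
    known = _known_lncrnas(assoc, disease)
    cand_mask = ~assoc.index.isin(known)
    cand_scores = scores[cand_mask]
    ranks = rankdata(-cand_scores.to_numpy(dtype=float), method="average")
    candidates = pd.DataFrame(
        {"score": cand_scores.to_numpy(dtype=float), "rank": ranks},
        index=cand_scores.index,
    ).sort_values(["rank", "score"], ascending=[True, False])
    candidates.index.name = "lncRNA"
    known_df = pd.DataFrame({"score": scores[known].to_numpy(dtype=float)}, index=known)
    known_df.index.name = "lncRNA"
    return candidates, known_df


def predict(
    disease: str,
    assoc: pd.DataFrame,
    ss: pd.DataFrame,
    es: pd.DataFrame,
    fs: pd.DataFrame | None = None,
    gamma_prime: float = 1.0,
    cfg: WalkConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end prioritization of candidate lncRNAs for one disease.

    Builds the interaction-profile kernel from `assoc`, integrates it
    with `fs` (if given), column-normalizes, seeds from similarity, runs
    the walk and ranks. Returns ``(candidates, known)`` as in
    :func:`rank_candidates`.
    """
    p0 = initial_probability(disease, es, ss, assoc)
    if (p0.to_numpy() == 0).all():
        # No seed evidence at all: the walk would stay at zero; report ties.
        return rank_candidates(p0, disease, assoc)
    kl = gaussian_kernel_matrix(assoc, gamma_prime=gamma_prime)
    ls = integrated_similarity(fs, kl)
    w = column_normalize(ls)
    state = walk(p0, w, cfg)
    return rank_candidates(state, disease, assoc)
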