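"""Leave-one-out cross-validation, ROC/AUC and ranking reports.

Each known (lncRNA, disease) association is held out in turn: it is
removed from the association matrix *before* the kernel, integrated
similarity and seed vector are computed (no leakage), and the held-out
lncRNA is then ranked among the disease's candidate lncRNAs — those
with no remaining known association to it, which now include the
held-out one.

When masking leaves the seed vector all zero the model has no
information for that fold and the held-out lncRNA receives the expected
random rank ``(N + 1) / 2`` over N candidates. These fallback folds are
flagged: pooled over many of them they produce the characteristic jump
of the ROC curve at FPR = 0.5.

Pooling ROC points across diseases with unequal candidate-set sizes
uses rank-fraction thresholds (absolute ranks are incomparable across
diseases); the closed-form rank-AUC — the mean of
``(N + 1 - rank) / N`` over folds — is reported alongside as a
pooling-free summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .lnc_similarity import gaussian_kernel_matrix, integrated_similarity
from .rwr import WalkConfig, column_normalize, initial_probability, rank_candidates, walk

__all__ = [
    "LoocvRecord",
    "RocCurve",
    "loocv",
    "roc_auc",
    "loocv_summary",
    "ranking_report",
    "zero_known_mode",
]


@dataclass(frozen=True)
class LoocvRecord:
    """Outcome of one held-out association.

    `rank` is the (possibly fractional, tie-averaged) rank of the
    held-out lncRNA among ``n_candidates + 1`` ranked transcripts;
    `fallback_random` marks folds whose seed vector was all zero and
    whose rank is the (N+1)/2 convention.
    """

    disease_id: str
    lncrna_id: str
    rank: float
    n_candidates: int
    fallback_random: bool
    converged: bool = True

    def __post_init__(self) -> None:
        if not (1.0 <= self.rank <= self.n_candidates + 1):
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates + 1}] "
                f"for {self.lncrna_id}/{self.disease_id}"
            )


@dataclass
class RocCurve:
    """Pooled ROC curve: threshold grid, FPR/TPR and two AUC summaries."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    rank_auc: float


def _rank_among(scores: np.ndarray, target_idx: int) -> float:
    """Average-tie rank of one entry under descending-score ranking."""
    return float(rankdata(-scores, method="average")[target_idx])


def loocv(
    assoc: pd.DataFrame,
    ss: pd.DataFrame,
    es: pd.DataFrame,
    fs: pd.DataFrame | None = None,
    cfg: WalkConfig | None = None,
    gamma_prime: float = 1.0,
    refit_kernel: bool = True,
) -> list[LoocvRecord]:
    """Leave each known association out in turn and rank it.

    With ``refit_kernel`` (default) the interaction-profile kernel and
    integrated similarity are recomputed per fold from the masked
    matrix, so the held-out pair never influences the network it is
    ranked on. Folds whose walk hits the iteration cap are flagged
    (``converged=False``), not dropped.
    """
    cfg = cfg or WalkConfig()
    lnc_pos, dis_pos = np.nonzero(assoc.to_numpy() > 0)
    if len(lnc_pos) == 0:
        raise ValueError("LOOCV needs at least one known association")

    w_full = None
    if not refit_kernel:
        kl = gaussian_kernel_matrix(assoc, gamma_prime=gamma_prime)
        w_full = column_normalize(integrated_similarity(fs, kl))

    records: list[LoocvRecord] = []
    masked = assoc.copy()
    for li, dj in zip(lnc_pos, dis_pos):
        lnc, dis = assoc.index[li], assoc.columns[dj]
        masked.iloc[li, dj] = 0.0
        try:
            records.append(
                _loocv_fold(masked, dis, lnc, ss, es, fs, cfg, gamma_prime, w_full)
            )
        finally:
            masked.iloc[li, dj] = 1.0
    return records


def _loocv_fold(
    masked: pd.DataFrame,
    disease: str,
    lnc: str,
    ss: pd.DataFrame,
    es: pd.DataFrame,
    fs: pd.DataFrame | None,
    cfg: WalkConfig,
    gamma_prime: float,
    w_full: pd.DataFrame | None,
) -> LoocvRecord:
    cand_mask = ~(masked[disease] > 0).to_numpy()
    cand_index = masked.index[cand_mask]
    n_candidates = len(cand_index) - 1  # the held-out lncRNA is one of them
    target = int(np.nonzero(cand_index == lnc)[0][0])

    p0 = initial_probability(disease, es, ss, masked)
    if (p0.to_numpy() == 0.0).all():
        # No seed evidence after masking: the stationary vector would be
        # identically zero, so the held-out lncRNA gets the expected
        # random rank among the candidates.
        return LoocvRecord(disease, lnc, (n_candidates + 1) / 2.0, n_candidates, True)

    if w_full is None:
        kl = gaussian_kernel_matrix(masked, gamma_prime=gamma_prime)
        w = column_normalize(integrated_similarity(fs, kl))
    else:
        w = w_full
    state = walk(p0, w, cfg)
    rank = _rank_among(state.p_inf[cand_index].to_numpy(dtype=float), target)
    return LoocvRecord(disease, lnc, rank, n_candidates, False, state.converged)


def roc_auc(records: list[LoocvRecord], grid: int = 1001) -> RocCurve:
    """Pooled ROC over LOOCV records with rank-fraction thresholds.

    At threshold ``k`` a fold counts as a true positive when its
    held-out rank fraction ``rank / (N + 1)`` is at most ``k``; its
    false-positive fraction is the share of its N candidates ranked at
    or above the same cut. The grid is a uniform [0, 1] sweep refined
    with every observed rank fraction, so the step positions are exact.
    The trapezoid AUC and the closed-form rank-AUC
    ``mean((N + 1 - rank) / N)`` are both reported.
    """
    if not records:
        raise ValueError("need at least one LOOCV record")
    ranks = np.array([r.rank for r in records], dtype=float)
    ncand = np.array([r.n_candidates for r in records], dtype=float)
    frac = ranks / (ncand + 1.0)

    thresholds = np.unique(np.concatenate([np.linspace(0.0, 1.0, grid), frac, [0.0, 1.0]]))
    eps = 1e-12
    hit = frac[None, :] <= thresholds[:, None] + eps  # fold detected at threshold
    # positions occupied among the N+1 ranked transcripts at each cut
    n_above = np.floor(thresholds[:, None] * (ncand[None, :] + 1.0) + eps)
    fp = np.clip(n_above - hit, 0.0, ncand[None, :])
    tpr = hit.mean(axis=1)
    fpr = (fp / ncand[None, :]).mean(axis=1)
    auc = float(np.trapezoid(tpr, fpr))
    rank_auc = float(np.mean((ncand + 1.0 - ranks) / ncand))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, rank_auc=rank_auc)


def loocv_summary(records: list[LoocvRecord]) -> dict[str, float | int]:
    """Flat summary: AUC, rank-AUC, fold counts and fallback count."""
    curve = roc_auc(records)
    return {
        "auc": curve.auc,
        "rank_auc": curve.rank_auc,
        "n_folds": len(records),
        "n_fallback": sum(r.fallback_random for r in records),
    }


def ranking_report(
    predictions: dict[str, pd.DataFrame],
    validation: list[tuple[str, str]] | None = None,
    top_k: int = 10,
) -> dict:
    """Per-disease top-k table plus ranks of a validation list.

    `predictions` maps disease -> candidate ranking (as returned by
    :func:`irwrlda.rwr.rank_candidates`). Validation pairs absent from a
    disease's candidate universe are listed as not evaluable and
    excluded from the average rank, with a warning.
    """
    top = {
        d: ranking.head(top_k).reset_index()[["lncRNA", "score", "rank"]]
        for d, ranking in predictions.items()
    }
    rows = []
    evaluable_ranks = []
    for dis, lnc in validation or []:
        ranking = predictions.get(dis)
        if ranking is None or lnc not in ranking.index:
            warnings.warn(
                f"validation pair ({lnc!r}, {dis!r}) not evaluable; excluded from average",
                stacklevel=2,
            )
            rows.append({"disease": dis, "lncRNA": lnc, "rank": np.nan, "evaluable": False})
            continue
        rank = float(ranking.loc[lnc, "rank"])
        evaluable_ranks.append(rank)
        rows.append({"disease": dis, "lncRNA": lnc, "rank": rank, "evaluable": True})
    table = pd.DataFrame(rows, columns=["disease", "lncRNA", "rank", "evaluable"])
    avg = float(np.mean(evaluable_ranks)) if evaluable_ranks else np.nan
    return {"top": top, "validation": table, "average_rank": avg}


def zero_known_mode(
    diseases: list[str],
    assoc: pd.DataFrame,
    ss: pd.DataFrame,
    es: pd.DataFrame,
    fs: pd.DataFrame | None = None,
    cfg: WalkConfig | None = None,
    gamma_prime: float = 1.0,
) -> dict[str, pd.DataFrame]:
    """Predict for diseases stripped of *all* their known lncRNAs.

    For each listed disease every one of its associations is masked
    before the kernel and seed computation, so prediction relies purely
    on disease semantic similarity (and expression similarity carried
    through other diseases) — the regime of a disease with no known
    related lncRNAs. Returns disease -> full candidate ranking.
    """
    cfg = cfg or WalkConfig()
    out: dict[str, pd.DataFrame] = {}
    for disease in diseases:
        masked = assoc.copy()
        if disease not in masked.columns:
            raise KeyError(f"unknown disease {disease!r}")
        masked[disease] = 0.0
        p0 = initial_probability(disease, es, ss, masked)
        if (p0.to_numpy() == 0.0).all() or not (masked.to_numpy() > 0).any():
            candidates, _ = rank_candidates(p0 * 0.0, disease, masked)
        else:
            kl = gaussian_kernel_matrix(masked, gamma_prime=gamma_prime)
            w = column_normalize(integrated_similarity(fs, kl))
            state = walk(p0, w, cfg)
            candidates, _ = rank_candidates(state, disease, masked)
        out[disease] = candidates
    return out
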