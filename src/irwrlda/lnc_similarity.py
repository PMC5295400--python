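"""LncRNA similarity measures and their integration.

Three measures feed the walk and its seed vector:

* **Expression similarity (ES)** — Spearman rank correlation between
  tissue expression profiles, defined only when both transcripts are
  flagged lincRNAs (profiles exist only for lincRNAs); otherwise 0.
* **Gaussian interaction-profile kernel (KL)** — a radial-basis kernel
  on the binary association profiles ``IP(l)`` over diseases:
  ``KL(i,j) = exp(-gamma * ||IP(i) - IP(j)||^2)`` with the bandwidth
  normalized by the mean squared profile norm,
  ``gamma = gamma' / mean_i ||IP(i)||^2``.
* **Functional similarity (FS)** — a precomputed input matrix (from an
  external miRNA-mediated model); not computed here.

The integrated similarity LS averages FS and KL where FS is available
and falls back to the kernel elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

__all__ = [
    "ExpressionProfiles",
    "expression_similarity",
    "expression_matrix",
    "gaussian_kernel_matrix",
    "integrated_similarity",
]


@dataclass
class ExpressionProfiles:
    """Expression profiles (lncRNAs x tissues) plus lincRNA flags.

    Only lncRNAs flagged as lincRNAs take part in expression similarity;
    every flagged lincRNA must have a profile row and at least two
    tissue columns are required for a defined rank correlation.
    """

    profiles: pd.DataFrame
    linc_flags: pd.Series

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 tissue columns for a rank correlation")
        self.linc_flags = self.linc_flags.astype(bool)
        flagged = self.linc_flags.index[self.linc_flags]
        missing = set(flagged) - set(self.profiles.index)
        if missing:
            raise ValueError(f"flagged lincRNAs without a profile row: {sorted(missing)}")

    def is_linc(self, lnc: str) -> bool:
        return bool(self.linc_flags.get(lnc, False))


def expression_similarity(prof: ExpressionProfiles, i: str, j: str) -> float:
    """Spearman correlation of two profiles, or 0 if either is not a lincRNA.

    A constant profile has no rank variance; its correlations are
    defined as 0 (an uninformative profile carries no evidence).
    """
    if not (prof.is_linc(i) and prof.is_linc(j)):
        return 0.0
    xi = prof.profiles.loc[i].to_numpy(dtype=float)
    xj = prof.profiles.loc[j].to_numpy(dtype=float)
    if np.ptp(xi) == 0.0 or np.ptp(xj) == 0.0:
        warnings.warn(
            f"constant expression profile for {i if np.ptp(xi) == 0 else j!r}; "
            "similarity set to 0",
            stacklevel=2,
        )
        return 0.0
    if i == j:
        return 1.0
    rho = spearmanr(xi, xj).statistic
    return float(rho)


def expression_matrix(
    prof: ExpressionProfiles, order: list[str] | None = None
) -> pd.DataFrame:
    """The full ES matrix over `order` (defaults to the profile index).

    Rows/columns of lncRNAs that are not flagged lincRNAs, lack a
    profile, or have a constant profile are 0, including the diagonal.
    Ties are ranked by average rank.
    """
    if order is None:
        order = list(prof.profiles.index)
    n = len(order)
    es = np.zeros((n, n))
    active = [
        k
        for k, lnc in enumerate(order)
        if prof.is_linc(lnc)
        and lnc in prof.profiles.index
        and np.ptp(prof.profiles.loc[lnc].to_numpy(dtype=float)) > 0.0
    ]
    if active:
        x = prof.profiles.loc[[order[k] for k in active]].to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 1, x)  # average ranks for ties
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(ranks)  # Pearson on ranks == Spearman
        corr = np.atleast_2d(corr)
        np.fill_diagonal(corr, 1.0)
        es[np.ix_(active, active)] = corr
    return pd.DataFrame(es, index=list(order), columns=list(order))


def gaussian_kernel_matrix(assoc: pd.DataFrame, gamma_prime: float = 1.0) -> pd.DataFrame:
    """Gaussian interaction-profile kernel over the association rows.

    ``KL(i,j) = exp(-gamma ||IP(i)-IP(j)||^2)`` where ``IP(i)`` is row i
    of the binary lncRNA x disease matrix and the bandwidth is
    ``gamma = gamma' / (mean squared profile norm)``.

    Raises
    ------
    ValueError
        If `gamma_prime` is not positive, or the matrix has no
        associations at all (mean norm zero, bandwidth undefined).
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    ip = assoc.to_numpy(dtype=float)
    sq_norms = (ip**2).sum(axis=1)
    mean_sq = sq_norms.mean() if len(sq_norms) else 0.0
    if mean_sq == 0.0:
        raise ValueError(
            "association matrix has no associations: kernel bandwidth is undefined; "
            "provide a matrix with at least one positive association count"
        )
    gamma = gamma_prime / mean_sq
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * ip @ ip.T
    np.maximum(d2, 0.0, out=d2)
    kl = np.exp(-gamma * d2)
    np.fill_diagonal(kl, 1.0)
    return pd.DataFrame(kl, index=assoc.index, columns=assoc.index)


def integrated_similarity(
    fs: pd.DataFrame | None,
    kl: pd.DataFrame,
    if_set: set[str] | None = None,
) -> pd.DataFrame:
    """Integrated lncRNA similarity LS.

    ``LS(i,j) = (FS(i,j) + KL(i,j)) / 2`` when both i and j belong to
    the set IF of lncRNAs with functional similarity, else ``KL(i,j)``.
    With no FS matrix (pure-kernel mode) LS is the kernel itself.

    `if_set` defaults to the row-label set of `fs`.
    """
    ls = kl.copy()
    if fs is None:
        if if_set:
            raise ValueError("an IF set was given but no FS matrix")
        return ls
    if if_set is None:
        if_set = set(fs.index)
    unknown = if_set - set(kl.index)
    if unknown:
        raise KeyError(f"IF lncRNAs absent from the kernel matrix: {sorted(unknown)}")
    missing = if_set - (set(fs.index) & set(fs.columns))
    if missing:
        raise KeyError(f"FS matrix missing entries for IF lncRNAs: {sorted(missing)}")
    members = [l for l in kl.index if l in if_set]
    if not members:
        return ls
    fs_block = fs.loc[members, members]
    if (fs_block.to_numpy() < 0).any():
        bad = fs_block.stack().idxmin()
        raise ValueError(f"negative functional similarity at {bad}")
    ls.loc[members, members] = (fs_block.to_numpy() + kl.loc[members, members].to_numpy()) / 2.0
    return ls
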