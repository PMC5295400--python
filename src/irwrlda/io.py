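"""Text I/O for association lists and labeled matrices.

All artifacts are plain tab-separated text so that inputs and every
intermediate matrix (semantic, expression, kernel, integrated similarity)
are diff-able and reproducible without binary dependencies.

Conventions
-----------
* Association files: two columns ``lncRNA<TAB>disease``; lines starting
  with ``#`` are comments; duplicate pairs are collapsed on load.
* Matrix files: first row is ``.`` (corner cell) followed by column
  labels; each subsequent row starts with its row label. Floats are
  written with 12 significant digits.
* Identifier matching is case-sensitive; leading/trailing whitespace is
  trimmed. Everywhere downstream, lncRNAs index rows and diseases index
  columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationList",
    "ParseError",
    "read_associations",
    "write_associations",
    "to_matrix",
    "read_matrix",
    "write_matrix",
]


class ParseError(ValueError):
    """Raised when an input text file violates the expected dialect."""


@dataclass
class AssociationList:
    """A deduplicated list of (lncRNA, disease) association pairs.

    Parameters
    ----------
    pairs
        Distinct ``(lncRNA_id, disease_id)`` tuples, in first-seen order.
    provenance
        Free-text tag recording where the list came from.
    """

    pairs: list[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        deduped = []
        for lnc, dis in self.pairs:
            if not lnc or not dis:
                raise ValueError(f"empty identifier in pair {(lnc, dis)!r}")
            if (lnc, dis) not in seen:
                seen.add((lnc, dis))
                deduped.append((lnc, dis))
        self.pairs = deduped

    @property
    def lncrnas(self) -> list[str]:
        """Distinct lncRNA ids in first-seen order."""
        return list(dict.fromkeys(l for l, _ in self.pairs))

    @property
    def diseases(self) -> list[str]:
        """Distinct disease ids in first-seen order."""
        return list(dict.fromkeys(d for _, d in self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


def read_associations(path: str | Path, provenance: str | None = None) -> AssociationList:
    """Read a two-column lncRNA/disease association TSV.

    Duplicate pairs (the same association reported with different
    evidence) are collapsed; the count of distinct pairs is logged.

    Raises
    ------
    ParseError
        If a non-comment line does not have exactly two columns.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            lnc, dis = fields[0].strip(), fields[1].strip()
            if not lnc or not dis:
                raise ParseError(f"{path}:{lineno}: empty identifier")
            pairs.append((lnc, dis))
    assoc = AssociationList(pairs, provenance=provenance or str(path))
    logger.info("read %d lines, %d distinct pairs from %s", len(pairs), len(assoc), path)
    return assoc


def write_associations(assoc: AssociationList, path: str | Path) -> None:
    """Write an association list as two-column TSV (one pair per line)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# lncRNA\tdisease\n")
        for lnc, dis in assoc.pairs:
            fh.write(f"{lnc}\t{dis}\n")


def read_flags(path: str | Path) -> pd.Series:
    """Read a two-column ``lncRNA<TAB>0/1`` lincRNA flag TSV as a bool Series."""
    path = Path(path)
    ids: list[str] = []
    vals: list[bool] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'lncRNA<TAB>flag'")
            ids.append(fields[0].strip())
            vals.append(fields[1].strip() not in ("0", "false", "False"))
    _check_unique(ids, "lncRNA", str(path))
    return pd.Series(vals, index=ids)


def _check_unique(labels: list[str], axis: str, where: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ParseError(f"{where}: duplicate {axis} label {lab!r}")
        seen.add(lab)


def to_matrix(
    assoc: AssociationList, lnc_order: list[str], dis_order: list[str]
) -> pd.DataFrame:
    """Build the binary lncRNA x disease incidence matrix.

    Entry ``(l, d)`` is 1.0 iff the pair is present in `assoc`, else 0.0.
    Every id appearing in `assoc` must be listed in the given orders.
    """
    _check_unique(list(lnc_order), "row", "to_matrix")
    _check_unique(list(dis_order), "column", "to_matrix")
    mat = pd.DataFrame(
        np.zeros((len(lnc_order), len(dis_order))),
        index=list(lnc_order),
        columns=list(dis_order),
    )
    lnc_set, dis_set = set(lnc_order), set(dis_order)
    for lnc, dis in assoc.pairs:
        if lnc not in lnc_set:
            raise KeyError(f"lncRNA id {lnc!r} not in the given lncRNA order")
        if dis not in dis_set:
            raise KeyError(f"disease id {dis!r} not in the given disease order")
        mat.loc[lnc, dis] = 1.0
    return mat


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a labeled matrix as TSV (corner cell ``.``, 12 sig. digits)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(".\t" + "\t".join(str(c) for c in matrix.columns) + "\n")
        for label, row in zip(matrix.index, matrix.to_numpy()):
            fh.write(str(label) + "\t" + "\t".join(f"{v:.12g}" for v in row) + "\n")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix written by :func:`write_matrix`.

    Round-trips with :func:`write_matrix`: labels are preserved exactly
    and values to better than 1e-12 relative error.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != ".":
            raise ParseError(f"{path}:1: matrix header must start with the '.' corner cell")
        col_labels = [c.strip() for c in header[1:]]
        _check_unique(col_labels, "column", str(path))
        row_labels: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != len(col_labels) + 1:
                raise ParseError(
                    f"{path}:{lineno}: ragged row — expected {len(col_labels) + 1} "
                    f"fields, got {len(fields)}"
                )
            row_labels.append(fields[0].strip())
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric value ({exc})") from exc
        _check_unique(row_labels, "row", str(path))
    return pd.DataFrame(np.asarray(rows, dtype=float), index=row_labels, columns=col_labels)
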