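"""Sparse label matrix: votes in {-1, +1}, absence means abstain.

The on-disk convention mirrors the in-memory one: an abstention is simply an
absent entry, never a stored zero.  Dense views encode abstain as 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["LabelMatrix"]


def _default_ids(prefix: str, k: int) -> list[str]:
    width = len(str(max(k - 1, 0)))
    return [f"{prefix}{i:0{width}d}" for i in range(k)]


class LabelMatrix:
    """An m x n matrix of labeling-function votes.

    Parameters
    ----------
    votes : array-like or sparse matrix of shape (m, n)
        Entries in {-1, 0, +1}; zeros are treated as abstentions and are
        never stored.
    row_ids : sequence of str, optional
        Candidate identifiers (length m).  Generated if omitted.
    col_names : sequence of str, optional
        Labeling-function names (length n).  Generated if omitted.
    """

    def __init__(self, votes, row_ids=None, col_names=None):
        mat = sp.csr_matrix(votes, dtype=np.int8)
        mat.eliminate_zeros()
        bad = np.setdiff1d(np.unique(mat.data), [-1, 1])
        if bad.size:
            raise ValueError(f"votes must lie in {{-1,+1}}; found {bad.tolist()}")
        self._mat = mat
        m, n = mat.shape
        self.row_ids = list(row_ids) if row_ids is not None else _default_ids("c", m)
        self.col_names = list(col_names) if col_names is not None else _default_ids("lf", n)
        if len(self.row_ids) != m:
            raise ValueError(f"row_ids has length {len(self.row_ids)}, expected {m}")
        if len(self.col_names) != n:
            raise ValueError(f"col_names has length {len(self.col_names)}, expected {n}")
        if len(set(self.col_names)) != n:
            raise ValueError("col_names must be unique")

    # -- basic views -------------------------------------------------------
    @property
    def m(self) -> int:
        return self._mat.shape[0]

    @property
    def n(self) -> int:
        return self._mat.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self._mat.shape

    @property
    def sparse(self) -> sp.csr_matrix:
        return self._mat

    def toarray(self) -> np.ndarray:
        """Dense int8 view with 0 for abstain."""
        return self._mat.toarray()

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabelMatrix):
            return NotImplemented
        return (
            self.shape == other.shape
            and self.row_ids == other.row_ids
            and self.col_names == other.col_names
            and (self._mat != other._mat).nnz == 0
        )

    def __repr__(self) -> str:
        return f"LabelMatrix(m={self.m}, n={self.n}, nnz={self._mat.nnz})"

    # -- MatrixMarket ------------------------------------------------------
    def to_mtx(self, path) -> None:
        """Write coordinate MatrixMarket plus ``.rows.txt``/``.cols.txt`` sidecars."""
        path = Path(path)
        mmwrite(str(path), self._mat.tocoo(), field="integer")
        path.with_suffix(".rows.txt").write_text("\n".join(self.row_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(self.col_names) + "\n")

    @classmethod
    def from_mtx(cls, path) -> "LabelMatrix":
        path = Path(path)
        mat = mmread(str(path))
        row_ids = col_names = None
        rows_file = path.with_suffix(".rows.txt")
        cols_file = path.with_suffix(".cols.txt")
        if rows_file.exists():
            row_ids = rows_file.read_text().splitlines()
        if cols_file.exists():
            col_names = cols_file.read_text().splitlines()
        return cls(mat, row_ids=row_ids, col_names=col_names)

    # -- long-form TSV -----------------------------------------------------
    def to_long_tsv(self, path) -> None:
        """Write (candidate_id, lf_name, vote) rows; abstentions are absent."""
        coo = self._mat.tocoo()
        frame = pd.DataFrame(
            {
                "candidate_id": [self.row_ids[i] for i in coo.row],
                "lf_name": [self.col_names[j] for j in coo.col],
                "vote": coo.data.astype(int),
            }
        )
        frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_tsv(cls, path, row_ids=None, col_names=None) -> "LabelMatrix":
        frame = pd.read_csv(path, sep="\t", dtype={"candidate_id": str, "lf_name": str})
        if row_ids is None:
            row_ids = list(dict.fromkeys(frame["candidate_id"]))
        if col_names is None:
            col_names = list(dict.fromkeys(frame["lf_name"]))
        ri = {r: i for i, r in enumerate(row_ids)}
        ci = {c: j for j, c in enumerate(col_names)}
        rows = frame["candidate_id"].map(ri).to_numpy()
        cols = frame["lf_name"].map(ci).to_numpy()
        mat = sp.coo_matrix(
            (frame["vote"].to_numpy(), (rows, cols)), shape=(len(row_ids), len(col_names))
        )
        return cls(mat, row_ids=row_ids, col_names=col_names)


def as_votes(L) -> np.ndarray:
    """Coerce a LabelMatrix / sparse matrix / array to a dense int8 vote array."""
    if isinstance(L, LabelMatrix):
        return L.toarray()
    if sp.issparse(L):
        return L.toarray().astype(np.int8)
    arr = np.asarray(L)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D label matrix, got shape {arr.shape}")
    out = arr.astype(np.int8)
    if not np.array_equal(out, arr):
        raise ValueError("votes must be integers in {-1,0,+1}")
    if not np.isin(out, (-1, 0, 1)).all():
        raise ValueError("votes must lie in {-1,0,+1}")
    return out
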