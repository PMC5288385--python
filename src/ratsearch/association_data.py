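"""Association matrices: loading, transforming and pruning.

The central object is a labelled, sparse, non-negative N x N matrix of
associative strengths, row = cue, column = target.  Two families of
source data are supported through one common container:

* free-association norms -- normed response frequencies from cued
  free-association experiments (strengths in (0, 1], strongly
  asymmetric: *left* evokes *right* far more than *right* evokes *left*);
* co-occurrence counts -- bigram and compound-word counts from a text
  corpus (non-negative integers, symmetric by construction).

Transformations produce the variants the search model and the response
filter consume: binarised (association existence only), symmetrised
(``A + A^T``), and randomly pruned (modelling individual differences in
associative networks by deleting a fraction of the links).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Tuple, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "AssociationMatrix",
    "ParseError",
    "load_norms",
    "save_norms",
    "binarize",
    "symmetrize",
    "prune",
    "build_from_bigrams",
    "load_bigram_table",
    "load_compound_table",
]


class ParseError(Exception):
    """Raised for malformed rows in a norms/count table."""


@dataclass
class AssociationMatrix:
    """Labelled sparse matrix of associative strengths.

    ``strengths[i, j]`` is the strength from cue ``labels[i]`` to target
    ``labels[j]``.  Entries are non-negative, the diagonal is zero and
    binary kinds contain only {0, 1}.  Storage is CSR throughout; none of
    the operations in this module densify the matrix.
    """

    labels: list
    strengths: sp.csr_matrix
    kind: str = "raw"
    provenance: str = ""
    _index: dict = field(init=False, repr=False)

    VALID_KINDS = ("raw", "binary", "symmetric-raw", "binary-symmetric")

    def __post_init__(self) -> None:
        self.labels = [str(w).lower() for w in self.labels]
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if self.kind not in self.VALID_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        self.strengths = sp.csr_matrix(self.strengths, dtype=float)
        n = len(self.labels)
        if self.strengths.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.strengths.shape} does not match "
                f"{n} labels"
            )
        if self.strengths.nnz and self.strengths.data.min() < 0:
            raise ValueError("association strengths must be non-negative")
        diag = self.strengths.diagonal()
        if np.any(diag != 0):
            raise ValueError("association matrix diagonal must be zero")
        if self.kind.startswith("binary") and self.strengths.nnz:
            vals = np.unique(self.strengths.data)
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("binary matrix contains values other than 0/1")
        self._index = {w: i for i, w in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, word: str) -> bool:
        return str(word).lower() in self._index

    def index(self, word: str) -> int:
        return self._index[str(word).lower()]

    def strength(self, cue: str, target: str) -> float:
        """Strength from cue to target; 0 for words not in the matrix."""
        try:
            i, j = self.index(cue), self.index(target)
        except KeyError:
            return 0.0
        return float(self.strengths[i, j])

    def associates(self, word: str) -> list:
        """Targets with non-zero strength from ``word``, strongest first."""
        i = self.index(word)
        row = self.strengths.getrow(i).tocoo()
        order = np.argsort(-row.data)
        return [self.labels[j] for j in row.col[order]]

    @property
    def nnz(self) -> int:
        return self.strengths.nnz


def _iter_table_rows(path: Union[str, Path], n_fields: int):
    """Yield (line_number, fields) from a TSV, skipping comments/blanks.

    A first row whose last field does not parse as a number is treated as
    an optional header and skipped.
    """
    first_data_row = True
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != n_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected {n_fields} tab-separated "
                    f"fields, got {len(fields)}"
                )
            if first_data_row:
                first_data_row = False
                try:
                    float(fields[-1])
                except ValueError:
                    continue  # header
            yield lineno, fields


def load_norms(path: Union[str, Path], provenance: Optional[str] = None) -> AssociationMatrix:
    """Load a cue / target / strength TSV into an association matrix.

    Words are lowercased; the label set is the union of all words seen,
    in order of first appearance; duplicate (cue, target) rows are
    summed; unseen pairs are zero.
    """
    labels: list = []
    index: dict = {}
    rows, cols, vals = [], [], []
    for lineno, (cue, target, strength) in (
        (ln, f) for ln, f in _iter_table_rows(path, 3)
    ):
        cue, target = cue.strip().lower(), target.strip().lower()
        try:
            value = float(strength)
        except ValueError as exc:
            raise ParseError(
                f"{path}:{lineno}: strength {strength!r} is not a number"
            ) from exc
        if value < 0:
            raise ParseError(f"{path}:{lineno}: negative strength {value}")
        for w in (cue, target):
            if w not in index:
                index[w] = len(labels)
                labels.append(w)
        if cue == target:
            continue  # self-associations are undefined; diagonal stays zero
        rows.append(index[cue])
        cols.append(index[target])
        vals.append(value)
    n = len(labels)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    mat.sum_duplicates()
    mat.eliminate_zeros()
    return AssociationMatrix(
        labels=labels, strengths=mat, kind="raw",
        provenance=provenance or f"norms:{path}",
    )


def save_norms(matrix: AssociationMatrix, path: Union[str, Path]) -> None:
    """Write the non-zero entries as a cue / target / strength TSV."""
    coo = matrix.strengths.tocoo()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("cue\ttarget\tstrength\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{matrix.labels[i]}\t{matrix.labels[j]}\t{float(v)!r}\n")


def binarize(matrix: AssociationMatrix) -> AssociationMatrix:
    """Map every non-zero strength to 1, keeping only link existence."""
    out = matrix.strengths.copy()
    out.data = np.ones_like(out.data)
    kind = "binary-symmetric" if "symmetric" in matrix.kind else "binary"
    return AssociationMatrix(
        labels=list(matrix.labels), strengths=out, kind=kind,
        provenance=f"binarize({matrix.provenance})",
    )


def symmetrize(matrix: AssociationMatrix) -> AssociationMatrix:
    """Sum the matrix with its transpose, making associations reciprocal."""
    out = (matrix.strengths + matrix.strengths.T).tocsr()
    kind = "symmetric-raw"
    return AssociationMatrix(
        labels=list(matrix.labels), strengths=out, kind=kind,
        provenance=f"symmetrize({matrix.provenance})",
    )


def prune(
    matrix: AssociationMatrix,
    fraction: float,
    seed: Optional[int] = None,
    couple_symmetric: bool = False,
) -> AssociationMatrix:
    """Randomly remove a fraction of the associations.

    Exactly ``round(fraction * nnz)`` non-zero entries, selected uniformly
    without replacement, are set to zero; the surviving entries keep their
    values.  With ``couple_symmetric=True`` removal acts on unordered word
    pairs, so dropping i->j also drops j->i.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    coo = matrix.strengths.tocoo()
    if couple_symmetric:
        pair_ids = {}
        entry_pair = np.empty(coo.nnz, dtype=int)
        for k, (i, j) in enumerate(zip(coo.row, coo.col)):
            key = (min(i, j), max(i, j))
            entry_pair[k] = pair_ids.setdefault(key, len(pair_ids))
        n_pairs = len(pair_ids)
        n_remove = int(round(fraction * n_pairs))
        removed = set(rng.choice(n_pairs, size=n_remove, replace=False).tolist())
        keep = np.array([p not in removed for p in entry_pair])
    else:
        n_remove = int(round(fraction * coo.nnz))
        removed_idx = rng.choice(coo.nnz, size=n_remove, replace=False)
        keep = np.ones(coo.nnz, dtype=bool)
        keep[removed_idx] = False
    out = sp.coo_matrix(
        (coo.data[keep], (coo.row[keep], coo.col[keep])),
        shape=coo.shape,
    ).tocsr()
    return AssociationMatrix(
        labels=list(matrix.labels), strengths=out, kind=matrix.kind,
        provenance=f"prune({matrix.provenance}, fraction={fraction}, seed={seed})",
    )


def load_bigram_table(path: Union[str, Path]) -> dict:
    """Load a ``w1 <TAB> w2 <TAB> count`` TSV into a dict keyed by pairs."""
    table: dict = {}
    for lineno, (w1, w2, count) in ((ln, f) for ln, f in _iter_table_rows(path, 3)):
        c = _parse_count(count, path, lineno)
        key = (w1.strip().lower(), w2.strip().lower())
        table[key] = table.get(key, 0) + c
    return table


def load_compound_table(path: Union[str, Path]) -> dict:
    """Load a ``token <TAB> count`` TSV into a dict keyed by tokens."""
    table: dict = {}
    for lineno, (token, count) in ((ln, f) for ln, f in _iter_table_rows(path, 2)):
        c = _parse_count(count, path, lineno)
        key = token.strip().lower()
        table[key] = table.get(key, 0) + c
    return table


def _parse_count(raw: str, path, lineno: int) -> int:
    try:
        value = int(float(raw))
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: count {raw!r} is not a number") from exc
    if value < 0:
        raise ParseError(f"{path}:{lineno}: negative count {value}")
    return value


def build_from_bigrams(
    bigram_counts: Mapping[Tuple[str, str], int],
    compound_counts: Mapping[str, int],
    word_list: Iterable[str],
) -> AssociationMatrix:
    """Build a co-occurrence matrix from bigram and compound-word counts.

    The strength of the pair (w1, w2) is the number of occurrences of the
    2-gram "w1 w2" plus the number of occurrences of the 1-gram "w1w2"
    (the compound written as one token, e.g. *fire* + *fly* -> *firefly*).
    Only words in ``word_list`` participate; pairs absent from both count
    tables get strength zero.  Compound tokens that split into two listed
    words at more than one position contribute their count to every valid
    split.
    """
    labels = [str(w).lower() for w in word_list]
    index = {w: i for i, w in enumerate(labels)}
    n = len(labels)
    acc: dict = {}

    for (w1, w2), count in bigram_counts.items():
        if count < 0:
            raise ValueError(f"negative bigram count for ({w1}, {w2})")
        w1, w2 = str(w1).lower(), str(w2).lower()
        if w1 in index and w2 in index and w1 != w2:
            key = (index[w1], index[w2])
            acc[key] = acc.get(key, 0) + count

    for token, count in compound_counts.items():
        if count < 0:
            raise ValueError(f"negative compound count for {token!r}")
        token = str(token).lower()
        for split in range(1, len(token)):
            w1, w2 = token[:split], token[split:]
            if w1 in index and w2 in index and w1 != w2:
                key = (index[w1], index[w2])
                acc[key] = acc.get(key, 0) + count

    if acc:
        rows, cols = zip(*acc.keys())
        mat = sp.coo_matrix(
            (list(acc.values()), (rows, cols)), shape=(n, n)
        ).tocsr()
    else:
        mat = sp.csr_matrix((n, n))
    mat.eliminate_zeros()
    return AssociationMatrix(
        labels=labels, strengths=mat, kind="raw", provenance="bigrams",
    )
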