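"""Labeled matrix I/O and dataset-bundle assembly.

The canonical on-disk format is a header-row/header-column TSV: the first row
holds column identifiers preceded by an empty cell, the first column holds row
identifiers, and the body holds decimal numbers.  A dataset bundle groups the
binary drug–disease association matrix with any number of named drug–drug and
disease–disease similarity matrices, all re-indexed to the association
matrix's identifier order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledMatrix",
    "DatasetBundle",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_matrix_mat",
    "load_bundle",
    "write_ranked_predictions",
]


class MatrixFormatError(ValueError):
    """Raised for malformed labeled-matrix files (ragged rows, bad cells)."""


class AlignmentError(ValueError):
    """Raised when matrix identifiers cannot be aligned across files."""


@dataclass
class LabeledMatrix:
    """A dense real matrix with ordered, unique row and column identifiers."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        self.row_ids = [str(r) for r in self.row_ids]
        self.col_ids = [str(c) for c in self.col_ids]
        if len(self.row_ids) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {self.values.shape[0]} rows"
            )
        if len(self.col_ids) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.col_ids)} col ids for {self.values.shape[1]} columns"
            )
        for ids, kind in ((self.row_ids, "row"), (self.col_ids, "column")):
            if len(set(ids)) != len(ids):
                dup = next(x for x in ids if ids.count(x) > 1)
                raise MatrixFormatError(f"duplicate {kind} id {dup!r}")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def reindex(self, row_ids: list[str], col_ids: list[str]) -> "LabeledMatrix":
        """Return a copy reordered to the given id order.

        Raises :class:`AlignmentError` listing the ids missing from this
        matrix when the requested order is not a permutation of its ids.
        """
        missing_r = [r for r in row_ids if r not in set(self.row_ids)]
        missing_c = [c for c in col_ids if c not in set(self.col_ids)]
        if missing_r or missing_c:
            raise AlignmentError(
                f"missing row ids {missing_r[:5]} / column ids {missing_c[:5]}"
            )
        rpos = {r: i for i, r in enumerate(self.row_ids)}
        cpos = {c: i for i, c in enumerate(self.col_ids)}
        ridx = [rpos[r] for r in row_ids]
        cidx = [cpos[c] for c in col_ids]
        return LabeledMatrix(self.values[np.ix_(ridx, cidx)], list(row_ids), list(col_ids))


@dataclass
class DatasetBundle:
    """Binary association matrix plus named similarity matrices per entity type.

    Invariants: every drug similarity is indexed by the association matrix's
    row (drug) ids, every disease similarity by its column (disease) ids,
    associations are strictly 0/1 and similarities lie in [0, 1].
    """

    association: LabeledMatrix
    drug_sims: dict[str, LabeledMatrix] = field(default_factory=dict)
    disease_sims: dict[str, LabeledMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = self.association.values
        if a.size and not np.all(np.isin(a, (0.0, 1.0))):
            raise ValueError("association matrix must be strictly binary")
        for name, s in list(self.drug_sims.items()) + list(self.disease_sims.items()):
            if s.values.size and (s.values.min() < 0 or s.values.max() > 1):
                raise ValueError(f"similarity {name!r} has values outside [0, 1]")

    @property
    def drug_ids(self) -> list[str]:
        return self.association.row_ids

    @property
    def disease_ids(self) -> list[str]:
        return self.association.col_ids


def read_matrix_tsv(path: str | os.PathLike) -> LabeledMatrix:
    """Read a labeled matrix from the header-row/header-column TSV dialect."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    col_ids = header[1:]
    row_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(col_ids) + 1:
            raise MatrixFormatError(
                f"{path}:{lineno}: ragged row {cells[0]!r}: "
                f"expected {len(col_ids)} cells, found {len(cells) - 1}"
            )
        row_ids.append(cells[0])
        parsed = []
        for col_id, cell in zip(col_ids, cells[1:]):
            try:
                parsed.append(float(cell))
            except ValueError:
                raise MatrixFormatError(
                    f"{path}:{lineno}: non-numeric cell at row {cells[0]!r}, "
                    f"column {col_id!r}: {cell!r}"
                ) from None
        rows.append(parsed)
    values = np.asarray(rows, dtype=float).reshape(len(row_ids), len(col_ids))
    return LabeledMatrix(values, row_ids, col_ids)


def write_matrix_tsv(m: LabeledMatrix, path: str | os.PathLike) -> None:
    """Write a labeled matrix in the dialect read by :func:`read_matrix_tsv`.

    Values are written with `repr` so a round trip reproduces them exactly.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t" + "\t".join(m.col_ids) + "\n")
        for rid, row in zip(m.row_ids, m.values):
            fh.write(rid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_matrix_mat(
    path: str | os.PathLike,
    values_key: str,
    row_ids_key: str | None = None,
    col_ids_key: str | None = None,
) -> LabeledMatrix:
    """Best-effort import of a matrix from a MATLAB v5 container file.

    ``values_key`` names the matrix variable; ``row_ids_key``/``col_ids_key``
    optionally name cell arrays of identifiers.  Positional identifiers
    (``R0001``.../``D0001``...) are generated when id variables are absent.
    """
    from scipy.io import loadmat

    raw = loadmat(os.fspath(path))
    if values_key not in raw:
        raise KeyError(f"{path}: no variable {values_key!r}")
    values = np.asarray(raw[values_key], dtype=float)

    def _ids(key: str | None, count: int, prefix: str) -> list[str]:
        if key is None or key not in raw:
            return [f"{prefix}{i + 1:04d}" for i in range(count)]
        flat = np.asarray(raw[key]).ravel()
        return [str(np.asarray(x).ravel()[0]) for x in flat]

    return LabeledMatrix(
        values,
        _ids(row_ids_key, values.shape[0], "R"),
        _ids(col_ids_key, values.shape[1], "D"),
    )


def load_bundle(
    assoc_path: str | os.PathLike,
    drug_sim_paths: dict[str, str | os.PathLike],
    disease_sim_paths: dict[str, str | os.PathLike],
) -> DatasetBundle:
    """Read association + similarity TSVs and align them into a bundle.

    Similarity matrices are re-indexed to the association matrix's id order,
    so the input files' row/column ordering is irrelevant.
    """
    assoc = read_matrix_tsv(assoc_path)
    drug_sims = {
        name: read_matrix_tsv(p).reindex(assoc.row_ids, assoc.row_ids)
        for name, p in drug_sim_paths.items()
    }
    disease_sims = {
        name: read_matrix_tsv(p).reindex(assoc.col_ids, assoc.col_ids)
        for name, p in disease_sim_paths.items()
    }
    return DatasetBundle(assoc, drug_sims, disease_sims)


def write_ranked_predictions(
    scores: LabeledMatrix,
    training: LabeledMatrix,
    path: str | os.PathLike,
    top_k: int,
) -> None:
    """Write the top-``top_k`` novel candidates per drug as a ranked TSV.

    Pairs already positive in ``training`` are excluded.  Rows are sorted by
    score descending within each drug; equal scores are ordered by disease id.
    Columns: drug_id, disease_id, score, rank.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if scores.shape != training.shape:
        raise AlignmentError("scores and training matrices differ in shape")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_id\tdisease_id\tscore\trank\n")
        for i, drug in enumerate(scores.row_ids):
            candidates = [
                (-scores.values[i, j], scores.col_ids[j], scores.values[i, j])
                for j in range(scores.shape[1])
                if training.values[i, j] == 0
            ]
            candidates.sort()
            for rank, (_, disease, score) in enumerate(candidates[:top_k], start=1):
                fh.write(f"{drug}\t{disease}\t{float(score)!r}\t{rank}\n")
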