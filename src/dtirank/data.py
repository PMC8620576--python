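"""Containers and I/O for interaction and similarity matrices.

The on-disk dialect is the tab-separated layout used by the public
gold-standard DTI datasets: first row holds column identifiers, first
column holds row identifiers, and the body holds the matrix entries.
Interaction files ("admat") are binary; similarity files ("simmat") hold
real scores in [0, 1].  In memory the canonical orientation is always
drugs x targets; the public admat files store targets as rows, which the
``auto`` orientation detects via the ``hsa`` protein-identifier prefix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class MatrixFormatError(ValueError):
    """Raised when a matrix file violates the dialect or a container invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise MatrixFormatError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class InteractionMatrix:
    """Binary drug-target interaction matrix Y (n drugs x m targets).

    ``values[d, t] == 1`` iff drug ``drugs[d]`` is experimentally verified
    to interact with target ``targets[t]``; 0 means unobserved (one-class
    data, not a confirmed negative).
    """

    drugs: list[str]
    targets: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.drugs = list(self.drugs)
        self.targets = list(self.targets)
        self.values = np.asarray(self.values)
        _check_unique(self.drugs, "drug")
        _check_unique(self.targets, "target")
        if self.values.shape != (len(self.drugs), len(self.targets)):
            raise MatrixFormatError(
                f"shape {self.values.shape} does not match "
                f"({len(self.drugs)} drugs, {len(self.targets)} targets)"
            )
        bad = ~np.isin(self.values, (0, 1))
        if bad.any():
            d, t = np.argwhere(bad)[0]
            raise MatrixFormatError(
                f"non-binary entry {self.values[d, t]!r} at "
                f"row {self.drugs[d]!r}, column {self.targets[t]!r}"
            )
        self.values = self.values.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_interactions(self) -> int:
        return int(self.values.sum())

    def positive_targets(self, d: int) -> np.ndarray:
        """Indices of verified targets for drug ``d`` (the set V_d^+)."""
        return np.flatnonzero(self.values[d] == 1)

    def negative_targets(self, d: int) -> np.ndarray:
        """Indices of unobserved targets for drug ``d`` (the set V_d^-)."""
        return np.flatnonzero(self.values[d] == 0)

    def positive_pairs(self) -> np.ndarray:
        """All verified (drug, target) index pairs, shape (V, 2)."""
        return np.argwhere(self.values == 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.targets == other.targets
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix over one identifier set.

    Values are unitless scores in [0, 1] (e.g. SIMCOMP common-substructure
    similarity for compounds, normalized Smith-Waterman for proteins) with
    unit diagonal.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.ids, "similarity")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise MatrixFormatError(f"similarity matrix not square: {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise MatrixFormatError("similarity matrix not symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-6):
            raise MatrixFormatError("similarity diagonal not 1")
        if self.values.min() < 0 or self.values.max() > 1:
            raise MatrixFormatError("similarity entries outside [0, 1]")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SimilarityMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.values, other.values)


@dataclass
class Dataset:
    """An interaction matrix plus optional drug/target similarity side information."""

    interactions: InteractionMatrix
    drug_sim: Optional[SimilarityMatrix] = None
    target_sim: Optional[SimilarityMatrix] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.drug_sim is not None and self.drug_sim.ids != self.interactions.drugs:
            raise MatrixFormatError("drug similarity identifiers do not match interaction drugs")
        if self.target_sim is not None and self.target_sim.ids != self.interactions.targets:
            raise MatrixFormatError(
                "target similarity identifiers do not match interaction targets"
            )


def _read_table(path) -> pd.DataFrame:
    # pandas silently renames duplicate column labels, so check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique([h for h in header[1:] if h != ""], "column")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixFormatError(f"malformed tab-separated file {path}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise MatrixFormatError(f"duplicate row identifier: {dup!r}")
    return df


Orientation = Literal["drugs_as_rows", "drugs_as_columns", "auto"]

#: Row-identifier prefix marking protein (target) rows in the public admat files.
TARGET_ID_PREFIX = "hsa"


def read_interaction_matrix(path, orientation: Orientation = "auto") -> InteractionMatrix:
    """Read a binary interaction matrix from a tab-separated admat-style file.

    ``orientation`` controls which axis holds drugs.  With ``auto`` the file
    is transposed when the row identifiers carry the ``hsa`` protein prefix
    (the convention of the public files, which store targets as rows), so
    the returned matrix is always drugs x targets.
    """
    df = _read_table(path)
    try:
        body = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric entry in {path}: {exc}") from exc
    if not np.isin(body, (0.0, 1.0)).all():
        r, c = np.argwhere(~np.isin(body, (0.0, 1.0)))[0]
        raise MatrixFormatError(
            f"non-binary entry {body[r, c]} at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "auto":
        rows_are_targets = all(str(r).startswith(TARGET_ID_PREFIX) for r in df.index)
        orientation = "drugs_as_columns" if rows_are_targets else "drugs_as_rows"
    if orientation == "drugs_as_columns":
        df = df.T
        body = body.T
    mat = InteractionMatrix(list(df.index), list(df.columns), body.astype(np.int8))
    logger.info(
        "read interaction matrix: %d drugs, %d targets, %d interactions",
        mat.n_drugs,
        mat.n_targets,
        mat.n_interactions,
    )
    return mat


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a similarity matrix, symmetrizing by averaging and clipping to [0, 1].

    Real SIMCOMP exports can be slightly asymmetric; ingestion replaces S
    with (S + S^T)/2, forces the diagonal to 1, and clips out-of-range
    values, logging the largest correction applied.
    """
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise MatrixFormatError(f"similarity matrix not square: {df.shape}")
    if list(df.index) != list(df.columns):
        if set(df.index) == set(df.columns):
            df = df.loc[:, list(df.index)]
        else:
            raise MatrixFormatError("row and column identifier sets differ")
    try:
        raw = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"non-numeric entry in {path}: {exc}") from exc
    sym = (raw + raw.T) / 2.0
    asym = float(np.abs(raw - raw.T).max()) / 2.0
    clipped = np.clip(sym, 0.0, 1.0)
    clip_corr = float(np.abs(sym - clipped).max())
    np.fill_diagonal(clipped, 1.0)
    if asym > 0 or clip_corr > 0:
        logger.warning(
            "similarity ingestion corrections: max symmetrization %.3g, max clip %.3g",
            asym,
            clip_corr,
        )
    return SimilarityMatrix(list(df.index), clipped)


def write_interaction_matrix(path, mat: InteractionMatrix) -> None:
    """Write an interaction matrix in the same tab-separated dialect (drugs as rows)."""
    pd.DataFrame(mat.values, index=mat.drugs, columns=mat.targets).to_csv(path, sep="\t")


def write_similarity_matrix(path, sim: SimilarityMatrix) -> None:
    pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids).to_csv(path, sep="\t")


def write_predictions(
    path, rows: Iterable[tuple[str, str, float, int]]
) -> None:
    """Write ranked predictions as a TSV with header drug/target/score/rank.

    ``rows`` must already be sorted by (drug, rank); scores are serialized
    with six decimal places.
    """
    with open(path, "w") as fh:
        fh.write("drug\ttarget\tscore\trank\n")
        for drug, target, score, rank in rows:
            fh.write(f"{drug}\t{target}\t{score:.6f}\t{rank}\n")
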