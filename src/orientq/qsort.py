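"""Objective Q-sorting: similarity scoring and the forced quasi-normal grid.

Instead of human participants ranking statements, every institution's
aggregated text embedding is scored against each statement by cosine
similarity, and the scores are forced into a fixed symmetric grid of
integer levels (-5 .. +5 by default).  Scores are used only ordinally:
any strictly increasing transform of a score row yields the same Q-sort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .corpus import AuditCorpus
from .embedding import EmbeddingMatrix, cosine_matrix
from .errors import ConfigError, SchemaError


@dataclass
class QGrid:
    """Forced-distribution grid: how many statements receive each level."""

    column_values: np.ndarray
    column_counts: np.ndarray

    def __post_init__(self):
        self.column_values = np.asarray(self.column_values, dtype=int)
        self.column_counts = np.asarray(self.column_counts, dtype=int)
        if self.column_values.shape != self.column_counts.shape:
            raise ConfigError("grid values and counts must align")
        if np.any(np.diff(self.column_values) <= 0):
            raise ConfigError("grid values must be strictly increasing")
        if not np.array_equal(self.column_values, -self.column_values[::-1]):
            raise ConfigError("grid values must be symmetric about 0")
        if not np.array_equal(self.column_counts, self.column_counts[::-1]):
            raise ConfigError("grid counts must be symmetric")
        if np.any(self.column_counts < 1):
            raise ConfigError("grid counts must be positive")

    @property
    def n_statements(self) -> int:
        return int(self.column_counts.sum())

    @property
    def n_levels(self) -> int:
        return len(self.column_values)

    @classmethod
    def default_54(cls) -> "QGrid":
        """11-level quasi-normal grid for a 54-statement Q sample."""
        return cls(
            column_values=np.arange(-5, 6),
            column_counts=np.array([2, 3, 5, 6, 7, 8, 7, 6, 5, 3, 2]),
        )

    @classmethod
    def quasi_normal(cls, n_statements: int, n_levels: int = 11) -> "QGrid":
        """Build a symmetric quasi-normal grid for an arbitrary statement
        count by rounding a discretized normal profile and repairing the
        total symmetrically."""
        if n_levels % 2 == 0 or n_levels < 3:
            raise ConfigError("n_levels must be odd and >= 3")
        half = n_levels // 2
        values = np.arange(-half, half + 1)
        weights = np.exp(-0.5 * (values / (half / 2.0)) ** 2)
        counts = np.maximum(1, np.round(weights / weights.sum() * n_statements).astype(int))
        # repair the total while keeping symmetry: adjust pairs inward/outward
        def total():
            return int(counts.sum())

        i = 0
        order = np.argsort(-weights)  # touch the most populated levels first
        while total() != n_statements:
            j = order[i % n_levels]
            jj = n_levels - 1 - j
            delta = 1 if total() < n_statements else -1
            if j == jj:
                if counts[j] + delta >= 1:
                    counts[j] += delta
            else:
                if counts[j] + delta >= 1 and counts[jj] + delta >= 1 and abs(
                    total() - n_statements
                ) >= 2:
                    counts[j] += delta
                    counts[jj] += delta
                else:
                    mid = n_levels // 2
                    if counts[mid] + delta >= 1:
                        counts[mid] += delta
            i += 1
        return cls(column_values=values, column_counts=counts)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(
                {
                    "column_values": self.column_values.tolist(),
                    "column_counts": self.column_counts.tolist(),
                },
                fh,
            )

    @classmethod
    def from_yaml(cls, path) -> "QGrid":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            column_values=np.asarray(raw["column_values"]),
            column_counts=np.asarray(raw["column_counts"]),
        )


@dataclass
class SimilarityScores:
    """Institutions x statements cosine similarity matrix."""

    matrix: np.ndarray
    institution_ids: list[str]
    statement_ids: list[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.institution_ids), len(self.statement_ids)):
            raise SchemaError("similarity matrix shape does not match the id lists")
        if np.any(np.isnan(self.matrix)):
            raise SchemaError("similarity matrix contains missing cells")
        if np.any(np.abs(self.matrix) > 1.0 + 1e-9):
            raise SchemaError("cosine similarities must lie in [-1, 1]")


def aggregate_institution(
    corpus: AuditCorpus, record_embeddings: EmbeddingMatrix
) -> tuple[list[str], np.ndarray]:
    """L2-normalized mean of each institution's record vectors.

    ``record_embeddings`` rows must align 1:1 with ``corpus.records``.
    """
    if record_embeddings.n_units != corpus.n_records:
        raise SchemaError(
            f"{record_embeddings.n_units} record embeddings for "
            f"{corpus.n_records} records"
        )
    rows = record_embeddings.rows
    dense = rows.toarray() if sp.issparse(rows) else np.asarray(rows, dtype=float)
    inst_ids = corpus.institution_ids()
    positions = {inst: [] for inst in inst_ids}
    for i, rec in enumerate(corpus.records):
        positions[rec.institution_id].append(i)
    vectors = np.zeros((len(inst_ids), dense.shape[1]))
    for j, inst in enumerate(inst_ids):
        idx = positions[inst]
        if not idx:
            raise SchemaError(f"institution {inst!r} has zero records")
        mean = dense[idx].mean(axis=0)
        norm = np.linalg.norm(mean)
        if norm < 1e-12:
            raise SchemaError(f"institution {inst!r} aggregates to a zero vector")
        vectors[j] = mean / norm
    return inst_ids, vectors


def score_statements(
    inst_ids: list[str],
    inst_vectors: np.ndarray,
    statement_embeddings: EmbeddingMatrix,
) -> SimilarityScores:
    """Cosine of every institution vector against every statement."""
    inst_matrix = EmbeddingMatrix(
        rows=inst_vectors, unit_ids=list(inst_ids), backend_name="aggregate"
    )
    matrix = cosine_matrix(inst_matrix, statement_embeddings)
    return SimilarityScores(
        matrix=matrix,
        institution_ids=list(inst_ids),
        statement_ids=list(statement_embeddings.unit_ids),
    )


def force_distribution(
    scores_row: np.ndarray, grid: QGrid, tie_policy: str = "index"
) -> np.ndarray:
    """Force one row of statement scores into the grid.

    Statements are sorted by descending score; the top ``count(+max)``
    receive the highest level, the next block the next level, and so on.
    Ties are broken by ascending statement index (deterministic).
    """
    scores = np.asarray(scores_row, dtype=float)
    if scores.ndim != 1 or scores.shape[0] != grid.n_statements:
        raise ConfigError(
            f"score row length {scores.shape[0]} does not match the grid "
            f"total {grid.n_statements}"
        )
    if tie_policy != "index":
        raise ConfigError(f"unknown tie policy: {tie_policy!r}")
    order = np.argsort(-scores, kind="stable")  # ties keep ascending index
    values = np.empty(grid.n_statements, dtype=int)
    pos = 0
    for value, count in zip(grid.column_values[::-1], grid.column_counts[::-1]):
        values[order[pos : pos + count]] = value
        pos += count
    return values


@dataclass
class QSortMatrix:
    """Statements x institutions forced-grid integer matrix."""

    values: np.ndarray
    grid: QGrid
    statement_ids: list[str]
    institution_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=int)
        n_stmt, n_inst = self.values.shape
        if n_stmt != grid_total(self.grid):
            raise ConfigError("row count must equal the grid statement total")
        if n_stmt != len(self.statement_ids) or n_inst != len(self.institution_ids):
            raise SchemaError("id lists do not match the value matrix shape")
        for j in range(n_inst):
            col = self.values[:, j]
            for value, count in zip(self.grid.column_values, self.grid.column_counts):
                if int(np.sum(col == value)) != count:
                    raise ConfigError(
                        f"column {self.institution_ids[j]!r} violates the grid "
                        f"count for level {value}"
                    )

    @property
    def n_statements(self) -> int:
        return self.values.shape[0]

    @property
    def n_institutions(self) -> int:
        return self.values.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=self.statement_ids, columns=self.institution_ids
        )
        df.index.name = "statement_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: QGrid) -> "QSortMatrix":
        df = pd.read_csv(path, index_col="statement_id")
        return cls(
            values=df.to_numpy(dtype=int),
            grid=grid,
            statement_ids=[str(s) for s in df.index],
            institution_ids=[str(c) for c in df.columns],
        )


def grid_total(grid: QGrid) -> int:
    return grid.n_statements


def build_qsort_matrix(scores: SimilarityScores, grid: QGrid) -> QSortMatrix:
    """Column-wise forced distribution over all institutions."""
    n_inst = len(scores.institution_ids)
    values = np.empty((len(scores.statement_ids), n_inst), dtype=int)
    for j in range(n_inst):
        values[:, j] = force_distribution(scores.matrix[j], grid)
    return QSortMatrix(
        values=values,
        grid=grid,
        statement_ids=list(scores.statement_ids),
        institution_ids=list(scores.institution_ids),
    )
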