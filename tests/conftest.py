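import numpy as np
import pytest

from orientq.corpus import AuditCorpus, AuditRecord
from orientq.embedding import EmbeddingMatrix
from orientq.qsort import QGrid


@pytest.fixture
def small_corpus() -> AuditCorpus:
    return AuditCorpus(
        [
            AuditRecord("inst_a", "r1", "The corridor has handrails. Lighting is even."),
            AuditRecord("inst_a", "r2", "The garden has dense greenery; benches are shaded."),
            AuditRecord("inst_b", "r1", "Rehabilitation equipment stands in the training room."),
            AuditRecord("inst_b", "r2", "The entrance gate carries a nameboard!"),
        ]
    )


@pytest.fixture
def unit_grid_11() -> QGrid:
    """11 statements, one per level from -5 to +5."""
    return QGrid(column_values=np.arange(-5, 6), column_counts=np.ones(11, dtype=int))


def dense_embedding(rows, ids=None, name="test") -> EmbeddingMatrix:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    rows = rows / norms
    if ids is None:
        ids = [f"u{i}" for i in range(rows.shape[0])]
    return EmbeddingMatrix(rows=rows, unit_ids=list(ids), backend_name=name)
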