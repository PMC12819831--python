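"""Pluggable text-to-vector backends and cosine utilities.

The default backend hashes lowercased word tokens into a fixed 4096-bin
space (scikit-learn's murmurhash with its fixed seed 0), applies TF-IDF
weighting computed over the embedding batch, and L2-normalizes each row.
It is fully deterministic, order-free (document frequency does not depend
on batch order) and needs no model download.  An optional
sentence-transformer backend can be registered when that package is
available; backend choice is configuration, not core behavior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import HashingVectorizer, TfidfTransformer

from .errors import ConfigError, EmbeddingError

#: Keep single-character tokens (the sklearn default drops them).
TOKEN_PATTERN = r"(?u)\b\w+\b"


@dataclass
class EmbeddingMatrix:
    """Row-per-unit embedding matrix; rows are L2-normalized.

    ``rows`` may be a dense ndarray or a scipy CSR matrix (the default
    backend produces sparse rows).
    """

    rows: np.ndarray | sp.spmatrix
    unit_ids: list[str]
    backend_name: str

    def __post_init__(self):
        if sp.issparse(self.rows):
            self.rows = self.rows.tocsr()
        else:
            self.rows = np.atleast_2d(np.asarray(self.rows, dtype=float))
        if self.rows.shape[0] != len(self.unit_ids):
            raise EmbeddingError(
                f"{self.rows.shape[0]} rows but {len(self.unit_ids)} unit ids"
            )
        norms = self.norms()
        bad = np.flatnonzero(np.abs(norms) < 1e-12)
        if bad.size:
            raise EmbeddingError(f"all-zero embedding rows at indices {bad.tolist()}")
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise EmbeddingError("embedding rows must be L2-normalized")

    @property
    def n_units(self) -> int:
        return self.rows.shape[0]

    @property
    def dim(self) -> int:
        return self.rows.shape[1]

    def norms(self) -> np.ndarray:
        if sp.issparse(self.rows):
            return np.sqrt(np.asarray(self.rows.multiply(self.rows).sum(axis=1)).ravel())
        return np.linalg.norm(self.rows, axis=1)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.rows):
            return self.rows.toarray()
        return self.rows

    def subset(self, indices: Sequence[int]) -> "EmbeddingMatrix":
        idx = list(indices)
        return EmbeddingMatrix(
            rows=self.rows[idx],
            unit_ids=[self.unit_ids[i] for i in idx],
            backend_name=self.backend_name,
        )

    def to_tsv(self, path) -> None:
        dense = self.dense()
        with open(path, "w", encoding="utf-8") as fh:
            for uid, row in zip(self.unit_ids, dense):
                fh.write(uid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def l2_normalize(rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    norms = np.linalg.norm(rows, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return rows / norms


class HashingTfidfBackend:
    """Hashed token counts + batch TF-IDF + L2 normalization (default)."""

    name = "hashing-tfidf"

    def __init__(self, n_features: int = 4096):
        self.n_features = int(n_features)

    def __call__(self, texts: Sequence[str]) -> sp.csr_matrix:
        vec = HashingVectorizer(
            n_features=self.n_features,
            alternate_sign=False,
            norm=None,
            lowercase=True,
            token_pattern=TOKEN_PATTERN,
        )
        counts = vec.transform(texts)
        empty = np.flatnonzero(np.asarray(counts.sum(axis=1)).ravel() == 0)
        if empty.size:
            raise EmbeddingError(
                "texts empty after normalization at indices "
                f"{empty.tolist()} (no word tokens found)"
            )
        tfidf = TfidfTransformer(norm="l2", smooth_idf=True, sublinear_tf=False)
        return tfidf.fit_transform(counts).tocsr()


class SentenceTransformerBackend:
    """Optional neural backend; requires the sentence-transformers package."""

    name = "sentence-transformer"

    def __init__(self, model_name: str = "paraphrase-multilingual-MiniLM-L12-v2", **kwargs):
        try:
            from sentence_transformers import SentenceTransformer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ConfigError(
                "backend 'sentence-transformer' requires the "
                "sentence-transformers package"
            ) from exc
        self._model = SentenceTransformer(model_name, **kwargs)

    def __call__(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        vectors = np.asarray(self._model.encode(list(texts)), dtype=float)
        return l2_normalize(vectors)


BackendFactory = Callable[..., Callable[[Sequence[str]], np.ndarray | sp.spmatrix]]

_REGISTRY: dict[str, BackendFactory] = {
    HashingTfidfBackend.name: HashingTfidfBackend,
    SentenceTransformerBackend.name: SentenceTransformerBackend,
}


def register_backend(name: str, factory: BackendFactory) -> None:
    _REGISTRY[name] = factory


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def embed(
    texts: Sequence[str],
    backend: str = "hashing-tfidf",
    unit_ids: Sequence[str] | None = None,
    **params,
) -> EmbeddingMatrix:
    """Embed a batch of texts with the named backend.

    TF-IDF statistics of the default backend are computed over exactly this
    batch, so callers that later compare two sets of texts (e.g. statements
    against documents) must embed them in one joint batch.
    """
    texts = list(texts)
    if not texts:
        raise EmbeddingError("cannot embed an empty list of texts")
    if backend not in _REGISTRY:
        raise ConfigError(
            f"unknown embedding backend {backend!r}; available: {available_backends()}"
        )
    rows = _REGISTRY[backend](**params)(texts)
    if unit_ids is None:
        unit_ids = [str(i) for i in range(len(texts))]
    return EmbeddingMatrix(rows=rows, unit_ids=list(unit_ids), backend_name=backend)


def cosine_matrix(a: EmbeddingMatrix, b: EmbeddingMatrix) -> np.ndarray:
    """All-pairs cosines between two embedding matrices (|a| x |b|)."""
    if a.dim != b.dim:
        raise EmbeddingError(f"dimension mismatch: {a.dim} vs {b.dim}")
    if sp.issparse(a.rows) or sp.issparse(b.rows):
        prod = sp.csr_matrix(a.rows) @ sp.csr_matrix(b.rows).T
        out = np.asarray(prod.todense(), dtype=float)
    else:
        out = a.rows @ b.rows.T
    return np.clip(out, -1.0, 1.0)
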