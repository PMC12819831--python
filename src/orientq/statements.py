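"""Build the Q statement set from the sentence pool.

Stages: sentence segmentation -> embedding -> PCA noise reduction ->
K selection (joint silhouette / Davies-Bouldin rank) -> K-means ->
centroid-nearest discriminative statement extraction with near-duplicate
removal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score, silhouette_score
from sklearn.utils.extmath import randomized_svd

from .corpus import AuditCorpus
from .embedding import EmbeddingMatrix, cosine_matrix, embed
from .errors import ConfigError, StatementError

logger = logging.getLogger(__name__)

#: Terminal punctuation for segmentation: western and CJK full stops,
#: question/exclamation marks and semicolons.
_TERMINALS = re.compile(r"[.!?;。！？；]+")


def segment_sentences(corpus: AuditCorpus) -> list[tuple[str, str, str]]:
    """Split record texts into sentences, keeping provenance.

    Returns ``(sentence, institution_id, record_id)`` triples.  Empty
    fragments are dropped; exact duplicates are removed only within one
    record.  A record yielding zero sentences is dropped with a warning.
    """
    out: list[tuple[str, str, str]] = []
    for rec in corpus.records:
        seen: set[str] = set()
        n_before = len(out)
        for fragment in _TERMINALS.split(rec.text):
            sentence = fragment.strip()
            if not sentence or sentence in seen:
                continue
            seen.add(sentence)
            out.append((sentence, rec.institution_id, rec.record_id))
        if len(out) == n_before:
            logger.warning(
                "record (%s, %s) yielded no sentences; dropped",
                rec.institution_id,
                rec.record_id,
            )
    return out


@dataclass
class SentencePool:
    """Segmented sentences aligned 1:1 with their embeddings."""

    sentences: list[tuple[str, str, str]]  # (text, institution_id, record_id)
    embedding: EmbeddingMatrix

    def __post_init__(self):
        if len(self.sentences) != self.embedding.n_units:
            raise StatementError("sentences and embedding rows are misaligned")
        if any(not s[0] for s in self.sentences):
            raise StatementError("sentence pool contains an empty sentence")

    @property
    def texts(self) -> list[str]:
        return [s[0] for s in self.sentences]


def build_sentence_pool(
    corpus: AuditCorpus, backend: str = "hashing-tfidf", **backend_params
) -> SentencePool:
    sentences = segment_sentences(corpus)
    if not sentences:
        raise StatementError("corpus yielded no sentences")
    matrix = embed(
        [s[0] for s in sentences],
        backend=backend,
        unit_ids=[f"{inst}/{rec}/{i}" for i, (_, inst, rec) in enumerate(sentences)],
        **backend_params,
    )
    return SentencePool(sentences=sentences, embedding=matrix)


# --------------------------------------------------------------------------
# PCA noise reduction
# --------------------------------------------------------------------------


@dataclass
class PCAReduction:
    X: np.ndarray  # n x m reduced coordinates
    explained_variance_ratio: np.ndarray  # per retained component
    n_components: int
    variance_target: float


def reduce_dimensions(
    E: EmbeddingMatrix | np.ndarray | sp.spmatrix,
    variance_target: float = 0.90,
    max_components: int = 1024,
) -> PCAReduction:
    """Project rows onto the smallest leading principal subspace whose
    cumulative explained variance reaches ``variance_target``.

    Rows are mean-centered first.  All-zero columns (common with hashed
    sparse embeddings) carry no variance and are dropped before the SVD,
    which changes nothing about the result.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ConfigError("variance_target must lie in (0, 1]")
    rows = E.rows if isinstance(E, EmbeddingMatrix) else E
    if sp.issparse(rows):
        rows = sp.csr_matrix(rows)
        nz_cols = np.flatnonzero(np.asarray((rows != 0).sum(axis=0)).ravel())
        dense = rows[:, nz_cols].toarray()
    else:
        dense = np.atleast_2d(np.asarray(rows, dtype=float))
    n = dense.shape[0]
    if n < 2:
        raise StatementError("need at least 2 rows for PCA")
    centered = dense - dense.mean(axis=0, keepdims=True)
    total_var = float(np.sum(centered**2))
    if total_var <= 1e-12:
        raise StatementError("rank-0 input: all rows identical after centering")

    k_max = min(centered.shape)
    if k_max <= max_components:
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
    else:
        u, s, _ = randomized_svd(centered, n_components=max_components, random_state=0)
    ratios = (s**2) / total_var
    cum = np.cumsum(ratios)
    rank_mask = s > max(centered.shape) * np.finfo(float).eps * (s[0] if s.size else 1.0)
    reachable = cum[rank_mask.sum() - 1] if rank_mask.any() else 0.0
    if reachable + 1e-9 < variance_target:
        raise StatementError(
            f"cannot reach variance target {variance_target} with "
            f"{len(s)} computed components (reached {reachable:.4f}); "
            "raise max_components"
        )
    m = int(np.searchsorted(cum + 1e-9, variance_target) + 1)
    m = min(m, int(rank_mask.sum()))
    X = u[:, :m] * s[:m]
    return PCAReduction(
        X=X,
        explained_variance_ratio=ratios[:m],
        n_components=m,
        variance_target=variance_target,
    )


# --------------------------------------------------------------------------
# K selection and clustering
# --------------------------------------------------------------------------


@dataclass
class KSelection:
    grid: list[int]
    inertia: list[float]
    silhouette: list[float]
    dbi: list[float]
    chosen_k: int
    rank_table: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return self.rank_table


def _kmeans(X: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(
        n_clusters=k,
        n_init=10,
        init="k-means++",
        tol=1e-6,
        max_iter=300,
        random_state=seed,
    ).fit(X)


def select_k(X: np.ndarray, grid, seed: int = 0) -> KSelection:
    """Choose K by the joint silhouette/Davies-Bouldin rank sum.

    For every K in the grid, K-means (10 restarts, fixed seed) is run and
    inertia (elbow diagnostic), mean silhouette and DBI recorded.  The
    chosen K minimizes rank(silhouette, descending) + rank(DBI, ascending);
    ties go to the smaller K.  The elbow curve is reported but not used for
    the final choice.  A K producing an empty cluster is flagged invalid
    and excluded.
    """
    X = np.asarray(X, dtype=float)
    grid = [int(k) for k in grid]
    if sorted(set(grid)) != grid:
        raise ConfigError("K grid must be strictly increasing")
    if grid[0] < 2 or grid[-1] > X.shape[0] - 1:
        raise ConfigError(f"K grid must lie within [2, {X.shape[0] - 1}]")

    inertia, sil, dbi, valid = [], [], [], []
    for k in grid:
        km = _kmeans(X, k, seed)
        labels = km.labels_
        ok = np.unique(labels).size == k
        valid.append(ok)
        inertia.append(float(km.inertia_))
        if ok:
            sil.append(float(silhouette_score(X, labels)))
            dbi.append(float(davies_bouldin_score(X, labels)))
        else:
            logger.warning("K=%d produced an empty cluster; excluded", k)
            sil.append(np.nan)
            dbi.append(np.nan)

    valid_idx = [i for i, ok in enumerate(valid) if ok]
    if not valid_idx:
        raise StatementError("no valid K in the grid")
    sil_v = np.array([sil[i] for i in valid_idx])
    dbi_v = np.array([dbi[i] for i in valid_idx])
    # rank 1 = best: highest silhouette, lowest DBI
    sil_rank = rankdata(-sil_v, method="min")
    dbi_rank = rankdata(dbi_v, method="min")
    joint = sil_rank + dbi_rank
    best_pos = int(np.argmin(joint))  # argmin takes first minimum -> smaller K
    chosen = grid[valid_idx[best_pos]]

    joint_full = np.full(len(grid), np.nan)
    for pos, i in enumerate(valid_idx):
        joint_full[i] = joint[pos]
    table = pd.DataFrame(
        {
            "K": grid,
            "inertia": inertia,
            "silhouette": sil,
            "dbi": dbi,
            "joint_rank": joint_full,
            "valid": valid,
        }
    )
    return KSelection(
        grid=grid,
        inertia=inertia,
        silhouette=sil,
        dbi=dbi,
        chosen_k=chosen,
        rank_table=table,
    )


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # sentence -> cluster id in [0, K)
    centroids: np.ndarray  # K x dim
    K: int
    X: np.ndarray = field(repr=False, default=None)  # the clustered coordinates

    def __post_init__(self):
        counts = np.bincount(self.labels, minlength=self.K)
        if np.any(counts == 0):
            raise StatementError("cluster assignment contains an empty cluster")
        if self.centroids.shape[0] != self.K:
            raise StatementError("centroid count must equal K")


def cluster(X: np.ndarray, K: int, seed: int = 0) -> ClusterAssignment:
    """K-means with 10 k-means++ restarts; deterministic under seed."""
    X = np.asarray(X, dtype=float)
    if not 1 <= K <= X.shape[0]:
        raise ConfigError(f"K={K} out of range for {X.shape[0]} rows")
    km = _kmeans(X, K, seed)
    return ClusterAssignment(labels=km.labels_, centroids=km.cluster_centers_, K=K, X=X)


# --------------------------------------------------------------------------
# Statement extraction
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Statement:
    statement_id: str
    text: str
    category_id: int
    centroid_distance: float
    margin: float


@dataclass
class StatementSet:
    """The Q sample: ordered statements with category labels and distances."""

    statements: list[Statement]

    def __post_init__(self):
        texts = [s.text for s in self.statements]
        if len(set(texts)) != len(texts):
            raise StatementError("statement texts must be unique")

    def __len__(self) -> int:
        return len(self.statements)

    @property
    def texts(self) -> list[str]:
        return [s.text for s in self.statements]

    @property
    def ids(self) -> list[str]:
        return [s.statement_id for s in self.statements]

    def per_category(self) -> dict[int, list[Statement]]:
        out: dict[int, list[Statement]] = {}
        for s in self.statements:
            out.setdefault(s.category_id, []).append(s)
        return out

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "statement_id": [s.statement_id for s in self.statements],
                "category_id": [s.category_id for s in self.statements],
                "text": [s.text for s in self.statements],
                "centroid_distance": [s.centroid_distance for s in self.statements],
                "margin": [s.margin for s in self.statements],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StatementSet":
        df = pd.read_csv(path, dtype={"statement_id": str})
        return cls(
            [
                Statement(
                    statement_id=row.statement_id,
                    text=row.text,
                    category_id=int(row.category_id),
                    centroid_distance=float(row.centroid_distance),
                    margin=float(row.margin),
                )
                for row in df.itertuples()
            ]
        )


def extract_statements(
    assignment: ClusterAssignment,
    pool: SentencePool,
    per_cluster: int = 3,
    dedup_threshold: float = 0.95,
) -> StatementSet:
    """Pick the ``per_cluster`` centroid-nearest discriminative sentences
    of every cluster.

    A sentence's discriminative margin is (distance to the nearest *other*
    centroid) - (distance to its own centroid); sentences with margin <= 0
    sit no closer to their own cluster than to a competitor and are
    skipped.  Near-duplicates (cosine in the original embedding space above
    ``dedup_threshold``) are dropped in favor of the sentence closer to the
    centroid, refilling from the ranking.
    """
    if assignment.X is None:
        raise StatementError("assignment must carry the clustered coordinates")
    if len(pool.sentences) != assignment.labels.shape[0]:
        raise StatementError("pool and assignment are misaligned")

    # distances of every sentence to every centroid
    d2 = (
        np.sum(assignment.X**2, axis=1, keepdims=True)
        - 2.0 * assignment.X @ assignment.centroids.T
        + np.sum(assignment.centroids**2, axis=1)
    )
    dists = np.sqrt(np.maximum(d2, 0.0))
    own = dists[np.arange(len(pool.sentences)), assignment.labels]
    masked = dists.copy()
    masked[np.arange(len(pool.sentences)), assignment.labels] = np.inf
    nearest_other = masked.min(axis=1) if assignment.K > 1 else np.full_like(own, np.inf)
    margin = nearest_other - own

    selected: list[Statement] = []
    used_texts: set[str] = set()
    for k in range(assignment.K):
        members = np.flatnonzero(assignment.labels == k)
        # rank by ascending own-centroid distance; ties by sentence index
        ranked = members[np.argsort(own[members], kind="stable")]
        kept_idx: list[int] = []
        for i in ranked:
            if len(kept_idx) == per_cluster:
                break
            if margin[i] <= 0:
                continue
            text = pool.sentences[i][0]
            if text in used_texts:
                continue
            cos_ok = True
            if kept_idx:
                sims = cosine_matrix(
                    pool.embedding.subset([i]), pool.embedding.subset(kept_idx)
                ).ravel()
                cos_ok = bool(np.all(sims <= dedup_threshold))
            if not cos_ok:
                continue
            kept_idx.append(int(i))
            used_texts.add(text)
        if len(kept_idx) < per_cluster:
            raise StatementError(
                f"cluster {k} exhausted: only {len(kept_idx)} of {per_cluster} "
                "eligible statements (after margin and duplicate filtering)"
            )
        for j, i in enumerate(kept_idx):
            selected.append(
                Statement(
                    statement_id=f"S{k * per_cluster + j + 1:02d}",
                    text=pool.sentences[i][0],
                    category_id=k,
                    centroid_distance=float(own[i]),
                    margin=float(margin[i]),
                )
            )
    return StatementSet(selected)
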