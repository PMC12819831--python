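"""Inverted (by-person) factor analysis for Q methodology.

The unit of analysis is a whole Q-sort: institutions are correlated with
each other over their sorted statements, principal components of that
correlation matrix are extracted, rotated (varimax, plus optional manual
Givens rotations), and defining sorts are flagged.  Statement z-scores per
factor use Brown's loading weights w = f / (1 - f^2); factor arrays
re-impose the forced grid on the z-scores.  Reliability follows the
Spearman-Brown composite with an assumed per-sort reliability, and
distinguishing/consensus statements compare z-scores across factors using
the standard error of score differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FactorError
from .qsort import QGrid, QSortMatrix, force_distribution

Z_CRIT_DEFAULT = 2.58  # two-sided P < 0.01
Z_ALPHA = {0.05: 1.96, 0.01: 2.58}


# --------------------------------------------------------------------------
# Correlation and extraction
# --------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    values: np.ndarray
    institution_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.institution_ids):
            raise FactorError("correlation matrix must be square and match ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise FactorError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-9):
            raise FactorError("correlation matrix must have a unit diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def correlate(qsorts: QSortMatrix) -> CorrelationMatrix:
    """Pearson correlations between institutions' Q-sort columns."""
    if qsorts.n_institutions < 2:
        raise FactorError("need at least 2 institutions to correlate")
    cols = qsorts.values.astype(float)
    # forced grid guarantees nonzero, identical column variance
    assert np.all(cols.std(axis=0) > 0), "grid invariant violated: constant column"
    r = np.corrcoef(cols, rowvar=False)
    return CorrelationMatrix(values=r, institution_ids=list(qsorts.institution_ids))


def significance_threshold(n_statements: int, z_crit: float = Z_CRIT_DEFAULT) -> float:
    """Loading significance threshold z_crit / sqrt(n_statements)."""
    if n_statements < 1:
        raise FactorError("n_statements must be >= 1")
    return z_crit / math.sqrt(n_statements)


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive
    (eigenvector sign is arbitrary; reports must be stable)."""
    out = loadings.copy()
    for j in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, j])))
        if out[i, j] < 0:
            out[:, j] = -out[:, j]
    return out


@dataclass
class FactorSolution:
    """Loadings and eigenvalues of an extracted (possibly rotated) solution."""

    loadings: np.ndarray  # institutions x factors
    eigenvalues: np.ndarray  # per extracted factor, non-increasing
    n_statements: int
    z_crit: float = Z_CRIT_DEFAULT
    rotation_log: list = field(default_factory=list)
    institution_ids: list[str] | None = None

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if self.loadings.ndim != 2:
            raise FactorError("loadings must be 2-D")
        if len(self.eigenvalues) != self.loadings.shape[1]:
            raise FactorError("one eigenvalue per factor is required")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise FactorError("eigenvalues must be non-increasing")

    @property
    def n_institutions(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def significance_threshold(self) -> float:
        return significance_threshold(self.n_statements, self.z_crit)

    def communalities(self) -> np.ndarray:
        return np.sum(self.loadings**2, axis=1)

    def explained_variance_pct(self) -> np.ndarray:
        """Per-factor explained variance, percent of total (= 100 eig / n)."""
        return 100.0 * self.eigenvalues / self.n_institutions

    def cumulative_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct())

    def retain(self, k: int) -> "FactorSolution":
        if not 1 <= k <= self.n_factors:
            raise FactorError(f"cannot retain {k} of {self.n_factors} factors")
        return replace(
            self,
            loadings=self.loadings[:, :k].copy(),
            eigenvalues=self.eigenvalues[:k].copy(),
            rotation_log=list(self.rotation_log),
        )


def extract(
    R: CorrelationMatrix,
    max_factors: int,
    n_statements: int,
    z_crit: float = Z_CRIT_DEFAULT,
) -> FactorSolution:
    """PCA extraction: leading eigenpairs of the correlation matrix.

    Loading column f is eigenvector_f * sqrt(eigenvalue_f), sign-fixed so
    each factor's largest-magnitude loading is positive.
    """
    if not 1 <= max_factors <= R.n:
        raise FactorError(f"max_factors must lie in [1, {R.n}]")
    eigvals, eigvecs = np.linalg.eigh(R.values)
    order = np.argsort(eigvals)[::-1][:max_factors]
    lam = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order] * np.sqrt(lam)
    return FactorSolution(
        loadings=_fix_signs(loadings),
        eigenvalues=lam,
        n_statements=n_statements,
        z_crit=z_crit,
        institution_ids=list(R.institution_ids),
    )


def explained_variance_percentages(
    eigenvalues, n_institutions: int, decimals: int = 0
) -> tuple[np.ndarray, float]:
    """Rounded per-factor explained-variance percentages and the rounded
    cumulative percentage (cumulative computed before rounding)."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    pct = 100.0 * eigenvalues / n_institutions
    cum = float(np.round(pct.sum(), decimals))
    rounded = np.round(pct, decimals)
    if decimals == 0:
        rounded = rounded.astype(int)
        cum = int(cum)
    return rounded, cum


def kaiser_guttman_screen(
    solution: FactorSolution, require_defining: bool = True, kaiser: bool = True
) -> int:
    """Admissible factor count under the Kaiser-Guttman screening rules.

    Candidate factors are the leading ones whose eigenvalue strictly
    exceeds 1.0 and that carry at least two loadings beyond the
    significance threshold; counting stops at the first failure.  With
    ``require_defining`` (default), candidate solutions are then examined
    from the largest down: the admissible count is the largest k whose
    varimax-rotated k-factor solution leaves at least two defining sorts
    (significant loading plus strict majority of communality) on every
    factor.  With a correlation matrix computed over far fewer statements
    than sorts, sampling-noise eigenvalues sit well above 1.0 and can show
    nominally significant loadings, but they never survive the
    defining-sort requirement; the two-stage screen is how candidate
    solutions are examined in standard Q practice.
    """
    thr = solution.significance_threshold
    ceiling = 0
    for f in range(solution.n_factors):
        if solution.eigenvalues[f] <= 1.0:
            break
        if int(np.sum(np.abs(solution.loadings[:, f]) > thr)) < 2:
            break
        ceiling += 1
    if not require_defining:
        return ceiling
    for k in range(ceiling, 0, -1):
        candidate = solution.retain(k)
        if k >= 2:
            candidate = varimax_solution(candidate, kaiser=kaiser)
        flags = flag_defining(candidate.loadings, thr)
        if int(flags.counts().min()) >= 2:
            return k
    return 0


# --------------------------------------------------------------------------
# Rotation
# --------------------------------------------------------------------------


def varimax_criterion(loadings: np.ndarray, kaiser: bool = True) -> float:
    """Raw varimax criterion: sum over factors of the variance of squared
    (optionally Kaiser row-normalized) loadings."""
    L = np.asarray(loadings, dtype=float)
    if kaiser:
        h = np.sqrt(np.sum(L**2, axis=1, keepdims=True))
        h[h == 0] = 1.0
        L = L / h
    sq = L**2
    return float(np.sum(sq.var(axis=0)))


def varimax(
    loadings: np.ndarray,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal varimax rotation via pairwise planar (Jacobi) sweeps.

    Returns (rotated loadings, rotation matrix) with
    ``rotated = loadings @ rotation``.  The criterion is non-decreasing
    across sweeps; convergence is declared when one full sweep gains less
    than ``tol``.  On non-convergence the best iterate is returned with a
    warning carrying the criterion trace.
    """
    L = np.asarray(loadings, dtype=float).copy()
    n, k = L.shape
    rotation = np.eye(k)
    if k < 2:
        return L, rotation

    h = np.sqrt(np.sum(L**2, axis=1, keepdims=True))
    if kaiser:
        scale = h.copy()
        scale[scale == 0] = 1.0
        L = L / scale

    trace = [varimax_criterion(L, kaiser=False)]
    converged = False
    for _ in range(max_iter):
        for p in range(k - 1):
            for q in range(p + 1, k):
                x, y = L[:, p], L[:, q]
                u = x**2 - y**2
                v = 2.0 * x * y
                a, b = u.sum(), v.sum()
                c = np.sum(u**2 - v**2)
                d = 2.0 * np.sum(u * v)
                num = d - 2.0 * a * b / n
                den = c - (a**2 - b**2) / n
                theta = 0.25 * math.atan2(num, den)
                if abs(theta) < 1e-14:
                    continue
                g = np.array(
                    [[math.cos(theta), -math.sin(theta)],
                     [math.sin(theta), math.cos(theta)]]
                )
                L[:, [p, q]] = L[:, [p, q]] @ g
                rotation[:, [p, q]] = rotation[:, [p, q]] @ g
        trace.append(varimax_criterion(L, kaiser=False))
        if trace[-1] - trace[-2] < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"varimax did not converge in {max_iter} sweeps; "
            f"criterion trace tail: {trace[-5:]}",
            RuntimeWarning,
        )
    if kaiser:
        L = L * scale
    return _fix_signs_with_rotation(L, rotation)


def _fix_signs_with_rotation(L: np.ndarray, rotation: np.ndarray):
    """Apply the stable sign convention to both the loadings and the
    accumulated rotation matrix so ``original @ rotation == rotated``."""
    signs = np.ones(L.shape[1])
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            signs[j] = -1.0
    return L * signs, rotation * signs


def varimax_solution(
    solution: FactorSolution,
    kaiser: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> FactorSolution:
    rotated, _ = varimax(solution.loadings, kaiser=kaiser, tol=tol, max_iter=max_iter)
    log = list(solution.rotation_log) + [("varimax", {"kaiser": kaiser})]
    return replace(solution, loadings=rotated, rotation_log=log)


def manual_rotate(
    loadings: np.ndarray,
    factor_a: int,
    factor_b: int,
    angle_degrees: float,
    direction: str = "ccw",
) -> np.ndarray:
    """Givens rotation of the (factor_a, factor_b) loading plane.

    Counterclockwise is positive with factor_a on the abscissa; pass
    ``direction="cw"`` (or a negative angle) for the opposite sense.  All
    other columns are untouched, so communalities are invariant.
    """
    L = np.asarray(loadings, dtype=float)
    k = L.shape[1]
    if factor_a == factor_b:
        raise FactorError("factor_a and factor_b must differ")
    if not (0 <= factor_a < k and 0 <= factor_b < k):
        raise FactorError(f"factor index out of range for {k} factors")
    if direction not in ("ccw", "cw"):
        raise FactorError(f"unknown rotation direction: {direction!r}")
    theta = math.radians(angle_degrees)
    if direction == "cw":
        theta = -theta
    out = L.copy()
    x, y = L[:, factor_a], L[:, factor_b]
    out[:, factor_a] = x * math.cos(theta) - y * math.sin(theta)
    out[:, factor_b] = x * math.sin(theta) + y * math.cos(theta)
    return out


def manual_rotate_solution(
    solution: FactorSolution,
    factor_a: int,
    factor_b: int,
    angle_degrees: float,
    direction: str = "ccw",
) -> FactorSolution:
    rotated = manual_rotate(
        solution.loadings, factor_a, factor_b, angle_degrees, direction
    )
    log = list(solution.rotation_log) + [
        ("manual", {"pair": (factor_a, factor_b), "degrees": angle_degrees,
                    "direction": direction})
    ]
    return replace(solution, loadings=rotated, rotation_log=log)


# --------------------------------------------------------------------------
# Defining sorts, scores, reliability
# --------------------------------------------------------------------------


@dataclass
class FlagMatrix:
    """Boolean defining-sort indicators (institutions x factors)."""

    flags: np.ndarray
    institution_ids: list[str] | None = None

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if np.any(self.flags.sum(axis=1) > 1):
            raise FactorError("an institution cannot define more than one factor")

    def counts(self) -> np.ndarray:
        return self.flags.sum(axis=0).astype(int)


def flag_defining(loadings: np.ndarray, threshold: float) -> FlagMatrix:
    """Flag sort i on factor f iff |loading| exceeds the significance
    threshold AND the squared loading strictly exceeds half the sort's
    communality (so at most one factor can qualify per sort)."""
    if threshold <= 0:
        raise FactorError("threshold must be positive")
    L = np.asarray(loadings, dtype=float)
    h2 = np.sum(L**2, axis=1, keepdims=True)
    flags = (np.abs(L) > threshold) & (L**2 > h2 / 2.0)
    return FlagMatrix(flags=flags)


def factor_zscores(
    qsorts: QSortMatrix, flags: FlagMatrix, loadings: np.ndarray
) -> np.ndarray:
    """Brown-weighted, standardized statement scores per factor.

    Each defining sort contributes with weight w = f / (1 - f^2); the
    weighted statement averages are standardized across statements to mean
    0, sd 1 (population sd).
    """
    L = np.asarray(loadings, dtype=float)
    n_stmt = qsorts.n_statements
    k = L.shape[1]
    z = np.empty((n_stmt, k))
    for f in range(k):
        idx = np.flatnonzero(flags.flags[:, f])
        if idx.size == 0:
            raise FactorError(f"factor {f + 1} has no defining sorts")
        fl = np.clip(L[idx, f], -0.999999, 0.999999)
        w = fl / (1.0 - fl**2)
        raw = qsorts.values[:, idx].astype(float) @ w / w.sum()
        sd = raw.std()
        if sd < 1e-12:
            raise FactorError(f"factor {f + 1} has constant statement scores")
        z[:, f] = (raw - raw.mean()) / sd
    return z


def factor_arrays(zscores: np.ndarray, grid: QGrid) -> np.ndarray:
    """Idealized Q-sorts: the forced grid re-imposed on each factor's
    z-scores (descending; ties by statement index)."""
    z = np.asarray(zscores, dtype=float)
    if z.shape[0] != grid.n_statements:
        raise FactorError("z-score row count does not match the grid total")
    return np.column_stack([force_distribution(z[:, f], grid) for f in range(z.shape[1])])


@dataclass
class ReliabilityStats:
    """Spearman-Brown composite reliability per factor."""

    p: np.ndarray  # defining sorts per factor
    avg_rel_coef: float
    composite_reliability: np.ndarray  # rounded to 3 decimals (reporting scale)
    composite_reliability_raw: np.ndarray
    se_zscores: np.ndarray  # sqrt(1 - CR_rounded)

    @property
    def n_factors(self) -> int:
        return len(self.p)


def reliability(flags_or_counts, avg_rel_coef: float = 0.8) -> ReliabilityStats:
    """Composite reliability CR = r*p / (1 + (p-1)*r) and the standard
    error of factor z-scores sqrt(1 - CR).

    CR is rounded to 3 decimals before the SE is taken; that is the
    reporting convention of the standard Q packages and is what printed
    CR/SE tables reproduce.
    """
    if isinstance(flags_or_counts, FlagMatrix):
        p = flags_or_counts.counts()
    else:
        p = np.asarray(flags_or_counts, dtype=int)
    if np.any(p < 1):
        raise FactorError("every factor needs at least one defining sort")
    if not 0.0 < avg_rel_coef <= 1.0:
        raise FactorError("avg_rel_coef must lie in (0, 1]")
    cr_raw = avg_rel_coef * p / (1.0 + (p - 1) * avg_rel_coef)
    cr = np.round(cr_raw, 3)
    se = np.sqrt(1.0 - cr)
    return ReliabilityStats(
        p=p,
        avg_rel_coef=avg_rel_coef,
        composite_reliability=cr,
        composite_reliability_raw=cr_raw,
        se_zscores=se,
    )


# --------------------------------------------------------------------------
# Distinguishing and consensus statements
# --------------------------------------------------------------------------


def _sed_matrix(rel: ReliabilityStats) -> np.ndarray:
    se = rel.se_zscores
    return np.sqrt(se[:, None] ** 2 + se[None, :] ** 2)


def distinguishing_statements(
    zscores: np.ndarray,
    rel: ReliabilityStats,
    levels: tuple[float, ...] = (0.05, 0.01),
) -> list[list[tuple[int, float]]]:
    """Per factor: statements whose z-score differs significantly from
    EVERY other factor, annotated with the strongest level attained.

    Returns one list per factor of ``(statement_index, alpha)`` pairs,
    alpha being the smallest (most stringent) level at which the statement
    distinguishes the factor.
    """
    z = np.asarray(zscores, dtype=float)
    k = z.shape[1]
    if k < 2:
        raise FactorError("distinguishing statements need at least 2 factors")
    if rel.n_factors != k:
        raise FactorError("reliability stats do not match the factor count")
    sed = _sed_matrix(rel)
    out: list[list[tuple[int, float]]] = [[] for _ in range(k)]
    for f in range(k):
        others = [g for g in range(k) if g != f]
        for s in range(z.shape[0]):
            best = None
            for alpha in sorted(levels, reverse=True):  # 0.05 first, then 0.01
                crit = Z_ALPHA[alpha]
                if all(abs(z[s, f] - z[s, g]) > crit * sed[f, g] for g in others):
                    best = alpha
            if best is not None:
                out[f].append((s, best))
    return out


def consensus_statements(
    zscores: np.ndarray, rel: ReliabilityStats, alpha: float = 0.05
) -> list[int]:
    """Statements whose z-scores do not differ significantly between any
    pair of factors at ``alpha``."""
    z = np.asarray(zscores, dtype=float)
    k = z.shape[1]
    if k < 2:
        raise FactorError("consensus is undefined for a single factor")
    sed = _sed_matrix(rel)
    crit = Z_ALPHA[alpha]
    out = []
    for s in range(z.shape[0]):
        if all(
            abs(z[s, f] - z[s, g]) <= crit * sed[f, g]
            for f in range(k)
            for g in range(f + 1, k)
        ):
            out.append(s)
    return out


@dataclass
class FactorScores:
    """Bundle of per-factor statement statistics for reporting."""

    zscores: np.ndarray  # statements x factors
    arrays: np.ndarray  # statements x factors, grid integers
    distinguishing: list[list[tuple[int, float]]]
    consensus: list[int]
    reliability: ReliabilityStats
    statement_ids: list[str] | None = None


def score_factors(
    qsorts: QSortMatrix,
    flags: FlagMatrix,
    solution: FactorSolution,
    avg_rel_coef: float = 0.8,
    levels: tuple[float, ...] = (0.05, 0.01),
) -> FactorScores:
    """Compute z-scores, arrays, reliability and the distinguishing /
    consensus annotations in one pass."""
    z = factor_zscores(qsorts, flags, solution.loadings)
    arrays = factor_arrays(z, qsorts.grid)
    rel = reliability(flags, avg_rel_coef=avg_rel_coef)
    if solution.n_factors >= 2:
        dist = distinguishing_statements(z, rel, levels=levels)
        cons = consensus_statements(z, rel, alpha=max(levels))
    else:
        dist, cons = [[]], []
    return FactorScores(
        zscores=z,
        arrays=arrays,
        distinguishing=dist,
        consensus=cons,
        reliability=rel,
        statement_ids=list(qsorts.statement_ids),
    )
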