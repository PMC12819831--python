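"""Stage orchestration: simulate -> build statements -> sort -> analyze -> report.

A single :class:`RunConfig` (loadable from YAML) drives every stage; each
stage writes plain-text artifacts into the output directory and the run
ends with a manifest of config snapshot, package version, artifact
checksums and stage timings.  Deterministic stages reproduce identical
checksums when re-run with the same config and inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .corpus import AuditCorpus, read_corpus, write_corpus
from .embedding import embed
from .errors import ConfigError, PipelineError
from .factors import (
    FactorScores,
    FactorSolution,
    FlagMatrix,
    correlate,
    extract,
    flag_defining,
    kaiser_guttman_screen,
    manual_rotate_solution,
    score_factors,
    varimax_solution,
)
from .qsort import (
    QGrid,
    QSortMatrix,
    aggregate_institution,
    build_qsort_matrix,
    score_statements,
)
from .report import render_factor_report, write_kselection_plot, write_scree
from .statements import (
    StatementSet,
    build_sentence_pool,
    cluster,
    extract_statements,
    reduce_dimensions,
    select_k,
)
from .synthetic import default_four_type_config, generate_corpus

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.  ``seed`` is mandatory."""

    seed: int
    out_dir: str = "orientq_run"
    corpus_path: str | None = None  # if None and simulate=True, generate
    # synthetic stage
    simulate: bool = False
    n_institutions: int = 200
    noise_rate: float = 0.1
    # statement stage
    backend: str = "hashing-tfidf"
    backend_params: dict = field(default_factory=dict)
    k: int = 18
    k_grid: list[int] | None = None  # when set, select K on this grid
    per_cluster: int = 3
    variance_target: float = 0.90
    dedup_threshold: float = 0.95
    # sorting stage
    grid_values: list[int] | None = None
    grid_counts: list[int] | None = None
    # analysis stage
    max_factors: int = 8
    z_crit: float = 2.58
    kaiser_normalize: bool = True
    manual_rotations: list = field(default_factory=list)  # (a, b, degrees) 1-based
    avg_rel_coef: float = 0.8
    alphas: tuple[float, ...] = (0.05, 0.01)
    render_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ConfigError("config must set a seed")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["alphas"] = list(self.alphas)
        return d

    def make_grid(self, n_statements: int) -> QGrid:
        if self.grid_values is not None and self.grid_counts is not None:
            grid = QGrid(
                column_values=np.asarray(self.grid_values),
                column_counts=np.asarray(self.grid_counts),
            )
        elif n_statements == 54:
            grid = QGrid.default_54()
        else:
            grid = QGrid.quasi_normal(n_statements)
        if grid.n_statements != n_statements:
            raise ConfigError(
                f"grid totals {grid.n_statements} but there are "
                f"{n_statements} statements"
            )
        return grid


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {"artifacts": {path: sha256}, "seconds": float}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"config": self.config, "version": self.version, "stages": self.stages},
                fh,
                indent=2,
                default=str,
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _StageRecorder:
    def __init__(self, out_dir: Path):
        self.out_dir = out_dir
        self.stages: dict = {}

    def record(self, stage: str, started: float, artifacts: list[Path]) -> None:
        self.stages[stage] = {
            "seconds": round(time.perf_counter() - started, 3),
            "artifacts": {str(p.relative_to(self.out_dir)): _sha256(p) for p in artifacts},
        }


# --------------------------------------------------------------------------
# Individual stages (also used by the CLI subcommands)
# --------------------------------------------------------------------------


def stage_build_statements(corpus: AuditCorpus, config: RunConfig):
    """Segment, embed, reduce, (select or fix K), cluster, extract."""
    pool = build_sentence_pool(corpus, backend=config.backend, **config.backend_params)
    reduction = reduce_dimensions(pool.embedding, variance_target=config.variance_target)
    kselection = None
    k = config.k
    if config.k_grid:
        kselection = select_k(reduction.X, config.k_grid, seed=config.seed)
        k = kselection.chosen_k
    assignment = cluster(reduction.X, k, seed=config.seed)
    statements = extract_statements(
        assignment, pool, per_cluster=config.per_cluster,
        dedup_threshold=config.dedup_threshold,
    )
    return statements, kselection, reduction


def stage_build_qsorts(
    corpus: AuditCorpus, statements: StatementSet, config: RunConfig
) -> QSortMatrix:
    """Embed statements and record texts in one joint batch (frozen TF-IDF
    statistics), aggregate institutions, score and force the grid."""
    stmt_texts = statements.texts
    record_texts = [rec.text for rec in corpus.records]
    joint = embed(
        stmt_texts + record_texts,
        backend=config.backend,
        unit_ids=statements.ids
        + [f"{r.institution_id}/{r.record_id}" for r in corpus.records],
        **config.backend_params,
    )
    stmt_emb = joint.subset(range(len(stmt_texts)))
    rec_emb = joint.subset(range(len(stmt_texts), joint.n_units))
    inst_ids, inst_vectors = aggregate_institution(corpus, rec_emb)
    scores = score_statements(inst_ids, inst_vectors, stmt_emb)
    grid = config.make_grid(len(statements))
    return build_qsort_matrix(scores, grid)


def stage_analyze(
    qsorts: QSortMatrix, config: RunConfig
) -> tuple[FactorSolution, FlagMatrix, FactorScores, int]:
    """Correlate, extract, screen, rotate, flag and score."""
    R = correlate(qsorts)
    max_factors = min(config.max_factors, R.n)
    full = extract(R, max_factors, qsorts.n_statements, z_crit=config.z_crit)
    n_admissible = kaiser_guttman_screen(full)
    if n_admissible == 0:
        raise PipelineError("analyze", "no admissible factors under Kaiser-Guttman")
    solution = full.retain(n_admissible)
    if n_admissible >= 2:
        solution = varimax_solution(solution, kaiser=config.kaiser_normalize)
    for a, b, degrees in config.manual_rotations:
        solution = manual_rotate_solution(solution, int(a) - 1, int(b) - 1, float(degrees))
    flags = flag_defining(solution.loadings, solution.significance_threshold)
    empty = np.flatnonzero(flags.counts() == 0)
    if empty.size:
        raise PipelineError(
            "analyze", f"factors {(empty + 1).tolist()} have no defining sorts"
        )
    scores = score_factors(
        qsorts, flags, solution, avg_rel_coef=config.avg_rel_coef, levels=config.alphas
    )
    return solution, flags, scores, n_admissible


# --------------------------------------------------------------------------
# Full run
# --------------------------------------------------------------------------


def run_pipeline(config: RunConfig, corpus: AuditCorpus | None = None) -> RunManifest:
    """Execute every configured stage; returns the manifest (also written
    to ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log", mode="w", encoding="utf-8")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("orientq")
    root.addHandler(log_handler)
    rec = _StageRecorder(out)
    try:
        # --- corpus ---------------------------------------------------
        t0 = time.perf_counter()
        if corpus is None:
            if config.simulate:
                gen = default_four_type_config(
                    config.n_institutions, seed=config.seed, noise_rate=config.noise_rate
                )
                corpus, truth = generate_corpus(gen)
                write_corpus(corpus, out / "corpus.jsonl")
                truth.to_frame().to_csv(out / "ground_truth.csv", index=False)
                rec.record("simulate", t0, [out / "corpus.jsonl", out / "ground_truth.csv"])
            elif config.corpus_path:
                if not Path(config.corpus_path).exists():
                    raise PipelineError("load", f"corpus path not found: {config.corpus_path}")
                corpus = read_corpus(config.corpus_path)
                rec.record("load", t0, [])
            else:
                raise PipelineError("load", "no corpus: set corpus_path or simulate=true")
        logger.info("corpus: %d institutions, %d records",
                    corpus.n_institutions, corpus.n_records)

        # --- statements -----------------------------------------------
        t0 = time.perf_counter()
        try:
            statements, kselection, _ = stage_build_statements(corpus, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("build-statements", str(exc)) from exc
        statements.to_csv(out / "statements.csv")
        artifacts = [out / "statements.csv"]
        if kselection is not None:
            png = out / "kselection.png" if config.render_plots else None
            write_kselection_plot(kselection, out / "kselection.tsv", png)
            artifacts.append(out / "kselection.tsv")
        rec.record("build-statements", t0, artifacts)
        logger.info("statements: %d in %d categories",
                    len(statements), len(statements.per_category()))

        # --- sorting --------------------------------------------------
        t0 = time.perf_counter()
        try:
            qsorts = stage_build_qsorts(corpus, statements, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("sort", str(exc)) from exc
        qsorts.to_csv(out / "qsorts.csv")
        qsorts.grid.to_yaml(out / "grid.yaml")
        rec.record("sort", t0, [out / "qsorts.csv", out / "grid.yaml"])

        # --- analysis -------------------------------------------------
        t0 = time.perf_counter()
        try:
            solution, flags, scores, n_admissible = stage_analyze(qsorts, config)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc
        loadings = pd.DataFrame(
            np.round(solution.loadings, 3),
            index=qsorts.institution_ids,
            columns=[f"F{f + 1}" for f in range(solution.n_factors)],
        )
        loadings.index.name = "institution_id"
        loadings.to_csv(out / "loadings.csv")
        flag_df = pd.DataFrame(
            flags.flags,
            index=qsorts.institution_ids,
            columns=[f"F{f + 1}" for f in range(solution.n_factors)],
        )
        flag_df.index.name = "institution_id"
        flag_df.to_csv(out / "flags.csv")
        z_df = pd.DataFrame(
            np.round(scores.zscores, 3),
            index=qsorts.statement_ids,
            columns=[f"F{f + 1}" for f in range(solution.n_factors)],
        )
        z_df.index.name = "statement_id"
        z_df.to_csv(out / "zscores.csv")
        arr_df = pd.DataFrame(
            scores.arrays,
            index=qsorts.statement_ids,
            columns=[f"F{f + 1}" for f in range(solution.n_factors)],
        )
        arr_df.index.name = "statement_id"
        arr_df.to_csv(out / "factor_arrays.csv")
        rec.record(
            "analyze",
            t0,
            [out / "loadings.csv", out / "flags.csv", out / "zscores.csv",
             out / "factor_arrays.csv"],
        )
        logger.info("analysis: %d admissible factors, defining counts %s",
                    n_admissible, flags.counts().tolist())

        # --- report ---------------------------------------------------
        t0 = time.perf_counter()
        report_text = render_factor_report(solution, scores, statements, flags)
        (out / "report.txt").write_text(report_text, encoding="utf-8")
        png = out / "scree.png" if config.render_plots else None
        write_scree(solution, out / "scree.tsv", png)
        rec.record("report", t0, [out / "report.txt", out / "scree.tsv"])

        manifest = RunManifest(
            config=config.to_dict(), version=__version__, stages=rec.stages
        )
        manifest.to_json(out / "manifest.json")
        return manifest
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
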