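"""Human-readable factor reports and diagnostic tables.

All floating values are printed at 3 decimals.  Plot outputs are data-only
TSV plus an optional rendered image, so headless runs can verify the TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .factors import FactorScores, FactorSolution, FlagMatrix
from .statements import StatementSet


def scree_table(solution: FactorSolution) -> pd.DataFrame:
    """Eigenvalue / explained-variance table backing the scree plot."""
    pct = solution.explained_variance_pct()
    return pd.DataFrame(
        {
            "factor": np.arange(1, solution.n_factors + 1),
            "eigenvalue": np.round(solution.eigenvalues, 3),
            "explained_pct": np.round(pct, 3),
            "cumulative_pct": np.round(np.cumsum(pct), 3),
        }
    )


def write_scree(solution: FactorSolution, tsv_path: str | Path, png_path=None) -> None:
    table = scree_table(solution)
    table.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.plot(table["factor"], table["eigenvalue"], marker="o")
        ax.axhline(1.0, color="grey", linestyle="--", linewidth=0.8)
        ax.set_xlabel("Factor")
        ax.set_ylabel("Eigenvalue")
        ax.set_title("Scree plot")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def write_kselection_plot(kselection, tsv_path: str | Path, png_path=None) -> None:
    table = kselection.to_frame()
    table.to_csv(tsv_path, sep="\t", index=False)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].plot(table["K"], table["inertia"], marker="o")
        axes[0].set_title("Elbow (inertia)")
        axes[1].plot(table["K"], table["silhouette"], marker="o")
        axes[1].set_title("Silhouette")
        axes[2].plot(table["K"], table["dbi"], marker="o")
        axes[2].set_title("Davies-Bouldin")
        for ax in axes:
            ax.set_xlabel("K")
            ax.axvline(kselection.chosen_k, color="grey", linestyle="--", linewidth=0.8)
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)


def _dist_mark(dist_for_factor: list[tuple[int, float]], statement_idx: int) -> str:
    for s, alpha in dist_for_factor:
        if s == statement_idx:
            return "D*" if alpha <= 0.01 else "D"
    return ""


def render_factor_report(
    solution: FactorSolution,
    scores: FactorScores,
    statements: StatementSet,
    flags: FlagMatrix | None = None,
) -> str:
    """Per-factor report: extreme-array statements first, distinguishing
    marks (D at P<0.05, D* at P<0.01), and all factors' array values side
    by side; consensus statements at the end."""
    k = solution.n_factors
    ids = scores.statement_ids or [s.statement_id for s in statements.statements]
    texts = {s.statement_id: s.text for s in statements.statements}
    rel = scores.reliability
    lines: list[str] = []
    lines.append("=" * 78)
    lines.append("Q FACTOR REPORT")
    lines.append("=" * 78)
    lines.append(f"factors: {k}   statements: {len(ids)}   "
                 f"institutions: {solution.n_institutions}")
    pct = solution.explained_variance_pct()
    lines.append(
        "explained variance (%): "
        + "  ".join(f"F{f + 1}={pct[f]:.3f}" for f in range(k))
        + f"   cumulative={pct.sum():.3f}"
    )
    lines.append(f"rotation history: {solution.rotation_log or 'none'}")
    lines.append("")

    extreme = np.max(np.abs(scores.arrays))
    for f in range(k):
        lines.append("-" * 78)
        lines.append(
            f"FACTOR {f + 1}: defining sorts p={rel.p[f]}, "
            f"avg rel coef={rel.avg_rel_coef:.3f}, "
            f"composite reliability={rel.composite_reliability[f]:.3f}, "
            f"SE of z-scores={rel.se_zscores[f]:.3f}"
        )
        lines.append("-" * 78)
        header = f"{'stmt':<6}{'array':>6}{'z':>9}{'mark':>6}  " + "  ".join(
            f"F{g + 1:>d}" for g in range(k)
        )
        lines.append(header)
        col = scores.arrays[:, f]
        # extreme (+/-max and next level) statements first, then the rest
        order = np.argsort(-np.abs(col) * 10 - col * 0.001, kind="stable")
        shown_first = [s for s in order if abs(col[s]) >= extreme - 1]
        rest = [s for s in order if abs(col[s]) < extreme - 1]
        for s in list(shown_first) + list(rest):
            mark = _dist_mark(scores.distinguishing[f], s) if k >= 2 else ""
            lines.append(
                f"{ids[s]:<6}{col[s]:>6d}{scores.zscores[s, f]:>9.3f}{mark:>6}  "
                + "  ".join(f"{scores.arrays[s, g]:>2d}" for g in range(k))
            )
        n_dist = len(scores.distinguishing[f]) if k >= 2 else 0
        if n_dist == 0:
            lines.append("(no distinguishing statements for this factor)")
        lines.append("")

    lines.append("-" * 78)
    if scores.consensus:
        lines.append("CONSENSUS STATEMENTS (non-significant across all pairs):")
        for s in scores.consensus:
            lines.append(f"  {ids[s]}: {texts.get(ids[s], '')}")
    else:
        lines.append("CONSENSUS STATEMENTS: none")
    lines.append("")
    lines.append("STATEMENT TEXTS")
    for sid in ids:
        lines.append(f"  {sid}: {texts.get(sid, '')}")
    lines.append("")
    return "\n".join(lines)
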