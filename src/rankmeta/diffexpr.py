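"""Per-study differential expression and directional ranked gene lists.

Each study is tested gene-by-gene with a two-sided two-sample t-test on
the log2 values (Welch by default; pooled variance behind a flag).  The
log2 fold change is the case-mean minus control-mean.  Significant DEGs
use the conventional p < 0.05 and |log2FC| > 1 cut (strict inequalities),
and ranked lists order genes by ascending p, ties broken by descending
|log2FC| and finally by gene id, separately for up- and down-regulated
genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionStudy

__all__ = [
    "DEResult",
    "RankedGeneList",
    "differential_expression",
    "significant_degs",
    "rank_degs",
    "full_directional_ranking",
]


@dataclass
class DEResult:
    """Per-gene log2 fold change and p-value for one study."""

    study_id: str
    table: pd.DataFrame  # index gene_id; columns log2fc, p_value

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


@dataclass
class RankedGeneList:
    """Ordered gene ids (most significant first) for one direction of one study."""

    study_id: str
    direction: str  # "up" or "down"
    genes: list[str]

    @property
    def m(self) -> int:
        return len(self.genes)


def differential_expression(study: ExpressionStudy, equal_var: bool = False) -> DEResult:
    """Two-sample t-test per gene: log2fc = mean(case) - mean(control).

    Welch's unequal-variance test by default (``equal_var=True`` gives the
    pooled Student t).  Genes with zero variance in both groups get p = 1
    when the means are equal and p = 0 otherwise.
    """
    study.check_valid()
    case = study.matrix[study.samples("case")].to_numpy()
    ctrl = study.matrix[study.samples("control")].to_numpy()

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)

    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    p[degenerate & (log2fc == 0)] = 1.0
    p[degenerate & (log2fc != 0)] = 0.0
    log2fc = np.where(degenerate & (log2fc == 0), 0.0, log2fc)

    table = pd.DataFrame({"log2fc": log2fc, "p_value": p}, index=study.matrix.index)
    return DEResult(study_id=study.study_id, table=table)


def significant_degs(
    de: DEResult, p_thresh: float = 0.05, lfc_thresh: float = 1.0
) -> tuple[set[str], set[str]]:
    """Split significant genes into (up, down) sets; strict inequalities."""
    if not 0.0 <= p_thresh <= 1.0:
        raise ValueError(f"p_thresh must be in [0, 1], got {p_thresh}")
    if lfc_thresh < 0:
        raise ValueError(f"lfc_thresh must be >= 0, got {lfc_thresh}")
    t = de.table
    sig = t["p_value"] < p_thresh
    up = set(t.index[sig & (t["log2fc"] > lfc_thresh)])
    down = set(t.index[sig & (t["log2fc"] < -lfc_thresh)])
    return up, down


def _order(table: pd.DataFrame, reverse: bool = False) -> list[str]:
    """Significance order: p asc, |log2fc| desc, gene id asc (or fully reversed)."""
    keyed = sorted(
        table.index,
        key=lambda g: (table.at[g, "p_value"], -abs(table.at[g, "log2fc"]), g),
    )
    return keyed[::-1] if reverse else keyed


def rank_degs(de: DEResult, direction: str) -> RankedGeneList:
    """Full ranking of all genes of one sign, best (most significant) first."""
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t = de.table
    sub = t[t["log2fc"] > 0] if direction == "up" else t[t["log2fc"] < 0]
    return RankedGeneList(study_id=de.study_id, direction=direction, genes=_order(sub))


def full_directional_ranking(
    de: DEResult, direction: str, universe: list[str] | None = None
) -> RankedGeneList:
    """Complete ordering of the (restricted) universe by one-sided evidence.

    Rank aggregation requires each study list to be a full permutation of
    the shared universe.  Genes of the matching sign come first in
    significance order, then zero-log2fc genes by id, then opposite-sign
    genes in reversed significance order (so the most significantly
    opposite-regulated genes sit at the bottom).  Under the null this is a
    uniform random permutation of the universe.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    t = de.table
    if universe is not None:
        missing = set(universe) - set(t.index)
        if missing:
            raise ValueError(
                f"{de.study_id}: universe genes absent from DE table: {sorted(missing)[:5]}"
            )
        t = t.loc[list(universe)]
    sign = 1.0 if direction == "up" else -1.0
    same = t[sign * t["log2fc"] > 0]
    zero = t[t["log2fc"] == 0]
    opposite = t[sign * t["log2fc"] < 0]
    genes = _order(same) + sorted(zero.index) + _order(opposite, reverse=True)
    return RankedGeneList(study_id=de.study_id, direction=direction, genes=genes)
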