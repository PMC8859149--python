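"""Expression matrix I/O and probe-to-gene collapsing.

Expression data is exchanged as plain TSV in the GEO series-matrix style:
a genes x samples table whose first column holds gene (or probe) ids, plus
a two-column sample annotation (sample_id, group) with group levels
``case`` and ``control``.  Values are normalized log2 intensities; this
module never normalizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionStudy", "read_expression", "write_expression", "collapse_probes"]

GROUP_LEVELS = ("case", "control")


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix with case/control sample labels.

    ``matrix`` rows are genes (or probes before collapsing), columns are
    samples; ``groups`` maps every sample id to ``case`` or ``control``.
    """

    study_id: str
    matrix: pd.DataFrame
    groups: pd.Series

    @property
    def universe(self) -> set[str]:
        return set(self.matrix.index)

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def check_valid(self) -> None:
        """Raise if any sample lacks a label or a group has < 2 samples."""
        missing = [s for s in self.matrix.columns if s not in self.groups.index]
        if missing:
            raise ValueError(
                f"{self.study_id}: samples missing from annotation: {', '.join(map(str, missing))}"
            )
        bad = set(self.groups.unique()) - set(GROUP_LEVELS)
        if bad:
            raise ValueError(
                f"{self.study_id}: unknown group labels {sorted(bad)}; expected {GROUP_LEVELS}"
            )
        for g in GROUP_LEVELS:
            n = int((self.groups.loc[self.matrix.columns] == g).sum())
            if n < 2:
                raise ValueError(f"{self.study_id}: group '{g}' has {n} samples; need >= 2")


def read_expression(matrix_path, annotation_path, study_id: str | None = None) -> ExpressionStudy:
    """Read an expression TSV and its sample annotation into an ExpressionStudy.

    Row order is preserved; duplicated gene ids are accepted (they are
    treated as probes and resolved by :func:`collapse_probes`).  Errors name
    the offending sample or cell.
    """
    matrix_path = Path(matrix_path)
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{matrix_path}: non-numeric value {raw.iat[r, c]!r} at row "
            f"{raw.index[r]!r}, column {raw.columns[c]!r}"
        )
    if values.isna().to_numpy().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"{matrix_path}: missing value at row {raw.index[r]!r}, column {raw.columns[c]!r}"
        )

    ann = pd.read_csv(annotation_path, sep="\t", dtype=str)
    if ann.shape[1] < 2:
        raise ValueError(f"{annotation_path}: expected columns sample_id and group")
    groups = pd.Series(ann.iloc[:, 1].values, index=ann.iloc[:, 0].values, name="group")

    study = ExpressionStudy(
        study_id=study_id or matrix_path.stem,
        matrix=values.astype(float),
        groups=groups,
    )
    study.check_valid()
    return study


def write_expression(study: ExpressionStudy, matrix_path, annotation_path) -> None:
    """Write the matrix and annotation TSVs (inverse of :func:`read_expression`)."""
    out = study.matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t")
    ann = pd.DataFrame(
        {"sample_id": list(study.matrix.columns),
         "group": [study.groups[s] for s in study.matrix.columns]}
    )
    ann.to_csv(annotation_path, sep="\t", index=False)


def read_probe_map(path) -> dict[str, str]:
    """Two-column TSV (probe_id, gene_id) -> dict; empty gene ids mean unmapped."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns probe_id and gene_id")
    out: dict[str, str] = {}
    for probe, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if isinstance(gene, str) and gene.strip():
            out[probe] = gene.strip()
    return out


def collapse_probes(
    study: ExpressionStudy, probe_map: Mapping[str, str] | None = None
) -> ExpressionStudy:
    """Collapse probe-level rows to one row per gene by averaging.

    With a ``probe_map``, probes without a gene annotation are dropped and
    the remaining rows are renamed to their genes; without one, duplicated
    row ids are taken to be probes of the same gene.  Each gene's value is
    the arithmetic mean of its probes' values per sample (missing values
    excluded cell-wise).  Idempotent; never changes the sample columns.
    """
    matrix = study.matrix
    if probe_map is not None:
        mapped = [p for p in matrix.index if p in probe_map]
        if not mapped:
            raise ValueError(f"{study.study_id}: no probes remain after dropping unmapped ones")
        matrix = matrix.loc[mapped]
        matrix = matrix.set_axis([probe_map[p] for p in mapped], axis=0)
    if matrix.shape[0] == 0:
        raise ValueError(f"{study.study_id}: empty matrix after probe filtering")
    collapsed = matrix.groupby(level=0, sort=False).mean()
    collapsed.index.name = "gene_id"
    return ExpressionStudy(study_id=study.study_id, matrix=collapsed, groups=study.groups)
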