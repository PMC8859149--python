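"""Synthetic multi-study expression data with planted differential signal.

Emulates the situation the aggregation pipeline is built for: several
case/control microarray cohorts measured on different platforms (different
gene universes), sharing a common set of truly differentially expressed
genes whose effect is attenuated study by study.  Also provides a null
rank-matrix generator for calibrating the aggregation statistic and a
random PPI-like graph with planted hubs for the network stage.

Everything is driven by a single :class:`numpy.random.Generator` seeded
from the configuration, so identical configurations give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import ExpressionStudy
from .rra import RankMatrix

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_multistudy",
    "simulate_null_rank_matrix",
    "simulate_network",
]


def _broadcast(value: float | int | Sequence, n: int, name: str) -> list:
    """Expand a scalar per-study parameter to a list of length ``n``."""
    if np.isscalar(value):
        return [value] * n
    vals = list(value)
    if len(vals) != n:
        raise ValueError(f"{name}: expected {n} per-study values, got {len(vals)}")
    return vals


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a multi-study simulation.

    Parameters
    ----------
    n_genes : total number of genes in the global universe.
    n_studies : number of case/control studies to generate.
    cases_per_study, controls_per_study : group sizes; a scalar applies to
        every study, a sequence gives one value per study.
    frac_de : fraction of genes that are truly differentially expressed.
    effect_lfc : magnitude of the planted log2 fold change.
    frac_up : fraction of DE genes that are up-regulated in cases.
    attenuation : per-study multiplier in [0, 1] applied to the effect
        (scalar or one value per study).
    noise_sd : standard deviation of the additive Gaussian noise (log2 units).
    platform_coverage : fraction of the global universe measured by each
        study's platform; DE genes are always included.
    baseline_mean, baseline_sd : distribution of per-gene baseline log2
        expression, drawn once and shared across studies.
    seed : RNG seed; determines every random draw.
    """

    n_genes: int = 2000
    n_studies: int = 4
    cases_per_study: int | Sequence[int] = 10
    controls_per_study: int | Sequence[int] = 10
    frac_de: float = 0.05
    effect_lfc: float = 2.0
    frac_up: float = 0.5
    attenuation: float | Sequence[float] = 0.8
    noise_sd: float = 0.5
    platform_coverage: float = 0.9
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes: must be >= 2")
        if self.n_studies < 1:
            raise ValueError("n_studies: must be >= 1")
        for name in ("frac_de", "frac_up"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        if not 0.0 < self.platform_coverage <= 1.0:
            raise ValueError(
                f"platform_coverage: must be in (0, 1], got {self.platform_coverage}"
            )
        if round(self.platform_coverage * self.n_genes) < 2:
            raise ValueError("platform_coverage: universe per study must have >= 2 genes")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd: must be >= 0, got {self.noise_sd}")
        for name in ("cases_per_study", "controls_per_study"):
            for v in _broadcast(getattr(self, name), self.n_studies, name):
                if v < 2:
                    raise ValueError(f"{name}: every group needs >= 2 samples, got {v}")
        for a in _broadcast(self.attenuation, self.n_studies, "attenuation"):
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"attenuation: must be in [0, 1], got {a}")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulation: which genes carry signal and how."""

    table: pd.DataFrame  # index gene_id; columns is_de, direction, true_lfc

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_de"]])

    def genes(self, direction: str) -> list[str]:
        mask = self.table["is_de"] & (self.table["direction"] == direction)
        return list(self.table.index[mask])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def simulate_multistudy(config: SimConfig) -> tuple[list[ExpressionStudy], TruthTable]:
    """Generate one :class:`ExpressionStudy` per configured study plus ground truth.

    Per-gene baselines are drawn once and shared across studies, so the only
    between-study differences are platform coverage, attenuation, group
    sizes and noise.  Case means of DE genes are shifted by
    ``direction * effect_lfc * attenuation`` relative to controls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    width = len(str(config.n_genes))
    genes = np.array([f"g{i:0{width}d}" for i in range(1, config.n_genes + 1)])

    n_de = int(round(config.frac_de * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = int(round(config.frac_up * n_de))
    up_idx = de_idx[:n_up]
    down_idx = de_idx[n_up:]

    direction = np.full(config.n_genes, "", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    signed_effect = np.zeros(config.n_genes)
    signed_effect[up_idx] = config.effect_lfc
    signed_effect[down_idx] = -config.effect_lfc

    truth = TruthTable(
        pd.DataFrame(
            {
                "is_de": signed_effect != 0,
                "direction": np.where(direction == "", pd.NA, direction),
                "true_lfc": signed_effect,
            },
            index=pd.Index(genes, name="gene_id"),
        )
    )

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    n_cases = _broadcast(config.cases_per_study, config.n_studies, "cases_per_study")
    n_ctrls = _broadcast(config.controls_per_study, config.n_studies, "controls_per_study")
    atten = _broadcast(config.attenuation, config.n_studies, "attenuation")

    universe_size = int(round(config.platform_coverage * config.n_genes))
    non_de_idx = np.setdiff1d(np.arange(config.n_genes), de_idx)

    studies: list[ExpressionStudy] = []
    for s in range(config.n_studies):
        study_id = f"study{s + 1}"
        # platform universe: all DE genes plus a random complement of non-DE genes
        n_extra = max(universe_size - n_de, 0)
        extra = rng.choice(non_de_idx, size=min(n_extra, len(non_de_idx)), replace=False)
        idx = np.sort(np.concatenate([de_idx, extra]))

        nc, nk = n_cases[s], n_ctrls[s]
        case_ids = [f"{study_id}_case{i + 1}" for i in range(nc)]
        ctrl_ids = [f"{study_id}_ctrl{i + 1}" for i in range(nk)]
        mean = np.tile(baseline[idx][:, None], (1, nc + nk))
        mean[:, :nc] += signed_effect[idx][:, None] * atten[s]
        values = mean + rng.normal(0.0, config.noise_sd, mean.shape)

        matrix = pd.DataFrame(
            values, index=pd.Index(genes[idx], name="gene_id"), columns=case_ids + ctrl_ids
        )
        groups = pd.Series(
            ["case"] * nc + ["control"] * nk, index=matrix.columns, name="group"
        )
        studies.append(ExpressionStudy(study_id=study_id, matrix=matrix, groups=groups))

    return studies, truth


def simulate_null_rank_matrix(m: int, n: int, seed: int, direction: str = "up") -> RankMatrix:
    """Rank matrix with every study column an independent uniform permutation.

    This is the exact null of the aggregation statistic: each gene's
    normalized rank in each study is marginally uniform on {1/m, ..., 1}.
    """
    if m < 1:
        raise ValueError(f"m: must be >= 1, got {m}")
    if n < 1:
        raise ValueError(f"n: must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    width = len(str(m))
    genes = [f"g{i:0{width}d}" for i in range(1, m + 1)]
    ranks = np.column_stack([rng.permutation(m) + 1 for _ in range(n)]) / m
    df = pd.DataFrame(
        ranks, index=pd.Index(genes, name="gene_id"),
        columns=[f"study{j + 1}" for j in range(n)],
    )
    return RankMatrix(ranks=df, direction=direction)


def simulate_network(
    n_nodes: int,
    edge_prob: float,
    n_planted_hubs: int = 0,
    hub_boost: float = 0.0,
    seed: int = 0,
    node_ids: Sequence[str] | None = None,
    hub_ids: Sequence[str] | None = None,
) -> nx.Graph:
    """Erdos-Renyi-style graph with optional planted hubs.

    Every unordered pair gets an edge with probability ``edge_prob``; pairs
    involving a planted hub additionally get an edge with probability
    ``hub_boost``, so hubs have a higher expected degree.  ``hub_ids``
    selects specific nodes as hubs (otherwise the first ``n_planted_hubs``
    nodes are used).  Simple and undirected; deterministic under ``seed``.
    """
    for name, p in (("edge_prob", edge_prob), ("hub_boost", hub_boost)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}: must be in [0, 1], got {p}")
    if node_ids is not None:
        node_ids = list(node_ids)
        if len(node_ids) != n_nodes:
            raise ValueError("node_ids: length must equal n_nodes")
    else:
        width = len(str(max(n_nodes, 1)))
        node_ids = [f"n{i:0{width}d}" for i in range(1, n_nodes + 1)]
    if hub_ids is not None:
        hubs = set(hub_ids)
        if not hubs <= set(node_ids):
            raise ValueError("hub_ids: must be a subset of node_ids")
    else:
        if n_planted_hubs > n_nodes:
            raise ValueError("n_planted_hubs: cannot exceed n_nodes")
        hubs = set(node_ids[:n_planted_hubs])

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(node_ids)
    is_hub = np.array([v in hubs for v in node_ids])
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(len(iu)) < edge_prob
    if hub_boost > 0:
        hub_pair = is_hub[iu] | is_hub[ju]
        keep |= hub_pair & (rng.random(len(iu)) < hub_boost)
    for i, j in zip(iu[keep], ju[keep]):
        g.add_edge(node_ids[i], node_ids[j], score=1.0)
    return g
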