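"""Robust rank aggregation with exact order-statistic p-values.

The aggregation statistic works on normalized ranks.  With n studies and a
shared universe of m genes, a gene's rank vector r = (r_1, ..., r_n) holds
its position in each study's full ranking divided by m, so each study
column of the rank matrix is a permutation of {1/m, 2/m, ..., 1} and under
the null every r_j is (discretely) uniform.

For the sorted vector r_(1) <= ... <= r_(n), the probability that at least
k of n i.i.d. uniforms fall at or below x is the binomial tail

    beta_{k,n}(x) = sum_{l=k}^{n} C(n, l) x^l (1-x)^(n-l),

which equals the Beta(k, n-k+1) distribution function at x.  The
aggregation score is

    rho(r) = min_k beta_{k,n}(r_(k)),

small when the gene sits near the top of several lists.  Because rho is a
minimum of n dependent p-values, its null distribution is not uniform; the
exact p-value P(rho_null <= rho) is obtained from the joint distribution
of uniform order statistics: with b_j = 1 - BetaQuantile(rho; n-j+1, j),

    P(rho_null <= rho) = 1 - P(U_(1) <= b_1, ..., U_(n) <= b_n),

where the joint probability is evaluated exactly by a dynamic program over
the counts of uniforms falling below each bound.  The per-gene exact
p-values are then Bonferroni- (default) or Benjamini-Hochberg-adjusted
over the universe, separately within the up and down analyses.
"""

from __future__ import annotations

from math import comb
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankMatrix",
    "RraResult",
    "intersect_universe",
    "normalize_ranks",
    "beta_score",
    "rho_score",
    "exact_pvalue",
    "adjust_pvalues",
    "aggregate",
    "run_meta",
]


@dataclass
class RankMatrix:
    """Genes x studies matrix of normalized ranks over a shared universe.

    Every column must be a permutation of {1/m, ..., 1}; checked on demand
    by :meth:`check_valid`.
    """

    ranks: pd.DataFrame  # index gene_id, columns study ids, values in (0, 1]
    direction: str

    @property
    def m(self) -> int:
        return self.ranks.shape[0]

    @property
    def n(self) -> int:
        return self.ranks.shape[1]

    def check_valid(self) -> None:
        m = self.m
        expected = np.arange(1, m + 1) / m
        for col in self.ranks.columns:
            vals = np.sort(self.ranks[col].to_numpy())
            if not np.allclose(vals, expected, rtol=0, atol=1e-12):
                raise ValueError(f"column {col!r} is not a permutation of {{1/m..1}}")


@dataclass
class RraResult:
    """Aggregation output: per-gene rho score, exact and adjusted p-values."""

    table: pd.DataFrame  # index gene_id; columns rho, exact_p, adj_p; sorted by exact_p
    direction: str

    def robust_genes(self, alpha: float = 0.05) -> list[str]:
        """Genes called robust: adjusted p-value strictly below ``alpha``."""
        return list(self.table.index[self.table["adj_p"] < alpha])

    def ppi_genes(self, alpha: float = 0.01, use_adjusted: bool = False) -> list[str]:
        """Genes feeding the PPI stage (default: exact p-value < alpha)."""
        col = "adj_p" if use_adjusted else "exact_p"
        return list(self.table.index[self.table[col] < alpha])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "direction", self.direction)
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")


def intersect_universe(universes: Sequence[Iterable[str]]) -> list[str]:
    """Lexicographically sorted intersection of the studies' gene universes."""
    if len(universes) < 2:
        raise ValueError("need at least 2 universes to intersect")
    sets = [set(u) for u in universes]
    common = set.intersection(*sets)
    if not common:
        raise ValueError("gene universes have an empty intersection")
    return sorted(common)


def normalize_ranks(lists, universe: Sequence[str], direction: str | None = None) -> RankMatrix:
    """Build the normalized rank matrix from one full ranking per study.

    ``lists`` is either a mapping {study_id: ordered genes} or a sequence
    of :class:`~rankmeta.diffexpr.RankedGeneList`.  Every list must be a
    permutation of ``universe``; gene at position i (1-based) of a list of
    length m gets normalized rank i/m in that study.
    """
    if isinstance(lists, Mapping):
        items = list(lists.items())
    else:
        items = [(rl.study_id, rl.genes) for rl in lists]
        if direction is None:
            dirs = {rl.direction for rl in lists}
            if len(dirs) == 1:
                direction = dirs.pop()
    if direction is None:
        direction = "up"
    universe = list(universe)
    uset = set(universe)
    m = len(universe)
    cols = {}
    for study_id, genes in items:
        genes = list(genes)
        gset = set(genes)
        if gset != uset or len(genes) != m:
            missing = sorted(uset - gset)[:5]
            extra = sorted(gset - uset)[:5]
            raise ValueError(
                f"list for {study_id!r} is not a permutation of the universe "
                f"(missing {missing}, extra {extra})"
            )
        pos = {g: i + 1 for i, g in enumerate(genes)}
        cols[study_id] = np.array([pos[g] for g in universe]) / m
    ranks = pd.DataFrame(cols, index=pd.Index(universe, name="gene_id"))
    return RankMatrix(ranks=ranks, direction=direction)


def beta_score(x: float, k: int, n: int) -> float:
    """P(at least k of n i.i.d. uniforms are <= x): the binomial tail sum.

    Equals the Beta(k, n-k+1) CDF at x.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must be in [0, 1], got {x}")
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    return float(sum(comb(n, l) * x**l * (1 - x) ** (n - l) for l in range(k, n + 1)))


def _rho_scores(ranks: np.ndarray) -> np.ndarray:
    """Vectorized rho over rows of a (m, n) rank array (Beta-CDF form)."""
    r = np.sort(np.asarray(ranks, dtype=float), axis=1)
    n = r.shape[1]
    k = np.arange(1, n + 1)
    betas = special.betainc(k[None, :], n - k[None, :] + 1, r)
    return betas.min(axis=1)


def rho_score(r: Sequence[float]) -> float:
    """Aggregation score: min over k of beta_{k,n}(r_(k)) for one rank vector."""
    r = np.asarray(list(r), dtype=float)
    if r.size == 0:
        raise ValueError("rank vector is empty")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalized ranks must lie in (0, 1]")
    rs = np.sort(r)
    n = r.size
    return float(min(beta_score(rs[k - 1], k, n) for k in range(1, n + 1)))


def _joint_orderstat_cdf(bounds: np.ndarray) -> np.ndarray:
    """P(U_(1) <= b_1, ..., U_(n) <= b_n) for each row of nondecreasing bounds.

    Dynamic program over N_k = #{uniforms <= b_k}: the event is
    {N_k >= k for all k} with N_n = n.  f[:, j] after step k holds the
    probability that exactly j points lie at or below b_k with all earlier
    constraints met, counting only the probability mass of those j points.
    Accumulated in extended precision.
    """
    b = np.asarray(bounds, dtype=np.longdouble)
    m, n = b.shape
    delta = np.diff(np.concatenate([np.zeros((m, 1), dtype=np.longdouble), b], axis=1), axis=1)
    f = np.zeros((m, n + 1), dtype=np.longdouble)
    f[:, 0] = 1.0
    for k in range(1, n + 1):
        new = np.zeros_like(f)
        d = delta[:, k - 1]
        # powers of the interval width (b_k - b_{k-1})
        dpow = np.ones((m, n + 1), dtype=np.longdouble)
        for t in range(1, n + 1):
            dpow[:, t] = dpow[:, t - 1] * d
        for j in range(k, n + 1):
            acc = np.zeros(m, dtype=np.longdouble)
            for i in range(k - 1, j + 1):
                acc += f[:, i] * comb(n - i, j - i) * dpow[:, j - i]
            new[:, j] = acc
        f = new
    return f[:, n]


def _exact_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Vectorized exact p-values P(rho_null <= rho) for score vector ``rho``."""
    rho = np.asarray(rho, dtype=float)
    out = np.empty_like(rho)
    if n == 1:
        return rho.copy()
    # bounds b_j = 1 - BetaQuantile(rho; n-j+1, j), nondecreasing in j
    bounds = np.empty((rho.size, n))
    for j in range(1, n + 1):
        bounds[:, j - 1] = 1.0 - special.betaincinv(n - j + 1, j, rho)
    bounds = np.maximum.accumulate(np.clip(bounds, 0.0, 1.0), axis=1)
    joint = _joint_orderstat_cdf(bounds)
    out = 1.0 - np.asarray(joint, dtype=np.longdouble)
    return np.clip(out.astype(float), 0.0, 1.0)


def exact_pvalue(rho: float, n: int) -> float:
    """Exact null probability that the rho score of n uniform ranks is <= rho.

    Monotone nondecreasing in rho and never smaller than rho itself (a
    minimum of n p-values cannot be more significant than its own null
    quantile suggests).
    """
    if not 0.0 < rho <= 1.0:
        raise ValueError(f"rho must be in (0, 1], got {rho}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return float(_exact_pvalues(np.array([rho]), n)[0])


def adjust_pvalues(p, m: int | None = None, method: str = "bonferroni") -> np.ndarray:
    """Multiplicity adjustment: Bonferroni (default, times m capped at 1) or BH."""
    p = np.asarray(p, dtype=float)
    if method == "bonferroni":
        if m is None:
            m = p.size
        return np.minimum(1.0, p * m)
    if method == "bh":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown adjustment method {method!r}")


def aggregate(
    matrix: RankMatrix,
    alpha_robust: float = 0.05,
    alpha_ppi: float = 0.01,
    adjust: str = "bonferroni",
) -> RraResult:
    """Score every universe gene and adjust for multiplicity.

    Returns the per-gene table (rho, exact_p, adj_p) sorted by exact_p then
    gene id.  Robust genes are those with adj_p < ``alpha_robust``; the
    PPI-input set uses exact_p < ``alpha_ppi`` (see :class:`RraResult`).
    """
    R = matrix.ranks.to_numpy()
    rho = _rho_scores(R)
    exact_p = _exact_pvalues(np.maximum(rho, np.finfo(float).tiny), matrix.n)
    adj_p = adjust_pvalues(exact_p, m=matrix.m, method=adjust)
    table = pd.DataFrame(
        {"rho": rho, "exact_p": exact_p, "adj_p": adj_p},
        index=matrix.ranks.index.copy(),
    )
    # sort by exact_p, ties by gene id (stable sort over a lexicographically
    # ordered index)
    table = table.loc[sorted(table.index)].sort_values("exact_p", kind="mergesort")
    return RraResult(table=table, direction=matrix.direction)


def run_meta(
    studies,
    adjust: str = "bonferroni",
    equal_var: bool = False,
) -> tuple[RraResult, RraResult]:
    """Full meta-analysis: per-study DE, universe intersection, rank aggregation.

    Runs differential expression on each study, intersects the platform
    universes, builds one full directional ranking per study and direction,
    and aggregates.  Returns the (up, down) result tables.
    """
    from .diffexpr import differential_expression, full_directional_ranking

    if len(studies) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    de_results = [differential_expression(s, equal_var=equal_var) for s in studies]
    universe = intersect_universe([s.universe for s in studies])
    results = []
    for direction in ("up", "down"):
        lists = [full_directional_ranking(de, direction, universe) for de in de_results]
        matrix = normalize_ranks(lists, universe, direction=direction)
        results.append(aggregate(matrix, adjust=adjust))
    return results[0], results[1]
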