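"""Gene-set over-representation analysis against GMT collections.

A query gene set (e.g. the robust DEGs) is tested term by term with the
one-sided hypergeometric (Fisher exact) test against a background
universe, with Benjamini-Hochberg control over the eligible terms.  The
collection arrives as a standard GMT file; no ontology structure is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["GeneSetCollection", "read_gmt", "hypergeometric_test", "enrich"]


@dataclass
class GeneSetCollection:
    """Named gene sets: term_id -> (term_name, member genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    source: str = ""

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id!r} has no member genes")

    def __len__(self) -> int:
        return len(self.terms)


def read_gmt(path, source: str | None = None) -> GeneSetCollection:
    """Read a tab-separated GMT file: term_id, description, member genes...."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected term, description, >=1 gene")
            term_id, name = parts[0], parts[1]
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term id {term_id!r}")
            members = frozenset(g for g in parts[2:] if g)
            if not members:
                raise ValueError(f"{path}:{lineno}: term {term_id!r} has no genes")
            terms[term_id] = (name, members)
    return GeneSetCollection(terms=terms, source=source or str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term_id, (name, members) in collection.terms.items():
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")


def hypergeometric_test(k: int, n_q: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) with X ~ Hypergeometric(N, K, n_q).

    k: overlap between query and term; n_q: query size; K: term size;
    N: universe size.  Equals the one-sided Fisher exact p on the 2x2 table.
    """
    if not (0 <= k <= min(n_q, K) and n_q <= N and K <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, n_q={n_q}, K={K}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n_q))


def enrich(
    query,
    collection: GeneSetCollection,
    universe,
    min_term: int = 5,
    max_term: int = 2000,
) -> pd.DataFrame:
    """Over-representation of ``query`` in each eligible term of ``collection``.

    Terms are restricted to the ``universe`` before testing and are
    eligible when their in-universe size lies in [min_term, max_term].
    Query genes outside the universe are ignored with a warning.  Returns
    one row per eligible term sorted by p-value, with BH-adjusted q-values.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        logger.warning(
            "%d query gene(s) outside the universe ignored (e.g. %s)",
            len(outside), sorted(outside)[:3],
        )
        query &= universe

    N, n_q = len(universe), len(query)
    rows = []
    for term_id, (name, members) in collection.terms.items():
        in_universe = members & universe
        K = len(in_universe)
        if not min_term <= K <= max_term:
            continue
        overlap = sorted(query & in_universe)
        k = len(overlap)
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap": k,
                "term_size": K,
                "query_size": n_q,
                "universe_size": N,
                "p_value": hypergeometric_test(k, n_q, K, N),
                "genes": ",".join(overlap),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "overlap", "term_size", "query_size",
            "universe_size", "p_value", "genes",
        ],
    )
    if len(table):
        table["q_value"] = multipletests(table["p_value"].to_numpy(), method="fdr_bh")[1]
        table = table.sort_values(
            ["p_value", "term_id"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["q_value"] = pd.Series(dtype=float)
    return table
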