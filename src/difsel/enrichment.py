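"""Hallmark gene-set over-representation analysis.

Selected mouse genes are translated to human symbols through an ortholog
map, then each gene set in a collection is tested for over-representation
in the query by an upper-tail hypergeometric test against the (translated)
filtered-universe background.  P-values are adjusted across the collection
by Benjamini-Hochberg step-up FDR and each set's enrichment score is
-log10 of its adjusted value.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection, OrthologMap

logger = logging.getLogger(__name__)


def map_orthologs(mouse_genes: Iterable[str], omap: OrthologMap) -> set[str]:
    """Translate mouse symbols to the union of paired human symbols.

    Many-to-many pairs use union semantics (each human symbol counted
    once).  Mouse genes with no pair are dropped and counted in the log,
    not raised.
    """
    if len(omap) == 0:
        raise ValueError("ortholog map is empty")
    mapped: set[str] = set()
    unmapped = 0
    for g in mouse_genes:
        human = omap.mouse_to_human.get(g)
        if human:
            mapped |= human
        else:
            unmapped += 1
    if unmapped:
        logger.info("ortholog mapping: %d mouse gene(s) had no human pair", unmapped)
    return mapped


def set_test(query: Iterable[str], gene_set: Iterable[str],
             universe: Iterable[str]) -> tuple[int, int, int, int, float]:
    """Hypergeometric over-representation test of ``query`` in ``gene_set``.

    Both query and set are intersected with the universe first.  Returns
    ``(k, K, n, N, p)`` with N the universe size, K the in-universe set
    size, n the in-universe query size, k their overlap, and p the
    upper-tail probability P(X >= k).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    gene_set = set(gene_set) & universe
    k = len(query & gene_set)
    K = len(gene_set)
    n = len(query)
    N = len(universe)
    p = float(hypergeom.sf(k - 1, N, K, n))
    return k, K, n, N, p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped to 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_collection(query: Iterable[str], collection: GeneSetCollection,
                      universe: Iterable[str]) -> pd.DataFrame:
    """Test every set in the collection and score by -log10(BH FDR).

    Returns one row per set with columns ``set, k, K, n, N, p, q, score``,
    sorted by score descending with ties broken by set name.  A q of
    exactly zero (underflow) is capped so the score stays finite.
    """
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    universe = set(universe)
    names = sorted(collection.sets)
    rows = [set_test(query, collection[name], universe) for name in names]
    table = pd.DataFrame(rows, columns=["k", "K", "n", "N", "p"])
    table.insert(0, "set", names)
    table["q"] = bh_fdr(table["p"].to_numpy())
    tiny = np.finfo(float).tiny
    table["score"] = -np.log10(np.maximum(table["q"].to_numpy(), tiny))
    table = table.sort_values(["score", "set"], ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    return table


def enrich_mouse_query(mouse_query: Iterable[str], mouse_universe: Iterable[str],
                       collection: GeneSetCollection,
                       omap: OrthologMap) -> pd.DataFrame:
    """Ortholog-translate a mouse query and universe, then enrich.

    Query and background universe are both mapped mouse -> human so the
    hypergeometric margins live in a single namespace.
    """
    query_h = map_orthologs(mouse_query, omap)
    universe_h = map_orthologs(mouse_universe, omap)
    return enrich_collection(query_h, collection, universe_h)
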