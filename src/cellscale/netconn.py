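"""Network connectivity of size-correlated gene sets vs a random-set null.

The statistic is *edges per gene*: the number of interaction-network edges
with both endpoints inside a gene set, divided by the set size.  Genes
absent from the network contribute no edges but stay in the denominator
(a conservative convention).  The null distribution comes from uniformly
sampled same-size gene sets — either Monte Carlo (with an add-one
empirical p, so p is never 0) or by exhaustive subset enumeration for
small universes (exact tail fraction).
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Optional, Sequence, Set

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ConnectivityResult, ValidationError

logger = logging.getLogger(__name__)

#: Refuse exhaustive enumeration beyond this many subsets.
MAX_EXHAUSTIVE_SUBSETS = 2_000_000


def select_significant(
    table: pd.DataFrame, direction: str, alpha: float = 0.05
) -> Set[str]:
    """Features with adjusted p < alpha whose r sign matches ``direction``."""
    if direction not in ("positive", "negative"):
        raise ValidationError(f"direction must be positive|negative, got {direction!r}")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    r = table["r"].to_numpy(dtype=float)
    p_adj = table["p_adj"].to_numpy(dtype=float)
    sign_ok = (r > 0) if direction == "positive" else (r < 0)
    mask = np.isfinite(p_adj) & (p_adj < alpha) & sign_ok
    selected = set(table.loc[mask, "feature_id"].astype(str))
    if not selected:
        logger.warning("no %s-correlating features at adjusted p < %g", direction, alpha)
    return selected


def connectivity(graph: nx.Graph, genes: Iterable[str]) -> tuple:
    """Induced edge count and edges per gene for a gene set."""
    gene_set = set(genes)
    if not gene_set:
        raise ValidationError("connectivity of an empty gene set is undefined")
    present = gene_set & set(graph.nodes)
    edges = graph.subgraph(present).number_of_edges()
    missing = len(gene_set) - len(present)
    if missing:
        logger.info("%d set genes absent from the network (kept in denominator)", missing)
    return edges, edges / len(gene_set)


def _adjacency(graph: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v in graph.edges():
        i, j = index.get(u), index.get(v)
        if i is not None and j is not None:
            a[i, j] = a[j, i] = True
    return a


def connectivity_null(
    graph: nx.Graph,
    set_size: int,
    observed_edges: int,
    n_iterations: int = 1000,
    universe: Optional[Iterable[str]] = None,
    seed: int = 0,
    exhaustive: bool = False,
    gene_set: str = "",
    keep_null: bool = False,
) -> ConnectivityResult:
    """Compare an observed induced-edge count against same-size random sets.

    Random sets are drawn uniformly without replacement from ``universe``
    (default: all network nodes).  Monte Carlo mode reports the add-one
    empirical p, ``(1 + #{null >= observed}) / (n_iterations + 1)``;
    exhaustive mode enumerates every subset and reports the exact tail
    fraction ``#{null >= observed} / N``.
    """
    nodes = sorted(universe) if universe is not None else sorted(graph.nodes)
    if set_size < 1:
        raise ValidationError("set_size must be >= 1")
    if set_size > len(nodes):
        raise ValidationError(
            f"set_size {set_size} exceeds the universe size {len(nodes)}"
        )
    if not exhaustive and n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    adjacency = _adjacency(graph, nodes)
    observed_epg = observed_edges / set_size

    if exhaustive:
        n_subsets = math.comb(len(nodes), set_size)
        if n_subsets > MAX_EXHAUSTIVE_SUBSETS:
            raise ValidationError(
                f"exhaustive enumeration of {n_subsets} subsets refused; "
                "use Monte Carlo sampling"
            )
        counts = np.empty(n_subsets, dtype=np.int64)
        for k, combo in enumerate(itertools.combinations(range(len(nodes)), set_size)):
            idx = np.fromiter(combo, dtype=np.intp)
            counts[k] = np.count_nonzero(adjacency[np.ix_(idx, idx)]) // 2
        null_epg = counts / set_size
        empirical_p = float(np.mean(null_epg >= observed_epg - 1e-12))
        empirical_p = max(empirical_p, float(np.nextafter(0.0, 1.0)))
        n_used = n_subsets
        seed_used: Optional[int] = None
    else:
        rng = np.random.default_rng(seed)
        counts = np.empty(n_iterations, dtype=np.int64)
        n_nodes = len(nodes)
        for k in range(n_iterations):
            idx = rng.choice(n_nodes, size=set_size, replace=False)
            counts[k] = np.count_nonzero(adjacency[np.ix_(idx, idx)]) // 2
        null_epg = counts / set_size
        empirical_p = (1 + int(np.sum(null_epg >= observed_epg - 1e-12))) / (
            n_iterations + 1
        )
        n_used = n_iterations
        seed_used = seed

    null_mean = float(null_epg.mean())
    null_sd = float(null_epg.std(ddof=0))
    if null_mean > 0:
        ratio = observed_epg / null_mean
    elif observed_epg > 0:
        ratio = math.inf
        logger.warning("null mean is 0 with a positive observation: ratio is infinite")
    else:
        ratio = math.nan
    return ConnectivityResult(
        gene_set=gene_set,
        set_size=set_size,
        observed_edges=int(observed_edges),
        observed_edges_per_gene=observed_epg,
        null_mean_edges_per_gene=null_mean,
        null_sd_edges_per_gene=null_sd,
        enrichment_ratio=ratio,
        empirical_p=empirical_p,
        n_iterations=n_used,
        seed=seed_used,
        exhaustive=exhaustive,
        null_values=null_epg if keep_null else None,
    )


def connectivity_enrichment(
    graph: nx.Graph,
    genes: Iterable[str],
    n_iterations: int = 1000,
    universe: Optional[Iterable[str]] = None,
    seed: int = 0,
    exhaustive: bool = False,
    gene_set: str = "",
    keep_null: bool = False,
) -> ConnectivityResult:
    """Observed connectivity of ``genes`` plus its random-set null, in one call."""
    gene_list = sorted(set(genes))
    edges, _ = connectivity(graph, gene_list)
    return connectivity_null(
        graph,
        set_size=len(gene_list),
        observed_edges=edges,
        n_iterations=n_iterations,
        universe=universe,
        seed=seed,
        exhaustive=exhaustive,
        gene_set=gene_set,
        keep_null=keep_null,
    )
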