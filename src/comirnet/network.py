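"""Cooperative miRNA network (CMN) construction.

Every pair of reliable miRNAs is tested for a surprisingly large
overlap of DE target genes with the upper-tail hypergeometric
probability

    P_overlap = sum_{k=m}^{min(Ni,Nj)} C(Ni,k) C(N-Ni, Nj-k) / C(N, Nj)

where Ni, Nj count each miRNA's DE targets, N the direction's DE
universe and m the shared DE targets. BH-significant pairs (adjusted
p < 0.01) become edges weighted by the Jaccard target-overlap score;
p-values are kept as edge attributes but never used as weights.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd
from scipy import stats

from .preprocess import bh_adjust

logger = logging.getLogger(__name__)

EDGE_COLUMNS = [
    "mirna_i", "mirna_j", "m", "N_i", "N_j", "N",
    "p_overlap", "p_adj", "s_overlap", "direction",
]


def overlap_pvalue(n_i: int, n_j: int, n_total: int, m: int) -> float:
    """Upper-tail hypergeometric probability of sharing >= m of N DE genes."""
    if n_total < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= n_i <= n_total and 0 <= n_j <= n_total):
        raise ValueError(f"N_i={n_i}, N_j={n_j} must lie in [0, N={n_total}]")
    if not 0 <= m <= min(n_i, n_j):
        raise ValueError(f"m={m} must lie in [0, min(N_i, N_j)={min(n_i, n_j)}]")
    return float(stats.hypergeom.sf(m - 1, n_total, n_i, n_j))


def overlap_score(targets_i, targets_j, same_mirna: bool = False) -> float:
    """Jaccard target-overlap score; defined as 1 for a miRNA with itself."""
    if same_mirna:
        return 1.0
    a, b = frozenset(targets_i), frozenset(targets_j)
    union = a | b
    if not union:
        logger.info("overlap_score: both target sets empty, returning 0 by convention")
        return 0.0
    return len(a & b) / len(union)


def build_cmn(
    de_target_sets: Mapping[str, frozenset],
    de_total: int,
    direction: str,
    alpha: float = 0.01,
    score_sets: Mapping[str, frozenset] | None = None,
) -> nx.Graph:
    """Build one direction's CMN from reliable miRNAs' DE target sets.

    All unordered pairs with both DE-target counts >= 1 are tested; BH
    runs across the tested pairs; surviving pairs become edges. When
    ``score_sets`` is given (e.g. full target sets) the Jaccard edge
    weight is computed on those sets instead of the DE-restricted ones.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if len(de_target_sets) < 2:
        g = nx.Graph(direction=direction, N=de_total)
        g.add_nodes_from(sorted(de_target_sets))
        return g
    score_sets = score_sets if score_sets is not None else de_target_sets
    g = nx.Graph(direction=direction, N=de_total)
    mirnas = sorted(de_target_sets)
    g.add_nodes_from(mirnas)
    pairs, pvals = [], []
    for mi, mj in combinations(mirnas, 2):
        ti, tj = de_target_sets[mi], de_target_sets[mj]
        if not ti or not tj:
            logger.info("skipping pair (%s, %s): empty DE target set", mi, mj)
            continue
        m = len(ti & tj)
        p = overlap_pvalue(len(ti), len(tj), de_total, m)
        pairs.append((mi, mj, m, len(ti), len(tj)))
        pvals.append(p)
    if not pairs:
        return g
    adj = bh_adjust(pvals)
    for (mi, mj, m, ni, nj), p, pa in zip(pairs, pvals, adj):
        if pa < alpha:
            g.add_edge(
                mi, mj,
                m=m, N_i=ni, N_j=nj, N=de_total,
                p_overlap=p, p_adj=float(pa),
                s_overlap=overlap_score(score_sets[mi], score_sets[mj]),
                weight=overlap_score(score_sets[mi], score_sets[mj]),
                direction=direction,
            )
    return g


def superimpose(cmn_up: nx.Graph, cmn_down: nx.Graph) -> nx.Graph:
    """Merge the up- and down-regulation CMNs into one classed network.

    Node class is ``both`` when a miRNA appears in both inputs; parallel
    edges are collapsed keeping each direction's attributes.
    """
    if cmn_up.graph.get("direction") != "up" or cmn_down.graph.get("direction") != "down":
        raise ValueError("superimpose expects an up-CMN and a down-CMN, in that order")
    merged = nx.Graph(direction="merged")
    for node in set(cmn_up) | set(cmn_down):
        if node in cmn_up and node in cmn_down:
            cls = "both"
        elif node in cmn_up:
            cls = "up_only"
        else:
            cls = "down_only"
        merged.add_node(node, node_class=cls)
    for g, tag in ((cmn_up, "up"), (cmn_down, "down")):
        for u, v, data in g.edges(data=True):
            if merged.has_edge(u, v):
                merged[u][v][tag] = dict(data)
                merged[u][v]["weight"] = max(merged[u][v]["weight"], data["s_overlap"])
            else:
                merged.add_edge(u, v, weight=data["s_overlap"], **{tag: dict(data)})
    return merged


def edge_table(cmn: nx.Graph) -> pd.DataFrame:
    """Flatten a direction-specific CMN into its edge-list table."""
    rows = []
    for u, v, d in sorted(cmn.edges(data=True)):
        rows.append(
            {
                "mirna_i": u, "mirna_j": v, "m": d["m"],
                "N_i": d["N_i"], "N_j": d["N_j"], "N": d["N"],
                "p_overlap": d["p_overlap"], "p_adj": d["p_adj"],
                "s_overlap": d["s_overlap"], "direction": d["direction"],
            }
        )
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)
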