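"""Per-miRNA DE-target enrichment screening and over-representation analysis.

A miRNA is a "reliable regulator" when its targets are over-represented
among DE genes: a 2x2 table (target vs non-target x DE vs non-DE) is
tested with the right-sided Fisher exact test and BH-adjusted across all
miRNAs within a direction. The same right-tail hypergeometric machinery
drives generic gene-set over-representation against an annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .interactions import TargetMap
from .preprocess import DESignature, bh_adjust


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # target & DE
    b: int  # target & not DE
    c: int  # non-target & DE
    d: int  # non-target & not DE

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def universe_size(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AnnotationTable:
    """Records of (term_id, term_name, gene_id)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        for col in ("term_id", "term_name", "gene_id"):
            if col not in df.columns:
                raise ValueError(f"annotation table missing column '{col}'")
        df = df[["term_id", "term_name", "gene_id"]].copy()
        dup = df.duplicated(subset=["term_id", "gene_id"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                f"duplicate (term_id, gene_id) pair: ({first.term_id}, {first.gene_id})"
            )
        self.records = df

    def term_sets(self) -> dict:
        out: dict[str, dict] = {}
        for (tid, tname), sub in self.records.groupby(["term_id", "term_name"], sort=True):
            out[tid] = {"name": tname, "genes": frozenset(sub["gene_id"])}
        return out

    def __len__(self) -> int:
        return len(self.records)


def build_contingency(
    targets: Iterable[str], de_set: Iterable[str], universe: Iterable[str]
) -> ContingencyTable2x2:
    """Count the 2x2 table of target membership against DE membership."""
    universe = frozenset(universe)
    de = frozenset(de_set)
    if not de <= universe:
        raise ValueError("DE set must be contained in the universe")
    t = frozenset(targets) & universe
    a = len(t & de)
    b = len(t - de)
    c = len(de - t)
    return ContingencyTable2x2(a=a, b=b, c=c, d=len(universe) - a - b - c)


def fisher_right(table: ContingencyTable2x2) -> float:
    """Right-sided Fisher exact p-value: P(X >= a) for the hypergeometric
    X with population a+b+c+d, a+b marked, a+c drawn."""
    return float(
        stats.hypergeom.sf(
            table.a - 1, table.universe_size, table.a + table.b, table.a + table.c
        )
    )


def screen_mirnas(
    de_targets: Mapping[str, Mapping[str, frozenset]],
    signature: DESignature,
    universe: Iterable[str],
    target_map: TargetMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher-screen every miRNA in both directions; BH within a direction.

    ``de_targets`` is the output of :func:`comirnet.interactions.de_target_sets`
    and is used for reporting DE target counts; the contingency table uses
    the miRNA's full reliable target set against the direction's DE set.
    Returns one row per (miRNA, direction) with the table counts, p, BH
    adjusted p and the ``reliable`` flag (p_adj strictly < alpha).
    """
    if not de_targets:
        raise ValueError("no miRNAs to screen")
    universe = frozenset(universe)
    rows = []
    for direction in ("up", "down"):
        de_set = (signature.up if direction == "up" else signature.down) & universe
        mirnas = sorted(de_targets)
        pvals = []
        for m in mirnas:
            tab = build_contingency(target_map[m], de_set, universe)
            pvals.append(fisher_right(tab))
            rows.append(
                {
                    "mirna_id": m,
                    "direction": direction,
                    "a": tab.a, "b": tab.b, "c": tab.c, "d": tab.d,
                    "n_de_targets": len(de_targets[m][direction]),
                    "p": pvals[-1],
                }
            )
        adj = bh_adjust(pvals)
        for i, m in enumerate(mirnas):
            rows[-len(mirnas) + i]["p_adj"] = adj[i]
    out = pd.DataFrame(rows)
    out["reliable"] = out["p_adj"] < alpha
    return out


def reliable_mirnas(screen: pd.DataFrame, direction: str) -> list[str]:
    """miRNA ids flagged reliable for one direction, sorted."""
    sub = screen[(screen["direction"] == direction) & screen["reliable"]]
    return sorted(sub["mirna_id"])


def run_ora(
    gene_set: Iterable[str],
    universe: Iterable[str],
    annotations: AnnotationTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Right-tail hypergeometric over-representation of ``gene_set`` in each
    annotated term, BH-adjusted across terms.

    Terms with no gene in the universe are skipped. Returns a DataFrame
    sorted by adjusted then raw p.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = frozenset(gene_set)
    if not genes <= universe:
        raise ValueError("gene set must be contained in the universe")
    rows = []
    for tid, info in annotations.term_sets().items():
        term_genes = info["genes"] & universe
        if not term_genes:
            continue
        overlap = len(term_genes & genes)
        p = float(
            stats.hypergeom.sf(overlap - 1, len(universe), len(term_genes), len(genes))
        )
        rows.append(
            {
                "term_id": tid,
                "term_name": info["name"],
                "overlap": overlap,
                "term_size": len(term_genes),
                "p": p,
            }
        )
    out = pd.DataFrame(
        rows, columns=["term_id", "term_name", "overlap", "term_size", "p"]
    )
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
        out = out.sort_values(["p_adj", "p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["p_adj"] = np.array([], dtype=float)
    out["enriched"] = out["p_adj"] < alpha
    return out


def screening_universe(datasets, target_map: TargetMap) -> frozenset:
    """Default Fisher universe: genes measured on every platform and
    targeted by at least one reliable-interaction miRNA."""
    measured = None
    for ds in datasets:
        u = ds.universe if hasattr(ds, "universe") else frozenset(ds)
        measured = u if measured is None else measured & u
    if measured is None:
        raise ValueError("no datasets supplied")
    return measured & target_map.all_targets
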