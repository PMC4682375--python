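"""Model/Results driver for the cooperative miRNA network pipeline.

`CooperativeMirnaModel` holds the study inputs (expression datasets,
interaction table, marker list, optional annotations) and a
`PipelineConfig`; `fit()` executes every stage — normalization, per-set
DE calling, cross-dataset intersection, interaction filtering, the
reliable-regulator screen, CMN construction per direction, their
superposition and MCODE module extraction — and returns a
`CooperativeMirnaResults` carrying every intermediate plus a run
manifest and a `summary()` table.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .enrichment import reliable_mirnas, run_ora, screen_mirnas, screening_universe
from .interactions import (
    InteractionTable,
    MarkerList,
    TargetMap,
    apply_marker_filter,
    de_target_sets,
    filter_interactions,
)
from .mcode import mcode
from .network import build_cmn, edge_table, superimpose
from .preprocess import (
    DESignature,
    ExpressionDataset,
    check_cross_comparable,
    differential_expression,
    intersect_signatures,
    normalize_dataset,
    restrict_to_interaction_universe,
)

logger = logging.getLogger(__name__)


@dataclass
class CooperativeMirnaResults:
    """Fitted pipeline state: every stage output plus the run manifest."""

    config: PipelineConfig
    de_results: list
    signature: DESignature
    signature_restricted: DESignature
    target_map: TargetMap
    universe: frozenset
    screen: pd.DataFrame
    cmn_up: nx.Graph
    cmn_down: nx.Graph
    cmn_merged: nx.Graph
    modules_up: list
    modules_down: list
    ora_up: pd.DataFrame | None = None
    ora_down: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def modules(self) -> list:
        return list(self.modules_up) + list(self.modules_down)

    def module_table(self, direction: str) -> pd.DataFrame:
        from .mcode import format_score

        mods = self.modules_up if direction == "up" else self.modules_down
        return pd.DataFrame(
            [
                {
                    "cluster": m.rank,
                    "score": format_score(m.score),
                    "nodes": m.n_nodes,
                    "edges": m.n_edges,
                    "mirnas": ", ".join(m.member_list()),
                }
                for m in mods
            ],
            columns=["cluster", "score", "nodes", "edges", "mirnas"],
        )

    def summary(self) -> str:
        man = self.manifest
        lines = [
            "Cooperative miRNA network pipeline",
            "=" * 50,
            f"datasets:                {man['n_datasets']}",
            f"DE per dataset (up/down): "
            + ", ".join(f"{u}/{d}" for u, d in man['de_per_dataset']),
            f"intersection up/down:    {man['intersect_up']}/{man['intersect_down']}",
            f"after universe filter:   {man['restricted_up']}/{man['restricted_down']}",
            f"interactions retained:   {man['interaction_pairs']} pairs",
            f"miRNAs retained:         {man['mirnas_retained']}",
            f"reliable miRNAs up/down: {man['reliable_up']}/{man['reliable_down']}",
            f"CMN up:    {man['cmn_up_nodes']} nodes / {man['cmn_up_edges']} edges",
            f"CMN down:  {man['cmn_down_nodes']} nodes / {man['cmn_down_edges']} edges",
            f"CMN merged:{man['cmn_merged_nodes']} nodes / {man['cmn_merged_edges']} edges"
            f" ({man['n_both_nodes']} both-direction)",
            f"modules up/down:         {man['modules_up']}/{man['modules_down']}",
        ]
        for direction in ("up", "down"):
            tab = self.module_table(direction)
            if len(tab):
                lines.append("")
                lines.append(f"Top {direction}-regulation modules (score = 2E/(V-1)):")
                lines.append(tab.head(5).to_string(index=False))
        return "\n".join(lines)


class CooperativeMirnaModel:
    """Cooperative-miRNA-module inference from expression + target data."""

    def __init__(
        self,
        datasets: list[ExpressionDataset],
        interactions: InteractionTable,
        markers: MarkerList | None = None,
        annotations=None,
        config: PipelineConfig | None = None,
    ):
        if not datasets:
            raise ValueError("at least one expression dataset is required")
        self.datasets = list(datasets)
        self.interactions = interactions
        self.markers = markers
        self.annotations = annotations
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(cls, config: PipelineConfig) -> "CooperativeMirnaModel":
        from . import io

        datasets = [
            io.read_expression(expr, pheno) for expr, pheno in config.expression_files
        ]
        interactions = io.read_interactions(config.interactions_file)
        markers = io.read_markers(config.markers_file) if config.markers_file else None
        annotations = (
            io.read_annotations(config.annotations_file) if config.annotations_file else None
        )
        return cls(datasets, interactions, markers, annotations, config)

    def fit(self) -> CooperativeMirnaResults:
        cfg = self.config
        t0 = time.time()

        logger.info("stage preprocess: %d datasets", len(self.datasets))
        normalized = []
        for ds in self.datasets:
            diag = check_cross_comparable(ds)
            logger.info(
                "  %s: median spread %.3f, comparable=%s",
                ds.dataset_id, diag["median_spread"], diag["comparable"],
            )
            normalized.append(normalize_dataset(ds, mode=cfg.normalize))
        de_results = [
            differential_expression(ds, alpha=cfg.de_alpha, moderate=cfg.moderate_variance)
            for ds in normalized
        ]
        signature = intersect_signatures(de_results)

        logger.info("stage interactions: %d records", len(self.interactions))
        target_map = filter_interactions(self.interactions)
        if self.markers is not None and len(self.markers):
            target_map = apply_marker_filter(target_map, self.markers, cfg.marker_mode)
        if len(target_map) == 0:
            raise RuntimeError("stage interactions: no miRNAs survive filtering")
        signature_r = restrict_to_interaction_universe(signature, target_map)

        universe = screening_universe(normalized, target_map)
        de_sets = de_target_sets(target_map, signature_r)
        logger.info("stage enrichment: %d miRNAs, universe %d", len(target_map), len(universe))
        screen = screen_mirnas(
            de_sets, signature_r, universe, target_map, alpha=cfg.enrichment_alpha
        )

        cmns, modules = {}, {}
        for direction in ("up", "down"):
            rel = reliable_mirnas(screen, direction)
            de_total = len(
                (signature_r.up if direction == "up" else signature_r.down) & universe
            )
            rel_sets = {m: frozenset(de_sets[m][direction]) for m in rel}
            score_sets = (
                {m: target_map[m] for m in rel}
                if cfg.jaccard_mode == "all_targets" else None
            )
            cmns[direction] = build_cmn(
                rel_sets, max(de_total, 1), direction,
                alpha=cfg.network_alpha, score_sets=score_sets,
            )
            modules[direction] = mcode(cmns[direction], cfg.mcode)
            logger.info(
                "stage network[%s]: %d reliable, %d edges, %d modules",
                direction, len(rel), cmns[direction].number_of_edges(),
                len(modules[direction]),
            )
        merged = superimpose(cmns["up"], cmns["down"])

        ora_up = ora_down = None
        if self.annotations is not None and len(self.annotations):
            ann_universe = frozenset().union(universe, signature_r.up, signature_r.down)
            ora_up = run_ora(signature_r.up, ann_universe, self.annotations,
                             alpha=cfg.enrichment_alpha)
            ora_down = run_ora(signature_r.down, ann_universe, self.annotations,
                               alpha=cfg.enrichment_alpha)

        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "elapsed_s": round(time.time() - t0, 3),
            "n_datasets": len(self.datasets),
            "genes_per_dataset": [len(ds.genes) for ds in self.datasets],
            "de_per_dataset": [(len(r.up), len(r.down)) for r in de_results],
            "intersect_up": len(signature.up),
            "intersect_down": len(signature.down),
            "restricted_up": len(signature_r.up),
            "restricted_down": len(signature_r.down),
            "interaction_pairs": target_map.n_pairs,
            "mirnas_retained": len(target_map),
            "universe_size": len(universe),
            "reliable_up": len(reliable_mirnas(screen, "up")),
            "reliable_down": len(reliable_mirnas(screen, "down")),
            "cmn_up_nodes": cmns["up"].number_of_nodes(),
            "cmn_up_edges": cmns["up"].number_of_edges(),
            "cmn_down_nodes": cmns["down"].number_of_nodes(),
            "cmn_down_edges": cmns["down"].number_of_edges(),
            "cmn_merged_nodes": merged.number_of_nodes(),
            "cmn_merged_edges": merged.number_of_edges(),
            "n_both_nodes": sum(
                1 for _, d in merged.nodes(data=True) if d.get("node_class") == "both"
            ),
            "modules_up": len(modules["up"]),
            "modules_down": len(modules["down"]),
        }
        return CooperativeMirnaResults(
            config=cfg,
            de_results=de_results,
            signature=signature,
            signature_restricted=signature_r,
            target_map=target_map,
            universe=universe,
            screen=screen,
            cmn_up=cmns["up"],
            cmn_down=cmns["down"],
            cmn_merged=merged,
            modules_up=modules["up"],
            modules_down=modules["down"],
            ora_up=ora_up,
            ora_down=ora_down,
            manifest=manifest,
        )


def run_pipeline(config: PipelineConfig) -> CooperativeMirnaResults:
    """Read inputs per config, fit, and write every stage output."""
    from . import io

    results = CooperativeMirnaModel.from_files(config).fit()
    if config.out_dir is not None:
        write_results(results, config.out_dir)
    return results


def write_results(results: CooperativeMirnaResults, out_dir) -> None:
    """Persist every stage table under ``out_dir`` and check manifest counts."""
    import json

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in results.de_results:
        io.write_de_result(r, out / f"de_{r.dataset_id}.tsv")
    io.write_signature(results.signature_restricted, out / "signature.tsv")
    io.write_table(results.screen, out / "enrichment.tsv")
    io.write_table(edge_table(results.cmn_up), out / "cmn_up_edges.tsv")
    io.write_table(edge_table(results.cmn_down), out / "cmn_down_edges.tsv")
    io.write_graphml(results.cmn_merged, out / "cmn_merged.graphml")
    for direction in ("up", "down"):
        io.write_table(results.module_table(direction), out / f"modules_{direction}.tsv")
    if results.ora_up is not None:
        io.write_table(results.ora_up, out / "ora_up.tsv")
        io.write_table(results.ora_down, out / "ora_down.tsv")
    io._atomic_write(out / "manifest.json", json.dumps(results.manifest, indent=2) + "\n")
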