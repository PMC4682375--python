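"""Readers and writers for the pipeline's tab-separated artifacts.

All tables are TSV with a single header row. Writes are atomic
(temp-then-rename in the destination directory) so an interrupted run
never leaves a partial file behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import networkx as nx
import pandas as pd

from .enrichment import AnnotationTable
from .interactions import INTERACTION_COLUMNS, InteractionTable, MarkerList
from .mcode import CooperativeModule, format_score
from .preprocess import CONTROL, TREATED, DEResult, DESignature, ExpressionDataset
from .synthetic import GroundTruth, SyntheticStudy


class FileFormatError(ValueError):
    """Malformed input file; the message names file and offending field."""


def _atomic_write(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=index))


def read_expression(expr_path, pheno_path, dataset_id: str | None = None) -> ExpressionDataset:
    expr_path, pheno_path = Path(expr_path), Path(pheno_path)
    try:
        expr = pd.read_csv(expr_path, sep="\t")
    except ValueError as exc:
        raise FileFormatError(f"{expr_path}: {exc}") from exc
    if expr.columns[0] != "gene_id":
        raise FileFormatError(f"{expr_path}: first column must be 'gene_id', "
                              f"got '{expr.columns[0]}'")
    dupes = expr["gene_id"][expr["gene_id"].duplicated()]
    if len(dupes):
        raise FileFormatError(f"{expr_path}: duplicate gene_id '{dupes.iloc[0]}'")
    values = expr.drop(columns="gene_id")
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise FileFormatError(f"{expr_path}: non-numeric cells in column '{non_numeric[0]}'")
    pheno = pd.read_csv(pheno_path, sep="\t")
    for col in ("sample_id", "group"):
        if col not in pheno.columns:
            raise FileFormatError(f"{pheno_path}: missing column '{col}'")
    bad = sorted(set(pheno["group"]) - {CONTROL, TREATED})
    if bad:
        raise FileFormatError(f"{pheno_path}: unknown group label '{bad[0]}' "
                              f"(expected '{CONTROL}' or '{TREATED}')")
    groups = dict(zip(pheno["sample_id"].astype(str), pheno["group"]))
    samples = [str(s) for s in values.columns]
    missing = [s for s in samples if s not in groups]
    if missing:
        raise FileFormatError(f"{pheno_path}: no group label for sample '{missing[0]}'")
    return ExpressionDataset(
        dataset_id=dataset_id or expr_path.stem,
        genes=[str(g) for g in expr["gene_id"]],
        samples=samples,
        values=values.to_numpy(dtype=float),
        group=[groups[s] for s in samples],
    )


def write_expression(dataset: ExpressionDataset, expr_path, pheno_path) -> None:
    frame = dataset.to_frame().reset_index(names="gene_id")
    write_table(frame, expr_path)
    write_table(
        pd.DataFrame({"sample_id": dataset.samples, "group": dataset.group}), pheno_path
    )


def read_interactions(path) -> InteractionTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return InteractionTable(records=df)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_interactions(table: InteractionTable, path) -> None:
    write_table(table.records[INTERACTION_COLUMNS], path)


def read_markers(path) -> MarkerList:
    with open(path) as fh:
        ids = [line.strip() for line in fh if line.strip()]
    return MarkerList(ids=frozenset(ids))


def write_markers(markers, path) -> None:
    ids = markers.ids if isinstance(markers, MarkerList) else markers
    _atomic_write(path, "\n".join(sorted(ids)) + "\n")


def read_annotations(path) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    try:
        return AnnotationTable(records=df)
    except ValueError as exc:
        raise FileFormatError(f"{path}: {exc}") from exc


def write_annotations(table: AnnotationTable, path) -> None:
    write_table(table.records, path)


def write_de_result(result: DEResult, path) -> None:
    write_table(result.table.reset_index(), path)


def read_de_result(path, dataset_id: str | None = None) -> DEResult:
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "effect", "p", "p_adj", "status"):
        if col not in df.columns:
            raise FileFormatError(f"{path}: missing column '{col}'")
    return DEResult(
        dataset_id=dataset_id or Path(path).stem, table=df.set_index("gene_id")
    )


def write_signature(signature: DESignature, path) -> None:
    rows = [("up", g) for g in sorted(signature.up)]
    rows += [("down", g) for g in sorted(signature.down)]
    write_table(pd.DataFrame(rows, columns=["direction", "gene_id"]), path)


def read_signature(path, n_datasets: int = 1) -> DESignature:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return DESignature(
        up=frozenset(df.loc[df["direction"] == "up", "gene_id"]),
        down=frozenset(df.loc[df["direction"] == "down", "gene_id"]),
        n_datasets=n_datasets,
    )


def write_graphml(graph: nx.Graph, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    g = nx.Graph(**{k: v for k, v in graph.graph.items()})
    for v, data in graph.nodes(data=True):
        g.add_node(v, **{k: d for k, d in data.items() if not isinstance(d, dict)})
    for u, v, data in graph.edges(data=True):
        flat = {k: d for k, d in data.items() if not isinstance(d, dict)}
        for tag in ("up", "down"):
            if isinstance(data.get(tag), dict):
                flat.update({f"{tag}_{k}": d for k, d in data[tag].items()})
        g.add_edge(u, v, **flat)
    tmp = path.with_name(f".{path.name}.tmp")
    nx.write_graphml(g, tmp)
    os.replace(tmp, path)


def write_modules(modules: list[CooperativeModule], path) -> None:
    rows = [
        {
            "cluster": m.rank,
            "score": format_score(m.score),
            "nodes": m.n_nodes,
            "edges": m.n_edges,
            "mirnas": ", ".join(m.member_list()),
        }
        for m in modules
    ]
    write_table(pd.DataFrame(rows, columns=["cluster", "score", "nodes", "edges", "mirnas"]), path)


def read_modules(path) -> list[CooperativeModule]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        members = frozenset(m.strip() for m in str(row["mirnas"]).split(",") if m.strip())
        out.append(
            CooperativeModule(
                rank=int(row["cluster"]),
                members=members,
                n_nodes=int(row["nodes"]),
                n_edges=int(row["edges"]),
                score=float(row["score"]),
            )
        )
    return out


def write_truth(truth: GroundTruth, path) -> None:
    rows = [("de_up", g, "") for g in sorted(truth.de_up)]
    rows += [("de_down", g, "") for g in sorted(truth.de_down)]
    for i, group in enumerate(truth.coop_groups):
        for m in sorted(group):
            rows.append(("coop_group", m, f"group{i + 1}:{truth.group_direction[i]}"))
    for m in sorted(truth.planted_targets):
        for g in sorted(truth.planted_targets[m]):
            rows.append(("target", m, g))
    write_table(pd.DataFrame(rows, columns=["entity_type", "id1", "id2"]), path)


def read_truth(path) -> dict:
    """Ground-truth file as plain sets (de_up, de_down, coop_groups, targets)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    groups: dict[str, set] = {}
    for _, row in df[df["entity_type"] == "coop_group"].iterrows():
        groups.setdefault(row["id2"], set()).add(row["id1"])
    targets: dict[str, set] = {}
    for _, row in df[df["entity_type"] == "target"].iterrows():
        targets.setdefault(row["id1"], set()).add(row["id2"])
    return {
        "de_up": frozenset(df.loc[df["entity_type"] == "de_up", "id1"]),
        "de_down": frozenset(df.loc[df["entity_type"] == "de_down", "id1"]),
        "coop_groups": [frozenset(v) for _, v in sorted(groups.items())],
        "planted_targets": {m: frozenset(v) for m, v in targets.items()},
    }


def write_study(study: SyntheticStudy, out_dir) -> dict:
    """Write every synthetic artifact; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict = {"expression": []}
    for ds in study.datasets:
        expr = out / f"{ds.dataset_id}_expression.tsv"
        pheno = out / f"{ds.dataset_id}_phenotype.tsv"
        write_expression(ds, expr, pheno)
        paths["expression"].append((expr, pheno))
    paths["interactions"] = out / "interactions.tsv"
    write_interactions(study.interactions, paths["interactions"])
    paths["markers"] = out / "markers.txt"
    write_markers(frozenset(study.markers), paths["markers"])
    paths["annotations"] = out / "annotations.tsv"
    write_annotations(study.annotations, paths["annotations"])
    paths["truth"] = out / "truth.tsv"
    write_truth(study.truth, paths["truth"])
    return paths
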