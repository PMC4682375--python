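"""Multi-source miRNA-target interaction filtering.

A (miRNA, gene) pair is considered reliable when it carries validated
evidence or is predicted by at least two of the three prediction
sources; reliable pairs are grouped into per-miRNA target sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .preprocess import DESignature

VALIDATED = "validated"
PREDICTED = "predicted"

INTERACTION_COLUMNS = ["mirna_id", "gene_id", "source_id", "evidence"]


@dataclass
class InteractionTable:
    """Records of (mirna_id, gene_id, source_id, evidence)."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"interaction table missing columns {missing}")
        df = df[INTERACTION_COLUMNS].copy()
        for col in INTERACTION_COLUMNS:
            df[col] = df[col].astype(str).str.strip()
        dup = df.duplicated(subset=["mirna_id", "gene_id", "source_id"])
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                "duplicate (mirna_id, gene_id, source_id) triple: "
                f"({first.mirna_id}, {first.gene_id}, {first.source_id})"
            )
        bad = sorted(set(df["evidence"]) - {VALIDATED, PREDICTED}) if len(df) else []
        if bad:
            raise ValueError(f"unknown evidence labels {bad}; expected "
                             f"'{VALIDATED}' or '{PREDICTED}'")
        val_src = set(df.loc[df["evidence"] == VALIDATED, "source_id"])
        pred_src = set(df.loc[df["evidence"] == PREDICTED, "source_id"])
        if val_src & pred_src:
            raise ValueError(
                f"source ids used with both evidence classes: {sorted(val_src & pred_src)}"
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class TargetMap:
    """Mapping miRNA id -> reliable target-gene set."""

    targets: dict  # mirna_id -> frozenset of gene ids

    def __post_init__(self) -> None:
        clean = {m: frozenset(g) for m, g in self.targets.items()}
        empty = sorted(m for m, g in clean.items() if not g)
        if empty:
            raise ValueError(f"miRNAs with empty target sets: {empty[:5]}")
        object.__setattr__(self, "targets", clean)

    def __getitem__(self, mirna: str) -> frozenset:
        return self.targets[mirna]

    def __contains__(self, mirna: str) -> bool:
        return mirna in self.targets

    def __len__(self) -> int:
        return len(self.targets)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets)

    @property
    def all_targets(self) -> frozenset:
        if not self.targets:
            return frozenset()
        return frozenset().union(*self.targets.values())

    @property
    def n_pairs(self) -> int:
        return sum(len(g) for g in self.targets.values())


@dataclass(frozen=True)
class MarkerList:
    """Official identifier list (genes and miRNAs)."""

    ids: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(str(i).strip() for i in self.ids))

    def __contains__(self, item: str) -> bool:
        return item in self.ids

    def __len__(self) -> int:
        return len(self.ids)


def filter_interactions(table: InteractionTable, min_predicted_sources: int = 2) -> TargetMap:
    """Retain pairs with validated evidence or >=2 distinct predicted sources."""
    df = table.records
    targets: dict[str, set[str]] = {}
    if len(df):
        grouped = df.groupby(["mirna_id", "gene_id"], sort=False)
        for (mirna, gene), sub in grouped:
            has_validated = (sub["evidence"] == VALIDATED).any()
            n_pred = sub.loc[sub["evidence"] == PREDICTED, "source_id"].nunique()
            if has_validated or n_pred >= min_predicted_sources:
                targets.setdefault(mirna, set()).add(gene)
    return TargetMap(targets={m: frozenset(g) for m, g in targets.items()})


def apply_marker_filter(
    target_map: TargetMap, markers: MarkerList, mode: str = "require_listed"
) -> TargetMap:
    """Restrict the miRNA list against the official marker list.

    ``require_listed`` keeps only miRNAs present in the list (the list is
    the universe of recognized identifiers); ``exclude_listed`` removes
    listed miRNAs instead.
    """
    if mode not in ("require_listed", "exclude_listed"):
        raise ValueError("mode must be 'require_listed' or 'exclude_listed'")
    if len(markers) == 0:
        raise ValueError("marker list is empty")
    if mode == "require_listed":
        kept = {m: g for m, g in target_map.targets.items() if m in markers}
    else:
        kept = {m: g for m, g in target_map.targets.items() if m not in markers}
    return TargetMap(targets=kept)


def de_target_sets(target_map: TargetMap, signature: DESignature) -> dict:
    """Per-miRNA DE target sets: Targets(i) split by DE direction."""
    return {
        m: {"up": g & signature.up, "down": g & signature.down}
        for m, g in target_map.targets.items()
    }
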