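"""Synthetic study generator with planted ground truth.

Emulates the pipeline's real inputs — several single-platform expression
series around an LPS-like two-group contrast, a multi-source miRNA-target
interaction table, an official marker list and a term annotation table —
with known planted structure: up/down DE genes shifted by a fixed log2
effect, and cooperative miRNA groups that share a pool of DE target
genes. All randomness derives from ``config.seed`` through per-stage
child streams, so a fixed config reproduces every artifact exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .enrichment import AnnotationTable
from .interactions import InteractionTable
from .preprocess import CONTROL, TREATED, ExpressionDataset

VALIDATED_SOURCE = "mirtarbase"
PREDICTED_SOURCES = ("microt_cds", "mirdb", "pictar")

BASELINE_MEAN = 7.0  # log2 microarray-like intensity
BASELINE_SD = 1.5


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure: DE genes, cooperative groups, target sets."""

    de_up: frozenset
    de_down: frozenset
    coop_groups: tuple  # tuple of frozensets of miRNA ids
    group_direction: tuple  # 'up' / 'down' per group
    group_pools: tuple  # tuple of frozensets of pool genes
    planted_targets: dict  # mirna_id -> frozenset of gene ids

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise ValueError("de_up and de_down must be disjoint")
        seen: set = set()
        for g in self.coop_groups:
            if g & seen:
                raise ValueError("cooperative groups must be pairwise disjoint")
            seen |= g


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # one documented stream per stage, all derived from the single seed
    return np.random.default_rng([int(config.seed), stage])


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list[str]:
    return [f"Mir{i}" for i in range(1, n + 1)]


def generate_truth(config: SimulationConfig) -> GroundTruth:
    """Plant DE genes, cooperative miRNA groups and their target sets."""
    rng = _rng(config, 0)
    genes = gene_ids(config.n_genes)
    mirnas = mirna_ids(config.n_mirnas)

    perm = rng.permutation(config.n_genes)
    de_up = frozenset(genes[i] for i in perm[: config.n_up])
    de_down = frozenset(genes[i] for i in perm[config.n_up: config.n_up + config.n_down])

    member_idx = rng.choice(
        config.n_mirnas, size=config.n_coop_groups * config.group_size, replace=False
    )
    groups, directions, pools = [], [], []
    up_pool_src = sorted(de_up)
    down_pool_src = sorted(de_down)
    rng.shuffle(up_pool_src)
    rng.shuffle(down_pool_src)
    n_up_groups = (config.n_coop_groups + 1) // 2  # odd count: extra group is 'up'
    for g in range(config.n_coop_groups):
        members = frozenset(
            mirnas[i] for i in member_idx[g * config.group_size: (g + 1) * config.group_size]
        )
        direction = "up" if g < n_up_groups else "down"
        src = up_pool_src if direction == "up" else down_pool_src
        if len(src) < config.shared_pool_size:
            raise ConfigError(
                f"not enough {direction}-DE genes for disjoint group pools "
                f"(need {config.shared_pool_size}, have {len(src)})"
            )
        pool = frozenset(src[: config.shared_pool_size])
        del src[: config.shared_pool_size]
        groups.append(members)
        directions.append(direction)
        pools.append(pool)

    pooled_genes = frozenset().union(*pools) if pools else frozenset()
    background_universe = [g for g in genes if g not in pooled_genes]
    planted: dict[str, set] = {m: set() for m in mirnas}
    for gi, members in enumerate(groups):
        for m in sorted(members):
            planted[m] |= pools[gi]
    if config.background_target_rate > 0 and background_universe:
        for m in mirnas:
            hits = rng.random(len(background_universe)) < config.background_target_rate
            planted[m] |= {g for g, h in zip(background_universe, hits) if h}
    return GroundTruth(
        de_up=de_up,
        de_down=de_down,
        coop_groups=tuple(groups),
        group_direction=tuple(directions),
        group_pools=tuple(pools),
        planted_targets={m: frozenset(t) for m, t in planted.items() if t},
    )


def generate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> list[ExpressionDataset]:
    """Per-platform expression matrices with the planted two-group shift.

    A common per-gene baseline (normal on the log2 scale) is shared by
    all platforms; each platform drops genes independently at
    ``platform_dropout`` and adds homoscedastic gaussian noise. Treated
    samples shift planted up-DE genes by +effect_size and down-DE genes
    by -effect_size.
    """
    rng = _rng(config, 1)
    genes = gene_ids(config.n_genes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    shift = np.zeros(config.n_genes)
    for i, g in enumerate(genes):
        if g in truth.de_up:
            shift[i] = config.effect_size
        elif g in truth.de_down:
            shift[i] = -config.effect_size
    datasets = []
    n = config.samples_per_group
    for d in range(config.n_datasets):
        keep = rng.random(config.n_genes) >= config.platform_dropout
        if not keep.any():
            keep[rng.integers(config.n_genes)] = True
        idx = np.flatnonzero(keep)
        noise = rng.normal(0.0, config.noise_sd, size=(idx.size, 2 * n))
        values = baseline[idx, None] + noise
        values[:, n:] += shift[idx, None]
        dataset_id = f"SIM{d + 1}"
        datasets.append(
            ExpressionDataset(
                dataset_id=dataset_id,
                genes=[genes[i] for i in idx],
                samples=[f"{dataset_id}_{grp}{s + 1}" for grp in ("C", "T") for s in range(n)],
                values=values,
                group=[CONTROL] * n + [TREATED] * n,
            )
        )
    return datasets


def generate_interaction_table(
    config: SimulationConfig, truth: GroundTruth
) -> InteractionTable:
    """Emit planted targets so they survive source filtering, plus noise.

    Planted interactions are validated with probability
    ``validated_rate`` and otherwise appear under two (or all three)
    predicted sources. Decoy interactions (never overlapping planted
    targets) appear under exactly one predicted source with probability
    0.5 — and are therefore removed by the >=2-source rule — or under
    two sources otherwise.
    """
    rng = _rng(config, 2)
    rows = []
    for m in sorted(truth.planted_targets):
        for g in sorted(truth.planted_targets[m]):
            if rng.random() < config.validated_rate:
                rows.append((m, g, VALIDATED_SOURCE, "validated"))
            else:
                k = 2 if rng.random() < 0.8 else 3
                for src in rng.choice(PREDICTED_SOURCES, size=k, replace=False):
                    rows.append((m, g, src, "predicted"))
    genes = gene_ids(config.n_genes)
    if config.background_target_rate > 0:
        for m in mirna_ids(config.n_mirnas):
            planted = truth.planted_targets.get(m, frozenset())
            free = [g for g in genes if g not in planted]
            hits = rng.random(len(free)) < config.background_target_rate
            for g, h in zip(free, hits):
                if not h:
                    continue
                if rng.random() < 0.5:
                    src = rng.choice(PREDICTED_SOURCES)
                    rows.append((m, g, src, "predicted"))
                else:
                    for src in rng.choice(PREDICTED_SOURCES, size=2, replace=False):
                        rows.append((m, g, src, "predicted"))
    return InteractionTable(
        records=pd.DataFrame(rows, columns=["mirna_id", "gene_id", "source_id", "evidence"])
    )


def generate_marker_list(config: SimulationConfig) -> list[str]:
    """Official-marker surrogate: all simulated gene and miRNA ids."""
    return gene_ids(config.n_genes) + mirna_ids(config.n_mirnas)


def generate_annotation_table(
    config: SimulationConfig,
    truth: GroundTruth,
    n_random_terms: int = 20,
    random_term_size: int = 25,
) -> AnnotationTable:
    """Term->gene annotations with one term per planted DE direction.

    The planted 'up' and 'down' terms equal the DE sets exactly; random
    terms are drawn independently of DE status.
    """
    rng = _rng(config, 3)
    genes = gene_ids(config.n_genes)
    rows = [("T_UP", "planted up-DE term", g) for g in sorted(truth.de_up)]
    rows += [("T_DOWN", "planted down-DE term", g) for g in sorted(truth.de_down)]
    size = min(random_term_size, config.n_genes)
    for t in range(n_random_terms):
        members = rng.choice(config.n_genes, size=size, replace=False)
        rows += [(f"T_R{t + 1:03d}", f"random term {t + 1}", genes[i]) for i in members]
    return AnnotationTable(
        records=pd.DataFrame(rows, columns=["term_id", "term_name", "gene_id"])
    )


@dataclass
class SyntheticStudy:
    """Bundle of every synthetic artifact for one configuration."""

    config: SimulationConfig
    truth: GroundTruth
    datasets: list
    interactions: InteractionTable
    markers: list
    annotations: AnnotationTable


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    truth = generate_truth(config)
    return SyntheticStudy(
        config=config,
        truth=truth,
        datasets=generate_expression(config, truth),
        interactions=generate_interaction_table(config, truth),
        markers=generate_marker_list(config),
        annotations=generate_annotation_table(config, truth),
    )
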