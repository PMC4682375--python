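"""Configuration objects for simulation, MCODE and the pipeline driver."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class McodeParams:
    """MCODE parameters; defaults are the Cytoscape v1 plugin defaults."""

    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_cutoff: float = 0.2
    max_depth: int = 100

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 0:
            raise ConfigError("degree_cutoff, k_core and max_depth must be non-negative")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ConfigError("node_score_cutoff must lie in [0, 1]")
        if not 0.0 <= self.fluff_cutoff <= 1.0:
            raise ConfigError("fluff_cutoff must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults are the strong-signal conditions used throughout the test
    suite: five platforms, six samples per group, a 4-log2-unit shift on
    planted DE genes with sd 0.5 noise, and four planted cooperative
    miRNA groups of six miRNAs sharing a 15-gene DE target pool.
    """

    n_genes: int = 2000
    n_mirnas: int = 60
    n_datasets: int = 5
    samples_per_group: int = 6
    frac_up_de: float = 0.05
    frac_down_de: float = 0.05
    effect_size: float = 4.0
    noise_sd: float = 0.5
    platform_dropout: float = 0.05
    n_coop_groups: int = 4
    group_size: int = 6
    shared_pool_size: int = 15
    background_target_rate: float = 0.01
    n_pred_sources: int = 3
    validated_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_datasets", "samples_per_group"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        for name in ("n_coop_groups", "group_size", "shared_pool_size"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("frac_up_de", "frac_down_de", "validated_rate",
                     "background_target_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_up_de + self.frac_down_de >= 1.0:
            raise ConfigError("frac_up_de + frac_down_de must be < 1")
        if not 0.0 <= self.platform_dropout < 1.0:
            raise ConfigError("platform_dropout must lie in [0, 1)")
        if self.n_coop_groups * self.group_size > self.n_mirnas:
            raise ConfigError("n_coop_groups * group_size exceeds n_mirnas")
        if self.n_pred_sources != 3:
            raise ConfigError("n_pred_sources is fixed at 3")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_coop_groups > 0:
            for frac, label in ((self.frac_up_de, "up"), (self.frac_down_de, "down")):
                n_de = round(frac * self.n_genes)
                if self.shared_pool_size > n_de:
                    raise ConfigError(
                        f"shared_pool_size ({self.shared_pool_size}) exceeds the "
                        f"number of planted {label}-DE genes ({n_de})"
                    )

    @property
    def n_up(self) -> int:
        return round(self.frac_up_de * self.n_genes)

    @property
    def n_down(self) -> int:
        return round(self.frac_down_de * self.n_genes)


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration: input paths and stage thresholds."""

    expression_files: list = field(default_factory=list)  # (expr, pheno) path pairs
    interactions_file: Path | str | None = None
    markers_file: Path | str | None = None
    annotations_file: Path | str | None = None
    out_dir: Path | str | None = None
    de_alpha: float = 0.05
    enrichment_alpha: float = 0.05
    network_alpha: float = 0.01
    jaccard_mode: str = "de_targets"
    marker_mode: str = "require_listed"
    normalize: str = "auto"
    moderate_variance: bool = True
    mcode: McodeParams = field(default_factory=McodeParams)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "enrichment_alpha", "network_alpha"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ConfigError(f"{name} must lie strictly in (0, 1), got {a}")
        if self.jaccard_mode not in ("de_targets", "all_targets"):
            raise ConfigError("jaccard_mode must be 'de_targets' or 'all_targets'")
        if self.marker_mode not in ("require_listed", "exclude_listed"):
            raise ConfigError("marker_mode must be 'require_listed' or 'exclude_listed'")
        if self.normalize not in ("auto", "always", "never"):
            raise ConfigError("normalize must be 'auto', 'always' or 'never'")
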