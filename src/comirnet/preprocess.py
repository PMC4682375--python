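"""Expression preprocessing and differential-expression calling.

Each platform's genes x samples matrix (log2 intensities, two sample
groups) is optionally quantile-normalized, tested gene-by-gene with a
variance-moderated two-sample t-test, BH-adjusted, and direction-split
DE calls are intersected across platforms into a single signature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
_TINY_P = np.finfo(float).tiny  # zero-variance, nonzero-effect sentinel


@dataclass
class ExpressionDataset:
    """One platform's log2 expression matrix with two-group sample labels."""

    dataset_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray  # genes x samples
    group: list[str]  # per sample, 'control' or 'treated'

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"{self.dataset_id}: matrix shape {self.values.shape} does not "
                f"match {len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(self.group) != len(self.samples):
            raise ValueError(f"{self.dataset_id}: one group label per sample required")
        bad = sorted(set(self.group) - {CONTROL, TREATED})
        if bad:
            raise ValueError(f"{self.dataset_id}: unknown group labels {bad}")
        counts = pd.Series(self.group).value_counts()
        if counts.get(CONTROL, 0) < 2 or counts.get(TREATED, 0) < 2:
            raise ValueError(f"{self.dataset_id}: need >=2 samples per group")
        if len(set(self.genes)) != len(self.genes):
            dupes = pd.Series(self.genes)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"{self.dataset_id}: duplicate gene ids {dupes[:5]}")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


@dataclass
class DEResult:
    """Per-gene differential-expression calls for one dataset."""

    dataset_id: str
    table: pd.DataFrame  # index gene_id; columns effect, p, p_adj, status

    @property
    def up(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["status"] == "up"])

    @property
    def down(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["status"] == "down"])

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.table.index)


@dataclass(frozen=True)
class DESignature:
    """Direction-consistent DE gene sets intersected across datasets."""

    up: frozenset[str]
    down: frozenset[str]
    n_datasets: int = 1

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("up and down DE sets must be disjoint")


def check_cross_comparable(dataset: ExpressionDataset, tol: float = 0.25) -> dict:
    """Diagnose whether samples share a comparable value distribution.

    Mirrors the per-sample value-distribution check applied to public
    microarray series: samples are comparable when no two medians differ
    by more than ``tol`` log2 units.
    """
    q = np.quantile(dataset.values, [0.0, 0.25, 0.5, 0.75, 1.0], axis=0)
    quartiles = pd.DataFrame(
        q.T, index=dataset.samples, columns=["min", "q1", "median", "q3", "max"]
    )
    medians = quartiles["median"].to_numpy()
    spread = float(medians.max() - medians.min())
    return {
        "dataset_id": dataset.dataset_id,
        "quartiles": quartiles,
        "median_spread": spread,
        "comparable": bool(spread <= tol),
    }


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Force every column to the common distribution of row-rank means.

    Ties within a column receive the mean of the reference values at the
    tied positions, so the operation is idempotent and rank-preserving.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 1:
        raise ValueError("quantile_normalize expects a 2-D matrix with >=1 column")
    if np.isnan(values).any():
        raise ValueError("quantile_normalize rejects matrices with missing values")
    mean_sorted = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")  # 1..n, ties averaged
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D sequence")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def _moderated_test(values: np.ndarray, is_treated: np.ndarray, prior_df: float):
    """Two-sample t with per-gene variances shrunk toward their mean.

    Pooled per-gene variance s_g^2 (df = n1+n2-2) is replaced by
    (d0 * s0^2 + df * s_g^2) / (d0 + df) with s0^2 the mean pooled
    variance across genes, and the statistic referred to a t
    distribution on d0 + df degrees of freedom.
    """
    x = values[:, is_treated]
    y = values[:, ~is_treated]
    n1, n2 = x.shape[1], y.shape[1]
    effect = x.mean(axis=1) - y.mean(axis=1)
    df = n1 + n2 - 2
    ss = x.var(axis=1, ddof=1) * (n1 - 1) + y.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    s2_prior = float(s2.mean())
    s2_mod = (prior_df * s2_prior + df * s2) / (prior_df + df)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    return effect, se, prior_df + df


def _welch_test(values: np.ndarray, is_treated: np.ndarray):
    x = values[:, is_treated]
    y = values[:, ~is_treated]
    n1, n2 = x.shape[1], y.shape[1]
    v1 = x.var(axis=1, ddof=1)
    v2 = y.var(axis=1, ddof=1)
    effect = x.mean(axis=1) - y.mean(axis=1)
    se = np.sqrt(v1 / n1 + v2 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    df = np.where(np.isfinite(df), df, 1.0)
    return effect, se, df


def differential_expression(
    dataset: ExpressionDataset,
    alpha: float = 0.05,
    moderate: bool = True,
    prior_df: float = 4.0,
) -> DEResult:
    """Call per-gene DE status at BH-adjusted p < alpha.

    Degenerate genes with zero standard error get p = 1 when the effect
    is also zero and the smallest positive float otherwise; both cases
    are logged.
    """
    is_treated = np.asarray([g == TREATED for g in dataset.group])
    if moderate:
        effect, se, df = _moderated_test(dataset.values, is_treated, prior_df)
    else:
        effect, se, df = _welch_test(dataset.values, is_treated)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    p = np.where(np.isfinite(t), 2.0 * stats.t.sf(np.abs(t), df), np.nan)
    degenerate = ~np.isfinite(np.asarray(t, dtype=float))
    if degenerate.any():
        n_null = int((degenerate & (effect == 0)).sum())
        n_sig = int((degenerate & (effect != 0)).sum())
        logger.info(
            "%s: %d zero-variance genes (p=1: %d, p=tiny: %d)",
            dataset.dataset_id, int(degenerate.sum()), n_null, n_sig,
        )
        p = np.where(degenerate & (effect == 0), 1.0, p)
        p = np.where(degenerate & (effect != 0), _TINY_P, p)
    p_adj = bh_adjust(p)
    status = np.where(
        (p_adj < alpha) & (effect > 0), "up",
        np.where((p_adj < alpha) & (effect < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {"effect": effect, "p": p, "p_adj": p_adj, "status": status},
        index=pd.Index(dataset.genes, name="gene_id"),
    )
    return DEResult(dataset_id=dataset.dataset_id, table=table)


def normalize_dataset(
    dataset: ExpressionDataset, mode: str = "auto", tol: float = 0.25
) -> ExpressionDataset:
    """Quantile-normalize a dataset according to ``mode``.

    ``auto`` normalizes only when the cross-comparability diagnostic
    fails; ``always``/``never`` force the respective behaviour.
    """
    if mode not in ("auto", "always", "never"):
        raise ValueError("mode must be 'auto', 'always' or 'never'")
    if mode == "never":
        return dataset
    if mode == "auto" and check_cross_comparable(dataset, tol=tol)["comparable"]:
        return dataset
    return ExpressionDataset(
        dataset_id=dataset.dataset_id,
        genes=list(dataset.genes),
        samples=list(dataset.samples),
        values=quantile_normalize(dataset.values),
        group=list(dataset.group),
    )


def intersect_signatures(results: list[DEResult]) -> DESignature:
    """Genes consistently up (or down) in every dataset's universe."""
    if not results:
        raise ValueError("intersect_signatures requires at least one DEResult")
    up = set(results[0].up)
    down = set(results[0].down)
    for r in results[1:]:
        up &= r.up
        down &= r.down
    return DESignature(up=frozenset(up), down=frozenset(down), n_datasets=len(results))


def restrict_to_interaction_universe(signature: DESignature, target_map) -> DESignature:
    """Drop DE genes not targeted by any miRNA in the filtered target map."""
    targeted = target_map.all_targets if hasattr(target_map, "all_targets") else (
        frozenset().union(*target_map.values()) if target_map else frozenset()
    )
    if not targeted:
        raise ValueError("target map is empty")
    return DESignature(
        up=signature.up & targeted,
        down=signature.down & targeted,
        n_datasets=signature.n_datasets,
    )
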