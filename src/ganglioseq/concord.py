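"""Cross-dataset and cross-species expression concordance.

Given a primary experiment (per-gene FPKM and presence calls) and a
comparison dataset (per-ortholog mean FPKM in two conditions), this module
measures how well the two agree: Spearman rank correlation of expression
levels, presence/absence agreement overall and among the most abundant
genes, direction-of-change concordance for differential genes, counts of
genes past a fold threshold, and a row-standardized matrix for heatmap
display.

Ortholog matching defaults to case-insensitive symbol equality; genes absent
from one dataset are treated as FPKM 0 before ranking unless restricted to
the shared set.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMappingError, ValidationError

#: Pseudo-FPKM added before ratios and logs so zero-FPKM genes stay finite.
PSEUDO_FPKM = 0.01


def rank_correlation(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValidationError("rank_correlation needs two equal-length vectors, n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValidationError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def presence_agreement_topk(
    primary_mean_fpkm: pd.Series, other_present, k: int
) -> float:
    """Fraction of the primary dataset's top-k most abundant genes that are
    called present in the other dataset.

    Ties in mean FPKM are broken by identifier order. ``other_present`` may
    be a boolean Series or any iterable of present gene identifiers.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if k > len(primary_mean_fpkm):
        raise ValidationError(f"k={k} exceeds the {len(primary_mean_fpkm)} primary genes")
    if isinstance(other_present, pd.Series):
        present = frozenset(other_present.index[other_present.astype(bool)])
    else:
        present = frozenset(other_present)
    order = primary_mean_fpkm.sort_index()
    top = order.sort_values(ascending=False, kind="stable").index[:k]
    return float(np.mean([g in present for g in top]))


def joint_presence_summary(calls_x: pd.Series, calls_y: pd.Series):
    """Union size and agreement of presence status between two datasets.

    ``calls_x`` and ``calls_y`` are boolean per-gene presence statuses on a
    shared key universe. Returns ``(n_union, frac_equal)`` where ``n_union``
    counts genes present in at least one dataset and ``frac_equal`` is the
    fraction of the union with matching status (which, over the union, means
    present in both).
    """
    keys = calls_x.index.intersection(calls_y.index)
    if len(keys) == 0:
        raise ValidationError("empty shared key universe")
    x = calls_x.reindex(keys).astype(bool)
    y = calls_y.reindex(keys).astype(bool)
    union = x | y
    n_union = int(union.sum())
    if n_union == 0:
        return 0, 1.0
    frac_equal = float((x[union] == y[union]).mean())
    return n_union, frac_equal


class TrendConcordance(NamedTuple):
    frac_same_trend: float
    n_ge_threshold_a: int
    n_ge_threshold_b: int
    n_compared: int


def trend_concordance(
    de_log2fc: pd.Series,
    comparison: pd.DataFrame,
    fold_threshold: float = 2.0,
) -> TrendConcordance:
    """Direction-of-change agreement between DE calls and a comparison dataset.

    ``de_log2fc`` is indexed by ortholog key (B-vs-A orientation) and is
    matched against the comparison table's ``fpkm_a``/``fpkm_b`` columns. A
    gene is same-trend when the sign of its fold change matches the sign of
    ``log((fpkm_b + eps) / (fpkm_a + eps))`` in the comparison (pseudo-FPKM
    eps = 0.01); a comparison ratio of exactly 1 supports neither direction
    and counts as not same-trend. Among same-trend genes,
    ``n_ge_threshold_a`` counts those with comparison
    ``fpkm_a/fpkm_b >= fold_threshold`` (higher on the A side) and
    ``n_ge_threshold_b`` the converse.
    """
    if fold_threshold < 1:
        raise ValidationError("fold_threshold must be >= 1")
    keys = de_log2fc.index.intersection(comparison.index)
    if len(de_log2fc) == 0 or len(keys) == 0:
        raise EmptyMappingError("no DE genes could be mapped to the comparison dataset")
    lfc = de_log2fc.reindex(keys).to_numpy(dtype=float)
    fa = comparison["fpkm_a"].reindex(keys).to_numpy(dtype=float) + PSEUDO_FPKM
    fb = comparison["fpkm_b"].reindex(keys).to_numpy(dtype=float) + PSEUDO_FPKM
    comp_ratio = fb / fa
    same = np.sign(lfc) * np.log(comp_ratio) > 0
    n_a = int(np.sum(same & (fa / fb >= fold_threshold)))
    n_b = int(np.sum(same & (fb / fa >= fold_threshold)))
    return TrendConcordance(
        frac_same_trend=float(same.mean()),
        n_ge_threshold_a=n_a,
        n_ge_threshold_b=n_b,
        n_compared=int(len(keys)),
    )


def standardized_heatmap_matrix(avg_log2_fpkm: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (sample SD) for heatmap display; constant rows map
    to all zeros."""
    if avg_log2_fpkm.shape[1] < 2:
        raise ValidationError("heatmap standardization needs at least 2 columns")
    mat = avg_log2_fpkm.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (mat - mean) / sd, 0.0)
    return pd.DataFrame(z, index=avg_log2_fpkm.index, columns=avg_log2_fpkm.columns)


@dataclass(frozen=True)
class ConcordanceReport:
    """Bundle of cross-dataset agreement statistics."""

    spearman_rho: float
    n_union_expressed: int
    frac_equal_presence: float
    top_k: int
    frac_topk_present_both: float
    frac_same_trend: float
    n_ge2fold_a: int
    n_ge2fold_b: int
    n_genes_compared: int

    def to_dict(self) -> dict:
        return asdict(self)


def compare_datasets(
    primary_mean_fpkm: pd.DataFrame,
    primary_calls: pd.DataFrame,
    symbols: pd.Series,
    comparison: pd.DataFrame,
    de_log2fc: pd.Series,
    *,
    min_fpkm: float = 1.0,
    top_k: int | None = None,
    fold_threshold: float = 2.0,
    intersect_only: bool = False,
) -> ConcordanceReport:
    """Full concordance report between a primary experiment and a comparison
    dataset keyed by upper-cased symbol.

    ``primary_mean_fpkm`` carries per-condition mean FPKM (``fpkm_a``,
    ``fpkm_b``) indexed by gene id; ``symbols`` maps gene ids to symbols;
    ``de_log2fc`` is the fold change of the significant neuronal DE genes
    (gene-id indexed). The comparison dataset is called present where either
    condition's mean FPKM reaches ``min_fpkm``. Genes absent from one
    dataset count as FPKM 0 unless ``intersect_only``.
    """
    keymap = symbols.astype(str).str.upper()
    primary_level = (primary_mean_fpkm["fpkm_a"] + primary_mean_fpkm["fpkm_b"]) / 2.0
    primary_level = primary_level.groupby(keymap.reindex(primary_level.index)).max()
    comp_level = (comparison["fpkm_a"] + comparison["fpkm_b"]) / 2.0

    if intersect_only:
        universe = primary_level.index.intersection(comp_level.index)
    else:
        universe = primary_level.index.union(comp_level.index)
    if len(universe) == 0:
        raise EmptyMappingError("no shared keys between datasets")
    x = primary_level.reindex(universe, fill_value=0.0)
    y = comp_level.reindex(universe, fill_value=0.0)
    rho = rank_correlation(x.to_numpy(), y.to_numpy())

    primary_present = (
        primary_calls["detected"]
        .groupby(keymap.reindex(primary_calls.index))
        .any()
        .reindex(universe, fill_value=False)
    )
    comp_present = (
        (comparison[["fpkm_a", "fpkm_b"]] >= min_fpkm)
        .any(axis=1)
        .reindex(universe, fill_value=False)
    )
    n_union, frac_equal = joint_presence_summary(primary_present, comp_present)

    k = top_k if top_k is not None else min(8000, len(x))
    frac_topk = presence_agreement_topk(x, comp_present, k)

    de_keys = de_log2fc.copy()
    de_keys.index = keymap.reindex(de_log2fc.index)
    trend = trend_concordance(de_keys, comparison, fold_threshold)

    return ConcordanceReport(
        spearman_rho=rho,
        n_union_expressed=n_union,
        frac_equal_presence=frac_equal,
        top_k=int(k),
        frac_topk_present_both=frac_topk,
        frac_same_trend=trend.frac_same_trend,
        n_ge2fold_a=trend.n_ge_threshold_a,
        n_ge2fold_b=trend.n_ge_threshold_b,
        n_genes_compared=trend.n_compared,
    )
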