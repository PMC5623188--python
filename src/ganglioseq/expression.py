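"""FPKM normalization and the per-condition presence-call rule.

A gene counts as expressed ("present") in a condition when its FPKM meets
the cut-off (default 1.0, inclusive) in at least ``min_replicates`` (default
2) replicates of that condition; it is "detected" when present in either.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import AnnotationError, ConfigurationError, DegenerateSampleError


def compute_fpkm(counts: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped reads.

    ``fpkm[g, s] = counts[g, s] * 1e9 / (total_counts[s] * length_bp[g])``,
    using each sample's own total assigned counts as the depth denominator
    and the annotated union-exon length as the effective length.

    Genes present in the annotation but absent from the count matrix are
    treated as zero counts everywhere (with a warning); genes in the count
    matrix with no annotated length raise :class:`AnnotationError`. A sample
    with zero total counts raises :class:`DegenerateSampleError`.
    """
    missing = counts.index.difference(annotation.index)
    if len(missing) > 0:
        raise AnnotationError(
            f"{len(missing)} genes in counts lack an annotated length, "
            f"e.g. {list(missing[:3])}"
        )
    extra = annotation.index.difference(counts.index)
    if len(extra) > 0:
        warnings.warn(
            f"{len(extra)} annotated genes absent from the count matrix; "
            "treated as zero counts",
            stacklevel=2,
        )
    aligned = counts.reindex(annotation.index, fill_value=0)
    totals = aligned.sum(axis=0)
    zero_samples = totals.index[totals == 0]
    if len(zero_samples) > 0:
        raise DegenerateSampleError(
            f"samples with zero total counts: {list(zero_samples)}"
        )
    lengths = annotation["length_bp"].astype(float)
    if (lengths < 1).any():
        raise AnnotationError("gene lengths must be >= 1 bp")
    fpkm = aligned.astype(float).mul(1e9).div(totals, axis=1).div(lengths, axis=0)
    return fpkm


def call_expressed(
    fpkm: pd.DataFrame,
    conditions: pd.Series,
    min_fpkm: float = 1.0,
    min_replicates: int = 2,
    strict: bool = False,
) -> pd.DataFrame:
    """Apply the presence-call rule per condition.

    ``present_a`` (resp. ``present_b``) is true when at least
    ``min_replicates`` samples of condition A (resp. B) reach the FPKM
    cut-off; the comparison is inclusive (``>=``) unless ``strict`` asks for
    ``>``. ``detected`` is the union of the two calls.
    """
    conditions = conditions.reindex(fpkm.columns)
    if conditions.isna().any():
        raise ConfigurationError("every sample needs a condition label")
    calls = {}
    for cond, col in (("A", "present_a"), ("B", "present_b")):
        cols = conditions.index[conditions == cond]
        if len(cols) < min_replicates:
            raise ConfigurationError(
                f"condition {cond} has {len(cols)} samples, fewer than "
                f"min_replicates={min_replicates}"
            )
        hits = (fpkm[cols] > min_fpkm) if strict else (fpkm[cols] >= min_fpkm)
        calls[col] = hits.sum(axis=1) >= min_replicates
    out = pd.DataFrame(calls, index=fpkm.index)
    out["detected"] = out["present_a"] | out["present_b"]
    return out


def count_detected(calls: pd.DataFrame) -> int:
    """Number of genes detected in either condition."""
    return int(calls["detected"].sum())


def condition_mean_fpkm(fpkm: pd.DataFrame, conditions: pd.Series) -> pd.DataFrame:
    """Mean FPKM per condition (columns ``fpkm_a``, ``fpkm_b``)."""
    conditions = conditions.reindex(fpkm.columns)
    return pd.DataFrame(
        {
            "fpkm_a": fpkm.loc[:, np.asarray(conditions == "A")].mean(axis=1),
            "fpkm_b": fpkm.loc[:, np.asarray(conditions == "B")].mean(axis=1),
        }
    )
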