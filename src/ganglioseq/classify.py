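"""Partition differential-expression results into biological categories.

A significant gene is excluded when it fails the expression cut-off
(``not_expressed``) or is missing from a pure-neuron reference dataset
(``non_neuronal``, attributing it to satellite glia or other non-neuronal
cells); the remainder are called exclusive to one ganglion when present in
only one condition, otherwise simply up-regulated on the side the fold
change favors. Non-significant genes are ``common``.

The decision order — not-expressed before non-neuronal before exclusivity —
makes the categories a total partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

CATEGORIES = (
    "up_a",
    "up_b",
    "exclusive_a",
    "exclusive_b",
    "common",
    "not_expressed",
    "non_neuronal",
)

#: Categories counted as differentially expressed genes of neuronal origin.
DE_NEURONAL = ("up_a", "up_b", "exclusive_a", "exclusive_b")

_TRUTHY = {"true", "t", "yes", "y", "1"}
_FALSY = {"false", "f", "no", "n", "0", ""}


def classify_genes(
    de: pd.DataFrame, calls: pd.DataFrame, reference: Iterable[str]
) -> pd.DataFrame:
    """Assign each gene exactly one category.

    Decision order per gene: (1) not significant -> ``common``;
    (2) significant but not detected by the presence rule -> ``not_expressed``;
    (3) significant but absent from the reference presence set ->
    ``non_neuronal``; (4) significant and present in exactly one condition ->
    exclusive for that condition; (5) significant and present in both ->
    ``up_a`` when the fold change favors A (log2fc < 0 in B-vs-A
    orientation), else ``up_b``.

    ``de`` and ``calls`` must cover the same gene universe; the reference
    may be any subset (ids outside the universe are ignored).
    """
    if set(de.index) != set(calls.index):
        raise ValidationError(
            "DE results and presence calls cover different gene universes"
        )
    calls = calls.reindex(de.index)
    ref = frozenset(reference)
    sig = de["significant"].to_numpy(dtype=bool)
    pa = calls["present_a"].to_numpy(dtype=bool)
    pb = calls["present_b"].to_numpy(dtype=bool)
    detected = pa | pb
    in_ref = de.index.isin(ref)
    lfc = de["log2fc"].to_numpy(dtype=float)

    category = np.select(
        [
            ~sig,
            sig & ~detected,
            sig & ~in_ref,
            sig & pa & ~pb,
            sig & pb & ~pa,
            sig & pa & pb & (lfc < 0),
        ],
        ["common", "not_expressed", "non_neuronal", "exclusive_a", "exclusive_b", "up_a"],
        default="up_b",
    )
    return pd.DataFrame(
        {
            "category": category,
            "significant": sig,
            "present_a": pa,
            "present_b": pb,
            "in_reference": in_ref,
        },
        index=de.index,
    )


@dataclass(frozen=True)
class ClassificationSummary:
    """Category counts plus the derived headline totals."""

    counts: dict
    n_de_neuronal: int
    n_excluded: int
    total: int

    def to_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_de_neuronal": self.n_de_neuronal,
            "n_excluded": self.n_excluded,
            "total": self.total,
        }


def summarize_classification(cls: pd.DataFrame) -> ClassificationSummary:
    """Exact category counts; ``n_de_neuronal`` sums the four DE categories,
    ``n_excluded`` the significant genes filtered out as not-expressed or
    non-neuronal."""
    vc = cls["category"].value_counts() if len(cls) else pd.Series(dtype=int)
    counts = {c: int(vc.get(c, 0)) for c in CATEGORIES}
    return ClassificationSummary(
        counts=counts,
        n_de_neuronal=sum(counts[c] for c in DE_NEURONAL),
        n_excluded=counts["not_expressed"] + counts["non_neuronal"],
        total=int(len(cls)),
    )


def count_gene_family(table: pd.DataFrame, family_prefix: str) -> int:
    """Number of rows whose symbol starts with ``family_prefix``
    (case-insensitive, anchored at position 0)."""
    if "symbol" not in table.columns:
        raise ValidationError("table needs a 'symbol' column")
    if len(table) == 0:
        return 0
    return int(
        table["symbol"].astype(str).str.lower().str.startswith(family_prefix.lower()).sum()
    )


def _parse_bool(value) -> bool:
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot parse boolean flag {value!r}")


def read_exclusive_table(path) -> pd.DataFrame:
    """Read a table of ganglion-exclusive genes.

    Expects TSV columns ``gene_id``, ``symbol``, ``exclusive_drg``,
    ``exclusive_tg``; every row must be flagged exclusive in exactly one
    ganglion, otherwise a :class:`ValidationError` is raised.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "symbol", "exclusive_drg", "exclusive_tg"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"exclusive table missing columns: {sorted(missing)}")
    for col in ("exclusive_drg", "exclusive_tg"):
        table[col] = table[col].map(_parse_bool)
    bad = table["exclusive_drg"] == table["exclusive_tg"]
    if bad.any():
        rows = table.loc[bad, "symbol"].tolist()
        raise ValidationError(
            f"rows flagged exclusive in both or neither ganglion: {rows}"
        )
    return table.set_index("gene_id")


def packaged_exclusive_table() -> pd.DataFrame:
    """The packaged 24-gene ganglion-exclusive fixture."""
    ref = resources.files("ganglioseq").joinpath("data/table1_exclusive.tsv")
    with resources.as_file(ref) as path:
        return read_exclusive_table(path)


def exclusive_table_to_classification(table: pd.DataFrame) -> pd.DataFrame:
    """Interpret an exclusive-gene table as a (partial) classification.

    DRG-exclusive rows map to ``exclusive_a``, trigeminal-exclusive rows to
    ``exclusive_b``; useful for summarising printed tables with
    :func:`summarize_classification`.
    """
    category = np.where(table["exclusive_drg"], "exclusive_a", "exclusive_b")
    return pd.DataFrame(
        {
            "category": category,
            "significant": True,
            "present_a": table["exclusive_drg"].to_numpy(),
            "present_b": table["exclusive_tg"].to_numpy(),
            "in_reference": True,
        },
        index=table.index,
    )
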