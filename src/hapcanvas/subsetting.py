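"""SNV filters and stable meta-driven sorting.

All filters act on the variant axis only and return a new matrix whose
surviving columns are bit-identical slices of the original; subjects are
never touched by a filter.  Sorting (of subjects or variants) is stable, so
sorting consecutively by B then by A equals a single sort by the compound
key (A, B) — the property that makes interactive multi-key ordering work.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .hapstore import MISSING_CODE, HaplotypeMatrix, MetaTable

logger = logging.getLogger(__name__)

__all__ = [
    "RegionQuery",
    "filter_region",
    "filter_id_list",
    "filter_id_regex",
    "alt_allele_frequency",
    "filter_frequency",
    "sort_rows_by_meta",
    "sort_columns_by_meta",
]


@dataclass(frozen=True)
class RegionQuery:
    """A chromosomal window, 1-based and inclusive at both ends."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @classmethod
    def parse(cls, text: str) -> "RegionQuery":
        """Parse a ``chrom:start-end`` string."""
        m = re.fullmatch(r"([^:]+):(\d+)-(\d+)", text.strip())
        if not m:
            raise ValueError(f"region must look like 'chrom:start-end': {text!r}")
        return cls(m.group(1), int(m.group(2)), int(m.group(3)))


def filter_region(matrix: HaplotypeMatrix, query: RegionQuery) -> HaplotypeMatrix:
    """Keep variants with matching chromosome and start <= pos <= end."""
    keep = [
        j
        for j, v in enumerate(matrix.variants)
        if v.chrom == query.chrom and query.start <= v.pos <= query.end
    ]
    return matrix.slice(variant_indices=keep)


def filter_id_list(matrix: HaplotypeMatrix, ids: Iterable[str]) -> HaplotypeMatrix:
    """Keep exactly the intersection with *ids*, in matrix order."""
    wanted = set(ids)
    keep = [j for j, v in enumerate(matrix.variants) if v.id in wanted]
    n_unknown = len(wanted) - len(keep)
    if n_unknown:
        logger.info("%d requested SNV ids not present in the data set", n_unknown)
    return matrix.slice(variant_indices=keep)


def filter_id_regex(matrix: HaplotypeMatrix, pattern: str) -> HaplotypeMatrix:
    """Keep variants whose id fully matches *pattern* (full-match semantics)."""
    try:
        rx = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid SNV id pattern {pattern!r}: {exc}") from None
    keep = [j for j, v in enumerate(matrix.variants) if rx.fullmatch(v.id)]
    return matrix.slice(variant_indices=keep)


def alt_allele_frequency(matrix: HaplotypeMatrix, j: int) -> float:
    """Non-reference allele frequency of variant *j*.

    Counted over all non-missing allele calls of all subjects and allele
    columns.  Raises for an all-missing variant, whose frequency is
    undefined.
    """
    v = matrix.variants[j]
    col = matrix.calls(variant_indices=[j]).reshape(-1)
    informative = col != MISSING_CODE
    n_inf = int(informative.sum())
    if n_inf == 0:
        raise ValueError(f"variant {v.id} has only missing calls; frequency undefined")
    return float((col[informative] == int(v.alt)).sum()) / n_inf


def filter_frequency(
    matrix: HaplotypeMatrix, threshold: float, mode: str
) -> HaplotypeMatrix:
    """Keep variants with alt-allele frequency strictly above/below *threshold*.

    The inequality is strict in both modes (a frequency exactly at the
    threshold is dropped by both).  All-missing variants are dropped with a
    logged count.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"frequency threshold must be in [0, 1], got {threshold}")
    if mode not in ("above", "below"):
        raise ValueError(f"mode must be 'above' or 'below', got {mode!r}")
    keep: list[int] = []
    n_all_missing = 0
    for j in range(matrix.n_variants):
        try:
            f = alt_allele_frequency(matrix, j)
        except ValueError:
            n_all_missing += 1
            continue
        if (mode == "above" and f > threshold) or (mode == "below" and f < threshold):
            keep.append(j)
    if n_all_missing:
        logger.info("dropped %d all-missing variants in frequency filter",
                    n_all_missing)
    return matrix.slice(variant_indices=keep)


# ---------------------------------------------------------------------------
# stable sorting

def _stable_order(ids: list[str], meta: MetaTable, column: str) -> list[int]:
    kind = meta.kind(column)  # raises KeyError for unknown columns
    values = meta.column(column)

    def key(i: int):
        v = values.get(ids[i])
        if v is None:
            return (1, 0)  # absent from meta: sort last, prior order kept
        return (0, str(v)) if kind == "categorical" else (0, float(v))

    return sorted(range(len(ids)), key=key)


def sort_rows_by_meta(
    matrix: HaplotypeMatrix, meta: MetaTable, column_name: str
) -> HaplotypeMatrix:
    """Reorder subjects by a meta column, stably.

    Categorical columns sort lexicographically by label, numerical ones
    ascending; ties and subjects absent from the meta table keep their
    prior relative order (absent ones last).
    """
    order = _stable_order(matrix.subject_ids, meta, column_name)
    return matrix.slice(subject_indices=order)


def sort_columns_by_meta(
    matrix: HaplotypeMatrix, meta: MetaTable, row_name: str
) -> HaplotypeMatrix:
    """Reorder variants by a variant-axis meta row, stably (as for rows)."""
    order = _stable_order(matrix.variant_ids, meta, row_name)
    return matrix.slice(variant_indices=order)
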