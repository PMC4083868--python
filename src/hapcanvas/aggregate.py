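"""Group-wise consensus aggregation of haplotype rows.

Subjects are collapsed into groups (typically populations taken from a
categorical meta column).  For every (variant, allele-column) cell of a
group the aggregation picks a representative base among the members'
non-missing calls and stores its relative frequency:

* ``maximum`` — the most frequent base (the consensus); its frequency says
  how representative the consensus is;
* ``minimum`` — the least frequent *observed* base, which surfaces rare
  variation inside the group.

Ties are broken by the fixed base order A < C < G < T.  Paternal and
maternal allele-columns are aggregated independently, so the chromosomal
origin of an allele pattern stays visible after aggregation.  Aggregated
rows carry labels "AGN<k>" where k is the member count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hapstore import Allele, MISSING_CODE, HaplotypeMatrix, MetaTable, VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SubjectGroup",
    "AggregateCell",
    "AggregatedMatrix",
    "group_by_meta",
    "consensus_cell",
    "aggregate_rows",
    "aggregate_meta_column",
]

METHODS = ("maximum", "minimum")


@dataclass(frozen=True)
class SubjectGroup:
    """A named, ordered set of member subjects.

    ``label`` is the display identifier "AGN<member count>"; ``name`` keeps
    the grouping value it came from (e.g. the population code).
    """

    name: str
    member_ids: tuple[str, ...]

    @property
    def label(self) -> str:
        return f"AGN{len(self.member_ids)}"

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class AggregateCell:
    """Consensus base, its relative frequency, and the informative count."""

    consensus: Allele
    frequency: float
    n_informative: int

    @property
    def is_missing(self) -> bool:
        return self.n_informative == 0


def group_by_meta(
    matrix: HaplotypeMatrix, meta: MetaTable, column_name: str
) -> list[SubjectGroup]:
    """One group per distinct label of a categorical subject-meta column.

    Groups appear in first-seen order along the current subject order, and
    members keep that order.  Subjects with an absent value join no group.
    """
    if meta.kind(column_name) != "categorical":
        raise ValueError(
            f"grouping needs a categorical column; {column_name!r} is numerical "
            "(bin it into categories first)"
        )
    values = meta.column(column_name)
    members: dict[str, list[str]] = {}
    n_unlabelled = 0
    for s in matrix.subject_ids:
        v = values.get(s)
        if v is None:
            n_unlabelled += 1
            continue
        members.setdefault(v, []).append(s)
    if n_unlabelled:
        logger.info("%d subjects lack a %r value and join no group",
                    n_unlabelled, column_name)
    return [SubjectGroup(name, tuple(ids)) for name, ids in members.items()]


def consensus_cell(bases: Iterable[Allele | int], method: str) -> AggregateCell:
    """Aggregate one multiset of member calls into an :class:`AggregateCell`.

    MISSING calls are excluded from the tally.  With no members at all this
    raises; with members but only MISSING calls the cell is flagged missing
    (``n_informative == 0``).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    codes = [int(b) for b in bases]
    if not codes:
        raise ValueError("cannot aggregate an empty member set")
    counts = np.bincount([c for c in codes if c != MISSING_CODE], minlength=4)[:4]
    n_inf = int(counts.sum())
    if n_inf == 0:
        return AggregateCell(Allele.MISSING, 0.0, 0)
    code = _pick(counts, method)
    return AggregateCell(Allele(code), counts[code] / n_inf, n_inf)


def _pick(counts: np.ndarray, method: str) -> int:
    # argmax/argmin take the first extreme, i.e. the A<C<G<T tie-break
    if method == "maximum":
        return int(np.argmax(counts))
    masked = np.where(counts > 0, counts, np.iinfo(np.int64).max)
    return int(np.argmin(masked))


class AggregatedMatrix:
    """Per group x variant x allele-column consensus summary of a matrix."""

    def __init__(
        self,
        groups: Sequence[SubjectGroup],
        variants: Sequence[VariantRecord],
        n_allele_columns: int,
        phased: bool,
        consensus: np.ndarray,
        frequency: np.ndarray,
        n_informative: np.ndarray,
        method: str,
    ) -> None:
        shape = (len(groups), len(variants), n_allele_columns)
        if consensus.shape != shape or frequency.shape != shape or \
                n_informative.shape != shape:
            raise ValueError("aggregate array shapes inconsistent with groups")
        self.groups = list(groups)
        self.variants = list(variants)
        self.n_allele_columns = n_allele_columns
        self.phased = phased
        self.consensus = consensus
        self.frequency = frequency
        self.n_informative = n_informative
        self.method = method

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.groups]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def cell(self, g: int, j: int, k: int) -> AggregateCell:
        return AggregateCell(
            Allele(int(self.consensus[g, j, k])),
            float(self.frequency[g, j, k]),
            int(self.n_informative[g, j, k]),
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"AggregatedMatrix({self.n_groups} groups x {self.n_variants} SNVs, "
            f"method={self.method!r})"
        )


def aggregate_rows(
    matrix: HaplotypeMatrix, groups: Sequence[SubjectGroup], method: str
) -> AggregatedMatrix:
    """Collapse subject groups into consensus rows (source matrix unchanged).

    Groups must be disjoint and every member present in the matrix.  Each
    allele-column is tallied independently.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    seen: set[str] = set()
    for g in groups:
        if not g.member_ids:
            raise ValueError(f"group {g.name!r} has no members")
        overlap = seen.intersection(g.member_ids)
        if overlap:
            raise ValueError(f"groups overlap on subjects {sorted(overlap)[:3]}")
        seen.update(g.member_ids)

    n_g, m, p = len(groups), matrix.n_variants, matrix.n_allele_columns
    consensus = np.full((n_g, m, p), int(Allele.MISSING), dtype=np.uint8)
    frequency = np.zeros((n_g, m, p), dtype=float)
    n_informative = np.zeros((n_g, m, p), dtype=np.int64)

    for gi, g in enumerate(groups):
        rows = [matrix.subject_index(s) for s in g.member_ids]
        block = matrix.calls(subject_indices=rows)  # members x m x p
        counts = np.stack(
            [(block == b).sum(axis=0) for b in range(4)], axis=0
        )  # 4 x m x p
        n_inf = counts.sum(axis=0)
        if method == "maximum":
            pick = counts.argmax(axis=0)
        else:
            masked = np.where(counts > 0, counts, np.iinfo(np.int64).max)
            pick = masked.argmin(axis=0)
        freq = np.take_along_axis(counts, pick[None], axis=0)[0] / np.maximum(n_inf, 1)
        informative = n_inf > 0
        consensus[gi][informative] = pick[informative].astype(np.uint8)
        frequency[gi][informative] = freq[informative]
        n_informative[gi] = n_inf

    return AggregatedMatrix(
        groups, matrix.variants, p, matrix.phased,
        consensus, frequency, n_informative, method,
    )


def aggregate_meta_column(values: Iterable, kind: str, method: str):
    """Summarize one meta column over a group's members.

    Numerical columns take ``minimum``/``maximum``/``mean``; categorical
    columns take ``mode`` (ties broken lexicographically).  Absent values
    (None/NaN) are skipped; an all-absent input returns None.
    """
    kind = kind.lower()
    if kind == "numerical":
        if method not in ("minimum", "maximum", "mean"):
            raise ValueError(
                f"numerical meta aggregation supports minimum/maximum/mean, "
                f"got {method!r}"
            )
        xs = [float(v) for v in values if v is not None and np.isfinite(float(v))]
        if not xs:
            return None
        if method == "minimum":
            return min(xs)
        if method == "maximum":
            return max(xs)
        return float(np.mean(xs))
    if kind == "categorical":
        if method != "mode":
            raise ValueError(
                f"categorical meta aggregation supports only mode, got {method!r}"
            )
        xs = [str(v) for v in values if v is not None]
        if not xs:
            return None
        counts: dict[str, int] = {}
        for v in xs:
            counts[v] = counts.get(v, 0) + 1
        top = max(counts.values())
        return min(v for v, c in counts.items() if c == top)
    raise ValueError(f"unknown column kind {kind!r}")
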