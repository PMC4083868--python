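"""Compressed in-memory model of phased/unphased haplotype data.

Haplotype calls over the nucleotide alphabet {A, C, G, T} are stored at
2 bits per (subject, variant, allele-column) cell, with a separate 1-bit
mask recording missing calls (e.g. the absent second allele of male X
genotypes).  For a cohort of n subjects, m SNVs and two allele columns the
payload is exactly ``n * m * 4`` bits — an 8-fold saving over the naive
2-bytes-per-character representation — which is what makes genome-scale
phased panels fit in desktop RAM.

The matrix is immutable: every transformation (:meth:`HaplotypeMatrix.slice`
and the filter/sort operations built on it) returns a new object.  Decoding
is range-based: :meth:`HaplotypeMatrix.calls` unpacks only the requested
(subject, variant) sub-block, so no global decompressed copy is ever
materialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Allele",
    "MISSING",
    "VariantRecord",
    "MetaTable",
    "HaplotypeMatrix",
    "allele_to_code",
    "code_to_allele",
    "pack",
    "unpack",
    "payload_size_bits",
    "naive_size_bytes",
]


class Allele(IntEnum):
    """One of the four nucleotides, or MISSING.

    The four bases carry the fixed 2-bit codes A=0, C=1, G=2, T=3
    (alphabetical).  MISSING is a fifth, distinguishable state: it never
    enters the 2-bit payload and is tracked in a separate bit mask.
    """

    A = 0
    C = 1
    G = 2
    T = 3
    MISSING = 4

    @property
    def symbol(self) -> str:
        return "-" if self is Allele.MISSING else self.name

    @classmethod
    def from_symbol(cls, s: str) -> "Allele":
        s = s.upper()
        if s in ("-", ".", ""):
            return cls.MISSING
        try:
            return cls[s]
        except KeyError:
            raise ValueError(f"not a valid allele symbol: {s!r}") from None


MISSING = Allele.MISSING

#: dense-array code for a missing call (outside the 2-bit range)
MISSING_CODE: int = int(Allele.MISSING)

_BASES = (Allele.A, Allele.C, Allele.G, Allele.T)


def allele_to_code(a: Allele) -> int:
    """Return the fixed 2-bit code of a non-missing allele.

    Raises ``ValueError`` for MISSING: missingness lives in the mask, not
    in the 2-bit code space.
    """
    a = Allele(a)
    if a is Allele.MISSING:
        raise ValueError(
            "MISSING has no 2-bit code; missingness is stored in the mask"
        )
    return int(a)


def code_to_allele(code: int) -> Allele:
    """Inverse of :func:`allele_to_code`."""
    if not 0 <= code <= 3:
        raise ValueError(f"2-bit allele code out of range: {code}")
    return Allele(code)


def payload_size_bits(n_subjects: int, n_variants: int, n_allele_columns: int) -> int:
    """Exact payload size in bits: ``n * m * p * 2``.

    With 1000 subjects, 4e6 SNVs and 2 allele columns this is 1.6e10 bits
    = 2 GByte, i.e. 4 bits per (subject, SNV).
    """
    for name, v in (
        ("n_subjects", n_subjects),
        ("n_variants", n_variants),
        ("n_allele_columns", n_allele_columns),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return n_subjects * n_variants * n_allele_columns * 2


def naive_size_bytes(
    n_subjects: int,
    n_variants: int,
    n_allele_columns: int,
    bytes_per_char: int = 2,
) -> int:
    """Size of the naive character representation (2-byte chars by default).

    Used only to report the compression ratio, which is exactly 8 for the
    default ``bytes_per_char``.
    """
    if bytes_per_char < 0:
        raise ValueError("bytes_per_char must be >= 0")
    n_cells = payload_size_bits(n_subjects, n_variants, n_allele_columns) // 2
    return n_cells * bytes_per_char


@dataclass(frozen=True, order=True)
class VariantRecord:
    """Identity of one biallelic SNV (1-based position)."""

    chrom: str
    pos: int
    id: str
    ref: Allele
    alt: Allele

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos} ({self.id})")
        if self.ref is Allele.MISSING or self.alt is Allele.MISSING:
            raise ValueError(f"ref/alt must be concrete bases ({self.id})")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt for {self.id}")


# ---------------------------------------------------------------------------
# 2-bit codec

def _validate_calls(calls: np.ndarray) -> np.ndarray:
    calls = np.asarray(calls)
    if calls.ndim != 3:
        raise ValueError(
            f"calls must be a 3-d (subjects, variants, allele-columns) array, "
            f"got ndim={calls.ndim}"
        )
    calls = calls.astype(np.uint8, copy=False)
    if calls.size and calls.max(initial=0) > MISSING_CODE:
        raise ValueError("calls contain values outside {A,C,G,T,MISSING} codes")
    return calls


def pack(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack a dense call array into (payload bytes, missing-mask bytes).

    ``calls`` holds the integer codes of :class:`Allele` (MISSING allowed).
    Four 2-bit codes are stored per payload byte, most significant pair
    first; masked (missing) cells contribute code 0 to keep the payload
    fully defined.  Returns ``(payload, mask)`` uint8 arrays of
    ``ceil(n_cells/4)`` and ``ceil(n_cells/8)`` bytes.
    """
    calls = _validate_calls(calls)
    flat = calls.reshape(-1)
    missing = flat == MISSING_CODE
    codes = np.where(missing, 0, flat).astype(np.uint8)
    pad = (-len(codes)) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    payload = (
        (quads[:, 0] << 6) | (quads[:, 1] << 4) | (quads[:, 2] << 2) | quads[:, 3]
    ).astype(np.uint8)
    mask = np.packbits(missing)
    return payload, mask


def unpack(
    payload: np.ndarray, mask: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Inverse of :func:`pack`: dense uint8 code array of the given shape."""
    n_cells = int(np.prod(shape))
    codes = _unpack_flat(payload, mask, np.arange(n_cells))
    return codes.reshape(shape)


def _unpack_flat(
    payload: np.ndarray, mask: np.ndarray, flat_idx: np.ndarray
) -> np.ndarray:
    """Decode only the cells at the given flat indices (range-based access)."""
    byte_idx = flat_idx >> 2
    shift = (3 - (flat_idx & 3)) * 2
    codes = (payload[byte_idx] >> shift) & 0b11
    mbit = (mask[flat_idx >> 3] >> (7 - (flat_idx & 7))) & 1
    return np.where(mbit.astype(bool), MISSING_CODE, codes).astype(np.uint8)


# ---------------------------------------------------------------------------


class MetaTable:
    """Ordered categorical/numerical annotation columns keyed by identifier.

    ``axis`` says whether the identifiers name subjects or variants.  Column
    order and declared kinds are preserved exactly as read.  Categorical
    values are strings, numerical values finite floats; an absent value is
    ``None`` / ``NaN``.
    """

    KINDS = ("categorical", "numerical")

    def __init__(
        self,
        axis: str,
        ids: Sequence[str],
        columns: Sequence[tuple[str, str, dict]],
    ) -> None:
        if axis not in ("subject", "variant"):
            raise ValueError(f"axis must be 'subject' or 'variant', got {axis!r}")
        ids = list(ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate identifiers in meta table")
        self.axis = axis
        self.ids = ids
        self._id_set = set(ids)
        self._columns: list[tuple[str, str]] = []
        self._values: dict[str, dict] = {}
        for name, kind, values in columns:
            self.add_column(name, kind, values)

    def add_column(self, name: str, kind: str, values: dict) -> None:
        kind = kind.lower()
        if kind not in self.KINDS:
            raise ValueError(f"unknown column kind {kind!r}")
        if name in self._values:
            raise ValueError(f"duplicate meta column {name!r}")
        clean: dict = {}
        for ident, v in values.items():
            if ident not in self._id_set:
                raise ValueError(f"value for unknown id {ident!r} in column {name!r}")
            if v is None:
                continue
            if kind == "numerical":
                v = float(v)
                if not np.isfinite(v):
                    raise ValueError(
                        f"non-finite value for {ident!r} in numerical column {name!r}"
                    )
            else:
                v = str(v)
            clean[ident] = v
        self._columns.append((name, kind))
        self._values[name] = clean

    @property
    def column_names(self) -> list[str]:
        return [n for n, _ in self._columns]

    @property
    def n_columns(self) -> int:
        return len(self._columns)

    def kind(self, name: str) -> str:
        for n, k in self._columns:
            if n == name:
                return k
        raise KeyError(f"no meta column named {name!r}")

    def get(self, name: str, ident: str):
        """Value of column *name* for *ident*, or None if absent."""
        if name not in self._values:
            raise KeyError(f"no meta column named {name!r}")
        return self._values[name].get(ident)

    def column(self, name: str) -> dict:
        """id -> value mapping for one column (absent ids omitted)."""
        if name not in self._values:
            raise KeyError(f"no meta column named {name!r}")
        return dict(self._values[name])

    def restrict(self, ids: Sequence[str]) -> "MetaTable":
        """New table keeping only the given ids, in the given order."""
        keep = set(ids)
        cols = [
            (n, k, {i: v for i, v in self._values[n].items() if i in keep})
            for n, k in self._columns
        ]
        return MetaTable(self.axis, list(ids), cols)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"MetaTable(axis={self.axis!r}, n_ids={len(self.ids)}, "
            f"columns={self.column_names})"
        )


class HaplotypeMatrix:
    """Immutable subjects x variants x allele-columns matrix, bit-packed.

    Phased data uses two allele columns per SNV (column 0 = left of the VCF
    ``|`` separator, displayed as "P"; column 1 = right, displayed as "M");
    unphased or haploid views use one.  Variants are sorted by
    (chrom, pos, id) at construction; slicing and sorting preserve whatever
    order they are given.
    """

    def __init__(
        self,
        subject_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        payload: np.ndarray,
        missing_mask: np.ndarray,
        n_allele_columns: int,
        phased: bool,
    ) -> None:
        subject_ids = list(subject_ids)
        variants = list(variants)
        if len(set(subject_ids)) != len(subject_ids):
            raise ValueError("subject ids must be unique")
        vids = [v.id for v in variants]
        if len(set(vids)) != len(vids):
            raise ValueError("variant ids must be unique")
        if n_allele_columns not in (1, 2):
            raise ValueError("n_allele_columns must be 1 or 2")
        if phased and n_allele_columns != 2:
            raise ValueError("phased data requires 2 allele columns")
        n_cells = len(subject_ids) * len(variants) * n_allele_columns
        if len(payload) != (n_cells + 3) // 4:
            raise ValueError("payload byte length inconsistent with shape")
        if len(missing_mask) != (n_cells + 7) // 8:
            raise ValueError("missing-mask byte length inconsistent with shape")
        self.subject_ids = subject_ids
        self.variants = variants
        self.n_allele_columns = n_allele_columns
        self.phased = phased
        self._payload = np.asarray(payload, dtype=np.uint8)
        self._missing = np.asarray(missing_mask, dtype=np.uint8)
        self._payload.setflags(write=False)
        self._missing.setflags(write=False)
        self._subject_index = {s: i for i, s in enumerate(subject_ids)}
        self._variant_index = {v.id: j for j, v in enumerate(variants)}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_calls(
        cls,
        calls: np.ndarray,
        subject_ids: Sequence[str],
        variants: Sequence[VariantRecord],
        phased: bool,
        sort_variants: bool = True,
    ) -> "HaplotypeMatrix":
        """Pack a dense call-code array (see :class:`Allele`) into a matrix.

        By default variants (and the corresponding call columns) are sorted
        by (chrom, pos, id).
        """
        calls = _validate_calls(calls)
        n, m, p = calls.shape
        if n != len(subject_ids) or m != len(variants):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(subject_ids)} subjects / {len(variants)} variants"
            )
        variants = list(variants)
        if sort_variants and m:
            order = sorted(range(m), key=lambda j: (variants[j].chrom,
                                                    variants[j].pos,
                                                    variants[j].id))
            if order != list(range(m)):
                variants = [variants[j] for j in order]
                calls = calls[:, order, :]
        payload, mask = pack(calls)
        return cls(subject_ids, variants, payload, mask, p, phased)

    # -- shape & size -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_subjects, self.n_variants, self.n_allele_columns)

    @property
    def payload_size_bits(self) -> int:
        return payload_size_bits(*self.shape)

    @property
    def missing_mask_size_bits(self) -> int:
        return self.n_subjects * self.n_variants * self.n_allele_columns

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def subject_index(self, subject_id: str) -> int:
        return self._subject_index[subject_id]

    def variant_index(self, variant_id: str) -> int:
        return self._variant_index[variant_id]

    # -- access -------------------------------------------------------------

    def get_allele(self, i: int, j: int, k: int) -> Allele:
        """Allele of subject *i* at variant *j*, allele-column *k*."""
        n, m, p = self.shape
        if not (0 <= i < n and 0 <= j < m and 0 <= k < p):
            raise IndexError(f"index ({i},{j},{k}) out of range for shape {self.shape}")
        flat = np.array([(i * m + j) * p + k])
        return Allele(int(_unpack_flat(self._payload, self._missing, flat)[0]))

    def calls(
        self,
        subject_indices: Sequence[int] | None = None,
        variant_indices: Sequence[int] | None = None,
    ) -> np.ndarray:
        """Decode a (sub-)block to a dense uint8 code array.

        Only the requested cells are unpacked; the packed store is the sole
        full-resolution copy.
        """
        n, m, p = self.shape
        si = np.arange(n) if subject_indices is None else _check_idx(subject_indices, n)
        vi = np.arange(m) if variant_indices is None else _check_idx(variant_indices, m)
        if si.size == 0 or vi.size == 0:
            return np.zeros((si.size, vi.size, p), dtype=np.uint8)
        flat = ((si[:, None] * m + vi[None, :])[:, :, None] * p
                + np.arange(p)[None, None, :]).reshape(-1)
        codes = _unpack_flat(self._payload, self._missing, flat)
        return codes.reshape(si.size, vi.size, p)

    # -- transformation -----------------------------------------------------

    def slice(
        self,
        subject_indices: Sequence[int] | None = None,
        variant_indices: Sequence[int] | None = None,
    ) -> "HaplotypeMatrix":
        """New matrix keeping the given rows/columns in the given order."""
        n, m, _ = self.shape
        si = np.arange(n) if subject_indices is None else _check_idx(
            subject_indices, n, forbid_duplicates=True)
        vi = np.arange(m) if variant_indices is None else _check_idx(
            variant_indices, m, forbid_duplicates=True)
        sub = self.calls(si, vi)
        return HaplotypeMatrix.from_calls(
            sub,
            [self.subject_ids[i] for i in si],
            [self.variants[j] for j in vi],
            phased=self.phased,
            sort_variants=False,
        )

    # -- comparison ---------------------------------------------------------

    def equals(self, other: "HaplotypeMatrix") -> bool:
        return (
            self.subject_ids == other.subject_ids
            and self.variants == other.variants
            and self.phased == other.phased
            and self.n_allele_columns == other.n_allele_columns
            and np.array_equal(self.calls(), other.calls())
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"HaplotypeMatrix({self.n_subjects} subjects x {self.n_variants} "
            f"SNVs x {self.n_allele_columns}, phased={self.phased}, "
            f"payload={self.payload_size_bits} bits)"
        )


def _check_idx(
    indices: Sequence[int], bound: int, forbid_duplicates: bool = False
) -> np.ndarray:
    idx = np.asarray(list(indices) if not isinstance(indices, np.ndarray) else indices,
                     dtype=np.intp)
    if idx.ndim != 1:
        raise ValueError("index list must be one-dimensional")
    if idx.size and (idx.min(initial=0) < 0 or idx.max(initial=-1) >= bound):
        raise IndexError(f"index out of range [0, {bound})")
    if forbid_duplicates and len(np.unique(idx)) != idx.size:
        raise ValueError("duplicate indices are not allowed here")
    return idx
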