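"""Readers and writers for haplotype inputs.

Supported on-disk formats:

* phased or unphased VCF 4.x (plain or bgzip/gzip), GT fields only —
  backed by :mod:`pysam`;
* IMPUTE2 haplotype text files (hap + legend + sample), the default output
  of common phasing tools;
* the two-header-line tab-delimited meta-information dialect: column names
  on the first line, CATEGORICAL/NUMERICAL declarations on the second,
  identifiers in the first column.

Only biallelic SNVs are loaded; multi-allelic records, INDELs and symbolic
alleles are skipped with a logged count.  The left GT allele becomes
allele-column 0 (displayed "P"), the right column 1 ("M"); true parental
origin is not inferable from a VCF, this is a display convention.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .hapstore import (
    Allele,
    MISSING_CODE,
    HaplotypeMatrix,
    MetaTable,
    VariantRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Impute2Triple",
    "read_vcf",
    "write_vcf",
    "read_impute2",
    "write_impute2",
    "read_meta",
    "write_meta",
]

_SNV_ALLELES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class Impute2Triple:
    """Paths of an IMPUTE2 haplotype file set (hap + legend + sample)."""

    hap_path: str | Path
    legend_path: str | Path
    sample_path: str | Path


def _pysam_readable(path: str | Path) -> str:
    """htslib seeks only in plain or BGZF files; inflate ordinary gzip first."""
    path = str(path)
    if not path.endswith(".gz"):
        return path
    with open(path, "rb") as fh:
        head = fh.read(18)
    is_bgzf = len(head) >= 18 and head[3] & 4 and head[12:14] == b"BC"
    if is_bgzf:
        return path
    import tempfile

    tmp = tempfile.NamedTemporaryFile(
        mode="wb", suffix=".vcf", delete=False)
    with gzip.open(path, "rb") as src:
        tmp.write(src.read())
    tmp.close()
    return tmp.name


def _open_text(path: str | Path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# VCF

def read_vcf(path: str | Path) -> tuple[HaplotypeMatrix, MetaTable]:
    """Load a VCF into a :class:`HaplotypeMatrix` plus a variant meta stub.

    GT ``a|b`` is phased (column 0 = left allele, column 1 = right);
    ``a/b`` marks the record unphased; ``.`` sub-fields become MISSING, and
    haploid calls like ``0`` leave allele-column 1 MISSING.  If phased and
    unphased records are mixed, the whole matrix is marked unphased with a
    warning.  Returns the matrix and a variant-axis meta table carrying the
    reference base as a categorical row.
    """
    vf = pysam.VariantFile(_pysam_readable(path))
    if "GT" not in vf.header.formats:
        # pysam tolerates undeclared GT; insist the field actually occurs
        pass
    subject_ids = list(vf.header.samples)
    if not subject_ids:
        raise ValueError(f"VCF has no sample columns: {path}")

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    saw_gt = False
    phased_flags: list[bool] = []

    for rec in vf:
        alts = rec.alts or ()
        if (
            len(alts) != 1
            or rec.ref is None
            or rec.ref.upper() not in _SNV_ALLELES
            or alts[0].upper() not in _SNV_ALLELES
        ):
            n_skipped += 1
            continue
        ref = Allele.from_symbol(rec.ref)
        alt = Allele.from_symbol(alts[0])
        vid = rec.id or f"{rec.chrom}:{rec.pos}"
        col = np.full((len(subject_ids), 2), MISSING_CODE, dtype=np.uint8)
        rec_phased = True
        informative = False
        for i, name in enumerate(subject_ids):
            call = rec.samples[name]
            if "GT" not in call:
                continue
            gt = call["GT"]
            if gt is None:
                continue
            saw_gt = True
            for k, a in enumerate(gt[:2]):
                if a is None:
                    continue
                if a not in (0, 1):
                    raise ValueError(
                        f"allele index {a} outside biallelic range at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                col[i, k] = int(ref if a == 0 else alt)
            if len(gt) >= 2 and any(a is not None for a in gt):
                informative = True
                if not call.phased:
                    rec_phased = False
        variants.append(VariantRecord(rec.chrom, rec.pos, vid, ref, alt))
        columns.append(col)
        if informative:
            phased_flags.append(rec_phased)

    if not saw_gt and variants:
        raise ValueError(f"VCF records carry no GT genotype fields: {path}")
    if n_skipped:
        logger.info("skipped %d non-biallelic-SNV records in %s", n_skipped, path)

    phased = bool(phased_flags) and all(phased_flags)
    if phased_flags and any(phased_flags) and not phased:
        logger.warning(
            "mixed phased/unphased GT separators in %s; matrix marked unphased",
            path,
        )
    if columns:
        calls = np.stack(columns, axis=1)
    else:
        calls = np.zeros((len(subject_ids), 0, 2), dtype=np.uint8)
    matrix = HaplotypeMatrix.from_calls(calls, subject_ids, variants, phased=phased)

    ref_row = {v.id: v.ref.symbol for v in matrix.variants}
    meta = MetaTable(
        "variant", matrix.variant_ids, [("Reference", "categorical", ref_row)]
    )
    return matrix, meta


def write_vcf(matrix: HaplotypeMatrix, path: str | Path) -> None:
    """Write a matrix as a minimal VCF 4.2 with GT-only sample columns.

    ``read_vcf(write_vcf(M))`` reproduces M (ids, order, alleles, phasing).
    """
    sep = "|" if matrix.phased else "/"
    calls = matrix.calls()
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in matrix.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.subject_ids)
            + "\n"
        )
        for j, v in enumerate(matrix.variants):
            fields = [v.chrom, str(v.pos), v.id, v.ref.symbol, v.alt.symbol,
                      ".", "PASS", ".", "GT"]
            for i in range(matrix.n_subjects):
                gt = []
                for k in range(matrix.n_allele_columns):
                    c = calls[i, j, k]
                    if c == MISSING_CODE:
                        gt.append(".")
                    else:
                        gt.append("0" if c == int(v.ref) else "1")
                if (
                    matrix.n_allele_columns == 2
                    and gt[0] != "."
                    and gt[1] == "."
                ):
                    gt = gt[:1]  # haploid call, e.g. male X
                fields.append(sep.join(gt))
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# IMPUTE2

def read_impute2(triple: Impute2Triple) -> HaplotypeMatrix:
    """Load an IMPUTE2 hap/legend/sample triple; the result is always phased.

    The hap file holds space-separated 0/1 tokens (``?`` = missing), two
    columns per subject; the legend has the header ``id position a0 a1``;
    token 0 maps to allele a0, token 1 to a1.
    """
    with _open_text(triple.sample_path) as fh:
        sample_lines = [ln.split() for ln in fh if ln.strip()]
    if sample_lines and sample_lines[0] and sample_lines[0][0].upper() in (
        "ID", "ID_1", "SAMPLE",
    ):
        header_rows = 1
        # classic IMPUTE2 sample files carry a second "0 0 0" type row
        if len(sample_lines) > 1 and sample_lines[1][0] == "0":
            header_rows = 2
        sample_lines = sample_lines[header_rows:]
    subject_ids = [row[0] for row in sample_lines]

    variants: list[VariantRecord] = []
    with _open_text(triple.legend_path) as fh:
        header = fh.readline().split()
        if [h.lower() for h in header[:4]] != ["id", "position", "a0", "a1"]:
            raise ValueError(
                f"legend header must start 'id position a0 a1', got {header!r}"
            )
        for ln in fh:
            if not ln.strip():
                continue
            vid, pos, a0, a1 = ln.split()[:4]
            variants.append(
                VariantRecord(
                    "1", int(pos), vid,
                    Allele.from_symbol(a0), Allele.from_symbol(a1),
                )
            )

    n, m = len(subject_ids), len(variants)
    calls = np.full((n, m, 2), MISSING_CODE, dtype=np.uint8)
    with _open_text(triple.hap_path) as fh:
        j = 0
        for ln in fh:
            if not ln.strip():
                continue
            tokens = ln.split()
            if j >= m:
                raise ValueError("hap file has more rows than the legend")
            if len(tokens) != 2 * n:
                raise ValueError(
                    f"hap row {j} has {len(tokens)} tokens, expected {2 * n}"
                )
            v = variants[j]
            for s in range(n):
                for k in (0, 1):
                    tok = tokens[2 * s + k]
                    if tok == "?":
                        continue
                    if tok == "0":
                        calls[s, j, k] = int(v.ref)
                    elif tok == "1":
                        calls[s, j, k] = int(v.alt)
                    else:
                        raise ValueError(
                            f"unexpected hap token {tok!r} at row {j}, subject {s}"
                        )
            j += 1
    if j != m:
        raise ValueError(f"hap file has {j} rows but the legend lists {m}")
    return HaplotypeMatrix.from_calls(calls, subject_ids, variants, phased=True)


def write_impute2(matrix: HaplotypeMatrix, triple: Impute2Triple) -> None:
    """Write a phased matrix as an IMPUTE2 hap/legend/sample triple."""
    if not matrix.phased:
        raise ValueError("IMPUTE2 haplotype files require phased data")
    calls = matrix.calls()
    with _open_text(triple.legend_path, "wt") as fh:
        fh.write("id position a0 a1\n")
        for v in matrix.variants:
            fh.write(f"{v.id} {v.pos} {v.ref.symbol} {v.alt.symbol}\n")
    with _open_text(triple.sample_path, "wt") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for s in matrix.subject_ids:
            fh.write(f"{s} {s} 0\n")
    with _open_text(triple.hap_path, "wt") as fh:
        for j, v in enumerate(matrix.variants):
            tokens = []
            for i in range(matrix.n_subjects):
                for k in (0, 1):
                    c = calls[i, j, k]
                    if c == MISSING_CODE:
                        tokens.append("?")
                    else:
                        tokens.append("0" if c == int(v.ref) else "1")
            fh.write(" ".join(tokens) + "\n")


# ---------------------------------------------------------------------------
# meta TSV

_MISSING_TOKENS = {"", "NA", "na", "NaN", "nan", "."}


def read_meta(path: str | Path, axis: str,
              known_ids: Sequence[str] | None = None) -> MetaTable:
    """Read the two-header-line tab-delimited meta dialect.

    First header line: column names (first cell labels the id column and is
    ignored).  Second header line: CATEGORICAL or NUMERICAL per column,
    case-insensitive.  Empty cells and "NA" are absent values.  Identifiers
    not in *known_ids* (when given) are kept but logged.
    """
    with _open_text(path) as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) < 2:
        raise ValueError(f"meta file needs two header lines: {path}")
    names = lines[0].split("\t")[1:]
    kinds = [k.strip().lower() for k in lines[1].split("\t")[1:]]
    if len(kinds) != len(names):
        raise ValueError(
            f"{path}: second header line declares {len(kinds)} kinds for "
            f"{len(names)} columns"
        )
    for k in kinds:
        if k not in MetaTable.KINDS:
            raise ValueError(
                f"{path}: unknown kind token {k!r} "
                f"(expected CATEGORICAL or NUMERICAL)"
            )
    ids: list[str] = []
    values: list[dict] = [dict() for _ in names]
    for row_no, ln in enumerate(lines[2:], start=3):
        cells = ln.split("\t")
        ident = cells[0].strip()
        ids.append(ident)
        for c, name in enumerate(names):
            raw = cells[c + 1].strip() if c + 1 < len(cells) else ""
            if raw in _MISSING_TOKENS:
                continue
            if kinds[c] == "numerical":
                try:
                    values[c][ident] = float(raw)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {raw!r} at line {row_no}, "
                        f"column {name!r}"
                    ) from None
            else:
                values[c][ident] = raw
    if known_ids is not None:
        unknown = [i for i in ids if i not in set(known_ids)]
        if unknown:
            logger.info(
                "%d meta identifiers not present in the matrix (kept): %s...",
                len(unknown), unknown[:5],
            )
    return MetaTable(axis, ids, list(zip(names, kinds, values)))


def write_meta(meta: MetaTable, path: str | Path) -> None:
    """Write a :class:`MetaTable` in the two-header-line dialect."""
    with _open_text(path, "wt") as fh:
        fh.write("ID\t" + "\t".join(meta.column_names) + "\n")
        fh.write(
            "ID\t" + "\t".join(meta.kind(n).upper() for n in meta.column_names) + "\n"
        )
        for ident in meta.ids:
            cells = [ident]
            for name in meta.column_names:
                v = meta.get(name, ident)
                if v is None:
                    cells.append("")
                elif meta.kind(name) == "numerical":
                    cells.append(repr(float(v)))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
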