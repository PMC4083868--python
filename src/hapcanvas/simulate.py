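"""Seeded synthetic multi-population phased cohorts.

The generator emulates the population structure of a large phased resequencing
panel in miniature: a handful of populations nested in super-populations,
biallelic SNVs with per-population alternate-allele frequencies, a
controllable share of rare variants (per-population frequency below a
threshold, 0.5% by default), and a small rate of missing calls such as male
X haplotypes produce.  Haplotype alleles are drawn i.i.d. per allele-column
from the population frequency — there is no linkage-disequilibrium model —
which is sufficient to exercise every filtering, sorting, aggregation and
rendering path.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hapstore import Allele, MISSING_CODE, HaplotypeMatrix, MetaTable, VariantRecord
from .io_formats import Impute2Triple, write_impute2, write_meta, write_vcf

__all__ = ["PopulationSpec", "CohortSpec", "simulate_cohort", "write_cohort",
           "default_cohort_spec"]

#: 14 populations in 4 super-populations, the structure of a typical
#: world-wide phased panel, used as the default fixture layout.
DEFAULT_POPULATIONS: tuple[tuple[str, str], ...] = (
    ("YRI", "AFR"), ("LWK", "AFR"), ("ASW", "AFR"),
    ("CEU", "EUR"), ("TSI", "EUR"), ("FIN", "EUR"), ("GBR", "EUR"), ("IBS", "EUR"),
    ("CHB", "ASN"), ("JPT", "ASN"), ("CHS", "ASN"),
    ("MXL", "AMR"), ("PUR", "AMR"), ("CLM", "AMR"),
)

_BASE_CODES = np.array([int(Allele.A), int(Allele.C), int(Allele.G), int(Allele.T)])


@dataclass(frozen=True)
class PopulationSpec:
    label: str
    super_label: str
    n_subjects: int

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"population {self.label!r} needs >= 1 subjects")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    ``rare_fraction`` of the variants are rare: their alternate-allele
    frequency in every population is drawn below ``rare_threshold``; the
    remaining, common variants draw per-population frequencies from
    ``common_freq_range``.  ``freqs`` may instead give the full
    populations x variants frequency matrix explicitly.  Naming one
    population in ``fixed_alt_population`` fixes it for the alternate
    allele (frequency 1.0) at variant index ``fixed_alt_site``, a designed
    differentiating site for aggregation demos.
    """

    populations: tuple[PopulationSpec, ...]
    n_variants: int = 200
    chrom: str = "1"
    pos_start: int = 10_000
    pos_step: int = 500
    rare_fraction: float = 0.3
    rare_threshold: float = 0.005
    common_freq_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.01
    freqs: np.ndarray | None = None
    fixed_alt_population: str | None = None
    fixed_alt_site: int | None = None
    genes_per_cohort: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 <= self.rare_fraction <= 1.0:
            raise ValueError("rare_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 < self.rare_threshold < 1.0:
            raise ValueError("rare_threshold must be in (0, 1)")
        lo, hi = self.common_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("common_freq_range must be an ordered pair in [0, 1]")
        if self.freqs is not None:
            f = np.asarray(self.freqs, dtype=float)
            if f.shape != (len(self.populations), self.n_variants):
                raise ValueError(
                    f"freqs must have shape (n_populations, n_variants) = "
                    f"({len(self.populations)}, {self.n_variants})"
                )
            if f.min() < 0 or f.max() > 1:
                raise ValueError("freqs must lie in [0, 1]")
        if (self.fixed_alt_population is None) != (self.fixed_alt_site is None):
            raise ValueError(
                "fixed_alt_population and fixed_alt_site must be given together"
            )
        if self.fixed_alt_site is not None and not (
            0 <= self.fixed_alt_site < self.n_variants
        ):
            raise ValueError("fixed_alt_site out of range")
        if self.fixed_alt_population is not None and self.fixed_alt_population not in [
            p.label for p in self.populations
        ]:
            raise ValueError(
                f"unknown fixed_alt_population {self.fixed_alt_population!r}"
            )

    @property
    def n_subjects(self) -> int:
        return sum(p.n_subjects for p in self.populations)


def default_cohort_spec(
    n_subjects_per_population: int = 6,
    n_variants: int = 200,
    seed: int = 0,
) -> CohortSpec:
    """The standard miniature fixture: 14 populations in 4 super-populations,
    30% rare variants at the 0.5% threshold, and one designed site at which
    the first population (YRI) is fixed for the alternate allele."""
    pops = tuple(
        PopulationSpec(lab, sup, n_subjects_per_population)
        for lab, sup in DEFAULT_POPULATIONS
    )
    return CohortSpec(
        populations=pops,
        n_variants=n_variants,
        fixed_alt_population=pops[0].label,
        fixed_alt_site=n_variants // 2,
        seed=seed,
    )


def _draw_freqs(spec: CohortSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(populations x variants frequency matrix, is_rare flags)."""
    n_pop, m = len(spec.populations), spec.n_variants
    if spec.freqs is not None:
        F = np.asarray(spec.freqs, dtype=float).copy()
        is_rare = (F < spec.rare_threshold).all(axis=0)
    else:
        n_rare = int(round(spec.rare_fraction * m))
        is_rare = np.zeros(m, dtype=bool)
        rare_idx = rng.choice(m, size=n_rare, replace=False)
        is_rare[rare_idx] = True
        lo, hi = spec.common_freq_range
        F = rng.uniform(lo, hi, size=(n_pop, m))
        F[:, is_rare] = rng.uniform(0.0, spec.rare_threshold,
                                    size=(n_pop, int(is_rare.sum())))
    if spec.fixed_alt_population is not None:
        pi = [p.label for p in spec.populations].index(spec.fixed_alt_population)
        F[pi, spec.fixed_alt_site] = 1.0
        is_rare[spec.fixed_alt_site] = False
    return F, is_rare


def simulate_cohort(
    spec: CohortSpec,
) -> tuple[HaplotypeMatrix, MetaTable, MetaTable]:
    """Draw one phased cohort: matrix + subject meta + variant meta.

    Each haplotype allele of a subject from population p at variant j is
    the alternate base with probability F[p, j], independently per
    allele-column; calls go missing independently at ``missing_rate``.
    Subject meta carries Population and SuperPopulation (categorical) and
    Age (numerical); variant meta carries a Gene label row (categorical
    blocks) and the Position (numerical).
    """
    rng = np.random.default_rng(spec.seed)
    n_pop, m = len(spec.populations), spec.n_variants
    F, is_rare = _draw_freqs(spec, rng)

    # variant identities: random distinct ref/alt bases
    ref_codes = rng.integers(0, 4, size=m)
    alt_offset = rng.integers(1, 4, size=m)
    alt_codes = (ref_codes + alt_offset) % 4
    variants = [
        VariantRecord(
            spec.chrom,
            spec.pos_start + j * spec.pos_step,
            f"rs{100000 + j}",
            Allele(int(ref_codes[j])),
            Allele(int(alt_codes[j])),
        )
        for j in range(m)
    ]

    subject_ids: list[str] = []
    pop_of: list[int] = []
    for pi, pop in enumerate(spec.populations):
        for s in range(pop.n_subjects):
            subject_ids.append(f"{pop.label}{s + 1:03d}")
            pop_of.append(pi)
    n = len(subject_ids)

    probs = F[np.array(pop_of)][:, :, None]          # n x m x 1
    is_alt = rng.random((n, m, 2)) < probs
    calls = np.where(is_alt, alt_codes[None, :, None],
                     ref_codes[None, :, None]).astype(np.uint8)
    if spec.missing_rate > 0:
        gone = rng.random((n, m, 2)) < spec.missing_rate
        calls[gone] = MISSING_CODE

    matrix = HaplotypeMatrix.from_calls(calls, subject_ids, variants, phased=True)

    ages = rng.integers(20, 71, size=n)
    subject_meta = MetaTable(
        "subject",
        subject_ids,
        [
            ("Population", "categorical",
             {s: spec.populations[pop_of[i]].label
              for i, s in enumerate(subject_ids)}),
            ("SuperPopulation", "categorical",
             {s: spec.populations[pop_of[i]].super_label
              for i, s in enumerate(subject_ids)}),
            ("Age", "numerical", {s: int(ages[i])
                                  for i, s in enumerate(subject_ids)}),
        ],
    )

    block = max(1, m // max(1, spec.genes_per_cohort))
    vids = matrix.variant_ids
    pos_by_id = {v.id: v.pos for v in matrix.variants}
    orig_index = {v.id: j for j, v in enumerate(variants)}
    variant_meta = MetaTable(
        "variant",
        vids,
        [
            ("Gene", "categorical",
             {vid: f"GENE{orig_index[vid] // block + 1}" for vid in vids}),
            ("Position", "numerical", {vid: pos_by_id[vid] for vid in vids}),
            ("Rare", "categorical",
             {vid: ("yes" if is_rare[orig_index[vid]] else "no")
              for vid in vids}),
        ],
    )
    return matrix, subject_meta, variant_meta


def write_cohort(
    matrix: HaplotypeMatrix,
    subject_meta: MetaTable,
    variant_meta: MetaTable,
    out_dir: str | Path,
    formats: Sequence[str] = ("vcf", "impute2", "meta"),
) -> dict[str, Path]:
    """Write a simulated cohort to disk; returns the paths written.

    ``vcf`` -> cohort.vcf; ``impute2`` -> cohort.hap/.legend/.sample;
    ``meta`` -> subjects.tsv + variants.tsv in the two-header-line dialect.
    Reading any haplotype file back reproduces the matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "vcf":
            paths["vcf"] = out_dir / "cohort.vcf"
            write_vcf(matrix, paths["vcf"])
        elif fmt == "impute2":
            triple = Impute2Triple(
                out_dir / "cohort.hap",
                out_dir / "cohort.legend",
                out_dir / "cohort.sample",
            )
            write_impute2(matrix, triple)
            paths.update(hap=Path(triple.hap_path),
                         legend=Path(triple.legend_path),
                         sample=Path(triple.sample_path))
        elif fmt == "meta":
            paths["subject_meta"] = out_dir / "subjects.tsv"
            paths["variant_meta"] = out_dir / "variants.tsv"
            write_meta(subject_meta, paths["subject_meta"])
            write_meta(variant_meta, paths["variant_meta"])
        else:
            raise ValueError(f"unknown cohort format {fmt!r}")
    return paths
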