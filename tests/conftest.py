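import numpy as np
import pytest

from hapcanvas import (
    Allele,
    HaplotypeMatrix,
    MetaTable,
    VariantRecord,
    default_cohort_spec,
    simulate_cohort,
)
from hapcanvas.hapstore import MISSING_CODE

A, C, G, T, MISS = (int(Allele.A), int(Allele.C), int(Allele.G),
                    int(Allele.T), MISSING_CODE)


def make_matrix(calls, phased=True, chrom="1", refs=None, alts=None):
    """Build a matrix from a nested call-code list (subjects x variants x p)."""
    calls = np.asarray(calls, dtype=np.uint8)
    n, m, p = calls.shape
    refs = refs or [C] * m
    alts = alts or [G] * m
    variants = [
        VariantRecord(chrom, 100 * (j + 1), f"rs{j + 1}",
                      Allele(refs[j]), Allele(alts[j]))
        for j in range(m)
    ]
    return HaplotypeMatrix.from_calls(
        calls, [f"S{i + 1}" for i in range(n)], variants, phased=phased
    )


@pytest.fixture
def tiny_phased():
    """3 subjects x 2 SNVs, phased, with one missing call."""
    calls = [
        [[C, G], [A, A]],
        [[C, C], [A, T]],
        [[G, G], [MISS, A]],
    ]
    return make_matrix(calls, refs=[C, A], alts=[G, T])


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 14-population cohort used across the suite (session-scoped)."""
    spec = default_cohort_spec(n_subjects_per_population=5, n_variants=120, seed=7)
    return simulate_cohort(spec)


@pytest.fixture
def handcrafted_vcf(tmp_path):
    """3-sample, 5-record VCF exercising phased/unphased/missing/haploid GTs
    plus one INDEL record that readers must skip."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tN1\tN2\tN3
2\t100\trs1\tC\tG\t.\tPASS\t.\tGT\t0|1\t1|1\t0|0
2\t200\trs2\tA\tT\t.\tPASS\t.\tGT\t.|.\t0|1\t1|0
2\t300\trs3\tG\tA\t.\tPASS\t.\tGT\t0\t1|1\t0|1
2\t400\trs4\tT\tC\t.\tPASS\t.\tGT\t0|0\t.\t1|1
2\t500\tindel1\tTA\tT\t.\tPASS\t.\tGT\t0|1\t0|0\t0|0
2\t600\trs5\tC\tA\t.\tPASS\t.\tGT\t1|1\t0|1\t0|0
"""
    path = tmp_path / "hand.vcf"
    path.write_text(text)
    return path
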