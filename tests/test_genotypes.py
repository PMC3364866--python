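"""Genotype I/O, QC statistics, the exact HWE test and sharing analysis."""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from suprapop.genotypes import (
    MISSING,
    GenotypeMatrix,
    bonferroni_alpha,
    hwe_exact_test,
    hwe_null_distribution,
    pairwise_test_count,
    polymorphic_loci,
    read_genotype_table,
    read_vcf,
    sharing_venn,
    summarize_locus,
    write_genotype_table,
)


# ---------------------------------------------------------------- TSV I/O


def test_read_well_formed_table(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "individual_id\tspecies\tlocality\tl1\tl2\n"
        "a\tsp1\tloc\t0\t1\n"
        "b\tsp1\tloc\t2\tNA\n"
        "c\tsp2\tloc\t1\t1\n"
    )
    m = read_genotype_table(path)
    assert m.n_individuals == 3 and m.n_loci == 2
    assert m.genotypes[1, 1] == MISSING
    assert m.group_labels == ["sp1", "sp1", "sp2"]


def test_illegal_token_names_the_cell(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "individual_id\tspecies\tlocality\tl1\n"
        "a\tsp1\tloc\t0\n"
        "b\tsp1\tloc\t3\n"
    )
    with pytest.raises(ValueError, match=r"'3'.*'b'.*'l1'"):
        read_genotype_table(path)


def test_roundtrip_is_identity(small_matrix, tmp_path):
    path = tmp_path / "rt.tsv"
    write_genotype_table(small_matrix, path)
    back = read_genotype_table(path)
    assert back.individual_ids == small_matrix.individual_ids
    assert back.locus_ids == small_matrix.locus_ids
    assert back.group_labels == small_matrix.group_labels
    np.testing.assert_array_equal(back.genotypes, small_matrix.genotypes)


def test_duplicate_ids_rejected():
    with pytest.raises(ValueError, match="duplicate individual"):
        GenotypeMatrix(["a", "a"], ["s", "s"], ["l1"], np.zeros((2, 1), dtype=np.int8))
    with pytest.raises(ValueError, match="duplicate locus"):
        GenotypeMatrix(["a", "b"], ["s", "s"], ["l1", "l1"], np.zeros((2, 2), dtype=np.int8))


def test_illegal_code_rejected_at_construction():
    with pytest.raises(ValueError, match="illegal genotype code"):
        GenotypeMatrix(["a"], ["s"], ["l1"], np.array([[5]], dtype=np.int8))


# ------------------------------------------------------------------- VCF


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\n"
)


def test_read_vcf_gt_mapping(tmp_path, caplog):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(
        VCF_HEADER
        + "1\t100\tsnp1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        + "1\t200\tsnp2\tA\tT\t.\t.\t.\tGT\t0|1\t./.\t1/0\n"
        + "1\t300\tsnp3\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    mapping = {"s1": "spA", "s2": "spA", "s3": "spB"}
    with caplog.at_level("WARNING"):
        m = read_vcf(vcf, mapping)
    assert m.locus_ids == ["snp1", "snp2"]  # multi-allelic snp3 skipped
    np.testing.assert_array_equal(m.genotypes[:, 0], [0, 1, 2])
    # phased 0|1 -> 1; ./. -> missing; 1/0 -> 1
    np.testing.assert_array_equal(m.genotypes[:, 1], [1, MISSING, 1])
    assert any("multi-allelic" in r.message for r in caplog.records)


def test_read_vcf_sidecar_and_no_biallelic(tmp_path):
    vcf = tmp_path / "t.vcf"
    vcf.write_text(VCF_HEADER + "1\t300\t.\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
    sidecar = tmp_path / "map.tsv"
    sidecar.write_text("s1\tspA\ns2\tspA\ns3\tspB\n")
    with pytest.raises(ValueError, match="no biallelic"):
        read_vcf(vcf, sidecar)


# ----------------------------------------------------------- QC summaries


def test_summarize_locus_direct_counts():
    # 10 hom-ref, 7 het, 3 hom-alt over 20 called -> maf 13/40, h_obs 0.35
    genos = np.array([[0]] * 10 + [[1]] * 7 + [[2]] * 3, dtype=np.int8)
    m = GenotypeMatrix(
        [f"i{k}" for k in range(20)], ["g"] * 20, ["l"], genos
    )
    (s,) = summarize_locus(m, "g")
    assert s.n_called == 20
    assert s.maf == pytest.approx(13 / 40)
    assert s.h_obs == pytest.approx(0.35)
    assert s.polymorphic


def test_summarize_monomorphic_and_missing():
    genos = np.array([[0, MISSING]] * 15 + [[0, 1]] * 5, dtype=np.int8)
    m = GenotypeMatrix([f"i{k}" for k in range(20)], ["g"] * 20, ["a", "b"], genos)
    sa, sb = summarize_locus(m, "g")
    assert sa.maf == 0 and sa.h_obs == 0 and not sa.polymorphic
    assert sb.n_called == 5 and sb.missing_fraction == pytest.approx(0.75)
    assert sb.maf == pytest.approx(5 / 10)


def test_summarize_all_missing_locus_is_undefined():
    genos = np.full((4, 1), MISSING, dtype=np.int8)
    m = GenotypeMatrix([f"i{k}" for k in range(4)], ["g"] * 4, ["l"], genos)
    (s,) = summarize_locus(m, "g")
    assert s.n_called == 0 and math.isnan(s.maf) and not s.polymorphic


def test_unknown_group_raises(small_matrix):
    with pytest.raises(KeyError):
        summarize_locus(small_matrix, "no-such-species")


def test_summaries_invariant_to_individual_order(small_matrix):
    ref = summarize_locus(small_matrix, "A")
    perm = [2, 0, 1, 5, 3, 4]
    shuffled = GenotypeMatrix(
        [small_matrix.individual_ids[i] for i in perm],
        [small_matrix.group_labels[i] for i in perm],
        small_matrix.locus_ids,
        small_matrix.genotypes[perm],
    )
    got = summarize_locus(shuffled, "A")
    for a, b in zip(ref, got):
        assert (a.maf, a.h_obs, a.n_called, a.hwe_p) == (b.maf, b.h_obs, b.n_called, b.hwe_p)


# ------------------------------------------------------------- HWE exact


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent enumeration with exact rational arithmetic.

    Probability of a genotype configuration conditional on allele counts
    is multinomial(n; counts) * 2^het / (sum over configurations); the
    two-sided p-value sums configurations no more probable than observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_ref = 2 * n_hom_ref + n_het
    n_alt = 2 * n - n_ref
    n_minor = min(n_ref, n_alt)
    if n_minor == 0:
        return 1.0
    weights = {}
    for h in range(n_minor % 2, n_minor + 1, 2):
        a = (n_ref - h) // 2
        b = (n_alt - h) // 2
        weights[h] = Fraction(comb(n, a) * comb(n - a, h) * 2**h)
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= obs))


@pytest.mark.parametrize(
    "counts",
    [(3, 5, 2), (10, 0, 0), (5, 1, 5), (0, 3, 7), (2, 2, 2), (50, 20, 5), (1, 1, 1)],
)
def test_hwe_matches_rational_enumeration_oracle(counts):
    assert hwe_exact_test(*counts) == pytest.approx(hwe_oracle(*counts), abs=1e-10)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(10, 0, 0) == 1.0
    assert hwe_exact_test(0, 0, 7) == 1.0


def test_hwe_large_sample_agrees_with_chi_square():
    # 500/1000/500 is exactly at HW proportions; compare a deviating table
    for table in [(500, 1000, 500), (550, 900, 550), (520, 960, 520)]:
        n_hom_ref, n_het, n_hom_alt = table
        n = sum(table)
        p_ref = (2 * n_hom_ref + n_het) / (2 * n)
        expected = np.array(
            [n * p_ref**2, 2 * n * p_ref * (1 - p_ref), n * (1 - p_ref) ** 2]
        )
        chi2 = ((np.array(table) - expected) ** 2 / expected).sum()
        p_asym = stats.chi2.sf(chi2, df=1)
        assert hwe_exact_test(*table) == pytest.approx(p_asym, abs=0.02)


@given(
    st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
)
@settings(max_examples=200, deadline=None)
def test_hwe_symmetric_and_in_unit_interval(a, h, b):
    if a + h + b == 0:
        return
    p = hwe_exact_test(a, h, b)
    assert 0 < p <= 1
    assert p == pytest.approx(hwe_exact_test(b, h, a), abs=1e-12)


def test_hwe_rejects_all_zero():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_null_distribution_sums_to_one_and_matches_oracle():
    dist = hwe_null_distribution(10, 9)
    assert sum(dist.values()) == pytest.approx(1.0)
    # same conditional distribution as the rational oracle for n=10, 9 minor
    weights = {}
    for h in range(1, 10, 2):
        a = (11 - h) // 2
        weights[h] = Fraction(comb(10, a) * comb(10 - a, h) * 2**h)
    total = sum(weights.values())
    for h, w in weights.items():
        assert dist[h] == pytest.approx(float(w / total))


# ------------------------------------------------------- sharing analysis


def test_polymorphic_loci_definitions(small_matrix):
    # species A: l1 {0,0,1} poly; l2 {1,1,1} poly; l3 {2,2,2} mono; l4 {NA,0,0} mono
    assert polymorphic_loci(small_matrix, "A") == {"l1", "l2"}
    # species B rows are [2,2,NA,0] and [2,2,2,0]: every locus monomorphic
    assert polymorphic_loci(small_matrix, "B") == set()
    with pytest.raises(KeyError):
        polymorphic_loci(small_matrix, "Z")


def test_sharing_venn_identical_and_disjoint():
    loci = {f"s{i}" for i in range(50)}
    rep = sharing_venn({c: set(loci) for c in "wxyz"}, panel_size=364)
    assert rep.core_count == 50
    assert all(v == 0 for k, v in rep.regions.items() if len(k) < 4)
    assert rep.fractions["w"] == pytest.approx(50 / 364)

    a = {f"a{i}" for i in range(5)}
    b = {f"b{i}" for i in range(7)}
    rep2 = sharing_venn({"a": a, "b": b})
    assert rep2.core_count == 0
    assert rep2.regions[("a",)] == 5 and rep2.regions[("b",)] == 7


def test_sharing_venn_matches_brute_force_regions():
    rng = np.random.default_rng(7)
    panel = [f"snp{i}" for i in range(364)]
    sets = {
        name: set(rng.choice(panel, size=rng.integers(30, 81), replace=False))
        for name in ["sp1", "sp2", "sp3", "sp4"]
    }
    rep = sharing_venn(sets, panel_size=364)
    names = sorted(sets)
    # brute force: classify each union locus by its exact membership pattern
    brute: dict[tuple[str, ...], int] = {}
    for locus in set().union(*sets.values()):
        members = tuple(n for n in names if locus in sets[n])
        brute[members] = brute.get(members, 0) + 1
    for region, count in rep.regions.items():
        assert count == brute.get(region, 0)
    assert sum(rep.regions.values()) == len(set().union(*sets.values()))
    assert rep.core_count == len(set.intersection(*sets.values()))
    assert rep.core_count <= min(rep.counts.values())


def test_sharing_venn_order_invariant():
    sets = {"a": {1, 2, 3}, "b": {2, 3, 4}, "c": {3, 4, 5}}
    r1 = sharing_venn(dict(sets))
    r2 = sharing_venn(dict(reversed(list(sets.items()))))
    assert r1.regions == r2.regions and r1.core_count == r2.core_count


def test_sharing_venn_needs_two_sets():
    with pytest.raises(ValueError):
        sharing_venn({"a": {1}})


# ---------------------------------------------------------- combinatorics


@pytest.mark.parametrize("n,expected", [(364, 66066), (2, 1), (10, 45)])
def test_pairwise_test_count(n, expected):
    assert pairwise_test_count(n) == expected


def test_pairwise_count_requires_two_loci():
    with pytest.raises(ValueError):
        pairwise_test_count(1)


def test_bonferroni():
    assert bonferroni_alpha(0.05, 66066) == pytest.approx(0.05 / 66066)
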