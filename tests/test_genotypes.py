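import numpy as np
import pytest

from ascbias.genotypes import (ATGC, MISSING, TRANSITION, TRANSVERSION_OTHER,
                               assign_blocks, filter_missing, load_eigenstrat,
                               mutation_class, polarize, write_eigenstrat)

from conftest import make_gm


@pytest.mark.parametrize("pair,expected", [
    (("A", "T"), ATGC), (("G", "C"), ATGC),
    (("A", "G"), TRANSITION), (("C", "T"), TRANSITION),
    (("A", "C"), TRANSVERSION_OTHER), (("G", "T"), TRANSVERSION_OTHER),
])
def test_mutation_class_partition(pair, expected):
    """The three mutation classes cover every biallelic SNP exactly once."""
    assert mutation_class(*pair) == expected
    assert mutation_class(pair[1], pair[0]) == expected


def test_mutation_class_rejects_non_snp():
    with pytest.raises(ValueError):
        mutation_class("A", "A")


def test_eigenstrat_round_trip(tmp_path):
    """load -> write -> load is bit-identical for dosages and metadata."""
    gm = make_gm([[0, 1], [2, -1], [1, 2]], ["popA", "popB"],
                 chrom=["1", "1", "2"], pos=[100, 4_000_001, 5],
                 anc=["A", "C", "G"], der=["T", "T", "C"])
    write_eigenstrat(gm, tmp_path / "toy")
    gm2 = load_eigenstrat(tmp_path / "toy.geno", tmp_path / "toy.snp",
                          tmp_path / "toy.ind")
    np.testing.assert_array_equal(gm.calls, gm2.calls)
    assert gm2.sites["pos"].tolist() == gm.sites["pos"].tolist()
    assert gm2.sites["anc"].tolist() == gm.sites["anc"].tolist()
    assert gm2.sites["mclass"].tolist() == [ATGC, TRANSITION, ATGC]
    assert gm2.individuals["population"].tolist() == ["popA", "popB"]


def test_eigenstrat_missing_code(tmp_path):
    gm = make_gm([[1, -1]], ["p", "p"])
    write_eigenstrat(gm, tmp_path / "m")
    text = (tmp_path / "m.geno").read_text().strip()
    assert text == "19"  # derived dosage 1 -> ref count 1; missing -> 9


def test_polarize_flips_and_drops():
    # outgroup is individual 0: hom-anc, hom-der, het, missing
    gm = make_gm([[0, 1, 2],
                  [2, 1, 0],
                  [1, 0, 2],
                  [-1, 1, 1]], ["og", "x", "x"])
    out = polarize(gm, "og_1")
    # het and missing outgroup sites dropped
    assert out.n_sites == 2
    # first site unchanged; second flipped d -> 2-d
    np.testing.assert_array_equal(out.calls[0], [0, 1, 2])
    np.testing.assert_array_equal(out.calls[1], [0, 1, 2])
    assert out.sites.iloc[1]["anc"] == gm.sites.iloc[1]["der"]


def test_polarize_idempotent():
    """Re-polarizing with the same outgroup is a no-op after the first pass."""
    rng = np.random.default_rng(0)
    calls = rng.integers(0, 3, size=(50, 4)).astype(np.int8)
    calls[rng.random(50) < 0.2, 0] = 1
    gm = make_gm(calls, ["og", "a", "a", "b"])
    once = polarize(gm, "og_1")
    twice = polarize(once, "og_1")
    np.testing.assert_array_equal(once.calls, twice.calls)
    assert once.sites.equals(twice.sites)


def test_polarize_unknown_outgroup():
    gm = make_gm([[0, 0]], ["a", "b"])
    with pytest.raises(KeyError):
        polarize(gm, "nobody")


def test_assign_blocks_floor_arithmetic():
    gm = make_gm([[0]] * 5, ["p"],
                 chrom=["1", "1", "1", "2", "2"],
                 pos=[1, 3_999_999, 4_000_001, 10, 4_000_000])
    bp = assign_blocks(gm, 4_000_000)
    # chr1: block 0 twice then block 1; chr2: block 0 twice (4e6 -> local 0)
    assert bp.block_index.tolist() == [0, 0, 1, 2, 2]
    assert bp.site_counts.tolist() == [2, 1, 2]


def test_assign_blocks_single_block():
    gm = make_gm([[0]] * 3, ["p"], pos=[10, 500_000, 999_999])
    bp = assign_blocks(gm, 4_000_000)
    assert bp.n_blocks == 1


def test_filter_missing_group_level():
    gm = make_gm([[-1, -1, 0, 1],   # popA all missing -> drop
                  [-1, 1, 0, -1],   # one of two called in each -> keep
                  [0, 0, -1, -1]],  # popB all missing -> drop
                 ["A", "A", "B", "B"])
    mask = filter_missing(gm, ["A", "B"])
    assert mask.keep.tolist() == [False, True, False]
    # stricter per-individual variant
    strict = filter_missing(gm, ["A", "B"], per_individual=True)
    assert strict.keep.tolist() == [False, False, False]
    # empty population list keeps everything
    assert filter_missing(gm, []).keep.all()


def test_filter_missing_unknown_population():
    gm = make_gm([[0]], ["a"])
    with pytest.raises(KeyError):
        filter_missing(gm, ["zz"])


def test_load_vcf_biallelic_snps(tmp_path):
    from ascbias.genotypes import load_vcf

    vcf = tmp_path / "toy.vcf"
    vcf.write_text("\n".join([
        "##fileformat=VCFv4.2",
        '##contig=<ID=1,length=1000>',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
        "1\t10\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1/1",
        "1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t0/0\t./.",
        "1\t30\t.\tG\tGT\t.\tPASS\t.\tGT\t0/1\t0/0",  # indel: skipped
    ]) + "\n")
    gm = load_vcf(vcf, populations={"s1": "p1", "s2": "p2"})
    assert gm.n_sites == 2
    assert gm.calls[0].tolist() == [1, 2]
    assert gm.calls[1].tolist() == [0, -1]
    assert gm.individuals["population"].tolist() == ["p1", "p2"]
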