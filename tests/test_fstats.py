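import itertools

import numpy as np
import pytest

from ascbias.fstats import (daf_spectrum, f2_blocks, f2_stat, f3, f4, f4_naive,
                            fst, jackknife, jackknife_cov)
from ascbias.genotypes import assign_blocks

from conftest import make_gm


def _freq_matrix(rng, n_sites, pops, n_ind=5):
    """Random complete-data matrix over several populations."""
    labels = [p for p in pops for _ in range(n_ind)]
    calls = rng.integers(0, 3, size=(n_sites, len(labels))).astype(np.int8)
    return make_gm(calls, labels)


def test_f2_hand_example():
    """One site: pA=0.5 on 4 chromosomes, pB=0 -> f2 = 1/4 - (1/4)/3 = 1/6."""
    gm = make_gm([[1, 1, 0, 0]], ["A", "A", "B", "B"])
    f2b = f2_blocks(gm, None, ["A", "B"], assign_blocks(gm))
    assert f2b.values[0, 0] == pytest.approx(0.25 - 0.25 / 3)


def test_f2_fixation_limit():
    n = 200
    gm = make_gm([[2] * n + [0] * n], ["A"] * n + ["B"] * n)
    f2b = f2_blocks(gm, None, ["A", "B"])
    assert f2b.values[0, 0] == pytest.approx(1.0, abs=1e-12)


def test_f4_identities(rng):
    """f4 symmetry/antisymmetry/additivity identities hold exactly."""
    gm = _freq_matrix(rng, 400, ["A", "B", "C", "D", "E"])
    # two chromosomes so the jackknife is defined
    gm.sites.loc[200:, "chrom"] = "2"
    f2b = f2_blocks(gm, None, list("ABCDE"), assign_blocks(gm))

    fabcd = f4(f2b, "A", "B", "C", "D")
    assert f4(f2b, "B", "A", "C", "D").estimate == pytest.approx(
        -fabcd.estimate, abs=1e-14)
    assert f4(f2b, "A", "B", "D", "C").estimate == pytest.approx(
        -fabcd.estimate, abs=1e-14)
    # f4(A,B;A,B) = f2(A,B)
    assert f4(f2b, "A", "B", "A", "B").estimate == pytest.approx(
        f2_stat(f2b, "A", "B").estimate, abs=1e-14)
    # identical first pair -> exactly 0
    assert f4(f2b, "A", "A", "C", "D").estimate == 0.0
    # additivity in the last slot: f4(A,B;C,D) + f4(A,B;D,E) = f4(A,B;C,E)
    lhs = fabcd.block_values + f4(f2b, "A", "B", "D", "E").block_values
    rhs = f4(f2b, "A", "B", "C", "E").block_values
    np.testing.assert_allclose(lhs, rhs, atol=1e-12)
    # f3 is the f4 specialisation
    assert f3(f2b, "A", "B", "C").estimate == pytest.approx(
        f4(f2b, "A", "B", "A", "C").estimate, abs=1e-14)


def test_f4_equals_naive_oracle(rng):
    """f2-combination equals the direct per-site (pA-pB)(pC-pD) average.

    On complete data the bias-correction terms cancel in the f4 combination,
    so the two routes agree to numerical precision.
    """
    gm = _freq_matrix(rng, 300, ["A", "B", "C", "D"])
    f2b = f2_blocks(gm, None, list("ABCD"), assign_blocks(gm))
    w = f2b.weights / f2b.weights.sum()
    for quad in [("A", "B", "C", "D"), ("A", "C", "B", "D")]:
        combo = float(w @ f2b.block_f4(*quad))
        naive = f4_naive(gm, None, *quad)
        assert combo == pytest.approx(naive, abs=1e-12)


def test_jackknife_constant_blocks():
    est, se, z = jackknife(np.full(10, 3.7), np.full(10, 100.0))
    assert est == pytest.approx(3.7)
    assert se == pytest.approx(0.0, abs=1e-12)


def test_jackknife_single_block_error():
    with pytest.raises(ValueError):
        jackknife(np.array([1.0]), np.array([5.0]))


def test_jackknife_se_matches_iid_oracle(rng):
    """Equal-weight jackknife SE tracks s/sqrt(m) for iid block values."""
    m = 30
    ratios = []
    for _ in range(100):
        vals = rng.normal(0, 1, m)
        _, se, _ = jackknife(vals, np.full(m, 50.0))
        ratios.append(se / (vals.std(ddof=1) / np.sqrt(m)))
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)


def test_jackknife_cov_diagonal_is_variance(rng):
    vals = rng.normal(0, 1, size=(25, 3))
    w = np.full(25, 10.0)
    cov = jackknife_cov(vals, w)
    for k in range(3):
        _, se, _ = jackknife(vals[:, k], w)
        assert cov[k, k] == pytest.approx(se ** 2, rel=1e-9)


def test_fst_identical_and_fixed():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 3, size=(200, 20)).astype(np.int8)
    gm = make_gm(np.hstack([calls, calls]), ["A"] * 20 + ["B"] * 20)
    gm.sites.loc[100:, "chrom"] = "2"
    res = fst(gm, None, "A", "B", assign_blocks(gm))
    # duplicated samples: unbiased numerator is exactly -den/(2n-1)
    assert res.estimate == pytest.approx(-1 / 39, abs=1e-12)

    n = 100
    gm2 = make_gm([[2] * n + [0] * n, [0] * n + [2] * n],
                  ["A"] * n + ["B"] * n, chrom=["1", "2"])
    res2 = fst(gm2, None, "A", "B", assign_blocks(gm2))
    assert res2.estimate == pytest.approx(1.0, abs=0.05)


def test_fst_subsamples_of_one_deme(rng):
    """Pooling arbitrary subsamples of one panmictic deme gives FST ~ 0."""
    calls = rng.binomial(2, rng.uniform(0.05, 0.95, 400)[:, None],
                         size=(400, 40)).astype(np.int8)
    gm = make_gm(calls, ["A"] * 20 + ["B"] * 20)
    gm.sites.loc[200:, "chrom"] = "2"
    res = fst(gm, None, "A", "B", assign_blocks(gm))
    assert abs(res.z) < 3


def test_daf_spectrum_projection():
    n = 10  # 20 chromosomes
    fixed_anc = np.zeros((5, n), dtype=np.int8)
    gm = make_gm(fixed_anc, ["p"] * n)
    spec = daf_spectrum(gm, None, "p", n_chrom=20)
    assert spec.proportions[0] == pytest.approx(1.0)

    # frequency-1/2 site projected to 2 chromosomes: ~ (1/4, 1/2, 1/4)
    half = np.array([[1] * n], dtype=np.int8)
    gm2 = make_gm(half, ["p"] * n)
    spec2 = daf_spectrum(gm2, None, "p", n_chrom=2)
    # exact hypergeometric (20 chromosomes, 10 derived): binomial-limit ~(1/4,1/2,1/4)
    assert spec2.proportions == pytest.approx([9 / 38, 10 / 19, 9 / 38], abs=1e-9)

    # projection to the full sample size reproduces the raw counts
    rng = np.random.default_rng(1)
    calls = rng.integers(0, 3, size=(50, n)).astype(np.int8)
    gm3 = make_gm(calls, ["p"] * n)
    spec3 = daf_spectrum(gm3, None, "p", n_chrom=2 * n)
    raw = np.bincount(calls.sum(axis=1), minlength=2 * n + 1) / 50
    np.testing.assert_allclose(spec3.proportions, raw, atol=1e-12)


def test_daf_spectrum_requires_enough_chromosomes():
    gm = make_gm([[1, 1]], ["p", "p"])
    with pytest.raises(ValueError):
        daf_spectrum(gm, None, "p", n_chrom=20)
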