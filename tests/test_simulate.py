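import numpy as np
import pytest

from ascbias.fstats import f2_blocks, f2_stat
from ascbias.genotypes import MISSING, assign_blocks
from ascbias.simulate import (GenomeSpec, case_study_reduced_graph,
                              load_params_file, preset_case_study,
                              preset_random_graph, preset_simple_tree,
                              retain_by_fst, simulate_model)

TINY = GenomeSpec(n_chromosomes=2, chromosome_length=2e5)


@pytest.fixture(scope="module")
def panmictic_sim():
    """One deme labelled as two populations: the null world for FST/f4."""
    from ascbias.simulate import DemographicModel
    model = DemographicModel(
        populations={"X": 10_000.0, "Y": 10_000.0, "XY": 10_000.0},
        splits=[(1.0, ["X", "Y"], "XY")],  # split yesterday: effectively one deme
        samples=[("X", 0.0, 8), ("Y", 0.0, 8)],
        genome=GenomeSpec(n_chromosomes=2, chromosome_length=5e5),
    )
    return simulate_model(model, seed=99)


def test_determinism():
    model = preset_simple_tree(100, genome=TINY)
    a = simulate_model(model, seed=11).genotypes
    b = simulate_model(preset_simple_tree(100, genome=TINY), seed=11).genotypes
    np.testing.assert_array_equal(a.calls, b.calls)
    assert a.sites.equals(b.sites)


def test_matrix_contract():
    sim = simulate_model(preset_simple_tree(100, genome=TINY), seed=2)
    gm = sim.genotypes
    assert gm.calls.min() >= 0  # simulated data are complete
    assert gm.calls.max() <= 2
    assert not np.any(gm.calls == MISSING)
    assert gm.individuals["population"].value_counts()["A"] == 25
    assert gm.individuals["population"].value_counts()["O"] == 10
    assert set(gm.sites["chrom"]) == {"chr01", "chr02"}


def test_pairwise_diversity_matches_neutral_expectation():
    """Panmictic deme: mean pairwise diversity per bp ~ 4*Ne*mu.

    Closed-form neutral expectation checked within 3 Monte-Carlo SE over
    replicates.
    """
    from ascbias.simulate import DemographicModel
    ne, mu, L = 10_000.0, 1.25e-8, 1e6
    pis = []
    for seed in range(1, 13):
        model = DemographicModel(
            populations={"P": ne},
            samples=[("P", 0.0, 5)],
            genome=GenomeSpec(n_chromosomes=1, chromosome_length=L),
        )
        gm = simulate_model(model, seed=seed).genotypes
        d, n = gm.allele_counts("P")
        # unbiased per-site heterozygosity, summed over segregating sites
        pi = np.sum(2 * d * (n - d) / (n * (n - 1))) / L
        pis.append(pi)
    pis = np.asarray(pis)
    expect = 4 * ne * mu
    mc_se = pis.std(ddof=1) / np.sqrt(len(pis))
    assert abs(pis.mean() - expect) < 3 * mc_se + 0.02 * expect


def test_null_fst_and_f4(panmictic_sim):
    """Subsamples of one deme: FST ~ 0 and f4(X,Y;X,Y) tiny."""
    gm = panmictic_sim.genotypes
    blocks = assign_blocks(gm, 250_000)
    from ascbias.fstats import fst
    res = fst(gm, None, "X", "Y", blocks)
    assert abs(res.z) < 4
    f2b = f2_blocks(gm, None, ["X", "Y"], blocks)
    f2xy = f2_stat(f2b, "X", "Y")
    assert abs(f2xy.z) < 4


def test_retain_by_fst(panmictic_sim):
    assert retain_by_fst(panmictic_sim, threshold=0.15)   # identical demes
    assert retain_by_fst(panmictic_sim, threshold=1.0)


def test_case_study_structure():
    m2 = preset_case_study(0.02, genome=TINY)
    g = m2.true_graph
    assert g.n_admixture == 1
    assert sorted(g.leaves) == ["African1", "African2", "Chimp", "Denisovan",
                                "Neanderthal1", "Neanderthal2", "NonAfrican1",
                                "NonAfrican2"]
    assert ("NEAPROXY" in dict(m2.populations))
    assert m2.pulses[0][3] == pytest.approx(0.02)
    # archaic sampling dates
    t = {pop: time for pop, time, n in m2.samples}
    assert t["Neanderthal1"] == 3_790
    assert t["Neanderthal2"] == 1_700
    assert t["Denisovan"] == 1_700

    m0 = preset_case_study(0.0, genome=TINY)
    assert m0.true_graph.n_admixture == 0
    assert not m0.pulses


def test_case_study_params_file(tmp_path):
    p = tmp_path / "params.txt"
    p.write_text("t_chimp_split = 200000\nne_afr = 30000  # bigger Africans\n")
    m = preset_case_study(0.02, params=p, genome=TINY)
    assert m.descriptor["params"]["t_chimp_split"] == 200_000
    assert m.populations["African1"] == 30_000
    assert load_params_file(p)["ne_afr"] == 30_000


def test_case_study_missing_params():
    with pytest.raises(ValueError):
        # an explicit params dict replacing the defaults entirely must be complete
        import ascbias.simulate as sim
        defaults = sim.CASE_STUDY_DEFAULTS
        incomplete = {k: v for k, v in list(defaults.items())[:3]}
        sim.CASE_STUDY_DEFAULTS, backup = {}, defaults
        try:
            preset_case_study(0.02, params=incomplete)
        finally:
            sim.CASE_STUDY_DEFAULTS = backup


def test_reduced_graph_shape():
    g = case_study_reduced_graph("Denisovan", 0.02)
    assert g.n_admixture == 1
    assert "Denisovan" in g.leaves and "Neanderthal1" not in g.leaves
    g0 = case_study_reduced_graph("Denisovan", 0.0)
    assert g0.n_admixture == 0


def test_random_graph_parameter_ranges():
    """Contract checks over many topology draws (no genetic simulation)."""
    gaps_ok, alphas = [], []
    for seed in range(60):
        n_pops = 9 if seed % 2 else 10
        n_admix = 4 if seed % 3 else 5
        m = preset_random_graph(n_pops, n_admix, seed=seed, genome=TINY)
        # outgroup divergence is always exactly 40,000 generations
        og_split = [t for t, derived, anc in m.splits if "OUTGROUP" in derived]
        assert og_split == [40_000.0]
        for t, dest, src, a in m.pulses:
            alphas.append(a)
        assert len(m.pulses) == n_admix
        # tips + outgroup sampled with 10 diploids each
        assert all(n == 10 for _, _, n in m.samples)
        assert len(m.samples) == (n_pops - 1) + 3  # tips + OG + root + non-OG root
        # split times fall on levels separated by 1,500-8,000 generations
        times = sorted({t for t, _, _ in m.splits}, reverse=True)
        gaps = np.diff(-np.asarray(times))
        gaps_ok.extend(g <= 8_000.001 for g in gaps if g > 0)
        assert m.true_graph.n_admixture == n_admix
        assert len(m.true_graph.leaves) == n_pops
    alphas = np.asarray(alphas)
    assert alphas.min() >= 0.10 and alphas.max() <= 0.40
    assert all(gaps_ok)


def test_simple_tree_contract():
    m = preset_simple_tree(10_000, genome=TINY)
    assert dict((p, t) for p, t, n in [(s[0], s[1], s[2]) for s in m.samples])
    n_by_pop = {p: n for p, t, n in m.samples}
    assert n_by_pop == {"A": 10, "B": 25, "C": 25, "O": 10}
    assert m.populations["A"] == pytest.approx(10.0)  # 100,000 / 10,000
    split_times = {anc: t for t, derived, anc in m.splits}
    assert split_times["AB"] == 1_999
    assert split_times["ROOT4"] == 4_000
    with pytest.raises(ValueError):
        preset_simple_tree(7)
    control = preset_simple_tree(1, genome=TINY)
    assert control.populations["A"] == 100_000
    assert {p: n for p, t, n in control.samples}["A"] == 25


def test_boundary_multichromosome_device():
    """The log(2) boundary-rate device also yields per-chromosome blocks."""
    model = preset_simple_tree(100, genome=GenomeSpec(2, 1e5))
    model.multi_chromosome = "boundary"
    sim = simulate_model(model, seed=4)
    assert set(sim.genotypes.sites["chrom"]) <= {"chr01", "chr02"}
    assert sim.genotypes.sites["pos"].max() <= 1e5
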