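"""Coalescent simulation of demographic scenarios with known truth.

Three scenario families are provided, mirroring the study designs this
package quantifies ascertainment bias on:

* :func:`preset_case_study` — a fixed history of one ape outgroup, three
  archaic lineages (two Neanderthals, one Denisovan) and four modern human
  groups (two African, two non-African) with an out-of-Africa bottleneck and
  optional ~2% Neanderthal-to-non-African gene flow through an unsampled
  proxy lineage.  Shipped parameter values are a documented, calibrated
  stand-in reproducing the qualitative FST structure of human/archaic data;
  a key=value parameter file can override any of them.
* :func:`preset_random_graph` — random admixture graphs with 8-9 tip
  populations plus a deep outgroup (divergence 40,000 generations, Ne
  100,000 or 1,000), 4-5 pulse admixture events with proportions in
  [0.10, 0.40], demographic events tied to topological levels separated by
  1,500-8,000 generations, and ancient samples at the simulation root and
  the root of the non-outgroup populations.
* :func:`preset_simple_tree` — a four-taxon clean tree (O,(C,(A,B))) of
  depth 4,000 generations, Ne 100,000, with a post-split bottleneck in A,
  used for f4 cladality null tests.

Genetic data are generated with msprime (binary mutation model, flat
recombination 2e-8 and mutation 1.25e-8 per bp per generation) and returned
as a polarized :class:`~ascbias.genotypes.GenotypeMatrix` together with the
true :class:`~ascbias.graphs.AdmixtureGraph`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from .fstats import fst_matrix
from .genotypes import ATGC, TRANSITION, TRANSVERSION_OTHER, GenotypeMatrix
from .graphs import AdmixtureGraph

#: flat per-bp per-generation rates used throughout
RECOMBINATION_RATE = 2e-8
MUTATION_RATE = 1.25e-8

#: boundary recombination rate of the multi-chromosome device
BOUNDARY_RATE = float(np.log(2))

_MCLASS_CHOICES = [("A", "G", TRANSITION), ("C", "T", TRANSITION),
                   ("A", "T", ATGC), ("C", "G", ATGC),
                   ("A", "C", TRANSVERSION_OTHER), ("G", "T", TRANSVERSION_OTHER)]
# transition:transversion ~ 2:1; among transversions the A/T+G/C half
_MCLASS_PROBS = [1 / 3, 1 / 3, 1 / 12, 1 / 12, 1 / 12, 1 / 12]


@dataclass
class GenomeSpec:
    n_chromosomes: int = 3
    chromosome_length: float = 100e6
    recombination_rate: float = RECOMBINATION_RATE
    mutation_rate: float = MUTATION_RATE


@dataclass
class DemographicModel:
    """Declarative demographic model compiled to an msprime Demography.

    ``populations``: name -> constant diploid Ne along that edge.
    ``splits``: (time, [derived...], ancestral), forward-time divergences.
    ``pulses``: (time, dest, source, proportion): at ``time`` generations ago
    the ``dest`` population received a fraction ``proportion`` of its
    ancestry from ``source`` (forward-time wording).
    ``size_changes``: (time, population, new_size) steps back in time.
    ``samples``: (population, time, n_diploids).
    """

    populations: dict[str, float]
    splits: list[tuple] = field(default_factory=list)
    pulses: list[tuple] = field(default_factory=list)
    size_changes: list[tuple] = field(default_factory=list)
    samples: list[tuple] = field(default_factory=list)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    true_graph: AdmixtureGraph | None = None
    internal_sample_pops: list[str] = field(default_factory=list)
    dtwf_generations: int = 25
    multi_chromosome: str = "independent"  # or "boundary"
    descriptor: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.samples:
            raise ValueError("model has no samples")
        for t, derived, anc in self.splits:
            if t <= 0:
                raise ValueError("split times must be positive")
            for d in derived:
                if d not in self.populations:
                    raise ValueError(f"unknown population {d}")
            if anc not in self.populations:
                raise ValueError(f"unknown population {anc}")
        for t, dest, src, a in self.pulses:
            if not 0 < a < 1:
                raise ValueError(f"pulse proportion {a} outside (0, 1)")

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for name, ne in self.populations.items():
            dem.add_population(name=name, initial_size=ne)
        events = []
        for t, derived, anc in self.splits:
            events.append((t, "split", (derived, anc)))
        for t, dest, src, a in self.pulses:
            events.append((t, "pulse", (dest, src, a)))
        for t, pop, size in self.size_changes:
            events.append((t, "size", (pop, size)))
        for t, kind, args in sorted(events, key=lambda e: e[0]):
            if kind == "split":
                dem.add_population_split(time=t, derived=list(args[0]),
                                         ancestral=args[1])
            elif kind == "pulse":
                dest, src, a = args
                dem.add_mass_migration(time=t, source=dest, dest=src,
                                       proportion=a)
            else:
                pop, size = args
                dem.add_population_parameters_change(time=t, population=pop,
                                                     initial_size=size)
        dem.sort_events()
        return dem


@dataclass
class SimulationResult:
    """Genotypes plus the truth needed for downstream evaluation."""

    genotypes: GenotypeMatrix
    true_graph: AdmixtureGraph | None
    seed: int
    scenario: dict
    internal_sample_pops: list[str] = field(default_factory=list)

    @property
    def tip_populations(self) -> list[str]:
        internal = set(self.internal_sample_pops)
        return [p for p in self.genotypes.populations if p not in internal]


def simulate_model(model: DemographicModel, seed: int) -> SimulationResult:
    """Simulate a DemographicModel into a polarized genotype matrix.

    Chromosomes are independent by default (separate coalescent replicates
    with sub-seeds derived from ``seed``); the single-simulation device with
    a log(2) per-bp boundary recombination rate is available via
    ``model.multi_chromosome = "boundary"``.  The first ``dtwf_generations``
    generations run under the discrete-time Wright-Fisher model, the rest
    under the standard coalescent.
    """
    model.validate()
    dem = model.to_demography()
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(1, 2**31 - 10, size=2 * model.genome.n_chromosomes + 1)

    sample_sets = [msprime.SampleSet(n, population=pop, time=t)
                   for pop, t, n in model.samples]
    sim_model = ([msprime.DiscreteTimeWrightFisher(duration=model.dtwf_generations),
                  msprime.StandardCoalescent()]
                 if model.dtwf_generations else "hudson")

    g = model.genome
    chrom_sims = []
    if model.multi_chromosome == "boundary" and g.n_chromosomes > 1:
        L = g.chromosome_length
        positions, rates = [0.0], []
        for i in range(g.n_chromosomes):
            if i:
                positions.append(positions[-1] + 1)
                rates.append(BOUNDARY_RATE)
            positions.append(positions[-1] + L)
            rates.append(g.recombination_rate)
        rate_map = msprime.RateMap(position=positions, rate=rates)
        ts = msprime.sim_ancestry(samples=sample_sets, demography=dem,
                                  recombination_rate=rate_map,
                                  model=sim_model,
                                  random_seed=int(sub_seeds[0]))
        mts = msprime.sim_mutations(ts, rate=g.mutation_rate,
                                    model=msprime.BinaryMutationModel(),
                                    random_seed=int(sub_seeds[1]))
        bounds = [(i * (L + 1), i * (L + 1) + L) for i in range(g.n_chromosomes)]
        chrom_sims = [(mts, bounds)]
    else:
        for i in range(g.n_chromosomes):
            ts = msprime.sim_ancestry(samples=sample_sets, demography=dem,
                                      sequence_length=g.chromosome_length,
                                      recombination_rate=g.recombination_rate,
                                      model=sim_model,
                                      random_seed=int(sub_seeds[2 * i]))
            mts = msprime.sim_mutations(ts, rate=g.mutation_rate,
                                        model=msprime.BinaryMutationModel(),
                                        random_seed=int(sub_seeds[2 * i + 1]))
            chrom_sims.append((mts, [(0.0, g.chromosome_length)]))

    gm = _tree_sequences_to_matrix(chrom_sims, model, int(sub_seeds[-1]))
    return SimulationResult(genotypes=gm, true_graph=model.true_graph,
                            seed=seed, scenario=dict(model.descriptor),
                            internal_sample_pops=list(model.internal_sample_pops))


def _tree_sequences_to_matrix(chrom_sims, model: DemographicModel,
                              allele_seed: int) -> GenotypeMatrix:
    first_ts = chrom_sims[0][0]
    pop_names = {p.id: (p.metadata.get("name", str(p.id))
                        if isinstance(p.metadata, dict) else str(p.id))
                 for p in first_ts.populations()}
    ind_ids, ind_pops, ind_nodes = [], [], []
    counters: dict[str, int] = {}
    for ind in first_ts.individuals():
        node_pops = {first_ts.node(n).population for n in ind.nodes}
        pop = pop_names[node_pops.pop()]
        counters[pop] = counters.get(pop, 0) + 1
        ind_ids.append(f"{pop}_{counters[pop]}")
        ind_pops.append(pop)
        ind_nodes.append(list(ind.nodes))

    chroms, poss, dosage_rows = [], [], []
    chrom_no = 0
    for mts, bounds in chrom_sims:
        G = mts.genotype_matrix()  # (sites, haplotypes), alleles 0/1
        G = (G > 0).astype(np.int8)
        site_pos = np.array([s.position for s in mts.sites()])
        for lo, hi in bounds:
            chrom_no += 1
            inside = (site_pos >= lo) & (site_pos < hi)
            sub = G[inside]
            pos = (site_pos[inside] - lo).astype(np.int64) + 1
            # collapse duplicate discrete positions (rare multi-hits)
            keep = np.concatenate([[True], np.diff(pos) > 0])
            sub, pos = sub[keep], pos[keep]
            dos = np.zeros((sub.shape[0], len(ind_nodes)), dtype=np.int8)
            for j, nodes in enumerate(ind_nodes):
                dos[:, j] = sub[:, nodes].sum(axis=1)
            chroms.append(np.full(len(pos), f"chr{chrom_no:02d}"))
            poss.append(pos)
            dosage_rows.append(dos)

    chrom_arr = np.concatenate(chroms) if chroms else np.empty(0, dtype=object)
    pos_arr = np.concatenate(poss) if poss else np.empty(0, dtype=np.int64)
    calls = np.vstack(dosage_rows) if dosage_rows else np.empty((0, len(ind_ids)), np.int8)

    # cosmetic nucleotide labels for the binary mutation model, so that
    # mutation-class ascertainment schemes are exercisable on simulated data
    rng = np.random.default_rng(allele_seed)
    choice = rng.choice(len(_MCLASS_CHOICES), size=len(pos_arr), p=_MCLASS_PROBS)
    swap = rng.random(len(pos_arr)) < 0.5
    anc = np.array([_MCLASS_CHOICES[c][0] for c in choice])
    der = np.array([_MCLASS_CHOICES[c][1] for c in choice])
    anc2 = np.where(swap, der, anc)
    der2 = np.where(swap, anc, der)
    mclass = np.array([_MCLASS_CHOICES[c][2] for c in choice])

    sites = pd.DataFrame({"chrom": chrom_arr, "pos": pos_arr,
                          "anc": anc2, "der": der2, "mclass": mclass})
    individuals = pd.DataFrame({"id": ind_ids, "population": ind_pops})
    return GenotypeMatrix(sites=sites, individuals=individuals, calls=calls)


def retain_by_fst(result: SimulationResult, threshold: float = 0.15) -> bool:
    """Keep a random simulation iff some pair of tip populations has FST
    below ``threshold`` (the range characteristic of human-scale data)."""
    pops = result.tip_populations
    if len(pops) < 2:
        raise ValueError("need at least two sampled populations")
    m = fst_matrix(result.genotypes, None, pops)
    vals = m.to_numpy()[np.triu_indices(len(pops), k=1)]
    return bool(np.min(vals) < threshold)


# ---------------------------------------------------------------------------
# case study preset
# ---------------------------------------------------------------------------

#: calibrated stand-in parameters (times in generations, sizes in diploids);
#: chosen to reproduce the qualitative FST structure among modern humans,
#: archaic humans and an ape outgroup.  Override any entry via params file.
CASE_STUDY_DEFAULTS = {
    "t_chimp_split": 240_000.0,
    "t_archaic_split": 18_000.0,
    "t_den_nea_split": 12_000.0,
    "t_nea1_nea2_split": 4_500.0,
    "t_proxy_split": 3_200.0,
    "t_afr1_split": 4_000.0,
    "t_ooa_split": 2_800.0,
    "t_nonafr_split": 1_400.0,
    "t_flow": 2_000.0,
    "t_nea1_sample": 3_790.0,
    "t_nea2_sample": 1_700.0,
    "t_den_sample": 1_700.0,
    "ne_root": 15_000.0,
    "ne_chimp": 25_000.0,
    "ne_amh_anc": 15_000.0,
    "ne_archaic_anc": 5_000.0,
    "ne_nea_anc": 2_500.0,
    "ne_nea1": 2_000.0,
    "ne_nea2": 2_000.0,
    "ne_den": 2_500.0,
    "ne_proxy": 2_000.0,
    "ne_afr": 20_000.0,
    "ne_ooa_bottleneck": 1_500.0,
    "ne_nonafr": 10_000.0,
}

_CASE_STUDY_REQUIRED = tuple(CASE_STUDY_DEFAULTS)


def load_params_file(path) -> dict[str, float]:
    """key = value parameter file (one entry per line, '#' comments)."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        out[key.strip()] = float(val)
    return out


def preset_case_study(neanderthal_flow: float = 0.02,
                      params: dict | str | Path | None = None,
                      genome: GenomeSpec | None = None) -> DemographicModel:
    """Case-study history: ape + three archaics + four modern human groups.

    ``neanderthal_flow`` is the proportion of Neanderthal-derived ancestry
    pulsed into the non-African ancestor (0 disables the event and removes
    the admixture edge from the true graph).
    """
    if isinstance(params, (str, Path)):
        params = load_params_file(params)
    p = dict(CASE_STUDY_DEFAULTS)
    if params is not None:
        p.update(params)
    missing = [k for k in _CASE_STUDY_REQUIRED if k not in p]
    if missing:
        raise ValueError(f"missing required parameters: {missing}")

    pops = {
        "ROOT": p["ne_root"], "Chimp": p["ne_chimp"],
        "AMH_ARCH": p["ne_root"], "ARCHAIC": p["ne_archaic_anc"],
        "NEA": p["ne_nea_anc"], "Neanderthal1": p["ne_nea1"],
        "Neanderthal2": p["ne_nea2"], "Denisovan": p["ne_den"],
        "NEA2PROXY": p["ne_nea_anc"], "NEAPROXY": p["ne_proxy"],
        "AMH": p["ne_amh_anc"], "African1": p["ne_afr"],
        "AFR2_NONAFR": p["ne_afr"], "African2": p["ne_afr"],
        "NONAFR": p["ne_ooa_bottleneck"],
        "NonAfrican1": p["ne_nonafr"], "NonAfrican2": p["ne_nonafr"],
    }
    splits = [
        (p["t_chimp_split"], ["Chimp", "AMH_ARCH"], "ROOT"),
        (p["t_archaic_split"], ["ARCHAIC", "AMH"], "AMH_ARCH"),
        (p["t_den_nea_split"], ["Denisovan", "NEA"], "ARCHAIC"),
        (p["t_nea1_nea2_split"], ["Neanderthal1", "NEA2PROXY"], "NEA"),
        (p["t_proxy_split"], ["Neanderthal2", "NEAPROXY"], "NEA2PROXY"),
        (p["t_afr1_split"], ["African1", "AFR2_NONAFR"], "AMH"),
        (p["t_ooa_split"], ["African2", "NONAFR"], "AFR2_NONAFR"),
        (p["t_nonafr_split"], ["NonAfrican1", "NonAfrican2"], "NONAFR"),
    ]
    pulses = []
    if neanderthal_flow:
        pulses.append((p["t_flow"], "NONAFR", "NEAPROXY", neanderthal_flow))
    samples = [
        ("Chimp", 0.0, 1),
        ("Neanderthal1", p["t_nea1_sample"], 1),
        ("Neanderthal2", p["t_nea2_sample"], 1),
        ("Denisovan", p["t_den_sample"], 1),
        ("African1", 0.0, 10), ("African2", 0.0, 10),
        ("NonAfrican1", 0.0, 10), ("NonAfrican2", 0.0, 10),
    ]

    edges = [
        ("R", "Chimp"), ("R", "amh_arch"),
        ("amh_arch", "archaic"), ("amh_arch", "amh"),
        ("archaic", "Denisovan"), ("archaic", "nea"),
        ("nea", "Neanderthal1"), ("nea", "neaproxy"),
        ("neaproxy", "Neanderthal2"),
        ("amh", "African1"), ("amh", "afr2_nonafr"),
        ("afr2_nonafr", "African2"),
        ("nonafr", "NonAfrican1"), ("nonafr", "NonAfrican2"),
    ]
    if neanderthal_flow:
        # admixture node above the shared non-African bottleneck drift
        edges += [("afr2_nonafr", "mixna"), ("neaproxy", "mixna"),
                  ("mixna", "nonafr")]
    else:
        edges += [("afr2_nonafr", "nonafr")]
    graph = AdmixtureGraph(edges)

    return DemographicModel(
        populations=pops, splits=splits, pulses=pulses, samples=samples,
        genome=genome or GenomeSpec(n_chromosomes=3, chromosome_length=100e6),
        true_graph=graph,
        descriptor={"scenario": "case-study",
                    "neanderthal_flow": neanderthal_flow,
                    "params": p},
    )


def case_study_reduced_graph(archaic: str,
                             neanderthal_flow: float = 0.02) -> AdmixtureGraph:
    """Correct single-archaic reduction of the case-study graph.

    The reduced graph keeps the ape outgroup, one archaic lineage and the
    four modern human groups; with gene flow, the non-African ancestor is
    admixed between the modern lineage and a ghost branch off the archaic
    terminal edge.
    """
    edges = [
        ("R", "Chimp"), ("R", "amh_arch"),
        ("amh_arch", "archghost"), ("archghost", archaic),
        ("amh_arch", "amh"),
        ("amh", "African1"), ("amh", "afr2_nonafr"),
        ("afr2_nonafr", "African2"),
        ("nonafr", "NonAfrican1"), ("nonafr", "NonAfrican2"),
    ]
    if neanderthal_flow:
        edges += [("afr2_nonafr", "mixna"), ("archghost", "mixna"),
                  ("mixna", "nonafr")]
    else:
        edges.append(("afr2_nonafr", "nonafr"))
    return AdmixtureGraph(edges)


# ---------------------------------------------------------------------------
# random admixture graphs
# ---------------------------------------------------------------------------

def preset_random_graph(n_pops: int, n_admix: int, seed: int,
                        outgroup_ne: float = 100_000.0,
                        genome: GenomeSpec | None = None) -> DemographicModel:
    """Random admixture-graph history with a deep outgroup.

    ``n_pops`` counts sampled tip populations *including* the outgroup (9 or
    10 in the study design); ``n_admix`` pulse events (4 or 5).  The
    outgroup diverges at exactly 40,000 generations; other demographic
    events sit on topological levels separated by gaps drawn uniformly from
    [1,500, 8,000] generations; admixture proportions are uniform in
    [0.10, 0.40]; non-outgroup Ne uniform in [2,000, 40,000].  Ten diploids
    are sampled per tip at its terminal date, at the simulation root, and at
    the root of the non-outgroup populations.
    """
    rng = np.random.default_rng(seed)
    m = n_pops - 1  # non-outgroup tips
    tips = [f"P{i+1}" for i in range(m)]

    # random rooted binary tree over the tips: sequential random attachment
    nodes = {"N0": {"parent": None, "children": []}}
    counter = 1

    # start with two tips under the non-outgroup root N0
    nodes[tips[0]] = {"parent": "N0", "children": []}
    nodes[tips[1]] = {"parent": "N0", "children": []}
    nodes["N0"]["children"] = [tips[0], tips[1]]
    edges = [("N0", tips[0]), ("N0", tips[1])]
    for tip in tips[2:]:
        i = rng.integers(len(edges))
        p, c = edges[i]
        new = f"N{counter}"; counter += 1
        edges[i] = (p, new)
        edges += [(new, c), (new, tip)]
        nodes[new] = {"parent": p, "children": [c, tip]}
        nodes[c]["parent"] = new
        nodes[tip] = {"parent": new, "children": []}
        nodes[p]["children"] = [new if x == c else x for x in nodes[p]["children"]]

    # topological levels and tied event times
    depth = {"N0": 0}
    order = ["N0"]
    while order:
        n = order.pop()
        for c in nodes[n]["children"]:
            depth[c] = depth[n] + 1
            order.append(c)
    max_depth = max(depth.values())
    level_time = {0: 40_000.0 - float(rng.uniform(1_500, 8_000))}
    for d in range(1, max_depth + 1):
        t = level_time[d - 1] - float(rng.uniform(1_500, 8_000))
        level_time[d] = max(t, 0.0)
    node_time = {n: (0.0 if (not nodes[n]["children"] and depth[n] == max_depth)
                     else level_time[depth[n]]) for n in nodes}
    # guarantee strictly decreasing times parent -> child
    def fix(n):
        for c in nodes[n]["children"]:
            if node_time[c] >= node_time[n]:
                node_time[c] = 0.0 if not nodes[c]["children"] else node_time[n] / 2
            fix(c)
    fix("N0")

    # admixture pulses between branches with overlapping time intervals
    def interval(n):
        p = nodes[n]["parent"]
        top = 40_000.0 if p is None else node_time[p]
        return node_time[n], top

    pulses = []
    pulse_edges = []
    branch_list = [n for n in nodes if nodes[n]["parent"] is not None or n == "N0"]
    attempts = 0
    while len(pulses) < n_admix and attempts < 4000:
        attempts += 1
        dest, src = (str(x) for x in rng.choice(branch_list, size=2, replace=False))
        lo = max(interval(dest)[0], interval(src)[0])
        hi = min(interval(dest)[1], interval(src)[1])
        if hi - lo < 1.0:
            continue
        t = float(rng.uniform(lo, hi))
        a = float(rng.uniform(0.10, 0.40))
        pulses.append((t, dest, src, a))
        pulse_edges.append((dest, src, t, a))
    if len(pulses) < n_admix:
        raise RuntimeError("could not place the requested admixture events")

    ne = {n: float(rng.uniform(2_000, 40_000)) for n in nodes}
    pops = dict(ne)
    pops["OUTGROUP"] = float(outgroup_ne)
    pops["ROOT"] = float(rng.uniform(2_000, 40_000))

    splits = [(40_000.0, ["OUTGROUP", "N0"], "ROOT")]
    for n in nodes:
        ch = nodes[n]["children"]
        if ch:
            splits.append((node_time[n] if n != "N0" else level_time[0],
                           list(ch), n))
    # N0's own split time: level_time[0]
    node_time["N0"] = level_time[0]

    samples = [(t, node_time[t], 10) for t in tips]
    samples += [("OUTGROUP", 0.0, 10),
                ("ROOT", 40_000.0, 10),
                ("N0", node_time["N0"], 10)]

    # true admixture graph: tree edges plus pulse insertions (edge-attached
    # sources so that the genealogical attachment points are explicit);
    # pulses processed oldest-first so nested insertions stack in time order
    graph_edges = [("RG", "OUTGROUP"), ("RG", "N0")]
    for n in nodes:
        for c in nodes[n]["children"]:
            graph_edges.append((n, c))
    true_alphas = {}
    ordered_pulses = sorted(enumerate(pulse_edges), key=lambda x: -x[1][2])
    for i, (dest, src, t, a) in ordered_pulses:
        u, v = f"src{i}", f"mix{i}"
        # subdivide current edge above dest and above src at the pulse time
        def split_edge(child, new):
            for j, (pp, cc) in enumerate(graph_edges):
                if cc == child:
                    graph_edges[j] = (pp, new)
                    graph_edges.append((new, child))
                    return
            raise RuntimeError(f"edge above {child} not found")
        split_edge(src, u)
        split_edge(dest, v)
        graph_edges.append((u, v))
        true_alphas[v] = 1.0 - a  # first-listed parent is the dest lineage
    true_graph = AdmixtureGraph(graph_edges, alphas=true_alphas)

    return DemographicModel(
        populations=pops, splits=splits, pulses=pulses, samples=samples,
        genome=genome or GenomeSpec(n_chromosomes=3, chromosome_length=100e6),
        true_graph=true_graph,
        internal_sample_pops=["ROOT", "N0"],
        descriptor={"scenario": "random-graph", "n_pops": n_pops,
                    "n_admix": n_admix, "seed": seed,
                    "outgroup_ne": outgroup_ne,
                    "pulses": pulse_edges},
    )


# ---------------------------------------------------------------------------
# simple trees
# ---------------------------------------------------------------------------

def preset_simple_tree(bottleneck_factor: int = 100, seed: int = 0,
                       genome: GenomeSpec | None = None) -> DemographicModel:
    """Four-taxon clean tree (O,(C,(A,B))) with a post-split bottleneck in A.

    Depth 4,000 generations, Ne 100,000 everywhere; A's size is divided by
    ``bottleneck_factor`` from 1,999 generations ago (immediately after the
    A-B divergence) to the present.  Samples: 25/25/25/10 diploids for
    A/B/C/O (10 for A in the 10,000x class).
    """
    if bottleneck_factor not in (1, 10, 100, 1_000, 10_000):
        raise ValueError("bottleneck_factor must be one of 1/10/100/1000/10000")
    ne = 100_000.0
    pops = {"A": ne / bottleneck_factor, "B": ne, "C": ne, "O": ne,
            "AB": ne, "ABC": ne, "ROOT4": ne}
    splits = [
        (1_999.0, ["A", "B"], "AB"),
        (3_000.0, ["AB", "C"], "ABC"),
        (4_000.0, ["ABC", "O"], "ROOT4"),
    ]
    n_a = 10 if bottleneck_factor == 10_000 else 25
    samples = [("A", 0.0, n_a), ("B", 0.0, 25), ("C", 0.0, 25), ("O", 0.0, 10)]
    graph = AdmixtureGraph([
        ("R", "O"), ("R", "abc"), ("abc", "C"), ("abc", "ab"),
        ("ab", "A"), ("ab", "B"),
    ])
    return DemographicModel(
        populations=pops, splits=splits, samples=samples,
        genome=genome or GenomeSpec(n_chromosomes=3, chromosome_length=100e6),
        true_graph=graph,
        descriptor={"scenario": "simple-tree",
                    "bottleneck_factor": bottleneck_factor, "seed": seed},
    )
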