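"""Config-driven orchestration of the three study designs.

The pipeline stages (simulate -> ascertain -> f-statistics -> graph fits ->
bias metrics) are individually importable; the ``run_*`` functions wire them
together for the three experiment families and return plain DataFrame/dict
bundles, optionally writing TSV/JSON artifacts to an output directory.

Default scale knobs follow the study's stated worlds (three 100 Mb
chromosomes, 10 case-study iterations, 20 random topologies per complexity
class); the ``genome``/``iterations``/``numstart`` fields of
:class:`ExperimentConfig` scale them down for desk-size runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ascertain as asc
from .biasmetrics import FitTable, ThinnedNull, bias_report
from .fstats import daf_spectrum, f2_blocks, fst
from .genotypes import GenotypeMatrix, SiteMask, assign_blocks
from .graphs import enumerate_topologies, fit_graph
from .simulate import (GenomeSpec, SimulationResult, case_study_reduced_graph,
                       preset_case_study, preset_random_graph,
                       preset_simple_tree, retain_by_fst, simulate_model)


@dataclass
class ExperimentConfig:
    """Serializable settings for one experiment run."""

    scenario: str = "case-study"            # case-study | random-graphs | simple-tree
    seed: int = 1
    iterations: int = 10
    neanderthal_flow: float = 0.02
    params_file: str | None = None
    schemes: list[str] = field(default_factory=lambda: [
        "subsampled", "ho-one-panel", "ho-four-panel", "archaic",
        "afr-maf", "global-maf", "nonafr-maf"])
    wr_threshold: float = 3.0
    maf_threshold: float = 0.05
    z_cap: float = 15.0
    null_replicates: int = 200
    null_percentile: float = 2.5
    numstart: int = 100
    diag: float = 0.0001
    block_size: int = 4_000_000
    n_chromosomes: int = 3
    chromosome_length: float = 100e6
    n_subsampled: int = 10
    random_classes: list[tuple] = field(default_factory=lambda: [
        (9, 4), (9, 5), (10, 4), (10, 5)])
    n_per_class: int = 20
    n_random_sets: int = 10
    outgroup_ne: float = 100_000.0
    out_dir: str | None = None

    @property
    def genome(self) -> GenomeSpec:
        return GenomeSpec(n_chromosomes=self.n_chromosomes,
                          chromosome_length=self.chromosome_length)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


def _rng_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(1, 2**31 - 10, n)]


def _write(bundle: dict, out_dir: str | None, name: str) -> None:
    if out_dir is None:
        return
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, val in bundle.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{name}_{key}.tsv", sep="\t", index=False)
        elif isinstance(val, (dict, list)):
            (out / f"{name}_{key}.json").write_text(
                json.dumps(val, indent=2, default=str))


# ---------------------------------------------------------------------------
# scheme application
# ---------------------------------------------------------------------------

def _random_individual(gm: GenotypeMatrix, population: str, rng) -> str:
    ids = gm.individuals.loc[
        gm.individuals["population"] == population, "id"].to_numpy()
    return str(rng.choice(ids))

def apply_case_study_scheme(gm: GenotypeMatrix, scheme: str, rng,
                            maf_threshold: float = 0.05) -> SiteMask:
    """One of the case-study ascertainment schemes, with seeded choices."""
    afr = ["African1", "African2"]
    nonafr = ["NonAfrican1", "NonAfrican2"]
    amh = afr + nonafr
    if scheme == "unascertained":
        return SiteMask(np.ones(gm.n_sites, bool), {"scheme": "unascertained"})
    if scheme == "ho-one-panel":
        ind = _random_individual(gm, "African2", rng)
        return asc.het_in_individual(gm, ind)
    if scheme == "ho-four-panel":
        masks = [asc.het_in_individual(gm, _random_individual(gm, p, rng))
                 for p in amh]
        return asc.union_panels(masks)
    if scheme == "archaic":
        ids = [f"{p}_1" for p in ("Denisovan", "Neanderthal1", "Neanderthal2")]
        return asc.polymorphic_in_group(gm, ids)
    if scheme == "afr-maf":
        return asc.maf_in_metapopulation(gm, afr, maf_threshold)
    if scheme == "nonafr-maf":
        return asc.maf_in_metapopulation(gm, nonafr, maf_threshold)
    if scheme == "global-maf":
        return asc.maf_in_metapopulation(gm, amh, maf_threshold)
    raise ValueError(f"unknown scheme: {scheme}")


# ---------------------------------------------------------------------------
# case study (Fig 3-style)
# ---------------------------------------------------------------------------

def run_case_study(config: ExperimentConfig) -> dict:
    """Fit true full and single-archaic graphs under each ascertainment.

    For every simulation iteration and scheme, fits the full 8-population
    true graph and the three single-archaic reductions, recording WR and LL.
    """
    seeds = _rng_seeds(config.seed, config.iterations)
    rows = []
    for it, s in enumerate(seeds):
        model = preset_case_study(config.neanderthal_flow,
                                  params=config.params_file,
                                  genome=config.genome)
        sim = simulate_model(model, seed=s)
        gm = sim.genotypes
        blocks = assign_blocks(gm, config.block_size)
        rng = np.random.default_rng(s + 1)

        graphs = {"full": sim.true_graph}
        for arch in ("Neanderthal1", "Neanderthal2", "Denisovan"):
            graphs[f"single-{arch}"] = case_study_reduced_graph(
                arch, config.neanderthal_flow)

        schemes = ["unascertained"] + [s2 for s2 in config.schemes
                                       if s2 != "subsampled"]
        masks = {s2: apply_case_study_scheme(gm, s2, rng, config.maf_threshold)
                 for s2 in schemes}
        if "subsampled" in config.schemes:
            target = masks.get("ho-one-panel")
            n_target = target.n_kept if target is not None else gm.n_sites // 10
            for j in range(config.n_subsampled):
                masks[f"subsampled-{j}"] = asc.random_thin(
                    gm, n_target, seed=int(rng.integers(1, 2**31 - 10)))

        for scheme, mask in masks.items():
            for gname, graph in graphs.items():
                pops = graph.leaves
                f2b = f2_blocks(gm, mask, pops, blocks)
                fit = fit_graph(graph, f2b, numstart=config.numstart,
                                diag=config.diag, seed=s + 17)
                rows.append({"iteration": it, "scheme": scheme,
                             "graph": gname, "wr": fit.wr, "ll": fit.ll,
                             "n_sites": mask.n_kept,
                             "worst_f4": str(fit.worst_f4)})
    fits = pd.DataFrame(rows)
    bundle = {"fits": fits, "config": json.loads(config.to_json())}
    _write(bundle, config.out_dir, "case_study")
    return bundle


# ---------------------------------------------------------------------------
# random-graph study (Fig 4-style)
# ---------------------------------------------------------------------------

def random_graph_design(classes=None, n_per_class: int = 20) -> pd.DataFrame:
    """Planned HO one-panel ascertainment jobs of the random-graph design.

    Each simulation samples its tip populations, the outgroup, the true
    root, and the non-outgroup root; HO one-panel ascertainment is repeated
    for every sampled group.
    """
    classes = classes or [(9, 4), (9, 5), (10, 4), (10, 5)]
    rows = []
    for n_pops, n_admix in classes:
        n_groups = (n_pops - 1) + 1 + 2  # tips + outgroup + root + non-OG root
        for rep in range(n_per_class):
            for g in range(n_groups):
                rows.append({"n_pops": n_pops, "n_admix": n_admix,
                             "replicate": rep, "group_index": g})
    return pd.DataFrame(rows)


def simulate_retained_random_graphs(config: ExperimentConfig):
    """Simulate random graphs, keeping those passing the FST retention rule."""
    out = []
    rng = np.random.default_rng(config.seed)
    for n_pops, n_admix in config.random_classes:
        kept = 0
        attempts = 0
        while kept < config.n_per_class and attempts < 50 * config.n_per_class:
            attempts += 1
            s = int(rng.integers(1, 2**31 - 10))
            try:
                model = preset_random_graph(n_pops, n_admix, seed=s,
                                            outgroup_ne=config.outgroup_ne,
                                            genome=config.genome)
                sim = simulate_model(model, seed=s + 1)
            except RuntimeError:
                continue
            if retain_by_fst(sim):
                kept += 1
                out.append(sim)
    return out


def run_random_graph_study(config: ExperimentConfig,
                           sims: list[SimulationResult] | None = None) -> dict:
    """True-graph fits under randomized ascertainments, with FST-to-root.

    For each retained simulation: fit the true graph (tips + outgroup) on
    unascertained data and under HO one-panel ascertainment on every sampled
    group; optionally HO four-panel / MAF / three-individual-polymorphism
    ascertainments on random group sets; record FST of each ascertainment
    population to the root sample and root-conditioned DAF spectra.
    """
    if sims is None:
        sims = simulate_retained_random_graphs(config)
    rows, fst_rows, daf_rows = [], [], []
    for si, sim in enumerate(sims):
        gm = sim.genotypes
        blocks = assign_blocks(gm, config.block_size)
        graph = sim.true_graph
        fit_pops = graph.leaves  # tips + OUTGROUP; root samples not co-modelled
        rng = np.random.default_rng(sim.seed + 101)

        root_pop = "ROOT"
        for pop in gm.populations:
            if pop == root_pop:
                continue
            fst_rows.append({
                "sim": si, "population": pop,
                "fst_to_root": fst(gm, None, pop, root_pop, blocks).estimate})

        def record(scheme, asc_pop, mask, co_modelled):
            f2b = f2_blocks(gm, mask, fit_pops, blocks)
            fit = fit_graph(graph, f2b, numstart=config.numstart,
                            diag=config.diag, seed=sim.seed + 31)
            rows.append({"sim": si, "scheme": scheme,
                         "asc_population": asc_pop,
                         "co_modelled": co_modelled,
                         "wr": fit.wr, "ll": fit.ll,
                         "n_sites": mask.n_kept if mask is not None else gm.n_sites})

        record("unascertained", None,
               SiteMask(np.ones(gm.n_sites, bool), {"scheme": "unascertained"}),
               None)
        for pop in gm.populations:
            ind = _random_individual(gm, pop, rng)
            mask = asc.het_in_individual(gm, ind)
            if mask.n_kept == 0:
                continue
            record("ho-one-panel", pop, mask, pop in fit_pops)

        tips = [p for p in sim.tip_populations if p != "OUTGROUP"]
        for j in range(config.n_random_sets):
            four = list(rng.choice(tips, size=min(4, len(tips)), replace=False))
            masks = [asc.het_in_individual(gm, _random_individual(gm, p, rng))
                     for p in four]
            record("ho-four-panel", "+".join(four), asc.union_panels(masks), True)
            four2 = list(rng.choice(tips, size=min(4, len(tips)), replace=False))
            record("maf-4-groups", "+".join(four2),
                   asc.maf_in_metapopulation(gm, four2, config.maf_threshold), True)
            three = list(rng.choice(tips, size=min(3, len(tips)), replace=False))
            ids = [_random_individual(gm, p, rng) for p in three]
            record("3-groups-poly", "+".join(three),
                   asc.polymorphic_in_group(gm, ids), True)

        # DAF spectra conditioned on root polymorphism
        root_ids = [f"{root_pop}_{i+1}" for i in range(10)]
        root_poly = asc.polymorphic_in_group(gm, root_ids)
        for pop in tips + ["N0"]:
            try:
                spec = daf_spectrum(gm, None, pop, n_chrom=20,
                                    conditioning=root_poly)
            except (ValueError, KeyError):
                continue
            daf_rows.append({"sim": si, "population": pop,
                             **{f"bin{k}": v for k, v in
                                enumerate(spec.proportions)}})

    bundle = {"fits": pd.DataFrame(rows),
              "fst_to_root": pd.DataFrame(fst_rows),
              "daf": pd.DataFrame(daf_rows),
              "config": json.loads(config.to_json())}
    _write(bundle, config.out_dir, "random_graphs")
    return bundle


# ---------------------------------------------------------------------------
# simple-tree cladality experiment (S10-style)
# ---------------------------------------------------------------------------

def run_simple_tree_study(config: ExperimentConfig,
                          bottleneck_factor: int = 100,
                          n_replicates: int = 20,
                          maf_threshold: float = 0.05,
                          schemes=("unascertained", "ho-one-panel", "maf")) -> dict:
    """f4(A, B; C, O) across replicates of the bottlenecked four-taxon tree.

    Returns per-replicate f4 estimates per scheme and the Z-score of the
    replicate mean against zero (the cladality null).
    """
    seeds = _rng_seeds(config.seed, n_replicates)
    rows = []
    for rep, s in enumerate(seeds):
        model = preset_simple_tree(bottleneck_factor, seed=s,
                                   genome=config.genome)
        sim = simulate_model(model, seed=s)
        gm = sim.genotypes
        blocks = assign_blocks(gm, config.block_size)
        rng = np.random.default_rng(s + 3)
        masks = {}
        for scheme in schemes:
            if scheme == "unascertained":
                masks[scheme] = SiteMask(np.ones(gm.n_sites, bool),
                                         {"scheme": "unascertained"})
            elif scheme == "ho-one-panel":
                masks[scheme] = asc.het_in_individual(
                    gm, _random_individual(gm, "A", rng))
            elif scheme == "maf":
                masks[scheme] = asc.maf_in_metapopulation(
                    gm, ["A", "B"], maf_threshold)
            elif scheme == "daf-tail":
                masks[scheme] = asc.daf_tail_removal(gm, ["A", "B"], 0.95)
            else:
                raise ValueError(scheme)
        for scheme, mask in masks.items():
            f2b = f2_blocks(gm, mask, ["A", "B", "C", "O"], blocks)
            from .fstats import f4 as f4_stat
            res = f4_stat(f2b, "A", "B", "C", "O")
            rows.append({"replicate": rep, "scheme": scheme,
                         "f4": res.estimate, "se": res.se, "z": res.z,
                         "n_sites": mask.n_kept})
    df = pd.DataFrame(rows)
    summary = []
    for scheme, grp in df.groupby("scheme"):
        vals = grp["f4"].to_numpy()
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(len(vals))
        summary.append({"scheme": scheme, "mean_f4": mean, "sem": sem,
                        "z_of_mean": mean / sem if sem > 0 else 0.0,
                        "n_replicates": len(vals)})
    bundle = {"replicates": df, "summary": pd.DataFrame(summary),
              "config": json.loads(config.to_json())}
    _write(bundle, config.out_dir, "simple_tree")
    return bundle


# ---------------------------------------------------------------------------
# exhaustive (n,2) scan
# ---------------------------------------------------------------------------

def run_exhaustive_scan(gm: GenotypeMatrix, populations: list[str],
                        config: ExperimentConfig,
                        schemes: dict[str, SiteMask] | None = None,
                        n_admix: int = 2,
                        max_topologies: int | None = None,
                        n_thinned: int | None = None,
                        top_k: int | None = 5000) -> dict:
    """Fit an exhaustive topology catalog on baseline/ascertained/thinned sets.

    ``max_topologies`` shards the catalog for desk-scale runs (fits the
    first K topologies in deterministic catalog order); the catalog size
    check against the published count applies to the full catalog either
    way.
    """
    if len(populations) > 6:
        raise ValueError("exhaustive scan is for small population sets")
    catalog = enumerate_topologies(len(populations), n_admix,
                                   labels=list(populations))
    graphs = catalog.graphs
    if max_topologies is not None:
        graphs = graphs[:max_topologies]
    blocks = assign_blocks(gm, config.block_size)
    rng = np.random.default_rng(config.seed)

    def fit_table(label, mask):
        f2b = f2_blocks(gm, mask, list(populations), blocks)
        fits = [fit_graph(g, f2b, numstart=config.numstart, diag=config.diag,
                          seed=config.seed + 7) for g in graphs]
        return FitTable.from_fits(label, range(len(graphs)), fits)

    baseline = fit_table("all-sites",
                         SiteMask(np.ones(gm.n_sites, bool), {"scheme": "all"}))
    tables = {"all-sites": baseline}
    reports = []
    if schemes:
        for name, mask in schemes.items():
            tables[name] = fit_table(name, mask)

    nn = n_thinned if n_thinned is not None else config.null_replicates
    thinned_tables, thin_seeds = [], []
    if schemes and nn:
        size = min(m.n_kept for m in schemes.values())
        for j in range(nn):
            s = int(rng.integers(1, 2**31 - 10))
            thin_seeds.append(s)
            tmask = asc.random_thin(gm, size, seed=s)
            thinned_tables.append(fit_table(f"thinned-{j}", tmask))
        null_vals = []
        for t in thinned_tables:
            from .biasmetrics import flipped_fractions
            b, _ = flipped_fractions(baseline, t, config.wr_threshold)
            null_vals.append(b)
        null = ThinnedNull("bias_fraction", np.array(null_vals), thin_seeds)
        for name, mask in schemes.items():
            reports.append(bias_report(baseline, tables[name],
                                       threshold=config.wr_threshold,
                                       null=null,
                                       null_percentile=config.null_percentile,
                                       top_k=top_k).to_dict())

    bundle = {"catalog_size": len(catalog),
              "tables": {k: t.table for k, t in tables.items()},
              "thinned": [t.table for t in thinned_tables],
              "thin_seeds": thin_seeds,
              "reports": reports,
              "config": json.loads(config.to_json())}
    if config.out_dir:
        _write({"reports": reports}, config.out_dir, "exhaustive")
    return bundle
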