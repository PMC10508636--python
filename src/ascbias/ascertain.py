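"""SNP ascertainment schemes as composable site-mask producers.

Each function returns a :class:`~ascbias.genotypes.SiteMask` whose provenance
records the scheme and its parameters, so any ascertained panel can be
re-derived from the matrix and a seed.  Schemes mirror the ones in common use
in archaeogenetics:

* ``het_in_individual`` — Human-Origins-style single-genome panels (sites
  heterozygous in one individual); union several with ``union_panels`` for a
  multi-panel array.
* ``polymorphic_in_group`` — "archaic ascertainment": sites variable among a
  pooled set of individuals.
* ``maf_in_metapopulation`` / ``global_maf`` — minor-allele-frequency
  thresholds in a pooled meta-population (strict ``>`` threshold).
* ``atgc_only`` / ``transversions_only`` — mutation-class filters.
* ``random_thin`` — seeded uniform down-sampling to a target panel size.
* ``daf_tail_removal`` — drop the derived tail of the frequency spectrum.
* ``fixed_site_list`` — intersect with an externally supplied panel.
"""

from __future__ import annotations

import logging

import numpy as np

from .genotypes import ATGC, MISSING, TRANSITION, GenotypeMatrix, SiteMask, load_site_list

logger = logging.getLogger(__name__)


def het_in_individual(gm: GenotypeMatrix, individual_id: str) -> SiteMask:
    """Sites heterozygous (dosage exactly 1) in one individual."""
    j = gm.individual_index(individual_id)
    keep = gm.calls[:, j] == 1
    return SiteMask(keep, {"scheme": "het-in-individual", "individual": individual_id})


def union_panels(masks: list[SiteMask]) -> SiteMask:
    """Union of single-genome panels (logical OR), e.g. HO four-panel."""
    if not masks:
        raise ValueError("no masks to union")
    out = masks[0]
    for m in masks[1:]:
        out = out | m
    out.provenance = {"scheme": "union-of-panels",
                      "panels": [m.provenance for m in masks]}
    return out


def polymorphic_in_group(gm: GenotypeMatrix, individual_ids: list[str]) -> SiteMask:
    """Sites where both alleles are seen among the pooled individuals' calls."""
    if not individual_ids:
        raise ValueError("empty individual list")
    cols = [gm.individual_index(i) for i in individual_ids]
    sub = gm.calls[:, cols]
    obs = sub != MISSING
    derived = np.where(obs, sub, 0).sum(axis=1)
    n = 2 * obs.sum(axis=1)
    keep = (derived > 0) & (derived < n)
    return SiteMask(keep, {"scheme": "polymorphic-in-group",
                           "individuals": list(individual_ids)})


def _pooled_daf(gm: GenotypeMatrix, population_ids: list[str]):
    """Pooled derived frequency over all chromosomes of the listed populations.

    Pooling weights every non-missing chromosome equally (allele-count
    pooling over the union of groups), not a mean of per-population
    frequencies.
    """
    if not population_ids:
        raise ValueError("empty population list")
    cols = np.concatenate([gm.population_indices(p) for p in population_ids])
    sub = gm.calls[:, cols]
    obs = sub != MISSING
    derived = np.where(obs, sub, 0).sum(axis=1)
    n = 2 * obs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, derived / np.maximum(n, 1), np.nan)
    return p, n


def maf_in_metapopulation(gm: GenotypeMatrix, population_ids: list[str],
                          threshold: float = 0.05) -> SiteMask:
    """Sites with minor-allele frequency strictly above ``threshold``.

    Frequency is pooled over the listed populations' chromosomes; a site
    with no data in the pool counts as MAF 0 and is dropped.
    """
    p, n = _pooled_daf(gm, population_ids)
    maf = np.where(n > 0, np.minimum(p, 1.0 - p), 0.0)
    keep = maf > threshold
    return SiteMask(keep, {"scheme": "maf-in-metapopulation",
                           "populations": list(population_ids),
                           "threshold": threshold})


def global_maf(gm: GenotypeMatrix, threshold: float = 0.05) -> SiteMask:
    """MAF threshold over every individual in the matrix."""
    mask = maf_in_metapopulation(gm, gm.populations, threshold)
    mask.provenance = {"scheme": "global-maf", "threshold": threshold}
    return mask


def atgc_only(gm: GenotypeMatrix) -> SiteMask:
    """Keep only A/T and G/C SNPs (immune to biased gene conversion)."""
    keep = (gm.sites["mclass"] == ATGC).to_numpy()
    return SiteMask(keep, {"scheme": "atgc-only"})


def transversions_only(gm: GenotypeMatrix) -> SiteMask:
    """Keep all transversions (everything that is not a transition)."""
    keep = (gm.sites["mclass"] != TRANSITION).to_numpy()
    return SiteMask(keep, {"scheme": "transversions-only"})


def random_thin(gm: GenotypeMatrix, n_target: int, seed: int,
                within: SiteMask | None = None) -> SiteMask:
    """Uniform sample of exactly ``n_target`` sites, without replacement.

    ``within`` restricts the pool (e.g. thin an already-ascertained set to a
    reference panel size).  Reproducible for a given seed.
    """
    pool = np.flatnonzero(within.keep) if within is not None else np.arange(gm.n_sites)
    if n_target > pool.size:
        raise ValueError(f"n_target {n_target} exceeds {pool.size} available sites")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(pool, size=n_target, replace=False)
    keep = np.zeros(gm.n_sites, dtype=bool)
    keep[chosen] = True
    return SiteMask(keep, {"scheme": "random-thin", "n_target": int(n_target),
                           "seed": int(seed)})


def daf_tail_removal(gm: GenotypeMatrix, population_ids: list[str],
                     threshold: float = 0.95) -> SiteMask:
    """Remove sites whose pooled derived-allele frequency exceeds ``threshold``.

    A site at exactly the threshold is kept (<= rule); sites with no data in
    the pool have DAF 0 and are kept.
    """
    p, n = _pooled_daf(gm, population_ids)
    daf = np.where(n > 0, p, 0.0)
    keep = daf <= threshold
    return SiteMask(keep, {"scheme": "daf-tail-removal",
                           "populations": list(population_ids),
                           "threshold": threshold})


def fixed_site_list(gm: GenotypeMatrix, list_path) -> SiteMask:
    """Keep sites matching a TSV panel on (chrom, pos, unordered allele pair).

    Position matches with a mismatching allele pair are dropped with a
    logged warning (strict matching).
    """
    panel = load_site_list(list_path)
    panel_pos = {}
    for row in panel.itertuples(index=False):
        panel_pos[(str(row.chrom), int(row.pos))] = frozenset((row.a1, row.a2))
    keep = np.zeros(gm.n_sites, dtype=bool)
    n_allele_mismatch = 0
    chroms = gm.sites["chrom"].to_numpy()
    poss = gm.sites["pos"].to_numpy()
    ancs = gm.sites["anc"].to_numpy()
    ders = gm.sites["der"].to_numpy()
    for i in range(gm.n_sites):
        alleles = panel_pos.get((str(chroms[i]), int(poss[i])))
        if alleles is None:
            continue
        if alleles == frozenset((ancs[i], ders[i])):
            keep[i] = True
        else:
            n_allele_mismatch += 1
    if n_allele_mismatch:
        logger.warning("fixed_site_list: %d positions matched with a different "
                       "allele pair; dropped", n_allele_mismatch)
    return SiteMask(keep, {"scheme": "fixed-site-list", "path": str(list_path)})
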