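"""Polarized genotype matrices, site metadata, genome blocks and site masks.

The central container is :class:`GenotypeMatrix`: an (n_sites, n_individuals)
matrix of derived-allele dosages in {0, 1, 2} (``-1`` for missing), with site
metadata (chromosome, position, ancestral/derived allele, mutation class) and
an individual-to-population assignment.  All downstream allele-frequency
machinery (f-statistics, FST, derived-allele-frequency spectra) consumes this
container, optionally restricted through a :class:`SiteMask`.

EIGENSTRAT (unpacked ASCII geno/snp/ind) and biallelic-SNP VCF are supported
for interoperability with the wider toolchain; simulated data are built
directly by :mod:`ascbias.simulate`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

#: mutation classes: A/T and G/C pairs are unaffected by GC-biased gene
#: conversion; transitions are A<->G and C<->T; everything else is an ordinary
#: transversion.
ATGC = "AT/GC"
TRANSITION = "transition"
TRANSVERSION_OTHER = "transversion-other"

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}
_ATGC_PAIRS = {frozenset("AT"), frozenset("GC")}


def mutation_class(ancestral: str, derived: str) -> str:
    """Classify a biallelic SNP by its allele pair.

    The three classes are mutually exclusive and exhaustive for biallelic
    nucleotide SNPs.  Non-nucleotide alleles (e.g. the 0/1 labels of a binary
    mutation model) raise ``ValueError``.
    """
    pair = frozenset((ancestral.upper(), derived.upper()))
    if len(pair) != 2 or not pair <= set("ACGT"):
        raise ValueError(f"not a biallelic nucleotide SNP: {ancestral}/{derived}")
    if pair in _ATGC_PAIRS:
        return ATGC
    if pair in _TRANSITION_PAIRS:
        return TRANSITION
    return TRANSVERSION_OTHER


@dataclass
class GenotypeMatrix:
    """Derived-allele dosage matrix with site and individual metadata.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int),
        ``anc``, ``der`` (allele strings) and ``mclass`` (mutation class).
        Rows are sorted by (chrom, pos).
    individuals:
        DataFrame with columns ``id`` and ``population``.
    calls:
        int8 array of shape (n_sites, n_individuals); derived-allele counts
        0/1/2, or ``MISSING`` (-1).
    """

    sites: pd.DataFrame
    individuals: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites), len(self.individuals)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individuals)} individuals"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        order = self.sites[["chrom", "pos"]]
        if not order.equals(order.sort_values(["chrom", "pos"])):
            raise ValueError("sites must be sorted by (chromosome, position)")

    # -- basic accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.individuals["population"]))

    def individual_index(self, individual_id: str) -> int:
        idx = np.flatnonzero(self.individuals["id"].to_numpy() == individual_id)
        if idx.size == 0:
            raise KeyError(f"unknown individual: {individual_id}")
        return int(idx[0])

    def population_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.individuals["population"].to_numpy() == population)
        if idx.size == 0:
            raise KeyError(f"unknown population: {population}")
        return idx

    def allele_counts(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site pooled (derived count, non-missing chromosome count)."""
        sub = self.calls[:, self.population_indices(population)]
        obs = sub != MISSING
        derived = np.where(obs, sub, 0).sum(axis=1)
        return derived.astype(np.int64), 2 * obs.sum(axis=1).astype(np.int64)

    def frequencies(self, population: str) -> np.ndarray:
        """Per-site derived-allele sample frequency (NaN where no data)."""
        d, n = self.allele_counts(population)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d / np.maximum(n, 1), np.nan)

    def restrict(self, mask: "SiteMask | np.ndarray") -> "GenotypeMatrix":
        keep = mask.keep if isinstance(mask, SiteMask) else np.asarray(mask, bool)
        return GenotypeMatrix(
            sites=self.sites.loc[keep].reset_index(drop=True),
            individuals=self.individuals,
            calls=self.calls[keep],
        )


@dataclass
class SiteMask:
    """Boolean keep-flag per site, with the provenance that produced it.

    Masks over the same matrix compose with ``&`` (intersection of schemes)
    and ``|`` (union of panels); provenance is combined so a mask can always
    be re-derived from the matrix and the recorded parameters/seed.
    """

    keep: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def _check(self, other: "SiteMask") -> None:
        if self.keep.shape != other.keep.shape:
            raise ValueError("masks are over different matrices")

    def __and__(self, other: "SiteMask") -> "SiteMask":
        self._check(other)
        return SiteMask(self.keep & other.keep,
                        {"and": [self.provenance, other.provenance]})

    def __or__(self, other: "SiteMask") -> "SiteMask":
        self._check(other)
        return SiteMask(self.keep | other.keep,
                        {"or": [self.provenance, other.provenance]})

    def to_json(self) -> str:
        return json.dumps({"n_kept": self.n_kept, "provenance": self.provenance})


@dataclass
class BlockPartition:
    """Assignment of sites to contiguous genome blocks.

    Blocks are ``block_size`` base pairs, never span chromosomes, and are
    numbered consecutively across chromosomes with empty blocks omitted.
    """

    block_size: int
    block_index: np.ndarray  # per-site global block id
    site_counts: np.ndarray  # per-block number of sites

    @property
    def n_blocks(self) -> int:
        return len(self.site_counts)


def assign_blocks(gm: GenotypeMatrix, block_size: int = 4_000_000) -> BlockPartition:
    """Map each site to a genome block of ``block_size`` bp.

    A site at 1-based position p falls in local block ``floor((p - 1) /
    block_size)`` of its chromosome; local blocks are renumbered globally in
    (chromosome, position) order, dropping empty blocks.
    """
    chrom = gm.sites["chrom"].to_numpy()
    pos = gm.sites["pos"].to_numpy()
    local = (pos - 1) // block_size
    # pair (chrom, local block) -> consecutive global id, in site order
    key = pd.Series(list(zip(chrom, local)))
    codes, _ = pd.factorize(key, sort=False)
    counts = np.bincount(codes)
    return BlockPartition(block_size=block_size,
                          block_index=codes.astype(np.int64),
                          site_counts=counts.astype(np.int64))


def polarize(gm: GenotypeMatrix, outgroup_individual_id: str) -> GenotypeMatrix:
    """Re-polarize using an outgroup individual as the ancestral-state proxy.

    At each site where the outgroup individual carries a homozygous call, its
    allele is declared ancestral; dosages are flipped (d -> 2 - d) where the
    current labelling disagrees.  Sites where the outgroup is missing or
    heterozygous are dropped.
    """
    j = gm.individual_index(outgroup_individual_id)
    og = gm.calls[:, j]
    keep = (og == 0) | (og == 2)
    flip = og == 2  # outgroup homozygous derived -> labels must swap

    calls = gm.calls.copy()
    fl = flip & keep
    sub = calls[fl]
    sub = np.where(sub == MISSING, MISSING, 2 - sub).astype(np.int8)
    calls[fl] = sub

    sites = gm.sites.copy()
    anc = sites["anc"].to_numpy().copy()
    der = sites["der"].to_numpy().copy()
    anc[fl], der[fl] = der[fl].copy(), anc[fl].copy()
    sites["anc"] = anc
    sites["der"] = der

    return GenotypeMatrix(
        sites=sites.loc[keep].reset_index(drop=True),
        individuals=gm.individuals,
        calls=calls[keep],
    )


def filter_missing(gm: GenotypeMatrix, populations: list[str],
                   per_individual: bool = False) -> SiteMask:
    """Group-level completeness mask ("no missing data at the group level").

    Keeps a site iff every listed population has at least one non-missing
    call there.  With ``per_individual=True`` the stricter rule is applied:
    every individual of every listed population must be called.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    for pop in populations:
        sub = gm.calls[:, gm.population_indices(pop)]
        obs = sub != MISSING
        keep &= obs.all(axis=1) if per_individual else obs.any(axis=1)
    return SiteMask(keep, {"scheme": "filter-missing",
                           "populations": list(populations),
                           "per_individual": per_individual})


# ---------------------------------------------------------------------------
# EIGENSTRAT / VCF / site-list I/O
# ---------------------------------------------------------------------------

def load_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    """Read unpacked-ASCII EIGENSTRAT geno/snp/ind triplet.

    The snp file's first allele column is taken as the reference ("ancestral")
    and the second as variant ("derived"); genotype digits count the *first*
    (reference) allele per EIGENSTRAT convention, so dosages are converted to
    derived-allele counts as ``2 - g``.  Code 9 means missing.  Callers that
    know a better ancestral-allele source should re-polarize afterwards.
    """
    ind = pd.read_csv(ind_path, sep=r"\s+", header=None,
                      names=["id", "sex", "population"], dtype=str)
    snp = pd.read_csv(snp_path, sep=r"\s+", header=None,
                      names=["snpid", "chrom", "gpos", "pos", "a1", "a2"],
                      dtype={"chrom": str})
    rows = []
    with open(geno_path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(line)
    if len(rows) != len(snp):
        raise ValueError(f"geno has {len(rows)} rows but snp has {len(snp)}")
    n_ind = len(ind)
    calls = np.empty((len(rows), n_ind), dtype=np.int8)
    for i, line in enumerate(rows):
        if len(line) != n_ind:
            raise ValueError(f"geno row {i} has {len(line)} columns, expected {n_ind}")
        g = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
        if not np.isin(g, (0, 1, 2, 9)).all():
            raise ValueError(f"unknown genotype code in geno row {i}")
        calls[i] = np.where(g == 9, MISSING, 2 - g)

    mclass = [
        _safe_mclass(a, b) for a, b in zip(snp["a1"], snp["a2"])
    ]
    sites = pd.DataFrame({
        "chrom": snp["chrom"].astype(str),
        "pos": snp["pos"].astype(np.int64),
        "anc": snp["a1"].astype(str),
        "der": snp["a2"].astype(str),
        "mclass": mclass,
    })
    order = np.lexsort((sites["pos"].to_numpy(),
                        sites["chrom"].to_numpy()))
    sites = sites.iloc[order].reset_index(drop=True)
    calls = calls[order]
    return GenotypeMatrix(sites=sites,
                          individuals=ind[["id", "population"]].reset_index(drop=True),
                          calls=calls)


def _safe_mclass(a: str, b: str) -> str:
    try:
        return mutation_class(a, b)
    except ValueError:
        return TRANSVERSION_OTHER


def write_eigenstrat(gm: GenotypeMatrix, prefix) -> None:
    """Write unpacked-ASCII EIGENSTRAT files ``prefix``.geno/.snp/.ind."""
    prefix = Path(prefix)
    with open(f"{prefix}.ind", "w") as fh:
        for _, row in gm.individuals.iterrows():
            fh.write(f"{row['id']}\tU\t{row['population']}\n")
    with open(f"{prefix}.snp", "w") as fh:
        for i, row in gm.sites.iterrows():
            fh.write(f"snp{i}\t{row['chrom']}\t0.0\t{row['pos']}\t{row['anc']}\t{row['der']}\n")
    with open(f"{prefix}.geno", "w") as fh:
        for i in range(gm.n_sites):
            g = gm.calls[i]
            # derived dosage d -> reference-allele count 2-d; missing -> 9
            out = np.where(g == MISSING, 9, 2 - g)
            fh.write("".join(map(str, out)) + "\n")


def load_vcf(path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF; REF is taken as ancestral.

    ``populations`` maps sample id -> population; unmapped samples form the
    population "pop0".  Multi-allelic and non-SNP records are skipped.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = [populations.get(s, "pop0") if populations else "pop0" for s in samples]
    chroms, poss, ancs, ders, rows = [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gts = var.genotype.array()
        a = gts[:, 0]
        b = gts[:, 1]
        d = np.where((a < 0) | (b < 0), MISSING, (a > 0).astype(int) + (b > 0).astype(int))
        chroms.append(str(var.CHROM))
        poss.append(var.POS)
        ancs.append(var.REF)
        ders.append(var.ALT[0])
        rows.append(d.astype(np.int8))
    sites = pd.DataFrame({
        "chrom": chroms, "pos": np.asarray(poss, dtype=np.int64),
        "anc": ancs, "der": ders,
        "mclass": [_safe_mclass(a, b) for a, b in zip(ancs, ders)],
    })
    calls = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    order = np.lexsort((sites["pos"].to_numpy(), sites["chrom"].to_numpy()))
    return GenotypeMatrix(
        sites=sites.iloc[order].reset_index(drop=True),
        individuals=pd.DataFrame({"id": samples, "population": pops}),
        calls=calls[order],
    )


def load_site_list(path) -> pd.DataFrame:
    """Read a TSV site list (chrom, pos, allele1, allele2) for fixed panels."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "pos", "a1", "a2"],
                     dtype={"chrom": str, "pos": np.int64, "a1": str, "a2": str})
    if df[["chrom", "pos"]].isna().any().any():
        raise ValueError(f"malformed site list: {path}")
    return df
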