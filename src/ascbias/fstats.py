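"""f-statistics with weighted block-jackknife errors, FST and DAF spectra.

The workflow mirrors the standard f-statistic toolchain: all pairwise
f2-statistics are first computed per genome block (:func:`f2_blocks`), and
every other f-statistic is a linear combination of block f2 values::

    f4(A, B; C, D) = ( f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D) ) / 2
    f3(T; A, B)    = f4(T, A; T, B)
    f2(A, B)       = f4(A, B; A, B)

Standard errors come from a weighted delete-one-block jackknife (Busing-style
weights proportional to per-block usable-site counts), and covariances across
statistics from the same leave-one-out replicates.

The per-site f2 estimator is the unbiased ("bias-corrected") form

    (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)

with p the sample derived-allele frequency and n the number of non-missing
chromosomes; a naive uncorrected mode exists for oracle tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genotypes import BlockPartition, GenotypeMatrix, SiteMask, assign_blocks


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def jackknife(values: np.ndarray, weights: np.ndarray):
    """Weighted delete-one-block jackknife for a weighted-mean statistic.

    Parameters
    ----------
    values:
        per-block statistic values (each block's contribution is its
        weighted mean over sites).
    weights:
        per-block usable-site counts; blocks with zero weight are ignored.

    Returns
    -------
    (estimate, se, z)
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = weights > 0
    values, weights = values[ok], weights[ok]
    g = values.size
    if g < 2:
        raise ValueError("jackknife needs at least 2 blocks with data")
    n = weights.sum()
    total = float(np.dot(values, weights))
    est = total / n
    # leave-one-out estimates
    loo = (total - values * weights) / (n - weights)
    h = n / weights
    theta_j = g * est - np.sum((1.0 - weights / n) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = est / se if se > 0 else np.inf if est != 0 else 0.0
    return est, se, float(z)


def jackknife_cov(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Jackknife covariance matrix for several block statistics.

    ``values`` has shape (n_blocks, n_stats); all statistics share the same
    per-block weights (usable-site counts).
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    ok = weights > 0
    values, weights = values[ok], weights[ok]
    g = len(weights)
    if g < 2:
        raise ValueError("jackknife needs at least 2 blocks with data")
    n = weights.sum()
    total = weights @ values
    est = total / n
    loo = (total[None, :] - values * weights[:, None]) / (n - weights)[:, None]
    h = n / weights
    theta_j = g * est - np.sum((1.0 - weights / n)[:, None] * loo, axis=0)
    tau = h[:, None] * est[None, :] - (h - 1.0)[:, None] * loo
    dev = tau - theta_j[None, :]
    scaled = dev / np.sqrt((h - 1.0))[:, None]
    return (scaled.T @ scaled) / g


# ---------------------------------------------------------------------------
# block f2
# ---------------------------------------------------------------------------

@dataclass
class F2Blocks:
    """Per-block unbiased f2 estimates for all population pairs.

    ``values[b, k]`` is the mean per-site f2 of pair ``pairs[k]`` in block
    ``b``; ``pair_counts[b, k]`` the number of usable sites behind it.
    ``weights`` are the per-block overall usable-site counts used as
    jackknife weights.
    """

    populations: list[str]
    pairs: list[tuple[str, str]]
    values: np.ndarray       # (n_blocks, n_pairs)
    pair_counts: np.ndarray  # (n_blocks, n_pairs)
    weights: np.ndarray      # (n_blocks,)
    blocks: BlockPartition | None = None
    settings: dict = field(default_factory=dict)

    def pair_index(self, a: str, b: str) -> int:
        key = (a, b) if (a, b) in self._index else (b, a)
        return self._index[key]

    @property
    def _index(self):
        if not hasattr(self, "_idx_cache"):
            self._idx_cache = {p: k for k, p in enumerate(self.pairs)}
        return self._idx_cache

    @property
    def n_blocks(self) -> int:
        return self.values.shape[0]

    def block_f2(self, a: str, b: str) -> np.ndarray:
        if a == b:
            return np.zeros(self.n_blocks)
        return self.values[:, self.pair_index(a, b)]

    def block_f4(self, a: str, b: str, c: str, d: str) -> np.ndarray:
        """Per-block f4 as the half-sum combination of f2 statistics."""
        if a == b or c == d:
            return np.zeros(self.n_blocks)  # identical pair: exactly zero
        return 0.5 * (self.block_f2(a, d) + self.block_f2(b, c)
                      - self.block_f2(a, c) - self.block_f2(b, d))

    def drop_block(self, j: int) -> "F2Blocks":
        """Leave-one-block-out copy (for jackknifing fitted parameters)."""
        keep = np.arange(self.n_blocks) != j
        return F2Blocks(populations=self.populations, pairs=self.pairs,
                        values=self.values[keep],
                        pair_counts=self.pair_counts[keep],
                        weights=self.weights[keep], blocks=self.blocks,
                        settings=dict(self.settings))


def f2_blocks(gm: GenotypeMatrix, mask: SiteMask | None, populations: list[str],
              blocks: BlockPartition | None = None,
              bias_correction: bool = True,
              min_allele_count: int = 0) -> F2Blocks:
    """All pairwise f2-statistics per genome block.

    Sites where either population of a pair has fewer than two non-missing
    chromosomes (or fewer than ``min_allele_count`` copies of either allele,
    when set) are skipped for that pair.
    """
    if blocks is None:
        blocks = assign_blocks(gm)
    keep = mask.keep if mask is not None else np.ones(gm.n_sites, bool)
    nb = blocks.n_blocks
    pops = list(populations)

    freqs, corrs, valid = {}, {}, {}
    for p in pops:
        d, n = gm.allele_counts(p)
        ok = keep & (n >= 2)
        if min_allele_count > 0:
            ok &= (d >= min_allele_count) | (n - d >= min_allele_count)
        with np.errstate(invalid="ignore", divide="ignore"):
            ph = np.where(n > 0, d / np.maximum(n, 1), 0.0)
            corr = np.where(n > 1, ph * (1 - ph) / np.maximum(n - 1, 1), 0.0)
        freqs[p], corrs[p], valid[p] = ph, corr, ok

    pairs = list(itertools.combinations(pops, 2))
    values = np.zeros((nb, len(pairs)))
    counts = np.zeros((nb, len(pairs)), dtype=np.int64)
    bi = blocks.block_index
    for k, (a, b) in enumerate(pairs):
        ok = valid[a] & valid[b]
        per_site = (freqs[a] - freqs[b]) ** 2
        if bias_correction:
            per_site = per_site - corrs[a] - corrs[b]
        per_site = np.where(ok, per_site, 0.0)
        sums = np.bincount(bi, weights=per_site, minlength=nb)
        ns = np.bincount(bi, weights=ok.astype(float), minlength=nb)
        with np.errstate(invalid="ignore", divide="ignore"):
            values[:, k] = np.where(ns > 0, sums / np.maximum(ns, 1), 0.0)
        counts[:, k] = ns.astype(np.int64)

    weights = np.bincount(bi, weights=keep.astype(float), minlength=nb).astype(np.int64)
    nonempty = weights > 0
    return F2Blocks(
        populations=pops, pairs=pairs,
        values=values[nonempty], pair_counts=counts[nonempty],
        weights=weights[nonempty], blocks=blocks,
        settings={"bias_correction": bias_correction,
                  "min_allele_count": min_allele_count},
    )


# ---------------------------------------------------------------------------
# f-statistics from block f2
# ---------------------------------------------------------------------------

@dataclass
class FStatResult:
    """Point estimate, jackknife SE and Z of one f-statistic."""

    statistic: str
    pops: tuple
    estimate: float
    se: float
    z: float
    n_blocks: int
    block_values: np.ndarray | None = None

    def __repr__(self) -> str:
        return (f"{self.statistic}{self.pops}: {self.estimate:.6g} "
                f"+- {self.se:.3g} (Z={self.z:.2f}, {self.n_blocks} blocks)")


def f4(f2b: F2Blocks, a: str, b: str, c: str, d: str) -> FStatResult:
    """f4(A, B; C, D) with block-jackknife error."""
    bv = f2b.block_f4(a, b, c, d)
    est, se, z = jackknife(bv, f2b.weights)
    return FStatResult("f4", (a, b, c, d), est, se, z, f2b.n_blocks, bv)


def f3(f2b: F2Blocks, target: str, a: str, b: str) -> FStatResult:
    """f3(target; A, B) = f4(target, A; target, B)."""
    res = f4(f2b, target, a, target, b)
    return FStatResult("f3", (target, a, b), res.estimate, res.se, res.z,
                       res.n_blocks, res.block_values)


def f2_stat(f2b: F2Blocks, a: str, b: str) -> FStatResult:
    res = f4(f2b, a, b, a, b)
    return FStatResult("f2", (a, b), res.estimate, res.se, res.z,
                       res.n_blocks, res.block_values)


def f4_naive(gm: GenotypeMatrix, mask: SiteMask | None,
             a: str, b: str, c: str, d: str) -> float:
    """Direct per-site average of (pA-pB)(pC-pD); oracle for complete data."""
    keep = mask.keep if mask is not None else np.ones(gm.n_sites, bool)
    pa, pb, pc, pd_ = (gm.frequencies(x) for x in (a, b, c, d))
    prod = (pa - pb) * (pc - pd_)
    ok = keep & ~np.isnan(prod)
    return float(prod[ok].mean())


# ---------------------------------------------------------------------------
# Hudson FST
# ---------------------------------------------------------------------------

def fst(gm: GenotypeMatrix, mask: SiteMask | None, a: str, b: str,
        blocks: BlockPartition | None = None) -> FStatResult:
    """Hudson-type FST as a ratio of site-averaged numerator and denominator.

    Numerator is the unbiased f2 per-site term; denominator is
    ``pA(1-pB) + pB(1-pA)``.  The jackknife is carried out on the ratio
    (ratio-of-averages, the standard behaviour for sparse data).
    """
    if blocks is None:
        blocks = assign_blocks(gm)
    keep = mask.keep if mask is not None else np.ones(gm.n_sites, bool)
    da, na = gm.allele_counts(a)
    db, nb_ = gm.allele_counts(b)
    ok = keep & (na >= 2) & (nb_ >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = np.where(na > 0, da / np.maximum(na, 1), 0.0)
        pb = np.where(nb_ > 0, db / np.maximum(nb_, 1), 0.0)
        num = ((pa - pb) ** 2
               - pa * (1 - pa) / np.maximum(na - 1, 1)
               - pb * (1 - pb) / np.maximum(nb_ - 1, 1))
        den = pa * (1 - pb) + pb * (1 - pa)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)
    bi = blocks.block_index
    nbk = blocks.n_blocks
    num_b = np.bincount(bi, weights=num, minlength=nbk)
    den_b = np.bincount(bi, weights=den, minlength=nbk)
    w = np.bincount(bi, weights=ok.astype(float), minlength=nbk)
    use = w > 0
    num_b, den_b, w = num_b[use], den_b[use], w[use]
    if den_b.sum() == 0:
        raise ValueError("FST undefined: zero denominator")
    est = num_b.sum() / den_b.sum()
    g = len(w)
    if g < 2:
        raise ValueError("FST jackknife needs at least 2 blocks")
    n = w.sum()
    loo = (num_b.sum() - num_b) / np.maximum(den_b.sum() - den_b, 1e-300)
    h = n / w
    theta_j = g * est - np.sum((1.0 - w / n) * loo)
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    se = float(np.sqrt(var))
    z = est / se if se > 0 else np.inf if est != 0 else 0.0
    return FStatResult("fst", (a, b), float(est), se, float(z), g)


def fst_matrix(gm: GenotypeMatrix, mask: SiteMask | None,
               populations: list[str],
               blocks: BlockPartition | None = None) -> pd.DataFrame:
    """All pairwise Hudson FST point estimates."""
    pops = list(populations)
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for a, b in itertools.combinations(pops, 2):
        v = fst(gm, mask, a, b, blocks=blocks).estimate
        out.loc[a, b] = out.loc[b, a] = v
    return out


# ---------------------------------------------------------------------------
# derived-allele-frequency spectra
# ---------------------------------------------------------------------------

@dataclass
class DAFSpectrum:
    """Down-projected derived-allele-count spectrum of one population."""

    population: str
    n_chrom: int
    proportions: np.ndarray  # bins 0..n_chrom
    conditioning: str | None = None


def daf_spectrum(gm: GenotypeMatrix, mask: SiteMask | None, population: str,
                 n_chrom: int = 20,
                 conditioning: SiteMask | None = None) -> DAFSpectrum:
    """Hypergeometric down-projection of each site's counts to ``n_chrom``.

    ``conditioning`` optionally restricts to an extra mask (e.g. sites
    polymorphic in a sample drawn at the root).  Sites with fewer than
    ``n_chrom`` observed chromosomes are skipped.
    """
    keep = mask.keep if mask is not None else np.ones(gm.n_sites, bool)
    if conditioning is not None:
        keep = keep & conditioning.keep
    d, n = gm.allele_counts(population)
    ok = keep & (n >= n_chrom)
    if not ok.any():
        raise ValueError("no usable sites for DAF spectrum")
    d, n = d[ok], n[ok]
    bins = np.zeros(n_chrom + 1)
    # group identical (n, d) for speed
    combos, counts = np.unique(np.stack([n, d]), axis=1, return_counts=True)
    ks = np.arange(n_chrom + 1)
    for (ni, di), c in zip(combos.T, counts):
        probs = hypergeom.pmf(ks, ni, di, n_chrom)
        bins += c * probs
    bins /= bins.sum()
    return DAFSpectrum(population=population, n_chrom=n_chrom, proportions=bins,
                       conditioning=(conditioning.provenance.get("scheme")
                                     if conditioning is not None else None))
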