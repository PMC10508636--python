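# Methods

`ascbias` quantifies how non-random SNP selection ("ascertainment") distorts
f-statistics and admixture-graph fitting, using coalescent simulations in
which the true demographic history is known.  This note records the models,
estimators, numerical choices, and the limits of what a passing test
establishes.

## f-statistics

All statistics are built from block f2-statistics.  For a site with sample
derived-allele frequencies `pA`, `pB` on `nA`, `nB` non-missing chromosomes,
the unbiased per-site estimator is

    f2 = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)

averaged within contiguous genome blocks (default 4 Mb; blocks never span
chromosomes).  Every other statistic is a linear combination:

    f4(A,B;C,D) = [f2(A,D) + f2(B,C) - f2(A,C) - f2(B,D)] / 2
    f3(T;A,B)   = f4(T,A;T,B),     f2(A,B) = f4(A,B;A,B)

Standard errors use the weighted delete-one-block jackknife (weights = per
block usable-site counts, Busing-style variance formula); covariances across
statistics come from the same leave-one-out replicates.  Z-scores are
estimate/SE with no small-sample t correction.  FST is the Hudson estimator
as a ratio of site-averaged numerator and denominator (ratio of averages,
not average of ratios), jackknifed on the ratio.  Derived-allele-frequency
spectra use exact hypergeometric down-projection to a fixed chromosome
count.

A deliberate small-sample property: computing FST or f2 between two
*identical* samples gives exactly `-1/(2n-1)` times the denominator scale,
because the unbiased numerator subtracts the within-sample sampling
variance.  Tests assert this rather than "0".

## Admixture graphs

A graph is a rooted DAG: leaves are populations, admixture nodes have two
parents with mixing proportions `alpha` / `1-alpha`.  Expected f2 between
leaves A and B is `sum_e len(e) * (wA(e) - wB(e))^2`, where `wX(e)` is the
probability that a lineage from X traverses edge `e` (products of mixing
proportions summed over paths).  **Every edge may carry drift, including the
in-edges of admixture nodes**: drift accumulated between a parent lineage's
attachment point and the admixture event lives on that in-edge.  This is
equivalent to the common zero-length-admixture-edge convention with explicit
pre-admixture parent nodes, but with fewer bookkeeping nodes; without it,
true histories whose admixing lineages drift before the pulse cannot be
expressed, and the correct model is spuriously rejected.

### Fitting

The objective is the inverse-covariance-weighted quadratic form over a
full-rank basis of f3-statistics anchored at the first fitted population:

    q(theta) = (f_obs - f_exp(theta))' Q^{-1} (f_obs - f_exp(theta))

* Given the mixing proportions, expected basis values are linear in edge
  lengths, so lengths are solved by non-negative least squares in the
  whitened space (Cholesky of Q).
* Mixing proportions are optimised by bound-constrained quasi-Newton
  (L-BFGS-B, box [1e-4, 1-1e-4]) from `numstart` uniform random starts in
  [0.05, 0.95] (default `numstart = 100`, `diag = 0.0001`); the best
  objective wins, ties broken by first encounter.
* Q is the block-jackknife covariance of the basis, ridge-regularised by
  `diag` x mean diagonal (a relative ridge; an absolute mode exists).  When
  the covariance is numerically degenerate (noise-free synthetic data) the
  ridge falls back to the squared data scale.
* **Covariance mode**: a g-block jackknife estimates a rank-(g-1) matrix.
  When `n_blocks < n_stats + 3` the full Q is unusable and the fitter
  automatically falls back to diagonal weighting (per-statistic variances),
  the classical least-squares mode of this model family.  At full scale
  (hundreds of blocks) the full covariance is used.

Reported metrics: `LL` = minimised q; `WR` = the worst residual, the largest
|observed - fitted| f4 deviation in jackknife-SE units, scanned over *all*
f4-statistics including f3/f2 specialisations.  SEs in the WR scan are
floored at 1e-7 of the largest statistic so that rounding residuals on
noise-free data do not masquerade as misfit.  By convention WR < 3 SE means
the model "fits".

`LL` is comparable across topologies of equal complexity on one dataset;
`WR`, being in SE units, grows with the amount of sequence: halving the
genome shrinks a bias signal's WR by about sqrt(2).  Scaled-down replications
therefore reproduce *directions* and *null results* faithfully but not
full-scale WR magnitudes (see Limitations).

### Exhaustive topology catalog

`enumerate_topologies(n_leaves, n_admix)` generates all rooted binary
leaf-labeled trees ((2n-3)!! of them, verified against a brute-force DAG
enumeration at 4 leaves) and inserts admixture events: a new admixture node
subdivides a destination edge and receives its second in-edge from an
existing node.  Graphs are deduplicated by color-aware directed-graph
isomorphism (BLISS canonical forms, leaf labels fixed).  Two admixture nodes
drawing from an identical parent pair span the same model space as a chained
configuration and are counted once, unless the two parents are joined by a
drift edge (there the events tap genuinely different genealogical points).
Published catalog sizes for this graph family do not state their
dedup convention; among the defensible conventions we explored (source
attached mid-edge vs. at a node; rooted vs. root-free; with or without
degenerate duplicate events) this is the one that reproduces the reference
count of 32,745 topologies for five leaves and two admixture events, and it
is fixed as the default.  Knobs expose the alternatives
(`source_attachment="edge"` gives the finer mid-edge convention: 78,510 at
(5,2)).

## Synthetic worlds

All data are simulated with msprime (binary mutation model, mutation rate
1.25e-8 and recombination rate 2e-8 per bp per generation, hybrid
discrete-time Wright-Fisher for the first 25 generations then standard
coalescent).  Chromosomes are independent replicates by default; the
single-simulation device with a log(2) per-bp boundary recombination rate is
available (`multi_chromosome="boundary"`).  Because the binary model has no
nucleotides, ancestral/derived allele labels are assigned cosmetically
(transition:transversion 2:1, A/T+G/C half of transversions) so that
mutation-class ascertainment schemes are exercisable; these labels carry no
genealogical signal, and tests of mutation-class schemes on simulated data
establish plumbing only.

* **Case study**: ape outgroup + two Neanderthals (sampled 3,790 and 1,700
  generations ago) + Denisovan (1,700) + two African + two non-African
  groups (10 diploids each at present), out-of-Africa bottleneck, optional
  archaic gene flow (default 2%) into the non-African ancestor via an
  unsampled proxy lineage, three 100 Mb chromosomes.  The published source
  of this design does not list its parameter values; the shipped defaults
  are a clearly-labeled calibrated stand-in (splits: ape 240k, archaic 18k,
  Denisovan/Neanderthal 12k generations; archaic Ne 2-2.5k, African Ne 20k,
  bottleneck Ne 1.5k) chosen to reproduce the qualitative FST structure of
  human data (African/non-African ~0.25, modern/archaic ~0.6-0.7,
  human/ape >0.85).  Any value can be overridden via a key=value parameter
  file.
* **Random graphs**: 8-9 tip populations plus an outgroup diverging at
  exactly 40,000 generations (Ne 100,000, or 1,000 in the drifted variant);
  4-5 pulses with proportions uniform in [0.10, 0.40]; other Ne uniform in
  [2,000, 40,000]; demographic events tied to topological levels separated
  by gaps uniform in [1,500, 8,000] generations (an emulation of the
  reference design's level-tied event placement, anchored to its stated
  parameter ranges rather than a port of its generator); samples of 10
  diploids per tip at the tip's terminal date, at the simulation root, and
  at the root of the non-outgroup populations.  Simulations are retained
  iff some pairwise tip FST is below 0.15.
* **Simple trees**: (O,(C,(A,B))), depth 4,000 generations, Ne 100,000,
  A-B split at 1,999 generations followed immediately by a bottleneck in A
  (factor 1-10,000); samples 25/25/25/10 (A reduced to 10 at factor
  10,000).  The C divergence time (3,000 generations) is not stated in the
  reference design and was fixed once, midway between the A-B split and the
  root.

Simulated genotypes are polarized by the simulator's known ancestral state;
re-polarization through an outgroup individual (`polarize`) exists for real
data.

## Bias metrics

`flipped_fractions` counts verdict flips at WR = 3 between an ascertained
and an all-sites fit table (rejected-under-ascertainment-but-accepted =
bias; the converse = power).  `trend_dispersion` fits OLS of ascertained on
baseline values (optionally through the origin, optionally restricted to
|Z| < 15) and reports residual SE and R^2.  `classify_bias` compares a
metric against its distribution across random site subsamples matched to
the ascertained panel's site count (exact matching rather than
"approximate"; 200 replicates and the 2.5th percentile by default, 10 and
the 10th percentile in the simulated-data variant); the inequality at the
threshold is strict.  `power_vs_incorrect` summarises fits of a set of
deliberately wrong topologies (median WR change and rejection-to-acceptance
flips); the wrong-graph sets are drawn from the exhaustive catalog by
baseline LL in [70, 300] — a documented substitution for a heuristic
topology search.

## What a green test does and does not establish

Green simulation tests establish: correctness of the estimators against
closed-form and brute-force oracles; recovery of true mixing proportions;
acceptance of true graphs on unascertained data; the cladality null under
ascertainment on clean trees; and the *direction* of ascertainment bias
(panels from root-like populations are benign, panels from root-drifted
co-modelled populations inflate WR of the true model).

They do not establish full-scale magnitudes: WR scales with sqrt(genome
length), so desk-scale runs (tens of Mb) cannot reach the WR medians of
300 Mb runs, and rejection *counts* at the 3 SE line are systematically
lower at reduced scale.  The pipeline accepts full-scale configs
(`ExperimentConfig(n_chromosomes=3, chromosome_length=1e8, ...)`) for
faithful replication on a larger budget.  The generator also does not
emulate: missing data (simulated calls are complete; group-level
missingness filters are exercised on constructed matrices), sequencing or
damage error, non-binary mutation, or linked selection.

## Numerical notes

* Seeds: one integer seed drives everything; sub-seeds are drawn from
  `numpy` Generators and kept below 2^31.
* Monomorphic sites are retained in matrices and contribute zero to
  f-statistics.
* MAF thresholds are strict (`> 0.05`); derived-tail removal keeps sites at
  exactly the threshold (`<= 0.95`).  Pooled frequencies weight every
  non-missing chromosome equally (allele-count pooling across the group
  union).
* A site enters a pair's f2 only if both populations have >= 2 non-missing
  chromosomes there; an optional `min_allele_count` flag reproduces the
  stricter real-data setting.
* Block assignment: site at 1-based position p -> local block
  floor((p-1)/block_size), renumbered globally, empty blocks dropped.
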