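# Methods

This note documents the models, estimators and numerical choices behind
`imcoal`, in the spirit of the methods documentation that accompanies
population-genetic inference packages. It describes what each component
assumes, which knobs matter, and what the synthetic-data generator does and
does not emulate.

## The two-population isolation–migration model

The core object is a continuous-time Markov chain over the locations of the
two ancestral lineages of a sampled pair of haplotypes. Two demes with
diploid effective sizes `N1(t)` and `N2(t)` exchange migrants at a symmetric
per-lineage probability `m(t)` per generation; both size trajectories and
the migration rate are piecewise constant on a time grid. The four states
are both-lineages-in-deme-1, both-in-deme-2, one-in-each (SPLIT), and
COALESCED (absorbing). Coalescence occurs at rate `1/(2N)` when both
lineages occupy a deme of diploid size `N` — the standard diploid
correspondence between effective size and pairwise coalescence rate, used
as the N↔λ dictionary throughout the package. Off-diagonal generator rates
are `2m` out of a same-deme state into SPLIT (either lineage may migrate)
and `m` from SPLIT into each same-deme state.

Survival curves and time-binned coalescence hazards follow from per-epoch
matrix exponentials chained from the present. The 3×3 transient
sub-generator is reversible with respect to the weights (1, 1, 2), so the
exponentials are computed by symmetrized eigendecomposition (batched
`eigh`) — stable and exact, with no Monte-Carlo error. Survival below
1e-250 is treated as underflow; hazards beyond that point are reported as
undefined (NaN), never silently zero.

The cumulative migration probability is defined as

    M(t) = 1 − exp(−2 ∫₀ᵗ m(u) du),

the probability that at least one lineage of a cross-population pair has
switched demes by `t`. The factor 2 reflects the two independently
migrating lineages; this convention is documented here because the
threshold semantics built on M — `M(t) < 0.5` for the median split time,
`M < 0.99` and `M < 0.999` for initial divergence — are what downstream
statistics use. When a grid starts after t = 0 the first interval's rate is
extended back to the present so that M keeps its absolute meaning.

Time is calibrated with a mutation rate of 7.1e-9 per bp per generation and
a generation time of 2 years (the calibration with the best alignment of
inferred events against the glacial–interglacial chronology for this
system). Mutation-scaled inputs convert as `t_gen = t_scaled / mu` and
`N = 1/(2 mu lambda_scaled)`.

## Fitting the model to coalescence-rate curves

The data are three hazard curves on a shared grid: within-population-1,
within-population-2 and cross-population, either read from MSMC2-style
tables or estimated from simulated coalescence times by occurrence/exposure.
The fit places one free epoch per grid interval (`im_N1`, `im_N2`, `m`) and
minimizes a weighted least-squares objective in log-hazard space,

    Σ w_ck (log(h_model + ε) − log(h_obs + ε))²
      + β_m Σ (m_k / m_ref)² + β_N Σ (ΔN_k / N_{k−1})²   (both populations)
      + w_N Σ (Δlog10 N_k)²,

with box bounds (N in [10, 1e7], m in [1e-12, 0.5]) on log10-transformed
parameters. Design choices, in order of importance:

* **Inverse-variance weights with an overdispersion cap.** A log-hazard
  estimated from `n` coalescences has sampling variance ≈ 1/n; the
  piecewise model on a log grid additionally carries a discretization error
  floor, so `w = 1/(1/n + σ_model²)` with `σ_model = 0.05`. This puts the
  objective on an approximate chi-square scale (which calibrates the
  isolation support screen below) while preventing the highest-count cells
  from amplifying discretization error into parameter distortions. Exact
  model curves (no counts) get unit weights.
* **Regularization.** The migration ridge `β_m = 1e-8` and size-smoothness
  `β_N = 1e-6` follow the recommended values for this model class; the
  ridge is measured against `m_ref = 1e-5` so both terms are dimensionless.
  At these weights the terms are tie-breakers, not active smoothing. The
  additional log-space smoothness `w_N = 3.0` on the sizes is this
  package's own stabilizer: once lineages are fully mixed the three curves
  collapse onto a single constraint and (N1, N2, m) ride a flat
  manifold — the smoothness term keeps sizes on the last identified values
  there instead of letting them chase sampling noise. Migration is *not*
  smoothed: genuine shut-offs are order-of-magnitude steps.
* **Observation mask.** Intervals with undefined hazards (no exposure),
  zero observed events, or observed hazards below 1e-8 per generation
  (below the representable range given the size bounds) carry no usable
  signal and are excluded from the residual.

### Optimization

The likelihood surface is multimodal: a bottleneck-with-isolation history
and a large-size-escape history can fit the same noisy curves almost
equally well. The fit therefore runs in structured phases rather than a
single descent:

1. **Warm start.** Sizes from `N = 1/(2 λ_within)`; migration from the
   relative cross-coalescence rate `rCCR = 2λ12/(λ11+λ22)`, which estimates
   the *cumulative* M(t), so initial per-interval rates are increments of
   `−½ log(1 − rCCR)` (made non-decreasing first; saturated stretches carry
   the last identified rate forward).
2. **Sequential pass.** Young to old, the lineage-state occupancy is
   propagated and each interval's three parameters are solved from that
   interval's hazards given the inherited occupancy, with a continuation
   anchor toward the previous interval (weight `w_N` in log10² units).
   This mirrors the Markov structure of the model and is extremely stable
   for the sizes.
3. **Migration phase.** The per-interval migration signal is non-local (it
   lives in the future cross-coalescence of still-unmixed pairs), so `m` is
   re-optimized against the full objective with the sizes frozen, by
   L-BFGS-B with an analytic-cost Jacobian that reuses cached per-epoch
   matrix exponentials. Freezing the sizes removes the N-versus-m
   compensation that makes the joint problem multimodal. One
   sequential-rebuild/migration-phase alternation (`n_cycles = 2`) follows.
4. **Isolation-hypothesis candidates.** Bottleneck entries announce
   themselves as die-off spikes — a multi-fold jump of a within-population
   hazard to above the curve's median from a baseline level (the gates
   separate entries from post-glacial recontact rebounds, which jump out of
   a deep hole instead). Each spike seeds candidate refits with migration
   pinned below the isolation threshold at the spike interval or the one
   just older (a log grid rarely aligns with the true shut-off; the older
   neighbour tends to lie fully inside the isolation). Candidates rebuild
   sizes under the pinned migration and re-refine. The best candidate
   replaces the base fit if it comes within `isolation_tiebreak = 2`
   chi-square units: between near-observationally-equivalent histories with
   and without migration, the fit prefers the migration-free one, matching
   the migration-ridge convention of the model class it reimplements. The
   spike gate means smooth (connected) histories are never probed, so
   fully-mixed flat stretches cannot acquire spurious isolation this way.
5. **Isolation support screen.** Any remaining run of intervals with
   fitted m below 1e-7 (outside an adopted candidate) is profile-tested:
   refit with those rates bounded at 1e-6 ("not isolated"); if the
   constrained objective comes within `6 + 2(dof−1)` of the free optimum
   the data do not support the isolation claim and the constrained solution
   is adopted. Genuine shut-offs degrade the constrained fit by orders of
   magnitude and always survive.

All phases are deterministic given the configuration; two identical inputs
produce bitwise-identical trajectories.

### Run acceptance

A "failure" epoch is one whose fitted size sits at a box bound; sizes
oscillating between both bounds across two or more failures discard the
run. Any failure disqualifies a run for initial-divergence estimates; a
failure inside the Holocene (fixed at 11,700 years) disqualifies it for
split times; current-N_E is always accepted because, by the Markov property
of the chain, ancient epochs cannot distort the most recent coalescence
rates. `im_N1` is the size conventionally reported as historical N_E; both
sizes are always stored.

## Derived trajectory statistics

Threshold crossings of M(t) are interpolated linearly in log-time (matching
the logarithmic grids); crossings pinned to the first or last grid interval
are flagged as at-resolution-limit. Isolation events are maximal runs of
intervals with `m < 1e-7` per generation, summarized by their midpoints;
event-midpoint histograms over replicate or bootstrap trajectories use a
common 80-point log grid by default.

Pattern classification evaluates the window from the end of the LGM
(17 ka) to the old edge of MIS 10 (374 ka). CORE requires historical N_E
(im_N1) at or above 20,000 everywhere in the window and no isolation event
with midpoint inside it. A trajectory is PERIPHERAL when the window holds
an isolation event or a bottleneck — N_E dropping by at least 90% against
its running pre-decline maximum, scanned from both window ends because
glacial bottlenecks sit between interglacial highs and the data resolve the
young side much better than the old side. The STRONG sub-label names the
glacial period (PGP before MIS 8) containing the evidence; bottleneck
minima are interval-valued (every interval within 5% of the minimum counts,
and an interval lies in a period when it overlaps it — behind a deep crash
the fit loses resolution and the minimum smears onto a flat stretch), event
midpoints are point-valued. The 90% bottleneck depth is a permissive floor
under the 96–98% declines quantified for the range-edge populations; MIS 8
defaults to 300–243 ka and MIS 10 to 374–337 ka (standard marine-isotope
chronology). All windows are configurable.

Percentile envelopes across replicate trajectories resample each step
function onto a common 80-point log grid and take empirical percentiles
(linear-interpolation convention) — the median, the 12.5–87.5% inner band
and the 2.5–97.5% outer band — in log space for m (zeros floored at 1e-12)
and linear scale for N_E, then smooth with monotonicity-preserving PCHIP
interpolation in log–log space without extrapolation beyond the common
span.

Group comparisons gate on Shapiro–Wilk normality (α = 0.05 in both groups):
t-test when both pass, otherwise the Wilcoxon rank-sum (exact enumeration
for small tie-free samples). Benjamini–Hochberg adjustment is applied
across a supplied family of comparisons.

## The synthetic-data generator

TMRCA-level simulation deliberately replaces sequence-level input: the
haplotype HMM that produces coalescence-rate curves from real genomes is
out of scope, and simulating genealogies directly gives exact ground truth
for the layers this package does implement. The simulator draws exponential
waiting times at per-epoch constant rates (restarting at epoch boundaries,
which is exact by memorylessness) in a compiled per-draw loop; censoring at
a horizon is recorded, and an isolated pair with no remaining migration is
censored rather than looped forever. Draws carry block labels so the
block bootstrap can resample 30 blocks with replacement, 100 times, with
the same blocks across all three curves — the structure of the 30 × 1 Mb
design it emulates. Blocks are exchangeable TMRCA pools rather than literal
sequence windows; there is no recombination model within blocks and full
independence across blocks.

What passing tests on this generator do **not** show about real data:
hazards estimated from an HMM over phased haplotypes carry correlated,
segment-structured errors rather than independent Poisson noise; real
genomes add phasing/imputation error, linked selection and mappability
masks. The generator isolates the inference layers from all of that by
construction.

Scenario presets encode the study's demographic regimes: a stable "core"
history (N = 25,000 both demes, m = 2e-5, back to 450 ka, ancestral size
15,000 beyond), "peripheral" histories adding a 95% bottleneck with
migration shut off inside the PGP (190–130 ka) or MIS 8 (300–243 ka)
windows, a Holocene split (migration ends 5,000 generations ago), and an
Arctic-style preset with post-split crashes of 98.3% and 96.0% relative to
the thermal-maximum peak. The stable sizes and rates are synthetic choices
consistent with the core pattern's floor of 20,000; the bottleneck depth is
a synthetic choice consistent with "strong" glacial bottlenecks; every
number carries a provenance note in the preset.

Genotype panels draw ancestral frequencies uniform on [0.05, 0.95],
regional frequencies from a Balding–Nichols Beta with the region's F_ST,
and genotypes with a within-region inbreeding coefficient F (P(het) =
2pq(1−F)). Planted-ROH panels lay SNPs at jittered spacing, make genotypes
heterozygous with probability 0.5 outside the planted segments and
homozygous inside (apart from a configurable error rate), and retain the
truth for recovery scoring.

## Genotype-level statistics

Runs of homozygosity follow the scanning-window algorithm of the standard
tool with the study's parameters: 35-SNP windows with at most 1
heterozygous and 5 missing calls, per-SNP hit rate over overlapping windows
at threshold 0.05, runs split at gaps above 500 kb, and segments reported
at ≥ 50 kb, ≥ 35 SNPs and at least 1 SNP per 100 kb. Parameters not named
by the study take the tool's documented defaults. F_ROH divides the summed
segment lengths by the fixed genome length 219,291,370 bp (centromeres
included). Coordinates are 1-based inclusive and segment length is
end − start + 1.

F_IS is the method-of-moments per-sample F — (O_hom − E_hom)/(L − E_hom)
with per-site expected heterozygosity `2pq·2n/(2n−1)` from regional allele
frequencies — summarized as the regional median (regional medians are the
reporting convention throughout), and requires at least four samples per
region. Nucleotide diversity is the unbiased mean pairwise difference
`2pq·nh/(nh−1)` per site, averaged over a caller-supplied mask or callable
denominator; it depends on allele frequencies only and is therefore
invariant to selfing at fixed frequencies. Regional differentiation uses
the Weir–Cockerham variance-components estimator weighted across sites
(ratio of summed components), with optional seeded subsampling of five
samples per region. The site filter is the exact one-sided
Hardy–Weinberg test for heterozygote *excess* (conditional enumeration
given allele counts, parity-matched heterozygote counts, no mid-p): a site
is removed when p < 0.01 in any regional sample set; homozygote excess
never removes a site (a self-compatible species is expected to be
homozygote-rich).

## Geography

Regions are summarized by arithmetic mean coordinates; distances are
great-circle (haversine, R = 6371 km — the formula itself is a
documented choice). Isolation by distance is the plain Pearson correlation
of pairwise distance against pairwise F_ST within the western cluster,
within the eastern cluster, and between clusters, with named outlier
regions excluded; no Mantel-style permutation is applied (a permutation
option is left to the user). Climate association is the Pearson
correlation of the eastern admixture proportion against each of 19
bioclimatic variables with Bonferroni correction at family size 19.

## Problem sizes and numerical settings

The working grid is 42 log-spaced boundaries over 1,000–500,000 generations
(2 ka to 1 Ma at 2 years per generation). The upper edge reflects that
nothing in the study window is older than 450 ka; the lower edge reflects
that below ~1,000 generations cross-coalescence hazards are unobservably
small at any realistic draw count; and 42 boundaries place at least one
full interval inside each of the PGP and MIS 8 windows, the minimum
resolution required to date isolation events to those periods. Whole-genome
analogue runs use 1e6 TMRCA draws per curve, emulating the information
content of genome-scale haplotype data; bootstrap replicates use 3e5 draws
split into 30 blocks. End-to-end fits take a few seconds each on one CPU.

Known limitations: only two demes with symmetric migration; fitted sizes
beyond the full-mixing horizon are continuation values, not measurements;
per-interval migration is identified through its cumulative effect, so
event boundaries are only resolved to about one grid interval; deep
bottlenecks starve the older side of data, and the post-bottleneck sizes
can sit at bounds (such runs are exactly what the run-acceptance rules
flag).
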