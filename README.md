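# imcoal

Isolation–migration demographic inference from coalescence-rate curves,
with a built-in structured-coalescent simulator and the population-genetic
summary statistics used alongside it.

## The scientific problem

How did a species' populations respond to Pleistocene glacial–interglacial
cycles — did they persist as large, connected "core" populations, or
repeatedly fragment into isolated "peripheral" refugia with glacial
bottlenecks and interglacial recontact? Sequentially Markovian coalescent
methods (MSMC2 and relatives) turn pairs of genomes into time-resolved
coalescence-rate curves; fitting a two-population isolation–migration (IM)
model to those curves yields the historical effective population sizes
`im_N1(t)`, `im_N2(t)` and the symmetric migration rate `m(t)`, from which
divergence chronologies and demographic-pattern classifications follow.
`imcoal` implements that inference chain for researchers who want a tested,
self-contained version of it: the forward model, the fit, the derived
statistics, and a simulator that provides exact ground truth for all of it.

## The model

The ancestry of a sampled pair of haplotypes is a continuous-time Markov
chain over the locations of its two lineages in two demes: states
both-in-1, both-in-2, one-in-each, coalesced. With piecewise-constant
diploid sizes and symmetric per-lineage migration `m` per generation, the
transition rates are `2m` (same-deme → split), `m` (split → same-deme) and
`1/(2N)` (same-deme → coalesced). Chained matrix exponentials give exact
survival curves and time-binned coalescence hazards λ₁₁, λ₁₂, λ₂₂ — the
model-side analogue of MSMC2 output. The cumulative migration probability

    M(t) = 1 − exp(−2 ∫₀ᵗ m(u) du)

carries the divergence semantics: the median split time of a pair of
populations is the youngest time with `M(t) ≥ 0.5`; initial divergence is
dated by the `M < 0.999` and `M < 0.99` crossings; an isolation event is a
maximal stretch with `m < 10⁻⁷` per generation. Times are calibrated with
μ = 7.1×10⁻⁹ per bp per generation and a 2-year generation time.

Alongside the IM chain the package implements the genotype-level statistics
of such studies with their exact parameterizations: PLINK-style runs of
homozygosity and F_ROH (genome length 219,291,370 bp), vcftools-style F_IS,
nucleotide diversity π, weighted Weir–Cockerham F_ST, the exact one-sided
Hardy–Weinberg heterozygote-excess site filter (p < 0.01 per region), and
isolation-by-distance / bioclimatic correlations.

See `docs/methods.md` for the full model description, estimator design and
numerical choices.

## Worked example

Simulate genome-scale coalescence data under the "peripheral" scenario — a
95% bottleneck with migration shut off during the Penultimate Glacial
Period (190–130 ka) — then fit the IM model and read off the story:

```python
import numpy as np
from imcoal import (TimeGrid, ScalingConfig, scenario, simulate_rate_curves,
                    fit_im, split_time, isolation_events, classify_pattern)

grid = TimeGrid.log_spaced(42, 1000, 5e5)   # 2 ka .. 1 Ma at g = 2
scaling = ScalingConfig()                   # mu = 7.1e-9, g = 2 years

preset = scenario("peripheral_pgp")
rates, draws = simulate_rate_curves(preset.history, grid, n=1_000_000, seed=7)
traj, diag = fit_im(rates)

label = classify_pattern(traj, scaling)
print(f"pattern: {label.label}")
print(f"minimum N_E in the glacial window: "
      f"{label.evidence['min_ne_window']:.0f}")
for e in isolation_events(traj, scaling):
    print(f"isolation event: {e.start_years/1e3:.0f}-{e.end_years/1e3:.0f} ka "
          f"(midpoint {e.midpoint_years/1e3:.0f} ka, min m = {e.min_m:.1e})")
```

prints

```
pattern: PERIPHERAL_STRONG_PGP
minimum N_E in the glacial window: 4169
isolation event: 139-162 ka (midpoint 151 ka, min m = 9.9e-09)
```

The fit has recovered the planted regime: the trajectory classifies as a
strong peripheral pattern anchored on the PGP, the effective size collapses
inside the glacial window, and the fitted migration rate drops below the
10⁻⁷ isolation threshold across an interval whose midpoint (151 ka) dates
the event inside the 190–130 ka window. A `core` preset run (same seed)
instead returns `CORE` with a window minimum N_E of 24,691 and no isolation
events, and the `holocene_split` preset — migration ending 5,000
generations ago — yields a fitted median split time of 16.3 ka against the
16.9 ka closed form of its `M < 0.5` crossing.

The same operations run from the shell: `imcoal simulate`, `imcoal rates`,
`imcoal fit-im`, `imcoal traj-stats`, `imcoal genome-stats` and
`imcoal geo-stats` chain the pipeline over MSMC2-style rate tables,
estimate files and VCFs (see `imcoal --help`).

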