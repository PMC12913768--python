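"""Genotype-level population-genetic statistics.

Implements the exact parameterizations used in the study's variant-level
analyses:

* PLINK-style scanning-window detection of runs of homozygosity (35-SNP
  windows, at most 1 heterozygote per window, 50 kb minimum length, 500 kb
  maximum gap, 1 SNP / 100 kb minimum density) and the genomic inbreeding
  coefficient F_ROH over a fixed genome length of 219,291,370 bp;
* vcftools-style per-sample F (method-of-moments heterozygote deficit) with
  regional medians as the reported F_IS, requiring at least four samples;
* nucleotide diversity pi (unbiased mean pairwise difference per site);
* the Weir-Cockerham weighted F_ST estimator (ratio of summed variance
  components) with optional fixed-size subsampling per region;
* the exact one-sided Hardy-Weinberg test for heterozygote EXCESS used as a
  site filter (alpha 0.01 within any region; homozygote excess never
  removes a site);
* per-sample heterozygosity.

Coordinates are 1-based inclusive (VCF convention); segment length is
end - start + 1.  Genotypes are alt-allele dosages 0/1/2 with -1 missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np

from .coalsim import GenotypePanel

__all__ = [
    "GENOME_LENGTH_BP",
    "RohParams",
    "RohSegment",
    "detect_roh",
    "f_roh",
    "f_is",
    "nucleotide_diversity",
    "weighted_fst",
    "hwe_exact_excess_p",
    "hwe_het_filter",
    "sample_heterozygosity",
]

#: Reference genome length (bp, centromeres included) used for F_ROH.
GENOME_LENGTH_BP = 219_291_370


@dataclass(frozen=True)
class RohParams:
    """PLINK-style ROH scan parameters.

    The five named study parameters: window/segment size 35 SNPs, at most 1
    heterozygote per scanning window, 50 kb minimum segment length, 500 kb
    maximum gap, 100 kb/SNP maximum inverse density.  ``hit_threshold`` and
    ``max_missing_per_window`` take the scanning tool's documented defaults.
    """

    window_snps: int = 35
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    min_snps: int = 35
    min_length_kb: float = 50.0
    max_gap_kb: float = 500.0
    max_inverse_density_kb_per_snp: float = 100.0
    hit_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("window_snps", "min_snps", "min_length_kb", "max_gap_kb",
                     "max_inverse_density_kb_per_snp", "hit_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("window allowances must be non-negative")


@dataclass(frozen=True)
class RohSegment:
    """One run of homozygosity (1-based inclusive bp coordinates)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


# ---------------------------------------------------------------------------
# ROH detection
# ---------------------------------------------------------------------------

def detect_roh(panel: GenotypePanel, params: RohParams | None = None
               ) -> list[RohSegment]:
    """PLINK-style scanning-window ROH detection.

    A window of ``window_snps`` consecutive SNPs is homozygous when it holds
    at most ``max_het_per_window`` heterozygous and at most
    ``max_missing_per_window`` missing calls.  Each SNP's hit rate is the
    fraction of existing overlapping windows that are homozygous; SNPs at or
    above ``hit_threshold`` form candidate runs.  Runs are split at
    adjacent-SNP gaps above ``max_gap_kb`` and reported when they satisfy
    the length, SNP-count and density requirements.
    """
    params = params or RohParams()
    segments: list[RohSegment] = []
    for ci, chrom in enumerate(_unique_keep_order(panel.chroms)):
        site_idx = np.flatnonzero(panel.chroms == chrom)
        pos = panel.positions[site_idx]
        for si, sample in enumerate(panel.samples):
            gt = panel.genotypes[site_idx, si]
            segments.extend(
                _roh_one_sequence(sample, str(chrom), pos, gt, params))
    return segments


def _unique_keep_order(arr) -> list:
    seen: dict = {}
    for x in arr:
        seen.setdefault(x, None)
    return list(seen)


def _candidate_mask(gt: np.ndarray, params: RohParams) -> np.ndarray:
    """Per-SNP candidate flags from the scanning-window hit rates."""
    n = gt.size
    W = params.window_snps
    if n < W:
        return np.zeros(n, dtype=bool)
    het = (gt == 1).astype(np.int64)
    mis = (gt == -1).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmis = np.concatenate([[0], np.cumsum(mis)])
    starts = np.arange(n - W + 1)
    win_ok = ((chet[starts + W] - chet[starts] <= params.max_het_per_window)
              & (cmis[starts + W] - cmis[starts]
                 <= params.max_missing_per_window))
    # windows covering SNP i start in [i - W + 1, i] clipped to valid range
    cok = np.concatenate([[0], np.cumsum(win_ok.astype(np.int64))])
    i = np.arange(n)
    lo = np.clip(i - W + 1, 0, n - W)
    hi = np.minimum(i, n - W)
    n_windows = hi - lo + 1
    n_hom = cok[hi + 1] - cok[lo]
    return n_hom / n_windows >= params.hit_threshold


def _roh_one_sequence(sample: str, chrom: str, pos: np.ndarray,
                      gt: np.ndarray, params: RohParams) -> list[RohSegment]:
    cand = _candidate_mask(gt, params)
    max_gap_bp = params.max_gap_kb * 1000.0
    segments: list[RohSegment] = []
    n = gt.size
    k = 0
    while k < n:
        if not cand[k]:
            k += 1
            continue
        j = k
        while (j + 1 < n and cand[j + 1]
               and pos[j + 1] - pos[j] <= max_gap_bp):
            j += 1
        length = int(pos[j] - pos[k] + 1)
        n_snps = j - k + 1
        density_ok = (length / n_snps
                      <= params.max_inverse_density_kb_per_snp * 1000.0)
        if (length >= params.min_length_kb * 1000.0
                and n_snps >= params.min_snps and density_ok):
            segments.append(RohSegment(
                sample=sample, chrom=chrom, start=int(pos[k]),
                end=int(pos[j]), n_snps=n_snps,
                n_het=int(np.sum(gt[k:j + 1] == 1))))
        k = j + 1
    return segments


def f_roh(segments: list[RohSegment],
          genome_length: int = GENOME_LENGTH_BP) -> dict[str, float]:
    """F_ROH per sample: total ROH length divided by the genome length."""
    totals: dict[str, int] = {}
    for seg in segments:
        totals[seg.sample] = totals.get(seg.sample, 0) + seg.length_bp
    return {sample: total / genome_length for sample, total in totals.items()}


# ---------------------------------------------------------------------------
# Inbreeding and diversity
# ---------------------------------------------------------------------------

def f_is(panel: GenotypePanel, region: str
         ) -> tuple[dict[str, float], float]:
    """Per-sample method-of-moments F and the regional median F_IS.

    For each sample, F = (O_hom - E_hom) / (L - E_hom) where E_hom sums the
    per-site expected homozygosity 1 - 2*p*q * (2n / (2n - 1)) computed from
    the region's allele frequencies (n = non-missing diploids at the site).
    Requires at least four samples in the region.
    """
    cols = panel.region_columns(region)
    if cols.size < 4:
        raise ValueError(
            f"region {region!r} has {cols.size} samples; F_IS requires at "
            "least four samples from the same region")
    G = panel.genotypes[:, cols]
    valid = G >= 0
    n_dip = valid.sum(axis=1)
    alt = np.where(valid, G, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_dip > 0, alt / (2.0 * n_dip), np.nan)
        corr = np.where(n_dip > 1, 2.0 * n_dip / (2.0 * n_dip - 1.0), np.nan)
    e_het_site = 2.0 * p * (1.0 - p) * corr
    usable = (n_dip > 1) & np.isfinite(e_het_site)

    out: dict[str, float] = {}
    for local, col in enumerate(cols):
        g = G[:, local]
        ok = usable & (g >= 0)
        L = int(ok.sum())
        e_hom = float(np.sum(1.0 - e_het_site[ok]))
        o_hom = float(np.sum((g[ok] == 0) | (g[ok] == 2)))
        denom = L - e_hom
        out[panel.samples[col]] = (o_hom - e_hom) / denom if denom != 0 else np.nan
    regional = float(np.median([v for v in out.values() if np.isfinite(v)]))
    return out, regional


def nucleotide_diversity(panel: GenotypePanel, region: str,
                         site_mask: np.ndarray | None = None,
                         n_callable: int | None = None) -> float:
    """Regional nucleotide diversity pi per site.

    Per site, the unbiased mean pairwise difference 2*p*q * nh/(nh - 1) with
    nh the number of called haplotypes; averaged over the masked sites, or
    divided by ``n_callable`` when a callable-site denominator is given
    (e.g. total intergenic sites).
    """
    cols = panel.region_columns(region)
    G = panel.genotypes[:, cols]
    if site_mask is None:
        site_mask = np.ones(panel.n_sites, dtype=bool)
    G = G[site_mask]
    valid = G >= 0
    nh = 2.0 * valid.sum(axis=1)
    alt = np.where(valid, G, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nh > 0, alt / nh, 0.0)
        per_site = np.where(nh > 1, 2.0 * p * (1.0 - p) * nh / (nh - 1.0), 0.0)
    denom = n_callable if n_callable is not None else per_site.size
    if denom == 0:
        raise ValueError("no sites to average over")
    return float(per_site.sum() / denom)


def sample_heterozygosity(panel: GenotypePanel) -> dict[str, float]:
    """Fraction of heterozygous calls among non-missing calls per sample."""
    out: dict[str, float] = {}
    for si, sample in enumerate(panel.samples):
        g = panel.genotypes[:, si]
        called = g >= 0
        out[sample] = (float(np.sum(g[called] == 1) / called.sum())
                       if called.any() else np.nan)
    return out


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def weighted_fst(panel: GenotypePanel, region_a: str, region_b: str,
                 subsample_n: int | None = None,
                 seed: int | None = None) -> float:
    """Weir-Cockerham weighted theta between two regions.

    The 1984 variance-components estimator: per-site components a (among
    populations), b (among individuals within populations) and c (within
    individuals), combined across sites as sum(a) / sum(a + b + c).
    ``subsample_n`` draws a fixed number of samples per region (seeded), the
    design used for regional pairs in the study (N = 5).
    """
    rng = np.random.default_rng(seed)
    cols = []
    for region in (region_a, region_b):
        c = panel.region_columns(region)
        if subsample_n is not None:
            if c.size < subsample_n:
                raise ValueError(
                    f"region {region!r} has {c.size} samples < subsample "
                    f"{subsample_n}")
            c = rng.choice(c, size=subsample_n, replace=False)
        cols.append(np.sort(c))

    Ga = panel.genotypes[:, cols[0]]
    Gb = panel.genotypes[:, cols[1]]
    a_sum = 0.0
    abc_sum = 0.0
    r = 2.0
    for k in range(panel.n_sites):
        comp = _wc_site_components(Ga[k], Gb[k], r)
        if comp is not None:
            a, b, c = comp
            a_sum += a
            abc_sum += a + b + c
    if abc_sum == 0.0:
        raise ValueError("no polymorphic sites with data in both regions")
    return float(a_sum / abc_sum)


def _wc_site_components(ga: np.ndarray, gb: np.ndarray, r: float):
    """Weir-Cockerham (a, b, c) for one biallelic site, two populations."""
    ga = ga[ga >= 0]
    gb = gb[gb >= 0]
    n1, n2 = ga.size, gb.size
    if n1 < 2 or n2 < 2:
        return None
    p1 = ga.sum() / (2.0 * n1)
    p2 = gb.sum() / (2.0 * n2)
    h1 = np.mean(ga == 1)
    h2 = np.mean(gb == 1)
    n_bar = (n1 + n2) / r
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    if p_bar <= 0.0 or p_bar >= 1.0:
        return None  # monomorphic across both regions
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
    s2 = (n1 * (p1 - p_bar)**2 + n2 * (p2 - p_bar)**2) / ((r - 1.0) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    pq = p_bar * (1.0 - p_bar)
    a = (n_bar / n_c) * (s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0)
                         / (n_bar - 1.0))
    b = (n_bar / (n_bar - 1.0)) * (pq - (r - 1.0) / r * s2
                                   - (2.0 * n_bar - 1.0)
                                   / (4.0 * n_bar) * h_bar)
    c = h_bar / 2.0
    return a, b, c


# ---------------------------------------------------------------------------
# Exact HWE heterozygote-excess filter
# ---------------------------------------------------------------------------

def hwe_exact_excess_p(n_het: int, n_alt_alleles: int, n_diploids: int
                       ) -> float:
    """Exact one-sided p for heterozygote EXCESS, conditional on allele
    counts.

    Enumerates the conditional (Levene) distribution of the heterozygote
    count given the minor/major allele counts — heterozygote counts share
    the parity of the rarer allele count — and sums the probabilities of
    outcomes at least as heterozygous as observed.  No mid-p correction.
    """
    n = n_diploids
    n_a = n_alt_alleles
    n_b = 2 * n - n_a
    if min(n_a, n_b) == 0:
        return 1.0  # monomorphic: test skipped
    h_max = min(n_a, n_b)
    h_min = n_a % 2
    hs = np.arange(h_min, h_max + 1, 2)
    log_w = np.array([
        lgamma(n + 1) - lgamma((n_a - h) / 2 + 1) - lgamma(h + 1)
        - lgamma((n_b - h) / 2 + 1) + h * np.log(2.0)
        for h in hs
    ])
    w = np.exp(log_w - log_w.max())
    probs = w / w.sum()
    return float(probs[hs >= n_het].sum())


def hwe_het_filter(panel: GenotypePanel, alpha: float = 0.01
                   ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Heterozygote-excess site filter across regional sample sets.

    Per site and region, the exact one-sided test above; a site is removed
    when p < alpha in ANY region.  Monomorphic sites score p = 1 in that
    region; homozygote excess never triggers removal (the test is one-sided
    toward heterozygote excess by construction).  Returns the retained-site
    boolean mask and the per-region p-value arrays.
    """
    regions = _unique_keep_order(panel.regions)
    p_by_region: dict[str, np.ndarray] = {}
    removed = np.zeros(panel.n_sites, dtype=bool)
    for region in regions:
        cols = panel.region_columns(region)
        G = panel.genotypes[:, cols]
        valid = G >= 0
        n_dip = valid.sum(axis=1)
        n_alt = np.where(valid, G, 0).sum(axis=1)
        n_het = (G == 1).sum(axis=1)
        p = np.ones(panel.n_sites)
        for k in range(panel.n_sites):
            if n_dip[k] >= 1:
                p[k] = hwe_exact_excess_p(int(n_het[k]), int(n_alt[k]),
                                          int(n_dip[k]))
        p_by_region[str(region)] = p
        removed |= p < alpha
    return ~removed, p_by_region
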