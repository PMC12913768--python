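"""Derived statistics on fitted isolation-migration trajectories.

Everything downstream of the fit lives here: split times and initial
divergence times from threshold crossings of the cumulative migration
probability M(t), isolation events (runs of near-zero migration) and their
midpoint histograms, core/peripheral pattern classification against the
named glacial windows, percentile envelopes across replicate trajectories,
time-unit conversions, and the group-comparison tests used when contrasting
populations.

Conventions:

* M(t) < 0.5 defines the median split time; M(t) < 0.99 / 0.999 define
  initial divergence (the oldest detectable onset of separation).
* an isolation event is a maximal run of grid intervals with m below 1e-7
  per generation, summarized by its midpoint;
* threshold crossings are interpolated linearly in log-time, matching the
  logarithmic grids the trajectories live on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.interpolate import PchipInterpolator

from .im_fit import IMTrajectory
from .im_model import ScalingConfig, TimeGrid

__all__ = [
    "PeriodCatalog",
    "IsolationEvent",
    "PatternLabel",
    "EnvelopeSummary",
    "CrossingResult",
    "split_time",
    "initial_divergence_times",
    "isolation_events",
    "isolation_frequency_histogram",
    "classify_pattern",
    "envelope",
    "generations_to_years",
    "scaled_time_to_generations",
    "scaled_lambda_to_size",
    "scale_times",
    "compare_groups",
    "adjust_bh",
    "GroupComparison",
]

#: Migration threshold defining an isolation event (per generation).
ISOLATION_M_THRESHOLD = 1e-7


@dataclass(frozen=True)
class PeriodCatalog:
    """Named geological windows in years before present (young, old).

    Defaults: LGM 22-17 ka, PGP 190-130 ka, MIS 3 59-29 ka, MIS 2 29-14 ka,
    HTM 9-4 ka; MIS 8 and MIS 10 follow the standard marine-isotope
    chronology and are configurable.
    """

    periods: dict = field(default_factory=lambda: {
        "LGM": (17_000.0, 22_000.0),
        "PGP": (130_000.0, 190_000.0),
        "MIS3": (29_000.0, 59_000.0),
        "MIS2": (14_000.0, 29_000.0),
        "HTM": (4_000.0, 9_000.0),
        "MIS8": (243_000.0, 300_000.0),
        "MIS10": (337_000.0, 374_000.0),
    })

    def __post_init__(self) -> None:
        for name, (young, old) in self.periods.items():
            if not young < old:
                raise ValueError(f"period {name!r} must be (young, old)")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.periods[name]

    def contains(self, name: str, years: float) -> bool:
        young, old = self.periods[name]
        return young <= years <= old

    @property
    def classification_window(self) -> tuple[float, float]:
        """[end of LGM, old edge of MIS 10] in years."""
        return (self.periods["LGM"][0], self.periods["MIS10"][1])


@dataclass(frozen=True)
class IsolationEvent:
    """Maximal run of grid intervals with migration below threshold."""

    start_years: float
    end_years: float
    min_m: float

    def __post_init__(self) -> None:
        if not self.start_years < self.end_years:
            raise ValueError("event start must precede end")

    @property
    def midpoint_years(self) -> float:
        return 0.5 * (self.start_years + self.end_years)


@dataclass(frozen=True)
class PatternLabel:
    """Demographic-pattern classification with its triggering evidence."""

    label: str  # CORE / PERIPHERAL_STRONG_PGP / PERIPHERAL_STRONG_MIS8 /
    # PERIPHERAL_OTHER / UNCLASSIFIED
    evidence: dict = field(default_factory=dict)


@dataclass
class EnvelopeSummary:
    """Median and percentile bands for m and N_E on a common time grid.

    Bands: inner = 12.5-87.5%, outer = 2.5-97.5%.  Arrays are (n_points,);
    the band dictionaries map band name -> (low, high) arrays.
    """

    times: np.ndarray  # generations (or years if scaled by the caller)
    m_median: np.ndarray
    m_bands: dict
    ne_median: np.ndarray
    ne_bands: dict
    n_trajectories: int = 0


@dataclass(frozen=True)
class CrossingResult:
    """A threshold crossing of M(t), with its resolution-limit flag."""

    years: float
    generations: float
    at_resolution_limit: bool = False


# ---------------------------------------------------------------------------
# Unit scaling
# ---------------------------------------------------------------------------

def generations_to_years(t_gen, scaling: ScalingConfig):
    return np.asarray(t_gen, dtype=float) * scaling.g


def scaled_time_to_generations(t_scaled, scaling: ScalingConfig):
    """Mutation-scaled time (expected mutations per bp) to generations."""
    return np.asarray(t_scaled, dtype=float) / scaling.mu


def scaled_lambda_to_size(lambda_scaled, scaling: ScalingConfig):
    """Mutation-scaled coalescence rate to diploid N: N = 1/(2 mu lambda)."""
    lam = np.asarray(lambda_scaled, dtype=float)
    return 1.0 / (2.0 * scaling.mu * lam)


def scale_times(values, scaling: ScalingConfig, units: str = "generations"):
    """Convert times to years: from generations or mutation-scaled units."""
    if units == "generations":
        return generations_to_years(values, scaling)
    if units == "scaled":
        return generations_to_years(
            scaled_time_to_generations(values, scaling), scaling)
    raise ValueError(f"unknown units {units!r}")


# ---------------------------------------------------------------------------
# M(t) crossings
# ---------------------------------------------------------------------------

def _crossing_generations(boundaries: np.ndarray, M: np.ndarray,
                          threshold: float) -> tuple[float, bool] | None:
    """Youngest time where the non-decreasing M reaches ``threshold``.

    Interpolates linearly in log-time between the bracketing boundaries.
    Returns (t_generations, at_resolution_limit) or None when M never
    reaches the threshold; the flag marks crossings in the first or last
    grid interval (at the resolution limit of the trajectory).
    """
    if M[-1] < threshold:
        return None
    if M[0] >= threshold:
        return float(boundaries[0]), True
    k = int(np.searchsorted(M, threshold, side="left"))  # M[k-1] < thr <= M[k]
    t0, t1 = boundaries[k - 1], boundaries[k]
    M0, M1 = M[k - 1], M[k]
    if M1 == M0:
        t = t1
    else:
        w = (threshold - M0) / (M1 - M0)
        t = np.exp(np.log(max(t0, 1e-12)) + w * (np.log(t1) - np.log(max(t0, 1e-12))))
    at_limit = k == 1 or k == M.size - 1
    return float(t), at_limit


def split_time(traj: IMTrajectory, scaling: ScalingConfig,
               threshold: float = 0.5) -> CrossingResult | None:
    """Median split time: youngest time with M(t) >= threshold, in years.

    None when M never reaches the threshold (the populations never merge
    within the trajectory's span under the fitted migration).
    """
    hit = _crossing_generations(traj.grid.boundaries, traj.M, threshold)
    if hit is None:
        return None
    t_gen, at_limit = hit
    return CrossingResult(years=float(generations_to_years(t_gen, scaling)),
                          generations=t_gen, at_resolution_limit=at_limit)


def initial_divergence_times(traj: IMTrajectory, scaling: ScalingConfig,
                             thresholds: tuple[float, ...] = (0.999, 0.99),
                             ) -> dict[float, CrossingResult | None]:
    """Initial divergence: oldest time at which M first drops below each
    threshold, scanning from the ancient end toward the present.

    Because M is non-decreasing this is the same crossing located by
    :func:`split_time`; a crossing pinned to the oldest grid interval is
    flagged ``at_resolution_limit`` (the separation may predate the span).
    None when M stays below the threshold everywhere (the crossing would be
    younger than the whole span) is not possible at the ancient end — the
    None case here means M never reaches the threshold at all.
    """
    out: dict[float, CrossingResult | None] = {}
    for thr in thresholds:
        hit = _crossing_generations(traj.grid.boundaries, traj.M, thr)
        if hit is None:
            out[thr] = None
            continue
        t_gen, at_limit = hit
        out[thr] = CrossingResult(
            years=float(generations_to_years(t_gen, scaling)),
            generations=t_gen, at_resolution_limit=at_limit)
    return out


# ---------------------------------------------------------------------------
# Isolation events
# ---------------------------------------------------------------------------

def isolation_events(traj: IMTrajectory, scaling: ScalingConfig,
                     m_threshold: float = ISOLATION_M_THRESHOLD,
                     ) -> list[IsolationEvent]:
    """Maximal runs of consecutive grid intervals with m below threshold."""
    below = traj.m < m_threshold
    b_years = generations_to_years(traj.grid.boundaries, scaling)
    events: list[IsolationEvent] = []
    k = 0
    n = below.size
    while k < n:
        if not below[k]:
            k += 1
            continue
        j = k
        while j + 1 < n and below[j + 1]:
            j += 1
        events.append(IsolationEvent(
            start_years=float(b_years[k]),
            end_years=float(b_years[j + 1]),
            min_m=float(traj.m[k:j + 1].min()),
        ))
        k = j + 1
    return events


def isolation_frequency_histogram(trajs, scaling: ScalingConfig,
                                  bins: TimeGrid | None = None,
                                  m_threshold: float = ISOLATION_M_THRESHOLD):
    """Per-bin isolation-event midpoint counts and frequencies.

    ``bins`` boundaries are interpreted in years; default is the common
    80-point grid spanning the trajectories.  Frequencies are counts divided
    by the number of trajectories.  Empty collections are an error.
    """
    trajs = list(trajs)
    if len(trajs) == 0:
        raise ValueError("need at least one trajectory")
    if bins is None:
        lo = min(generations_to_years(t.grid.boundaries[0], scaling) for t in trajs)
        hi = max(generations_to_years(t.grid.boundaries[-1], scaling) for t in trajs)
        bins = TimeGrid(np.geomspace(max(lo, 1.0), hi, 81))
    edges = bins.boundaries
    counts = np.zeros(bins.n_intervals)
    for t in trajs:
        mids = [e.midpoint_years for e in isolation_events(t, scaling, m_threshold)]
        if mids:
            counts += np.histogram(mids, bins=edges)[0]
    return counts, counts / len(trajs), edges


# ---------------------------------------------------------------------------
# Pattern classification
# ---------------------------------------------------------------------------

def classify_pattern(traj: IMTrajectory, scaling: ScalingConfig,
                     periods: PeriodCatalog | None = None,
                     core_N_floor: float = 20_000.0,
                     bottleneck_drop: float = 0.9,
                     ne_series: str = "im_N1") -> PatternLabel:
    """Classify a trajectory as core, peripheral or unclassified.

    The evidence window runs from the end of the LGM to the old edge of
    MIS 10.  CORE requires the historical N_E to stay at or above
    ``core_N_floor`` across the window with no isolation event whose
    midpoint falls inside it.  A trajectory is PERIPHERAL when the window
    contains an isolation event or a bottleneck — N_E dropping by at least
    ``bottleneck_drop`` relative to its running pre-decline maximum (scanned
    from old to young).  The STRONG sub-label names the glacial period (PGP
    before MIS 8) containing the deepest bottleneck minimum or, failing
    that, the midpoint of the deepest isolation event.  N_E follows the
    im_N1 reporting convention by default (``ne_series`` may name im_N2 or
    "min" for the elementwise minimum).
    """
    periods = periods or PeriodCatalog()
    win_lo, win_hi = periods.classification_window
    b_years = generations_to_years(traj.grid.boundaries, scaling)
    if b_years[0] > win_lo or b_years[-1] < win_hi:
        raise ValueError(
            f"trajectory spans [{b_years[0]:.0f}, {b_years[-1]:.0f}] years; "
            f"classification needs [{win_lo:.0f}, {win_hi:.0f}]")

    if ne_series == "min":
        ne = np.minimum(traj.im_N1, traj.im_N2)
    else:
        ne = getattr(traj, ne_series)
    mid_years = generations_to_years(traj.grid.midpoints, scaling)
    in_win = (mid_years >= win_lo) & (mid_years <= win_hi)

    events = [e for e in isolation_events(traj, scaling)
              if win_lo <= e.midpoint_years <= win_hi]

    # bottleneck scan against the running pre-decline maximum; glacial
    # bottlenecks sit between interglacial highs, so the drop is tested
    # from both sides (approaching the window from the old end and from
    # the young end) and either direction may establish it
    win_idx = np.flatnonzero(in_win)
    bottleneck_idx: list[int] = []
    for order in (win_idx[::-1], win_idx):
        running_max = -np.inf
        for k in order:
            running_max = max(running_max, ne[k])
            if (running_max > 0
                    and ne[k] <= (1.0 - bottleneck_drop) * running_max
                    and k not in bottleneck_idx):
                bottleneck_idx.append(k)

    evidence = {
        "min_ne_window": float(ne[in_win].min()),
        "n_isolation_events": len(events),
        "events": events,
        "window_years": (win_lo, win_hi),
        "ne_series": ne_series,
    }

    if not events and not bottleneck_idx and ne[in_win].min() >= core_N_floor:
        return PatternLabel("CORE", evidence)

    if events or bottleneck_idx:
        # pool the dating evidence.  Bottleneck minima are interval-valued:
        # the minimum may sit on a flat stretch when the fit loses
        # resolution behind a deep crash, so every interval within 5% of
        # the minimum counts and an interval "lies in" a period when it
        # overlaps it.  Event midpoints are point-valued.  PGP takes
        # precedence over MIS 8 across the whole pool.
        spans: list[tuple[float, float]] = []
        if bottleneck_idx:
            ne_min = min(ne[k] for k in bottleneck_idx)
            near_min = sorted(k for k in bottleneck_idx
                              if ne[k] <= 1.05 * ne_min)
            evidence["bottleneck_min_ne"] = float(ne_min)
            evidence["bottleneck_min_years"] = float(mid_years[near_min[0]])
            spans += [(b_years[k], b_years[k + 1]) for k in near_min]
        spans += [(e.midpoint_years, e.midpoint_years) for e in events]
        strong = None
        for name in ("PGP", "MIS8"):
            young, old = periods[name]
            if any(a <= old and b >= young for a, b in spans):
                strong = name
                break
        if strong == "PGP":
            return PatternLabel("PERIPHERAL_STRONG_PGP", evidence)
        if strong == "MIS8":
            return PatternLabel("PERIPHERAL_STRONG_MIS8", evidence)
        return PatternLabel("PERIPHERAL_OTHER", evidence)

    return PatternLabel("UNCLASSIFIED", evidence)


# ---------------------------------------------------------------------------
# Envelopes
# ---------------------------------------------------------------------------

_PERCENTILES = (2.5, 12.5, 50.0, 87.5, 97.5)
_LOG_FLOOR = 1e-12


def _step_resample(traj: IMTrajectory, times: np.ndarray, values: np.ndarray
                   ) -> np.ndarray:
    """Evaluate a per-interval step function at arbitrary times."""
    b = traj.grid.boundaries
    idx = np.clip(np.searchsorted(b, times, side="right") - 1, 0,
                  values.size - 1)
    return values[idx]


def envelope(trajs, n_points: int = 80) -> EnvelopeSummary:
    """Percentile envelope of m and N_E across replicate trajectories.

    Each trajectory is resampled onto a common log-spaced grid of
    ``n_points`` times covering the span shared by all trajectories.
    Percentiles (linear-interpolation convention) are taken in log space for
    m (zeros floored at 1e-12) and in linear scale for N_E, then the median
    and band curves are smoothed with PCHIP interpolation in log-log space,
    without extrapolation beyond the common span.
    """
    trajs = list(trajs)
    if len(trajs) < 2:
        raise ValueError("envelope needs at least two trajectories")
    lo = max(t.grid.boundaries[0] for t in trajs)
    hi = min(t.grid.boundaries[-1] for t in trajs)
    if not lo < hi:
        raise ValueError("trajectories share no common time span")
    times = np.geomspace(max(lo, _LOG_FLOOR), hi, n_points)

    m_mat = np.stack([_step_resample(t, times, t.m) for t in trajs])
    ne_mat = np.stack([_step_resample(t, times, t.historical_ne)
                       for t in trajs])

    log_m = np.log10(np.maximum(m_mat, _LOG_FLOOR))
    m_pct = 10.0 ** np.percentile(log_m, _PERCENTILES, axis=0)
    ne_pct = np.percentile(ne_mat, _PERCENTILES, axis=0)

    def smooth(curve: np.ndarray) -> np.ndarray:
        # PCHIP through the points in log-log space; monotone-preserving,
        # identity at the nodes, no extrapolation outside [times0, times-1]
        pos = np.maximum(curve, _LOG_FLOOR)
        interp = PchipInterpolator(np.log10(times), np.log10(pos),
                                   extrapolate=False)
        return 10.0 ** interp(np.log10(times))

    m_curves = {p: smooth(c) for p, c in zip(_PERCENTILES, m_pct)}
    ne_curves = {p: smooth(c) for p, c in zip(_PERCENTILES, ne_pct)}

    return EnvelopeSummary(
        times=times,
        m_median=m_curves[50.0],
        m_bands={"inner": (m_curves[12.5], m_curves[87.5]),
                 "outer": (m_curves[2.5], m_curves[97.5])},
        ne_median=ne_curves[50.0],
        ne_bands={"inner": (ne_curves[12.5], ne_curves[87.5]),
                  "outer": (ne_curves[2.5], ne_curves[97.5])},
        n_trajectories=len(trajs),
    )


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    p_value: float
    test: str  # "t" or "wilcoxon"
    shapiro_p: tuple[float, float] | None = None


def compare_groups(a, b, mode: str = "auto") -> GroupComparison:
    """Two-sample comparison with a Shapiro-Wilk normality gate.

    mode="auto": Shapiro-Wilk on both groups (alpha 0.05); a t-test when
    both pass, otherwise the Wilcoxon rank-sum (Mann-Whitney U, two-sided,
    exact for small tie-free samples).  mode="t" or "wilcoxon" force the
    choice.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least three observations per group")
    shapiro = None
    if mode == "auto":
        pa = sps.shapiro(a).pvalue
        pb = sps.shapiro(b).pvalue
        shapiro = (float(pa), float(pb))
        mode = "t" if (pa > 0.05 and pb > 0.05) else "wilcoxon"
    if mode == "t":
        res = sps.ttest_ind(a, b)
        return GroupComparison(float(res.statistic), float(res.pvalue), "t",
                               shapiro)
    if mode == "wilcoxon":
        exact = (a.size <= 25 and b.size <= 25
                 and np.unique(np.concatenate([a, b])).size == a.size + b.size)
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact" if exact else "asymptotic")
        return GroupComparison(float(res.statistic), float(res.pvalue),
                               "wilcoxon", shapiro)
    raise ValueError(f"unknown mode {mode!r}")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values for a family of comparisons."""
    p = np.asarray(p_values, dtype=float)
    return sps.false_discovery_control(p, method="bh")
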