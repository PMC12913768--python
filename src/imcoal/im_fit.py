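"""Regularized least-squares fit of the piecewise IM model to rate curves.

The observed data are three time-binned coalescence-hazard curves (within
population 1, cross, within population 2).  The fit places one free epoch on
every grid interval — diploid sizes ``im_N1``, ``im_N2`` and a symmetric
migration rate ``m`` — and minimizes

    sum over curves and intervals of (log(model hazard + eps)
                                      - log(observed hazard + eps))^2
    + beta_m * sum_k (m_k / m_ref)^2
    + beta_N * sum_k ((N_k - N_{k-1}) / N_{k-1})^2        (both populations)

plus a log-space size-smoothness stabilizer, subject to box bounds, on
log10-transformed parameters.  Residuals are inverse-variance weighted by
the coalescence counts behind each hazard estimate (with an overdispersion
cap for the model's own discretization error), putting the objective on an
approximate chi-square scale; the log-hazard form keeps it scale-invariant
across the five orders of magnitude spanned by realistic hazards, and the
migration ridge is measured against a reference rate ``m_ref`` so the
regularization weights are dimensionless.  Model hazards come from the
matrix-exponential forward model (:mod:`imcoal.im_model`); gradients reuse
the cached per-epoch matrix exponentials, so one gradient costs about three
objective evaluations instead of ``3n``.

Intervals whose observed hazard is undefined (zero exposure), exactly zero
(no observed coalescences — a log-residual there would be dominated by the
eps floor) or below the representable range given the size bounds are
excluded from the residual; the model remains defined everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .im_model import (
    EpochedHistory,
    RateCurves,
    TimeGrid,
    cumulative_migration,
    expm_transient,
    transient_generator,
)

__all__ = [
    "FitConfig",
    "IMTrajectory",
    "FitDiagnostics",
    "RunAcceptance",
    "initialize_from_rates",
    "fit_im",
    "qc_run",
    "HOLOCENE_YEARS",
]

#: Holocene onset used by the run-acceptance rules (standard chronology).
HOLOCENE_YEARS = 11_700.0

_SURV_FLOOR = 1e-250

#: Observed hazards below this floor are excluded from the residual.  The
#: size bounds already cap the smallest representable hazard at
#: 1/(2e7 diploids) = 5e-8 per generation; observations an order of
#: magnitude below that carry no fittable signal (and their log-residuals
#: sit in the eps-floor regime where finite differences are pure rounding
#: noise).
HAZARD_MIN = 1e-8


@dataclass(frozen=True)
class FitConfig:
    """Fit settings.

    beta_m / beta_N are the migration and size regularization weights
    (defaults 1e-8 and 1e-6, the recommended values for this model class);
    N_ancestral is the size pinned beyond the oldest fitted epoch (default
    15,000).  m_ref makes the migration ridge dimensionless.  ``seed`` and
    ``multistart`` are part of the configuration surface for optimizer
    variants; the default phased optimizer is fully deterministic and uses
    neither.
    """

    beta_m: float = 1e-8
    beta_N: float = 1e-6
    N_ancestral: float = 15_000.0
    N_bounds: tuple[float, float] = (10.0, 1e7)
    m_bounds: tuple[float, float] = (1e-12, 0.5)
    m_ref: float = 1e-5
    continuation_weight: float = 3.0
    m_smooth_weight: float = 0.0
    model_error: float = 0.05  # log-hazard discretization-error floor
    support_test: bool = True
    support_cut: float = 6.0  # chi-square-scale cut per isolation run
    support_cut_per_dof: float = 2.0
    support_floor: float = 1e-6  # "not isolated" reference rate
    isolation_tiebreak: float = 2.0  # chi-square slack favouring isolation
    eps: float = 1e-12
    seed: int = 0
    multistart: int = 1
    n_cycles: int = 2  # sequential <-> m-phase alternations
    maxiter: int = 100  # L-BFGS-B iterations per migration phase

    def __post_init__(self) -> None:
        if self.beta_m < 0 or self.beta_N < 0:
            raise ValueError("regularization weights must be >= 0")
        if not (self.N_bounds[0] < self.N_bounds[1]):
            raise ValueError("N bounds must be ordered")
        if not (0 <= self.m_bounds[0] < self.m_bounds[1]):
            raise ValueError("m bounds must be ordered and non-negative")
        if not (self.N_bounds[0] <= self.N_ancestral <= self.N_bounds[1]):
            raise ValueError("N_ancestral must lie within the N bounds")


@dataclass
class IMTrajectory:
    """Fitted IM-model trajectory on a time grid.

    ``m``, ``im_N1``, ``im_N2`` are per-interval; ``M`` is the cumulative
    migration probability at the grid boundaries (non-decreasing, in [0, 1]).
    """

    grid: TimeGrid
    m: np.ndarray
    M: np.ndarray
    im_N1: np.ndarray
    im_N2: np.ndarray

    def __post_init__(self) -> None:
        n = self.grid.n_intervals
        for name in ("m", "im_N1", "im_N2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per interval")
            setattr(self, name, arr)
        M = np.asarray(self.M, dtype=float)
        if M.shape != (n + 1,):
            raise ValueError("M must have one value per grid boundary")
        if np.any(np.diff(M) < -1e-12) or M.min() < -1e-12 or M.max() > 1 + 1e-12:
            raise ValueError("M must be non-decreasing within [0, 1]")
        self.M = np.clip(M, 0.0, 1.0)

    @property
    def historical_ne(self) -> np.ndarray:
        """im_N1, the size conventionally reported as historical N_E."""
        return self.im_N1


@dataclass
class FitDiagnostics:
    """Optimizer outcome and per-epoch failure bookkeeping.

    A "failure" epoch is one where either population size sits at a box
    bound after convergence (the optimizer pushed it to an extreme value);
    ``oscillation`` flags runs where failures alternate between the lower
    and upper bound.
    """

    final_objective: float
    converged: bool
    bound_low: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    bound_high: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    failure_times_gen: np.ndarray = field(default_factory=lambda: np.zeros(0))
    n_failures: int = 0
    oscillation: bool = False
    n_iterations: int = 0
    objective_path: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class RunAcceptance:
    """Which derived statistics a fitted run may contribute to."""

    accepted_for_initial_divergence: bool
    accepted_for_split_time: bool
    accepted_for_current_Ne: bool
    discarded: bool
    reasons: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Warm start
# ---------------------------------------------------------------------------

def initialize_from_rates(rates: RateCurves, config: FitConfig | None = None
                          ) -> EpochedHistory:
    """Deterministic warm start by inverting the hazard dictionary.

    Sizes come from N_i = 1/(2 lambda_ii).  Migration starts from the
    relative cross-coalescence rate rCCR = 2*lambda_12/(lambda_11 +
    lambda_22), which estimates the cumulative migration probability M(t)
    rather than the instantaneous rate: the initial m per interval is
    therefore the increment of -0.5*log(1 - M) over the interval (made
    non-decreasing first, since M is cumulative), clipped into the
    migration bounds.  Undefined or zero within-population hazards are
    carried forward from the last informative interval (clipping to the
    bounds), never an error.
    """
    config = config or FitConfig()
    if rates.units != "per_generation":
        raise ValueError("rates must be in per-generation units")
    if rates.lambda_11 is None or rates.lambda_22 is None:
        raise ValueError("need both within-population curves")
    l11, l22 = rates.lambda_11, rates.lambda_22
    l12 = rates.lambda_12
    n = rates.grid.n_intervals

    def invert(lam, fallback):
        with np.errstate(divide="ignore"):
            N = np.where(lam > 0, 1.0 / (2.0 * np.maximum(lam, 1e-300)), np.nan)
        N = _fill_forward(N, fallback)
        return np.clip(N, *config.N_bounds)

    N1 = invert(l11, config.N_ancestral)
    N2 = invert(l22, config.N_ancestral)

    if l12 is None:
        m = np.zeros(n)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            denom = l11 + l22
            rccr = np.where(denom > 0, 2.0 * l12 / np.maximum(denom, 1e-300),
                            np.nan)
        rccr = _fill_forward(rccr, 0.0)
        M_hat = np.maximum.accumulate(np.clip(rccr, 0.0, 0.995))
        integral = -0.5 * np.log1p(-M_hat)  # ∫ m dt up to each right boundary
        dts = np.diff(np.concatenate([[0.0], rates.grid.boundaries[1:]]))
        m = np.diff(np.concatenate([[0.0], integral])) / dts
        # beyond M ~ 1 the increments are pure saturation artifacts: the
        # populations are fully mixed and m is unidentified there, so carry
        # the last pre-saturation rate forward instead of reporting zero
        saturated = M_hat >= 0.995  # a suffix, since M_hat is non-decreasing
        if saturated.any() and not saturated.all():
            m[saturated] = np.nan
            m = _fill_forward(m, 0.0)
    m = np.clip(m, config.m_bounds[0], config.m_bounds[1])

    boundaries = np.concatenate([[0.0], rates.grid.boundaries[1:-1]])
    # epoch k spans grid interval k; the first epoch extends to t = 0
    return EpochedHistory(boundaries=boundaries, N1=N1, N2=N2, m=m)


def _fill_forward(x: np.ndarray, fallback: float) -> np.ndarray:
    """Replace NaNs by the previous finite value (fallback before the first)."""
    out = x.copy()
    last = np.nan
    for i in range(out.size):
        if np.isfinite(out[i]):
            last = out[i]
        else:
            out[i] = last
    if np.isnan(out).any():
        out = np.where(np.isnan(out), fallback, out)
    return out


# ---------------------------------------------------------------------------
# Objective machinery
# ---------------------------------------------------------------------------

class _Objective:
    """Residuals, objective and Jacobian with cached matrix exponentials.

    Parameter vector: theta = [log10 N1 (n), log10 N2 (n), log10 m (n)].
    Segment j = 0 covers [0, b_0] with interval-0 parameters; segment j >= 1
    covers grid interval j - 1.  The residual vector stacks the masked
    log-hazard residuals (3 curves x n intervals) with the square-rooted
    regularization terms, so that sum(r^2) equals the fit objective.

    The Jacobian uses per-epoch forward differences that reuse the cached
    matrix exponentials of every unperturbed epoch: perturbing interval k
    only requires one fresh 3x3 exponential and a re-propagation of the
    chain from boundary k on, so a full Jacobian costs about three times
    one objective evaluation instead of 3n times.
    """

    def __init__(self, rates: RateCurves, config: FitConfig):
        self.cfg = config
        grid = rates.grid
        self.n = grid.n_intervals
        b = grid.boundaries
        if not np.all(np.isfinite(b)):
            raise ValueError("fit requires finite grid boundaries")
        self.dts = np.concatenate([[b[0]], grid.widths])  # per segment
        self.widths = grid.widths
        # observed hazards, rows aligned with start states (1,1), (2,2), split
        obs = np.full((3, self.n), np.nan)
        if rates.lambda_11 is not None:
            obs[0] = rates.lambda_11
        if rates.lambda_22 is not None:
            obs[1] = rates.lambda_22
        if rates.lambda_12 is not None:
            obs[2] = rates.lambda_12
        if np.any(np.isinf(obs)):
            raise ValueError("observed hazards contain infinities")
        self.obs = obs
        self.use = np.isfinite(obs) & (obs > HAZARD_MIN)
        self.log_obs = np.where(self.use, np.log(np.where(self.use, obs, 1.0)
                                                 + config.eps), 0.0)
        # inverse-variance weights: a log-hazard from n coalescences has
        # sampling variance ~ 1/n; the model itself (piecewise epochs on a
        # log grid) carries a discretization error floor, so the effective
        # variance is 1/n + model_error^2 (quasi-likelihood overdispersion
        # cap).  This puts the objective on a chi-square scale and
        # calibrates the isolation support test.  Curves without counts
        # (exact model curves, external tables) get unit weights.
        if rates.events is not None:
            cnt = np.zeros_like(obs)
            for row, name in enumerate(("lambda_11", "lambda_22",
                                        "lambda_12")):
                if name in rates.events:
                    cnt[row] = rates.events[name]
            with np.errstate(divide="ignore"):
                w = 1.0 / (1.0 / np.maximum(cnt, 1e-300)
                           + config.model_error**2)
            self.weighted = True
        else:
            w = np.ones_like(obs)
            self.weighted = False
        self.sqrt_w = np.sqrt(np.where(self.use, w, 0.0))

    # -- parameter handling -------------------------------------------------

    def unpack(self, theta: np.ndarray):
        n = self.n
        N1 = 10.0 ** theta[:n]
        N2 = 10.0 ** theta[n:2 * n]
        m = 10.0 ** theta[2 * n:]
        return N1, N2, m

    def pack(self, N1, N2, m) -> np.ndarray:
        lo_m = max(self.cfg.m_bounds[0], 1e-12)
        return np.concatenate([
            np.log10(np.clip(N1, *self.cfg.N_bounds)),
            np.log10(np.clip(N2, *self.cfg.N_bounds)),
            np.log10(np.clip(m, lo_m, self.cfg.m_bounds[1])),
        ])

    @property
    def bounds(self):
        n = self.n
        lo_m = max(self.cfg.m_bounds[0], 1e-12)
        bN = (np.log10(self.cfg.N_bounds[0]), np.log10(self.cfg.N_bounds[1]))
        bm = (np.log10(lo_m), np.log10(self.cfg.m_bounds[1]))
        return [bN] * (2 * n) + [bm] * n

    # -- forward model ------------------------------------------------------

    def _segment_matrices(self, N1, N2, m) -> np.ndarray:
        idx = np.concatenate([[0], np.arange(self.n)])  # interval per segment
        Q = transient_generator(N1[idx], N2[idx], m[idx])
        return expm_transient(Q, self.dts)

    def _propagate(self, E: np.ndarray) -> np.ndarray:
        """Occupancy matrices P[j] (start x state) at grid boundary j."""
        P = np.empty((self.n + 1, 3, 3))
        cur = E[0]
        P[0] = cur
        for j in range(1, self.n + 1):
            cur = cur @ E[j]
            P[j] = cur
        return P

    def _residuals_from_survival(self, s: np.ndarray, N1, N2, m) -> np.ndarray:
        """s: (n+1, 3) survival at boundaries (rows boundary, cols start)."""
        cfg = self.cfg
        with np.errstate(divide="ignore", invalid="ignore"):
            logs = np.log(np.maximum(s, _SURV_FLOOR))
            h = np.maximum(-(logs[1:] - logs[:-1]).T / self.widths, 0.0)
            log_h = np.log(h + cfg.eps)
        ok = self.use & (s[1:, :].T > _SURV_FLOOR)
        r = (self.sqrt_w * np.where(ok, log_h - self.log_obs, 0.0)).ravel()
        pen_m = np.sqrt(cfg.beta_m) * (m / cfg.m_ref)
        pen_1 = np.sqrt(cfg.beta_N) * (np.diff(N1) / N1[:-1])
        pen_2 = np.sqrt(cfg.beta_N) * (np.diff(N2) / N2[:-1])
        # log-space smoothness: suppresses noise chasing along the
        # quasi-stationary ridge where the three curves carry one equation
        wN = np.sqrt(cfg.continuation_weight)
        # m-smoothness is L1-like (Charbonnier): genuine migration shut-offs
        # are order-of-magnitude steps and pass at linear cost, while
        # single-interval noise wiggles are suppressed
        dm = np.diff(np.log10(np.maximum(m, 1e-12)))
        sm_m = np.sqrt(cfg.m_smooth_weight * np.sqrt(0.01 + dm * dm))
        sm = [wN * np.diff(np.log10(N1)), wN * np.diff(np.log10(N2)), sm_m]
        return np.concatenate([r, pen_m, pen_1, pen_2, *sm])

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        N1, N2, m = self.unpack(theta)
        P = self._propagate(self._segment_matrices(N1, N2, m))
        return self._residuals_from_survival(P.sum(axis=2), N1, N2, m)

    def value(self, theta: np.ndarray) -> float:
        r = self.residuals(theta)
        return float(r @ r)

    # -- Jacobian -----------------------------------------------------------

    def jacobian(self, theta: np.ndarray, r0: np.ndarray | None = None,
                 m_only: bool = False) -> np.ndarray:
        n = self.n
        step = 1e-6  # forward difference in log10-parameter space
        N1, N2, m = self.unpack(theta)
        E = self._segment_matrices(N1, N2, m)
        P = self._propagate(E)
        s0 = P.sum(axis=2)
        if r0 is None:
            r0 = self._residuals_from_survival(s0, N1, N2, m)
        if m_only:
            return self._jacobian_m(theta, r0, N1, N2, m, E, P, s0, step)
        J = np.empty((r0.size, 3 * n))
        pN1 = 10.0 ** (np.log10(N1) + step)
        pN2 = 10.0 ** (np.log10(N2) + step)
        pm = 10.0 ** (np.log10(m) + step)
        # flattened perturbation table: index 3*k + p holds interval k's
        # parameters with block p (N1, N2, m) perturbed
        A1 = np.repeat(N1, 3)
        A2 = np.repeat(N2, 3)
        AM = np.repeat(m, 3)
        A1[0::3] = pN1
        A2[1::3] = pN2
        AM[2::3] = pm
        Epert = expm_transient(transient_generator(A1, A2, AM),
                               np.repeat(self.dts[1:], 3))
        # interval 0 also owns the leading segment [0, b0]
        E0pert = expm_transient(transient_generator(A1[:3], A2[:3], AM[:3]),
                                np.full(3, self.dts[0]))

        for k in range(n):
            Ek = Epert[3 * k:3 * k + 3]  # perturbed variants of segment k+1
            s = np.repeat(s0[None, :, :], 3, axis=0)  # (3 pert, n+1, 3)
            if k == 0:
                s[:, 0, :] = E0pert.sum(axis=2)
                cur = np.einsum("pij,pjk->pik", E0pert, Ek)
            else:
                cur = np.einsum("ij,pjk->pik", P[k], Ek)
            s[:, k + 1, :] = cur.sum(axis=2)
            for j in range(k + 2, n + 1):
                cur = cur @ E[j]
                s[:, j, :] = cur.sum(axis=2)
            for p in range(3):
                v1 = N1 if p != 0 else _with(N1, k, pN1[k])
                v2 = N2 if p != 1 else _with(N2, k, pN2[k])
                vm = m if p != 2 else _with(m, k, pm[k])
                r1 = self._residuals_from_survival(s[p], v1, v2, vm)
                J[:, p * n + k] = (r1 - r0) / step
        return J

    def _jacobian_m(self, theta, r0, N1, N2, m, E, P, s0, step) -> np.ndarray:
        """Jacobian columns for the migration block only (sizes frozen)."""
        n = self.n
        J = np.zeros((r0.size, 3 * n))
        pm = 10.0 ** (np.log10(m) + step)
        Epert = expm_transient(transient_generator(N1, N2, pm), self.dts[1:])
        E0pert = expm_transient(
            transient_generator(N1[0], N2[0], pm[0]), self.dts[0])
        for k in range(n):
            s = s0.copy()
            if k == 0:
                s[0] = E0pert.sum(axis=1)
                cur = E0pert @ Epert[0]
            else:
                cur = P[k] @ Epert[k]
            s[k + 1] = cur.sum(axis=1)
            for j in range(k + 2, n + 1):
                cur = cur @ E[j]
                s[j] = cur.sum(axis=1)
            vm = _with(m, k, pm[k])
            r1 = self._residuals_from_survival(s, N1, N2, vm)
            J[:, 2 * n + k] = (r1 - r0) / step
        return J

    def value_and_grad(self, theta: np.ndarray):
        r = self.residuals(theta)
        J = self.jacobian(theta, r0=r)
        return float(r @ r), 2.0 * (J.T @ r)

    def value_and_grad_m(self, theta: np.ndarray):
        r = self.residuals(theta)
        J = self.jacobian(theta, r0=r, m_only=True)
        return float(r @ r), 2.0 * (J.T @ r)


def _with(arr: np.ndarray, k: int, value: float) -> np.ndarray:
    out = arr.copy()
    out[k] = value
    return out


def _fit_sequential(obj: _Objective, config: FitConfig,
                    init: EpochedHistory,
                    m_fixed: np.ndarray | None = None) -> np.ndarray:
    """Sequential per-interval solve, young to old.

    Mirrors the Markov structure of the model: the lineage-state occupancy
    is propagated from the present, and each interval's three parameters
    (N1, N2, m) are solved from that interval's three observed hazards
    given the inherited occupancy.  Each solve starts from both the global
    warm start and the previous interval's solution (continuation), keeping
    the better optimum.

    A continuation anchor — ``continuation_weight`` times the squared
    log10-distance from the previous interval's parameters — shrinks the
    solve toward the inherited values.  Once lineages are fully mixed the
    three hazard curves coincide and the local problem is degenerate; the
    anchor keeps parameters on the last identified values there instead of
    letting them chase sampling noise, while genuine demographic signals
    (bottlenecks, migration shut-offs) move the residuals by orders of
    magnitude and pass through it freely.
    """
    n = obj.n
    cfg = config
    lo_m = max(cfg.m_bounds[0], 1e-12)
    bounds3 = [
        (np.log10(cfg.N_bounds[0]), np.log10(cfg.N_bounds[1])),
        (np.log10(cfg.N_bounds[0]), np.log10(cfg.N_bounds[1])),
        (np.log10(lo_m), np.log10(cfg.m_bounds[1])),
    ]
    N1 = np.clip(init.N1, *cfg.N_bounds).copy()
    N2 = np.clip(init.N2, *cfg.N_bounds).copy()
    m = np.clip(init.m, lo_m, cfg.m_bounds[1]).copy()
    if m_fixed is not None:  # NaN entries stay free
        pin = np.isfinite(m_fixed)
        m[pin] = np.clip(m_fixed[pin], lo_m, cfg.m_bounds[1])

    P_prev = np.eye(3)
    s_prev = np.ones(3)
    log_eps = cfg.eps
    for k in range(n):
        use_k = obj.use[:, k]
        log_obs_k = obj.log_obs[:, k]
        width = obj.widths[k]
        prev_params = (N1[k - 1], N2[k - 1], m[k - 1]) if k else None
        prev_theta3 = (np.log10([prev_params[0], prev_params[1],
                                 max(prev_params[2], lo_m)])
                       if prev_params is not None else None)

        def local(theta3):
            v1, v2, vm = 10.0 ** theta3
            E = expm_transient(transient_generator(v1, v2, vm),
                               obj.dts[k + 1])
            if k == 0:
                E0 = expm_transient(transient_generator(v1, v2, vm),
                                    obj.dts[0])
                s0 = E0.sum(axis=1)
                s1 = (E0 @ E).sum(axis=1)
            else:
                s0 = s_prev
                s1 = (P_prev @ E).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                h = np.maximum(-(np.log(np.maximum(s1, _SURV_FLOOR))
                                 - np.log(np.maximum(s0, _SURV_FLOOR)))
                               / width, 0.0)
                r = obj.sqrt_w[:, k] * np.where(
                    use_k & (s1 > _SURV_FLOOR),
                    np.log(h + log_eps) - log_obs_k, 0.0)
            val = float(r @ r) + cfg.beta_m * (vm / cfg.m_ref) ** 2
            if prev_params is not None:
                val += cfg.beta_N * (((v1 - prev_params[0]) / prev_params[0]) ** 2
                                     + ((v2 - prev_params[1]) / prev_params[1]) ** 2)
                d = theta3 - prev_theta3
                val += cfg.continuation_weight * float(d @ d)
            return val

        if m_fixed is None or not np.isfinite(m_fixed[k]):
            bounds_k = bounds3
        else:
            zk = np.log10(max(m[k], lo_m))
            bounds_k = [bounds3[0], bounds3[1], (zk, zk)]
        starts = [np.log10([N1[k], N2[k], max(m[k], lo_m)])]
        if prev_params is not None:
            starts.append(np.log10([prev_params[0], prev_params[1],
                                    max(prev_params[2], lo_m)]))
        best = None
        for x0 in starts:
            res = minimize(local, np.clip(x0, [b[0] for b in bounds_k],
                                          [b[1] for b in bounds_k]),
                           method="L-BFGS-B", bounds=bounds_k,
                           options={"maxiter": 60, "ftol": 1e-14})
            if best is None or res.fun < best.fun:
                best = res
        N1[k], N2[k], m[k] = 10.0 ** best.x
        E = expm_transient(transient_generator(N1[k], N2[k], m[k]),
                           obj.dts[k + 1])
        if k == 0:
            E0 = expm_transient(transient_generator(N1[k], N2[k], m[k]),
                                obj.dts[0])
            P_prev = E0 @ E
        else:
            P_prev = P_prev @ E
        s_prev = P_prev.sum(axis=1)
    return obj.pack(N1, N2, m)


def fit_im(rates: RateCurves, config: FitConfig | None = None
           ) -> tuple[IMTrajectory, FitDiagnostics]:
    """Fit the piecewise IM model to observed rate curves.

    Optimization runs in phases (see docs/methods.md for the full design):
    a sequential young-to-old pass solves each interval's parameters from
    its own hazards given the inherited lineage-state occupancy; a global
    migration phase re-optimizes m against the whole objective with the
    sizes frozen (alternating with sequential size rebuilds for
    ``config.n_cycles`` cycles); die-off spikes in the observed hazards
    seed isolation-hypothesis candidate refits that win on near-ties (the
    migration-ridge convention); and a profile-likelihood screen removes
    sub-threshold migration dips the data do not support.  Returns the
    fitted trajectory (with M from the cumulative-migration integral) and
    diagnostics.  Deterministic given the configuration; non-convergence is
    flagged in the diagnostics, the trajectory is still returned.
    """
    import warnings

    config = config or FitConfig()
    if rates.grid.n_intervals < 8:
        raise ValueError("fit requires a grid with at least 8 intervals")
    for lam in rates.curves.values():
        if np.any(np.isinf(lam)):
            raise ValueError("rate curves contain non-finite values")
    obj = _Objective(rates, config)
    init = initialize_from_rates(rates, config)
    n = obj.n
    lo = np.array([b[0] for b in obj.bounds])
    hi = np.array([b[1] for b in obj.bounds])

    def m_phase(theta, maxiter, path=None, cap_idx=None):
        """Global migration refinement with sizes frozen.

        The per-interval m signal is non-local (it lives in the future
        cross-coalescence of still-unmixed pairs), so m is re-optimized
        against the full objective; freezing N removes the N-versus-m
        compensation that makes the joint problem multimodal.  ``cap_idx``
        optionally bounds one interval's migration below the isolation
        threshold (the isolation-hypothesis candidates).
        """
        if maxiter <= 0:
            return theta
        frozen = [(theta[i], theta[i]) for i in range(2 * n)]
        mb = list(zip(lo[2 * n:], hi[2 * n:]))
        if cap_idx is not None:
            cap = np.log10(1e-8)
            mb[cap_idx] = (mb[cap_idx][0], cap)
            theta = theta.copy()
            theta[2 * n + cap_idx] = min(theta[2 * n + cap_idx], cap)
        res = minimize(
            obj.value_and_grad_m, theta, jac=True, method="L-BFGS-B",
            bounds=frozen + mb,
            callback=(None if path is None
                      else (lambda xk: path.append(obj.value(xk)))),
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-9},
        )
        return res.x

    def refine(theta_seq, path=None, cap_idx=None):
        """m-phase plus block-coordinate alternation cycles."""
        theta = m_phase(theta_seq, config.maxiter, path, cap_idx)
        for _ in range(config.n_cycles - 1):
            _, _, m_cur = obj.unpack(theta)
            theta = _fit_sequential(obj, config, init, m_fixed=m_cur)
            theta = m_phase(theta, config.maxiter, path, cap_idx)
        return theta

    path: list[float] = []
    theta = _fit_sequential(obj, config, init)
    path.append(obj.value(theta))
    theta = refine(theta, path)
    base_theta = theta
    best_val = obj.value(theta)
    path.append(best_val)
    nit = len(path)
    converged = True
    exempt_idx: int | None = None

    # Die-off spikes in the observed within-population hazards mark
    # bottleneck entries.  A glacial isolation (m -> 0) behind such a spike
    # is a separate objective basin that the greedy young-to-old pass
    # cannot reach (its evidence is the post-bottleneck coalescence of
    # still-separated pairs), so each spike seeds a candidate refit under
    # an isolation hypothesis.  Near-observationally-equivalent histories
    # with and without migration are resolved in favour of the
    # migration-free one (the migration-ridge convention of this model
    # class), but only behind a die-off spike — smooth histories are never
    # probed, so fully-mixed flat stretches cannot pick up spurious
    # isolation this way.
    for k_spike in _dieoff_spikes(obj):
        # a log grid rarely aligns with the true shut-off: the entry
        # interval itself straddles the onset, while the next-older
        # interval tends to lie fully inside the isolation, so both pins
        # are tried
        adopted = False
        for pin in (k_spike + 1, k_spike):
            if pin >= n or adopted:
                continue
            # the first capped pass only shapes m; the size rebuild in the
            # following cycle does the heavy lifting, so it gets a smaller
            # iteration budget
            theta_c = m_phase(base_theta, config.maxiter // 2, cap_idx=pin)
            for _ in range(max(config.n_cycles - 1, 1)):
                _, _, m_cur = obj.unpack(theta_c)
                theta_c = _fit_sequential(obj, config, init, m_fixed=m_cur)
                theta_c = m_phase(theta_c, config.maxiter, cap_idx=pin)
            val_c = obj.value(theta_c)
            if val_c <= best_val + config.isolation_tiebreak:
                theta, best_val = theta_c, val_c
                exempt_idx = pin
                adopted = True
                path.append(val_c)

    if config.support_test and obj.weighted:
        theta = _isolation_support_filter(obj, theta, config,
                                          exempt_idx=exempt_idx)

    final = obj.value(theta)
    N1, N2, m = obj.unpack(theta)
    M = cumulative_migration(m, rates.grid)
    traj = IMTrajectory(grid=rates.grid, m=m, M=M, im_N1=N1, im_N2=N2)
    diag = _diagnose(final, converged, nit, N1, N2, rates.grid, config, path)
    return traj, diag


def _dieoff_spikes(obj: _Objective, ratio_min: float = 3.0,
                   min_events: float = 30.0, max_spikes: int = 2
                   ) -> list[int]:
    """Intervals where a within-population hazard jumps into a die-off.

    A sudden multi-fold rise of a within-population coalescence hazard is
    the die-off signature of entering a bottleneck; these intervals seed
    the isolation-hypothesis candidate starts.  Two gates separate genuine
    bottleneck entries from post-glacial recontact rebounds (which also
    jump): the post-jump hazard must rise clearly above the curve's median
    level (die-offs are the fastest coalescence anywhere on the curve),
    and the pre-jump hazard must be at baseline rather than in a deep hole
    (rebounds climb out of the near-zero parked-pair regime).  A minimal
    event count keeps small-count noise from firing candidates.
    """
    spikes: dict[int, float] = {}
    counts = obj.sqrt_w**2
    for row in (0, 1):  # the two within-population curves
        used = np.flatnonzero(obj.use[row])
        if used.size < 3:
            continue
        med = float(np.median(obj.obs[row, used]))
        for a, b in zip(used[:-1], used[1:]):
            prev, cur = obj.obs[row, a], obj.obs[row, b]
            if (prev > 0 and cur / prev >= ratio_min
                    and cur > 1.5 * med and prev >= 0.2 * med
                    and (not obj.weighted or counts[row, b] >= min_events)):
                spikes[b] = max(spikes.get(b, 0.0), cur / prev)
    ranked = sorted(spikes, key=lambda k: -spikes[k])
    return ranked[:max_spikes]


#: Migration threshold below which an interval counts as isolated
#: (matches the isolation-event definition in traj_stats).
_ISOLATION_M = 1e-7


def _isolation_support_filter(obj: _Objective, theta: np.ndarray,
                              config: FitConfig,
                              exempt_idx: int | None = None) -> np.ndarray:
    """Profile-likelihood screen for sub-threshold migration dips.

    For every maximal run of intervals with fitted m below the isolation
    threshold, refit with those rates bounded at ``support_floor`` ("not
    isolated").  If the constrained objective is within the chi-square-scale
    cut of the free optimum, the data do not support the isolation claim —
    the dip is a flat-likelihood artifact — and the constrained solution is
    adopted.  Genuine migration shut-offs degrade the constrained fit by
    orders of magnitude and always survive the screen.  Requires
    count-weighted residuals (the cut is calibrated on that scale).
    """
    n = obj.n
    lo = np.array([b[0] for b in obj.bounds])
    hi = np.array([b[1] for b in obj.bounds])
    floor_z = np.log10(config.support_floor)
    kept: set[tuple[int, int]] = set()

    for _ in range(12):
        _, _, m = obj.unpack(theta)
        below = m < _ISOLATION_M
        runs = []
        k = 0
        while k < n:
            if below[k]:
                j = k
                while j + 1 < n and below[j + 1]:
                    j += 1
                exempt = (exempt_idx is not None
                          and k <= exempt_idx <= j)  # adopted isolation
                if (k, j) not in kept and not exempt:
                    runs.append((k, j))
                k = j + 1
            else:
                k += 1
        if not runs:
            break
        i, j = runs[0]
        dof = j - i + 1
        lo2 = lo.copy()
        hi2 = hi.copy()
        lo2[:2 * n] = theta[:2 * n]  # sizes stay frozen, as in the m phase
        hi2[:2 * n] = theta[:2 * n]
        lo2[2 * n + i:2 * n + j + 1] = floor_z
        theta_start = np.maximum(theta, lo2)
        free_val = obj.value(theta)
        res = minimize(
            obj.value_and_grad_m, theta_start, jac=True, method="L-BFGS-B",
            bounds=list(zip(lo2, hi2)),
            options={"maxiter": 40, "ftol": 1e-10, "gtol": 1e-9},
        )
        cut = config.support_cut + config.support_cut_per_dof * (dof - 1)
        if res.fun - free_val < cut:
            theta = res.x  # isolation not supported: keep constrained fit
        else:
            kept.add((i, j))
    return theta


def _diagnose(final_objective: float, converged: bool, n_iterations: int,
              N1, N2, grid: TimeGrid, config: FitConfig,
              path: list[float]) -> FitDiagnostics:
    tol = 1e-3  # in log10 units
    lo, hi = np.log10(config.N_bounds[0]), np.log10(config.N_bounds[1])
    z1, z2 = np.log10(N1), np.log10(N2)
    low = (z1 < lo + tol) | (z2 < lo + tol)
    high = (z1 > hi - tol) | (z2 > hi - tol)
    fail = low | high
    mids = grid.midpoints
    osc = bool(fail.sum() >= 2 and low.any() and high.any())
    return FitDiagnostics(
        final_objective=float(final_objective),
        converged=converged,
        bound_low=low,
        bound_high=high,
        failure_times_gen=mids[fail],
        n_failures=int(fail.sum()),
        oscillation=osc,
        n_iterations=n_iterations,
        objective_path=np.asarray(path),
    )


# ---------------------------------------------------------------------------
# Run acceptance
# ---------------------------------------------------------------------------

def qc_run(diag: FitDiagnostics, traj: IMTrajectory, scaling,
           holocene_years: float = HOLOCENE_YEARS) -> RunAcceptance:
    """Apply the run-acceptance rules to a fitted trajectory.

    Repeated failures with size oscillation between extreme values discard
    the run; any failure epoch disqualifies the run for initial-divergence
    estimates; a failure inside the Holocene disqualifies it for split
    times.  Current-N_E is always accepted: by the Markov property of the
    underlying chain, ancient epochs cannot distort the most recent
    coalescence rates.
    """
    reasons: dict[str, str] = {}
    failure_years = diag.failure_times_gen * scaling.g

    discarded = bool(diag.n_failures >= 2 and diag.oscillation)
    if discarded:
        reasons["discarded"] = (
            f"{diag.n_failures} failure epochs with sizes oscillating "
            "between bound extremes")

    div_ok = not discarded and diag.n_failures == 0
    if not div_ok and not discarded:
        reasons["initial_divergence"] = (
            f"{diag.n_failures} failure epoch(s); initial divergence not "
            "accepted")

    holocene_fail = bool(np.any(failure_years < holocene_years))
    split_ok = not discarded and not holocene_fail
    if holocene_fail and not discarded:
        reasons["split_time"] = "failure epoch within the Holocene"

    return RunAcceptance(
        accepted_for_initial_divergence=div_ok,
        accepted_for_split_time=split_ok,
        accepted_for_current_Ne=True,
        discarded=discarded,
        reasons=reasons,
    )
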