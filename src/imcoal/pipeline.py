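"""End-to-end pipeline helpers tying simulation, fitting and statistics.

These are the compositions the command-line interface and the acceptance
checks run: simulate TMRCA draws under a demographic scenario, estimate
hazard curves, fit the IM model, and derive trajectory statistics —
including the block-bootstrap replication of the whole chain.
"""

from __future__ import annotations

import numpy as np

from .coalsim import (
    TmrcaSample,
    block_bootstrap,
    empirical_hazard,
    simulate_rate_curves,
)
from .im_fit import FitConfig, FitDiagnostics, IMTrajectory, fit_im
from .im_model import EpochedHistory, RateCurves, TimeGrid

__all__ = [
    "simulate_and_fit",
    "bootstrap_trajectories",
    "rates_from_draws",
]


def rates_from_draws(draws: dict[str, TmrcaSample], grid: TimeGrid
                     ) -> RateCurves:
    """Hazard curves (with event counts) from per-curve TMRCA draws."""
    events = {
        name: np.histogram(s.times[~s.censored],
                           bins=grid.boundaries)[0].astype(float)
        for name, s in draws.items()
    }
    return RateCurves(
        grid=grid,
        lambda_11=empirical_hazard(draws["lambda_11"], grid),
        lambda_12=empirical_hazard(draws["lambda_12"], grid),
        lambda_22=empirical_hazard(draws["lambda_22"], grid),
        events=events,
    )


def simulate_and_fit(history: EpochedHistory, grid: TimeGrid, n_draws: int,
                     seed: int | None = None,
                     config: FitConfig | None = None,
                     n_blocks: int = 1,
                     ) -> tuple[RateCurves, IMTrajectory, FitDiagnostics,
                                dict[str, TmrcaSample]]:
    """Simulate all three curves, estimate hazards and fit the IM model."""
    rates, draws = simulate_rate_curves(history, grid, n=n_draws, seed=seed,
                                        n_blocks=n_blocks)
    traj, diag = fit_im(rates, config)
    return rates, traj, diag, draws


def bootstrap_trajectories(draws: dict[str, TmrcaSample], grid: TimeGrid,
                           n_blocks: int = 30, n_reps: int = 100,
                           seed: int | None = None,
                           config: FitConfig | None = None,
                           ) -> list[IMTrajectory]:
    """Refit the IM model on block-bootstrap replicates of the draws.

    The draws must carry block labels (simulate with ``n_blocks`` set);
    every replicate resamples ``n_blocks`` blocks with replacement — the
    same blocks across all three curves — re-estimates hazards and refits.
    """
    reps = block_bootstrap(draws, n_blocks=n_blocks, n_reps=n_reps, seed=seed)
    trajs = []
    for rep in reps:
        rates = rates_from_draws(rep, grid)
        traj, _ = fit_im(rates, config)
        trajs.append(traj)
    return trajs
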