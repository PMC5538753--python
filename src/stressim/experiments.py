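"""Cycle-length sweeps and treatment comparisons as tidy tables.

Each experiment runs the appropriate simulator over a grid of cycle
lengths ``tau`` and attaches the closed-form prediction alongside, so a
single table carries both the simulation and its analytic overlay:

* :func:`tau_sweep` — long-term SIM prevalence vs ``tau`` for the
  recurrent / non-recurrent regimes or cyclic multi-stress rotation;
* :func:`randomized_summary` — mean and spread of SIM prevalence when the
  stress order is randomized, per seed and pooled;
* :func:`treatment_comparison` — combined vs paired vs sequential
  application of four stresses, with the multi-resistance class spectrum
  of the final population.

All outputs are deterministic functions of (parameters, grid, seeds).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import analytic
from .model_core import run_cycles
from .multistress import StressSchedule, build_space, multiresistance_frequencies, simulate_schedule
from .params import ModelParameters

__all__ = [
    "default_tau_grid",
    "tau_sweep",
    "randomized_summary",
    "treatment_comparison",
]


def default_tau_grid(
    params: ModelParameters, n: int = 20, lo: float = 0.02, hi: float = 1.5
) -> np.ndarray:
    """Logarithmic grid of cycle lengths spanning tau/tau_c in [lo, hi]."""
    tau_c = analytic.critical_cycle_length(params)
    return np.geomspace(lo * tau_c, hi * tau_c, n)


def _filter_grid(params: ModelParameters, tau_grid) -> np.ndarray:
    """Drop grid points that leave no room for the stress phase."""
    tau_grid = np.asarray(tau_grid, dtype=float)
    keep = tau_grid > params.tau_S
    if not keep.all():
        warnings.warn(
            f"skipping {int((~keep).sum())} grid point(s) with tau <= tau_S "
            f"({params.tau_S})",
            stacklevel=3,
        )
    return tau_grid[keep]


def tau_sweep(
    params: ModelParameters,
    tau_grid,
    scenario: str,
    *,
    chi: int | None = None,
    seed: int | None = None,
    n_iterations: int = 10_000,
    n_last: int = 1_000,
    max_cycles: int = 10_000,
    convergence_tol: float = 1e-9,
    extinction_tol: float = 1e-10,
) -> pd.DataFrame:
    """Long-term SIM prevalence across a grid of cycle lengths.

    ``scenario`` is ``"R"``, ``"NR"``, ``"cyclic"``, or ``"randomized"``;
    the latter two need ``chi`` (and ``"randomized"`` a ``seed``).  For
    multi-stress scenarios ``tau`` is the length of one stress/no-stress
    phase, so one full rotation through all stresses takes ``chi * tau``.
    The analytic column holds the matching closed-form value (recurrent or
    non-recurrent equilibrium, or the multi-stress heuristic, which is
    known to overestimate the simulation).
    """
    if scenario in ("cyclic", "randomized") and chi is None:
        raise ValueError(f"scenario {scenario!r} requires chi")
    if scenario == "randomized" and seed is None:
        raise ValueError("scenario 'randomized' requires a seed")
    if scenario not in ("R", "NR", "cyclic", "randomized"):
        raise ValueError(f"unknown scenario {scenario!r}")

    tau_c = analytic.critical_cycle_length(params)
    rows = []
    for tau in _filter_grid(params, tau_grid):
        run_params = params.with_durations(tau_NS=tau - params.tau_S)
        label = scenario if chi is None else f"{scenario}({chi})"
        row = {
            "tau": tau,
            "tau_over_tau_c": tau / tau_c,
            "scenario": label,
            "mean": np.nan,
            "sd": np.nan,
        }
        if scenario in ("R", "NR"):
            res = run_cycles(
                None, run_params, scenario, max_cycles=max_cycles,
                convergence_tol=convergence_tol, extinction_tol=extinction_tol,
            )
            row["p_hat_M_analytic"] = (
                analytic.equilibrium_nr(run_params, tau)
                if scenario == "NR"
                else analytic.equilibrium_r(run_params, tau)
            )
        else:
            space = build_space(chi)
            if scenario == "cyclic":
                sched = StressSchedule.cyclic(chi, run_params.tau_S, run_params.tau_NS)
                res = simulate_schedule(
                    space, run_params, sched, max_supercycles=max_cycles,
                    convergence_tol=convergence_tol, extinction_tol=extinction_tol,
                )
            else:
                sched = StressSchedule.randomized(
                    chi, run_params.tau_S, run_params.tau_NS,
                    seed=seed, n_iterations=n_iterations,
                )
                res = simulate_schedule(space, run_params, sched, n_last=n_last)
                row["mean"], row["sd"] = res.mean, res.sd
            row["p_hat_M_analytic"] = analytic.heuristic_multistress_equilibrium(
                run_params, tau, chi
            )
        row["p_hat_M_simulated"] = res.p_hat_M
        row["converged"] = res.converged
        row["n_cycles"] = res.n_cycles
        rows.append(row)
    return pd.DataFrame(rows)


def randomized_summary(
    params: ModelParameters,
    tau_grid,
    chi: int,
    seeds,
    *,
    n_iterations: int = 10_000,
    n_last: int = 1_000,
) -> pd.DataFrame:
    """Randomized-order sweeps per seed plus a pooled summary row per tau.

    For each ``tau`` and seed, the stress sequence is drawn uniformly from
    the ``chi`` available stresses for ``n_iterations`` phases, and the
    mean/sd of the SIM frequency over the last ``n_last`` samples is
    recorded.  Pooled rows (seed column ``"pooled"``) aggregate the tail
    samples of all seeds.
    """
    seeds = list(seeds)
    if not seeds:
        raise ValueError("seeds must be non-empty")
    tau_c = analytic.critical_cycle_length(params)
    space = build_space(chi)
    rows = []
    for tau in _filter_grid(params, tau_grid):
        run_params = params.with_durations(tau_NS=tau - params.tau_S)
        tails = []
        for seed in seeds:
            sched = StressSchedule.randomized(
                chi, run_params.tau_S, run_params.tau_NS,
                seed=seed, n_iterations=n_iterations,
            )
            res = simulate_schedule(space, run_params, sched, n_last=n_last)
            tail = np.array(res.history[-min(n_last, len(res.history)):])
            tails.append(tail)
            rows.append(
                {
                    "tau": tau,
                    "tau_over_tau_c": tau / tau_c,
                    "scenario": f"randomized({chi})",
                    "seed": str(seed),
                    "mean": res.mean,
                    "sd": res.sd,
                    "n_samples": len(tail),
                }
            )
        pooled = np.concatenate(tails)
        rows.append(
            {
                "tau": tau,
                "tau_over_tau_c": tau / tau_c,
                "scenario": f"randomized({chi})",
                "seed": "pooled",
                "mean": float(pooled.mean()),
                "sd": float(pooled.std(ddof=0)),
                "n_samples": len(pooled),
            }
        )
    return pd.DataFrame(rows)


_STRATEGIES = {
    "combined-4": StressSchedule.combined,
    "paired-2x2": StressSchedule.paired,
    "sequential-4": StressSchedule.sequential,
}


def treatment_comparison(
    params: ModelParameters,
    tau_grid,
    *,
    max_cycles: int = 10_000,
    convergence_tol: float = 1e-9,
    extinction_tol: float = 1e-10,
) -> pd.DataFrame:
    """Compare simultaneous, paired, and sequential application of 4 stresses.

    One full pass through all stresses takes ``tau`` in every strategy:
    all four at once every ``tau`` (combined), two pairs alternating every
    ``tau/2`` (paired), or each stress alone every ``tau/4`` (sequential).
    Besides the long-term SIM prevalence, the multi-resistance class
    frequencies (share of the population resistant to exactly k stresses)
    of the final population are reported.
    """
    chi = 4
    space = build_space(chi)
    tau_c = analytic.critical_cycle_length(params)
    rows = []
    tau_grid = np.asarray(tau_grid, dtype=float)
    keep = tau_grid / chi > params.tau_S  # sequential needs tau/4 > tau_S
    if not keep.all():
        warnings.warn(
            f"skipping {int((~keep).sum())} grid point(s) with tau/4 <= tau_S",
            stacklevel=2,
        )
    for tau in tau_grid[keep]:
        for strategy, maker in _STRATEGIES.items():
            sched = maker(chi, params.tau_S, float(tau))
            res = simulate_schedule(
                space, params, sched, max_supercycles=max_cycles,
                convergence_tol=convergence_tol, extinction_tol=extinction_tol,
            )
            row = {
                "tau": tau,
                "tau_over_tau_c": tau / tau_c,
                "scenario": strategy,
                "p_hat_M_simulated": res.p_hat_M,
                "converged": res.converged,
                "n_cycles": res.n_cycles,
            }
            multi = multiresistance_frequencies(res.final_state, space)
            for k, freq in enumerate(multi):
                row[f"multiresistance_{k}"] = float(freq)
            rows.append(row)
    return pd.DataFrame(rows)
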