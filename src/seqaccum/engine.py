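"""Shared integration driver, session batching, psychometrics, model
tuning curves, and simulated single-neuron perturbations.

Trials are integrated piecewise between "breakpoints" — the positions at
which the right-hand side is discontinuous (square-gate transitions, cue
pulse edges, perturbation-window edges).  Within each segment the cue
indicators and (square-type) gate drive are constant, so a stiff-capable
adaptive integrator with an enforced maximum step integrates each piece
accurately; the breakpoints also guarantee that no 1-cm cue pulse can be
stepped over.  Trajectories are reported on a fixed 0.1 cm position grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .maze import (
    MazeGeometry,
    NoiseConfig,
    Trial,
    apply_input_noise,
    evidence_before,
    final_evidence,
)

__all__ = [
    "SolverConfig",
    "SimulationResult",
    "SessionResult",
    "Perturbation",
    "integrate",
    "simulate_trial",
    "simulate_trials",
    "run_noise_sessions",
    "psychometric_curve",
    "model_tuning_curves",
    "run_perturbation",
]


@dataclass(frozen=True)
class SolverConfig:
    """Integration settings.

    ``max_step`` (s) must satisfy max_step * velocity <= 1 cm (the cue
    pulse width); the default 0.01 s equals 0.5 cm at 50 cm/s.
    """

    max_step: float = 0.01
    grid_step: float = 0.1
    rtol: float = 1e-6
    atol: float = 1e-8
    method: str = "LSODA"

    def validate(self, geometry: MazeGeometry) -> None:
        if self.max_step * geometry.velocity > 2 * 0.5 + 1e-9:
            raise ValueError(
                "max_step too large: a cue pulse could be skipped"
            )


@dataclass
class SimulationResult:
    """Per-unit firing-rate trajectories on the position grid, plus choice."""

    rates: np.ndarray          # (n_units, n_grid), Hz
    grid: np.ndarray           # positions, cm
    choice: str                # 'left' or 'right'
    trial: Trial
    model_name: str = ""

    @property
    def final_rates(self) -> np.ndarray:
        return self.rates[:, -1]

    @property
    def correct(self) -> bool | None:
        ev = final_evidence(self.trial)
        if ev == 0:
            return None
        return self.choice == ("right" if ev > 0 else "left")


@dataclass
class SessionResult:
    """One simulated session: results plus the pre-noise source trials."""

    results: list[SimulationResult]
    original_trials: list[Trial]
    noise_applied: bool
    seed: int | None = None

    @property
    def choices(self) -> list[str]:
        return [r.choice for r in self.results]

    @property
    def original_deltas(self) -> np.ndarray:
        return np.array([final_evidence(t) for t in self.original_trials])


@dataclass(frozen=True)
class Perturbation:
    """Subthreshold excitatory drive O (Hz/s) to one unit, applied while the
    subject is within the unit's active position window."""

    unit: int
    magnitude: float
    window: tuple[float, float]

    def drive(self, n_units: int) -> np.ndarray:
        out = np.zeros(n_units)
        out[self.unit] = self.magnitude
        return out


def integrate(
    model,
    trial: Trial,
    solver: SolverConfig | None = None,
    perturb: Perturbation | None = None,
    extra_breakpoints: Sequence[float] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate one trial; returns (grid positions, rates (n_units, n_grid)).

    The model supplies ``init_state``, ``breakpoints`` (positions of RHS
    discontinuities) and ``make_rhs(trial, p_mid, perturb_drive)``.
    """
    solver = solver or SolverConfig()
    g: MazeGeometry = model.geometry
    solver.validate(g)
    grid = g.position_grid(solver.grid_step)
    t_grid = np.asarray(g.time_at(grid), dtype=float)
    t_end = float(t_grid[-1])

    bp_pos = np.asarray(model.breakpoints(trial), dtype=float)
    if extra_breakpoints is not None and len(extra_breakpoints):
        bp_pos = np.concatenate([bp_pos, np.asarray(extra_breakpoints, dtype=float)])
    if perturb is not None:
        bp_pos = np.concatenate([bp_pos, np.asarray(perturb.window)])
    bp_t = np.asarray(g.time_at(bp_pos), dtype=float)
    bp_t = bp_t[(bp_t > 0) & (bp_t < t_end)]
    edges = np.unique(np.concatenate([[0.0], bp_t, [t_end]]))

    n_units = model.n_units
    rates = np.empty((n_units, t_grid.size))
    y = np.asarray(model.init_state(trial), dtype=float)

    for ta, tb in zip(edges[:-1], edges[1:]):
        if tb - ta < 1e-12:
            continue
        p_mid = float(g.position_at(0.5 * (ta + tb)))
        drive = None
        if perturb is not None and perturb.window[0] <= p_mid < perturb.window[1]:
            drive = perturb.drive(n_units)
        rhs = model.make_rhs(trial, p_mid, drive)
        lo = int(np.searchsorted(t_grid, ta - 1e-9, side="left"))
        hi = int(np.searchsorted(t_grid, tb - 1e-9, side="left"))
        if tb >= t_end - 1e-9:
            hi = t_grid.size
        sel = t_grid[lo:hi]
        # always integrate to the exact segment endpoint to carry the state
        if sel.size and sel[-1] >= tb - 1e-9:
            t_eval = sel
            n_keep = sel.size
        else:
            t_eval = np.append(sel, tb)
            n_keep = sel.size
        sol = solve_ivp(
            rhs,
            (ta, tb),
            y,
            method=solver.method,
            t_eval=t_eval,
            max_step=solver.max_step,
            rtol=solver.rtol,
            atol=solver.atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on trial {trial.trial_id}: {sol.message}"
            )
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            raise RuntimeError(
                f"non-finite state on trial {trial.trial_id} at t={tb:.3f}"
            )
        if n_keep:
            rates[:, lo:lo + n_keep] = sol.y[:, :n_keep]

    # the dense-output interpolant can undershoot the rectified dynamics
    # by ~1e-13 near zero; the true solutions are non-negative
    np.maximum(rates, 0.0, out=rates)
    return grid, rates


def simulate_trial(
    model,
    trial: Trial,
    solver: SolverConfig | None = None,
    rng: np.random.Generator | None = None,
    perturb: Perturbation | None = None,
) -> SimulationResult:
    rng = rng if rng is not None else np.random.default_rng()
    grid, rates = integrate(model, trial, solver, perturb)
    choice = model.readout(rates[:, -1], rng)
    return SimulationResult(
        rates=rates, grid=grid, choice=choice, trial=trial,
        model_name=getattr(model, "name", type(model).__name__),
    )


def simulate_trials(
    model,
    trials: Sequence[Trial],
    solver: SolverConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SimulationResult]:
    rng = rng if rng is not None else np.random.default_rng()
    return [simulate_trial(model, t, solver, rng) for t in trials]


def run_noise_sessions(
    model,
    trial_pool: Sequence[Trial],
    cfg: NoiseConfig | None = None,
    solver: SolverConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[SessionResult]:
    """Simulate sessions with input noise.

    Each session draws ``trials_per_session`` trials without replacement
    from the pool, independently drops each cue with probability
    1 - keep_prob, and simulates the model on the reduced cue sets.
    Psychometrics are computed downstream against the ORIGINAL cue counts.
    """
    cfg = cfg or NoiseConfig()
    if len(trial_pool) < cfg.trials_per_session:
        raise ValueError("trial pool smaller than trials_per_session")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    sessions = []
    for s in range(cfg.n_sessions):
        idx = rng.choice(len(trial_pool), size=cfg.trials_per_session, replace=False)
        originals = [trial_pool[i] for i in idx]
        noisy = [apply_input_noise(t, cfg, rng) for t in originals]
        results = simulate_trials(model, noisy, solver, rng)
        sessions.append(
            SessionResult(results=results, original_trials=originals,
                          noise_applied=cfg.keep_prob < 1.0, seed=cfg.seed)
        )
    return sessions


def psychometric_curve(
    deltas: np.ndarray,
    choices: Sequence[str],
    bin_size: int = 3,
    delta_range: tuple[int, int] = (-14, 14),
) -> pd.DataFrame:
    """Fraction of left choices per final-cue-difference bin.

    Deltas (#right - #left, from the original cue sets) are assigned to
    bins centered on multiples of ``bin_size``; values beyond the range are
    clipped into the outermost bins, keeping the binning symmetric about
    zero.  The s.e.m. is the per-bin binomial standard error.
    """
    deltas = np.asarray(deltas)
    left = np.array([c == "left" for c in choices], dtype=float)
    lo, hi = delta_range
    max_center = bin_size * int(np.floor(hi / bin_size))
    centers = bin_size * np.round(
        np.clip(deltas, lo, hi) / bin_size
    ).astype(int)
    centers = np.clip(centers, -max_center, max_center)
    rows = []
    for c in range(-max_center, max_center + 1, bin_size):
        m = centers == c
        n = int(m.sum())
        if n == 0:
            rows.append((c, np.nan, np.nan, 0))
            continue
        frac = left[m].mean()
        sem = np.sqrt(frac * (1 - frac) / n)
        rows.append((c, frac, sem, n))
    return pd.DataFrame(rows, columns=["delta_bin", "frac_left", "sem", "n_trials"])


def session_psychometrics(sessions: Sequence[SessionResult], **kw) -> pd.DataFrame:
    """Per-bin mean fraction-left across sessions with across-session s.e.m."""
    per = []
    for s in sessions:
        df = psychometric_curve(s.original_deltas, s.choices, **kw)
        per.append(df.set_index("delta_bin")["frac_left"])
    mat = pd.concat(per, axis=1)
    out = pd.DataFrame(
        {
            "frac_left": mat.mean(axis=1, skipna=True),
            "sem": mat.sem(axis=1, skipna=True),
            "n_sessions": mat.notna().sum(axis=1),
        }
    ).reset_index()
    return out


def model_tuning_curves(
    results: Sequence[SimulationResult],
    ev_range: tuple[int, int] = (-15, 15),
    min_samples: int = 2,
    units: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-unit evidence tuning at the unit's most active position.

    Rates are averaged in (grid position x integer evidence) bins across
    trials; bins with fewer than ``min_samples`` samples are dropped.  For
    each unit the position of maximal mean rate (averaged across evidence
    bins) is found, and the tuning curve is the mean rate versus evidence
    at that position.  Returns long-format rows
    (unit, peak_position, evidence, rate).
    """
    if len(results) < min_samples:
        raise ValueError("need at least min_samples trials")
    grid = results[0].grid
    n_units = results[0].rates.shape[0]
    if units is None:
        units = range(n_units)
    lo, hi = ev_range
    n_ev = hi - lo + 1
    n_bins = grid.size * n_ev
    # flat (position, evidence) bin index per grid sample, one per trial
    flats, masks = [], []
    counts = np.zeros(n_bins)
    for res in results:
        ev = np.asarray(evidence_before(res.trial, grid)) - lo
        ok = (ev >= 0) & (ev < n_ev)
        flat = np.arange(grid.size) * n_ev + np.where(ok, ev, 0)
        flats.append(flat)
        masks.append(ok)
        counts += np.bincount(flat[ok], minlength=n_bins)
    counts = counts.reshape(grid.size, n_ev)
    valid = counts >= min_samples
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        for u in units:
            sums = np.zeros(n_bins)
            for res, flat, ok in zip(results, flats, masks):
                sums += np.bincount(
                    flat[ok], weights=res.rates[u][ok], minlength=n_bins
                )
            m = sums.reshape(grid.size, n_ev) / counts
            m[~valid] = np.nan
            if np.all(np.isnan(m)):
                continue
            pos_mean = np.nanmean(m, axis=1)
            k = int(np.nanargmax(pos_mean))
            for j in range(n_ev):
                if valid[k, j]:
                    rows.append((u, grid[k], lo + j, m[k, j]))
    return pd.DataFrame(rows, columns=["unit", "peak_position", "evidence", "rate"])


def run_perturbation(
    model,
    unit: int,
    magnitude: float,
    solver: SolverConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Delta-rate map of stimulating one unit on a cue-free trial.

    The excitatory term is applied inside the thresholded dynamics while
    the subject is at the stimulated unit's active position.  Returns
    (grid, rates_perturbed - rates_control), shape (n_units, n_grid).
    """
    trial = Trial(trial_id=-1)
    window = _unit_window(model, unit)
    pert = Perturbation(unit=unit, magnitude=magnitude, window=window)
    # the control run uses identical segment boundaries so that the two
    # trajectories are bitwise identical up to perturbation onset
    grid, r_ctrl = integrate(model, trial, solver, None, extra_breakpoints=window)
    _, r_pert = integrate(model, trial, solver, pert)
    return grid, r_pert - r_ctrl


def _unit_window(model, unit: int) -> tuple[float, float]:
    """Active position window of a unit, for chain or bump state layouts."""
    table = model.unit_table()
    pos_index = int(table.loc[table["unit"] == unit, "position_index"].iloc[0])
    return model.gate.active_window(pos_index)
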