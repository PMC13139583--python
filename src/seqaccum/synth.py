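"""Synthetic neural sessions with known ground truth.

Every stage of the analysis pipeline (binning, joint tuning fits,
pseudosession significance, encoding/decoding regressions) is exercised
on sessions generated here, either

* **model-driven** — each synthetic neuron carries the firing-rate
  trajectory of one unit of a simulated circuit model (competing chains
  or position-gated bump attractor), resampled at the imaging frame rate,
  optionally with additive or Poisson-count noise; or
* **parametric** — neurons with separable ground-truth tuning
  FR(p, e) = A * P(p) * E(e) + B, where P is a position Gaussian and E is
  an evidence Gaussian (``gauss``), a logistic ramp (``logistic``), a pure
  choice dependence (``choice``), or absent (``null``).

Sessions emulate the structure the analyses consume: frames at 30 Hz
during a constant-velocity traversal, synchronized position and trial
indices, per-trial choices.  Choices follow the majority cue side with a
lapse probability that decays with |evidence| so that error trials exist
(required to separate evidence from choice coding).  What the generator
deliberately does not emulate: calcium indicator dynamics, spike
inference, view-angle or running-speed variability, and cross-neuron
noise correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .maze import MazeGeometry, Trial, evidence_before, final_evidence, generate_trials

__all__ = [
    "SyntheticSessionConfig",
    "SyntheticSession",
    "generate_session",
    "session_from_results",
    "smooth_rates",
    "gaussian_kernel",
    "causal_half_gaussian_kernel",
]


@dataclass(frozen=True)
class SyntheticSessionConfig:
    """Configuration of a parametric synthetic session."""

    n_neurons: int = 50
    n_trials: int = 150
    tuning_family: str = "gauss"   # gauss | logistic | choice | null
    noise_model: str = "none"      # none | gaussian | poisson
    noise_sd: float = 0.5          # Hz, gaussian noise only
    frame_rate: float = 30.0       # Hz
    amp_range: tuple[float, float] = (2.0, 8.0)
    offset_range: tuple[float, float] = (0.1, 1.0)
    mu_p_range: tuple[float, float] = (-20.0, 290.0)
    sigma_p_range: tuple[float, float] = (20.0, 45.0)
    mu_e_range: tuple[float, float] = (-8.0, 8.0)
    sigma_e_range: tuple[float, float] = (2.0, 6.0)
    logistic_k_range: tuple[float, float] = (0.15, 0.5)
    lapse_scale: float = 0.4       # lapse prob at |evidence| = 0 is 0.5*scale
    lapse_slope: float = 0.3       # decay of lapse with |evidence|
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        if self.tuning_family not in ("gauss", "logistic", "choice", "null"):
            raise ValueError(f"unknown tuning family {self.tuning_family!r}")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class SyntheticSession:
    """Raw traces plus synchronization and ground truth."""

    rates: np.ndarray        # (n_neurons, n_samples), Hz
    positions: np.ndarray    # (n_samples,), cm
    trial_index: np.ndarray  # (n_samples,), trial_id per sample
    trials: list[Trial]
    choices: np.ndarray      # (n_trials,)
    ground_truth: pd.DataFrame
    frame_rate: float = 30.0


def _lapse_choices(
    trials: Sequence[Trial],
    lapse_scale: float,
    lapse_slope: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Majority-side choices with evidence-dependent lapses.

    The probability of an error is 0.5 * lapse_scale * 2 /
    (1 + exp(lapse_slope * |e|)) — i.e. lapse_scale/ (1+exp(..)) * ... —
    shrinking with the final evidence magnitude; zero-evidence trials are
    unbiased coin flips.
    """
    out = []
    for t in trials:
        ev = final_evidence(t)
        if ev == 0:
            out.append("left" if rng.random() < 0.5 else "right")
            continue
        best = "right" if ev > 0 else "left"
        p_err = lapse_scale / (1.0 + np.exp(lapse_slope * abs(ev)))
        if rng.random() < p_err:
            best = "left" if best == "right" else "right"
        out.append(best)
    return np.asarray(out)


def _frame_grid(geometry: MazeGeometry, frame_rate: float) -> np.ndarray:
    n = int(np.floor(geometry.duration * frame_rate))
    t = np.arange(n + 1) / frame_rate
    return np.asarray(geometry.position_at(t))


def generate_session(
    cfg: SyntheticSessionConfig,
    geometry: MazeGeometry | None = None,
    rng: np.random.Generator | None = None,
    trials: Sequence[Trial] | None = None,
) -> SyntheticSession:
    """Generate a parametric synthetic session with stored ground truth."""
    geometry = geometry or MazeGeometry()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if trials is None:
        trials = generate_trials(cfg.n_trials, geometry=geometry, rng=rng)
    trials = list(trials)
    choices = _lapse_choices(trials, cfg.lapse_scale, cfg.lapse_slope, rng)

    frames = _frame_grid(geometry, cfg.frame_rate)
    n_f = frames.size
    positions = np.tile(frames, len(trials))
    trial_index = np.repeat([t.trial_id for t in trials], n_f)
    ev = np.stack([np.asarray(evidence_before(t, frames)) for t in trials])
    c_sign = np.where(choices == "right", 1.0, -1.0)

    gt_rows = []
    rates = np.empty((cfg.n_neurons, len(trials) * n_f))
    for u in range(cfg.n_neurons):
        A = rng.uniform(*cfg.amp_range)
        B = rng.uniform(*cfg.offset_range)
        mu_p = rng.uniform(*cfg.mu_p_range)
        sig_p = rng.uniform(*cfg.sigma_p_range)
        P = np.exp(-((frames - mu_p) ** 2) / (2 * sig_p**2))
        gt = {"neuron": u, "family": cfg.tuning_family, "amp": A, "offset": B,
              "mu_p": mu_p, "sigma_p": sig_p, "mu_e": np.nan, "sigma_e": np.nan,
              "k": np.nan}
        if cfg.tuning_family == "gauss":
            mu_e = rng.uniform(*cfg.mu_e_range)
            sig_e = rng.uniform(*cfg.sigma_e_range)
            E = np.exp(-((ev - mu_e) ** 2) / (2 * sig_e**2))
            gt.update(mu_e=mu_e, sigma_e=sig_e)
        elif cfg.tuning_family == "logistic":
            k = rng.uniform(*cfg.logistic_k_range) * (1 if rng.random() < 0.5 else -1)
            E = 1.0 / (1.0 + np.exp(-k * ev))
            gt.update(k=k)
        elif cfg.tuning_family == "choice":
            E = 0.5 * (1.0 + c_sign[:, None] * np.ones_like(ev))
        else:  # null: no evidence or choice dependence
            E = np.ones_like(ev, dtype=float)
        field_ = A * P[None, :] * E + B
        rates[u] = field_.reshape(-1)
        gt_rows.append(gt)

    if cfg.noise_model == "gaussian":
        rates = rates + rng.normal(0.0, cfg.noise_sd, rates.shape)
    elif cfg.noise_model == "poisson":
        # Poisson spike counts per frame, converted back to a rate
        counts = rng.poisson(np.maximum(rates, 0.0) / cfg.frame_rate)
        rates = counts * cfg.frame_rate
    return SyntheticSession(
        rates=rates,
        positions=positions,
        trial_index=trial_index,
        trials=trials,
        choices=choices,
        ground_truth=pd.DataFrame(gt_rows),
        frame_rate=cfg.frame_rate,
    )


def session_from_results(
    results,
    geometry: MazeGeometry | None = None,
    frame_rate: float = 30.0,
    noise_sd: float = 0.0,
    units: Sequence[int] | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticSession:
    """Build a session whose neurons are units of simulated model trials.

    Rates are linearly interpolated from the simulation grid onto imaging
    frames; choices are the model's own readout.  ``units`` selects a
    subset of model units (default: all).
    """
    geometry = geometry or MazeGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    frames = _frame_grid(geometry, frame_rate)
    n_f = frames.size
    grid = results[0].grid
    n_units = results[0].rates.shape[0]
    units = np.arange(n_units) if units is None else np.asarray(units, int)
    rates = np.empty((units.size, len(results) * n_f))
    for k, res in enumerate(results):
        block = slice(k * n_f, (k + 1) * n_f)
        for j, u in enumerate(units):
            rates[j, block] = np.interp(frames, grid, res.rates[u])
    if noise_sd > 0:
        rates = np.maximum(rates + rng.normal(0.0, noise_sd, rates.shape), 0.0)
    gt = pd.DataFrame({"neuron": np.arange(units.size), "model_unit": units})
    return SyntheticSession(
        rates=rates,
        positions=np.tile(frames, len(results)),
        trial_index=np.repeat([r.trial.trial_id for r in results], n_f),
        trials=[r.trial for r in results],
        choices=np.asarray([r.choice for r in results]),
        ground_truth=gt,
        frame_rate=frame_rate,
    )


def gaussian_kernel(frame_rate: float, window: float = 1.0, sd: float = 0.25) -> np.ndarray:
    """Symmetric Gaussian smoothing kernel, normalized to unit sum."""
    half = window / 2.0
    t = np.arange(-half, half + 0.5 / frame_rate, 1.0 / frame_rate)
    k = np.exp(-(t**2) / (2 * sd**2))
    return k / k.sum()


def causal_half_gaussian_kernel(
    frame_rate: float, window: float = 1.0, sd: float = 0.25
) -> np.ndarray:
    """Causal half-Gaussian kernel (zero weight on future samples)."""
    t = np.arange(0.0, window + 0.5 / frame_rate, 1.0 / frame_rate)
    k = np.exp(-(t**2) / (2 * sd**2))
    return k / k.sum()


def smooth_rates(
    spikes: np.ndarray,
    frame_rate: float = 30.0,
    window: float = 1.0,
    sd: float = 0.25,
    causal: bool = False,
) -> np.ndarray:
    """Convolve spike/rate traces with a (half-)Gaussian window.

    The kernel is normalized to unit sum, so total mass is preserved up to
    edge effects; the causal variant produces no output before a spike.
    ``spikes`` is (n_neurons, n_samples) or (n_samples,).
    """
    x = np.atleast_2d(np.asarray(spikes, dtype=float))
    if causal:
        k = causal_half_gaussian_kernel(frame_rate, window, sd)
        pad = k.size - 1
        out = np.stack([
            np.convolve(np.r_[np.zeros(0), row], k, mode="full")[: row.size]
            for row in x
        ])
    else:
        k = gaussian_kernel(frame_rate, window, sd)
        out = np.stack([
            np.convolve(row, k, mode="same") for row in x
        ])
    return out if np.asarray(spikes).ndim > 1 else out[0]
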