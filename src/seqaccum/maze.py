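"""Task geometry and trial generation for the accumulating-towers task.

The task is a virtual T-maze traversed at constant speed: a 30 cm precue
region, a 200 cm cue region in which "tower" cues appear on the left and
right walls with Poisson counts, and a 100 cm delay region with no cues.
The subject is rewarded for choosing the side that carried more towers, so
correct behavior requires accumulating the signed cue count (right minus
left) and holding it across the delay.

This module owns the geometry, the per-trial cue lists, the cue-indicator
pulses that drive the circuit models, the accumulated-evidence bookkeeping
used by every analysis, and the sensory-noise protocol in which a fraction
of cues is dropped before simulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CUE_HALF_WIDTH_CM",
    "MazeGeometry",
    "Trial",
    "NoiseConfig",
    "generate_trial",
    "generate_trials",
    "cue_indicator",
    "final_evidence",
    "evidence_before",
    "apply_input_noise",
    "mirror_trial",
    "trials_to_frame",
    "trials_from_frame",
    "write_trials_csv",
    "read_trials_csv",
]

#: Half-width (cm) of the position window over which a cue drives the
#: indicator 1_left/1_right: the indicator is 1 iff some cue of that side
#: lies strictly within this distance of the current position.
CUE_HALF_WIDTH_CM = 0.5


@dataclass(frozen=True)
class MazeGeometry:
    """Maze layout and traversal speed.

    Positions are in cm; the subject moves at constant ``velocity`` (cm/s)
    so that position and time are interchangeable via
    ``p(t) = precue_start + velocity * t``.
    """

    precue_start: float = -30.0
    cue_start: float = 0.0
    cue_end: float = 200.0
    maze_end: float = 300.0
    velocity: float = 50.0

    def __post_init__(self) -> None:
        if not (self.precue_start < self.cue_start < self.cue_end < self.maze_end):
            raise ValueError(
                "geometry requires precue_start < cue_start < cue_end < maze_end"
            )
        if self.velocity <= 0:
            raise ValueError("velocity must be positive")

    @property
    def span(self) -> float:
        return self.maze_end - self.precue_start

    @property
    def duration(self) -> float:
        """Trial duration in seconds at constant velocity."""
        return self.span / self.velocity

    def position_at(self, t: float | np.ndarray) -> float | np.ndarray:
        return self.precue_start + self.velocity * np.asarray(t)

    def time_at(self, p: float | np.ndarray) -> float | np.ndarray:
        return (np.asarray(p) - self.precue_start) / self.velocity

    def position_grid(self, step: float = 0.1) -> np.ndarray:
        """Uniform position grid from precue start to maze end, inclusive."""
        n = int(round(self.span / step))
        return self.precue_start + step * np.arange(n + 1)


def _as_sorted_tuple(cues: Iterable[float]) -> tuple[float, ...]:
    return tuple(sorted(float(c) for c in cues))


@dataclass(frozen=True)
class Trial:
    """One trial's cue lists: ordered left/right tower positions in cm."""

    left_cues: tuple[float, ...] = ()
    right_cues: tuple[float, ...] = ()
    trial_id: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_cues", _as_sorted_tuple(self.left_cues))
        object.__setattr__(self, "right_cues", _as_sorted_tuple(self.right_cues))

    def validate(self, geometry: MazeGeometry, min_spacing: float = 0.0) -> None:
        for side in (self.left_cues, self.right_cues):
            arr = np.asarray(side, dtype=float)
            if arr.size and not (
                (arr >= geometry.cue_start).all() & (arr < geometry.cue_end).all()
            ):
                raise ValueError("cue positions must lie within the cue region")
            if arr.size > 1 and np.diff(arr).min() < min_spacing:
                raise ValueError("cues on one side closer than min_spacing")

    @property
    def n_left(self) -> int:
        return len(self.left_cues)

    @property
    def n_right(self) -> int:
        return len(self.right_cues)


@dataclass(frozen=True)
class NoiseConfig:
    """Input-noise protocol: each cue is kept with probability ``keep_prob``.

    The default 0.33 corresponds to the subject ignoring or failing to
    perceive 67% of the cues; sessions of 150 trials are resampled without
    replacement from a larger pool, 25 sessions per experiment.
    """

    keep_prob: float = 0.33
    n_sessions: int = 25
    trials_per_session: int = 150
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.keep_prob <= 1.0:
            raise ValueError("keep_prob must lie in [0, 1]")


def _draw_spaced_positions(
    n: int,
    geometry: MazeGeometry,
    min_spacing: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform cue positions in the cue region with pairwise gaps >= min_spacing.

    Uses the order-statistics construction: draw n uniforms on the cue
    region shrunk by (n-1) * min_spacing, sort, and add i * min_spacing to
    the i-th — this is exactly the uniform distribution conditioned on all
    gaps exceeding the minimum, so it never rejects and the Poisson count
    marginals are preserved.  If n cues cannot physically fit, the count is
    reduced to the largest feasible number.
    """
    if n == 0:
        return np.empty(0)
    span = geometry.cue_end - geometry.cue_start
    if min_spacing > 0:
        n_max = int(span // min_spacing) + 1
        n = min(n, n_max)
    free = span - (n - 1) * min_spacing
    base = np.sort(rng.uniform(0.0, free, size=n))
    return geometry.cue_start + base + min_spacing * np.arange(n)


def generate_trial(
    mean_left: float,
    mean_right: float,
    geometry: MazeGeometry | None = None,
    min_spacing: float = 12.0,
    rng: np.random.Generator | None = None,
    trial_id: int = 0,
) -> Trial:
    """Draw one trial: Poisson cue counts, uniform spaced positions."""
    if mean_left < 0 or mean_right < 0:
        raise ValueError("Poisson rates must be non-negative")
    if min_spacing < 0:
        raise ValueError("min_spacing must be non-negative")
    geometry = geometry or MazeGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    n_left = rng.poisson(mean_left)
    n_right = rng.poisson(mean_right)
    left = _draw_spaced_positions(n_left, geometry, min_spacing, rng)
    right = _draw_spaced_positions(n_right, geometry, min_spacing, rng)
    return Trial(left_cues=tuple(left), right_cues=tuple(right), trial_id=trial_id)


def generate_trials(
    n_trials: int,
    mean_low: float = 2.3,
    mean_high: float = 7.7,
    geometry: MazeGeometry | None = None,
    min_spacing: float = 12.0,
    rng: np.random.Generator | None = None,
    randomize_sides: bool = True,
) -> list[Trial]:
    """Generate a trial pool; the higher-rate side is randomized per trial."""
    rng = rng if rng is not None else np.random.default_rng()
    trials = []
    for k in range(n_trials):
        if randomize_sides and rng.random() < 0.5:
            ml, mr = mean_high, mean_low
        else:
            ml, mr = mean_low, mean_high
        trials.append(
            generate_trial(ml, mr, geometry, min_spacing, rng, trial_id=k)
        )
    return trials


def cue_indicator(trial: Trial, p: float, side: str) -> int:
    """1 iff a cue of ``side`` lies strictly within 0.5 cm of position p."""
    cues = trial.left_cues if side == "left" else trial.right_cues
    if not cues:
        return 0
    arr = np.asarray(cues)
    return int(np.min(np.abs(arr - p)) < CUE_HALF_WIDTH_CM)


def final_evidence(trial: Trial) -> int:
    """Signed final cue count: number of right minus number of left cues."""
    return trial.n_right - trial.n_left


def evidence_before(trial: Trial, p: float | np.ndarray) -> int | np.ndarray:
    """Accumulated evidence from cues strictly before position p.

    Defined as the number of right minus the number of left cues whose
    position is < p, matching the convention that the evidence assigned to
    a position bin counts the cues observed before the bin start.
    """
    left = np.asarray(trial.left_cues)
    right = np.asarray(trial.right_cues)
    p_arr = np.asarray(p)
    ev = np.searchsorted(right, p_arr, side="left") - np.searchsorted(
        left, p_arr, side="left"
    )
    if np.isscalar(p) or p_arr.ndim == 0:
        return int(ev)
    return ev


def apply_input_noise(
    trial: Trial, cfg: NoiseConfig | float, rng: np.random.Generator
) -> Trial:
    """Drop cues independently, keeping each with probability keep_prob."""
    keep_prob = cfg.keep_prob if isinstance(cfg, NoiseConfig) else float(cfg)
    left = tuple(c for c in trial.left_cues if rng.random() < keep_prob)
    right = tuple(c for c in trial.right_cues if rng.random() < keep_prob)
    return Trial(left_cues=left, right_cues=right, trial_id=trial.trial_id)


def mirror_trial(trial: Trial) -> Trial:
    """Swap the left and right cue lists (used in symmetry checks)."""
    return Trial(
        left_cues=trial.right_cues,
        right_cues=trial.left_cues,
        trial_id=trial.trial_id,
    )


def trials_to_frame(trials: Sequence[Trial]) -> pd.DataFrame:
    rows = []
    for t in trials:
        for c in t.left_cues:
            rows.append((t.trial_id, "L", c))
        for c in t.right_cues:
            rows.append((t.trial_id, "R", c))
        if not t.left_cues and not t.right_cues:
            # keep empty trials representable in the table
            rows.append((t.trial_id, "none", np.nan))
    return pd.DataFrame(rows, columns=["trial_id", "side", "cue_position_cm"])


def trials_from_frame(df: pd.DataFrame) -> list[Trial]:
    trials = []
    for tid, grp in df.groupby("trial_id", sort=True):
        left = grp.loc[grp["side"] == "L", "cue_position_cm"].tolist()
        right = grp.loc[grp["side"] == "R", "cue_position_cm"].tolist()
        trials.append(Trial(left_cues=tuple(left), right_cues=tuple(right), trial_id=int(tid)))
    return trials


def write_trials_csv(trials: Sequence[Trial], path) -> None:
    # %.17g keeps the float round-trip exact
    trials_to_frame(trials).to_csv(path, index=False, float_format="%.17g")


def read_trials_csv(path) -> list[Trial]:
    return trials_from_frame(pd.read_csv(path, float_precision="round_trip"))
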