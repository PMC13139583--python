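"""Position-gating signals shared by the sequence models.

A position gate P_i(p) delivers a suprathreshold drive to the pair (or
layer) of neurons encoding the current maze position and nothing to the
rest, so that the feedforward chain advances in lockstep with the subject.
Three gate families are provided:

* ``SquareGate`` — the default: gate i is on while i <= p/P0 < i+1, with
  drive T + X.  With P0 = 20 cm the −30..300 cm maze is partitioned into
  17 sections.
* ``GaussianGate`` — a smooth bell-shaped gate alpha * exp(-(p-mu_i)^2/beta)
  with mu_i = 20 i − 10; every gate is simultaneously (weakly) nonzero.
  This variant is paired with a lowered firing threshold (T = 1100 Hz/s).
* ``HeterogeneousGate`` — square sections with random widths: transition
  points are drawn uniformly over the maze and nudged apart so that no
  section is narrower than 5 cm.

Gate indices for the square gate run from floor(precue_start/P0) (−2 at
defaults) to 14; neuron indices are 0-based from the maze start, i.e.
neuron k corresponds to gate index k + floor(precue_start/P0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maze import MazeGeometry

__all__ = [
    "SquareGate",
    "GaussianGate",
    "HeterogeneousGate",
    "draw_heterogeneous_gates",
]


@dataclass(frozen=True)
class SquareGate:
    """Square position gate: drive T + X on section [i*P0, (i+1)*P0)."""

    P0: float = 20.0
    T: float = 15000.0
    X: float = 500.0
    geometry: MazeGeometry = field(default_factory=MazeGeometry)

    def __post_init__(self) -> None:
        if self.P0 <= 0:
            raise ValueError("P0 must be positive")

    @property
    def index_origin(self) -> int:
        """Gate index of the first section (floor(precue_start / P0))."""
        return math.floor(self.geometry.precue_start / self.P0)

    @property
    def n_gates(self) -> int:
        """Number of distinct gate sections covering [precue_start, maze_end)."""
        last = math.floor(
            (self.geometry.maze_end - 1e-9) / self.P0
        )  # maze_end itself is exclusive
        return last - self.index_origin + 1

    def index(self, p: float) -> int:
        """The unique gate index i with i <= p/P0 < i+1."""
        return math.floor(p / self.P0)

    def value(self, p: float, i: int) -> float:
        return self.T + self.X if i <= p / self.P0 < i + 1 else 0.0

    def neuron_index(self, p: float) -> int:
        """0-based neuron index active at position p."""
        return self.index(p) - self.index_origin

    def active_window(self, neuron: int) -> tuple[float, float]:
        """Position interval [lo, hi) over which ``neuron`` is gated on."""
        i = neuron + self.index_origin
        return (i * self.P0, (i + 1) * self.P0)

    def drive(self, p: float, n_units: int) -> np.ndarray:
        out = np.zeros(n_units)
        k = self.neuron_index(p)
        if 0 <= k < n_units:
            out[k] = self.T + self.X
        return out

    def boundaries(self) -> np.ndarray:
        """Interior gate-transition positions (strictly inside the maze)."""
        g = self.geometry
        first = math.ceil(g.precue_start / self.P0 + 1e-12)
        pts = self.P0 * np.arange(first, math.ceil(g.maze_end / self.P0))
        return pts[(pts > g.precue_start) & (pts < g.maze_end)]


@dataclass(frozen=True)
class GaussianGate:
    """Smooth Gaussian gate alpha * exp(-(p - mu_i)^2 / beta), mu_i = 20 i - 10.

    All gates are simultaneously nonzero; the chain variant using this gate
    runs with a lowered threshold (T = 1100 Hz/s by convention).
    """

    alpha: float = 60.0
    beta: float = 1250.0
    spacing: float = 20.0
    geometry: MazeGeometry = field(default_factory=MazeGeometry)

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    @property
    def index_origin(self) -> int:
        return math.floor(self.geometry.precue_start / self.spacing)

    @property
    def n_gates(self) -> int:
        last = math.floor((self.geometry.maze_end - 1e-9) / self.spacing)
        return last - self.index_origin + 1

    def center(self, i: int) -> float:
        return self.spacing * i - 10.0

    def value(self, p: float, i: int) -> float:
        return self.alpha * math.exp(-((p - self.center(i)) ** 2) / self.beta)

    def active_window(self, neuron: int) -> tuple[float, float]:
        # same index map as the square gate; used for perturbation windows
        i = neuron + self.index_origin
        return (i * self.spacing, (i + 1) * self.spacing)

    def drive(self, p: float, n_units: int) -> np.ndarray:
        i = self.index_origin + np.arange(n_units)
        mu = self.spacing * i - 10.0
        return self.alpha * np.exp(-((p - mu) ** 2) / self.beta)

    def boundaries(self) -> np.ndarray:
        return np.empty(0)  # smooth gate: no RHS discontinuities


@dataclass(frozen=True)
class HeterogeneousGate:
    """Square gate with random section widths.

    Gate i is active on [rho_i, rho_{i+1}); the last gate extends to the
    maze end.  Positions before rho_0 activate no gate.
    """

    transition_points: tuple[float, ...]
    T: float = 15000.0
    X: float = 500.0
    geometry: MazeGeometry = field(default_factory=MazeGeometry)

    def __post_init__(self) -> None:
        pts = np.asarray(self.transition_points, dtype=float)
        if pts.size < 1:
            raise ValueError("need at least one transition point")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("transition points must be strictly increasing")
        if pts[-1] >= self.geometry.maze_end:
            raise ValueError("transition points exceed the maze end")

    @property
    def n_gates(self) -> int:
        return len(self.transition_points)

    def edges(self) -> np.ndarray:
        """Section edges, closing the final section at the maze end."""
        return np.append(
            np.asarray(self.transition_points, dtype=float),
            self.geometry.maze_end,
        )

    def neuron_index(self, p: float) -> int:
        """Active neuron index at p, or -1 if p precedes the first section."""
        e = self.edges()
        if p < e[0] or p >= e[-1]:
            return -1
        return int(np.searchsorted(e, p, side="right") - 1)

    def active_window(self, neuron: int) -> tuple[float, float]:
        e = self.edges()
        return (e[neuron], e[neuron + 1])

    def value(self, p: float, i: int) -> float:
        lo, hi = self.active_window(i)
        return self.T + self.X if lo <= p < hi else 0.0

    def drive(self, p: float, n_units: int) -> np.ndarray:
        out = np.zeros(n_units)
        k = self.neuron_index(p)
        if 0 <= k < n_units:
            out[k] = self.T + self.X
        return out

    def boundaries(self) -> np.ndarray:
        g = self.geometry
        pts = np.asarray(self.transition_points)
        return pts[(pts > g.precue_start) & (pts < g.maze_end)]


def draw_heterogeneous_gates(
    n: int,
    geometry: MazeGeometry | None = None,
    min_gap: float = 5.0,
    rng: np.random.Generator | None = None,
    T: float = 15000.0,
    X: float = 500.0,
) -> HeterogeneousGate:
    """Draw n transition points uniformly over the maze, enforcing min gaps.

    Points are sorted; scanning left to right, whenever two consecutive
    points are closer than ``min_gap`` the later point is incremented by
    ``min_gap`` (exactly), after which subsequent gaps are re-checked.
    Raises if the adjusted points run past the maze end.
    """
    if n < 1:
        raise ValueError("need n >= 1 gates")
    geometry = geometry or MazeGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    pts = np.sort(rng.uniform(geometry.precue_start, geometry.maze_end, size=n))
    for i in range(1, n):
        if pts[i] - pts[i - 1] < min_gap:
            pts[i] = pts[i] + min_gap
    if pts[-1] >= geometry.maze_end:
        raise ValueError("adjusted transition points exceed the maze end")
    if n > 1 and np.diff(pts).min() < min_gap:
        # a +5 cm nudge can still leave a short gap if the raw points were
        # extremely dense; re-apply until stable (bounded by n passes)
        for _ in range(n):
            changed = False
            for i in range(1, n):
                if pts[i] - pts[i - 1] < min_gap:
                    pts[i] += min_gap
                    changed = True
            if not changed:
                break
        if pts[-1] >= geometry.maze_end:
            raise ValueError("adjusted transition points exceed the maze end")
    return HeterogeneousGate(
        transition_points=tuple(pts), T=T, X=X, geometry=geometry
    )
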