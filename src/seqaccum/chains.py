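"""Competing-chains circuit models of evidence accumulation.

Two chains of rate units (left and right) encode position in which pair is
active and accumulated evidence in the difference of the active pair's
firing rates.  The active pair is selected by a position gate; feedforward
connections hand the accumulated difference to the next pair as the
subject advances.

The mutually inhibiting variant obeys, for the i-th left-chain unit,

    dr_iL/dt = -a r_iL + [b r_iL + c r_(i-1)L - e r_iR
                          + f 1_left(t) + P_i(t) - T]^+

with the mirror-image equation for the right chain.  At the default
parameters (a=50, b=10, c=50, e=40 s^-1) the difference r_L - r_R of the
active pair is a perfect integrator of the cue pulses (-a + b + e = 0) and
is transferred with unit gain to the next pair (c = a), so each 1-cm cue
pulse at f = 100 Hz/s and 50 cm/s adds exactly 2 Hz to the difference,
until the nondominant chain saturates at zero rate.

Variants: ``uncoupled`` removes cross-inhibition and feeds cues push-pull
(+f for own side, -f for the other) into each chain; ``unstable`` ramps the
self-excitation b_i = b0 + delta*i along the chain so the integrator grows
increasingly unstable toward the end of the maze, sharpening evidence
tuning into choice tuning.  A population of threshold ("choice readout")
cells reading the sign of the active pair's difference is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .maze import CUE_HALF_WIDTH_CM, MazeGeometry, Trial
from .gating import GaussianGate, HeterogeneousGate, SquareGate

__all__ = [
    "ChainModelParams",
    "ChainModel",
    "TraditionalAccumulator",
    "ReadoutParams",
    "readout_choice_chains",
    "choice_readout_rates",
    "unstable_self_excitation",
]


def unstable_self_excitation(i: int | np.ndarray, b0: float, delta: float):
    """Position-dependent self-excitation b_i = b0 + delta * i."""
    return b0 + delta * np.asarray(i)


@dataclass(frozen=True)
class ChainModelParams:
    """Parameters of the competing-chains rate equations (rates in s^-1,
    drives in Hz/s)."""

    a: float = 50.0
    b: float = 10.0
    c: float = 50.0
    e: float = 40.0
    f: float = 100.0
    T: float = 15000.0
    X: float = 500.0
    n_positions: int = 17
    variant: str = "mutual"
    delta: float = 0.5  # instability increment, unstable variant only
    r_init: float = 0.0  # baseline rate of the first active pair

    def __post_init__(self) -> None:
        if self.variant not in ("mutual", "uncoupled", "unstable"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("a", "b", "c", "e", "f", "T"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def mutual(cls, **kw) -> "ChainModelParams":
        return cls(variant="mutual", **kw)

    @classmethod
    def uncoupled(cls, **kw) -> "ChainModelParams":
        """Uncoupled chains: no cross-inhibition, push-pull cue input.

        Perfect accumulation in a single chain requires the self-excitation
        to cancel the decay (b = a), and the gate must equal the threshold
        exactly (X = 0) to avoid integrating the gate itself.  A positive
        baseline rate lets opposing cues push activity below baseline.
        """
        kw.setdefault("b", kw.get("a", 50.0))
        kw.setdefault("e", 0.0)
        kw.setdefault("X", 0.0)
        kw.setdefault("r_init", 10.0)
        return cls(variant="uncoupled", **kw)

    @classmethod
    def unstable(cls, **kw) -> "ChainModelParams":
        return cls(variant="unstable", **kw)

    @property
    def n_units(self) -> int:
        return 2 * self.n_positions

    def b_vector(self) -> np.ndarray:
        i = np.arange(self.n_positions)
        if self.variant == "unstable":
            return unstable_self_excitation(i, self.b, self.delta)
        return np.full(self.n_positions, self.b)


class ChainModel:
    """Simulatable competing-chains model bound to a gate and geometry.

    State layout: ``y = [r_0L .. r_(n-1)L, r_0R .. r_(n-1)R]``.
    """

    name = "chains"

    def __init__(
        self,
        params: ChainModelParams | None = None,
        gate: SquareGate | GaussianGate | HeterogeneousGate | None = None,
        geometry: MazeGeometry | None = None,
    ):
        self.geometry = geometry or MazeGeometry()
        self.params = params or ChainModelParams()
        if gate is None:
            gate = SquareGate(T=self.params.T, X=self.params.X, geometry=self.geometry)
        self.gate = gate
        if gate.n_gates != self.params.n_positions:
            raise ValueError(
                f"gate has {gate.n_gates} sections but params expect "
                f"{self.params.n_positions} positions"
            )
        self._b = self.params.b_vector()

    @property
    def n_units(self) -> int:
        return self.params.n_units

    def unit_table(self):
        """Per-unit metadata: chain side and position index."""
        import pandas as pd

        n = self.params.n_positions
        return pd.DataFrame(
            {
                "unit": np.arange(2 * n),
                "side": ["left"] * n + ["right"] * n,
                "position_index": np.r_[np.arange(n), np.arange(n)],
            }
        )

    def init_state(self, trial: Trial) -> np.ndarray:
        y0 = np.zeros(self.n_units)
        if self.params.r_init > 0:
            n = self.params.n_positions
            y0[0] = y0[n] = self.params.r_init
        return y0

    def breakpoints(self, trial: Trial) -> np.ndarray:
        pts = [self.gate.boundaries()]
        for cues in (trial.left_cues, trial.right_cues):
            for cue in cues:
                pts.append(np.array([cue - CUE_HALF_WIDTH_CM, cue + CUE_HALF_WIDTH_CM]))
        return np.concatenate(pts) if pts else np.empty(0)

    def make_rhs(
        self,
        trial: Trial,
        p_mid: float,
        perturb: np.ndarray | None = None,
    ) -> Callable[[float, np.ndarray], np.ndarray]:
        """RHS closure valid on a segment with constant cue indicators.

        ``p_mid`` is any position interior to the segment; cue indicators
        are frozen at their value there.  For square-type gates the gate
        drive is frozen too; the Gaussian gate is evaluated continuously.
        ``perturb`` is an optional per-unit drive (Hz/s) added inside the
        rectification bracket.
        """
        prm = self.params
        n = prm.n_positions
        g = self.geometry
        from .maze import cue_indicator

        ind_l = cue_indicator(trial, p_mid, "left")
        ind_r = cue_indicator(trial, p_mid, "right")
        b_vec = self._b
        a, c, e, f, T = prm.a, prm.c, prm.e, prm.f, prm.T
        O = np.zeros(self.n_units) if perturb is None else perturb
        O_L, O_R = O[:n], O[n:]
        uncoupled = prm.variant == "uncoupled"
        if uncoupled:
            in_l = f * (ind_l - ind_r)
            in_r = f * (ind_r - ind_l)
        else:
            in_l = f * ind_l
            in_r = f * ind_r

        gate = self.gate
        smooth_gate = isinstance(gate, GaussianGate)
        if not smooth_gate:
            P_fixed = gate.drive(p_mid, n)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            rL = y[:n]
            rR = y[n:]
            P = gate.drive(g.position_at(t), n) if smooth_gate else P_fixed
            ff_L = np.empty(n)
            ff_R = np.empty(n)
            ff_L[0] = 0.0  # the first unit has no predecessor
            ff_R[0] = 0.0
            ff_L[1:] = c * rL[:-1]
            ff_R[1:] = c * rR[:-1]
            brk_L = b_vec * rL + ff_L + in_l + P - T + O_L
            brk_R = b_vec * rR + ff_R + in_r + P - T + O_R
            if not uncoupled:
                brk_L = brk_L - e * rR
                brk_R = brk_R - e * rL
            dL = -a * rL + np.maximum(brk_L, 0.0)
            dR = -a * rR + np.maximum(brk_R, 0.0)
            return np.concatenate([dL, dR])

        return rhs

    def readout(self, final_rates: np.ndarray, rng: np.random.Generator) -> str:
        return readout_choice_chains(final_rates, self.params.n_positions, rng)


def readout_choice_chains(
    final_rates: np.ndarray, n_positions: int, rng: np.random.Generator
) -> str:
    """Choice from the final units of the two chains; exact ties are random."""
    last_L = final_rates[n_positions - 1]
    last_R = final_rates[2 * n_positions - 1]
    if last_L > last_R:
        return "left"
    if last_R > last_L:
        return "right"
    return "left" if rng.random() < 0.5 else "right"


@dataclass(frozen=True)
class ReadoutParams:
    """Choice readout cells: r = alpha * (sgn(r_L - r_R + xi) + 1), with i
    cells per choice at position i (1-based count along the chain)."""

    alpha: float = 5.0
    noise_sd: float = 2.0


def choice_readout_rates(
    rates_L: np.ndarray,
    rates_R: np.ndarray,
    rp: ReadoutParams,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Readout population rates per position.

    ``rates_L``/``rates_R`` are the chain rates per position index
    (n_positions,) at one timepoint.  Position i (0-based) carries i + 1
    left and i + 1 right readout cells, each with independent noise.
    Values are 0 or 2*alpha almost surely.
    """
    n = rates_L.shape[0]
    left_out, right_out = [], []
    for i in range(n):
        diff = rates_L[i] - rates_R[i]
        xi_L = rng.normal(0.0, rp.noise_sd, size=i + 1)
        xi_R = rng.normal(0.0, rp.noise_sd, size=i + 1)
        left_out.append(rp.alpha * (np.sign(diff + xi_L) + 1.0))
        right_out.append(rp.alpha * (np.sign(-diff + xi_R) + 1.0))
    return left_out, right_out


class TraditionalAccumulator:
    """Classic two-population mutual-inhibition accumulator (no sequences).

    dr_L/dt = -a r_L + [b r_L - e r_R + f 1_left(t) + X]^+ and mirror.
    State layout [r_L, r_R].
    """

    name = "trad-accum"

    def __init__(
        self,
        a: float = 50.0,
        b: float = 10.0,
        e: float = 40.0,
        f: float = 100.0,
        X: float = 500.0,
        geometry: MazeGeometry | None = None,
    ):
        self.a, self.b, self.e, self.f, self.X = a, b, e, f, X
        self.geometry = geometry or MazeGeometry()
        self.n_units = 2

    def unit_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"unit": [0, 1], "side": ["left", "right"], "position_index": [0, 0]}
        )

    def init_state(self, trial: Trial) -> np.ndarray:
        return np.zeros(2)

    def breakpoints(self, trial: Trial) -> np.ndarray:
        pts = []
        for cues in (trial.left_cues, trial.right_cues):
            for cue in cues:
                pts.append(np.array([cue - CUE_HALF_WIDTH_CM, cue + CUE_HALF_WIDTH_CM]))
        return np.concatenate(pts) if pts else np.empty(0)

    def make_rhs(self, trial, p_mid, perturb=None):
        from .maze import cue_indicator

        in_l = self.f * cue_indicator(trial, p_mid, "left") + self.X
        in_r = self.f * cue_indicator(trial, p_mid, "right") + self.X
        O = np.zeros(2) if perturb is None else perturb
        a, b, e = self.a, self.b, self.e

        def rhs(t, y):
            rL, rR = y
            dL = -a * rL + max(b * rL - e * rR + in_l + O[0], 0.0)
            dR = -a * rR + max(b * rR - e * rL + in_r + O[1], 0.0)
            return np.array([dL, dR])

        return rhs

    def readout(self, final_rates: np.ndarray, rng: np.random.Generator) -> str:
        return readout_choice_chains(final_rates, 1, rng)
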