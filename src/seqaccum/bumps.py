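"""Position-gated bump attractor model of evidence accumulation.

Neurons are arranged in layers (one per maze position); within a layer,
each neuron prefers one integer evidence level.  Cosine-profile recurrent
weights plus a saturating output nonlinearity sustain a stereotyped,
unimodal bump of activity whose location along the evidence axis encodes
the accumulated evidence.  A cue briefly activates "shifter" neurons that
move the bump one level left or right; a square position gate selects the
active layer, and feedforward connections between layers (same evidence
level to same evidence level) hand the bump to the next layer as the
subject advances.

Dynamics of the unit at position i, evidence level j:

    dr_ij/dt = -a r_ij + F( sum_k W_jk r_ik + b r_(i-1)j
                            + c (I_i,j+1,L + I_i,j-1,R) + P_i - T + O_ij )

with F(x) = q (1 + tanh(gamma x)) / 2,  W_jk = w0 (cos(theta_j - theta_k)
+ w1) on angles evenly spaced over [0, 2*pi), and shifter rates
I_ijL = r_ij 1_left(t), I_ijR = r_ij 1_right(t).

Evidence levels are labeled by integers -(J-1)/2 .. (J-1)/2 (J odd).  The
nominally periodic evidence ring is severed at the ends: neighbors beyond
the range contribute nothing.  Enough levels are used that the bump never
approaches the ends during a typical trial, so this differs from a
periodic seam only in degenerate cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .maze import CUE_HALF_WIDTH_CM, MazeGeometry, Trial
from .gating import SquareGate

__all__ = [
    "BumpModelParams",
    "BumpModel",
    "TraditionalBump",
    "cosine_weights",
    "output_nonlinearity",
    "shifter_rates",
    "readout_choice_bump",
]


@dataclass(frozen=True)
class BumpModelParams:
    """Parameters of the position-gated bump attractor."""

    a: float = 55.0       # decay (s^-1)
    b: float = 0.088      # feedforward between layers (s^-1)
    c: float = 0.2        # shifter synapse (s^-1)
    T: float = 300.0      # soft threshold (Hz/s)
    X: float = 0.04       # gate drive above threshold (Hz/s)
    q: float = 1250.0     # max output of F (Hz/s)
    gamma: float = 1.0    # gain of F (s/Hz)
    omega0: float = 0.12  # cosine weight scale (s^-1)
    omega1: float = -1.0  # cosine weight offset
    n_evidence: int = 35  # evidence levels -17..17
    n_positions: int = 17
    init_rates: tuple[float, float, float] = (15.0, 17.5, 15.0)

    def __post_init__(self) -> None:
        if self.n_evidence < 3 or self.n_evidence % 2 == 0:
            raise ValueError("n_evidence must be odd and >= 3")
        if self.q <= 0 or self.gamma <= 0:
            raise ValueError("q and gamma must be positive")

    @property
    def n_units(self) -> int:
        return self.n_positions * self.n_evidence

    @property
    def evidence_levels(self) -> np.ndarray:
        half = (self.n_evidence - 1) // 2
        return np.arange(-half, half + 1)


def cosine_weights(params: BumpModelParams) -> np.ndarray:
    """Within-layer weight matrix W_jk = w0 (cos(theta_j - theta_k) + w1).

    Angles are evenly spaced on [0, 2*pi); the matrix is symmetric and
    circulant, excitatory (relative to the long-range level) near the
    diagonal and inhibitory far from it.
    """
    J = params.n_evidence
    theta = 2.0 * np.pi * np.arange(J) / J
    return params.omega0 * (np.cos(theta[:, None] - theta[None, :]) + params.omega1)


def output_nonlinearity(x: np.ndarray | float, params: BumpModelParams):
    """Saturating output F(x) = q (1 + tanh(gamma x)) / 2, range (0, q)."""
    return params.q * (1.0 + np.tanh(params.gamma * np.asarray(x))) / 2.0


def shifter_rates(
    rates: np.ndarray, trial: Trial, p: float
) -> tuple[np.ndarray, np.ndarray]:
    """Left/right shifter-neuron rates I_L = r * 1_left, I_R = r * 1_right."""
    from .maze import cue_indicator

    ind_l = cue_indicator(trial, p, "left")
    ind_r = cue_indicator(trial, p, "right")
    return rates * ind_l, rates * ind_r


def readout_choice_bump(
    final_layer: np.ndarray,
    evidence_levels: np.ndarray,
    rng: np.random.Generator,
) -> str:
    """Choice from the evidence label of the most active final-layer unit.

    Negative label -> left, positive -> right; a peak exactly at level 0
    is resolved by an unbiased coin flip.
    """
    label = int(evidence_levels[int(np.argmax(final_layer))])
    if label < 0:
        return "left"
    if label > 0:
        return "right"
    return "left" if rng.random() < 0.5 else "right"


class BumpModel:
    """Simulatable position-gated bump attractor.

    State layout: ``y.reshape(n_positions, n_evidence)`` with evidence
    levels ordered from most-left to most-right.
    """

    name = "bump"

    def __init__(
        self,
        params: BumpModelParams | None = None,
        gate: SquareGate | None = None,
        geometry: MazeGeometry | None = None,
    ):
        self.geometry = geometry or MazeGeometry()
        self.params = params or BumpModelParams()
        if gate is None:
            gate = SquareGate(
                T=self.params.T, X=self.params.X, geometry=self.geometry
            )
        self.gate = gate
        if gate.n_gates != self.params.n_positions:
            raise ValueError(
                f"gate has {gate.n_gates} sections but params expect "
                f"{self.params.n_positions} positions"
            )
        self.W = cosine_weights(self.params)

    @property
    def n_units(self) -> int:
        return self.params.n_units

    def unit_table(self):
        import pandas as pd

        prm = self.params
        pos = np.repeat(np.arange(prm.n_positions), prm.n_evidence)
        ev = np.tile(prm.evidence_levels, prm.n_positions)
        return pd.DataFrame(
            {
                "unit": np.arange(prm.n_units),
                "position_index": pos,
                "evidence_level": ev,
                "side": np.where(ev < 0, "left", np.where(ev > 0, "right", "none")),
            }
        )

    def init_state(self, trial: Trial) -> np.ndarray:
        prm = self.params
        r = np.zeros((prm.n_positions, prm.n_evidence))
        mid = (prm.n_evidence - 1) // 2
        lo, c0, hi = prm.init_rates
        r[0, mid - 1] = lo
        r[0, mid] = c0
        r[0, mid + 1] = hi
        return r.ravel()

    def breakpoints(self, trial: Trial) -> np.ndarray:
        pts = [self.gate.boundaries()]
        for cues in (trial.left_cues, trial.right_cues):
            for cue in cues:
                pts.append(np.array([cue - CUE_HALF_WIDTH_CM, cue + CUE_HALF_WIDTH_CM]))
        return np.concatenate(pts)

    def make_rhs(
        self,
        trial: Trial,
        p_mid: float,
        perturb: np.ndarray | None = None,
    ) -> Callable[[float, np.ndarray], np.ndarray]:
        from .maze import cue_indicator

        prm = self.params
        n_pos, J = prm.n_positions, prm.n_evidence
        ind_l = cue_indicator(trial, p_mid, "left")
        ind_r = cue_indicator(trial, p_mid, "right")
        P = self.gate.drive(p_mid, n_pos)[:, None]  # constant within a segment
        W_T = self.W.T
        a, b, c, T, q, gamma = prm.a, prm.b, prm.c, prm.T, prm.q, prm.gamma
        O = None if perturb is None else perturb.reshape(n_pos, J)

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            r = y.reshape(n_pos, J)
            x = r @ W_T
            x[1:] += b * r[:-1]
            if ind_l:
                # left shifter at level j+1 drives level j (bump moves left)
                x[:, :-1] += c * r[:, 1:]
            if ind_r:
                # right shifter at level j-1 drives level j (bump moves right)
                x[:, 1:] += c * r[:, :-1]
            x += P - T
            if O is not None:
                x += O
            dr = -a * r + q * 0.5 * (1.0 + np.tanh(gamma * x))
            return dr.ravel()

        return rhs

    def readout(self, final_rates: np.ndarray, rng: np.random.Generator) -> str:
        prm = self.params
        final_layer = final_rates.reshape(prm.n_positions, prm.n_evidence)[-1]
        return readout_choice_bump(final_layer, prm.evidence_levels, rng)


class TraditionalBump:
    """Ungated single-layer bump attractor (no sequences).

    dr_j/dt = -a r_j + F( sum_k W_jk r_k + c (I_j+1,L + I_j-1,R) + X ).
    The bump shifts with cues but otherwise stays put, so it cannot
    produce position sequences.
    """

    name = "trad-bump"

    def __init__(
        self,
        params: BumpModelParams | None = None,
        geometry: MazeGeometry | None = None,
    ):
        self.geometry = geometry or MazeGeometry()
        self.params = params or BumpModelParams(
            a=55.0, X=0.04, q=1250.0, gamma=1.0, omega0=0.12, omega1=-1.0, c=0.2
        )
        self.W = cosine_weights(self.params)

    @property
    def n_units(self) -> int:
        return self.params.n_evidence

    def unit_table(self):
        import pandas as pd

        ev = self.params.evidence_levels
        return pd.DataFrame(
            {
                "unit": np.arange(ev.size),
                "position_index": 0,
                "evidence_level": ev,
                "side": np.where(ev < 0, "left", np.where(ev > 0, "right", "none")),
            }
        )

    def init_state(self, trial: Trial) -> np.ndarray:
        prm = self.params
        r = np.zeros(prm.n_evidence)
        mid = (prm.n_evidence - 1) // 2
        lo, c0, hi = prm.init_rates
        r[mid - 1], r[mid], r[mid + 1] = lo, c0, hi
        return r

    def breakpoints(self, trial: Trial) -> np.ndarray:
        pts = [np.empty(0)]
        for cues in (trial.left_cues, trial.right_cues):
            for cue in cues:
                pts.append(np.array([cue - CUE_HALF_WIDTH_CM, cue + CUE_HALF_WIDTH_CM]))
        return np.concatenate(pts)

    def make_rhs(self, trial, p_mid, perturb=None):
        from .maze import cue_indicator

        prm = self.params
        ind_l = cue_indicator(trial, p_mid, "left")
        ind_r = cue_indicator(trial, p_mid, "right")
        W_T = self.W.T
        a, c, q, gamma, X = prm.a, prm.c, prm.q, prm.gamma, prm.X
        O = perturb

        def rhs(t, y):
            x = y @ W_T
            if ind_l:
                x[:-1] += c * y[1:]
            if ind_r:
                x[1:] += c * y[:-1]
            x += X
            if O is not None:
                x = x + O
            return -a * y + q * 0.5 * (1.0 + np.tanh(gamma * x))

        return rhs

    def readout(self, final_rates: np.ndarray, rng: np.random.Generator) -> str:
        return readout_choice_bump(final_rates, self.params.evidence_levels, rng)
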