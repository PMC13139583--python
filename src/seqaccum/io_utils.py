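"""Run configuration and result I/O.

A run config is a YAML (or JSON) mapping with optional sections
``geometry``, ``solver``, ``noise``, ``model``, ``gate``, ``session`` and
top-level ``seed`` / ``out``; unknown keys are rejected with their paths.
Defaults reproduce the standard parameterization of each model, so an
empty file is a valid config.

Results are written as plain tables (CSV) plus compressed arrays (.npz)
for rate matrices and perturbation delta maps; integers and identifiers
round-trip losslessly, rates at float64.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .maze import MazeGeometry, NoiseConfig
from .engine import SolverConfig, SimulationResult
from .chains import ChainModel, ChainModelParams, TraditionalAccumulator
from .bumps import BumpModel, BumpModelParams, TraditionalBump
from .gating import GaussianGate, HeterogeneousGate, SquareGate, draw_heterogeneous_gates

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "build_model",
    "write_outputs",
    "read_outputs",
    "seed_streams",
]

_SECTION_TYPES = {
    "geometry": MazeGeometry,
    "solver": SolverConfig,
    "noise": NoiseConfig,
}

_MODEL_NAMES = ("mutual", "uncoupled", "unstable", "bump", "trad-accum", "trad-bump")
_GATE_NAMES = ("square", "gaussian", "heterogeneous")


@dataclass
class RunConfig:
    geometry: MazeGeometry = field(default_factory=MazeGeometry)
    solver: SolverConfig = field(default_factory=SolverConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    model: str = "mutual"
    model_params: dict = field(default_factory=dict)
    gate: str = "square"
    gate_params: dict = field(default_factory=dict)
    seed: int = 0
    out: str = "runs"

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "geometry": dataclasses.asdict(self.geometry),
                "solver": dataclasses.asdict(self.solver),
                "noise": dataclasses.asdict(self.noise),
                "model": self.model,
                "model_params": self.model_params,
                "gate": self.gate,
                "gate_params": self.gate_params,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(data) - names
    if bad:
        raise ValueError(f"unknown key(s) {sorted(bad)} in config section '{path}'")
    return cls(**data)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config, filling defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {"geometry", "solver", "noise", "model", "gate", "seed", "out"}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown key(s) {sorted(bad)} at config root")
    cfg = RunConfig()
    for sec, cls in _SECTION_TYPES.items():
        if sec in data:
            setattr(cfg, sec, _build_section(cls, dict(data[sec] or {}), sec))
    if "model" in data:
        m = data["model"]
        if isinstance(m, str):
            m = {"name": m}
        name = m.pop("name", "mutual")
        if name not in _MODEL_NAMES:
            raise ValueError(f"unknown model {name!r}; choose from {_MODEL_NAMES}")
        cfg.model, cfg.model_params = name, dict(m)
    if "gate" in data:
        g = data["gate"]
        if isinstance(g, str):
            g = {"kind": g}
        kind = g.pop("kind", "square")
        if kind not in _GATE_NAMES:
            raise ValueError(f"unknown gate {kind!r}; choose from {_GATE_NAMES}")
        cfg.gate, cfg.gate_params = kind, dict(g)
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "out" in data:
        cfg.out = str(data["out"])
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    data = {
        "geometry": dataclasses.asdict(cfg.geometry),
        "solver": dataclasses.asdict(cfg.solver),
        "noise": dataclasses.asdict(cfg.noise),
        "model": {"name": cfg.model, **cfg.model_params},
        "gate": {"kind": cfg.gate, **cfg.gate_params},
        "seed": cfg.seed,
        "out": cfg.out,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def build_model(cfg: RunConfig, rng: np.random.Generator | None = None):
    """Instantiate the configured model (and gate)."""
    geo = cfg.geometry
    if cfg.model in ("mutual", "uncoupled", "unstable"):
        ctor = {
            "mutual": ChainModelParams.mutual,
            "uncoupled": ChainModelParams.uncoupled,
            "unstable": ChainModelParams.unstable,
        }[cfg.model]
        params = ctor(**cfg.model_params)
        gate = _build_gate(cfg, params.T, params.X, geo, rng)
        if isinstance(gate, HeterogeneousGate):
            params = dataclasses.replace(params, n_positions=gate.n_gates)
        return ChainModel(params, gate=gate, geometry=geo)
    if cfg.model == "bump":
        params = BumpModelParams(**cfg.model_params)
        gate = _build_gate(cfg, params.T, params.X, geo, rng)
        return BumpModel(params, gate=gate, geometry=geo)
    if cfg.model == "trad-accum":
        return TraditionalAccumulator(geometry=geo, **cfg.model_params)
    if cfg.model == "trad-bump":
        params = BumpModelParams(**cfg.model_params) if cfg.model_params else None
        return TraditionalBump(params, geometry=geo)
    raise ValueError(f"unknown model {cfg.model!r}")


def _build_gate(cfg: RunConfig, T: float, X: float, geo, rng):
    gp = dict(cfg.gate_params)
    if cfg.gate == "square":
        gp.setdefault("T", T)
        gp.setdefault("X", X)
        return SquareGate(geometry=geo, **gp)
    if cfg.gate == "gaussian":
        return GaussianGate(geometry=geo, **gp)
    if cfg.gate == "heterogeneous":
        n = int(gp.pop("n", 12))
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        return draw_heterogeneous_gates(n, geometry=geo, rng=rng, T=T, X=X, **gp)
    raise ValueError(cfg.gate)


def seed_streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Expand one global seed into named, independent substreams."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def write_outputs(results, out_dir, prefix: str = "sim") -> Path:
    """Write simulation results: rates container + choices table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from .maze import final_evidence, trials_to_frame

    rates = np.stack([r.rates for r in results])
    np.savez_compressed(
        out / f"{prefix}_rates.npz", rates=rates, grid=results[0].grid
    )
    pd.DataFrame(
        {
            "trial_id": [r.trial.trial_id for r in results],
            "final_evidence": [final_evidence(r.trial) for r in results],
            "choice": [r.choice for r in results],
        }
    ).to_csv(out / f"{prefix}_choices.csv", index=False)
    trials_to_frame([r.trial for r in results]).to_csv(
        out / f"{prefix}_trials.csv", index=False
    )
    return out


def read_outputs(out_dir, prefix: str = "sim"):
    """Read back simulation results written by :func:`write_outputs`."""
    from .maze import read_trials_csv

    out = Path(out_dir)
    for name in (f"{prefix}_rates.npz", f"{prefix}_choices.csv", f"{prefix}_trials.csv"):
        if not (out / name).exists():
            raise FileNotFoundError(f"incomplete outputs: missing {name}")
    arrs = np.load(out / f"{prefix}_rates.npz")
    choices = pd.read_csv(out / f"{prefix}_choices.csv")
    trials = {t.trial_id: t for t in read_trials_csv(out / f"{prefix}_trials.csv")}
    results = []
    for k, row in choices.iterrows():
        tid = int(row["trial_id"])
        results.append(
            SimulationResult(
                rates=arrs["rates"][k],
                grid=arrs["grid"],
                choice=row["choice"],
                trial=trials.get(tid),
            )
        )
    return results
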