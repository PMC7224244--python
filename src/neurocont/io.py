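"""Configuration, branch-table I/O, structured logging, and demo drivers.

Every demo is reproducible from a flat config alone: the starting solution
is generated by time-stepping the relevant model (no bundled data), then the
branch is traced by continuation and written as a UTF-8 delimited table with
a ``#``-prefixed metadata header that carries enough parameters to re-run
the demo.  One structured log record is emitted per continuation step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bump2d, bumps1d, foldcurve, front1d, poincare, shooting
from .continuation import (
    BranchPoint,
    ContinuationProblem,
    ContinuationSettings,
    continue_branch,
)
from .models import toy_residual

__all__ = [
    "DemoConfig",
    "ConfigError",
    "BranchTable",
    "BranchParseError",
    "write_branch",
    "read_branch",
    "run_demo",
    "time_step_initializer",
    "DEMO_IDS",
]

logger = logging.getLogger("neurocont")

DEMO_IDS = ("toy", "bumps1d", "front1d", "shoot", "bump2d", "foldcurve", "fhn")


class ConfigError(ValueError):
    """Invalid or unknown configuration key/value (names the key)."""


# key -> (type, (lo, hi) or None)
_CONT_KEYS = {
    "continuation.ds": (float, (0.0, np.inf)),
    "continuation.max_newton": (int, (1, 1000)),
    "continuation.newton_tol": (float, (0.0, 1.0)),
    "continuation.theta": (float, (0.0, np.inf)),
    "continuation.max_steps": (int, (1, 100000)),
    "continuation.direction": (int, (-1, 1)),
}
_COMMON_KEYS = {"seed": (int, None), "out_dir": (str, None), **_CONT_KEYS}

_DEMO_KEYS = {
    "toy": {"model.mu0": (float, None)},
    "bumps1d": {
        "model.beta": (float, (0.0, np.inf)),
        "model.h0": (float, None),
        "disc.N": (int, (2, 4096)),
        "disc.M": (int, (8, 65536)),
    },
    "front1d": {
        "model.beta": (float, (0.0, np.inf)),
        "model.h0": (float, (0.0, 1.0)),
        "disc.N": (int, (8, 100000)),
        "disc.L_dom": (float, (1.0, np.inf)),
    },
    "shoot": {
        "model.beta": (float, (0.0, np.inf)),
        "model.h_values": (list, None),
    },
    "bump2d": {
        "model.beta": (float, (0.0, np.inf)),
        "model.h": (float, None),
        "model.A": (float, (0.0, np.inf)),
        "model.B": (float, (0.0, np.inf)),
        "model.tau": (float, (0.0, np.inf)),
        "disc.N": (int, (8, 1024)),
        "disc.L": (float, (1.0, np.inf)),
    },
    "foldcurve": {
        "model.beta": (float, (0.0, np.inf)),
        "kernel.B0": (float, (0.0, np.inf)),
        "disc.N": (int, (2, 4096)),
        "disc.M": (int, (8, 65536)),
    },
    "fhn": {
        "model.i_app": (float, None),
        "model.V0": (float, None),
    },
}


@dataclass
class DemoConfig:
    """Validated flat configuration for one demo run."""

    demo: str
    values: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.demo not in DEMO_IDS:
            raise ConfigError(
                f"unknown demo id {self.demo!r}; valid ids: {', '.join(DEMO_IDS)}")
        schema = {**_COMMON_KEYS, **_DEMO_KEYS[self.demo]}
        for key, val in self.values.items():
            if key not in schema:
                raise ConfigError(f"unknown config key {key!r} for demo "
                                  f"{self.demo!r}")
            typ, rng = schema[key]
            if typ in (int, float) and isinstance(val, bool):
                raise ConfigError(f"config key {key!r}: boolean is not a {typ.__name__}")
            if typ is float and isinstance(val, int):
                val = float(val)
            if not isinstance(val, typ):
                raise ConfigError(
                    f"config key {key!r}: expected {typ.__name__}, got "
                    f"{type(val).__name__}")
            if rng is not None and not (rng[0] <= val <= rng[1]):
                raise ConfigError(
                    f"config key {key!r}: value {val} outside [{rng[0]}, {rng[1]}]")
            self.values[key] = val

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        demo = raw.pop("demo", None)
        if demo is None:
            raise ConfigError("config file must set the 'demo' key")
        return cls(demo=demo, values=raw)

    def get(self, key, default=None):
        return self.values.get(key, default)

    def settings(self, **defaults):
        kw = dict(defaults)
        for key, (attr_typ, _) in _CONT_KEYS.items():
            if key in self.values:
                kw[key.split(".", 1)[1]] = self.values[key]
        return ContinuationSettings(**kw)


# ----------------------------------------------------------------------
# branch tables

class BranchParseError(ValueError):
    """Malformed branch file; message carries the 1-based line number."""


@dataclass
class BranchTable:
    """Per-point branch records plus header metadata."""

    meta: dict
    table: pd.DataFrame


def write_branch(bt: BranchTable, path):
    """Write a branch table as delimited text with a ``#`` metadata header.

    Values round-trip at full precision (floats are written as shortest
    exact repr)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for key, val in bt.meta.items():
            fh.write(f"# {key}: {json.dumps(val)}\n")
        fh.write("\t".join(bt.table.columns) + "\n")
        for _, row in bt.table.iterrows():
            fh.write("\t".join(repr(x) if isinstance(x, float) else str(x)
                               for x in row) + "\n")
    return path


def read_branch(path) -> BranchTable:
    """Parse a branch file; raises :class:`BranchParseError` with the line
    number on malformed input."""
    meta, columns, rows = {}, None, []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if columns is not None:
                    raise BranchParseError(
                        f"line {lineno}: metadata after the header row")
                try:
                    key, val = line[1:].split(":", 1)
                except ValueError as exc:
                    raise BranchParseError(f"line {lineno}: bad metadata") from exc
                try:
                    meta[key.strip()] = json.loads(val.strip())
                except json.JSONDecodeError as exc:
                    raise BranchParseError(
                        f"line {lineno}: bad metadata value") from exc
                continue
            cells = line.split("\t")
            if columns is None:
                columns = cells
                continue
            if len(cells) != len(columns):
                raise BranchParseError(
                    f"line {lineno}: expected {len(columns)} fields, got {len(cells)}")
            try:
                rows.append([_parse_cell(c) for c in cells])
            except ValueError as exc:
                raise BranchParseError(f"line {lineno}: {exc}") from exc
    if columns is None:
        raise BranchParseError("line 1: no header row found")
    return BranchTable(meta=meta, table=pd.DataFrame(rows, columns=columns))


def _parse_cell(cell):
    if cell in ("True", "False"):
        return cell == "True"
    if cell == "None":
        return None
    try:
        return int(cell)
    except ValueError:
        return float(cell)


# ----------------------------------------------------------------------
# time-stepping fixture generators

def time_step_initializer(model_id, spec=None, T=None, dt=None):
    """Settle a starting solution for a demo by forward time integration.

    Returns ``(state, drift_norm_or_speed)``: for the travelling models the
    second element is the measured drift speed over the final quarter of
    the horizon; otherwise the final time-derivative norm.
    """
    spec = spec or {}
    if model_id == "toy":
        mu = spec.get("mu", 0.0)
        u = spec.get("u0", 0.0)
        dt = dt or 0.01
        T = T or 50.0
        drift = np.inf
        for _ in range(int(T / dt)):
            k1 = toy_residual(u, mu)[0]
            k2 = toy_residual(u + 0.5 * dt * k1, mu)[0]
            k3 = toy_residual(u + 0.5 * dt * k2, mu)[0]
            k4 = toy_residual(u + dt * k3, mu)[0]
            u += (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if abs(u) > 1e6:
                raise FloatingPointError("toy time-stepping blew up")
            drift = abs(toy_residual(u, mu)[0])
            if drift < 1e-8:
                break
        return u, drift
    if model_id == "bumps1d":
        problem = spec["problem"]
        coeffs0 = spec["coeffs0"]
        return bumps1d.time_step_modes(problem, coeffs0, T=T or 60.0, dt=dt or 0.01)
    if model_id == "front1d":
        problem = spec["problem"]
        return front1d.time_step_front(problem, u0=spec.get("u0"),
                                       T=T or 15.0, dt=dt or 0.05)
    if model_id == "bump2d":
        problem = spec["problem"]
        u, a, drift = bump2d.time_step_2d(problem, T=T or 60.0, dt=dt or 0.05)
        return (u, a), drift
    raise ConfigError(f"unknown model id {model_id!r} for time stepping")


# ----------------------------------------------------------------------
# demos

def _log_step(step, point):
    logger.info(json.dumps({
        "event": "step", "step": step,
        "parameter": float(point.parameter),
        "norm": float(np.linalg.norm(point.state)),
        "newton_iterations": int(point.newton_iterations),
        "stable": point.stable,
    }))


def _log_branch(branch):
    """One structured record per continuation step, plus fold events."""
    for k, pt in enumerate(branch.points):
        _log_step(k, pt)
    for fold in branch.folds:
        logger.info(json.dumps({"event": "fold",
                                "parameter": float(fold.parameter)}))
    if branch.diagnostic:
        logger.info(json.dumps({"event": "truncated",
                                "diagnostic": branch.diagnostic}))


def run_demo(demo, config=None, out_dir=None):
    """Run a named demo end-to-end; returns the :class:`BranchTable` written.

    Artifacts: ``<out>/<demo>_branch.tsv`` plus per-point state snapshots
    (plain text arrays) for the field demos.
    """
    if config is None:
        config = DemoConfig(demo=demo)
    if config.demo != demo:
        raise ConfigError(f"config is for demo {config.demo!r}, not {demo!r}")
    out = Path(out_dir or config.get("out_dir", "neurocont_out"))
    out.mkdir(parents=True, exist_ok=True)
    runner = {
        "toy": _demo_toy, "bumps1d": _demo_bumps1d, "front1d": _demo_front1d,
        "shoot": _demo_shoot, "bump2d": _demo_bump2d,
        "foldcurve": _demo_foldcurve, "fhn": _demo_fhn,
    }[demo]
    bt = runner(config, out)
    path = write_branch(bt, out / f"{demo}_branch.tsv")
    logger.info(json.dumps({"event": "done", "demo": demo, "path": str(path),
                            "points": len(bt.table)}))
    return bt


def _demo_toy(config, out):
    mu0 = config.get("model.mu0", 0.0)
    u0, _ = time_step_initializer("toy", {"mu": mu0})
    cp = ContinuationProblem(
        residual=lambda v, mu: np.array([toy_residual(v[0], mu)[0]]),
        jacobian_state=lambda v, mu: np.array([[toy_residual(v[0], mu)[1]]]),
        jacobian_param=lambda v, mu: np.array([toy_residual(v[0], mu)[2]]),
        parameter_name="mu")
    settings = config.settings(ds=0.1, max_steps=80)
    branch = continue_branch(cp, BranchPoint(state=np.array([u0]), parameter=mu0),
                             settings, stability=True, callback=_log_step)
    for fold in branch.folds:
        logger.info(json.dumps({"event": "fold", "parameter": fold.parameter}))
    df = pd.DataFrame({
        "mu": branch.parameters, "u": branch.states[:, 0],
        "stable": [p.stable for p in branch.points],
        "eigenvalue": [float(p.eigen_summary.rightmost.real) for p in branch.points],
        "newton_iterations": [p.newton_iterations for p in branch.points],
    })
    meta = {"demo": "toy", "mu0": mu0, "ds": settings.ds,
            "folds": [f.parameter for f in branch.folds]}
    return BranchTable(meta=meta, table=df)


def _demo_bumps1d(config, out):
    N = config.get("disc.N", 15)
    M = config.get("disc.M", 128)
    beta = config.get("model.beta", 20.0)
    h0 = config.get("model.h0", 0.3)
    problem = bumps1d.BumpProblem(N=N, M=M, beta=beta, h=h0)
    coeffs = bumps1d.initial_bump(problem)
    settings = config.settings(ds=0.05, max_steps=150)
    branch = bumps1d.continue_bumps_in_h(problem, coeffs, settings)
    _log_branch(branch)
    np.savetxt(out / "bumps1d_modes.txt", branch.states)
    df = pd.DataFrame({
        "h": branch.parameters, "norm": branch.norms,
        "stable": [p.stable for p in branch.points],
        "leading_eig": [float(p.eigen_summary.rightmost.real)
                        for p in branch.points],
    })
    for i in range(N):
        df[f"u{i}"] = branch.states[:, i]
    meta = {"demo": "bumps1d", "N": N, "M": M, "beta": beta, "h0": h0,
            "folds": [f.parameter for f in branch.folds]}
    return BranchTable(meta=meta, table=df)


def _demo_front1d(config, out):
    problem = front1d.FrontProblem(
        N=config.get("disc.N", 1000), L_dom=config.get("disc.L_dom", 50.0),
        beta=config.get("model.beta", 20.0), h=config.get("model.h0", 0.3))
    state = front1d.initial_front(problem)
    settings = config.settings(ds=0.25, max_steps=40, newton_tol=1e-9)
    branch = front1d.continue_front_in_h(problem, state, settings)
    _log_branch(branch)
    np.savetxt(out / "front1d_profiles.txt", branch.states[:, :-1])
    trans = []
    stables = []
    for p in branch.points:
        summary, lam_t = front1d.front_stability(p.state, problem, h=p.parameter)
        trans.append(abs(lam_t))
        stables.append(summary.stable)
    df = pd.DataFrame({
        "h": branch.parameters, "c": branch.states[:, -1],
        "stable": stables, "translational_eig_magnitude": trans,
    })
    meta = {"demo": "front1d", "N": problem.N, "L_dom": problem.L_dom,
            "beta": problem.beta, "h0": problem.h,
            "folds": [f.parameter for f in branch.folds]}
    return BranchTable(meta=meta, table=df)


def _demo_shoot(config, out):
    beta = config.get("model.beta", 20.0)
    h_values = config.get("model.h_values", [0.3, 0.4, 0.6, 0.7])
    rows = []
    for h in h_values:
        c = shooting.shoot_front_speed(beta, h)
        _, sol = shooting.shoot_mismatch(c, beta, h, return_trajectory=True)
        np.savetxt(out / f"shoot_trajectory_h{h:g}.txt",
                   np.column_stack([sol.t, sol.y.T]),
                   header="xi u v z")
        rows.append({"h": h, "c": c})
        logger.info(json.dumps({"event": "shoot", "h": h, "c": c}))
    return BranchTable(meta={"demo": "shoot", "beta": beta},
                       table=pd.DataFrame(rows))


def _demo_bump2d(config, out):
    problem = bump2d.Problem2D(
        N=config.get("disc.N", 64), L=config.get("disc.L", 15.0),
        beta=config.get("model.beta", 5.0), h=config.get("model.h", 0.8),
        A=config.get("model.A", 2.0), B=config.get("model.B", 0.4),
        tau=config.get("model.tau", 3.0))
    state = bump2d.initial_bump_2d(problem)
    np.savetxt(out / "bump2d_u0.txt", state.u_field)
    np.savetxt(out / "bump2d_a0.txt", state.a_field)
    (out / "bump2d_meta.json").write_text(json.dumps(
        {"L": problem.L, "N": problem.N, "A": problem.A, "B": problem.B,
         "tau": problem.tau, "beta": problem.beta, "h": problem.h,
         "c": state.speed}))
    settings = config.settings(ds=0.5, max_steps=30, newton_tol=1e-8,
                               max_newton=12)
    settings.fold_refine_tol = 1e-3
    branch = bump2d.continue_bump_2d_in_A(problem, state, settings)
    _log_branch(branch)
    df = pd.DataFrame({
        "A": branch.parameters, "c": branch.states[:, -1],
        "stable": [p.stable for p in branch.points],
        "rightmost_eig": [float(p.eigen_summary.rightmost.real)
                          if p.eigen_summary is not None
                          and len(p.eigen_summary.eigenvalues) else np.nan
                          for p in branch.points],
    })
    meta = {"demo": "bump2d", "N": problem.N, "L": problem.L,
            "folds": [f.parameter for f in branch.folds]}
    return BranchTable(meta=meta, table=df)


def _demo_foldcurve(config, out):
    family = foldcurve.BumpFamily(N=config.get("disc.N", 15),
                                  beta=config.get("model.beta", 20.0),
                                  M=config.get("disc.M", 128))
    B0 = config.get("kernel.B0", 6.0)
    problem = family.problem(B0)
    coeffs = bumps1d.initial_bump(problem)
    bump_branch = bumps1d.continue_bumps_in_h(problem, coeffs,
                                              stability=False)
    if not bump_branch.folds:
        raise RuntimeError("no fold found on the seeding bump branch")
    seed = foldcurve.fold_state_from_branch_fold(family, B0, bump_branch.folds[0])
    seed, _ = foldcurve.newton_polish_fold(seed, B0, family)
    settings = config.settings(ds=0.2, max_steps=50, newton_tol=1e-9)
    branch = foldcurve.continue_fold_curve(family, seed, B0, settings)
    _log_branch(branch)
    df = pd.DataFrame({
        "B": branch.parameters,
        "h": foldcurve.curve_thresholds(branch),
        "norm_v": [np.linalg.norm(p.state[:family.N]) for p in branch.points],
        "smallest_eig_magnitude": [
            foldcurve.smallest_jacobian_eigenvalue(family, p)
            for p in branch.points],
    })
    return BranchTable(meta={"demo": "foldcurve", "N": family.N,
                             "beta": family.beta, "B0": B0}, table=df)


def _demo_fhn(config, out):
    ode = poincare.fhn_default()
    if config.get("model.i_app") is not None:
        ode.i_app = config.get("model.i_app")
    section = poincare.PoincareSection()
    V0 = config.get("model.V0", 1.2)
    iterates = [V0]
    for _ in range(40):
        iterates.append(poincare.poincare_map(ode, section, iterates[-1]))
        if abs(iterates[-1] - iterates[-2]) < 1e-10:
            break
    np.savetxt(out / "fhn_iterates.txt", np.asarray(iterates))
    V_star = iterates[-1]
    branch, derivs = poincare.continue_periodic_orbit(ode, section, V_star)
    _log_branch(branch)
    times = [poincare.poincare_map(ode, section, p.state[0],
                                   i_app=p.parameter, return_time=True)[1]
             for p in branch.points]
    df = pd.DataFrame({
        "i_app": branch.parameters, "V_star": branch.states[:, 0],
        "map_derivative": derivs, "return_time": times,
        "stable": [p.stable for p in branch.points],
    })
    return BranchTable(meta={"demo": "fhn", "V0": V0,
                             "i_app0": ode.i_app}, table=df)
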