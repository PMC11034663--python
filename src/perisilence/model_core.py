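"""Deterministic models of RNAi-dependent H3K9 methylation at pericentromeric
repeats.

Two ODE models are defined.  The three-variable model tracks the
concentrations of repeat-derived lncRNA (``x1``), siRNA (``x2``) and the
methylated fraction of H3K9 sites (``x3``):

.. math::

    \\dot x_1 &= \\frac{C\\alpha}{1+(x_3/k_1)^{\\rho_1}} - \\delta_1 x_1
                - \\gamma x_1 H_2(x_3) \\\\
    \\dot x_2 &= \\gamma x_1 H_2(x_3) - \\delta_2 x_2 \\\\
    \\dot x_3 &= \\epsilon x_2 (1-x_3) H_3(x_3) - \\delta_3 x_3
                + \\phi (1-x_3) x_3 + \\zeta (1-x_3)

with Hill functions :math:`H_i(x) = (x/k_i)^{\\rho_i}/(1+(x/k_i)^{\\rho_i})`.
The repeat copy number ``C`` multiplies the maximal transcription rate: each
repeat is transcribed independently.  Methylation represses transcription
(Hill ``rho1, k1``), stimulates siRNA biogenesis from the lncRNA
(``rho2, k2``) and cooperates with siRNA-guided methylation (``rho3, k3``),
closing the positive feedback loop that makes silencing bistable.

The five-variable model additionally resolves the acetylated (``x4``) and
unmodified (``x5``) H3K9 states; only unmodified histones can be methylated
or acetylated, histone turnover ``xi`` replaces histones of any state with
acetylated ones, and ``x3 + x4 + x5 = 1`` is conserved.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp

__all__ = [
    "ParameterSet",
    "ExtendedParameterSet",
    "ModelState",
    "Trajectory",
    "default_parameters",
    "rhs_three_state",
    "rhs_five_state",
    "integrate",
    "find_attractor",
    "ATTRACTOR_TIME",
    "RHS_TOLERANCE",
]

#: Integration horizon used to declare a trajectory "at steady state" (min).
ATTRACTOR_TIME = 25_000.0

#: Max-norm tolerance on the RHS at the endpoint for convergence.
RHS_TOLERANCE = 1e-7

_CLIP_WARN = 1e-6


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class ParameterSet:
    """Rate constants and Hill parameters of the three-variable model.

    All rates are per minute; ``alpha`` is a transcription rate per repeat
    copy, ``epsilon`` is per unit siRNA concentration per minute.  The Hill
    half-max constants ``k1, k2, k3`` are methylation fractions in (0, 1].
    ``copy_number`` is real-valued internally; scans use integers.
    """

    alpha: float
    delta1: float
    delta2: float
    delta3: float
    gamma: float
    epsilon: float
    phi: float
    zeta: float
    rho1: float = 1.0
    rho2: float = 2.0
    rho3: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    copy_number: float = 15.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(isinstance(v, (int, float)) and math.isfinite(v),
                     f"parameter {f.name!r} must be a finite number, got {v!r}")
        for name in ("alpha", "delta1", "delta2", "delta3", "gamma",
                     "epsilon", "phi", "zeta"):
            _require(getattr(self, name) >= 0.0,
                     f"rate {name!r} must be >= 0")
        for name in ("rho1", "rho2", "rho3"):
            _require(getattr(self, name) >= 1.0,
                     f"Hill coefficient {name!r} must be >= 1")
        for name in ("k1", "k2", "k3"):
            _require(0.0 < getattr(self, name) <= 1.0,
                     f"half-max constant {name!r} must be in (0, 1]")
        _require(self.copy_number >= 1.0, "copy_number must be >= 1")

    @property
    def n_variables(self) -> int:
        return 3

    def replace(self, **changes: float) -> "ParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        _require(not unknown, f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class ExtendedParameterSet:
    """Parameters of the five-variable model with acetylation.

    ``phi1``/``zeta1`` play the roles of ``phi``/``zeta`` but act on the
    unmodified fraction; ``xi`` is the histone turnover rate, ``zeta2`` the
    acetylation rate and ``delta4`` the deacetylation (HDAC) rate.
    """

    alpha: float
    delta1: float
    delta2: float
    delta3: float
    gamma: float
    epsilon: float
    phi1: float
    zeta1: float
    xi: float
    zeta2: float
    delta4: float
    rho1: float = 1.0
    rho2: float = 2.0
    rho3: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    k3: float = 1.0
    copy_number: float = 15.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            _require(isinstance(v, (int, float)) and math.isfinite(v),
                     f"parameter {f.name!r} must be a finite number, got {v!r}")
        for name in ("alpha", "delta1", "delta2", "delta3", "gamma",
                     "epsilon", "phi1", "zeta1", "xi", "zeta2", "delta4"):
            _require(getattr(self, name) >= 0.0,
                     f"rate {name!r} must be >= 0")
        for name in ("rho1", "rho2", "rho3"):
            _require(getattr(self, name) >= 1.0,
                     f"Hill coefficient {name!r} must be >= 1")
        for name in ("k1", "k2", "k3"):
            _require(0.0 < getattr(self, name) <= 1.0,
                     f"half-max constant {name!r} must be in (0, 1]")
        _require(self.copy_number >= 1.0, "copy_number must be >= 1")

    @property
    def n_variables(self) -> int:
        return 5

    def replace(self, **changes: float) -> "ExtendedParameterSet":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ExtendedParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        _require(not unknown, f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})


ModelState = tuple  # (x1, x2, x3) or (x1, x2, x3, x4, x5)

SIMPLEX_TOL = 1e-6


def validate_state(state: Sequence[float], extended: bool = False) -> None:
    """Check a model state against its invariants; raise ValueError if bad."""
    state = tuple(float(v) for v in state)
    n = 5 if extended else 3
    _require(len(state) == n, f"state must have {n} components")
    _require(all(math.isfinite(v) for v in state), "state must be finite")
    _require(state[0] >= 0 and state[1] >= 0, "x1, x2 must be >= 0")
    if extended:
        _require(all(-SIMPLEX_TOL <= v <= 1 + SIMPLEX_TOL for v in state[2:]),
                 "histone fractions must lie in [0, 1]")
        _require(abs(sum(state[2:]) - 1.0) <= 1e-6,
                 "x3 + x4 + x5 must equal 1")
    else:
        _require(-SIMPLEX_TOL <= state[2] <= 1 + SIMPLEX_TOL,
                 "x3 must lie in [0, 1]")


def default_parameters(model: str = "three"):
    """Load the packaged reference (wild-type) parameter set.

    Parameters
    ----------
    model:
        ``"three"`` for :class:`ParameterSet`, ``"five"`` for
        :class:`ExtendedParameterSet`.
    """
    text = (resources.files("perisilence") / "data"
            / "default_parameters.yaml").read_text()
    doc = yaml.safe_load(text)
    if model == "three":
        return ParameterSet.from_dict(doc["three_state"])
    if model == "five":
        return ExtendedParameterSet.from_dict(doc["five_state"])
    raise ValueError(f"model must be 'three' or 'five', got {model!r}")


def _hill(x, k, rho):
    r = (x / k) ** rho
    return r / (1.0 + r)


def rhs_three_state(state: Sequence[float], params: ParameterSet):
    """Right-hand side of the three-variable model.

    Returns ``(dx1/dt, dx2/dt, dx3/dt)``.  Accepts scalars or arrays for the
    state components.
    """
    x1, x2, x3 = np.asarray(state[0]), np.asarray(state[1]), np.asarray(state[2])
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))
            and np.all(np.isfinite(x3))):
        raise ValueError("non-finite model state")
    p = params
    h1 = 1.0 / (1.0 + (x3 / p.k1) ** p.rho1)
    h2 = _hill(x3, p.k2, p.rho2)
    h3 = _hill(x3, p.k3, p.rho3)
    dx1 = p.copy_number * p.alpha * h1 - p.delta1 * x1 - p.gamma * x1 * h2
    dx2 = p.gamma * x1 * h2 - p.delta2 * x2
    dx3 = (p.epsilon * x2 * (1.0 - x3) * h3 - p.delta3 * x3
           + p.phi * (1.0 - x3) * x3 + p.zeta * (1.0 - x3))
    if dx1.ndim == 0:
        return float(dx1), float(dx2), float(dx3)
    return dx1, dx2, dx3


def rhs_five_state(state: Sequence[float], params: ExtendedParameterSet,
                   simplex_tol: float = 1e-6):
    """Right-hand side of the five-variable model with acetylation.

    The state is ``(x1, x2, x3, x4, x5)`` with ``x3 + x4 + x5 = 1`` (within
    ``simplex_tol``).  Methylation acts on the unmodified fraction ``x5``;
    histone turnover ``xi`` removes methylated and unmodified histones and
    deposits acetylated ones.
    """
    x1, x2, x3, x4, x5 = (np.asarray(v) for v in state)
    if not all(np.all(np.isfinite(v)) for v in (x1, x2, x3, x4, x5)):
        raise ValueError("non-finite model state")
    total = x3 + x4 + x5
    if np.any(np.abs(total - 1.0) > simplex_tol):
        raise ValueError(
            f"x3+x4+x5 must equal 1 within {simplex_tol}; got {total}")
    p = params
    h1 = 1.0 / (1.0 + (x3 / p.k1) ** p.rho1)
    h2 = _hill(x3, p.k2, p.rho2)
    h3 = _hill(x3, p.k3, p.rho3)
    dx1 = p.copy_number * p.alpha * h1 - p.delta1 * x1 - p.gamma * x1 * h2
    dx2 = p.gamma * x1 * h2 - p.delta2 * x2
    meth = p.epsilon * x2 * x5 * h3
    dx3 = meth - p.delta3 * x3 + p.phi1 * x3 * x5 + p.zeta1 * x5 - p.xi * x3
    dx4 = p.zeta2 * x5 - p.delta4 * x4 + p.xi - p.xi * x4
    dx5 = (-(meth - p.delta3 * x3 + p.phi1 * x3 * x5 + p.zeta1 * x5)
           - (p.zeta2 * x5 - p.delta4 * x4) - p.xi * x5)
    if dx1.ndim == 0:
        return float(dx1), float(dx2), float(dx3), float(dx4), float(dx5)
    return dx1, dx2, dx3, dx4, dx5


@dataclass
class Trajectory:
    """Time course of a deterministic model run."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_variables)
    parameters: ParameterSet | ExtendedParameterSet

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def final_state(self) -> tuple:
        return tuple(self.states[-1])

    def to_frame(self):
        import pandas as pd

        cols = ["x1", "x2", "x3", "x4", "x5"][: self.states.shape[1]]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "time", self.times)
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rhs_flat(t, y, params, extended):
    if extended:
        n = y.size // 5
        x = [y[i::5] if n > 1 else y[i] for i in range(5)]
        x = list(x)
        x3 = np.clip(x[2], 0.0, 1.0)
        x4 = np.clip(x[3], 0.0, 1.0)
        x5 = np.clip(x[4], 0.0, 1.0)
        d = rhs_five_state((x[0], x[1], x3, x4, x5), params,
                           simplex_tol=np.inf)
        out = np.empty_like(y)
        for i, di in enumerate(d):
            if n > 1:
                out[i::5] = di
            else:
                out[i] = di
        return out
    n = y.size // 3
    x1 = y[0::3] if n > 1 else y[0]
    x2 = y[1::3] if n > 1 else y[1]
    x3 = np.clip(y[2::3] if n > 1 else y[2], 0.0, 1.0)
    d = rhs_three_state((x1, x2, x3), params)
    out = np.empty_like(y)
    for i, di in enumerate(d):
        if n > 1:
            out[i::3] = di
        else:
            out[i] = di
    return out


def integrate(params, initial_state: Sequence[float], t_end: float,
              record_step: float = 10.0, rtol: float = 1e-8,
              atol: float = 1e-10) -> Trajectory:
    """Integrate a model from ``initial_state`` to ``t_end`` minutes.

    Uses an adaptive solver (LSODA) with tight tolerances.  Recorded
    methylation fractions are clipped to [0, 1]; a warning is emitted if the
    solver excursion beyond the unit interval exceeds 1e-6, which would
    indicate a misconfigured solver (the flow itself is forward-invariant).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    extended = getattr(params, "n_variables", 3) == 5
    validate_state(initial_state, extended=extended)
    y0 = np.asarray(initial_state, dtype=float)
    t_eval = np.arange(0.0, t_end + 0.5 * record_step, record_step)
    t_eval = t_eval[t_eval <= t_end]
    if t_eval[-1] < t_end:
        t_eval = np.append(t_eval, t_end)
    sol = solve_ivp(_rhs_flat, (0.0, t_end), y0, args=(params, extended),
                    method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(
            f"ODE solver failed: {sol.message}; parameters: {params.to_dict()}")
    states = sol.y.T.copy()
    frac = states[:, 2:]
    excursion = max(float(np.max(frac - 1.0, initial=0.0)),
                    float(np.max(-frac, initial=0.0)))
    if excursion > _CLIP_WARN:
        warnings.warn(
            f"methylation fraction left [0,1] by {excursion:.2e}; "
            "clipped (check solver tolerances)", RuntimeWarning)
    states[:, 2:] = np.clip(frac, 0.0, 1.0)
    return Trajectory(sol.t, states, params)


def integrate_batch(params, initial_states: Iterable[Sequence[float]],
                    t_end: float, rtol: float = 1e-8,
                    atol: float = 1e-10) -> np.ndarray:
    """Integrate many initial conditions as one stacked system.

    Returns the array of final states, shape ``(n_ics, n_variables)``.  This
    is an internal fast path used by the bifurcation scans; the trajectories
    themselves are not recorded.
    """
    extended = getattr(params, "n_variables", 3) == 5
    nvar = 5 if extended else 3
    ics = [tuple(map(float, s)) for s in initial_states]
    for s in ics:
        validate_state(s, extended=extended)
    y0 = np.asarray(ics, dtype=float).ravel()
    sol = solve_ivp(_rhs_flat, (0.0, t_end), y0, args=(params, extended),
                    method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover
        raise RuntimeError(
            f"ODE solver failed: {sol.message}; parameters: {params.to_dict()}")
    out = sol.y[:, -1].reshape(len(ics), nvar)
    out[:, 2:] = np.clip(out[:, 2:], 0.0, 1.0)
    return out


def find_attractor(params, initial_state: Sequence[float],
                   t_end: float = ATTRACTOR_TIME,
                   tol: float = RHS_TOLERANCE):
    """Integrate to ``t_end`` (default 25,000 min) and return the endpoint.

    Returns ``(state, converged)`` where ``converged`` is True when the
    max-norm of the RHS at the endpoint is below ``tol``.  Non-convergence is
    flagged, never silently dropped.
    """
    traj = integrate(params, initial_state, t_end, record_step=t_end)
    end = traj.final_state
    extended = getattr(params, "n_variables", 3) == 5
    rhs = rhs_five_state(end, params, simplex_tol=1e-3) if extended \
        else rhs_three_state(end, params)
    converged = bool(max(abs(v) for v in rhs) < tol)
    return end, converged
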