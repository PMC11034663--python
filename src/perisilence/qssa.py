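"""Quasi-steady-state reduction, nullclines, fixed points and bifurcations.

Because siRNA turns over much more slowly than lncRNA, the RNA concentration
can be assumed equilibrated at any given siRNA / methylation level.  Setting
the RNA equation to zero gives ``x1`` as a function of ``x3`` alone, which
reduces the model to two variables ``(x2, x3)`` and lets the steady states
be read off as intersections of two nullclines in the ``(x3, x2)`` plane:

* the siRNA nullcline (where ``dx2/dt = 0``) scales linearly with copy
  number, so adding repeats pushes it upward;
* the H3K9me nullcline (where ``dx3/dt = 0``) is copy-number independent
  and its nonlinear shape allows one to three intersections.

Intersections with low methylation (< 0.2) are desilenced states, those with
high methylation are silenced; when three coexist the middle one is
unstable, and the stable pair disappears through a saddle-node bifurcation
as the copy number grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .model_core import ParameterSet, rhs_three_state

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "rna_quasi_equilibrium",
    "sirna_nullcline",
    "h3k9me_nullcline",
    "reduced_rhs",
    "find_fixed_points",
    "qssa_bifurcation",
    "regime_label",
    "DESILENCED_MAX",
    "SILENCED_MIN",
]

#: Regime thresholds on the methylation fraction: below DESILENCED_MAX the
#: state is desilenced, above SILENCED_MIN silenced, in between intermediate.
DESILENCED_MAX = 0.2
SILENCED_MIN = 0.5

#: Grid used to bracket nullcline intersections on (0, 1).
_GRID_N = 4001
_GRID_LO = 1e-6
_GRID_HI = 1.0 - 1e-6


def regime_label(x3: float) -> str:
    if x3 < DESILENCED_MAX:
        return "desilenced"
    if x3 > SILENCED_MIN:
        return "silenced"
    return "intermediate"


@dataclass(frozen=True)
class FixedPoint:
    """A steady state of the reduced (QSSA) system."""

    x1: float
    x2: float
    x3: float
    stability: str  # "stable" | "unstable"
    regime: str  # "desilenced" | "silenced" | "intermediate"

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


def rna_quasi_equilibrium(x3, params: ParameterSet):
    """RNA level with the RNA equation equilibrated at methylation ``x3``."""
    p = params
    x3 = np.asarray(x3, dtype=float)
    g = (x3 / p.k2) ** p.rho2
    h1 = 1.0 + (x3 / p.k1) ** p.rho1
    x1 = (p.copy_number * p.alpha / h1 * (1.0 + g)
          / (p.delta1 * (1.0 + g) + p.gamma * g))
    return float(x1) if x1.ndim == 0 else x1


def sirna_nullcline(x3, params: ParameterSet):
    """siRNA level solving ``dx2/dt = 0`` at methylation ``x3``.

    Linear in copy number; strictly increasing in ``C`` at every ``x3 > 0``.
    """
    p = params
    if p.delta2 <= 0:
        raise ValueError("sirna_nullcline requires delta2 > 0")
    x3 = np.asarray(x3, dtype=float)
    g = (x3 / p.k2) ** p.rho2
    h1 = 1.0 + (x3 / p.k1) ** p.rho1
    x2 = (p.gamma * p.copy_number * p.alpha * g
          / (p.delta2 * h1 * (p.delta1 * (1.0 + g) + p.gamma * g)))
    return float(x2) if x2.ndim == 0 else x2


def h3k9me_nullcline(x3, params: ParameterSet):
    """siRNA level solving ``dx3/dt = 0`` at methylation ``x3``.

    Singular at ``x3 = 0`` and ``x3 = 1``; those endpoints are rejected.
    May be negative at small ``x3`` (no physical siRNA level is needed to
    sustain such methylation); intersection logic keeps only ``x2 >= 0``.
    Copy-number independent.
    """
    p = params
    if p.epsilon <= 0:
        raise ValueError("h3k9me_nullcline requires epsilon > 0")
    x3 = np.asarray(x3, dtype=float)
    if np.any(x3 <= 0.0) or np.any(x3 >= 1.0):
        raise ValueError("h3k9me_nullcline is singular at x3 = 0 and x3 = 1")
    r3 = (x3 / p.k3) ** p.rho3
    num = (1.0 + r3) * (p.delta3 * x3 - p.phi * (1.0 - x3) * x3
                        - p.zeta * (1.0 - x3))
    x2 = num / (p.epsilon * (1.0 - x3) * r3)
    return float(x2) if x2.ndim == 0 else x2


def reduced_rhs(x2, x3, params: ParameterSet):
    """RHS of the reduced two-variable system (x1 at quasi-equilibrium)."""
    x1 = rna_quasi_equilibrium(x3, params)
    _, dx2, dx3 = rhs_three_state((x1, x2, x3), params)
    return dx2, dx3


def _reduced_jacobian(x2: float, x3: float, params: ParameterSet,
                      h: float = 1e-7) -> np.ndarray:
    j = np.empty((2, 2))
    for col, (d2, d3) in enumerate(((h, 0.0), (0.0, h))):
        fp = reduced_rhs(x2 + d2, min(x3 + d3, 1 - 1e-9), params)
        fm = reduced_rhs(x2 - d2, max(x3 - d3, 1e-9), params)
        j[0, col] = (fp[0] - fm[0]) / (2 * h)
        j[1, col] = (fp[1] - fm[1]) / (2 * h)
    return j


def _dx3_on_sirna_nullcline(x3, params: ParameterSet):
    """``dx3/dt`` evaluated with ``x2`` on the siRNA nullcline.

    For ``epsilon > 0`` this equals
    ``epsilon*(1-x3)*H3(x3) * (sirna_nullcline - h3k9me_nullcline)`` so its
    roots are exactly the nullcline intersections with ``x2 >= 0`` (the
    negative-``x2`` branch of the H3K9me nullcline can never balance a
    nonnegative siRNA level and is excluded automatically).  It stays
    well-defined for ``epsilon = 0`` or ``gamma = 0``, where the single
    root is the desilenced balance of basal methylation, spreading and
    demethylation.
    """
    p = params
    x2 = np.maximum(sirna_nullcline(x3, p), 0.0)
    r3 = (np.asarray(x3, dtype=float) / p.k3) ** p.rho3
    h3 = r3 / (1.0 + r3)
    return (p.epsilon * x2 * (1.0 - x3) * h3 - p.delta3 * x3
            + p.phi * (1.0 - x3) * x3 + p.zeta * (1.0 - x3))


def find_fixed_points(params: ParameterSet) -> list[FixedPoint]:
    """All steady states of the reduced system with ``x3`` in (0, 1).

    ``dx3/dt`` along the siRNA nullcline is bracketed on a uniform
    4001-point grid and each sign change polished by bisection; for
    ``epsilon > 0`` the roots coincide with the nullcline intersections at
    ``x2 >= 0``.  Stability comes from the eigenvalues of the reduced 2x2
    Jacobian.  More than three roots signals a grid/parameter pathology and
    raises.  An empty list means the flow is monotone on (0, 1) (e.g. with
    ``delta3 = 0`` methylation always wins and the attractor sits at the
    ``x3 = 1`` boundary).
    """
    p = params
    if p.delta1 <= 0 or p.delta2 <= 0:
        raise ValueError("find_fixed_points requires delta1, delta2 > 0")
    x = np.linspace(_GRID_LO, _GRID_HI, _GRID_N)
    diff = _dx3_on_sirna_nullcline(x, p)
    sign = np.sign(diff)
    idx = np.where(np.diff(sign) != 0)[0]
    roots: list[float] = []
    for i in idx:
        r = brentq(lambda t: float(_dx3_on_sirna_nullcline(t, p)),
                   x[i], x[i + 1], xtol=1e-12)
        roots.append(float(r))
    roots.sort()
    if len(roots) > 3:
        raise RuntimeError(
            f"found {len(roots)} nullcline intersections at "
            f"copy_number={p.copy_number}: {roots}; parameter pathology")
    out = []
    for r in roots:
        x2 = max(float(sirna_nullcline(r, p)), 0.0)
        eig = np.linalg.eigvals(_reduced_jacobian(x2, r, p))
        stab = "stable" if np.all(eig.real < 0) else "unstable"
        out.append(FixedPoint(x1=float(rna_quasi_equilibrium(r, p)), x2=x2,
                              x3=r, stability=stab, regime=regime_label(r)))
    return out


@dataclass
class BifurcationDiagram:
    """Fixed points along a one-parameter sweep."""

    sweep_parameter: str
    values: np.ndarray
    fixed_points: list[list[FixedPoint]]
    saddle_nodes: list[tuple[float, float]] = field(default_factory=list)

    def stable_counts(self) -> np.ndarray:
        return np.array([sum(fp.is_stable for fp in fps)
                         for fps in self.fixed_points])

    def to_frame(self):
        import pandas as pd

        rows = []
        for v, fps in zip(self.values, self.fixed_points):
            for fp in fps:
                rows.append((v, fp.x3, fp.x2, fp.x1, fp.stability, fp.regime))
        return pd.DataFrame(rows, columns=[self.sweep_parameter, "x3", "x2",
                                           "x1", "stability", "regime"])


def qssa_bifurcation(params: ParameterSet, parameter_name: str,
                     values) -> BifurcationDiagram:
    """Fixed points for each value of one swept parameter.

    Saddle-node locations are reported as the intervals between adjacent
    grid values where the stable fixed-point count changes (matching the
    integer copy-number resolution of the scans; no continuation is done).
    """
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(values) <= 0):
        raise ValueError("value grid must be strictly increasing")
    if parameter_name not in params.to_dict():
        raise ValueError(f"unknown parameter {parameter_name!r}")
    all_fps = []
    for v in values:
        try:
            all_fps.append(find_fixed_points(params.replace(
                **{parameter_name: float(v)})))
        except Exception as exc:
            raise RuntimeError(
                f"fixed-point search failed at {parameter_name}={v}") from exc
    diagram = BifurcationDiagram(parameter_name, values, all_fps)
    counts = diagram.stable_counts()
    for i in range(len(values) - 1):
        if counts[i] != counts[i + 1]:
            diagram.saddle_nodes.append((float(values[i]),
                                         float(values[i + 1])))
    return diagram
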