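"""Parameter-sensitivity regime maps and gene-deletion experiments.

Sensitivity scans vary one rate or Hill parameter within +/-25% of its
reference value (21 grid points) for copy numbers 1-40 and classify each
(value, copy number) cell as desilenced, bistable or silenced from the
stable fixed points of the reduced model.  Deletion experiments set one
parameter to zero — mimicking the deletion of the corresponding RNAi or
chromatin factor — and recompute the full-model bifurcation diagram plus
the wild-type-copy-number steady states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bifurcation, qssa
from .model_core import ParameterSet, default_parameters

__all__ = [
    "RegimeMap",
    "DeletionResult",
    "regime_classify",
    "sweep_parameter",
    "deletion_experiment",
    "nullcline_perturbation_report",
    "DELETABLE",
    "SIRNA_NULLCLINE_PARAMS",
    "H3K9ME_NULLCLINE_PARAMS",
]

#: Parameters whose deletion (value 0) maps onto a known genetic background.
DELETABLE = ("delta1", "delta2", "delta3", "epsilon", "gamma", "phi")

#: Which nullcline each parameter moves.
SIRNA_NULLCLINE_PARAMS = ("alpha", "delta1", "delta2", "gamma", "rho1",
                          "rho2", "k1", "k2", "copy_number")
H3K9ME_NULLCLINE_PARAMS = ("delta3", "epsilon", "phi", "zeta", "rho3", "k3")


def regime_classify(params: ParameterSet) -> str:
    """Classify one parameter set as desilenced / bistable / silenced.

    Bistable when the reduced model has two stable fixed points; otherwise
    the label of the single stable state.  A monostable *intermediate*
    state (methylation between the regime thresholds) is reported as
    ``"intermediate"`` — a diagnostic, never coerced into either regime.
    With no interior fixed point at all the flow is monotone toward full
    methylation and the state is silenced.
    """
    fps = qssa.find_fixed_points(params)
    stable = [fp for fp in fps if fp.is_stable]
    if len(stable) >= 2:
        return "bistable"
    if not stable:
        return "silenced"  # boundary attractor at x3 = 1 (e.g. delta3 = 0)
    return stable[0].regime  # "silenced" | "desilenced" | "intermediate"


@dataclass
class RegimeMap:
    """Regime labels over a (parameter value) x (copy number) grid."""

    parameter: str
    values: np.ndarray
    copy_numbers: np.ndarray
    labels: np.ndarray  # shape (n_cn, n_values), dtype str
    critical_values: dict = field(default_factory=dict)

    def row(self, cn: int) -> np.ndarray:
        return self.labels[list(self.copy_numbers).index(cn)]

    @property
    def smallest_uniform_silenced_cn(self) -> int | None:
        """Smallest copy number whose entire value range is silenced."""
        for i, cn in enumerate(self.copy_numbers):
            if np.all(self.labels[i] == "silenced"):
                return int(cn)
        return None

    @property
    def uniform_bistable_cns(self) -> list[int]:
        """Copy numbers whose entire value range is bistable."""
        return [int(cn) for i, cn in enumerate(self.copy_numbers)
                if np.all(self.labels[i] == "bistable")]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.labels,
                            index=pd.Index(self.copy_numbers,
                                           name="copy_number"),
                            columns=[f"{self.parameter}={v:.6g}"
                                     for v in self.values])


def sweep_parameter(params: ParameterSet, name: str, n_values: int = 21,
                    cn_range=range(1, 41), rel_range: float = 0.25,
                    ) -> RegimeMap:
    """Regime map for one parameter varied within +/-25% of its value.

    Critical values are reported per copy number as the grid intervals
    ``(v_i, v_{i+1})`` across which the label changes.
    """
    if name not in params.to_dict():
        raise ValueError(f"unknown parameter {name!r}")
    if n_values < 3:
        raise ValueError("n_values must be >= 3")
    p0 = getattr(params, name)
    values = np.linspace((1 - rel_range) * p0, (1 + rel_range) * p0, n_values)
    copy_numbers = np.asarray(list(cn_range), dtype=int)
    labels = np.empty((copy_numbers.size, values.size), dtype=object)
    for i, cn in enumerate(copy_numbers):
        for j, v in enumerate(values):
            q = params.replace(**{name: float(v), "copy_number": float(cn)})
            try:
                labels[i, j] = regime_classify(q)
            except Exception as exc:
                raise RuntimeError(
                    f"classification failed at {name}={v}, "
                    f"copy_number={cn}") from exc
    crit = {}
    for i, cn in enumerate(copy_numbers):
        flips = [(float(values[j]), float(values[j + 1]))
                 for j in range(values.size - 1)
                 if labels[i, j] != labels[i, j + 1]]
        if flips:
            crit[int(cn)] = flips
    return RegimeMap(name, values, copy_numbers, labels.astype(str), crit)


@dataclass
class DeletionResult:
    """Outcome of setting one parameter to zero."""

    deleted: str
    parameters: ParameterSet
    diagram: bifurcation.FullBifurcationResult
    h3k9me_at_wt: tuple  # stable-branch methylation fraction(s) at CN=15
    rna_at_wt: tuple  # matching RNA levels (quasi-equilibrium)


def deletion_experiment(name: str, params: ParameterSet | None = None,
                        cn_range=range(1, 21), wt_copy_number: float = 15.0,
                        ) -> DeletionResult:
    """Set one rate to zero and recompute the bifurcation diagram.

    The diagram uses the full-model endpoint scan (the quasi-steady-state
    reduction is unavailable when ``delta2 = 0``), with the standard
    initial-condition lattice built from the *reference* scales.  Branch
    steady states at the wild-type copy number are the k-means cluster
    means; RNA levels follow from the RNA quasi-equilibrium.
    """
    if name not in DELETABLE:
        raise ValueError(f"cannot delete {name!r}; valid: {DELETABLE}")
    base = default_parameters("three") if params is None else params
    deleted = base.replace(**{name: 0.0})
    diagram = bifurcation.full_bifurcation_diagram(deleted, cn_range=cn_range)
    pwt = deleted.replace(copy_number=float(wt_copy_number))
    ics = bifurcation.generate_initial_conditions(
        base, copy_number=wt_copy_number)
    ends = bifurcation.endpoint_scan(deleted, ics, [wt_copy_number])
    cls = bifurcation.classify_by_kmeans(ends[float(wt_copy_number)],
                                         wt_copy_number)
    if cls.is_bistable:
        branches = cls.cluster_means
    else:
        branches = (float(np.mean(cls.endpoints)),)
    rna = tuple(float(qssa.rna_quasi_equilibrium(min(b, 1.0 - 1e-9), pwt))
                for b in branches)
    return DeletionResult(deleted=name, parameters=deleted, diagram=diagram,
                          h3k9me_at_wt=branches, rna_at_wt=rna)


@dataclass
class NullclineFamily:
    """Both nullclines on the standard grid for several parameter values."""

    parameter: str
    moves: str  # "sirna" | "h3k9me"
    x3: np.ndarray
    sirna: dict  # value -> x2 array
    h3k9me: dict  # value -> x2 array


def nullcline_perturbation_report(params: ParameterSet, name: str, values,
                                  n_grid: int = 1001) -> NullclineFamily:
    """Nullcline families as one parameter varies (at fixed copy number)."""
    if name in SIRNA_NULLCLINE_PARAMS:
        moves = "sirna"
    elif name in H3K9ME_NULLCLINE_PARAMS:
        moves = "h3k9me"
    else:
        raise ValueError(f"unknown parameter {name!r}")
    x3 = np.linspace(1e-4, 1.0 - 1e-4, n_grid)
    sirna, h3k9me = {}, {}
    for v in values:
        q = params.replace(**{name: float(v)})
        sirna[float(v)] = np.asarray(qssa.sirna_nullcline(x3, q))
        h3k9me[float(v)] = np.asarray(qssa.h3k9me_nullcline(x3, q))
    return NullclineFamily(name, moves, x3, sirna, h3k9me)
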