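"""Exact stochastic (Gillespie) simulation of the silencing switch.

The deterministic model is mapped to discrete molecule numbers: RNA and
siRNA concentrations are rescaled by a factor ``omega`` (default 100) to
represent individual transcripts, and methylation is tracked as the number
``M`` of methylated H3K9 sites out of ``n_sites_per_copy * copy_number``
independently (de)methylatable sites.  Cell growth is linear in time,
``V = v_min + K t`` with ``K = (v_max - v_min) / division_time``, and at
each division RNA, siRNA and methylated sites are halved and the volume
resets, so division acts as a two-fold dilution.  Extrinsic noise is a
per-particle random walk: three extra channels fire at rate ``beta`` times
the RNA / siRNA / methylated-site count and move the chosen count by +/-1
with equal probability.

Volume enters the propensities by the usual mass-action convention:
zero-order production scales with ``omega * V``, first-order channels are
volume-free, and concentrations inside Hill terms or the bimolecular
methylation channel are counts over ``omega * V``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from numba import njit

from . import qssa
from .model_core import ParameterSet

__all__ = [
    "SSAConfig",
    "SSATrajectory",
    "build_propensities",
    "gillespie_run",
    "silencing_fraction",
    "methylation_density",
]

NO_DIVISION = math.inf


@dataclass(frozen=True)
class SSAConfig:
    """Settings of a stochastic run."""

    omega: float = 100.0  # RNA/siRNA count rescaling factor
    n_sites_per_copy: int = 20  # H3K9 sites per repeat copy
    t_end: float = 10_000.0  # min
    burn_in: float = 4_000.0  # discarded initial time (min)
    division_time: float = NO_DIVISION  # min between divisions; inf = none
    noise_rate: float = 0.0  # beta, per molecule per min
    v_min: float = 2.0 / 3.0
    v_max: float = 4.0 / 3.0
    seed: int = 0
    n_replicates: int = 50
    silenced_threshold: float = 0.5
    sample_step: float = 10.0  # min
    binomial_partition: bool = False  # binomial instead of floor-halving

    def __post_init__(self) -> None:
        if self.omega < 1:
            raise ValueError("omega must be >= 1")
        if not 0 < self.v_min < self.v_max:
            raise ValueError("need 0 < v_min < v_max")
        if not self.burn_in < self.t_end:
            raise ValueError("burn_in must be smaller than t_end")
        if not 0 < self.silenced_threshold < 1:
            raise ValueError("silenced_threshold must be in (0, 1)")
        if self.n_sites_per_copy < 1:
            raise ValueError("n_sites_per_copy must be >= 1")

    def replace(self, **changes) -> "SSAConfig":
        return replace(self, **changes)

    def total_sites(self, params: ParameterSet) -> int:
        return int(round(self.n_sites_per_copy * params.copy_number))


@dataclass
class SSATrajectory:
    """Uniformly sampled stochastic trajectory."""

    times: np.ndarray
    rna: np.ndarray
    sirna: np.ndarray
    methylated: np.ndarray
    volume: np.ndarray
    total_sites: int
    parameters: ParameterSet
    config: SSAConfig

    @property
    def methylation_fraction(self) -> np.ndarray:
        return self.methylated / self.total_sites

    def after_burn_in(self) -> np.ndarray:
        keep = self.times >= self.config.burn_in
        return self.methylation_fraction[keep]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time": self.times, "N1": self.rna, "N2": self.sirna,
            "M": self.methylated, "fraction": self.methylation_fraction,
            "V": self.volume,
        })


def build_propensities(state: Sequence[float], params: ParameterSet,
                       config: SSAConfig):
    """Reaction channels at one discrete state.

    ``state`` is ``(N1, N2, M, V)``.  Returns ``(rates, changes)`` where
    ``changes`` rows are ``(dN1, dN2, dM)``; the three trailing noise
    channels carry symbolic change ``(0, 0, 0)`` because their +/-1
    direction is drawn at firing time.  Used by tests and as the reference
    for the compiled kernel.
    """
    n1, n2, m_count, vol = state
    if min(n1, n2, m_count) < 0 or vol <= 0:
        raise ValueError("invalid SSA state")
    p = params
    sites = config.total_sites(p)
    if m_count > sites:
        raise ValueError("methylated sites exceed total sites")
    m = m_count / sites
    ov = config.omega * vol
    h1 = 1.0 / (1.0 + (m / p.k1) ** p.rho1)
    r2 = (m / p.k2) ** p.rho2
    h2 = r2 / (1.0 + r2)
    r3 = (m / p.k3) ** p.rho3
    h3 = r3 / (1.0 + r3)
    rates = np.array([
        ov * p.copy_number * p.alpha * h1,          # transcription
        p.delta1 * n1,                              # RNA decay
        p.gamma * n1 * h2,                          # siRNA biogenesis
        p.delta2 * n2,                              # siRNA decay
        p.epsilon * (n2 / ov) * (sites - m_count) * h3,  # methylation
        p.delta3 * m_count,                         # demethylation
        p.phi * m * (sites - m_count),              # spreading
        p.zeta * (sites - m_count),                 # basal methylation
        config.noise_rate * n1,                     # noise on RNA
        config.noise_rate * n2,                     # noise on siRNA
        config.noise_rate * m_count,                # noise on methylation
    ])
    if np.any(rates < 0):
        raise RuntimeError(f"negative propensity: {rates}")
    changes = np.array([
        (1, 0, 0), (-1, 0, 0), (-1, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1), (0, 0, 1), (0, 0, 1),
        (0, 0, 0), (0, 0, 0), (0, 0, 0),
    ])
    return rates, changes


@njit(cache=False)
def _ssa_kernel(alpha, delta1, delta2, delta3, gamma, epsilon, phi, zeta,
                rho1, rho2, rho3, k1, k2, k3, copy_number,
                omega, sites, t_end, division_time, beta, v_min, v_max,
                n1_0, n2_0, m_0, sample_step, seed, binom):
    np.random.seed(seed)
    n_samples = int(t_end / sample_step) + 1
    ts = np.empty(n_samples)
    o1 = np.empty(n_samples, dtype=np.int64)
    o2 = np.empty(n_samples, dtype=np.int64)
    om = np.empty(n_samples, dtype=np.int64)
    ov_ = np.empty(n_samples)

    n1, n2, m_count = n1_0, n2_0, m_0
    t = 0.0
    last_div = 0.0
    has_div = division_time < 1e17
    K = (v_max - v_min) / division_time if has_div else 0.0
    next_div = division_time if has_div else 1e300
    isample = 0
    status = 0
    while isample < n_samples:
        vol = v_min + K * (t - last_div) if has_div else 1.0
        m = m_count / sites
        ovol = omega * vol
        h1 = 1.0 / (1.0 + (m / k1) ** rho1)
        r2 = (m / k2) ** rho2
        h2 = r2 / (1.0 + r2)
        r3 = (m / k3) ** rho3
        h3 = r3 / (1.0 + r3)
        free = sites - m_count
        a = np.empty(11)
        a[0] = ovol * copy_number * alpha * h1
        a[1] = delta1 * n1
        a[2] = gamma * n1 * h2
        a[3] = delta2 * n2
        a[4] = epsilon * (n2 / ovol) * free * h3
        a[5] = delta3 * m_count
        a[6] = phi * m * free
        a[7] = zeta * free
        a[8] = beta * n1
        a[9] = beta * n2
        a[10] = beta * m_count
        a0 = 0.0
        for i in range(11):
            a0 += a[i]
        if a0 > 1e9:
            status = 1  # runaway propensity
            break
        if a0 > 0.0:
            tau = -math.log(np.random.random()) / a0
        else:
            tau = 1e300
        t_next = t + tau
        event_is_division = has_div and t_next >= next_div
        t_event = next_div if event_is_division else t_next
        # record samples strictly before the event with the current state;
        # a sample landing exactly on a division time reflects the
        # post-division state (recorded on the next pass)
        while isample < n_samples and isample * sample_step < t_event:
            ts[isample] = isample * sample_step
            o1[isample] = n1
            o2[isample] = n2
            om[isample] = m_count
            ov_[isample] = (v_min + K * (isample * sample_step - last_div)
                            if has_div else 1.0)
            isample += 1
        if isample >= n_samples:
            break
        if event_is_division:
            t = next_div
            last_div = t
            next_div = t + division_time
            if binom:
                n1 = np.random.binomial(n1, 0.5)
                n2 = np.random.binomial(n2, 0.5)
                m_count = np.random.binomial(m_count, 0.5)
            else:
                n1 //= 2
                n2 //= 2
                m_count //= 2
            continue
        t = t_next
        r = np.random.random() * a0
        c = 0.0
        ch = 10
        for i in range(11):
            c += a[i]
            if r < c:
                ch = i
                break
        if ch == 0:
            n1 += 1
        elif ch == 1:
            n1 -= 1
        elif ch == 2:
            n1 -= 1
            n2 += 1
        elif ch == 3:
            n2 -= 1
        elif ch == 4 or ch == 6 or ch == 7:
            m_count += 1
        elif ch == 5:
            m_count -= 1
        elif ch == 8:
            if np.random.random() < 0.5:
                n1 = n1 - 1 if n1 > 0 else 0
            else:
                n1 += 1
        elif ch == 9:
            if np.random.random() < 0.5:
                n2 = n2 - 1 if n2 > 0 else 0
            else:
                n2 += 1
        else:
            if np.random.random() < 0.5:
                m_count = m_count - 1 if m_count > 0 else 0
            elif m_count < sites:
                m_count += 1
    return ts[:isample], o1[:isample], o2[:isample], om[:isample], \
        ov_[:isample], status


def _default_initial_counts(params: ParameterSet, config: SSAConfig):
    """Counts at the silenced deterministic branch (the wild-type start).

    Falls back to the single stable state when the system is monostable.
    """
    fps = [fp for fp in qssa.find_fixed_points(params) if fp.is_stable]
    if fps:
        fp = max(fps, key=lambda f: f.x3)
        x1, x2, x3 = fp.x1, fp.x2, fp.x3
    else:  # boundary attractor
        x3 = 1.0 - 1e-6
        x1 = qssa.rna_quasi_equilibrium(x3, params)
        x2 = qssa.sirna_nullcline(x3, params)
    sites = config.total_sites(params)
    return (int(round(x1 * config.omega)), int(round(x2 * config.omega)),
            int(round(x3 * sites)))


def gillespie_run(params: ParameterSet, config: SSAConfig,
                  initial_counts=None, seed: int | None = None,
                  ) -> SSATrajectory:
    """One exact-SSA trajectory sampled on a uniform grid.

    The initial state defaults to the silenced deterministic branch
    converted to counts.  Identical ``(params, config, seed)`` give a
    bit-identical trajectory (NumPy legacy MT19937 generator inside the
    compiled kernel).
    """
    sites = config.total_sites(params)
    if initial_counts is None:
        n1, n2, m0 = _default_initial_counts(params, config)
    else:
        n1, n2, m0 = (int(v) for v in initial_counts)
    if not (0 <= m0 <= sites and n1 >= 0 and n2 >= 0):
        raise ValueError("invalid initial counts")
    use_seed = config.seed if seed is None else int(seed)
    if not 0 <= use_seed < 2 ** 32:
        raise ValueError("seed must fit in 32 bits")
    p = params
    out = _ssa_kernel(
        p.alpha, p.delta1, p.delta2, p.delta3, p.gamma, p.epsilon, p.phi,
        p.zeta, p.rho1, p.rho2, p.rho3, p.k1, p.k2, p.k3, p.copy_number,
        float(config.omega), sites, float(config.t_end),
        float(config.division_time) if math.isfinite(config.division_time)
        else 1e300,
        float(config.noise_rate), config.v_min, config.v_max,
        n1, n2, m0, float(config.sample_step), use_seed,
        config.binomial_partition)
    ts, o1, o2, om, ov, status = out
    if status == 1:
        raise RuntimeError(
            f"runaway total propensity (> 1e9/min) at t={ts[-1] if len(ts) else 0}"
            f" with parameters {params.to_dict()}")
    return SSATrajectory(times=ts, rna=o1, sirna=o2, methylated=om,
                         volume=ov, total_sites=sites, parameters=params,
                         config=config)


def silencing_fraction(params: ParameterSet, config: SSAConfig):
    """Mean fraction of post-burn-in time spent silenced, over replicates.

    Per replicate, the fraction of samples after ``burn_in`` whose
    methylation fraction exceeds ``silenced_threshold``; returns
    ``(mean, sem, per_replicate)``.  Replicate r uses seed ``seed + r``.
    """
    if config.n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    fracs = np.empty(config.n_replicates)
    for r in range(config.n_replicates):
        traj = gillespie_run(params, config, seed=config.seed + r)
        post = traj.after_burn_in()
        fracs[r] = float(np.mean(post > config.silenced_threshold))
    sem = float(np.std(fracs, ddof=1) / math.sqrt(len(fracs)))
    return float(np.mean(fracs)), sem, fracs


def methylation_density(params: ParameterSet, config: SSAConfig,
                        time_bins: int = 10, fraction_bins: int = 25):
    """Probability density of the methylation fraction over time.

    Pools all replicates, bins samples into ``time_bins`` equal windows of
    the full run and histograms the methylation fraction in each window;
    every time bin is normalised to unit mass.  Returns
    ``(time_edges, fraction_edges, density)`` with density shape
    ``(time_bins, fraction_bins)``.
    """
    if config.n_replicates < 1:
        raise ValueError("need at least one replicate")
    t_edges = np.linspace(0.0, config.t_end, time_bins + 1)
    f_edges = np.linspace(0.0, 1.0, fraction_bins + 1)
    counts = np.zeros((time_bins, fraction_bins))
    for r in range(config.n_replicates):
        traj = gillespie_run(params, config, seed=config.seed + r)
        ti = np.clip(np.searchsorted(t_edges, traj.times, side="right") - 1,
                     0, time_bins - 1)
        fi = np.clip(np.searchsorted(f_edges, traj.methylation_fraction,
                                     side="right") - 1, 0, fraction_bins - 1)
        np.add.at(counts, (ti, fi), 1.0)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return t_edges, f_edges, counts / totals
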