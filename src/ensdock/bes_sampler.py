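"""Blockwise excursion sampling (BES) of peptide conformers.

An excursion chain alternates simulated-annealing (SA) blocks, which hop
between basins by heating to a block-specific maximum temperature and
cooling back down, with constant-temperature relaxation blocks, which
equilibrate locally.  Each relaxation block contributes exactly one
*representative* structure: the trajectory frame closest (by all-atom RMSD,
after superposition) to the window-mean structure, energy-minimized by
conjugate gradients.  A library of ``n_chains x blocks_per_chain``
representatives results; chains are independent and start from the same
extended structure.

The sampler is defined over a pluggable :class:`EnergyModel` contract and
ships a coarse-grained bead-chain potential (bonded springs, pairwise
excluded volume, dihedral cosine term) as its default test system; it is a
desk-scale stand-in for a molecular force field, not an approximation of
one.  Dynamics are overdamped Langevin with a per-bead step-length cap for
stability, with a Metropolis Monte Carlo fallback.

Time is measured in integrator steps.  The default window covers the final
5/6 of each relaxation block, mirroring the convention of discarding the
first sixth of a block as re-equilibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy.optimize import minimize

from .structure_io import Structure, write_pdb
from .trajectory_metrics import kabsch_superpose

__all__ = [
    "EnergyModel",
    "HarmonicWellModel",
    "BeadChainModel",
    "ExcursionConfig",
    "RepresentativeRecord",
    "SamplingError",
    "run_sa_block",
    "run_relaxation_block",
    "select_representative",
    "run_excursion_chain",
    "build_library",
    "write_library",
    "manifest_text",
    "derive_chain_seed",
]

KB = 0.0019872041  # kcal/(mol K)


class SamplingError(RuntimeError):
    pass


class EnergyModel(Protocol):
    """Evaluation contract for the sampler: energy and gradient of a
    coordinate set, plus a human-readable label."""

    label: str

    def energy(self, coords: np.ndarray) -> float: ...

    def gradient(self, coords: np.ndarray) -> np.ndarray: ...


@dataclass
class HarmonicWellModel:
    """Isotropic harmonic well around a fixed centre — analytic test system."""

    center: np.ndarray
    k: float = 1.0
    label: str = "harmonic-well"

    def energy(self, coords: np.ndarray) -> float:
        d = np.asarray(coords, float) - self.center
        return float(0.5 * self.k * np.sum(d * d))

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.k * (np.asarray(coords, float) - self.center)


try:  # numba accelerates the bead-chain potential ~10x; numpy path is the fallback
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None


def _bead_energy_gradient_py(x, k_bond, r0, eps_rep, sigma, k_dih):
    """Fused energy + gradient of the bead-chain potential (scalar loops;
    compiled with numba when available, also serves as the pure-python
    reference implementation)."""
    n = x.shape[0]
    e = 0.0
    g = np.zeros_like(x)
    sigma12 = sigma ** 12
    for i in range(n - 1):
        dx = x[i + 1, 0] - x[i, 0]
        dy = x[i + 1, 1] - x[i, 1]
        dz = x[i + 1, 2] - x[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += k_bond * (r - r0) ** 2
        if r > 1e-12:
            coef = 2.0 * k_bond * (r - r0) / r
            g[i, 0] -= coef * dx; g[i, 1] -= coef * dy; g[i, 2] -= coef * dz
            g[i + 1, 0] += coef * dx; g[i + 1, 1] += coef * dy; g[i + 1, 2] += coef * dz
    for i in range(n - 2):
        for j in range(i + 2, n):
            dx = x[i, 0] - x[j, 0]
            dy = x[i, 1] - x[j, 1]
            dz = x[i, 2] - x[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            s = sigma12 / d2 ** 6
            e += eps_rep * s
            coef = -12.0 * eps_rep * s / d2
            g[i, 0] += coef * dx; g[i, 1] += coef * dy; g[i, 2] += coef * dz
            g[j, 0] -= coef * dx; g[j, 1] -= coef * dy; g[j, 2] -= coef * dz
    for t in range(n - 3):
        b1 = x[t + 1] - x[t]
        b2 = x[t + 2] - x[t + 1]
        b3 = x[t + 3] - x[t + 2]
        m0 = b1[1] * b2[2] - b1[2] * b2[1]
        m1 = b1[2] * b2[0] - b1[0] * b2[2]
        m2_ = b1[0] * b2[1] - b1[1] * b2[0]
        n0 = b2[1] * b3[2] - b2[2] * b3[1]
        n1 = b2[2] * b3[0] - b2[0] * b3[2]
        n2_ = b2[0] * b3[1] - b2[1] * b3[0]
        p2 = m0 * m0 + m1 * m1 + m2_ * m2_
        q2 = n0 * n0 + n1 * n1 + n2_ * n2_
        if p2 < 1e-10 or q2 < 1e-10:
            # collinear: cos(phi) -> -1 (trans), zero torque
            continue
        c = m0 * n0 + m1 * n1 + m2_ * n2_
        pq = math.sqrt(p2 * q2)
        cosphi = c / pq
        e += k_dih * (1.0 + cosphi)
        m = np.empty(3); m[0] = m0; m[1] = m1; m[2] = m2_
        nn = np.empty(3); nn[0] = n0; nn[1] = n1; nn[2] = n2_
        b12 = b1 + b2
        b23 = b2 + b3
        gc0 = -_cross3(b2, nn)
        gc1 = _cross3(b12, nn) - _cross3(b3, m)
        gc2 = _cross3(nn, b1) + _cross3(b23, m)
        gc3 = _cross3(m, b2)
        gp0 = -2.0 * _cross3(b2, m)
        gp1 = 2.0 * _cross3(b12, m)
        gp2v = 2.0 * _cross3(m, b1)
        gq1 = -2.0 * _cross3(b3, nn)
        gq2v = 2.0 * _cross3(b23, nn)
        gq3 = 2.0 * _cross3(nn, b2)
        inv = 1.0 / pq
        g[t] += k_dih * (gc0 * inv - cosphi * (gp0 / (2.0 * p2)))
        g[t + 1] += k_dih * (gc1 * inv - cosphi * (gp1 / (2.0 * p2) + gq1 / (2.0 * q2)))
        g[t + 2] += k_dih * (gc2 * inv - cosphi * (gp2v / (2.0 * p2) + gq2v / (2.0 * q2)))
        g[t + 3] += k_dih * (gc3 * inv - cosphi * (gq3 / (2.0 * q2)))
    return e, g


def _cross3_py(a, b):
    out = np.empty(3)
    out[0] = a[1] * b[2] - a[2] * b[1]
    out[1] = a[2] * b[0] - a[0] * b[2]
    out[2] = a[0] * b[1] - a[1] * b[0]
    return out


if _njit is not None:
    _cross3 = _njit(cache=True)(_cross3_py)
    _bead_energy_gradient = _njit(cache=True)(_bead_energy_gradient_py)
else:  # pragma: no cover
    _cross3 = _cross3_py
    _bead_energy_gradient = _bead_energy_gradient_py


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise cross product of (K, 3) arrays; avoids np.cross overhead
    in the integrator hot loop."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


@dataclass
class BeadChainModel:
    """Coarse-grained bead-per-residue chain potential.

    E = sum_bonds k_bond (r - r0)^2
      + sum_{|i-j|>=2} eps_rep (sigma / r)^12
      + sum_dihedrals k_dihedral (1 + cos phi)

    The repulsive term is smooth (no cutoff) and negligible beyond ~2 sigma;
    the dihedral term makes extended (trans, phi = 180 deg) states the
    bonded-energy minimum, so compaction is driven by entropy/temperature
    rather than attraction — adequate for generating diverse chain
    geometries.  Near-collinear dihedrals are treated as trans (zero energy
    contribution, zero torque) since their torsion angle is undefined.
    """

    n_beads: int
    k_bond: float = 5.0       # kcal/(mol A^2)
    r0: float = 3.8           # A, consecutive-bead distance
    eps_rep: float = 1.0      # kcal/mol
    sigma: float = 4.0        # A
    k_dihedral: float = 0.5   # kcal/mol
    label: str = "bead-chain"

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("bead chain needs at least 2 beads")
        n = self.n_beads
        ii, jj = np.triu_indices(n, k=2)
        self._rep_i, self._rep_j = ii, jj

    def energy_gradient(self, coords: np.ndarray) -> tuple[float, np.ndarray]:
        """Fused energy + gradient (numba-compiled when available)."""
        x = np.ascontiguousarray(np.asarray(coords, float).reshape(self.n_beads, 3))
        e, g = _bead_energy_gradient(x, self.k_bond, self.r0, self.eps_rep,
                                     self.sigma, self.k_dihedral)
        return float(e), g

    def energy(self, coords: np.ndarray) -> float:
        return self.energy_gradient(coords)[0]

    def gradient(self, coords: np.ndarray) -> np.ndarray:
        return self.energy_gradient(coords)[1]

    def reference_energy(self, coords: np.ndarray) -> float:
        """Vectorized numpy implementation, kept as an independent
        cross-check of the compiled path."""
        x = np.asarray(coords, float).reshape(self.n_beads, 3)
        e = 0.0
        bonds = np.linalg.norm(np.diff(x, axis=0), axis=1)
        e += self.k_bond * np.sum((bonds - self.r0) ** 2)
        if self._rep_i.size:
            d = np.linalg.norm(x[self._rep_i] - x[self._rep_j], axis=1)
            e += self.eps_rep * np.sum((self.sigma / d) ** 12)
        if self.n_beads >= 4:
            e += self.k_dihedral * np.sum(1.0 + self._dihedral_cos(x))
        return float(e)

    def _dihedral_cos(self, x: np.ndarray) -> np.ndarray:
        b1 = x[1:-2] - x[0:-3]
        b2 = x[2:-1] - x[1:-2]
        b3 = x[3:] - x[2:-1]
        m = _cross(b1, b2)
        n = _cross(b2, b3)
        mn = np.linalg.norm(m, axis=1) * np.linalg.norm(n, axis=1)
        cosphi = np.einsum("ij,ij->i", m, n) / np.where(mn > 1e-12, mn, 1.0)
        cosphi = np.where(mn > 1e-12, cosphi, -1.0)  # collinear -> trans
        return np.clip(cosphi, -1.0, 1.0)

    def reference_gradient(self, coords: np.ndarray) -> np.ndarray:
        x = np.asarray(coords, float).reshape(self.n_beads, 3)
        g = np.zeros_like(x)
        # bonds
        dvec = np.diff(x, axis=0)
        r = np.linalg.norm(dvec, axis=1)
        f = (2.0 * self.k_bond * (r - self.r0) / np.where(r > 1e-12, r, 1.0))[:, None] * dvec
        g[:-1] -= f
        g[1:] += f
        # excluded volume
        if self._rep_i.size:
            dv = x[self._rep_i] - x[self._rep_j]
            d = np.linalg.norm(dv, axis=1)
            coef = -12.0 * self.eps_rep * self.sigma ** 12 / d ** 14
            fv = coef[:, None] * dv
            np.add.at(g, self._rep_i, fv)
            np.subtract.at(g, self._rep_j, fv)
        # dihedral cosine term: E = k (1 + cos phi) with
        # cos phi = m.n / (|m||n|), m = b1 x b2, n = b2 x b3; the gradient of
        # cos phi is taken directly (no signed-angle convention involved).
        if self.n_beads >= 4:
            b1 = x[1:-2] - x[0:-3]
            b2 = x[2:-1] - x[1:-2]
            b3 = x[3:] - x[2:-1]
            m = _cross(b1, b2)
            n = _cross(b2, b3)
            p2 = np.einsum("ij,ij->i", m, m)
            q2 = np.einsum("ij,ij->i", n, n)
            ok = (p2 > 1e-10) & (q2 > 1e-10)  # collinear dihedrals exert no torque
            if np.any(ok):
                c = np.einsum("ij,ij->i", m, n)
                pq = np.sqrt(p2 * q2)
                inv = np.where(ok, 1.0 / np.where(ok, pq, 1.0), 0.0)
                # gradients of c = m.n, p^2 = |m|^2, q^2 = |n|^2 per atom role
                gc = [
                    -_cross(b2, n),
                    _cross(b1 + b2, n) - _cross(b3, m),
                    _cross(n, b1) + _cross(b2 + b3, m),
                    _cross(m, b2),
                ]
                gp2 = [
                    -2.0 * _cross(b2, m),
                    2.0 * _cross(b1 + b2, m),
                    2.0 * _cross(m, b1),
                    np.zeros_like(m),
                ]
                gq2 = [
                    np.zeros_like(n),
                    -2.0 * _cross(b3, n),
                    2.0 * _cross(b2 + b3, n),
                    2.0 * _cross(n, b2),
                ]
                cos = c * inv
                for role in range(4):
                    # d(cos)/dx = dc/(pq) - cos * (dp2/(2 p2) + dq2/(2 q2))
                    term = gc[role] * inv[:, None] - cos[:, None] * (
                        gp2[role] / (2.0 * np.where(ok, p2, 1.0))[:, None]
                        + gq2[role] / (2.0 * np.where(ok, q2, 1.0))[:, None])
                    term[~ok] = 0.0
                    np.add.at(g, np.arange(self.n_beads - 3) + role,
                              self.k_dihedral * term)
        return g


@dataclass
class ExcursionConfig:
    """Configuration of one library build.

    ``sa_max_temperatures`` supplies one SA peak temperature per block;
    ``representative_window_steps`` is the tail of each relaxation block
    used for mean-structure averaging.
    """

    n_chains: int = 2000
    blocks_per_chain: int = 5
    sa_max_temperatures: Sequence[float] = (700.0, 600.0, 500.0, 400.0, 350.0)
    sa_duration_steps: int = 60
    relax_duration_steps: int = 120
    representative_window_steps: int = 100
    base_temperature: float = 300.0
    timestep: float = 0.01
    friction: float = 1.0
    frame_stride: int = 1
    seed: int = 0
    integrator: str = "langevin"  # or "metropolis"
    cooling: str = "linear"       # or "exponential"
    max_step_length: float = 0.75  # A, per-bead displacement cap
    minimizer_maxiter: int = 200

    def __post_init__(self):
        if self.n_chains < 1 or self.blocks_per_chain < 1:
            raise ValueError("n_chains and blocks_per_chain must be positive")
        if len(self.sa_max_temperatures) != self.blocks_per_chain:
            raise ValueError("need one SA max temperature per block")
        if self.representative_window_steps > self.relax_duration_steps:
            raise ValueError("representative window exceeds relaxation duration")
        if self.representative_window_steps < 1 or self.relax_duration_steps < 1:
            raise ValueError("step counts must be positive")
        if any(t <= self.base_temperature for t in self.sa_max_temperatures):
            raise ValueError("SA max temperatures must exceed the base temperature")
        if self.integrator not in ("langevin", "metropolis"):
            raise ValueError(f"unknown integrator {self.integrator!r}")
        if self.cooling not in ("linear", "exponential"):
            raise ValueError(f"unknown cooling schedule {self.cooling!r}")

    @classmethod
    def desk_scale(cls, seed: int = 0, n_chains: int = 2000,
                   blocks_per_chain: int = 5) -> "ExcursionConfig":
        """Full ensemble bookkeeping (2000 chains x 5 blocks by default) at
        reduced per-block step counts, sized so a complete library build
        runs in minutes on one CPU.  The 5/6 window-to-block ratio of the
        defaults is preserved (window 20 of 24 relaxation steps)."""
        temps = (700.0, 600.0, 500.0, 400.0, 350.0)
        if blocks_per_chain != 5:
            temps = tuple(np.linspace(700.0, 350.0, blocks_per_chain))
        return cls(n_chains=n_chains, blocks_per_chain=blocks_per_chain,
                   sa_max_temperatures=temps, sa_duration_steps=20,
                   relax_duration_steps=24, representative_window_steps=20,
                   seed=seed, minimizer_maxiter=20)


@dataclass
class RepresentativeRecord:
    """One library member: which chain/block produced it, its RMSD to the
    window-mean structure, and its minimized energy."""

    chain_index: int
    block_index: int
    structure: Structure
    rmsd_to_mean: float
    minimized_energy: float
    frame_index: int = 0
    seed: int = 0


def derive_chain_seed(seed: int, chain_index: int) -> int:
    """Deterministic per-chain seed: base seed XOR Knuth-hashed chain index."""
    return (seed ^ ((chain_index + 1) * 2654435761)) % (2 ** 31)


def _check_finite(value, context: str):
    if not np.all(np.isfinite(value)):
        raise SamplingError(f"non-finite energy/gradient encountered during {context}")


def _langevin_step(x, model, temperature, dt, friction, cap, rng):
    g = model.gradient(x)
    _check_finite(g, "langevin step")
    drift = -dt / friction * g
    noise = math.sqrt(2.0 * KB * temperature * dt / friction) * rng.standard_normal(x.shape)
    step = drift + noise
    norms = np.linalg.norm(step.reshape(-1, 3), axis=1)
    scale = np.minimum(1.0, cap / np.where(norms > 1e-12, norms, 1.0))
    step = (step.reshape(-1, 3) * scale[:, None]).reshape(x.shape)
    return x + step


def _metropolis_sweep(x, model, temperature, step_size, rng, e_current):
    n = x.shape[0]
    for _ in range(n):
        i = rng.integers(n)
        trial = x.copy()
        trial[i] += rng.normal(scale=step_size, size=3)
        e_trial = model.energy(trial)
        _check_finite(e_trial, "metropolis sweep")
        if e_trial <= e_current or rng.random() < math.exp(-(e_trial - e_current) / (KB * temperature)):
            x, e_current = trial, e_trial
    return x, e_current


def _temperature_schedule(t_max: float, t_base: float, n_steps: int, cooling: str) -> np.ndarray:
    if cooling == "linear":
        return np.linspace(t_max, t_base, n_steps)
    return t_max * (t_base / t_max) ** (np.arange(n_steps) / max(n_steps - 1, 1))


def _propagate(coords, model, temperatures, config, rng, record_stride=None):
    """Drive the configured integrator over a temperature sequence."""
    x = coords.copy()
    frames = []
    energies = []
    if config.integrator == "metropolis":
        e = model.energy(x)
        _check_finite(e, "metropolis start")
    for step, temp in enumerate(temperatures):
        if config.integrator == "langevin":
            x = _langevin_step(x, model, temp, config.timestep, config.friction,
                               config.max_step_length, rng)
        else:
            x, e = _metropolis_sweep(x, model, temp, config.max_step_length / 2.0, rng, e)
        if record_stride is not None and (step + 1) % record_stride == 0:
            frames.append(x.copy())
            energies.append(model.energy(x))
    _check_finite(model.energy(x), "block end")
    return x, frames, energies


def run_sa_block(start: Structure, model: EnergyModel, t_max: float,
                 config: ExcursionConfig, seed: int,
                 schedule: np.ndarray | None = None) -> Structure:
    """One simulated-annealing block: heat-free anneal from ``t_max`` down a
    monotone non-increasing schedule to the base temperature; returns the
    final configuration.  Deterministic given the seed."""
    if schedule is None:
        schedule = _temperature_schedule(t_max, config.base_temperature,
                                         config.sa_duration_steps, config.cooling)
    schedule = np.asarray(schedule, float)
    if np.any(np.diff(schedule) > 1e-9):
        raise ValueError("cooling schedule must be monotone non-increasing")
    rng = np.random.default_rng(seed)
    x, _, _ = _propagate(start.coords, model, schedule, config, rng)
    return start.with_coords(x)


def run_relaxation_block(start: Structure, model: EnergyModel,
                         config: ExcursionConfig, seed: int
                         ) -> tuple[list[Structure], list[float]]:
    """Constant-temperature relaxation trajectory; frames recorded every
    ``frame_stride`` steps (floor(duration/stride) frames)."""
    rng = np.random.default_rng(seed)
    temperatures = np.full(config.relax_duration_steps, config.base_temperature)
    _, frames, energies = _propagate(start.coords, model, temperatures, config,
                                     rng, record_stride=config.frame_stride)
    return [start.with_coords(c) for c in frames], energies


def select_representative(trajectory: Sequence[Structure], window: int,
                          model: EnergyModel,
                          minimizer_maxiter: int = 200,
                          chain_index: int = 0, block_index: int = 0,
                          seed: int = 0) -> RepresentativeRecord:
    """Pick the window frame closest to the window-mean structure and
    energy-minimize it.

    Each window frame is Kabsch-superposed onto the first window frame
    before the coordinate mean is taken; RMSD to the mean is all-atom and
    mass-unweighted; ties break to the earliest frame.  The selected frame
    is then minimized by conjugate gradients (the minimizer never returns a
    higher energy than its start).
    """
    if window < 1:
        raise ValueError("representative window must contain at least one frame")
    if window > len(trajectory):
        raise ValueError(f"window {window} exceeds trajectory length {len(trajectory)}")
    frames = trajectory[-window:]
    ref = frames[0].coords
    superposed = [ref] + [kabsch_superpose(f.coords, ref) for f in frames[1:]]
    mean = np.mean(superposed, axis=0)
    rmsds = [float(np.sqrt(np.mean(np.sum((c - mean) ** 2, axis=1)))) for c in superposed]
    # earliest frame within float noise of the minimum (tie-break rule)
    best = int(np.flatnonzero(np.asarray(rmsds) <= min(rmsds) + 1e-9)[0])
    selected = frames[best]

    x0 = selected.coords.ravel()
    e0 = model.energy(x0.reshape(-1, 3))

    def _fun(v):  # energy and gradient share most work; evaluate together
        xs = v.reshape(-1, 3)
        return model.energy(xs), model.gradient(xs).ravel()

    res = minimize(_fun, x0, jac=True, method="CG",
                   options={"maxiter": minimizer_maxiter})
    if res.fun <= e0:
        coords, e_min = res.x.reshape(-1, 3), float(res.fun)
    else:  # pathological line search; keep the unminimized frame
        coords, e_min = selected.coords, float(e0)
    frame_index = len(trajectory) - window + best
    return RepresentativeRecord(
        chain_index=chain_index, block_index=block_index,
        structure=selected.with_coords(coords, label=f"chain{chain_index}_block{block_index}"),
        rmsd_to_mean=rmsds[best], minimized_energy=e_min,
        frame_index=frame_index, seed=seed,
    )


def run_excursion_chain(start: Structure, model: EnergyModel,
                        config: ExcursionConfig, chain_index: int
                        ) -> list[RepresentativeRecord]:
    """One excursion chain: SA block then relaxation block, repeated
    ``blocks_per_chain`` times; block k+1 starts from block k's minimized
    representative."""
    chain_seed = derive_chain_seed(config.seed, chain_index)
    seed_rng = np.random.default_rng(chain_seed)
    block_seeds = seed_rng.integers(0, 2 ** 31, size=2 * config.blocks_per_chain)
    current = start
    records: list[RepresentativeRecord] = []
    for block in range(config.blocks_per_chain):
        annealed = run_sa_block(current, model, config.sa_max_temperatures[block],
                                config, int(block_seeds[2 * block]))
        frames, _ = run_relaxation_block(annealed, model, config,
                                         int(block_seeds[2 * block + 1]))
        window_frames = max(1, config.representative_window_steps // config.frame_stride)
        window_frames = min(window_frames, len(frames))
        record = select_representative(frames, window_frames, model,
                                       minimizer_maxiter=config.minimizer_maxiter,
                                       chain_index=chain_index, block_index=block,
                                       seed=chain_seed)
        records.append(record)
        current = record.structure
    return records


def build_library(model: EnergyModel, config: ExcursionConfig,
                  start: Structure,
                  progress: Callable[[int], None] | None = None
                  ) -> list[RepresentativeRecord]:
    """Run ``n_chains`` independent excursion chains from the same extended
    start; returns ``n_chains * blocks_per_chain`` representatives."""
    records: list[RepresentativeRecord] = []
    for chain in range(config.n_chains):
        records.extend(run_excursion_chain(start, model, config, chain))
        if progress is not None:
            progress(chain)
    return records


def manifest_text(records: Sequence[RepresentativeRecord]) -> str:
    """TSV manifest of a library; fixed float formatting so that identical
    runs produce byte-identical manifests."""
    lines = ["chain\tblock\tframe\trmsd_to_mean\tminimized_energy\tseed"]
    for r in records:
        lines.append(f"{r.chain_index}\t{r.block_index}\t{r.frame_index}\t"
                     f"{r.rmsd_to_mean:.6f}\t{r.minimized_energy:.6f}\t{r.seed}")
    return "\n".join(lines) + "\n"


def write_library(records: Sequence[RepresentativeRecord], outdir) -> Path:
    """Write one PDB per representative plus ``manifest.tsv``; returns the
    manifest path.  Files are named ``conformer_<chain>_<block>.pdb``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in records:
        write_pdb(r.structure, outdir / f"conformer_{r.chain_index:05d}_{r.block_index}.pdb")
    manifest = outdir / "manifest.tsv"
    manifest.write_text(manifest_text(records))
    return manifest
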