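"""Dynamic Monte Carlo engine: Metropolis single-monomer displacement moves.

One Monte Carlo step (MCS) is ``n_beads = N + 1`` trial moves, each
displacing a uniformly chosen bead by a uniform increment in
``[-max_displacement, +max_displacement]^3`` and accepting with probability
``min(1, exp(-dU))``.  Moves that would place a bead below the wall or
stretch a bond outside its FENE range carry infinite energy and are always
rejected.

A replica is one independent trajectory: a fresh bending-biased initial
conformation placed with its lowest bead at the wall-potential minimum,
an equilibration burn-in, then periodic sampling.  If the chain diffuses
away from the wall (lowest bead above ``escape_threshold``, checked at
interval boundaries) the replica restarts from scratch, as the adsorption
kinetics require a chain that starts within reach of the surface.

Reproducibility: each replica draws from its own ``SeedSequence([seed,
replica_id])`` stream; compiled-kernel blocks are seeded from that stream
in a fixed order, so a (seed, replica_id) pair maps to a bit-identical
trajectory.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np

from . import _kernel
from .model import (Conformation, ModelParams,
                    delta_energy, total_energy)

__all__ = [
    "RunSchedule",
    "ReplicaResult",
    "SampleSet",
    "accept_move",
    "initial_conformation",
    "metropolis_step",
    "run_mcs",
    "run_replica",
    "run_samples",
]

logger = logging.getLogger(__name__)

_MAX_SEED = 2 ** 31 - 1


@dataclasses.dataclass
class RunSchedule:
    """MCS budget and sampling plan for a set of replicas.

    Defaults are the reference production schedule: 100 replicas, 100
    samples per replica at intervals of 1e6 MCS, burn-in of ten sampling
    intervals.  Scaled-down profiles override these for tests and desk
    runs.
    """

    n_replicas: int = 100
    n_samples_per_replica: int = 100
    sampling_interval_mcs: int = 1_000_000
    equilibration_mcs: int | None = None  # None -> 10 * sampling_interval_mcs
    max_displacement: float = 0.15
    seed: int = 0
    escape_threshold: float = 5.0
    restart_limit: int = 20

    def __post_init__(self) -> None:
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.sampling_interval_mcs < 1:
            raise ValueError("sampling_interval_mcs must be >= 1")
        if self.max_displacement <= 0:
            raise ValueError("max_displacement must be > 0")
        if self.n_samples_per_replica < 1:
            raise ValueError("n_samples_per_replica must be >= 1")

    @property
    def burn_in_mcs(self) -> int:
        if self.equilibration_mcs is None:
            return 10 * self.sampling_interval_mcs
        return self.equilibration_mcs

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name)
                for f in dataclasses.fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunSchedule":
        return cls(**d)


def accept_move(du: float, rng: np.random.Generator) -> bool:
    """Metropolis acceptance: always for dU <= 0, else with prob exp(-dU)."""
    if du <= 0.0:
        return True
    if math.isinf(du):
        return False
    return rng.random() < math.exp(-du)


# ---------------------------------------------------------------------------
# initial placement
# ---------------------------------------------------------------------------

def _sample_cos_bend(b: float, rng: np.random.Generator) -> float:
    """Draw cos(phi) of a bond joint from p(c) ~ exp(b c) on [-1, 1]."""
    u = rng.random()
    if b < 1e-12:
        return 2.0 * u - 1.0
    if b > 350.0:  # exp(-2b) underflows; tail is exponential near c = 1
        return 1.0 + math.log(max(u, 1e-300)) / b
    emin = math.exp(-2.0 * b)
    return 1.0 + math.log(u * (1.0 - emin) + emin) / b


def _rotate_about(d: np.ndarray, cos_phi: float, psi: float) -> np.ndarray:
    """Unit vector at angle arccos(cos_phi) from unit vector d, azimuth psi."""
    # orthonormal frame around d
    if abs(d[0]) < 0.9:
        a = np.array([1.0, 0.0, 0.0])
    else:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    sin_phi = math.sqrt(max(0.0, 1.0 - cos_phi * cos_phi))
    return cos_phi * d + sin_phi * (math.cos(psi) * e1 + math.sin(psi) * e2)


def initial_conformation(params: ModelParams, rng: np.random.Generator,
                         restart_limit: int = 100,
                         per_bead_attempts: int = 200) -> Conformation:
    """Grow a self-avoiding chain with bending-biased joints at stiffness
    ``b``, bonds at the preferred length, then translate it rigidly so the
    lowest bead sits at the wall-potential minimum ``r_min_s``.

    Self-avoidance: all non-bonded pair distances >= 0.9 * r_min_ev.
    """
    n = params.n_beads
    min_sep = 0.9 * params.r_min_ev
    for _ in range(restart_limit):
        pos = np.empty((n, 3))
        pos[0] = 0.0
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pos[1] = pos[0] + params.l0 * d
        grown = True
        for i in range(2, n):
            placed = False
            for _ in range(per_bead_attempts):
                c = _sample_cos_bend(params.b, rng)
                new_d = _rotate_about(d, c, 2.0 * math.pi * rng.random())
                cand = pos[i - 1] + params.l0 * new_d
                dist = np.linalg.norm(pos[: i - 1] - cand, axis=1)
                if np.all(dist >= min_sep):
                    placed = True
                    break
            if not placed:
                grown = False
                break
            d = new_d
            pos[i] = cand
        if grown:
            pos[:, 2] -= pos[:, 2].min()
            pos[:, 2] += params.r_min_s
            if math.isfinite(params.z_max) and pos[:, 2].max() > params.z_max:
                continue  # too tall for the slit; redraw
            return Conformation(pos, copy=False)
    raise RuntimeError(
        f"failed to grow a self-avoiding initial chain in {restart_limit} "
        f"attempts (n_bonds={params.n_bonds}, b={params.b})")


# ---------------------------------------------------------------------------
# single-step reference path and the compiled bulk path
# ---------------------------------------------------------------------------

def metropolis_step(conf: Conformation, params: ModelParams,
                    rng: np.random.Generator,
                    max_displacement: float = 0.15):
    """One trial move on a uniformly chosen bead (pure-python reference
    path).  Returns ``(conf, accepted, du)``; rejected moves leave ``conf``
    unchanged and report the (possibly infinite) dU of the rejected trial."""
    j = int(rng.integers(0, conf.n_beads))
    disp = (2.0 * rng.random(3) - 1.0) * max_displacement
    new_pos = conf.positions[j] + disp
    du = delta_energy(conf, j, new_pos, params)
    if accept_move(du, rng):
        conf.positions[j] = new_pos
        return conf, True, du
    return conf, False, du


def _run_block(conf: Conformation, params: ModelParams, n_trials: int,
               kernel_seed: int, max_displacement: float):
    n_acc, du_sum = _kernel.run_trials(
        conf.positions, n_trials, max_displacement,
        params.l_min, params.l_max, params.l0, params.k_spring, params.r0,
        params.alpha, params.r_min_ev, params.eps_ev, params.b,
        params.eps_a, params.alpha_s, params.r_min_s,
        params.pair_cutoff, params.z_max, kernel_seed)
    return int(n_acc), float(du_sum)


def run_mcs(conf: Conformation, params: ModelParams, n_mcs: int,
            rng: np.random.Generator, max_displacement: float = 0.15):
    """Advance ``conf`` in place by ``n_mcs`` Monte Carlo steps (each
    ``n_beads`` trial moves) using the compiled kernel.  Returns
    ``(conf, acceptance_rate)``."""
    if n_mcs < 0:
        raise ValueError("n_mcs must be >= 0")
    if n_mcs == 0:
        return conf, 0.0
    n_trials = n_mcs * conf.n_beads
    seed = int(rng.integers(1, _MAX_SEED))
    n_acc, _ = _run_block(conf, params, n_trials, seed, max_displacement)
    return conf, n_acc / n_trials


# ---------------------------------------------------------------------------
# replicas and sample collection
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ReplicaResult:
    """Samples and diagnostics from one independent trajectory."""

    replica_id: int
    positions: np.ndarray          # (n_samples, n_beads, 3)
    energies: np.ndarray           # (n_samples, 4): fene, morse, bend, surf
    mcs_index: np.ndarray          # (n_samples,) MCS count at each sample
    restarts: int
    failed: bool
    acceptance_rate: float
    max_energy_drift: float        # worst |accumulated - recomputed| / scale

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]


def _equilibrate(conf: Conformation, params: ModelParams,
                 schedule: RunSchedule, rng: np.random.Generator):
    """Burn-in in segments; warn if the last two block means of the wall
    energy still differ by more than one standard error (slow relaxation).
    Returns (escaped, trials, accepted)."""
    burn = schedule.burn_in_mcs
    if burn == 0:
        return False, 0, 0
    n_seg = min(10, burn)
    seg = [burn // n_seg] * n_seg
    seg[-1] += burn - sum(seg)
    us_series = []
    trials = acc = 0
    for s in seg:
        n_trials = s * conf.n_beads
        seed = int(rng.integers(1, _MAX_SEED))
        n_acc, _ = _run_block(conf, params, n_trials, seed,
                              schedule.max_displacement)
        trials += n_trials
        acc += n_acc
        us_series.append(total_energy(conf, params).u_surf)
        if float(conf.z.min()) > schedule.escape_threshold:
            return True, trials, acc
    if len(us_series) >= 6:
        tail = np.asarray(us_series[-6:], dtype=float)
        blk_a, blk_b = tail[:3], tail[3:]
        se = float(np.std(tail, ddof=1)) / math.sqrt(3.0)
        # the 0.5 kT floor keeps the check quiet for near-zero wall energies
        if se > 0 and abs(blk_a.mean() - blk_b.mean()) > max(se, 0.5):
            logger.warning(
                "equilibration check: wall-energy block means differ by more "
                "than 1 SE (%.3g vs %.3g); consider a longer burn-in",
                blk_a.mean(), blk_b.mean())
    return False, trials, acc


def run_replica(params: ModelParams, schedule: RunSchedule,
                replica_id: int) -> ReplicaResult:
    """Run one replica: grow, equilibrate, sample every
    ``sampling_interval_mcs``; restart from scratch whenever the chain has
    escaped (lowest bead above ``escape_threshold`` at a boundary check).
    A replica that exceeds ``restart_limit`` restarts is marked failed and
    returned with the samples it had collected (possibly none)."""
    rng = np.random.default_rng(np.random.SeedSequence([schedule.seed,
                                                        replica_id]))
    n_beads = params.n_beads
    restarts = 0
    failed = False
    positions = []
    energies = []
    mcs_idx = []
    trials_tot = acc_tot = 0
    max_drift = 0.0

    while True:
        conf = initial_conformation(params, rng,
                                    restart_limit=schedule.restart_limit)
        escaped, t, a = _equilibrate(conf, params, schedule, rng)
        trials_tot += t
        acc_tot += a
        if not escaped:
            u_run = total_energy(conf, params).u_total
            positions.clear()
            energies.clear()
            mcs_idx.clear()
            mcs = schedule.burn_in_mcs
            for _ in range(schedule.n_samples_per_replica):
                n_trials = schedule.sampling_interval_mcs * n_beads
                seed = int(rng.integers(1, _MAX_SEED))
                n_acc, du = _run_block(conf, params, n_trials, seed,
                                       schedule.max_displacement)
                trials_tot += n_trials
                acc_tot += n_acc
                mcs += schedule.sampling_interval_mcs
                if float(conf.z.min()) > schedule.escape_threshold:
                    escaped = True
                    break
                u_run += du
                eb = total_energy(conf, params)
                drift = abs(u_run - eb.u_total) / max(1.0, abs(eb.u_total))
                max_drift = max(max_drift, drift)
                u_run = eb.u_total  # re-sync to kill accumulation error
                positions.append(conf.positions.copy())
                energies.append([eb.u_fene, eb.u_morse, eb.u_bend, eb.u_surf])
                mcs_idx.append(mcs)
            if not escaped:
                break
        restarts += 1
        if restarts > schedule.restart_limit:
            failed = True
            logger.warning("replica %d exceeded restart_limit=%d; marked "
                           "failed", replica_id, schedule.restart_limit)
            break

    pos_arr = (np.asarray(positions)
               if positions else np.empty((0, n_beads, 3)))
    en_arr = (np.asarray(energies) if energies else np.empty((0, 4)))
    return ReplicaResult(
        replica_id=replica_id,
        positions=pos_arr,
        energies=en_arr,
        mcs_index=np.asarray(mcs_idx, dtype=np.int64),
        restarts=restarts,
        failed=failed,
        acceptance_rate=acc_tot / trials_tot if trials_tot else 0.0,
        max_energy_drift=max_drift,
    )


@dataclasses.dataclass
class SampleSet:
    """Pooled samples from all replicas at one (b, eps_a) state point."""

    params: ModelParams
    schedule: RunSchedule
    positions: np.ndarray      # (n_samples_total, n_beads, 3)
    energies: np.ndarray       # (n_samples_total, 4)
    mcs_index: np.ndarray      # (n_samples_total,)
    replica_id: np.ndarray     # (n_samples_total,)
    restarts: list             # per replica
    failed_replicas: list      # replica ids marked failed

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def u_surf(self) -> np.ndarray:
        """Total wall attraction energy U_s of each sample."""
        return self.energies[:, 3]

    def conformations(self):
        return [Conformation(p, copy=False) for p in self.positions]

    def final_conformations(self):
        """Last stored sample of each non-empty replica."""
        out = []
        for rid in np.unique(self.replica_id):
            idx = np.flatnonzero(self.replica_id == rid)
            out.append(Conformation(self.positions[idx[-1]], copy=False))
        return out

    @classmethod
    def from_replicas(cls, params: ModelParams, schedule: RunSchedule,
                      replicas: Sequence[ReplicaResult]) -> "SampleSet":
        non_empty = [r for r in replicas if r.n_samples]
        if non_empty:
            pos = np.concatenate([r.positions for r in non_empty])
            en = np.concatenate([r.energies for r in non_empty])
            mcs = np.concatenate([r.mcs_index for r in non_empty])
            rid = np.concatenate([
                np.full(r.n_samples, r.replica_id, dtype=np.int64)
                for r in non_empty])
        else:
            pos = np.empty((0, params.n_beads, 3))
            en = np.empty((0, 4))
            mcs = np.empty(0, dtype=np.int64)
            rid = np.empty(0, dtype=np.int64)
        return cls(params=params, schedule=schedule, positions=pos,
                   energies=en, mcs_index=mcs, replica_id=rid,
                   restarts=[r.restarts for r in replicas],
                   failed_replicas=[r.replica_id for r in replicas
                                    if r.failed])


def run_samples(params: ModelParams, schedule: RunSchedule,
                progress: bool = False) -> SampleSet:
    """Run every replica of ``schedule`` sequentially and pool the samples."""
    iterator = range(schedule.n_replicas)
    if progress:  # pragma: no cover - cosmetic
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="replicas")
        except ImportError:
            pass
    replicas = [run_replica(params, schedule, rid) for rid in iterator]
    return SampleSet.from_replicas(params, schedule, replicas)
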