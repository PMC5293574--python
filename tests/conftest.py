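"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own computational paths:
total energies are re-derived with plain double loops, Boltzmann marginals
with numeric quadrature, and turn counts with a winding-angle integral, so
agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate

from polyadsorb import Conformation, ModelParams
from polyadsorb.engine import _run_block


@pytest.fixture
def rng():
    return np.random.default_rng(20160220)


@pytest.fixture
def free_params():
    """Small chain, no stiffness, no wall attraction."""
    return ModelParams(n_bonds=8, b=0.0, eps_a=0.0)


def perturbed_conformation(params: ModelParams, rng: np.random.Generator,
                           scale: float = 0.04) -> Conformation:
    """A random wiggly chain with bonds safely inside the FENE range."""
    from polyadsorb.engine import initial_conformation
    conf = initial_conformation(params, rng)
    conf.positions += scale * rng.standard_normal(conf.positions.shape)
    conf.positions[:, 2] = np.abs(conf.positions[:, 2]) + 0.05
    # re-centre so the chain stays a valid wall configuration
    conf.positions[:, 2] += max(0.0, -conf.positions[:, 2].min())
    return conf


# ---------------------------------------------------------------------------
# oracle: brute-force energy (independent of model.total_energy's vector path)
# ---------------------------------------------------------------------------

def oracle_total_energy(conf: Conformation, params: ModelParams,
                        pair_cutoff: float | None = None) -> float:
    """Double-loop sum of all four energy terms, scalar math only."""
    if pair_cutoff is None:
        pair_cutoff = params.pair_cutoff
    pos = conf.positions
    n = len(pos)
    e = 0.0
    k2 = 0.5 * params.k_spring * params.r0 ** 2
    for i in range(n - 1):
        l = math.dist(pos[i], pos[i + 1])
        x = (l - params.l0) / params.r0
        if abs(x) >= 1:
            return math.inf
        e += -k2 * math.log(1 - x * x)
    for i in range(1, n - 1):
        u = pos[i] - pos[i - 1]
        v = pos[i + 1] - pos[i]
        e += params.b * (1 - float(u @ v) /
                         (np.linalg.norm(u) * np.linalg.norm(v)))
    for i in range(n):
        for j in range(i + 2, n):
            r = math.dist(pos[i], pos[j])
            if r <= pair_cutoff:
                ex = math.exp(-params.alpha * (r - params.r_min_ev))
                e += params.eps_ev * (ex * ex - 2 * ex)
        ez = math.exp(-params.alpha_s * (pos[i, 2] - params.r_min_s))
        e += params.eps_a * (ez * ez - 2 * ez)
    return e


# ---------------------------------------------------------------------------
# oracle: winding angle turn count (independent of the spectral classifier)
# ---------------------------------------------------------------------------

def oracle_winding_turns(conf: Conformation) -> float:
    """Total signed in-plane turning of the bond direction, in turns."""
    u = np.diff(conf.positions[:, :2], axis=0)
    ang = np.arctan2(u[:, 1], u[:, 0])
    d = np.diff(ang)
    d = (d + np.pi) % (2 * np.pi) - np.pi
    return abs(float(d.sum())) / (2 * np.pi)


# ---------------------------------------------------------------------------
# oracle: Metropolis sampling of tiny systems + quadrature marginals
# ---------------------------------------------------------------------------

def sample_chain_series(params: ModelParams, start: np.ndarray,
                        n_samples: int, spacing_mcs: int, seed: int,
                        extract, burn_in_mcs: int = 5000) -> np.ndarray:
    """Drive the compiled engine on a tiny chain and record ``extract(conf)``
    every ``spacing_mcs`` steps."""
    conf = Conformation(start.copy())
    rng = np.random.default_rng(seed)
    nb = conf.n_beads
    _run_block(conf, params, burn_in_mcs * nb,
               int(rng.integers(1, 2 ** 31 - 1)), 0.15)
    out = []
    for _ in range(n_samples):
        _run_block(conf, params, spacing_mcs * nb,
                   int(rng.integers(1, 2 ** 31 - 1)), 0.15)
        out.append(extract(conf))
    return np.asarray(out)


def fene_bond_weight(l: np.ndarray, params: ModelParams) -> np.ndarray:
    """Unnormalised Boltzmann density of a free FENE bond length
    (includes the l^2 Jacobian of the 3D bond vector)."""
    x = (l - params.l0) / params.r0
    return l ** 2 * np.clip(1 - x * x, 0, None) ** (
        0.5 * params.k_spring * params.r0 ** 2)


def quadrature_cdf(grid: np.ndarray, density: np.ndarray):
    """Normalised CDF on ``grid`` as an interpolating callable."""
    cdf = integrate.cumulative_trapezoid(density, grid, initial=0.0)
    cdf /= cdf[-1]
    return lambda x: np.interp(x, grid, cdf)
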