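"""Compiled Metropolis inner loop.

A single njit kernel performs a block of single-monomer trial moves in
place, computing the energy change dU of each trial in one pass over the
affected terms (the <= 2 bonds, <= 3 interior angles, the wall term and
the non-bonded pair terms of the moved bead).  Energies mirror
:mod:`polyadsorb.model` term by term (same pair cutoff convention, no tail
cutoff on the wall term) so that the running energy accumulated from
accepted-move increments can be checked against a full recomputation.

RNG: the kernel seeds numba's internal Mersenne Twister once per call and
draws, per trial, in this fixed order: bead index, dx, dy, dz, and (only
when 0 < dU < inf) the acceptance uniform.  Callers derive per-block seeds
from a reproducible stream, so trajectories are bit-identical for a fixed
top-level seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["run_trials"]


@njit(cache=False, inline="always")
def _cos_between(pos, i, j, px, py, pz):
    """cos(angle) between bond vectors (i-1 -> i) and (i -> i+1), with
    bead j taken at (px, py, pz)."""
    if i - 1 == j:
        x0, y0, z0 = px, py, pz
    else:
        x0, y0, z0 = pos[i - 1, 0], pos[i - 1, 1], pos[i - 1, 2]
    if i == j:
        x1, y1, z1 = px, py, pz
    else:
        x1, y1, z1 = pos[i, 0], pos[i, 1], pos[i, 2]
    if i + 1 == j:
        x2, y2, z2 = px, py, pz
    else:
        x2, y2, z2 = pos[i + 1, 0], pos[i + 1, 1], pos[i + 1, 2]
    ux, uy, uz = x1 - x0, y1 - y0, z1 - z0
    vx, vy, vz = x2 - x1, y2 - y1, z2 - z1
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    nv = math.sqrt(vx * vx + vy * vy + vz * vz)
    return (ux * vx + uy * vy + uz * vz) / (nu * nv)


@njit(cache=False)
def run_trials(pos, n_trials, max_disp, l_min, l_max, l0, k_spring, r0,
               alpha, r_min_ev, eps_ev, b, eps_a, alpha_s, r_min_s,
               cutoff, z_max, seed):
    """Run ``n_trials`` Metropolis single-monomer moves in place.

    Returns ``(n_accepted, du_sum)`` where ``du_sum`` is the sum of the
    energy changes of all accepted moves.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    half_k_r02 = 0.5 * k_spring * r0 * r0
    cut2 = cutoff * cutoff
    n_acc = 0
    du_sum = 0.0
    for _ in range(n_trials):
        j = np.random.randint(0, n)
        ddx = (2.0 * np.random.random() - 1.0) * max_disp
        ddy = (2.0 * np.random.random() - 1.0) * max_disp
        ddz = (2.0 * np.random.random() - 1.0) * max_disp
        ox, oy, oz = pos[j, 0], pos[j, 1], pos[j, 2]
        px, py, pz = ox + ddx, oy + ddy, oz + ddz
        if pz < 0.0 or pz > z_max:
            continue

        du = 0.0
        reject = False
        # bonds (j-1, j) and (j, j+1): FENE difference
        for k in range(j - 1, j + 1):
            if 0 <= k <= n - 2:
                other = k if k != j else k + 1
                bx = pos[other, 0]
                by = pos[other, 1]
                bz = pos[other, 2]
                dxn, dyn, dzn = bx - px, by - py, bz - pz
                l_new = math.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
                if l_new <= l_min or l_new >= l_max:
                    reject = True
                    break
                xn = (l_new - l0) / r0
                dxo, dyo, dzo = bx - ox, by - oy, bz - oz
                l_old = math.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
                xo = (l_old - l0) / r0
                du += -half_k_r02 * (math.log(1.0 - xn * xn)
                                     - math.log(1.0 - xo * xo))
        if reject:
            continue
        # interior angles centred at j-1, j, j+1: bending difference
        if b != 0.0:
            for i in range(j - 1, j + 2):
                if 1 <= i <= n - 2:
                    c_new = _cos_between(pos, i, j, px, py, pz)
                    c_old = _cos_between(pos, i, j, ox, oy, oz)
                    du += b * (c_old - c_new)
        # non-bonded pairs of the moved bead: Morse difference (two ranges
        # so the excluded k in {j-1, j, j+1} costs no branch per iteration)
        for rng_lo, rng_hi in ((0, j - 1), (j + 2, n)):
            for k in range(rng_lo, rng_hi):
                bx = pos[k, 0]
                by = pos[k, 1]
                bz = pos[k, 2]
                dxn, dyn, dzn = bx - px, by - py, bz - pz
                r2n = dxn * dxn + dyn * dyn + dzn * dzn
                dxo, dyo, dzo = bx - ox, by - oy, bz - oz
                r2o = dxo * dxo + dyo * dyo + dzo * dzo
                if r2n <= cut2:
                    rn = math.sqrt(r2n)
                    ex = math.exp(-alpha * (rn - r_min_ev))
                    du += eps_ev * (ex * ex - 2.0 * ex)
                if r2o <= cut2:
                    ro = math.sqrt(r2o)
                    ex = math.exp(-alpha * (ro - r_min_ev))
                    du -= eps_ev * (ex * ex - 2.0 * ex)
        # wall term
        if eps_a != 0.0:
            en = math.exp(-alpha_s * (pz - r_min_s))
            eo = math.exp(-alpha_s * (oz - r_min_s))
            du += eps_a * ((en * en - 2.0 * en) - (eo * eo - 2.0 * eo))

        if du <= 0.0 or np.random.random() < math.exp(-du):
            pos[j, 0] = px
            pos[j, 1] = py
            pos[j, 2] = pz
            n_acc += 1
            du_sum += du
    return n_acc, du_sum
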