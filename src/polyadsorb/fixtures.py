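"""Deterministic reference conformations for observable tests and demos.

All generators produce exact analytic geometry with every bond length
exactly equal to ``bond_length``: a collinear rod, a regular-polygon
circle, a flat archimedean spiral of a given number of turns (the
idealised film-like toroid), a helix, and a seeded self-avoiding random
coil.  Generation is a pure function of the spec: the same FixtureSpec
always yields the same geometry.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .model import Conformation

__all__ = ["FixtureSpec", "make_fixture", "FixtureError"]

_KINDS = ("rod", "circle", "toroid_spiral", "helix", "coil")


class FixtureError(ValueError):
    """Requested fixture geometry is infeasible; message names the
    violated constraint."""


@dataclasses.dataclass(frozen=True)
class FixtureSpec:
    kind: str
    n_bonds: int
    bond_length: float = 0.7
    turns: int = 1              # toroid_spiral / helix
    height: float = 0.8         # placement of the lowest bead above the wall
    gap: float = 0.9            # toroid_spiral: spacing between loops
    pitch: float = 0.9          # helix: rise per turn
    seed: int = 0               # coil only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise FixtureError(f"unknown fixture kind {self.kind!r}; "
                               f"choose from {_KINDS}")
        if self.n_bonds < 1:
            raise FixtureError("n_bonds must be >= 1")
        if not 0.4 < self.bond_length < 1.0:
            raise FixtureError("bond_length must lie inside the FENE range "
                               "(0.4, 1.0)")
        if self.height < 0:
            raise FixtureError("height must be >= 0")


def make_fixture(spec: FixtureSpec) -> Conformation:
    builder = {
        "rod": _rod,
        "circle": _circle,
        "toroid_spiral": _toroid_spiral,
        "helix": _helix,
        "coil": _coil,
    }[spec.kind]
    return builder(spec)


def _rod(spec: FixtureSpec) -> Conformation:
    n = spec.n_bonds + 1
    pos = np.zeros((n, 3))
    pos[:, 0] = spec.bond_length * np.arange(n)
    pos[:, 2] = spec.height
    return Conformation(pos, copy=False)


def _circle(spec: FixtureSpec) -> Conformation:
    """Closed regular polygon traversed once; the first and last bead
    coincide in x, y up to the unclosed final bond (the chain is open, so
    the polygon has n_bonds sides and n_bonds + 1 beads, the last lying on
    top of the first vertex position)."""
    nb = spec.n_bonds
    if nb < 3:
        raise FixtureError("circle needs n_bonds >= 3")
    radius = spec.bond_length / (2.0 * math.sin(math.pi / nb))
    ang = 2.0 * math.pi * np.arange(nb + 1) / nb
    pos = np.empty((nb + 1, 3))
    pos[:, 0] = radius * np.cos(ang)
    pos[:, 1] = radius * np.sin(ang)
    pos[:, 2] = spec.height
    return Conformation(pos, copy=False)


def _toroid_spiral(spec: FixtureSpec) -> Conformation:
    """Flat archimedean spiral of ``turns`` loops at constant height: the
    idealised film-like toroid.  The inner radius is chosen so the total
    arc length carries n_bonds bonds over exactly ``turns`` windings; beads
    are stepped along the curve with exact chord length bond_length."""
    t = spec.turns
    if t < 1:
        raise FixtureError("toroid_spiral needs turns >= 1")
    if spec.gap < 0.8:
        raise FixtureError("toroid_spiral inter-loop gap must be >= 0.8 "
                           "(excluded-volume contact distance)")
    length = spec.n_bonds * spec.bond_length
    theta_tot = 2.0 * math.pi * t
    # arc length of r(theta) = r_in + gap * theta / (2 pi) over theta_tot,
    # ignoring the (tiny) r'^2 term: L = r_in * theta_tot + pi * t^2 * gap
    r_in = (length - math.pi * t * t * spec.gap) / theta_tot
    if r_in < spec.gap / 2.0:
        raise FixtureError(
            f"toroid_spiral infeasible: {t} turns of gap {spec.gap} need "
            f"more contour than n_bonds={spec.n_bonds} bonds provide "
            f"(inner radius would be {r_in:.3f})")
    k = spec.gap / (2.0 * math.pi)

    def point(theta: float) -> np.ndarray:
        r = r_in + k * theta
        return np.array([r * math.cos(theta), r * math.sin(theta)])

    pos = np.empty((spec.n_bonds + 1, 3))
    pos[:, 2] = spec.height
    theta = 0.0
    pos[0, :2] = point(theta)
    for i in range(1, spec.n_bonds + 1):
        # solve |point(theta') - point(theta)| = bond_length by bisection
        p0 = point(theta)
        lo = theta
        hi = theta + 2.0 * spec.bond_length / max(r_in + k * theta, 1e-9)
        while np.linalg.norm(point(hi) - p0) < spec.bond_length:
            hi += 0.1
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if np.linalg.norm(point(mid) - p0) < spec.bond_length:
                lo = mid
            else:
                hi = mid
        theta = 0.5 * (lo + hi)
        pos[i, :2] = point(theta)
    return Conformation(pos, copy=False)


def _helix(spec: FixtureSpec) -> Conformation:
    t = spec.turns
    if t < 1:
        raise FixtureError("helix needs turns >= 1")
    dtheta = 2.0 * math.pi * t / spec.n_bonds
    dz = spec.pitch * dtheta / (2.0 * math.pi)
    chord_xy_sq = spec.bond_length ** 2 - dz ** 2
    if chord_xy_sq <= 0:
        raise FixtureError("helix pitch too steep for the bond length")
    radius = math.sqrt(chord_xy_sq) / (2.0 * math.sin(dtheta / 2.0))
    idx = np.arange(spec.n_bonds + 1)
    pos = np.empty((spec.n_bonds + 1, 3))
    pos[:, 0] = radius * np.cos(dtheta * idx)
    pos[:, 1] = radius * np.sin(dtheta * idx)
    pos[:, 2] = spec.height + dz * idx
    return Conformation(pos, copy=False)


def _coil(spec: FixtureSpec) -> Conformation:
    """Seeded self-avoiding random walk (uniform joint angles) translated
    so its lowest bead sits at ``height``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_bonds + 1
    min_sep = 0.72  # 0.9 * excluded-volume contact distance
    for _ in range(200):
        pos = np.zeros((n, 3))
        d = rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pos[1] = pos[0] + spec.bond_length * d
        ok = True
        for i in range(2, n):
            placed = False
            for _ in range(200):
                d = rng.standard_normal(3)
                d /= np.linalg.norm(d)
                cand = pos[i - 1] + spec.bond_length * d
                if np.all(np.linalg.norm(pos[: i - 1] - cand, axis=1)
                          >= min_sep):
                    placed = True
                    break
            if not placed:
                ok = False
                break
            pos[i] = cand
        if ok:
            pos[:, 2] -= pos[:, 2].min()
            pos[:, 2] += spec.height
            return Conformation(pos, copy=False)
    raise FixtureError("coil: failed to grow a self-avoiding walk")
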