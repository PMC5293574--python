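"""Energy model of a semiflexible bead--spring chain near an attractive planar wall.

The polymer is a chain of ``n_bonds + 1`` spherical beads joined by finitely
extensible nonlinear elastic (FENE) bonds.  Non-bonded bead pairs repel/attract
through a Morse potential (steep core, shallow minimum of depth ``eps_ev`` at
``r_min_ev``), consecutive bonds pay a bending penalty ``b * (1 - cos phi)``
where ``phi`` is the angle between successive bond vectors (zero when the chain
is locally straight), and every bead interacts with the wall at ``z = 0``
through a Morse potential of depth ``eps_a`` with its minimum at ``r_min_s``.

Units: all energies are in units of k_B T (temperature absorbed), all lengths
in units of the maximum bond extension ``l_max``.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "ModelParams",
    "Conformation",
    "EnergyBreakdown",
    "InvalidConformationError",
    "fene_energy",
    "morse_pair_energy",
    "bending_energy",
    "surface_energy",
    "total_energy",
    "delta_energy",
]

#: Sentinel for a forbidden state (bond outside its FENE range, bead below the
#: wall).  Trial moves producing it must be rejected by the caller.
INFINITE_ENERGY = math.inf


class InvalidConformationError(ValueError):
    """A conformation violates a hard constraint of the model."""


@dataclasses.dataclass
class ModelParams:
    """Physical constants of the chain + wall energy model.

    Defaults are the reference parameter set: FENE bonds confined to
    (0.4, 1.0) with preferred length 0.7 and spring constant 20 k_B T,
    Morse excluded volume with steepness 24, minimum at 0.8 and depth
    1 k_B T, and a wall Morse potential with the same steepness and
    minimum position.  ``b`` (bending energy) and ``eps_a`` (wall
    attraction depth) are the two control parameters and have no
    privileged default.
    """

    n_bonds: int = 300
    b: float = 0.0
    eps_a: float = 0.0
    l_min: float = 0.4
    l_max: float = 1.0
    l0: float = 0.7
    k_spring: float = 20.0
    alpha: float = 24.0
    r_min_ev: float = 0.8
    eps_ev: float = 1.0
    alpha_s: float = 24.0
    r_min_s: float = 0.8
    #: Non-bonded Morse interactions are treated as exactly zero beyond this
    #: separation (the potential is negligible there for alpha = 24).
    pair_cutoff: float = 1.0
    #: Optional reflecting ceiling: trial positions with z > z_max are
    #: rejected.  +inf (default) means the half-space z >= 0 is unbounded
    #: above; a finite value confines the chain to a slit, which gives the
    #: wall-bound chain a normalizable equilibrium distribution.
    z_max: float = math.inf

    def __post_init__(self) -> None:
        self.validate()

    @property
    def r0(self) -> float:
        """FENE range: ``l_max - l0`` (equal to ``l0 - l_min``)."""
        return self.l_max - self.l0

    @property
    def n_beads(self) -> int:
        return self.n_bonds + 1

    def validate(self) -> None:
        if self.n_bonds < 1:
            raise ValueError("n_bonds must be >= 1")
        if not (self.l_min < self.l0 < self.l_max):
            raise ValueError("require l_min < l0 < l_max")
        if not math.isclose(self.l_max - self.l0, self.l0 - self.l_min,
                            rel_tol=0, abs_tol=1e-12):
            raise ValueError(
                "FENE range must be symmetric: l_max - l0 == l0 - l_min")
        for name in ("k_spring", "alpha", "eps_ev", "alpha_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.b < 0:
            raise ValueError("b must be >= 0")
        if self.eps_a < 0:
            raise ValueError("eps_a must be >= 0")
        if self.pair_cutoff <= self.r_min_ev:
            raise ValueError("pair_cutoff must exceed r_min_ev")
        if self.z_max <= self.r_min_s:
            raise ValueError("z_max must exceed r_min_s")

    # -- serialization (flat mapping, exactly these field names) -------------

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d["r0"] = self.r0
        if math.isinf(d["z_max"]):
            d["z_max"] = "inf"
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        r0 = d.pop("r0", None)
        if isinstance(d.get("z_max"), str):
            d["z_max"] = float(d["z_max"])
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - field_names
        if unknown:
            raise ValueError(f"unknown ModelParams fields: {sorted(unknown)}")
        params = cls(**d)
        if r0 is not None and not math.isclose(r0, params.r0, abs_tol=1e-12):
            raise ValueError("inconsistent r0 in parameter mapping")
        return params


class Conformation:
    """Ordered 3D bead positions of one chain state.

    Positions are an ``(n_beads, 3)`` float64 array; the wall lies at z = 0
    and every bead must satisfy z >= 0.  Bond lengths must lie strictly
    inside the FENE range of the governing :class:`ModelParams`.
    """

    __slots__ = ("positions",)

    def __init__(self, positions: np.ndarray, copy: bool = True):
        pos = np.array(positions, dtype=np.float64, copy=copy)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 2:
            raise ValueError("positions must have shape (n_beads >= 2, 3)")
        self.positions = pos

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.positions.shape[0] - 1

    @property
    def z(self) -> np.ndarray:
        """Bead heights above the wall (the D_i of the height analyses)."""
        return self.positions[:, 2]

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def copy(self) -> "Conformation":
        return Conformation(self.positions, copy=True)

    def validate(self, params: ModelParams) -> None:
        """Raise :class:`InvalidConformationError` on any hard violation."""
        if self.n_bonds != params.n_bonds:
            raise InvalidConformationError(
                f"chain has {self.n_bonds} bonds, params expect {params.n_bonds}")
        lengths = self.bond_lengths()
        bad = np.flatnonzero((lengths <= params.l_min) | (lengths >= params.l_max))
        if bad.size:
            raise InvalidConformationError(
                f"bond {bad[0]} has length {lengths[bad[0]]:.6f} outside "
                f"({params.l_min}, {params.l_max})")
        if np.any(self.z < 0):
            i = int(np.argmin(self.z))
            raise InvalidConformationError(
                f"bead {i} below the wall (z = {self.z[i]:.6f})")
        if np.any(self.z > params.z_max):
            i = int(np.argmax(self.z))
            raise InvalidConformationError(
                f"bead {i} above the ceiling (z = {self.z[i]:.6f})")


@dataclasses.dataclass(frozen=True)
class EnergyBreakdown:
    """Total energy split into its four physical contributions (k_B T)."""

    u_fene: float
    u_morse: float
    u_bend: float
    u_surf: float

    @property
    def u_total(self) -> float:
        return self.u_fene + self.u_morse + self.u_bend + self.u_surf


# ---------------------------------------------------------------------------
# elementary potentials (vectorized over numpy arrays)
# ---------------------------------------------------------------------------

def fene_energy(l, params: ModelParams):
    """FENE bond energy at length ``l``.

    ``-(k r0^2 / 2) ln(1 - ((l - l0)/r0)^2)``; zero at the preferred length
    and divergent at the range limits.  Outside (l_min, l_max) the infinite-
    energy sentinel is returned (never a finite number).
    """
    l_arr = np.asarray(l, dtype=np.float64)
    x = (l_arr - params.l0) / params.r0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            (l_arr > params.l_min) & (l_arr < params.l_max),
            -0.5 * params.k_spring * params.r0 ** 2 * np.log(
                np.clip(1.0 - x * x, 1e-300, None)),
            INFINITE_ENERGY,
        )
    return float(out) if np.isscalar(l) else out


def morse_pair_energy(r, params: ModelParams, cutoff: float | None = None):
    """Morse excluded-volume energy between two non-bonded beads.

    Minimum ``-eps_ev`` at ``r = r_min_ev``; treated as exactly zero for
    ``r > cutoff`` (default ``params.pair_cutoff``).  Pass ``cutoff=inf``
    to evaluate the bare potential.
    """
    if cutoff is None:
        cutoff = params.pair_cutoff
    r_arr = np.asarray(r, dtype=np.float64)
    e = np.exp(-params.alpha * (r_arr - params.r_min_ev))
    out = params.eps_ev * (e * e - 2.0 * e)
    out = np.where(r_arr > cutoff, 0.0, out)
    return float(out) if np.isscalar(r) else out


def bending_energy(theta, params: ModelParams):
    """Bending energy ``b (1 + cos theta)`` for interior bond angle ``theta``.

    ``theta`` is the interior angle at a bead (straight chain: theta = pi,
    energy 0; complete fold-back: theta = 0, energy 2b).  Equivalently
    ``b (1 - cos phi)`` with ``phi`` the angle between successive bond
    vectors, which is the form used internally.
    """
    theta_arr = np.asarray(theta, dtype=np.float64)
    out = params.b * (1.0 + np.cos(theta_arr))
    return float(out) if np.isscalar(theta) else out


def surface_energy(z, params: ModelParams):
    """Monomer--wall Morse energy at height ``z >= 0``.

    Minimum ``-eps_a`` at ``z = r_min_s``; strongly repulsive toward z = 0.
    No tail cutoff is applied (one term per bead is cheap, and the tail is
    below 1e-12 * eps_a beyond z = 2).
    """
    z_arr = np.asarray(z, dtype=np.float64)
    if np.any(z_arr < 0):
        raise InvalidConformationError("surface_energy: height z < 0")
    e = np.exp(-params.alpha_s * (z_arr - params.r_min_s))
    out = params.eps_a * (e * e - 2.0 * e)
    return float(out) if np.isscalar(z) else out


# ---------------------------------------------------------------------------
# whole-chain energy and the incremental single-move difference
# ---------------------------------------------------------------------------

def _bend_sum(pos: np.ndarray, params: ModelParams) -> float:
    bonds = np.diff(pos, axis=0)
    norms = np.linalg.norm(bonds, axis=1)
    cos_phi = np.sum(bonds[:-1] * bonds[1:], axis=1) / (norms[:-1] * norms[1:])
    return params.b * float(np.sum(1.0 - cos_phi))


def total_energy(conf: Conformation, params: ModelParams,
                 pair_cutoff: float | None = None) -> EnergyBreakdown:
    """Exact energy of ``conf``: FENE over all bonds, Morse over all pairs
    with ``|i - j| > 1`` (within the cutoff), bending over all interior
    angles, and the wall term over all beads."""
    pos = conf.positions
    n = pos.shape[0]
    if pair_cutoff is None:
        pair_cutoff = params.pair_cutoff

    lengths = conf.bond_lengths()
    x = (lengths - params.l0) / params.r0
    if np.any((lengths <= params.l_min) | (lengths >= params.l_max)):
        u_fene = INFINITE_ENERGY
    else:
        u_fene = -0.5 * params.k_spring * params.r0 ** 2 * float(
            np.sum(np.log(1.0 - x * x)))

    u_bend = _bend_sum(pos, params) if n >= 3 else 0.0

    u_morse = 0.0
    for off in range(2, n):
        d = np.linalg.norm(pos[off:] - pos[:-off], axis=1)
        near = d <= pair_cutoff
        if np.any(near):
            e = np.exp(-params.alpha * (d[near] - params.r_min_ev))
            u_morse += params.eps_ev * float(np.sum(e * e - 2.0 * e))

    u_surf = float(np.sum(surface_energy(pos[:, 2], params)))

    return EnergyBreakdown(u_fene=u_fene, u_morse=u_morse,
                           u_bend=u_bend, u_surf=u_surf)


def _local_energy(pos: np.ndarray, j: int, pj: np.ndarray,
                  params: ModelParams, pair_cutoff: float) -> float:
    """Sum of all energy terms that involve bead ``j``, with bead ``j``
    taken at position ``pj`` (other beads at their stored positions)."""
    n = pos.shape[0]

    def bead(i: int) -> np.ndarray:
        return pj if i == j else pos[i]

    e = 0.0
    # the <= 2 bonds touching j
    for k in (j - 1, j):
        if 0 <= k <= n - 2:
            l = float(np.linalg.norm(bead(k + 1) - bead(k)))
            if l <= params.l_min or l >= params.l_max:
                return INFINITE_ENERGY
            x = (l - params.l0) / params.r0
            e += -0.5 * params.k_spring * params.r0 ** 2 * math.log(1.0 - x * x)
    # the <= 3 interior angles touching j
    for i in (j - 1, j, j + 1):
        if 1 <= i <= n - 2:
            u = bead(i) - bead(i - 1)
            v = bead(i + 1) - bead(i)
            cos_phi = float(np.dot(u, v)) / (
                float(np.linalg.norm(u)) * float(np.linalg.norm(v)))
            e += params.b * (1.0 - cos_phi)
    # pair terms of j against every non-bonded bead
    others = np.concatenate([pos[: max(j - 1, 0)], pos[j + 2:]])
    if others.size:
        d = np.linalg.norm(others - pj, axis=1)
        near = d <= pair_cutoff
        if np.any(near):
            ex = np.exp(-params.alpha * (d[near] - params.r_min_ev))
            e += params.eps_ev * float(np.sum(ex * ex - 2.0 * ex))
    # wall term
    zj = float(pj[2])
    if zj < 0.0 or zj > params.z_max:
        return INFINITE_ENERGY
    es = math.exp(-params.alpha_s * (zj - params.r_min_s))
    e += params.eps_a * (es * es - 2.0 * es)
    return e


def delta_energy(conf: Conformation, bead_index: int, new_position,
                 params: ModelParams, pair_cutoff: float | None = None) -> float:
    """Energy change of moving one bead to ``new_position``.

    Touches only the <= 2 bonds, <= 3 angles, the bead's wall term and the
    pair terms involving the moved bead, so a Metropolis trial costs O(N)
    rather than O(N^2).  Returns the infinite-energy sentinel when the move
    would stretch a bond outside the FENE range or place the bead outside
    the allowed half-space/slit (caller must reject).
    """
    if not 0 <= bead_index < conf.n_beads:
        raise IndexError(f"bead_index {bead_index} out of range")
    if pair_cutoff is None:
        pair_cutoff = params.pair_cutoff
    pj_new = np.asarray(new_position, dtype=np.float64)
    if pj_new.shape != (3,):
        raise ValueError("new_position must be a 3-vector")
    pos = conf.positions
    e_new = _local_energy(pos, bead_index, pj_new, params, pair_cutoff)
    if math.isinf(e_new):
        return INFINITE_ENERGY
    e_old = _local_energy(pos, bead_index, pos[bead_index], params, pair_cutoff)
    return e_new - e_old


def brute_force_reference(conf: Conformation, params: ModelParams,
                          pair_cutoff: float | None = None) -> float:
    """Plain double-loop total energy without vectorized shortcuts or
    neighbor acceleration.  Intended for cross-checks at small N."""
    if pair_cutoff is None:
        pair_cutoff = params.pair_cutoff
    pos = conf.positions
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        e += fene_energy(float(np.linalg.norm(pos[i + 1] - pos[i])), params)
    for i in range(1, n - 1):
        u = pos[i] - pos[i - 1]
        v = pos[i + 1] - pos[i]
        cos_phi = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        e += params.b * (1.0 - cos_phi)
    for i in range(n):
        for jj in range(i + 2, n):
            e += morse_pair_energy(
                float(np.linalg.norm(pos[jj] - pos[i])), params,
                cutoff=pair_cutoff)
        e += surface_energy(float(pos[i, 2]), params)
    return e
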