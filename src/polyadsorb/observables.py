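"""Analysis quantities for adsorbed-chain ensembles.

Implements the height distribution N_m / P(D) (unit-width bins centred on
integer distances from the wall), the adsorbed fraction, the per-snapshot
spatial correlation G(m) of inter-bond direction cosines (whose periodic
oscillation diagnoses helical/toroidal winding), the ensemble tangent
correlation C(s), the wall-energy fluctuation <U_s^2> - <U_s>^2 (the
specific-heat-like transition locator), and a geometric toroid classifier
with turn counting.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .engine import SampleSet
from .model import Conformation

__all__ = [
    "HeightHistogram",
    "CorrelationCurve",
    "ToroidCall",
    "height_histogram",
    "adsorbed_fraction",
    "spatial_correlation_G",
    "tangent_correlation_C",
    "surface_energy_fluctuation",
    "classify_toroid",
    "toroid_probability",
]

#: Beads within this distance of the wall count as adsorbed: the wall
#: attraction is negligible beyond one unit length.
ADSORPTION_CUTOFF = 1.0


@dataclasses.dataclass(frozen=True)
class HeightHistogram:
    """Bead-height distribution in unit bins [D - 0.5, D + 0.5) centred on
    integer distances D = 0, 1, 2, ... from the wall."""

    bin_centers: np.ndarray
    counts: np.ndarray        # N_m: beads per bin, summed over conformations
    proportions: np.ndarray   # P(D): counts / total beads counted


@dataclasses.dataclass(frozen=True)
class CorrelationCurve:
    lag: np.ndarray
    value: np.ndarray
    n_pairs: np.ndarray
    normalized: np.ndarray | None = None


@dataclasses.dataclass(frozen=True)
class ToroidCall:
    is_toroid: bool
    n_turns: int
    mean_radius: float
    height_extent: float
    periodicity_score: float


def _as_conformations(confs) -> list[Conformation]:
    if isinstance(confs, SampleSet):
        return confs.conformations()
    if isinstance(confs, Conformation):
        return [confs]
    return list(confs)


def height_histogram(confs) -> HeightHistogram:
    """Bin all bead heights of ``confs`` (a Conformation, an iterable of
    them, or a SampleSet) into unit-width bins centred at integers."""
    confs = _as_conformations(confs)
    if not confs:
        raise ValueError("height_histogram needs at least one conformation")
    z = np.concatenate([c.z for c in confs])
    centers = np.rint(z).astype(np.int64)  # [D-0.5, D+0.5) -> D
    d_max = int(centers.max())
    counts = np.bincount(centers, minlength=d_max + 1).astype(np.int64)
    bin_centers = np.arange(d_max + 1)
    return HeightHistogram(bin_centers=bin_centers, counts=counts,
                           proportions=counts / z.size)


def adsorbed_fraction(conf: Conformation,
                      cutoff: float = ADSORPTION_CUTOFF) -> float:
    """Fraction of beads within the wall attraction range (z <= cutoff)."""
    return float(np.mean(conf.z <= cutoff))


# ---------------------------------------------------------------------------
# spatial correlation G(m) of the direction-cosine sequences
# ---------------------------------------------------------------------------

def spatial_correlation_G(conf: Conformation) -> CorrelationCurve:
    """Per-snapshot shape correlation.

    With ``c[i, j] = unit bond i . unit bond j`` (N' beads, N' - 1 bonds,
    1-based bond indices), each reference bond i contributes the lag-m
    autocorrelation of its sequence {c[i, j]}_j, normalized by that
    sequence's variance:

        g(m, i) = [ (1/(N'-m-1)) sum_{j=1}^{N'-m-1} (c[i,j] - cbar_i)
                                               (c[i,j+m] - cbar_i) ]
                  / [ (1/(N'-1)) sum_{j=1}^{N'-1} (c[i,j] - cbar_i)^2 ]

    and G(m) averages g(m, i) over the interior reference bonds
    i = 2 ... N'-2.  Lags run m = 1 ... N'-4.  Reference bonds with zero
    variance are skipped; a lag where every reference bond was skipped is
    NaN.  A sustained oscillation of G(m) with period p means the bond
    direction rotates through a full turn every p bonds.
    """
    nb = conf.n_bonds
    if nb < 5:
        raise ValueError("spatial_correlation_G needs a chain of >= 5 bonds")
    n_prime = conf.n_beads
    u = conf.bond_vectors()
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    c = u @ u.T                                   # c[i, j], 0-based
    cbar = c.mean(axis=1, keepdims=True)
    dc = c - cbar
    var = np.mean(dc * dc, axis=1)                # divisor N' - 1 = nb
    lags = np.arange(1, n_prime - 3)              # m = 1 ... N' - 4
    values = np.full(lags.size, np.nan)
    n_pairs = np.empty(lags.size, dtype=np.int64)
    # interior reference bonds i = 2 .. N'-2 (1-based) -> 1 .. nb-2 0-based
    ref = np.arange(1, nb - 1)
    ok = var[ref] > 0
    for k, m in enumerate(lags):
        n_pairs[k] = nb - m                        # N' - m - 1 products
        prod = np.mean(dc[:, : nb - m] * dc[:, m:], axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            g = prod[ref] / var[ref]
        if np.any(ok):
            values[k] = float(np.mean(g[ok]))
    return CorrelationCurve(lag=lags, value=values, n_pairs=n_pairs)


# ---------------------------------------------------------------------------
# ensemble tangent correlation C(s)
# ---------------------------------------------------------------------------

def _tangent_cov(u: np.ndarray) -> np.ndarray:
    """C(s) = <(u(s) - <u(s)>) . (u(0) - <u(0)>)> over axis 0 of the
    (n_samples, n_bonds, 3) tangent array."""
    du = u - u.mean(axis=0, keepdims=True)
    return np.einsum("msk,mk->s", du, du[:, 0, :]) / u.shape[0]


def tangent_correlation_C(samples) -> CorrelationCurve:
    """Ensemble tangent--tangent correlation against the chain end.

    ``u(s)`` is the unit bond (tangent) vector at contour index s and
    ``<.>`` the ensemble average; C(s) is the covariance of u(s) with
    u(0), averaged over the two chain orientations (the ends are
    indistinguishable, so the chain read backwards, with reversed tangent
    sign, contributes equally).  ``value`` is the raw covariance;
    ``normalized`` is C(s)/C(0), the variant used for period counting.
    Accepts a SampleSet, a sequence of Conformations, or an
    (n_samples, n_bonds, 3) tangent array.
    """
    if isinstance(samples, SampleSet):
        confs = samples.conformations()
        u = np.stack([c.bond_vectors() for c in confs])
    elif isinstance(samples, np.ndarray):
        u = np.asarray(samples, dtype=np.float64)
    else:
        u = np.stack([c.bond_vectors() for c in samples])
    if u.ndim != 3 or u.shape[0] < 2:
        raise ValueError("tangent_correlation_C needs >= 2 samples")
    u = u / np.linalg.norm(u, axis=2, keepdims=True)
    c_fwd = _tangent_cov(u)
    c_rev = _tangent_cov(-u[:, ::-1, :])
    value = 0.5 * (c_fwd + c_rev)
    n = u.shape[0]
    normalized = value / value[0] if value[0] != 0 else np.full_like(value,
                                                                     np.nan)
    return CorrelationCurve(
        lag=np.arange(u.shape[1]),
        value=value,
        n_pairs=np.full(u.shape[1], n, dtype=np.int64),
        normalized=normalized,
    )


# ---------------------------------------------------------------------------
# wall-energy fluctuation
# ---------------------------------------------------------------------------

def surface_energy_fluctuation(samples, n_boot: int = 1000,
                               seed: int = 0):
    """Specific-heat-like fluctuation ``<U_s^2> - <U_s>^2`` of the total
    wall attraction energy, pooled over all samples, with a bootstrap
    standard error over replicas.

    Accepts a SampleSet, or ``(u_s, replica_id)`` arrays.  Returns
    ``(fluctuation, stderr)``.
    """
    if isinstance(samples, SampleSet):
        u_s = samples.u_surf
        rid = samples.replica_id
    else:
        u_s, rid = samples
        u_s = np.asarray(u_s, dtype=np.float64)
        rid = np.asarray(rid)
    if u_s.size < 2:
        raise ValueError("surface_energy_fluctuation needs >= 2 samples")
    fluct = float(np.var(u_s))
    uniq = np.unique(rid)
    if uniq.size < 2:
        return fluct, float("nan")
    rng = np.random.default_rng(seed)
    groups = [u_s[rid == r] for r in uniq]
    boots = np.empty(n_boot)
    for i in range(n_boot):
        pick = rng.integers(0, uniq.size, size=uniq.size)
        boots[i] = np.var(np.concatenate([groups[k] for k in pick]))
    return fluct, float(np.std(boots, ddof=1))


# ---------------------------------------------------------------------------
# toroid classifier
# ---------------------------------------------------------------------------

def _dominant_period(values: np.ndarray, pad_factor: int = 8):
    """Dominant period of a (possibly NaN-holed) sequence via the padded
    discrete spectrum.  Returns (period_in_lags, score) where score is the
    peak power over the median nonzero-frequency power."""
    g = np.array(values, dtype=np.float64)
    good = np.isfinite(g)
    if good.sum() < 4:
        return math.inf, 0.0
    g[~good] = np.nanmean(g)
    g = g - g.mean()
    if not np.any(g != 0.0):
        return math.inf, 0.0
    n = g.size
    n_fft = pad_factor * n
    power = np.abs(np.fft.rfft(g, n_fft)) ** 2
    power = power[1:]  # drop DC
    k = int(np.argmax(power)) + 1
    freq = k / n_fft   # cycles per lag
    med = float(np.median(power))
    score = float(power[k - 1] / med) if med > 0 else math.inf
    return 1.0 / freq, score


def classify_toroid(conf: Conformation,
                    adsorbed_min: float = 0.9,
                    film_height: float = 1.0,
                    score_min: float = 4.0) -> ToroidCall:
    """Decide whether ``conf`` is a film-like toroid and count its turns.

    A toroid must be (i) essentially fully adsorbed (adsorbed fraction >=
    ``adsorbed_min``), (ii) flat (height extent max z - min z <=
    ``film_height``), and (iii) periodically wound: the spectrum of its
    G(m) curve must carry a dominant peak at least ``score_min`` times the
    median power.  The turn count is the number of full periods of G(m)
    along the chain: n_turns = round(n_bonds / period).
    """
    frac = adsorbed_fraction(conf)
    extent = float(conf.z.max() - conf.z.min())
    if conf.n_bonds < 5:
        return ToroidCall(False, 0, _mean_radius(conf), extent, 0.0)
    curve = spatial_correlation_G(conf)
    period, score = _dominant_period(curve.value)
    periodic = math.isfinite(period) and score >= score_min
    n_turns = int(round(conf.n_bonds / period)) if periodic else 0
    is_toroid = (frac >= adsorbed_min and extent <= film_height
                 and periodic and n_turns >= 1)
    return ToroidCall(is_toroid=bool(is_toroid), n_turns=n_turns,
                      mean_radius=_mean_radius(conf), height_extent=extent,
                      periodicity_score=float(score))


def _mean_radius(conf: Conformation) -> float:
    xy = conf.positions[:, :2]
    centroid = xy.mean(axis=0)
    return float(np.mean(np.linalg.norm(xy - centroid, axis=1)))


def toroid_probability(samples: SampleSet, **kwargs) -> float:
    """Fraction of replicas whose final stored sample classifies as a
    toroid."""
    finals = samples.final_conformations()
    if not finals:
        return 0.0
    calls = [classify_toroid(c, **kwargs) for c in finals]
    return float(np.mean([c.is_toroid for c in calls]))
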