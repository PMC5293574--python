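"""Parameter-sweep pipeline: adsorption curves, transition location and the
(b, eps_a) diagram of states.

For every grid point (bending energy b, wall attraction eps_a) the pipeline
runs the scheduled replicas, pools the samples and reduces them to a
:class:`PhasePoint`: mean adsorbed fraction (+- standard error over
replicas), wall-energy fluctuation <U_s^2> - <U_s>^2 (+- bootstrap SE),
toroid statistics and a state label.  The transition at fixed b is located
at the fluctuation maximum on the eps_a grid (grid resolution = reporting
resolution), and the boundary curve critical_eps_a(b) is expected to be
monotone non-decreasing: a stiffer chain needs a stronger wall attraction
to adsorb fully.

Three profiles scale the same schedule schema: ``smoke`` (minutes, CI),
``desk`` (trend reproduction, tens of minutes), ``full`` (production
scale: N = 300, 100 replicas, 100 samples at 1e6-MCS intervals;
hours-to-days).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .engine import RunSchedule, SampleSet, run_samples
from .model import ModelParams
from .observables import (adsorbed_fraction, classify_toroid,
                          surface_energy_fluctuation)

__all__ = [
    "PROFILES",
    "FULL_PROFILE_REFERENCE",
    "SweepSpec",
    "PhasePoint",
    "TransitionEstimate",
    "make_profile",
    "run_sweep",
    "locate_transition",
    "phase_diagram",
    "fit_boundary",
    "turns_vs_parameters",
    "validate_full_results",
]

logger = logging.getLogger(__name__)

#: Mean adsorbed fraction at or above this labels a point fully adsorbed
#: ("almost reaches 1.0"; a stiff chain with a dozen of 301 beads off the
#: wall still counts as partially adsorbed).
FULLY_ADSORBED_THRESHOLD = 0.99

#: Schedule/size knobs per profile.  ``full`` is the production scale.
PROFILES = {
    "smoke": dict(n_bonds=32, n_replicas=4, n_samples_per_replica=5,
                  sampling_interval_mcs=10_000, equilibration_mcs=20_000),
    "desk": dict(n_bonds=64, n_replicas=8, n_samples_per_replica=4,
                 sampling_interval_mcs=100_000, equilibration_mcs=200_000),
    "full": dict(n_bonds=300, n_replicas=100, n_samples_per_replica=100,
                 sampling_interval_mcs=1_000_000,
                 equilibration_mcs=10_000_000),
}

#: Published reference values the full profile is validated against:
#: transition points eps_a*(b) on the 0.25 grid, landmark P(D=1) plateau
#: values of the height distribution, and the minimum toroid probability
#: in the moderate-(b, eps_a) regime.
FULL_PROFILE_REFERENCE = {
    "transition_eps_a": {100: 2.0, 200: 2.75, 300: 3.5, 400: 4.25,
                         500: 5.0},
    "p_bound": {(50, 1.5): 0.93, (100, 1.5): 0.64, (300, 3.0): 0.87},
    "toroid_probability_min": 0.80,
    "eps_a_grid_step": 0.25,
}


@dataclasses.dataclass
class SweepSpec:
    """Grid + schedule for one sweep.  Grids must be strictly increasing."""

    b_values: Sequence[float]
    eps_a_values: Sequence[float]
    schedule: RunSchedule
    n_bonds: int = 300
    profile: str = "desk"

    def __post_init__(self) -> None:
        for name in ("b_values", "eps_a_values"):
            vals = list(getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(nxt <= prev for nxt, prev in zip(vals[1:], vals)):
                raise ValueError(f"{name} must be strictly increasing")
            setattr(self, name, vals)


@dataclasses.dataclass
class PhasePoint:
    """Reduced observables at one (b, eps_a) grid point."""

    b: float
    eps_a: float
    mean_adsorbed_fraction: float
    adsorbed_fraction_stderr: float
    fluctuation: float
    fluctuation_stderr: float
    toroid_probability: float
    mean_n_turns: float          # NaN if < 3 toroidal finals
    mean_toroid_radius: float    # NaN if < 3 toroidal finals
    n_toroidal: int
    n_failed_replicas: int
    n_replicas: int
    restarts: int
    incomplete: bool

    @property
    def state_label(self) -> str:
        return ("fully_adsorbed"
                if self.mean_adsorbed_fraction >= FULLY_ADSORBED_THRESHOLD
                else "partially_adsorbed")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["state_label"] = self.state_label
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhasePoint":
        d = dict(d)
        d.pop("state_label", None)
        return cls(**d)


def make_profile(profile: str, seed: int = 0,
                 **overrides) -> tuple[int, RunSchedule]:
    """(n_bonds, RunSchedule) for a named profile; keyword overrides patch
    individual schedule fields."""
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cfg = dict(PROFILES[profile])
    n_bonds = cfg.pop("n_bonds")
    cfg.update(overrides)
    return n_bonds, RunSchedule(seed=seed, **cfg)


# ---------------------------------------------------------------------------
# one grid point
# ---------------------------------------------------------------------------

def reduce_samples(samples: SampleSet) -> PhasePoint:
    """Reduce a pooled SampleSet at one (b, eps_a) point to a PhasePoint."""
    params, schedule = samples.params, samples.schedule
    rid = samples.replica_id
    uniq = np.unique(rid)
    confs = samples.conformations()
    all_fracs = np.asarray([adsorbed_fraction(c) for c in confs])
    fracs = np.asarray([all_fracs[rid == r].mean() for r in uniq])
    mean_frac = float(fracs.mean()) if fracs.size else math.nan
    se_frac = (float(fracs.std(ddof=1) / math.sqrt(fracs.size))
               if fracs.size > 1 else math.nan)
    if samples.n_samples >= 2:
        fluct, fluct_se = surface_energy_fluctuation(samples,
                                                     seed=schedule.seed)
    else:
        fluct, fluct_se = math.nan, math.nan
    finals = samples.final_conformations()
    calls = [classify_toroid(c) for c in finals]
    toroidal = [c for c in calls if c.is_toroid]
    prob = float(np.mean([c.is_toroid for c in calls])) if calls else 0.0
    if len(toroidal) >= 3:
        mean_turns = float(np.mean([c.n_turns for c in toroidal]))
        mean_radius = float(np.mean([c.mean_radius for c in toroidal]))
    else:
        mean_turns = mean_radius = math.nan
    n_failed = len(samples.failed_replicas)
    return PhasePoint(
        b=params.b, eps_a=params.eps_a,
        mean_adsorbed_fraction=mean_frac,
        adsorbed_fraction_stderr=se_frac,
        fluctuation=fluct, fluctuation_stderr=fluct_se,
        toroid_probability=prob,
        mean_n_turns=mean_turns, mean_toroid_radius=mean_radius,
        n_toroidal=len(toroidal),
        n_failed_replicas=n_failed,
        n_replicas=schedule.n_replicas,
        restarts=int(sum(samples.restarts)),
        incomplete=n_failed > 0.2 * schedule.n_replicas,
    )


def _point_key(spec: SweepSpec, b: float, eps_a: float) -> str:
    payload = {
        "b": b, "eps_a": eps_a, "n_bonds": spec.n_bonds,
        "schedule": spec.schedule.to_dict(),
    }
    return hashlib.sha1(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_sweep(spec: SweepSpec, out_dir=None,
              progress: bool = False) -> list[PhasePoint]:
    """Run every (b, eps_a) grid point of ``spec``.

    With ``out_dir`` each completed point is persisted as a JSON file
    keyed by a content hash of its parameters and schedule; re-running the
    same spec skips completed points, so an interrupted sweep resumes
    where it stopped.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    points = []
    for b in spec.b_values:
        for eps_a in spec.eps_a_values:
            key = _point_key(spec, b, eps_a)
            cache = out / f"point_{key}.json" if out is not None else None
            if cache is not None and cache.exists():
                points.append(PhasePoint.from_dict(
                    json.loads(cache.read_text())))
                continue
            params = ModelParams(n_bonds=spec.n_bonds, b=b, eps_a=eps_a)
            samples = run_samples(params, spec.schedule, progress=progress)
            point = reduce_samples(samples)
            if point.incomplete:
                logger.warning("point (b=%g, eps_a=%g): %d/%d replicas "
                               "failed; marked incomplete", b, eps_a,
                               point.n_failed_replicas, point.n_replicas)
            if cache is not None:
                cache.write_text(json.dumps(point.to_dict(), sort_keys=True,
                                            indent=1))
            points.append(point)
    return points


# ---------------------------------------------------------------------------
# transition location and the diagram of states
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TransitionEstimate:
    b: float
    eps_a: float
    on_boundary: bool   # maximum sits on the first/last grid point
    ambiguous: bool     # maximum within 1 SE of the runner-up


def locate_transition(points: Sequence[PhasePoint]) -> TransitionEstimate:
    """Critical eps_a at fixed b: the grid position of the wall-energy
    fluctuation maximum (no interpolation)."""
    pts = sorted(points, key=lambda p: p.eps_a)
    bs = {p.b for p in pts}
    if len(bs) != 1:
        raise ValueError("locate_transition expects points at a single b")
    if len(pts) < 5:
        raise ValueError("locate_transition needs >= 5 grid points")
    fluct = np.asarray([p.fluctuation for p in pts])
    k = int(np.nanargmax(fluct))
    on_boundary = k in (0, len(pts) - 1)
    order = np.argsort(fluct)
    runner = fluct[order[-2]]
    se = pts[k].fluctuation_stderr
    ambiguous = bool(np.isfinite(se) and fluct[k] - runner <= se)
    return TransitionEstimate(b=pts[0].b, eps_a=pts[k].eps_a,
                              on_boundary=on_boundary, ambiguous=ambiguous)


def locate_transition_midpoint(points: Sequence[PhasePoint]) -> float:
    """Alternative transition estimator: the first grid eps_a at which the
    mean adsorbed fraction crosses the midpoint of its observed rise.
    Near the transition this agrees with the fluctuation-peak location to
    about one grid step."""
    pts = sorted(points, key=lambda p: p.eps_a)
    if len({p.b for p in pts}) != 1:
        raise ValueError("expects points at a single b")
    frac = np.asarray([p.mean_adsorbed_fraction for p in pts])
    mid = 0.5 * (np.nanmin(frac) + np.nanmax(frac))
    k = int(np.argmax(frac >= mid))
    return pts[k].eps_a


def fit_boundary(b_values, eps_values) -> tuple[float, float]:
    """Least-squares line eps_a*(b) = slope * b + intercept."""
    slope, intercept = np.polyfit(np.asarray(b_values, dtype=float),
                                  np.asarray(eps_values, dtype=float), 1)
    return float(slope), float(intercept)


def phase_diagram(points: Sequence[PhasePoint]):
    """Boundary curve critical_eps_a(b) plus per-point state labels.

    Returns ``(boundary, labels, fit)`` where ``boundary`` is a DataFrame
    (b, critical_eps_a, on_boundary, ambiguous), ``labels`` a DataFrame of
    every input point with its state label, and ``fit`` a dict with the
    least-squares slope/intercept of the boundary and any monotonicity
    violations (the boundary is expected non-decreasing in b; violations
    are reported, not hidden).
    """
    by_b: dict[float, list[PhasePoint]] = {}
    for p in points:
        by_b.setdefault(p.b, []).append(p)
    if len(by_b) < 2:
        raise ValueError("phase_diagram needs >= 2 distinct b values")
    rows = []
    for b in sorted(by_b):
        est = locate_transition(by_b[b])
        rows.append(dict(b=b, critical_eps_a=est.eps_a,
                         on_boundary=est.on_boundary,
                         ambiguous=est.ambiguous))
    boundary = pd.DataFrame(rows)
    labels = pd.DataFrame([
        dict(b=p.b, eps_a=p.eps_a,
             mean_adsorbed_fraction=p.mean_adsorbed_fraction,
             state_label=p.state_label)
        for p in sorted(points, key=lambda p: (p.b, p.eps_a))])
    slope, intercept = fit_boundary(boundary["b"], boundary["critical_eps_a"])
    crit = boundary["critical_eps_a"].to_numpy()
    violations = [
        (float(boundary["b"][i]), float(boundary["b"][i + 1]))
        for i in range(len(crit) - 1) if crit[i + 1] < crit[i]]
    if violations:
        logger.warning("phase boundary not monotone at b pairs: %s",
                       violations)
    fit = dict(slope=slope, intercept=intercept,
               monotone=not violations, violations=violations)
    return boundary, labels, fit


def turns_vs_parameters(points: Sequence[PhasePoint]) -> dict:
    """Toroid turn-count and size trends over the grid.

    Uses only points with >= 3 toroidal final samples.  Returns a dict
    with a tidy ``table`` (b, eps_a, mean N_t, mean radius) and Kendall
    tau sign tests of N_t vs eps_a at fixed b and of N_t vs b at fixed
    eps_a (empty lists when fewer than two usable points share the fixed
    coordinate)."""
    usable = [p for p in points if p.n_toroidal >= 3]
    skipped = [(p.b, p.eps_a) for p in points if 0 < p.n_toroidal < 3]
    if skipped:
        logger.info("turns_vs_parameters: excluded points with < 3 "
                    "toroidal samples: %s", skipped)
    table = pd.DataFrame([
        dict(b=p.b, eps_a=p.eps_a, mean_n_turns=p.mean_n_turns,
             mean_toroid_radius=p.mean_toroid_radius,
             n_toroidal=p.n_toroidal)
        for p in sorted(usable, key=lambda p: (p.b, p.eps_a))])
    trends_eps = []
    for b in sorted({p.b for p in usable}):
        grp = sorted((p for p in usable if p.b == b),
                     key=lambda p: p.eps_a)
        if len(grp) >= 2:
            tau, pval = stats.kendalltau([p.eps_a for p in grp],
                                         [p.mean_n_turns for p in grp])
            trends_eps.append(dict(b=b, tau=float(tau), p_value=float(pval)))
    trends_b = []
    for eps in sorted({p.eps_a for p in usable}):
        grp = sorted((p for p in usable if p.eps_a == eps),
                     key=lambda p: p.b)
        if len(grp) >= 2:
            tau, pval = stats.kendalltau([p.b for p in grp],
                                         [p.mean_n_turns for p in grp])
            trends_b.append(dict(eps_a=eps, tau=float(tau),
                                 p_value=float(pval)))
    return dict(table=table, n_turns_vs_eps_a=trends_eps,
                n_turns_vs_b=trends_b)


# ---------------------------------------------------------------------------
# full-profile validation gate
# ---------------------------------------------------------------------------

def validate_full_results(transitions: dict, p_bound: dict | None = None,
                          toroid_probability: float | None = None) -> dict:
    """Compare production-scale results against the reference values.

    ``transitions`` maps b -> measured critical eps_a (compared within one
    0.25 grid step); ``p_bound`` maps (b, eps_a) -> measured P(D=1)
    (compared within 0.05); ``toroid_probability`` must exceed 0.80.
    Returns {"passed": bool, "failures": [...]}.  This is the long-run
    validation gate: it needs full-profile data (N = 300, 100 replicas at
    1e6-MCS intervals) produced by :func:`run_sweep`.
    """
    ref = FULL_PROFILE_REFERENCE
    failures = []
    step = ref["eps_a_grid_step"]
    for b, expected in ref["transition_eps_a"].items():
        if b not in transitions:
            failures.append(f"missing transition at b={b}")
        elif abs(transitions[b] - expected) > step + 1e-12:
            failures.append(
                f"transition at b={b}: {transitions[b]} vs {expected} "
                f"(tolerance one grid step {step})")
    if p_bound is not None:
        for key, expected in ref["p_bound"].items():
            if key in p_bound and abs(p_bound[key] - expected) > 0.05:
                failures.append(f"P(D=1) at (b, eps_a)={key}: "
                                f"{p_bound[key]} vs {expected} (+-0.05)")
    if toroid_probability is not None:
        if toroid_probability <= ref["toroid_probability_min"]:
            failures.append(
                f"toroid probability {toroid_probability} not above "
                f"{ref['toroid_probability_min']}")
    return dict(passed=not failures, failures=failures)
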