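"""Sweep pipeline tests: plumbing, resumability, transition location,
boundary fitting and trend detection on synthetic and smoke-scale data."""

import dataclasses
import json
import math

import numpy as np
import pytest

from polyadsorb.engine import RunSchedule
from polyadsorb.experiments import (FULL_PROFILE_REFERENCE, PROFILES,
                                    PhasePoint, SweepSpec,
                                    TransitionEstimate, fit_boundary,
                                    locate_transition,
                                    locate_transition_midpoint,
                                    make_profile, phase_diagram, run_sweep,
                                    turns_vs_parameters,
                                    validate_full_results)


def synthetic_point(b, eps_a, frac=0.5, fluct=1.0, fluct_se=0.01,
                    n_turns=math.nan, n_toroidal=0):
    return PhasePoint(
        b=b, eps_a=eps_a, mean_adsorbed_fraction=frac,
        adsorbed_fraction_stderr=0.01, fluctuation=fluct,
        fluctuation_stderr=fluct_se, toroid_probability=0.0,
        mean_n_turns=n_turns, mean_toroid_radius=10.0 / max(n_turns, 1.0),
        n_toroidal=n_toroidal, n_failed_replicas=0, n_replicas=8,
        restarts=0, incomplete=False)


@pytest.fixture(scope="module")
def smoke_points(tmp_path_factory):
    """A tiny but real sweep: N = 16, 2 b-values x 3 eps_a-values."""
    sched = RunSchedule(n_replicas=2, n_samples_per_replica=2,
                        sampling_interval_mcs=2000, equilibration_mcs=2000,
                        seed=3)
    spec = SweepSpec(b_values=[5, 50], eps_a_values=[1.0, 3.0, 8.0],
                     schedule=sched, n_bonds=16, profile="smoke")
    out = tmp_path_factory.mktemp("sweep")
    return spec, out, run_sweep(spec, out_dir=out)


class TestRunSweep:
    def test_emits_one_point_per_grid_cell(self, smoke_points):
        spec, out, points = smoke_points
        assert len(points) == 6
        assert {(p.b, p.eps_a) for p in points} == {
            (b, e) for b in [5, 50] for e in [1.0, 3.0, 8.0]}

    @staticmethod
    def _digest(points):
        return json.dumps([p.to_dict() for p in points], sort_keys=True)

    def test_resume_returns_identical_results(self, smoke_points):
        spec, out, points = smoke_points
        again = run_sweep(spec, out_dir=out)  # all loaded from cache
        assert self._digest(again) == self._digest(points)

    def test_interrupted_sweep_recomputes_identically(self, smoke_points):
        spec, out, points = smoke_points
        victim = sorted(out.glob("point_*.json"))[2]
        victim.unlink()
        again = run_sweep(spec, out_dir=out)
        assert self._digest(again) == self._digest(points)

    def test_strong_attraction_adsorbs_more(self, smoke_points):
        _, _, points = smoke_points
        for b in (5, 50):
            row = sorted((p for p in points if p.b == b),
                         key=lambda p: p.eps_a)
            assert row[-1].mean_adsorbed_fraction > \
                row[0].mean_adsorbed_fraction

    def test_invalid_grids_rejected(self):
        sched = RunSchedule(n_replicas=1, sampling_interval_mcs=10)
        with pytest.raises(ValueError):
            SweepSpec(b_values=[], eps_a_values=[1], schedule=sched)
        with pytest.raises(ValueError):
            SweepSpec(b_values=[1, 1], eps_a_values=[1], schedule=sched)


class TestLocateTransition:
    def _curve(self, fluctuations, ses=None):
        eps = [1.0, 2.0, 3.0, 4.0, 5.0]
        ses = ses or [0.01] * 5
        return [synthetic_point(100, e, fluct=f, fluct_se=s)
                for e, f, s in zip(eps, fluctuations, ses)]

    def test_peak_located_on_grid(self):
        est = locate_transition(self._curve([1, 5, 20, 7, 2]))
        assert est.eps_a == 3.0
        assert not est.on_boundary and not est.ambiguous

    def test_boundary_maximum_flagged(self):
        est = locate_transition(self._curve([30, 5, 4, 3, 2]))
        assert est.eps_a == 1.0 and est.on_boundary

    def test_flat_noisy_curve_flagged_ambiguous(self):
        est = locate_transition(self._curve([10.0, 10.2, 10.4, 10.3, 10.1],
                                            ses=[1.0] * 5))
        assert est.ambiguous

    def test_two_estimators_agree_within_one_grid_step(self):
        # fluctuation peaked at eps_a = 3 with the adsorbed fraction rising
        # through its midpoint there: both estimators land on the same bin
        eps = [1.0, 2.0, 3.0, 4.0, 5.0]
        fracs = [0.05, 0.2, 0.7, 0.98, 1.0]
        flucts = [1, 5, 20, 7, 2]
        pts = [synthetic_point(100, e, frac=f, fluct=fl)
               for e, f, fl in zip(eps, fracs, flucts)]
        peak = locate_transition(pts).eps_a
        mid = locate_transition_midpoint(pts)
        assert abs(peak - mid) <= 1.0

    def test_needs_five_points_and_single_b(self):
        with pytest.raises(ValueError):
            locate_transition(self._curve([1, 2, 3, 4, 5])[:4])
        mixed = self._curve([1, 2, 3, 4, 5])
        mixed[0] = dataclasses.replace(mixed[0], b=200)
        with pytest.raises(ValueError):
            locate_transition(mixed)


class TestPhaseDiagram:
    def _points_from_transitions(self, transitions, grid=None):
        grid = grid or np.arange(1.0, 6.01, 0.25)
        pts = []
        for b, crit in transitions.items():
            for e in grid:
                # synthetic fluctuation peaked at the printed transition
                f = 1.0 / (1e-3 + (e - crit) ** 2)
                pts.append(synthetic_point(b, float(e), fluct=f,
                                           frac=1.0 if e >= crit else 0.5))
        return pts

    def test_printed_transition_points_are_affine(self):
        ref = FULL_PROFILE_REFERENCE["transition_eps_a"]
        slope, intercept = fit_boundary(list(ref), list(ref.values()))
        assert slope == pytest.approx(0.0075, abs=1e-12)

    def test_boundary_recovered_from_fluctuation_peaks(self):
        ref = FULL_PROFILE_REFERENCE["transition_eps_a"]
        boundary, labels, fit = phase_diagram(
            self._points_from_transitions(ref))
        got = dict(zip(boundary["b"], boundary["critical_eps_a"]))
        assert got == ref
        assert fit["monotone"]
        assert fit["slope"] == pytest.approx(0.0075, abs=1e-9)

    def test_two_b_values_suffice(self):
        boundary, _, fit = phase_diagram(
            self._points_from_transitions({100: 2.0, 500: 5.0}))
        assert len(boundary) == 2 and fit["monotone"]

    def test_input_order_invariance(self):
        pts = self._points_from_transitions({100: 2.0, 300: 3.5, 500: 5.0})
        rng = np.random.default_rng(0)
        shuffled = list(pts)
        rng.shuffle(shuffled)
        b1, l1, f1 = phase_diagram(pts)
        b2, l2, f2 = phase_diagram(shuffled)
        assert b1.equals(b2) and l1.equals(l2) and f1 == f2

    def test_monotonicity_violation_reported_not_hidden(self):
        pts = self._points_from_transitions({100: 4.0, 300: 2.0, 500: 5.0})
        _, _, fit = phase_diagram(pts)
        assert not fit["monotone"]
        assert fit["violations"] == [(100.0, 300.0)]

    def test_fully_adsorbed_label_threshold(self):
        assert synthetic_point(50, 5.0, frac=0.995).state_label == \
            "fully_adsorbed"
        # a dozen of 301 beads off the wall -> partially adsorbed
        assert synthetic_point(500, 5.0, frac=1 - 12 / 301).state_label == \
            "partially_adsorbed"


class TestTurnsVsParameters:
    def test_positive_trend_detected(self):
        pts = [synthetic_point(50, e, n_turns=t, n_toroidal=5)
               for e, t in [(2.0, 2), (3.0, 3), (4.0, 4)]]
        res = turns_vs_parameters(pts)
        assert res["n_turns_vs_eps_a"][0]["tau"] == pytest.approx(1.0)

    def test_stiffer_chain_winds_less(self):
        pts = [synthetic_point(b, 5.0, n_turns=t, n_toroidal=4)
               for b, t in [(50, 5), (300, 3)]]
        res = turns_vs_parameters(pts)
        assert res["n_turns_vs_b"][0]["tau"] == pytest.approx(-1.0)

    def test_sparse_points_excluded_and_single_point_is_empty(self):
        pts = [synthetic_point(50, 2.0, n_turns=3, n_toroidal=5),
               synthetic_point(50, 3.0, n_turns=4, n_toroidal=2)]
        res = turns_vs_parameters(pts)
        assert len(res["table"]) == 1
        assert res["n_turns_vs_eps_a"] == [] and res["n_turns_vs_b"] == []


class TestProfilesAndValidation:
    def test_profiles_share_schema_and_scale(self):
        for name in ("smoke", "desk", "full"):
            n_bonds, sched = make_profile(name, seed=1)
            assert isinstance(sched, RunSchedule) and sched.seed == 1
        assert PROFILES["smoke"]["n_bonds"] < PROFILES["desk"]["n_bonds"] \
            < PROFILES["full"]["n_bonds"]

    def test_validation_gate_accepts_reference_and_rejects_shifted(self):
        ref = FULL_PROFILE_REFERENCE["transition_eps_a"]
        ok = validate_full_results(dict(ref), p_bound={
            (50, 1.5): 0.95, (100, 1.5): 0.62, (300, 3.0): 0.90},
            toroid_probability=0.85)
        assert ok["passed"], ok["failures"]
        shifted = {b: v + 0.5 for b, v in ref.items()}
        bad = validate_full_results(shifted)
        assert not bad["passed"] and len(bad["failures"]) == 5
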