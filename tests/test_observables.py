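"""Observable tests: height binning, correlation functions against
independent analytic/brute-force oracles, fluctuation estimator and the
toroid classifier."""

import math

import numpy as np
import pytest

from polyadsorb import Conformation, ModelParams
from polyadsorb.fixtures import FixtureSpec, make_fixture
from polyadsorb.observables import (adsorbed_fraction, classify_toroid,
                                    height_histogram, spatial_correlation_G,
                                    surface_energy_fluctuation,
                                    tangent_correlation_C,
                                    toroid_probability)

from conftest import oracle_winding_turns


def brute_force_G(conf):
    """Triple-loop transcription of the printed double average; kept
    independent of the library's vectorized path."""
    pos = conf.positions
    u = np.diff(pos, axis=0)
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    nb = len(u)                      # N' - 1 bonds
    c = np.array([[float(u[i] @ u[j]) for j in range(nb)]
                  for i in range(nb)])
    lags = np.arange(1, nb - 2)      # m = 1 .. N' - 4
    out = np.full(lags.size, np.nan)
    for k, m in enumerate(lags):
        vals = []
        for i in range(1, nb - 1):   # reference bonds 2 .. N'-2 (1-based)
            cbar = c[i].mean()
            num = np.mean([(c[i, j] - cbar) * (c[i, j + m] - cbar)
                           for j in range(nb - m)])
            den = np.mean([(c[i, j] - cbar) ** 2 for j in range(nb)])
            if den > 0:
                vals.append(num / den)
        if vals:
            out[k] = np.mean(vals)
    return lags, out


class TestHeightHistogram:
    def test_delta_distribution_falls_in_unit_bin_centre_one(self):
        conf = make_fixture(FixtureSpec(kind="rod", n_bonds=9, height=0.8))
        h = height_histogram(conf)
        assert h.proportions[1] == 1.0  # z = 0.8 lies in [0.5, 1.5)
        assert h.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_vertical_rod_matches_hand_binning(self):
        # bead heights 0.8, 1.5, 2.2, 2.9, 3.6 -> bins 1, 2 (x2), 3, 4
        pos = np.zeros((5, 3))
        pos[:, 2] = 0.8 + 0.7 * np.arange(5)
        h = height_histogram(Conformation(pos))
        assert list(h.counts) == [0, 1, 2, 1, 1]

    def test_two_conformations_average_linearly(self):
        flat = make_fixture(FixtureSpec(kind="rod", n_bonds=4, height=0.8))
        pos = np.zeros((5, 3))
        pos[:, 2] = 0.8 + 0.7 * np.arange(5)
        tall = Conformation(pos)
        combined = height_histogram([flat, tall])
        a, b = height_histogram(flat), height_histogram(tall)
        na = np.pad(a.counts, (0, len(combined.counts) - len(a.counts)))
        nb = np.pad(b.counts, (0, len(combined.counts) - len(b.counts)))
        assert np.array_equal(combined.counts, na + nb)


class TestAdsorbedFraction:
    def test_flat_and_vertical_limits(self):
        flat = make_fixture(FixtureSpec(kind="rod", n_bonds=10, height=0.8))
        assert adsorbed_fraction(flat) == 1.0
        pos = np.zeros((11, 3))
        pos[:, 2] = 0.8 + 0.7 * np.arange(11)
        assert adsorbed_fraction(Conformation(pos)) == pytest.approx(1 / 11)

    def test_hand_enumerated_mixture(self):
        pos = np.zeros((6, 3))
        pos[:, 0] = 0.7 * np.arange(6)
        pos[:, 2] = [0.8, 0.9, 1.0, 1.4, 2.0, 0.3]
        assert adsorbed_fraction(Conformation(pos)) == pytest.approx(4 / 6)


class TestSpatialCorrelationG:
    def test_matches_brute_force_on_circle_and_spiral(self):
        for spec in (FixtureSpec(kind="circle", n_bonds=20),
                     FixtureSpec(kind="toroid_spiral", n_bonds=64,
                                 turns=1)):
            conf = make_fixture(spec)
            curve = spatial_correlation_G(conf)
            lags, ref = brute_force_G(conf)
            assert np.array_equal(curve.lag, lags)
            np.testing.assert_allclose(curve.value, ref, rtol=1e-10)

    def test_circle_oscillates_with_polygon_period(self):
        conf = make_fixture(FixtureSpec(kind="circle", n_bonds=20))
        curve = spatial_correlation_G(conf)
        expected = np.cos(2 * np.pi * curve.lag / 20)
        # truncated-window ripple allowed; the oscillation must track cos
        assert np.max(np.abs(curve.value[:10] - expected[:10])) < 0.1

    def test_short_chain_rejected(self):
        conf = make_fixture(FixtureSpec(kind="rod", n_bonds=4))
        with pytest.raises(ValueError):
            spatial_correlation_G(conf)

    def test_invariant_under_rigid_motion(self, rng):
        conf = make_fixture(FixtureSpec(kind="toroid_spiral", n_bonds=96,
                                        turns=2))
        base = spatial_correlation_G(conf).value
        th = 1.234
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1]])
        moved = Conformation(conf.positions @ rot.T + [3.0, -7.0, 0.0])
        np.testing.assert_allclose(spatial_correlation_G(moved).value, base,
                                   atol=1e-10)

    def test_random_directions_show_no_structure(self):
        rng = np.random.default_rng(99)
        n_exceed = 0
        n_total = 0
        for _ in range(100):
            u = rng.standard_normal((40, 3))
            pos = np.vstack([[0, 0, 0], np.cumsum(u, axis=0)])
            pos[:, 2] -= pos[:, 2].min()
            curve = spatial_correlation_G(Conformation(pos))
            bound = 3.0 / np.sqrt(curve.n_pairs)
            n_exceed += int(np.sum(np.abs(curve.value) > bound))
            n_total += curve.value.size
        # ~3 sigma bound: only a few-percent tail may exceed it
        assert n_exceed / n_total < 0.02


class TestTangentCorrelationC:
    @staticmethod
    def rotated_circle_tangents(n_samples, nb, seed):
        rng = np.random.default_rng(seed)
        s = np.arange(nb)
        out = []
        for _ in range(n_samples):
            ang = rng.random() * 2 * np.pi + 2 * np.pi * s / nb
            out.append(np.stack([np.cos(ang), np.sin(ang),
                                 np.zeros(nb)], axis=1))
        return np.stack(out)

    def test_rotated_circle_ensemble_gives_cosine(self):
        nb = 24
        u = self.rotated_circle_tangents(500, nb, seed=1)
        curve = tangent_correlation_C(u)
        expected = np.cos(2 * np.pi * np.arange(nb) / nb)
        assert np.max(np.abs(curve.normalized - expected)) < 0.05

    def test_isotropic_noise_has_no_correlation(self):
        rng = np.random.default_rng(2)
        u = rng.standard_normal((500, 24, 3))
        curve = tangent_correlation_C(u)
        assert np.all(np.abs(curve.value[1:]) < 0.1)
        assert curve.value[0] == pytest.approx(1.0, abs=0.05)

    def test_end_indistinguishability_by_construction(self):
        u = self.rotated_circle_tangents(100, 16, seed=3)
        fwd = tangent_correlation_C(u)
        rev = tangent_correlation_C(-u[:, ::-1, :])
        np.testing.assert_allclose(fwd.value, rev.value, atol=1e-12)

    def test_single_sample_rejected(self):
        u = np.zeros((1, 10, 3))
        u[..., 0] = 1.0
        with pytest.raises(ValueError):
            tangent_correlation_C(u)


class TestSurfaceEnergyFluctuation:
    def test_degenerate_and_bernoulli_cases(self):
        rid = np.repeat(np.arange(4), 5)
        val, _ = surface_energy_fluctuation((np.full(20, -3.0), rid))
        assert val == 0.0
        us = np.tile([-1.0, 1.0], 10)
        val, _ = surface_energy_fluctuation((us, rid))
        assert val == pytest.approx(1.0)

    def test_known_variance_recovery(self):
        rng = np.random.default_rng(8)
        us = rng.normal(-40.0, 3.0, size=2000)
        rid = np.repeat(np.arange(20), 100)
        val, se = surface_energy_fluctuation((us, rid), seed=1)
        assert abs(val - 9.0) < 3 * se

    def test_scale_covariance_and_positivity(self):
        rng = np.random.default_rng(9)
        us = rng.normal(0, 2.0, size=500)
        rid = np.repeat(np.arange(10), 50)
        v1, _ = surface_energy_fluctuation((us, rid), seed=2)
        v3, _ = surface_energy_fluctuation((3.0 * us, rid), seed=2)
        assert v1 >= 0
        assert v3 == pytest.approx(9.0 * v1, rel=1e-9)


class TestToroidClassifier:
    @pytest.mark.parametrize("turns", [1, 2, 3, 4, 5])
    def test_spiral_turn_counts_recovered(self, turns):
        conf = make_fixture(FixtureSpec(kind="toroid_spiral",
                                        n_bonds=64 * turns, turns=turns))
        call = classify_toroid(conf)
        assert call.is_toroid
        assert call.n_turns == turns
        # independent winding-angle oracle agrees
        assert round(oracle_winding_turns(conf)) == turns

    def test_rod_and_desorbed_coil_are_not_toroids(self):
        rod = make_fixture(FixtureSpec(kind="rod", n_bonds=30, height=0.8))
        assert not classify_toroid(rod).is_toroid
        coil = make_fixture(FixtureSpec(kind="coil", n_bonds=60, height=4.0,
                                        seed=11))
        assert not classify_toroid(coil).is_toroid

    def test_no_false_positives_on_random_coils(self):
        calls = [classify_toroid(make_fixture(
            FixtureSpec(kind="coil", n_bonds=60, height=3.0, seed=s)))
            for s in range(100)]
        assert sum(c.is_toroid for c in calls) == 0

    def test_radius_shrinks_as_turns_pack_tighter(self):
        radii = [classify_toroid(make_fixture(FixtureSpec(
            kind="toroid_spiral", n_bonds=160, turns=t))).mean_radius
            for t in (1, 2, 3)]
        assert radii[0] > radii[1] > radii[2]


class TestToroidProbability:
    def test_fraction_of_toroidal_final_samples(self):
        from polyadsorb.engine import RunSchedule, SampleSet

        spiral = make_fixture(FixtureSpec(kind="toroid_spiral", n_bonds=128,
                                          turns=2)).positions
        rod = make_fixture(FixtureSpec(kind="rod", n_bonds=128,
                                       height=0.8)).positions
        params = ModelParams(n_bonds=128, b=1.0, eps_a=1.0)
        sched = RunSchedule(n_replicas=4, n_samples_per_replica=1,
                            sampling_interval_mcs=1, seed=0)
        ss = SampleSet(params=params, schedule=sched,
                       positions=np.stack([spiral, rod, spiral, spiral]),
                       energies=np.zeros((4, 4)),
                       mcs_index=np.arange(4),
                       replica_id=np.arange(4),
                       restarts=[0] * 4, failed_replicas=[])
        assert toroid_probability(ss) == pytest.approx(0.75)
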