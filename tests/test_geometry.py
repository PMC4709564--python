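"""Surface areas, RMSD/RMSF, distances, windowing and moving averages."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pepedit import (
    RmsdSpec, TimeSeries, Trajectory, buried_surface, discard_equilibration,
    fraction_below, min_distance, moving_average, named_distances,
    rmsd_series, rmsf, sas, sphere_fixture, sphere_sas_analytic,
    two_sphere_buried_analytic, two_sphere_sas_analytic,
)


class TestSAS:
    def test_single_sphere_matches_analytic(self):
        top, traj = sphere_fixture([1.9], [[0.0, 0, 0]])
        res = sas(top, traj.coords[0], n_points=960)
        assert res.total == pytest.approx(sphere_sas_analytic(1.9), rel=0.005)

    def test_far_spheres_are_additive(self):
        top, traj = sphere_fixture([1.9, 1.6], [[0.0, 0, 0], [20.0, 0, 0]])
        res = sas(top, traj.coords[0], n_points=960)
        expected = sphere_sas_analytic(1.9) + sphere_sas_analytic(1.6)
        assert res.total == pytest.approx(expected, rel=0.005)

    def test_overlapping_spheres_match_cap_formula(self):
        top, traj = sphere_fixture([1.9, 1.9], [[0.0, 0, 0], [3.0, 0, 0]])
        res = sas(top, traj.coords[0], n_points=960)
        expected = two_sphere_sas_analytic(1.9, 1.9, 3.0)
        assert res.total == pytest.approx(expected, rel=0.005)

    def test_polar_apolar_partition(self, toy_peptide):
        coords = np.array([a.position for a in toy_peptide.atoms])
        res = sas(toy_peptide, coords)
        assert res.total == pytest.approx(res.polar + res.apolar, abs=1e-6)
        assert res.apolar == res.total  # all-carbon toy

    def test_sas_decreases_as_spheres_approach(self):
        """Two-sphere scan: total SAS is non-increasing as separation
        shrinks."""
        areas = []
        for d in (12.0, 8.0, 5.0, 3.0, 1.5):
            top, traj = sphere_fixture([1.9, 1.9], [[0.0, 0, 0], [d, 0, 0]])
            areas.append(sas(top, traj.coords[0], n_points=960).total)
        assert all(a >= b - 1e-6 for a, b in zip(areas, areas[1:]))


class TestBuriedSurface:
    def test_separated_groups_bury_nothing(self):
        top, traj = sphere_fixture([1.9, 1.9], [[0.0, 0, 0], [30.0, 0, 0]])
        series = buried_surface(traj, top, np.array([0]), np.array([1]))
        assert abs(series.values[0]) < 1e-6

    def test_two_sphere_fixture_matches_cap_oracle(self):
        d = 3.0
        top, traj = sphere_fixture([1.9, 1.9], [[0.0, 0, 0], [d, 0, 0]])
        series = buried_surface(traj, top, np.array([0]), np.array([1]),
                                n_points=960)
        expected = two_sphere_buried_analytic(1.9, 1.9, d)
        assert series.values[0] == pytest.approx(expected, rel=0.005)

    def test_symmetric_in_groups(self):
        top, traj = sphere_fixture([1.9, 1.6, 1.7],
                                   [[0.0, 0, 0], [3.0, 0, 0], [1.5, 2.0, 0]])
        a = buried_surface(traj, top, np.array([0, 2]), np.array([1]))
        b = buried_surface(traj, top, np.array([1]), np.array([0, 2]))
        np.testing.assert_array_equal(a.values, b.values)


def two_domain_toy():
    """Two rigid triads 20 Å apart; in later frames the second triad is
    displaced by (3, 4, 0) while the first stays put."""
    d1 = np.array([[0.0, 0, 0], [3.0, 0, 0], [0.0, 3, 0]])
    d2 = d1 + np.array([20.0, 0, 0])
    frame0 = np.vstack([d1, d2])
    frame1 = np.vstack([d1, d2 + np.array([3.0, 4.0, 0.0])])
    coords = np.stack([frame0, frame1])
    return Trajectory(times=np.array([0.0, 1.0]), coords=coords)


class TestRmsd:
    def test_reference_frame_measures_zero(self, static_trajectory):
        spec = RmsdSpec(np.arange(4), np.arange(4), 0)
        series = rmsd_series(static_trajectory, spec)
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_rigid_rotation_zero_when_fit_equals_measure(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 2]])
        rot = Rotation.from_euler("z", 1.1).as_matrix()
        coords = np.stack([base, base @ rot.T + np.array([2.0, -1, 4])])
        traj = Trajectory(times=np.array([0.0, 1.0]), coords=coords)
        series = rmsd_series(traj, RmsdSpec(np.arange(4), np.arange(4), 0))
        np.testing.assert_allclose(series.values, 0.0, atol=1e-9)

    def test_fit_measure_split_reports_distal_displacement(self):
        """Fitting on the static domain, a (3,4,0) Å displacement of the
        measured distal domain reads as exactly 5 Å."""
        traj = two_domain_toy()
        spec = RmsdSpec(fit_selection=np.arange(3),
                        measure_selection=np.arange(3, 6), reference=0)
        series = rmsd_series(traj, spec)
        assert series.values[0] == pytest.approx(0.0, abs=1e-9)
        assert series.values[1] == pytest.approx(5.0, rel=1e-9)

    def test_invariant_under_global_rigid_motion(self):
        traj = two_domain_toy()
        rot = Rotation.from_euler("xyz", [0.4, 0.8, -0.2]).as_matrix()
        moved = Trajectory(times=traj.times,
                           coords=traj.coords @ rot.T + np.array([7.0, -2, 3]))
        spec = RmsdSpec(np.arange(3), np.arange(3, 6), 0)
        np.testing.assert_allclose(rmsd_series(moved, spec).values,
                                   rmsd_series(traj, spec).values, atol=1e-9)

    def test_reference_shape_mismatch_rejected(self):
        traj = two_domain_toy()
        with pytest.raises(ValueError, match="reference"):
            rmsd_series(traj, RmsdSpec(np.arange(3), np.arange(3),
                                       np.zeros((4, 3))))


class TestFractionBelow:
    def test_hand_series(self):
        s = TimeSeries(times=np.arange(4.0), values=np.array([1.0, 2, 3, 4]),
                       unit="A")
        assert fraction_below(s, 2.5) == 0.5

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1,
                    max_size=50),
           st.floats(-1, 11))
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_exact_count(self, values, threshold):
        s = TimeSeries(times=np.arange(len(values), dtype=float),
                       values=np.array(values), unit="A")
        frac = fraction_below(s, threshold)
        assert 0.0 <= frac <= 1.0
        assert frac == sum(v < threshold for v in values) / len(values)


class TestRmsf:
    def test_static_trajectory_is_zero(self, static_trajectory):
        np.testing.assert_allclose(rmsf(static_trajectory, np.arange(4)), 0.0,
                                   atol=1e-12)

    def test_oscillating_atom_reads_one_angstrom(self):
        """One atom at ±1 Å about its mean on x (fit on the static atoms):
        RMSF exactly 1 Å; the fixed atoms read 0."""
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [10.0, 5, 5]])
        f0, f1 = base.copy(), base.copy()
        f0[3, 0] += 1.0
        f1[3, 0] -= 1.0
        traj = Trajectory(times=np.array([0.0, 1.0]), coords=np.stack([f0, f1]))
        vals = rmsf(traj, np.arange(4), fit_selection=np.arange(3))
        np.testing.assert_allclose(vals[:3], 0.0, atol=1e-9)
        assert vals[3] == pytest.approx(1.0, rel=1e-9)

    def test_rigid_body_motion_fits_away(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 4, 0], [1, 1, 2]])
        rng = np.random.default_rng(3)
        frames = [base]
        for _ in range(5):
            rot = Rotation.random(rng=rng).as_matrix()
            frames.append(base @ rot.T + rng.uniform(-3, 3, 3))
        traj = Trajectory(times=np.arange(6.0), coords=np.array(frames))
        np.testing.assert_allclose(rmsf(traj, np.arange(4)), 0.0, atol=1e-9)


class TestDistances:
    def test_pythagorean_pair(self, toy_peptide):
        coords = np.array([a.position for a in toy_peptide.atoms])
        coords[0] = [0.0, 0, 0]
        coords[2] = [3.0, 4, 0]  # CA of residue 2
        traj = Trajectory(times=np.array([0.0]), coords=coords[None])
        (series,) = named_distances(traj, toy_peptide,
                                    [(("A", 1, "CA"), ("A", 2, "CA"))])
        assert series.values[0] == pytest.approx(5.0)

    def test_unresolvable_atom_named_in_error(self, toy_peptide):
        coords = np.array([a.position for a in toy_peptide.atoms])[None]
        traj = Trajectory(times=np.array([0.0]), coords=coords)
        with pytest.raises(KeyError, match="CG"):
            named_distances(traj, toy_peptide, [(("A", 1, "CG"),
                                                 ("A", 2, "CA"))])

    def test_min_distance_bounds_named_pairs(self, toy_peptide):
        coords = np.array([a.position for a in toy_peptide.atoms])[None]
        traj = Trajectory(times=np.array([0.0]), coords=coords)
        mind = min_distance(traj, np.array([0, 1]), np.array([4, 5]))
        (named,) = named_distances(traj, toy_peptide,
                                   [(("A", 1, "CA"), ("A", 3, "CA"))])
        assert mind.values[0] <= named.values[0] + 1e-12


class TestWindowing:
    def test_discard_fraction_of_trajectory(self):
        traj = Trajectory(times=np.arange(100.0),
                          coords=np.zeros((100, 2, 3)))
        kept = discard_equilibration(traj, 0.10)
        assert kept.n_frames == 90
        assert kept.times[0] == 10.0

    def test_moving_average_of_constant_is_unchanged(self):
        s = TimeSeries(times=np.arange(50.0), values=np.full(50, 2.5), unit="A")
        out = moving_average(s, 10.0)
        np.testing.assert_allclose(out.values, 2.5)

    def test_moving_average_kills_alternating_signal(self):
        s = TimeSeries(times=np.arange(40.0),
                       values=np.tile([1.0, -1.0], 20), unit="A")
        out = moving_average(s, 2.0)
        np.testing.assert_allclose(out.values[1:-1], 0.0, atol=1e-12)

    def test_window_larger_than_span_rejected(self):
        s = TimeSeries(times=np.arange(10.0), values=np.zeros(10), unit="A")
        with pytest.raises(ValueError, match="window"):
            moving_average(s, 100.0)

    def test_equilibrium_statistics_stable_across_discard_fractions(self):
        """Mean of a converged series varies < 1% for discards 0.05-0.15."""
        rng = np.random.default_rng(5)
        s = TimeSeries(times=np.arange(20_000.0),
                       values=10.0 + rng.standard_normal(20_000), unit="A")
        means = [discard_equilibration(s, f).values.mean()
                 for f in (0.05, 0.10, 0.15)]
        assert (max(means) - min(means)) / np.mean(means) < 0.01
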