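"""Pairwise forces: unit oracles, brute-force equivalence, block errors and
the state-difference table."""

import numpy as np
import pytest
from scipy import constants

from pepedit import (
    BeadComplexSpec, NonbondedParams, PairForce, PairForceTable,
    atom_pair_force, bead_complex, block_error, delta_force_table,
    residue_pair_forces,
)


def brute_force_residue_table(traj, topology, group1, group2, cutoff=10.0):
    """Independent oracle: plain double loop over atoms and frames with its
    own unit constants, no vectorization, no neighbor structures."""
    ke = (constants.e ** 2 / (4 * np.pi * constants.epsilon_0)
          * constants.Avogadro / 1e3 / 1e-9)
    pn = 1e3 / constants.Avogadro / 1e-9 * 1e12
    sums: dict = {}
    for f in range(traj.n_frames):
        frame_sum: dict = {}
        for i in group1:
            for j in group2:
                ai, aj = topology.atoms[i], topology.atoms[j]
                r_ang = float(np.linalg.norm(traj.coords[f, j] - traj.coords[f, i]))
                if r_ang > cutoff:
                    continue
                r = r_ang / 10.0
                q = topology.charges[i] * topology.charges[j]
                sig = 0.5 * (topology.lj_sigma[i] + topology.lj_sigma[j])
                eps = float(np.sqrt(topology.lj_epsilon[i] * topology.lj_epsilon[j]))
                coul = ke * q / r ** 2
                lj = 4 * eps * (12 * sig ** 12 / r ** 13 - 6 * sig ** 6 / r ** 7)
                key = ((ai.chain_id, ai.residue_index, ai.residue_name),
                       (aj.chain_id, aj.residue_index, aj.residue_name))
                frame_sum[key] = frame_sum.get(key, 0.0) + (coul + lj) * pn
        for key, v in frame_sum.items():
            sums.setdefault(key, []).append(v)
    n = traj.n_frames
    return {key: sum(vals + [0.0] * (n - len(vals))) / n
            for key, vals in sums.items()}


class TestAtomPairForce:
    def test_zero_beyond_cutoff(self):
        f, vec = atom_pair_force(np.array([10.5, 0, 0]), 1.0, 1.0, 0.3, 0.5)
        assert f == 0.0
        np.testing.assert_array_equal(vec, 0.0)

    def test_coulomb_unit_conversion_oracle(self):
        """Two +1 e charges at exactly 1 nm: the scalar equals k_e/1 nm²
        converted to pN with independently computed constants."""
        ke = (constants.e ** 2 / (4 * np.pi * constants.epsilon_0)
              * constants.Avogadro / 1e3 / 1e-9)
        pn_per = 1e3 / constants.Avogadro / 1e-9 * 1e12
        f, vec = atom_pair_force(np.array([10.0, 0, 0]), 1.0, 1.0, 0.0, 0.0)
        assert ke == pytest.approx(138.935458, rel=1e-6)
        assert pn_per == pytest.approx(1.66054, rel=1e-5)
        assert f == pytest.approx(ke * pn_per, rel=1e-12)
        assert f > 0  # like charges repel
        np.testing.assert_allclose(vec, [f, 0, 0])

    def test_lj_minimum_is_force_free(self):
        sigma = 0.32
        r = 2 ** (1 / 6) * sigma * 10.0  # Å
        f, _ = atom_pair_force(np.array([r, 0, 0]), 0.0, 0.0, sigma, 0.7)
        assert f == pytest.approx(0.0, abs=1e-10)

    def test_opposite_charges_attract(self):
        f, _ = atom_pair_force(np.array([8.0, 0, 0]), 1.0, -1.0, 0.0, 0.0)
        assert f < 0

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(ValueError, match="verlap"):
            atom_pair_force(np.array([1e-5, 0, 0]), 1.0, 1.0, 0.0, 0.0)


class TestResiduePairForces:
    def test_single_opposite_charge_pair_matches_coulomb(self):
        """Two opposite unit charges 10 Å apart: one attractive pair whose
        magnitude is the analytic Coulomb force."""
        spec = BeadComplexSpec(
            positions_a=[[0.0, 0, 0]], positions_b=[[10.0, 0, 0]],
            charges_a=[1.0], charges_b=[-1.0],
            sigma_a=[0.0], sigma_b=[0.0], epsilon_a=[0.0], epsilon_b=[0.0])
        top, traj = bead_complex(spec)
        table = residue_pair_forces(traj, top, np.array([0]), np.array([1]))
        assert len(table.pairs) == 1
        ke = (constants.e ** 2 / (4 * np.pi * constants.epsilon_0)
              * constants.Avogadro / 1e3 / 1e-9)
        expected = -ke * (1e3 / constants.Avogadro / 1e-9 * 1e12)
        assert table.pairs[0].F_mean == pytest.approx(expected, rel=1e-12)
        assert table.pairs[0].F_mean < 0  # attractive

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_matches_brute_force_oracle(self, seed):
        """Seeded 5x5-bead complexes equal the double-loop oracle to
        1e-9 relative, across seeds."""
        rng = np.random.default_rng(seed)
        spec = BeadComplexSpec(
            positions_a=rng.uniform(0, 8, (5, 3)),
            positions_b=rng.uniform(0, 8, (5, 3)) + [0.0, 0.0, 6.0],
            charges_a=rng.uniform(-1, 1, 5), charges_b=rng.uniform(-1, 1, 5),
            sigma_a=rng.uniform(0.25, 0.4, 5), sigma_b=rng.uniform(0.25, 0.4, 5),
            epsilon_a=rng.uniform(0.1, 1.0, 5), epsilon_b=rng.uniform(0.1, 1.0, 5),
            jitter=0.3, n_frames=4, seed=seed + 100)
        top, traj = bead_complex(spec)
        g1, g2 = np.arange(5), np.arange(5, 10)
        table = residue_pair_forces(traj, top, g1, g2)
        oracle = brute_force_residue_table(traj, top, g1, g2)
        assert len(table.pairs) == len(oracle)
        for p in table.pairs:
            assert p.F_mean == pytest.approx(
                oracle[(p.residue_a, p.residue_b)], rel=1e-9)

    def test_group_swap_transposes_table(self, seeded_bead_complex):
        """Newton's third law at residue level: swapping the groups yields
        the transposed table with identical scalars."""
        _, top, traj = seeded_bead_complex
        g1, g2 = np.arange(5), np.arange(5, 10)
        fwd = residue_pair_forces(traj, top, g1, g2)
        rev = residue_pair_forces(traj, top, g2, g1)
        fwd_map = {(p.residue_a, p.residue_b): p.F_mean for p in fwd.pairs}
        rev_map = {(p.residue_b, p.residue_a): p.F_mean for p in rev.pairs}
        assert fwd_map.keys() == rev_map.keys()
        for k in fwd_map:
            assert fwd_map[k] == pytest.approx(rev_map[k], rel=1e-12)

    def test_out_of_cutoff_pairs_absent(self):
        spec = BeadComplexSpec(
            positions_a=[[0.0, 0, 0]], positions_b=[[50.0, 0, 0]],
            charges_a=[1.0], charges_b=[-1.0],
            sigma_a=[0.3], sigma_b=[0.3], epsilon_a=[0.5], epsilon_b=[0.5])
        top, traj = bead_complex(spec)
        table = residue_pair_forces(traj, top, np.array([0]), np.array([1]))
        assert table.pairs == []

    def test_threshold_monotonicity(self, seeded_bead_complex):
        """Raising the report threshold never adds rows."""
        _, top, traj = seeded_bead_complex
        g1, g2 = np.arange(5), np.arange(5, 10)
        sizes = [
            len(residue_pair_forces(traj, top, g1, g2, threshold=t).pairs)
            for t in (0.0, 50.0, 200.0, 1000.0)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_overlapping_groups_rejected(self, seeded_bead_complex):
        _, top, traj = seeded_bead_complex
        with pytest.raises(ValueError, match="overlap"):
            residue_pair_forces(traj, top, np.arange(5), np.arange(4, 10))

    def test_missing_parameters_rejected(self, toy_peptide):
        from pepedit import Trajectory

        coords = np.array([a.position for a in toy_peptide.atoms])[None]
        traj = Trajectory(times=np.array([0.0]), coords=coords)
        with pytest.raises(ValueError, match="parameters"):
            residue_pair_forces(traj, toy_peptide, np.array([0]), np.array([2]))


class TestBlockError:
    def test_constant_series_is_zero(self):
        assert block_error(np.full(100, 3.7)) == 0.0

    def test_iid_gaussian_matches_standard_error(self):
        """White noise, n = 10 000: block error within 20% of sigma/sqrt(n)."""
        rng = np.random.default_rng(0)
        s = rng.standard_normal(10_000)
        expected = 1.0 / np.sqrt(10_000)
        assert block_error(s) == pytest.approx(expected, rel=0.2)

    def test_correlated_series_exceeds_naive_error(self):
        """AR(1) noise with strong autocorrelation: the block estimate is
        larger than the naive i.i.d. standard error."""
        rng = np.random.default_rng(1)
        phi, n = 0.95, 20_000
        eps = rng.standard_normal(n)
        s = np.empty(n)
        s[0] = eps[0]
        for t in range(1, n):
            s[t] = phi * s[t - 1] + np.sqrt(1 - phi ** 2) * eps[t]
        naive = np.std(s, ddof=1) / np.sqrt(n)
        assert block_error(s) > 2 * naive

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_error(np.array([1.0, 2.0, 3.0]))


class TestDeltaForceTable:
    def _pair(self, f, err, a=("T", 193, "LYS"), b=("A", 122, "ASP")):
        return PairForce(residue_a=a, residue_b=b, F_mean=f, F_err=err,
                         n_frames=10)

    def test_printed_state_forces_give_published_delta(self):
        """F_PD = −532 ± 22 and F_PL = −298 ± 38 pN for the K193–D122 salt
        bridge combine to ΔF = 234 ± 60 pN (linear error sum)."""
        t_pd = PairForceTable(pairs=[self._pair(-532.0, 22.0)])
        t_pl = PairForceTable(pairs=[self._pair(-298.0, 38.0)])
        rows = delta_force_table(t_pd, t_pl)
        assert rows[0].delta == pytest.approx(234.0)
        assert rows[0].delta_err == pytest.approx(60.0)

    def test_identical_tables_give_zero_delta(self, seeded_bead_complex):
        _, top, traj = seeded_bead_complex
        g1, g2 = np.arange(5), np.arange(5, 10)
        t = residue_pair_forces(traj, top, g1, g2)
        for row in delta_force_table(t, t):
            assert row.delta == 0.0

    def test_pair_in_one_state_keeps_value_marks_delta_absent(self):
        t_pd = PairForceTable(pairs=[])
        t_pl = PairForceTable(pairs=[self._pair(-225.0, 18.0)])
        rows = delta_force_table(t_pd, t_pl)
        assert rows[0].F_pd is None
        assert rows[0].F_pl == pytest.approx(-225.0)
        assert rows[0].delta is None

    def test_group_mismatch_rejected(self):
        t1 = PairForceTable(pairs=[], group1_label="x")
        t2 = PairForceTable(pairs=[], group1_label="y")
        with pytest.raises(ValueError, match="group"):
            delta_force_table(t1, t2)
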