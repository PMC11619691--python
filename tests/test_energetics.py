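"""Trajectory statistics and free-energy estimation."""

import itertools
import math

import numpy as np
import pytest

from hcquant._util import R_KCAL, kt
from hcquant.energetics import (FreeEnergyLeg,
                                TrajectoryFrames, WindowWorkSamples,
                                aggregate_protomers, bar_estimator,
                                combine_leg, contact_fraction, estimate_leg,
                                exp_estimator, fold_change, rmsd_series,
                                thermo_cycle)
from hcquant.synthdata import gen_fep_samples, gen_toy_trajectory

KT310 = kt(310.0)


def brute_force_fraction(traj, sel_a, sel_b, cutoff):
    """Independent oracle: all-pairs heavy-atom distances per frame."""
    ma = traj.select(**sel_a)
    mb = traj.select(**sel_b)
    hits = 0
    for f in range(traj.n_frames):
        dmin = min(
            math.dist(traj.coords[f, i], traj.coords[f, j])
            for i in np.flatnonzero(ma) for j in np.flatnonzero(mb))
        hits += dmin < cutoff
    return hits / traj.n_frames


SEL_A = {"chain": "A", "res_number": 178}
SEL_B = {"chain": "H", "res_number": 56}


class TestContactFraction:
    def test_prescribed_schedule_seven_of_ten(self):
        schedule = [True] * 7 + [False] * 3
        traj = gen_toy_trajectory(schedule, seed=3)
        res = contact_fraction(traj, SEL_A, SEL_B)
        assert res.fraction == pytest.approx(0.7)
        assert res.fraction == pytest.approx(
            brute_force_fraction(traj, SEL_A, SEL_B, 3.0))

    @pytest.mark.parametrize("schedule,expected", [
        ([False] * 6, 0.0),
        ([True] * 6, 1.0),
    ])
    def test_degenerate_schedules(self, schedule, expected):
        traj = gen_toy_trajectory(schedule, seed=0)
        assert contact_fraction(traj, SEL_A, SEL_B).fraction == expected

    def test_matches_brute_force_on_random_trajectories(self, rng):
        for _ in range(5):
            schedule = rng.random(12) < 0.5
            traj = gen_toy_trajectory(schedule, seed=int(rng.integers(1e6)))
            res = contact_fraction(traj, SEL_A, SEL_B)
            assert res.fraction == pytest.approx(
                brute_force_fraction(traj, SEL_A, SEL_B, 3.0))

    def test_zero_cutoff_strict_inequality(self):
        traj = gen_toy_trajectory([True] * 5, seed=1)
        assert contact_fraction(traj, SEL_A, SEL_B, cutoff=0.0).fraction == 0.0

    def test_monotone_in_cutoff(self):
        traj = gen_toy_trajectory([True, False] * 5, seed=2)
        fracs = [contact_fraction(traj, SEL_A, SEL_B, cutoff=c).fraction
                 for c in (1.0, 2.6, 4.6, 10.0)]
        assert fracs == sorted(fracs)

    def test_hydrogens_excluded(self):
        # one H pair at 2.0 A while the closest heavy pair sits at 4.0 A:
        # heavy-atom contact analysis must report a non-contact
        import pandas as pd
        atoms = pd.DataFrame({
            "chain": ["A", "A", "B", "B"],
            "res_number": [1, 1, 2, 2],
            "res_name": ["ALA"] * 4,
            "atom_name": ["CA", "HA", "CA", "HA"],
            "is_hydrogen": [False, True, False, True],
        })
        coords = np.array([[[0, 0, 0], [1, 0, 0], [4, 0, 0], [3, 0, 0]]],
                          dtype=float)
        traj = TrajectoryFrames(atoms=atoms, coords=coords)
        res = contact_fraction(traj, {"chain": "A"}, {"chain": "B"})
        assert res.fraction == 0.0

    def test_coincident_selections_full_contact(self):
        import pandas as pd
        atoms = pd.DataFrame({
            "chain": ["A", "B"], "res_number": [1, 2],
            "res_name": ["ALA", "ALA"], "atom_name": ["CA", "CA"],
            "is_hydrogen": [False, False]})
        coords = np.zeros((4, 2, 3))
        traj = TrajectoryFrames(atoms=atoms, coords=coords)
        assert contact_fraction(traj, {"chain": "A"},
                                {"chain": "B"}).fraction == 1.0

    def test_empty_and_overlapping_selections_rejected(self):
        traj = gen_toy_trajectory([True] * 4, seed=0)
        with pytest.raises(ValueError, match="non-empty"):
            contact_fraction(traj, {"chain": "Z"}, SEL_B)
        with pytest.raises(ValueError, match="disjoint"):
            contact_fraction(traj, {"chain": "A"}, SEL_A)


class TestRmsd:
    def rigid(self, coords, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        a = rng.uniform(0, 2 * np.pi)
        k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
        return coords @ rot.T + rng.uniform(-10, 10, 3)

    def test_identical_frames_zero(self):
        traj = gen_toy_trajectory([True] * 3, seed=0)
        coords = np.repeat(traj.coords[:1], 3, axis=0)
        same = TrajectoryFrames(atoms=traj.atoms, coords=coords)
        np.testing.assert_allclose(rmsd_series(same, align=False), 0.0)

    def test_rigid_copy_zero_after_alignment(self, rng):
        traj = gen_toy_trajectory([True] * 2, seed=5)
        base = traj.coords[0]
        coords = np.stack([base, self.rigid(base, rng)])
        moved = TrajectoryFrames(atoms=traj.atoms, coords=coords)
        assert rmsd_series(moved, align=True)[1] < 1e-9

    def test_four_atom_displacement_hand_computed(self):
        import pandas as pd
        atoms = pd.DataFrame({
            "chain": ["A"] * 4, "res_number": [1] * 4,
            "res_name": ["ALA"] * 4,
            "atom_name": ["N", "CA", "C", "O"],
            "is_hydrogen": [False] * 4})
        f0 = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]],
                      dtype=float)
        f1 = f0.copy()
        f1[2, 1] += 2.0  # one atom displaced by 2 A
        traj = TrajectoryFrames(atoms=atoms, coords=np.stack([f0, f1]))
        series = rmsd_series(traj, align=False)
        assert series[1] == pytest.approx(2.0 / math.sqrt(4))

    def test_invariant_under_rigid_transform_of_whole_trajectory(self, rng):
        traj = gen_toy_trajectory([True, False, True, False], seed=9)
        ref = rmsd_series(traj, align=True)
        moved = TrajectoryFrames(
            atoms=traj.atoms,
            coords=np.stack([self.rigid(f, rng) for f in traj.coords]))
        np.testing.assert_allclose(rmsd_series(moved, align=True), ref,
                                   atol=1e-9)

    def test_collinear_atoms_rejected_for_alignment(self):
        import pandas as pd
        atoms = pd.DataFrame({
            "chain": ["A"] * 3, "res_number": [1] * 3,
            "res_name": ["ALA"] * 3, "atom_name": ["N", "CA", "C"],
            "is_hydrogen": [False] * 3})
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
        traj = TrajectoryFrames(atoms=atoms,
                                coords=np.stack([line, line + 1.0]))
        with pytest.raises(ValueError, match="collinear"):
            rmsd_series(traj, align=True)


class TestExpEstimator:
    def test_constant_work(self):
        assert exp_estimator(np.full(10, 1.5), 310.0) == pytest.approx(1.5)

    def test_single_sample_identity(self):
        assert exp_estimator(np.array([0.37]), 310.0) == pytest.approx(0.37)

    def test_gaussian_closed_form(self, rng):
        # W ~ N(2, 1) in kT units -> dG -> mu - sigma^2/2 = 1.5 kT
        n = 200_000
        w_kt = rng.normal(2.0, 1.0, n)
        dg = exp_estimator(w_kt * KT310, 310.0) / KT310
        se = 3.0 / math.sqrt(n)  # generous bound on the estimator s.e.
        assert dg == pytest.approx(1.5, abs=3 * se + 0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            exp_estimator(np.array([]), 310.0)


def bar_grid_oracle(wf, wr, temperature, lo, hi):
    """Brute-force grid/bisection solution of the self-consistent equation."""
    from scipy.special import expit
    beta = 1.0 / kt(temperature)
    m = math.log(len(wf) / len(wr))

    def g(dg):
        return (expit(-(beta * (wf - dg) + m)).sum()
                - expit(-(beta * (wr + dg) - m)).sum())

    grid = np.linspace(lo, hi, 20001)
    vals = np.array([g(x) for x in grid])
    i = int(np.argmin(np.abs(vals)))
    a, b = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    for _ in range(80):  # bisection to ~1e-20 interval
        mid = 0.5 * (a + b)
        if g(a) * g(mid) <= 0:
            b = mid
        else:
            a = mid
    return 0.5 * (a + b)


class TestBarEstimator:
    def test_symmetric_point_masses(self):
        dg, _ = bar_estimator(np.full(50, 1.0), np.full(50, -1.0), 310.0,
                              n_boot=0)
        assert dg == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetry_under_direction_swap(self, rng):
        # with reverse work stored as the work of the reverse
        # transformation (Crooks convention of the generator), exchanging
        # the two sample sets negates the free energy, and additionally
        # negating both leaves it invariant (f(-x) = 1 - f(x))
        wf = rng.normal(1.2, 0.5, 400)
        wr = rng.normal(-0.8, 0.5, 400)
        dg_fwd, _ = bar_estimator(wf, wr, 310.0, n_boot=0)
        dg_swap, _ = bar_estimator(wr, wf, 310.0, n_boot=0)
        dg_swap_neg, _ = bar_estimator(-wr, -wf, 310.0, n_boot=0)
        assert dg_swap == pytest.approx(-dg_fwd, abs=5e-9)
        assert dg_swap_neg == pytest.approx(dg_fwd, abs=5e-9)

    def test_crooks_gaussian_recovery_within_three_se(self):
        # true dG = 1 kT, sigma^2 = 1 kT^2, n = 1e4 per direction
        dg_true = KT310
        samples = gen_fep_samples([dg_true], work_sd=KT310,
                                  n_samples=10_000, temperature=310.0,
                                  seed=11)
        dg, se = bar_estimator(samples.forward[0], samples.reverse[0],
                               310.0, n_boot=100, seed=1)
        assert se > 0
        assert abs(dg - dg_true) < 3 * se

    def test_matches_grid_oracle(self, rng):
        wf = rng.normal(0.9, 0.3, 200)
        wr = rng.normal(-0.7, 0.3, 200)
        dg, _ = bar_estimator(wf, wr, 310.0, n_boot=0)
        oracle = bar_grid_oracle(wf, wr, 310.0, -2.0, 3.0)
        assert dg == pytest.approx(oracle, abs=1e-6)

    def test_unequal_sample_counts(self, rng):
        wf = rng.normal(0.5, 0.2, 300)
        wr = rng.normal(-0.5, 0.2, 120)
        dg, _ = bar_estimator(wf, wr, 310.0, n_boot=0)
        oracle = bar_grid_oracle(wf, wr, 310.0, -1.0, 2.0)
        assert dg == pytest.approx(oracle, abs=1e-6)

    def test_bar_no_worse_than_exp_on_crooks_gaussian(self):
        # at equal n, the two-sided estimator should beat one-sided EXP
        dg_true = KT310
        bar_err, exp_err = [], []
        for seed in range(12):
            s = gen_fep_samples([dg_true], work_sd=2.0 * KT310,
                                n_samples=400, temperature=310.0, seed=seed)
            dg_bar, _ = bar_estimator(s.forward[0], s.reverse[0], 310.0,
                                      n_boot=0)
            dg_exp = exp_estimator(s.forward[0], 310.0)
            bar_err.append((dg_bar - dg_true) ** 2)
            exp_err.append((dg_exp - dg_true) ** 2)
        assert np.mean(bar_err) <= np.mean(exp_err)


class TestLegAndCycle:
    def test_thirty_two_windows_of_005(self):
        leg = combine_leg([(0.05, 0.0)] * 32)
        assert leg.dg == pytest.approx(1.6)

    def test_single_window_identity(self):
        leg = combine_leg([(0.4, 0.1)])
        assert (leg.dg, leg.se) == (0.4, 0.1)

    def test_mixed_signs(self):
        assert combine_leg([(0.5, 0), (-0.2, 0), (0.1, 0)]).dg == \
            pytest.approx(0.4)

    def test_se_in_quadrature(self):
        leg = combine_leg([(0.0, 3.0), (0.0, 4.0)])
        assert leg.se == pytest.approx(5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            combine_leg([])

    @pytest.mark.parametrize("dgc,dgf,expected", [
        (2.00, 0.68, 1.32),
        (1.0, 1.0, 0.0),
        (0.5, 1.0, -0.5),
    ])
    def test_thermo_cycle(self, dgc, dgf, expected):
        cplx = FreeEnergyLeg("complex", dgc, 0.0, [])
        free = FreeEnergyLeg("free", dgf, 0.0, [])
        ddg, _ = thermo_cycle(cplx, free)
        assert ddg == pytest.approx(expected)

    def test_estimate_leg_exact_on_deterministic_work(self):
        samples = gen_fep_samples([0.05] * 32, work_sd=0.0, n_samples=5,
                                  temperature=310.0, seed=0)
        leg = estimate_leg(samples, n_boot=0)
        assert leg.dg == pytest.approx(1.6, abs=1e-7)


class TestProtomerAggregation:
    def test_printed_per_protomer_values_sum(self):
        agg = aggregate_protomers([1.43, 0.50, -0.37, 0, 0, 0])
        assert agg.total_ddg == pytest.approx(1.56)

    def test_all_zero(self):
        agg = aggregate_protomers([0.0] * 6)
        assert agg.total_ddg == 0.0
        assert agg.fold_change == pytest.approx(1.0)
        assert agg.fold_change_power_of_ten == 1

    def test_total_132_gives_tenfold(self):
        agg = aggregate_protomers([1.32, 0, 0, 0, 0, 0], temperature=310.0)
        assert agg.fold_change == pytest.approx(
            math.exp(1.32 / (R_KCAL * 310.0)), rel=1e-12)
        assert agg.fold_change == pytest.approx(8.52, abs=0.01)
        assert agg.fold_change_power_of_ten == 10

    def test_permutation_invariance(self, rng):
        vals = rng.normal(0, 1, 6)
        totals = {aggregate_protomers(list(p)).total_ddg
                  for p in itertools.islice(
                      itertools.permutations(vals), 24)}
        assert max(totals) - min(totals) < 1e-12

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="six"):
            aggregate_protomers([1.0] * 5)


class TestFoldChange:
    def test_zero_ddg_unity(self):
        assert fold_change(0.0, 310.0) == 1.0
        assert fold_change(0.0, 298.0) == 1.0

    def test_reciprocal_symmetry(self):
        x = 0.73
        assert fold_change(-x, 310.0) == pytest.approx(
            1.0 / fold_change(x, 310.0), rel=1e-12)

    def test_printed_value(self):
        assert fold_change(1.32, 310.0) == pytest.approx(8.52, abs=0.01)


class TestWorkSamplesContainer:
    def test_frame_roundtrip(self):
        samples = gen_fep_samples([0.1, -0.2], work_sd=0.3, n_samples=8,
                                  temperature=310.0, seed=5)
        back = WindowWorkSamples.from_frame(samples.to_frame())
        assert back.n_windows == 2
        for i in range(2):
            np.testing.assert_allclose(back.forward[i], samples.forward[i])
            np.testing.assert_allclose(back.reverse[i], samples.reverse[i])

    def test_minimum_samples_enforced(self):
        with pytest.raises(ValueError, match=">= 2"):
            WindowWorkSamples(forward=[np.array([1.0])],
                              reverse=[np.array([1.0, 2.0])],
                              temperature=310.0)


class TestPdbRoundtrip:
    def test_multi_model_pdb_preserves_contacts(self, tmp_path):
        schedule = [True, False, True, True]
        traj = gen_toy_trajectory(schedule, seed=4)
        path = tmp_path / "toy.pdb"
        traj.to_pdb(path)
        back = TrajectoryFrames.from_pdb(path)
        assert back.n_frames == 4
        # PDB stores 3 decimals; distances survive far beyond the margin
        # between the 2.5 A contact and 4.5 A apart geometries
        res = contact_fraction(back, SEL_A, SEL_B)
        assert res.fraction == pytest.approx(0.75)
        np.testing.assert_allclose(back.coords, traj.coords, atol=2e-3)
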