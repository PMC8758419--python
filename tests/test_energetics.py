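"""PMF post-processing, interaction energies, pose clustering, ligand math."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2

import poregate as pg
from poregate.constants import KJ_PER_KCAL


def _table(z, dg):
    return pg.ProfileTable(z=np.asarray(z, dtype=float),
                           columns={"dg": np.asarray(dg, dtype=float)},
                           metadata={"units": "kJ/mol"})


class TestAveragePmf:
    Z = np.arange(-30.0, 0.0, 1.0)

    def test_identical_profiles_have_zero_error(self):
        base = np.sin(self.Z / 5.0)
        avg = pg.average_pmf([_table(self.Z, base)] * 10)
        np.testing.assert_allclose(avg.dg, base)
        np.testing.assert_allclose(avg.err, 0.0, atol=1e-12)
        assert avg.reference == "raw"

    def test_mean_and_sd_hand_arithmetic(self):
        avg = pg.average_pmf([_table([0.0, 1.0], [0.0, 0.0]),
                              _table([0.0, 1.0], [2.0, 2.0])])
        np.testing.assert_allclose(avg.dg, 1.0)
        np.testing.assert_allclose(avg.err, 1.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            pg.average_pmf([_table([0.0, 1.0], [0.0, 0.0]),
                            _table([0.0, 2.0], [0.0, 0.0])])

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError):
            pg.average_pmf([_table([0.0, 1.0], [0.0, 0.0])])

    def test_window_sd_within_chisquare_band(self):
        """10 windows of sigma=0.5 noise: per-bin SD inside the central
        chi-square band [0.25, 0.9] at >= 95% of bins."""
        z = np.arange(-50.0, 50.0, 1.0)
        base = _table(z, np.zeros_like(z))
        windows = pg.make_pmf_windows(base, n_windows=10, noise_sd=0.5, seed=77)
        avg = pg.average_pmf(windows)
        inside = (avg.err >= 0.25) & (avg.err <= 0.9)
        assert inside.mean() >= 0.95
        # the band itself covers the analytic chi-square 95% interval (n=10)
        lo = 0.5 * np.sqrt(chi2.ppf(0.025, df=9) / 10)
        hi = 0.5 * np.sqrt(chi2.ppf(0.975, df=9) / 10)
        assert 0.25 <= lo and hi <= 0.9


class TestShiftReference:
    def test_anchor_bin_becomes_zero(self):
        prof = pg.average_pmf([_table([0.0, 1.0, 2.0], [5.0, 7.0, 9.0])] * 2)
        shifted = pg.shift_reference(prof, "bilayer_center", 0.0)
        np.testing.assert_allclose(shifted.dg, [0.0, 2.0, 4.0])
        assert shifted.reference == "bilayer_center"
        np.testing.assert_array_equal(shifted.err, prof.err)

    def test_idempotent_for_fixed_anchor(self):
        prof = pg.average_pmf([_table([0.0, 1.0], [5.0, 7.0])] * 2)
        once = pg.shift_reference(prof, "bulk", 1.0)
        twice = pg.shift_reference(once, "bulk", 1.0)
        np.testing.assert_array_equal(once.dg, twice.dg)

    def test_barrier_invariant_under_shift(self):
        z = np.arange(-20.0, 0.0, 1.0)
        dg = 10.0 * np.exp(-((z + 10.0) ** 2) / 8.0)
        prof = pg.average_pmf([_table(z, dg)] * 2)
        b0 = pg.barrier_height(prof, (-15.0, -5.0))
        b1 = pg.barrier_height(pg.shift_reference(prof, "bulk", -1.0), (-15.0, -5.0))
        assert b0.height == pytest.approx(b1.height, abs=1e-12)

    def test_anchor_outside_grid_rejected(self):
        prof = pg.average_pmf([_table([0.0, 1.0], [5.0, 7.0])] * 2)
        with pytest.raises(ValueError):
            pg.shift_reference(prof, "bulk", 50.0)


class TestBarrierHeight:
    def test_flat_profile_has_zero_barrier(self):
        prof = pg.average_pmf([_table(np.arange(10.0), np.full(10, 3.0))] * 2)
        assert pg.barrier_height(prof, (2.0, 8.0)).height == 0.0

    def test_gaussian_bump_recovers_amplitude(self):
        z = np.arange(-30.0, 30.0, 0.5)
        amp = 104.6  # 25 kcal/mol in kJ/mol
        prof = pg.average_pmf([_table(z, amp * np.exp(-((z + 10) ** 2) / 18.0))] * 2)
        barrier = pg.barrier_height(prof, (-20.0, 0.0))
        assert barrier.height == pytest.approx(amp, rel=1e-3)
        assert barrier.height_kcal == pytest.approx(25.0, rel=1e-3)
        assert barrier.z_at_max == pytest.approx(-10.0, abs=0.5)

    def test_tie_reports_smaller_z(self):
        z = np.arange(0.0, 6.0)
        dg = np.array([0.0, 5.0, 0.0, 0.0, 5.0, 0.0])
        barrier = pg.barrier_height(pg.average_pmf([_table(z, dg)] * 2), (0.0, 5.0))
        assert barrier.z_at_max == 1.0

    def test_empty_region_rejected(self):
        prof = pg.average_pmf([_table([0.0, 1.0], [0.0, 0.0])] * 2)
        with pytest.raises(ValueError):
            pg.barrier_height(prof, (10.0, 20.0))


def _two_site_traj(distance):
    """A -1e point site (residue 1) and a Na+ ion at the given separation."""
    coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
    top = pg.Structure([1, 2], ["X", "NA"], ["X", "NA"], ["SIT", "NA"],
                       [1, 2], ["A", "I"], coords)
    return pg.Trajectory(topology=top, frames=coords[None])


class TestInteractionEnergy:
    def test_coulomb_constant_arithmetic(self):
        """q=+1 at 3.0 A from q=-1, LJ zeroed: -138.935/0.3 kJ/mol."""
        traj = _two_site_traj(3.0)
        table = pg.residue_ion_interaction_energy(
            traj, "chain A", "chain I",
            charges=[-1.0, 1.0], sigma=[0.0, 0.0], epsilon=[0.0, 0.0])
        mean, sd = table.energies[("A", 1)]
        assert mean == pytest.approx(-138.935 / 0.3, abs=1e-6)
        assert sd == 0.0

    def test_beyond_cutoff_is_zero(self):
        traj = _two_site_traj(13.0)
        table = pg.residue_ion_interaction_energy(
            traj, "chain A", "chain I",
            charges=[-1.0, 1.0], sigma=[0.0, 0.0], epsilon=[0.0, 0.0], cutoff=12.0)
        assert table.energies[("A", 1)][0] == 0.0

    def test_lj_vanishes_at_sigma(self):
        traj = _two_site_traj(3.0)
        table = pg.residue_ion_interaction_energy(
            traj, "chain A", "chain I",
            charges=[0.0, 0.0], sigma=[3.0, 3.0], epsilon=[1.0, 1.0])
        assert table.energies[("A", 1)][0] == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_under_selection_swap(self):
        traj = _two_site_traj(3.0)
        kwargs = dict(charges=[-1.0, 1.0], sigma=[2.0, 3.0], epsilon=[0.5, 0.2])
        a = pg.residue_ion_interaction_energy(traj, "chain A", "chain I", **kwargs)
        b = pg.residue_ion_interaction_energy(traj, "chain I", "chain A", **kwargs)
        assert a.energies[("A", 1)][0] == pytest.approx(b.energies[("I", 2)][0])

    def test_additive_over_disjoint_residues(self):
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 4.0, 0.0], [3.0, 0.0, 0.0]])
        top = pg.Structure([1, 2, 3], ["X", "Y", "NA"], ["X", "Y", "NA"],
                           ["SIT", "SIT", "NA"], [1, 2, 3], ["A", "A", "I"], coords)
        traj = pg.Trajectory(topology=top, frames=coords[None])
        kwargs = dict(charges=[-1.0, -0.5, 1.0], sigma=[0.0] * 3, epsilon=[0.0] * 3)
        both = pg.residue_ion_interaction_energy(traj, "chain A", "chain I", **kwargs)
        only1 = pg.residue_ion_interaction_energy(traj, "resid 1", "chain I", **kwargs)
        only2 = pg.residue_ion_interaction_energy(traj, "resid 2", "chain I", **kwargs)
        total = both.energies[("A", 1)][0] + both.energies[("A", 2)][0]
        assert total == pytest.approx(only1.energies[("A", 1)][0]
                                      + only2.energies[("A", 2)][0])

    def test_missing_parameter_names_the_atom(self):
        traj = _two_site_traj(3.0)
        with pytest.raises(ValueError, match="NA"):
            pg.residue_ion_interaction_energy(
                traj, "chain A", "chain I",
                charges=[-1.0, np.nan], sigma=[0.0, 0.0], epsilon=[0.0, 0.0])


def _translated_frames(offsets_nm):
    base = np.zeros((4, 3))
    base[:, 0] = [0.0, 1.0, 2.0, 3.0]
    return np.stack([base + np.asarray(o) * 10.0 for o in offsets_nm])


class TestClusterPoses:
    def test_cutoff_splits_far_pose(self):
        frames = _translated_frames([[0.0, 0, 0], [0.05, 0, 0], [0.5, 0, 0]])
        result = pg.cluster_poses(frames, cutoff=0.1)
        assert result.clusters == [[0, 1], [2]]

    def test_identical_frames_form_one_cluster(self):
        frames = _translated_frames([[0.0, 0, 0]] * 5)
        result = pg.cluster_poses(frames, cutoff=0.1)
        assert result.clusters == [[0, 1, 2, 3, 4]]
        assert result.representatives == [0]

    def test_single_linkage_transitivity(self):
        frames = _translated_frames([[0.0, 0, 0], [0.08, 0, 0], [0.16, 0, 0]])
        result = pg.cluster_poses(frames, cutoff=0.1)
        assert result.clusters == [[0, 1, 2]]

    def test_matches_brute_force_connected_components(self):
        """200 random rigid translations: exact agreement with an
        independent union-find over the strict-inequality edge graph."""
        rng = np.random.default_rng(123)
        offsets = rng.uniform(-0.3, 0.3, size=(200, 3))
        frames = _translated_frames(offsets)
        result = pg.cluster_poses(frames, cutoff=0.1)

        parent = list(range(200))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(200):
            for j in range(i + 1, 200):
                rms = np.sqrt(np.mean(np.sum(
                    (frames[i] - frames[j]) ** 2, axis=1))) / 10.0
                if rms < 0.1:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(200):
            groups.setdefault(find(i), []).append(i)
        expected = sorted(groups.values(), key=lambda c: (-len(c), c[0]))
        assert result.clusters == expected

    def test_medoid_is_central_member(self):
        frames = _translated_frames([[0.0, 0, 0], [0.04, 0, 0], [0.08, 0, 0]])
        result = pg.cluster_poses(frames, cutoff=0.1)
        assert result.representatives == [1]

    def test_empty_frames_rejected(self):
        with pytest.raises(ValueError):
            pg.cluster_poses(np.zeros((0, 3, 3)))

    def test_planted_two_cluster_recovery(self):
        ens = pg.make_pose_ensemble([[0.0, 0, 0], [1.0, 0, 0]],
                                    members_per_cluster=[6, 4],
                                    spread_nm=0.02, seed=5)
        result = pg.cluster_poses(ens.frames, cutoff=0.1)
        assert [len(c) for c in result.clusters] == [6, 4]
        assert set(result.clusters[0]) == set(np.nonzero(ens.labels == 0)[0])


class TestLigandIonization:
    def test_flecainide_is_99_percent_charged(self):
        """pKa 9.3 base at physiological pH 7.4: 99% charged, 1% neutral."""
        ion = pg.ionization_fraction(9.3, 7.4, "base")
        assert ion.charged_fraction == pytest.approx(0.9876, abs=5e-4)
        assert round(ion.charged_percent) == 99
        assert round(100 * ion.neutral_fraction) == 1

    def test_ph_equal_pka_is_half(self):
        assert pg.ionization_fraction(7.4, 7.4, "base").charged_fraction == 0.5

    def test_lidocaine_at_7_4(self):
        ion = pg.ionization_fraction(7.56, 7.4, "base")
        assert ion.charged_fraction == pytest.approx(0.591, abs=1e-3)

    def test_acid_mirror(self):
        acid = pg.ionization_fraction(4.0, 7.4, "acid")
        base = pg.ionization_fraction(10.8, 7.4, "base")
        assert acid.charged_fraction == pytest.approx(base.charged_fraction)

    @settings(deadline=None, derandomize=True)
    @given(pka=st.floats(0.0, 14.0), pka2=st.floats(0.0, 14.0))
    def test_fractions_sum_to_one_and_monotone_in_pka(self, pka, pka2):
        a = pg.ionization_fraction(pka, 7.4, "base")
        assert a.charged_fraction + a.neutral_fraction == pytest.approx(1.0)
        b = pg.ionization_fraction(pka2, 7.4, "base")
        if pka < pka2:
            assert a.charged_fraction <= b.charged_fraction

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pg.ionization_fraction(np.nan, 7.4)


class TestLogPToDG:
    def test_charged_lidocaine_partitioning(self):
        """logP 1.49 at 298 K converts to -8.5 kJ/mol."""
        assert pg.logp_to_dg(1.49, 298.0) == pytest.approx(-8.5, abs=0.05)

    def test_zero_logp_is_zero(self):
        assert pg.logp_to_dg(0.0, 310.0) == 0.0

    def test_unit_logp_at_standard_temperature(self):
        assert pg.logp_to_dg(1.0, 298.15) == pytest.approx(-5.708, abs=1e-3)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            pg.logp_to_dg(1.0, 0.0)
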