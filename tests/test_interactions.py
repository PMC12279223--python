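import numpy as np
import pytest
from scipy.spatial.distance import cdist

from httex1 import (
    ConstructSpec,
    CoordEnsemble,
    ResidueSelection,
    SSTrajectory,
    beta_conformers,
    bifurcated_hb_occupancy,
    contact_count,
    contact_map,
    detect_hbonds,
    gen_beta_frames,
    gen_hbond_fixture,
    gen_random_coil_coords,
)


def brute_force_contact_map(coords: CoordEnsemble, cutoff: float) -> np.ndarray:
    """Independent all-pairs oracle with the |i-j|>3 exclusion."""
    n = coords.n_residues()
    acc = np.zeros((n, n))
    heavy = np.flatnonzero(coords.is_heavy)
    by_res = {
        i: [a for a in heavy if coords.residue_index[a] == i] for i in range(1, n + 1)
    }
    for f in range(coords.n_frames):
        xyz = coords.coordinates[f]
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if abs(i - j) <= 3:
                    continue
                if cdist(xyz[by_res[i]], xyz[by_res[j]]).min() <= cutoff:
                    acc[i - 1, j - 1] += 1
    return acc / coords.n_frames


def two_residue_ensemble(distance_nm: float, sep: int = 5) -> CoordEnsemble:
    """Two single-atom residues at a controlled distance, |i-j| = sep."""
    coords = np.zeros((1, 2, 3))
    coords[0, 1, 0] = distance_nm
    return CoordEnsemble(
        coordinates=coords,
        residue_index=np.array([1, 1 + sep]),
        chain_id=np.array(["A", "A"]),
        atom_name=np.array(["CA", "CA"]),
        element=np.array(["C", "C"]),
    )


class TestContactMap:
    def test_matches_brute_force_oracle(self):
        coords = gen_random_coil_coords(12, 5, seed=17)
        cm = contact_map(coords, cutoff=0.6, mode="intra")
        np.testing.assert_array_equal(
            cm.probabilities, brute_force_contact_map(coords, 0.6)
        )

    def test_symmetry(self):
        coords = gen_random_coil_coords(15, 4, seed=23)
        cm = contact_map(coords)
        np.testing.assert_array_equal(cm.probabilities, cm.probabilities.T)

    @pytest.mark.parametrize("d,expect", [(0.59, 1.0), (0.61, 0.0)])
    def test_cutoff_boundary(self, d, expect):
        cm = contact_map(two_residue_ensemble(d))
        assert cm.probabilities[0, 5] == expect

    def test_sequence_separation_exclusion(self):
        # residues 1 and 4 (|i-j|=3) co-located: still never a contact
        cm = contact_map(two_residue_ensemble(0.1, sep=3))
        assert cm.probabilities.sum() == 0

    def test_shrinking_cutoff_never_creates_contacts(self):
        coords = gen_random_coil_coords(10, 3, seed=31)
        wide = contact_map(coords, cutoff=0.6).probabilities
        narrow = contact_map(coords, cutoff=0.4).probabilities
        assert (narrow <= wide).all()

    def test_inter_mode_requires_two_chains(self):
        coords = gen_random_coil_coords(6, 1, seed=1)
        with pytest.raises(ValueError, match="two chains"):
            contact_map(coords, mode="inter")

    def test_inter_mode_symmetric_over_chain_pairs(self):
        from httex1 import DimerGeometryParams, gen_dimer_coords

        ens = gen_dimer_coords(DimerGeometryParams(separation=0.5, n_frames=2))
        cm = contact_map(ens, mode="inter")
        np.testing.assert_allclose(cm.probabilities, cm.probabilities.T)
        assert cm.probabilities.max() > 0


class TestContactCount:
    def test_monotone_in_cutoff(self):
        from httex1 import DimerGeometryParams, gen_dimer_coords

        ens = gen_dimer_coords(DimerGeometryParams(separation=0.6, n_frames=1))
        sa = ResidueSelection("A", 1, 17)
        sb = ResidueSelection("B", 1, 17)
        c_wide = contact_count(ens, sa, sb, cutoff=0.8)
        c_narrow = contact_count(ens, sa, sb, cutoff=0.5)
        assert (c_narrow <= c_wide).all()

    def test_matches_pairwise_oracle(self):
        from httex1 import DimerGeometryParams, gen_dimer_coords

        ens = gen_dimer_coords(DimerGeometryParams(separation=0.45, n_frames=1))
        sa = ResidueSelection("A", 1, 17)
        sb = ResidueSelection("B", 1, 17)
        got = contact_count(ens, sa, sb, cutoff=0.6)[0]
        a_mask = ens.chain_id == "A"
        expected = 0
        for i in range(1, 18):
            for j in range(1, 18):
                xi = ens.coordinates[0][a_mask & (ens.residue_index == i)]
                xj = ens.coordinates[0][~a_mask & (ens.residue_index == j)]
                if cdist(xi, xj).min() <= 0.6:
                    expected += 1
        assert got == expected

    def test_overlapping_same_chain_selections_rejected(self):
        coords = gen_random_coil_coords(10, 1, seed=3)
        with pytest.raises(ValueError, match="overlap"):
            contact_count(
                coords, ResidueSelection("A", 1, 5), ResidueSelection("A", 4, 8)
            )


class TestBetaConformers:
    def _traj_with_counts(self, counts):
        codes = np.full((len(counts), 38), "C")
        for f, k in enumerate(counts):
            codes[f, 10 : 10 + k] = "E"
        return SSTrajectory(codes)

    def test_strictly_more_than_four(self):
        bset = beta_conformers(self._traj_with_counts([5, 4, 6, 0]))
        assert set(bset.conformers["frame"]) == {0, 2}
        assert bset.population == pytest.approx(0.5)

    def test_exactly_four_never_extracted(self):
        bset = beta_conformers(self._traj_with_counts([4, 4, 4]))
        assert len(bset) == 0

    def test_classification_by_n17_participation(self):
        codes = np.full((2, 38), "C")
        codes[0, 14:20] = "E"  # residues 15-20: touches N17
        codes[1, 20:26] = "E"  # residues 21-26: polyQ only
        bset = beta_conformers(SSTrajectory(codes))
        assert bset.conformers["conformer_class"].tolist() == [
            "n17_direct",
            "polyq_internal",
        ]

    def test_bridge_only_frames_counted_separately(self):
        codes = np.full((3, 38), "C")
        codes[0, 12] = "B"
        bset = beta_conformers(SSTrajectory(codes))
        assert len(bset) == 0
        assert bset.bridge_frames == 1

    def test_recovers_injected_population(self):
        base = SSTrajectory(np.full((10_000, 38), "C"))
        traj = gen_beta_frames(base, 0.02, [(10, 15), (25, 30)], seed=42)
        bset = beta_conformers(traj)
        sigma = np.sqrt(0.02 * 0.98 / 10_000)
        assert abs(bset.population - 0.02) <= 3 * sigma

    def test_estimator_unbiased_over_seeds(self):
        base = SSTrajectory(np.full((2000, 38), "C"))
        pops = [
            beta_conformers(gen_beta_frames(base, 0.02, [(10, 15)], seed=s)).population
            for s in range(10)
        ]
        sigma_mean = np.sqrt(0.02 * 0.98 / 2000) / np.sqrt(10)
        assert abs(np.mean(pops) - 0.02) <= 3 * sigma_mean


class TestBifurcatedHB:
    def test_occupancy_half_when_two_of_four_frames(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 4, {1, 2})
        ss = SSTrajectory(np.full((4, 38), "H"))
        occ = bifurcated_hb_occupancy(hb, ss, sequence=q16_spec.sequence)
        assert occ.occupancy[21] == pytest.approx(0.5)

    def test_zero_when_sidechain_bond_absent(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 4, set())
        ss = SSTrajectory(np.full((4, 38), "H"))
        occ = bifurcated_hb_occupancy(hb, ss, sequence=q16_spec.sequence)
        assert occ.occupancy[21] == 0.0

    def test_zero_when_backbone_bond_absent(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 4, {0, 1, 2, 3})
        ev = hb.events
        hb.events = ev[ev["donor_role"] != "backbone"].reset_index(drop=True)
        ss = SSTrajectory(np.full((4, 38), "H"))
        occ = bifurcated_hb_occupancy(hb, ss, sequence=q16_spec.sequence)
        assert occ.occupancy[21] == 0.0

    def test_helicity_gate_excludes_coil_frames(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 4, {0, 1})
        codes = np.full((4, 38), "H")
        codes[1] = "C"  # frame 1 fails the >30% helicity gate
        occ = bifurcated_hb_occupancy(
            hb, SSTrajectory(codes), sequence=q16_spec.sequence
        )
        # 3 eligible frames, only frame 0 retains both bonds
        assert occ.eligible_frames == 3
        assert occ.occupancy[21] == pytest.approx(1 / 3)

    def test_all_coil_flagged_undefined(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 4, {0})
        ss = SSTrajectory(np.full((4, 38), "C"))
        with pytest.warns(UserWarning, match="helicity gate"):
            occ = bifurcated_hb_occupancy(hb, ss)
        assert np.isnan(occ.occupancy).all()
        assert occ.eligible_frames == 0

    def test_prevalence_threshold(self, q16_spec):
        hb = gen_hbond_fixture(q16_spec, 100, set(range(6)))
        ss = SSTrajectory(np.full((100, 38), "H"))
        occ = bifurcated_hb_occupancy(hb, ss, sequence=q16_spec.sequence)
        assert occ.occupancy[21] == pytest.approx(0.06)
        assert occ.prevalent()[21]


class TestDetectHbonds:
    def _nh_o_ensemble(self, d_nm, angle_deg):
        """Donor N with H, acceptor O at distance d and H-N-O angle."""
        a = np.deg2rad(angle_deg)
        coords = np.array(
            [
                [
                    [0.0, 0.0, 0.0],  # N (donor)
                    [0.1, 0.0, 0.0],  # H, 0.1 nm from N
                    [d_nm * np.cos(a), d_nm * np.sin(a), 0.0],  # O (acceptor)
                ]
            ]
        )
        return CoordEnsemble(
            coordinates=coords,
            residue_index=np.array([5, 5, 1]),
            chain_id=np.array(["A", "A", "A"]),
            atom_name=np.array(["N", "H", "O"]),
            element=np.array(["N", "H", "O"]),
        )

    def test_colinear_bond_recorded(self):
        table = detect_hbonds(self._nh_o_ensemble(0.30, 0.0))
        assert len(table) == 1
        row = table.events.iloc[0]
        assert (row["donor_residue"], row["acceptor_residue"]) == (5, 1)

    def test_distance_cutoff(self):
        assert len(detect_hbonds(self._nh_o_ensemble(0.40, 0.0))) == 0

    def test_angle_cutoff(self):
        assert len(detect_hbonds(self._nh_o_ensemble(0.30, 45.0))) == 0

    def test_no_hydrogens_raises(self):
        coords = gen_random_coil_coords(5, 1, seed=2)
        with pytest.raises(ValueError, match="hydrogens"):
            detect_hbonds(coords)
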