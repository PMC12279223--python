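import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from httex1 import (
    SSTrajectory,
    ShiftTable,
    scsd,
    shift_rmsd,
    ss_fraction,
    ss_fraction_ensemble,
    ss_map,
)

from conftest import random_ss_matrix


def brute_force_ss_map(codes: np.ndarray, mode: str = "exact") -> np.ndarray:
    """Independent oracle: rescan every frame character by character."""
    n_frames, n_res = codes.shape
    counts = np.zeros((n_res, n_res))
    for row in codes:
        i = 0
        while i < n_res:
            if row[i] == "H":
                j = i
                while j < n_res and row[j] == "H":
                    j += 1
                length = j - i
                for r in range(i, j):
                    if mode == "exact":
                        counts[r, length - 1] += 1
                    else:
                        counts[r, :length] += 1
                i = j
            else:
                i += 1
    return counts / n_frames


class TestSSFraction:
    def test_simple_fraction(self):
        codes = np.full((10, 3), "C")
        codes[:3, 1] = "H"
        assert ss_fraction(SSTrajectory(codes))[1] == pytest.approx(0.3)

    def test_all_coil_is_zero(self):
        assert (ss_fraction(SSTrajectory(np.full((5, 8), "C"))) == 0).all()

    def test_strand_codes(self):
        codes = np.full((4, 6), "C")
        codes[:, 2:4] = "E"
        frac = ss_fraction(SSTrajectory(codes), codes={"E"})
        assert frac.tolist() == [0, 0, 1, 1, 0, 0]

    def test_empty_code_set_rejected(self):
        with pytest.raises(ValueError):
            ss_fraction(SSTrajectory(np.full((2, 2), "H")), codes=set())

    def test_permutation_invariant_over_frames(self):
        rng = np.random.default_rng(0)
        codes = random_ss_matrix(rng, 30, 8)
        shuffled = codes[rng.permutation(30)]
        np.testing.assert_array_equal(
            ss_fraction(SSTrajectory(codes)), ss_fraction(SSTrajectory(shuffled))
        )


class TestEnsembleProfile:
    def test_identical_trajectories_have_zero_sem(self):
        t = SSTrajectory(np.full((10, 4), "H"))
        prof = ss_fraction_ensemble([t, t, t])
        assert (prof.sem == 0).all()
        assert (prof.mean == 1).all()

    def test_closed_form_sem_for_two_trajectories(self):
        a = SSTrajectory(np.full((5, 2), "C"))
        b = SSTrajectory(np.full((5, 2), "H"))
        prof = ss_fraction_ensemble([a, b])
        assert prof.mean[0] == pytest.approx(0.5)
        assert prof.sem[0] == pytest.approx(0.5)

    def test_single_trajectory_warns_and_reports_zero_sem(self):
        t = SSTrajectory(np.full((5, 2), "H"))
        with pytest.warns(UserWarning, match="single"):
            prof = ss_fraction_ensemble([t])
        assert (prof.sem == 0).all()

    def test_mismatched_residue_counts_rejected(self):
        a = SSTrajectory(np.full((5, 2), "H"))
        b = SSTrajectory(np.full((5, 3), "H"))
        with pytest.raises(ValueError):
            ss_fraction_ensemble([a, b])


class TestSSMap:
    def test_forced_example(self):
        traj = SSTrajectory([list("CCHHHHCC"), list("CCCCCCCC")])
        m = ss_map(traj)
        assert m.probabilities[3, 3] == pytest.approx(0.5)
        assert m.helical_fraction()[3] == pytest.approx(0.5)

    def test_all_helix_single_frame(self):
        m = ss_map(SSTrajectory([["H"] * 8]))
        assert (m.probabilities[:, 7] == 1).all()
        assert m.probabilities[:, :7].sum() == 0

    @pytest.mark.parametrize("mode", ["exact", "cumulative"])
    def test_matches_brute_force_oracle(self, mode):
        rng = np.random.default_rng(21)
        codes = random_ss_matrix(rng, 200, 15)
        m = ss_map(SSTrajectory(codes), mode=mode)
        np.testing.assert_array_equal(
            m.probabilities, brute_force_ss_map(codes, mode)
        )

    def test_conservation_on_random_matrices(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            codes = random_ss_matrix(
                rng, int(rng.integers(1, 100)), int(rng.integers(1, 30))
            )
            traj = SSTrajectory(codes)
            m = ss_map(traj)
            np.testing.assert_allclose(
                m.helical_fraction(), ss_fraction(traj), atol=1e-12
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        n_frames=st.integers(1, 40),
        n_res=st.integers(1, 20),
        seed=st.integers(0, 10_000),
    )
    def test_conservation_property(self, n_frames, n_res, seed):
        """Sum over segment lengths equals the per-residue helical fraction."""
        rng = np.random.default_rng(seed)
        traj = SSTrajectory(random_ss_matrix(rng, n_frames, n_res))
        m = ss_map(traj)
        np.testing.assert_allclose(m.helical_fraction(), ss_fraction(traj), atol=1e-12)

    def test_concatenates_trajectories(self):
        a = SSTrajectory([list("HHHH")])
        b = SSTrajectory([list("CCCC")])
        m = ss_map([a, b])
        assert m.n_frames == 2
        assert m.probabilities[0, 3] == pytest.approx(0.5)


class TestShifts:
    def _table(self, rows):
        return ShiftTable(
            shifts=pd.DataFrame(
                rows, columns=["residue_index", "residue_type", "delta_ca", "delta_cb"]
            )
        )

    def test_scsd_zero_at_random_coil(self):
        t = self._table([[1, "A", 52.5, 19.1]])
        assert scsd(t)["scsd"].iloc[0] == pytest.approx(0.0)

    def test_scsd_arithmetic(self):
        t = self._table([[1, "A", 54.5, 19.6]])  # +2.0 Ca, +0.5 Cb
        assert scsd(t)["scsd"].iloc[0] == pytest.approx(1.5)

    def test_glycine_uses_ca_only_and_is_flagged(self):
        t = self._table([[1, "G", 47.1, np.nan]])
        out = scsd(t)
        assert out["ca_only"].iloc[0]
        assert out["scsd"].iloc[0] == pytest.approx(2.0)

    def test_missing_reference_raises(self):
        t = self._table([[1, "A", 52.5, 19.1]])
        t.random_coil.pop("A")
        with pytest.raises(KeyError, match="A"):
            scsd(t)

    def test_rmsd_identical_tables(self):
        t = self._table([[1, "A", 52.5, 19.1], [2, "Q", 55.7, 29.4]])
        assert shift_rmsd(t, t, "CA") == 0.0

    def test_rmsd_single_residue(self):
        a = self._table([[1, "A", 53.5, 19.1]])
        b = self._table([[1, "A", 52.5, 19.1]])
        assert shift_rmsd(a, b, "CA") == pytest.approx(1.0)

    def test_rmsd_closed_form_two_residues(self):
        a = self._table([[1, "A", 55.5, 19.1], [2, "Q", 59.7, 29.4]])
        b = self._table([[1, "A", 52.5, 19.1], [2, "Q", 55.7, 29.4]])
        assert shift_rmsd(a, b, "CA") == pytest.approx(np.sqrt(12.5))

    def test_rmsd_empty_intersection_rejected(self):
        a = self._table([[1, "A", 52.5, 19.1]])
        b = self._table([[9, "A", 52.5, 19.1]])
        with pytest.raises(ValueError):
            shift_rmsd(a, b, "CA")
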