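"""Per-residue secondary-structure statistics and NMR comparisons.

The central object is the SS-map: for each residue i and helix length L,
the probability (fraction of frames) that i belongs to a maximal
contiguous alpha-helical segment of exactly length L.  Summed over L this
recovers the per-residue helical fraction exactly, which is the
conservation law the implementation is tested against.  Alpha-helical
means DSSP 'H' only by default — 3-10 ('G') and pi ('I') helices are
excluded unless requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ShiftTable
from .model import SSTrajectory

__all__ = [
    "SSMap",
    "HelicityProfile",
    "ss_fraction",
    "ss_fraction_ensemble",
    "ss_map",
    "scsd",
    "shift_rmsd",
]

HELIX_CODES = frozenset("H")


@dataclass
class SSMap:
    """Residue x segment-length helical probability matrix.

    ``probabilities[i-1, L-1]`` is P(residue i in a maximal helical run of
    exactly length L) for mode='exact', or of length >= L for
    mode='cumulative'.
    """

    probabilities: np.ndarray  # (N, N)
    n_frames: int
    mode: str = "exact"
    helix_codes: frozenset = HELIX_CODES

    @property
    def n_residues(self) -> int:
        return self.probabilities.shape[0]

    def helical_fraction(self) -> np.ndarray:
        """Per-residue helical fraction implied by the map.

        For the exact-length mode this is the sum over L (each frame
        contributes a residue to exactly one run length); for the
        cumulative mode it is the L=1 column.
        """
        if self.mode == "exact":
            return self.probabilities.sum(axis=1)
        return self.probabilities[:, 0].copy()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.probabilities,
            index=pd.RangeIndex(1, self.n_residues + 1, name="residue"),
            columns=[f"L{L}" for L in range(1, self.probabilities.shape[1] + 1)],
        )
        return df.reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_frames: int, mode: str = "exact") -> "SSMap":
        cols = [c for c in df.columns if c.startswith("L")]
        return cls(df[cols].to_numpy(float), n_frames=n_frames, mode=mode)


@dataclass
class HelicityProfile:
    """Ensemble-mean per-residue helical fraction with SEM across trajectories."""

    mean: np.ndarray
    sem: np.ndarray
    n_trajectories: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.mean) + 1),
                "helical_fraction": self.mean,
                "sem": self.sem,
            }
        )


def ss_fraction(traj: SSTrajectory, codes: frozenset | set = HELIX_CODES) -> np.ndarray:
    """Fraction of frames in which each residue's DSSP code is in ``codes``."""
    if not codes:
        raise ValueError("empty code set")
    member = np.isin(traj.codes, sorted(codes))
    return member.mean(axis=0)


def ss_fraction_ensemble(
    trajs: list[SSTrajectory], codes: frozenset | set = HELIX_CODES
) -> HelicityProfile:
    """Mean and SEM of per-residue fractions across independent trajectories."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    n_res = trajs[0].n_residues
    if any(t.n_residues != n_res for t in trajs):
        raise ValueError("trajectories have mismatched residue counts")
    per_traj = np.stack([ss_fraction(t, codes) for t in trajs])
    mean = per_traj.mean(axis=0)
    n = len(trajs)
    if n == 1:
        warnings.warn("single trajectory: SEM reported as 0", stacklevel=2)
        sem = np.zeros(n_res)
    else:
        sem = per_traj.std(axis=0, ddof=1) / np.sqrt(n)
    return HelicityProfile(mean=mean, sem=sem, n_trajectories=n)


def _helix_runs(row: np.ndarray, codes: frozenset) -> list[tuple[int, int]]:
    """Maximal runs of helix codes in one frame as 0-based [start, stop) pairs."""
    member = np.isin(row, sorted(codes)).astype(np.int8)
    edges = np.diff(np.concatenate(([0], member, [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return list(zip(starts, stops))


def ss_map(
    trajs: list[SSTrajectory] | SSTrajectory,
    mode: str = "exact",
    helix_codes: frozenset | set = HELIX_CODES,
) -> SSMap:
    """Compute the SS-map over one or several concatenated trajectories.

    For each frame, maximal contiguous helical runs are enumerated; a run
    of length L contributes to P[i][L] for every residue i it covers.  The
    'cumulative' mode instead counts membership in runs of length >= L.
    """
    if isinstance(trajs, SSTrajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("need at least one trajectory")
    if mode not in ("exact", "cumulative"):
        raise ValueError(f"unknown SS-map mode {mode!r}")
    n_res = trajs[0].n_residues
    if any(t.n_residues != n_res for t in trajs):
        raise ValueError("trajectories have mismatched residue counts")
    codes = frozenset(helix_codes)
    counts = np.zeros((n_res, n_res), dtype=np.int64)
    total = 0
    for traj in trajs:
        total += traj.n_frames
        for row in traj.codes:
            for start, stop in _helix_runs(row, codes):
                length = stop - start
                if mode == "exact":
                    counts[start:stop, length - 1] += 1
                else:
                    counts[start:stop, :length] += 1
    return SSMap(
        probabilities=counts / total,
        n_frames=total,
        mode=mode,
        helix_codes=codes,
    )


def scsd(table: ShiftTable) -> pd.DataFrame:
    """Per-residue secondary chemical-shift difference in ppm.

    SCSD_i = (dCa_i - dCa_rc) - (dCb_i - dCb_rc); positive values indicate
    helix.  Glycine has no Cb, so its SCSD uses the Ca term only and is
    flagged in the ``ca_only`` column rather than dropped, preserving
    profile continuity.
    """
    rows = []
    for r in table.shifts.itertuples():
        rt = str(r.residue_type).upper()
        if rt not in table.random_coil:
            raise KeyError(f"no random-coil reference for residue type {rt!r}")
        ca_rc, cb_rc = table.random_coil[rt]
        d_ca = float(r.delta_ca) - ca_rc
        ca_only = cb_rc is None or pd.isna(r.delta_cb)
        value = d_ca if ca_only else d_ca - (float(r.delta_cb) - cb_rc)
        rows.append(
            dict(
                residue_index=int(r.residue_index),
                residue_type=rt,
                scsd=value,
                ca_only=bool(ca_only),
            )
        )
    return pd.DataFrame(rows)


def shift_rmsd(
    predicted: ShiftTable, experimental: ShiftTable, nucleus: str = "CA"
) -> float:
    """RMSD (ppm) between predicted and experimental shifts for one nucleus.

    Computed over the intersection of residue indices; ``nucleus`` is 'CA'
    or 'CB' (residues lacking the nucleus, e.g. Gly Cb, are skipped).
    """
    col = {"CA": "delta_ca", "CB": "delta_cb"}.get(nucleus.upper())
    if col is None:
        raise ValueError(f"nucleus must be 'CA' or 'CB', got {nucleus!r}")
    p = predicted.shifts.set_index("residue_index")[col]
    e = experimental.shifts.set_index("residue_index")[col]
    common = p.index.intersection(e.index)
    diff = (p.loc[common] - e.loc[common]).dropna()
    if diff.empty:
        raise ValueError("no overlapping residues with defined shifts")
    return float(np.sqrt(np.mean(diff.to_numpy() ** 2)))
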