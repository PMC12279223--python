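"""Hydrogen bonds, bifurcated-H-bond occupancy, contact maps, beta conformers.

Contact semantics are uniform package-wide: residues i and j are in
contact in a frame iff any two heavy atoms are within the cutoff
(default 0.6 nm), counted once per frame no matter how many atom pairs
qualify; intramolecular maps exclude |i-j| <= 3.  A bifurcated hydrogen
bond at glutamine i means the sidechain NE2(i) -> backbone O(i-4) bond
coexists, in the same frame, with the helical backbone N(i) -> O(i-4)
bond; occupancy is evaluated only over frames whose helical-residue
fraction exceeds 30%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .io import HBondTable
from .model import CoordEnsemble, RegionAnnotation, ResidueSelection, SSTrajectory
from .ss_analysis import HELIX_CODES

__all__ = [
    "ContactMap",
    "BetaConformerSet",
    "BifurcatedHBOccupancy",
    "detect_hbonds",
    "bifurcated_hb_occupancy",
    "contact_map",
    "contact_count",
    "beta_conformers",
]

#: Occupancies above this are styled "prevalent" in reports.
PREVALENT_OCCUPANCY = 0.05


@dataclass
class ContactMap:
    """Residue x residue contact-probability matrix."""

    probabilities: np.ndarray
    cutoff: float  # nm
    mode: str  # 'intra' | 'inter'
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        n = self.probabilities.shape[0]
        df = pd.DataFrame(
            self.probabilities,
            index=pd.RangeIndex(1, n + 1, name="residue_i"),
            columns=[f"r{j}" for j in range(1, self.probabilities.shape[1] + 1)],
        )
        return df.reset_index()


@dataclass
class BetaConformerSet:
    """Frames carrying an extended beta conformation, with classification.

    ``conformers`` has columns frame, n_beta_residues, beta_residues
    (comma-joined 1-based indices) and conformer_class (``n17_direct`` when
    any beta residue lies in N17, else ``polyq_internal``).  ``population``
    is the extracted-frame fraction of the ensemble.  Frames whose only
    extended signal is an isolated beta-bridge ('B') are counted separately
    in ``bridge_frames`` and never extracted.
    """

    conformers: pd.DataFrame
    population: float
    n_frames: int
    min_beta_residues: int
    bridge_frames: int = 0

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass
class BifurcatedHBOccupancy:
    """Per-residue bifurcated-H-bond occupancy over helicity-gated frames."""

    occupancy: np.ndarray  # (N,) fraction of eligible frames, NaN if undefined
    eligible_frames: int
    helicity_threshold: float

    def prevalent(self) -> np.ndarray:
        """Residues whose occupancy exceeds the 5% prevalence threshold."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.occupancy) > PREVALENT_OCCUPANCY

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": np.arange(1, len(self.occupancy) + 1),
                "bhb_occupancy": self.occupancy,
                "prevalent": self.prevalent(),
            }
        )


def detect_hbonds(
    coords: CoordEnsemble, d_cut: float = 0.35, angle_cut: float = 30.0
) -> HBondTable:
    """Geometric hydrogen-bond detection on an explicit-hydrogen ensemble.

    A bond is recorded when the donor-acceptor heavy-atom distance is
    <= ``d_cut`` (nm) and the H-D-A angle is <= ``angle_cut`` (degrees) —
    the conventional gmx-hbond style criterion.  Donor hydrogens are
    assigned to the nearest N/O within 0.12 nm in the first frame, since
    the ensemble carries no bond topology.

    Raises
    ------
    ValueError
        If the ensemble contains no hydrogens (supply a precomputed
        HBondTable from your MD engine instead).
    """
    is_h = ~coords.is_heavy
    if not is_h.any():
        raise ValueError(
            "no hydrogens in the ensemble; hydrogen-bond geometry cannot be "
            "evaluated — supply a precomputed HBondTable instead"
        )
    polar = np.flatnonzero(np.isin(np.char.upper(coords.element), ["N", "O"]))
    h_idx = np.flatnonzero(is_h)
    if polar.size == 0:
        raise ValueError("no N/O atoms to act as donors or acceptors")
    # donor assignment from frame 0
    d0 = cdist(coords.coordinates[0, h_idx], coords.coordinates[0, polar])
    nearest = d0.argmin(axis=1)
    ok = d0[np.arange(h_idx.size), nearest] <= 0.12
    donors = polar[nearest[ok]]  # heavy donor per hydrogen
    hydros = h_idx[ok]
    rows = []
    for f in range(coords.n_frames):
        xyz = coords.coordinates[f]
        dists = cdist(xyz[donors], xyz[polar])
        for k in range(donors.size):
            d_atom = donors[k]
            h_atom = hydros[k]
            close = np.flatnonzero(dists[k] <= d_cut)
            for a_pos in close:
                a_atom = polar[a_pos]
                if a_atom == d_atom:
                    continue
                dh = xyz[h_atom] - xyz[d_atom]
                da = xyz[a_atom] - xyz[d_atom]
                norm = np.linalg.norm(dh) * np.linalg.norm(da)
                if norm == 0:
                    continue
                ang = np.degrees(np.arccos(np.clip(np.dot(dh, da) / norm, -1.0, 1.0)))
                if ang <= angle_cut:
                    rows.append(
                        dict(
                            frame=f,
                            donor_residue=int(coords.residue_index[d_atom]),
                            donor_role=str(coords.role[d_atom]),
                            donor_atom=str(coords.atom_name[d_atom]),
                            hydrogen=str(coords.atom_name[h_atom]),
                            acceptor_residue=int(coords.residue_index[a_atom]),
                            acceptor_role=str(coords.role[a_atom]),
                            acceptor_atom=str(coords.atom_name[a_atom]),
                            donor_chain=str(coords.chain_id[d_atom]),
                            acceptor_chain=str(coords.chain_id[a_atom]),
                        )
                    )
    columns = [
        "frame",
        "donor_residue",
        "donor_role",
        "donor_atom",
        "hydrogen",
        "acceptor_residue",
        "acceptor_role",
        "acceptor_atom",
        "donor_chain",
        "acceptor_chain",
    ]
    return HBondTable(events=pd.DataFrame(rows, columns=columns))


def bifurcated_hb_occupancy(
    hbonds: HBondTable,
    ss: SSTrajectory,
    helicity_threshold: float = 0.30,
    helix_codes: frozenset | set = HELIX_CODES,
    sequence: str | None = None,
) -> BifurcatedHBOccupancy:
    """Per-residue occupancy of coexisting sidechain/backbone i -> i-4 bonds.

    Eligible frames are those whose fraction of helical residues strictly
    exceeds ``helicity_threshold``.  For residue i, a frame counts when it
    carries both the sidechain(i) -> backbone(i-4) and the
    backbone(i) -> backbone(i-4) bond.  With ``sequence`` given, occupancy
    is reported only at glutamines (others are NaN).  If no frame passes
    the helicity gate the whole vector is NaN and a warning is issued.
    """
    member = np.isin(ss.codes, sorted(helix_codes))
    eligible = member.mean(axis=1) > helicity_threshold
    n_eligible = int(eligible.sum())
    n_res = ss.n_residues
    occ = np.full(n_res, np.nan)
    if n_eligible == 0:
        warnings.warn(
            "no frames pass the helicity gate; occupancy undefined", stacklevel=2
        )
        return BifurcatedHBOccupancy(occ, 0, helicity_threshold)
    ev = hbonds.events
    in_gate = ev[ev["frame"].isin(np.flatnonzero(eligible))]
    pair = in_gate[in_gate["donor_residue"] - in_gate["acceptor_residue"] == 4]
    pair = pair[pair["acceptor_role"] == "backbone"]
    sc = pair[pair["donor_role"] == "sidechain"]
    bb = pair[pair["donor_role"] == "backbone"]
    residues = (
        range(5, n_res + 1)
        if sequence is None
        else [i for i in range(5, n_res + 1) if sequence[i - 1] == "Q"]
    )
    sc_frames = sc.groupby("donor_residue")["frame"].agg(set)
    bb_frames = bb.groupby("donor_residue")["frame"].agg(set)
    for i in residues:
        both = sc_frames.get(i, set()) & bb_frames.get(i, set())
        occ[i - 1] = len(both) / n_eligible
    return BifurcatedHBOccupancy(occ, n_eligible, helicity_threshold)


def _residue_min_dists(
    xyz: np.ndarray,
    idx_a: np.ndarray,
    res_a: np.ndarray,
    idx_b: np.ndarray,
    res_b: np.ndarray,
    n_a: int,
    n_b: int,
) -> np.ndarray:
    """Min heavy-atom distance per residue pair for one frame."""
    d = cdist(xyz[idx_a], xyz[idx_b])
    out = np.full((n_a, n_b), np.inf)
    flat = (res_a[:, None] - 1) * n_b + (res_b[None, :] - 1)
    np.minimum.at(out.ravel(), flat.ravel(), d.ravel())
    return out


def contact_map(
    coords: CoordEnsemble, cutoff: float = 0.6, mode: str = "intra"
) -> ContactMap:
    """Ensemble-averaged residue-residue contact probability map.

    'intra' averages same-chain maps over frames (and over chains when
    several identical chains are present), applying the |i-j| > 3 sequence
    separation rule.  'inter' averages over all ordered chain pairs, which
    yields a symmetric map for identical chains.
    """
    chains = coords.chains
    if mode not in ("intra", "inter"):
        raise ValueError(f"unknown contact-map mode {mode!r}")
    if mode == "inter" and len(chains) < 2:
        raise ValueError("intermolecular contact map needs at least two chains")
    heavy = coords.is_heavy
    per_chain = {}
    for c in chains:
        m = (coords.chain_id == c) & heavy
        per_chain[c] = (np.flatnonzero(m), coords.residue_index[m])
    sizes = {c: int(r.max()) for c, (_, r) in per_chain.items()}
    n = max(sizes.values())
    acc = np.zeros((n, n))
    if mode == "intra":
        if len(set(sizes.values())) != 1:
            raise ValueError("intra map over chains of unequal residue counts")
        for f in range(coords.n_frames):
            for c in chains:
                idx, res = per_chain[c]
                d = _residue_min_dists(coords.coordinates[f], idx, res, idx, res, n, n)
                acc += d <= cutoff
        prob = acc / (coords.n_frames * len(chains))
        ii, jj = np.indices((n, n))
        prob[np.abs(ii - jj) <= 3] = 0.0
    else:
        pairs = [(a, b) for a in chains for b in chains if a != b]
        for f in range(coords.n_frames):
            for a, b in pairs:
                ia, ra = per_chain[a]
                ib, rb = per_chain[b]
                d = _residue_min_dists(coords.coordinates[f], ia, ra, ib, rb, n, n)
                acc += d <= cutoff
        prob = acc / (coords.n_frames * len(pairs))
    return ContactMap(probabilities=prob, cutoff=cutoff, mode=mode, n_frames=coords.n_frames)


def contact_count(
    coords: CoordEnsemble,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
    cutoff: float = 0.6,
) -> np.ndarray:
    """Per-frame number of residue pairs in contact between two selections."""
    if selection_a.chain_id == selection_b.chain_id and (
        selection_a.start <= selection_b.end and selection_b.start <= selection_a.end
    ):
        raise ValueError("selections overlap on the same chain")
    out = np.zeros(coords.n_frames, dtype=int)
    ma = coords.atom_mask(
        chain=selection_a.chain_id, residues=selection_a.residues, heavy_only=True
    )
    mb = coords.atom_mask(
        chain=selection_b.chain_id, residues=selection_b.residues, heavy_only=True
    )
    if not ma.any() or not mb.any():
        raise ValueError("empty selection")
    ia, ib = np.flatnonzero(ma), np.flatnonzero(mb)
    ra = coords.residue_index[ia] - selection_a.start + 1
    rb = coords.residue_index[ib] - selection_b.start + 1
    na, nb = len(selection_a.residues), len(selection_b.residues)
    for f in range(coords.n_frames):
        d = _residue_min_dists(coords.coordinates[f], ia, ra, ib, rb, na, nb)
        out[f] = int((d <= cutoff).sum())
    return out


def beta_conformers(
    ss: SSTrajectory,
    regions: dict[str, RegionAnnotation] | None = None,
    min_beta_residues: int = 4,
) -> BetaConformerSet:
    """Extract frames with an extended beta conformation and classify them.

    A frame is extracted when strictly more than ``min_beta_residues``
    residues carry DSSP 'E'.  Classification is ``n17_direct`` if any beta
    residue index is <= 17 (the N17 domain participates directly in the
    sheet) and ``polyq_internal`` otherwise.  Isolated beta-bridges ('B')
    never contribute to the count; frames with 'B' but no qualifying 'E'
    content are tallied in ``bridge_frames``.
    """
    n17_end = 17
    if regions is not None and "n_terminal_n17" in regions:
        n17_end = max(n17_end, regions["n_terminal_n17"].end)
    is_e = ss.codes == "E"
    n_beta = is_e.sum(axis=1)
    extracted = np.flatnonzero(n_beta > min_beta_residues)
    rows = []
    for f in extracted:
        res = np.flatnonzero(is_e[f]) + 1
        cls = "n17_direct" if (res <= n17_end).any() else "polyq_internal"
        rows.append(
            dict(
                frame=int(f),
                n_beta_residues=int(n_beta[f]),
                beta_residues=",".join(map(str, res)),
                conformer_class=cls,
            )
        )
    has_bridge = (ss.codes == "B").any(axis=1)
    bridge_only = int((has_bridge & (n_beta <= min_beta_residues)).sum())
    df = pd.DataFrame(
        rows, columns=["frame", "n_beta_residues", "beta_residues", "conformer_class"]
    )
    return BetaConformerSet(
        conformers=df,
        population=len(df) / ss.n_frames,
        n_frames=ss.n_frames,
        min_beta_residues=min_beta_residues,
        bridge_frames=bridge_only,
    )
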