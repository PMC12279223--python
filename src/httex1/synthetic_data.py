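"""Synthetic inputs with the statistical structure the analyses assume.

MD trajectory data for these systems is rarely depositable at full scale,
so the generators here produce (a) per-residue DSSP time series from a
nucleation/propagation/retraction lattice process, (b) two-chain ideal
alpha-helix coordinates with a controlled inter-helical angle, (c)
glutamine sidechain/backbone hydrogen-bond coexistence fixtures, and (d)
rare beta-sheet frames injected at a controlled population.  None of this
is physically realistic — no energetics, no solvent — it exists to give
the estimators ground truth to recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import HBondTable
from .model import ConstructSpec, CoordEnsemble, RegionAnnotation, SSTrajectory

__all__ = [
    "HelixKineticsParams",
    "DimerGeometryParams",
    "gen_ss_trajectory",
    "gen_beta_frames",
    "gen_dimer_coords",
    "gen_hbond_fixture",
    "gen_random_coil_coords",
]


@dataclass(frozen=True)
class HelixKineticsParams:
    """Rates of the helix nucleation/propagation lattice process.

    k_nuc is the per-frame probability that a nucleus of ``nucleus_length``
    residues appears (uniformly placed) inside ``nucleation_region`` when no
    helix is active; each helix end then independently extends with p_ext
    and retracts with p_ret per frame.  Defaults give occasional nucleation
    with slow net growth, which is the phenomenology the initiation-time
    analyses assume: early helicity at the nucleation site, later arrival
    further along the chain.
    """

    nucleation_region: RegionAnnotation
    k_nuc: float = 0.02
    p_ext: float = 0.20
    p_ret: float = 0.15
    nucleus_length: int = 4
    n_frames: int = 5000
    frame_interval: float = 1.0  # ns
    seed: int = 0
    multi_nucleus: bool = False

    def __post_init__(self) -> None:
        for name in ("k_nuc", "p_ext", "p_ret"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.nucleus_length < 4:
            raise ValueError("nucleus_length must be >= 4 (one helical turn)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass(frozen=True)
class DimerGeometryParams:
    """Geometry of a synthetic two-helix dimer (Calpha traces).

    Ideal-helix constants are textbook: 3.6 residues per turn, 0.15 nm rise
    per residue, 0.23 nm Calpha radius.  ``inter_helical_angle`` is the angle
    between the N->C axes; ``separation`` the inter-axial distance in nm.
    """

    helix_length: int = 17
    inter_helical_angle: float = 180.0  # degrees
    separation: float = 1.0  # nm
    axial_offset: float = 0.0  # nm
    rise_per_residue: float = 0.15  # nm
    residues_per_turn: float = 3.6
    ca_radius: float = 0.23  # nm
    n_frames: int = 1
    noise: float = 0.0  # nm, isotropic Gaussian jitter per atom
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.inter_helical_angle <= 180.0:
            raise ValueError("inter_helical_angle must be in [0, 180] degrees")
        if self.separation <= 0:
            raise ValueError("separation must be positive (nm)")
        if self.helix_length < 4:
            raise ValueError("helix_length must be >= 4")


def gen_ss_trajectory(
    params: HelixKineticsParams, construct: ConstructSpec
) -> SSTrajectory:
    """Simulate a DSSP code matrix from the nucleation/propagation process.

    Residues inside active helices emit 'H', everything else 'C'.  A helix
    dissolves when retraction shrinks it below one residue.  With the
    default single-nucleus dynamics at most one helix is active at a time;
    ``multi_nucleus`` allows concurrent helices.  Bit-reproducible from
    ``params.seed``.
    """
    n = construct.length
    region = params.nucleation_region
    if region.end > n:
        raise ValueError(f"nucleation region {region} outside construct (length {n})")
    if len(region) < params.nucleus_length:
        raise ValueError(
            f"nucleus of {params.nucleus_length} residues does not fit in "
            f"region {region.name} [{region.start},{region.end}]"
        )
    rng = np.random.default_rng(params.seed)
    codes = np.full((params.n_frames, n), "C", dtype="<U1")
    # helices as [start, end] 1-based inclusive
    helices: list[list[int]] = []
    max_start = region.end - params.nucleus_length + 1
    for f in range(params.n_frames):
        # propagate/retract existing helices (one residue per end per frame)
        survivors: list[list[int]] = []
        for h in helices:
            s, e = h
            if rng.random() < params.p_ext and s > 1:
                s -= 1
            if rng.random() < params.p_ret:
                s += 1
            if rng.random() < params.p_ext and e < n:
                e += 1
            if rng.random() < params.p_ret:
                e -= 1
            if e >= s:
                survivors.append([s, e])
        helices = survivors
        # nucleation
        if (params.multi_nucleus or not helices) and rng.random() < params.k_nuc:
            s = int(rng.integers(region.start, max_start + 1))
            helices.append([s, s + params.nucleus_length - 1])
        for s, e in helices:
            codes[f, s - 1 : e] = "H"
    return SSTrajectory(
        codes,
        frame_interval=params.frame_interval,
        trajectory_id=f"synthetic-seed{params.seed}",
    )


def gen_beta_frames(
    base: SSTrajectory,
    beta_fraction: float,
    strand_ranges: list[tuple[int, int]],
    seed: int = 0,
) -> SSTrajectory:
    """Inject extended ('E') strands into a random fraction of frames.

    Each frame is independently selected with probability ``beta_fraction``;
    selected frames have every residue in ``strand_ranges`` (1-based,
    inclusive, non-overlapping) rewritten to 'E'.  The expected injected
    population equals ``beta_fraction``.
    """
    if not 0.0 <= beta_fraction <= 1.0:
        raise ValueError("beta_fraction must be in [0, 1]")
    covered: set[int] = set()
    for s, e in strand_ranges:
        if s < 1 or e > base.n_residues or e < s:
            raise ValueError(f"strand range [{s},{e}] outside trajectory")
        r = set(range(s, e + 1))
        if covered & r:
            raise ValueError("overlapping strand ranges")
        covered |= r
    rng = np.random.default_rng(seed)
    pick = rng.random(base.n_frames) < beta_fraction
    codes = base.codes.copy()
    idx0 = np.array(sorted(covered)) - 1
    codes[np.ix_(pick, idx0)] = "E"
    return SSTrajectory(
        codes,
        frame_interval=base.frame_interval,
        trajectory_id=base.trajectory_id + "+beta",
    )


def _ideal_helix(p: DimerGeometryParams) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix along +z, centred at the origin.

    A trace covering a non-integer number of turns has its spiral slightly
    correlated with z, which would tilt a fitted principal axis off the
    nominal one; the z-correlated component of x and y is projected out so
    the nominal axis is exactly recoverable, which is what makes the
    generator usable as geometric ground truth.
    """
    i = np.arange(p.helix_length)
    theta = 2.0 * np.pi * i / p.residues_per_turn
    xyz = np.stack(
        [
            p.ca_radius * np.cos(theta),
            p.ca_radius * np.sin(theta),
            p.rise_per_residue * i,
        ],
        axis=1,
    )
    xyz -= xyz.mean(axis=0)
    z = xyz[:, 2]
    for k in (0, 1):
        xyz[:, k] -= z * (xyz[:, k] @ z) / (z @ z)
    return xyz


def _rotation_about_x(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def gen_dimer_coords(
    params: DimerGeometryParams, check_overlap: bool = False
) -> CoordEnsemble:
    """Two ideal Calpha-trace helices at a controlled relative geometry.

    Chain A runs along +z at the origin; chain B's axis is chain A's
    rotated by ``inter_helical_angle`` about x, displaced by ``separation``
    along y and ``axial_offset`` along z.  Angle-recovery by principal-axis
    fitting is the geometric ground truth the dimer analyses are tested
    against.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    a = _ideal_helix(p)
    rot = _rotation_about_x(p.inter_helical_angle)
    b = _ideal_helix(p) @ rot.T
    b[:, 1] += p.separation
    b[:, 2] += p.axial_offset
    coords0 = np.concatenate([a, b])
    if check_overlap:
        from scipy.spatial.distance import cdist

        if cdist(a, b).min() < 0.1:
            raise ValueError("chains overlap below 0.1 nm")
    frames = np.repeat(coords0[None], p.n_frames, axis=0)
    if p.noise > 0:
        frames = frames + rng.normal(0.0, p.noise, frames.shape)
    nres = p.helix_length
    return CoordEnsemble(
        coordinates=frames,
        residue_index=np.tile(np.arange(1, nres + 1), 2),
        chain_id=np.array(["A"] * nres + ["B"] * nres),
        atom_name=np.array(["CA"] * 2 * nres),
        element=np.array(["C"] * 2 * nres),
    )


def gen_hbond_fixture(
    construct: ConstructSpec,
    n_frames: int,
    bhb_frames: set[int],
    residue_index: int | None = None,
) -> HBondTable:
    """Hydrogen-bond event table exercising bifurcated-bond detection.

    For glutamine residue i (default: the fifth polyQ residue, so i-4 is
    still within the construct), every frame carries the helical backbone
    i -> i-4 bond; frames in ``bhb_frames`` (0-based) additionally carry the
    coexisting sidechain NE2(i) -> backbone O(i-4) bond.
    """
    if residue_index is None:
        residue_index = 22 if construct.polyq_length >= 5 else 17 + construct.polyq_length
    i = residue_index
    if i - 4 < 1:
        raise ValueError(f"residue {i}: acceptor i-4 would precede the chain start")
    if i > construct.length:
        raise ValueError(f"residue {i} outside construct of length {construct.length}")
    if construct.sequence[i - 1] != "Q":
        raise ValueError(f"residue {i} is {construct.sequence[i - 1]}, not Gln")
    extra = set(bhb_frames) - set(range(n_frames))
    if extra:
        raise ValueError(f"bhb_frames outside 0..{n_frames - 1}: {sorted(extra)}")
    rows = []
    for f in range(n_frames):
        rows.append(
            dict(
                frame=f,
                donor_residue=i,
                donor_role="backbone",
                donor_atom="N",
                hydrogen="H",
                acceptor_residue=i - 4,
                acceptor_role="backbone",
                acceptor_atom="O",
            )
        )
        if f in bhb_frames:
            rows.append(
                dict(
                    frame=f,
                    donor_residue=i,
                    donor_role="sidechain",
                    donor_atom="NE2",
                    hydrogen="HE21",
                    acceptor_residue=i - 4,
                    acceptor_role="backbone",
                    acceptor_atom="O",
                )
            )
    return HBondTable(events=pd.DataFrame(rows))


def gen_random_coil_coords(
    n_residues: int,
    n_frames: int,
    seed: int = 0,
    atoms_per_residue: int = 4,
    bond_length: float = 0.38,  # nm, Calpha-Calpha
    chain_id: str = "A",
) -> CoordEnsemble:
    """Self-avoiding-ish random-walk coil used as contact-map fuzz input.

    Each residue gets a Calpha on a fixed-step random walk plus
    ``atoms_per_residue - 1`` pseudo heavy atoms jittered around it.  Frames
    are independent walks, so contact statistics are broad — exactly what an
    oracle-equivalence test wants.
    """
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_residues * atoms_per_residue, 3))
    for f in range(n_frames):
        steps = rng.normal(size=(n_residues, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        ca = np.cumsum(steps * bond_length, axis=0)
        atoms = np.repeat(ca, atoms_per_residue, axis=0)
        jitter = rng.normal(0.0, 0.08, atoms.shape)
        jitter[:: atoms_per_residue] = 0.0  # Calpha itself stays on the walk
        frames[f] = atoms + jitter
    names = (["CA"] + [f"CB{k}" for k in range(1, atoms_per_residue)]) * n_residues
    return CoordEnsemble(
        coordinates=frames,
        residue_index=np.repeat(np.arange(1, n_residues + 1), atoms_per_residue),
        chain_id=np.full(n_residues * atoms_per_residue, chain_id),
        atom_name=np.array(names),
        element=np.full(n_residues * atoms_per_residue, "C"),
    )
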