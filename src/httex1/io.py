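"""Readers and writers for the external formats the pipeline touches.

Secondary-structure input is a plain-text matrix (one line per frame, one
DSSP character per residue) or a headerless CSV of the same shape.
Coordinates come in as multi-model PDB or any topology+trajectory pair
MDAnalysis understands, and are converted to nm on read (the contact and
hydrogen-bond cutoffs used throughout are in nm).  Tabular data (chemical
shifts, hydrogen-bond events, result matrices) travel as CSV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    DSSP_CODES,
    ConstructSpec,
    CoordEnsemble,
    MotifVariant,
    SSTrajectory,
    Tail,
)

__all__ = [
    "ShiftTable",
    "HBondTable",
    "RANDOM_COIL_SHIFTS",
    "read_ss_matrix",
    "write_ss_matrix",
    "read_coordinates",
    "write_pdb",
    "read_shift_table",
    "write_shift_table",
    "read_hbond_table",
    "write_hbond_table",
    "read_construct_config",
    "write_fasta",
    "write_results",
]

# Random-coil 13C chemical shifts (ppm) in the style of the standard
# Wishart reference set; editable, and replaceable by a user CSV.
RANDOM_COIL_SHIFTS: dict[str, tuple[float, float | None]] = {
    "A": (52.5, 19.1),
    "R": (56.0, 30.9),
    "N": (53.1, 38.9),
    "D": (54.2, 41.1),
    "C": (58.2, 28.0),
    "Q": (55.7, 29.4),
    "E": (56.6, 29.9),
    "G": (45.1, None),
    "H": (55.0, 29.0),
    "I": (61.1, 38.8),
    "L": (55.1, 42.4),
    "K": (56.2, 33.1),
    "M": (55.4, 32.9),
    "F": (57.7, 39.6),
    "P": (63.3, 31.7),
    "S": (58.3, 63.8),
    "T": (61.8, 69.8),
    "W": (57.5, 29.6),
    "Y": (57.9, 38.8),
    "V": (62.2, 32.9),
}

_SHIFT_COLUMNS = ["residue_index", "residue_type", "delta_ca", "delta_cb"]
_HBOND_COLUMNS = [
    "frame",
    "donor_residue",
    "donor_role",
    "donor_atom",
    "hydrogen",
    "acceptor_residue",
    "acceptor_role",
    "acceptor_atom",
]


@dataclass
class ShiftTable:
    """Per-residue 13C chemical shifts plus a random-coil reference.

    ``shifts`` has columns residue_index, residue_type, delta_ca, delta_cb
    and optionally ssp_score; ``random_coil`` maps residue type to
    (Ca, Cb) reference shifts in ppm.
    """

    shifts: pd.DataFrame
    random_coil: dict[str, tuple[float, float | None]] = field(
        default_factory=lambda: dict(RANDOM_COIL_SHIFTS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in _SHIFT_COLUMNS if c not in self.shifts.columns]
        if missing:
            raise ValueError(f"shift table missing mandatory columns: {missing}")
        idx = self.shifts["residue_index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("residue indices must be unique")
        if not (np.diff(idx) > 0).all():
            self.shifts = self.shifts.sort_values("residue_index").reset_index(drop=True)
        for col in ("delta_ca", "delta_cb"):
            vals = self.shifts[col].to_numpy(float)
            if np.isinf(vals).any():
                raise ValueError(f"non-finite values in {col}")

    def __len__(self) -> int:
        return len(self.shifts)


@dataclass
class HBondTable:
    """Frame-resolved donor-hydrogen-acceptor event records."""

    events: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _HBOND_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"hbond table missing mandatory columns: {missing}")
        roles = set(self.events["donor_role"]) | set(self.events["acceptor_role"])
        bad = roles - {"backbone", "sidechain"}
        if bad:
            raise ValueError(f"unknown hydrogen-bond roles: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.events)


def read_ss_matrix(path, frame_interval: float = 1.0, trajectory_id: str | None = None) -> SSTrajectory:
    """Read a plain-text or CSV DSSP matrix into an :class:`SSTrajectory`.

    Each line is one frame; characters (or comma-separated single
    characters) are per-residue DSSP codes.  Ragged lines, unknown codes
    and empty files are rejected with the offending line number.
    """
    path = Path(path)
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            chars = line.split(",") if "," in line else list(line)
            chars = [c.strip() for c in chars]
            if any(len(c) != 1 for c in chars):
                raise ValueError(f"{path}:{lineno}: multi-character cell in SS matrix")
            bad = set(chars) - DSSP_CODES
            if bad:
                raise ValueError(
                    f"{path}:{lineno}: unknown DSSP codes {sorted(bad)}"
                )
            if lines and len(chars) != len(lines[0]):
                raise ValueError(
                    f"{path}:{lineno}: ragged line ({len(chars)} residues, "
                    f"expected {len(lines[0])})"
                )
            lines.append(chars)
    if not lines:
        raise ValueError(f"{path}: empty secondary-structure file")
    return SSTrajectory(
        np.array(lines, dtype="<U1"),
        frame_interval=frame_interval,
        trajectory_id=trajectory_id or path.stem,
    )


def write_ss_matrix(traj: SSTrajectory, path) -> None:
    """Write an SS matrix in the plain-text dialect read_ss_matrix accepts."""
    with open(path, "w") as fh:
        for frame in traj.codes:
            fh.write("".join(frame) + "\n")


def read_coordinates(path, fmt: str = "pdb", topology=None) -> CoordEnsemble:
    """Read a coordinate ensemble via MDAnalysis into nm-based storage.

    Parameters
    ----------
    path : path
        Multi-model PDB, or a trajectory file when ``topology`` is given.
    fmt : str
        'pdb' for a multi-model PDB; 'trajectory' for a topology+trajectory
        pair handled by MDAnalysis.
    topology : path, optional
        Required for fmt='trajectory'.
    """
    import MDAnalysis as mda

    if fmt == "pdb":
        args = (str(path),)
    elif fmt == "trajectory":
        if topology is None:
            raise ValueError("trajectory format requires a topology file")
        args = (str(topology), str(path))
    else:
        raise ValueError(f"unknown coordinate format {fmt!r}; use 'pdb' or 'trajectory'")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(*args)
        atoms = u.atoms
        try:
            chain_ids = atoms.chainIDs
        except (AttributeError, mda.exceptions.NoDataError):
            chain_ids = atoms.segids
        try:
            elements = atoms.elements
        except (AttributeError, mda.exceptions.NoDataError):
            elements = np.array([_guess_element(n) for n in atoms.names])
        # renumber residues 1..n within each chain
        resids = np.empty(len(atoms), dtype=int)
        for cid in np.unique(chain_ids):
            m = chain_ids == cid
            raw = atoms.resids[m]
            uniq = {r: i + 1 for i, r in enumerate(dict.fromkeys(raw))}
            resids[m] = [uniq[r] for r in raw]
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    return CoordEnsemble(
        coordinates=coords * 0.1,  # Angstrom -> nm
        residue_index=resids,
        chain_id=np.asarray(chain_ids, dtype="<U4"),
        atom_name=np.asarray(atoms.names, dtype="<U6"),
        element=np.asarray(elements, dtype="<U2"),
    )


def _guess_element(name: str) -> str:
    name = name.strip()
    for ch in name:
        if ch.isalpha():
            return ch.upper() if ch.upper() != "H" or name[0].upper() == "H" else ch
    return "X"


def write_pdb(ens: CoordEnsemble, path, resnames: np.ndarray | None = None) -> None:
    """Write a CoordEnsemble as a multi-model PDB (nm converted to Angstrom)."""
    import MDAnalysis as mda

    n = ens.n_atoms
    u = mda.Universe.empty(
        n,
        n_residues=n,
        atom_resindex=np.arange(n),
        residue_segindex=np.zeros(n, dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", ens.atom_name)
    u.add_TopologyAttr("resids", ens.residue_index)
    u.add_TopologyAttr(
        "resnames", resnames if resnames is not None else np.full(n, "GLY")
    )
    u.add_TopologyAttr("chainIDs", ens.chain_id)
    u.add_TopologyAttr("elements", ens.element)
    u.add_TopologyAttr("segids", np.array(["SYS"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n, multiframe=True) as w:
            for frame in ens.coordinates:
                u.atoms.positions = frame * 10.0  # nm -> Angstrom
                w.write(u.atoms)


def read_shift_table(path, random_coil_path=None) -> ShiftTable:
    """Read a chemical-shift CSV (and optional random-coil reference CSV)."""
    df = pd.read_csv(path)
    missing = [c for c in _SHIFT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    rc = dict(RANDOM_COIL_SHIFTS)
    if random_coil_path is not None:
        rdf = pd.read_csv(random_coil_path)
        for col in ("residue_type", "ca", "cb"):
            if col not in rdf.columns:
                raise ValueError(f"{random_coil_path}: missing column {col}")
        rc = {
            str(r.residue_type): (float(r.ca), None if pd.isna(r.cb) else float(r.cb))
            for r in rdf.itertuples()
        }
    return ShiftTable(shifts=df, random_coil=rc)


def write_shift_table(table: ShiftTable, path) -> None:
    table.shifts.to_csv(path, index=False)


def read_hbond_table(path) -> HBondTable:
    """Read a hydrogen-bond event CSV."""
    df = pd.read_csv(path)
    missing = [c for c in _HBOND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return HBondTable(events=df)


def write_hbond_table(table: HBondTable, path) -> None:
    table.events.to_csv(path, index=False)


def read_construct_config(path) -> ConstructSpec:
    """Read a ConstructSpec from a YAML key-value config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "polyq_length" not in cfg:
        raise ValueError(f"{path}: config must define polyq_length")
    return ConstructSpec(
        polyq_length=int(cfg["polyq_length"]),
        tail=Tail(cfg.get("tail", "P5")),
        motif_variant=MotifVariant(cfg.get("motif_variant", "LKSF")),
        n17_sequence=cfg.get("n17_sequence", ConstructSpec.n17_sequence),
    )


def write_fasta(spec: ConstructSpec, path, header: str | None = None) -> None:
    """Export a construct sequence as FASTA."""
    name = header or (
        f"N17-Q{spec.polyq_length}-{spec.tail.value}_{spec.motif_variant.value}"
    )
    seq = spec.sequence
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), 60):
            fh.write(seq[i : i + 60] + "\n")


def write_results(obj, path) -> None:
    """Serialize a result object to CSV (matrix-like) or JSON (mapping-like).

    DataFrames and 2-D arrays go to CSV; dictionaries and dataclass-like
    result summaries go to JSON.
    """
    path = Path(path)
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif isinstance(obj, np.ndarray):
        pd.DataFrame(obj).to_csv(path, index=False)
    elif isinstance(obj, dict):
        with open(path, "w") as fh:
            json.dump(_jsonify(obj), fh, indent=2)
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, index=False)
    elif hasattr(obj, "to_dict"):
        with open(path, "w") as fh:
            json.dump(_jsonify(obj.to_dict()), fh, indent=2)
    else:
        raise TypeError(f"don't know how to serialize {type(obj).__name__}")


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
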