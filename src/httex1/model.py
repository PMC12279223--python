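"""Domain types shared by every analysis stage.

The package studies huntingtin exon-1 (Httex1) constructs of the form
N17 - polyQ - tail, where N17 is the 17-residue N-terminal amphipathic
domain, polyQ is a homopolymeric glutamine tract, and the tail is either
the minimal five-proline tract (P5), the full proline-rich domain (PRD)
or absent.  Residue numbering is 1-based and inclusive throughout,
matching the "aa:11-17" style used in the structural literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = [
    "N17_SEQUENCE",
    "PRD_SEQUENCE",
    "P5_SEQUENCE",
    "DSSP_CODES",
    "Tail",
    "MotifVariant",
    "ConstructSpec",
    "RegionAnnotation",
    "SSTrajectory",
    "CoordEnsemble",
    "ResidueSelection",
    "build_construct",
    "default_regions",
]

#: Human huntingtin N17 domain.  Positions 14-17 carry the LKSF motif whose
#: substitution modulates polyQ helicity; these constants are editable but
#: the default must keep "LKSF" at 14-17.
N17_SEQUENCE = "MATLEKLMKAFESLKSF"

#: C-terminal proline-rich domain of human huntingtin exon-1, containing the
#: P11 and P10 polyproline tracts.
PRD_SEQUENCE = "PPPPPPPPPPPQLPQPPPQAQPLLPQPQPPPPPPPPPPGPAVAEEPLHRP"

#: Minimal C-terminal polyproline tail used in the reduced constructs.
P5_SEQUENCE = "PPPPP"

#: The DSSP single-letter alphabet ('~' is an accepted alias for coil).
DSSP_CODES = frozenset("HGIEBTSC~")

_AA_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Tail(str, Enum):
    """C-terminal tail attached after the polyQ tract."""

    P5 = "P5"
    PRD = "PRD"
    NONE = "none"


class MotifVariant(str, Enum):
    """Four-residue motif occupying N17 positions 14-17."""

    LKSF = "LKSF"  # wild type
    LKAA = "LKAA"  # helix promoting
    LLLF = "LLLF"  # helix promoting
    LKGG = "LKGG"  # helix disrupting


@dataclass(frozen=True)
class ConstructSpec:
    """Assembly rule for an N17-Qn-tail construct.

    Parameters
    ----------
    polyq_length : int
        Number of glutamine residues in the tract (>= 0).
    tail : Tail
        Which C-terminal tail to append.
    motif_variant : MotifVariant
        Motif written over N17 positions 14-17.
    n17_sequence : str
        17-letter N17 sequence before motif substitution.
    """

    polyq_length: int
    tail: Tail = Tail.P5
    motif_variant: MotifVariant = MotifVariant.LKSF
    n17_sequence: str = N17_SEQUENCE

    def __post_init__(self) -> None:
        if self.polyq_length < 0:
            raise ValueError(f"polyq_length must be >= 0, got {self.polyq_length}")
        if len(self.n17_sequence) != 17:
            raise ValueError(
                f"n17_sequence must have 17 residues, got {len(self.n17_sequence)}"
            )
        bad = set(self.n17_sequence.upper()) - _AA_LETTERS
        if bad:
            raise ValueError(f"non-standard amino-acid letters in N17: {sorted(bad)}")
        if not isinstance(self.tail, Tail):
            object.__setattr__(self, "tail", Tail(self.tail))
        if not isinstance(self.motif_variant, MotifVariant):
            object.__setattr__(self, "motif_variant", MotifVariant(self.motif_variant))

    @property
    def tail_sequence(self) -> str:
        if self.tail is Tail.P5:
            return P5_SEQUENCE
        if self.tail is Tail.PRD:
            return PRD_SEQUENCE
        return ""

    @property
    def length(self) -> int:
        return 17 + self.polyq_length + len(self.tail_sequence)

    @property
    def sequence(self) -> str:
        return build_construct(self)


def build_construct(spec: ConstructSpec) -> str:
    """Assemble the full amino-acid sequence of a construct.

    The motif variant rewrites exactly positions 14-17 of N17; the polyQ
    tract occupies positions 18..17+polyq_length; the tail follows.
    Deterministic and case-stable (always uppercase).
    """
    n17 = spec.n17_sequence.upper()
    motif = spec.motif_variant.value
    n17 = n17[:13] + motif + n17[17:]
    seq = n17 + "Q" * spec.polyq_length + spec.tail_sequence
    if len(seq) != spec.length:
        raise AssertionError("sequence length does not match spec arithmetic")
    return seq


@dataclass(frozen=True)
class RegionAnnotation:
    """Named 1-based inclusive residue range."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region range [{self.start}, {self.end}]")

    @property
    def residues(self) -> range:
        """Residue indices (1-based) covered by the region."""
        return range(self.start, self.end + 1)

    def __len__(self) -> int:
        return self.end - self.start + 1

    def indices0(self) -> np.ndarray:
        """0-based numpy index array for slicing per-residue vectors."""
        return np.arange(self.start - 1, self.end)


def default_regions(
    spec: ConstructSpec,
    central: tuple[int, int] = (11, 17),
    n_terminal: tuple[int, int] = (3, 10),
) -> dict[str, RegionAnnotation]:
    """Default region annotations for a construct.

    Returns ``n_terminal_n17`` (aa 3-10), ``central`` (aa 11-17 by default;
    some analyses use 11-23 which may be requested via ``central``),
    ``polyq`` (18..17+polyq_length) and, when a tail is present, ``tail``.

    Raises
    ------
    ValueError
        If the construct has no polyQ tract (a polyq region cannot be
        annotated) or a custom range falls outside the construct.
    """
    if spec.polyq_length == 0:
        raise ValueError("construct has polyq_length=0; no polyq region exists")
    n = spec.length
    regions = {
        "n_terminal_n17": RegionAnnotation("n_terminal_n17", *n_terminal),
        "central": RegionAnnotation("central", *central),
        "polyq": RegionAnnotation("polyq", 18, 17 + spec.polyq_length),
    }
    if spec.tail is not Tail.NONE:
        regions["tail"] = RegionAnnotation("tail", 18 + spec.polyq_length, n)
    for r in regions.values():
        if r.end > n:
            raise ValueError(f"region {r.name} [{r.start},{r.end}] exceeds length {n}")
    return regions


class SSTrajectory:
    """Frames x residues matrix of DSSP secondary-structure codes.

    Parameters
    ----------
    codes : array-like of single characters, shape (frames, residues)
    frame_interval : float
        Time per saved frame in ns.
    trajectory_id : str
        Free-form label.
    """

    def __init__(self, codes, frame_interval: float = 1.0, trajectory_id: str = ""):
        arr = np.asarray(codes, dtype="<U1")
        if arr.ndim != 2:
            raise ValueError(f"codes must be 2-D (frames x residues), got {arr.ndim}-D")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"empty trajectory: shape {arr.shape}")
        bad = set(np.unique(arr)) - DSSP_CODES
        if bad:
            raise ValueError(f"unknown DSSP codes: {sorted(bad)}")
        if frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ns)")
        self.codes = arr
        self.frame_interval = float(frame_interval)
        self.trajectory_id = trajectory_id

    @property
    def n_frames(self) -> int:
        return self.codes.shape[0]

    @property
    def n_residues(self) -> int:
        return self.codes.shape[1]

    def times(self) -> np.ndarray:
        """Frame times in ns; frame k (1-based) occurs at k * frame_interval."""
        return (np.arange(self.n_frames) + 1) * self.frame_interval

    def validate_against(self, spec: ConstructSpec) -> None:
        if self.n_residues != spec.length:
            raise ValueError(
                f"trajectory has {self.n_residues} residues but construct "
                f"has {spec.length}"
            )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SSTrajectory({self.n_frames} frames x {self.n_residues} residues, "
            f"dt={self.frame_interval} ns, id={self.trajectory_id!r})"
        )


_BACKBONE_NAMES = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3", "HN"}
)


@dataclass
class CoordEnsemble:
    """Frames x atoms x 3 coordinate ensemble with per-atom annotations.

    Coordinates are stored in nm.  ``residue_index`` is 1-based within each
    chain; ``role`` distinguishes backbone from sidechain atoms and
    ``is_heavy`` is False only for hydrogens.
    """

    coordinates: np.ndarray  # (F, A, 3) nm
    residue_index: np.ndarray  # (A,) int, 1-based per chain
    chain_id: np.ndarray  # (A,) str
    atom_name: np.ndarray  # (A,) str
    element: np.ndarray  # (A,) str
    is_heavy: np.ndarray = field(default=None)  # type: ignore[assignment]
    role: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, atoms, 3)")
        if not np.isfinite(self.coordinates).all():
            raise ValueError("coordinates contain non-finite values")
        a = self.coordinates.shape[1]
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.chain_id = np.asarray(self.chain_id, dtype="<U4")
        self.atom_name = np.asarray(self.atom_name, dtype="<U6")
        self.element = np.asarray(self.element, dtype="<U2")
        if self.is_heavy is None:
            self.is_heavy = np.array([e.upper() != "H" for e in self.element])
        else:
            self.is_heavy = np.asarray(self.is_heavy, dtype=bool)
        if self.role is None:
            self.role = np.array(
                [
                    "backbone" if n.upper() in _BACKBONE_NAMES else "sidechain"
                    for n in self.atom_name
                ],
                dtype="<U9",
            )
        else:
            self.role = np.asarray(self.role, dtype="<U9")
        for name, arr in [
            ("residue_index", self.residue_index),
            ("chain_id", self.chain_id),
            ("atom_name", self.atom_name),
            ("element", self.element),
            ("is_heavy", self.is_heavy),
            ("role", self.role),
        ]:
            if arr.shape != (a,):
                raise ValueError(f"{name} must have one entry per atom ({a})")
        if (self.residue_index < 1).any():
            raise ValueError("residue_index must be 1-based (>= 1)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c), None)
        return list(seen)

    def n_residues(self, chain: str | None = None) -> int:
        mask = np.ones(self.n_atoms, bool) if chain is None else self.chain_id == chain
        if not mask.any():
            raise ValueError(f"no atoms in chain {chain!r}")
        return int(self.residue_index[mask].max())

    def atom_mask(
        self,
        chain: str | None = None,
        residues: range | np.ndarray | None = None,
        heavy_only: bool = False,
        role: str | None = None,
        names: set[str] | None = None,
    ) -> np.ndarray:
        """Boolean atom mask combining the given filters."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if residues is not None:
            mask &= np.isin(self.residue_index, np.asarray(list(residues)))
        if heavy_only:
            mask &= self.is_heavy
        if role is not None:
            mask &= self.role == role
        if names is not None:
            mask &= np.isin(self.atom_name, sorted(names))
        return mask


@dataclass(frozen=True)
class ResidueSelection:
    """Residue range on one chain, used for dimer order parameters."""

    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid selection range [{self.start}, {self.end}]")

    @property
    def residues(self) -> range:
        return range(self.start, self.end + 1)

    @classmethod
    def from_region(cls, chain_id: str, region: RegionAnnotation) -> "ResidueSelection":
        return cls(chain_id, region.start, region.end)


def _region_override(
    regions: dict[str, RegionAnnotation], name: str, start: int, end: int
) -> dict[str, RegionAnnotation]:
    """Return a copy of ``regions`` with one range replaced."""
    out = dict(regions)
    out[name] = replace(regions[name], start=start, end=end) if name in regions else \
        RegionAnnotation(name, start, end)
    return out
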