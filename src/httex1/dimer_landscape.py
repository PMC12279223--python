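"""Dimer order parameters, 2D free-energy surfaces, association events.

The dimerization landscape of two N17-led chains is characterized by two
order parameters per frame — the number of inter-chain N17 residue
contacts and the inter-helical angle between the chains' N17 axes — a 2D
potential of mean force over them, and a hysteresis state machine that
segments the contact series into bound/unbound stretches to count
dissociation and reassociation events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import CoordEnsemble, ResidueSelection

__all__ = [
    "PMF2D",
    "AssociationTrace",
    "interhelical_angle",
    "min_distance",
    "pmf2d",
    "association_events",
]


@dataclass
class PMF2D:
    """Binned free-energy surface F(x, y) in kT, min-shifted to zero.

    Empty bins hold NaN (a sentinel), never a fabricated barrier height.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray  # (nx, ny), kT, NaN where unobserved
    counts: np.ndarray
    n_frames: int

    def occupied(self) -> np.ndarray:
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        nx, ny = self.free_energy.shape
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        xs, ys = np.meshgrid(xc, yc, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xs.ravel(),
                "y_center": ys.ravel(),
                "free_energy_kT": self.free_energy.ravel(),
                "count": self.counts.ravel(),
            }
        )


@dataclass
class AssociationTrace:
    """Bound/unbound segmentation of a contact-count series.

    ``bound`` flags each frame; dissociations fire when the count drops
    below ``unbound_threshold`` and reassociations when it climbs back to
    ``bound_threshold`` or above, so oscillation between the two thresholds
    produces no events (hysteresis).
    """

    bound: np.ndarray  # (F,) bool
    dissociation_frames: list[int]
    reassociation_frames: list[int]
    bound_threshold: float
    unbound_threshold: float

    @property
    def n_dissociations(self) -> int:
        return len(self.dissociation_frames)

    @property
    def n_reassociations(self) -> int:
        return len(self.reassociation_frames)

    def to_dict(self) -> dict:
        return {
            "bound_threshold": self.bound_threshold,
            "unbound_threshold": self.unbound_threshold,
            "n_dissociations": self.n_dissociations,
            "n_reassociations": self.n_reassociations,
            "dissociation_frames": self.dissociation_frames,
            "reassociation_frames": self.reassociation_frames,
            "fraction_bound": float(np.mean(self.bound)),
        }


def _axis(ca: np.ndarray) -> np.ndarray:
    """Dominant principal axis of a Calpha selection, oriented N -> C."""
    centred = ca - ca.mean(axis=0)
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[0] <= 1e-12 or (s.size > 1 and not np.isfinite(s[0])):
        raise ValueError("degenerate selection: no dominant axis")
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def interhelical_angle(
    coords: CoordEnsemble,
    helix_a: ResidueSelection,
    helix_b: ResidueSelection,
    method: str = "principal_axis",
) -> np.ndarray:
    """Per-frame angle (degrees, in [0, 180]) between two helix axes.

    The default fits each helix axis as the dominant principal component
    of its Calpha coordinates, oriented from N- to C-terminus; the
    'end_vector' mode instead uses the first-to-last Calpha vector.
    """
    if method not in ("principal_axis", "end_vector"):
        raise ValueError(f"unknown angle method {method!r}")
    out = np.empty(coords.n_frames)
    masks = []
    for sel in (helix_a, helix_b):
        m = coords.atom_mask(chain=sel.chain_id, residues=sel.residues, names={"CA"})
        if m.sum() < 4:
            raise ValueError(
                f"selection {sel} has {int(m.sum())} Calpha atoms; need >= 4"
            )
        masks.append(np.flatnonzero(m))
    for f in range(coords.n_frames):
        axes = []
        for idx in masks:
            ca = coords.coordinates[f, idx]
            if method == "principal_axis":
                axes.append(_axis(ca))
            else:
                v = ca[-1] - ca[0]
                n = np.linalg.norm(v)
                if n == 0:
                    raise ValueError("degenerate selection: coincident termini")
                axes.append(v / n)
        out[f] = np.degrees(np.arccos(np.clip(np.dot(axes[0], axes[1]), -1.0, 1.0)))
    return out


def min_distance(
    coords: CoordEnsemble,
    selection_a: ResidueSelection,
    selection_b: ResidueSelection,
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance (nm) between two selections."""
    ma = coords.atom_mask(
        chain=selection_a.chain_id, residues=selection_a.residues, heavy_only=True
    )
    mb = coords.atom_mask(
        chain=selection_b.chain_id, residues=selection_b.residues, heavy_only=True
    )
    if not ma.any() or not mb.any():
        raise ValueError("empty selection")
    ia, ib = np.flatnonzero(ma), np.flatnonzero(mb)
    out = np.empty(coords.n_frames)
    for f in range(coords.n_frames):
        out[f] = cdist(coords.coordinates[f, ia], coords.coordinates[f, ib]).min()
    return out


def pmf2d(
    x_series: np.ndarray,
    y_series: np.ndarray,
    bins=None,
    x_bin_width: float = 2.0,
    y_bin_width: float = 10.0,
) -> PMF2D:
    """2D potential of mean force over two order-parameter series.

    The joint histogram is normalized over occupied bins and converted to
    F = -ln(P / P_max) in kT, so the global minimum sits at exactly zero.
    Default binning uses width 2 on the contact-count axis and 10 degrees
    on the angle axis; pass explicit ``bins`` (numpy-histogram style) to
    override.
    """
    x = np.asarray(x_series, float)
    y = np.asarray(y_series, float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("order-parameter series must be equal-length and non-empty")
    if bins is None:
        bins = (_width_edges(x, x_bin_width), _width_edges(y, y_bin_width))
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=bins)
    p = counts / counts.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        f = -np.log(p / p.max())
    f[counts == 0] = np.nan
    return PMF2D(
        x_edges=x_edges,
        y_edges=y_edges,
        free_energy=f,
        counts=counts.astype(int),
        n_frames=x.size,
    )


def _width_edges(v: np.ndarray, width: float) -> np.ndarray:
    lo = np.floor(v.min() / width) * width
    hi = np.ceil(v.max() / width) * width
    if hi <= lo:
        hi = lo + width
    return np.arange(lo, hi + width / 2, width)


def association_events(
    contact_counts: np.ndarray,
    bound_threshold: float = 10.0,
    unbound_threshold: float = 1.0,
) -> AssociationTrace:
    """Segment a contact-count series into bound/unbound with hysteresis.

    The dimer leaves the bound state when the count drops below
    ``unbound_threshold`` and re-enters it when the count reaches
    ``bound_threshold``; the gap between thresholds suppresses spurious
    event pairs from boundary noise.  The initial state is bound iff the
    first frame's count is at or above ``bound_threshold``.
    """
    if not bound_threshold > unbound_threshold >= 0:
        raise ValueError(
            "hysteresis requires bound_threshold > unbound_threshold >= 0"
        )
    counts = np.asarray(contact_counts, float)
    if counts.size == 0:
        raise ValueError("empty contact-count series")
    bound = np.empty(counts.size, dtype=bool)
    state = counts[0] >= bound_threshold
    dis: list[int] = []
    reas: list[int] = []
    for f, c in enumerate(counts):
        if state and c < unbound_threshold:
            state = False
            dis.append(f)
        elif not state and c >= bound_threshold:
            # cannot fire at f=0: the initial state already absorbs it
            state = True
            reas.append(f)
        bound[f] = state
    return AssociationTrace(
        bound=bound,
        dissociation_frames=dis,
        reassociation_frames=reas,
        bound_threshold=bound_threshold,
        unbound_threshold=unbound_threshold,
    )
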