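"""Named active-site distances and the composite scalar coordinates built from them.

Distances are heavy-atom Euclidean distances in Å.  Inputs are assumed to be
whole-molecule, unwrapped frames: no minimum-image handling is applied, which
is safe because active-site distances are far smaller than any box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "AtomSelection",
    "pair_distance",
    "nearest_solvent_distance",
    "reaction_coordinate",
    "d_actsite",
    "d_react",
    "contact_occupancy",
]


@dataclass
class AtomSelection:
    """A labelled set of atom indices into a coordinate frame."""

    label: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.atleast_1d(np.asarray(self.indices, dtype=int))
        if self.indices.size == 0:
            raise ValidationError(f"selection {self.label!r} is empty")


def _coords_of(frame: np.ndarray, sel: AtomSelection) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if np.any(sel.indices < 0) or np.any(sel.indices >= frame.shape[0]):
        raise ValidationError(
            f"selection {sel.label!r} has indices outside the {frame.shape[0]}-atom frame"
        )
    return frame[sel.indices]


def pair_distance(frame: np.ndarray, a: AtomSelection, b: AtomSelection,
                  mode: str = "single") -> float:
    """Distance between two selections in one frame.

    ``single`` requires one atom per selection; ``min_pair`` returns the
    minimum over the full a×b pair set (the convention used for
    donor/acceptor hydrogen-bond distances over heavy atoms).
    """
    pa, pb = _coords_of(frame, a), _coords_of(frame, b)
    if mode == "single":
        if len(pa) != 1 or len(pb) != 1:
            raise ValidationError("mode 'single' requires one atom per selection")
        return float(np.linalg.norm(pa[0] - pb[0]))
    if mode == "min_pair":
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        return float(d.min())
    raise ValidationError(f"unknown mode {mode!r}")


def nearest_solvent_distance(frame: np.ndarray, target: AtomSelection,
                             solvent: AtomSelection) -> tuple[float, int]:
    """Minimum target→solvent distance and the index of the nearest solvent atom.

    The solvent selection should list one reference atom (e.g. the oxygen)
    per solvent molecule; the identity returned is the attaining atom's
    index within the frame.
    """
    pt, ps = _coords_of(frame, target), _coords_of(frame, solvent)
    d = np.linalg.norm(pt[:, None, :] - ps[None, :, :], axis=-1)
    flat = int(np.argmin(d))
    j = flat % ps.shape[0]
    return float(d.min()), int(solvent.indices[j])


def _check_finite(*arrays) -> None:
    for arr in arrays:
        if not np.all(np.isfinite(arr)):
            raise ValidationError("non-finite distance input")


def reaction_coordinate(d_glyc, d_acid):
    """RC = d_glyc − d_acid: scissile-bond stretch minus acid proton distance.

    Negative on the reactant side, positive on the product side.
    Vectorizes over series.
    """
    d_glyc, d_acid = np.asarray(d_glyc, dtype=float), np.asarray(d_acid, dtype=float)
    _check_finite(d_glyc, d_acid)
    return d_glyc - d_acid


def d_actsite(d_acid, d_nuc, d_glu233_wat):
    """Active-site compactness: d_acid + d_nuc + d_Glu233–WAT."""
    arrays = [np.asarray(a, dtype=float) for a in (d_acid, d_nuc, d_glu233_wat)]
    _check_finite(*arrays)
    return arrays[0] + arrays[1] + arrays[2]


def d_react(d_acid, d_glyc_wat, d_nuc):
    """Monotone composite coordinate d_acid − d_glyc–WAT + d_nuc."""
    arrays = [np.asarray(a, dtype=float) for a in (d_acid, d_glyc_wat, d_nuc)]
    _check_finite(*arrays)
    return arrays[0] - arrays[1] + arrays[2]


def contact_occupancy(distances, cutoff: float) -> tuple[float, int, int]:
    """Fraction of frames with distance < cutoff; returns (fraction, count, total)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    distances = np.asarray(distances, dtype=float)
    if distances.size == 0:
        raise ValidationError("empty distance series")
    count = int(np.count_nonzero(distances < cutoff))
    return count / distances.size, count, int(distances.size)
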