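"""Cremer–Pople puckering coordinates and canonical conformer classification.

Six-membered rings are described by a total puckering amplitude ``Q`` (Å) and
two spherical angles: the pseudorotation phase ``phi`` in [0, 360) and the
polar angle ``theta`` in [0, 180].  Chairs sit at the poles, boats and
skews (twist-boats) on the equator, and half-chairs/envelopes on two tropic
bands in each hemisphere.

Ring-atom ordering convention: the ring oxygen (O5) is atom index 0, followed
by C1…C5 in IUPAC numbering order.  Under this convention the ``4C1`` chair
of an α-D-glucopyranose generated by :mod:`glycopmf.synthetic` sits at
``theta = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import GeometryError, ValidationError

__all__ = [
    "RingGeometry",
    "PuckerState",
    "canonical_table",
    "cremer_pople",
    "classify_conformer",
    "pucker_series",
    "PLANARITY_TOLERANCE",
]

#: Rings with Q below this amplitude (Å) are reported as planar; phi/theta
#: are numerically meaningless there.
PLANARITY_TOLERANCE = 0.01

# Polar angles of the ideal envelope (one atom out of the plane of the other
# five) and half-chair (two adjacent atoms on opposite sides of the plane of
# the other four) displacement patterns: q3/q2 = 1/sqrt(2) and sqrt(2/3).
_THETA_ENVELOPE = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356
_THETA_HALFCHAIR = math.degrees(math.acos(math.sqrt(2.0 / 5.0)))  # 50.7685

_ATOM_NAMES = ("O", "1", "2", "3", "4", "5")

# Skew (twist-boat) labels are restricted to the canonical exoplanar pairs.
_SKEW_PAIRS = ({0, 2}, {1, 3}, {1, 5})


@dataclass
class RingGeometry:
    """Cartesian coordinates of one six-membered ring in one frame.

    ``coords`` holds six positions in Å ordered ring-oxygen first, then the
    carbons in IUPAC numbering order.
    """

    coords: np.ndarray
    frame_id: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (6, 3):
            raise ValidationError(
                f"ring must have exactly 6 atoms with xyz, got shape {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite ring coordinates")


@dataclass
class PuckerState:
    """Cremer–Pople description of one ring frame."""

    Q: float
    phi: float
    theta: float
    conformer: str
    planar: bool
    q2: float = 0.0
    q3: float = 0.0
    frame_id: int = 0
    #: out-of-plane displacements, kept for diagnostics
    z: np.ndarray = field(default_factory=lambda: np.zeros(6))


def _ideal_z_pattern(phi2_deg: float) -> np.ndarray:
    """Unit equatorial displacement pattern cos(phi2 + 120°·j), j = 0..5."""
    j = np.arange(6)
    return np.cos(np.radians(phi2_deg) + 2.0 * np.pi * j / 3.0)


def _equator_label(phi_deg: float) -> str:
    """Boat or skew label for an equatorial vertex at ``phi_deg``."""
    z = _ideal_z_pattern(phi_deg)
    ups = set(np.flatnonzero(z > 0.7).tolist())
    downs = set(np.flatnonzero(z < -0.7).tolist())
    if len(ups) == 2 and not downs:  # boat, prow and stern above the plane
        a, b = sorted(ups)
        pair = f"{_ATOM_NAMES[b]},{_ATOM_NAMES[a]}" if a == 0 else f"{_ATOM_NAMES[a]},{_ATOM_NAMES[b]}"
        return f"{pair}B"
    if len(downs) == 2 and not ups:
        a, b = sorted(downs)
        pair = f"{_ATOM_NAMES[b]},{_ATOM_NAMES[a]}" if a == 0 else f"{_ATOM_NAMES[a]},{_ATOM_NAMES[b]}"
        return f"B{pair}"
    # twist-boat: two up, two down; the canonical name uses the unique
    # up/down combination drawn from the conventional exoplanar pairs
    for u in ups:
        for d in downs:
            if {u, d} in _SKEW_PAIRS:
                return f"{_ATOM_NAMES[u]}S{_ATOM_NAMES[d]}"
    raise RuntimeError(f"no canonical skew pair at phi={phi_deg}")  # pragma: no cover


@lru_cache(maxsize=1)
def canonical_table() -> dict[str, tuple[float, float]]:
    """Canonical (phi, theta) vertex for each of the 38 named conformers.

    Built from the ideal displacement patterns rather than hand-typed:
    2 chairs, 6 boats, 6 skews, 12 envelopes, 12 half-chairs.
    """
    table: dict[str, tuple[float, float]] = {"4C1": (0.0, 0.0), "1C4": (0.0, 180.0)}
    for m in range(12):
        phi = 30.0 * m
        table[_equator_label(phi)] = (phi, 90.0)
    for j in range(6):
        north = j % 2 == 0  # even-index atom displaced upward -> northern tropic
        # envelope with atom j above the plane / below the plane
        table[f"{_ATOM_NAMES[j]}E"] = (
            (-120.0 * j) % 360.0,
            _THETA_ENVELOPE if north else 180.0 - _THETA_ENVELOPE,
        )
        table[f"E{_ATOM_NAMES[j]}"] = (
            (180.0 - 120.0 * j) % 360.0,
            180.0 - _THETA_ENVELOPE if north else _THETA_ENVELOPE,
        )
        # half-chair with atom j above and atom j+1 below, and its mirror
        k = (j + 1) % 6
        table[f"{_ATOM_NAMES[j]}H{_ATOM_NAMES[k]}"] = (
            (30.0 - 120.0 * j) % 360.0,
            _THETA_HALFCHAIR if north else 180.0 - _THETA_HALFCHAIR,
        )
        table[f"{_ATOM_NAMES[k]}H{_ATOM_NAMES[j]}"] = (
            (210.0 - 120.0 * j) % 360.0,
            180.0 - _THETA_HALFCHAIR if north else _THETA_HALFCHAIR,
        )
    assert len(table) == 38
    return table


def displacements_from_pucker(q2: float, phi2_deg: float, q3: float) -> np.ndarray:
    """Invert the puckering decomposition to per-atom displacements z_j."""
    j = np.arange(6)
    return (
        math.sqrt(1.0 / 3.0) * q2 * np.cos(np.radians(phi2_deg) + 2.0 * np.pi * j / 3.0)
        + math.sqrt(1.0 / 6.0) * q3 * np.cos(np.pi * j)
    )


def cremer_pople(ring: RingGeometry | np.ndarray, planarity_tol: float = PLANARITY_TOLERANCE) -> PuckerState:
    """Compute (Q, phi, theta) and the conformer label for one ring frame.

    Raises :class:`GeometryError` on degenerate input (coincident or
    collinear atoms) instead of returning NaNs.
    """
    if not isinstance(ring, RingGeometry):
        ring = RingGeometry(np.asarray(ring))
    r = ring.coords - ring.coords.mean(axis=0)
    j = np.arange(6)
    r1 = (r * np.sin(2.0 * np.pi * j / 6.0)[:, None]).sum(axis=0)
    r2 = (r * np.cos(2.0 * np.pi * j / 6.0)[:, None]).sum(axis=0)
    normal = np.cross(r1, r2)
    norm = np.linalg.norm(normal)
    if norm < 1e-9:
        raise GeometryError(
            f"degenerate ring geometry in frame {ring.frame_id}: mean plane undefined"
        )
    normal /= norm
    z = r @ normal

    q2cos = math.sqrt(1.0 / 3.0) * float(np.sum(z * np.cos(4.0 * np.pi * j / 6.0)))
    q2sin = -math.sqrt(1.0 / 3.0) * float(np.sum(z * np.sin(4.0 * np.pi * j / 6.0)))
    q3 = math.sqrt(1.0 / 6.0) * float(np.sum(z * np.cos(np.pi * j)))
    q2 = math.hypot(q2cos, q2sin)
    big_q = math.hypot(q2, q3)

    if big_q < planarity_tol:
        return PuckerState(
            Q=big_q, phi=float("nan"), theta=float("nan"),
            conformer="planar", planar=True, q2=q2, q3=q3,
            frame_id=ring.frame_id, z=z,
        )
    phi = math.degrees(math.atan2(q2sin, q2cos)) % 360.0
    theta = math.degrees(math.acos(max(-1.0, min(1.0, q3 / big_q))))
    state = PuckerState(
        Q=big_q, phi=phi, theta=theta, conformer="", planar=False,
        q2=q2, q3=q3, frame_id=ring.frame_id, z=z,
    )
    state.conformer = classify_conformer(state)
    return state


def _angular_distance(phi1: float, theta1: float, phi2: float, theta2: float) -> float:
    """Great-circle distance (radians) between two puckering-sphere points."""
    t1, t2 = math.radians(theta1), math.radians(theta2)
    dphi = math.radians(phi1 - phi2)
    c = math.cos(t1) * math.cos(t2) + math.sin(t1) * math.sin(t2) * math.cos(dphi)
    return math.acos(max(-1.0, min(1.0, c)))


def classify_conformer(state: PuckerState, table: dict[str, tuple[float, float]] | None = None) -> str:
    """Nearest canonical vertex on the puckering sphere; ties break lexicographically."""
    if state.planar:
        return "planar"
    if table is None:
        table = canonical_table()
    best_label, best_dist = None, float("inf")
    for label in sorted(table):
        phi_c, theta_c = table[label]
        d = _angular_distance(state.phi, state.theta, phi_c, theta_c)
        if d < best_dist - 1e-12:
            best_label, best_dist = label, d
    assert best_label is not None
    return best_label


def pucker_series(
    trajectory: list[RingGeometry],
    planarity_tol: float = PLANARITY_TOLERANCE,
) -> tuple[list[PuckerState], dict[str, float]]:
    """Per-frame pucker states plus label occupancy fractions (summing to 1)."""
    if not trajectory:
        raise ValidationError("empty ring trajectory")
    states: list[PuckerState] = []
    for i, ring in enumerate(trajectory):
        try:
            states.append(cremer_pople(ring, planarity_tol=planarity_tol))
        except GeometryError as exc:
            raise GeometryError(f"frame {i}: {exc}") from exc
    occupancy: dict[str, float] = {}
    for state in states:
        occupancy[state.conformer] = occupancy.get(state.conformer, 0.0) + 1.0
    n = float(len(states))
    return states, {label: count / n for label, count in sorted(occupancy.items())}
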