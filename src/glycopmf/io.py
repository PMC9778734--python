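"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: multi-model PDB and XYZ trajectories, tab-separated CV tables
(`# time_ps  <label> ...`), and tab-separated free-energy profiles.  Floats in
the text tables are written with 17 significant digits so write→read round
trips are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .constants import DEFAULT_TEMPERATURE
from .collective_variables import AtomSelection
from .errors import ValidationError
from .free_energy import FreeEnergyProfile
from .puckering import RingGeometry
from .series import CVSeries

__all__ = [
    "Trajectory",
    "read_trajectory",
    "write_trajectory",
    "ring_frames_to_trajectory",
    "read_cv_table",
    "write_cv_table",
    "write_profile",
    "resolve_selection",
]

_RING_ATOM_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")


@dataclass
class Trajectory:
    """Ordered coordinate frames plus per-atom metadata for selections."""

    coords: np.ndarray  # (n_frames, n_atoms, 3)
    atom_names: np.ndarray
    elements: np.ndarray
    res_ids: np.ndarray
    res_names: np.ndarray
    chain_ids: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValidationError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def ring_geometries(self, selection: AtomSelection) -> list[RingGeometry]:
        if selection.indices.size != 6:
            raise ValidationError("ring selection must resolve to exactly 6 atoms")
        return [RingGeometry(self.coords[i][selection.indices], frame_id=i)
                for i in range(self.n_frames)]


def _read_pdb(path: Path) -> Trajectory:
    text = path.read_text()
    altlocs = {
        line[16] for line in text.splitlines()
        if line.startswith(("ATOM", "HETATM")) and len(line) > 16 and line[16] != " "
    }
    if altlocs - {"A"} or len(altlocs) > 1:
        warnings.warn(f"{path}: alternate locations present; keeping the first altloc",
                      stacklevel=3)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, altloc="first")
    if isinstance(stack, struc.AtomArray):  # single model
        stack = struc.stack([stack])
    return Trajectory(
        coords=np.asarray(stack.coord, dtype=float),
        atom_names=np.asarray(stack.atom_name),
        elements=np.asarray(stack.element),
        res_ids=np.asarray(stack.res_id),
        res_names=np.asarray(stack.res_name),
        chain_ids=np.asarray(stack.chain_id),
    )


def _read_xyz(path: Path) -> Trajectory:
    lines = path.read_text().splitlines()
    frames, names, times = [], None, []
    i = 0
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValidationError(f"{path}:{i + 1}: expected an atom count") from None
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        t = None
        for token in comment.split():
            if token.startswith("t="):
                try:
                    t = float(token[2:])
                except ValueError:
                    pass
        times.append(t if t is not None else float(frame_no))
        block = lines[i + 2:i + 2 + n]
        if len(block) < n:
            raise ValidationError(f"{path}: truncated frame starting at line {i + 1}")
        symbols, coords = [], []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValidationError(f"{path}:{i + 3 + k}: malformed atom line")
            symbols.append(parts[0])
            try:
                coords.append([float(v) for v in parts[1:4]])
            except ValueError:
                raise ValidationError(f"{path}:{i + 3 + k}: non-numeric coordinate") from None
        if names is None:
            names = symbols
        elif symbols != names:
            raise ValidationError(f"{path}: inconsistent atoms across frames")
        frames.append(coords)
        i += 2 + n
        frame_no += 1
    if not frames:
        raise ValidationError(f"{path}: no frames found")
    n_atoms = len(names)
    return Trajectory(
        coords=np.asarray(frames, dtype=float),
        atom_names=np.asarray(names),
        elements=np.asarray([n.strip("0123456789") or n for n in names]),
        res_ids=np.ones(n_atoms, dtype=int),
        res_names=np.asarray(["UNK"] * n_atoms),
        chain_ids=np.asarray(["A"] * n_atoms),
        times=np.asarray(times, dtype=float),
    )


def read_trajectory(path, fmt: str | None = None) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory (format inferred from suffix)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such trajectory file: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "pdb":
        return _read_pdb(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValidationError(f"unknown trajectory format {fmt!r} (expected pdb or xyz)")


def write_trajectory(traj: Trajectory, path, fmt: str | None = None) -> None:
    """Write frames as multi-model PDB or XYZ (the reader's inverse)."""
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        with path.open("w") as fh:
            for i in range(traj.n_frames):
                fh.write(f"{traj.n_atoms}\n")
                fh.write(f"t={traj.times[i]:.17g} frame {i}\n")
                for name, xyz in zip(traj.elements, traj.coords[i]):
                    fh.write(f"{name} {xyz[0]:.17g} {xyz[1]:.17g} {xyz[2]:.17g}\n")
        return
    if fmt == "pdb":
        n = traj.n_atoms
        template = struc.AtomArray(n)
        template.atom_name = traj.atom_names
        template.element = traj.elements
        template.res_id = traj.res_ids
        template.res_name = traj.res_names
        template.chain_id = traj.chain_ids
        template.hetero = np.zeros(n, dtype=bool)
        arrays = []
        for i in range(traj.n_frames):
            arr = template.copy()
            arr.coord = traj.coords[i].astype(np.float32)
            arrays.append(arr)
        pdb = PDBFile()
        pdb.set_structure(struc.stack(arrays))
        pdb.write(str(path))
        return
    raise ValidationError(f"unknown trajectory format {fmt!r}")


def ring_frames_to_trajectory(rings: list[RingGeometry],
                              times: np.ndarray | None = None) -> Trajectory:
    """Package generated ring geometries as a writable trajectory."""
    if not rings:
        raise ValidationError("no ring frames")
    coords = np.stack([r.coords for r in rings])
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(_RING_ATOM_NAMES),
        elements=np.asarray(["O", "C", "C", "C", "C", "C"]),
        res_ids=np.ones(6, dtype=int),
        res_names=np.asarray(["GLC"] * 6),
        chain_ids=np.asarray(["A"] * 6),
        times=times,
    )


def write_cv_table(series: CVSeries, path) -> None:
    """Tab-separated CV table: `# time_ps  <label1> <label2> ...`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# temperature_K\t{series.temperature:.17g}\n")
        fh.write("# time_ps\t" + "\t".join(series.labels) + "\n")
        for t, row in zip(series.times, series.values):
            fh.write(f"{t:.17g}\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_cv_table(path, temperature: float | None = None) -> CVSeries:
    """Read a CV table; errors name the offending line."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such CV table: {path}")
    labels: list[str] | None = None
    file_temp = None
    times, rows = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            parts = line.lstrip("#").split()
            if parts and parts[0] == "temperature_K" and len(parts) > 1:
                file_temp = float(parts[1])
            elif parts and parts[0] == "time_ps":
                labels = parts[1:]
            continue
        parts = line.split()
        if labels is None:
            raise ValidationError(f"{path}:{lineno}: data before the header line")
        if len(parts) != len(labels) + 1:
            raise ValidationError(
                f"{path}:{lineno}: expected {len(labels) + 1} columns, got {len(parts)}"
            )
        try:
            values = [float(v) for v in parts]
        except ValueError:
            raise ValidationError(f"{path}:{lineno}: non-numeric cell") from None
        times.append(values[0])
        rows.append(values[1:])
    if labels is None or not rows:
        raise ValidationError(f"{path}: no data rows")
    if temperature is None:
        temperature = file_temp if file_temp is not None else DEFAULT_TEMPERATURE
    return CVSeries(times=np.asarray(times), values=np.asarray(rows),
                    labels=labels, temperature=temperature)


def write_profile(profile: FreeEnergyProfile, path) -> None:
    """Tab-separated profile: bin center(s), ΔG, probability mass, occupancy flag."""
    path = Path(path)
    centers = profile.centers
    with path.open("w") as fh:
        axis_cols = "\t".join(f"{a}_bin_center" for a in profile.axis_labels)
        fh.write(f"# {axis_cols}\tdelta_g_kcal_mol\tmass\tflag\n")
        if len(centers) == 1:
            for i, c in enumerate(centers[0]):
                g, m = profile.delta_g[i], profile.mass[i]
                flag = "occupied" if np.isfinite(g) else "empty"
                fh.write(f"{c:.17g}\t{g:.17g}\t{m:.17g}\t{flag}\n")
        else:
            for i, cx in enumerate(centers[0]):
                for j, cy in enumerate(centers[1]):
                    g, m = profile.delta_g[i, j], profile.mass[i, j]
                    flag = "occupied" if np.isfinite(g) else "empty"
                    fh.write(f"{cx:.17g}\t{cy:.17g}\t{g:.17g}\t{m:.17g}\t{flag}\n")


def resolve_selection(traj: Trajectory, spec, label: str) -> AtomSelection:
    """Resolve a selection config entry to atom indices.

    ``spec`` is either a list of flat 0-based indices or a mapping with any
    of ``chain_id``, ``res_id``, ``res_name``, ``atom_name`` (scalar or list)
    plus optional ``heavy: true`` to drop hydrogens.
    """
    if isinstance(spec, (list, tuple, np.ndarray)):
        return AtomSelection(label=label, indices=np.asarray(spec, dtype=int))
    if not isinstance(spec, dict):
        raise ValidationError(f"selection {label!r}: expected list of indices or mapping")
    if "indices" in spec:
        return AtomSelection(label=label, indices=np.asarray(spec["indices"], dtype=int))
    mask = np.ones(traj.n_atoms, dtype=bool)
    fields = {"chain_id": traj.chain_ids, "res_id": traj.res_ids,
              "res_name": traj.res_names, "atom_name": traj.atom_names}
    known = set(fields) | {"heavy"}
    unknown = set(spec) - known
    if unknown:
        raise ValidationError(f"selection {label!r}: unknown keys {sorted(unknown)}")
    for key, column in fields.items():
        if key not in spec:
            continue
        wanted = spec[key]
        if not isinstance(wanted, (list, tuple)):
            wanted = [wanted]
        mask &= np.isin(column, np.asarray(wanted))
    if spec.get("heavy"):
        mask &= np.asarray([e.upper() != "H" for e in traj.elements])
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise ValidationError(f"selection {label!r} matches no atoms")
    return AtomSelection(label=label, indices=indices)
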