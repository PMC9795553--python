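"""Domain types and structure/trajectory I/O.

Coordinates are Å throughout, times ns, atom indices 0-based, residue
ids 1-based (as in PDB). File parsing and writing delegate to
MDAnalysis; the in-memory containers here are deliberately small and
format-agnostic.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES
from .errors import ConsistencyError, FormatError, SelectionError

__all__ = [
    "AtomRecord",
    "Trajectory",
    "TimeSeriesTable",
    "element_from_name",
    "mass_of_element",
    "read_structure",
    "write_structure",
    "read_coordinates",
    "write_coordinates",
    "select_atoms",
]


def element_from_name(name: str) -> str:
    """Infer the element symbol from a PDB-style atom name.

    Two-letter symbols (NA, CL, MG, ...) are recognised when the whole
    stripped name matches; otherwise the first alphabetic character wins,
    so ``C1'`` -> C, ``N9`` -> N, ``O4'`` -> O.
    """
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        raise FormatError(f"cannot infer element from atom name {name!r}")
    if stripped in ATOMIC_MASSES and len(stripped) == 2:
        return stripped
    return stripped[0]


def mass_of_element(element: str) -> float:
    """Standard atomic weight in amu; unknown elements are an error."""
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise FormatError(f"unknown element {element!r}: no standard mass") from None


@dataclass(frozen=True)
class AtomRecord:
    """One atom's identity and mass."""

    name: str
    element: str
    residue_id: int
    residue_name: str
    mass: float
    index: int

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ConsistencyError(f"atom {self.name}: mass must be > 0, got {self.mass}")


@dataclass
class Trajectory:
    """An ordered atom list plus one or more coordinate frames.

    coords has shape (n_frames, n_atoms, 3) in Å.  frame_times, when
    present, are strictly increasing and in ns.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConsistencyError(f"coords must be (frames, atoms, 3), got {self.coords.shape}")
        n = len(self.atoms)
        if n < 1:
            raise ConsistencyError("a trajectory needs at least one atom")
        if self.coords.shape[1] != n:
            raise ConsistencyError(
                f"{n} atoms but frames carry {self.coords.shape[1]} positions"
            )
        indices = [a.index for a in self.atoms]
        if sorted(indices) != list(range(n)):
            raise ConsistencyError("atom indices must be 0..N-1 and unique")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.n_frames:
                raise ConsistencyError("frame_times length must match frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
                raise ConsistencyError("frame_times must be strictly increasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return int(self.coords.shape[0])

    def frame(self, i: int) -> np.ndarray:
        """Coordinates of frame i, shape (n_atoms, 3)."""
        return self.coords[i]

    def with_coords(self, coords: np.ndarray, frame_times: np.ndarray | None = None) -> "Trajectory":
        """New Trajectory sharing this one's atom metadata."""
        return Trajectory(self.atoms, coords, frame_times)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])


@dataclass
class TimeSeriesTable:
    """Per-frame scalar observables: a time column plus named value columns."""

    columns: list[str]
    data: pd.DataFrame = field(repr=False)

    @classmethod
    def from_arrays(cls, times: Sequence[float], **series) -> "TimeSeriesTable":
        df = pd.DataFrame({"time": np.asarray(times, dtype=float), **series})
        return cls(columns=list(df.columns), data=df)

    def __post_init__(self) -> None:
        if "time" not in self.data.columns:
            raise ConsistencyError("TimeSeriesTable needs a 'time' column")
        t = self.data["time"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) < 0):
            raise ConsistencyError("times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "TimeSeriesTable":
        df = pd.read_csv(path)
        return cls(columns=list(df.columns), data=df)


def _records_from_universe(u) -> list[AtomRecord]:
    records = []
    for i, atom in enumerate(u.atoms):
        element = getattr(atom, "element", "") or ""
        element = element.strip()
        if not element:
            element = element_from_name(atom.name)
        records.append(
            AtomRecord(
                name=atom.name,
                element=element.upper() if len(element) > 1 else element.upper(),
                residue_id=int(atom.resid),
                residue_name=str(atom.resname),
                mass=mass_of_element(element),
                index=i,
            )
        )
    return records


def read_structure(path: str | Path) -> Trajectory:
    """Read a PDB file into a single-frame Trajectory."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except (OSError, IOError):
        raise
    except Exception as exc:  # MDAnalysis raises assorted parse errors
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if len(u.atoms) == 0:
        raise FormatError(f"{path}: no atoms")
    records = _records_from_universe(u)
    coords = u.atoms.positions.astype(float)[None]
    return Trajectory(records, coords)


def write_structure(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as PDB."""
    u = _universe_from(traj)
    u.atoms.positions = traj.coords[frame]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))


def _universe_from(traj: Trajectory):
    import MDAnalysis as mda

    resids_per_atom = [a.residue_id for a in traj.atoms]
    unique_res = sorted(set(resids_per_atom))
    res_index = {r: i for i, r in enumerate(unique_res)}
    u = mda.Universe.empty(
        traj.n_atoms,
        n_residues=len(unique_res),
        atom_resindex=[res_index[r] for r in resids_per_atom],
        trajectory=True,
    )
    u.add_TopologyAttr("names", [a.name for a in traj.atoms])
    u.add_TopologyAttr("elements", [a.element for a in traj.atoms])
    u.add_TopologyAttr("masses", [a.mass for a in traj.atoms])
    resname_of = {a.residue_id: a.residue_name for a in traj.atoms}
    u.add_TopologyAttr("resnames", [resname_of[r] for r in unique_res])
    u.add_TopologyAttr("resids", unique_res)
    return u


def write_coordinates(traj: Trajectory, path: str | Path) -> None:
    """Write all frames to a trajectory file (format from extension: DCD/XTC)."""
    import MDAnalysis as mda

    u = _universe_from(traj)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), traj.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coords[f]
                w.write(u.atoms)


def read_coordinates(path: str | Path, template: Trajectory) -> Trajectory:
    """Read a multi-frame coordinate file, borrowing atom metadata from template."""
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    u = _universe_from(template)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.load_new(str(path))
    except (ValueError, IndexError) as exc:
        msg = str(exc)
        if "atom" in msg.lower() or "shape" in msg.lower() or "mismatch" in msg.lower():
            raise ConsistencyError(f"{path}: atom count mismatch with template") from exc
        raise FormatError(f"cannot read {path}: {exc}") from exc
    except EOFError as exc:
        raise FormatError(f"{path}: truncated trajectory") from exc
    if len(u.atoms) != template.n_atoms:
        raise ConsistencyError(
            f"{path} has {len(u.atoms)} atoms, template has {template.n_atoms}"
        )
    frames = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
            times.append(float(ts.time))
    coords = np.stack(frames)
    times_arr = np.asarray(times) / 1000.0  # MDAnalysis ps -> ns
    if len(times_arr) > 1 and np.all(np.diff(times_arr) > 0):
        frame_times = times_arr
    else:
        frame_times = None
    return template.with_coords(coords, frame_times)


def select_atoms(
    traj: Trajectory,
    residue_ids: Iterable[int] | None = None,
    atom_names: Iterable[str] | None = None,
) -> list[int]:
    """Indices of atoms matching both filters, in trajectory order.

    A filter of None matches everything; an empty set matches nothing.
    """
    rid = None if residue_ids is None else set(residue_ids)
    names = None if atom_names is None else set(atom_names)
    out = []
    for a in traj.atoms:
        if rid is not None and a.residue_id not in rid:
            continue
        if names is not None and a.name not in names:
            continue
        out.append(a.index)
    return out


def require_atom(traj: Trajectory, residue_id: int, name: str) -> int:
    """Index of the unique atom (residue_id, name); SelectionError if absent."""
    hits = select_atoms(traj, {residue_id}, {name})
    if len(hits) != 1:
        raise SelectionError(
            f"expected exactly one atom {name!r} in residue {residue_id}, found {len(hits)}"
        )
    return hits[0]
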