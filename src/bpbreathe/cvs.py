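"""Collective variables for base-pair breathing and WC/HG state assignment.

The glycosidic angle χ (dihedral O4′–C1′–N9–C4 of the purine) reports
the *anti*/*syn* orientation of the adenine base; the pseudodihedral Θ
of four atom-group centers reports base flipping toward the major
(Θ > 0) or minor (Θ < 0) groove.  Watson–Crick pairing puts the
N1(A)–N3(T) donor–acceptor pair in hydrogen-bonding range, Hoogsteen
pairing the N7(A)–N3(T) pair, so the two distances identify the states
unambiguously.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core import TimeSeriesTable, Trajectory, require_atom
from .errors import GeometryError, SelectionError

__all__ = [
    "StateLabel",
    "ClassifierThresholds",
    "BasePairGeometry",
    "dihedral_angle",
    "chi_angle",
    "theta_angle",
    "basepair_geometry",
    "classify_state",
    "cv_timeseries",
]


class StateLabel(str, Enum):
    WC = "WC"
    HG = "HG"
    OPEN = "OPEN"
    UNASSIGNED = "UNASSIGNED"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Distance cutoffs for hydrogen-bond based state assignment.

    bond_max is the longest donor–acceptor distance still counted as a
    hydrogen bond; open_min the shortest counted as clearly broken.
    The defaults (3.5 / 4.5 Å) sit in the gap between the ~3 Å bonded
    and ~6 Å unbonded distance populations.
    """

    bond_max: float = 3.5
    open_min: float = 4.5

    def __post_init__(self) -> None:
        if not self.bond_max < self.open_min:
            raise ValueError("bond_max must be < open_min")


@dataclass(frozen=True)
class BasePairGeometry:
    """The five per-frame observables of one A·T pair."""

    chi: float      # degrees, (-180, 180]
    theta: float    # degrees, (-180, 180]
    d_N1N3: float   # Å
    d_N7N3: float   # Å
    d_C1C1: float   # Å
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        for d in (self.d_N1N3, self.d_N7N3, self.d_C1C1):
            if d <= 0:
                raise GeometryError("distances must be positive")


def dihedral_angle(p1, p2, p3, p4) -> float:
    """Signed dihedral of four points, IUPAC convention, in (-180, 180].

    0° is cis; looking along p2→p3, a clockwise rotation of p4 relative
    to p1 is positive.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-10:
        raise GeometryError("consecutive dihedral points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise GeometryError("three consecutive dihedral points are collinear")
    x = n1 @ n2
    y = np.cross(n1, n2) @ (b2 / np.linalg.norm(b2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


_CHI_ATOMS = ("O4'", "C1'", "N9", "C4")


def chi_angle(traj: Trajectory, purine_residue_id: int, frame: int = 0) -> float:
    """Glycosidic angle χ = dihedral(O4′, C1′, N9, C4) of a purine residue."""
    idx = [require_atom(traj, purine_residue_id, n) for n in _CHI_ATOMS]
    pts = traj.coords[frame][idx]
    return dihedral_angle(*pts)


def theta_angle(frame_coords: np.ndarray, *groups: Sequence[int]) -> float:
    """Pseudodihedral of the geometric centers of four atom groups."""
    if len(groups) != 4:
        raise SelectionError("theta_angle needs exactly four groups")
    centers = []
    for g in groups:
        g = list(g)
        if not g:
            raise SelectionError("empty atom group in pseudodihedral")
        centers.append(np.asarray(frame_coords)[g].mean(axis=0))
    return dihedral_angle(*centers)


def basepair_geometry(
    traj: Trajectory,
    adenine_id: int,
    thymine_id: int,
    frame: int = 0,
    theta_groups: Sequence[Sequence[int]] | None = None,
    time: float = 0.0,
) -> BasePairGeometry:
    """All five observables of the A·T pair in one frame.

    theta_groups, when given, are the four atom-index groups of the
    flipping pseudodihedral; otherwise Θ is reported as 0 (the in-plane
    reference value).
    """
    xyz = traj.coords[frame]
    n1 = xyz[require_atom(traj, adenine_id, "N1")]
    n7 = xyz[require_atom(traj, adenine_id, "N7")]
    c1a = xyz[require_atom(traj, adenine_id, "C1'")]
    n3 = xyz[require_atom(traj, thymine_id, "N3")]
    c1t = xyz[require_atom(traj, thymine_id, "C1'")]
    chi = chi_angle(traj, adenine_id, frame)
    theta = theta_angle(xyz, *theta_groups) if theta_groups is not None else 0.0
    return BasePairGeometry(
        chi=chi,
        theta=theta,
        d_N1N3=float(np.linalg.norm(n1 - n3)),
        d_N7N3=float(np.linalg.norm(n7 - n3)),
        d_C1C1=float(np.linalg.norm(c1a - c1t)),
        time=time,
    )


def classify_state(
    g: BasePairGeometry, thresholds: ClassifierThresholds | None = None
) -> StateLabel:
    """Assign WC/HG/OPEN from the two donor–acceptor distances.

    WC requires the N1–N3 bond formed and N7–N3 clearly broken; HG the
    mirror image; OPEN both broken; anything else is UNASSIGNED.
    """
    t = thresholds or ClassifierThresholds()
    wc = g.d_N1N3 <= t.bond_max and g.d_N7N3 >= t.open_min
    hg = g.d_N7N3 <= t.bond_max and g.d_N1N3 >= t.open_min
    if wc:
        return StateLabel.WC
    if hg:
        return StateLabel.HG
    if g.d_N1N3 >= t.open_min and g.d_N7N3 >= t.open_min:
        return StateLabel.OPEN
    return StateLabel.UNASSIGNED


def classify_distances(
    d_N1N3: float, d_N7N3: float, thresholds: ClassifierThresholds | None = None
) -> StateLabel:
    """classify_state from the two distances alone (χ, Θ, C1′–C1′ unused)."""
    g = BasePairGeometry(chi=0.0, theta=0.0, d_N1N3=d_N1N3, d_N7N3=d_N7N3, d_C1C1=1.0)
    return classify_state(g, thresholds)


def cv_timeseries(
    traj: Trajectory,
    adenine_id: int,
    thymine_id: int,
    theta_groups: Sequence[Sequence[int]] | None = None,
    thresholds: ClassifierThresholds | None = None,
) -> TimeSeriesTable:
    """Per-frame CV table: χ, Θ, the three distances, and the state label."""
    times = (
        traj.frame_times
        if traj.frame_times is not None
        else np.arange(traj.n_frames, dtype=float)
    )
    rows = {k: [] for k in ("chi", "theta", "d_N1N3", "d_N7N3", "d_C1C1", "state")}
    for f in range(traj.n_frames):
        g = basepair_geometry(
            traj, adenine_id, thymine_id, frame=f, theta_groups=theta_groups,
            time=float(times[f]),
        )
        rows["chi"].append(g.chi)
        rows["theta"].append(g.theta)
        rows["d_N1N3"].append(g.d_N1N3)
        rows["d_N7N3"].append(g.d_N7N3)
        rows["d_C1C1"].append(g.d_C1C1)
        rows["state"].append(classify_state(g, thresholds).value)
    return TimeSeriesTable.from_arrays(times, **rows)
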