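"""Pairwise nonbonded interaction energies between atom selections.

Coulomb plus 12-6 Lennard-Jones over all cross pairs of two disjoint
selections, with either a CHARMM-style cubic switching function
(energy-switched between switch_on and cutoff) or a hard truncation at
the cutoff.  No periodic images, no Ewald, no bonded exclusions: the
contract is the direct selection–selection sum used when post-processing
base–base, base-pair–duplex and stacking energies from trajectories.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .constants import COULOMB_KCAL
from .core import Trajectory
from .errors import ConfigurationError, ConsistencyError, GeometryError
from .fluctuations import WindowSpec, mean_ci95, segment_windows

__all__ = [
    "AtomParameters",
    "NonbondedScheme",
    "InteractionEnergy",
    "ParameterTable",
    "switching_factor",
    "pair_energy",
    "interaction_energy",
    "stacking_energy",
    "ensemble_mean_energy",
]


@dataclass(frozen=True)
class AtomParameters:
    charge: float        # e
    lj_epsilon: float    # kcal/mol (well depth, ≥ 0)
    lj_rmin_half: float  # Å (Rmin/2)

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ConfigurationError("lj_epsilon must be ≥ 0")
        if self.lj_rmin_half <= 0:
            raise ConfigurationError("lj_rmin_half must be > 0")


@dataclass(frozen=True)
class NonbondedScheme:
    style: Literal["switched", "truncated"]
    cutoff: float              # Å
    switch_on: float | None = None  # Å, switched style only

    def __post_init__(self) -> None:
        if self.style not in ("switched", "truncated"):
            raise ConfigurationError(f"unknown nonbonded style {self.style!r}")
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")
        if self.style == "switched":
            if self.switch_on is None or not 0 < self.switch_on < self.cutoff:
                raise ConfigurationError("switched style needs 0 < switch_on < cutoff")


#: the two schemes used for the CHARMM- and AMBER-family trajectories
CHARMM_SCHEME = NonbondedScheme("switched", cutoff=12.0, switch_on=10.0)
AMBER_SCHEME = NonbondedScheme("truncated", cutoff=9.0)


@dataclass(frozen=True)
class InteractionEnergy:
    electrostatic: float  # kcal/mol
    vdw: float            # kcal/mol

    @property
    def total(self) -> float:
        return self.electrostatic + self.vdw

    def __add__(self, other: "InteractionEnergy") -> "InteractionEnergy":
        return InteractionEnergy(
            self.electrostatic + other.electrostatic, self.vdw + other.vdw
        )


class ParameterTable:
    """Per-atom charges and LJ parameters keyed by (residue_name, atom_name)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"residue_name", "atom_name", "charge", "lj_epsilon", "lj_rmin_half"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"parameter table missing columns {sorted(missing)}")
        self._by_key = {
            (row.residue_name, row.atom_name): AtomParameters(
                float(row.charge), float(row.lj_epsilon), float(row.lj_rmin_half)
            )
            for row in frame.itertuples()
        }
        self.frame = frame

    @classmethod
    def read_csv(cls, path: str | Path) -> "ParameterTable":
        return cls(pd.read_csv(path))

    def lookup(self, residue_name: str, atom_name: str) -> AtomParameters:
        try:
            return self._by_key[(residue_name, atom_name)]
        except KeyError:
            raise ConfigurationError(
                f"no parameters for atom {atom_name!r} in residue {residue_name!r}"
            ) from None

    def arrays(self, traj: Trajectory, selection: Sequence[int]):
        """(charges, epsilons, rmin_halves) for the selected atoms."""
        params = [
            self.lookup(traj.atoms[i].residue_name, traj.atoms[i].name)
            for i in selection
        ]
        return (
            np.array([p.charge for p in params]),
            np.array([p.lj_epsilon for p in params]),
            np.array([p.lj_rmin_half for p in params]),
        )


def switching_factor(r, scheme: NonbondedScheme):
    """Multiplicative energy attenuation at distance r (Å); vectorised.

    Switched: 1 below switch_on, the CHARMM cubic polynomial
    (c²−r²)²(c²+2r²−3s²)/(c²−s²)³ between, 0 at and beyond the cutoff.
    Truncated: a unit step down to 0 at the cutoff.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise GeometryError("switching_factor needs r > 0")
    if scheme.style == "truncated":
        out = np.where(r < scheme.cutoff, 1.0, 0.0)
    else:
        c2 = scheme.cutoff**2
        s2 = scheme.switch_on**2
        r2 = r**2
        mid = (c2 - r2) ** 2 * (c2 + 2 * r2 - 3 * s2) / (c2 - s2) ** 3
        out = np.where(r <= scheme.switch_on, 1.0, np.where(r >= scheme.cutoff, 0.0, mid))
    return out if out.ndim else float(out)


def pair_energy(
    r: float, params_a: AtomParameters, params_b: AtomParameters, scheme: NonbondedScheme
) -> InteractionEnergy:
    """Energy of one atom pair at separation r (Å).

    Electrostatics C·q_a·q_b/r, LJ ε_ab[(R_ab/r)¹² − 2(R_ab/r)⁶] with
    Lorentz–Berthelot combination ε_ab = √(ε_a ε_b),
    R_ab = Rmin/2_a + Rmin/2_b; both multiplied by the switching factor.
    """
    if r <= 0:
        raise GeometryError("pair separation must be positive")
    sw = switching_factor(r, scheme)
    elec = COULOMB_KCAL * params_a.charge * params_b.charge / r * sw
    eps = np.sqrt(params_a.lj_epsilon * params_b.lj_epsilon)
    rmin = params_a.lj_rmin_half + params_b.lj_rmin_half
    ratio6 = (rmin / r) ** 6
    vdw = eps * (ratio6**2 - 2 * ratio6) * sw
    return InteractionEnergy(float(elec), float(vdw))


def interaction_energy(
    frame: np.ndarray,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    params: ParameterTable,
    scheme: NonbondedScheme,
    traj: Trajectory | None = None,
) -> InteractionEnergy:
    """Sum of pair energies over all cross pairs (a ∈ A, b ∈ B).

    frame may be a Trajectory (first frame used) or an (N, 3) coordinate
    array with traj supplying atom metadata.  Selections must be disjoint.
    """
    if isinstance(frame, Trajectory):
        traj = frame
        xyz = frame.coords[0]
    else:
        xyz = np.asarray(frame, dtype=float)
        if traj is None:
            raise ConsistencyError("coordinate-array input needs the traj argument")
    sel_a = list(sel_a)
    sel_b = list(sel_b)
    if set(sel_a) & set(sel_b):
        raise ConsistencyError("selections overlap; intra-selection pairs are not defined")
    if not sel_a or not sel_b:
        return InteractionEnergy(0.0, 0.0)
    qa, ea, ra = params.arrays(traj, sel_a)
    qb, eb, rb = params.arrays(traj, sel_b)
    d = cdist(xyz[sel_a], xyz[sel_b])
    if np.any(d <= 0):
        raise GeometryError("coincident atoms across selections")
    sw = switching_factor(d, scheme)
    elec = COULOMB_KCAL * np.outer(qa, qb) / d * sw
    eps = np.sqrt(np.outer(ea, eb))
    rmin = ra[:, None] + rb[None, :]
    ratio6 = (rmin / d) ** 6
    vdw = eps * (ratio6**2 - 2 * ratio6) * sw
    return InteractionEnergy(float(elec.sum()), float(vdw.sum()))


def stacking_energy(
    frame,
    bp_ring_atoms: Sequence[int],
    neighbor1_ring_atoms: Sequence[int],
    neighbor2_ring_atoms: Sequence[int],
    params: ParameterTable,
    scheme: NonbondedScheme,
    traj: Trajectory | None = None,
) -> InteractionEnergy:
    """Base-stacking energy: ring atoms of one pair vs both flanking pairs."""
    sets = [set(bp_ring_atoms), set(neighbor1_ring_atoms), set(neighbor2_ring_atoms)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ConsistencyError("stacking selections must be pairwise disjoint")
    e1 = (
        interaction_energy(frame, bp_ring_atoms, neighbor1_ring_atoms, params, scheme, traj)
        if neighbor1_ring_atoms
        else InteractionEnergy(0.0, 0.0)
    )
    e2 = (
        interaction_energy(frame, bp_ring_atoms, neighbor2_ring_atoms, params, scheme, traj)
        if neighbor2_ring_atoms
        else InteractionEnergy(0.0, 0.0)
    )
    return e1 + e2


def ensemble_mean_energy(
    traj: Trajectory,
    sel_a: Sequence[int],
    sel_b: Sequence[int],
    params: ParameterTable,
    scheme: NonbondedScheme,
    windows: WindowSpec | None = None,
):
    """Window-averaged interaction energy with a 95% CI across windows.

    Returns a dict {"electrostatic": (mean, hw), "vdw": ..., "total": ...}.
    Without a WindowSpec the whole trajectory is one window (CI 0).
    """
    if windows is not None:
        segs = segment_windows(traj, windows)
    else:
        segs = [traj]
    per_window = {"electrostatic": [], "vdw": [], "total": []}
    for seg in segs:
        es, vs = [], []
        for f in range(seg.n_frames):
            e = interaction_energy(seg.coords[f], sel_a, sel_b, params, scheme, traj=seg)
            es.append(e.electrostatic)
            vs.append(e.vdw)
        per_window["electrostatic"].append(float(np.mean(es)))
        per_window["vdw"].append(float(np.mean(vs)))
        per_window["total"].append(float(np.mean(es) + np.mean(vs)))
    out = {}
    for key, vals in per_window.items():
        if len(vals) >= 2:
            out[key] = mean_ci95(vals)
        else:
            out[key] = (vals[0], 0.0)
    return out
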