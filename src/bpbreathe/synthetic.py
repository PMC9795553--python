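"""Synthetic inputs for every pipeline stage.

Everything the analysis consumes can be generated here at desk scale:
idealised WC/HG base-pair fragments reproducing the reference mean
geometries, Gaussian-fluctuating ensembles with a known covariance
(hence a closed-form quasi-harmonic entropy), two-state Markov CV
series with ground-truth labels, analytic multi-well free-energy grids
with known minima and watershed barriers, and random charged
Lennard-Jones clusters for energy oracles.  Every generator is a pure
function of its parameters and seed.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core import AtomRecord, TimeSeriesTable, Trajectory, mass_of_element, element_from_name
from .cvs import dihedral_angle
from .errors import BpBreatheError, ConsistencyError
from .landscape import GridAxis, PMFGrid, anchor_zero
from .energetics import ParameterTable

__all__ = [
    "REFERENCE_CHI",
    "REFERENCE_THETA",
    "REFERENCE_DISTANCES",
    "build_basepair_template",
    "gaussian_ensemble",
    "cv_transition_series",
    "toy_pmf",
    "watershed_barrier",
    "charged_cluster",
]

# Mean ± SD of the glycosidic angle χ (degrees) per force-field model,
# from 100 ns equilibrium trajectories of the A16·T9 pair in A6-DNA.
REFERENCE_CHI = {
    "CHARMM27": {"WC": (-109.2, 13.1), "HG": (46.7, 10.3)},
    "CHARMM36": {"WC": (-113.0, 14.8), "HG": (45.2, 10.7)},
    "AMBERbsc0": {"WC": (-113.3, 20.1), "HG": (26.8, 22.8)},
    "AMBERbsc1": {"WC": (-110.3, 15.7), "HG": (61.0, 9.3)},
}

# Base flip-out pseudodihedral θ (degrees), same provenance.
REFERENCE_THETA = {
    "CHARMM27": {"WC": (-2.2, 3.9), "HG": (0.0, 2.4)},
    "CHARMM36": {"WC": (-0.4, 3.8), "HG": (-0.2, 2.3)},
    "AMBERbsc0": {"WC": (-5.9, 5.2), "HG": (-0.3, 2.2)},
    "AMBERbsc1": {"WC": (-5.3, 6.0), "HG": (-1.3, 2.0)},
}

# Donor–acceptor and C1′–C1′ distances (Å): {ff: {state: {obs: (mean, sd)}}}.
REFERENCE_DISTANCES = {
    "CHARMM27": {
        "WC": {"d_N1N3": (2.96, 0.13), "d_N7N3": (6.31, 0.15), "d_C1C1": (10.60, 0.28)},
        "HG": {"d_N1N3": (5.90, 0.25), "d_N7N3": (3.12, 0.30), "d_C1C1": (8.88, 0.51)},
    },
    "CHARMM36": {
        "WC": {"d_N1N3": (2.96, 0.13), "d_N7N3": (6.29, 0.16), "d_C1C1": (10.60, 0.29)},
        "HG": {"d_N1N3": (5.87, 0.21), "d_N7N3": (3.08, 0.22), "d_C1C1": (8.85, 0.40)},
    },
    "AMBERbsc0": {
        "WC": {"d_N1N3": (2.96, 0.12), "d_N7N3": (6.48, 0.15), "d_C1C1": (10.56, 0.29)},
        "HG": {"d_N1N3": (5.84, 0.17), "d_N7N3": (3.02, 0.16), "d_C1C1": (9.03, 0.31)},
    },
    "AMBERbsc1": {
        "WC": {"d_N1N3": (2.97, 0.12), "d_N7N3": (6.51, 0.14), "d_C1C1": (10.59, 0.29)},
        "HG": {"d_N1N3": (5.89, 0.17), "d_N7N3": (3.05, 0.14), "d_C1C1": (9.04, 0.30)},
    },
}

# idealised adenine base-frame coordinates (Å, base plane z = 0)
_ADENINE_PLANE = {
    "C1'": np.array([-2.477, 5.399, 0.0]),
    "N9": np.array([-1.291, 4.498, 0.0]),
    "C4": np.array([-1.267, 3.124, 0.0]),
    "N7": np.array([0.877, 3.902, 0.0]),
    "N1": np.array([-0.668, 0.532, 0.0]),
}


def _wrap_deg(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def _place_o4prime(chi_target: float) -> np.ndarray:
    """O4′ position giving dihedral(O4′, C1′, N9, C4) = chi_target."""
    c1 = _ADENINE_PLANE["C1'"]
    n9 = _ADENINE_PLANE["N9"]
    c4 = _ADENINE_PLANE["C4"]
    u = (n9 - c1) / np.linalg.norm(n9 - c1)
    v = np.cross([0.0, 0.0, 1.0], u)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    bond, ang = 1.42, np.radians(110.0)

    def o4(phi):
        direction = np.cos(ang) * u + np.sin(ang) * (np.cos(phi) * v + np.sin(phi) * w)
        return c1 + bond * direction

    chi0 = dihedral_angle(o4(0.0), c1, n9, c4)
    chi1 = dihedral_angle(o4(np.radians(10.0)), c1, n9, c4)
    sign = 1.0 if _wrap_deg(chi1 - chi0) > 0 else -1.0
    phi = sign * np.radians(_wrap_deg(chi_target - chi0))
    return o4(phi)


def build_basepair_template(state: str, force_field: str = "CHARMM27") -> Trajectory:
    """Idealised A·T fragment whose geometry hits the reference means.

    The fragment is a geometric scaffold, not a chemically complete
    nucleotide: only the atoms the CV and classification machinery
    needs are placed (adenine C1′, O4′, N9, C4, N1, N7; thymine N3,
    C1′), so the three reference distances and the reference χ of the
    requested state/force-field are satisfied exactly.
    """
    state = state.upper()
    if state not in ("WC", "HG"):
        raise BpBreatheError(f"state must be WC or HG, got {state!r}")
    dists = REFERENCE_DISTANCES[force_field][state]
    chi_mean = REFERENCE_CHI[force_field][state][0]

    coords = dict(_ADENINE_PLANE)
    coords["O4'"] = _place_o4prime(chi_mean)

    # thymine N3 from the two donor-acceptor distances: in-plane
    # intersection of circles around adenine N1 and N7
    p1, p2 = coords["N1"], coords["N7"]
    r1, r2 = dists["d_N1N3"][0], dists["d_N7N3"][0]
    d = np.linalg.norm(p2 - p1)
    if not abs(r1 - r2) < d < r1 + r2:
        raise BpBreatheError("reference distances admit no in-plane N3 placement")
    a = (r1**2 - r2**2 + d**2) / (2 * d)
    h = np.sqrt(r1**2 - a**2)
    base = p1 + a * (p2 - p1) / d
    perp = np.cross([0.0, 0.0, 1.0], (p2 - p1) / d)
    ring_centroid = np.mean([coords[k] for k in ("N9", "C4", "N7", "N1")], axis=0)
    cand = [base + h * perp, base - h * perp]
    n3 = max(cand, key=lambda p: np.linalg.norm(p - ring_centroid))
    coords_t = {"N3": n3}
    # thymine C1' along the line from adenine C1' through N3, at the
    # reference helix diameter
    direction = n3 - coords["C1'"]
    direction /= np.linalg.norm(direction)
    coords_t["C1'"] = coords["C1'"] + dists["d_C1C1"][0] * direction

    atoms = []
    frame = []
    idx = 0
    for name in ("C1'", "O4'", "N9", "C4", "N1", "N7"):
        el = element_from_name(name)
        atoms.append(AtomRecord(name, el, 1, "ADE", mass_of_element(el), idx))
        frame.append(coords[name])
        idx += 1
    for name in ("N3", "C1'"):
        el = element_from_name(name)
        atoms.append(AtomRecord(name, el, 2, "THY", mass_of_element(el), idx))
        frame.append(coords_t[name])
        idx += 1
    return Trajectory(atoms, np.array(frame)[None])


def gaussian_ensemble(
    template: Trajectory,
    covariance,
    n_frames: int,
    seed: int,
    frame_times: np.ndarray | None = None,
) -> Trajectory:
    """Frames = template + correlated Gaussian displacements.

    covariance may be a scalar (isotropic per-coordinate variance σ², Å²),
    a length-3N array of per-coordinate variances, or a full 3N×3N PSD
    matrix.
    """
    rng = np.random.default_rng(seed)
    n3 = 3 * template.n_atoms
    base = template.coords[0].reshape(-1)
    cov = np.asarray(covariance, dtype=float)
    if cov.ndim == 0:
        disp = rng.normal(0.0, np.sqrt(float(cov)), size=(n_frames, n3))
    elif cov.ndim == 1:
        if cov.shape[0] != n3:
            raise ConsistencyError("variance vector must have length 3N")
        disp = rng.normal(size=(n_frames, n3)) * np.sqrt(cov)
    else:
        if cov.shape != (n3, n3):
            raise ConsistencyError("covariance must be 3N×3N")
        w, v = np.linalg.eigh(0.5 * (cov + cov.T))
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ConsistencyError("covariance is not positive semidefinite")
        root = v * np.sqrt(np.clip(w, 0.0, None))
        disp = rng.standard_normal((n_frames, n3)) @ root.T
    coords = (base + disp).reshape(n_frames, template.n_atoms, 3)
    return template.with_coords(coords, frame_times)


def cv_transition_series(
    n_points: int,
    seed: int,
    switch_prob: tuple[float, float] = (0.0, 0.0),
    state_sequence: Sequence[str] | None = None,
    force_field: str = "CHARMM27",
    dt: float = 0.01,
) -> TimeSeriesTable:
    """Two-state Markov CV series with ground-truth labels.

    switch_prob = (P(WC→HG), P(HG→WC)) per step; alternatively a fixed
    state_sequence.  Emissions are Gaussian around the reference means
    with the reference SDs for the chosen force field.  Columns: time,
    chi, d_N1N3, d_N7N3, d_C1C1, state_true.
    """
    rng = np.random.default_rng(seed)
    if state_sequence is not None:
        states = list(state_sequence)
        if len(states) != n_points:
            raise ConsistencyError("state_sequence length must equal n_points")
    else:
        p_wh, p_hw = switch_prob
        states = []
        s = "WC"
        for _ in range(n_points):
            states.append(s)
            u = rng.random()
            if s == "WC" and u < p_wh:
                s = "HG"
            elif s == "HG" and u < p_hw:
                s = "WC"
    chi_tab = REFERENCE_CHI[force_field]
    dist_tab = REFERENCE_DISTANCES[force_field]
    cols = {"chi": [], "d_N1N3": [], "d_N7N3": [], "d_C1C1": [], "state_true": states}
    for s in states:
        m, sd = chi_tab[s]
        cols["chi"].append(rng.normal(m, sd))
        for obs in ("d_N1N3", "d_N7N3", "d_C1C1"):
            m, sd = dist_tab[s][obs]
            cols[obs].append(rng.normal(m, sd))
    times = np.arange(n_points) * dt
    return TimeSeriesTable.from_arrays(times, **cols)


def toy_pmf(
    well_centers: Sequence[Sequence[float]],
    depths: Sequence[float],
    widths: Sequence[float],
    axes: Sequence[GridAxis],
):
    """Analytic multi-Gaussian-well free-energy grid with ground truth.

    F(x) = −Σ_i depth_i · exp(−|Δ_i|²/2w_i²) with minimum-image Δ on
    periodic axes, evaluated at bin centres and anchored to zero.
    Returns (PMFGrid, truth) where truth carries the minima bin indices,
    the pairwise ΔG between the first two wells, and the watershed
    barrier between them computed by threshold connectivity (an
    algorithm independent of the path search).
    """
    axes = tuple(axes)
    centers = [np.asarray(c, dtype=float) for c in well_centers]
    mesh = np.meshgrid(*[a.centers() for a in axes], indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=1)
    values = np.zeros(len(pts))
    for c, depth, w in zip(centers, depths, widths):
        d = pts - c[None, :]
        for k, a in enumerate(axes):
            if a.periodic:
                d[:, k] -= a.span * np.round(d[:, k] / a.span)
        values -= depth * np.exp(-(d**2).sum(axis=1) / (2 * w**2))
    shape = tuple(a.n_bins for a in axes)
    grid = anchor_zero(PMFGrid(axes, values.reshape(shape)))

    minima = []
    for c in centers:
        idx = []
        for k, a in enumerate(axes):
            idx.append(int(np.argmin(np.abs(a.centers() - c[k]))))
        # refine to the local minimum bin nearest the analytic centre
        minima.append(tuple(idx))
    truth = {"minima": minima}
    if len(minima) >= 2:
        va = grid.values[minima[0]]
        vb = grid.values[minima[1]]
        truth["delta_g"] = float(vb - va)
        truth["barrier"] = watershed_barrier(
            grid.values, minima[0], minima[1], tuple(a.periodic for a in axes)
        )
    return grid, truth


def watershed_barrier(values: np.ndarray, start, end, periodic) -> float:
    """Minimax barrier by threshold connectivity (flood-fill oracle).

    The barrier is the smallest level t such that start and end lie in
    the same connected component of {bins with energy ≤ t} under
    8-neighbour (2-neighbour in 1-D) connectivity with periodic wrap.
    """
    from collections import deque

    vals = np.asarray(values, dtype=float)
    start, end = tuple(start), tuple(end)
    levels = np.unique(vals[~np.isnan(vals)])
    lo_i = int(np.searchsorted(levels, max(vals[start], vals[end])))
    hi_i = len(levels) - 1

    def connected(t):
        mask = ~np.isnan(vals) & (vals <= t)
        if not (mask[start] and mask[end]):
            return False
        from .landscape import _neighbors

        seen = {start}
        q = deque([start])
        while q:
            node = q.popleft()
            if node == end:
                return True
            for nb in _neighbors(vals.shape, periodic, node):
                if mask[nb] and nb not in seen:
                    seen.add(nb)
                    q.append(nb)
        return False

    if not connected(levels[hi_i]):
        raise BpBreatheError("start and end are not connected at any level")
    while lo_i < hi_i:
        mid = (lo_i + hi_i) // 2
        if connected(levels[mid]):
            hi_i = mid
        else:
            lo_i = mid + 1
    return float(levels[lo_i])


def charged_cluster(
    n_atoms: int,
    box: float = 20.0,
    charge_range: tuple[float, float] = (-1.0, 1.0),
    eps_range: tuple[float, float] = (0.05, 0.3),
    rmin_half_range: tuple[float, float] = (1.5, 2.1),
    seed: int = 0,
    min_separation: float = 1.5,
):
    """Random non-overlapping charged LJ cluster plus its parameter table.

    Returns (Trajectory, ParameterTable).  Atom names C0..C{n-1} in a
    single CLU residue.
    """
    if n_atoms < 2:
        raise BpBreatheError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    positions = []
    attempts = 0
    while len(positions) < n_atoms:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= min_separation for p in positions):
            positions.append(cand)
        attempts += 1
        if attempts > 2000 * n_atoms:
            raise BpBreatheError("cannot place atoms without overlap; enlarge the box")
    atoms = [
        AtomRecord(f"C{i}", "C", 1, "CLU", mass_of_element("C"), i)
        for i in range(n_atoms)
    ]
    traj = Trajectory(atoms, np.array(positions)[None])
    table = pd.DataFrame(
        {
            "residue_name": ["CLU"] * n_atoms,
            "atom_name": [f"C{i}" for i in range(n_atoms)],
            "charge": rng.uniform(*charge_range, size=n_atoms),
            "lj_epsilon": rng.uniform(*eps_range, size=n_atoms),
            "lj_rmin_half": rng.uniform(*rmin_half_range, size=n_atoms),
        }
    )
    return traj, ParameterTable(table)
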