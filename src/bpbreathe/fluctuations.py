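"""Ensemble fluctuation analysis: superposition, mass-weighted covariance,
quasi-harmonic entropy, RMSF, and the overlapping-window mean ± 95% CI scheme.

The quasi-harmonic model treats each eigenmode of the mass-weighted
coordinate covariance σ = M^{1/2} σ′ M^{1/2} as a quantum harmonic
oscillator of frequency ω_i = sqrt(k_B T / λ_i) and sums the exact
oscillator entropies:

    S = R Σ_i [ α_i / (e^{α_i} − 1) − ln(1 − e^{−α_i}) ],   α_i = ħω_i / k_B T

reported per mole in cal·mol⁻¹·K⁻¹.  Stiff modes (λ → 0) contribute
nothing; soft modes dominate, which is why hydrogens are excluded by
selection in practice.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .constants import AMU_KG, HBAR_SI, KB_SI, R_CAL
from .core import Trajectory
from .errors import ConsistencyError, GeometryError, StatisticsError

__all__ = [
    "CovarianceResult",
    "EntropyEstimate",
    "WindowSpec",
    "kabsch_rotation",
    "superpose",
    "mass_weighted_covariance",
    "quasiharmonic_entropy",
    "rmsf",
    "rmsf_ratio",
    "segment_windows",
    "mean_ci95",
    "windowed_entropy",
]

#: eigenvalues below this (amu·Å²) are treated as rigid-body/numerical-zero modes
EIGENVALUE_TOLERANCE = 1e-8


@dataclass
class CovarianceResult:
    covariance: np.ndarray       # 3N×3N coordinate covariance σ′, Å²
    mw_eigenvalues: np.ndarray   # eigenvalues of M^{1/2} σ′ M^{1/2}, amu·Å², non-increasing
    n_atoms: int
    n_frames: int


@dataclass
class EntropyEstimate:
    entropy: float               # cal·mol⁻¹·K⁻¹ (mean over windows)
    per_window: list[float]
    ci95_halfwidth: float
    temperature: float


@dataclass(frozen=True)
class WindowSpec:
    """Overlapping analysis windows: [start + k·stride, ... + window_length]."""

    window_length: float  # ns
    stride: float         # ns
    start: float = 0.0    # ns

    def __post_init__(self) -> None:
        if self.window_length <= 0 or self.stride <= 0:
            raise ValueError("window_length and stride must be positive")


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray):
    """Optimal rotation R and translation so R @ (mobile - cm) + cr ≈ reference.

    Returns (R, mobile_centroid, reference_centroid).  Proper rotation
    enforced (det = +1).
    """
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return rot, cm, cr


def superpose(
    traj: Trajectory,
    reference_frame: int | np.ndarray = 0,
    selection: Sequence[int] | None = None,
) -> Trajectory:
    """Least-squares superpose every frame onto the reference over selection.

    The fit uses the selected atoms; the resulting rigid motion is
    applied to all atoms of the frame.
    """
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(list(selection))
    if len(sel) < 3:
        raise GeometryError("superposition needs at least 3 selected atoms")
    if isinstance(reference_frame, (int, np.integer)):
        ref = traj.coords[int(reference_frame)][sel]
    else:
        ref = np.asarray(reference_frame, dtype=float)
        if ref.shape[0] == traj.n_atoms:
            ref = ref[sel]
        elif ref.shape[0] != len(sel):
            raise ConsistencyError("reference shape matches neither all atoms nor selection")
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        rot, cm, cr = kabsch_rotation(traj.coords[f][sel], ref)
        out[f] = (traj.coords[f] - cm) @ rot.T + cr
    return traj.with_coords(out, traj.frame_times)


def mass_weighted_covariance(
    traj: Trajectory, selection: Sequence[int] | None = None
) -> CovarianceResult:
    """Coordinate covariance over frames and the mass-weighted spectrum.

    σ′_{ij} = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩ with the population (1/n)
    normalisation; eigenvalues are of M^{1/2} σ′ M^{1/2} with the
    per-atom mass repeated over x, y, z.  Superposition is the caller's
    responsibility.
    """
    if traj.n_frames < 2:
        raise StatisticsError("covariance needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(list(selection))
    x = traj.coords[:, sel, :].reshape(traj.n_frames, -1)
    xc = x - x.mean(axis=0)
    cov = (xc.T @ xc) / traj.n_frames
    cov = 0.5 * (cov + cov.T)
    masses = traj.masses()[sel]
    sqrt_m = np.sqrt(np.repeat(masses, 3))
    mw = cov * np.outer(sqrt_m, sqrt_m)
    eig = np.linalg.eigvalsh(mw)[::-1]
    eig = np.clip(eig, 0.0, None)
    return CovarianceResult(
        covariance=cov, mw_eigenvalues=eig, n_atoms=len(sel), n_frames=traj.n_frames
    )


def entropy_from_eigenvalues(
    eigenvalues: np.ndarray, temperature: float, tolerance: float = EIGENVALUE_TOLERANCE
) -> float:
    """Quasi-harmonic entropy (cal·mol⁻¹·K⁻¹) from mass-weighted eigenvalues (amu·Å²)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > tolerance]
    if lam.size == 0:
        import warnings

        warnings.warn("all eigenvalues below tolerance; entropy is 0")
        return 0.0
    lam_si = lam * AMU_KG * 1e-20  # kg·m²
    omega = np.sqrt(KB_SI * temperature / lam_si)           # s⁻¹
    alpha = HBAR_SI * omega / (KB_SI * temperature)
    per_mode = alpha / np.expm1(alpha) - np.log1p(-np.exp(-alpha))
    return float(R_CAL * per_mode.sum())


def quasiharmonic_entropy(cov: CovarianceResult, temperature: float) -> float:
    """Entropy of a CovarianceResult at temperature (K), in cal·mol⁻¹·K⁻¹."""
    return entropy_from_eigenvalues(cov.mw_eigenvalues, temperature)


def rmsf(traj: Trajectory, selection: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Å) about the time-mean position."""
    if traj.n_frames < 2:
        raise StatisticsError("RMSF needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(list(selection))
    x = traj.coords[:, sel, :]
    dev = x - x.mean(axis=0)
    return np.sqrt((dev**2).sum(axis=2).mean(axis=0))


def rmsf_ratio(
    rmsf_hg: np.ndarray,
    rmsf_wc: np.ndarray,
    aggregation: Literal["atom", "residue"] = "atom",
    residue_ids: Sequence[int] | None = None,
) -> np.ndarray:
    """Elementwise HG/WC fluctuation ratio.

    With aggregation="residue", atom RMSFs are averaged per residue
    (residue_ids required, one per atom) before dividing.  Zero
    denominators yield NaN, flagged rather than infinite.
    """
    a = np.asarray(rmsf_hg, dtype=float)
    b = np.asarray(rmsf_wc, dtype=float)
    if a.shape != b.shape:
        raise ConsistencyError("RMSF arrays must have matching atom lists")
    if aggregation == "residue":
        if residue_ids is None:
            raise ConsistencyError("residue aggregation needs residue_ids")
        rid = np.asarray(list(residue_ids))
        if rid.shape != a.shape:
            raise ConsistencyError("residue_ids must align with the RMSF arrays")
        uniq = np.unique(rid)
        a = np.array([a[rid == r].mean() for r in uniq])
        b = np.array([b[rid == r].mean() for r in uniq])
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.nan)
    return out


def segment_windows(traj: Trajectory, spec: WindowSpec) -> list[Trajectory]:
    """Maximal list of overlapping windows fully inside the trajectory.

    Window k covers times [start + k·stride, start + k·stride + window_length]
    (inclusive on both ends).  Frames without time stamps are given their
    index in ns.
    """
    times = (
        traj.frame_times
        if traj.frame_times is not None
        else np.arange(traj.n_frames, dtype=float)
    )
    t_end = times[-1]
    if t_end - spec.start < spec.window_length:
        raise StatisticsError("trajectory span shorter than the window length")
    windows = []
    k = 0
    while True:
        lo = spec.start + k * spec.stride
        hi = lo + spec.window_length
        if hi > t_end + 1e-9:
            break
        mask = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        windows.append(traj.with_coords(traj.coords[mask], times[mask]))
        k += 1
    return windows


def mean_ci95(values: Sequence[float], method: Literal["t", "normal"] = "t"):
    """Mean and 95% confidence halfwidth of a small sample.

    The default t-interval halfwidth is t_{0.975, n−1} · s / √n with the
    unbiased (n−1) standard deviation.
    """
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n < 2:
        raise StatisticsError("need at least 2 values for a confidence interval")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(n))
    if method == "t":
        q = float(stats.t.ppf(0.975, n - 1))
    else:
        q = float(stats.norm.ppf(0.975))
    return mean, q * sem


def windowed_entropy(
    traj: Trajectory,
    spec: WindowSpec,
    temperature: float,
    selection: Sequence[int] | None = None,
) -> EntropyEstimate:
    """Quasi-harmonic entropy per overlapping window, with mean ± 95% CI.

    Each window is superposed onto its own mean structure (first pass
    aligns to the window's first frame, second pass to the resulting
    mean) before the covariance is accumulated.
    """
    per = []
    for w in segment_windows(traj, spec):
        aligned = superpose(w, 0, selection)
        mean_struct = aligned.coords.mean(axis=0)
        aligned = superpose(w, mean_struct, selection)
        cov = mass_weighted_covariance(aligned, selection)
        per.append(quasiharmonic_entropy(cov, temperature))
    if len(per) >= 2:
        mean, hw = mean_ci95(per)
    else:
        mean, hw = per[0], 0.0
    return EntropyEstimate(
        entropy=mean, per_window=per, ci95_halfwidth=hw, temperature=temperature
    )
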