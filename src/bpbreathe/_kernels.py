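"""Numba inner loops for the Langevin / meta-eABF sampler.

Sequential single-particle dynamics cannot be vectorised, so the hot
loops are JIT-compiled.  Potentials arrive as tabulated force arrays
with linear interpolation; angular domains are periodic with
minimum-image wrapping.  All energies kcal/mol, CVs in degrees, time ps.
"""
import numpy as np
from numba import njit


@njit(cache=False, inline="always")
def _wrap(x, lower, span):
    return x - span * np.floor((x - lower) / span)


@njit(cache=False, inline="always")
def _min_image(d, span):
    return d - span * np.round(d / span)


@njit(cache=False, inline="always")
def _interp_periodic(table, lower, span, x):
    n = table.shape[0]
    dx = span / n
    u = (x - lower) / dx
    i0 = int(np.floor(u))
    frac = u - np.floor(u)
    i = i0 % n
    j = (i + 1) % n
    return table[i] * (1.0 - frac) + table[j] * frac


@njit(cache=False, inline="always")
def _interp_clamped(table, lower, span, x):
    # table has n+1 nodes spanning [lower, lower+span]
    n = table.shape[0] - 1
    u = (x - lower) / span * n
    i = int(np.floor(u))
    if i < 0 or i >= n:
        return np.nan
    frac = u - i
    return table[i] * (1.0 - frac) + table[i + 1] * frac


@njit(cache=False)
def langevin_1d(
    ftab, lower, span, periodic, n_steps, dt, gamma, kt, mass,
    x0, seed, save_stride, out,
):
    """BAOAB Langevin on a tabulated 1-D potential.  Returns 0, or 1 on
    leaving a non-periodic domain (instability)."""
    np.random.seed(seed)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(kt / mass * (1.0 - c1 * c1))
    x = x0
    v = np.sqrt(kt / mass) * np.random.standard_normal()
    if periodic:
        f = _interp_periodic(ftab, lower, span, x)
    else:
        f = _interp_clamped(ftab, lower, span, x)
    if np.isnan(f):
        return 1
    k = 0
    for step in range(n_steps):
        v += 0.5 * dt * f / mass
        x += 0.5 * dt * v
        v = c1 * v + c2 * np.random.standard_normal()
        x += 0.5 * dt * v
        if periodic:
            x = _wrap(x, lower, span)
            f = _interp_periodic(ftab, lower, span, x)
        else:
            f = _interp_clamped(ftab, lower, span, x)
            if np.isnan(f):
                return 1
        v += 0.5 * dt * f / mass
        if (step + 1) % save_stride == 0:
            out[k] = x
            k += 1
    return 0


@njit(cache=False)
def meta_eabf_1d(
    ftab, lower, span,
    n_steps, dt, gamma, kt, mass_x, mass_lam, kappa,
    hill_height, hill_width, deposit_every,
    meta_v, meta_f,
    abf_count, abf_fsum, abf_threshold,
    x0, lam0, seed, save_stride,
    out_x, out_lam, hill_centers,
):
    """meta-eABF on a periodic 1-D CV.

    The physical coordinate x feels the potential plus the harmonic
    coupling to the fictitious coordinate lam; lam feels the coupling,
    the metadynamics hill force (accumulated on the meta_v/meta_f
    grids) and, once a lam-bin holds abf_threshold samples, the ABF
    force −(force sum)/count.  Each step deposits one ABF sample: the
    instantaneous spring force on lam, kappa·min_image(x − lam).
    Returns the number of hills deposited, or −1 on numerical blow-up.
    """
    np.random.seed(seed)
    n_meta = meta_v.shape[0]
    n_abf = abf_count.shape[0]
    dx_meta = span / n_meta
    dx_abf = span / n_abf
    c1x = np.exp(-gamma * dt)
    c2x = np.sqrt(kt / mass_x * (1.0 - c1x * c1x))
    c2l = np.sqrt(kt / mass_lam * (1.0 - c1x * c1x))
    x = x0
    lam = lam0
    vx = np.sqrt(kt / mass_x) * np.random.standard_normal()
    vl = np.sqrt(kt / mass_lam) * np.random.standard_normal()
    n_hills = 0
    k = 0

    # initial forces
    d = _min_image(x - lam, span)
    fx = _interp_periodic(ftab, lower, span, x) - kappa * d
    fbin = int((_wrap(lam, lower, span) - lower) / dx_abf) % n_abf
    fl = kappa * d + _interp_periodic(meta_f, lower, span, lam)
    if abf_count[fbin] >= abf_threshold and abf_count[fbin] > 0:
        fl -= abf_fsum[fbin] / abf_count[fbin]

    for step in range(n_steps):
        # B
        vx += 0.5 * dt * fx / mass_x
        vl += 0.5 * dt * fl / mass_lam
        # A
        x += 0.5 * dt * vx
        lam += 0.5 * dt * vl
        # O
        vx = c1x * vx + c2x * np.random.standard_normal()
        vl = c1x * vl + c2l * np.random.standard_normal()
        # A
        x += 0.5 * dt * vx
        lam += 0.5 * dt * vl
        x = _wrap(x, lower, span)
        lam = _wrap(lam, lower, span)

        # ABF sample: spring force on the fictitious particle
        d = _min_image(x - lam, span)
        fspring = kappa * d
        ibin = int((lam - lower) / dx_abf)
        if ibin >= n_abf:
            ibin = n_abf - 1
        abf_count[ibin] += 1.0
        abf_fsum[ibin] += fspring

        # metadynamics deposit on the grid
        if deposit_every > 0 and (step + 1) % deposit_every == 0:
            if n_hills < hill_centers.shape[0]:
                hill_centers[n_hills] = lam
            n_hills += 1
            for j in range(n_meta):
                xj = lower + (j + 0.5) * dx_meta
                dj = _min_image(xj - lam, span)
                g = hill_height * np.exp(-dj * dj / (2.0 * hill_width * hill_width))
                meta_v[j] += g
                meta_f[j] += g * dj / (hill_width * hill_width)

        # forces for the closing B step
        fx = _interp_periodic(ftab, lower, span, x) - fspring
        fl = fspring + _interp_periodic(meta_f, lower, span, lam)
        if abf_count[ibin] >= abf_threshold:
            fl -= abf_fsum[ibin] / abf_count[ibin]
        # B
        vx += 0.5 * dt * fx / mass_x
        vl += 0.5 * dt * fl / mass_lam
        if not (np.isfinite(x) and np.isfinite(lam)):
            return -1
        if (step + 1) % save_stride == 0:
            out_x[k] = x
            out_lam[k] = lam
            k += 1
    return n_hills
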