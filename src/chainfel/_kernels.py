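"""Numba-compiled inner loops for the Monte Carlo samplers.

Everything here works in radians and raw float64 arrays; the public
modules own unit conversion, validation and bookkeeping.  The wall term is
evaluated with the chain centered and principal-axis-aligned in the cavity
frame (rigid-body placement is relaxed, not sampled), so the sampler state
is purely torsional.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mc_chunk", "ris_mc_chunk", "chain_coords", "chain_energy"]


@njit(cache=True)
def chain_coords(phi: np.ndarray, bond: float, theta: float,
                 out: np.ndarray) -> None:
    """Build backbone coordinates in-place from dihedrals (radians)."""
    n = out.shape[0]
    out[0, 0] = 0.0
    out[0, 1] = 0.0
    out[0, 2] = 0.0
    out[1, 0] = bond
    out[1, 1] = 0.0
    out[1, 2] = 0.0
    if n >= 3:
        out[2, 0] = bond - bond * np.cos(theta)
        out[2, 1] = bond * np.sin(theta)
        out[2, 2] = 0.0
    for i in range(3, n):
        ax, ay, az = out[i - 3, 0], out[i - 3, 1], out[i - 3, 2]
        bx, by, bz = out[i - 2, 0], out[i - 2, 1], out[i - 2, 2]
        cx, cy, cz = out[i - 1, 0], out[i - 1, 1], out[i - 1, 2]
        bcx, bcy, bcz = cx - bx, cy - by, cz - bz
        inv = 1.0 / np.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
        bcx *= inv
        bcy *= inv
        bcz *= inv
        abx, aby, abz = bx - ax, by - ay, bz - az
        nx = aby * bcz - abz * bcy
        ny = abz * bcx - abx * bcz
        nz = abx * bcy - aby * bcx
        inv = 1.0 / np.sqrt(nx * nx + ny * ny + nz * nz)
        nx *= inv
        ny *= inv
        nz *= inv
        mx = ny * bcz - nz * bcy
        my = nz * bcx - nx * bcz
        mz = nx * bcy - ny * bcx
        p = phi[i - 3]
        d0 = -bond * np.cos(theta)
        d1 = bond * np.sin(theta) * np.cos(p)
        d2 = bond * np.sin(theta) * np.sin(p)
        out[i, 0] = cx + d0 * bcx + d1 * mx + d2 * nx
        out[i, 1] = cy + d0 * bcy + d1 * my + d2 * ny
        out[i, 2] = cz + d0 * bcz + d1 * mz + d2 * nz


@njit(cache=True)
def _wall_energy_aligned(coords: np.ndarray, a: float, c: float,
                         kw: float) -> float:
    """Confinement energy after principal-axis alignment of the chain."""
    n = coords.shape[0]
    # centroid
    mx = 0.0
    my = 0.0
    mz = 0.0
    for i in range(n):
        mx += coords[i, 0]
        my += coords[i, 1]
        mz += coords[i, 2]
    mx /= n
    my /= n
    mz /= n
    centered = np.empty((n, 3))
    for i in range(n):
        centered[i, 0] = coords[i, 0] - mx
        centered[i, 1] = coords[i, 1] - my
        centered[i, 2] = coords[i, 2] - mz
    gyr = np.zeros((3, 3))
    for i in range(n):
        for p in range(3):
            for q in range(3):
                gyr[p, q] += centered[i, p] * centered[i, q]
    gyr /= n
    _, evecs = np.linalg.eigh(gyr)
    # largest eigenvalue is last column -> local z axis
    e = 0.0
    inv_a2 = 1.0 / (a * a)
    inv_c2 = 1.0 / (c * c)
    for i in range(n):
        x = (
            centered[i, 0] * evecs[0, 0]
            + centered[i, 1] * evecs[1, 0]
            + centered[i, 2] * evecs[2, 0]
        )
        y = (
            centered[i, 0] * evecs[0, 1]
            + centered[i, 1] * evecs[1, 1]
            + centered[i, 2] * evecs[2, 1]
        )
        z = (
            centered[i, 0] * evecs[0, 2]
            + centered[i, 1] * evecs[1, 2]
            + centered[i, 2] * evecs[2, 2]
        )
        s = np.sqrt((x * x + y * y) * inv_a2 + z * z * inv_c2)
        if s > 1.0:
            over = s - 1.0
            e += kw * over * over
    return e


@njit(cache=True)
def chain_energy(phi: np.ndarray, coords: np.ndarray, tors: np.ndarray,
                 eps: float, sigma: float, excl: int,
                 use_wall: bool, a: float, c: float, kw: float,
                 bias_k: float, bias_r0: float) -> float:
    """Total energy: torsion + LJ + (optional) wall + umbrella bias."""
    e = 0.0
    # torsion: Horner in cos(phi - pi)
    for k in range(phi.shape[0]):
        x = np.cos(phi[k] - np.pi)
        acc = 0.0
        for j in range(tors.shape[0] - 1, -1, -1):
            acc = acc * x + tors[j]
        e += acc
    # Lennard-Jones beyond the exclusion depth
    n = coords.shape[0]
    sig2 = sigma * sigma
    for i in range(n):
        for j in range(i + excl + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            s2 = sig2 / d2
            s6 = s2 * s2 * s2
            e += 4.0 * eps * (s6 * s6 - s6)
    if use_wall:
        e += _wall_energy_aligned(coords, a, c, kw)
    if bias_k > 0.0:
        dx = coords[n - 1, 0] - coords[0, 0]
        dy = coords[n - 1, 1] - coords[0, 1]
        dz = coords[n - 1, 2] - coords[0, 2]
        ree = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = ree - bias_r0
        e += 0.5 * bias_k * dr * dr
    return e


@njit(cache=True)
def mc_chunk(phi: np.ndarray, n_steps: int, stride: int,
             beta: float, bond: float, theta: float, tors: np.ndarray,
             eps: float, sigma: float, excl: int,
             use_wall: bool, a: float, c: float, kw: float,
             bias_k: float, bias_r0: float,
             max_step: float, pivot_prob: float, seed: int):
    """Run canonical Metropolis MC in torsion space.

    ``phi`` (radians) is modified in place and holds the final state.
    Every ``stride`` steps the end-to-end distance and dihedral vector are
    recorded.  Returns (r_samples, dih_samples, n_accepted, final_energy).
    """
    np.random.seed(seed)
    m = phi.shape[0]
    n = m + 3
    coords = np.empty((n, 3))
    trial = np.empty((n, 3))
    chain_coords(phi, bond, theta, coords)
    energy = chain_energy(phi, coords, tors, eps, sigma, excl,
                          use_wall, a, c, kw, bias_k, bias_r0)
    n_samples = n_steps // stride
    r_samples = np.empty(n_samples)
    dih_samples = np.empty((n_samples, m))
    n_accept = 0
    isamp = 0
    two_pi = 2.0 * np.pi
    for step in range(n_steps):
        j = np.random.randint(0, m)
        old = phi[j]
        if np.random.random() < pivot_prob:
            new = np.random.uniform(-np.pi, np.pi)
        else:
            new = old + np.random.uniform(-max_step, max_step)
            if new <= -np.pi:
                new += two_pi
            elif new > np.pi:
                new -= two_pi
        phi[j] = new
        chain_coords(phi, bond, theta, trial)
        e_new = chain_energy(phi, trial, tors, eps, sigma, excl,
                             use_wall, a, c, kw, bias_k, bias_r0)
        de = e_new - energy
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            energy = e_new
            for ii in range(n):
                coords[ii, 0] = trial[ii, 0]
                coords[ii, 1] = trial[ii, 1]
                coords[ii, 2] = trial[ii, 2]
            n_accept += 1
        else:
            phi[j] = old
        if stride > 0 and (step + 1) % stride == 0 and isamp < n_samples:
            dx = coords[n - 1, 0] - coords[0, 0]
            dy = coords[n - 1, 1] - coords[0, 1]
            dz = coords[n - 1, 2] - coords[0, 2]
            r_samples[isamp] = np.sqrt(dx * dx + dy * dy + dz * dz)
            for k in range(m):
                dih_samples[isamp, k] = phi[k]
            isamp += 1
    return r_samples, dih_samples, n_accept, energy


@njit(cache=True)
def batch_ree(phis: np.ndarray, bond: float, theta: float) -> np.ndarray:
    """End-to-end distances for a batch of dihedral vectors (radians)."""
    n_states, m = phis.shape
    n = m + 3
    out = np.empty(n_states)
    coords = np.empty((n, 3))
    for s in range(n_states):
        chain_coords(phis[s], bond, theta, coords)
        dx = coords[n - 1, 0] - coords[0, 0]
        dy = coords[n - 1, 1] - coords[0, 1]
        dz = coords[n - 1, 2] - coords[0, 2]
        out[s] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out


@njit(cache=True)
def ris_energy(state: np.ndarray, eps_g: float, eps_pent: float) -> float:
    """RIS energy: gauche penalty plus pentane-effect penalty for g+g-/g-g+."""
    e = 0.0
    m = state.shape[0]
    for k in range(m):
        if state[k] != 0:
            e += eps_g
    for k in range(m - 1):
        a = state[k]
        b = state[k + 1]
        if (a == 1 and b == 2) or (a == 2 and b == 1):
            e += eps_pent
    return e


@njit(cache=True)
def ris_mc_chunk(state: np.ndarray, n_steps: int, stride: int,
                 beta: float, eps_g: float, eps_pent: float,
                 r_lookup: np.ndarray, bias_k: float, bias_r0: float,
                 seed: int):
    """Metropolis MC over discrete RIS states {t, g+, g-} per dihedral.

    ``r_lookup`` maps the base-3 state index to the chain's end-to-end
    distance (precomputed by full enumeration).  ``state`` is modified in
    place.  Returns (r_samples, state_samples, n_accepted).
    """
    np.random.seed(seed)
    m = state.shape[0]
    pow3 = np.empty(m, dtype=np.int64)
    p = 1
    for k in range(m):
        pow3[k] = p
        p *= 3
    idx = 0
    for k in range(m):
        idx += state[k] * pow3[k]
    energy = ris_energy(state, eps_g, eps_pent)
    if bias_k > 0.0:
        dr = r_lookup[idx] - bias_r0
        energy += 0.5 * bias_k * dr * dr
    n_samples = n_steps // stride
    r_samples = np.empty(n_samples)
    state_samples = np.empty((n_samples, m), dtype=np.int64)
    n_accept = 0
    isamp = 0
    for step in range(n_steps):
        j = np.random.randint(0, m)
        old = state[j]
        new = (old + 1 + np.random.randint(0, 2)) % 3
        new_idx = idx + (new - old) * pow3[j]
        state[j] = new
        e_new = ris_energy(state, eps_g, eps_pent)
        if bias_k > 0.0:
            dr = r_lookup[new_idx] - bias_r0
            e_new += 0.5 * bias_k * dr * dr
        de = e_new - energy
        if de <= 0.0 or np.random.random() < np.exp(-beta * de):
            energy = e_new
            idx = new_idx
            n_accept += 1
        else:
            state[j] = old
        if stride > 0 and (step + 1) % stride == 0 and isamp < n_samples:
            r_samples[isamp] = r_lookup[idx]
            for k in range(m):
                state_samples[isamp, k] = state[k]
            isamp += 1
    return r_samples, state_samples, n_accept
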