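"""Numba kernels: pair lists, forces, and the leap-frog integrator.

Everything here works on plain float64 arrays so the hot loop stays inside
compiled code.  The kernels assume reduced units (sigma = epsilon = m = 1).
Post axes are aligned with x; the post lattice lives in the yz plane with
spacing ``S_p`` and bare post radius ``Dp_half`` measured from the post
center.  A bead interacts with at most the four posts at the vertices of
its interstitial cell, which is exhaustive because the lattice spacing
always exceeds the interaction range.
"""

import math

import numpy as np
from numba import njit

# integrator / force status codes
OK = 0
OVERSTRETCH = 1
INSIDE_POST = 2
NAN = 3
PAIR_OVERFLOW = 4

RC2 = 2.0 ** (1.0 / 3.0)  # squared WCA cutoff


@njit(cache=True)
def build_pairs(pos, cutoff2, pairs):
    """Fill ``pairs`` with all i<j within sqrt(cutoff2); return count (-1 on overflow)."""
    n = pos.shape[0]
    cap = pairs.shape[0]
    count = 0
    for i in range(n - 1):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            if dx * dx + dy * dy + dz * dz < cutoff2:
                if count >= cap:
                    return -1
                pairs[count, 0] = i
                pairs[count, 1] = j
                count += 1
    return count


@njit(cache=True)
def energy_forces(
    pos,
    forces,
    pairs,
    n_pairs,
    circular,
    bend_k,
    kappa,
    R0,
    has_array,
    S_p,
    Dp_half,
    oy,
    oz,
):
    """Total potential energy and forces; returns (energy, status).

    Terms: WCA over the supplied pair list (all pairs including bonded
    neighbors), FENE on bonds, bending ``bend_k * (1 - u_i.u_{i+1})`` on
    consecutive bonds, and the radially shifted bead-post WCA acting in
    the yz plane only.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
    energy = 0.0
    R02 = R0 * R0

    # nonbonded WCA (purely repulsive, cut at 2^(1/6))
    for k in range(n_pairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < RC2:
            inv2 = 1.0 / r2
            inv6 = inv2 * inv2 * inv2
            inv12 = inv6 * inv6
            energy += 4.0 * (inv12 - inv6) + 1.0
            fr = 24.0 * (2.0 * inv12 - inv6) * inv2  # -dU/dr / r
            forces[i, 0] -= fr * dx
            forces[i, 1] -= fr * dy
            forces[i, 2] -= fr * dz
            forces[j, 0] += fr * dx
            forces[j, 1] += fr * dy
            forces[j, 2] += fr * dz

    # FENE bonds
    nb = n if circular else n - 1
    for k in range(nb):
        i = k
        j = (k + 1) % n
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        l2 = dx * dx + dy * dy + dz * dz
        x = 1.0 - l2 / R02
        if x <= 0.0:
            return 0.0, OVERSTRETCH
        energy += -0.5 * kappa * R02 * math.log(x)
        fk = kappa / x  # F_i = +fk * d (restoring)
        forces[i, 0] += fk * dx
        forces[i, 1] += fk * dy
        forces[i, 2] += fk * dz
        forces[j, 0] -= fk * dx
        forces[j, 1] -= fk * dy
        forces[j, 2] -= fk * dz

    # bending on consecutive bond pairs
    if bend_k > 0.0:
        na = n if circular else n - 2
        for a in range(na):
            i = a
            j = (a + 1) % n
            k2 = (a + 2) % n
            ax = pos[j, 0] - pos[i, 0]
            ay = pos[j, 1] - pos[i, 1]
            az = pos[j, 2] - pos[i, 2]
            bx = pos[k2, 0] - pos[j, 0]
            by = pos[k2, 1] - pos[j, 1]
            bz = pos[k2, 2] - pos[j, 2]
            la = math.sqrt(ax * ax + ay * ay + az * az)
            lb = math.sqrt(bx * bx + by * by + bz * bz)
            if la == 0.0 or lb == 0.0:
                return 0.0, OVERSTRETCH
            u1x = ax / la
            u1y = ay / la
            u1z = az / la
            u2x = bx / lb
            u2y = by / lb
            u2z = bz / lb
            c = u1x * u2x + u1y * u2y + u1z * u2z
            energy += bend_k * (1.0 - c)
            # F_i = -bend_k*(u2 - c*u1)/la ; F_k = bend_k*(u1 - c*u2)/lb
            fix = -bend_k * (u2x - c * u1x) / la
            fiy = -bend_k * (u2y - c * u1y) / la
            fiz = -bend_k * (u2z - c * u1z) / la
            fkx = bend_k * (u1x - c * u2x) / lb
            fky = bend_k * (u1y - c * u2y) / lb
            fkz = bend_k * (u1z - c * u2z) / lb
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k2, 0] += fkx
            forces[k2, 1] += fky
            forces[k2, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz

    # bead-post interactions (yz plane only)
    if has_array:
        for i in range(n):
            y = pos[i, 1] - oy
            z = pos[i, 2] - oz
            cy = math.floor(y / S_p)
            cz = math.floor(z / S_p)
            for di in range(2):
                for dj in range(2):
                    ry = y - (cy + di) * S_p
                    rz = z - (cz + dj) * S_p
                    r = math.sqrt(ry * ry + rz * rz)
                    s = r - Dp_half
                    if s <= 0.0:
                        return 0.0, INSIDE_POST
                    if s * s < RC2:
                        invs2 = 1.0 / (s * s)
                        invs6 = invs2 * invs2 * invs2
                        invs12 = invs6 * invs6
                        energy += 4.0 * (invs12 - invs6) + 1.0
                        fs = 24.0 * (2.0 * invs12 - invs6) / s  # -dU/ds
                        forces[i, 1] += fs * ry / r
                        forces[i, 2] += fs * rz / r

    if not math.isfinite(energy):
        return 0.0, NAN
    return energy, OK


@njit(cache=True)
def run_md(
    pos,
    vhalf,
    circular,
    bend_k,
    kappa,
    R0,
    has_array,
    S_p,
    Dp_half,
    oy,
    oz,
    dt,
    T0,
    thermostat,  # 0 = none (NVE), 1 = Nose-Hoover, 2 = Langevin
    tau_T,
    gamma,
    n_steps,
    sample_every,
    seed,
    skin,
    chi0,
):
    """Leap-frog integration with optional thermostat.

    ``vhalf`` holds the half-step velocities v(t - dt/2).  Samples are taken
    at steps 0, sample_every, 2*sample_every, ... recording the positions,
    potential energy, and full-step kinetic energy at the sample time.

    Returns (frames, pe, ke, chi, status, fail_step).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    g = 3.0 * n - 3.0  # COM momentum removed at initialization
    n_samples = (n_steps + sample_every - 1) // sample_every
    frames = np.empty((n_samples, n, 3))
    pe_series = np.empty(n_samples)
    ke_series = np.empty(n_samples)

    forces = np.empty((n, 3))
    rlist = math.sqrt(RC2) + skin
    pairs = np.empty((n * 128, 2), np.int64)
    n_pairs = build_pairs(pos, rlist * rlist, pairs)
    if n_pairs < 0:
        return frames, pe_series, ke_series, chi0, PAIR_OVERFLOW, 0
    disp2_max = 0.0
    disp = np.zeros((n, 3))

    chi = chi0
    half_skin2 = 0.25 * skin * skin
    isample = 0
    for step in range(n_steps):
        if disp2_max > half_skin2:
            n_pairs = build_pairs(pos, rlist * rlist, pairs)
            if n_pairs < 0:
                return frames, pe_series, ke_series, chi, PAIR_OVERFLOW, step
            for i in range(n):
                disp[i, 0] = 0.0
                disp[i, 1] = 0.0
                disp[i, 2] = 0.0
            disp2_max = 0.0

        pe, status = energy_forces(
            pos, forces, pairs, n_pairs, circular, bend_k, kappa, R0,
            has_array, S_p, Dp_half, oy, oz,
        )
        if status != OK:
            return frames, pe_series, ke_series, chi, status, step

        vnew = np.empty((n, 3))
        if thermostat == 1:
            # iterative Nose-Hoover leap-frog:
            # chi advanced with the full-step kinetic temperature, velocity
            # update uses the mid-step friction and full-step velocity.
            vfull = np.empty((n, 3))
            for i in range(n):
                for d in range(3):
                    vfull[i, d] = vhalf[i, d] + 0.5 * dt * forces[i, d]
            chi_new = chi
            for _ in range(3):
                twoK = 0.0
                for i in range(n):
                    for d in range(3):
                        twoK += vfull[i, d] * vfull[i, d]
                T_inst = twoK / g
                chi_new = chi + dt * (T_inst / T0 - 1.0) / (tau_T * tau_T)
                chi_mid = 0.5 * (chi + chi_new)
                for i in range(n):
                    for d in range(3):
                        vnew[i, d] = vhalf[i, d] + dt * (
                            forces[i, d] - chi_mid * vfull[i, d]
                        )
                        vfull[i, d] = 0.5 * (vhalf[i, d] + vnew[i, d])
            chi = chi_new
        elif thermostat == 2:
            # BBK-style leap-frog Langevin
            c1 = 1.0 - 0.5 * gamma * dt
            c2 = 1.0 / (1.0 + 0.5 * gamma * dt)
            amp = math.sqrt(2.0 * gamma * T0 * dt)
            for i in range(n):
                for d in range(3):
                    vnew[i, d] = c2 * (
                        c1 * vhalf[i, d]
                        + dt * forces[i, d]
                        + amp * np.random.normal()
                    )
        else:
            for i in range(n):
                for d in range(3):
                    vnew[i, d] = vhalf[i, d] + dt * forces[i, d]

        if step % sample_every == 0:
            ke = 0.0
            for i in range(n):
                for d in range(3):
                    vf = 0.5 * (vhalf[i, d] + vnew[i, d])
                    ke += vf * vf
            frames[isample] = pos
            pe_series[isample] = pe
            ke_series[isample] = 0.5 * ke
            isample += 1

        disp2_max = 0.0
        for i in range(n):
            for d in range(3):
                dx = dt * vnew[i, d]
                pos[i, d] += dx
                disp[i, d] += dx
                vhalf[i, d] = vnew[i, d]
            d2 = disp[i, 0] ** 2 + disp[i, 1] ** 2 + disp[i, 2] ** 2
            if d2 > disp2_max:
                disp2_max = d2

    return frames, pe_series, ke_series, chi, OK, n_steps
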