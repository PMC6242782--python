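"""Numba kernels: neighbour lists, forces, and the BAOAB Langevin integrator.

Particles 0..n_beads-1 are chromatin beads (a FENE/Kratky-Porod chain);
the remainder are diffusing bridging proteins (TFs).  All positions are
unwrapped; the minimum-image convention is applied to every displacement,
which is valid while the chain extent stays below half the box side.

Interaction rules (energies in kBT, lengths in σ, pair diameter d = 1):

* consecutive chromatin beads: FENE bond (includes its own WCA core), so
  they are excluded from the non-bonded loop;
* every other pair: WCA sterics;
* additionally, when TF attractions are on, a TF in the binding state and a
  chromatin bead interact through a truncated+shifted LJ (ε = eps_specific
  for binding beads, eps_nonspecific otherwise, cutoff rcut);
* harmonic springs (compaction i,i+2 bonds and extruder bonds) add a plain
  K(r-r0)² term; their WCA core is already supplied by the non-bonded loop.

The integrator is the BAOAB splitting of the Langevin equation: velocity
half-kick (B), half-drift (A), exact Ornstein-Uhlenbeck velocity update (O),
half-drift (A), half-kick (B).  Noise is generated in-kernel from a seed
passed per chunk, making trajectories bit-reproducible.

Status codes returned by ``integrate_chunk``: 0 ok, 1 FENE bond reached R0
(timestep too large), 2 neighbour-list overflow (retry with larger buffer),
3 non-finite coordinate (integration blow-up).
"""

import numpy as np
from numba import njit

WCA_CUT2 = 2.0 ** (1.0 / 3.0)  # squared WCA cutoff (2^(1/6))^2


@njit(cache=True)
def _build_pairs(pos, box, cutoff, pairs):
    """Half neighbour list (i<j) within ``cutoff``; cell list when the box
    admits >= 3 cells per side, otherwise all-pairs.  Returns the number of
    pairs found (may exceed the buffer; caller must check)."""
    n = pos.shape[0]
    max_pairs = pairs.shape[0]
    c2 = cutoff * cutoff
    ncell = int(box // cutoff)
    k = 0
    if ncell < 3 or n < 64:
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dx -= box * np.rint(dx / box)
                dy = pos[i, 1] - pos[j, 1]
                dy -= box * np.rint(dy / box)
                dz = pos[i, 2] - pos[j, 2]
                dz -= box * np.rint(dz / box)
                if dx * dx + dy * dy + dz * dz < c2:
                    if k < max_pairs:
                        pairs[k, 0] = i
                        pairs[k, 1] = j
                    k += 1
        return k

    cell = box / ncell
    ncell3 = ncell * ncell * ncell
    head = np.full(ncell3, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        x = pos[i, 0] % box
        y = pos[i, 1] % box
        z = pos[i, 2] % box
        a = min(int(x / cell), ncell - 1)
        b = min(int(y / cell), ncell - 1)
        c = min(int(z / cell), ncell - 1)
        cx[i] = a
        cy[i] = b
        cz[i] = c
        idx = (a * ncell + b) * ncell + c
        nxt[i] = head[idx]
        head[idx] = i
    for i in range(n):
        for da in range(-1, 2):
            a = (cx[i] + da) % ncell
            for db in range(-1, 2):
                b = (cy[i] + db) % ncell
                for dc in range(-1, 2):
                    c = (cz[i] + dc) % ncell
                    j = head[(a * ncell + b) * ncell + c]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dx -= box * np.rint(dx / box)
                            dy = pos[i, 1] - pos[j, 1]
                            dy -= box * np.rint(dy / box)
                            dz = pos[i, 2] - pos[j, 2]
                            dz -= box * np.rint(dz / box)
                            if dx * dx + dy * dy + dz * dz < c2:
                                if k < max_pairs:
                                    pairs[k, 0] = i
                                    pairs[k, 1] = j
                                k += 1
                        j = nxt[j]
    return k


@njit(cache=True)
def _compute_forces(pos, f, n_beads, binding, tf_state, attract_on,
                    KFENE, R0, KBEND, eps_s, eps_ns, rcut,
                    sp_i, sp_j, sp_K, sp_r0,
                    pairs, npairs, box):
    """Fill ``f`` with forces; return status (0 ok, 1 FENE overextension)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    status = 0
    rcut2 = rcut * rcut
    shift_c = 0.0  # LJ shift is a constant energy offset: no force term

    # FENE bonds along the chromatin chain (WCA core included here)
    for i in range(n_beads - 1):
        j = i + 1
        dx = pos[i, 0] - pos[j, 0]
        dx -= box * np.rint(dx / box)
        dy = pos[i, 1] - pos[j, 1]
        dy -= box * np.rint(dy / box)
        dz = pos[i, 2] - pos[j, 2]
        dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r >= R0:
            status = 1
            r = 0.999 * R0
            r2 = r * r
        fr = 0.0
        if r2 < WCA_CUT2:
            inv6 = 1.0 / (r2 * r2 * r2)
            fr += (48.0 * inv6 * inv6 - 24.0 * inv6) / r2
        fr += -KFENE / (1.0 - r2 / (R0 * R0))
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz

    # Kratky-Porod bending over chromatin triplets
    if KBEND > 0.0:
        for i in range(1, n_beads - 1):
            ax = pos[i, 0] - pos[i - 1, 0]
            ax -= box * np.rint(ax / box)
            ay = pos[i, 1] - pos[i - 1, 1]
            ay -= box * np.rint(ay / box)
            az = pos[i, 2] - pos[i - 1, 2]
            az -= box * np.rint(az / box)
            bx = pos[i + 1, 0] - pos[i, 0]
            bx -= box * np.rint(bx / box)
            by = pos[i + 1, 1] - pos[i, 1]
            by -= box * np.rint(by / box)
            bz = pos[i + 1, 2] - pos[i, 2]
            bz -= box * np.rint(bz / box)
            a2 = ax * ax + ay * ay + az * az
            b2 = bx * bx + by * by + bz * bz
            ab = np.sqrt(a2 * b2)
            if ab <= 0.0:
                continue
            dot = ax * bx + ay * by + az * bz
            cth = dot / ab
            # U = K(1 - cosθ);  F_k = K * d(cosθ)/d r_k
            # d cosθ/da = b/|a||b| − cosθ a/|a|²;  d cosθ/db = a/|a||b| − cosθ b/|b|²
            dax = bx / ab - cth * ax / a2
            day = by / ab - cth * ay / a2
            daz = bz / ab - cth * az / a2
            dbx = ax / ab - cth * bx / b2
            dby = ay / ab - cth * by / b2
            dbz = az / ab - cth * bz / b2
            # r_{i-1}: dcos/dr = −dcos/da ; r_{i+1}: +dcos/db ; r_i: da − db
            f[i - 1, 0] += KBEND * (-dax)
            f[i - 1, 1] += KBEND * (-day)
            f[i - 1, 2] += KBEND * (-daz)
            f[i + 1, 0] += KBEND * dbx
            f[i + 1, 1] += KBEND * dby
            f[i + 1, 2] += KBEND * dbz
            f[i, 0] += KBEND * (dax - dbx)
            f[i, 1] += KBEND * (day - dby)
            f[i, 2] += KBEND * (daz - dbz)

    # harmonic springs (compaction + extruder bonds); WCA core of these
    # pairs is supplied by the non-bonded loop below
    for s in range(sp_i.shape[0]):
        i = sp_i[s]
        j = sp_j[s]
        dx = pos[i, 0] - pos[j, 0]
        dx -= box * np.rint(dx / box)
        dy = pos[i, 1] - pos[j, 1]
        dy -= box * np.rint(dy / box)
        dz = pos[i, 2] - pos[j, 2]
        dz -= box * np.rint(dz / box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r <= 0.0:
            continue
        fr = -2.0 * sp_K[s] * (r - sp_r0[s]) / r
        f[i, 0] += fr * dx
        f[i, 1] += fr * dy
        f[i, 2] += fr * dz
        f[j, 0] -= fr * dx
        f[j, 1] -= fr * dy
        f[j, 2] -= fr * dz

    # non-bonded pairs
    for p in range(npairs):
        i = pairs[p, 0]
        j = pairs[p, 1]
        chrom_i = i < n_beads
        chrom_j = j < n_beads
        if chrom_i and chrom_j and j - i == 1:
            continue  # handled by FENE
        dx = pos[i, 0] - pos[j, 0]
        dx -= box * np.rint(dx / box)
        dy = pos[i, 1] - pos[j, 1]
        dy -= box * np.rint(dy / box)
        dz = pos[i, 2] - pos[j, 2]
        dz -= box * np.rint(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 <= 0.0:
            continue
        attract = False
        eps = 0.0
        if attract_on and (chrom_i != chrom_j):
            # chromatin-TF pair; attraction only for binding-state TFs
            if chrom_i:
                bead = i
                tf = j - n_beads
            else:
                bead = j
                tf = i - n_beads
            if tf_state[tf] == 1:
                attract = True
                eps = eps_s if binding[bead] == 1 else eps_ns
        fr = 0.0
        if attract:
            if r2 < rcut2:
                inv6 = 1.0 / (r2 * r2 * r2)
                fr = eps * (48.0 * inv6 * inv6 - 24.0 * inv6) / r2
        else:
            if r2 < WCA_CUT2:
                inv6 = 1.0 / (r2 * r2 * r2)
                fr = (48.0 * inv6 * inv6 - 24.0 * inv6) / r2
        if fr != 0.0:
            f[i, 0] += fr * dx
            f[i, 1] += fr * dy
            f[i, 2] += fr * dz
            f[j, 0] -= fr * dx
            f[j, 1] -= fr * dy
            f[j, 2] -= fr * dz
    return status


@njit(cache=True)
def _cap_forces(f, fmax):
    if fmax <= 0.0:
        return
    for i in range(f.shape[0]):
        mag = np.sqrt(f[i, 0] ** 2 + f[i, 1] ** 2 + f[i, 2] ** 2)
        if mag > fmax:
            s = fmax / mag
            f[i, 0] *= s
            f[i, 1] *= s
            f[i, 2] *= s


@njit(cache=True)
def integrate_chunk(pos, vel, nsteps, dt, gamma, m, kBT,
                    n_beads, binding, tf_state, attract_on,
                    KFENE, R0, KBEND, eps_s, eps_ns, rcut,
                    sp_i, sp_j, sp_K, sp_r0,
                    box, cutoff_nb, rebuild_every, fmax,
                    noise_seed, noise_scale, pairs):
    """Advance the system ``nsteps`` BAOAB steps; returns a status code."""
    np.random.seed(noise_seed)
    n = pos.shape[0]
    c1 = np.exp(-gamma * dt / m)
    c2 = noise_scale * np.sqrt((1.0 - c1 * c1) * kBT / m)
    half = 0.5 * dt
    f = np.zeros((n, 3))

    npairs = _build_pairs(pos, box, cutoff_nb, pairs)
    if npairs > pairs.shape[0]:
        return 2
    st = _compute_forces(pos, f, n_beads, binding, tf_state, attract_on,
                         KFENE, R0, KBEND, eps_s, eps_ns, rcut,
                         sp_i, sp_j, sp_K, sp_r0, pairs, npairs, box)
    if st != 0 and fmax <= 0.0:
        return st
    _cap_forces(f, fmax)

    for step in range(nsteps):
        xi = np.random.standard_normal(3 * n)
        for i in range(n):
            vx = vel[i, 0] + half * f[i, 0] / m
            vy = vel[i, 1] + half * f[i, 1] / m
            vz = vel[i, 2] + half * f[i, 2] / m
            x = pos[i, 0] + half * vx
            y = pos[i, 1] + half * vy
            z = pos[i, 2] + half * vz
            vx = c1 * vx + c2 * xi[3 * i]
            vy = c1 * vy + c2 * xi[3 * i + 1]
            vz = c1 * vz + c2 * xi[3 * i + 2]
            pos[i, 0] = x + half * vx
            pos[i, 1] = y + half * vy
            pos[i, 2] = z + half * vz
            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz
        if (step + 1) % rebuild_every == 0:
            for i in range(n):
                if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                        and np.isfinite(pos[i, 2])):
                    return 3
            npairs = _build_pairs(pos, box, cutoff_nb, pairs)
            if npairs > pairs.shape[0]:
                return 2
        st = _compute_forces(pos, f, n_beads, binding, tf_state, attract_on,
                             KFENE, R0, KBEND, eps_s, eps_ns, rcut,
                             sp_i, sp_j, sp_K, sp_r0, pairs, npairs, box)
        if st != 0 and fmax <= 0.0:
            return st
        _cap_forces(f, fmax)
        for i in range(n):
            vel[i, 0] += half * f[i, 0] / m
            vel[i, 1] += half * f[i, 1] / m
            vel[i, 2] += half * f[i, 2] / m
    for i in range(n):
        if not (np.isfinite(pos[i, 0]) and np.isfinite(pos[i, 1])
                and np.isfinite(pos[i, 2])):
            return 3
    return 0


def compute_forces_array(pos, n_beads, binding, tf_state, attract_on, params,
                         sp_i, sp_j, sp_K, sp_r0, all_pairs_cutoff=None):
    """Python-facing wrapper: forces on every particle via the kernel,
    using an all-pairs-capable neighbour list (for tests and single steps)."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    cutoff = all_pairs_cutoff if all_pairs_cutoff is not None else params.rcut + params.skin
    max_pairs = max(64, n * (n - 1) // 2)
    pairs = np.empty((max_pairs, 2), dtype=np.int64)
    npairs = _build_pairs(pos, params.box, cutoff, pairs)
    if npairs > max_pairs:
        raise RuntimeError("neighbour buffer overflow")
    _compute_forces(pos, f, n_beads, binding, tf_state, attract_on,
                    params.KFENE, params.R0, params.KBEND,
                    params.eps_specific, params.eps_nonspecific, params.rcut,
                    sp_i, sp_j, sp_K, sp_r0, pairs, npairs, params.box)
    return f
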