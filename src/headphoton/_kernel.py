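"""Numba voxel Monte Carlo kernel.

Single-threaded photon-packet transport on a labelled voxel grid:
exponentially sampled dimensionless steps consumed across voxels of varying
mu_s by a 3-D DDA walk, implicit capture (weight *= exp(-mu_a * l) per
traversed length), Henyey-Greenstein deflection with uniform azimuth,
Russian roulette below a weight threshold, and unpolarized Fresnel
reflection/refraction (probabilistic choice, total internal reflection
honored) wherever the refractive index changes between adjacent voxels.

RNG: one xorshift64* stream per packet, seeded by splitmix64 from
(seed, packet index) — runs are bitwise reproducible and independent of
any batching.
"""

import numpy as np
from numba import njit

C_MM_PER_NS = 299.792458

# terminal-event codes
EV_DETECTED = 1
EV_EXIT_OTHER = 2
EV_ROULETTE = 3
EV_TIME = 4
EV_NEVER_ENTERED = 5
EV_ERROR = 6

# tally indices
T_LAUNCHED = 0
T_ABSORBED = 1
T_DETECTED = 2
T_EXIT_OTHER = 3
T_ROULETTE = 4
T_TIME = 5
T_NEVER_ENTERED = 6
T_ERROR = 7
N_TALLIES = 8

_U64 = np.uint64


@njit(cache=True, inline="always")
def _splitmix64(x):
    z = x + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _packet_state(seed, ipk):
    s = _splitmix64(_splitmix64(_U64(seed)) ^ _splitmix64(_U64(ipk) + _U64(1)))
    if s == _U64(0):
        s = _U64(0x853C49E6748FEA9B)
    return s


@njit(cache=True, inline="always")
def _next_u64(s):
    s ^= s >> _U64(12)
    s ^= s << _U64(25)
    s ^= s >> _U64(27)
    return s, s * _U64(0x2545F4914F6CDD1D)


@njit(cache=True, inline="always")
def _u01(s):
    s, x = _next_u64(s)
    return s, (x >> _U64(11)) * (1.0 / 9007199254740992.0)  # [0, 1)


@njit(cache=True, inline="always")
def _hg_cos(g, u):
    if g >= 1.0:
        return 1.0
    if g <= -1.0:
        return -1.0
    if abs(g) < 1e-7:
        return 1.0 - 2.0 * u
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cost, phi):
    sint = np.sqrt(max(0.0, 1.0 - cost * cost))
    cosp = np.cos(phi)
    sinp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = sint * cosp
        ny = sint * sinp
        nz = cost * (1.0 if uz >= 0.0 else -1.0)
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = sint * (ux * uz * cosp - uy * sinp) / den + ux * cost
        ny = sint * (uy * uz * cosp + ux * sinp) / den + uy * cost
        nz = -sint * cosp * den + uz * cost
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _fresnel_unpolarized(n1, n2, cosi):
    """Unpolarized reflectance for |cos incidence| = cosi; returns (R, cost).

    cost is the transmitted cosine; R = 1.0 signals total internal
    reflection (cost then meaningless).
    """
    if n1 == n2:
        return 0.0, cosi
    sin2t = (n1 / n2) * (n1 / n2) * (1.0 - cosi * cosi)
    if sin2t >= 1.0:
        return 1.0, 0.0
    cost = np.sqrt(1.0 - sin2t)
    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
    return 0.5 * (rs * rs + rp * rp), cost


@njit(cache=True)
def run_kernel(
    labels,            # int16[nx, ny, nz]
    pitch,             # f8, mm
    mua, mus, gg, nn,  # f8[n_labels] property lookups (label 0 = exterior)
    src_mode,          # 0 = collimated disk, 1 = isotropic point
    src_center, src_dir, src_radius,
    accept_all,        # bool: accept every tissue->exterior exit
    accept_mask,       # bool[nx, ny, nz, 3, 2] (dummy 1-element when accept_all)
    n_packets, seed,
    roulette_threshold, roulette_survival,
    max_time, max_steps,
    record_vp,         # record per-voxel pathlengths of detected packets
    record_traj,       # record scattering-event positions of detected packets
    # outputs
    fluence,           # f8[nx, ny, nz]
    tallies,           # f8[N_TALLIES]
    det_weight, det_time, det_layer_path,   # f8[cap], f8[cap], f8[cap, n_labels]
    det_pos, det_dir, det_packet,           # f8[cap,3], f8[cap,3], i8[cap]
    vp_voxel, vp_len, vp_offsets,           # i8[vpcap], f8[vpcap], i8[cap+1]
    traj_xyz, traj_offsets,                 # f8[tjcap,3], i8[cap+1]
    hash_keys, hash_vals,                   # i8[H], f8[H] scratch (H power of 2)
    traj_scratch,                           # f8[tscap, 3] scratch
):
    nx, ny, nz = labels.shape
    n_labels = mua.shape[0]
    voxvol = pitch * pitch * pitch
    inv_c = 1.0 / C_MM_PER_NS
    hsize = hash_keys.shape[0]
    hmask = hsize - 1
    occ = np.empty(hsize, dtype=np.int64)

    # orthonormal frame for the source disk:
    # e1 = normalize(cross(dir, k)) with k the least-aligned coordinate axis
    ax, ay, az = src_dir[0], src_dir[1], src_dir[2]
    if abs(ax) <= abs(ay) and abs(ax) <= abs(az):
        kx, ky, kz = 1.0, 0.0, 0.0
    elif abs(ay) <= abs(az):
        kx, ky, kz = 0.0, 1.0, 0.0
    else:
        kx, ky, kz = 0.0, 0.0, 1.0
    e1x = ay * kz - az * ky
    e1y = az * kx - ax * kz
    e1z = ax * ky - ay * kx
    norm = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x, e1y, e1z = e1x / norm, e1y / norm, e1z / norm
    e2x = ay * e1z - az * e1y
    e2y = az * e1x - ax * e1z
    e2z = ax * e1y - ay * e1x

    # per-label reciprocals so the hot scatter path avoids divisions
    inv_mus = np.zeros(n_labels, dtype=np.float64)
    c_over_n = np.zeros(n_labels, dtype=np.float64)
    n_over_c = np.zeros(n_labels, dtype=np.float64)
    for j in range(n_labels):
        if mus[j] > 0.0:
            inv_mus[j] = 1.0 / mus[j]
        c_over_n[j] = C_MM_PER_NS / nn[j]
        n_over_c[j] = nn[j] * inv_c

    per_layer = np.zeros(n_labels, dtype=np.float64)
    n_det = 0
    vp_ptr = 0
    tj_ptr = 0
    vp_offsets[0] = 0
    traj_offsets[0] = 0
    vp_cap = vp_voxel.shape[0]
    tj_cap = traj_xyz.shape[0]
    ts_cap = traj_scratch.shape[0]

    for ipk in range(n_packets):
        state = _packet_state(seed, ipk)
        tallies[T_LAUNCHED] += 1.0

        # --- launch ---
        if src_mode == 0:
            state, u1 = _u01(state)
            state, u2 = _u01(state)
            r = src_radius * np.sqrt(u1)
            phi = 2.0 * np.pi * u2
            px = src_center[0] + r * (np.cos(phi) * e1x + np.sin(phi) * e2x)
            py = src_center[1] + r * (np.cos(phi) * e1y + np.sin(phi) * e2y)
            pz = src_center[2] + r * (np.cos(phi) * e1z + np.sin(phi) * e2z)
            ux, uy, uz = ax, ay, az
        else:
            px, py, pz = src_center[0], src_center[1], src_center[2]
            state, u1 = _u01(state)
            state, u2 = _u01(state)
            cz = 1.0 - 2.0 * u1
            sz = np.sqrt(max(0.0, 1.0 - cz * cz))
            phi = 2.0 * np.pi * u2
            ux, uy, uz = sz * np.cos(phi), sz * np.sin(phi), cz

        ix = int(np.floor(px / pitch))
        iy = int(np.floor(py / pitch))
        iz = int(np.floor(pz / pitch))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            tallies[T_ERROR] += 1.0
            continue

        w = 1.0
        t = 0.0
        for j in range(n_labels):
            per_layer[j] = 0.0
        s = -1.0  # force a fresh dimensionless step
        n_occ = 0
        n_tscratch = 0
        traj_overflow = False
        steps = 0
        event = 0

        while True:
            steps += 1
            if steps > max_steps:
                event = EV_ERROR
                break
            if not (np.isfinite(px) and np.isfinite(py) and np.isfinite(pz)):
                event = EV_ERROR
                break

            lab = labels[ix, iy, iz]
            mus_v = mus[lab]
            mua_v = mua[lab]
            n_v = nn[lab]

            if s < 0.0 and mus_v > 0.0:
                state, u = _u01(state)
                s = -np.log(1.0 - u)

            # fast path: the next scattering event falls inside this voxel
            # (no boundary distances, hence no divisions, needed)
            if mus_v > 0.0:
                t_scat_f = s * inv_mus[lab]
                if t_scat_f < (max_time - t) * c_over_n[lab]:
                    qx = px + ux * t_scat_f
                    qy = py + uy * t_scat_f
                    qz = pz + uz * t_scat_f
                    bx = ix * pitch
                    by = iy * pitch
                    bz = iz * pitch
                    if (bx < qx < bx + pitch and by < qy < by + pitch
                            and bz < qz < bz + pitch):
                        ell = t_scat_f
                        per_layer[lab] += ell
                        t += ell * n_over_c[lab]
                        if mua_v > 0.0:
                            dw = w * (1.0 - np.exp(-mua_v * ell))
                            tallies[T_ABSORBED] += dw
                            fluence[ix, iy, iz] += dw / (mua_v * voxvol)
                            w -= dw
                        else:
                            fluence[ix, iy, iz] += w * ell / voxvol
                        if record_vp:
                            key = (np.int64(ix) * ny + iy) * nz + iz + 1
                            h = int((np.uint64(key) * _U64(0x9E3779B97F4A7C15))
                                    >> _U64(40)) & hmask
                            bad = False
                            while True:
                                k = hash_keys[h]
                                if k == key:
                                    hash_vals[h] += ell
                                    break
                                if k == 0:
                                    if n_occ >= hsize - 8:
                                        bad = True
                                        break
                                    hash_keys[h] = key
                                    hash_vals[h] = ell
                                    occ[n_occ] = h
                                    n_occ += 1
                                    break
                                h = (h + 1) & hmask
                            if bad:
                                event = EV_ERROR
                                break
                        px, py, pz = qx, qy, qz
                        s = -1.0
                        if record_traj:
                            if n_tscratch < ts_cap:
                                traj_scratch[n_tscratch, 0] = px
                                traj_scratch[n_tscratch, 1] = py
                                traj_scratch[n_tscratch, 2] = pz
                                n_tscratch += 1
                            else:
                                traj_overflow = True
                        state, u = _u01(state)
                        cost = _hg_cos(gg[lab], u)
                        state, u = _u01(state)
                        ux, uy, uz = _rotate(ux, uy, uz, cost, 2.0 * np.pi * u)
                        if w < roulette_threshold:
                            state, u = _u01(state)
                            if u < roulette_survival:
                                w /= roulette_survival
                            else:
                                event = EV_ROULETTE
                                break
                        continue

            # distance to the next voxel boundary along each axis
            if ux > 0.0:
                tbx = ((ix + 1) * pitch - px) / ux
            elif ux < 0.0:
                tbx = (ix * pitch - px) / ux
            else:
                tbx = 1e308
            if uy > 0.0:
                tby = ((iy + 1) * pitch - py) / uy
            elif uy < 0.0:
                tby = (iy * pitch - py) / uy
            else:
                tby = 1e308
            if uz > 0.0:
                tbz = ((iz + 1) * pitch - pz) / uz
            elif uz < 0.0:
                tbz = (iz * pitch - pz) / uz
            else:
                tbz = 1e308
            # ties broken toward the smallest crossing parameter (axis order x,y,z)
            baxis = 0
            tb = tbx
            if tby < tb:
                tb = tby
                baxis = 1
            if tbz < tb:
                tb = tbz
                baxis = 2
            if tb < 0.0:
                tb = 0.0

            t_scat = s / mus_v if mus_v > 0.0 else 1e308
            if lab != 0:
                t_time = (max_time - t) * C_MM_PER_NS / n_v
                if t_time < 0.0:
                    t_time = 0.0
            else:
                t_time = 1e308

            ell = tb
            which = 0  # 0 boundary, 1 scatter, 2 time
            if t_scat < ell:
                ell = t_scat
                which = 1
            if t_time < ell:
                ell = t_time
                which = 2

            # --- accumulate over the segment (inside tissue/cavity only) ---
            if lab != 0 and ell > 0.0:
                per_layer[lab] += ell
                t += ell * n_v * inv_c
                if mua_v > 0.0:
                    dw = w * (1.0 - np.exp(-mua_v * ell))
                    tallies[T_ABSORBED] += dw
                    fluence[ix, iy, iz] += dw / (mua_v * voxvol)
                    w -= dw
                else:
                    # track-length estimator where absorption vanishes
                    fluence[ix, iy, iz] += w * ell / voxvol
                if record_vp:
                    key = (np.int64(ix) * ny + iy) * nz + iz + 1
                    h = int((np.uint64(key) * _U64(0x9E3779B97F4A7C15)) >> _U64(40)) & hmask
                    while True:
                        k = hash_keys[h]
                        if k == key:
                            hash_vals[h] += ell
                            break
                        if k == 0:
                            if n_occ >= hsize - 8:
                                event = EV_ERROR
                                which = -1
                                break
                            hash_keys[h] = key
                            hash_vals[h] = ell
                            occ[n_occ] = h
                            n_occ += 1
                            break
                        h = (h + 1) & hmask
                    if which == -1:
                        break
            if mus_v > 0.0:
                s -= mus_v * ell
                if s < 0.0:
                    s = 0.0

            px += ux * ell
            py += uy * ell
            pz += uz * ell

            if which == 2:
                event = EV_TIME
                break
            if which == 1:
                s = -1.0
                if record_traj:
                    if n_tscratch < ts_cap:
                        traj_scratch[n_tscratch, 0] = px
                        traj_scratch[n_tscratch, 1] = py
                        traj_scratch[n_tscratch, 2] = pz
                        n_tscratch += 1
                    else:
                        traj_overflow = True
                state, u = _u01(state)
                cost = _hg_cos(gg[lab], u)
                state, u = _u01(state)
                ux, uy, uz = _rotate(ux, uy, uz, cost, 2.0 * np.pi * u)
                if w < roulette_threshold:
                    state, u = _u01(state)
                    if u < roulette_survival:
                        w /= roulette_survival
                    else:
                        event = EV_ROULETTE
                        break
                continue

            # --- boundary crossing ---
            if baxis == 0:
                step_dir = 1 if ux > 0.0 else -1
                jx, jy, jz = ix + step_dir, iy, iz
                cosi = abs(ux)
            elif baxis == 1:
                step_dir = 1 if uy > 0.0 else -1
                jx, jy, jz = ix, iy + step_dir, iz
                cosi = abs(uy)
            else:
                step_dir = 1 if uz > 0.0 else -1
                jx, jy, jz = ix, iy, iz + step_dir
                cosi = abs(uz)

            out_of_grid = jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz
            if out_of_grid:
                next_lab = 0
            else:
                next_lab = labels[jx, jy, jz]
            n2 = nn[next_lab]

            crossed = True
            if n2 != n_v:
                R, cost = _fresnel_unpolarized(n_v, n2, cosi)
                state, u = _u01(state)
                if u < R:
                    # specular reflection off the face; stay in the voxel
                    if baxis == 0:
                        ux = -ux
                    elif baxis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                    crossed = False
                else:
                    scale = n_v / n2
                    if baxis == 0:
                        uy *= scale
                        uz *= scale
                        ux = cost if ux > 0.0 else -cost
                    elif baxis == 1:
                        ux *= scale
                        uz *= scale
                        uy = cost if uy > 0.0 else -cost
                    else:
                        ux *= scale
                        uy *= scale
                        uz = cost if uz > 0.0 else -cost
                    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm
                    uy /= norm
                    uz /= norm

            if not crossed:
                continue

            if lab != 0 and next_lab == 0:
                # exit through the head surface
                if accept_all:
                    ok = True
                else:
                    ok = accept_mask[ix, iy, iz, baxis, 1 if step_dir > 0 else 0]
                event = EV_DETECTED if ok else EV_EXIT_OTHER
                break
            if out_of_grid:
                # still in the exterior and leaving the grid
                event = EV_NEVER_ENTERED
                break
            ix, iy, iz = jx, jy, jz

        # --- settle the terminal event ---
        if event == EV_DETECTED and n_det < det_weight.shape[0]:
            ok_store = True
            vlo = vp_ptr
            tlo = tj_ptr
            if record_vp:
                if vp_ptr + n_occ > vp_cap:
                    tallies[T_ERROR] += 1.0
                    ok_store = False
                else:
                    for q in range(n_occ):
                        h = occ[q]
                        vp_voxel[vp_ptr] = hash_keys[h] - 1
                        vp_len[vp_ptr] = hash_vals[h]
                        vp_ptr += 1
            if ok_store and record_traj:
                if tj_ptr + n_tscratch > tj_cap or traj_overflow:
                    tallies[T_ERROR] += 1.0
                    ok_store = False
                    vp_ptr = vlo
                else:
                    for q in range(n_tscratch):
                        traj_xyz[tj_ptr, 0] = traj_scratch[q, 0]
                        traj_xyz[tj_ptr, 1] = traj_scratch[q, 1]
                        traj_xyz[tj_ptr, 2] = traj_scratch[q, 2]
                        tj_ptr += 1
            if ok_store:
                det_weight[n_det] = w
                det_time[n_det] = t
                for j in range(n_labels):
                    det_layer_path[n_det, j] = per_layer[j]
                det_pos[n_det, 0] = px
                det_pos[n_det, 1] = py
                det_pos[n_det, 2] = pz
                det_dir[n_det, 0] = ux
                det_dir[n_det, 1] = uy
                det_dir[n_det, 2] = uz
                det_packet[n_det] = ipk
                n_det += 1
                vp_offsets[n_det] = vp_ptr
                traj_offsets[n_det] = tj_ptr
                tallies[T_DETECTED] += w
            else:
                tallies[T_EXIT_OTHER] += w
        elif event == EV_DETECTED:
            tallies[T_EXIT_OTHER] += w  # record capacity exhausted
        elif event == EV_EXIT_OTHER:
            tallies[T_EXIT_OTHER] += w
        elif event == EV_ROULETTE:
            tallies[T_ROULETTE] += w
        elif event == EV_TIME:
            tallies[T_TIME] += w
        elif event == EV_NEVER_ENTERED:
            tallies[T_NEVER_ENTERED] += w
        else:
            tallies[T_ERROR] += 1.0

        # reset per-packet hash scratch
        if record_vp:
            for q in range(n_occ):
                hash_keys[occ[q]] = 0
                hash_vals[occ[q]] = 0.0

    return n_det, vp_ptr, tj_ptr
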