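"""Numba kernels: energy/force evaluation and the BAOAB Langevin loop.

Everything here operates on flat numpy arrays prepared by
:mod:`picmelt.energy`.  Energies are accumulated into a fixed-length
term vector indexed by the ``TERM_*`` constants of
:mod:`picmelt.topology`:

    0 protein local   1 protein Go      2 DNA bonded
    3 DNA stacking    4 DNA pairing     5 protein–DNA Go
    6 excluded volume 7 electrostatics  8 restraints

All forces are exact analytic gradients of the implemented energies
(verified against central differences in the test suite).
"""

import numpy as np
from numba import njit

N_TERMS = 9
KB = 0.0019872041

# clamp for the 12-10 well: below CLAMP_FRAC*r0 the potential continues
# linearly so r -> 0 stays finite
CLAMP_FRAC = 0.6


@njit(cache=True, fastmath=False)
def _pair_12_10(r, r0, eps):
    """12-10 well energy and dU/dr with a linear small-r continuation."""
    rmin = CLAMP_FRAC * r0
    rr = r if r > rmin else rmin
    x = r0 / rr
    x2 = x * x
    x10 = x2 * x2 * x2 * x2 * x2
    x12 = x10 * x2
    u = eps * (5.0 * x12 - 6.0 * x10)
    du = 60.0 * eps * (x10 - x12) / rr
    if r <= rmin:
        u = u + du * (r - rmin)
    return u, du


@njit(cache=True, fastmath=False)
def _angle_grad(x, ia, ib, ic):
    """Angle at vertex ib and the gradients d(theta)/d(r_a,r_b,r_c)."""
    ux = x[ia, 0] - x[ib, 0]; uy = x[ia, 1] - x[ib, 1]; uz = x[ia, 2] - x[ib, 2]
    vx = x[ic, 0] - x[ib, 0]; vy = x[ic, 1] - x[ib, 1]; vz = x[ic, 2] - x[ib, 2]
    lu = np.sqrt(ux * ux + uy * uy + uz * uz)
    lv = np.sqrt(vx * vx + vy * vy + vz * vz)
    c = (ux * vx + uy * vy + uz * vz) / (lu * lv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    th = np.arccos(c)
    s = np.sqrt(1.0 - c * c)
    if s < 1.0e-8:
        s = 1.0e-8
    ga = np.empty(3); gc = np.empty(3)
    inv = -1.0 / s
    ga[0] = inv * (vx / (lu * lv) - c * ux / (lu * lu))
    ga[1] = inv * (vy / (lu * lv) - c * uy / (lu * lu))
    ga[2] = inv * (vz / (lu * lv) - c * uz / (lu * lu))
    gc[0] = inv * (ux / (lu * lv) - c * vx / (lv * lv))
    gc[1] = inv * (uy / (lu * lv) - c * vy / (lv * lv))
    gc[2] = inv * (uz / (lu * lv) - c * vz / (lv * lv))
    return th, ga, gc


@njit(cache=True, fastmath=True)
def compute_forces(
        x, f,
        bonds_idx, bonds_r0, bonds_k, bonds_term,
        angles_idx, angles_t0, angles_k, angles_term,
        dihs_idx, dihs_p0, dihs_k, dihs_term,
        pairs_idx, pairs_r0, pairs_eps, pairs_term,
        wc_base, wc_sugar, wc_r0, wc_eps, wc_ti0, wc_tj0, wc_sig,
        sigma, eps_ev, ev_cap,
        charges, k_dh, lam, dh_cut,
        ev_pairs, dh_pairs,
        res_idx, res_ref, res_k):
    terms = np.zeros(N_TERMS)
    f[:, :] = 0.0

    # ---- harmonic bonds ------------------------------------------------
    for b in range(bonds_idx.shape[0]):
        i = bonds_idx[b, 0]; j = bonds_idx[b, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bonds_r0[b]
        terms[bonds_term[b]] += bonds_k[b] * d * d
        c = -2.0 * bonds_k[b] * d / r
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz

    # ---- harmonic angles -----------------------------------------------
    for a in range(angles_idx.shape[0]):
        ia = angles_idx[a, 0]; ib = angles_idx[a, 1]; ic = angles_idx[a, 2]
        th, ga, gc = _angle_grad(x, ia, ib, ic)
        d = th - angles_t0[a]
        terms[angles_term[a]] += angles_k[a] * d * d
        coef = -2.0 * angles_k[a] * d
        for k in range(3):
            f[ia, k] += coef * ga[k]
            f[ic, k] += coef * gc[k]
            f[ib, k] -= coef * (ga[k] + gc[k])

    # ---- periodic native-biased dihedrals --------------------------------
    for d0 in range(dihs_idx.shape[0]):
        i1 = dihs_idx[d0, 0]; i2 = dihs_idx[d0, 1]
        i3 = dihs_idx[d0, 2]; i4 = dihs_idx[d0, 3]
        b1 = x[i2] - x[i1]; b2 = x[i3] - x[i2]; b3 = x[i4] - x[i3]
        n1 = np.empty(3); n2 = np.empty(3)
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        lb2 = np.sqrt(b2[0] * b2[0] + b2[1] * b2[1] + b2[2] * b2[2])
        m1 = np.empty(3)
        m1[0] = n1[1] * b2[2] - n1[2] * b2[1]
        m1[1] = n1[2] * b2[0] - n1[0] * b2[2]
        m1[2] = n1[0] * b2[1] - n1[1] * b2[0]
        xx = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        yy = (m1[0] * n2[0] + m1[1] * n2[1] + m1[2] * n2[2]) / lb2
        phi = np.arctan2(yy, xx)
        dphi = phi - dihs_p0[d0]
        terms[dihs_term[d0]] += dihs_k[d0] * (1.0 - np.cos(dphi))
        dudphi = dihs_k[d0] * np.sin(dphi)
        ln1 = n1[0] * n1[0] + n1[1] * n1[1] + n1[2] * n1[2]
        ln2 = n2[0] * n2[0] + n2[1] * n2[1] + n2[2] * n2[2]
        if ln1 < 1.0e-12 or ln2 < 1.0e-12:
            continue
        g1 = np.empty(3); g4 = np.empty(3)
        for k in range(3):
            g1[k] = (lb2 / ln1) * n1[k]
            g4[k] = -(lb2 / ln2) * n2[k]
        c12 = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / (lb2 * lb2)
        c32 = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / (lb2 * lb2)
        for k in range(3):
            g2 = -(1.0 + c12) * g1[k] + c32 * g4[k]
            g3 = c12 * g1[k] - (1.0 + c32) * g4[k]
            f[i1, k] -= dudphi * g1[k]
            f[i2, k] -= dudphi * g2
            f[i3, k] -= dudphi * g3
            f[i4, k] -= dudphi * g4[k]

    # ---- 12-10 pair wells (Go contacts, stacking) ------------------------
    for p in range(pairs_idx.shape[0]):
        i = pairs_idx[p, 0]; j = pairs_idx[p, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        u, du = _pair_12_10(r, pairs_r0[p], pairs_eps[p])
        terms[pairs_term[p]] += u
        c = -du / r
        f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
        f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz

    # ---- orientation-gated Watson-Crick pairing --------------------------
    # U = eps * g(theta_i) * g(theta_j) * w(r), w the 12-10 well,
    # g a Gaussian in the S-B...B gate angle.  A negative eps marks a
    # mismatched (non-pairing) position: the well is replaced by a pure
    # (r0/r)^12 repulsion of amplitude |eps| modeling the steric
    # incompatibility of non-complementary bases.
    for p in range(wc_base.shape[0]):
        eps = wc_eps[p]
        if eps == 0.0:
            continue
        if eps < 0.0:
            bi = wc_base[p, 0]; bj = wc_base[p, 1]
            dx = x[bi, 0] - x[bj, 0]; dy = x[bi, 1] - x[bj, 1]
            dz = x[bi, 2] - x[bj, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            rmin = CLAMP_FRAC * wc_r0[p]
            rr = r if r > rmin else rmin
            y = wc_r0[p] / rr
            y2 = y * y
            y12 = y2 * y2 * y2 * y2 * y2 * y2
            u = -eps * y12
            du = 12.0 * eps * y12 / rr
            if r <= rmin:
                u = u + du * (r - rmin)
            terms[4] += u
            c = -du / r
            f[bi, 0] += c * dx; f[bi, 1] += c * dy; f[bi, 2] += c * dz
            f[bj, 0] -= c * dx; f[bj, 1] -= c * dy; f[bj, 2] -= c * dz
            continue
        bi = wc_base[p, 0]; bj = wc_base[p, 1]
        si = wc_sugar[p, 0]; sj = wc_sugar[p, 1]
        dx = x[bi, 0] - x[bj, 0]; dy = x[bi, 1] - x[bj, 1]; dz = x[bi, 2] - x[bj, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        w, dw = _pair_12_10(r, wc_r0[p], 1.0)
        thi, gai, gci = _angle_grad(x, si, bi, bj)
        thj, gaj, gcj = _angle_grad(x, sj, bj, bi)
        s2 = wc_sig[p] * wc_sig[p]
        di = thi - wc_ti0[p]; dj = thj - wc_tj0[p]
        gi = np.exp(-di * di / (2.0 * s2))
        gj = np.exp(-dj * dj / (2.0 * s2))
        terms[4] += eps * gi * gj * w
        # radial part
        c = -eps * gi * gj * dw / r
        f[bi, 0] += c * dx; f[bi, 1] += c * dy; f[bi, 2] += c * dz
        f[bj, 0] -= c * dx; f[bj, 1] -= c * dy; f[bj, 2] -= c * dz
        # angular parts
        ci = -eps * gj * w * gi * (-di / s2)   # -dU/dtheta_i
        cj = -eps * gi * w * gj * (-dj / s2)
        for k in range(3):
            # theta_i spans (s_i, b_i, b_j), vertex b_i
            f[si, k] += ci * gai[k]
            f[bj, k] += ci * gci[k]
            f[bi, k] -= ci * (gai[k] + gci[k])
            # theta_j spans (s_j, b_j, b_i), vertex b_j
            f[sj, k] += cj * gaj[k]
            f[bi, k] += cj * gcj[k]
            f[bj, k] -= cj * (gaj[k] + gcj[k])

    # ---- excluded volume over its neighbor list --------------------------
    for p in range(ev_pairs.shape[0]):
        i = ev_pairs[p, 0]; j = ev_pairs[p, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        sij = sigma[i] + sigma[j]
        if r < 2.0 * sij:
            # purely repulsive (sij/r)^12, linearly capped near r=0
            rcap = sij * (eps_ev / ev_cap) ** (1.0 / 12.0)
            rr = r if r > rcap else rcap
            y = sij / rr
            y2 = y * y
            y12 = y2 * y2 * y2 * y2 * y2 * y2
            u = eps_ev * y12
            du = -12.0 * eps_ev * y12 / rr
            if r <= rcap:
                u = u + du * (r - rcap)
            terms[6] += u
            c = -du / max(r, 1.0e-10)
            f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
            f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz

    # ---- Debye-Hückel over its neighbor list -----------------------------
    for p in range(dh_pairs.shape[0]):
        i = dh_pairs[p, 0]; j = dh_pairs[p, 1]
        dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = np.sqrt(r2)
        if r < dh_cut:
            qq = charges[i] * charges[j]
            e = np.exp(-r / lam)
            u = k_dh * qq * e / r
            ushift = k_dh * qq * np.exp(-dh_cut / lam) / dh_cut
            terms[7] += u - ushift
            du = -k_dh * qq * e * (1.0 / (lam * r) + 1.0 / r2)
            c = -du / r
            f[i, 0] += c * dx; f[i, 1] += c * dy; f[i, 2] += c * dz
            f[j, 0] -= c * dx; f[j, 1] -= c * dy; f[j, 2] -= c * dz

    # ---- harmonic position restraints -----------------------------------
    for p in range(res_idx.shape[0]):
        i = res_idx[p]
        for k in range(3):
            d = x[i, k] - res_ref[p, k]
            terms[8] += 0.5 * res_k[p] * d * d
            f[i, k] -= res_k[p] * d

    return terms


@njit(cache=True, fastmath=True)
def build_neighbor_pairs(x, ev_cutoff, dh_cutoff, excl_ev, excl_dh,
                         charges):
    """Verlet lists for the two nonbonded terms: excluded-volume pairs
    within ``ev_cutoff`` and charged pairs within ``dh_cutoff``."""
    n = x.shape[0]
    ev2 = ev_cutoff * ev_cutoff
    dh2 = dh_cutoff * dh_cutoff
    big2 = max(ev2, dh2)
    cap_e = max(16, n * 32)
    cap_d = max(16, n * 32)
    ev = np.empty((cap_e, 2), dtype=np.int64)
    dh = np.empty((cap_d, 2), dtype=np.int64)
    me = 0; md = 0
    for i in range(n - 1):
        qi = charges[i]
        for j in range(i + 1, n):
            dx = x[i, 0] - x[j, 0]; dy = x[i, 1] - x[j, 1]; dz = x[i, 2] - x[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > big2:
                continue
            if r2 <= ev2 and excl_ev[i, j] == 0:
                if me >= cap_e:
                    cap_e *= 2
                    new = np.empty((cap_e, 2), dtype=np.int64)
                    new[:me] = ev[:me]
                    ev = new
                ev[me, 0] = i; ev[me, 1] = j
                me += 1
            if r2 <= dh2 and qi != 0.0 and charges[j] != 0.0 \
                    and excl_dh[i, j] == 0:
                if md >= cap_d:
                    cap_d *= 2
                    new = np.empty((cap_d, 2), dtype=np.int64)
                    new[:md] = dh[:md]
                    dh = new
                dh[md, 0] = i; dh[md, 1] = j
                md += 1
    return ev[:me].copy(), dh[:md].copy()


@njit(cache=True)
def run_baoab(
        x0, masses, dt, gamma, tsched, save_interval, seed,
        bonds_idx, bonds_r0, bonds_k, bonds_term,
        angles_idx, angles_t0, angles_k, angles_term,
        dihs_idx, dihs_p0, dihs_k, dihs_term,
        pairs_idx, pairs_r0, pairs_eps, pairs_term,
        wc_base, wc_sugar, wc_r0, wc_eps, wc_ti0, wc_tj0, wc_sig,
        sigma, eps_ev, ev_cap,
        charges, k_dh, lam, dh_cut,
        excl_ev, excl_dh,
        res_idx, res_ref, res_k,
        ev_cutoff, nb_skin, nb_every,
        v0, use_v0, energy_limit):
    """BAOAB Langevin integration.

    ``tsched`` holds the target temperature for every step.  Returns
    (frames, per-frame energy terms, per-frame kinetic energies, final
    velocities, status); status is -1 on success or the step index at
    which the energy diverged.
    """
    n = x0.shape[0]
    n_steps = tsched.shape[0]
    n_save = n_steps // save_interval + 1
    frames = np.empty((n_save, n, 3))
    eterms = np.empty((n_save, N_TERMS))
    kins = np.empty(n_save)

    np.random.seed(seed)
    x = x0.copy()
    v = np.empty((n, 3))
    if use_v0:
        v[:, :] = v0
    else:
        t0 = tsched[0] if n_steps > 0 else 300.0
        for i in range(n):
            s = np.sqrt(KB * t0 / masses[i])
            for k in range(3):
                v[i, k] = s * np.random.standard_normal()

    f = np.empty((n, 3))
    ev_pairs, dh_pairs = build_neighbor_pairs(
        x, ev_cutoff + nb_skin, dh_cut + nb_skin, excl_ev, excl_dh, charges)
    terms = compute_forces(
        x, f,
        bonds_idx, bonds_r0, bonds_k, bonds_term,
        angles_idx, angles_t0, angles_k, angles_term,
        dihs_idx, dihs_p0, dihs_k, dihs_term,
        pairs_idx, pairs_r0, pairs_eps, pairs_term,
        wc_base, wc_sugar, wc_r0, wc_eps, wc_ti0, wc_tj0, wc_sig,
        sigma, eps_ev, ev_cap,
        charges, k_dh, lam, dh_cut,
        ev_pairs, dh_pairs,
        res_idx, res_ref, res_k)

    isave = 0
    frames[0] = x
    eterms[0] = terms
    ke = 0.0
    for i in range(n):
        ke += 0.5 * masses[i] * (v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
    kins[0] = ke
    isave = 1

    h = dt
    status = -1
    for step in range(n_steps):
        temp = tsched[step]
        c1 = np.exp(-gamma * h)
        if gamma > 0.0 and temp > 0.0:
            c2 = np.sqrt((1.0 - c1 * c1) * KB * temp)
        else:
            c2 = 0.0
        # B: half kick
        for i in range(n):
            im = 0.5 * h / masses[i]
            v[i, 0] += im * f[i, 0]
            v[i, 1] += im * f[i, 1]
            v[i, 2] += im * f[i, 2]
        # A: half drift
        x += (0.5 * h) * v
        # O: Ornstein-Uhlenbeck
        if gamma > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                s = c2 / np.sqrt(masses[i])
                v[i, 0] = c1 * v[i, 0] + s * noise[i, 0]
                v[i, 1] = c1 * v[i, 1] + s * noise[i, 1]
                v[i, 2] = c1 * v[i, 2] + s * noise[i, 2]
        # A: half drift
        x += (0.5 * h) * v
        # neighbor-list refresh
        if (step + 1) % nb_every == 0:
            ev_pairs, dh_pairs = build_neighbor_pairs(
                x, ev_cutoff + nb_skin, dh_cut + nb_skin,
                excl_ev, excl_dh, charges)
        # force at new positions, then B: half kick
        terms = compute_forces(
            x, f,
            bonds_idx, bonds_r0, bonds_k, bonds_term,
            angles_idx, angles_t0, angles_k, angles_term,
            dihs_idx, dihs_p0, dihs_k, dihs_term,
            pairs_idx, pairs_r0, pairs_eps, pairs_term,
            wc_base, wc_sugar, wc_r0, wc_eps, wc_ti0, wc_tj0, wc_sig,
            sigma, eps_ev, ev_cap,
            charges, k_dh, lam, dh_cut,
            ev_pairs, dh_pairs,
            res_idx, res_ref, res_k)
        for i in range(n):
            im = 0.5 * h / masses[i]
            v[i, 0] += im * f[i, 0]
            v[i, 1] += im * f[i, 1]
            v[i, 2] += im * f[i, 2]

        etot = 0.0
        for t in range(N_TERMS):
            etot += terms[t]
        if not np.isfinite(etot) or abs(etot) > energy_limit:
            status = step
            break

        if (step + 1) % save_interval == 0:
            frames[isave] = x
            eterms[isave] = terms
            ke = 0.0
            for i in range(n):
                ke += 0.5 * masses[i] * (
                    v[i, 0] ** 2 + v[i, 1] ** 2 + v[i, 2] ** 2)
            kins[isave] = ke
            isave += 1

    return frames[:isave], eterms[:isave], kins[:isave], v, status
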