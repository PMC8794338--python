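"""Numba inner loops for the CF1 Monte Carlo engine and the frame analysis.

Everything here is private plumbing.  The engine kernels work on flat numpy
arrays (positions, species codes, per-site charges, Ewald structure factors)
so that a whole chunk of attempted moves runs without touching the Python
interpreter.  Short-range pair energies (non-Coulomb CF1 terms plus the
erfc-screened real-space Ewald term) come from per-pair-type lookup tables
with linear interpolation; reciprocal-space sums are updated incrementally
through the structure factors S_k.

The analytic CF1 potentials are duplicated here as scalar @njit functions
(default parameterization) for the analysis kernels; their agreement with
:mod:`cf1water.model` is asserted in the test suite.
"""

import math

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# analytic CF1 potentials (kcal/mol, r in Å) -- default parameterization
# --------------------------------------------------------------------------

KCAL = 4.184


@njit(cache=True)
def u_oo_kcal(r):
    u = 144.538 / r + 24082.38 * r ** (-8.8591)
    u += -0.25 * math.exp(-4.0 * (r - 3.4) ** 2)
    u += -0.25 * math.exp(-1.5 * (r - 4.5) ** 2)
    return u


@njit(cache=True)
def u_hh_kcal(r):
    x = 40.0 * (r - 2.0)
    fermi = 0.0 if x > 700.0 else 18.0 / (1.0 + math.exp(x))
    return 36.1345 / r + fermi - 17.0 * math.exp(-7.62177 * (r - 1.45251) ** 2)


@njit(cache=True)
def u_oh_kcal(r):
    u = -72.269 / r + 6.23403 * r ** (-9.19912)
    x1 = 40.0 * (r - 1.05)
    if x1 <= 700.0:
        u += -10.0 / (1.0 + math.exp(x1))
    x2 = 5.49305 * (r - 2.2)
    if x2 <= 700.0:
        u += -4.0 / (1.0 + math.exp(x2))
    return u


@njit(cache=True)
def pair_energy_kj(si, sj, r):
    """Full CF1 pair energy in kJ/mol (direct 1/r Coulomb), default params."""
    t = si + sj
    if t == 0:
        return KCAL * u_oo_kcal(r)
    elif t == 1:
        return KCAL * u_oh_kcal(r)
    else:
        return KCAL * u_hh_kcal(r)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


# --------------------------------------------------------------------------
# minimum image helpers
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _mi(d, L):
    if d > 0.5 * L:
        d -= L
    elif d < -0.5 * L:
        d += L
    return d


@njit(cache=True, inline="always")
def _wrap(x, L):
    x = x % L
    if x < 0.0:
        x += L
    return x


@njit(cache=True)
def min_image_dist2(ax, ay, az, bx, by, bz, L):
    dx = _mi(ax - bx, L)
    dy = _mi(ay - by, L)
    dz = _mi(az - bz, L)
    return dx * dx + dy * dy + dz * dz


# --------------------------------------------------------------------------
# tabulated short-range energy of one site against the rest
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def site_sr_energy(pos, species, n, L, x, y, z, s_i, utab, inv_dr, rcut2,
                   skip1, skip2, skip3):
    """Tabulated pair-energy sum of a probe site at (x,y,z) with species
    code ``s_i`` against sites 0..n-1, excluding up to three skip indices."""
    e = 0.0
    ntab = utab.shape[1]
    for j in range(n):
        if j == skip1 or j == skip2 or j == skip3:
            continue
        dx = _mi(x - pos[j, 0], L)
        dy = _mi(y - pos[j, 1], L)
        dz = _mi(z - pos[j, 2], L)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rcut2:
            r = math.sqrt(r2)
            t = r * inv_dr
            idx = int(t)
            if idx >= ntab - 1:
                idx = ntab - 2
            frac = t - idx
            p = s_i + species[j]
            e += utab[p, idx] + frac * (utab[p, idx + 1] - utab[p, idx])
    return e


@njit(cache=True, fastmath=True)
def pair_table_energy(r, p, utab, inv_dr):
    ntab = utab.shape[1]
    t = r * inv_dr
    idx = int(t)
    if idx >= ntab - 1:
        idx = ntab - 2
    frac = t - idx
    return utab[p, idx] + frac * (utab[p, idx + 1] - utab[p, idx])


@njit(cache=True, fastmath=True)
def total_sr_energy(pos, species, n, L, utab, inv_dr, rcut2):
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], L)
            dy = _mi(pos[i, 1] - pos[j, 1], L)
            dz = _mi(pos[i, 2] - pos[j, 2], L)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rcut2:
                r = math.sqrt(r2)
                e += pair_table_energy(r, species[i] + species[j], utab, inv_dr)
    return e


# --------------------------------------------------------------------------
# reciprocal-space incremental updates
# --------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _fill_phases(x, L, kmax, out):
    """out[kmax+n] = exp(i 2 pi n x / L) for n in [-kmax, kmax]."""
    c = math.cos(2.0 * math.pi * x / L)
    s = math.sin(2.0 * math.pi * x / L)
    e = complex(c, s)
    out[kmax] = 1.0 + 0.0j
    for n in range(1, kmax + 1):
        out[kmax + n] = out[kmax + n - 1] * e
        out[kmax - n] = out[kmax + n].conjugate()


@njit(cache=True, fastmath=True)
def recip_delta_move(kn, Ak, Sk, kmax, q, xo, yo, zo, xn, yn, zn, L,
                     pxo, pyo, pzo, pxn, pyn, pzn, dS):
    """Energy change of moving one charge q; fills dS with the S_k update."""
    _fill_phases(xo, L, kmax, pxo)
    _fill_phases(yo, L, kmax, pyo)
    _fill_phases(zo, L, kmax, pzo)
    _fill_phases(xn, L, kmax, pxn)
    _fill_phases(yn, L, kmax, pyn)
    _fill_phases(zn, L, kmax, pzn)
    dE = 0.0
    nk = kn.shape[0]
    for k in range(nk):
        ix = kn[k, 0] + kmax
        iy = kn[k, 1] + kmax
        iz = kn[k, 2] + kmax
        d = q * (pxn[ix] * pyn[iy] * pzn[iz] - pxo[ix] * pyo[iy] * pzo[iz])
        s = Sk[k]
        dE += Ak[k] * (2.0 * (s.real * d.real + s.imag * d.imag)
                       + d.real * d.real + d.imag * d.imag)
        dS[k] = d
    return dE


@njit(cache=True, fastmath=True)
def recip_delta_triplet(kn, Ak, Sk, kmax, qs3, xs3, ys3, zs3, L, sign,
                        px, py, pz, dS):
    """Energy change of adding (sign=+1) or removing (sign=-1) three charges."""
    nk = kn.shape[0]
    for k in range(nk):
        dS[k] = 0.0 + 0.0j
    for s in range(3):
        _fill_phases(xs3[s], L, kmax, px)
        _fill_phases(ys3[s], L, kmax, py)
        _fill_phases(zs3[s], L, kmax, pz)
        qq = sign * qs3[s]
        for k in range(nk):
            ix = kn[k, 0] + kmax
            iy = kn[k, 1] + kmax
            iz = kn[k, 2] + kmax
            dS[k] += qq * (px[ix] * py[iy] * pz[iz])
    dE = 0.0
    for k in range(nk):
        d = dS[k]
        s = Sk[k]
        dE += Ak[k] * (2.0 * (s.real * d.real + s.imag * d.imag)
                       + d.real * d.real + d.imag * d.imag)
    return dE


@njit(cache=True, fastmath=True)
def recip_energy(Sk, Ak):
    e = 0.0
    for k in range(Sk.shape[0]):
        s = Sk[k]
        e += Ak[k] * (s.real * s.real + s.imag * s.imag)
    return e


@njit(cache=True, fastmath=True)
def structure_factors(pos, qs, n, L, kn, kmax, Sk):
    nk = kn.shape[0]
    px = np.empty(2 * kmax + 1, dtype=np.complex128)
    py = np.empty(2 * kmax + 1, dtype=np.complex128)
    pz = np.empty(2 * kmax + 1, dtype=np.complex128)
    for k in range(nk):
        Sk[k] = 0.0 + 0.0j
    for i in range(n):
        _fill_phases(pos[i, 0], L, kmax, px)
        _fill_phases(pos[i, 1], L, kmax, py)
        _fill_phases(pos[i, 2], L, kmax, pz)
        q = qs[i]
        for k in range(nk):
            ix = kn[k, 0] + kmax
            iy = kn[k, 1] + kmax
            iz = kn[k, 2] + kmax
            Sk[k] += q * (px[ix] * py[iy] * pz[iz])


# --------------------------------------------------------------------------
# Metropolis displacement chunk
# --------------------------------------------------------------------------

_HARD_REJECT = 1.0e4  # in beta*dE units: skip the k-space work, reject outright


@njit(cache=True)
def run_displacement_chunk(pos, species, qs, n, L, beta, max_disp,
                           utab, inv_dr, rcut2, kn, Ak, Sk, kmax,
                           n_steps, U):
    """Run ``n_steps`` single-site displacement attempts; returns (U, n_acc)."""
    m = 2 * kmax + 1
    pxo = np.empty(m, dtype=np.complex128)
    pyo = np.empty(m, dtype=np.complex128)
    pzo = np.empty(m, dtype=np.complex128)
    pxn = np.empty(m, dtype=np.complex128)
    pyn = np.empty(m, dtype=np.complex128)
    pzn = np.empty(m, dtype=np.complex128)
    dS = np.empty(Sk.shape[0], dtype=np.complex128)
    n_acc = 0
    for _ in range(n_steps):
        i = int(np.random.random() * n)
        if i >= n:
            i = n - 1
        xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
        xn = _wrap(xo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
        yn = _wrap(yo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
        zn = _wrap(zo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
        s_i = species[i]
        e_old = site_sr_energy(pos, species, n, L, xo, yo, zo, s_i,
                               utab, inv_dr, rcut2, i, -1, -1)
        e_new = site_sr_energy(pos, species, n, L, xn, yn, zn, s_i,
                               utab, inv_dr, rcut2, i, -1, -1)
        dE_sr = e_new - e_old
        if beta * dE_sr > _HARD_REJECT:
            continue
        dE_rec = recip_delta_move(kn, Ak, Sk, kmax, qs[i], xo, yo, zo,
                                  xn, yn, zn, L, pxo, pyo, pzo, pxn, pyn, pzn, dS)
        dU = dE_sr + dE_rec
        if dU <= 0.0:
            accept = True
        else:
            arg = beta * dU
            accept = arg <= 700.0 and np.random.random() < math.exp(-arg)
        if accept:
            pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
            for k in range(Sk.shape[0]):
                Sk[k] += dS[k]
            U += dU
            n_acc += 1
    return U, n_acc


# --------------------------------------------------------------------------
# GCMC insertion geometry + grand-canonical chunk
# --------------------------------------------------------------------------


@njit(cache=True)
def _random_unit_vector():
    while True:
        x = 2.0 * np.random.random() - 1.0
        y = 2.0 * np.random.random() - 1.0
        z = 2.0 * np.random.random() - 1.0
        r2 = x * x + y * y + z * z
        if 1e-8 < r2 <= 1.0:
            r = math.sqrt(r2)
            return x / r, y / r, z / r


@njit(cache=True)
def sample_insertion_triplet(L, r_oh_lo, r_oh_hi, r_hh_lo, r_hh_hi, max_retry,
                             xs3, ys3, zs3):
    """Sample O + 2 H in the admissible geometry windows; fills xs3/ys3/zs3
    (order O, H, H) with wrapped coordinates.  Returns True on success."""
    ox = np.random.random() * L
    oy = np.random.random() * L
    oz = np.random.random() * L
    ux, uy, uz = _random_unit_vector()
    r1 = r_oh_lo + np.random.random() * (r_oh_hi - r_oh_lo)
    h1x, h1y, h1z = ox + r1 * ux, oy + r1 * uy, oz + r1 * uz
    ok = False
    h2x = h2y = h2z = 0.0
    for _ in range(max_retry):
        vx, vy, vz = _random_unit_vector()
        r2 = r_oh_lo + np.random.random() * (r_oh_hi - r_oh_lo)
        cx, cy, cz = ox + r2 * vx, oy + r2 * vy, oz + r2 * vz
        d2 = min_image_dist2(h1x, h1y, h1z, cx, cy, cz, L)
        if r_hh_lo * r_hh_lo <= d2 <= r_hh_hi * r_hh_hi:
            h2x, h2y, h2z = cx, cy, cz
            ok = True
            break
    if not ok:
        return False
    xs3[0], ys3[0], zs3[0] = _wrap(ox, L), _wrap(oy, L), _wrap(oz, L)
    xs3[1], ys3[1], zs3[1] = _wrap(h1x, L), _wrap(h1y, L), _wrap(h1z, L)
    xs3[2], ys3[2], zs3[2] = _wrap(h2x, L), _wrap(h2y, L), _wrap(h2z, L)
    return True


@njit(cache=True)
def _triplet_sr_energy(pos, species, n, L, xs3, ys3, zs3, sp3, utab, inv_dr,
                       rcut2, skip1, skip2, skip3):
    """Short-range energy of a free-standing triplet against sites 0..n-1
    (minus skips) plus the triplet's three mutual pair terms."""
    e = 0.0
    for s in range(3):
        e += site_sr_energy(pos, species, n, L, xs3[s], ys3[s], zs3[s], sp3[s],
                            utab, inv_dr, rcut2, skip1, skip2, skip3)
    for a in range(3):
        for b in range(a + 1, 3):
            d2 = min_image_dist2(xs3[a], ys3[a], zs3[a], xs3[b], ys3[b], zs3[b], L)
            if d2 < rcut2:
                e += pair_table_energy(math.sqrt(d2), sp3[a] + sp3[b], utab, inv_dr)
    return e


@njit(cache=True)
def _nearest_two_h(pos, species, n, L, io):
    d1 = 1e300
    d2 = 1e300
    i1 = -1
    i2 = -1
    for j in range(n):
        if species[j] != 1:
            continue
        d = min_image_dist2(pos[io, 0], pos[io, 1], pos[io, 2],
                            pos[j, 0], pos[j, 1], pos[j, 2], L)
        if d < d1:
            d2, i2 = d1, i1
            d1, i1 = d, j
        elif d < d2:
            d2, i2 = d, j
    return i1, i2


@njit(cache=True)
def _remove_site(pos, species, qs, n, idx):
    last = n - 1
    if idx != last:
        pos[idx, 0] = pos[last, 0]
        pos[idx, 1] = pos[last, 1]
        pos[idx, 2] = pos[last, 2]
        species[idx] = species[last]
        qs[idx] = qs[last]
    return last


@njit(cache=True)
def run_gcmc_chunk(pos, species, qs, n, L, beta, max_disp, B,
                   utab, inv_dr, rcut2, kn, Ak, Sk, kmax,
                   q_O, q_H, dself_mol, ideal_gas,
                   r_oh_lo, r_oh_hi, r_hh_lo, r_hh_hi, max_retry,
                   n_pairs, U, counters):
    """Alternate one displacement attempt with one insert-or-delete attempt.

    ``counters`` accumulates [disp_att, disp_acc, ins_att, ins_acc,
    del_att, del_acc, geom_fail].  Returns (n, U).
    """
    m = 2 * kmax + 1
    pxo = np.empty(m, dtype=np.complex128)
    pyo = np.empty(m, dtype=np.complex128)
    pzo = np.empty(m, dtype=np.complex128)
    pxn = np.empty(m, dtype=np.complex128)
    pyn = np.empty(m, dtype=np.complex128)
    pzn = np.empty(m, dtype=np.complex128)
    dS = np.empty(Sk.shape[0], dtype=np.complex128)
    xs3 = np.empty(3)
    ys3 = np.empty(3)
    zs3 = np.empty(3)
    sp3 = np.empty(3, dtype=np.int8)
    sp3[0] = 0
    sp3[1] = 1
    sp3[2] = 1
    qs3 = np.empty(3)
    qs3[0] = q_O
    qs3[1] = q_H
    qs3[2] = q_H
    for _ in range(n_pairs):
        # --- displacement attempt -------------------------------------
        counters[0] += 1
        if n > 0:
            i = int(np.random.random() * n)
            if i >= n:
                i = n - 1
            xo, yo, zo = pos[i, 0], pos[i, 1], pos[i, 2]
            xn = _wrap(xo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
            yn = _wrap(yo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
            zn = _wrap(zo + (np.random.random() - 0.5) * 2.0 * max_disp, L)
            if ideal_gas:
                pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
                counters[1] += 1
            else:
                s_i = species[i]
                e_old = site_sr_energy(pos, species, n, L, xo, yo, zo, s_i,
                                       utab, inv_dr, rcut2, i, -1, -1)
                e_new = site_sr_energy(pos, species, n, L, xn, yn, zn, s_i,
                                       utab, inv_dr, rcut2, i, -1, -1)
                dE_sr = e_new - e_old
                if beta * dE_sr <= _HARD_REJECT:
                    dE_rec = recip_delta_move(kn, Ak, Sk, kmax, qs[i],
                                              xo, yo, zo, xn, yn, zn, L,
                                              pxo, pyo, pzo, pxn, pyn, pzn, dS)
                    dU = dE_sr + dE_rec
                    if dU <= 0.0:
                        acc = True
                    else:
                        arg = beta * dU
                        acc = arg <= 700.0 and np.random.random() < math.exp(-arg)
                    if acc:
                        pos[i, 0], pos[i, 1], pos[i, 2] = xn, yn, zn
                        for k in range(Sk.shape[0]):
                            Sk[k] += dS[k]
                        U += dU
                        counters[1] += 1
        # --- grand-canonical attempt ----------------------------------
        n_O = n // 3
        n_H = 2 * n_O
        if np.random.random() < 0.5:
            # insertion
            counters[2] += 1
            if n + 3 > pos.shape[0]:
                continue
            ok = sample_insertion_triplet(L, r_oh_lo, r_oh_hi, r_hh_lo, r_hh_hi,
                                          max_retry, xs3, ys3, zs3)
            if not ok:
                counters[6] += 1
                continue
            if ideal_gas:
                dU = 0.0
                for k in range(dS.shape[0]):
                    dS[k] = 0.0 + 0.0j
            else:
                dE_sr = _triplet_sr_energy(pos, species, n, L, xs3, ys3, zs3,
                                           sp3, utab, inv_dr, rcut2, -1, -1, -1)
                if beta * dE_sr > _HARD_REJECT:
                    continue
                dE_rec = recip_delta_triplet(kn, Ak, Sk, kmax, qs3, xs3, ys3,
                                             zs3, L, 1.0, pxo, pyo, pzo, dS)
                dU = dE_sr + dE_rec + dself_mol
            ln_y = (B - beta * dU
                    - math.log((n_O + 1.0) * (n_H + 1.0) * (n_H + 2.0)))
            u = np.random.random()
            if ln_y >= 0.0 or (u > 0.0 and math.log(u) < ln_y):
                for s in range(3):
                    pos[n + s, 0] = xs3[s]
                    pos[n + s, 1] = ys3[s]
                    pos[n + s, 2] = zs3[s]
                    species[n + s] = sp3[s]
                    qs[n + s] = qs3[s]
                n += 3
                if not ideal_gas:
                    for k in range(Sk.shape[0]):
                        Sk[k] += dS[k]
                U += dU
                counters[3] += 1
        else:
            # deletion
            counters[4] += 1
            if n_O == 0:
                continue
            ko = int(np.random.random() * n_O)
            if ko >= n_O:
                ko = n_O - 1
            io = -1
            seen = -1
            for j in range(n):
                if species[j] == 0:
                    seen += 1
                    if seen == ko:
                        io = j
                        break
            ih1, ih2 = _nearest_two_h(pos, species, n, L, io)
            xs3[0], ys3[0], zs3[0] = pos[io, 0], pos[io, 1], pos[io, 2]
            xs3[1], ys3[1], zs3[1] = pos[ih1, 0], pos[ih1, 1], pos[ih1, 2]
            xs3[2], ys3[2], zs3[2] = pos[ih2, 0], pos[ih2, 1], pos[ih2, 2]
            if ideal_gas:
                dU = 0.0
            else:
                e_trip = _triplet_sr_energy(pos, species, n, L, xs3, ys3, zs3,
                                            sp3, utab, inv_dr, rcut2,
                                            io, ih1, ih2)
                dE_rec = recip_delta_triplet(kn, Ak, Sk, kmax, qs3, xs3, ys3,
                                             zs3, L, -1.0, pxo, pyo, pzo, dS)
                dU = -e_trip + dE_rec - dself_mol
            ln_acc = (-B - beta * dU
                      + math.log(n_O * (n_H - 1.0) * float(n_H)))
            u = np.random.random()
            if ln_acc >= 0.0 or (u > 0.0 and math.log(u) < ln_acc):
                if not ideal_gas:
                    for k in range(Sk.shape[0]):
                        Sk[k] += dS[k]
                # remove highest indices first so lower ones stay valid
                i_a, i_b, i_c = io, ih1, ih2
                if i_a < i_b:
                    i_a, i_b = i_b, i_a
                if i_b < i_c:
                    i_b, i_c = i_c, i_b
                if i_a < i_b:
                    i_a, i_b = i_b, i_a
                n = _remove_site(pos, species, qs, n, i_a)
                n = _remove_site(pos, species, qs, n, i_b)
                n = _remove_site(pos, species, qs, n, i_c)
                U += dU
                counters[5] += 1
    return n, U


# --------------------------------------------------------------------------
# analysis kernels
# --------------------------------------------------------------------------


@njit(cache=True)
def rdf_counts(frames, species, L, sA, sB, nbins, bin_width):
    """Unordered pair-distance histogram restricted to one species pair."""
    counts = np.zeros(nbins)
    nf, n = frames.shape[0], frames.shape[1]
    for f in range(nf):
        for i in range(n):
            si = species[i]
            for j in range(i + 1, n):
                sj = species[j]
                if (si == sA and sj == sB) or (si == sB and sj == sA):
                    d2 = min_image_dist2(frames[f, i, 0], frames[f, i, 1],
                                         frames[f, i, 2], frames[f, j, 0],
                                         frames[f, j, 1], frames[f, j, 2], L)
                    b = int(math.sqrt(d2) / bin_width)
                    if b < nbins:
                        counts[b] += 1.0
    return counts


@njit(cache=True)
def greedy_assignment(pos, species, n, L):
    """Assign each O its hydrogens greedily by ascending O-H distance.

    Returns (o_idx, h_idx) where o_idx[m] is the oxygen site of molecule m
    and h_idx[m, 0:2] its two hydrogens.
    """
    n_O = 0
    for i in range(n):
        if species[i] == 0:
            n_O += 1
    n_H = n - n_O
    o_sites = np.empty(n_O, dtype=np.int64)
    h_sites = np.empty(n_H, dtype=np.int64)
    a = 0
    b = 0
    for i in range(n):
        if species[i] == 0:
            o_sites[a] = i
            a += 1
        else:
            h_sites[b] = i
            b += 1
    d = np.empty(n_O * n_H)
    for oi in range(n_O):
        i = o_sites[oi]
        for hj in range(n_H):
            j = h_sites[hj]
            d[oi * n_H + hj] = min_image_dist2(pos[i, 0], pos[i, 1], pos[i, 2],
                                               pos[j, 0], pos[j, 1], pos[j, 2], L)
    order = np.argsort(d)
    n_assigned_h = np.zeros(n_O, dtype=np.int64)
    h_taken = np.zeros(n_H, dtype=np.uint8)
    h_idx = np.full((n_O, 2), -1, dtype=np.int64)
    remaining = min(n_H, 2 * n_O)
    for t in range(order.shape[0]):
        if remaining == 0:
            break
        flat = order[t]
        oi = flat // n_H
        hj = flat % n_H
        if n_assigned_h[oi] < 2 and h_taken[hj] == 0:
            h_idx[oi, n_assigned_h[oi]] = h_sites[hj]
            n_assigned_h[oi] += 1
            h_taken[hj] = 1
            remaining -= 1
    return o_sites, h_idx


@njit(cache=True)
def molecule_geometry(pos, L, o_idx, h_idx):
    """Per-molecule (l_OH1, l_OH2, l_HH, theta_deg) from an assignment."""
    n_mol = o_idx.shape[0]
    out = np.empty((n_mol, 4))
    for m in range(n_mol):
        io = o_idx[m]
        i1 = h_idx[m, 0]
        i2 = h_idx[m, 1]
        l1 = math.sqrt(min_image_dist2(pos[io, 0], pos[io, 1], pos[io, 2],
                                       pos[i1, 0], pos[i1, 1], pos[i1, 2], L))
        l2 = math.sqrt(min_image_dist2(pos[io, 0], pos[io, 1], pos[io, 2],
                                       pos[i2, 0], pos[i2, 1], pos[i2, 2], L))
        lhh = math.sqrt(min_image_dist2(pos[i1, 0], pos[i1, 1], pos[i1, 2],
                                        pos[i2, 0], pos[i2, 1], pos[i2, 2], L))
        c = (l1 * l1 + l2 * l2 - lhh * lhh) / (2.0 * l1 * l2)
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        out[m, 0] = l1
        out[m, 1] = l2
        out[m, 2] = lhh
        out[m, 3] = math.degrees(math.acos(c))
    return out


@njit(cache=True)
def molecule_pair_energies(pos, L, o_idx, h_idx):
    """9-term site-site CF1 energies (kJ/mol, direct Coulomb) per molecule pair."""
    n_mol = o_idx.shape[0]
    n_pair = n_mol * (n_mol - 1) // 2
    out = np.empty(n_pair)
    sites = np.empty((n_mol, 3), dtype=np.int64)
    for m in range(n_mol):
        sites[m, 0] = o_idx[m]
        sites[m, 1] = h_idx[m, 0]
        sites[m, 2] = h_idx[m, 1]
    sp = np.empty(3, dtype=np.int64)
    sp[0] = 0
    sp[1] = 1
    sp[2] = 1
    t = 0
    for a in range(n_mol):
        for b in range(a + 1, n_mol):
            e = 0.0
            for u in range(3):
                iu = sites[a, u]
                for v in range(3):
                    iv = sites[b, v]
                    r = math.sqrt(min_image_dist2(
                        pos[iu, 0], pos[iu, 1], pos[iu, 2],
                        pos[iv, 0], pos[iv, 1], pos[iv, 2], L))
                    e += pair_energy_kj(sp[u], sp[v], r)
            out[t] = e
            t += 1
    return out


@njit(cache=True)
def hbond_distance_pairs(pos, L, o_idx, h_idx, r_cut):
    """Number of intermolecular O...H contacts within r_cut (unordered)."""
    n_mol = o_idx.shape[0]
    rc2 = r_cut * r_cut
    count = 0
    for a in range(n_mol):
        io = o_idx[a]
        for b in range(n_mol):
            if b == a:
                continue
            for v in range(2):
                ih = h_idx[b, v]
                d2 = min_image_dist2(pos[io, 0], pos[io, 1], pos[io, 2],
                                     pos[ih, 0], pos[ih, 1], pos[ih, 2], L)
                if d2 <= rc2:
                    count += 1
    return count


@njit(cache=True)
def tetrahedral_q_values(pos_o, L):
    """Per-oxygen tetrahedral order parameter from the 4 nearest oxygens."""
    n = pos_o.shape[0]
    qv = np.empty(n)
    nb = np.empty(4, dtype=np.int64)
    nd = np.empty(4)
    for i in range(n):
        for t in range(4):
            nd[t] = 1e300
            nb[t] = -1
        for j in range(n):
            if j == i:
                continue
            d2 = min_image_dist2(pos_o[i, 0], pos_o[i, 1], pos_o[i, 2],
                                 pos_o[j, 0], pos_o[j, 1], pos_o[j, 2], L)
            # insertion into the running 4 smallest
            if d2 < nd[3]:
                t = 3
                while t > 0 and d2 < nd[t - 1]:
                    nd[t] = nd[t - 1]
                    nb[t] = nb[t - 1]
                    t -= 1
                nd[t] = d2
                nb[t] = j
        # min-image displacement vectors to the 4 neighbours
        vx = np.empty(4)
        vy = np.empty(4)
        vz = np.empty(4)
        for t in range(4):
            j = nb[t]
            vx[t] = _mi(pos_o[j, 0] - pos_o[i, 0], L)
            vy[t] = _mi(pos_o[j, 1] - pos_o[i, 1], L)
            vz[t] = _mi(pos_o[j, 2] - pos_o[i, 2], L)
        s = 0.0
        for a in range(3):
            for b in range(a + 1, 4):
                na = math.sqrt(vx[a] ** 2 + vy[a] ** 2 + vz[a] ** 2)
                nbm = math.sqrt(vx[b] ** 2 + vy[b] ** 2 + vz[b] ** 2)
                c = (vx[a] * vx[b] + vy[a] * vy[b] + vz[a] * vz[b]) / (na * nbm)
                s += (c + 1.0 / 3.0) ** 2
        qv[i] = 1.0 - 0.375 * s
    return qv
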