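"""Numba kernels for the kinetic-segregation Monte-Carlo simulator.

All lengths in nm, energies in kT.  The membrane height field lives on a
square grid with clamped edges; molecules carry continuous coordinates with
periodic wrapping.  One call advances the state by ``n_sweeps`` Metropolis
sweeps; the Python wrapper in :mod:`tcrmeta.ks_sim` handles sampling,
validation and storage.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _wall_energy(zv, h_c, u_rep, u_adh, adh_w):
    # one-sided harmonic steric wall below the CD45 ectodomain height,
    # with a shallow Gaussian adhesion well at the ectodomain height
    e = 0.0
    if zv < h_c:
        d = h_c - zv
        e += u_rep * d * d
    d = (zv - h_c) / adh_w
    e -= u_adh * np.exp(-0.5 * d * d)
    return e


@njit(cache=True, inline="always")
def _node_of(x, a, n):
    i = int(x / a)
    if i >= n:
        i = n - 1
    if i < 0:
        i = 0
    return i


@njit(cache=True, inline="always")
def _min_image(dx, L):
    if dx > 0.5 * L:
        dx -= L
    elif dx < -0.5 * L:
        dx += L
    return dx


@njit(cache=True)
def _local_bend(z, i, j, n, zval):
    """Sum of squared Laplacians over the stencils touched by node (i, j),
    evaluating node (i, j) at height ``zval``."""
    s = 0.0
    for di in range(-1, 2):
        for dj in range(-1, 2):
            if abs(di) + abs(dj) > 1:
                continue
            ii = i + di
            jj = j + dj
            if ii < 1 or ii > n - 2 or jj < 1 or jj > n - 2:
                continue
            lap = -4.0 * (zval if (ii == i and jj == j) else z[ii, jj])
            for k in range(4):
                ni = ii + (1 if k == 0 else (-1 if k == 1 else 0))
                nj = jj + (1 if k == 2 else (-1 if k == 3 else 0))
                lap += zval if (ni == i and nj == j) else z[ni, nj]
            s += lap * lap
    return s


@njit(cache=True)
def total_energy(
    z, nb_bound, nb_free, nb_cd45, R, a, h_t, h_c, u_rep, u_adh, adh_w, k_bond, k_free
):
    n = z.shape[0]
    coef = R / (2.0 * a * a)
    e = 0.0
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            lap = z[i + 1, j] + z[i - 1, j] + z[i, j + 1] + z[i, j - 1] - 4.0 * z[i, j]
            e += coef * lap * lap
    for i in range(n):
        for j in range(n):
            zv = z[i, j]
            if nb_bound[i, j] > 0:
                e += nb_bound[i, j] * k_bond * (zv - h_t) ** 2
            if nb_free[i, j] > 0:
                e += nb_free[i, j] * k_free * (zv - h_t) ** 2
            if nb_cd45[i, j] > 0:
                e += nb_cd45[i, j] * _wall_energy(zv, h_c, u_rep, u_adh, adh_w)
    return e


@njit(cache=True)
def run_sweeps(
    z,
    mol_x,
    mol_y,
    n_tcr,
    bond_partner,
    refract,
    pmhc_x,
    pmhc_y,
    pmhc_taken,
    nb_bound,
    nb_free,
    nb_cd45,
    n_sweeps,
    freeze_height,
    suspend_unbind,
    clamp_mask,
    clamp_k,
    clamp_h,
    # parameters
    L,
    a,
    R,
    h_t,
    h_c,
    u_rep,
    u_adh,
    adh_w,
    k_bond,
    k_free,
    u_assoc,
    nu_dt,
    cap_r,
    bind_tol,
    bind_p,
    refract_sweeps,
    sigma_step,
    dz_step,
    z_max,
    press,
    seed,
):
    """Advance the state by ``n_sweeps`` sweeps in place.

    Each sweep updates (a) every interior height node, (b) every mobile
    molecule, (c) every TCR's bond state.  Returns the number of accepted
    height moves and molecule moves (for acceptance-rate logging).
    """
    np.random.seed(seed)
    n = z.shape[0]
    n_mol = mol_x.shape[0]
    n_pmhc = pmhc_x.shape[0]
    coef = R / (2.0 * a * a)
    cap_r2 = cap_r * cap_r
    acc_h = 0
    acc_m = 0

    for _ in range(n_sweeps):
        # --- height-field moves -------------------------------------
        if not freeze_height:
            for i in range(1, n - 1):
                for j in range(1, n - 1):
                    zv = z[i, j]
                    zp = zv + dz_step * (2.0 * np.random.random() - 1.0)
                    if zp < 0.0 or zp > z_max:
                        continue
                    dE = 0.0
                    if R > 0.0:
                        dE += coef * (
                            _local_bend(z, i, j, n, zp) - _local_bend(z, i, j, n, zv)
                        )
                    nb = nb_bound[i, j]
                    if nb > 0:
                        dE += nb * k_bond * ((zp - h_t) ** 2 - (zv - h_t) ** 2)
                    nf = nb_free[i, j]
                    if nf > 0:
                        dE += nf * k_free * ((zp - h_t) ** 2 - (zv - h_t) ** 2)
                    nc = nb_cd45[i, j]
                    if nc > 0:
                        dE += nc * (
                            _wall_energy(zp, h_c, u_rep, u_adh, adh_w)
                            - _wall_energy(zv, h_c, u_rep, u_adh, adh_w)
                        )
                    if press > 0.0:
                        # glycocalyx separation pressure below the CD45
                        # resting height: pushes unsqueezed membrane apart
                        pe0 = press * (h_c - zv) if zv < h_c else 0.0
                        pe1 = press * (h_c - zp) if zp < h_c else 0.0
                        dE += pe1 - pe0
                    if clamp_k > 0.0 and clamp_mask[i, j] == 1:
                        dE += clamp_k * (
                            (zp - clamp_h) ** 2 - (zv - clamp_h) ** 2
                        )
                    if dE <= 0.0 or np.random.random() < np.exp(-dE):
                        z[i, j] = zp
                        acc_h += 1

        # --- lateral molecule moves ---------------------------------
        for m in range(n_mol):
            x0 = mol_x[m]
            y0 = mol_y[m]
            x1 = (x0 + sigma_step * np.random.normal()) % L
            y1 = (y0 + sigma_step * np.random.normal()) % L
            is_tcr = m < n_tcr
            bound = is_tcr and bond_partner[m] >= 0
            if bound:
                p = bond_partner[m]
                dx = _min_image(x1 - pmhc_x[p], L)
                dy = _min_image(y1 - pmhc_y[p], L)
                if dx * dx + dy * dy > cap_r2:
                    continue  # bond constrains lateral motion
            i0 = _node_of(x0, a, n)
            j0 = _node_of(y0, a, n)
            i1 = _node_of(x1, a, n)
            j1 = _node_of(y1, a, n)
            dE = 0.0
            if i0 != i1 or j0 != j1:
                z0 = z[i0, j0]
                z1 = z[i1, j1]
                if is_tcr:
                    k = k_bond if bound else k_free
                    dE = k * ((z1 - h_t) ** 2 - (z0 - h_t) ** 2)
                else:
                    dE = _wall_energy(z1, h_c, u_rep, u_adh, adh_w) - _wall_energy(
                        z0, h_c, u_rep, u_adh, adh_w
                    )
            if dE <= 0.0 or np.random.random() < np.exp(-dE):
                mol_x[m] = x1
                mol_y[m] = y1
                acc_m += 1
                if i0 != i1 or j0 != j1:
                    if is_tcr:
                        if bound:
                            nb_bound[i0, j0] -= 1
                            nb_bound[i1, j1] += 1
                        else:
                            nb_free[i0, j0] -= 1
                            nb_free[i1, j1] += 1
                    else:
                        nb_cd45[i0, j0] -= 1
                        nb_cd45[i1, j1] += 1

        # --- TCR-pMHC bond toggling ---------------------------------
        for t in range(n_tcr):
            i = _node_of(mol_x[t], a, n)
            j = _node_of(mol_y[t], a, n)
            zv = z[i, j]
            if bond_partner[t] >= 0:
                if suspend_unbind:
                    continue
                # Kramers-type dissociation: barrier U_assoc lowered by the
                # elastic energy stored in the stretched bond spring
                e_spring = k_bond * (zv - h_t) ** 2
                arg = -u_assoc + e_spring
                p_un = nu_dt * (np.exp(arg) if arg < 0.0 else 1.0)
                if p_un > 1.0:
                    p_un = 1.0
                if np.random.random() < p_un:
                    pmhc_taken[bond_partner[t]] = 0
                    bond_partner[t] = -1
                    nb_bound[i, j] -= 1
                    nb_free[i, j] += 1
                    # ruptured complexes need diffusional escape and
                    # conformational recovery before re-engagement
                    refract[t] = refract_sweeps
            else:
                if refract[t] > 0:
                    refract[t] -= 1
                    continue
                if abs(zv - h_t) <= bind_tol and u_assoc > 0.0:
                    if bind_p >= 1.0 or np.random.random() < bind_p:
                        best = -1
                        best_d2 = cap_r2
                        for p in range(n_pmhc):
                            if pmhc_taken[p] == 1:
                                continue
                            dx = _min_image(mol_x[t] - pmhc_x[p], L)
                            if dx * dx > cap_r2:
                                continue
                            dy = _min_image(mol_y[t] - pmhc_y[p], L)
                            d2 = dx * dx + dy * dy
                            if d2 <= best_d2:
                                best_d2 = d2
                                best = p
                        if best >= 0:
                            pmhc_taken[best] = 1
                            bond_partner[t] = best
                            nb_free[i, j] -= 1
                            nb_bound[i, j] += 1

    return acc_h, acc_m
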