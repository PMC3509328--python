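"""Compiled inner loop of the Monte Carlo engine.

Implements exactly the same stochastic process as the pure-numpy
:meth:`cfcsim.engine.Ensemble.step` (two drawings per step, thinning with
per-pool probability bounds, windowed Gaussian conditioning for chain
state), with incremental pool bookkeeping so a step costs O(events) rather
than O(sites).  Random streams differ between the two backends (numba uses
its own global generator), but each is deterministic for a given seed.

All angles here are radians; pool ids: 0 free, 1 weak, 2 strong for myosin
site pools and 0 bound / 1 unbound for TnI pools.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is an optional speedup
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def deco(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return deco


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _pool_remove(lst, pos, sz, pid, idx):
    p = pos[idx]
    last = lst[pid, sz[pid] - 1]
    lst[pid, p] = last
    pos[last] = p
    sz[pid] -= 1


@njit(cache=True, inline="always")
def _pool_add(lst, pos, sz, pid, idx):
    lst[pid, sz[pid]] = idx
    pos[idx] = sz[pid]
    sz[pid] += 1


@njit(cache=True)
def _draw_distinct(lst, sz, pid, k, out, mark, stamp):
    """k distinct members of pool pid into out[:k]; returns count drawn.

    Uniform over k-subsets (rejection on duplicates via a stamp array).
    """
    n = sz[pid]
    if k >= n:
        for j in range(n):
            out[j] = lst[pid, j]
        return n
    stamp[0] += 1
    s0 = stamp[0]
    drawn = 0
    while drawn < k:
        idx = lst[pid, int(np.random.random() * n)]
        if mark[idx] != s0:
            mark[idx] = s0
            out[drawn] = idx
            drawn += 1
    return drawn


@njit(cache=True)
def _chain_eval(G, sigma_site, pin_code, s, i, phi_minus, phi_plus,
                window, nk, p_buf, a_buf, A, L, y, xa, xg):
    """Conditional mean and SD (radians) of the chain angle at site i.

    Conditions the free-chain Gaussian (site covariance G) on the nearest
    <= nk pin values on each side within ``window`` monomers.
    """
    code_i = pin_code[s, i]
    if code_i == 1:
        return phi_minus, 0.0
    if code_i == 2:
        return phi_plus, 0.0
    n_sites = pin_code.shape[1]
    m = 0
    cnt = 0
    for d in range(1, window + 1):
        j = i - d
        if j < 0:
            break
        c = pin_code[s, j]
        if c != 0:
            p_buf[m] = j
            a_buf[m] = phi_minus if c == 1 else phi_plus
            m += 1
            cnt += 1
            if cnt == nk:
                break
    cnt = 0
    for d in range(1, window + 1):
        j = i + d
        if j >= n_sites:
            break
        c = pin_code[s, j]
        if c != 0:
            p_buf[m] = j
            a_buf[m] = phi_minus if c == 1 else phi_plus
            m += 1
            cnt += 1
            if cnt == nk:
                break
    if m == 0:
        return 0.0, sigma_site[i]
    # local covariance and cross-covariance
    for r in range(m):
        pr = p_buf[r]
        for c2 in range(r + 1):
            A[r, c2] = G[pr, p_buf[c2]]
        A[r, r] += 1e-12
        xg[r] = G[i, pr]       # reuse xg as gsp before solving
    # Cholesky A = L L^T (lower), in place into L
    for c2 in range(m):
        acc = A[c2, c2]
        for k in range(c2):
            acc -= L[c2, k] * L[c2, k]
        L[c2, c2] = math.sqrt(acc)
        for r in range(c2 + 1, m):
            acc = A[r, c2]
            for k in range(c2):
                acc -= L[r, k] * L[c2, k]
            L[r, c2] = acc / L[c2, c2]
    # solve for rhs a (-> xa) and gsp (-> xg), forward then back
    for r in range(m):
        acc_a = a_buf[r]
        acc_g = xg[r]
        for k in range(r):
            acc_a -= L[r, k] * y[k]
            acc_g -= L[r, k] * y[m + k]
        y[r] = acc_a / L[r, r]
        y[m + r] = acc_g / L[r, r]
    for r in range(m - 1, -1, -1):
        acc_a = y[r]
        acc_g = y[m + r]
        for k in range(r + 1, m):
            acc_a -= L[k, r] * xa[k]
            acc_g -= L[k, r] * xg[k]     # xg[k>r] already back-substituted
        xa[r] = acc_a / L[r, r]
        xg[r] = acc_g / L[r, r]
    phi = 0.0
    var = G[i, i]
    for r in range(m):
        gsp = G[i, p_buf[r]]
        phi += gsp * xa[r]
        var -= gsp * xg[r]
    if var < 0.0:
        var = 0.0
    return phi, math.sqrt(var)


@njit(cache=True)
def step_chunk(n_steps, site_state, tni_bound, pin_code, tni_cols,
               m_list, m_pos, m_sz, t_list, t_pos, t_sz,
               G, sigma_site, window, nk,
               phi_minus, phi_plus, phi_o, r_I_o, r_M2_o,
               k_on2, k_off_weak, k_iso_fwd, k_iso_rev, k_tni_on, k_tni_off,
               dt, A_tot, M_tot, myosin_active, couple_chain,
               ev_buf, mark_m, mark_t, stamp,
               scratch_f, scratch_af, scratch_A, scratch_L,
               scratch_y, scratch_xa, scratch_xg):
    """Advance the ensemble by n_steps Monte Carlo steps in place.

    m_list/m_pos/m_sz: myosin pools (free/weak/strong) over flat site index
    s*N+i; t_list/t_pos/t_sz: TnI pools (bound/unbound) over flat s*I+t.
    ev_buf is an int64 scratch of shape (6, cap) for per-step event lists.
    """
    S, N = site_state.shape
    I = tni_cols.size
    n_A = S * N
    sqrt2 = math.sqrt(2.0)

    for _ in range(n_steps):
        n_weak = m_sz[1]
        n_strong = m_sz[2]
        f = (n_weak + n_strong) / n_A
        if myosin_active:
            M_free = M_tot - f * A_tot
            if M_free < 0.0:
                M_free = 0.0
        else:
            M_free = 0.0
        delta = 1.0 - 0.82 * f

        # --- draw 1: TnI detach candidates (all fire) -------------------
        n_det = 0
        if k_tni_off > 0.0 and t_sz[0] > 0:
            p = k_tni_off * dt
            if p > 1.0:
                p = 1.0
            k = np.random.binomial(t_sz[0], p)
            if k > 0:
                n_det = _draw_distinct(t_list, t_sz, 0, k, ev_buf[0], mark_t, stamp)

        # --- draw 1: TnI rebind candidates -> accept with r_I -----------
        n_reb = 0
        if k_tni_on > 0.0 and t_sz[1] > 0:
            p_max = k_tni_on / r_I_o * dt
            if p_max > 1.0:
                p_max = 1.0
            k = np.random.binomial(t_sz[1], p_max)
            if k > 0:
                kc = _draw_distinct(t_list, t_sz, 1, k, ev_buf[5], mark_t, stamp)
                for j in range(kc):
                    ft = ev_buf[5, j]
                    s = ft // I
                    site = tni_cols[ft % I]
                    if site_state[s, site] != 0:
                        continue
                    phi, sig = _chain_eval(G, sigma_site, pin_code, s, site,
                                           phi_minus, phi_plus, window, nk,
                                           scratch_f, scratch_af, scratch_A,
                                           scratch_L, scratch_y, scratch_xa,
                                           scratch_xg)
                    if sig > 0.0:
                        r_I = 0.5 * math.erfc((phi - phi_minus) / (sqrt2 * sig))
                    else:
                        r_I = 1.0 if phi < phi_minus else (0.5 if phi == phi_minus else 0.0)
                    if np.random.random() < r_I:
                        ev_buf[1, n_reb] = ft
                        n_reb += 1

        # --- draw 2: weak binding candidates -> accept with r_M1 --------
        n_bind = 0
        if M_free > 0.0 and m_sz[0] > 0:
            p_max = 2.0 * delta * k_on2 * M_free * dt
            if p_max > 1.0:
                p_max = 1.0
            if p_max > 0.0:
                k = np.random.binomial(m_sz[0], p_max)
                if k > 0:
                    kc = _draw_distinct(m_list, m_sz, 0, k, ev_buf[5], mark_m, stamp)
                    for j in range(kc):
                        fs = ev_buf[5, j]
                        s = fs // N
                        site = fs % N
                        phi, sig = _chain_eval(G, sigma_site, pin_code, s, site,
                                               phi_minus, phi_plus, window, nk,
                                               scratch_f, scratch_af, scratch_A,
                                               scratch_L, scratch_y, scratch_xa,
                                               scratch_xg)
                        if sig > 0.0:
                            r_M1 = 0.5 * math.erfc((phi_o - phi) / (sqrt2 * sig))
                        else:
                            r_M1 = 1.0 if phi > phi_o else (0.5 if phi == phi_o else 0.0)
                        if np.random.random() < r_M1:
                            ev_buf[2, n_bind] = fs
                            n_bind += 1

        # --- draw 2: weak-site pool (detach or isomerise) ---------------
        n_wdet = 0
        n_iso = 0
        if m_sz[1] > 0:
            p_det = k_off_weak * dt
            p_pool = p_det + k_iso_fwd / r_M2_o * dt
            if p_pool > 1.0:
                p_pool = 1.0
            if p_pool > 0.0:
                k = np.random.binomial(m_sz[1], p_pool)
                if k > 0:
                    kc = _draw_distinct(m_list, m_sz, 1, k, ev_buf[5], mark_m, stamp)
                    for j in range(kc):
                        fs = ev_buf[5, j]
                        u = np.random.random() * p_pool
                        if u < p_det:
                            ev_buf[3, n_wdet] = fs
                            n_wdet += 1
                            continue
                        s = fs // N
                        site = fs % N
                        phi, sig = _chain_eval(G, sigma_site, pin_code, s, site,
                                               phi_minus, phi_plus, window, nk,
                                               scratch_f, scratch_af, scratch_A,
                                               scratch_L, scratch_y, scratch_xa,
                                               scratch_xg)
                        if sig > 0.0:
                            r_M2 = 0.5 * math.erfc((phi_plus - phi) / (sqrt2 * sig))
                        else:
                            r_M2 = 1.0 if phi > phi_plus else (0.5 if phi == phi_plus else 0.0)
                        if (u - p_det) < r_M2 / r_M2_o * k_iso_fwd * dt:
                            ev_buf[4, n_iso] = fs
                            n_iso += 1

        # --- draw 2: reverse isomerisation (all fire) -------------------
        n_rev = 0
        if k_iso_rev > 0.0 and m_sz[2] > 0:
            p = k_iso_rev * dt
            if p > 1.0:
                p = 1.0
            k = np.random.binomial(m_sz[2], p)
            if k > 0:
                n_rev = _draw_distinct(m_list, m_sz, 2, k, ev_buf[5], mark_m, stamp)

        # --- apply: TnI first, then myosin ------------------------------
        for j in range(n_det):
            ft = ev_buf[0, j]
            s = ft // I
            t = ft % I
            tni_bound[s, t] = False
            if couple_chain:
                pin_code[s, tni_cols[t]] = 0
            _pool_remove(t_list, t_pos, t_sz, 0, ft)
            _pool_add(t_list, t_pos, t_sz, 1, ft)
        for j in range(n_reb):
            ft = ev_buf[1, j]
            s = ft // I
            t = ft % I
            tni_bound[s, t] = True
            if couple_chain:
                pin_code[s, tni_cols[t]] = 1
            _pool_remove(t_list, t_pos, t_sz, 1, ft)
            _pool_add(t_list, t_pos, t_sz, 0, ft)
        for j in range(n_wdet):
            fs = ev_buf[3, j]
            site_state[fs // N, fs % N] = 0
            _pool_remove(m_list, m_pos, m_sz, 1, fs)
            _pool_add(m_list, m_pos, m_sz, 0, fs)
        for j in range(n_rev):
            fs = ev_buf[5, j]
            s = fs // N
            site = fs % N
            site_state[s, site] = 1
            if couple_chain:
                pin_code[s, site] = 0
            _pool_remove(m_list, m_pos, m_sz, 2, fs)
            _pool_add(m_list, m_pos, m_sz, 1, fs)
        for j in range(n_bind):
            fs = ev_buf[2, j]
            s = fs // N
            site = fs % N
            # a TnI that rebound this step blocks binding on its monomer
            if pin_code[s, site] == 1 or site_state[s, site] != 0:
                continue
            site_state[s, site] = 1
            _pool_remove(m_list, m_pos, m_sz, 0, fs)
            _pool_add(m_list, m_pos, m_sz, 1, fs)
        for j in range(n_iso):
            fs = ev_buf[4, j]
            s = fs // N
            site = fs % N
            if site_state[s, site] != 1:
                continue
            site_state[s, site] = 2
            if couple_chain:
                pin_code[s, site] = 2
            _pool_remove(m_list, m_pos, m_sz, 1, fs)
            _pool_add(m_list, m_pos, m_sz, 2, fs)
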