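"""Numba-compiled integration kernels.

These duplicate the gating laws of :mod:`slacksim.channels` in scalar
form for speed; the pure-numpy engine in :mod:`slacksim.neuron_models`
is the reference implementation and the test suite asserts that both
paths agree.  Channel order everywhere: nat, nap, kdr, leak, kcnt1.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def _vtrap(x: float, y: float) -> float:
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / (2.0 * y))
    return x / (np.expm1(x / y))


@njit(cache=True, fastmath=False)
def _gate_updates(v, na, m_nat, h_nat, n_kdr, m_nap, m_kc, dt, vt, m_shift,
                  h_scale, kc_ec50, kc_hill, kc_v50, kc_k, kc_decay):
    nsw, nc = v.shape
    for s in range(nsw):
        for c in range(nc):
            u = v[s, c] - vt
            # transient Na m (activation right-shifted by m_shift)
            um = u - m_shift
            am = 0.32 * _vtrap(13.0 - um, 4.0)
            bm = 0.28 * _vtrap(um - 40.0, 5.0)
            tau = 1.0 / (am + bm)
            minf = am * tau
            m_nat[s, c] = minf + (m_nat[s, c] - minf) * np.exp(-dt / tau)
            # transient Na h
            ah = h_scale * 0.128 * np.exp(-(u - 17.0) / 18.0)
            bh = h_scale * 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
            tau = 1.0 / (ah + bh)
            minf = ah * tau
            h_nat[s, c] = minf + (h_nat[s, c] - minf) * np.exp(-dt / tau)
            # delayed rectifier n
            an = 0.032 * _vtrap(15.0 - u, 5.0)
            bn = 0.5 * np.exp(-(u - 10.0) / 40.0)
            tau = 1.0 / (an + bn)
            minf = an * tau
            n_kdr[s, c] = minf + (n_kdr[s, c] - minf) * np.exp(-dt / tau)
            # persistent Na (Boltzmann, tau 1 ms)
            minf = 1.0 / (1.0 + np.exp(-(u - 3.0) / 5.0))
            m_nap[s, c] = minf + (m_nap[s, c] - minf) * np.exp(-dt)
            # KCNT1: Hill(Na) x Boltzmann(V), first-order with fixed tau
            x = na[s, c]
            xh = x**kc_hill
            fna = xh / (xh + kc_ec50**kc_hill)
            fv = 1.0 / (1.0 + np.exp(-(v[s, c] - kc_v50) / kc_k))
            minf = fna * fv
            m_kc[s, c] = minf + (m_kc[s, c] - minf) * kc_decay


@njit(cache=True, fastmath=False)
def iclamp_kernel(i_inj, dt, n_settle, cap, gax,
                  g_nat, g_nap, g_kdr, g_leak, g_kcnt1,
                  ena, ek, eleak,
                  vt, m_shift, h_scale, kc_ec50, kc_hill, kc_v50, kc_k, kc_tau,
                  na_clamped, na_clamp_val, na_rest, na_tau, na_factor,
                  v0):
    """Backward-Euler current clamp on the star-topology compartments.

    Returns (v_all, na_all, currents[5, nsw, nt], diverged flag).
    """
    nsw, nt = i_inj.shape
    nc = cap.shape[0]
    v = np.full((nsw, nc), v0)
    na0 = na_clamp_val if na_clamped else na_rest
    na = np.full((nsw, nc), na0)

    m_nat = np.zeros((nsw, nc))
    h_nat = np.zeros((nsw, nc))
    n_kdr = np.zeros((nsw, nc))
    m_nap = np.zeros((nsw, nc))
    m_kc = np.zeros((nsw, nc))
    kc_decay = np.exp(-dt / kc_tau)
    # initialize gates at steady state for v0 (large dt relaxation)
    _gate_updates(v, na, m_nat, h_nat, n_kdr, m_nap, m_kc, 1e9, vt, m_shift,
                  h_scale, kc_ec50, kc_hill, kc_v50, kc_k, 0.0)

    v_all = np.empty((nsw, nc, nt))
    na_all = np.empty((nsw, nc, nt))
    currents = np.zeros((5, nsw, nt))
    diverged = False

    gsum = 0.0
    for step in range(-n_settle, nt):
        _gate_updates(v, na, m_nat, h_nat, n_kdr, m_nap, m_kc, dt, vt, m_shift,
                      h_scale, kc_ec50, kc_hill, kc_v50, kc_k, kc_decay)
        for s in range(nsw):
            i_stim = i_inj[s, step] if step >= 0 else 0.0
            denom = 0.0
            rhs = 0.0
            a0 = 0.0
            b0 = 0.0
            a_child = np.empty(nc)
            b_child = np.empty(nc)
            for c in range(nc):
                gm = g_nat[c] * m_nat[s, c] ** 3 * h_nat[s, c]
                gp = g_nap[c] * m_nap[s, c]
                gk = g_kdr[c] * n_kdr[s, c] ** 4
                gl = g_leak[c]
                gc = g_kcnt1[c] * m_kc[s, c]
                gtot = gm + gp + gk + gl + gc
                gesum = (gm + gp) * ena + (gk + gc) * ek + gl * eleak
                a = cap[c] / dt + gtot
                b = cap[c] / dt * v[s, c] + gesum
                if c == 0:
                    for cc in range(1, nc):
                        a += gax[cc]
                    b += i_stim
                    a0 = a
                    b0 = b
                else:
                    a += gax[c]
                    a_child[c] = a
                    b_child[c] = b
            denom = a0
            rhs = b0
            for c in range(1, nc):
                denom -= gax[c] * gax[c] / a_child[c]
                rhs += gax[c] * b_child[c] / a_child[c]
            vs_new = rhs / denom
            v[s, 0] = vs_new
            for c in range(1, nc):
                v[s, c] = (b_child[c] + gax[c] * vs_new) / a_child[c]
            if abs(vs_new) > 200.0:
                diverged = True
            # Na shell update and current recording
            for c in range(nc):
                gm = g_nat[c] * m_nat[s, c] ** 3 * h_nat[s, c]
                gp = g_nap[c] * m_nap[s, c]
                i_nat = gm * (v[s, c] - ena)
                i_nap = gp * (v[s, c] - ena)
                if not na_clamped:
                    dna = -(i_nat + i_nap) * na_factor[c] - (na[s, c] - na_rest) / na_tau
                    na[s, c] += dt * dna
                    if na[s, c] < 0.0:
                        na[s, c] = 0.0
                if step >= 0:
                    currents[0, s, step] += i_nat
                    currents[1, s, step] += i_nap
                    currents[2, s, step] += g_kdr[c] * n_kdr[s, c] ** 4 * (v[s, c] - ek)
                    currents[3, s, step] += g_leak[c] * (v[s, c] - eleak)
                    currents[4, s, step] += g_kcnt1[c] * m_kc[s, c] * (v[s, c] - ek)
                    v_all[s, c, step] = v[s, c]
                    na_all[s, c, step] = na[s, c]
        if diverged:
            break
    return v_all, na_all, currents, diverged


@njit(cache=True, fastmath=False)
def vclamp_kernel(v_cmd, dt, n_settle, cap, gax,
                  g_nat, g_nap, g_kdr, g_leak, g_kcnt1,
                  ena, ek, eleak,
                  vt, m_shift, h_scale, kc_ec50, kc_hill, kc_v50, kc_k, kc_tau,
                  na_clamped, na_clamp_val, na_rest, na_tau, na_factor):
    """Ideal space clamp: every compartment follows the command voltage.

    Returns (na_all, currents[5, nsw, nt], i_clamp).
    """
    nsw, nt = v_cmd.shape
    nc = cap.shape[0]
    v = np.empty((nsw, nc))
    for s in range(nsw):
        for c in range(nc):
            v[s, c] = v_cmd[s, 0]
    na0 = na_clamp_val if na_clamped else na_rest
    na = np.full((nsw, nc), na0)
    m_nat = np.zeros((nsw, nc))
    h_nat = np.zeros((nsw, nc))
    n_kdr = np.zeros((nsw, nc))
    m_nap = np.zeros((nsw, nc))
    m_kc = np.zeros((nsw, nc))
    kc_decay = np.exp(-dt / kc_tau)
    _gate_updates(v, na, m_nat, h_nat, n_kdr, m_nap, m_kc, 1e9, vt, m_shift,
                  h_scale, kc_ec50, kc_hill, kc_v50, kc_k, 0.0)

    na_all = np.empty((nsw, nc, nt))
    currents = np.zeros((5, nsw, nt))
    i_clamp = np.zeros((nsw, nt))

    for step in range(-n_settle, nt):
        idx = step if step >= 0 else 0
        for s in range(nsw):
            for c in range(nc):
                v[s, c] = v_cmd[s, idx]
        _gate_updates(v, na, m_nat, h_nat, n_kdr, m_nap, m_kc, dt, vt, m_shift,
                      h_scale, kc_ec50, kc_hill, kc_v50, kc_k, kc_decay)
        for s in range(nsw):
            for c in range(nc):
                gm = g_nat[c] * m_nat[s, c] ** 3 * h_nat[s, c]
                gp = g_nap[c] * m_nap[s, c]
                i_nat = gm * (v[s, c] - ena)
                i_nap = gp * (v[s, c] - ena)
                if not na_clamped:
                    dna = -(i_nat + i_nap) * na_factor[c] - (na[s, c] - na_rest) / na_tau
                    na[s, c] += dt * dna
                    if na[s, c] < 0.0:
                        na[s, c] = 0.0
                if step >= 0:
                    i_kdr = g_kdr[c] * n_kdr[s, c] ** 4 * (v[s, c] - ek)
                    i_leak = g_leak[c] * (v[s, c] - eleak)
                    i_kc = g_kcnt1[c] * m_kc[s, c] * (v[s, c] - ek)
                    currents[0, s, step] += i_nat
                    currents[1, s, step] += i_nap
                    currents[2, s, step] += i_kdr
                    currents[3, s, step] += i_leak
                    currents[4, s, step] += i_kc
                    i_clamp[s, step] += i_nat + i_nap + i_kdr + i_leak + i_kc
                    na_all[s, c, step] = na[s, c]
    return na_all, currents, i_clamp
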