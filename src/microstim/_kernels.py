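"""Numba kernels for the double-cable backward-Euler integrator.

The discretized fiber has two potentials per compartment: intracellular
``a`` and periaxonal ``b`` (the space under the myelin sheath).  With the
extracellular potential ``e`` prescribed outside the myelin, each step of
the implicit first-order scheme solves one pentadiagonal linear system in
the interleaved vector ``[a0, b0, a1, b1, ...]``:

  membrane row:   Cm/dt·ΔVm + G_ion·Vm' − I_E = Σ ga·(a_nb − a)
  periaxonal row: Cmy/dt·ΔVmy + Gmy·Vmy' − Σ gp·(b_nb − b) = Im

where Vm = a − b, Vmy = b − e, and Im is the axolemmal membrane current.
Nodes of Ranvier carry the MRG nodal channels (fast Na⁺ m³h, persistent
Na⁺ p³, slow K⁺ s, linear leak); gates advance by an implicit Euler
substep evaluated at the pre-step membrane potential, mirroring the
staggered update of fixed-step compartmental solvers.

Only the 21 nodal conductances change between steps, and each enters the
matrix as a symmetric rank-one block G·uuᵀ with u = e_intra − e_peri at
that node.  The constant part A0 is LU-factored once, and each step solves
the exact implicit system with the Woodbury identity: one pentadiagonal
substitution plus a 21×21 capacitance-matrix solve.  This is algebraically
identical to refactoring the full matrix every step, at a fraction of the
cost.

Units: mV, ms, µS, nF, nA.
"""

import numpy as np
from numba import njit

# MRG nodal channel densities (S/cm²) and reversal potentials (mV)
GNABAR = 3.0
GNAPBAR = 0.01
GKBAR = 0.08
GL = 0.007
ENA = 50.0
EK = -90.0
EL = -90.0

_FM = {"contract", "reassoc", "arcp"}  # keep NaN/Inf semantics


@njit(cache=True, fastmath=_FM)
def _rates(v, q1, q2, q3):
    """MRG nodal gate rate constants (1/ms) at membrane potential v (mV)."""
    # fast Na activation
    x = v + 21.4
    if abs(x) < 1e-6:
        am = q1 * 1.86 * 10.3
    else:
        am = q1 * 1.86 * x / (1.0 - np.exp(-x / 10.3))
    x = v + 25.7
    if abs(x) < 1e-6:
        bm = q1 * 0.086 * 9.16
    else:
        bm = q1 * 0.086 * (-x) / (1.0 - np.exp(x / 9.16))
    # fast Na inactivation
    x = v + 114.0
    if abs(x) < 1e-6:
        ah = q2 * 0.062 * 11.0
    else:
        ah = q2 * 0.062 * (-x) / (1.0 - np.exp(x / 11.0))
    bh = q2 * 2.3 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    # persistent Na activation
    x = v + 27.0
    if abs(x) < 1e-6:
        ap = q1 * 0.01 * 10.2
    else:
        ap = q1 * 0.01 * x / (1.0 - np.exp(-x / 10.2))
    x = v + 34.0
    if abs(x) < 1e-6:
        bp = q1 * 0.00025 * 10.0
    else:
        bp = q1 * 0.00025 * (-x) / (1.0 - np.exp(x / 10.0))
    # slow K
    as_ = q3 * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    bs = q3 * 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return am, bm, ah, bh, ap, bp, as_, bs


@njit(cache=True)
def gate_steady_state(v, q1, q2, q3):
    am, bm, ah, bh, ap, bp, as_, bs = _rates(v, q1, q2, q3)
    return (am / (am + bm), ah / (ah + bh), ap / (ap + bp), as_ / (as_ + bs))


@njit(cache=True)
def factor_penta(d0, d1u, d2u, d1l, d2l):
    """LU-factor a pentadiagonal matrix (no pivoting; the cable matrix is
    diagonally dominant).  dku[i] = A[i, i+k], dkl[i] = A[i+k, i].
    Returns (inv_u0, u1, u2, l1, l2) with U's diagonal stored inverted."""
    n = d0.shape[0]
    u0 = d0.copy()
    u1 = d1u.copy()
    u2 = d2u.copy()
    a1l = d1l.copy()
    l1 = np.empty(n - 1)
    l2 = np.empty(n - 2)
    inv0 = np.empty(n)
    for i in range(n - 1):
        inv0[i] = 1.0 / u0[i]
        f1 = a1l[i] * inv0[i]
        l1[i] = f1
        u0[i + 1] -= f1 * u1[i]
        if i + 2 < n:
            u1[i + 1] -= f1 * u2[i]
            f2 = d2l[i] * inv0[i]
            l2[i] = f2
            a1l[i + 1] -= f2 * u1[i]
            u0[i + 2] -= f2 * u2[i]
    inv0[n - 1] = 1.0 / u0[n - 1]
    return inv0, u1, u2, l1, l2


@njit(cache=True, fastmath=_FM, inline="always")
def _substitute(inv0, u1, u2, l1, l2, rhs, y, x):
    n = rhs.shape[0]
    y[0] = rhs[0]
    y[1] = rhs[1] - l1[0] * y[0]
    for i in range(2, n):
        y[i] = rhs[i] - l1[i - 1] * y[i - 1] - l2[i - 2] * y[i - 2]
    x[n - 1] = y[n - 1] * inv0[n - 1]
    x[n - 2] = (y[n - 2] - u1[n - 2] * x[n - 1]) * inv0[n - 2]
    for i in range(n - 3, -1, -1):
        x[i] = (y[i] - u1[i] * x[i + 1] - u2[i] * x[i + 2]) * inv0[i]


@njit(cache=True, fastmath=_FM)
def woodbury_precompute(inv0, u1, u2, l1, l2, node_idx):
    """Z = A0⁻¹U and S0 = UᵀA0⁻¹U for the nodal update directions
    u_j = e(2k_j) − e(2k_j+1)."""
    n2 = inv0.shape[0]
    nn = node_idx.shape[0]
    Z = np.empty((n2, nn))
    rhs = np.zeros(n2)
    y = np.empty(n2)
    x = np.empty(n2)
    for j in range(nn):
        k = node_idx[j]
        rhs[2 * k] = 1.0
        rhs[2 * k + 1] = -1.0
        _substitute(inv0, u1, u2, l1, l2, rhs, y, x)
        for i in range(n2):
            Z[i, j] = x[i]
        rhs[2 * k] = 0.0
        rhs[2 * k + 1] = 0.0
    S0 = np.empty((nn, nn))
    for i in range(nn):
        k = node_idx[i]
        for j in range(nn):
            S0[i, j] = Z[2 * k, j] - Z[2 * k + 1, j]
    return Z, S0


@njit(cache=True, fastmath=_FM)
def run_cable(dt, n_steps, ve_profile, ve_schedule, ve_full, use_full,
              inv0, u1, u2, l1, l2, Z, S0,
              cm_dt, gpas, ipas, cmy_dt, gmy, node_idx,
              gna_us, gnap_us, gk_us, gl_us, q1, q2, q3,
              a, b, m, h, p, s, spike_mv, trace,
              early_exit, abort_step, abort_mv):
    """Advance the fiber ``n_steps`` steps of ``dt`` (ms).

    The extracellular potential during step j is ``ve_schedule[j] *
    ve_profile`` or, when ``use_full``, ``ve_full[j]``.  ``(inv0..l2)`` is
    the LU factorization of the gate-independent system matrix.  State
    arrays update in place; node membrane potentials are written to
    ``trace`` (n_steps+1, n_nodes).

    Early termination: if ``early_exit`` return as soon as the last node
    exceeds ``spike_mv``; independently, past ``abort_step`` return 0 once
    every node is below ``abort_mv`` (a trajectory still heading for a
    spike keeps at least one node depolarized).  Returns 1 on activation,
    0 otherwise, -1 on numerical blow-up.
    """
    n = a.shape[0]
    n2 = 2 * n
    nn = node_idx.shape[0]
    last = nn - 1

    rhs = np.empty(n2)
    y = np.empty(n2)
    x = np.empty(n2)
    gion = np.empty(nn)
    w = np.empty(nn)
    c = np.empty(nn)
    M = np.empty((nn, nn))
    e_prev = np.zeros(n)
    e_new = np.empty(n)

    for j in range(nn):
        trace[0, j] = a[node_idx[j]] - b[node_idx[j]]

    activated = 0
    for step in range(n_steps):
        if use_full:
            for k in range(n):
                e_new[k] = ve_full[step, k]
        else:
            scale = ve_schedule[step]
            for k in range(n):
                e_new[k] = scale * ve_profile[k]

        # base right-hand side (gate-independent part)
        for k in range(n):
            vm_old = a[k] - b[k]
            vmy_old = b[k] - e_prev[k]
            rhs[2 * k] = cm_dt[k] * vm_old + ipas[k]
            rhs[2 * k + 1] = (cmy_dt[k] * vmy_old + (cmy_dt[k] + gmy[k]) * e_new[k]
                             - cm_dt[k] * vm_old - ipas[k])

        # nodal gates: implicit substep at v_old; nodal current linearized
        # as gion·Vm_new − ion_e and handled via fixed-point correction
        for j in range(nn):
            k = node_idx[j]
            v = a[k] - b[k]
            am, bm, ah, bh, ap, bp, as_, bs = _rates(v, q1, q2, q3)
            m[j] = (m[j] + dt * am) / (1.0 + dt * (am + bm))
            h[j] = (h[j] + dt * ah) / (1.0 + dt * (ah + bh))
            p[j] = (p[j] + dt * ap) / (1.0 + dt * (ap + bp))
            s[j] = (s[j] + dt * as_) / (1.0 + dt * (as_ + bs))
            gna = gna_us * m[j] * m[j] * m[j] * h[j]
            gnap = gnap_us * p[j] * p[j] * p[j]
            gk = gk_us * s[j]
            gion[j] = gna + gnap + gk + gl_us
            ie = (gna + gnap) * ENA + gk * EK + gl_us * EL
            rhs[2 * k] += ie
            rhs[2 * k + 1] -= ie

        # exact solve of (A0 + U·diag(gion)·Uᵀ)x = rhs via Woodbury:
        #   x = x0 − Z·c   with   (I + diag(gion)·S0)·c = diag(gion)·Uᵀx0
        _substitute(inv0, u1, u2, l1, l2, rhs, y, x)
        for j in range(nn):
            k = node_idx[j]
            w[j] = gion[j] * (x[2 * k] - x[2 * k + 1])
        for i in range(nn):
            gi = gion[i]
            for j in range(nn):
                M[i, j] = gi * S0[i, j]
            M[i, i] += 1.0
        # small dense solve (M is I + small PSD perturbation; no pivoting)
        for i in range(nn - 1):
            inv = 1.0 / M[i, i]
            for r in range(i + 1, nn):
                f = M[r, i] * inv
                if f != 0.0:
                    for cc in range(i + 1, nn):
                        M[r, cc] -= f * M[i, cc]
                    w[r] -= f * w[i]
        for i in range(nn - 1, -1, -1):
            acc = w[i]
            for j in range(i + 1, nn):
                acc -= M[i, j] * c[j]
            c[i] = acc / M[i, i]
        for i in range(n2):
            acc = x[i]
            for j in range(nn):
                acc -= Z[i, j] * c[j]
            x[i] = acc

        for k in range(n):
            a[k] = x[2 * k]
            b[k] = x[2 * k + 1]
            e_prev[k] = e_new[k]

        vmax = -1e30
        for j in range(nn):
            vmn = a[node_idx[j]] - b[node_idx[j]]
            trace[step + 1, j] = vmn
            if vmn > vmax:
                vmax = vmn
        if not np.isfinite(vmax):
            return -1
        if trace[step + 1, last] > spike_mv:
            activated = 1
            if early_exit:
                return 1
        if step >= abort_step and vmax < abort_mv and activated == 0:
            return 0
    return activated
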