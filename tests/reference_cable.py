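"""Independent dense-linear-algebra backward-Euler integrator.

Solves the same double-cable equations as the production kernel but
assembles the full (A0 + D) matrix each step and solves it with
numpy.linalg.solve — an independent route through the linear algebra used
to cross-check the prefactored iterative kernel.
"""

import numpy as np

from microstim import _kernels


def rates(v, q1, q2, q3):
    return _kernels._rates(v, q1, q2, q3)


def run_dense(system, profile, schedule, config):
    """Returns (activated, node_vm trace) for the schedule×profile field."""
    g = system.geometry
    n = g.n_compartments
    n2 = 2 * n
    dt = config.dt * 1e-3
    q1, q2, q3 = config.q10
    a, b, m, h, p, s = system.resting_state(config)
    cm_dt = system.cm / dt
    cmy_dt = system.cmy / dt
    node_idx = system.node_idx
    nn = node_idx.size

    trace = np.empty((schedule.size + 1, nn))
    trace[0] = (a - b)[node_idx]
    e_prev = np.zeros(n)
    for step in range(schedule.size):
        e_new = schedule[step] * profile
        # gates (implicit substep at pre-step Vm)
        gion = np.zeros(n)
        ion_e = np.zeros(n)
        for j, k in enumerate(node_idx):
            v = a[k] - b[k]
            am, bm, ah, bh, ap, bp, as_, bs = rates(v, q1, q2, q3)
            m[j] = (m[j] + dt * am) / (1 + dt * (am + bm))
            h[j] = (h[j] + dt * ah) / (1 + dt * (ah + bh))
            p[j] = (p[j] + dt * ap) / (1 + dt * (ap + bp))
            s[j] = (s[j] + dt * as_) / (1 + dt * (as_ + bs))
            gna = system.gna_us * m[j] ** 3 * h[j]
            gnap = system.gnap_us * p[j] ** 3
            gk = system.gk_us * s[j]
            gion[k] = gna + gnap + gk + system.gl_us
            ion_e[k] = (gna + gnap) * _kernels.ENA + gk * _kernels.EK + system.gl_us * _kernels.EL

        A = np.zeros((n2, n2))
        rhs = np.zeros(n2)
        for k in range(n):
            gm = cm_dt[k] + system.gpas[k] + gion[k]
            ie = system.ipas[k] + ion_e[k]
            vm_old = a[k] - b[k]
            vmy_old = b[k] - e_prev[k]
            A[2 * k, 2 * k] += gm
            A[2 * k, 2 * k + 1] -= gm
            rhs[2 * k] = cm_dt[k] * vm_old + ie
            A[2 * k + 1, 2 * k + 1] += cmy_dt[k] + system.gmy[k] + gm
            A[2 * k + 1, 2 * k] -= gm
            rhs[2 * k + 1] = (cmy_dt[k] * vmy_old + (cmy_dt[k] + system.gmy[k]) * e_new[k]
                             - cm_dt[k] * vm_old - ie)
            if k < n - 1:
                A[2 * k, 2 * k] += system.ga[k]
                A[2 * k, 2 * k + 2] -= system.ga[k]
                A[2 * k + 2, 2 * k + 2] += system.ga[k]
                A[2 * k + 2, 2 * k] -= system.ga[k]
                A[2 * k + 1, 2 * k + 1] += system.gp[k]
                A[2 * k + 1, 2 * k + 3] -= system.gp[k]
                A[2 * k + 3, 2 * k + 3] += system.gp[k]
                A[2 * k + 3, 2 * k + 1] -= system.gp[k]
        x = np.linalg.solve(A, rhs)
        a = x[0::2].copy()
        b = x[1::2].copy()
        e_prev = e_new
        trace[step + 1] = (a - b)[node_idx]
    spike = bool((trace[:, -1] > config.spike_threshold).any())
    return spike, trace
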