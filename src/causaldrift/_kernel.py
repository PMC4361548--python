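"""Numba kernels for the 14-state insulin-signaling circuit.

State layout (index -> variable):
    0 IRS1, 1 IRS1P, 2 IRS1SP, 3 PI3K, 4 IRS1P_PI3K          [nM]
    5 PI345P3, 6 PI45P2, 7 PI34P2, 8 Akt, 9 AktP,
    10 PKCZ, 11 PKCZP, 12 GLUT4_int, 13 GLUT4_mem            [%]

Parameter layout (canonical order, index -> rate constant):
    0 kF_IRS1P, 1 kB_IRS1P, 2 kB_IRS1SP, 3 kF_IRS1P_PI3K,
    4 kB_IRS1P_PI3K, 5 kF_PI45P2, 6 kB_PI45P2, 7 kF_PI34P2,
    8 kB_PI34P2, 9 kF_AktP, 10 kB_AktP, 11 kF_PKCZP,
    12 kB_PKCZP, 13 f_AktP, 14 f_PKCZP

Fixed-constant layout:
    0 k13, 1 k_minus13, 2 k14, 3 k_minus14, 4 AP_eq, 5 translocation_gain

Signal layout:
    0 amplitude, 1 pulse_start, 2 pulse_end, 3 tau_rise, 4 tau_decay
"""

import numpy as np
from numba import njit

N_STATE = 14
N_PARAM = 15


@njit(cache=True)
def signal_value(t, sig):
    """Insulin-bound receptor surrogate: exponential rise to a plateau
    during the pulse, exponential decay afterwards."""
    amp, t0, t1, tau_r, tau_d = sig[0], sig[1], sig[2], sig[3], sig[4]
    if t < t0:
        return 0.0
    if t < t1:
        return amp * (1.0 - np.exp(-(t - t0) / tau_r))
    v1 = amp * (1.0 - np.exp(-(t1 - t0) / tau_r))
    return v1 * np.exp(-(t - t1) / tau_d)


@njit(cache=True)
def k13_prime(aktp, pkczp, c):
    # insulin-stimulated translocation rate, linear in weighted kinase activity
    return c[5] * c[1] * (0.2 * pkczp + 0.8 * aktp) / c[4]


@njit(cache=True)
def rhs(y, t, p, c, sig):
    s = signal_value(t, sig)
    dy = np.empty(N_STATE)

    r1 = p[0] * y[0] * s              # IRS1 + SIGNAL -> IRS1P
    r2 = p[13] * p[1] * y[8] * y[1]   # AktP-feedback dephosphorylation of IRS1P
    r3 = p[2] * y[2]                  # IRS1SP -> IRS1
    r4 = p[14] * y[11] * y[0]         # PKCZP-feedback serine phosphorylation
    r5 = p[4] * y[4]                  # complex dissociation
    r6 = p[3] * y[3] * y[1]           # complex association
    r7 = p[5] * y[4] * y[6]           # PI45P2 -> PI345P3 (via complex)
    r8 = p[7] * y[7]                  # PI34P2 -> PI345P3
    r9 = p[6] * y[5]                  # PI345P3 -> PI45P2 (PTEN)
    r10 = p[8] * y[5]                 # PI345P3 -> PI34P2 (SHIP)
    r11 = p[9] * y[5] * y[8]          # Akt phosphorylation
    r12 = p[10] * y[9]                # AktP dephosphorylation
    r13 = p[11] * y[5] * y[10]        # PKCZ phosphorylation
    r14 = p[12] * y[11]               # PKCZP dephosphorylation

    dy[0] = -r1 + r2 + r3 - r4
    dy[1] = r1 - r2 + r5 - r6
    dy[2] = r4 - r3
    dy[3] = r5 - r6
    dy[4] = r6 - r5
    dy[5] = r7 + r8 - r9 - r10
    dy[6] = r9 - r7
    dy[7] = r10 - r8
    dy[8] = r12 - r11
    dy[9] = r11 - r12
    dy[10] = r14 - r13
    dy[11] = r13 - r14

    k13p = k13_prime(y[9], y[11], c)
    ktot = c[0] + k13p
    dy[12] = c[1] * y[13] - ktot * y[12] + c[2] - c[3] * y[12]
    dy[13] = ktot * y[12] - c[1] * y[13]
    return dy


@njit(cache=True)
def jacobian(y, t, p, c, sig):
    s = signal_value(t, sig)
    J = np.zeros((N_STATE, N_STATE))

    # IRS1 block
    J[0, 0] = -p[0] * s - p[14] * y[11]
    J[0, 1] = p[13] * p[1] * y[8]
    J[0, 2] = p[2]
    J[0, 8] = p[13] * p[1] * y[1]
    J[0, 11] = -p[14] * y[0]

    J[1, 0] = p[0] * s
    J[1, 1] = -p[13] * p[1] * y[8] - p[3] * y[3]
    J[1, 3] = -p[3] * y[1]
    J[1, 4] = p[4]
    J[1, 8] = -p[13] * p[1] * y[1]

    J[2, 0] = p[14] * y[11]
    J[2, 2] = -p[2]
    J[2, 11] = p[14] * y[0]

    J[3, 1] = -p[3] * y[3]
    J[3, 3] = -p[3] * y[1]
    J[3, 4] = p[4]

    J[4, 1] = p[3] * y[3]
    J[4, 3] = p[3] * y[1]
    J[4, 4] = -p[4]

    # phospholipid block
    J[5, 4] = p[5] * y[6]
    J[5, 5] = -(p[6] + p[8])
    J[5, 6] = p[5] * y[4]
    J[5, 7] = p[7]

    J[6, 4] = -p[5] * y[6]
    J[6, 5] = p[6]
    J[6, 6] = -p[5] * y[4]

    J[7, 5] = p[8]
    J[7, 7] = -p[7]

    # kinase blocks
    J[8, 5] = -p[9] * y[8]
    J[8, 8] = -p[9] * y[5]
    J[8, 9] = p[10]

    J[9, 5] = p[9] * y[8]
    J[9, 8] = p[9] * y[5]
    J[9, 9] = -p[10]

    J[10, 5] = -p[11] * y[10]
    J[10, 10] = -p[11] * y[5]
    J[10, 11] = p[12]

    J[11, 5] = p[11] * y[10]
    J[11, 10] = p[11] * y[5]
    J[11, 11] = -p[12]

    # GLUT4 translocation block
    k13p = k13_prime(y[9], y[11], c)
    ktot = c[0] + k13p
    g = c[5] * c[1] / c[4]
    J[12, 9] = -0.8 * g * y[12]
    J[12, 11] = -0.2 * g * y[12]
    J[12, 12] = -ktot - c[3]
    J[12, 13] = c[1]
    J[13, 9] = 0.8 * g * y[12]
    J[13, 11] = 0.2 * g * y[12]
    J[13, 12] = ktot
    J[13, 13] = -c[1]
    return J


@njit(cache=True)
def rk4_fixed(y0, t_grid, dt, p, c, sig):
    """Fixed-step classic Runge-Kutta integration, sampled on t_grid.

    Independent oracle for the adaptive solver; dt must resolve the fastest
    rate in the system (explicit-stability constraint), which the caller is
    responsible for.
    """
    n_out = t_grid.shape[0]
    out = np.empty((n_out, N_STATE))
    y = y0.copy()
    out[0] = y
    t = t_grid[0]
    for i in range(1, n_out):
        t_target = t_grid[i]
        while t < t_target - 1e-12:
            h = min(dt, t_target - t)
            k1 = rhs(y, t, p, c, sig)
            k2 = rhs(y + 0.5 * h * k1, t + 0.5 * h, p, c, sig)
            k3 = rhs(y + 0.5 * h * k2, t + 0.5 * h, p, c, sig)
            k4 = rhs(y + h * k3, t + h, p, c, sig)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            t += h
        out[i] = y
        t = t_target
    return out
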