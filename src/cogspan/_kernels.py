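"""Numba kernels for the three-state panel likelihood.

The model has states CH=1 (cognitively healthy), CI=2 (impaired), DEAD=3
(absorbing).  Transition intensities are Gompertz in age with log-linear
covariate effects:

    q_rs(a, z) = exp(alpha_rs + xi_rs * (a - a0) + beta_rs . z)

for the four allowed transitions (1,2), (1,3), (2,1), (2,3) in that fixed
order.  Because death is absorbing, the 2x2 living-states block of the
transition probability matrix multiplies independently across sub-intervals;
the death column is recovered as the row deficit.  The 2x2 matrix exponential
is evaluated in closed form from its (always real) spectrum.

Parameter vector layout (length 8 + 4p):
    theta[0:4]   alpha for the four transitions
    theta[4:8]   xi    for the four transitions
    theta[8+t*p : 8+(t+1)*p]  beta for transition t
"""

import numpy as np
from numba import njit

# transition order: index 0 -> 1->2, 1 -> 1->3, 2 -> 2->1, 3 -> 2->3
N_TRANSITIONS = 4


@njit(cache=False)
def _rates(theta, p, age, z, a0):
    """The four transition intensities at a given age and covariate row."""
    out = np.empty(4)
    for t in range(4):
        lp = theta[t] + theta[4 + t] * (age - a0)
        for j in range(p):
            lp += theta[8 + t * p + j] * z[j]
        out[t] = np.exp(lp)
    return out


@njit(cache=False)
def _expm2(q12, q13, q21, q23, dt):
    """exp(A*dt) for the living-states block A = [[-(q12+q13), q12],
    [q21, -(q21+q23)]].  Spectrum is real: disc = (a-d)^2 + 4 b c >= 0."""
    a = -(q12 + q13)
    d = -(q21 + q23)
    b = q12
    c = q21
    tr = a + d
    diff = a - d
    disc = diff * diff + 4.0 * b * c
    s = np.sqrt(disc) if disc > 0.0 else 0.0
    scale = abs(a) + abs(d) + 1.0
    if s > 1e-12 * scale:
        l1 = 0.5 * (tr + s)
        l2 = 0.5 * (tr - s)
        e1 = np.exp(l1 * dt)
        e2 = np.exp(l2 * dt)
        inv = 1.0 / s
        p11 = (e1 * (a - l2) - e2 * (a - l1)) * inv
        p12 = (e1 - e2) * b * inv
        p21 = (e1 - e2) * c * inv
        p22 = (e1 * (d - l2) - e2 * (d - l1)) * inv
    else:
        # (near-)defective: exp(A dt) ~ e^{l dt} (I + dt (A - l I))
        l = 0.5 * tr
        e = np.exp(l * dt)
        p11 = e * (1.0 + dt * (a - l))
        p12 = e * dt * b
        p21 = e * dt * c
        p22 = e * (1.0 + dt * (d - l))
    return p11, p12, p21, p22


@njit(cache=False)
def interval_pll(theta, p, z, a1, a2, step, a0):
    """Living-block transition probabilities over [a1, a2], piecewise-constant
    intensities on sub-intervals of width <= step evaluated at midpoints."""
    T = a2 - a1
    P11 = 1.0
    P12 = 0.0
    P21 = 0.0
    P22 = 1.0
    if T <= 0.0:
        return P11, P12, P21, P22
    m = int(np.ceil(T / step - 1e-12))
    if m < 1:
        m = 1
    dt = T / m
    for k in range(m):
        mid = a1 + (k + 0.5) * dt
        q = _rates(theta, p, mid, z, a0)
        e11, e12, e21, e22 = _expm2(q[0], q[1], q[2], q[3], dt)
        n11 = P11 * e11 + P12 * e21
        n12 = P11 * e12 + P12 * e22
        n21 = P21 * e11 + P22 * e21
        n22 = P21 * e12 + P22 * e22
        P11, P12, P21, P22 = n11, n12, n21, n22
    return P11, P12, P21, P22


@njit(cache=False)
def panel_loglik(theta, p, a1s, a2s, s_from, s_to, Z, step, a0):
    """Panel log-likelihood over consecutive observation pairs.

    Living -> living pairs contribute log P_{rs}(a1, a2); an exactly observed
    death contributes log sum_s P_{r s}(a1, a_d) q_{s3}(a_d)."""
    ll = 0.0
    n = a1s.shape[0]
    for i in range(n):
        z = Z[i]
        P11, P12, P21, P22 = interval_pll(theta, p, z, a1s[i], a2s[i], step, a0)
        if s_to[i] == 3:
            q = _rates(theta, p, a2s[i], z, a0)
            if s_from[i] == 1:
                lik = P11 * q[1] + P12 * q[3]
            else:
                lik = P21 * q[1] + P22 * q[3]
        elif s_from[i] == 1:
            lik = P11 if s_to[i] == 1 else P12
        else:
            lik = P21 if s_to[i] == 1 else P22
        if lik < 1e-300:
            lik = 1e-300
        ll += np.log(lik)
    return ll


@njit(cache=False)
def _expm2_cs(q12, q13, q21, q23, dt):
    """Complex-valued twin of :func:`_expm2` for complex-step
    differentiation with respect to one of the four rates."""
    a = -(q12 + q13)
    d = -(q21 + q23)
    b = q12
    c = q21
    tr = a + d
    diff = a - d
    disc = diff * diff + 4.0 * b * c
    s = np.sqrt(disc)
    scale = abs(a) + abs(d) + 1.0
    if abs(s) > 1e-12 * scale:
        l1 = 0.5 * (tr + s)
        l2 = 0.5 * (tr - s)
        e1 = np.exp(l1 * dt)
        e2 = np.exp(l2 * dt)
        inv = 1.0 / s
        p11 = (e1 * (a - l2) - e2 * (a - l1)) * inv
        p12 = (e1 - e2) * b * inv
        p21 = (e1 - e2) * c * inv
        p22 = (e1 * (d - l2) - e2 * (d - l1)) * inv
    else:
        l = 0.5 * tr
        e = np.exp(l * dt)
        p11 = e * (1.0 + dt * (a - l))
        p12 = e * dt * b
        p21 = e * dt * c
        p22 = e * (1.0 + dt * (d - l))
    return p11, p12, p21, p22


_CS_H = 1e-200  # complex-step size: exact to machine precision


@njit(cache=False)
def panel_loglik_grad(theta, p, a1s, a2s, s_from, s_to, Z, step, a0):
    """Log-likelihood and its exact gradient by forward sensitivity.

    Per sub-interval, dE/dq_t is obtained by complex-step differentiation
    of the closed-form 2x2 exponential and chained to the parameters via
    dq_t/dalpha_t = q_t, dq_t/dxi_t = q_t (age - a0), dq_t/dbeta_tj =
    q_t z_j; the product rule propagates sensitivities through the chain
    of sub-interval factors."""
    npar = 8 + 4 * p
    n = a1s.shape[0]
    grad = np.zeros(npar)
    G = np.empty((npar, 2, 2))
    dE = np.empty((4, 2, 2))
    dlik = np.empty(npar)
    ll = 0.0
    for i in range(n):
        z = Z[i]
        T = a2s[i] - a1s[i]
        m = int(np.ceil(T / step - 1e-12))
        if m < 1:
            m = 1
        dt = T / m
        P11 = 1.0
        P12 = 0.0
        P21 = 0.0
        P22 = 1.0
        for kk in range(npar):
            G[kk, 0, 0] = 0.0
            G[kk, 0, 1] = 0.0
            G[kk, 1, 0] = 0.0
            G[kk, 1, 1] = 0.0
        for k in range(m):
            mid = a1s[i] + (k + 0.5) * dt
            q = _rates(theta, p, mid, z, a0)
            e11, e12, e21, e22 = _expm2(q[0], q[1], q[2], q[3], dt)
            for t in range(4):
                c0 = complex(q[0], 0.0)
                c1 = complex(q[1], 0.0)
                c2 = complex(q[2], 0.0)
                c3 = complex(q[3], 0.0)
                if t == 0:
                    c0 = complex(q[0], _CS_H)
                elif t == 1:
                    c1 = complex(q[1], _CS_H)
                elif t == 2:
                    c2 = complex(q[2], _CS_H)
                else:
                    c3 = complex(q[3], _CS_H)
                d11, d12, d21, d22 = _expm2_cs(c0, c1, c2, c3,
                                               complex(dt, 0.0))
                dE[t, 0, 0] = d11.imag / _CS_H
                dE[t, 0, 1] = d12.imag / _CS_H
                dE[t, 1, 0] = d21.imag / _CS_H
                dE[t, 1, 1] = d22.imag / _CS_H
            # sensitivities through the product: G_k <- G_k E + P dE_k
            for kk in range(npar):
                g11 = G[kk, 0, 0] * e11 + G[kk, 0, 1] * e21
                g12 = G[kk, 0, 0] * e12 + G[kk, 0, 1] * e22
                g21 = G[kk, 1, 0] * e11 + G[kk, 1, 1] * e21
                g22 = G[kk, 1, 0] * e12 + G[kk, 1, 1] * e22
                G[kk, 0, 0] = g11
                G[kk, 0, 1] = g12
                G[kk, 1, 0] = g21
                G[kk, 1, 1] = g22
            age_dev = mid - a0
            for t in range(4):
                m11 = (P11 * dE[t, 0, 0] + P12 * dE[t, 1, 0]) * q[t]
                m12 = (P11 * dE[t, 0, 1] + P12 * dE[t, 1, 1]) * q[t]
                m21 = (P21 * dE[t, 0, 0] + P22 * dE[t, 1, 0]) * q[t]
                m22 = (P21 * dE[t, 0, 1] + P22 * dE[t, 1, 1]) * q[t]
                G[t, 0, 0] += m11
                G[t, 0, 1] += m12
                G[t, 1, 0] += m21
                G[t, 1, 1] += m22
                G[4 + t, 0, 0] += m11 * age_dev
                G[4 + t, 0, 1] += m12 * age_dev
                G[4 + t, 1, 0] += m21 * age_dev
                G[4 + t, 1, 1] += m22 * age_dev
                for j in range(p):
                    kk = 8 + t * p + j
                    G[kk, 0, 0] += m11 * z[j]
                    G[kk, 0, 1] += m12 * z[j]
                    G[kk, 1, 0] += m21 * z[j]
                    G[kk, 1, 1] += m22 * z[j]
            n11 = P11 * e11 + P12 * e21
            n12 = P11 * e12 + P12 * e22
            n21 = P21 * e11 + P22 * e21
            n22 = P21 * e12 + P22 * e22
            P11, P12, P21, P22 = n11, n12, n21, n22
        r = 0 if s_from[i] == 1 else 1
        Pr0 = P11 if r == 0 else P21
        Pr1 = P12 if r == 0 else P22
        if s_to[i] == 3:
            qd = _rates(theta, p, a2s[i], z, a0)
            lik = Pr0 * qd[1] + Pr1 * qd[3]
            for kk in range(npar):
                dlik[kk] = G[kk, r, 0] * qd[1] + G[kk, r, 1] * qd[3]
            # the density factor q_{s3}(a_d) also depends on the parameters
            age_dev = a2s[i] - a0
            dlik[1] += Pr0 * qd[1]
            dlik[5] += Pr0 * qd[1] * age_dev
            dlik[3] += Pr1 * qd[3]
            dlik[7] += Pr1 * qd[3] * age_dev
            for j in range(p):
                dlik[8 + 1 * p + j] += Pr0 * qd[1] * z[j]
                dlik[8 + 3 * p + j] += Pr1 * qd[3] * z[j]
        else:
            cidx = 0 if s_to[i] == 1 else 1
            lik = Pr0 if cidx == 0 else Pr1
            for kk in range(npar):
                dlik[kk] = G[kk, r, cidx]
        if lik < 1e-300:
            lik = 1e-300
        ll += np.log(lik)
        for kk in range(npar):
            grad[kk] += dlik[kk] / lik
    return ll, grad


@njit(cache=False)
def occupancy_grid(theta, p, z, a, omega, h, a0):
    """P_rs(a, a + j*h) for living r, s on the grid j = 0..N, N = (omega-a)/h.

    Each grid cell is one piecewise-constant sub-interval (midpoint
    intensity), so h doubles as the approximation step."""
    N = int(np.round((omega - a) / h))
    out = np.empty((N + 1, 2, 2))
    P11 = 1.0
    P12 = 0.0
    P21 = 0.0
    P22 = 1.0
    out[0, 0, 0] = 1.0
    out[0, 0, 1] = 0.0
    out[0, 1, 0] = 0.0
    out[0, 1, 1] = 1.0
    for j in range(1, N + 1):
        mid = a + (j - 0.5) * h
        q = _rates(theta, p, mid, z, a0)
        e11, e12, e21, e22 = _expm2(q[0], q[1], q[2], q[3], h)
        n11 = P11 * e11 + P12 * e21
        n12 = P11 * e12 + P12 * e22
        n21 = P21 * e11 + P22 * e21
        n22 = P21 * e12 + P22 * e22
        P11, P12, P21, P22 = n11, n12, n21, n22
        out[j, 0, 0] = P11
        out[j, 0, 1] = P12
        out[j, 1, 0] = P21
        out[j, 1, 1] = P22
    return out
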