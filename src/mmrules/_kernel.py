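"""Numba-compiled likelihood/gradient kernel for the rule network.

Computes the Bernoulli negative log likelihood and its gradients with
respect to every learnable parameter in one fused pass, avoiding the
per-operation overhead of the pure-numpy path.  The numpy implementation
in :mod:`mmrules.model` remains the reference; the test suite checks the
two agree (and both match finite differences).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def _sig(x):
    # saturate beyond +-40: sigmoid(40) is 1 to double precision, and the
    # early exit avoids exp() calls and denormal intermediates
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=True, fastmath=True)
def nll_and_grads(
    X_M, X_T, E_M, E_T, y,
    centers_M, log_radii_M, thr_M,
    centers_T, log_radii_T, thr_T,
    det_logits, rule_logits, beta, beta0,
    tau_u, tau_g_M, tau_g_T, tau_z, tau_q,
    hard,
):
    S, NM = X_M.shape
    NT = X_T.shape[1]
    K, J, DM = centers_M.shape
    L, DT = centers_T.shape[1], centers_T.shape[2]
    JL = J + L

    # ---- soft inclusions (stored feature-major for BLAS-friendly dots)
    u_M = np.empty((NM, K * J))
    eps_M = np.empty((K * J, NM))
    U_M = np.empty(K * J)
    for k in range(K):
        for j in range(J):
            kj = k * J + j
            kap = np.exp(log_radii_M[k, j])
            tot = 0.0
            for i in range(NM):
                d2 = 0.0
                for d in range(DM):
                    diff = E_M[i, d] - centers_M[k, j, d]
                    d2 += diff * diff
                e = np.sqrt(d2) if d2 > 1e-24 else 1e-12
                uu = _sig((kap - e) / tau_u)
                u_M[i, kj] = uu
                eps_M[kj, i] = e
                tot += uu
            U_M[kj] = tot + 1e-10

    u_T = np.empty((NT, K * L))
    eps_T = np.empty((K * L, NT))
    for k in range(K):
        for el in range(L):
            kl = k * L + el
            kap = np.exp(log_radii_T[k, el])
            for i in range(NT):
                d2 = 0.0
                for d in range(DT):
                    diff = E_T[i, d] - centers_T[k, el, d]
                    d2 += diff * diff
                e = np.sqrt(d2) if d2 > 1e-24 else 1e-12
                u_T[i, kl] = _sig((kap - e) / tau_u)
                eps_T[kl, i] = e

    # ---- aggregates and activations
    a_M = np.dot(X_M, u_M)  # (S, K*J)
    a_T = np.dot(X_T, u_T)  # (S, K*L)
    g = np.empty((S, K, JL))
    for s in range(S):
        for k in range(K):
            for j in range(J):
                g[s, k, j] = _sig(
                    (a_M[s, k * J + j] / U_M[k * J + j] - thr_M[k, j]) / tau_g_M
                )
            for el in range(L):
                g[s, k, J + el] = _sig(
                    (a_T[s, k * L + el] - thr_T[k, el]) / tau_g_T
                )

    # ---- selectors, soft AND, prediction
    z_soft = np.empty((K, JL))
    z = np.empty((K, JL))
    for k in range(K):
        for d in range(JL):
            zs = _sig(det_logits[k, d] / tau_z)
            z_soft[k, d] = zs
            z[k, d] = (1.0 if zs > 0.5 else 0.0) if hard else zs
    q_soft = np.empty(K)
    q = np.empty(K)
    for k in range(K):
        qs = _sig(rule_logits[k] / tau_q)
        q_soft[k] = qs
        q[k] = (1.0 if qs > 0.5 else 0.0) if hard else qs

    m = np.empty((S, K, JL))
    r = np.empty((S, K))
    o = np.empty(S)
    p = np.empty(S)
    nll = 0.0
    for s in range(S):
        tot = beta0
        for k in range(K):
            prod = 1.0
            for d in range(JL):
                mm = 1.0 - z[k, d] * (1.0 - g[s, k, d])
                if mm < 1e-12:
                    mm = 1e-12
                m[s, k, d] = mm
                prod *= mm
            r[s, k] = prod
            tot += q[k] * beta[k] * prod
        o[s] = tot
        p[s] = _sig(tot)
        if tot > 0:
            nll += tot + np.log1p(np.exp(-tot)) - y[s] * tot
        else:
            nll += np.log1p(np.exp(tot)) - y[s] * tot

    # ---- backward
    g_beta = np.zeros(K)
    g_beta0 = 0.0
    dq = np.zeros(K)
    dz = np.zeros((K, JL))
    da_M = np.zeros((S, K * J))  # w.r.t. the normalized aggregate
    da_T = np.zeros((S, K * L))
    g_thr_M = np.zeros((K, J))
    g_thr_T = np.zeros((K, L))
    for s in range(S):
        do = p[s] - y[s]
        g_beta0 += do
        for k in range(K):
            g_beta[k] += do * q[k] * r[s, k]
            dq[k] += do * beta[k] * r[s, k]
            dr = do * q[k] * beta[k]
            for d in range(JL):
                dm = dr * (r[s, k] / m[s, k, d])
                dz[k, d] += dm * (-(1.0 - g[s, k, d]))
                dg = dm * z[k, d]
                gg = g[s, k, d]
                if d < J:
                    da = dg * gg * (1.0 - gg) / tau_g_M
                    da_M[s, k * J + d] = da
                    g_thr_M[k, d] -= da
                else:
                    el = d - J
                    da = dg * gg * (1.0 - gg) / tau_g_T
                    da_T[s, k * L + el] = da
                    g_thr_T[k, el] -= da

    # chain through soft relaxation (straight-through when hard)
    g_det_logits = np.empty((K, JL))
    for k in range(K):
        for d in range(JL):
            g_det_logits[k, d] = (
                dz[k, d] * z_soft[k, d] * (1.0 - z_soft[k, d]) / tau_z
            )
    g_rule_logits = np.empty(K)
    for k in range(K):
        g_rule_logits[k] = dq[k] * q_soft[k] * (1.0 - q_soft[k]) / tau_q

    # ---- metabolite aggregate backprop: du = (X^T da - sum(da*a/U)) / U
    T1 = np.dot(da_M.T.copy(), X_M)  # (K*J, NM)
    SA = np.zeros(K * J)
    for s in range(S):
        for kj in range(K * J):
            SA[kj] += da_M[s, kj] * (a_M[s, kj] / U_M[kj])
    g_centers_M = np.zeros((K, J, DM))
    g_log_radii_M = np.zeros((K, J))
    for k in range(K):
        for j in range(J):
            kj = k * J + j
            kap = np.exp(log_radii_M[k, j])
            acc_kappa = 0.0
            for i in range(NM):
                du = (T1[kj, i] - SA[kj]) / U_M[kj]
                uu = u_M[i, kj]
                sigd = du * uu * (1.0 - uu) / tau_u
                acc_kappa += sigd
                t = -sigd / eps_M[kj, i]
                for d in range(DM):
                    g_centers_M[k, j, d] += t * (centers_M[k, j, d] - E_M[i, d])
            g_log_radii_M[k, j] = acc_kappa * kap

    T2 = np.dot(da_T.T.copy(), X_T)  # (K*L, NT)
    g_centers_T = np.zeros((K, L, DT))
    g_log_radii_T = np.zeros((K, L))
    for k in range(K):
        for el in range(L):
            kl = k * L + el
            kap = np.exp(log_radii_T[k, el])
            acc_kappa = 0.0
            for i in range(NT):
                du = T2[kl, i]
                uu = u_T[i, kl]
                sigd = du * uu * (1.0 - uu) / tau_u
                acc_kappa += sigd
                t = -sigd / eps_T[kl, i]
                for d in range(DT):
                    g_centers_T[k, el, d] += t * (centers_T[k, el, d] - E_T[i, d])
            g_log_radii_T[k, el] = acc_kappa * kap

    return (
        nll, g_centers_M, g_log_radii_M, g_thr_M,
        g_centers_T, g_log_radii_T, g_thr_T,
        g_det_logits, g_rule_logits, g_beta, g_beta0,
    )
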