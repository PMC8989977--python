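"""Numba kernel for the collapsed likelihood and its gradient.

Numerically identical to the vectorized numpy path in
:mod:`protect._collapsed` (which remains the tested reference); this kernel
exists because posterior sampling evaluates the gradient tens of thousands
of times per fit and the per-patient quadrature loops fuse much better than
a chain of small numpy temporaries.

The kernel works on pre-extracted arrays and returns gradients with respect
to *per-patient linear predictors* for the treatment and outcome equations
(``g_base_a``, ``g_e0``, ``g_cf``); the Python wrapper contracts those with
the design matrices to get covariate-coefficient gradients.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=False)
def collapsed_loglik_grad(
    zf, wf, u2, th_o,            # fitness-axis grid (Qf,), extra-confounder values/coef
    zb, wb,                      # behavior-axis grid (Qb,)
    age, has_alpha, alpha,
    YF, signs_f, af, bf,         # fitness proxies: (n_fp, n) targets, signs, params
    YB, signs_b, ab, bb,         # behavior proxies
    has_cat, cat1, cat2, a1, b1, a2, b2,
    treat_in_kernel, A, base_a, tauf, th_t, treat_on_fitness,
    e0, cf, has_ub_out, betab,
    k, logt, event,
    # outputs
    g_af, g_bf, g_ab, g_bb, g_cat, g_base_a, g_e0, g_cf, g_scalars,
):
    n = age.shape[0]
    Qf = zf.shape[0]
    Qb = zb.shape[0]
    n_fp = af.shape[0]
    n_bp = ab.shape[0]

    if not (k > 0.0) or not np.isfinite(k):
        return -np.inf

    # behavior-side quantities do not depend on the patient except through y
    eta_b = np.empty((n_bp, Qb))
    sp_b = np.empty((n_bp, Qb))
    sig_b = np.empty((n_bp, Qb))
    for j in range(n_bp):
        for r in range(Qb):
            e = ab[j] + signs_b[j] * bb[j] * zb[r]
            eta_b[j, r] = e
            if e > 0.0:
                sp_b[j, r] = e + np.log1p(np.exp(-e))
            else:
                sp_b[j, r] = np.log1p(np.exp(e))
            sig_b[j, r] = 1.0 / (1.0 + np.exp(-e))
    l1 = np.empty(Qb)
    l2 = np.empty(Qb)
    logz_cat = np.empty(Qb)
    p1 = np.empty(Qb)
    p2 = np.empty(Qb)
    if has_cat == 1:
        for r in range(Qb):
            l1[r] = a1 + b1 * zb[r]
            l2[r] = a2 + b2 * zb[r]
            mx = 0.0
            if l1[r] > mx:
                mx = l1[r]
            if l2[r] > mx:
                mx = l2[r]
            z = np.exp(-mx) + np.exp(l1[r] - mx) + np.exp(l2[r] - mx)
            logz_cat[r] = mx + np.log(z)
            p1[r] = np.exp(l1[r] - logz_cat[r])
            p2[r] = np.exp(l2[r] - logz_cat[r])
    eb = np.empty(Qb)
    Eb = np.empty(Qb)
    for r in range(Qb):
        eb[r] = betab * zb[r] if has_ub_out == 1 else 0.0
        Eb[r] = np.exp(eb[r])

    # scratch arrays reused across patients
    uf = np.empty(Qf)
    Lf = np.empty(Qf)
    Af = np.empty(Qf)
    Ef = np.empty(Qf)
    sf = np.empty((n_fp, Qf))
    sA = np.empty(Qf)
    Lb = np.empty(Qb)
    Bb = np.empty(Qb)
    sb = np.empty((n_bp, Qb))
    sc1 = np.empty(Qb)
    sc2 = np.empty(Qb)
    W = np.empty((Qf, Qb))
    Rf = np.empty(Qf)
    Rb = np.empty(Qb)
    ELam_f = np.empty(Qf)
    ELam_b = np.empty(Qb)

    ll = 0.0
    g_alpha = 0.0
    g_betab = 0.0
    g_k = 0.0
    g_tau0 = 0.0
    g_tauf = 0.0

    for i in range(n):
        m = alpha * age[i] if has_alpha == 1 else 0.0
        ev = event[i]

        for q in range(Qf):
            u = m + zf[q]
            uf[q] = u
            acc = 0.0
            for j in range(n_fp):
                e = af[j] + signs_f[j] * bf[j] * u
                if e > 0.0:
                    sp = e + np.log1p(np.exp(-e))
                else:
                    sp = np.log1p(np.exp(e))
                y = YF[j, i]
                acc += y * e - sp
                sf[j, q] = y - 1.0 / (1.0 + np.exp(-e))
            if treat_in_kernel == 1:
                e = base_a[i] + th_t * u2[q]
                if treat_on_fitness == 1:
                    e += tauf * u
                if e > 0.0:
                    sp = e + np.log1p(np.exp(-e))
                else:
                    sp = np.log1p(np.exp(e))
                acc += A[i] * e - sp
                sA[q] = A[i] - 1.0 / (1.0 + np.exp(-e))
            Lf[q] = acc
            efq = cf[i] * u + th_o * u2[q]
            Ef[q] = np.exp(efq)
            Af[q] = acc + ev * efq

        for r in range(Qb):
            acc = 0.0
            for j in range(n_bp):
                y = YB[j, i]
                acc += y * eta_b[j, r] - sp_b[j, r]
                sb[j, r] = y - sig_b[j, r]
            if has_cat == 1:
                acc += cat1[i] * l1[r] + cat2[i] * l2[r] - logz_cat[r]
                sc1[r] = cat1[i] - p1[r]
                sc2[r] = cat2[i] - p2[r]
            Lb[r] = acc
            Bb[r] = acc + ev * eb[r]

        h0 = np.exp(k * logt[i] + e0[i])
        gmax = -1e308
        for q in range(Qf):
            hq = h0 * Ef[q]
            for r in range(Qb):
                lam = hq * Eb[r]
                if lam > 1e300:
                    lam = 1e300
                gv = Af[q] + Bb[r] - lam
                W[q, r] = gv
                if gv > gmax:
                    gmax = gv
        z = 0.0
        for q in range(Qf):
            for r in range(Qb):
                w = wf[q] * wb[r] * np.exp(W[q, r] - gmax)
                W[q, r] = w
                z += w
        if not (z > 0.0) or not np.isfinite(z):
            g_scalars[6] = 0.0
            return -np.inf
        const = ev * (np.log(k) + (k - 1.0) * logt[i] + e0[i])
        ll += const + gmax + np.log(z)

        # responsibilities and hazard expectations
        elam = 0.0
        for q in range(Qf):
            Rf[q] = 0.0
            ELam_f[q] = 0.0
        for r in range(Qb):
            Rb[r] = 0.0
            ELam_b[r] = 0.0
        for q in range(Qf):
            hq = h0 * Ef[q]
            for r in range(Qb):
                rr = W[q, r] / z
                lam = hq * Eb[r]
                if lam > 1e300:
                    lam = 1e300
                rl = rr * lam
                Rf[q] += rr
                Rb[r] += rr
                ELam_f[q] += rl
                ELam_b[r] += rl
                elam += rl
        resid = ev - elam
        euf = 0.0
        elam_uf = 0.0
        for q in range(Qf):
            euf += Rf[q] * uf[q]
            elam_uf += ELam_f[q] * uf[q]

        g_e0[i] = resid
        g_cf[i] = ev * euf - elam_uf
        g_k += ev * (1.0 / k + logt[i]) - elam * logt[i]
        if has_ub_out == 1:
            eub = 0.0
            elam_ub = 0.0
            for r in range(Qb):
                eub += Rb[r] * zb[r]
                elam_ub += ELam_b[r] * zb[r]
            g_betab += ev * eub - elam_ub

        sfit_dot = 0.0  # sum_q Rf[q] * (d loglik / d u_f)(q)
        for j in range(n_fp):
            gaj = 0.0
            gbj = 0.0
            for q in range(Qf):
                rs = Rf[q] * sf[j, q]
                gaj += rs
                gbj += rs * uf[q]
                sfit_dot += rs * signs_f[j] * bf[j]
            g_af[j] += gaj
            g_bf[j] += signs_f[j] * gbj
        if treat_in_kernel == 1:
            row = 0.0
            for q in range(Qf):
                rsa = Rf[q] * sA[q]
                row += rsa
                if treat_on_fitness == 1:
                    g_tauf += rsa * uf[q]
                    sfit_dot += rsa * tauf
            g_tau0 += row
            g_base_a[i] = row
        if has_alpha == 1:
            g_alpha += age[i] * (sfit_dot + cf[i] * resid)

        for j in range(n_bp):
            gaj = 0.0
            gbj = 0.0
            for r in range(Qb):
                rs = Rb[r] * sb[j, r]
                gaj += rs
                gbj += rs * zb[r]
            g_ab[j] += gaj
            g_bb[j] += signs_b[j] * gbj
        if has_cat == 1:
            for r in range(Qb):
                g_cat[0] += Rb[r] * sc1[r]
                g_cat[1] += Rb[r] * sc1[r] * zb[r]
                g_cat[2] += Rb[r] * sc2[r]
                g_cat[3] += Rb[r] * sc2[r] * zb[r]

    g_scalars[0] = g_alpha
    g_scalars[1] = g_tau0
    g_scalars[2] = g_tauf
    g_scalars[3] = g_betab
    g_scalars[4] = g_k
    g_scalars[6] = 1.0
    return ll
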