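"""Numba-compiled adaptive Metropolis-within-Gibbs kernel for the CJS model.

The packed parameter vector theta (all on the sampling scale) is laid out

    [ a_c | ds_c | du_c | beta_c | gamma_t | eps_phi[c,t] | eps_p[c,t] |
      sigma_gamma, sigma_phi_eps, sigma_p_eps ]

with a = logit(alpha) etc.  One sweep updates every free component with a
Gaussian random-walk proposal; step sizes adapt toward a 0.44 acceptance
rate during burn-in (Robbins-Monro on the log step) and are frozen after.
The likelihood is the exact sufficient-statistics CJS likelihood; each
proposal re-evaluates only the colony rows it touches plus the O(T)
backward recursion for the never-seen-again terms, so a sweep costs
O(D * T) independent of the number of individuals.
"""

import numpy as np
from numba import njit

SIGMA_LO = 0.1
SIGMA_HI = 10.0
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)

# component kinds
K_A, K_DS, K_DU, K_BETA, K_GAMMA, K_EPHI, K_EP, K_SG, K_SPHI, K_SP = range(10)
# likelihood-invariant translation moves (interweaving along flat ridges):
# R_PHI shifts a_c up and the colony's eps_phi row down; R_P shifts both
# recapture intercepts up and the colony's eps_p row down; R_GAMMA shifts
# the shared year effects up and every survival intercept down.  All three
# leave every phi and p unchanged, so only the prior enters the ratio;
# they decorrelate the intercepts from the means of their random effects.
R_PHI, R_P, R_GAMMA = 10, 11, 12
# R_GT moves one year's partition: gamma_t up, every colony's eps_phi[c,t]
# down.  With few colonies the shared/idiosyncratic split of a year effect
# is informed only by the prior, so without this move the split barely
# mixes and the ICC inherits the initialization.
R_GT = 13


def layout(C, n_int):
    """Offsets of each block in the packed vector; returns (offsets, D)."""
    off = {}
    o = 0
    off["a"] = o; o += C
    off["ds"] = o; o += C
    off["du"] = o; o += C
    off["beta"] = o; o += C
    off["gamma"] = o; o += n_int
    off["eps_phi"] = o; o += C * n_int
    off["eps_p"] = o; o += C * n_int
    off["sigma"] = o; o += 3
    return off, o


def component_tables(C, n_int, use_wind, use_gamma):
    """comp_kind / comp_c / comp_t / update-mask arrays for the kernel."""
    off, D = layout(C, n_int)
    kind = np.empty(D, dtype=np.int64)
    cc = np.zeros(D, dtype=np.int64)
    tt = np.zeros(D, dtype=np.int64)
    free = np.ones(D, dtype=np.bool_)
    for c in range(C):
        kind[off["a"] + c] = K_A; cc[off["a"] + c] = c
        kind[off["ds"] + c] = K_DS; cc[off["ds"] + c] = c
        kind[off["du"] + c] = K_DU; cc[off["du"] + c] = c
        kind[off["beta"] + c] = K_BETA; cc[off["beta"] + c] = c
        free[off["beta"] + c] = use_wind
    for t in range(n_int):
        kind[off["gamma"] + t] = K_GAMMA; tt[off["gamma"] + t] = t
        free[off["gamma"] + t] = use_gamma
    for c in range(C):
        for t in range(n_int):
            i = off["eps_phi"] + c * n_int + t
            kind[i] = K_EPHI; cc[i] = c; tt[i] = t
            i = off["eps_p"] + c * n_int + t
            kind[i] = K_EP; cc[i] = c; tt[i] = t
    kind[off["sigma"]] = K_SG
    kind[off["sigma"] + 1] = K_SPHI
    kind[off["sigma"] + 2] = K_SP
    free[off["sigma"]] = use_gamma
    # translation-move pseudo-components (hold adaptive step sizes only)
    n_ridge = 2 * C + 1 + n_int
    rkind = np.empty(n_ridge, dtype=np.int64)
    rc = np.zeros(n_ridge, dtype=np.int64)
    rt = np.zeros(n_ridge, dtype=np.int64)
    rfree = np.ones(n_ridge, dtype=np.bool_)
    for c in range(C):
        rkind[c] = R_PHI; rc[c] = c
        rkind[C + c] = R_P; rc[C + c] = c
    rkind[2 * C] = R_GAMMA
    rfree[2 * C] = use_gamma
    for t in range(n_int):
        rkind[2 * C + 1 + t] = R_GT
        rt[2 * C + 1 + t] = t
        rfree[2 * C + 1 + t] = use_gamma
    kind = np.concatenate([kind, rkind])
    cc = np.concatenate([cc, rc])
    tt = np.concatenate([tt, rt])
    free = np.concatenate([free, rfree])
    return kind, cc, tt, free


@njit(cache=True, inline="always")
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _logistic_logpdf(x):
    ax = abs(x)
    return -ax - 2.0 * np.log1p(np.exp(-ax))


@njit(cache=True)
def _set_phi_entry(theta, c, t, use_wind, use_gamma, W, C, n_int, phi, lphi, l1mphi):
    lp = theta[c] + theta[4 * C + n_int + c * n_int + t]
    if use_gamma:
        lp += theta[4 * C + t]
    if use_wind:
        lp += theta[3 * C + c] * W[t]
    f = _sigmoid(lp)
    if f < 1e-12:
        f = 1e-12
    elif f > 1.0 - 1e-12:
        f = 1.0 - 1e-12
    phi[c, t] = f
    lphi[c, t] = np.log(f)
    l1mphi[c, t] = np.log1p(-f)


@njit(cache=True)
def _set_p_entry(theta, c, t, C, n_int, ps, pu, lps, l1mps, lpu, l1mpu):
    e = theta[4 * C + n_int + C * n_int + c * n_int + t]
    a = _sigmoid(theta[C + c] + e)
    b = _sigmoid(theta[2 * C + c] + e)
    if a < 1e-12:
        a = 1e-12
    elif a > 1.0 - 1e-12:
        a = 1.0 - 1e-12
    if b < 1e-12:
        b = 1e-12
    elif b > 1.0 - 1e-12:
        b = 1.0 - 1e-12
    ps[c, t] = a
    lps[c, t] = np.log(a)
    l1mps[c, t] = np.log1p(-a)
    pu[c, t] = b
    lpu[c, t] = np.log(b)
    l1mpu[c, t] = np.log1p(-b)


@njit(cache=True)
def _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
               nphi, ncs, nms, ncu, nmu, L):
    s = 0.0
    psi = 1.0  # P(never detected after t | alive at t, not detected at t)
    for t in range(n_int - 1, -1, -1):
        f = phi[c, t]
        if L[c, t] > 0.0:
            chi = (1.0 - f) + f * (1.0 - ps[c, t]) * psi
            s += L[c, t] * np.log(chi)
        psi = (1.0 - f) + f * (1.0 - pu[c, t]) * psi
        s += (nphi[c, t] * lphi[c, t] + ncs[c, t] * lps[c, t]
              + nms[c, t] * l1mps[c, t] + ncu[c, t] * lpu[c, t]
              + nmu[c, t] * l1mpu[c, t])
    return s


@njit(cache=True)
def _full_prior(theta, use_wind, use_gamma, C, n_int):
    sg = theta[4 * C + n_int + 2 * C * n_int]
    sphi = theta[4 * C + n_int + 2 * C * n_int + 1]
    sp = theta[4 * C + n_int + 2 * C * n_int + 2]
    if sphi < SIGMA_LO or sphi > SIGMA_HI or sp < SIGMA_LO or sp > SIGMA_HI:
        return -np.inf
    if use_gamma and (sg < SIGMA_LO or sg > SIGMA_HI):
        return -np.inf
    lp = -3.0 * np.log(SIGMA_HI - SIGMA_LO)
    for i in range(3 * C):
        lp += _logistic_logpdf(theta[i])
    if use_wind:
        for c in range(C):
            b = theta[3 * C + c]
            lp += -0.5 * b * b - _HALF_LOG_2PI
    if use_gamma:
        for t in range(n_int):
            g = theta[4 * C + t]
            lp += -0.5 * (g / sg) ** 2 - np.log(sg) - _HALF_LOG_2PI
    o = 4 * C + n_int
    for i in range(C * n_int):
        e = theta[o + i]
        lp += -0.5 * (e / sphi) ** 2 - np.log(sphi) - _HALF_LOG_2PI
    o += C * n_int
    for i in range(C * n_int):
        e = theta[o + i]
        lp += -0.5 * (e / sp) ** 2 - np.log(sp) - _HALF_LOG_2PI
    return lp


@njit(cache=True)
def full_loglik(theta, use_wind, use_gamma, W,
                nphi, ncs, nms, ncu, nmu, L):
    """Dataset log-likelihood for a packed vector (used for init checks)."""
    C, n_int = nphi.shape
    phi = np.empty((C, n_int)); lphi = np.empty((C, n_int)); l1mphi = np.empty((C, n_int))
    ps = np.empty((C, n_int)); pu = np.empty((C, n_int))
    lps = np.empty((C, n_int)); l1mps = np.empty((C, n_int))
    lpu = np.empty((C, n_int)); l1mpu = np.empty((C, n_int))
    for c in range(C):
        for t in range(n_int):
            _set_phi_entry(theta, c, t, use_wind, use_gamma, W, C, n_int, phi, lphi, l1mphi)
            _set_p_entry(theta, c, t, C, n_int, ps, pu, lps, l1mps, lpu, l1mpu)
    ll = 0.0
    for c in range(C):
        ll += _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                         nphi, ncs, nms, ncu, nmu, L)
    return ll


@njit(cache=True)
def run_chain(theta, log_step, comp_kind, comp_c, comp_t, free,
              n_sweeps, burnin, thin, seed,
              use_wind, use_gamma, W,
              nphi, ncs, nms, ncu, nmu, L,
              target_accept, adapt_interval):
    np.random.seed(seed)
    C, n_int = nphi.shape
    D = theta.shape[0]
    off_gamma = 4 * C
    off_ephi = 4 * C + n_int
    off_ep = off_ephi + C * n_int
    off_sig = off_ep + C * n_int

    phi = np.empty((C, n_int)); lphi = np.empty((C, n_int)); l1mphi = np.empty((C, n_int))
    ps = np.empty((C, n_int)); pu = np.empty((C, n_int))
    lps = np.empty((C, n_int)); l1mps = np.empty((C, n_int))
    lpu = np.empty((C, n_int)); l1mpu = np.empty((C, n_int))
    for c in range(C):
        for t in range(n_int):
            _set_phi_entry(theta, c, t, use_wind, use_gamma, W, C, n_int, phi, lphi, l1mphi)
            _set_p_entry(theta, c, t, C, n_int, ps, pu, lps, l1mps, lpu, l1mpu)
    ll_col = np.empty(C)
    for c in range(C):
        ll_col[c] = _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                               nphi, ncs, nms, ncu, nmu, L)

    n_keep = 0
    for s in range(burnin, n_sweeps):
        if (s - burnin) % thin == 0:
            n_keep += 1
    D_all = comp_kind.shape[0]
    draws = np.empty((n_keep, D))
    acc = np.zeros(D_all)
    prop = np.zeros(D_all)
    acc_total = np.zeros(D_all)
    prop_total = np.zeros(D_all)
    # scratch for restoring rejected proposals
    sv_phi = np.empty(n_int); sv_lphi = np.empty(n_int); sv_l1mphi = np.empty(n_int)
    sv_ps = np.empty(n_int); sv_lps = np.empty(n_int); sv_l1mps = np.empty(n_int)
    sv_pu = np.empty(n_int); sv_lpu = np.empty(n_int); sv_l1mpu = np.empty(n_int)
    svc_phi = np.empty(C); svc_lphi = np.empty(C); svc_l1mphi = np.empty(C)
    sv_ll = np.empty(C)
    new_ll = np.empty(C)

    keep_i = 0
    batch = 0
    for sweep in range(n_sweeps):
        for i in range(D_all):
            if not free[i]:
                continue
            kind = comp_kind[i]
            c = comp_c[i]
            t = comp_t[i]

            if kind >= R_PHI:
                # likelihood-invariant translation along a flat ridge
                d = np.exp(log_step[i]) * np.random.normal()
                prop[i] += 1.0
                prop_total[i] += 1.0
                dlp = 0.0
                if kind == R_PHI:
                    a_old = theta[c]
                    dlp += _logistic_logpdf(a_old + d) - _logistic_logpdf(a_old)
                    sphi = theta[off_sig + 1]
                    for tt2 in range(n_int):
                        e = theta[off_ephi + c * n_int + tt2]
                        dlp += -0.5 * ((e - d) ** 2 - e * e) / (sphi * sphi)
                elif kind == R_P:
                    dlp += _logistic_logpdf(theta[C + c] + d) - _logistic_logpdf(theta[C + c])
                    dlp += _logistic_logpdf(theta[2 * C + c] + d) - _logistic_logpdf(theta[2 * C + c])
                    sp = theta[off_sig + 2]
                    for tt2 in range(n_int):
                        e = theta[off_ep + c * n_int + tt2]
                        dlp += -0.5 * ((e - d) ** 2 - e * e) / (sp * sp)
                elif kind == R_GAMMA:
                    sg = theta[off_sig]
                    for tt2 in range(n_int):
                        g = theta[off_gamma + tt2]
                        dlp += -0.5 * ((g + d) ** 2 - g * g) / (sg * sg)
                    for c2 in range(C):
                        dlp += _logistic_logpdf(theta[c2] - d) - _logistic_logpdf(theta[c2])
                else:  # R_GT: one year's shared/idiosyncratic partition
                    sg = theta[off_sig]
                    sphi = theta[off_sig + 1]
                    g = theta[off_gamma + t]
                    dlp += -0.5 * ((g + d) ** 2 - g * g) / (sg * sg)
                    for c2 in range(C):
                        e = theta[off_ephi + c2 * n_int + t]
                        dlp += -0.5 * ((e - d) ** 2 - e * e) / (sphi * sphi)
                if np.log(np.random.random()) < dlp:
                    if kind == R_PHI:
                        theta[c] += d
                        for tt2 in range(n_int):
                            theta[off_ephi + c * n_int + tt2] -= d
                    elif kind == R_P:
                        theta[C + c] += d
                        theta[2 * C + c] += d
                        for tt2 in range(n_int):
                            theta[off_ep + c * n_int + tt2] -= d
                    elif kind == R_GAMMA:
                        for tt2 in range(n_int):
                            theta[off_gamma + tt2] += d
                        for c2 in range(C):
                            theta[c2] -= d
                    else:  # R_GT
                        theta[off_gamma + t] += d
                        for c2 in range(C):
                            theta[off_ephi + c2 * n_int + t] -= d
                    acc[i] += 1.0
                    acc_total[i] += 1.0
                continue

            old = theta[i]
            theta_new = old + np.exp(log_step[i]) * np.random.normal()
            prop[i] += 1.0
            prop_total[i] += 1.0

            if kind >= K_SG:
                if theta_new < SIGMA_LO or theta_new > SIGMA_HI:
                    continue
                # prior-only update of the relevant Gaussian block
                if kind == K_SG:
                    ss = 0.0
                    for tt in range(n_int):
                        ss += theta[off_gamma + tt] ** 2
                    n_terms = n_int
                elif kind == K_SPHI:
                    ss = 0.0
                    for j in range(C * n_int):
                        ss += theta[off_ephi + j] ** 2
                    n_terms = C * n_int
                else:
                    ss = 0.0
                    for j in range(C * n_int):
                        ss += theta[off_ep + j] ** 2
                    n_terms = C * n_int
                d = (-0.5 * ss / theta_new ** 2 - n_terms * np.log(theta_new)) \
                    - (-0.5 * ss / old ** 2 - n_terms * np.log(old))
                if np.log(np.random.random()) < d:
                    theta[i] = theta_new
                    acc[i] += 1.0
                    acc_total[i] += 1.0
                continue

            # prior delta for the single component
            if kind <= K_DU:
                dprior = _logistic_logpdf(theta_new) - _logistic_logpdf(old)
            elif kind == K_BETA:
                dprior = -0.5 * (theta_new ** 2 - old ** 2)
            elif kind == K_GAMMA:
                sg = theta[off_sig]
                dprior = -0.5 * (theta_new ** 2 - old ** 2) / sg ** 2
            elif kind == K_EPHI:
                sphi = theta[off_sig + 1]
                dprior = -0.5 * (theta_new ** 2 - old ** 2) / sphi ** 2
            else:  # K_EP
                sp = theta[off_sig + 2]
                dprior = -0.5 * (theta_new ** 2 - old ** 2) / sp ** 2

            theta[i] = theta_new
            dll = 0.0
            nl = 0.0
            f0 = 0.0; lf0 = 0.0; l1f0 = 0.0
            p0 = 0.0; lp0 = 0.0; l1p0 = 0.0
            q0 = 0.0; lq0 = 0.0; l1q0 = 0.0
            if kind == K_GAMMA:
                for c2 in range(C):
                    svc_phi[c2] = phi[c2, t]
                    svc_lphi[c2] = lphi[c2, t]
                    svc_l1mphi[c2] = l1mphi[c2, t]
                    sv_ll[c2] = ll_col[c2]
                    _set_phi_entry(theta, c2, t, use_wind, use_gamma, W, C, n_int,
                                   phi, lphi, l1mphi)
                    new_ll[c2] = _colony_ll(c2, n_int, phi, ps, pu, lphi, lps, l1mps,
                                            lpu, l1mpu, nphi, ncs, nms, ncu, nmu, L)
                    dll += new_ll[c2] - sv_ll[c2]
            elif kind == K_EPHI:
                f0 = phi[c, t]; lf0 = lphi[c, t]; l1f0 = l1mphi[c, t]
                ll0 = ll_col[c]
                _set_phi_entry(theta, c, t, use_wind, use_gamma, W, C, n_int,
                               phi, lphi, l1mphi)
                nl = _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                                nphi, ncs, nms, ncu, nmu, L)
                dll = nl - ll0
            elif kind == K_EP:
                p0 = ps[c, t]; lp0 = lps[c, t]; l1p0 = l1mps[c, t]
                q0 = pu[c, t]; lq0 = lpu[c, t]; l1q0 = l1mpu[c, t]
                ll0 = ll_col[c]
                _set_p_entry(theta, c, t, C, n_int, ps, pu, lps, l1mps, lpu, l1mpu)
                nl = _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                                nphi, ncs, nms, ncu, nmu, L)
                dll = nl - ll0
            elif kind == K_A or kind == K_BETA:
                for tt in range(n_int):
                    sv_phi[tt] = phi[c, tt]
                    sv_lphi[tt] = lphi[c, tt]
                    sv_l1mphi[tt] = l1mphi[c, tt]
                ll0 = ll_col[c]
                for tt in range(n_int):
                    _set_phi_entry(theta, c, tt, use_wind, use_gamma, W, C, n_int,
                                   phi, lphi, l1mphi)
                nl = _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                                nphi, ncs, nms, ncu, nmu, L)
                dll = nl - ll0
            else:  # K_DS or K_DU: rebuild the colony's p rows
                for tt in range(n_int):
                    sv_ps[tt] = ps[c, tt]; sv_lps[tt] = lps[c, tt]; sv_l1mps[tt] = l1mps[c, tt]
                    sv_pu[tt] = pu[c, tt]; sv_lpu[tt] = lpu[c, tt]; sv_l1mpu[tt] = l1mpu[c, tt]
                ll0 = ll_col[c]
                for tt in range(n_int):
                    _set_p_entry(theta, c, tt, C, n_int, ps, pu, lps, l1mps, lpu, l1mpu)
                nl = _colony_ll(c, n_int, phi, ps, pu, lphi, lps, l1mps, lpu, l1mpu,
                                nphi, ncs, nms, ncu, nmu, L)
                dll = nl - ll0

            if np.log(np.random.random()) < dprior + dll:
                # accept
                if kind == K_GAMMA:
                    for c2 in range(C):
                        ll_col[c2] = new_ll[c2]
                else:
                    ll_col[c] = nl
                acc[i] += 1.0
                acc_total[i] += 1.0
            else:
                # restore
                theta[i] = old
                if kind == K_GAMMA:
                    for c2 in range(C):
                        phi[c2, t] = svc_phi[c2]
                        lphi[c2, t] = svc_lphi[c2]
                        l1mphi[c2, t] = svc_l1mphi[c2]
                elif kind == K_EPHI:
                    phi[c, t] = f0; lphi[c, t] = lf0; l1mphi[c, t] = l1f0
                elif kind == K_EP:
                    ps[c, t] = p0; lps[c, t] = lp0; l1mps[c, t] = l1p0
                    pu[c, t] = q0; lpu[c, t] = lq0; l1mpu[c, t] = l1q0
                elif kind == K_A or kind == K_BETA:
                    for tt in range(n_int):
                        phi[c, tt] = sv_phi[tt]
                        lphi[c, tt] = sv_lphi[tt]
                        l1mphi[c, tt] = sv_l1mphi[tt]
                else:
                    for tt in range(n_int):
                        ps[c, tt] = sv_ps[tt]; lps[c, tt] = sv_lps[tt]; l1mps[c, tt] = sv_l1mps[tt]
                        pu[c, tt] = sv_pu[tt]; lpu[c, tt] = sv_lpu[tt]; l1mpu[c, tt] = sv_l1mpu[tt]

        if sweep < burnin:
            batch += 1
            if batch == adapt_interval:
                delta = min(0.1, 1.0 / np.sqrt(1.0 + sweep / adapt_interval))
                for i in range(D_all):
                    if prop[i] > 0.0:
                        if acc[i] / prop[i] > target_accept:
                            log_step[i] += delta
                        else:
                            log_step[i] -= delta
                    acc[i] = 0.0
                    prop[i] = 0.0
                batch = 0
        if sweep >= burnin and (sweep - burnin) % thin == 0:
            for i in range(D):
                draws[keep_i, i] = theta[i]
            keep_i += 1

    accept_rate = np.zeros(D_all)
    for i in range(D_all):
        if prop_total[i] > 0.0:
            accept_rate[i] = acc_total[i] / prop_total[i]
    return draws, accept_rate
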