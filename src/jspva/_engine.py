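"""Compiled MCMC kernel for the data-augmented Jolly-Seber model.

One chain = repeated sweeps of
  (1) exact full-conditional (Gibbs) updates of each pseudo-individual's
      latent trajectory (entry year b, first-year age, last alive year d),
      enumerated over all trajectories compatible with that individual's
      detections, and
  (2) Metropolis / Gibbs updates of the demographic and observation
      parameters (conjugate Beta draws for k and tau, adaptive random-walk
      Metropolis on transformed scales for the rest, including the latent
      true covariate values of the climate variants).

Invalid configurations (counts exceeding the unmarked pool, cumulative
entry probability above one) are handled with a large negative sentinel
rather than -inf so that an invalid initial state anneals towards the
support instead of deadlocking the sampler.

Everything here works on plain arrays; the public face is
``jspva.infer.run_mcmc``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .datasets import (
    I_ALPHA, I_B0C, I_B0G, I_B0P_ASY, I_B0P_SY, I_B1C, I_B1G, I_B1G_POST,
    I_B1P, I_B1P_POST, I_B2G, I_K, I_PETA, I_PI1, I_PR, I_TAU,
    N_SCALAR_PARAMS,
)

NEG = -1.0e9  # sentinel log-density for invalid configurations
NP = N_SCALAR_PARAMS

# transform codes for Metropolis updates
T_IDENT, T_LOG, T_LOGIT = 0, 1, 2
# prior codes
P_NORMAL, P_EXPON, P_HALFNORMAL, P_UNIFORM, P_BETA = 0, 1, 2, 3, 4
# likelihood block codes
B_ENTRY, B_SURV, B_CAP, B_RES = 0, 1, 2, 3


@njit(cache=True, inline="always")
def _log_expit(x):
    """log(1/(1+exp(-x))), stable for large |x|."""
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(cache=True)
def _recompute_counts(b, a1, d, mfrom, T, e, n1, n2, N, U):
    """Refresh per-year aggregates from the per-individual latent state."""
    M = b.shape[0]
    nnever = 0
    for t in range(T):
        e[t] = 0
        n1[t] = 0
        n2[t] = 0
        N[t] = 0
        U[t] = 0
    for i in range(M):
        bi = b[i]
        if bi >= T:
            nnever += 1
            continue
        e[bi] += 1
        for t in range(bi, d[i] + 1):
            sy = (t == bi) and not (bi == 0 and a1[i] == 1)
            if sy:
                n1[t] += 1
            else:
                n2[t] += 1
            N[t] += 1
            if t < mfrom[i]:
                U[t] += 1
    return nnever


@njit(cache=True)
def _recompute_survstats(b, a1, d, T, SD, DD):
    """Survivor / death counts by age class and transition year."""
    M = b.shape[0]
    for t in range(T - 1):
        for j in range(2):
            SD[j, t] = 0
            DD[j, t] = 0
    for i in range(M):
        bi = b[i]
        if bi >= T:
            continue
        di = d[i]
        for t in range(bi, di):
            j = 0 if ((t == bi) and not (bi == 0 and a1[i] == 1)) else 1
            SD[j, t] += 1
        if di < T - 1:
            j = 0 if ((di == bi) and not (bi == 0 and a1[i] == 1)) else 1
            DD[j, di] += 1


@njit(cache=True)
def _entry_ll(pi1v, alpha, b0g, b1g, b1gp, b2g, w, cp, e, nnever,
              n1, n2, N, T, M, area, dp):
    """Entry log-likelihood sum_t e_t log pi_t + n_never log pi_{T+1}."""
    ll = 0.0
    if pi1v <= 0.0 or pi1v >= 1.0:
        return NEG
    S = pi1v
    if e[0] > 0:
        ll += e[0] * np.log(pi1v)
    for t in range(1, T):
        A = n1[t - 1] + n2[t - 1]
        slope = b1gp if cp[t - 1] == 1 else b1g
        ed = N[t - 1] / area
        edp = ed * ed if dp == 2 else ed
        lin = b0g + slope * w[t - 1] - b2g * edp
        g = alpha * np.exp(_log_expit(lin))
        pv = A * g / M
        S += pv
        if e[t] > 0:
            if pv <= 0.0:
                return NEG
            ll += e[t] * np.log(pv)
    pin = 1.0 - S
    if pin < 0.0:
        return NEG
    if nnever > 0:
        if pin <= 0.0:
            return NEG
        ll += nnever * np.log(pin)
    return ll


@njit(cache=True)
def _surv_ll(b0sy, b0asy, b1p, b1pp, w, cp, SD, DD, T):
    ll = 0.0
    for t in range(T - 1):
        slope = b1pp if cp[t] == 1 else b1p
        lin0 = b0sy + slope * w[t]
        lin1 = b0asy + slope * w[t]
        if SD[0, t] > 0:
            ll += SD[0, t] * _log_expit(lin0)
        if DD[0, t] > 0:
            ll += DD[0, t] * _log_expit(-lin0)
        if SD[1, t] > 0:
            ll += SD[1, t] * _log_expit(lin1)
        if DD[1, t] > 0:
            ll += DD[1, t] * _log_expit(-lin1)
    return ll


@njit(cache=True)
def _cap_ll(b0c, b1c, ts, CA, CH, U, T):
    """Capture terms without the k factor (k is Gibbs-updated separately)."""
    ll = 0.0
    for t in range(T):
        lin = b0c + b1c * ts[t]
        ncap = CA[t] + CH[t]
        if ncap > 0:
            ll += ncap * _log_expit(lin)
        if U[t] > 0:
            ll += U[t] * _log_expit(-lin)
    return ll


@njit(cache=True)
def _res_ll(peta, pr, sdflag, RY, N, U, u, T):
    if peta <= 0.0 or peta >= 1.0 or pr <= 0.0 or pr >= 1.0:
        return NEG
    ll = 0.0
    for t in range(T):
        pe = peta * pr if sdflag[t] == 1 else peta
        lpe = np.log(pe)
        l1m = np.log1p(-pe)
        RN = N[t] - U[t] - RY[t]
        if u[t] <= U[t]:  # invalid years are parameter-independent; skip
            ll += (RY[t] + u[t]) * lpe + (RN + U[t] - u[t]) * l1m
        else:
            ll += RY[t] * lpe + RN * l1m
    return ll


@njit(cache=True)
def _block_ll(code, theta, w, cp, ts, sdflag, e, nnever, n1, n2, N, U, u,
              SD, DD, CA, CH, RY, T, M, area, dp):
    if code == B_ENTRY:
        return _entry_ll(theta[I_PI1], theta[I_ALPHA], theta[I_B0G],
                         theta[I_B1G], theta[I_B1G_POST], theta[I_B2G],
                         w, cp, e, nnever, n1, n2, N, T, M, area, dp)
    if code == B_SURV:
        return _surv_ll(theta[I_B0P_SY], theta[I_B0P_ASY], theta[I_B1P],
                        theta[I_B1P_POST], w, cp, SD, DD, T)
    if code == B_CAP:
        return _cap_ll(theta[I_B0C], theta[I_B1C], ts, CA, CH, U, T)
    return _res_ll(theta[I_PETA], theta[I_PR], sdflag, RY, N, U, u, T)


@njit(cache=True)
def _log_prior(code, x, sd_beta, alpha_rate, pr_a, pr_b):
    if code == P_NORMAL:
        return -0.5 * (x / sd_beta) ** 2
    if code == P_EXPON:
        return -alpha_rate * x
    if code == P_HALFNORMAL:
        return -0.5 * (x / sd_beta) ** 2
    if code == P_UNIFORM:
        return 0.0
    return (pr_a - 1.0) * np.log(x) + (pr_b - 1.0) * np.log1p(-x)


@njit(cache=True)
def run_chain(seed, n_adapt, n_keep,
              T, M, area, dp,
              nobs, fc, aged, ydat, lastdet, u, sdflag,
              variant, cp, ts, mu, sig,
              sd_beta, alpha_rate, pr_a, pr_b, sd_w,
              sample_params, sample_pr,
              mh_idx, mh_tcode, mh_pcode, mh_bcode,
              theta0, b0, a10, d0,
              out_theta, out_n1, out_n2, out_N):
    """Run one MCMC chain; fills the ``out_*`` arrays with kept draws."""
    np.random.seed(seed)
    theta = theta0.copy()
    b = b0.copy()
    a1 = a10.copy()
    d = d0.copy()

    mfrom = np.empty(M, dtype=np.int64)
    for i in range(M):
        mfrom[i] = fc[i] if i < nobs else T

    # static tables
    EDp = np.empty(M + 1)
    for n in range(M + 1):
        ed = n / area
        EDp[n] = ed * ed if dp == 2 else ed
    LA = np.empty(M + 2)
    LA[0] = NEG
    for n in range(1, M + 2):
        LA[n] = np.log(n)
    lgam = np.empty(M + 3)  # lgam[n] = log((n-1)!)
    lgam[0] = 0.0
    lgam[1] = 0.0
    for n in range(2, M + 3):
        lgam[n] = lgam[n - 1] + np.log(n - 1.0)
    logM = np.log(M)

    # aggregates
    e = np.zeros(T, dtype=np.int64)
    n1 = np.zeros(T, dtype=np.int64)
    n2 = np.zeros(T, dtype=np.int64)
    N = np.zeros(T, dtype=np.int64)
    U = np.zeros(T, dtype=np.int64)
    SD = np.zeros((2, T - 1), dtype=np.int64)
    DD = np.zeros((2, T - 1), dtype=np.int64)
    CA = np.zeros(T, dtype=np.int64)  # aged (SY/ASY) captures per year
    CH = np.zeros(T, dtype=np.int64)  # AHY captures per year
    RY = np.zeros(T, dtype=np.int64)  # resightings per year
    for i in range(nobs):
        if aged[i] == 3:
            CH[fc[i]] += 1
        else:
            CA[fc[i]] += 1
        for t in range(T):
            if ydat[i, t] == 1:
                RY[t] += 1
    nnever = _recompute_counts(b, a1, d, mfrom, T, e, n1, n2, N, U)

    # per-sweep tables
    w = np.empty(T)
    G = np.empty((T - 1, M + 1))
    LG = np.empty((T - 1, M + 1))
    logphi = np.empty((2, T - 1))
    log1mphi = np.empty((2, T - 1))
    l1mpc = np.empty(T)
    lcap_aged = np.empty(T)
    lcap_ahy = np.empty(T)
    lpe = np.empty(T)
    l1mpe = np.empty(T)
    P = np.zeros((nobs, T + 1))
    Paug = np.zeros(T + 1)

    piB = np.empty(T)
    logpiB = np.empty(T)
    cE = np.empty(T)
    cb = np.empty(T)
    dc = np.empty(T)

    max_cand = 1 + (T * (T + 1)) // 2 + T
    cand_b = np.empty(max_cand, dtype=np.int64)
    cand_a = np.empty(max_cand, dtype=np.int64)
    cand_d = np.empty(max_cand, dtype=np.int64)
    cand_ll = np.empty(max_cand)

    # Metropolis bookkeeping
    n_mh = mh_idx.shape[0]
    scales = np.full(n_mh, 0.3)
    acc = np.zeros(n_mh, dtype=np.int64)
    wscales = np.full(T, 0.3)
    wacc = np.zeros(T, dtype=np.int64)
    batch = 0

    n_iter = n_adapt + n_keep
    for it in range(n_iter):
        nnever = _recompute_counts(b, a1, d, mfrom, T, e, n1, n2, N, U)
        # ---- per-sweep tables from current theta --------------------------
        alpha = theta[I_ALPHA]
        b0g, b1g, b1gp, b2g = theta[I_B0G], theta[I_B1G], theta[I_B1G_POST], theta[I_B2G]
        b0sy, b0asy, b1p, b1pp = (theta[I_B0P_SY], theta[I_B0P_ASY],
                                  theta[I_B1P], theta[I_B1P_POST])
        b0c, b1c = theta[I_B0C], theta[I_B1C]
        kpar, tau, pi1v = theta[I_K], theta[I_TAU], theta[I_PI1]
        peta, pr = theta[I_PETA], theta[I_PR]

        for t in range(T):
            w[t] = theta[NP + t] if variant == 1 else ts[t]
        for t in range(T - 1):
            slope_g = b1gp if cp[t] == 1 else b1g
            base = b0g + slope_g * w[t]
            for n in range(M + 1):
                lg = _log_expit(base - b2g * EDp[n])
                G[t, n] = alpha * np.exp(lg)
                LG[t, n] = np.log(alpha) + lg
            slope_p = b1pp if cp[t] == 1 else b1p
            lin0 = b0sy + slope_p * w[t]
            lin1 = b0asy + slope_p * w[t]
            logphi[0, t] = _log_expit(lin0)
            log1mphi[0, t] = _log_expit(-lin0)
            logphi[1, t] = _log_expit(lin1)
            log1mphi[1, t] = _log_expit(-lin1)
        for t in range(T):
            lin = b0c + b1c * ts[t]
            lpc = _log_expit(lin)
            l1mpc[t] = _log_expit(-lin)
            lcap_aged[t] = lpc + (np.log(kpar) if kpar > 0.0 else NEG)
            lcap_ahy[t] = lpc + (np.log1p(-kpar) if kpar < 1.0 else NEG)
            pe = peta * pr if sdflag[t] == 1 else peta
            lpe[t] = np.log(pe) if pe > 0.0 else NEG
            l1mpe[t] = np.log1p(-pe) if pe < 1.0 else NEG
        ltau1 = np.log(tau) if tau > 0.0 else NEG
        ltau0 = np.log1p(-tau) if tau < 1.0 else NEG
        lpi1 = np.log(pi1v) if pi1v > 0.0 else NEG

        # observation prefix sums (capture-year column excluded)
        for i in range(nobs):
            f = fc[i]
            P[i, 0] = 0.0
            for t in range(T):
                if t < f:
                    oa = l1mpc[t]
                elif t == f:
                    oa = 0.0
                else:
                    oa = lpe[t] if ydat[i, t] == 1 else l1mpe[t]
                P[i, t + 1] = P[i, t] + oa
        Paug[0] = 0.0
        for t in range(T):
            Paug[t + 1] = Paug[t] + l1mpc[t]

        # ---- latent trajectory updates ------------------------------------
        for i in range(M):
            # remove i from aggregates
            bi = b[i]
            if bi >= T:
                nnever -= 1
            else:
                e[bi] -= 1
                for t in range(bi, d[i] + 1):
                    sy = (t == bi) and not (bi == 0 and a1[i] == 1)
                    if sy:
                        n1[t] -= 1
                    else:
                        n2[t] -= 1
                    N[t] -= 1
                    if t < mfrom[i]:
                        U[t] -= 1

            # base entry probabilities and per-year contributions
            piB[0] = pi1v
            logpiB[0] = lpi1
            Sbase = pi1v
            Ebase = 0.0
            for t in range(1, T):
                A = n1[t - 1] + n2[t - 1]
                if A > 0:
                    pv = A * G[t - 1, N[t - 1]] / M
                    lv = LA[A] + LG[t - 1, N[t - 1]] - logM
                else:
                    pv = 0.0
                    lv = NEG
                piB[t] = pv
                logpiB[t] = lv
                Sbase += pv
            for t in range(T):
                if e[t] > 0:
                    cE[t] = e[t] * logpiB[t] if piB[t] > 0.0 else NEG
                else:
                    cE[t] = 0.0
                Ebase += cE[t]

            # count-term base and deltas
            CBsum = 0.0
            for t in range(T):
                Ub = U[t]
                ut = u[t]
                pe_l = lpe[t]
                l1m = l1mpe[t]
                if ut <= Ub:
                    cb[t] = (lgam[Ub + 1] - lgam[ut + 1] - lgam[Ub - ut + 1]
                             + ut * pe_l + (Ub - ut) * l1m)
                else:
                    cb[t] = NEG
                if ut <= Ub + 1:
                    cb1 = (lgam[Ub + 2] - lgam[ut + 1] - lgam[Ub + 1 - ut + 1]
                           + ut * pe_l + (Ub + 1 - ut) * l1m)
                else:
                    cb1 = NEG
                dc[t] = cb1 - cb[t]
                CBsum += cb[t]

            # candidate enumeration
            if i < nobs:
                bmax = fc[i]
                dmin = lastdet[i]
                allow_never = False
            else:
                bmax = T - 1
                dmin = 0
                allow_never = True

            nc = 0
            for bb in range(bmax + 1):
                na = 2 if bb == 0 else 1
                for ac in range(na):
                    dlo = bb if bb > dmin else dmin
                    for dd in range(dlo, T):
                        ll = Ebase + CBsum
                        # entry terms: affected years and own entry
                        S = Sbase
                        tmax_aff = dd + 1 if dd + 1 < T else T - 1
                        for t in range(bb + 1, tmax_aff + 1):
                            A1 = n1[t - 1] + n2[t - 1] + 1
                            N1 = N[t - 1] + 1
                            pv = A1 * G[t - 1, N1] / M
                            lv = LA[A1] + LG[t - 1, N1] - logM
                            S += pv - piB[t]
                            if e[t] > 0:
                                ll += e[t] * lv - cE[t]
                        # own entry at bb (uses counts at bb-1: unaffected)
                        if piB[bb] > 0.0:
                            ll += logpiB[bb]
                        else:
                            ll += NEG
                        pin = 1.0 - S
                        if pin < 0.0:
                            ll += NEG
                        elif nnever > 0:
                            ll += nnever * np.log(pin) if pin > 0.0 else NEG
                        # first-year age
                        if bb == 0:
                            ll += ltau1 if ac == 1 else ltau0
                        # own survival run
                        for t in range(bb, dd):
                            j = 0 if ((t == bb) and not (bb == 0 and ac == 1)) else 1
                            ll += logphi[j, t]
                        if dd < T - 1:
                            j = 0 if ((dd == bb) and not (bb == 0 and ac == 1)) else 1
                            ll += log1mphi[j, dd]
                        # own observations
                        if i < nobs:
                            ll += P[i, dd + 1] - P[i, bb]
                            f = fc[i]
                            sy_at_f = (f == bb) and not (bb == 0 and ac == 1)
                            ag = aged[i]
                            if ag == 1:
                                ll += lcap_aged[f] if sy_at_f else NEG
                            elif ag == 2:
                                ll += NEG if sy_at_f else lcap_aged[f]
                            else:
                                ll += lcap_ahy[f]
                            ll += lpe[f] if ydat[i, f] == 1 else l1mpe[f]
                            tend = dd if dd < f - 1 else f - 1
                            for t in range(bb, tend + 1):
                                ll += dc[t]
                        else:
                            ll += Paug[dd + 1] - Paug[bb]
                            for t in range(bb, dd + 1):
                                ll += dc[t]
                        cand_b[nc] = bb
                        cand_a[nc] = ac
                        cand_d[nc] = dd
                        cand_ll[nc] = ll
                        nc += 1
            if allow_never:
                ll = Ebase + CBsum
                pin = 1.0 - Sbase
                nv = nnever + 1
                if pin <= 0.0:
                    ll += NEG
                else:
                    ll += nv * np.log(pin)
                cand_b[nc] = T
                cand_a[nc] = 0
                cand_d[nc] = -1
                cand_ll[nc] = ll
                nc += 1

            # sample a candidate
            best = cand_ll[0]
            for c in range(1, nc):
                if cand_ll[c] > best:
                    best = cand_ll[c]
            tot = 0.0
            for c in range(nc):
                cand_ll[c] = np.exp(cand_ll[c] - best)
                tot += cand_ll[c]
            r = np.random.random() * tot
            acc_p = 0.0
            pick = nc - 1
            for c in range(nc):
                acc_p += cand_ll[c]
                if r <= acc_p:
                    pick = c
                    break
            bb = cand_b[pick]
            ac = cand_a[pick]
            dd = cand_d[pick]
            b[i] = bb
            a1[i] = ac
            d[i] = dd

            # add i back into aggregates
            if bb >= T:
                nnever += 1
            else:
                e[bb] += 1
                for t in range(bb, dd + 1):
                    sy = (t == bb) and not (bb == 0 and ac == 1)
                    if sy:
                        n1[t] += 1
                    else:
                        n2[t] += 1
                    N[t] += 1
                    if t < mfrom[i]:
                        U[t] += 1

        # ---- parameter updates --------------------------------------------
        if sample_params == 1:
            _recompute_survstats(b, a1, d, T, SD, DD)
            # conjugate Gibbs draws for k and tau
            CAtot = 0
            CHtot = 0
            for t in range(T):
                CAtot += CA[t]
                CHtot += CH[t]
            theta[I_K] = np.random.beta(1.0 + CAtot, 1.0 + CHtot)
            nb1 = 0
            nb1a = 0
            for i in range(M):
                if b[i] == 0:
                    nb1 += 1
                    if a1[i] == 1:
                        nb1a += 1
            theta[I_TAU] = np.random.beta(1.0 + nb1a, 1.0 + nb1 - nb1a)

            for p in range(n_mh):
                idx = mh_idx[p]
                tc = mh_tcode[p]
                pc_ = mh_pcode[p]
                bc = mh_bcode[p]
                x = theta[idx]
                ll_cur = _block_ll(bc, theta, w, cp, ts, sdflag, e, nnever,
                                   n1, n2, N, U, u, SD, DD, CA, CH, RY,
                                   T, M, area, dp)
                if tc == T_IDENT:
                    xn = x + scales[p] * np.random.normal()
                    jac = 0.0
                elif tc == T_LOG:
                    yv = np.log(x) + scales[p] * np.random.normal()
                    xn = np.exp(yv)
                    jac = np.log(xn) - np.log(x)
                else:
                    yv = np.log(x / (1.0 - x)) + scales[p] * np.random.normal()
                    xn = 1.0 / (1.0 + np.exp(-yv))
                    if xn <= 0.0 or xn >= 1.0:
                        continue
                    jac = (np.log(xn) + np.log1p(-xn)) - (np.log(x) + np.log1p(-x))
                theta[idx] = xn
                ll_new = _block_ll(bc, theta, w, cp, ts, sdflag, e, nnever,
                                   n1, n2, N, U, u, SD, DD, CA, CH, RY,
                                   T, M, area, dp)
                dlp = (_log_prior(pc_, xn, sd_beta, alpha_rate, pr_a, pr_b)
                       - _log_prior(pc_, x, sd_beta, alpha_rate, pr_a, pr_b))
                lacc = ll_new - ll_cur + dlp + jac
                if np.log(np.random.random()) < lacc:
                    acc[p] += 1
                else:
                    theta[idx] = x

            # latent covariate values (climate variants)
            if variant == 1:
                alpha = theta[I_ALPHA]
                b0g, b1g, b1gp, b2g = (theta[I_B0G], theta[I_B1G],
                                       theta[I_B1G_POST], theta[I_B2G])
                b0sy, b0asy, b1p, b1pp = (theta[I_B0P_SY], theta[I_B0P_ASY],
                                          theta[I_B1P], theta[I_B1P_POST])
                # current pi array under current w
                S = theta[I_PI1]
                for t in range(1, T):
                    A = n1[t - 1] + n2[t - 1]
                    slope = b1gp if cp[t - 1] == 1 else b1g
                    lin = (b0g + slope * theta[NP + t - 1]
                           - b2g * EDp[N[t - 1]])
                    pv = A * alpha * np.exp(_log_expit(lin)) / M
                    piB[t] = pv
                    S += pv
                piB[0] = theta[I_PI1]
                for t in range(T):
                    wt = theta[NP + t]
                    wn = wt + wscales[t] * np.random.normal()
                    dll = (-0.5 * ((mu[t] - wn) / sig[t]) ** 2
                           + 0.5 * ((mu[t] - wt) / sig[t]) ** 2
                           - 0.5 * (wn * wn - wt * wt) / (sd_w * sd_w))
                    ok = True
                    pv_new = 0.0
                    if t < T - 1:
                        A = n1[t] + n2[t]
                        slope_g = b1gp if cp[t] == 1 else b1g
                        lin_new = b0g + slope_g * wn - b2g * EDp[N[t]]
                        pv_new = A * alpha * np.exp(_log_expit(lin_new)) / M
                        pv_old = piB[t + 1]
                        Snew = S - pv_old + pv_new
                        pin_new = 1.0 - Snew
                        pin_old = 1.0 - S
                        if pin_new < 0.0:
                            ok = False
                        else:
                            if e[t + 1] > 0:
                                if pv_new <= 0.0 or pv_old <= 0.0:
                                    dll += NEG if pv_new <= 0.0 else -NEG
                                else:
                                    dll += e[t + 1] * (np.log(pv_new) - np.log(pv_old))
                            if nnever > 0:
                                if pin_new <= 0.0 or pin_old <= 0.0:
                                    dll += NEG if pin_new <= 0.0 else -NEG
                                else:
                                    dll += nnever * (np.log(pin_new) - np.log(pin_old))
                            slope_p = b1pp if cp[t] == 1 else b1p
                            for j in range(2):
                                b0j = b0sy if j == 0 else b0asy
                                lin_n = b0j + slope_p * wn
                                lin_o = b0j + slope_p * wt
                                if SD[j, t] > 0:
                                    dll += SD[j, t] * (_log_expit(lin_n) - _log_expit(lin_o))
                                if DD[j, t] > 0:
                                    dll += DD[j, t] * (_log_expit(-lin_n) - _log_expit(-lin_o))
                    if ok and np.log(np.random.random()) < dll:
                        theta[NP + t] = wn
                        wacc[t] += 1
                        if t < T - 1:
                            S = S - piB[t + 1] + pv_new
                            piB[t + 1] = pv_new

            # step-size adaptation
            if it < n_adapt:
                batch += 1
                if batch == 25:
                    for p in range(n_mh):
                        rate = acc[p] / 25.0
                        scales[p] *= np.exp(rate - 0.44)
                        if scales[p] < 1e-3:
                            scales[p] = 1e-3
                        elif scales[p] > 10.0:
                            scales[p] = 10.0
                        acc[p] = 0
                    if variant == 1:
                        for t in range(T):
                            rate = wacc[t] / 25.0
                            wscales[t] *= np.exp(rate - 0.44)
                            if wscales[t] < 1e-3:
                                wscales[t] = 1e-3
                            elif wscales[t] > 10.0:
                                wscales[t] = 10.0
                            wacc[t] = 0
                    batch = 0

        # ---- record --------------------------------------------------------
        if it >= n_adapt:
            kidx = it - n_adapt
            for p_ in range(theta.shape[0]):
                out_theta[kidx, p_] = theta[p_]
            for t in range(T):
                out_n1[kidx, t] = n1[t]
                out_n2[kidx, t] = n2[t]
                out_N[kidx, t] = N[t]
    return 0
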