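"""Numba kernels for the adaptive Metropolis-within-Gibbs sampler.

Everything here operates on flat arrays laid out by `_layout.HyperLayout`.
Each update recomputes only the likelihood terms its parameter touches:

* fecundity parameters → the Poisson recruitment terms of one group;
* juvenile survival/movement → the binomial/immigration terms they feed and
  only the juvenile release rows of the m-array (juvenile rates act on the
  first interval after a juvenile release);
* adult survival/movement and detection → the affected process rows plus a
  full m-array pass (adult rates enter every release row's path recursion);
* latent integer states → the handful of process/observation cells around
  one group-year.

Movement proposals that would push a group's total outflow to ≥ 1 are
rejected outright (the prior support excludes them); nothing is
renormalized.  Step sizes adapt by Robbins–Monro toward 0.44 acceptance for
scalar updates and 0.23 for vector blocks, with diminishing adaptation.
"""

import math

import numpy as np
from numba import njit

from ._layout import (
    F_A_GAM, F_B_FEC, F_S_GAM, F_EPS_GAM,
    F_A_PHIJ, F_B5, F_HUNT1, F_EPS_PHIJ, F_S_PHIJ,
    F_A_PHIA, F_B6, F_HUNT2, F_EPS_PHIA, F_S_PHIA,
    F_MU_B5, F_L_B5, F_MU_B6, F_L_B6,
    F_MU_H1, F_L_H1, F_MU_H2, F_L_H2,
    F_A_PSIJ, F_EPS_PSIJ, F_A_PSIA, F_EPS_PSIA, F_S_PSI,
    F_A_P, F_EPS_P, F_S_P, F_LTAU,
    NFA, NFJ,
)

G = 4
GF = 3
E = 3
PSI_CAP = 0.2

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# scalar math helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


@njit(cache=True, inline="always")
def _log_expit(x):
    if x >= 0.0:
        return -math.log1p(math.exp(-x))
    return x - math.log1p(math.exp(x))


@njit(cache=True, inline="always")
def _pois_lpmf(k, lam):
    if lam <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    return k * math.log(lam) - lam - math.lgamma(k + 1.0)


@njit(cache=True, inline="always")
def _binom_lpmf(k, n, q):
    if k < 0 or k > n:
        return NEG_INF
    if q <= 0.0:
        return 0.0 if k == 0 else NEG_INF
    if q >= 1.0:
        return 0.0 if k == n else NEG_INF
    return (math.lgamma(n + 1.0) - math.lgamma(k + 1.0) - math.lgamma(n - k + 1.0)
            + k * math.log(q) + (n - k) * math.log1p(-q))


@njit(cache=True, inline="always")
def _lognorm_lpdf(y, mu_log, tau):
    ly = math.log(y)
    return -0.5 * math.log(2.0 * math.pi * tau) - ly \
        - 0.5 * (ly - mu_log) * (ly - mu_log) / tau


@njit(cache=True, inline="always")
def _pr01(x):
    # U(0,1) prior on expit(x) plus the logit Jacobian
    return _log_expit(x) + _log_expit(-x)


@njit(cache=True, inline="always")
def _norm_lpdf(x, mu, sd):
    z = (x - mu) / sd
    return -math.log(sd) - 0.5 * z * z - 0.9189385332046727


@njit(cache=True, inline="always")
def _laplace_lpdf(x, mu, b):
    return -math.log(2.0 * b) - abs(x - mu) / b


# ---------------------------------------------------------------------------
# rate-cache builders
# ---------------------------------------------------------------------------

@njit(cache=True)
def upd_gamma_row(hv, off, X, gamma, i):
    T = gamma.shape[1]
    la = _log_expit(hv[off[F_A_GAM] + i])
    b0 = hv[off[F_B_FEC] + 4 * i]
    b1 = hv[off[F_B_FEC] + 4 * i + 1]
    b2 = hv[off[F_B_FEC] + 4 * i + 2]
    b3 = hv[off[F_B_FEC] + 4 * i + 3]
    e0 = off[F_EPS_GAM] + i * T
    for t in range(T):
        lp = la + b0 * X[0, i, t] + b1 * X[1, i, t] + b2 * X[2, i, t] \
            + b3 * X[3, i, t] + hv[e0 + t]
        gamma[i, t] = math.exp(lp)


@njit(cache=True)
def _phiJ_lp(hv, off, storms, hlev, g, t, Ti):
    lp = hv[off[F_A_PHIJ] + g] + hv[off[F_B5] + g] * storms[g, t] \
        + hv[off[F_EPS_PHIJ] + g * Ti + t]
    h = hlev[t]
    if h > 0:
        lp += hv[off[F_HUNT1] + 2 * g + (h - 1)]
    return lp


@njit(cache=True)
def upd_phiJ_cell(hv, off, storms, hlev, lpJ, phiJ, g, t):
    Ti = phiJ.shape[1]
    lpJ[g, t] = _phiJ_lp(hv, off, storms, hlev, g, t, Ti)
    phiJ[g, t] = _expit(lpJ[g, t])
    phiJ[E, t] = _expit((lpJ[0, t] + lpJ[1, t] + lpJ[2, t]) / 3.0)


@njit(cache=True)
def upd_phiJ_row(hv, off, storms, hlev, lpJ, phiJ, g):
    Ti = phiJ.shape[1]
    for t in range(Ti):
        upd_phiJ_cell(hv, off, storms, hlev, lpJ, phiJ, g, t)


@njit(cache=True)
def upd_phiA_row(hv, off, storms, hlev, phiA, g):
    Ti = phiA.shape[1]
    for t in range(Ti):
        lp = hv[off[F_A_PHIA] + g] + hv[off[F_B6] + g] * storms[g, t] \
            + hv[off[F_EPS_PHIA] + g * Ti + t]
        h = hlev[t]
        if h > 0:
            lp += hv[off[F_HUNT2] + 2 * g + (h - 1)]
        phiA[g, t] = _expit(lp)


@njit(cache=True, inline="always")
def _psi_logit_alpha(a_tr):
    # stored value is logit(alpha / 0.2); return logit(alpha)
    alpha = PSI_CAP * _expit(a_tr)
    return math.log(alpha) - math.log1p(-alpha)


@njit(cache=True)
def upd_psiJ_flow(hv, off, psiJ, f):
    Ti = psiJ.shape[1]
    la = _psi_logit_alpha(hv[off[F_A_PSIJ] + f])
    e0 = off[F_EPS_PSIJ] + f * Ti
    for t in range(Ti):
        psiJ[f, t] = _expit(la + hv[e0 + t])


@njit(cache=True)
def upd_psiA_flow(hv, off, psiA, f):
    Ti = psiA.shape[1]
    la = _psi_logit_alpha(hv[off[F_A_PSIA] + f])
    e0 = off[F_EPS_PSIA] + f * Ti
    for t in range(Ti):
        psiA[f, t] = _expit(la + hv[e0 + t])


@njit(cache=True)
def upd_fidJ_row(psiJ, fidJ, outJ_ptr, outJ_f, g):
    """Recompute juvenile fidelity of group g; returns the minimum value."""
    Ti = fidJ.shape[1]
    mn = 1.0
    for t in range(Ti):
        s = 1.0
        for k in range(outJ_ptr[g], outJ_ptr[g + 1]):
            s -= psiJ[outJ_f[k], t]
        fidJ[g, t] = s
        if s < mn:
            mn = s
    return mn


@njit(cache=True)
def upd_fidA_row(psiA, fidA, outA_ptr, outA_f, g):
    Ti = fidA.shape[1]
    mn = 1.0
    for t in range(Ti):
        s = 1.0
        for k in range(outA_ptr[g], outA_ptr[g + 1]):
            s -= psiA[outA_f[k], t]
        fidA[g, t] = s
        if s < mn:
            mn = s
    return mn


@njit(cache=True)
def upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, s):
    """Adult transition matrices: MA[t, s, j] = Pr(alive in j | in s)."""
    Ti = phiA.shape[1]
    for t in range(Ti):
        for j in range(G):
            MA[t, s, j] = 0.0
        MA[t, s, s] = phiA[s, t] * fidA[s, t]
        for k in range(outA_ptr[s], outA_ptr[s + 1]):
            MA[t, s, outA_d[k]] = phiA[s, t] * psiA[outA_f[k], t]


@njit(cache=True)
def upd_pdet_row(hv, off, pdet, g):
    T = pdet.shape[1]
    a = hv[off[F_A_P] + g]
    e0 = off[F_EPS_P] + g * T
    for t in range(T):
        pdet[g, t] = _expit(a + hv[e0 + t])


@njit(cache=True)
def rebuild_all_rates(hv, off, X, storms, hlev, gamma, lpJ, phiJ, phiA,
                      psiJ, psiA, fidJ, fidA, pdet, MA,
                      outJ_ptr, outJ_f, outA_ptr, outA_f, outA_d):
    ok = True
    for i in range(G):
        upd_gamma_row(hv, off, X, gamma, i)
        upd_phiA_row(hv, off, storms, hlev, phiA, i)
        upd_pdet_row(hv, off, pdet, i)
    for g in range(GF):
        upd_phiJ_row(hv, off, storms, hlev, lpJ, phiJ, g)
    for f in range(NFJ):
        upd_psiJ_flow(hv, off, psiJ, f)
    for f in range(NFA):
        upd_psiA_flow(hv, off, psiA, f)
    for g in range(G):
        if upd_fidJ_row(psiJ, fidJ, outJ_ptr, outJ_f, g) <= 0.0:
            ok = False
        if upd_fidA_row(psiA, fidA, outA_ptr, outA_f, g) <= 0.0:
            ok = False
    for s in range(G):
        upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, s)
    return ok


# ---------------------------------------------------------------------------
# process / observation likelihood terms
# ---------------------------------------------------------------------------

@njit(cache=True)
def f_llJ(J, A, gamma, i, t):
    return _pois_lpmf(J[i, t], A[i, t] * gamma[i, t])


@njit(cache=True)
def f_llN1(J, N1, phiJ, fidJ, i, t):
    if t == 0:
        return 0.0
    return _binom_lpmf(N1[i, t], J[i, t - 1], phiJ[i, t - 1] * fidJ[i, t - 1])


@njit(cache=True)
def f_llNad(A, Nad, phiA, fidA, i, t):
    if t == 0:
        return 0.0
    return _binom_lpmf(Nad[i, t], A[i, t - 1], phiA[i, t - 1] * fidA[i, t - 1])


@njit(cache=True)
def f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
          inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t):
    if t == 0:
        return 0.0
    lam = 0.0
    for k in range(inJ_ptr[i], inJ_ptr[i + 1]):
        s = inJ_s[k]
        lam += phiJ[s, t - 1] * psiJ[inJ_f[k], t - 1] * J[s, t - 1]
    for k in range(inA_ptr[i], inA_ptr[i + 1]):
        s = inA_s[k]
        lam += phiA[s, t - 1] * psiA[inA_f[k], t - 1] * A[s, t - 1]
    return _pois_lpmf(I[i, t], lam)


@njit(cache=True)
def f_llY(J, A, yobs, tau, i, t):
    y = yobs[i, t]
    if np.isnan(y):
        return 0.0
    ntot = J[i, t] + A[i, t]
    if ntot <= 0:
        return NEG_INF
    return _lognorm_lpdf(y, math.log(ntot), tau)


@njit(cache=True)
def f_llJobs(J, jobs, i, t):
    jo = jobs[i, t]
    if np.isnan(jo):
        return 0.0
    return _pois_lpmf(jo, float(J[i, t]))


@njit(cache=True)
def sl_llJ_row(J, A, gamma, i):
    T = J.shape[1]
    s = 0.0
    for t in range(T):
        s += f_llJ(J, A, gamma, i, t)
    return s


@njit(cache=True)
def sl_llN1_row(J, N1, phiJ, fidJ, i):
    T = J.shape[1]
    s = 0.0
    for t in range(1, T):
        s += f_llN1(J, N1, phiJ, fidJ, i, t)
    return s


@njit(cache=True)
def sl_llNad_row(A, Nad, phiA, fidA, i):
    T = A.shape[1]
    s = 0.0
    for t in range(1, T):
        s += f_llNad(A, Nad, phiA, fidA, i, t)
    return s


@njit(cache=True)
def sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
               inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i):
    T = J.shape[1]
    s = 0.0
    for t in range(1, T):
        s += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                   inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t)
    return s


@njit(cache=True)
def sl_llY_all(J, A, yobs, tau):
    s = 0.0
    for i in range(G):
        for t in range(J.shape[1]):
            s += f_llY(J, A, yobs, tau, i, t)
    return s


# ---------------------------------------------------------------------------
# m-array likelihood
# ---------------------------------------------------------------------------

@njit(cache=True)
def marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                  outJ_ptr, outJ_f, outJ_d,
                  row_ptr, nz_cell, nz_cnt, nev_cnt, r, isjuv, g, y, T, qbuf):
    """Log-likelihood contribution of one release row (constants dropped).

    ``qbuf`` is caller-provided scratch of length 2·G (avoids per-row
    allocations in the sampler's hot loop)."""
    q = qbuf[:G]
    qn = qbuf[G:2 * G]
    for j in range(G):
        q[j] = 0.0
    # first interval, age-specific
    if isjuv:
        q[g] = phiJ[g, y] * fidJ[g, y]
        for k in range(outJ_ptr[g], outJ_ptr[g + 1]):
            q[outJ_d[k]] = phiJ[g, y] * psiJ[outJ_f[k], y]
    else:
        for j in range(G):
            q[j] = MA[y, g, j]
    ll = 0.0
    surv = 0.0
    k = row_ptr[r]
    kend = row_ptr[r + 1]
    for u in range(y + 1, T):
        base = (u - 1) * G
        for j in range(G):
            surv += q[j] * pdet[j, u]
        while k < kend and nz_cell[k] < base + G:
            j = nz_cell[k] - base
            det = q[j] * pdet[j, u]
            if det <= 0.0:
                return NEG_INF
            ll += nz_cnt[k] * math.log(det)
            k += 1
        if u < T - 1:
            qsum = 0.0
            for j in range(G):
                q[j] *= 1.0 - pdet[j, u]
                qsum += q[j]
            # once every counted cell is consumed and the surviving
            # undetected mass is negligible, the remaining terms change the
            # log-likelihood by < 1e-13 — stop early
            if k == kend and qsum < 1e-13:
                break
            for j in range(G):
                acc = 0.0
                for s in range(G):
                    acc += q[s] * MA[u, s, j]
                qn[j] = acc
            for j in range(G):
                q[j] = qn[j]
    if nev_cnt[r] > 0:
        nev = 1.0 - surv
        if nev <= 0.0:
            return NEG_INF
        ll += nev_cnt[r] * math.log(nev)
    return ll


@njit(cache=True)
def marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                 outJ_ptr, outJ_f, outJ_d,
                 row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll_out, T):
    Ti = T - 1
    tot = 0.0
    qbuf = np.empty(2 * G)
    # juvenile rows
    for g in range(GF):
        for y in range(Ti):
            r = g * Ti + y
            if row_tot[r] == 0:
                rowll_out[r] = 0.0
                continue
            v = marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                              outJ_ptr, outJ_f, outJ_d,
                              row_ptr, nz_cell, nz_cnt, nev_cnt,
                              r, True, g, y, T, qbuf)
            rowll_out[r] = v
            tot += v
    for g in range(G):
        for y in range(Ti):
            r = GF * Ti + g * Ti + y
            if row_tot[r] == 0:
                rowll_out[r] = 0.0
                continue
            v = marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                              outJ_ptr, outJ_f, outJ_d,
                              row_ptr, nz_cell, nz_cnt, nev_cnt,
                              r, False, g, y, T, qbuf)
            rowll_out[r] = v
            tot += v
    return tot


@njit(cache=True)
def marray_jrows(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                 outJ_ptr, outJ_f, outJ_d,
                 row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, g, T, buf):
    """Sum and per-row values of group-g juvenile rows (buffer length T−1)."""
    Ti = T - 1
    tot = 0.0
    qbuf = np.empty(2 * G)
    for y in range(Ti):
        r = g * Ti + y
        if row_tot[r] == 0:
            buf[y] = 0.0
            continue
        v = marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                          outJ_ptr, outJ_f, outJ_d,
                          row_ptr, nz_cell, nz_cnt, nev_cnt, r, True, g, y, T,
                          qbuf)
        buf[y] = v
        tot += v
    return tot


@njit(cache=True)
def total_components(J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA,
                     fidJ, fidA, pdet, MA, yobs, jobs, tau,
                     inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
                     outJ_ptr, outJ_f, outJ_d,
                     row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll):
    """(process, counts, juveniles, m-array) log-likelihood totals."""
    T = J.shape[1]
    proc = 0.0
    for i in range(G):
        proc += sl_llJ_row(J, A, gamma, i)
        proc += sl_llN1_row(J, N1, phiJ, fidJ, i)
        proc += sl_llNad_row(A, Nad, phiA, fidA, i)
        proc += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                           inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i)
    cnt = sl_llY_all(J, A, yobs, tau)
    juv = 0.0
    for i in range(G):
        for t in range(T):
            juv += f_llJobs(J, jobs, i, t)
    marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                        outJ_ptr, outJ_f, outJ_d,
                        row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll, T)
    return proc, cnt, juv, marr


@njit(cache=True)
def _gibbs_sigma_z(S, n, cap, z_cur):
    """Exact draw of a year-effect scale from its full conditional.

    With sigma ~ Uniform(0, cap) and eps_t ~ N(0, sigma), the conditional of
    u = sigma^2 is InverseGamma((n-1)/2, S/2) truncated to (0, cap^2); the
    likelihood does not involve sigma.  Returns the stored transform
    logit(sigma/cap); keeps the current value if the truncation rejects 200
    proposals (essentially impossible away from degenerate states).
    """
    shape = 0.5 * (n - 1)
    for _ in range(200):
        g = np.random.gamma(shape)
        if g <= 0.0:
            continue
        u = 0.5 * S / g
        sig = math.sqrt(u)
        if sig < cap:
            r = sig / cap
            if r < 1e-12:
                r = 1e-12
            return math.log(r) - math.log1p(-r)
    return z_cur


# ---------------------------------------------------------------------------
# latent-state local sums
# ---------------------------------------------------------------------------

@njit(cache=True)
def lat_sum_J(J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA, fidJ, fidA,
              yobs, jobs, tau,
              inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t):
    """Every term that depends on J[i, t]."""
    T = J.shape[1]
    s = f_llJ(J, A, gamma, i, t) + f_llJobs(J, jobs, i, t) \
        + f_llY(J, A, yobs, tau, i, t)
    if t < T - 1:
        s += f_llN1(J, N1, phiJ, fidJ, i, t + 1)
        if i < GF:   # juvenile outflow feeds other groups' immigration
            for j in range(G):
                if j != i:
                    s += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                               inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
                               j, t + 1)
    return s


@njit(cache=True)
def lat_sum_Acommon(J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA,
                    fidJ, fidA, yobs, tau,
                    inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t):
    """Terms that depend on A[i, t] (shared by N1/Nad/I updates)."""
    T = J.shape[1]
    s = f_llJ(J, A, gamma, i, t) + f_llY(J, A, yobs, tau, i, t)
    if t < T - 1:
        s += f_llNad(A, Nad, phiA, fidA, i, t + 1)
        for j in range(G):
            if j != i:
                s += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                           inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
                           j, t + 1)
    return s


# ---------------------------------------------------------------------------
# the full sweep
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_chain(seed, n_iter, n_burn, thin,
              hv, off,
              J, N1, Nad, I, A, A1,
              gamma, lpJ, phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
              X, storms, hlev, yobs, jobs,
              row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot, rowll, rowll_new,
              outJ_ptr, outJ_f, outJ_d, outA_ptr, outA_f, outA_d,
              inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
              flowJ_s, flowJ_d, flowA_s, flowA_d,
              A1_lo, A1_hi,
              ls, ls_blk, ls_lat, ls_A1, ls_shift, ls_ex,
              out_hv, out_lat):
    np.random.seed(seed)
    T = J.shape[1]
    Ti = T - 1
    TARGET = 0.44
    TARGET_BLK = 0.23

    cur_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                            outJ_ptr, outJ_f, outJ_d,
                            row_ptr, nz_cell, nz_cnt, nev_cnt, row_tot,
                            rowll, T)

    # scratch buffers
    bgam = np.empty(T)
    blpJ = np.empty(Ti)
    bphiJg = np.empty(Ti)
    bphiJE = np.empty(Ti)
    bphiA = np.empty(Ti)
    bpsi = np.empty(Ti)
    bfid = np.empty(Ti)
    bMA = np.empty((Ti, G))
    bpdet = np.empty(T)
    bjll = np.empty(Ti)
    beps = np.empty(T)
    qbuf = np.empty(2 * G)

    kept = 0
    for it in range(n_iter):
        gain = (20.0 + it) ** -0.6

        # === 1. fecundity ===============================================
        for i in range(G):
            for k in range(5):
                if k == 0:
                    idx = off[F_A_GAM] + i
                else:
                    idx = off[F_B_FEC] + 4 * i + (k - 1)
                old = hv[idx]
                if k == 0:
                    dpr = -_pr01(old)
                else:
                    dpr = -_norm_lpdf(old, 0.0, 10.0)
                old_ll = sl_llJ_row(J, A, gamma, i)
                hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
                if k == 0:
                    dpr += _pr01(hv[idx])
                else:
                    dpr += _norm_lpdf(hv[idx], 0.0, 10.0)
                for t in range(T):
                    bgam[t] = gamma[i, t]
                upd_gamma_row(hv, off, X, gamma, i)
                new_ll = sl_llJ_row(J, A, gamma, i)
                acc = 0.0
                if math.log(np.random.random()) < dpr + new_ll - old_ll:
                    acc = 1.0
                else:
                    hv[idx] = old
                    for t in range(T):
                        gamma[i, t] = bgam[t]
                ls[idx] += gain * (acc - TARGET)

        # eps_gamma element-wise
        sgam = 10.0 * _expit(hv[off[F_S_GAM]])
        for i in range(G):
            for t in range(T):
                idx = off[F_EPS_GAM] + i * T + t
                old = hv[idx]
                old_ll = f_llJ(J, A, gamma, i, t)
                oldg = gamma[i, t]
                new = old + math.exp(ls[idx]) * np.random.normal()
                hv[idx] = new
                gamma[i, t] = oldg * math.exp(new - old)
                new_ll = f_llJ(J, A, gamma, i, t)
                dpr = (old * old - new * new) / (2.0 * sgam * sgam)
                acc = 0.0
                if math.log(np.random.random()) < dpr + new_ll - old_ll:
                    acc = 1.0
                else:
                    hv[idx] = old
                    gamma[i, t] = oldg
                ls[idx] += gain * (acc - TARGET)

        # sigma_gamma: exact Gibbs draw from its truncated conditional
        S = 0.0
        for k in range(off[F_EPS_GAM], off[F_EPS_GAM] + G * T):
            S += hv[k] * hv[k]
        hv[off[F_S_GAM]] = _gibbs_sigma_z(S, G * T, 10.0, hv[off[F_S_GAM]])

        # === 2. juvenile survival =======================================
        sphiJ = 10.0 * _expit(hv[off[F_S_PHIJ]])
        for g in range(GF):
            for k in range(4):
                if k == 0:
                    idx = off[F_A_PHIJ] + g
                elif k == 1:
                    idx = off[F_B5] + g
                else:
                    idx = off[F_HUNT1] + 2 * g + (k - 2)
                old = hv[idx]
                if k == 0:
                    dpr = -_pr01(old)
                elif k == 1:
                    b = math.exp(-2.0 * hv[off[F_L_B5]])
                    dpr = -_laplace_lpdf(old, hv[off[F_MU_B5]], b)
                else:
                    h = k - 2
                    b = math.exp(-2.0 * hv[off[F_L_H1] + h])
                    dpr = -_laplace_lpdf(old, hv[off[F_MU_H1] + h], b)
                old_ll = sl_llN1_row(J, N1, phiJ, fidJ, g) \
                    + sl_llN1_row(J, N1, phiJ, fidJ, E)
                for j in range(G):
                    if j != g:
                        old_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                             inJ_ptr, inJ_f, inJ_s,
                                             inA_ptr, inA_f, inA_s, j)
                old_mj = 0.0
                for y in range(Ti):
                    old_mj += rowll[g * Ti + y]
                hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
                if k == 0:
                    dpr += _pr01(hv[idx])
                elif k == 1:
                    b = math.exp(-2.0 * hv[off[F_L_B5]])
                    dpr += _laplace_lpdf(hv[idx], hv[off[F_MU_B5]], b)
                else:
                    h = k - 2
                    b = math.exp(-2.0 * hv[off[F_L_H1] + h])
                    dpr += _laplace_lpdf(hv[idx], hv[off[F_MU_H1] + h], b)
                for t in range(Ti):
                    blpJ[t] = lpJ[g, t]
                    bphiJg[t] = phiJ[g, t]
                    bphiJE[t] = phiJ[E, t]
                upd_phiJ_row(hv, off, storms, hlev, lpJ, phiJ, g)
                new_ll = sl_llN1_row(J, N1, phiJ, fidJ, g) \
                    + sl_llN1_row(J, N1, phiJ, fidJ, E)
                for j in range(G):
                    if j != g:
                        new_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                             inJ_ptr, inJ_f, inJ_s,
                                             inA_ptr, inA_f, inA_s, j)
                new_mj = marray_jrows(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                      pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                      row_ptr, nz_cell, nz_cnt, nev_cnt,
                                      row_tot, g, T, bjll)
                acc = 0.0
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_mj - old_mj:
                    acc = 1.0
                    for y in range(Ti):
                        rowll[g * Ti + y] = bjll[y]
                    cur_marr += new_mj - old_mj
                else:
                    hv[idx] = old
                    for t in range(Ti):
                        lpJ[g, t] = blpJ[t]
                        phiJ[g, t] = bphiJg[t]
                        phiJ[E, t] = bphiJE[t]
                ls[idx] += gain * (acc - TARGET)

        # eps_phiJ element-wise
        for g in range(GF):
            for t in range(Ti):
                idx = off[F_EPS_PHIJ] + g * Ti + t
                r = g * Ti + t
                old = hv[idx]
                old_ll = f_llN1(J, N1, phiJ, fidJ, g, t + 1) \
                    + f_llN1(J, N1, phiJ, fidJ, E, t + 1)
                for j in range(G):
                    if j != g:
                        old_ll += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                        inJ_ptr, inJ_f, inJ_s,
                                        inA_ptr, inA_f, inA_s, j, t + 1)
                old_mr = rowll[r]
                olpJ = lpJ[g, t]
                ophiJg = phiJ[g, t]
                ophiJE = phiJ[E, t]
                new = old + math.exp(ls[idx]) * np.random.normal()
                hv[idx] = new
                upd_phiJ_cell(hv, off, storms, hlev, lpJ, phiJ, g, t)
                new_ll = f_llN1(J, N1, phiJ, fidJ, g, t + 1) \
                    + f_llN1(J, N1, phiJ, fidJ, E, t + 1)
                for j in range(G):
                    if j != g:
                        new_ll += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                        inJ_ptr, inJ_f, inJ_s,
                                        inA_ptr, inA_f, inA_s, j, t + 1)
                if row_tot[r] > 0:
                    new_mr = marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                           pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                           row_ptr, nz_cell, nz_cnt, nev_cnt,
                                           r, True, g, t, T, qbuf)
                else:
                    new_mr = 0.0
                dpr = (old * old - new * new) / (2.0 * sphiJ * sphiJ)
                acc = 0.0
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_mr - old_mr:
                    acc = 1.0
                    rowll[r] = new_mr
                    cur_marr += new_mr - old_mr
                else:
                    hv[idx] = old
                    lpJ[g, t] = olpJ
                    phiJ[g, t] = ophiJg
                    phiJ[E, t] = ophiJE
                ls[idx] += gain * (acc - TARGET)

        # sigma_phiJ: Gibbs
        S = 0.0
        for k in range(off[F_EPS_PHIJ], off[F_EPS_PHIJ] + GF * Ti):
            S += hv[k] * hv[k]
        hv[off[F_S_PHIJ]] = _gibbs_sigma_z(S, GF * Ti, 10.0, hv[off[F_S_PHIJ]])

        # === 3. adult survival ==========================================
        sphiA = 10.0 * _expit(hv[off[F_S_PHIA]])
        for g in range(G):
            for k in range(4):
                if k == 0:
                    idx = off[F_A_PHIA] + g
                elif k == 1:
                    if g % 4 != it % 4:
                        continue
                    idx = off[F_B6] + g
                else:
                    if (2 * g + k - 2) % 4 != it % 4:
                        continue
                    idx = off[F_HUNT2] + 2 * g + (k - 2)
                old = hv[idx]
                if k == 0:
                    dpr = -_pr01(old)
                elif k == 1:
                    b = math.exp(-2.0 * hv[off[F_L_B6]])
                    dpr = -_laplace_lpdf(old, hv[off[F_MU_B6]], b)
                else:
                    h = k - 2
                    b = math.exp(-2.0 * hv[off[F_L_H2] + h])
                    dpr = -_laplace_lpdf(old, hv[off[F_MU_H2] + h], b)
                old_ll = sl_llNad_row(A, Nad, phiA, fidA, g)
                for j in range(G):
                    if j != g:
                        old_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                             inJ_ptr, inJ_f, inJ_s,
                                             inA_ptr, inA_f, inA_s, j)
                hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
                if k == 0:
                    dpr += _pr01(hv[idx])
                elif k == 1:
                    b = math.exp(-2.0 * hv[off[F_L_B6]])
                    dpr += _laplace_lpdf(hv[idx], hv[off[F_MU_B6]], b)
                else:
                    h = k - 2
                    b = math.exp(-2.0 * hv[off[F_L_H2] + h])
                    dpr += _laplace_lpdf(hv[idx], hv[off[F_MU_H2] + h], b)
                for t in range(Ti):
                    bphiA[t] = phiA[g, t]
                    for j in range(G):
                        bMA[t, j] = MA[t, g, j]
                upd_phiA_row(hv, off, storms, hlev, phiA, g)
                upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, g)
                new_ll = sl_llNad_row(A, Nad, phiA, fidA, g)
                for j in range(G):
                    if j != g:
                        new_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                             inJ_ptr, inJ_f, inJ_s,
                                             inA_ptr, inA_f, inA_s, j)
                new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                        pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                        row_ptr, nz_cell, nz_cnt, nev_cnt,
                                        row_tot, rowll_new, T)
                acc = 0.0
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_marr - cur_marr:
                    acc = 1.0
                    for r in range(rowll.shape[0]):
                        rowll[r] = rowll_new[r]
                    cur_marr = new_marr
                else:
                    hv[idx] = old
                    for t in range(Ti):
                        phiA[g, t] = bphiA[t]
                        for j in range(G):
                            MA[t, g, j] = bMA[t, j]
                ls[idx] += gain * (acc - TARGET)

        # eps_phiA blocks (two groups per iteration)
        for g in range(G):
            if g % 2 != it % 2:
                continue
            blk = g
            step = math.exp(ls_blk[blk])
            e0 = off[F_EPS_PHIA] + g * Ti
            dpr = 0.0
            for t in range(Ti):
                beps[t] = hv[e0 + t]
            old_ll = sl_llNad_row(A, Nad, phiA, fidA, g)
            for j in range(G):
                if j != g:
                    old_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                         inJ_ptr, inJ_f, inJ_s,
                                         inA_ptr, inA_f, inA_s, j)
            for t in range(Ti):
                new = beps[t] + step * np.random.normal()
                hv[e0 + t] = new
                dpr += (beps[t] * beps[t] - new * new) / (2.0 * sphiA * sphiA)
            for t in range(Ti):
                bphiA[t] = phiA[g, t]
                for j in range(G):
                    bMA[t, j] = MA[t, g, j]
            upd_phiA_row(hv, off, storms, hlev, phiA, g)
            upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, g)
            new_ll = sl_llNad_row(A, Nad, phiA, fidA, g)
            for j in range(G):
                if j != g:
                    new_ll += sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                         inJ_ptr, inJ_f, inJ_s,
                                         inA_ptr, inA_f, inA_s, j)
            new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                    pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                    row_ptr, nz_cell, nz_cnt, nev_cnt,
                                    row_tot, rowll_new, T)
            acc = 0.0
            if math.log(np.random.random()) < dpr + new_ll - old_ll \
                    + new_marr - cur_marr:
                acc = 1.0
                for r in range(rowll.shape[0]):
                    rowll[r] = rowll_new[r]
                cur_marr = new_marr
            else:
                for t in range(Ti):
                    hv[e0 + t] = beps[t]
                    phiA[g, t] = bphiA[t]
                    for j in range(G):
                        MA[t, g, j] = bMA[t, j]
            ls_blk[blk] += gain * (acc - TARGET_BLK)

        # sigma_phiA: Gibbs
        S = 0.0
        for k in range(off[F_EPS_PHIA], off[F_EPS_PHIA] + G * Ti):
            S += hv[k] * hv[k]
        hv[off[F_S_PHIA]] = _gibbs_sigma_z(S, G * Ti, 10.0, hv[off[F_S_PHIA]])

        # === 4. shrinkage hyperpriors (prior-only moves) =================
        # (mu, log-lambda) pairs for b5, b6, hunt1 levels, hunt2 levels
        for fam in range(6):
            if fam == 0:
                mu_i = off[F_MU_B5]
                l_i = off[F_L_B5]
                c0 = off[F_B5]
                nc = GF
            elif fam == 1:
                mu_i = off[F_MU_B6]
                l_i = off[F_L_B6]
                c0 = off[F_B6]
                nc = G
            elif fam <= 3:
                h = fam - 2
                mu_i = off[F_MU_H1] + h
                l_i = off[F_L_H1] + h
                c0 = -1
                nc = GF
            else:
                h = fam - 4
                mu_i = off[F_MU_H2] + h
                l_i = off[F_L_H2] + h
                c0 = -2
                nc = G
            for which in range(2):
                idx = mu_i if which == 0 else l_i
                old = hv[idx]
                new = old + math.exp(ls[idx]) * np.random.normal()
                mu_o = hv[mu_i]
                lam_o = math.exp(hv[l_i])
                if which == 0:
                    mu_n, lam_n = new, lam_o
                    dpr = _norm_lpdf(new, 0.0, 1.0) - _norm_lpdf(old, 0.0, 1.0)
                else:
                    mu_n, lam_n = mu_o, math.exp(new)
                    # Exponential(0.1) on lambda plus log Jacobian
                    dpr = -0.1 * (lam_n - lam_o) + (new - old)
                b_o = 1.0 / (lam_o * lam_o)
                b_n = 1.0 / (lam_n * lam_n)
                for c in range(nc):
                    if c0 == -1:
                        x = hv[off[F_HUNT1] + 2 * c + (fam - 2)]
                    elif c0 == -2:
                        x = hv[off[F_HUNT2] + 2 * c + (fam - 4)]
                    else:
                        x = hv[c0 + c]
                    dpr += _laplace_lpdf(x, mu_n, b_n) - _laplace_lpdf(x, mu_o, b_o)
                acc = 0.0
                if math.log(np.random.random()) < dpr:
                    hv[idx] = new
                    acc = 1.0
                ls[idx] += gain * (acc - TARGET)

        # === 5. juvenile movement =======================================
        spsi = _expit(hv[off[F_S_PSI]])
        for f in range(NFJ):
            s = flowJ_s[f]
            d = flowJ_d[f]
            idx = off[F_A_PSIJ] + f
            old = hv[idx]
            dpr = -_pr01(old)
            old_ll = sl_llN1_row(J, N1, phiJ, fidJ, s) \
                + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                             inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
            old_mj = 0.0
            for y in range(Ti):
                old_mj += rowll[s * Ti + y]
            hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
            dpr += _pr01(hv[idx])
            for t in range(Ti):
                bpsi[t] = psiJ[f, t]
                bfid[t] = fidJ[s, t]
            upd_psiJ_flow(hv, off, psiJ, f)
            ok = upd_fidJ_row(psiJ, fidJ, outJ_ptr, outJ_f, s) > 0.0
            acc = 0.0
            if ok:
                new_ll = sl_llN1_row(J, N1, phiJ, fidJ, s) \
                    + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                 inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
                new_mj = marray_jrows(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                      pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                      row_ptr, nz_cell, nz_cnt, nev_cnt,
                                      row_tot, s, T, bjll)
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_mj - old_mj:
                    acc = 1.0
                    for y in range(Ti):
                        rowll[s * Ti + y] = bjll[y]
                    cur_marr += new_mj - old_mj
            if acc == 0.0:
                hv[idx] = old
                for t in range(Ti):
                    psiJ[f, t] = bpsi[t]
                    fidJ[s, t] = bfid[t]
            ls[idx] += gain * (acc - TARGET)

        # eps_psiJ element-wise (half the flows per iteration)
        for f in range(NFJ):
            if f % 2 != it % 2:
                continue
            s = flowJ_s[f]
            d = flowJ_d[f]
            for t in range(Ti):
                idx = off[F_EPS_PSIJ] + f * Ti + t
                r = s * Ti + t
                old = hv[idx]
                old_ll = f_llN1(J, N1, phiJ, fidJ, s, t + 1) \
                    + f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                            inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
                            d, t + 1)
                old_mr = rowll[r]
                opsi = psiJ[f, t]
                ofid = fidJ[s, t]
                new = old + math.exp(ls[idx]) * np.random.normal()
                hv[idx] = new
                la = _psi_logit_alpha(hv[off[F_A_PSIJ] + f])
                psiJ[f, t] = _expit(la + new)
                fidJ[s, t] = ofid + opsi - psiJ[f, t]
                acc = 0.0
                if fidJ[s, t] > 0.0:
                    new_ll = f_llN1(J, N1, phiJ, fidJ, s, t + 1) \
                        + f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s,
                                d, t + 1)
                    if row_tot[r] > 0:
                        new_mr = marray_row_ll(phiJ, phiA, psiJ, psiA, fidJ,
                                               fidA, pdet, MA,
                                               outJ_ptr, outJ_f, outJ_d,
                                               row_ptr, nz_cell, nz_cnt,
                                               nev_cnt, r, True, s, t, T, qbuf)
                    else:
                        new_mr = 0.0
                    dpr = (old * old - new * new) / (2.0 * spsi * spsi)
                    if math.log(np.random.random()) < dpr + new_ll - old_ll \
                            + new_mr - old_mr:
                        acc = 1.0
                        rowll[r] = new_mr
                        cur_marr += new_mr - old_mr
                if acc == 0.0:
                    hv[idx] = old
                    psiJ[f, t] = opsi
                    fidJ[s, t] = ofid
                ls[idx] += gain * (acc - TARGET)

        # === 6. adult movement ==========================================
        for f in range(NFA):
            if f % 3 != (it + 1) % 3:
                continue
            s = flowA_s[f]
            d = flowA_d[f]
            idx = off[F_A_PSIA] + f
            old = hv[idx]
            dpr = -_pr01(old)
            old_ll = sl_llNad_row(A, Nad, phiA, fidA, s) \
                + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                             inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
            hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
            dpr += _pr01(hv[idx])
            for t in range(Ti):
                bpsi[t] = psiA[f, t]
                bfid[t] = fidA[s, t]
                for j in range(G):
                    bMA[t, j] = MA[t, s, j]
            upd_psiA_flow(hv, off, psiA, f)
            ok = upd_fidA_row(psiA, fidA, outA_ptr, outA_f, s) > 0.0
            acc = 0.0
            if ok:
                upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, s)
                new_ll = sl_llNad_row(A, Nad, phiA, fidA, s) \
                    + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                 inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
                new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                        pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                        row_ptr, nz_cell, nz_cnt, nev_cnt,
                                        row_tot, rowll_new, T)
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_marr - cur_marr:
                    acc = 1.0
                    for r in range(rowll.shape[0]):
                        rowll[r] = rowll_new[r]
                    cur_marr = new_marr
            if acc == 0.0:
                hv[idx] = old
                for t in range(Ti):
                    psiA[f, t] = bpsi[t]
                    fidA[s, t] = bfid[t]
                    for j in range(G):
                        MA[t, s, j] = bMA[t, j]
            ls[idx] += gain * (acc - TARGET)

        # eps_psiA blocks (four flows per iteration)
        for f in range(NFA):
            if f % 3 != it % 3:
                continue
            s = flowA_s[f]
            d = flowA_d[f]
            blk = 4 + f
            step = math.exp(ls_blk[blk])
            e0 = off[F_EPS_PSIA] + f * Ti
            dpr = 0.0
            for t in range(Ti):
                beps[t] = hv[e0 + t]
            old_ll = sl_llNad_row(A, Nad, phiA, fidA, s) \
                + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                             inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
            for t in range(Ti):
                new = beps[t] + step * np.random.normal()
                hv[e0 + t] = new
                dpr += (beps[t] * beps[t] - new * new) / (2.0 * spsi * spsi)
            for t in range(Ti):
                bpsi[t] = psiA[f, t]
                bfid[t] = fidA[s, t]
                for j in range(G):
                    bMA[t, j] = MA[t, s, j]
            upd_psiA_flow(hv, off, psiA, f)
            ok = upd_fidA_row(psiA, fidA, outA_ptr, outA_f, s) > 0.0
            acc = 0.0
            if ok:
                upd_MA_row(phiA, psiA, fidA, MA, outA_ptr, outA_f, outA_d, s)
                new_ll = sl_llNad_row(A, Nad, phiA, fidA, s) \
                    + sl_llI_row(J, A, I, phiJ, phiA, psiJ, psiA,
                                 inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, d)
                new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                        pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                        row_ptr, nz_cell, nz_cnt, nev_cnt,
                                        row_tot, rowll_new, T)
                if math.log(np.random.random()) < dpr + new_ll - old_ll \
                        + new_marr - cur_marr:
                    acc = 1.0
                    for r in range(rowll.shape[0]):
                        rowll[r] = rowll_new[r]
                    cur_marr = new_marr
            if acc == 0.0:
                for t in range(Ti):
                    hv[e0 + t] = beps[t]
                    psiA[f, t] = bpsi[t]
                    fidA[s, t] = bfid[t]
                    for j in range(G):
                        MA[t, s, j] = bMA[t, j]
            ls_blk[blk] += gain * (acc - TARGET_BLK)

        # sigma_psi (shared across juvenile and adult flows): Gibbs
        S = 0.0
        for k in range(off[F_EPS_PSIJ], off[F_EPS_PSIJ] + NFJ * Ti):
            S += hv[k] * hv[k]
        for k in range(off[F_EPS_PSIA], off[F_EPS_PSIA] + NFA * Ti):
            S += hv[k] * hv[k]
        hv[off[F_S_PSI]] = _gibbs_sigma_z(S, (NFJ + NFA) * Ti, 1.0,
                                          hv[off[F_S_PSI]])

        # === 7. detection ===============================================
        sp = 10.0 * _expit(hv[off[F_S_P]])
        for g in range(G):
            if g % 2 != it % 2:
                continue
            idx = off[F_A_P] + g
            old = hv[idx]
            dpr = -_pr01(old)
            hv[idx] = old + math.exp(ls[idx]) * np.random.normal()
            dpr += _pr01(hv[idx])
            for t in range(T):
                bpdet[t] = pdet[g, t]
            upd_pdet_row(hv, off, pdet, g)
            new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                    pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                    row_ptr, nz_cell, nz_cnt, nev_cnt,
                                    row_tot, rowll_new, T)
            acc = 0.0
            if math.log(np.random.random()) < dpr + new_marr - cur_marr:
                acc = 1.0
                for r in range(rowll.shape[0]):
                    rowll[r] = rowll_new[r]
                cur_marr = new_marr
            else:
                hv[idx] = old
                for t in range(T):
                    pdet[g, t] = bpdet[t]
            ls[idx] += gain * (acc - TARGET)

        # eps_p blocks
        for g in range(G):
            if g % 2 == it % 2:   # opposite phase to the intercepts
                continue
            blk = 16 + g
            step = math.exp(ls_blk[blk])
            e0 = off[F_EPS_P] + g * T
            dpr = 0.0
            for t in range(T):
                beps[t] = hv[e0 + t]
                bpdet[t] = pdet[g, t]
            for t in range(T):
                new = beps[t] + step * np.random.normal()
                hv[e0 + t] = new
                dpr += (beps[t] * beps[t] - new * new) / (2.0 * sp * sp)
            upd_pdet_row(hv, off, pdet, g)
            new_marr = marray_total(phiJ, phiA, psiJ, psiA, fidJ, fidA,
                                    pdet, MA, outJ_ptr, outJ_f, outJ_d,
                                    row_ptr, nz_cell, nz_cnt, nev_cnt,
                                    row_tot, rowll_new, T)
            acc = 0.0
            if math.log(np.random.random()) < dpr + new_marr - cur_marr:
                acc = 1.0
                for r in range(rowll.shape[0]):
                    rowll[r] = rowll_new[r]
                cur_marr = new_marr
            else:
                for t in range(T):
                    hv[e0 + t] = beps[t]
                    pdet[g, t] = bpdet[t]
            ls_blk[blk] += gain * (acc - TARGET_BLK)

        # sigma_p: Gibbs
        S = 0.0
        for k in range(off[F_EPS_P], off[F_EPS_P] + G * T):
            S += hv[k] * hv[k]
        hv[off[F_S_P]] = _gibbs_sigma_z(S, G * T, 10.0, hv[off[F_S_P]])

        # === 8. count observation variance ==============================
        idx = off[F_LTAU]
        old = hv[idx]
        tau_o = math.exp(old)
        old_ll = sl_llY_all(J, A, yobs, tau_o)
        new = old + math.exp(ls[idx]) * np.random.normal()
        tau_n = math.exp(new)
        new_ll = sl_llY_all(J, A, yobs, tau_n)
        # InverseGamma(0.01, 0.01) plus log Jacobian
        dpr = -0.01 * (new - old) - 0.01 * (1.0 / tau_n - 1.0 / tau_o)
        acc = 0.0
        if math.log(np.random.random()) < dpr + new_ll - old_ll:
            hv[idx] = new
            acc = 1.0
        ls[idx] += gain * (acc - TARGET)
        tau = math.exp(hv[idx])

        # === 8b. intercept/year-effect translation moves =================
        # the likelihood constrains only (intercept + mean year effect); a
        # joint shift leaves every rate unchanged, so only the priors (and,
        # for non-additive transforms, a Jacobian) enter the ratio.  These
        # moves decorrelate the intercepts from their year effects.
        sgam = 10.0 * _expit(hv[off[F_S_GAM]])
        sphiJ = 10.0 * _expit(hv[off[F_S_PHIJ]])
        sphiA = 10.0 * _expit(hv[off[F_S_PHIA]])
        spsi = _expit(hv[off[F_S_PSI]])
        sp = 10.0 * _expit(hv[off[F_S_P]])
        for i in range(G):
            # fecundity: log-intercept shift, multiplicative on alpha
            sh = i
            delta = math.exp(ls_shift[sh]) * np.random.normal()
            x = hv[off[F_A_GAM] + i]
            a = _expit(x)
            an = a * math.exp(delta)
            acc = 0.0
            if an < 1.0:
                e0 = off[F_EPS_GAM] + i * T
                se = 0.0
                for t in range(T):
                    se += hv[e0 + t]
                dpr = (2.0 * delta * se - T * delta * delta) / (2.0 * sgam * sgam)
                xn = math.log(an) - math.log1p(-an)
                dpr += _pr01(xn) - _pr01(x)
                dpr += math.log1p(-a) - math.log1p(-an)   # d x'/d x
                if math.log(np.random.random()) < dpr:
                    acc = 1.0
                    hv[off[F_A_GAM] + i] = xn
                    for t in range(T):
                        hv[e0 + t] -= delta
            ls_shift[sh] += gain * (acc - TARGET)

        for g in range(GF):
            # juvenile survival: additive logit shift
            sh = 4 + g
            delta = math.exp(ls_shift[sh]) * np.random.normal()
            x = hv[off[F_A_PHIJ] + g]
            e0 = off[F_EPS_PHIJ] + g * Ti
            se = 0.0
            for t in range(Ti):
                se += hv[e0 + t]
            dpr = (2.0 * delta * se - Ti * delta * delta) \
                / (2.0 * sphiJ * sphiJ)
            dpr += _pr01(x + delta) - _pr01(x)
            acc = 0.0
            if math.log(np.random.random()) < dpr:
                acc = 1.0
                hv[off[F_A_PHIJ] + g] = x + delta
                for t in range(Ti):
                    hv[e0 + t] -= delta
            ls_shift[sh] += gain * (acc - TARGET)

        for g in range(G):
            sh = 7 + g
            delta = math.exp(ls_shift[sh]) * np.random.normal()
            x = hv[off[F_A_PHIA] + g]
            e0 = off[F_EPS_PHIA] + g * Ti
            se = 0.0
            for t in range(Ti):
                se += hv[e0 + t]
            dpr = (2.0 * delta * se - Ti * delta * delta) \
                / (2.0 * sphiA * sphiA)
            dpr += _pr01(x + delta) - _pr01(x)
            acc = 0.0
            if math.log(np.random.random()) < dpr:
                acc = 1.0
                hv[off[F_A_PHIA] + g] = x + delta
                for t in range(Ti):
                    hv[e0 + t] -= delta
            ls_shift[sh] += gain * (acc - TARGET)

        for f in range(NFJ + NFA):
            # movement: shift on logit(alpha), alpha bounded by the 0.2 cap
            sh = 11 + f
            if f < NFJ:
                idx = off[F_A_PSIJ] + f
                e0 = off[F_EPS_PSIJ] + f * Ti
            else:
                idx = off[F_A_PSIA] + (f - NFJ)
                e0 = off[F_EPS_PSIA] + (f - NFJ) * Ti
            delta = math.exp(ls_shift[sh]) * np.random.normal()
            x = hv[idx]
            alpha = PSI_CAP * _expit(x)
            la_n = math.log(alpha) - math.log1p(-alpha) + delta
            an = _expit(la_n)
            acc = 0.0
            if an < PSI_CAP:
                se = 0.0
                for t in range(Ti):
                    se += hv[e0 + t]
                dpr = (2.0 * delta * se - Ti * delta * delta) \
                    / (2.0 * spsi * spsi)
                xn = math.log(an / PSI_CAP) - math.log1p(-an / PSI_CAP)
                dpr += _pr01(xn) - _pr01(x)
                # Jacobian of x -> x' through the logit(alpha) shift
                dpr += (math.log1p(-alpha / PSI_CAP) - math.log1p(-alpha)
                        + math.log1p(-an) - math.log1p(-an / PSI_CAP))
                if math.log(np.random.random()) < dpr:
                    acc = 1.0
                    hv[idx] = xn
                    for t in range(Ti):
                        hv[e0 + t] -= delta
            ls_shift[sh] += gain * (acc - TARGET)

        for g in range(G):
            sh = 32 + g
            delta = math.exp(ls_shift[sh]) * np.random.normal()
            x = hv[off[F_A_P] + g]
            e0 = off[F_EPS_P] + g * T
            se = 0.0
            for t in range(T):
                se += hv[e0 + t]
            dpr = (2.0 * delta * se - T * delta * delta) / (2.0 * sp * sp)
            dpr += _pr01(x + delta) - _pr01(x)
            acc = 0.0
            if math.log(np.random.random()) < dpr:
                acc = 1.0
                hv[off[F_A_P] + g] = x + delta
                for t in range(T):
                    hv[e0 + t] -= delta
            ls_shift[sh] += gain * (acc - TARGET)

        # hunting intercepts vs their period's year effects (likelihood-free)
        for fam in range(2):
            nG = GF if fam == 0 else G
            sig = sphiJ if fam == 0 else sphiA
            for g in range(nG):
                for hlv in range(1, 3):
                    delta = 0.3 * np.random.normal()
                    if fam == 0:
                        hidx = off[F_HUNT1] + 2 * g + (hlv - 1)
                        e0 = off[F_EPS_PHIJ] + g * Ti
                        b = math.exp(-2.0 * hv[off[F_L_H1] + hlv - 1])
                        mu = hv[off[F_MU_H1] + hlv - 1]
                    else:
                        hidx = off[F_HUNT2] + 2 * g + (hlv - 1)
                        e0 = off[F_EPS_PHIA] + g * Ti
                        b = math.exp(-2.0 * hv[off[F_L_H2] + hlv - 1])
                        mu = hv[off[F_MU_H2] + hlv - 1]
                    se = 0.0
                    nh = 0
                    for t in range(Ti):
                        if hlev[t] == hlv:
                            se += hv[e0 + t]
                            nh += 1
                    if nh == 0:
                        continue
                    x = hv[hidx]
                    dpr = (2.0 * delta * se - nh * delta * delta) \
                        / (2.0 * sig * sig)
                    dpr += _laplace_lpdf(x + delta, mu, b) \
                        - _laplace_lpdf(x, mu, b)
                    if math.log(np.random.random()) < dpr:
                        hv[hidx] = x + delta
                        for t in range(Ti):
                            if hlev[t] == hlv:
                                hv[e0 + t] -= delta

        # === 9. latent states ===========================================
        for i in range(G):
            # initial adults (discrete uniform prior)
            old = A1[i]
            d = int(round(math.exp(ls_A1[i]) * np.random.normal()))
            acc = 0.0
            if d != 0:
                new = old + d
                if A1_lo[i] <= new <= A1_hi[i]:
                    old_ll = f_llY(J, A, yobs, tau, i, 0) \
                        + f_llJ(J, A, gamma, i, 0) \
                        + f_llNad(A, Nad, phiA, fidA, i, 1)
                    for j in range(G):
                        if j != i:
                            old_ll += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, 1)
                    A1[i] = new
                    A[i, 0] = new
                    new_ll = f_llY(J, A, yobs, tau, i, 0) \
                        + f_llJ(J, A, gamma, i, 0) \
                        + f_llNad(A, Nad, phiA, fidA, i, 1)
                    for j in range(G):
                        if j != i:
                            new_ll += f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, 1)
                    if math.log(np.random.random()) < new_ll - old_ll:
                        acc = 1.0
                    else:
                        A1[i] = old
                        A[i, 0] = old
            ls_A1[i] += gain * (acc - TARGET)
            if ls_A1[i] < 0.0:
                ls_A1[i] = 0.0

        for t in range(T):
            for i in range(G):
                # J
                sidx = (0 * G + i) * T + t
                old = J[i, t]
                d = int(round(math.exp(ls_lat[sidx]) * np.random.normal()))
                acc = 0.0
                if d != 0 and old + d >= 0:
                    old_ll = lat_sum_J(J, N1, Nad, I, A, gamma, phiJ, phiA,
                                       psiJ, psiA, fidJ, fidA, yobs, jobs, tau,
                                       inJ_ptr, inJ_f, inJ_s,
                                       inA_ptr, inA_f, inA_s, i, t)
                    J[i, t] = old + d
                    new_ll = lat_sum_J(J, N1, Nad, I, A, gamma, phiJ, phiA,
                                       psiJ, psiA, fidJ, fidA, yobs, jobs, tau,
                                       inJ_ptr, inJ_f, inJ_s,
                                       inA_ptr, inA_f, inA_s, i, t)
                    if math.log(np.random.random()) < new_ll - old_ll:
                        acc = 1.0
                    else:
                        J[i, t] = old
                ls_lat[sidx] += gain * (acc - TARGET)
                if ls_lat[sidx] < -0.7:
                    ls_lat[sidx] = -0.7

                if t == 0:
                    continue
                # N1, Nad, I (stage index 1..3)
                for stg in range(1, 4):
                    sidx = (stg * G + i) * T + t
                    if stg == 1:
                        arr = N1
                    elif stg == 2:
                        arr = Nad
                    else:
                        arr = I
                    old = arr[i, t]
                    d = int(round(math.exp(ls_lat[sidx]) * np.random.normal()))
                    acc = 0.0
                    if d != 0 and old + d >= 0:
                        old_own = 0.0
                        if stg == 1:
                            old_own = f_llN1(J, N1, phiJ, fidJ, i, t)
                        elif stg == 2:
                            old_own = f_llNad(A, Nad, phiA, fidA, i, t)
                        else:
                            old_own = f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, i, t)
                        old_ll = old_own + lat_sum_Acommon(
                            J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA,
                            fidJ, fidA, yobs, tau,
                            inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t)
                        arr[i, t] = old + d
                        A[i, t] += d
                        new_own = 0.0
                        if stg == 1:
                            new_own = f_llN1(J, N1, phiJ, fidJ, i, t)
                        elif stg == 2:
                            new_own = f_llNad(A, Nad, phiA, fidA, i, t)
                        else:
                            new_own = f_llI(J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, i, t)
                        new_ll = new_own + lat_sum_Acommon(
                            J, N1, Nad, I, A, gamma, phiJ, phiA, psiJ, psiA,
                            fidJ, fidA, yobs, tau,
                            inJ_ptr, inJ_f, inJ_s, inA_ptr, inA_f, inA_s, i, t)
                        if math.log(np.random.random()) < new_ll - old_ll:
                            acc = 1.0
                        else:
                            arr[i, t] = old
                            A[i, t] -= d
                    ls_lat[sidx] += gain * (acc - TARGET)
                    if ls_lat[sidx] < -0.7:
                        ls_lat[sidx] = -0.7

                # exchange N1 <-> Nad at fixed A (only the two binomial
                # terms change)
                exidx = (G + i) * T + t
                d = int(round(math.exp(ls_ex[exidx]) * np.random.normal()))
                acc = 0.0
                if d != 0 and N1[i, t] + d >= 0 and Nad[i, t] - d >= 0:
                    old_ll = f_llN1(J, N1, phiJ, fidJ, i, t) \
                        + f_llNad(A, Nad, phiA, fidA, i, t)
                    N1[i, t] += d
                    Nad[i, t] -= d
                    new_ll = f_llN1(J, N1, phiJ, fidJ, i, t) \
                        + f_llNad(A, Nad, phiA, fidA, i, t)
                    if math.log(np.random.random()) < new_ll - old_ll:
                        acc = 1.0
                    else:
                        N1[i, t] -= d
                        Nad[i, t] += d
                ls_ex[exidx] += gain * (acc - TARGET)
                if ls_ex[exidx] < -0.7:
                    ls_ex[exidx] = -0.7

            # exchange J <-> adults at fixed Ntot: traverses the direction
            # the tight count likelihood would otherwise freeze
            for i in range(G):
                exidx = i * T + t
                d = int(round(math.exp(ls_ex[exidx]) * np.random.normal()))
                acc = 0.0
                if d != 0:
                    if t == 0:
                        newA1 = A1[i] - d
                        if J[i, 0] + d >= 0 and A1_lo[i] <= newA1 <= A1_hi[i]:
                            old_ll = f_llJ(J, A, gamma, i, 0) \
                                + f_llJobs(J, jobs, i, 0)
                            if T > 1:
                                old_ll += f_llN1(J, N1, phiJ, fidJ, i, 1) \
                                    + f_llNad(A, Nad, phiA, fidA, i, 1)
                                for j in range(G):
                                    if j != i:
                                        old_ll += f_llI(
                                            J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, 1)
                            J[i, 0] += d
                            A1[i] = newA1
                            A[i, 0] = newA1
                            new_ll = f_llJ(J, A, gamma, i, 0) \
                                + f_llJobs(J, jobs, i, 0)
                            if T > 1:
                                new_ll += f_llN1(J, N1, phiJ, fidJ, i, 1) \
                                    + f_llNad(A, Nad, phiA, fidA, i, 1)
                                for j in range(G):
                                    if j != i:
                                        new_ll += f_llI(
                                            J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, 1)
                            if math.log(np.random.random()) < new_ll - old_ll:
                                acc = 1.0
                            else:
                                J[i, 0] -= d
                                A1[i] = newA1 + d
                                A[i, 0] = newA1 + d
                    else:
                        if J[i, t] + d >= 0 and Nad[i, t] - d >= 0:
                            old_ll = f_llJ(J, A, gamma, i, t) \
                                + f_llJobs(J, jobs, i, t) \
                                + f_llNad(A, Nad, phiA, fidA, i, t)
                            if t < T - 1:
                                old_ll += f_llN1(J, N1, phiJ, fidJ, i, t + 1) \
                                    + f_llNad(A, Nad, phiA, fidA, i, t + 1)
                                for j in range(G):
                                    if j != i:
                                        old_ll += f_llI(
                                            J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, t + 1)
                            J[i, t] += d
                            Nad[i, t] -= d
                            A[i, t] -= d
                            new_ll = f_llJ(J, A, gamma, i, t) \
                                + f_llJobs(J, jobs, i, t) \
                                + f_llNad(A, Nad, phiA, fidA, i, t)
                            if t < T - 1:
                                new_ll += f_llN1(J, N1, phiJ, fidJ, i, t + 1) \
                                    + f_llNad(A, Nad, phiA, fidA, i, t + 1)
                                for j in range(G):
                                    if j != i:
                                        new_ll += f_llI(
                                            J, A, I, phiJ, phiA, psiJ, psiA,
                                            inJ_ptr, inJ_f, inJ_s,
                                            inA_ptr, inA_f, inA_s, j, t + 1)
                            if math.log(np.random.random()) < new_ll - old_ll:
                                acc = 1.0
                            else:
                                J[i, t] -= d
                                Nad[i, t] += d
                                A[i, t] += d
                ls_ex[exidx] += gain * (acc - TARGET)
                if ls_ex[exidx] < -0.7:
                    ls_ex[exidx] = -0.7

        # clamp step sizes
        for k in range(ls.shape[0]):
            if ls[k] < -12.0:
                ls[k] = -12.0
            elif ls[k] > 5.0:
                ls[k] = 5.0
        for k in range(ls_blk.shape[0]):
            if ls_blk[k] < -12.0:
                ls_blk[k] = -12.0
            elif ls_blk[k] > 3.0:
                ls_blk[k] = 3.0
        for k in range(ls_shift.shape[0]):
            if ls_shift[k] < -12.0:
                ls_shift[k] = -12.0
            elif ls_shift[k] > 3.0:
                ls_shift[k] = 3.0

        # === record =====================================================
        if it >= n_burn and (it - n_burn) % thin == 0:
            kq = (it - n_burn) // thin
            if kq < out_hv.shape[0]:
                for k in range(hv.shape[0]):
                    out_hv[kq, k] = hv[k]
                for i in range(G):
                    for t in range(T):
                        out_lat[kq, 0, i, t] = J[i, t]
                        out_lat[kq, 1, i, t] = N1[i, t]
                        out_lat[kq, 2, i, t] = Nad[i, t]
                        out_lat[kq, 3, i, t] = I[i, t]
                    # year-1 adults ride in the structurally-zero I slot so
                    # A = N1 + Nad + I reconstructs in every year
                    out_lat[kq, 3, i, 0] = A1[i]
                kept += 1

    return kept, cur_marr


@njit(cache=True)
def marray_probs_full(phiJ, phiA, psiJ, psiA, fidJ, fidA, pdet, MA,
                      outJ_ptr, outJ_f, outJ_d, T, probs):
    """Cell probabilities for every release row into ``probs`` (R × C)."""
    Ti = T - 1
    R = probs.shape[0]
    for r in range(R):
        if r < GF * Ti:
            isjuv = True
            g = r // Ti
            y = r - g * Ti
        else:
            isjuv = False
            g = (r - GF * Ti) // Ti
            y = (r - GF * Ti) - g * Ti
        for c in range(probs.shape[1]):
            probs[r, c] = 0.0
        q = np.zeros(G)
        if isjuv:
            q[g] = phiJ[g, y] * fidJ[g, y]
            for k in range(outJ_ptr[g], outJ_ptr[g + 1]):
                q[outJ_d[k]] = phiJ[g, y] * psiJ[outJ_f[k], y]
        else:
            for j in range(G):
                q[j] = MA[y, g, j]
        surv = 0.0
        qn = np.zeros(G)
        for u in range(y + 1, T):
            base = (u - 1) * G
            for j in range(G):
                det = q[j] * pdet[j, u]
                probs[r, base + j] = det
                surv += det
            if u < T - 1:
                for j in range(G):
                    q[j] *= 1.0 - pdet[j, u]
                for j in range(G):
                    acc = 0.0
                    for s in range(G):
                        acc += q[s] * MA[u, s, j]
                    qn[j] = acc
                for j in range(G):
                    q[j] = qn[j]
        probs[r, probs.shape[1] - 1] = 1.0 - surv
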