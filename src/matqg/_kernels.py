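"""Numba kernels for the single-site Gibbs location sweeps and the BayesB
marker loop.  Everything here operates on flat index arrays prepared by the
calling modules; residuals are maintained in place (Gauss-Seidel style) so a
full sweep is linear in records plus the non-zeros of A-inverse."""

import numpy as np
from numba import njit


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def location_sweep(
    e,  # (n_rec, t) residuals, updated in place
    R0inv,  # (t, t)
    b,  # (n_levels_total, t) fixed-effect solutions, level 0 of each
    lvl_indptr,  # factor constrained via lvl_free
    lvl_rec,
    lvl_free,  # (n_levels_total,) bool
    u,  # (n_anim, g) genetic effects; g = 0 disables
    eff_trait,  # (g,) trait of each genetic-effect column
    eff_role,  # (g,) 0 = direct, 1 = maternal
    dir_indptr,
    dir_rec,
    mat_indptr,
    mat_rec,
    ai_indptr,
    ai_idx,
    ai_val,  # A-inverse CSR
    G0inv,  # (g, g)
    cvec,  # (n_litters, t); empty disables
    lit_indptr,
    lit_rec,
    Ccinv,
    mevec,  # (n_me, t); empty disables
    me_indptr,
    me_rec,
    Cmeinv,
):
    t = e.shape[1]
    # ---- fixed effects -------------------------------------------------
    for lv in range(b.shape[0]):
        if not lvl_free[lv]:
            continue
        i0, i1 = lvl_indptr[lv], lvl_indptr[lv + 1]
        for tt in range(t):
            old = b[lv, tt]
            prec = (i1 - i0) * R0inv[tt, tt]
            if prec <= 0.0:
                continue
            rhs = 0.0
            for p in range(i0, i1):
                r = lvl_rec[p]
                rhs += R0inv[tt, tt] * (e[r, tt] + old)
                for t2 in range(t):
                    if t2 != tt:
                        rhs += R0inv[tt, t2] * e[r, t2]
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            d = new - old
            for p in range(i0, i1):
                e[lvl_rec[p], tt] -= d
            b[lv, tt] = new
    # ---- genetic effects (direct / maternal, all pedigree animals) -----
    g = u.shape[1]
    n_anim = u.shape[0]
    for i in range(n_anim):
        for k in range(g):
            tt = eff_trait[k]
            if eff_role[k] == 0:
                i0, i1 = dir_indptr[i], dir_indptr[i + 1]
                recs = dir_rec
            else:
                i0, i1 = mat_indptr[i], mat_indptr[i + 1]
                recs = mat_rec
            old = u[i, k]
            prec = (i1 - i0) * R0inv[tt, tt]
            rhs = 0.0
            for p in range(i0, i1):
                r = recs[p]
                rhs += R0inv[tt, tt] * (e[r, tt] + old)
                for t2 in range(t):
                    if t2 != tt:
                        rhs += R0inv[tt, t2] * e[r, t2]
            a0, a1 = ai_indptr[i], ai_indptr[i + 1]
            for p in range(a0, a1):
                j = ai_idx[p]
                aij = ai_val[p]
                for l in range(g):
                    if j == i and l == k:
                        prec += aij * G0inv[k, k]
                    else:
                        rhs -= aij * G0inv[k, l] * u[j, l]
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            d = new - old
            for p in range(i0, i1):
                e[recs[p], tt] -= d
            u[i, k] = new
    # ---- common litter effects ----------------------------------------
    for lit in range(cvec.shape[0]):
        i0, i1 = lit_indptr[lit], lit_indptr[lit + 1]
        for tt in range(t):
            old = cvec[lit, tt]
            prec = (i1 - i0) * R0inv[tt, tt] + Ccinv[tt, tt]
            rhs = 0.0
            for p in range(i0, i1):
                r = lit_rec[p]
                rhs += R0inv[tt, tt] * (e[r, tt] + old)
                for t2 in range(t):
                    if t2 != tt:
                        rhs += R0inv[tt, t2] * e[r, t2]
            for t2 in range(t):
                if t2 != tt:
                    rhs -= Ccinv[tt, t2] * cvec[lit, t2]
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            d = new - old
            for p in range(i0, i1):
                e[lit_rec[p], tt] -= d
            cvec[lit, tt] = new
    # ---- maternal-environment effects ---------------------------------
    for m in range(mevec.shape[0]):
        i0, i1 = me_indptr[m], me_indptr[m + 1]
        for tt in range(t):
            old = mevec[m, tt]
            prec = (i1 - i0) * R0inv[tt, tt] + Cmeinv[tt, tt]
            rhs = 0.0
            for p in range(i0, i1):
                r = me_rec[p]
                rhs += R0inv[tt, tt] * (e[r, tt] + old)
                for t2 in range(t):
                    if t2 != tt:
                        rhs += R0inv[tt, t2] * e[r, t2]
            for t2 in range(t):
                if t2 != tt:
                    rhs -= Cmeinv[tt, t2] * mevec[m, t2]
            new = rhs / prec + np.random.normal() / np.sqrt(prec)
            d = new - old
            for p in range(i0, i1):
                e[me_rec[p], tt] -= d
            mevec[m, tt] = new


@njit(cache=True, fastmath=True)
def bayesb_sweep(
    e,  # (n_rec,) residuals in place
    b,  # (n_levels_total,) fixed effects (level 0 holds the mean mu)
    lvl_indptr,
    lvl_rec,
    lvl_free,
    edam,  # (n_dams,) per-dam residual sums, maintained
    rec_dam,  # (n_rec,)
    dam_indptr,
    dam_rec,  # dam -> record CSR
    n_d,  # (n_dams,) records per dam
    Z,  # (k, n_dams) centered dam genotype covariates
    czz,  # (k,) record-level z'z
    active,  # (k,) bool; constant columns are inactive
    alpha,
    delta,
    sig2snp,  # per-locus state, in place
    nu,
    s2alpha,
    pi,
    sig2e,
):
    n_rec = e.shape[0]
    n_dams = edam.shape[0]
    k = Z.shape[0]
    # fixed effects (single-trait normal conditionals, flat prior)
    for lv in range(b.shape[0]):
        if not lvl_free[lv]:
            continue
        i0, i1 = lvl_indptr[lv], lvl_indptr[lv + 1]
        n = i1 - i0
        if n == 0:
            continue
        old = b[lv]
        s = 0.0
        for p in range(i0, i1):
            s += e[lvl_rec[p]] + old
        new = s / n + np.random.normal() * np.sqrt(sig2e / n)
        d = new - old
        for p in range(i0, i1):
            e[lvl_rec[p]] -= d
        b[lv] = new
    # refresh per-dam residual sums after record-level updates
    for dmi in range(n_dams):
        edam[dmi] = 0.0
    for r in range(n_rec):
        edam[rec_dam[r]] += e[r]
    log_prior_odds = np.log((1.0 - pi) / pi)
    for j in range(k):
        if not active[j]:
            # no information: delta from its prior, alpha stays 0
            delta[j] = 1 if np.random.random() < (1.0 - pi) else 0
            sig2snp[j] = nu * s2alpha / np.random.chisquare(nu)
            continue
        cz = czz[j]
        rhs = cz * alpha[j] * delta[j]
        for dmi in range(n_dams):
            rhs += Z[j, dmi] * edam[dmi]
        v0 = cz * sig2e
        v1 = cz * cz * sig2snp[j] + v0
        logodds = log_prior_odds + 0.5 * (
            np.log(v0 / v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1)
        )
        if logodds > 35.0:
            p1 = 1.0
        elif logodds < -35.0:
            p1 = 0.0
        else:
            p1 = 1.0 / (1.0 + np.exp(-logodds))
        new_delta = 1 if np.random.random() < p1 else 0
        if new_delta == 1:
            prec = cz / sig2e + 1.0 / sig2snp[j]
            mean = (rhs / sig2e) / prec
            new_alpha = mean + np.random.normal() / np.sqrt(prec)
        else:
            new_alpha = 0.0
        diff = new_alpha * new_delta - alpha[j] * delta[j]
        if diff != 0.0:
            for dmi in range(n_dams):
                zd = Z[j, dmi]
                if zd != 0.0:
                    step = zd * diff
                    for p in range(dam_indptr[dmi], dam_indptr[dmi + 1]):
                        e[dam_rec[p]] -= step
                    edam[dmi] -= n_d[dmi] * step
        alpha[j] = new_alpha
        delta[j] = new_delta
        sig2snp[j] = (nu * s2alpha + new_delta * new_alpha * new_alpha) / (
            np.random.chisquare(nu + new_delta)
        )
    sse = 0.0
    for r in range(n_rec):
        sse += e[r] * e[r]
    return sse / np.random.chisquare(n_rec)
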