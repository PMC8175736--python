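"""Compiled Metropolis-within-Gibbs kernel for the dating sampler.

Everything here operates on plain arrays so numba can compile it; the
user-facing wrapper lives in :mod:`endoclock.sampler`.  The state is

* ``ages``  — per-node ages in Ma (leaves pinned at 0),
* ``lr``    — per-node log-rates (AR) or per-branch log-rates (IR, indexed
  by child node id with the root slot unused),
* ``mu``, ``s2`` — clock hyperparameters.

Branches are indexed by child node id (0 .. n-2; the root is node n-1).
The approximate likelihood is quadratic in the branch lengths, so move
deltas are computed from cached residuals ``d = b - b_hat`` and ``H d``
without ever re-evaluating the full quadratic form; the full posterior is
recomputed from scratch whenever a sample is stored, which also prevents
floating-point drift in the caches.

One iteration (sweep) updates, in order: every internal non-root node age,
the root age, every rate variable, ``mu``, ``s2``, and finally a whole-tree
scaling move that multiplies all ages by ``c`` and divides all rates by
``c`` (branch lengths, hence the likelihood, are invariant; the Jacobian
``c^{n_internal}`` enters the acceptance ratio).  Proposal scales adapt
toward 20-40% acceptance during burn-in only, so the sampled chain targets
a fixed kernel.
"""

import numpy as np
from numba import njit

# move-class indices for acceptance bookkeeping
AGE, ROOT, RATE, MU, S2, MIX, SUBTREE = 0, 1, 2, 3, 4, 5, 6

LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True, inline="always")
def _norm_lpdf(x, m, v):
    return -0.5 * (LOG2PI + np.log(v) + (x - m) * (x - m) / v)


@njit(cache=True)
def _cal_logpdf(t, ct, tmin, tmax, logh, thl, lam):
    """Soft-bounded uniform log density; ct: 0 none, 1 min-max, 2 min-only."""
    if ct == 0:
        return 0.0
    if t <= 0.0:
        return -np.inf
    if t < tmin:
        if np.isinf(thl):
            return -np.inf
        return logh + (thl - 1.0) * np.log(t / tmin)
    if ct == 2:
        return 0.0
    if t > tmax:
        if np.isinf(lam):
            return -np.inf
        return logh - lam * (t - tmax)
    return logh


@njit(cache=True)
def _branch_rate(j, parent, lr, clock_model, ar_geo):
    if clock_model == 1:  # IR
        return np.exp(lr[j])
    p = parent[j]
    if ar_geo == 1:
        return np.exp(0.5 * (lr[j] + lr[p]))
    return 0.5 * (np.exp(lr[j]) + np.exp(lr[p]))


@njit(cache=True)
def _branch_len(j, parent, ages, lr, clock_model, ar_geo):
    return _branch_rate(j, parent, lr, clock_model, ar_geo) * (
        ages[parent[j]] - ages[j]
    )


@njit(cache=True)
def _rate_prior_term(i, parent, ages, lr, mu, s2, clock_model, root_var_time, n):
    """Log-prior contribution of rate variable i (density in log-rate space)."""
    if clock_model == 1:  # IR branch term
        return _norm_lpdf(lr[i], np.log(mu) - 0.5 * s2, s2)
    if i == n - 1:  # AR root node
        v0 = s2 * root_var_time
        return _norm_lpdf(lr[i], np.log(mu) - 0.5 * v0, v0)
    dt = ages[parent[i]] - ages[i]
    return _norm_lpdf(lr[i], lr[parent[i]] - 0.5 * s2 * dt, s2 * dt)


@njit(cache=True)
def _gamma_lpdf(x, shape, scale):
    # unnormalised
    return (shape - 1.0) * np.log(x) - x / scale


@njit(cache=True)
def _total_prior(ages, lr, mu, s2, parent, child_ptr,
                 cal_type, cal_tmin, cal_tmax, cal_logh, cal_thl, cal_lam,
                 clock_model, root_var_time,
                 mu_fixed, mu_shape, mu_scale, s2_fixed, s2_shape, s2_scale):
    n = ages.shape[0]
    lp = 0.0
    for i in range(n):
        if cal_type[i] != 0:
            lp += _cal_logpdf(ages[i], cal_type[i], cal_tmin[i], cal_tmax[i],
                              cal_logh[i], cal_thl[i], cal_lam[i])
    if clock_model == 1:
        for j in range(n - 1):
            lp += _rate_prior_term(j, parent, ages, lr, mu, s2, clock_model,
                                   root_var_time, n)
    else:
        for i in range(n):
            lp += _rate_prior_term(i, parent, ages, lr, mu, s2, clock_model,
                                   root_var_time, n)
    if mu_fixed == 0:
        lp += _gamma_lpdf(mu, mu_shape, mu_scale)
    if s2_fixed == 0:
        lp += _gamma_lpdf(s2, s2_shape, s2_scale)
    return lp


@njit(cache=True)
def _refresh_lik(ages, lr, parent, clock_model, ar_geo,
                 bhat, grad, hess, b, d, Hd):
    """Recompute branch lengths and likelihood caches from scratch."""
    P = bhat.shape[0]
    nb = bhat.shape[1]
    for j in range(nb):
        b[j] = _branch_len(j, parent, ages, lr, clock_model, ar_geo)
    ll = 0.0
    for p in range(P):
        for j in range(nb):
            d[p, j] = b[j] - bhat[p, j]
        for j in range(nb):
            acc = 0.0
            for k in range(nb):
                acc += hess[p, j, k] * d[p, k]
            Hd[p, j] = acc
        for j in range(nb):
            ll += grad[p, j] * d[p, j] + 0.5 * d[p, j] * Hd[p, j]
    return ll


@njit(cache=True)
def _delta_lik(J, e, nJ, grad, hess, Hd):
    P = Hd.shape[0]
    dll = 0.0
    for p in range(P):
        for a in range(nJ):
            dll += (grad[p, J[a]] + Hd[p, J[a]]) * e[a]
        for a in range(nJ):
            for c in range(nJ):
                dll += 0.5 * hess[p, J[a], J[c]] * e[a] * e[c]
    return dll


@njit(cache=True)
def _apply_lik(J, e, nJ, hess, b, d, Hd):
    P = Hd.shape[0]
    nb = Hd.shape[1]
    for a in range(nJ):
        j = J[a]
        b[j] += e[a]
        for p in range(P):
            d[p, j] += e[a]
    for p in range(P):
        for a in range(nJ):
            j = J[a]
            for k in range(nb):
                Hd[p, k] += hess[p, k, j] * e[a]


@njit(cache=True)
def _fold(t, lo, hi):
    """Reflect a proposal into (lo, hi); exact and symmetric."""
    w = hi - lo
    y = (t - lo) % (2.0 * w)
    if y < 0.0:
        y += 2.0 * w
    if y > w:
        y = 2.0 * w - y
    return lo + y


@njit(cache=True)
def run_kernel(parent, child_ptr, child_idx, internal_ids,
               sub_ptr, sub_idx, n_sub_internal,
               cal_type, cal_tmin, cal_tmax, cal_logh, cal_thl, cal_lam,
               clock_model, ar_geo, root_var_time,
               mu_fixed, mu_shape, mu_scale,
               s2_fixed, s2_shape, s2_scale,
               bhat, grad, hess, prior_only, disable_scaling,
               ages, lr, mu0, s20,
               burn_in, sample_every, n_samples, tune_interval, seed,
               scale_age, scale_rate, scale_mix, scale_other,
               out_ages, out_lr, out_mu, out_s2, out_logpost,
               acc, prop):
    np.random.seed(seed)
    n = parent.shape[0]
    root = n - 1
    nb = n - 1
    m_int = internal_ids.shape[0]
    mu = mu0
    s2 = s20

    b = np.zeros(nb)
    P = bhat.shape[0]
    d = np.zeros((P, nb))
    Hd = np.zeros((P, nb))
    cur_ll = 0.0
    if prior_only == 0:
        cur_ll = _refresh_lik(ages, lr, parent, clock_model, ar_geo,
                              bhat, grad, hess, b, d, Hd)

    lp0 = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                       cal_type, cal_tmin, cal_tmax, cal_logh, cal_thl,
                       cal_lam, clock_model, root_var_time,
                       mu_fixed, mu_shape, mu_scale,
                       s2_fixed, s2_shape, s2_scale)
    if not np.isfinite(lp0 + cur_ll):
        return 1

    # per-parameter adaptation windows
    win_acc_age = np.zeros(n)
    win_prop_age = np.zeros(n)
    win_acc_rate = np.zeros(n)
    win_prop_rate = np.zeros(n)
    win_acc_mix = np.zeros(n)
    win_prop_mix = np.zeros(n)
    win_acc_other = np.zeros(3)
    win_prop_other = np.zeros(3)

    J = np.zeros(16, dtype=np.int64)
    e = np.zeros(16)

    total_iter = burn_in + n_samples * sample_every
    stored = 0

    for it in range(total_iter):
        # ---------------------------------------------- internal node ages
        for a_i in range(m_int):
            i = internal_ids[a_i]
            if i == root:
                continue
            lo = -1.0
            for ci in range(child_ptr[i], child_ptr[i + 1]):
                c = child_idx[ci]
                if ages[c] > lo:
                    lo = ages[c]
            hi = ages[parent[i]]
            if hi - lo <= 0.0:
                continue
            t_old = ages[i]
            t_new = _fold(t_old + np.random.normal() * scale_age[i], lo, hi)
            dlp = (_cal_logpdf(t_new, cal_type[i], cal_tmin[i], cal_tmax[i],
                               cal_logh[i], cal_thl[i], cal_lam[i])
                   - _cal_logpdf(t_old, cal_type[i], cal_tmin[i], cal_tmax[i],
                                 cal_logh[i], cal_thl[i], cal_lam[i]))
            if clock_model == 0:
                # AR: durations enter the Brownian step terms
                dlp -= _rate_prior_term(i, parent, ages, lr, mu, s2, 0,
                                        root_var_time, n)
                for ci in range(child_ptr[i], child_ptr[i + 1]):
                    dlp -= _rate_prior_term(child_idx[ci], parent, ages, lr,
                                            mu, s2, 0, root_var_time, n)
                ages[i] = t_new
                dlp += _rate_prior_term(i, parent, ages, lr, mu, s2, 0,
                                        root_var_time, n)
                for ci in range(child_ptr[i], child_ptr[i + 1]):
                    dlp += _rate_prior_term(child_idx[ci], parent, ages, lr,
                                            mu, s2, 0, root_var_time, n)
                ages[i] = t_old
            nJ = 0
            if prior_only == 0:
                J[nJ] = i
                rate_i = _branch_rate(i, parent, lr, clock_model, ar_geo)
                e[nJ] = rate_i * (hi - t_new) - b[i]
                nJ += 1
                for ci in range(child_ptr[i], child_ptr[i + 1]):
                    c = child_idx[ci]
                    rate_c = _branch_rate(c, parent, lr, clock_model, ar_geo)
                    J[nJ] = c
                    e[nJ] = rate_c * (t_new - ages[c]) - b[c]
                    nJ += 1
                dlp += _delta_lik(J, e, nJ, grad, hess, Hd)
            prop[AGE] += 1
            win_prop_age[i] += 1
            if np.log(np.random.random()) < dlp:
                ages[i] = t_new
                if prior_only == 0:
                    _apply_lik(J, e, nJ, hess, b, d, Hd)
                acc[AGE] += 1
                win_acc_age[i] += 1

        # --------------------------------------------------------- root age
        lo = -1.0
        for ci in range(child_ptr[root], child_ptr[root + 1]):
            c = child_idx[ci]
            if ages[c] > lo:
                lo = ages[c]
        t_old = ages[root]
        t_new = t_old + np.random.normal() * scale_age[root]
        if t_new < lo:
            t_new = 2.0 * lo - t_new
        dlp = (_cal_logpdf(t_new, cal_type[root], cal_tmin[root],
                           cal_tmax[root], cal_logh[root], cal_thl[root],
                           cal_lam[root])
               - _cal_logpdf(t_old, cal_type[root], cal_tmin[root],
                             cal_tmax[root], cal_logh[root], cal_thl[root],
                             cal_lam[root]))
        if clock_model == 0:
            for ci in range(child_ptr[root], child_ptr[root + 1]):
                dlp -= _rate_prior_term(child_idx[ci], parent, ages, lr, mu,
                                        s2, 0, root_var_time, n)
            ages[root] = t_new
            for ci in range(child_ptr[root], child_ptr[root + 1]):
                dlp += _rate_prior_term(child_idx[ci], parent, ages, lr, mu,
                                        s2, 0, root_var_time, n)
            ages[root] = t_old
        nJ = 0
        if prior_only == 0:
            for ci in range(child_ptr[root], child_ptr[root + 1]):
                c = child_idx[ci]
                rate_c = _branch_rate(c, parent, lr, clock_model, ar_geo)
                J[nJ] = c
                e[nJ] = rate_c * (t_new - ages[c]) - b[c]
                nJ += 1
            dlp += _delta_lik(J, e, nJ, grad, hess, Hd)
        prop[ROOT] += 1
        win_prop_other[0] += 0  # root tracked via scale_age[root]
        win_prop_age[root] += 1
        if np.log(np.random.random()) < dlp:
            ages[root] = t_new
            if prior_only == 0:
                _apply_lik(J, e, nJ, hess, b, d, Hd)
            acc[ROOT] += 1
            win_acc_age[root] += 1

        # ------------------------------------------------------------ rates
        n_rate = n if clock_model == 0 else nb
        for i in range(n_rate):
            lr_old = lr[i]
            lr_new = lr_old + np.random.normal() * scale_rate[i]
            dlp = 0.0
            lr[i] = lr_new
            dlp += _rate_prior_term(i, parent, ages, lr, mu, s2, clock_model,
                                    root_var_time, n)
            if clock_model == 0:
                for ci in range(child_ptr[i], child_ptr[i + 1]):
                    dlp += _rate_prior_term(child_idx[ci], parent, ages, lr,
                                            mu, s2, 0, root_var_time, n)
            lr[i] = lr_old
            dlp -= _rate_prior_term(i, parent, ages, lr, mu, s2, clock_model,
                                    root_var_time, n)
            if clock_model == 0:
                for ci in range(child_ptr[i], child_ptr[i + 1]):
                    dlp -= _rate_prior_term(child_idx[ci], parent, ages, lr,
                                            mu, s2, 0, root_var_time, n)
            nJ = 0
            if prior_only == 0:
                lr[i] = lr_new
                if i != root:
                    J[nJ] = i
                    e[nJ] = _branch_len(i, parent, ages, lr, clock_model,
                                        ar_geo) - b[i]
                    nJ += 1
                if clock_model == 0:
                    for ci in range(child_ptr[i], child_ptr[i + 1]):
                        c = child_idx[ci]
                        J[nJ] = c
                        e[nJ] = _branch_len(c, parent, ages, lr, 0, ar_geo) - b[c]
                        nJ += 1
                lr[i] = lr_old
                dlp += _delta_lik(J, e, nJ, grad, hess, Hd)
            prop[RATE] += 1
            win_prop_rate[i] += 1
            if np.log(np.random.random()) < dlp:
                lr[i] = lr_new
                if prior_only == 0:
                    _apply_lik(J, e, nJ, hess, b, d, Hd)
                acc[RATE] += 1
                win_acc_rate[i] += 1

        # ------------------------------------------- subtree scaling moves
        # scale every age inside the subtree of an internal non-root node
        # by c and shift its log-rates by -log c: branch lengths within the
        # subtree are invariant, so only the stem branch and the priors
        # enter the acceptance ratio.  This decouples the local age/rate
        # scale directions that elementwise moves mix slowly.
        for a_i in range(m_int):
            if disable_scaling == 1:
                break
            i = internal_ids[a_i]
            if i == root:
                continue
            u = (np.random.random() * 2.0 - 1.0) * scale_mix[i]
            c_scale = np.exp(u)
            prop[SUBTREE] += 1
            win_prop_mix[i] += 1
            if c_scale * ages[i] >= ages[parent[i]]:
                continue  # out of support: reject
            old_prior = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                                     cal_type, cal_tmin, cal_tmax, cal_logh,
                                     cal_thl, cal_lam, clock_model,
                                     root_var_time, mu_fixed, mu_shape,
                                     mu_scale, s2_fixed, s2_shape, s2_scale)
            for si in range(sub_ptr[i], sub_ptr[i + 1]):
                j = sub_idx[si]
                if child_ptr[j + 1] > child_ptr[j]:  # internal: scale age
                    ages[j] *= c_scale
                if clock_model == 0 or j != i:
                    # AR: shift every subtree node rate (incl. i, leaves);
                    # IR: shift strict-descendant branch rates only
                    lr[j] -= u
            new_prior = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                                     cal_type, cal_tmin, cal_tmax, cal_logh,
                                     cal_thl, cal_lam, clock_model,
                                     root_var_time, mu_fixed, mu_shape,
                                     mu_scale, s2_fixed, s2_shape, s2_scale)
            dlp = new_prior - old_prior + n_sub_internal[i] * u
            nJ = 0
            if prior_only == 0:
                J[nJ] = i
                e[nJ] = _branch_len(i, parent, ages, lr, clock_model,
                                    ar_geo) - b[i]
                nJ += 1
                dlp += _delta_lik(J, e, nJ, grad, hess, Hd)
            if np.log(np.random.random()) < dlp:
                if prior_only == 0:
                    _apply_lik(J, e, nJ, hess, b, d, Hd)
                acc[SUBTREE] += 1
                win_acc_mix[i] += 1
            else:
                for si in range(sub_ptr[i], sub_ptr[i + 1]):
                    j = sub_idx[si]
                    if child_ptr[j + 1] > child_ptr[j]:
                        ages[j] /= c_scale
                    if clock_model == 0 or j != i:
                        lr[j] += u

        # ------------------------------------------------- hyperparameters
        if mu_fixed == 0:
            lmu_new = np.log(mu) + np.random.normal() * scale_other[0]
            mu_new = np.exp(lmu_new)
            dlp = (_gamma_lpdf(mu_new, mu_shape, mu_scale)
                   - _gamma_lpdf(mu, mu_shape, mu_scale)
                   + lmu_new - np.log(mu))  # Jacobian of log walk
            if clock_model == 0:
                dlp += (_rate_prior_term(root, parent, ages, lr, mu_new, s2,
                                         0, root_var_time, n)
                        - _rate_prior_term(root, parent, ages, lr, mu, s2,
                                           0, root_var_time, n))
            else:
                for j in range(nb):
                    dlp += (_rate_prior_term(j, parent, ages, lr, mu_new, s2,
                                             1, root_var_time, n)
                            - _rate_prior_term(j, parent, ages, lr, mu, s2,
                                               1, root_var_time, n))
            prop[MU] += 1
            win_prop_other[0] += 1
            if np.log(np.random.random()) < dlp:
                mu = mu_new
                acc[MU] += 1
                win_acc_other[0] += 1

        if s2_fixed == 0:
            ls2_new = np.log(s2) + np.random.normal() * scale_other[1]
            s2_new = np.exp(ls2_new)
            dlp = (_gamma_lpdf(s2_new, s2_shape, s2_scale)
                   - _gamma_lpdf(s2, s2_shape, s2_scale)
                   + ls2_new - np.log(s2))
            if clock_model == 0:
                for i in range(n):
                    dlp += (_rate_prior_term(i, parent, ages, lr, mu, s2_new,
                                             0, root_var_time, n)
                            - _rate_prior_term(i, parent, ages, lr, mu, s2,
                                               0, root_var_time, n))
            else:
                for j in range(nb):
                    dlp += (_rate_prior_term(j, parent, ages, lr, mu, s2_new,
                                             1, root_var_time, n)
                            - _rate_prior_term(j, parent, ages, lr, mu, s2,
                                               1, root_var_time, n))
            prop[S2] += 1
            win_prop_other[1] += 1
            if np.log(np.random.random()) < dlp:
                s2 = s2_new
                acc[S2] += 1
                win_acc_other[1] += 1

        # --------------------------------------------- whole-tree scaling
        if disable_scaling == 0:
            u = (np.random.random() * 2.0 - 1.0) * scale_other[2]
            c_scale = np.exp(u)
            old_prior = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                                     cal_type, cal_tmin, cal_tmax, cal_logh,
                                     cal_thl, cal_lam, clock_model,
                                     root_var_time, mu_fixed, mu_shape,
                                     mu_scale, s2_fixed, s2_shape, s2_scale)
            for a_i in range(m_int):
                ages[internal_ids[a_i]] *= c_scale
            for i in range(n):
                lr[i] -= u
            new_prior = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                                     cal_type, cal_tmin, cal_tmax, cal_logh,
                                     cal_thl, cal_lam, clock_model,
                                     root_var_time, mu_fixed, mu_shape,
                                     mu_scale, s2_fixed, s2_shape, s2_scale)
            dlp = new_prior - old_prior + m_int * u
            prop[MIX] += 1
            win_prop_other[2] += 1
            if np.log(np.random.random()) < dlp:
                acc[MIX] += 1
                win_acc_other[2] += 1
            else:
                for a_i in range(m_int):
                    ages[internal_ids[a_i]] /= c_scale
                for i in range(n):
                    lr[i] += u

        # ------------------------------------------------------ adaptation
        if it < burn_in and (it + 1) % tune_interval == 0:
            for i in range(n):
                if win_prop_age[i] > 0:
                    r = win_acc_age[i] / win_prop_age[i]
                    scale_age[i] *= np.exp(1.2 * (r - 0.3))
                    scale_age[i] = min(max(scale_age[i], 1e-3), 1e4)
                    win_acc_age[i] = 0.0
                    win_prop_age[i] = 0.0
                if win_prop_rate[i] > 0:
                    r = win_acc_rate[i] / win_prop_rate[i]
                    scale_rate[i] *= np.exp(1.2 * (r - 0.3))
                    scale_rate[i] = min(max(scale_rate[i], 1e-3), 5.0)
                    win_acc_rate[i] = 0.0
                    win_prop_rate[i] = 0.0
                if win_prop_mix[i] > 0:
                    r = win_acc_mix[i] / win_prop_mix[i]
                    scale_mix[i] *= np.exp(1.2 * (r - 0.3))
                    scale_mix[i] = min(max(scale_mix[i], 1e-3), 2.0)
                    win_acc_mix[i] = 0.0
                    win_prop_mix[i] = 0.0
            for k in range(3):
                if win_prop_other[k] > 0:
                    r = win_acc_other[k] / win_prop_other[k]
                    scale_other[k] *= np.exp(1.2 * (r - 0.3))
                    scale_other[k] = min(max(scale_other[k], 1e-3), 5.0)
                    win_acc_other[k] = 0.0
                    win_prop_other[k] = 0.0

        # ---------------------------------------------------------- sample
        if it >= burn_in and (it - burn_in + 1) % sample_every == 0:
            if stored < n_samples:
                if prior_only == 0:
                    cur_ll = _refresh_lik(ages, lr, parent, clock_model,
                                          ar_geo, bhat, grad, hess, b, d, Hd)
                lp = _total_prior(ages, lr, mu, s2, parent, child_ptr,
                                  cal_type, cal_tmin, cal_tmax, cal_logh,
                                  cal_thl, cal_lam, clock_model,
                                  root_var_time, mu_fixed, mu_shape,
                                  mu_scale, s2_fixed, s2_shape, s2_scale)
                lp += cur_ll
                if np.isnan(lp):
                    return 2
                for a_i in range(m_int):
                    out_ages[stored, a_i] = ages[internal_ids[a_i]]
                for i in range(n):
                    out_lr[stored, i] = lr[i]
                out_mu[stored] = mu
                out_s2[stored] = s2
                out_logpost[stored] = lp
                stored += 1
    return 0
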