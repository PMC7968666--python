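"""Independent brute-force oracles used to validate the likelihood engine.

The marginal likelihood here is computed by nested adaptive Gauss-Hermite
quadrature with scipy optimisers locating the quadrature centres - nothing
is shared with the package's own Laplace machinery beyond the model
definition itself.
"""
from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

LOG2PI = math.log(2.0 * math.pi)


def _record_neg_log_joint(pop, rec, eta_d, eta_k, kappa):
    """-log [ p(y | eta, kappa) * phi(eta_d) * phi(eta_k) ] for one record."""
    rel_w = rec["wt"] / pop.wt_ref_mg
    dose = (pop.theta_dose_ng * rel_w ** pop.exp_wt_dose
            * math.exp(pop.omega_dose * eta_d + pop.omega_iov_dose * kappa))
    kel = (pop.theta_kel_ng_per_h * rel_w ** pop.exp_wt_kel
           * math.exp(pop.omega_kel * eta_k))
    tlag = pop.theta_tlag_h + (pop.theta_tlag_add_rit_h if rec["rit"] else 0.0)
    f = max(dose - kel * max(rec["t"] - tlag, 0.0), 0.0)
    v = f * f * pop.sigma_prop ** 2 + pop.sigma_add_ng ** 2
    r = rec["y"] - f
    return (0.5 * (eta_d ** 2 + eta_k ** 2) + LOG2PI
            + 0.5 * (LOG2PI + math.log(v)) + r * r / (2.0 * v))


def _log_I_record(pop, rec, kappa, n_nodes):
    """2-d adaptive Gauss-Hermite integral over (eta_d, eta_k)."""
    def q(u):
        return _record_neg_log_joint(pop, rec, u[0], u[1], kappa)

    res = minimize(q, np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
    mu = res.x
    # FD Hessian of q at the mode
    h = 1e-4
    H = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            upp = mu.copy(); upp[i] += h; upp[j] += h
            upm = mu.copy(); upm[i] += h; upm[j] -= h
            ump = mu.copy(); ump[i] -= h; ump[j] += h
            umm = mu.copy(); umm[i] -= h; umm[j] -= h
            H[i, j] = (q(upp) - q(upm) - q(ump) + q(umm)) / (4 * h * h)
    H = (H + H.T) / 2.0
    # scale matrix from the (regularised) Hessian
    evals, evecs = np.linalg.eigh(H)
    evals = np.maximum(evals, 1e-6)
    L = evecs @ np.diag(1.0 / np.sqrt(evals))
    z, w = hermgauss(n_nodes)
    logw = np.log(w)
    terms = []
    for a in range(n_nodes):
        for b in range(n_nodes):
            zz = np.array([z[a], z[b]])
            u = mu + math.sqrt(2.0) * (L @ zz)
            terms.append(logw[a] + logw[b] + zz @ zz - q(u))
    log_det_L = float(np.log(np.abs(np.linalg.det(L))))
    return float(logsumexp(terms)) + math.log(2.0) + log_det_L


def quadrature_neg2ll(pop, records, n_nodes: int = 32) -> float:
    """-2 log marginal likelihood by nested adaptive Gauss-Hermite
    quadrature (outer 1-d integral over the shared batch deviate, inner 2-d
    integrals per record).  Records: list of dicts with y, t, wt, rit, batch;
    below-LLOQ records must already be excluded.
    """
    batches = sorted({r["batch"] for r in records})
    total = 0.0
    for b in batches:
        recs = [r for r in records if r["batch"] == b]

        def neg_log_integrand(kappa):
            return (0.5 * kappa * kappa + 0.5 * LOG2PI
                    - sum(_log_I_record(pop, r, kappa, n_nodes) for r in recs))

        if pop.omega_iov_dose == 0.0:
            # the kappa prior integrates to 1 and the rest is constant:
            # log L_b = sum_i log I_i = -m(0) + kappa-prior constant
            total += -2.0 * (-neg_log_integrand(0.0) + 0.5 * LOG2PI)
            continue
        res = minimize_scalar(neg_log_integrand, bounds=(-8.0, 8.0),
                              method="bounded",
                              options={"xatol": 1e-10})
        mu = res.x
        h = 1e-3
        d2 = (neg_log_integrand(mu + h) - 2.0 * res.fun
              + neg_log_integrand(mu - h)) / (h * h)
        scale = 1.0 / math.sqrt(max(d2, 1e-6))
        z, w = hermgauss(n_nodes)
        terms = [math.log(w[a]) + z[a] ** 2
                 - neg_log_integrand(mu + math.sqrt(2.0) * scale * z[a])
                 for a in range(n_nodes)]
        log_L = logsumexp(terms) + 0.5 * math.log(2.0) + math.log(scale)
        total += -2.0 * float(log_L)
    return total
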