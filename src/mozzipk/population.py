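"""Population model: covariates, random effects and the marginal likelihood.

The individual model maps population parameters to a zero-order structural
curve:

    D_i     = theta_dose * (w_i/w_ref)^p_D * exp(omega_dose*eta_D + omega_iov*kappa_b)
    k_el,i  = theta_kel  * (w_i/w_ref)^p_k * exp(omega_kel*eta_k)
    T_lag,i = theta_tlag + theta_tlag_add_rit * 1[ritonavir co-treatment]

with eta_D, eta_k ~ N(0,1) per mosquito and kappa_b ~ N(0,1) per feeding
batch (inter-occasion variability on dose; every mosquito feeds exactly
once, so the occasion is the batch).  The observation is the whole-body
amount with combined residual error,

    y_i ~ N(f_i, f_i^2 sigma_prop^2 + sigma_add^2),

i.e. the residual variance depends on the individual prediction
(eta-epsilon interaction).

``marginal_neg2ll`` returns -2 log of the likelihood marginalised over all
random effects by a nested approximation: the per-mosquito deviates are
integrated record by record (a Laplace term at the on-curve conditional
mode plus an exact Gaussian half-plane mass over the fully-depleted
region), and the shared batch deviate by a 1-d Laplace step per batch.
Everything is vectorised across records, so the cost is linear in the
number of mosquitoes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .datamodel import (MosquitoRecord, PopulationParams, RandomEffects,
                        StructuralParams, ValidationError)
from .io import records_to_frame

LOG2PI = math.log(2.0 * math.pi)

__all__ = ["ModelConfig", "individual_params", "observation_loglik",
           "marginal_neg2ll", "LaplaceObjective", "DegenerateErrorModel"]


class DegenerateErrorModel(ValueError):
    """Residual variance is zero: the error model is degenerate."""


@dataclass
class ModelConfig:
    """Estimation-relevant model switches.

    blq_mode: 'conditional' (the default) excludes below-LLOQ records and
    conditions each retained record on exceeding the LLOQ (truncated
    Gaussian, the M2 method) - plain exclusion is biased because censoring
    near full depletion is informative; 'drop' excludes them without the
    truncation correction (M1); 'censored' keeps them with a Gaussian-CDF
    contribution below the LLOQ amount (M3).
    variance_parameterization: read omega/sigma entries of PopulationParams
    as variances instead of standard deviations.  ritonavir_lag: enable the
    additive lag covariate for ritonavir arms.
    """
    blq_mode: str = "conditional"
    variance_parameterization: bool = False
    ritonavir_lag: bool = True
    lloq_ng: float = 0.005
    analyte: str = "IVM"

    def sd(self, value: float) -> float:
        return math.sqrt(value) if self.variance_parameterization else value


def individual_params(pop: PopulationParams, weight_mg: float,
                      is_ritonavir: bool, effects: RandomEffects,
                      config: Optional[ModelConfig] = None) -> StructuralParams:
    """Individual zero-order curve parameters for one mosquito."""
    if weight_mg <= 0:
        raise ValidationError("weight_mg must be > 0")
    cfg = config or ModelConfig()
    rel_w = weight_mg / pop.wt_ref_mg
    dose = (pop.theta_dose_ng * rel_w ** pop.exp_wt_dose
            * math.exp(cfg.sd(pop.omega_dose) * effects.eta_dose
                       + cfg.sd(pop.omega_iov_dose) * effects.kappa_batch))
    kel = (pop.theta_kel_ng_per_h * rel_w ** pop.exp_wt_kel
           * math.exp(cfg.sd(pop.omega_kel) * effects.eta_kel))
    tlag = pop.theta_tlag_h
    if is_ritonavir and cfg.ritonavir_lag:
        tlag += pop.theta_tlag_add_rit_h
    return StructuralParams(dose_ng=dose, tlag_h=tlag, model_kind="zero_order",
                            kel_ng_per_h=kel)


def observation_loglik(y_ng, pred_ng, sigma_prop: float, sigma_add_ng: float):
    """Gaussian log-density of the observed amount given the individual
    prediction, under combined proportional + additive residual error."""
    y = np.asarray(y_ng, dtype=float)
    f = np.asarray(pred_ng, dtype=float)
    v = f * f * sigma_prop ** 2 + sigma_add_ng ** 2
    if np.any(v <= 0):
        raise DegenerateErrorModel("residual variance is zero")
    out = -0.5 * (LOG2PI + np.log(v)) - (y - f) ** 2 / (2.0 * v)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# data preparation

RecordsLike = Union[Sequence[MosquitoRecord], pd.DataFrame]


def _as_frame(data: RecordsLike) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return records_to_frame(list(data))


@dataclass
class _Prepared:
    y: np.ndarray
    t: np.ndarray
    w: np.ndarray
    rit: np.ndarray
    batch: np.ndarray          # int codes
    blq: np.ndarray            # bool, only present in censored mode
    batch_ids: list
    n_total: int
    n_blq_dropped: int
    index: np.ndarray          # positions in the original frame


def _prepare(data: RecordsLike, config: ModelConfig) -> _Prepared:
    df = _as_frame(data)
    if "ANALYTE" in df.columns:
        df = df[df["ANALYTE"] == config.analyte]
    n_total = len(df)
    blq = df["BLQ"].astype(int).to_numpy().astype(bool)
    if config.blq_mode in ("drop", "conditional"):
        keep = ~blq
        n_dropped = int(blq.sum())
    elif config.blq_mode == "censored":
        keep = np.ones(len(df), dtype=bool)
        n_dropped = 0
    else:
        raise ValueError(f"unknown blq_mode {config.blq_mode!r}")
    sub = df.loc[keep]
    if len(sub) == 0:
        raise ValidationError("no quantifiable observations to fit")
    t = sub["TIME"].to_numpy(dtype=float)
    w = sub["WT"].to_numpy(dtype=float)
    if np.any(t < 0) or np.any(w <= 0) or np.any(~np.isfinite(t)) or np.any(~np.isfinite(w)):
        raise ValidationError("invalid time or weight in dataset")
    y = sub["DV"].to_numpy(dtype=float)
    sub_blq = blq[keep]
    y = np.where(sub_blq, 0.0, y)
    if np.any(~np.isfinite(y)):
        bad = sub.index[~np.isfinite(y)][0]
        raise ValidationError(f"non-finite amount in record {bad}")
    codes, uniques = pd.factorize(sub["BATCH"].astype(str))
    rit = sub["ARM"].astype(str).str.contains("RTV").to_numpy()
    return _Prepared(y=y, t=t, w=w, rit=rit, batch=codes.astype(np.int64),
                     blq=sub_blq, batch_ids=list(uniques),
                     n_total=n_total, n_blq_dropped=n_dropped,
                     index=np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Laplace engine


class LaplaceObjective:
    """Reusable -2 log-likelihood evaluator for one dataset.

    The marginalisation is nested: for each feeding batch the occasion
    deviate kappa is integrated by a 1-d Laplace step around the mode of

        h_b(kappa) = kappa^2/2 + log(2 pi)/2 - sum_i log I_i(kappa),

    where I_i is the per-record integral over (eta_D, eta_k).  I_i itself
    splits at the zero-amount clip: the fully-depleted half-plane
    contributes EXACTLY (constant observation factor times a Gaussian
    half-plane mass), while the on-curve part is a Laplace term at the
    interior conditional mode with a smooth half-plane truncation factor.
    The two parts are combined by log-sum-exp, so the OFV stays smooth as
    records migrate between the declining curve and full depletion.

    All mode searches start from deterministic analytic candidates, making
    the OFV a pure function of (data, config, parameters); only the kappa
    solution is warm-started between evaluations.
    """

    #: inf-norm tolerance on the conditional-mode gradient
    GRAD_TOL = 1e-8
    #: FD step for kappa derivatives of h (wide: log h'' enters the OFV and
    #: must average over the ~1e-8 noise floor of the inner refinements)
    KAPPA_STEP = 1e-2

    def __init__(self, data: RecordsLike, config: Optional[ModelConfig] = None):
        self.config = config or ModelConfig()
        self.data = _prepare(data, self.config)
        self.n_obs = len(self.data.y)
        self.n_batches = len(self.data.batch_ids)
        self._ka = np.zeros(self.n_batches)

    # -- per-record context for one parameter vector ---------------------
    def _constants(self, pop: PopulationParams) -> dict:
        d, cfg = self.data, self.config
        rel_w = d.w / pop.wt_ref_mg
        tlag = pop.theta_tlag_h + np.where(
            d.rit & cfg.ritonavir_lag, pop.theta_tlag_add_rit_h, 0.0)
        sa2 = cfg.sd(pop.sigma_add_ng) ** 2
        if sa2 <= 0:
            raise DegenerateErrorModel("additive residual variance is zero")
        return dict(cd=pop.theta_dose_ng * rel_w ** pop.exp_wt_dose,
                    ck=pop.theta_kel_ng_per_h * rel_w ** pop.exp_wt_kel,
                    tau=np.maximum(d.t - tlag, 0.0),
                    y=d.y, blq=d.blq, batch=d.batch, nb=self.n_batches,
                    sd_d=cfg.sd(pop.omega_dose), sd_k=cfg.sd(pop.omega_kel),
                    sd_v=cfg.sd(pop.omega_iov_dose),
                    sp2=cfg.sd(pop.sigma_prop) ** 2, sa2=sa2)

    @staticmethod
    def _tile(ctx: dict, m: int) -> dict:
        """Stack m copies of the record context with disjoint batch codes,
        so several kappa vectors can be evaluated in one vector pass."""
        out = dict(ctx)
        for key in ("cd", "ck", "tau", "y", "blq",
                    "sd_d", "sd_k", "sd_v", "sp2", "sa2"):
            if np.ndim(ctx[key]) > 0:
                out[key] = np.tile(ctx[key], m)
        nb = ctx["nb"]
        out["batch"] = np.concatenate(
            [ctx["batch"] + j * nb for j in range(m)])
        out["nb"] = nb * m
        return out

    @staticmethod
    def _batch_sum(ctx, x):
        return np.bincount(ctx["batch"], weights=x, minlength=ctx["nb"])

    def _f_v(self, c, ed, ek, ka_rec):
        # exponents capped: such trial points are rejected by the line
        # searches anyway, the cap only prevents overflow while probing
        Dt = c["cd"] * np.exp(np.minimum(c["sd_d"] * ed + c["sd_v"] * ka_rec, 50.0))
        El = c["ck"] * np.exp(np.minimum(c["sd_k"] * ek, 50.0)) * c["tau"]
        f0 = Dt - El
        f = np.maximum(f0, 0.0)
        v = f * f * c["sp2"] + c["sa2"]
        return Dt, El, f0, f, v

    def _q(self, c, ed, ek, ka_rec):
        """Per-record negative log joint density (obs + eta priors)."""
        _, _, _, f, v = self._f_v(c, ed, ek, ka_rec)
        r = c["y"] - f
        obs = 0.5 * (LOG2PI + np.log(v)) + r * r / (2.0 * v)
        if self.config.blq_mode == "conditional":
            obs = obs + log_ndtr((f - self.config.lloq_ng) / np.sqrt(v))
        elif self.config.blq_mode == "censored" and c["blq"].any():
            z = (self.config.lloq_ng - f) / np.sqrt(v)
            obs = np.where(c["blq"], -log_ndtr(z), obs)
        return 0.5 * (ed * ed + ek * ek) + LOG2PI + obs

    def _dq_df(self, c, f, v):
        """First derivative of the per-record observation term wrt the
        prediction f (combined error, eta-epsilon interaction)."""
        r = c["y"] - f
        vp = 2.0 * f * c["sp2"]
        out = vp / (2.0 * v) - r / v - r * r * vp / (2.0 * v * v)
        if self.config.blq_mode == "conditional":
            out = out + self._trunc_terms(c, f, v)[0]
        return out

    def _trunc_terms(self, c, f, v):
        """First and second f-derivatives of the LLOQ truncation penalty
        log Phi((f - LLOQ)/sqrt(v)) of the conditional (M2) likelihood."""
        L = self.config.lloq_ng
        sv = np.sqrt(v)
        z = (f - L) / sv
        vp = 2.0 * f * c["sp2"]
        vpp = 2.0 * c["sp2"]
        sp_ = vp / (2.0 * sv)                      # d sqrt(v) / df
        z1 = 1.0 / sv - (f - L) * vp / (2.0 * v * sv)
        z2 = (-sp_ / v
              - 0.5 * (vp + (f - L) * vpp) / (v * sv)
              + 1.5 * (f - L) * vp * sp_ / (v * v))
        ratio = np.exp(-0.5 * z * z - 0.5 * LOG2PI - log_ndtr(z))
        dratio = -ratio * (z + ratio)              # d(phi/Phi)/dz
        d1 = ratio * z1
        d2 = dratio * z1 * z1 + ratio * z2
        return d1, d2

    def _grad(self, c, ed, ek, ka_rec):
        """Per-record gradient of q wrt (eta_D, eta_k, kappa); the kappa
        component excludes the batch-level prior term."""
        Dt, El, f0, f, v = self._f_v(c, ed, ek, ka_rec)
        pos = f0 > 0
        dq_df = self._dq_df(c, f, v)
        if self.config.blq_mode == "censored" and c["blq"].any():
            sv = np.sqrt(v)
            z = (self.config.lloq_ng - f) / sv
            vp = 2.0 * f * c["sp2"]
            # d(-log Phi(z))/df with dz/df = -1/sqrt(v) - z*v'/(2v)
            ratio = np.exp(-0.5 * z * z - 0.5 * LOG2PI - log_ndtr(z))
            dq_df = np.where(c["blq"], ratio * (1.0 / sv + z * vp / (2.0 * v)),
                             dq_df)
        df_ded = np.where(pos, Dt * c["sd_d"], 0.0)
        df_dek = np.where(pos, -El * c["sd_k"], 0.0)
        df_dka = np.where(pos, Dt * c["sd_v"], 0.0)
        return (ed + dq_df * df_ded,
                ek + dq_df * df_dek,
                dq_df * df_dka), (df_ded, df_dek, df_dka, f, v)

    def _qgh(self, c, ed, ek, ka_rec):
        """Fused per-record value, gradient and 2x2 Hessian of q wrt
        (eta_D, eta_k).  The Hessian is analytic:

            H = I + u * D2f + u' * Df Df^T

        with u = dq/df, u' = d2q/df2, Df the prediction gradient and D2f
        its (diagonal) second derivative; censored records fall back to
        finite differences of the analytic gradient.
        """
        Dt, El, f0, f, v = self._f_v(c, ed, ek, ka_rec)
        pos = f0 > 0
        r = c["y"] - f
        obs = 0.5 * (LOG2PI + np.log(v)) + r * r / (2.0 * v)
        q = 0.5 * (ed * ed + ek * ek) + LOG2PI + obs
        vp = 2.0 * f * c["sp2"]
        vpp = 2.0 * c["sp2"]
        u = vp / (2.0 * v) - r / v - r * r * vp / (2.0 * v * v)
        du = (vpp / (2.0 * v) - vp * vp / (2.0 * v * v)
              + 1.0 / v + r * vp / (v * v)
              + (2.0 * r * vp - r * r * vpp) / (2.0 * v * v)
              + r * r * vp * vp / (v * v * v))
        if self.config.blq_mode == "conditional":
            q = q + log_ndtr((f - self.config.lloq_ng) / np.sqrt(v))
            t1, t2 = self._trunc_terms(c, f, v)
            u = u + t1
            du = du + t2
        gd = np.where(pos, Dt * c["sd_d"], 0.0)
        gk = np.where(pos, -El * c["sd_k"], 0.0)
        g0 = ed + u * gd
        g1 = ek + u * gk
        H00 = 1.0 + u * np.where(pos, Dt * c["sd_d"] ** 2, 0.0) + du * gd * gd
        H01 = du * gd * gk
        H11 = 1.0 + u * np.where(pos, -El * c["sd_k"] ** 2, 0.0) + du * gk * gk
        if self.config.blq_mode == "censored" and c["blq"].any():
            q = self._q(c, ed, ek, ka_rec)
            (g0c, g1c, _), _ = self._grad(c, ed, ek, ka_rec)
            g0 = np.where(c["blq"], g0c, g0)
            g1 = np.where(c["blq"], g1c, g1)
            h = 1e-5
            gp0, _ = self._grad(c, ed + h, ek, ka_rec)
            gm0, _ = self._grad(c, ed - h, ek, ka_rec)
            gp1, _ = self._grad(c, ed, ek + h, ka_rec)
            gm1, _ = self._grad(c, ed, ek - h, ka_rec)
            H00 = np.where(c["blq"], (gp0[0] - gm0[0]) / (2 * h), H00)
            H01 = np.where(c["blq"],
                           ((gp0[1] - gm0[1]) + (gp1[0] - gm1[0])) / (4 * h),
                           H01)
            H11 = np.where(c["blq"], (gp1[1] - gm1[1]) / (2 * h), H11)
        return q, g0, g1, H00, H01, H11

    @staticmethod
    def _reg_2x2(a, b, cc, floor=1e-7):
        """Eigenvalue-floor regularisation of per-record 2x2 blocks."""
        half_tr = 0.5 * (a + cc)
        rad = np.sqrt(0.25 * (a - cc) ** 2 + b * b)
        eig_min = half_tr - rad
        bump = np.maximum(floor - eig_min, 0.0)
        return a + bump, b, cc + bump

    def _eta_candidate(self, c, ka_rec):
        """Analytic on-curve start: eta_k = 0 and the dose deviate chosen
        so the curve passes through the observation (or, when the dose
        carries no random effect, the elimination deviate instead)."""
        wd, wk, wv = c["sd_d"], c["sd_k"], c["sd_v"]
        y_eff = np.where(c["blq"], self.config.lloq_ng, c["y"])
        y_eff = np.maximum(y_eff, 1e-12)
        if np.ndim(wd) > 0 or wd > 0:
            target = y_eff + c["ck"] * c["tau"]
            ed0 = (np.log(target / c["cd"]) - wv * ka_rec) / np.maximum(wd, 1e-300)
            ek0 = np.zeros_like(ed0)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                Dt0 = c["cd"] * np.exp(wv * ka_rec)
                ratio = (np.maximum(Dt0 - y_eff, 1e-300)
                         / np.maximum(c["ck"] * c["tau"], 1e-300))
                ek0 = np.where(c["tau"] > 0, np.log(ratio) / wk, 0.0)
            ed0 = np.zeros_like(ek0)
        return np.clip(ed0, -40.0, 40.0), np.clip(ek0, -40.0, 40.0)

    def _clip_candidate(self, c, ka_rec, beta):
        """Optimum of the prior inside the depleted half-plane: the origin
        if already depleted there, else its projection on the boundary."""
        wd, wk = c["sd_d"], c["sd_k"]
        denom = wd * wd + wk * wk
        inside = beta >= 0
        active = c["tau"] > 0
        with np.errstate(invalid="ignore"):
            ed0 = np.where(active & ~inside, wd * beta / denom, 0.0)
            ek0 = np.where(active & ~inside, -wk * beta / denom, 0.0)
        return np.nan_to_num(ed0), np.nan_to_num(ek0)

    def _refine_eta(self, c, ed, ek, ka_rec, max_iter=50):
        """Vectorised damped-Newton minimisation of q over (eta_D, eta_k)
        per record, batch deviates held fixed.

        Every record is driven independently: improvements are committed
        per record, damping is per record, and records that converge (or
        stall at the non-smooth depletion boundary under heavy damping)
        drop out without holding the others back.  Returns the modes, q and
        the (unregularised) Hessian entries at the modes.
        """
        n = len(ed)
        # full-vector outputs, scattered back from the shrinking working set
        ed_f, ek_f = ed.copy(), ek.copy()
        q_f, g0_f, g1_f, H00_f, H01_f, H11_f = self._qgh(c, ed, ek, ka_rec)
        idx = np.arange(n)
        cw, kaw = c, ka_rec
        edw, ekw = ed_f.copy(), ek_f.copy()
        qw, g0, g1, H00, H01, H11 = (x.copy() for x in
                                     (q_f, g0_f, g1_f, H00_f, H01_f, H11_f))
        lam = np.zeros(n)
        for _ in range(max_iter):
            gn = np.maximum(np.abs(g0), np.abs(g1))
            active = (gn > self.GRAD_TOL) & (lam < 1e6)
            if not active.any():
                break
            if active.sum() < 0.7 * len(idx):
                # compress the working set: converged and stalled records
                # keep their last full-vector values
                sel = np.flatnonzero(active)
                idx = idx[sel]
                cw = {k: (v[idx] if np.ndim(v) > 0 else v)
                      for k, v in c.items()}
                kaw = ka_rec[idx]
                edw, ekw, lam = edw[sel], ekw[sel], lam[sel]
                qw, g0, g1 = qw[sel], g0[sel], g1[sel]
                H00, H01, H11 = H00[sel], H01[sel], H11[sel]
                active = np.ones(len(idx), dtype=bool)
            a, b, cc = self._reg_2x2(H00 + lam, H01, H11 + lam)
            det = a * cc - b * b
            d0 = np.where(active, (cc * g0 - b * g1) / det, 0.0)
            d1 = np.where(active, (a * g1 - b * g0) / det, 0.0)
            alpha = np.ones(len(idx))
            ok = np.zeros(len(idx), dtype=bool)
            for _ls in range(8):
                te = edw - alpha * d0
                tk = ekw - alpha * d1
                qt = self._q(cw, te, tk, kaw)
                better = active & ~ok & (qt < qw - 1e-14)
                edw = np.where(better, te, edw)
                ekw = np.where(better, tk, ekw)
                ok |= better
                if not (active & ~ok).any():
                    break
                alpha *= 0.5
            failed = active & ~ok
            lam = np.where(ok, lam / 3.0, lam)
            lam[lam < 1e-10] = 0.0
            # aggressive escalation: records pinned at the depletion kink
            # cannot descend and must drop out quickly
            lam[failed] = np.maximum(lam[failed] * 100.0, 10.0)
            qw, g0, g1, H00, H01, H11 = self._qgh(cw, edw, ekw, kaw)
            ed_f[idx], ek_f[idx], q_f[idx] = edw, ekw, qw
            g0_f[idx], g1_f[idx] = g0, g1
            H00_f[idx], H01_f[idx], H11_f[idx] = H00, H01, H11
        gn_f = np.maximum(np.abs(g0_f), np.abs(g1_f))
        return ed_f, ek_f, q_f, (H00_f, H01_f, H11_f), gn_f

    def _record_logI(self, c, ka_rec, want_modes: bool = False):
        """log of the per-record 2-d integral over (eta_D, eta_k) given the
        batch deviates.

        The zero-amount clip splits the conditional density of a post-lag
        record in two.  Over the fully-depleted half-plane
        {wd*eta_D - wk*eta_k <= beta} the observation factor is constant,
        so that part is EXACT: the residual density at zero amount times a
        Gaussian half-plane mass.  The on-curve part is a Laplace term at
        the interior mode, multiplied by the Gaussian mass of the mode's
        own half-plane in the Hessian metric - a smooth truncation factor
        that vanishes as the mode slides into the depleted region, so the
        parts never double-count and the OFV stays smooth in the
        population parameters.
        """
        wd, wk, wv = c["sd_d"], c["sd_k"], c["sd_v"]
        denom = wd * wd + wk * wk
        if np.ndim(denom) == 0 and denom <= 0:
            # no individual random effects: the integral is the plain
            # observation density at eta = 0 (q handles the clip itself)
            zeros = np.zeros(len(c["y"]))
            logI = LOG2PI - self._q(c, zeros, zeros, ka_rec)
            if want_modes:
                return logI, (zeros, zeros)
            return logI
        norm = np.sqrt(denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (np.log(c["ck"] * np.maximum(c["tau"], 1e-300) / c["cd"])
                    - wv * ka_rec)
        beta = np.where(c["tau"] > 0, beta, -np.inf)
        # exact depleted-region term
        sa2 = c["sa2"]
        obs_clip = 0.5 * np.log(2.0 * math.pi * sa2) + c["y"] ** 2 / (2.0 * sa2)
        if self.config.blq_mode == "conditional":
            obs_clip = obs_clip + log_ndtr(-self.config.lloq_ng / np.sqrt(sa2))
        elif self.config.blq_mode == "censored" and c["blq"].any():
            z0 = self.config.lloq_ng / np.sqrt(sa2)
            obs_clip = np.where(c["blq"], -log_ndtr(z0), obs_clip)
        with np.errstate(invalid="ignore"):
            term_clip = -obs_clip + log_ndtr(
                np.where(np.isneginf(beta), -np.inf, beta / norm))
        # on-curve Laplace term with smooth half-plane truncation
        ed0, ek0 = self._eta_candidate(c, ka_rec)
        ed, ek, q, (H00, H01, H11), gn = self._refine_eta(c, ed0, ek0, ka_rec)
        stuck = (gn > 1e-5) & np.isfinite(beta)
        if stuck.any():
            # a record whose on-curve optimum sits ON the depletion boundary
            # has a one-sided stationarity condition Newton cannot satisfy;
            # snap it to the analytic boundary optimum (prior projection),
            # nudged infinitesimally to the curve side so q and the Hessian
            # are evaluated on the same branch as nearby interior modes
            zeta = 1e-9
            bnd = beta + zeta
            ed = np.where(stuck, wd * bnd / denom, ed)
            ek = np.where(stuck, -wk * bnd / denom, ek)
            q2, _, _, h00, h01, h11 = self._qgh(c, ed, ek, ka_rec)
            q = np.where(stuck, q2, q)
            H00 = np.where(stuck, h00, H00)
            H01 = np.where(stuck, h01, H01)
            H11 = np.where(stuck, h11, H11)
        a, b, cc = self._reg_2x2(H00, H01, H11)
        det = a * cc - b * b
        s = (wd * ed - wk * ek - beta) / norm
        n0, n1 = wd / norm, -wk / norm
        sigma_n = np.sqrt(np.maximum(
            (cc * n0 * n0 - 2.0 * b * n0 * n1 + a * n1 * n1) / det, 1e-12))
        with np.errstate(invalid="ignore"):
            trunc = log_ndtr(np.where(np.isneginf(beta), np.inf, s / sigma_n))
        term_curve = LOG2PI - q - 0.5 * np.log(det) + trunc
        logI = np.logaddexp(term_curve, term_clip)
        if want_modes:
            clip_dominates = term_clip > term_curve
            ed_c, ek_c = self._clip_candidate(c, ka_rec, beta)
            ed = np.where(clip_dominates, ed_c, ed)
            ek = np.where(clip_dominates, ek_c, ek)
            return logI, (ed, ek)
        return logI

    def _h(self, c, ka) -> np.ndarray:
        """Per-batch negative log integrand of the occasion deviate:
        h_b(kappa) = kappa^2/2 + log(2 pi)/2 - sum_i log I_i(kappa)."""
        logI = self._record_logI(c, ka[c["batch"]])
        return 0.5 * ka * ka + 0.5 * LOG2PI - self._batch_sum(c, logI)

    def _solve_kappa(self, c, ka0=None, max_iter=40):
        """1-d Newton per batch for the occasion-deviate mode, plus the
        curvature h'' used by the outer Laplace step.  Batches are updated
        simultaneously (their records are disjoint), converged batches are
        frozen, and the three points of each derivative stencil are
        evaluated in one stacked vector pass.

        Returns (ka, h0, h'', converged-per-batch).
        """
        delta = self.KAPPA_STEP
        np_err = np.seterr(all="ignore")   # probes may overflow; handled
        nb = c["nb"]
        ka = np.zeros(nb) if ka0 is None else np.asarray(ka0, dtype=float).copy()
        if not np.all(np.isfinite(ka)):
            ka = np.zeros(nb)
        all_ok = np.ones(nb, dtype=bool)
        if np.all(np.asarray(c["sd_v"]) == 0.0):
            ka = np.zeros(nb)
            return ka, self._h(c, ka), np.ones(nb), all_ok
        c3 = self._tile(c, 3)

        def stencil(k):
            kk = np.concatenate([k, k + delta, k - delta])
            h3 = self._h(c3, kk)
            return h3[:nb], h3[nb:2 * nb], h3[2 * nb:]

        h0, hp, hm = stencil(ka)
        if not np.all(np.isfinite(h0)):
            ka = np.where(np.isfinite(h0), ka, 0.0)
            h0, hp, hm = stencil(ka)
        d1 = (hp - hm) / (2 * delta)
        d2 = (hp - 2 * h0 + hm) / delta ** 2
        converged = np.zeros(nb, dtype=bool)
        for it in range(max_iter):
            # negative or vanishing curvature far from the mode: fall back
            # to a bounded gradient step (the prior guarantees h'' > 0 near
            # the mode, so this only happens in the far tails)
            d2_safe = np.where(d2 > 0.1, d2, 1.0)
            # remaining OFV error after one more Newton step is ~d1^2/d2
            err = d1 * d1 / d2_safe
            converged = ((err < 3e-9) & (d2 > 0)) | ~np.isfinite(h0)
            if converged.all():
                break
            step = np.where(converged, 0.0, np.clip(d1 / d2_safe, -3.0, 3.0))
            if np.max(np.abs(step)) < 1e-5:
                converged |= True
                break
            alpha = np.ones(nb)
            moved = False
            for _ls in range(10):
                h_t = self._h(c, np.clip(ka - alpha * step, -40.0, 40.0))
                worse = ~converged & ~(h_t <= h0 + 1e-10)
                if not worse.any():
                    ka = np.clip(ka - alpha * step, -40.0, 40.0)
                    moved = True
                    break
                alpha[worse] *= 0.5
            if not moved:
                # the backtracking line search found no descent at any step
                # size: the current point is a (possibly kinked) minimum of
                # h at the evaluation resolution, so accept it
                converged = np.ones(nb, dtype=bool)
                break
            h0, hp, hm = stencil(ka)
            d1 = (hp - hm) / (2 * delta)
            d2 = (hp - 2 * h0 + hm) / delta ** 2
        d2 = np.maximum(d2, 1e-6)
        converged = converged & np.isfinite(h0)
        np.seterr(**np_err)
        return ka, h0, d2, converged

    def neg2ll(self, pop: PopulationParams) -> float:
        """Approximate -2 log marginal likelihood (OFV): nested Laplace over
        the per-mosquito deviates (dual-region, per record) and the
        per-batch occasion deviate.

        Returns +inf when the mode searches fail to converge.
        """
        pop.validate()
        c = self._constants(pop)
        try:
            ka, h0, d2, ok = self._solve_kappa(c, self._ka)
            if not ok.all():
                # retry once from a cold start before declaring failure
                ka, h0, d2, ok = self._solve_kappa(c, None)
        except FloatingPointError:
            return math.inf
        self._ka = ka
        if not ok.all() or not np.all(np.isfinite(h0)):
            return math.inf
        return float(np.sum(2.0 * h0 - LOG2PI + np.log(d2)))

    __call__ = neg2ll

    def neg2ll_multi(self, pops: Sequence[PopulationParams]) -> np.ndarray:
        """OFV for several parameter vectors on the same data in one stacked
        vector pass (used for finite-difference gradients: the cost of m
        evaluations is close to the cost of one)."""
        m = len(pops)
        ctxs = []
        for pop in pops:
            pop.validate()
            ctxs.append(self._constants(pop))
        if any(np.ndim(c["sd_d"]) == 0 and c["sd_d"] ** 2 + c["sd_k"] ** 2 <= 0
               for c in ctxs) and m > 1:
            # degenerate eta dimensions use a scalar shortcut; keep it simple
            return np.array([self.neg2ll(pop) for pop in pops])
        nb, n = self.n_batches, self.n_obs
        mega = dict(ctxs[0])
        for key in ("cd", "ck", "tau", "y", "blq"):
            mega[key] = np.concatenate([c[key] for c in ctxs])
        for key in ("sd_d", "sd_k", "sd_v", "sp2", "sa2"):
            vals = [c[key] for c in ctxs]
            if all(v == vals[0] for v in vals):
                mega[key] = vals[0]
            else:
                mega[key] = np.concatenate(
                    [np.full(n, float(v)) for v in vals])
        mega["batch"] = np.concatenate(
            [ctxs[0]["batch"] + j * nb for j in range(m)])
        mega["nb"] = nb * m
        try:
            ka, h0, d2, ok = self._solve_kappa(mega, np.tile(self._ka, m))
            if not ok.all():
                ka, h0, d2, ok = self._solve_kappa(mega, None)
        except FloatingPointError:
            return np.full(m, math.inf)
        self._ka = ka[:nb]
        per_batch = 2.0 * h0 - LOG2PI + np.log(d2)
        out = per_batch.reshape(m, nb).sum(axis=1)
        bad = (~ok.reshape(m, nb)).any(axis=1) | ~np.isfinite(out)
        out[bad] = math.inf
        return out

    def conditional(self, pop: PopulationParams) -> pd.DataFrame:
        """Conditional modes and linearisation pieces per record (used for
        individual predictions and CWRES)."""
        c = self._constants(pop)
        ka, h0, _, ok = self._solve_kappa(c, self._ka)
        if not ok.all():
            raise RuntimeError("conditional-mode search did not converge")
        ka_rec = ka[self.data.batch]
        _, (ed, ek) = self._record_logI(c, ka_rec, want_modes=True)
        _, deriv = self._grad(c, ed, ek, ka_rec)
        df_ded, df_dek, df_dka, f, v = deriv
        return pd.DataFrame({
            "y": self.data.y, "time_h": self.data.t, "ipred": f, "var": v,
            "eta_dose": ed, "eta_kel": ek, "kappa": ka_rec,
            "df_deta_dose": df_ded, "df_deta_kel": df_dek,
            "df_dkappa": df_dka, "blq": self.data.blq,
        }, index=self.data.index)

    def reset_cache(self) -> None:
        self._ka[:] = 0.0


def marginal_neg2ll(pop: PopulationParams, data: RecordsLike,
                    config: Optional[ModelConfig] = None) -> float:
    """One-shot OFV (-2 log marginal likelihood) for a dataset."""
    return LaplaceObjective(data, config).neg2ll(pop)
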