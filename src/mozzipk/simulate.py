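"""Synthetic study generators: PK time courses, dosing-linearity feedings
and drug-effect endpoint experiments.

The PK generator reproduces the destructive-sampling design: per feeding
batch a shared occasion deviate on dose, per mosquito individual deviates on
dose and elimination rate, a body weight recorded at extraction, combined
residual error and LLOQ censoring.

Weights are modelled compositionally: an unfed body mass (lognormal) plus
the imbibed blood-meal mass (meal volume in ul times blood density
1.06 mg/ul), with the meal fraction digested linearly over 72 h.  The
defaults give a mean post-feeding weight near 4.5 mg, a pooled median
recorded weight near 3.4 mg and a ~52% total weight loss over 72 h, and they
couple weight to meal size so that weight-normalising a measured amount
genuinely removes meal-volume variability.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datamodel import (EffectsRecord, LinearityRecord, MosquitoRecord,
                        PopulationParams, StudyDesign, default_design,
                        reference_params)
from .population import ModelConfig

__all__ = ["SimulationConfig", "EffectScenario", "simulate_pk_study",
           "simulate_linearity_experiment", "simulate_effects_study",
           "default_effect_scenarios", "rng_for"]


def rng_for(seed: int, key: str) -> np.random.Generator:
    """Independent, reproducible stream derived from one study seed and a
    named substream key ('simulate', 'bootstrap', 'vpc', ...)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(key.encode("utf8"))]))


def _lognormal_median(rng, median: float, cv: float, size) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(np.log(median), sigma, size=size)


def _lognormal_mean(rng, mean: float, cv: float, size) -> np.ndarray:
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2), size=size)


@dataclass
class SimulationConfig:
    """Study conditions for the PK simulator."""
    design: StudyDesign = field(default_factory=default_design)
    truth: PopulationParams = field(default_factory=reference_params)
    model: ModelConfig = field(default_factory=ModelConfig)
    unfed_median_mg: float = 0.9
    unfed_cv: float = 0.15
    meal_volume_mean_ul: float = 3.6
    meal_volume_cv: float = 0.167
    blood_density_mg_per_ul: float = 1.06
    meal_loss_frac_72h: float = 0.64
    #: draw the per-batch occasion deviates with their sample mean removed;
    #: used by recovery experiments, where the population dose is otherwise
    #: confounded with the mean of the few realised occasion effects
    center_occasion_deviates: bool = False
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        self.truth.validate()
        for name in ("unfed_median_mg", "meal_volume_mean_ul",
                     "blood_density_mg_per_ul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.meal_loss_frac_72h <= 1.0:
            raise ValueError("meal_loss_frac_72h must be in [0, 1]")


def _weights(cfg: SimulationConfig, rng, t: float, n: int) -> np.ndarray:
    unfed = _lognormal_median(rng, cfg.unfed_median_mg, cfg.unfed_cv, n)
    vol = _lognormal_mean(rng, cfg.meal_volume_mean_ul, cfg.meal_volume_cv, n)
    remaining = 1.0 - cfg.meal_loss_frac_72h * min(t, 72.0) / 72.0
    return unfed + vol * cfg.blood_density_mg_per_ul * remaining


def _simulate_arrays(config: SimulationConfig, rng) -> dict:
    """Array-level PK simulation (shared by the record builder and the VPC)."""
    pop, mc = config.truth, config.model
    sd_d, sd_k = mc.sd(pop.omega_dose), mc.sd(pop.omega_kel)
    sd_v = mc.sd(pop.omega_iov_dose)
    sp, sa = mc.sd(pop.sigma_prop), mc.sd(pop.sigma_add_ng)
    batch_l, arm_l, t_l, w_l, y_l = [], [], [], [], []
    kappas = rng.standard_normal(len(config.design.batches))
    if config.center_occasion_deviates and len(kappas) > 1:
        kappas = kappas - kappas.mean()
    for kappa, batch in zip(kappas, config.design.batches):
        for arm in batch.arms:
            is_rit = "RTV" in arm
            tlag = pop.theta_tlag_h + (pop.theta_tlag_add_rit_h
                                       if (is_rit and mc.ritonavir_lag) else 0.0)
            for t in config.design.time_grid_h:
                n = config.design.n_per_timepoint
                w = _weights(config, rng, t, n)
                eta_d = rng.standard_normal(n)
                eta_k = rng.standard_normal(n)
                rel_w = w / pop.wt_ref_mg
                dose = (pop.theta_dose_ng * rel_w ** pop.exp_wt_dose
                        * np.exp(sd_d * eta_d + sd_v * kappa))
                kel = (pop.theta_kel_ng_per_h * rel_w ** pop.exp_wt_kel
                       * np.exp(sd_k * eta_k))
                f = np.maximum(dose - kel * max(t - tlag, 0.0), 0.0)
                v = f * f * sp * sp + sa * sa
                y = f + np.sqrt(v) * rng.standard_normal(n)
                batch_l.extend([batch.batch_id] * n)
                arm_l.extend([arm] * n)
                t_l.append(np.full(n, float(t)))
                w_l.append(w)
                y_l.append(y)
    t = np.concatenate(t_l)
    y = np.concatenate(y_l)
    return dict(batch=np.array(batch_l), arm=np.array(arm_l), t=t,
                w=np.concatenate(w_l), y=y, blq=y < config.design.lloq_ng)


def simulate_pk_study(config: SimulationConfig) -> list[MosquitoRecord]:
    """Draw one full destructive-sampling PK dataset under the configured
    design and generating parameters (deterministic given the seed)."""
    config.validate()
    rng = rng_for(config.seed, "simulate")
    arr = _simulate_arrays(config, rng)
    records = []
    for j in range(len(arr["y"])):
        blq = bool(arr["blq"][j])
        records.append(MosquitoRecord(
            mosquito_id=f"M{j + 1:05d}", batch_id=str(arr["batch"][j]),
            arm=str(arr["arm"][j]), analyte="IVM", time_h=float(arr["t"][j]),
            weight_mg=float(arr["w"][j]),
            amount_ng=None if blq else float(arr["y"][j]), blq=blq))
    return records


def simulate_linearity_experiment(
        concentrations: Sequence[float] = (0.01, 0.05, 0.1, 0.5, 1.0),
        n_per_conc: int = 30,
        meal_volume_mean_ul: float = 3.6,
        meal_volume_cv: float = 0.167,
        assay_cv: float = 0.08,
        unfed_median_mg: float = 0.9,
        unfed_cv: float = 0.15,
        blood_density_mg_per_ul: float = 1.06,
        seed: int = 0) -> list[LinearityRecord]:
    """Dosing-linearity feeding: amount = blood concentration x imbibed
    volume (lognormal), with a proportional assay error; weights as recorded
    directly after the feeding (unfed mass + meal mass)."""
    if n_per_conc < 1:
        raise ValueError("n_per_conc must be >= 1")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be > 0")
    rng = rng_for(seed, "linearity")
    records = []
    for conc in concentrations:
        vol = (_lognormal_mean(rng, meal_volume_mean_ul, meal_volume_cv, n_per_conc)
               if meal_volume_cv > 0
               else np.full(n_per_conc, meal_volume_mean_ul))
        noise = (_lognormal_mean(rng, 1.0, assay_cv, n_per_conc)
                 if assay_cv > 0 else np.ones(n_per_conc))
        unfed = (_lognormal_median(rng, unfed_median_mg, unfed_cv, n_per_conc)
                 if unfed_cv > 0 else np.full(n_per_conc, unfed_median_mg))
        amount = conc * vol * noise
        weight = unfed + vol * blood_density_mg_per_ul
        records.extend(
            LinearityRecord(blood_conc_ug_ml=float(conc),
                            amount_ng=float(a), weight_mg=float(wt))
            for a, wt in zip(amount, weight))
    return records


@dataclass
class EffectScenario:
    """Per-arm generating rates for the endpoint experiment."""
    survival_4day: float
    fecundity_mean: float
    fertility_p: float
    fecundity_dispersion: float = 20.0

    def validate(self) -> None:
        if not 0.0 <= self.survival_4day <= 1.0:
            raise ValueError("survival_4day must be in [0, 1]")
        if not 0.0 <= self.fertility_p <= 1.0:
            raise ValueError("fertility_p must be in [0, 1]")
        if self.fecundity_mean <= 0:
            raise ValueError("fecundity_mean must be > 0")


def default_effect_scenarios() -> dict[str, EffectScenario]:
    """Reference endpoint scenario: 92% four-day control survival, modest
    mortality from the CYP modulators alone, a strong mortality boost for
    the ivermectin + ritonavir combination, and near-complete egg
    sterilisation by ivermectin."""
    return {
        "CONTROL": EffectScenario(0.92, 3000.0, 0.83),
        "IVM": EffectScenario(0.83, 1800.0, 0.02),
        "KCZ": EffectScenario(0.90, 2800.0, 0.78),
        "RIF": EffectScenario(0.89, 2800.0, 0.76),
        "RTV": EffectScenario(0.88, 2800.0, 0.75),
        "PBO": EffectScenario(0.87, 2800.0, 0.72),
        "IVM_KCZ": EffectScenario(0.81, 1700.0, 0.02),
        "IVM_RIF": EffectScenario(0.88, 1800.0, 0.02),
        "IVM_RTV": EffectScenario(0.58, 1000.0, 0.01),
        "IVM_PBO": EffectScenario(0.73, 1500.0, 0.02),
    }


def simulate_effects_study(arm_rates: Optional[dict[str, EffectScenario]] = None,
                           n_replicates: int = 3, n_per_group: int = 50,
                           eggs_assayed: int = 100,
                           seed: int = 0) -> list[EffectsRecord]:
    """Replicated endpoint experiment: daily-survival binomial chains at
    24/48/72/96 h (monotone non-increasing by construction), overdispersed
    egg counts (negative binomial) and binomial hatching out of the eggs
    assayed."""
    rates = arm_rates or default_effect_scenarios()
    rng = rng_for(seed, "effects")
    records = []
    for arm, sc in rates.items():
        sc.validate()
        p_day = sc.survival_4day ** 0.25
        for rep in range(1, n_replicates + 1):
            alive = [n_per_group]
            for _ in range(4):
                alive.append(int(rng.binomial(alive[-1], p_day)))
            k = sc.fecundity_dispersion
            eggs = float(rng.negative_binomial(k, k / (k + sc.fecundity_mean)))
            n_assay = int(min(eggs_assayed, eggs)) if eggs < eggs_assayed else eggs_assayed
            hatched = int(rng.binomial(n_assay, sc.fertility_p)) if n_assay else 0
            records.append(EffectsRecord(
                arm=arm, replicate=f"R{rep}", n_initial=n_per_group,
                alive_24h=alive[1], alive_48h=alive[2], alive_72h=alive[3],
                alive_96h=alive[4], eggs=eggs, eggs_assayed=max(n_assay, 1),
                hatched=hatched))
    return records
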