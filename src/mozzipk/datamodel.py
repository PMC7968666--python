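"""Shared domain types for whole-body pharmacokinetic studies in mosquitoes.

Units are fixed throughout the package: drug amounts in ng, time in hours
since the end of the blood feeding, body weight in mg, blood concentration
in ug/ml (1 ug/ml == 1 ng/ul).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

ARMS = ("CONTROL", "IVM", "IVM_KCZ", "IVM_RIF", "IVM_RTV", "IVM_PBO",
        "KCZ", "RIF", "RTV", "PBO")
ANALYTES = ("IVM", "KCZ", "RIF", "RTV", "PBO")

#: arms in which ritonavir is co-administered with ivermectin
RITONAVIR_ARMS = frozenset({"IVM_RTV"})

#: nominal sampling grid of the destructive-sampling design (hours)
DESIGN_TIME_GRID = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0)


class SchemaError(ValueError):
    """A dataset file does not match the expected column schema."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass
class MosquitoRecord:
    """One destructively sampled individual: a single (time, amount) point.

    ``blq`` marks a measurement below the lower limit of quantification;
    in that case ``amount_ng`` is absent and ignored.
    """
    mosquito_id: str
    batch_id: str
    arm: str
    time_h: float
    weight_mg: float
    amount_ng: Optional[float]
    blq: bool = False
    analyte: str = "IVM"
    extra: dict = field(default_factory=dict)

    def validate(self, index: Optional[int] = None) -> None:
        where = "" if index is None else f" (row {index})"
        if self.arm not in ARMS:
            raise ValidationError(f"unknown arm {self.arm!r}{where}")
        if self.analyte not in ANALYTES:
            raise ValidationError(f"unknown analyte {self.analyte!r}{where}")
        if not math.isfinite(self.time_h) or self.time_h < 0:
            raise ValidationError(f"negative or non-finite time {self.time_h!r}{where}")
        if not math.isfinite(self.weight_mg) or self.weight_mg <= 0:
            raise ValidationError(f"non-positive weight {self.weight_mg!r}{where}")
        if self.blq:
            # amount is ignored for censored records
            return
        if self.amount_ng is None or not math.isfinite(self.amount_ng):
            raise ValidationError(f"missing amount for non-BLQ record{where}")
        if self.amount_ng < 0:
            raise ValidationError(f"negative amount {self.amount_ng!r}{where}")

    @property
    def is_ritonavir(self) -> bool:
        return self.arm in RITONAVIR_ARMS


def validate_records(records: Sequence[MosquitoRecord]) -> None:
    """Validate every record and the one-observation-per-individual rule."""
    seen = set()
    for i, rec in enumerate(records):
        rec.validate(index=i)
        key = (rec.mosquito_id, rec.analyte)
        if key in seen:
            raise ValidationError(
                f"duplicate observation for mosquito {rec.mosquito_id!r} "
                f"analyte {rec.analyte!r} (row {i}); sampling is destructive"
            )
        seen.add(key)


@dataclass
class BatchDescriptor:
    batch_id: str
    arms: tuple[str, ...]
    median_weight_mg: float = 3.4


@dataclass
class StudyDesign:
    """Destructive-sampling study layout driving simulation and VPC."""
    batches: list[BatchDescriptor]
    time_grid_h: tuple[float, ...] = DESIGN_TIME_GRID
    n_per_timepoint: int = 20
    blood_conc_ug_ml: float = 0.1
    lloq_ng: float = 0.005

    def validate(self) -> None:
        if self.n_per_timepoint < 1:
            raise ValidationError("n_per_timepoint must be >= 1")
        if self.blood_conc_ug_ml <= 0:
            raise ValidationError("blood_conc_ug_ml must be > 0")
        if any(t < 0 for t in self.time_grid_h):
            raise ValidationError("sampling times must be non-negative")
        if not self.batches:
            raise ValidationError("design needs at least one batch")

    @property
    def n_records(self) -> int:
        return sum(len(b.arms) for b in self.batches) * len(self.time_grid_h) * self.n_per_timepoint


def default_design() -> StudyDesign:
    """The four-occasion paired design: every batch receives ivermectin alone
    plus ivermectin combined with one CYP modulator."""
    combos = ("IVM_KCZ", "IVM_RIF", "IVM_RTV", "IVM_PBO")
    batches = [BatchDescriptor(batch_id=f"B{i + 1}", arms=("IVM", combo))
               for i, combo in enumerate(combos)]
    return StudyDesign(batches=batches)


@dataclass
class LinearityRecord:
    """One mosquito from the dosing-linearity experiment."""
    blood_conc_ug_ml: float
    amount_ng: float
    weight_mg: float

    def validate(self, index: Optional[int] = None) -> None:
        where = "" if index is None else f" (row {index})"
        if self.blood_conc_ug_ml <= 0:
            raise ValidationError(f"non-positive concentration{where}")
        if self.amount_ng < 0:
            raise ValidationError(f"negative amount{where}")
        if self.weight_mg <= 0:
            raise ValidationError(f"non-positive weight{where}")


@dataclass
class EffectsRecord:
    """One replicate cup of a drug-effect experiment."""
    arm: str
    replicate: str
    n_initial: int
    alive_24h: int
    alive_48h: int
    alive_72h: int
    alive_96h: int
    eggs: float
    eggs_assayed: int = 100
    hatched: int = 0

    def validate(self, index: Optional[int] = None) -> None:
        where = "" if index is None else f" (row {index})"
        counts = [self.n_initial, self.alive_24h, self.alive_48h,
                  self.alive_72h, self.alive_96h]
        if any(c < 0 for c in counts):
            raise ValidationError(f"negative count{where}")
        if any(a > b for a, b in zip(counts[1:], counts[:-1])):
            raise ValidationError(f"survival counts must be non-increasing{where}")
        if self.hatched > self.eggs_assayed:
            raise ValidationError(f"hatched exceeds eggs assayed{where}")
        if self.eggs < 0:
            raise ValidationError(f"negative egg count{where}")

    @property
    def survival_pct(self) -> float:
        return 100.0 * self.alive_96h / self.n_initial

    @property
    def fertility_pct(self) -> float:
        return 100.0 * self.hatched / self.eggs_assayed


@dataclass
class StructuralParams:
    """Individual-level amount-time curve parameters.

    Exactly the parameter set of ``model_kind`` must be present:
    zero_order -> kel_ng_per_h; first_order -> k_per_h;
    michaelis_menten -> vmax_ng_per_h and km_ng.
    """
    dose_ng: float
    tlag_h: float = 0.0
    model_kind: str = "zero_order"
    kel_ng_per_h: Optional[float] = None
    k_per_h: Optional[float] = None
    vmax_ng_per_h: Optional[float] = None
    km_ng: Optional[float] = None

    _REQUIRED = {
        "zero_order": ("kel_ng_per_h",),
        "first_order": ("k_per_h",),
        "michaelis_menten": ("vmax_ng_per_h", "km_ng"),
    }

    def validate(self) -> None:
        if self.model_kind not in self._REQUIRED:
            raise ValidationError(f"unknown model_kind {self.model_kind!r}")
        if self.dose_ng <= 0:
            raise ValidationError("dose_ng must be > 0")
        if self.tlag_h < 0:
            raise ValidationError("tlag_h must be >= 0")
        needed = self._REQUIRED[self.model_kind]
        for name in needed:
            v = getattr(self, name)
            if v is None or v <= 0:
                raise ValidationError(f"{name} must be > 0 for {self.model_kind}")
        for kind, names in self._REQUIRED.items():
            if kind == self.model_kind:
                continue
            for name in names:
                if name not in needed and getattr(self, name) is not None:
                    raise ValidationError(
                        f"{name} must be absent for model_kind {self.model_kind!r}")


@dataclass
class PopulationParams:
    """Population-level fixed effects, variability magnitudes and covariate
    exponents of the final whole-body model.

    Variability magnitudes (omega, sigma) are standard deviations by default;
    see the ``variance_parameterization`` flag of :class:`ModelConfig` for the
    alternative reading.  Defaults are the package's reference scenario for
    ivermectin in Ae. aegypti: 0.28 ng absorbed, zero-order elimination at
    5.5 pg/h starting after an 18.5 h lag, an additional 11.4 h lag under
    ritonavir co-treatment.
    """
    theta_dose_ng: float = 0.28
    theta_kel_ng_per_h: float = 0.0055
    theta_tlag_h: float = 18.5
    theta_tlag_add_rit_h: float = 11.4
    omega_dose: float = 0.075
    omega_kel: float = 0.25
    omega_iov_dose: float = 0.11
    sigma_prop: float = 0.02
    sigma_add_ng: float = 0.018
    exp_wt_dose: float = 1.0
    exp_wt_kel: float = 0.75
    wt_ref_mg: float = 3.4

    FIXED_EFFECTS = ("theta_dose_ng", "theta_kel_ng_per_h",
                     "theta_tlag_h", "theta_tlag_add_rit_h")
    VARIABILITY = ("omega_dose", "omega_kel", "omega_iov_dose",
                   "sigma_prop", "sigma_add_ng")

    def validate(self) -> None:
        for name in ("theta_dose_ng", "theta_kel_ng_per_h", "wt_ref_mg"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.theta_tlag_h < 0 or self.theta_tlag_add_rit_h < 0:
            raise ValidationError("lag times must be >= 0")
        for name in self.VARIABILITY:
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    def replace(self, **kw) -> "PopulationParams":
        from dataclasses import replace
        return replace(self, **kw)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class RandomEffects:
    """Standard-normal deviates entering the individual parameter model.

    ``kappa_batch`` is the feeding-occasion (batch) deviate on dose, shared
    by every mosquito fed on that occasion.
    """
    eta_dose: float = 0.0
    eta_kel: float = 0.0
    kappa_batch: float = 0.0


def reference_params() -> PopulationParams:
    """Reference population estimates for ivermectin whole-body kinetics."""
    return PopulationParams()
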