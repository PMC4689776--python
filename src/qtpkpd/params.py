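"""Parameter containers for the concentration-QT analysis.

Three parameter sets travel through the pipeline:

* :class:`SpeciesParams` — the system- and drug-specific parameters of the
  individual-correction QT model (baseline QTc at RR = 1 s, the power-law
  heart-rate exponent, the 24-h circadian cosine, and the linear
  concentration-effect slope) together with between-subject variability (BSV)
  fractions and the residual SD.
* :class:`PKModelSpec` — the compartmental structure and parameters used to
  predict plasma concentration at ECG assessment times.
* :class:`DesignSpec` — the study design (subjects, doses, crossover vs
  parallel, sampling grids, RR-interval generator settings).

Species x compound presets (dog/monkey/human, moxifloxacin/NCE05) ship as YAML
files under ``qtpkpd/presets`` and are loaded with :func:`load_preset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "SpeciesParams",
    "PKModelSpec",
    "DesignSpec",
    "StudyPreset",
    "load_preset",
    "available_presets",
]


@dataclass
class SpeciesParams:
    """QT-model parameters for one species x compound.

    Parameters
    ----------
    qtc0_ms : float
        Baseline corrected QT (ms) at RR = 1 s.
    sex_effect_ms : float
        Additive baseline shift for females (ms); 0 where absent.
    alpha : float
        Dimensionless RR-correction exponent (QT = QTc0 * RR^alpha, RR in s).
    amp_ms : float
        Circadian cosine amplitude A (ms), >= 0.
    phase_h : float
        Circadian phase phi (clock hours, in [0, 24)).
    slope_ms_per_nM : float
        Linear concentration-effect coefficient (ms per nM).
    bsv : dict
        Fractional between-subject SDs with keys
        ``{"qtc0", "alpha", "amp", "phase", "slope"}``.  For log-normally
        distributed parameters the fraction is the SD of the log; for phase and
        slope it is the SD expressed as a fraction of the population value.
    resid_sd_ms : float
        Additive residual SD (ms).
    """

    qtc0_ms: float
    sex_effect_ms: float
    alpha: float
    amp_ms: float
    phase_h: float
    slope_ms_per_nM: float
    bsv: dict = field(default_factory=dict)
    resid_sd_ms: float = 1.0

    _BSV_KEYS = ("qtc0", "alpha", "amp", "phase", "slope")

    def __post_init__(self) -> None:
        if self.qtc0_ms <= 0:
            raise ValueError(f"qtc0_ms must be > 0, got {self.qtc0_ms}")
        if self.amp_ms < 0:
            raise ValueError(f"amp_ms must be >= 0, got {self.amp_ms}")
        if self.resid_sd_ms <= 0:
            raise ValueError(f"resid_sd_ms must be > 0, got {self.resid_sd_ms}")
        if not 0.0 <= self.phase_h < 24.0:
            raise ValueError(f"phase_h must lie in [0, 24), got {self.phase_h}")
        full = {k: 0.0 for k in self._BSV_KEYS}
        full.update(self.bsv or {})
        unknown = set(full) - set(self._BSV_KEYS)
        if unknown:
            raise ValueError(f"unknown bsv keys: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise ValueError("bsv entries must be >= 0")
        self.bsv = full


@dataclass
class PKModelSpec:
    """Compartmental PK structure + parameters for concentration prediction.

    ``structure`` is one of ``onecpt_first_order`` (oral one-compartment),
    ``twocpt_zero_plus_first_order`` (zero-order input of duration ``d1_h``
    into a depot, first-order transfer to a two-compartment disposition
    system) or ``interpolated`` (sparse observed samples interpolated to ECG
    times; the compartmental fields then describe the generator used to
    synthesise the observed samples, not an analysis model).

    ``f_by_dose`` maps dose level -> bioavailability, with key ``"default"``
    as fallback.  Values are apparent (they may exceed 1 when the disposition
    parameters are F-confounded).  ``mw_g_per_mol`` converts mg doses to nM.
    """

    structure: str
    cl_L_per_h: float
    vc_L: float
    mw_g_per_mol: float
    ka_per_h: Optional[float] = None
    d1_h: Optional[float] = None
    vp_L: Optional[float] = None
    q_L_per_h: Optional[float] = None
    f_by_dose: dict = field(default_factory=lambda: {"default": 1.0})
    bsv_cl: float = 0.0

    _STRUCTURES = ("onecpt_first_order", "twocpt_zero_plus_first_order", "interpolated")

    def __post_init__(self) -> None:
        if self.structure not in self._STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        required = {"cl_L_per_h": self.cl_L_per_h, "vc_L": self.vc_L,
                    "mw_g_per_mol": self.mw_g_per_mol}
        if self.structure in ("onecpt_first_order", "interpolated"):
            required["ka_per_h"] = self.ka_per_h
        if self.structure == "twocpt_zero_plus_first_order":
            required.update(ka_per_h=self.ka_per_h, d1_h=self.d1_h,
                            vp_L=self.vp_L, q_L_per_h=self.q_L_per_h)
        for name, val in required.items():
            if val is None or val <= 0:
                raise ValueError(f"{name} must be positive for structure "
                                 f"{self.structure!r}, got {val}")
        if self.bsv_cl < 0:
            raise ValueError("bsv_cl must be >= 0")
        if "default" not in self.f_by_dose:
            self.f_by_dose = {**self.f_by_dose, "default": 1.0}

    def bioavailability(self, dose: float) -> float:
        """Dose-level bioavailability lookup (dose keys compared numerically)."""
        for key, val in self.f_by_dose.items():
            if key != "default" and float(key) == float(dose):
                return float(val)
        return float(self.f_by_dose["default"])


@dataclass
class DesignSpec:
    """Study design: subjects, dosing, sampling grids and RR generator.

    ``dose_levels`` are in mg (``dose_unit="mg"``) or mg/kg
    (``dose_unit="mg_per_kg"``, converted with per-subject weights drawn
    uniformly from ``weight_range_kg``).  ``crossover=True`` gives every
    subject one occasion per dose level; otherwise subjects are split into
    parallel groups across dose levels.  The RR series is generated as
    ``rr_baseline_ms * (1 + rr_circadian_frac*cos(2*pi*(t - rr_phase_h)/24))
    * (1 + eps)`` with ``eps ~ N(0, rr_noise_frac)``.
    """

    n_subjects: int
    dose_levels: list
    pk_sample_times_h: list
    ecg_sample_times_h: list
    rr_baseline_ms: float
    sex_ratio: float = 1.0  # fraction male
    crossover: bool = True
    dose_unit: str = "mg"
    weight_range_kg: Optional[list] = None
    rr_circadian_frac: float = 0.0
    rr_noise_frac: float = 0.0
    rr_phase_h: float = 4.0
    dose_clock_h: float = 8.0
    balance_n_per_phase: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= self.sex_ratio <= 1.0:
            raise ValueError("sex_ratio must be in [0, 1]")
        for name in ("pk_sample_times_h", "ecg_sample_times_h"):
            t = list(getattr(self, name))
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.dose_unit not in ("mg", "mg_per_kg"):
            raise ValueError(f"dose_unit must be 'mg' or 'mg_per_kg', got {self.dose_unit!r}")
        if self.dose_unit == "mg_per_kg" and not self.weight_range_kg:
            raise ValueError("weight_range_kg required for mg_per_kg dosing")
        if self.rr_baseline_ms <= 0 or self.rr_circadian_frac >= 1.0:
            raise ValueError("RR settings imply non-positive RR intervals")


@dataclass
class StudyPreset:
    """One species x compound study definition (generator + reference values)."""

    species: str
    compound: str
    species_params: SpeciesParams
    pk: PKModelSpec
    design: DesignSpec
    cmax_ref_nM: Optional[float] = None
    lloq_nM: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)


def _preset_dir():
    return resources.files("qtpkpd") / "presets"


def available_presets() -> list[str]:
    """Names of the shipped species x compound presets."""
    return sorted(p.name[:-5] for p in _preset_dir().iterdir() if p.name.endswith(".yaml"))


def load_preset(name_or_path: str | Path) -> StudyPreset:
    """Load a shipped preset by name (e.g. ``"human_moxifloxacin"``) or a YAML path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        candidate = _preset_dir() / f"{name_or_path}.yaml"
        try:
            raw = yaml.safe_load(candidate.read_text())
        except FileNotFoundError:
            raise FileNotFoundError(
                f"no preset {name_or_path!r}; available: {available_presets()}"
            ) from None
    return preset_from_dict(raw)


def preset_from_dict(raw: dict) -> StudyPreset:
    return StudyPreset(
        species=raw["species"],
        compound=raw["compound"],
        species_params=SpeciesParams(**raw["species_params"]),
        pk=PKModelSpec(**raw["pk"]),
        design=DesignSpec(**raw["design"]),
        cmax_ref_nM=raw.get("cmax_ref_nM"),
        lloq_nM=float(raw.get("lloq_nM", 0.0)),
    )
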