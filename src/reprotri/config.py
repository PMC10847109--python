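"""Simulation configuration.

The defaults encode the study conditions the pipeline is designed around:
a female cohort with population-cohort age structure (mean 56.4, SD 8,
range 38-73), reproductive exposures instrumented by independent
Hardy-Weinberg SNPs whose score explains 7.4% (age at menarche), 0.2%
(parity) and 8.2% (age at natural menopause) of phenotypic variance,
menopause age unobserved for ~24.5% premenopausal and ~12% surgical
women, a correlated metabolite panel driven by 18 latent factors carrying
~97% of variance, and a chronological-age modification of the
menopause -> LDL-cholesterol effect calibrated so the effect is about
-0.019 SD/year in women aged <=50 and about +0.005 SD/year in women >63.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import yaml

EXPOSURES = ("menarche", "parity", "menopause")

#: Named metabolites at the head of the synthetic panel. The first entries
#: are proxies for measures the analysis cares about individually
#: (LDL cholesterol, inflammation via GlycA, VLDL particles, ...).
NAMED_METABOLITES = (
    "LDL_C",
    "HDL_C",
    "VLDL_P",
    "Triglycerides",
    "ApoB",
    "ApoA1",
    "GlycA",
    "Glutamine",
    "Glycine",
    "Omega3_pct",
)

#: Exposure distributions on their natural scales (mean, SD).
EXPOSURE_SCALES = {
    "menarche": (13.0, 1.6),
    "parity": (1.83, 1.4),
    "menopause": (49.7, 5.1),
}

#: GWAS-scale instrument presets: (n_snps, score R^2, GWAS sample size).
#: These are the instrument-arm conditions of the study design the package
#: emulates: 389 menarche SNPs explaining 7.4%, 32 parity SNPs explaining
#: 0.2%, 290 menopause SNPs explaining 8.2%.
INSTRUMENT_PRESETS = {
    "menarche": (389, 0.074, 329_345),
    "parity": (32, 0.002, 496_000),
    "menopause": (290, 0.082, 496_151),
}


def panel_names(n_metabolites: int) -> list[str]:
    names = list(NAMED_METABOLITES[:n_metabolites])
    names += [f"met_{i:02d}" for i in range(len(names) + 1, n_metabolites + 1)]
    return names


def default_exposure_r2() -> dict[str, float]:
    return {"menarche": 0.074, "parity": 0.002, "menopause": 0.082}


def default_causal_effects() -> dict[str, dict[str, float]]:
    """Direct exposure -> metabolite effects, SD units per exposure unit."""
    return {
        # glutamine/glycine associations persist after BMI adjustment, so
        # they are modelled as direct; the bulk of the menarche signature is
        # mediated through adult BMI (see menarche_bmi_effect).
        "menarche": {"Glutamine": 0.012, "Glycine": 0.010},
        "parity": {
            "VLDL_P": 0.020,
            "Triglycerides": 0.018,
            "HDL_C": -0.015,
            "ApoA1": -0.012,
            "Glycine": 0.008,
        },
        # LDL_C carries the age-modified base effect (see age_modification).
        "menopause": {
            "LDL_C": -0.0085,
            "ApoB": -0.004,
            "GlycA": -0.005,
            "Glutamine": -0.004,
        },
    }


def default_confounder_effects() -> dict[tuple[str, str], float]:
    """(confounder, target) -> effect.

    Confounder scores are standardized (education level, childhood body
    size, baseline age); targets in exposure units (years/children), kg/m2
    for bmi, SD units for metabolites.
    """
    return {
        ("education", "menarche"): 0.06,
        ("body_size_age10", "menarche"): -0.30,
        ("education", "parity"): -0.18,
        ("age_baseline", "parity"): 0.12,
        ("education", "menopause"): 0.25,
        ("body_size_age10", "bmi"): 1.8,
        ("education", "bmi"): -0.6,
        ("education", "GlycA"): -0.03,
        ("education", "HDL_C"): 0.02,
        ("age_baseline", "GlycA"): 0.03,
        ("age_baseline", "LDL_C"): 0.04,
    }


def default_bmi_metabolite_effects() -> dict[str, float]:
    """Adult BMI -> metabolite effects, SD units per kg/m^2."""
    return {
        "LDL_C": 0.015,
        "VLDL_P": 0.020,
        "Triglycerides": 0.020,
        "HDL_C": -0.018,
        "GlycA": 0.015,
        "ApoB": 0.012,
    }


@dataclass
class Pleiotropy:
    """Invalid-instrument model: a fraction of each exposure's SNPs gets a
    direct SNP -> metabolite effect drawn Normal(mu, effect_sd), mu > 0 when
    directional."""

    proportion_invalid: float = 0.0
    effect_sd: float = 0.0
    directional: bool = False
    mean: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.proportion_invalid <= 1.0:
            raise ValueError("proportion_invalid must lie in [0, 1]")
        if self.effect_sd < 0:
            raise ValueError("effect_sd must be non-negative")


@dataclass
class MenopauseMissing:
    premenopausal_frac: float = 0.245
    surgical_frac: float = 0.12
    #: SD (years) of the noise added to baseline age when picking which women
    #: are premenopausal; smaller values tie missingness more tightly to
    #: young age.
    age_link_sd: float = 5.0

    def validate(self) -> None:
        for f in (self.premenopausal_frac, self.surgical_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("missingness fractions must lie in [0, 1]")
        if self.premenopausal_frac + self.surgical_frac >= 1.0:
            raise ValueError("premenopausal_frac + surgical_frac must be < 1")


@dataclass
class SimulationConfig:
    n_females: int = 50_000
    n_males: int = 40_000
    n_snps_per_exposure: int = 100
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_r2: dict[str, float] = field(default_factory=default_exposure_r2)
    causal_effects: dict[str, dict[str, float]] = field(
        default_factory=default_causal_effects
    )
    confounder_effects: dict[tuple[str, str], float] = field(
        default_factory=default_confounder_effects
    )
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    n_metabolites: int = 40
    n_factors: int = 18
    #: fraction of each metabolite's variance carried by the shared factors.
    factor_variance_share: float = 0.97
    menopause_missing: MenopauseMissing = field(default_factory=MenopauseMissing)
    #: slope of the menopause -> LDL_C effect per year of baseline age
    #: (SD per year-of-menopause per year-of-age, centred at age 56.4).
    age_modification: float = 0.0012
    #: adult BMI change (kg/m^2) per year of menarche age: the
    #: menarche -> BMI residual path of the bidirectional structure.
    menarche_bmi_effect: float = -0.5
    bmi_metabolite_effects: dict[str, float] = field(
        default_factory=default_bmi_metabolite_effects
    )
    statin_prevalence: float = 0.113
    hrt_prevalence: float = 0.383
    seed: int = 0

    # -- derived ---------------------------------------------------------
    @property
    def metabolite_names(self) -> list[str]:
        return panel_names(self.n_metabolites)

    def validate(self) -> None:
        for name, v in (("n_females", self.n_females), ("n_males", self.n_males)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_females == 0:
            raise ValueError("n_females must be positive")
        if self.n_snps_per_exposure <= 0:
            raise ValueError("n_snps_per_exposure must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"maf_range must lie within (0, 1), got {self.maf_range}")
        if self.n_metabolites < 2:
            raise ValueError("n_metabolites must be at least 2")
        if not 1 <= self.n_factors <= self.n_metabolites:
            raise ValueError("n_factors must lie in [1, n_metabolites]")
        if not 0.0 < self.factor_variance_share < 1.0:
            raise ValueError("factor_variance_share must lie in (0, 1)")
        names = set(self.metabolite_names)
        for exposure, effects in self.causal_effects.items():
            if exposure not in EXPOSURES:
                raise ValueError(f"unknown exposure in causal_effects: {exposure!r}")
            unknown = set(effects) - names
            if unknown:
                raise ValueError(
                    f"causal_effects for {exposure!r} name unknown metabolites: "
                    f"{sorted(unknown)}"
                )
        unknown = set(self.bmi_metabolite_effects) - names
        if unknown:
            raise ValueError(f"bmi_metabolite_effects name unknown metabolites: {sorted(unknown)}")
        for r2 in self.exposure_r2.values():
            if not 0.0 <= r2 < 1.0:
                raise ValueError("exposure_r2 values must lie in [0, 1)")
        self.pleiotropy.validate()
        self.menopause_missing.validate()

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["confounder_effects"] = [
            {"confounder": c, "target": t, "effect": e}
            for (c, t), e in self.confounder_effects.items()
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["maf_range"] = tuple(d["maf_range"])
        d["confounder_effects"] = {
            (row["confounder"], row["target"]): row["effect"]
            for row in d.get("confounder_effects", [])
        }
        d["pleiotropy"] = Pleiotropy(**d.get("pleiotropy", {}))
        d["menopause_missing"] = MenopauseMissing(**d.get("menopause_missing", {}))
        cfg = cls(**d)
        cfg.validate()
        return cfg


def confounder_effects_for(
    effects: Mapping[tuple[str, str], float], target: str
) -> dict[str, float]:
    """Confounder -> coefficient map for one target variable."""
    return {c: e for (c, t), e in effects.items() if t == target}
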