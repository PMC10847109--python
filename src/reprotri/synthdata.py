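"""Synthetic cohort and GWAS-summary-statistic generator.

Generates individual-level data with the causal and confounding structure
the triangulation analysis assumes:

* independent Hardy-Weinberg SNPs instrumenting each reproductive exposure,
  with equal per-allele effects scaled to a configurable score R^2;
* confounding of exposures and metabolites by education, childhood body
  size and baseline age (acting through the observed covariate scores, so
  the model-2 adjustment set can block them exactly);
* a bidirectional menarche-adiposity structure: childhood body size lowers
  menarche age and raises adult BMI, and menarche age feeds back into adult
  BMI, which in turn shifts the lipid-related metabolites — so BMI
  adjustment attenuates the menarche signature;
* a metabolite panel driven by ``n_factors`` latent factors built from an
  equal-norm harmonic frame, so the population correlation matrix has
  ``n_factors`` equal leading eigenvalues carrying ``factor_variance_share``
  of total variance;
* menopause age observed only for women with a natural menopause, with
  premenopausal status tied to younger baseline age, and a chronological-age
  modification of the menopause -> LDL_C effect;
* males who share the confounding structure of parity (children count) but
  carry no causal path from children count to their metabolites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import (
    EXPOSURE_SCALES,
    EXPOSURES,
    INSTRUMENT_PRESETS,
    SimulationConfig,
    confounder_effects_for,
)

__all__ = [
    "GenotypeMatrix",
    "SimulatedCohort",
    "simulate_genotypes",
    "simulate_cohort",
    "compute_summary_stats",
    "simulate_exposure_summary_stats",
    "instrument_summary_stats",
    "null_config",
]

# allele pairs avoiding palindromic (A/T, C/G) combinations
_ALLELE_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)

_EDU_LEVELS = ("none", "o_level", "a_level", "university")
_EDU_PROBS = (0.169, 0.394, 0.117, 0.319)
_SIZE_LEVELS = ("thinner", "average", "plumper")
_SIZE_PROBS = (0.316, 0.507, 0.177)
_SMOKING_LEVELS = ("never", "previous", "current")
_SMOKING_PROBS = (0.595, 0.315, 0.089)
_ALCOHOL_LEVELS = ("never", "occasional", "regular", "frequent")
_ALCOHOL_PROBS = (0.094, 0.279, 0.257, 0.369)

_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 56.4, 8.0, 38.0, 73.0
_BMI_MEAN, _BMI_SD = 27.1, 5.2


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with per-SNP metadata."""

    dosages: np.ndarray  # (n, k) int8, entries in {0, 1, 2}
    snps: list[str]
    ea: list[str]
    oa: list[str]
    maf: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp: str) -> np.ndarray:
        return self.dosages[:, self.snps.index(snp)]

    def subset_rows(self, mask) -> "GenotypeMatrix":
        return GenotypeMatrix(
            dosages=self.dosages[np.asarray(mask)],
            snps=list(self.snps),
            ea=list(self.ea),
            oa=list(self.oa),
            maf=self.maf.copy(),
        )

    def to_frame(self, prefix: str = "g_") -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, columns=[prefix + s for s in self.snps]
        )


def _draw_alleles(rng: np.random.Generator, k: int) -> tuple[list[str], list[str]]:
    idx = rng.integers(0, len(_ALLELE_PAIRS), size=k)
    ea = [_ALLELE_PAIRS[i][0] for i in idx]
    oa = [_ALLELE_PAIRS[i][1] for i in idx]
    return ea, oa


def simulate_genotypes(
    config: SimulationConfig,
    n_snps: int | None = None,
    mafs: Sequence[float] | None = None,
    rng: np.random.Generator | None = None,
    prefix: str = "snp",
) -> GenotypeMatrix:
    """Draw an independent-SNP genotype matrix under Hardy-Weinberg
    equilibrium.

    ``mafs`` overrides the uniform draw from ``config.maf_range`` (boundary
    frequencies 0/1 are tolerated there for degenerate test cases).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_females + config.n_males
    k = int(n_snps) if n_snps is not None else config.n_snps_per_exposure
    if k <= 0:
        raise ValueError(f"number of SNPs must be positive, got {k}")
    if mafs is None:
        lo, hi = config.maf_range
        maf = rng.uniform(lo, hi, size=k)
    else:
        maf = np.asarray(mafs, dtype=float)
        if maf.shape != (k,):
            raise ValueError("mafs length must equal the number of SNPs")
        if ((maf < 0) | (maf > 1)).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
    dosages = rng.binomial(2, maf[None, :], size=(n, k)).astype(np.int8)
    ea, oa = _draw_alleles(rng, k)
    snps = [f"{prefix}_{i + 1:04d}" for i in range(k)]
    return GenotypeMatrix(dosages=dosages, snps=snps, ea=ea, oa=oa, maf=maf)


def _category_score(codes: np.ndarray, probs: Sequence[float], values: np.ndarray) -> np.ndarray:
    """Standardize category codes by their population moments so confounder
    coefficients are per population-SD of the score."""
    p = np.asarray(probs, float)
    p = p / p.sum()
    v = np.asarray(values, float)
    mu = float(p @ v)
    sd = float(np.sqrt(p @ (v - mu) ** 2))
    return (values[codes] - mu) / sd


def _equal_effect_beta(r2: float, sd: float, maf: np.ndarray) -> float:
    """Per-allele effect (natural units) so the SNP score explains ``r2`` of
    a trait with SD ``sd``, with equal effects across SNPs."""
    denom = float(np.sum(2.0 * maf * (1.0 - maf)))
    if denom == 0:
        return 0.0
    return sd * np.sqrt(r2 / denom)


def _factor_loadings(n_metabolites: int, n_factors: int, share: float) -> np.ndarray:
    """Equal-norm tight-frame loadings: rows (metabolites) all have squared
    norm ``share`` and the factor Gram matrix is a multiple of the identity,
    so the population correlation matrix has ``n_factors`` equal leading
    eigenvalues."""
    m, k = n_metabolites, n_factors
    if k == m:
        return np.sqrt(share) * np.eye(m)
    if k > m - 1:
        raise ValueError("n_factors must be <= n_metabolites - 1 (or == n_metabolites)")
    idx = np.arange(m)
    cols = []
    if k % 2 == 1:
        cols.append(np.full(m, 1.0 / np.sqrt(2.0)))
    for f in range(1, k // 2 + 1):
        ang = 2.0 * np.pi * f * idx / m
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    L = np.column_stack(cols)
    row_norm2 = float(np.sum(L[0] ** 2))  # identical across rows by construction
    return L * np.sqrt(share / row_norm2)


@dataclass
class SimulatedCohort:
    """Individual-level cohort plus the generative ground truth."""

    table: pd.DataFrame
    genotypes: dict[str, GenotypeMatrix]
    truth: dict[str, Any] = field(default_factory=dict)
    config: SimulationConfig | None = None

    @property
    def females(self) -> pd.DataFrame:
        return self.table[self.table["sex"] == "F"]

    @property
    def males(self) -> pd.DataFrame:
        return self.table[self.table["sex"] == "M"]

    def to_cohort_table(self) -> pd.DataFrame:
        """Phenotype table with genotype dosage columns appended."""
        parts = [self.table.reset_index(drop=True)]
        for exposure, gm in self.genotypes.items():
            parts.append(gm.to_frame(prefix=f"g_{exposure}_").reset_index(drop=True))
        return pd.concat(parts, axis=1)


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every causal, confounding and mediating effect
    switched off — the reference point for type-I-error checks."""
    cfg = SimulationConfig(
        causal_effects={},
        confounder_effects={},
        bmi_metabolite_effects={},
        menarche_bmi_effect=0.0,
        age_modification=0.0,
        **overrides,
    )
    return cfg


def simulate_cohort(config: SimulationConfig | None = None, rng=None) -> SimulatedCohort:
    """Generate the full two-sex cohort (females first, then males)."""
    cfg = config if config is not None else SimulationConfig()
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_f, n_m = cfg.n_females, cfg.n_males
    n = n_f + n_m
    female = np.zeros(n, dtype=bool)
    female[:n_f] = True

    # --- covariates -----------------------------------------------------
    a, b = (_AGE_LO - _AGE_MEAN) / _AGE_SD, (_AGE_HI - _AGE_MEAN) / _AGE_SD
    age = _AGE_MEAN + _AGE_SD * stats.truncnorm.rvs(a, b, size=n, random_state=rng)

    def _draw_cat(levels, probs):
        p = np.asarray(probs, float)
        return rng.choice(len(levels), size=n, p=p / p.sum())

    edu_code = _draw_cat(_EDU_LEVELS, _EDU_PROBS)
    size_code = _draw_cat(_SIZE_LEVELS, _SIZE_PROBS)
    smoking = _draw_cat(_SMOKING_LEVELS, _SMOKING_PROBS)
    alcohol = _draw_cat(_ALCOHOL_LEVELS, _ALCOHOL_PROBS)

    scores = {
        "education": _category_score(edu_code, _EDU_PROBS, np.arange(4.0)),
        "body_size_age10": _category_score(size_code, _SIZE_PROBS, np.array([-1.0, 0.0, 1.0])),
        "age_baseline": (age - _AGE_MEAN) / _AGE_SD,
    }

    def conf_term(target: str) -> np.ndarray:
        out = np.zeros(n)
        coeffs = confounder_effects_for(cfg.confounder_effects, target)
        for c, e in coeffs.items():
            if c not in scores:
                raise ValueError(f"unknown confounder {c!r} for target {target!r}")
            out += e * scores[c]
        return out

    def conf_var(target: str) -> float:
        return sum(
            e**2 for e in confounder_effects_for(cfg.confounder_effects, target).values()
        )

    # --- genotypes and exposure latents ---------------------------------
    genotypes: dict[str, GenotypeMatrix] = {}
    exposure_latent: dict[str, np.ndarray] = {}
    snp_truth: dict[str, Any] = {}
    for exposure in EXPOSURES:
        gm = simulate_genotypes(cfg, rng=rng, prefix=exposure)
        genotypes[exposure] = gm
        mean_e, sd_e = EXPOSURE_SCALES[exposure]
        r2 = cfg.exposure_r2.get(exposure, 0.0)
        beta = _equal_effect_beta(r2, sd_e, gm.maf)
        gscore = (gm.dosages - 2.0 * gm.maf[None, :]) @ np.full(gm.n_snps, beta)
        cterm = conf_term(exposure)
        resid_var = sd_e**2 * (1.0 - r2) - conf_var(exposure)
        if resid_var <= 0:
            raise ValueError(
                f"confounder effects on {exposure!r} exceed its residual variance"
            )
        latent = mean_e + gscore + cterm + rng.normal(0.0, np.sqrt(resid_var), size=n)
        exposure_latent[exposure] = latent
        snp_truth[exposure] = {"beta_per_allele": beta, "r2": r2}

    menarche = np.where(female, exposure_latent["menarche"], np.nan)
    n_children = np.clip(np.round(exposure_latent["parity"]), 0, 12).astype(int)
    menopause_latent = exposure_latent["menopause"]

    # --- adult BMI (menarche feedback applies to females only) ----------
    bmi_struct = conf_term("bmi")
    bmi_struct = bmi_struct + np.where(
        female, cfg.menarche_bmi_effect * (np.nan_to_num(menarche) - 13.0), 0.0
    )
    bmi_resid = _BMI_SD**2 - conf_var("bmi") - (cfg.menarche_bmi_effect * 1.6) ** 2
    if bmi_resid <= 0:
        raise ValueError("BMI structural paths exceed its variance budget")
    bmi = _BMI_MEAN + bmi_struct + rng.normal(0.0, np.sqrt(bmi_resid), size=n)

    # --- menopause status / observed age --------------------------------
    mm = cfg.menopause_missing
    status = np.full(n, "na", dtype=object)
    prem_score = age[:n_f] + rng.normal(0.0, mm.age_link_sd, size=n_f)
    thr = np.quantile(prem_score, mm.premenopausal_frac)
    pre = prem_score <= thr
    surg_p = mm.surgical_frac / max(1.0 - mm.premenopausal_frac, 1e-12)
    surgical = (~pre) & (rng.uniform(size=n_f) < surg_p)
    st_f = np.where(pre, "pre", np.where(surgical, "surgical", "natural"))
    status[:n_f] = st_f
    menopause_age = np.full(n, np.nan)
    nat = np.zeros(n, dtype=bool)
    nat[:n_f] = st_f == "natural"
    menopause_age[nat] = menopause_latent[nat]

    # --- metabolite panel ------------------------------------------------
    names = cfg.metabolite_names
    share = cfg.factor_variance_share
    L = _factor_loadings(cfg.n_metabolites, cfg.n_factors, share)
    factors = rng.standard_normal((n, cfg.n_factors))
    mets = factors @ L.T
    mets += np.sqrt(1.0 - share) * rng.standard_normal((n, cfg.n_metabolites))

    col = {m: i for i, m in enumerate(names)}
    # direct causal effects (females only; exposures centred at population mean)
    centred = {
        "menarche": np.where(female, np.nan_to_num(menarche) - 13.0, 0.0),
        "parity": np.where(female, n_children - EXPOSURE_SCALES["parity"][0], 0.0),
        "menopause": np.where(female, menopause_latent - EXPOSURE_SCALES["menopause"][0], 0.0),
    }
    for exposure, effects in cfg.causal_effects.items():
        for met, eff in effects.items():
            if exposure == "menopause" and met == "LDL_C" and cfg.age_modification != 0.0:
                slope = eff + cfg.age_modification * (age - _AGE_MEAN)
                mets[:, col[met]] += slope * centred[exposure]
            else:
                mets[:, col[met]] += eff * centred[exposure]
    # BMI-mediated effects (both sexes)
    for met, eff in cfg.bmi_metabolite_effects.items():
        mets[:, col[met]] += eff * (bmi - _BMI_MEAN)
    # confounder -> metabolite effects (both sexes)
    for met in names:
        term = conf_term(met)
        if term.any():
            mets[:, col[met]] += term
    # horizontal pleiotropy: direct SNP -> metabolite effects for a fraction
    # of instruments of each exposure
    invalid: dict[str, np.ndarray] = {}
    pl = cfg.pleiotropy
    for exposure in EXPOSURES:
        gm = genotypes[exposure]
        k_inv = int(round(pl.proportion_invalid * gm.n_snps))
        flags = np.zeros(gm.n_snps, dtype=bool)
        if k_inv > 0 and pl.effect_sd > 0:
            flags[:k_inv] = True
            mu = pl.mean if pl.directional else 0.0
            alpha = rng.normal(mu, pl.effect_sd, size=(k_inv, cfg.n_metabolites))
            gc = gm.dosages[:, :k_inv] - 2.0 * gm.maf[None, :k_inv]
            mets += gc @ alpha
        invalid[exposure] = flags

    table = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "sex": np.where(female, "F", "M"),
            "age_baseline": age,
            "education": pd.Categorical.from_codes(edu_code, list(_EDU_LEVELS)),
            "body_size_age10": pd.Categorical.from_codes(size_code, list(_SIZE_LEVELS)),
            "bmi": bmi,
            "smoking": pd.Categorical.from_codes(smoking, list(_SMOKING_LEVELS)),
            "alcohol": pd.Categorical.from_codes(alcohol, list(_ALCOHOL_LEVELS)),
            "menarche_age": menarche,
            "n_children": n_children,
            "menopause_age": menopause_age,
            "menopause_latent": menopause_latent,
            "menopause_status": np.where(female, status, "na"),
            "statin_flag": rng.uniform(size=n) < cfg.statin_prevalence,
            "hrt_flag": female & (rng.uniform(size=n) < cfg.hrt_prevalence),
        }
    )
    table["menopause_status"] = table["menopause_status"].where(table["sex"] == "F", other=pd.NA)
    for i, m in enumerate(names):
        table[m] = mets[:, i]

    truth = {
        "snp_effects": snp_truth,
        "invalid_instruments": invalid,
        "factor_loadings": L,
        "exposure_scales": dict(EXPOSURE_SCALES),
    }
    return SimulatedCohort(table=table, genotypes=genotypes, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# per-SNP association scans
# ---------------------------------------------------------------------------

def _covariate_design(covariates, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = pd.DataFrame(covariates)
    num = pd.get_dummies(C, drop_first=True, dtype=float)
    X = np.column_stack([np.ones(n), num.to_numpy(dtype=float)])
    return X


def compute_summary_stats(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype,
    covariates=None,
    chunk: int = 64,
) -> pd.DataFrame:
    """Per-SNP linear-regression summary statistics.

    Regresses the phenotype on each SNP's allele count plus the covariates
    (equivalently: on covariate-residualized allele counts). Returns one row
    per SNP with columns ``snp, ea, oa, eaf, beta, se, p, n, monomorphic``.
    Monomorphic SNPs are flagged and their beta/se/p set to NaN.
    """
    if isinstance(genotypes, GenotypeMatrix):
        G = genotypes.dosages
        snps, ea, oa = genotypes.snps, genotypes.ea, genotypes.oa
    else:
        G = np.asarray(genotypes)
        snps = [f"snp_{i + 1:04d}" for i in range(G.shape[1])]
        ea = ["A"] * G.shape[1]
        oa = ["G"] * G.shape[1]
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != G.shape[0]:
        raise ValueError("phenotype length must equal genotype rows")
    keep = np.isfinite(y)
    if covariates is not None:
        cov_df = pd.DataFrame(covariates)
        keep &= ~cov_df.isna().any(axis=1).to_numpy()
        cov_df = cov_df.loc[keep]
    else:
        cov_df = None
    y = y[keep]
    G = G[keep]
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"too few complete observations ({n}) for the scan")
    X = _covariate_design(cov_df, n)
    Q, _ = np.linalg.qr(X)
    yr = y - Q @ (Q.T @ y)
    syy = float(yr @ yr)
    df = n - X.shape[1] - 1

    k = G.shape[1]
    beta = np.full(k, np.nan)
    se = np.full(k, np.nan)
    pval = np.full(k, np.nan)
    eaf = G.mean(axis=0) / 2.0
    mono = np.zeros(k, dtype=bool)
    for start in range(0, k, chunk):
        sl = slice(start, min(start + chunk, k))
        Gf = G[:, sl].astype(float)
        Gr = Gf - Q @ (Q.T @ Gf)
        sgg = np.einsum("ij,ij->j", Gr, Gr)
        zero = sgg <= 1e-12
        mono[sl] = zero
        sgg_safe = np.where(zero, np.nan, sgg)
        sgy = yr @ Gr
        b = sgy / sgg_safe
        rss = syy - b**2 * sgg_safe
        sigma2 = np.maximum(rss, 0.0) / df
        s = np.sqrt(sigma2 / sgg_safe)
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = b / s
        beta[sl] = b
        se[sl] = s
        pval[sl] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return pd.DataFrame(
        {
            "snp": snps,
            "ea": ea,
            "oa": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "p": pval,
            "n": n,
            "monomorphic": mono,
        }
    )


# ---------------------------------------------------------------------------
# summary-level instrument generator
# ---------------------------------------------------------------------------

def simulate_exposure_summary_stats(
    n_snps: int,
    r2_total: float,
    n: int,
    trait_sd: float = 1.0,
    maf_range: tuple[float, float] = (0.05, 0.45),
    rng: np.random.Generator | int | None = None,
    prefix: str = "snp",
    equal_effects: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a GWAS instrument table directly at the summary level.

    Per-SNP true effects are equal per allele (or half-normal heterogeneous
    when ``equal_effects=False``), scaled so the score explains ``r2_total``
    of the trait variance; the sampled estimate for SNP j is drawn from its
    large-sample distribution N(beta_j, se_j) with
    ``se_j = trait_sd * sqrt((1 - r2_j) / (2 p_j (1 - p_j) n))``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = maf_range
    maf = rng.uniform(lo, hi, size=n_snps)
    het = 2.0 * maf * (1.0 - maf)
    if equal_effects:
        beta_true = np.full(n_snps, _equal_effect_beta(r2_total, trait_sd, maf))
    else:
        raw = np.abs(rng.standard_normal(n_snps))
        scale = trait_sd * np.sqrt(r2_total / float(np.sum(het * raw**2)))
        beta_true = raw * scale
    r2_j = het * beta_true**2 / trait_sd**2
    se = trait_sd * np.sqrt((1.0 - r2_j) / (het * n))
    beta_hat = rng.normal(beta_true, se)
    z = beta_hat / se
    ea, oa = _draw_alleles(rng, n_snps)
    frame = pd.DataFrame(
        {
            "snp": [f"{prefix}_{i + 1:04d}" for i in range(n_snps)],
            "ea": ea,
            "oa": oa,
            "eaf": maf,
            "beta": beta_hat,
            "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n": n,
        }
    )
    truth = {"beta_true": beta_true, "maf": maf, "r2_total": r2_total, "trait_sd": trait_sd}
    return frame, truth


def instrument_summary_stats(
    exposure: str, rng: np.random.Generator | int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Instrument table for one exposure under the preset study conditions
    (SNP count, score R^2 and GWAS sample size)."""
    if exposure not in INSTRUMENT_PRESETS:
        raise KeyError(f"unknown exposure {exposure!r}")
    n_snps, r2, n = INSTRUMENT_PRESETS[exposure]
    _, sd = EXPOSURE_SCALES[exposure]
    return simulate_exposure_summary_stats(
        n_snps=n_snps, r2_total=r2, n=n, trait_sd=sd, rng=rng, prefix=exposure
    )
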