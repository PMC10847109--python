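"""Seeded simulation studies built on the generator.

These functions define the package's repeatable experiments: estimator
calibration (CI coverage when instrument assumptions hold, weighted-median
robustness under invalid instruments), the BMI-mediation attenuation
signature for age at menarche, the male negative-control classification
signature for parity, and the chronological-age / sample-selection
signature for age at natural menopause. They are used by the test suite,
the acceptance script and the examples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .datatypes import EffectEstimate, MREstimate
from .mr_core import HarmonizedInstrumentSet, ivw, mr_egger, mvmr_ivw, weighted_median
from .mr_onesample import build_pgs, selected_vs_full_contrast
from .mvreg import age_stratify, fit_adjusted_model
from .negcontrol import run_negative_control
from .synthdata import compute_summary_stats, null_config, simulate_cohort
from .transforms import rank_inverse_normal

__all__ = [
    "two_sample_mr_replicate",
    "mr_coverage_study",
    "weighted_median_robustness_study",
    "bmi_attenuation_study",
    "mvmr_mediation_study",
    "negative_control_study",
    "menopause_age_signature_study",
    "true_weight_frame",
]


def _sub_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(path)))


def _hwe_genotypes(rng: np.random.Generator, maf: np.ndarray, n: int) -> np.ndarray:
    """Binomial(2, p) dosages as the sum of two allele draws (equivalent to
    rng.binomial but considerably faster for large matrices)."""
    g = (rng.random((n, maf.size)) < maf).astype(np.int8)
    g += rng.random((n, maf.size)) < maf
    return g


def _marginal_scan(g: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple-regression (with intercept) beta and SE, vectorized.

    Matches :func:`reprotri.synthdata.compute_summary_stats` without
    covariates; used inside replicate loops where the full record frame is
    not needed.
    """
    n = y.size
    gf = g.astype(np.float32)
    gsum = gf.sum(axis=0, dtype=np.float64)
    gss = np.einsum("ij,ij->j", gf, gf, dtype=np.float64)
    yc = y - y.mean()
    sgy = yc @ gf
    sgg = gss - gsum**2 / n
    beta = sgy / sgg
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta**2 * sgg, 0.0)
    se = np.sqrt(rss / (n - 2) / sgg)
    return beta, se


# ---------------------------------------------------------------------------
# two-sample MR calibration
# ---------------------------------------------------------------------------

def two_sample_mr_replicate(
    n: int = 50_000,
    k: int = 100,
    theta: float = 0.1,
    r2: float = 0.074,
    prop_invalid: float = 0.0,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    mode: str = "individual",
) -> tuple[HarmonizedInstrumentSet, dict]:
    """One two-sample MR dataset.

    Two independent samples of ``n`` individuals share the same SNP ->
    exposure architecture (heavy-tailed per-SNP effects, as in real GWAS
    instrument sets, scaled to total R^2 ``r2``); the outcome sample adds
    ``y = theta * x + pleiotropy + noise`` where the first
    ``prop_invalid * k`` SNPs carry a direct outcome effect drawn
    Normal(pleiotropy_mean, pleiotropy_sd).

    ``mode='individual'`` simulates genotype matrices and runs the per-SNP
    scans; ``mode='summary'`` draws the instrument-level estimates from
    the exact large-sample distributions those scans imply (the sampling
    model the summary-data estimators assume), which is the reference
    condition for coverage calibration.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    maf = rng.uniform(0.05, 0.45, size=k)
    het = 2.0 * maf * (1.0 - maf)
    raw = rng.lognormal(0.0, 1.0, size=k)
    beta = raw * np.sqrt(r2 / float(np.sum(het * raw**2)))
    k_inv = int(round(prop_invalid * k))
    alpha = np.zeros(k)
    if k_inv:
        alpha[:k_inv] = rng.normal(pleiotropy_mean, pleiotropy_sd, size=k_inv)

    if mode == "summary":
        var_y = theta**2 + 1.0
        sex = np.sqrt((1.0 - r2) / (het * n))
        sey = np.sqrt(var_y / (het * n))
        bx = rng.normal(beta, sex)
        by = rng.normal(theta * beta + alpha, sey)
    elif mode == "individual":
        def draw_sample(with_outcome: bool):
            g = _hwe_genotypes(rng, maf, n)
            gc = g - 2.0 * maf[None, :]
            x = gc @ beta + rng.normal(0.0, np.sqrt(1.0 - r2), size=n)
            if not with_outcome:
                return g, x, None
            y = theta * x + gc @ alpha + rng.normal(0.0, 1.0, size=n)
            return g, x, y

        g1, x1, _ = draw_sample(False)
        g2, _, y2 = draw_sample(True)
        bx, sex = _marginal_scan(g1, x1)
        by, sey = _marginal_scan(g2, y2)
    else:
        raise ValueError(f"mode must be 'individual' or 'summary', got {mode!r}")
    hset = HarmonizedInstrumentSet.from_arrays(bx=bx, sex=sex, by=by, sey=sey)
    truth = {"theta": theta, "beta": beta, "alpha": alpha, "maf": maf,
             "invalid": np.arange(k) < k_inv}
    return hset, truth


def mr_coverage_study(
    n_reps: int = 500,
    n: int = 50_000,
    k: int = 100,
    theta: float = 0.1,
    r2: float = 0.074,
    seed: int = 0,
    n_boot: int = 1000,
    mode: str = "summary",
) -> dict:
    """95%-CI coverage of IVW, MR-Egger (slope and intercept) and the
    weighted median across replicates with all-valid instruments.

    Coverage is assessed under the estimators' own sampling model
    (``mode='summary'``); the individual-level mode is available for
    comparison (cross-SNP correlations within shared samples make the
    formula SEs mildly conservative there).
    """
    cover = {m: 0 for m in ("ivw", "egger", "egger_intercept", "weighted_median")}
    for rep in range(n_reps):
        rng = _sub_rng(seed, 1, rep)
        hset, truth = two_sample_mr_replicate(
            n=n, k=k, theta=theta, r2=r2, rng=rng, mode=mode
        )
        th = truth["theta"]
        cover["ivw"] += ivw(hset).ci_covers(th)
        slope, intercept = mr_egger(hset)
        cover["egger"] += slope.ci_covers(th)
        cover["egger_intercept"] += intercept.ci_covers(0.0)
        wm = weighted_median(hset, n_boot=n_boot, seed=rep)
        cover["weighted_median"] += wm.ci_covers(th)
    return {m: 100.0 * c / n_reps for m, c in cover.items()} | {"n_reps": n_reps}


def weighted_median_robustness_study(
    n_reps: int = 200,
    n: int = 50_000,
    k: int = 100,
    theta: float = 0.1,
    r2: float = 0.074,
    prop_invalid: float = 0.4,
    pleiotropy_mean: float = 0.015,
    pleiotropy_sd: float = 0.004,
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Breakdown behaviour under 40% invalid instruments with large
    directional pleiotropy (ratio offsets several times the causal effect):
    the weighted median should stay near the truth while IVW is biased
    upward beyond its own confidence interval."""
    wm_ok = ivw_biased = wm_closer = 0
    wm_err = []
    ivw_err = []
    for rep in range(n_reps):
        rng = _sub_rng(seed, 2, rep)
        hset, truth = two_sample_mr_replicate(
            n=n, k=k, theta=theta, r2=r2, prop_invalid=prop_invalid,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=pleiotropy_sd, rng=rng,
        )
        th = truth["theta"]
        est_i = ivw(hset)
        est_w = weighted_median(hset, n_boot=n_boot, seed=rep)
        wm_ok += abs(est_w.beta - th) <= 3.0 * est_w.se
        ivw_biased += est_i.ci_low > th  # truth below the whole IVW interval
        wm_closer += abs(est_w.beta - th) < abs(est_i.beta - th)
        wm_err.append(est_w.beta - th)
        ivw_err.append(est_i.beta - th)
    return {
        "wm_within_3se_pct": 100.0 * wm_ok / n_reps,
        "ivw_biased_high_pct": 100.0 * ivw_biased / n_reps,
        "wm_closer_pct": 100.0 * wm_closer / n_reps,
        "wm_mean_error": float(np.mean(wm_err)),
        "ivw_mean_error": float(np.mean(ivw_err)),
        "n_reps": n_reps,
    }


# ---------------------------------------------------------------------------
# menarche / BMI mediation signatures
# ---------------------------------------------------------------------------

def bmi_attenuation_study(
    n_seeds: int = 100,
    n_females: int = 50_000,
    metabolite: str = "Triglycerides",
    seed: int = 0,
) -> dict:
    """Share of seeds in which BMI adjustment (model3) moves the menarche
    association closer to the null than model2 for a metabolite whose
    menarche effect is generated entirely through adult BMI."""
    attenuated = 0
    b2s, b3s = [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(
            n_females=n_females, n_males=0, n_snps_per_exposure=20,
            n_metabolites=10, n_factors=6, seed=0,
        )
        cohort = simulate_cohort(cfg, rng=_sub_rng(seed, 3, s))
        fem = cohort.females
        b2 = fit_adjusted_model(fem, "menarche", metabolite, model="model2")
        b3 = fit_adjusted_model(fem, "menarche", metabolite, model="model3")
        attenuated += abs(b3.beta) < abs(b2.beta)
        b2s.append(b2.beta)
        b3s.append(b3.beta)
    return {
        "attenuated_pct": 100.0 * attenuated / n_seeds,
        "mean_beta_model2": float(np.mean(b2s)),
        "mean_beta_model3": float(np.mean(b3s)),
        "n_seeds": n_seeds,
    }


def mvmr_mediation_study(
    n: int = 50_000,
    k: int = 100,
    menarche_bmi: float = -0.16,
    bmi_met: float = 0.25,
    seed: int = 0,
) -> dict:
    """Multivariable-IVW signature when the exposure acts only through BMI.

    Half the SNPs instrument menarche age, half have direct BMI effects;
    the metabolite depends on BMI alone. Univariable IVW over the menarche
    SNPs recovers the total (mediated) effect; MVMR conditioning on BMI
    drives the direct menarche effect to the null.
    """
    rng = _sub_rng(seed, 4)
    maf = rng.uniform(0.05, 0.45, size=k)
    het = 2.0 * maf * (1.0 - maf)
    half = k // 2
    beta_men = np.zeros(k)
    beta_bmi_direct = np.zeros(k)
    raw1 = np.abs(rng.standard_normal(half)) + 0.1
    beta_men[:half] = raw1 * np.sqrt(0.074 * 1.6**2 / float(np.sum(het[:half] * raw1**2)))
    raw2 = np.abs(rng.standard_normal(k - half)) + 0.1
    beta_bmi_direct[half:] = raw2 * np.sqrt(0.10 / float(np.sum(het[half:] * raw2**2)))

    def sample():
        g = rng.binomial(2, maf[None, :], size=(n, k)).astype(np.int8)
        gc = g - 2.0 * maf[None, :]
        men = 13.0 + gc @ beta_men + rng.normal(0.0, 1.6 * np.sqrt(1 - 0.074), size=n)
        bmi = menarche_bmi * (men - 13.0) + gc @ beta_bmi_direct + rng.normal(
            0.0, np.sqrt(1.0 - 0.10 - (menarche_bmi * 1.6) ** 2), size=n
        )
        met = bmi_met * bmi + rng.normal(0.0, np.sqrt(1.0 - bmi_met**2), size=n)
        return g, men, bmi, met

    g1, men1, bmi1, _ = sample()
    g2, _, _, met2 = sample()
    ss_men = compute_summary_stats(g1, men1)
    ss_bmi = compute_summary_stats(g1, bmi1)
    ss_met = compute_summary_stats(g2, met2)

    men_snps = np.arange(k) < half
    uni = HarmonizedInstrumentSet.from_arrays(
        bx=ss_men["beta"][men_snps], sex=ss_men["se"][men_snps],
        by=ss_met["beta"][men_snps], sey=ss_met["se"][men_snps],
    )
    total = ivw(uni)
    mv = HarmonizedInstrumentSet.from_arrays(
        bx=ss_men["beta"], sex=ss_men["se"], by=ss_met["beta"], sey=ss_met["se"],
        bx2=ss_bmi["beta"], sex2=ss_bmi["se"],
        exposure_names=("menarche", "bmi"),
    )
    direct = mvmr_ivw(mv)
    return {
        "total_ivw": total,
        "direct_menarche": direct["menarche"],
        "direct_bmi": direct["bmi"],
        "true_total": menarche_bmi * bmi_met,
    }


# ---------------------------------------------------------------------------
# parity negative control
# ---------------------------------------------------------------------------

def negative_control_study(
    n_seeds: int = 100,
    n_per_sex: int = 5_000,
    seed: int = 0,
) -> dict:
    """Classification rates for a generator with a female-only causal
    parity effect (0.1 SD/child on one metabolite) and a shared confounded
    association (~0.03 SD/child via education) on another.

    Unadjusted (model1) associations are compared so the shared
    confounding is visible to the negative control, which is the situation
    the design is meant to detect.
    """
    causal_met, confounded_met = "VLDL_P", "GlycA"
    counts = {"causal_as_causal": 0, "confounded_as_bias": 0}
    for s in range(n_seeds):
        cfg = null_config(
            n_females=n_per_sex, n_males=n_per_sex, n_snps_per_exposure=10,
            n_metabolites=10, n_factors=6, seed=0,
        )
        cfg.causal_effects = {"parity": {causal_met: 0.1}}
        cfg.confounder_effects = {
            ("education", "parity"): 0.5,
            ("education", confounded_met): 0.12,
        }
        cohort = simulate_cohort(cfg, rng=_sub_rng(seed, 5, s))
        verdicts = run_negative_control(
            cohort.table, [causal_met, confounded_met], model="model1"
        )
        by_met = {v.metabolite: v.classification for v in verdicts}
        counts["causal_as_causal"] += by_met[causal_met] == "causal-suggestive"
        counts["confounded_as_bias"] += by_met[confounded_met] == "bias-suggestive"
    return {
        "causal_classified_pct": 100.0 * counts["causal_as_causal"] / n_seeds,
        "confounded_classified_pct": 100.0 * counts["confounded_as_bias"] / n_seeds,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# menopause: age modification and sample selection
# ---------------------------------------------------------------------------

def true_weight_frame(cohort) -> pd.DataFrame:
    """PGS weight table from the generator's true per-allele menopause
    effects (the stand-in for published GWAS weights)."""
    gm = cohort.genotypes["menopause"]
    beta = cohort.truth["snp_effects"]["menopause"]["beta_per_allele"]
    return pd.DataFrame({"snp": gm.snps, "ea": gm.ea, "weight": beta})


@dataclass
class MenopauseSignature:
    stratum_le50: EffectEstimate
    stratum_gt63: EffectEstimate
    mv_selected: EffectEstimate
    tsls_selected: EffectEstimate
    ratio_full: EffectEstimate


def menopause_age_signature_study(
    n_females: int = 120_000,
    metabolite: str = "LDL_C",
    seed: int = 0,
    transform: bool = True,
) -> MenopauseSignature:
    """Age-stratified menopause -> LDL estimates plus the selected-sample
    vs full-sample contrast under the default age-modified generator."""
    cfg = SimulationConfig(
        n_females=n_females, n_males=0, n_snps_per_exposure=100,
        n_metabolites=10, n_factors=6, seed=0,
    )
    cohort = simulate_cohort(cfg, rng=_sub_rng(seed, 6))
    fem = cohort.females.copy()
    if transform:
        fem[metabolite] = rank_inverse_normal(fem[metabolite].to_numpy())
    strata = age_stratify(fem)
    sel = [s[s["menopause_status"] == "natural"] for s in strata]
    b_young = fit_adjusted_model(sel[0], "menopause", metabolite, model="model2")
    b_old = fit_adjusted_model(sel[3], "menopause", metabolite, model="model2")

    weights = true_weight_frame(cohort)
    fem_mask = (cohort.table["sex"] == "F").to_numpy()
    pgs = build_pgs(cohort.genotypes["menopause"].subset_rows(fem_mask), weights)
    contrast = selected_vs_full_contrast(fem, pgs, metabolite, model="model2")
    return MenopauseSignature(
        stratum_le50=b_young,
        stratum_gt63=b_old,
        mv_selected=contrast["mv_selected"],
        tsls_selected=contrast["tsls_selected"],
        ratio_full=contrast["ratio_full"],
    )
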