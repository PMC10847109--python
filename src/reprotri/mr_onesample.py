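"""Individual-level (one-sample) Mendelian randomization.

A weighted polygenic score (PGS) summarises the instrument SNPs; causal
effects are estimated by two-stage least squares (2SLS) and by the
PGS-ratio (Wald) estimator — the covariate-adjusted PGS-outcome
coefficient divided by the PGS-exposure coefficient, which allows the
exposure association to come from a selected subsample while the outcome
association uses the full sample. The selected-vs-full contrast runs the
multivariable-regression, 2SLS and PGS-ratio analyses side by side with
exactly those sample definitions, which is the diagnostic for
selection-driven discrepancies between regression and MR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EffectEstimate
from .mvreg import MODEL_COVARIATES, _complete_cases, _design, resolve_exposure_column
from .synthdata import GenotypeMatrix

__all__ = [
    "PolygenicScore",
    "build_pgs",
    "two_stage_least_squares",
    "pgs_ratio",
    "selected_vs_full_contrast",
    "WeakInstrumentWarning",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class WeakInstrumentWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PolygenicScore:
    values: np.ndarray
    n_snps_used: int
    n_snps_skipped: int
    source: str = "weights"


def build_pgs(genotypes: GenotypeMatrix, weights: pd.DataFrame) -> PolygenicScore:
    """Weighted allele-count score.

    ``weights`` needs columns ``snp, ea, weight``. Allele orientation is
    resolved against the genotype metadata (direct or strand-complement
    match; a weight stated for the genotype's other allele counts 2-g).
    SNPs absent from the genotype columns are skipped with a logged count.
    """
    required = {"snp", "ea", "weight"}
    if not required <= set(weights.columns):
        raise ValueError(f"weights need columns {sorted(required)}")
    score = np.zeros(genotypes.n_individuals)
    index = {s: i for i, s in enumerate(genotypes.snps)}
    used = skipped = 0
    for row in weights.itertuples(index=False):
        j = index.get(row.snp)
        if j is None:
            skipped += 1
            continue
        g = genotypes.dosages[:, j].astype(float)
        ea_g, oa_g = genotypes.ea[j], genotypes.oa[j]
        if row.ea in (ea_g, _COMPLEMENT.get(ea_g)):
            score += row.weight * g
        elif row.ea in (oa_g, _COMPLEMENT.get(oa_g)):
            score += row.weight * (2.0 - g)
        else:
            skipped += 1
            continue
        used += 1
    if used == 0:
        raise ValueError("no usable SNPs shared between weights and genotypes")
    if skipped:
        logger.info("build_pgs: skipped %d of %d weight SNPs", skipped, len(weights))
    return PolygenicScore(values=score, n_snps_used=used, n_snps_skipped=skipped)


def _prepare(
    cohort: pd.DataFrame, pgs, exposure: str, outcome: str, covariates: list[str],
    require_exposure: bool = True,
):
    exposure_col = resolve_exposure_column(cohort, exposure)
    data = cohort.copy()
    data["_pgs"] = np.asarray(pgs.values if isinstance(pgs, PolygenicScore) else pgs, float)
    needed = ["_pgs", outcome, *covariates]
    if require_exposure:
        needed.append(exposure_col)
    data = _complete_cases(data, needed)
    return data, exposure_col


def two_stage_least_squares(
    cohort: pd.DataFrame,
    pgs,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    model: str | None = None,
    weak_f_threshold: float = 10.0,
) -> EffectEstimate:
    """2SLS with the PGS instrumenting the exposure.

    Stage 1 regresses the exposure on PGS + covariates; stage 2 regresses
    the outcome on the fitted exposure + covariates. The SE uses the
    instrumental-variable variance formula with residuals from the
    *observed* exposure. A first-stage partial F below ``weak_f_threshold``
    triggers a weak-instrument warning (the estimate is still returned).
    """
    covs = MODEL_COVARIATES[model] if model else list(covariates or [])
    data, exposure_col = _prepare(cohort, pgs, exposure, outcome, covs)
    n = len(data)
    if n < 30:
        raise ValueError(f"only {n} complete rows for 2SLS")
    y = data[outcome].to_numpy(dtype=float)
    Xz, _ = _design(data, "_pgs", covs)  # [1, pgs, covars]
    x_obs = data[exposure_col].to_numpy(dtype=float)
    # structural design: [1, exposure, covars]
    X = Xz.copy()
    X[:, 1] = x_obs

    # stage 1 and its partial F for the instrument
    coef1, *_ = np.linalg.lstsq(Xz, x_obs, rcond=None)
    fitted_x = Xz @ coef1
    resid1 = x_obs - fitted_x
    s1_sigma2 = float(resid1 @ resid1) / (n - Xz.shape[1])
    cov1 = s1_sigma2 * np.linalg.inv(Xz.T @ Xz)
    f_stat = float(coef1[1] ** 2 / cov1[1, 1])
    if f_stat < weak_f_threshold:
        warnings.warn(
            f"first-stage F = {f_stat:.2f} < {weak_f_threshold}: weak instrument",
            WeakInstrumentWarning,
            stacklevel=2,
        )

    Xhat = X.copy()
    Xhat[:, 1] = fitted_x
    theta, *_ = np.linalg.lstsq(Xhat, y, rcond=None)
    resid = y - X @ theta  # residuals from observed, not fitted, exposure
    sigma2 = float(resid @ resid) / (n - X.shape[1])
    cov = sigma2 * np.linalg.inv(Xhat.T @ Xhat)
    return EffectEstimate.from_beta_se(
        beta=theta[1],
        se=float(np.sqrt(cov[1, 1])),
        n=n,
        method="2sls",
        model=model or "",
        diagnostics={"first_stage_f": f_stat, "weak_instrument": f_stat < weak_f_threshold},
    )


def pgs_ratio(
    cohort: pd.DataFrame,
    pgs,
    exposure: str,
    outcome: str,
    covariates: list[str] | None = None,
    model: str | None = None,
    exposure_sample: pd.Series | np.ndarray | None = None,
) -> EffectEstimate:
    """Wald-ratio estimate from two covariate-adjusted PGS regressions.

    The PGS-outcome coefficient is estimated on all rows with outcome data;
    the PGS-exposure coefficient on ``exposure_sample`` (default: rows with
    observed exposure). SE by the two-term delta method, treating the two
    coefficients as independent.
    """
    covs = MODEL_COVARIATES[model] if model else list(covariates or [])
    data_out, exposure_col = _prepare(
        cohort, pgs, exposure, outcome, covs, require_exposure=False
    )
    Xo, names = _design(data_out, "_pgs", covs)
    yo = data_out[outcome].to_numpy(dtype=float)
    co, *_ = np.linalg.lstsq(Xo, yo, rcond=None)
    ro = yo - Xo @ co
    s2o = float(ro @ ro) / (len(yo) - Xo.shape[1])
    covo = s2o * np.linalg.inv(Xo.T @ Xo)
    b_out, se_out = float(co[1]), float(np.sqrt(covo[1, 1]))

    # exposure-side regression, possibly on a selected subsample
    tmp = cohort.copy()
    tmp["_pgs"] = np.asarray(pgs.values if isinstance(pgs, PolygenicScore) else pgs, float)
    if exposure_sample is not None:
        tmp = tmp[np.asarray(exposure_sample, bool)]
    tmp = _complete_cases(tmp, ["_pgs", exposure_col, *covs])
    Xe, _ = _design(tmp, "_pgs", covs)
    xe = tmp[exposure_col].to_numpy(dtype=float)
    ce, *_ = np.linalg.lstsq(Xe, xe, rcond=None)
    re = xe - Xe @ ce
    s2e = float(re @ re) / (len(xe) - Xe.shape[1])
    cove = s2e * np.linalg.inv(Xe.T @ Xe)
    b_exp, se_exp = float(ce[1]), float(np.sqrt(cove[1, 1]))

    if abs(b_exp) < 1e-12:
        raise ZeroDivisionError("PGS-exposure association is (numerically) zero")
    beta = b_out / b_exp
    se = np.sqrt(se_out**2 / b_exp**2 + b_out**2 * se_exp**2 / b_exp**4)
    return EffectEstimate.from_beta_se(
        beta=beta,
        se=se,
        n=len(data_out),
        method="pgs_ratio",
        model=model or "",
        diagnostics={
            "b_outcome": b_out,
            "se_outcome": se_out,
            "b_exposure": b_exp,
            "se_exposure": se_exp,
            "n_exposure_sample": len(tmp),
        },
    )


def selected_vs_full_contrast(
    cohort: pd.DataFrame,
    pgs,
    metabolite: str,
    covariates: list[str] | None = None,
    model: str = "model2",
) -> dict[str, EffectEstimate]:
    """Side-by-side menopause-age analyses under the study's sample
    definitions.

    * ``mv_selected`` — OLS on women with observed natural-menopause age;
    * ``tsls_selected`` — one-sample 2SLS on the same selected women;
    * ``ratio_full`` — PGS ratio with the outcome association from all
      women and the exposure association from the selected sample.
    """
    from .mvreg import fit_adjusted_model

    if "menopause_status" not in cohort.columns:
        raise ValueError("cohort must carry a menopause_status column")
    females = cohort[cohort["sex"] == "F"] if "sex" in cohort.columns else cohort
    pgs_vals = np.asarray(pgs.values if isinstance(pgs, PolygenicScore) else pgs, float)
    if len(pgs_vals) == len(cohort):
        pgs_vals = pgs_vals[(cohort["sex"] == "F").to_numpy()] if "sex" in cohort.columns else pgs_vals
    selected = (females["menopause_status"] == "natural").to_numpy()
    if not selected.any():
        raise ValueError("contrast degenerate: no women with natural menopause")
    if (females["menopause_status"] == "pre").sum() == 0:
        warnings.warn(
            "no premenopausal rows: selected and full samples coincide",
            RuntimeWarning,
            stacklevel=2,
        )
    covs = MODEL_COVARIATES[model] if model else list(covariates or [])
    fem_sel = females[selected]
    mv = fit_adjusted_model(fem_sel, "menopause", metabolite, model=model)
    tsls = two_stage_least_squares(
        fem_sel, pgs_vals[selected], "menopause", metabolite, covariates=covs
    )
    ratio = pgs_ratio(
        females, pgs_vals, "menopause", metabolite, covariates=covs,
        exposure_sample=selected,
    )
    return {"mv_selected": mv, "tsls_selected": tsls, "ratio_full": ratio}
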