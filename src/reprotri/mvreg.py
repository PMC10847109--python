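"""Multivariable-regression stage.

Three nested adjustment sets are used throughout:

* ``model1`` — unadjusted;
* ``model2`` — education, baseline age and body size at age 10 (the
  preferred causal model: these proxies precede the reproductive
  exposures);
* ``model3`` — model2 plus baseline BMI, smoking and alcohol (these may be
  mediators, so attenuation between model2 and model3 is itself
  informative).

Also provides exposure categorisation with the study cut-points, a
likelihood-ratio test of non-linearity (categorical vs linear-in-scores
coding), restricted cubic splines with Harrell knot percentiles,
medication-exclusion filters and baseline-age stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datatypes import EffectEstimate

__all__ = [
    "MODEL_COVARIATES",
    "CollinearityError",
    "fit_adjusted_model",
    "categorize",
    "test_nonlinearity",
    "fit_rcs",
    "rcs_basis",
    "harrell_knots",
    "SplineFit",
    "exclude_medication",
    "age_stratify",
    "AGE_STRATA",
]

MODEL_COVARIATES = {
    "model1": [],
    "model2": ["education", "age_baseline", "body_size_age10"],
    "model3": ["education", "age_baseline", "body_size_age10", "bmi", "smoking", "alcohol"],
}

EXPOSURE_COLUMNS = {
    "menarche": "menarche_age",
    "parity": "n_children",
    "menopause": "menopause_age",
}

#: baseline-age strata: <=50, (50, 58], (58, 63], >63 years
AGE_STRATA = ((-np.inf, 50.0), (50.0, 58.0), (58.0, 63.0), (63.0, np.inf))


class CollinearityError(ValueError):
    pass


def _design(frame: pd.DataFrame, exposure_col: str, covariates: list[str]):
    """Intercept + exposure + dummy-coded covariates; checks rank."""
    cols = [np.ones(len(frame)), frame[exposure_col].to_numpy(dtype=float)]
    names = ["const", exposure_col]
    for c in covariates:
        s = frame[c]
        if isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object:
            dums = pd.get_dummies(s, prefix=c, drop_first=True, dtype=float)
            for dc in dums.columns:
                cols.append(dums[dc].to_numpy())
                names.append(dc)
        else:
            cols.append(s.to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = [names[i] for i in piv[rank:]]
        raise CollinearityError(f"collinear design columns: {bad}")
    return X, names


def _complete_cases(cohort: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    return cohort.dropna(subset=[c for c in columns if c in cohort.columns])


def resolve_exposure_column(cohort: pd.DataFrame, exposure: str) -> str:
    if exposure in cohort.columns:
        return exposure
    if exposure in EXPOSURE_COLUMNS and EXPOSURE_COLUMNS[exposure] in cohort.columns:
        return EXPOSURE_COLUMNS[exposure]
    raise KeyError(f"exposure {exposure!r} not found in cohort")


def fit_adjusted_model(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    model: str = "model2",
    min_rows: int = 30,
) -> EffectEstimate:
    """OLS slope of ``outcome`` on the continuous exposure under one of the
    three adjustment models; complete-case per exposure/outcome/model."""
    if model not in MODEL_COVARIATES:
        raise ValueError(f"model must be one of {sorted(MODEL_COVARIATES)}, got {model!r}")
    exposure_col = resolve_exposure_column(cohort, exposure)
    if outcome not in cohort.columns:
        raise KeyError(f"outcome {outcome!r} not found in cohort")
    covs = MODEL_COVARIATES[model]
    data = _complete_cases(cohort, [exposure_col, outcome, *covs])
    if len(data) < min_rows:
        raise ValueError(
            f"only {len(data)} complete rows for {exposure}/{outcome}/{model}; need >= {min_rows}"
        )
    X, names = _design(data, exposure_col, covs)
    fit = sm.OLS(data[outcome].to_numpy(dtype=float), X).fit()
    i = names.index(exposure_col)
    return EffectEstimate.from_beta_se(
        beta=fit.params[i],
        se=fit.bse[i],
        n=len(data),
        method="ols",
        model=model,
        diagnostics={"r_squared": float(fit.rsquared)},
    )


# ---------------------------------------------------------------------------
# categorisation and non-linearity
# ---------------------------------------------------------------------------

_CATEGORY_BINS = {
    # right-open intervals on the continuous scale; labels follow the
    # integer-year reading of the cut-points
    "menarche": ([-np.inf, 13.0, 15.0, np.inf], ["<13", "13-14", ">14"]),
    "menopause": ([-np.inf, 49.0, 51.0, 54.0, np.inf], ["<49", "49-50", "51-53", ">53"]),
}


def categorize(exposure: str, values) -> pd.Categorical:
    """Study categorisation: menarche tertiles (<13, 13-14, >14 years),
    menopause quartiles (<49, 49-50, 51-53, >53 years), parity 0/1/2/3+."""
    v = np.asarray(values, dtype=float)
    if exposure == "parity":
        if np.nanmin(v) < 0:
            raise ValueError("negative parity encountered")
        labels = ["0", "1", "2", "3+"]
        codes = np.minimum(v, 3)
        out = pd.cut(codes, bins=[-0.5, 0.5, 1.5, 2.5, 3.5], labels=labels)
        return out
    if exposure not in _CATEGORY_BINS:
        raise ValueError(f"exposure must be menarche, parity or menopause, got {exposure!r}")
    bins, labels = _CATEGORY_BINS[exposure]
    return pd.cut(v, bins=bins, labels=labels, right=False)


def test_nonlinearity(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    model: str = "model2",
    min_per_category: int = 2,
) -> dict:
    """Likelihood-ratio comparison of category-indicator vs
    linear-in-category-scores coding of the exposure.

    Category scores are the integer codes 0..k-1 (logged in the result so
    the scoring convention is explicit). ``p_trend`` is the two-sided
    p-value of the score-linear slope; ``p_nonlinear`` is the chi-square
    LRT p on k-2 degrees of freedom.
    """
    exposure_col = resolve_exposure_column(cohort, exposure)
    covs = MODEL_COVARIATES[model]
    data = _complete_cases(cohort, [exposure_col, outcome, *covs]).copy()
    cats = categorize(exposure, data[exposure_col].to_numpy())
    data["_cat"] = cats
    counts = data["_cat"].value_counts()
    small = counts[counts < min_per_category].index.tolist()
    if small:
        warnings.warn(f"dropping sparse categories {small}", RuntimeWarning, stacklevel=2)
        data = data[~data["_cat"].isin(small)]
    data["_cat"] = data["_cat"].cat.remove_unused_categories()
    k = data["_cat"].nunique()
    if k < 3:
        raise ValueError(f"only {k} occupied categories; non-linearity test undefined (df=0)")
    scores = data["_cat"].cat.codes.to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    data_scores = data.assign(_score=scores)
    Xlin, names_lin = _design(data_scores, "_score", covs)
    fit_lin = sm.OLS(y, Xlin).fit()
    dums = pd.get_dummies(data["_cat"], prefix="cat", drop_first=True, dtype=float)
    Xcat = np.column_stack([np.ones(len(data)), dums.to_numpy(), Xlin[:, 2:]])
    fit_cat = sm.OLS(y, Xcat).fit()

    lrt = 2.0 * (fit_cat.llf - fit_lin.llf)
    df = k - 2
    i = names_lin.index("_score")
    return {
        "lrt_stat": float(lrt),
        "df": int(df),
        "p_trend": float(fit_lin.pvalues[i]),
        "p_nonlinear": float(stats.chi2.sf(lrt, df)),
        "n": int(len(data)),
        "k_categories": int(k),
        "score_convention": "integer category codes 0..k-1",
    }


test_nonlinearity.__test__ = False  # not a pytest case despite the name


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

HARRELL_PERCENTILES = {
    3: (10.0, 50.0, 90.0),
    4: (5.0, 35.0, 65.0, 95.0),
    5: (5.0, 27.5, 50.0, 72.5, 95.0),
}


def harrell_knots(values, n_knots: int) -> np.ndarray:
    if n_knots not in HARRELL_PERCENTILES:
        raise ValueError("n_knots must be 3, 4 or 5")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return np.percentile(v, HARRELL_PERCENTILES[n_knots])


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, truncated-power form.

    Columns: x itself followed by k-2 non-linear terms
    ``[(x-t_j)^3_+ - (x-t_{k-1})^3_+ (t_k-t_j)/(t_k-t_{k-1})
       + (x-t_k)^3_+ (t_{k-1}-t_j)/(t_k-t_{k-1})] / (t_k-t_1)^2``,
    which makes the fitted function linear beyond the boundary knots.
    """
    t = np.sort(np.asarray(knots, dtype=float))
    if np.unique(t).size != t.size:
        raise ValueError("duplicate knots")
    k = t.size
    x = np.asarray(x, dtype=float)
    scale = (t[-1] - t[0]) ** 2

    def pos3(u):
        return np.clip(u, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        term = (
            pos3(x - t[j])
            - pos3(x - t[k - 2]) * (t[-1] - t[j]) / (t[-1] - t[k - 2])
            + pos3(x - t[-1]) * (t[k - 2] - t[j]) / (t[-1] - t[k - 2])
        )
        cols.append(term / scale)
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineFit:
    knots: np.ndarray
    coefficients: np.ndarray
    aic: float
    bic: float
    rmse: float
    n_knots: int
    aic_linear: float
    bic_linear: float
    rmse_linear: float
    n: int
    #: LRT p-value for the joint nullity of the non-linear spline terms
    p_nonlinear: float = float("nan")

    @property
    def prefers_spline(self) -> bool:
        return self.aic < self.aic_linear


def fit_rcs(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str,
    n_knots: int = 3,
    knots=None,
    model: str = "model1",
) -> SplineFit:
    """Fit a restricted cubic spline in the exposure (plus the model's
    covariates) and the linear comparator; returns AIC/BIC/RMSE for both."""
    exposure_col = resolve_exposure_column(cohort, exposure)
    covs = MODEL_COVARIATES[model]
    data = _complete_cases(cohort, [exposure_col, outcome, *covs])
    x = data[exposure_col].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    t = np.asarray(knots, float) if knots is not None else harrell_knots(x, n_knots)
    if len(t) != n_knots:
        raise ValueError("length of knots must equal n_knots")
    B = rcs_basis(x, t)
    Xcov, _ = _design(data, exposure_col, covs)
    cov_part = Xcov[:, 2:]
    Xs = np.column_stack([np.ones(len(data)), B, cov_part])
    Xl = np.column_stack([np.ones(len(data)), x, cov_part])
    fit_s = sm.OLS(y, Xs).fit()
    fit_l = sm.OLS(y, Xl).fit()
    lrt = 2.0 * (fit_s.llf - fit_l.llf)
    p_nl = float(stats.chi2.sf(lrt, n_knots - 2))
    return SplineFit(
        knots=t,
        coefficients=fit_s.params[: 1 + B.shape[1]],
        aic=float(fit_s.aic),
        bic=float(fit_s.bic),
        rmse=float(np.sqrt(np.mean(fit_s.resid**2))),
        n_knots=n_knots,
        aic_linear=float(fit_l.aic),
        bic_linear=float(fit_l.bic),
        rmse_linear=float(np.sqrt(np.mean(fit_l.resid**2))),
        n=len(data),
        p_nonlinear=p_nl,
    )


# ---------------------------------------------------------------------------
# filters and strata
# ---------------------------------------------------------------------------

def exclude_medication(cohort: pd.DataFrame, which: str = "both") -> pd.DataFrame:
    """Drop rows flagged for statin and/or HRT use at baseline."""
    flags = {"statin": ["statin_flag"], "hrt": ["hrt_flag"], "both": ["statin_flag", "hrt_flag"]}
    if which not in flags:
        raise ValueError("which must be 'statin', 'hrt' or 'both'")
    mask = np.zeros(len(cohort), dtype=bool)
    for f in flags[which]:
        mask |= cohort[f].fillna(False).to_numpy(dtype=bool)
    return cohort[~mask]


def age_stratify(cohort: pd.DataFrame) -> list[pd.DataFrame]:
    """Partition by baseline age into <=50, (50,58], (58,63], >63 years."""
    age = cohort["age_baseline"]
    missing = age.isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} rows with missing baseline age",
            RuntimeWarning,
            stacklevel=2,
        )
    kept = cohort[~missing]
    out = []
    for lo, hi in AGE_STRATA:
        out.append(kept[(kept["age_baseline"] > lo) & (kept["age_baseline"] <= hi)])
    return out
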