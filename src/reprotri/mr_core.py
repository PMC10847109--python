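"""Two-sample Mendelian-randomization machinery.

Implements harmonization of exposure and outcome GWAS summary statistics
to a common effect allele, and the summary-data estimators used in the
triangulation: the Wald ratio, inverse-variance-weighted (IVW) regression
through the origin (fixed or multiplicative-random-effects), MR-Egger
(whose intercept estimates average directional pleiotropy under the
InSIDE assumption), the weighted median (consistent when >=50% of weight
comes from valid instruments), multivariable IVW for direct effects
conditional on a co-exposure, Cochran's Q heterogeneity, and per-SNP
R^2 / F instrument-strength diagnostics.

Summary statistics travel as DataFrames with columns
``snp, ea, oa, eaf, beta, se[, p, n]`` (EA = effect allele); a
:class:`SummaryStatRecord` dataclass is provided for single records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MREstimate

__all__ = [
    "SummaryStatRecord",
    "HarmonizedInstrumentSet",
    "InstrumentStrength",
    "harmonize",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mvmr_ivw",
    "instrument_strength",
    "negative_control_outcome_mr",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class SummaryStatRecord:
    """Per-SNP association with one trait."""

    snp: str
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float = float("nan")
    n: int = 0

    def __post_init__(self):
        if self.se <= 0:
            raise ValueError(f"{self.snp}: se must be positive")
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(f"{self.snp}: eaf must lie in (0, 1)")
        if self.ea == self.oa:
            raise ValueError(f"{self.snp}: effect and other allele are identical")


def as_sumstats_frame(records) -> pd.DataFrame:
    """Coerce a DataFrame or an iterable of SummaryStatRecord to a frame."""
    if isinstance(records, pd.DataFrame):
        missing = {"snp", "ea", "oa", "eaf", "beta", "se"} - set(records.columns)
        if missing:
            raise ValueError(f"summary-stat frame missing columns: {sorted(missing)}")
        return records
    rows = [
        r.__dict__ if isinstance(r, SummaryStatRecord) else dict(r) for r in records
    ]
    return pd.DataFrame(rows)


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class HarmonizedInstrumentSet:
    """Exposure/outcome effects aligned to a common effect allele, one row
    per retained SNP; MVMR sets additionally carry a second exposure."""

    data: pd.DataFrame  # snp, bx, sex, by, sey [, bx2, sex2], flipped, inferred_by_eaf
    log: list[dict] = field(default_factory=list)
    exposure_names: tuple[str, ...] = ("exposure",)

    @property
    def k(self) -> int:
        return len(self.data)

    @property
    def bx(self) -> np.ndarray:
        return self.data["bx"].to_numpy(dtype=float)

    @property
    def sex(self) -> np.ndarray:
        return self.data["sex"].to_numpy(dtype=float)

    @property
    def by(self) -> np.ndarray:
        return self.data["by"].to_numpy(dtype=float)

    @property
    def sey(self) -> np.ndarray:
        return self.data["sey"].to_numpy(dtype=float)

    @property
    def has_second_exposure(self) -> bool:
        return "bx2" in self.data.columns

    @classmethod
    def from_arrays(
        cls, bx, sex, by, sey, bx2=None, sex2=None, snps=None,
        exposure_names: tuple[str, ...] | None = None,
    ) -> "HarmonizedInstrumentSet":
        bx = np.asarray(bx, float)
        d = {
            "snp": snps if snps is not None else [f"snp_{i + 1:04d}" for i in range(bx.size)],
            "bx": bx,
            "sex": np.asarray(sex, float),
            "by": np.asarray(by, float),
            "sey": np.asarray(sey, float),
        }
        names = exposure_names or ("exposure",)
        if bx2 is not None:
            d["bx2"] = np.asarray(bx2, float)
            d["sex2"] = np.asarray(sex2, float)
            names = exposure_names or ("exposure", "exposure2")
        frame = pd.DataFrame(d)
        frame["flipped"] = False
        frame["inferred_by_eaf"] = False
        return cls(data=frame, exposure_names=names)


def harmonize(
    exposure,
    outcome,
    palindrome_eaf_window: float = 0.08,
    exposure2=None,
) -> HarmonizedInstrumentSet:
    """Align outcome (and optional second-exposure) effects to the exposure
    file's effect alleles.

    Outcome betas are sign-flipped when allele labels are swapped (directly
    or on the opposite strand). Palindromic SNPs (A/T, C/G) are oriented by
    allele-frequency concordance when both EAFs lie outside
    0.5 +/- ``palindrome_eaf_window``, and dropped otherwise. SNPs with
    irreconcilable alleles are dropped. Every drop is logged with a reason.
    """
    exp = as_sumstats_frame(exposure).set_index("snp")
    out = as_sumstats_frame(outcome).set_index("snp")
    exp2 = as_sumstats_frame(exposure2).set_index("snp") if exposure2 is not None else None
    shared = exp.index.intersection(out.index)
    if exp2 is not None:
        shared = shared.intersection(exp2.index)
    log: list[dict] = []
    for snp in exp.index.difference(shared):
        log.append({"snp": snp, "action": "dropped", "reason": "absent_from_outcome"})
    if len(shared) == 0:
        raise ValueError("no shared SNP identifiers between exposure and outcome")

    def orient(row_x, row_o):
        """Return (sign, eaf_aligned, flipped, inferred, reason)."""
        ea_x, oa_x = row_x["ea"], row_x["oa"]
        ea_o, oa_o = row_o["ea"], row_o["oa"]
        if _is_palindromic(ea_x, oa_x):
            # for a palindromic SNP the strand-complement allele set equals
            # the original, so labels cannot resolve orientation
            if {ea_o, oa_o} != {ea_x, oa_x}:
                return None, None, None, None, "allele_mismatch"
            wx = abs(row_x["eaf"] - 0.5)
            wo = abs(row_o["eaf"] - 0.5)
            if wx <= palindrome_eaf_window or wo <= palindrome_eaf_window:
                return None, None, None, None, "palindromic_ambiguous"
            same_side = (row_x["eaf"] - 0.5) * (row_o["eaf"] - 0.5) > 0
            if same_side:
                return 1.0, row_o["eaf"], False, True, None
            return -1.0, 1.0 - row_o["eaf"], True, True, None
        pairs_same = {(ea_x, oa_x), (_COMPLEMENT[ea_x], _COMPLEMENT[oa_x])}
        pairs_swap = {(oa_x, ea_x), (_COMPLEMENT[oa_x], _COMPLEMENT[ea_x])}
        if (ea_o, oa_o) in pairs_same:
            return 1.0, row_o["eaf"], False, False, None
        if (ea_o, oa_o) in pairs_swap:
            return -1.0, 1.0 - row_o["eaf"], True, False, None
        return None, None, None, None, "allele_mismatch"

    rows = []
    for snp in shared:
        rx = exp.loc[snp]
        ro = out.loc[snp]
        sign, eaf_o, flipped, inferred, reason = orient(rx, ro)
        if reason is not None:
            log.append({"snp": snp, "action": "dropped", "reason": reason})
            continue
        rec = {
            "snp": snp,
            "bx": float(rx["beta"]),
            "sex": float(rx["se"]),
            "by": sign * float(ro["beta"]),
            "sey": float(ro["se"]),
            "flipped": bool(flipped),
            "inferred_by_eaf": bool(inferred),
            "eaf": float(rx["eaf"]),
        }
        if exp2 is not None:
            r2 = exp2.loc[snp]
            s2, _, f2, i2, reason2 = orient(rx, r2)
            if reason2 is not None:
                log.append({"snp": snp, "action": "dropped", "reason": f"exposure2_{reason2}"})
                continue
            rec["bx2"] = s2 * float(r2["beta"])
            rec["sex2"] = float(r2["se"])
            rec["flipped"] = bool(flipped or f2)
            rec["inferred_by_eaf"] = bool(inferred or i2)
        if flipped:
            log.append({"snp": snp, "action": "flipped", "reason": "allele_order"})
        rows.append(rec)
    if not rows:
        raise ValueError("harmonization retained no SNPs")
    names = ("exposure",) if exp2 is None else ("exposure", "exposure2")
    return HarmonizedInstrumentSet(
        data=pd.DataFrame(rows), log=log, exposure_names=names
    )


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def wald_ratio(bx: float, sex: float, by: float, sey: float) -> MREstimate:
    """Single-instrument causal estimate by/bx with first-order delta SE."""
    if bx == 0:
        raise ZeroDivisionError("Wald ratio undefined for bx = 0")
    beta = by / bx
    se = abs(sey / bx)
    return MREstimate.from_beta_se(beta, se, method="wald", k_snps=1)


def _check_k(h: HarmonizedInstrumentSet, minimum: int, method: str) -> None:
    if h.k < minimum:
        hint = "; use wald_ratio for a single SNP" if minimum == 2 else ""
        raise ValueError(f"{method} requires >= {minimum} SNPs, got {h.k}{hint}")


def ivw(h: HarmonizedInstrumentSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate: WLS of by on bx through the
    origin with weights 1/sey^2. ``mode='fixed'`` keeps the fixed-effect SE;
    the default scales it by sqrt(max(1, Q/(k-1)))."""
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    _check_k(h, 2, "ivw")
    bx, by, sey = h.bx, h.by, h.sey
    w = sey**-2.0
    sxx = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    q_df = h.k - 1
    scale = np.sqrt(max(1.0, q / q_df)) if mode == "multiplicative_random" else 1.0
    return MREstimate.from_beta_se(
        beta,
        se_fixed * scale,
        method="ivw_mre" if mode == "multiplicative_random" else "ivw_fixed",
        k_snps=h.k,
        cochran_q=q,
        q_df=q_df,
    )


def mr_egger(
    h: HarmonizedInstrumentSet, mode: str = "multiplicative_random"
) -> tuple[MREstimate, MREstimate]:
    """Weighted regression of by on bx with an unconstrained intercept,
    after orienting all bx >= 0. Returns (slope, intercept); the intercept
    is the average directional-pleiotropy estimate."""
    _check_k(h, 3, "mr_egger")
    sign = np.where(h.bx < 0, -1.0, 1.0)
    bx = sign * h.bx
    by = sign * h.by
    sey = h.sey
    if np.allclose(bx, bx[0]):
        raise ValueError("all bx equal after orientation; Egger slope unidentified")
    w = sey**-2.0
    X = np.column_stack([np.ones_like(bx), bx])
    XtW = X.T * w
    cov_unit = np.linalg.inv(XtW @ X)
    coef = cov_unit @ (XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (h.k - 2)
    q = float(np.sum(w * resid**2))
    dispersion = max(1.0, sigma2) if mode == "multiplicative_random" else 1.0
    ses = np.sqrt(np.diag(cov_unit) * dispersion)
    slope = MREstimate.from_beta_se(
        coef[1], ses[1], method="egger", k_snps=h.k, cochran_q=q, q_df=h.k - 2
    )
    intercept = MREstimate.from_beta_se(
        coef[0], ses[0], method="egger_intercept", k_snps=h.k, cochran_q=q, q_df=h.k - 2
    )
    return slope, intercept


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w)
    p = cum - w / 2.0
    return float(np.interp(0.5, p, r))


def weighted_median(
    h: HarmonizedInstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted median of per-SNP Wald ratios.

    Ratios are ordered and the weighted empirical CDF (midpoint convention
    ``p_j = (S_j - w_j/2) / sum(w)``) is linearly interpolated at 0.5.
    Weights are the inverse first-order delta-method variances of the
    ratios. The SE comes from a seeded parametric bootstrap resampling bx
    and by from their standard errors.
    """
    _check_k(h, 3, "weighted_median")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small for a bootstrap SE", RuntimeWarning, stacklevel=2)
    keep = h.bx != 0
    dropped = int((~keep).sum())
    bx, sex, by, sey = h.bx[keep], h.sex[keep], h.by[keep], h.sey[keep]
    if bx.size < 3:
        raise ValueError("fewer than 3 usable SNPs after dropping bx == 0")
    ratios = by / bx
    weights = (sey**2 / bx**2) ** -1.0
    est = _weighted_median_point(ratios, weights)

    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sex, size=(n_boot, bx.size))
    bys = rng.normal(by, sey, size=(n_boot, bx.size))
    ok = bxs != 0
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r = bys[i, ok[i]] / bxs[i, ok[i]]
        # weights held at their observed values across draws
        boots[i] = _weighted_median_point(r, weights[ok[i]])
    se = float(boots.std(ddof=1))
    return MREstimate.from_beta_se(
        est,
        se,
        method="weighted_median",
        k_snps=int(bx.size),
        diagnostics={"n_boot": n_boot, "dropped_zero_bx": dropped},
    )


def mvmr_ivw(
    h: HarmonizedInstrumentSet, mode: str = "multiplicative_random"
) -> dict[str, MREstimate]:
    """Multivariable IVW: WLS of by on (bx, bx2) without intercept, weights
    1/sey^2. Returns the direct effect of each exposure conditional on the
    other, keyed by the set's exposure names."""
    if not h.has_second_exposure:
        raise ValueError("mvmr_ivw requires a set with a second exposure (bx2)")
    n_exp = 2
    _check_k(h, n_exp + 1, "mvmr_ivw")
    by, sey = h.by, h.sey
    X_full = np.column_stack([h.bx, h.data["bx2"].to_numpy(dtype=float)])
    names = list(h.exposure_names[:n_exp])
    # an identically-zero exposure column carries no information: the model
    # reduces to univariable IVW for the remaining exposure
    active = [j for j in range(n_exp) if np.any(X_full[:, j] != 0.0)]
    if not active:
        raise ValueError("all exposure effects are zero")
    X = X_full[:, active]
    w = sey**-2.0
    XtW = X.T * w
    gram = XtW @ X
    if np.linalg.matrix_rank(gram) < len(active):
        raise ValueError("rank-deficient MVMR design (collinear exposure effects)")
    cov_unit = np.linalg.inv(gram)
    coef = cov_unit @ (XtW @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    q_df = h.k - len(active)
    dispersion = max(1.0, q / q_df) if mode == "multiplicative_random" else 1.0
    ses = np.sqrt(np.diag(cov_unit) * dispersion)
    out: dict[str, MREstimate] = {}
    for pos, j in enumerate(active):
        out[names[j]] = MREstimate.from_beta_se(
            coef[pos], ses[pos], method="mvmr_ivw", k_snps=h.k, cochran_q=q, q_df=q_df
        )
    for j in range(n_exp):
        if j not in active:
            out[names[j]] = MREstimate(
                beta=float("nan"), se=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), p=float("nan"), method="mvmr_ivw",
                k_snps=h.k, cochran_q=q, q_df=q_df,
                diagnostics={"dropped": "all exposure effects zero"},
            )
    return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentStrength:
    r2_total: float
    mean_f: float
    r2_j: np.ndarray
    f_j: np.ndarray
    k: int


def instrument_strength(records, trait_variance: float) -> InstrumentStrength:
    """Variance explained and F statistics for an instrument set.

    ``r2_j = 2 eaf_j (1 - eaf_j) beta_j^2 / trait_variance`` and
    ``f_j = r2_j (n_j - 2) / (1 - r2_j)``; the total R^2 sums the per-SNP
    values (independent SNPs assumed).
    """
    if trait_variance <= 0:
        raise ValueError("trait_variance must be positive")
    frame = as_sumstats_frame(records)
    if "n" not in frame.columns or frame["n"].isna().any():
        raise ValueError("instrument records need per-SNP sample sizes")
    eaf = frame["eaf"].to_numpy(dtype=float)
    beta = frame["beta"].to_numpy(dtype=float)
    n = frame["n"].to_numpy(dtype=float)
    r2 = 2.0 * eaf * (1.0 - eaf) * beta**2 / trait_variance
    f = r2 * (n - 2.0) / (1.0 - r2)
    return InstrumentStrength(
        r2_total=float(r2.sum()),
        mean_f=float(f.mean()),
        r2_j=r2,
        f_j=f,
        k=len(frame),
    )


def negative_control_outcome_mr(
    h: HarmonizedInstrumentSet, alpha: float = 0.05, mode: str = "multiplicative_random"
) -> tuple[MREstimate, bool]:
    """IVW against an outcome that cannot plausibly be affected by the
    exposure (e.g. skin pigmentation); a sub-alpha p-value flags residual
    population stratification in the instrument set."""
    est = ivw(h, mode=mode)
    return est, bool(est.p < alpha)
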