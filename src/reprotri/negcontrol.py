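"""Male negative-control comparison for parity.

Men cannot experience pregnancy, but their children count shares the
socio-demographic confounding structure of women's parity. A
female-vs-male comparison of the children-count association with each
metabolite therefore separates confounding from a plausibly causal effect
of parity: concordant associations in both sexes point to bias, a clear
female association absent (or reversed) in males points to a causal
effect.

The concordance criterion is operationalised as (direction agreement,
95%-CI overlap) and a z-test for the female-male difference is reported
alongside, so either rule can be applied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EffectEstimate
from .mvreg import fit_adjusted_model

__all__ = ["NegativeControlVerdict", "run_negative_control", "verdicts_to_frame"]


@dataclass(frozen=True)
class NegativeControlVerdict:
    metabolite: str
    beta_f: EffectEstimate
    beta_m: EffectEstimate
    same_direction: bool
    ci_overlap: bool
    z_diff: float
    p_diff: float
    classification: str  # bias-suggestive | causal-suggestive | inconclusive


def _classify(
    f: EffectEstimate, m: EffectEstimate, alpha: float
) -> tuple[bool, bool, str]:
    same_direction = np.sign(f.beta) == np.sign(m.beta)
    ci_overlap = f.ci_overlaps(m)
    if same_direction and ci_overlap:
        return same_direction, ci_overlap, "bias-suggestive"
    if f.p < alpha and (m.p >= alpha or not same_direction):
        return same_direction, ci_overlap, "causal-suggestive"
    return same_direction, ci_overlap, "inconclusive"


def run_negative_control(
    cohort: pd.DataFrame,
    metabolites: list[str],
    model: str = "model2",
    alpha: float = 0.05,
) -> list[NegativeControlVerdict]:
    """Fit the children-count association separately by sex and classify
    each metabolite's female-vs-male concordance."""
    sexes = set(cohort["sex"].dropna().unique())
    if not {"F", "M"} <= sexes:
        raise ValueError(f"cohort must contain both sexes, found {sorted(sexes)}")
    females = cohort[cohort["sex"] == "F"]
    males = cohort[cohort["sex"] == "M"]
    out = []
    for met in metabolites:
        bf = fit_adjusted_model(females, "parity", met, model=model)
        bm = fit_adjusted_model(males, "parity", met, model=model)
        z = (bf.beta - bm.beta) / np.sqrt(bf.se**2 + bm.se**2)
        p = float(2.0 * stats.norm.sf(abs(z)))
        same, overlap, cls = _classify(bf, bm, alpha)
        out.append(
            NegativeControlVerdict(
                metabolite=met,
                beta_f=bf,
                beta_m=bm,
                same_direction=bool(same),
                ci_overlap=bool(overlap),
                z_diff=float(z),
                p_diff=p,
                classification=cls,
            )
        )
    return out


def verdicts_to_frame(verdicts: list[NegativeControlVerdict]) -> pd.DataFrame:
    rows = []
    for v in verdicts:
        rows.append(
            {
                "metabolite": v.metabolite,
                "beta_f": v.beta_f.beta,
                "se_f": v.beta_f.se,
                "p_f": v.beta_f.p,
                "beta_m": v.beta_m.beta,
                "se_m": v.beta_m.se,
                "p_m": v.beta_m.p,
                "same_direction": v.same_direction,
                "ci_overlap": v.ci_overlap,
                "z_diff": v.z_diff,
                "p_diff": v.p_diff,
                "classification": v.classification,
            }
        )
    return pd.DataFrame(rows)
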