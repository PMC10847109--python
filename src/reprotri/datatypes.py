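"""Shared result containers used across the analysis stages.

All effect sizes are reported in outcome-SD units per one exposure unit
(one year of menarche/menopause age, one child for parity) so that the
regression, negative-control and Mendelian-randomization arms are directly
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import stats

Z95 = 1.959963984540054  # normal 97.5% quantile; large-sample CIs throughout


@dataclass(frozen=True)
class EffectEstimate:
    """A single slope estimate with its uncertainty.

    ``method`` labels the estimator (e.g. ``"ols"``, ``"2sls"``,
    ``"pgs_ratio"``) and ``model`` the covariate set (``"model1"`` ..
    ``"model3"``) where applicable.
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    method: str
    model: str = ""
    diagnostics: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        n: int,
        method: str,
        model: str = "",
        diagnostics: Mapping[str, Any] | None = None,
    ) -> "EffectEstimate":
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        p = float(2.0 * stats.norm.sf(abs(z)))
        return cls(
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            p=max(p, np.finfo(float).tiny),
            n=int(n),
            method=method,
            model=model,
            diagnostics=dict(diagnostics or {}),
        )

    def ci_overlaps(self, other: "EffectEstimate") -> bool:
        return self.ci_low <= other.ci_high and other.ci_low <= self.ci_high


@dataclass(frozen=True)
class MREstimate:
    """Result of a summary-data MR estimator."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    k_snps: int
    cochran_q: float = float("nan")
    q_df: int = 0
    diagnostics: Mapping[str, Any] = field(default_factory=dict)

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        method: str,
        k_snps: int,
        cochran_q: float = float("nan"),
        q_df: int = 0,
        diagnostics: Mapping[str, Any] | None = None,
    ) -> "MREstimate":
        z = beta / se if se > 0 else np.inf * np.sign(beta)
        p = float(2.0 * stats.norm.sf(abs(z)))
        return cls(
            beta=float(beta),
            se=float(se),
            ci_low=float(beta - Z95 * se),
            ci_high=float(beta + Z95 * se),
            p=max(p, np.finfo(float).tiny),
            method=method,
            k_snps=int(k_snps),
            cochran_q=float(cochran_q),
            q_df=int(q_df),
            diagnostics=dict(diagnostics or {}),
        )

    def ci_covers(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high
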