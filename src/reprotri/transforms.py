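"""Metabolite normalization applied before every analysis stage.

Metabolic measures are mapped to standard-normal quantiles of their
offset-adjusted ranks (rank-based inverse normal transformation, Blom
offset 3/8 by default) so that effect sizes are comparable across traits
in SD units. Missing entries are left missing; the transformation is
computed on observed values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

__all__ = ["rank_inverse_normal", "standardize", "transform_panel", "TransformedPanel"]


def rank_inverse_normal(values, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform of a vector.

    A non-missing value with (average, tie-aware) rank ``r`` among ``n``
    observed values maps to ``Phi^{-1}((r - offset) / (n - 2*offset + 1))``.

    Parameters
    ----------
    values : array-like
        Input vector; NaN marks missing and is preserved.
    offset : float
        Rank offset in [0, 0.5]; 3/8 (Blom) by default.
    """
    if not 0.0 <= offset <= 0.5:
        raise ValueError(f"offset must lie in [0, 0.5], got {offset}")
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(f"need at least 3 non-missing values, got {n}")
    obs = x[mask]
    if np.ptp(obs) == 0:
        raise ValueError("all observed values are identical; transform undefined")
    ranks = stats.rankdata(obs, method="average")
    out = np.full(x.shape, np.nan)
    out[mask] = ndtri((ranks - offset) / (n - 2.0 * offset + 1.0))
    return out


def standardize(values) -> np.ndarray:
    """Center and scale to unit sample SD (ddof=1) on non-missing entries."""
    x = np.asarray(values, dtype=float)
    mask = np.isfinite(x)
    if mask.sum() < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    obs = x[mask]
    sd = obs.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; standardization undefined")
    out = np.full(x.shape, np.nan)
    out[mask] = (obs - obs.mean()) / sd
    return out


@dataclass(frozen=True)
class TransformedPanel:
    """Rank-INT-transformed metabolite matrix plus per-column coverage."""

    data: pd.DataFrame
    n_nonmissing: pd.Series
    offset: float


def transform_panel(
    panel: pd.DataFrame, columns: list[str] | None = None, offset: float = 0.375
) -> TransformedPanel:
    """Apply :func:`rank_inverse_normal` column-wise to a metabolite panel."""
    cols = list(columns) if columns is not None else list(panel.columns)
    out = panel.copy()
    for c in cols:
        out[c] = rank_inverse_normal(panel[c].to_numpy(dtype=float), offset=offset)
    counts = out[cols].notna().sum()
    return TransformedPanel(data=out, n_nonmissing=counts, offset=offset)
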