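"""Effective number of tests for a correlated outcome panel.

NMR metabolite panels are strongly collinear, so a Bonferroni correction
over raw column counts is far too harsh. Following the study design this
package emulates, the number of independent tests per exposure is taken as
the number of principal components of the (correlation-matrix) PCA needed
to explain at least 95% of panel variance, and the significance threshold
is 0.05 / (n_exposures * n_components).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "effective_tests",
    "bonferroni_threshold",
    "multiplicity_summary",
    "MultiplicityResult",
]


@dataclass(frozen=True)
class MultiplicityResult:
    n_components_95: int
    n_exposures: int
    n_tests: int
    alpha: float
    eigenvalues: np.ndarray
    threshold: float


def _panel_correlation(panel, use: str) -> np.ndarray:
    df = pd.DataFrame(panel)
    if df.shape[1] < 2:
        raise ValueError("panel needs at least 2 columns")
    if use == "complete":
        df = df.dropna(axis=0)
        if df.shape[0] < 3:
            raise ValueError("fewer than 3 complete rows in panel")
        sds = df.std(ddof=1)
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"constant column(s) in panel: {bad}")
        corr = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    elif use == "pairwise":
        sds = df.std(ddof=1)
        if (sds == 0).any():
            bad = list(sds.index[sds == 0])
            raise ValueError(f"constant column(s) in panel: {bad}")
        corr = df.corr(method="pearson", min_periods=3).to_numpy()
        if np.isnan(corr).any():
            raise ValueError("pairwise correlation undefined for some column pair")
    else:
        raise ValueError(f"use must be 'complete' or 'pairwise', got {use!r}")
    return corr


def multiplicity_summary(
    panel,
    threshold: float = 0.95,
    n_exposures: int = 3,
    use: str = "complete",
) -> MultiplicityResult:
    """PCA-based effective-test count and the implied Bonferroni alpha.

    Parameters
    ----------
    panel : DataFrame or 2-D array
        Metabolite matrix (rows = individuals). Correlation-based PCA, so
        column scaling is irrelevant.
    threshold : float
        Variance fraction the leading components must explain (default 0.95).
    use : str
        ``"complete"`` drops rows with any missing cell before computing the
        correlation matrix; ``"pairwise"`` uses pairwise-complete
        correlations (eigenvalues may then go slightly negative; warned).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    corr = _panel_correlation(panel, use)
    eig = np.linalg.eigvalsh(corr)[::-1]
    if eig[-1] < -1e-10:
        warnings.warn(
            "pairwise-complete correlation matrix is not positive semidefinite; "
            f"smallest eigenvalue {eig[-1]:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    total = eig.sum()
    cumfrac = np.cumsum(eig) / total
    m = int(np.searchsorted(cumfrac, threshold - 1e-12) + 1)
    n_tests = n_exposures * m
    return MultiplicityResult(
        n_components_95=m,
        n_exposures=int(n_exposures),
        n_tests=n_tests,
        alpha=bonferroni_threshold(n_exposures, m),
        eigenvalues=eig,
        threshold=threshold,
    )


def effective_tests(panel, threshold: float = 0.95, use: str = "complete") -> int:
    """Smallest m such that the top-m correlation eigenvalues reach ``threshold``."""
    return multiplicity_summary(panel, threshold=threshold, use=use).n_components_95


def bonferroni_threshold(n_exposures: int, n_eff: int) -> float:
    """0.05 divided by the total independent test count."""
    if n_exposures <= 0 or n_eff <= 0:
        raise ValueError("counts must be positive")
    return 0.05 / (n_exposures * n_eff)
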