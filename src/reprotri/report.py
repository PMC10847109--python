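"""Triangulation of estimates across methods.

Causal inference is strengthened when methods with different bias
structures agree. For each exposure-metabolite pair the available
estimates (regression models, negative control, MR estimators) are
assembled, compared at the multiplicity-corrected alpha, and classified:

* ``concordant`` — all CIs overlap and all signs agree;
* ``discordant`` — conflicting signs with non-overlapping CIs;
* ``mr-uninformative`` — the MR interval is so wide relative to the
  regression interval (default 5x) that the MR arm carries no information;
* ``partial`` — anything in between.

Thresholds are explicit configuration and the raw estimates are always
emitted, so the classification is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import EffectEstimate, MREstimate

__all__ = ["TriangulationRecord", "triangulate", "forest_table", "read_forest_table"]

Estimate = EffectEstimate | MREstimate

_MR_METHODS = {
    "wald", "ivw_fixed", "ivw_mre", "egger", "weighted_median", "mvmr_ivw",
    "2sls", "pgs_ratio",
}
_REGRESSION_METHODS = {"ols", "model1", "model2", "model3"}


@dataclass(frozen=True)
class TriangulationRecord:
    exposure: str
    metabolite: str
    estimates: Mapping[str, Estimate]
    passes_threshold: Mapping[str, bool]
    consistency: str
    notes: str = ""
    alpha: float = 0.05
    metabolite_class: str = ""


def _ci_width(e: Estimate) -> float:
    return e.ci_high - e.ci_low


def _is_mr(label: str, est: Estimate) -> bool:
    return est.method in _MR_METHODS or label.startswith("mr")


def triangulate(
    exposure: str,
    metabolite: str,
    estimates: Mapping[str, Estimate],
    alpha: float,
    mr_width_multiple: float = 5.0,
    metabolite_class: str = "",
) -> TriangulationRecord:
    """Classify cross-method consistency for one exposure-metabolite pair.

    ``estimates`` maps method labels (e.g. ``"mv_model2"``, ``"mr_ivw"``)
    to estimates; at least two are required.
    """
    if len(estimates) == 0:
        raise ValueError("empty estimate map")
    if len(estimates) < 2:
        raise ValueError("triangulation needs at least 2 methods")
    passes = {k: bool(e.p < alpha) for k, e in estimates.items()}

    items = list(estimates.items())
    signs = {np.sign(e.beta) for _, e in items if e.beta != 0}
    all_overlap = all(
        a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
        for (_, a), (_, b) in combinations(items, 2)
    )
    mr_items = [(k, e) for k, e in items if _is_mr(k, e)]
    reg_items = [(k, e) for k, e in items if not _is_mr(k, e)]
    notes = []
    consistency = "partial"
    if mr_items and reg_items:
        widest_mr = max(_ci_width(e) for _, e in mr_items)
        narrow_reg = min(_ci_width(e) for _, e in reg_items)
        if widest_mr > mr_width_multiple * narrow_reg:
            consistency = "mr-uninformative"
            notes.append(
                f"MR CI width {widest_mr:.3g} exceeds {mr_width_multiple}x "
                f"regression CI width {narrow_reg:.3g}"
            )
    if consistency != "mr-uninformative":
        if all_overlap and len(signs) <= 1:
            consistency = "concordant"
        elif len(signs) > 1 and not all_overlap:
            consistency = "discordant"
    return TriangulationRecord(
        exposure=exposure,
        metabolite=metabolite,
        estimates=dict(estimates),
        passes_threshold=passes,
        consistency=consistency,
        notes="; ".join(notes),
        alpha=alpha,
        metabolite_class=metabolite_class,
    )


def forest_table(
    records: list[TriangulationRecord],
    path=None,
    plot_path=None,
) -> pd.DataFrame:
    """Long-format table of per-method estimates, one row per
    (exposure, metabolite, method), ordered by metabolite class then name.
    ``significant`` marks p below the record's alpha (the filled-marker
    convention of forest plots). Optionally written as TSV and rendered as
    an SVG forest plot."""
    if not records:
        raise ValueError("no records to tabulate")
    rows = []
    for rec in records:
        for label, e in rec.estimates.items():
            rows.append(
                {
                    "exposure": rec.exposure,
                    "metabolite_class": rec.metabolite_class,
                    "metabolite": rec.metabolite,
                    "method": label,
                    "beta": e.beta,
                    "se": e.se,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "p": e.p,
                    "significant": bool(e.p < rec.alpha),
                    "alpha": rec.alpha,
                    "consistency": rec.consistency,
                }
            )
    table = pd.DataFrame(rows).sort_values(
        ["exposure", "metabolite_class", "metabolite", "method"], kind="stable"
    )
    table = table.reset_index(drop=True)
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    if plot_path is not None:
        _forest_plot(table, plot_path)
    return table


def read_forest_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _forest_plot(table: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = table["metabolite"] + " [" + table["method"] + "]"
    y = np.arange(len(table))[::-1]
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.28 * len(table))))
    for filled in (True, False):
        sub = table["significant"] == filled
        ax.errorbar(
            table.loc[sub, "beta"],
            y[sub.to_numpy()],
            xerr=np.vstack(
                [
                    table.loc[sub, "beta"] - table.loc[sub, "ci_low"],
                    table.loc[sub, "ci_high"] - table.loc[sub, "beta"],
                ]
            ),
            fmt="o",
            mfc="black" if filled else "white",
            mec="black",
            ecolor="grey",
            linestyle="none",
        )
    ax.axvline(0.0, color="red", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("difference in means (SD units) per exposure unit")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
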