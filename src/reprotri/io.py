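"""Plain-text serialization: cohort CSV with a JSON schema sidecar, and
tab-delimited GWAS summary statistics (SNP, EA, OA, EAF, BETA, SE, P, N)."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = [
    "write_cohort_csv",
    "read_cohort_csv",
    "write_summary_stats",
    "read_summary_stats",
]

_SUMSTAT_COLUMNS = {"snp": "SNP", "ea": "EA", "oa": "OA", "eaf": "EAF",
                    "beta": "BETA", "se": "SE", "p": "P", "n": "N"}

_CATEGORICAL = ("sex", "education", "body_size_age10", "smoking", "alcohol", "menopause_status")


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    """Write the cohort table as CSV plus ``<path>.schema.json`` recording
    column dtypes and category levels."""
    path = Path(path)
    table.to_csv(path, index=False)
    schema = {}
    for c in table.columns:
        s = table[c]
        if isinstance(s.dtype, pd.CategoricalDtype):
            schema[c] = {"type": "category", "levels": list(map(str, s.cat.categories))}
        elif s.dtype == bool:
            schema[c] = {"type": "bool"}
        elif pd.api.types.is_integer_dtype(s):
            schema[c] = {"type": "int"}
        elif pd.api.types.is_float_dtype(s):
            schema[c] = {"type": "float"}
        else:
            schema[c] = {"type": "str"}
    with open(path.with_suffix(path.suffix + ".schema.json"), "w") as fh:
        json.dump(schema, fh, indent=1)


def read_cohort_csv(path) -> pd.DataFrame:
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".schema.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            schema = json.load(fh)
        for c, spec in schema.items():
            if c not in table.columns:
                continue
            if spec["type"] == "category":
                table[c] = pd.Categorical(
                    table[c].astype("string"), categories=spec["levels"]
                )
            elif spec["type"] == "bool":
                table[c] = table[c].astype(bool)
    else:
        for c in _CATEGORICAL:
            if c in table.columns:
                table[c] = table[c].astype("category")
    return table


def write_summary_stats(frame: pd.DataFrame, path) -> None:
    out = frame.rename(columns=_SUMSTAT_COLUMNS)
    cols = [c for c in _SUMSTAT_COLUMNS.values() if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    inverse = {v: k for k, v in _SUMSTAT_COLUMNS.items()}
    return frame.rename(columns=inverse)
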