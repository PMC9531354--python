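"""Survey CSV input/output and report writing.

Survey files are comma-separated UTF-8 with a header row of item ids plus
an optional ``group`` column; missing responses are empty fields.  A
companion ``*_latents.csv`` can carry generating latent scores for
synthetic datasets.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .synthetic import SurveyDataset

__all__ = ["read_survey_csv", "write_survey_csv", "write_reports"]


def read_survey_csv(path, scale=(1, 10), group_col: str = "group",
                    model=None) -> SurveyDataset:
    """Read a survey table, validating that every response is an in-range
    integer; out-of-range or non-integer cells are rejected with their
    row and column named."""
    df = pd.read_csv(path)
    group = None
    if group_col in df.columns:
        group = df[group_col].astype(str)
        df = df.drop(columns=[group_col])
    if model is not None:
        missing = [i for i in model.all_indicators if i not in df.columns]
        if missing:
            raise ValueError(f"file lacks model indicators: {missing}")
        extra = [c for c in df.columns if c not in model.all_indicators]
        df = df[[c for c in df.columns if c not in extra]]
    lo, hi = scale
    for colname in df.columns:
        col = pd.to_numeric(df[colname], errors="coerce")
        bad_numeric = col.isna() & df[colname].notna() \
            & (df[colname].astype(str).str.strip() != "")
        if bad_numeric.any():
            row = int(np.where(bad_numeric)[0][0])
            raise ValueError(
                f"non-numeric response at row {row}, column {colname!r}: "
                f"{df[colname].iloc[row]!r}")
        obs = col.dropna()
        if not np.allclose(obs, np.round(obs)):
            row = int(obs.index[~np.isclose(obs, np.round(obs))][0])
            raise ValueError(
                f"non-integer response at row {row}, column {colname!r}")
        out_of_range = obs[(obs < lo) | (obs > hi)]
        if len(out_of_range):
            row = int(out_of_range.index[0])
            raise ValueError(
                f"response {out_of_range.iloc[0]:g} out of range "
                f"[{lo}, {hi}] at row {row}, column {colname!r}")
        df[colname] = col
    return SurveyDataset(responses=df, group=group, scale=tuple(scale))


def write_survey_csv(d: SurveyDataset, path, write_latents: bool = True):
    """Write a dataset (missing cells empty); generating latent scores, if
    present, go to a ``_latents.csv`` companion file."""
    out = d.responses.copy()
    # integer-formatted cells, empty where missing
    out = out.apply(lambda c: c.map(
        lambda v: "" if pd.isna(v) else str(int(v))))
    out["group"] = d.group.to_numpy()
    out.to_csv(path, index=False)
    if write_latents and d.true_latent_scores is not None:
        base, ext = os.path.splitext(str(path))
        d.true_latent_scores.to_csv(base + "_latents" + ext, index=False)


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        df = obj.reset_index()
        df.columns = [str(c) if not isinstance(c, tuple) else "_".join(map(str, c))
                      for c in df.columns]
        return json.loads(df.to_json(orient="records", double_precision=10))
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def write_reports(results: dict, outdir) -> list:
    """Write each entry as CSV (DataFrames) and everything as one JSON.

    Returns the list of files written; output is deterministic for a
    given `results` mapping."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = os.path.join(outdir, f"{name}.csv")
            obj.to_csv(p)
            written.append(p)
    p = os.path.join(outdir, "reports.json")
    with open(p, "w", encoding="utf-8") as fh:
        json.dump({k: _jsonable(v) for k, v in sorted(results.items())},
                  fh, indent=1, sort_keys=True)
    written.append(p)
    return written
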