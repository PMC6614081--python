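"""Delimited-table input/output with ISO-8601 dates (UTF-8 CSV)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

_STAY_DATES = ["admit_date", "discharge_date"]


def write_table(df: pd.DataFrame, path, date_cols=()):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in date_cols:
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_stays(stays: pd.DataFrame, path):
    write_table(stays, path, date_cols=_STAY_DATES)


def read_stays(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=_STAY_DATES)
    if "destination" in df.columns:
        df["destination"] = df["destination"].where(df["destination"].notna(), None)
    return df


def write_enrollment(enrollment: pd.DataFrame, path):
    write_table(enrollment, path)


def read_enrollment(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["month"] = df["month"].astype(str)
    return df


def write_general_ward_stays(gw: pd.DataFrame, path):
    write_table(gw, path, date_cols=_STAY_DATES)


def read_general_ward_stays(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=_STAY_DATES)


def write_latent(latent: pd.DataFrame, path):
    write_table(latent, path, date_cols=["admission_date"])


def read_latent(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["admission_date"])
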