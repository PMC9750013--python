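"""Reading and writing the pipeline's delimited text tables.

All tables are UTF-8 tab-separated files with a header row.  Schemas:

roster        respondent_id, age_group, sex, region, u_i
assignments   respondent_id, vignette_index, trade, risk, deal
responses     respondent_id, vignette_index, cash, doses
video         respondent_id, treated, attitude, donation_points, donation_share
priorities    respondent_id, priority
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SCHEMAS = {
    "roster": ["respondent_id", "age_group", "sex", "region", "u_i"],
    "assignments": ["respondent_id", "vignette_index", "trade", "risk", "deal"],
    "responses": ["respondent_id", "vignette_index", "cash", "doses"],
    "video": ["respondent_id", "treated", "attitude", "donation_points", "donation_share"],
    "priorities": ["respondent_id", "priority"],
}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if kind is not None:
        if kind not in SCHEMAS:
            raise ValueError(f"unknown table kind {kind!r}")
        missing = [c for c in SCHEMAS[kind] if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: {kind} table is missing columns {missing}")
    return df
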