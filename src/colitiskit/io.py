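"""TSV reading/writing with schema checks.

All on-disk artefacts are tab-separated text so that runs are diffable and
reproducible bit-for-bit for a fixed seed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CRYPT_COLUMNS = ["animal_id", "position_um", "region", "height_um", "infiltrate_score", "off_axis"]
METADATA_COLUMNS = ["animal_id", "true_class"]


def read_table(path, required_columns: list[str] | None = None, index_col=None) -> pd.DataFrame:
    """Read a TSV, failing loudly on ragged rows or missing columns."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=index_col)
    except pd.errors.ParserError as err:  # pandas reports the offending line number
        raise ValueError(f"{path}: malformed TSV: {err}") from err
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_crypt_measurements(path) -> pd.DataFrame:
    return read_table(path, required_columns=CRYPT_COLUMNS)


def read_panel(path) -> pd.DataFrame:
    df = read_table(path, required_columns=["animal_id"])
    return df.set_index("animal_id")


def read_metadata(path) -> pd.DataFrame:
    return read_table(path, required_columns=METADATA_COLUMNS)
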