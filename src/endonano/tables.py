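"""Localization-table schema and plain-text I/O.

A localization table is a :class:`pandas.DataFrame` with one row per detected
(or simulated) blink / grouped blink and the fixed column set
:data:`COLUMNS`.  All positions are in nanometres with the origin at the
field-of-view corner; pixel ``(i, j)`` of a camera with pixel size ``p``
covers the half-open square ``[i*p, (i+1)*p) x [j*p, (j+1)*p)``.
"""

from __future__ import annotations

import pandas as pd

#: Canonical column order of a localization table.
COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "bg",
    "sigma_nm",
    "precision_nm",
    "channel",
]

_DTYPES = {
    "frame": "int64",
    "x_nm": "float64",
    "y_nm": "float64",
    "photons": "float64",
    "bg": "float64",
    "sigma_nm": "float64",
    "precision_nm": "float64",
    "channel": "int64",
}


def empty_table() -> pd.DataFrame:
    """Return an empty localization table with the canonical schema."""
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in _DTYPES.items()})


def validate_table(table: pd.DataFrame, require: list[str] | None = None) -> None:
    """Check that ``table`` carries the required columns.

    Raises
    ------
    ValueError
        Naming the first missing column.
    """
    for col in require if require is not None else COLUMNS:
        if col not in table.columns:
            raise ValueError(f"localization table is missing column {col!r}")


def make_table(**columns) -> pd.DataFrame:
    """Build a localization table from keyword columns, filling defaults.

    Unspecified columns default to zero (channel to 0, frame to 0).
    """
    n = max((len(v) for v in columns.values()), default=0)
    data = {}
    for col in COLUMNS:
        if col in columns:
            data[col] = columns[col]
        else:
            data[col] = [0] * n
    df = pd.DataFrame(data)
    return df.astype(_DTYPES)[COLUMNS]


def read_localizations(path) -> pd.DataFrame:
    """Read a localization table from CSV, validating the schema."""
    df = pd.read_csv(path)
    validate_table(df)
    return df.astype(_DTYPES)[COLUMNS]


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table to CSV with the canonical column order."""
    validate_table(table)
    table[COLUMNS].to_csv(path, index=False)
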