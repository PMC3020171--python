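"""Delimited-text input for recorded or simulated time series.

Two column conventions are supported, one row per time step:

* raw intensity: ``ch<i>_w<lambda>`` (e.g. ``ch1_w760``, ``ch1_w830``) —
  converted through the MBLL;
* precomputed concentration changes: ``ch<i>_hbo`` (uM) — used directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mbll import IntensitySeries

__all__ = ["sniff_format", "read_timeseries", "read_hbo_frame",
           "read_intensity"]


class DataError(ValueError):
    pass


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # noqa: BLE001 - surfaced as a data error
        raise DataError(f"cannot read {path}: {exc}") from exc
    if df.empty:
        raise DataError(f"{path} contains no data rows")
    bad = df.columns[~df.map(np.isreal).all(axis=0)]
    if len(bad):
        raise DataError(f"non-numeric values in column(s) {list(bad)}")
    if not np.all(np.isfinite(df.to_numpy(dtype=float))):
        rows = np.argwhere(
            ~np.isfinite(df.to_numpy(dtype=float))
        )
        raise DataError(f"non-finite value at row {rows[0][0]}, "
                        f"column {df.columns[rows[0][1]]!r}")
    return df


def sniff_format(df: pd.DataFrame) -> str:
    """Classify the column convention: 'hbo' or 'intensity'."""
    if all("_hbo" in c for c in df.columns):
        return "hbo"
    if all("_w" in c for c in df.columns):
        return "intensity"
    raise DataError(
        "columns match neither ch<i>_hbo nor ch<i>_w<lambda> conventions"
    )


def read_hbo_frame(path) -> pd.DataFrame:
    """dHbO matrix with channel names as columns (``_hbo`` suffix stripped)."""
    df = _read_table(path)
    cols = [c for c in df.columns if c.endswith("_hbo")]
    if not cols:
        raise DataError("no ch<i>_hbo columns found")
    out = df[cols].copy()
    out.columns = [c[: -len("_hbo")] for c in cols]
    return out


def read_intensity(path, wavelengths, sampling_rate_hz) -> IntensitySeries:
    df = _read_table(path)
    return IntensitySeries.from_dataframe(df, tuple(wavelengths),
                                          sampling_rate_hz)


def read_timeseries(path, fmt: str = "auto"):
    """Return ('hbo', DataFrame) or ('intensity', DataFrame) for *path*."""
    df = _read_table(path)
    if fmt == "auto":
        fmt = sniff_format(df)
    if fmt not in ("hbo", "intensity"):
        raise DataError(f"unknown input format {fmt!r}")
    return fmt, df
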