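"""Reading and writing genetic-map tables and bucket-order text files.

Two plain-text formats are supported:

* **Map TSV** — header ``marker<TAB>chromosome<TAB>position`` (the
  chromosome column is optional), UTF-8, positions parsed as decimal
  reals (centimorgans or base pairs; the unit is irrelevant because
  only the ordering is used).
* **Bucket-order text** — one bucket per line, markers comma-separated,
  convenient for entering worked examples directly.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import pandas as pd

from .orders import BucketOrder, InvalidOrderError

__all__ = [
    "read_map_table",
    "write_map_table",
    "read_bucket_order",
    "write_bucket_order",
]

_MAP_COLUMNS = ("marker", "chromosome", "position")


def read_map_table(path: str | PathLike) -> pd.DataFrame:
    """Load a genetic-map TSV into a validated DataFrame."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chromosome": str})
    unknown = set(df.columns) - set(_MAP_COLUMNS)
    if unknown:
        raise InvalidOrderError(f"unexpected map columns: {sorted(unknown)}")
    for col in ("marker", "position"):
        if col not in df.columns:
            raise InvalidOrderError(f"map table lacks required column {col!r}")
    df["position"] = pd.to_numeric(df["position"], errors="raise")
    return df


def write_map_table(df: pd.DataFrame, path: str | PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bucket_order(path: str | PathLike) -> BucketOrder:
    return BucketOrder.from_text(Path(path).read_text(encoding="utf-8"))


def write_bucket_order(order: BucketOrder, path: str | PathLike) -> None:
    Path(path).write_text(order.to_text(), encoding="utf-8")
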