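"""Patient-table I/O: CSV with a provenance comment line.

Tables are comma-separated UTF-8 with "." decimals, a mandatory header row
and one leading comment line (prefixed ``#``) recording provenance (seed,
config hash, row count).  Floats are written with shortest-roundtrip
precision, so read(write(table)) reproduces values exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .categories import COHORT_COLUMNS, PRIMARY_COLUMNS
from .errors import ConfigurationError, EvaluationError


def write_cohort(
    table: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write a cohort table as CSV with a leading provenance comment."""
    fields = dict(provenance or {})
    fields.setdefault("rows", len(table))
    comment = "# oncopop cohort " + " ".join(f"{k}={v}" for k, v in fields.items())
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(comment + "\n")
        table.to_csv(fh, index=False)


def read_cohort(
    path: str | Path, required: str = "full"
) -> pd.DataFrame:
    """Read a cohort table, checking the documented column set.

    ``required`` is ``"full"`` (all simulated columns must be present, the
    default), ``"primaries"`` (only the primary-variable columns) or
    ``"none"``.
    """
    expected: tuple[str, ...]
    if required == "full":
        expected = COHORT_COLUMNS
    elif required == "primaries":
        expected = PRIMARY_COLUMNS
    elif required == "none":
        expected = ()
    else:
        raise ConfigurationError(f"unknown requirement level '{required}'")
    table = pd.read_csv(path, comment="#")
    missing = [c for c in expected if c not in table.columns]
    if missing:
        raise EvaluationError(f"{path}: missing required column(s) {missing}")
    if len(table) == 0:
        raise ConfigurationError(f"{path}: table has a header but no rows")
    return table
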