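"""Reading and writing the canonical trial-table format and configs.

The canonical trial table is comma-separated text with a header row and
exactly the columns of :data:`metaroc.observer_sim.TRIAL_COLUMNS`;
stimulus/response are coded ``"S1"``/``"S2"``, booleans ``"true"``/
``"false"``, block and trial indices 1-based.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .observer_sim import TRIAL_COLUMNS

__all__ = ["read_trial_table", "write_trial_table", "validate_trial_table",
           "load_config", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a trial table or config violates the canonical schema."""


_DTYPES = {
    "subject_id": str,
    "block": int,
    "trial_idx": int,
    "stimulus": str,
    "response": str,
    "correct": bool,
    "confidence": float,
    "rt_ms": float,
    "soa_ms": float,
    "comprehension_passed": bool,
}


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check column names, codes and ranges; return the table unchanged."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    extra = [c for c in table.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise SchemaError(f"trial table has unknown columns: {extra}")
    if len(table):
        for col in ("stimulus", "response"):
            bad = ~table[col].isin(["S1", "S2"])
            if bad.any():
                row = int(table.index[bad][0])
                raise SchemaError(f"column {col!r} row {row}: expected 'S1' or 'S2'")
        if (table["confidence"].lt(0) | table["confidence"].gt(1)).any():
            raise SchemaError("confidence outside [0, 1]")
        if table["rt_ms"].le(0).any():
            raise SchemaError("rt_ms must be strictly positive")
    return table


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as canonical CSV (booleans as "true"/"false")."""
    out = validate_trial_table(table).copy()
    for col in ("correct", "comprehension_passed"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a canonical trial-table CSV."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in raw.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise SchemaError(f"{path}: unknown columns {extra}")
    table = pd.DataFrame(index=raw.index)
    for col, typ in _DTYPES.items():
        vals = raw[col]
        try:
            if typ is bool:
                lowered = vals.str.lower()
                bad = ~lowered.isin(["true", "false"])
                if bad.any():
                    row = int(raw.index[bad][0])
                    raise SchemaError(
                        f"{path}: column {col!r} row {row}: expected true/false"
                    )
                table[col] = lowered == "true"
            elif typ is str:
                table[col] = vals
            else:
                table[col] = vals.astype(typ)
        except (ValueError, TypeError) as exc:
            if isinstance(exc, SchemaError):
                raise
            raise SchemaError(f"{path}: column {col!r}: {exc}") from exc
    return validate_trial_table(table)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg
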