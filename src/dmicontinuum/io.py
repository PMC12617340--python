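"""File readers/writers: CSV cross tables and matrices, newick trees, YAML
configs, JSON results, and provenance records.

All text formats are UTF-8; CSV is comma-separated with a mandatory header
and "." decimals.  Malformed input is reported with row numbers, never
silently skipped.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .ri import REQUIRED_COLUMNS, SchemaError

__all__ = [
    "read_crosses",
    "write_crosses",
    "read_matrix",
    "write_matrix",
    "read_tree",
    "load_yaml",
    "dump_json",
    "write_provenance",
]

_COUNT_COLUMNS = ["seeds_fertilised", "seeds_total", "seeds_germinated", "seeds_tested"]


def read_crosses(path) -> pd.DataFrame:
    """Read and validate a cross table CSV.

    Raises :class:`dmicontinuum.ri.SchemaError` naming missing columns, and
    reports non-integer or inconsistent counts with their row numbers
    (1-based, excluding the header).
    """
    table = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    bad_rows = []
    for col in _COUNT_COLUMNS:
        vals = pd.to_numeric(table[col], errors="coerce")
        bad = table.index[vals.isna() | (vals != vals.round()) | (vals < 0)]
        bad_rows.extend((int(i) + 1, col) for i in bad)
    if bad_rows:
        detail = ", ".join(f"row {r} ({c})" for r, c in bad_rows[:10])
        raise SchemaError(f"{path}: non-count values: {detail}")
    table[_COUNT_COLUMNS] = table[_COUNT_COLUMNS].astype(int)
    inconsistent = table.index[
        (table["seeds_fertilised"] > table["seeds_total"])
        | (table["seeds_germinated"] > table["seeds_tested"])
    ]
    if len(inconsistent):
        rows = [int(i) + 1 for i in inconsistent[:10]]
        raise SchemaError(f"{path}: successes exceed trials in rows {rows}")
    return table


def write_crosses(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_matrix(path, index_col: int = 0) -> pd.DataFrame:
    """Read a populations x variables (or distance) matrix with an ID column."""
    m = pd.read_csv(path, index_col=index_col)
    if m.shape[1] == 0:
        raise SchemaError(f"{path}: matrix has no data columns")
    non_numeric = [c for c in m.columns if not np.issubdtype(m[c].dtype, np.number)]
    if non_numeric:
        raise SchemaError(f"{path}: non-numeric columns: {non_numeric}")
    return m


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True)


def read_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def load_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected a YAML mapping at top level")
    return data


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def dump_json(data: dict, path=None) -> str:
    text = json.dumps(data, indent=2, default=_jsonable, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def write_provenance(out_path, command: str, params: dict, seed=None) -> Path:
    """Write a provenance record next to an output file.

    Records the command, a stable hash of its parameters, the seed and the
    package version, so results can be traced to the run that produced them.
    """
    from . import __version__

    blob = json.dumps(params, sort_keys=True, default=str).encode()
    record = {
        "command": command,
        "argv": sys.argv,
        "params": params,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
        "package_version": __version__,
    }
    prov_path = Path(str(out_path) + ".provenance.json")
    prov_path.write_text(json.dumps(record, indent=2, default=str) + "\n", encoding="utf-8")
    return prov_path
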