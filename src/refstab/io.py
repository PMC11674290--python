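"""Reading and writing the delimited-text formats used throughout the package.

Ct tables follow the common qPCR export convention: first column gene ids,
remaining columns one sample each (a ``transpose`` flag handles
samples-as-rows exports).  Group assignments come from a two-column
samplesheet (sample_id, group), a YAML mapping, or an in-memory dict.
Instrument-native formats (Bio-Rad CFX etc.) are out of scope; users export
to TSV/CSV first.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .model import CtMatrix, ExpressionMatrix

__all__ = [
    "read_ct_table",
    "write_ct_table",
    "read_expression_table",
    "read_group_map",
    "write_group_map",
    "write_run_metadata",
]

FLOAT_FORMAT = "%.6f"  # round-trip precision contract: 6 decimals


def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def _read_numeric_table(path: str | Path, sep: str | None, transpose: bool) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path, sep), index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    offenders = numeric.isna()
    if offenders.to_numpy().any():
        rows, cols = offenders.to_numpy().nonzero()
        cells = [
            f"gene {df.index[i]!r}, sample {df.columns[j]!r} (value {df.iat[i, j]!r})"
            for i, j in zip(rows, cols)
        ]
        raise ValueError(f"{path}: non-numeric or missing cells: " + "; ".join(cells))
    return numeric.astype(float)


def read_group_map(groups: str | Path | Mapping[str, str]) -> pd.Series:
    """Load a sample -> group mapping from a dict, a two-column samplesheet, or YAML."""
    if isinstance(groups, Mapping):
        return pd.Series({str(k): str(v) for k, v in groups.items()})
    path = Path(groups)
    if path.suffix in {".yaml", ".yml"}:
        with open(path) as fh:
            mapping = yaml.safe_load(fh)
        if not isinstance(mapping, Mapping):
            raise ValueError(f"{path}: YAML group map must be a mapping sample -> group")
        return pd.Series({str(k): str(v) for k, v in mapping.items()})
    df = pd.read_csv(path, sep=_sep_for(path, None), dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: samplesheet needs two columns (sample_id, group)")
    first_two = df.iloc[:, :2]
    if first_two.iloc[:, 0].duplicated().any():
        dups = list(first_two.iloc[:, 0][first_two.iloc[:, 0].duplicated()])
        raise ValueError(f"{path}: duplicate sample ids in samplesheet: {dups}")
    return pd.Series(first_two.iloc[:, 1].values, index=first_two.iloc[:, 0].values)


def write_group_map(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": groups.index, "group": groups.values}).to_csv(
        path, sep=_sep_for(path, None), index=False
    )


def read_ct_table(
    path: str | Path,
    groups: str | Path | Mapping[str, str],
    *,
    sep: str | None = None,
    transpose: bool = False,
) -> CtMatrix:
    """Read a delimited Ct table plus group assignment into a validated CtMatrix.

    Any missing or non-numeric cell is a hard error naming the offending
    gene and sample; values are never imputed.  Row and column order are
    preserved from the file.
    """
    data = _read_numeric_table(path, sep, transpose)
    return CtMatrix(data=data, groups=read_group_map(groups))


def write_ct_table(ct: CtMatrix, path: str | Path, *, groups_path: str | Path | None = None) -> None:
    """Write a Ct table (6-decimal round-trip precision) and optional group samplesheet."""
    out = ct.data.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sep_for(path, None), float_format=FLOAT_FORMAT)
    if groups_path is not None:
        write_group_map(ct.groups, groups_path)


def read_expression_table(
    path: str | Path, *, sep: str | None = None, transpose: bool = False
) -> ExpressionMatrix:
    """Read an FPKM-style abundance matrix (genes x samples/tissues)."""
    return ExpressionMatrix(data=_read_numeric_table(path, sep, transpose))


def write_run_metadata(path: str | Path, *, parameters: Mapping, seed: int | None = None) -> None:
    """Dump run parameters, seed and version info as JSON alongside result tables."""
    import refstab

    meta = {
        "parameters": dict(parameters),
        "seed": seed,
        "versions": {
            "refstab": refstab.__version__,
            "python": sys.version.split()[0],
            "numpy": __import__("numpy").__version__,
            "pandas": pd.__version__,
            "scipy": __import__("scipy").__version__,
        },
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
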