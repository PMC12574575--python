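"""Tabular readers/writers: feature × sample matrices (TSV/CSV) and GMT gene sets.

Matrices are stored features-as-rows, samples-as-columns; missing values are
encoded as ``NA``. Round-trip stability (write then read gives back the same
identifiers and values) is part of the contract and is tested.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

logger = logging.getLogger("alcyte")

NA_MARKER = "NA"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_matrix(path: str | Path, orient_features_rows: bool = True) -> pd.DataFrame:
    """Read a numeric feature × sample matrix from a TSV/CSV file.

    The first column holds feature identifiers and the first row sample
    identifiers. Non-numeric cells other than the ``NA`` marker are rejected;
    duplicated identifiers and ragged rows are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_delimiter(path)

    # manual ragged-row check so the error carries a line number
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
        ncol = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            n = len(line.rstrip("\n").split(sep))
            if n != ncol:
                raise ValueError(
                    f"{path}: ragged row at line {lineno}: {n} fields, expected {ncol}"
                )

    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[NA_MARKER], keep_default_na=False)
    for axis, labels in (("feature", df.index), ("sample", df.columns)):
        dup = labels[labels.duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate {axis} identifier: {dup[0]!r}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell encountered: {exc}") from exc
    if not orient_features_rows:
        df = df.T
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a feature × sample matrix; floats are written at full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, na_rep=NA_MARKER, float_format=None)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a generic annotation/covariate table (first column = identifier)."""
    path = Path(path)
    sep = _sniff_delimiter(path)
    return pd.read_csv(path, sep=sep, index_col=0, na_values=[NA_MARKER], keep_default_na=False)


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> gene1 <tab> ...

    Duplicate genes within a set are collapsed; duplicate set names are an
    error; an empty file yields an empty collection with a warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected ≥3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            genes = {g for g in fields[2:] if g}
            sets[name] = genes
    if not sets:
        logger.warning("GMT file %s is empty", path)
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")
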