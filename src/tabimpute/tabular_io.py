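"""Reading, typing, filtering, summarising and writing mixed-type tables.

The central container is :class:`Dataset`: a dense ``n_samples x n_features``
matrix of cell values with an explicit boolean missingness mask.  Continuous
cells hold reals; categorical cells hold integer level codes that index into
the column's ordered level list.  A masked cell stores ``NaN`` and its value
is ignored by every computation in the package.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: tokens treated as missing on input (matched exactly after trimming
#: surrounding whitespace)
DEFAULT_MISSING_TOKENS = frozenset({"", "NA", "NaN", "nan", "NULL"})


class TableFormatError(ValueError):
    """Raised for malformed delimited input (ragged rows, duplicate headers...)."""


@dataclass
class Dataset:
    """A samples x features table with explicit missingness.

    Parameters
    ----------
    values
        ``(n_samples, n_features)`` float matrix.  Categorical cells hold
        level codes; masked cells hold ``NaN``.
    mask
        Boolean matrix of the same shape; ``True`` marks a missing cell.
    col_names
        Unique, non-empty column names.
    col_types
        Per column, ``"continuous"`` or ``"categorical"``.
    cat_levels
        Per column, the ordered list of level labels (``None`` for
        continuous columns).  Every categorical code indexes this list.
    """

    values: np.ndarray
    mask: np.ndarray
    col_names: list[str]
    col_types: list[str]
    cat_levels: list[list[str] | None] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must equal values shape")
        m = self.values.shape[1]
        if len(self.col_names) != m or len(self.col_types) != m:
            raise ValueError("col_names/col_types length must match n_features")
        if len(set(self.col_names)) != m or any(not n for n in self.col_names):
            raise ValueError("col_names must be unique and non-empty")
        for t in self.col_types:
            if t not in (CONTINUOUS, CATEGORICAL):
                raise ValueError(f"unknown column type {t!r}")
        if self.cat_levels is None:
            self.cat_levels = [None] * m
        if len(self.cat_levels) != m:
            raise ValueError("cat_levels length must match n_features")
        # masked cells carry NaN so stray reads are loud
        self.values[self.mask] = np.nan
        for j, t in enumerate(self.col_types):
            if t == CATEGORICAL:
                levels = self.cat_levels[j]
                if levels is None:
                    raise ValueError(f"categorical column {self.col_names[j]!r} lacks levels")
                codes = self.values[~self.mask[:, j], j]
                if codes.size and (codes.min() < 0 or codes.max() >= len(levels)):
                    raise ValueError(
                        f"level code out of range in column {self.col_names[j]!r}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def continuous_columns(self) -> np.ndarray:
        return np.array([t == CONTINUOUS for t in self.col_types], dtype=bool)

    @property
    def categorical_columns(self) -> np.ndarray:
        return ~self.continuous_columns

    def column_index(self, name: str) -> int:
        try:
            return self.col_names.index(name)
        except ValueError:
            raise KeyError(f"no column named {name!r}") from None

    def copy(self) -> "Dataset":
        return Dataset(
            self.values.copy(),
            self.mask.copy(),
            list(self.col_names),
            list(self.col_types),
            [None if lv is None else list(lv) for lv in self.cat_levels],
        )

    def select_columns(self, indices: Sequence[int]) -> "Dataset":
        idx = list(indices)
        return Dataset(
            self.values[:, idx].copy(),
            self.mask[:, idx].copy(),
            [self.col_names[j] for j in idx],
            [self.col_types[j] for j in idx],
            [None if self.cat_levels[j] is None else list(self.cat_levels[j]) for j in idx],
        )

    def equals(self, other: "Dataset", rtol: float = 1e-12) -> bool:
        """Structural equality: names, types, levels, mask, and values
        (exact for categorical codes, relative ``rtol`` for continuous)."""
        if (
            self.col_names != other.col_names
            or self.col_types != other.col_types
            or self.cat_levels != other.cat_levels
            or not np.array_equal(self.mask, other.mask)
        ):
            return False
        obs = ~self.mask
        a, b = self.values[obs], other.values[obs]
        cont = np.broadcast_to(self.continuous_columns, self.mask.shape)[obs]
        if not np.array_equal(a[~cont], b[~cont]):
            return False
        return bool(np.allclose(a[cont], b[cont], rtol=rtol, atol=0.0))


@dataclass
class ColumnSummary:
    """Per-column missingness and distribution summary."""

    name: str
    type: str
    missing_fraction: float
    n_observed: int
    mean: float | None = None
    median: float | None = None
    level_counts: dict[str, int] | None = None


def _infer_delimiter(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _parses_as_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_table(
    path: str | Path,
    missing_tokens: Iterable[str] = DEFAULT_MISSING_TOKENS,
    type_hints: Mapping[str, str] | None = None,
    max_categories: int = 20,
    delimiter: str | None = None,
) -> Dataset:
    """Read a delimited text table (header row required) into a :class:`Dataset`.

    Cells matching any ``missing_tokens`` entry (after trimming surrounding
    whitespace) are masked.  Columns whose non-missing cells all parse as
    numbers are typed continuous; all other columns are categorical with
    levels in sorted label order.  ``type_hints`` (name -> type) overrides
    inference, e.g. to force an integer-coded column to be categorical.
    ``max_categories`` is accepted for API stability but numeric columns stay
    continuous regardless of their distinct-value count unless hinted.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter=sep))
    if not rows:
        raise TableFormatError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise TableFormatError(f"{path}: duplicate header names {dupes}")
    body = rows[1:]
    if not body:
        raise TableFormatError(f"{path}: no data rows")
    for i, row in enumerate(body):
        if len(row) != len(header):
            raise TableFormatError(
                f"{path}: row {i + 1} has {len(row)} fields, expected {len(header)}"
            )
    tokens = {t.strip() for t in missing_tokens}
    hints = dict(type_hints or {})
    for name in hints:
        if name not in header:
            raise KeyError(f"type hint for unknown column {name!r}")

    n, m = len(body), len(header)
    cells = [[body[i][j].strip() for j in range(m)] for i in range(n)]
    mask = np.array([[c in tokens for c in row] for row in cells], dtype=bool)
    values = np.full((n, m), np.nan)
    col_types: list[str] = []
    cat_levels: list[list[str] | None] = []
    for j, name in enumerate(header):
        observed = [cells[i][j] for i in range(n) if not mask[i, j]]
        numeric = all(_parses_as_number(c) for c in observed) and observed
        ctype = hints.get(name, CONTINUOUS if numeric else CATEGORICAL)
        if ctype not in (CONTINUOUS, CATEGORICAL):
            raise ValueError(f"bad type hint {ctype!r} for column {name!r}")
        if ctype == CONTINUOUS:
            if not numeric:
                bad = next(c for c in observed if not _parses_as_number(c))
                raise TableFormatError(
                    f"{path}: column {name!r} hinted continuous but cell {bad!r} is not numeric"
                )
            for i in range(n):
                if not mask[i, j]:
                    values[i, j] = float(cells[i][j])
            cat_levels.append(None)
        else:
            levels = sorted(set(observed))
            code = {lab: k for k, lab in enumerate(levels)}
            for i in range(n):
                if not mask[i, j]:
                    values[i, j] = code[cells[i][j]]
            cat_levels.append(levels)
        col_types.append(ctype)
    return Dataset(values, mask, header, col_types, cat_levels)


def write_table(
    d: Dataset,
    path: str | Path,
    missing_token: str = "NA",
    delimiter: str | None = None,
) -> None:
    """Write a :class:`Dataset` as delimited text.

    Continuous cells use the shortest float representation that round-trips
    exactly; categorical cells are written as their level labels; masked
    cells become ``missing_token``.
    """
    path = Path(path)
    sep = _infer_delimiter(path, delimiter)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(d.col_names)
        for i in range(d.n_samples):
            row = []
            for j in range(d.n_features):
                if d.mask[i, j]:
                    row.append(missing_token)
                elif d.col_types[j] == CATEGORICAL:
                    row.append(d.cat_levels[j][int(d.values[i, j])])
                else:
                    row.append(repr(float(d.values[i, j])))
            writer.writerow(row)


def missing_rate_summary(d: Dataset) -> list[ColumnSummary]:
    """One :class:`ColumnSummary` per column, in column order.

    ``missing_fraction`` is the exact ratio of masked cells to rows.
    """
    out = []
    for j, name in enumerate(d.col_names):
        col_mask = d.mask[:, j]
        n_missing = int(col_mask.sum())
        n_obs = d.n_samples - n_missing
        obs = d.values[~col_mask, j]
        if d.col_types[j] == CONTINUOUS:
            out.append(
                ColumnSummary(
                    name=name,
                    type=CONTINUOUS,
                    missing_fraction=n_missing / d.n_samples,
                    n_observed=n_obs,
                    mean=float(obs.mean()) if n_obs else None,
                    median=float(np.median(obs)) if n_obs else None,
                )
            )
        else:
            levels = d.cat_levels[j]
            counts = Counter(levels[int(c)] for c in obs)
            out.append(
                ColumnSummary(
                    name=name,
                    type=CATEGORICAL,
                    missing_fraction=n_missing / d.n_samples,
                    n_observed=n_obs,
                    level_counts={lab: counts.get(lab, 0) for lab in levels},
                )
            )
    return out


def filter_by_missingness(d: Dataset, max_fraction: float) -> Dataset:
    """Keep exactly the columns whose missing fraction is <= ``max_fraction``.

    Column order and rows are unchanged.  Removing every column is an error
    (the threshold is too strict for this table).
    """
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError("max_fraction must lie in [0, 1]")
    fractions = d.mask.mean(axis=0)
    keep = [j for j in range(d.n_features) if fractions[j] <= max_fraction]
    if not keep:
        raise ValueError(
            "every column exceeds the missingness threshold "
            f"{max_fraction}; raise the threshold"
        )
    return d.select_columns(keep)


def summaries_to_records(summaries: list[ColumnSummary]) -> list[dict]:
    """Flatten summaries for CSV/JSON serialisation."""
    records = []
    for s in summaries:
        rec = {
            "name": s.name,
            "type": s.type,
            "missing_fraction": s.missing_fraction,
            "n_observed": s.n_observed,
            "mean": s.mean if s.mean is None or math.isfinite(s.mean) else None,
            "median": s.median,
            "level_counts": "" if s.level_counts is None else ";".join(
                f"{k}={v}" for k, v in s.level_counts.items()
            ),
        }
        records.append(rec)
    return records
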