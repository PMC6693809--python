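"""Rectangular datasets with an explicit missingness mask and variable roles.

The :class:`Dataset` is the unit every stage of the pipeline consumes and
produces: a numeric value matrix, a boolean mask (``True`` = missing), and a
declared type and role per column.  Categorical variables are stored
internally as float level codes ``0..K-1``; their string levels only appear
at the CSV boundary.  Cells flagged missing are unreadable through the
public accessors (they come back as NaN), so downstream code cannot
accidentally peek at amputed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

KINDS = ("continuous", "binary", "categorical")
ROLES = ("outcome", "exposure", "confounder", "auxiliary", "id", "latent")


class DatasetError(ValueError):
    """Contract violation on Dataset construction or access."""


@dataclass(frozen=True)
class Column:
    """Declared type and analysis role of one variable.

    ``latent`` columns are generator-internal (e.g. the continuous score
    underlying a dichotomized outcome): missingness mechanisms may read
    them, but they are excluded from analyses and from CSV export.
    """

    name: str
    kind: str = "continuous"
    role: str = "auxiliary"
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise DatasetError(f"unknown column kind {self.kind!r}")
        if self.role not in ROLES:
            raise DatasetError(f"unknown column role {self.role!r}")
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 2:
                raise DatasetError(f"categorical column {self.name!r} needs >= 2 levels")
        elif self.levels is not None:
            raise DatasetError(f"levels only allowed for categorical columns ({self.name!r})")


@dataclass
class Dataset:
    """Value matrix + missingness mask + per-column metadata."""

    columns: list[Column]
    _values: np.ndarray = field(repr=False)
    mask: np.ndarray = field(repr=False)

    def __init__(self, columns: Sequence[Column], values: np.ndarray,
                 mask: np.ndarray | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != len(columns):
            raise DatasetError("values must be an (n, p) array matching columns")
        if mask is None:
            mask = np.zeros(values.shape, dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise DatasetError("mask shape must equal values shape")
        names = [c.name for c in columns]
        if len(set(names)) != len(names):
            raise DatasetError("duplicate column names")
        # binary columns must be 0/1 where observed
        for j, c in enumerate(columns):
            obs = values[:, j][~mask[:, j]]
            obs = obs[~np.isnan(obs)]
            if c.kind == "binary" and obs.size and not np.isin(obs, (0.0, 1.0)).all():
                raise DatasetError(f"binary column {c.name!r} has values outside {{0,1}}")
            if c.kind == "categorical" and obs.size:
                if not np.isin(obs, np.arange(len(c.levels))).all():
                    raise DatasetError(f"categorical column {c.name!r} has codes outside its levels")
        self.columns = list(columns)
        vals = values.copy()
        vals[mask] = np.nan  # masked cells are not retained
        self._values = vals
        self.mask = mask.copy()
        self._index = {c.name: j for j, c in enumerate(self.columns)}

    # ------------------------------------------------------------------ basics
    @property
    def n(self) -> int:
        return self._values.shape[0]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def roles(self) -> dict[str, str]:
        return {c.name: c.role for c in self.columns}

    def column(self, name: str) -> Column:
        try:
            return self.columns[self._index[name]]
        except KeyError:
            raise DatasetError(f"no column named {name!r}") from None

    def values(self, name: str) -> np.ndarray:
        """Observed values of one column; NaN where the mask flags missing."""
        j = self._index[name]
        out = self._values[:, j].copy()
        out[self.mask[:, j]] = np.nan
        return out

    def observed(self, name: str) -> np.ndarray:
        """Boolean vector: True where the value is observed."""
        return ~self.mask[:, self._index[name]]

    def missing_any(self, names: Iterable[str]) -> np.ndarray:
        idx = [self._index[n] for n in names]
        return self.mask[:, idx].any(axis=1)

    def complete_cases(self, names: Iterable[str] | None = None) -> np.ndarray:
        """True for rows fully observed on ``names`` (default: all non-latent)."""
        if names is None:
            names = [c.name for c in self.columns if c.role != "latent"]
        return ~self.missing_any(names)

    # --------------------------------------------------------------- mutation
    def with_mask(self, mask: np.ndarray) -> "Dataset":
        """New Dataset with the given mask; newly-masked values are scrubbed."""
        return Dataset(self.columns, self._values, mask)

    def with_values(self, name: str, values: np.ndarray,
                    mask_col: np.ndarray | None = None) -> "Dataset":
        j = self._index[name]
        vals = self._values.copy()
        vals[:, j] = values
        mask = self.mask.copy()
        if mask_col is not None:
            mask[:, j] = mask_col
        else:
            mask[:, j] = np.isnan(values)
        return Dataset(self.columns, vals, mask)

    def filled(self, name: str, values: np.ndarray) -> "Dataset":
        """Replace the missing cells of ``name`` with ``values`` (imputation)."""
        j = self._index[name]
        miss = self.mask[:, j]
        vals = self._values.copy()
        col = vals[:, j]
        col[miss] = values
        vals[:, j] = col
        mask = self.mask.copy()
        mask[:, j] = False
        return Dataset(self.columns, vals, mask)

    def subset_rows(self, keep: np.ndarray) -> "Dataset":
        return Dataset(self.columns, self._values[keep], self.mask[keep])

    def with_roles(self, roles: Mapping[str, str]) -> "Dataset":
        cols = [replace(c, role=roles.get(c.name, c.role)) for c in self.columns]
        return Dataset(cols, self._values, self.mask)

    # ------------------------------------------------------------- validation
    def check_analysis_roles(self) -> None:
        role_list = [c.role for c in self.columns]
        if role_list.count("outcome") != 1 or role_list.count("exposure") != 1:
            raise DatasetError("an analysis requires exactly one outcome and one exposure role")

    # ------------------------------------------------------------------- i/o
    def to_frame(self, decode: bool = True, include_latent: bool = False) -> pd.DataFrame:
        """Public view as a pandas DataFrame (masked cells are NA)."""
        cols = {}
        for c in self.columns:
            if c.role == "latent" and not include_latent:
                continue
            v = self.values(c.name)
            if decode and c.kind == "categorical":
                s = pd.Series(v).map(
                    {float(i): lev for i, lev in enumerate(c.levels)})
                cols[c.name] = s
            else:
                cols[c.name] = v
        return pd.DataFrame(cols)

    def __eq__(self, other: object) -> bool:  # bitwise equality, used in tests
        if not isinstance(other, Dataset):
            return NotImplemented
        return (self.columns == other.columns
                and np.array_equal(self.mask, other.mask)
                and np.array_equal(self._values, other._values, equal_nan=True))
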