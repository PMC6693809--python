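"""CSV + YAML-sidecar I/O for datasets.

The on-disk convention is deliberately plain: a CSV with a header row where
an empty cell (or a configured sentinel such as ``NA``) means missing, and
a YAML sidecar declaring each column's type, role and — for categoricals —
the ordered level list.  Round-tripping through write/load preserves the
mask and values bit-for-bit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import Column, Dataset, DatasetError

DEFAULT_SENTINELS = ("", "NA")


def roles_sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".roles.yaml")


def write_dataset(data: Dataset, path: str | Path,
                  roles_path: str | Path | None = None) -> None:
    """Write values as CSV (empty cell = missing) plus a roles/types sidecar."""
    path = Path(path)
    frame = data.to_frame(decode=True)
    with np.errstate(all="ignore"):
        frame.to_csv(path, index=False, na_rep="", float_format="%.10g")
    meta = {"columns": {}}
    for c in data.columns:
        if c.role == "latent":
            continue
        entry = {"type": c.kind, "role": c.role}
        if c.levels:
            entry["levels"] = list(c.levels)
        meta["columns"][c.name] = entry
    roles_path = roles_sidecar_path(path) if roles_path is None else Path(roles_path)
    roles_path.write_text(yaml.safe_dump(meta, sort_keys=False))


def load_dataset(path: str | Path, roles_path: str | Path | None = None,
                 sentinels: tuple[str, ...] = DEFAULT_SENTINELS) -> Dataset:
    """Load a CSV + sidecar pair into a Dataset.

    Empty strings and any configured sentinel are parsed as missing.
    Declared types are enforced: a non-numeric entry in a continuous column
    or an undeclared categorical level raises with its row and column.
    """
    path = Path(path)
    roles_path = roles_sidecar_path(path) if roles_path is None else Path(roles_path)
    if not roles_path.exists():
        raise DatasetError(f"roles sidecar not found: {roles_path}")
    meta = yaml.safe_load(roles_path.read_text())
    declared = meta.get("columns", {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = set(declared) - set(raw.columns)
    if unknown:
        raise DatasetError(f"roles file declares unknown columns: {sorted(unknown)}")
    columns: list[Column] = []
    mats, masks = [], []
    sent = set(sentinels)
    for name in raw.columns:
        entry = declared.get(name)
        if entry is None:
            raise DatasetError(f"column {name!r} missing from roles file")
        kind = entry.get("type", "continuous")
        role = entry.get("role", "auxiliary")
        levels = tuple(entry["levels"]) if "levels" in entry else None
        col = Column(name, kind, role, levels)
        cells = raw[name].tolist()
        vals = np.full(len(cells), np.nan)
        mask = np.zeros(len(cells), dtype=bool)
        for i, cell in enumerate(cells):
            s = cell.strip()
            if s in sent:
                mask[i] = True
                continue
            if kind == "categorical":
                if s not in col.levels:
                    raise DatasetError(
                        f"row {i + 2}, column {name!r}: {s!r} is not a declared level")
                vals[i] = col.levels.index(s)
            else:
                try:
                    vals[i] = float(s)
                except ValueError:
                    raise DatasetError(
                        f"row {i + 2}, column {name!r}: {s!r} is not numeric") from None
                if kind == "binary" and vals[i] not in (0.0, 1.0):
                    raise DatasetError(
                        f"row {i + 2}, column {name!r}: binary value must be 0 or 1")
        columns.append(col)
        mats.append(vals)
        masks.append(mask)
    return Dataset(columns, np.column_stack(mats), np.column_stack(masks))
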