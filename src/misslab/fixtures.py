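"""Deterministic synthetic fixtures packaged with the library.

``make_pattern_fixture`` builds a 951-row growth-style dataset whose
missing-data patterns follow a published six-pattern layout exactly
(547 complete; 125 with partially missing confounders; 7 missing the
exposure; 210 missing the outcome; 61 missing the outcome plus some
confounders; 1 missing outcome and exposure).  The *values* are synthetic
draws from the growth generator — only the pattern structure is real —
which is enough to exercise pattern tabulation and CSV round-trips.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np

from .dataset import Dataset
from .synthetic import GrowthParams, generate_growth_cohort

PATTERN_COUNTS = (547, 125, 7, 210, 61, 1)  # six patterns, n = 951
FIXTURE_NAME = "growth_patterns_synthetic.csv"


def make_pattern_fixture(seed: int = 20190316) -> Dataset:
    """Synthetic 951-row dataset carrying the six-pattern missingness layout."""
    n = sum(PATTERN_COUNTS)
    data = generate_growth_cohort(GrowthParams(n=n, seed=seed))
    # keep the printed CSV compact: round values to 2 decimals
    vals = np.round(data._values, 2)
    keep = [c for c in data.columns if c.role != "auxiliary"]
    kidx = [data.names.index(c.name) for c in keep]
    data = Dataset(keep, vals[:, kidx])
    idx = {c.name: j for j, c in enumerate(data.columns)}
    mask = np.zeros((n, len(keep)), dtype=bool)
    b = np.cumsum((0,) + PATTERN_COUNTS)
    rng = np.random.default_rng(seed)
    confs = ["maternal_weight", "paternal_weight", "ses"]

    def mix_confounders(rows: np.ndarray) -> None:
        # some-but-not-all confounders missing per row
        for i in rows:
            k = rng.integers(1, len(confs))        # 1 or 2 of the 3
            for name in rng.choice(confs, size=k, replace=False):
                mask[i, idx[name]] = True

    mix_confounders(np.arange(b[1], b[2]))                      # pattern 2
    mask[b[2]:b[3], idx["weight_5"]] = True                     # pattern 3
    mask[b[3]:b[4], idx["adult_bmi"]] = True                    # pattern 4
    mask[b[4]:b[5], idx["adult_bmi"]] = True                    # pattern 5
    mix_confounders(np.arange(b[4], b[5]))
    mask[b[5]:b[6], idx["adult_bmi"]] = True                    # pattern 6
    mask[b[5]:b[6], idx["weight_5"]] = True
    return data.with_mask(mask)


def pattern_fixture_path() -> Path:
    """Path of the packaged fixture CSV (sidecar sits next to it)."""
    return Path(resources.files("misslab") / "data" / FIXTURE_NAME)


def write_pattern_fixture(directory: str | Path, seed: int = 20190316) -> Path:
    from .io import write_dataset
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / FIXTURE_NAME
    write_dataset(make_pattern_fixture(seed), out)
    return out
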