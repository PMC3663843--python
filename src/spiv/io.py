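"""Cohort CSV dialect and config serialisation.

The cohort CSV has a header row with columns, in order: ``id``, ``y``,
``xt_raw``, ``month``, the 13 environmental covariates, and the 20
genotype dosage columns ``snp01``..``snp20``.  Values are validated on
read (no missing values, y in {0,1}, dosages in {0,1,2}, months 1-12).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COVARIATE_NAMES, SNP_COLUMNS

__all__ = ["write_cohort_csv", "load_cohort_csv"]

_REQUIRED = ("id", "y", "xt_raw", "month") + COVARIATE_NAMES + SNP_COLUMNS


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cols = [c for c in _REQUIRED if c in cohort.columns]
    cohort[cols].to_csv(path, index=False)


def load_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Raises ``ValueError`` naming the offending column (and row, for cell
    level problems) on any dialect violation.
    """
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"cohort file {path} is empty") from None
    if table.empty:
        raise ValueError(f"cohort file {path} contains no rows")
    missing = [c for c in _REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"cohort file {path} lacks column(s): {missing}")
    for col in _REQUIRED:
        nulls = table[col].isna()
        if nulls.any():
            raise ValueError(
                f"missing value in column {col!r}, row {int(nulls.idxmax())}"
            )
    y = table["y"].to_numpy()
    if not np.isin(y, (0, 1)).all():
        bad = int(np.flatnonzero(~np.isin(y, (0, 1)))[0])
        raise ValueError(f"outcome y must be 0/1; row {bad} has {y[bad]!r}")
    months = table["month"].to_numpy()
    if ((months < 1) | (months > 12)).any():
        bad = int(np.flatnonzero((months < 1) | (months > 12))[0])
        raise ValueError(f"month outside 1..12 in row {bad}")
    for snp in SNP_COLUMNS:
        dosages = table[snp].to_numpy()
        ok = np.isin(dosages, (0, 1, 2))
        if not ok.all():
            bad = int(np.flatnonzero(~ok)[0])
            raise ValueError(
                f"dosage outside {{0,1,2}} in column {snp!r}, row {bad} "
                f"(value {dosages[bad]!r})"
            )
    return table
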