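"""Label-free intensity preprocessing: filtering, imputation, normalization.

The pipeline applied to protein and PTM-site intensity matrices is

1. keep features with at least two valid values overall *and* a valid
   fraction of at least 50% in at least one condition group;
2. impute missing cells with the feature's group mean where the group is
   at least half observed, and with half of the global minimum observed
   intensity otherwise;
3. scale each sample to a common median, take log2, and shift every cell
   by ``10 + |min(log2 matrix)|`` so all values are positive.

All imputation statistics are computed from observed values only, before
any cell is filled, so imputed values never feed later imputations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import InputError, OmicsMatrix


def valid_feature_mask(
    present: pd.DataFrame,
    design: pd.Series,
    min_valid_total: int = 2,
    min_group_frac: float = 0.5,
) -> pd.Series:
    """Boolean keep-mask implementing the two filtering clauses.

    ``present`` is a boolean feature x sample frame (True = observed).
    A feature is kept iff its total observed count is >= ``min_valid_total``
    and at least one condition group is observed at a fraction >=
    ``min_group_frac`` (inclusive at the boundary).
    """
    total_ok = present.sum(axis=1) >= min_valid_total
    group_ok = pd.Series(False, index=present.index)
    for cond in design.unique():
        cols = design.index[design == cond]
        frac = present[cols].sum(axis=1) / len(cols)
        group_ok |= frac >= min_group_frac
    return total_ok & group_ok


def filter_features(
    matrix: OmicsMatrix,
    min_valid_total: int = 2,
    min_group_frac: float = 0.5,
) -> OmicsMatrix:
    """Drop features failing the valid-value rules; feature order is preserved."""
    keep = valid_feature_mask(matrix.mask_missing(), matrix.design, min_valid_total, min_group_frac)
    return matrix.with_values(matrix.values.loc[keep])


def impute(matrix: OmicsMatrix, min_group_frac: float = 0.5) -> OmicsMatrix:
    """Two-tier imputation: group means, then half the global minimum.

    A missing cell whose condition group is observed at >= ``min_group_frac``
    receives that feature's mean of the group's observed values; every other
    missing cell receives half the minimum observed value of the whole matrix.
    """
    values = matrix.values.copy()
    observed = values.notna()
    if observed.to_numpy().all():
        return matrix.with_values(values)
    all_obs = values.to_numpy()[observed.to_numpy()]
    if all_obs.size == 0:
        raise InputError("cannot impute a matrix with no observed values")
    half_min = float(np.min(all_obs)) / 2.0

    filled = values.copy()
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        block = values[cols]
        frac = observed[cols].sum(axis=1) / len(cols)
        group_mean = block.mean(axis=1, skipna=True)
        eligible = frac >= min_group_frac
        for col in cols:
            need = values[col].isna() & eligible
            filled.loc[need, col] = group_mean[need]
    filled = filled.fillna(half_min)
    return matrix.with_values(filled)


def normalize_and_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """Median-normalize per sample, log2-transform, and shift positive.

    Each column is scaled multiplicatively so its median equals the global
    median of the pre-normalization column medians; the shift adds
    ``10 + |min(log2 matrix)|`` to every cell.  Requires a complete,
    strictly positive matrix.
    """
    values = matrix.values
    arr = values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise InputError("normalize_and_transform requires a complete matrix; impute first")
    if (arr <= 0).any():
        i, j = np.argwhere(arr <= 0)[0]
        raise InputError(
            f"nonpositive value {arr[i, j]!r} at feature {values.index[i]!r}, "
            f"sample {values.columns[j]!r}: cannot log2-transform"
        )
    col_medians = np.median(arr, axis=0)
    target = np.median(col_medians)
    scaled = arr * (target / col_medians)
    logged = np.log2(scaled)
    shifted = logged + 10.0 + abs(logged.min())
    out = pd.DataFrame(shifted, index=values.index, columns=values.columns)
    return matrix.with_values(out)


def preprocess(
    matrix: OmicsMatrix,
    min_valid_total: int = 2,
    min_group_frac: float = 0.5,
) -> OmicsMatrix:
    """Full filter -> impute -> normalize/transform chain for intensity layers."""
    m = filter_features(matrix, min_valid_total, min_group_frac)
    m = impute(m, min_group_frac)
    return normalize_and_transform(m)
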