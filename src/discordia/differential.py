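"""Per-contrast fold changes, Welch tests, BH adjustment, significance calls.

A contrast is an ordered pair ``(B, A)`` read as "B versus A": positive
log2 fold changes mean higher abundance in B.  The RNA layer works on raw
TPM with a pseudocount (``log2((mean_B + 1) / (mean_A + 1))``); intensity
layers are assumed already log2-scale after preprocessing, so the fold
change is a difference of group means.

The per-feature test is a Welch two-sample t-test on the log-scale values.
Differential-expression calling deliberately stays simple and swappable:
the thresholds that define significance live in :class:`ThresholdPolicy`,
with layer defaults of |log2FC| > 1.5 at adjusted p < 0.01 for RNA and
|log2FC| > 1.2 at raw p < 0.05 for protein and PTM-site layers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import InputError, OmicsMatrix

Contrast = tuple[str, str]  # (B, A) meaning B vs A

_ZERO_VAR_TOL = 1e-12


@dataclass(frozen=True)
class ThresholdPolicy:
    """Layer-specific significance rule: |log2FC| > fc_cut and p < p_cut."""

    layer: str
    fc_cut: float
    p_cut: float
    use_adjusted: bool

    def __post_init__(self) -> None:
        if self.fc_cut <= 0:
            raise InputError("fc_cut must be positive")
        if not 0 < self.p_cut < 1:
            raise InputError("p_cut must be in (0, 1)")


DEFAULT_POLICIES: dict[str, ThresholdPolicy] = {
    "rna": ThresholdPolicy("rna", fc_cut=1.5, p_cut=0.01, use_adjusted=True),
    "protein": ThresholdPolicy("protein", fc_cut=1.2, p_cut=0.05, use_adjusted=False),
    "phospho": ThresholdPolicy("phospho", fc_cut=1.2, p_cut=0.05, use_adjusted=False),
    "acetyl": ThresholdPolicy("acetyl", fc_cut=1.2, p_cut=0.05, use_adjusted=False),
}


def _contrast_blocks(matrix: OmicsMatrix, contrast: Contrast, min_reps: int = 2):
    cond_b, cond_a = contrast
    for cond in (cond_b, cond_a):
        if cond not in set(matrix.design):
            raise InputError(f"condition {cond!r} absent from design")
    b = matrix.values[matrix.samples_of(cond_b)]
    a = matrix.values[matrix.samples_of(cond_a)]
    if b.shape[1] < min_reps or a.shape[1] < min_reps:
        raise InputError(f"contrast {cond_b} vs {cond_a} needs >= {min_reps} replicates per group")
    return b, a


def contrast_log2fc(matrix: OmicsMatrix, contrast: Contrast, pseudocount: float = 1.0) -> pd.Series:
    """Per-feature log2 fold change for ``contrast = (B, A)``.

    RNA: ``log2((mean TPM_B + pseudocount) / (mean TPM_A + pseudocount))``.
    Other layers (already log2 after prep): difference of group means.
    """
    b, a = _contrast_blocks(matrix, contrast)
    mean_b = b.mean(axis=1, skipna=True)
    mean_a = a.mean(axis=1, skipna=True)
    if matrix.layer == "rna":
        fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    else:
        fc = mean_b - mean_a
    fc.name = "log2fc"
    return fc


def contrast_test(matrix: OmicsMatrix, contrast: Contrast) -> pd.Series:
    """Welch t-test p-value per feature, on log2 scale for the RNA layer.

    Degenerate features (zero variance in both groups) get p = 1 when the
    group means coincide and p -> 0 when they differ: with no replicate
    scatter any nonzero shift is, in the limit, infinitely many standard
    errors away from zero.
    """
    b, a = _contrast_blocks(matrix, contrast)
    xb, xa = b.to_numpy(dtype=float), a.to_numpy(dtype=float)
    if matrix.layer == "rna":
        xb, xa = np.log2(xb + 1.0), np.log2(xa + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant features trip scipy's precision-loss warning; the
        # degenerate branch below overrides those p-values anyway
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(xb, xa, axis=1, equal_var=False, nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
    var_b = np.nanvar(xb, axis=1)
    var_a = np.nanvar(xa, axis=1)
    degenerate = (var_b < _ZERO_VAR_TOL) & (var_a < _ZERO_VAR_TOL)
    mean_diff = np.nanmean(xb, axis=1) - np.nanmean(xa, axis=1)
    p = np.where(degenerate, np.where(np.abs(mean_diff) < 1e-9, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=matrix.feature_ids, name="p_raw")


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise InputError("adjust_bh expects a 1-d array of p-values")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise InputError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downward
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def flag_significance(results: pd.DataFrame, policy: ThresholdPolicy) -> pd.DataFrame:
    """Add ``significant`` and ``direction`` columns under a threshold policy."""
    out = results.copy()
    p = out["p_adj"] if policy.use_adjusted else out["p_raw"]
    out["significant"] = (out["log2fc"].abs() > policy.fc_cut) & (p < policy.p_cut)
    out["direction"] = np.where(
        out["significant"], np.where(out["log2fc"] > 0, "up", "down"), "none"
    )
    return out


def run_contrast(
    matrix: OmicsMatrix,
    contrast: Contrast,
    policy: ThresholdPolicy | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-feature contrast table: log2fc, p_raw, p_adj, significance."""
    if policy is None:
        policy = DEFAULT_POLICIES[matrix.layer]
    fc = contrast_log2fc(matrix, contrast, pseudocount)
    p_raw = contrast_test(matrix, contrast)
    table = pd.DataFrame({"log2fc": fc, "p_raw": p_raw})
    table["p_adj"] = adjust_bh(table["p_raw"].to_numpy())
    table = flag_significance(table, policy)
    table.insert(0, "contrast", f"{contrast[0]}vs{contrast[1]}")
    table.index.name = "feature_id"
    return table
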