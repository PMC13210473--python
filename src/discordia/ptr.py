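"""Protein-to-RNA ratio (PTR) computation, MAD dispersion, stratification.

PTR for a gene in a condition is ``log2(protein abundance) - log2(TPM + 1)``
where the protein abundance is already on the transformed log2 scale from
preprocessing, so it enters directly.  Dispersion of RNA, protein, and PTR
distributions is summarized with the unscaled median absolute deviation
``MAD = median(|x_i - median(x)|)`` (no 1.4826 consistency factor).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import InputError, OmicsMatrix


def compute_ptr(
    rna: OmicsMatrix,
    protein: OmicsMatrix,
    condition: str,
    id_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene PTR records for one condition.

    ``id_map`` maps protein ids to gene ids (identity when omitted).
    Returns a frame indexed by gene id with columns ``rna_log`` (condition
    mean of log2(TPM+1)), ``prot_log`` (condition mean of the transformed
    intensity) and ``ptr = prot_log - rna_log``.
    """
    rna_mean = rna.values[rna.samples_of(condition)].mean(axis=1, skipna=True)
    rna_log = np.log2(rna_mean + 1.0)
    prot_mean = protein.values[protein.samples_of(condition)].mean(axis=1, skipna=True)
    if id_map is not None:
        prot_mean = prot_mean.rename(index=id_map.to_dict())
        prot_mean = prot_mean[~prot_mean.index.duplicated()]
    shared = rna_log.index.intersection(prot_mean.index)
    if len(shared) == 0:
        raise InputError("no genes quantified in both RNA and protein layers")
    out = pd.DataFrame(
        {
            "rna_log": rna_log.loc[shared],
            "prot_log": prot_mean.loc[shared],
        }
    )
    out["ptr"] = out["prot_log"] - out["rna_log"]
    out = out.dropna()
    out.index.name = "gene_id"
    return out


def mad(values) -> float:
    """Unscaled median absolute deviation: median(|x_i - median(x)|)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise InputError("mad requires at least one finite value")
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


def dispersion_summary(ptr_records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Median and MAD of the RNA, protein, and PTR distributions."""
    rows = []
    for layer, col in (("rna", "rna_log"), ("protein", "prot_log"), ("ptr", "ptr")):
        vals = ptr_records[col].to_numpy()
        rows.append(
            {
                "condition": condition,
                "layer": layer,
                "median": float(np.median(vals)),
                "mad": mad(vals),
            }
        )
    return pd.DataFrame(rows)


def stratify_ptr(
    ptr_records: pd.DataFrame,
    high_k: float = 2.0,
    low_frac: float = 0.25,
) -> tuple[pd.Index, pd.Index]:
    """High/low PTR gene sets for one condition.

    High: ``ptr > median + high_k * MAD``.  Low: the ``floor(low_frac * n)``
    genes with the smallest PTR, ties broken deterministically by gene id.
    """
    n = len(ptr_records)
    if n < 4:
        raise InputError("stratification needs at least 4 PTR records")
    ptr = ptr_records["ptr"]
    threshold = float(ptr.median()) + high_k * mad(ptr)
    high = ptr.index[ptr > threshold]
    k = int(np.floor(low_frac * n))
    ordered = ptr.to_frame().assign(_gene=ptr.index).sort_values(["ptr", "_gene"])
    low = pd.Index(ordered.index[:k])
    return high, low


def compare_ptr_distributions(records_by_condition: dict[str, pd.DataFrame]):
    """Kruskal-Wallis rank test of PTR distributions across conditions.

    Returns ``(H, p)``; identical-in-every-group degenerate input (all ranks
    tied) yields ``H = 0, p = 1``.
    """
    if len(records_by_condition) < 2:
        raise InputError("need at least two conditions to compare")
    groups = []
    for cond, rec in records_by_condition.items():
        vals = rec["ptr"].to_numpy(dtype=float)
        if vals.size < 2:
            raise InputError(f"condition {cond!r} has fewer than 2 PTR records")
        groups.append(vals)
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)
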