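"""Gene-protein discordance classification and PTM-residual correlation.

The central question: when a gene's protein change disagrees with its RNA
change across a treatment contrast, is the disagreement associated with
post-translational modification (PTM) changes?  Three pieces answer it:

* a four-way classification of each quantified gene-protein pair into
  translation-dominant, transcription-dominant, inconsistent, or stable,
  from the contrast log2 fold changes (dRNA, dProtein) and the layer
  significance calls;
* a per-contrast ordinary least squares fit ``dProtein = b0 + b1*dRNA + e``
  over all quantified pairs, whose residuals capture protein change not
  explained by RNA change;
* Spearman rank correlation of those residuals with site-level PTM changes
  (each site paired with its gene's residual) and with protein-level PTM
  summaries (the median of a protein's site deltas per modification type).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import InputError

CATEGORIES = ("translation_dominant", "transcription_dominant", "inconsistent", "stable", "NA")

EXACT_PERM_MAX_N = 10


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def classify_pair(
    delta_rna: float,
    rna_significant: bool,
    delta_protein: float,
    protein_significant: bool,
    rna_missing: bool = False,
    protein_missing: bool = False,
) -> str:
    """Category of one gene-protein pair for one contrast.

    Rules, evaluated in order:

    0. either layer unquantified -> ``NA``;
    1. opposite-signed changes with at least one layer significant
       -> ``inconsistent``;
    2. |dProtein| >= 2|dRNA| and the protein change significant
       -> ``translation_dominant``;
    3. |dRNA| >= 2|dProtein| and the RNA change significant
       -> ``transcription_dominant``;
    4. otherwise -> ``stable``.

    A zero delta carries no sign, so zero-vs-nonzero pairs are never
    inconsistent.  Opposite signs take precedence over the dominance
    clauses: a pair moving in opposite directions is discordant regardless
    of which magnitude dominates.
    """
    if rna_missing or protein_missing:
        return "NA"
    opposite = delta_rna * delta_protein < 0
    if opposite and (rna_significant or protein_significant):
        return "inconsistent"
    if abs(delta_protein) >= 2.0 * abs(delta_rna) and protein_significant:
        return "translation_dominant"
    if abs(delta_rna) >= 2.0 * abs(delta_protein) and rna_significant:
        return "transcription_dominant"
    return "stable"


def classify_table(
    rna_contrast: pd.DataFrame,
    protein_contrast: pd.DataFrame,
    id_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Classify every gene with a contrast row in either layer.

    ``rna_contrast`` / ``protein_contrast`` are per-feature tables from
    :func:`discordia.differential.run_contrast`; ``id_map`` maps protein ids
    to gene ids (identity when omitted).  Genes quantified in only one layer
    get category ``NA``.
    """
    prot = protein_contrast.copy()
    if id_map is not None:
        prot = prot.rename(index=id_map.to_dict())
        prot = prot[~prot.index.duplicated()]
    genes = rna_contrast.index.union(prot.index)
    rows = []
    for gene in genes:
        in_rna = gene in rna_contrast.index
        in_prot = gene in prot.index
        d_rna = float(rna_contrast.at[gene, "log2fc"]) if in_rna else np.nan
        d_prot = float(prot.at[gene, "log2fc"]) if in_prot else np.nan
        sig_rna = bool(rna_contrast.at[gene, "significant"]) if in_rna else False
        sig_prot = bool(prot.at[gene, "significant"]) if in_prot else False
        rows.append(
            {
                "gene_id": gene,
                "delta_rna": d_rna,
                "rna_significant": sig_rna,
                "delta_protein": d_prot,
                "protein_significant": sig_prot,
                "category": classify_pair(
                    d_rna, sig_rna, d_prot, sig_prot,
                    rna_missing=not in_rna, protein_missing=not in_prot,
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def category_counts(calls: pd.DataFrame) -> pd.Series:
    """Counts per category over all classified pairs (fixed category order)."""
    counts = calls["category"].value_counts()
    return pd.Series({c: int(counts.get(c, 0)) for c in CATEGORIES})


def inconsistent_percentages(calls: pd.DataFrame) -> dict[str, float]:
    """Share of inconsistent pairs under two denominators.

    ``of_quantified``: all pairs quantified in both layers (NA excluded);
    ``of_changed``: only pairs in the three non-stable change categories.
    """
    counts = category_counts(calls)
    n_inc = counts["inconsistent"]
    quantified = counts.drop("NA").sum()
    changed = counts[["translation_dominant", "transcription_dominant", "inconsistent"]].sum()
    return {
        "of_quantified": 100.0 * n_inc / quantified if quantified else float("nan"),
        "of_changed": 100.0 * n_inc / changed if changed else float("nan"),
    }


# ---------------------------------------------------------------------------
# 4-set layer overlap (Venn regions)
# ---------------------------------------------------------------------------

def layer_overlap(sets_by_layer: dict[str, set]) -> dict[frozenset, int]:
    """Counts for every region of the partition induced by the layer sets.

    Keys are frozensets naming the layers containing the region's elements
    (the empty-key region is omitted); region counts sum to the union size.
    """
    layers = list(sets_by_layer)
    universe = set().union(*sets_by_layer.values()) if sets_by_layer else set()
    regions: dict[frozenset, int] = {}
    for element in universe:
        key = frozenset(l for l in layers if element in sets_by_layer[l])
        regions[key] = regions.get(key, 0) + 1
    return regions


# ---------------------------------------------------------------------------
# residual regression
# ---------------------------------------------------------------------------

def fit_residuals(pairs: pd.DataFrame) -> tuple[float, float, pd.Series]:
    """OLS fit of ``delta_protein ~ delta_rna`` with intercept.

    ``pairs`` needs columns ``delta_rna`` and ``delta_protein``; rows with a
    missing delta are dropped.  Returns ``(b0, b1, residuals)`` where the
    residual of gene g is ``delta_protein_g - (b0 + b1 * delta_rna_g)``.
    """
    df = pairs[["delta_rna", "delta_protein"]].dropna()
    if len(df) < 3:
        raise InputError("need at least 3 quantified pairs to fit the residual model")
    x = df["delta_rna"].to_numpy(dtype=float)
    y = df["delta_protein"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise InputError("delta_rna has zero variance; slope is unidentifiable")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    b0, b1 = float(coef[0]), float(coef[1])
    residuals = pd.Series(y - (b0 + b1 * x), index=df.index, name="residual")
    return b0, b1, residuals


# ---------------------------------------------------------------------------
# Spearman correlation (average-rank ties; exact permutation at small n)
# ---------------------------------------------------------------------------

def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    rho is the Pearson correlation of average ranks.  The p-value uses the
    t approximation for n > 10 and an exact permutation distribution (all
    n! orderings of one variable) for n <= 10, where the approximation is
    unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("spearman expects two equal-length 1-d arrays")
    n = x.size
    if n < 3:
        raise InputError("spearman needs at least 3 pairs")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan"), float("nan")
    rho = _pearson(rx, ry)
    if n <= EXACT_PERM_MAX_N:
        p = _exact_perm_p(rx, ry, rho)
    else:
        rho_c = min(max(rho, -1.0), 1.0)
        if abs(rho_c) == 1.0:
            p = 0.0
        else:
            t = rho_c * np.sqrt((n - 2) / (1.0 - rho_c**2))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return float(rho), p


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    return float((a @ b) / np.sqrt((a @ a) * (b @ b)))


def _exact_perm_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p over all orderings of one rank vector."""
    n = rx.size
    a = rx - rx.mean()
    norm_a = np.sqrt(a @ a)
    b = ry - ry.mean()
    norm_b = np.sqrt(b @ b)
    thresh = abs(rho_obs) - 1e-12
    count = 0
    total = 0
    chunk: list[tuple] = []
    chunk_size = 50000
    for perm in permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == chunk_size:
            count += _count_extreme(a, b, np.array(chunk), norm_a, norm_b, thresh)
            total += len(chunk)
            chunk = []
    if chunk:
        count += _count_extreme(a, b, np.array(chunk), norm_a, norm_b, thresh)
        total += len(chunk)
    return count / total


def _count_extreme(a, b, perm_idx, norm_a, norm_b, thresh) -> int:
    rhos = (b[perm_idx] @ a) / (norm_a * norm_b)
    return int(np.count_nonzero(np.abs(rhos) >= thresh))


# ---------------------------------------------------------------------------
# PTM deltas vs residuals
# ---------------------------------------------------------------------------

def aggregate_ptm_to_protein(site_deltas: pd.DataFrame) -> pd.DataFrame:
    """Median site-level delta per (protein, modification type, contrast).

    ``site_deltas`` needs columns ``protein_id``, ``gene_id``, ``mod_type``,
    ``contrast``, ``delta_ptm``; the summary column is ``dptm_pro``.
    """
    grouped = (
        site_deltas.groupby(["protein_id", "gene_id", "mod_type", "contrast"], sort=True)[
            "delta_ptm"
        ]
        .median()
        .reset_index()
        .rename(columns={"delta_ptm": "dptm_pro"})
    )
    return grouped


def _correlation_report(level, mod_type, contrast, deltas, residuals_for) -> dict:
    matched = deltas.assign(residual=deltas["gene_id"].map(residuals_for)).dropna(
        subset=["residual"]
    )
    n = len(matched)
    if n < 3:
        return {
            "level": level, "mod_type": mod_type, "contrast": contrast,
            "rho": float("nan"), "p": float("nan"), "n": n,
        }
    value_col = "delta_ptm" if level == "site" else "dptm_pro"
    rho, p = spearman(matched[value_col].to_numpy(), matched["residual"].to_numpy())
    return {"level": level, "mod_type": mod_type, "contrast": contrast, "rho": rho, "p": p, "n": n}


def site_level_correlation(
    residuals: pd.Series,
    site_deltas: pd.DataFrame,
    mod_type: str,
    contrast: str,
) -> dict:
    """Spearman correlation of site PTM deltas with their genes' residuals.

    ``residuals`` is indexed by gene id; a gene's residual is reused for
    each of its sites (unweighted duplication).
    """
    sel = site_deltas[(site_deltas["mod_type"] == mod_type) & (site_deltas["contrast"] == contrast)]
    return _correlation_report("site", mod_type, contrast, sel, residuals)


def protein_level_correlation(
    residuals: pd.Series,
    protein_deltas: pd.DataFrame,
    mod_type: str,
    contrast: str,
) -> dict:
    """Spearman correlation of per-protein median PTM deltas with residuals."""
    sel = protein_deltas[
        (protein_deltas["mod_type"] == mod_type) & (protein_deltas["contrast"] == contrast)
    ]
    return _correlation_report("protein", mod_type, contrast, sel, residuals)
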