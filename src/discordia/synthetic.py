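"""Coupled RNA / protein / PTM-site simulator with ground truth.

The generator emulates a three-condition (control CK, drought DT,
rewatered DTR) design with replicated measurements of four layers:

* RNA as TPM-like nonnegative values, built from per-gene log2(TPM+1)
  trajectories;
* protein intensities, log-normal, coupled to RNA through a global linear
  model ``dProtein = b0 + b1*dRNA + s + gamma*dPTM_pro + noise`` where the
  structured offset ``s`` places each gene in a target discordance
  category (translation-dominant, transcription-dominant, inconsistent,
  stable) for each contrast;
* phospho and acetyl site intensities attached to a subset of detected
  proteins, with a site-multiplicity distribution matching typical
  phosphoproteome surveys (~46% single-site proteins) and per-site,
  per-contrast log2 changes drawn independently;
* missingness on the intensity layers: uniform missing-completely-at-random
  plus a logistic intensity-dependent (missing-not-at-random) dropout.

Ground truth records, for every gene and contrast, the noiseless deltas
and the discordance category implied by them, and for every site its true
delta; the protein-level PTM effect injected into ``dProtein`` is the
median of the protein's site deltas, so protein-level aggregation
downstream recovers it exactly.

Each layer draws from its own RNG stream spawned from the master seed, so
adding or removing a layer never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import OmicsMatrix
from .clustering import ARCHETYPES, _standardize_rows
from .discordance import classify_pair

CONTRASTS = (("DT", "CK"), ("DTR", "DT"))


class ConfigurationError(ValueError):
    """Raised when a SynthConfig violates its invariants."""


@dataclass
class SynthConfig:
    """Generative parameters for one synthetic multi-omics dataset.

    Category fractions follow the quantified-pair composition of a drought
    time-course proteogenomics experiment (roughly 13% translation-dominant,
    43% transcription-dominant, 32% inconsistent, 12% stable).  Noise SDs
    are on the log2 scale.  ``site_multiplicity_probs[k]`` is the
    probability a PTM-carrying protein has k+1 sites (single-site 46%,
    two-site 21%).
    """

    n_genes: int = 2000
    protein_detect_frac: float = 0.7
    conditions: tuple[str, ...] = ("CK", "DT", "DTR")
    n_reps: int = 3
    frac_transcription_dominant: float = 0.43
    frac_translation_dominant: float = 0.13
    frac_inconsistent: float = 0.32
    frac_stable: float = 0.12
    beta0: float = 0.0
    beta1: float = 0.4
    gamma_phos: float = 0.3
    gamma_acet: float = 0.35
    sigma_rna: float = 0.15
    sigma_prot: float = 0.2
    sigma_ptm: float = 0.25
    missing_mcar_rate: float = 0.02
    mnar_logistic_midpoint: float = 13.0
    mnar_logistic_slope: float = 1.0
    site_multiplicity_probs: tuple[float, ...] = (0.46, 0.21, 0.12, 0.08, 0.07, 0.06)
    ptm_carrier_frac: float = 0.4
    site_delta_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be nonnegative")
        if not 0 < self.protein_detect_frac <= 1:
            raise ConfigurationError("protein_detect_frac must be in (0, 1]")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2 (group means need replicates)")
        fracs = (
            self.frac_transcription_dominant,
            self.frac_translation_dominant,
            self.frac_inconsistent,
            self.frac_stable,
        )
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigurationError("category fractions must be nonnegative and sum to 1")
        for name in ("sigma_rna", "sigma_prot", "sigma_ptm", "site_delta_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.missing_mcar_rate <= 1:
            raise ConfigurationError("missing_mcar_rate must be in [0, 1]")
        probs = self.site_multiplicity_probs
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError("site_multiplicity_probs must be probabilities summing to 1")
        if not 0 <= self.ptm_carrier_frac <= 1:
            raise ConfigurationError("ptm_carrier_frac must be in [0, 1]")


@dataclass
class SynthDataset:
    """One generated dataset: four layers, design, site map, and truth."""

    rna: OmicsMatrix
    protein: OmicsMatrix
    phospho: OmicsMatrix
    acetyl: OmicsMatrix
    design: pd.Series
    metadata: pd.DataFrame
    site_map: pd.DataFrame
    gene_truth: pd.DataFrame = field(repr=False)
    site_truth: pd.DataFrame = field(repr=False)
    config: SynthConfig = field(repr=False, default=None)


_CATEGORY_ORDER = ("transcription_dominant", "translation_dominant", "inconsistent", "stable")


def _draw_structured_deltas(rng: np.random.Generator, category: str, b0: float, b1: float):
    """(delta_rna, base delta_protein) realizing a target category.

    The draws keep a margin of at least ~0.27 log2 units between every
    delta and the nearest decision boundary (the 1.5/1.2 fold-change cuts,
    the x2 dominance ratio, and the zero-crossing that defines opposite
    signs), so the small global shift that per-sample median normalization
    introduces on the protein scale cannot flip a noiseless category.
    """
    sign = rng.choice([-1.0, 1.0])
    if category == "stable":
        d_rna = sign * rng.uniform(0.1, 0.9)
        d_prot = b0 + b1 * d_rna
    elif category == "transcription_dominant":
        d_rna = sign * rng.uniform(1.8, 3.5)
        d_prot = d_rna * rng.uniform(0.15, 0.3)
    elif category == "translation_dominant":
        d_prot = sign * rng.uniform(1.6, 3.5)
        d_rna = d_prot * rng.uniform(0.0, 0.4)
    elif category == "inconsistent":
        d_rna = sign * rng.uniform(1.8, 3.0)
        d_prot = -sign * rng.uniform(0.3, 1.05)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown category {category!r}")
    return d_rna, d_prot


def _truth_category(d_rna: float, d_prot: float, detected: bool) -> str:
    """Category implied by noiseless deltas under the standard thresholds."""
    return classify_pair(
        d_rna, abs(d_rna) > 1.5, d_prot, abs(d_prot) > 1.2, protein_missing=not detected
    )


def _nearest_archetype(profile: np.ndarray) -> str:
    arch = _standardize_rows(np.array(list(ARCHETYPES.values()), dtype=float))
    sd = profile.std(ddof=0)
    if sd == 0:
        return "flat"
    z = (profile - profile.mean()) / sd
    d = ((arch - z) ** 2).sum(axis=1)
    return list(ARCHETYPES)[int(np.argmin(d))]


def _make_sites(rng, proteins, gene_of, probs, mod_type, site_delta_sd):
    """Site table + true per-contrast deltas for one modification type."""
    multiplicities = rng.choice(np.arange(1, len(probs) + 1), size=len(proteins), p=probs)
    rows = []
    for prot, k in zip(proteins, multiplicities):
        positions = np.sort(rng.choice(np.arange(1, 1200), size=k, replace=False))
        for j, pos in enumerate(positions):
            if mod_type == "phos":
                residue = rng.choice(["S", "T", "Y"], p=[0.80, 0.15, 0.05])
            else:
                residue = "K"
            rows.append(
                {
                    "site_id": f"{prot}_{mod_type}_{j + 1}",
                    "protein_id": prot,
                    "gene_id": gene_of[prot],
                    "residue": residue,
                    "position": int(pos),
                    "mod_type": mod_type,
                }
            )
    site_map = pd.DataFrame(rows, columns=["site_id", "protein_id", "gene_id", "residue", "position", "mod_type"])
    deltas = rng.normal(0.0, site_delta_sd, size=(len(site_map), len(CONTRASTS)))
    return site_map, deltas


def _apply_missingness(rng, raw: np.ndarray, latent_log2: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """MCAR + intensity-dependent logistic dropout; returns raw with NaNs."""
    out = raw.copy()
    drop = rng.random(raw.shape) < cfg.missing_mcar_rate
    if cfg.mnar_logistic_slope != 0:
        p_mnar = 1.0 / (1.0 + np.exp(cfg.mnar_logistic_slope * (latent_log2 - cfg.mnar_logistic_midpoint)))
        drop |= rng.random(raw.shape) < p_mnar
    out[drop] = np.nan
    return out


def generate_multiomics(config: SynthConfig) -> SynthDataset:
    """Generate one dataset; identical config (incl. seed) => identical output."""
    cfg = config
    streams = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_assign, rng_rna, rng_prot, rng_phos, rng_acet, rng_miss = (
        np.random.default_rng(s) for s in streams
    )

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    conditions = list(cfg.conditions)
    samples = [f"{c}_{r + 1}" for c in conditions for r in range(cfg.n_reps)]
    design = pd.Series(
        [c for c in conditions for _ in range(cfg.n_reps)], index=samples, name="condition"
    )
    metadata = pd.DataFrame(
        {
            "sample_id": samples,
            "condition": design.values,
            "replicate": [r + 1 for _ in conditions for r in range(cfg.n_reps)],
        }
    )

    # --- per-gene category targets and structured deltas per contrast ----
    fracs = np.array(
        [
            cfg.frac_transcription_dominant,
            cfg.frac_translation_dominant,
            cfg.frac_inconsistent,
            cfg.frac_stable,
        ]
    )
    target_cat = rng_assign.choice(_CATEGORY_ORDER, size=(cfg.n_genes, len(CONTRASTS)), p=fracs)
    d_rna = np.zeros((cfg.n_genes, len(CONTRASTS)))
    d_prot_base = np.zeros_like(d_rna)
    for i in range(cfg.n_genes):
        for j in range(len(CONTRASTS)):
            d_rna[i, j], d_prot_base[i, j] = _draw_structured_deltas(
                rng_assign, target_cat[i, j], cfg.beta0, cfg.beta1
            )

    # --- protein detection and PTM carriers ------------------------------
    n_detected = int(round(cfg.protein_detect_frac * cfg.n_genes))
    detected_idx = np.sort(rng_prot.choice(cfg.n_genes, size=n_detected, replace=False))
    detected = np.zeros(cfg.n_genes, dtype=bool)
    detected[detected_idx] = True
    proteins = [f"P{genes[i][1:]}" for i in detected_idx]
    gene_of = {p: genes[i] for p, i in zip(proteins, detected_idx)}
    protein_of_gene = {genes[i]: p for p, i in zip(proteins, detected_idx)}

    probs = np.asarray(cfg.site_multiplicity_probs, dtype=float)
    probs = probs / probs.sum()
    site_frames, site_delta_blocks = [], []
    dptm_pro: dict[str, np.ndarray] = {}  # mod_type -> per-gene aggregated effect
    for mod_type, rng_mod in (("phos", rng_phos), ("acet", rng_acet)):
        carrier_mask = rng_mod.random(len(proteins)) < cfg.ptm_carrier_frac
        carriers = [p for p, keep in zip(proteins, carrier_mask) if keep]
        smap, deltas = _make_sites(rng_mod, carriers, gene_of, probs, mod_type, cfg.site_delta_sd)
        site_frames.append(smap)
        site_delta_blocks.append(deltas)
        agg = np.zeros((cfg.n_genes, len(CONTRASTS)))
        if len(smap):
            med = (
                pd.DataFrame(deltas, index=smap["protein_id"].values)
                .groupby(level=0)
                .median()
            )
            gene_index = {g: i for i, g in enumerate(genes)}
            for prot, row in med.iterrows():
                agg[gene_index[gene_of[prot]]] = row.to_numpy()
        dptm_pro[mod_type] = agg
    site_map = pd.concat(site_frames, ignore_index=True)
    site_deltas = np.vstack(site_delta_blocks) if len(site_map) else np.zeros((0, len(CONTRASTS)))

    # --- final protein deltas and truth categories -----------------------
    d_prot = d_prot_base + cfg.gamma_phos * dptm_pro["phos"] + cfg.gamma_acet * dptm_pro["acet"]
    categories = np.array(
        [
            [_truth_category(d_rna[i, j], d_prot[i, j], detected[i]) for j in range(len(CONTRASTS))]
            for i in range(cfg.n_genes)
        ],
        dtype=object,
    )

    # --- RNA matrix on the log2(TPM + 1) scale ---------------------------
    base_rna = rng_rna.uniform(8.0, 13.0, size=cfg.n_genes)
    level_rna = np.column_stack(
        [base_rna, base_rna + d_rna[:, 0], base_rna + d_rna[:, 0] + d_rna[:, 1]]
    )
    rna_cols = {}
    for ci, cond in enumerate(conditions):
        noise = rng_rna.normal(0.0, cfg.sigma_rna, size=(cfg.n_genes, cfg.n_reps))
        block = np.maximum(level_rna[:, ci][:, None] + noise, 0.0)
        for r in range(cfg.n_reps):
            rna_cols[f"{cond}_{r + 1}"] = np.exp2(block[:, r]) - 1.0
    rna = OmicsMatrix(pd.DataFrame(rna_cols, index=genes), "rna", design)

    # --- protein matrix (raw log-normal intensities) ----------------------
    base_prot = rng_prot.normal(17.0, 1.2, size=n_detected)
    dp = d_prot[detected_idx]
    level_prot = np.column_stack([base_prot, base_prot + dp[:, 0], base_prot + dp[:, 0] + dp[:, 1]])
    prot_latent = np.zeros((n_detected, len(samples)))
    for ci in range(len(conditions)):
        noise = rng_prot.normal(0.0, cfg.sigma_prot, size=(n_detected, cfg.n_reps))
        prot_latent[:, ci * cfg.n_reps : (ci + 1) * cfg.n_reps] = level_prot[:, ci][:, None] + noise
    prot_raw = _apply_missingness(rng_miss, np.exp2(prot_latent), prot_latent, cfg)
    protein = OmicsMatrix(pd.DataFrame(prot_raw, index=proteins, columns=samples), "protein", design)

    # --- PTM site matrices -------------------------------------------------
    ptm_matrices = {}
    for mod_type, layer, rng_mod in (("phos", "phospho", rng_phos), ("acet", "acetyl", rng_acet)):
        mask = site_map["mod_type"].to_numpy() == mod_type
        ids = site_map.loc[mask, "site_id"].tolist()
        deltas = site_deltas[mask]
        n_sites = len(ids)
        base = rng_mod.normal(15.0, 1.5, size=n_sites)
        if n_sites:
            level = np.column_stack(
                [base, base + deltas[:, 0], base + deltas[:, 0] + deltas[:, 1]]
            )
        else:
            level = np.zeros((0, len(conditions)))
        latent = np.zeros((n_sites, len(samples)))
        for ci in range(len(conditions)):
            noise = rng_mod.normal(0.0, cfg.sigma_ptm, size=(n_sites, cfg.n_reps))
            latent[:, ci * cfg.n_reps : (ci + 1) * cfg.n_reps] = level[:, ci][:, None] + noise
        raw = _apply_missingness(rng_miss, np.exp2(latent), latent, cfg)
        ptm_matrices[layer] = OmicsMatrix(
            pd.DataFrame(raw, index=ids, columns=samples), layer, design
        )

    # --- truth tables -------------------------------------------------------
    contrast_names = [f"{b}vs{a}" for b, a in CONTRASTS]
    gt_rows = []
    for i, gene in enumerate(genes):
        cluster = _nearest_archetype(level_rna[i])
        for j, cname in enumerate(contrast_names):
            gt_rows.append(
                {
                    "gene_id": gene,
                    "protein_id": protein_of_gene.get(gene, ""),
                    "detected_protein": bool(detected[i]),
                    "contrast": cname,
                    "delta_rna": d_rna[i, j],
                    "delta_protein": d_prot[i, j] if detected[i] else np.nan,
                    "category": categories[i, j],
                    "target_category": target_cat[i, j],
                    "cluster": cluster,
                }
            )
    gene_truth = pd.DataFrame(
        gt_rows,
        columns=[
            "gene_id", "protein_id", "detected_protein", "contrast",
            "delta_rna", "delta_protein", "category", "target_category", "cluster",
        ],
    )
    st_rows = []
    for k in range(len(site_map)):
        for j, cname in enumerate(contrast_names):
            st_rows.append(
                {
                    "site_id": site_map.at[k, "site_id"],
                    "protein_id": site_map.at[k, "protein_id"],
                    "gene_id": site_map.at[k, "gene_id"],
                    "mod_type": site_map.at[k, "mod_type"],
                    "contrast": cname,
                    "delta_ptm": site_deltas[k, j],
                }
            )
    site_truth = pd.DataFrame(
        st_rows, columns=["site_id", "protein_id", "gene_id", "mod_type", "contrast", "delta_ptm"]
    )

    return SynthDataset(
        rna=rna,
        protein=protein,
        phospho=ptm_matrices["phospho"],
        acetyl=ptm_matrices["acetyl"],
        design=design,
        metadata=metadata,
        site_map=site_map,
        gene_truth=gene_truth,
        site_truth=site_truth,
        config=cfg,
    )


def generate_temporal_profiles(
    n: int, noise_sd: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, pd.Series]:
    """Condition-mean profiles drawn from the five archetypal trajectories.

    Returns standardized noisy profiles (features x CK/DT/DTR) and the true
    archetype label per feature; used to benchmark cluster recovery.
    """
    rng = np.random.default_rng(seed)
    names = list(ARCHETYPES)
    arch = _standardize_rows(np.array(list(ARCHETYPES.values()), dtype=float))
    labels = rng.integers(0, len(names), size=n)
    x = arch[labels] + rng.normal(0.0, noise_sd, size=(n, arch.shape[1]))
    x = _standardize_rows(x)
    idx = [f"F{i:05d}" for i in range(n)]
    profiles = pd.DataFrame(x, index=idx, columns=["CK", "DT", "DTR"])
    truth = pd.Series([names[k] for k in labels], index=idx, name="cluster")
    return profiles, truth


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(dataset: SynthDataset, directory) -> dict[str, Path]:
    """Write the dataset as the documented tab-delimited file set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _write_matrix(mat: OmicsMatrix, name: str) -> None:
        p = directory / name
        mat.values.to_csv(p, sep="\t", index_label="feature_id", na_rep="")
        paths[name] = p

    _write_matrix(dataset.rna, "rna_tpm.tsv")
    _write_matrix(dataset.protein, "protein_intensity.tsv")
    _write_matrix(dataset.phospho, "phospho_sites.tsv")
    _write_matrix(dataset.acetyl, "acetyl_sites.tsv")
    for name, frame in (
        ("samples.tsv", dataset.metadata),
        ("site_map.tsv", dataset.site_map),
        ("truth.tsv", dataset.gene_truth),
        ("site_truth.tsv", dataset.site_truth),
    ):
        p = directory / name
        frame.to_csv(p, sep="\t", index=False, na_rep="")
        paths[name] = p
    return paths


def read_fixture(directory) -> SynthDataset:
    """Read a fixture directory written by :func:`write_fixture`."""
    from .matrix import read_design, read_matrix

    directory = Path(directory)
    design = read_design(directory / "samples.tsv")
    metadata = pd.read_csv(directory / "samples.tsv", sep="\t")
    site_map = pd.read_csv(directory / "site_map.tsv", sep="\t")
    gene_truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    site_truth_path = directory / "site_truth.tsv"
    site_truth = (
        pd.read_csv(site_truth_path, sep="\t") if site_truth_path.exists() else pd.DataFrame()
    )
    return SynthDataset(
        rna=read_matrix(directory / "rna_tpm.tsv", "rna", design),
        protein=read_matrix(directory / "protein_intensity.tsv", "protein", design),
        phospho=read_matrix(directory / "phospho_sites.tsv", "phospho", design),
        acetyl=read_matrix(directory / "acetyl_sites.tsv", "acetyl", design),
        design=design,
        metadata=metadata,
        site_map=site_map,
        gene_truth=gene_truth,
        site_truth=site_truth,
        config=None,
    )
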