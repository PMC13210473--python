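"""End-to-end orchestration: synth/load -> prep -> contrasts -> clusters ->
PTR -> discordance -> PTM correlations, with a machine-readable summary.

Every stage writes its own tab-delimited outputs into the output directory
and nothing mutates an earlier stage's files; a single master seed from the
config is split per stage so the whole bundle is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering, differential, discordance, prep, ptr
from .matrix import InputError, OmicsMatrix, read_design, read_matrix
from .synthetic import SynthConfig, SynthDataset, generate_multiomics, read_fixture, write_fixture

log = logging.getLogger("discordia")


@dataclass
class PipelineConfig:
    """Declarative configuration for one pipeline run.

    Exactly one of ``input_dir`` (a fixture-dialect directory) or ``synth``
    (generator parameters) must be set.
    """

    input_dir: str | None = None
    synth: SynthConfig | None = None
    contrasts: tuple[tuple[str, str], ...] = (("DT", "CK"), ("DTR", "DT"))
    policies: dict[str, differential.ThresholdPolicy] = field(
        default_factory=lambda: dict(differential.DEFAULT_POLICIES)
    )
    n_clusters: int = 5
    fuzzifier: float = 1.25
    high_k: float = 2.0
    low_frac: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synth is None):
            raise InputError("config must set exactly one of input_dir or synth")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "synth" in raw and raw["synth"] is not None:
            synth_kw = dict(raw.pop("synth"))
            for key in ("conditions", "site_multiplicity_probs"):
                if key in synth_kw:
                    synth_kw[key] = tuple(synth_kw[key])
            kwargs["synth"] = SynthConfig(**synth_kw)
        if "policies" in raw and raw["policies"] is not None:
            pol = {}
            for layer, params in raw.pop("policies").items():
                pol[layer] = differential.ThresholdPolicy(layer=layer, **params)
            base = dict(differential.DEFAULT_POLICIES)
            base.update(pol)
            kwargs["policies"] = base
        if "contrasts" in raw and raw["contrasts"] is not None:
            kwargs["contrasts"] = tuple(tuple(c) for c in raw.pop("contrasts"))
        known = {f.name for f in fields(cls)}
        for key, value in raw.items():
            if key not in known:
                raise InputError(f"unknown pipeline config key {key!r}")
            kwargs[key] = value
        return cls(**kwargs)


def _load_dataset(config: PipelineConfig) -> SynthDataset:
    if config.synth is not None:
        return generate_multiomics(config.synth)
    return read_fixture(config.input_dir)


def _validate(config: PipelineConfig, dataset: SynthDataset) -> None:
    available = set(dataset.design)
    for b, a in config.contrasts:
        for cond in (b, a):
            if cond not in available:
                raise InputError(f"contrast condition {cond!r} absent from sample metadata")


def _id_map(dataset: SynthDataset) -> pd.Series | None:
    truth = dataset.gene_truth
    if truth is None or len(truth) == 0 or "protein_id" not in truth:
        return None
    pairs = truth[truth["detected_protein"]][["protein_id", "gene_id"]].drop_duplicates()
    return pd.Series(pairs["gene_id"].values, index=pairs["protein_id"].values)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all stages in dependency order and write the report bundle.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    stage = "load"
    try:
        dataset = _load_dataset(config)
        _validate(config, dataset)
        if config.synth is not None:
            write_fixture(dataset, outdir / "synth")
        id_map = _id_map(dataset)

        # ---- preprocessing ------------------------------------------------
        stage = "prep"
        prepped: dict[str, OmicsMatrix] = {"rna": dataset.rna}
        for layer, mat in (
            ("protein", dataset.protein),
            ("phospho", dataset.phospho),
            ("acetyl", dataset.acetyl),
        ):
            if len(mat.values) == 0:
                prepped[layer] = mat
                continue
            prepped[layer] = prep.preprocess(mat)
            prepped[layer].values.to_csv(
                outdir / f"prep_{layer}.tsv", sep="\t", index_label="feature_id"
            )
        summary["prep"] = {
            layer: {"n_features": int(len(m.values))} for layer, m in prepped.items()
        }

        # ---- differential contrasts --------------------------------------
        stage = "contrast"
        contrast_tables: dict[tuple[str, str], pd.DataFrame] = {}
        for layer, mat in prepped.items():
            for contrast in config.contrasts:
                name = f"{contrast[0]}vs{contrast[1]}"
                if len(mat.values) == 0:
                    continue
                table = differential.run_contrast(mat, contrast, config.policies[layer])
                contrast_tables[(layer, name)] = table
                table.to_csv(outdir / f"contrast_{layer}_{name}.tsv", sep="\t")
        summary["differential"] = {
            f"{layer}:{name}": {
                "n": int(len(t)),
                "n_significant": int(t["significant"].sum()),
                "n_up": int((t["direction"] == "up").sum()),
                "n_down": int((t["direction"] == "down").sum()),
            }
            for (layer, name), t in contrast_tables.items()
        }

        # ---- temporal clustering -------------------------------------------
        stage = "cluster"
        rng = np.random.SeedSequence(config.seed).spawn(1)[0]
        cluster_seed = int(rng.generate_state(1)[0] % (2**31))
        summary["clusters"] = {}
        cluster_results = {}
        for layer in ("rna", "protein"):
            mat = prepped[layer]
            if len(mat.values) < config.n_clusters:
                continue
            if layer == "rna":
                mat = mat.with_values(np.log2(mat.values + 1.0))
            result = clustering.cluster_layer(
                mat, c=config.n_clusters, m=config.fuzzifier, seed=cluster_seed
            )
            cluster_results[layer] = result
            out = result.memberships.copy()
            out.insert(0, "hard_label", result.hard_labels)
            out.to_csv(outdir / f"clusters_{layer}.tsv", sep="\t", index_label="feature_id")
            summary["clusters"][layer] = {
                "sizes": {
                    name: int((result.hard_labels == i + 1).sum())
                    for i, name in enumerate(result.memberships.columns)
                },
                "archetypes": result.archetype_names(),
            }
        if len(cluster_results) == 2:
            rows = []
            for gc in cluster_results["rna"].memberships.columns:
                for pc in cluster_results["protein"].memberships.columns:
                    n, pg, pp = clustering.cluster_pair_overlap(
                        cluster_results["rna"].members(gc),
                        cluster_results["protein"].members(pc),
                        id_map,
                    )
                    rows.append(
                        {"gene_cluster": gc, "protein_cluster": pc,
                         "n_overlap": n, "pct_of_genes": pg, "pct_of_proteins": pp}
                    )
            pd.DataFrame(rows).to_csv(outdir / "cluster_overlap.tsv", sep="\t", index=False)

        # ---- PTR ------------------------------------------------------------
        stage = "ptr"
        conditions = []
        for c in dataset.design:
            if c not in conditions:
                conditions.append(c)
        ptr_records = {}
        disp_frames = []
        summary["ptr"] = {}
        if len(prepped["protein"].values):
            for cond in conditions:
                rec = ptr.compute_ptr(prepped["rna"], prepped["protein"], cond, id_map)
                ptr_records[cond] = rec
                rec.to_csv(outdir / f"ptr_{cond}.tsv", sep="\t")
                disp_frames.append(ptr.dispersion_summary(rec, cond))
                high, low = ptr.stratify_ptr(rec, config.high_k, config.low_frac)
                summary["ptr"][cond] = {
                    "n": int(len(rec)),
                    "n_high": int(len(high)),
                    "n_low": int(len(low)),
                }
            pd.concat(disp_frames, ignore_index=True).to_csv(
                outdir / "ptr_dispersion.tsv", sep="\t", index=False
            )
            h_stat, kw_p = ptr.compare_ptr_distributions(ptr_records)
            summary["ptr"]["kruskal_wallis"] = {"H": h_stat, "p": kw_p}

        # ---- layer overlap ---------------------------------------------------
        stage = "overlap"
        gene_sets = {"rna": set(prepped["rna"].feature_ids)}
        if id_map is not None:
            to_gene = id_map.to_dict()
        else:
            to_gene = {}
        gene_sets["protein"] = {to_gene.get(p, p) for p in prepped["protein"].feature_ids}
        site_gene = dataset.site_map.set_index("site_id")["gene_id"].to_dict() if len(dataset.site_map) else {}
        for layer in ("phospho", "acetyl"):
            gene_sets[layer] = {site_gene.get(s, s) for s in prepped[layer].feature_ids}
        regions = discordance.layer_overlap(gene_sets)
        pd.DataFrame(
            [{"layers": "&".join(sorted(k)), "count": v} for k, v in sorted(regions.items(), key=lambda kv: "&".join(sorted(kv[0])))]
        ).to_csv(outdir / "layer_overlap.tsv", sep="\t", index=False)
        summary["layer_overlap"] = {"&".join(sorted(k)): v for k, v in regions.items()}

        # ---- discordance + PTM correlation ----------------------------------
        stage = "discord"
        summary["discordance"] = {}
        summary["ptm_correlation"] = []
        corr_rows = []
        for contrast in config.contrasts:
            name = f"{contrast[0]}vs{contrast[1]}"
            rna_t = contrast_tables.get(("rna", name))
            prot_t = contrast_tables.get(("protein", name))
            if rna_t is None or prot_t is None:
                continue
            calls = discordance.classify_table(rna_t, prot_t, id_map)
            calls.to_csv(outdir / f"discordance_{name}.tsv", sep="\t")
            counts = discordance.category_counts(calls)
            summary["discordance"][name] = {
                "counts": counts.to_dict(),
                "pct_inconsistent": discordance.inconsistent_percentages(calls),
            }
            b0, b1, residuals = discordance.fit_residuals(calls)
            residuals.to_frame().assign(contrast=name).to_csv(
                outdir / f"residuals_{name}.tsv", sep="\t", index_label="gene_id"
            )
            summary["discordance"][name]["ols"] = {
                "beta0": b0, "beta1": b1, "n": int(residuals.size)
            }
            site_deltas = build_site_deltas(contrast_tables, dataset.site_map, name)
            if len(site_deltas):
                prot_deltas = discordance.aggregate_ptm_to_protein(site_deltas)
                for mod_type in ("phos", "acet"):
                    corr_rows.append(
                        discordance.site_level_correlation(residuals, site_deltas, mod_type, name)
                    )
                    corr_rows.append(
                        discordance.protein_level_correlation(residuals, prot_deltas, mod_type, name)
                    )
        if corr_rows:
            pd.DataFrame(corr_rows).to_csv(outdir / "ptm_correlation.tsv", sep="\t", index=False)
            summary["ptm_correlation"] = corr_rows

        stage = "report"
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary


def build_site_deltas(
    contrast_tables: dict[tuple[str, str], pd.DataFrame],
    site_map: pd.DataFrame,
    contrast_name: str,
) -> pd.DataFrame:
    """Join PTM-site contrast tables with the site map into site-delta rows."""
    frames = []
    for layer, mod_type in (("phospho", "phos"), ("acetyl", "acet")):
        table = contrast_tables.get((layer, contrast_name))
        if table is None or len(site_map) == 0:
            continue
        sel = site_map[site_map["mod_type"] == mod_type].set_index("site_id")
        shared = table.index.intersection(sel.index)
        if len(shared) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "site_id": shared,
                    "protein_id": sel.loc[shared, "protein_id"].values,
                    "gene_id": sel.loc[shared, "gene_id"].values,
                    "mod_type": mod_type,
                    "contrast": contrast_name,
                    "delta_ptm": table.loc[shared, "log2fc"].values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["site_id", "protein_id", "gene_id", "mod_type", "contrast", "delta_ptm"]
        )
    return pd.concat(frames, ignore_index=True)
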