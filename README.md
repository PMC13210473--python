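# discordia

Tools for asking where — and by how much — protein-level regulation departs
from transcript-level regulation in a three-condition stress/recovery design
(control `CK`, drought `DT`, drought-then-rewatered `DTR`), and whether
post-translational modification (PTM) changes track the departure.

The package targets the common proteogenomics situation: matched RNA-seq
(TPM), DIA protein intensities, and phospho-/acetyl-site intensities over the
same plants, with the protein layer covering only a fraction of expressed
genes and carrying missing values. It provides:

* **Intensity preprocessing** — valid-value filtering (≥2 observations overall
  and ≥50% observed in at least one condition), two-tier imputation (group
  mean where the group is ≥50% observed, else half the global minimum),
  per-sample median normalization, and the positivity shift
  `log2(x) + 10 + |min(log2(x))|`.
* **Differential contrasts** — per-feature log2 fold changes
  (`log2((TPM_B + 1)/(TPM_A + 1))` for RNA, group-mean differences for
  log2-scale intensity layers), Welch *t*-tests, Benjamini–Hochberg
  adjustment, and layer-specific calling (RNA: |log2FC| > 1.5, adjusted
  *p* < 0.01; protein/PTM: |log2FC| > 1.2, *p* < 0.05).
* **Temporal clustering** — fuzzy c-means (Mfuzz-style, fuzzifier 1.25,
  c = 5) of z-scored CK→DT→DTR condition-mean profiles, plus RNA/protein
  cluster-pair overlap percentages.
* **PTR analysis** — the protein-to-RNA ratio
  `PTR = log2(protein) − log2(TPM + 1)` per gene and condition, unscaled MAD
  dispersion `median(|x_i − median(x)|)`, high-PTR (`> median + 2·MAD`) and
  low-PTR (lowest 25%) strata, and a Kruskal–Wallis comparison across
  conditions.
* **Discordance classification** — each gene–protein pair and contrast is
  called `translation_dominant` (|ΔProtein| ≥ 2|ΔRNA|, protein significant),
  `transcription_dominant` (|ΔRNA| ≥ 2|ΔProtein|, RNA significant),
  `inconsistent` (opposite signs, at least one significant), `stable`, or
  `NA` (a layer unquantified); opposite signs take precedence over dominance.
* **PTM–residual correlation** — per contrast, OLS of
  `ΔProtein = β0 + β1·ΔRNA + ε` over all quantified pairs; Spearman
  correlation of the residuals with site-level ΔPTM (each site paired with
  its gene's residual) and with the per-protein median ΔPTM (`dPTM_pro`),
  separately for phosphorylation and acetylation.
* **A synthetic multi-omics generator** with full ground truth (true deltas,
  categories, cluster archetypes, site effects), so the entire pipeline is
  testable without any external data.

## Worked example

```python
import discordia as d

cfg = d.SynthConfig(n_genes=800, seed=3, gamma_phos=1.0)
summary = d.run_pipeline(d.PipelineConfig(synth=cfg, seed=3), "out")

print(summary["discordance"]["DTvsCK"]["counts"])
for r in summary["ptm_correlation"]:
    if r["contrast"] == "DTvsCK":
        print(r["level"], r["mod_type"], round(r["rho"], 3), r["n"])
```

prints (seed 3):

```
{'translation_dominant': 73, 'transcription_dominant': 201, 'inconsistent': 188, 'stable': 96, 'NA': 242}
site phos 0.306 427
protein phos 0.507 194
site acet 0.185 521
protein acet 0.235 233
```

The counts are the four discordance categories among the 558 gene–protein
pairs quantified in both layers (242 genes lack protein evidence). The
correlation rows give Spearman ρ between PTM log2 fold changes and the
RNA-unexplained protein change: with a strong injected phospho effect
(`gamma_phos = 1`) the phospho correlations are clearly positive, and
aggregating sites to proteins (median, `dPTM_pro`) strengthens them
(0.31 → 0.51) because site-level measurement noise averages out.

The same pipeline runs from files (`discordia run --config cfg.yaml
--outdir out`), where the config either points at tab-delimited
matrices + a sample table or embeds a `synth:` block; every stage also has
its own subcommand (`synth`, `prep`, `contrast`, `cluster`, `ptr`,
`physiology`).

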