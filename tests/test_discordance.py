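"""Four-category classification, layer overlap, residual OLS, Spearman, PTM links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from discordia import (
    InputError,
    aggregate_ptm_to_protein,
    classify_pair,
    classify_table,
    fit_residuals,
    layer_overlap,
    protein_level_correlation,
    site_level_correlation,
    spearman,
)
from discordia.discordance import category_counts


class TestClassifyPair:
    @pytest.mark.parametrize(
        "d_rna, sig_rna, d_prot, sig_prot, expected",
        [
            (2.0, True, -1.5, True, "inconsistent"),
            (0.1, False, 2.0, True, "translation_dominant"),
            (3.0, True, 0.5, False, "transcription_dominant"),
            (0.2, False, 0.3, False, "stable"),
            # opposite signs take precedence over dominance
            (3.0, True, -0.5, False, "inconsistent"),
            # opposite signs but nothing significant -> falls through to stable
            (0.3, False, -0.2, False, "stable"),
            # zero delta carries no sign: cannot be inconsistent
            (0.0, False, -2.0, True, "translation_dominant"),
            (-2.0, True, 0.0, False, "transcription_dominant"),
        ],
    )
    def test_rules(self, d_rna, sig_rna, d_prot, sig_prot, expected):
        assert classify_pair(d_rna, sig_rna, d_prot, sig_prot) == expected

    def test_missing_layer_is_na(self):
        assert classify_pair(1.0, True, np.nan, False, protein_missing=True) == "NA"
        assert classify_pair(np.nan, False, 1.0, True, rna_missing=True) == "NA"

    def test_totality_and_exclusivity(self, rng):
        """Every input gets exactly one category from the closed set."""
        cats = set()
        for _ in range(500):
            c = classify_pair(
                rng.normal(0, 2), bool(rng.integers(2)), rng.normal(0, 2), bool(rng.integers(2))
            )
            cats.add(c)
        assert cats <= {"translation_dominant", "transcription_dominant", "inconsistent", "stable"}

    def test_table_counts_sum_to_pairs(self, rng):
        rna = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 50), "significant": rng.integers(2, size=50).astype(bool)},
            index=[f"g{i}" for i in range(50)],
        )
        prot = pd.DataFrame(
            {"log2fc": rng.normal(0, 2, 40), "significant": rng.integers(2, size=40).astype(bool)},
            index=[f"g{i}" for i in range(40)],
        )
        calls = classify_table(rna, prot)
        assert category_counts(calls).sum() == len(calls) == 50


class TestLayerOverlap:
    def test_identical_sets(self):
        s = {"a", "b"}
        regions = layer_overlap({"rna": s, "protein": s, "phospho": s, "acetyl": s})
        assert regions == {frozenset(["rna", "protein", "phospho", "acetyl"]): 2}

    def test_pairwise_disjoint(self):
        regions = layer_overlap({"rna": {"a"}, "protein": {"b"}, "phospho": {"c"}})
        assert regions == {
            frozenset(["rna"]): 1,
            frozenset(["protein"]): 1,
            frozenset(["phospho"]): 1,
        }

    def test_brute_force_on_random_sets(self, rng):
        universe = [f"g{i}" for i in range(60)]
        sets = {
            layer: set(rng.choice(universe, size=rng.integers(5, 40), replace=False))
            for layer in ("rna", "protein", "phospho", "acetyl")
        }
        regions = layer_overlap(sets)
        # brute force: enumerate membership of each universe element
        expected: dict[frozenset, int] = {}
        for g in universe:
            key = frozenset(l for l, s in sets.items() if g in s)
            if key:
                expected[key] = expected.get(key, 0) + 1
        assert regions == expected
        assert sum(regions.values()) == len(set().union(*sets.values()))


class TestFitResiduals:
    def test_exact_line(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        pairs = pd.DataFrame({"delta_rna": x, "delta_protein": 0.5 + 2.0 * x})
        b0, b1, res = fit_residuals(pairs)
        assert b0 == pytest.approx(0.5, abs=1e-12)
        assert b1 == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(res, 0.0, atol=1e-12)

    def test_parameter_recovery(self, rng):
        x = rng.normal(0, 1, 1000)
        y = 0.3 + 1.2 * x + rng.normal(0, 0.1, 1000)
        b0, b1, _ = fit_residuals(pd.DataFrame({"delta_rna": x, "delta_protein": y}))
        assert b1 == pytest.approx(1.2, abs=0.05)
        assert b0 == pytest.approx(0.3, abs=0.05)

    def test_shift_equivariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        pairs = pd.DataFrame({"delta_rna": x, "delta_protein": y})
        b0a, b1a, _ = fit_residuals(pairs)
        shifted = pd.DataFrame({"delta_rna": x, "delta_protein": y + 3.0})
        b0b, b1b, _ = fit_residuals(shifted)
        assert b1b == pytest.approx(b1a, abs=1e-9)
        assert b0b == pytest.approx(b0a + 3.0, abs=1e-9)

    def test_orthogonality(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        _, _, res = fit_residuals(pd.DataFrame({"delta_rna": x, "delta_protein": y}))
        assert abs(res.sum()) < 1e-9
        assert abs((res.to_numpy() * x).sum()) < 1e-9

    def test_zero_variance_rejected(self):
        pairs = pd.DataFrame({"delta_rna": [1.0, 1.0, 1.0], "delta_protein": [1.0, 2.0, 3.0]})
        with pytest.raises(InputError):
            fit_residuals(pairs)


class TestSpearman:
    def test_monotone_identity(self, rng):
        x = rng.normal(size=30)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_negated(self, rng):
        x = rng.normal(size=30)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_against_rank_then_pearson_brute_force(self, rng):
        """rho equals Pearson on average ranks, including heavy ties."""
        for _ in range(1000):
            n = rng.integers(11, 60)
            x = rng.integers(0, 8, size=n).astype(float)  # many ties
            y = rng.normal(size=n) + x
            rho, _ = spearman(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            ref = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(ref, abs=1e-12)

    def test_p_matches_scipy_t_approximation(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_permutation_small_n(self, rng):
        """For n <= 10 the p-value is the exact permutation tail probability."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        rho, p = spearman(x, y)

        def statistic(perm_y):
            return stats.spearmanr(x, perm_y).statistic

        ref = stats.permutation_test(
            (y,), statistic, permutation_type="pairings", alternative="two-sided",
            n_resamples=np.inf,
        )
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_constant_input_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestAggregatePtm:
    def test_medians(self):
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(6)],
                "protein_id": ["p1"] * 3 + ["p2"] * 2 + ["p3"],
                "gene_id": ["g1"] * 3 + ["g2"] * 2 + ["g3"],
                "mod_type": ["phos"] * 6,
                "contrast": ["DTvsCK"] * 6,
                "delta_ptm": [1.0, 2.0, 3.0, 1.0, 3.0, 5.0],
            }
        )
        agg = aggregate_ptm_to_protein(sites).set_index("protein_id")
        assert agg.loc["p1", "dptm_pro"] == pytest.approx(2.0)  # odd count: middle
        assert agg.loc["p2", "dptm_pro"] == pytest.approx(2.0)  # even: mean of middle
        assert agg.loc["p3", "dptm_pro"] == pytest.approx(5.0)  # singleton

    def test_mod_types_kept_separate(self):
        sites = pd.DataFrame(
            {
                "site_id": ["s1", "s2"],
                "protein_id": ["p1", "p1"],
                "gene_id": ["g1", "g1"],
                "mod_type": ["phos", "acet"],
                "contrast": ["DTvsCK", "DTvsCK"],
                "delta_ptm": [1.0, -1.0],
            }
        )
        agg = aggregate_ptm_to_protein(sites)
        assert len(agg) == 2


class TestCorrelations:
    def _sites(self, genes, deltas, mod="phos", contrast="DTvsCK"):
        return pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(len(genes))],
                "protein_id": [f"p_{g}" for g in genes],
                "gene_id": genes,
                "mod_type": mod,
                "contrast": contrast,
                "delta_ptm": deltas,
            }
        )

    def test_site_deltas_equal_residuals(self, rng):
        genes = [f"g{i}" for i in range(20)]
        residuals = pd.Series(rng.normal(size=20), index=genes)
        sites = self._sites(genes, residuals.to_numpy())
        rep = site_level_correlation(residuals, sites, "phos", "DTvsCK")
        assert rep["rho"] == pytest.approx(1.0)
        assert rep["n"] == 20

    def test_negated_residuals(self, rng):
        genes = [f"g{i}" for i in range(15)]
        residuals = pd.Series(rng.normal(size=15), index=genes)
        sites = self._sites(genes, -residuals.to_numpy())
        rep = site_level_correlation(residuals, sites, "phos", "DTvsCK")
        assert rep["rho"] == pytest.approx(-1.0)

    def test_residuals_duplicated_across_sites(self, rng):
        genes = ["g1"] * 3 + ["g2"] * 2 + ["g3"]
        residuals = pd.Series({"g1": 0.5, "g2": -1.0, "g3": 2.0})
        sites = self._sites(genes, rng.normal(size=6))
        rep = site_level_correlation(residuals, sites, "phos", "DTvsCK")
        assert rep["n"] == 6

    def test_too_few_pairs_undefined(self):
        residuals = pd.Series({"g1": 1.0, "g2": 2.0})
        sites = self._sites(["g1", "g2"], [0.1, 0.2])
        rep = site_level_correlation(residuals, sites, "phos", "DTvsCK")
        assert rep["n"] == 2 and np.isnan(rep["rho"])

    def test_protein_level_null_is_small(self, rng):
        genes = [f"g{i}" for i in range(400)]
        residuals = pd.Series(rng.normal(size=400), index=genes)
        prot = pd.DataFrame(
            {
                "protein_id": [f"p_{g}" for g in genes],
                "gene_id": genes,
                "mod_type": "acet",
                "contrast": "DTvsCK",
                "dptm_pro": rng.normal(size=400),
            }
        )
        rep = protein_level_correlation(residuals, prot, "acet", "DTvsCK")
        assert abs(rep["rho"]) < 0.1

    def test_aggregation_reduces_noise(self, rng):
        """Protein-level rho beats site-level rho when site deltas are i.i.d.
        noise around a protein-level effect that drives the residual."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(150)]
            effect = r.normal(size=150)
            residuals = pd.Series(effect + r.normal(0, 0.3, 150), index=genes)
            rows = []
            for gi, g in enumerate(genes):
                for s in range(4):
                    rows.append(
                        {
                            "site_id": f"{g}_s{s}",
                            "protein_id": f"p_{g}",
                            "gene_id": g,
                            "mod_type": "phos",
                            "contrast": "DTvsCK",
                            "delta_ptm": effect[gi] + r.normal(0, 1.5),
                        }
                    )
            sites = pd.DataFrame(rows)
            agg = aggregate_ptm_to_protein(sites)
            site_rho = site_level_correlation(residuals, sites, "phos", "DTvsCK")["rho"]
            prot_rho = protein_level_correlation(residuals, agg, "phos", "DTvsCK")["rho"]
            wins += prot_rho >= site_rho
        assert wins >= 8
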