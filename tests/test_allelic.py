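"""Staircase design, per-protein OLS, closed-form oracle, rankings."""
import numpy as np
import pandas as pd
import pytest

import erphagyquant as eq
from erphagyquant import DesignError
from erphagyquant.allelic import fit_protein

SERIES = ("WT", "DKO", "TKO", "QKO", "PKO")


def _design(counts):
    rows = []
    i = 1
    for g, n in counts:
        for r in range(1, n + 1):
            rows.append({"channel": f"ch{i:03d}", "genotype": g,
                         "replicate": r, "condition": "day12"})
            i += 1
    return pd.DataFrame(rows).set_index("channel")


def closed_form_beta(y, design, series=SERIES):
    """Oracle: successive differences of adjacent genotype sample means."""
    means = []
    for g in series:
        cols = design.index[design["genotype"] == g]
        means.append(float(np.mean([y[design.index.get_loc(c)] for c in cols])))
    return np.diff(means)


class TestBuildDesign:
    def test_staircase_rows_one_sample_each(self):
        d = _design([(g, 1) for g in SERIES])
        ad = eq.build_design(d, SERIES)
        np.testing.assert_array_equal(
            ad.X.to_numpy(),
            [[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0], [1, 1, 1, 0], [1, 1, 1, 1]])
        assert ad.steps == ["WT->DKO", "DKO->TKO", "TKO->QKO", "QKO->PKO"]

    def test_wt_only_raises_rank_deficient(self):
        with pytest.raises(DesignError, match="rank-deficient"):
            eq.build_design(_design([("WT", 4)]), SERIES)

    def test_replicates_repeat_staircase_rows(self):
        d = _design([(g, 3) for g in SERIES])
        ad = eq.build_design(d, SERIES)
        assert ad.X.shape == (15, 4)
        for i, row in enumerate([[0, 0, 0, 0], [1, 0, 0, 0], [1, 1, 0, 0],
                                 [1, 1, 1, 0], [1, 1, 1, 1]]):
            block = ad.X.to_numpy()[3 * i:3 * i + 3]
            np.testing.assert_array_equal(block, [row] * 3)

    def test_genotype_outside_series_raises(self):
        with pytest.raises(DesignError, match="ATG12KO"):
            eq.build_design(_design([("WT", 2), ("ATG12KO", 2)]), SERIES)


class TestFitProtein:
    def test_all_zero_y_gives_zero_beta_degenerate_p(self):
        d = _design([(g, 3) for g in SERIES])
        ad = eq.build_design(d, SERIES)
        r = fit_protein(np.zeros(15), ad)
        np.testing.assert_array_equal(r["beta"], 0.0)
        assert r["flag"] == "degenerate_variance"
        np.testing.assert_array_equal(r["p"], 1.0)

    def test_noise_free_staircase_inversion(self):
        d = _design([(g, 2) for g in SERIES])
        ad = eq.build_design(d, SERIES)
        y = np.repeat([0.0, 1.0, 1.0, 1.0, 1.0], 2)
        r = fit_protein(y, ad)
        np.testing.assert_allclose(r["beta"], [1, 0, 0, 0], atol=1e-12)

    def test_no_residual_df_returns_beta_with_flag(self):
        # one sample per genotype: the fit is saturated, no residual df
        d = _design([(g, 1) for g in SERIES])
        ad = eq.build_design(d, SERIES)
        r = fit_protein(np.array([0.0, 1.0, 1.5, 2.0, 2.5]), ad)
        assert r["flag"] == "no_inference"
        assert np.isfinite(r["beta"]).all()
        np.testing.assert_allclose(r["beta"], [1.0, 0.5, 0.5, 0.5], atol=1e-12)
        assert np.isnan(r["p"]).all()

    def test_closed_form_oracle_random_unbalanced_designs(self):
        """OLS equals successive-difference-of-genotype-means, 300 random designs."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            counts = [(g, int(rng.integers(1, 6))) for g in SERIES]
            d = _design(counts)
            ad = eq.build_design(d, SERIES)
            y = rng.normal(size=len(d))
            r = fit_protein(y, ad)
            np.testing.assert_allclose(r["beta"], closed_form_beta(y, d),
                                       atol=1e-10)


class TestFitAll:
    def test_noise_free_exact_recovery(self):
        cfg = eq.SimConfig(n_proteins=200, noise_sigma=0.0, seed=3)
        truth = eq.generate_truth(cfg)
        pq = eq.simulate_protein_matrix(truth, cfg)
        model = eq.fit_all(eq.log2_transform_and_center(pq), pq.design)
        np.testing.assert_allclose(model.beta_.to_numpy(),
                                   eq.truth_beta(truth).to_numpy(), atol=1e-10)

    def test_receptor_like_protein_recovered_and_significant(self):
        cfg = eq.SimConfig(n_proteins=300, noise_sigma=0.1, seed=8)
        truth = eq.generate_truth(cfg)
        pq = eq.simulate_protein_matrix(truth, cfg)
        model = eq.fit_all(eq.log2_transform_and_center(pq), pq.design)
        b = model.beta_.loc["FAM134A"]
        assert b.iloc[0] == pytest.approx(-2.5, abs=0.3)
        assert model.significant_.loc["FAM134A"].iloc[0]
        assert np.abs(b.iloc[1:]).max() < 0.3
        assert not model.significant_.loc["FAM134A"].iloc[1:].any()

    def test_interpretation_contract_beta3(self, small_experiment):
        """beta_3 is the mean fold change from the triple to quadruple knockout."""
        pq = small_experiment["protein_quant"]
        centred = eq.log2_transform_and_center(pq)
        model = eq.fit_all(centred, pq.design)
        diff = (centred[pq.channels_for("QKO")].mean(axis=1)
                - centred[pq.channels_for("TKO")].mean(axis=1))
        np.testing.assert_allclose(model.beta_["TKO->QKO"].to_numpy(),
                                   diff.to_numpy(), atol=1e-10)

    def test_shift_property(self, small_experiment):
        """Adding c to every mutant sample shifts beta_1 by c, others unchanged."""
        pq = small_experiment["protein_quant"]
        centred = eq.log2_transform_and_center(pq)
        model = eq.fit_all(centred, pq.design)
        shifted = centred.copy()
        mut = [c for c in centred.columns
               if pq.design.loc[c, "genotype"] != "WT"]
        shifted[mut] = shifted[mut] + 0.7
        model2 = eq.fit_all(shifted, pq.design)
        np.testing.assert_allclose(model2.beta_["WT->DKO"].to_numpy(),
                                   model.beta_["WT->DKO"].to_numpy() + 0.7,
                                   atol=1e-10)
        for step in ("DKO->TKO", "TKO->QKO", "QKO->PKO"):
            np.testing.assert_allclose(model2.beta_[step].to_numpy(),
                                       model.beta_[step].to_numpy(), atol=1e-10)

    def test_padj_dominates_p(self, small_experiment):
        pq = small_experiment["protein_quant"]
        model = eq.fit_all(eq.log2_transform_and_center(pq), pq.design)
        p, padj = model.pvalues_.to_numpy(), model.padj_.to_numpy()
        ok = np.isfinite(p)
        assert (padj[ok] >= p[ok] - 1e-15).all()

    def test_missing_genotype_rows_fitted_when_rank_permits(self, small_experiment):
        pq = small_experiment["protein_quant"]
        centred = eq.log2_transform_and_center(pq)
        # knock out one WT replicate of the first protein only
        centred.iloc[0, centred.columns.get_loc(pq.channels_for("WT")[0])] = np.nan
        model = eq.fit_all(centred, pq.design)
        assert np.isfinite(model.beta_.iloc[0].to_numpy()).all()
        assert model.n_used_.iloc[0] == len(centred.columns) - 1


class TestSummaries:
    def _model(self):
        cfg = eq.SimConfig(n_proteins=120, seed=5)
        truth = eq.generate_truth(cfg)
        pq = eq.simulate_protein_matrix(truth, cfg)
        model = eq.fit_all(eq.log2_transform_and_center(pq), pq.design)
        ann = eq.parse_annotations(eq.truth_to_annotation(truth))
        return model, ann, truth

    def test_single_protein_group_mean_is_its_beta(self):
        model, ann, _ = self._model()
        rec = ann[ann["is_receptor"]].index[:1]
        sub = ann.copy()
        sub["er_class"] = np.where(sub.index.isin(rec), "ER-lumen", "none")
        sub["organelle"] = np.where(sub.index.isin(rec), "ER", "Golgi")
        summary = eq.summarize_beta(model, sub, by="er_class")
        np.testing.assert_allclose(
            summary.loc["ER-lumen", model.beta_.columns].to_numpy(dtype=float),
            model.beta_.loc[rec[0]].to_numpy())

    def test_two_protein_group_mean(self):
        model, ann, _ = self._model()
        ids = model.beta_.index[:2]
        sub = pd.DataFrame({"er_class": ["ER-lumen"] * 2,
                            "organelle": ["ER"] * 2}, index=ids)
        summary = eq.summarize_beta(model, sub, by="er_class")
        np.testing.assert_allclose(
            summary.loc["ER-lumen", model.beta_.columns].to_numpy(dtype=float),
            model.beta_.loc[ids].mean().to_numpy())
        assert summary.loc["ER-lumen", "n_proteins"] == 2

    def test_counts_conserve_annotated_plus_unannotated(self):
        model, ann, _ = self._model()
        summary = eq.summarize_beta(model, ann.iloc[:50], by="er_class")
        assert summary["n_proteins"].sum() == len(model.beta_)


class TestRankTop:
    def test_partition_of_thirty_distinct(self):
        beta = pd.DataFrame(
            {"WT->DKO": np.linspace(1, -1, 30)},
            index=pd.Index([f"P{i:02d}" for i in range(30)], name="protein_id"))
        ranked = eq.rank_top(beta, "WT->DKO", n_top=25, n_bottom=5)
        assert (ranked["rank_class"] == "top").sum() == 25
        assert (ranked["rank_class"] == "bottom").sum() == 5
        assert set(ranked.index) == set(beta.index)

    def test_ties_broken_by_accession(self):
        beta = pd.DataFrame(
            {"WT->DKO": [0.5, 0.5, 0.1, 0.0, -0.1, -0.2, -0.3]},
            index=pd.Index(["ZZZ", "AAA", "M1", "M2", "M3", "M4", "M5"],
                           name="protein_id"))
        ranked = eq.rank_top(beta, "WT->DKO", n_top=2, n_bottom=1)
        assert list(ranked.index[:2]) == ["AAA", "ZZZ"]

    def test_constructed_step4_effects_fill_top(self):
        rng = np.random.default_rng(1)
        n = 60
        ids = pd.Index([f"P{i:02d}" for i in range(n)], name="protein_id")
        vals = rng.normal(0, 0.05, n)
        strong = ids[:10]
        vals[:10] = 2.0 + rng.normal(0, 0.05, 10)
        beta = pd.DataFrame({"QKO->PKO": vals}, index=ids)
        ranked = eq.rank_top(beta, "QKO->PKO", n_top=25, n_bottom=5)
        top = ranked[ranked["rank_class"] == "top"].index
        assert set(strong) <= set(top)

    def test_too_few_proteins_raises(self):
        beta = pd.DataFrame({"WT->DKO": [0.1, 0.2]},
                            index=pd.Index(["A", "B"], name="protein_id"))
        with pytest.raises(ValueError, match="at least"):
            eq.rank_top(beta, "WT->DKO")
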