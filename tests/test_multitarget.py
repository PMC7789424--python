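import numpy as np
import pandas as pd
import pytest

from crisprbf.io import TARGET_MAP_COLUMNS
from crisprbf.multitarget import (
    apply_penalty,
    compute_increments,
    filter_guides,
    fit_offtarget_model,
)


def target_map(rows):
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=TARGET_MAP_COLUMNS).astype(np.int64)
    df.index.name = "GUIDE"
    return df


class TestFilterGuides:
    def make_table(self):
        return pd.DataFrame(
            {"GENE": ["A", "A", "B", "C"]},
            index=pd.Index(["g1", "g2", "g3", "g4"], name="GUIDE"))

    def test_multicoding_and_promiscuous_guides_dropped_with_reason(self):
        tmap = target_map({
            "g1": (2, 0, 2, 0),    # hits two coding genes
            "g2": (11, 0, 1, 0),   # > 10 perfect loci
            "g3": (1, 11, 1, 0),   # > 10 mismatched loci
            "g4": (1, 0, 1, 0),    # clean
        })
        filtered, report = filter_guides(self.make_table(), tmap)
        assert list(filtered.index) == ["g4"]
        assert report.loc["g1", "REASON"] == "multi-coding"
        assert report.loc["g2", "REASON"] == "promiscuous"
        assert report.loc["g3", "REASON"] == "promiscuous"

    def test_clean_and_unmapped_guides_retained(self):
        tmap = target_map({"g1": (3, 2, 1, 0)})
        filtered, report = filter_guides(self.make_table(), tmap)
        assert len(filtered) == 4 and report.empty

    def test_gene_losing_all_guides_triggers_warning(self, caplog):
        tmap = target_map({"g3": (12, 0, 1, 0)})
        with caplog.at_level("WARNING"):
            filter_guides(self.make_table(), tmap)
        assert any("B" in r.message for r in caplog.records)


class TestIncrements:
    def test_increment_is_bf_minus_clean_gene_mean(self):
        bf = pd.Series([10.0, 12.0, 18.0],
                       index=pd.Index(["c1", "c2", "m1"], name="GUIDE"))
        genes = pd.Series(["A", "A", "A"], index=bf.index)
        tmap = target_map({"c1": (1, 0, 1, 0), "c2": (1, 0, 1, 0),
                           "m1": (3, 2, 1, 0)})
        obs = compute_increments(bf, genes, tmap)
        assert list(obs.index) == ["m1"]
        assert obs.loc["m1", "increment"] == pytest.approx(18 - 11)
        assert obs.loc["m1", "extra_perfect"] == 2
        assert obs.loc["m1", "n_1bp"] == 2

    def test_clean_guides_and_orphan_genes_excluded(self):
        bf = pd.Series([5.0, 9.0, 7.0],
                       index=pd.Index(["c1", "m1", "m2"], name="GUIDE"))
        genes = pd.Series(["A", "A", "B"], index=bf.index)
        tmap = target_map({"c1": (1, 0, 1, 0), "m1": (2, 0, 1, 0),
                           "m2": (2, 0, 1, 0)})  # gene B has no clean guide
        obs = compute_increments(bf, genes, tmap)
        assert list(obs.index) == ["m1"]

    def test_guides_with_coding_mismatch_hits_excluded(self):
        bf = pd.Series([5.0, 9.0], index=pd.Index(["c1", "m1"], name="GUIDE"))
        genes = pd.Series(["A", "A"], index=bf.index)
        tmap = target_map({"c1": (1, 0, 1, 0), "m1": (2, 3, 1, 1)})
        assert compute_increments(bf, genes, tmap).empty

    def test_additive_model_increments_recovered_noise_free(self):
        # guides built to obey increment = (n_perfect-1)*tp_p + n_1bp*tp_1
        tp_p, tp_1 = 3.5, 1.4
        rows, bfs, genes = {}, {}, {}
        for i, (e, n) in enumerate([(0, 0), (2, 1), (4, 0), (0, 3), (1, 5)]):
            g_clean, g_multi = f"c{i}", f"m{i}"
            rows[g_clean] = (1, 0, 1, 0)
            rows[g_multi] = (1 + e, n, 1, 0)
            bfs[g_clean] = 10.0
            bfs[g_multi] = 10.0 + e * tp_p + n * tp_1
            genes[g_clean] = genes[g_multi] = f"G{i}"
        bf = pd.Series(bfs)
        bf.index.name = "GUIDE"
        obs = compute_increments(bf, pd.Series(genes), target_map(rows))
        expected = obs["extra_perfect"] * tp_p + obs["n_1bp"] * tp_1
        np.testing.assert_allclose(obs["increment"], expected, atol=1e-12)


class TestOffTargetFit:
    def observations(self, tp_p, tp_1, n=500, noise_sd=0.0, seed=7):
        rng = np.random.default_rng(seed)
        e = rng.integers(0, 8, n)
        m = rng.integers(0, 9, n)
        keep = (e + m) > 0
        e, m = e[keep], m[keep]
        inc = e * tp_p + m * tp_1 + rng.normal(0, noise_sd, e.size)
        return pd.DataFrame({
            "GENE": "G", "increment": inc, "extra_perfect": e, "n_1bp": m,
        }, index=pd.Index([f"g{i}" for i in range(e.size)], name="GUIDE"))

    def test_noise_free_exact_recovery(self):
        fit = fit_offtarget_model(self.observations(3.5, 1.4))
        assert fit.tp_perfect == pytest.approx(3.5, abs=1e-9)
        assert fit.tp_1bp == pytest.approx(1.4, abs=1e-9)

    def test_noisy_recovery_matches_normal_equations_oracle(self):
        obs = self.observations(3.5, 1.4, n=500, noise_sd=1.0, seed=7)
        fit = fit_offtarget_model(obs)
        X = obs[["extra_perfect", "n_1bp"]].to_numpy(dtype=float)
        y = obs["increment"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.tp_perfect == pytest.approx(beta[0], abs=1e-9)
        assert fit.tp_1bp == pytest.approx(beta[1], abs=1e-9)
        assert fit.tp_perfect == pytest.approx(3.5, rel=0.10)
        assert fit.tp_1bp == pytest.approx(1.4, rel=0.10)

    def test_single_predictor_combination_rejected(self):
        obs = pd.DataFrame({
            "GENE": "G", "increment": [3.0, 3.1, 2.9],
            "extra_perfect": [1, 1, 1], "n_1bp": [2, 2, 2],
        }, index=pd.Index(["a", "b", "c"], name="GUIDE"))
        with pytest.raises(ValueError, match="predictor combination"):
            fit_offtarget_model(obs)

    def test_collinear_predictors_rejected(self):
        obs = pd.DataFrame({
            "GENE": "G", "increment": [1.0, 2.0, 3.0],
            "extra_perfect": [1, 2, 3], "n_1bp": [2, 4, 6],
        }, index=pd.Index(["a", "b", "c"], name="GUIDE"))
        with pytest.raises(ValueError, match="collinear"):
            fit_offtarget_model(obs)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_offtarget_model(self.observations(1, 1).head(2))

    def test_negative_coefficient_clamped_with_warning(self, caplog):
        obs = self.observations(-2.0, 1.0)
        with caplog.at_level("WARNING"):
            fit = fit_offtarget_model(obs)
        assert fit.tp_perfect == 0.0
        assert fit.raw_tp_perfect == pytest.approx(-2.0, abs=1e-9)
        assert any("clamped" in r.message for r in caplog.records)


class TestPenalty:
    def test_penalty_arithmetic(self):
        from crisprbf.multitarget import OffTargetModel
        bf = pd.Series([20.0], index=pd.Index(["g1"], name="GUIDE"))
        genes = pd.Series(["A"], index=bf.index)
        tmap = target_map({"g1": (3, 2, 1, 0)})
        model = OffTargetModel(3.5, 1.4, 10, 0.0, 3.5, 1.4)
        corrected, gene_bf = apply_penalty(bf, genes, tmap, model)
        assert corrected["g1"] == pytest.approx(20 - (2 * 3.5 + 2 * 1.4))
        assert gene_bf["A"] == pytest.approx(10.2)

    def test_clean_and_unmapped_guides_unchanged(self):
        from crisprbf.multitarget import OffTargetModel
        bf = pd.Series([4.0, 6.0], index=pd.Index(["g1", "gX"], name="GUIDE"))
        genes = pd.Series(["A", "B"], index=bf.index)
        tmap = target_map({"g1": (1, 0, 1, 0)})
        model = OffTargetModel(3.5, 1.4, 10, 0.0, 3.5, 1.4)
        corrected, _ = apply_penalty(bf, genes, tmap, model)
        pd.testing.assert_series_equal(corrected, bf)

    def test_zero_coefficient_model_is_identity(self):
        from crisprbf.multitarget import OffTargetModel
        bf = pd.Series([4.0, -2.0], index=pd.Index(["g1", "g2"], name="GUIDE"))
        genes = pd.Series(["A", "B"], index=bf.index)
        tmap = target_map({"g1": (5, 3, 1, 0), "g2": (2, 2, 1, 0)})
        model = OffTargetModel(0.0, 0.0, 10, 0.0, 0.0, 0.0)
        corrected, _ = apply_penalty(bf, genes, tmap, model)
        pd.testing.assert_series_equal(corrected, bf)

    def test_correction_is_identity_on_clean_library(self):
        from crisprbf.multitarget import OffTargetModel
        bf = pd.Series([4.0, -2.0, 7.0],
                       index=pd.Index(["g1", "g2", "g3"], name="GUIDE"))
        genes = pd.Series(["A", "B", "B"], index=bf.index)
        tmap = target_map({g: (1, 0, 1, 0) for g in bf.index})
        table = pd.DataFrame({"GENE": genes})
        filtered, report = filter_guides(table, tmap)
        assert report.empty and len(filtered) == 3
        model = OffTargetModel(3.5, 1.4, 10, 0.0, 3.5, 1.4)
        corrected, _ = apply_penalty(bf, genes, tmap, model)
        pd.testing.assert_series_equal(corrected, bf)
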