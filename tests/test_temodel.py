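"""Feature table assembly and two-round stepwise TE modeling."""

import numpy as np
import pandas as pd
import pytest

from tailscape import temodel


def _noise_design(rng, n, n_features, prefix="noise"):
    return pd.DataFrame(
        rng.normal(0, 1, (n, n_features)),
        index=[f"g{i}" for i in range(n)],
        columns=[f"{prefix}{j}" for j in range(n_features)],
    )


@pytest.fixture(scope="module")
def inputs():
    seqs = pd.DataFrame(
            {
                "utr5": ["ACGTACGTAC" * 5] * 2,
                "cds": ["ATG" + "GCC" * 99 + "TAA"] * 2,
                "utr3": ["ACGT" * 50, "ACGT" * 100],
        },
        index=["g1", "g2"],
    )
    folding = pd.DataFrame(
        {"fe_utr3_per_nt": [-0.2, -0.3], "fe_utr5_region": [-20.0, -30.0]},
        index=seqs.index,
    )
    tails = pd.Series([80.0, 95.0], seqs.index)
    expr = pd.Series([100.0, 50.0], seqs.index)
    return seqs, tails, expr, folding


class TestBuildFeatureTable:
    def test_isoform_weighted_utr3_length(self, inputs):
        seqs, tails, expr, folding = inputs
        iso = pd.DataFrame(
            {
                "gene": ["g1", "g1"],
                "utr3_length": [200.0, 400.0],
                "expression": [3.0, 1.0],
                "fe_per_nt": [-0.2, -0.2],
            }
        )
        table = temodel.build_feature_table(seqs, tails, expr, folding, isoform_utr3=iso)
        assert table.simple.loc["g1", "log_len_utr3"] == pytest.approx(np.log10(250.0))

    def test_mfe_per_nt_passthrough(self, inputs):
        seqs, tails, expr, folding = inputs
        table = temodel.build_feature_table(seqs, tails, expr, folding)
        # -50 kcal/mol over 250 nt corresponds to -0.2 per nt
        assert table.simple.loc["g1", "fe_utr3_per_nt"] == pytest.approx(-0.2)

    def test_complex_feature_inputs_present(self, inputs):
        table = temodel.build_feature_table(*inputs)
        names = [c.name for c in table.complexes]
        assert names == ["codon_composition", "utr5_motifs"]
        codon = table.complexes[0].matrix
        assert codon.loc["g1", "GCC"] == pytest.approx(99 / 100)


class TestSubfeatureModel:
    def test_perfect_linear_signal_gives_unit_heldout_r2(self):
        rng = np.random.default_rng(1)
        matrix = _noise_design(rng, 400, 20, prefix="c")
        beta = rng.normal(0, 1, 20)
        te = pd.Series(matrix.to_numpy() @ beta, matrix.index)
        train = matrix.index[:300]
        pred = temodel.fit_subfeature_model(matrix, te, train)
        test = matrix.index[300:]
        resid = te.loc[test] - pred.loc[test]
        assert 1 - resid.var() / te.loc[test].var() == pytest.approx(1.0, abs=1e-9)

    def test_null_subfeatures_give_no_heldout_r2(self):
        rng = np.random.default_rng(2)
        matrix = _noise_design(rng, 500, 30, prefix="c")
        te = pd.Series(rng.normal(0, 1, 500), matrix.index)
        train = matrix.index[:400]
        pred = temodel.fit_subfeature_model(matrix, te, train)
        test = matrix.index[400:]
        r = np.corrcoef(pred.loc[test], te.loc[test])[0, 1]
        assert abs(r) < 0.25

    def test_permuted_training_labels_destroy_signal(self):
        rng = np.random.default_rng(3)
        matrix = _noise_design(rng, 500, 10, prefix="c")
        te = pd.Series(matrix.to_numpy() @ rng.normal(0, 1, 10), matrix.index)
        shuffled = pd.Series(rng.permutation(te.to_numpy()), te.index)
        train = matrix.index[:400]
        pred = temodel.fit_subfeature_model(matrix, shuffled, train)
        test = matrix.index[400:]
        r = np.corrcoef(pred.loc[test], te.loc[test])[0, 1]
        assert abs(r) < 0.25


class TestStepwise:
    def test_informative_feature_selected_first_noise_mostly_excluded(self):
        rng = np.random.default_rng(4)
        design = _noise_design(rng, 2000, 10)
        design = design.rename(columns={"noise0": "real"})
        te = pd.Series(design["real"] + rng.normal(0, 1, 2000), design.index)
        order = temodel.stepwise_select(design, te)
        assert order[0] == "real"
        assert len(order) <= 4

    def test_pure_noise_selection_stops_early(self):
        rng = np.random.default_rng(5)
        design = _noise_design(rng, 1500, 10)
        te = pd.Series(rng.normal(0, 1, 1500), design.index)
        assert len(temodel.stepwise_select(design, te)) <= 2

    def test_duplicated_feature_enters_once(self):
        rng = np.random.default_rng(6)
        design = _noise_design(rng, 800, 3)
        design["dup"] = design["noise0"]
        te = pd.Series(design["noise0"] * 2 + rng.normal(0, 0.5, 800), design.index)
        order = temodel.stepwise_select(design, te)
        assert ("noise0" in order) != ("dup" in order)

    def test_selection_deterministic(self):
        rng = np.random.default_rng(7)
        design = _noise_design(rng, 1000, 8)
        te = pd.Series(design["noise1"] - design["noise3"] + rng.normal(0, 1, 1000),
                       design.index)
        assert temodel.stepwise_select(design, te) == temodel.stepwise_select(design, te)

    def test_needs_two_candidates(self):
        design = _noise_design(np.random.default_rng(8), 50, 1)
        with pytest.raises(ValueError, match=">= 2"):
            temodel.stepwise_select(design, pd.Series(np.zeros(50), design.index))


class TestFilterAndRefit:
    @pytest.fixture()
    def planted(self):
        rng = np.random.default_rng(9)
        design = _noise_design(rng, 3000, 12)
        design = design.rename(columns={"noise0": "strong", "noise1": "weak"})
        design["tail_length"] = rng.normal(90, 20, 3000)
        te = pd.Series(
            design["strong"] + 0.035 * design["weak"] + rng.normal(0, 1, 3000),
            design.index,
        )
        return design, te

    def test_weak_contributors_dropped_forced_kept(self, planted):
        design, te = planted
        round1 = temodel.stepwise_select(design, te)
        out = temodel.filter_and_refit(design, te, round1, forced=("tail_length",))
        # weak adds ~0.001 R^2: below the 0.003 bar
        assert "weak" not in out["round2"]
        assert "strong" in out["round2"]
        assert "tail_length" in out["round2"]

    def test_zero_delta_keeps_round1_menu(self, planted):
        design, te = planted
        round1 = temodel.stepwise_select(design, te)
        out = temodel.filter_and_refit(design, te, round1, delta_r2=0.0, forced=())
        assert set(out["menu"]) == set(round1)

    def test_missing_forced_feature_errors(self, planted):
        design, te = planted
        with pytest.raises(ValueError, match="forced"):
            temodel.filter_and_refit(design.drop(columns="tail_length"), te,
                                     ["strong"], forced=("tail_length",))


class TestEvaluate:
    def test_noiseless_planted_model_reaches_unit_r2(self):
        rng = np.random.default_rng(10)
        simple = _noise_design(rng, 600, 3, prefix="f")
        te = pd.Series(simple.to_numpy() @ np.array([1.0, -0.5, 0.25]), simple.index)
        table = temodel.FeatureTable(simple=simple)
        fit = temodel.evaluate_model(table, te, ["f0", "f1", "f2"], n_boot=10, seed=0)
        assert fit.heldout_r2_mean == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.cumulative_r2_mean) >= -1e-9)

    def test_same_seed_reproduces_cis(self):
        rng = np.random.default_rng(11)
        simple = _noise_design(rng, 300, 2, prefix="f")
        te = pd.Series(simple["f0"] + rng.normal(0, 1, 300), simple.index)
        table = temodel.FeatureTable(simple=simple)
        a = temodel.evaluate_model(table, te, ["f0", "f1"], n_boot=20, seed=5)
        b = temodel.evaluate_model(table, te, ["f0", "f1"], n_boot=20, seed=5)
        assert np.array_equal(a.cumulative_r2_ci, b.cumulative_r2_ci)

    def test_degenerate_split_rejected(self):
        simple = _noise_design(np.random.default_rng(12), 50, 2, prefix="f")
        te = pd.Series(np.zeros(50), simple.index)
        table = temodel.FeatureTable(simple=simple)
        with pytest.raises(ValueError, match="split"):
            temodel.evaluate_model(table, te, ["f0"], n_boot=5, split_fraction=1.0)


class TestCorrelationMatrix:
    def test_unit_diagonal_and_symmetry(self):
        rng = np.random.default_rng(13)
        feats = _noise_design(rng, 400, 4)
        corr = temodel.feature_correlation_matrix(feats)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(14)
        feats = _noise_design(rng, 5000, 4)
        corr = temodel.feature_correlation_matrix(feats).to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)

    def test_planted_correlation_sign_recovered(self):
        rng = np.random.default_rng(15)
        utr3 = rng.normal(0, 1, 1000)
        tail = 0.5 * utr3 + rng.normal(0, 1, 1000)
        feats = pd.DataFrame({"log_len_utr3": utr3, "tail_length": tail})
        corr = temodel.feature_correlation_matrix(feats)
        assert corr.loc["log_len_utr3", "tail_length"] > 0.2

    def test_constant_feature_reported_missing(self):
        feats = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        corr = temodel.feature_correlation_matrix(feats)
        assert np.isnan(corr.loc["b", "a"])
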