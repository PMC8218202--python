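"""Feature assembly, gene selection, grid prediction, biomarker ranking."""

import numpy as np
import pandas as pd
import pytest

from synscreen import (
    InvalidInputError,
    build_features,
    dose_grid,
    predict_grid,
    rank_biomarkers,
    select_variant_genes,
    train_bundle,
    train_model,
)
from synscreen.predict import LookupFeatureError, fingerprints_from_smiles
from synscreen.simulate import simulate_screen


@pytest.fixture(scope="module")
def small_screen():
    return simulate_screen(40, seed=5, n_drugs=8, n_cells=5, n_genes=60,
                           noise_sd=3.0)


class TestSelectVariantGenes:
    def test_top_fraction_count(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(10, 1000)),
                            columns=[f"G{i:04d}" for i in range(1000)])
        assert len(select_variant_genes(expr, 0.05)) == 50

    def test_high_variance_genes_lead(self):
        rng = np.random.default_rng(1)
        cols = [f"G{i}" for i in range(20)]
        data = np.zeros((6, 20))
        loud = {"G3", "G7", "G11", "G15", "G19", "G2", "G5"}
        for j, c in enumerate(cols):
            if c in loud:
                data[:, j] = rng.normal(0, np.sqrt(10), 6)
        expr = pd.DataFrame(data, columns=cols)
        top = select_variant_genes(expr, 0.5)   # 10 genes
        assert loud <= set(top)

    def test_matches_brute_force_sort(self, small_screen):
        expr = small_screen.expression
        got = select_variant_genes(expr, 0.1)
        var = expr.to_numpy().var(axis=0, ddof=1)
        order = np.argsort(-var, kind="stable")
        want = list(expr.columns[order][: len(got)])
        assert got == want

    def test_constant_matrix_warns_empty(self):
        expr = pd.DataFrame(np.ones((4, 5)))
        with pytest.warns(UserWarning):
            assert select_variant_genes(expr) == []


class TestBuildFeatures:
    def test_one_row_per_well_and_determinism(self, small_screen):
        genes = select_variant_genes(small_screen.expression, 0.1)
        X, Y = build_features(small_screen.records, small_screen.fingerprints,
                              small_screen.expression, genes)
        assert len(X) == len(small_screen.records)
        assert "inhibition" in Y.columns
        X2, Y2 = build_features(small_screen.records, small_screen.fingerprints,
                                small_screen.expression, genes)
        pd.testing.assert_frame_equal(X, X2)
        pd.testing.assert_frame_equal(Y, Y2)

    def test_drug_slots_are_canonical(self, small_screen):
        recs = small_screen.records[:1]
        r = recs[0]
        swapped = [type(r)(block_id=r.block_id, drug_row=r.drug_col,
                           drug_col=r.drug_row, conc_r=r.conc_c,
                           conc_c=r.conc_r, response=r.response,
                           cell_line=r.cell_line)]
        genes = []
        Xa, _ = build_features(recs, small_screen.fingerprints,
                               small_screen.expression, genes)
        Xb, _ = build_features(swapped, small_screen.fingerprints,
                               small_screen.expression, genes)
        pd.testing.assert_frame_equal(Xa, Xb)

    def test_unknown_identifiers_named(self, small_screen):
        recs = small_screen.records[:4]
        drug = recs[0].drug_row
        with pytest.raises(LookupFeatureError, match=drug):
            build_features(recs, small_screen.fingerprints.drop(index=drug),
                           small_screen.expression, [])
        bad_expr = small_screen.expression.drop(index=recs[0].cell_line)
        with pytest.raises(LookupFeatureError, match=recs[0].cell_line):
            build_features(recs, small_screen.fingerprints, bad_expr, [])

    def test_synergy_targets_on_interior_wells_only(self, small_screen):
        recs = [r for r in small_screen.records if r.block_id == "B00000"]
        X, Y = build_features(recs, small_screen.fingerprints,
                              small_screen.expression, [],
                              targets=("inhibition", "bliss"))
        interior = np.array([r.conc_r > 0 and r.conc_c > 0 for r in recs])
        assert np.isfinite(Y["bliss"][interior]).all()
        assert Y["bliss"][~interior].isna().all()


class TestTrainModel:
    def test_constant_target_learned(self, small_screen):
        genes = []
        X, _ = build_features(small_screen.records[:200],
                              small_screen.fingerprints,
                              small_screen.expression, genes)
        model = train_model(X, np.full(len(X), 37.5))
        assert np.allclose(model.predict(X), 37.5, atol=1e-6)

    def test_length_mismatch_rejected(self, small_screen):
        X, _ = build_features(small_screen.records[:10],
                              small_screen.fingerprints,
                              small_screen.expression, [])
        with pytest.raises(InvalidInputError):
            train_model(X, [1.0, 2.0])

    def test_seeded_retraining_identical(self, small_screen):
        genes = select_variant_genes(small_screen.expression, 0.1)
        X, Y = build_features(small_screen.records, small_screen.fingerprints,
                              small_screen.expression, genes)
        m1 = train_model(X, Y["inhibition"], seed=3)
        m2 = train_model(X, Y["inhibition"], seed=3)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestPredictGrid:
    def test_dose_axis_construction(self):
        d = dose_grid(50.0)
        assert d.size == 10
        assert d[-1] == 50.0
        assert np.allclose(np.diff(d), 5.0)
        assert d[0] > 0
        with pytest.raises(InvalidInputError):
            dose_grid(-1.0)

    def test_grid_shape_and_finiteness(self, small_screen):
        bundle = train_bundle(small_screen.records, small_screen.fingerprints,
                              small_screen.expression, seed=0,
                              hyperparams={"n_trees": 50})
        grids = predict_grid(bundle, "D001", "D002", 10.0, 20.0, "CL001")
        assert grids["inhibition"].shape == (10, 10)
        assert np.isfinite(grids["inhibition"]).all()
        assert grids["doses_a"][-1] == 10.0 and grids["doses_b"][-1] == 20.0

    def test_unknown_drug_rejected(self, small_screen):
        bundle = train_bundle(small_screen.records[:72],
                              small_screen.fingerprints,
                              small_screen.expression, seed=0,
                              hyperparams={"n_trees": 10})
        with pytest.raises(LookupFeatureError, match="Dxx"):
            predict_grid(bundle, "Dxx", "D002", 10.0, 20.0, "CL001")

    def test_bundle_save_load_round_trip(self, small_screen, tmp_path):
        bundle = train_bundle(small_screen.records[:360],
                              small_screen.fingerprints,
                              small_screen.expression, seed=0,
                              hyperparams={"n_trees": 20})
        path = tmp_path / "m.joblib"
        bundle.save(path)
        from synscreen import ModelBundle

        loaded = ModelBundle.load(path)
        a = predict_grid(bundle, "D001", "D002", 10.0, 20.0, "CL001")
        b = predict_grid(loaded, "D001", "D002", 10.0, 20.0, "CL001")
        np.testing.assert_array_equal(a["inhibition"], b["inhibition"])


class TestSimulationRecovery:
    def test_holdout_r2_on_inhibition(self):
        """Predictor recovers the generator's dose-response structure."""
        screen = simulate_screen(150, seed=17, n_drugs=10, n_cells=6,
                                 n_genes=80, noise_sd=5.0)
        genes = select_variant_genes(screen.expression, 0.05)
        X, Y = build_features(screen.records, screen.fingerprints,
                              screen.expression, genes)
        rng = np.random.default_rng(17)
        test = rng.random(len(X)) < 0.2
        model = train_model(X[~test], Y["inhibition"][~test], seed=17)
        pred = model.predict(X[test])
        truth = Y["inhibition"][test].to_numpy()
        ss_res = np.sum((pred - truth) ** 2)
        ss_tot = np.sum((truth - truth.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.8


class TestRankBiomarkers:
    def test_self_correlated_gene_ranks_first(self):
        rng = np.random.default_rng(0)
        cells = [f"C{i}" for i in range(12)]
        sens = pd.Series(rng.normal(50, 15, 12), index=cells)
        expr = pd.DataFrame(rng.normal(size=(12, 30)), index=cells,
                            columns=[f"G{i}" for i in range(30)])
        expr["G7"] = sens.to_numpy()
        table = rank_biomarkers(expr, sens)
        assert table.iloc[0]["gene"] == "G7"
        assert table.iloc[0]["r"] == pytest.approx(1.0)

    def test_constant_gene_flagged(self):
        rng = np.random.default_rng(1)
        cells = [f"C{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(8, 5)), index=cells,
                            columns=list("abcde"))
        expr["c"] = 3.0
        table = rank_biomarkers(expr, pd.Series(rng.normal(size=8), index=cells))
        row = table[table["gene"] == "c"].iloc[0]
        assert row["zero_variance"]
        assert np.isnan(row["r"])

    def test_correlations_match_direct_formula(self):
        rng = np.random.default_rng(2)
        cells = [f"C{i}" for i in range(15)]
        expr = pd.DataFrame(rng.normal(size=(15, 20)), index=cells,
                            columns=[f"G{i}" for i in range(20)])
        sens = pd.Series(rng.normal(size=15), index=cells)
        table = rank_biomarkers(expr, sens).set_index("gene")
        s = sens.to_numpy()
        for g in expr.columns:
            e = expr[g].to_numpy()
            oracle = (((e - e.mean()) * (s - s.mean())).sum()
                      / np.sqrt(((e - e.mean())**2).sum() * ((s - s.mean())**2).sum()))
            assert table.loc[g, "r"] == pytest.approx(oracle, abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        expr = pd.DataFrame(np.ones((2, 3)), index=["a", "b"])
        with pytest.raises(InvalidInputError):
            rank_biomarkers(expr, pd.Series([1.0, 2.0], index=["a", "b"]))

    def test_planted_signal_recovered(self):
        """Gene = sensitivity + small noise lands in the top 10 of 500."""
        hits = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cells = [f"C{i}" for i in range(20)]
            sens = pd.Series(rng.normal(50, 20, 20), index=cells)
            expr = pd.DataFrame(rng.normal(size=(20, 500)), index=cells,
                                columns=[f"G{i:03d}" for i in range(500)])
            expr["G250"] = (sens - sens.mean()) / sens.std() \
                + rng.normal(0, 0.3, 20)
            table = rank_biomarkers(expr, sens)
            if "G250" in set(table["gene"].head(10)):
                hits += 1
        assert hits >= 0.95 * n_seeds


class TestFingerprints:
    def test_maccs_from_smiles(self):
        fp = fingerprints_from_smiles({"aspirin": "CC(=O)Oc1ccccc1C(=O)O",
                                       "ethanol": "CCO"})
        assert fp.shape == (2, 166)
        assert set(fp.to_numpy().ravel()) <= {0, 1}
        assert fp.loc["aspirin"].sum() > fp.loc["ethanol"].sum()

    def test_bad_smiles_rejected(self):
        with pytest.raises(InvalidInputError, match="junk"):
            fingerprints_from_smiles({"junk": "not-a-smiles(("})
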