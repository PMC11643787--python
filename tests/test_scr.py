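"""Self-consistent regression, RBF-SCR, consensus assembly, LMO, stability."""

import numpy as np
import pandas as pd
import pytest

import loxqsar as lq
from loxqsar.consensus import (
    build_consensus,
    lmo_cross_validation,
    predict,
    stability,
    stability_class,
)
from loxqsar.molgraph import Atom, MolecularGraph
from loxqsar.scr import SCRConfig, fit_rbf_scr, fit_scr


def named_frame(arr):
    return pd.DataFrame(arr, columns=[f"x{i}" for i in range(arr.shape[1])])


class TestFitScr:
    def test_noiseless_identifiability(self):
        rng = np.random.default_rng(3)
        X = named_frame(rng.normal(size=(60, 10)))
        y = (2.0 * X["x1"] - 1.5 * X["x4"] + 0.8 * X["x7"]).to_numpy()
        m = fit_scr(X, y)
        assert set(m.columns) == {"x1", "x4", "x7"}
        recovered = dict(zip(m.columns, m.coef))
        assert recovered["x1"] == pytest.approx(2.0, abs=1e-6)
        assert recovered["x4"] == pytest.approx(-1.5, abs=1e-6)
        assert recovered["x7"] == pytest.approx(0.8, abs=1e-6)

    def test_planted_signal_survives_noise_columns(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = named_frame(rng.normal(size=(100, 23)))
            y = (X["x0"] - 2.0 * X["x1"] + 1.5 * X["x2"]).to_numpy() + rng.normal(0, 0.1, 100)
            m = fit_scr(X, y)
            hits += {"x0", "x1", "x2"} <= set(m.columns)
        assert hits >= 95

    def test_too_few_rows(self):
        X = named_frame(np.ones((4, 2)))
        with pytest.raises(ValueError):
            fit_scr(X, np.arange(4.0))

    def test_intercept_only_when_nothing_significant(self):
        rng = np.random.default_rng(5)
        X = named_frame(rng.normal(size=(40, 3)))
        y = rng.normal(size=40)  # unrelated response
        m = fit_scr(X, y, SCRConfig(t_threshold=6.0))
        assert m.columns == []
        assert any("intercept-only" in f for f in m.flags)
        assert np.allclose(m.predict(X), y.mean())

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = named_frame(rng.normal(size=(50, 8)))
        y = X["x0"].to_numpy() + rng.normal(0, 0.2, 50)
        a, b = fit_scr(X, y), fit_scr(X, y)
        assert a.columns == b.columns
        assert np.array_equal(a.coef, b.coef)

    def test_orthonormal_design_matches_all_subsets_elimination(self):
        """On an orthonormal design SCR reduces to |t|-threshold selection;
        cross-check against an independent OLS-based elimination oracle."""
        rng = np.random.default_rng(11)
        n, p = 32, 6
        raw = rng.normal(size=(n, p))
        raw -= raw.mean(axis=0)
        Q, _ = np.linalg.qr(raw)
        X = named_frame(Q)
        w = np.array([1.0, 0.0, -0.8, 0.0, 0.5, 0.0])
        y = Q @ w + rng.normal(0, 0.05, n)

        # oracle: plain OLS backward elimination with lstsq-refits
        active = list(range(p))
        while active:
            Xa = Q[:, active]
            coef, *_ = np.linalg.lstsq(Xa, y - y.mean(), rcond=None)
            resid = (y - y.mean()) - Xa @ coef
            df = n - len(active) - 1
            sigma2 = float(resid @ resid) / df
            se = np.sqrt(sigma2 * np.diag(np.linalg.inv(Xa.T @ Xa)))
            t = np.abs(coef) / se
            if t.min() >= 2.0:
                break
            active.pop(int(np.argmin(t)))
        oracle_cols = {f"x{j}" for j in active}

        m = fit_scr(X, y)
        assert set(m.columns) == oracle_cols


class TestFitRbfScr:
    def test_interpolates_training_data_with_negligible_ridge(self):
        rng = np.random.default_rng(13)
        X = named_frame(rng.normal(size=(50, 10)))
        y = (2.0 * X["x1"] - 1.5 * X["x4"] + 0.8 * X["x7"]).to_numpy()
        m = fit_rbf_scr(X, y, SCRConfig(rbf_ridge=1e-12))
        assert np.abs(m.predict(X) - y).max() < 1e-6

    def test_shares_selection_with_scr(self):
        rng = np.random.default_rng(17)
        X = named_frame(rng.normal(size=(60, 8)))
        y = (2 * X["x2"] - X["x5"]).to_numpy() + rng.normal(0, 0.1, 60)
        assert fit_rbf_scr(X, y).columns == fit_scr(X, y).columns

    def test_beats_linear_model_on_smooth_nonlinearity(self):
        rng = np.random.default_rng(19)
        X = named_frame(rng.uniform(-2, 2, size=(80, 4)))
        y = np.sin(2.0 * X["x0"].to_numpy()) + rng.normal(0, 0.05, 80)
        linear = fit_scr(X, y, SCRConfig(t_threshold=1.0))
        rbf = fit_rbf_scr(X, y, SCRConfig(t_threshold=1.0, rbf_ridge=1e-6))
        assert rbf.r2 > linear.r2

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(23)
        X = named_frame(rng.normal(size=(30, 4)))
        y = X["x0"].to_numpy() + rng.normal(0, 0.1, 30)
        m = fit_rbf_scr(X, y)
        m2 = lq.PartialModel.from_dict(m.to_dict())
        assert np.allclose(m2.predict(X), m.predict(X))


class TestConsensus:
    def test_partial_structure_single_family(self, trs1):
        m = build_consensus(trs1, method="SCR", families="QNA", n_partials=20, seed=2)
        assert len(m.partials) == 20
        assert all(p.family == "QNA" and p.method == "SCR" for p in m.partials)

    def test_mixed_families_split_evenly(self, trs1):
        m = build_consensus(trs1, method="Both", families="both", n_partials=8, seed=2)
        fams = [p.family for p in m.partials]
        meths = [p.method for p in m.partials]
        assert fams.count("QNA") == fams.count("MNA") == 4
        assert meths.count("SCR") == meths.count("RBF-SCR") == 4

    def test_single_partial_consensus_equals_partial(self, trs1):
        m = build_consensus(trs1, method="SCR", families="QNA", n_partials=1, seed=3)
        res = predict(m, trs1.structures[:5], ids=trs1.ids[:5])
        X = m.featurizer.transform(trs1.structures[:5], "QNA")
        direct = m.partials[0].predict(X)
        assert [r.predicted for r in res] == pytest.approx(direct.tolist())
        assert all(r.spread == 0 for r in res)

    def test_prediction_permutation_invariant_in_partials(self, trs1):
        m = build_consensus(trs1, method="SCR", families="QNA", n_partials=6, seed=4)
        res1 = predict(m, trs1.structures[:3], ids=trs1.ids[:3])
        m.partials = m.partials[::-1]
        res2 = predict(m, trs1.structures[:3], ids=trs1.ids[:3])
        assert [r.predicted for r in res1] == pytest.approx([r.predicted for r in res2])

    def test_training_compounds_in_domain(self, trs1):
        m = build_consensus(trs1, method="SCR", families="QNA", n_partials=4, seed=5)
        res = predict(m, trs1.structures[:10], ids=trs1.ids[:10])
        assert all(r.in_ad for r in res)

    def test_alien_molecule_out_of_domain(self, trs1):
        m = build_consensus(trs1, method="SCR", families="QNA", n_partials=4, seed=5)
        # iodine chain: valid elements but MNA sets disjoint from training
        alien = lq.read_structures("ICl", "smiles")[0]
        res = predict(m, [alien])
        assert not res[0].in_ad
        assert res[0].predicted is None

    def test_precondition_enforced(self):
        flat = lq.ActivityDataSet([
            lq.ActivityRecord(f"c{i}", 5.0 + 0.01 * i,
                              structure=MolecularGraph([Atom("C")], []))
            for i in range(10)
        ])
        with pytest.raises(ValueError, match="range"):
            build_consensus(flat)

    def test_archive_round_trip(self, trs1, tmp_path):
        m = build_consensus(trs1, method="Both", families="both", n_partials=4, seed=6)
        path = tmp_path / "model.json"
        m.save(path)
        m2 = lq.ConsensusModel.load(path)
        r1 = predict(m, trs1.structures[:4], ids=trs1.ids[:4])
        r2 = predict(m2, trs1.structures[:4], ids=trs1.ids[:4])
        assert [a.predicted for a in r1] == pytest.approx([b.predicted for b in r2])
        assert m2.summary == pytest.approx(m.summary, abs=1e-12)


class TestLmoCrossValidation:
    def test_noiseless_planted_data(self):
        rng = np.random.default_rng(29)
        X = named_frame(rng.normal(size=(60, 6)))
        y = (1.5 * X["x0"] - X["x3"]).to_numpy()
        assert lmo_cross_validation(X, y, seed=1) >= 0.99

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(31)
        X = named_frame(rng.normal(size=(50, 5)))
        y = X["x0"].to_numpy() + rng.normal(0, 0.3, 50)
        assert lmo_cross_validation(X, y, seed=9) == lmo_cross_validation(X, y, seed=9)

    def test_pure_noise_scores_low(self):
        low = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            X = named_frame(rng.normal(size=(60, 10)))
            y = rng.normal(size=60)
            low += lmo_cross_validation(X, y, seed=seed) <= 0.2
        assert low >= 19

    def test_constant_response_rejected(self):
        X = named_frame(np.random.default_rng(0).normal(size=(20, 3)))
        with pytest.raises(ValueError):
            lmo_cross_validation(X, np.ones(20))


class TestStability:
    @pytest.mark.parametrize("r2,q2,expected", [
        (0.825, 0.758, 0.067),
        (0.996, 0.753, 0.243),
        (0.5, 0.5, 0.0),
    ])
    def test_difference(self, r2, q2, expected):
        assert stability(r2, q2) == pytest.approx(expected)

    @pytest.mark.parametrize("a,cls", [
        (0.05, "high"), (0.15, "acceptable"), (0.25, "low"), (0.35, "unstable"),
    ])
    def test_classification_bands(self, a, cls):
        assert stability_class(a) == cls

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stability(1.5, 0.5)
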