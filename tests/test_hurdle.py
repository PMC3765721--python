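"""Design construction and the two-step logistic / log-linear fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from teexon import hurdle
from teexon.annotation import TEExonFeature


def feat(eid="e", location="CDS", family="Alu", eln=100, rte=0.5):
    return TEExonFeature(exon_id=eid, location=location, family=family,
                         eln=eln, rte=rte)


class TestDesign:
    def test_indicator_row(self):
        X = hurdle.build_design([feat(location="UTR5", family="MIR",
                                      eln=100, rte=0.8)])
        row = X.iloc[0]
        assert row["UTR5"] == 1 and row["UTR3"] == 0
        assert row["MIR"] == 1 and row["L1"] == 0
        assert row["log10ELN"] == pytest.approx(2.0)
        assert row["RTE"] == pytest.approx(0.8)

    def test_baseline_row_is_all_zero_indicators(self):
        X = hurdle.build_design([feat(location="CDS", family="Alu",
                                      eln=10, rte=0.0)])
        row = X.iloc[0]
        assert row["intercept"] == 1
        assert row[list(X.columns[1:11])].sum() == 0
        assert row["log10ELN"] == pytest.approx(1.0)

    def test_excluded_family_is_an_error(self):
        with pytest.raises(ValueError, match="excluded"):
            hurdle.build_design([feat(family="CR1")])

    def test_column_order_fixed(self):
        X = hurdle.build_design([feat()])
        assert tuple(X.columns) == hurdle.DESIGN_COLUMNS


def _random_design(rng, n):
    locations = rng.choice(["CDS", "UTR3", "UTR5"], size=n, p=[0.6, 0.2, 0.2])
    families = rng.choice(["Alu", "ERV1", "ERVL", "L1", "L2", "MaLR",
                           "MER1", "MER2", "MIR"], size=n)
    return hurdle.build_design([
        feat(f"e{i}", locations[i], families[i],
             int(rng.integers(60, 500)), float(rng.uniform(0, 1)))
        for i in range(n)])


class TestModel1:
    def test_intercept_only_closed_form(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        z = [1] * 7 + [0] * 3
        table = hurdle.fit_model1(X, z)
        assert table.loc["intercept", "estimate"] == pytest.approx(
            np.log(7 / 3), abs=1e-6)

    def test_degenerate_response(self):
        X = pd.DataFrame({"intercept": np.ones(5)})
        with pytest.raises(ValueError, match="degenerate"):
            hurdle.fit_model1(X, [1, 1, 1, 1, 1])

    def test_duplicated_data_halves_variance(self):
        rng = np.random.default_rng(0)
        X = _random_design(rng, 120)[["intercept", "log10ELN", "RTE"]]
        z = (rng.random(120) < 0.5).astype(int)
        one = hurdle.fit_model1(X, z)
        two = hurdle.fit_model1(pd.concat([X, X]), np.concatenate([z, z]))
        assert np.allclose(one["estimate"], two["estimate"], atol=1e-6)
        assert np.allclose(one["se"] / np.sqrt(2), two["se"], rtol=1e-6)

    def test_matches_generic_likelihood_maximizer(self):
        """Newton fit equals a generic numerical Bernoulli-ML optimum."""
        rng = np.random.default_rng(1)
        X = _random_design(rng, 180)
        lp = -0.3 + 0.8 * X["UTR5"] - 1.2 * X["RTE"]
        z = (rng.random(180) < 1 / (1 + np.exp(-lp))).astype(int)
        table = hurdle.fit_model1(X, z)
        A = X.to_numpy()

        def nll(beta):
            eta = A @ beta
            return float(np.sum(np.log1p(np.exp(eta)) - z * eta))

        res = optimize.minimize(nll, np.zeros(A.shape[1]), method="BFGS",
                                options={"gtol": 1e-12, "maxiter": 2000})
        assert np.allclose(table["estimate"], res.x, atol=1e-6)

    def test_separation_detected(self):
        X = pd.DataFrame({"intercept": np.ones(20),
                          "x": np.r_[np.zeros(10), np.ones(10)]})
        z = np.r_[np.zeros(10), np.ones(10)]
        with pytest.raises(hurdle.SeparationError):
            hurdle.fit_model1(X, z)


class TestModel2:
    def test_exact_line(self):
        X = pd.DataFrame({"intercept": [1.0, 1, 1], "x": [0.0, 1, 2]})
        table, resid = hurdle.fit_model2(X, 10.0 ** np.array([0.0, 1, 2]))
        assert table.loc["x", "estimate"] == pytest.approx(1.0, abs=1e-9)
        assert table.loc["intercept", "estimate"] == pytest.approx(0, abs=1e-9)
        assert np.allclose(resid, 0, atol=1e-9)

    def test_constant_response(self):
        rng = np.random.default_rng(2)
        X = _random_design(rng, 200)
        table, _ = hurdle.fit_model2(X, np.full(200, 2.5))
        non_int = table.drop(index="intercept")["estimate"]
        assert np.allclose(non_int, 0, atol=1e-9)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        X = _random_design(rng, 150)
        y = rng.lognormal(0, 0.5, size=150)
        table, _ = hurdle.fit_model2(X, y)
        A = X.to_numpy()
        beta = np.linalg.solve(A.T @ A, A.T @ np.log10(y))
        assert np.allclose(table["estimate"], beta, atol=1e-9)

    def test_singular_design_names_columns(self):
        X = pd.DataFrame({"intercept": np.ones(30),
                          "a": np.arange(30.0),
                          "b": 2 * np.arange(30.0)})
        with pytest.raises(ValueError, match="collinear"):
            hurdle.fit_model2(X, np.ones(30) + np.arange(30.0))

    def test_underdetermined_is_an_error(self):
        X = pd.DataFrame(np.eye(3), columns=["a", "b", "c"])
        with pytest.raises(ValueError, match="observations"):
            hurdle.fit_model2(X, [1.0, 2.0, 3.0])

    def test_requires_positive_response_for_log(self):
        X = pd.DataFrame({"intercept": np.ones(20),
                          "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="positive"):
            hurdle.fit_model2(X, np.r_[0.0, np.ones(19)])


class TestTwoStep:
    def test_observation_count_nesting(self, study):
        # full-size datasets: both steps estimable, counts nested
        for res in study:
            fit = res["fit"]
            assert fit.n2 <= fit.n1
            assert fit.model1 is not None and fit.model2 is not None

    def test_all_expressed_degenerates_gracefully(self, small_dataset,
                                                  small_samples):
        s = small_samples[0]
        forced = s.exon_counts.copy()
        forced[forced == 0] = 1          # every exon now has a read
        rescaled = s.rescaled.copy()
        rescaled[rescaled == 0] = 1e-3   # consistent tiny positive level
        import dataclasses
        s2 = dataclasses.replace(s, exon_counts=forced, rescaled=rescaled)
        fit = hurdle.two_step_fit(s2, small_dataset.annotation)
        assert fit.model1 is None
        assert any("model1" in n for n in fit.notes)
        assert fit.model2 is not None


class TestSummaryModels:
    def test_noiseless_median_model_recovers_truth(self):
        rng = np.random.default_rng(4)
        X = _random_design(rng, 200)
        beta = pd.Series(0.0, index=X.columns)
        beta[["intercept", "UTR5", "MIR", "log10ELN", "RTE"]] = \
            [-0.5, 0.4, 0.7, -0.3, -0.8]
        m = 10.0 ** (X @ beta)
        disp = pd.DataFrame({"m": m, "v": np.full(200, 50.0),
                             "n_expressed_samples": 26}, index=X.index)
        # rebuild features identical to the design rows
        feats = _features_from_design(X)
        annot = _AnnotStub({f.exon_id: f for f in feats})
        fit_m, fit_v = hurdle.fit_summary_models(disp, annot)
        assert np.allclose(fit_m.model2["estimate"], beta, atol=1e-6)
        non_int = fit_v.model2.drop(index="intercept")["estimate"]
        assert np.allclose(non_int, 0, atol=1e-8)

    def test_opposite_planted_signs_recovered(self):
        """Level-raising covariates planted to lower dispersion come out
        with opposite signs in the two summary fits."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = _random_design(rng, 300)
            m = 10.0 ** (-0.5 + 0.6 * X["MIR"] - 0.8 * X["RTE"]
                         + rng.normal(0, 0.2, 300))
            v = (120 - 40 * X["MIR"] + 60 * X["RTE"]
                 + rng.normal(0, 15, 300))
            disp = pd.DataFrame({"m": m, "v": v,
                                 "n_expressed_samples": 26}, index=X.index)
            feats = _features_from_design(X)
            annot = _AnnotStub({f.exon_id: f for f in feats})
            fit_m, fit_v = hurdle.fit_summary_models(disp, annot)
            ok = (fit_m.model2.loc["MIR", "estimate"] > 0
                  > fit_v.model2.loc["MIR", "estimate"]
                  and fit_m.model2.loc["RTE", "estimate"] < 0
                  < fit_v.model2.loc["RTE", "estimate"])
            hits += ok
        assert hits >= 18


class _AnnotStub:
    def __init__(self, features):
        self.te_features = features


def _features_from_design(X: pd.DataFrame):
    feats = []
    for eid, row in X.iterrows():
        location = "UTR3" if row["UTR3"] else ("UTR5" if row["UTR5"] else "CDS")
        family = "Alu"
        for fam in ("ERV1", "ERVL", "L1", "L2", "MaLR", "MER1", "MER2", "MIR"):
            if row[fam]:
                family = fam
        feats.append(feat(eid, location, family,
                          int(round(10 ** row["log10ELN"])), row["RTE"]))
    return feats


@pytest.mark.parametrize("coef,p,expected", [
    (2.1, 0.003, "pos p<0.01"),
    (-0.4, 0.2, "ns"),
    (-0.4, 0.049, "neg p<0.05"),
    (0.4, 0.05, "ns"),
    (-1.0, 0.01, "neg p<0.05"),
])
def test_discretize_p(coef, p, expected):
    assert hurdle.discretize_p(coef, p) == expected


def test_discretize_p_rejects_invalid():
    with pytest.raises(ValueError):
        hurdle.discretize_p(1.0, 1.5)
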