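import numpy as np
import pandas as pd
import pytest

from rfinet import mixed_model as mm
from rfinet.datatypes import ValidationError

from conftest import balanced_meta, simulate_mixed_model_y

TRUTH = {"G": 1.0, "GT": 0.5, "GA": 0.25, "GS": 0.1, "e": 0.5}


def moment_estimates(Y, meta):
    """Independent oracle: regress empirical between-sample covariances on
    shared-factor indicators.

    Cov(y_s, y_s') within gene = G + GT*[same tissue] + GA*[same animal]
    + GS*[same sire] + e*[same sample]; least squares over all sample pairs
    gives a method-of-moments estimator that never touches the REML path.
    """
    values = Y.to_numpy(float)
    meta = meta.loc[Y.columns]
    n = values.shape[1]
    centred = values - values.mean(axis=0, keepdims=True)
    C = centred.T @ centred / (values.shape[0] - 1)
    same_t = (meta["tissue"].to_numpy()[:, None] == meta["tissue"].to_numpy()[None, :])
    same_a = (meta["animal"].to_numpy()[:, None] == meta["animal"].to_numpy()[None, :])
    same_s = (meta["sire_group"].to_numpy()[:, None] == meta["sire_group"].to_numpy()[None, :])
    same_sample = np.eye(n, dtype=bool)
    X = np.column_stack([
        np.ones(n * n),
        same_t.ravel().astype(float),
        same_a.ravel().astype(float),
        same_s.ravel().astype(float),
        same_sample.ravel().astype(float),
    ])
    beta, *_ = np.linalg.lstsq(X, C.ravel(), rcond=None)
    return dict(zip(("G", "GT", "GA", "GS", "e"), beta))


class TestFitVarianceComponents:
    def test_constant_response(self, meta80):
        Y = pd.DataFrame(3.25, index=[f"g{i}" for i in range(20)], columns=meta80.index)
        fit = mm.fit_variance_components(Y, meta80)
        assert fit.converged
        assert fit.mu == pytest.approx(3.25)
        assert all(v == 0.0 for v in fit.varcomp.values())

    def test_recovery_small(self, meta80):
        rng = np.random.default_rng(10)
        Y = simulate_mixed_model_y(meta80, 300, TRUTH, rng)
        fit = mm.fit_variance_components(Y, meta80)
        assert fit.converged
        for name, truth in TRUTH.items():
            assert fit.varcomp[name] == pytest.approx(truth, rel=0.5), name
        assert fit.mu == pytest.approx(2.0, abs=0.3)

    def test_moment_oracle_agreement(self, meta80):
        # both estimators are consistent and share the data, so in the
        # interior of the parameter space they agree much more tightly
        # than either agrees with the truth
        rng = np.random.default_rng(21)
        big = {"G": 1.0, "GT": 0.8, "GA": 0.6, "GS": 0.5, "e": 0.7}
        Y = simulate_mixed_model_y(meta80, 600, big, rng)
        fit = mm.fit_variance_components(Y, meta80)
        mom = moment_estimates(Y, meta80)
        for name in mm.COMPONENTS:
            assert fit.varcomp[name] == pytest.approx(mom[name], rel=0.10), name

    def test_gene_reordering_invariance(self, meta80):
        rng = np.random.default_rng(3)
        Y = simulate_mixed_model_y(meta80, 50, TRUTH, rng)
        fit1 = mm.fit_variance_components(Y, meta80)
        fit2 = mm.fit_variance_components(Y.iloc[::-1], meta80)
        for name in mm.COMPONENTS:
            assert fit1.varcomp[name] == pytest.approx(fit2.varcomp[name], rel=1e-4)

    def test_nonnegative_components(self, meta80):
        rng = np.random.default_rng(4)
        # no gene x sire signal at all: GS should pin at (or clamp to) zero
        Y = simulate_mixed_model_y(meta80, 100, {**TRUTH, "GS": 0.0}, rng)
        fit = mm.fit_variance_components(Y, meta80)
        assert all(v >= 0 for v in fit.varcomp.values())
        assert fit.varcomp["GS"] < 0.05

    def test_degenerate_design_raises(self):
        meta = balanced_meta(2, tissues=["muscle"])
        Y = pd.DataFrame(np.random.default_rng(0).normal(size=(20, len(meta))),
                         columns=meta.index)
        with pytest.raises(ValidationError):
            mm.fit_variance_components(Y, meta)

    def test_nonfinite_raises(self, meta80):
        Y = pd.DataFrame(np.nan, index=["g1", "g2"], columns=meta80.index)
        with pytest.raises(ValidationError):
            mm.fit_variance_components(Y, meta80)


class TestBlups:
    def test_blups_sum_to_zero(self, meta80):
        rng = np.random.default_rng(5)
        Y = simulate_mixed_model_y(meta80, 100, TRUTH, rng)
        fit = mm.fit_variance_components(Y, meta80)
        sols = mm.solve_blups(Y, meta80, fit)
        # balanced data: solutions for each factor sum ~0 over genes x levels
        assert abs(sols.G.sum()) / (abs(sols.G).sum() + 1e-12) < 1e-6
        for frame in (sols.GT, sols.GA, sols.GS):
            total = np.abs(frame.to_numpy()).sum() + 1e-12
            assert abs(frame.to_numpy().sum()) / total < 1e-6

    def test_identical_groups_give_zero_gs(self, meta80):
        rng = np.random.default_rng(6)
        half = simulate_mixed_model_y(meta80, 40, TRUTH, rng)
        Y = half.copy()
        # mirror low-group values onto the high group animal-by-animal
        for t in meta80["tissue"].unique():
            for i in range(1, 9):
                Y[f"H{i:02d}_{t}"] = half[f"L{i:02d}_{t}"]
        fit = mm.fit_variance_components(Y, meta80)
        sols = mm.solve_blups(Y, meta80, fit)
        np.testing.assert_allclose(sols.GS.to_numpy(), 0.0, atol=1e-8)

    def test_no_shrinkage_limit(self, meta80):
        # sigma2_GS -> infinity: the sire contrast approaches the raw
        # difference of gene-level group means
        rng = np.random.default_rng(7)
        Y = simulate_mixed_model_y(meta80, 30, TRUTH, rng)
        fit = mm.fit_variance_components(Y, meta80)
        fit.varcomp = {**fit.varcomp, "GS": 1e8}
        sols = mm.solve_blups(Y, meta80, fit)
        low = meta80.index[meta80["sire_group"] == "low"]
        high = meta80.index[meta80["sire_group"] == "high"]
        raw = Y[low].mean(axis=1) - Y[high].mean(axis=1)
        np.testing.assert_allclose(sols.sire_contrast, raw, atol=1e-4)

    def test_planted_de_have_largest_contrasts(self, meta80):
        rng = np.random.default_rng(8)
        tiny = {"G": 1.0, "GT": 0.5, "GA": 1e-4, "GS": 1e-4, "e": 1e-4}
        effects = np.zeros(100)
        effects[:10] = 2.0
        Y = simulate_mixed_model_y(meta80, 100, tiny, rng, sire_effects=effects)
        fit = mm.fit_variance_components(Y, meta80)
        sols = mm.solve_blups(Y, meta80, fit)
        top10 = set(sols.sire_contrast.abs().nlargest(10).index)
        assert top10 == {f"g{i:04d}" for i in range(10)}

    def test_refuses_nonconverged(self, meta80):
        rng = np.random.default_rng(9)
        Y = simulate_mixed_model_y(meta80, 20, TRUTH, rng)
        fit = mm.fit_variance_components(Y, meta80)
        fit.converged = False
        with pytest.raises(mm.ConvergenceError):
            mm.solve_blups(Y, meta80, fit)


class TestCallDe:
    @staticmethod
    def _solutions(d_values):
        idx = pd.Index([f"g{i}" for i in range(len(d_values))])
        gs = pd.DataFrame({"low": np.asarray(d_values) / 2, "high": -np.asarray(d_values) / 2},
                          index=idx)
        return mm.BlupSolutions(
            G=pd.Series(0.0, index=idx), GT=pd.DataFrame(index=idx),
            GA=pd.DataFrame(index=idx), GS=gs,
            residuals=pd.DataFrame(index=idx),
        )

    def test_z_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        res = mm.call_de(self._solutions(rng.normal(size=500)))
        assert res["z"].mean() == pytest.approx(0.0, abs=1e-12)
        assert res["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_two_sd_rule(self):
        d = np.zeros(100)
        d[0] = 50.0  # one extreme gene
        res = mm.call_de(self._solutions(d), k=2.0)
        assert bool(res.loc["g0", "is_de"])
        assert res["is_de"].sum() == 1

    def test_all_equal_no_calls(self):
        with pytest.warns(UserWarning):
            res = mm.call_de(self._solutions(np.ones(50)))
        assert not res["is_de"].any()

    def test_label_swap_antisymmetry(self, meta80):
        rng = np.random.default_rng(11)
        Y = simulate_mixed_model_y(meta80, 60, TRUTH, rng)
        swapped = meta80.copy()
        swapped["sire_group"] = swapped["sire_group"].map({"low": "high", "high": "low"})
        fit1 = mm.fit_variance_components(Y, meta80)
        fit2 = mm.fit_variance_components(Y, swapped)
        d1 = mm.solve_blups(Y, meta80, fit1).sire_contrast
        d2 = mm.solve_blups(Y, swapped, fit2).sire_contrast
        np.testing.assert_allclose(d1, -d2, atol=1e-5)

    def test_too_few_genes_raises(self):
        with pytest.raises(ValidationError):
            mm.call_de(self._solutions(np.arange(5.0)))


class TestTissueFoldChanges:
    def test_planted_tissue_fold_change(self, meta80):
        Y = pd.DataFrame(0.0, index=["g1"], columns=meta80.index)
        muscle_low = [s for s in meta80.index
                      if meta80.loc[s, "tissue"] == "muscle"
                      and meta80.loc[s, "sire_group"] == "low"]
        Y.loc["g1", muscle_low] = 1.5
        fc = mm.tissue_fold_changes(Y, meta80)
        assert fc.loc["g1", "muscle"] == pytest.approx(1.5)
        assert fc.loc["g1", "liver"] == pytest.approx(0.0)
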