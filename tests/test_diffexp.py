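import itertools

import numpy as np
import pandas as pd
import pytest

from pool3seq import core_io, diffexp, simulate
from pool3seq.diffexp import (
    DesignError,
    bh_adjust,
    call_degs,
    fit_nb_glm,
    make_design,
    roc_auc,
    run_de,
    size_factors,
)


def _two_group_design(n_per_group=3):
    cond = pd.Series(
        ["A"] * n_per_group + ["B"] * n_per_group,
        index=[f"s{i}" for i in range(2 * n_per_group)],
    )
    return cond, make_design(cond)


class TestDesign:
    def test_condition_and_pool_columns(self):
        cond = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        pools = pd.Series([1, 2, 1, 2], index=list("wxyz"))
        d = make_design(cond, pools)
        assert list(d.columns) == ["intercept", "condition[B]", "pool[2]"]

    def test_confounded_design_names_aliased_terms(self):
        """Condition nested in pool cannot be fit; the error says which."""
        cond = pd.Series(["A", "A", "B", "B"], index=list("wxyz"))
        pools = pd.Series([1, 1, 2, 2], index=list("wxyz"))
        with pytest.raises(DesignError, match="condition|pool"):
            make_design(cond, pools)


class TestNbGlm:
    def test_fold_change_recovery_closed_form(self):
        """Near-zero dispersion, balanced means 100 vs 400: log2FC ~ 2, and
        the estimate matches log2 of the group mean ratio."""
        rng = np.random.default_rng(0)
        n = 6
        cond, design = _two_group_design(n // 2)
        y = np.concatenate([rng.poisson(100, n // 2), rng.poisson(400, n // 2)])
        background = rng.poisson(200, size=(20, n))  # stable genes anchor size factors
        counts = pd.DataFrame(
            np.vstack([y, background]),
            index=["g1"] + [f"bg{i}" for i in range(20)],
            columns=cond.index,
        )
        disp = pd.Series(1e-8, index=counts.index)
        res = fit_nb_glm(counts, design, dispersion=disp)
        sf = size_factors(counts).to_numpy()
        norm = y / sf
        expected = np.log2(norm[3:].mean() / norm[:3].mean())
        assert res.loc["g1", "log2FC"] == pytest.approx(expected, abs=1e-3)
        assert res.loc["g1", "log2FC"] == pytest.approx(2.0, abs=0.3)

    def test_intercept_only_recovers_log_mean(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(6)]
        counts = pd.DataFrame(
            rng.poisson(50, size=(3, 6)), index=["g1", "g2", "g3"], columns=samples
        )
        design = pd.DataFrame({"intercept": np.ones(6)}, index=samples)
        disp = pd.Series(1e-8, index=counts.index)
        res = fit_nb_glm(counts, design, dispersion=disp, coef="intercept")
        sf = size_factors(counts)
        # Poisson-limit GLM identity: exp(beta0) = sum(y) / sum(size factors)
        expected = counts.sum(axis=1) / sf.sum()
        recovered = np.exp(res["log2FC"] * np.log(2))
        assert np.allclose(recovered, expected, rtol=1e-6)

    def test_all_zero_gene_gets_nan(self):
        cond, design = _two_group_design()
        counts = pd.DataFrame(
            [[0] * 6, [5, 6, 7, 8, 9, 10]], index=["dead", "alive"], columns=cond.index
        )
        res = fit_nb_glm(counts, design)
        assert np.isnan(res.loc["dead", "pvalue"])
        assert np.isfinite(res.loc["alive", "pvalue"])

    def test_matches_independent_nb_glm(self):
        """Coefficients and standard errors agree with an independently
        implemented NB GLM (statsmodels) at fixed dispersion."""
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        cond, design = _two_group_design()
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.1, size=(5, 6)),
            index=[f"g{i}" for i in range(5)],
            columns=cond.index,
        )
        alpha = 0.1
        disp = pd.Series(alpha, index=counts.index)
        res = fit_nb_glm(counts, design, dispersion=disp)
        sf = size_factors(counts)
        offset = np.log(sf.to_numpy())
        for g in counts.index:
            fit = sm.GLM(
                counts.loc[g].to_numpy(),
                design.to_numpy(),
                family=sm.families.NegativeBinomial(alpha=alpha),
                offset=offset,
            ).fit()
            assert res.loc[g, "log2FC"] == pytest.approx(fit.params[1] / np.log(2), rel=1e-4)
            assert res.loc[g, "lfcSE"] == pytest.approx(fit.bse[1] / np.log(2), rel=1e-3)


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_order_preserved_and_na_propagated(self):
        p = pd.Series([0.001, np.nan, 0.5, 0.04])
        q = bh_adjust(p)
        assert np.isnan(q[1])
        valid = q.dropna()
        assert (valid.rank() == p.dropna().rank()).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDegs:
    @pytest.mark.parametrize(
        "q,lfc,expected",
        [
            (0.04, 1.5, True),
            (0.04, 0.5, False),
            (0.01, -1.2, True),
            (0.05, 1.5, False),  # strict inequality on q
            (0.01, 1.0, False),  # strict inequality on |lfc|
        ],
    )
    def test_thresholds(self, q, lfc, expected):
        res = pd.DataFrame({"qvalue": [q], "log2FC": [lfc]}, index=["g"])
        assert call_degs(res).loc["g"] == expected


class TestRocAuc:
    def test_perfect_ranking(self):
        p = pd.Series([1e-6, 1e-5, 0.5, 0.9], index=list("abcd"))
        roc = roc_auc(p, {"a", "b"})
        assert roc.auc == 1.0
        assert roc.points.iloc[0].tolist() == [0.0, 0.0]
        assert roc.points.iloc[-1].tolist() == [1.0, 1.0]

    def test_reversed_ranking(self):
        p = pd.Series([1e-6, 1e-5, 0.5, 0.9], index=list("abcd"))
        assert roc_auc(p, {"c", "d"}).auc == 0.0

    def test_degenerate_truth_rejected(self):
        p = pd.Series([0.1, 0.2], index=list("ab"))
        with pytest.raises(ValueError):
            roc_auc(p, set())
        with pytest.raises(ValueError):
            roc_auc(p, {"a", "b"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_pair_counting(self, seed):
        """AUC equals the fraction of concordant (truth, non-truth) pairs,
        enumerated exhaustively, on random instances of <= 12 genes."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        m = int(rng.integers(1, n))
        p = pd.Series(
            rng.choice([0.01, 0.05, 0.2, 0.5, 0.9], size=n),  # ties likely
            index=[f"g{i}" for i in range(n)],
        )
        truth = set(rng.choice(p.index, size=m, replace=False))
        got = roc_auc(p, truth).auc
        pairs = list(itertools.product(
            [p[g] for g in p.index if g in truth],
            [p[g] for g in p.index if g not in truth],
        ))
        brute = np.mean([1.0 if t < f else 0.5 if t == f else 0.0 for t, f in pairs])
        assert got == pytest.approx(brute)


class TestEndToEndDe:
    @pytest.fixture(scope="class")
    def simulated(self):
        ref = simulate.build_reference(n_mrna=800, seed=31)
        layout = core_io.make_row_pooling_layout(2, 6, conditions=["A", "B"] * 6)
        rng = np.random.default_rng(32)
        genes = ref.ids_of_class("mRNA")
        truth = list(rng.choice(genes, 80, replace=False))
        fc = {"B": {g: float(s) for g, s in zip(truth, rng.choice([-2.0, 2.0], 80))}}
        prof = simulate.simulate_expression(
            layout, ref, fc_spec=fc, depth=500_000,
            bias=simulate.BiasModel.identity(), dispersion=0.1, seed=33,
        )
        cond = pd.Series(layout.condition_of())
        return prof.counts.loc[genes], cond, truth

    def test_truth_recovery_auc(self, simulated):
        counts, cond, truth = simulated
        res = run_de(counts, cond)
        roc = roc_auc(res["pvalue"], truth)
        assert roc.auc >= 0.95

    def test_empirical_fdr_controlled(self, simulated):
        counts, cond, truth = simulated
        res = run_de(counts, cond)
        called = set(res.index[res["DEG"]])
        assert called, "no DEGs called"
        fdr = len(called - set(truth)) / len(called)
        assert fdr <= 0.10
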