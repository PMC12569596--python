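import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adict.core import (
    adict_statistic,
    bootstrap_mean_rcs,
    compare_class_conservation,
    confound_model,
    conservation_profiles,
    sample_ec_correlation,
)
from adict.errors import AnalysisError, ConfigurationError
from adict.normalize import ExpressionDataset
from adict.simulate import simulate_confound_genes


def _expr(values, ages):
    cols = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionDataset(
        values=pd.DataFrame(values, columns=cols,
                            index=[f"g{i}" for i in range(values.shape[0])]),
        sample_age=pd.Series(ages, index=cols, dtype=float),
        is_normalized=True,
    )


class TestECCorrelation:
    def test_perfect_concordance_and_discordance(self, scored_genes):
        retained = scored_genes.loc[~scored_genes.excluded]
        expr_up = pd.Series(
            sps.rankdata(retained["cs"].values), index=retained["gene_id"].values
        )
        rho, n = sample_ec_correlation(expr_up, scored_genes)
        assert rho == pytest.approx(1.0)
        assert n == len(retained)
        rho_dn, _ = sample_ec_correlation(-expr_up, scored_genes)
        assert rho_dn == pytest.approx(-1.0)

    def test_six_gene_oracle(self, scored_genes):
        # brute-force rank correlation over a printed expression vector
        genes = scored_genes.loc[~scored_genes.excluded, "gene_id"].values[:6]
        expr = pd.Series([4.1, 0.2, 9.5, 3.3, 3.3, 7.0], index=genes)
        cs = scored_genes.set_index("gene_id").loc[genes, "cs"].values
        rho, n = sample_ec_correlation(expr, scored_genes, gene_subset=genes)
        assert n == 6
        assert rho == pytest.approx(sps.spearmanr(expr.values, cs).statistic, abs=1e-12)

    def test_too_few_genes(self, scored_genes):
        expr = pd.Series([1.0, 2.0], index=["g0", "g1"])
        with pytest.raises(AnalysisError):
            sample_ec_correlation(expr, scored_genes, gene_subset=["g0", "g1"])

    def test_monotone_transform_invariance(self, scored_genes, rng):
        retained = scored_genes.loc[~scored_genes.excluded]
        vals = rng.uniform(1, 100, size=(len(retained), 4))
        ds = _expr(vals, [1, 2, 3, 4])
        ds.values.index = retained["gene_id"].values
        p1 = conservation_profiles(ds, scored_genes)
        ds2 = _expr(np.log1p(vals) ** 3, [1, 2, 3, 4])
        ds2.values.index = retained["gene_id"].values
        p2 = conservation_profiles(ds2, scored_genes)
        assert np.allclose(p1["ec_rho"], p2["ec_rho"])


class TestADICTStatistic:
    def _profiles(self, ec, ages):
        return pd.DataFrame({"unit_id": range(len(ec)), "age": ages, "ec_rho": ec})

    def test_perfect_decline(self):
        res = adict_statistic(self._profiles([0.5, 0.4, 0.3, 0.2], [1, 2, 3, 4]))
        assert res.rho_adict == pytest.approx(-1.0)

    def test_antisymmetry_under_cs_negation(self, scored_genes, rng):
        retained = scored_genes.loc[~scored_genes.excluded]
        vals = rng.uniform(1, 50, size=(len(retained), 5))
        ds = _expr(vals, [1, 2, 3, 4, 5])
        ds.values.index = retained["gene_id"].values
        flipped = scored_genes.copy()
        flipped["cs"] = -flipped["cs"]
        r1 = adict_statistic(conservation_profiles(ds, scored_genes))
        r2 = adict_statistic(conservation_profiles(ds, flipped))
        assert r1.rho_adict == pytest.approx(-r2.rho_adict)

    def test_age_rescaling_invariance(self):
        ec = [0.1, 0.5, 0.2, 0.4, 0.3]
        ages = np.array([3.0, 9, 18, 24, 30])
        r1 = adict_statistic(self._profiles(ec, ages))
        r2 = adict_statistic(self._profiles(ec, ages * 30.4 + 7))
        assert r1.rho_adict == pytest.approx(r2.rho_adict)

    def test_permutation_null_centred(self, rng):
        rhos = []
        ages = np.repeat([1, 2, 3, 4, 5], 3)
        for _ in range(1000):
            ec = rng.normal(size=15)
            rhos.append(adict_statistic(self._profiles(ec, rng.permutation(ages))).rho_adict)
        assert abs(np.mean(rhos)) < 0.05

    def test_degenerate_and_small(self):
        with pytest.raises(AnalysisError):
            adict_statistic(self._profiles([0.1, 0.2], [1, 2]))
        res = adict_statistic(self._profiles([0.3, 0.3, 0.3], [1, 2, 3]))
        assert res.degenerate and np.isnan(res.rho_adict)


class TestClassComparison:
    def _classes(self, old_genes, young_genes):
        idx = list(old_genes) + list(young_genes)
        return pd.DataFrame(
            {"label": ["old_biased"] * len(old_genes) + ["young_biased"] * len(young_genes)},
            index=idx,
        )

    def test_identical_multisets(self, rng):
        vals = rng.normal(1.5, 0.3, size=10)
        div = pd.DataFrame(
            {
                "gene_id": [f"o{i}" for i in range(10)] + [f"y{i}" for i in range(10)],
                "dN": np.concatenate([np.exp(-vals), np.exp(-vals)]) * 0.1,
                "dS": 0.1,
                "is_one2one": True,
                "has_paralog": False,
            }
        )
        from adict.conservation import compute_conservation_scores

        cons = compute_conservation_scores(div)
        rep = compare_class_conservation(
            cons, self._classes([f"o{i}" for i in range(10)], [f"y{i}" for i in range(10)])
        )
        assert rep["welch_t"] == pytest.approx(0.0, abs=1e-12)
        assert rep["welch_p"] == pytest.approx(1.0)

    def test_shifted_fixture_matches_hand_welch(self):
        # old scores = young scores - 1, equal n and variance
        young = np.linspace(2.0, 3.0, 10)
        old = young - 1.0
        div = pd.DataFrame(
            {
                "gene_id": [f"o{i}" for i in range(10)] + [f"y{i}" for i in range(10)],
                "dN": np.exp(-np.concatenate([old, young])) * 0.1,
                "dS": 0.1,
                "is_one2one": True,
                "has_paralog": False,
            }
        )
        from adict.conservation import compute_conservation_scores

        cons = compute_conservation_scores(div)
        rep = compare_class_conservation(
            cons, self._classes([f"o{i}" for i in range(10)], [f"y{i}" for i in range(10)])
        )
        se = np.sqrt(old.var(ddof=1) / 10 + young.var(ddof=1) / 10)
        assert rep["mean_difference"] == pytest.approx(-1.0)
        assert rep["welch_t"] == pytest.approx(-1.0 / se)
        # equal variance, equal n: Welch t equals Student t
        student = sps.ttest_ind(old, young, equal_var=True)
        assert rep["welch_t"] == pytest.approx(student.statistic)

    def test_empty_class_errors(self, scored_genes):
        with pytest.raises(AnalysisError):
            compare_class_conservation(scored_genes, self._classes(["g0"], ["g1", "g2"]))


class TestBootstrap:
    def test_zero_variance_ci(self, scored_genes):
        cons = scored_genes.copy()
        cons["rcs"] = 0.7
        res = bootstrap_mean_rcs(cons, cons["gene_id"], B=200, seed=1)
        assert res["ci_low"] == res["ci_high"] == pytest.approx(0.7)

    def test_seed_reproducibility(self, scored_genes):
        a = bootstrap_mean_rcs(scored_genes, scored_genes["gene_id"], B=300, seed=5)
        b = bootstrap_mean_rcs(scored_genes, scored_genes["gene_id"], B=300, seed=5)
        assert a == b

    def test_requires_seed_and_B(self, scored_genes):
        with pytest.raises(ConfigurationError):
            bootstrap_mean_rcs(scored_genes, scored_genes["gene_id"], B=300)
        with pytest.raises(ConfigurationError):
            bootstrap_mean_rcs(scored_genes, scored_genes["gene_id"], B=10, seed=1)


class TestConfoundModel:
    def test_recovers_planted_class_effect(self):
        tab = simulate_confound_genes(2000, class_effect=0.05, seed=3)
        rep = confound_model(tab)
        assert rep["class_coefficient"] == pytest.approx(0.05, abs=0.01)
        assert rep["class_p"] < 1e-6

    def test_null_effect_moderate_p(self):
        # a single null dataset: coefficient near zero
        rep = confound_model(simulate_confound_genes(2000, class_effect=0.0, seed=4))
        assert abs(rep["class_coefficient"]) < 0.01

    def test_max_expression_variant(self):
        rep = confound_model(simulate_confound_genes(500, 0.05, seed=5), expression="max")
        assert rep["expression_variant"] == "max"

    def test_constant_class_errors(self):
        tab = simulate_confound_genes(100, 0.0, seed=6)
        tab["label"] = "old_biased"
        with pytest.raises(AnalysisError):
            confound_model(tab)
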