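import numpy as np
import pytest

from packrate import (
    CollinearPredictorsError,
    GeometryRecipe,
    NoOverlapError,
    NoProteinsError,
    ProteinComparison,
    RateProfile,
    RateRecipe,
    ZeroVarianceError,
    aggregate,
    aggregate_to_frames,
    compare_protein,
    comparisons_to_frame,
    make_dataset,
    make_sites,
    predicted_profile,
    r_squared,
    semipartial_r_squared,
    wcn_alpha_alpha,
    wcn_alpha_alpharho,
    wcn_rho_alpharho,
    wcn_rho_rho,
)

from oracles import two_model_r2_increment


class TestRSquared:
    def test_exact_linear_map(self):
        assert r_squared([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        assert r_squared(y, 5.0 - 2.0 * y) == pytest.approx(1.0, rel=1e-12)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(1)
        assert r_squared(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_affine_invariance_and_symmetry(self):
        rng = np.random.default_rng(2)
        y, x = rng.normal(size=40), rng.normal(size=40)
        base = r_squared(y, x)
        assert r_squared(x, y) == pytest.approx(base, rel=1e-12)
        assert r_squared(y, -3.0 * x + 7.0) == pytest.approx(base, rel=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError, match="zero variance"):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSemipartial:
    def test_orthogonal_control_is_identity(self):
        # x constructed with exactly zero sample correlation against z
        rng = np.random.default_rng(3)
        z = rng.normal(size=50)
        x = rng.normal(size=50)
        zc = z - z.mean()
        x = x - (x - x.mean()) @ zc / (zc @ zc) * zc
        y = rng.normal(size=50)
        assert semipartial_r_squared(y, x, z) == pytest.approx(
            r_squared(y, x), rel=1e-10
        )

    def test_near_copy_of_control_is_negligible(self):
        rng = np.random.default_rng(4)
        z = rng.normal(size=2_000)
        x = z + rng.normal(0, 1e-4, size=2_000)
        y = rng.normal(size=2_000)
        assert semipartial_r_squared(y, x, z) < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_r2_increment(self, seed):
        rng = np.random.default_rng(seed)
        y, x, z = rng.normal(size=(3, 50))
        sp2 = semipartial_r_squared(y, x, z)
        assert sp2 == pytest.approx(two_model_r2_increment(y, z, x), abs=1e-10)

    def test_agrees_with_statsmodels_and_pingouin(self):
        import pandas as pd
        import pingouin as pg
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        y, x, z = rng.normal(size=(3, 80))
        sp2 = semipartial_r_squared(y, x, z)

        full = sm.OLS(y, sm.add_constant(np.column_stack([z, x]))).fit()
        reduced = sm.OLS(y, sm.add_constant(z)).fit()
        assert sp2 == pytest.approx(full.rsquared - reduced.rsquared, abs=1e-10)

        df = pd.DataFrame({"y": y, "x": x, "z": z})
        r_sp = pg.partial_corr(df, x="x", y="y", x_covar="z")["r"].iloc[0]
        assert sp2 == pytest.approx(r_sp**2, abs=1e-10)

    def test_collinear_rejected(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=20)
        y = rng.normal(size=20)
        with pytest.raises(CollinearPredictorsError, match="collinear"):
            semipartial_r_squared(y, 2.0 * z - 1.0, z)


class TestPredictedProfile:
    def test_exact_affine_zero_residuals(self):
        x = np.linspace(0, 1, 20)
        y = 3.0 - 2.0 * x
        np.testing.assert_allclose(predicted_profile(y, x), y, atol=1e-12)

    def test_mean_preserved_and_r2_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=60)
        y = 1.0 - x + rng.normal(0, 0.5, size=60)
        fitted = predicted_profile(y, x)
        assert fitted.mean() == pytest.approx(y.mean(), abs=1e-10)
        assert r_squared(fitted, y) == pytest.approx(r_squared(x, y), rel=1e-10)


def _protein(seed, n_sites=120, target_r2=0.5):
    sites = make_sites(GeometryRecipe(n_sites=n_sites, gly_fraction=0.1,
                                      seed=seed), label=f"p{seed}")
    rates = RateProfile.from_raw(
        [r[1] for r in sites.residue_ids],
        np.maximum(
            2.0 - wcn_rho_alpharho(sites).values
            + np.random.default_rng(seed).normal(
                0, wcn_rho_alpharho(sites).values.std(), n_sites),
            1e-6,
        ),
    )
    predictors = {
        "WCN_rho_alpharho": wcn_rho_alpharho(sites),
        "WCN_alpha_alpharho": wcn_alpha_alpharho(sites),
        "WCN_alpha_alpha": wcn_alpha_alpha(sites),
        "WCN_rho_rho": wcn_rho_rho(sites),
    }
    return sites, rates, predictors


class TestCompareProtein:
    def test_control_dominates_when_it_generates_rates(self):
        wins, sp2s = 0, []
        for seed in range(12):
            sites, rates, predictors = _protein(seed)
            comp = compare_protein(sites, rates, predictors,
                                   control="WCN_rho_alpharho")
            if comp.r2["WCN_rho_alpharho"] == max(comp.r2.values()):
                wins += 1
            sp2s.extend(comp.sp2.values())
        assert wins >= 10
        assert np.mean(sp2s) < 0.02

    def test_identical_predictors_collinear(self):
        sites, rates, predictors = _protein(1)
        same = {name: predictors["WCN_alpha_alpha"] for name in predictors}
        with pytest.raises(CollinearPredictorsError, match="collinear"):
            compare_protein(sites, rates, same, control="WCN_rho_alpharho")

    def test_no_overlap_propagates(self):
        sites, _, predictors = _protein(2)
        rates = RateProfile.from_raw([10_000, 10_001], [1.0, 2.0])
        with pytest.raises(NoOverlapError, match="no overlap"):
            compare_protein(sites, rates, predictors,
                            control="WCN_rho_alpharho")

    def test_sign_flip_changes_nothing(self):
        sites, rates, predictors = _protein(3)
        comp = compare_protein(sites, rates, predictors,
                               control="WCN_rho_alpharho")
        flipped = dict(predictors)
        flipped["WCN_alpha_alpha"] = -predictors["WCN_alpha_alpha"].values
        comp2 = compare_protein(sites, rates, flipped,
                                control="WCN_rho_alpharho")
        assert comp2.r2["WCN_alpha_alpha"] == pytest.approx(
            comp.r2["WCN_alpha_alpha"], rel=1e-10)
        assert comp2.sp2["WCN_alpha_alpha"] == pytest.approx(
            comp.sp2["WCN_alpha_alpha"], rel=1e-10)


def _fake_comparisons(r2_by_protein, control="A"):
    out = []
    for k, r2s in enumerate(r2_by_protein):
        sp2 = {p: 0.001 for p in r2s if p != control}
        out.append(ProteinComparison(label=f"p{k}", n_sites=100,
                                     control=control, r2=dict(r2s), sp2=sp2))
    return out


class TestAggregate:
    def test_identical_proteins_zero_sd(self):
        comps = _fake_comparisons([{"A": 0.5, "B": 0.4}] * 10)
        agg = aggregate(comps, n_boot=200, seed=0)
        assert agg.sd_r2["A"] == pytest.approx(0.0, abs=1e-12)
        assert agg.sd_r2["B"] == pytest.approx(0.0, abs=1e-12)
        assert agg.pairs[0].sd == pytest.approx(0.0, abs=1e-12)

    def test_uniform_margin_gives_floor_p_value(self):
        rng = np.random.default_rng(9)
        comps = _fake_comparisons(
            [{"A": 0.5 + rng.uniform(-0.05, 0.05), "B": 0.3} for _ in range(30)]
        )
        agg = aggregate(comps, n_boot=500, seed=1)
        pair = agg.pairs[0]
        assert pair.wins_a == 30 and pair.wins_b == 0 and pair.ties == 0
        assert pair.p_value == pytest.approx(1 / 500)  # reported bound, never 0

    def test_win_counts_partition_proteins(self):
        rng = np.random.default_rng(10)
        comps = _fake_comparisons(
            [{"A": rng.uniform(), "B": rng.uniform()} for _ in range(25)]
        )
        agg = aggregate(comps, n_boot=100, seed=2)
        pair = agg.pairs[0]
        assert pair.wins_a + pair.wins_b + pair.ties == 25

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(11)
        comps = _fake_comparisons(
            [{"A": rng.uniform(), "B": rng.uniform()} for _ in range(12)]
        )
        a = aggregate(comps, n_boot=300, seed=5)
        b = aggregate(comps, n_boot=300, seed=5)
        assert a == b

    def test_bootstrap_sd_matches_analytic_se(self):
        rng = np.random.default_rng(12)
        values = rng.beta(2, 3, size=200)
        comps = _fake_comparisons([{"A": v, "B": v / 2} for v in values])
        agg = aggregate(comps, n_boot=10_000, seed=3)
        analytic = values.std(ddof=1) / np.sqrt(200)
        assert agg.sd_r2["A"] == pytest.approx(analytic, rel=0.2)

    def test_empty_rejected(self):
        with pytest.raises(NoProteinsError, match="no proteins"):
            aggregate([], n_boot=100, seed=0)

    def test_single_protein_degenerate_bootstrap(self):
        comps = _fake_comparisons([{"A": 0.7, "B": 0.2}])
        agg = aggregate(comps, n_boot=100, seed=0)
        assert agg.sd_r2["A"] == pytest.approx(0.0, abs=1e-12)

    def test_null_sp2_p_values_super_uniform(self):
        # rates generated from the control alone: the unique contribution of
        # x is sampling noise with mean ~ 1/(n_sites - 1); with a threshold
        # above that mean, small p-values should be rare
        p_values = []
        for trial in range(20):
            comps = []
            for k in range(15):
                rng = np.random.default_rng(1000 * trial + k)
                z = rng.normal(size=80)
                x = 0.8 * z + rng.normal(0, 0.6, size=80)
                y = 1.0 - z + rng.normal(0, 1.0, size=80)
                comps.append(ProteinComparison(
                    label=f"p{k}", n_sites=80, control="z",
                    r2={"z": r_squared(y, z), "x": r_squared(y, x)},
                    sp2={"x": semipartial_r_squared(y, x, z)},
                ))
            agg = aggregate(comps, n_boot=400, seed=trial,
                            sp2_threshold=0.03)
            p_values.append(agg.p_sp2["x"])
        p_values = np.array(p_values)
        assert np.mean(p_values <= 0.05) <= 0.15
        assert np.mean(p_values <= 0.25) <= 0.45


class TestTables:
    def test_per_protein_and_aggregate_frames(self):
        sites, rates, predictors = _protein(5)
        comp = compare_protein(sites, rates, predictors,
                               control="WCN_rho_alpharho")
        frame = comparisons_to_frame([comp])
        assert frame.shape[0] == 1
        assert "R2_WCN_rho_alpharho" in frame.columns
        assert "sp2_WCN_alpha_alpha" in frame.columns
        agg = aggregate([comp, comp], n_boot=100, seed=0)
        summary, pairwise = aggregate_to_frames(agg)
        assert set(summary["predictor"]) == set(predictors)
        assert {"delta_R2", "p_value", "wins_A"} <= set(pairwise.columns)


def test_end_to_end_recovery_small():
    """Rates generated from the side-chain WCN: it should rank first."""
    dataset = make_dataset(
        8,
        GeometryRecipe(n_sites=100, gly_fraction=0.1),
        RateRecipe(predictor="WCN_rho_alpharho", target_r2=0.5),
        seed=21,
    )
    comps = []
    for sites, rates in dataset:
        predictors = {
            "WCN_rho_alpharho": wcn_rho_alpharho(sites),
            "WCN_alpha_alpharho": wcn_alpha_alpharho(sites),
            "WCN_alpha_alpha": wcn_alpha_alpha(sites),
            "WCN_rho_rho": wcn_rho_rho(sites),
        }
        comps.append(compare_protein(sites, rates, predictors,
                                     control="WCN_rho_alpharho"))
    agg = aggregate(comps, n_boot=500, seed=22)
    best = max(agg.mean_r2, key=agg.mean_r2.get)
    assert best == "WCN_rho_alpharho"
    assert agg.mean_r2["WCN_rho_alpharho"] == pytest.approx(0.5, abs=0.1)
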