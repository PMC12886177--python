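"""Unit and property tests for the dilution-experiment mortality estimator."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ksw.dilution import (
    DegenerateDesignError,
    DilutionDesign,
    InsufficientDataError,
    analyze_experiment,
    apparent_growth_rate,
    filter_replicate_outliers,
    fit_dilution_slope,
    fit_endpoint_difference,
    phage_mortality,
)
from ksw.synthetic import CommunityTruth, NoiseSpec, simulate_dilution_experiment


def brute_force_outlier_flags(rates, floor=1e-6):
    """Independent restatement of the >2-SD rule for cross-checking."""
    rates = np.asarray(rates, float)
    flagged = []
    for i in range(3):
        others = [rates[j] for j in range(3) if j != i]
        mean = sum(others) / 2
        sd = math.sqrt(sum((o - mean) ** 2 for o in others))  # ddof=1 with n=2
        if abs(rates[i] - mean) > max(2 * sd, floor):
            flagged.append(i)
    return flagged


class TestApparentGrowthRate:
    @pytest.mark.parametrize(
        "p0,pt,t,expected",
        [
            (1e6, 1e6, 24.0, 0.0),
            (5e5, 5e5 * math.e, 24.0, 1 / 24),
            (8e5, 1.1e6, 24.0, math.log(1.375) / 24),
        ],
    )
    def test_known_values(self, p0, pt, t, expected):
        assert apparent_growth_rate(p0, pt, t) == pytest.approx(expected, abs=1e-12)

    @given(
        p0=st.floats(1e2, 1e8),
        pt=st.floats(1e2, 1e8),
        t=st.floats(1.0, 100.0),
    )
    def test_sign_symmetry(self, p0, pt, t):
        """Swapping initial and final abundance negates the rate."""
        assert apparent_growth_rate(p0, pt, t) == pytest.approx(
            -apparent_growth_rate(pt, p0, t), rel=1e-9, abs=1e-15
        )

    def test_nonpositive_abundance_is_below_detection(self):
        assert math.isnan(apparent_growth_rate(0.0, 1e6, 24))
        assert math.isnan(apparent_growth_rate(1e6, 0.0, 24))

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            apparent_growth_rate(1e6, 1e6, 0.0)


class TestOutlierFilter:
    @pytest.mark.parametrize(
        "rates,expected_dropped",
        [
            ((0.10, 0.10, 0.10), None),
            ((0.10, 0.11, 0.50), 2),
            ((0.10, 0.11, 0.12), None),
        ],
    )
    def test_spec_examples(self, rates, expected_dropped):
        retained, record = filter_replicate_outliers(rates)
        if expected_dropped is None:
            assert retained.all() and record is None
        else:
            assert not retained[expected_dropped]
            assert retained.sum() == 2

    def test_matches_brute_force_on_grid(self):
        """Exhaustive crafted triples agree with an independent restatement
        (modulo the at-most-one-discard cap, triggered when >1 is flagged)."""
        grid = np.array([-0.5, -0.1, 0.0, 0.01, 0.1, 0.5, 2.0])
        for a in grid:
            for b in grid:
                for c in grid:
                    retained, record = filter_replicate_outliers((a, b, c))
                    flagged = brute_force_outlier_flags((a, b, c))
                    if len(flagged) <= 1:
                        dropped = [] if record is None else [record["index"]]
                        assert dropped == flagged, (a, b, c)
                    else:
                        assert retained.sum() >= 2

    def test_wild_replicate_always_removed(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            base = rng.normal(0.02, 0.005, size=2)
            spread = abs(base[0] - base[1]) + 1e-3
            wild = base.mean() + 10 * spread
            pos = rng.integers(3)
            rates = np.insert(base, pos, wild)
            retained, record = filter_replicate_outliers(rates)
            assert record is not None and record["index"] == pos

    @given(st.permutations([0.10, 0.11, 0.50]))
    def test_permutation_invariance(self, perm):
        retained, record = filter_replicate_outliers(perm)
        assert record is not None
        assert perm[record["index"]] == 0.50

    def test_never_discards_more_than_one(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            rates = rng.normal(0, 1, size=3)
            retained, _ = filter_replicate_outliers(rates)
            assert retained.sum() >= 2

    def test_float_jitter_retained(self):
        retained, record = filter_replicate_outliers((0.1, 0.1, 0.1 + 1e-9))
        assert retained.all() and record is None

    def test_fewer_than_three_all_retained(self):
        retained, record = filter_replicate_outliers((0.1, 5.0))
        assert retained.all() and record is None


class TestSlopeFit:
    def test_perfect_line(self):
        x = np.array([0.05, 0.3, 0.7, 1.0])
        fit = fit_dilution_slope(x, 0.05 - 0.08 * x)
        assert fit.slope == pytest.approx(-0.08, abs=1e-12)
        assert fit.intercept == pytest.approx(0.05, abs=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-12)

    def test_flat_rates_zero_slope(self):
        fit = fit_dilution_slope([0.1, 0.5, 1.0], [0.02, 0.02, 0.02])
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_agrees_with_normal_equations(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.uniform(0, 1, size=12)
            y = rng.normal(0, 0.05, size=12)
            fit = fit_dilution_slope(x, y)
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            se = math.sqrt(resid @ resid / (len(x) - 2) / np.sum((x - x.mean()) ** 2))
            assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
            assert fit.slope == pytest.approx(beta[1], rel=1e-9)
            assert fit.se == pytest.approx(se, rel=1e-9)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_dilution_slope([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        with pytest.raises(InsufficientDataError):
            fit_dilution_slope([0.5], [0.1])

    def test_endpoint_estimator_on_line(self):
        x = np.array([0.05, 0.3, 0.7, 1.0])
        fit = fit_endpoint_difference(x, 0.05 - 0.08 * x)
        assert fit.slope == pytest.approx(-0.08, abs=1e-12)


class TestPhageMortality:
    def test_equal_slopes_give_zero(self):
        value, _ = phage_mortality(-0.08, 0.01, -0.08, 0.01)
        assert value == 0.0

    def test_definition_and_quadrature(self):
        value, err = phage_mortality(-0.12, 0.01, -0.08, 0.02)
        assert value == pytest.approx(-0.04)
        assert err == pytest.approx(math.sqrt(0.0005))
        assert err >= max(0.01, 0.02)  # quadrature dominates each component

    def test_sign_convention_switch(self):
        value, _ = phage_mortality(-0.12, 0, -0.08, 0, convention="protist-minus-combined")
        assert value == pytest.approx(0.04)


class TestAnalyzeExperiment:
    def test_noiseless_synthetic_decomposition(self, noiseless_experiment):
        """g=0.08, v=0.03 community: protist slope -g, combined slope -(g+v),
        phage mortality -v."""
        res = analyze_experiment(noiseless_experiment.bottles)
        assert res.slope_protist == pytest.approx(-0.08, abs=1e-10)
        assert res.slope_combined == pytest.approx(-0.11, abs=1e-10)
        assert res.phage_mortality == pytest.approx(-0.03, abs=1e-10)
        assert res.calls["protist"] == "predation"

    def test_no_phage_community(self):
        truth = CommunityTruth(["a"], [0.05], [0.08], [0.0], [1e6], [3.0], ["select-winner"])
        sim = simulate_dilution_experiment(truth, noise=NoiseSpec(0.0, None))
        res = analyze_experiment(sim.bottles)
        assert res.phage_mortality == pytest.approx(0.0, abs=1e-12)

    def test_x_zero_bottles_excluded(self, noiseless_experiment):
        res = analyze_experiment(noiseless_experiment.bottles)
        # 4 usable fractions x 3 replicates per series
        assert res.n_bottles_used == {"protist": 12, "combined": 12}

    def test_planted_wild_replicate_is_filtered(self, noiseless_experiment):
        clean = analyze_experiment(noiseless_experiment.bottles)
        bottles = noiseless_experiment.bottles.copy()
        idx = bottles[
            (bottles.series == "protist")
            & np.isclose(bottles.whole_water_fraction, 0.3)
            & (bottles.replicate == 2)
        ].index[0]
        bottles.loc[idx, "pt"] = bottles.loc[idx, "p0"] * math.exp(10 * 24)  # rate +10
        res = analyze_experiment(bottles)
        assert len(res.discarded) == 1
        assert res.discarded[0]["whole_water_fraction"] == pytest.approx(0.3)
        assert res.slope_protist == pytest.approx(clean.slope_protist, abs=1e-9)

    def test_missing_series_flags_and_skips_decomposition(self, noiseless_experiment):
        bottles = noiseless_experiment.bottles
        res = analyze_experiment(bottles[bottles.series == "protist"])
        assert math.isnan(res.phage_mortality)
        assert any("combined" in f for f in res.flags)

    def test_replicate_mean_fit_matches_pooled_on_balanced_noiseless(self, noiseless_experiment):
        pooled = analyze_experiment(noiseless_experiment.bottles, pool_replicates=True)
        means = analyze_experiment(noiseless_experiment.bottles, pool_replicates=False)
        assert means.slope_protist == pytest.approx(pooled.slope_protist, abs=1e-12)


class TestParameterRecovery:
    def test_noiseless_recovery_over_random_communities(self):
        """-slope_protist recovers g and -phage_mortality recovers v to 1e-8
        across seeded single-population communities."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            mu, g, v = rng.uniform(0, 0.1, size=3)
            truth = CommunityTruth(["a"], [mu], [g], [v], [1e6], [3.0], ["background" if g == 0 else "slow"])
            sim = simulate_dilution_experiment(truth, noise=NoiseSpec(0.0, None))
            res = analyze_experiment(sim.bottles)
            assert -res.slope_protist == pytest.approx(g, abs=1e-8)
            assert -res.phage_mortality == pytest.approx(v, abs=1e-8)

    def test_noise_widens_slope_spread(self):
        """Empirical spread of recovered grazing slopes grows with count_cv."""
        spreads = []
        for cv in (0.02, 0.1):
            rng = np.random.default_rng(1)
            est = []
            truth = CommunityTruth(["a"], [0.05], [0.05], [0.02], [1e6], [3.0], ["slow"])
            for _ in range(100):
                sim = simulate_dilution_experiment(truth, noise=NoiseSpec(cv, None), rng=rng)
                est.append(analyze_experiment(sim.bottles).slope_protist)
            spreads.append(np.std(est))
        assert spreads[1] > spreads[0]


def test_design_validation():
    with pytest.raises(ValueError):
        DilutionDesign(filtrate_fractions=())
    with pytest.raises(ValueError):
        DilutionDesign(duration_h=-1)
    with pytest.raises(ValueError):
        DilutionDesign(filtrate_fractions=(0.5, 0.1))
    d = DilutionDesign()
    assert d.whole_water_fractions == (1.0, 0.7, 0.30000000000000004, 0.050000000000000044, 0.0)


def test_analyze_experiments_table_shape(noiseless_experiment):
    from ksw.dilution import analyze_experiments

    table = analyze_experiments(noiseless_experiment.bottles)
    assert list(table["experiment_id"]) == ["exp-001"]
    assert {"slope_combined", "se_combined", "slope_protist", "se_protist", "phage_mortality", "phage_error"} <= set(table.columns)
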