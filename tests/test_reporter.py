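"""Standard curves, GUS rates, LUC/GUS ratios, pairwise statistics, letters."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from crmscreen.reporter import (
    KineticSeries,
    compact_letter_display,
    compare_constructs,
    fit_standard_curve,
    fold_change,
    gus_rate,
    luc_gus_ratio,
)
from crmscreen.simulate import SimulationConfig, simulate_kinetics


def series(slope_au_per_min, intercept=0.0, protein=0.1, line="L1", dup="A", n=20):
    t = np.arange(n) * 2.0
    return KineticSeries(
        line_id=line,
        construct_id="c",
        duplicate_id=dup,
        times_min=t,
        fluorescence=intercept + slope_au_per_min * t,
        protein_mg=protein,
    )


class TestStandardCurve:
    def test_exact_line(self):
        curve = fit_standard_curve(pd.DataFrame({"conc": [0, 1, 2], "fluorescence": [0, 10, 20]}))
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_noisy_line_recovers_slope(self):
        rng = np.random.default_rng(2)
        conc = np.linspace(0, 10, 10)
        true_slope, sd = 50.0, 5.0
        fluo = 7.0 + true_slope * conc + rng.normal(0, sd, size=10)
        curve = fit_standard_curve(pd.DataFrame({"conc": conc, "fluorescence": fluo}))
        se = sd / np.sqrt(np.sum((conc - conc.mean()) ** 2))
        assert abs(curve.slope - true_slope) < 3 * se

    def test_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_standard_curve(pd.DataFrame({"conc": [1.0, 1.0], "fluorescence": [5, 6]}))


class TestGusRate:
    def test_exact_rate_from_linear_series(self):
        # slope 20 AU/min, curve 10 AU/nmol, 0.1 mg -> 20/10/0.1 = 20 nmol/min/mg
        curve = fit_standard_curve(pd.DataFrame({"conc": [0, 1, 2], "fluorescence": [0, 10, 20]}))
        m = gus_rate([series(20.0)], curve)
        assert m.rate == pytest.approx(20.0)

    def test_duplicates_averaged(self):
        curve = fit_standard_curve(pd.DataFrame({"conc": [0, 1], "fluorescence": [0, 1]}))
        m = gus_rate([series(10.0, dup="A", protein=1.0), series(20.0, dup="B", protein=1.0)], curve)
        assert m.duplicate_slopes == pytest.approx((10.0, 20.0))
        assert m.rate == pytest.approx(15.0)

    def test_scale_equivariance(self):
        """Scaling all fluorescence (standards included) leaves the rate unchanged."""
        for c in (1.0, 3.7):
            curve = fit_standard_curve(
                pd.DataFrame({"conc": [0, 1, 2], "fluorescence": np.array([0.0, 10, 20]) * c})
            )
            m = gus_rate([series(20.0 * c)], curve)
            assert m.rate == pytest.approx(20.0)

    def test_nonpositive_protein_rejected(self):
        curve = fit_standard_curve(pd.DataFrame({"conc": [0, 1], "fluorescence": [0, 1]}))
        with pytest.raises(ValueError, match="protein"):
            gus_rate([series(10.0, protein=0.0)], curve)

    def test_noiseless_simulation_returns_planted_rates(self):
        sim = simulate_kinetics(SimulationConfig(seed=4, kinetic_noise_sd=0.0))
        curve = fit_standard_curve(sim.standards)
        by_line = {}
        for s in sim.series:
            by_line.setdefault(s.line_id, []).append(s)
        for row in sim.truth.itertuples():
            m = gus_rate(by_line[row.line_id], curve)
            assert m.rate == pytest.approx(row.true_rate, rel=1e-9)


class TestLucGusRatio:
    def test_simple_ratio_and_log2(self):
        assert luc_gus_ratio(100.0, 10.0) == pytest.approx(10.0)
        assert luc_gus_ratio(8.0, 1.0, log2=True) == pytest.approx(3.0)

    def test_scale_invariance(self):
        assert luc_gus_ratio(100.0, 10.0) == pytest.approx(luc_gus_ratio(300.0, 30.0))

    def test_zero_gus_rejected(self):
        with pytest.raises(ValueError):
            luc_gus_ratio(100.0, 0.0)


class TestCompareConstructs:
    def test_identical_groups_share_a_letter(self):
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_constructs({"a": vals, "b": vals.copy()}, test="wilcoxon")
        assert res.pairs.p_adjusted.iloc[0] == pytest.approx(1.0)
        assert res.letters["a"] == res.letters["b"]

    def test_benjamini_hochberg_closed_form(self):
        # BH on (0.01, 0.02, 0.03) with m = 3: min over j>=i of p_j * 3/j
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03], method="fdr_bh")
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_far_shifted_group_gets_unique_letter(self):
        rng = np.random.default_rng(3)
        groups = {
            "low1": rng.normal(1.0, 0.1, size=8),
            "low2": rng.normal(1.0, 0.1, size=8),
            "high": rng.normal(100.0, 0.5, size=8),
        }
        res = compare_constructs(groups, test="wilcoxon")
        assert set(res.letters["high"]).isdisjoint(set(res.letters["low1"]))
        assert set(res.letters["high"]).isdisjoint(set(res.letters["low2"]))
        assert set(res.letters["low1"]) & set(res.letters["low2"])

    def test_t_test_path(self):
        rng = np.random.default_rng(4)
        groups = {"a": rng.normal(0, 1, size=6), "b": rng.normal(5, 1, size=6)}
        res = compare_constructs(groups, test="t")
        assert res.pairs.p_adjusted.iloc[0] < 0.05

    def test_singleton_group_excluded_with_warning(self, caplog):
        rng = np.random.default_rng(5)
        groups = {"a": rng.normal(0, 1, 5), "b": rng.normal(0, 1, 5), "solo": np.array([1.0])}
        with caplog.at_level("WARNING", logger="crmscreen"):
            res = compare_constructs(groups)
        assert res.excluded == ["solo"]
        assert "solo" not in res.letters

    def test_letters_reproduce_thresholded_p_matrix(self):
        """Two groups share a letter iff adjusted p >= alpha."""
        sim = simulate_kinetics(SimulationConfig(seed=9))
        curve = fit_standard_curve(sim.standards)
        by_line = {}
        for s in sim.series:
            by_line.setdefault(s.line_id, []).append(s)
        rates = {}
        for row in sim.truth.itertuples():
            rates.setdefault(row.construct_id, []).append(gus_rate(by_line[row.line_id], curve).rate)
        res = compare_constructs({k: np.array(v) for k, v in rates.items()})
        for r in res.pairs.itertuples():
            share = bool(set(res.letters[r.group1]) & set(res.letters[r.group2]))
            assert share == (r.p_adjusted >= res.alpha)

    def test_wilcoxon_type_one_error_under_null(self):
        """Single-pair Wilcoxon at n=8 per group rejects ~5% of null replicates."""
        rng = np.random.default_rng(6)
        n_rep, alpha = 1000, 0.05
        rejections = 0
        for _ in range(n_rep):
            res = compare_constructs(
                {"a": rng.normal(0, 1, 8), "b": rng.normal(0, 1, 8)}, test="wilcoxon", alpha=alpha
            )
            if res.pairs.p_adjusted.iloc[0] < alpha:
                rejections += 1
        # exact test is conservative at small n; allow binomial error around
        # the largest achievable size <= 0.05
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert rejections / n_rep < alpha + 3 * se


class TestCompactLetterDisplay:
    def test_all_different(self):
        letters = compact_letter_display(["a", "b", "c"], {frozenset(["a", "b"]), frozenset(["a", "c"]), frozenset(["b", "c"])})
        assert len({letters[g] for g in "abc"}) == 3

    def test_chain_structure(self):
        # a != c significant, b indistinguishable from both: b shares with each
        letters = compact_letter_display(["a", "b", "c"], {frozenset(["a", "c"])})
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestFoldChange:
    def test_reference_is_one(self):
        groups = {"ref": np.array([2.0, 4.0]), "x": np.array([2.0, 4.0])}
        assert fold_change(groups, "ref")["ref"] == pytest.approx(1.0)

    def test_median_ratio(self):
        groups = {"ref": np.array([1.0, 2.0, 3.0]), "x": np.array([25.0, 50.0, 75.0])}
        assert fold_change(groups, "ref")["x"] == pytest.approx(25.0)

    def test_planted_tenfold_shift_recovered(self):
        rng = np.random.default_rng(7)
        ref = rng.lognormal(0, 0.2, size=30)
        groups = {"ref": ref, "x": 10 * rng.lognormal(0, 0.2, size=30)}
        assert fold_change(groups, "ref")["x"] == pytest.approx(10.0, rel=0.3)
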