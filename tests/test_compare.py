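"""Normalization, multiple testing and the cross-system comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from tpaquant.compare import (
    _anova_tukey_vectorized,
    anova_tukey,
    categorize,
    compare_systems,
    holm_adjust,
    loess_normalize,
    presence_filter,
)
from tpaquant.quant_core import tpa_copy_numbers
from tpaquant.synthetic import SimulationConfig, simulate_proteome

from conftest import replicate_copies


def holm_bruteforce(p):
    """Literal step-down definition, kept independent of the implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min((m - rank) * p[idx], 1.0))
        out[idx] = running
    return out


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.04, 0.04])

    def test_single_test_passthrough(self):
        assert holm_adjust([1.0]) == pytest.approx([1.0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            holm_adjust([-0.1])

    def test_matches_bruteforce_and_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            ours = holm_adjust(p)
            np.testing.assert_allclose(ours, holm_bruteforce(p), atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="holm")[1], atol=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=50))
    def test_conservative_and_monotone(self, p):
        adj = holm_adjust(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()


class TestLoessNormalize:
    def test_identical_columns_unchanged(self):
        rng = np.random.default_rng(1)
        col = 10 ** rng.normal(4, 1, 200)
        copies = pd.DataFrame({"a": col, "b": col})
        out = loess_normalize(copies)
        np.testing.assert_allclose(out.to_numpy(), copies.to_numpy(), rtol=1e-9)

    def test_constant_tenfold_offset_removed(self):
        rng = np.random.default_rng(2)
        col = 10 ** rng.normal(4, 1, 300)
        copies = pd.DataFrame({"a": col, "b": col * 10})
        out = loess_normalize(copies)
        med = np.median(np.log10(out["b"] / out["a"]))
        assert abs(med) < 0.01

    def test_intensity_dependent_bias_suppressed(self):
        rng = np.random.default_rng(3)
        base = 10 ** rng.normal(4, 1, 500)
        bias = 10 ** (0.3 * (np.log10(base) - 4))  # trend in abundance
        copies = pd.DataFrame({"a": base, "b": base * bias})
        out = loess_normalize(copies)

        def trend_amplitude(df):
            m = np.log10(df["a"] / df["b"])
            a = (np.log10(df["a"]) + np.log10(df["b"])) / 2
            fit = lowess(m, a, frac=0.75, return_sorted=False)
            return float(fit.max() - fit.min())

        assert trend_amplitude(out) < 0.1 * trend_amplitude(copies)

    def test_missing_values_pass_through(self):
        rng = np.random.default_rng(4)
        col = 10 ** rng.normal(4, 1, 120)
        copies = pd.DataFrame({"a": col, "b": col * 3})
        copies.iloc[5, 0] = np.nan
        out = loess_normalize(copies)
        assert np.isnan(out.iloc[5, 0])
        assert out.iloc[5, 1] > 0

    def test_too_few_common_proteins_rejected(self):
        copies = pd.DataFrame({"a": np.full(20, 1e4), "b": np.full(20, 2e4)})
        with pytest.raises(ValueError, match="common|detected"):
            loess_normalize(copies)


class TestPresenceFilter:
    def test_trivial_rules(self):
        det = pd.DataFrame({"A": [True, True], "B": [True, False], "C": [True, False]},
                           index=["all3", "only1"])
        retained, absent = presence_filter(det)
        assert list(retained) == ["all3"]
        assert not absent.loc["all3"].any()

    def test_matches_enumeration_of_patterns(self):
        # all 2^3 detection patterns over ten proteins
        patterns = [(a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)]
        det = pd.DataFrame(patterns + [(1, 1, 0), (0, 1, 1)],
                           columns=["A", "B", "C"]).astype(bool)
        det.index = [f"p{i}" for i in range(len(det))]
        retained, absent = presence_filter(det, min_systems=2)
        for acc in det.index:
            expected = det.loc[acc].sum() >= 2
            assert (acc in retained) == expected
            if expected:
                assert (absent.loc[acc] == ~det.loc[acc]).all()


class TestAnovaTukey:
    def test_identical_groups_give_p_one(self):
        p, tukey = anova_tukey({"A": [1.0, 1.0], "B": [1.0, 1.0], "C": [1.0, 1.0]})
        assert p == 1.0
        assert all(v == 1.0 for v in tukey.values())

    def test_strong_single_group_shift(self):
        rng = np.random.default_rng(5)
        groups = {"A": rng.normal(0, 0.1, 3), "B": rng.normal(0, 0.1, 3),
                  "C": rng.normal(10, 0.1, 3)}
        p, tukey = anova_tukey(groups)
        assert p < 1e-6
        assert tukey[("A", "C")] < 0.01 and tukey[("B", "C")] < 0.01
        assert tukey[("A", "B")] > 0.05

    def test_matches_statsmodels_tukey_oracle(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(6)
        for _ in range(50):
            sizes = rng.integers(3, 7, size=3)
            data = [rng.normal(rng.normal(0, 1), 1.0, n) for n in sizes]
            labels = np.concatenate([[f"g{i}"] * n for i, n in enumerate(sizes)])
            ours = anova_tukey({f"g{i}": d for i, d in enumerate(data)})[1]
            ref = pairwise_tukeyhsd(np.concatenate(data), labels)
            ref_p = dict(zip([tuple(pair) for pair in
                              np.array(ref.summary().data)[1:, :2]], ref.pvalues))
            for (a, b), p in ours.items():
                assert p == pytest.approx(ref_p[(a, b)], abs=1e-6)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(7)
        pvals = [anova_tukey({"A": rng.normal(0, 1, 4), "B": rng.normal(0, 1, 4),
                              "C": rng.normal(0, 1, 4)})[0] for _ in range(1000)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_insufficient_replication_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"A": [1.0], "B": [1.0, 2.0]})

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            sizes = {s: int(rng.integers(2, 6)) for s in "ABC"}
            data = {s: 10 ** rng.normal(4, 1, n) for s, n in sizes.items()}
            ap, tk = anova_tukey({s: np.log10(v) for s, v in data.items()})
            frames = {s: pd.DataFrame(v.reshape(1, -1)) for s, v in data.items()}
            vec = _anova_tukey_vectorized(frames, ["A", "B", "C"])
            assert vec["anova_p"].iloc[0] == pytest.approx(ap, abs=1e-8)
            for (a, b), p in tk.items():
                assert vec[f"tukey_p_{a}_vs_{b}"].iloc[0] == pytest.approx(p, abs=1e-6)


class TestCategorize:
    def test_absent_present_takes_precedence(self):
        assert categorize(None, None, True, False) == "absent_present"
        assert categorize(25.0, 0.001, False, True) == "absent_present"

    def test_large_fold_change_is_obvious_despite_p(self):
        assert categorize(25.0, 0.2, True, True) == "obvious"
        assert categorize(1 / 25.0, 0.2, True, True) == "obvious"

    def test_significant_and_unchanged(self):
        assert categorize(3.0, 0.01, True, True) == "significant"
        assert categorize(1.1, 0.5, True, True) == "unchanged"

    def test_threshold_is_strict(self):
        assert categorize(20.0, 0.5, True, True) == "unchanged"


@pytest.fixture(scope="module")
def cv20_run():
    cfg = SimulationConfig(
        seed=2, n_proteins=500, detect_midpoint_log10=None,
        replicates={"HepaRG": 3, "PHH": 3, "HepG2": 3})
    sim = simulate_proteome(cfg)
    copies = replicate_copies(sim)
    table = compare_systems(copies, sim.sample_systems, "PHH", normalize=False)
    return sim, table


class TestCompareSystems:
    def test_holm_dominates_anova_p(self, cv20_run):
        _, table = cv20_run
        ok = table["anova_p"].notna()
        assert (table.loc[ok, "holm_p"] >= table.loc[ok, "anova_p"] - 1e-15).all()

    def test_planted_labels_recovered_at_cv20(self, cv20_run):
        sim, table = cv20_run
        ok = tot = 0
        for s in ("HepaRG", "HepG2"):
            truth = sim.true_category[s].reindex(table.index)
            ok += (table[f"category_{s}"] == truth).sum()
            tot += len(truth)
        assert ok / tot >= 0.90

    def test_planted_labels_recovered_noiselessly(self):
        cfg = SimulationConfig(
            seed=2, n_proteins=500, noise_sd=0.0, detect_midpoint_log10=None,
            replicates={"HepaRG": 3, "PHH": 3, "HepG2": 3})
        sim = simulate_proteome(cfg)
        table = compare_systems(replicate_copies(sim), sim.sample_systems, "PHH",
                                normalize=False)
        ok = tot = 0
        for s in ("HepaRG", "HepG2"):
            truth = sim.true_category[s].reindex(table.index)
            ok += (table[f"category_{s}"] == truth).sum()
            tot += len(truth)
        assert ok / tot >= 0.99

    def test_no_effect_simulation_keeps_fold_changes_small(self):
        cfg = SimulationConfig(
            seed=3, n_proteins=400, detect_midpoint_log10=None,
            fraction_moderate_fc=0.0, fraction_large_fc=0.0,
            fraction_absent={"HepaRG": 0.0, "PHH": 0.0, "HepG2": 0.0},
            replicates={"HepaRG": 3, "PHH": 3, "HepG2": 3})
        sim = simulate_proteome(cfg)
        table = compare_systems(replicate_copies(sim), sim.sample_systems, "PHH",
                                normalize=False)
        for s in ("HepaRG", "HepG2"):
            frac_small = (table[f"log10_fc_{s}"].abs() < 1).mean()
            assert frac_small > 0.999

    def test_proteins_in_one_system_are_excluded(self):
        rng = np.random.default_rng(9)
        copies = pd.DataFrame(
            10 ** rng.normal(4, 1, (5, 6)),
            index=[f"p{i}" for i in range(5)],
            columns=[f"{s}_r{r}" for s in "ABC" for r in (1, 2)])
        systems = pd.Series([c.split("_")[0] for c in copies.columns],
                            index=copies.columns)
        copies.loc["p0", ~copies.columns.str.startswith("A")] = np.nan
        table = compare_systems(copies, systems, "A", normalize=False)
        assert "p0" not in table.index
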