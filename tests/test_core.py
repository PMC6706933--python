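"""Unit and property tests for the drugZ scoring stages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chemoscreen import (
    ConfigurationError,
    DrugzConfig,
    ScreenCounts,
    ValidationError,
    compute_fold_change,
    drugz,
    estimate_eb_std,
    gene_normz,
    guide_zscores,
    normalize_counts,
    pvalues_and_fdr,
)
from conftest import null_sim_config
from chemoscreen.simulate import simulate_screen
from helpers import bh_oracle, eb_std_oracle


class TestNormalization:
    def test_proportional_scaling(self):
        np.testing.assert_allclose(
            normalize_counts([1, 2, 3, 4], 1e7), [1e6, 2e6, 3e6, 4e6]
        )

    def test_output_sums_to_target(self, strong_screen):
        screen, _ = strong_screen
        for s in screen.sample_names:
            norm = normalize_counts(screen.counts[s], 1e7)
            assert norm.sum() == pytest.approx(1e7)

    def test_all_zero_column_errors(self):
        with pytest.raises(ValidationError, match="T1"):
            normalize_counts(np.zeros(5), 1e7, sample="T1")


class TestFoldChange:
    @pytest.mark.parametrize(
        "t,c,pc,expected",
        [
            (5.0, 5.0, 5.0, 0.0),
            (15.0, 5.0, 5.0, 1.0),  # log2(20/10)
            (0.0, 0.0, 5.0, 0.0),
        ],
    )
    def test_printed_formula(self, t, c, pc, expected):
        fc = compute_fold_change(np.array([t]), np.array([c]), pc)
        assert fc[0] == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            compute_fold_change(np.ones(3), np.ones(4), 5.0)

    @given(
        st.lists(
            st.integers(min_value=0, max_value=10**6), min_size=2, max_size=30
        ),
        st.lists(
            st.integers(min_value=0, max_value=10**6), min_size=2, max_size=30
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_always_finite(self, t, c):
        n = min(len(t), len(c))
        fc = compute_fold_change(
            np.array(t[:n], float), np.array(c[:n], float), 5.0
        )
        assert np.isfinite(fc).all()


class TestEbStd:
    def test_constant_fc_gives_rms_about_zero(self):
        fc = np.full(10, -1.5)
        cn = np.arange(10, 0, -1.0)
        eb = estimate_eb_std(fc, cn, window_size=4)
        np.testing.assert_allclose(eb, 1.5)

    def test_two_guide_window_hand_value(self):
        # window [3, 4] -> sqrt((9 + 16) / 2)
        eb = estimate_eb_std(
            np.array([3.0, 4.0]), np.array([2.0, 1.0]), window_size=2
        )
        np.testing.assert_allclose(eb, np.sqrt(25 / 2))
        assert eb[0] == pytest.approx(3.5355339)

    def test_monotone_filter_is_running_maximum(self):
        rng = np.random.default_rng(5)
        fc = rng.normal(0, 1, 200) * np.linspace(0.5, 2.0, 200)
        cn = np.arange(200, 0, -1.0)
        raw = estimate_eb_std(fc, cn, 20, monotone_filter=False)
        filt = estimate_eb_std(fc, cn, 20, monotone_filter=True)
        # cn is already descending, so row order == ranking order
        np.testing.assert_allclose(filt, np.maximum.accumulate(raw))
        assert (np.diff(filt) >= 0).all()

    @pytest.mark.parametrize("monotone", [False, True])
    @pytest.mark.parametrize("n_guides,window", [(30, 6), (9, 20), (50, 7)])
    def test_matches_brute_force_oracle(self, monotone, n_guides, window):
        rng = np.random.default_rng(n_guides)
        fc = rng.normal(0, 1, n_guides)
        cn = rng.integers(0, 500, n_guides).astype(float)
        ids = np.array([f"g{i:03d}" for i in range(n_guides)])
        got = estimate_eb_std(fc, cn, window, monotone, ids)
        want = eb_std_oracle(fc, cn, window, monotone, ids)
        np.testing.assert_allclose(got, want)

    def test_small_window_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_eb_std(np.ones(5), np.ones(5), window_size=1)


class TestGuideZ:
    def test_ratio_and_zero(self):
        z = guide_zscores(np.array([1.0, 0.0]), np.array([0.5, 7.0]))
        np.testing.assert_allclose(z, [2.0, 0.0])

    def test_zero_eb_std_errors(self):
        with pytest.raises(ValidationError):
            guide_zscores(np.ones(2), np.array([1.0, 0.0]))


class TestGeneAggregation:
    def test_single_term(self):
        out = gene_normz(np.array([2.0]), np.array(["A"]))
        assert out.loc[0, "normZ"] == pytest.approx(2.0)
        assert out.loc[0, "numObs"] == 1

    def test_four_terms_sqrt_normalization(self):
        out = gene_normz(np.ones(4), np.array(["A"] * 4))
        assert out.loc[0, "sumZ"] == pytest.approx(4.0)
        assert out.loc[0, "normZ"] == pytest.approx(2.0)

    def test_normz_is_standard_normal_under_null(self):
        """10,000 genes x 4 iid N(0,1) terms: the sqrt(n) normalization
        keeps the gene score standard normal."""
        rng = np.random.default_rng(0)
        z = rng.normal(size=40_000)
        genes = np.repeat([f"G{i}" for i in range(10_000)], 4)
        out = gene_normz(z, genes)
        assert abs(out["normZ"].mean()) < 0.05
        assert abs(out["normZ"].std(ddof=1) - 1) < 0.05


class TestPvaluesAndFdr:
    def test_zero_normz_is_half_in_both_directions(self):
        out = pvalues_and_fdr(
            pd.DataFrame({"GENE": ["A"], "normZ": [0.0]})
        )
        assert out.loc[0, "pval_synth"] == pytest.approx(0.5)
        assert out.loc[0, "pval_supp"] == pytest.approx(0.5)

    def test_standard_normal_quantile(self):
        out = pvalues_and_fdr(
            pd.DataFrame({"GENE": ["A"], "normZ": [-1.6449]})
        )
        assert out.loc[0, "pval_synth"] == pytest.approx(0.05, abs=1e-4)

    def test_bh_hand_example(self):
        # p = [0.01, 0.02, 0.03, 0.04] -> all adjusted to 0.04
        normz = stats.norm.ppf([0.01, 0.02, 0.03, 0.04])
        out = pvalues_and_fdr(
            pd.DataFrame({"GENE": list("ABCD"), "normZ": normz})
        )
        np.testing.assert_allclose(out["fdr_synth"], 0.04, rtol=1e-6)

    def test_ranks_are_permutations_and_fdr_ge_pval(self, strong_screen):
        screen, _ = strong_screen
        res = drugz(screen)
        g = len(res)
        for side in ("synth", "supp"):
            assert sorted(res[f"rank_{side}"]) == list(range(1, g + 1))
            assert (res[f"fdr_{side}"] >= res[f"pval_{side}"] - 1e-12).all()
            assert (res[f"fdr_{side}"] <= 1).all()
            assert res[f"pval_{side}"].between(0, 1).all()


class TestDrugzPipeline:
    def test_null_identity_treated_equals_control(self, tiny_screen):
        """Treated columns identical to control: every fc is 0, every
        normZ is 0, and both one-tailed p-values sit at 0.5."""
        counts = tiny_screen.counts.copy()
        counts["T1"] = counts["C1"]
        screen = ScreenCounts(
            counts=counts,
            genes=tiny_screen.genes,
            control_samples=["C1"],
            treated_samples=["T1"],
        )
        res = drugz(screen, DrugzConfig(window_size=3))
        np.testing.assert_allclose(res["normZ"], 0.0)
        np.testing.assert_allclose(res["pval_synth"], 0.5)
        np.testing.assert_allclose(res["pval_supp"], 0.5)

    def test_planted_synergy_genes_rank_most_negative(self, strong_screen):
        screen, truth = strong_screen
        res = drugz(screen)
        synergy = set(truth.genes_with("synergy"))
        top75 = set(res.head(75)["GENE"])  # results sorted by normZ asc
        assert len(synergy & top75) >= 45

    def test_paired_vs_unpaired_concordance(self, strong_screen):
        screen, _ = strong_screen
        paired = drugz(screen).set_index("GENE")["normZ"]
        unpaired = drugz(screen, DrugzConfig(paired=False)).set_index(
            "GENE"
        )["normZ"]
        rho = stats.spearmanr(paired, unpaired.loc[paired.index]).statistic
        assert rho >= 0.9

    def test_paired_mode_rejects_unequal_arms(self, tiny_screen):
        screen = tiny_screen.with_roles(["C1"], ["T1", "C1"])
        with pytest.raises(ConfigurationError, match="unpaired"):
            drugz(screen, DrugzConfig(paired=True))
        # unpaired tolerates the asymmetry
        res = drugz(screen, DrugzConfig(paired=False, window_size=3))
        assert len(res) == 3

    def test_normz_invariant_to_row_and_pair_order(self, null_screen):
        screen, _ = null_screen
        base = drugz(screen).set_index("GENE")["normZ"]

        rng = np.random.default_rng(1)
        perm = rng.permutation(screen.n_guides)
        shuffled = ScreenCounts(
            counts=screen.counts.iloc[perm],
            genes=screen.genes.iloc[perm],
            control_samples=screen.control_samples,
            treated_samples=screen.treated_samples,
        )
        np.testing.assert_allclose(
            drugz(shuffled).set_index("GENE")["normZ"].loc[base.index],
            base,
        )
        # permuting replicate pairs (both arms together) changes nothing
        repaired = screen.with_roles(
            [screen.control_samples[i] for i in (2, 0, 1)],
            [screen.treated_samples[i] for i in (2, 0, 1)],
        )
        np.testing.assert_allclose(
            drugz(repaired).set_index("GENE")["normZ"].loc[base.index],
            base,
        )

    def test_unpaired_invariant_to_within_arm_order(self, null_screen):
        screen, _ = null_screen
        cfg = DrugzConfig(paired=False)
        base = drugz(screen, cfg).set_index("GENE")["normZ"]
        swapped = screen.with_roles(
            screen.control_samples[::-1], screen.treated_samples[::-1]
        )
        np.testing.assert_allclose(
            drugz(swapped, cfg).set_index("GENE")["normZ"].loc[base.index],
            base,
        )

    def test_doubling_counts_leaves_normz_unchanged(self, null_screen):
        """Depth normalization makes a uniform count doubling an exact
        no-op: the pseudocount is added on the normalized scale."""
        screen, _ = null_screen
        doubled = ScreenCounts(
            counts=screen.counts * 2,
            genes=screen.genes,
            control_samples=screen.control_samples,
            treated_samples=screen.treated_samples,
        )
        np.testing.assert_allclose(
            drugz(doubled)["normZ"], drugz(screen)["normZ"]
        )

    def test_remove_genes_excluded_before_fdr(self, null_screen):
        screen, _ = null_screen
        drop = set(screen.genes.unique()[:10])
        res = drugz(screen, DrugzConfig(remove_genes=frozenset(drop)))
        assert drop.isdisjoint(res["GENE"])
        assert sorted(res["rank_synth"]) == list(range(1, len(res) + 1))

    def test_min_control_reads_drops_low_guides(self, strong_screen):
        screen, _ = strong_screen
        res = drugz(screen, DrugzConfig(min_control_reads=50))
        base = drugz(screen)
        assert res["numObs"].sum() < base["numObs"].sum()


def test_bh_matches_brute_force_oracle():
    """statsmodels' step-up BH equals the O(m^2) oracle on random vectors."""
    rng = np.random.default_rng(0)
    for _ in range(25):
        m = rng.integers(1, 40)
        p = rng.uniform(size=m)
        df = pd.DataFrame(
            {"GENE": [f"G{i}" for i in range(m)], "normZ": stats.norm.ppf(p)}
        )
        out = pvalues_and_fdr(df)
        np.testing.assert_allclose(
            out["fdr_synth"], bh_oracle(p), rtol=1e-9, atol=1e-12
        )


def test_null_calibration_small():
    """Null screens: normZ approximately standard normal, few false hits."""
    fracs = []
    for seed in range(3):
        screen, _ = simulate_screen(null_sim_config(seed, n_genes=300))
        res = drugz(screen)
        assert abs(res["normZ"].mean()) < 0.15
        assert abs(res["normZ"].std(ddof=1) - 1) < 0.15
        fracs.append((res["fdr_synth"] < 0.05).mean())
    assert np.mean(fracs) <= 0.07
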