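"""Dual-control differential editing: pooling, chi-square, Bonferroni, delta gate."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orgedit import (
    ConfigError,
    InputError,
    SimConfig,
    bonferroni_threshold,
    call_reduced_sites,
    chi2_2x2,
    compare_site_sets,
    exclude_control_affected,
    pool_replicates,
)
from orgedit.differential import _chi2_arrays
from orgedit.io import COUNT_COLUMNS
from orgedit.simulate import simulate_counts, simulate_reference, simulate_truth


def counts_row(lib, nC, nT, nOther=0, pos=100, org="mitochondrion"):
    return [org, "mt-gene01", "C10", pos, "+", lib, nC, nT, nOther]


def counts_frame(rows):
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


DESIGN = {
    "uninoculated_rep1": "uninoculated",
    "uninoculated_rep2": "uninoculated",
    "gfp_silenced_rep1": "gfp_silenced",
    "gfp_silenced_rep2": "gfp_silenced",
    "treatment_rep1": "treatment",
    "treatment_rep2": "treatment",
}


def experiment_counts(seed, n_sites=618, depth=1000.0, n_virus=0, n_silencing=0):
    cfg = SimConfig.mito_universe(
        seed=seed,
        n_sites=n_sites,
        mean_depth=depth,
        n_virus=n_virus,
        n_silencing=n_silencing,
    )
    _, _, sites = simulate_reference(cfg)
    truth = simulate_truth(sites, cfg)
    return truth, simulate_counts(truth, cfg), cfg.design()


class TestPooling:
    def test_single_replicate_is_identity(self):
        c = counts_frame([counts_row("a", 10, 5, 1)])
        pooled = pool_replicates(c)
        assert pooled[["nC", "nT", "nOther"]].iloc[0].tolist() == [10, 5, 1]

    def test_pooling_sums_elementwise(self):
        c = counts_frame([counts_row("a", 10, 5, 0), counts_row("b", 20, 15, 1)])
        pooled = pool_replicates(c)
        assert pooled[["nC", "nT", "nOther"]].iloc[0].tolist() == [30, 20, 1]

    def test_pooled_extent_of_equal_depth_replicates_is_mean_extent(self):
        # with equal C+T depth per replicate, pooling averages the extents
        c = counts_frame([counts_row("a", 80, 20), counts_row("b", 60, 40)])
        pooled = pool_replicates(c)
        ext = pooled["nT"] / (pooled["nC"] + pooled["nT"])
        assert ext.iloc[0] == pytest.approx((0.2 + 0.4) / 2)


class TestBonferroni:
    def test_mitochondrial_universe_threshold(self):
        # 1e-3 familywise over 618 sites -> 1.6e-6 at two significant figures
        thr = bonferroni_threshold(1e-3, 618)
        assert float(f"{thr:.1e}") == 1.6e-6

    def test_plastid_universe_threshold(self):
        thr = bonferroni_threshold(1e-3, 38)
        assert float(f"{thr:.1e}") == 2.6e-5

    def test_single_test_is_identity(self):
        assert bonferroni_threshold(0.01, 1) == 0.01

    def test_zero_tests_rejected(self):
        with pytest.raises(ConfigError):
            bonferroni_threshold(1e-3, 0)


class TestChi2:
    def test_equal_proportions_give_zero(self):
        stat, p = chi2_2x2((100, 100), (50, 50))
        assert stat == 0.0 and p == 1.0

    def test_textbook_2x2_value(self):
        # 200 * (90*50 - 10*50)^2 / (100 * 100 * 140 * 60)
        stat, _ = chi2_2x2((90, 10), (50, 50))
        assert stat == pytest.approx(200 * (90 * 50 - 10 * 50) ** 2 / (100 * 100 * 140 * 60))
        assert stat == pytest.approx(38.095238, abs=1e-6)

    def test_maximal_association_is_total_n(self):
        stat, _ = chi2_2x2((0, 50), (50, 0))
        assert stat == pytest.approx(100.0)

    def test_zero_column_margin_is_not_testable(self):
        stat, p = chi2_2x2((50, 0), (70, 0))
        assert np.isnan(stat) and np.isnan(p)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            chi2_2x2((0, 0), (10, 10))

    @settings(derandomize=True, max_examples=300)
    @given(
        c1=st.integers(0, 500),
        t1=st.integers(0, 500),
        c2=st.integers(0, 500),
        t2=st.integers(0, 500),
    )
    def test_row_swap_symmetry(self, c1, t1, c2, t2):
        if c1 + t1 == 0 or c2 + t2 == 0:
            return
        s1, _ = _chi2_arrays(c1, t1, c2, t2)
        s2, _ = _chi2_arrays(c2, t2, c1, t1)
        assert np.isnan(s1) and np.isnan(s2) or s1 == pytest.approx(float(s2), rel=1e-12)

    def test_vectorised_path_matches_scalar_scipy_route(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a = tuple(rng.integers(1, 400, size=2))
            b = tuple(rng.integers(1, 400, size=2))
            stat_s, p_s = chi2_2x2(a, b)
            stat_v, p_v = _chi2_arrays(a[0], a[1], b[0], b[1])
            if np.isnan(stat_s):
                assert np.isnan(float(stat_v))
            else:
                assert float(stat_v) == pytest.approx(stat_s, abs=1e-9)
                assert float(p_v) == pytest.approx(p_s, abs=1e-12)


class TestCompareSiteSets:
    def test_identical_sets_share_everything(self):
        a = {("m", i, "+") for i in range(10)}
        assert compare_site_sets(a, a) == (10, 100, 100)

    def test_printed_overlap_percentage(self):
        # 25 of 32 sites shared -> 78%
        a = set(range(32))
        b = set(range(25)) | {100 + i for i in range(40)}
        inter, pct_a, _ = compare_site_sets(a, b)
        assert inter == 25 and pct_a == 78

    def test_disjoint_sets_share_nothing(self):
        assert compare_site_sets({1, 2}, {3}) == (0, 0, 0)

    def test_rounding_is_half_up(self):
        # 35/618 = 5.66% -> 6; 1/8 = 12.5% -> 13
        assert compare_site_sets(set(range(8)), {0})[1] == 13


class TestControlAffectedExclusion:
    def test_identical_controls_are_not_flagged(self):
        rows = [counts_row(lib, 500, 500) for lib in DESIGN]
        flags = exclude_control_affected(counts_frame(rows), DESIGN, threshold=1.6e-6)
        assert not flags["control_affected"].any()

    def test_virus_depressed_site_is_flagged_at_depth(self):
        # extent 0.8 -> 0.5 in the GFP-silenced control, depth 2000
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.5 if cond in ("gfp_silenced", "treatment") else 0.8
            rows.append(counts_row(lib, int(2000 * (1 - ext)), int(2000 * ext)))
        flags = exclude_control_affected(counts_frame(rows), DESIGN, threshold=1.6e-6)
        assert flags["control_affected"].all()

    def test_same_delta_at_tiny_depth_lacks_power(self):
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.5 if cond in ("gfp_silenced", "treatment") else 0.8
            rows.append(counts_row(lib, int(5 * (1 - ext)), int(5 * ext)))
        flags = exclude_control_affected(counts_frame(rows), DESIGN, threshold=1.6e-6)
        assert not flags["control_affected"].any()


class TestCallReducedSites:
    def test_virus_artifact_is_excluded_not_significant(self):
        # reduced in BOTH GFP-silenced and treatment -> dual-control exclusion
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.5 if cond in ("gfp_silenced", "treatment") else 0.8
            rows.append(counts_row(lib, int(2000 * (1 - ext)), int(2000 * ext)))
        calls = call_reduced_sites(counts_frame(rows), DESIGN)
        assert calls["excluded_control_affected"].all()
        assert not calls["significant"].any()

    def test_genuine_silencing_site_is_significant(self):
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.5 if cond == "treatment" else 0.8
            rows.append(counts_row(lib, int(2000 * (1 - ext)), int(2000 * ext)))
        calls = call_reduced_sites(counts_frame(rows), DESIGN)
        assert calls["significant"].all()
        assert calls["delta_vs_uninoc"].iloc[0] == pytest.approx(0.3, abs=0.01)

    def test_small_delta_fails_the_effect_size_gate(self):
        # massively significant chi-square but delta < 0.1 must not be called
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.75 if cond == "treatment" else 0.8
            rows.append(counts_row(lib, int(50_000 * (1 - ext)), int(50_000 * ext)))
        calls = call_reduced_sites(counts_frame(rows), DESIGN)
        assert (calls["p_vs_uninoc"] < calls["threshold"]).all()
        assert not calls["significant"].any()

    def test_increase_is_never_called(self):
        rows = []
        for lib, cond in DESIGN.items():
            ext = 0.9 if cond == "treatment" else 0.5
            rows.append(counts_row(lib, int(5000 * (1 - ext)), int(5000 * ext)))
        calls = call_reduced_sites(counts_frame(rows), DESIGN)
        assert not calls["significant"].any()

    def test_replicate_order_is_irrelevant(self):
        truth, counts, design = experiment_counts(seed=9, n_sites=60, n_silencing=6)
        calls = call_reduced_sites(counts, design)
        swapped = {
            "uninoculated_rep1": "uninoculated",
            "uninoculated_rep2": "uninoculated",
            "gfp_silenced_rep2": "gfp_silenced",
            "gfp_silenced_rep1": "gfp_silenced",
            "treatment_rep2": "treatment",
            "treatment_rep1": "treatment",
        }
        shuffled = counts.sample(frac=1.0, random_state=0)
        calls2 = call_reduced_sites(shuffled, swapped)
        pd.testing.assert_frame_equal(calls, calls2)

    def test_dual_control_verdict_is_subset_of_single_control(self):
        truth, counts, design = experiment_counts(
            seed=4, n_sites=200, n_virus=10, n_silencing=10
        )
        calls = call_reduced_sites(counts, design)
        single = (calls["p_vs_uninoc"] < calls["threshold"]) & (
            calls["delta_vs_uninoc"] >= 0.1
        )
        assert (calls["significant"] <= single).all()

    def test_planted_effects_recovered_and_virus_excluded(self):
        truth, counts, design = experiment_counts(
            seed=11, depth=2000.0, n_virus=54, n_silencing=35
        )
        calls = call_reduced_sites(counts, design)
        merged = calls.merge(
            truth[["organelle", "genomic_pos_0based", "strand", "effect"]],
            on=["organelle", "genomic_pos_0based", "strand"],
        )
        by_effect = merged.groupby("effect")["significant"].agg(["sum", "count"])
        assert by_effect.loc["silencing_affected", "sum"] == 35
        assert by_effect.loc["stable", "sum"] == 0
        assert by_effect.loc["virus_affected", "sum"] == 0
        assert merged.loc[
            merged["effect"] == "virus_affected", "excluded_control_affected"
        ].all()

    def test_per_replicate_mode_agrees_on_strong_effects(self):
        truth, counts, design = experiment_counts(
            seed=12, depth=2000.0, n_sites=100, n_silencing=10
        )
        pooled = call_reduced_sites(counts, design, mode="pooled")
        per_rep = call_reduced_sites(counts, design, mode="per_replicate")
        assert pooled["significant"].sum() == 10
        pd.testing.assert_series_equal(pooled["significant"], per_rep["significant"])

    def test_missing_condition_is_design_error(self):
        rows = [counts_row(lib, 100, 100) for lib in DESIGN if "gfp" not in lib]
        design = {k: v for k, v in DESIGN.items() if "gfp" not in k}
        with pytest.raises(InputError):
            call_reduced_sites(counts_frame(rows), design)
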