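from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metscreen as ms
from metscreen.enrich import EnrichmentError, DetectionRule
from metscreen.io import build_library, build_sample_meta
from metscreen.quant import GuideStats


def exact_wilcoxon_oracle(x, y):
    """One-sided rank-sum p by exhaustive enumeration of rank assignments.

    P(W >= w_obs) where W is the sum of x's ranks, over all C(n+m, n)
    equally likely assignments of the pooled ranks to the x positions.
    Valid when the pooled values have no ties.
    """
    pooled = sorted(x) + sorted(y)
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    w_obs = sum(ranks[v] for v in x)
    n, total = len(x), len(x) + len(y)
    count = sum(
        1 for comb in combinations(range(1, total + 1), n) if sum(comb) >= w_obs
    )
    from math import comb as nchoosek

    return count / nchoosek(total, n)


def bh_oracle(p):
    """Brute-force BH step-up: q_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        q[idx] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0
        )
    return q


class TestDetection:
    @pytest.mark.parametrize(
        "count,threshold,expected",
        [(0, 1, False), (1, 1, True), (4, 5, False), (5, 5, True)],
    )
    def test_raw_count_threshold_boundaries(self, count, threshold, expected):
        counts = pd.DataFrame({"s": [count]}, index=["g1"])
        det = ms.detect_guides(counts, DetectionRule(min_raw_count=threshold))
        assert bool(det.loc["g1", "s"]) is expected

    def test_abundance_rule_needs_abundance_matrix(self):
        counts = pd.DataFrame({"s": [5]}, index=["g1"])
        rule = DetectionRule(min_raw_count=None, min_abundance=100.0)
        with pytest.raises(EnrichmentError):
            ms.detect_guides(counts, rule)
        ab = pd.DataFrame({"s": [250.0]}, index=["g1"])
        assert ms.detect_guides(counts, rule, abundance=ab).loc["g1", "s"]

    def test_exactly_one_criterion_enforced(self):
        with pytest.raises(EnrichmentError):
            DetectionRule(min_raw_count=1, min_abundance=1.0)
        with pytest.raises(EnrichmentError):
            DetectionRule(min_raw_count=None, min_abundance=None)


class TestWilcoxon:
    def test_identical_samples_give_p_at_least_half(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert ms.wilcoxon_one_sided(x, x) >= 0.5

    def test_complete_separation_matches_combinatorial_value(self):
        # all x above all y: one-sided p = 1 / C(8, 3) = 1/56
        p = ms.wilcoxon_one_sided([10, 11, 12], [1, 2, 3, 4, 5])
        assert p == pytest.approx(1 / 56)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(EnrichmentError):
            ms.wilcoxon_one_sided([], [1.0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.data(),
        st.integers(min_value=1, max_value=6),
        st.integers(min_value=1, max_value=6),
    )
    def test_exact_path_equals_enumeration_oracle(self, data, nx, ny):
        vals = data.draw(
            st.lists(
                st.integers(min_value=-100, max_value=100),
                min_size=nx + ny,
                max_size=nx + ny,
                unique=True,
            )
        )
        x = [float(v) for v in vals[:nx]]
        y = [float(v) for v in vals[nx:]]
        assert ms.wilcoxon_one_sided(x, y) == pytest.approx(
            exact_wilcoxon_oracle(x, y), rel=1e-12
        )

    def test_null_rejection_rate_close_to_alpha(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_sim = 2000
        for _ in range(n_sim):
            x = rng.normal(size=12)
            y = rng.normal(size=30)
            if ms.wilcoxon_one_sided(x, y) < 0.05:
                rejections += 1
        rate = rejections / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert abs(rate - 0.05) < 4 * se


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert ms.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_three_value_step_up(self):
        assert np.allclose(ms.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_ones_stay_capped(self):
        assert ms.bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_out_of_range_rejected(self):
        with pytest.raises(EnrichmentError):
            ms.bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=50,
        )
    )
    def test_matches_brute_force_and_is_monotone(self, p):
        q = ms.bh_adjust(p)
        assert np.allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _stats_from_lfc(lfc, library):
    """GuideStats with a placeholder abundance sharing the LFC layout."""
    ab = 2.0 ** lfc * 100.0
    return GuideStats(abundance=ab, lfc=lfc, pseudocount=0.5)


class TestGeneTable:
    @pytest.fixture
    def single_guide_library(self):
        return build_library(
            pd.DataFrame(
                {
                    "guide_id": ["g1", "c1", "c2"],
                    "gene": ["GENEA", "CONTROL", "CONTROL"],
                    "protospacer": [
                        "ACGTACGTACGTACGTACGT",
                        "TTTTACGTACGTACGTACGT",
                        "GGGGACGTACGTACGTACGT",
                    ],
                }
            )
        )

    @pytest.fixture
    def four_sample_meta(self):
        return build_sample_meta(
            pd.DataFrame(
                {
                    "sample_id": ["l1", "l2", "b1", "b2"],
                    "mouse_id": ["m1", "m2", "m1", "m2"],
                    "tissue": ["lung", "lung", "brain", "brain"],
                }
            )
        )

    def test_hand_computed_tissue_means_and_fold_enrichment(
        self, single_guide_library, four_sample_meta
    ):
        # one guide: lung lfc {1, 3}, brain lfc {5, 7}
        lfc = pd.DataFrame(
            {"l1": [1.0, 0, 0], "l2": [3.0, 0, 0], "b1": [5.0, 0, 0], "b2": [7.0, 0, 0]},
            index=single_guide_library.guide_ids,
        )
        det = lfc.abs() >= 0  # everything detected
        enr = ms.gene_table(
            _stats_from_lfc(lfc, single_guide_library),
            det,
            four_sample_meta,
            single_guide_library,
        )
        row = enr.genes.iloc[0]
        assert row["mean_lung_lfc"] == pytest.approx(2.0)
        assert row["mean_brain_lfc"] == pytest.approx(6.0)
        assert row["fold_enrichment"] == pytest.approx(16.0)

    def test_symmetric_tissues_give_fold_enrichment_one(self, toy_library, toy_meta):
        rng = np.random.default_rng(5)
        base = rng.integers(10, 500, size=6)
        counts = pd.DataFrame(
            {s: base for s in ["T0", "lung_m1", "lung_m2", "brain_m1", "brain_m2"]},
            index=toy_library.guide_ids,
        ).astype(np.int64)
        res = ms.ScreenModel(ms.CountMatrix(counts=counts), toy_library, toy_meta).fit()
        assert np.allclose(res.gene_table["fold_enrichment"], 1.0)

    def test_fold_enrichment_invariant_to_common_lfc_shift(
        self, single_guide_library, four_sample_meta
    ):
        lfc = pd.DataFrame(
            {"l1": [1.0, 0, 0], "l2": [3.0, 0, 0], "b1": [5.0, 0, 0], "b2": [7.0, 0, 0]},
            index=single_guide_library.guide_ids,
        )
        det = lfc.abs() >= 0
        fe1 = ms.gene_table(
            _stats_from_lfc(lfc, single_guide_library), det, four_sample_meta,
            single_guide_library,
        ).genes["fold_enrichment"].iloc[0]
        fe2 = ms.gene_table(
            _stats_from_lfc(lfc + 2.5, single_guide_library), det, four_sample_meta,
            single_guide_library,
        ).genes["fold_enrichment"].iloc[0]
        assert fe1 == pytest.approx(fe2)

    def test_undetected_guide_contributes_zero_to_brain_count(
        self, toy_library, toy_meta, toy_counts
    ):
        counts = toy_counts.counts.copy()
        counts.loc["gA1", ["brain_m1", "brain_m2"]] = 0
        counts.loc["gA2", ["brain_m1", "brain_m2"]] = 0
        res = ms.ScreenModel(ms.CountMatrix(counts=counts), toy_library, toy_meta).fit()
        row = res.gene_table.set_index("gene").loc["GENEA"]
        assert row["n_guides_brain_detected"] == 0

    def test_detection_counts_are_unions_over_tissue_samples(
        self, toy_library, toy_meta, toy_counts
    ):
        counts = toy_counts.counts.copy()
        counts.loc["gA1", "brain_m1"] = 0
        counts.loc["gA1", "brain_m2"] = 3  # detected in one brain only
        res = ms.ScreenModel(ms.CountMatrix(counts=counts), toy_library, toy_meta).fit()
        row = res.gene_table.set_index("gene").loc["GENEA"]
        assert row["n_guides_brain_detected"] == 2

    def test_per_sample_test_mode_also_produces_valid_p(self, toy_library, toy_meta, toy_counts):
        res = ms.ScreenModel(toy_counts, toy_library, toy_meta).fit(test="per_sample")
        p = res.gene_table["p_value"]
        assert ((p >= 0) & (p <= 1)).all()
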