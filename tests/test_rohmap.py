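"""Homozygosity-mapping tests, including brute-force oracles over all
intervals and hypothesis property checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lethalmap.rohmap import (
    CASE_SHARED_INFORMATIVE,
    CASE_SHARED_ONLY,
    NOT_SHARED,
    classify_snp,
    filter_informative,
    longest_shared_segment,
    segment_span_mbp,
    summary_rows,
)


def make_map(n, chrom=1, start=1_000_000, step=100_000):
    return pd.DataFrame(
        {
            "snp": [f"s{chrom}_{j}" for j in range(n)],
            "chrom": chrom,
            "pos": start + step * np.arange(n),
            "a1": "1",
            "a2": "2",
        }
    )


class TestFilterInformative:
    def test_monomorphic_and_all_het_dropped(self):
        g = np.array([[0, 1, 2], [0, 1, 0], [0, 1, 1]])  # snp0 fixed, snp1 all-het
        _, m, kept = filter_informative(g, make_map(3))
        assert kept == 1 and list(m["snp"]) == ["s1_2"]

    def test_non_autosomal_dropped(self):
        g = np.array([[0, 2], [2, 0]])
        snp_map = make_map(2)
        snp_map["chrom"] = snp_map["chrom"].astype(object)
        snp_map.loc[1, "chrom"] = "X"
        _, m, kept = filter_informative(g, snp_map)
        assert kept == 1 and list(m["chrom"]) == [1]

    def test_planted_violations_counted(self):
        rng = np.random.default_rng(0)
        n, bad = 1000, 50
        g = rng.integers(0, 3, size=(12, n)).astype(np.int8)
        # ensure baseline informativeness everywhere, then plant violations
        g[0, :] = 0
        g[1, :] = 2
        viol = rng.choice(n, size=bad, replace=False)
        g[:, viol[:25]] = 1  # completely heterozygous
        g[:, viol[25:]] = 0  # fixed
        _, _, kept = filter_informative(g, make_map(n))
        assert kept == n - bad

    def test_empty_result_errors(self):
        with pytest.raises(ValueError, match="no informative"):
            filter_informative(np.ones((4, 3), dtype=int), make_map(3))


def classify_oracle(cases, controls):
    cases = [c for c in cases if c >= 0]
    if not cases or 1 in cases or (0 in cases and 2 in cases):
        return NOT_SHARED
    shared = cases[0]
    informative = any(c == 1 or c == 2 - shared for c in controls if c >= 0)
    return CASE_SHARED_INFORMATIVE if informative else CASE_SHARED_ONLY


class TestClassify:
    def test_shared_hom_with_het_control(self):
        assert classify_snp([2, 2, 2], [1, 0]) == CASE_SHARED_INFORMATIVE

    def test_split_homozygotes_not_shared(self):
        assert classify_snp([0, 2], [0, 0]) == NOT_SHARED

    def test_shared_without_informative_control(self):
        assert classify_snp([0, 0], [0, 0]) == CASE_SHARED_ONLY

    def test_all_missing_cases_not_shared(self):
        assert classify_snp([-1, -1], [1]) == NOT_SHARED

    @given(st.integers(0, 2**40 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_on_random_panels(self, packed):
        rng = np.random.default_rng(packed)
        cases = rng.integers(-1, 3, size=10)
        controls = rng.integers(-1, 3, size=10)
        assert classify_snp(cases, controls) == classify_oracle(
            list(cases), list(controls)
        )


def brute_force_segments(case_g, snp_map, allow_het=0):
    """All-intervals scan: the longest run is the maximal interval in which
    every SNP individually satisfies the shared-homozygosity predicate."""
    m = case_g.shape[1]
    ok = np.zeros(m, dtype=bool)
    for j in range(m):
        col = [c for c in case_g[:, j] if c >= 0]
        if not col:
            continue
        n_het = sum(c == 1 for c in col)
        homs = {c for c in col if c != 1}
        ok[j] = n_het <= allow_het and len(homs) <= 1
    best = (0, None, None)
    chroms = snp_map["chrom"].to_numpy()
    for i in range(m):
        for j in range(i, m):
            if chroms[i] != chroms[j]:
                continue
            if all(ok[i : j + 1]):
                if j - i + 1 > best[0]:
                    best = (j - i + 1, i, j)
    return best


class TestLongestSegment:
    def test_single_fully_homozygous_case_spans_chromosome(self):
        g = np.zeros((1, 20), dtype=np.int8)
        segs = longest_shared_segment(g, make_map(20), [True])
        assert len(segs) == 1 and segs[0].n_snps == 20

    def test_planted_run_recovered_exactly(self):
        """A planted 55-SNP shared-homozygous run is the unique top segment."""
        rng = np.random.default_rng(1)
        n = 300
        snp_map = make_map(n)
        g = rng.integers(0, 3, size=(20, n)).astype(np.int8)
        cases = np.arange(10)
        start = 120
        g[cases, :] = rng.integers(0, 3, size=(10, n))
        # break any accidental case-shared run: make one case het everywhere
        g[0, :] = 1
        g[np.ix_(cases, range(start, start + 55))] = 2
        segs = longest_shared_segment(g, snp_map, [True] * 10 + [False] * 10)
        top = segs[0]
        assert top.n_snps == 55
        assert top.start_snp == f"s1_{start}" and top.end_snp == f"s1_{start + 54}"

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_equals_brute_force_interval_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        g = rng.integers(0, 3, size=(6, n)).astype(np.int8)
        g[g == 0] = rng.integers(-1, 1, size=(g == 0).sum())  # sprinkle missing
        snp_map = make_map(n)
        case_mask = np.array([True] * 3 + [False] * 3)
        segs = longest_shared_segment(g, snp_map, case_mask)
        best_len, i, j = brute_force_segments(g[case_mask], snp_map)
        if best_len == 0:
            assert segs == []
        else:
            assert segs[0].n_snps == best_len

    def test_segments_are_maximal(self):
        rng = np.random.default_rng(5)
        n = 200
        g = rng.integers(0, 3, size=(8, n)).astype(np.int8)
        snp_map = make_map(n)
        case_mask = np.array([True] * 4 + [False] * 4)
        segs = longest_shared_segment(g, snp_map, case_mask)
        snp_pos = {s: k for k, s in enumerate(snp_map["snp"])}
        for s in segs:
            lo, hi = snp_pos[s.start_snp], snp_pos[s.end_snp]
            for edge in (lo - 1, hi + 1):
                if 0 <= edge < n:
                    assert classify_oracle(list(g[case_mask][:, edge]), []) == NOT_SHARED

    def test_het_tolerance_is_monotone(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(8, 150)).astype(np.int8)
        snp_map = make_map(150)
        mask = np.array([True] * 4 + [False] * 4)
        strict = longest_shared_segment(g, snp_map, mask, allow_case_het=0)
        relaxed = longest_shared_segment(g, snp_map, mask, allow_case_het=1)
        n0 = strict[0].n_snps if strict else 0
        n1 = relaxed[0].n_snps if relaxed else 0
        assert n1 >= n0


class TestSpanAndSummary:
    def test_span_worked_example(self):
        assert segment_span_mbp(86_745_668, 95_062_143) == 8.3

    def test_span_degenerate_and_unit(self):
        assert segment_span_mbp(5, 5) == 0.0
        assert segment_span_mbp(1, 1_000_001) == 1.0

    def test_span_negative_rejected(self):
        with pytest.raises(ValueError):
            segment_span_mbp(10, 5)

    def test_consensus_rules(self):
        g = np.array([[0, 0, 2], [0, 0, 2], [0, 1, 2]])
        rows = summary_rows(g, ["case", "case", "case"])
        np.testing.assert_array_equal(rows.loc["case"].to_numpy(), [0, 1, 2])

    @given(st.integers(0, 2**40 - 1))
    @settings(max_examples=40, deadline=None)
    def test_consensus_matches_brute_force(self, packed):
        rng = np.random.default_rng(packed)
        g = rng.integers(-1, 3, size=(6, 8))
        labels = np.array(["a"] * 3 + ["b"] * 3)
        rows = summary_rows(g, labels)
        for grp in ("a", "b"):
            sub = g[labels == grp]
            for j in range(8):
                obs = [c for c in sub[:, j] if c >= 0]
                if not obs:
                    exp = -1
                elif 1 in obs or (0 in obs and 2 in obs):
                    exp = 1
                else:
                    exp = obs[0]
                assert rows.loc[grp].iloc[j] == exp
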