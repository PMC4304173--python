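"""Differential map: ratios, extreme flags, windows, hypergeometric calls,
single-gene map, chromosome medians, ranked lists."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from txmap import LocusAnnotation, MapParams, ValidationError
from txmap.mapping import (
    build_windows,
    call_segments,
    chromosome_medians,
    compute_differential,
    correct_q,
    flag_extremes,
    segment_pvalue,
    single_gene_map,
    top_genes,
)
from txmap.pooling import pool_frame


def _pool(means, pool_id="A", symbols=None):
    symbols = symbols or [f"G{i}" for i in range(len(means))]
    return pool_frame(
        pd.DataFrame({"symbol": symbols, "value": list(means)}), pool_id
    )


def _entries(ratios, chromosome="chr1", spacing=100_000, flags=None,
             value_b=100.0):
    """Entry frame with loci every `spacing` bp and given A/B ratios."""
    n = len(ratios)
    df = pd.DataFrame({
        "symbol": [f"G{i}" for i in range(n)],
        "value_A": [value_b * r for r in ratios],
        "value_B": [value_b] * n,
        "ratio": list(map(float, ratios)),
        "n_points_A": 10, "n_points_B": 10,
        "sd_percent_A": 0.0, "sd_percent_B": 0.0,
        "flag": flags if flags is not None else "none",
        "chromosome": chromosome,
        "start": [1 + i * spacing for i in range(n)],
        "end": [1 + i * spacing + 10_000 for i in range(n)],
        "cytoband": "",
    })
    return df


class TestComputeDifferential:
    def test_equal_means_ratio_one(self):
        entries = compute_differential(_pool([10, 20], "A"), _pool([10, 20], "B"))
        assert (entries["ratio"] == 1.0).all()

    def test_locus_in_one_pool_excluded(self):
        a = _pool([10, 20], "A", ["G0", "ONLY_A"])
        b = _pool([10, 30], "B", ["G0", "ONLY_B"])
        entries = compute_differential(a, b)
        assert list(entries["symbol"]) == ["G0"]

    def test_no_shared_loci_is_error(self):
        with pytest.raises(ValidationError, match="shared"):
            compute_differential(_pool([1], "A", ["X"]), _pool([1], "B", ["Y"]))

    def test_swapping_pools_inverts_ratios(self):
        a, b = _pool([12.5, 70, 3], "A"), _pool([5, 35, 9], "B")
        ab = compute_differential(a, b)["ratio"].to_numpy()
        ba = compute_differential(b, a)["ratio"].to_numpy()
        np.testing.assert_allclose(ab * ba, 1.0, rtol=1e-12)


class TestFlagExtremes:
    def test_distinct_ratios_exact_tail_counts(self):
        rng = np.random.default_rng(5)
        entries = _entries(rng.permutation(np.linspace(0.1, 10, 200)))
        out = flag_extremes(entries, tail=0.025)
        assert (out["flag"] == "over").sum() == 5
        assert (out["flag"] == "under").sum() == 5

    def test_zero_tail_flags_nothing(self):
        out = flag_extremes(_entries([1, 2, 3, 4]), tail=0.0)
        assert (out["flag"] == "none").all()

    def test_tie_heavy_distribution_against_quantile_oracle(self):
        entries = _entries([1.0, 1.0, 1.0, 10.0])
        out = flag_extremes(entries, tail=0.025)
        ratios = entries["ratio"].to_numpy()
        upper = np.quantile(ratios, 0.975)
        expected_over = set(entries.loc[ratios >= upper, "symbol"])
        assert set(out.loc[out["flag"] == "over", "symbol"]) == expected_over
        assert expected_over == {"G3"}  # the 10x entry

    def test_flags_swap_under_pool_exchange(self):
        rng = np.random.default_rng(6)
        ratios = rng.lognormal(0, 1, 400)
        fwd = flag_extremes(_entries(ratios), tail=0.025)
        rev = flag_extremes(_entries(1.0 / ratios), tail=0.025)
        swap = {"over": "under", "under": "over", "none": "none"}
        assert list(rev["flag"]) == [swap[f] for f in fwd["flag"]]


class TestBuildWindows:
    def test_default_grid_contains_printed_segment(self):
        ann = [LocusAnnotation("G", "chr21", 1, 60_000_000)]
        win = build_windows(ann)
        row = win[win["start"] == 50_250_001]
        assert len(row) == 1 and int(row["end"].iloc[0]) == 50_750_000

    def test_extent_one_megabase_gives_four_windows(self):
        ann = [LocusAnnotation("G", "chr1", 1, 1_000_000)]
        win = build_windows(ann)
        assert list(win["start"]) == [1, 250_001, 500_001, 750_001]

    def test_interior_locus_belongs_to_two_windows(self):
        entries = _entries([1.0])
        entries.loc[0, "start"] = 250_100
        seg = call_segments(
            entries,
            build_windows([LocusAnnotation("G0", "chr1", 250_100, 260_000)]),
            MapParams(),
        )
        assert sorted(seg["start"]) == [1, 250_001]

    def test_window_start_is_on_the_shift_lattice(self):
        ann = [LocusAnnotation("G", "chr2", 5, 3_456_789)]
        win = build_windows(ann)
        assert ((win["start"] - 1) % 250_000 == 0).all()


class TestSegmentPvalue:
    def test_hand_computed_example(self):
        # (C(3,2)C(7,2) + C(3,3)C(7,1)) / C(10,4) = 70/210
        assert segment_pvalue(10, 3, 4, 2) == pytest.approx(70 / 210, abs=1e-12)

    def test_k_zero_is_one(self):
        assert segment_pvalue(50, 5, 10, 0) == 1.0

    def test_inconsistent_k_is_error(self):
        with pytest.raises(ValidationError):
            segment_pvalue(10, 3, 4, 5)

    def test_matches_exhaustive_enumeration(self):
        for N, K, n in [(8, 3, 4), (10, 4, 5), (12, 6, 6)]:
            flagged = set(range(K))
            draws = list(itertools.combinations(range(N), n))
            for k in range(min(K, n) + 1):
                frac = sum(
                    1 for d in draws if len(flagged.intersection(d)) >= k
                ) / len(draws)
                assert segment_pvalue(N, K, n, k) == pytest.approx(frac, abs=1e-12)

    def test_strictly_decreasing_in_k(self):
        ps = [segment_pvalue(30, 8, 10, k) for k in range(9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestCorrectQ:
    def test_single_test_unchanged(self):
        np.testing.assert_allclose(correct_q([0.01]), [0.01])

    def test_bh_hand_example(self):
        np.testing.assert_allclose(
            correct_q([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_all_ones(self):
        np.testing.assert_allclose(correct_q([1.0, 1.0, 1.0]), [1.0] * 3)

    def test_bonferroni_option(self):
        np.testing.assert_allclose(
            correct_q([0.01, 0.5], method="bonferroni"), [0.02, 1.0]
        )

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, 100)
        assert (correct_q(p) >= p - 1e-15).all()


def _clustered_entries(n_null=400, k_flagged=6, ratio=10.0, rng_seed=8):
    """Null entries plus a co-located flagged cluster inside one window."""
    rng = np.random.default_rng(rng_seed)
    ratios = rng.lognormal(0, 0.3, n_null)
    entries = _entries(ratios, spacing=50_000)
    cluster = _entries([ratio] * k_flagged, spacing=60_000)
    cluster["symbol"] = [f"C{i}" for i in range(k_flagged)]
    cluster["start"] = 30_000_101 + 60_000 * np.arange(k_flagged)
    cluster["end"] = cluster["start"] + 10_000
    return pd.concat([entries, cluster], ignore_index=True)


def _windows_for(entries):
    ann = [
        LocusAnnotation(r.symbol, r.chromosome, int(r.start), int(r.end))
        for r in entries.itertuples()
    ]
    return build_windows(ann)


class TestCallSegments:
    def test_cluster_is_called_and_min_gene_rule_holds(self):
        entries = flag_extremes(_clustered_entries(), 0.025)
        seg = call_segments(entries, _windows_for(entries), MapParams())
        called = seg[seg["call"] != "none"]
        assert len(called) >= 1
        assert called["start"].between(29_750_001, 30_250_001).any()
        for _, s in called.iterrows():
            k = s["k_over"] if s["call"] == "over" else s["k_under"]
            assert k >= 3

    def test_two_flagged_genes_never_called(self):
        entries = flag_extremes(_clustered_entries(k_flagged=2, ratio=50), 0.025)
        seg = call_segments(entries, _windows_for(entries), MapParams())
        in_cluster = seg[seg["start"].between(29_750_001, 30_250_001)]
        assert (in_cluster["call"] == "none").all()
        assert (in_cluster["k_over"] <= 2).all()

    def test_overlapping_calls_are_deduplicated(self):
        entries = flag_extremes(_clustered_entries(), 0.025)
        seg = call_segments(entries, _windows_for(entries), MapParams())
        called = seg[seg["call"] != "none"]
        flagged_sets = [frozenset(
            s["flagged_over"] if s["call"] == "over" else s["flagged_under"]
        ) for _, s in called.iterrows()]
        for s1, s2 in itertools.combinations(flagged_sets, 2):
            assert len(s1 & s2) <= 0.5 * min(len(s1), len(s2))
        assert seg["dedup_dropped"].any()  # the 50%-overlap twin was dropped

    def test_empty_window_emits_no_test(self):
        entries = flag_extremes(_entries([1.0, 2.0, 0.5]), 0.025)
        ann = [LocusAnnotation("G", "chr1", 1, 5_000_000)]
        seg = call_segments(entries, build_windows(ann), MapParams())
        # loci sit at the chromosome head: only the first two windows hold them
        assert (seg["n"] >= 1).all()
        assert len(seg) <= 2


class TestSingleGeneMap:
    """Fine-window calls require co-located flagged loci: an isolated flagged
    locus gives p = K/N ~ 0.05 at best, which cannot survive correction
    across the full window family."""

    def _cluster(self, ratios_in_window, neighbor=None, n_null=300):
        rng = np.random.default_rng(10)
        null = rng.lognormal(0, 0.2, n_null)
        entries = _entries(np.concatenate([ratios_in_window, null]),
                           spacing=100_000)
        k = len(ratios_in_window)
        # pack the first k loci (plus optional unflagged neighbor) into 5 kb
        for i in range(k):
            entries.loc[i, "start"] = 100_001 + i * 1_000
            entries.loc[i, "end"] = entries.loc[i, "start"] + 400
        if neighbor is not None:
            j = k  # first null locus becomes the co-member
            entries.loc[j, "start"] = 100_001 + k * 1_000
            entries.loc[j, "end"] = entries.loc[j, "start"] + 400
            entries.loc[j, "value_A"] = neighbor
            entries.loc[j, "value_B"] = neighbor
        return flag_extremes(entries, 0.025)

    def test_isolated_flagged_locus_not_significant(self):
        rng = np.random.default_rng(11)
        ratios = np.concatenate([[20.0], rng.lognormal(0, 0.2, 200)])
        entries = flag_extremes(_entries(ratios), 0.025)
        calls = single_gene_map(entries, params=MapParams())
        assert calls.empty

    def test_prevailing_value_keeps_the_call(self):
        # three co-located flagged loci; the largest value prevails
        calls = single_gene_map(self._cluster([30.0, 20.0, 10.0]),
                                params=MapParams())
        maintained = set(calls.loc[calls["maintained"], "symbol"])
        dropped = set(calls.loc[~calls["maintained"], "symbol"])
        assert maintained == {"G0"}
        assert dropped == {"G1", "G2"}

    def test_dominated_values_drop_every_call(self):
        # an unflagged co-member with a larger pooled value dominates all
        calls = single_gene_map(self._cluster([30.0, 20.0, 10.0],
                                              neighbor=9_000.0),
                                params=MapParams())
        assert len(calls) == 3
        assert not calls["maintained"].any()


class TestChromosomeMedians:
    def test_single_locus(self):
        out = chromosome_medians(_entries([1.7], chromosome="chr21"))
        assert out.loc[0, "median_ratio"] == pytest.approx(1.7)
        assert out.loc[0, "n_loci"] == 1

    def test_hand_median(self):
        out = chromosome_medians(_entries([1, 2, 4]))
        assert out.loc[0, "median_ratio"] == pytest.approx(2.0)

    def test_order_invariant_and_matches_sort_oracle(self):
        rng = np.random.default_rng(9)
        ratios = rng.lognormal(0, 1, 101)
        e1 = _entries(ratios)
        e2 = e1.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m1, m2 = chromosome_medians(e1), chromosome_medians(e2)
        pd.testing.assert_frame_equal(m1, m2)
        assert m1.loc[0, "median_ratio"] == pytest.approx(
            np.sort(ratios)[50]  # odd count: middle order statistic
        )


class TestTopGenes:
    def test_data_point_filter_excludes(self):
        entries = _entries([100.0, 2.0])
        entries.loc[0, "n_points_A"] = 4  # below the 5-point minimum
        over, _ = top_genes(entries, min_data_points=5, count=5)
        assert "G0" not in set(over["symbol"])

    def test_ranking(self):
        entries = _entries([10.0, 2.0])
        over, under = top_genes(entries, min_data_points=5, count=1)
        assert list(over["symbol"]) == ["G0"]
        assert list(under["symbol"]) == ["G1"]

    def test_empty_eligible_set(self):
        entries = _entries([10.0, 2.0])
        entries[["n_points_A", "n_points_B"]] = 1
        over, under = top_genes(entries, min_data_points=5)
        assert over.empty and under.empty
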