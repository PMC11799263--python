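"""TFBS clustering, guide-site annotation and association analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import cluster_oracle
from crisprascreen.promoter_context import (
    TFBSRecord,
    annotate_guide_site,
    correlate_activation,
    detect_tfbs_clusters,
    read_tfbs_table,
    welch_split_test,
)


def _sites(intervals):
    return [TFBSRecord(f"tf{i}", s, e) for i, (s, e) in enumerate(intervals)]


# ---------------------------------------------------------------------------
# Cluster detection

def test_min_members_boundary():
    overlapping = [(10, 20)] * 9
    assert detect_tfbs_clusters(_sites(overlapping)) == []
    clusters = detect_tfbs_clusters(_sites(overlapping + [(12, 18)]))
    assert len(clusters) == 1 and clusters[0].members == 10


def test_chaining_across_small_gaps():
    # 10 sites of width 6 with 5-bp gaps chain into one spanning cluster
    intervals = [(11 * i, 11 * i + 6) for i in range(10)]
    (cluster,) = detect_tfbs_clusters(_sites(intervals))
    assert (cluster.start, cluster.end, cluster.members) == (0, 105, 10)


def test_blocks_separated_beyond_gap_stay_apart():
    block1 = [(0, 10)] * 10
    block2 = [(22, 32)] * 10  # 12-bp gap from block1's end
    clusters = detect_tfbs_clusters(_sites(block1 + block2))
    assert len(clusters) == 2


def test_order_invariance_and_oracle_agreement():
    rng = np.random.default_rng(31)
    for _ in range(100):
        n = int(rng.integers(0, 50))
        intervals = []
        for _ in range(n):
            s = int(rng.integers(0, 580))
            intervals.append((s, s + int(rng.integers(1, 20))))
        mine = [
            (c.start, c.end, c.members)
            for c in detect_tfbs_clusters(_sites(intervals), min_members=4)
        ]
        assert sorted(mine) == cluster_oracle(intervals, min_members=4)
        shuffled = list(intervals)
        rng.shuffle(shuffled)
        again = [
            (c.start, c.end, c.members)
            for c in detect_tfbs_clusters(_sites(shuffled), min_members=4)
        ]
        assert sorted(again) == sorted(mine)


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        TFBSRecord("tf", 10, 10)


# ---------------------------------------------------------------------------
# Annotation

def test_one_bp_overlap_counts():
    ann = annotate_guide_site("g", 100, 122, 600, _sites([(121, 127)]), [])
    assert ann.n_overlap == 1


def test_window_boundary_inclusive():
    ann = annotate_guide_site("g", 100, 122, 600, _sites([(172, 180)]), [])
    assert ann.n_overlap == 0
    assert ann.n_within_50 == 1  # edge distance exactly 50
    assert ann.n_within_100 == 1


def test_adjacent_interval_not_an_overlap():
    ann = annotate_guide_site("g", 100, 122, 600, _sites([(122, 130)]), [])
    assert ann.n_overlap == 0 and ann.n_within_50 == 1


@given(
    data=st.lists(
        st.tuples(st.integers(0, 580), st.integers(1, 20)), min_size=0, max_size=40
    ),
    start=st.integers(0, 578),
)
@settings(deadline=None, max_examples=100)
def test_window_counts_nested(data, start):
    sites = _sites([(s, s + w) for s, w in data])
    ann = annotate_guide_site("g", start, start + 22, 600, sites, [])
    assert ann.n_overlap <= ann.n_within_50 <= ann.n_within_100 <= len(sites)


def test_distances():
    clusters = detect_tfbs_clusters(_sites([(200, 210)] * 10))
    ann = annotate_guide_site("g", 100, 122, 600, [], clusters)
    assert ann.distance_to_tss == abs(111 - 600)
    assert ann.distance_to_nearest_cluster == 200 - 122
    overlapping = annotate_guide_site("g", 205, 227, 600, [], clusters)
    assert overlapping.distance_to_nearest_cluster == 0


def test_no_clusters_reports_missing_distance():
    ann = annotate_guide_site("g", 100, 122, 600, [], [])
    assert ann.distance_to_nearest_cluster is None


# ---------------------------------------------------------------------------
# TFBS table input

def test_read_tfbs_tsv_and_bed(tmp_path):
    tsv = tmp_path / "tfbs.tsv"
    tsv.write_text("factor\tstart\tend\tstrand\tscore\nSp1\t10\t20\t+\t0.9\n")
    bed = tmp_path / "tfbs.bed"
    bed.write_text("promoter\t10\t20\tSp1\t0.9\t+\n")
    (a,), (b,) = read_tfbs_table(tsv), read_tfbs_table(bed)
    assert (a.start, a.end, a.strand) == (b.start, b.end, b.strand) == (10, 20, "+")


def test_score_filter(tmp_path):
    tsv = tmp_path / "tfbs.tsv"
    tsv.write_text(
        "factor\tstart\tend\tstrand\tscore\nSp1\t10\t20\t+\t0.9\nKlf4\t30\t40\t-\t0.2\n"
    )
    assert len(read_tfbs_table(tsv, min_score=0.5)) == 1


# ---------------------------------------------------------------------------
# Association analyses

def test_perfect_correlation():
    values = {f"c{i}": float(i) for i in range(5)}
    res = correlate_activation(values, dict(values))
    assert res.r == pytest.approx(1.0)


def test_correlation_matches_direct_formula():
    pts = {"a": (0.0, 0.0), "b": (1.0, 1.0), "c": (2.0, 2.0), "d": (3.0, 4.0)}
    values = {k: v[0] for k, v in pts.items()}
    cov = {k: v[1] for k, v in pts.items()}
    x = np.array([v[0] for v in pts.values()])
    y = np.array([v[1] for v in pts.values()])
    r_direct = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
        np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
    )
    res = correlate_activation(values, cov)
    assert res.r == pytest.approx(r_direct, abs=1e-12)
    assert res.n == 4


def test_null_correlation_rarely_large():
    rng = np.random.default_rng(8)
    big = 0
    for _ in range(1000):
        x = rng.normal(0, 1, 30)
        y = rng.normal(0, 1, 30)
        values = {f"c{i}": x[i] for i in range(30)}
        cov = {f"c{i}": y[i] for i in range(30)}
        if abs(correlate_activation(values, cov).r) >= 0.5:
            big += 1
    assert big <= 10  # |r| < 0.5 in >= 99% of null runs


def test_zero_variance_flagged():
    values = {"a": 1.0, "b": 1.0, "c": 1.0}
    res = correlate_activation(values, {"a": 1.0, "b": 2.0, "c": 3.0})
    assert res.undefined and math.isnan(res.r)


def test_label_permutation_invariance():
    rng = np.random.default_rng(2)
    labels = [f"c{i}" for i in range(10)]
    x, y = rng.normal(size=10), rng.normal(size=10)
    res = correlate_activation(dict(zip(labels, x)), dict(zip(labels, y)))
    perm = rng.permutation(10)
    relabel = {labels[i]: labels[perm[i]] for i in range(10)}
    res2 = correlate_activation(
        {relabel[l]: v for l, v in zip(labels, x)},
        {relabel[l]: v for l, v in zip(labels, y)},
    )
    assert res2.r == pytest.approx(res.r, rel=1e-12)


def test_welch_identical_groups():
    values = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 1.0, "e": 2.0, "f": 3.0}
    grouping = {"a": "low", "b": "low", "c": "low", "d": "high", "e": "high", "f": "high"}
    t, df, p = welch_split_test(values, grouping)
    assert t == pytest.approx(0.0, abs=1e-12)


def test_welch_matches_hand_formula():
    a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 100.0]
    values = {f"a{i}": v for i, v in enumerate(a)} | {f"b{i}": v for i, v in enumerate(b)}
    grouping = {k: ("low" if k.startswith("a") else "high") for k in values}
    t, df, p = welch_split_test(values, grouping)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    t_hand = (np.mean(a) - np.mean(b)) / math.sqrt(va + vb)
    df_hand = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    # group order inside the test is alphabetical; compare magnitudes
    assert abs(t) == pytest.approx(abs(t_hand), rel=1e-10)
    assert df == pytest.approx(df_hand, rel=1e-10)
    assert df <= len(a) + len(b) - 2


def test_welch_needs_two_groups_of_two():
    with pytest.raises(ValueError):
        welch_split_test({"a": 1.0, "b": 2.0, "c": 3.0},
                         {"a": "low", "b": "high", "c": "high"})
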