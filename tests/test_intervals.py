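"""Interval algebra, BED I/O, CGI partitioning and overlap statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifmethylome import (FeatureSet, Interval, OverlapStats, feature_set, format_percent,
                            intersect, midpoint, overlap_statistics, partition_by_cgi,
                            read_bed, write_bed)
from motifmethylome.errors import BedParseError

from conftest import intersect_bruteforce


def random_set(rng, n, span=10_000, max_len=60, chroms=("chr1", "chr2")):
    ivs = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(Interval(str(rng.choice(chroms)), start, start + length,
                            str(rng.choice(["SP1", "E2F", ""])),
                            str(rng.choice(["+", "-", "."]))))
    return feature_set(ivs)


# ---------------------------------------------------------------------------
# BED I/O


def test_read_single_bed6_line(tmp_path):
    p = tmp_path / "one.bed"
    p.write_text("chr1\t10\t30\tSP1\t0\t+\n")
    fs = read_bed(p)
    assert list(fs) == [Interval("chr1", 10, 30, "SP1", "+")]


def test_read_empty_and_headered_bed(tmp_path):
    p = tmp_path / "empty.bed"
    p.write_text("")
    assert len(read_bed(p)) == 0
    p2 = tmp_path / "hdr.bed"
    p2.write_text('track name="x"\nbrowser position chr1\n# comment\nchr1\t0\t5\n')
    assert len(read_bed(p2)) == 1


@pytest.mark.parametrize("line,fragment", [
    ("chr1\t30\t10", "start >= end"),
    ("chr1\tten\t30", "non-integer"),
    ("chr1\t10", "fields"),
])
def test_malformed_bed_reports_line_number(tmp_path, line, fragment):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t5\n" + line + "\n")
    with pytest.raises(BedParseError) as exc:
        read_bed(p)
    assert exc.value.lineno == 2
    assert fragment in str(exc.value)


def test_bed_round_trip_is_identity(tmp_path):
    rng = np.random.default_rng(0)
    fs = random_set(rng, 1000)
    p = tmp_path / "rt.bed"
    write_bed(fs, p)
    back = read_bed(p)
    assert [(i.chrom, i.start, i.end, i.family, i.strand) for i in fs] == \
           [(i.chrom, i.start, i.end, i.family, i.strand) for i in back]


# ---------------------------------------------------------------------------
# intersect


def test_intersect_basic_and_half_open():
    a = feature_set([Interval("chr1", 0, 20)])
    b = feature_set([Interval("chr1", 10, 30)])
    assert [(i.start, i.end) for i in intersect(a, b)] == [(0, 20)]
    touching = feature_set([Interval("chr1", 20, 40)])
    assert len(intersect(a, touching)) == 0  # half-open: touching != overlapping


def test_intersect_min_overlap_threshold():
    a = feature_set([Interval("chr1", 0, 20)])
    b = feature_set([Interval("chr1", 15, 40)])
    assert len(intersect(a, b, min_overlap_bp=5)) == 1
    assert len(intersect(a, b, min_overlap_bp=6)) == 0


def test_intersect_counts_each_a_interval_once():
    a = feature_set([Interval("chr1", 0, 100, "SP1")])
    b = feature_set([Interval("chr1", 0, 10), Interval("chr1", 20, 30), Interval("chr1", 40, 50)])
    out = intersect(a, b)
    assert len(out) == 1 and out[0].family == "SP1"


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_intersect_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    a = random_set(rng, 500)
    b = random_set(rng, 500)
    got = sorted((i.chrom, i.start, i.end) for i in intersect(a, b))
    want = sorted((i.chrom, i.start, i.end) for i in intersect_bruteforce(a, b))
    assert got == want


def test_operations_invariant_to_input_order():
    rng = np.random.default_rng(5)
    ivs = list(random_set(rng, 200))
    b = random_set(rng, 200)
    shuffled = list(ivs)
    rng.shuffle(shuffled)
    assert intersect(feature_set(ivs), b).intervals == intersect(feature_set(shuffled), b).intervals


# ---------------------------------------------------------------------------
# midpoint / partition


@pytest.mark.parametrize("start,end,mid", [(10, 20, 15), (10, 21, 15), (0, 2, 1)])
def test_midpoint_floor_rule(start, end, mid):
    assert midpoint(Interval("chr1", start, end)) == mid


def test_partition_by_midpoint():
    cgis = feature_set([Interval("chr1", 0, 200)], role="cgi")
    fs = feature_set([Interval("chr1", 100, 120), Interval("chr1", 190, 250),
                      Interval("chr1", 500, 520)])
    inside, outside = partition_by_cgi(fs, cgis)
    assert [(i.start, i.end) for i in inside] == [(100, 120)]  # 190-250 midpoint=220 outside
    assert len(outside) == 2


def test_partition_with_empty_cgis_puts_all_outside():
    fs = feature_set([Interval("chr1", 0, 10), Interval("chr2", 5, 9)])
    inside, outside = partition_by_cgi(fs, feature_set([], role="cgi"))
    assert len(inside) == 0 and len(outside) == 2


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_partition_conserves_counts(seed):
    rng = np.random.default_rng(seed)
    fs = random_set(rng, 300)
    cgis = random_set(rng, 30).with_role("cgi")
    inside, outside = partition_by_cgi(fs, cgis)
    assert len(inside) + len(outside) == len(fs)
    assert sorted(inside.intervals + outside.intervals) == sorted(fs.intervals)


# ---------------------------------------------------------------------------
# overlap statistics


def test_worked_overlap_percentages_render_one_decimal():
    stats = OverlapStats.from_counts(n_overlap=40876, n_empirical=1187431, n_predicted=771221)
    assert format_percent(stats.pct_empirical_with_motif) == "3.4"
    assert format_percent(stats.pct_predicted_bound) == "5.3"


def test_zero_overlap_gives_zero_percent():
    stats = OverlapStats.from_counts(0, 100, 50)
    assert stats.pct_empirical_with_motif == 0.0
    assert stats.pct_predicted_bound == 0.0


def test_zero_denominator_is_undefined_not_zero():
    stats = OverlapStats.from_counts(0, 0, 0)
    assert stats.pct_empirical_with_motif is None
    assert format_percent(stats.pct_empirical_with_motif) == "NA"


def test_overlap_statistics_full(default_truth):
    truth = default_truth
    stats = overlap_statistics(truth.planted_predicted, truth.planted_empirical,
                               truth.planted_cgis)
    assert stats.n_overlap <= min(stats.n_predicted, stats.n_empirical)
    # bound sites are a small minority; in-CGI enrichment of the overlap set
    # far exceeds the predicted set's (the study's 7% vs 40% contrast)
    assert stats.pct_empirical_with_motif < 10
    assert stats.pct_empirical_overlap_in_cgi > 4 * (stats.pct_predicted_in_cgi or 0.0)
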