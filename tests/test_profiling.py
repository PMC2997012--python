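"""Aggregate profiles, bedGraph I/O, hyper/hypo/neutral classification."""

import numpy as np
import pytest

from motifmethylome import (ClassificationTable, Interval, MethylationTrack, aggregate_profile,
                            classify_families, classify_profile, feature_set,
                            planted_contrast_track, read_bedgraph, write_bedgraph)
from motifmethylome.errors import BedGraphFormatError, EmptyProfileError

# the 17-family empirical-TFBS screen labels used as a rendering fixture
# (synthetic transcription of a published two-tissue screen)
SEVENTEEN_FAMILY_LABELS = {
    "E2F": ("hypo", "hypo"), "NFY": ("hypo", "hypo"), "YY1": ("hypo", "hypo"),
    "MYCMAX": ("hypo", "hyper"), "NFKB": ("hypo", "hyper"), "AP": ("hypo", "hyper"),
    "NRSF": ("hypo", "neutral"), "SREBP": ("hypo", "neutral"), "SRF": ("hypo", "neutral"),
    "STAT": ("hypo", "neutral"), "TCF": ("hypo", "neutral"),
    "GATA": ("neutral", "hyper"), "NFE2": ("neutral", "neutral"),
    "OCT": ("neutral", "neutral"), "SOX": ("neutral", "neutral"),
    "EP300": ("neutral", "neutral"), "TP53": ("neutral", "neutral"),
}


def toy_track(values, window=50):
    return MethylationTrack({"chr1": np.asarray(values, dtype=float)}, window)


# ---------------------------------------------------------------------------
# bedGraph I/O


def test_bedgraph_single_record(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t50\t80.0\n")
    t = read_bedgraph(p)
    assert t.window_size == 50 and t.values["chr1"].tolist() == [80.0]


def test_bedgraph_rejects_out_of_range_value(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t50\t101\n")
    with pytest.raises(BedGraphFormatError):
        read_bedgraph(p)


def test_bedgraph_rejects_inconsistent_window(tmp_path):
    p = tmp_path / "t.bedgraph"
    p.write_text("chr1\t0\t50\t10\nchr1\t50\t120\t10\n")
    with pytest.raises(BedGraphFormatError) as exc:
        read_bedgraph(p)
    assert exc.value.lineno == 2


def test_bedgraph_round_trip_identity(tmp_path):
    rng = np.random.default_rng(0)
    t = MethylationTrack({"chr1": rng.uniform(0, 100, 6000),
                          "chr2": rng.uniform(0, 100, 4000)}, 50)
    p = tmp_path / "rt.bedgraph"
    write_bedgraph(t, p)
    back = read_bedgraph(p)
    assert back.window_size == 50
    for c in t.chroms:
        np.testing.assert_allclose(back.values[c], t.values[c], rtol=1e-5)
    p2 = tmp_path / "rt2.bedgraph"
    write_bedgraph(back, p2)
    assert p.read_bytes() == p2.read_bytes()


# ---------------------------------------------------------------------------
# aggregate profiles


def test_constant_track_gives_flat_profile_with_zero_ci_width():
    t = toy_track([80.0] * 400)
    anchors = feature_set([Interval("chr1", 4000, 4020), Interval("chr1", 12000, 12020)])
    prof = aggregate_profile(t, anchors, half_width=2000, bin_size=100, n_boot=200, seed=1)
    assert np.all(prof.bin_means == 80.0)
    assert np.all(prof.ci_low == 80.0) and np.all(prof.ci_high == 80.0)
    assert classify_profile(prof).value == "neutral"


def test_two_anchor_profile_is_hand_computable():
    # 6-window toy track, window 50, half_width 100, bin 100 -> offsets -50, +50
    t = toy_track([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
    anchors = feature_set([Interval("chr1", 95, 105), Interval("chr1", 195, 205)])
    # midpoints 100 and 200; positions (50,150) and (150,250) -> windows (1,3),(3,5)
    prof = aggregate_profile(t, anchors, half_width=100, bin_size=100, n_boot=100, seed=0)
    assert prof.bin_offsets.tolist() == [-50, 50]
    assert prof.bin_means.tolist() == [(20.0 + 40.0) / 2, (40.0 + 60.0) / 2]


def test_edge_anchors_dropped_and_counted():
    t = toy_track([50.0] * 100)  # chr1 length 5000
    anchors = feature_set([Interval("chr1", 0, 20), Interval("chr1", 2490, 2510),
                           Interval("chr1", 4990, 5000)])
    prof = aggregate_profile(t, anchors, half_width=2000, bin_size=100, n_boot=50, seed=0)
    assert prof.n_anchors == 1 and prof.n_dropped == 2


def test_all_anchors_outside_raises_empty_profile():
    t = toy_track([50.0] * 10)
    anchors = feature_set([Interval("chr1", 0, 20)])
    with pytest.raises(EmptyProfileError):
        aggregate_profile(t, anchors, half_width=2000, bin_size=100)


def test_strand_flipping_mirrors_profile():
    vals = np.full(400, 50.0)
    vals[90:100] = 90.0  # asymmetric bump at 4500-5000
    t = toy_track(vals)
    plus = feature_set([Interval("chr1", 3990, 4010, "", "+")])
    minus = feature_set([Interval("chr1", 3990, 4010, "", "-")])
    p = aggregate_profile(t, plus, 2000, 100, n_boot=10, seed=0, oriented=True)
    m = aggregate_profile(t, minus, 2000, 100, n_boot=10, seed=0, oriented=True)
    np.testing.assert_array_equal(p.bin_means, m.bin_means[::-1])


def test_ci_width_shrinks_like_root_n():
    rng = np.random.default_rng(11)
    t = toy_track(np.clip(rng.normal(70, 8, 200_000), 0, 100))
    def width(n, seed):
        anchors = feature_set([Interval("chr1", int(s), int(s) + 20)
                               for s in rng.integers(3000, 200_000 * 50 - 3000, n)])
        prof = aggregate_profile(t, anchors, 2000, 100, n_boot=400, seed=seed)
        return float(np.mean(prof.ci_high - prof.ci_low))
    w1, w4 = width(500, 1), width(2000, 2)
    assert 1.6 <= w1 / w4 <= 2.4


def test_planted_center_contrasts_classified_correctly():
    track, sites = planted_contrast_track(
        {"UP": 3.0, "DOWN": -3.0, "FLAT": 0.0}, 1000, seed=21)
    tbl = classify_families({"t": track}, sites, seed=21)
    assert tbl.label("UP", "t") == "hyper"
    assert tbl.label("DOWN", "t") == "hypo"
    assert tbl.label("FLAT", "t") == "neutral"


def test_predicted_sites_profile_hyper_on_default_genome(default_truth):
    # unbound conserved motifs sit in methylated background away from islands,
    # so their center exceeds the profile's own flank mean
    from motifmethylome import subtract
    track = default_truth.true_methylation
    unbound = subtract(default_truth.planted_predicted, default_truth.planted_empirical)
    prof = aggregate_profile(track, unbound, seed=31)
    lab = classify_profile(prof)
    assert lab.center_mean > lab.flank_mean
    assert lab.value == "hyper"


# ---------------------------------------------------------------------------
# classification tables


def test_identical_tracks_give_identical_labels():
    track, sites = planted_contrast_track({"X": 3.0}, 500, seed=5)
    tbl = classify_families({"a": track, "b": track}, sites, seed=5)
    assert tbl.label("X", "a") == tbl.label("X", "b") == "hyper"


def test_opposite_tissue_effects_recovered_in_cross_tab():
    track_a, sites = planted_contrast_track({"F1": 3.0, "F2": -3.0}, 800, seed=6)
    track_b, _ = planted_contrast_track({"F1": -3.0, "F2": 3.0}, 800, seed=7)
    tbl = classify_families({"heart": track_a, "sperm": track_b}, sites, seed=6)
    ct = tbl.cross_tab("heart", "sperm")
    assert ct.loc["hyper", "hypo"] == 1 and ct.loc["hypo", "hyper"] == 1


def test_family_with_no_usable_anchors_marked_unclassifiable():
    track = toy_track([50.0] * 40)  # 2 kb chromosome, too short for the window
    sites = {"GHOST": feature_set([Interval("chr1", 900, 920)])}
    tbl = classify_families({"t": track}, sites, seed=0)
    assert tbl.label("GHOST", "t") == "unclassifiable"


def test_seventeen_family_screen_tallies():
    tbl = ClassificationTable.from_labels(["heart", "sperm"], SEVENTEEN_FAMILY_LABELS)
    heart = tbl.tally("heart")
    assert (heart["hypo"], heart["neutral"], heart["hyper"]) == (11, 6, 0)
    ct = tbl.cross_tab("heart", "sperm")
    assert ct.loc["hypo", "hypo"] == 3
    assert ct.loc["hypo", "hyper"] == 3
    assert ct.loc["hypo", "neutral"] == 5
    assert int(ct.to_numpy().sum()) == 17
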