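"""Synthetic genome/track/feature-set generator: planted structure is real."""

import numpy as np
import pytest

from motifmethylome import (CgiCriteria, SyntheticConfig, generate_genome, intersect,
                            partition_by_cgi, place_feature_sets, random_intervals,
                            segment_stats, simulate_methylation_track, write_fasta)
from motifmethylome.cgi import ScoredSegment
from motifmethylome.errors import ConfigError, PlacementError


def test_invalid_config_names_offending_field():
    with pytest.raises(ConfigError) as exc:
        SyntheticConfig(cgi_methylation_mean=80.0, background_methylation_mean=75.0)
    assert exc.value.field == "cgi_methylation_mean"
    with pytest.raises(ConfigError) as exc:
        SyntheticConfig(overlap_fraction=1.5)
    assert exc.value.field == "overlap_fraction"
    with pytest.raises(ConfigError) as exc:
        SyntheticConfig(genome_length=10_000, n_cgis=100, cgi_length_mean=1000)
    assert exc.value.field == "genome_length"


def test_gc_zero_genome_has_no_islands():
    cfg = SyntheticConfig(genome_length=100_000, n_chromosomes=1, n_cgis=0,
                          background_gc=0.0, seed=4)
    truth = generate_genome(cfg)
    seq = truth.sequences["chr1"]
    assert "C" not in seq and "G" not in seq
    from motifmethylome import call_cpg_islands
    assert call_cpg_islands(seq) == []


def test_planted_islands_satisfy_criteria_when_measured(default_truth):
    crit = CgiCriteria()
    assert len(default_truth.planted_cgis) == default_truth.config.n_cgis
    for iv in default_truth.planted_cgis:
        st = segment_stats(default_truth.sequences[iv.chrom],
                           ScoredSegment(iv.chrom, iv.start, iv.end, 1))
        assert st.gc_content >= crit.min_gc
        assert iv.length > crit.min_length_exclusive
        assert st.obs_exp_cpg > crit.min_obs_exp_exclusive


def test_planted_intervals_within_chromosomes(default_truth):
    lengths = default_truth.chrom_lengths()
    for fs in (default_truth.planted_cgis, default_truth.planted_predicted,
               default_truth.planted_empirical):
        for iv in fs:
            assert 0 <= iv.start < iv.end <= lengths[iv.chrom]


def test_background_gc_close_to_configured(default_truth):
    seq = default_truth.sequences["chr1"]
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc = float(((arr == ord("C")) | (arr == ord("G"))).mean())
    assert abs(gc - default_truth.config.background_gc) < 0.02


def test_fixed_seed_gives_byte_identical_fasta(tmp_path):
    cfg = SyntheticConfig(genome_length=200_000, n_chromosomes=1, n_cgis=6, seed=9)
    for name in ("a.fa", "b.fa"):
        write_fasta(generate_genome(cfg).sequences, tmp_path / name)
    assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


# ---------------------------------------------------------------------------
# methylation track


def test_zero_noise_track_is_exactly_two_level():
    cfg = SyntheticConfig(genome_length=400_000, n_chromosomes=1, n_cgis=10, seed=2,
                          methylation_noise_sd=0.0, background_methylation_mean=80.0,
                          cgi_methylation_mean=20.0)
    truth = generate_genome(cfg)
    t = truth.true_methylation
    w = t.window_size
    covered = np.zeros(t.values["chr1"].size, dtype=bool)
    full = np.zeros_like(covered)
    for iv in truth.planted_cgis:
        covered[iv.start // w:(iv.end + w - 1) // w] = True
        full[(iv.start + w - 1) // w:iv.end // w] = True
    vals = t.values["chr1"]
    assert np.all(vals[~covered] == 80.0)
    assert np.all(vals[full] == 20.0)


def test_track_mean_converges_to_background_mean():
    cfg = SyntheticConfig(genome_length=1_000_000, n_chromosomes=1, n_cgis=0, seed=3,
                          methylation_noise_sd=5.0, background_methylation_mean=80.0)
    truth = generate_genome(cfg)
    vals = truth.true_methylation.values["chr1"]
    assert vals.size >= 10_000
    assert abs(vals.mean() - 80.0) < 0.2


def test_track_values_clipped_to_percent_range():
    cfg = SyntheticConfig(genome_length=200_000, n_chromosomes=1, n_cgis=4, seed=5,
                          methylation_noise_sd=40.0)
    truth = generate_genome(cfg)
    for v in truth.true_methylation.values.values():
        assert v.min() >= 0.0 and v.max() <= 100.0


def test_tissue_streams_differ_but_share_structure(default_truth):
    t0 = simulate_methylation_track(default_truth, tissue_index=0)
    t1 = simulate_methylation_track(default_truth, tissue_index=1)
    assert not np.array_equal(t0.values["chr1"], t1.values["chr1"])
    assert abs(t0.genome_mean - t1.genome_mean) < 0.5


# ---------------------------------------------------------------------------
# feature sets


def test_zero_overlap_fraction_means_disjoint_sets():
    cfg = SyntheticConfig(genome_length=500_000, n_chromosomes=1, n_cgis=10,
                          overlap_fraction=0.0, n_predicted_sites=500,
                          n_empirical_sites=500, seed=6)
    truth = generate_genome(cfg)
    assert len(intersect(truth.planted_predicted, truth.planted_empirical)) == 0


def test_full_cgi_bias_puts_every_empirical_site_inside_an_island():
    cfg = SyntheticConfig(genome_length=500_000, n_chromosomes=1, n_cgis=10,
                          empirical_cgi_bias=1.0, n_predicted_sites=200,
                          n_empirical_sites=200, seed=7)
    truth = generate_genome(cfg)
    trees = truth.planted_cgis.trees()
    for iv in truth.planted_empirical:
        hits = trees[iv.chrom].overlap(iv.start, iv.end)
        assert any(h.begin <= iv.start and iv.end <= h.end for h in hits)


def test_realized_overlap_fraction_within_binomial_bounds():
    cfg = SyntheticConfig(n_empirical_sites=10_000, seed=8)
    truth = generate_genome(cfg)
    ov = intersect(truth.planted_empirical, truth.planted_predicted)
    frac = len(ov) / len(truth.planted_empirical)
    # 99% binomial interval at n=10,000, p=0.034
    assert 0.030 <= frac <= 0.038


def test_realized_cgi_bias_within_binomial_bounds():
    cfg = SyntheticConfig(n_empirical_sites=10_000, seed=8)
    truth = generate_genome(cfg)
    inside, outside = partition_by_cgi(truth.planted_empirical, truth.planted_cgis)
    assert len(inside) + len(outside) == 10_000
    assert 0.37 <= len(inside) / 10_000 <= 0.43


def test_place_feature_sets_is_reproducible(default_truth):
    p1, e1 = place_feature_sets(default_truth)
    p2, e2 = place_feature_sets(default_truth)
    assert p1.intervals == p2.intervals and e1.intervals == e2.intervals


def test_overcommitted_placement_raises():
    cfg = SyntheticConfig(genome_length=200_000, n_chromosomes=1, n_cgis=0,
                          n_predicted_sites=10, n_empirical_sites=1000,
                          overlap_fraction=1.0, empirical_cgi_bias=0.0, seed=1)
    with pytest.raises(PlacementError):
        generate_genome(cfg)


# ---------------------------------------------------------------------------
# random intervals


def test_random_intervals_empty_and_deterministic(default_truth):
    assert len(random_intervals(default_truth, 0, 20, seed=1)) == 0
    a = random_intervals(default_truth, 500, 20, seed=2)
    b = random_intervals(default_truth, 500, 20, seed=2)
    assert a.intervals == b.intervals
    assert any(a.intervals != random_intervals(default_truth, 500, 20, seed=3).intervals
               for _ in [0])


def test_random_intervals_length_error():
    with pytest.raises(PlacementError):
        random_intervals({"chr1": 100}, 5, 200, seed=0)
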