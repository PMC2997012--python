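# motif-methylome

Genome-wide, most conserved consensus transcription-factor motifs
("predicted TFBS") are *not* occupied by their factor in vivo. One proposed
explanation is that DNA methylation silences promiscuous binding: conserved
motifs should then sit in hyper-methylated sequence, while sites with
biologically proven binding (ChIP-seq "empirical TFBS") should be
hypo-methylated — largely because bound sites concentrate in un-methylated
CpG islands. This package implements that analysis as a tested, reusable
pipeline for anyone working with windowed percent-methylation tracks
(e.g. MeDIP-seq scores deconvolved to %-methylation per 50 bp window):

* **CpG-island calling** by maximal scoring segments: every dinucleotide
  scores +17 (`CG`) or −1 (anything else); all maximal scoring segments
  (Ruzzo–Tompa sense) are kept as islands when GC ≥ 50 %, length > 200 bp,
  and the observed/expected CpG ratio exceeds 0.6, with
  O/E = n_CG · L / (n_C · n_G) over the segment.
* **Feature-set construction**: predicted motifs (set 1), random locations
  (set 2, negative control), the predicted subset for families with
  empirical data (set 3), the predicted∩empirical overlap (set 4), and
  CGI / non-CGI partitions of sets 3–4, plus the overlap percentages
  (100·n_overlap/n_empirical, 100·n_overlap/n_predicted) rendered at one
  decimal.
* **Aggregate methylation profiles**: mean track value at 100 bp bin
  offsets over ±2 kb around anchor midpoints, with a percentile-bootstrap
  confidence band over anchors (1,000 replicates).
* **Hyper/hypo/neutral classification**: a profile is *hyper*-methylated
  when the bootstrap CI of (center mean − flank mean) lies wholly above 0
  (center ±250 bp, flanks the outer 25 % of bins per side), *hypo* when
  wholly below, *neutral* otherwise; applied per TF family and tissue to
  give screen tables and cross-tabulations.
* **A synthetic methylome generator** that plants all of the above
  structure (islands, tracks, motif/bound sites with configured overlap and
  CGI bias) so the whole pipeline is testable without any downloads.

## Worked example

The numbered drivers under `analysis/` run the study end to end on the
default synthetic methylome (2 Mb genome, 60 planted islands, 75 %
background / 20 % island methylation, noise sd 8):

```bash
python analysis/01_simulate_methylome.py --seed 1
python analysis/02_call_cpg_islands.py
python analysis/03_build_tfbs_sets.py --seed 1
python analysis/04_profile_sets.py --seed 1
python analysis/05_classify_families.py --seed 1
```

which prints (abridged):

```
called 60 islands; planted 60
planted-island recovery Jaccard: mean 0.956, min 0.901
% empirical with conserved motif: 2.6
% predicted biologically bound:   3.6
% predicted in CGI:               1.3
% overlap set in CGI:             36.5
set1_predicted_all:heart            hyper    delta=  +1.21 n=1991
set2_random:heart                   neutral  delta=  +0.03 n=20886
set4_overlap:heart                  hypo     delta= -15.14 n=52
set3_cgi:heart                      hypo     delta= -44.81 n=19
set3_noncgi:heart                   hyper    delta=  +1.65 n=1409
set4_noncgi:heart                   neutral  delta=  +1.95 n=33
```

Reading it: every planted island is recovered almost exactly; only a few
percent of "bound" sites carry a motif while the bound∩motif overlap set is
strongly enriched in CpG islands (36.5 % vs 1.3 %); predicted motifs
profile *hyper*-methylated relative to their own flanks, random locations
are flat, the bound overlap set is *hypo*-methylated, and the CGI/non-CGI
partitions show the hypo signal comes from islands — the study's headline
contrast, recovered from planted truth. `delta` is the center-minus-flank
contrast in percentage points and `n` the number of usable anchors.

The same run is available as a single command (plus per-family tables,
report JSON and a text summary):

```bash
motif-methylome run --seed 1 --outdir results/run
```

`motif-methylome simulate|call-cgi|build-sets|profile|classify|report`
expose the individual stages for user-supplied FASTA/BED/bedGraph inputs.

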