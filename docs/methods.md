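# Methods

## The analysis in one paragraph

Given a genome sequence, a windowed percent-methylation track per tissue,
and two interval sets — predicted TF motifs and empirically bound sites —
the pipeline (i) annotates CpG islands from sequence alone, (ii) builds the
four analysis sets (all motifs; random locations; motifs of families with
empirical data; their intersection with bound sites) and the CGI/non-CGI
partitions, (iii) averages the track around each set's anchor midpoints to
an aggregate profile with a bootstrap confidence band, and (iv) labels each
profile hyper-, hypo-methylated or neutral from the CI of the
center-versus-flank contrast. A synthetic methylome generator supplies
inputs with known planted structure so every stage is testable end to end.

## CpG-island calling

Each dinucleotide scores +17 if it is exactly `CG` and −1 otherwise
(case-insensitive; any pair containing `N` scores −1). Islands are the
maximal scoring segments of this score sequence that pass all of:
GC ≥ 0.50, length strictly > 200 bp, observed/expected CpG strictly > 0.6,
where O/E = n_CG · L / (n_C · n_G) and is defined as 0 when n_C · n_G = 0.
`N` bases count toward length but not toward the C/G tallies; CpGs are
counted only when fully inside a segment.

"Maximal scoring segment" is formalized in the Ruzzo–Tompa sense (disjoint
positive-score runs, none extendable into or contained in a better-scoring
overlapping run), because that is the standard reading of the phrase, it
admits a linear-time algorithm, and it has an easy exhaustive oracle. Two
deliberate conventions:

* **Tie-breaking is leftmost-longest.** A zero-gain extension (e.g.
  `CG` + seventeen non-CG dinucleotides + `CG`) is merged into one segment
  rather than split. Segments always begin and end on a `CG`, so a segment
  over dinucleotide indices [i, j] is reported as bases [i, j+2) — the
  island includes the final base of its last CpG.
* **No post-processing.** Rejected segments are dropped, not re-evaluated
  on sub-segments, and adjacent accepted islands are not merged. Production
  genome-browser annotators add further undocumented steps; this caller is
  the documented core only.

The production path run-length-compresses inter-CpG gaps into single
weighted items; this is output-identical to scoring every dinucleotide
(segments cannot begin or end inside a gap) and makes whole-genome calling
linear in practice. Equivalence with the exhaustive O(n³) enumerator is
asserted over hundreds of random score vectors in the test suite.

## Intervals and overlap statistics

Coordinates are 0-based half-open (BED native) everywhere; touching
intervals do not overlap. Intersection keeps each qualifying interval of
the first set exactly once (≥ 1 bp overlap by default, configurable),
matching common table-browser behaviour. Duplicate intervals are retained —
motif tracks legitimately contain overlapping entries for different
matrices. CGI membership of a site is decided by its midpoint (consistent
with midpoint-centred profiling); whole-interval containment is available
behind a flag. The overlap count defaults to counting motif locations
rather than peaks; both countings are exposed because a peak can contain
several motifs. Percentages are stored at full precision and rendered at
one decimal; a zero denominator renders `NA`, never `0.0`.

## Aggregate profiles

For each anchor midpoint m the profile samples the track at bin-center
offsets o ∈ {−hw + b/2, …, hw − b/2} (defaults hw = 2,000 bp, b = 100 bp,
hence 40 bins), taking the value of the window containing m + o — no
interpolation, since the scores are window-level summaries. Anchors whose
±hw span leaves the chromosome are dropped and counted. The band is a
percentile bootstrap over anchors (default 1,000 replicates, 95 %),
implemented with multinomial weights so memory stays flat at tens of
thousands of anchors. Profile extent and band method are not externally
prescribed; these defaults match the smoothing scale of fragment-based
methylation assays and are fully configurable. Strand-aware mirroring
exists but is off by default (the plots this reproduces are
midpoint-centred without flipping).

## Classification

center_mean averages bins within ±250 bp; flank_mean averages the outer
25 % of bins per side; delta = center_mean − flank_mean. The label is
*hyper* if the bootstrap CI of the contrast (computed over the same
replicates as the band) lies wholly above 0, *hypo* if wholly below,
*neutral* otherwise. The contrast CI uses a 99 % level by design: the
classifier is run as a screen over ~10²  families × tissues, and a 1 %
per-test false hyper/hypo rate keeps screen tables stable while costing no
power against the planted ±3-point effects (|z| ≳ 6 at 2,000 anchors). A
family with zero usable anchors is labelled `unclassifiable`, never
silently dropped.

## The synthetic methylome

The generator's defaults are the study conditions used throughout the
tests: 2 Mb over 2 chromosomes; background GC 0.40 with CpG obs/exp ≈ 0.25
(mammalian-like depletion, which also keeps spurious islands out of the
background); 60 planted islands with gamma-distributed lengths around
1,000 bp, GC 0.60 and obs/exp 0.75; track window 50 bp; methylation 75 %
background / 20 % islands with Gaussian noise sd 8, partially covered
windows interpolating the two means by covered fraction, all clipped to
[0, 100]; 2,000 predicted and 2,000 empirical 20 bp sites; 3.4 % of
empirical sites carry a co-located motif and 40 % lie inside islands;
random control sets use 20,982 locations.

Sequence synthesis draws bases i.i.d. at a compensated GC and then thins
`CG` dinucleotides to the target obs/exp by replacing the G of a removed
CpG with A or T. Island sequences are reject-and-resampled until, measured
directly on the emitted bases, they satisfy all three caller criteria *and*
form a single maximal segment covering ≥ 90 % of the island — so planted
islands are recoverable by construction (independent-base sampling alone
cannot guarantee either the target obs/exp or single-segment structure).

Placement encodes the study's assumed biology. Per empirical site, two
independent Bernoulli draws decide motif carriage (overlap fraction) and
island membership (CGI bias); motif carriers get an identical predicted
partner interval. The remaining predicted-only motifs are placed in
background at least 500 bp clear of any island: an unbound conserved motif
sits in fully methylated local context, while its distant flanks
occasionally cross hypo-methylated islands, which is what makes the
predicted set's aggregate profile rise at the center (~ +1.3 points at
default geometry) without any per-motif methylation offset in the track —
the track itself stays exactly two-level plus noise. Motif-free empirical
sites are rejection-sampled away from every predicted interval so the
realized overlap equals the designated draws. Family names are assigned
round-robin: seventeen families mirror the publicly ChIP-profiled set,
plus seven motif-only families.

Randomness is split into fixed per-artifact streams (genome, islands,
sites, per-tissue tracks, random sets) derived from the master seed, so
regenerating one artifact never perturbs another and all outputs are
byte-identical per seed.

A separate harness, `planted_contrast_track`, plants explicit ±δ-point
center elevations (default extent ±300 bp) at grid-spaced anchors on an
otherwise flat noisy track; it is the calibrated instrument for measuring
label-recovery accuracy at known effect sizes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no fragment pulldown, read sampling or
deconvolution (the track is emitted directly at the percent-methylation
level, so assay-specific biases such as CpG-density-dependent sensitivity
are absent); no repeats or masking; no chromatin-driven correlation between
binding and methylation beyond the configured island bias; window noise is
i.i.d. Gaussian rather than autocorrelated; empirical "peaks" have motif
width. Recovery rates measured here are therefore statements about the
pipeline's statistics, not about any particular assay.

## Pipeline and reporting

The orchestrated run is staged (data → islands → sets → profiles →
classification → report) with per-stage counts logged, outputs written
atomically (temp file + rename; completed outputs are never overwritten by
partial ones), and stage artifacts cached on disk for resume. Tracks are
always consumed in their on-disk `%.6g` representation so cached and fresh
runs produce bit-identical downstream numbers. The report bundle always
contains the eight profile analogues (sets 1–4 plus the CGI partitions of
sets 3 and 4, and additionally the unbound-motif set) per tissue, the
overlap statistics, per-family labels with a tissue cross-tabulation, and a
provenance block echoing the full configuration and seed.

## Problem sizes and determinism

The shipped study conditions run in minutes on one core: whole-genome
island calling on 2 Mb takes ~1.5 s; a 20,982-anchor profile with a
1,000-replicate band ~0.5 s; the replicate sweeps used for recovery rates
(100 seeds in the test suite, 25 in the acceptance script) a few minutes
total. All stochastic tests use fixed seed lists and are therefore exactly
reproducible.

## Known limitations

Per-family labels at desk scale rest on ~80–120 anchors per family, so
genuinely small contrasts label neutral — the per-family screen is
power-limited even though set-level contrasts are unambiguous. The island
caller reproduces the documented scoring/criteria core only, not any
specific historical genome-browser track. Bound sites inherit motif-length
intervals rather than realistic peak widths, and tissue tracks differ only
in noise realization, not in planted biology, so cross-tissue differences
in the synthetic screen are pure noise.
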