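#!/usr/bin/env python
"""Build the four TFBS analysis sets and their overlap/CGI statistics.

Set 1: all predicted motif locations. Set 2: random genomic locations
(negative control). Set 3: predicted motifs of the families with empirical
ChIP-seq-like data. Set 4: set-3 motifs that are also empirically bound.
Sets 3 and 4 are additionally partitioned by called-CGI membership.

Writes BEDs and overlap_stats.json under results/analysis/sets/.
"""

import argparse
import json
from pathlib import Path

from motifmethylome import (EMPIRICAL_FAMILIES, intersect, overlap_statistics,
                            partition_by_cgi, random_intervals, read_bed, subtract, write_bed)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-random", type=int, default=20982)
    args = ap.parse_args()
    setdir = args.outdir / "sets"
    setdir.mkdir(parents=True, exist_ok=True)

    predicted = read_bed(args.datadir / "predicted.bed", role="predicted")
    empirical = read_bed(args.datadir / "empirical.bed", role="empirical")
    cgis = read_bed(args.outdir / "islands.bed", role="cgi")
    truth = json.loads((args.datadir / "truth.json").read_text())
    lengths = truth["chrom_lengths"]

    set1 = predicted
    set2 = random_intervals(lengths, args.n_random, 20, seed=args.seed)
    set3 = set1.subset_by_family(EMPIRICAL_FAMILIES)
    set4 = intersect(set3, empirical)
    unbound = subtract(set1, empirical)
    for name, fs in [("set1_predicted_all", set1), ("set2_random", set2),
                     ("set3_predicted_subset", set3), ("set4_overlap", set4),
                     ("predicted_unbound", unbound)]:
        write_bed(fs, setdir / f"{name}.bed")
    for base, fs in [("set3", set3), ("set4", set4)]:
        inside, outside = partition_by_cgi(fs, cgis)
        write_bed(inside, setdir / f"{base}_cgi.bed")
        write_bed(outside, setdir / f"{base}_noncgi.bed")

    stats = overlap_statistics(set3, empirical, cgis)
    (setdir / "overlap_stats.json").write_text(json.dumps(stats.to_dict(), indent=1))
    print("\n".join(stats.render_lines()))


if __name__ == "__main__":
    main()
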