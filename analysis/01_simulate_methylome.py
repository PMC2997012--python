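#!/usr/bin/env python
"""Generate the default synthetic methylome: a 2 Mb two-chromosome genome
with 60 planted CpG islands, two tissue-like percent-methylation tracks
(75% background, 20% islands, noise sd 8), 2,000 predicted-motif sites and
2,000 empirical binding sites (3.4% motif-carrying, 40% inside islands).

Writes FASTA/BED/bedGraph plus a JSON truth file under results/data/.
"""

import argparse
from pathlib import Path

from motifmethylome import (SyntheticConfig, generate_genome, simulate_methylation_track,
                            write_bed, write_fasta)
from motifmethylome.profiling import write_bedgraph
from motifmethylome.synthetic import write_truth_json


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    truth = generate_genome(cfg)
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.sequences, out / "genome.fa")
    write_truth_json(truth, out / "truth.json")
    write_bed(truth.planted_cgis, out / "cgi_truth.bed")
    write_bed(truth.planted_predicted, out / "predicted.bed")
    write_bed(truth.planted_empirical, out / "empirical.bed")
    for ti, tissue in enumerate(("heart", "sperm")):
        write_bedgraph(simulate_methylation_track(truth, cfg, tissue_index=ti),
                       out / f"track_{tissue}.bedgraph")

    print(f"genome: {sum(truth.chrom_lengths().values()):,} bp over "
          f"{len(truth.sequences)} chromosomes (seed={args.seed})")
    print(f"planted: {len(truth.planted_cgis)} CpG islands, "
          f"{len(truth.planted_predicted)} predicted sites, "
          f"{len(truth.planted_empirical)} empirical sites")
    print(f"wrote {out}/")


if __name__ == "__main__":
    main()
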