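"""End-to-end orchestration: simulate or ingest, call islands, build the four
feature sets, profile each set per tissue, classify families, report.

Stage outputs are cached on disk under the run directory; a re-run with
``resume=True`` loads completed stages instead of recomputing them, and a
fixed master seed makes every artifact byte-identical across runs. Partial
writes go to a temporary file first and never overwrite completed outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import cgi as cgi_mod
from .cgi import CgiCriteria, CgiScoringParams, CgiSegment, ScoredSegment
from .errors import ConfigError, DataError
from .intervals import (FeatureSet, Interval, OverlapStats, format_percent, intersect,
                        overlap_statistics, partition_by_cgi, read_bed, subtract, write_bed)
from .profiling import (AggregateProfile, ClassificationTable, MethylationTrack, ProfileLabel,
                        aggregate_profile, classify_families, classify_profile, read_bedgraph,
                        write_bedgraph)
from .synthetic import (GenomeTruth, SyntheticConfig, generate_genome, random_intervals,
                        simulate_methylation_track, write_fasta, write_truth_json)

log = logging.getLogger("motifmethylome")

SET_NAMES = ("set1_predicted_all", "set2_random", "set3_predicted_subset",
             "set4_overlap", "set3_cgi", "set3_noncgi", "set4_cgi", "set4_noncgi",
             "predicted_unbound")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic or user-data mode)."""

    mode: str = "synthetic"
    synthetic: Optional[SyntheticConfig] = None
    # user-data mode paths
    fasta: Optional[str] = None
    tracks: dict[str, str] = field(default_factory=dict)   # tissue -> bedGraph
    predicted_bed: Optional[str] = None
    empirical_bed: Optional[str] = None
    cgi_bed: Optional[str] = None
    # analysis parameters
    half_width: int = 2000
    bin_size: int = 100
    n_boot: int = 1000
    ci_level: float = 0.95
    center_halfwidth: int = 250
    flank_fraction: float = 0.25
    alpha: float = 0.01
    min_overlap_bp: int = 1
    n_random: int = 20982
    tissues: tuple[str, ...] = ("heart", "sperm")
    seed: int = 0
    outdir: str = "results/run"

    def __post_init__(self):
        if self.mode not in ("synthetic", "user-data"):
            raise ConfigError("mode must be 'synthetic' or 'user-data'", field="mode")
        if self.mode == "synthetic":
            if self.fasta or self.predicted_bed or self.empirical_bed or self.tracks:
                raise ConfigError("synthetic mode must not set user-data paths", field="mode")
            if self.synthetic is None:
                self.synthetic = SyntheticConfig(seed=self.seed)
        else:
            if self.synthetic is not None:
                raise ConfigError("user-data mode must not set a synthetic config", field="mode")
            missing = [n for n in ("fasta", "predicted_bed", "empirical_bed")
                       if getattr(self, n) is None]
            if missing or not self.tracks:
                raise ConfigError(f"user-data mode requires fasta/predicted_bed/empirical_bed "
                                  f"and at least one track (missing: {missing})", field="mode")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        if "tissues" in raw:
            raw["tissues"] = tuple(raw["tissues"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        d["tissues"] = list(self.tissues)
        return d


@dataclass
class ReportBundle:
    """Everything one run computes, ready for rendering."""

    overlap_stats: Optional[OverlapStats]
    set_sizes: dict[str, int]
    profiles: dict[str, AggregateProfile]          # "<set>:<tissue>"
    labels: dict[str, ProfileLabel]                # "<set>:<tissue>"
    classification: Optional[ClassificationTable]
    provenance: dict

    def to_json_dict(self) -> dict:
        def prof(p: AggregateProfile):
            return {"bin_offsets": p.bin_offsets.tolist(), "bin_means": p.bin_means.tolist(),
                    "ci_low": p.ci_low.tolist(), "ci_high": p.ci_high.tolist(),
                    "n_anchors": p.n_anchors, "n_dropped": p.n_dropped,
                    "n_boot": p.n_boot, "ci_level": p.ci_level}

        def label(l: ProfileLabel):
            return {"value": l.value, "center_mean": l.center_mean, "flank_mean": l.flank_mean,
                    "delta": l.delta, "ci_low": l.ci_low, "ci_high": l.ci_high}

        cls = None
        if self.classification is not None:
            cls = {"tissues": self.classification.tissues,
                   "rows": {fam: {t: label(lab) for t, lab in labs.items()}
                            for fam, labs in self.classification.rows.items()}}
        return {
            "overlap_stats": self.overlap_stats.to_dict() if self.overlap_stats else None,
            "set_sizes": self.set_sizes,
            "profiles": {k: prof(p) for k, p in self.profiles.items()},
            "labels": {k: label(l) for k, l in self.labels.items()},
            "classification": cls,
            "provenance": self.provenance,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ReportBundle":
        def prof(p):
            return AggregateProfile(bin_offsets=np.array(p["bin_offsets"]),
                                    bin_means=np.array(p["bin_means"]),
                                    ci_low=np.array(p["ci_low"]), ci_high=np.array(p["ci_high"]),
                                    n_anchors=p["n_anchors"], n_dropped=p["n_dropped"],
                                    n_boot=p["n_boot"], ci_level=p["ci_level"])

        def label(l):
            return ProfileLabel(l["value"], l["center_mean"], l["flank_mean"], l["delta"],
                                l["ci_low"], l["ci_high"])

        ov = d.get("overlap_stats")
        classification = None
        if d.get("classification"):
            c = d["classification"]
            classification = ClassificationTable(
                tissues=list(c["tissues"]),
                rows={fam: {t: label(lab) for t, lab in labs.items()}
                      for fam, labs in c["rows"].items()})
        return cls(
            overlap_stats=OverlapStats(**ov) if ov else None,
            set_sizes=dict(d["set_sizes"]),
            profiles={k: prof(p) for k, p in d["profiles"].items()},
            labels={k: label(l) for k, l in d["labels"].items()},
            classification=classification,
            provenance=dict(d["provenance"]),
        )


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_name(path.name + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    have = {getattr(h, "_mm_tag", None) for h in log.handlers}
    if "stderr" not in have:
        h = logging.StreamHandler(sys.stderr)
        h._mm_tag = "stderr"
        h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(h)
    logfile = outdir / "run.log"
    for h in list(log.handlers):
        if getattr(h, "_mm_tag", None) == "file":
            log.removeHandler(h)
            h.close()
    fh = logging.FileHandler(logfile)
    fh._mm_tag = "file"
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)


def _islands_to_featureset(islands: list[CgiSegment]) -> FeatureSet:
    return FeatureSet("cgi", tuple(Interval(i.chrom, i.start, i.end) for i in islands),
                      "called CpG islands")


def _load_islands_tsv(path: Path) -> FeatureSet:
    ivs = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            f = line.split("\t")
            ivs.append(Interval(f[0], int(f[1]), int(f[2])))
    return FeatureSet("cgi", tuple(ivs), "called CpG islands")


def run_pipeline(config: RunConfig, resume: bool = True) -> ReportBundle:
    """Execute all stages; deterministic per seed, stage outputs cached on disk."""
    outdir = Path(config.outdir)
    datadir = outdir / "data"
    datadir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    log.info("run start: mode=%s seed=%d outdir=%s", config.mode, config.seed, outdir)

    # ---- stage 1: data -----------------------------------------------------
    truth: Optional[GenomeTruth] = None
    if config.mode == "synthetic":
        fasta = datadir / "genome.fa"
        truth = generate_genome(config.synthetic)
        if not (resume and fasta.exists()):
            _atomic_write(fasta, lambda p: write_fasta(truth.sequences, p))
            _atomic_write(datadir / "truth.json", lambda p: write_truth_json(truth, p))
            _atomic_write(datadir / "predicted.bed",
                          lambda p: write_bed(truth.planted_predicted, p))
            _atomic_write(datadir / "empirical.bed",
                          lambda p: write_bed(truth.planted_empirical, p))
        sequences = truth.sequences
        predicted = truth.planted_predicted
        empirical = truth.planted_empirical
        tracks: dict[str, MethylationTrack] = {}
        for ti, tissue in enumerate(config.tissues):
            bg = datadir / f"track_{tissue}.bedgraph"
            if not (resume and bg.exists()):
                fresh = simulate_methylation_track(truth, config.synthetic, tissue_index=ti)
                _atomic_write(bg, lambda p: write_bedgraph(fresh, p))
            # always consume the on-disk representation so cached and fresh
            # runs produce bit-identical downstream outputs
            tracks[tissue] = read_bedgraph(bg)
        chrom_lengths = truth.chrom_lengths()
    else:
        from pyfaidx import Fasta
        fa = Fasta(str(config.fasta))
        sequences = {name: str(fa[name][:]) for name in fa.keys()}
        predicted = read_bed(config.predicted_bed, role="predicted")
        empirical = read_bed(config.empirical_bed, role="empirical")
        tracks = {t: read_bedgraph(p) for t, p in config.tracks.items()}
        chrom_lengths = {c: len(s) for c, s in sequences.items()}
    log.info("data: %d chroms, %d predicted, %d empirical, %d tissue tracks",
             len(sequences), len(predicted), len(empirical), len(tracks))

    # ---- stage 2: CpG islands ---------------------------------------------
    islands_tsv = outdir / "islands.tsv"
    if config.mode == "user-data" and config.cgi_bed:
        called_cgis = read_bed(config.cgi_bed, role="cgi")
    elif resume and islands_tsv.exists():
        called_cgis = _load_islands_tsv(islands_tsv)
    else:
        islands = cgi_mod.call_cpg_islands_genome(sequences)
        _atomic_write(outdir / "islands.bed", lambda p: cgi_mod.islands_to_bed(islands, p))
        _atomic_write(islands_tsv, lambda p: cgi_mod.islands_to_tsv(islands, p))
        called_cgis = _islands_to_featureset(islands)
    log.info("cgi: %d islands", len(called_cgis))

    # ---- stage 3: feature sets ---------------------------------------------
    emp_families = (set(config.synthetic.empirical_families) if config.mode == "synthetic"
                    else set(empirical.families()))
    set1 = predicted.with_role("predicted", "set1: all predicted motifs")
    set2 = random_intervals(chrom_lengths, config.n_random,
                            length=(config.synthetic.site_length if config.synthetic else 20),
                            seed=config.seed)
    set3 = (set1.subset_by_family(emp_families) if emp_families
            else set1).with_role("predicted", "set3: predicted motifs, profiled families")
    set4 = intersect(set3, empirical, config.min_overlap_bp)
    set3_cgi, set3_noncgi = partition_by_cgi(set3, called_cgis)
    set4_cgi, set4_noncgi = partition_by_cgi(set4, called_cgis)
    unbound = subtract(set1, empirical, config.min_overlap_bp)
    sets: dict[str, FeatureSet] = {
        "set1_predicted_all": set1, "set2_random": set2,
        "set3_predicted_subset": set3, "set4_overlap": set4,
        "set3_cgi": set3_cgi, "set3_noncgi": set3_noncgi,
        "set4_cgi": set4_cgi, "set4_noncgi": set4_noncgi,
        "predicted_unbound": unbound,
    }
    setdir = outdir / "sets"
    setdir.mkdir(exist_ok=True)
    for name, fs in sets.items():
        _atomic_write(setdir / f"{name}.bed", lambda p, f=fs: write_bed(f, p))
    stats = overlap_statistics(set3, empirical, called_cgis, config.min_overlap_bp)
    log.info("sets: %s; overlap %s/%s empirical (%s%%)",
             {k: len(v) for k, v in sets.items()}, stats.n_overlap, stats.n_empirical,
             format_percent(stats.pct_empirical_with_motif))

    # ---- stage 4: profiles --------------------------------------------------
    profiles: dict[str, AggregateProfile] = {}
    labels: dict[str, ProfileLabel] = {}
    ss = np.random.SeedSequence(config.seed, spawn_key=(11,))
    children = iter(ss.spawn(len(sets) * len(tracks)))
    for name in SET_NAMES:
        fs = sets[name]
        for tissue, track in tracks.items():
            child = int(next(children).generate_state(1)[0] % (2 ** 31))
            key = f"{name}:{tissue}"
            if len(fs) == 0:
                labels[key] = ProfileLabel("unclassifiable")
                continue
            prof = aggregate_profile(track, fs, half_width=config.half_width,
                                     bin_size=config.bin_size, n_boot=config.n_boot,
                                     ci_level=config.ci_level, seed=child)
            profiles[key] = prof
            labels[key] = classify_profile(prof, config.center_halfwidth,
                                           config.flank_fraction, config.alpha)
            log.info("profile %s: n=%d dropped=%d label=%s delta=%.3f",
                     key, prof.n_anchors, prof.n_dropped, labels[key].value, labels[key].delta)

    # ---- stage 5: per-family classification ---------------------------------
    classification = None
    if emp_families:
        fam_sites = {f: set3.subset_by_family([f]) for f in sorted(emp_families)}
        fam_sites = {f: s for f, s in fam_sites.items() if len(s)}
        if fam_sites:
            classification = classify_families(
                tracks, fam_sites, half_width=config.half_width, bin_size=config.bin_size,
                n_boot=config.n_boot, ci_level=config.ci_level,
                center_halfwidth=config.center_halfwidth, flank_fraction=config.flank_fraction,
                alpha=config.alpha, seed=config.seed)
            log.info("classification: %d families x %d tissues",
                     len(fam_sites), len(tracks))

    bundle = ReportBundle(
        overlap_stats=stats,
        set_sizes={k: len(v) for k, v in sets.items()},
        profiles=profiles, labels=labels, classification=classification,
        provenance={"config": config.to_dict(), "seed": config.seed,
                    "package": "motif-methylome 0.1.0"},
    )
    render_report(bundle, outdir)
    log.info("run complete")
    return bundle


def render_report(bundle: ReportBundle, outdir) -> list[Path]:
    """Write TSV/JSON artifacts plus a single human-readable summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    _atomic_write(outdir / "report.json",
                  lambda p: Path(p).write_text(json.dumps(bundle.to_json_dict(), indent=1)))
    written.append(outdir / "report.json")

    profdir = outdir / "profiles"
    profdir.mkdir(exist_ok=True)
    for key, prof in bundle.profiles.items():
        path = profdir / (key.replace(":", "_") + ".tsv")
        _atomic_write(path, lambda p, pr=prof: pr.to_frame().to_csv(p, sep="\t", index=False))
        written.append(path)

    if bundle.classification is not None:
        path = outdir / "classification.tsv"
        _atomic_write(path, lambda p: bundle.classification.to_frame().to_csv(p, sep="\t", index=False))
        written.append(path)

    lines = ["Methylation at transcription factor binding sites - run summary", ""]
    if bundle.overlap_stats is not None:
        lines += bundle.overlap_stats.render_lines() + [""]
    if bundle.set_sizes:
        lines.append("set sizes:")
        lines += [f"  {k}: {v}" for k, v in bundle.set_sizes.items()]
        lines.append("")
    if bundle.labels:
        lines.append("aggregate profile labels (set:tissue -> label, center-flank delta):")
        for key, lab in bundle.labels.items():
            if lab.value == "unclassifiable":
                lines.append(f"  {key}: unclassifiable (empty set)")
            else:
                lines.append(f"  {key}: {lab.value} (delta={lab.delta:+.2f})")
        lines.append("")
    if bundle.classification is not None and len(bundle.classification.families) > 0:
        t = bundle.classification
        lines.append(f"per-family labels ({len(t.families)} families):")
        for fam in t.families:
            lines.append("  " + fam + ": " + ", ".join(f"{ti}={t.label(fam, ti)}" for ti in t.tissues))
        if len(t.tissues) >= 2:
            lines.append("")
            lines.append(f"cross-tabulation ({t.tissues[0]} x {t.tissues[1]}):")
            lines += ["  " + row for row in t.cross_tab(t.tissues[0], t.tissues[1]).to_string().splitlines()]
    else:
        lines.append("per-family labels: zero families classified")
    lines.append("")
    lines.append(f"provenance: seed={bundle.provenance.get('seed')}")
    path = outdir / "summary.txt"
    _atomic_write(path, lambda p: Path(p).write_text("\n".join(lines) + "\n"))
    written.append(path)
    return written
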