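"""Anchor-centred aggregate methylation profiles and hyper/hypo classification.

A methylation track holds one percent-methylation value per fixed-width
genomic window (the resolution at which MeDIP-seq deconvolution emits
scores). A profile averages the track at fixed offsets around the midpoints
of a set of anchor intervals; its confidence band is a percentile bootstrap
over anchors. A profile is labelled hyper-methylated when the bootstrap CI
of (center mean - flank mean) lies wholly above zero, hypo-methylated when
wholly below, and neutral otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import BedGraphFormatError, EmptyProfileError
from .intervals import FeatureSet

LABELS = ("hyper", "hypo", "neutral")
UNCLASSIFIABLE = "unclassifiable"


class MethylationTrack:
    """Windowed percent-methylation values (0-100) tiling each chromosome."""

    def __init__(self, values: Mapping[str, np.ndarray], window_size: int):
        if window_size < 1:
            raise ValueError("window_size must be >= 1")
        self.window_size = int(window_size)
        self.values: dict[str, np.ndarray] = {}
        for chrom, v in values.items():
            v = np.asarray(v, dtype=np.float64)
            if v.size and (v.min() < 0 or v.max() > 100):
                raise ValueError(f"{chrom}: track values outside [0, 100]")
            self.values[chrom] = v

    @property
    def chroms(self) -> list[str]:
        return sorted(self.values)

    def chrom_length(self, chrom: str) -> int:
        return self.values[chrom].size * self.window_size

    @property
    def n_windows(self) -> int:
        return sum(v.size for v in self.values.values())

    @property
    def genome_mean(self) -> float:
        total = sum(float(v.sum()) for v in self.values.values())
        n = self.n_windows
        return total / n if n else float("nan")

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Track value of the window containing each position (no interpolation)."""
        v = self.values[chrom]
        idx = np.clip(positions // self.window_size, 0, v.size - 1)
        return v[idx]

    def __eq__(self, other) -> bool:
        if not isinstance(other, MethylationTrack):
            return NotImplemented
        return (self.window_size == other.window_size
                and self.chroms == other.chroms
                and all(np.array_equal(self.values[c], other.values[c]) for c in self.chroms))


def read_bedgraph(path) -> MethylationTrack:
    """Read a constant-window bedGraph (chrom, start, end, value; 0-based half-open).

    Windows must tile each chromosome contiguously from 0; values outside
    [0, 100] and inconsistent window sizes are rejected with line numbers.
    """
    per_chrom: dict[str, list[float]] = {}
    expected_start: dict[str, int] = {}
    window: Optional[int] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise BedGraphFormatError(f"expected 4 fields, got {len(fields)}", path, lineno)
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise BedGraphFormatError("non-numeric coordinates or value", path, lineno) from None
            if end <= start:
                raise BedGraphFormatError(f"end <= start ({end} <= {start})", path, lineno)
            if window is None:
                window = end - start
            elif end - start != window:
                raise BedGraphFormatError(
                    f"inconsistent window size {end - start} (expected {window})", path, lineno)
            if not 0.0 <= value <= 100.0:
                raise BedGraphFormatError(f"value {value} outside [0, 100]", path, lineno)
            if expected_start.setdefault(chrom, 0) != start:
                raise BedGraphFormatError(
                    f"windows must tile contiguously; expected start {expected_start[chrom]}, got {start}",
                    path, lineno)
            expected_start[chrom] = end
            per_chrom.setdefault(chrom, []).append(value)
    if window is None:
        raise BedGraphFormatError("no data records", path)
    return MethylationTrack({c: np.array(v) for c, v in per_chrom.items()}, window)


def write_bedgraph(track: MethylationTrack, path) -> None:
    w = track.window_size
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for i, v in enumerate(track.values[chrom]):
                fh.write(f"{chrom}\t{i * w}\t{(i + 1) * w}\t{v:.6g}\n")


@dataclass
class AggregateProfile:
    """Binned mean methylation around anchor midpoints, with bootstrap CI band."""

    bin_offsets: np.ndarray          # bin-center offsets relative to the anchor midpoint
    bin_means: np.ndarray            # percent methylation per bin
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_anchors: int
    n_dropped: int
    n_boot: int
    ci_level: float
    boot_means: np.ndarray = field(repr=False, default=None)  # (n_boot, n_bins) replicates

    @property
    def n_bins(self) -> int:
        return self.bin_offsets.size

    @property
    def global_mean(self) -> float:
        return float(self.bin_means.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"offset": self.bin_offsets, "mean": self.bin_means,
                             "ci_low": self.ci_low, "ci_high": self.ci_high})


def _bootstrap_bin_means(matrix: np.ndarray, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    # multinomial-weight bootstrap: one bincount + mat-vec per replicate keeps
    # memory flat even for tens of thousands of anchors
    n = matrix.shape[0]
    out = np.empty((n_boot, matrix.shape[1]))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        w = np.bincount(idx, minlength=n).astype(np.float64)
        out[b] = w @ matrix / n
    return out


def aggregate_profile(track: MethylationTrack, anchors: FeatureSet, half_width: int = 2000,
                      bin_size: int = 100, n_boot: int = 1000, ci_level: float = 0.95,
                      seed: int = 0, oriented: bool = False) -> AggregateProfile:
    """Aggregate methylation profile centred on anchor midpoints.

    Each anchor contributes the track value of the window containing
    (midpoint + offset) for every bin offset; anchors whose +-half_width
    span leaves the chromosome are dropped and counted. With
    ``oriented=True`` offsets are mirrored for minus-strand anchors.
    """
    if half_width % bin_size != 0:
        raise ValueError("bin_size must divide half_width")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    offsets = np.arange(-half_width + bin_size // 2, half_width, bin_size, dtype=np.int64)
    rows: list[np.ndarray] = []
    n_dropped = 0
    for chrom, ivs in anchors.by_chrom().items():
        if chrom not in track.values:
            n_dropped += len(ivs)
            continue
        clen = track.chrom_length(chrom)
        mids, flip = [], []
        for iv in ivs:
            m = iv.midpoint
            if m - half_width < 0 or m + half_width > clen:
                n_dropped += 1
                continue
            mids.append(m)
            flip.append(oriented and iv.strand == "-")
        if not mids:
            continue
        mids_a = np.asarray(mids)[:, None]
        off = np.where(np.asarray(flip)[:, None], -offsets[None, :], offsets[None, :])
        rows.append(track.values_at(chrom, mids_a + off))
    if not rows:
        raise EmptyProfileError("no usable anchors after edge filtering")
    matrix = np.vstack(rows)
    rng = np.random.default_rng(seed)
    boot = _bootstrap_bin_means(matrix, n_boot, rng)
    alpha = 1.0 - ci_level
    lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return AggregateProfile(bin_offsets=offsets, bin_means=matrix.mean(axis=0),
                            ci_low=lo, ci_high=hi, n_anchors=matrix.shape[0],
                            n_dropped=n_dropped, n_boot=n_boot, ci_level=ci_level,
                            boot_means=boot)


@dataclass(frozen=True)
class ProfileLabel:
    """Hyper/hypo/neutral call for one profile, with the contrast behind it."""

    value: str
    center_mean: float = float("nan")
    flank_mean: float = float("nan")
    delta: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self):
        if self.value not in LABELS + (UNCLASSIFIABLE,):
            raise ValueError(f"bad label {self.value!r}")


def _center_flank_masks(offsets: np.ndarray, center_halfwidth: int,
                        flank_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    center = np.abs(offsets) <= center_halfwidth
    per_side = offsets.size // 2
    k = max(1, int(np.floor(flank_fraction * per_side)))
    flank = np.zeros_like(center)
    flank[:k] = True
    flank[-k:] = True
    if not center.any():
        raise ValueError("center_halfwidth selects no bins")
    return center, flank


def classify_profile(profile: AggregateProfile, center_halfwidth: int = 250,
                     flank_fraction: float = 0.25, alpha: float = 0.01) -> ProfileLabel:
    """Label a profile hyper/hypo/neutral from the CI of (center - flank).

    The contrast CI (level 1 - alpha) is taken over the same bootstrap
    replicates as the profile band: hyper if wholly above 0, hypo if wholly
    below, neutral otherwise. A conservative default level (99%) keeps the
    per-family false call rate low in multi-family screens.
    """
    center, flank = _center_flank_masks(profile.bin_offsets, center_halfwidth, flank_fraction)
    center_mean = float(profile.bin_means[center].mean())
    flank_mean = float(profile.bin_means[flank].mean())
    delta = center_mean - flank_mean
    reps = profile.boot_means[:, center].mean(axis=1) - profile.boot_means[:, flank].mean(axis=1)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if lo > 0:
        value = "hyper"
    elif hi < 0:
        value = "hypo"
    else:
        value = "neutral"
    return ProfileLabel(value, center_mean, flank_mean, delta, float(lo), float(hi))


@dataclass
class ClassificationTable:
    """Per-family, per-tissue profile labels (the shape of a TF screen table)."""

    tissues: list[str]
    rows: dict[str, dict[str, ProfileLabel]]

    def __post_init__(self):
        for fam, labels in self.rows.items():
            missing = [t for t in self.tissues if t not in labels]
            if missing:
                raise ValueError(f"family {fam}: missing labels for {missing}")

    @property
    def families(self) -> list[str]:
        return list(self.rows)

    def label(self, family: str, tissue: str) -> str:
        return self.rows[family][tissue].value

    def tally(self, tissue: str) -> dict[str, int]:
        counts = {lab: 0 for lab in LABELS + (UNCLASSIFIABLE,)}
        for fam in self.rows:
            counts[self.label(fam, tissue)] += 1
        return counts

    def cross_tab(self, tissue_a: str, tissue_b: str) -> pd.DataFrame:
        labels = list(LABELS + (UNCLASSIFIABLE,))
        table = pd.DataFrame(0, index=labels, columns=labels)
        for fam in self.rows:
            table.loc[self.label(fam, tissue_a), self.label(fam, tissue_b)] += 1
        table.index.name = tissue_a
        table.columns.name = tissue_b
        return table

    def to_frame(self) -> pd.DataFrame:
        records = []
        for fam, labels in self.rows.items():
            rec: dict = {"family": fam}
            for t in self.tissues:
                lab = labels[t]
                rec[t] = lab.value
                rec[f"{t}_delta"] = lab.delta
            records.append(rec)
        return pd.DataFrame(records)

    @classmethod
    def from_labels(cls, tissues: list[str], labels: Mapping[str, tuple[str, ...]]) -> "ClassificationTable":
        """Build from bare label strings (e.g. a transcribed published table)."""
        rows = {fam: {t: ProfileLabel(v) for t, v in zip(tissues, vals)}
                for fam, vals in labels.items()}
        return cls(tissues=list(tissues), rows=rows)


def classify_families(track_by_tissue: Mapping[str, MethylationTrack],
                      sites_by_family: Mapping[str, FeatureSet],
                      half_width: int = 2000, bin_size: int = 100, n_boot: int = 1000,
                      ci_level: float = 0.95, center_halfwidth: int = 250,
                      flank_fraction: float = 0.25, alpha: float = 0.01,
                      seed: int = 0, oriented: bool = False) -> ClassificationTable:
    """One hyper/hypo/neutral label per (family, tissue).

    Deterministic for a fixed seed: each (family, tissue) pair profiles with
    its own child RNG stream. A family with zero usable anchors in a tissue
    is labelled 'unclassifiable' rather than dropped.
    """
    tissues = list(track_by_tissue)
    families = list(sites_by_family)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(families) * len(tissues))
    rows: dict[str, dict[str, ProfileLabel]] = {}
    for fi, fam in enumerate(families):
        fam_labels: dict[str, ProfileLabel] = {}
        for ti, tissue in enumerate(tissues):
            child_seed = int(children[fi * len(tissues) + ti].generate_state(1)[0] % (2 ** 31))
            try:
                prof = aggregate_profile(track_by_tissue[tissue], sites_by_family[fam],
                                         half_width=half_width, bin_size=bin_size,
                                         n_boot=n_boot, ci_level=ci_level,
                                         seed=child_seed, oriented=oriented)
            except EmptyProfileError:
                fam_labels[tissue] = ProfileLabel(UNCLASSIFIABLE)
                continue
            fam_labels[tissue] = classify_profile(prof, center_halfwidth, flank_fraction, alpha)
        rows[fam] = fam_labels
    return ClassificationTable(tissues=tissues, rows=rows)


def plot_profile(profile: AggregateProfile, path, title: str = "") -> None:
    """Mean +- CI band against offset; requires matplotlib (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.fill_between(profile.bin_offsets, profile.ci_low, profile.ci_high,
                    alpha=0.3, lw=0, label=f"{profile.ci_level:.0%} CI")
    ax.plot(profile.bin_offsets, profile.bin_means, lw=1.5)
    ax.set_xlabel("offset from anchor midpoint (bp)")
    ax.set_ylabel("methylation (%)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
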