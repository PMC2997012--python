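"""Genomic intervals, feature sets, BED I/O and overlap statistics.

Coordinates are 0-based half-open throughout (BED native). Feature sets keep
their intervals sorted by (chrom, start, end); duplicate intervals are
retained, since motif tracks legitimately contain overlapping entries for
different matrices.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree

from .errors import BedParseError

VALID_STRANDS = ("+", "-", ".")
ROLES = ("predicted", "empirical", "overlap", "random", "cgi", "user")


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval with an optional TF-family label."""

    chrom: str
    start: int
    end: int
    family: str = ""
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def midpoint(iv: Interval) -> int:
    """Midpoint of an interval: floor((start + end) / 2)."""
    return iv.midpoint


@dataclass(frozen=True)
class FeatureSet:
    """A role-tagged collection of intervals, sorted by (chrom, start, end)."""

    role: str
    intervals: tuple[Interval, ...]
    source_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "intervals", tuple(sorted(self.intervals)))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = defaultdict(list)
        for iv in self.intervals:
            out[iv.chrom].append(iv)
        return dict(out)

    def trees(self) -> dict[str, IntervalTree]:
        out: dict[str, IntervalTree] = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = IntervalTree.from_tuples((iv.start, iv.end, i) for i, iv in enumerate(ivs))
        return out

    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            if iv.family:
                seen.setdefault(iv.family, None)
        return list(seen)

    def subset_by_family(self, families: Iterable[str]) -> "FeatureSet":
        wanted = set(families)
        return FeatureSet(self.role, tuple(iv for iv in self.intervals if iv.family in wanted),
                          self.source_label)

    def with_role(self, role: str, source_label: str | None = None) -> "FeatureSet":
        return FeatureSet(role, self.intervals,
                          self.source_label if source_label is None else source_label)


def feature_set(intervals: Iterable[Interval], role: str = "user", source_label: str = "") -> FeatureSet:
    return FeatureSet(role, tuple(intervals), source_label)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path, role: str = "user", source_label: str | None = None) -> FeatureSet:
    """Read a BED3/BED6 file; track/browser/comment lines are tolerated.

    Column 4 (name) is taken as the TF family label; column 6 as the strand.
    Malformed lines raise :class:`BedParseError` with their line number.
    """
    intervals: list[Interval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"expected >= 3 tab-separated fields, got {len(fields)}",
                                    path, lineno)
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"non-integer coordinates {fields[1]!r}, {fields[2]!r}",
                                    path, lineno) from None
            if start >= end:
                raise BedParseError(f"start >= end ({start} >= {end})", path, lineno)
            name = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand not in VALID_STRANDS:
                raise BedParseError(f"bad strand {strand!r}", path, lineno)
            try:
                intervals.append(Interval(chrom, start, end, name, strand))
            except ValueError as exc:
                raise BedParseError(str(exc), path, lineno) from None
    return FeatureSet(role, tuple(intervals), source_label if source_label is not None else str(path))


def write_bed(fs: FeatureSet, path) -> None:
    """Write BED6 (name = family or '.', score = 0)."""
    with open(path, "w") as fh:
        for iv in fs:
            name = iv.family if iv.family else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def intersect(a: FeatureSet, b: FeatureSet, min_overlap_bp: int = 1) -> FeatureSet:
    """Intervals of `a` overlapping >= min_overlap_bp bases with any interval of `b`.

    Each qualifying interval of `a` appears exactly once, regardless of how
    many `b` intervals it hits; family labels come from `a`.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees = b.trees()
    kept: list[Interval] = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap_bp:
                kept.append(iv)
                break
    return FeatureSet("overlap", tuple(kept), f"{a.source_label} ∩ {b.source_label}")


def subtract(a: FeatureSet, b: FeatureSet, min_overlap_bp: int = 1) -> FeatureSet:
    """Intervals of `a` NOT overlapping >= min_overlap_bp bases with any of `b`."""
    hit = set(intersect(a, b, min_overlap_bp).intervals)
    # duplicates: removal is by value, consistent with duplicate retention
    return FeatureSet(a.role, tuple(iv for iv in a if iv not in hit), a.source_label)


def partition_by_cgi(fs: FeatureSet, cgis: FeatureSet, mode: str = "midpoint") -> tuple[FeatureSet, FeatureSet]:
    """Split a feature set into (inside-CGI, outside-CGI) parts.

    Membership defaults to midpoint-in-island, consistent with
    midpoint-centred profiling; ``mode='containment'`` requires the whole
    interval to lie inside an island. Counts are conserved:
    |in| + |out| == |input|.
    """
    if mode not in ("midpoint", "containment"):
        raise ValueError(f"unknown mode {mode!r}")
    trees = cgis.trees()
    inside: list[Interval] = []
    outside: list[Interval] = []
    for iv in fs:
        tree = trees.get(iv.chrom)
        is_in = False
        if tree is not None:
            if mode == "midpoint":
                is_in = bool(tree.at(iv.midpoint))
            else:
                is_in = any(h.begin <= iv.start and iv.end <= h.end
                            for h in tree.overlap(iv.start, iv.end))
        (inside if is_in else outside).append(iv)
    return (FeatureSet(fs.role, tuple(inside), f"{fs.source_label} [CGI]"),
            FeatureSet(fs.role, tuple(outside), f"{fs.source_label} [non-CGI]"))


# ---------------------------------------------------------------------------
# Overlap statistics


def _pct(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den else None


def format_percent(value: Optional[float]) -> str:
    """One-decimal rendering; undefined (zero denominator) renders as 'NA'."""
    return "NA" if value is None else f"{value:.1f}"


@dataclass(frozen=True)
class OverlapStats:
    """Counts and percentages relating predicted motifs, empirical peaks and CGIs."""

    n_predicted: int
    n_empirical: int
    n_overlap: int
    pct_empirical_with_motif: Optional[float]
    pct_predicted_bound: Optional[float]
    pct_predicted_in_cgi: Optional[float] = None
    pct_empirical_overlap_in_cgi: Optional[float] = None

    def __post_init__(self):
        if self.n_overlap > max(self.n_predicted, self.n_empirical):
            raise ValueError("n_overlap cannot exceed both set sizes")

    @classmethod
    def from_counts(cls, n_overlap: int, n_empirical: int, n_predicted: int) -> "OverlapStats":
        return cls(n_predicted=n_predicted, n_empirical=n_empirical, n_overlap=n_overlap,
                   pct_empirical_with_motif=_pct(n_overlap, n_empirical),
                   pct_predicted_bound=_pct(n_overlap, n_predicted))

    def to_dict(self) -> dict:
        return {
            "n_predicted": self.n_predicted,
            "n_empirical": self.n_empirical,
            "n_overlap": self.n_overlap,
            "pct_empirical_with_motif": self.pct_empirical_with_motif,
            "pct_predicted_bound": self.pct_predicted_bound,
            "pct_predicted_in_cgi": self.pct_predicted_in_cgi,
            "pct_empirical_overlap_in_cgi": self.pct_empirical_overlap_in_cgi,
        }

    def render_lines(self) -> list[str]:
        return [
            f"predicted motif locations: {self.n_predicted}",
            f"empirical binding sites:   {self.n_empirical}",
            f"overlap (motif & bound):   {self.n_overlap}",
            f"% empirical with conserved motif: {format_percent(self.pct_empirical_with_motif)}",
            f"% predicted biologically bound:   {format_percent(self.pct_predicted_bound)}",
            f"% predicted in CGI:               {format_percent(self.pct_predicted_in_cgi)}",
            f"% overlap set in CGI:             {format_percent(self.pct_empirical_overlap_in_cgi)}",
        ]


def overlap_statistics(predicted: FeatureSet, empirical: FeatureSet,
                       cgis: FeatureSet | None = None, min_overlap_bp: int = 1,
                       count_mode: str = "motif") -> OverlapStats:
    """Overlap counts and percentages between predicted and empirical sets.

    ``count_mode='motif'`` counts overlapping predicted (motif) locations,
    ``'peak'`` counts overlapping empirical peaks; with one-to-one planted
    pairs the two coincide.
    """
    if count_mode not in ("motif", "peak"):
        raise ValueError(f"unknown count_mode {count_mode!r}")
    overlap_pred = intersect(predicted, empirical, min_overlap_bp)
    if count_mode == "motif":
        n_overlap = len(overlap_pred)
    else:
        n_overlap = len(intersect(empirical, predicted, min_overlap_bp))
    pct_pred_cgi = pct_ov_cgi = None
    if cgis is not None:
        in_p, _ = partition_by_cgi(predicted, cgis)
        pct_pred_cgi = _pct(len(in_p), len(predicted))
        in_o, _ = partition_by_cgi(overlap_pred, cgis)
        pct_ov_cgi = _pct(len(in_o), len(overlap_pred))
    return OverlapStats(
        n_predicted=len(predicted), n_empirical=len(empirical), n_overlap=n_overlap,
        pct_empirical_with_motif=_pct(n_overlap, len(empirical)),
        pct_predicted_bound=_pct(n_overlap, len(predicted)),
        pct_predicted_in_cgi=pct_pred_cgi,
        pct_empirical_overlap_in_cgi=pct_ov_cgi,
    )
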