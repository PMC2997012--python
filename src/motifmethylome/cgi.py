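"""CpG-island annotation by maximal scoring segments.

The genome is scanned one dinucleotide at a time; each dinucleotide scores
+17 if it is exactly ``CG`` and -1 otherwise. All maximal scoring segments
of this score sequence (in the Ruzzo-Tompa sense: positive score, disjoint,
none extendable into or contained in a better-scoring overlapping segment)
are candidate islands, and a candidate is accepted when

* GC content >= 50%,
* length strictly greater than 200 bp, and
* observed/expected CpG ratio strictly greater than 0.6, where the expected
  count is (#C x #G) / length for the segment.

Equal-score extensions are resolved leftmost-longest. A segment over
dinucleotide indices [i, j] maps to the base interval [i, j+2), so the
reported island includes the final base of its last CG. Dinucleotides
containing ``N`` score -1; ``N`` bases count toward segment length but not
toward the C/G tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import BoundsError

_C = ord("C")
_G = ord("G")


@dataclass(frozen=True)
class CgiScoringParams:
    cg_score: int = 17
    other_score: int = -1

    def __post_init__(self):
        if not (self.cg_score > 0 > self.other_score):
            raise ValueError("require cg_score > 0 > other_score")


@dataclass(frozen=True)
class CgiCriteria:
    min_gc: float = 0.50
    min_length_exclusive: int = 200
    min_obs_exp_exclusive: float = 0.6

    def __post_init__(self):
        if not 0 < self.min_gc < 1:
            raise ValueError("min_gc must be in (0, 1)")
        if self.min_length_exclusive <= 0:
            raise ValueError("min_length_exclusive must be > 0")
        if self.min_obs_exp_exclusive <= 0:
            raise ValueError("min_obs_exp_exclusive must be > 0")


@dataclass(frozen=True)
class ScoredSegment:
    """A maximal scoring segment in base coordinates ([start, end), 0-based)."""

    chrom: str
    start: int
    end: int
    score: int

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CgiSegment:
    """A scored segment annotated with its composition statistics."""

    interval: ScoredSegment
    gc_content: float
    obs_exp_cpg: float
    n_cpg: int
    n_c: int
    n_g: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def length(self) -> int:
        return self.interval.length


def _to_array(sequence) -> np.ndarray:
    if isinstance(sequence, np.ndarray):
        return sequence
    return np.frombuffer(str(sequence).upper().encode("ascii"), dtype=np.uint8)


def score_dinucleotides(sequence, params: CgiScoringParams = CgiScoringParams()) -> np.ndarray:
    """Score every dinucleotide of `sequence`: cg_score for CG, other_score else.

    Returns an integer array of length len(sequence) - 1 (empty for
    sequences shorter than 2). Case-insensitive; any dinucleotide containing
    N (or any non-CG pair) takes other_score.
    """
    arr = _to_array(sequence)
    if arr.size < 2:
        return np.empty(0, dtype=np.int64)
    is_cg = (arr[:-1] == _C) & (arr[1:] == _G)
    return np.where(is_cg, params.cg_score, params.other_score).astype(np.int64)


def _rt_items(items: Iterable[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Ruzzo-Tompa over weighted items (score, first_index, last_index).

    Items arrive in positional order; nonpositive items only shift the
    cumulative score. Returns disjoint spans as (first_index, last_index,
    score), sorted by position, with leftmost-longest tie-breaking: a
    zero-gain extension is merged rather than split.
    """
    stack: list[list[int]] = []  # [L, R, first, last]
    cum = 0
    min_l = None  # conservative lower bound on min L in stack (stale after merges is safe)
    for score, first, last in items:
        new_cum = cum + score
        if score <= 0:
            cum = new_cum
            continue
        cur = [cum, new_cum, first, last]
        cum = new_cum
        while True:
            if not stack or (min_l is not None and cur[0] < min_l):
                # fast path for long low-scoring stretches: no entry can satisfy
                # L_j <= L_cur, so cur stands alone
                stack.append(cur)
                min_l = cur[0] if min_l is None else min(min_l, cur[0])
                break
            j = len(stack) - 1
            while j >= 0 and stack[j][0] > cur[0]:
                j -= 1
            if j < 0 or stack[j][1] > cur[1]:
                stack.append(cur)
                min_l = cur[0] if min_l is None else min(min_l, cur[0])
                break
            # absorb stack[j:] into cur and reconsider further left
            cur[0] = stack[j][0]
            cur[2] = stack[j][2]
            del stack[j:]
    return [(first, last, R - L) for L, R, first, last in stack]


def maximal_scoring_segments(scores: Sequence[int], chrom: str = "seq") -> list[ScoredSegment]:
    """All maximal scoring segments of a dinucleotide score sequence.

    A span over dinucleotide indices [i, j] is reported in base coordinates
    [i, j + 2). All-nonpositive input yields an empty list.
    """
    arr = np.asarray(scores)
    spans = _rt_items((int(s), i, i) for i, s in enumerate(arr))
    return [ScoredSegment(chrom, first, last + 2, score) for first, last, score in spans]


def _compressed_items(cg_pos: np.ndarray, params: CgiScoringParams) -> Iterable[tuple[int, int, int]]:
    # run-length compression: +cg items at CG dinucleotide indices, a single
    # weighted negative item per inter-CG gap; flanking gaps never enter a
    # maximal segment and are dropped.
    prev = None
    for p in cg_pos:
        p = int(p)
        if prev is not None and p - prev > 1:
            gap = p - prev - 1
            yield (params.other_score * gap, prev + 1, p - 1)
        yield (params.cg_score, p, p)
        prev = p


def _counts(arr: np.ndarray) -> tuple[int, int, int]:
    n_c = int(np.count_nonzero(arr == _C))
    n_g = int(np.count_nonzero(arr == _G))
    if arr.size < 2:
        n_cpg = 0
    else:
        n_cpg = int(np.count_nonzero((arr[:-1] == _C) & (arr[1:] == _G)))
    return n_c, n_g, n_cpg


def _stats_from_array(arr: np.ndarray, segment: ScoredSegment) -> CgiSegment:
    if segment.start < 0 or segment.end > arr.size:
        raise BoundsError(
            f"segment [{segment.start}, {segment.end}) outside sequence of length {arr.size}")
    sub = arr[segment.start:segment.end]
    n_c, n_g, n_cpg = _counts(sub)
    length = segment.length
    gc = (n_c + n_g) / length
    denom = n_c * n_g
    obs_exp = (n_cpg * length / denom) if denom else 0.0
    return CgiSegment(segment, gc_content=gc, obs_exp_cpg=obs_exp,
                      n_cpg=n_cpg, n_c=n_c, n_g=n_g)


def segment_stats(sequence, segment: ScoredSegment) -> CgiSegment:
    """GC content, CpG count and observed/expected CpG ratio of a segment.

    obs/exp = n_cpg / ((n_c * n_g) / length), defined as 0 when n_c * n_g
    is 0; CpG dinucleotides are counted only when fully inside the segment.
    """
    return _stats_from_array(_to_array(sequence), segment)


def _passes(c: CgiSegment, criteria: CgiCriteria) -> bool:
    return (c.gc_content >= criteria.min_gc
            and c.length > criteria.min_length_exclusive
            and c.obs_exp_cpg > criteria.min_obs_exp_exclusive)


def call_cpg_islands(sequence, params: CgiScoringParams = CgiScoringParams(),
                     criteria: CgiCriteria = CgiCriteria(), chrom: str = "seq") -> list[CgiSegment]:
    """Call CpG islands on one sequence.

    Maximal scoring segments of the +17/-1 dinucleotide score are computed on
    a run-length-compressed representation (identical output to scoring every
    dinucleotide, since segments always start and end on a CG), then filtered
    by the three criteria. Rejected segments are dropped, not re-evaluated.
    """
    arr = _to_array(sequence)
    if arr.size < 2:
        return []
    cg_pos = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    if cg_pos.size == 0:
        return []
    spans = _rt_items(_compressed_items(cg_pos, params))
    out = []
    for first, last, score in spans:
        seg = ScoredSegment(chrom, first, last + 2, score)
        stats = _stats_from_array(arr, seg)
        if _passes(stats, criteria):
            out.append(stats)
    return out


def call_cpg_islands_genome(sequences: dict[str, str],
                            params: CgiScoringParams = CgiScoringParams(),
                            criteria: CgiCriteria = CgiCriteria()) -> list[CgiSegment]:
    """Call islands chromosome by chromosome; output order follows sorted names."""
    out: list[CgiSegment] = []
    for chrom in sorted(sequences):
        out.extend(call_cpg_islands(sequences[chrom], params, criteria, chrom=chrom))
    return out


def islands_to_bed(islands: list[CgiSegment], path) -> None:
    """BED4 with the common CGI-track naming shape, name = 'CpG: k'."""
    with open(path, "w") as fh:
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\tCpG: {isl.n_cpg}\n")


def islands_to_tsv(islands: list[CgiSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tscore\tlength\tgc_content\tobs_exp_cpg\tn_cpg\n")
        for isl in islands:
            fh.write(f"{isl.chrom}\t{isl.start}\t{isl.end}\t{isl.interval.score}\t"
                     f"{isl.length}\t{isl.gc_content:.4f}\t{isl.obs_exp_cpg:.4f}\t{isl.n_cpg}\n")
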