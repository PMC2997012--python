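import numpy as np
import pytest

from motifmethylome import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def default_truth():
    """One default synthetic genome shared across tests (read-only)."""
    return generate_genome(SyntheticConfig(seed=1))


def maximal_segments_bruteforce(scores):
    """Independent oracle: enumerate every contiguous subarray and extract
    maximal scoring segments by repeated best-first selection.

    A candidate never starts or ends on a nonpositive score; ties resolve
    leftmost start, then longest. Returns sorted (first, last, score) spans
    over score indices.
    """
    out = []

    def best(lo, hi):
        b = None
        for i in range(lo, hi):
            if scores[i] <= 0:
                continue
            s = 0
            for j in range(i, hi):
                s += scores[j]
                if scores[j] <= 0:
                    continue
                if s > 0 and (b is None or s > b[0]
                              or (s == b[0] and (i < b[1] or (i == b[1] and j > b[2])))):
                    b = (s, i, j)
        return b

    def rec(lo, hi):
        b = best(lo, hi)
        if b is None:
            return
        s, i, j = b
        rec(lo, i)
        out.append((i, j, s))
        rec(j + 1, hi)

    rec(0, len(scores))
    return sorted(out)


def intersect_bruteforce(a, b, min_overlap_bp=1):
    """All-pairs oracle for interval intersection membership."""
    kept = []
    for iv in a:
        for jv in b:
            if iv.chrom == jv.chrom and min(iv.end, jv.end) - max(iv.start, jv.start) >= min_overlap_bp:
                kept.append(iv)
                break
    return kept


def jaccard(a, b):
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0
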