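"""Synthetic genomes, methylation tracks and TFBS feature sets.

The generator emulates the statistical structure the downstream analysis
assumes: a mostly methylated genomic background with CpG-depleted sequence,
a set of planted CpG islands that are CG-dense, CpG-rich and hypo-methylated,
a predicted-motif feature set placed clear of islands (so the local context
of an unbound conserved motif is methylated), and an empirical
(ChIP-seq-like) feature set of which a small configured fraction co-locates
with a motif and a larger configured fraction falls inside islands.

Sequence synthesis draws bases i.i.d. at a target GC and then thins CG
dinucleotides to a target observed/expected ratio (replacing the G of a
removed CpG with A or T); planted islands are reject-and-resampled until,
measured directly on the emitted sequence, they satisfy the island caller's
criteria and form a single dominant maximal scoring segment, so every
planted island is recoverable by construction.

All randomness flows from the master seed through fixed per-artifact
labels, so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .cgi import CgiCriteria, CgiScoringParams, ScoredSegment, _counts, _rt_items, _to_array
from .errors import ConfigError, PlacementError
from .intervals import FeatureSet, Interval
from .profiling import MethylationTrack

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (int(b) for b in _BASES)

# the 17 TF families with public genome-wide ChIP-seq used by the empirical
# set, plus a handful of motif-only families for the full predicted track
EMPIRICAL_FAMILIES = (
    "E2F", "NFY", "YY1", "MYCMAX", "NFKB", "AP", "NRSF", "SREBP", "SRF",
    "STAT", "TCF", "GATA", "NFE2", "OCT", "SOX", "EP300", "TP53",
)
PREDICTED_ONLY_FAMILIES = ("SP1", "CREB", "MYOD", "PAX", "HOX", "MEF2", "ER")
DEFAULT_FAMILIES = EMPIRICAL_FAMILIES + PREDICTED_ONLY_FAMILIES

_STREAMS = {"genome": 1, "cgi": 2, "sites": 3, "track": 4, "random": 5}


def _rng(seed: int, label: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[label], index)))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic methylome.

    Defaults: a 2 Mb genome over 2 chromosomes at 50 bp track resolution,
    75% background / 20% island methylation with 8-point Gaussian noise,
    2,000 predicted and 2,000 empirical 20 bp sites, 3.4% of empirical sites
    carrying a planted motif and 40% of them inside islands.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    background_gc: float = 0.40
    n_cgis: int = 60
    cgi_length_mean: int = 1000
    cgi_gc: float = 0.60
    cgi_obs_exp: float = 0.75
    background_methylation_mean: float = 75.0
    cgi_methylation_mean: float = 20.0
    methylation_noise_sd: float = 8.0
    track_window: int = 50
    n_predicted_sites: int = 2000
    n_empirical_sites: int = 2000
    overlap_fraction: float = 0.034
    empirical_cgi_bias: float = 0.40
    site_length: int = 20
    seed: int = 0
    # mammalian background CpG depletion (obs/exp well below 1 outside islands)
    background_cpg_depletion: float = 0.25
    # unbound motifs are planted at least this far from any island
    cgi_clearance: int = 500
    families: tuple[str, ...] = DEFAULT_FAMILIES
    empirical_families: tuple[str, ...] = EMPIRICAL_FAMILIES

    def __post_init__(self):
        def bad(fieldname, msg):
            raise ConfigError(msg, field=fieldname)

        if self.genome_length < 1:
            bad("genome_length", "must be >= 1")
        if self.n_chromosomes < 1:
            bad("n_chromosomes", "must be >= 1")
        if not 0.0 <= self.background_gc < 1.0:
            bad("background_gc", "must be in [0, 1)")
        if self.n_cgis < 0:
            bad("n_cgis", "must be >= 0")
        if self.n_cgis > 0:
            if not 0.0 < self.cgi_gc < 1.0:
                bad("cgi_gc", "must be in (0, 1)")
            if self.cgi_obs_exp <= 0:
                bad("cgi_obs_exp", "must be > 0")
            if self.genome_length < self.n_cgis * self.cgi_length_mean:
                bad("genome_length", "must be >= n_cgis * cgi_length_mean")
        for name in ("background_methylation_mean", "cgi_methylation_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                bad(name, "must be in [0, 100]")
        if self.cgi_methylation_mean >= self.background_methylation_mean:
            bad("cgi_methylation_mean", "must be < background_methylation_mean")
        if self.methylation_noise_sd < 0:
            bad("methylation_noise_sd", "must be >= 0")
        if self.track_window < 1:
            bad("track_window", "must be >= 1")
        for name in ("n_predicted_sites", "n_empirical_sites"):
            if getattr(self, name) < 0:
                bad(name, "must be >= 0")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            bad("overlap_fraction", "must be in [0, 1]")
        if not 0.0 <= self.empirical_cgi_bias <= 1.0:
            bad("empirical_cgi_bias", "must be in [0, 1]")
        if self.site_length < 1:
            bad("site_length", "must be >= 1")
        if not 0.0 < self.background_cpg_depletion <= 1.0:
            bad("background_cpg_depletion", "must be in (0, 1]")
        if self.cgi_clearance < 0:
            bad("cgi_clearance", "must be >= 0")

    def chrom_lengths(self) -> dict[str, int]:
        # equal split, rounded down to whole track windows so windows tile exactly
        w = self.track_window
        per = (self.genome_length // self.n_chromosomes) // w * w
        if per < w:
            raise ConfigError("chromosomes shorter than one track window", field="genome_length")
        return {f"chr{i + 1}": per for i in range(self.n_chromosomes)}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        d["empirical_families"] = list(self.empirical_families)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("families", "empirical_families"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown field(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class GenomeTruth:
    """A generated genome plus the ground truth of everything planted in it."""

    sequences: dict[str, str]
    planted_cgis: FeatureSet
    planted_predicted: FeatureSet
    planted_empirical: FeatureSet
    true_methylation: MethylationTrack
    config: SyntheticConfig

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


# ---------------------------------------------------------------------------
# sequence synthesis


def _compensated_gc(target_gc: float, keep: float) -> float:
    # CG thinning replaces the G of (1 - keep) of CpGs with A/T, lowering GC
    # by ~(1 - keep) * (gc/2)^2 per base; invert by fixed point
    g = target_gc
    for _ in range(8):
        g = target_gc + (1.0 - keep) * (g / 2.0) ** 2
    return min(g, 0.999)


def _iid_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    at = (1.0 - gc) / 2.0
    cg = gc / 2.0
    cum = np.cumsum([at, cg, cg, at])
    idx = np.searchsorted(cum, rng.random(n), side="right")
    return _BASES[np.clip(idx, 0, 3)]


def _thin_cpg(arr: np.ndarray, rng: np.random.Generator, keep: float) -> np.ndarray:
    if keep >= 1.0 or arr.size < 2:
        return arr
    pos = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    if pos.size == 0:
        return arr
    drop = pos[rng.random(pos.size) >= keep]
    repl = np.where(rng.random(drop.size) < 0.5, _A, _T).astype(np.uint8)
    arr[drop + 1] = repl
    return arr


def _sample_sequence(rng: np.random.Generator, n: int, gc: float, obs_exp: float) -> np.ndarray:
    arr = _iid_bases(rng, n, _compensated_gc(gc, obs_exp))
    return _thin_cpg(arr, rng, obs_exp)


def _island_is_recoverable(arr: np.ndarray, criteria: CgiCriteria,
                           params: CgiScoringParams, min_cover: float = 0.9) -> bool:
    n_c, n_g, n_cpg = _counts(arr)
    length = arr.size
    gc = (n_c + n_g) / length
    denom = n_c * n_g
    oe = (n_cpg * length / denom) if denom else 0.0
    if not (gc >= criteria.min_gc and length > criteria.min_length_exclusive
            and oe > criteria.min_obs_exp_exclusive):
        return False
    cg_pos = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    if cg_pos.size == 0:
        return False
    items = []
    prev = None
    for p in cg_pos:
        p = int(p)
        if prev is not None and p - prev > 1:
            items.append((params.other_score * (p - prev - 1), prev + 1, p - 1))
        items.append((params.cg_score, p, p))
        prev = p
    spans = _rt_items(items)
    best = max(spans, key=lambda s: s[1] - s[0])
    return (best[1] + 2 - best[0]) >= min_cover * length


def sample_island(rng: np.random.Generator, length: int, gc: float, obs_exp: float,
                  criteria: CgiCriteria = CgiCriteria(),
                  params: CgiScoringParams = CgiScoringParams(),
                  max_attempts: int = 200) -> np.ndarray:
    """Draw an island sequence that verifiably passes the caller's criteria.

    Rejection-resamples until the realized GC, obs/exp and segment structure
    guarantee the island is called as a single dominant maximal segment.
    """
    for _ in range(max_attempts):
        arr = _sample_sequence(rng, length, gc, obs_exp)
        if _island_is_recoverable(arr, criteria, params):
            return arr
    raise PlacementError(
        f"could not sample a recoverable island (length={length}, gc={gc}, obs_exp={obs_exp})")


# ---------------------------------------------------------------------------
# genome generation


def _place_islands(rng: np.random.Generator, config: SyntheticConfig,
                   chrom_lengths: dict[str, int]) -> list[Interval]:
    if config.n_cgis == 0:
        return []
    shape = 6.0
    lengths = rng.gamma(shape, config.cgi_length_mean / shape, size=config.n_cgis)
    lengths = np.clip(lengths, max(300, config.cgi_length_mean // 2),
                      2 * config.cgi_length_mean).astype(int)
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    out: list[Interval] = []
    gap = 200
    for L in lengths:
        L = int(L)
        for _ in range(2000):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            clen = chrom_lengths[chrom]
            if clen < L + 100:
                continue
            start = int(rng.integers(50, clen - L - 50))
            if all(start >= e + gap or start + L + gap <= s for s, e in placed[chrom]):
                placed[chrom].append((start, start + L))
                out.append(Interval(chrom, start, start + L))
                break
        else:
            raise PlacementError("could not place all CpG islands; genome too crowded")
    return sorted(out)


def generate_genome(config: SyntheticConfig) -> GenomeTruth:
    """Generate sequence, planted islands, feature sets and the true track.

    Deterministic for a fixed seed; planted islands satisfy the island
    caller's three criteria when measured directly on the emitted sequence.
    """
    chrom_lengths = config.chrom_lengths()
    island_rng = _rng(config.seed, "cgi")
    islands = _place_islands(island_rng, config, chrom_lengths)

    genome_rng = _rng(config.seed, "genome")
    arrays: dict[str, np.ndarray] = {}
    for chrom, clen in chrom_lengths.items():
        arrays[chrom] = _sample_sequence(genome_rng, clen, config.background_gc,
                                         config.background_cpg_depletion)
    for iv in islands:
        arrays[iv.chrom][iv.start:iv.end] = sample_island(
            island_rng, iv.length, config.cgi_gc, config.cgi_obs_exp)

    sequences = {c: a.tobytes().decode("ascii") for c, a in arrays.items()}
    cgi_set = FeatureSet("cgi", tuple(islands), "planted CpG islands")
    truth = GenomeTruth(sequences=sequences, planted_cgis=cgi_set,
                        planted_predicted=FeatureSet("predicted", ()),
                        planted_empirical=FeatureSet("empirical", ()),
                        true_methylation=None, config=config)
    predicted, empirical = place_feature_sets(truth, config)
    truth.planted_predicted = predicted
    truth.planted_empirical = empirical
    truth.true_methylation = simulate_methylation_track(truth, config)
    return truth


# ---------------------------------------------------------------------------
# methylation track


def simulate_methylation_track(truth: GenomeTruth, config: SyntheticConfig | None = None,
                               tissue_index: int = 0) -> MethylationTrack:
    """One value per track window: island windows around the island mean,
    background windows around the background mean, Gaussian noise, clipped
    to [0, 100]. Windows partially covered by an island interpolate the two
    means by covered fraction. `tissue_index` selects an independent noise
    stream (e.g. two tissues over one genome)."""
    config = config or truth.config
    w = config.track_window
    rng = _rng(config.seed, "track", tissue_index)
    values: dict[str, np.ndarray] = {}
    cgis = truth.planted_cgis.by_chrom()
    for chrom, clen in truth.chrom_lengths().items():
        nwin = clen // w
        frac = np.zeros(nwin)
        for iv in cgis.get(chrom, []):
            lo = iv.start // w
            hi = (iv.end + w - 1) // w
            for k in range(lo, min(hi, nwin)):
                ov = min(iv.end, (k + 1) * w) - max(iv.start, k * w)
                frac[k] = min(1.0, frac[k] + ov / w)
        base = (1.0 - frac) * config.background_methylation_mean + frac * config.cgi_methylation_mean
        noise = rng.normal(0.0, config.methylation_noise_sd, nwin) if config.methylation_noise_sd > 0 else 0.0
        values[chrom] = np.clip(base + noise, 0.0, 100.0)
    return MethylationTrack(values, w)


# ---------------------------------------------------------------------------
# feature sets


def _tree_dict(chroms) -> dict[str, IntervalTree]:
    return {c: IntervalTree() for c in chroms}


def place_feature_sets(truth: GenomeTruth, config: SyntheticConfig | None = None
                       ) -> tuple[FeatureSet, FeatureSet]:
    """Plant (predicted, empirical) sets with the configured structure.

    Per empirical site, independent Bernoulli draws decide whether it
    carries a planted motif (overlap_fraction) and whether it sits inside an
    island (empirical_cgi_bias). Motif-carrying sites get a co-located
    predicted partner; the remaining predicted sites are placed in the
    methylated background, at least `cgi_clearance` bp from any island, and
    empirical sites without a motif are rejection-sampled away from every
    predicted site so the realized overlap equals the designated draws.
    Family names are assigned round-robin.
    """
    config = config or truth.config
    rng = _rng(config.seed, "sites")
    chrom_lengths = truth.chrom_lengths()
    chroms = list(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    L = config.site_length
    margin = L  # keep in-island sites comfortably interior

    cgi_trees = truth.planted_cgis.trees()
    islands = [iv for iv in truth.planted_cgis
               if iv.length >= L + 2 * margin]
    n_emp = config.n_empirical_sites
    in_cgi = rng.random(n_emp) < config.empirical_cgi_bias
    bound = rng.random(n_emp) < config.overlap_fraction
    if not islands:
        # island-free genome: the CGI bias has nothing to bias toward
        in_cgi[:] = False
    n_pred_only = config.n_predicted_sites - int(bound.sum())
    if n_pred_only < 0:
        raise PlacementError("more designated overlap sites than predicted sites")

    def clear_of(trees, chrom, start, end, pad=0):
        t = trees.get(chrom)
        return t is None or not t.overlaps(start - pad, end + pad)

    def draw_background(avoid_trees, pad=0, max_attempts=20000):
        for _ in range(max_attempts):
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            clen = chrom_lengths[chrom]
            if clen <= L:
                continue
            start = int(rng.integers(0, clen - L))
            if not clear_of(cgi_trees, chrom, start, start + L, pad=pad):
                continue
            if avoid_trees is not None and not clear_of(avoid_trees, chrom, start, start + L):
                continue
            return chrom, start
        raise PlacementError("could not place site in background; genome too crowded")

    def draw_in_island():
        iv = islands[int(rng.integers(0, len(islands)))]
        start = int(rng.integers(iv.start + margin, iv.end - margin - L + 1))
        return iv.chrom, start

    placed_trees = _tree_dict(chroms)  # all predicted sites + bound empirical

    def remember(chrom, start):
        placed_trees[chrom].addi(start, start + L)

    predicted: list[Interval] = []
    empirical: list[Interval] = []
    fam_all = config.families
    fam_emp = config.empirical_families

    # predicted-only motifs: methylated background, clear of islands
    for i in range(n_pred_only):
        chrom, start = draw_background(None, pad=config.cgi_clearance)
        predicted.append(Interval(chrom, start, start + L,
                                  fam_all[i % len(fam_all)], "+"))
        remember(chrom, start)

    # empirical sites; motif carriers first so non-carriers can avoid them
    order = np.argsort(~bound, kind="stable")  # bound sites first
    for rank, i in enumerate(order):
        fam = fam_emp[int(i) % len(fam_emp)]
        if bound[i]:
            if in_cgi[i]:
                chrom, start = draw_in_island()
            else:
                chrom, start = draw_background(placed_trees)
            site = Interval(chrom, start, start + L, fam, "+")
            empirical.append(site)
            predicted.append(Interval(chrom, start, start + L, fam, "+"))
            remember(chrom, start)
        else:
            for _ in range(20000):
                if in_cgi[i]:
                    chrom, start = draw_in_island()
                else:
                    chrom, start = draw_background(None)
                if clear_of(placed_trees, chrom, start, start + L):
                    break
            else:
                raise PlacementError("could not place motif-free empirical site")
            empirical.append(Interval(chrom, start, start + L, fam, "+"))

    return (FeatureSet("predicted", tuple(predicted), "planted predicted TFBS"),
            FeatureSet("empirical", tuple(empirical), "planted empirical TFBS"))


def random_intervals(genome: GenomeTruth | dict[str, int], n: int, length: int,
                     seed: int = 0) -> FeatureSet:
    """`n` uniformly placed intervals of fixed length, ignoring all planted
    structure; the negative-control anchor set."""
    if n < 0:
        raise ValueError("n must be >= 0")
    chrom_lengths = genome.chrom_lengths() if isinstance(genome, GenomeTruth) else dict(genome)
    chroms = sorted(chrom_lengths)
    if n and any(chrom_lengths[c] < length for c in chroms):
        raise PlacementError("length exceeds a chromosome length")
    rng = _rng(seed, "random")
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    which = rng.choice(len(chroms), size=n, p=weights)
    out = []
    for i in range(n):
        chrom = chroms[int(which[i])]
        start = int(rng.integers(0, chrom_lengths[chrom] - length + 1))
        out.append(Interval(chrom, start, start + length, "", "."))
    return FeatureSet("random", tuple(out), "random genomic locations")


# ---------------------------------------------------------------------------
# planted-contrast benchmark track (classification power harness)


def planted_contrast_track(contrasts: dict[str, float], n_anchors_per_family: int,
                           background: float = 75.0, noise_sd: float = 8.0,
                           window: int = 50, site_length: int = 20,
                           effect_halfwidth: int = 300, spacing: int = 5000,
                           seed: int = 0) -> tuple[MethylationTrack, dict[str, FeatureSet]]:
    """A flat noisy track with per-family methylation offsets planted at
    anchor centers (+-effect_halfwidth), for measuring label recovery.

    Anchors lie on a grid with `spacing` >= profile extent so family effects
    never overlap; families are interleaved along the grid.
    """
    fams = list(contrasts)
    total = len(fams) * n_anchors_per_family
    length = (total + 2) * spacing // window * window
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    nwin = length // window
    values = background + (rng.normal(0.0, noise_sd, nwin) if noise_sd > 0 else 0.0)
    sites: dict[str, list[Interval]] = {f: [] for f in fams}
    for k in range(total):
        fam = fams[k % len(fams)]
        mid = spacing // 2 + (k + 1) * spacing
        delta = contrasts[fam]
        if delta:
            lo = max(0, (mid - effect_halfwidth) // window)
            hi = min(nwin, (mid + effect_halfwidth + window - 1) // window)
            values[lo:hi] += delta
        sites[fam].append(Interval("chr1", mid - site_length // 2, mid + site_length // 2, fam, "+"))
    track = MethylationTrack({"chr1": np.clip(values, 0.0, 100.0)}, window)
    return track, {f: FeatureSet("predicted", tuple(v), f"planted {f}") for f, v in sites.items()}


# ---------------------------------------------------------------------------
# serialization


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sequences):
            fh.write(f">{chrom}\n")
            seq = sequences[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_truth_json(truth: GenomeTruth, path) -> None:
    def fs_to_list(fs: FeatureSet):
        return [[iv.chrom, iv.start, iv.end, iv.family, iv.strand] for iv in fs]

    payload = {
        "config": truth.config.to_dict(),
        "chrom_lengths": truth.chrom_lengths(),
        "planted_cgis": fs_to_list(truth.planted_cgis),
        "planted_predicted": fs_to_list(truth.planted_predicted),
        "planted_empirical": fs_to_list(truth.planted_empirical),
    }
    Path(path).write_text(json.dumps(payload, indent=1))
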