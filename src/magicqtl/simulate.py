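"""Forward simulation of MAGIC populations with known founder mosaics.

Emulates the NIAB elite eight-founder wheat design: founders are crossed
through balanced funnels (four 2-way crosses, two 4-way crosses, one 8-way
cross) and the 8-way hybrid is taken through repeated selfing by
single-seed descent to derive near-inbred recombinant lines (RILs). Every
simulated genome is stored as its true mosaic of founder segments, so
downstream inference can be scored against ground truth.

Meiosis uses the Haldane model: crossovers form a Poisson process along the
chromosome at 1 per 100 cM with no interference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gmap import GeneticMap

__all__ = [
    "FounderSet",
    "HaplotypeTrack",
    "MosaicGenome",
    "GenotypeMatrix",
    "FOUNDER_NAMES",
    "simulate_founders",
    "meiosis",
    "simulate_funnel",
    "simulate_population_mosaics",
    "emit_genotypes",
    "MISSING",
]

#: The eight NIAB MAGIC founder varieties, in the conventional column order.
FOUNDER_NAMES: tuple[str, ...] = (
    "Alchemy", "Brompton", "Claire", "Hereward",
    "Rialto", "Robigus", "Soissons", "Xi-19",
)

#: Sentinel for a missing genotype call in integer-coded matrices.
MISSING: int = -1


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FounderSet:
    """Named founders with biallelic haplotypes aligned to a genetic map.

    ``haplotypes`` is an (S, M) 0/1 array, one row per founder, one column
    per mapped marker.
    """

    names: tuple[str, ...]
    haplotypes: np.ndarray = field(repr=False)
    gmap: GeneticMap = field(repr=False)

    def __post_init__(self) -> None:
        H = np.asarray(self.haplotypes, dtype=np.int8)
        if H.ndim != 2 or H.shape[0] != len(self.names):
            raise ValueError("haplotype matrix must be (n_founders, n_markers)")
        if H.shape[1] != self.gmap.n_markers:
            raise ValueError(
                f"haplotypes have {H.shape[1]} markers, map has {self.gmap.n_markers}"
            )
        if len(set(self.names)) != len(self.names):
            raise ValueError("founder names must be unique")
        if not np.isin(H, (0, 1)).all():
            raise ValueError("founder haplotypes must be biallelic 0/1")
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "haplotypes", H)

    @property
    def n_founders(self) -> int:
        return len(self.names)


def _max_pairwise_divergence(n_founders: int) -> float:
    """Largest achievable random-pair difference rate for biallelic markers.

    Attained by a balanced allele split: k = floor(S/2) founders on one
    allele gives k(S-k) differing pairs out of C(S,2).
    """
    s = n_founders
    k = s // 2
    return k * (s - k) / (s * (s - 1) / 2)


def simulate_founders(
    gmap: GeneticMap,
    n_founders: int = 8,
    divergence: float = 0.5,
    seed: int | np.random.Generator = 0,
    names: tuple[str, ...] | None = None,
) -> FounderSet:
    """Draw biallelic founder haplotypes with a target pairwise difference rate.

    ``divergence`` is the probability that a randomly chosen founder pair
    carries different alleles at a marker. For rates up to 0.5 alleles are
    drawn independently per founder; beyond 0.5 (possible only for small S)
    markers mix in balanced bipartitions. Monomorphic draws are redrawn, so
    every marker is polymorphic among the founders.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if not 0.0 < divergence <= 1.0:
        raise ValueError("divergence must be in (0, 1]; 0 gives no informative markers")
    dmax = _max_pairwise_divergence(n_founders)
    if divergence > dmax + 1e-12:
        raise ValueError(
            f"divergence {divergence} unattainable with {n_founders} founders "
            f"(max {dmax:.3f})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if names is None:
        names = FOUNDER_NAMES if n_founders == 8 else tuple(
            f"F{i + 1}" for i in range(n_founders)
        )

    s, m = n_founders, gmap.n_markers
    H = np.empty((s, m), dtype=np.int8)

    if divergence <= 0.5:
        # independent Bernoulli(p) per founder: pair-difference = 2p(1-p)
        p = (1.0 - np.sqrt(1.0 - 2.0 * divergence)) / 2.0
        w_split = 0.0
    else:
        # mix balanced bipartitions (difference dmax) with Bernoulli(0.5)
        p = 0.5
        w_split = (divergence - 0.5) / (dmax - 0.5)

    k = s // 2
    for j in range(m):
        while True:
            if w_split and rng.random() < w_split:
                col = np.zeros(s, dtype=np.int8)
                col[rng.permutation(s)[:k]] = 1
            else:
                col = (rng.random(s) < p).astype(np.int8)
            if 0 < col.sum() < s:  # redraw monomorphic markers
                H[:, j] = col
                break
    return FounderSet(tuple(names)[:s], H, gmap)


# ---------------------------------------------------------------------------
# mosaics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeTrack:
    """One homolog of one chromosome as founder-labelled segments.

    Segment ``i`` covers (ends[i-1], ends[i]] in cM (the first starts at
    ``start``); ``founders[i]`` is the founder index of that segment.
    """

    start: float
    ends: np.ndarray
    founders: np.ndarray

    def __post_init__(self) -> None:
        ends = np.asarray(self.ends, dtype=float)
        fnd = np.asarray(self.founders, dtype=np.int64)
        if ends.shape != fnd.shape or ends.ndim != 1 or ends.size == 0:
            raise ValueError("ends and founders must be equal-length 1-D arrays")
        if np.any(np.diff(ends) <= 0) or ends[0] <= self.start:
            raise ValueError("segment ends must be strictly increasing past start")
        object.__setattr__(self, "ends", ends)
        object.__setattr__(self, "founders", fnd)

    @property
    def end(self) -> float:
        return float(self.ends[-1])

    def founder_at(self, pos: np.ndarray | float) -> np.ndarray:
        """Founder index at each query position (positions within the span)."""
        idx = np.searchsorted(self.ends, np.atleast_1d(pos), side="left")
        idx = np.minimum(idx, len(self.ends) - 1)
        return self.founders[idx]

    def n_segments(self) -> int:
        return len(self.ends)


def _constant_track(start: float, end: float, founder: int) -> HaplotypeTrack:
    return HaplotypeTrack(start, np.array([end]), np.array([founder]))


def _merge_runs(ends: np.ndarray, founders: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    keep = np.append(founders[1:] != founders[:-1], True)
    return ends[keep], founders[keep]


def meiosis(
    homologs: tuple[HaplotypeTrack, HaplotypeTrack],
    rng: np.random.Generator,
) -> HaplotypeTrack:
    """Form one gamete track from a diplotype by Haldane recombination.

    Crossover count is Poisson with mean (length in cM)/100, positions
    uniform; the gamete alternates between the two parental homologs,
    starting from one chosen uniformly.
    """
    a, b = homologs
    if a.start != b.start or a.end != b.end:
        raise ValueError("homolog tracks must span the same interval")
    start, end = a.start, a.end
    length = end - start
    n_x = rng.poisson(length / 100.0) if length > 0 else 0
    cuts = np.sort(rng.uniform(start, end, size=n_x)) if n_x else np.empty(0)
    source = int(rng.integers(2))

    seg_ends: list[np.ndarray] = []
    seg_fnd: list[np.ndarray] = []
    lo = start
    for hi in [*cuts, end]:
        if hi <= lo:
            source ^= 1
            continue
        trk = homologs[source]
        i0 = int(np.searchsorted(trk.ends, lo, side="right"))
        i1 = int(np.searchsorted(trk.ends, hi, side="left"))
        i1 = min(i1, len(trk.ends) - 1)
        ends = trk.ends[i0:i1 + 1].copy()
        ends[-1] = hi
        seg_ends.append(ends)
        seg_fnd.append(trk.founders[i0:i1 + 1])
        lo = hi
        source ^= 1

    ends = np.concatenate(seg_ends)
    fnd = np.concatenate(seg_fnd)
    ends, fnd = _merge_runs(ends, fnd)
    return HaplotypeTrack(start, ends, fnd)


@dataclass(frozen=True)
class MosaicGenome:
    """True founder-origin mosaic of one line: two tracks per chromosome."""

    tracks: dict[str, tuple[HaplotypeTrack, HaplotypeTrack]]

    def chromosomes(self) -> list[str]:
        return list(self.tracks)

    def founders_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """(n_pos, 2) founder indices of the two homologs at each position."""
        t0, t1 = self.tracks[chrom]
        return np.stack([t0.founder_at(pos), t1.founder_at(pos)], axis=1)

    def heterozygosity(self, gmap: GeneticMap) -> float:
        """Fraction of mapped markers where the two homologs differ in origin."""
        diff = total = 0
        for chrom in gmap.chromosomes:
            f = self.founders_at(chrom, gmap.positions(chrom))
            diff += int((f[:, 0] != f[:, 1]).sum())
            total += len(f)
        return diff / total

    def validate(self, gmap: GeneticMap) -> None:
        """Check segments tile each chromosome span and labels are sane."""
        for chrom in gmap.chromosomes:
            lo, hi = gmap.chrom_span(chrom)
            for trk in self.tracks[chrom]:
                if trk.start > lo or trk.end < hi:
                    raise ValueError(f"track does not cover chromosome {chrom}")
                if trk.founders.min() < 0:
                    raise ValueError("negative founder label")

    def segment_table(self, line_id: str = "") -> pd.DataFrame:
        """BED-like long table: chrom, start_cM, end_cM, founder, homolog."""
        rows = []
        for chrom, pair in self.tracks.items():
            for h, trk in enumerate(pair):
                lo = trk.start
                for end, fnd in zip(trk.ends, trk.founders):
                    rows.append((chrom, lo, float(end), int(fnd), h, line_id))
                    lo = float(end)
        return pd.DataFrame(
            rows, columns=["chrom", "start_cM", "end_cM", "founder", "homolog", "line_id"]
        )


def _cross(
    p1: MosaicGenome, p2: MosaicGenome, rng: np.random.Generator
) -> MosaicGenome:
    tracks = {}
    for chrom in p1.tracks:
        tracks[chrom] = (meiosis(p1.tracks[chrom], rng), meiosis(p2.tracks[chrom], rng))
    return MosaicGenome(tracks)


def _founder_genome(gmap: GeneticMap, founder: int) -> MosaicGenome:
    tracks = {}
    for chrom in gmap.chromosomes:
        lo, hi = gmap.chrom_span(chrom)
        hi = max(hi, lo + 1e-9)
        tracks[chrom] = (
            _constant_track(lo, hi, founder),
            _constant_track(lo, hi, founder),
        )
    return MosaicGenome(tracks)


def simulate_funnel(
    founders: FounderSet,
    funnel_order: tuple[int, ...] | list[int],
    gmap: GeneticMap,
    n_self: int = 5,
    seed: int | np.random.Generator = 0,
) -> MosaicGenome:
    """Run one 8-way funnel and selfing series; return the final RIL mosaic.

    ``funnel_order`` gives the eight founder indices in funnel position
    order: ((0x1)x(2x3)) x ((4x5)x(6x7)). Selfing proceeds by single-seed
    descent: one selfed offspring is carried forward per generation.
    """
    order = list(funnel_order)
    if len(order) != 8 or len(set(order)) != 8:
        raise ValueError("funnel_order must be 8 distinct founder indices")
    if any(not 0 <= f < founders.n_founders for f in order):
        raise ValueError("funnel_order contains an invalid founder index")
    if n_self < 0:
        raise ValueError("n_self must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    g = [_founder_genome(gmap, f) for f in order]
    f1 = [_cross(g[i], g[i + 1], rng) for i in (0, 2, 4, 6)]   # 4 two-way crosses
    f2 = [_cross(f1[0], f1[1], rng), _cross(f1[2], f1[3], rng)]  # 2 four-way
    plant = _cross(f2[0], f2[1], rng)                            # 1 eight-way
    for _ in range(n_self):
        plant = _cross(plant, plant, rng)
    return plant


def simulate_population_mosaics(
    founders: FounderSet,
    gmap: GeneticMap,
    n_lines: int = 208,
    n_self: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[list[MosaicGenome], list[str]]:
    """Simulate `n_lines` RILs, one per random funnel permutation.

    Line ids follow the population's "MEL" naming convention.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if founders.n_founders != 8:
        raise ValueError("funnel design requires exactly 8 founders")
    mosaics = []
    for _ in range(n_lines):
        order = tuple(rng.permutation(8))
        mosaics.append(simulate_funnel(founders, order, gmap, n_self=n_self, seed=rng))
    ids = [f"MEL_{i + 1:03d}" for i in range(n_lines)]
    return mosaics, ids


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeMatrix:
    """Integer-coded genotypes: rows are lines, columns mapped markers.

    Values count copies of the alternate allele (0/1/2); missing calls are
    the ``MISSING`` (-1) sentinel.
    """

    line_ids: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)
    gmap: GeneticMap = field(repr=False)

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=np.int8)
        if G.shape != (len(self.line_ids), self.gmap.n_markers):
            raise ValueError("genotype matrix shape does not match lines x markers")
        if not np.isin(G, (MISSING, 0, 1, 2)).all():
            raise ValueError("genotype codes must be 0/1/2 or missing (-1)")
        object.__setattr__(self, "matrix", G)
        object.__setattr__(self, "line_ids", tuple(self.line_ids))

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def missing_fraction(self) -> float:
        return float((self.matrix == MISSING).mean())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.matrix.astype(float), index=list(self.line_ids),
            columns=list(self.gmap.markers),
        )
        return df.mask(df < 0)


def true_diplotypes(
    mosaics: list[MosaicGenome], gmap: GeneticMap
) -> np.ndarray:
    """(n_lines, n_markers, 2) true founder indices at every mapped marker."""
    n, m = len(mosaics), gmap.n_markers
    out = np.empty((n, m, 2), dtype=np.int64)
    for chrom in gmap.chromosomes:
        sl = gmap.chrom_slice(chrom)
        pos = gmap.positions(chrom)
        for i, mos in enumerate(mosaics):
            out[i, sl, :] = mos.founders_at(chrom, pos)
    return out


def emit_genotypes(
    mosaics: list[MosaicGenome],
    founders: FounderSet,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator = 0,
    line_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Read marker genotypes off the true mosaics, with noise and dropout.

    Each allele is flipped independently with ``error_rate``; whole calls
    are masked with ``missing_rate`` (the study's array data had 2.19%
    missing points).
    """
    if not 0 <= error_rate < 1 or not 0 <= missing_rate < 1:
        raise ValueError("error_rate and missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gmap = founders.gmap
    for mos in mosaics:
        if set(mos.tracks) != set(gmap.chromosomes):
            raise ValueError("mosaic chromosomes do not match the map")

    dip = true_diplotypes(mosaics, gmap)           # (n, m, 2)
    alleles = founders.haplotypes[dip, np.arange(gmap.n_markers)[None, :, None]]
    if error_rate > 0:
        flips = rng.random(alleles.shape) < error_rate
        alleles = np.where(flips, 1 - alleles, alleles)
    G = alleles.sum(axis=2).astype(np.int8)
    if missing_rate > 0:
        G[rng.random(G.shape) < missing_rate] = MISSING
    if line_ids is None:
        line_ids = [f"MEL_{i + 1:03d}" for i in range(len(mosaics))]
    return GenotypeMatrix(tuple(line_ids), G, gmap)
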