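"""Mosaic-structure analyses of duplication segments.

Once duplicons are called, the architecture of the duplications they
compose is analysed through

* binary phylogenetic profiles (presence/absence of each duplicon in
  each duplication segment, with presence requiring an aligned copy at
  >= 95% identity over >= 100 bp, and segments kept only when they
  contain >= 10 duplicons);
* neighbor-joining trees over profile distances, whose clades group
  segments with shared duplication ancestry;
* core duplicons — duplicons shared by more than 67% of the segments of
  a clade;
* flanking duplicon pairs — two highly similar duplicon copies sitting
  in the terminal 25% windows of a CNV, the substrate of nonallelic
  homologous recombination (NAHR);
* weighted duplicon density of genomic regions, used to contrast CNV
  against non-CNV sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "GenomicInterval",
    "DupliconOccurrence",
    "PhyloProfile",
    "CladeCore",
    "WelchResult",
    "build_profiles",
    "profile_distance",
    "shares_history",
    "distance_matrix",
    "nj_tree",
    "core_duplicons",
    "flanking_pairs",
    "weighted_density",
    "duplicon_weights",
    "merge_intervals",
    "complement_intervals",
    "compare_densities",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    name: str = ""
    category: str = "other"  # CNV, SD, non-CNV, other

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DupliconOccurrence:
    """One aligned copy of a duplicon somewhere in the genome."""

    duplicon_id: str
    interval: GenomicInterval
    identity: float
    length: int

    def __post_init__(self) -> None:
        if self.identity < 0:
            raise ValueError("identity cannot be negative")
        if self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass
class PhyloProfile:
    segment_id: str
    bits: np.ndarray
    index: tuple[str, ...]  # duplicon ids, shared across profiles

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.int8)
        if self.bits.shape != (len(self.index),):
            raise ValueError("bit vector length must match the duplicon index")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("profile entries must be 0/1")


def _overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def build_profiles(
    segments,
    occurrences,
    min_duplicons: int = 10,
    min_identity: float = 95.0,
    min_len: int = 100,
) -> list[PhyloProfile]:
    """Binary phylogenetic profiles of duplication segments.

    A duplicon is present in a segment when one of its occurrences with
    identity >= ``min_identity`` and length >= ``min_len`` overlaps the
    segment.  Segments with fewer than ``min_duplicons`` distinct
    duplicons are dropped; duplicons absent from every retained segment
    are dropped from the shared index.
    """
    qual = [
        occ
        for occ in occurrences
        if occ.identity >= min_identity and occ.length >= min_len
    ]
    present: dict[str, set[str]] = {}
    for seg in segments:
        dups = {occ.duplicon_id for occ in qual if _overlaps(occ.interval, seg)}
        if len(dups) >= min_duplicons:
            present[seg.name] = dups
    index = tuple(sorted(set().union(*present.values()))) if present else ()
    profiles = []
    for seg_id in sorted(present):
        bits = np.fromiter(
            (1 if d in present[seg_id] else 0 for d in index), dtype=np.int8, count=len(index)
        )
        profiles.append(PhyloProfile(segment_id=seg_id, bits=bits, index=index))
    return profiles


def profile_distance(a: PhyloProfile, b: PhyloProfile) -> float:
    """Hamming fraction between two profiles over the shared index."""
    if a.index != b.index:
        raise ValueError("profiles built over different duplicon indices")
    if len(a.index) == 0:
        return 0.0
    return float(np.count_nonzero(a.bits != b.bits)) / len(a.index)


def shares_history(a: PhyloProfile, b: PhyloProfile) -> bool:
    """Segments sharing no duplicon have no related evolutionary history."""
    return bool(np.dot(a.bits, b.bits) > 0)


def distance_matrix(profiles) -> DistanceMatrix:
    """Pairwise Hamming-fraction matrix, ids sorted for determinism."""
    profs = sorted(profiles, key=lambda p: p.segment_id)
    ids = [p.segment_id for p in profs]
    mat = np.stack([p.bits for p in profs]).astype(float)
    d = np.abs(mat[:, None, :] - mat[None, :, :]).mean(axis=2)
    return DistanceMatrix(d, ids=ids)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree over the distance table (>= 3 leaves)."""
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 segments")
    return nj(distances)


@dataclass(frozen=True)
class CladeCore:
    clade_id: str
    leaves: tuple[str, ...]
    core_duplicons: tuple[str, ...]
    shares: dict[str, float] = field(hash=False, default_factory=dict)


def core_duplicons(
    tree: TreeNode,
    profiles,
    share_threshold: float = 0.67,
) -> list[CladeCore]:
    """Core duplicons per clade: shared by strictly more than the threshold.

    Every internal node with >= 3 leaf descendants is treated as a
    clade; for each, duplicons present in > ``share_threshold`` of its
    leaf segments are reported.
    """
    by_id = {p.segment_id: p for p in profiles}
    # NJ roots arbitrarily; midpoint rooting makes clades on both sides
    # of the deepest split visible to the scan
    try:
        tree = tree.root_at_midpoint()
    except Exception:
        pass  # unrooted/degenerate trees are scanned as-is
    out: list[CladeCore] = []
    cid = 0
    for node in tree.preorder():
        if node.is_tip():
            continue
        leaves = tuple(sorted(t.name for t in node.tips()))
        if len(leaves) < 3:
            continue
        missing = [l for l in leaves if l not in by_id]
        if missing:
            raise ValueError(f"profiles missing for leaves: {missing}")
        index = by_id[leaves[0]].index
        counts = np.zeros(len(index), dtype=int)
        for leaf in leaves:
            counts += by_id[leaf].bits
        shares = counts / len(leaves)
        core_mask = shares > share_threshold
        cores = tuple(d for d, c in zip(index, core_mask) if c)
        out.append(
            CladeCore(
                clade_id=f"clade_{cid:03d}",
                leaves=leaves,
                core_duplicons=cores,
                shares={d: float(s) for d, s in zip(index, shares) if s > 0},
            )
        )
        cid += 1
    return out


def _pair_identity(a: DupliconOccurrence, b: DupliconOccurrence, sequences) -> float:
    import edlib

    sa = sequences[a.interval.chrom][a.interval.start : a.interval.end]
    sb = sequences[b.interval.chrom][b.interval.start : b.interval.end]
    if not sa or not sb:
        return 0.0
    d = edlib.align(sa, sb, task="distance")["editDistance"]
    return 100.0 * (1.0 - d / max(len(sa), len(sb)))


def flanking_pairs(
    cnv: GenomicInterval,
    occurrences,
    end_frac: float = 0.25,
    min_sim: float = 90.0,
    sequences: dict[str, str] | None = None,
) -> list[tuple[DupliconOccurrence, DupliconOccurrence]]:
    """Duplicon pairs flanking both ends of a CNV (NAHR substrates).

    The end windows span ``end_frac`` of the CNV from each boundary.
    With sequences, a pair is one occurrence per window whose lengths
    agree within ``min_sim``/100 (shorter/longer ratio) and whose
    sequences match at > ``min_sim`` percent identity; without
    sequences, two copies of the same duplicon stand in for the
    similarity-and-length test.
    """
    w = int(end_frac * cnv.length)
    if cnv.length < 4 or w < 1:
        raise ValueError(f"CNV too short for {end_frac:.0%} end windows: {cnv}")
    left = GenomicInterval(cnv.chrom, cnv.start, cnv.start + w, "left")
    right = GenomicInterval(cnv.chrom, cnv.end - w, cnv.end, "right")

    def within(occ: DupliconOccurrence, win: GenomicInterval) -> bool:
        iv = occ.interval
        return iv.chrom == win.chrom and iv.start >= win.start and iv.end <= win.end

    lefts = [o for o in occurrences if within(o, left)]
    rights = [o for o in occurrences if within(o, right)]
    pairs = []
    for a, b in itertools.product(lefts, rights):
        if sequences is not None:
            ratio = min(a.length, b.length) / max(a.length, b.length)
            if ratio <= min_sim / 100.0:
                continue
            if _pair_identity(a, b, sequences) <= min_sim:
                continue
        elif a.duplicon_id != b.duplicon_id:
            continue
        pairs.append((a, b))
    return pairs


def weighted_density(
    region: GenomicInterval,
    occurrences,
    weights: dict[str, float],
) -> float:
    """Sum of weights of duplicons in the region, per base of region.

    An occurrence belongs to the region when at least half of its bases
    fall inside.  The weight of a duplicon is its frequency across the
    training CNVs (see :func:`duplicon_weights`).
    """
    total = 0.0
    for occ in occurrences:
        iv = occ.interval
        if iv.chrom != region.chrom:
            continue
        ov = min(iv.end, region.end) - max(iv.start, region.start)
        if ov > 0 and 2 * ov >= iv.length:
            total += weights.get(occ.duplicon_id, 0.0)
    return total / region.length


def duplicon_weights(occurrences, training_cnvs) -> dict[str, float]:
    """Weight of each duplicon = number of training CNVs containing it."""
    cnvs_of: dict[str, set[str]] = {}
    for occ in occurrences:
        for cnv in training_cnvs:
            if _overlaps(occ.interval, cnv):
                cnvs_of.setdefault(occ.duplicon_id, set()).add(cnv.name)
    return {d: float(len(s)) for d, s in cnvs_of.items()}


def merge_intervals(intervals) -> list[GenomicInterval]:
    """Union of possibly overlapping intervals, per chromosome."""
    out: list[GenomicInterval] = []
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    for iv in sorted(intervals, key=key):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.name, last.category)
        else:
            out.append(iv)
    return out


def complement_intervals(
    intervals, chrom_sizes: dict[str, int], category: str = "non-CNV"
) -> list[GenomicInterval]:
    """Gaps between merged intervals, within the chromosome bounds."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in merged:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        cursor = 0
        for iv in by_chrom.get(chrom, []):
            if iv.start > cursor:
                out.append(
                    GenomicInterval(chrom, cursor, iv.start, f"{chrom}:{cursor}", category)
                )
            cursor = max(cursor, iv.end)
        if cursor < size:
            out.append(GenomicInterval(chrom, cursor, size, f"{chrom}:{cursor}", category))
    return out


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float


def compare_densities(cnv_densities, noncnv_densities) -> WelchResult:
    """Two-tailed Welch's t test between two density collections."""
    a = np.asarray(list(cnv_densities), dtype=float)
    b = np.asarray(list(noncnv_densities), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            # no variance, no difference: the test is vacuous
            return WelchResult(0.0, float(len(a) + len(b) - 2), 1.0, float(a.mean()), float(b.mean()))
        raise ValueError("zero variance in both groups: Welch statistic undefined")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(
        t=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )
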