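"""Synthetic fixtures with known ground truth.

Real alignment matrices mix two signals: duplicons produce column
blocks of consecutive 1s carried by many SD rows, while spurious
alignments produce sparse, short 1-runs.  The generators here plant
both — duplicon column-blocks carried by a Bernoulli subset of rows,
plus Poisson-many background runs per row with geometric lengths — and
return the planted truth alongside, so decoding, permutation testing
and the downstream mosaic analyses can all be validated without any
external data.  All generators are reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import AlignmentMatrix, _merge_spans
from .mosaic import DupliconOccurrence, GenomicInterval

__all__ = [
    "PlantedMatrixSpec",
    "PlantedTruth",
    "generate_matrix",
    "generate_segment_set",
    "generate_flanked_cnv",
    "matrix_to_blast_tab",
]


@dataclass(frozen=True)
class PlantedMatrixSpec:
    """Recipe for a synthetic alignment matrix.

    ``blocks`` are (start, end, carrier_fraction) column intervals;
    each row carries a given block with probability carrier_fraction.
    ``noise_rate`` is the expected number of background runs per row,
    with geometric lengths of mean ``noise_len_mean``.
    """

    m: int
    n_cols: int
    blocks: tuple[tuple[int, int, float], ...] = ()
    noise_rate: float = 0.0
    noise_len_mean: float = 20.0
    seed: int = 0
    cnv_id: str = "cnv_sim"

    def __post_init__(self) -> None:
        if self.m < 0 or self.n_cols < 1:
            raise ValueError("need m >= 0 and n_cols >= 1")
        if self.noise_rate < 0:
            raise ValueError("noise_rate must be >= 0")
        prev_end = 0
        for s, e, cf in sorted(self.blocks):
            if not (0 <= s < e <= self.n_cols):
                raise ValueError(f"block ({s}, {e}) outside [0, {self.n_cols})")
            if s < prev_end:
                raise ValueError("planted blocks must not overlap")
            if not 0.0 < cf <= 1.0:
                raise ValueError("carrier_fraction must lie in (0, 1]")
            prev_end = e


@dataclass
class PlantedTruth:
    blocks: list[tuple[int, int]]
    carrier_counts: list[int]
    row_runs: list[list[tuple[int, int]]] = field(default_factory=list)


def generate_matrix(spec: PlantedMatrixSpec) -> tuple[AlignmentMatrix, PlantedTruth]:
    """Plant duplicon blocks and background noise into a run-list matrix."""
    rng = np.random.default_rng(spec.seed)
    blocks = sorted((s, e) for s, e, _ in spec.blocks)
    fractions = [cf for _, _, cf in sorted(spec.blocks)]
    carrier_counts = [0] * len(blocks)
    rows: list[list[tuple[int, int]]] = []
    row_ids: list[str] = []
    for i in range(spec.m):
        spans: list[tuple[int, int]] = []
        for b, ((s, e), cf) in enumerate(zip(blocks, fractions)):
            if rng.random() < cf:
                spans.append((s, e))
                carrier_counts[b] += 1
        n_noise = rng.poisson(spec.noise_rate)
        for _ in range(n_noise):
            ln = min(int(rng.geometric(1.0 / spec.noise_len_mean)), spec.n_cols)
            start = int(rng.integers(0, spec.n_cols - ln + 1))
            spans.append((start, start + ln))
        row_ids.append(f"sd_{i:04d}")
        rows.append(_merge_spans(spans))
    mat = AlignmentMatrix(cnv_id=spec.cnv_id, n_cols=spec.n_cols, row_ids=row_ids, rows=rows)
    mat.validate()
    truth = PlantedTruth(
        blocks=blocks,
        carrier_counts=carrier_counts,
        row_runs=[list(r) for r in rows],
    )
    return mat, truth


def generate_segment_set(
    n_groups: int,
    segments_per_group: int,
    duplicons_per_group: int,
    sharing: float,
    seed: int = 0,
    core_fraction: float = 0.8,
):
    """Duplication segments in groups with controlled duplicon sharing.

    Each group owns ``duplicons_per_group`` duplicons; each of its
    segments carries each group duplicon with probability ``sharing``
    (no cross-group duplicons).  One designated core duplicon per group
    is forced into ``core_fraction`` of its segments (> 67% by
    default).  Returns (segments, occurrences, truth) where truth maps
    group id -> (segment names, core duplicon id).
    """
    if not 0.0 < sharing <= 1.0:
        raise ValueError("sharing must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    seg_len, occ_len = 5000, 150
    segments: list[GenomicInterval] = []
    occurrences: list[DupliconOccurrence] = []
    truth: dict[str, tuple[list[str], str]] = {}
    pos = 0
    for g in range(n_groups):
        chrom = f"chr_sim{g}"
        dup_ids = [f"dup_g{g}_{d:03d}" for d in range(duplicons_per_group)]
        core = dup_ids[0]
        names = []
        n_core = max(int(np.ceil(core_fraction * segments_per_group)), 1)
        core_carriers = set(rng.choice(segments_per_group, size=n_core, replace=False).tolist())
        for s in range(segments_per_group):
            name = f"seg_g{g}_{s:02d}"
            start = pos
            seg = GenomicInterval(chrom, start, start + seg_len, name, "SD")
            segments.append(seg)
            names.append(name)
            cursor = start
            for d, dup in enumerate(dup_ids):
                carried = (s in core_carriers) if dup == core else (rng.random() < sharing)
                if carried:
                    occurrences.append(
                        DupliconOccurrence(
                            duplicon_id=dup,
                            interval=GenomicInterval(chrom, cursor, cursor + occ_len, f"{name}:{dup}"),
                            identity=float(rng.uniform(96.0, 100.0)),
                            length=occ_len,
                        )
                    )
                cursor += occ_len + 10
            pos += seg_len + 1000
        truth[f"group_{g}"] = (names, core)
    return segments, occurrences, truth


def generate_flanked_cnv(
    cnv_len: int,
    n_pairs: int,
    seed: int = 0,
    n_fillers: int = 2,
    chrom: str = "chr_sim",
):
    """A CNV with ``n_pairs`` duplicons placed once in each 25% end window.

    Filler duplicons (unpaired, distinct ids) are placed in the middle
    half.  Returns (cnv, occurrences).
    """
    if cnv_len < 100:
        raise ValueError("cnv_len must be >= 100")
    rng = np.random.default_rng(seed)
    cnv = GenomicInterval(chrom, 0, cnv_len, "cnv_flank", "CNV")
    w = cnv_len // 4
    occ_len = max(min(100, w // max(n_pairs, 1) - 1), 10)
    occurrences: list[DupliconOccurrence] = []

    def place(window_start: int, window_end: int, dup: str, tag: str) -> None:
        start = int(rng.integers(window_start, window_end - occ_len + 1))
        occurrences.append(
            DupliconOccurrence(
                duplicon_id=dup,
                interval=GenomicInterval(chrom, start, start + occ_len, f"{dup}:{tag}"),
                identity=float(rng.uniform(96.0, 100.0)),
                length=occ_len,
            )
        )

    for i in range(n_pairs):
        dup = f"dup_pair_{i:02d}"
        place(0, w, dup, "L")
        place(cnv_len - w, cnv_len, dup, "R")
    mid_lo, mid_hi = w, cnv_len - w
    for i in range(n_fillers):
        if mid_hi - mid_lo > occ_len:
            place(mid_lo, mid_hi, f"dup_fill_{i:02d}", "M")
    return cnv, occurrences


def matrix_to_blast_tab(matrix: AlignmentMatrix, path, identity: float = 99.0) -> None:
    """Write a matrix back out as 12-column BLAST tabular hits.

    One record per 1-run (subject coordinates 1-based inclusive), so
    the full file-based pipeline can be exercised end to end.
    """
    with open(path, "w") as fh:
        for sd_id, runs in zip(matrix.row_ids, matrix.rows):
            qpos = 1
            for s, e in runs:
                ln = e - s
                fh.write(
                    "\t".join(
                        map(
                            str,
                            [
                                sd_id,
                                matrix.cnv_id,
                                f"{identity:.2f}",
                                ln,
                                0,
                                0,
                                qpos,
                                qpos + ln - 1,
                                s + 1,
                                e,
                                "1e-10",
                                f"{2 * ln:.1f}",
                            ],
                        )
                    )
                    + "\n"
                )
                qpos += ln
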