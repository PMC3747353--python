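"""Binary alignment matrices of segmental duplications over CNV sequences.

A CNV of length ``n`` aligned by ``m`` segmental duplications (SDs) is
summarised as a binary m x n matrix whose entry (i, j) is 1 when SD i
aligns to position j of the CNV.  The matrix is kept in a run-list
representation (per-row maximal intervals of consecutive 1s), which is
what every downstream computation — column sums, adjacent-column pattern
counts, run relocation — actually needs.

Coordinates are 0-based half-open internally.  BLAST tabular input is
1-based inclusive and is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlignmentHit",
    "AlignmentMatrix",
    "ColumnStats",
    "read_blast_tab",
    "build_matrix",
    "column_stats",
]


@dataclass(frozen=True)
class AlignmentHit:
    """One HSP of an SD against a CNV, in CNV coordinates."""

    sd_id: str
    cnv_id: str
    cnv_start: int  # 0-based
    cnv_end: int  # half-open
    identity: float  # percent, [0, 100]
    aln_length: int
    strand: str = "+"
    #: optional matched sub-spans relative to cnv_start (strict mode);
    #: None means the whole subject span counts as aligned.
    match_spans: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if not self.cnv_start < self.cnv_end:
            raise ValueError(f"empty hit interval: {self}")
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError(f"identity outside [0, 100]: {self.identity}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length < 1: {self.aln_length}")


@dataclass
class AlignmentMatrix:
    """Run-list representation of one CNV's binary alignment matrix.

    ``rows[i]`` is the sorted list of disjoint, non-adjacent (maximal)
    1-runs of the SD named ``row_ids[i]``.
    """

    cnv_id: str
    n_cols: int
    row_ids: list[str] = field(default_factory=list)
    rows: list[list[tuple[int, int]]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.rows)

    def validate(self) -> None:
        if self.n_cols < 1:
            raise ValueError("matrix must have at least one column")
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids and rows out of sync")
        for rid, runs in zip(self.row_ids, self.rows):
            prev_end = -2
            for s, e in runs:
                if not (0 <= s < e <= self.n_cols):
                    raise ValueError(f"run ({s}, {e}) of {rid!r} outside [0, {self.n_cols})")
                if s <= prev_end + 1 and prev_end >= 0:
                    raise ValueError(f"runs of {rid!r} not maximal/disjoint")
                prev_end = e - 1

    def to_dense(self) -> np.ndarray:
        """Materialize the full 0/1 matrix (small inputs / testing only)."""
        dense = np.zeros((self.m, self.n_cols), dtype=np.int8)
        for i, runs in enumerate(self.rows):
            for s, e in runs:
                dense[i, s:e] = 1
        return dense

    def column_counts(self) -> np.ndarray:
        """Per-column number of 1s, computed from the run lists."""
        diff = np.zeros(self.n_cols + 1, dtype=np.int64)
        for runs in self.rows:
            for s, e in runs:
                diff[s] += 1
                diff[e] -= 1
        return np.cumsum(diff[:-1])


@dataclass
class ColumnStats:
    """Column sums and adjacent-column 0/1 pattern counts of a matrix."""

    o: np.ndarray  # length n_cols
    f11: np.ndarray  # length n_cols - 1
    f01: np.ndarray
    f10: np.ndarray


class BlastParseError(ValueError):
    pass


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of intervals; overlapping or bookended spans are merged."""
    if not spans:
        return []
    spans = sorted(spans)
    out = [spans[0]]
    for s, e in spans[1:]:
        ps, pe = out[-1]
        if s <= pe:  # overlap or adjacency -> one maximal run
            out[-1] = (ps, max(pe, e))
        else:
            out.append((s, e))
    return out


def read_blast_tab(path, min_identity: float = 0.0) -> list[AlignmentHit]:
    """Parse 12-column BLAST tabular output (outfmt 6) into alignment hits.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore.  The query is the SD,
    the subject the CNV.  Subject coordinates are 1-based inclusive and
    converted to 0-based half-open; reversed coordinates (sstart > send)
    are normalised with strand '-'.  Records below ``min_identity`` are
    dropped.  An optional 13th column lists matched sub-spans relative
    to the subject span start ("s-e,s-e", 0-based half-open) for strict
    per-base masking.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise BlastParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                sd_id, cnv_id = fields[0], fields[1]
                identity = float(fields[2])
                aln_length = int(fields[3])
                sstart, send = int(fields[8]), int(fields[9])
            except ValueError as exc:
                raise BlastParseError(f"{path}: line {lineno}: {exc}") from exc
            if identity < min_identity:
                continue
            if sstart <= send:
                start, end, strand = sstart - 1, send, "+"
            else:
                start, end, strand = send - 1, sstart, "-"
            match_spans = None
            if len(fields) >= 13 and fields[12]:
                try:
                    match_spans = tuple(
                        (int(a), int(b))
                        for a, b in (tok.split("-") for tok in fields[12].split(","))
                    )
                except ValueError as exc:
                    raise BlastParseError(
                        f"{path}: line {lineno}: bad match-span column"
                    ) from exc
            hits.append(
                AlignmentHit(
                    sd_id=sd_id,
                    cnv_id=cnv_id,
                    cnv_start=start,
                    cnv_end=end,
                    identity=identity,
                    aln_length=aln_length,
                    strand=strand,
                    match_spans=match_spans,
                )
            )
    return hits


def build_matrix(
    hits,
    cnv_id: str,
    cnv_len: int,
    strict: bool = False,
) -> AlignmentMatrix:
    """Assemble the binary alignment matrix of one CNV from its hits.

    One row per distinct SD; all HSPs of an SD are OR-ed together and
    overlapping/adjacent spans merged into maximal 1-runs.  In strict
    mode only the matched sub-spans of hits carrying a match mask are
    set; hits without a mask fall back to the whole span.
    """
    by_sd: dict[str, list[tuple[int, int]]] = {}
    for hit in hits:
        if hit.cnv_id != cnv_id:
            raise ValueError(f"hit targets CNV {hit.cnv_id!r}, expected {cnv_id!r}")
        if hit.cnv_end > cnv_len:
            raise ValueError(
                f"hit {hit.sd_id!r} [{hit.cnv_start}, {hit.cnv_end}) exceeds CNV length {cnv_len}"
            )
        spans: list[tuple[int, int]]
        if strict and hit.match_spans is not None:
            spans = [
                (hit.cnv_start + a, hit.cnv_start + b) for a, b in hit.match_spans
            ]
            for s, e in spans:
                if not (hit.cnv_start <= s < e <= hit.cnv_end):
                    raise ValueError(f"match span ({s}, {e}) outside hit {hit}")
        else:
            spans = [(hit.cnv_start, hit.cnv_end)]
        by_sd.setdefault(hit.sd_id, []).extend(spans)

    mat = AlignmentMatrix(cnv_id=cnv_id, n_cols=cnv_len)
    for sd_id, spans in by_sd.items():
        mat.row_ids.append(sd_id)
        mat.rows.append(_merge_spans(spans))
    mat.validate()
    return mat


def column_stats(matrix: AlignmentMatrix) -> ColumnStats:
    """Column sums and adjacent-column pattern counts f11/f01/f10.

    For each adjacent column pair (j, j+1): f11 counts rows set at both
    positions, f01 rows set only at j+1, f10 rows set only at j.  Both
    are accumulated directly from the run lists; because runs are
    maximal, a row can only cover j and j+1 from within a single run.
    """
    n = matrix.n_cols
    if n < 1:
        raise ValueError("matrix has no columns")
    o = matrix.column_counts()
    f11 = np.zeros(max(n - 1, 0), dtype=np.int64)
    f01 = np.zeros_like(f11)
    f10 = np.zeros_like(f11)
    if n >= 2:
        for runs in matrix.rows:
            for s, e in runs:
                if e - s >= 2:
                    f11[s : e - 1] += 1
                if e <= n - 1:
                    f10[e - 1] += 1
                if s >= 1:
                    f01[s - 1] += 1
    return ColumnStats(o=o, f11=f11, f01=f01, f10=f10)
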