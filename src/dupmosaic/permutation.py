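"""Copy-number permutation test for candidate duplicons.

The copy number of a duplicon is the mean, over its columns, of the
number of SD rows aligned there.  Real duplicons accumulate copies;
alignment noise does not.  The null model relocates every maximal 1-run
within its own row (run-length multiset and per-row mass preserved),
decodes each artificial matrix with the same HMM, and records the
maximum candidate copy number.  A candidate's P value is the fraction
of artificial matrices whose maximum copy number strictly exceeds the
candidate's, and calls with P below alpha (default 0.01, with B = 100
artificial matrices) are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hmm import HmmParams, estimate_P_o, extract_candidates, viterbi
from .matrix import AlignmentMatrix, column_stats

__all__ = [
    "DupliconCall",
    "NullDistribution",
    "copy_number",
    "permute_matrix",
    "null_distribution",
    "p_value",
    "call_duplicons",
    "dedup_calls",
    "dedup_calls_by_sequence",
]


@dataclass(frozen=True)
class DupliconCall:
    cnv_id: str
    start: int
    end: int
    state_label: str
    copy_number: float
    p_value: float
    significant: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NullDistribution:
    max_copy_numbers: np.ndarray
    B: int
    seed: int

    def __post_init__(self) -> None:
        self.max_copy_numbers = np.asarray(self.max_copy_numbers, dtype=float)
        if self.max_copy_numbers.shape != (self.B,):
            raise ValueError("need exactly B recorded maxima")
        if np.any(self.max_copy_numbers < 0):
            raise ValueError("copy numbers cannot be negative")


def copy_number(matrix: AlignmentMatrix, segment: tuple[int, int]) -> float:
    """Mean per-position count of aligned SD rows over the segment."""
    s, e = segment
    if not (0 <= s < e <= matrix.n_cols):
        raise ValueError(f"segment ({s}, {e}) outside [0, {matrix.n_cols})")
    total = 0
    for runs in matrix.rows:
        for rs, re_ in runs:
            if rs >= e:
                break
            ov = min(re_, e) - max(rs, s)
            if ov > 0:
                total += ov
    return total / (e - s)


def _compose_gaps(rng: np.random.Generator, total: int, parts: int) -> np.ndarray:
    """Uniform composition of ``total`` into ``parts`` non-negative parts."""
    if parts == 1:
        return np.array([total], dtype=np.int64)
    if total == 0:
        return np.zeros(parts, dtype=np.int64)
    # stars and bars: choose parts-1 bar positions among total + parts - 1 slots
    bars = np.sort(rng.choice(total + parts - 1, size=parts - 1, replace=False))
    prev = -1
    out = np.empty(parts, dtype=np.int64)
    for i, b in enumerate(bars):
        out[i] = b - prev - 1
        prev = b
    out[parts - 1] = total + parts - 1 - prev - 1
    return out


def permute_matrix(matrix: AlignmentMatrix, rng: np.random.Generator) -> AlignmentMatrix:
    """Randomly relocate every maximal 1-run within its own row.

    Run order is shuffled and zero gaps are redrawn uniformly over all
    layouts that keep the runs separated (internal gaps >= 1, end gaps
    >= 0), so the multiset of maximal run lengths of every row — and
    hence its total number of 1s — is conserved exactly.
    """
    n = matrix.n_cols
    new_rows: list[list[tuple[int, int]]] = []
    for runs in matrix.rows:
        r = len(runs)
        if r == 0:
            new_rows.append([])
            continue
        lengths = np.array([e - s for s, e in runs], dtype=np.int64)
        lengths = lengths[rng.permutation(r)]
        zeros = n - int(lengths.sum())
        free = zeros - (r - 1)  # zeros left after the mandatory separators
        if free < 0:
            raise RuntimeError("runs cannot fit in the row; matrix is inconsistent")
        gaps = _compose_gaps(rng, free, r + 1)
        gaps[1:r] += 1  # separators between runs
        new_runs: list[tuple[int, int]] = []
        cursor = 0
        for g, ln in zip(gaps[:r], lengths):
            cursor += int(g)
            new_runs.append((cursor, cursor + int(ln)))
            cursor += int(ln)
        new_rows.append(new_runs)
    return AlignmentMatrix(
        cnv_id=matrix.cnv_id,
        n_cols=n,
        row_ids=list(matrix.row_ids),
        rows=new_rows,
    )


def null_distribution(
    matrix: AlignmentMatrix,
    params: HmmParams,
    B: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Decode B artificial matrices and record each one's maximum copy number.

    Artificial matrices with no candidate duplicons contribute 0.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    maxima = np.zeros(B, dtype=float)
    for b in range(B):
        art = permute_matrix(matrix, rng)
        stats = column_stats(art)
        path = viterbi(art, stats, params)
        cands = extract_candidates(path, params.min_len)
        if cands:
            maxima[b] = max(copy_number(art, (c.start, c.end)) for c in cands)
    return NullDistribution(max_copy_numbers=maxima, B=B, seed=seed)


def p_value(observed_cn: float, null: NullDistribution) -> float:
    """Fraction of artificial maxima strictly exceeding the observed copy number."""
    if null.B < 1:
        raise ValueError("empty null distribution")
    return float(np.count_nonzero(null.max_copy_numbers > observed_cn)) / null.B


def call_duplicons(
    matrix: AlignmentMatrix,
    params: HmmParams | None = None,
    alpha: float = 0.01,
    B: int = 100,
    seed: int = 0,
) -> list[DupliconCall]:
    """Full single-matrix pipeline: decode, test, filter, deduplicate.

    One null distribution is built per matrix and shared by all of its
    candidates.  Calls with P value below ``alpha`` are significant;
    only significant calls are returned, after merging near-identical
    ones (reciprocal overlap >= 95%, keeping the lower P value).

    When ``params`` is omitted, P_o is estimated from the matrix's own
    1-density (see :func:`dupmosaic.hmm.estimate_P_o`); the same value
    applies to the artificial matrices, whose density is identical by
    construction.
    """
    if params is None:
        params = HmmParams(P_o=estimate_P_o(matrix))
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    stats = column_stats(matrix)
    path = viterbi(matrix, stats, params)
    candidates = extract_candidates(path, params.min_len)
    if not candidates:
        return []
    null = null_distribution(matrix, params, B=B, seed=seed)
    calls: list[DupliconCall] = []
    for cand in candidates:
        cn = copy_number(matrix, (cand.start, cand.end))
        p = p_value(cn, null)
        # alpha = 1.0 is the vacuous filter: every candidate is retained
        sig = p < alpha or alpha >= 1.0
        if sig:
            calls.append(
                DupliconCall(
                    cnv_id=cand.cnv_id,
                    start=cand.start,
                    end=cand.end,
                    state_label=cand.state_label,
                    copy_number=cn,
                    p_value=p,
                    significant=True,
                )
            )
    return dedup_calls(calls)


def _reciprocal_overlap(a: DupliconCall, b: DupliconCall) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def dedup_calls(calls, reciprocal: float = 0.95) -> list[DupliconCall]:
    """Remove near-identical calls on the same CNV.

    Calls with reciprocal overlap >= ``reciprocal`` are considered the
    same duplicon; the one with the lower P value (ties: longer, then
    leftmost) is kept.
    """
    kept: list[DupliconCall] = []
    for call in sorted(calls, key=lambda c: (c.p_value, -c.length, c.cnv_id, c.start)):
        dup = any(
            k.cnv_id == call.cnv_id and _reciprocal_overlap(k, call) >= reciprocal
            for k in kept
        )
        if not dup:
            kept.append(call)
    kept.sort(key=lambda c: (c.cnv_id, c.start))
    return kept


def dedup_calls_by_sequence(
    calls,
    sequences: dict[str, str],
    min_identity: float = 95.0,
    min_len: int = 100,
) -> list[DupliconCall]:
    """Sequence-based deduplication across CNVs.

    Calls whose underlying sequences match at >= ``min_identity``
    percent over >= ``min_len`` bp collapse to the one with the lower
    P value.  Requires the CNV sequences; identity is estimated from
    edit distance of the two call subsequences.
    """
    import edlib

    def identity(a: str, b: str) -> float:
        if not a or not b:
            return 0.0
        d = edlib.align(a, b, task="distance")["editDistance"]
        return 100.0 * (1.0 - d / max(len(a), len(b)))

    kept: list[DupliconCall] = []
    for call in sorted(calls, key=lambda c: (c.p_value, -c.length, c.cnv_id, c.start)):
        seq = sequences[call.cnv_id][call.start : call.end]
        dup = False
        for k in kept:
            if min(call.length, k.length) < min_len:
                continue
            kseq = sequences[k.cnv_id][k.start : k.end]
            if identity(seq, kseq) >= min_identity:
                dup = True
                break
        if not dup:
            kept.append(call)
    kept.sort(key=lambda c: (c.cnv_id, c.start))
    return kept
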