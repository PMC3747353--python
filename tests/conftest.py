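"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: dense
matrices instead of run lists, exhaustive path enumeration instead of
dynamic programming, term-by-term summation instead of a CDF call.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from dupmosaic.hmm import HmmParams, emission_prob, transition_row
from dupmosaic.matrix import AlignmentMatrix, _merge_spans


def random_runlist_matrix(
    rng: np.random.Generator,
    m: int,
    n: int,
    density: float = 0.3,
    mean_run: float = 4.0,
    cnv_id: str = "cnv_t",
) -> AlignmentMatrix:
    """Random run-list matrix: per row, geometric runs until ~density filled."""
    rows, row_ids = [], []
    for i in range(m):
        spans = []
        budget = int(density * n)
        while budget > 0:
            ln = min(int(rng.geometric(1.0 / mean_run)), n)
            start = int(rng.integers(0, n - ln + 1))
            spans.append((start, start + ln))
            budget -= ln
        rows.append(_merge_spans(spans))
        row_ids.append(f"r{i}")
    mat = AlignmentMatrix(cnv_id=cnv_id, n_cols=n, row_ids=row_ids, rows=rows)
    mat.validate()
    return mat


def dense_column_stats(dense: np.ndarray):
    """Brute-force o / f11 / f01 / f10 from a dense 0/1 matrix."""
    m, n = dense.shape
    o = dense.sum(axis=0)
    f11 = np.zeros(n - 1, dtype=int)
    f01 = np.zeros(n - 1, dtype=int)
    f10 = np.zeros(n - 1, dtype=int)
    for j in range(n - 1):
        a, b = dense[:, j], dense[:, j + 1]
        f11[j] = int(np.sum((a == 1) & (b == 1)))
        f01[j] = int(np.sum((a == 0) & (b == 1)))
        f10[j] = int(np.sum((a == 1) & (b == 0)))
    return o, f11, f01, f10


def exhaustive_viterbi_logscore(matrix: AlignmentMatrix, params: HmmParams) -> float:
    """Maximum path log-probability by enumerating all 3^n state paths.

    Uses the same model definition as the decoder: initial distribution
    (1/2, 0, 1/2) over (D1, D2, N), pattern-count transitions between
    each adjacent column pair, uniform 1/3 transitions out of N,
    cumulative-binomial emissions, and the probability floor applied to
    every transition/emission probability (the zero prior of D2 stays
    a hard -inf).
    """
    from dupmosaic.matrix import column_stats

    n, m = matrix.n_cols, matrix.m
    floor = params.prob_floor
    stats = column_stats(matrix)

    def lg(x: float) -> float:
        return math.log(max(x, floor))

    log_pi = [math.log(0.5), float("-inf"), math.log(0.5)]
    em = []
    for j in range(n):
        pd = emission_prob(int(stats.o[j]), m, params.P_o)
        em.append([lg(pd), lg(pd), lg(1.0 - pd)])
    trans = []
    third = math.log(1.0 / 3.0)
    for j in range(n - 1):
        row = transition_row(int(stats.f11[j]), int(stats.f01[j]), int(stats.f10[j]), params.p)
        t = [
            [lg(row.stay), lg(row.switch), lg(row.to_non)],
            [lg(row.switch), lg(row.stay), lg(row.to_non)],
            [third, third, third],
        ]
        trans.append(t)

    best = float("-inf")
    for path in itertools.product(range(3), repeat=n):
        score = log_pi[path[0]] + em[0][path[0]]
        for j in range(1, n):
            score += trans[j - 1][path[j - 1]][path[j]] + em[j][path[j]]
        if score > best:
            best = score
    return best


def binom_cdf_by_summation(k: int, m: int, p: float) -> float:
    return sum(math.comb(m, i) * p**i * (1.0 - p) ** (m - i) for i in range(k + 1))


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random binary tree as (newick string, leaf names).

    Branch lengths are uniform in [0.5, 2.0], so all tip-to-tip
    distances satisfy the four-point condition exactly and neighbor
    joining must reconstruct the tree.
    """
    frags = [f"L{i}" for i in range(n_leaves)]
    while len(frags) > 2:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        a, b = frags[i], frags[j]
        la, lb = rng.uniform(0.5, 2.0, size=2)
        joined = f"({a}:{la:.6f},{b}:{lb:.6f})"
        frags = [f for idx, f in enumerate(frags) if idx not in (i, j)] + [joined]
    la, lb = rng.uniform(0.5, 2.0, size=2)
    newick = f"({frags[0]}:{la:.6f},{frags[1]}:{lb:.6f});"
    return newick, [f"L{i}" for i in range(n_leaves)]


@pytest.fixture
def rng():
    return np.random.default_rng(20250917)
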