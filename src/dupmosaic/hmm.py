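"""Three-state non-homogeneous HMM for decoding duplicons.

States are two duplicon states D1/D2 (two, so that adjacent duplicons
can be distinguished) and a nonduplicon state N.  The chain is
non-homogeneous: the transition matrix used between columns j and j+1
is rebuilt from the 0/1 pattern counts of that column pair, so runs of
co-aligned SDs pull the path into a duplicon state while their
boundaries push it out.

Model summary, for an alignment matrix with m rows and column sums o:

* self-transition base probability ``p = 1 - 1/L`` where L is the mean
  length of known duplicons (geometric length prior with mean L);
* per column pair, with pattern counts f11/f01/f10,
  ``omega = f11 / (f11 + f01 + f10)`` and ``gamma = f01 / (f01 + f10)``;
  a duplicon state stays with probability ``p*omega``, switches to the
  other duplicon state with ``(1 - p*omega)*gamma`` and leaves to N
  with ``(1 - p*omega)*(1 - gamma)``;
* N transitions to each state with probability 1/3;
* a duplicon state emits the cumulative binomial probability
  ``P_d = BinomCDF(o_j; m, P_o)`` of seeing at most o_j of m SDs align
  by chance, N emits ``1 - P_d``;
* the initial distribution puts 1/2 on D1 and 1/2 on N (D2 is only
  reachable by switching).

The maximum-probability path is decoded with the Viterbi algorithm in
log space, and maximal duplicon-state runs of at least ``min_len``
columns (default 100) become candidate duplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from .matrix import AlignmentMatrix, ColumnStats

__all__ = [
    "D1",
    "D2",
    "N",
    "HmmParams",
    "TransitionRow",
    "StatePath",
    "CandidateDuplicon",
    "transition_row",
    "emission_prob",
    "estimate_P_o",
    "viterbi",
    "extract_candidates",
]

D1, D2, N = "D1", "D2", "N"
_STATES = (D1, D2, N)
_LOG_THIRD = float(np.log(1.0 / 3.0))


@dataclass
class HmmParams:
    """HMM constants.

    Parameters
    ----------
    L : float
        Mean length (bp) of known duplicons; sets the self-transition
        base probability ``p = 1 - 1/L``.  Default 4651, the mean
        length of duplicons in the published duplicon library.
    P_o : float
        Probability that a given SD carries a given duplicon (the
        average duplicon copy number over the number of SDs in the
        library).  Library-dependent; default 0.05.
    min_len : int
        Minimum duplicon run length in columns, default 100.
    prob_floor : float
        Positive floor applied to transition/emission probabilities
        before taking logs, so structurally-zero evidence does not
        produce NaNs.  The initial probability of D2 is a true zero.
    """

    L: float = 4651.0
    P_o: float = 0.05
    min_len: int = 100
    prob_floor: float = 1e-300

    def __post_init__(self) -> None:
        if self.L <= 1:
            raise ValueError("L must exceed 1")
        if not 0.0 < self.P_o < 1.0:
            raise ValueError("P_o must lie in (0, 1)")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not 0.0 < self.prob_floor < 1.0:
            raise ValueError("prob_floor must lie in (0, 1)")

    @property
    def p(self) -> float:
        """Self-transition base probability, recomputed from L."""
        return 1.0 - 1.0 / self.L


@dataclass(frozen=True)
class TransitionRow:
    """Outgoing transition probabilities of a duplicon state."""

    omega: float
    gamma: float
    stay: float
    switch: float
    to_non: float


@dataclass
class StatePath:
    cnv_id: str
    states: list[str]
    log_score: float


@dataclass(frozen=True)
class CandidateDuplicon:
    cnv_id: str
    start: int
    end: int
    state_label: str

    @property
    def length(self) -> int:
        return self.end - self.start


def transition_row(f11: int, f01: int, f10: int, p: float) -> TransitionRow:
    """Duplicon-state transition probabilities from one column pair.

    Degenerate denominators: with no pattern evidence at all
    (f11 = f01 = f10 = 0) omega is 0; with no switch evidence
    (f01 = f10 = 0) gamma is 0, sending all non-stay mass to N.
    """
    if min(f11, f01, f10) < 0:
        raise ValueError("pattern counts must be non-negative")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    tot = f11 + f01 + f10
    omega = f11 / tot if tot > 0 else 0.0
    sw = f01 + f10
    gamma = f01 / sw if sw > 0 else 0.0
    stay = p * omega
    switch = (1.0 - stay) * gamma
    to_non = (1.0 - stay) * (1.0 - gamma)
    return TransitionRow(omega=omega, gamma=gamma, stay=stay, switch=switch, to_non=to_non)


def emission_prob(k: int, m: int, P_o: float) -> float:
    """Duplicon-state emission: cumulative binomial P_d = CDF(k; m, P_o).

    The nonduplicon state emits 1 - P_d.  Computed with the regularised
    incomplete beta function, stable for m up to at least 1e5.
    """
    if k < 0 or m < 0 or k > m:
        raise ValueError(f"need 0 <= k <= m, got k={k}, m={m}")
    return float(binom.cdf(k, m, P_o))


def estimate_P_o(matrix: AlignmentMatrix, default: float = 0.05) -> float:
    """Estimate the per-SD duplicon-occurrence probability from a matrix.

    P_o is defined from library statistics (mean duplicon copy number
    over the number of catalogued SDs), which amounts to the chance
    that a given SD covers a given duplicon position.  When the library
    constants are unavailable it is estimated as the matrix's overall
    1-density — the empirical probability that a given SD row covers a
    given column.  The estimate is floored at ``1 - 0.5**(1/m)`` so an
    empty column never favours a duplicon state (BinomCDF(0; m, P_o)
    stays <= 1/2), and capped at 0.99.  A matrix with no rows returns
    ``default``.
    """
    if matrix.m == 0:
        return default
    density = float(matrix.column_counts().sum()) / (matrix.m * matrix.n_cols)
    lo = 1.0 - 0.5 ** (1.0 / matrix.m)
    return min(max(density, lo), 0.99)


def _column_log_emissions(
    o: np.ndarray, m: int, P_o: float, floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """(log P_d, log (1-P_d)) per column, floor-clamped."""
    uniq, inv = np.unique(o, return_inverse=True)
    cdf = binom.cdf(uniq, m, P_o)
    log_pd = np.log(np.maximum(cdf, floor))[inv]
    log_qd = np.log(np.maximum(1.0 - cdf, floor))[inv]
    return log_pd, log_qd


def viterbi(matrix: AlignmentMatrix, stats: ColumnStats, params: HmmParams) -> StatePath:
    """Decode the maximum-probability state path over the matrix columns.

    Ties are broken deterministically, preferring N over D1 over D2 at
    every choice point (conservative: ambiguity never creates a
    duplicon).  A matrix with no rows carries no alignment evidence and
    decodes to the all-N path.
    """
    n = matrix.n_cols
    if n < 1:
        raise ValueError("matrix has no columns")
    floor = params.prob_floor
    log_floor = float(np.log(floor))

    if matrix.m == 0:
        # no SDs: no evidence of duplication anywhere
        score = n * log_floor  # N emits 1 - P_d = 0 when P_d = 1
        return StatePath(cnv_id=matrix.cnv_id, states=[N] * n, log_score=score)

    log_pd, log_qd = _column_log_emissions(stats.o, matrix.m, params.P_o, floor)

    # per column pair: log stay / switch / to-N for duplicon states
    if n >= 2:
        f11 = stats.f11.astype(float)
        f01 = stats.f01.astype(float)
        f10 = stats.f10.astype(float)
        tot = f11 + f01 + f10
        omega = np.divide(f11, tot, out=np.zeros_like(tot), where=tot > 0)
        sw = f01 + f10
        gamma = np.divide(f01, sw, out=np.zeros_like(sw), where=sw > 0)
        stay = params.p * omega
        switch = (1.0 - stay) * gamma
        to_non = (1.0 - stay) * (1.0 - gamma)
        l_stay = np.log(np.maximum(stay, floor))
        l_switch = np.log(np.maximum(switch, floor))
        l_tonon = np.log(np.maximum(to_non, floor))

    neg_inf = float("-inf")
    log_half = float(np.log(0.5))
    # scores for (D1, D2, N); python floats in the hot loop
    s_d1 = log_half + float(log_pd[0])
    s_d2 = neg_inf  # D2 has zero initial probability
    s_n = log_half + float(log_qd[0])

    back: list[tuple[int, int, int]] = []
    for j in range(1, n):
        ls, lw, lt = float(l_stay[j - 1]), float(l_switch[j - 1]), float(l_tonon[j - 1])
        # candidate predecessors evaluated in preference order N, D1, D2
        # (strict > keeps the earlier, preferred, predecessor on ties)
        c_n, c_1, c_2 = s_n + _LOG_THIRD, s_d1 + ls, s_d2 + lw
        b1, v1 = 2, c_n
        if c_1 > v1:
            b1, v1 = 0, c_1
        if c_2 > v1:
            b1, v1 = 1, c_2

        c_n, c_1, c_2 = s_n + _LOG_THIRD, s_d1 + lw, s_d2 + ls
        b2, v2 = 2, c_n
        if c_1 > v2:
            b2, v2 = 0, c_1
        if c_2 > v2:
            b2, v2 = 1, c_2

        c_n, c_1, c_2 = s_n + _LOG_THIRD, s_d1 + lt, s_d2 + lt
        bn, vn = 2, c_n
        if c_1 > vn:
            bn, vn = 0, c_1
        if c_2 > vn:
            bn, vn = 1, c_2

        lp, lq = float(log_pd[j]), float(log_qd[j])
        s_d1, s_d2, s_n = v1 + lp, v2 + lp, vn + lq
        back.append((b1, b2, bn))

    # final state, same preference order
    last, best = 2, s_n
    if s_d1 > best:
        last, best = 0, s_d1
    if s_d2 > best:
        last, best = 1, s_d2

    idx_path = [last]
    for ptrs in reversed(back):
        last = ptrs[last]
        idx_path.append(last)
    idx_path.reverse()
    states = [_STATES[i] for i in idx_path]
    return StatePath(cnv_id=matrix.cnv_id, states=states, log_score=best)


def extract_candidates(path: StatePath, min_len: int = 100) -> list[CandidateDuplicon]:
    """Maximal runs of one duplicon label with length >= min_len.

    Adjacent runs with different duplicon labels are distinct
    candidates (that is what the second duplicon state is for).
    """
    out: list[CandidateDuplicon] = []
    states = path.states
    n = len(states)
    j = 0
    while j < n:
        lab = states[j]
        if lab == N:
            j += 1
            continue
        k = j + 1
        while k < n and states[k] == lab:
            k += 1
        if k - j >= min_len:
            out.append(CandidateDuplicon(cnv_id=path.cnv_id, start=j, end=k, state_label=lab))
        j = k
    return out
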