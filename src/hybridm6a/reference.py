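"""Independent brute-force reference implementations.

These routines re-derive, by direct enumeration or first-principles dynamic
programming, quantities that the main modules compute by faster or delegated
routes.  They exist for validation: the test suite and the acceptance script
compare the production code against them on small instances.  They share no
code with the implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from .homology import AlignParams
from .structure import PAIR_ENERGY, MIN_HAIRPIN

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# affine-gap alignment score (Gotoh recurrence written from the definition)

def affine_alignment_score(seq_a: str, seq_b: str, params: AlignParams) -> float:
    """Optimal affine-gap alignment score.

    Gap of length L costs ``gap_open + L * gap_extend`` (EMBOSS convention).
    Local mode returns 0 when no positive-scoring alignment exists.
    """
    m, n = len(seq_a), len(seq_b)
    local = params.mode == "local"
    go = params.gap_open + params.gap_extend  # first gap column
    ge = params.gap_extend

    M = np.full((m + 1, n + 1), NEG_INF)   # ends in a match/mismatch
    Ia = np.full((m + 1, n + 1), NEG_INF)  # ends in a gap in A (consumes B)
    Ib = np.full((m + 1, n + 1), NEG_INF)  # ends in a gap in B (consumes A)
    M[0, 0] = 0.0
    if not local:
        for j in range(1, n + 1):
            Ia[0, j] = -go - ge * (j - 1)
        for i in range(1, m + 1):
            Ib[i, 0] = -go - ge * (i - 1)

    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = params.match if seq_a[i - 1] == seq_b[j - 1] else params.mismatch
            prev = max(M[i - 1, j - 1], Ia[i - 1, j - 1], Ib[i - 1, j - 1])
            if local:
                prev = max(prev, 0.0)
            M[i, j] = prev + s
            Ia[i, j] = max(M[i, j - 1] - go, Ia[i, j - 1] - ge,
                           Ib[i, j - 1] - go)
            Ib[i, j] = max(M[i - 1, j] - go, Ib[i - 1, j] - ge,
                           Ia[i - 1, j] - go)
            if local:
                best = max(best, M[i, j])
    if local:
        return float(best)
    if m == 0 and n == 0:
        return 0.0
    return float(max(M[m, n], Ia[m, n], Ib[m, n]))


def enumerate_global_alignment_score(seq_a: str, seq_b: str,
                                     params: AlignParams) -> float:
    """Plain recursive enumeration over every global alignment path.

    Exponential; only for tiny sequences.  Used to validate
    :func:`affine_alignment_score` itself.
    """
    go, ge = params.gap_open + params.gap_extend, params.gap_extend

    def rec(i, j, last):
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        best = NEG_INF
        if i < len(seq_a) and j < len(seq_b):
            s = params.match if seq_a[i] == seq_b[j] else params.mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(seq_a):
            cost = ge if last == "B" else go
            best = max(best, -cost + rec(i + 1, j, "B"))
        if j < len(seq_b):
            cost = ge if last == "A" else go
            best = max(best, -cost + rec(i, j + 1, "A"))
        return best

    return rec(0, 0, "M")


# ---------------------------------------------------------------------------
# exhaustive RNA secondary structure enumeration

def _pairable(x: str, y: str) -> bool:
    return (x + y) in PAIR_ENERGY


def enumerate_structures(seq: str):
    """Yield every valid pair set (frozenset of (i, j)) for the simplified
    energy model: complementary GC/AU/GU pairs, non-crossing, hairpin loops
    of at least MIN_HAIRPIN unpaired bases, no lone (unstacked) pairs."""
    n = len(seq)

    def gen(i, j):
        # all pair sets over seq[i..j], constraints checked later
        if i >= j:
            yield frozenset()
            return
        for rest in gen(i + 1, j):
            yield rest
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if not _pairable(seq[i], seq[k]):
                continue
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    yield frozenset({(i, k)}) | inner | outer

    for struct in gen(0, n - 1):
        if _valid(struct):
            yield struct


def _valid(struct: frozenset) -> bool:
    pairs = set(struct)
    for (i, j) in pairs:
        inside = any(i < a and b < j for a, b in pairs if (a, b) != (i, j))
        if not inside and j - i - 1 < MIN_HAIRPIN:
            return False
        if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs:
            return False
    return True


def structure_energy(seq: str, struct: frozenset) -> float:
    return sum(PAIR_ENERGY[seq[i] + seq[j]] for i, j in struct)


def brute_force_mfe(seq: str) -> float:
    """Minimum energy over all enumerated structures (0 for the empty one)."""
    best = 0.0
    for struct in enumerate_structures(seq):
        e = structure_energy(seq, struct)
        if e < best:
            best = e
    return best


# ---------------------------------------------------------------------------
# run-length window detection oracle

def brute_force_windows(profile, threshold: float, min_len: int):
    """Maximal runs with profile > threshold at every position and run length
    strictly greater than min_len, found by direct scanning."""
    out = []
    n = len(profile)
    i = 0
    while i < n:
        if profile[i] > threshold:
            j = i
            while j < n and profile[j] > threshold:
                j += 1
            if j - i > min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# fragment pileup oracle

def brute_force_pileup(fragments, length: int) -> np.ndarray:
    """Per-base coverage by counting, for every base, the fragments that
    span it."""
    cov = np.zeros(length, dtype=np.int64)
    for start, end in fragments:
        for x in range(max(0, start), min(length, end)):
            cov[x] += 1
    return cov
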