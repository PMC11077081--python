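"""Independent brute-force oracles used only by the test suite.

The split-call oracle enumerates gapless segment pairs with a plain 2-D
dynamic program over (read position, reference position) — no diagonals, no
seeding, no vectorisation — and applies the same junction semantics (maximal
microhomology extension, larger-MH / smaller-insertion / smallest-d_end tie
break) from scratch.  The Fisher oracle enumerates hypergeometric tables
with exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

MATCH = 1
MISMATCH = 3


def _end_scores(read: str, ref: str) -> list[list[int]]:
    """E[j][p]: best gapless segment score ending exactly at (read j, ref p)."""
    L, R = len(read), len(ref)
    E = [[0] * R for _ in range(L)]
    for j in range(L):
        for p in range(R):
            s = MATCH if read[j] == ref[p] else -MISMATCH
            prev = E[j - 1][p - 1] if j > 0 and p > 0 else 0
            E[j][p] = max(prev, 0) + s
    return E


def _start_scores(read: str, ref: str) -> list[list[int]]:
    """S[i][q]: best gapless segment score starting exactly at (read i, ref q)."""
    L, R = len(read), len(ref)
    S = [[0] * R for _ in range(L)]
    for i in range(L - 1, -1, -1):
        for q in range(R - 1, -1, -1):
            s = MATCH if read[i] == ref[q] else -MISMATCH
            nxt = S[i + 1][q + 1] if i + 1 < L and q + 1 < R else 0
            S[i][q] = max(nxt, 0) + s
    return S


def oracle_call(read: str, donor: str, acceptor: str):
    """Exhaustive score-maximal split with junction post-processing.

    Returns (status, mh_length, insertion_seq); status is "called",
    "unalignable" (no positive two-sided split) or "ambiguous".
    """
    L = len(read)
    E = _end_scores(read, donor)
    S = _start_scores(read, acceptor)
    F = [max(row) if row else -(10**9) for row in E]
    G = [max(row) if row else -(10**9) for row in S]

    best = None
    for c in range(L + 1):
        f = max(F[:c]) if c > 0 else -(10**9)
        g = max(G[c:]) if c < L else -(10**9)
        if f <= 0 or g <= 0:
            continue
        if best is None or f + g > best:
            best = f + g
    if best is None:
        return "unalignable", 0, ""

    candidates = {}
    for c in range(L + 1):
        f = max(F[:c]) if c > 0 else -(10**9)
        g = max(G[c:]) if c < L else -(10**9)
        if f <= 0 or g <= 0 or f + g != best:
            continue
        for j1 in range(c):
            if F[j1] != f:
                continue
            for i2 in range(c, L):
                if G[i2] != g:
                    continue
                for p in range(len(donor)):
                    if E[j1][p] != f:
                        continue
                    for q in range(len(acceptor)):
                        if S[i2][q] != g:
                            continue
                        cand = _postprocess(read, donor, acceptor, j1, i2, p, q)
                        candidates[cand] = True
    cands = list(candidates)
    best_mh = max(mh for mh, _, _ in cands)
    pool = [c for c in cands if c[0] == best_mh]
    min_ins = min(len(ins) for _, ins, _ in pool)
    pool = [c for c in pool if len(c[1]) == min_ins]
    if len({ins for _, ins, _ in pool}) > 1:
        return "ambiguous", best_mh, ""
    mh, ins, _ = min(pool, key=lambda c: c[2])
    return "called", mh, ins


def _postprocess(read, donor, acceptor, j1, i2, p, q):
    """(mh, insertion, d_end) for one optimal (donor end, acceptor start)."""
    if i2 != j1 + 1:
        return 0, read[j1 + 1 : i2], j1 + 1
    cl = 0
    while (
        j1 - cl >= 0
        and p - cl >= 0
        and q - 1 - cl >= 0
        and read[j1 - cl] == donor[p - cl] == acceptor[q - 1 - cl]
    ):
        cl += 1
    cr = 0
    while (
        i2 + cr < len(read)
        and p + 1 + cr < len(donor)
        and q + cr < len(acceptor)
        and read[i2 + cr] == donor[p + 1 + cr] == acceptor[q + cr]
    ):
        cr += 1
    return cl + cr, "", j1 + cr + 1


def random_instance(rng):
    """A small random donor/acceptor/read triple with a planted junction.

    References are 30-60 nt, reads at most ~90 nt: blunt joins, insertions of
    1-8 nt, and noisy variants are all produced so the comparison exercises
    every call type.
    """
    import numpy as np

    bases = np.array(list("ACGT"))

    def seq(n):
        return "".join(bases[rng.integers(0, 4, n)])

    donor = seq(int(rng.integers(30, 61)))
    acceptor = seq(int(rng.integers(30, 61)))
    kind = rng.integers(0, 4)
    e = int(rng.integers(10, len(donor) - 5))
    a0 = int(rng.integers(5, len(acceptor) - 10))
    ins = seq(int(rng.integers(1, 9))) if kind == 2 else ""
    read = donor[max(0, e - 40) : e] + ins + acceptor[a0 : a0 + 40]
    if kind == 3:  # sprinkle substitution noise
        r = list(read)
        for _ in range(int(rng.integers(1, 4))):
            pos = int(rng.integers(0, len(r)))
            r[pos] = "ACGT"[int(rng.integers(0, 4))]
        read = "".join(r)
    return donor, acceptor, read


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher p by exhaustive enumeration in exact rationals."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, r1)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    probs = {
        k: Fraction(comb(c1, k) * comb(n - c1, r1 - k), denom)
        for k in range(lo, hi + 1)
    }
    obs = probs[a]
    return float(sum(p for p in probs.values() if p <= obs))
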