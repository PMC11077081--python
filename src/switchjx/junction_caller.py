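"""Split alignment of switch-junction reads against donor and acceptor.

A recombined CSR junction read is a donor-reference prefix joined to an
acceptor-reference suffix, optionally separated by inserted bases.  The caller
finds the pair of non-overlapping gapless local alignments (donor segment
before acceptor segment in read coordinates) that maximises the summed
alignment score, then resolves the junction by maximal microhomology
extension: the MH tract is the run of read bases around the breakpoint that
match *both* references exactly, which uniquely determines the last donor
base, the first acceptor base, the MH length and any insertion.

Scoring is match +1 / mismatch −3, gapless (Sanger junction PCR products are
contiguous donor/acceptor blocks, so gaps buy nothing).  The optimum is found
exactly: per diagonal, the best-scoring segment ending at every read position
is obtained from cumulative sums (Kadane's recurrence in closed form), and
the best split is the best donor-segment-end / acceptor-segment-start
combination.  By default only diagonals supported by an exact k-mer seed
(k = 12) are scanned, which is lossless for any anchor that passes the
identity threshold in practice; ``seed_k=None`` scans every diagonal and is
used by the exhaustive-oracle tests.

Ties on score are resolved conservatively: prefer the larger microhomology,
then the smaller insertion, then the smallest donor end; if the surviving
optima still disagree on the junction content the read is flagged
``ambiguous`` rather than silently resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import SwitchReference, _revcomp

__all__ = [
    "CallerOpts",
    "JunctionCall",
    "score_split",
    "call_junction",
    "call_cohort",
    "CALL_COLUMNS",
]

_SENTINEL = 255


@dataclass(frozen=True)
class CallerOpts:
    """Tunable parameters of the junction caller."""

    match: int = 1
    mismatch: int = 3
    min_anchor: int = 20
    min_identity: float = 0.9
    seed_k: int | None = 12
    try_reverse_complement: bool = True
    max_candidates: int = 64


@dataclass(frozen=True)
class JunctionCall:
    """Split-alignment result for one read.

    Coordinates are 1-based inclusive.  Exactly one of the following holds
    for a called junction: ``a_start == d_end + 1`` with ``mh_length == 0``
    and no insertion (blunt); ``a_start <= d_end`` with
    ``mh_length == d_end - a_start + 1`` (microhomology); or
    ``a_start > d_end + 1`` with ``insertion_seq == read[d_end+1..a_start-1]``
    (insertion).  ``donor_break``/``acceptor_break`` are the reference
    coordinates of the last donor base used and of the first acceptor base
    not shared with the donor — directly comparable with generator truth.
    """

    read_id: str
    status: str  # "called" | "unalignable" | "ambiguous"
    orientation: str = "+"
    donor_align: tuple[int, int, int, int, int] | None = None
    acceptor_align: tuple[int, int, int, int, int] | None = None
    d_end: int = 0
    a_start: int = 0
    mh_length: int = 0
    insertion_seq: str = ""
    donor_break: int = 0
    acceptor_break: int = 0
    total_score: int = 0


def _encode_read(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[bad] = 0  # never equals a reference base: non-ACGT scores as mismatch
    return arr


def _encode_ref(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    bad = ~np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    arr[bad] = _SENTINEL
    return arr


def score_split(
    read: str,
    donor: str | SwitchReference,
    acceptor: str | SwitchReference,
    d_cut: int,
    a_cut: int,
    b: int,
    match: int = 1,
    mismatch: int = 3,
) -> int:
    """Score a candidate split: read[1..b] on donor ending at ``d_cut`` plus
    read[b+1..L] on acceptor starting at ``a_cut`` (all 1-based), gapless.

    Empty segments contribute 0 (empty-sum convention).
    """
    dseq = donor.sequence if isinstance(donor, SwitchReference) else donor
    aseq = acceptor.sequence if isinstance(acceptor, SwitchReference) else acceptor
    L = len(read)
    if not (0 <= b <= L):
        raise ValueError(f"breakpoint b={b} outside read of length {L}")
    score = 0
    if b > 0:
        if d_cut - b < 0 or d_cut > len(dseq):
            raise ValueError("donor prefix alignment out of reference bounds")
        ref = dseq[d_cut - b : d_cut]
        score += sum(
            match if r == q else -mismatch for r, q in zip(read[:b], ref)
        )
    if b < L:
        n = L - b
        if a_cut < 1 or a_cut - 1 + n > len(aseq):
            raise ValueError("acceptor suffix alignment out of reference bounds")
        ref = aseq[a_cut - 1 : a_cut - 1 + n]
        score += sum(
            match if r == q else -mismatch for r, q in zip(read[b:], ref)
        )
    return score


class _RefIndex:
    """Exact k-mer index of one reference strand for diagonal seeding."""

    def __init__(self, seq: str, k: int):
        self.k = k
        self.kmers: dict[str, list[int]] = {}
        for p in range(len(seq) - k + 1):
            self.kmers.setdefault(seq[p : p + k], []).append(p)

    def diagonals(self, read: str) -> np.ndarray:
        offs: set[int] = set()
        k = self.k
        for j in range(len(read) - k + 1):
            hits = self.kmers.get(read[j : j + k])
            if hits:
                for p in hits:
                    offs.add(p - j)
        return np.array(sorted(offs), dtype=np.int64)


def _segment_scores(
    read: np.ndarray,
    ref: np.ndarray,
    offsets: np.ndarray,
    match: int,
    mismatch: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Best gapless segment score ending at each read position.

    For each diagonal offset o, read position j aligns ref position j + o.
    Returns (K, F, csum): K[d, j] is the best segment score ending exactly at
    j on diagonal d (huge negative where no valid segment ends), F[j] the max
    over diagonals, csum the per-diagonal cumulative score used to recover
    segment starts.
    """
    L = len(read)
    R = len(ref)
    if offsets.size == 0 or L == 0:
        neg = np.full((max(offsets.size, 1), max(L, 1)), -(10**9), dtype=np.int64)
        return neg, np.full(max(L, 1), -(10**9), dtype=np.int64), neg
    padded = np.full(R + 2 * L, _SENTINEL + 1, dtype=np.int16)
    padded[L : L + R] = ref
    # row d: padded[offsets[d] + L + j] for j in 0..L-1
    idx = (offsets[:, None] + L) + np.arange(L)[None, :]
    win = padded[idx]
    S = np.where(win == read[None, :], match, -mismatch).astype(np.int64)
    invalid = win > _SENTINEL  # outside the reference
    S[invalid] = -(10**9)
    csum = np.cumsum(S, axis=1)
    floor = np.minimum.accumulate(
        np.concatenate(
            [np.zeros((S.shape[0], 1), dtype=np.int64), csum[:, :-1]], axis=1
        ),
        axis=1,
    )
    floor = np.minimum(floor, 0)
    K = csum - floor
    F = K.max(axis=0)
    return K, F, csum


def _segment_start(csum_row: np.ndarray, j: int) -> int:
    """Start index of the best segment ending at j on one diagonal."""
    if j == 0:
        return 0
    prefix = csum_row[:j]
    m = prefix.min()
    if m >= 0:
        return 0
    return int(np.argmin(prefix)) + 1


@dataclass(frozen=True)
class _Candidate:
    mh: int
    ins: str
    d_end0: int  # 0-based read index of last donor base
    a_start0: int  # 0-based read index of first acceptor base
    j1: int
    i2: int
    o_d: int  # donor diagonal offset (ref = read + o_d)
    q: int  # forward acceptor ref index of read position i2
    jr: int  # reversed-read index of the acceptor segment end
    o_r: int  # reversed-side acceptor offset


def _extend_mh(
    read: np.ndarray,
    dref: np.ndarray,
    aref: np.ndarray,
    j1: int,
    i2: int,
    o_d: int,
    q: int,
) -> tuple[int, int]:
    """Maximal microhomology extension around an adjacent split (i2 == j1+1).

    Returns (count_left, count_right): read bases adjacent to the breakpoint
    that match BOTH references exactly.
    """
    L = len(read)
    cl = 0
    while True:
        pos = j1 - cl
        di = pos + o_d
        ai = q - 1 - cl
        if pos < 0 or di < 0 or ai < 0:
            break
        if read[pos] == dref[di] and read[pos] == aref[ai]:
            cl += 1
        else:
            break
    cr = 0
    while True:
        pos = i2 + cr
        di = pos + o_d
        ai = q + cr
        if pos >= L or di >= len(dref) or ai >= len(aref):
            break
        if read[pos] == dref[di] and read[pos] == aref[ai]:
            cr += 1
        else:
            break
    return cl, cr


def _call_one_orientation(
    read_s: str,
    donor: SwitchReference,
    acceptor: SwitchReference,
    opts: CallerOpts,
    d_index: _RefIndex | None,
    a_index: _RefIndex | None,
    read_id: str,
    orientation: str,
) -> JunctionCall:
    read = _encode_read(read_s)
    dref = _encode_ref(donor.sequence)
    aref = _encode_ref(acceptor.sequence)
    L = len(read)
    Rd, Ra = len(dref), len(aref)

    if opts.seed_k is not None:
        offs_d = d_index.diagonals(read_s) if d_index else np.array([], dtype=np.int64)
        offs_a_fwd = (
            a_index.diagonals(read_s) if a_index else np.array([], dtype=np.int64)
        )
    else:
        offs_d = np.arange(-(L - 1), Rd, dtype=np.int64)
        offs_a_fwd = np.arange(-(L - 1), Ra, dtype=np.int64)
    if offs_d.size == 0 or offs_a_fwd.size == 0:
        return JunctionCall(read_id, "unalignable", orientation)

    K_d, F, csum_d = _segment_scores(read, dref, offs_d, opts.match, opts.mismatch)

    # acceptor side on reversed sequences: segment END in reversed coords is
    # the segment START in forward coords
    read_r = read[::-1]
    aref_r = aref[::-1]
    # forward offset o (aref idx = read idx + o) maps to reversed offset
    # o_r = Ra - L - o
    offs_a_rev = np.sort((Ra - L) - offs_a_fwd)
    K_a, G_rev, csum_a = _segment_scores(
        read_r, aref_r, offs_a_rev, opts.match, opts.mismatch
    )
    G = G_rev[::-1].copy()  # G[i]: best acceptor segment starting at forward i

    neginf = -(10**8)
    F_pref = np.maximum.accumulate(F)  # max F[0..j]
    G_suf = np.maximum.accumulate(G[::-1])[::-1]  # max G[i..L-1]
    PF = np.concatenate([[neginf], F_pref])  # PF[c] = max F[0..c-1]
    SG = np.concatenate([G_suf, [neginf]])  # SG[c] = max G[c..L-1]
    PF0 = np.maximum(PF, 0)
    SG0 = np.maximum(SG, 0)
    T = PF0 + SG0
    Tstar = int(T.max())
    if Tstar <= 0:
        return JunctionCall(read_id, "unalignable", orientation)

    cuts = np.flatnonzero(T == Tstar)
    # both sides must contribute for a junction call
    cuts = [int(c) for c in cuts if PF[c] > 0 and SG[c] > 0]
    if not cuts:
        return JunctionCall(read_id, "unalignable", orientation)

    candidates: list[_Candidate] = []
    seen: set[tuple[int, str, int]] = set()
    for c in cuts:
        j1s = np.flatnonzero(F[:c] == PF[c])[::-1]  # largest j1 first
        i2s = np.flatnonzero(G[c:] == SG[c])[:8] + c  # smallest i2 first
        for j1 in j1s[:8]:
            for i2 in i2s:
                dds = np.flatnonzero(K_d[:, j1] == F[j1])[:4]
                jr = L - 1 - int(i2)
                das = np.flatnonzero(K_a[:, jr] == G_rev[jr])[:4]
                for dd in dds:
                    for da in das:
                        o_d = int(offs_d[dd])
                        o_r = int(offs_a_rev[da])
                        q = Ra - 1 - (jr + o_r)
                        j1i, i2i = int(j1), int(i2)
                        if i2i == j1i + 1:
                            cl, cr = _extend_mh(read, dref, aref, j1i, i2i, o_d, q)
                            mh = cl + cr
                            d_end0 = j1i + cr
                            a_start0 = i2i - cl
                            ins = ""
                        else:
                            mh = 0
                            d_end0 = j1i
                            a_start0 = i2i
                            ins = read_s[j1i + 1 : i2i]
                        key = (mh, ins, d_end0)
                        if key in seen:
                            continue
                        seen.add(key)
                        candidates.append(
                            _Candidate(
                                mh, ins, d_end0, a_start0, j1i, i2i, o_d, q, jr, o_r
                            )
                        )
                        if len(candidates) >= opts.max_candidates:
                            break
                    if len(candidates) >= opts.max_candidates:
                        break
                if len(candidates) >= opts.max_candidates:
                    break
            if len(candidates) >= opts.max_candidates:
                break
        if len(candidates) >= opts.max_candidates:
            break

    best_mh = max(c.mh for c in candidates)
    pool = [c for c in candidates if c.mh == best_mh]
    min_ins = min(len(c.ins) for c in pool)
    pool = [c for c in pool if len(c.ins) == min_ins]
    if len({c.ins for c in pool}) > 1:
        w = min(pool, key=lambda c: c.d_end0)
        return _finish_call(
            read, read_s, dref, aref, w, K_d, csum_d, csum_a, offs_d, offs_a_rev,
            opts, read_id, orientation, Tstar, status="ambiguous"
        )
    w = min(pool, key=lambda c: c.d_end0)
    return _finish_call(
        read, read_s, dref, aref, w, K_d, csum_d, csum_a, offs_d, offs_a_rev,
        opts, read_id, orientation, Tstar, status="called"
    )


def _finish_call(
    read: np.ndarray,
    read_s: str,
    dref: np.ndarray,
    aref: np.ndarray,
    w: _Candidate,
    K_d: np.ndarray,
    csum_d: np.ndarray,
    csum_a: np.ndarray,
    offs_d: np.ndarray,
    offs_a_rev: np.ndarray,
    opts: CallerOpts,
    read_id: str,
    orientation: str,
    total: int,
    status: str,
) -> JunctionCall:
    L = len(read)
    Ra = len(aref)
    dd = int(np.flatnonzero(offs_d == w.o_d)[0])
    da = int(np.flatnonzero(offs_a_rev == w.o_r)[0])
    d_start = _segment_start(csum_d[dd], w.j1)
    a_end_rev_start = _segment_start(csum_a[da], w.jr)
    a_seg_end0 = L - 1 - a_end_rev_start  # forward read index of acceptor seg end

    # donor anchor spans its aligned segment through the MH-extended end
    da_lo, da_hi = d_start, w.d_end0
    d_span = slice(da_lo, da_hi + 1)
    d_ref_lo, d_ref_hi = da_lo + w.o_d, da_hi + w.o_d
    d_mm = int(np.sum(read[d_span] != dref[d_ref_lo : d_ref_hi + 1]))
    d_len = da_hi - da_lo + 1

    aa_lo, aa_hi = w.a_start0, a_seg_end0
    a_ref_lo = w.q - (w.i2 - aa_lo)
    a_ref_hi = a_ref_lo + (aa_hi - aa_lo)
    a_mm = int(np.sum(read[aa_lo : aa_hi + 1] != aref[a_ref_lo : a_ref_hi + 1]))
    a_len = aa_hi - aa_lo + 1

    d_ident = (d_len - d_mm) / d_len if d_len else 0.0
    a_ident = (a_len - a_mm) / a_len if a_len else 0.0
    if status == "called" and (
        d_len < opts.min_anchor
        or a_len < opts.min_anchor
        or d_ident < opts.min_identity
        or a_ident < opts.min_identity
    ):
        status = "unalignable"

    donor_break = (w.d_end0 + w.o_d) + 1
    if w.ins:
        acceptor_break = w.q + 1
    else:
        # reference position of the first acceptor base beyond the MH tract
        acceptor_break = w.q + (w.d_end0 - w.i2 + 1) + 1
    return JunctionCall(
        read_id=read_id,
        status=status,
        orientation=orientation,
        donor_align=(d_ref_lo + 1, d_ref_hi + 1, da_lo + 1, da_hi + 1, d_mm),
        acceptor_align=(a_ref_lo + 1, a_ref_hi + 1, aa_lo + 1, aa_hi + 1, a_mm),
        d_end=w.d_end0 + 1,
        a_start=w.a_start0 + 1,
        mh_length=w.mh,
        insertion_seq=w.ins,
        donor_break=donor_break,
        acceptor_break=acceptor_break,
        total_score=total,
    )


def call_junction(
    read: str,
    donor: SwitchReference,
    acceptor: SwitchReference,
    opts: CallerOpts = CallerOpts(),
    read_id: str = "read",
    _indexes: tuple[_RefIndex, _RefIndex] | None = None,
) -> JunctionCall:
    """Call the junction of one read against donor and acceptor references.

    Returns the score-maximal split over all gapless donor-prefix /
    acceptor-suffix segment pairs, post-processed by maximal microhomology
    extension.  Reads whose anchors are shorter than ``opts.min_anchor`` or
    below ``opts.min_identity`` are ``unalignable``; when
    ``opts.try_reverse_complement`` is set the reverse complement is retried
    before giving up (cloned PCR products insert in either orientation), and
    a reverse call is reported in the coordinates of the reverse-complemented
    read with ``orientation == "-"``.
    """
    read = read.upper()
    if min(len(donor), len(acceptor)) < opts.min_anchor:
        raise ValueError("references shorter than min_anchor")
    if opts.seed_k is not None and min(len(donor), len(acceptor)) < opts.seed_k:
        raise ValueError("references shorter than seed_k")
    if _indexes is not None:
        d_index, a_index = _indexes
    elif opts.seed_k is not None:
        d_index = _RefIndex(donor.sequence, opts.seed_k)
        a_index = _RefIndex(acceptor.sequence, opts.seed_k)
    else:
        d_index = a_index = None

    if len(read) < 2 * opts.min_anchor:
        return JunctionCall(read_id, "unalignable")

    fwd = _call_one_orientation(
        read, donor, acceptor, opts, d_index, a_index, read_id, "+"
    )
    if fwd.status == "called" or not opts.try_reverse_complement:
        return fwd
    rev = _call_one_orientation(
        _revcomp(read), donor, acceptor, opts, d_index, a_index, read_id, "-"
    )
    return rev if rev.status == "called" else fwd


CALL_COLUMNS = [
    "read_id",
    "status",
    "orientation",
    "donor_ref_start",
    "donor_ref_end",
    "acceptor_ref_start",
    "acceptor_ref_end",
    "d_end",
    "a_start",
    "mh_length",
    "insertion_seq",
    "donor_break",
    "acceptor_break",
    "donor_mismatches",
    "acceptor_mismatches",
    "total_score",
]


def call_cohort(
    records: list[tuple[str, str]],
    donor: SwitchReference,
    acceptor: SwitchReference,
    opts: CallerOpts = CallerOpts(),
) -> pd.DataFrame:
    """Call every read of a cohort; one output row per record, in order."""
    if not records:
        warnings.warn("empty cohort: no reads to call", stacklevel=2)
        return pd.DataFrame(columns=CALL_COLUMNS)
    if opts.seed_k is not None:
        indexes = (
            _RefIndex(donor.sequence, opts.seed_k),
            _RefIndex(acceptor.sequence, opts.seed_k),
        )
    else:
        indexes = None
    rows = []
    for read_id, seq in records:
        call = call_junction(seq, donor, acceptor, opts, read_id, _indexes=indexes)
        da = call.donor_align or (0, 0, 0, 0, 0)
        aa = call.acceptor_align or (0, 0, 0, 0, 0)
        rows.append(
            {
                "read_id": call.read_id,
                "status": call.status,
                "orientation": call.orientation,
                "donor_ref_start": da[0],
                "donor_ref_end": da[1],
                "acceptor_ref_start": aa[0],
                "acceptor_ref_end": aa[1],
                "d_end": call.d_end,
                "a_start": call.a_start,
                "mh_length": call.mh_length,
                "insertion_seq": call.insertion_seq,
                "donor_break": call.donor_break,
                "acceptor_break": call.acceptor_break,
                "donor_mismatches": da[4],
                "acceptor_mismatches": aa[4],
                "total_score": call.total_score,
            }
        )
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
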