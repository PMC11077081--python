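"""Synthetic switch-junction cohorts, decoy genomes and qPCR panels.

Class switch recombination (CSR) joins AID-induced double-strand breaks in a
donor switch region (e.g. Smu) to breaks in an acceptor switch region (e.g.
Salpha).  The repair outcome leaves a characteristic signature at the sequenced
junction: blunt ligation, a short (1-3 nt) or long (>=4 nt) stretch of
microhomology shared by both break ends, a small untemplated insertion, or a
long (>30 nt) insertion captured from elsewhere in the genome (ectopic
sequence capture, ECS).

This module builds cohorts of junction reads with *exact* ground truth so the
breakpoint caller, pathway classifier and cohort statistics can be validated
end to end.  References are switch-like (tandem repeat units interleaved with
GC-biased spacers); junction reads are Sanger-clone scale (500-1000 nt by
default) with AID-like point mutations in a halo around the junction; the
bases that define the junction itself (the microhomology tract plus a 3 nt
guard on each side, or the full insertion plus guards) are kept exact so the
recorded truth is unambiguous.

The qPCR generator inverts the restriction-protection resection formula
``ssDNA% = 1/(2^(dCt-1) + 0.5) * 100``: given a true single-stranded fraction
f it emits mock and digested Cq values whose difference is
``dCt(f) = log2(1/f - 0.5) + 1`` plus i.i.d. Gaussian noise, so the analysis
side can be checked by round trip.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SwitchReference",
    "JunctionTruth",
    "CohortSpec",
    "QpcrPanelSpec",
    "CohortResult",
    "JunctionSim",
    "make_switch_reference",
    "make_decoy_genome",
    "simulate_junction",
    "simulate_cohort",
    "simulate_qpcr_panel",
    "delta_ct_for_fraction",
    "control_like_mix",
    "knockdown_like_mix",
    "CATEGORIES",
    "truth_table",
]

_BASES = "ACGT"
CATEGORIES = ("blunt", "mh_short", "mh_long", "small_insertion", "ecs_insertion")

#: flanking sequence kept on each side of a sampled break so the caller always
#: has an alignable anchor
_MARGIN = 60
#: minimal donor portion of a read, nt
_MIN_SIDE = 50


class GenerationError(RuntimeError):
    """Raised when a requested repair outcome cannot be realised."""


@dataclass(frozen=True)
class SwitchReference:
    """A donor or acceptor switch-region reference sequence.

    ``repeat_unit`` records the motif used to build switch-like
    repetitiveness; it is metadata only.
    """

    name: str
    sequence: str
    role: str  # "donor" | "acceptor"
    repeat_unit: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("donor", "acceptor"):
            raise ValueError(f"role must be donor|acceptor, got {self.role!r}")
        seq = self.sequence.upper()
        if set(seq) - set(_BASES):
            raise ValueError("reference sequence must contain only A/C/G/T")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class JunctionTruth:
    """Ground truth for one simulated junction read.

    Coordinates are 1-based: ``donor_break`` is the last donor base used by
    the read (microhomology bases count as donor), ``acceptor_break`` the
    first acceptor base that is *not* shared with the donor.  Exactly one of
    ``mh_length > 0`` / ``insertion_seq != ""`` can hold.
    """

    read_id: str
    category: str
    donor_break: int
    acceptor_break: int
    mh_length: int
    insertion_seq: str
    ecs_source: tuple[str, int, int, str] | None = None
    mutations: tuple[tuple[int, str, str], ...] = ()
    read_start_offset: int = 0  # 0-based donor offset where the read begins
    duplicate_of: str | None = None

    def __post_init__(self) -> None:
        if self.mh_length > 0 and self.insertion_seq:
            raise ValueError("a junction is MH-joined or insertion-joined, never both")
        if self.mh_length < 0:
            raise ValueError("mh_length must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated junction cohort."""

    n_junctions: int
    mix: dict[str, float]
    mh_long_max: int = 8
    mutation_rate: float = 0.01
    mutation_window: int = 50
    read_length_range: tuple[int, int] = (500, 1000)
    ecs_length_range: tuple[int, int] = (31, 120)
    duplication_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_junctions <= 0:
            raise ValueError("n_junctions must be positive")
        unknown = set(self.mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        total = sum(self.mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mix probabilities must sum to 1, got {total}")
        lo, hi = self.read_length_range
        if not (200 <= lo <= hi <= 2000):
            raise ValueError("read_length_range must lie within [200, 2000]")
        if self.mh_long_max < 4:
            raise ValueError("mh_long_max must be >= 4")
        if not (0.0 <= self.duplication_rate < 1.0):
            raise ValueError("duplication_rate must be in [0, 1)")


@dataclass(frozen=True)
class QpcrPanelSpec:
    """Parameters of a simulated restriction-protection resection panel."""

    amplicons: tuple[tuple[str, str], ...]  # (name, "target"|"negative_control")
    true_ssdna_fraction: dict[str, float]
    baseline_cq: dict[str, float]
    replicates: int = 3
    cq_noise_sd: float = 0.1
    delta_ct_ceiling: float = 15.0
    condition: str = "sample"
    sample: str = "s1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        for name, role in self.amplicons:
            if role not in ("target", "negative_control"):
                raise ValueError(f"bad locus role {role!r} for amplicon {name}")
            f = self.true_ssdna_fraction.get(name)
            if f is None or not (0.0 < f <= 1.0):
                raise ValueError(f"ssDNA fraction for {name} must be in (0, 1]")
            if role == "negative_control" and f > 0.005:
                raise ValueError(
                    f"negative-control amplicon {name} must have fraction <= 0.005"
                )
            if name not in self.baseline_cq:
                raise ValueError(f"missing baseline Cq for amplicon {name}")


@dataclass(frozen=True)
class JunctionSim:
    """One simulated junction: the read, its truth, and the references used.

    MH outcomes may require engineering a shared flank by copying acceptor
    bases into the donor; the (possibly edited) references that the read was
    built against are therefore returned alongside it, with the edits listed
    as ``(donor_position_1based, old_base, new_base)``.
    """

    read: str
    truth: JunctionTruth
    donor: SwitchReference
    acceptor: SwitchReference
    reference_edits: tuple[tuple[int, str, str], ...] = ()


@dataclass(frozen=True)
class CohortResult:
    """A simulated cohort: FASTA-ready records plus exact truth."""

    records: tuple[tuple[str, str], ...]  # (read_id, sequence)
    truths: tuple[JunctionTruth, ...]
    donor: SwitchReference
    acceptor: SwitchReference
    reference_edits: tuple[tuple[int, str, str], ...] = ()


def control_like_mix() -> dict[str, float]:
    """Repair-outcome mixture emulating an unperturbed (control) cohort.

    Dominated by blunt joins and short microhomology, i.e. ~90% C-NHEJ.
    """
    return {
        "blunt": 0.55,
        "mh_short": 0.35,
        "mh_long": 0.06,
        "small_insertion": 0.03,
        "ecs_insertion": 0.01,
    }


def knockdown_like_mix() -> dict[str, float]:
    """Mixture emulating a C-NHEJ-impaired (knockdown-like) cohort.

    Shifted toward long microhomology and insertions, i.e. ~65% C-NHEJ —
    a 25-percentage-point drop in C-NHEJ share relative to the control mix.
    """
    return {
        "blunt": 0.30,
        "mh_short": 0.35,
        "mh_long": 0.20,
        "small_insertion": 0.10,
        "ecs_insertion": 0.05,
    }


def _random_bases(rng: np.random.Generator, n: int, gc_bias: float = 0.5) -> str:
    p = np.array([(1 - gc_bias) / 2, gc_bias / 2, gc_bias / 2, (1 - gc_bias) / 2])
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=p)])


def make_switch_reference(
    name: str,
    role: str,
    length: int,
    repeat_unit: str = "GAGCT",
    gc_bias: float = 0.6,
    seed: int = 0,
) -> SwitchReference:
    """Build a switch-like repetitive reference.

    Tandem copies of ``repeat_unit`` are interleaved with random spacers of
    the same length drawn at the requested GC bias, which guarantees at least
    ``length / (4 * len(repeat_unit))`` copies of the unit (real switch
    regions such as Smu are dense tandem arrays of short GC-rich motifs).
    Deterministic for a fixed seed.
    """
    if length < 200:
        raise ValueError("reference length must be >= 200")
    if not repeat_unit:
        raise ValueError("repeat_unit must be non-empty")
    if not (0.0 < gc_bias < 1.0):
        raise ValueError("gc_bias must be in (0, 1)")
    repeat_unit = repeat_unit.upper()
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    n = 0
    while n < length:
        parts.append(repeat_unit)
        parts.append(_random_bases(rng, len(repeat_unit), gc_bias))
        n += 2 * len(repeat_unit)
    return SwitchReference(name, "".join(parts)[:length], role, repeat_unit)


def make_decoy_genome(
    n_contigs: int = 3,
    contig_length: int = 5000,
    gc_bias: float = 0.45,
    seed: int = 0,
) -> dict[str, str]:
    """Random contigs standing in for 'the rest of the genome' in ECS tests."""
    rng = np.random.default_rng(seed)
    return {
        f"decoy{i + 1}": _random_bases(rng, contig_length, gc_bias)
        for i in range(n_contigs)
    }


# ---------------------------------------------------------------------------
# microhomology site machinery
# ---------------------------------------------------------------------------


def _exact_mh_sites(donor: str, acceptor: str, k: int) -> list[tuple[int, int]]:
    """All (e, a0) pairs with an *exactly* k-long shared flank.

    0-based: ``donor[e-k:e] == acceptor[a0-k:a0]`` while the bases just
    outside the flank disagree on both sides, so a maximal-extension caller
    recovers exactly k.  Only sites with enough flanking margin for read
    anchors are returned.
    """
    index: dict[str, list[int]] = {}
    for a0 in range(k + _MARGIN // 2, len(acceptor) - _MARGIN):
        index.setdefault(acceptor[a0 - k : a0], []).append(a0)
    sites = []
    for e in range(max(k, _MIN_SIDE), len(donor) - 2):
        hits = index.get(donor[e - k : e])
        if not hits:
            continue
        for a0 in hits:
            if donor[e - k - 1] == acceptor[a0 - k - 1]:
                continue
            if donor[e] == acceptor[a0]:
                continue
            sites.append((e, a0))
    return sites


def _other_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in _BASES if b != base]
    return choices[rng.integers(len(choices))]


def _plant_mh_site(
    donor: list[str],
    acceptor: str,
    k: int,
    rng: np.random.Generator,
    occupied: list[tuple[int, int]],
    min_e: int = 0,
) -> tuple[tuple[int, int], list[tuple[int, str, str]]]:
    """Engineer an exact-k shared flank by copying acceptor bases into donor.

    Edits are applied to the mutable donor sequence *before* any read is
    generated, so every read in the cohort sees the same references.  Returns
    the site and the list of edits (1-based donor position, old, new).
    ``min_e`` keeps planted sites far enough from the donor start that a
    minimum-length read fits.
    """
    edits: list[tuple[int, str, str]] = []
    lo_e = max(_MIN_SIDE + k + 2, min_e)
    if lo_e >= len(donor) - _MARGIN:
        raise GenerationError("donor too short to plant a microhomology site")
    for _ in range(200):
        e = int(rng.integers(lo_e, len(donor) - _MARGIN))
        if any(lo - 1 <= e <= hi + 1 for lo, hi in occupied):
            continue
        a0 = int(rng.integers(k + _MARGIN // 2, len(acceptor) - _MARGIN))
        window = list(range(e - k - 1, e + 1))
        for pos, newbase in zip(range(e - k, e), acceptor[a0 - k : a0]):
            if donor[pos] != newbase:
                edits.append((pos + 1, donor[pos], newbase))
                donor[pos] = newbase
        if donor[e - k - 1] == acceptor[a0 - k - 1]:
            nb = _other_base(rng, donor[e - k - 1])
            while nb == acceptor[a0 - k - 1]:
                nb = _other_base(rng, donor[e - k - 1])
            edits.append((e - k, donor[e - k - 1], nb))
            donor[e - k - 1] = nb
        if donor[e] == acceptor[a0]:
            nb = _other_base(rng, donor[e])
            while nb == acceptor[a0]:
                nb = _other_base(rng, donor[e])
            edits.append((e + 1, donor[e], nb))
            donor[e] = nb
        occupied.append((window[0], window[-1]))
        return (e, a0), edits
    raise GenerationError(f"could not plant an exact {k}-nt microhomology site")


# ---------------------------------------------------------------------------
# read construction
# ---------------------------------------------------------------------------


def _sample_blunt_site(
    donor: str, acceptor: str, rng: np.random.Generator, min_total: int = 0
) -> tuple[int, int]:
    for _ in range(500):
        e = int(rng.integers(_MIN_SIDE, len(donor) - 2))
        a0 = int(rng.integers(_MARGIN // 2, len(acceptor) - _MARGIN))
        if e + len(acceptor) - a0 < min_total:
            continue
        if donor[e - 1] != acceptor[a0 - 1] and acceptor[a0] != donor[e]:
            return e, a0
    raise GenerationError("could not sample a blunt junction site")


def _absorbable(ins_side: str, ref_side: str) -> bool:
    """True if some prefix of ins_side aligns to ref_side with net score >= 0.

    Uses the caller's scoring (match +1, mismatch -3).  An insertion whose
    boundary run is absorbable would be claimed by the flanking anchor at
    equal or better score, making the planted truth unrecoverable; such
    insertions are rejected at generation time.
    """
    s = 0
    for i, b in enumerate(ins_side):
        s += 1 if i < len(ref_side) and b == ref_side[i] else -3
        if s >= 0:
            return True
    return False


def _insertion_ok(ins: str, donor: str, acceptor: str, e: int, a0: int) -> bool:
    n = len(ins)
    if _absorbable(ins, donor[e : e + n]):
        return False
    if _absorbable(ins[::-1], acceptor[max(0, a0 - n) : a0][::-1]):
        return False
    return True


def _sample_insertion(
    donor: str,
    acceptor: str,
    e: int,
    a0: int,
    rng: np.random.Generator,
    length_range: tuple[int, int],
) -> str:
    lo, hi = length_range
    for _ in range(200):
        ins = _random_bases(rng, int(rng.integers(lo, hi + 1)))
        if _insertion_ok(ins, donor, acceptor, e, a0):
            return ins
    raise GenerationError("could not sample an admissible insertion")


def _sample_ecs_insertion(
    donor: str,
    acceptor: str,
    e: int,
    a0: int,
    decoy: dict[str, str],
    rng: np.random.Generator,
    length_range: tuple[int, int],
) -> tuple[str, tuple[str, int, int, str]]:
    lo, hi = length_range
    names = sorted(decoy)
    for _ in range(500):
        contig = names[rng.integers(len(names))]
        seq = decoy[contig]
        n = int(rng.integers(lo, hi + 1))
        if len(seq) < n + 2:
            continue
        start = int(rng.integers(0, len(seq) - n))
        strand = "+" if rng.random() < 0.5 else "-"
        frag = seq[start : start + n]
        ins = frag if strand == "+" else _revcomp(frag)
        if _insertion_ok(ins, donor, acceptor, e, a0):
            return ins, (contig, start + 1, start + n, strand)
    raise GenerationError("could not sample an admissible ECS insertion from the decoy")


_RC = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _build_read(
    donor: str,
    acceptor: str,
    e: int,
    a0: int,
    k: int,
    ins: str,
    rng: np.random.Generator,
    spec: CohortSpec,
) -> tuple[str, int, int, list[tuple[int, str, str]]]:
    """Assemble donor[s:e] + ins + acceptor[a0:a0+a_len] and mutate the halo.

    Returns (read, s, d_len, mutations).  The protected exact zone spans the
    microhomology tract (or the whole insertion) plus 3 nt on each side: the
    guard width equals the caller's mismatch penalty, so a mutation at the
    first unprotected position makes anchor trimming a score *tie* (resolved
    toward the true junction by the smaller-insertion tie-break) rather than
    a win.
    """
    lo, hi = spec.read_length_range
    target = int(rng.integers(lo, hi + 1))
    target = max(target, 2 * _MIN_SIDE + len(ins))
    if target > hi:
        raise GenerationError(
            "insertion too long for the requested read length range"
        )
    phi = rng.uniform(0.35, 0.65)
    a_avail = len(acceptor) - a0
    core = min(target - len(ins), e + a_avail)
    lo_d = max(_MIN_SIDE, core - a_avail)
    hi_d = min(e, core - _MIN_SIDE)
    if lo_d > hi_d:
        raise GenerationError("junction site too close to a reference edge")
    d_len = int(min(max(round(phi * core), lo_d), hi_d))
    a_len = core - d_len
    s = e - d_len
    read = list(donor[s:e] + ins + acceptor[a0 : a0 + a_len])
    jx = d_len  # 0-based read index of the first non-donor base
    protected = set(range(jx - k - 3, jx + len(ins) + 3))
    w = spec.mutation_window
    mutations: list[tuple[int, str, str]] = []
    if spec.mutation_rate > 0:
        for pos in range(max(0, jx - w), min(len(read), jx + len(ins) + w)):
            if pos in protected:
                continue
            if rng.random() < spec.mutation_rate:
                old = read[pos]
                new = _other_base(rng, old)
                read[pos] = new
                mutations.append((pos + 1, old, new))
    return "".join(read), s, d_len, mutations


def simulate_junction(
    donor: SwitchReference,
    acceptor: SwitchReference,
    outcome: str,
    params: CohortSpec,
    decoy: dict[str, str] | None = None,
    seed: int = 0,
    mh_length: int | None = None,
) -> JunctionSim:
    """Simulate a single junction read with exact truth.

    For microhomology outcomes the references must admit a site pair sharing
    the requested identical flank; if none exists, one is engineered by
    copying the flank from the acceptor into a copy of the donor (the edits
    are recorded and the edited donor is returned in the result).  A decoy
    genome is required for ``ecs_insertion``.
    """
    if outcome not in CATEGORIES:
        raise GenerationError(f"unknown outcome category {outcome!r}")
    rng = np.random.default_rng(seed)
    dseq, aseq = donor.sequence, acceptor.sequence
    edits: list[tuple[int, str, str]] = []

    if outcome in ("mh_short", "mh_long"):
        if mh_length is None:
            k = (
                int(rng.integers(1, 4))
                if outcome == "mh_short"
                else int(rng.integers(4, params.mh_long_max + 1))
            )
        else:
            k = mh_length
        if outcome == "mh_short" and not (1 <= k <= 3):
            raise GenerationError("mh_short requires mh_length in 1..3")
        if outcome == "mh_long" and k < 4:
            raise GenerationError("mh_long requires mh_length >= 4")
        lo = params.read_length_range[0]
        sites = [
            (e, a0)
            for e, a0 in _exact_mh_sites(dseq, aseq, k)
            if e + len(aseq) - a0 >= lo
        ]
        if not sites:
            dlist = list(dseq)
            site, edits = _plant_mh_site(dlist, aseq, k, rng, [], min_e=lo)
            dseq = "".join(dlist)
            donor = replace(donor, sequence=dseq)
            sites = [site]
        e, a0 = sites[rng.integers(len(sites))]
        ins = ""
        ecs = None
    elif outcome == "blunt":
        e, a0 = _sample_blunt_site(dseq, aseq, rng, params.read_length_range[0])
        k, ins, ecs = 0, "", None
    elif outcome == "small_insertion":
        e, a0 = _sample_blunt_site(dseq, aseq, rng, params.read_length_range[0])
        k = 0
        ins = _sample_insertion(dseq, aseq, e, a0, rng, (1, 2))
        ecs = None
    else:  # ecs_insertion
        if not decoy:
            raise GenerationError("ecs_insertion requires a decoy genome")
        e, a0 = _sample_blunt_site(dseq, aseq, rng, params.read_length_range[0])
        k = 0
        ins, ecs = _sample_ecs_insertion(
            dseq, aseq, e, a0, decoy, rng, params.ecs_length_range
        )

    read, s, _d_len, mutations = _build_read(dseq, aseq, e, a0, k, ins, rng, params)
    truth = JunctionTruth(
        read_id="jx00000",
        category=outcome,
        donor_break=e,  # 1-based: e 0-based-exclusive == 1-based last base used
        acceptor_break=a0 + 1,
        mh_length=k,
        insertion_seq=ins,
        ecs_source=ecs,
        mutations=tuple(mutations),
        read_start_offset=s,
    )
    return JunctionSim(read, truth, donor, acceptor, tuple(edits))


def simulate_cohort(
    spec: CohortSpec,
    donor: SwitchReference,
    acceptor: SwitchReference,
    decoy: dict[str, str] | None = None,
) -> CohortResult:
    """Simulate a cohort of junction reads with per-read exact truth.

    Category labels are i.i.d. draws from ``spec.mix``.  Any microhomology
    lengths that the references do not naturally support are engineered into
    a working copy of the donor *before* any read is generated, so the
    returned references are authoritative for the whole cohort.  A
    ``duplication_rate`` fraction of reads is re-emitted verbatim under new
    IDs (marked via ``duplicate_of``) to exercise unique-junction filtering.
    """
    if "ecs_insertion" in spec.mix and spec.mix["ecs_insertion"] > 0 and not decoy:
        raise GenerationError("mix includes ecs_insertion but no decoy genome given")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.read_length_range
    if len(donor) < hi + _MARGIN or len(acceptor) < hi + _MARGIN:
        raise GenerationError(
            f"references must be at least {hi + _MARGIN} nt for reads up to {hi} nt"
        )

    cats = sorted(spec.mix)
    probs = np.array([spec.mix[c] for c in cats])
    labels = [cats[i] for i in rng.choice(len(cats), size=spec.n_junctions, p=probs)]
    mh_lengths = [
        int(rng.integers(1, 4))
        if c == "mh_short"
        else int(rng.integers(4, spec.mh_long_max + 1))
        if c == "mh_long"
        else 0
        for c in labels
    ]

    # engineer enough *distinct* exact-MH sites per requested length before
    # any read is generated, then freeze the references: every junction in
    # the cohort then has its own signature (independent recombination
    # events never coincide, so unique-junction filtering is exact)
    dlist = list(donor.sequence)
    all_edits: list[tuple[int, str, str]] = []
    occupied: list[tuple[int, int]] = []
    needed = Counter(k for k in mh_lengths if k > 0)
    site_cache: dict[int, list[tuple[int, int]]] = {}
    for _round in range(6):
        dseq = "".join(dlist)
        short: dict[int, int] = {}
        for k in needed:
            site_cache[k] = [
                (e, a0)
                for e, a0 in _exact_mh_sites(dseq, acceptor.sequence, k)
                if e + len(acceptor) - a0 >= lo
            ]
            if len(site_cache[k]) < needed[k]:
                short[k] = needed[k] - len(site_cache[k])
        if not short:
            break
        for k, m in short.items():
            for _ in range(m):
                _, edits = _plant_mh_site(
                    dlist, acceptor.sequence, k, rng, occupied, min_e=lo
                )
                all_edits.extend(edits)
    else:
        raise GenerationError("could not engineer enough distinct MH sites")
    if all_edits:
        donor = replace(donor, sequence=dseq)
    aseq = acceptor.sequence

    # distinct-site draws per MH length, in junction order
    site_draws: dict[int, list[tuple[int, int]]] = {}
    for k, m in needed.items():
        picks = rng.choice(len(site_cache[k]), size=m, replace=False)
        site_draws[k] = [site_cache[k][int(i)] for i in picks]
    used_sigs: set[tuple[int, int, int, str]] = set()

    records: list[tuple[str, str]] = []
    truths: list[JunctionTruth] = []
    seen: set[str] = set()
    for i, (cat, k) in enumerate(zip(labels, mh_lengths)):
        read_id = f"jx{i:05d}"
        mh_site = site_draws[k].pop() if cat in ("mh_short", "mh_long") else None
        for _attempt in range(50):
            if mh_site is not None:
                e, a0 = mh_site
                ins, ecs = "", None
            elif cat == "blunt":
                e, a0 = _sample_blunt_site(dseq, aseq, rng, lo)
                ins, ecs = "", None
            elif cat == "small_insertion":
                e, a0 = _sample_blunt_site(dseq, aseq, rng, lo)
                ins, ecs = _sample_insertion(dseq, aseq, e, a0, rng, (1, 2)), None
            else:
                e, a0 = _sample_blunt_site(dseq, aseq, rng, lo)
                ins, ecs = _sample_ecs_insertion(
                    dseq, aseq, e, a0, decoy, rng, spec.ecs_length_range
                )
            if (e, a0, k, ins) in used_sigs:
                continue
            read, s, _dl, muts = _build_read(dseq, aseq, e, a0, k, ins, rng, spec)
            if read not in seen:
                break
        else:  # pragma: no cover - essentially unreachable
            raise GenerationError(f"could not generate a unique read for {read_id}")
        used_sigs.add((e, a0, k, ins))
        seen.add(read)
        records.append((read_id, read))
        truths.append(
            JunctionTruth(
                read_id=read_id,
                category=cat,
                donor_break=e,
                acceptor_break=a0 + 1,
                mh_length=k,
                insertion_seq=ins,
                ecs_source=ecs,
                mutations=tuple(muts),
                read_start_offset=s,
            )
        )

    n_dup = int(round(spec.duplication_rate * spec.n_junctions))
    if n_dup:
        dup_idx = rng.choice(spec.n_junctions, size=n_dup, replace=True)
        for j, idx in enumerate(dup_idx):
            src_id, seq = records[idx]
            dup_id = f"dup{j:05d}"
            records.append((dup_id, seq))
            truths.append(replace(truths[idx], read_id=dup_id, duplicate_of=src_id))

    return CohortResult(
        tuple(records), tuple(truths), donor, acceptor, tuple(all_edits)
    )


def truth_table(result: CohortResult) -> pd.DataFrame:
    """Flatten cohort truth into the TSV-ready schema."""
    rows = []
    for t in result.truths:
        contig, start, end, strand = t.ecs_source or ("", 0, 0, "")
        rows.append(
            {
                "read_id": t.read_id,
                "category": t.category,
                "donor_break": t.donor_break,
                "acceptor_break": t.acceptor_break,
                "mh_length": t.mh_length,
                "insertion_seq": t.insertion_seq,
                "ecs_contig": contig,
                "ecs_start": start,
                "ecs_end": end,
                "ecs_strand": strand,
                "duplicate_of": t.duplicate_of or "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# qPCR panel generation
# ---------------------------------------------------------------------------


def delta_ct_for_fraction(f: float) -> float:
    """Mock-to-digested Cq shift implied by a true ssDNA fraction f.

    Inverse of the restriction-protection readout
    ``ssDNA% = 1/(2^(dCt-1) + 0.5) * 100`` evaluated at ``ssDNA% = 100 f``:
    ``dCt = log2(1/f - 0.5) + 1``.  f = 1 (fully single-stranded, fully
    protected) gives dCt = 0, i.e. digestion does not delay amplification.
    """
    if not (0.0 < f <= 1.0):
        raise ValueError("ssDNA fraction must be in (0, 1]")
    return math.log2(1.0 / f - 0.5) + 1.0 if f < 1.0 else 0.0


def simulate_qpcr_panel(spec: QpcrPanelSpec) -> pd.DataFrame:
    """Simulate mock/digested Cq replicates for a resection panel.

    Mock Cq = baseline + noise; digested Cq = baseline + dCt(f) + noise with
    i.i.d. Gaussian noise of SD ``cq_noise_sd``.  dCt is capped at
    ``delta_ct_ceiling`` (column ``capped`` records when the cap bites, which
    happens only for vanishingly small fractions).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for name, role in spec.amplicons:
        f = spec.true_ssdna_fraction[name]
        base = spec.baseline_cq[name]
        dct = delta_ct_for_fraction(f)
        capped = dct > spec.delta_ct_ceiling
        dct = min(dct, spec.delta_ct_ceiling)
        for digestion, shift in (("mock", 0.0), ("digested", dct)):
            for r in range(1, spec.replicates + 1):
                noise = rng.normal(0.0, spec.cq_noise_sd) if spec.cq_noise_sd else 0.0
                rows.append(
                    {
                        "sample": spec.sample,
                        "amplicon": name,
                        "role": role,
                        "condition": spec.condition,
                        "digestion": digestion,
                        "replicate": r,
                        "cq": base + shift + noise,
                        "capped": capped,
                    }
                )
    return pd.DataFrame(rows)
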