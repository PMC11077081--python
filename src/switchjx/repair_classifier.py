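"""Repair-pathway classification of called junctions.

The operational rule for CSR junctions: microhomology of at most 3 nt
(including blunt joins) indicates classical non-homologous end joining
(C-NHEJ); microhomology of 4 nt or more, or any nucleotide insertion,
indicates alternative end joining (A-EJ).  Long insertions (> 30 nt) are
additionally screened against a genome index for ectopic sequence capture
(ECS) — stretches copied from a distant genomic location into the break
junction.

Counting is done over *unique* junctions: sequenced clones that share the
same junction signature (donor break, acceptor break, MH length, insertion)
descend from one recombination event and are collapsed before statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .junction_caller import JunctionCall
from .synthetic_data import _revcomp

__all__ = [
    "RepairClassification",
    "EcsHit",
    "GenomeIndex",
    "classify",
    "classify_cohort",
    "detect_ecs",
    "unique_junctions",
    "PATHWAY_CNHEJ",
    "PATHWAY_AEJ",
]

PATHWAY_CNHEJ = "C-NHEJ"
PATHWAY_AEJ = "A-EJ"
CATEGORY_ORDER = ("blunt", "mh_1_3", "mh_ge4", "ins_small", "ins_long")


class ClassificationError(ValueError):
    """Raised when a non-called junction reaches the classifier."""


@dataclass(frozen=True)
class EcsHit:
    contig: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    identity: float


@dataclass(frozen=True)
class RepairClassification:
    read_id: str
    pathway: str
    category: str
    mh_length: int
    insertion_len: int
    ecs: bool
    ecs_hit: EcsHit | None = None


class GenomeIndex:
    """Exact k-mer index over a set of contigs, for ECS insertion mapping."""

    def __init__(self, contigs: dict[str, str], k: int = 12):
        self.k = k
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self.kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            for p in range(len(seq) - k + 1):
                self.kmers.setdefault(seq[p : p + k], []).append((name, p))


def detect_ecs(
    insertion_seq: str,
    genome_index: GenomeIndex | None,
    min_len: int = 30,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> EcsHit | None:
    """Map an insertion to the genome index by seeded gapless alignment.

    Searches both strands; a hit must cover at least ``min_coverage`` of the
    insertion at identity >= ``min_identity``.  Returns the best-identity
    (then best-coverage) hit, or None.  Insertions of ``min_len`` nt or
    shorter are never searched.
    """
    if genome_index is None or len(insertion_seq) <= min_len:
        return None
    ins_fwd = insertion_seq.upper()
    n = len(ins_fwd)
    k = genome_index.k
    best: tuple[float, int, EcsHit] | None = None
    for strand, ins in (("+", ins_fwd), ("-", _revcomp(ins_fwd))):
        seen_diag: set[tuple[str, int]] = set()
        for j in range(n - k + 1):
            for contig, p in genome_index.kmers.get(ins[j : j + k], ()):
                diag = (contig, p - j)
                if diag in seen_diag:
                    continue
                seen_diag.add(diag)
                seq = genome_index.contigs[contig]
                start = p - j  # contig position of insertion base 0
                lo = max(0, start)
                hi = min(len(seq), start + n)
                covered = hi - lo
                if covered < min_coverage * n:
                    continue
                frag = np.frombuffer(
                    ins[lo - start : hi - start].encode(), dtype=np.uint8
                )
                ref = np.frombuffer(seq[lo:hi].encode(), dtype=np.uint8)
                matches = int(np.sum(frag == ref))
                identity = matches / covered
                if identity < min_identity:
                    continue
                # for "-" the insertion is the reverse complement of the
                # genomic span; coordinates always refer to the + strand
                hit = EcsHit(contig, lo + 1, hi, strand, identity)
                if best is None or (identity, covered) > (best[0], best[1]):
                    best = (identity, covered, hit)
    return best[2] if best else None


def classify(
    call: JunctionCall,
    mh_cnhej_max: int = 3,
    ecs_min_len: int = 30,
    genome_index: GenomeIndex | None = None,
    min_identity: float = 0.9,
) -> RepairClassification:
    """Apply the pathway rule to one called junction.

    C-NHEJ iff microhomology <= ``mh_cnhej_max`` and no insertion; A-EJ
    otherwise.  Insertions longer than ``ecs_min_len`` are ``ins_long`` and
    searched for an ECS origin when a genome index is supplied; with no
    index the ECS flag falls back to the length-only criterion.
    """
    if call.status != "called":
        raise ClassificationError(
            f"cannot classify {call.read_id}: status is {call.status}"
        )
    mh = call.mh_length
    ins = call.insertion_seq
    if ins:
        pathway = PATHWAY_AEJ
        category = "ins_long" if len(ins) > ecs_min_len else "ins_small"
    elif mh > mh_cnhej_max:
        pathway, category = PATHWAY_AEJ, "mh_ge4"
    elif mh > 0:
        pathway, category = PATHWAY_CNHEJ, "mh_1_3"
    else:
        pathway, category = PATHWAY_CNHEJ, "blunt"

    ecs_hit = None
    ecs = False
    if len(ins) > ecs_min_len:
        if genome_index is not None:
            ecs_hit = detect_ecs(
                ins, genome_index, min_len=ecs_min_len, min_identity=min_identity
            )
            ecs = ecs_hit is not None
        else:
            ecs = True  # length-only fallback
    return RepairClassification(
        read_id=call.read_id,
        pathway=pathway,
        category=category,
        mh_length=mh,
        insertion_len=len(ins),
        ecs=ecs,
        ecs_hit=ecs_hit,
    )


def unique_junctions(calls: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Collapse duplicate junction signatures among called reads.

    The signature is (donor_break, acceptor_break, mh_length, insertion_seq):
    reads that differ only by distal point mutations (PCR/sequencing noise on
    clones of the same recombination event) share a signature and collapse to
    the first occurrence.  Non-called reads are excluded but accounted for in
    the returned ledger, never silently dropped.
    """
    ledger = {
        "n_input": len(calls),
        "unalignable": int((calls["status"] == "unalignable").sum()),
        "ambiguous": int((calls["status"] == "ambiguous").sum()),
    }
    called = calls[calls["status"] == "called"]
    sig = ["donor_break", "acceptor_break", "mh_length", "insertion_seq"]
    unique = called.drop_duplicates(subset=sig, keep="first")
    ledger["called"] = len(called)
    ledger["duplicates"] = len(called) - len(unique)
    ledger["unique"] = len(unique)
    return unique.reset_index(drop=True), ledger


def classify_cohort(
    calls: pd.DataFrame,
    genome_index: GenomeIndex | None = None,
    mh_cnhej_max: int = 3,
    ecs_min_len: int = 30,
    min_identity: float = 0.9,
    collapse: bool = True,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify a cohort of calls; optionally collapse to unique junctions.

    Returns a classification table (one row per unique called junction) and
    the filtering ledger.
    """
    if collapse:
        unique, ledger = unique_junctions(calls)
    else:
        unique = calls[calls["status"] == "called"].reset_index(drop=True)
        ledger = {"n_input": len(calls), "called": len(unique)}
    rows = []
    for rec in unique.itertuples(index=False):
        call = JunctionCall(
            read_id=rec.read_id,
            status=rec.status,
            mh_length=int(rec.mh_length),
            insertion_seq=rec.insertion_seq or "",
            donor_break=int(rec.donor_break),
            acceptor_break=int(rec.acceptor_break),
        )
        c = classify(
            call,
            mh_cnhej_max=mh_cnhej_max,
            ecs_min_len=ecs_min_len,
            genome_index=genome_index,
            min_identity=min_identity,
        )
        hit = c.ecs_hit
        rows.append(
            {
                "read_id": c.read_id,
                "pathway": c.pathway,
                "category": c.category,
                "mh_length": c.mh_length,
                "insertion_len": c.insertion_len,
                "ecs": c.ecs,
                "ecs_contig": hit.contig if hit else "",
                "ecs_start": hit.start if hit else 0,
                "ecs_end": hit.end if hit else 0,
                "ecs_strand": hit.strand if hit else "",
                "ecs_identity": hit.identity if hit else np.nan,
            }
        )
    columns = [
        "read_id", "pathway", "category", "mh_length", "insertion_len", "ecs",
        "ecs_contig", "ecs_start", "ecs_end", "ecs_strand", "ecs_identity",
    ]
    return pd.DataFrame(rows, columns=columns), ledger
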