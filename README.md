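# switchjx

Analysis of DNA double-strand-break repair outcomes at class switch
recombination (CSR) junctions, plus the qPCR calculi used alongside such
experiments (DSB-end resection, relative expression, ChIP enrichment).

## Who this is for

During CSR, activation-induced cytidine deaminase (AID) creates breaks in a
donor switch region (Sμ) and an acceptor switch region (e.g. Sα) of the IgH
locus; repair joins the two, and the sequence at the recombined junction
records *how* the join happened. Labs that clone and Sanger-sequence such
junctions typically align each clone to the two references by hand and score
microhomology and insertions. `switchjx` replaces that manual step with a
deterministic, tested caller, and packages the downstream counting,
classification and statistics.

## The core calculus

For a junction read *r* the caller finds the score-maximal pair of
non-overlapping gapless local alignments — a donor segment before an
acceptor segment in read coordinates — under match +1 / mismatch −3. The
junction is then resolved by **maximal microhomology (MH) extension**: the MH
tract is the run of read bases around the breakpoint that match *both*
references exactly, which uniquely determines the last donor base `d_end`,
the first acceptor base `a_start`, the MH length, and any untemplated
insertion. Exactly one of the following holds per call:

* blunt join: `a_start = d_end + 1`, MH 0, no insertion
* microhomology: `a_start ≤ d_end`, MH `= d_end − a_start + 1`
* insertion: `a_start > d_end + 1`, insertion `= r[d_end+1 .. a_start−1]`

Repair pathway is assigned by the standard operational rule: MH ≤ 3 nt with
no insertion → classical non-homologous end joining (C-NHEJ); MH ≥ 4 nt or
any insertion → alternative end joining (A-EJ). Insertions > 30 nt are
screened against a genome k-mer index for ectopic sequence capture (ECS).
Clones sharing a junction signature (donor break, acceptor break, MH,
insertion) are collapsed to one *unique junction* before counting, and
condition contrasts use a two-tailed Fisher's exact test computed by exact
integer enumeration (point-probability method).

The qPCR module implements the restriction-protection resection readout

    ssDNA% = 1 / (2^(ΔCt − 1) + 0.5) × 100,  ΔCt = Cq_digested − Cq_mock

together with ΔΔCq relative expression and ChIP percent-input.

Because published junction figures are graphical and the underlying clones
are not public, the package ships a first-class synthetic-data generator:
switch-like repetitive references, junction cohorts with exact per-read
truth (configurable mixtures of blunt / short-MH / long-MH / small-insertion
/ ECS outcomes, AID-like mutation halos), and Gaussian-noise Cq panels built
by inverting the resection formula. Every analysis stage is validated by
round trip against this truth.

## Worked example

```python
from switchjx import *

donor = make_switch_reference("Smu", "donor", length=2500,
                              repeat_unit="GAGCT", gc_bias=0.6, seed=11)
acceptor = make_switch_reference("Salpha", "acceptor", length=2500,
                                 repeat_unit="TGGGC", gc_bias=0.6, seed=12)
decoy = make_decoy_genome(n_contigs=3, contig_length=5000, seed=13)
index = GenomeIndex(decoy)

summaries = {}
for label, mix, seed in [("siControl", control_like_mix(), 1),
                         ("siBrd2", knockdown_like_mix(), 2)]:
    spec = CohortSpec(n_junctions=150, mix=mix, seed=seed)
    cohort = simulate_cohort(spec, donor, acceptor, decoy)
    calls = call_cohort(list(cohort.records), cohort.donor, cohort.acceptor)
    classified, ledger = classify_cohort(calls, genome_index=index)
    summaries[label] = summarize(classified, label)

for label, s in summaries.items():
    p3 = s.partition3
    print(f"{label}: n={s.n_unique}  "
          f"MH 0-3 nt {p3['mh_0_3'][1]:.1f}%  MH >=4 nt {p3['mh_ge4'][1]:.1f}%  "
          f"insertions {p3['insertion'][1]:.1f}%  ECS sizes {list(s.ecs_sizes)}")

[test] = compare_conditions(summaries["siControl"], summaries["siBrd2"], "pathway")
print(f"C-NHEJ vs A-EJ table {test.result.table}, "
      f"two-tailed Fisher p = {test.result.p_two_tailed:.2e}")

res = ssdna_percent(ct_digested=29.1, ct_mock=24.0)
print(f"resection: dCt = {res.delta_ct:.1f} -> ssDNA% = {res.ssdna_pct:.3f}")
```

prints

```
siControl: n=150  MH 0-3 nt 94.0%  MH >=4 nt 4.0%  insertions 2.0%  ECS sizes []
siBrd2: n=150  MH 0-3 nt 67.3%  MH >=4 nt 19.3%  insertions 13.3%  ECS sizes [67, 72, 41, 37, 116]
C-NHEJ vs A-EJ table ((141, 9), (101, 49)), two-tailed Fisher p = 3.44e-09
resection: dCt = 5.1 -> ssDNA% = 5.666
```

The control-like cohort is dominated by blunt/short-MH joins (94% C-NHEJ);
the knockdown-like cohort shifts toward long microhomology and insertions,
including five junctions whose >30 nt inserts map back to the decoy genome
(ECS). The Fisher test quantifies the pathway shift; the resection line shows
a 5.1-cycle protection shift translating to ~5.7% single-stranded template.

A command-line interface mirrors the library:
`switchjx simulate cohort`, `switchjx call`, `switchjx classify`,
`switchjx stats`, `switchjx resect`, `switchjx expr`, `switchjx chip`
(see `switchjx --help`).

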