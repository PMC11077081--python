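# Methods

This note records the models, conventions and numerical choices behind
`switchjx`, and what the synthetic-data validation does and does not show.

## Junction model and the split-alignment caller

A recombined switch junction read is modelled as a donor-reference block
followed by an acceptor-reference block, optionally separated by inserted
bases — the structure produced by junction PCR of a deletional
recombination event. Gapless alignment therefore suffices; indels within an
anchor are out of scope and would surface as reduced anchor identity.

**Objective.** The caller maximises the summed score of two non-overlapping
gapless local alignments (donor segment strictly before acceptor segment in
read coordinates) with match +1 and mismatch −3. Unaligned read bases (the
insertion, plus any unreadable tails) contribute zero. The optimum is
computed *exactly*: for every diagonal, the best segment ending at each read
position follows in closed form from cumulative sums (`K[j] = csum[j] −
min(0, min csum[<j])`), and the best donor-end/acceptor-start combination is
read off prefix/suffix maxima. By default only diagonals supported by an
exact 12-mer seed are scanned (`seed_k=12`); for any anchor passing the 90%
identity threshold, a shared 12-mer is essentially guaranteed at the anchor
lengths this package handles (≥ 20 nt, typically hundreds), and
`seed_k=None` scans all diagonals for the oracle-equivalence tests. An
X-drop heuristic is unnecessary because the scan is exact and cheap at
Sanger scale.

**Junction resolution.** The score-maximal split is post-processed by
maximal microhomology extension: starting from the breakpoint, read bases
matching *both* references extend the MH tract in both directions. This
uniquely determines `(d_end, a_start, mh_length, insertion_seq)` and yields
the blunt / MH / insertion trichotomy. MH bases must be sequence-identical
to both references — mismatches are allowed (and scored) inside anchors but
never inside the MH tract, since AID mutations near the junction would
otherwise manufacture spurious homology.

**Ties.** Equal-score optima are resolved: larger MH first, then shorter
insertion, then smallest `d_end`. If the surviving optima still disagree on
the insertion content the read is reported `ambiguous` rather than silently
resolved. Reads whose anchors are shorter than `min_anchor` (default 20 nt)
or below `min_identity` (default 0.9) are `unalignable`; the reverse
complement is retried first (`try_reverse_complement`, default on), since
cloned PCR products insert in either orientation.

**Coordinates.** All reported coordinates are 1-based inclusive.
`donor_break` is the reference position of the last donor base used
(counting MH bases as donor) and `acceptor_break` the first acceptor base
not shared with the donor, which makes calls directly comparable with
generator truth.

## Classification and counting

Pathway assignment is a pure function of `(mh_length, insertion length)`:
MH ≤ 3 with no insertion → C-NHEJ; MH ≥ 4 or any insertion → A-EJ
(`mh_cnhej_max=3`). Insertions are binned as `ins_small` (≤ 30 nt) or
`ins_long` (> 30 nt, `ecs_min_len=30`); all insertions are A-EJ regardless
of size, so the 3–30 nt grouping affects only the spectrum display. ECS
detection maps `ins_long` insertions to a genome k-mer index (k = 12, both
strands, gapless) and requires ≥ 90% coverage at ≥ 90% identity — the
coverage/identity thresholds are conventions, exposed as parameters. With no
genome available the ECS flag falls back to the length-only criterion.

Unique-junction filtering collapses calls with identical
`(donor_break, acceptor_break, mh_length, insertion_seq)`. The signature
deliberately ignores distal point mutations, so clones of one recombination
event differing by PCR/sequencing noise collapse, which is the intended
meaning of "unique junction". Unalignable and ambiguous reads are counted
in a side ledger, never silently dropped.

The MH spectrum is binned per length 0–9 with ≥ 10 grouped (bins are
parameters; published figures do not fix them), and coarsened to the
three-way partition short MH (0–3) / long MH (≥ 4) / insertion.

## Exact test

`fisher_two_tailed` uses the point-probability method: the two-tailed p sums
hypergeometric probabilities of all tables with the observed margins whose
probability does not exceed the observed one. It is computed with exact
integer numerators (`math.comb`), so tie comparison is exact and the result
carries no tolerance beyond final float division; the test suite verifies it
against an independent rational-arithmetic enumeration on every table with
grand total ≤ 40 and against `scipy.stats.fisher_exact` on random tables.
The odds ratio is the sample odds ratio ad/bc with 0/∞/NaN conventions for
zero cells. Per-category contrasts report raw p together with the
Bonferroni-adjusted alpha; the pathway contrast reports raw p only.

## qPCR calculi

Resection: ΔCt = mean Cq(digested) − mean Cq(mock), replicates averaged
arithmetically (per-arm SDs are propagated into the report; replicate
aggregation is a package choice). ssDNA% = 1/(2^(ΔCt−1) + 0.5) × 100, which
is exact under 100% amplification efficiency for a double-stranded genome in
which one strand of a resected (single-stranded) site survives restriction
digestion; ΔCt = 0 means full protection, ssDNA% = 100. Negative ΔCt —
possible only through noise near full protection — is clamped to 0 and
QC-flagged rather than raised. Amplification efficiency is fixed at 2.0 per
cycle throughout; standard-curve calibration is out of scope. Relative
expression is standard ΔΔCq against a housekeeping gene; ChIP enrichment
shifts the input Cq by log2(1/input_fraction) before
%input = 100·2^(adjusted−IP). Both are invariant under a global Cq shift.

## Synthetic data: what it emulates, and what it does not

**References** are tandem arrays of a short repeat unit (defaults: donor
`GAGCT`, a Sμ-like motif; acceptor `TGGGC`) alternating with random spacers
at GC bias 0.6, giving switch-like repetitiveness with guaranteed unit
density. **Reads** are 500–1000 nt (the size window typically cloned from
junction PCR), built as donor-prefix + insertion + acceptor-suffix with the
5′ end trimmed to fit; every read keeps ≥ 50 nt on each side of the
junction.

**Truth exactness.** The junction-defining bases are engineered to be
unambiguous under the caller's own scoring:

* MH sites are chosen (or, when a requested length has no natural site,
  planted by copying the flank from the acceptor into the donor *before any
  read is generated*, with edits recorded) such that the shared flank is
  exactly k: the bases just outside disagree on both sides.
* Insertions are rejected if any prefix (suffix) aligns to the continuing
  donor (preceding acceptor) with running score ≥ 0 — otherwise a flanking
  anchor could absorb part of the insertion at equal or better score and no
  score-maximal caller could recover the planted truth.
* AID-like mutations are uniform substitutions at rate 0.01/nt within a
  50 nt halo around the junction, but a protected exact zone spans the MH
  tract (or whole insertion) plus 3 nt on each side. The 3 nt guard equals
  the mismatch penalty: a mutation at the first unprotected distance makes
  anchor trimming a score *tie*, which the smaller-insertion tie-break
  resolves toward the truth; closer mutations would make trimming strictly
  win and the truth unrecoverable in principle. Mutation placement is a
  modelling choice — real AID targeting is hotspot-biased (WRC motifs) and
  is not modelled.
* Each cohort junction gets a distinct signature (MH sites are drawn without
  replacement, with extra sites planted when a length is scarce), so
  independent events never coincide and unique-junction filtering has an
  exact expected answer; the optional duplication rate then re-emits reads
  verbatim to exercise the collapse.

**ECS inserts** are verbatim copies (either strand) of a random decoy
genome, lengths uniform on [31, 120] — published size distributions are
graphical only, so the range is a package default. **qPCR panels** draw
mock/digested Cq replicates at the ΔCt implied by the planted ssDNA fraction
plus i.i.d. Gaussian noise (default SD 0.1 cycles, triplicates); ΔCt is
capped at 15 cycles for vanishing fractions, with the cap recorded.

Passing round trips on these data show that the caller, classifier and
statistics are *internally correct* — they recover exactly what the
generative model planted. They do not validate the biological model itself:
real clones carry indels, chromatogram artefacts, hotspot-clustered
mutations and inverted segments that this generator deliberately omits.

**Default condition mixtures.** `control_like_mix()` (55% blunt, 35% short
MH, 6% long MH, 3% small insertion, 1% ECS; ≈ 90% C-NHEJ) and
`knockdown_like_mix()` (30/35/20/10/5; ≈ 65% C-NHEJ) encode the qualitative
control-vs-knockdown picture — blunt-dominated control, a ~25-point C-NHEJ
drop with long-MH and insertion gain after knockdown — at effect sizes
chosen a priori as realistic for a C-NHEJ-impairment experiment.

## Problem sizes in the validation suite

Oracle equivalence uses 500 random instances with references ≤ 60 nt and
reads ≤ ~90 nt, where exhaustive 2-D dynamic programming is feasible; round
trips use 2,000-junction cohorts at full read length; the discrimination
experiment runs 200 replicate pairs of 100-junction cohorts at 250–400 nt
reads against 1,200 nt references — read length carries no information for
the pathway contrast, so the shorter reads simply keep the experiment brisk;
the Fisher sweep covers all 135,750 tables with grand total ≤ 40; resection
recovery uses 200 seeded noisy panels at a planted fraction of 0.03
(control-like core-Sμ scale). All sizes are package choices, declared here.

## Known limitations

* Gapless model: indels inside anchors lower identity instead of being
  aligned; badly indeled reads end up `unalignable`.
* Two-reference split only: chimeras involving a third locus are not
  detected (ECS covers inserted fragments, not anchor-level chimerism).
* Junctions in repeat-perfect regions can be genuinely ambiguous; the
  tie-break is a convention and such reads are flagged, not resolved.
* Base qualities are ignored (Sanger clones; no per-base error model).
* The Fisher test treats junctions as independent draws; clonal structure
  beyond identical signatures is not modelled.
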