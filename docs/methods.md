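# Methods

This note documents the models, parameter choices and numerical
conventions behind `ribopool`, and what the synthetic tests do and do not
establish about real data.

## The rDNA pool model

Each sample is treated as a pool of full-length amplicons of the nuclear
18S rDNA–ITS1–5.8S region.  Because the rDNA repeat occurs in many copies
per genome — and in allopolyploids the parental repeat families diverge —
one individual yields several distinct sequence variants (*ribotypes*) at
characteristic frequencies.  The pipeline makes two identifications:

1. a ribotype is defined by *exact full-length identity* of the merged
   amplicon (dereplication at 100%), and
2. two samples *share* a ribotype exactly when the identical sequence
   occurs in both pools.

Near-identical variants are deliberately not clustered; their relatedness
is expressed through the parsimony network instead.  This keeps the
sharing relation an equivalence relation and makes hybrid evidence
("the hybrid's main ribotype is identical to the parent's") unambiguous.

## Read processing

**Trimming.**  Sliding-window trimming scans 5'→3' over every full window
of `window` bases (default 4) and cuts the read at the start of the first
window whose mean Phred quality is *strictly below* `quality_threshold`
(default 12); reads shorter than `min_length` (default 130 nt) after
cutting are rejected.  The defaults are the standard parameters for this
marker system.  Only full windows are evaluated; a read shorter than the
window passes untrimmed.  The rule is idempotent by construction, which
the suite property-tests.

**Merging.**  The reverse read is reverse-complemented and the longest
ungapped overlap with mismatch fraction ≤ `max_mismatch_fraction`
(default 0.05) and length ≥ `min_overlap` (default 20 nt) is accepted;
within the overlap each position takes the base with the higher Phred
score (ties go to the forward read) and quality `max(q_f, q_r)`.  Pairs
with no admissible overlap are rejected and counted.  Merging is exposed
both per pair (`merge_pair`, the definitional operation) and vectorised
over a whole pool (`merge_pairs_batch`); a property test asserts the two
paths agree read for read.

**Dereplication.**  Case-insensitive exact grouping; sequences containing
`N` are excluded from the table and tallied separately so that ambiguous
calls never fragment counts.  Tables are sorted by count descending with
lexicographic tie-break, making them byte-stable.  The pool total is the
number of reads that survived trimming, merging and N-exclusion, so the
ribotype counts always sum to it (conservation invariant).

## Major/minor classification

The depth-dependent cutoff reflects how published pool summaries are
read: in pools of ≥ 10,000 reads a ribotype is major with **more than
1,000** reads (strict), otherwise with **100 or more** reads (inclusive).
Percentages are integers, rounded half up, computed exactly in integer
arithmetic as `(200·count + total) // (2·total)`.  This convention
reproduces every internally consistent count/total/percent triple in the
packaged published table (38 triples asserted in the suite).  The same
table contains rows that *cannot* be reproduced from their own totals
(about one row in seven, plus one 80-read ribotype printed among the
majors of a 1,704-read pool); `reference.consistency_report()` flags
them rather than guessing the intent.

Note one boundary effect of the stated rule: raising a count is monotone
at fixed pool total, but if the raise also pushes the *total* across the
10,000-read boundary the cutoff jumps from 100 to 1,001 and a 100–1,000
read ribotype is demoted.  That is a property of the published rule, not
of the implementation.

## Statistical-parsimony networks

**Distance.**  Equal-length sequences use the Hamming distance.  For
unequal lengths, a global alignment under ordinary unit edit costs
(substitution 1, each gapped position 1) anchors homologous regions;
mutational steps are then counted on that alignment with each contiguous
gap collapsed to one step (a single indel event).  Among co-optimal edit
alignments the fewest-step one is taken, so the distance is well defined
and symmetric.  A literal "gap open 1, extension free" optimisation was
rejected because it is degenerate (delete-everything + insert-everything
costs two steps for any pair).  `gap_mode="exclude"` counts only the
substitution columns of the same alignment.

**Connection limit.**  The limit is the largest step count `j` whose
probability of being parsimonious is at least the stated confidence
(default 0.95).  The estimator assumes per-site substitution counts are
Poisson with mean λ under a Jukes–Cantor process.  Two sequences of
length `m` differing at `j` sites give the moment estimate
`p = j/m`, inverted to `λ = -¾·ln(1 - 4p/3)`; a connection is
parsimonious when every differing site experienced exactly one hit,
which conditional on a site differing has probability `λe^{-λ}/p`, giving

    P_j = (λ e^{-λ} / p)^j .

`P_j` decreases in `j` and increases with `m`; single steps are always
connected (the limit's floor is 1), and confidence → 1 collapses the
limit to 1.  For ITS-scale amplicons the 95% limits are 6 steps at 300
nt, 8 at 450 nt and 9 at 600 nt — the familiar range for this marker.
The closed form is cross-checked in the suite by Monte-Carlo simulation
of the generative model and by an independent high-precision (symbolic)
recomputation of the limit.

**Assembly.**  Nodes are the unique sequences across the input pools,
ordered by total read count (ties lexicographic) so node ids do not
depend on pool order.  All 1-step pairs are connected first; then for
each distance `d = 2 … limit`, every pair whose endpoints are not
already connected by joins of distance `< d` is linked through a path of
`d − 1` inferred intermediates (all tying pairs at a distance join, so
the total number of single-step edges equals the total path length of
the distance-truncated minimum spanning network — verified against a
brute-force oracle for up to 8 haplotypes).  Ties at a distance are
processed highest-frequency node first, which only fixes inferred-node
naming.  Inferred nodes carry positional metadata, not invented bases:
their states are underdetermined by the data.  The representative length
for the limit is the median observed sequence length.  Connected
components are reported as subnetworks; in real pools, separate
subnetworks correspond to rDNA lineages too divergent to connect — e.g.
parental lineages of different taxonomic sections co-occurring in a
hybrid or high polyploid.

## Hybrid parentage and introgression

The sharing matrix records, for every unique sequence, its count,
integer percentage and status in each sample.  Parentage scoring uses
major status on the hybrid side only: each hybrid major is assigned
`from_a`, `from_b`, `from_both` or `hybrid_specific` by identity with
*any* ribotype (major or minor) of the candidate parents, since a
parental signal may persist as a minor fraction.  The verdict is
`both_parents_detected` when at least one major traces to each side;
`hybrid_specific` majors are candidate post-hybridization derivatives.
The introgression scan lists ribotypes major in one sample and minor in
the other, with counts; no read-count threshold is imposed on what
constitutes "evidence" — published case narratives treat such fractions
case by case, and so does the scan's caller.

## The synthetic generator

`synth` emulates the statistical structure of real pools: amplicons of
~450 nt (coverable by overlapping 2 × 300 nt reads), 1–8 ribotypes per
sample at main-ribotype fractions of roughly 20–56%, pool depths from
~1,700 to ~26,000 read pairs, and hybrids formed as weighted unions of
two parents' compositions (shared sequences merged, proportions
renormalised).  Reads are drawn by a seeded multinomial over the true
proportions; the forward read is the amplicon's 5' prefix and the
reverse read the reverse complement of its 3' suffix.

Errors are substitution-only, injected per base at a flat rate
(`error_rate`, default 0.001), keeping dereplication and Hamming
semantics exact; indels, PCR chimeras, concerted-evolution dynamics and
quality miscalibration are out of scope.  Quality strings come from a
deterministic Phred profile (`mean_quality` minus `quality_decay` per
cycle, clamped to [2, 41]); by default the mean is set to
`-10·log10(error_rate)` so the profile is consistent with the injected
rate, but qualities are a *prediction*, not a record of where errors
landed — as on a real instrument.  One top-level seed expands into
per-stream seeds (assignment, forward errors, reverse errors), so
simulated FASTQ output is byte-identical across runs.

Because families built by `make_ribotype_family` mutate previously
untouched positions, all pairwise distances within a family equal sums
of step counts exactly — the generator doubles as a distance oracle for
the network tests.

**What passing tests show.**  Synthetic pools demonstrate that the
pipeline recovers planted compositions, parentage and cluster structure
under idealised noise.  They do not establish robustness to indel
sequencing error, chimeric amplicons, primer/adapter artefacts, rDNA
copy-number variation between subgenomes, or unequal PCR efficiency
between divergent templates — all of which affect real pools and are
outside the generator's model.

## Problem sizes and determinism

The end-to-end recovery check runs 20 seeded replicates of a
two-parent + hybrid design at 5,000 read pairs per pool and error rate
0.001, requiring `both_parents_detected` in at least 19 of 20 and each
planted major's dereplicated count within a 3σ multinomial band of its
truth.  With per-base error `e`, a read dereplicates onto its source
sequence only if no injected error survives merging, so the band is
`[n·p·(1-e)^{2R} − 3σ, n·p + 3σ]` (R = 300 nt read length): the lower
edge assumes no overlap-consensus correction, the upper edge error-free
recovery.  Exact 3σ multinomial agreement is asserted separately at
`error_rate = 0` and n = 10,000.  Network oracle comparisons use ≤ 8
haplotypes, where brute force is exact.  All randomness flows from
explicit integer seeds; there is no global RNG state.
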