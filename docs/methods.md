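# Methods

This note documents the models and procedures implemented in `locustrans`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Ortholog calling and the translation rate

The unit of translation is the query gene: a query with several strong
subjects still yields one call, graded `SM`/`M`, so call counts equal gene
counts. The best counterpart minimises the E-value; ties break by larger
bit score, then longer alignment, then lexicographically smallest subject
ID. `parse_alignment_table` preserves an input `0.0` as exact zero — search
tools report `0` when the E-value underflows their floating-point floor,
and that class of hits is informative enough to deserve its own bin.

**E-value bins.** The axis is partitioned into `E = 0`, `(0, 1e-100)`,
and half-open decade bins down to `[1e-10, inf)`. Interval notation like
"1e-100 < E < 1e-80" leaves boundary values unassigned; we place every
boundary in the *weaker* (larger-E) bin, so exactly one bin holds any
non-negative value. Bins weaker than `1e-60` are an extension chosen to
keep the partition exhaustive; their edges (`1e-40`, `1e-30`, `1e-10`)
align with the filter threshold and the significance threshold below.

**Specificity remarks.** Historically this grading was expert visual
inspection of alignments. The implementation is a deterministic surrogate
driven by two thresholds and three bit-score ratios (`RemarkParams`, all
configurable):

* no hits → `NA`; best `E` above `1e-5` → `UC`;
* hits at `E <= 1e-10` count as significant homologs; a single one → `UQ`;
* otherwise the gap `g` = best / second-best bit score grades
  `VS` (g ≥ 4), `S` (g ≥ 2), `FS` (g ≥ 1.3);
* with `g < 1.3`: at most 3 significant homologs → `LS`; more than 3 but
  the best/third ratio ≥ 1.3 → `SM`; else `M`.

Edge case the thresholds leave open: a best hit at `1e-5 >= E > 1e-10` is
credible but clears no significance bar, so the gap grading is undefined;
such calls are graded `UC`. The surrogate is validated only against
synthetic truth — it is an approximation of expert judgement, not a
reimplementation of it.

**Report.** `filter_translated_set` retains calls with `E` strictly below
the threshold (default `1e-30`) **and** a remark outside `{UC, NA}`.
"At or above level `FS`" is inclusive of `FS` by default (a strictness flag
exists). Rates are `100 × count / base`, rounded half-up to one decimal
(`decimal.Decimal`, not banker's rounding), on both the unfiltered and the
filtered base. An empty call set reports `rates = None` rather than zeros:
an undefined percentage is not a zero percentage. Calls with no counterpart
are tallied in the weakest E bin so bin counts always sum to the call count.

## Synteny blocks

Anchors (ortholog pairs placed on both genomes) are ordered by
within-chromosome rank, the computable stand-in for "locus ID order" —
which is why the simulator's locus IDs encode rank. Within each
(chromosome A, chromosome B) pairing the detector scans in genome-A order
and extends a chain while three criteria hold:

1. **length** — a block needs `min_anchors` anchors. The traditional
   phrasing "at least more than four" is self-contradictory; we resolve it
   as ≥ 4 (the weaker reading) and expose `min_anchors`.
2. **monotonicity** — counterpart ranks strictly increase or strictly
   decrease; strict because locus IDs are unique (two queries sharing a
   counterpart cannot be collinear). The direction is fixed by the first
   two anchors of the chain; a decreasing chain is an inverted block.
3. **gap** — start-to-start distance of consecutive anchors below
   `max_gap` (default 2 Mb) on *both* genomes. Applying it to both sides
   is the symmetric reading; nothing in the criterion singles out one
   genome.

Chaining is greedy left-to-right with restart: the maximal chain starting
at the cursor is emitted if long enough (and the cursor jumps past it),
otherwise the cursor advances a single anchor — so a block beginning in the
middle of a failed chain is still found. No anchor joins two blocks, and no
dynamic-programming/score-based chaining (DAGchainer/MCScanX style) is
used: the criteria describe consecutive collinear genes, and the greedy
reading is the faithful one. Constraints bind on anchors only; intervening
non-anchor genes are allowed. Strand is carried but ignored — the criteria
never mention it. `validate_block` re-checks all three criteria from
scratch, independent of the chaining path, and the test suite also compares
the detector against a brute-force maximal-run enumerator on random inputs.

## Tandem duplications

A tandem array is a run of same-chromosome genes sharing one best
counterpart in the other genome, with consecutive members at most
`max_intervening + 1` ranks apart (defaults: 1 intervening gene, minimum 2
members — the criterion is not standardised anywhere, so these are this
package's defaults, chosen to capture adjacent duplicates while tolerating
a single inserted gene). Family labels come from the raw hit table, not
from the per-query calls: best-hit calling keeps one subject per query, so
a duplicated family on the *subject* genome would be invisible in calls —
only one member ever appears there. The detector therefore derives a best
counterpart per query gene *and* per subject gene (same tie rules,
applied symmetrically). Sites are classified `A-only` / `B-only` / `both`;
two arrays form one `both` site when either array's counterpart is a member
of the other.

## Stress catalog

GO classes are opaque integers 1–18 (flat labels, no hierarchy reasoning).
Cues are subsets of {drought, salt, cold, misc}; `misc` models
ambiguous-cue genes (e.g. ABA- or ROS-induced) and is reported alongside
the three-set Venn, never inside it. Duplicate catalog rows merge by union
of cues and sources. "Multiple evidence" defaults to ≥ 2 sources (the
threshold is configurable; the combined GO 3/4/6 share is reported as a
count pair, leaving percentage formatting to the caller). All summaries are
permutation-invariant and sum checks (regions + misc-only = catalog size)
hold by construction.

## PPI networks

Edges are undirected, unweighted and keyed by the sorted endpoint pair;
node identity is the uppercased locus ID (no isoform handling). Merging is
idempotent; self-loops are dropped and counted. Both plausible subnetwork
rules are exposed — `induced` (both endpoints are seeds) and
`seed-plus-neighbors` (seeds, their direct neighbors, and the induced
closure among included nodes) — because published descriptions of
"sub-networks shared between datasets" are ambiguous between them; neither
is claimed to be canonical. Seed selection itself (functional-network ROC
scoring, evidence codes) is out of scope: the seed list is an input file.
Interaction modes (activation/inhibition) are not modelled.

## Synthetic data: what it emulates, and what it does not

The generator lays genes out with near-even spacing plus jitter
(non-overlapping, order encoded in AGI-style locus IDs), then plants
blocks, tandem arrays, background ortholog pairs and noise hits. Defaults
describe a mid-size comparative setting: 2 000 genes per side on 5 vs 8
chromosomes of 30 Mb, 8 blocks of 4–12 anchors with 30% inverted, 5 tandem
sites of 2–4 copies (site categories weighted 0.5/0.3/0.2 for
A-only/B-only/both, echoing the usual preponderance of single-genome
sites), ortholog fraction 0.6, one spurious hit per query on average.

The E-value model draws `log10 E` per relation class from normals
(true: mean −150, sd 25; noise: mean −4, sd 2; everything clamped to
`E ≤ 1`) with a 0.256 point mass at the literal `E = 0` for true pairs —
the share such a bin typically holds in real cross-family surveys. Within
a tandem family one base draw is shared and each extra copy index adds a
fixed +5 log10 offset, which pins the primary pair as the best hit on both
the query and the subject side; without the shared base, independent draws
would scramble family labels. E-values, identities and bit scores are
rounded to short decimal forms so that writing and re-parsing the table is
lossless.

Two guarantees are enforced at generation time, not hoped for:

* planted blocks satisfy all three detection criteria by construction
  (consecutive genes, spacing checked against the 2 Mb rule — a config
  whose spacing breaks it raises an infeasibility error rather than
  silently planting undetectable blocks);
* planted blocks are exactly the maximal collinear runs of the
  noise-free anchor set. After assembly, an internal validator
  (an independent re-implementation of the criteria) recomputes the
  maximal runs; if a background pair creates or extends a run, the
  offending pairs swap counterparts with random peers and the check
  repeats. Block flank genes are reserved so no other planted structure
  can sit immediately adjacent to a block. This is constructive rejection
  within the stated world — no parameter, threshold or count is moved.

Not emulated: sequences (only alignment statistics), evolutionary realism
(no whole-genome-duplication history, no Ks dating), and clean recovery
under noise — queries with *only* noise hits still produce (weak) calls,
so in noisy regimes spurious anchors can occasionally assemble into an
extra block or 2-gene tandem site. A green planted-recovery test therefore
establishes correctness of the detectors on well-separated signal, not
robustness to adversarial noise.

All generators take explicit seeds and share no global state; identical
configurations produce byte-identical output files.

## Numerical conventions

Coordinates are 0-based half-open internally and 1-based inclusive at GFF3
boundaries. Percentages round half-up to one decimal. E-value boundary
values belong to the weaker bin. Best-hit ties break
(E, −bit, −length, subject ID); the same key orders counterpart families.
Empty inputs yield empty outputs (empty hit file → empty list; empty call
set → zero-count report with undefined rates), never exceptions, while
malformed rows fail loudly with their line number.
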