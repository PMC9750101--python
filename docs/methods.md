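# Methods

## Model and procedure

`magrefine` treats bin refinement as iterated selection over a candidate
pool.  The pool is the union of all input bins plus hybrid bins; the
objective is the weighted single-copy marker score; dereplication (removing
a winner's contigs from all other candidates) enforces a disjoint output.

The score for one domain set is

    score = a·completeness − b·duplicate − c·multiplicate

where completeness is the fraction of the set's markers present at least
once, the duplicate term is the fraction of *present* markers that occur in
two or more copies, and the multiplicate term counts copies beyond the
second, normalised by the set size.  These three terms are disjoint by
construction: each present marker contributes once to completeness, at most
once to the duplicate term, and only its third and later copies inflate the
multiplicate term.  An alternative reading — taking "duplicates" to mean
total excess copies — double-counts second copies in both penalty terms and
was rejected; the implemented reading is locked by a unit test against an
independent recount from the expanded hit list (a profile of 90 unique
markers, 12 of them duplicated, 110 copies total against a 120-marker set
scores exactly 0.65 at default weights).

A bin is scored against both shipped domain sets and the larger value wins
(ties break toward bacteria, the first set in the mapping).  This domain-max
rule means contamination from the *other* domain is invisible to the score —
an inherent property of domain-specific marker sets, shared by comparable
refiners; it only matters for bins mixing archaeal and bacterial content.

Underlying assumptions: each input binset assigns a contig to at most one
bin (verified at run time; see the skip guard below); proteins are named
`<contig>_<orf>` as prodigal emits them; a marker hit list may contain
multiple hits per protein, of which exactly one is accepted.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `a`, `b`, `c` | 1, 0.5, 0.5 | completeness weight and the two contamination penalties; `b = c = 0.5` makes one duplicated marker cost half of one missing marker |
| `t` | 0.5 | reporting threshold; selection stops when no candidate scores ≥ t, and candidates with `a·completeness < t` are pruned (for `a = 1` a bin below 50 % completeness can never reach t) |
| `min_markers` | 20 | minimum marker genes for a bin to enter the merge scan; tiny fragments produce unstable overlap ratios |
| `overlap_threshold` | 0.8 | shared-gene proportion required to form a hybrid |
| merge `iterations` | 2 | scan rounds; each round can add many candidates, two rounds suffice to reunite a bisected genome through an intermediate hybrid |
| `evalue_cutoff` | 1e-5 | global hit filter before best-hit selection; configurable because per-model trusted cutoffs are an equally defensible convention |
| overlap `denominator` | `min` | see below |

## Design choices where the design was open

**Overlap is measured over marker-annotated genes, not marker
identifiers.**  Two near-complete bacterial bins share almost all 120
marker *identifiers* regardless of which organisms they represent, so an
identifier-based scan would merge every complete bin with every other and
the candidate pool would explode combinatorially (observed in development:
66 input bins → ~24 000 hybrids).  Counting shared annotated *genes* —
protein instances, shared exactly when the bins share the contigs carrying
them — merges only bins covering the same region of the assembly, which is
the event hybrid merging exists for.  The identifier-level utility
(`marker_overlap`) remains available for profile comparisons.

**Overlap denominator.**  The proportion is relative to the smaller bin's
gene count (`min`), so a fragment scores 1.0 against a superset bin —
exactly the fragment-reunification case.  `union` (Jaccard) and `query`
are selectable for users who want symmetric-strict or directional
behaviour.  "Reaches the threshold" is implemented inclusively (≥ 0.8) so
the printed default is attainable exactly; a flag switches to strict.

**Round 2 pairs hybrids with originals only**, not hybrids with hybrids:
pairing hybrids with each other adds nothing a later round with originals
cannot, while squaring the pool size.

**Tie-breaking.**  Equal-score candidates are ordered by more unique
markers, then fewer contigs, then lexicographic id.  Any deterministic
order is defensible; this one prefers information-dense, compact bins and
guarantees byte-identical reruns.

**Pruning** uses `a·completeness < t` rather than `completeness < t` so the
justification (a pruned bin can never reach the reporting threshold,
because completeness is non-increasing under contig removal and
`score ≤ a·completeness`) survives user-set `a ≠ 1`.

**The re-scoring skip** between consecutive same-set winners is only sound
when every input binset is a partition: then the previous winner's contigs
cannot occur in another bin of its own set, so the current winner's score
is still current.  The guard is checked once at start; a non-partition
input disables the skip with a logged notice.  A hybrid win never skips,
since a hybrid's contigs span several sets.  The skip can leave *other*
candidates with stale (over-estimated) scores, so it may in principle alter
the selection relative to full re-scoring; it is on by default, a flag
turns it off, and the oracle-equivalence guarantee (below) is stated for
the skip-off configuration.

**Degenerate cases.**  The duplicate ratio 0/0 of an empty profile is
defined as 0, so an empty bin scores 0 rather than NaN.  Protein ids
without an ORF suffix map to themselves, with a once-per-run warning.
Identifiers are opaque and case-sensitive throughout.

## Correctness oracle

`refine_naive` re-scores every candidate every round, with no incremental
bookkeeping, no pruning and no skip.  `refine` with the skip heuristic off
must reproduce its selected list exactly — ids, order and scores.  The test
suite and the acceptance script check this on 200 randomized communities
(6 genomes, 8 contigs each, down-scaled 40/20-marker domain sets so that
completeness spans the full range at small profile sizes; ≤ 50 candidate
bins per instance).

## The synthetic benchmark

The generator emulates only what the algorithm consumes: a known
contig-to-genome truth, markers scattered uniformly over each genome's
contigs (the algorithm never uses gene coordinates, so spatial clustering
is irrelevant), a small duplicate-marker rate, and per-binner noise applied
to the true partition:

* **split** — an even bisection with random membership (real split events
  yield substantial fragments, not single stray contigs);
* **merge** — a genome fused into an earlier bin of the *same domain*.
  Binners fuse compositionally similar genomes; a wholesale cross-domain
  fusion would also be invisible to the domain-max score by construction,
  which is not the error mode this caricatures.  Within-domain fusion is
  precisely the case the duplicate penalty is designed to catch;
* **dropout** — per-contig omission (unbinned contigs);
* **contamination** — a bin steals contigs from other bins, so every
  simulated binset remains a partition, as real binners produce.

All sampling uses Python's integer-based `random.Random`, so a fixed seed
reproduces bit-identically across platforms.

The three default binner caricatures mirror the qualitative contrasts
reported for popular tools — greedy (high completeness, high
contamination: split 0.05, merge 0.08, dropout 0.02, contamination 0.08),
cautious (very pure, incomplete: split 0.25, dropout 0.08), balanced
(split 0.08, merge 0.05, dropout 0.04, contamination 0.03).  The standard
benchmark community is 20 genomes (20 % archaeal), 30 contigs per genome,
full domain marker sets, 2 % marker duplication.  These sizes keep the
whole pipeline and its tests in the seconds range while leaving every
mechanism (merging, dereplication, pruning, the skip) exercised.

What passing on this fixture does **not** show: performance on real
assemblies, where marker annotation is noisy, contigs vary in length
(completeness by contig count ≠ completeness by genome fraction),
chimeric contigs exist, and strain mixtures blur the genome concept.  The
fixture validates the algorithm's logic, not its ecological accuracy.

The shipped marker-set files carry synthetic placeholder identifiers with
the canonical set sizes (120 bacterial, 53 archaeal).  Scoring depends
only on set membership, so every identity and invariant holds verbatim;
real analyses must supply the marker lists matching their annotation HMMs.

## Known limitations

* Cross-domain chimeras are invisible to the score (domain-max rule).
* Completeness is marker-based; a bin can be 100 % marker-complete while
  missing accessory genome content.
* Dereplication assigns a shared contig to the earlier (higher-scoring)
  winner; there is no coverage- or composition-based arbitration.
* The merge scan is O(bins²) per round; for extreme inputs (hundreds of
  thousands of bins) an inverted index over genes would be the next step.
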