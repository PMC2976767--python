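# Methods

This note documents the models, conventions and numerical choices behind
`barcomm`, in the order data flow through the pipeline.

## Inputs and taxonomy

A community is described by a four-rank taxonomy (species → genus →
family → order), read from TSV and validated for strict nesting: species
unique, each genus in exactly one family, each family in exactly one
order. Sequences arrive as per-marker FASTA with `sampleID|speciesCode`
headers (a bare code serves as both). When several samples per species
exist, one representative per (species, marker) is chosen: the longest
sequence, ties broken by the lexicographically smallest sample id. This
rule is deterministic in the record multiset, so input order never
changes results.

## Alignment strategies

Each barcode locus gets the treatment its biology demands:

* **Coding, indel-free (rbcLa-like).** Equal-length inputs stack
  directly — with no indel variation the alignment is the identity.
  Length variation (partial sequences) falls back to the progressive
  aligner below.
* **Coding, unknown frame (matK-like).** Each sequence is read in the
  frame (offset 0/1/2) minimizing internal stop codons, ties to the
  lowest offset; translation uses the bacterial/plastid code (table 11).
  A sequence whose best frame still leaves >5% of codons as stops is
  excluded and logged — it is unlikely to be clean coding sequence.
  Proteins are aligned and gaps mapped back in codon triples; leading
  offsets and trailing partial codons are padded with gaps into whole
  triples, so the output length is ≡ 0 (mod 3) and deleting gaps from
  any row reproduces the input exactly.
* **Spacer (trnH-psbA-like).** Spacers are alignable only among close
  relatives, so records are grouped by family (or order) and each group
  aligned independently. Groups with a single species are omitted: a
  lone spacer has nothing to align against and would contribute only
  autapomorphic noise.

The built-in aligner is progressive: pairwise/profile Needleman–Wunsch
with affine gaps (match +1, mismatch −1, gap open −2, extend −1; the
open score is the first gap column's cost), columns represented as
fractional state frequencies (IUPAC codes spread over their states,
wildcards scoring 0), merged along a UPGMA guide tree built from 8-mer
Jaccard distances. The recurrence is vectorized per row; the
within-row affine dependency is resolved with a prefix-max transform.
This aligner is intentionally simple and self-contained; any external
aligner producing aligned FASTA can be dropped in instead, since
downstream stages only consume aligned blocks.

## Supermatrix

Blocks are concatenated in input order; partitions are tracked 0-based
half-open internally and exported 1-based inclusive as NEXUS charsets
(also relaxed PHYLIP and a partition-per-column-group CSV; NEXUS and CSV
round-trip bit-exactly). Absent cells are `?`. Gaps are **not** coded as
characters; `?` and `-` are both scored as missing everywhere
(`missing_fraction` counts both, including terminal padding). A species
whose only data lie in partitioned spacer blocks is excluded — with no
globally aligned anchor locus its placement would rest entirely on a
family-local alignment. The rule is vacuous in a spacer-only analysis.

## Constraint tree

The ordinal backbone (rooted Newick, tips = order names, possibly only
partially resolved) is expanded by replacing each order tip with a
polytomy over that order's included species; empty orders are pruned,
single-species orders become pendant tips. Compatibility is defined on
rooted clades: a candidate is compatible iff every non-trivial constraint
clade is a clade of the candidate. Rooted semantics were chosen because
the backbone supplies the root a priori; order names are kept as internal
node labels for readability but ignored in comparisons.

## Parsimony scoring

Characters are 4-bit state sets (A=1 C=2 G=4 T=8; IUPAC codes partial
sets; `?`, `-`, `N` full sets). At binary nodes the Fitch
intersection/union rule applies; at polytomies Hartigan's majority-vote
generalization (cost = #children − max state votes). Both are exact for
unit-cost unordered characters, which the test suite verifies against
brute-force enumeration of internal state assignments, including
polytomies and ambiguity. Duplicate columns are collapsed with summed
weights before scoring; optional integer column weights multiply
per-column costs (this is also how the ratchet's upweighting is
implemented).

## Constrained search

`random_addition_tree` inserts taxa in seeded random order, each at the
constraint-compatible position of minimum tree length (ties to the first
candidate edge in postorder). Candidate evaluation re-scores only the
path from the insertion edge to the root using cached Fitch sets, with
early exit when a recomputed state set matches the cache.

`ratchet_search` then runs, per addition replicate: an NNI(+SPR)
first-improvement hill-climb on the original weights; then
`ratchet_iterations` cycles of (i) hill-climb with a seeded random
`perturb_fraction` of columns upweighted by `perturb_weight`, (ii)
hill-climb again on original weights. Every rearrangement is filtered
for constraint compatibility via integer tip-bitsets. All distinct trees
attaining the pooled minimum score are retained (canonical-form
deduplication, deterministic eviction above `max_retained`, default
10,000). Defaults follow Nixon's published scheme: 200 addition
replicates, 50 ratchet iterations, 25% of columns upweighted ×2. Branch
swapping is NNI + SPR; TBR is omitted as unnecessary at desk scale. The
SPR neighborhood can be subsampled per sweep (`spr_sample`) to bound the
O(n²) move set on larger trees.

`exhaustive_constrained_search` enumerates every binary refinement of the
constraint (product of (2k−3)!! resolutions per polytomy) and serves as
the exact reference for small instances.

## Consensus and support

The 50% majority-rule consensus keeps clades with frequency strictly
above the threshold; node support is the clade frequency as a percentage,
rounded half up. Support values are clade frequencies among the pooled
equally-most-parsimonious trees — a search-based support, not a
bootstrap. A majority-rule-extended variant (greedy addition of
compatible minority clades by descending frequency) is available but off
by default.

## Metrics conventions

* **Resolution** = 100·(I−1)/(n−2) with I internal nodes including the
  root: 100 for a fully binary rooted tree, 0 for a star. Whether the
  root should count is not derivable from common usage; this formula is
  one consistent convention and is stated prominently because reported
  resolution percentages depend on it.
* **Support bins** reproduce the cumulative, overlapping six-column
  layout (<50, >50, 50–70, >70, 70–85, >85) over non-root internal
  nodes. Boundaries: `<50` strict; the `>` columns include their bound
  (≥); the range columns are half-open ([50,70), [70,85)). Hence
  (<50)+(>50)=100 and (50–70)+(>70)=(>50) up to rounding.
* **Monophyly**: a taxon is monophyletic iff the smallest clade
  containing its tips contains no others; single-tip taxa are reported
  as singletons (trivially monophyletic).
* **Misplaced orders**: the tree is reduced to one exemplar tip per
  order (for a non-monophyletic order, the tip topologically closest to
  the order's MRCA, ties lexicographic, and the order is flagged
  misplaced by definition). The largest order subset on which the
  reduced tree and the pruned backbone induce identical rooted
  topologies is found exhaustively up to 12 orders and by seeded
  simulated annealing above; the complement is the misplaced set.

## Recovery and identification

Recovery tables roll per-(sample, marker) success flags up the
hierarchy: a taxon succeeds if any member does; marker-union columns
apply "any marker" per sample before the rollup. Totals at species and
coarser ranks come from the full taxonomy, so never-sampled taxa count
against the rate, as in a community census.

Leave-one-out identification queries each sequence against all others
with a global pairwise aligner (same scores as the MSA engine, end gaps
free); identity = identical aligned bases / shorter sequence length. A
query is correct at a rank iff **all** tied best hits share its taxon at
that rank — ties spanning taxa are conservatively wrong. A species with a
single sequence can therefore never be species-correct (no conspecific
exists) but can be correct at coarser ranks. BLAST can be substituted
via the `similarity` hook; the built-in kernel keeps the package
self-contained. Recovery×CI is the product of the recovery proportion
and the CI frequency, reported as an integer percent (round half up,
matching the published convention).

## Synthetic communities

The generator emulates a scaled-down tropical-plot barcoding campaign.
Defaults: 6 orders × 2 families × 2 genera × 1–2 species (≈36 species;
the real community this emulates had species/genus ≈ 1.3, so most genera
are small), three loci of 520 / 450 / 801 bp with rate scalings 0.5
(rbcLa, JC69), 1.5 (trnH-psbA, K2P κ=2 plus geometric indels at 0.1
events/site/substitution), 1.0 (matK, K2P), and per-species dropout
{rbcLa 0.10, trnH 0.08, matK 0.30} chosen near the published per-marker
failure rates. The true tree glues per-rank coalescent-style ultrametric
radiations with stem-depth budgets 0.10 / 0.05 / 0.03 / 0.015 expected
substitutions per site (order stems deepest), giving within-genus
divergences of a few substitutions per locus and deep-order divergences
around 0.2–0.4 — realistic orders of magnitude for plastid barcodes.
Coding loci draw their root from the 61 sense codons so frame detection
sees a genuine ORF. Substitutions use exact JC69/K2P transition
probabilities per branch (testable against the closed forms), not event
simulation. Discordance injection regrafts one species from each of k
donor genera onto a congeneric genus' stem in the same family, breaking
exactly k genera while preserving family and order monophyly.

What the simulation does **not** emulate: rate heterogeneity across sites
(Γ), codon models, coalescent gene-tree discordance, sequencing error,
or misidentified vouchers. Passing the end-to-end tests therefore shows
the machinery is correct and the constraint behaves as designed, not
that real communities will reach the same recovery rates.

## Problem sizes used by tests and the acceptance script

These are the package's desk-scale study conditions: 5–6-taxon matrices
against full brute-force enumeration; 100 seeded 8-taxon instances with
a two-order constraint (225 compatible refinements) for ratchet-vs-
exhaustive comparison (the ratchet uses 3 replicates × 5 iterations
there); ten 60-species communities (5×2×2×3) with zero dropout for
end-to-end parameter recovery, searched with 1 replicate × 2 ratchet
iterations and SPR subsampled at 120 moves — ample for a constrained
60-taxon problem with clean signal, as the recovery results show.

## Known limitations

* The progressive aligner has no iterative refinement; on highly
  divergent spacers its family blocks depend on guide-tree quality.
* Hill-climbing uses first improvement with full re-scoring per
  candidate; very large communities (many hundreds of taxa) would want
  incremental rescoring for SPR as well as addition.
* Equally-most-parsimonious tree counts depend on search thoroughness
  and the retention cap; they are not comparable across implementations.
* The misplaced-orders annealer is heuristic above 12 orders; the count
  it reports is an upper bound on the true minimum in that regime.
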