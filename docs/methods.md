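# Methods

## Signal model

The package treats the distance between two homologous gap-free blocks as
a parsimony character. For a pair of quartet blocks `(B1, B2)` in
sequences `S_i, S_j, S_k, S_l`, the character state of taxon `ι` is the
inter-block distance `D_ι = k2 − k1 − ℓ1` (segment length between the
blocks). Under the assumption that both blocks are true homologies, any
difference between two `D` values requires at least one indel on the path
between those two leaves since their divergence. On an unrooted quartet
this gives a clean case analysis over the multiset of the four distances:

| distance multiset | call | minimal indel events |
|---|---|---|
| `{a,a,b,b}`, `a≠b` | strong support for the equal-pairs topology | 1 (alternatives: 2) |
| `{a,a,b,c}`, `a,b,c` distinct | weak support for the equal-pair topology | 2 on every topology |
| `{a,a,a,a}`, `{a,a,a,b}`, `{a,b,c,d}` | uninformative | 0 / 1 / ≥2 on every topology |

Distances are compared by exact integer equality — the signal is "equal
vs. different", never magnitude. Weak support is justified
probabilistically rather than by parsimony: if an indel occurs on each
branch independently with probability `p < 0.5`, the topology pairing the
two equal distances has the highest likelihood even though all three
topologies tie at two events. `min_indel_events` implements quartet small
parsimony over an unbounded integer alphabet (Fitch on the single internal
edge) and is verified exhaustively against internal-state enumeration.

## Block discovery

Spaced words are projections of sequence windows onto the match positions
of a binary pattern. Windows containing any non-ACGT symbol produce no
occurrence (the don't-care score would be undefined). The default
reference pattern has length 110 and weight 10, with match positions at
offsets 0, 12, …, 108: the pattern shape is deliberately deterministic and
evenly spread — reproducibility is preferred over pattern optimisation,
which this package does not attempt. Scores at the 100 don't-care
positions use a symmetric nucleotide matrix (positive diagonal, negative
off-diagonal; the widely used values A/A = 91, C/C = G/G = 100, T/T = 91,
A/C = −114, A/G = −31, A/T = −123, C/G = −125, C/T = −31, G/T = −114),
loadable from a plain-text file for exact substitution. With 100
don't-care positions, homologous matches score strongly positive while
background matches are expected negative, so the strictly-positive anchor
filter removes nearly all random blocks.

Sampling visits spaced words in a seeded random order; for each word with
occurrences in ≥ 4 distinct sequences one quartet is drawn (random anchor,
three random other sequences, one random occurrence each), retried up to
five times if the positive-score filter fails, up to `max_blocks` total.
This makes runs reproducible from a single seed while matching the
"sample up to a cap" semantics of block-based alignment-free tools.
Scanning is forward-strand only; a reverse-complement scan would be a
straightforward extension but is not a default behaviour of the method.

Second blocks use pattern `1111111` (exact 7-mers) inside a window of
`L = 500` nt starting immediately after the reference block, clipped at
the sequence end. Candidate words must occur exactly once in each of the
four windows; candidates are ordered by start position in the reference
block's anchor sequence, ties broken lexicographically, and the first is
taken. No score filter is applied to second blocks: the chance of a
spurious common unique word in four short windows is small. The
uniqueness requirement applies to the second block's word only. Second
blocks are only searched to the right of the reference block; leftward
windows would duplicate pairs without adding information.

## Tree building

**Character matrix.** Each informative pair is one column; within a
column, distances map to symbols `'0'`, `'1'`, `'2'` in first-seen order
over ascending taxon order, and uninvolved taxa are `'-'` (missing).
Missing cells receive the full state set in Fitch (the standard treatment
of missing information), so they never contribute changes. Weak columns
cost exactly 2 on every topology and therefore cannot change the optimum;
they are included by default for completeness of the encoding, and a
strong-only flag reproduces the stricter regime. Fitch scoring roots the
unrooted tree along a leaf edge and is exact for fully resolved trees; it
is vectorised across columns.

**Parsimony search.** Up to 8 taxa the search enumerates all unrooted
topologies (10,395 at 8 leaves) and is therefore globally optimal. Beyond
that, stepwise addition followed by tree-bisection-reconnection (TBR)
hill-climbing from four seeded addition orders is used; on random
instances with ≤ 8 taxa it matches the exhaustive optimum in every trial
of the test suite. Ties between equally parsimonious trees are broken by a
deterministic canonical ordering of the trees' bipartition sets — the
reproducible analogue of "take the first reported tree".

**Quartet amalgamation.** The supertree heuristic recursively bipartitions
the taxon set by a weighted max-cut: each quartet call votes +w for a cut
that separates its two cherries intact and −w for every cherry the cut
splits. Cuts are enumerated exhaustively up to 16 taxa and found by
seeded local search with restarts beyond. Both sides of a cut must hold
at least two taxa, which guarantees the recursion shrinks; each side is
resolved with a placeholder leaf standing for the opposite side (so
three-in-side quartets keep their attachment information) and the two
halves are joined at the placeholder positions. Four-taxon subproblems
are decided by weighted majority. On a conflict-free, fully covering
quartet set the result displays every input quartet. The quartet list can
be exported (one `a,b|c,d` line per call, repeated by multiplicity) for
external amalgamation tools, and the character matrix as relaxed PHYLIP
or NEXUS for external parsimony programs.

## Evaluation

Quartet correctness is the percentage of informative calls whose topology
equals the reference tree's induced quartet, counted per call; coverage is
the percentage of all `C(N,4)` four-taxon sets with at least one
informative call. Calls whose induced reference quartet is unresolved are
counted as incorrect but also reported separately, since conventions
differ. RF distances go through dendropy's bipartition comparison and are
normalised by `2N − 6`.

## Synthetic data

The generator evolves a uniform-random root sequence along a Newick tree:
Jukes–Cantor substitutions (branch length = expected substitutions/site),
indels as a Poisson process with rate `indel_rate` events per site per
unit branch length, geometric lengths (mean 5), insertion/deletion
equiprobable, uniform positions, every event logged. Defaults are a
balanced 8-taxon tree with 0.01 substitutions/site per branch, a 50 kb
root and `indel_rate = 0.05` — i.e. one indel event per twenty
substitution events, within the empirically reported range for nuclear
DNA, and pairwise divergences comparable to the low-divergence bacterial
data sets on which block-based methods work well. The recovery experiment
samples 20,000 reference blocks per replicate, a desk-scale stand-in for
the millions used on real multi-megabase genomes; at these settings
roughly 2% of block pairs are informative, enough to cover nearly all 70
quartets of 8 taxa.

The generator omits rearrangements, duplications, rate heterogeneity,
GC bias and heterotachy. Passing recovery tests therefore shows that the
pipeline converts indel events between conserved blocks into the correct
topology under neutral homologous evolution — not that it is robust to
repeats or segmental duplications, which can pair non-homologous block
occurrences in real genomes (mitigated, but not eliminated, by the
positive-score anchor filter and the uniqueness rule for second blocks).

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open internally; 1-based only in
  human-readable TSV reports.
* A pattern must start with a match position; the empty pattern is
  rejected.
* `D < 0` (overlapping blocks) cannot arise by construction and is
  rejected defensively.
* Sequence sets require `N ≥ 4` and unique taxon ids; ambiguous bases are
  skipped at indexing time rather than scored.
* All randomness (sampling, heuristic restarts, simulation) flows through
  numpy `default_rng` seeds recorded in output headers; equal seeds give
  byte-identical outputs.

## Known limitations

* Only quartet blocks (four-way) are used; blocks involving more
  sequences are future work.
* Indel lengths are not modelled — only equality/inequality of distances.
* The supertree heuristic is a self-contained max-cut scheme, not a
  re-implementation of any specific external amalgamation program; for
  publication-grade supertrees the exported quartet list can be fed to a
  dedicated tool.
* In-memory indexing targets desk-scale inputs (tens of megabases), not
  gigabase genomes.
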