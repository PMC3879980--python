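# Methods

## The model: gene flows on rooted rings

A **flow graph** is a rooted DAG whose leaves are taxa. Edges carry gene
flows from ancestors toward descendants; a node with in-degree ≥ 2 (a
*merge*) represents a symbiotic/endosymbiotic convergence of two
lineages, which is what makes the graph a ring rather than a tree. A
binary character — a gene family's presence/absence vector, or the
residue-vs-gap state of a shared indel — is explained by:

- exactly **one gain site**, an edge or the root, where the character
  originates (for paralog pairs, by duplication from the partner that
  predates the split), and
- a set of **loss edges**, each of which blocks flow through that edge
  only.

A leaf carries the character iff at least one directed path from the
gain site to the leaf contains no loss edge. This is Dollo logic
generalized to DAGs: single origin, arbitrary losses, but on a ring a
flow can survive a loss by arriving along the other arc — which is
exactly why some distributions that force losses on every tree fit a
ring with none.

### Parsimony search

Gains are fixed at one per character; the optimization minimizes the
number of loss edges, and the reported score is gains + losses. The
search is exact: every gain site is tried (root first, then edges in
sorted order), and for each site the minimal cut is found by
branch-and-bound on *offending paths* — while any absent leaf retains a
loss-free path, branch over which edge of that path to cut, pruning
branches that disconnect a present leaf or reach the incumbent bound.
Graphs in this problem domain have ≲ 20 edges, so exact search is
instant. Ties are broken deterministically: lexicographically smallest
(gain site id, sorted loss edge ids), with the root sentinel sorting
before any edge. The test suite proves the search equal to plain
exhaustive enumeration over (gain site, loss subset) on 500+ random DAGs
of ≤ 12 edges.

Characters are scored independently and unweighted. Probabilistic
gain/loss models, multi-gain parsimony and branch lengths are
deliberately out of scope.

## The two-urn rooting test

For a candidate root, the K marked sequences (the members of the two
contrasted groups, K = x₁ + x₂) are imagined distributed between two
equal urns of n = N/2 sequences drawn without replacement from the N
available — a hypergeometric null. The observed marked count in the
larger urn is x_obs = max(x₁, x₂). Because n = N/2 makes the
distribution symmetric about K/2, the two-sided probability is

    p = 2 · Σ_{x ≥ x_obs} C(K,x) C(N−K, n−x) / C(N,n),   x_obs > K/2,

capped at 1, and p = 1 at or below the center. For unequal urns (not a
standard design here) the implementation instead sums all outcomes no
more probable than x_obs and documents that choice.

**Numerics.** Headline values reach 10⁻⁷⁹⁴, far beyond double-precision
underflow, so everything is carried in natural logs. The pmf over the
support is built from the exact ratio recurrence
pmf(x+1)/pmf(x) = (K−x)(n−x)/((x+1)(N−K−n+x+1)) accumulated in log
space and normalized with log-sum-exp; this avoids the cancellation of
three ~10⁵-magnitude log-gamma terms and keeps Σ pmf = 1 at machine
precision up to N = 10⁴ and beyond. Tails are log-sum-exp sums. Results
carry (log₁₀ p, p) pairs; p itself may print as 0 when it underflows,
the log form never does. Infeasible x returns a −∞ sentinel. Odd
populations are rejected by default (the equal-urn design needs N even);
an opt-in floors n = ⌊N/2⌋ with a warning.

For the ParC census the marked count is parameterized conservatively:
N = 8,014 sequences, K = 2,288 (2,249 AD-side + 39 euryarchaeal unique
species), with the 376 + 256 uncharacterized/probable-DM species
excluded from K; the census record keeps the exclusion explicit so other
parameterizations can be tried. Any reasonable variant stays hundreds of
orders of magnitude below significance.

## Informative patterns and ranking concordance

A presence/absence pattern over n super-taxa is **phylogenetically
informative** when ≥ 2 taxa carry the gene and ≥ 1 lacks it; singletons,
ubiquitous and absent families carry no grouping signal and are tallied
separately. There are 2ⁿ − n − 2 informative patterns (25 for n = 5),
listed canonically by decreasing presence count, then lexicographically.
A gene counts as present in a super-taxon if ≥ 1 member taxon has it.

Each gain site of a ring floods a fixed leaf set — its **flow
signature**, expressed as a pattern. Signatures that are non-informative
(e.g. the root's, which floods everything) are flagged and excluded;
duplicate signatures are reported, never silently merged. The
concordance question is whether the k predicted signatures are exactly
the k largest counts in an independent ortholog tabulation. Under the
null of a uniformly random ordering of the n patterns (no
count-magnitude weighting), p = k!(n−k)!/n! = 1/C(n,k), computed as an
exact rational. A tie spanning the k-th boundary makes the match
indeterminate and is reported as such, never broken silently.

## Indel characters

Indel calling operates in alignment-column space (0-based, half-open).
A column is *mixed* when some rows are gapped and some are not. At the
default purity 1.0 a call is a maximal run of mixed columns with an
identical gap-row set throughout; extending the range one column breaks
uniformity, and calls never overlap. Purity < 1 relaxes this per row: a
run is accepted if every row is gap (or residue) in ≥ purity of its
columns. The default `min_width = 2` suppresses single-column alignment
noise — real diagnostic indels are clean multi-column blocks.

Two deliberate rules: gene absence is **metadata** from the label table,
never inferred from an all-gap row (absence annotations are not
sequences); and characters are stored **unpolarized** — deciding whether
the residue side is the insertion requires the rooted graph, which is
downstream of this module. Composite labels in the packaged blocks are
expanded explicitly (one Firmicutes row stands for Bacilli and
Clostridia, one Archaebacteria row for Halobacteria and Eocyta; the
Thermoprotei row is assigned to the eocytes since Thermoprotei are the
Crenarchaeota). When present and absent evidence meet at the same
super-taxon, presence wins (≥ 1 member suffices).

## The synthetic-data generator

The generator emulates the *structure* of whole-genome ortholog tables
and paralog alignment blocks, not sequence realism. Families are
assigned to gain sites by fixed allocation (a multinomial option
exists); losses are drawn independently per family × edge at a single
rate — the simplest null consistent with treating losses as rare,
unlikely events; presence follows the same path-reachability semantics
as the parsimony stage, so truth records are exact. Defaults:

- **ring**: the packaged five-super-taxon ring, six gain sites with six
  distinct informative signatures;
- **allocations**: 263 families for the A+D flow — the scale of the one
  published whole-genome pattern count — and a decreasing series
  (190, 150, 120, 90, 60) for the remaining sites, chosen once as a
  realistic spread of flow sizes;
- **loss rate 0.02** per family per edge (losses are rare);
- **alignments**: length 40, uniform background over the 20 amino
  acids, per-site substitution noise 0.1, planted gap width 2–6.

Alignment simulation shares one random consensus across taxa, applies
independent substitution noise, and plants a single gap block in the
absent-side taxa, recording its coordinates.

What passing recovery tests shows: the pipeline identifies the
generating ring and its signatures when its own model assumptions hold.
What it does not show: robustness to rate heterogeneity across
families or edges, alignment error, paralog misassignment, or
non-uniform amino-acid composition — none of which the generator
emulates.

## Problem sizes and numerical choices

Graphs: ≤ ~20 edges (exact search); the exhaustive-oracle property test
uses ≥ 500 random DAGs of ≤ 12 edges. Hypergeometric enumeration oracle:
all parameter combinations with N ≤ 12. Permutation nulls are fully
enumerated up to n = 7. Recovery experiments use 10–50 replicates of a
few hundred families, deduplicating realized patterns before scoring so
each unique pattern is solved once. All stochastic components take a
single integer seed; identical seeds give byte-identical outputs.

## Known limitations

- Parsimony is exact but exponential in the worst case; the
  branch-and-bound is meant for desk-scale graphs, not networks with
  hundreds of reticulations.
- The two-urn test assumes the sequence census is an unbiased sample of
  the two sides; database composition bias is not modeled.
- The ranking-concordance null ignores count magnitudes; a weighted
  null would be stricter but has no closed form.
- Newick IO covers tree-shaped graphs only; rings round-trip through
  the edge-list format, since Newick cannot express merge nodes.
- The five-taxon ring shipped in `datasets` is a reconstruction from
  published flow descriptions, and the pattern tables the examples
  tabulate are simulated; no claim is made that they reproduce any
  specific whole-genome tabulation.
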