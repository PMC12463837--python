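# Methods

## Lexical distance

The unit of comparison is the gloss: a standardized meaning slot whose
translation is collected in every language variety of a wordlist. For two
forms the normalized Levenshtein distance LDN = lev(a,b)/max(|a|,|b|) uses
strict unit-cost edit distance (insert/delete/substitute, no
transpositions) over Unicode code points. Code points — not grapheme
clusters or digraph tokens — are the character unit because they are
deterministic across platforms and need no language-specific tokenizer;
the cost is that a digraph substitution (e.g. *ny* → *ch*) counts as two
edits. Forms are normalized before comparison: Unicode NFC, casefold,
whitespace trimmed and collapsed, and multi-variant cells ("maji/mto")
resolved to the first listed variant. Multi-word forms are compared
verbatim, space included.

The variety-pair distance is the mean LDN over the glosses where both
varieties have a form (pairwise-complete). Each pair therefore averages
over its own gloss set; the `support` matrix records that count so users
can see how much evidence backs each entry. `min_shared_glosses`
(default 1) turns thin support into a hard error rather than a silent
low-quality estimate. Length-normalized LDN does not satisfy the triangle
inequality in general and nothing downstream assumes it does.

## Structure recovery

**Classical MDS.** Torgerson's method: double-center the squared-distance
matrix, eigendecompose, scale the top-k (k = 2 or 3) eigenvectors by the
square roots of their eigenvalues. LDN matrices are typically
non-Euclidean, so negative eigenvalues occur; they are excluded from the
coordinates but reported in full so the user can judge distortion, and the
residual sum of squared distance discrepancies is reported as `stress`.
Sign indeterminacy is resolved by flipping each axis so that the
lexicographically smallest variety has a nonpositive coordinate —
embeddings are then bit-reproducible across runs and platforms.

**Agglomerative clustering** uses scipy's hierarchical clustering on the
precomputed distances. Both average linkage and Ward are exposed because
both are defensible on lexical matrices; the default is average linkage
(Ward's variance interpretation presumes Euclidean geometry that LDN does
not satisfy). Ward operates directly on the supplied distances with merge
heights in distance units (the ward.D2 convention). Dendrogram Newick
branch lengths are merge-height differences with leaves at height 0.
Cutting at k removes the k−1 highest merges.

**Neighbor joining** is the standard Saitou–Nei agglomeration with the
Q-criterion and two-point branch-length formulas, returned unrooted with a
trifurcating root node. It is exact on additive matrices (property-tested
against randomly generated trees). On non-additive input negative branch
lengths can arise; they are clamped to 0 and the node is flagged rather
than silently altered. Ties in the Q minimization break on the lowest
(row, column) index pair in the current ordering, for bit-reproducibility.

## Matrix comparison

The Mantel statistic r is the Pearson correlation of the vectorized strict
lower triangles; the permutation null jointly permutes rows and columns of
the second matrix, and p = (#{|r*| ≥ |r|} + 1)/(n_perm + 1) (two-sided
default, 9,999 permutations). With n populations there are only n!
distinct permutations, so at n = 3 the achievable p-values are extremely
coarse (≥ 1/6 one-sided); the implementation documents rather than hides
this. When label sets differ the test runs on the sorted intersection and
logs the dropped labels.

The confidence interval for r is a gloss-level percentile bootstrap:
glosses are the sampling unit of a wordlist, so each replicate resamples
glosses with replacement, rebuilds the LDN matrix and recomputes r; the
2.5/97.5 percentiles over (default) 1,000 replicates form the interval.
Replicates in which any pair loses all shared glosses, or whose matrix
degenerates to a constant, are discarded and counted. Coverage is checked
by simulation in the test suite.

Geographic matrices use the haversine great-circle distance with Earth
radius 6371.0088 km between user-supplied homeland centroid coordinates;
no coordinate gazetteer is bundled.

## Prioritization

Maximin (farthest-point) selection starts from the pair attaining the
matrix maximum and greedily adds the variety with the largest minimum
distance to the panel; its final coverage radius carries the classic
factor-2 guarantee relative to the optimal panel, which the tests verify
against exhaustive search at small n. Medoid selection returns, per
cluster of a supplied partition, the member minimizing the summed distance
to co-members. All ties break lexicographically.

Bridge intermediacy is s = 1 − d_nearest/d_second, where the two values
are the mean distances to the variety's own cluster co-members and to the
closest foreign cluster, ordered so d_nearest ≤ d_second. s near 0 marks a
variety sitting between clusters (the bridge signature); s near 1 marks a
well-nested variety. The score is computed from the distance matrix
directly, not from MDS coordinates, which are orientation-dependent and
lossy. Reports mark s < 0.15 as bridges by default (tunable). Singleton
clusters have no within-cluster distance; their s is reported as missing.

## Synthetic data generator

`synthlex` emulates a multi-family wordlist: per gloss, a random root word
evolves along a balanced two-level tree (root → family ancestors at branch
length `between_family_depth`, ancestors → varieties at
`within_family_depth`) via an i.i.d. per-character edit process with event
probability min(1, rate × branch length) per character; an event is a
substitution with probability 0.8, a deletion with 0.1, or an insertion
with 0.1 — substitution-dominated, as in orthographic divergence of
related forms, and a word is never allowed to vanish entirely. Missing
cells are dropped uniformly at random. An optional hybrid variety copies
each gloss from one of two donor families with the configured mixing
proportion, emulating heavy lexical borrowing.

Reference condition (the package defaults): 3 families × 4 varieties,
60 glosses, root words of 6 lowercase letters, edit probability 0.12 per
character per unit branch length, depths 0.3 within vs 3.0 between
families, 5% missingness. Sixty glosses is the scale of a typical core
vocabulary list; the 10× depth contrast yields mean within-family LDN
≈ 0.1 versus between-family ≈ 0.6–0.7, matching the block structure seen
in real multi-family matrices. The pseudo-F_ST generator rescales tree
path lengths to [0, 0.2] (a realistic range for strongly differentiated
human populations) and mixes them with independent uniform noise at the
configured coupling; it is a rescaled tree metric, not a coalescent
quantity, and exists to exercise the matrix-comparison machinery.

What the generator does not emulate: sound-correspondence structure,
borrowing gradients beyond the single hybrid, gloss-specific evolutionary
rates, and non-uniform missingness. Passing tests therefore demonstrate
the pipeline's correctness and its behavior under controlled divergence,
not performance guarantees on any particular real wordlist.

## Numerical and design choices

- Distance matrices are validated on construction (symmetry, zero
  diagonal, nonnegativity, [0, 1] range for lexical/genetic kinds);
  asymmetric input is refused, not repaired.
- Missing-cell tokens default to {"", "NA", "?"}, configurable; delimiter
  is auto-detected between comma and tab with an override flag.
- All stochastic operations take explicit integer seeds
  (`numpy.random.default_rng`); the CLI refuses stochastic runs without
  one and writes a manifest (version, parameters, seed, input checksums)
  sufficient to reproduce any run.
- Simulation scales in the test suite (e.g. 100–500 replicates, n ≤ 12)
  were chosen to give stable pass/fail behavior at interactive runtimes.

## Known limitations

- LDN treats orthography as the data; differing spelling conventions
  between sources inflate distances and no sound-class recoding is
  provided.
- The Mantel permutation test is uninformative below ~5 populations; the
  bootstrap CI, whose resampling unit is glosses rather than populations,
  is the more useful uncertainty statement at small n.
- Published pairwise F_ST tables rarely cover all pairs; the pair-list
  reader requires a complete pairing and will name the absent pairs rather
  than impute them.
- The bridge score formalizes "intermediate positioning" but any variety
  equidistant from two clusters scores low, whether the cause is contact,
  admixture, or simple isolation.
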