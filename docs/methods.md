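# Methods

This note records the model as implemented, the defaults and the reasoning
behind the choices that the score definitions leave open.

## Modules and localization

A phenotype module is the intersection of the phenotype's gene set with the
network's node set, together with the induced edges. Genes absent from the
network are dropped and counted; an empty module is allowed but flagged.

Two localization statistics are computed per module:

- **module size** `s_A` — the number of proteins in the largest connected
  component of the induced subgraph;
- **mean shortest distance** `d_A` — the mean over members of the distance
  to the closest other member, measured **on the full network**, not the
  induced subgraph. This matters for modules split into several induced
  components: paths through non-member proteins still give finite distances.
  Members with no reachable co-member at all are excluded from the average
  and reported as `n_isolated` (assigning them an arbitrary large constant
  would make `d_A` depend on that constant; exclusion does not).

The null randomises phenotype–protein associations: `n_perm` uniform random
node sets of the same size (default 100,000; scaled-down analyses use
1,000). Uniform sampling is the primary null; a degree-binned variant
(`degree_binned=True`) is available for sensitivity analysis on heavy-tailed
networks. Null moments use the sample (n−1) standard deviation. z-scores are
`(s_A − μ₁)/σ₁` and `(d_A − μ₂)/σ₂`; empirical p-values use the
(r+1)/(n+1) pseudocount so they are never 0 (the floor at 100,000
permutations is 1e-5). A zero-variance null yields z = ±inf with a warning
rather than an exception. The significance threshold is z ≥ 1.6 (inclusive,
as a one-sided ≈5% cutoff) for size and z ≤ −1.6 for distance; it is a
parameter, not a constant.

Because the null depends only on the network and the module size, the CLI
and the test battery draw it once per distinct size and share it across
modules; this is numerically identical to redrawing per module.

## Similarity score

Protein-pair similarity is `Sim(i,j) = 1/d(i,j)` with two conventions the
definition leaves open:

- **identical proteins**: Sim = 1 (the identity branch of the directed
  node-to-module sum). Consequently `Sim(A,A) = (1 − Sim_intra(A))/|A|`,
  which is 0 exactly when A is an induced clique and small-positive
  otherwise — self-similarity reflects module cohesion. This is tested, not
  hidden.
- **disconnected pairs**: Sim = 0, the limit of 1/d. A ratio has a natural
  limit; a distance does not, which is why the separation baseline instead
  *excludes* unreachable pairs from its means.

`Sim_intra` averages over distinct ordered pairs (identical to unordered
since Sim is symmetric); `Sim_inter` symmetrises the two directed
node-to-module means; the final score is inter minus the mean of the two
intras, so it lies in (−1, 1] with higher = more similar.

For the separation baseline `s_ab = h_ab − (h_aa + h_bb)/2`, cross pairs of
*distinct* proteins enter `h_ab` and distinct within-module pairs enter
`h_aa`, `h_bb`; identical-protein cross pairs are skipped, which makes
`s(A,A) = 0` exactly for any module. Lower separation means more similar;
wherever the three methods are compared on one scale the separation enters
as `−s_ab`.

All distances are unweighted hop counts. The similarity engine caches one
BFS per distinct module member; the permutation loop uses early-stopping
nearest-co-member searches, whose agreement with an independent dense
all-pairs BFS oracle is asserted to 1e-12 on random graphs.

## Ontology handling and the IC baseline

Only `is_a` edges are used; other relationship types are ignored. The
hierarchy is validated acyclic on construction. Up-propagation unions each
term's genes into all ancestors (DAG semantics — a diamond counts a gene
once); it is monotone and idempotent by construction, which the tests assert.

Study-term selection keeps propagated terms with ≥ `min_genes` genes
(default 25) and then removes every term that is an ancestor of another
retained term, eliminating parent–child redundancy; output order is
lexicographic for determinism.

Information content is `IC(t) = −ln(|D_t|/D)` with D the table's total
annotated-gene count. Natural log: the base only rescales, and every
downstream use (ranking, correlation) is scale-free. The term-pair baseline
is the IC of the common ancestor with maximal IC (minimal |D_t|); ties in
|D_t| give equal scores, so no tie-break is needed.

## Evaluation references

**GO**: `Sim_pro(g_i, g_j) = 2/n_t`, n_t the annotation count of the most
specific term shared after propagation; 0 with no shared term. The
phenotype-level score averages over the full G₁ × G₂ cross product,
including identical genes when the sets overlap. For an identical-gene pair
whose most specific term annotates that single gene the literal formula
gives 2; the score is capped at 1 so references stay in [0, 1]. GAF input
keeps rows with evidence in {EXP, IDA, IMP, IGI, IEP, ISS, ISA, ISM, ISO},
drops IPI (it would leak the interactome into the reference) and drops any
row with a non-empty qualifier.

**Co-expression**: mean |Spearman ρ| over the cross product, average ranks
for ties, computed as Pearson on rank-transformed rows. Genes absent from
the matrix are dropped (logged). Undefined correlations (constant profiles)
contribute 0, except identical-gene pairs, which contribute 1.

**Binned correlation**: pairs are sorted by method score and split into
`n_bins` equal-count bins (default 10; equal-count rather than equal-width
because score distributions are heavy-tailed and equal-width bins go empty);
per bin the mean method score and the median and mean reference score are
taken; PCC is the Pearson correlation of the binned points and R² the
coefficient of determination of the least-squares line through them.
`n_bins=0` correlates raw pairs. A constant input yields 0 with a warning.
Binning inflates |PCC| under independence; the tests calibrate the null
behaviour (|PCC| < 0.7 in ≥ 90% of seeds at 10 bins over 10⁴ records).

## Significance model

The null is built from 100,000 uniformly sampled distinct unordered module
pairs (with replacement across draws; duplicates stay in the null). Each
distinct pair is scored once and cached — identical results, bounded cost.
A pair is *similar* when its empirical quantile in the null is ≥ 1 − α and
*dissimilar* when ≤ α (default α = 0.05 per tail), otherwise *neither*.
Group comparisons use the two-sided Mann–Whitney U with normal approximation
and tie correction.

## Synthetic data and what it shows

The generators produce Erdős–Rényi backgrounds (Barabási–Albert behind a
flag), planted dense modules (internal edge rate `p_in` added to the
background), module pairs with exact designed overlaps, balanced toy
ontologies whose leaves carry disjoint gene blocks, and Gaussian-copula
expression matrices with block-correlated genes. All generators are pure
functions of parameters and seed.

The full benchmark couples these: 30 planted size-20 modules in ER(600,
0.008) with pairwise overlap design (16, 12, 8, 4, 0) × 3 pairs each and
`p_in = 0.5`; each module's genes form one GO leaf and one expression block
(shared genes keep their first module's block), 40 conditions,
within-block ρ = 0.7. Average background degree ≈ 4.8 keeps the graph
mostly one component, as in real interactomes, while planted modules are
clearly denser than chance. Localization-recovery checks use ER(500, 0.01)
with a planted size-20, `p_in = 0.5` module at 1,000 permutations.

What passing on this benchmark shows: the statistics detect genuinely
planted agglomeration at calibrated false-positive rates, the score is
monotone in true module overlap, and pairs it calls similar are
independently more functionally related and more co-expressed. What it does
not show: performance on real HPO/GO/GEO releases or on the empirical
interactome's degree structure, identifier-mapping noise, annotation
incompleteness, or literature bias in PPI data.

## Numerical and engineering choices

- Floats written with `%.10g`; all iteration over sets is sorted before
  entering floating-point sums, so outputs are byte-stable across processes.
- The final score's symmetry is exact (bit-for-bit) because both the inter
  symmetrisation and the intra average are commutative sums.
- Empty modules, sub-2-member modules, all-unreachable member sets, empty
  nulls and empty groups raise `ValueError` with a description rather than
  returning sentinels; parse failures raise `ParseError` naming the line.
- Duplicate expression rows collapse by element-wise maximum (the
  multiple-transcript rule applied to any duplicated identifier).

## Known limitations

- The permutation engine is single-threaded; 100,000 permutations on a
  13k-node interactome is minutes-scale per distinct module size.
- The uniform null ignores degree bias; for scale-free networks the
  degree-binned variant should be compared.
- GO term-to-gene evidence filtering assumes GAF 2.x column order and takes
  the DB-object-symbol column as the gene identifier; cross-namespace
  mapping is out of scope.
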