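# Methods

## Problem setting

For one gene, a *strategy* is the full chain of algorithms that produced a
phylogeny: aligner → alignment refiner → character coding → tree
estimator/bootstrap. Each strategy contributes a Newick topology and a
row of site-wise log-likelihoods (SWLH), and the file name encodes the
chain as `GENE_AE_ARC_CC_ED` (gene, alignment code, refinement code,
character-coding/estimation code, bootstrap/edit suffix). The toolkit
ranks the strategies of each gene statistically, compares them
topologically, and crosses the two views to nominate optimal strategies.

## Strategy names

Names are parsed right-to-left against per-stage code vocabularies: the
trailing token is consumed as an edit/bootstrap code if it is in that
vocabulary, then a coding code, then a refinement code, then (required) an
alignment code; everything left is the gene name, which may therefore
contain underscores while stage codes may not. `render ∘ parse` is the
identity on well-formed names for any vocabulary, and the vocabularies are
configurable (YAML) because stage-code inventories differ between
pipelines.

## Character coding

* **RY**: A, G and the purine code R map to R; C, T, U and Y map to Y;
  gap `-` and missing `?` pass through; every mixed ambiguity code maps to
  N (it carries no pure purine/pyrimidine information). The transform is
  idempotent and length-preserving. Third-position-only RY is provided
  because saturation mitigation is usually applied there; codon positions
  are labelled cyclically from the 1-based frame offset, so with frame 2
  the first column (the tail of a truncated codon) counts as a third
  position.
* **Degeneracy coding** is *derived*, not hard-coded: on the 64 ACGT
  codons, join two codons when they differ at exactly one position and
  translate identically; each connected component of this graph is a
  synonymous codon group, and its degenerate codon carries at every
  position the IUPAC code of the union of nucleotides observed there
  across the group (stop-codon components treated like any other). This
  reproduces the classic degeneracy tables for the standard code (Leu
  CTN+TTR → YTN; Ser splits into AGY and TCN because no single
  substitution connects them) and works for any NCBI or user-supplied
  translation table. Codons containing gaps, `?` or ambiguity codes are
  copied through unchanged — partial degeneration would require inventing
  semantics for symbols whose underlying base is unknown.
* **Translation** maps fully gapped codons to `-`, anything else
  unresolved to `X`, stops to `*`; final-stop stripping and
  internal-stop masking (`NNN`) are separate, explicit operations, and a
  final codon that is a stop in some rows but not others raises rather
  than silently truncating.

## Topological comparison

Trees are compared purely topologically (branch lengths and support
values are parsed and ignored). A tree whose root has degree two is
interpreted as rooted (cluster semantics: nontrivial leaf subsets below
internal nodes); otherwise as unrooted (split semantics: bipartition sides
canonicalised as the side not containing the smallest leaf label), with an
explicit override. Two metrics:

* **Robinson–Foulds**: the size of the symmetric difference of the two
  split/cluster systems; an optional normalised variant divides by
  |S₁| + |S₂|.
* **Matching distance**: pad the smaller system with null entries, weight
  a pair of splits by the minimum symmetric difference over orientations
  (plain symmetric difference for clusters), weight split-to-null as
  min(|A|, |B|), and take the minimum-weight perfect matching (Hungarian
  algorithm via `scipy.optimize.linear_sum_assignment`; the optimal total
  is unique even when the matching is not).

Both metrics are integer, symmetric, zero exactly on equal systems — the
property the consensus step relies on — and the matching metric satisfies
the triangle inequality (checked empirically on random triples; both are
also checked against independent oracles: dendropy bipartitions for RF and
exhaustive enumeration over all perfect matchings for the matching
metric).

Polytomies simply contribute fewer splits; star trees have empty systems
and compare at distance 0 to each other and at the null-padding cost to
resolved trees.

## Statistical comparison (RELL and AU)

SWLH rows are grouped by (gene, coding): mixing codings would compare
likelihoods over different site spaces. Within a group, rows whose site
count differs from the majority are split into separate groups and logged
rather than padded or truncated — padding would fabricate likelihoods.

* **RELL BP**: each replicate draws `n_sites` sites with replacement
  (implemented as multinomial weight vectors, in chunks of 2000 replicates
  to bound memory) and is awarded to the strategy with the maximum
  resampled total log-likelihood; exact ties are split fractionally among
  the maxima, so BPs sum to one exactly and two identical rows get exactly
  0.5 each. Default 10 000 replicates.
* **AU**: bootstrap proportions are computed at ten scales
  r ∈ {0.5, 0.6, …, 1.4} (replicate length round(r·n_sites), all strategies
  sharing the same replicates at each scale). Scales with BP ∈ {0, 1} are
  uninformative and dropped; if none remain, AU is 1 for a strategy that
  dominated every replicate at every scale and 0 otherwise, and with fewer
  than two informative scales AU degrades to the plain BP at scale 1 with
  a warning. Otherwise z(r) = Φ⁻¹(1 − BP(r)) is fitted by weighted least
  squares to z = d√r + c/√r with delta-method weights
  n_rep·φ(z)²/(BP(1 − BP)), and au = 1 − Φ(d − c), clamped to [0, 1].
  A flat BP of 0.5 across scales gives d = c = 0 and au = 0.5 exactly.

Strategies are ranked by AU descending, ties broken by observed total
log-likelihood descending, then by label — a committed total order so the
consensus step always has a single seed per group. All resampling streams
derive from one seed (`numpy` `SeedSequence`), making every report
byte-reproducible.

## Consensus and TTS

For each gene, every (gene, coding) group contributes its rank-1 strategy
as a *seed*. Seeds carry the statistical mark; every strategy of the
gene's matching-distance matrix at distance zero from a seed (the seed
itself included) carries the topological mark. Seeds are thus doubly
marked and their topological twins singly marked; the *consensus set* is
the marked strategies — a twin of a statistical winner shares its
topology, which is exactly the evidence the topological test contributes.
The condensed matrix is the submatrix over marked strategies. The TTS of a
consensus strategy counts the off-diagonal zeros of its row in the *full*
matrix (the diagonal is excluded so that an isolated strategy scores 0,
and unmarked columns still count: topological support does not depend on
the partner's own marks). All strategies attaining the gene's maximum TTS
are flagged optimal; with planted clusters of sizes {5, 2, 1} and the
statistical winner inside the 5-cluster this yields max TTS 4 and an
optimal fraction of 5/8.

Matrix rows and columns are identical by symmetry, so "the seed's
row/column" is implemented as the row.

## Synthetic data

The generator plants exactly the structure the pipeline is meant to
recover. Topologies come from sequential random leaf attachment (uniform
over addition orders), one per cluster, with distinctness enforced by
rejection on RF > 0; cluster members share the topology object, so planted
clusters are exactly the zero-distance equivalence classes. SWLH matrices
are i.i.d. normal per site and strategy, mean −2.0 (a typical per-site
log-likelihood magnitude), with the planted best strategy shifted by
+delta; defaults are 12 taxa, 8 strategies in clusters (5, 2, 1),
1000 sites, delta = 0.05, sigma = 1.0. Drawing log-likelihoods from a
distribution rather than from a sequence model is deliberate: the RELL/AU
machinery consumes only the SWLH matrix, and the distributional form gives
exact control of the effect size for recovery experiments. It also means
the generator does not emulate the strong across-strategy correlation of
real SWLH rows (which share the data), alignment-length variation, or any
site-pattern structure — passing tests demonstrate the correctness of the
resampling, fitting and consensus logic, not field performance on real
alignments.

Under these conditions the planted-best recovery has a hard ceiling: with
independent N(−2, 1) noise, delta = 0.05, 2000 sites and five strategies,
the probability that the planted strategy attains the maximum total
log-likelihood is ∫φ(u)Φ(u + 0.05·√2000)⁴ du ≈ 0.839, and AU-rank-1
recovery cannot systematically exceed it; measured rates are ~0.8–0.88
depending on seed. The recovery experiment uses 1500 bootstrap replicates
per scale (ranking noise is already small there, and 50 simulated
datasets complete in under two minutes on one CPU).

## Numerical and design choices

* Tie replicates split fractionally (Σ BP = 1 exactly; identical rows are
  deterministic).
* Multinomial resampling in chunks of 2000 replicates; distances and TTS
  are exact integers throughout.
* Newick parsing accepts quoted labels, support values and branch
  lengths; duplicate leaves and unbalanced parentheses are errors.
* sitelh dialect: header `n_trees n_sites`, then name + values per record
  with arbitrary wrapping accepted on input; output is unwrapped at six
  significant digits by default (the merged "agglutinated" file is what
  `compare-stat` writes per group for external cross-checks).
* `group_swlh` accepts only single-row sitelh files as input — the
  multi-row dialect is the *merged* output, and tagging multi-row inputs
  with one strategy id would be ambiguous.
* Empty report inputs produce empty-but-headed CSVs so downstream tooling
  can always parse the six files.

## Known limitations

* The AU implementation is the standard two-coefficient multiscale fit;
  it does not implement the iterative refinements or the `.mt/.rmt/.pv`
  file formats of dedicated implementations.
* The matching distance follows the padded minimum-weight-matching
  construction described above; variants differing in null-entry cost
  exist in the literature. The consensus logic depends only on
  d = 0 ⟺ identical topology, which holds for any of them.
* KH/SH-type tests, branch-length-aware distances, consensus-tree
  construction and gene concatenation are out of scope.
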