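# Methods

This note documents the models, conventions and numerical choices behind
`coevotree`, and what the synthetic benchmark does and does not emulate.

## Pipeline conventions

**Orthology.** Orthologs are best bi-directional (reciprocal best) hits
from 12-column BLAST-tabular input, after filtering at E ≤ 1e-5 and
alignment coverage ≥ 70%. The coverage denominator is deliberately the
*stricter* symmetric reading — the alignment must cover ≥ 70% of **both**
query and subject sequence — and both thresholds are arguments
(`filter_hits(e_max, coverage_min)`). When a protein pair has several
HSPs, only the single lowest-E row is kept (ties broken by higher bit
score); "best hit" uses lowest E-value, then highest bit score, then
lexicographic subject id, so the result is deterministic. Self-hits
within the reference genome are ignored. The package consumes
precomputed hit tables; it never runs a search tool.

**Sequence distances.** Distances from alignments are uncorrected
p-distances with *pairwise* gap deletion: for each sequence pair only
columns where neither sequence has a gap are compared. A pair with no
comparable column is a hard error naming the pair. A Kimura-style
correction (`d = -ln(1 - p - p²/5)`) is available behind
`correction="kimura"` but off by default; the uncorrected distance is
the documented default because it is the literal "exclude the gaps"
procedure and the downstream correlation is invariant to monotone
differences only approximately — the choice is therefore exposed, not
hidden.

**Neighbor joining.** A native Saitou–Nei implementation. The Q
criterion is computed as `(m-2)·d_ij - (r_i + r_j)` with the row sums
added first, keeping Q exactly symmetric in floating point; ties on Q
are broken by the lexicographically smallest pair of cluster keys, a
cluster's key being its smallest leaf label. Negative branch-length
estimates are clamped to zero (standard practice; additive inputs are
unaffected). The final three clusters are joined on a trifurcating root
using the three-taxon closed form. On exactly additive input the
recovered path metric equals the input to < 1e-8 (verified for 5–15
taxa). Trees are treated as unrooted for patristic purposes: path sums
are independent of root placement.

**Patristic distances.** One post-order sweep merges per-subtree maps of
leaf distances; every non-root edge must carry a length. The result is
checked in tests against an independent library implementation
(dendropy's phylogenetic distance matrix) and against the four-point
condition.

**Mirrortree.** The two distance vectors are the upper triangles, in
canonical (lexicographically sorted) organism-pair order, of both
matrices restricted to the shared organisms. Requirements: ≥ 15 common
organisms (`min_common`) and correlation P ≤ 1e-5 (`p_max`) for an entry
to enter the genome-wide score matrix. The P-value is the two-sided t
approximation for a Pearson coefficient with `m·(m−1)/2 − 2` degrees of
freedom. The distance pairs are treated as independent observations, as
in the original method; they are not (pairs sharing a leaf are
dependent, and redundant strains make this worse), so the P-value is an
optimistic screening statistic, not a calibrated error rate. This is a
documented caveat, not a bug to fix, because the screening rule is part
of the method being studied. Zero-variance vectors yield a masked
(not-evaluable) score rather than an exception.

**Profile-correlation.** Profiles are rows of the significant-only score
matrix. Positions corresponding to the pair itself are excluded; the
correlation is computed over positions available in *both* profiles
(pairwise-complete), requiring at least `min_joint = 3` of them — the
minimum for a defined correlation plus one degree of freedom. A
zero-fill compatibility mode (unavailable entries read as 0 over all
positions) exists because the textual description of the method is
ambiguous; pairwise-complete is the default since zero-filling invents a
value for pairs that were merely unevaluable. PC does not require the
pair's own MT correlation to be significant.

**Context-mirror.** For pair (A, B) at level L, candidate controllers
are proteins C with available r_AC and r_BC, ranked by |r_AC·r_BC|
descending (ties lexicographic); the top `min(L, available)` controllers
are partialled out by inverting the (|S|+2)×(|S|+2) correlation
submatrix, with unavailable controller–controller entries taken as 0 and
the partial correlation read off the precision matrix as
`-P_01/sqrt(P_00·P_11)`. Submatrices with condition number above 1e12
are treated as singular and the largest non-singular *leading* subset of
the ranked controllers is used instead; a pair with no controllers
degrades to its raw correlation and is flagged. The ranked-top-k /
submatrix-inversion construction is this package's explicit
interpretation of "levels of specificity"; both the ranking rule and the
estimator agree with first-order recursion (checked for k ≤ 3) and with
a residual-regression oracle to 1e-8.

**Evaluation.** Negatives are all unordered pairs among the proteins
involved in the positives, minus the positives; the totals P and N are
frozen at construction. ROC curves sweep distinct score values
descending, moving all tied pairs in one step; TPR and FPR use the
frozen totals, so unscored gold pairs are implicitly "never predicted" —
this is exactly what shortens the curves of low-coverage methods — and
the AUC is the trapezoid area under the realized (possibly truncated)
curve. Two AUC conventions coexist by design: the *global* totals-based
one above, and a *local* in-list AUC for per-protein interactor ranking,
computed as the normalized Mann–Whitney U with ties counted as 1/2.

**Taxonomy sampling.** Depth is counted in explicit tree levels, not
named ranks, since rank names are irregular; `nearest_k` is the genome
content of the k-th lineage node of the reference genome (k = 1 being
the attachment node itself). For `level_k`, a genome attached above the
cut depth forms its own singleton group, so no genome is silently
dropped, and cuts deepen until every genome stands alone — hence the
deepest level returns the full usable collection. Genomes with no known
proteome size are excluded from level sampling with a warning, mirroring
how organisms without proteome information must be skipped in practice.
Ties on proteome size break by lexicographic genome id.

## The synthetic benchmark

Real studies of this kind start from hundreds of genomes and curated
interaction databases. The bundled generator replaces them with an
explicit stand-in model; every end-to-end claim verified on it is a
claim about this model, not about real proteomes.

**Species tree.** Yule (pure-birth) process with unit birth rate:
exponential waiting times between splits, uniformly chosen splitting
lineage, a final waiting period so all pendant edges are positive.
Branch lengths are in arbitrary substitution units; a 40-leaf tree has
patristic distances roughly in [0.1, 6].

**Family matrices.** A family's inter-ortholog distance matrix is a
multiplicative log-normal distortion of the species patristic matrix:
`d_f(i,j) = t(i,j) · exp(g_f(i,j))` with `g_f` a zero-mean symmetric
Gaussian field of standard deviation `noise_sd` (default σ = 0.3,
giving ±35% typical rate modulation). This is the simplest model that
preserves positivity and symmetry while giving a tunable tree
correlation. For the designated interacting pairs the field is split
into shared and private components so that `corr(g_f1, g_f2) = ρ`
(`coevolution_strength`, default 0.9) with unchanged marginal variance.
With `recent_clade_fraction < 1`, the shared component applies only to
organism pairs inside one clade of the species tree (the internal node
whose leaf count best matches the requested fraction); outside it the
two families receive independent perturbations of equal variance —
interactions that exist only in a group of related organisms and have
been rewired elsewhere.

**Strain redundancy.** `add_strain_redundancy` replaces k random leaves
by cherries of two strains separated by branch length ε (default 1e-4).
Crucially, rate perturbations are drawn at the level of *base* organisms
and copied to strain leaves, and retention is drawn per base organism,
so a strain duplicates its sibling's matrix rows and gene content
exactly instead of contributing independent information — which is what
phylogenetic redundancy does in real data. Under this model, adding 10
strains to the 40-organism benchmark inflates the mean raw tree
correlation of non-interacting pairs (the shared near-zero strain
coordinates act as common leverage points) by about +0.01 to +0.03 while
profile correlations barely move; the inflation is common-mode, so at
the default strong-signal conditions ranking performance stays saturated
for both scorers. The model does not reproduce a large redundancy-driven
*ranking* collapse of MT: with perturbations drawn independently per
organism pair, duplicated coordinates are statistically inert, whereas
in real data lineage-correlated estimation noise gives redundancy more
destructive power. This is a known limitation of the generative model.

**Retention and degeneracy.** Each base organism is present in a family
with probability `retention_prob` (independently per family). Families
with fewer than 3 retained organisms are emitted but flagged degenerate,
to exercise downstream minimum-organism filters.

**Taxonomy, hits, sequences.** The taxonomy is derived from the species
tree by keeping internal nodes down to depth 4 as ranked taxa and
attaching each genome to its deepest kept ancestor — guaranteeing
tree/taxonomy consistency and collapsing strain cherries into shared
species-level nodes. Proteome sizes are drawn uniformly from 1000–5999.
The hit-table emitter produces reciprocal low-E hits between the
reference-genome protein of each family and every other member (~90%
mutual coverage), plus decoys that fail the E-value, coverage or
best-hit rules. The sequence emitter evolves nucleotide alignments along
the tree under the Jukes–Cantor model, so the expected p-distance at
patristic distance D is `(3/4)(1 − e^(−4D/3))`; sequence-level
round-trip tests run at rate 0.1 to keep distances clear of the 0.75
saturation ceiling.

**Reproducibility.** One root seed; every stochastic step draws from a
substream derived via `numpy.random.SeedSequence(seed, spawn_key=...)`
with a documented stream table, so identical configurations produce
byte-identical output files.

## Problem sizes and scaled-down thresholds

The default benchmark (40 organisms, 60 families, 20 interacting pairs)
is deliberately desk-scale; score matrices build in ~1 s. Two
consequences of the reduced scale are handled explicitly:

- Organism-set comparisons that include very small subsets (the
  12-organism clade experiment) use `min_common = 8` and disable the
  significance filter (`p_max = 1`), because a screening rule tuned for
  hundreds of distance pairs is meaningless at 45–66 pairs and its
  coverage effects would otherwise swamp the ranking comparison being
  made.
- The coverage drop-off experiment keeps the standard
  `min_common = 15` and P-cutoff, since the applicability collapse of
  the network-based scorer under those rules is precisely the effect of
  interest; fractions are compared relative to the 40-organism baseline.

## Known limitations

- The generative model has no lineage-specific rate structure, no
  horizontal transfer, paralogy or indels, and its background tree
  correlation between unrelated families (r ≈ 0.9 at σ = 0.3) is higher
  than typical real data; the raw mirrortree scorer is close to optimal
  in this world, so relative method rankings (PC/CM above MT on real
  data) are not reproduced and are not claimed.
- P-values inherit the independence approximation described above.
- The taxonomy emitted by the generator is balanced-ish and shallow
  (depth ≤ 5); NCBI taxonomies are far more ragged, though the samplers
  are rank-agnostic by construction.
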