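# Methods

## The model

`icmhost` treats host prediction as model selection over genome
composition. For each candidate host taxon an interpolated context model
(ICM) — a variable-weight mixture of fixed-order Markov models over the
4-letter DNA alphabet — is trained on the taxon's genome sequence(s). A
viral contig's log-likelihood under each model is computed position by
position, and the relative likelihoods across models carry the host
signal. The biological assumption is amelioration: a phage's
polynucleotide composition drifts toward its host's, so the host's
composition model is, on average, the best generative explanation of the
phage sequence. The method is deliberately homology-free; it can
therefore propose hosts for viral dark matter, at the cost of depending
entirely on how distinct and how ameliorated the candidate compositions
are.

### Interpolation

For a context `w` of length `k` with next-base counts `c_k(w, ·)` and
total `N`, the raw estimate is add-α smoothed,
`P̂_k(b|w) = (c_k(w,b)+α)/(N+4α)`, and the interpolated estimate is

    P_k(b|w) = λ_k(w)·P̂_k(b|w) + (1−λ_k(w))·P_{k−1}(b|w[1:]).

λ is driven by how much evidence the context has and whether that
evidence *disagrees* with what the shorter context already predicts:
λ = 1 when `N ≥ C`; λ = 0 when `N = 0`; otherwise the observed counts are
compared to the expectation `N·P_{k−1}(·|w[1:])` with a chi-square
statistic on 3 degrees of freedom, and with `d = 1 − p`,
λ = 0 if `d < 0.5`, else `λ = min(1, d·N/C)`. The historic ICM of the
Glimmer/Phymm lineage additionally selects informative context positions
in a decision tree; this package implements the plain interpolated
variant, which satisfies the same scoring contract (per-context
normalized conditionals, count-gated order selection) and is fully
specified above. Any drop-in model honoring that contract could replace
it.

A consequence worth noting: the interpolated conditional depends only on
the model and the context, never on the query. The implementation
therefore resolves the entire interpolation hierarchy into per-order
lookup tables once per model (the chi-square gate applied vectorized over
all contexts of each order), and scoring reduces to a table gather — the
scalar and vectorized paths are the same arithmetic by construction.

### Parameters

| parameter | default | meaning |
|---|---|---|
| K | 8 | maximum context length, bases; orders 0..K all trained |
| α | 1.0 | pseudocount added to every (context, base) cell at every order |
| C | 400 | context count at which the order-k estimate is fully trusted |
| δ | 0.01 | candidate margin, nats per scored base |
| min contig length | 5000 | inclusive filter on viral contigs, bases |
| min scaffold length | 100000 | strict filter on cellular scaffolds, bases |

K = 8 matches the usual depth of composition classifiers of this family;
C = 400 makes order-8 contexts (4^8 = 65 536 of them) effectively
inactive for small training genomes and progressively active as training
data grows, which is the intended behavior of the gate. α = 1 is the
simplest smoothing consistent with per-order normalization. All are
configurable everywhere (library, CLI, model store).

### Strand and N handling

Models are trained on the forward strand only; scoring evaluates both
strands and keeps the better, so contig orientation is irrelevant and
`score(s) = score(revcomp(s))` exactly. Any position whose base or
preceding `min(i, K)`-base context contains an N is skipped in both
training and scoring; because the skip pattern depends only on the query,
scored-position counts are identical across models and scores stay
comparable. Sequence starts are scored with the truncated available
context (order ramps 0 → K) rather than discarding the first K bases.

## Assignment and rejection

All models within `δ · scored_positions` nats of the best form the
candidate set; the assignment is the LCA of their label taxa. If the
nearest canonically ranked ancestor of that LCA is at rank *order* or
coarser, the contig is *unassigned*. The margin mechanism reproduces with
one knob both behaviors a practitioner needs: a pure argmax (δ = 0) and a
reconciliation that backs off to coarser ranks when several taxa explain
the contig about equally well. Genus is the reporting level; a call that
resolves only to family is still "assigned" but carries no genus.

Unranked ("no rank") taxonomy nodes are transparent throughout: they can
be the LCA itself but never decide the rejection comparison, which always
uses the nearest canonically ranked ancestor, and sub-species ranks
collapse to species. This is a convention of this package; rank-sparse
taxonomies (as NCBI's is) admit no unique alternative.

The transitive route trains one unlabelled model per scaffold longer than
100 kb (strict), links each contig to its candidate scaffolds by the same
δ margin, assigns each scaffold's taxonomy by the direct route, and takes
the LCA of the candidate scaffolds' assigned taxa under the same
rejection rule. With δ = 0 it degenerates to best-scaffold propagation;
contigs whose candidate scaffolds are all themselves unassigned are
unassigned.

Benchmarking reports accuracy per rank over non-rejected pairs (truth
lacking the rank is excluded from that rank's denominator; a prediction
lacking it counts as wrong) and the rejection rate separately, so the two
figures are independently interpretable. An optional guard can exclude,
per query, any reference model whose training genome shares an exact
≥ 5 kb stretch with the query phage — the situation where a prophage copy
of the query sits inside a candidate host genome and would trivially win.

## The synthetic community

The generator emulates exactly the statistical structure the method
relies on, and nothing else. Per genus, an order-m (default m = 2) Markov
transition table is drawn row-wise from Dirichlet(divergence); species
tables are tight Dirichlet perturbations of their genus table
(concentration 500 — distinguishable but clearly intra-genus); phages are
sampled from their host's genus table with an independent per-position
probability ε of a uniform background draw (default ε = 0.1, i.e. a 90%
ameliorated phage); scaffolds are verbatim chunks of the genomes. The
default community is 5 phyla × 4 genera × 2 species with 200 kb genomes,
200 phages of 40 kb, and one 150 kb scaffold per genome; the taxonomy is
a minimal canonical ladder (one order and family per phylum) so the
rejection rule is exercisable. Everything derives from one integer seed.

What this does *not* emulate: genes, GC skew, repeats, horizontal
transfer, strain mixtures, assembly and sequencing error, and — most
importantly — the subtlety of real inter-genus composition differences.
i.i.d. Dirichlet genus tables at divergence ≤ 0.5 are far more divergent
than real bacterial genera, so recovery accuracies measured here are
upper bounds on realistic performance; passing tests demonstrate the
pipeline's internal correctness and the direction of its behavior, not
field accuracy. Concretely, at the reference conditions the per-position
log-likelihood margin between the true and the best wrong genus is so
large (mean ≈ 82 nats over 100 bp fragments) that genus recovery is
saturated at 1.0 down to 100 bp; degradation toward chance only becomes
visible below ~25 bp or at ε → 1. The ε = 1 control is therefore
evaluated with δ = 0 (pure argmax): under the margin rule a
composition-free phage ties dozens of models, the LCA escalates to the
root and nearly everything is rejected, leaving no denominator on which
"accuracy equals 1/G" could be tested, whereas argmax assigns every
contig and makes the comparison well-posed.

## Numerical and procedural choices

- Problem sizes in the test suite and the acceptance script are the
  reference conditions above (40 genomes × 200 kb, 20 genus models,
  200 contigs); the end-to-end evaluation completes in about a minute on
  one CPU.
- Exact score ties are broken lexicographically by model id for the
  reported best model only; the candidate LCA sees all tied models, so
  assignments are invariant under model and contig reordering.
- Count tables are exact int64; probabilities are formed in float64 once
  per model. The chi-square gate uses the survival function of χ²(3).
- An all-N contig scores 0 with zero scored positions and is flagged; the
  margin is then 0 and the contig is rejected through the normal path.
- The model store is a JSON manifest (format version, kind, K, α, C,
  labels) plus one compressed array container of count tables per model;
  loading verifies the format version and fails loudly on corruption.
- Missing read counts in abundance summaries default to 1 with a warning
  so contig-count weighting stays meaningful; negative counts are errors.

## Known limitations

- Plain interpolation, no context-position selection (see above); noted
  as an extension point.
- Scores are not calibrated into posterior host probabilities; δ is a
  margin in nats per base, not a significance level.
- Taxonomies with merged/deleted taxids are not resolved; inputs must be
  self-consistent.
- Host signal in real viromes is weaker and patchier than the generator's
  (mosaic genomes, broad host ranges, shared amelioration among related
  hosts); genus-level accuracy on real data is expected to be much lower
  than on the synthetic community, and the rejection rule exists
  precisely to absorb part of that uncertainty.
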