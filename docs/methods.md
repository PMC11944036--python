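# Methods

## Problem and model

Given a set of compounds with known structures and a pathway knowledgebase
with partial compound→pathway membership annotations, the task is binary
classification over all (compound, pathway) pairs: does this compound belong
to this pathway? Training on the annotated pairs and predicting held-out
pairs lets the model propose pathway assignments for structurally
characterized but unannotated molecules.

The pipeline treats the knowledgebase inputs as three tables: one V2000
molfile per compound, a two-column membership table, and a parent→child
pathway relation table (the hierarchy must be a DAG; multi-parent pathways
are allowed and take their minimum depth as their level).

## Atom-coloring featurization

A compound's feature vector counts canonical atom-neighborhood strings
("colors"):

- radius 0: element symbol, suffixed with the signed formal charge when
  nonzero (`N+1`, `O-1`);
- radius r+1: the atom's radius-r color, `|`, then the lexicographically
  sorted terms `(order:neighbor_radius_r_color)` over its bonds.

The grammar (versioned `pc-color-v1`) is injective on rooted neighborhoods
and invariant to atom input order, which is the property the counts rely on;
any other injective, order-invariant encoding would serve equally.
Hydrogens are stripped first, so *compound size* = non-hydrogen atom count
equals the sum of radius-0 counts. Aromatic bonds keep their order code 4
(no kekulization); isotopes and stereochemistry are ignored. A feature
vector is the union over radii 0..R of per-radius color counts; an atom with
no neighbors keeps its color unchanged across radii and is counted once.

`max_radius` choices: an integer fixes R; `"auto"` (library default) refines
until the number of distinct colors in the graph stops increasing
(Weisfeiler–Lehman stabilization, final radius included), capped at the
graph diameter. The reference benchmark uses R = 1: the planted motifs are
unique in the corpus already at radius 1 (see below), and radius 1 keeps the
feature width (~900 columns) small enough that the full study runs in under
a minute on one CPU. Real applications would typically use R = 2–3.

## Dataset construction

Order of operations: featurize compounds → aggregate pathway features →
deduplicate → normalize → cross-join → (optionally) restrict by hierarchy
level.

- **Aggregation.** Pathway row = element-wise sum of member compounds' raw
  count rows. Annotated compounds without a parseable structure are dropped
  (logged); pathways left without members are excluded rather than kept as
  zero rows.
- **Deduplication** runs on raw counts (scaling cannot split ties). Within a
  group of identical rows the lexicographically smallest ID is kept and the
  group's annotations are merged by union — identical feature vectors must
  not carry contradictory labels.
- **Normalization** divides each column by its maximum over the corpus
  (zero columns stay zero), independently for the compound and pathway
  matrices; every value lands in [0, 1] and sparsity is preserved. A
  per-row unit-sum alternative is available (`normalize(..., "row_sum")`).
- **Cross-join.** Entry k pairs compound k // |P| with pathway k % |P|; its
  feature vector (materialized on demand) is the concatenation of the two
  normalized rows, and its label is annotation membership. Entry count is
  always |C|·|P|.
- **Hierarchy levels.** Roots are level 1, children take 1 + min parent
  level; levels ≥ 6 are displayed pooled as "L6+". Annotated pathways
  missing from the hierarchy are treated as roots (logged). The L*n*+
  subset keeps pathways with level ≥ n; compounds are never removed.

## Classifier and cross-validation

The classifier is a feed-forward network (ReLU hidden layers, inverted
dropout, Adam) minimizing class-weighted binary cross-entropy, implemented
directly on numpy arrays so that training is exactly reproducible from an
integer seed (weight init, batch order, dropout masks, and splits all flow
from `numpy.random.default_rng`). Relevant `ModelConfig` parameters:

| parameter | default | benchmark | notes |
|---|---|---|---|
| hidden_sizes | (256, 128) | (64, 32) | benchmark sized to ~900 input columns |
| dropout | 0.1 | 0.1 | hidden layers only |
| learning_rate | 1e-3 | 1e-3 | Adam |
| batch_size | 256 | 256 | |
| max_epochs | 100 | 100 | |
| early_stopping_patience | 5 | 10 | on a stratified 10% slice of train |
| positive_class_weight | "balanced" | "balanced" | N_neg/N_pos of the training labels |
| decision_threshold | 0.5 | 0.5 | probability ≥ threshold is a positive call |

Positive entries are a small fraction of the cross-join, hence the balanced
class weight. `max_epochs=0` yields the untrained network (a near-constant
null predictor). A non-finite loss raises a training-divergence error that
echoes the config.

Cross-validation runs `n_iterations` *independent* seeded stratified
shuffle-splits at a 9:1 train/test ratio — resampling with the flavor of a
bootstrap/jackknife hybrid rather than disjoint folds (disjoint folds would
cap iterations at 10; independent splits are what makes 20/50/200-iteration
analyses meaningful). The stratified split chooses the test-set positive
count t to minimize |t/n_test − (P−t)/n_train| — the closed-form optimum is
the floor or ceiling of P·n_test/n — then samples members uniformly within
each class. Train and test sets are disjoint by construction every
iteration; per-iteration confusion counts are tallied overall, per compound,
and per pathway, and each scope's counts sum to the test-set size.

## Metrics

MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)), computed in exact
integer arithmetic before the square root. Whenever a marginal factor is
zero the metric is **undefined** — represented as `None`, never coerced to
0, and written as the literal string `undefined` in report tables. The same
convention applies to accuracy/F1/precision/recall/specificity on zero
denominators.

Per-iteration test-set MCCs are summarized by mean, median, and sample
standard deviation (ddof = 1; reported as 0.0 when only one defined
iteration exists); undefined iterations are excluded with a logged count.
Individual compounds and pathways rarely admit a per-iteration MCC (their
test slices are tiny), so their **oMCC** sums TP/TN/FP/FN across all
iterations first and computes one MCC from the summed matrix; level-scope
oMCC additionally sums across the level's pathways. Over a single iteration
oMCC reduces to that iteration's MCC.

Cross-dataset comparison uses Cohen's d with pooled standard deviation,
√(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)), and relative improvement
100·(mean_new − mean_ref)/mean_ref (the reference mean in the denominator).

## Synthetic benchmark

The generator emulates the three real inputs at desk scale with a planted,
recoverable signal:

- **Molecules**: random connected trees (optional single ring closure) of
  3–30 heavy atoms over C/N/O/S/P with bond orders 1–2, under element degree
  caps (C/N 4, O/S 2, P 3). Chemistry is deliberately schematic — degree
  caps rather than valence/aromaticity rules — because the benchmark tests
  the pipeline, not chemical realism.
- **Motifs**: 3-atom chains containing an order-3 bond. Backgrounds never
  contain triple bonds, so the motif's middle-atom radius-1 color is unique
  in the corpus; the chain end is the only attachment point (and never to
  another motif's atoms), so that signature survives embedding.
- **Pathway families**: pathways share motifs in families (default 10
  families tiling the pathway list). This mirrors how related knowledgebase
  pathways share substrate chemistry, and it is what makes the planted
  signal statistically recoverable: with one unique motif per pathway, each
  pathway's matching rule would be supported by only ~8 positive examples
  at benchmark scale, too few for a concatenated-input MLP to generalize
  from (it memorizes instead); with families of ~5 pathways each motif
  pattern has ~170 supporting positives.
- **Annotations**: every carrier pair (compound carries the pathway's family
  motif) is annotated independently with probability `signal_strength`
  (default 0.95); each compound additionally gains, with probability
  `noise_rate` (default 0.01), one spurious annotation to a uniformly chosen
  pathway whose motif it does not carry. `noise_rate` is deliberately
  per-compound, not per-pair: a per-pair rate of 0.01 would make spurious
  labels ~20% of all positives and cap even the Bayes-optimal MCC near
  0.87, destroying the benchmark's headroom.
- **Hierarchy**: levels assigned round-robin up to the requested depth
  (default 6, so the L6+ pooled display level is exercised); each non-root
  draws a random parent one level up, ~10% gain a second parent at the same
  level.

With signal 1.0 and noise 0.0 the label is a deterministic function of motif
carriage, so a trivial rule on the motif color feature separates the classes
perfectly — an upper bound the MLP is measured against. At the default
signal 0.95 the 5% unannotated carrier pairs are irreducible label noise:
the Bayes-optimal carrier-rule predictor scores oMCC ≈ 0.96–0.97 on the
benchmark, which is what the trained MLP approaches (mean CV MCC ≈ 0.96,
sd ≈ 0.01, stable across seeds).

What the benchmark does *not* emulate: realistic molecule size/valence
distributions, Reactome's empirical pathway-size distribution and its
strongly skewed membership counts, cross-species annotation structure, and
knowledgebase-scale positive prevalence (~17% here vs ≪1% in a real
cross-join — a deliberate trade to keep the benchmark learnable at 10⁴
entries). Passing the benchmark therefore demonstrates pipeline correctness
and signal recovery under controlled conditions, not expected performance
on real knowledgebase data, which requires the full-scale inputs and far
more compute (hundreds of CV iterations on ~10⁷-entry datasets).

## Numerical and degenerate-input choices

- Molfile parsing: V2000 only; V3000 raises an explicit unsupported-dialect
  error. `M  CHG` property lines supersede all atom-block charge codes.
  Writing uses zero coordinates and `M  CHG` lines; >999 atoms/bonds exceeds
  the fixed-width fields and raises a capacity error. write→parse→write is
  byte-stable.
- Empty graphs (e.g. an all-hydrogen molecule after stripping) featurize to
  empty color sets; empty corpora, annotation tables, or pathway sets raise
  empty-input errors at the operation that first needs them.
- Ties in stratified splitting (floor vs ceiling equally good) resolve to
  the count closer to the real optimum, then to the smaller count.
- Matrix persistence: TSV by default, HDF5 for `.h5`/`.hdf5` paths; both
  round-trip IDs, vocabulary order, and values losslessly.

## Known limitations

- The color grammar produces strings that grow quickly with radius; for very
  large molecules or radii a hashed variant would be preferable (out of
  scope here).
- `run_cv` materializes the full entry-feature matrix once; datasets beyond
  ~10⁶ entries × 10³ columns need a streaming driver.
- The MLP is CPU-bound numpy; it is meant for benchmark- and moderate-scale
  runs, not for 10⁷-entry knowledgebase studies.
- Species handling in Reactome-dialect annotation files defaults to pooling
  all species; restrict with the `species` argument if a single-organism
  study is intended.
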