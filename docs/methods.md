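# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that make results reproducible.

## Synthetic data model

Cells occupy one of `n_states` discrete states ordered along the EMT
axis (default 4: E, I1, I2, M). Three gene programs have state-specific
negative-binomial means (`program_means`, a state x program matrix):

| state | epithelial | mesenchymal | housekeeping |
|-------|-----------:|------------:|-------------:|
| E     | 8.0        | 0.5         | 5.0          |
| I1    | 7.0        | 1.5         | 5.0          |
| I2    | 6.0        | 4.0         | 5.0          |
| M     | 5.0        | 9.0         | 5.0          |

Design rationale:

- The mesenchymal program rises ~18-fold while the epithelial program
  falls to 62% of its E-state level — late states co-express both
  programs (hybrid E/M plasticity). The terminal epithelial mean is
  deliberately kept at >= 40% of the E-state value so the EMT circuit
  energy (which rewards co-expression) increases monotonically along
  the designed order. This is a default, not a constraint of the code.
- The mesenchymal steps are roughly geometric (0.5, 1.5, 4, 9) so that
  on the log scale adjacent states are about equally spaced. With the
  original arithmetic-style spacing the two terminal states were much
  closer than the others, and ensemble clusterings merged only that
  pair — no boundary signal ever connected E to I1.
- Per-gene means are the program mean times a fixed scale factor drawn
  once per gene from U(0.7, 1.3), so genes within a program are not
  identically distributed while every monotone trend is preserved.
- Counts are NB(mean, dispersion) with `nb_dispersion = 5` (moderate
  overdispersion: variance = m + m^2/5) followed by independent
  Bernoulli dropout with probability 0.2. These values were chosen so
  that the state programs dominate technical noise at the designed mean
  levels; far noisier settings (dispersion ~2, dropout ~0.3) leave
  gene-gene correlations below the tau = 0.4 network threshold and no
  method could recover the designed structure from the resulting data.
- **Transition cells**: a fraction (`transition_fraction = 0.15`) of
  each state's cells have their mean profile blended toward a random
  adjacent state with weight U(0.4, 0.5) (below 0.5, so the nominal
  state remains the majority program and the truth label stays
  meaningful). Real EMT data is a continuum; purely discrete states
  produce consensus matrices that are exactly block-diagonal, soft
  memberships collapse to hard ones, and the transition-cell trajectory
  machinery has nothing to work with. The blended cells are flagged in
  the ground truth.
- Ligand/receptor genes per toy pathway have either a "spike" profile
  (design level in the designated sender/receiver state, baseline 0.2
  elsewhere; default design makes I2 the strongest Notch-toy/Wnt-toy
  sender) or a "graded" profile in which the mean rises with the state
  index. The graded profile is quadratic in the state fraction rather
  than linear: total library size itself grows along the state order
  (the mesenchymal program rises), and per-cell library-size
  normalization cancels a linear gradient almost exactly at the top of
  the range. Graded design levels (4.0 / 3.0) keep cluster-level L x R
  products inside the responsive range of the Hill transform; much
  higher levels saturate the probability near 1 for every state and the
  between-state ordering degenerates to noise.
- Each cell's time-point label is drawn conditional on its state from
  the `timecourse_mix` matrix (time point x state fractions, rows
  summing to 1); `sample_timecourse` additionally draws per-time-point
  cohorts directly from the mix rows for composition tests.

What the generator does **not** emulate: transcriptome-wide correlation
structure beyond the shared state programs, batch effects, doublets,
gene-length or GC biases, and mean-variance trends fitted to any real
dataset. Passing tests therefore certify the pipeline's behavior under
an idealized but structurally faithful noise model, not performance on
any particular real dataset.

## Preprocessing

Top `top_n_genes` genes by total count (default 3000; ties at the
boundary break by ascending gene name for cross-platform determinism),
then cells expressing fewer than `ceil(min_gene_fraction x panel)`
genes are dropped (default 5%), then `log(pseudocount + count)` with
natural log and pseudocount 1. The 5% filter counts against the kept
top-n panel by default (`min_frac_panel="kept"`); the alternative
convention counting against the full pre-selection panel is available
as `"full"`. Preprocessing is idempotent on its own output, and gene
selection is invariant to cell order (and vice versa).

## Signature scoring

Genes are ranked per cell by descending expression with ties broken by
ascending gene name — a deterministic substitute for random
tie-breaking, chosen so exact oracle tests are possible. The score is
the recovery-curve AUC over the top `top_k` ranks, normalized by the
maximum achievable area, hence in [0, 1] and dependent only on
within-cell ranks (any monotone transform of a cell's expression leaves
it unchanged; computing on log or raw counts is immaterial). Signature
genes absent from the matrix are dropped with a warning and the
normalizer uses the retained count, so a partially measured signature
can still reach 1.0.

## Consensus clustering and trajectory

- **Ensemble**: `n_runs` (default 100) k-means runs over PCA embeddings
  of the cells, cycling component counts (5, 10, 15) and k (3..8) in a
  seeded order, each run on a random 60% gene subspace. Subsampling
  genes — rather than reseeding k-means — diversifies the ensemble
  while keeping the whole stage equivariant under cell permutations:
  k-means is initialized by a deterministic farthest-point rule instead
  of a randomized one. Similarity = co-clustering fraction.
- **Model selection**: largest gap between consecutive eigenvalues of
  the similarity matrix itself (not a graph Laplacian), over
  k in [3, 8]; near-equal gaps (within 1e-9 relative tolerance) count
  as ties and resolve to the smallest k. The floor of three clusters
  reserves room for at least one intermediate state.
- **Soft membership**: symmetric NMF `S ~ HH^T` by damped
  multiplicative updates (`H <- H * (1/2 + 1/2 * SH / (H H^T H))`) from
  a seeded init (hard k-means partition of the spectral embedding,
  softened with 20% uniform noise); stop at relative objective change
  < 1e-6 or 500 iterations (non-convergence warns and returns the best
  iterate). Rows are normalized to sum 1; the hard label is the argmax.
- **Transition cells**: membership gap (largest minus second largest)
  below `delta`. Default `delta = 0.2`: with row-stochastic memberships
  over ~4 clusters, confidently assigned cells have gaps >= 0.5 while
  genuinely blended cells land around 0.1-0.3; a 0.1 threshold flags
  almost nothing and leaves the trajectory without edges.
- **Trajectory**: start = cluster minimizing (rank of E score
  descending + rank of M score ascending); an unresolved rank-sum tie
  is an error naming the tied clusters so candidates can be tried
  explicitly. Edge weight between two clusters = number of transition
  cells whose two largest memberships are exactly that pair. The order
  is the maximum-weight simple path from the start — exhaustive
  enumeration for k <= 6 (ties resolve lexicographically), greedy
  beyond; alternative paths are reported in weight order. Pseudotime of
  a cell in cluster a at position i is `i ± h_b / (h_a + h_b)` toward
  the adjacent cluster b with the larger membership, giving values in
  [0, k-1] that are nondecreasing along the order.

## Energies

- Transcriptional diversity = number of genes with >= 1 raw count;
  normalization-independent by construction.
- The gene network connects pairs with |Pearson r| >= tau (default 0.4)
  on log expression across all cells; zero-variance genes get no edges;
  Spearman is available.
- Energy: per gene, expression is rescaled to z in [0, 1] by the gene's
  maximum across cells (0 if the max is 0); a cell's energy is
  `sum_i -z_i ln(z_i / sum_{j in N(i)} z_j)` over expressed, networked
  genes, with a term set to 0 when the neighbor sum vanishes. The form
  is zero for silent cells, ignores isolated genes, and grows when many
  connected genes are broadly co-expressed. It is one reasonable member
  of a family of neighbor-driven scores; it is isolated behind
  `single_cell_energy` so an alternative can be swapped, and every test
  asserts ordinal behavior rather than values specific to this form.
- EMT circuit energy = the same computation on the matrix restricted to
  the union of the two signatures; by construction it cannot depend on
  any gene outside them (verified bit-exactly in tests).

## Communication

Counts are library-size normalized per cell to the median depth and
log1p-transformed. Cluster ligand expression is the geometric mean over
subunits of the cluster-mean expression (a silent subunit nullifies the
complex); the probability is `L*R / (Kh + L*R)` with `Kh = 0.5` on the
normalized-log scale — the midpoint L*R = Kh maps to 0.5. The
arithmetic cluster mean replaces a trimmed mean, and cofactor/agonist
terms are omitted (the toy database has none); all downstream claims
are ordinal, not numeric parity with any particular implementation.
Significance: labels permuted globally `nperm` times (default 100),
`p = (1 + #{perm >= obs}) / (1 + nperm)`. Aggregation zeroes pairs with
p >= alpha (0.05); outgoing/incoming strengths are row/column sums over
pairs; per pathway, sender/receiver are row/column sums, influencer
their total, and mediator the betweenness centrality of the cluster in
the pathway's significant-probability digraph with edge distance
1/prob (a flow-betweenness stand-in that is well defined on sparse
directed graphs). Information flow per pathway is the total significant
probability; the condition-comparison table reports absolute and
relative flows and flags pathways active in exactly one condition.

## Statistics

Welch's unequal-variance t-test, one-tailed (the direction along a
trajectory defaults to "later cluster greater"). Stars: `***` p<0.001,
`**` p<0.01, `*` p<0.1, strictly — a p equal to a threshold takes the
weaker label. Both consecutive-pair and all-pairs comparison modes
exist. Marker composition binarizes at count > threshold (default 0,
dropout-tolerant) and bins cells by the 2^m high/low combination with
TN/TP aliases.

## Problem sizes and determinism

The acceptance script and the recovery tests use 4 states x 100 cells
x ~400 genes and 20 seeds per rate estimate, 50 simulations for the
permutation-null calibration — sizes at which every rate estimate is
stable yet a full run completes in minutes on one CPU. All randomness
flows through explicit integer seeds (`numpy.random.default_rng`);
fixed seeds give bit-identical outputs, including the simulator, the
k-means ensemble, symmetric NMF and the permutation test.

## Known limitations

- The eigengap occasionally (roughly 1 run in 20 at the default design)
  selects 3 clusters by merging the two least-separated intermediate
  states; downstream stages then still run but against a coarser
  partition.
- Transition-cell edges can tie (e.g. a zero-weight link inside an
  otherwise forced path); ties resolve deterministically but
  arbitrarily, so the inferred order between weakly connected clusters
  is less reliable than between well-bridged ones.
- The energy's absolute scale depends on network density and gene count
  and is not comparable across datasets; only within-dataset contrasts
  are meaningful.
- Mediator scores use shortest-path betweenness on 1/prob distances,
  which ignores parallel weak paths that a true current-flow measure
  would aggregate.
- The library-size normalization couples communication probabilities to
  total transcriptional output; designs in which ligand gradients grow
  slower than library size will appear flat (see the graded-profile
  discussion above).
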