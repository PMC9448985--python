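# Methods

## Model

`lncda` treats lncRNA–disease association prediction as supervised link
prediction on a tripartite network. The observed lncRNA×disease layer LD
is sparse; the two auxiliary layers (lncRNA×miRNA LM, miRNA×disease MD)
carry indirect evidence: a lncRNA and a disease that interact with many
of the same miRNAs are more likely to be associated. The pipeline has
four stages.

**Geometric complement.** LMD(i,j) = LM(i,·)·MD(·,j) / (‖LM(i,·)‖₁ +
‖MD(·,j)‖₁). The numerator counts shared miRNA partners; the denominator
normalises by the total miRNA degree of the pair, so hub lncRNAs and hub
diseases are not automatically favoured. Since the dot product is at
most the smaller of the two L1 norms, LMD ≤ 0.5; the merged matrix
LDnew = max(LD, LMD) therefore equals 1 exactly where LD does, i.e.
complementation only fills in unobserved cells. Cells where both degrees
are zero have no heterogeneous evidence; they are defined as 0 and their
count is logged rather than raised, because empty rows/columns occur
routinely after registry alignment.

**Similarity fusion.** Jaccard similarity captures overlap of binary
interaction profiles; the Gaussian interaction profile (GIP) kernel,
exp(−λ‖xᵢ−xⱼ‖²), captures graded profile distance. The bandwidth is
normalised by the mean squared profile norm over all entities of the
kind (λ = λ̃ / mean‖x‖²; λ̃ = 1 by default), which makes the kernel scale
with network density. The two matrices are fused by the elementwise
maximum — an optimistic combination that keeps whichever notion of
similarity is stronger for a pair. Two deliberate conventions:

- Jaccard of two all-zero profiles is 0, not NaN: no shared evidence is
  treated as no similarity.
- The Jaccard denominator is the set union |A∪B|. A Dice-like
  alternative (|A|+|B|) is available via `denominator="sum"` for
  comparison, since the two readings differ only by counting the
  intersection twice.
- Similarities are computed from the original binary LD by default;
  `similarity_source="ld_new"` computes them from the complemented
  matrix instead (GIP on the real-valued profiles, Jaccard on their
  support). The default keeps the similarity stage independent of the
  complement stage.

**Feature compression.** Raw features are [LDnew block | similarity
block], width l + d for both entity kinds (652 at the reference scale
l = 240, d = 412). A single-hidden-layer autoencoder —
input(p) → dense(latent, sigmoid) → output(p, sigmoid), MSE loss — is
trained separately per entity kind; this is the minimal architecture
consistent with one hidden compression layer, and all inputs already lie
in [0, 1], so the sigmoid output needs no rescaling. Defaults: latent
256, Adam with learning rate 1e-3, 200 epochs, batch 32, Glorot-uniform
initialisation. It is implemented directly in NumPy (a dense layer pair
needs no framework) with fully seeded initialisation and batch
shuffling, so training is bit-reproducible. The loss history (initial
loss plus one entry per epoch) is recorded; on all fixture data the
final loss is below the first. Latent sizes over the grid
{16, 32, 64, 128, 256, 512} can be compared with `run_dimension_sweep`
(`lncda sweep`); cells whose dimension is not smaller than the raw width
are recorded as NaN and skipped rather than failing the grid.

**Classifier.** All observed pairs are positives; the same number of
unlabeled pairs is drawn uniformly without replacement as negatives
(seeded). Sampling happens once, before cross-validation — the CV then
evaluates the classifier on that fixed balanced set; per-fold resampling
is available behind a flag. Pair features are [encoded lncRNA | encoded
disease] — this order is arbitrary but fixed for reproducibility. The
random forest uses ntree = 500 and mtry = ⌊√p⌋ (the classical
classification defaults; "default" is implementation-relative, so both
values are pinned and echoed in the report). Scores are vote fractions
in [0, 1]. Metrics: per-fold AUC (rank statistic on held-out scores),
AUPR (integrated precision–recall curve), and recall/accuracy/F1 at a
0.5 cutoff; reported values are arithmetic fold means (pooled held-out
scores are also kept on the report). Candidate ranking scores only
LD == 0 pairs and breaks score ties by entity name so output is
deterministic.

## Feature-information leakage

In the default pipeline the similarities and autoencoders are computed
from the full LD matrix, so a held-out positive pair has contributed to
the features it is later evaluated on; the report carries an explicit
note to that effect. `strict_features=True` rebuilds the complement,
similarities and encoders per fold from the training-fold positives
only. On planted networks the strict estimate does not exceed the
default one (the paired test in the suite checks the direction), and the
strict mode is the honest generalisation estimate.

## Synthetic networks

The generator draws non-negative latent factors U (l×r), V (m×r),
W (d×r) from Gamma(2, 1) and binarises U·Wᵀ, U·Vᵀ, V·Wᵀ by keeping the
top cells of each matrix at the target density (exact count control
regardless of factor scale; ties broken by an infinitesimal random
jitter). Because the layers share factors, two-hop miRNA evidence
genuinely predicts held-out LD pairs — the property that makes
end-to-end recovery testable. Defaults mirror the reference data scale:
l = 240, m = 495, d = 412, LD density 2697/(240·412) ≈ 0.0273, rank 6,
10% of LD positives held out into a truth list (removed from LD but
still scoreable as candidates, the way novel associations surface in a
screen). The auxiliary densities are not pinned down by the reference
data, so they were fixed once at values realistic for curated
interactomes of this size: lm_density = 0.01, md_density = 0.05.
`noise_flip_rate` defaults to 0: curated positive associations are
experiment-backed, and the unlabeled zeros already contain unknown
positives, which is the dominant label noise in this problem.

What the generator does **not** emulate: the heavy-tailed degree
distributions, block structure and name semantics of real curated
networks, correlated measurement biases, or disease-ontology
relatedness. Passing recovery tests therefore shows the pipeline can
extract planted shared structure at realistic size and sparsity — not
that it attains any particular performance on real curated data.

## Numerical choices

- Similarity matrices are symmetrised as (S + Sᵀ)/2 and clipped to
  [0, 1] to remove floating-point asymmetry; the GIP diagonal is set to
  exactly 1.
- 0/0 cells (Jaccard, geometric complement) are defined as 0; the
  complement logs a count of such cells.
- GIP on an all-zero matrix raises (the bandwidth normaliser is 0).
- All stage seeds derive deterministically from a single pipeline seed,
  and per-fold forests use seed + fold, so end-to-end runs are exactly
  reproducible.
- Problem sizes in the test suite: unit and property tests use networks
  up to ~60 entities per side; the end-to-end recovery checks run five
  reference-scale networks (240×495×412), which dominate suite runtime.
  The acceptance script averages CV metrics over three reference-scale
  seeds.

## Known limitations

- Randomly drawn negatives can be unknown positives; this depresses
  measured precision and is inherent to the balanced-sampling design.
- The default (non-strict) CV estimate is optimistic; see the leakage
  section.
- Only miRNA-mediated heterogeneous evidence is used; no disease
  semantic similarity or lncRNA functional similarity is incorporated.
- Alternative classifiers are reachable by training any scikit-learn
  estimator on `SampleSet.features`/`labels`, but only the random
  forest is wired into the pipeline.
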