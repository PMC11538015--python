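# Methods

## Problem

Protein function prediction is a multi-label classification task: each
protein may carry many Gene Ontology (GO) terms, and each GO aspect
(Biological Process, Molecular Function, Cellular Component) defines its own
label space. STRING-style protein–protein interaction (PPI) resources
provide not one network but seven, one per evidence channel (neighborhood,
fusion, cooccurence, coexpression, experimental, database, textmining), and
these channels differ widely in density, structure and noise. Concatenating
embeddings of all channels dilutes the informative ones; using a single
channel discards complementary evidence. `gosel` treats the choice of
channels (plus a protein-attribute matrix and optional extras such as
protein language-model embeddings) as a discrete feature-selection problem
solved jointly with classifier training.

## Model

**Feature matrix space.** Each evidence network is turned into an
`n x d_f` per-protein feature matrix by a pluggable backend; together with
the attribute matrix these form the ordered space `M` (eight matrices for
seven channels + attributes). A binary mask `m` over `M` says which
matrices the classifier consumes.

**Classifier.** One single-layer ReLU projection per matrix maps each
`d_f` to a common width `d_c`; the branch outputs of the selected matrices
are averaged (an unweighted mean, so the result is order-invariant and
independent of unselected matrices) and passed through a two-layer
prediction head that scores all `K` GO terms. Scores are per-term logistic
probabilities by default. A softmax head is available as an option, but the
asymmetric loss treats each term as an independent Bernoulli probability,
which a softmax cannot represent, so the logistic head is the default.

**Asymmetric loss (ASL).** With scores `p_ik` and labels `y_ik`,

    ASL = (1/(N K)) Σ_i Σ_k [ −y_ik (1−p_ik)^{γ+} log p_ik
                              − (1−y_ik) p_ik^{γ−} log(1−p_ik) ]

with focusing exponents `γ+ = 0`, `γ− = 2` by default. At `γ+ = γ− = 0`
this is exactly mean binary cross-entropy (asserted to 1e-8 in the tests);
`γ− = 2` down-weights easy negatives, which dominate sparse GO label
matrices. Scores are clipped to `[1e-7, 1−1e-7]` before the logarithms.

**Selector.** A two-layer MLP (`|M| → 32 → 1`) mapping a mask to a scalar
that approximates the classifier's validation ASL under that mask, fitted
by squared error. Because the input is a vector, the absolute input
gradient at the all-0.5 probe mask ranks the matrices by importance.

## Training procedure

Three stages; the classifier trains for `E1+E2+E3` epochs (less early
stopping), the selector for `E1+E2`. Defaults: `E1 = 100`, `E2+E3 = 100`
(50/50), `N_f = 2` (the cap on selected matrices; 2–5 is the recommended
range), one full-batch Adam step per epoch.

1. **Exploration.** Sample a random mask with 1..N_f ones (subset size
   uniform, members uniform — every admissible mask has positive
   probability), take one classifier step on the training split, measure
   the validation ASL `L_c`, and fit the selector on `(m1, L_c)`.
2. **Exploitation.** Read the selector's input gradient at the 0.5 probe,
   keep the top-`N_f` matrices (ties to the lower index) as the narrowed
   space `M_f`, evaluate candidate subsets of `M_f` on the validation split
   forward-only (all `2^|M_f| − 1` subsets when that is at most 31,
   otherwise 20 uniform draws), record each, and use the best candidate
   `m2` for one classifier step and one selector fit.
3. **Refinement.** `m*` is the mask with the lowest loss anywhere in the
   record (earliest on ties; a `record_scope="stage2"` option restricts
   the argmin to stage-2 entries). Only the branches named by `m*` and the
   head keep training; unselected branches receive no gradient and are
   bit-identical before and after. The model is checkpointed at the epoch
   of best validation Fmax (patience 10) and test metrics are reported from
   that checkpoint.

### Selector fitting: replay refits

The literal scheme — one gradient step per epoch on the newest
`(mask, L_c)` pair — fails at desk scale: with ~100 noisy, drifting
observations, a single online pass cannot fit the surrogate, and the 0.5
probe lies outside the training distribution of binary masks with at most
`N_f` ones, so an underfit MLP extrapolates arbitrarily there. On the
planted benchmark the pair-recovery rate was 10–20%, although a ridge
regression on the very same record identifies the planted pair every time
and the same MLP trained to convergence on the record ranks it correctly
in 9/10 seeds. Each observation therefore triggers one online step on the
new pair plus 20 full-batch Adam steps (lr 1e-2, weight decay 1e-3) over
the accumulated record. The weight decay keeps the network near-linear
where the data do not constrain it, which is what makes the probe gradient
a faithful importance measure. This raised recovery to 19/20 under
identical conditions.

### Other numerical choices

- Classifier Adam lr 3e-3 (full batch), selector lr 1e-2; chosen by manual
  search on the synthetic benchmark.
- `d_c = 64`, head hidden width 64, selector hidden width 32 at desk scale.
- He initialization throughout, deterministic per seed; one master seed
  fixes the mask sequence, all initializations, and `m*`.
- Ties (importance ranking, record argmin, Fmax threshold) always resolve
  to the lowest index / earliest entry / smallest threshold.

## Data handling

- **Edges.** A channel interaction exists wherever the score is strictly
  positive; duplicate pairs (either order) keep the maximum score; whole
  matrices are min-max normalized globally (a constant matrix maps to
  zeros). Per-row normalization was considered and rejected to preserve
  relative row densities.
- **Temporal holdout.** A protein's split is decided by its earliest
  annotation date in the chosen aspect: before 2018-01-01 train,
  2018-01-02..2020-12-31 validation, 2021-01-01 onwards test. The boundary
  day 2018-01-01 is not covered by any window as printed; it goes to train
  (configurable). Unparseable dates are dropped with a warning count.
- **Label filters.** Retained GO terms need at least 10/5/1 positive
  proteins in train/val/test and at most 5% of the network's proteins in
  total. Evidence is restricted to the experimental codes IDA, IPI, EXP,
  IGI, IMP, IEP, IC, TA. GO true-path propagation is *not* applied (off by
  default, switchable).
- **Attributes.** Binary indicator columns (Pfam domains, subcellular
  locations) with fewer than six supporting proteins are removed.
- **Protein universe.** Proteins present in at least one network and the
  attribute table; identifiers are taken verbatim.

## Embedding backends

`noembed` returns normalized adjacency rows (`d_f = n`). `mlpae` is a
one-hidden-layer autoencoder reconstructing adjacency rows under binary
cross-entropy. `transformerae` fuses one network with the shared attribute
matrix: per protein, the adjacency row and the attribute row are projected
to a common width and form a two-token sequence that passes through
multi-head self-attention blocks (scaled dot-product attention,
`softmax(QK^T/√d_k)V`, with residual connections and a position-wise ReLU
layer); a mirror decoder reconstructs both inputs under binary
cross-entropy, and only the network-token encoder state enters the feature
space. The two-token design is the minimal structure in which both
modalities pass through shared attention layers yet keep separable hidden
states; full-scale systems use deeper stacks (six layers per side), and the
desk-scale default is 2+2 layers, width 64, 4 heads, 200 epochs. `node2vec`
and variational graph autoencoder backends are name-reserved stubs —
published results indicate the selection procedure is largely insensitive
to the embedding choice.

All neural components run on a small in-package reverse-mode automatic
differentiation engine over numpy arrays (`gosel._autodiff`), validated
against central finite differences in the test suite.

## Synthetic benchmark

The generator emulates the regime the selector must detect: a feature
space in which a known subset of matrices carries the label signal and the
rest are noise.

- Proteins get block assignments (4 blocks) and latent factors
  `z = μ_block + 0.5 ε` (6 dimensions).
- Per-term labels follow a logistic model on `z` with a slope of 6 standard
  deviations and an intercept set by quantile so the expected density is
  0.15; terms are resampled until the 10/5/1 split filter holds, and every
  protein receives at least one term (the universe is annotated proteins).
- Each planted matrix is `β · z[:, S_m] A_m + ε` where the factor sets
  `S_m` partition the latent dimensions across the planted matrices — no
  single matrix covers the signal, so the full planted subset is the
  uniquely best choice. Noise matrices are pure `ε`. All matrices are
  standardized, leaving first and second moments uninformative.
- `β = 2` by default, calibrated once so that a per-term logistic probe on
  the concatenated planted pair reaches validation micro-AUPR ≈ 0.8 while
  any single planted matrix stays near 0.49 and noise near 0.18.
- Companion generators produce stochastic-block-model networks per channel
  (planted channels block-aligned with the labels, noise channels
  density-matched Erdős–Rényi), block-affine binary attributes, and dated
  annotation tables that round-trip the temporal split exactly.
- Default size n = 600, split 60/20/20, 12 terms, 8 matrices of width 32,
  planted pair {1, 6}.

What the generator does *not* emulate: GO term hierarchies and term–term
correlations, realistic STRING score distributions, heavy-tailed degree
distributions, annotation biases between validation and test periods.
Passing tests therefore show that the machinery detects a planted
informative subset under matched-moment noise — not that it reproduces any
particular published score on real proteomes. One deliberate deviation: the
5% label-generality cap cannot hold at desk scale when every protein is
annotated (K × 0.05 n < n), so synthetic datasets leave the cap off; the
cap itself is implemented and brute-force tested.

## Evaluation

Fmax scans thresholds 0.01..0.99 (step 0.01): precision at τ averages
per-protein precision over the s(τ) proteins with at least one score
strictly above τ; recall averages per-protein recall over all proteins
(proteins without true terms contribute zero; precision is defined 0 when
s(τ) = 0). Micro-AUPR is average precision on flattened (protein, term)
pairs; macro-AUPR is the unweighted mean over terms with at least one
positive (empty terms are skipped and counted). Subset accuracy, micro-F1
and macro-F1 are computed at the threshold that maximizes validation Fmax.
The naive baseline scores every test protein with each term's training
frequency.

## Known limitations

- Desk-scale defaults throughout; the problem sizes here (hundreds of
  proteins, tens of terms) are chosen so the full benchmark suite runs in
  minutes on one CPU.
- The stage-2 exploitation loop can self-confirm a wrong narrowing when the
  surrogate is poor; the replay refits mitigate but do not eliminate this
  (recovery is ~90–95%, not 100%).
- No GO-hierarchy propagation, no homology/ensemble post-processing, no
  information-content-weighted metrics (S-min), no confidence intervals.
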