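# Methods

This note documents the models, schedules, and numerical choices behind the
package, and what its synthetic experiments do and do not demonstrate.

## Setting and model

We simulate cross-silo federated learning over `n` data-silo nodes whose raw
samples may never leave their origin. Knowledge moves in two ways only:
model weights travel between nodes (each such movement is one *transfer
operation*, the unit of communication cost), and teacher models contribute
*soft labels* — temperature-softened class distributions — to the loss of a
student training on whatever node currently hosts it.

The distillation objective is the canonical softened-KL form: for student
logits `z_i`, hard label `y_i`, and combined teacher distribution `q_i`,

    L_i = α · CE(y_i, softmax(z_i)) + (1 − α) · T² · KL(q_i ‖ softmax(z_i / T))

and the batch loss is `Σ w_i L_i / N` with `w_i` = sample weight × class
weight of `y_i` × node weight. Dividing by the batch size `N` rather than by
`Σ w_i` makes `α = 1` with unit weights coincide exactly with the plain mean
cross-entropy used by direct training — this is what makes the single-node
reduction test an equality of weight vectors, not an approximation. The
method calls for a KL-divergence term added to the standard cross-entropy
loss; the canonical softened form above realizes that and is exposed through
`DistillationConfig`. Multi-teacher combination averages softened distributions *before* a single
KL (a `per_teacher_kl` switch exists for sensitivity runs); the three
weighting levels are multiplicative, with class weights defaulting to
inverse label frequency `N/(K·N_c)` computed per node, and node weight
defaulting to 1.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| temperature `T` | 2.0 | softening of teacher/student outputs; higher flattens |
| `α` | 0.5 | weight on hard-label CE vs. teacher KL |
| teacher weights | uniform | convex combination of teacher distributions |
| class weights | inverse label frequency | counteracts asymmetric-noise label imbalance |
| `k` (epochs/node) | 2 | student residence before moving on |
| `R` (rounds) | 2 | full traversals of the ring |
| learning rate / batch | 0.1 / 32 | minibatch gradient descent on the loss above |

The defaults `T = 2`, `α = 0.5`, uniform teacher weights are the field's
common conventions, exposed for tuning; they are not claims about any
particular published run.

## Transfer accounting

Ledger entries carry a `kind`: `train` for a delivery of a model to a
training node, `eval` for a movement to the evaluation host. All reported
counts and closed forms count `train` deliveries only. At the end of every
round the traveling convoy (student plus teachers) passes through the
evaluation host, where the student is scored on the shared validation set
and checkpointed; this keeps the accounting exact — `n · R · (t + 1)`
training deliveries — for every ring size including the degenerate
single-node ring, and means validation never requires moving validation
data. Per-circuit costs: each of a cluster's `s` models makes `s` hops of
its ring (the last hop returns it home), giving `Σ s_i²`, plus `m²` for the
representative circuit when `m > 1`; the single-cluster case omits the
inter-cluster term (a 15-node ring costs 15² = 225, not 226). In the closing
pass the `n` per-node models travel as one convoy, and a model already
resident at a node is not counted as transferred to it (5 nodes → 24, not
25). The client–server comparator rounds the per-epoch batch count to one
decimal by default (1125/16 ≈ 70.3 → 56,240); an `exact` mode returns the
unrounded 56,250.

## Training schedules

*Specialists* train only on their node's data; nothing moves, and the data
access log proves it. *Student traversal* (`daita_train`) visits nodes in
the listed order (no start node is canonical; the list head is used), trains `k` epochs per node on the local transfer set, and
selects the final model as the best per-round checkpoint by validation
balanced accuracy (or log loss). Teachers are frozen throughout. *Closing
pass*: one traversal in which every per-node model trains at every node with
the other models' softened outputs — snapshotted before any update at that
node, so the result does not depend on within-node update order — as its
teachers; the driver seeds the per-node models by locally refining copies of
the traversal's best model — a desk-scale stand-in for training `n` students
fully in parallel before the joint distillation. *Cluster training*: within each cluster every
specialist circuits the cluster ring once as a student, distilling against
the resident node's specialist (so only students move and the `Σ s_i²` count
is exact); the cluster's generalists are weight-averaged into a
representative, and representatives circuit the cluster-level ring the same
way, training at each cluster's head node. Weight averaging is also the
privacy device: a representative is not invertible back to any member's
exact parameters. "Concurrent" cluster training is simulated sequentially
with independent seed streams; the contract is result-equivalence to
parallel execution, not wall-clock parallelism.

Whether the traversal's teachers should themselves be products of a prior
traversal is a genuinely open design point; this implementation defaults to
per-node locally trained specialists as teachers, and `daita_train` accepts
any teacher dict should the other sourcing be wanted.

## Determinism

One global seed fans out by stable SHA-256 hashing to independent streams
(per node, per model, per purpose), so adding a node never perturbs another
node's randomness, and derived seeds stay below 2³¹. Model initialization,
batch shuffling, splits, partitions, and noise injection all draw from such
streams; rerunning a config byte-reproduces the metrics CSV.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the study conditions at their stated sizes: 2250+2250
balanced samples, an 80/20 class-stratified split (3600/900 — stratification
is implied by the printed per-node class counts, which require an exactly
balanced training set), even stratified partitions (720/node at 5 nodes,
240/node at 15), deterministic asymmetric flips of 50% (class 0→1) and 10%
(class 1→0) chosen by seeded permutation with exact counts
(`round(rate·N_c)`), reproducing 216/504 and 72/168 per-node compositions
and 17%/36% (1/6 and 5/14) within-class noise; a clean test set; and the
five-clinic non-IID size profile via largest-remainder scaling (for tiny
totals, at least one item per clinic). Exact-count flipping was chosen over
i.i.d. Bernoulli flips because the printed per-node compositions are exact
numbers, not expectations.

Two sample kinds: `gaussian_blobs` (2-D Gaussians, means `class_separation`
apart, unit variance — separation 3.0 is the default "realistic but not
trivial" regime: a linear model exceeds 95% clean accuracy, and label noise
visibly damages it) and `toy_images` (16×16 class-conditioned stripe
textures in Gaussian noise, exercising the PNG/manifest pipeline).

What passing these experiments shows: the *mechanics* of the method — exact
cost accounting, loss correctness against an independent oracle, exact
reduction to direct training, privacy invariants — and the *direction* of
its behavior under asymmetric label noise: a centrally trained model fits
the noisy label posterior and collapses on the heavily flipped class, while
multi-teacher distillation with inverse-frequency class weighting recovers
it. What it does not show: accuracy levels of deep pretrained networks on
real photographs or clinical embryo images; the synthetic uplift
(~20–30 points at separation 3.0) is much larger than what is achievable on
real data, where features do not separate classes nearly as cleanly.

## Model contract

Any classifier exposing `train_epochs` (under the distillation loss),
`predict_logits`, and flat `export_weights`/`import_weights` can ride the
machinery. Two numpy reference models are provided — softmax regression and
a one-hidden-layer tanh MLP — trained by minibatch gradient descent using
the analytic logit gradient of the loss (`α·w·(p − 1_y)/N` for the CE term,
`(1−α)·T·w·(p_T − q)/N` for the KL term, verified against central finite
differences). Deep convolutional backbones are deliberately out of scope.

## Numerical choices and degenerate inputs

Probabilities are clamped to `[1e-12, 1]` inside logarithms (degenerate,
fully confident teachers would otherwise produce infinities). Argmax ties
resolve to the lower class index. Log loss uses the natural logarithm.
Accuracies are reported in percent to two decimals. Selection ties resolve
to the earliest checkpoint. A node missing a class warns and renormalizes
class weights over the classes present. Empty batches, zero batch sizes,
self-transfers, and mismatched weight-vector lengths raise validation
errors. Split and partition remainders are allocated by largest remainder /
round-robin so no node is ever empty.

## Problem sizes

Unit tests run on pools of a few hundred samples; the training-property
checks run the full protocol sizes (3600/900 train/validation, 1000+1000
clean test, 5 seeds) with the linear model, which keeps the whole suite in
the seconds range while exercising every schedule at the study's stated
sample counts.

## Known limitations

- No real network transport, encryption, or secure aggregation; transfers
  are in-process and ledger-recorded.
- The closing-pass seeding (local refinement of the traversal's best model)
  is one reconstruction of an underspecified step; alternatives (fully
  independent per-node students) are expressible through the library API.
- The ensemble alternative and `single_transfer_set` mode are implemented
  as driver-level steps, not separately optimized pipelines.
- Linear/MLP models cannot capture architecture-specific distillation
  effects (e.g. cross-architecture teacher/student pairs), although the
  contract permits mixing architectures everywhere except weight averaging.
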