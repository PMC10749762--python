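# Methods

This note documents the model, its numerical choices, the synthetic study
design, and the limits of what the test suite demonstrates.

## Model and procedure

The classifier treats host disease-status prediction as semi-supervised node
classification on an inter-host similarity graph, with a domain-adaptation
stage that makes the graph robust to cohort-level distribution shift.

**Normalization.** Relative abundances are transformed as
`log10(x + pseudocount)` and z-scored per taxon. The pseudocount (default
1e-5, below typical MetaPhlAn detection) is added to *all* cells, keeping the
transform strictly monotone. Mean and *population* standard deviation are
estimated on training samples only and frozen; test samples are normalized
with the same statistics, so no test information enters normalization.
Zero-variance taxa are mapped to 0 (uninformative) with a logged warning.
Feature spaces of different cohorts are aligned to the lexicographically
sorted union of taxa, zero-filling taxa a profiler did not report;
union-with-zero-fill keeps test-only taxa rather than discarding them.

**Adaptation network.** A fully connected network (hidden widths 256/128/64,
ReLU, linear 2-class head) is trained full-batch on the labeled source
samples with loss `CE + λ · MMD²` where the MK-MMD couples the last hidden
layer's activations of source and target samples. MK-MMD is a biased
V-statistic under an equal-weight mixture of five Gaussian kernels whose
bandwidths are the median pairwise distance of the pooled batch scaled by
{0.25, 0.5, 1, 2, 4}; the bandwidth is treated as a constant in the gradient
(standard practice). The V-statistic form makes the estimate non-negative,
exactly zero for identical inputs, and defined for a single target sample
(the degenerate single-run case, where a warning is logged). Gradients are
derived analytically and verified against finite differences in the test
suite.

**Graph.** Latent features of the last hidden layer embed all samples; each
node selects its k = 5 nearest neighbors by Euclidean distance (ties at the
k-th neighbor broken deterministically toward the lower node index), and the
directed relation is symmetrized by union — an edge exists if either endpoint
selects the other — preserving every stated neighbor connection. Edges are
unweighted. The convolution operator `D̃^{-1/2}(A + I)D̃^{-1/2}` is
precomputed.

**GCN.** Two convolution layers (hidden width 64, ReLU, dropout 0.5 during
training) followed by a linear head; node features are the normalized
abundance vectors; the loss is cross-entropy over the labeled (training)
nodes only. The masked labels are copied out before training starts, so
labels attached to test nodes can never influence the weights — asserted
bitwise in the tests. Probability ties at 0.5 are resolved toward health
(conservative).

**Biomarker ranking.** The graph is built once from the full training data
(latent space of an unregularized classifier, since a train-only setting has
no target domain) and held fixed; the GCN is then retrained per species with
that species' normalized abundance as the sole node feature, and species are
ranked by the training AUC they achieve alone (descending, dense ranks, ties
listed lexicographically). Fit-on-train evaluation is used rather than
internal cross-validation.

**Contribution scores.** For each biomarker and each correctly predicted
training sample (model argmax equals the true label on the unmodified node),
the two substitution rules matching the biomarker's within-sample abundance
rank are applied to the *raw* abundances; the sample is re-normalized with
the frozen training statistics and GCN inference is re-run with the graph
topology held fixed — rebuilding the graph would conflate topology and
abundance effects. The contribution value is |ΔP(health)|. Rules Min2Max,
Min2Median and Middle2Max raise the abundance; Max2Median, Max2Min and
Middle2Min lower it. A value accrues to Increase2Disease when a raising rule
lowers P(health), to Increase2Health when it raises it, and symmetrically
for lowering rules; each type's score is the mean over all n correctly
predicted samples (zero contributions count in the denominator). For a
sample with constant abundances the taxon is simultaneously maximum and
minimum; the canonical rule pair is the Max pair, any rule whose rank
condition holds is accepted, and all substitutions are then no-ops.

**Evaluation.** AUC is the Mann–Whitney concordance of disease
probabilities. Repeated stratified 10-fold cross-validation scores pooled
out-of-fold predictions per repeat (well defined even when folds are small)
and reports the mean with margin of error `t(1−α/2, n−1) · s/√n`, `s` the
sample (n−1) standard deviation over repeats and α = 0.05. Leave-one-study-out
holds out an entire cohort as the unlabeled target domain; its labels are
used only for scoring.

## Tunable parameters

| Parameter | Default | Notes |
|---|---|---|
| pseudocount | 1e-5 | added to all cells before log10 |
| k_neighbors | 5 | kNN graph degree (outgoing, before union) |
| λ (adaptation penalty) | 0.3 | 0 disables adaptation; large values over-align and can erase class structure when shift is strong |
| regularized layers | last hidden | configurable to any subset of {1,2,3} |
| DAN widths / epochs / lr / weight decay | 256·128·64 / 300 / 1e-3 / 5e-2 | full-batch Adam; weight decay is essential at ~100 features per ~200 samples |
| GCN layers / width / epochs / lr / dropout / weight decay | 2 / 64 / 200 / 1e-2 / 0.5 / 5e-4 | standard graph-convolution practice at this size |
| CV folds / repeats / α | 10 / 10 / 0.05 | per-repeat AUC pools out-of-fold predictions |

All randomness flows through seeded NumPy generators; identical seeds
reproduce every artifact byte-for-byte. Per-stage seeds are derived
deterministically from the run seed.

## Synthetic study design

The generator emulates a multi-study case/control collection: per-taxon base
log10 means shared across cohorts (sd 1.5 — abundances spanning orders of
magnitude), between-subject variation of 0.5 log10 units plus 0.2 units of
measurement noise, five planted taxa (three promoters, two protectors) whose
log10 abundance shifts by 1.0 in case samples, per-cohort per-taxon offsets
of sd 0.7 on the log scale (study-level batch/dietary effects larger than
biological variation), compositional closure to row sums of 1, and balanced
labels. The standard design is 3 cohorts × 100 samples × 100 taxa.

Closure makes the nuisance structure realistic and genuinely hard: when
promoters dominate a sample's composition, raising them in cases pushes all
other relative abundances down, inducing spurious associations whose
direction depends on which taxa dominate in a given cohort — associations
that do not transfer across cohorts. Individual data realizations therefore
vary widely in difficulty, which is why the end-to-end checks are stated as
medians (and win counts) over ten generator seeds rather than per-seed
bounds.

What the generator does **not** emulate: sparsity/zero-inflation of real
profiles, taxon–taxon correlation beyond closure, uneven cohort sizes,
repeated sampling of the same individual, and label noise. Passing tests
demonstrate that the method recovers planted, compositionally entangled
signal under strong additive batch shift — not performance on real cohorts.

## Design choices where the design was open

- **Union vs mutual kNN symmetrization:** union, because each stated
  neighbor connection is preserved; mutual kNN can isolate nodes.
- **λ default:** 0.3. On the synthetic conditions, λ = 1 sometimes
  over-aligned the marginals and degraded held-out AUC; 0.3 was the most
  robust across data realizations while still reducing source/target MMD by
  roughly two orders of magnitude.
- **Latent layer:** the last hidden layer is both regularized and used for
  graph construction (configurable).
- **Weight decay:** without it the networks drive the training cross-entropy
  to exactly zero (memorization at ~100 features per ~200 samples) and the
  latent space encodes cohort-specific noise; L2 regularization restores
  neighbor-label purity of the graph.
- **Per-repeat CV AUC** pools out-of-fold predictions instead of averaging
  per-fold AUCs, which is ill-defined for very small folds.
- **Single-run mode** keeps the (degenerate, single-target-point) MK-MMD term
  by default and logs a warning; adaptation can be disabled via λ = 0. A
  batch run with a one-sample test set and a single run on that sample are
  the same computation by construction.
- **Biomarker ranking** retrains only the GCN per species on one fixed
  graph; rebuilding the whole pipeline per species would conflate graph
  topology changes with single-species signal and is two orders of magnitude
  slower.

## Known limitations

- With a single test sample the graph contributes little (the GCN cannot
  exploit unlabeled structure), mirroring the batch > single performance gap.
- MK-MMD aligns marginal latent distributions; it cannot repair
  label-conditional shift (e.g. closure-induced sign flips between cohorts),
  which is the dominant failure mode on hard synthetic realizations.
- Contribution values are small in absolute terms when the GCN spreads
  evidence over many features; only their relative pattern across the four
  types is interpreted.
- The networks are plain NumPy implementations with analytic gradients —
  adequate and fully deterministic at these problem sizes (hundreds of
  samples), but not intended for thousands of nodes.
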