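# ensemblediff

Supervised split autoencoders for comparing protein conformational ensembles.

## The problem

Molecular-dynamics simulations of protein variants produce ensembles of
structures that often overlap heavily: the variants differ not in which
conformations they can reach but in how *probable* a subtle structural
feature is — for example a sub-Ångstrom compaction of backbone hydrogen
bonds that tracks thermodynamic stability, buried under nanometre-scale
loop motion. Unsupervised dimensionality reduction (PCA, plain
autoencoders) ranks directions by geometric variance and misses such
features. `ensemblediff` is for computational biophysicists who have
ensembles for two classes of variants (stable/unstable, high/low activity)
and want a low-dimensional representation that is *forced* to expose the
structural basis of the class difference, plus automated tools to read that
basis off the trained model.

## The model

Each frame's backbone coordinates **x** (atoms C, CA, CB, N; no carbonyl
oxygens) are superposed on a reference and passed through a frozen
whitening layer, x̃ = C₀₀^(-1/2) (x − x̄), fit on the pooled training
frames. One or two encoders (affine + logistic nonlinearity, a four-fold
reduction layer, then a bottleneck) map x̃ to a latent vector **z**; when
the architecture is split, encoder A sees only atoms within a cutoff of a
region of interest and the sub-latents are concatenated, z = (z_A, z_B).
A decoder reconstructs x̂ through a frozen unwhitening layer, and a
logistic head ŷ = σ(w·z_A + b) must predict a per-frame label. Training
minimizes

  L = ℓ_recon + ℓ_class + ℓ_corr,

where ℓ_recon is the mean of |x̃ − x̂̃| + (x̃ − x̂̃)² over batch and output
nodes, ℓ_class is binary cross-entropy against the (possibly fractional)
frame labels, and ℓ_corr = Σ_{i≠j} Cov(z_i, z_j)² decorrelates the latent
variables. Training is progressive (shallow pretraining → frozen-prior
bottleneck training → full fine-tuning, Adam, lr 1e-4, batch 32, 20
epochs/stage) with validation-based model selection.

Because only the variant, not the frame, carries a label, labels are
refined by expectation maximization: after each epoch, each frame's label
is replaced by the conditional expectation of its Bernoulli realization
given class-level bounds (S_L, S_U) on how many frames per batch carry the
property,

  y_i = ŷ_i · P(S_L−1 ≤ ŷ_r − ŷ_i ≤ S_U−1) / P(S_L ≤ ŷ_r ≤ S_U),

with the batch count ŷ_r a Poisson-binomial variable computed exactly by
convolution. This turns hard variant labels into a continuum of per-frame
labels that allows ensemble overlap.

The network and its training loop are implemented directly in NumPy with
analytic gradients and a hand-written Adam optimizer — the architecture is
four affine layers plus a classifier head, which keeps runs exact,
dependency-light and bit-reproducible under fixed seeds.

## Worked example

The built-in generator creates the package's benchmark conditions: two
classes of pseudo-protein ensembles, identical except that a single
atom-pair distance is 0.50 nm ("compact") vs 0.58 nm ("extended") with
probability 0.75 in the positive class and 0.25 in the negative class,
under a 0.5 nm RMS nuisance loop mode and thermal jitter.

```python
import ensemblediff as ed
from ensemblediff.losses import LossWeights

spec = ed.ToyEnsembleSpec(n_frames_per_variant=1000, seed=1)
dataset, compact = ed.generate_toy_ensembles(spec)
dataset = ed.align_to_reference(dataset)

region = ed.split_region(dataset, target_residue=15, cutoff=1.0)
arch = ed.ArchitectureSpec.for_split(region, total_latent=12, seed=0)

supervised = ed.run_training(dataset, arch, ed.TrainingConfig(), region=region,
                             initial_labels=compact.astype(float))
baseline = ed.run_training(dataset, arch,
                           ed.TrainingConfig(loss_weights=LossWeights(classify=0.0)),
                           region=region)
for name, result in (("supervised", supervised), ("unsupervised", baseline)):
    z = ed.encoder_a_latents(result.params, dataset.coords)
    roc = ed.frozen_latent_roc(z, compact.astype(int), seed=0)
    print(f"{name:>12s} frozen-latent AUC: {roc.mean_auc:.3f}")

em = ed.run_training(dataset, arch, ed.TrainingConfig(em_enabled=True), region=region)
K = em.labels.labels[em.train_indices]
cls = dataset.frame_classes[em.train_indices]
print(f"EM-refined label mean, positive class: {K[cls == 1].mean():.3f}")
print(f"EM-refined label mean, negative class: {K[cls == 0].mean():.3f}")

outputs = ed.predict_new_variant(em.params, dataset).labels
centers, _ = ed.cluster_conformations(dataset.flat_coords(), k=250, seed=0)
report = ed.distance_correlation_scan(
    dataset.coords[centers], region.encoder_a_atoms, outputs[centers],
    selection=("top_n", 3), atoms=dataset.atoms)
print(report.records[["atom_i", "atom_j", "pearson_r", "direction"]].to_string(index=False))
```

prints

```
  supervised frozen-latent AUC: 0.957
unsupervised frozen-latent AUC: 0.521
EM-refined label mean, positive class: 0.657
EM-refined label mean, negative class: 0.267
 atom_i  atom_j  pearson_r   direction
     58      62  -0.808075 contracting
     54      58   0.668211   expanding
     58      64  -0.633182 contracting
```

Three readings. First, a logistic classifier on the *frozen* supervised
sub-latent separates compact from extended frames almost perfectly
(AUC 0.96) while the matched unsupervised autoencoder's latent is barely
better than chance (AUC 0.52) — the classification task, not reconstruction,
is what organizes the latent space around the subtle feature. Second, EM
relaxes the binary variant labels to a continuum whose class means (0.66 /
0.27) sit inside the configured per-class occupancy bounds, reflecting that
both classes contain both states. Third, the automated attribution scan
recovers the planted feature: atoms 58 and 62 *are* the constructed pair,
ranked first, and "contracting" correctly reports that they approach each
other as the output label (association with the positive class) rises.

The same workflows are available from the shell via
`ensemblediff simulate|featurize|train|analyze|predict`, each driven by a
YAML config and writing a run manifest alongside its artifacts.

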