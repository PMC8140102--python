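# Methods

## Featurization and whitening

Frames are reduced to the backbone atoms C, CA, CB and N (carbonyl oxygens
dropped; glycine contributes three atoms since it has no CB), superposed on
an origin-centered reference structure by the closed-form least-squares
rotation (SVD solution of the orthogonal Procrustes problem, uniform
weights over all selected atoms), and flattened to 3N-dimensional vectors
in nm. Whitening is fit once on the pooled training frames of all variants
— never per variant — so every variant shares one coordinate embedding:
the transform stores the pooled mean x̄ and covariance C₀₀ and applies
x̃ = C₀₀^(-1/2)(x − x̄), with the inverse square root computed by
eigendecomposition. Eigenvalues below a floor of 1e-8 nm² are excluded
(pseudo-inverse). Rigid-body superposition removes exactly six degrees of
freedom, so even a full-rank ensemble yields a retained rank of 3N − 6; the
whitened covariance is the identity on the retained subspace and the
whiten/unwhiten round trip reproduces the projection onto that subspace.

All internal lengths are nm (the trajectory-format convention); Ångstroms
appear only at reporting boundaries (reconstruction RMSD, the 4.2 Å
hydrogen-bond rule used for compact/extended state labels).

## Architecture

The network is a supervised autoencoder of fixed depth: input → reduction
(ceil(input/4) units) → latent → expansion (the concatenated reduction
width) → output. All hidden layers use the logistic nonlinearity (the
default; tanh/relu are configurable) and the final whitened-output layer is
linear. When a region of interest is given, atoms within a cutoff (default
1.0 nm) of the target residue go to encoder A and the rest to encoder B;
the total latent budget is split proportionally to per-encoder atom counts
with largest-remainder rounding and a minimum of one unit per encoder. The
classification head is an affine map plus logistic on encoder A's latent
(the full latent in the unsplit architecture), read *after* the latent
nonlinearity — the output label is a linear combination of the latent
values passed through a sigmoid, and using the post-nonlinearity values
keeps the label a function of exactly the representation the decoder sees.

The whitening and unwhitening layers live inside the model as frozen
weights. Each encoder whitens only its own atoms' coordinates, using the
inverse square root of that region's block of the pooled covariance (a
submatrix of the full inverse square root would not whiten the regional
marginal). This routing makes encoder A's sub-latent and the output label
structurally independent of encoder-B atoms, which the tests verify by
direct evaluation.

Weights are initialized from a seeded uniform distribution scaled by
1/sqrt(fan-in). Gradients are analytic (hand-written backprop over the four
affine layers plus head) and verified against central finite differences to
~1e-10; the optimizer is a standard Adam (β = 0.9/0.999, ε = 1e-8, lr
1e-4). Everything is float64 and bit-reproducible under fixed seeds on a
single CPU.

## Loss

The objective is the unweighted sum (weights configurable) of:

* reconstruction — mean over batch and output nodes of |r| + r² with
  r the whitened-space residual. L1 pulls reconstructions onto the target,
  L2 penalizes outliers. Residuals are taken in whitened coordinates since
  the frozen layers bracket the trainable network; RMSD for reporting is
  computed after unwhitening.
* classification — binary cross-entropy, supporting fractional targets
  (it is linear in the target, so a fractional label is exactly the
  mixture of the two pure-label losses). Outputs at exactly 0 or 1 are
  clamped to [1e-7, 1 − 1e-7] and the clamp logged. The term is written as
  a minimized (negated) cross-entropy.
* latent decorrelation — Σ_{i≠j} Cov(z_i, z_j)² with the biased (1/N_b)
  covariance normalizer and both (i, j) orderings counted; the constant
  does not move the minimizer.

## EM label refinement

Per-frame labels K ∈ [0,1] are initialized to the variant's binary class.
After every training epoch, frames are grouped by class, shuffled with a
seeded generator, and partitioned into batches of the training batch size
(32; a trailing batch of fewer than two frames merges into its
predecessor). Class-level fraction bounds convert to counts as
S_L = ceil(f_L·n), S_U = floor(f_U·n). Each label is replaced by the
conditional expectation of its Bernoulli realization given that the batch's
success count lies in [S_L, S_U]; the count law is Poisson-binomial,
computed exactly by sequential convolution, and the leave-one-out laws come
from prefix/suffix convolutions (O(n²) per batch, exact — numerical
deconvolution is avoided). Classifier outputs are clamped to
[1e-7, 1 − 1e-7] before the computation; with that clamp every count window
has positive probability, so the infeasible-constraint error path exists
only as a guard. The update conserves the batch label budget: Σᵢ yᵢ equals
the conditional mean count and lies in [S_L, S_U], which the tests check
against 2ⁿ brute-force enumeration at n ≤ 12.

Default bounds are (0, 0.30) for the negative class and (0.60, 0.90) for
the positive class, expressing that a minority of negative-class frames and
a strong majority of positive-class frames are expected to carry the
property; a gentler preset (0.10, 0.40)/(0.60, 0.90) suits weaker class
separation. The E-step is applied at batch granularity (the bounds are
statements about a batch, and batch composition within a class is a seeded
shuffle); the batch size is exposed as a parameter.

## Training procedure

Stage 1 trains a shallow autoencoder (input → reduction → output, no
bottleneck) to produce priors for the reduction layer; stage 2 freezes
those priors exactly and trains the bottleneck, decoder and classifier;
stage 3 unfreezes everything. Each stage runs 20 epochs by default and
resets the optimizer state (the stages are separate trainings). Because
stage 1 has no latent layer, the shallow model carries a temporary
classification head on encoder A's reduction layer — discarded together
with the temporary decoder — so the classification loss and the per-epoch
EM update run uniformly across all three stages.

A per-variant-stratified validation split (10%) is excluded from gradient
updates *and* from EM batches, keeping model selection unbiased; validation
frames retain their initial labels. A checkpoint is recorded after every
full-model epoch (stages 2 and 3) and the checkpoint with the lowest
validation reconstruction loss is returned, ties broken by the earliest
epoch. The unsupervised baseline is the same procedure with the
classification weight at zero and EM off.

## Synthetic study conditions

The generator emulates the regime the method targets: two classes of
ensembles that overlap structurally and differ only in the probability of a
geometrically subtle feature. The template is a 30-residue zig-zag chain of
pseudo-residues (N, CA, CB, C at protein-like ~0.15 nm offsets, 0.38 nm
residue spacing; 120 atoms), so the backbone atom-name filters apply
unchanged. Per frame, independently: the compact/extended state is drawn
with probability 0.75 (positive class) or 0.25 (negative class); the
feature atom pair (the CB atoms of residues 14 and 15) is placed at exactly
0.50 nm (compact) or 0.58 nm (extended) — a 0.8 Å difference; a 5-residue
"loop" (residues 17–21) is translated along a fixed random unit direction
by a Gaussian coefficient of 0.5 nm RMS — a single rigid collective mode
giving low-rank, realistic nuisance covariance that loads on both encoders;
and every coordinate receives 0.02 nm of isotropic thermal jitter.
The default study size is 4000 frames per variant and two variants per
class, with a twelve-dimensional total latent (giving the supervised
encoder a 2–3 dimensional sub-latent, small enough that separation there is
meaningful). At 0.02 nm jitter the distance noise is ~0.03 nm against a
0.04 nm half-gap, so roughly 8% of frames cross the midpoint — the feature
is probabilistic, not a clean split.

What the generator does **not** emulate: temporal autocorrelation (frames
are i.i.d., no kinetics), force-field physics, side chains or solvent, and
sequence differences between variants (all variants share one topology).
Passing tests therefore demonstrate that the pipeline recovers a planted
probabilistic feature under dominant nuisance variance — not that it will
resolve any particular real system, where alignment quality, sampling
convergence and feature complexity dominate.

## Numerical choices and degenerate inputs

* Eigenvalue floor 1e-8 nm² for the covariance pseudo-inverse; rank
  deficiency is expected whenever frames < 3N and after superposition.
* Superposition raises a degeneracy error for collinear/coincident atoms
  (second singular value at zero), where the rotation is ill-defined.
* A region cutoff that swallows the whole molecule is rejected with
  guidance to use the unsplit architecture; a cutoff of zero selects the
  target residue's own atoms.
* Distance-correlation scans exclude pairs within one residue (trivially
  rigid) and skip zero-variance pairs, reporting the skipped count; the
  top-percentile denominator is the number of non-skipped pairs.
* Clustering is greedy k-centers (seeded first center, farthest-point) with
  five k-medoids sweeps (medoid = member minimizing summed within-cluster
  distance), stopping early on convergence; the default k scales down as
  min(2000, n_frames/10).
* Label bins over [0,1] are equal-width with the last bin right-closed;
  empty bins are reported as missing, never zero.
* Checkpoint selection ties break to the earliest epoch; no gradient
  clipping is applied.

## Problem sizes used by the test suite and acceptance script

Unit tests run on a reduced fixture (150 frames/variant). The acceptance
checks and `scripts/acceptance.py` use the full default study (4000
frames/variant; 16,000 training frames), 250 cluster centers for the
attribution scan, 100 label permutations for the control, and one held-out
negative variant of 4000 frames — sizes chosen so a complete from-scratch
run finishes in a few minutes on one CPU while keeping every statistical
check well-powered.

## Known limitations

* The architecture is not rotationally or translationally invariant;
  results depend on the quality of the initial superposition.
* Multi-protein training (variants with different sequences) requires a
  user-supplied shared atom set; the package does not infer one.
* Prediction on new variants is reliable only within the training
  ensemble's support — frames outside the training whitened-feature range
  are flagged as extrapolating and a dominant-extrapolation warning is
  attached when they are the majority.
* Markov-state-model equilibrium weighting is out of scope; analyses weight
  frames uniformly (externally computed weights can be applied by the
  caller before binning).
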