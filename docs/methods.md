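# Methods

## Problem setting

A cryo-EM density map is a 3D scalar field sampled on a voxel grid with a
physical voxel size (here assumed orthogonal; ~1 Å in the regime of
interest). De novo model building asks for the ordered C&alpha; positions
of every chain of a protein of known sequence, without homologous or
predicted structures. `cryotrace` decomposes this into voxel
classification (where are C&alpha; atoms, and what type are they?) and
sequence-to-structure alignment (which residue sits on which atom?).

All grid geometry follows one convention: 0-based voxel indices, world
coordinate of a voxel = `origin + index * voxel_size` (the voxel center).
Axis permutations declared in MRC headers are undone at read time, so
in-memory grids are always indexed (x, y, z).

## Voxel classifier

The network follows the UNETR pattern: the 32³ input is cut into eight 16³
patches, linearly embedded to 768 dimensions with a learnable positional
encoding, and processed by 12 pre-norm transformer blocks (12 heads, MLP
width 3072, dropout 0.1 in the encoder only). Features tapped after
blocks 3, 6, 9 and 12 are reshaped onto the 2×2×2 patch lattice and
deconvolved upward (kernel-2/stride-2 transposed convolutions with
instance normalization and leaky ReLU), concatenated U-Net-style with the
next-shallower tap, while the raw input enters through a two-layer 3×3×3
stem at full resolution. A 1×1×1 convolution over the final 16 feature
channels yields per-voxel logits (4 atom classes or 21 amino-acid
classes).

The reference architecture fixes the encoder completely but leaves the
decoder stage widths free; its defining parameter totals pin them. With a
standard final encoder LayerNorm, the unique tapering integer solution we
adopt is 152/53/38 decoder channels at 4³/8³/16³ and a 47-channel stem
hidden layer, giving exactly 92,281,604 (4-class) and 92,281,893
(21-class) trainable parameters. The 289-parameter difference is
17 × (16 + 1), which independently pins the 16-channel final feature
width. These widths are not round numbers because the count constraint is
exact.

The loss divides by the sample count N rather than by the sum of selected
class weights (the common library convention); the regression test pins
the distinguishing case (two classes, weights 0.3/0.7, uniform logits →
0.7·ln 2). Class weights `w_c = 1 − n_c/Σ n_k` always sum to C − 1.

Training uses NAdam (lr 1e-4 default), plateau LR decay (factor 0.1 after
5 epochs without validation-loss improvement) and best-model selection by
validation macro-F1. Only toy-scale, single-device training is in scope:
the loop exists to demonstrate that the architecture learns (it overfits a
handful of sub-grids) — not to reproduce production training, which
requires thousands of curated maps and multi-node hardware. The network
and its gradients run on a small reverse-mode autograd written on numpy;
gradient correctness is checked against central finite differences in the
test suite.

Inference tiles a map into non-overlapping zero-padded 32³ sub-grids and
stitches softmax probabilities back, discarding padding. Overlapping
tiles with averaging would be a straightforward extension; non-overlap was
chosen as the simplest exact cover. The prediction source is pluggable
(network, callable surrogate, or precomputed grids) so the downstream
pipeline does not depend on trained weights.

## C-alpha extraction

Classifiers typically fire on several voxels around one true atom.
Candidates (C&alpha; probability strictly above 0.4; the threshold is
strict by definition) are grouped into single-linkage connected components
at 2 Å. "Centrally located" is implemented as the medoid — the member
minimizing summed distance to the others — with ties broken by higher
C&alpha; probability, then lower voxel index, making the result
order-independent and deterministic. Cluster probabilities are means; the
21-class amino-acid vector drops the none/unknown class and renormalizes
over the 20 standard types before HMM use. Predicted C and N voxels are
carried for inspection but unused downstream.

## HMM and the no-repeat Viterbi decoder

States are predicted C&alpha; atoms; symbols are the 20 amino acids.

- **Transitions**: `γ[i,j] ∝ f(d(i,j))` with the scaled Gaussian
  `f(x) = exp(−(x−μ)²/2(Λσ)²)/(Λσ√2π)`, μ = 3.8047 Å and σ = 0.036 Å
  (adjacent-C&alpha; distance statistics of experimental structures), and
  Λ = 10 widening the density so that discretization error of voxel-center
  coordinates (up to ±0.87 Å at 1 Å voxels) does not zero out true
  adjacencies. The diagonal is zero (a residue cannot succeed itself) and
  rows are normalized entirely in log space, so geometries whose densities
  underflow linearly still produce finite stochastic rows.
- **Emissions**: `δ[i,v] ∝ √(a_iv · b_v)` — the geometric mean of the
  state's predicted amino-acid probabilities and background frequencies,
  normalized per state. The bundled background vector is the
  UniProtKB/Swiss-Prot amino-acid composition (config-overridable). The
  geometric mean deliberately tempers the classifier: even a 0.95-certain
  prediction emits its type with probability ≈ 0.5 after mixing with the
  prior.
- **Initial distribution**: rebuilt per chain from the emission column of
  that chain's first residue, restricted to the still-available states.

Decoding must place each residue on a distinct atom. The decoder runs the
Viterbi recurrence in natural-log space with a greedy commit rule: after
each observation column, the column argmax is committed and excluded as an
update target for all later columns. The path is recovered by backpointer
traceback from the final column's argmax. Plain backpointer chasing alone
cannot guarantee a simple path (a state can appear at two columns), so a
collision on traceback is repaired by substituting the best predecessor
not yet on the path; the no-repeat property is thereby structural and
asserted on every run. We evaluated the alternative reading — returning
the committed column argmaxes themselves as the path — and rejected it:
column argmaxes need not form a connected chain, and on the synthetic
recovery benchmark below it loses several percent of sequence
registration whenever a same-letter confusion lets an atom be committed
out of order.

With two observations the commit mechanism cannot act, so the decode
coincides with standard Viterbi; the tests exploit this to cross-check
against `hmmlearn`. On small instances the decoded path is also verified
never to exceed the exhaustive optimum over all simple paths. Exact
optimal simple-path decoding is NP-hard in general and out of scope.

Chains are aligned longest-first (ties by input order); each aligned
chain's states are removed and the surviving rows renormalized. Alignment
is infeasible when residues outnumber available states; the error suggests
lowering the C&alpha; threshold.

## Confidence scores

Two logistic regressions estimate per-residue correctness: the C&alpha;
model uses the classifier probability (1 feature); the amino-acid model
uses the HMM emission at the aligned position, the classifier probability,
and the one-hot assigned type (22 features, linear — no interactions).
Labels derive from 3 Å one-to-one matching against a reference: matched →
C&alpha; label 1; matched and type-identical → amino-acid label 1. Fits
are maximum likelihood with a tiny L2 ridge (default 1e-6) so separable
toy datasets remain finite. No pretrained coefficients are shipped — the
published ones are not available, and inventing them would be worse than
fitting on the user's own reference data. Structure-level confidence is
the arithmetic mean of per-residue scores.

## Evaluation metrics

Matching is greedy globally-nearest one-to-one pairing within 3 Å
(increasing distance, ties by model then reference index). From a match of
a model with `n_model` residues against a reference with `n_reference`:
recall = matched/n_reference; precision = C&alpha; match =
matched/n_model; F1 is their harmonic mean; sequence match is the
type-identical fraction of matched pairs (position-only matching — residue
numbering is ignored); the C&alpha; quality score is
precision · n_model/n_reference, clamped to [0, 1] with a warning.
Greedy matching is a maximal matching, hence within a factor two of the
optimal-assignment cardinality and usually equal to it; exact agreement
with external chain-comparison tools on dense structures is not expected
and not claimed.

## Synthetic data

The generator produces exactly the statistics the method assumes, so
failures are attributable to the algorithms rather than to a data
mismatch:

- backbones are self-avoiding random walks with bond lengths from
  N(3.8047 Å, 0.036 Å) truncated to [3.6, 4.0] Å, bond angles uniform in
  [80°, 150°], and a 3.0 Å exclusion radius between any two atoms;
  sequences are drawn from the background frequencies;
- maps place isotropic Gaussian blobs (σ = 1 Å) at C&alpha; positions
  (plus weaker cosmetic pseudo-C/N blobs between consecutive C&alpha;) on
  a 1 Å grid with 10 Å padding, min-max normalized; exactly one voxel — the
  nearest — is labeled per atom, and C&alpha; labels win collisions;
- surrogate predictions put `correct_prob` mass on the true class and
  spread the rest uniformly, with an optional false-positive rate on
  background voxels; everything is a pure function of its seed.

What this does *not* emulate: resolution-dependent blurring and
anisotropy, side-chain density, intensity inhomogeneity, and classifier
error correlations. Passing the synthetic benchmarks therefore validates
the pipeline's logic and its tolerance to voxel discretization — not
performance on experimental maps, which depends on the trained classifier.
The generation σ = 0.036 Å is intentionally the HMM's own transition σ,
even though real backbones vary more: the benchmark isolates the decoder
under its own model assumptions.

Problem sizes used by the test suite and acceptance checks — two chains of
20 + 30 residues, maps of roughly 60³–70³ voxels, 20 replicate seeds,
200-instance decoder oracles with K ≤ 7 — were chosen as the smallest
sizes at which every failure mode above is observable.

## Known limitations

- Sub-voxel coordinate refinement is not performed; model coordinates are
  voxel centers, so ~0.5 Å RMS placement error is inherent at 1 Å voxels.
- The greedy-commit decoder is a heuristic; adversarial geometries (long
  chains of equidistant same-letter atoms) can still shift registration.
- Anisotropic voxel sizes are accepted with a warning but untested against
  real anisotropic maps; mmCIF output and full-atom models are out of
  scope.
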