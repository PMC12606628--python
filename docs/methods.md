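# Methods

## Overview

`qdpr` implements a quantified dynamics–property relationship (QDPR)
workflow for machine-learning-guided protein engineering. The premise: short
simulations of many point-mutant variants yield per-residue biophysical
features (flexibility, hydrogen bonding, solvent exposure, collective-motion
weights); small neural networks learn the sequence→feature map; a downstream
score network combines the feature predictions with a direct sequence→property
prediction and is trained on the few experimentally labeled variants
available during an engineering campaign. Because the feature predictors are
trained on simulation data alone, scoring new sequences needs no further
simulation or experiment, and correlating predicted features with measured
labels yields a per-residue account of *which* dynamics drive the property.

## Feature extraction

Input is a trajectory ensemble: a `(frames, atoms, 3)` coordinate array in
Å, a light topology (atom names, elements, van der Waals radii, 1-based
residue assignment), and segment boundaries marking independent runs. The
first 10 % of each segment (`floor(0.1·n)` frames) is discarded as
equilibration before any extraction.

Feature families:

- **RMSF** — alpha-carbon root-mean-square fluctuation about the mean
  structure, after a two-pass least-squares (Kabsch) superposition: frames
  are first aligned to frame 0, a mean structure is computed, and frames are
  re-aligned to that mean. Superposition removes six rigid-body degrees of
  freedom, so on isotropic test data the estimator converges to
  `σ√3·√(1 − 6/3N)`, not `σ√3`; tests account for this.
- **Kabsch–Sander hydrogen-bond energy** — the DSSP electrostatic model
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol over
  donor(N–H)/acceptor(C=O) residue pairs, excluding self and the covalently
  linked `j = i − 1` acceptor; bonds accepted below −0.5 kcal/mol. Each
  accepted bond credits its energy to both participants (preserving total
  energy bookkeeping), frame-averaged. Proline donors are skipped; missing
  amide hydrogens are rebuilt 1.01 Å from N along the bisector of the
  N–CA and N–C(prev) directions.
- **Wernet–Nilsson hydrogen-bond occupancy** — the distance–angle cone
  criterion `r_DA < 3.3 Å − 0.00044·δ²` (δ = H deviation from the
  donor→acceptor axis, degrees). The criterion is geometric and defines no
  energy, so the family reports the mean count of bonds per frame in which a
  residue participates.
- **Shrake–Rupley SASA** — solvent-accessible surface area with a
  deterministic golden-spiral sphere lattice (default 960 points, probe
  1.4 Å); per-residue sums, frame-averaged. Exactly coincident atoms are
  treated as duplicates (only the first contributes surface). The lattice is
  RNG-free for bit-reproducibility.
- **Essential-dynamics weights** — PCA of alpha-carbon motion in a reference
  trajectory; a variant trajectory is superposed on the basis mean structure
  and the projection variance on each retained component, normalized by the
  sum over retained components, gives a weight distribution summing to 1.

A `FeatureSchema` fixes the order and residue assignment of every label; the
56-residue benchmark layout (four by-residue families + 70 PCA weights = 294
labels) ships as `gb1_schema()`. Custom families can be registered as
callables.

## Surrogate and score models

Sequences are encoded residue-by-residue as 20 one-hot channels plus 19
built-in physicochemical descriptor channels (hydropathy, volume, charge,
secondary-structure propensities, …), each descriptor standardized to zero
mean/unit variance over the amino-acid alphabet. The exact descriptor basis
is not critical — any fixed, information-rich embedding serves — and
user-supplied tables can replace the built-in one.

`FeatureSurrogate` (one per feature family) is a small 1-D convolutional
network over the residue axis (default two 64-filter width-5 convolutions,
leaky-ReLU, dense 128, linear outputs — desk-scale presets shrink this).
Labels are linearly rescaled to [0, 1] on the training range (constant
labels flagged degenerate; out-of-range inputs extrapolate). Training is
minibatch Adam on MSE with validation-based early stopping (patience 500 by
default, best-epoch weights restored), repeated over 3 independent restarts,
keeping the restart with lowest validation error. All randomness threads
through a single seed. `PropertySurrogate` uses the same protocol with a
single output and a validation split of `max(1, floor(0.1·n))` labels;
below 10 labels it trains a fixed number of epochs without validation
(with a warning). The networks are implemented directly in NumPy
(`qdpr.nn`): at these sizes a hand-written forward/backward pass is fast,
dependency-free, and exactly reproducible; gradients are verified against
finite differences in the test suite.

`ScorePredictor` is the downstream combiner: eight densely connected
leaky-ReLU units and one linear output, trained for a fixed 400 epochs
(no early stopping) at learning rate 1e-4, batch size 8, on all available
labels — these constants are the class defaults. Engineering choices the
protocol leaves open: input columns are standardized per column (training
rows by default; a label-free alternative uses statistics over the full
candidate pool, which is far more stable when only 8–16 labels exist);
labels are standardized internally and un-standardized at prediction; the
output layer starts at zero so training behaves like a shrunken regression
on the hidden projections before the hidden layer specializes; optional
decoupled weight decay. The desk-scale campaign preset uses learning rate
1e-2 with weight decay 0.3 because a few dozen Adam steps at 1e-4 cannot
re-align a randomly initialized network to a handful of labels; the
canonical constants remain the defaults and are exercised as such in tests.

## Campaign simulation

A campaign draws from a labeled pool in place of experiments. Round 0
selects `batch_size` variants uniformly at random; each later round retrains
the label-dependent models (property surrogate + score predictor) on all
labels collected so far, scores the not-yet-selected pool, and takes the top
scorers (ties broken by stable id order). Recorded per round: NDCG and
Spearman correlation of scores against labels, and the running best label.

NDCG uses linear min-shifted gains (`gain = label − min(label)`) and the
`1/log2(rank+1)` discount; the normalizer is the label-sorted ideal
ordering. Tied predicted scores contribute the mean gain of their tie group
at each tied position — the expectation over random tie orderings. All-equal
labels define NDCG = 1. Gains are shift-invariant by construction; the
linear (not exponential) gain keeps the metric scale-equivariant.
Multi-campaign evaluation reports per-round means ± SEM, the median of each
campaign's best label ± SEM, and NDCG stratified by mutation count.

## Quantified importance

After a round, each feature's importance is the Pearson correlation
(Spearman available by flag) between its surrogate-predicted values and the
measured labels of the selected variants. Features sort by |r| (rank 1 most
important; zero-variance predictions get r = 0 and sort last, stably);
residue score = mean rank of that residue's features; features without a
residue assignment (PCA weights) are discarded before averaging.
Cross-campaign consensus is the median of per-campaign residue ranks, ties
broken by mean rank then residue index; a subset consensus can exclude
campaigns whose training variants touched given residues. Consensus can be
painted into the B-factor column of a PDB copy for structure viewers.

## Synthetic study system

Real inputs (all-atom MD of thousands of variants; deep-mutational-scanning
label tables) are out of desk-scale reach, so the package carries its own
study system with known ground truth:

- **Toy protein** — a helix-loop-helix chain built from ideal backbone
  internal coordinates (NeRF chain extension at canonical φ/ψ), with a
  seeded random sequence (prolines excluded so every non-terminal residue
  donates an amide hydrogen). Contacts: residue pairs with Cα–Cα < 8 Å,
  plus chain bonds.
- **Dynamics** — a Gaussian-network model: contact springs
  `k_ij = √(s_i·s_j)` plus a per-residue tether spring `k_i = s_i`
  (a local packing restraint, incident to exactly one residue), where
  `s(aa) = exp(z_hydropathy(aa))` spans roughly [0.2, 5]. A substitution
  rescales only springs incident to its residue; the matrix is then
  rescaled to the wild-type trace so mutations *redistribute* stiffness
  rather than changing overall rigidity — without this, every substitution
  moves all residues through one collective softness mode that swamps the
  local signal. Frames are i.i.d. samples with per-axis covariance
  `noise_scale²·Γ⁺` (noise_scale 0.55 Å), residue displacements applied
  rigidly to that residue's backbone atoms. Frames carry no time ordering,
  which is immaterial: no in-scope extractor uses it. The closed-form
  fluctuation profile (including a rigid-body-projected variant that
  predicts exactly what superposed RMSF converges to) serves as the oracle
  for both the generator and the extractor.
- **Landscape** — fitness rewards flexibility at one mid-helix residue per
  helix (chosen programmatically: the helix-core residue, ≥4 residues from
  either terminus, whose wild-type amino acid has the most neutral
  hydropathy, so substitutions move the site in both directions), each
  target's feature deviation standardized by its across-pool spread, plus a
  bounded synergistic epistatic interaction `0.5·tanh(z₁)·tanh(z₂)` and
  observation noise (σ = 0.03). Both coefficients are positive because
  rigidification saturates (a site cannot fluctuate less than its neighbors
  allow) while softening does not; mixed signs give the two targets very
  different effect tails and an unbalanced landscape. The interaction is
  saturated rather than a raw product because the z's are strongly skewed
  and (through stiffness redistribution) anticorrelated, and an unbounded
  product can then cancel a target's main effect entirely — the bounded
  form keeps the landscape nonadditive while guaranteeing both ground-truth
  residues remain statistically visible. The default pool holds 350 unique
  variants with 1–3 substitutions, 1000 frames per variant.
- **Study schema** — per-residue RMSF plus 6 PCA weights. RMSF responds to
  spring rescaling at first order; per-residue hydrogen-bond observables in
  this generator respond only at second order (mean-energy shifts of
  ~0.02 kcal/mol against frame-sampling noise of the same size, measured
  to be independent of frame count and amplitude), making them
  noise-dominated labels no sequence model can learn. They remain available
  for explicit schemas and are validated against geometric oracles and an
  independent implementation, but the recoverable ground truth is defined
  on the first-order observable.

## What the default experiments show — and what they cannot

The packaged study (`qdpr.experiments`, also driven by
`scripts/acceptance.py`) measures, at the conditions above:

- held-out sequence→RMSF surrogate correlation (strong, ≳0.9);
- guided campaigns (batch 8, 5 rounds, 50 campaigns) against random and
  label-oracle baselines on the median best label found;
- importance recovery over 100 one-round campaigns (16 labels each): the
  cross-campaign median-rank consensus places both ground-truth residues at
  the top of the 24-residue ranking, which is the recovery claim this
  method makes; the per-campaign both-in-top-3 rate is also reported, and
  is intrinsically modest (~20–25 %): a Pearson correlation estimated from
  16 variants has a standard error of ~0.25, so among ~22 null residues
  with population correlations of 0.1–0.3 one to three interlopers per
  campaign are expected, and the round-1 selection model is information-
  limited (a ridge regression given the same inputs and 8 labels reaches
  only ~0.33 pool correlation). Identifying driver residues from 16 labels
  is a consensus-across-campaigns claim, not a single-campaign claim.

Passing these tests demonstrates internal consistency of the pipeline on a
generator whose ground truth is known exactly. It does not demonstrate that
real MD features predict real assay labels: the synthetic dynamics are
harmonic, frames are independent, mutations act only through local spring
stiffness, and the fitness function touches two residues — none of which
holds for real proteins.

## Numerical and reproducibility choices

- One global seed fans out to per-module streams by hashing
  `seed:module-name` (blake2b, < 2³¹); campaign c in a batch uses
  `SeedSequence([seed, c])`.
- Sphere lattices, tie-breaks (stable id order in selection; feature order
  in rank ties; mean-then-index in consensus), and the NumPy network stack
  are deterministic; two runs with the same seed produce byte-identical
  CSV outputs.
- Degenerate inputs: constant labels (degenerate scaler / constant
  predictor), all-equal labels in NDCG (defined 1), zero-variance features
  (rank last), pools smaller than a batch (select all, terminate),
  disconnected contact graphs (rejected — more than one zero mode).

## Known limitations

- Per-residue hydrogen-bond and SASA families are weak mutation reporters
  under the harmonic generator (see above); testing surrogates for those
  families end-to-end requires a generator with anharmonic or
  conformational responses.
- The importance estimator inherits Pearson's fragility at n = 16; the
  consensus is the robust quantity.
- The score network's canonical training constants are kept as defaults for
  fidelity, but they underfit severely in the few-label regime; the
  desk-scale preset documents the adjustment.
- The encoder hook for external sequence models (logit-based encodings in
  place of the built-in physicochemical channels) is a plug point only; no
  pretrained model ships with the package.
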