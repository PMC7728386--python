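# Methods

## Problem and model

A point mutation changes a protein's Gibbs free energy of folding by
ΔΔG = ΔG_mutant − ΔG_wild-type (kcal/mol, positive = destabilizing).
`voxstab` predicts ΔΔG from a pair of all-atom structures — the wild type
and a pre-modeled mutant — by treating the neighborhood of the mutation
site as a multi-channel 3D image and regressing ΔΔG with an ensemble of
small 3D convolutional networks.

The pipeline is:

1. **Superposition.** The mutant model is rigidly fitted onto the wild-type
   structure by least squares (Kabsch algorithm) over the Cα atoms of the
   residues common to both chains, excluding the mutated position.  The
   atom set for the fit is this package's choice; any anchor set that
   excludes the perturbed site gives near-identical grids at typical RMSDs.
2. **Centering.** The grid center is the mutated residue's Cβ atom in the
   wild-type structure (Cα for glycine).  Both the wild-type and the
   superposed mutant grid use this same center, so the two feature blocks
   are voxel-aligned.
3. **Voxelization.** A cubic grid of `edge³` voxels (default 16, 1 Å
   resolution) is laid axis-aligned in the structure frame.  Each voxel
   carries seven channels — hydrophobic, aromatic, H-bond donor, H-bond
   acceptor, positive ionizable, negative ionizable, occupancy — and the
   channel value is the saturation

       f(d) = 1 − exp[−(r_vdw / d)^12]

   of the nearest property-carrying atom at distance `d` from the voxel
   center, with `f(0) = 1` as the continuous limit.  Values lie in (0, 1].
4. **Stacking.** Wild-type channels 1–7 and mutant channels 8–14 are
   concatenated into the `[edge, edge, edge, 14]` network input.
5. **Regression.** Ten 3D-CNN members, each validated on a different tenth
   of the (paired) training data, are averaged.

## Property-channel rules

Channel membership is decided by residue/atom-name template lookup, not
bond perception:

- *hydrophobic*: all carbons except the backbone carbonyl C and the
  side-chain carboxyl/amide/guanidinium carbons (Asp CG, Glu CD, Asn CG,
  Gln CD, Arg CZ).
- *aromatic*: ring carbons of Phe, Tyr, Trp, His.  Aromatic ⇒ hydrophobic.
- *donor*: every N, O, S atom (lone-pair bearers).
- *acceptor*: polar hydrogens, i.e. hydrogens whose template parent is
  N, O, or S.  This donor/acceptor naming follows the descriptor scheme
  the channels are modeled on, which is inverted relative to common
  hydrogen-bonding convention; `PropertyRuleSet(swap_donor_acceptor=True)`
  swaps the two channels for users who prefer the conventional labels.
- *positive*: Lys NZ, Arg NE/NH1/NH2, the N-terminal amine nitrogen.
  Histidine is neutral by default (pH 7);
  `PropertyRuleSet(protonated_histidine=True)` adds ND1/NE2.
- *negative*: Asp OD1/OD2, Glu OE1/OE2, the C-terminal carboxylate
  (O and OXT of the last residue).
- *occupancy*: every atom, hydrogens included.

Hydrogen parents are resolved from standard PDB v3 names (HB2 → CB,
HD21 → ND2, …) by longest-prefix matching of the remote-position code;
structures without hydrogens are accepted with a warning and an empty
acceptor channel.  Van der Waals radii are a Bondi-style element table
(C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å), overridable in the rule set.

## Numerical choices in the voxelizer

- **Aggregation** over multiple atoms contributing the same channel to the
  same voxel is the voxelwise maximum, preserving the [0, 1] saturation
  semantics; the occupancy channel therefore dominates every other channel
  at every voxel.
- **Voxel centers** sit at offsets `(i − (edge−1)/2)·resolution`; with an
  even edge count the grid center falls between voxels.
- **Cutoff.** Atoms outside the grid bounding box expanded by 6 Å are
  skipped: a skipped atom is at least 6.5 Å from the nearest voxel center,
  where the saturation of even the largest default radius (1.8 Å) is
  ~2 × 10⁻⁸, so the cutoff perturbs no grid value by more than 10⁻⁶.
  `voxelize(..., exact=True)` disables the cutoff; tests verify agreement
  with an exhaustive per-(voxel, atom) reference to 10⁻⁶ (and 10⁻¹² in
  exact mode).
- **No rotational augmentation** by default — structure orientations are
  taken as given; `GridSpec.rotation_angles` provides opt-in x-then-y-then-z
  rotation about the grid center.

## Network and training

Architecture (valid padding, derived from the parameter-count constraint:
same-padding would change the dense fan-in):

    Conv3D(16, 3³, ReLU) → Conv3D(24, 3³, ReLU) → Conv3D(32, 3³, ReLU)
    → MaxPool(2³) → Flatten → Dropout(0.5) → Dense(24, ReLU)
    → Dropout(0.5) → Linear(1)

For the default 16³ × 14 input the spatial sizes run 16 → 14 → 12 → 10 → 5
and the model has exactly 133,273 trainable parameters; the closed form in
`count_parameters` is checked against the instantiated model across the
supported grid sizes (8, 12, 16, 20) and layer widths.

Training: Adam (lr 0.001, β₁ 0.9, β₂ 0.999), MSE loss, batches of 8,
Glorot-uniform init, up to 200 epochs with early stopping once the
validation MSE has not improved for 10 consecutive epochs; the retained
weights are those of the best validation epoch.  The output unit is linear
because ΔΔG is signed; no input normalization is applied beyond the
intrinsic [0, 1] saturation scale.  Dropout acts only in training, so
inference is deterministic.  One master seed derives independent
per-member seeds (initialization, shuffling, dropout); members do not
share an initialization.

The engine is a NumPy implementation (im2col convolutions, window-argmax
pooling, inverted dropout, Adam) written for this package; training is
CPU-sized and bit-reproducible for a fixed seed on fixed hardware.

**Ensemble.** The augmented table is split into ten equal subsets of whole
direct/reverse pairs; member *i* validates on subset *i* and trains on the
rest; predictions are the unweighted member mean.  A thin cross-validation
loop over `NetworkSpec` variants supports hyperparameter exploration.

## Dataset curation

- **Anti-symmetric augmentation.** Thermodynamics requires
  ΔΔG(Y→X) = −ΔΔG(X→Y).  `augment_reverse` adds, for each direct record,
  a reverse record with swapped amino acids, swapped structure roles, and
  the exactly negated label, sharing a pair id.  Re-augmenting is an error.
- **Homology pruning.** Training proteins with global-alignment percent
  identity ≥ 25% (BLOSUM62, gap open −10, extend −0.5; identical aligned
  columns over alignment length) to any test protein are removed —
  a deliberately lighter-weight criterion than an e-value search, matching
  the identity threshold commonly used for redundancy removal.  

  Within-train single-linkage clusters at the same threshold are reported
  for leakage audits.
- **Paired split.** The k-subset split randomizes over mutations (pairs),
  not proteins, keeping each direct record with its reverse; a
  protein-grouped split can be had by pruning first.  Duplicate mutations
  keep their first occurrence.

## Evaluation statistics

For experimental/predicted vectors (x, y): Pearson r and RMSE σ, computed
separately for direct and reverse mutations.  Bias statistics over pairs:
δᵢ = pred_revᵢ + pred_dirᵢ, its mean ⟨δ⟩, and the correlation r_dir−rev
between the two prediction vectors.  A perfectly anti-symmetric predictor
gives δ ≡ 0, ⟨δ⟩ = 0, r_dir−rev = −1.  The full δ vector is always kept
because opposite-direction biases cancel in ⟨δ⟩.  Additional summaries:
cumulative error fractions (|error| ≤ 0.5 and 1.0 kcal/mol by default) and
the fraction of ΔΔG values in the neutral zone [−0.5, +0.5] kcal/mol
(boundaries inclusive, since the interval is stated without strictness).
The thermodynamic conversion `folding_factor(ddg, T) = exp(ddg/RT)` uses
R = 1.987 × 10⁻³ kcal mol⁻¹ K⁻¹, reproducing the 5.1-fold equilibrium
reduction for 1 kcal/mol at 310 K.

## Synthetic data generator

Real inputs (experimental structures, mutant models built with a
macromolecular modeling suite, measured ΔΔG) are replaced at desk scale
by an idealized generator:

- ~20-residue α-helical proteins with template side-chain geometry and
  hydrogens, built deterministically from a seed; a mutation pair differs
  at exactly one residue, and both structures receive independent Gaussian
  coordinate jitter (default 0.05 Å, emulating independent relaxation).
- Planted labels are a linear functional of the paired grids:
  ddg = Σ_c w_c (S_c(mut) − S_c(wt)) + ε, with S_c the channel-c voxel sum
  and ε ~ N(0, 0.1 kcal/mol).  Default coefficients weight the hydrophobic
  (0.04) and occupancy (0.02) channel differences, scaled so direct labels
  span roughly −5..+5 kcal/mol with an SD near 1.9 — the range typical of
  measured single-mutation ΔΔG values.  Labels are exactly anti-symmetric
  before noise.

Because the label is a known functional of the input features, a trained
ensemble must recover it; this makes the full featurize → train →
ensemble → evaluate path falsifiable.  What passing does **not** show:
anything about real energetics — the fixture has no physics, no packing,
no solvent, and its label is far simpler than a true ΔΔG surface.  It
validates the machinery, not the science of any particular training set.

## Problem sizes

The parameter-recovery experiment uses 500 planted mutations (400 training
pairs → 800 records for the 10-member ensemble, 100 held-out pairs), an
8-voxel grid — one of the supported grid-search sizes, chosen as the
package's standard desk-scale configuration for the NumPy engine — and at
most 50 epochs per member.  The planted labels are defined on the same
8-voxel grid, so the signal is fully representable.  Expected results
(seeded): held-out Pearson r ≈ 0.95, |⟨δ⟩| < 0.1 kcal/mol.  The default
16-voxel configuration is used everywhere else (CLI defaults, architecture
accounting, voxelizer/oracle checks).

## Known limitations

- The NumPy engine is single-threaded BLAS-bound; training the default
  16³ configuration on thousands of records is minutes-to-hours work, not
  seconds.  It is intended for method verification and small studies.
- PDB input only (no mmCIF); no bond-order perception; non-standard
  residues get occupancy-only flags.
- The identity-based homology proxy does not detect remote homology the
  way a profile search would; an external alignment tool can be swapped in
  by supplying precomputed identities.
- Percent identity is computed from one optimal alignment; co-optimal
  alignments with slightly different identity values are possible.
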