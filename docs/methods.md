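# Methods

## Problem setting and representation

The package models pocket-conditioned molecular growth: given a protein
pocket and a seed fragment with marked growth sites, generate the missing
scaffold atoms, then the R-group, as 3D point clouds of typed atoms, and
finally reconstruct a bonded molecule from the generated geometry.

Atoms are represented by a one-hot element vector over the vocabulary
{C, N, O, F, P, S, Cl, Br, other} plus a tenth "virtual" category used
only as padding in the R-group stage. Hydrogens are implicit throughout
(an explicit-H option exists on fixtures for geometry tests). Coordinates
are Cartesian ångströms in the right-handed PDB/SDF frame; indices are
0-based internally and 1-based only inside serialized formats. Pockets
are represented by all heavy atoms of the selected residues
(residue-level inclusion within a 10 Å default radius of the ligand);
Cα-trace or residue-type representations were considered and rejected
because the bond-distance scale of the generator benefits from true atom
positions.

## Diffusion model

Both stages share the variance-preserving forward chain
q(x_t|x_{t-1}) = N(sqrt(1-β_t) x_{t-1}, β_t I), applied to coordinates
and to continuous relaxations of the one-hot type rows; decoding takes
the arg-max category at the end of sampling. The reverse chain is
ε-parameterized with the variance fixed at β_t I — the ε-only L2 loss
implies a fixed-variance parameterization, and no learned-variance or
v-prediction variants are in scope. At t = 1 the posterior mean is
returned without added noise.

Schedules:

* **linear** — β_t equally spaced from 1e-4 to 0.02 inclusive, any
  T ≥ 2; used by the scaffold stage.
* **polynomial** — ᾱ_t = (1 − (t/T)^p)² with p = 2 by default, βs
  derived from successive ᾱ ratios and clipped to [1e-5, 0.999]; used by
  the R-group stage. The exact polynomial form is an open design point;
  the squared-polynomial ᾱ parameterization follows the equivariant
  diffusion lineage this family of models builds on. Which schedule each
  stage uses is per-stage configurable, since only the R-group stage
  strictly requires the polynomial one.

T defaults to 1000 in full-scale configurations and 100 in the
desk-scale experiments shipped with the tests; the acceptance experiments
use T = 100 so a full overfit-train-and-sample cycle of both stages fits
in minutes on one CPU core.

## Denoiser

The denoiser is an E(3)-equivariant graph network over the fully
connected graph of context atoms (pocket + fragment, or pocket +
scaffold) and generated atoms. Node inputs are the ten category channels,
a four-way role one-hot (pocket / fragment / scaffold / generated), an
anchor bit, and t/T as a scalar; an affine embedding lifts them to the
hidden width. Each layer computes messages from
(x_i, x_j, d_ij², RBF(d_ij)) through two dense layers with SiLU, updates
features through dense→batch-norm→SiLU→dense→batch-norm with a residual
add, and updates coordinates by Σ_j (r_i−r_j)/(d_ij+1)·φ_r(·) where φ_r
is three dense layers (SiLU between, hidden width reused — the head's
widths are otherwise unspecified). Context atoms receive a coordinate
update of exactly zero. The RBF expansion uses K = 16 Gaussians uniformly
centered on [0, 10 Å] with σ = d_max/K — chosen to span pocket-scale
distances with neighboring-kernel overlap. The network output minus the
input coordinates, restricted to the generated rows, is the noise
prediction; this subtraction plus the centering of the system on the
context centroid fixes the translation gauge, and the prediction is
exactly translation invariant because displacements depend only on
relative positions.

Batch normalization always normalizes by the current node batch's
statistics (running statistics are kept only as a fallback for
single-node graphs, and are updated only during training). Accumulated
statistics were evaluated for sampling and rejected: they average feature
scales across all diffusion timesteps, and the resulting miscalibration
near t = 0 destroys the element decode — the batch-statistics form
recovers the R-group overfit experiment completely where the running-stat
form fails it. Distances are computed as sqrt(d² + 1e-12) so coincident atoms
cannot produce infinite gradients.

The networks run on a package-local reverse-mode autodiff core
(`fdcdiff.nnet`) over float64 NumPy arrays, with gather/segment-sum
primitives for message passing, Adam, and global-norm gradient clipping.
Gradients are verified against central finite differences in the test
suite. Float64 keeps the equivariance checks at the 1e-8 level and makes
runs bit-reproducible for a fixed seed.

## Stages and training

Stage 1 (scaffold): the fragment and pocket are frozen; n_new atoms are
initialized with standard Gaussian coordinates centered on the anchors'
centroid (anchors are growth sites, so initializing there rather than at
the global origin respects the pocket frame) and Gaussian type channels,
then denoised for T steps. Stage 2 (R-group): exactly 10 padded slots are
denoised with pocket and scaffold frozen; slots decoding to the virtual
category are dropped, so the R-group size is an outcome of sampling,
never above 10. In training tuples the virtual slots' reference
coordinates sit at the real R-group centroid (scaffold centroid when the
R-group is empty), giving the padding a well-defined target; at sampling
time slots are initialized around the scaffold centroid. Stage 2
conditions on the generated scaffold's decoded types (hard arg-max), not
its soft features.

The padded slots are an ordered tensor, and each slot carries a one-hot
slot-index input feature (zero for every other node). This deliberately
breaks permutation symmetry among the slots: training tuples assign
fixed roles (real atoms first, then virtual), and a fully
permutation-equivariant denoiser would face an ill-posed regression —
symmetric slot states with asymmetric targets — leaving the sampled
real-atom count binomially random instead of committed. With the slot
encoding, each slot's role is learnable and the sampled composition
stabilizes. The scaffold stage carries no slot features and remains
permutation-equivariant.

Training draws a uniform t ∈ {1..T} per example, noises the stage's
target atoms through the closed-form marginal, and takes an Adam step on
the mean squared noise error after global-norm clipping (default 1.0).
The stages never share parameters, optimizer state, or data — each owns
its own network, and the loss of one cannot touch the other. An
exponential moving average of the parameters (decay 0.995) is kept during
training and used for sampling; it noticeably stabilizes the small
desk-scale runs.

Two numerical guards protect the reverse chain. First, the implied clean
state x0_hat = (x_t − sqrt(1−ᾱ) ε̂)/sqrt(ᾱ) is clamped before each
posterior step — coordinates to the context bounding box ±15 Å, feature
channels to [−3, 3] — and converted back to an effective ε̂; this is the
standard "clip denoised" guard and matters for the polynomial schedule,
whose late-step betas approach 1 and would otherwise amplify early
prediction errors by ~1/sqrt(1−β) ≈ 30× per step. Second, the evolving
state itself is clipped to the same box (features to ±8). A converged
denoiser stays far from every bound (where no bound binds, both guards
are exact identities); they only prevent divergence of undertrained
models. The box is axis-aligned, so rigid-motion covariance of sampling
is exact only while the guards do not bind.

Molecule sizes at sampling time come from an unconditional empirical
histogram of new-atom counts over the training tuples;
pocket-conditioned size models are out of scope.

Desk-scale training configuration (acceptance experiments): 3 layers,
hidden 64, K = 16, learning rate 1e-3, batch 8, 1500 steps (scaffold) /
1200 steps (rgroup), T = 100, single toy complex. The full-scale defaults
(6 layers, hidden 128, lr 2e-4, batch 32, 2000 iterations over the
training set — iterations are treated as epochs, configurable) are kept
as the documented configuration for real corpora.

## Preprocessing

Reaction-template slicing cleaves one acyclic bond per (template, match):
the bond between the SMIRKS map atoms :1 and :2. The repository ships a
10-template starter set (amide, ester, aryl/alkyl ether, sulfonamide,
aryl/alkyl amine, biaryl, benzyl, thioether) in
`src/fdcdiff/data/reaction_templates.yaml`; it is a documented subset,
extendable by the user, since the full experimentally verified template
collection is not distributable here. The larger component becomes the
scaffold; ties break toward the side with the lower minimum canonical
atom rank, a deterministic rule chosen because the decomposition must be
reproducible.

BRICS fragmentation cuts the scaffold at RDKit's BRICS bonds; fragments
partition the heavy atoms, inherit 3D coordinates, and carry the atoms
incident to cleaved bonds as anchors. The scaffold's attachment atom is
added to the anchors of the seed containing it, so every emitted seed has
a growth site. Seeds are then filtered by the Rule of Three — MW
< 300 Da, logP ≤ 3, H-bond donors ≤ 3, acceptors ≤ 3, TPSA ≤ 60 Å²,
zero rotatable bonds — computed with RDKit (Crippen logP; donors as
N-H/O-H hydrogen counts, acceptors as N+O counts, matching the simple
counting rule the filter is defined with). The slice → BRICS → filter
order follows the stated pipeline sequence. logD at pH 7.4 as an
alternative lipophilicity measure is not implemented (it requires pKa
prediction).

## Bond reconstruction

Candidate edges are all atom pairs within 3 Å. The refinement network
embeds nodes from their element channels and edges from distance + RBF;
each of 3 iterations builds per-atom context from the atom and its
incident edges, updates edge features from the symmetrized endpoint
contexts plus the distance features, then updates nodes from aggregated
incident edges; a linear head plus softmax yields class probabilities. A
fifth "none" class extends the four chemical bond classes — candidate
edges at ≤ 3 Å include non-bonded 1–3 contacts that a four-way softmax
could never reject — and this is a deliberate design deviation.

Training is per-edge cross-entropy on the fixture panel (plus any
user-supplied molecules with known bonds), with two augmentations: fresh
coordinate jitter per epoch at scales drawn uniformly up to 0.1 Å, and
random dense atom clutter labeled by the deterministic rule, which
teaches the model to handle the unphysical geometries undertrained
samplers produce. Small-step full-graph optimization turned out to be
unstable at a fixed learning rate, so the rate decays by 0.98 per epoch.

The deterministic fallback connects pairs with d ≤ 1.3 (r_i + r_j) over
single-bond covalent radii, in increasing-distance order under
per-element valence caps (C 4, N 3, O 2, halogens 1, S 6, P 5), assigns
orders by nearest tabulated expected length — aromatic (scored midway
between single and double) only for ring bonds — and repairs residual
valence by demoting the most over-stretched multiple bond. On the
ideal-geometry fixtures it reproduces the reference bonds exactly; under
coordinate jitter its connectivity is robust but its order assignment is
not (the aromatic/single/double margins are a few hundredths of an
ångström), which is precisely the argument for the learned model.

Assembly builds an RDKit molecule, keeps the largest connected component
(flagged) if the graph is disconnected, and records sanitization failures
in the record instead of raising. The pipeline's bond selection is
valence-capped: arg-max edges are accepted in decreasing bond confidence
while both endpoints have capacity, and stray non-ring aromatic picks are
demoted to single. No stereo-bond assignment or formal-charge inference
is attempted.

## Evaluation battery

Per molecule: QED (desirability product), synthetic accessibility
normalized as (10 − raw)/9 so higher = easier, Crippen logP, a Lipinski
rule-compliance count on a 0–5 scale (MW < 500, logP ∈ [−2, 5], donors
≤ 5, acceptors ≤ 10, rotatable bonds ≤ 10), TPSA, ring count, heavy and
total atom counts, and the R value — the fraction of heavy atoms that are
not carbon, with drug-like range ≈ 0.05–0.50. Set level: diversity = 1 −
mean pairwise Tanimoto over 2048-bit radius-2 circular fingerprints;
similarity to a reference set = mean best-match Tanimoto; joint
SA/QED-threshold counts. Geometric scrutiny histograms element-pattern
keys (bond lengths in Å over [0.5, 3], angles in radians over [0, π],
dihedrals over [−π, π]; 64 uniform bins shared per arity) and compares
distributions by KL divergence with the second argument floored at
1e-10. Docking is exposed only as an optional external-command hook and
is never required.

## Synthetic fixtures — what they do and do not show

The fixture catalog contains seventeen small molecules with analytic
ideal geometries (tabulated bond lengths and angles: C-C 1.54, C=C 1.33,
aromatic C-C 1.39, C-O 1.43, C=O 1.21, C≡C 1.20 Å, tetrahedral and
trigonal angles). Reference bond lists are consistent with the
geometries — every bonded heavy pair under 1.9 Å, every non-bonded pair
above 2.2 Å — so the fixtures double as the bond-reconstruction oracle.
Toy complexes add a pocket of 16 pseudo-atoms (elements drawn C/N/O/S
with probabilities 0.6/0.15/0.2/0.05) on a shell of radius 6 Å around
the ligand centroid, plus a fragment ⊆ scaffold ⊆ ligand partition with
anchors at the partition boundary. Complex construction is a pure
function of its spec (template, radius, seed).

These fixtures exercise every mechanism — conditioning, equivariance,
frozen context, padding, bond classes including aromaticity — but they
are not real data: pockets have no backbone chemistry or surface shape,
ligand conformers have no strain, and the overfit-recovery experiments
demonstrate capacity and correctness of the sampling machinery, not
generalization. Results on CrossDocked-scale corpora require full-scale
training outside this repository's scope.

## Numerical choices and degenerate inputs

* Sampling with n_new = 0 returns the fragment unchanged; an R-group
  whose slots all decode to virtual is the empty R-group.
* Diversity of fewer than two molecules is defined as 0 with a warning;
  geometry keys matching nothing yield an empty histogram with a warning.
* KL terms with p_i = 0 contribute zero; mismatched bin edges are an
  error, not a silent rebin.
* Scaffold/R-group ties (equal component sizes) break by canonical rank;
  duplicate (template, bond) matches are deduplicated.
* SDF records that fail sanitization are kept with `valid=False`, never
  dropped; unparseable records yield empty invalid records so that record
  counts are preserved.
* All randomness flows through `numpy.random.Generator` objects seeded
  from a single integer; the demo pipeline is byte-reproducible across
  runs at a fixed seed.

## Known limitations

Single-conformer, charge-neutral chemistry; no protonation or
stereochemistry handling; the shipped reaction-template set is a subset;
the bond model is trained at desk scale on the fixture panel, and its
accuracy numbers refer to that panel's chemistry; pocket representation
ignores residue identity beyond element types.
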