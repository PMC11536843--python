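# Methods

## The scoring problem

Virtual screening needs a scoring function that (i) ranks true binders
above non-binders for one target (forward screening), (ii) ranks the
true target above other proteins for one ligand (reverse screening),
and (iii) distinguishes near-native docked poses (RMSD < 2 Å from the
crystallographic pose) from badly docked ones.  Plain affinity
regressors trained only on crystal complexes do none of these things
well: they never see non-binders or wrong poses.  This package
implements a three-network design that attacks the problem with
decoy-conditional training and a physics/ML hybrid score.

## Models

All three sub-networks share a graph vocabulary: heavy atoms are nodes
with 73-dimensional features; covalent bonds are edges with
12-dimensional features; protein–ligand atom pairs closer than 8 Å are
non-covalent edges, extending the edge feature to 24 dimensions in
complex graphs.  Each network embeds node features linearly into a
D-dimensional space, applies a stack of edge-aware GATv2 attention
layers (each followed by ReLU and dropout 0.1), and mean-pools node
embeddings into one graph vector.

* **NonDock** (interaction classifier).  Two towers — 5 GATv2 layers
  for the pocket, 3 for the ligand, both over covalent-only graphs —
  whose pooled embeddings are concatenated and passed through a
  three-layer MLP to a logit.  A sigmoid at inference yields the
  interaction probability `p_pred ∈ [0, 1]`.  Trained with binary
  cross-entropy: natives are positive; cross-docked and random decoys
  negative; conformational decoys are excluded (the classifier never
  sees poses).  Batches of 30 mix native : cross : random = 1 : 2 : 2.

* **DockS** (two-headed pose regressor).  A shared 5-layer encoder over
  the complex graph feeds two independent MLP heads that predict the
  binding free energy `E_pred` (kcal/mol) and the pose RMSD `R_pred`
  (Å; softplus at inference keeps it non-negative — training uses the
  raw head, since MSE to non-negative targets drives it there).  The
  inference score is `E_pred + R_pred`: a wrong pose pays its RMSD as
  an energy penalty.

* **DockC** (combined regressor).  Same encoder, one head, trained to
  predict the RMSD-penalized affinity directly.

Loss routing by training-set tag (batches of 36 mix
native : conformational : cross : random = 1 : 4 : 2 : 2, exactly, in
every batch):

| set                | energy loss                          | RMSD loss (DockS)  |
|--------------------|--------------------------------------|--------------------|
| native             | MSE(E_pred, E_true)                  | MSE(R_pred, 0)     |
| conformational     | DockC: MSE(E_pred, E_true + R_true)  | MSE(R_pred, R_true)|
| cross / random     | max(−E_pred − 5, 0)                  | —                  |

The hinge encodes the assumption that arbitrary ligands docked to a
target are overwhelmingly non-binders: −5 kcal/mol corresponds to an
IC₅₀ of roughly 240 μM at RT = 0.6 kcal/mol, far into inactive
territory, so decoys are only required to score weaker than that, not
to hit any particular value.  Totals: DockS = L_native^E + 5·L_hinge +
L_native^RMSD + L_conf^RMSD; DockC = L_native^E + L_conf^E + 5·L_hinge.
Each term is averaged over the samples eligible for it, keeping term
scales comparable under the skewed batch composition.

The final screening scores multiply classifier and regressor and add a
weighted physics docking energy read from a table:

    AK-Score-C = p_pred · E_DockC + α · E_physics,      α = 0.65

(and the DockS analogue with `E_pred + R_pred`).  If either factor
calls the complex a non-binder the product collapses toward zero
(non-binding); the physics term anchors the prediction in an
independent error model.  Lower is better; the classifier alone ranks
descending by `p_pred`.

## Feature schema

Node (73): element one-hot 16, degree 6, formal charge 6, hybridization
6, aromatic 1, in-ring 1, ring sizes 3–8 6, **pharmacophore multi-hot
7** (aromatic, ring, hydrophobic, H-bond donor, H-bond acceptor,
acidic, basic; SMARTS definitions shipped as a versioned data file),
valence electrons 8, H-count 5, scaled Gasteiger charge 1, is-ligand 1,
scaled vdW radius 1, scaled mass 1, chirality 3, ring-membership count
4.  Covalent edges (12): bond-type 4, conjugated 1, in-ring 1, stereo
3, scaled length 1, rotatable 1, covalent flag 1.  Non-covalent block
(12): eight 1-Å distance bins over [0, 8), inverse distance, a
protein–ligand flag, donor–acceptor-pair and hydrophobic-pair flags.
Whether contact distances are best binned, kept raw, or RBF-encoded is
an open modelling choice; bins are the package's choice.  Every feature depends only on element, topology, perception
and interatomic distances, so graphs — and therefore all network
outputs — are invariant under rigid motions of the complex and under
atom reordering.

Ablation zero-fills a group in place rather than removing it, so tensor
shapes (and checkpoints) are identical across ablation arms.

## Numerical backbone

The networks run on a small reverse-mode autodiff core over NumPy
(`akscore2.autograd`), with scipy.sparse incidence matrices providing
the gather/scatter message-passing primitives and a dst-sorted
segment-max giving a numerically stable attention softmax.  Self-loops
with zero edge features keep the softmax defined on isolated nodes.
Gradients are validated against central finite differences in the test
suite.  Training uses an in-repo Adam.  Float64 is the default dtype;
the desk-scale experiment driver switches to float32, which halves
memory traffic with no observable effect on the recovered metrics.

## The synthetic world

The generator emulates the four training sets of a docking pipeline
with a planted ground truth:

    E(pose) = −s · Σ_{i∈ligand, j∈pocket} tᵢᵀ W tⱼ · φ(d_ij)

where `t` are the 7-dim pharmacophore multi-hots *as perceived by the
package's own featurizer*, `W` is a fixed symmetric complementarity
matrix (donor–acceptor +0.60, acid–base +0.80, hydrophobic packing
+0.25, like-with-like polar contacts negative), and `φ` is a Gaussian
contact well centred at 3.5 Å with 1 Å width — comfortably inside the
8 Å edge cutoff, so the energy is a function of exactly the information
the graphs encode.  That identity is what makes parameter recovery a
meaningful test: a model that learns the features has everything it
needs to reproduce the energy.

Construction, per target:

* **Pocket**: eight rigid 3-atom pseudo-residues on an 8 Å shell.  The
  per-pocket residue-template distribution is drawn from a Dirichlet,
  so pockets differ in character (donor-rich, hydrophobic, basic, …) —
  without this diversity there is no pocket-conditional signal for the
  classifier to generalize to held-out targets.
* **Native**: candidate ligands (random valence-respecting heavy-atom
  graphs, 8–22 atoms, ETKDG-embedded) are sampled with element
  frequencies biased toward the pocket's complementarity profile,
  pre-screened by perceived-type complementarity, docked by a
  random-restart rigid search with staged greedy refinement, and the
  best-scoring pose kept.  True binders are thus chemically matched to
  their pocket, not merely well-placed.  `E_true` = planted energy +
  N(0, 0.5 kcal/mol).  The energy scale s = 0.6 puts native affinities
  in a realistic −4 … −18 kcal/mol band.
* **Conformational decoys** (6): rigid perturbations of the native pose
  with recorded symmetry-aware RMSD spanning ~0.5–10 Å.
* **Cross decoys** (3): other targets' native ligands; **random
  decoys** (3): fresh unbiased ligands.  Both are placed by a
  *type-blind* packing optimizer, so actives and inactives look equally
  "docked" geometrically and only complementarity separates them —
  docking programs pack every ligand they are given.
* **Surrogate physics score**: planted energy + N(0, 2 kcal/mol),
  mirroring a force-field score that is informative but much noisier
  than a well-trained ML model.

What the world does **not** emulate: sterics and torsional strain,
solvation, protonation states, real residue chemistry, conformational
flexibility beyond rigid motions.  Passing recovery tests therefore
demonstrates that the pipeline can learn a planted
complementarity-plus-geometry signal end-to-end — not that it would
match production-scale benchmark performance, which requires full-scale
training data and GPU budgets and is out of scope here.

## Desk-scale recipe and problem sizes

The end-to-end experiment (`akscore2.experiments.desk_benchmark`) uses
200 targets (≈ 2,600 complexes), a 10% target-level hold-out, embedding
width 48 with 4 attention heads, Adam at 1e-3 (2e-3 for DockS, whose
RMSD head learns the subtlest signal), and 16 / 12 / 25 epochs for
NonDock / DockC / DockS.  These are deliberate desk-scale choices — the
production-style configuration (embedding 256, 1000 epochs, batch
ratios and sizes unchanged) is the `NetConfig` / `TrainConfig` default.
Screening evaluation ranks, per held-out target, the native against 39
fresh packing-placed inactives and averages per-target EF@5%.

The feature-ablation check zero-fills a group **at inference time** on
the trained models and re-scores the same held-out screen, comparing
the pure product score `p_pred · E_DockC` between arms.  Ablation with
retraining is uninformative in this world by construction: the planted
pharmacophore types are perceivable functions of the remaining
chemistry features (element, degree, H-count, aromaticity), so a
retrained network simply re-derives them and recovers full
performance.  The inference-time variant asks the feature-importance
question — how much does the trained model actually rely on the group —
which is also why ablated groups are zero-filled rather than removed:
the same trained weights must apply across arms.  The `pharmacophore`
ablation covers every perception-derived channel (the node multi-hot
plus the donor–acceptor and hydrophobic pair flags on contact edges).

## Numerical and design notes

* Pocket = whole residues with any heavy atom ≤ 5.0 Å (inclusive) of a
  ligand heavy atom; non-covalent edges use a strict `< 8 Å`.
* RMSD is computed without re-superposition (poses share the receptor
  frame); symmetry-aware by default, minimizing over bond-graph
  automorphisms.
* Altlocs resolve to highest occupancy; hydrogens and waters are always
  stripped; other HETATM residues are dropped unless allowlisted.
* Attention heads: 4, concatenated back to the embedding width.  MLP
  heads: three linear layers D → D/2 → D/4 → 1 (2D input for NonDock).
* Mean pooling is over node embeddings only; edge information reaches
  the readout through attention messages.
* Batch-exhaustion policy: an epoch covers the largest set once;
  smaller sets cycle with reshuffling, so natives repeat within an
  epoch (with |D_conf| ≫ |N| this is forced by the 1 : 4 : 2 : 2 mix).
* Ties in top-x% cutoffs break by stable sort on input order; the
  cutoff is ⌈x% · n⌉; the docking-power RMSD cutoff (2 Å) is strict.
* Degenerate inputs: correlation of a constant vector warns and returns
  NaN; EF without any active raises; a screening direction flag
  distinguishes energies (ascending) from probabilities (descending).

## Limitations

The autodiff core is single-threaded NumPy: adequate for desk-scale
graphs (tens of atoms, thousands of complexes) but not for
PDBbind-scale training.  The synthetic chemistry is deliberately
minimal; aromatic and acidic pocket atoms are rare because pseudo-
residue perception assigns bond orders by proximity.  Recovery metrics
on 20 held-out targets carry sampling noise of a few hundredths; seeds
are pinned in the acceptance tests for reproducibility rather than
hidden cherry-picking — other seeds give comparable values.
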