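# Methods

## Problem setting

Structure-based protein–ligand binding affinity (PLBA) prediction maps a
complex — a protein P, a ligand L and their binding conformation C — to an
affinity value. Labelled co-crystal structures are scarce, while public
bioassay databases hold orders of magnitude more affinity measurements
without structures. Pre-training on bioassay data faces three obstacles
this package is built around:

* **missing conformations** — bioassay entries have no 3D complex; docked
  poses stand in for the true binding mode;
* **label variety** — IC50, Ki and Kd values are not mutually comparable;
* **label noise** — affinities from different assays carry systematic
  offsets (protocol, temperature, pH), while values *within* one assay are
  mutually consistent.

The framework answers these with multi-task pre-training on
*within-assay ligand pairs*: a sampled training unit is the six-tuple
(P_i, L_ij, L_ik, y_ij, y_ik, t_i) of one target, two ligands measured in
the same assay, their affinities and the measurement type.

## Data model and curation

An affinity record carries the raw curation fields used by ChEMBL-style
filtering. A record survives curation iff it satisfies all eight criteria:
measurement type in {IC50, Ki, Kd}; relation `=`; units nM; assay type B
(binding); target type SINGLE PROTEIN; component type PROTEIN; molecule
type Small molecule; BAO format BAO_0000357. Removals are attributed to
the first violated criterion in that order, so that the report buckets
partition the input (a conservation identity asserted in the tests).
After filtering, assays with a single ligand or with more than one
measurement type are excluded. Duplicate (assay, ligand) measurements
collapse to their geometric mean — the natural average for
log-distributed affinities; the choice is deterministic and config-free.

Measurement types map onto two task families: IC50 stays its own family;
Ki and Kd merge into a single K family (they quantify the same physical
binding; Kd data alone would be too scarce to carry a task).

Pair sampling is two-stage: an assay is drawn with probability
proportional to its size n_i, then two distinct ligands uniformly without
replacement, in random order. Exactly equal values would make the ranking
label undefined; the second ligand is redrawn (bounded retries), and an
assay whose values are all identical raises an explicit error. One epoch
of the pair stream is defined as Σ n_i sampled pairs.

Regression targets use the pAff scale, 9 − log10(value in nM) (1 nM ↔ 9.0):
mean-squared error on raw nM would be dominated by weak binders, and the
pK scale is the norm for downstream benchmarks. Ranking labels are
computed literally on the stored nM values, label = 1[y_ij > y_ik]; the
label is invariant to any monotone rescaling of both values.

## Multi-graph representation

A complex is represented as three graphs built from coordinates only:

* **ligand graph** — heavy atoms as nodes; edges between atom pairs at
  Euclidean distance < 5.0 Å;
* **protein graph** — residues as nodes at their Cα coordinate; edges
  between Cα pairs < 8.0 Å;
* **interaction graph** — bipartite residue–atom graph with edges for
  Cα–atom pairs < 12.0 Å.

All cutoffs compare strictly (`<`), self-loops are excluded, and the
homogeneous graphs are stored undirected with (i, j), i < j, expanded to
both directions only when tensors are built. By default the protein is
truncated to pocket residues — those within the interaction cutoff of any
ligand atom — since more distant residues can never touch the interaction
graph; a flag restores the full chain.

Feature schema (version 2024.1, config-exposed): atoms carry an element
one-hot over {C, N, O, S, P, F, Cl, Br, I, other}, degree one-hot 0–5,
formal charge, aromaticity and ring flags, and a hybridization one-hot;
residues carry a 20+1 one-hot, Kyte–Doolittle hydropathy, side-chain
charge class and scaled molecular weight; unknown categories always map
to an explicit "other" slot. Edge features are a 16-center Gaussian
radial-basis expansion of the distance on [0, cutoff] with bandwidth equal
to the center spacing (a distance at a center contributes exactly 1.0 in
that slot); ligand edges append a bond-order one-hot when the file
provides connectivity. Ligand parsing uses RDKit (SDF/MOL2), protein
parsing uses Biopython (PDB): residues without a Cα are skipped with a
warning, HETATM records are ignored, and for disordered atoms the
alternate location with the smallest altloc identifier is kept.

## Encoder

The shared bottom encoder runs in three stages.

**Message passing.** For each of the ligand and protein graphs, a GNN
iterates: messages M_ℓ(h_i, h_j, e_ij) are aggregated over neighbours
N(i) and an update U_ℓ produces h_i^(ℓ+1); isolated nodes receive the
zero message. The final node embedding is the jumping-knowledge sum over
layers, h_i = Σ_ℓ h_i^(ℓ). Five variants share this scheme — GCN
(degree-normalised sum), GIN (sum aggregation into an MLP update with a
learnable ε), GAT (softmax attention over incoming edges), EGNN (messages
conditioned on squared pairwise distances; implemented in its invariant
form without coordinate updates, so the affinity output is exactly
invariant to rigid motions), and an AttentiveFP-style gated-attention
layer (attention over edge-conditioned neighbour features with a sigmoid
gate blending candidate and previous state; the super-node read-out of
the original is not used because the framework applies its own read-out
after the GNN). Variants that do not natively consume edge features
receive them concatenated into the neighbour message.

**Interaction fusion.** For each contact edge (i, j), the interaction
embedding is h^I_ij = MLP(h^P_i ‖ h^L_j ‖ FC(e^I_ij)): a fully connected
layer maps the edge feature to d_I/2, and the fusion MLP (2 layers,
hidden width d_I, LeakyReLU) produces a d_I-dimensional embedding per
contact. A complex with no contact edge raises an explicit error and is
excluded at dataset assembly with a logged count — never zero-padded.

**Read-out.** o_sum = Σ_(i,j) tanh(w·h^I_ij) · h^I_ij with a learned
attention vector w, o_max is the elementwise maximum over contact edges,
and the complex embedding is o = o_sum ‖ o_max (dimension 2·d_I). The
per-edge tanh scores, bounded in (−1, 1), are retained for contact-level
interpretation.

## Multi-task heads and losses

Four heads sit on the shared encoder (hard parameter sharing), one per
(family, objective) cell of {IC50, K} × {regression, ranking}. Routing is
by the pair's label type only. Regression heads map o to a scalar pAff;
ranking heads map the ordered concatenation o_1 ‖ o_2 to a logit whose
sigmoid estimates P(y_ij > y_ik). The ranking head is deliberately not
antisymmetric; random pair order during sampling exposes both orders in
training. Heads are 2-layer MLPs (input → d_o/2 → 1, LeakyReLU). Head
inputs pass through an elementwise asinh: the attention-sum read-out
grows linearly with the number of contact edges, and compressing that
dynamic range (log-like but smooth and sign-preserving) is what keeps
head optimization well-conditioned across complexes of very different
contact counts.

Losses per pair: L_reg is the squared error of the *first* sample's pAff
only; L_rank is binary cross-entropy computed in logit space
(softplus form, numerically stable); the total is

    L_total = L_rank + λ · L_reg,

with λ ≥ 0 (default 0.1, the centre of the standard ablation grid
{0, 0.01, 0.1, 0.3, 1.0}; λ = 0 reduces exactly to ranking-only
pre-training). Any subset of the four tasks can be disabled; the loss
then contains only the enabled terms. Batch losses are means over pairs.

## Training protocol

Adam with initial learning rate 1e-3 and L2 factor 1e-6; the learning
rate is multiplied by 0.6 whenever the epoch-mean training loss sets no
new minimum for 10 consecutive epochs ("no drop" = no new minimum; the
patience counter resets on any new minimum). A configurable floor
(default 1e-6) guards degenerate schedules. Dropout 0.1 on node
embeddings during training; evaluation is fully deterministic. Reference
batch sizes are 256 (pre-training) and 128 (fine-tuning) with 100 and
1000 epochs respectively; fine-tuning stops early after 70 epochs without
validation-RMSE improvement and restores the best epoch. The desk-scale
benchmark runs use the same protocol with smaller budgets (25 pre-training
epochs at batch 32, up to 120 fine-tuning epochs) chosen to fit the
package's CPU-only compute backend; both phases use the same plateau rule.

For fine-tuning, the shared encoder and the two regression heads are
transferred; ranking heads are discarded. Mixed IC50/K batches route each
sample to its own regression head. Checkpoints are versioned .npz
archives with a config hash; loading against a different configuration is
refused, and a save/load round trip is bit-exact.

The numerical core is a small reverse-mode automatic-differentiation
engine over NumPy arrays (dense linear algebra plus sparse gather/scatter
operators for message passing over static graph structure), validated
against central-difference gradients in the test suite.

## Synthetic data generator

The generator emulates the statistical structure the framework assumes,
with full provenance:

* residues sit on a jittered cubic lattice (spacing 5.5 Å, jitter
  ±0.8 Å); the ligand is an atom blob (radius 2 Å) placed at a uniform
  2–12 Å from the pocket centre, plus Gaussian pose jitter (0.3 Å)
  emulating docking-pose imprecision;
* the *true* affinity is planted on the contact count c — the number of
  interaction-graph edges of the emitted coordinates:

      pAff = 4.0 + 0.02·c + b_assay + δ_type·1[IC50] + ε,
      value(nM) = 10^(9 − pAff),

  with per-assay offset b_assay ~ N(0, 0.4²) (label noise), a −0.5 pAff
  shift for IC50 assays (label variety; IC50 values run weaker than
  binding constants), and measurement noise ε ~ N(0, 0.1²);
* collections default to 40 assays of 6–14 ligands (one protein target
  and one measurement type per assay, types drawn 0.5/0.3/0.2 for
  IC50/Ki/Kd), giving ≈ 400 records whose table satisfies all eight
  curation criteria by construction.

Affinity is planted on the contact count rather than on chemistry because
the contact count is the one structural quantity the encoder provably
sees; recovery therefore isolates the learning framework from the
featurization schema. The whole generator is deterministic given the
seed, and contact counts stored in the truth record equal a brute-force
recount over the emitted files.

What the generator does **not** emulate: real protein folds and secondary
structure, chemically valid ligand topologies, docking-pose physics,
assay-size and chemotype distributions of real databases, and any
affinity dependence on atom types or charges. Passing the recovery
benchmarks therefore shows that the pipeline — curation, pair sampling,
encoding, multi-task optimisation, transfer — can extract a planted
structural signal under assay-level label corruption; it does not certify
accuracy on real complexes.

## Benchmarks the package runs on itself

* **Graph oracle suite**: edge sets of all three graphs equal an O(n²)
  brute-force recomputation over seeded random geometries; boundary
  strictness and rigid-motion invariance hold.
* **Loss identities**: L_total = L_rank + λ·L_reg to 1e-6 relative on
  random pairs across the λ grid; BCE at zero logit equals ln 2;
  regression ignores the pair's second label.
* **Sampler distributions**: assay selection matches size-proportional
  probabilities and unordered pairs are uniform (chi-square, α = 0.001).
* **Learnability**: pre-training on 40 synthetic assays reaches held-out
  within-assay pair-ranking accuracy well above 0.75, and fine-tuning
  from the pre-trained encoder attains mean test RMSE at or below the
  identically initialised from-scratch arm over five paired seeds.

## Known limitations

* The compute backend is CPU-only and optimised for clarity; complexes
  are encoded one at a time (no cross-complex batching).
* The exact atom/residue feature lists used alongside the original
  cutoffs are not reproduced; the schema here is a declared, versioned
  substitute, and absolute metric values depend on it.
* GAT/AttentiveFP attention normalisation makes those variants' outputs
  depend on edge multiplicity only through the attention weights; all
  variants are simplified single-head forms.
* The ranking orientation follows the literal label 1[y_ij > y_ik] on nM
  values — the head predicts "first value larger", i.e. first binder
  weaker; downstream interpretation must apply the inversion.
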