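# Methods

This note documents the models, conventions and numerical choices behind
`ppigcn`, including the points where the design was genuinely open and a
convention had to be fixed.

## Structure model and PDB conventions

A protein is an ordered list of residues grouped contiguously by chain;
every residue must have a Cα atom, because all three graph abstractions
and the contact-number feature are Cα-distance based. Residues lacking a
Cα (disordered side products of crystallography) are dropped at parse
time — they could not participate in any abstraction, and how the
original experiments handled them is not recoverable, so the drop rule is
our documented choice. Further parsing conventions, all chosen for
determinism and standard practice rather than derived from any single
source: first MODEL only for multi-model files; alternate locations
resolved to the highest-occupancy conformer with ties broken toward
altloc `A`; selenomethionine (MSE) mapped to MET; all other HETATM and
waters excluded; unrecognized ATOM residue names kept as `UNK` (all-zero
one-hot, mean HQI8 values) so chains stay connected without inventing
chemistry. Hydrogens are retained but flagged; interface labeling and
surface areas use heavy atoms only.

## Graph abstractions

Two residues are *sequential neighbours* when they are consecutive within
one chain: adjacent in file order with consecutive (or
insertion-adjacent) author numbering, or with a Cα–Cα gap of at most
4.5 Å. The 4.5 Å guard prevents spurious sequential edges across
unmodelled loops (a trans peptide bond places consecutive Cα atoms near
3.8 Å) while still bridging pure renumbering artifacts. *Spatial
neighbours* are all other pairs with Cα distance strictly below the
threshold; the strict `<` at the boundary follows the "less than a
threshold" reading, and ties at exactly the threshold are excluded.

The hierarchical weight is 1 for sequential pairs and `1/(1+x)` for
spatial pairs at distance `x`; where both cases could apply the
sequential case wins, keeping the weight single-valued. Contact maps
include sequential pairs that fall within the threshold (no carve-out —
the standard contact-map convention), and all builders keep a zero
diagonal: the self-loop enters only through `A + I` in the GCN
normalization. Within a multi-chain protein, spatial edges may span
chains — the molecule is one graph. Cα is used for every residue
including glycine; Cβ-based or side-chain-centroid contact definitions
are out of scope.

## Features

Each residue gets 33 numbers: 8 HQI8 AAindex values, ASA, rASA, contact
number, φ, ψ, and a 20-way one-hot (alphabetical by three-letter code).
φ and ψ are kept as two separate columns; a 32-column variant (collapsing
one) would also be defensible, and the layout constants are exposed so an
implementer can drop a column if desired.

* **HQI8** — eight physico-chemical indices selected as cluster centres
  of a consensus fuzzy clustering of AAindex1; shipped as a plain-text
  table keyed by the original accessions, so the data is swappable.
* **ASA** — an internal Shrake–Rupley implementation: each heavy atom's
  sphere (van der Waals radius + 1.4 Å probe) is sampled with a 960-point
  golden-spiral lattice; a point is exposed iff outside every other
  expanded sphere. Before sampling, coordinates are rotated into the
  molecule's principal-axes frame with a deterministic sign convention,
  which makes the discretized result invariant under rigid motion of the
  input rather than merely approximately so. For an isolated atom the
  result is exactly `4π(r+probe)²` for any point count. Radii: C 1.70,
  N 1.55, O 1.52, S 1.80 Å, default 1.70 for unlisted elements (logged).
  DSSP would give slightly different absolute values; this engine was
  chosen because it requires no external binary and is testable against
  closed forms.
* **rASA** — ASA divided by a per-type theoretical maximum
  (Gly-X-Gly extended reference values, packaged as data); values are not
  clipped and may slightly exceed 1.
* **Contact number** — the residue's degree in the spatial-pairs graph,
  i.e. excluding sequential neighbours, mirroring the sequential/spatial
  dichotomy; an inclusive variant is available behind a flag.
* **Torsions** — IUPAC convention, degrees in (−180, 180], computed with
  the standard signed-dihedral formula (verified against Bio.PDB's
  `calc_dihedral` to 1e-13). Angles undefined at termini, chain breaks or
  missing backbone atoms are encoded as 0.0 (keeping the matrix dense)
  with a definedness mask retained for diagnostics. Degrees rather than
  radians, and raw angles rather than sin/cos pairs, are fixed
  conventions.

Feature standardization z-scores the 13 leading columns using statistics
of *training-mask nodes only* (constant columns are centered, not
divided); the one-hot block is untouched. Fitting on training nodes only
avoids leakage through the shared composite matrix.

## Interface labels and datasets

A residue is an interface residue iff at least one of its heavy atoms
lies within 5.0 Å — inclusive — of any heavy atom of the partner;
"within" is read as ≤, and the boundary behaviour is tested at
4.9/5.0/5.1 Å. Labeling uses a KD-tree over partner atoms but must (and
is tested to) equal the all-pairs brute force. Labels computed on a bound
complex can be transferred to another conformation by chain id + author
number + insertion code, a documented choice for the unbound case.

Datasets are transductive: per-protein graphs become blocks of one
block-diagonal sparse adjacency, features are stacked, and three disjoint
node masks mark train/validation/test membership. Splits are always by
whole protein, never by residue.

## The classifier

The GCN is implemented directly over numpy/scipy.sparse with analytic
gradients (verified against central finite differences at 1e-5 relative).
Architecture and training follow the reference setup: input → 35 → 32 → 2
with ReLU on the hidden layers and a softmax head; dropout 0.5 on layer
inputs during training (inverted scaling); full-batch gradient descent at
learning rate 0.001; at most 1500 epochs. Choices the setup left open,
fixed here:

* **Degree mode.** The normalization `D̂^{-1/2}(A+I)D̂^{-1/2}` needs a
  degree definition. The weighted row-sum of `A+I` is the default — the
  hierarchical graph is real-valued, and a weighted degree is the natural
  reading — but the literal "number of incident edges plus one"
  (unweighted) is also implemented; the two coincide on binary graphs.
* **Output head and loss**: 2-unit softmax with mean cross-entropy over
  training nodes; optional inverse-frequency class weights (off by
  default).
* **Early stopping**: validation loss monitored every epoch (with dropout
  off), patience 50, parameters restored from the best-validation epoch.
  Validation AUC is logged but not used for stopping.
* **Initialization**: seeded Glorot-uniform; no biases by default
  (matching the propagation rule's form), biases available by flag.
* **Full-batch descent**: one gradient step per epoch over all training
  nodes, as in the original spectral-GCN training regime.
* **Decision threshold** 0.5 for hard labels; all ranking metrics are
  threshold-free.
* A non-finite training loss aborts with a learning-rate diagnostic
  rather than silently diverging.

The per-node aggregation view of the propagation rule is exactly the
row-wise reading of the matrix form and is not a separate code path.

## Evaluation

Scalar metrics follow the standard confusion-count formulas with
degenerate-denominator conventions: precision, recall and F1 are 0 when
undefined, MCC is 0 when any factor under the root vanishes. AUC is the
Mann–Whitney statistic with half credit for ties, identical to trapezoid
integration of the threshold-sweep ROC. Pooled-over-nodes metrics are the
primary report; per-protein vertical curve averaging (101-point grid,
ROC endpoints pinned, single-class proteins skipped and counted) is
emitted separately, since either pooling is defensible for corpus-level
tables.

## Synthetic data

The generators exist so every stage is testable without downloads; their
defaults are the study conditions used throughout.

* `ideal_helix` builds the backbone from canonical internal coordinates
  (φ=−57°, ψ=−47°, ω=180°, standard bond lengths/angles), so torsion
  recovery inverts the construction exactly. `extended_chain` places Cα
  on a straight line at 3.8 Å with a planar schematic backbone.
  `self_avoiding_walk` and `globule` take 3.8 Å steps keeping all
  non-consecutive Cα pairs ≥ 3.5 Å, the globule with a centripetal bias.
  Every residue carries N/CA/C/O plus a single pseudo side-chain heavy
  atom (named CB, present on glycine too) — enough reach for surface and
  labeling machinery at toy scale, but deliberately non-physical: no
  rotamers, no packing, no chemistry.
* Complexes are posed for extended chains only: two chains run
  face-to-face with side-chain atoms separated by 4.3 Å so exactly the
  designated residue pairs fall in the (3.5, 5.0] Å contact window and
  every other cross-pair exceeds 5 Å. The pose is re-verified with the
  interface labeler; other geometries raise a generation error rather
  than returning unverified labels.
* The planted dataset (defaults: 20 proteins × 60 residues, interface
  fraction 0.25, 60/20/20 protein-level split, hierarchical graphs at
  8 Å — a mid-range threshold) computes *real* features from the
  structures and then shifts 4 designated physico-chemical columns of
  interface rows by `signal_strength` × column standard deviation
  (default 2). Planting the signal in feature space rather than geometry
  gives a controllable, analyzable effect size for recovery tests.

What passing these tests shows — and does not. The recovery experiment
demonstrates that the pipeline wiring, masking, standardization and
optimization can extract a label-correlated feature signal through the
graph convolution, and the label-randomized null (test AUC ≈ 0.5 across
seeds) shows no information leaks through the masks. It does not show
that real interfaces are predictable at any particular accuracy: real
proteins have correlated features, conformational change between bound
and unbound forms, and interface chemistry that a planted mean shift
does not emulate.

## Problem sizes and tolerances

Default experiment sizes (20 × 60-residue proteins, 1200 nodes) keep the
full recovery experiment and its null repeats to a couple of minutes on
one CPU. Oracle comparisons use exact equality where both routes perform
the same IEEE operations (graph weights vs. a literal double loop),
1e-8 for sparse-vs-dense forward passes, 2% for the 960-point surface
sampling against the analytic two-sphere formula, and 1° for torsion
recovery on the ideal helix.

## Known limitations

* The pose generator guarantees planted labels only for extended-chain
  geometry; helical or globular complexes would need a search-based pose.
* The SASA engine's absolute values differ slightly from DSSP's
  algorithm; comparisons with DSSP-derived features should re-standardize.
* No minibatching or neighbour sampling: the composite adjacency must fit
  in memory (fine up to ~10⁵ residues in sparse form).
* No evolutionary features (PSSM), secondary-structure assignment or
  homology reduction; class-imbalance weighting is off by default.
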