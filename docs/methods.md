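# Methods

## Data model and labeling

A mutation record holds a reference ("wild-type") sequence, an ordered
set of point substitutions (each validated against the reference), and a
measurement: ΔΔG (kcal/mol) and/or ΔTm (°C). The binary label derives
from the measurement's sign under an explicit, dataset-level convention.
The default, `stabilizing_positive`, maps ΔΔG > 0 → 1 (stabilizing) and
ΔΔG < 0 → 0; the mirrored `stabilizing_negative` convention is available
because both sign conventions circulate in the thermodynamics literature
and silent inference would corrupt labels. An exact zero is labeled 0
with a warning — a measured zero carries no sign information, and the
conservative reading is "not stabilizing". When both measurements exist,
ΔΔG is the labeling source; ΔTm-only records are labeled from sign(ΔTm)
under the same convention (no ΔΔG↔ΔTm conversion is attempted).

Curation: deduplication keys on (wild-type sequence, mutation set,
direction) and keeps the first occurrence, logging conflicting duplicate
measurements; records with neither measurement are dropped; homology
filtering removes every record whose reference sequence a search backend
flags against a held-out set (default e-value cut 0.001). The backend is
injectable — a subprocess blastp wrapper is provided, and tests use a
deterministic identity oracle — and its absence is an error, never a
silent pass-through.

## Thermodynamic augmentation

**Looping (TL).** ΔΔG is a state function, so for variants A and B of
one wild type W the cycle W→A→B→W closes:
ΔΔG(A→B) = ΔΔG(W→B) − ΔΔG(W→A). TL groups records by identical reference
sequence and emits, for every ordered pair of distinct variants with
numeric ΔΔG, a derived record whose reference is A's mutant sequence and
whose mutation set is the sequence difference A→B. Derived |ΔΔG| below
1e−9 kcal/mol (an exact tie) is skipped rather than arbitrarily labeled;
derived duplicates are dropped; derived records with exactly one
substitution are routed to a separate single-point dataset (they merge
into single-point training sets), and one pass is performed (TL output
is not fed back into itself). When A lies above the wild type on the
folding-energy scale (ΔΔG(W→A) > 0) and B below it, the derived value is
necessarily ≤ 0 — this bound is asserted in the acceptance suite.
Structures for TL records reference the variant's mutant sequence; the
package threads sequences onto existing backbones and otherwise consumes
externally modeled structures.

**Reversibility (TR).** Mutating X→Y and Y→X have opposite ΔΔG, so every
record gains a reverse twin: reference and mutant swapped, mutations
inverted, ΔΔG/ΔTm negated, label flipped, direction `reverse`. On a
deduplicated input the output is exactly twice the input, the class
balance becomes exact, and reversal is an involution (re-reversing the
reverse half reproduces the direct half record-by-record).

## Splitting by mutation-type combination

Each record is encoded as a multi-hot vector over the vocabulary of
observed (from, to) substitution types — positions are deliberately not
encoded, because generalization in multiple-point prediction tracks the
*combination of types*, not loci. Unique vectors are embedded to 2-D
with seeded t-SNE (perplexity 30, clamped below the number of unique
vectors) and clustered with DBSCAN (min_samples 5; eps from the
k-distance curve's maximum-curvature elbow when not supplied). Clustering
runs on unique combinations with back-mapping to records, so duplicated
combinations do not reweight the embedding; an input of identical
vectors short-circuits to a single cluster. DBSCAN noise keeps label −1
and is routed to train.

Allocation fills each cluster's test quota — round-half-up(cluster size ×
test fraction) — by moving whole wild types (all their records, across
all clusters) into test in seeded random order. When the next random
candidate would overshoot the remaining quota, the smallest-footprint
candidate is tried instead and accepted only if the overshoot stays
within one quota-remainder; otherwise the cluster under-fills and the
shortfall is reported, mirroring clusters monopolized by one large wild
type. A global record quota caps the overall test size, since moved wild
types drag along records (e.g. noise) that no cluster quota counts. The
hard invariant — no wild-type sequence in both partitions — holds by
construction; on ≥ 20 equal-size wild types the achieved fraction stays
within [0.15, 0.25] of a requested 0.2 across seeds.

## Geometric featurization

Nodes are residues; directed edges connect each residue to its k = 30
nearest CA neighbors (truncated to n−1; exact distance ties broken by
residue index). Defaults follow the GVP-GNN lineage and are
config-exposed.

Node scalars concatenate up to six families (order fixed; width 72 with
all enabled): one-hot identity (20), Atchley's five standardized
physicochemical factors (bundled constant table; each column has
near-zero mean over the 20 residues), a PSSM profile (20; raw log-odds
squashed by the monotone bounded transform sigmoid(x/2)), a structure
potential (1), per-residue energy-term scores (20; a 20-column named
schema in the style of an all-atom scoring function's per-residue
breakdown, matched by header not position), and backbone-dihedral
features (6). The structure potential is a documented contact-count
stand-in — CA neighbors within 10 Å, scaled by a fixed saturation
constant of 24 — kept behind a swappable function so a pairwise contact
potential can replace it.

Dihedrals φ/ψ/ω use the standard four-atom torsion (validated against an
independent implementation); angles at termini or spanning a chain break
(consecutive CA–CA outside [2.5, 4.5] Å) are masked to (0, 0) with a
validity flag. The feature encoding is [|sin|, cos] per angle: a
torsion's *sign* flips in a mirror image, so using the sine magnitude
keeps scalar features invariant under reflections as well as rotations —
the invariance the classifier promises. Signed angles remain available.

Node vectors are three unit vectors per residue: to the previous CA, to
the next CA, and an imputed side-chain direction taken as the in-plane
bisector of CA←N and CA←C. The bisector is a *proper* vector (no cross
products), so all vector features transform exactly with any orthogonal
matrix, improper ones included; a cross-product ("tetrahedral")
imputation would be a pseudovector and break reflection equivariance.
Edge scalars are a 16-center Gaussian RBF of the CA–CA distance over
[0, 20] Å (width = center spacing; value 1 exactly at a center); edge
vectors are the unit displacement source→destination. Equivariance is
verified over random orthogonal transforms (half of them reflections)
plus translations: scalars move < 1e−4, vectors match the applied matrix
to < 1e−6.

## The classifier

A geometric vector perceptron transforms a tuple (s, V) of scalars and
stacked 3-vectors: vector channels are linearly mixed (Wh, then Wv) and
gated by a sigmoid of the scalar path; the scalar path consumes the
input scalars concatenated with the mixed-vector norms. Scalars are thus
invariant and vectors equivariant under any orthogonal transform — the
property, not a particular formula, is the normative contract, and it is
property-tested at every level (layer, message passing, end to end).

One GVP-GNN layer forms messages from the concatenated (source, edge,
destination) tuples through a chain of 2 GVPs, mean-aggregates over
incoming edges, and applies residual + dropout + tuple normalization
(LayerNorm on scalars, RMS normalization of vector norms), followed by a
4-GVP feedforward chain with the same residual treatment. The full model
runs both graphs through a *shared-weight* encoder (an input GVP
embedding plus 3 such layers) — sharing halves the parameters and keeps
the wild-type/mutant representations directly comparable; a
jumping-knowledge concatenation of the three layers' scalar outputs is
mean-pooled per graph; the two graph embeddings form a length-2 sequence
processed by multi-head self-attention (default 4 heads, reduced to the
largest divisor of the embedding width when needed) with a residual
connection; a final affine + sigmoid yields P(stabilizing), thresholded
at 0.5.

Hyperparameter defaults are the published profile: 3 GVP-GNN layers, 2
message GVPs, 4 feedforward GVPs, hidden scalar width 182, batch size
64; pretraining with dropout 0.6, Adam at lr 1e−4, weight decay 1e−3;
fine-tuning with dropout 0.4, lr 1e−3, weight decay 1e−6. The hidden
vector width (16) and attention head count are package choices exposed
in `ModelConfig`. Fine-tuning updates only the GVP-GNN encoder
parameters (input embedding + message-passing layers); attention and
head stay frozen, switchable to full fine-tuning. Training minimizes
binary cross-entropy; 5-fold cross-validation (rotating folds, seeded)
reports per-fold and mean ± sd accuracy/precision/recall/AUC, skipping
single-class folds with a report entry; the default budget is 100 epochs
with early stopping on the training loss (patience 10). All randomness
derives from the supplied seed, and checkpoints round-trip bit-exactly
through npz archives with embedded JSON config.

The network runs on an in-repo reverse-mode autodiff engine over numpy
(`gvpstab.autodiff`) providing exactly the operations the architecture
needs (broadcast arithmetic, batched matmul, vector-channel mixing,
segment means for aggregation, softmax, dropout, BCE); gradients are
checked against central finite differences. Batches are processed as
disjoint graph unions with segment pooling, so an epoch is a handful of
vectorized array operations rather than a Python loop over graphs.

## Evaluation

Test sets split exhaustively by direction. Accuracy, precision and
recall are computed at threshold 0.5, AUC by the rank statistic with the
midrank tie convention; single-class inputs report AUC as undefined
rather than 0.5. Bias marks derive from the direct/reverse accuracy gap:
no mark ≤ 0.05 < ● ≤ 0.1 < ●● ≤ 0.2 < ●●●. The marks use the *absolute*
gap (bias is bias in either direction); the signed difference
(reverse − direct) is reported alongside. The gap is rounded at the
ninth decimal before thresholding so values sitting exactly on a
boundary are not pushed over it by float artifacts.

## Synthetic data

Fixtures emulate the statistical shape of curated thermodynamic
databases, not their physics. Backbones are built atom-by-atom by
natural-extension-reference-frame placement from standard bond lengths
(N–CA 1.458, CA–C 1.525, C–N 1.329 Å) and angles, with ideal α-helix
torsions (φ −57°, ψ −47°, ω 180°) or fully extended chains as a
minimal-contact control; optional seeded jitter ≤ 0.1 Å breaks the exact
distance ties of ideal geometry (tests that rely on a stable k-NN graph
under rotation use jittered helices; ideal-angle checks use jitter 0).
Mutation datasets draw ΔΔG from a two-Gaussian mixture at ±1.5 kcal/mol
(sd 0.8) — magnitudes typical of measured point mutations — with a
stabilizing fraction of 0.3 by default, reflecting the destabilizing
skew of experimental databases; wild types are shared across variants so
looping pairs exist. The classification fixture encodes the class in the
mutant residue identity (label 1 → tryptophan, label 0 → glycine), a
linearly recoverable signal that a working architecture must overfit;
passing it shows the model trains and memorizes, not that it would
generalize to real mutations. PSSM and score tables are seeded random
matrices matching the featurization schemas.

## Problem sizes and numerical choices

Tests and the acceptance suite run on one CPU: graphs of 12–20 residues
with k = 8, hidden widths 12–24, datasets of 8–48 pairs, and the
training-sanity check (32 separable pairs, ≤ 200 epochs) uses the
published fine-tuning profile — the pretraining profile's dropout 0.6
and lr 1e−4 are regularization for database-scale training, not for an
overfitting check. Count-conservation checks run at the published
dataset sizes (up to 5,936 records) since augmentation is O(n).
Zero-norm safeguards: vector norms are computed as sqrt(Σx² + 1e−8), and
normalization layers add 1e−6 inside square roots; undefined orientation
vectors at termini are zero vectors, which the GVP maps to zero vectors.

## Known limitations

The contact-count structure potential and the threaded (non-relaxed)
mutant structures are stand-ins for external physics-based tooling; the
synthetic fixtures cannot certify real-data accuracy, only contracts
(counts, bounds, equivariance, determinism, trainability); paper-scale
training (hidden 182 on thousands of records) is supported by the same
code paths but is not exercised in the test suite; and multi-chain
complexes and ΔΔG regression are out of scope.
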