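# gvpstab

Classifying protein thermostability change upon single- and multiple-point
mutation with a geometric-vector-perceptron graph neural network (GVP-GNN).

## The problem

A point mutation shifts a protein's folding free energy by ΔΔG (kcal/mol):
under the stabilizing-positive convention, ΔΔG > 0 marks a stabilizing
mutation and ΔΔG < 0 a destabilizing one. Predicting that sign from
structure is central to protein engineering, but curated thermodynamic
data are scarce, skewed toward destabilizing mutations, and nearly absent
for multiple-point mutants. `gvpstab` implements a complete desk-scale
workflow for this problem:

- **Curation** (`gvpstab.data_model`) — mutation records with explicit
  sign conventions, deduplication, ΔΔG/ΔTm measurement selection, and
  homology exclusion (blastp or an injected similarity oracle) against
  held-out benchmark sequences.
- **Thermodynamic augmentation** (`gvpstab.augmentation`) — *looping*
  (TL): for variants A and B of one wild type W, energy conservation in
  the cycle W→A→B→W gives ΔΔG(A→B) = ΔΔG(W→B) − ΔΔG(W→A); and
  *reversibility* (TR): the reverse mutation carries the negated ΔΔG and
  flipped label, exactly doubling a deduplicated dataset and balancing
  the classes.
- **Leakage-free splitting** (`gvpstab.splitter`) — multi-hot encoding of
  mutation-type combinations, t-SNE + DBSCAN clustering, and per-cluster
  test quotas filled by moving whole wild types so no wild-type sequence
  appears in both partitions.
- **Geometric featurization** (`gvpstab.featurize`) — backbone PDB →
  directed k-NN residue graph with six scalar encoder families (one-hot,
  Atchley factors, PSSM, contact potential, per-residue energy scores,
  backbone dihedrals), orientation node vectors, RBF-expanded edge
  distances, and unit edge displacement vectors. Scalar features are
  invariant and vector features exactly equivariant under rigid motions
  *and* reflections.
- **The classifier** (`gvpstab.model`) — wild-type and mutant graphs pass
  through a shared GVP-GNN encoder (scalars invariant, vectors
  equivariant by construction); jumping-knowledge concatenation, mean
  pooling, multi-head attention over the two graph embeddings, and a
  sigmoid head give P(stabilizing). Training runs binary cross-entropy
  with Adam, 5-fold cross-validation, and a pretrain (single-point) →
  fine-tune (multiple-point, GVP layers only) schedule.
- **Symmetric evaluation** (`gvpstab.evaluation`) — accuracy, precision,
  recall and midrank AUC reported separately on direct and reverse
  mutations, with categorical bias marks (●/●●/●●●) from the
  direct/reverse accuracy gap.
- **Synthetic fixtures** (`gvpstab.synthetic`) — ideal α-helical and
  extended backbones from standard bond geometry, mutation datasets with
  controlled ΔΔG mixtures, and random PSSM/score tables, so the whole
  pipeline runs without downloads.

The network is implemented on a small in-repo reverse-mode autodiff
engine over numpy (`gvpstab.autodiff`); gradients are verified against
finite differences in the test suite.

## Worked example

```python
from gvpstab import (Dataset, MutationRecord, PointMutation,
                     tl_augment, tr_augment)

wt = "ACDEFGHIKL"
a = MutationRecord("A", "demo", wt, (PointMutation(1, "A", "M"),), ddg=+1.2)
b = MutationRecord("B", "demo", wt,
                   (PointMutation(1, "A", "M"), PointMutation(3, "D", "E")),
                   ddg=-0.8)
multi, single = tl_augment(Dataset(records=[a, b], name="loop"))
for rec in single:
    print(f"{rec.record_id}: {';'.join(map(str, rec.mutations))} "
          f"ddg={rec.ddg:+.1f} label={rec.label}")
print(f"TR: {len(multi)} -> {len(tr_augment(multi))} records")
```

prints

```
tl:A->B: D3E ddg=-2.0 label=0
tl:B->A: E3D ddg=+2.0 label=1
TR: 2 -> 4 records
```

Variant A (ΔΔG = +1.2) sits above the wild type on the folding-energy
scale and B (ΔΔG = −0.8) below it, so the looping-derived A→B record —
the single substitution D3E — must release energy: ΔΔG = −0.8 − 1.2 =
−2.0 ≤ 0, labeled destabilizing. Reversibility then doubles the two
originals to four records.

Training on synthetic graph pairs (a few minutes on one CPU):

```python
from gvpstab import ModelConfig, ThermostabilityModel
from gvpstab.synthetic import gen_classification_fixture

pairs, labels = gen_classification_fixture(48, seed=11)
config = ModelConfig(hidden_dim=24, vector_dim=4, epochs=120,
                     batch_size=48, patience=120, cv_folds=3, seed=0)
results = ThermostabilityModel(pairs, labels, config).fit(
    mode="finetune", seed=1)
print(results.summary())
```

```
Thermostability classifier (finetune, seed=1)
  parameters: 40944
  epochs run: 120
  cross-validation (mean +/- sd over folds):
    accuracy   0.500 +/- 0.135
    precision  0.591 +/- 0.191
    recall     0.631 +/- 0.027
    auc        0.577 +/- 0.229
training accuracy: 1.000
```

The 48-sample fixture is far too small to generalize (held-out accuracy
hovers near chance) but the model memorizes it perfectly — the expected
behavior for an architecture sanity check. `results.predict(pairs)`
returns the 0/1 calls at the 0.5 threshold.

A command-line interface mirrors the workflow (`gvpstab --help`):
`curate`, `augment-tl`, `augment-tr`, `split`, `featurize`, `pretrain`,
`finetune`, `predict`, `evaluate`, `make-fixtures`; every command takes a
YAML `--config` and a `--seed` and writes a run manifest.

## Scope

Structure preparation is consumed, not performed: relaxed mutant models,
PSSMs, and per-residue energy-score tables are external inputs with
documented schemas (synthetic generators stand in for them in tests).
Multi-chain complexes, full-atom featurization, and ΔΔG regression are
out of scope. See `docs/methods.md` for the model, parameter, and design
details.
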