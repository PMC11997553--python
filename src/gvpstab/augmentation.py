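"""Thermodynamic-cycle data augmentation.

Two augmentations enlarge a mutation dataset without new experiments, both
consequences of ΔΔG being a state function of folding free energy:

* **Thermodynamic looping (TL).**  If variants A and B share a wild type W,
  the closed cycle W → A → B → W conserves energy, so the variant-to-variant
  change is ΔΔG(A→B) = ΔΔG(W→B) − ΔΔG(W→A).  In particular, when A sits at
  a higher energy state than W (ΔΔG(W→A) > 0 under the folding-energy
  convention) and B at a lower one (ΔΔG(W→B) < 0), the derived ΔΔG(A→B)
  must be below 0 kcal/mol.  TL treats A's mutant sequence as the new
  reference and the sequence difference A→B as the new mutation set.

* **Thermodynamic reversibility (TR).**  The free-energy change of mutating
  X into Y is exactly the negative of mutating Y back into X.  TR adds, for
  every record, the reverse record with reference and mutant swapped, ΔΔG
  negated and the label flipped, doubling a deduplicated dataset and
  balancing stabilizing against destabilizing examples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace
from itertools import permutations

from .data_model import (
    DIRECT,
    Dataset,
    MutationRecord,
    REVERSE,
    TL,
    TR,
    ValidationError,
    classify_label,
    diff_sequences,
)

logger = logging.getLogger(__name__)

#: |ΔΔG| below this is treated as an exact tie and the TL pair is skipped.
TL_ZERO_TOLERANCE = 1e-9


def tl_ddg(ddg_wa: float, ddg_wb: float) -> float:
    """Cycle-closure ΔΔG(A→B) = ΔΔG(W→B) − ΔΔG(W→A) for variants of one W."""
    if not (math.isfinite(ddg_wa) and math.isfinite(ddg_wb)):
        raise ValidationError(f"non-finite ddg inputs ({ddg_wa}, {ddg_wb})")
    return ddg_wb - ddg_wa


def tl_augment(
    dataset: Dataset, convention: str = "stabilizing_positive"
) -> tuple[Dataset, Dataset]:
    """Derive variant-to-variant records by thermodynamic looping.

    Records are grouped by identical reference sequence; every ordered pair
    (A, B) of distinct variants with numeric ΔΔG yields a derived record
    with reference = A's mutant sequence, mutations = diff(seq(A), seq(B))
    and ΔΔG from :func:`tl_ddg`.  Pairs whose derived |ΔΔG| falls below the
    tie tolerance are skipped, and derived duplicates are dropped.

    Returns ``(augmented_multi, derived_single)``: derived records carrying
    exactly one substitution are routed to the single-point dataset (they
    merge into single-point training sets); everything else, plus the
    original records verbatim, forms the augmented multiple-point dataset.
    """
    groups: dict[str, list[MutationRecord]] = {}
    for rec in dataset.records:
        groups.setdefault(rec.wt_sequence, []).append(rec)

    multi: list[MutationRecord] = list(dataset.records)
    single: list[MutationRecord] = []
    seen_keys = {r.key() for r in dataset.records}
    counter = 0

    for wt_seq in sorted(groups):
        variants = groups[wt_seq]
        usable = []
        for rec in variants:
            if rec.ddg is None:
                logger.warning("TL: skipping %s (no ddg)", rec.record_id)
                continue
            usable.append(rec)
        for a, b in permutations(usable, 2):
            if a.mutations == b.mutations:
                continue
            ddg = tl_ddg(a.ddg, b.ddg)
            if abs(ddg) < TL_ZERO_TOLERANCE:
                continue
            seq_a = a.mutant_sequence
            seq_b = b.mutant_sequence
            mutations = diff_sequences(seq_a, seq_b)
            if not mutations:
                continue
            derived = MutationRecord(
                record_id=f"tl:{a.record_id}->{b.record_id}",
                wt_id=f"{a.wt_id}|{'_'.join(map(str, a.mutations))}",
                wt_sequence=seq_a,
                mutations=mutations,
                ddg=ddg,
                label=classify_label(ddg, convention),
                direction=a.direction,
                provenance=TL,
            )
            if derived.key() in seen_keys:
                continue
            seen_keys.add(derived.key())
            counter += 1
            if derived.n_mutations == 1:
                single.append(derived)
            else:
                multi.append(derived)

    logger.info("TL derived %d records (%d single-point)", counter, len(single))
    return (
        Dataset(records=multi, name=f"{dataset.name}+TL"),
        Dataset(records=single, name=f"{dataset.name}+TL-single"),
    )


def _invert_record(rec: MutationRecord) -> MutationRecord:
    """The reverse record: reference and mutant swapped, sign and label flipped."""
    if rec.ddg is None and rec.label is None:
        raise ValidationError(
            f"record {rec.record_id}: TR needs ddg or label"
        )
    return MutationRecord(
        record_id=f"tr:{rec.record_id}",
        wt_id=f"{rec.wt_id}|mut",
        wt_sequence=rec.mutant_sequence,
        mutations=tuple(m.inverted() for m in rec.mutations),
        ddg=None if rec.ddg is None else -rec.ddg,
        dtm=None if rec.dtm is None else -rec.dtm,
        label=None if rec.label is None else 1 - rec.label,
        direction=REVERSE if rec.direction == DIRECT else DIRECT,
        provenance=TR,
    )


def tr_augment(dataset: Dataset) -> Dataset:
    """Add the reverse record for every input record (antisymmetry).

    On a deduplicated input the output has exactly twice as many records;
    direct records are preserved verbatim and each reverse record carries
    the negated ΔΔG/ΔTm, the flipped label, and the inverted mutation set
    applied to the mutant sequence.
    """
    out: list[MutationRecord] = []
    for rec in dataset.records:
        out.append(rec)
        out.append(_invert_record(rec))
    return Dataset(records=out, name=f"{dataset.name}+TR")
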