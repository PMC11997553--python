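"""Mutation records, stability labels, and curation rules.

A mutation event is a set of point substitutions applied to a reference
("wild-type") protein sequence, together with an experimental thermodynamic
measurement: the change in folding Gibbs free energy ΔΔG (kcal/mol) and/or
the change in melting temperature ΔTm (°C).  The binary stability label is
derived from the sign of the measurement under an explicit convention:
under ``stabilizing_positive`` (the default), ΔΔG > 0 means the mutation
stabilizes the protein (label 1) and ΔΔG < 0 destabilizes it (label 0).
Both sign conventions appear in the literature, so the convention is a
dataset-level parameter and is never inferred.

Curation follows the usual thermodynamic-database hygiene: exact duplicate
removal, measurement selection (records with neither ΔΔG nor ΔTm are
useless and dropped), and exclusion of records whose reference sequence is
homologous to any sequence in a held-out set (to prevent train/test
leakage through shared folds).
"""

from __future__ import annotations

import csv
import logging
import re
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids, one-letter codes, alphabetical.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

STABILIZING_POSITIVE = "stabilizing_positive"
STABILIZING_NEGATIVE = "stabilizing_negative"

DIRECT = "direct"
REVERSE = "reverse"

#: Record provenance markers: experimental, thermodynamic looping,
#: thermodynamic reversibility.
EXPERIMENTAL = "experimental"
TL = "TL"
TR = "TR"

_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


class ValidationError(ValueError):
    """A record or operation input violated a contract."""


@dataclass(frozen=True, order=True)
class PointMutation:
    """A single substitution ``from_aa`` → ``to_aa`` at a 1-based position."""

    position: int
    from_aa: str
    to_aa: str

    def __post_init__(self) -> None:
        if self.from_aa not in CANONICAL_AA:
            raise ValidationError(f"non-canonical from_aa {self.from_aa!r}")
        if self.to_aa not in CANONICAL_AA:
            raise ValidationError(f"non-canonical to_aa {self.to_aa!r}")
        if self.from_aa == self.to_aa:
            raise ValidationError(
                f"silent mutation {self.from_aa}{self.position}{self.to_aa}"
            )
        if self.position < 1:
            raise ValidationError(f"position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, token: str) -> "PointMutation":
        """Parse compact notation like ``"L10A"`` (1-based position)."""
        m = _MUTATION_RE.match(token.strip())
        if not m:
            raise ValidationError(f"cannot parse mutation token {token!r}")
        return cls(position=int(m.group(2)), from_aa=m.group(1), to_aa=m.group(3))

    def inverted(self) -> "PointMutation":
        """The reverse substitution (to_aa → from_aa at the same position)."""
        return PointMutation(self.position, self.to_aa, self.from_aa)

    def __str__(self) -> str:
        return f"{self.from_aa}{self.position}{self.to_aa}"


def parse_mutations(text: str) -> tuple[PointMutation, ...]:
    """Parse a semicolon-joined mutation list, e.g. ``"L10A;K20R"``."""
    text = text.strip()
    if not text:
        return ()
    muts = tuple(PointMutation.parse(tok) for tok in text.split(";"))
    return tuple(sorted(muts))


@dataclass(frozen=True)
class MutationRecord:
    """One labeled mutation event against a reference sequence."""

    record_id: str
    wt_id: str
    wt_sequence: str
    mutations: tuple[PointMutation, ...]
    ddg: float | None = None
    dtm: float | None = None
    label: int | None = None
    direction: str = DIRECT
    provenance: str = EXPERIMENTAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "mutations", tuple(sorted(self.mutations)))
        if self.ddg is None and self.dtm is None and self.label is None:
            raise ValidationError(
                f"record {self.record_id}: needs at least one of ddg/dtm/label"
            )
        if self.direction not in (DIRECT, REVERSE):
            raise ValidationError(
                f"record {self.record_id}: bad direction {self.direction!r}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValidationError(f"record {self.record_id}: label must be 0/1")
        seen: set[int] = set()
        for mut in self.mutations:
            if mut.position in seen:
                raise ValidationError(
                    f"record {self.record_id}: duplicate position {mut.position}"
                )
            seen.add(mut.position)
            if mut.position > len(self.wt_sequence):
                raise ValidationError(
                    f"record {self.record_id}: position {mut.position} beyond "
                    f"sequence of length {len(self.wt_sequence)}"
                )
            actual = self.wt_sequence[mut.position - 1]
            if actual != mut.from_aa:
                raise ValidationError(
                    f"record {self.record_id}: mutation {mut} inconsistent with "
                    f"reference ({actual!r} at position {mut.position})"
                )

    @property
    def mutant_sequence(self) -> str:
        return apply_mutations(self.wt_sequence, self.mutations)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    def key(self) -> tuple:
        """Identity key used for deduplication."""
        return (self.wt_sequence, self.mutations, self.direction)


@dataclass
class Dataset:
    """An ordered collection of :class:`MutationRecord` with unique ids."""

    records: list[MutationRecord] = field(default_factory=list)
    name: str = "dataset"

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"dataset {self.name}: duplicate record_ids")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def wildtype_sequences(self) -> set[str]:
        return {r.wt_sequence for r in self.records}


def classify_label(
    ddg: float, convention: str = STABILIZING_POSITIVE
) -> int:
    """Map a ΔΔG (or ΔTm) value to the binary stability label.

    Under ``stabilizing_positive`` a positive value marks a stabilizing
    change (label 1) and a negative value a destabilizing one (label 0);
    ``stabilizing_negative`` mirrors the mapping.  An exact zero is labeled
    destabilizing (0) with a warning — a measured zero carries no sign
    information.
    """
    import math

    if ddg is None or not math.isfinite(ddg):
        raise ValidationError(f"non-finite ddg {ddg!r}")
    if convention not in (STABILIZING_POSITIVE, STABILIZING_NEGATIVE):
        raise ValidationError(f"unknown sign convention {convention!r}")
    if ddg == 0.0:
        warnings.warn("ddg == 0 labeled destabilizing (0)", stacklevel=2)
        return 0
    positive = ddg > 0
    if convention == STABILIZING_NEGATIVE:
        positive = not positive
    return 1 if positive else 0


def apply_mutations(
    wt_sequence: str, mutations: Iterable[PointMutation]
) -> str:
    """Apply substitutions to a sequence, checking reference consistency."""
    seq = list(wt_sequence)
    for mut in mutations:
        if mut.position > len(seq):
            raise ValidationError(
                f"mutation {mut}: position beyond sequence length {len(seq)}"
            )
        if seq[mut.position - 1] != mut.from_aa:
            raise ValidationError(
                f"mutation {mut}: reference has {seq[mut.position - 1]!r} "
                f"at position {mut.position}"
            )
        seq[mut.position - 1] = mut.to_aa
    return "".join(seq)


def diff_sequences(seq_a: str, seq_b: str) -> tuple[PointMutation, ...]:
    """Minimal substitution set turning ``seq_a`` into ``seq_b``."""
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"sequence length mismatch ({len(seq_a)} vs {len(seq_b)})"
        )
    return tuple(
        PointMutation(i + 1, a, b)
        for i, (a, b) in enumerate(zip(seq_a, seq_b))
        if a != b
    )


def dedup_records(dataset: Dataset) -> Dataset:
    """Keep one record per (wt_sequence, mutation set, direction).

    First occurrence wins; duplicates with conflicting ΔΔG values are
    logged, not raised — the retained measurement is the first seen.
    """
    seen: dict[tuple, MutationRecord] = {}
    out: list[MutationRecord] = []
    for rec in dataset.records:
        key = rec.key()
        prev = seen.get(key)
        if prev is None:
            seen[key] = rec
            out.append(rec)
        elif prev.ddg is not None and rec.ddg is not None and prev.ddg != rec.ddg:
            logger.warning(
                "conflicting ddg for duplicate %s vs %s (%s vs %s); keeping first",
                prev.record_id, rec.record_id, prev.ddg, rec.ddg,
            )
    return Dataset(records=out, name=dataset.name)


def select_measurement(
    dataset: Dataset, convention: str = STABILIZING_POSITIVE
) -> Dataset:
    """Drop unmeasured records and derive labels.

    Records carrying neither ΔΔG nor ΔTm are removed.  When ΔΔG is present
    it is the labeling source; a record with only ΔTm is labeled from
    sign(ΔTm) under the same convention (a hotter melting point under
    ``stabilizing_positive`` is stabilizing).
    """
    out: list[MutationRecord] = []
    for rec in dataset.records:
        if rec.ddg is not None:
            out.append(replace(rec, label=classify_label(rec.ddg, convention)))
        elif rec.dtm is not None:
            out.append(replace(rec, label=classify_label(rec.dtm, convention)))
        # neither value: dropped
    return Dataset(records=out, name=dataset.name)


# ---------------------------------------------------------------------------
# Homology filtering

SimilarityBackend = Callable[[str, Sequence[str], float], bool]
"""Callable(query_sequence, reference_sequences, evalue_threshold) -> flagged."""


def identity_oracle(min_identity: float = 0.9) -> SimilarityBackend:
    """Injected test backend: flags equal-length pairs above an identity cut."""

    def backend(query: str, references: Sequence[str], threshold: float) -> bool:
        for ref in references:
            if len(ref) != len(query) or not query:
                continue
            ident = sum(a == b for a, b in zip(query, ref)) / len(query)
            if ident >= min_identity:
                return True
        return False

    return backend


def blastp_backend(workdir: str | Path | None = None) -> SimilarityBackend:
    """Similarity backend shelling out to NCBI ``blastp`` (tabular output).

    Requires ``makeblastdb`` and ``blastp`` on PATH; raises a clear error
    otherwise so the caller can inject an oracle instead.
    """

    def backend(query: str, references: Sequence[str], threshold: float) -> bool:
        with tempfile.TemporaryDirectory(dir=workdir) as tmp:
            tmp_path = Path(tmp)
            db_fa = tmp_path / "refs.fasta"
            db_fa.write_text(
                "".join(f">ref{i}\n{seq}\n" for i, seq in enumerate(references))
            )
            q_fa = tmp_path / "query.fasta"
            q_fa.write_text(f">query\n{query}\n")
            try:
                subprocess.run(
                    ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
                    check=True, capture_output=True,
                )
                res = subprocess.run(
                    ["blastp", "-query", str(q_fa), "-db", str(db_fa),
                     "-outfmt", "6 sseqid evalue", "-evalue", str(threshold)],
                    check=True, capture_output=True, text=True,
                )
            except (FileNotFoundError, subprocess.CalledProcessError) as exc:
                raise RuntimeError(
                    "blastp backend unavailable; inject a similarity oracle "
                    "(e.g. data_model.identity_oracle()) instead"
                ) from exc
        return bool(res.stdout.strip())

    return backend


def homology_filter(
    dataset: Dataset,
    reference_set: Sequence[str],
    evalue_threshold: float = 0.001,
    search_backend: SimilarityBackend | None = None,
) -> Dataset:
    """Remove records whose reference sequence is homologous to any sequence
    in ``reference_set`` according to the search backend (default e-value
    cut 0.001)."""
    if search_backend is None:
        raise ValidationError(
            "homology_filter requires a search_backend (blastp_backend() or an "
            "injected similarity oracle); refusing to silently pass through"
        )
    if not reference_set:
        return Dataset(records=list(dataset.records), name=dataset.name)
    flagged: dict[str, bool] = {}
    out = []
    for rec in dataset.records:
        if rec.wt_sequence not in flagged:
            flagged[rec.wt_sequence] = search_backend(
                rec.wt_sequence, reference_set, evalue_threshold
            )
        if not flagged[rec.wt_sequence]:
            out.append(rec)
    return Dataset(records=out, name=dataset.name)


# ---------------------------------------------------------------------------
# Tabular I/O

CSV_COLUMNS = [
    "record_id", "wt_id", "wt_sequence", "mutations",
    "ddg", "dtm", "label", "direction", "provenance",
]


def write_csv(dataset: Dataset, path: str | Path, delimiter: str = ",") -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(CSV_COLUMNS)
        for r in dataset.records:
            writer.writerow([
                r.record_id, r.wt_id, r.wt_sequence,
                ";".join(str(m) for m in r.mutations),
                "" if r.ddg is None else repr(r.ddg),
                "" if r.dtm is None else repr(r.dtm),
                "" if r.label is None else r.label,
                r.direction, r.provenance,
            ])


def read_csv(path: str | Path, name: str | None = None,
             delimiter: str = ",") -> Dataset:
    path = Path(path)
    records: list[MutationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValidationError(f"{path}: missing columns {sorted(missing)}")
        for row in reader:
            records.append(MutationRecord(
                record_id=row["record_id"],
                wt_id=row["wt_id"],
                wt_sequence=row["wt_sequence"],
                mutations=parse_mutations(row["mutations"]),
                ddg=float(row["ddg"]) if row["ddg"] else None,
                dtm=float(row["dtm"]) if row["dtm"] else None,
                label=int(row["label"]) if row["label"] != "" else None,
                direction=row["direction"] or DIRECT,
                provenance=row["provenance"] or EXPERIMENTAL,
            ))
    return Dataset(records=records, name=name or path.stem)
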