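"""Mutation-type clustering and leakage-free train/test splitting.

Multiple-point mutation datasets are small and heterogeneous: generalization
depends on whether the *combinations of substitution types* (e.g. {L→A,
K→R}) seen at test time were represented during training.  The splitter
therefore:

1. encodes each record as a multi-hot vector over the vocabulary of
   observed (from_aa, to_aa) substitution types (positions deliberately
   ignored),
2. embeds the unique vectors to 2-D with t-SNE and clusters the embedding
   with DBSCAN, so train and test can be balanced per cluster, and
3. allocates whole wild-type proteins to the test partition, cluster by
   cluster, until each cluster's test quota (cluster size × test fraction)
   is met — never splitting one wild-type sequence across partitions, which
   would leak fold information between train and test.

Clusters owned by too few wild types may be unable to fill their quota
without gross overshoot; such shortfalls are reported, not hidden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import DBSCAN
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors

from .data_model import Dataset, MutationRecord, ValidationError

NOISE = -1
TRAIN = "train"
TEST = "test"


@dataclass(frozen=True)
class MutationTypeVocabulary:
    """Ordered vocabulary of (from_aa, to_aa) substitution types."""

    types: tuple[tuple[str, str], ...]

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "MutationTypeVocabulary":
        observed = {(m.from_aa, m.to_aa) for r in dataset for m in r.mutations}
        return cls(types=tuple(sorted(observed)))

    def __len__(self) -> int:
        return len(self.types)

    @property
    def index(self) -> dict[tuple[str, str], int]:
        return {t: i for i, t in enumerate(self.types)}


def encode_type_combination(
    record: MutationRecord, vocabulary: MutationTypeVocabulary
) -> np.ndarray:
    """Multi-hot vector marking the record's constituent substitution types."""
    index = vocabulary.index
    vec = np.zeros(len(vocabulary), dtype=np.float64)
    for mut in record.mutations:
        key = (mut.from_aa, mut.to_aa)
        if key not in index:
            raise ValidationError(f"mutation type {key} not in vocabulary")
        vec[index[key]] = 1.0
    return vec


@dataclass
class ClusterParams:
    """t-SNE + DBSCAN knobs; eps=None triggers the k-distance elbow rule."""

    perplexity: float = 30.0
    n_components: int = 2
    eps: float | None = None
    min_samples: int = 5


def _kdistance_elbow(embedding: np.ndarray, k: int) -> float:
    """DBSCAN eps from the sorted k-distance curve's point of max curvature."""
    k = min(k, len(embedding) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    dists, _ = nn.kneighbors(embedding)
    curve = np.sort(dists[:, -1])
    if len(curve) < 3:
        return float(max(curve[-1], 1e-8))
    second_diff = np.diff(curve, n=2)
    elbow = int(np.argmax(second_diff)) + 1
    return float(max(curve[elbow], 1e-8))


def cluster_types(
    vectors: np.ndarray,
    params: ClusterParams | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Cluster multi-hot type-combination vectors (one row per record).

    Unique vectors are embedded with seeded t-SNE and clustered with DBSCAN;
    labels are broadcast back to the records.  Degenerate input (a single
    unique combination) short-circuits to one cluster.  DBSCAN noise keeps
    the ``NOISE`` (-1) label.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or len(vectors) < 2:
        raise ValidationError("cluster_types needs >= 2 vectors")
    params = params or ClusterParams()

    uniq, inverse = np.unique(vectors, axis=0, return_inverse=True)
    if len(uniq) == 1:
        return np.zeros(len(vectors), dtype=int)

    perplexity = min(params.perplexity, max(1.0, (len(uniq) - 1) / 3.0))
    tsne = TSNE(
        n_components=params.n_components,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if len(uniq) > params.n_components else "random",
    )
    embedding = tsne.fit_transform(uniq)

    eps = params.eps
    if eps is None:
        eps = _kdistance_elbow(embedding, params.min_samples)
    labels_uniq = DBSCAN(
        eps=eps, min_samples=min(params.min_samples, len(uniq))
    ).fit_predict(embedding)
    return labels_uniq[inverse]


@dataclass
class SplitAssignment:
    """Per-record cluster id and train/test membership, plus the audit trail."""

    partition: dict[str, str]            # record_id -> train/test
    cluster_of: dict[str, int]           # record_id -> cluster label
    test_wildtypes: set[str] = field(default_factory=set)
    quotas: dict[int, int] = field(default_factory=dict)
    filled: dict[int, int] = field(default_factory=dict)
    seed: int = 0

    @property
    def shortfalls(self) -> dict[int, int]:
        """Per-cluster records still missing from test after allocation."""
        return {
            c: self.quotas[c] - self.filled.get(c, 0)
            for c in self.quotas
            if self.quotas[c] > self.filled.get(c, 0)
        }

    def subset(self, dataset: Dataset, which: str) -> Dataset:
        recs = [r for r in dataset if self.partition[r.record_id] == which]
        return Dataset(records=recs, name=f"{dataset.name}-{which}")

    def write(self, tsv_path: str | Path, manifest_path: str | Path,
              params: dict | None = None) -> None:
        with open(tsv_path, "w") as fh:
            fh.write("record_id\tpartition\n")
            for rid in sorted(self.partition):
                fh.write(f"{rid}\t{self.partition[rid]}\n")
        manifest = {
            "seed": self.seed,
            "params": params or {},
            "quotas": {str(k): v for k, v in self.quotas.items()},
            "filled": {str(k): v for k, v in self.filled.items()},
            "shortfalls": {str(k): v for k, v in self.shortfalls.items()},
            "n_test_wildtypes": len(self.test_wildtypes),
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def allocate_split(
    dataset: Dataset,
    cluster_labels: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> SplitAssignment:
    """Allocate whole wild types to test until per-cluster quotas are met.

    Per cluster the quota is round-half-up(cluster size × test_fraction).
    Candidate wild types are visited in seeded random order; a wild type is
    moved to test (all its records, across every cluster) only while the
    visiting cluster is still under quota, and clusters never overshoot by
    more than one wild type's worth of records.  When a cluster's remaining
    candidates would all overshoot grossly, the smallest-footprint candidate
    is preferred; if even that fails the cluster under-fills and the
    shortfall is reported.  Noise records (label −1) are routed to train.
    """
    if not 0 < test_fraction < 1:
        raise ValidationError("test_fraction must lie in (0, 1)")
    labels = np.asarray(cluster_labels)
    if len(labels) != len(dataset):
        raise ValidationError("cluster labels do not cover the dataset")

    rng = np.random.default_rng(seed)
    records = list(dataset.records)
    cluster_of = {r.record_id: int(c) for r, c in zip(records, labels)}

    clusters = sorted({int(c) for c in labels if c != NOISE})
    quota = {
        c: _round_half_up(int(np.sum(labels == c)) * test_fraction)
        for c in clusters
    }
    # wild type -> per-cluster record counts
    wt_counts: dict[str, dict[int, int]] = {}
    for rec, c in zip(records, labels):
        wt_counts.setdefault(rec.wt_sequence, {})[int(c)] = (
            wt_counts.setdefault(rec.wt_sequence, {}).get(int(c), 0) + 1
        )

    filled = {c: 0 for c in clusters}
    test_wts: set[str] = set()
    wt_total = {wt: sum(counts.values()) for wt, counts in wt_counts.items()}
    global_quota = _round_half_up(len(records) * test_fraction)
    global_filled = 0

    # Visit clusters largest-quota first so tight clusters are not starved
    # by wild types consumed elsewhere.  A global record quota caps the
    # overall test size (moved wild types drag along records outside the
    # visiting cluster, e.g. noise records, which no cluster quota counts).
    for c in sorted(clusters, key=lambda c: (-quota[c], c)):
        if quota[c] == 0:
            continue
        candidates = sorted(
            wt for wt, counts in wt_counts.items() if c in counts
        )
        order = [candidates[i] for i in rng.permutation(len(candidates))]
        while filled[c] < quota[c] and global_filled < global_quota:
            eligible = [wt for wt in order if wt not in test_wts]
            if not eligible:
                break
            remaining = quota[c] - filled[c]
            wt = eligible[0]
            contribution = wt_counts[wt].get(c, 0)
            if contribution > remaining:
                # tight endgame: fall back to the smallest-footprint wild
                # type, and accept it only if the overshoot stays within
                # one quota-remainder's worth — otherwise the cluster
                # under-fills and the shortfall is reported.
                wt = min(eligible, key=lambda w: (wt_counts[w].get(c, 0), w))
                contribution = wt_counts[wt].get(c, 0)
                if contribution > 2 * remaining:
                    break
            if global_filled + wt_total[wt] > global_quota + max(
                    wt_total[wt] - 1, 0) and global_filled > 0:
                break
            test_wts.add(wt)
            global_filled += wt_total[wt]
            for cc, n in wt_counts[wt].items():
                if cc in filled:
                    filled[cc] += n

    partition = {
        r.record_id: (TEST if r.wt_sequence in test_wts else TRAIN)
        for r in records
    }
    return SplitAssignment(
        partition=partition,
        cluster_of=cluster_of,
        test_wildtypes=test_wts,
        quotas=quota,
        filled=filled,
        seed=seed,
    )
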