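import numpy as np
import pytest

from gvpstab.data_model import Dataset, MutationRecord, PointMutation
from gvpstab.featurize import EncoderStack, build_graph
from gvpstab.synthetic import (
    gen_helix_backbone,
    gen_pssm,
    gen_residue_scores,
)


@pytest.fixture(scope="session")
def helix():
    """Jittered 14-residue ideal helix (jitter breaks k-NN distance ties)."""
    return gen_helix_backbone(14, seed=5, jitter=0.05)


@pytest.fixture(scope="session")
def helix_graph(helix):
    return build_graph(
        helix,
        EncoderStack(),
        k_neighbors=8,
        pssm=gen_pssm(helix.sequence, 1),
        residue_scores=gen_residue_scores(helix.sequence, 1),
    )


@pytest.fixture()
def two_variant_dataset():
    """One wild type with two measured variants (a thermodynamic loop)."""
    wt = "ACDEFGHIKL"
    a = MutationRecord("A", "wt1", wt, (PointMutation(1, "A", "M"),),
                       ddg=1.0, label=1)
    b = MutationRecord(
        "B", "wt1", wt,
        (PointMutation(1, "A", "M"), PointMutation(3, "D", "E")),
        ddg=-0.5, label=0)
    return Dataset(records=[a, b])


def make_records(n_wt: int, per_wt: int, seed: int = 0,
                 chain_length: int = 20) -> Dataset:
    """Equal-size wild types, one single-point mutation per record."""
    assert per_wt <= chain_length, "need distinct positions per wild type"
    rng = np.random.default_rng(seed)
    recs = []
    for w in range(n_wt):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                 size=chain_length))
        positions = rng.permutation(chain_length)[:per_wt]
        for v in range(per_wt):
            pos = int(positions[v])
            to = "W" if seq[pos] != "W" else "Y"
            ddg = float(rng.normal(0, 2)) or 0.1
            recs.append(MutationRecord(
                record_id=f"w{w}v{v}", wt_id=f"wt{w}", wt_sequence=seq,
                mutations=(PointMutation(pos + 1, seq[pos], to),),
                ddg=ddg, label=int(ddg > 0)))
    return Dataset(records=recs)
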