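"""The dual-graph stability classifier and its training harness.

Architecture: the wild-type and mutant protein graphs pass through a
*shared-weight* GVP-GNN encoder (input GVP embedding + a stack of
message-passing layers).  Jumping-knowledge aggregation concatenates each
layer's scalar node representations, which are mean-pooled per graph; the
two graph embeddings form a length-2 sequence fed to multi-head
self-attention (capturing the wild-type/mutant difference), and a final
affine + sigmoid head yields P(stabilizing).  The prediction is invariant
to rigid motions and reflections of both input structures and to
consistent node reindexing.

The public surface follows the Model/Results convention: build a
:class:`ThermostabilityModel` from graph pairs and labels, call
:meth:`~ThermostabilityModel.fit`, and read metrics off the returned
:class:`ThermostabilityResults`.  ``pretrain``/``finetune`` wrap this
surface with the two hyperparameter profiles (fine-tuning updates only the
GVP-GNN encoder parameters; attention and head stay frozen).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .autodiff import (
    Adam,
    Parameter,
    Tensor,
    binary_cross_entropy,
    concatenate,
    segment_mean,
    softmax,
)
from .data_model import ValidationError
from .featurize import ProteinGraph
from .gvp import GVP, GVPConvLayer
from . import evaluation

logger = logging.getLogger(__name__)

#: A (wild-type graph, mutant graph) input pair.
GraphPair = tuple[ProteinGraph, ProteinGraph]


@dataclass
class ModelConfig:
    """Architecture and optimizer hyperparameters.

    Defaults are the published training profile: 3 GVP-GNN layers with 2
    message GVPs and 4 feedforward GVPs, hidden scalar width 182, batch
    size 64; pretraining uses dropout 0.6, Adam lr 1e-4, weight decay
    1e-3; fine-tuning dropout 0.4, lr 1e-3, weight decay 1e-6.  The hidden
    vector width and attention head count are package choices exposed here.
    """

    n_gnn_layers: int = 3
    n_message_gvps: int = 2
    n_feedforward_gvps: int = 4
    hidden_dim: int = 182
    vector_dim: int = 16
    batch_size: int = 64
    dropout_pretrain: float = 0.6
    dropout_finetune: float = 0.4
    lr_pretrain: float = 1e-4
    lr_finetune: float = 1e-3
    weight_decay_pretrain: float = 1e-3
    weight_decay_finetune: float = 1e-6
    n_attention_heads: int = 4
    jk_mode: str = "concat"
    epochs: int = 100
    patience: int = 10
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_pretrain < 1 or not 0 <= self.dropout_finetune < 1:
            raise ValidationError("dropout must lie in [0, 1)")
        for name in ("n_gnn_layers", "n_message_gvps", "n_feedforward_gvps",
                     "hidden_dim", "vector_dim", "batch_size", "epochs",
                     "cv_folds"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")

    def profile(self, mode: str) -> tuple[float, float, float]:
        """(dropout, lr, weight_decay) for 'pretrain' or 'finetune'."""
        if mode == "pretrain":
            return (self.dropout_pretrain, self.lr_pretrain,
                    self.weight_decay_pretrain)
        if mode == "finetune":
            return (self.dropout_finetune, self.lr_finetune,
                    self.weight_decay_finetune)
        raise ValidationError(f"unknown training mode {mode!r}")


def _effective_heads(dim: int, requested: int) -> int:
    h = min(requested, dim)
    while dim % h:
        h -= 1
    return h


class DualGraphClassifier:
    """The network itself: shared GVP-GNN encoder + attention head."""

    def __init__(self, node_scalar_dim: int, edge_scalar_dim: int,
                 config: ModelConfig, rng: np.random.Generator | None = None):
        self.config = config
        self.node_in = (node_scalar_dim, 3)
        self.edge_in = (edge_scalar_dim, 1)
        rng = rng or np.random.default_rng(config.seed)
        sh, vh = config.hidden_dim, config.vector_dim

        self.embed = GVP(self.node_in, (sh, vh), rng)
        self.layers = [
            GVPConvLayer((sh, vh), self.edge_in, rng,
                         n_message=config.n_message_gvps,
                         n_feedforward=config.n_feedforward_gvps)
            for _ in range(config.n_gnn_layers)
        ]
        D = sh * config.n_gnn_layers if config.jk_mode == "concat" else sh
        self.attn_dim = D
        self.n_heads = _effective_heads(D, config.n_attention_heads)
        from .gvp import _glorot
        self.head_params: dict[str, Parameter] = {
            "attn.wq": Parameter(_glorot(rng, D, D)),
            "attn.wk": Parameter(_glorot(rng, D, D)),
            "attn.wv": Parameter(_glorot(rng, D, D)),
            "attn.wo": Parameter(_glorot(rng, D, D)),
            "head.w": Parameter(_glorot(rng, 1, 2 * D)),
            "head.b": Parameter(np.zeros(1)),
        }

    # -- parameters ---------------------------------------------------------
    def parameters(self) -> dict[str, Parameter]:
        out = self.embed.named_params("encoder.embed")
        for i, layer in enumerate(self.layers):
            out.update(layer.named_params(f"encoder.layer{i}"))
        out.update(self.head_params)
        return out

    def gvp_parameter_names(self) -> set[str]:
        """Names of the GVP-GNN encoder parameters (the fine-tunable set)."""
        return {k for k in self.parameters() if k.startswith("encoder.")}

    # -- forward ------------------------------------------------------------
    def _encode_nodes(self, graphs: list[ProteinGraph],
                      rng: np.random.Generator | None, training: bool,
                      drop_rate: float) -> Tensor:
        """Run the shared encoder over a disjoint union of graphs; returns
        per-graph jumping-knowledge embeddings, shape (len(graphs), D)."""
        sig = {g.stack_signature for g in graphs}
        if len(sig) > 1:
            raise ValidationError(
                f"graphs built with different encoder stacks: {sorted(sig)}"
            )
        offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
        node_s = Tensor(np.concatenate([g.node_scalar for g in graphs]))
        node_v = Tensor(np.concatenate([g.node_vector for g in graphs]))
        edge_index = np.concatenate(
            [g.edge_index + off for g, off in zip(graphs, offsets[:-1])],
            axis=1,
        )
        edge_s = Tensor(np.concatenate([g.edge_scalar for g in graphs]))
        edge_v = Tensor(np.concatenate([g.edge_vector for g in graphs]))
        graph_ids = np.concatenate(
            [np.full(g.n_nodes, i) for i, g in enumerate(graphs)]
        )

        for layer in self.layers:
            layer.drop_rate = drop_rate
        s, V = self.embed(node_s, node_v)
        jk: list[Tensor] = []
        for layer in self.layers:
            s, V = layer(s, V, edge_index, edge_s, edge_v,
                         rng=rng, training=training)
            jk.append(s)
        if self.config.jk_mode == "concat":
            node_repr = concatenate(jk, axis=-1)
        else:
            node_repr = jk[-1]
        return segment_mean(node_repr, graph_ids, len(graphs))

    def forward(self, pairs: list[GraphPair],
                rng: np.random.Generator | None = None,
                training: bool = False, drop_rate: float = 0.0) -> Tensor:
        """Predicted probabilities of the stabilizing class, shape (B,)."""
        if not pairs:
            raise ValidationError("empty batch")
        graphs: list[ProteinGraph] = []
        for wt, mut in pairs:
            graphs.extend((wt, mut))
        emb = self._encode_nodes(graphs, rng, training, drop_rate)
        B, D = len(pairs), self.attn_dim
        X = emb.reshape(B, 2, D)

        h, dh = self.n_heads, D // self.n_heads
        p = self.head_params

        def split_heads(t: Tensor) -> Tensor:
            return t.reshape(B, 2, h, dh).swapaxes(1, 2)   # (B, h, 2, dh)

        Q = split_heads(X @ p["attn.wq"].swapaxes(0, 1))
        K = split_heads(X @ p["attn.wk"].swapaxes(0, 1))
        Vv = split_heads(X @ p["attn.wv"].swapaxes(0, 1))
        scores = (Q @ K.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn_out = softmax(scores, axis=-1) @ Vv            # (B, h, 2, dh)
        attn_out = attn_out.swapaxes(1, 2).reshape(B, 2, D)
        X = X + attn_out @ p["attn.wo"].swapaxes(0, 1)      # residual

        flat = X.reshape(B, 2 * D)
        logits = flat @ p["head.w"].swapaxes(0, 1) + p["head.b"]
        return logits.sigmoid().reshape(B)

    def predict_proba(self, pairs: list[GraphPair]) -> np.ndarray:
        return self.forward(pairs, training=False).data

    # -- checkpointing -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        arrays = {k.replace(".", "__"): p.data
                  for k, p in self.parameters().items()}
        np.savez(
            path,
            config_json=np.array(json.dumps({
                "config": asdict(self.config),
                "node_scalar_dim": self.node_in[0],
                "edge_scalar_dim": self.edge_in[0],
            })),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "DualGraphClassifier":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["config_json"]))
            net = cls(meta["node_scalar_dim"], meta["edge_scalar_dim"],
                      ModelConfig(**meta["config"]))
            params = net.parameters()
            for k, p in params.items():
                key = k.replace(".", "__")
                if key not in z:
                    raise ValidationError(f"checkpoint missing parameter {k}")
                if z[key].shape != p.data.shape:
                    raise ValidationError(
                        f"checkpoint shape mismatch for {k}: "
                        f"{z[key].shape} vs {p.data.shape}"
                    )
                p.data = z[key].copy()
        return net

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(state) != set(params):
            raise ValidationError("architecture mismatch with checkpoint")
        for k, p in params.items():
            if state[k].shape != p.data.shape:
                raise ValidationError(f"shape mismatch for {k}")
            p.data = state[k].copy()


# ---------------------------------------------------------------------------
# Model / Results surface

@dataclass
class FoldReport:
    fold: int
    n_train: int
    n_val: int
    metrics: dict[str, float | None]
    skipped: bool = False
    reason: str = ""


@dataclass
class ThermostabilityResults:
    """Fitted-model container: network, CV reports, training history."""

    network: DualGraphClassifier
    fold_reports: list[FoldReport]
    history: list[dict]
    mode: str
    seed: int

    def predict_proba(self, pairs: list[GraphPair]) -> np.ndarray:
        return self.network.predict_proba(pairs)

    def predict(self, pairs: list[GraphPair],
                threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(pairs) >= threshold).astype(int)

    def cv_summary(self) -> dict[str, tuple[float, float]]:
        """mean ± sd of each metric over non-skipped folds."""
        out: dict[str, tuple[float, float]] = {}
        live = [f for f in self.fold_reports if not f.skipped]
        for key in ("accuracy", "precision", "recall", "auc"):
            vals = [f.metrics[key] for f in live
                    if f.metrics.get(key) is not None]
            if vals:
                out[key] = (float(np.mean(vals)), float(np.std(vals)))
        return out

    def summary(self) -> str:
        lines = [
            f"Thermostability classifier ({self.mode}, seed={self.seed})",
            f"  parameters: "
            f"{sum(p.data.size for p in self.network.parameters().values())}",
            f"  epochs run: {len(self.history)}",
            "  cross-validation (mean +/- sd over folds):",
        ]
        for key, (mu, sd) in self.cv_summary().items():
            lines.append(f"    {key:<10s} {mu:.3f} +/- {sd:.3f}")
        for rep in self.fold_reports:
            if rep.skipped:
                lines.append(f"    fold {rep.fold}: skipped ({rep.reason})")
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        self.network.save(path)


class ThermostabilityModel:
    """Model object: graph pairs + labels + config, fitted via :meth:`fit`."""

    def __init__(self, pairs: list[GraphPair], labels,
                 config: ModelConfig | None = None):
        labels = np.asarray(labels, dtype=int)
        if len(pairs) != len(labels):
            raise ValidationError("pairs and labels differ in length")
        if len(pairs) == 0:
            raise ValidationError("no training data")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValidationError("labels must be 0/1")
        self.pairs = list(pairs)
        self.labels = labels
        self.config = config or ModelConfig()

    @classmethod
    def from_arrays(cls, wt_graphs, mut_graphs, labels, config=None):
        return cls(list(zip(wt_graphs, mut_graphs)), labels, config)

    # -- training loop -------------------------------------------------------
    def _train_network(self, net: DualGraphClassifier, idx: np.ndarray,
                       mode: str, seed: int,
                       trainable: set[str] | None = None,
                       epochs: int | None = None) -> list[dict]:
        drop, lr, wd = self.config.profile(mode)
        params = net.parameters()
        if trainable is not None:
            params = {k: p for k, p in params.items() if k in trainable}
        opt = Adam(params, lr=lr, weight_decay=wd)
        rng = np.random.default_rng(seed)
        n_epochs = epochs if epochs is not None else self.config.epochs
        history: list[dict] = []
        best = np.inf
        stale = 0
        for epoch in range(n_epochs):
            order = rng.permutation(idx)
            losses = []
            for lo in range(0, len(order), self.config.batch_size):
                batch = order[lo:lo + self.config.batch_size]
                probs = net.forward(
                    [self.pairs[i] for i in batch],
                    rng=rng, training=True, drop_rate=drop,
                )
                loss = binary_cross_entropy(probs, self.labels[batch])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            epoch_loss = float(np.mean(losses))
            history.append({"epoch": epoch, "loss": epoch_loss})
            if epoch_loss < best - 1e-6:
                best, stale = epoch_loss, 0
            else:
                stale += 1
                if self.config.patience and stale >= self.config.patience:
                    break
        return history

    def _evaluate(self, net: DualGraphClassifier,
                  idx: np.ndarray) -> dict[str, float | None]:
        probs = net.predict_proba([self.pairs[i] for i in idx])
        report = evaluation.compute_metrics(self.labels[idx], probs)
        return {"accuracy": report.accuracy, "precision": report.precision,
                "recall": report.recall, "auc": report.auc}

    def fit(self, mode: str = "pretrain", seed: int | None = None,
            init_state: dict[str, np.ndarray] | None = None,
            trainable: set[str] | None = None,
            run_cv: bool = True) -> ThermostabilityResults:
        """Cross-validate, then train a final network on all records.

        ``mode`` selects the hyperparameter profile.  ``init_state`` warm
        starts from a checkpointed parameter set; ``trainable`` restricts
        updates to the named parameters (used by fine-tuning).  K-fold
        assignments and all initialization are derived from ``seed``.
        """
        seed = self.config.seed if seed is None else seed
        dims = self._dims()
        fold_reports: list[FoldReport] = []
        if run_cv:
            from sklearn.model_selection import KFold
            kf = KFold(n_splits=min(self.config.cv_folds, len(self.pairs)),
                       shuffle=True, random_state=seed)
            for fold, (tr, va) in enumerate(kf.split(self.pairs)):
                if len(np.unique(self.labels[tr])) < 2:
                    fold_reports.append(FoldReport(
                        fold, len(tr), len(va), {}, skipped=True,
                        reason="single-class training fold"))
                    continue
                net = self._fresh_network(dims, seed + 1000 + fold,
                                          init_state, mode)
                self._train_network(net, tr, mode, seed + 2000 + fold,
                                    trainable=trainable)
                fold_reports.append(FoldReport(
                    fold, len(tr), len(va), self._evaluate(net, va)))

        net = self._fresh_network(dims, seed, init_state, mode)
        history = self._train_network(
            net, np.arange(len(self.pairs)), mode, seed + 1,
            trainable=trainable)
        return ThermostabilityResults(
            network=net, fold_reports=fold_reports, history=history,
            mode=mode, seed=seed)

    def _dims(self) -> tuple[int, int]:
        g = self.pairs[0][0]
        return g.node_scalar.shape[1], g.edge_scalar.shape[1]

    def _fresh_network(self, dims, seed, init_state, mode):
        net = DualGraphClassifier(
            dims[0], dims[1], replace(self.config, seed=seed),
            rng=np.random.default_rng(seed))
        if init_state is not None:
            net.load_state_dict(init_state)
        return net


def pretrain(pairs: list[GraphPair], labels,
             config: ModelConfig | None = None,
             seed: int = 0) -> ThermostabilityResults:
    """Train from scratch with the pretraining profile + 5-fold CV report."""
    model = ThermostabilityModel(pairs, labels, config)
    return model.fit(mode="pretrain", seed=seed)


def finetune(pretrained: DualGraphClassifier | ThermostabilityResults,
             pairs: list[GraphPair], labels,
             config: ModelConfig | None = None, seed: int = 0,
             full: bool = False) -> ThermostabilityResults:
    """Fine-tune a pretrained checkpoint on new (multiple-point) data.

    Only the GVP-GNN encoder parameters are updated; the attention and
    output head stay frozen (``full=True`` unfreezes everything).
    """
    net = pretrained.network if isinstance(pretrained, ThermostabilityResults) \
        else pretrained
    config = config or net.config
    model = ThermostabilityModel(pairs, labels, config)
    trainable = None if full else net.gvp_parameter_names()
    return model.fit(mode="finetune", seed=seed,
                     init_state=net.state_dict(), trainable=trainable)
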