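"""Geometric vector perceptron layers and message passing.

A GVP jointly transforms a *tuple* (s, V) of per-node scalar features
s ∈ R^{si} and stacked 3-vector features V ∈ R^{vi×3}.  Vector channels
are mixed only by learned linear combinations and gated by functions of
rotation-invariant quantities (vector norms and scalars), so the scalar
output is invariant and the vector output equivariant under any orthogonal
transform of the input vectors — the property the whole architecture
inherits.

The message-passing layer follows the GVP-GNN pattern: a chain of GVPs
over the concatenated (source node, edge, destination node) tuple forms
the message, messages are mean-aggregated over incoming edges, added
residually with dropout and tuple normalization, and a second GVP chain
provides the feedforward update.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    Parameter,
    Tensor,
    concatenate,
    dropout,
    segment_mean,
    vecmat,
    vector_norm,
)
from .data_model import ValidationError


def _glorot(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


class GVP:
    """One geometric vector perceptron: (si, vi) -> (so, vo).

    ``activations=(True, True)`` applies ReLU on the scalar path and a
    sigmoid vector gate driven by the scalar path; disable for the final
    layer of a chain.  The hidden vector width defaults to max(vi, vo).
    """

    def __init__(self, in_dims: tuple[int, int], out_dims: tuple[int, int],
                 rng: np.random.Generator,
                 activations: tuple[bool, bool] = (True, True)):
        self.si, self.vi = in_dims
        self.so, self.vo = out_dims
        self.scalar_act, self.vector_gate = activations
        self.h = max(self.vi, self.vo)
        self.params: dict[str, Parameter] = {}
        if self.vi > 0:
            self.params["wh"] = Parameter(_glorot(rng, self.h, self.vi))
        s_in = self.si + (self.h if self.vi > 0 else 0)
        self.params["ws"] = Parameter(_glorot(rng, self.so, s_in))
        self.params["bs"] = Parameter(np.zeros(self.so))
        if self.vo > 0:
            if self.vi == 0:
                raise ValidationError("cannot emit vectors from a vector-free input")
            self.params["wv"] = Parameter(_glorot(rng, self.vo, self.h))
            if self.vector_gate:
                self.params["wg"] = Parameter(_glorot(rng, self.vo, self.so))
                self.params["bg"] = Parameter(np.zeros(self.vo))

    def __call__(self, s: Tensor, V: Tensor | None) -> tuple[Tensor, Tensor | None]:
        if s.shape[-1] != self.si:
            raise ValidationError(
                f"scalar width mismatch: expected {self.si}, got {s.shape[-1]}"
            )
        if self.vi > 0:
            if V is None or V.shape[-2] != self.vi:
                got = None if V is None else V.shape[-2]
                raise ValidationError(
                    f"vector width mismatch: expected {self.vi}, got {got}"
                )
            Vh = vecmat(self.params["wh"], V)
            s_in = concatenate([s, vector_norm(Vh)], axis=-1)
        else:
            Vh = None
            s_in = s
        s_lin = s_in @ self.params["ws"].swapaxes(0, 1) + self.params["bs"]
        s_out = s_lin.relu() if self.scalar_act else s_lin
        V_out = None
        if self.vo > 0:
            Vu = vecmat(self.params["wv"], Vh)
            if self.vector_gate:
                gate = (s_lin @ self.params["wg"].swapaxes(0, 1)
                        + self.params["bg"]).sigmoid()
                V_out = Vu * gate.reshape(*gate.shape, 1)
            else:
                V_out = Vu
        return s_out, V_out

    def named_params(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.{k}": p for k, p in self.params.items()}


class GVPChain:
    """A sequential chain of GVPs; the last one runs without activations."""

    def __init__(self, n: int, in_dims, out_dims, rng,
                 final_activations: tuple[bool, bool] = (False, False)):
        self.layers: list[GVP] = []
        for i in range(n):
            dims_in = in_dims if i == 0 else out_dims
            act = final_activations if i == n - 1 else (True, True)
            self.layers.append(GVP(dims_in, out_dims, rng, activations=act))

    def __call__(self, s, V):
        for layer in self.layers:
            s, V = layer(s, V)
        return s, V

    def named_params(self, prefix: str) -> dict[str, Parameter]:
        out = {}
        for i, layer in enumerate(self.layers):
            out.update(layer.named_params(f"{prefix}.gvp{i}"))
        return out


class TupleLayerNorm:
    """Normalizes the tuple: LayerNorm on scalars, RMS norm on vectors."""

    def __init__(self, s_dim: int):
        self.params = {
            "gamma": Parameter(np.ones(s_dim)),
            "beta": Parameter(np.zeros(s_dim)),
        }

    def __call__(self, s: Tensor, V: Tensor | None, eps: float = 1e-6):
        mu = s.mean(axis=-1, keepdims=True)
        var = ((s - mu) * (s - mu)).mean(axis=-1, keepdims=True)
        s_out = (s - mu) / (var + eps).sqrt() * self.params["gamma"] \
            + self.params["beta"]
        if V is not None:
            sq = vector_norm(V).pow_const(2.0).mean(axis=-1, keepdims=True)
            V_out = V / (sq + eps).sqrt().reshape(*sq.shape, 1)
        else:
            V_out = None
        return s_out, V_out

    def named_params(self, prefix: str) -> dict[str, Parameter]:
        return {f"{prefix}.{k}": p for k, p in self.params.items()}


class GVPConvLayer:
    """One GVP-GNN layer: message passing + residual feedforward."""

    def __init__(self, node_dims: tuple[int, int], edge_dims: tuple[int, int],
                 rng: np.random.Generator, n_message: int = 2,
                 n_feedforward: int = 4, drop_rate: float = 0.0):
        si, vi = node_dims
        se, ve = edge_dims
        self.node_dims = node_dims
        self.drop_rate = drop_rate
        self.message = GVPChain(
            n_message, (2 * si + se, 2 * vi + ve), node_dims, rng)
        self.ff = GVPChain(n_feedforward, node_dims, node_dims, rng)
        self.norm1 = TupleLayerNorm(si)
        self.norm2 = TupleLayerNorm(si)

    def __call__(self, s: Tensor, V: Tensor, edge_index: np.ndarray,
                 edge_s: Tensor, edge_v: Tensor,
                 rng: np.random.Generator | None = None,
                 training: bool = False):
        n_nodes = s.shape[0]
        if edge_index.size and edge_index.max() >= n_nodes:
            raise ValidationError("edge index refers to a nonexistent node")
        src, dst = edge_index[0], edge_index[1]

        if len(src) > 0:
            ms = concatenate([s.take_rows(src), edge_s, s.take_rows(dst)],
                             axis=-1)
            mv = concatenate([V.take_rows(src), edge_v, V.take_rows(dst)],
                             axis=-2)
            ms, mv = self.message(ms, mv)
            agg_s = segment_mean(ms, dst, n_nodes)
            agg_v = segment_mean(mv, dst, n_nodes)
            s = s + self._drop(agg_s, rng, training)
            V = V + self._drop(agg_v, rng, training)
        s, V = self.norm1(s, V)

        fs, fv = self.ff(s, V)
        s = s + self._drop(fs, rng, training)
        V = V + self._drop(fv, rng, training)
        s, V = self.norm2(s, V)
        return s, V

    def _drop(self, t: Tensor, rng, training: bool) -> Tensor:
        if not training or self.drop_rate <= 0 or rng is None:
            return t
        return dropout(t, self.drop_rate, rng, training=True)

    def named_params(self, prefix: str) -> dict[str, Parameter]:
        out = {}
        out.update(self.message.named_params(f"{prefix}.message"))
        out.update(self.ff.named_params(f"{prefix}.ff"))
        out.update(self.norm1.named_params(f"{prefix}.norm1"))
        out.update(self.norm2.named_params(f"{prefix}.norm2"))
        return out
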