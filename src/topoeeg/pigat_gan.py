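"""The forecasting model: graph-attention generator, FC discriminator.

Generator pipeline for one persistence image PI_t (R x R):

    pixels-as-nodes grid graph
      -> GAT layer 1, K = 8 heads (head-averaged aggregation)
      -> GAT layer 2, single head, back to one feature per node
      -> row-major flatten to an (R^2, 1) scalar sequence
      -> LSTM over the R^2 steps, hidden size 5, last hidden state kept
      -> fully connected 5 -> R^2 + sigmoid
      -> reshape to R x R: the predicted PI_{t+1}, all pixels in [0, 1]

Attention follows the additive scheme: e_ij = a(W h_i, W h_j) for every
neighbour j of i (self-loops included), a_ij = softmax_j(LeakyReLU(e_ij)),
and the node update averages the K heads:
h'_i = sigma((1/K) sum_k sum_{j in N_i} a^k_ij W^k h_j).

The discriminator is two fully connected layers over the flattened image
with a final sigmoid, Y_d = Sigmoid(W_d . V_d + b_d).

Everything is NumPy with hand-derived backpropagation; a finite-difference
check over every parameter family is part of the test suite.  All
initialization and dropout randomness comes from explicitly passed
generators, so forward and training passes are reproducible bit-for-bit.
"""

from __future__ import annotations

import numpy as np

from .pi_graph import PIGraph, grid_graph

__all__ = [
    "GATLayer",
    "LSTM",
    "Dense",
    "Generator",
    "GatOnlyGenerator",
    "LstmOnlyGenerator",
    "Discriminator",
    "RMSProp",
    "Adam",
    "sigmoid",
    "bce_loss",
    "bce_grad_logits",
    "attention_scores",
]


# ---------------------------------------------------------------------------
# Elementary functions
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _elu(x):
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(x))


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


def bce_loss(p: np.ndarray, target: np.ndarray, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy between probabilities and targets."""
    p = np.clip(p, eps, 1.0 - eps)
    return float(np.mean(-target * np.log(p) - (1.0 - target) * np.log(1.0 - p)))


def bce_grad_logits(p: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Gradient of mean BCE with respect to the pre-sigmoid logits."""
    return (p - target) / p.size


def _glorot(rng: np.random.Generator, shape) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


# ---------------------------------------------------------------------------
# Graph attention layer
# ---------------------------------------------------------------------------

class GATLayer:
    """Multi-head graph attention with head-averaged aggregation.

    Parameters: per head k a weight matrix W^k (f_in x f_out) and an
    attention vector split into its destination and source halves (the
    additive logit is a_dst . W h_i + a_src . W h_j).  LeakyReLU slope 0.2.
    """

    def __init__(self, f_in: int, f_out: int, n_heads: int,
                 activation: str = "elu", leaky_slope: float = 0.2,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.f_in, self.f_out, self.n_heads = f_in, f_out, n_heads
        self.leaky_slope = leaky_slope
        self.act, self.act_grad = _ACTIVATIONS[activation]
        self.params = {
            "W": _glorot(rng, (n_heads, f_in, f_out)),
            "a_src": _glorot(rng, (n_heads, f_out)) .reshape(n_heads, f_out),
            "a_dst": _glorot(rng, (n_heads, f_out)).reshape(n_heads, f_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    # -- segment helpers ---------------------------------------------------

    @staticmethod
    def _seg_softmax(logits: np.ndarray, seg_ptr: np.ndarray,
                     dst: np.ndarray) -> np.ndarray:
        """Softmax over contiguous destination segments of the edge axis."""
        starts = seg_ptr[:-1]
        m = np.maximum.reduceat(logits, starts, axis=-1)
        ex = np.exp(logits - m[..., dst])
        s = np.add.reduceat(ex, starts, axis=-1)
        return ex / s[..., dst]

    def attention(self, graph: PIGraph, h: np.ndarray,
                  return_parts: bool = False):
        """Edgewise attention coefficients a_ij for input features h.

        h: (B, N, f_in).  Returns alpha of shape (B, K, E); with
        return_parts also the transformed features z (B, K, N, f_out) and
        raw logits e (B, K, E).
        """
        W, a_src, a_dst = (self.params[k] for k in ("W", "a_src", "a_dst"))
        z = np.einsum("bnf,kfo->bkno", h, W)
        s_src = np.einsum("bkno,ko->bkn", z, a_src)
        s_dst = np.einsum("bkno,ko->bkn", z, a_dst)
        e = s_src[:, :, graph.src] + s_dst[:, :, graph.dst]
        lrelu = np.where(e > 0, e, self.leaky_slope * e)
        alpha = self._seg_softmax(lrelu, graph.seg_ptr, graph.dst)
        if return_parts:
            return alpha, z, e
        return alpha

    # -- forward / backward ------------------------------------------------

    def forward(self, graph: PIGraph, h: np.ndarray, training: bool = False,
                dropout: float = 0.0,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """h: (B, N, f_in) -> (B, N, f_out)."""
        feat_mask = None
        if training and dropout > 0.0:
            if rng is None:
                raise ValueError("dropout requires an rng")
            feat_mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
            h = h * feat_mask
        alpha, z, e = self.attention(graph, h, return_parts=True)
        attn_mask = None
        alpha_used = alpha
        if training and dropout > 0.0:
            attn_mask = (rng.random(alpha.shape) >= dropout) / (1.0 - dropout)
            alpha_used = alpha * attn_mask
        msg = alpha_used[..., None] * z[:, :, graph.src, :]
        agg = np.add.reduceat(msg, graph.seg_ptr[:-1], axis=2)
        pre = agg.mean(axis=1)
        out = self.act(pre)
        self._cache = (graph, h, z, e, alpha, attn_mask, feat_mask, pre)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        graph, h, z, e, alpha, attn_mask, feat_mask, pre = self._cache
        W, a_src, a_dst = (self.params[k] for k in ("W", "a_src", "a_dst"))
        K = self.n_heads
        src, dst = graph.src, graph.dst
        starts = graph.seg_ptr[:-1]
        src_order, src_starts = graph.src_order, graph.src_seg_ptr[:-1]

        dpre = dout * self.act_grad(pre)                    # (B,N,Fo)
        dagg_e = np.take(dpre, dst, axis=1)[:, None] / K    # (B,1,E,Fo)
        alpha_used = alpha if attn_mask is None else alpha * attn_mask
        z_src = np.take(z, src, axis=2)                     # (B,K,E,Fo)
        dalpha = np.einsum("bxef,bkef->bke", dagg_e, z_src)
        # scatter dmsg into dz by source, via the source-sorted permutation
        dmsg = dagg_e * alpha_used[..., None]
        dz = np.add.reduceat(np.take(dmsg, src_order, axis=2),
                             src_starts, axis=2)
        if attn_mask is not None:
            dalpha *= attn_mask
        # softmax (per destination segment) backward
        inner = np.add.reduceat(dalpha * alpha, starts, axis=-1)
        de = alpha * (dalpha - inner[..., dst])
        de *= np.where(e > 0, 1.0, self.leaky_slope)
        # e = s_src[src] + s_dst[dst]
        ds_src = np.add.reduceat(np.take(de, src_order, axis=2),
                                 src_starts, axis=-1)
        ds_dst = np.add.reduceat(de, starts, axis=-1)
        dz += ds_src[..., None] * a_src[None, :, None, :]
        dz += ds_dst[..., None] * a_dst[None, :, None, :]
        self.grads["a_src"] += np.einsum("bkno,bkn->ko", z, ds_src)
        self.grads["a_dst"] += np.einsum("bkno,bkn->ko", z, ds_dst)
        self.grads["W"] += np.einsum("bnf,bkno->kfo", h, dz)
        dh = np.einsum("bkno,kfo->bnf", dz, W)
        if feat_mask is not None:
            dh = dh * feat_mask
        return dh

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


def attention_scores(graph: PIGraph, layer: GATLayer, h: np.ndarray,
                     head: int = 0):
    """Edgewise (e_ij, a_ij) for one head; h is (N, f_in) for one image."""
    alpha, _, e = layer.attention(graph, h[None], return_parts=True)
    return e[0, head], alpha[0, head]


# ---------------------------------------------------------------------------
# LSTM over the flattened pixel sequence
# ---------------------------------------------------------------------------

class LSTM:
    """Standard LSTM (input, forget, output gates + candidate cell).

    Runs over the step axis of an (B, T, input_size) array and exposes the
    last hidden state.  Gate order in the stacked weights: i, f, g, o.
    """

    def __init__(self, input_size: int, hidden_size: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.input_size, self.hidden_size = input_size, hidden_size
        H = hidden_size
        self.params = {
            "Wx": _glorot(rng, (input_size, 4 * H)),
            "Wh": _glorot(rng, (H, 4 * H)),
            "b": np.zeros(4 * H),
        }
        # Forget-gate bias starts at 1 so early training does not erase the cell.
        self.params["b"][H:2 * H] = 1.0
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, input_size) -> last hidden state (B, H)."""
        B, T, _ = x.shape
        H = self.hidden_size
        Wx, Wh, b = (self.params[k] for k in ("Wx", "Wh", "b"))
        hs = np.zeros((T + 1, B, H))
        cs = np.zeros((T + 1, B, H))
        gates = np.zeros((T, B, 4 * H))
        tanh_c = np.zeros((T, B, H))
        for t in range(T):
            a = x[:, t] @ Wx + hs[t] @ Wh + b
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = sigmoid(a[:, 3 * H:])
            cs[t + 1] = f * cs[t] + i * g
            tanh_c[t] = np.tanh(cs[t + 1])
            hs[t + 1] = o * tanh_c[t]
            gates[t] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates, tanh_c)
        return hs[T]

    def backward(self, dh_last: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, tanh_c = self._cache
        T, B, H = gates.shape[0], x.shape[0], self.hidden_size
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dx = np.zeros_like(x)
        dh = dh_last.copy()
        dc = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (gates[t][:, k * H:(k + 1) * H] for k in range(4))
            do = dh * tanh_c[t]
            dc = dc + dh * o * (1.0 - tanh_c[t] ** 2)
            di, df, dg = dc * g, dc * cs[t], dc * i
            da = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g ** 2), do * o * (1 - o),
            ], axis=1)
            self.grads["Wx"] += x[:, t].T @ da
            self.grads["Wh"] += hs[t].T @ da
            self.grads["b"] += da.sum(axis=0)
            dx[:, t] = da @ Wx.T
            dh = da @ Wh.T
            dc = dc * f
        return dx

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class Dense:
    """Affine layer y = x W + b."""

    def __init__(self, f_in: int, f_out: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.params = {"W": _glorot(rng, (f_in, f_out)), "b": np.zeros(f_out)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dy
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"].T

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

class _Model:
    """Shared parameter bookkeeping over named sub-layers."""

    _layers: dict

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v for name, layer in self._layers.items()
                for k, v in layer.params.items()}

    @property
    def grads(self) -> dict[str, np.ndarray]:
        return {f"{name}.{k}": v for name, layer in self._layers.items()
                for k, v in layer.grads.items()}

    def zero_grads(self) -> None:
        for layer in self._layers.values():
            for g in layer.grads.values():
                g[...] = 0.0

    def set_param(self, key: str, value: np.ndarray) -> None:
        name, k = key.split(".", 1)
        self._layers[name].params[k][...] = value

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = self.params
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise ValueError(f"parameter name mismatch: {sorted(missing)}")
        for k, v in state.items():
            if own[k].shape != np.asarray(v).shape:
                raise ValueError(f"shape mismatch for {k}")
            self.set_param(k, np.asarray(v, dtype=float))


def _as_batch(images: np.ndarray, resolution: int) -> np.ndarray:
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1:] != (resolution, resolution):
        raise ValueError(
            f"expected images of shape (B, {resolution}, {resolution}), "
            f"got {arr.shape}")
    return arr


class Generator(_Model):
    """Full generator: GAT(8 heads) -> GAT(1 head) -> LSTM -> FC sigmoid."""

    variant = "full"

    def __init__(self, resolution: int = 100, gat_hidden: int = 8,
                 gat1_heads: int = 8, lstm_hidden: int = 5,
                 dropout: float = 0.6, neighborhood: int = 8,
                 activation: str = "elu", seed: int = 0):
        self.resolution = resolution
        self.dropout = dropout
        n = resolution * resolution
        src, dst, seg_ptr = grid_graph(resolution, resolution, neighborhood)
        self.graph = PIGraph(np.zeros((n, 1)), src, dst, seg_ptr,
                             (resolution, resolution))
        rng = np.random.default_rng(seed)
        self.gat1 = GATLayer(1, gat_hidden, gat1_heads, activation, rng=rng)
        self.gat2 = GATLayer(gat_hidden, 1, 1, activation, rng=rng)
        self.lstm = LSTM(1, lstm_hidden, rng=rng)
        self.fc = Dense(lstm_hidden, n, rng=rng)
        self._layers = {"gat1": self.gat1, "gat2": self.gat2,
                        "lstm": self.lstm, "fc": self.fc}

    def forward(self, images: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        x = _as_batch(images, self.resolution)
        B = x.shape[0]
        n = self.resolution * self.resolution
        h = x.reshape(B, n, 1)
        h = self.gat1.forward(self.graph, h, training, self.dropout, rng)
        h = self.gat2.forward(self.graph, h)
        seq = h.reshape(B, n, 1)
        h_last = self.lstm.forward(seq)
        logits = self.fc.forward(h_last)
        return sigmoid(logits).reshape(B, self.resolution, self.resolution)

    def backward(self, dlogits: np.ndarray) -> None:
        """dlogits: (B, R*R) gradient at the pre-sigmoid output."""
        dh_last = self.fc.backward(dlogits)
        dseq = self.lstm.backward(dh_last)
        dh = self.gat2.backward(dseq.reshape(dseq.shape[0], -1, 1))
        self.gat1.backward(dh)


class GatOnlyGenerator(_Model):
    """Ablation: GAT stack -> shared per-node affine map -> sigmoid."""

    variant = "gat_only"

    def __init__(self, resolution: int = 100, gat_hidden: int = 8,
                 gat1_heads: int = 8, dropout: float = 0.6,
                 neighborhood: int = 8, activation: str = "elu", seed: int = 0):
        self.resolution = resolution
        self.dropout = dropout
        n = resolution * resolution
        src, dst, seg_ptr = grid_graph(resolution, resolution, neighborhood)
        self.graph = PIGraph(np.zeros((n, 1)), src, dst, seg_ptr,
                             (resolution, resolution))
        rng = np.random.default_rng(seed)
        self.gat1 = GATLayer(1, gat_hidden, gat1_heads, activation, rng=rng)
        self.gat2 = GATLayer(gat_hidden, 1, 1, activation, rng=rng)
        self.head = Dense(1, 1, rng=rng)  # shared across nodes
        self._layers = {"gat1": self.gat1, "gat2": self.gat2, "head": self.head}

    def forward(self, images, training=False, rng=None):
        x = _as_batch(images, self.resolution)
        B = x.shape[0]
        n = self.resolution * self.resolution
        h = x.reshape(B, n, 1)
        h = self.gat1.forward(self.graph, h, training, self.dropout, rng)
        h = self.gat2.forward(self.graph, h)
        logits = self.head.forward(h.reshape(B * n, 1)).reshape(B, n)
        return sigmoid(logits).reshape(B, self.resolution, self.resolution)

    def backward(self, dlogits):
        B = dlogits.shape[0]
        n = self.resolution * self.resolution
        dh = self.head.backward(dlogits.reshape(B * n, 1)).reshape(B, n, 1)
        dh = self.gat2.backward(dh)
        self.gat1.backward(dh)


class LstmOnlyGenerator(_Model):
    """Ablation: flatten -> LSTM -> FC sigmoid (no graph attention)."""

    variant = "lstm_only"

    def __init__(self, resolution: int = 100, lstm_hidden: int = 5,
                 seed: int = 0, **_ignored):
        self.resolution = resolution
        n = resolution * resolution
        rng = np.random.default_rng(seed)
        self.lstm = LSTM(1, lstm_hidden, rng=rng)
        self.fc = Dense(lstm_hidden, n, rng=rng)
        self._layers = {"lstm": self.lstm, "fc": self.fc}

    def forward(self, images, training=False, rng=None):
        x = _as_batch(images, self.resolution)
        B = x.shape[0]
        n = self.resolution * self.resolution
        h_last = self.lstm.forward(x.reshape(B, n, 1))
        logits = self.fc.forward(h_last)
        return sigmoid(logits).reshape(B, self.resolution, self.resolution)

    def backward(self, dlogits):
        dh_last = self.fc.backward(dlogits)
        self.lstm.backward(dh_last)


class Discriminator(_Model):
    """Two FC layers over the flattened PI, ReLU between, final sigmoid."""

    def __init__(self, resolution: int = 100, hidden: int = 32, seed: int = 0):
        self.resolution = resolution
        n = resolution * resolution
        rng = np.random.default_rng(seed)
        self.fc1 = Dense(n, hidden, rng=rng)
        self.fc2 = Dense(hidden, 1, rng=rng)
        self._layers = {"fc1": self.fc1, "fc2": self.fc2}
        self._relu_in = None

    def forward(self, images: np.ndarray) -> np.ndarray:
        x = _as_batch(images, self.resolution)
        B = x.shape[0]
        z1 = self.fc1.forward(x.reshape(B, -1))
        self._relu_in = z1
        logits = self.fc2.forward(np.maximum(z1, 0.0))
        return sigmoid(logits).ravel()

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        """dlogits: (B,) at the output logit; returns d(input image) (B,R,R)."""
        da = self.fc2.backward(dlogits.reshape(-1, 1))
        dz1 = da * (self._relu_in > 0)
        dx = self.fc1.backward(dz1)
        return dx.reshape(-1, self.resolution, self.resolution)


# ---------------------------------------------------------------------------
# Optimizers
# ---------------------------------------------------------------------------

class RMSProp:
    """RMSprop with the usual running mean of squared gradients."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 alpha: float = 0.99, eps: float = 1e-8):
        self.lr, self.alpha, self.eps = lr, alpha, eps
        self._sq = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        for k, p in params.items():
            g = grads[k]
            sq = self._sq[k]
            sq *= self.alpha
            sq += (1 - self.alpha) * g * g
            p -= self.lr * g / (np.sqrt(sq) + self.eps)


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self._m = {k: np.zeros_like(v) for k, v in params.items()}
        self._v = {k: np.zeros_like(v) for k, v in params.items()}
        self._t = 0

    def step(self, params, grads) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self._m[k] = b1 * self._m[k] + (1 - b1) * g
            self._v[k] = b2 * self._v[k] + (1 - b2) * g * g
            mhat = self._m[k] / (1 - b1 ** self._t)
            vhat = self._v[k] / (1 - b2 ** self._t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
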