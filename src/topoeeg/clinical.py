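"""Image-quality coefficients and their correlation with clinical scores.

A small convolutional network (two conv + max-pool blocks and a dense head)
regresses a clinical score from a subject's persistence image; after a fixed
training budget (default 500 rounds of Adam) the network's per-sample
outputs are taken as that band's "image quality coefficients".  Those
coefficients are then correlated (Pearson, two-sided) with each clinical
variable, per band.

The coefficient is thus defined operationally: it is the prediction of a
score-supervised CNN at a fixed training budget, not an intrinsic image
statistic.  Targets are z-scored internally during training (the optimizer
step size is far smaller than raw PANSS magnitudes) and predictions are
mapped back to the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .pigat_gan import Adam, Dense
from .synthetic import substream_rng

__all__ = [
    "QualityModel",
    "CorrelationResult",
    "fit_quality_model",
    "correlate",
    "correlation_table",
]

CLINICAL_VARIABLES = ("panss_total", "panss_positive", "panss_negative")


class _Conv2D:
    """Valid 3x3 convolution with bias (im2col-free, sliding-window einsum)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (c_in * 9 + c_out * 9))
        self.params = {
            "W": rng.uniform(-lim, lim, size=(c_out, c_in, 3, 3)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._sw = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        sw = sliding_window_view(x, (3, 3), axis=(2, 3))
        self._sw = sw
        out = np.einsum("bchwij,ocij->bohw", sw, self.params["W"])
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += np.einsum("bchwij,bohw->ocij", self._sw, dout)
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        padded = np.pad(dout, ((0, 0), (0, 0), (2, 2), (2, 2)))
        sw2 = sliding_window_view(padded, (3, 3), axis=(2, 3))
        Wf = self.params["W"][:, :, ::-1, ::-1]
        return np.einsum("bohwij,ocij->bchw", sw2, Wf)

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


class _MaxPool2:
    """2x2 max pooling, stride 2; trailing odd row/column dropped."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        h, w = H // 2, W // 2
        blocks = x[:, :, :2 * h, :2 * w].reshape(B, C, h, 2, w, 2)
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, h, w, 4)
        self._arg = flat.argmax(axis=-1)
        self._in_shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._in_shape
        h, w = H // 2, W // 2
        dflat = np.zeros((B, C, h, w, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape)
        dx[:, :, :2 * h, :2 * w] = (
            dflat.reshape(B, C, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            .reshape(B, C, 2 * h, 2 * w)
        )
        return dx


class QualityModel:
    """CNN regressor from an R x R persistence image to a scalar score.

    Topology: conv(1->16, 3x3) + ReLU + pool, conv(16->32, 3x3) + ReLU +
    pool, dense hidden (16, ReLU), dense to one output.  Channel widths and
    the hidden size are configurable.
    """

    def __init__(self, resolution: int, channels=(16, 32), hidden: int = 16,
                 seed: int = 0):
        if resolution < 12:
            raise ValueError("resolution too small for two conv+pool blocks")
        rng = np.random.default_rng(seed)
        self.resolution = resolution
        self.conv1 = _Conv2D(1, channels[0], rng)
        self.pool1 = _MaxPool2()
        self.conv2 = _Conv2D(channels[0], channels[1], rng)
        self.pool2 = _MaxPool2()
        side = ((resolution - 2) // 2 - 2) // 2
        self._flat_dim = channels[1] * side * side
        self.dense1 = Dense(self._flat_dim, hidden, rng=rng)
        self.dense2 = Dense(hidden, 1, rng=rng)
        self._layers = {"conv1": self.conv1, "conv2": self.conv2,
                        "dense1": self.dense1, "dense2": self.dense2}
        self._relu_masks = None
        # target standardization, fitted during training
        self.target_mean = 0.0
        self.target_std = 1.0

    @property
    def params(self):
        return {f"{n}.{k}": v for n, l in self._layers.items()
                for k, v in l.params.items()}

    @property
    def grads(self):
        return {f"{n}.{k}": v for n, l in self._layers.items()
                for k, v in l.grads.items()}

    def zero_grads(self):
        for l in self._layers.values():
            for g in l.grads.values():
                g[...] = 0.0

    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())

    def _forward_z(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=float)
        if x.ndim == 2:
            x = x[None]
        x = x[:, None]  # (B,1,R,R)
        z1 = self.conv1.forward(x)
        r1 = np.maximum(z1, 0.0)
        p1 = self.pool1.forward(r1)
        z2 = self.conv2.forward(p1)
        r2 = np.maximum(z2, 0.0)
        p2 = self.pool2.forward(r2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = self.dense1.forward(flat)
        r3 = np.maximum(z3, 0.0)
        out = self.dense2.forward(r3).ravel()
        self._relu_masks = (z1 > 0, z2 > 0, z3 > 0, p2.shape)
        return out

    def _backward_z(self, dout: np.ndarray) -> None:
        m1, m2, m3, p2_shape = self._relu_masks
        dr3 = self.dense2.backward(dout.reshape(-1, 1))
        dz3 = dr3 * m3
        dflat = self.dense1.backward(dz3)
        dp2 = dflat.reshape(p2_shape)
        dr2 = self.pool2.backward(dp2)
        dz2 = dr2 * m2
        dp1 = self.conv2.backward(dz2)
        dr1 = self.pool1.backward(dp1)
        dz1 = dr1 * m1
        self.conv1.backward(dz1)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Per-sample coefficients on the original score scale."""
        z = self._forward_z(images)
        return z * self.target_std + self.target_mean


@dataclass
class CorrelationResult:
    band: str
    clinical_variable: str
    r: float
    p: float


def fit_quality_model(pis: np.ndarray, targets: np.ndarray, epochs: int = 500,
                      seed: int = 0, lr: float = 1e-3, batch_size: int = 16,
                      channels=(16, 32), hidden: int = 16):
    """Train the CNN regressor; return (model, coefficients, loss curve).

    Coefficients are the trained model's outputs on the training samples —
    one scalar per (subject, band) image.  MSE loss on z-scored targets,
    Adam, fixed epoch budget, fully seeded.
    """
    x = np.asarray(pis, dtype=float)
    t = np.asarray(targets, dtype=float).ravel()
    if x.ndim != 3 or x.shape[0] != t.shape[0]:
        raise ValueError("pis must be (n, R, R) matching targets")
    if t.shape[0] < 5:
        raise ValueError("need at least 5 paired samples")
    model = QualityModel(x.shape[1], channels=channels, hidden=hidden, seed=seed)
    model.target_mean = float(t.mean())
    model.target_std = float(t.std()) if t.std() > 0 else 1.0
    tz = (t - model.target_mean) / model.target_std
    opt = Adam(model.params, lr=lr)
    rng = substream_rng(seed, "quality-shuffle")
    curve = []
    n = t.shape[0]
    for _epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            model.zero_grads()
            z = model._forward_z(x[idx])
            err = z - tz[idx]
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise RuntimeError("quality-model training diverged")
            model._backward_z(2.0 * err / err.size)
            opt.step(model.params, model.grads)
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    coefficients = model.predict(x)
    return model, coefficients, curve


def correlate(coefficients, scores, band: str = "",
              variable: str = "") -> CorrelationResult:
    """Pearson correlation with two-sided p (via the t transform)."""
    a = np.asarray(coefficients, dtype=float).ravel()
    b = np.asarray(scores, dtype=float).ravel()
    if a.shape != b.shape or a.shape[0] < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(band, variable, float(r), float(p))


def correlation_table(coefficients_by_band: dict[str, tuple[list[str], np.ndarray]],
                      scores: pd.DataFrame) -> pd.DataFrame:
    """Bands x clinical-variables table of Pearson p-values (r alongside).

    ``coefficients_by_band`` maps band name to (subject_ids, coefficients);
    ``scores`` must have columns subject_id plus the three PANSS variables.
    Returns a tidy frame with columns band, clinical_variable, r, p.
    """
    scores = scores.set_index("subject_id")
    rows = []
    for band, (sids, coeffs) in coefficients_by_band.items():
        sub = scores.loc[list(sids)]
        for var in CLINICAL_VARIABLES:
            res = correlate(coeffs, sub[var].to_numpy(), band, var)
            rows.append({"band": band, "clinical_variable": var,
                         "r": res.r, "p": res.p})
    return pd.DataFrame(rows)
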