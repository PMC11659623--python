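"""Stack-and-pad CNN over per-molecule substructure applicability features.

Each mixture sample is a variable-height "image": one row per detected
molecule, one column per substructure pattern, optionally scaled row-wise by
the molecule's relative peak area.  Samples in a batch are stacked and
zero-padded to a common height; a mask records how many rows of each sample
are real molecules.

The network is a small CPU-friendly 2D CNN written directly in NumPy with
hand-coded backpropagation: two strided convolutions with ReLU, an adaptive
max-pool to a fixed grid computed *only over each sample's real rows* (so
predictions are exactly invariant to extra zero padding), and two fully
connected layers.  Classification uses a per-class weighted binary
cross-entropy (the class weights come from the fold's inverted-frequency
scheme); regression uses L1 or MSE on raw summed panel ratings.  All
randomness flows through one seeded generator, so training is bitwise
reproducible on CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .chem_features import ConfigError, InputError
from .owsum import predict as topk_predict

__all__ = [
    "SampleFeatureStack",
    "CnnConfig",
    "CnnModel",
    "scale_features_by_peak_area",
    "stack_and_pad",
    "train_cnn",
    "predict_cnn",
]

Loss = Literal["weighted_bce", "l1", "mse"]


@dataclass
class SampleFeatureStack:
    """Applicability rows of one sample's detected molecules."""

    sample_id: str
    rows: np.ndarray  # (n_molecules + pad_rows, n_patterns)
    peak_areas: np.ndarray | None = None  # (n_molecules,)
    pad_rows: int = 0

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2:
            raise InputError("feature stack must be 2-D (molecules x patterns)")
        if self.peak_areas is not None:
            self.peak_areas = np.asarray(self.peak_areas, dtype=float)
            if self.peak_areas.shape != (self.n_molecules,):
                raise InputError(
                    f"{self.sample_id}: need one peak area per molecule row "
                    f"({self.n_molecules}), got {self.peak_areas.shape}"
                )
            if (self.peak_areas <= 0).any():
                raise InputError(f"{self.sample_id}: peak areas must be > 0")
        if self.pad_rows and not np.all(self.rows[self.n_molecules:] == 0):
            raise InputError(f"{self.sample_id}: padding rows must be exactly zero")

    @property
    def n_molecules(self) -> int:
        return self.rows.shape[0] - self.pad_rows

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    def padded(self, extra_rows: int) -> "SampleFeatureStack":
        """Return a copy with ``extra_rows`` additional all-zero rows."""
        if extra_rows < 0:
            raise InputError("extra_rows must be >= 0")
        new_rows = np.vstack([self.rows, np.zeros((extra_rows, self.width))])
        return replace(self, rows=new_rows, pad_rows=self.pad_rows + extra_rows)


@dataclass(frozen=True)
class CnnConfig:
    """Architecture and training hyperparameters.

    Defaults: conv 1->8 and 8->16 channels, 3x3 kernels, stride 2, adaptive
    max-pool to 1x8, fully connected 128->64->output, Adam.  Pooling the row
    dimension globally treats the molecule rows as the unordered set they
    are: each pooled unit asks whether *any* detected molecule activates a
    learned substructure-applicability motif.  Epoch defaults (11
    classification / 21 regression) follow the original training protocol;
    pass ``epochs`` explicitly to train longer.
    """

    output_size: int
    conv_channels: tuple[int, int] = (8, 16)
    kernel_size: int = 3
    stride: int = 2
    pool_size: tuple[int, int] = (1, 8)
    hidden: int = 64
    epochs: int = 11
    learning_rate: float = 1e-2
    seed: int = 0
    feature_scaling: bool = False
    loss: Loss = "weighted_bce"

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.output_size < 1:
            raise ConfigError("output_size must be >= 1")
        if self.loss not in ("weighted_bce", "l1", "mse"):
            raise ConfigError(f"unknown loss: {self.loss!r}")


def scale_features_by_peak_area(
    stack: SampleFeatureStack, scaling_on: bool = True
) -> SampleFeatureStack:
    """Multiply each molecule row by its relative peak area.

    Serves as a concentration proxy; padding rows are untouched.  With
    ``scaling_on=False`` the stack is returned unchanged.
    """
    if not scaling_on:
        return stack
    if stack.peak_areas is None:
        raise InputError(f"{stack.sample_id}: feature scaling is on but peak areas are missing")
    rows = stack.rows.copy()
    rows[: stack.n_molecules] *= stack.peak_areas[:, None]
    return replace(stack, rows=rows)


def stack_and_pad(
    batch: Sequence[SampleFeatureStack],
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a batch to a common height; returns (tensor, real-row counts).

    The tensor has shape (batch, 1, H, W) with H the maximum molecule count in
    the batch; shorter samples are zero-padded at the bottom.  The mask array
    gives each sample's number of real (molecule) rows.
    """
    if not batch:
        raise InputError("empty batch")
    widths = {s.width for s in batch}
    if len(widths) != 1:
        raise InputError(f"pattern-count width mismatch across batch: {sorted(widths)}")
    height = max(s.n_molecules for s in batch)
    width = widths.pop()
    x = np.zeros((len(batch), 1, height, width))
    n_real = np.zeros(len(batch), dtype=int)
    for i, s in enumerate(batch):
        n = s.n_molecules
        x[i, 0, :n] = s.rows[:n]
        n_real[i] = n
    return x, n_real


# ---------------------------------------------------------------------------
# layers (forward + backward)


def _conv_out(size: int, k: int, s: int) -> int:
    return (size + 2 - k) // s + 1  # pad = 1 on each side


def _im2col(x: np.ndarray, k: int, s: int) -> tuple[np.ndarray, tuple[int, int]]:
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    ho, wo = _conv_out(h, k, s), _conv_out(w, k, s)
    sb, sc, sh, sw = xp.strides
    cols = as_strided(
        xp,
        shape=(b, c, ho, wo, k, k),
        strides=(sb, sc, sh * s, sw * s, sh, sw),
    )
    # (b, ho, wo, c*k*k)
    return np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(b, ho, wo, c * k * k), (
        ho,
        wo,
    )


def _conv_forward(x, weight, bias, s):
    c_out, c_in, k, _ = weight.shape
    cols, (ho, wo) = _im2col(x, k, s)
    out = cols @ weight.reshape(c_out, -1).T + bias
    return out.transpose(0, 3, 1, 2), cols


def _conv_backward(dout, cols, x_shape, weight, s):
    b, c_in, h, w = x_shape
    c_out, _, k, _ = weight.shape
    dflat = dout.transpose(0, 2, 3, 1)  # (b, ho, wo, c_out)
    dw = np.tensordot(dflat, cols, axes=([0, 1, 2], [0, 1, 2])).reshape(weight.shape)
    db = dflat.sum(axis=(0, 1, 2))
    dcols = dflat @ weight.reshape(c_out, -1)  # (b, ho, wo, c_in*k*k)
    ho, wo = dout.shape[2], dout.shape[3]
    dcols = dcols.reshape(b, ho, wo, c_in, k, k)
    dxp = np.zeros((b, c_in, h + 2, w + 2))
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki : ki + s * ho : s, kj : kj + s * wo : s] += dcols[
                :, :, :, :, ki, kj
            ].transpose(0, 3, 1, 2)
    return dxp[:, :, 1 : h + 1, 1 : w + 1], dw, db


def _pool_bins(n: int, out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n / out)), int(np.ceil((i + 1) * n / out))) for i in range(out)]


def _masked_adaptive_maxpool(x, real_rows, out_hw):
    """Adaptive max pool over each sample's real-row region only."""
    b, c, h, w = x.shape
    oh, ow = out_hw
    out = np.zeros((b, c, oh, ow))
    arg = np.zeros((b, c, oh, ow, 2), dtype=int)
    col_bins = _pool_bins(w, ow)
    for i in range(b):
        n = max(int(real_rows[i]), 1)
        row_bins = _pool_bins(n, oh)
        for bi, (r0, r1) in enumerate(row_bins):
            for bj, (c0, c1) in enumerate(col_bins):
                region = x[i, :, r0:r1, c0:c1].reshape(c, -1)
                idx = region.argmax(axis=1)
                out[i, :, bi, bj] = region[np.arange(c), idx]
                rr, cc = np.unravel_index(idx, (r1 - r0, c1 - c0))
                arg[i, :, bi, bj, 0] = r0 + rr
                arg[i, :, bi, bj, 1] = c0 + cc
    return out, arg


def _maxpool_backward(dout, arg, x_shape):
    dx = np.zeros(x_shape)
    b, c, oh, ow = dout.shape
    for i in range(b):
        for bi in range(oh):
            for bj in range(ow):
                np.add.at(
                    dx[i],
                    (np.arange(c), arg[i, :, bi, bj, 0], arg[i, :, bi, bj, 1]),
                    dout[i, :, bi, bj],
                )
    return dx


def _real_rows_after_conv(n_real: np.ndarray, s: int) -> np.ndarray:
    # with pad=1 and kernel 3, output row r sees input rows s*r-1 .. s*r+1
    return n_real // s + 1


@dataclass
class CnnModel:
    """Trained parameters plus the shape contract they were trained with."""

    config: CnnConfig
    params: dict[str, np.ndarray]
    input_width: int
    class_weights: np.ndarray | None = None

    def save(self, path) -> None:
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "schema": "mixodor.cnn_model/1",
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(self.config).items()
            },
            "input_width": self.input_width,
            "class_weights": None
            if self.class_weights is None
            else list(map(float, self.class_weights)),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "CnnModel":
        import json
        from pathlib import Path

        path = Path(path)
        doc = json.loads(path.with_suffix(".json").read_text())
        cfg = doc["config"]
        for key in ("conv_channels", "pool_size"):
            cfg[key] = tuple(cfg[key])
        config = CnnConfig(**cfg)
        with np.load(path.with_suffix(".npz")) as data:
            params = {k: data[k] for k in data.files}
        cw = doc["class_weights"]
        return cls(
            config=config,
            params=params,
            input_width=doc["input_width"],
            class_weights=None if cw is None else np.asarray(cw),
        )


def _init_params(config: CnnConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    c1, c2 = config.conv_channels
    k = config.kernel_size
    oh, ow = config.pool_size
    flat = c2 * oh * ow
    def he(shape, fan_in):
        return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

    return {
        "w1": he((c1, 1, k, k), k * k),
        "b1": np.zeros(c1),
        "w2": he((c2, c1, k, k), c1 * k * k),
        "b2": np.zeros(c2),
        "w3": he((flat, config.hidden), flat),
        "b3": np.zeros(config.hidden),
        "w4": he((config.hidden, config.output_size), config.hidden),
        "b4": np.zeros(config.output_size),
    }


def _min_height(n_real_max: int, s: int) -> int:
    # enough rows that every real-influenced conv output exists at both stages
    return n_real_max + 3 * s + 1


def _forward(params, x, n_real, config, want_cache=False):
    s = config.stride
    h1, cols1 = _conv_forward(x, params["w1"], params["b1"], s)
    a1 = np.maximum(h1, 0.0)
    h2, cols2 = _conv_forward(a1, params["w2"], params["b2"], s)
    a2 = np.maximum(h2, 0.0)
    n1 = _real_rows_after_conv(n_real, s)
    n2 = np.minimum(_real_rows_after_conv(n1, s), h2.shape[2])
    pooled, arg = _masked_adaptive_maxpool(a2, n2, config.pool_size)
    flat = pooled.reshape(x.shape[0], -1)
    z3 = flat @ params["w3"] + params["b3"]
    a3 = np.maximum(z3, 0.0)
    out = a3 @ params["w4"] + params["b4"]
    if not want_cache:
        return out, None
    cache = dict(
        x=x, h1=h1, a1=a1, cols1=cols1, h2=h2, a2=a2, cols2=cols2,
        arg=arg, flat=flat, z3=z3, a3=a3,
    )
    return out, cache


def _backward(params, cache, dout, config):
    s = config.stride
    grads = {}
    grads["w4"] = cache["a3"].T @ dout
    grads["b4"] = dout.sum(axis=0)
    da3 = dout @ params["w4"].T
    dz3 = da3 * (cache["z3"] > 0)
    grads["w3"] = cache["flat"].T @ dz3
    grads["b3"] = dz3.sum(axis=0)
    dflat = dz3 @ params["w3"].T
    b = cache["x"].shape[0]
    c2 = config.conv_channels[1]
    dpooled = dflat.reshape(b, c2, *config.pool_size)
    da2 = _maxpool_backward(dpooled, cache["arg"], cache["a2"].shape)
    dh2 = da2 * (cache["h2"] > 0)
    da1, grads["w2"], grads["b2"] = _conv_backward(
        dh2, cache["cols2"], cache["a1"].shape, params["w2"], s
    )
    dh1 = da1 * (cache["h1"] > 0)
    _, grads["w1"], grads["b1"] = _conv_backward(
        dh1, cache["cols1"], cache["x"].shape, params["w1"], s
    )
    return grads


def _loss_and_grad(out, targets, config, class_weights):
    b, c = out.shape
    if config.loss == "weighted_bce":
        w = np.ones(c) if class_weights is None else np.asarray(class_weights, dtype=float)
        if w.shape != (c,):
            raise InputError(f"class-weight vector length {w.shape} != n classes {c}")
        p = 1.0 / (1.0 + np.exp(-out))
        eps = 1e-12
        bce = -(targets * np.log(p + eps) + (1 - targets) * np.log(1 - p + eps))
        loss = float((w * bce.mean(axis=0)).mean())
        dout = (p - targets) * w / (b * c)
        return loss, dout
    diff = out - targets
    if config.loss == "l1":
        return float(np.abs(diff).mean()), np.sign(diff) / diff.size
    return float((diff**2).mean()), 2.0 * diff / diff.size


def _prepare_batch(stacks, config):
    scaled = [scale_features_by_peak_area(s, config.feature_scaling) for s in stacks]
    x, n_real = stack_and_pad(scaled)
    need = _min_height(int(n_real.max()), config.stride)
    if x.shape[2] < need:
        pad = np.zeros((x.shape[0], 1, need - x.shape[2], x.shape[3]))
        x = np.concatenate([x, pad], axis=2)
    return x, n_real


def train_cnn(
    train_stacks: Sequence[SampleFeatureStack],
    targets: np.ndarray,
    config: CnnConfig,
    class_weights: Sequence[float] | None = None,
) -> tuple[CnnModel, list[float]]:
    """Full-batch Adam training; returns the model and the per-epoch loss curve.

    Classification targets are 0/1 matrices (samples x classes) with the
    fold's inverted-frequency class weights; regression targets are raw
    non-negative score matrices.  Deterministic given ``config.seed``.
    """
    if not train_stacks:
        raise InputError("empty training set")
    targets = np.asarray(targets, dtype=float)
    if targets.shape != (len(train_stacks), config.output_size):
        raise InputError(
            f"targets shape {targets.shape} != ({len(train_stacks)}, {config.output_size})"
        )
    x, n_real = _prepare_batch(train_stacks, config)
    rng = np.random.default_rng(config.seed & 0x7FFFFFFF)
    params = _init_params(config, rng)
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    losses = []
    for t in range(1, config.epochs + 1):
        out, cache = _forward(params, x, n_real, config, want_cache=True)
        loss, dout = _loss_and_grad(out, targets, config, class_weights)
        losses.append(loss)
        grads = _backward(params, cache, dout, config)
        lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
        for k in params:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            params[k] = params[k] - lr_t * m[k] / (np.sqrt(v[k]) + eps)
    model = CnnModel(
        config=config,
        params=params,
        input_width=x.shape[3],
        class_weights=None if class_weights is None else np.asarray(class_weights, float),
    )
    return model, losses


def forward_scores(model: CnnModel, stacks: Sequence[SampleFeatureStack]) -> np.ndarray:
    """Raw network outputs (logits or regression scores) for a batch."""
    for s in stacks:
        if s.width != model.input_width:
            raise InputError(
                f"{s.sample_id}: width {s.width} != training width {model.input_width}"
            )
    x, n_real = _prepare_batch(stacks, model.config)
    out, _ = _forward(model.params, x, n_real, model.config)
    return out


def predict_cnn(
    model: CnnModel,
    stack: SampleFeatureStack,
    task: Literal["classify", "regress"] = "classify",
    class_names: Sequence[str] | None = None,
    k: int = 5,
):
    """Top-k classes (classification) or the raw score vector (regression)."""
    out = forward_scores(model, [stack])[0]
    if task == "regress":
        return out
    if task != "classify":
        raise ConfigError(f"unknown task: {task!r}")
    names = (
        list(class_names)
        if class_names is not None
        else [f"class_{i:02d}" for i in range(model.config.output_size)]
    )
    if len(names) != model.config.output_size:
        raise InputError("class_names length does not match model output size")
    scores = dict(zip(names, out))
    labels, _ = topk_predict(scores, k=k)
    return labels, out
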