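"""Convolutional-recurrent network over dFC tensors, in plain NumPy.

The architecture consumes a scan's dFC tensor (T windows x N x N correlation
matrices, one input channel) and extracts features hierarchically:

* conv1 — region features: kernel S1 x N x 1 slides over time and collapses
  the first spatial axis, producing per-ROI features from S1 consecutive
  networks; output (T-S1+1, 1, N, K1).
* conv2 — whole-network features: kernel S2 x 1 x N collapses the remaining
  spatial axis; output (T-S1-S2+2, 1, 1, K2).
* conv3 — temporal features: kernel S3 x 1 x 1 with temporal stride 2;
  output (T1, 1, 1, K3).
* sequence stage — the T1-step sequence of K3-vectors is fed to an LSTM
  whose final hidden state is the scan representation ("lstm"), or mean-pooled
  over time ("mean", the CNN ablation).
* head — fully connected 32 -> 16 -> n_classes with ReLU, dropout 0.25 on
  the hidden layers, and a softmax output.

All convolutions are "valid" (no padding): with the default configuration and
T=34 windows the time axis shrinks 34 -> 33 -> 32 -> T1=13.

Everything (forward, backprop, Adam) is implemented directly on NumPy
arrays; gradients are exercised against central finite differences in the
test suite, and the LSTM step against a scalar-loop oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

GATES = ("f", "g", "o", "i")


class ConfigurationError(ValueError):
    """Architecture hyperparameters incompatible with the input shape."""


@dataclass(frozen=True)
class CrnnConfig:
    """Architecture hyperparameters.

    Defaults follow the reference configuration: temporal kernel extents
    S1=S2=2, S3=8 with conv3 temporal stride 2; channel counts K1=8, K2=16,
    K3=32; LSTM hidden width 64; fully connected sizes 32 and 16; dropout
    rate 0.25 on the hidden FC layers.
    """

    s1: int = 2
    s2: int = 2
    s3: int = 8
    k1: int = 8
    k2: int = 16
    k3: int = 32
    stride3_time: int = 2
    lstm_hidden: int = 64
    fc_sizes: tuple[int, ...] = (32, 16)
    n_classes: int = 2
    dropout_rate: float = 0.25
    sequence_model: str = "lstm"  # "lstm" (CRNN) or "mean" (CNN ablation)

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3", "k1", "k2", "k3", "stride3_time", "lstm_hidden"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout_rate must lie in [0, 1)")
        if self.sequence_model not in ("lstm", "mean"):
            raise ConfigurationError("sequence_model must be 'lstm' or 'mean'")
        if self.n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")


@dataclass
class ShapeTrace:
    """Per-layer output shapes (time, dim1, dim2, channels) and the conv3
    time length T1."""

    shapes: list[tuple[int, int, int, int]]
    T1: int


@dataclass
class LstmState:
    """Hidden vector h and cell state vector s (equal width)."""

    h: np.ndarray
    s: np.ndarray


def conv_output_length(in_len: int, kernel: int, stride: int = 1) -> int:
    """Output length of a valid (unpadded) 1-D convolution."""
    if kernel > in_len:
        raise ConfigurationError(
            f"kernel {kernel} does not fit input of length {in_len}"
        )
    return (in_len - kernel) // stride + 1


def propagate_shapes(config: CrnnConfig, T: int, N: int) -> ShapeTrace:
    """Propagate the input shape (T windows, N ROIs) through the conv stack."""
    shapes: list[tuple[int, int, int, int]] = []
    try:
        t1 = conv_output_length(T, config.s1, 1)
    except ConfigurationError as exc:
        raise ConfigurationError(f"conv1: {exc}") from None
    shapes.append((t1, 1, N, config.k1))
    try:
        t2 = conv_output_length(t1, config.s2, 1)
    except ConfigurationError as exc:
        raise ConfigurationError(f"conv2: {exc}") from None
    shapes.append((t2, 1, 1, config.k2))
    try:
        t3 = conv_output_length(t2, config.s3, config.stride3_time)
    except ConfigurationError as exc:
        raise ConfigurationError(f"conv3: {exc}") from None
    shapes.append((t3, 1, 1, config.k3))
    return ShapeTrace(shapes=shapes, T1=t3)


def count_sequential_features(config: CrnnConfig) -> int:
    """Width of the scan representation entering the first FC layer:
    lstm_hidden (64) for the CRNN, K3 (32) for the mean-pooling ablation."""
    return config.lstm_hidden if config.sequence_model == "lstm" else config.k3


# ---------------------------------------------------------------------------
# Parameter initialisation
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def init_params(config: CrnnConfig, n_rois: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Glorot-uniform kernels, orthogonal LSTM recurrence, zero biases
    (forget-gate bias 1), mirroring common framework defaults."""
    N = n_rois
    p: dict[str, np.ndarray] = {}
    p["W1"] = _glorot(rng, (config.k1, config.s1, N), config.s1 * N, config.k1)
    p["b1"] = np.zeros(config.k1)
    p["W2"] = _glorot(
        rng, (config.k2, config.s2, N, config.k1), config.s2 * N * config.k1, config.k2
    )
    p["b2"] = np.zeros(config.k2)
    p["W3"] = _glorot(rng, (config.k3, config.s3, config.k2), config.s3 * config.k2, config.k3)
    p["b3"] = np.zeros(config.k3)
    feat = config.k3
    if config.sequence_model == "lstm":
        H = config.lstm_hidden
        for k in GATES:
            p[f"U{k}"] = _glorot(rng, (H, config.k3), config.k3, H)
            p[f"W{k}"] = _orthogonal(rng, H)
            p[f"b{k}"] = np.full(H, 1.0) if k == "f" else np.zeros(H)
        feat = H
    sizes = (feat, *config.fc_sizes, config.n_classes)
    for i in range(len(sizes) - 1):
        p[f"A{i + 1}"] = _glorot(rng, (sizes[i + 1], sizes[i]), sizes[i], sizes[i + 1])
        p[f"c{i + 1}"] = np.zeros(sizes[i + 1])
    return p


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_step(
    x: np.ndarray, state: LstmState, params: dict[str, np.ndarray]
) -> LstmState:
    """One step of the LSTM cell.

    f = sigma(Uf x + Wf h + bf); g = tanh(Ug x + Wg h + bg);
    o = sigma(Uo x + Wo h + bo); i = sigma(Ui x + Wi h + bi);
    s' = f*s + g*i; h' = tanh(s')*o.  Accepts a single vector or a batch
    of row vectors.
    """
    x = np.asarray(x, dtype=float)
    h, s = state.h, state.s
    single = x.ndim == 1
    if single:
        x, h, s = x[None, :], h[None, :], s[None, :]
    acts = {}
    for k in GATES:
        pre = x @ params[f"U{k}"].T + h @ params[f"W{k}"].T + params[f"b{k}"]
        acts[k] = np.tanh(pre) if k == "g" else _sigmoid(pre)
    s_new = acts["f"] * s + acts["g"] * acts["i"]
    h_new = np.tanh(s_new) * acts["o"]
    if single:
        return LstmState(h=h_new[0], s=s_new[0])
    return LstmState(h=h_new, s=s_new)


def conv_features(
    X: np.ndarray, params: dict[str, np.ndarray], config: CrnnConfig
) -> tuple[np.ndarray, dict]:
    """Run the three-layer conv stack on a batch of dFC tensors.

    X has shape (B, T, N, N); returns the (B, T1, K3) feature sequence and a
    cache for backprop.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 4 or X.shape[2] != X.shape[3]:
        raise ConfigurationError(f"expected batch of (T, N, N) tensors, got {X.shape}")
    B, T, N, _ = X.shape
    trace = propagate_shapes(config, T, N)
    (t1, _, _, k1), (t2, _, _, k2), (t3, _, _, k3) = trace.shapes

    # conv1: out[b,t,j,k] = sum_{a,i} W1[k,a,i] X[b,t+a,i,j] + b1[k]
    pre1 = np.zeros((B, t1, N, k1))
    for a in range(config.s1):
        pre1 += np.einsum("ki,btij->btjk", params["W1"][:, a], X[:, a : a + t1])
    pre1 += params["b1"]
    out1 = np.maximum(pre1, 0.0)

    # conv2: out[b,t,k] = sum_{a,j,c} W2[k,a,j,c] out1[b,t+a,j,c] + b2[k]
    pre2 = np.zeros((B, t2, k2))
    for a in range(config.s2):
        pre2 += np.einsum("kjc,btjc->btk", params["W2"][:, a], out1[:, a : a + t2])
    pre2 += params["b2"]
    out2 = np.maximum(pre2, 0.0)

    # conv3 (stride along time): out[b,t,k] = sum_{a,c} W3[k,a,c] out2[b,st*t+a,c] + b3[k]
    st = config.stride3_time
    pre3 = np.zeros((B, t3, k3))
    for a in range(config.s3):
        pre3 += np.einsum("kc,btc->btk", params["W3"][:, a], out2[:, a : a + st * (t3 - 1) + 1 : st])
    pre3 += params["b3"]
    seq = np.maximum(pre3, 0.0)

    cache = dict(X=X, pre1=pre1, out1=out1, pre2=pre2, out2=out2, pre3=pre3, seq=seq, trace=trace)
    return seq, cache


def _lstm_forward(seq: np.ndarray, params: dict[str, np.ndarray]) -> tuple[np.ndarray, dict]:
    B, T1, _ = seq.shape
    H = params["Uf"].shape[0]
    h = np.zeros((B, H))
    s = np.zeros((B, H))
    steps = []
    for t in range(T1):
        x = seq[:, t]
        acts = {}
        for k in GATES:
            pre = x @ params[f"U{k}"].T + h @ params[f"W{k}"].T + params[f"b{k}"]
            acts[k] = np.tanh(pre) if k == "g" else _sigmoid(pre)
        s_new = acts["f"] * s + acts["g"] * acts["i"]
        tanh_s = np.tanh(s_new)
        h_new = tanh_s * acts["o"]
        steps.append(dict(x=x, h_prev=h, s_prev=s, acts=acts, s=s_new, tanh_s=tanh_s))
        h, s = h_new, s_new
    return h, dict(steps=steps, h_final=h)


def sequence_features(
    seq: np.ndarray, params: dict[str, np.ndarray], config: CrnnConfig
) -> tuple[np.ndarray, dict]:
    """Collapse the (B, T1, K3) sequence to one feature vector per scan:
    final LSTM hidden state, or the time mean for the CNN ablation."""
    if config.sequence_model == "lstm":
        feat, cache = _lstm_forward(seq, params)
        cache["kind"] = "lstm"
        cache["T1"] = seq.shape[1]
        return feat, cache
    feat = seq.mean(axis=1)
    return feat, dict(kind="mean", T1=seq.shape[1])


def head_forward(
    feat: np.ndarray,
    params: dict[str, np.ndarray],
    config: CrnnConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Fully connected head with ReLU, inverted dropout (train only) and softmax."""
    n_hidden = len(config.fc_sizes)
    acts = [feat]
    masks: list[np.ndarray | None] = []
    h = feat
    for i in range(n_hidden):
        z = h @ params[f"A{i + 1}"].T + params[f"c{i + 1}"]
        h = np.maximum(z, 0.0)
        if train and config.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            keep = 1.0 - config.dropout_rate
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
            masks.append(mask)
        else:
            masks.append(None)
        acts.append(h)
    logits = h @ params[f"A{n_hidden + 1}"].T + params[f"c{n_hidden + 1}"]
    shifted = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(shifted)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return probs, dict(acts=acts, masks=masks, logits=logits, probs=probs)


def forward(
    X: np.ndarray,
    params: dict[str, np.ndarray],
    config: CrnnConfig,
    train: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Full forward pass: (B, T, N, N) batch -> (B, n_classes) class probabilities."""
    seq, conv_cache = conv_features(X, params, config)
    feat, seq_cache = sequence_features(seq, params, config)
    probs, head_cache = head_forward(feat, params, config, train=train, rng=rng)
    return probs, dict(conv=conv_cache, seqstage=seq_cache, head=head_cache, config=config)


def crnn_forward(X: np.ndarray, params: dict[str, np.ndarray], config: CrnnConfig) -> np.ndarray:
    """Evaluation-mode CRNN forward pass (dropout disabled)."""
    cfg = replace(config, sequence_model="lstm")
    return forward(X, params, cfg, train=False)[0]


def cnn_ablation_forward(
    X: np.ndarray, params: dict[str, np.ndarray], config: CrnnConfig
) -> np.ndarray:
    """Evaluation-mode forward pass of the mean-pooling (no-LSTM) ablation."""
    cfg = replace(config, sequence_model="mean")
    return forward(X, params, cfg, train=False)[0]


# ---------------------------------------------------------------------------
# Backward pass
# ---------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean negative log-likelihood of integer labels ``y``."""
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + eps)))


def _head_backward(cache: dict, y: np.ndarray, params, config) -> tuple[dict, np.ndarray]:
    B = len(y)
    probs = cache["probs"]
    dlogits = probs.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits /= B
    grads: dict[str, np.ndarray] = {}
    n_hidden = len(config.fc_sizes)
    acts, masks = cache["acts"], cache["masks"]
    d = dlogits
    grads[f"A{n_hidden + 1}"] = d.T @ acts[-1]
    grads[f"c{n_hidden + 1}"] = d.sum(axis=0)
    dh = d @ params[f"A{n_hidden + 1}"]
    for i in range(n_hidden, 0, -1):
        if masks[i - 1] is not None:
            dh = dh * masks[i - 1]
        dh = dh * (acts[i] > 0)  # acts[i] already post-dropout; mask>0 where kept
        grads[f"A{i}"] = dh.T @ acts[i - 1]
        grads[f"c{i}"] = dh.sum(axis=0)
        dh = dh @ params[f"A{i}"]
    return grads, dh


def _lstm_backward(cache: dict, dfeat: np.ndarray, params) -> tuple[dict, np.ndarray]:
    steps = cache["steps"]
    T1 = len(steps)
    B, H = dfeat.shape
    K = steps[0]["x"].shape[1]
    grads = {}
    for k in GATES:
        grads[f"U{k}"] = np.zeros((H, K))
        grads[f"W{k}"] = np.zeros((H, H))
        grads[f"b{k}"] = np.zeros(H)
    dseq = np.zeros((B, T1, K))
    dh = dfeat.copy()
    ds = np.zeros((B, H))
    for t in range(T1 - 1, -1, -1):
        st = steps[t]
        f, g, o, i = (st["acts"][k] for k in GATES)
        tanh_s = st["tanh_s"]
        do = dh * tanh_s
        ds = ds + dh * o * (1.0 - tanh_s**2)
        df = ds * st["s_prev"]
        dg = ds * i
        di = ds * g
        ds_prev = ds * f
        da = {
            "f": df * f * (1.0 - f),
            "g": dg * (1.0 - g**2),
            "o": do * o * (1.0 - o),
            "i": di * i * (1.0 - i),
        }
        dh_prev = np.zeros((B, H))
        dx = np.zeros((B, K))
        for k in GATES:
            grads[f"U{k}"] += da[k].T @ st["x"]
            grads[f"W{k}"] += da[k].T @ st["h_prev"]
            grads[f"b{k}"] += da[k].sum(axis=0)
            dh_prev += da[k] @ params[f"W{k}"]
            dx += da[k] @ params[f"U{k}"]
        dseq[:, t] = dx
        dh, ds = dh_prev, ds_prev
    return grads, dseq


def _conv_backward(cache: dict, dseq: np.ndarray, params, config) -> dict:
    X = cache["X"]
    trace = cache["trace"]
    (t1, _, _, _), (t2, _, _, _), (t3, _, _, _) = trace.shapes
    grads = {}
    st = config.stride3_time

    da3 = dseq * (cache["pre3"] > 0)
    grads["W3"] = np.zeros_like(params["W3"])
    grads["b3"] = da3.sum(axis=(0, 1))
    dout2 = np.zeros_like(cache["out2"])
    for a in range(config.s3):
        sl = slice(a, a + st * (t3 - 1) + 1, st)
        grads["W3"][:, a] = np.einsum("btk,btc->kc", da3, cache["out2"][:, sl])
        dout2[:, sl] += np.einsum("btk,kc->btc", da3, params["W3"][:, a])

    da2 = dout2 * (cache["pre2"] > 0)
    grads["W2"] = np.zeros_like(params["W2"])
    grads["b2"] = da2.sum(axis=(0, 1))
    dout1 = np.zeros_like(cache["out1"])
    for a in range(config.s2):
        grads["W2"][:, a] = np.einsum("btk,btjc->kjc", da2, cache["out1"][:, a : a + t2])
        dout1[:, a : a + t2] += np.einsum("btk,kjc->btjc", da2, params["W2"][:, a])

    da1 = dout1 * (cache["pre1"] > 0)
    grads["W1"] = np.zeros_like(params["W1"])
    grads["b1"] = da1.sum(axis=(0, 1, 2))
    for a in range(config.s1):
        grads["W1"][:, a] = np.einsum("btjk,btij->ki", da1, X[:, a : a + t1])
    return grads


def loss_and_grads(
    X: np.ndarray,
    y: np.ndarray,
    params: dict[str, np.ndarray],
    config: CrnnConfig,
    train: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[float, dict[str, np.ndarray], np.ndarray]:
    """Cross-entropy loss, full parameter gradients, and the class probabilities."""
    y = np.asarray(y, dtype=int)
    probs, cache = forward(X, params, config, train=train, rng=rng)
    loss = cross_entropy(probs, y)
    grads, dfeat = _head_backward(cache["head"], y, params, config)
    if config.sequence_model == "lstm":
        lstm_grads, dseq = _lstm_backward(cache["seqstage"], dfeat, params)
        grads.update(lstm_grads)
    else:
        T1 = cache["seqstage"]["T1"]
        dseq = np.repeat(dfeat[:, None, :] / T1, T1, axis=1)
    grads.update(_conv_backward(cache["conv"], dseq, params, config))
    return loss, grads, probs


# ---------------------------------------------------------------------------
# Adam optimiser (recommended defaults)
# ---------------------------------------------------------------------------

@dataclass
class AdamState:
    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def adam_init(params: dict[str, np.ndarray], lr: float = 1e-3) -> AdamState:
    return AdamState(
        m={k: np.zeros_like(v) for k, v in params.items()},
        v={k: np.zeros_like(v) for k, v in params.items()},
        lr=lr,
    )


def adam_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray], state: AdamState) -> None:
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    corr1 = 1.0 - b1**state.t
    corr2 = 1.0 - b2**state.t
    for k, g in grads.items():
        state.m[k] = b1 * state.m[k] + (1 - b1) * g
        state.v[k] = b2 * state.v[k] + (1 - b2) * g * g
        params[k] -= state.lr * (state.m[k] / corr1) / (np.sqrt(state.v[k] / corr2) + state.eps)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_params(path: str | Path, params: dict[str, np.ndarray], config: CrnnConfig,
                trace: ShapeTrace | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with the config and shape trace."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **params)
    sidecar = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(config).items()},
        "shape_trace": None if trace is None else {"shapes": trace.shapes, "T1": trace.T1},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_params(path: str | Path) -> tuple[dict[str, np.ndarray], CrnnConfig]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k].copy() for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text())["config"]
    meta["fc_sizes"] = tuple(meta["fc_sizes"])
    return params, CrnnConfig(**meta)
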