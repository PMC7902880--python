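"""Sparsity-regularized stacked autoencoder with a SoftMax head.

A single sparse autoencoder layer maps an input vector x through a logistic
encoder h = sigma(W_e x + b_e) and decodes it back with y = sigma(W_d h + b_d).
Training minimizes

    K(W, b) = 1/(2p) * sum_i ||x_i - y_i||^2
              + lambda/2 * (||W_e||^2 + ||W_d||^2)
              + beta * sum_j KL(rho || rho_hat_j)

where p is the batch size, rho_hat_j is the mean activation of hidden unit j
over the batch, and KL is the Bernoulli relative entropy that drives hidden
units toward a low target activation rho (most units suppressed, a few
selectively active).  Layers are stacked greedily: each layer is trained,
unsupervised, on the encoded output of the previous one; a SoftMax head is
then attached and the whole network fine-tuned on a (small) labelled batch.
All optimization is deterministic full-batch limited-memory quasi-Newton
(L-BFGS), so runs are exactly reproducible from a seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

__all__ = [
    "SAEHyper",
    "SAELayer",
    "StackedSAE",
    "TrainReport",
    "SAEError",
    "DimensionMismatchError",
    "OptimizerDivergenceError",
    "encode",
    "decode",
    "reconstruction_loss",
    "mean_activation",
    "kl_penalty",
    "sae_objective",
    "layer_gradients",
    "train_layer",
    "greedy_pretrain",
    "attach_and_finetune",
    "classify",
    "classify_batch",
    "features",
    "save_stack",
    "load_stack",
]

#: clamp applied to mean activations before taking logs
RHO_EPS = 1e-8

MODEL_FORMAT_VERSION = 1


class SAEError(Exception):
    """Base class for autoencoder errors."""


class DimensionMismatchError(SAEError):
    """Input shape is inconsistent with the layer/stack dimensions."""


class OptimizerDivergenceError(SAEError):
    """The objective became non-finite during training."""

    def __init__(self, message: str, report: "TrainReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass(frozen=True)
class SAEHyper:
    """Hyperparameters of one sparse autoencoder layer.

    lambda_decay : weight-decay coefficient lambda (>= 0)
    beta_sparsity: weight beta of the KL sparsity penalty (>= 0)
    rho_target   : target mean activation rho, strictly inside (0, 1)
    max_iter     : L-BFGS iteration cap
    seed         : weight-initialization seed
    """

    lambda_decay: float = 1e-4
    beta_sparsity: float = 3.0
    rho_target: float = 0.05
    max_iter: int = 400
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.rho_target < 1.0):
            raise ValueError(f"rho_target must lie strictly in (0,1), got {self.rho_target}")
        for name in ("lambda_decay", "beta_sparsity"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.max_iter < 0:
            raise ValueError("max_iter must be >= 0")


@dataclass
class SAELayer:
    """Encoder/decoder weight pair of one sparse autoencoder layer."""

    W_enc: np.ndarray  # (d_hidden, d_in)
    b_enc: np.ndarray  # (d_hidden,)
    W_dec: np.ndarray  # (d_in, d_hidden)
    b_dec: np.ndarray  # (d_in,)
    hyper: SAEHyper = field(default_factory=SAEHyper)

    def __post_init__(self):
        h, d = self.W_enc.shape
        if self.W_dec.shape != (d, h) or self.b_enc.shape != (h,) or self.b_dec.shape != (d,):
            raise DimensionMismatchError("inconsistent layer shapes")
        for a in (self.W_enc, self.b_enc, self.W_dec, self.b_dec):
            if not np.all(np.isfinite(a)):
                raise ValueError("layer weights must be finite")

    @property
    def d_in(self) -> int:
        return self.W_enc.shape[1]

    @property
    def d_hidden(self) -> int:
        return self.W_enc.shape[0]


@dataclass
class TrainReport:
    """Objective trajectory of one optimization run."""

    objectives: list[float]
    final_objective: float
    converged: bool
    iterations: int


@dataclass
class StackedSAE:
    """Greedily pretrained encoder stack plus optional SoftMax head."""

    layers: list[SAELayer]
    softmax_W: np.ndarray | None = None  # (n_classes, d_feat)
    softmax_b: np.ndarray | None = None  # (n_classes,)
    class_names: tuple[str, ...] = ()

    def __post_init__(self):
        for prev, nxt in zip(self.layers, self.layers[1:]):
            if nxt.d_in != prev.d_hidden:
                raise DimensionMismatchError(
                    f"layer input dim {nxt.d_in} != previous hidden dim {prev.d_hidden}"
                )

    @property
    def d_in(self) -> int:
        return self.layers[0].d_in

    @property
    def d_feat(self) -> int:
        return self.layers[-1].d_hidden

    @property
    def has_head(self) -> bool:
        return self.softmax_W is not None


def _as_batch(X: np.ndarray, d_in: int) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != d_in:
        raise DimensionMismatchError(f"expected input dim {d_in}, got {X.shape[1]}")
    return X


def encode(layer: SAELayer, X: np.ndarray) -> np.ndarray:
    """Hidden activations sigma(W_e x + b_e), one row per sample."""
    X = _as_batch(X, layer.d_in)
    return expit(X @ layer.W_enc.T + layer.b_enc)


def decode(layer: SAELayer, H: np.ndarray) -> np.ndarray:
    """Reconstruction sigma(W_d h + b_d), one row per sample."""
    H = _as_batch(H, layer.d_hidden)
    return expit(H @ layer.W_dec.T + layer.b_dec)


def reconstruction_loss(layer: SAELayer, X: np.ndarray) -> float:
    """Data term plus weight-decay term of the layer objective (no sparsity)."""
    X = _as_batch(X, layer.d_in)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    Y = decode(layer, encode(layer, X))
    p = X.shape[0]
    data = np.sum((X - Y) ** 2) / (2.0 * p)
    lam = layer.hyper.lambda_decay
    decay = 0.5 * lam * (np.sum(layer.W_enc**2) + np.sum(layer.W_dec**2))
    return float(data + decay)


def mean_activation(layer: SAELayer, X: np.ndarray) -> np.ndarray:
    """Per-hidden-unit mean activation rho_hat over the batch."""
    X = _as_batch(X, layer.d_in)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    return encode(layer, X).mean(axis=0)


def kl_penalty(rho: float, rho_hat: np.ndarray) -> float:
    """Bernoulli relative entropy sum_j KL(rho || rho_hat_j).

    rho_hat entries are clamped into [RHO_EPS, 1-RHO_EPS] before the logs.
    Nonnegative; zero iff every rho_hat_j equals rho.
    """
    if not (0.0 < rho < 1.0):
        raise ValueError(f"rho must lie strictly in (0,1), got {rho}")
    r = np.clip(np.asarray(rho_hat, dtype=float), RHO_EPS, 1.0 - RHO_EPS)
    return float(np.sum(rho * np.log(rho / r) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - r))))


def sae_objective(layer: SAELayer, X: np.ndarray) -> float:
    """Full training objective: reconstruction + decay + beta * KL."""
    h = layer.hyper
    return reconstruction_loss(layer, X) + h.beta_sparsity * kl_penalty(
        h.rho_target, mean_activation(layer, X)
    )


def layer_gradients(layer: SAELayer, X: np.ndarray) -> dict[str, np.ndarray]:
    """Analytic gradients of the full objective w.r.t. all layer parameters.

    Backpropagation with the sparsity correction in the hidden delta:
    delta_hidden = (W_d^T delta_out + beta/p * (-rho/rho_hat + (1-rho)/(1-rho_hat)))
                   * h * (1 - h)
    """
    X = _as_batch(X, layer.d_in)
    p = X.shape[0]
    if p == 0:
        raise ValueError("empty batch")
    hyp = layer.hyper
    A = encode(layer, X)  # (p, h)
    Y = decode(layer, A)  # (p, d)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(Y))):
        raise OptimizerDivergenceError("non-finite activations in forward pass")

    delta_out = ((Y - X) / p) * Y * (1.0 - Y)  # (p, d)
    gW_dec = delta_out.T @ A + hyp.lambda_decay * layer.W_dec
    gb_dec = delta_out.sum(axis=0)

    rho_hat = np.clip(A.mean(axis=0), RHO_EPS, 1.0 - RHO_EPS)
    sparsity = (hyp.beta_sparsity / p) * (
        -hyp.rho_target / rho_hat + (1.0 - hyp.rho_target) / (1.0 - rho_hat)
    )
    dA = delta_out @ layer.W_dec + sparsity  # broadcast over rows
    delta_hid = dA * A * (1.0 - A)
    gW_enc = delta_hid.T @ X + hyp.lambda_decay * layer.W_enc
    gb_enc = delta_hid.sum(axis=0)
    return {"W_enc": gW_enc, "b_enc": gb_enc, "W_dec": gW_dec, "b_dec": gb_dec}


# ---------------------------------------------------------------------------
# layer training


def _init_layer(d_in: int, d_hidden: int, hyper: SAEHyper, seed=None) -> SAELayer:
    # uniform +-sqrt(6/(d_in+d_hidden)) fan-based init, zero biases
    rng = np.random.default_rng(hyper.seed if seed is None else seed)
    r = np.sqrt(6.0 / (d_in + d_hidden))
    return SAELayer(
        W_enc=rng.uniform(-r, r, size=(d_hidden, d_in)),
        b_enc=np.zeros(d_hidden),
        W_dec=rng.uniform(-r, r, size=(d_in, d_hidden)),
        b_dec=np.zeros(d_in),
        hyper=hyper,
    )


def _pack(layer: SAELayer) -> np.ndarray:
    return np.concatenate(
        [layer.W_enc.ravel(), layer.b_enc, layer.W_dec.ravel(), layer.b_dec]
    )


def _unpack(theta: np.ndarray, d_in: int, d_hidden: int, hyper: SAEHyper) -> SAELayer:
    n1 = d_hidden * d_in
    W_enc = theta[:n1].reshape(d_hidden, d_in)
    b_enc = theta[n1 : n1 + d_hidden]
    n2 = n1 + d_hidden
    W_dec = theta[n2 : n2 + n1].reshape(d_in, d_hidden)
    b_dec = theta[n2 + n1 :]
    return SAELayer(W_enc.copy(), b_enc.copy(), W_dec.copy(), b_dec.copy(), hyper)


def train_layer(
    X: np.ndarray, d_hidden: int, hyper: SAEHyper, seed=None
) -> tuple[SAELayer, TrainReport]:
    """Train one sparse autoencoder layer by full-batch L-BFGS.

    Deterministic given (X, hyper, seed); with max_iter=0 the seeded
    initialization is returned untouched.
    """
    if d_hidden < 1:
        raise ValueError("d_hidden must be >= 1")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    d_in = X.shape[1]
    layer0 = _init_layer(d_in, d_hidden, hyper, seed=seed)
    if hyper.max_iter == 0:
        return layer0, TrainReport([], sae_objective(layer0, X), False, 0)

    trace: list[float] = []

    def fun(theta):
        lay = _unpack(theta, d_in, d_hidden, hyper)
        obj = sae_objective(lay, X)
        g = layer_gradients(lay, X)
        grad = np.concatenate(
            [g["W_enc"].ravel(), g["b_enc"], g["W_dec"].ravel(), g["b_dec"]]
        )
        return obj, grad

    def cb(theta):
        lay = _unpack(theta, d_in, d_hidden, hyper)
        trace.append(sae_objective(lay, X))

    res = minimize(
        fun,
        _pack(layer0),
        jac=True,
        method="L-BFGS-B",
        callback=cb,
        options={"maxiter": hyper.max_iter, "maxcor": 20},
    )
    layer = _unpack(res.x, d_in, d_hidden, hyper)
    report = TrainReport(trace, float(res.fun), bool(res.success), int(res.nit))
    if not np.isfinite(res.fun):
        raise OptimizerDivergenceError("objective became non-finite", report)
    return layer, report


def greedy_pretrain(
    X: np.ndarray,
    hidden_dims: tuple[int, ...] = (120, 60, 30, 15),
    hyper: SAEHyper | None = None,
) -> StackedSAE:
    """Layer-wise unsupervised pretraining: layer k trains on the encoded
    output of layers 1..k-1.  No labels are used anywhere."""
    hyper = hyper or SAEHyper()
    if not all(b < a for a, b in zip(hidden_dims, hidden_dims[1:])):
        warnings.warn("hidden_dims are not strictly decreasing", stacklevel=2)
    layers: list[SAELayer] = []
    cur = np.atleast_2d(np.asarray(X, dtype=float))
    for k, dh in enumerate(hidden_dims):
        layer, _ = train_layer(cur, dh, hyper, seed=[hyper.seed, k])
        layers.append(layer)
        cur = encode(layer, cur)
    return StackedSAE(layers=layers)


# ---------------------------------------------------------------------------
# stack forward pass, head and fine-tuning


def features(stack: StackedSAE, X: np.ndarray) -> np.ndarray:
    """Deep features: input propagated through every encoder."""
    H = _as_batch(X, stack.d_in)
    for layer in stack.layers:
        H = encode(layer, H)
    return H


def _forward_all(stack, W_encs, b_encs, X):
    acts = [X]
    H = X
    for W, b in zip(W_encs, b_encs):
        H = expit(H @ W.T + b)
        acts.append(H)
    return acts


def _softmax(Z):
    return np.exp(Z - logsumexp(Z, axis=1, keepdims=True))


def _finetune_objective(theta, shapes, X, Yhot, lam):
    W_encs, b_encs, W_head, b_head = _unpack_stack(theta, shapes)
    n = X.shape[0]
    acts = _forward_all(None, W_encs, b_encs, X)
    F = acts[-1]
    Z = F @ W_head.T + b_head
    logP = Z - logsumexp(Z, axis=1, keepdims=True)
    ce = -np.sum(Yhot * logP) / n
    decay = 0.5 * lam * (sum(np.sum(W**2) for W in W_encs) + np.sum(W_head**2))
    obj = ce + decay

    P = np.exp(logP)
    G = (P - Yhot) / n
    gW_head = G.T @ F + lam * W_head
    gb_head = G.sum(axis=0)
    dH = G @ W_head
    gWs, gbs = [], []
    for k in range(len(W_encs) - 1, -1, -1):
        H = acts[k + 1]
        delta = dH * H * (1.0 - H)
        gWs.append(delta.T @ acts[k] + lam * W_encs[k])
        gbs.append(delta.sum(axis=0))
        dH = delta @ W_encs[k]
    gWs.reverse()
    gbs.reverse()
    grad = np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in zip(gWs, gbs)]
        + [gW_head.ravel(), gb_head]
    )
    return obj, grad


def _pack_stack(W_encs, b_encs, W_head, b_head):
    return np.concatenate(
        [np.concatenate([W.ravel(), b]) for W, b in zip(W_encs, b_encs)]
        + [W_head.ravel(), b_head]
    )


def _unpack_stack(theta, shapes):
    W_encs, b_encs = [], []
    i = 0
    enc_shapes, head_shape = shapes
    for h, d in enc_shapes:
        W_encs.append(theta[i : i + h * d].reshape(h, d))
        i += h * d
        b_encs.append(theta[i : i + h])
        i += h
    c, f = head_shape
    W_head = theta[i : i + c * f].reshape(c, f)
    i += c * f
    b_head = theta[i : i + c]
    return W_encs, b_encs, W_head, b_head


def attach_and_finetune(
    stack: StackedSAE,
    X: np.ndarray,
    labels,
    hyper: SAEHyper | None = None,
    class_names: tuple[str, ...] | None = None,
) -> tuple[StackedSAE, TrainReport]:
    """Attach a SoftMax head and fine-tune the whole network jointly.

    The head is first fitted alone (convex SoftMax regression on the frozen
    deep features), then every encoder weight and the head are optimized
    together by L-BFGS on cross-entropy + lambda/2 * sum ||W||^2.
    """
    hyper = hyper or (stack.layers[0].hyper if stack.layers else SAEHyper())
    X = _as_batch(X, stack.d_in)
    labels = np.asarray(labels)
    if class_names is None:
        class_names = tuple(sorted(set(labels.tolist())))
    if len(set(labels.tolist())) < 2:
        raise ValueError("at least 2 classes must be present in labels")
    idx = {c: i for i, c in enumerate(class_names)}
    y = np.array([idx[v] for v in labels.tolist()])
    n_classes = len(class_names)
    Yhot = np.zeros((len(y), n_classes))
    Yhot[np.arange(len(y)), y] = 1.0
    lam = hyper.lambda_decay

    F = features(stack, X)
    # head-only convex fit from zero init
    def head_fun(theta):
        W = theta[: n_classes * F.shape[1]].reshape(n_classes, F.shape[1])
        b = theta[n_classes * F.shape[1] :]
        Z = F @ W.T + b
        logP = Z - logsumexp(Z, axis=1, keepdims=True)
        obj = -np.sum(Yhot * logP) / len(y) + 0.5 * lam * np.sum(W**2)
        G = (np.exp(logP) - Yhot) / len(y)
        return obj, np.concatenate([(G.T @ F + lam * W).ravel(), G.sum(axis=0)])

    res_head = minimize(
        head_fun,
        np.zeros(n_classes * (F.shape[1] + 1)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max(hyper.max_iter, 100)},
    )
    W_head = res_head.x[: n_classes * F.shape[1]].reshape(n_classes, F.shape[1])
    b_head = res_head.x[n_classes * F.shape[1] :]

    W_encs = [lay.W_enc.copy() for lay in stack.layers]
    b_encs = [lay.b_enc.copy() for lay in stack.layers]
    shapes = ([(W.shape[0], W.shape[1]) for W in W_encs], (n_classes, F.shape[1]))
    theta0 = _pack_stack(W_encs, b_encs, W_head, b_head)

    trace: list[float] = []

    def cb(theta):
        trace.append(_finetune_objective(theta, shapes, X, Yhot, lam)[0])

    if hyper.max_iter > 0:
        res = minimize(
            _finetune_objective,
            theta0,
            args=(shapes, X, Yhot, lam),
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": hyper.max_iter, "maxcor": 20},
        )
        theta = res.x
        final, converged, nit = float(res.fun), bool(res.success), int(res.nit)
    else:
        theta = theta0
        final, converged, nit = float(_finetune_objective(theta0, shapes, X, Yhot, lam)[0]), False, 0
    if not np.isfinite(final):
        raise OptimizerDivergenceError(
            "fine-tune objective became non-finite", TrainReport(trace, final, False, nit)
        )
    W_encs, b_encs, W_head, b_head = _unpack_stack(theta, shapes)
    new_layers = [
        replace(lay, W_enc=W.copy(), b_enc=b.copy())
        for lay, W, b in zip(stack.layers, W_encs, b_encs)
    ]
    tuned = StackedSAE(
        layers=new_layers,
        softmax_W=W_head.copy(),
        softmax_b=b_head.copy(),
        class_names=tuple(class_names),
    )
    return tuned, TrainReport(trace, final, converged, nit)


def classify_batch(stack: StackedSAE, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and class-probability rows for a batch."""
    if not stack.has_head:
        raise SAEError("stack has no SoftMax head attached")
    F = features(stack, X)
    Z = F @ stack.softmax_W.T + stack.softmax_b
    P = _softmax(Z)
    # np.argmax returns the first (lowest-index) maximum: documented tie-break
    pred = np.argmax(P, axis=1)
    names = np.array(stack.class_names)
    return names[pred], P


def classify(stack: StackedSAE, x: np.ndarray) -> tuple[str, np.ndarray]:
    """Classify one vector; returns (label, probability vector)."""
    labels, P = classify_batch(stack, np.atleast_2d(x))
    return str(labels[0]), P[0]


# ---------------------------------------------------------------------------
# serialization (single portable .npz file, bit-exact round trip)


def save_stack(stack: StackedSAE, path) -> None:
    arrays = {}
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_layers": len(stack.layers),
        "class_names": list(stack.class_names),
        "has_head": stack.has_head,
        "hyper": [
            {
                "lambda_decay": lay.hyper.lambda_decay,
                "beta_sparsity": lay.hyper.beta_sparsity,
                "rho_target": lay.hyper.rho_target,
                "max_iter": lay.hyper.max_iter,
                "seed": lay.hyper.seed,
            }
            for lay in stack.layers
        ],
    }
    for k, lay in enumerate(stack.layers):
        arrays[f"W_enc_{k}"] = lay.W_enc
        arrays[f"b_enc_{k}"] = lay.b_enc
        arrays[f"W_dec_{k}"] = lay.W_dec
        arrays[f"b_dec_{k}"] = lay.b_dec
    if stack.has_head:
        arrays["softmax_W"] = stack.softmax_W
        arrays["softmax_b"] = stack.softmax_b
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_stack(path) -> StackedSAE:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise SAEError(f"unsupported model format version {meta['format_version']}")
        layers = []
        for k in range(meta["n_layers"]):
            h = meta["hyper"][k]
            layers.append(
                SAELayer(
                    z[f"W_enc_{k}"],
                    z[f"b_enc_{k}"],
                    z[f"W_dec_{k}"],
                    z[f"b_dec_{k}"],
                    SAEHyper(**h),
                )
            )
        head_W = z["softmax_W"] if meta["has_head"] else None
        head_b = z["softmax_b"] if meta["has_head"] else None
    return StackedSAE(
        layers=layers,
        softmax_W=head_W,
        softmax_b=head_b,
        class_names=tuple(meta["class_names"]),
    )
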