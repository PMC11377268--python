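"""Layer DAG, the three CNN architectures, and training.

A :class:`LayerGraph` is the single representation that the forward pass,
the Adam/backprop trainer and the relevance engine all operate on: an
ordered DAG of typed layers with exactly one input node and one softmax
output node. Gait windows of shape (frames, channels) enter as
single-feature-map images ``(frames, channels, 1)``.

Training minimizes categorical cross-entropy with Adam (defaults
alpha=0.002, beta1=0.9, beta2=0.999, eps=1e-8, batch 100, 200 epochs),
Glorot-uniform weight initialization with zero biases, and is
deterministic under a fixed seed on a fixed platform.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import h5py
import numpy as np

from .data import GaitDataset
from .layers import (
    AvgPool, BatchNorm, Concat, Conv2D, Dense, Dropout, Flatten, Input, Layer,
    MaxPool, Softmax,
)

__all__ = [
    "LayerGraph", "TrainingConfig", "TrainedModel", "build_architecture",
    "train", "LSTMClassifier",
]

ARCHITECTURES = ("single", "parallel", "quadruplet")


class LayerGraph:
    """Ordered DAG of typed layers.

    Nodes are added in topological order; every node except concat has
    exactly one parent. The graph ends in a softmax node whose parent's
    activations are the pre-softmax class scores f_c(x).
    """

    def __init__(self, architecture_name: str = "custom",
                 output_classes: Optional[Sequence] = None) -> None:
        self.architecture_name = architecture_name
        self.output_classes = list(output_classes) if output_classes else []
        self.layers: Dict[str, Layer] = {}
        self.parents: Dict[str, List[str]] = {}
        self.order: List[str] = []

    def add(self, name: str, layer: Layer, parents: Optional[Sequence[str]] = None) -> str:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        parents = list(parents) if parents is not None else ([self.order[-1]] if self.order else [])
        for p in parents:
            if p not in self.layers:
                raise ValueError(f"unknown parent {p!r} for layer {name!r}")
        if layer.kind == "concat" and len(parents) < 2:
            raise ValueError("concat nodes need >= 2 parents")
        if layer.kind != "concat" and layer.kind != "input" and len(parents) != 1:
            raise ValueError(f"layer {name!r} must have exactly 1 parent")
        layer.infer_shape([self.layers[p].out_shape for p in parents] or [None])
        self.layers[name] = layer
        self.parents[name] = parents
        self.order.append(name)
        return name

    # -- structure ---------------------------------------------------------
    @property
    def input_name(self) -> str:
        names = [n for n in self.order if self.layers[n].kind == "input"]
        if len(names) != 1:
            raise ValueError("graph must have exactly one input node")
        return names[0]

    @property
    def output_name(self) -> str:
        names = [n for n in self.order if self.layers[n].kind == "softmax"]
        if len(names) != 1:
            raise ValueError("graph must have exactly one softmax output node")
        return names[0]

    @property
    def logit_name(self) -> str:
        return self.parents[self.output_name][0]

    def children(self) -> Dict[str, List[str]]:
        ch: Dict[str, List[str]] = {n: [] for n in self.order}
        for n, ps in self.parents.items():
            for p in ps:
                ch[p].append(n)
        return ch

    def stacked_layer_count(self) -> int:
        """Count of conv/pool/dense layers (the architecture-size tally)."""
        return sum(1 for n in self.order if self.layers[n].stacked)

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.layers.values())

    def init_params(self, rng: np.random.Generator) -> None:
        for name in self.order:
            self.layers[name].init_params(rng)

    # -- execution ---------------------------------------------------------
    def forward(self, x: np.ndarray, mode: str = "eval",
                rng: Optional[np.random.Generator] = None,
                ) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
        """Run the graph; returns (logits, probabilities, activations)."""
        acts: Dict[str, np.ndarray] = {}
        for name in self.order:
            layer = self.layers[name]
            if layer.kind == "input":
                inputs = [x]
            else:
                inputs = [acts[p] for p in self.parents[name]]
            acts[name] = layer.forward(inputs, mode=mode, rng=rng)
        return acts[self.logit_name], acts[self.output_name], acts

    def backward(self, dlogits: np.ndarray, relu_mode: str = "grad") -> np.ndarray:
        """Backpropagate from the pre-softmax scores; returns d(input).

        Must be called directly after ``forward`` (layers cache their
        activations). Parameter gradients are accumulated on the layers.
        """
        douts: Dict[str, np.ndarray] = {self.logit_name: dlogits}
        for name in reversed(self.order):
            if name == self.output_name or name not in douts:
                continue
            layer = self.layers[name]
            if layer.kind == "input":
                continue
            dins = layer.backward(douts.pop(name), relu_mode=relu_mode)
            for p, d in zip(self.parents[name], dins):
                if p in douts:
                    douts[p] = douts[p] + d
                else:
                    douts[p] = d
        return douts.get(self.input_name, None)

    def parameters(self) -> List[Tuple[str, str, np.ndarray]]:
        out = []
        for name in self.order:
            for pname, arr in self.layers[name].params.items():
                out.append((name, pname, arr))
        return out


# ---------------------------------------------------------------------------
# architectures

def _scaled(filters: Sequence[int], scale: float) -> List[int]:
    return [max(1, int(round(f * scale))) for f in filters]


def build_architecture(
    name: str,
    input_shape: Tuple[int, int],
    n_classes: int,
    hyperparams: Optional[Dict] = None,
) -> LayerGraph:
    """Build one of the three CNN classifiers.

    ``single``: four conv+avgpool blocks and two dense layers (10 stacked
    layers). ``parallel``: an inception-style net — a conv/pool stem, two
    stages of two parallel (1xk then kx1 conv, pool) streams fused by
    concatenation with a 1x1 conv after each fusion, then two dense layers
    (18 stacked layers). ``quadruplet``: four parallel streams with
    independent parameters (two max-pool paths, two average-pool paths)
    concatenated into a dense head. All heads apply batchnorm then dropout
    after the flatten, and end in softmax.

    ``input_shape`` is (frames, channels); the window enters as a
    single-feature-map image. ``hyperparams`` may override ``scale``
    (filter-count multiplier), ``dense_width``, ``dropout`` and ``kernel``.
    """
    hp = dict(hyperparams or {})
    scale = hp.get("scale", 1.0)
    dense_width = hp.get("dense_width", 64)
    drop = hp.get("dropout", 0.3)
    k = hp.get("kernel", 3)
    h, w = input_shape
    g = LayerGraph(architecture_name=name, output_classes=list(range(n_classes)))
    g.add("input", Input((h, w, 1)))

    if name == "single":
        filters = _scaled(hp.get("filters", (16, 32, 64, 64)), scale)
        prev = "input"
        for i, f in enumerate(filters):
            prev = g.add(f"conv{i}", Conv2D(f, (k, k)), [prev])
            prev = g.add(f"pool{i}", AvgPool((2, 2)), [prev])
        prev = g.add("flatten", Flatten(), [prev])
        prev = g.add("bn", BatchNorm(), [prev])
        prev = g.add("drop", Dropout(drop), [prev])
        prev = g.add("fc0", Dense(dense_width, "relu"), [prev])
        prev = g.add("logits", Dense(n_classes, "linear"), [prev])
    elif name == "parallel":
        f_stem, f_stream = _scaled(hp.get("filters", (16, 16)), scale)
        prev = g.add("stem_conv", Conv2D(f_stem, (k, k)), ["input"])
        prev = g.add("stem_pool", AvgPool((2, 2)), [prev])
        for stage in range(2):
            ends = []
            for s in range(2):
                kern = (1, k) if s == 0 else (k, 1)
                a = g.add(f"s{stage}_{s}_conv0", Conv2D(f_stream, kern), [prev])
                a = g.add(f"s{stage}_{s}_conv1", Conv2D(f_stream, kern[::-1]), [a])
                a = g.add(f"s{stage}_{s}_pool", AvgPool((2, 2)), [a])
                ends.append(a)
            prev = g.add(f"s{stage}_concat", Concat(), ends)
            prev = g.add(f"s{stage}_fuse", Conv2D(f_stream, (1, 1)), [prev])
        prev = g.add("flatten", Flatten(), [prev])
        prev = g.add("bn", BatchNorm(), [prev])
        prev = g.add("drop", Dropout(drop), [prev])
        prev = g.add("fc0", Dense(dense_width, "relu"), [prev])
        prev = g.add("logits", Dense(n_classes, "linear"), [prev])
    elif name == "quadruplet":
        f = _scaled(hp.get("filters", (16,)), scale)[0]
        ends = []
        for s in range(4):
            pool_cls = MaxPool if s < 2 else AvgPool
            a = g.add(f"q{s}_conv0", Conv2D(f, (k, k)), ["input"])
            a = g.add(f"q{s}_pool0", pool_cls((2, 2)), [a])
            a = g.add(f"q{s}_conv1", Conv2D(f, (k, k)), [a])
            a = g.add(f"q{s}_pool1", pool_cls((2, 2)), [a])
            ends.append(a)
        prev = g.add("concat", Concat(), ends)
        prev = g.add("flatten", Flatten(), [prev])
        prev = g.add("bn", BatchNorm(), [prev])
        prev = g.add("drop", Dropout(drop), [prev])
        prev = g.add("fc0", Dense(dense_width, "relu"), [prev])
        prev = g.add("logits", Dense(n_classes, "linear"), [prev])
    else:
        raise ValueError(f"unknown architecture {name!r}; expected one of {ARCHITECTURES}")

    g.add("softmax", Softmax(), [prev])
    return g


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    """Adam / categorical-cross-entropy training settings."""

    learning_rate: float = 0.002
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    batch_size: int = 100
    epochs: int = 200
    seed: int = 0
    shuffle: bool = True
    #: numerical precision of the fit ("float64" or "float32"; single
    #: precision roughly halves training time at negligible accuracy cost)
    dtype: str = "float64"


@dataclass
class TrainedModel:
    """A trained LayerGraph together with its training provenance."""

    graph: LayerGraph
    config: TrainingConfig
    history: Dict[str, List[float]] = field(default_factory=dict)
    classes: List = field(default_factory=list)

    def _as_input(self, X: np.ndarray) -> np.ndarray:
        if X.ndim == 3:
            return X[..., None]
        return X

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._as_input(np.asarray(X, dtype=float))
        out = []
        for i in range(0, X.shape[0], batch_size):
            _, probs, _ = self.graph.forward(X[i : i + batch_size], mode="eval")
            out.append(probs)
        return np.concatenate(out) if out else np.empty((0, len(self.classes)))

    def predict_indices(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size).argmax(axis=1)

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        idx = self.predict_indices(X, batch_size)
        return np.array([self.classes[i] for i in idx], dtype=object)

    def accuracy(self, X: np.ndarray, labels: Sequence) -> float:
        pred = self.predict(X)
        return float(np.mean([p == l for p, l in zip(pred, labels)]))

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        g = self.graph
        topo = {
            "architecture_name": g.architecture_name,
            "order": g.order,
            "parents": g.parents,
            "specs": {
                n: {
                    "kind": g.layers[n].kind,
                    "spec": _layer_spec(g.layers[n]),
                }
                for n in g.order
            },
            "classes": [json.dumps(c) for c in self.classes],
            "config": asdict(self.config),
            "history": self.history,
        }
        with h5py.File(path, "w") as f:
            f.attrs["topology"] = json.dumps(topo)
            for name, pname, arr in g.parameters():
                f.create_dataset(f"params/{name}/{pname}", data=arr)
            for n in g.order:
                layer = g.layers[n]
                if isinstance(layer, BatchNorm):
                    f.create_dataset(f"moments/{n}/mean", data=layer.running_mean)
                    f.create_dataset(f"moments/{n}/var", data=layer.running_var)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with h5py.File(path, "r") as f:
            topo = json.loads(f.attrs["topology"])
            g = LayerGraph(architecture_name=topo["architecture_name"])
            for n in topo["order"]:
                info = topo["specs"][n]
                layer = _layer_from_spec(info["kind"], info["spec"])
                g.add(n, layer, topo["parents"][n] or None)
            for n in g.order:
                layer = g.layers[n]
                if f"params/{n}" in f:
                    for pname in f[f"params/{n}"]:
                        layer.params[pname] = f[f"params/{n}/{pname}"][:]
                if isinstance(layer, BatchNorm):
                    layer.running_mean = f[f"moments/{n}/mean"][:]
                    layer.running_var = f[f"moments/{n}/var"][:]
            classes = [json.loads(c) for c in topo["classes"]]
            model = cls(
                graph=g,
                config=TrainingConfig(**topo["config"]),
                history={k: list(v) for k, v in topo["history"].items()},
                classes=classes,
            )
            g.output_classes = classes
            return model


def _layer_spec(layer: Layer) -> Dict:
    if isinstance(layer, Input):
        return {"shape": list(layer.out_shape)}
    if isinstance(layer, Conv2D):
        return {"n_filters": layer.n_filters, "kernel": list(layer.kernel),
                "padding": layer.padding, "activation": layer.activation}
    if isinstance(layer, Dense):
        return {"width": layer.width, "activation": layer.activation}
    if isinstance(layer, (AvgPool, MaxPool)):
        return {"window": list(layer.window)}
    if isinstance(layer, Dropout):
        return {"rate": layer.rate}
    if isinstance(layer, BatchNorm):
        return {"momentum": layer.momentum, "eps": layer.eps}
    return {}


def _layer_from_spec(kind: str, spec: Dict) -> Layer:
    if kind == "input":
        return Input(tuple(spec["shape"]))
    if kind == "conv2d":
        return Conv2D(spec["n_filters"], tuple(spec["kernel"]),
                      padding=spec["padding"], activation=spec["activation"])
    if kind == "dense":
        return Dense(spec["width"], spec["activation"])
    if kind == "avgpool":
        return AvgPool(tuple(spec["window"]))
    if kind == "maxpool":
        return MaxPool(tuple(spec["window"]))
    if kind == "flatten":
        return Flatten()
    if kind == "concat":
        return Concat()
    if kind == "batchnorm":
        return BatchNorm(spec["momentum"], spec["eps"])
    if kind == "dropout":
        return Dropout(spec["rate"])
    if kind == "softmax":
        return Softmax()
    raise ValueError(f"unknown layer kind {kind!r}")


def _cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> Tuple[float, np.ndarray]:
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = logits.shape[0]
    loss = -logp[np.arange(n), y_idx].mean()
    probs = np.exp(logp)
    dlogits = probs.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return float(loss), dlogits / n


def train(
    graph: LayerGraph,
    dataset: GaitDataset,
    config: Optional[TrainingConfig] = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the graph on the dataset's train split with Adam.

    The dataset must carry train (and optionally val) split assignments and
    standardized values. Weights start from Glorot-uniform with zero bias;
    ``epochs=0`` returns the initialized, untrained model. Raises on
    non-finite loss.
    """
    config = config or TrainingConfig()
    rng_init = np.random.default_rng(config.seed)
    rng_shuffle = np.random.default_rng(config.seed + 1)
    rng_drop = np.random.default_rng(config.seed + 2)
    graph.init_params(rng_init)
    graph.output_classes = dataset.classes
    dtype = np.dtype(config.dtype)
    if dtype != np.float64:
        for lname in graph.order:
            layer = graph.layers[lname]
            layer.params = {k: v.astype(dtype) for k, v in layer.params.items()}

    y_all = dataset.label_indices()
    tr = dataset.split == "train"
    if not tr.any():
        raise ValueError("dataset has no train split")
    Xtr = dataset.values[tr][..., None].astype(dtype)
    ytr = y_all[tr]
    va = dataset.split == "val"
    Xva = dataset.values[va][..., None].astype(dtype) if va.any() else None
    yva = y_all[va] if va.any() else None

    model = TrainedModel(graph=graph, config=config, classes=list(dataset.classes),
                         history={"loss": [], "val_accuracy": []})

    # Adam state
    params = graph.parameters()
    m = [np.zeros_like(a) for _, _, a in params]
    v = [np.zeros_like(a) for _, _, a in params]
    t = 0
    n = Xtr.shape[0]
    for epoch in range(config.epochs):
        idx = np.arange(n)
        if config.shuffle:
            rng_shuffle.shuffle(idx)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            bidx = idx[start : start + config.batch_size]
            logits, _, _ = graph.forward(Xtr[bidx], mode="train", rng=rng_drop)
            loss, dlogits = _cross_entropy(logits, ytr[bidx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {n_batches}: {loss}"
                )
            graph.backward(dlogits)
            t += 1
            for i, (lname, pname, arr) in enumerate(params):
                ggrad = graph.layers[lname].grads[pname]
                m[i] = config.beta1 * m[i] + (1 - config.beta1) * ggrad
                v[i] = config.beta2 * v[i] + (1 - config.beta2) * ggrad**2
                mhat = m[i] / (1 - config.beta1**t)
                vhat = v[i] / (1 - config.beta2**t)
                arr -= config.learning_rate * mhat / (np.sqrt(vhat) + config.eps)
            epoch_loss += loss
            n_batches += 1
        model.history["loss"].append(epoch_loss / max(n_batches, 1))
        if Xva is not None:
            pred = model.predict_indices(Xva)
            model.history["val_accuracy"].append(float(np.mean(pred == yva)))
        if verbose:
            va_str = (
                f" val_acc={model.history['val_accuracy'][-1]:.3f}" if Xva is not None else ""
            )
            print(f"epoch {epoch + 1}/{config.epochs} loss={model.history['loss'][-1]:.4f}{va_str}")
    return model


# ---------------------------------------------------------------------------
# thin recurrent baseline

class LSTMClassifier:
    """Single-layer LSTM over (frames, channels) windows with a softmax head.

    A deliberately small comparison baseline (relevance propagation is not
    applied to it). Trained with the same Adam settings as the CNNs.
    """

    def __init__(self, n_units: int = 64, time_stride: int = 1) -> None:
        self.n_units = n_units
        self.time_stride = time_stride
        self.params: Dict[str, np.ndarray] = {}

    def _init(self, n_in: int, n_classes: int, rng: np.random.Generator) -> None:
        H = self.n_units
        fan = n_in + H
        self.params = {
            "W": _glorot_mat(rng, (fan, 4 * H)),
            "b": np.zeros(4 * H),
            "Wo": _glorot_mat(rng, (H, n_classes)),
            "bo": np.zeros(n_classes),
        }
        # forget-gate bias 1 (standard initialization)
        self.params["b"][self.n_units : 2 * self.n_units] = 1.0

    def _forward(self, X: np.ndarray):
        N, T, D = X.shape
        H = self.n_units
        W, b = self.params["W"], self.params["b"]
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        cache = []
        for t in range(T):
            zin = np.concatenate([X[:, t], h], axis=1)
            gates = zin @ W + b
            i = _sigmoid(gates[:, :H])
            f = _sigmoid(gates[:, H : 2 * H])
            o = _sigmoid(gates[:, 2 * H : 3 * H])
            g = np.tanh(gates[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            cache.append((zin, i, f, o, g, c, c_new))
            h, c = h_new, c_new
        logits = h @ self.params["Wo"] + self.params["bo"]
        return logits, h, cache

    def _backward(self, X: np.ndarray, dlogits: np.ndarray, h_last: np.ndarray, cache):
        N, T, D = X.shape
        H = self.n_units
        W = self.params["W"]
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["Wo"] = h_last.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ self.params["Wo"].T
        dc = np.zeros((N, H))
        for t in reversed(range(T)):
            zin, i, f, o, g, c_prev, c_new = cache[t]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc = dc * f
            dgates = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g**2)],
                axis=1,
            )
            grads["W"] += zin.T @ dgates
            grads["b"] += dgates.sum(axis=0)
            dzin = dgates @ W.T
            dh = dzin[:, D:]
        return grads

    def fit(self, dataset: GaitDataset, config: Optional[TrainingConfig] = None) -> "LSTMClassifier":
        config = config or TrainingConfig()
        self.classes = list(dataset.classes)
        rng = np.random.default_rng(config.seed)
        tr = dataset.split == "train"
        X = dataset.values[tr][:, :: self.time_stride, :]
        y = dataset.label_indices()[tr]
        self._init(X.shape[2], len(self.classes), rng)
        names = sorted(self.params)
        m = {k: np.zeros_like(self.params[k]) for k in names}
        v = {k: np.zeros_like(self.params[k]) for k in names}
        t = 0
        for _ in range(config.epochs):
            idx = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], config.batch_size):
                b = idx[start : start + config.batch_size]
                logits, h, cache = self._forward(X[b])
                loss, dlogits = _cross_entropy(logits, y[b])
                if not np.isfinite(loss):
                    raise RuntimeError(f"non-finite LSTM loss {loss}")
                grads = self._backward(X[b], dlogits, h, cache)
                t += 1
                for k in names:
                    m[k] = config.beta1 * m[k] + (1 - config.beta1) * grads[k]
                    v[k] = config.beta2 * v[k] + (1 - config.beta2) * grads[k] ** 2
                    self.params[k] -= config.learning_rate * (
                        m[k] / (1 - config.beta1**t)
                    ) / (np.sqrt(v[k] / (1 - config.beta2**t)) + config.eps)
        return self

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = np.asarray(X, dtype=float)[:, :: self.time_stride, :]
        preds = []
        for i in range(0, X.shape[0], batch_size):
            logits, _, _ = self._forward(X[i : i + batch_size])
            preds.append(logits.argmax(axis=1))
        idx = np.concatenate(preds) if preds else np.array([], dtype=int)
        return np.array([self.classes[i] for i in idx], dtype=object)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -40, 40)))


def _glorot_mat(rng: np.random.Generator, shape: Tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)
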