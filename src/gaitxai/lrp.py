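"""Layer-wise relevance propagation and gradient-based saliency.

The engine redistributes a chosen pre-softmax class score f_c(x) backward
through a trained layer graph onto the input window, under selectable
per-layer rules, following the conservation principle

    sum_i R_i<-j = sum_j R_j<-k = sum_k R_k = f_c(x).

Supported per-layer rules: epsilon (stabilized proportional
redistribution), alpha-beta (separate positive/negative contribution
shares; alpha=1/beta=0 is the z+ / deep-Taylor rule on ReLU networks),
flat (uniform redistribution over the receptive field) and the bounded
z^B box rule for input layers. Named composites mirror the usual toolkit
presets, including "LRP sequential preset A, flat" (epsilon on dense
layers, alpha1-beta0 on convolutions, flat at the input layer). Guided
backpropagation and deconvnet are provided as modified-ReLU gradient
backpasses.

Bias relevance is absorbed (denominators include the bias but inputs only
receive the a_j * w_jk shares), so conservation can leak through biases;
the leak is surfaced as ``conservation_residual`` rather than hidden.
Batch normalization is folded into the following dense layer's effective
weights before rules are applied. Max-pooling redirects relevance to the
argmax input of each window (ties to the first index); average pooling is
treated as a fixed uniform-weight convolution under the surrounding rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .graph import LayerGraph, TrainedModel, _layer_from_spec, _layer_spec
from .layers import (
    AvgPool, BatchNorm, Concat, Conv2D, Dense, Dropout, Flatten, Input,
    MaxPool, Softmax, conv2d_forward, conv_input_grad,
)

__all__ = [
    "EpsilonRule", "AlphaBetaRule", "FlatRule", "ZBoxRule", "RuleAssignment",
    "RelevanceMap", "make_ruleset", "explain", "explain_batch",
    "conservation_residual", "RULESET_NAMES",
]

RULESET_NAMES = (
    "deep_taylor", "deep_taylor_bounded", "deconvnet", "guided_backprop",
    "lrp_spf", "epsilon", "alphabeta", "flat",
)


# ---------------------------------------------------------------------------
# rules

@dataclass(frozen=True)
class EpsilonRule:
    """R_j = sum_k a_j w_jk / (z_k + eps*sign(z_k)) R_k, sign(0) = +1."""

    eps: float = 0.1

    def __post_init__(self):
        if self.eps < 0:
            raise ValueError("eps must be >= 0")


@dataclass(frozen=True)
class AlphaBetaRule:
    """Positive/negative pre-activation shares weighted alpha and -beta."""

    alpha: float = 1.0
    beta: float = 0.0

    def __post_init__(self):
        if abs(self.alpha - self.beta - 1.0) > 1e-12 or self.alpha < 1.0:
            raise ValueError("alpha - beta must equal 1 with alpha >= 1")


@dataclass(frozen=True)
class FlatRule:
    """Uniform redistribution over each unit's receptive field."""


@dataclass(frozen=True)
class ZBoxRule:
    """Bounded-input rule; low/high are the admissible input bounds."""

    low: float = 0.0
    high: float = 1.0

    def __post_init__(self):
        if not self.high > self.low:
            raise ValueError("high must exceed low")


Rule = Union[EpsilonRule, AlphaBetaRule, FlatRule, ZBoxRule]


@dataclass(frozen=True)
class RuleAssignment:
    """Per-layer-kind rule map for one composite method."""

    name: str
    dense: Rule = field(default_factory=lambda: EpsilonRule(0.1))
    conv: Rule = field(default_factory=lambda: AlphaBetaRule(1.0, 0.0))
    first_layer: Optional[Rule] = None
    #: gradient-based methods bypass the relevance rules entirely
    gradient_mode: Optional[str] = None  # None | "guided" | "deconvnet"

    def rule_for(self, kind: str, is_first: bool) -> Rule:
        if is_first and self.first_layer is not None:
            return self.first_layer
        if kind == "dense":
            return self.dense
        return self.conv


def make_ruleset(
    name: str,
    eps: float = 0.1,
    alpha: float = 1.0,
    input_bounds: Optional[Tuple[float, float]] = None,
) -> RuleAssignment:
    """Build a named composite rule assignment.

    ``lrp_spf``: epsilon on dense layers, alpha1-beta0 on convolutions,
    flat at the first layer. ``deep_taylor``: alpha1-beta0 (z+)
    everywhere. ``deep_taylor_bounded``: the same with the z^B box rule at
    the input layer (bounds default to (-3, 3), roughly the range of
    standardized inputs, and should be set to the observed min/max).
    ``guided_backprop`` / ``deconvnet``: modified-ReLU gradient backpasses.
    """
    ab = AlphaBetaRule(alpha, alpha - 1.0)
    if name == "lrp_spf":
        return RuleAssignment(name, dense=EpsilonRule(eps), conv=AlphaBetaRule(1.0, 0.0),
                              first_layer=FlatRule())
    if name == "deep_taylor":
        return RuleAssignment(name, dense=AlphaBetaRule(1.0, 0.0), conv=AlphaBetaRule(1.0, 0.0))
    if name == "deep_taylor_bounded":
        lo, hi = input_bounds if input_bounds is not None else (-3.0, 3.0)
        return RuleAssignment(name, dense=AlphaBetaRule(1.0, 0.0), conv=AlphaBetaRule(1.0, 0.0),
                              first_layer=ZBoxRule(lo, hi))
    if name == "epsilon":
        return RuleAssignment(name, dense=EpsilonRule(eps), conv=EpsilonRule(eps))
    if name == "alphabeta":
        return RuleAssignment(name, dense=ab, conv=ab)
    if name == "flat":
        return RuleAssignment(name, dense=FlatRule(), conv=FlatRule(),
                              first_layer=FlatRule())
    if name == "guided_backprop":
        return RuleAssignment(name, gradient_mode="guided")
    if name == "deconvnet":
        return RuleAssignment(name, gradient_mode="deconvnet")
    raise ValueError(f"unknown ruleset {name!r}; expected one of {RULESET_NAMES}")


# ---------------------------------------------------------------------------
# relevance map

@dataclass
class RelevanceMap:
    """Per-input relevance of one (batch of) sample(s) for one class."""

    scores: np.ndarray  # (T, C) or (N, T, C)
    target_class: object
    rule: RuleAssignment
    f_c: Union[float, np.ndarray]
    conservation_residual: Union[float, np.ndarray]
    residual_is_absolute: bool = False


def conservation_residual(rmap: RelevanceMap) -> Union[float, np.ndarray]:
    """Relative deviation |sum_i R_i - f_c| / |f_c| (absolute when f_c=0)."""
    total = rmap.scores.reshape(np.shape(rmap.f_c) + (-1,)).sum(axis=-1) \
        if np.ndim(rmap.f_c) else rmap.scores.sum()
    dev = np.abs(total - rmap.f_c)
    fc = np.abs(rmap.f_c)
    if np.ndim(fc) == 0:
        return float(dev if fc == 0 else dev / fc)
    out = np.where(fc == 0, dev, dev / np.where(fc == 0, 1.0, fc))
    return out


# ---------------------------------------------------------------------------
# per-layer relevance backward

def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.divide(num, den, out=np.zeros_like(num), where=den != 0)


def _stab(z: np.ndarray, eps: float) -> np.ndarray:
    sign = np.where(z >= 0, 1.0, -1.0)  # sign(0) treated as +1
    return z + eps * sign


def rule_epsilon(a, w, b, R, eps):
    """Dense epsilon rule (independent of layer classes; used by tests)."""
    z = a @ w + b
    s = R / _stab(z, eps)
    return a * (s @ w.T)


def rule_alphabeta(a, w, b, R, alpha, beta):
    """Dense alpha-beta rule; bias share stays with the bias term."""
    if abs(alpha - beta - 1.0) > 1e-12:
        raise ValueError("alpha - beta must equal 1")
    ap, am = np.maximum(a, 0), np.minimum(a, 0)
    wp, wm = np.maximum(w, 0), np.minimum(w, 0)
    bp, bm = np.maximum(b, 0), np.minimum(b, 0)
    zp = ap @ wp + am @ wm + bp
    zn = ap @ wm + am @ wp + bm
    sp = alpha * _safe_div(R, zp)
    sn = beta * _safe_div(R, zn)
    return (ap * (sp @ wp.T) + am * (sp @ wm.T)) - (ap * (sn @ wm.T) + am * (sn @ wp.T))


def rule_flat(n_inputs, R):
    """Dense flat rule: each unit's relevance spread equally over inputs."""
    if n_inputs < 1:
        raise ValueError("empty receptive field")
    share = R.sum(axis=-1, keepdims=True) / n_inputs
    return np.broadcast_to(share, R.shape[:-1] + (n_inputs,)).copy()


def _dense_lrp(layer: Dense, a: np.ndarray, R: np.ndarray, rule: Rule) -> np.ndarray:
    w, b = layer.params["w"], layer.params["b"]
    if isinstance(rule, EpsilonRule):
        return rule_epsilon(a, w, b, R, rule.eps)
    if isinstance(rule, AlphaBetaRule):
        return rule_alphabeta(a, w, b, R, rule.alpha, rule.beta)
    if isinstance(rule, FlatRule):
        return rule_flat(w.shape[0], R)
    if isinstance(rule, ZBoxRule):
        lo = np.full_like(a, rule.low)
        hi = np.full_like(a, rule.high)
        wp, wm = np.maximum(w, 0), np.minimum(w, 0)
        z = a @ w - lo @ wp - hi @ wm + b
        s = _safe_div(R, z)
        return a * (s @ w.T) - lo * (s @ wp.T) - hi * (s @ wm.T)
    raise TypeError(f"unsupported rule {rule!r} for dense layer")


def _conv_lrp(layer: Conv2D, a: np.ndarray, R: np.ndarray, rule: Rule) -> np.ndarray:
    w, b = layer.params["w"], layer.params["b"]
    pad, hw = layer.padding, layer.in_shape[:2]

    def grad(s, wk):
        return conv_input_grad(s, wk, pad, hw)

    if isinstance(rule, EpsilonRule):
        z = conv2d_forward(a, w, pad) + b
        s = R / _stab(z, rule.eps)
        return a * grad(s, w)
    if isinstance(rule, AlphaBetaRule):
        ap, am = np.maximum(a, 0), np.minimum(a, 0)
        wp, wm = np.maximum(w, 0), np.minimum(w, 0)
        zp = conv2d_forward(ap, wp, pad) + conv2d_forward(am, wm, pad) + np.maximum(b, 0)
        zn = conv2d_forward(ap, wm, pad) + conv2d_forward(am, wp, pad) + np.minimum(b, 0)
        sp = rule.alpha * _safe_div(R, zp)
        sn = rule.beta * _safe_div(R, zn)
        pos = ap * grad(sp, wp) + am * grad(sp, wm)
        neg = ap * grad(sn, wm) + am * grad(sn, wp)
        return pos - neg
    if isinstance(rule, FlatRule):
        ones_w = np.ones_like(w)
        ones_a = np.ones_like(a)
        counts = conv2d_forward(ones_a, ones_w, pad)
        s = _safe_div(R, counts)
        return grad(s, ones_w)
    if isinstance(rule, ZBoxRule):
        lo = np.full_like(a, rule.low)
        hi = np.full_like(a, rule.high)
        wp, wm = np.maximum(w, 0), np.minimum(w, 0)
        z = (conv2d_forward(a, w, pad) - conv2d_forward(lo, wp, pad)
             - conv2d_forward(hi, wm, pad) + b)
        s = _safe_div(R, z)
        return a * grad(s, w) - lo * grad(s, wp) - hi * grad(s, wm)
    raise TypeError(f"unsupported rule {rule!r} for conv layer")


def _avgpool_lrp(layer: AvgPool, a: np.ndarray, R: np.ndarray, rule: Rule) -> np.ndarray:
    """Average pooling as a fixed uniform-weight convolution under ``rule``."""
    ph, pw = layer.window
    oh, ow, c = layer.out_shape
    n = a.shape[0]
    win = layer._windows(a)  # (N,oh,ph,ow,pw,C)
    npool = ph * pw
    if isinstance(rule, EpsilonRule):
        z = win.mean(axis=(2, 4))
        s = R / _stab(z, rule.eps)
        shares = win / npool * s[:, :, None, :, None, :]
    elif isinstance(rule, AlphaBetaRule):
        wp_ = np.maximum(win, 0)
        wm_ = np.minimum(win, 0)
        zp = wp_.sum(axis=(2, 4)) / npool
        zn = wm_.sum(axis=(2, 4)) / npool
        sp = rule.alpha * _safe_div(R, zp)
        sn = rule.beta * _safe_div(R, zn)
        shares = (wp_ * sp[:, :, None, :, None, :] - wm_ * sn[:, :, None, :, None, :]) / npool
    elif isinstance(rule, FlatRule):
        shares = np.broadcast_to(
            (R / npool)[:, :, None, :, None, :], win.shape
        ).copy()
    else:
        raise TypeError(f"unsupported rule {rule!r} for average pooling")
    dx = np.zeros((n,) + layer.in_shape)
    dx[:, : oh * ph, : ow * pw] = shares.reshape(n, oh * ph, ow * pw, c)
    return dx


def _maxpool_lrp(layer: MaxPool, R: np.ndarray) -> np.ndarray:
    """Winner-take-all redirection to the forward-pass argmax."""
    return layer.backward(R)[0]


# ---------------------------------------------------------------------------
# batchnorm folding

def fold_batchnorm(graph: LayerGraph) -> LayerGraph:
    """Equivalent inference graph with batchnorm folded into the next dense.

    Each batchnorm's per-feature affine map (running moments, gamma, beta)
    is absorbed into the effective weights/bias of the nearest downstream
    dense layer reachable through shape-preserving pass-through nodes
    (dropout). Batchnorms that cannot be folded are kept and propagated as
    identity with a warning at explain time.
    """
    # pending affine transform flowing from a folded batchnorm to consumers
    pending: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    out = LayerGraph(graph.architecture_name, graph.output_classes)
    rename: Dict[str, str] = {}
    children = graph.children()
    for name in graph.order:
        layer = graph.layers[name]
        parents = [rename[p] for p in graph.parents[name] if p in rename]
        inherited = [pending[p] for p in graph.parents[name] if p in pending]
        if isinstance(layer, BatchNorm):
            kids = children[name]
            if _foldable(graph, name):
                scale, shift = layer.effective_affine()
                rename[name] = rename[graph.parents[name][0]]
                pending[name] = (scale, shift)
                continue
            warnings.warn(f"batchnorm {name!r} has no downstream dense to fold into")
        new_layer = _layer_from_spec(layer.kind, _layer_spec(layer))
        new_layer.params = {k: v.copy() for k, v in layer.params.items()}
        if isinstance(layer, BatchNorm):
            new_layer.running_mean = layer.running_mean.copy()
            new_layer.running_var = layer.running_var.copy()
        if inherited:
            scale, shift = inherited[0]
            if isinstance(layer, Dense):
                w = new_layer.params["w"]
                new_layer.params["w"] = w * scale[:, None]
                new_layer.params["b"] = new_layer.params["b"] + shift @ w
            elif isinstance(layer, Dropout):
                # pass the pending affine through unchanged
                pass
            else:
                raise AssertionError("fold reached a non-foldable layer")
        out.add(name, new_layer, parents or None)
        rename[name] = name
        if inherited and isinstance(layer, Dropout):
            pending[name] = inherited[0]
    return out


def _foldable(graph: LayerGraph, bn_name: str) -> bool:
    children = graph.children()
    cur = bn_name
    while True:
        kids = children[cur]
        if len(kids) != 1:
            return False
        kid = kids[0]
        layer = graph.layers[kid]
        if isinstance(layer, Dense):
            return True
        if isinstance(layer, Dropout):
            cur = kid
            continue
        return False


# ---------------------------------------------------------------------------
# engine

def _first_linear_layers(graph: LayerGraph) -> set:
    """Conv/dense nodes with no other conv/dense between them and the input."""
    firsts = set()
    for name in graph.order:
        if graph.layers[name].kind not in ("conv2d", "dense"):
            continue
        stack = list(graph.parents[name])
        seen_linear = False
        while stack:
            p = stack.pop()
            if graph.layers[p].kind in ("conv2d", "dense"):
                seen_linear = True
                break
            stack.extend(graph.parents[p])
        if not seen_linear:
            firsts.add(name)
    return firsts


def explain_batch(
    model: TrainedModel,
    X: np.ndarray,
    target_class: object,
    rules: Union[str, RuleAssignment] = "lrp_spf",
) -> RelevanceMap:
    """Relevance maps for a batch of windows toward one target class.

    ``X`` has shape (N, frames, channels); ``target_class`` is a class
    label from the model's vocabulary (or an int index when the label is
    not in the vocabulary). Returns a RelevanceMap whose scores have the
    batch shape and whose f_c / conservation_residual are per-sample.
    """
    if isinstance(rules, str):
        rules = make_ruleset(rules)
    X = np.asarray(X, dtype=float)
    single = X.ndim == 2
    if single:
        X = X[None]
    if target_class in model.classes:
        c_idx = model.classes.index(target_class)
    elif isinstance(target_class, (int, np.integer)) and 0 <= target_class < len(model.classes):
        c_idx = int(target_class)
    else:
        raise ValueError(f"unknown target class {target_class!r}")

    if rules.gradient_mode is not None:
        graph = model.graph
        logits, _, _ = graph.forward(X[..., None], mode="eval")
        seed = np.zeros_like(logits)
        seed[:, c_idx] = 1.0
        grad = graph.backward(seed, relu_mode=rules.gradient_mode)
        scores = grad[..., 0]
        f_c = logits[:, c_idx]
        res = np.abs(scores.reshape(scores.shape[0], -1).sum(axis=1) - f_c)
        rmap = RelevanceMap(scores if not single else scores[0], target_class, rules,
                            f_c if not single else float(f_c[0]),
                            res if not single else float(res[0]),
                            residual_is_absolute=True)
        return rmap

    graph = model.graph
    if any(isinstance(l, BatchNorm) for l in graph.layers.values()):
        graph = fold_batchnorm(graph)
    firsts = _first_linear_layers(graph)
    logits, _, acts = graph.forward(X[..., None], mode="eval")
    f_c = logits[:, c_idx]
    R: Dict[str, np.ndarray] = {}
    R[graph.logit_name] = np.zeros_like(logits)
    R[graph.logit_name][:, c_idx] = f_c
    for name in reversed(graph.order):
        if name not in R:
            continue
        layer = graph.layers[name]
        if layer.kind in ("input", "softmax"):
            continue
        r_out = R.pop(name)
        parents = graph.parents[name]
        a_parent = acts[parents[0]] if parents else None
        if isinstance(layer, Dense):
            rins = [_dense_lrp(layer, a_parent, r_out, rules.rule_for("dense", name in firsts))]
        elif isinstance(layer, Conv2D):
            rins = [_conv_lrp(layer, a_parent, r_out, rules.rule_for("conv2d", name in firsts))]
        elif isinstance(layer, AvgPool):
            rins = [_avgpool_lrp(layer, a_parent, r_out, rules.rule_for("conv2d", False))]
        elif isinstance(layer, MaxPool):
            rins = [_maxpool_lrp(layer, r_out)]
        elif isinstance(layer, Flatten):
            rins = [r_out.reshape((-1,) + layer.in_shape)]
        elif isinstance(layer, Concat):
            rins = list(np.split(r_out, np.cumsum(layer.part_channels)[:-1], axis=-1))
        elif isinstance(layer, (Dropout,)):
            rins = [r_out]
        elif isinstance(layer, BatchNorm):
            warnings.warn("unfolded batchnorm treated as identity for relevance")
            rins = [r_out]
        else:
            raise TypeError(f"no relevance rule for layer kind {layer.kind!r}")
        for p, r in zip(parents, rins):
            R[p] = R[p] + r if p in R else r

    scores = R[graph.input_name][..., 0]
    total = scores.reshape(scores.shape[0], -1).sum(axis=1)
    dev = np.abs(total - f_c)
    absolute = f_c == 0
    residual = np.where(absolute, dev, dev / np.where(absolute, 1.0, np.abs(f_c)))
    return RelevanceMap(
        scores if not single else scores[0],
        target_class,
        rules,
        f_c if not single else float(f_c[0]),
        residual if not single else float(residual[0]),
        residual_is_absolute=bool(np.any(absolute)),
    )


def explain(
    model: TrainedModel,
    sample,
    target_class: object,
    rules: Union[str, RuleAssignment] = "lrp_spf",
) -> RelevanceMap:
    """Relevance map of one sample (values array or GaitSample)."""
    values = getattr(sample, "values", sample)
    return explain_batch(model, np.asarray(values, dtype=float), target_class, rules)
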