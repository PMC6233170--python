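"""Neural embedding models for expression profiles.

Three supervised training modes share one multilayer-perceptron core:

* ``classifier`` — softmax cross-entropy over single-term cell-type labels;
  the last hidden layer is taken as the reduced-dimension embedding.
* ``siamese`` — twin networks with shared weights trained with the
  contrastive loss on pairs: same-class pairs are pulled together
  (loss D^2/2) and different-class pairs pushed beyond a margin m
  (loss max{0, m - D}^2 / 2), D being the Euclidean distance between the twin
  embeddings.
* ``triplet`` — anchors are pulled toward a same-class positive and away from
  a different-class negative: loss max{0, d_ap - d_an + alpha} on squared
  Euclidean distances.  A triplet is "active" while its loss is positive; the
  fraction of active triplets is available as an epoch-selection metric.

Architectures may be fully dense, or carry a sparse first layer whose
connectivity encodes prior knowledge (one unit per gene set, connected only
to member genes, optionally alongside a dense side branch), or mirror a GO
hierarchy layer by layer.  Sparsity is enforced with binary masks that zero
the forbidden weight positions after every update, so masked weights remain
exactly zero throughout training.

Optimization is plain minibatch SGD with momentum; all gradients are
hand-derived and checked against numerical differentiation in the test
suite.  Every source of randomness runs off an explicit seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .dataset import ExpressionMatrix
from .ontology import OntologyDAG

__all__ = [
    "ArchitectureSpec",
    "ConnectivityMask",
    "EmbeddingModel",
    "TrainingConfig",
    "TrainingHistory",
    "TrainingDivergedError",
    "ModelError",
    "read_gmt",
    "build_dense",
    "build_masked_prior",
    "build_go_hierarchy",
    "contrastive_loss",
    "contrastive_loss_grad",
    "triplet_loss",
    "triplet_loss_grad",
    "fraction_active_triplets",
    "make_pairs",
    "make_triplets",
    "pretrain_unsupervised",
    "train",
    "embed",
    "save_model",
    "load_model",
]


class ModelError(ValueError):
    pass


class TrainingDivergedError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def _act_apply(name: str, z: np.ndarray) -> np.ndarray:
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "linear":
        return z
    raise ModelError(f"unknown activation {name!r}")


def _act_grad(name: str, z: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Derivative of the activation, from pre-activation z and output h."""
    if name == "tanh":
        return 1.0 - h * h
    if name == "sigmoid":
        return h * (1.0 - h)
    if name == "relu":
        return (z > 0).astype(float)
    if name == "linear":
        return np.ones_like(z)
    raise ModelError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# Architecture containers
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMask:
    """Binary genes x units mask derived from named gene groups."""

    groups: dict[str, set[str]]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=float)
        if any(len(g) == 0 for g in self.groups.values()):
            raise ModelError("every mask group must be non-empty")


@dataclass
class ArchitectureSpec:
    kind: str  # dense | masked-prior | go-hierarchy
    n_inputs: int
    hidden_sizes: list[int]
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if not self.hidden_sizes:
            raise ModelError("at least one hidden layer is required")
        if any(s <= 0 for s in self.hidden_sizes):
            raise ModelError(f"hidden sizes must be positive: {self.hidden_sizes}")
        if self.hidden_sizes[-1] < 2:
            raise ModelError("embedding dimension must be >= 2")


class EmbeddingModel:
    """An MLP whose last hidden layer is the neural embedding."""

    def __init__(
        self,
        spec: ArchitectureSpec,
        genes: Sequence[str] | None = None,
        classes: Sequence[str] | None = None,
        masks: Sequence[np.ndarray | None] | None = None,
        seed: int = 0,
    ) -> None:
        self.spec = spec
        self.genes = list(genes) if genes is not None else None
        if self.genes is not None and len(self.genes) != spec.n_inputs:
            raise ModelError("gene list length does not match n_inputs")
        self.classes = list(classes) if classes is not None else None
        self.masks: list[np.ndarray | None] = (
            list(masks) if masks is not None else [None] * len(spec.hidden_sizes)
        )
        if len(self.masks) != len(spec.hidden_sizes):
            raise ModelError("one mask slot per hidden layer is required")
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        sizes = [spec.n_inputs, *spec.hidden_sizes]
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            W = _glorot(rng, n_in, n_out)
            if self.masks[i] is not None:
                m = np.asarray(self.masks[i], dtype=float)
                if m.shape != (n_in, n_out):
                    raise ModelError(f"mask {i} has shape {m.shape}, expected {(n_in, n_out)}")
                self.masks[i] = m
                W = W * m
            self.weights.append(W)
            self.biases.append(np.zeros(n_out))
        if self.classes is not None:
            self.head_W: np.ndarray | None = _glorot(rng, sizes[-1], len(self.classes))
            self.head_b: np.ndarray | None = np.zeros(len(self.classes))
        else:
            self.head_W = None
            self.head_b = None

    # -- forward ------------------------------------------------------------
    @property
    def embedding_dim(self) -> int:
        return self.spec.hidden_sizes[-1]

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], list[np.ndarray]]:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.n_inputs:
            raise ModelError(
                f"input has {X.shape[1] if X.ndim == 2 else '?'} features, "
                f"model expects {self.spec.n_inputs}"
            )
        hs, zs = [X], []
        for W, b in zip(self.weights, self.biases):
            z = hs[-1] @ W + b
            zs.append(z)
            hs.append(_act_apply(self.spec.activation, z))
        return hs, zs

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Deterministic forward pass to the last hidden layer."""
        hs, _ = self._forward(X)
        return hs[-1]

    def logits(self, X: np.ndarray) -> np.ndarray:
        if self.head_W is None:
            raise ModelError("model has no classifier head")
        return self.embed(X) @ self.head_W + self.head_b

    def predict(self, X: np.ndarray) -> list[str]:
        idx = np.argmax(self.logits(X), axis=1)
        return [self.classes[i] for i in idx]

    # -- bookkeeping --------------------------------------------------------
    def copy_weights(self) -> list[np.ndarray]:
        ws = [W.copy() for W in self.weights] + [b.copy() for b in self.biases]
        if self.head_W is not None:
            ws += [self.head_W.copy(), self.head_b.copy()]
        return ws

    def set_weights(self, ws: list[np.ndarray]) -> None:
        n = len(self.weights)
        for i in range(n):
            self.weights[i] = ws[i].copy()
            self.biases[i] = ws[n + i].copy()
        if self.head_W is not None:
            self.head_W = ws[2 * n].copy()
            self.head_b = ws[2 * n + 1].copy()
        self._apply_masks()

    def _apply_masks(self) -> None:
        for i, m in enumerate(self.masks):
            if m is not None:
                self.weights[i] *= m


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=(n_in, n_out))


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_dense(
    genes: Sequence[str] | int,
    hidden_sizes: Sequence[int],
    activation: str = "tanh",
    classes: Sequence[str] | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Fully connected architecture; e.g. sizes [1136, 100] give a two-hidden-
    layer perceptron with a 100-dimensional embedding."""
    n_inputs = genes if isinstance(genes, int) else len(genes)
    spec = ArchitectureSpec("dense", n_inputs, list(hidden_sizes), activation)
    return EmbeddingModel(spec, genes=None if isinstance(genes, int) else genes,
                          classes=classes, seed=seed)


def read_gmt(source: str | Path) -> dict[str, set[str]]:
    """Read gene sets from GMT text (set name, description, member genes)."""
    s = str(source)
    text = s if "\n" in s or "\t" in s else Path(s).read_text()
    groups: dict[str, set[str]] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ModelError(f"malformed GMT line (need name, description, genes): {line!r}")
        groups[parts[0]] = {g.strip() for g in parts[2:] if g.strip()}
    return groups


def connectivity_mask(
    groups: Mapping[str, Iterable[str]], genes: Sequence[str], side_units: int = 0
) -> tuple[ConnectivityMask, list[str]]:
    """Build a genes x (group units + dense side units) binary mask.

    Groups with no gene on the list are dropped with a warning; dropping all
    of them is an error.  Side-branch columns are fully connected.
    """
    gene_pos = {g: i for i, g in enumerate(genes)}
    kept: dict[str, set[str]] = {}
    for name in sorted(groups):
        members = {g for g in groups[name] if g in gene_pos}
        if members:
            kept[name] = members
        else:
            warnings.warn(f"gene group {name!r} shares no genes with the input list; dropped")
    if not kept:
        raise ModelError("no gene group overlaps the input gene list")
    names = sorted(kept)
    mask = np.zeros((len(genes), len(names) + side_units))
    for j, name in enumerate(names):
        for g in kept[name]:
            mask[gene_pos[g], j] = 1.0
    if side_units:
        mask[:, len(names):] = 1.0
    return ConnectivityMask(kept, mask), names


def build_masked_prior(
    groups: Mapping[str, Iterable[str]],
    genes: Sequence[str],
    dense_tail_sizes: Sequence[int],
    dense_side_units: int = 0,
    activation: str = "tanh",
    classes: Sequence[str] | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Sparse first layer from prior-knowledge gene groups (PPI/TF style).

    The first hidden layer has one unit per surviving group wired only to its
    member genes, plus ``dense_side_units`` fully connected units; subsequent
    layers are dense.
    """
    cmask, _ = connectivity_mask(groups, genes, dense_side_units)
    first_width = cmask.mask.shape[1]
    hidden = [first_width, *dense_tail_sizes]
    spec = ArchitectureSpec("masked-prior", len(genes), hidden, activation)
    masks: list[np.ndarray | None] = [cmask.mask] + [None] * len(dense_tail_sizes)
    return EmbeddingModel(spec, genes=genes, classes=classes, masks=masks, seed=seed)


def build_go_hierarchy(
    go_dag: OntologyDAG,
    gene_to_terms: Mapping[str, Iterable[str]],
    embedding_dim: int,
    genes: Sequence[str] | None = None,
    activation: str = "tanh",
    classes: Sequence[str] | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Architecture mirroring a GO-style hierarchy.

    A term's layer is set by its maximum distance to a root: the deepest terms
    form the first hidden layer (wired to their annotated genes) and each
    subsequent layer holds the terms one level closer to the root, wired along
    child->parent edges only.  Every layer carries one extra catch-all unit
    that collects genes without annotation and units whose parent skips a
    level, so connectivity never dead-ends.  A final dense layer maps to the
    requested embedding dimension.
    """
    if genes is None:
        genes = sorted(gene_to_terms)
    genes = list(genes)
    depth: dict[str, int] = {}
    order = list(reversed(list(_topological(go_dag))))  # roots first
    for t in order:
        parents = go_dag.parents(t)
        depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
    max_depth = max(depth.values(), default=0)
    if max_depth < 1:
        raise ModelError("ontology has no non-root terms to build layers from")
    # layer 0 = deepest terms ... last GO layer = depth-1 terms (roots excluded)
    layers: list[list[str]] = [
        sorted(t for t, d in depth.items() if d == lvl)
        for lvl in range(max_depth, 0, -1)
    ]
    layers = [lay for lay in layers if lay]
    term_layer = {t: i for i, lay in enumerate(layers) for t in lay}

    masks: list[np.ndarray] = []
    # genes -> first layer
    first = layers[0]
    m0 = np.zeros((len(genes), len(first) + 1))
    pos0 = {t: j for j, t in enumerate(first)}
    for i, g in enumerate(genes):
        wired = False
        for t in gene_to_terms.get(g, ()):  # only terms sitting in layer 0
            if t in pos0:
                m0[i, pos0[t]] = 1.0
                wired = True
        if not wired:
            m0[i, -1] = 1.0  # catch-all
    masks.append(m0)
    # term layer i -> term layer i+1 along parent edges
    for i in range(len(layers) - 1):
        src = layers[i] + ["__other__"]
        dst = layers[i + 1]
        m = np.zeros((len(src), len(dst) + 1))
        dpos = {t: j for j, t in enumerate(dst)}
        for j, t in enumerate(layers[i]):
            wired = False
            for p in go_dag.parents(t):
                if p in dpos:
                    m[j, dpos[p]] = 1.0
                    wired = True
            if not wired:
                m[j, -1] = 1.0
        m[-1, -1] = 1.0  # catch-all chains forward
        masks.append(m)

    hidden = [len(lay) + 1 for lay in layers] + [embedding_dim]
    spec = ArchitectureSpec("go-hierarchy", len(genes), hidden, activation)
    model = EmbeddingModel(
        spec, genes=genes, classes=classes, masks=[*masks, None], seed=seed
    )
    model.layer_terms = [list(lay) + ["__other__"] for lay in layers]  # type: ignore[attr-defined]
    return model


def _topological(dag: OntologyDAG) -> Iterable[str]:
    import networkx as nx

    return nx.topological_sort(dag.graph)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def contrastive_loss(D, Y, m: float = 1.0):
    """Contrastive loss on a pair distance D with label Y (1 = same class).

    Same-class pairs pay D^2/2; different-class pairs pay max{0, m - D}^2/2.
    """
    D = np.asarray(D, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if np.any(D < 0):
        raise ModelError("distances must be non-negative")
    if m <= 0:
        raise ModelError("margin must be positive")
    same = 0.5 * D**2
    diff = 0.5 * np.maximum(0.0, m - D) ** 2
    out = Y * same + (1.0 - Y) * diff
    return float(out) if out.ndim == 0 else out


def contrastive_loss_grad(D, Y, m: float = 1.0):
    """dL/dD for the contrastive loss."""
    D = np.asarray(D, dtype=float)
    Y = np.asarray(Y, dtype=float)
    grad = Y * D - (1.0 - Y) * np.maximum(0.0, m - D)
    return float(grad) if grad.ndim == 0 else grad


def triplet_loss(d_ap, d_an, alpha: float = 0.2):
    """Triplet loss max{0, d_ap - d_an + alpha} on squared distances."""
    d_ap = np.asarray(d_ap, dtype=float)
    d_an = np.asarray(d_an, dtype=float)
    if np.any(d_ap < 0) or np.any(d_an < 0):
        raise ModelError("squared distances must be non-negative")
    if alpha <= 0:
        raise ModelError("margin alpha must be positive")
    out = np.maximum(0.0, d_ap - d_an + alpha)
    return float(out) if out.ndim == 0 else out


def triplet_loss_grad(d_ap, d_an, alpha: float = 0.2):
    """(dL/dd_ap, dL/dd_an) for the triplet loss."""
    active = (np.asarray(d_ap, float) - np.asarray(d_an, float) + alpha) > 0
    g = active.astype(float)
    if g.ndim == 0:
        return float(g), float(-g)
    return g, -g


def fraction_active_triplets(
    model: EmbeddingModel,
    anchors: np.ndarray,
    positives: np.ndarray,
    negatives: np.ndarray,
    alpha: float = 0.2,
) -> float:
    """Fraction of triplets in a batch with positive loss."""
    anchors = np.atleast_2d(anchors)
    if anchors.shape[0] == 0:
        raise ModelError("empty triplet batch")
    ea = model.embed(anchors)
    ep = model.embed(np.atleast_2d(positives))
    en = model.embed(np.atleast_2d(negatives))
    d_ap = np.sum((ea - ep) ** 2, axis=1)
    d_an = np.sum((ea - en) ** 2, axis=1)
    return float(np.mean(triplet_loss(d_ap, d_an, alpha) > 0))


# ---------------------------------------------------------------------------
# Pair / triplet sampling
# ---------------------------------------------------------------------------

def _class_members(labels: Sequence[str]) -> dict[str, np.ndarray]:
    members: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        members.setdefault(str(lab), []).append(i)
    return {k: np.asarray(v) for k, v in sorted(members.items())}


def make_pairs(
    labels: Sequence[str], n_pairs: int, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Sample (i, j, Y) index pairs, balanced 50/50 same/different class."""
    rng = np.random.default_rng(seed)
    members = _class_members(labels)
    if len(members) < 2:
        raise ModelError("pair sampling needs at least two classes")
    multi = [c for c, idx in members.items() if len(idx) >= 2]
    if len(multi) < len(members):
        warnings.warn("classes with a single member cannot form same-class pairs")
    if not multi:
        raise ModelError("no class has two members to form same-class pairs")
    classes = list(members)
    n_same = n_pairs // 2
    pairs: list[tuple[int, int, int]] = []
    for _ in range(n_same):
        c = multi[int(rng.integers(len(multi)))]
        i, j = rng.choice(members[c], size=2, replace=False)
        pairs.append((int(i), int(j), 1))
    for _ in range(n_pairs - n_same):
        ca, cb = rng.choice(len(classes), size=2, replace=False)
        i = rng.choice(members[classes[ca]])
        j = rng.choice(members[classes[cb]])
        pairs.append((int(i), int(j), 0))
    return pairs


def make_triplets(
    labels: Sequence[str], n_triplets: int, seed: int = 0
) -> list[tuple[int, int, int]]:
    """Sample (anchor, positive, negative) index triplets."""
    rng = np.random.default_rng(seed)
    members = _class_members(labels)
    if len(members) < 2:
        raise ModelError("triplet sampling needs at least two classes")
    anchor_classes = [c for c, idx in members.items() if len(idx) >= 2]
    if len(anchor_classes) < len(members):
        warnings.warn("classes with a single member cannot anchor a triplet; skipped")
    if not anchor_classes:
        raise ModelError("no class has two members to anchor a triplet")
    classes = list(members)
    out: list[tuple[int, int, int]] = []
    for _ in range(n_triplets):
        c = anchor_classes[int(rng.integers(len(anchor_classes)))]
        a, p = rng.choice(members[c], size=2, replace=False)
        others = [cb for cb in classes if cb != c]
        n = rng.choice(members[others[int(rng.integers(len(others)))]])
        out.append((int(a), int(p), int(n)))
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    mode: str = "classifier"  # classifier | siamese | triplet
    epochs: int = 100
    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32
    margin: float = 1.0        # contrastive margin m
    alpha: float = 0.2         # triplet margin
    pretrain: bool = False
    pretrain_epochs: int = 10
    val_fraction: float = 0.1
    selection: str = "val-loss"  # val-loss | frac-active
    patience: int = 10
    pairs_per_epoch: int | None = None     # default: one per training cell
    triplets_per_epoch: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("classifier", "siamese", "triplet"):
            raise ModelError(f"unknown training mode {self.mode!r}")
        if self.epochs < 1:
            raise ModelError("epochs must be >= 1")
        if self.margin <= 0 or self.alpha <= 0:
            raise ModelError("margins must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ModelError("validation fraction must be in (0, 1)")
        if self.selection not in ("val-loss", "frac-active"):
            raise ModelError(f"unknown selection metric {self.selection!r}")
        if self.selection == "frac-active" and self.mode != "triplet":
            raise ModelError("frac-active selection applies to triplet mode only")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    frac_active: list[float] = field(default_factory=list)
    best_epoch: int = -1

    def selection_series(self, selection: str) -> list[float]:
        return self.frac_active if selection == "frac-active" else self.val_loss

    def to_frame(self):
        import pandas as pd

        d = {"epoch": list(range(len(self.train_loss))),
             "train_loss": self.train_loss, "val_loss": self.val_loss}
        if self.frac_active:
            d["frac_active"] = self.frac_active
        return pd.DataFrame(d)


class _SGD:
    def __init__(self, model: EmbeddingModel, lr: float, momentum: float) -> None:
        self.model = model
        self.lr = lr
        self.momentum = momentum
        self.vel_W = [np.zeros_like(W) for W in model.weights]
        self.vel_b = [np.zeros_like(b) for b in model.biases]
        self.vel_head = (
            (np.zeros_like(model.head_W), np.zeros_like(model.head_b))
            if model.head_W is not None
            else None
        )

    def step(self, grads_W, grads_b, grad_head=None) -> None:
        m = self.model
        for i in range(len(m.weights)):
            self.vel_W[i] = self.momentum * self.vel_W[i] - self.lr * grads_W[i]
            self.vel_b[i] = self.momentum * self.vel_b[i] - self.lr * grads_b[i]
            m.weights[i] += self.vel_W[i]
            m.biases[i] += self.vel_b[i]
        if grad_head is not None:
            vW, vb = self.vel_head
            vW[...] = self.momentum * vW - self.lr * grad_head[0]
            vb[...] = self.momentum * vb - self.lr * grad_head[1]
            m.head_W += vW
            m.head_b += vb
        m._apply_masks()


def _backward(model: EmbeddingModel, hs, zs, d_top):
    """Backpropagate d(loss)/d(last hidden) through the hidden stack."""
    grads_W, grads_b = [], []
    dH = d_top
    for i in range(len(model.weights) - 1, -1, -1):
        dZ = dH * _act_grad(model.spec.activation, zs[i], hs[i + 1])
        gW = hs[i].T @ dZ
        if model.masks[i] is not None:
            gW = gW * model.masks[i]
        grads_W.append(gW)
        grads_b.append(dZ.sum(axis=0))
        if i > 0:
            dH = dZ @ model.weights[i].T
    return grads_W[::-1], grads_b[::-1]


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _ce_loss(model: EmbeddingModel, X: np.ndarray, y: np.ndarray) -> float:
    probs = _softmax(model.logits(X))
    return float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-300)))


def _pair_loss(model, X, pairs, m) -> float:
    i, j, Y = (np.asarray(v) for v in zip(*pairs))
    e1, e2 = model.embed(X[i]), model.embed(X[j])
    D = np.linalg.norm(e1 - e2, axis=1)
    return float(np.mean(contrastive_loss(D, Y, m)))


def _triplet_metrics(model, X, triplets, alpha) -> tuple[float, float]:
    a, p, n = (np.asarray(v) for v in zip(*triplets))
    ea, ep, en = model.embed(X[a]), model.embed(X[p]), model.embed(X[n])
    d_ap = np.sum((ea - ep) ** 2, axis=1)
    d_an = np.sum((ea - en) ** 2, axis=1)
    losses = triplet_loss(d_ap, d_an, alpha)
    return float(np.mean(losses)), float(np.mean(losses > 0))


def train(
    model: EmbeddingModel,
    X: np.ndarray | ExpressionMatrix,
    labels: Sequence[str],
    config: TrainingConfig | None = None,
    pairs: Sequence[tuple[int, int, int]] | None = None,
    triplets: Sequence[tuple[int, int, int]] | None = None,
) -> tuple[EmbeddingModel, TrainingHistory]:
    """Train an embedding model with minibatch SGD.

    ``X`` is cells x genes (an :class:`ExpressionMatrix` is transposed
    automatically).  Pairs/triplets are resampled from ``labels`` every epoch
    unless a fixed set is supplied.  A held-out validation fraction of cells
    drives per-epoch metric tracking, best-epoch weight selection (lowest
    validation loss, or lowest fraction of active triplets when configured)
    and early stopping with a fixed patience.
    """
    if config is None:
        config = TrainingConfig()
    if isinstance(X, ExpressionMatrix):
        X = X.values.T
    X = np.asarray(X, dtype=float)
    labels = [str(l) for l in labels]
    if len(labels) != X.shape[0]:
        raise ModelError("one label per cell is required")

    rng = np.random.default_rng(config.seed)
    n = X.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    if n - n_val < 2:
        raise ModelError("too few cells to split off a validation set")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Xval = X[tr_idx], X[val_idx]
    labs_tr = [labels[i] for i in tr_idx]
    labs_val = [labels[i] for i in val_idx]

    if config.pretrain:
        pretrain_unsupervised(model, Xtr, config.pretrain_epochs, seed=config.seed)

    if config.mode == "classifier":
        if model.classes is None:
            raise ModelError("classifier training requires a model with a class head")
        class_pos = {c: i for i, c in enumerate(model.classes)}
        try:
            ytr = np.asarray([class_pos[l] for l in labs_tr])
            yval = np.asarray([class_pos[l] for l in labs_val])
        except KeyError as exc:
            raise ModelError(f"label {exc} not among model classes") from exc

    # fixed validation pairs/triplets drawn once from validation cells
    val_pairs = val_triplets = None
    if config.mode == "siamese":
        fixed_pairs = list(pairs) if pairs is not None else None
        n_val_pairs = max(32, 2 * n_val)
        val_pairs = make_pairs(labs_val, n_val_pairs, seed=config.seed + 1) if len(set(labs_val)) >= 2 else None
        if val_pairs is None:
            raise ModelError("validation split contains fewer than two classes; lower val_fraction")
    if config.mode == "triplet":
        fixed_triplets = list(triplets) if triplets is not None else None
        if len(set(labs_val)) < 2:
            raise ModelError("validation split contains fewer than two classes; lower val_fraction")
        val_triplets = make_triplets(labs_val, max(32, 2 * n_val), seed=config.seed + 1)

    opt = _SGD(model, config.learning_rate, config.momentum)
    history = TrainingHistory()
    best_metric = np.inf
    best_weights = model.copy_weights()
    best_epoch = -1
    since_best = 0

    for epoch in range(config.epochs):
        # ---- one SGD epoch -------------------------------------------------
        if config.mode == "classifier":
            order = rng.permutation(len(tr_idx))
            losses = []
            for start in range(0, len(order), config.batch_size):
                b = order[start:start + config.batch_size]
                losses.append(_classifier_step(model, opt, Xtr[b], ytr[b]))
            train_loss = float(np.mean(losses))
            val_loss = _ce_loss(model, Xval, yval)
        elif config.mode == "siamese":
            epoch_pairs = (
                fixed_pairs
                if fixed_pairs is not None
                else make_pairs(labs_tr, config.pairs_per_epoch or len(tr_idx),
                                seed=int(rng.integers(2**31)))
            )
            losses = []
            for start in range(0, len(epoch_pairs), config.batch_size):
                losses.append(
                    _siamese_step(model, opt, Xtr, epoch_pairs[start:start + config.batch_size],
                                  config.margin)
                )
            train_loss = float(np.mean(losses))
            val_loss = _pair_loss(model, Xval, val_pairs, config.margin)
        else:  # triplet
            epoch_triplets = (
                fixed_triplets
                if fixed_triplets is not None
                else make_triplets(labs_tr, config.triplets_per_epoch or len(tr_idx),
                                   seed=int(rng.integers(2**31)))
            )
            losses = []
            for start in range(0, len(epoch_triplets), config.batch_size):
                losses.append(
                    _triplet_step(model, opt, Xtr,
                                  epoch_triplets[start:start + config.batch_size], config.alpha)
                )
            train_loss = float(np.mean(losses))
            val_loss, frac = _triplet_metrics(model, Xval, val_triplets, config.alpha)
            history.frac_active.append(frac)

        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
        if any(not np.all(np.isfinite(W)) for W in model.weights):
            raise TrainingDivergedError(f"non-finite weights at epoch {epoch}")
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)

        metric = history.selection_series(config.selection)[-1]
        if metric < best_metric:
            best_metric = metric
            best_weights = model.copy_weights()
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_weights(best_weights)
    history.best_epoch = best_epoch
    return model, history


def _classifier_step(model, opt, Xb, yb) -> float:
    hs, zs = model._forward(Xb)
    logits = hs[-1] @ model.head_W + model.head_b
    probs = _softmax(logits)
    B = len(yb)
    loss = float(-np.mean(np.log(probs[np.arange(B), yb] + 1e-300)))
    dlogits = probs.copy()
    dlogits[np.arange(B), yb] -= 1.0
    dlogits /= B
    g_head = (hs[-1].T @ dlogits, dlogits.sum(axis=0))
    dH = dlogits @ model.head_W.T
    gW, gb = _backward(model, hs, zs, dH)
    opt.step(gW, gb, g_head)
    return loss


def _siamese_step(model, opt, X, batch_pairs, m) -> float:
    i, j, Y = (np.asarray(v) for v in zip(*batch_pairs))
    hs1, zs1 = model._forward(X[i])
    hs2, zs2 = model._forward(X[j])
    diff = hs1[-1] - hs2[-1]
    D = np.linalg.norm(diff, axis=1)
    B = len(batch_pairs)
    loss = float(np.mean(contrastive_loss(D, Y, m)))
    dD = contrastive_loss_grad(D, Y, m) / B
    safe = np.where(D > 0, D, 1.0)
    dE1 = (dD / safe)[:, None] * diff
    gW1, gb1 = _backward(model, hs1, zs1, dE1)
    gW2, gb2 = _backward(model, hs2, zs2, -dE1)
    opt.step([a + b for a, b in zip(gW1, gW2)], [a + b for a, b in zip(gb1, gb2)])
    return loss


def _triplet_step(model, opt, X, batch_triplets, alpha) -> float:
    a, p, n = (np.asarray(v) for v in zip(*batch_triplets))
    hsa, zsa = model._forward(X[a])
    hsp, zsp = model._forward(X[p])
    hsn, zsn = model._forward(X[n])
    ea, ep, en = hsa[-1], hsp[-1], hsn[-1]
    d_ap = np.sum((ea - ep) ** 2, axis=1)
    d_an = np.sum((ea - en) ** 2, axis=1)
    losses = triplet_loss(d_ap, d_an, alpha)
    B = len(batch_triplets)
    active = (losses > 0).astype(float)[:, None] / B
    dEa = 2.0 * active * (en - ep)
    dEp = -2.0 * active * (ea - ep)
    dEn = 2.0 * active * (ea - en)
    gWa, gba = _backward(model, hsa, zsa, dEa)
    gWp, gbp = _backward(model, hsp, zsp, dEp)
    gWn, gbn = _backward(model, hsn, zsn, dEn)
    opt.step(
        [x + y + z for x, y, z in zip(gWa, gWp, gWn)],
        [x + y + z for x, y, z in zip(gba, gbp, gbn)],
    )
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# Unsupervised pretraining
# ---------------------------------------------------------------------------

def pretrain_unsupervised(
    model: EmbeddingModel,
    X: np.ndarray | ExpressionMatrix,
    epochs: int,
    seed: int = 0,
    learning_rate: float = 0.01,
) -> EmbeddingModel:
    """Greedy layer-wise autoencoder pretraining of the hidden stack.

    Each hidden layer is trained in turn as the encoder of a one-layer
    autoencoder (linear decoder, mean-squared-error, full-batch gradient
    descent) on the activations produced by the layers before it.  The
    supervised head is untouched.  Per-layer reconstruction losses are kept on
    ``model.pretrain_losses_``.
    """
    if isinstance(X, ExpressionMatrix):
        X = X.values.T
    X = np.asarray(X, dtype=float)
    rng = np.random.default_rng(seed)
    act = model.spec.activation
    H = X
    all_losses: list[list[float]] = []
    for layer in range(len(model.weights)):
        W, b = model.weights[layer], model.biases[layer]
        Wd = _glorot(rng, W.shape[1], W.shape[0])
        bd = np.zeros(W.shape[0])
        losses: list[float] = []
        for _ in range(epochs):
            z = H @ W + b
            h = _act_apply(act, z)
            recon = h @ Wd + bd
            err = recon - H
            loss = float(np.mean(err**2))
            losses.append(loss)
            dRecon = 2.0 * err / err.size
            gWd = h.T @ dRecon
            gbd = dRecon.sum(axis=0)
            dH = dRecon @ Wd.T
            dZ = dH * _act_grad(act, z, h)
            gW = H.T @ dZ
            if model.masks[layer] is not None:
                gW = gW * model.masks[layer]
            gb = dZ.sum(axis=0)
            W -= learning_rate * gW
            b -= learning_rate * gb
            Wd -= learning_rate * gWd
            bd -= learning_rate * gbd
            if model.masks[layer] is not None:
                W *= model.masks[layer]
        all_losses.append(losses)
        H = _act_apply(act, H @ W + b)
    model.pretrain_losses_ = all_losses  # type: ignore[attr-defined]
    return model


# ---------------------------------------------------------------------------
# Embedding + persistence
# ---------------------------------------------------------------------------

def embed(model: EmbeddingModel, X: np.ndarray | ExpressionMatrix) -> np.ndarray:
    """Cells x embedding-dim representation from the last hidden layer."""
    if isinstance(X, ExpressionMatrix):
        if model.genes is not None and list(X.genes) != list(model.genes):
            raise ModelError(
                "expression gene list does not match the model; align it first "
                "(scretrieve.dataset.align_to_genes)"
            )
        X = X.values.T
    return model.embed(np.asarray(X, dtype=float))


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Persist weights and a JSON spec block in one HDF5 container."""
    import h5py

    meta = {
        "kind": model.spec.kind,
        "n_inputs": model.spec.n_inputs,
        "hidden_sizes": model.spec.hidden_sizes,
        "activation": model.spec.activation,
        "classes": model.classes,
        "genes": model.genes,
        "has_masks": [m is not None for m in model.masks],
    }
    with h5py.File(path, "w", track_order=True) as f:
        f.attrs["spec_json"] = json.dumps(meta)
        for i, (W, b) in enumerate(zip(model.weights, model.biases)):
            f.create_dataset(f"W{i}", data=W, track_times=False)
            f.create_dataset(f"b{i}", data=b, track_times=False)
            if model.masks[i] is not None:
                f.create_dataset(f"mask{i}", data=model.masks[i], track_times=False)
        if model.head_W is not None:
            f.create_dataset("head_W", data=model.head_W, track_times=False)
            f.create_dataset("head_b", data=model.head_b, track_times=False)


def load_model(path: str | Path) -> EmbeddingModel:
    import h5py

    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["spec_json"])
        spec = ArchitectureSpec(
            meta["kind"], meta["n_inputs"], list(meta["hidden_sizes"]), meta["activation"]
        )
        masks = [
            f[f"mask{i}"][...] if has else None for i, has in enumerate(meta["has_masks"])
        ]
        model = EmbeddingModel(
            spec, genes=meta["genes"], classes=meta["classes"], masks=masks, seed=0
        )
        for i in range(len(model.weights)):
            model.weights[i] = f[f"W{i}"][...]
            model.biases[i] = f[f"b{i}"][...]
        if "head_W" in f:
            model.head_W = f["head_W"][...]
            model.head_b = f["head_b"][...]
    model._apply_masks()
    return model
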