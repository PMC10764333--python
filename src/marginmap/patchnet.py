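"""Patch-level prediction stack: CNN embedding backbone, radius patch
graph, graph-attention node classification, prediction propagation,
follicle-confounder docking, and the study's evaluation statistics.

The node set may be patch centers or nucleus centroids — the graph
machinery is agnostic.  Two tasks are predefined: ``tumor_map``
(tumor / benign / inflammation; a patch containing both tumor and
inflammation is labelled tumor) and ``macro_map`` (hole-tear / fat /
epidermis / dermis for tissue-completeness assessment).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point
from shapely.geometry import Polygon as ShapelyPolygon
from shapely.ops import unary_union
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import radius_neighbors_graph

from ._autodiff import Tensor
from ._nn import (
    Adam,
    GATNet,
    SmallConvNet,
    cosine_lr,
    cross_entropy,
    drop_edges,
    dropout,
)

__all__ = [
    "TASK_CLASSES",
    "ModelConfig",
    "PatchGraph",
    "PatchCNN",
    "GNNModel",
    "train_patch_cnn",
    "embed_patches",
    "build_patch_graph",
    "train_gnn",
    "gnn_predict",
    "propagate_predictions",
    "follicle_adjust",
    "evaluate_auc",
    "bootstrap_ci",
]

TASK_CLASSES = {
    "tumor_map": ("tumor", "benign", "inflammation"),
    "macro_map": ("hole_tear", "fat", "epidermis", "dermis"),
}


@dataclass
class ModelConfig:
    """Training configuration.

    Defaults follow the full-scale recipe (CNN: batch 32, lr 1e-4,
    100 epochs; GNN: batch 16 graphs, lr 1e-2, 1500 epochs; both under a
    cosine-annealed schedule; GAT dims 32/32/64 with DropEdge and Dropout).
    ``desk()`` returns a profile sized for seconds-scale CPU runs on the
    synthetic fixtures; it differs only in epoch counts and backbone input
    size, expressible purely through this config.
    """

    backbone: str = "small"
    input_size: int = 32
    embedding_dim: int = 64
    gnn_dims: tuple = (32, 32, 64)
    dropedge: float = 0.2
    dropout: float = 0.2
    lr_cnn: float = 1e-4
    lr_gnn: float = 1e-2
    batch_cnn: int = 32
    batch_gnn: int = 16
    epochs_cnn: int = 100
    epochs_gnn: int = 1500
    scheduler: str = "cosine"
    seed: int = 0

    def __post_init__(self):
        for name in ("dropedge", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def desk(cls, seed: int = 0) -> "ModelConfig":
        return cls(epochs_cnn=40, epochs_gnn=400, seed=seed)

    def to_json(self) -> str:
        d = asdict(self)
        d["gnn_dims"] = list(self.gnn_dims)
        return json.dumps(d)


@dataclass
class PatchGraph:
    """Radius-neighbor graph over patch (or nucleus) centers."""

    coords: np.ndarray  # (n, 2)
    features: np.ndarray  # (n, d) embeddings
    edge_index: np.ndarray  # (2, E), symmetric, no self-loops
    radius: float
    task: str = "tumor_map"
    probs: np.ndarray | None = None  # (n, C) after prediction
    labels: np.ndarray | None = None
    slide_id: str = "slide"

    @property
    def n_nodes(self) -> int:
        return len(self.coords)


def build_patch_graph(coords, embeddings, radius: float, task="tumor_map",
                      labels=None, slide_id="slide") -> PatchGraph:
    """Undirected edges between all node pairs within ``radius`` of each
    other (self-loops excluded); edges stored in both directions."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=float)
    adj = radius_neighbors_graph(coords, radius, mode="connectivity").tocoo()
    edge_index = np.vstack([adj.row, adj.col]).astype(int)
    return PatchGraph(coords, np.asarray(embeddings, dtype=float), edge_index,
                      radius, task=task, labels=labels, slide_id=slide_id)


# ---------------------------------------------------------------------------
# CNN backbone


@dataclass
class PatchCNN:
    net: SmallConvNet
    classes: tuple
    patch_shape: tuple  # raw (h, w) the backbone was trained on
    mean: float
    std: float
    config: ModelConfig
    loss_curve: list = field(default_factory=list)

    @property
    def embed_dim(self) -> int:
        return self.net.embed_dim


def _prep_patches(patches: np.ndarray, size: int, mean=None, std=None):
    """uint8 HWC patches -> float NCHW at the backbone input size."""
    x = np.asarray(patches, dtype=float)
    if x.ndim == 3:
        x = x[..., None].repeat(3, axis=-1)
    if x.max() > 1.5:
        x = x / 255.0
    n, h, w, _ = x.shape
    if (h, w) != (size, size):
        if h % size == 0 and w % size == 0:
            x = x.reshape(n, size, h // size, size, w // size, 3).mean(axis=(2, 4))
        else:
            from skimage.transform import resize

            x = np.stack([resize(p, (size, size, 3), anti_aliasing=True) for p in x])
    if mean is None:
        mean, std = float(x.mean()), float(x.std() + 1e-8)
    x = (x - mean) / std
    return x.transpose(0, 3, 1, 2), mean, std


def train_patch_cnn(patches, labels, config: ModelConfig | None = None) -> PatchCNN:
    """Train the patch classification backbone; its global-pooled penultimate
    activation is the patch embedding."""
    config = config or ModelConfig()
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("training requires >= 2 classes")
    rng = np.random.default_rng(config.seed)
    x, mean, std = _prep_patches(patches, config.input_size)
    n = len(x)
    net = SmallConvNet(int(labels.max()) + 1, rng, input_size=config.input_size)
    opt = Adam(net.parameters(), lr=config.lr_cnn)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_cnn)))
    total = config.epochs_cnn * steps_per_epoch
    losses, step = [], 0
    for _ in range(config.epochs_cnn):
        order = rng.permutation(n)
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_cnn : (b + 1) * config.batch_cnn]
            if len(idx) == 0:
                continue
            opt.lr = cosine_lr(step, total, config.lr_cnn)
            logits = net(Tensor(x[idx]))
            loss = cross_entropy(logits, labels[idx])
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
    raw = np.asarray(patches)
    return PatchCNN(net, tuple(classes.tolist()), tuple(raw.shape[1:3]),
                    mean, std, config, losses)


def embed_patches(backbone: PatchCNN, patches) -> np.ndarray:
    """Penultimate-layer embedding for each patch, order preserved."""
    raw = np.asarray(patches)
    if tuple(raw.shape[1:3]) != backbone.patch_shape:
        raise ValueError(
            f"patch size {raw.shape[1:3]} != backbone's {backbone.patch_shape}"
        )
    x, _, _ = _prep_patches(raw, backbone.config.input_size, backbone.mean, backbone.std)
    outs = []
    for i in range(0, len(x), 256):
        outs.append(backbone.net.embed(Tensor(x[i : i + 256])).data)
    return np.concatenate(outs, axis=0)


def cnn_predict(backbone: PatchCNN, patches) -> np.ndarray:
    """Class probabilities straight from the backbone head (node-only model)."""
    raw = np.asarray(patches)
    x, _, _ = _prep_patches(raw, backbone.config.input_size, backbone.mean, backbone.std)
    outs = []
    for i in range(0, len(x), 256):
        logits = backbone.net(Tensor(x[i : i + 256])).data
        outs.append(_softmax(logits))
    return np.concatenate(outs, axis=0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# GNN


@dataclass
class GNNModel:
    net: GATNet
    task: str
    classes: tuple
    config: ModelConfig
    loss_curve: list = field(default_factory=list)


def _with_self_loops(edge_index: np.ndarray, n: int) -> np.ndarray:
    loops = np.vstack([np.arange(n), np.arange(n)])
    return np.hstack([edge_index, loops]) if edge_index.size else loops


def _merge(graphs: list[PatchGraph], labels: list[np.ndarray]):
    feats, edges, labs, off = [], [], [], 0
    for g, y in zip(graphs, labels):
        feats.append(g.features)
        edges.append(g.edge_index + off)
        labs.append(np.asarray(y, dtype=int))
        off += g.n_nodes
    return np.concatenate(feats), np.hstack(edges), np.concatenate(labs), off


def train_gnn(graphs: list[PatchGraph], labels: list[np.ndarray],
              config: ModelConfig | None = None, task: str = "tumor_map") -> GNNModel:
    """Train the graph-attention node classifier on whole-slide graphs.

    DropEdge and Dropout are active only here; prediction is deterministic.
    """
    config = config or ModelConfig()
    classes = TASK_CLASSES.get(task)
    n_cls = len(classes) if classes else int(max(np.max(y) for y in labels)) + 1
    for y in labels:
        if np.max(y) >= n_cls or np.min(y) < 0:
            raise ValueError(f"labels exceed the {task} class set ({n_cls} classes)")
    rng = np.random.default_rng(config.seed)
    in_dim = graphs[0].features.shape[1]
    net = GATNet(in_dim, n_cls, rng, dims=tuple(config.gnn_dims))
    opt = Adam(net.parameters(), lr=config.lr_gnn)
    n_graphs = len(graphs)
    steps_per_epoch = max(1, int(np.ceil(n_graphs / config.batch_gnn)))
    total = config.epochs_gnn * steps_per_epoch
    losses, step = [], 0
    for _ in range(config.epochs_gnn):
        order = rng.permutation(n_graphs)
        for b in range(steps_per_epoch):
            sel = order[b * config.batch_gnn : (b + 1) * config.batch_gnn]
            if len(sel) == 0:
                continue
            feats, edges, labs, n = _merge([graphs[i] for i in sel],
                                           [labels[i] for i in sel])
            edges = drop_edges(edges, config.dropedge, rng)
            edges = _with_self_loops(edges, n)
            opt.lr = cosine_lr(step, total, config.lr_gnn)
            logits = net(Tensor(feats), edges, dropout_p=config.dropout, rng=rng)
            loss = cross_entropy(logits, labs)
            net.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
    return GNNModel(net, task, classes or tuple(range(n_cls)), config, losses)


def gnn_predict(model: GNNModel, graph: PatchGraph) -> np.ndarray:
    """Per-node class probabilities (eval mode: no DropEdge/Dropout)."""
    edges = _with_self_loops(graph.edge_index, graph.n_nodes)
    logits = model.net(Tensor(graph.features), edges).data
    return _softmax(logits)


# ---------------------------------------------------------------------------
# prediction propagation


def propagate_predictions(graph: PatchGraph, probs: np.ndarray, query_coords):
    """Interpolate node probabilities at arbitrary coordinates.

    A fixed-weight message pass: each query averages the probabilities of
    nodes within the graph radius, weighted by inverse distance (a query at
    a node's exact position returns that node's probabilities).  Queries
    with no node in radius are flagged missing, never extrapolated.

    Returns ``(values (m, C), found (m,) bool)``.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if probs.shape[0] != graph.n_nodes:
        probs = probs.T
    q = np.atleast_2d(np.asarray(query_coords, dtype=float))
    lo, hi = graph.coords.min(axis=0), graph.coords.max(axis=0)
    if ((q < lo - graph.radius).any() or (q > hi + graph.radius).any()):
        raise ValueError("query outside the node bounding box")
    tree = cKDTree(graph.coords)
    out = np.full((len(q), probs.shape[1]), np.nan)
    found = np.zeros(len(q), dtype=bool)
    for i, neighbors in enumerate(tree.query_ball_point(q, graph.radius)):
        if not neighbors:
            continue
        d = np.linalg.norm(graph.coords[neighbors] - q[i], axis=1)
        if d.min() < 1e-9:
            out[i] = probs[neighbors[int(np.argmin(d))]]
        else:
            w = 1.0 / d
            out[i] = (w[:, None] * probs[neighbors]).sum(axis=0) / w.sum()
        found[i] = True
    return out, found


# ---------------------------------------------------------------------------
# follicle-confounder docking


def follicle_adjust(patch_probs, patch_coords, follicle_polygons,
                    radii=(128.0, 256.0, 512.0), weights=(0.6, 0.3, 0.1)) -> np.ndarray:
    """Dock tumor probability near hair follicles (a BCC mimic).

    Three concentric circles (default radii 128/256/512 px) are drawn
    around each patch center; ``overlap_i`` is the fraction of circle i's
    area intersecting the follicle masks.  The docking penalty is the
    convex combination ``sum_i w_i * overlap_i`` (weights must sum to one
    and decrease with radius, weighting proximity most), and the adjusted
    probability is ``p * (1 - penalty)``.  Never increases a probability.
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-8:
        raise ValueError("penalty weights must sum to 1")
    if not np.all(np.diff(weights) <= 0):
        raise ValueError("penalty weights must decrease with radius")
    probs = np.asarray(patch_probs, dtype=float)
    coords = np.atleast_2d(np.asarray(patch_coords, dtype=float))
    if not follicle_polygons:
        return probs.copy()
    folls = unary_union(
        [p if hasattr(p, "area") else ShapelyPolygon(p) for p in follicle_polygons]
    )
    adjusted = np.empty_like(probs)
    for i, (x, y) in enumerate(coords):
        penalty = 0.0
        for r, w in zip(radii, weights):
            circle = Point(x, y).buffer(r, quad_segs=64)
            penalty += w * circle.intersection(folls).area / circle.area
        adjusted[i] = probs[i] * (1.0 - penalty)
    return adjusted


# ---------------------------------------------------------------------------
# statistics


def evaluate_auc(scores, labels, slide_ids=None, macro: bool = False) -> float:
    """ROC AUC of binary node scores; ``macro`` computes one AUC per slide
    and averages with equal slide weight (slides lacking a class are
    skipped with a warning)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not macro:
        if len(np.unique(labels)) < 2:
            raise ValueError("AUC undefined: only one class present")
        return float(roc_auc_score(labels, scores))
    slide_ids = np.asarray(slide_ids)
    aucs = []
    for sid in np.unique(slide_ids):
        m = slide_ids == sid
        if len(np.unique(labels[m])) < 2:
            warnings.warn(f"slide {sid!r} lacks a class; skipped in macro-AUC")
            continue
        aucs.append(roc_auc_score(labels[m], scores[m]))
    if not aucs:
        raise ValueError("AUC undefined on every slide")
    return float(np.mean(aucs))


def bootstrap_ci(statistic_fn, records, cluster_ids, n_boot: int = 1000,
                 level: float = 0.95, seed: int = 0, max_retries: int = 100):
    """Cluster (slide-level) non-parametric bootstrap percentile interval.

    Clusters are resampled with replacement; the statistic is recomputed on
    the concatenated member records of each resample.  A resample on which
    the statistic is undefined (raises) is redrawn, up to ``max_retries``
    per replicate.
    """
    cluster_ids = np.asarray(cluster_ids)
    uniq = np.unique(cluster_ids)
    if len(uniq) < 2:
        raise ValueError("cluster bootstrap needs >= 2 clusters")
    members = {c: np.nonzero(cluster_ids == c)[0] for c in uniq}
    rng = np.random.default_rng(seed)

    def take(rows):
        if hasattr(records, "iloc"):
            return records.iloc[rows]
        return np.asarray(records)[rows]

    stats = []
    for _ in range(n_boot):
        for attempt in range(max_retries + 1):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            rows = np.concatenate([members[c] for c in chosen])
            try:
                stats.append(float(statistic_fn(take(rows))))
                break
            except Exception:
                if attempt == max_retries:
                    raise RuntimeError(
                        f"statistic undefined after {max_retries} redraws"
                    )
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [a, 1.0 - a])
    return float(lo), float(hi)
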