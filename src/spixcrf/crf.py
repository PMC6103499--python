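"""Conditional random field over the learned superpixel graph.

Binary labels y_i in {-1, +1} are modeled conditionally on the image via

    P(y | x) ∝ exp( sum_i psi_i(x, y_i) + sum_{(i,j)} psi_ij(x, y_i, y_j) ),

with node potential psi_i = (w_node . f_i(x)) y_i on the augmented node
feature vector f_i = [1, phi_i] and edge potential
psi_ij = (w_edge . g_ij(x)) y_i y_j on g_ij = [1, |delta mean|, centroid
distance].  One weight vector is shared across all nodes and one across all
edges, so a model trained on one cohort transfers to new images with
different superpixel counts.

Training minimizes the penalized pseudo-likelihood: each conditional
p(y_i | x, y_Ni) is a logistic regression in the local field, with an l1
penalty on the node feature weights (driving feature selection) and a
squared-l2 penalty on the edge weights; biases are unpenalized.  MAP
inference is by iterated conditional modes (ICM) from an independent-unary
initialization; exhaustive enumeration is available for small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
import warnings

import numpy as np
from scipy.special import expit

from ._optim import prox_gradient
from .features import EdgeFeatures, FeatureTable
from .superpixels import SuperpixelMap

__all__ = [
    "CRFModel",
    "Labeling",
    "CRFTrainItem",
    "node_potential",
    "edge_potential",
    "crf_conditional",
    "train_crf",
    "crf_energy",
    "infer_labels",
    "labels_to_mask",
    "make_item",
]


@dataclass
class CRFModel:
    """Tied CRF parameters: one node weight vector, one edge weight vector.

    ``w_node`` has length 1 + n_node_features (leading bias); ``w_edge`` has
    one weight per edge-feature column (whose first column is the constant
    1, i.e. the edge bias).
    """

    w_node: np.ndarray
    w_edge: np.ndarray
    feature_names: list[str]
    center: np.ndarray | None = None
    scale: np.ndarray | None = None
    lambda1: float = 0.0
    lambda2: float = 0.0
    trace: list[float] = field(default_factory=list)
    converged: bool = True

    def selected_features(self, tol: float = 1e-10) -> list[str]:
        """Node features surviving the l1 penalty."""
        return [n for n, w in zip(self.feature_names, self.w_node[1:])
                if abs(w) > tol]


@dataclass
class Labeling:
    """Inferred node labels with conditional +1 probabilities."""

    labels: np.ndarray          # (p,) in {-1, +1}
    prob_pos: np.ndarray        # (p,) in [0, 1]
    provenance: str = "icm"


@dataclass
class CRFTrainItem:
    """One training image, already featurized and labeled.

    ``node_x`` is the standardized (p, d) node feature matrix (no bias
    column), ``edge_g`` the (m, 3) edge features, ``edges`` the (m, 2) graph
    edge list and ``labels`` the ground-truth node labels in +-1.
    """

    node_x: np.ndarray
    edge_g: np.ndarray
    edges: np.ndarray
    labels: np.ndarray


def node_potential(model: CRFModel, features_i: np.ndarray, y_i: int) -> float:
    """psi_i(x, y_i) = (bias + tau . phi_i(x)) * y_i."""
    f = np.concatenate([[1.0], np.asarray(features_i, dtype=float)])
    if len(f) != len(model.w_node):
        raise ValueError("node feature dimension mismatch")
    return float((model.w_node @ f) * y_i)


def edge_potential(model: CRFModel, edge_features_ij: np.ndarray,
                   y_i: int, y_j: int) -> float:
    """psi_ij(x, y_i, y_j) = (w_edge . g_ij(x)) * y_i * y_j."""
    g = np.asarray(edge_features_ij, dtype=float)
    if len(g) != len(model.w_edge):
        raise ValueError("edge feature dimension mismatch")
    return float((model.w_edge @ g) * y_i * y_j)


def _local_fields(
    w_node: np.ndarray, w_edge: np.ndarray, item: CRFTrainItem,
    labels: np.ndarray,
) -> np.ndarray:
    """b_i = w_node . f_i + sum_{j in N_i} (w_edge . g_ij) y_j for all i."""
    p = item.node_x.shape[0]
    b = item.node_x @ w_node[1:] + w_node[0]
    if len(item.edges):
        ew = item.edge_g @ w_edge
        np.add.at(b, item.edges[:, 0], ew * labels[item.edges[:, 1]])
        np.add.at(b, item.edges[:, 1], ew * labels[item.edges[:, 0]])
    return b


def crf_conditional(model: CRFModel, item: CRFTrainItem,
                    labels: np.ndarray, i: int) -> float:
    """P(y_i = +1 | x, y_Ni) — logistic in the local field, overflow-safe."""
    b = _local_fields(model.w_node, model.w_edge, item, np.asarray(labels, dtype=float))
    return float(expit(2.0 * b[i]))


def _crf_value_grad(
    w: np.ndarray, items: list[CRFTrainItem], d_node: int,
) -> tuple[float, np.ndarray]:
    """Negative pseudo-likelihood over all images; gradient wrt all weights."""
    w_node, w_edge = w[: d_node + 1], w[d_node + 1 :]
    value = 0.0
    grad = np.zeros_like(w)
    for item in items:
        y = item.labels.astype(float)
        b = _local_fields(w_node, w_edge, item, y)
        z = 2.0 * y * b
        value += float(np.logaddexp(0.0, -z).sum())
        g = -2.0 * y * expit(-z)           # dL/db_i
        grad[0] += g.sum()
        grad[1 : d_node + 1] += item.node_x.T @ g
        if len(item.edges):
            i0, i1 = item.edges[:, 0], item.edges[:, 1]
            coef = g[i0] * y[i1] + g[i1] * y[i0]
            grad[d_node + 1 :] += item.edge_g.T @ coef
    return value, grad


def train_crf(
    items: list[CRFTrainItem] | CRFTrainItem,
    lambda1: float,
    lambda2: float,
    max_iter: int = 50,
    tol: float = 1e-9,
    feature_names: list[str] | None = None,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> CRFModel:
    """Fit the tied CRF weights by penalized pseudo-likelihood.

    Objective: sum_images sum_i -log p(y_i | x, y_Ni)
    + lambda1 ||node feature weights||_1 + lambda2 ||edge weights||_2^2.
    The node bias is unpenalized; the l2 penalty covers the whole edge
    parameter vector (including its constant-column coupling), which stops
    a free uniform coupling from soaking up neighbor correlation during
    pseudo-likelihood training.  The l1 block is handled by
    soft-thresholding, the squared-l2 block by its closed-form shrinkage,
    inside a monotone accelerated proximal-gradient loop.
    """
    if lambda1 < 0 or lambda2 < 0:
        raise ValueError("penalties must be >= 0")
    if isinstance(items, CRFTrainItem):
        items = [items]
    d_node = items[0].node_x.shape[1]
    d_edge = items[0].edge_g.shape[1] if items[0].edge_g.size else 3
    for item in items:
        if not np.all(np.isin(item.labels, (-1, 1))):
            raise ValueError("training labels must be +-1")
        if len(np.unique(item.labels)) == 1:
            warnings.warn("training image has single-class node labels",
                          RuntimeWarning)

    n_w = 1 + d_node + d_edge
    l1_slice = slice(1, 1 + d_node)          # node feature weights
    l2_slice = slice(1 + d_node, n_w)        # the full edge parameter vector

    def smooth(x: np.ndarray) -> tuple[float, np.ndarray]:
        return _crf_value_grad(x, items, d_node)

    def penalty(x: np.ndarray) -> float:
        return (lambda1 * np.abs(x[l1_slice]).sum()
                + lambda2 * float(x[l2_slice] @ x[l2_slice]))

    def prox(x: np.ndarray, t: float) -> np.ndarray:
        out = x.copy()
        out[l1_slice] = np.sign(x[l1_slice]) * np.maximum(
            np.abs(x[l1_slice]) - t * lambda1, 0.0)
        out[l2_slice] = x[l2_slice] / (1.0 + 2.0 * t * lambda2)
        return out

    res = prox_gradient(smooth, penalty, prox, x0=np.zeros(n_w),
                        max_iter=max_iter, tol=tol)
    names = feature_names or [f"f{k}" for k in range(d_node)]
    return CRFModel(
        w_node=res.x[: d_node + 1], w_edge=res.x[d_node + 1 :],
        feature_names=list(names), center=center, scale=scale,
        lambda1=lambda1, lambda2=lambda2, trace=res.trace,
        converged=res.converged,
    )


def crf_energy(model: CRFModel, item: CRFTrainItem, labels: np.ndarray) -> float:
    """Total potential sum psi_i + sum psi_ij of a labeling (to maximize)."""
    y = np.asarray(labels, dtype=float)
    unary = item.node_x @ model.w_node[1:] + model.w_node[0]
    e = float(unary @ y)
    if len(item.edges):
        ew = item.edge_g @ model.w_edge
        e += float((ew * y[item.edges[:, 0]] * y[item.edges[:, 1]]).sum())
    return e


def infer_labels(
    model: CRFModel,
    item: CRFTrainItem,
    mode: str = "icm",
    max_sweeps: int = 100,
) -> Labeling:
    """MAP labeling by ICM or, for small graphs, exhaustive enumeration.

    ICM initializes every node at the argmax of its unary logistic and
    sweeps nodes in fixed index order, flipping each to its conditional
    mode, until a full sweep changes nothing.  Deterministic by
    construction.
    """
    p = item.node_x.shape[0]
    unary = item.node_x @ model.w_node[1:] + model.w_node[0]
    if mode == "exact":
        if p > 15:
            raise ValueError("exact enumeration limited to <= 15 nodes")
        best, best_e = None, -np.inf
        for comb in product((-1, 1), repeat=p):
            y = np.array(comb, dtype=float)
            e = crf_energy(model, item, y)
            if e > best_e:
                best, best_e = y, e
        b = _local_fields(model.w_node, model.w_edge, item, best)
        return Labeling(labels=best.astype(np.int8), prob_pos=expit(2.0 * b),
                        provenance="exact")
    if mode != "icm":
        raise ValueError("mode must be 'icm' or 'exact'")

    y = np.where(unary > 0, 1.0, -1.0)
    if len(item.edges):
        ew = item.edge_g @ model.w_edge
        nbr = [[] for _ in range(p)]
        for k, (i, j) in enumerate(item.edges):
            nbr[i].append((j, ew[k]))
            nbr[j].append((i, ew[k]))
        for _ in range(max_sweeps):
            changed = False
            for i in range(p):
                b = unary[i] + sum(wk * y[j] for j, wk in nbr[i])
                new = 1.0 if b > 0 else -1.0
                if new != y[i]:
                    y[i] = new
                    changed = True
            if not changed:
                break
    b = _local_fields(model.w_node, model.w_edge, item, y)
    return Labeling(labels=y.astype(np.int8), prob_pos=expit(2.0 * b),
                    provenance="icm")


def labels_to_mask(sp: SuperpixelMap, labeling: Labeling | np.ndarray) -> np.ndarray:
    """Render node labels back to a pixel mask (+1 -> 1, -1 -> 0)."""
    labels = labeling.labels if isinstance(labeling, Labeling) else np.asarray(labeling)
    if len(labels) != sp.n_regions:
        raise ValueError("one label per region required")
    return (labels[sp.labels] > 0).astype(np.uint8)


def make_item(
    features: FeatureTable,
    edge_features: EdgeFeatures,
    labels: np.ndarray | None = None,
) -> CRFTrainItem:
    """Bundle standardized features + graph edges into a CRF work item."""
    p = features.values.shape[0]
    y = np.zeros(p, dtype=np.int8) if labels is None else np.asarray(labels)
    return CRFTrainItem(node_x=features.values, edge_g=edge_features.data,
                        edges=edge_features.edges, labels=y)
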