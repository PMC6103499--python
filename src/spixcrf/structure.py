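"""Sparse graph structure learning for the binary pairwise Markov field.

Superpixel node labels y_i in {-1, +1} are modeled by an Ising distribution

    P(y) ∝ exp( sum_i theta_i y_i + sum_{(i,j) in E} theta_ij y_i y_j ),

whose full conditional for one node is a logistic in the local field
a_i = theta_i + sum_j theta_ij y_j:  p(y_i = +1 | rest) = e^{2 a_i} /
(e^{2 a_i} + 1).  The graph is learned by minimizing the symmetric negative
pseudo-likelihood over i.i.d. label samples plus an l1 penalty on the edge
couplings (node biases unpenalized); couplings driven exactly to zero delete
their edges, so the penalty level selects the neighborhood structure.  The
optimizer is an accelerated proximal-gradient scheme with adaptive step-size
line search.

The i.i.d. samples for a single image are produced by ``pixel_draw_samples``
(one random pixel per superpixel, binarized at the global Otsu threshold);
``gibbs_sample`` provides model-generated samples for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from skimage.filters import threshold_otsu

from ._optim import ProxGradResult, prox_gradient
from .superpixels import SuperpixelMap

__all__ = [
    "IsingModel",
    "LabelSamples",
    "ising_conditional",
    "npl_objective",
    "fit_structure",
    "extract_graph",
    "gibbs_sample",
    "pixel_draw_samples",
]


@dataclass
class IsingModel:
    """Node biases, symmetric edge couplings and the candidate edge set.

    ``theta_edge[k]`` is the single shared coupling of unordered pair
    ``edges[k]``; pairs outside the candidate set are implicitly zero.
    """

    theta_node: np.ndarray          # (p,)
    theta_edge: np.ndarray          # (m,)
    edges: np.ndarray               # (m, 2) with i < j
    lambda_struct: float = 0.0
    trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.theta_node)

    def coupling_matrix(self) -> np.ndarray:
        """Dense symmetric (p, p) coupling matrix with zero diagonal."""
        w = np.zeros((self.n_nodes, self.n_nodes))
        if len(self.edges):
            w[self.edges[:, 0], self.edges[:, 1]] = self.theta_edge
            w[self.edges[:, 1], self.edges[:, 0]] = self.theta_edge
        return w


@dataclass
class LabelSamples:
    """n_draws x n_nodes matrix of +-1 labels with a provenance tag."""

    data: np.ndarray
    provenance: str = "ground_truth"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1:
            raise ValueError("samples must be a nonempty n_draws x n_nodes matrix")
        if not np.all(np.isin(self.data, (-1, 1))):
            raise ValueError("label samples must be +-1")


def ising_conditional(model: IsingModel, sample_row: np.ndarray, i: int) -> float:
    """P(y_i = +1 | y_rest) under the Ising model, overflow-safe."""
    y = np.asarray(sample_row, dtype=float)
    a = model.theta_node[i]
    for k, (u, v) in enumerate(model.edges):
        if u == i:
            a += model.theta_edge[k] * y[v]
        elif v == i:
            a += model.theta_edge[k] * y[u]
    return float(expit(2.0 * a))


def _npl_value_grad(
    theta_node: np.ndarray,
    theta_edge: np.ndarray,
    edges: np.ndarray,
    y: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Vectorized symmetric negative pseudo-likelihood and its gradient.

    The local fields are A = theta_node + Y W with W the symmetric coupling
    matrix; each edge coupling receives gradient contributions from the
    conditionals of both of its endpoints.
    """
    p = len(theta_node)
    w = np.zeros((p, p))
    if len(edges):
        w[edges[:, 0], edges[:, 1]] = theta_edge
        w[edges[:, 1], edges[:, 0]] = theta_edge
    a = theta_node[None, :] + y @ w                      # (n, p)
    z = 2.0 * y * a
    value = float(np.logaddexp(0.0, -z).sum())
    g = -2.0 * y * expit(-z)                             # dL/da, (n, p)
    grad_node = g.sum(axis=0)
    if len(edges):
        gy = g.T @ y                                     # (p, p)
        grad_edge = gy[edges[:, 0], edges[:, 1]] + gy[edges[:, 1], edges[:, 0]]
    else:
        grad_edge = np.zeros(0)
    return value, grad_node, grad_edge


def npl_objective(model: IsingModel, samples: LabelSamples) -> tuple[float, dict]:
    """Unpenalized pseudo-likelihood objective and its gradient blocks."""
    y = samples.data.astype(float)
    value, gn, ge = _npl_value_grad(model.theta_node, model.theta_edge, model.edges, y)
    return value, {"theta_node": gn, "theta_edge": ge}


def fit_structure(
    samples: LabelSamples,
    candidate_edges: np.ndarray,
    lambda_struct: float,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> IsingModel:
    """Fit the l1-penalized symmetric pseudo-likelihood Ising model.

    Minimizes npl + lambda * ||theta_edge||_1 (biases unpenalized) by
    monotone accelerated proximal gradient with soft-threshold prox and
    backtracking line search.
    """
    if lambda_struct < 0:
        raise ValueError("lambda_struct must be >= 0")
    edges = np.asarray(candidate_edges, dtype=np.int64).reshape(-1, 2)
    y = samples.data.astype(float)
    p = y.shape[1]
    m = len(edges)

    def smooth(x: np.ndarray) -> tuple[float, np.ndarray]:
        v, gn, ge = _npl_value_grad(x[:p], x[p:], edges, y)
        return v, np.concatenate([gn, ge])

    def penalty(x: np.ndarray) -> float:
        return lambda_struct * np.abs(x[p:]).sum()

    def prox(x: np.ndarray, t: float) -> np.ndarray:
        out = x.copy()
        out[p:] = np.sign(x[p:]) * np.maximum(np.abs(x[p:]) - t * lambda_struct, 0.0)
        return out

    res: ProxGradResult = prox_gradient(
        smooth, penalty, prox, x0=np.zeros(p + m),
        max_iter=max_iter, tol=tol,
    )
    return IsingModel(
        theta_node=res.x[:p], theta_edge=res.x[p:], edges=edges,
        lambda_struct=lambda_struct, trace=res.trace, converged=res.converged,
    )


def extract_graph(model: IsingModel, zero_tol: float = 1e-6) -> np.ndarray:
    """Learned edge set: candidate edges with |coupling| above tolerance."""
    if len(model.edges) == 0:
        return np.empty((0, 2), dtype=np.int64)
    keep = np.abs(model.theta_edge) > zero_tol
    return model.edges[keep]


def gibbs_sample(
    model: IsingModel,
    n_draws: int,
    burn_in: int = 500,
    thin: int = 2,
    seed: int = 0,
) -> LabelSamples:
    """Single-site Gibbs sampler over the Ising model; seeded and thinned."""
    rng = np.random.default_rng(seed)
    p = model.n_nodes
    w = model.coupling_matrix()
    y = rng.choice([-1.0, 1.0], size=p)
    out = np.empty((n_draws, p), dtype=np.int8)
    kept = 0
    sweep = 0
    while kept < n_draws:
        for i in range(p):
            a = model.theta_node[i] + w[i] @ y
            y[i] = 1.0 if rng.random() < expit(2.0 * a) else -1.0
        sweep += 1
        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            out[kept] = y
            kept += 1
    return LabelSamples(data=out, provenance="gibbs")


def pixel_draw_samples(
    image: np.ndarray,
    sp: SuperpixelMap,
    n_draws: int,
    seed: int = 0,
) -> LabelSamples:
    """I.i.d. label samples for one image: per draw, one uniform-random pixel
    per superpixel, binarized at the image's global Otsu threshold and mapped
    {0, 1} -> {-1, +1}."""
    img = np.asarray(image, dtype=float)
    if img.shape != sp.labels.shape:
        raise ValueError("image and superpixel map shapes differ")
    rng = np.random.default_rng(seed)
    if np.ptp(img) < 1e-12:
        binary = np.zeros(img.shape, dtype=np.int8)
    else:
        binary = (img > threshold_otsu(img)).astype(np.int8)
    signed = 2 * binary - 1
    out = np.empty((n_draws, sp.n_regions), dtype=np.int8)
    flat_labels = sp.labels.ravel()
    order = np.argsort(flat_labels, kind="stable")
    sizes = sp.region_sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    signed_sorted = signed.ravel()[order]
    for rid in range(sp.n_regions):
        block = signed_sorted[starts[rid] : starts[rid] + sizes[rid]]
        out[:, rid] = block[rng.integers(0, sizes[rid], size=n_draws)]
    return LabelSamples(data=out, provenance="pixel_draw")
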