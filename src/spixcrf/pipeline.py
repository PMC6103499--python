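"""End-to-end pipeline: superpixels -> features -> structure learning ->
CRF training / inference -> pixel mask -> evaluation.

A model is trained on a cohort of (slice, truth-mask) pairs and applied to
new slices.  At test time the pairwise graph of each slice is learned from
the slice itself (l1-Ising structure learning on Otsu-binarized pixel
draws), falling back to the plain 1-hop region adjacency graph when
``graph_mode`` is "rag".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .config import RunConfig
from .crf import CRFModel, CRFTrainItem, infer_labels, labels_to_mask, make_item, train_crf
from .features import (
    EdgeFeatures,
    FeatureTable,
    assemble_edge_features,
    assemble_node_features,
    fit_standardization,
)
from .metrics import evaluate_cohort, evaluate_pair
from .structure import extract_graph, fit_structure, pixel_draw_samples
from .superpixels import RegionGraph, SuperpixelMap, build_rag, node_labels_from_mask, slic_adaptive

__all__ = ["SegmentationResult", "segment_image", "train_model", "run_pipeline"]


@dataclass
class SegmentationResult:
    """Predicted mask plus every intermediate artifact of one slice."""

    mask: np.ndarray
    labels: np.ndarray
    prob_pos: np.ndarray
    superpixels: SuperpixelMap
    graph: RegionGraph
    learned_edges: np.ndarray
    features: FeatureTable
    report: pd.DataFrame | None = None


def _featurize(image: np.ndarray, config: RunConfig, n_superpixels: int):
    sp = slic_adaptive(image, n_superpixels, config.compactness, config.slic_iters)
    rag = build_rag(sp, max_hops=config.max_hops)
    feats = assemble_node_features(
        image, sp,
        curvature_mode=config.curvature_mode,
        curvature_sigma=config.curvature_sigma,
        entropy_bins=config.entropy_bins,
        glrl_levels=config.glrl_levels,
    )
    efeats = assemble_edge_features(image, sp, rag)
    return sp, rag, feats, efeats


def _slice_graph(image, sp, rag: RegionGraph, efeats: EdgeFeatures,
                 config: RunConfig, seed: int) -> tuple[np.ndarray, EdgeFeatures]:
    """Edges the CRF will use for this slice, with their features."""
    if config.graph_mode == "rag":
        keep = rag.hops == 1
    else:
        samples = pixel_draw_samples(image, sp, config.n_draws_struct, seed=seed)
        with warnings.catch_warnings():
            # nodes whose draws are single-class push their (unpenalized)
            # biases toward infinity, so the objective keeps creeping; the
            # learned edge support stabilizes long before, making the
            # max-iter warning uninformative here
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_structure(samples, rag.edges, config.lambda_struct,
                                  max_iter=config.struct_max_iter)
        learned = extract_graph(model, config.zero_tol)
        learned_set = {tuple(e) for e in learned}
        keep = np.array([tuple(e) in learned_set for e in rag.edges], dtype=bool) \
            if len(rag.edges) else np.zeros(0, dtype=bool)
    return rag.edges[keep], EdgeFeatures(data=efeats.data[keep], edges=rag.edges[keep])


def _derive_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31 - 1))


def train_model(
    train_pairs: list[tuple[np.ndarray, np.ndarray]],
    config: RunConfig,
) -> tuple[CRFModel, int]:
    """Train the tied CRF on (slice, truth-mask) pairs.

    Returns the fitted model and the superpixel count used.  When
    ``sweep_superpixels`` is on, every count in ``superpixel_grid`` is tried
    and the one maximizing mean training-set Dice wins.
    """
    if not train_pairs:
        raise ValueError("need at least one training pair")
    counts = config.superpixel_grid if config.sweep_superpixels else [config.n_superpixels]
    best = None
    for count in counts:
        model = _train_at_count(train_pairs, config, count)
        if len(counts) == 1:
            return model, count
        dices = []
        for k, (image, truth) in enumerate(train_pairs):
            res = segment_image(image, model, config, n_superpixels=count,
                                seed=_derive_seed(config.seed, 10_000 + k))
            dices.append(evaluate_pair(res.mask, truth).dice)
        score = float(np.mean(dices))
        if best is None or score > best[0]:
            best = (score, model, count)
    return best[1], best[2]


def _train_at_count(train_pairs, config: RunConfig, n_superpixels: int) -> CRFModel:
    raw_tables: list[FeatureTable] = []
    partial = []
    for k, (image, truth) in enumerate(train_pairs):
        sp, rag, feats, efeats = _featurize(image, config, n_superpixels)
        labels = node_labels_from_mask(sp, truth)
        edges, sub_ef = _slice_graph(image, sp, rag, efeats, config,
                                     seed=_derive_seed(config.seed, k))
        raw_tables.append(feats)
        partial.append((feats, sub_ef, labels))
    center, scale = fit_standardization(raw_tables)
    items = [
        make_item(feats.standardized(center, scale), sub_ef, labels)
        for feats, sub_ef, labels in partial
    ]
    return train_crf(
        items, lambda1=config.lambda1, lambda2=config.lambda2,
        max_iter=config.crf_max_iter,
        feature_names=list(raw_tables[0].data.columns),
        center=center, scale=scale,
    )


def segment_image(
    image: np.ndarray,
    model: CRFModel,
    config: RunConfig,
    n_superpixels: int | None = None,
    truth: np.ndarray | None = None,
    seed: int | None = None,
) -> SegmentationResult:
    """Segment one slice with a trained model; evaluates if truth given."""
    if model.center is None or model.scale is None:
        raise ValueError("model carries no standardization parameters")
    count = n_superpixels or config.n_superpixels
    sp, rag, feats, efeats = _featurize(image, config, count)
    edges, sub_ef = _slice_graph(image, sp, rag, efeats, config,
                                 seed=config.seed if seed is None else seed)
    std = feats.standardized(model.center, model.scale)
    item = make_item(std, sub_ef)
    labeling = infer_labels(model, item, mode=config.infer_mode)
    mask = labels_to_mask(sp, labeling)
    report = None
    if truth is not None:
        report = evaluate_cohort([(mask, truth)])
    return SegmentationResult(
        mask=mask, labels=labeling.labels, prob_pos=labeling.prob_pos,
        superpixels=sp, graph=rag, learned_edges=edges, features=std,
        report=report,
    )


def run_pipeline(
    config: RunConfig,
    image: np.ndarray,
    truth: np.ndarray | None = None,
    model: CRFModel | None = None,
    train_pairs: list[tuple[np.ndarray, np.ndarray]] | None = None,
    outdir: str | Path | None = None,
) -> SegmentationResult:
    """Full per-slice pipeline with artifact persistence.

    Either a trained ``model`` or ``train_pairs`` must be supplied; with
    ``outdir`` set, every intermediate (superpixel map, features, graph,
    model, mask, report, manifest) is written there.
    """
    if model is None:
        if train_pairs is None:
            raise ValueError("supply a trained model or training data")
        model, count = train_model(train_pairs, config)
    else:
        count = config.n_superpixels
    result = segment_image(image, model, config, n_superpixels=count, truth=truth)

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.save_superpixels(out / "superpixels", result.superpixels,
                             params={"n_superpixels": count,
                                     "compactness": config.compactness,
                                     "n_iter": config.slic_iters})
        _io.save_features(out / "features", result.features)
        _io.save_graph(out / "graph.csv", result.graph)
        np.savetxt(out / "learned_edges.csv", result.learned_edges,
                   fmt="%d", delimiter=",", header="node_i,node_j", comments="")
        _io.save_crf_model(out / "model.json", model)
        _io.write_mask(out / "mask.png", result.mask)
        pd.DataFrame({"region_id": np.arange(len(result.prob_pos)),
                      "prob_pos": result.prob_pos}).to_csv(out / "probabilities.csv",
                                                           index=False)
        if result.report is not None:
            result.report.to_csv(out / "report.csv")
        manifest = {"config": config.to_dict(), **config.provenance()}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
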