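"""Desk-scale end-to-end experiment on synthetic slides.

Renders a small cohort of fixture slides, trains the patch CNN and the
graph-attention network on the training split using ground-truth patch
labels, and evaluates both on held-out slides.  Shared by the CLI ``run``
verb, the test-suite, and the README walkthrough.
"""

from __future__ import annotations

import numpy as np

from . import patchnet, synthfix
from .pipeline import RunConfig, crop_patches
from .slideprep import PatchSet

# tumor_map class indices
TUMOR, BENIGN = 0, 1


def render_cohort(fixture_seed: int, n_slides: int = 6, patch_size: int = 64,
                  canvas=(1024, 1024), piece_radius: float = 260.0):
    """Render fixture slides with tumor regions; returns
    ``[(slide_id, raster, labels_df)]`` with ground-truth patch labels."""
    out = []
    for i in range(n_slides):
        spec = synthfix.random_section_spec(
            fixture_seed * 1000 + i, canvas=canvas, tumor=True,
            piece_radius=piece_radius, patch_size=patch_size)
        img, gt = synthfix.make_section_image(spec)
        labels = gt.patch_labels(patch_size, min_tissue_frac=0.5)
        labels = labels[~labels["hole"]].reset_index(drop=True)
        out.append((f"slide_{i}", img, labels))
    return out


def _patches_and_labels(slide, patch_size):
    sid, img, df = slide
    import pandas as pd

    recs = pd.DataFrame({
        "x": df["x"], "y": df["y"], "tissue_frac": df["tissue_frac"],
        "section": df["section"], "piece": df["piece"],
        "config": "tumor_map", "hole_candidate": False,
    })
    ps = PatchSet(sid, patch_size, recs)
    patches = crop_patches(img, ps)
    y = np.where(df["tumor"].to_numpy(), TUMOR, BENIGN)
    return ps, patches, y


def train_desk_models(fixture_seed: int, config: RunConfig, n_train: int = 4,
                      n_test: int = 2):
    """Train desk-profile CNN + GNN; returns (models, test slides, template)."""
    cohort = render_cohort(fixture_seed, n_train + n_test, config.patch_size)
    mc = config.model_config()
    train = cohort[:n_train]
    all_patches, all_labels = [], []
    per_slide = []
    for slide in train:
        ps, patches, y = _patches_and_labels(slide, config.patch_size)
        per_slide.append((ps, patches, y))
        all_patches.append(patches)
        all_labels.append(y)
    backbone = patchnet.train_patch_cnn(
        np.concatenate(all_patches), np.concatenate(all_labels), mc)
    graphs, labels = [], []
    for ps, patches, y in per_slide:
        emb = patchnet.embed_patches(backbone, patches)
        graphs.append(patchnet.build_patch_graph(
            ps.centers, emb, radius=1.5 * config.patch_size,
            task="tumor_map", slide_id=ps.slide_id))
        labels.append(y)
    gnn = patchnet.train_gnn(graphs, labels, mc, task="tumor_map")
    template_ellipse = (256.0, 256.0, 150.0, 120.0, 0.0)
    _, template = synthfix.make_template(
        "scalp", template_ellipse, blue_mark=(256.0, 136.0), red_mark=(256.0, 376.0))
    slides = [(sid, img) for sid, img, _ in cohort[n_train:]]
    models = {"backbone": backbone, "gnn": gnn}
    return models, slides, template


def desk_experiment(fixture_seed: int = 0, seed: int = 0, n_train: int = 4,
                    n_test: int = 2, patch_size: int = 64):
    """Full CNN -> graph -> GNN tumor experiment with a held-out test split.

    Returns a dict with pooled test AUCs for the node-only CNN probe and the
    GNN (scored on the tumor class), plus the trained models.
    """
    config = RunConfig(seed=seed, patch_size=patch_size, profile="desk")
    cohort = render_cohort(fixture_seed, n_train + n_test, patch_size)
    mc = config.model_config()
    split = [_patches_and_labels(s, patch_size) for s in cohort]
    train, test = split[:n_train], split[n_train:]
    backbone = patchnet.train_patch_cnn(
        np.concatenate([p for _, p, _ in train]),
        np.concatenate([y for _, _, y in train]), mc)

    def graphs_of(part):
        gs, ys = [], []
        for ps, patches, y in part:
            emb = patchnet.embed_patches(backbone, patches)
            gs.append(patchnet.build_patch_graph(
                ps.centers, emb, radius=1.5 * patch_size,
                task="tumor_map", slide_id=ps.slide_id))
            ys.append(y)
        return gs, ys

    g_train, y_train = graphs_of(train)
    g_test, y_test = graphs_of(test)
    gnn = patchnet.train_gnn(g_train, y_train, mc, task="tumor_map")

    cnn_scores, gnn_scores, labels, slide_ids = [], [], [], []
    for (ps, patches, y), g in zip(test, g_test):
        cnn_scores.append(patchnet.cnn_predict(backbone, patches)[:, TUMOR])
        gnn_scores.append(patchnet.gnn_predict(gnn, g)[:, TUMOR])
        labels.append((y == TUMOR).astype(int))
        slide_ids.append(np.full(len(y), ps.slide_id, dtype=object))
    cnn_scores = np.concatenate(cnn_scores)
    gnn_scores = np.concatenate(gnn_scores)
    labels = np.concatenate(labels)
    slide_ids = np.concatenate(slide_ids)
    return {
        "cnn_auc": patchnet.evaluate_auc(cnn_scores, labels),
        "gnn_auc": patchnet.evaluate_auc(gnn_scores, labels),
        "gnn_macro_auc": patchnet.evaluate_auc(gnn_scores, labels, slide_ids, macro=True),
        "n_test_patches": int(len(labels)),
        "backbone": backbone,
        "gnn": gnn,
    }
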