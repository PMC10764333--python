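"""Case orchestration: per-slide preprocessing in series, per-section
fan-out (embedding + GNN, ink orientation, optional tile export) in
parallel, then mapping — plus the Deep Zoom (DZI) tile writer.

Results are a pure function of (inputs, RunConfig): every stochastic step
draws its seed from the config, and worker count never changes numbers,
only wall time.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
from joblib import Parallel, delayed

from . import gross3d, inkorient, patchnet, sitemap, slideprep

__all__ = ["RunConfig", "run_pipeline", "export_tiles", "crop_patches", "load_raster"]


@dataclass
class RunConfig:
    seed: int = 0
    profile: str = "desk"  # 'desk' | 'full'
    patch_size: int = 64
    min_tissue_frac: float = 0.5
    n_sections: int = 1
    pieces_per_section: tuple = (1,)
    r_section: float | None = None
    r_piece: float | None = None
    band_px: int = 16
    min_component_px: int = 50
    workers: int = 1
    ot_iters: int = 300
    ot_projections: int = 64
    export_dzi: bool = False
    paths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        d["pieces_per_section"] = tuple(d["pieces_per_section"])
        return cls(**d)

    def model_config(self) -> patchnet.ModelConfig:
        if self.profile == "desk":
            return patchnet.ModelConfig.desk(seed=self.seed)
        return patchnet.ModelConfig(seed=self.seed)


def load_raster(path) -> np.ndarray:
    path = str(path)
    if path.endswith((".tif", ".tiff", ".svs")):
        import tifffile

        return tifffile.imread(path)
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def crop_patches(raster: np.ndarray, patchset: slideprep.PatchSet) -> np.ndarray:
    """Stack the pixel content of every patch record, order preserved."""
    ps = patchset.patch_size
    h, w = raster.shape[:2]
    out = np.zeros((len(patchset), ps, ps, 3), dtype=raster.dtype)
    for i, (x, y) in enumerate(patchset.coords.astype(int)):
        tile = raster[max(y, 0) : y + ps, max(x, 0) : x + ps]
        out[i, : tile.shape[0], : tile.shape[1]] = tile[..., :3]
    return out


# ---------------------------------------------------------------------------
# per-section work unit


def _assess_section(raster, patchset, section_id, models, config: RunConfig):
    rec: dict = {"section": int(section_id)}
    t0 = time.perf_counter()
    sub = patchset.subset(patchset.records["section"] == section_id)
    try:
        # ink orientation over the section's bounding box
        ps = config.patch_size
        x0, y0 = sub.coords.min(axis=0).astype(int)
        x1, y1 = (sub.coords.max(axis=0) + ps).astype(int)
        crop = raster[y0:y1, x0:x1]
        mask = slideprep.compute_tissue_mask(crop).mask
        inks, line = inkorient.orient_section(
            crop, mask, band_px=config.band_px,
            min_component_px=config.min_component_px)
        rec["inks"] = inks.to_record()
        rec["orientation"] = None if line is None else {
            "theta": line.theta,
            "blue_xy": [line.blue_xy[0] + x0, line.blue_xy[1] + y0],
            "red_xy": [line.red_xy[0] + x0, line.red_xy[1] + y0],
        }
        rec["oriented"] = line is not None
    except Exception as exc:  # stage failure -> partial bundle
        rec["error"] = f"ink: {exc}"
        return rec

    try:
        if models is not None:
            backbone, gnn = models["backbone"], models["gnn"]
            patches = crop_patches(raster, sub)
            emb = patchnet.embed_patches(backbone, patches)
            graph = patchnet.build_patch_graph(
                sub.centers, emb, radius=1.5 * config.patch_size,
                task=gnn.task, slide_id=patchset.slide_id)
            probs = patchnet.gnn_predict(gnn, graph)
            rec["patches"] = [
                {"x": int(x), "y": int(y), "probs": [round(float(p), 6) for p in row]}
                for (x, y), row in zip(sub.coords, probs)
            ]
    except Exception as exc:
        rec["error"] = f"assess: {exc}"
    rec["seconds"] = round(time.perf_counter() - t0, 4)
    return rec


def run_pipeline(slides, config: RunConfig, models=None, template=None):
    """Run the per-case workflow over ``slides`` (iterable of
    ``(slide_id, RGB raster)``).

    Per slide: tissue mask, patch grid, and section/piece assignment run in
    series; then every section fans out (GNN assessment + ink orientation)
    across ``config.workers`` workers; sections with a detected ink line
    are finally morphed onto ``template`` when one is given.  Returns a
    JSON-serializable bundle; stage failures mark it ``partial``.
    """
    bundle = {"config": json.loads(config.to_json()), "slides": [], "partial": False}
    for slide_id, raster in slides:
        srec = {"slide_id": str(slide_id), "sections": []}
        t0 = time.perf_counter()
        try:
            tm = slideprep.compute_tissue_mask(raster, slide_id=str(slide_id))
            if not tm.mask.any():
                warnings.warn(f"slide {slide_id}: no tissue found")
                srec["empty"] = True
                bundle["slides"].append(srec)
                continue
            patchset = slideprep.extract_patches(
                tm, config.patch_size, config.min_tissue_frac)
            patchset = slideprep.assign_sections_pieces(
                patchset, config.n_sections, config.pieces_per_section,
                config.r_section, config.r_piece, seed=config.seed)
        except Exception as exc:
            srec["error"] = f"preprocess: {exc}"
            bundle["partial"] = True
            bundle["slides"].append(srec)
            continue
        sections = sorted(patchset.records["section"].unique())
        results = Parallel(n_jobs=config.workers, backend="threading")(
            delayed(_assess_section)(raster, patchset, sid, models, config)
            for sid in sections
        )
        for rec in results:
            if "error" in rec:
                bundle["partial"] = True
            if template is not None and rec.get("oriented"):
                sub = patchset.subset(patchset.records["section"] == rec["section"])
                try:
                    res = sitemap.morph_to_ellipse(
                        sub.centers,
                        (template.center[0], template.center[1],
                         template.axes[0], template.axes[1], template.rotation),
                        iters=config.ot_iters,
                        n_projections=config.ot_projections,
                        seed=config.seed)
                    line = inkorient.OrientationLine(
                        tuple(rec["orientation"]["blue_xy"]),
                        tuple(rec["orientation"]["red_xy"]),
                        rec["orientation"]["theta"])
                    res = sitemap.rotate_to_template(res, line, template.line)
                    rec["mapping"] = {
                        "applied_rotation": round(float(res.applied_rotation), 4),
                        "final_distance": round(float(res.final_distance), 4),
                        "inside_fraction": round(res.inside_fraction(), 4),
                    }
                except Exception as exc:
                    rec["error"] = f"mapping: {exc}"
                    bundle["partial"] = True
            elif template is not None:
                rec["mapping"] = None  # unoriented section: flagged, not mapped
            srec["sections"].append(rec)
        srec["seconds"] = round(time.perf_counter() - t0, 4)
        srec["n_patches"] = int(len(patchset))
        bundle["slides"].append(srec)
    return bundle


# ---------------------------------------------------------------------------
# Deep Zoom export


def export_tiles(raster: np.ndarray, out_dir, name: str = "slide",
                 tile_size: int = 256, fmt: str = "png"):
    """Write a Deep Zoom Image pyramid: ``{name}.dzi`` descriptor plus
    ``{name}_files/<level>/<col>_<row>.<fmt>`` tiles.  Level-0-resolution
    tiles (the deepest level) stitch back to the input exactly."""
    from pathlib import Path

    from PIL import Image

    if tile_size < 1 or (tile_size & (tile_size - 1)) != 0:
        raise ValueError("tile size must be a power of two")
    raster = np.ascontiguousarray(raster)
    h, w = raster.shape[:2]
    out_dir = Path(out_dir)
    max_level = int(np.ceil(np.log2(max(w, h)))) if max(w, h) > 1 else 0
    files = out_dir / f"{name}_files"
    img = Image.fromarray(raster)
    for level in range(max_level, -1, -1):
        scale = 2 ** (max_level - level)
        lw, lh = max(1, int(np.ceil(w / scale))), max(1, int(np.ceil(h / scale)))
        lvl_img = img if scale == 1 else img.resize((lw, lh), Image.LANCZOS)
        lvl_dir = files / str(level)
        lvl_dir.mkdir(parents=True, exist_ok=True)
        for row in range(int(np.ceil(lh / tile_size))):
            for col in range(int(np.ceil(lw / tile_size))):
                box = (col * tile_size, row * tile_size,
                       min((col + 1) * tile_size, lw), min((row + 1) * tile_size, lh))
                lvl_img.crop(box).save(lvl_dir / f"{col}_{row}.{fmt}")
    dzi = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<Image xmlns="http://schemas.microsoft.com/deepzoom/2008" '
        f'Format="{fmt}" Overlap="0" TileSize="{tile_size}">\n'
        f'  <Size Width="{w}" Height="{h}"/>\n'
        "</Image>\n"
    )
    (out_dir / f"{name}.dzi").write_text(dzi)
    return out_dir / f"{name}.dzi"
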