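"""Tissue masking, patch grids, section/piece assignment, hole candidates."""

import numpy as np
import pytest
from shapely.geometry import Point
from skimage.draw import polygon as draw_polygon

from conftest import layout_patchset, piece_agreement
from marginmap import slideprep, synthfix
from marginmap.slideprep import (
    MaskParams,
    SectionCountError,
    TissueMask,
    alpha_shape,
    assign_sections_pieces,
    compute_tissue_mask,
    extract_patches,
    hole_candidates,
)


class TestTissueMask:
    def test_uniform_white_gives_empty_mask(self):
        img = np.full((512, 512, 3), 255, dtype=np.uint8)
        assert not compute_tissue_mask(img).mask.any()

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError):
            compute_tissue_mask(np.empty((0, 0, 3)))

    def test_disk_blob_iou(self, tumor_section):
        img, gt = tumor_section
        mask = compute_tissue_mask(img).mask
        truth = np.zeros(mask.shape, dtype=bool)
        for sec in gt.outline_polygons:
            for poly in sec:
                xy = np.asarray(poly.exterior.coords)
                rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=mask.shape)
                truth[rr, cc] = True
        # the rendered hole is background-colored, so cut it from truth
        for sec in gt.hole_polygons:
            for poly in sec:
                xy = np.asarray(poly.exterior.coords)
                rr, cc = draw_polygon(xy[:, 1], xy[:, 0], shape=mask.shape)
                truth[rr, cc] = False
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.95

    def test_gray_text_block_excluded(self):
        img = np.full((512, 512, 3), 255, dtype=np.uint8)
        img[50:200, 50:200] = (120, 120, 120)  # gray scanner text, saturation 0
        img[300:420, 300:420] = (200, 120, 150)  # pink tissue
        mask = compute_tissue_mask(img).mask
        assert not mask[60:190, 60:190].any()
        assert mask[310:410, 310:410].mean() > 0.9


class TestExtractPatches:
    def test_full_tissue_grid(self):
        tm = TissueMask(np.ones((512, 512), dtype=bool))
        ps = extract_patches(tm, 256, 0.5)
        assert sorted(map(tuple, ps.coords.astype(int))) == [
            (0, 0), (0, 256), (256, 0), (256, 256)]
        assert (ps.records["tissue_frac"] == 1.0).all()

    def test_empty_mask_gives_empty_set(self):
        ps = extract_patches(TissueMask(np.zeros((512, 512), dtype=bool)), 256, 0.5)
        assert len(ps) == 0

    def test_matches_brute_force_fraction(self):
        rng = np.random.default_rng(0)
        mask = rng.random((320, 320)) < 0.5
        ps = extract_patches(TissueMask(mask), 64, 0.5)
        got = set(map(tuple, ps.coords.astype(int)))
        want = set()
        for y in range(0, 320, 64):
            for x in range(0, 320, 64):
                if mask[y : y + 64, x : x + 64].mean() >= 0.5:
                    want.add((x, y))
        assert got == want

    def test_patch_larger_than_raster_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(TissueMask(np.ones((100, 100), dtype=bool)), 256)


class TestAssignment:
    def test_two_distant_sections(self):
        spec = synthfix.random_section_spec(
            301, canvas=(1024, 3072), n_sections=2, pieces_per_section=(1, 1),
            piece_radius=150, ink=False)
        _, gt = synthfix.make_section_image(spec)
        ps, df = layout_patchset(gt)
        out = assign_sections_pieces(ps, 2, (1, 1), seed=0)
        assert piece_agreement(out, df) == 1.0

    def test_one_section_two_pieces(self):
        spec = synthfix.random_section_spec(
            302, canvas=(1200, 1024), n_sections=1, pieces_per_section=(2,),
            piece_radius=150, ink=False)
        _, gt = synthfix.make_section_image(spec)
        ps, df = layout_patchset(gt)
        out = assign_sections_pieces(ps, 1, (2,), seed=0)
        assert out.records["section"].nunique() == 1
        assert out.records["piece"].nunique() == 2
        assert piece_agreement(out, df) == 1.0

    def test_conjoined_pieces_split_by_spectral_clustering(self):
        spec = synthfix.random_section_spec(
            303, canvas=(1024, 1024), pieces_per_section=(2,),
            piece_radius=150, ink=False, conjoined=True)
        _, gt = synthfix.make_section_image(spec)
        ps, df = layout_patchset(gt)
        out = assign_sections_pieces(ps, 1, (2,), seed=0)
        assert out.records["piece"].nunique() == 2
        assert piece_agreement(out, df) >= 0.90

    def test_excess_sections_rejected_with_count(self):
        spec = synthfix.random_section_spec(
            304, canvas=(1024, 3072), n_sections=2, pieces_per_section=(1, 1),
            piece_radius=150, ink=False)
        _, gt = synthfix.make_section_image(spec)
        ps, _ = layout_patchset(gt)
        with pytest.raises(SectionCountError, match="2"):
            assign_sections_pieces(ps, 1, (1,), seed=0)

    def test_invariant_to_order_and_translation(self):
        spec = synthfix.random_section_spec(
            305, canvas=(1200, 1024), pieces_per_section=(2,), piece_radius=150,
            ink=False)
        _, gt = synthfix.make_section_image(spec)
        ps, _ = layout_patchset(gt)
        base = assign_sections_pieces(ps, 1, (2,), seed=0)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(ps))
        shuffled = ps.subset(perm)
        shuffled.records["x"] += 4096  # global translation
        shuffled.records["y"] += 2048
        out = assign_sections_pieces(shuffled, 1, (2,), seed=0)
        assert np.array_equal(out.records["section"].to_numpy(),
                              base.records["section"].to_numpy()[perm])
        assert np.array_equal(out.records["piece"].to_numpy(),
                              base.records["piece"].to_numpy()[perm])

    def test_agrees_with_union_find_oracle(self):
        """Non-spectral stages equal a brute-force union-find partition."""
        spec = synthfix.random_section_spec(
            306, canvas=(1024, 3072), n_sections=2, pieces_per_section=(2, 1),
            piece_radius=140, ink=False)
        _, gt = synthfix.make_section_image(spec)
        ps, _ = layout_patchset(gt)
        assert len(ps) <= 500
        out = assign_sections_pieces(ps, 2, (2, 1), seed=0)

        def uf_partition(centers, radius):
            parent = list(range(len(centers)))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(len(centers)):
                for j in range(i + 1, len(centers)):
                    if np.linalg.norm(centers[i] - centers[j]) <= radius:
                        parent[find(i)] = find(j)
            return np.array([find(i) for i in range(len(centers))])

        centers = ps.centers
        for radius, labels in ((1024.0, out.records["section"].to_numpy()),):
            uf = uf_partition(centers, radius)
            # same partition: label pairs agree
            for lab in np.unique(uf):
                members = labels[uf == lab]
                assert (members == members[0]).all()
            assert len(np.unique(uf)) == len(np.unique(labels))


class TestHoleCandidates:
    @pytest.fixture(scope="class")
    def annulus(self):
        spec = synthfix.random_section_spec(42, piece_radius=260, ink=False, hole=True)
        img, gt = synthfix.make_section_image(spec)
        ps = extract_patches(compute_tissue_mask(img), 64, 0.5)
        ps = assign_sections_pieces(ps, 1, (1,), seed=0)
        return ps, hole_candidates(ps), gt

    def test_convex_disk_has_no_candidates(self):
        spec = synthfix.random_section_spec(42, piece_radius=260, ink=False)
        img, _ = synthfix.make_section_image(spec)
        ps = extract_patches(compute_tissue_mask(img), 64, 0.5)
        ps = assign_sections_pieces(ps, 1, (1,), seed=0)
        mm = hole_candidates(ps)
        assert not mm.records["hole_candidate"].any()

    def test_annulus_matches_point_in_polygon_brute_force(self, annulus):
        ps, mm, _ = annulus
        pred = set(map(tuple, mm.records.loc[mm.records["hole_candidate"],
                                             ["x", "y"]].to_numpy()))
        shape = alpha_shape(ps.centers, 1.0 / (2 * 64)).buffer(16.0)
        geoms = [shape] if shape.geom_type == "Polygon" else list(shape.geoms)

        def ray_cast(coords, pt):
            x, y = pt
            inside = False
            for i in range(len(coords)):
                x1, y1 = coords[i]
                x2, y2 = coords[(i + 1) % len(coords)]
                if (y1 > y) != (y2 > y):
                    if x1 + (y - y1) * (x2 - x1) / (y2 - y1) > x:
                        inside = not inside
            return inside

        have = set(zip(ps.records["x"].astype(int), ps.records["y"].astype(int)))
        x0, y0, x1, y1 = shape.bounds
        want = set()
        for gy in range(int(np.floor(y0 / 64)) * 64, int(y1) + 1, 64):
            for gx in range(int(np.floor(x0 / 64)) * 64, int(x1) + 1, 64):
                if (gx, gy) in have:
                    continue
                c = (gx + 32, gy + 32)
                if any(ray_cast(list(g.exterior.coords)[:-1], c)
                       and not any(ray_cast(list(r.coords)[:-1], c)
                                   for r in g.interiors) for g in geoms):
                    want.add((gx, gy))
        assert pred == want and len(pred) > 0

    def test_candidates_tile_the_true_hole(self, annulus):
        _, mm, gt = annulus
        pred = set(map(tuple, mm.records.loc[mm.records["hole_candidate"],
                                             ["x", "y"]].to_numpy()))
        df = gt.patch_labels(64, 0.5)
        truth = set(map(tuple, df.loc[df["hole"], ["x", "y"]].to_numpy()))
        assert truth <= pred

    def test_edge_tear_bridged_by_alpha_shape(self):
        spec = synthfix.random_section_spec(43, piece_radius=280, ink=False,
                                            rotation=0.0)
        sec = spec.sections[0]
        sec.tears = [synthfix.wedge_polygon(sec.pieces[0].polygon, 90.0,
                                            depth_frac=0.8, width_deg=30.0)]
        img, gt = synthfix.make_section_image(spec)
        ps = extract_patches(compute_tissue_mask(img), 64, 0.5)
        ps = assign_sections_pieces(ps, 1, (1,), seed=0)
        mm = hole_candidates(ps)
        pred = set(map(tuple, mm.records.loc[mm.records["hole_candidate"],
                                             ["x", "y"]].to_numpy()))
        df = gt.patch_labels(64, 0.5)
        truth = set(map(tuple, df.loc[df["hole"], ["x", "y"]].to_numpy()))
        iou = len(pred & truth) / max(len(pred | truth), 1)
        assert iou >= 0.8

    def test_macro_map_is_superset_and_candidates_lack_tissue(self, annulus):
        ps, mm, _ = annulus
        tumor = set(map(tuple, ps.coords.astype(int)))
        macro = set(map(tuple, mm.coords.astype(int)))
        assert tumor <= macro
        assert (mm.records.loc[mm.records["hole_candidate"], "tissue_frac"] < 0.5).all()

    def test_tiny_piece_skipped_with_warning(self):
        import pandas as pd

        recs = pd.DataFrame({
            "x": [0, 64, 128], "y": [0, 0, 0], "tissue_frac": 1.0,
            "section": 0, "piece": 0, "config": "tumor_map",
            "hole_candidate": False})
        ps = slideprep.PatchSet("s", 64, recs)
        with pytest.warns(UserWarning, match="skipped"):
            mm = hole_candidates(ps)
        assert not mm.records["hole_candidate"].any()


def test_alpha_shape_recovers_annulus_hole():
    rng = np.random.default_rng(0)
    phi = rng.uniform(0, 2 * np.pi, 600)
    r = rng.uniform(60, 100, 600)
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    shape = alpha_shape(pts, alpha=1 / 25.0)
    assert not shape.contains(Point(0, 0))  # hole preserved
    assert shape.contains(Point(80, 0))
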