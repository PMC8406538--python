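"""Shape metric correctness against closed forms and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
import trimesh

from notomorph import shape_metrics as sm
from notomorph import synthetic as syn


def _row(feats, label):
    return feats[feats["cell_id"] == label].iloc[0]


class TestClosedForms:
    def test_axis_aligned_cuboid_is_exact(self, fixture_features):
        feats, _ = fixture_features
        r = _row(feats, 1)
        assert r["volume_um3"] == pytest.approx(1000.0)
        assert (r["l_ap_um"], r["l_dv_um"], r["l_ml_um"]) == (20.0, 10.0, 5.0)
        assert (r["o1_um"], r["o2_um"], r["o3_um"]) == (20.0, 10.0, 5.0)
        assert r["cuboidness"] == pytest.approx(1.0)
        assert r["aspect_ap_dv"] == pytest.approx(2.0)
        assert r["aspect_ap_ml"] == pytest.approx(4.0)
        assert r["aspect_dv_ml"] == pytest.approx(2.0)
        assert r["orientation_ap"] == pytest.approx(1.0)
        assert r["orientation_dv"] == pytest.approx(0.0, abs=1e-9)
        assert r["area_transverse_um2"] == pytest.approx(50.0)
        assert r["ap_anisotropy"] == pytest.approx(20.0 / math.sqrt(50.0))

    def test_cuboid_centroid_at_box_centre(self, fixture_shapes):
        volume, _ = fixture_shapes
        cells = sm.extract_cells(volume, 0.5)
        cell = [c for c in cells if c.cell_id == 1][0]
        met = sm.compute_metrics(cell)
        # box occupies [4, 24] x [4, 14] x [4, 6.5] µm
        assert met["centroid_ap_um"] == pytest.approx(14.0, abs=0.25)
        assert met["centroid_dv_um"] == pytest.approx(9.0, abs=0.25)

    def test_sphere_metrics(self, fixture_features):
        feats, _ = fixture_features
        r = _row(feats, 2)
        assert r["volume_um3"] == pytest.approx(4 / 3 * math.pi * 1000, rel=0.02)
        for ax in ("ax_a_um", "ax_b_um", "ax_c_um"):
            assert r[ax] == pytest.approx(10.0, rel=0.02)
        assert r["sphericity"] >= 0.97
        assert r["cuboidness"] == pytest.approx(math.pi / 6, rel=0.02)
        assert bool(r["isotropic"])

    def test_triaxial_ellipsoid_and_rotated_copy(self, fixture_features):
        """The 10/5/2.5 µm ellipsoid recovers its semi-axes; rotating it 90°
        about ML swaps the major axis onto DV."""
        feats, _ = fixture_features
        r = _row(feats, 3)
        assert r["ax_a_um"] == pytest.approx(10.0, rel=0.02)
        assert r["ax_b_um"] == pytest.approx(5.0, rel=0.02)
        assert r["ax_c_um"] == pytest.approx(2.5, rel=0.02)
        assert r["orientation_ap"] == pytest.approx(1.0, abs=0.02)
        rot = _row(feats, 4)
        assert rot["orientation_dv"] == pytest.approx(1.0, abs=0.02)
        assert rot["orientation_ap"] == pytest.approx(0.0, abs=0.02)
        assert rot["flatness"] == pytest.approx(r["flatness"], rel=0.02)

    def test_rotated_cuboid_orientation_cosines(self, fixture_features):
        feats, _ = fixture_features
        r = _row(feats, 5)
        s2 = math.sqrt(2) / 2
        assert r["orientation_ap"] == pytest.approx(s2, abs=0.02)
        assert r["orientation_dv"] == pytest.approx(s2, abs=0.02)
        assert r["orientation_ml"] == pytest.approx(0.0, abs=0.02)


class TestInvariants:
    def test_axis_ordering_and_cosine_normalisation(
        self, fixture_features, superellipsoid_cells
    ):
        feats, _ = fixture_features
        rows = [feats.iloc[i] for i in range(len(feats))]
        for mask, _ in superellipsoid_cells[:10]:
            cell = sm.CellShape(cell_id=1, mask=mask, origin=(0, 0, 0),
                                voxel_size_um=0.5)
            rows.append(pd.Series(sm.compute_metrics(cell)))
        for r in rows:
            assert r["o1_um"] >= r["o2_um"] >= r["o3_um"]
            assert r["ax_a_um"] >= r["ax_b_um"] >= r["ax_c_um"] > 0
            total = (
                r["orientation_ap"] ** 2
                + r["orientation_dv"] ** 2
                + r["orientation_ml"] ** 2
            )
            assert total == pytest.approx(1.0, abs=1e-6)
            assert r["o1_um"] * r["o2_um"] * r["o3_um"] >= r["volume_um3"]
            assert 0 < r["sphericity"] <= 1
            assert 0 < r["cuboidness"] <= 1

    def test_mesh_enclosed_volume_matches_voxel_count(self, superellipsoid_cells):
        """The raw marching-cubes enclosure is an independent route to cell
        volume; it agrees with voxel counting within 2%."""
        for mask, params in superellipsoid_cells:
            cell = sm.CellShape(cell_id=1, mask=mask, origin=(0, 0, 0),
                                voxel_size_um=0.5)
            met = sm.compute_metrics(cell)
            verts, faces = sm.boundary_mesh(mask, 0.5, smooth_sigma=0.0)
            mesh_vol = abs(trimesh.Trimesh(verts, faces, process=False).volume)
            assert mesh_vol == pytest.approx(met["volume_um3"], rel=0.02)
            # and both sit near the analytic superellipsoid volume (slightly
            # looser: boundary-inclusive voxelisation biases small shapes)
            assert met["volume_um3"] == pytest.approx(params["volume_um3"], rel=0.03)

    def test_axis_permutation_rotation_invariance(self, superellipsoid_cells):
        """90° axis-permutation rotations leave V, sphericity, cuboidness and
        flatness unchanged within 2%."""
        perms = [(0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1)]
        for mask, _ in superellipsoid_cells[:10]:
            ref = None
            for perm in perms:
                cell = sm.CellShape(
                    cell_id=1, mask=np.transpose(mask, perm), origin=(0, 0, 0),
                    voxel_size_um=0.5,
                )
                met = sm.compute_metrics(cell)
                vals = {
                    k: met[k]
                    for k in ("volume_um3", "sphericity", "cuboidness", "flatness")
                }
                if ref is None:
                    ref = vals
                else:
                    for k, v in vals.items():
                        assert v == pytest.approx(ref[k], rel=0.02), k


class TestExtraction:
    def test_extracts_one_record_per_label(self, fixture_shapes):
        volume, _ = fixture_shapes
        cells = sm.extract_cells(volume, 0.5)
        assert sorted(c.cell_id for c in cells) == [1, 2, 3, 4, 5]

    def test_non_integer_volume_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            sm.extract_cells(np.zeros((4, 4, 4), np.float32), 0.5)

    def test_empty_volume_rejected(self):
        with pytest.raises(ValueError, match="no labels"):
            sm.extract_cells(np.zeros((4, 4, 4), np.uint16), 0.5)

    def test_disconnected_label_is_an_error_naming_it(self):
        vol = np.zeros((12, 6, 6), np.uint16)
        vol[1:3, 1:4, 1:4] = 7
        vol[8:10, 1:4, 1:4] = 7
        with pytest.raises(ValueError, match="label 7"):
            sm.extract_cells(vol, 0.5)

    def test_orphan_nucleus_rows_warn_and_drop(self):
        vol = np.zeros((8, 8, 8), np.uint16)
        vol[2:6, 2:6, 2:6] = 1
        nuc = pd.DataFrame(
            {
                "cell_id": [1, 99],
                "nucleus_ap_um": [2.0, 2.0],
                "nucleus_dv_um": [2.0, 2.0],
                "nucleus_ml_um": [2.0, 2.0],
            }
        )
        with pytest.warns(UserWarning, match="99"):
            cells = sm.extract_cells(vol, 0.5, nuc)
        assert cells[0].nucleus_centroid_um is not None

    def test_border_touching_cells_are_flagged(self):
        vol = np.zeros((8, 8, 8), np.uint16)
        vol[0:3, 2:5, 2:5] = 1
        vol[4:7, 2:5, 2:5] = 2
        cells = {c.cell_id: c for c in sm.extract_cells(vol, 0.5)}
        assert cells[1].touches_border and not cells[2].touches_border

    def test_degenerate_cell_flagged_with_missing_metrics(self):
        vol = np.zeros((6, 6, 6), np.uint16)
        vol[2, 2, 2:4] = 1
        cells = sm.extract_cells(vol, 0.5)
        met = sm.compute_metrics(cells[0])
        assert met["degenerate"]
        assert np.isnan(met["volume_um3"])


class TestFeatureTable:
    @pytest.mark.parametrize(
        "p,region",
        [(0.05, "anterior"), (0.15, "pharynx"), (0.39, "pharynx"),
         (0.40, "trunk"), (0.50, "trunk"), (0.60, "posterior"),
         (0.99, "posterior")],
    )
    def test_ap_region_half_open_bins(self, p, region):
        assert sm._ap_region(p) == region

    def test_layer_inference_three_row_stack(self):
        """In a 3-row stack the most dorsal and ventral rows become Müller
        and the middle row stays central."""
        vol = np.zeros((40, 30, 8), np.uint16)
        lab = 0
        ys = [(2, 8), (12, 18), (22, 28)]
        for i in range(4):
            for j, (y0, y1) in enumerate(ys):
                lab += 1
                vol[2 + i * 9:9 + i * 9, y0:y1, 2:6] = lab
        cells = sm.extract_cells(vol, 0.5)
        ann = pd.DataFrame(
            {
                "cell_id": range(1, 13),
                "stage": 10,
                "ap_position_norm": np.repeat(
                    np.linspace(0.2, 0.8, 4), 3
                ),
            }
        )
        feats = sm.feature_table(cells, ann)
        by_row = feats.groupby(
            pd.cut(feats["centroid_dv_um"], bins=[0, 5, 10, 15])
        , observed=True)["layer"].agg(lambda s: s.mode()[0])
        assert by_row.iloc[0] == "muller_ventral"
        assert by_row.iloc[1] == "central"
        assert by_row.iloc[2] == "muller_dorsal"

    def test_unannotated_cells_excluded_with_warning(self, fixture_shapes):
        volume, _ = fixture_shapes
        cells = sm.extract_cells(volume, 0.5)
        ann = pd.DataFrame(
            {"cell_id": [1, 2, 3], "stage": [6, 6, 8],
             "ap_position_norm": [0.1, 0.5, 0.9],
             "layer": ["central"] * 3}
        )
        with pytest.warns(UserWarning, match="excluded 2"):
            feats = sm.feature_table(cells, ann)
        assert len(feats) == 3

    def test_missing_nucleus_gives_missing_displacement(self, fixture_shapes):
        volume, _ = fixture_shapes
        cells = sm.extract_cells(volume, 0.5)
        feats = sm.feature_table(cells)
        assert feats["nuc_disp_ap_um"].isna().all()
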