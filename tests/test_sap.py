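"""SAP coordinates and crypt regions: oracles, geometry, invariances."""

import numpy as np
import pandas as pd
import pytest

import villustat as vs
from villustat.sap import nearest_distance

from conftest import brute_force_nearest, flood_fill_components, tiny_tissue


class TestNearestDistance:
    def test_hand_example(self):
        d = nearest_distance(np.array([[0.0, 0.0]]),
                             np.array([[0.0, 3.0], [4.0, 0.0]]))
        assert d[0] == pytest.approx(3.0)

    def test_query_on_reference_is_zero(self):
        d = nearest_distance(np.array([[1.0, 2.0]]),
                             np.array([[5.0, 5.0], [1.0, 2.0]]))
        assert d[0] == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(vs.ValidationError, match="non-empty"):
            nearest_distance(np.array([[0.0, 0.0]]), np.empty((0, 2)))

    def test_nonfinite_rejected(self):
        with pytest.raises(vs.ValidationError, match="finite"):
            nearest_distance(np.array([[np.nan, 0.0]]), np.array([[1.0, 1.0]]))

    def test_kdtree_equals_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        query = rng.uniform(0, 100, size=(1000, 2))
        ref = rng.uniform(0, 100, size=(500, 2))
        fast = nearest_distance(query, ref, method="kdtree")
        slow = brute_force_nearest(query, ref)
        assert np.abs(fast - slow).max() < 1e-9

    def test_internal_exhaustive_matches_kdtree(self):
        rng = np.random.default_rng(3)
        query = rng.normal(size=(200, 2))
        ref = rng.normal(size=(100, 2))
        np.testing.assert_allclose(
            nearest_distance(query, ref, "kdtree"),
            nearest_distance(query, ref, "exhaustive"), atol=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        query = rng.uniform(size=(50, 2))
        ref = rng.uniform(size=(30, 2))
        shift = np.array([123.4, -56.7])
        np.testing.assert_allclose(
            nearest_distance(query, ref),
            nearest_distance(query + shift, ref + shift), atol=1e-9)

    def test_monotone_under_reference_removal(self):
        rng = np.random.default_rng(8)
        query = rng.uniform(size=(40, 2))
        ref = rng.uniform(size=(25, 2))
        full = nearest_distance(query, ref)
        reduced = nearest_distance(query, ref[:10])
        assert (reduced >= full - 1e-12).all()


class TestComputeSap:
    def test_muscle_on_a_line_gives_vertical_distance(self):
        rows = [("m%d" % i, float(i), 0.0, "smooth_muscle", "") for i in range(200)]
        rows.append(("q", 50.0, 7.5, "crypt", ""))
        rows.append(("e", 50.0, 30.0, "enterocyte", ""))
        spots = pd.DataFrame(rows, columns=["spot_id", "x_um", "y_um",
                                            "compartment", "cell_type"])
        sap = vs.compute_sap(spots).set_index("spot_id")
        assert sap.loc["q", "d_sm"] == pytest.approx(7.5)
        assert sap.loc["m0", "d_sm"] == 0.0
        assert sap.loc["e", "d_ent"] == 0.0

    def test_zero_iff_member_of_reference_compartment(self, small_section):
        _, spots, _, _ = small_section
        sap = vs.compute_sap(spots)
        merged = spots.merge(sap, on="spot_id")
        assert ((merged["d_sm"] == 0) ==
                (merged["compartment"] == "smooth_muscle")).all()
        assert ((merged["d_ent"] == 0) ==
                (merged["compartment"] == "enterocyte")).all()

    def test_missing_compartment_named_in_error(self, small_section):
        _, spots, _, _ = small_section
        no_ent = spots[spots["compartment"] != "enterocyte"]
        with pytest.raises(vs.ValidationError, match="enterocyte"):
            vs.compute_sap(no_ent)

    def test_crypt_spots_closer_to_muscle_than_enterocytes(self):
        """Section anatomy: crypts abut the muscle band, 20/20 seeds."""
        for seed in range(20):
            spots, _, _ = vs.simulate_section(tiny_tissue(seed=seed))
            sap = spots.merge(vs.compute_sap(spots), on="spot_id")
            crypt = sap.loc[sap["compartment"] == "crypt", "d_sm"].mean()
            ent = sap.loc[sap["compartment"] == "enterocyte", "d_sm"].mean()
            assert crypt < ent

    def test_row_order_matches_input(self, small_section):
        _, spots, _, _ = small_section
        shuffled = spots.sample(frac=1.0, random_state=0).reset_index(drop=True)
        sap = vs.compute_sap(shuffled)
        assert list(sap["spot_id"]) == list(shuffled["spot_id"])


def _grid_spots(occ: np.ndarray, pitch: float = 2.0) -> pd.DataFrame:
    """Spot table whose crypt spots follow a boolean occupancy grid."""
    rows = []
    i = 0
    h, w = occ.shape
    for y in range(h):
        for x in range(w):
            comp = "crypt" if occ[y, x] else "lamina_propria"
            rows.append((f"s{i}", (x + 0.5) * pitch, (y + 0.5) * pitch, comp, ""))
            i += 1
    return pd.DataFrame(rows, columns=["spot_id", "x_um", "y_um",
                                       "compartment", "cell_type"])


class TestCryptRegions:
    def test_two_separated_blocks(self):
        occ = np.zeros((5, 12), dtype=bool)
        occ[1:4, 1:4] = True
        occ[1:4, 8:11] = True
        regions = vs.define_crypt_regions(_grid_spots(occ), pitch=2.0)
        assert len(regions) == 2
        assert [r.region_id for r in regions] == ["crypt_000", "crypt_001"]

    def test_contiguous_band_is_one_region(self):
        occ = np.zeros((4, 10), dtype=bool)
        occ[1:3, :] = True
        regions = vs.define_crypt_regions(_grid_spots(occ), pitch=2.0)
        assert len(regions) == 1
        assert len(regions[0]) == int(occ.sum())

    def test_no_crypt_spots_returns_empty_list(self):
        occ = np.zeros((3, 3), dtype=bool)
        assert vs.define_crypt_regions(_grid_spots(occ), pitch=2.0) == []

    def test_diagonal_touching_merges_under_8_connectivity(self):
        occ = np.zeros((4, 4), dtype=bool)
        occ[0, 0] = occ[1, 1] = True
        spots = _grid_spots(occ)
        assert len(vs.define_crypt_regions(spots, pitch=2.0, connectivity=8)) == 1
        assert len(vs.define_crypt_regions(spots, pitch=2.0, connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_grids_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(17)
        for _ in range(30):
            occ = rng.random((rng.integers(3, 15), rng.integers(3, 15))) < 0.4
            if not occ.any():
                continue
            got = len(vs.define_crypt_regions(_grid_spots(occ), pitch=2.0,
                                              connectivity=connectivity))
            want = flood_fill_components(occ, connectivity)
            assert got == want

    def test_regions_are_disjoint_and_crypt_only(self, small_section):
        cfg, spots, _, _ = small_section
        regions = vs.define_crypt_regions(spots, pitch=cfg.spot_pitch_um)
        all_ids = [s for r in regions for s in r.spot_ids]
        assert len(all_ids) == len(set(all_ids))
        crypt_ids = set(spots.loc[spots["compartment"] == "crypt", "spot_id"])
        assert set(all_ids) == crypt_ids


class TestRegionAssignment:
    def test_adjacent_spot_assigned_within_radius(self):
        occ = np.zeros((5, 10), dtype=bool)
        occ[1:3, 1:4] = True
        spots = _grid_spots(occ)
        # labelled spot one pitch to the right of the block edge
        target = spots[(spots["x_um"] == 9.0) & (spots["y_um"] == 3.0)].index[0]
        spots.loc[target, "cell_type"] = "CD8T"
        regions = vs.define_crypt_regions(spots, pitch=2.0)
        amap = vs.assign_spots_to_regions(spots, regions, radius_um=4.0)
        sid = spots.loc[target, "spot_id"]
        assert amap[sid] == regions[0].region_id

    def test_radius_zero_leaves_off_crypt_spot_unassigned(self):
        occ = np.zeros((3, 3), dtype=bool)
        occ[0, 0] = True
        spots = _grid_spots(occ)
        spots.loc[spots["spot_id"] == "s8", "cell_type"] = "M1"
        regions = vs.define_crypt_regions(spots, pitch=2.0)
        amap = vs.assign_spots_to_regions(spots, regions, radius_um=0.0)
        assert pd.isna(amap["s8"])

    def test_matches_exhaustive_nearest_region_search(self, small_section):
        cfg, spots, _, _ = small_section
        regions = vs.define_crypt_regions(spots, pitch=cfg.spot_pitch_um)
        radius = 3 * cfg.spot_pitch_um
        amap = vs.assign_spots_to_regions(spots, regions, radius_um=radius)

        coords = spots.set_index("spot_id")[["x_um", "y_um"]]
        labelled = spots[spots["cell_type"] != ""]
        for _, row in labelled.head(200).iterrows():
            best_d, best_r = np.inf, None
            for r in regions:
                pts = coords.loc[list(r.spot_ids)].to_numpy()
                d = np.sqrt(((pts - [row.x_um, row.y_um]) ** 2).sum(axis=1)).min()
                if d < best_d:
                    best_d, best_r = d, r.region_id
            expected = best_r if best_d <= radius else None
            got = amap[row.spot_id]
            assert (pd.isna(got) and expected is None) or got == expected
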