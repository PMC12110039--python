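"""mIF spatial metrics: gating, compartments, densities, distances, ratios."""

import numpy as np
import pandas as pd
import pytest

from spatialtme import synthetic
from spatialtme.exceptions import (
    DegenerateCompartmentError,
    EmptyClassError,
    SchemaError,
)
from spatialtme.mif_spatial import (
    assign_compartment,
    cell_density,
    density_ratio,
    density_table,
    distance_ratio,
    distance_table,
    gate_phenotypes,
    nearest_neighbor_distance,
)

THRESH = {m: 5.0 for m in ["CK", "CD8", "PD1", "CD68", "FOXP3", "CD56"]}


def _cells(rows):
    df = pd.DataFrame(rows)
    if "cell_id" not in df.columns:
        df.insert(0, "cell_id", [f"c{i}" for i in range(len(df))])
    return df


def _map_from_cells(cells, w=1000.0, h=1000.0, nests=()):
    return synthetic.CellMap(
        cells=cells, window_w_um=w, window_h_um=h, nests=list(nests)
    )


class TestGating:
    def _base(self, **markers):
        row = {m: 0.0 for m in THRESH}
        row.update(markers)
        row.update({"x_um": 0.0, "y_um": 0.0})
        return _cells([row])

    def test_ck_wins_over_cd8(self):
        cells = self._base(CK=9.0, CD8=9.0)
        assert gate_phenotypes(cells, THRESH)["phenotype"].iloc[0] == "cancer"

    def test_all_negative_is_other(self):
        cells = self._base()
        assert gate_phenotypes(cells, THRESH)["phenotype"].iloc[0] == "other"

    def test_cd8_split_by_pd1(self):
        neg = gate_phenotypes(self._base(CD8=9.0), THRESH)
        pos = gate_phenotypes(self._base(CD8=9.0, PD1=9.0), THRESH)
        assert neg["phenotype"].iloc[0] == "CD8_PD1neg"
        assert pos["phenotype"].iloc[0] == "CD8_PD1pos"

    def test_priority_chain(self):
        assert (
            gate_phenotypes(self._base(CD68=9.0, FOXP3=9.0), THRESH)["phenotype"].iloc[0]
            == "macrophage"
        )
        assert (
            gate_phenotypes(self._base(FOXP3=9.0, CD8=9.0), THRESH)["phenotype"].iloc[0]
            == "Treg"
        )

    def test_missing_marker_column_rejected(self):
        cells = self._base().drop(columns=["CD56"])
        with pytest.raises(SchemaError, match="CD56"):
            gate_phenotypes(cells, THRESH)

    def test_separated_intensities_recover_labels(self):
        cmap = synthetic.generate_cell_map("non_recur", seed=5)
        cells = synthetic.attach_marker_intensities(cmap.cells, seed=6)
        gated = gate_phenotypes(cells, THRESH)
        labelable = cells["phenotype"] != "other"
        agree = (gated.loc[labelable, "phenotype"] ==
                 cells.loc[labelable, "phenotype"]).mean()
        assert agree >= 0.99


class TestAssignCompartment:
    def test_disc_center_is_nest(self):
        cells = _cells([{"x_um": 50.0, "y_um": 50.0}])
        out = assign_compartment(cells, [(50.0, 50.0, 10.0)])
        assert out["compartment"].iloc[0] == "tumor_nest"

    def test_boundary_counts_as_inside(self):
        cells = _cells([{"x_um": 60.0, "y_um": 50.0}])
        out = assign_compartment(cells, [(50.0, 50.0, 10.0)])
        assert out["compartment"].iloc[0] == "tumor_nest"

    def test_empty_region_set_is_all_stroma(self):
        cells = _cells([{"x_um": 1.0, "y_um": 2.0}, {"x_um": 3.0, "y_um": 4.0}])
        out = assign_compartment(cells, [])
        assert (out["compartment"] == "stroma").all()

    def test_matches_brute_force_point_in_disc(self, rng):
        xy = rng.uniform(0, 500, size=(1000, 2))
        cells = _cells([{"x_um": x, "y_um": y} for x, y in xy])
        nests = [(100.0, 100.0, 60.0), (300.0, 350.0, 90.0), (420.0, 80.0, 40.0)]
        out = assign_compartment(cells, nests)
        for (x, y), got in zip(xy, out["compartment"]):
            inside = any((x - cx) ** 2 + (y - cy) ** 2 <= r**2 for cx, cy, r in nests)
            assert got == ("tumor_nest" if inside else "stroma")


class TestDensity:
    def test_hundred_cells_per_mm2(self, rng):
        xy = rng.uniform(0, 1000, size=(100, 2))
        cells = _cells(
            [{"x_um": x, "y_um": y, "phenotype": "Treg", "compartment": "stroma"}
             for x, y in xy]
        )
        cmap = _map_from_cells(cells)  # 1 mm^2 window
        assert cell_density(cmap, "Treg", "all") == pytest.approx(100.0)

    def test_doubling_area_halves_density(self, rng):
        xy = rng.uniform(0, 1000, size=(50, 2))
        cells = _cells(
            [{"x_um": x, "y_um": y, "phenotype": "NK", "compartment": "stroma"}
             for x, y in xy]
        )
        d1 = cell_density(_map_from_cells(cells, 1000, 1000), "NK", "all")
        d2 = cell_density(_map_from_cells(cells, 2000, 1000), "NK", "all")
        assert d1 == pytest.approx(2 * d2)

    def test_zero_area_compartment_rejected(self):
        cells = _cells(
            [{"x_um": 1.0, "y_um": 1.0, "phenotype": "NK", "compartment": "stroma"}]
        )
        cmap = _map_from_cells(cells, nests=())
        with pytest.raises(DegenerateCompartmentError):
            cell_density(cmap, "NK", "tumor_nest")

    def test_poisson_intensity_recovered(self):
        lam = 200.0  # cells/mm^2 over a 1 mm^2 window
        est = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = rng.poisson(lam)
            xy = rng.uniform(0, 1000, size=(n, 2))
            cells = _cells(
                [{"x_um": x, "y_um": y, "phenotype": "NK", "compartment": "stroma"}
                 for x, y in xy]
            )
            est.append(cell_density(_map_from_cells(cells), "NK", "all"))
        se = np.std(est, ddof=1) / 10
        assert abs(np.mean(est) - lam) < 2 * se + 1e-9 or abs(np.mean(est) - lam) < 3


class TestNearestNeighbor:
    def test_three_four_five_triangle(self):
        cells = _cells(
            [
                {"x_um": 0.0, "y_um": 0.0, "phenotype": "Treg", "compartment": "stroma"},
                {"x_um": 3.0, "y_um": 4.0, "phenotype": "cancer", "compartment": "stroma"},
                {"x_um": 10.0, "y_um": 0.0, "phenotype": "cancer", "compartment": "stroma"},
            ]
        )
        d = nearest_neighbor_distance(_map_from_cells(cells), "Treg", "cancer")
        assert d == pytest.approx(5.0)

    def test_coincident_distinct_phenotypes_give_zero(self):
        cells = _cells(
            [
                {"x_um": 5.0, "y_um": 5.0, "phenotype": "Treg", "compartment": "stroma"},
                {"x_um": 5.0, "y_um": 5.0, "phenotype": "cancer", "compartment": "stroma"},
            ]
        )
        assert nearest_neighbor_distance(
            _map_from_cells(cells), "Treg", "cancer"
        ) == pytest.approx(0.0)

    def test_self_class_excludes_own_instance(self):
        cells = _cells(
            [
                {"x_um": 0.0, "y_um": 0.0, "phenotype": "Treg", "compartment": "stroma"},
                {"x_um": 2.0, "y_um": 0.0, "phenotype": "Treg", "compartment": "stroma"},
            ]
        )
        assert nearest_neighbor_distance(
            _map_from_cells(cells), "Treg", "Treg"
        ) == pytest.approx(2.0)

    def test_empty_class_named_in_error(self):
        cells = _cells(
            [{"x_um": 0.0, "y_um": 0.0, "phenotype": "Treg", "compartment": "stroma"}]
        )
        with pytest.raises(EmptyClassError, match="cancer"):
            nearest_neighbor_distance(_map_from_cells(cells), "Treg", "cancer")

    def test_matches_brute_force_on_500_cells(self, rng):
        xy = rng.uniform(0, 600, size=(500, 2))
        pheno = rng.choice(["Treg", "cancer"], size=500, p=[0.3, 0.7])
        cells = _cells(
            [{"x_um": x, "y_um": y, "phenotype": p, "compartment": "stroma"}
             for (x, y), p in zip(xy, pheno)]
        )
        got = nearest_neighbor_distance(_map_from_cells(cells), "Treg", "cancer")
        ref = xy[pheno == "Treg"]
        tgt = xy[pheno == "cancer"]
        brute = np.mean(
            [np.min(np.hypot(tgt[:, 0] - x, tgt[:, 1] - y)) for x, y in ref]
        )
        assert got == pytest.approx(brute, abs=1e-9)

    def test_rigid_motion_invariance_and_scale_equivariance(self, rng):
        xy = rng.uniform(0, 100, size=(60, 2))
        pheno = ["Treg"] * 20 + ["cancer"] * 40
        def dist(points):
            cells = _cells(
                [{"x_um": x, "y_um": y, "phenotype": p, "compartment": "stroma"}
                 for (x, y), p in zip(points, pheno)]
            )
            return nearest_neighbor_distance(_map_from_cells(cells), "Treg", "cancer")
        base = dist(xy)
        theta = 0.7
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert dist(xy @ rot.T + [37.0, 11.0]) == pytest.approx(base, rel=1e-9)
        assert dist(xy * 3.5) == pytest.approx(3.5 * base, rel=1e-9)


class TestRatios:
    def _density_frame(self, per_sample):
        rows = []
        for sample, (treg, cd8) in per_sample.items():
            rows += [
                {"sample": sample, "compartment": "tumor_nest",
                 "phenotype": "Treg", "density": treg, "area_mm2": 1.0},
                {"sample": sample, "compartment": "tumor_nest",
                 "phenotype": "CD8_total", "density": cd8, "area_mm2": 1.0},
            ]
        return pd.DataFrame(rows)

    def test_simple_ratio(self):
        dens = self._density_frame({"s1": (10.0, 5.0)})
        ratios = density_ratio(dens, "Treg", "CD8_total", "tumor_nest")
        assert ratios["s1"] == pytest.approx(2.0)

    def test_identical_groups_p_one(self):
        dens = self._density_frame(
            {"a": (2.0, 1.0), "b": (4.0, 2.0), "c": (2.0, 1.0), "d": (4.0, 2.0)}
        )
        groups = {"a": "recur", "b": "recur", "c": "non_recur", "d": "non_recur"}
        res = density_ratio(dens, "Treg", "CD8_total", "tumor_nest", groups=groups)
        assert res.pvalue == pytest.approx(1.0)
        assert res.fold == pytest.approx(1.0)

    def test_zero_denominator_sample_excluded(self):
        dens = self._density_frame({"s1": (10.0, 0.0), "s2": (6.0, 3.0)})
        ratios = density_ratio(dens, "Treg", "CD8_total", "tumor_nest")
        assert np.isnan(ratios["s1"]) and ratios["s2"] == pytest.approx(2.0)

    def test_equal_distances_ratio_one(self):
        dist = pd.DataFrame(
            [
                {"sample": "s", "reference": "cancer", "target": "Treg",
                 "mean_distance_um": 30.0, "n_reference": 5, "computable": True},
                {"sample": "s", "reference": "cancer", "target": "CD8_total",
                 "mean_distance_um": 30.0, "n_reference": 5, "computable": True},
            ]
        )
        ratios = distance_ratio(dist, "Treg", "CD8_total")
        assert ratios["s"] == pytest.approx(1.0)

    def test_phenotype_permutation_centers_ratio_at_one(self):
        """Permuting phenotype labels within a map destroys the planted
        proximity structure: the Treg/CD8 distance ratio averages ~1."""
        cmap = synthetic.generate_cell_map("recur", seed=13)
        cells = cmap.cells
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(200):
            perm = cells.copy()
            perm["phenotype"] = rng.permutation(perm["phenotype"].to_numpy())
            pm = synthetic.CellMap(
                cells=perm, window_w_um=cmap.window_w_um,
                window_h_um=cmap.window_h_um, nests=cmap.nests,
            )
            try:
                dt = nearest_neighbor_distance(pm, "Treg", "cancer")
                dc = nearest_neighbor_distance(pm, "CD8_total", "cancer")
                ratios.append(dt / dc)
            except EmptyClassError:
                continue
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)


def test_density_and_distance_tables_are_order_invariant():
    cmap = synthetic.generate_cell_map("recur", seed=21)
    shuffled = synthetic.CellMap(
        cells=cmap.cells.sample(frac=1.0, random_state=5).reset_index(drop=True),
        window_w_um=cmap.window_w_um,
        window_h_um=cmap.window_h_um,
        nests=cmap.nests,
    )
    d1 = density_table({"s": cmap}).set_index(["compartment", "phenotype"])["density"]
    d2 = density_table({"s": shuffled}).set_index(["compartment", "phenotype"])["density"]
    pd.testing.assert_series_equal(d1, d2)
    t1 = distance_table({"s": cmap})["mean_distance_um"]
    t2 = distance_table({"s": shuffled})["mean_distance_um"]
    assert t1.to_numpy() == pytest.approx(t2.to_numpy(), rel=1e-12)
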