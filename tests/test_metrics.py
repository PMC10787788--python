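import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from sstseg.markers import MarkerSets
from sstseg.metrics import (CellShape, baseline_metrics, concordance_with_reference,
                            neighbour_contamination, proportion_correlation,
                            purity_f1, purity_scores, replicability,
                            shannon_entropy, shape_metrics,
                            shape_metrics_for_mask, spatial_diversity)

TOL = 1e-3


class TestShapeMetrics:
    def test_circle_identities(self):
        m = shape_metrics(CellShape.circle(10.0))
        for name in ("circularity", "sphericity", "compactness", "convexity",
                     "eccentricity", "solidity"):
            assert m[name] == pytest.approx(1.0, abs=TOL), name

    def test_square_elongation_one(self):
        sq = CellShape(Polygon([(0, 0), (10, 0), (10, 10), (0, 10)]))
        assert shape_metrics(sq)["elongation"] == pytest.approx(1.0, abs=TOL)

    def test_rectangle_elongation_and_solidity(self):
        rect = CellShape(Polygon([(0, 0), (10, 0), (10, 5), (0, 5)]))
        m = shape_metrics(rect)
        assert m["elongation"] in (pytest.approx(2.0, abs=TOL),
                                   pytest.approx(0.5, abs=TOL))
        assert m["solidity"] == pytest.approx(1.0, abs=TOL)
        assert m["convexity"] == pytest.approx(1.0, abs=TOL)

    def test_hexagon_solidity_exact(self):
        pts = [(math.cos(a), math.sin(a))
               for a in np.linspace(0, 2 * math.pi, 7)[:-1]]
        assert shape_metrics(CellShape(Polygon(pts)))["solidity"] == \
            pytest.approx(1.0, abs=1e-9)

    def test_rasterised_disc_converges_to_circle(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2
        m = shape_metrics(CellShape.from_mask(mask))
        assert m["eccentricity"] == pytest.approx(1.0, abs=5e-2)
        assert m["compactness"] == pytest.approx(1.0, abs=5e-2)
        assert m["area"] == pytest.approx(np.pi * 400, rel=0.05)

    def test_inequalities_hold_on_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = np.zeros((48, 48), bool)
            for _ in range(4):
                cy, cx = rng.integers(12, 36, 2)
                r = rng.integers(4, 9)
                yy, xx = np.mgrid[0:48, 0:48]
                mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
            m = shape_metrics(CellShape.from_mask(mask))
            assert m["solidity"] <= 1 + TOL
            assert m["convexity"] <= 1 + TOL
            assert m["compactness"] <= m["circularity"] + TOL
            assert m["sphericity"] <= 1 + TOL

    def test_degenerate_mask_flagged_nan(self):
        mask = np.zeros((8, 8), np.int32)
        mask[4, 4] = 1  # single pixel: traceable but tiny
        mask[0, 0:3] = 2
        out = shape_metrics_for_mask(mask)
        assert set(out.index) == {1, 2}


class TestBaseline:
    def test_density_arithmetic(self):
        matrix = pd.DataFrame({"A": [100]}, index=[1])
        mask = np.zeros((10, 10), np.int32)
        mask.ravel()[:50] = 1
        per_cell, _, overall = baseline_metrics(matrix, mask)
        assert per_cell.loc[1, "density"] == pytest.approx(2.0)
        assert overall["n_cells"] == 1

    def test_zero_transcript_cell(self):
        matrix = pd.DataFrame({"A": [0]}, index=[1])
        mask = np.zeros((4, 4), np.int32)
        mask[0, 0] = 1
        per_cell, gene_frac, _ = baseline_metrics(matrix, mask)
        assert per_cell.loc[1, "density"] == 0.0
        assert per_cell.loc[1, "n_genes"] == 0
        assert gene_frac["A"] == 0.0

    def test_proportion_assigned(self):
        matrix = pd.DataFrame({"A": [30], "B": [20]}, index=[1])
        mask = np.ones((5, 5), np.int32)
        _, _, overall = baseline_metrics(matrix, mask, total_transcripts=100)
        assert overall["proportion_assigned"] == pytest.approx(0.5)


class TestPurity:
    @pytest.mark.parametrize("fp,fn,expected", [
        (1.0, 0.0, 1.0),
        (0.5, 0.5, 0.5),
        (0.0, 0.3, 0.0),
    ])
    def test_purity_f1_endpoints(self, fp, fn, expected):
        assert purity_f1(fp, fn) == pytest.approx(expected)

    def test_purity_f1_degenerate_zero_over_zero(self):
        assert purity_f1(0.0, 1.0) == 0.0

    def test_purity_f1_monotone_in_positive(self):
        vals = [purity_f1(x, 0.3) for x in np.linspace(0, 1, 11)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_perfect_marker_cells_score_one(self):
        genes = [f"G{i}" for i in range(10)]
        markers = MarkerSets(positive={"T": frozenset({"G0"})},
                             negative={"T": frozenset({"G9"})},
                             percentile=0.1, commonality_threshold=0.25)
        row = [50, 5, 5, 5, 5, 5, 5, 5, 5, 0]
        matrix = pd.DataFrame([row, row], index=[1, 2], columns=genes)
        per_cell, per_type = purity_scores(matrix, {1: "T", 2: "T"}, markers)
        assert per_type.loc["T", "f1_pos"] == pytest.approx(1.0)
        assert per_type.loc["T", "f1_neg"] == pytest.approx(1.0)
        # perfect negative-marker prediction means worst purity contribution
        assert per_type.loc["T", "purity_f1"] == pytest.approx(0.0)


class TestConcordance:
    def test_exact_reference_recovery(self, toy_profile):
        rows, types = [], {}
        for i, t in enumerate(toy_profile.cell_types):
            for k in range(3):
                rows.append(toy_profile.mean_expression.loc[t] * (k + 1))
                types[len(rows)] = t
        matrix = pd.DataFrame(rows, index=range(1, len(rows) + 1),
                              columns=toy_profile.genes)
        per_type, _ = concordance_with_reference(matrix, types, toy_profile)
        for t, r in per_type.items():
            assert r == pytest.approx(1.0, abs=0.02)

    def test_type_with_single_cell_missing(self, toy_profile):
        matrix = pd.DataFrame([toy_profile.mean_expression.iloc[0]], index=[1],
                              columns=toy_profile.genes)
        per_type, _ = concordance_with_reference(matrix, {1: "type_0"},
                                                 toy_profile)
        assert per_type["type_0"] is None

    def test_proportion_correlation_antithetic(self):
        p1 = {"a": 0.7, "b": 0.2, "c": 0.1}
        p2 = {"a": 0.1, "b": 0.2, "c": 0.7}
        assert proportion_correlation(p1, p1) == pytest.approx(1.0)
        assert proportion_correlation(p1, p2) < 0


class TestSpatialDiversity:
    def _table(self, positions, types, char=None):
        df = pd.DataFrame({"centroid_row": [p[0] for p in positions],
                           "centroid_col": [p[1] for p in positions],
                           "cell_type": types})
        df["n_transcripts"] = char if char is not None else 1.0
        return df

    def test_entropy_closed_forms(self):
        assert shannon_entropy([1.0]) == 0.0
        assert shannon_entropy([0.5, 0.5]) == pytest.approx(np.log(2))
        assert shannon_entropy([0.25] * 4) == pytest.approx(np.log(4))

    def test_pure_region_zero_entropy(self):
        tbl = self._table([(5, 5), (6, 6), (7, 7), (55, 55), (56, 56), (57, 57)],
                          ["A"] * 3 + ["B"] * 3)
        regions, _ = spatial_diversity(tbl, (60, 60), n_regions=2)
        assert (regions["entropy"] == 0).all()

    def test_balanced_region_ln2(self):
        tbl = self._table([(5, 5), (6, 6), (7, 7), (8, 8), (55, 55), (56, 56)],
                          ["A", "B", "A", "B", "A", "A"])
        regions, _ = spatial_diversity(tbl, (60, 60), n_regions=2)
        balanced = regions[regions["n_cells"] == 4]
        assert balanced["entropy"].iloc[0] == pytest.approx(np.log(2))

    def test_identical_cells_cv_zero_correlation_missing(self):
        tbl = self._table([(5, 5), (6, 6), (7, 7), (55, 55), (56, 56), (57, 57)],
                          ["A", "B", "A", "B", "A", "B"], char=3.0)
        regions, corr = spatial_diversity(tbl, (60, 60), n_regions=2)
        assert (regions["cv_n_transcripts"].dropna() == 0).all()
        assert corr["n_transcripts"] is None


class TestContamination:
    def test_no_expression_all_zero(self):
        a = np.array([[0, 0], [0, 5], [0, 10]])
        b = np.array([[10, 0]])
        expr = pd.DataFrame({"M": [0, 0, 0]})
        out = neighbour_contamination(a, b, expr, "M", [0, 6, 12])
        assert (out["fraction_expressing"].dropna() == 0).all()

    def test_all_express_all_one(self):
        a = np.array([[0, 0], [0, 5]])
        b = np.array([[3, 0]])
        expr = pd.DataFrame({"M": [2, 1]})
        out = neighbour_contamination(a, b, expr, "M", [0, 10])
        assert (out["fraction_expressing"] == 1.0).all()

    def test_overexpanded_masks_show_more_near_contamination(self, small_dataset):
        cfg, ds = small_dataset
        # construct contamination: near cells express the marker, far do not
        a = np.array([[0.0, d] for d in (1, 2, 3, 30, 40, 50)])
        b = np.array([[0.0, 0.0]])
        tight = pd.DataFrame({"M": [0, 0, 0, 0, 0, 0]})
        leaky = pd.DataFrame({"M": [1, 1, 0, 0, 0, 0]})
        bins = [0, 10, 60]
        near_tight = neighbour_contamination(a, b, tight, "M", bins)
        near_leaky = neighbour_contamination(a, b, leaky, "M", bins)
        assert near_leaky["fraction_expressing"].iloc[0] > \
            near_tight["fraction_expressing"].iloc[0]

    def test_unsorted_bins_error(self):
        with pytest.raises(ValueError):
            neighbour_contamination(np.zeros((1, 2)), np.ones((1, 2)),
                                    pd.DataFrame({"M": [1]}), "M", [5, 1])


class TestReplicability:
    def _report(self, seed, flip=False):
        rng = np.random.default_rng(seed)
        types = {i: ("A" if i % 2 else "B") for i in range(1, 21)}
        per_cell = pd.DataFrame({
            "n_transcripts": rng.uniform(50, 150, 20),
            "area": rng.uniform(100, 400, 20),
        }, index=range(1, 21))
        if flip:
            per_cell = -per_cell
        return per_cell, types

    def test_identical_reports_correlate_one(self):
        pc, ty = self._report(0)
        out = replicability(pc, ty, pc.copy(), dict(ty))
        # with two shared types every per-type correlation is +-1; identical
        # replicates give exactly 1
        assert all(v == pytest.approx(1.0) for v in out.values()
                   if v is not None)

    def test_no_shared_types_errors(self):
        pc, _ = self._report(1)
        t1 = {i: "A" for i in pc.index}
        t2 = {i: "B" for i in pc.index}
        with pytest.raises(ValueError):
            replicability(pc, t1, pc, t2)

    def test_same_seed_family_replicates_correlate(self, toy_profile):
        from sstseg.config import SimConfig
        from sstseg.synthetic import simulate_dataset
        from sstseg.postprocess import map_transcripts_to_cells
        reports = []
        for seed in (21, 22):
            cfg = SimConfig(image_height=192, image_width=192, n_cells=30,
                            n_genes=20, mean_transcripts_per_cell=150,
                            background_noise_rate=0.0, rng_seed=seed)
            ds = simulate_dataset(cfg)
            matrix, _ = map_transcripts_to_cells(ds.transcripts,
                                                 ds.truth.cell_mask,
                                                 ds.profile.genes)
            per_cell, _, _ = baseline_metrics(matrix, ds.truth.cell_mask)
            reports.append((per_cell, ds.truth.cell_types))
        out = replicability(reports[0][0], reports[0][1],
                            reports[1][0], reports[1][1])
        assert out["n_transcripts"] is not None
        assert out["n_transcripts"] > 0.9
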