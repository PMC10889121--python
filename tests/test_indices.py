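"""Global indices (mean/weighted), their AUROCs, comparisons and ranking."""

import numpy as np
import pytest

from ppgrid.grid import (
    Cohort,
    EyeRecord,
    Group,
    GridOrientation,
    Laterality,
    Segmentation,
    ThicknessGridSet,
)
from ppgrid.heatmap import AurocHeatmap, CellSelection, build_heatmap
from ppgrid.indices import (
    EmptySelectionError,
    GlobalIndexResult,
    IndexKind,
    compare_mean_vs_weighted,
    compare_orientations,
    compute_index,
    layer_ranking,
    mean_index,
    weighted_index,
)
from ppgrid.roc import AurocResult
from ppgrid.simulate import SimulationConfig, generate_cohort

SEG = Segmentation.RNFL
ORIENT = GridOrientation.TILTED_7


def fake_result(auc):
    return AurocResult(
        auc=auc, se=0.02, ci_low=auc - 0.04, ci_high=auc + 0.04,
        p_value=0.001, n_neg=10, n_pos=10,
    )


def fake_heatmap(auc_matrix):
    cells = [[fake_result(float(auc_matrix[r][c])) for c in range(8)] for r in range(8)]
    return AurocHeatmap(segmentation=SEG, orientation=ORIENT, cells=cells)


def gridset(eye_id, grid):
    gs = ThicknessGridSet(eye_id=eye_id)
    gs.set_grid(SEG, ORIENT, np.asarray(grid, float))
    return gs


def make_cohort(values_by_eye):
    """values_by_eye: list of (eye_id, group, 8x8 grid)."""
    records, grids = [], []
    for eye_id, group, grid in values_by_eye:
        records.append(
            EyeRecord(
                subject_id=eye_id, eye_id=eye_id,
                laterality=Laterality.RIGHT, group=group, age=60.0,
            )
        )
        grids.append(gridset(eye_id, grid))
    return Cohort(records, grids)


class TestIndexArithmetic:
    def test_mean_index_of_two_cells(self):
        grid = np.full((8, 8), 99.0)
        grid[0, 0], grid[0, 1] = 10.0, 20.0
        sel = CellSelection(SEG, ORIENT, frozenset({(1, 1), (1, 2)}))
        assert mean_index(gridset("e", grid), sel) == pytest.approx(15.0)

    def test_singleton_selection_returns_cell_value(self):
        grid = np.full((8, 8), 42.0)
        grid[4, 6] = 77.0
        sel = CellSelection(SEG, ORIENT, frozenset({(5, 7)}))
        assert mean_index(gridset("e", grid), sel) == pytest.approx(77.0)

    def test_uniform_grid_any_selection(self):
        grid = np.full((8, 8), 33.0)
        sel = CellSelection(SEG, ORIENT, frozenset({(1, 1), (4, 4), (8, 8)}))
        assert mean_index(gridset("e", grid), sel) == pytest.approx(33.0)

    def test_weighted_index_arithmetic(self):
        """thickness {10, 20} with weights {0.8, 0.9} -> (8 + 18)/2 = 13."""
        grid = np.full((8, 8), 99.0)
        grid[0, 0], grid[0, 1] = 10.0, 20.0
        auc = np.full((8, 8), 0.75)
        auc[0, 0], auc[0, 1] = 0.8, 0.9
        sel = CellSelection(SEG, ORIENT, frozenset({(1, 1), (1, 2)}))
        value = weighted_index(gridset("e", grid), sel, fake_heatmap(auc))
        assert value == pytest.approx(13.0)

    def test_equal_weights_factorise(self):
        grid = np.arange(64, dtype=float).reshape(8, 8) + 1.0
        auc = np.full((8, 8), 0.85)
        sel = CellSelection(SEG, ORIENT, frozenset({(2, 3), (5, 5), (7, 1)}))
        gs = gridset("e", grid)
        assert weighted_index(gs, sel, fake_heatmap(auc)) == pytest.approx(
            0.85 * mean_index(gs, sel)
        )

    def test_empty_selection_raises(self):
        sel = CellSelection(SEG, ORIENT, frozenset())
        with pytest.raises(EmptySelectionError):
            mean_index(gridset("e", np.full((8, 8), 1.0)), sel)


class TestIndexAuroc:
    def _cohort_with_signal(self, separated=True):
        rng = np.random.default_rng(0)
        eyes = []
        for i in range(10):
            base = 100.0 + rng.normal(0, 1)
            eyes.append((f"c{i}", Group.CONTROL, np.full((8, 8), base)))
        for i in range(10):
            base = (80.0 if separated else 100.0) + rng.normal(0, 1)
            eyes.append((f"g{i}", Group.GLAUCOMA, np.full((8, 8), base)))
        return make_cohort(eyes)

    def test_perfect_separation_gives_one(self):
        cohort = self._cohort_with_signal(separated=True)
        hm = fake_heatmap(np.full((8, 8), 0.75))
        res = compute_index(cohort, hm, IndexKind.MEAN)
        assert res.auroc.auc == pytest.approx(1.0)
        assert not res.excluded

    def test_constant_index_is_degenerate_half(self):
        eyes = [(f"c{i}", Group.CONTROL, np.full((8, 8), 50.0)) for i in range(5)]
        eyes += [(f"g{i}", Group.GLAUCOMA, np.full((8, 8), 50.0)) for i in range(5)]
        cohort = make_cohort(eyes)
        hm = fake_heatmap(np.full((8, 8), 0.75))
        res = compute_index(cohort, hm, IndexKind.MEAN)
        assert res.auroc.auc == pytest.approx(0.5)
        assert res.auroc.degenerate
        assert res.excluded  # 0.5 < 0.70

    def test_empty_selection_marks_excluded(self):
        cohort = self._cohort_with_signal()
        hm = fake_heatmap(np.full((8, 8), 0.55))
        res = compute_index(cohort, hm, IndexKind.MEAN)
        assert res.excluded
        assert res.auroc is None
        assert "no cells" in res.exclusion_reason


class TestComparisons:
    def test_constant_weights_make_kinds_degenerate(self):
        """Equal AUROC weights scale the mean index by a constant, so the
        mean-vs-weighted DeLong comparison is exactly degenerate."""
        rng = np.random.default_rng(1)
        eyes = [
            (f"c{i}", Group.CONTROL, np.full((8, 8), 100.0) + rng.normal(0, 5, (8, 8)))
            for i in range(8)
        ] + [
            (f"g{i}", Group.GLAUCOMA, np.full((8, 8), 90.0) + rng.normal(0, 5, (8, 8)))
            for i in range(8)
        ]
        cohort = make_cohort(eyes)
        hm = fake_heatmap(np.full((8, 8), 0.72))
        mres = compute_index(cohort, hm, IndexKind.MEAN)
        wres = compute_index(cohort, hm, IndexKind.WEIGHTED)
        assert wres.auroc.auc == pytest.approx(mres.auroc.auc)
        cmp_ = compare_mean_vs_weighted(cohort, mres, wres)
        assert cmp_.degenerate
        assert cmp_.p_value == 1.0

    def test_heterogeneous_weights_give_finite_z(self, small_cohort):
        hm = build_heatmap(small_cohort, SEG, ORIENT)
        mres = compute_index(small_cohort, hm, IndexKind.MEAN)
        wres = compute_index(small_cohort, hm, IndexKind.WEIGHTED)
        if mres.excluded or wres.excluded:
            pytest.skip("weak-signal draw selected no cells")
        cmp_ = compare_mean_vs_weighted(small_cohort, mres, wres)
        assert np.isfinite(cmp_.z)
        assert 0.0 <= cmp_.p_value <= 1.0
        rev = compare_mean_vs_weighted(small_cohort, wres, mres)
        assert rev.z == pytest.approx(-cmp_.z)

    def test_tilt_zero_orientation_comparison_degenerate(self):
        cfg = SimulationConfig(
            n_control=40, n_glaucoma=40, tilt_deg=0.0,
            segmentations=(SEG,), seed=21,
        )
        cohort = generate_cohort(cfg)
        hm_t = build_heatmap(cohort, SEG, GridOrientation.TILTED_7)
        hm_h = build_heatmap(cohort, SEG, GridOrientation.HORIZONTAL)
        res_t = compute_index(cohort, hm_t, IndexKind.MEAN)
        res_h = compute_index(cohort, hm_h, IndexKind.MEAN)
        cmp_ = compare_orientations(cohort, res_t, res_h)
        assert cmp_.degenerate
        assert cmp_.p_value == 1.0

    def test_larger_tilt_amplifies_orientation_difference(self):
        """With sharply localized damage, a 45-degree tilt smears the
        horizontal grid far more than 7 degrees: the median orientation
        |z| grows with the tilt angle."""
        from ppgrid.simulate import default_cell_sd, single_cell_pattern

        sd = default_cell_sd()[SEG][2, 1]
        pat = single_cell_pattern(SEG, 3, 2, 2.0 * sd)
        medians = {}
        for tilt in (7.0, 45.0):
            zs = []
            for seed in range(8):
                cfg = SimulationConfig(
                    n_control=100, n_glaucoma=100, tilt_deg=tilt,
                    pattern=pat, segmentations=(SEG,), seed=500 + seed,
                )
                cohort = generate_cohort(cfg)
                hm_t = build_heatmap(cohort, SEG, GridOrientation.TILTED_7)
                hm_h = build_heatmap(cohort, SEG, GridOrientation.HORIZONTAL)
                res_t = compute_index(cohort, hm_t, IndexKind.MEAN)
                res_h = compute_index(cohort, hm_h, IndexKind.MEAN)
                if res_t.excluded or res_h.excluded:
                    continue
                zs.append(abs(compare_orientations(cohort, res_t, res_h).z))
            medians[tilt] = np.median(zs)
        assert medians[45.0] > medians[7.0]

    def test_mismatched_grids_rejected(self):
        a = GlobalIndexResult(SEG, ORIENT, IndexKind.MEAN,
                              CellSelection(SEG, ORIENT, frozenset({(1, 1)})),
                              {}, None)
        b = GlobalIndexResult(Segmentation.GCL, ORIENT, IndexKind.MEAN,
                              CellSelection(Segmentation.GCL, ORIENT,
                                            frozenset({(1, 1)})),
                              {}, None)
        with pytest.raises(ValueError):
            compare_mean_vs_weighted(None, a, b)


class TestRanking:
    def _result(self, seg, auc, excluded=False, reason=None):
        return GlobalIndexResult(
            segmentation=seg, orientation=ORIENT, index_kind=IndexKind.MEAN,
            selection=CellSelection(seg, ORIENT, frozenset({(1, 1)})),
            per_eye_value={},
            auroc=None if auc is None else fake_result(auc),
            excluded=excluded, exclusion_reason=reason,
        )

    def test_sorted_by_descending_auc(self):
        results = [
            self._result(Segmentation.RETINA, 0.75),
            self._result(Segmentation.RNFL, 0.80),
            self._result(Segmentation.GCL, 0.78),
        ]
        ranked = layer_ranking(results)
        assert [e.segmentation for e in ranked] == [
            Segmentation.RNFL, Segmentation.GCL, Segmentation.RETINA
        ]

    def test_excluded_sort_last_with_reason(self):
        results = [
            self._result(Segmentation.ORL, None, excluded=True, reason="no cells"),
            self._result(Segmentation.RNFL, 0.80),
            self._result(Segmentation.OPLONL, 0.62, excluded=True,
                         reason="index AUROC 0.620 < 0.70"),
        ]
        ranked = layer_ranking(results)
        assert [e.segmentation for e in ranked[:1]] == [Segmentation.RNFL]
        assert all(e.excluded for e in ranked[1:])
        assert ranked[1].segmentation == Segmentation.OPLONL  # enum order
        assert ranked[2].segmentation == Segmentation.ORL

    def test_ties_break_by_enumeration_order(self):
        results = [
            self._result(Segmentation.GCL, 0.8),
            self._result(Segmentation.RETINA, 0.8),
            self._result(Segmentation.RNFL, 0.8),
        ]
        ranked = layer_ranking(results)
        assert [e.segmentation for e in ranked] == [
            Segmentation.RETINA, Segmentation.RNFL, Segmentation.GCL
        ]
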