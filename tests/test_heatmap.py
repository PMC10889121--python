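"""Per-cell AUROC heatmaps: colour rule, selection, spatial recovery."""

import numpy as np
import pytest

from ppgrid.grid import Group, GridOrientation, Segmentation, read_cohort, write_cohort
from ppgrid.heatmap import (
    ColorClass,
    build_heatmap,
    classify_color,
    heatmap_frame,
    plot_heatmap,
    select_cells,
)
from ppgrid.simulate import (
    SimulationConfig,
    default_cell_sd,
    default_glaucoma_pattern,
    generate_cohort,
    null_pattern,
    single_cell_pattern,
)


class TestColorRule:
    @pytest.mark.parametrize(
        "auc, expected",
        [
            (0.30, ColorClass.BLUE),
            (0.50, ColorClass.BLUE),          # boundary inclusive
            (0.55, ColorClass.INTERMEDIATE),  # unnamed band (0.5, 0.6)
            (0.60, ColorClass.WHITE),
            (0.65, ColorClass.WHITE),
            (0.69, ColorClass.WHITE),
            (0.695, ColorClass.INTERMEDIATE), # unnamed band (0.69, 0.70)
            (0.70, ColorClass.RED),           # selection boundary inclusive
            (0.95, ColorClass.RED),
        ],
    )
    def test_bands(self, auc, expected):
        assert classify_color(auc) == expected


@pytest.fixture(scope="module")
def null_heatmap():
    cfg = SimulationConfig(
        n_control=500,
        n_glaucoma=500,
        tilt_deg=0.0,
        pattern=null_pattern(),
        segmentations=(Segmentation.RNFL,),
        seed=5,
    )
    cohort = generate_cohort(cfg)
    return build_heatmap(cohort, Segmentation.RNFL, GridOrientation.HORIZONTAL)


class TestBuildAndSelect:
    def test_null_cohort_aurocs_near_half(self, null_heatmap):
        """No signal, n = 500/group: every cell AUROC stays in [0.4, 0.6]
        (a ~5.5 sigma band under the null)."""
        auc = null_heatmap.auc_matrix
        assert np.all((auc >= 0.4) & (auc <= 0.6))

    def test_null_selection_empty(self, null_heatmap):
        assert len(select_cells(null_heatmap)) == 0

    def test_selection_matches_threshold(self, small_cohort):
        hm = build_heatmap(small_cohort, Segmentation.RNFL, GridOrientation.TILTED_7)
        sel = select_cells(hm)
        expected = {
            (r, c)
            for r in range(1, 9)
            for c in range(1, 9)
            if hm.cell(r, c).auc >= 0.70
        }
        assert sel.selected == frozenset(expected)

    def test_too_few_eyes_rejected(self, small_cohort):
        from ppgrid.grid import Cohort

        one_control = [
            i for i, r in enumerate(small_cohort.records)
            if r.group == Group.CONTROL
        ][:1]
        glaucoma = [
            i for i, r in enumerate(small_cohort.records)
            if r.group == Group.GLAUCOMA
        ]
        keep = one_control + glaucoma
        sub = Cohort(
            [small_cohort.records[i] for i in keep],
            [small_cohort.grids[i] for i in keep],
        )
        with pytest.raises(ValueError, match="2 eyes per group"):
            build_heatmap(sub, Segmentation.RNFL, GridOrientation.TILTED_7)

    def test_frame_has_64_rows(self, small_cohort):
        hm = build_heatmap(small_cohort, Segmentation.RNFL, GridOrientation.TILTED_7)
        df = heatmap_frame(hm)
        assert len(df) == 64
        assert set(df.color.unique()) <= {c.value for c in ColorClass}

    def test_plot_writes_image(self, small_cohort, tmp_path):
        hm = build_heatmap(small_cohort, Segmentation.RNFL, GridOrientation.TILTED_7)
        out = tmp_path / "hm.png"
        plot_heatmap(hm, out)
        assert out.stat().st_size > 0


class TestMirroringCommutes:
    def test_heatmap_identical_after_file_round_trip(self, small_cohort, tmp_path):
        """Mirroring at ingest commutes with per-cell statistics: the
        heatmap from the in-memory cohort equals the heatmap from the
        cohort written to device convention and read back."""
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        back = read_cohort(path)
        hm_a = build_heatmap(small_cohort, Segmentation.RNFL, GridOrientation.TILTED_7)
        hm_b = build_heatmap(back, Segmentation.RNFL, GridOrientation.TILTED_7)
        assert np.allclose(hm_a.auc_matrix, hm_b.auc_matrix)


class TestSpatialRecovery:
    def test_damaged_cell_is_argmax_in_most_seeds(self):
        """Damage implanted in one known cell is recovered as the heatmap
        argmax (20 seeds, effect delta/(sigma sqrt 2) = 1, 150 eyes per
        group; the acceptance run repeats this over 200 seeds)."""
        sd = default_cell_sd()[Segmentation.RNFL][2, 5]
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(
                n_control=150,
                n_glaucoma=150,
                tilt_deg=0.0,
                pattern=single_cell_pattern(
                    Segmentation.RNFL, 3, 6, sd * np.sqrt(2)
                ),
                segmentations=(Segmentation.RNFL,),
                seed=300 + seed,
            )
            cohort = generate_cohort(cfg)
            hm = build_heatmap(cohort, Segmentation.RNFL, GridOrientation.HORIZONTAL)
            if hm.argmax_cell() == (3, 6):
                hits += 1
        assert hits >= 18

    def test_red_count_monotone_in_effect_size(self):
        """Median number of selected (red) cells does not decrease as the
        damage pattern is scaled up."""
        base = default_glaucoma_pattern()
        medians = []
        for factor in (0.5, 1.0, 1.5):
            counts = []
            for seed in range(12):
                cfg = SimulationConfig(
                    n_control=136,
                    n_glaucoma=163,
                    pattern=base.scaled(factor),
                    segmentations=(Segmentation.RNFL,),
                    seed=700 + seed,
                )
                cohort = generate_cohort(cfg)
                hm = build_heatmap(
                    cohort, Segmentation.RNFL, GridOrientation.TILTED_7
                )
                counts.append(len(select_cells(hm)))
            medians.append(np.median(counts))
        assert medians[0] <= medians[1] <= medians[2]
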