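"""Synthetic cohort generator: determinism, geometry, closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from ppgrid.grid import GridOrientation, Laterality, Segmentation
from ppgrid.heatmap import build_heatmap
from ppgrid.roc import auroc
from ppgrid.simulate import (
    SimulationConfig,
    UnsupportedConfigurationError,
    default_cell_sd,
    default_glaucoma_pattern,
    expected_cell_auroc,
    generate_cohort,
    null_pattern,
    single_cell_pattern,
)


def _cfg(**kw):
    kw.setdefault("n_control", 20)
    kw.setdefault("n_glaucoma", 20)
    kw.setdefault("segmentations", (Segmentation.RNFL,))
    return SimulationConfig(**kw)


class TestDeterminism:
    def test_same_seed_same_cohort(self):
        a = generate_cohort(_cfg(seed=7))
        b = generate_cohort(_cfg(seed=7))
        assert [r.eye_id for r, _ in a] == [r.eye_id for r, _ in b]
        for (_, ga), (_, gb) in zip(a, b):
            for key in ga.keys():
                assert np.array_equal(ga.values[key], gb.values[key])

    def test_different_seed_different_noise(self):
        a = generate_cohort(_cfg(seed=7))
        b = generate_cohort(_cfg(seed=8))
        key = (Segmentation.RNFL, GridOrientation.TILTED_7)
        assert not np.array_equal(a.grids[0].values[key], b.grids[0].values[key])


class TestGeometry:
    def test_tilt_zero_orientations_bit_identical(self, tilt0_cohort):
        for _, gs in tilt0_cohort:
            t = gs.grid(Segmentation.RNFL, GridOrientation.TILTED_7)
            h = gs.grid(Segmentation.RNFL, GridOrientation.HORIZONTAL)
            assert np.array_equal(t, h)

    def test_tilt_seven_orientations_differ_but_correlate(self, small_cohort):
        t = small_cohort.thickness_array(Segmentation.RNFL, GridOrientation.TILTED_7)
        h = small_cohort.thickness_array(Segmentation.RNFL, GridOrientation.HORIZONTAL)
        assert not np.array_equal(t, h)
        assert np.corrcoef(t.ravel(), h.ravel())[0, 1] > 0.9

    def test_all_thickness_positive(self, small_cohort):
        for _, gs in small_cohort:
            for grid in gs.values.values():
                assert np.all(grid > 0)

    def test_laterality_mix_and_subject_pairing(self):
        cohort = generate_cohort(_cfg(n_control=40, n_glaucoma=40, seed=3))
        lats = {r.laterality for r, _ in cohort}
        assert lats == {Laterality.RIGHT, Laterality.LEFT}
        subjects = {r.subject_id for r, _ in cohort}
        # ~76% of eyes in fellow pairs: clearly fewer subjects than eyes
        assert len(subjects) < len(cohort)
        for rec, _ in cohort:
            assert rec.age >= 20

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            _cfg(n_control=1)
        with pytest.raises(ValueError):
            _cfg(tilt_deg=95.0)
        with pytest.raises(ValueError):
            _cfg(inter_eye_correlation=1.5)
        with pytest.raises(ValueError):
            _cfg(severity_sd=-0.1)


class TestClosedFormOracle:
    def test_null_cell_is_half(self):
        cfg = _cfg(tilt_deg=0.0, pattern=null_pattern())
        assert expected_cell_auroc(cfg, Segmentation.RNFL, 4, 4) == 0.5

    def test_unit_effect_is_phi_one(self):
        """delta/(sigma sqrt 2) = 1 under the pure binormal model gives
        the standard normal CDF at 1 (~0.8413)."""
        sd = default_cell_sd()[Segmentation.RNFL][3, 3]
        cfg = _cfg(
            tilt_deg=0.0,
            severity_sd=0.0,
            pattern=single_cell_pattern(Segmentation.RNFL, 4, 4, sd * math.sqrt(2)),
        )
        expected = expected_cell_auroc(cfg, Segmentation.RNFL, 4, 4)
        assert expected == pytest.approx(stats.norm.cdf(1.0), abs=1e-12)

    def test_large_effect_approaches_one(self):
        cfg = _cfg(
            tilt_deg=0.0,
            severity_sd=0.0,
            pattern=single_cell_pattern(Segmentation.RNFL, 4, 4, 40.0),
        )
        assert expected_cell_auroc(cfg, Segmentation.RNFL, 4, 4) > 0.999999

    def test_severity_dispersion_shrinks_auc(self):
        sd = default_cell_sd()[Segmentation.RNFL][3, 3]
        pat = single_cell_pattern(Segmentation.RNFL, 4, 4, sd * math.sqrt(2))
        a0 = expected_cell_auroc(
            _cfg(tilt_deg=0.0, severity_sd=0.0, pattern=pat),
            Segmentation.RNFL, 4, 4,
        )
        a4 = expected_cell_auroc(
            _cfg(tilt_deg=0.0, severity_sd=0.4, pattern=pat),
            Segmentation.RNFL, 4, 4,
        )
        assert a4 < a0

    def test_tilted_config_unsupported(self):
        with pytest.raises(UnsupportedConfigurationError):
            expected_cell_auroc(_cfg(tilt_deg=7.0), Segmentation.RNFL, 4, 4)

    def test_monte_carlo_recovery(self):
        """Empirical cell AUROC at n = 2000/group within 3 standard errors
        of the closed form (the acceptance run repeats this at 5000)."""
        sd = default_cell_sd()[Segmentation.RNFL][3, 3]
        cfg = _cfg(
            n_control=2000,
            n_glaucoma=2000,
            tilt_deg=0.0,
            severity_sd=0.0,
            inter_eye_correlation=0.0,
            pattern=single_cell_pattern(Segmentation.RNFL, 4, 4, sd * math.sqrt(2)),
            seed=99,
        )
        cohort = generate_cohort(cfg)
        control, glaucoma = cohort.cell_values(
            Segmentation.RNFL, GridOrientation.HORIZONTAL, 4, 4
        )
        res = auroc(control, glaucoma)
        expected = expected_cell_auroc(cfg, Segmentation.RNFL, 4, 4)
        assert abs(res.auc - expected) < 3 * res.se


class TestNullCalibration:
    def test_cell_pvalue_rate_within_binomial_bounds(self):
        """With no signal and independent cells, the per-cell DeLong test
        rejects at ~5%: the rate over 20 cohorts x 64 cells stays inside
        99% binomial bounds around 0.05.

        Independence across cells is part of the calibration condition, so
        the noise field correlation length is set well below the cell size
        and the shared variance components are switched off.
        """
        n_cohorts, alpha = 20, 0.05
        rejections = 0
        total = 0
        for seed in range(n_cohorts):
            cfg = _cfg(
                n_control=60,
                n_glaucoma=60,
                tilt_deg=0.0,
                pattern=null_pattern(),
                within_eye_correlation=0.0,
                inter_eye_correlation=0.0,
                noise_corr_length=0.05,
                seed=1000 + seed,
            )
            cohort = generate_cohort(cfg)
            hm = build_heatmap(cohort, Segmentation.RNFL, GridOrientation.HORIZONTAL)
            for r in range(1, 9):
                for c in range(1, 9):
                    total += 1
                    if hm.cell(r, c).p_value < alpha:
                        rejections += 1
        rate = rejections / total
        half = 2.576 * math.sqrt(alpha * (1 - alpha) / total)
        assert alpha - half <= rate <= alpha + half


class TestDefaultPattern:
    def test_outer_layers_spared(self):
        pat = default_glaucoma_pattern()
        assert np.all(pat.for_segmentation(Segmentation.ORL) == 0)
        assert np.all(pat.for_segmentation(Segmentation.OPLONL) == 0)

    def test_rnfl_has_many_damaged_cells(self):
        pat = default_glaucoma_pattern()
        assert (pat.for_segmentation(Segmentation.RNFL) > 0).sum() >= 10

    def test_gcc_peak_is_off_centre(self):
        d = default_glaucoma_pattern().for_segmentation(Segmentation.GCC)
        r, c = np.unravel_index(np.argmax(d), d.shape)
        assert not (3 <= r <= 4 and 3 <= c <= 4)  # not a foveal cell

    def test_scaling_preserves_topography(self):
        pat = default_glaucoma_pattern()
        double = pat.scaled(2.0)
        d1 = pat.for_segmentation(Segmentation.GCL)
        d2 = double.for_segmentation(Segmentation.GCL)
        assert np.allclose(d2, 2 * d1)


class TestConfigYaml:
    def test_yaml_round_trip(self, tmp_path):
        cfg = _cfg(tilt_deg=5.0, seed=11, n_control=12, n_glaucoma=13)
        path = tmp_path / "sim.yaml"
        cfg.to_yaml(path)
        back = SimulationConfig.from_yaml(path)
        assert back.tilt_deg == cfg.tilt_deg
        assert back.n_control == cfg.n_control
        assert back.seed == cfg.seed
        assert back.segmentations == cfg.segmentations
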