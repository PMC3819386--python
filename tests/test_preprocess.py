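import numpy as np
import pytest

from voxgraph.preprocess import (
    GrayMatterMask,
    apply_mask,
    bandpass,
    build_nuisance_design,
    normalize_and_concatenate,
    preprocess_subject,
    regress_nuisance,
    unmask,
    voxelwise_psd,
    NuisanceDesign,
)
from .oracles import normal_equations_residuals


def design_from(cols, labels):
    return NuisanceDesign(np.column_stack(cols), labels)


class TestRegressNuisance:
    def test_series_equal_to_design_column_gives_zero_residual(self, rng):
        t = 60
        col = rng.normal(size=t)
        design = design_from([np.ones(t), col], ["intercept", "global"])
        series = np.vstack([col, 2 * col + 3])
        resid = regress_nuisance(series, design)
        assert np.abs(resid).max() < 1e-10

    def test_residuals_orthogonal_to_every_column(self, rng):
        t, p = 80, 4
        x = np.column_stack([np.ones(t), rng.normal(size=(t, p - 1))])
        design = NuisanceDesign(x, ["intercept", "a", "b", "c"])
        series = rng.normal(size=(7, t))
        resid = regress_nuisance(series, design)
        for j in range(p):
            col = x[:, j]
            cos = np.abs(resid @ col) / (
                np.linalg.norm(resid, axis=1) * np.linalg.norm(col)
            )
            assert cos.max() < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        t = 50
        x = np.column_stack([np.ones(t), rng.normal(size=(t, 2))])
        design = NuisanceDesign(x, ["intercept", "a", "b"])
        series = rng.normal(size=(5, t))
        resid = regress_nuisance(series, design)
        ref = np.vstack([normal_equations_residuals(row, x) for row in series])
        np.testing.assert_allclose(resid, ref, atol=1e-10)

    def test_collinear_column_dropped_with_warning(self, rng):
        t = 40
        a = rng.normal(size=t)
        design = design_from([np.ones(t), a, 2 * a], ["intercept", "a", "a2"])
        with pytest.warns(UserWarning, match="collinear"):
            resid = regress_nuisance(rng.normal(size=(3, t)), design)
        assert resid.shape == (3, t)

    def test_all_zero_column_rejected(self):
        t = 30
        with pytest.raises(ValueError, match="all-zero"):
            design_from([np.ones(t), np.zeros(t)], ["intercept", "dead"])


class TestBandpass:
    TR = 1.5

    def test_constant_series_removed(self):
        out = bandpass(np.full((3, 128), 7.0), 0.008, 0.08, self.TR)
        assert np.abs(out).max() < 1e-10

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(300) * self.TR
        x = np.sin(2 * np.pi * 0.05 * t)[None, :]
        out = bandpass(x, 0.008, 0.08, self.TR)
        # compare amplitude away from the window edges
        sl = slice(30, 270)
        gain = np.abs(out[0, sl]).max() / np.abs(x[0, sl]).max()
        assert 0.95 <= gain <= 1.05

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(300) * self.TR
        x = np.sin(2 * np.pi * 0.20 * t)[None, :]
        out = bandpass(x, 0.008, 0.08, self.TR)
        assert np.sqrt((out**2).mean()) < 0.05 * np.sqrt((x**2).mean())

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros((2, 64)), 0.008, 0.4, self.TR)


class TestNormalizeConcatenate:
    def test_zscored_run_is_fixed_point(self, rng):
        run = rng.normal(size=(6, 120))
        run = (run - run.mean(axis=1, keepdims=True)) / run.std(axis=1, keepdims=True)
        out = normalize_and_concatenate([run])
        np.testing.assert_allclose(out.data, run, atol=1e-12)

    def test_three_standard_runs_concatenate_to_550(self, rng):
        runs = [rng.normal(size=(5, t)) for t in (150, 220, 180)]
        out = normalize_and_concatenate(runs)
        assert out.n_time == 550
        assert out.run_boundaries == [150, 370, 550]

    def test_each_segment_unit_variance_zero_mean(self, rng):
        runs = [rng.normal(loc=3, scale=9, size=(4, t)) for t in (60, 90)]
        out = normalize_and_concatenate(runs)
        start = 0
        for end in out.run_boundaries:
            seg = out.data[:, start:end]
            np.testing.assert_allclose(seg.mean(axis=1), 0, atol=1e-10)
            np.testing.assert_allclose(seg.std(axis=1), 1, atol=1e-10)
            start = end
        sd = out.data.std(axis=1)
        assert np.all(np.abs(out.data.mean(axis=1)) < 1e-8 * sd)

    def test_node_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="node count"):
            normalize_and_concatenate([rng.normal(size=(4, 50)), rng.normal(size=(5, 50))])


class TestMasking:
    def test_round_trip_on_mask_support(self, rng):
        vol = np.zeros((3, 3, 3), dtype=bool)
        vol[np.unravel_index([0, 5, 13, 20, 26], vol.shape)] = True
        mask = GrayMatterMask(vol)
        series = rng.normal(size=(3, 3, 3, 7))
        x = apply_mask(series, mask)
        assert x.shape == (5, 7)
        restored = unmask(x, mask)
        np.testing.assert_array_equal(restored[vol], series[vol])

    def test_all_true_mask_keeps_every_voxel(self, rng):
        mask = GrayMatterMask.full((4, 3, 2))
        x = apply_mask(rng.normal(size=(4, 3, 2, 5)), mask)
        assert x.shape == (24, 5)

    def test_row_order_is_x_fastest_raster(self):
        mask = GrayMatterMask.full((2, 2, 1))
        vol = np.zeros((2, 2, 1, 1))
        vol[1, 0, 0, 0] = 42.0  # flat x-fastest index 1
        x = apply_mask(vol, mask)
        assert x[1, 0] == 42.0

    def test_tissue_prior_keeps_top_fraction(self, rng):
        vol = rng.normal(size=(9, 9, 9))
        mask = GrayMatterMask.from_tissue_prior(vol, top_fraction=0.80)
        cut = np.percentile(vol, 20)
        np.testing.assert_array_equal(mask.data, vol >= cut)

    def test_dimension_mismatch_rejected(self, rng):
        mask = GrayMatterMask.full((3, 3, 3))
        with pytest.raises(ValueError, match="match"):
            apply_mask(rng.normal(size=(3, 3, 4, 5)), mask)


class TestVoxelwisePsd:
    def test_white_noise_flat_across_equal_bands(self, rng):
        series = rng.normal(size=(40, 512))
        table = voxelwise_psd(series, 1.0, bands=[(0.1, 0.2), (0.2, 0.3)])
        ratio = table.iloc[:, 0].mean() / table.iloc[:, 1].mean()
        assert 0.5 <= ratio <= 2.0

    def test_sinusoid_concentrates_in_its_band(self):
        t = np.arange(512) * 1.5
        series = np.sin(2 * np.pi * 0.025 * t)[None, :]
        table = voxelwise_psd(series, 1.5, bands=[(0.0, 0.016), (0.019, 0.03)])
        assert table.iloc[0, 1] > 10 * table.iloc[0, 0]

    def test_zero_series_zero_power(self):
        table = voxelwise_psd(np.zeros((3, 64)), 1.5)
        assert (table.to_numpy() == 0).all()

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            voxelwise_psd(np.zeros((2, 64)), 1.5, bands=[(0.0, 0.5)])


class TestSubjectPipeline:
    def test_rerun_reproduces_identical_output(self, rng):
        runs = [rng.normal(size=(10, t)) for t in (60, 80)]
        motion = [rng.normal(size=(t, 6)) for t in (60, 80)]
        a = preprocess_subject(runs, motion)
        b = preprocess_subject(runs, motion)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.provenance["order"] == [
            "regress_nuisance",
            "bandpass",
            "normalize_and_concatenate",
        ]

    def test_residual_decorrelated_from_nuisance(self, rng):
        t = 200
        run = rng.normal(size=(12, t))
        motion = rng.normal(size=(t, 6))
        design = build_nuisance_design(run, motion)
        resid = regress_nuisance(run, design)
        for j in range(design.matrix.shape[1]):
            col = design.matrix[:, j]
            if col.std() == 0:
                continue
            r = np.corrcoef(np.vstack([col[None, :], resid]))[0, 1:]
            assert np.abs(r).max() < 1e-8
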