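import warnings

import numpy as np
import pandas as pd
import pytest

import memascreen as ms
from memascreen.errors import ParameterError
from memascreen.features import gate_edu, summarize_spots
from memascreen.normalize import (
    SignalMatrix,
    build_residual_controls,
    build_signal_matrix,
    loess2d,
    loess_normalize,
    normalize_pipeline,
    ruv_normalize,
    transform_signal,
)


def _toy_matrix(values, groups=None):
    values = np.asarray(values, float)
    n_arr, n_spot = values.shape
    positions = pd.DataFrame(
        {"row": np.zeros(n_spot, int), "col": np.arange(n_spot), "ecm": "E"}
    )
    if groups is None:
        # whole columns as replicate groups spanning all arrays
        groups = {
            f"g{j}": [(i, j) for i in range(n_arr)] for j in range(n_spot)
        }
    return SignalMatrix(values, [f"A{i}" for i in range(n_arr)], positions, groups)


def _screen_matrix(seed, array_log_sd=0.5, n_lig=12, arrays_per_ligand=4):
    design = ms.build_screen_design(
        ms.default_ligand_panel(n_lig), ms.default_ecm_panel(4),
        arrays_per_ligand=arrays_per_ligand,
    )
    spec = ms.EffectSpec(
        array_factor_log_sd=array_log_sd,
        spatial_surface=ms.SurfaceSpec("none", ()),
        seed=seed,
    )
    cells, truth = ms.make_null_experiment(design, spec=spec, seed=seed)
    gate = gate_edu(cells, scope="global")
    spots = summarize_spots(cells, gate, design)
    spots["_v"] = transform_signal(spots, "cell_count")
    return build_signal_matrix(spots, "_v"), truth


class TestResidualControls:
    def test_replicate_group_residuals(self):
        sm = _toy_matrix([[10.0], [12.0], [14.0]])
        resid = build_residual_controls(sm)
        np.testing.assert_allclose(resid.ravel(), [-2.0, 0.0, 2.0])

    def test_constant_matrix_zero_residuals(self):
        sm = _toy_matrix(np.full((3, 4), 7.0))
        np.testing.assert_allclose(build_residual_controls(sm), 0.0)

    def test_singleton_group_warns_zero(self):
        sm = _toy_matrix(
            [[1.0, 5.0], [2.0, np.nan]],
            groups={"a": [(0, 0), (1, 0)], "b": [(0, 1)]},
        )
        with pytest.warns(UserWarning, match="size 1"):
            resid = build_residual_controls(sm)
        assert resid[0, 1] == 0.0


class TestRUV:
    def test_k0_is_identity(self):
        sm = _toy_matrix(np.random.default_rng(0).normal(size=(4, 6)))
        out, fit = ruv_normalize(sm, k=0)
        np.testing.assert_array_equal(out.values, sm.values)
        assert fit.k == 0

    def test_constant_matrix_unchanged(self):
        sm = _toy_matrix(np.full((4, 6), 3.0))
        out, _ = ruv_normalize(sm, k=2)
        np.testing.assert_allclose(out.values, sm.values)

    def test_k_bounds_enforced(self):
        sm = _toy_matrix(np.zeros((3, 5)))
        with pytest.raises(ParameterError):
            ruv_normalize(sm, k=3)
        with pytest.raises(ParameterError):
            ruv_normalize(sm, k=-1)

    def test_factor_scores_match_brute_force_svd(self):
        """Oracle equivalence on a 3-array x 6-spot toy matrix: RUV factor
        scores equal an independently assembled SVD of the residuals."""
        rng = np.random.default_rng(4)
        values = rng.normal(size=(3, 6)) + np.array([[1.0], [-0.5], [-0.5]])
        sm = _toy_matrix(values)
        _, fit = ruv_normalize(sm, k=1)
        # independent construction: residuals by explicit loops, then SVD
        resid = np.empty_like(values)
        for j in range(values.shape[1]):
            med = np.median(values[:, j])
            for i in range(values.shape[0]):
                resid[i, j] = values[i, j] - med
        u, s, _ = np.linalg.svd(resid)
        expected = u[:, :1] * s[0]
        expected = expected - expected.mean()
        got = fit.unwanted_factors
        sign = np.sign(expected.ravel() @ got.ravel())
        np.testing.assert_allclose(got, sign * expected, atol=1e-8)

    def test_removes_planted_array_effect(self):
        """Planted rank-1 multiplicative array effect (log scale), k=1:
        between-array variance of replicate residuals drops >= 80% and the
        normalized residuals decorrelate from the planted factor."""
        sm, truth = _screen_matrix(seed=5)
        resid_before = build_residual_controls(sm)
        smn, fit = ruv_normalize(sm, k=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            resid_after = build_residual_controls(smn)
        var_before = np.nanvar(np.nanmean(resid_before, axis=1))
        var_after = np.nanvar(np.nanmean(resid_after, axis=1))
        assert var_after <= 0.2 * var_before
        logf = np.log([truth.array_factors[a] for a in sm.array_ids])
        broadcast = np.broadcast_to(logf[:, None], sm.values.shape)
        ok = ~np.isnan(resid_after)
        corr = np.corrcoef(resid_after[ok], broadcast[ok])[0, 1]
        assert abs(corr) <= 0.1


class TestLoess:
    def test_flattens_planted_row_gradient(self):
        rng = np.random.default_rng(2)
        rows, cols = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        a = 0.3
        z = a * rows.ravel() + rng.normal(0, 0.05, 36)
        frame = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(), "v": z})
        corrected, surface = loess_normalize(frame, "v", span=0.5)
        slope = np.polyfit(rows.ravel(), corrected, 1)[0]
        assert abs(slope) < 0.05 * a

    def test_flat_data_small_correction(self):
        rng = np.random.default_rng(3)
        sigma = 0.2
        rows, cols = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        z = rng.normal(0, sigma, 36)
        frame = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(), "v": z})
        corrected, _ = loess_normalize(frame, "v", span=0.7)
        assert np.abs(corrected - z).mean() <= sigma

    def test_too_few_spots_returns_unchanged_with_warning(self):
        frame = pd.DataFrame({"row": [0], "col": [0], "v": [3.0]})
        with pytest.warns(UserWarning, match="usable spots"):
            corrected, surface = loess_normalize(frame, "v", min_spots=20)
        np.testing.assert_array_equal(corrected, [3.0])
        np.testing.assert_array_equal(surface, [0.0])

    @pytest.mark.parametrize("span", [0.0, -0.2, 1.5])
    def test_invalid_span_rejected(self, span):
        frame = pd.DataFrame({"row": [0, 1], "col": [0, 1], "v": [1.0, 2.0]})
        with pytest.raises(ParameterError):
            loess_normalize(frame, "v", span=span)
        with pytest.raises(ParameterError):
            loess2d(np.arange(4.0), np.arange(4.0), np.arange(4.0), span=span)

    def test_location_preserving(self):
        rng = np.random.default_rng(5)
        rows, cols = np.meshgrid(np.arange(6), np.arange(6), indexing="ij")
        z = 5.0 + 0.2 * rows.ravel() + rng.normal(0, 0.05, 36)
        frame = pd.DataFrame({"row": rows.ravel(), "col": cols.ravel(), "v": z})
        corrected, _ = loess_normalize(frame, "v", span=0.5)
        assert np.median(corrected) == pytest.approx(np.median(z), abs=0.05)


class TestPipeline:
    def test_empty_input_empty_output(self):
        out, diag = normalize_pipeline(pd.DataFrame())
        assert out.empty and diag == {}

    def test_counts_and_labels_never_altered(self, null_screen, screen_design):
        cells, _ = null_screen
        gate = gate_edu(cells, scope="global")
        spots = summarize_spots(cells, gate, screen_design)
        normed, _ = normalize_pipeline(spots, signals=("cell_count", "edu_prop"))
        pd.testing.assert_series_equal(normed["cell_count"], spots["cell_count"])
        pd.testing.assert_series_equal(normed["edu_pos"], spots["edu_pos"])
        pd.testing.assert_series_equal(normed["edu_prop"], spots["edu_prop"])

    def test_no_artifact_screen_nearly_unchanged(self, screen_design):
        """With artifacts disabled, normalization should be close to the
        identity on the transformed scale: mean absolute change bounded by
        the replicate noise scale."""
        cells, truth = ms.make_null_experiment(screen_design, seed=10, artifacts=False)
        gate = gate_edu(cells, scope="global")
        spots = summarize_spots(cells, gate, screen_design)
        spots["_t"] = transform_signal(spots, "cell_count")
        normed, _ = normalize_pipeline(spots, signals=("cell_count",))
        delta = np.abs(normed["cell_count_norm"] - spots["_t"])
        noise_sd = spots.groupby(["ecm", "ligand"])["_t"].std().median()
        assert delta.mean() <= noise_sd

    def test_artifact_screen_replicate_cv_reduced(self, screen_design):
        cells, _ = ms.make_null_experiment(screen_design, seed=11, artifacts=True)
        gate = gate_edu(cells, scope="global")
        spots = summarize_spots(cells, gate, screen_design)
        spots["_t"] = transform_signal(spots, "cell_count")
        normed, _ = normalize_pipeline(spots, signals=("cell_count",))

        def replicate_sd(col):
            return normed.groupby(["ecm", "ligand"])[col].std().mean()

        assert replicate_sd("cell_count_norm") < replicate_sd("_t")

    def test_planted_effect_spearman_recovery(self):
        """2-fold-range planted ligand effects with artifacts on: Spearman
        correlation of planted effects vs normalized MEP medians >= 0.9."""
        from scipy.stats import spearmanr

        names = [f"L{i + 1:02d}" for i in range(12)]
        effects = dict(zip(names, np.logspace(np.log10(0.5), np.log10(2.0), 12)))
        design = ms.build_screen_design(
            ms.default_ligand_panel(12), ms.default_ecm_panel(4)
        )
        spec = ms.EffectSpec(ligand_effects=effects, seed=7)
        cells, _ = ms.simulate_experiment(design, spec)
        cfg = ms.PipelineConfig(gating_scope="global", signals=("cell_count",))
        result = ms.analyze_screen(cells, design, cfg)
        med = result.mep_summaries.groupby("ligand")["median_cell_count_norm"].median()
        rho = spearmanr([effects[n] for n in names], med.loc[names].values).statistic
        assert rho >= 0.9
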