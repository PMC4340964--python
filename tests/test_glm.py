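import numpy as np
import pytest

import blockmvpa as bm
from blockmvpa.design import Block, BlockSchedule, FIXATION
from blockmvpa.errors import DesignError
from blockmvpa.glm import PLATEAU_WINDOW, build_design_matrix
from blockmvpa.hemo import HRFParams, condition_boxcar, hrf_kernel


def toy_run(n_trs=20, n_voxels=2, seed=0, tr=2.0):
    rng = np.random.default_rng(seed)
    data = rng.normal(100, 1, size=(n_voxels, 1, 1, n_trs))
    return bm.BOLDRun(data=data, tr_seconds=tr, voxel_mm=2.0, session_id=0)


def toy_schedule(n_trs=20):
    blocks = [
        Block("identity1", 0, 4),
        Block("cup1", 4, 4),
        Block(FIXATION, 8, 2),
        Block("cup1", 10, 4),
        Block("identity1", 14, 4),
        Block(FIXATION, 18, 2),
    ]
    return BlockSchedule(session_id=0, blocks=blocks)


class TestFitBlockGLM:
    def test_matches_normal_equations_oracle(self):
        # oracle: explicit (X'X)^-1 X'y on a 2-voxel, 20-TR toy
        run = toy_run()
        schedule = toy_schedule()
        regressors = {"identity1": ("identity1",), "cup1": ("cup1",)}
        glm = bm.fit_block_glm([run], [schedule], regressors)

        X, _ = build_design_matrix(
            [schedule], regressors, [20], HRFParams(), run.tr_seconds
        )
        Y = run.flat().T
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        np.testing.assert_allclose(glm.beta, beta_oracle, atol=1e-10)

    def test_fitted_plus_residuals_reconstruct_input(self):
        run = toy_run(seed=3)
        schedule = toy_schedule()
        glm = bm.fit_block_glm([run], [schedule], ["identity1", "cup1"])
        Y = run.flat().T
        fitted = glm.design @ glm.beta
        resid = Y - fitted
        np.testing.assert_allclose(fitted + resid, Y, atol=1e-12)
        assert glm.df == 20 - glm.design.shape[1]

    def test_localizer_two_regressor_form(self, subject_factory):
        runs, schedules, _, _ = subject_factory(seed=2)
        glm = bm.fit_block_glm(
            [runs[0]], [schedules[0]],
            {"faces": bm.FACE_CONDITIONS, "cups": bm.CUP_CONDITIONS},
        )
        assert glm.condition_names == ["faces", "cups"]
        assert glm.beta.shape[0] == 2 + 2  # two conditions + intercept + drift

    def test_missing_condition_rejected(self):
        run = toy_run()
        with pytest.raises(DesignError, match="absent"):
            bm.fit_block_glm([run], [toy_schedule()], ["identity2"])

    def test_rank_deficient_names_columns(self):
        run = toy_run()
        schedule = toy_schedule()
        regressors = {"a": ("identity1",), "b": ("identity1",)}  # duplicate column
        with pytest.raises(DesignError, match="collinear"):
            bm.fit_block_glm([run], [schedule], regressors)

    def test_no_runs_rejected(self):
        with pytest.raises(DesignError, match="at least one run"):
            bm.fit_block_glm([], [], ["identity1"])


class TestContrastMap:
    def test_zero_weights_zero_t(self):
        run = toy_run()
        glm = bm.fit_block_glm([run], [toy_schedule()], ["identity1", "cup1"])
        stat = bm.contrast_map(glm, [0.0, 0.0])
        np.testing.assert_array_equal(stat.t, 0.0)

    def test_matches_oracle_formula(self):
        run = toy_run(seed=5)
        schedule = toy_schedule()
        regressors = {"identity1": ("identity1",), "cup1": ("cup1",)}
        glm = bm.fit_block_glm([run], [schedule], regressors)
        stat = bm.contrast_map(glm, [1.0, -1.0])

        X, _ = build_design_matrix([schedule], regressors, [20], HRFParams(), 2.0)
        Y = run.flat().T
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ Y
        resid = Y - X @ beta
        df = X.shape[0] - X.shape[1]
        sigma2 = (resid**2).sum(axis=0) / df
        c = np.array([1.0, -1.0, 0.0, 0.0])
        t_oracle = (c @ beta) / np.sqrt(sigma2 * (c @ xtx_inv @ c))
        np.testing.assert_allclose(stat.t.ravel(), t_oracle, atol=1e-10)

    def test_positive_in_constructed_face_region(self, subject_factory):
        runs, schedules, truths, _ = subject_factory(seed=4)
        glm = bm.fit_block_glm(
            [runs[0]], [schedules[0]],
            {"faces": bm.FACE_CONDITIONS, "cups": bm.CUP_CONDITIONS},
        )
        stat = bm.contrast_map(glm, [1.0, -1.0])
        region_t = stat.t[tuple(truths[0].coords.T)]
        assert np.all(region_t > 0)

    def test_intercept_absorbs_constant_shift(self):
        run = toy_run(seed=6)
        schedule = toy_schedule()
        glm1 = bm.fit_block_glm([run], [schedule], ["identity1", "cup1"])
        shifted = bm.BOLDRun(run.data + 50.0, run.tr_seconds, run.voxel_mm, 0)
        glm2 = bm.fit_block_glm([shifted], [schedule], ["identity1", "cup1"])
        t1 = bm.contrast_map(glm1, [1.0, -1.0]).t
        t2 = bm.contrast_map(glm2, [1.0, -1.0]).t
        np.testing.assert_allclose(t1, t2, atol=1e-8)

    def test_zero_variance_flagged(self):
        run = toy_run()
        run.data[:] = 0.0
        box = condition_boxcar(toy_schedule(), ("identity1",), 20)
        run.data[0, 0, 0, :] = 100 + np.convolve(box, hrf_kernel(HRFParams(), 2.0))[:20]
        glm = bm.fit_block_glm([run], [toy_schedule()], ["identity1", "cup1"])
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            stat = bm.contrast_map(glm, [1.0, 0.0])
        assert stat.flagged is not None and stat.flagged.any()
        assert np.isinf(stat.t[stat.flagged]).all() or (stat.t[stat.flagged] == 0).all()

    def test_wrong_weight_length(self):
        run = toy_run()
        glm = bm.fit_block_glm([run], [toy_schedule()], ["identity1", "cup1"])
        with pytest.raises(DesignError, match="weights"):
            bm.contrast_map(glm, [1.0])


class TestPlateauPSC:
    def test_constant_series_gives_zero_psc(self, params):
        schedule = bm.generate_session_schedule(params, seed=0)
        data = np.full((2, 1, 1, schedule.n_trs), 100.0)
        run = bm.BOLDRun(data, 2.0, 2.0, 0)
        psc = bm.plateau_psc([run], [schedule], list(bm.FACE_CONDITIONS))
        for cond in bm.FACE_CONDITIONS:
            assert psc.plateau[cond] == pytest.approx(0.0)

    def test_plateau_window_is_7_samples(self):
        lo, hi = PLATEAU_WINDOW
        assert (lo, hi) == (4, 10)
        assert hi - lo + 1 == 7

    def test_noiseless_boxcar_matches_convolution_oracle(self, params, subject_factory):
        runs, schedules, _, mask = subject_factory(
            noise_sd=0.0, drift_amplitude=0.0, session_offset_sd=0.0
        )
        psc = bm.plateau_psc(
            runs, schedules, list(bm.FACE_CONDITIONS), roi_coords=mask.coords
        )
        # oracle: direct convolution arithmetic on the known generative model
        kernel = hrf_kernel(HRFParams(), 2.0)
        expected = {}
        for cond in bm.FACE_CONDITIONS:
            values = []
            for run, schedule in zip(runs, schedules):
                box_faces = condition_boxcar(schedule, bm.FACE_CONDITIONS, schedule.n_trs)
                box_cups = condition_boxcar(schedule, bm.CUP_CONDITIONS, schedule.n_trs)
                series = (
                    100.0
                    + 3.0 * np.convolve(box_faces, kernel)[: schedule.n_trs]
                    + 0.5 * np.convolve(box_cups, kernel)[: schedule.n_trs]
                )
                fix = np.concatenate(
                    [np.arange(b.onset_tr, b.end_tr) for b in schedule.blocks_of(bm.FIXATION)]
                )
                baseline = series[fix].mean()
                course = np.mean(
                    [
                        100.0 * (series[b.onset_tr : b.onset_tr + 12] - baseline) / baseline
                        for b in schedule.blocks_of(cond)
                    ],
                    axis=0,
                )
                values.append(course)
            expected[cond] = np.mean(values, axis=0)[3:10].mean()
        for cond in bm.FACE_CONDITIONS:
            assert psc.plateau[cond] == pytest.approx(expected[cond], abs=1e-10)

    def test_absent_condition_rejected(self, params):
        schedule = bm.generate_session_schedule(params, seed=0)
        run = bm.BOLDRun(np.full((1, 1, 1, schedule.n_trs), 100.0), 2.0, 2.0, 0)
        with pytest.raises(DesignError, match="absent"):
            bm.plateau_psc([run], [schedule], ["not_a_condition"])

    def test_identity_psc_paired_t_null(self, subject_factory):
        # identity_effect=0: the two identities have identical mean responses
        pscs = {c: [] for c in bm.FACE_CONDITIONS}
        for seed in range(8):
            runs, schedules, _, mask = subject_factory(seed=seed)
            p = bm.plateau_psc(
                runs[1:], schedules[1:], list(bm.FACE_CONDITIONS), roi_coords=mask.coords
            )
            for c in bm.FACE_CONDITIONS:
                pscs[c].append(p.plateau[c])
        result = bm.paired_t(pscs["identity1"], pscs["identity2"], "two")
        assert result.p > 0.01
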