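import numpy as np
import pytest

import blockmvpa as bm
from blockmvpa.decode import (
    PatternSet,
    block_averages,
    concat_pattern_sets,
    subtract_condition_means,
)
from blockmvpa.design import Block, BlockSchedule, FIXATION
from blockmvpa.errors import ConfigurationError, DesignError


def make_run(data_2d, tr=2.0, session_id=0):
    n_vox, n_trs = data_2d.shape
    return bm.BOLDRun(data_2d.reshape(n_vox, 1, 1, n_trs), tr, 2.0, session_id)


class TestPreprocessSession:
    def test_linear_ramp_removed(self):
        ramp = np.outer(np.ones(3), np.arange(30, dtype=float))
        run = make_run(5.0 + 2.0 * ramp)
        with pytest.warns(RuntimeWarning, match="zero variance"):
            pre = bm.preprocess_session(run, bm.DecodeConfig(lag_trs=0))
        np.testing.assert_allclose(pre.data, 0.0, atol=1e-6)
        assert len(pre.flagged_voxels) == 3

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        run = make_run(rng.normal(100, 3, size=(6, 50)))
        pre = bm.preprocess_session(run, bm.DecodeConfig(lag_trs=0))
        np.testing.assert_allclose(pre.data.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(pre.data.std(axis=1, ddof=1), 1.0, atol=1e-10)

    def test_shift_drops_trailing_samples(self):
        rng = np.random.default_rng(1)
        run = make_run(rng.normal(size=(2, 40)))
        cfg = bm.DecodeConfig(lag_trs=2)
        pre = bm.preprocess_session(run, cfg)
        assert pre.data.shape == (2, 38)
        assert pre.lag_seconds == 4.0

    def test_matches_step_by_step_oracle(self):
        # oracle: naive per-voxel reimplementation of detrend -> zscore -> shift
        rng = np.random.default_rng(42)
        raw = rng.normal(50, 5, size=(4, 60))
        run = make_run(raw.copy())
        cfg = bm.DecodeConfig(lag_trs=2)
        pre = bm.preprocess_session(run, cfg)

        expected = np.empty_like(raw)
        t = np.arange(60, dtype=float)
        for v in range(4):
            slope, intercept = np.polyfit(t, raw[v], 1)
            detr = raw[v] - (slope * t + intercept)
            expected[v] = (detr - detr.mean()) / detr.std(ddof=1)
        expected = expected[:, 2:]
        np.testing.assert_allclose(pre.data, expected, atol=1e-10)

    def test_session_too_short(self):
        run = make_run(np.zeros((1, 2)))
        with pytest.raises(ConfigurationError, match="too short"):
            bm.preprocess_session(run, bm.DecodeConfig(lag_trs=2))


def two_block_session(session_id=0):
    """3-voxel toy session with hand-checkable block averages."""
    blocks = [
        Block("identity1", 0, 4),
        Block("identity2", 4, 4),
        Block(FIXATION, 8, 2),
        Block("identity2", 10, 4),
        Block("identity1", 14, 4),
        Block(FIXATION, 18, 2),
    ]
    return BlockSchedule(session_id=session_id, blocks=blocks)


class TestExtractBlockPatterns:
    def test_8tr_block_discard_2_averages_6(self, subject_factory):
        runs, schedules, _, mask = subject_factory(seed=1)
        cfg = bm.DecodeConfig()
        pre = bm.preprocess_session(runs[1], cfg)
        patterns = bm.extract_block_patterns(
            pre, schedules[1], mask, bm.FACE_CONDITIONS, cfg
        )
        assert patterns.n_trs_averaged == 6
        assert len(patterns) == 10  # 5 per class
        for cond in bm.FACE_CONDITIONS:
            assert (patterns.labels == cond).sum() == 5

    def test_hand_computed_toy(self):
        # handcrafted 3-voxel session; values frozen by hand arithmetic
        schedule = two_block_session()
        data = np.zeros((3, 20))
        # identity1 block at TR 0-3: after discarding 2 -> TRs 2,3
        data[:, 2] = [1.0, 2.0, 3.0]
        data[:, 3] = [3.0, 4.0, 5.0]  # average (2,3,4)
        # identity2 block at TR 4-7 -> TRs 6,7
        data[:, 6] = [10.0, 10.0, 10.0]
        data[:, 7] = [12.0, 14.0, 10.0]  # average (11,12,10)
        # identity2 block at TR 10-13 -> TRs 12,13
        data[:, 12] = [0.0, 0.0, 6.0]
        data[:, 13] = [0.0, 0.0, 2.0]  # average (0,0,4)
        # identity1 block at TR 14-17 -> TRs 16,17
        data[:, 16] = [4.0, 4.0, 4.0]
        data[:, 17] = [0.0, 2.0, 10.0]  # average (2,3,7)
        pre = bm.PreprocessedSession(
            data=data, session_id=0, lag_trs=0, tr_seconds=2.0,
            grid_shape=(3, 1, 1), flagged_voxels=np.array([]),
        )
        cfg = bm.DecodeConfig(lag_trs=0, discard_trs=2)
        raw = block_averages(pre, schedule, np.arange(3), bm.FACE_CONDITIONS, cfg)
        np.testing.assert_allclose(
            raw.patterns,
            [[2, 3, 4], [11, 12, 10], [0, 0, 4], [2, 3, 7]],
        )
        out = subtract_condition_means(raw)
        # identity1 mean over voxels x blocks: (2+3+4+2+3+7)/6 = 3.5
        # identity2 mean: (11+12+10+0+0+4)/6 = 6.1666...
        np.testing.assert_allclose(
            out.patterns[0], np.array([2, 3, 4]) - 3.5, atol=1e-12
        )
        np.testing.assert_allclose(
            out.patterns[1], np.array([11, 12, 10]) - 37 / 6, atol=1e-12
        )

    def test_condition_group_mean_is_zero(self, subject_factory):
        runs, schedules, _, mask = subject_factory(seed=2)
        cfg = bm.DecodeConfig()
        pre = bm.preprocess_session(runs[1], cfg)
        patterns = bm.extract_block_patterns(pre, schedules[1], mask, bm.FACE_CONDITIONS, cfg)
        for cond in bm.FACE_CONDITIONS:
            sel = patterns.labels == cond
            assert patterns.patterns[sel].mean() == pytest.approx(0.0, abs=1e-12)

    def test_constant_patterns_become_zero(self):
        schedule = two_block_session()
        pre = bm.PreprocessedSession(
            data=np.full((3, 20), 7.0), session_id=0, lag_trs=0, tr_seconds=2.0,
            grid_shape=(3, 1, 1), flagged_voxels=np.array([]),
        )
        cfg = bm.DecodeConfig(lag_trs=0)
        patterns = block_averages(pre, schedule, np.arange(3), bm.FACE_CONDITIONS, cfg)
        out = subtract_condition_means(patterns)
        np.testing.assert_allclose(out.patterns, 0.0, atol=1e-12)

    def test_block_too_short(self):
        schedule = BlockSchedule(0, [Block("identity1", 0, 2), Block("identity2", 2, 2)])
        pre = bm.PreprocessedSession(
            data=np.zeros((1, 10)), session_id=0, lag_trs=0, tr_seconds=2.0,
            grid_shape=(1, 1, 1), flagged_voxels=np.array([]),
        )
        with pytest.raises(DesignError, match="discard"):
            block_averages(pre, schedule, np.arange(1), bm.FACE_CONDITIONS, bm.DecodeConfig(lag_trs=0))

    def test_missing_class_rejected(self, subject_factory):
        runs, schedules, _, mask = subject_factory(seed=3)
        cfg = bm.DecodeConfig()
        pre = bm.preprocess_session(runs[0], cfg)
        with pytest.raises(DesignError, match="absent"):
            bm.extract_block_patterns(pre, schedules[0], mask, ["nope"], cfg)


def synthetic_patterns(n_sessions=5, n_per_class=5, n_vox=8, separation=0.0, seed=0):
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=n_vox)
    direction /= np.linalg.norm(direction)
    patterns, labels, sids = [], [], []
    for s in range(n_sessions):
        for cond, sign in zip(bm.FACE_CONDITIONS, (1.0, -1.0)):
            for _ in range(n_per_class):
                patterns.append(rng.normal(size=n_vox) + sign * separation * direction)
                labels.append(cond)
                sids.append(s)
    return PatternSet(
        patterns=np.array(patterns),
        labels=np.array(labels),
        session_ids=np.array(sids),
        n_trs_averaged=6,
    )


class TestLOSODecode:
    def test_fold_structure(self):
        ps = synthetic_patterns(n_sessions=5)
        acc, folds = bm.loso_decode(ps, bm.DecodeConfig())
        assert folds == 5
        # 10 test patterns per fold, 5 per class
        for sid in range(5):
            sel = ps.session_ids == sid
            assert sel.sum() == 10
            assert (ps.labels[sel] == "identity1").sum() == 5

    def test_separable_classes_perfect(self):
        ps = synthetic_patterns(separation=50.0, seed=1)
        acc, _ = bm.loso_decode(ps, bm.DecodeConfig())
        assert acc == 1.0

    def test_permutation_null_near_chance(self):
        # oracle: permutation-null simulation (labels shuffled within session)
        rng = np.random.default_rng(5)
        accs = []
        for seed in range(500):
            ps = synthetic_patterns(n_sessions=3, n_per_class=3, n_vox=4, seed=seed)
            for sid in np.unique(ps.session_ids):
                sel = np.nonzero(ps.session_ids == sid)[0]
                ps.labels[sel] = ps.labels[sel][rng.permutation(len(sel))]
            try:
                acc, _ = bm.loso_decode(ps, bm.DecodeConfig())
            except DesignError:
                continue  # a session lost one class entirely
            accs.append(acc)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) <= max(3 * se, 0.02)

    def test_missing_class_in_session_named(self):
        ps = synthetic_patterns(n_sessions=3)
        ps.labels[ps.session_ids == 1] = "identity1"
        with pytest.raises(DesignError, match="session 1"):
            bm.loso_decode(ps, bm.DecodeConfig())

    def test_two_sessions_minimum(self):
        ps = synthetic_patterns(n_sessions=1)
        with pytest.raises(DesignError, match="2 sessions"):
            bm.loso_decode(ps, bm.DecodeConfig())

    def test_session_offset_invariance(self):
        # a scalar offset on one session's raw patterns vanishes after
        # per-condition mean subtraction, so accuracy is unchanged
        ps = synthetic_patterns(separation=0.8, seed=3)
        cfg = bm.DecodeConfig()
        base = subtract_condition_means(ps)
        acc0, _ = bm.loso_decode(base, cfg)
        shifted = PatternSet(
            ps.patterns.copy(), ps.labels.copy(), ps.session_ids.copy(), 6
        )
        shifted.patterns[shifted.session_ids == 2] += 123.0
        acc1, _ = bm.loso_decode(subtract_condition_means(shifted), cfg)
        assert acc0 == acc1


class TestLeakageIsolation:
    def test_other_sessions_do_not_affect_patterns(self, subject_factory):
        runs, schedules, _, mask = subject_factory(seed=4)
        cfg = bm.DecodeConfig()
        pre1 = bm.preprocess_session(runs[1], cfg)
        before = bm.extract_block_patterns(pre1, schedules[1], mask, bm.FACE_CONDITIONS, cfg)
        runs[2].data[:] += 1e6  # corrupt a different session
        pre1b = bm.preprocess_session(runs[1], cfg)
        after = bm.extract_block_patterns(pre1b, schedules[1], mask, bm.FACE_CONDITIONS, cfg)
        np.testing.assert_array_equal(before.patterns, after.patterns)

    def test_concat_requires_consistent_provenance(self):
        a = synthetic_patterns(n_sessions=2)
        b = synthetic_patterns(n_sessions=2)
        b.n_trs_averaged = 5
        with pytest.raises(ValueError, match="n_trs_averaged"):
            concat_pattern_sets([a, b])
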