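import numpy as np
import pytest

import blockmvpa as bm


@pytest.fixture
def params():
    return bm.DesignParams()


@pytest.fixture
def schedule(params):
    return bm.generate_session_schedule(params, seed=1)


@pytest.fixture
def subject_factory():
    """Factory for small simulated subjects with a known coding region."""

    def make(
        identity_effect=0.0,
        noise_sd=1.0,
        n_sessions=5,
        seed=0,
        grid=(6, 6, 5),
        region_corner=(1, 1, 1),
        region_shape=(3, 3, 2),
        **synth_kw,
    ):
        dparams = bm.DesignParams()
        seq = np.random.SeedSequence(seed)
        dseq, sseq = seq.spawn(2)
        schedules = [
            bm.generate_session_schedule(dparams, int(s), session_id=i)
            for i, s in enumerate(dseq.generate_state(n_sessions))
        ]
        region = bm.cube_region(
            "region", region_corner, region_shape, identity_effect=identity_effect
        )
        synth = bm.SynthParams(
            grid_shape=grid,
            regions=(region,),
            noise_sd=noise_sd,
            n_sessions=n_sessions,
            seed=int(sseq.generate_state(1)[0]),
            **synth_kw,
        )
        runs, truths = bm.simulate_subject(synth, schedules)
        mask = bm.ROIMask(
            name="truth",
            coords=truths[0].coords,
            stats=np.zeros(len(truths[0].coords)),
            peak=tuple(truths[0].coords[0]),
        )
        return runs, schedules, truths, mask

    return make


def truth_roi_accuracy(make, identity_effect, noise_sd, n_subjects, seed0):
    """Mean LOSO accuracy over subjects, decoding in the ground-truth region."""
    cfg = bm.DecodeConfig()
    accs = []
    for i in range(n_subjects):
        runs, schedules, _, mask = make(
            identity_effect=identity_effect, noise_sd=noise_sd, seed=seed0 + i
        )
        patterns = bm.build_patterns(runs[1:], schedules[1:], mask, cfg)
        acc, _ = bm.loso_decode(patterns, cfg)
        accs.append(acc)
    return np.asarray(accs)
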