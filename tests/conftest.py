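"""Shared fixtures.

The two expensive artifacts — the contrastively pre-trained backbone and
the leave-one-participant-out evaluation — are computed once per session
and shared between the behavioral tests and the acceptance suite.
"""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from vidspo2.contrastive import mean_reference_similarity, train_stage1, train_stage2  # noqa: E402
from vidspo2.data import roi_clip
from vidspo2.rppg_net import RppgEstimator, RppgEstimatorConfig, forward
from vidspo2.signalcore import Waveform, compute_psd
from vidspo2.train_eval import (ExperimentConfig, leave_one_out,
                                make_pretrain_cohort, make_subjects)


@pytest.fixture(scope="session")
def desk_cfg():
    """The desk-scale experiment profile used across the suite."""
    return ExperimentConfig(seed=7)


@pytest.fixture(scope="session")
def backbone_run(desk_cfg):
    """Stages 1-2 on the auxiliary cohort (8 subjects, T=60, 20+20 epochs),
    with diagnostics on a held-out subject recorded along the way."""
    cfg = desk_cfg
    cohort = make_pretrain_cohort(cfg)
    held = make_subjects(cfg, condition="stable", seed_offset=123457,
                         n_subjects=1, id_prefix="h")[0]
    est = RppgEstimator(RppgEstimatorConfig(
        input_size=cfg.frame_size, width_mult=cfg.width_mult, seed=cfg.seed))
    sc1 = cfg.stage_config("stage1")
    sc2 = cfg.stage_config("stage2", seed_offset=1)
    sim_init = mean_reference_similarity(est, [held], sc1)
    hist1 = train_stage1(est, cohort, sc1)
    sim_stage1 = mean_reference_similarity(est, [held], sc1)
    hist2 = train_stage2(est, cohort, sc2)
    sim_stage2 = mean_reference_similarity(est, [held], sc2)

    roi = roi_clip(held.face_clip, held.face_bbox, cfg.frame_size)
    pred = forward(est, roi)
    cm = pred.channel_mean()
    psd = compute_psd(Waveform(cm - cm.mean(), roi.rate))
    return {
        "cfg": cfg,
        "estimator": est,
        "cohort": cohort,
        "held": held,
        "hist1": hist1,
        "hist2": hist2,
        "sims": (sim_init, sim_stage1, sim_stage2),
        "heldout_peak_hz": psd.peak_freq,
        "heldout_hr_hz": held.meta.hr_bpm / 60.0,
        "heldout_bin_hz": 1.0 / roi.n_frames * roi.rate,
    }


@pytest.fixture(scope="session")
def loso_run(desk_cfg, backbone_run):
    """Leave-one-participant-out reports for the full model and the
    end-to-end baseline arm, on identical subjects, folds and seeds."""
    cfg = desk_cfg
    subjects = make_subjects(cfg)
    full = leave_one_out(subjects, cfg, variant="full",
                         backbone=backbone_run["estimator"])
    baseline = leave_one_out(subjects, cfg, variant="baseline")
    return {"cfg": cfg, "subjects": subjects, "full": full,
            "baseline": baseline, "backbone": backbone_run["estimator"]}


@pytest.fixture(scope="session")
def tiny_cfg():
    """A micro profile for smoke tests of orchestration code paths."""
    return ExperimentConfig(
        seed=11, n_subjects=3, duration_s=6.0, windows_per_subject=2,
        pretrain_subjects=2, stage1_epochs=1, stage2_epochs=1,
        stage3_epochs=10, e2e_epochs=1, window_frames=60,
        eval_windows_per_subject=2)
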