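"""Experiment orchestration: staged training, leave-one-participant-out
evaluation, ablation arms, and per-condition robustness suites.

The published schedule is three stages — contrastive pre-training (lr 1e-3,
300 epochs), supervised rPPG fine-tuning (lr 1e-4, 200 epochs), and frozen-
backbone end-to-end SpO2 training (lr 5e-3, 50 epochs).  The desk-scale
profile keeps the learning rates and shrinks problem sizes (32x32 ROIs,
width multiplier 0.5, epochs (8, 8, 60), a handful of windows per subject)
so a full leave-one-out experiment runs on one CPU; docs/methods.md
discusses the choice.

Evaluation is leave-one-participant-out: every subject is the test fold
exactly once, no test-subject frames enter any training stage of its fold,
and per-fold MAE / RMSE / Pearson are aggregated as median and IQR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .contrastive import StageConfig, train_stage1, train_stage2
from .data import build_windows
from .exceptions import ConfigError, LeakageError
from .rppg_net import RppgEstimator, RppgEstimatorConfig
from .spo2_head import (
    MFAM,
    CnnBiLstm,
    Fusion,
    GenericLstmHead,
    Spo2Model,
    predict_windows,
    train_end_to_end,
    train_stage3,
)
from .signalcore import metrics
from .synthetic import SceneConfig, SyntheticSample, dip_trace, generate

__all__ = [
    "FULL_SCALE_SCHEDULE",
    "ABLATION_VARIANTS",
    "ExperimentConfig",
    "EvalReport",
    "make_subjects",
    "build_variant",
    "train_variant",
    "fold_splits",
    "leave_one_out",
    "run_ablation",
    "condition_suite",
]

#: The published three-stage schedule (lr, epochs); the desk profile keeps
#: the learning rates and overrides the epoch counts.
FULL_SCALE_SCHEDULE = {
    "stage1": (1e-3, 300),
    "stage2": (1e-4, 200),
    "stage3": (5e-3, 50),
}

ABLATION_VARIANTS = ("baseline", "proposed-backbone", "+contrastive", "+mfam", "full")

_CONDITIONS = {
    "stable": {"lighting_amp": 0.0, "rotation_deg": 0.0},
    "lighting": {"lighting_amp": 0.10, "rotation_deg": 0.0},
    "rotation": {"lighting_amp": 0.0, "rotation_deg": 5.0},
}


@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale experiment profile.

    Contrastive pre-training and rPPG fine-tuning (stages 1-2) run once on
    a separate auxiliary cohort — the stand-in for the external unlabeled /
    PPG-labeled corpora — so the shared backbone never sees any
    leave-one-out subject; only the SpO2 stage (and the end-to-end
    ablation arms) trains per fold.
    """

    n_subjects: int = 6
    duration_s: float = 16.0
    frame_size: int = 16
    window_frames: int = 60
    width_mult: float = 0.25
    windows_per_subject: int = 3
    eval_windows_per_subject: int | None = None     # None = all windows
    condition: str = "stable"
    variant: str = "full"
    seed: int = 0
    pretrain_subjects: int = 8
    pretrain_windows_per_subject: int = 1
    stage1_epochs: int = 20
    stage2_epochs: int = 20
    stage3_epochs: int = 250
    e2e_epochs: int = 10
    batch_size: int = 8
    stage3_batch: int = 4
    head_conv: tuple = (16, 32)
    head_hidden: int = 32

    def __post_init__(self):
        if self.variant not in ABLATION_VARIANTS:
            raise ConfigError(f"unknown ablation variant {self.variant!r}; "
                              f"choose from {ABLATION_VARIANTS}")
        if self.condition not in _CONDITIONS:
            raise ConfigError(f"unknown condition {self.condition!r}")

    def stage_config(self, stage: str, seed_offset: int = 0) -> StageConfig:
        lr, _ = FULL_SCALE_SCHEDULE[stage]
        epochs = {"stage1": self.stage1_epochs, "stage2": self.stage2_epochs,
                  "stage3": self.stage3_epochs}[stage]
        wps = (self.pretrain_windows_per_subject if stage in ("stage1", "stage2")
               else self.windows_per_subject)
        bs = self.stage3_batch if stage == "stage3" else self.batch_size
        return StageConfig(lr=lr, epochs=epochs, seed=self.seed + seed_offset,
                           batch_size=bs,
                           window_frames=self.window_frames,
                           windows_per_subject=wps)


@dataclass
class EvalReport:
    """Per-subject metrics with median/IQR aggregation."""

    per_subject: pd.DataFrame
    condition: str = "stable"

    def median(self, metric: str) -> float:
        return float(self.per_subject[metric].median())

    def iqr(self, metric: str) -> float:
        q = self.per_subject[metric].quantile([0.25, 0.75])
        return float(q.loc[0.75] - q.loc[0.25])

    def summary(self) -> pd.DataFrame:
        rows = []
        for metric in ("mae", "rmse", "pearson"):
            rows.append({"metric": metric, "median": self.median(metric),
                         "iqr": self.iqr(metric)})
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# synthetic cohorts
# ----------------------------------------------------------------------

def make_subjects(cfg: ExperimentConfig, condition: str | None = None,
                  seed_offset: int = 0, n_subjects: int | None = None,
                  id_prefix: str = "s") -> list[SyntheticSample]:
    """A cohort of synthetic participants with individual physiology.

    Heart rate, baseline SpO2 and a breath-hold-like desaturation dip vary
    per subject, so a global-mean predictor is meaningfully imperfect.
    """
    condition = condition or cfg.condition
    knobs = _CONDITIONS[condition]
    subjects = []
    for i in range(n_subjects if n_subjects is not None else cfg.n_subjects):
        rng = np.random.default_rng(cfg.seed + seed_offset + 7919 * i)
        hr = float(rng.uniform(60.0, 90.0))
        base = float(rng.uniform(95.0, 99.0))
        depth = float(rng.uniform(1.5, 3.5))
        center = float(rng.uniform(0.35, 0.65) * cfg.duration_s)
        trace = dip_trace(cfg.duration_s, base, depth, center,
                          width_s=cfg.duration_s / 6.0)
        scene = SceneConfig(
            duration_s=cfg.duration_s, size=cfg.frame_size, hr_bpm=hr,
            spo2_trace=trace, seed=int(cfg.seed + seed_offset + 104729 * i) % (2**31),
            structure_seed=i, **knobs,
        )
        subjects.append(generate(scene, subject_id=f"{id_prefix}{i}"))
    return subjects


def make_pretrain_cohort(cfg: ExperimentConfig) -> list[SyntheticSample]:
    """The auxiliary cohort used only for stages 1-2 (never evaluated)."""
    return make_subjects(cfg, condition="stable", seed_offset=90001,
                         n_subjects=cfg.pretrain_subjects, id_prefix="p")


def pretrain_backbone(cfg: ExperimentConfig,
                      cohort: list[SyntheticSample] | None = None,
                      ) -> RppgEstimator:
    """Stages 1-2 on the auxiliary cohort; returns the trained estimator."""
    cohort = cohort or make_pretrain_cohort(cfg)
    est = RppgEstimator(RppgEstimatorConfig(
        input_size=cfg.frame_size, width_mult=cfg.width_mult, seed=cfg.seed))
    train_stage1(est, cohort, cfg.stage_config("stage1"))
    train_stage2(est, cohort, cfg.stage_config("stage2", seed_offset=1))
    return est


# ----------------------------------------------------------------------
# model variants
# ----------------------------------------------------------------------

def needs_pretraining(variant: str) -> bool:
    return variant in ("+contrastive", "full")


def build_variant(variant: str, cfg: ExperimentConfig, seed: int,
                  backbone: RppgEstimator | None = None) -> Spo2Model:
    if variant not in ABLATION_VARIANTS:
        raise ConfigError(f"unknown ablation variant {variant!r}")
    est = RppgEstimator(RppgEstimatorConfig(
        input_size=cfg.frame_size, width_mult=cfg.width_mult, seed=seed))
    if backbone is not None:
        est.load_state_dict(backbone.state_dict())
    rng = np.random.default_rng(seed + 1)
    deep_head = variant in ("proposed-backbone", "full")
    head = (CnnBiLstm(conv_channels=tuple(cfg.head_conv),
                      hidden=cfg.head_hidden, rng=rng) if deep_head
            else GenericLstmHead(hidden=cfg.head_hidden, rng=rng))
    with_mfam = variant in ("+mfam", "full")
    mfam = MFAM(rng=np.random.default_rng(seed + 2)) if with_mfam else None
    return Spo2Model(est, head, mfam=mfam, fusion=Fusion() if with_mfam else None)


def train_variant(variant: str, train_samples: list[SyntheticSample],
                  cfg: ExperimentConfig, seed: int,
                  backbone: RppgEstimator | None = None) -> Spo2Model:
    """Train one ablation arm on the given subjects.

    Pre-trained variants receive the shared stage-1/2 backbone (trained on
    the auxiliary cohort) and only fit the SpO2 stage here; the other arms
    train end-to-end from scratch.
    """
    if needs_pretraining(variant):
        if backbone is None:
            backbone = pretrain_backbone(cfg)
        model = build_variant(variant, cfg, seed, backbone=backbone)
        train_stage3(model, train_samples, cfg.stage_config("stage3", 2 + seed))
    else:
        model = build_variant(variant, cfg, seed)
        e2e = replace(cfg.stage_config("stage3", 2 + seed), epochs=cfg.e2e_epochs)
        train_end_to_end(model, train_samples, e2e)
    return model


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def fold_splits(subject_ids: list[str], seed: int) -> list[tuple[str, list[str]]]:
    """Deterministic leave-one-out folds: a function of (ids, seed) only."""
    order = sorted(subject_ids)
    rng = np.random.default_rng(seed)
    order = [order[i] for i in rng.permutation(len(order))]
    return [(sid, [t for t in order if t != sid]) for sid in order]


def _eval_windows(sample: SyntheticSample, cfg: ExperimentConfig):
    return build_windows(sample, cfg.window_frames,
                         max_windows=cfg.eval_windows_per_subject)


def leave_one_out(subjects: list[SyntheticSample], cfg: ExperimentConfig,
                  variant: str | None = None,
                  backbone: RppgEstimator | None = None) -> EvalReport:
    """Leave-one-participant-out evaluation of one ablation arm.

    For pre-trained variants the shared auxiliary-cohort backbone (which
    has never seen any of ``subjects``) is reused across folds; per-fold
    training therefore touches only the fold's training subjects.
    """
    variant = variant or cfg.variant
    by_id = {s.subject_id: s for s in subjects}
    if len(by_id) != len(subjects):
        raise LeakageError("duplicate subject ids in cohort")
    if needs_pretraining(variant) and backbone is None:
        backbone = pretrain_backbone(cfg)
    rows = []
    for fold, (test_id, train_ids) in enumerate(fold_splits(list(by_id), cfg.seed)):
        if test_id in train_ids:
            raise LeakageError(f"subject {test_id} leaked into its own training fold")
        train = [by_id[t] for t in train_ids]
        model = train_variant(variant, train, cfg, seed=cfg.seed + fold,
                              backbone=backbone)
        test_windows = _eval_windows(by_id[test_id], cfg)
        preds = predict_windows(model, test_windows)
        labels = np.array([w.label for w in test_windows])
        train_mean = float(np.mean([w.label for s in train
                                    for w in _eval_windows(s, cfg)]))
        row = {"subject": test_id, **metrics(preds, labels),
               "baseline_mae": float(np.abs(labels - train_mean).mean())}
        rows.append(row)
    return EvalReport(pd.DataFrame(rows), condition=cfg.condition)


def run_ablation(subjects: list[SyntheticSample], variants,
                 cfg: ExperimentConfig,
                 backbone: RppgEstimator | None = None) -> pd.DataFrame:
    """One report per variant on identical folds, data, and seeds."""
    if backbone is None and any(needs_pretraining(v) for v in variants):
        backbone = pretrain_backbone(cfg)
    rows = []
    for variant in variants:
        report = leave_one_out(subjects, cfg, variant=variant, backbone=backbone)
        rows.append({
            "variant": variant,
            "mae_median": report.median("mae"), "mae_iqr": report.iqr("mae"),
            "rmse_median": report.median("rmse"), "rmse_iqr": report.iqr("rmse"),
            "pearson_median": report.median("pearson"),
            "pearson_iqr": report.iqr("pearson"),
        })
    return pd.DataFrame(rows)


def condition_suite(cfg: ExperimentConfig, model: Spo2Model | None = None,
                    backbone: RppgEstimator | None = None,
                    ) -> dict[str, EvalReport]:
    """Train once on stable data, evaluate on the three test conditions."""
    if model is None:
        train = make_subjects(replace(cfg, condition="stable"))
        model = train_variant(cfg.variant, train, cfg, seed=cfg.seed,
                              backbone=backbone)
    reports = {}
    for condition in _CONDITIONS:
        test_cfg = replace(cfg, condition=condition)
        test_subjects = make_subjects(test_cfg, condition=condition,
                                      seed_offset=50021)
        rows = []
        for s in test_subjects:
            windows = _eval_windows(s, cfg)
            preds = predict_windows(model, windows)
            labels = np.array([w.label for w in windows])
            rows.append({"subject": s.subject_id, **metrics(preds, labels)})
        reports[condition] = EvalReport(pd.DataFrame(rows), condition=condition)
    return reports
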