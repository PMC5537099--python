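"""End-to-end orchestration: cohorts, sweeps, and the full inference chain.

Two harnesses mirror the published experiments at phantom scale: a
five-way architecture comparison (FCN-32s .. FCN-2s against the HU
thresholding baseline, all at window (40, 400) and 8 bits) and a window/
bit-depth sweep of the best architecture over the seven published window
settings at 8, 6 and 4 bits.  Both consume one seeded phantom cohort and
emit tidy pandas tables; every row records the cohort content hash, so
shared inputs across sweep cells are verifiable after the fact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcn import (
    FCNConfig,
    FCNNet,
    TrainConfig,
    TrainedModel,
    build_fcn,
    muscle_mask,
    predict,
    train,
)
from .metrics import MetricsReport, csa_error, dsc, evaluate_masks
from .phantom import (
    HUImage,
    PhantomSample,
    PhantomSpec,
    generate_cohort,
    stratified_split,
)
from .threshold import BinaryMask, ThresholdRanges, remove_intramuscular_fat, threshold_segment
from .windowing import SWEEP_WINDOW_SETTINGS, WindowConfig, hu_to_gray, sweep_grid

__all__ = [
    "DEFAULT_STRATA",
    "ExperimentConfig",
    "run_architecture_sweep",
    "run_window_sweep",
    "full_pipeline",
]

#: Habitus strata standing in for BMI categories (normal/overweight/obese).
DEFAULT_STRATA: dict[str, tuple[float, float]] = {
    "normal": (0.85, 1.0),
    "overweight": (1.0, 1.15),
    "obese": (1.15, 1.3),
}


@dataclass(frozen=True)
class ExperimentConfig:
    """One sweep's worth of reproducible settings.

    ``n_test`` must be divisible by the number of strata so the held-out
    set stays balanced.  Every random choice descends from ``cohort_seed``
    and ``train.seed``.
    """

    cohort_seed: int = 11
    n_train: int = 60
    n_test: int = 30
    architectures: tuple[int, ...] = (32, 16, 8, 4, 2)
    window: WindowConfig = WindowConfig(40, 400, 8)
    window_grid: tuple[WindowConfig, ...] = tuple(sweep_grid())
    train: TrainConfig = TrainConfig()
    phantom: PhantomSpec = PhantomSpec()
    strata: tuple[tuple[str, tuple[float, float]], ...] = tuple(DEFAULT_STRATA.items())
    threshold_ranges: ThresholdRanges = ThresholdRanges()
    base_channels: int = 8

    def validate(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("n_train and n_test must be >= 1")
        if not self.architectures:
            raise ValueError("architectures must be non-empty")
        if self.n_test % len(self.strata):
            raise ValueError("n_test must be divisible by the number of strata")

    def make_cohort(self) -> tuple[list[PhantomSample], list[PhantomSample]]:
        """Generate the seeded cohort and its balanced train/test split."""
        self.validate()
        cohort = generate_cohort(
            dict(self.strata),
            self.n_train + self.n_test,
            self.cohort_seed,
            base_spec=self.phantom,
        )
        return stratified_split(
            cohort, self.n_test // len(self.strata), self.cohort_seed
        )


def _cohort_hash(samples) -> str:
    h = hashlib.sha256()
    for s in samples:
        h.update(np.ascontiguousarray(s.image.values).tobytes())
        h.update(np.ascontiguousarray(s.labels.classes).tobytes())
    return h.hexdigest()[:16]


def _evaluate(
    model: TrainedModel,
    test: list[PhantomSample],
    window: WindowConfig,
    ranges: ThresholdRanges,
) -> pd.DataFrame:
    rows = []
    for s in test:
        raw = muscle_mask(predict(model, hu_to_gray(s.image, window)),
                          s.image.pixel_spacing)
        post = remove_intramuscular_fat(raw, s.image, ranges)
        gt = muscle_mask(s.labels, s.image.pixel_spacing)
        rows.append(
            {
                "dsc_raw": dsc(gt, raw),
                "dsc": dsc(gt, post),
                "csa_error_pct_raw": csa_error(gt, raw),
                "csa_error_pct": csa_error(gt, post),
            }
        )
    return pd.DataFrame(rows)


def _train_cell(
    cfg: ExperimentConfig,
    trainset: list[PhantomSample],
    window: WindowConfig,
    stride: int,
) -> TrainedModel:
    net = build_fcn(
        FCNConfig(fusion_stride=stride, base_channels=cfg.base_channels),
        seed=cfg.train.seed,
    )
    pairs = [(hu_to_gray(s.image, window), s.labels) for s in trainset]
    return train(net, pairs, cfg.train)


def run_architecture_sweep(cfg: ExperimentConfig) -> pd.DataFrame:
    """Train each requested fusion stride on one cohort; include baseline.

    Returns one row per architecture plus an untrained ``threshold``
    baseline row, with mean/SD of post-processed DSC and CSA error on the
    held-out set.
    """
    trainset, test = cfg.make_cohort()
    chash = _cohort_hash(trainset) + "/" + _cohort_hash(test)
    rows = []
    # baseline: HU-interval segmentation of the raw HU image, no training
    base = [
        {
            "dsc": dsc(
                muscle_mask(s.labels),
                threshold_segment(s.image, *cfg.threshold_ranges.muscle),
            ),
            "csa_error_pct": csa_error(
                muscle_mask(s.labels),
                threshold_segment(s.image, *cfg.threshold_ranges.muscle),
            ),
        }
        for s in test
    ]
    bdf = pd.DataFrame(base)
    rows.append(
        {
            "model": "threshold",
            "dsc_mean": bdf["dsc"].mean(),
            "dsc_sd": bdf["dsc"].std(ddof=1),
            "csa_error_mean": bdf["csa_error_pct"].mean(),
            "csa_error_sd": bdf["csa_error_pct"].std(ddof=1),
            "final_loss": np.nan,
            "cohort_hash": chash,
        }
    )
    for stride in cfg.architectures:
        model = _train_cell(cfg, trainset, cfg.window, stride)
        ev = _evaluate(model, test, cfg.window, cfg.threshold_ranges)
        rows.append(
            {
                "model": f"fcn{stride}s",
                "dsc_mean": ev["dsc"].mean(),
                "dsc_sd": ev["dsc"].std(ddof=1),
                "csa_error_mean": ev["csa_error_pct"].mean(),
                "csa_error_sd": ev["csa_error_pct"].std(ddof=1),
                "final_loss": model.loss_history[-1],
                "cohort_hash": chash,
            }
        )
    return pd.DataFrame(rows)


def run_window_sweep(cfg: ExperimentConfig, fusion_stride: int = 2) -> pd.DataFrame:
    """Train the chosen architecture once per window/bit cell.

    The same underlying HU cohort feeds every cell (only the grayscale
    conversion differs); each row records with- and without-post-processing
    metrics and the shared cohort hash.
    """
    trainset, test = cfg.make_cohort()
    chash = _cohort_hash(trainset) + "/" + _cohort_hash(test)
    rows = []
    for window in cfg.window_grid:
        model = _train_cell(cfg, trainset, window, fusion_stride)
        ev = _evaluate(model, test, window, cfg.threshold_ranges)
        rows.append(
            {
                "wl": window.wl,
                "ww": window.ww,
                "bit": window.bit,
                "dsc_mean": ev["dsc"].mean(),
                "dsc_sd": ev["dsc"].std(ddof=1),
                "dsc_raw_mean": ev["dsc_raw"].mean(),
                "csa_error_mean": ev["csa_error_pct"].mean(),
                "csa_error_raw_mean": ev["csa_error_pct_raw"].mean(),
                "final_loss": model.loss_history[-1],
                "cohort_hash": chash,
            }
        )
    return pd.DataFrame(rows)


def full_pipeline(
    img: HUImage,
    model: TrainedModel | FCNNet,
    window: WindowConfig,
    ranges: ThresholdRanges | None = None,
    ground_truth=None,
) -> tuple[BinaryMask, MetricsReport | None]:
    """Window -> segment -> muscle mask -> fat removal (-> metrics).

    The deployment chain for one slice.  Metrics are attached only when a
    ground-truth label map (or muscle mask) is supplied.
    """
    ranges = ranges if ranges is not None else ThresholdRanges()
    gray = hu_to_gray(img, window)
    labels = predict(model, gray)
    raw = muscle_mask(labels, img.pixel_spacing)
    post = remove_intramuscular_fat(raw, img, ranges)
    report = None
    if ground_truth is not None:
        gt = (
            muscle_mask(ground_truth, img.pixel_spacing)
            if not isinstance(ground_truth, BinaryMask)
            else ground_truth
        )
        report = evaluate_masks(gt, post, pixel_spacing=img.pixel_spacing)
    return post, report
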