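"""Multi-center leave-one-center-out cross-validation and reporting.

Folds are defined by acquisition center: each fold tests on one center and
trains on all others (with a center-stratified 20% validation split inside
the training pool).  The proposed network, the standard U-Net baseline and
the fixed-threshold T40 baseline are evaluated on identical case lists;
fold means are aggregated into a cross-fold average as the unweighted mean
over folds.  Stratified analyses group cases into rank-based deciles of
tumor volume or contrast; outliers are flagged per fold by the boxplot rule
(DSC below Q1 - 1.5 IQR); paired methods are compared with Wilcoxon
signed-rank and Kolmogorov-Smirnov tests at alpha = 0.05.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .augmentation import AugmentConfig
from .grids import BinaryMask3D
from .inference import binarize, predict_volume
from .nn.network import ModelConfig, build_model
from .objectives import (
    case_metrics,
    operational_contrast,
    t40_search_region,
    t40_segment,
)
from .phantom import PatientCase
from .preprocessing import COMMON_SPACING, resample_mask, resample_volume, znormalize
from .training import TrainConfig, split_train_val, train

METRICS = ("dsc", "precision", "recall")


# ---------------------------------------------------------------------------
# preprocessing of whole cohorts


def preprocess_case(case: PatientCase, spacing=COMMON_SPACING) -> PatientCase:
    """Resample a case to the common grid and Z-score normalize the volume.

    The raw (un-normalized) resampled intensities are kept in provenance as
    ``raw_values`` so intensity-based baselines (T40) and contrast
    statistics see physical uptake rather than Z-scores.
    """
    vol = resample_volume(case.volume, spacing)
    truth = resample_mask(case.truth, spacing, out_shape=vol.shape)
    bladder = resample_mask(case.bladder, spacing, out_shape=vol.shape)
    normed = znormalize(vol)
    prov = dict(case.provenance)
    prov["native_spacing"] = tuple(case.volume.spacing)
    prov["native_shape"] = tuple(case.volume.shape)
    prov["raw_values"] = vol.values
    return PatientCase(normed, truth, bladder, case.center, case.case_id, prov)


def preprocess_cohort(cases: list[PatientCase], spacing=COMMON_SPACING) -> list[PatientCase]:
    return [preprocess_case(c, spacing) for c in cases]


# ---------------------------------------------------------------------------
# folds


@dataclass
class Fold:
    test_center: str
    train_cases: list[PatientCase]
    test_cases: list[PatientCase]


def make_folds(cases: list[PatientCase]) -> list[Fold]:
    """One fold per center; train pool = every other center."""
    centers = sorted({c.center for c in cases})
    if len(centers) < 2:
        raise ValueError("leave-one-center-out needs at least 2 centers")
    folds = []
    for center in centers:
        test = [c for c in cases if c.center == center]
        trainp = [c for c in cases if c.center != center]
        folds.append(Fold(center, trainp, test))
    return folds


@dataclass
class FoldReport:
    """Per-fold evaluation of all methods on the held-out center."""

    test_center: str
    n_train: int
    n_val: int
    n_test: int
    cases: pd.DataFrame  # one row per (method, case)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of each metric per method over the fold's cases."""
        return self.cases.groupby("method")[list(METRICS)].agg(["mean", "std"])

    def mean(self, method: str, metric: str) -> float:
        sel = self.cases[self.cases["method"] == method]
        return float(sel[metric].mean())


def _evaluate_case(pred: BinaryMask3D, case: PatientCase, method: str) -> dict:
    raw = case.provenance.get("raw_values")
    contrast = case.provenance.get("contrast", float("nan"))
    if raw is not None:
        from .grids import Volume3D

        contrast = operational_contrast(
            Volume3D(raw, case.volume.spacing), case.truth, case.bladder
        )
    m = case_metrics(
        pred, case.truth, spacing=case.truth.spacing,
        contrast=contrast, case_id=case.case_id, center=case.center,
    )
    overlap = int((pred.astype_bool() & case.bladder.astype_bool()).sum())
    row = dataclasses.asdict(m)
    row.update({"method": method, "bladder_overlap": overlap})
    return row


def _predict_cnn(model, case: PatientCase, patch_size) -> BinaryMask3D:
    prob = predict_volume(model, case.volume, patch_size)
    return binarize(prob, 0.5, spacing=case.volume.spacing)


def _t40_predict(case: PatientCase) -> BinaryMask3D:
    from .grids import Volume3D

    raw = case.provenance.get("raw_values", case.volume.values)
    vol = Volume3D(np.asarray(raw), case.volume.spacing)
    region = t40_search_region(case.truth, dilate_voxels=2)
    return t40_segment(vol, region)


def run_cv(
    cases: list[PatientCase],
    model_config: ModelConfig,
    train_cfg: TrainConfig,
    aug_cfg: AugmentConfig | None = None,
    *,
    methods=("proposed", "stdunet", "t40"),
) -> list[FoldReport]:
    """Leave-one-center-out cross-validation of the configured methods.

    CNN methods are trained from scratch per fold with identical seeds and
    configs (only the architecture differs); all methods are evaluated on
    the identical held-out case list.  Cases must be preprocessed
    (:func:`preprocess_cohort`).
    """
    reports = []
    for fold in make_folds(cases):
        tr, val = split_train_val(
            fold.train_cases, train_cfg.validation_fraction, train_cfg.seed
        )
        test_ids = {c.case_id for c in fold.test_cases}
        assert not test_ids & {c.case_id for c in tr + val}, "test leakage"
        rows = []
        for method in methods:
            if method == "t40":
                preds = [_t40_predict(c) for c in fold.test_cases]
            else:
                arch = "res-scse" if method == "proposed" else "std"
                cfg = replace(model_config, arch=arch)
                model = build_model(cfg)
                model, _ = train(model, tr, val, train_cfg, aug_cfg)
                preds = [
                    _predict_cnn(model, c, train_cfg.patch_size) for c in fold.test_cases
                ]
            for pred, case in zip(preds, fold.test_cases):
                rows.append(_evaluate_case(pred, case, method))
        reports.append(
            FoldReport(
                fold.test_center,
                len(tr),
                len(val),
                len(fold.test_cases),
                pd.DataFrame(rows),
            )
        )
    return reports


def summarize_cv(reports: list[FoldReport]) -> pd.DataFrame:
    """Cross-validation table: per-fold mean +/- SD for each method and
    metric, plus the cross-fold Average column (unweighted mean of the fold
    means, spread = SD over fold means)."""
    rows = []
    methods = sorted(reports[0].cases["method"].unique())
    for metric in METRICS:
        for method in methods:
            row = {"metric": metric, "method": method}
            fold_means = []
            for rep in reports:
                sel = rep.cases[rep.cases["method"] == method][metric]
                row[rep.test_center] = f"{sel.mean():.2f} +/- {sel.std(ddof=0):.2f}"
                fold_means.append(sel.mean())
            row["Average"] = (
                f"{np.mean(fold_means):.2f} +/- {np.std(fold_means, ddof=0):.2f}"
            )
            rows.append(row)
    return pd.DataFrame(rows)


def cross_fold_mean(reports: list[FoldReport], method: str, metric: str) -> float:
    """Unweighted mean over folds of the per-fold mean metric."""
    return float(np.mean([rep.mean(method, metric) for rep in reports]))


# ---------------------------------------------------------------------------
# stratified analyses


@dataclass
class StratifiedReport:
    by: str
    n_groups: int
    table: pd.DataFrame  # per-group means + boundaries


def stratify(case_df: pd.DataFrame, by: str = "truth_volume_cm3", n_groups: int = 10) -> StratifiedReport:
    """Rank-based decile grouping of per-case metrics by tumor volume or
    contrast (ties broken by case id); reduces the group count with a
    warning when there are fewer cases than groups."""
    import warnings

    if by not in case_df.columns:
        raise ValueError(f"unknown stratification variable {by!r}")
    df = case_df.sort_values([by, "case_id"], kind="mergesort").reset_index(drop=True)
    n = len(df)
    if n < n_groups:
        warnings.warn(f"only {n} cases; reducing group count from {n_groups} to {n}")
        n_groups = max(1, n)
    groups = np.array_split(np.arange(n), n_groups)
    rows = []
    for gi, idx in enumerate(groups):
        sub = df.iloc[idx]
        row = {"group": gi, "n": len(sub), "lo": sub[by].min(), "hi": sub[by].max()}
        for m in METRICS:
            row[m] = sub[m].mean()
        rows.append(row)
    return StratifiedReport(by, n_groups, pd.DataFrame(rows))


def flag_outliers(case_df: pd.DataFrame, metric: str = "dsc") -> pd.DataFrame:
    """Boxplot rule per fold: cases with ``metric`` below Q1 - 1.5 IQR."""
    if len(case_df) < 5:
        raise ValueError("need at least 5 cases for the boxplot rule")
    q1, q3 = np.percentile(case_df[metric], [25, 75])
    lo = q1 - 1.5 * (q3 - q1)
    out = case_df[case_df[metric] < lo].copy()
    out.attrs["rule"] = f"{metric} < Q1 - 1.5*IQR = {lo:.4f}"
    return out


def compare_methods(df_a: pd.DataFrame, df_b: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Paired Wilcoxon signed-rank plus two-sample KS per metric.

    The two frames must carry the same cases in the same order.  A fully
    degenerate pairing (all differences zero) is reported as no difference
    with p = 1.
    """
    if list(df_a["case_id"]) != list(df_b["case_id"]):
        raise ValueError("method case lists are not paired")
    rows = []
    for metric in METRICS:
        a = df_a[metric].to_numpy(dtype=float)
        b = df_b[metric].to_numpy(dtype=float)
        diffs = a - b
        if np.allclose(diffs, 0.0):
            w_p = 1.0
        else:
            w_p = float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)
        ks_p = float(stats.ks_2samp(a, b).pvalue)
        rows.append(
            {
                "metric": metric,
                "wilcoxon_p": w_p,
                "ks_p": ks_p,
                "significant": bool(w_p < alpha),
            }
        )
    return pd.DataFrame(rows)


def bladder_exclusion_rate(reports: list[FoldReport], method: str = "proposed") -> float:
    """Fraction of test cases whose predicted mask has zero overlap with the
    bladder mask."""
    rows = pd.concat([r.cases for r in reports])
    sel = rows[rows["method"] == method]
    return float((sel["bladder_overlap"] == 0).mean())
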