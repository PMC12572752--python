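"""Evaluation harness.

Speaker-independent stratified splits, train-parameter z-scoring, early
fusion, ROC/AUC, paired DeLong tests, Spearman/RMSE regression metrics,
and the within-/between-language protocols (the between-language protocol
is strictly 0-shot: no target-cohort row touches fitting or
normalization).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from speechmark.io_preprocess import CohortManifest
from speechmark.tree_sparse_mlp import fit_sparse_mlp, grid_search, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SplitPlan:
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int
    fraction: float = 0.8


@dataclass
class EvaluationReport:
    modality: str
    setting: str  # "within" | "between"
    auc: float = math.nan
    roc: list[tuple[float, float]] = field(default_factory=list)
    bootstrap_aucs: list[float] = field(default_factory=list)
    delong: dict = field(default_factory=dict)
    spearman_rho: float = math.nan
    rmse: float = math.nan
    best_spec: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "modality": self.modality,
            "setting": self.setting,
            "auc": self.auc,
            "bootstrap_auc_mean": float(np.mean(self.bootstrap_aucs))
            if self.bootstrap_aucs
            else math.nan,
            "bootstrap_aucs": self.bootstrap_aucs,
            "spearman_rho": self.spearman_rho,
            "rmse": self.rmse,
            "best_spec": self.best_spec,
            "roc": [list(p) for p in self.roc],
        }


# ---------------------------------------------------------------------------
# splitting and normalization
# ---------------------------------------------------------------------------


def make_split(
    manifest: CohortManifest, fraction: float = 0.8, seed: int = 0
) -> SplitPlan:
    """Stratified, speaker-independent train/test split of participants."""
    groups: dict[str, list[str]] = {}
    for p in manifest.participants:
        groups.setdefault(p.group, []).append(p.id)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for group, ids in sorted(groups.items()):
        if len(ids) < 2:
            raise ValueError(f"group {group!r} too small to stratify")
        ids = list(ids)
        rng.shuffle(ids)
        n_train = int(round(fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        test.extend(ids[n_train:])
    return SplitPlan(tuple(sorted(train)), tuple(sorted(test)), seed, fraction)


def zscore_fit_transform(
    train: pd.DataFrame, test: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.Series]:
    """Z-score both tables with *train* mean/sd; drop zero-sd columns.

    Returns (train_z, test_z, mean, sd) over the retained columns.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = list(sd.index[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s", len(dropped), dropped[:5])
    mean, sd = mean[keep], sd[keep]
    cols = list(mean.index)
    return (
        (train[cols] - mean) / sd,
        (test[cols] - mean) / sd,
        mean,
        sd,
    )


def early_fusion(timing: pd.DataFrame, lexsem: pd.DataFrame) -> pd.DataFrame:
    """Column-wise concatenation of the two modality tables, aligned by id."""
    if set(timing.index) != set(lexsem.index):
        raise ValueError("participant id sets differ between modalities")
    overlap = set(timing.columns) & set(lexsem.columns)
    if overlap:
        raise ValueError(f"duplicate feature columns in fusion: {sorted(overlap)[:5]}")
    return pd.concat([timing, lexsem.loc[timing.index]], axis=1)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def auc_roc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve over all score thresholds and its trapezoidal AUC.

    Tied scores step the curve diagonally (simultaneous TP/FP increments).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    order = np.argsort(-scores, kind="stable")
    scores_s, labels_s = scores[order], labels[order]
    roc = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < scores_s.size:
        j = i
        while j < scores_s.size and scores_s[j] == scores_s[i]:
            tp += int(labels_s[j] == 1)
            fp += int(labels_s[j] == 0)
            j += 1
        roc.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(roc, roc[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return float(auc), roc


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values: V10 per positive, V01 per negative."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (
        pos[:, None] == neg[None, :]
    )
    return cmp.mean(axis=1), cmp.mean(axis=0)


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, bool]:
    """Paired DeLong test for two correlated AUCs on the same samples.

    Returns (delta_auc, two-sided p, degenerate flag).  Zero estimated
    variance (e.g. a model compared with itself) yields p = 1 with the
    degenerate flag set.
    """
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired DeLong requires equal-length score/label vectors")
    v10_a, v01_a = _placements(scores_a, labels)
    v10_b, v01_b = _placements(scores_b, labels)
    auc_a, auc_b = v10_a.mean(), v10_b.mean()
    delta = float(auc_a - auc_b)
    m, n = v10_a.size, v01_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var <= 0:
        return delta, 1.0, True
    z = delta / math.sqrt(var)
    p = 2.0 * (1.0 - norm.cdf(abs(z)))
    return delta, float(p), False


def regression_metrics(
    predicted: Sequence[float], true: Sequence[float]
) -> tuple[float, float]:
    """(Spearman rho with average-rank ties, RMSE)."""
    predicted = np.asarray(predicted, dtype=np.float64)
    true = np.asarray(true, dtype=np.float64)
    if predicted.size != true.size or predicted.size < 3:
        raise ValueError("regression metrics need >= 3 paired values")
    rmse = float(np.sqrt(((predicted - true) ** 2).mean()))
    if np.ptp(predicted) == 0 or np.ptp(true) == 0:
        logger.warning("constant vector: Spearman rho undefined")
        return math.nan, rmse
    rp, rt = rankdata(predicted), rankdata(true)
    rho = float(np.corrcoef(rp, rt)[0, 1])
    return rho, rmse


# ---------------------------------------------------------------------------
# protocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """Knobs for run_protocol; the grid defaults to a single affordable cell."""

    tree_grid: tuple[int, ...] = (20,)
    depth_grid: tuple[int, ...] = (4,)
    n_bootstrap: int = 50
    fraction: float = 0.8
    seed: int = 0
    run_grid_search: bool = False
    regression: bool = False
    max_epochs: int = 500


def select_modality(features: pd.DataFrame, modality: str) -> pd.DataFrame:
    if modality == "fusion":
        return features
    cols = [c for c in features.columns if c.startswith(f"{modality}__")]
    if not cols:
        raise ValueError(f"no columns for modality {modality!r}")
    return features[cols]


def _labels_for(manifest: CohortManifest, ids: Sequence[str]) -> np.ndarray:
    by_id = {p.id: p for p in manifest.participants}
    return np.array([1 if by_id[i].group == "patient" else 0 for i in ids])


def _mmse_for(manifest: CohortManifest, ids: Sequence[str]) -> np.ndarray:
    by_id = {p.id: p for p in manifest.participants}
    return np.array(
        [by_id[i].mmse if by_id[i].mmse is not None else np.nan for i in ids],
        dtype=np.float64,
    )


def _impute_train_median(train: pd.DataFrame, test: pd.DataFrame):
    """Fill absent-feature markers with train-column medians (train stats only)."""
    med = train.median(axis=0)
    med = med.fillna(0.0)
    return train.fillna(med), test.fillna(med)


def _fit_and_score(
    X_train_df: pd.DataFrame,
    X_test_df: pd.DataFrame,
    y_train: np.ndarray,
    config: ProtocolConfig,
    seed: int,
):
    """Impute + z-score with train statistics, fit, score the test rows.

    Shared by both protocol settings: test rows never influence imputation,
    normalization, model selection, or training.
    """
    X_train_df = X_train_df[sorted(X_train_df.columns)]
    X_test_df = X_test_df[sorted(X_test_df.columns)]
    X_train_df, X_test_df = _impute_train_median(X_train_df, X_test_df)
    X_train_z, X_test_z, mean, sd = zscore_fit_transform(X_train_df, X_test_df)
    X_train = X_train_z.to_numpy()

    if config.run_grid_search:
        best_cell, model, _ = grid_search(
            X_train, y_train,
            tree_grid=config.tree_grid, depth_grid=config.depth_grid,
            task="classification", seed=seed,
        )
    else:
        from speechmark.tree_sparse_mlp import _holdout_split

        rng = np.random.default_rng(seed)
        tr, va = _holdout_split(y_train, 0.25, rng)
        best_cell = (config.tree_grid[0], config.depth_grid[0])
        model = fit_sparse_mlp(
            X_train[tr], y_train[tr], X_train[va], y_train[va],
            best_cell[0], best_cell[1], task="classification", seed=seed,
            max_epochs=config.max_epochs,
        )
    scores = predict(model, X_test_z.to_numpy())
    model.norm_mean = mean.to_numpy()
    model.norm_sd = sd.to_numpy()
    return model, scores, best_cell


def run_protocol(
    source: CohortManifest,
    features: pd.DataFrame,
    modality: str,
    config: ProtocolConfig | None = None,
    target: CohortManifest | None = None,
    target_features: pd.DataFrame | None = None,
    setting: str = "within",
) -> EvaluationReport:
    """Run the within- or between-language evaluation protocol.

    within: repeated stratified 80/20 resampling with per-repetition
    retraining (bootstrap AUC distribution; the first repetition supplies
    the ROC and regression metrics).

    between: train once on the source cohort (internal 80/20 model
    selection), then score the *entire* target cohort using source-fitted
    normalization parameters — no target row ever touches fitting.
    """
    config = config or ProtocolConfig()
    if setting not in ("within", "between"):
        raise ValueError(f"unknown setting {setting!r}")
    if setting == "within" and target is not None:
        raise ValueError("target cohort given in within-language mode")
    if setting == "between" and (target is None or target_features is None):
        raise ValueError("between-language mode requires a target cohort")

    feats = select_modality(features, modality)
    report = EvaluationReport(modality=modality, setting=setting)

    if setting == "within":
        first_plan = None
        for rep in range(config.n_bootstrap):
            plan = make_split(source, config.fraction, seed=config.seed + rep)
            _, scores, cell = _fit_and_score(
                feats.loc[list(plan.train_ids)],
                feats.loc[list(plan.test_ids)],
                _labels_for(source, plan.train_ids),
                config,
                config.seed + rep,
            )
            labels = _labels_for(source, plan.test_ids)
            auc, roc = auc_roc(scores, labels)
            report.bootstrap_aucs.append(auc)
            if rep == 0:
                report.auc, report.roc = auc, roc
                report.best_spec = cell
                first_plan = plan
        # regression on patients' MMSE, first repetition's split
        if config.regression:
            rho, rmse = _protocol_regression(
                feats, source, first_plan.train_ids, first_plan.test_ids, config
            )
            report.spearman_rho, report.rmse = rho, rmse
        return report

    # between: the model is fit on the source cohort alone; the target
    # cohort supplies scoring rows only (0-shot).
    tgt_feats = select_modality(target_features, modality)
    source_ids = [p.id for p in source.participants]
    target_ids = [p.id for p in target.participants]
    model, scores, cell = _fit_and_score(
        feats.loc[source_ids],
        tgt_feats.loc[target_ids],
        _labels_for(source, source_ids),
        config,
        config.seed,
    )
    labels = _labels_for(target, target_ids)
    report.auc, report.roc = auc_roc(scores, labels)
    report.best_spec = cell
    if config.regression:
        rho, rmse = _protocol_regression(
            feats, source,
            [p.id for p in source.participants],
            [p.id for p in target.participants],
            config,
            target_manifest=target,
            target_features=tgt_feats,
        )
        report.spearman_rho, report.rmse = rho, rmse
    return report


def _protocol_regression(
    features: pd.DataFrame,
    source: CohortManifest,
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    config: ProtocolConfig,
    target_manifest: CohortManifest | None = None,
    target_features: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """MMSE regression on patients only (those with MMSE present)."""
    by_id = {p.id: p for p in source.participants}
    train_pat = [i for i in train_ids if i in by_id and by_id[i].mmse is not None]
    if target_manifest is not None:
        by_id_t = {p.id: p for p in target_manifest.participants}
        test_pat = [i for i in by_id_t if by_id_t[i].mmse is not None]
        test_feats = target_features.loc[test_pat]
        true_mmse = _mmse_for(target_manifest, test_pat)
    else:
        test_pat = [i for i in test_ids if by_id[i].mmse is not None]
        test_feats = features.loc[test_pat]
        true_mmse = _mmse_for(source, test_pat)
    if len(train_pat) < 4 or len(test_pat) < 3:
        return math.nan, math.nan

    X_train_df = features.loc[train_pat]
    X_train_df, test_feats = _impute_train_median(X_train_df, test_feats)
    X_train_z, X_test_z, _, _ = zscore_fit_transform(X_train_df, test_feats)
    y_train = _mmse_for(source, train_pat)

    from speechmark.tree_sparse_mlp import _holdout_split

    rng = np.random.default_rng(config.seed)
    tr, va = _holdout_split(np.zeros(len(train_pat)), 0.25, rng)
    model = fit_sparse_mlp(
        X_train_z.to_numpy()[tr], y_train[tr],
        X_train_z.to_numpy()[va], y_train[va],
        config.tree_grid[0], config.depth_grid[0],
        task="regression", seed=config.seed, max_epochs=config.max_epochs,
    )
    predicted = predict(model, X_test_z.to_numpy())
    return regression_metrics(predicted, true_mmse)
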