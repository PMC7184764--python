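"""Cross-validated SVM evaluation: segment metrics and channel AUC.

Segments are partitioned into k contiguous blocks of segment indices
(all channels of a segment share its fold, avoiding temporal leakage
between adjacent 20-s windows).  Per fold the training rows are
z-scored per subband, sparse-LDA selection is fitted, ADASYN balances
the selected training vectors, and an RBF SVM (C = 1, gamma = 'scale')
predicts the held-out segments.  Ablations of the full pipeline
(selection off, balancing off) are single config switches.

Segment-level performance is summarized by sensitivity, specificity,
precision and fall-out in percent, the F-score as a fraction, and the
positive likelihood ratio SEN/FPR.  Channel-level performance thresholds
the per-channel count of detected focal segments from 0 to the maximum
per fold, traces the (FPR, SEN) ROC polyline and integrates it by the
trapezoid rule; fold AUCs are averaged.  That construction is
numerically identical to the tie-aware Mann-Whitney rank statistic on
the counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .adasyn import adasyn_balance
from .features import feature_matrices
from .slda import SldaSolution, fit_slda, select_features

__all__ = [
    "ConfusionCounts",
    "SegmentMetrics",
    "CVConfig",
    "CVResult",
    "confusion",
    "segment_metrics",
    "f_score",
    "positive_likelihood_ratio",
    "channel_auc",
    "run_cv",
    "detection_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class SegmentMetrics:
    """Percent-scale SEN/SPE/PPV/FPR, fraction-scale F1, ratio-scale PLR.

    Undefined metrics (zero denominators) are NaN."""

    sen: float
    spe: float
    ppv: float
    fpr: float
    f1: float
    plr: float


def confusion(predictions: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    """Count the 2x2 confusion table (True = focal)."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise ValueError("predictions and labels differ in length")
    return ConfusionCounts(
        tp=int((pred & lab).sum()),
        fn=int((~pred & lab).sum()),
        fp=int((pred & ~lab).sum()),
        tn=int((~pred & ~lab).sum()),
    )


def f_score(sen_pct: float, ppv_pct: float) -> float:
    """F1 (fraction) as the harmonic mean of percent-scale recall and precision."""
    if sen_pct + ppv_pct == 0:
        return float("nan")
    return 2 * sen_pct * ppv_pct / (sen_pct + ppv_pct) / 100.0


def positive_likelihood_ratio(sen_pct: float, fpr_pct: float) -> float:
    """PLR = SEN / FPR (both percent-scale)."""
    if fpr_pct == 0:
        return float("nan")
    return sen_pct / fpr_pct


def segment_metrics(c: ConfusionCounts) -> SegmentMetrics:
    """Segment-level metrics; SPE + FPR = 100 exactly."""
    pos = c.tp + c.fn
    neg = c.fp + c.tn
    det = c.tp + c.fp
    sen = 100.0 * c.tp / pos if pos else float("nan")
    spe = 100.0 * c.tn / neg if neg else float("nan")
    fpr = 100.0 * c.fp / neg if neg else float("nan")
    ppv = 100.0 * c.tp / det if det else float("nan")
    return SegmentMetrics(
        sen=sen, spe=spe, ppv=ppv, fpr=fpr,
        f1=f_score(sen, ppv) if not (np.isnan(sen) or np.isnan(ppv)) else float("nan"),
        plr=positive_likelihood_ratio(sen, fpr) if not np.isnan(fpr) else float("nan"),
    )


def channel_auc(counts: np.ndarray, soz_mask: np.ndarray) -> float:
    """Channel-level ROC AUC from detected-focal-segment counts.

    A channel is called positive when its count >= t; sweeping t from 0
    to max+1 traces the ROC from (1,1) to (0,0), integrated by the
    trapezoid rule.  Equivalent to the Mann-Whitney statistic with
    half-credit ties.
    """
    counts = np.asarray(counts, dtype=float)
    soz = np.asarray(soz_mask, dtype=bool)
    if counts.shape != soz.shape:
        raise ValueError("counts and soz_mask differ in length")
    n_pos, n_neg = int(soz.sum()), int((~soz).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("channel AUC needs both SOZ and non-SOZ channels")
    # descending thresholds trace the ROC monotonically from (0,0) to (1,1)
    thresholds = np.arange(counts.max() + 1, -1, -1)
    sen = np.array([(counts[soz] >= t).mean() for t in thresholds])
    fpr = np.array([(counts[~soz] >= t).mean() for t in thresholds])
    return float(np.trapezoid(sen, fpr))


@dataclass(frozen=True)
class CVConfig:
    """Pipeline / cross-validation settings.

    The three published algorithm variants map to the switches:
    multiband features only (``use_selection=False, use_adasyn=False``),
    + ADASYN (``use_adasyn=True``), + selection (both True, the full
    pipeline).
    """

    k: int = 10
    g: int = 3
    delta: float = 3.0
    use_selection: bool = True
    use_adasyn: bool = True
    adasyn_beta: float = 1.0
    adasyn_k: int = 5
    svm_c: float = 1.0
    svm_gamma: str | float = "scale"
    seed: int | None = None


@dataclass
class CVResult:
    predictions: pd.DataFrame  # channel, segment, label, fold, predicted
    confusion: ConfusionCounts
    metrics: SegmentMetrics
    detection_counts: pd.DataFrame  # channel, soz, detected (over all folds)
    fold_aucs: list[float]
    mean_auc: float
    solutions: list[dict[int, SldaSolution]]  # per-fold fitted selections


def _segment_folds(segment_ids: np.ndarray, k: int) -> list[np.ndarray]:
    """Contiguous blocks of sorted segment indices (remainder spread)."""
    uniq = np.unique(segment_ids)
    if k < 2 or k > len(uniq):
        raise ValueError(f"k must be in 2..{len(uniq)}")
    return [b for b in np.array_split(uniq, k)]


def run_cv(
    features: pd.DataFrame,
    config: CVConfig = CVConfig(),
) -> CVResult:
    """k-fold segment-wise cross-validation of the full pipeline.

    ``features`` is the tidy table from
    :func:`ieegfocus.features.extract_features`.  Every segment is
    predicted exactly once; fold assignment depends only on segment
    indices, never on channel order.
    """
    matrices, rows = feature_matrices(features)
    subbands = sorted(matrices)
    seg_ids = rows["segment"].to_numpy()
    labels = rows["label"].to_numpy(dtype=bool)
    folds = _segment_folds(seg_ids, config.k)
    rng = np.random.default_rng(config.seed)

    pred_rows: list[pd.DataFrame] = []
    fold_aucs: list[float] = []
    all_solutions: list[dict[int, SldaSolution]] = []
    for fold_i, test_segs in enumerate(folds):
        test_mask = np.isin(seg_ids, test_segs)
        train_mask = ~test_mask
        y_train = labels[train_mask]
        if y_train.all() or not y_train.any():
            raise ValueError(f"fold {fold_i}: training rows are single-class")

        solutions: dict[int, SldaSolution] = {}
        train_blocks: dict[int, np.ndarray] = {}
        test_blocks: dict[int, np.ndarray] = {}
        for n in subbands:
            M = matrices[n]
            g = config.g if config.use_selection else M.shape[1]
            sol = fit_slda(
                M[train_mask], y_train, delta=config.delta, g=g, subband=n
            )
            solutions[n] = sol
            # apply training-fold standardization to both halves
            train_blocks[n] = (M[train_mask] - sol.mean) / sol.scale
            test_blocks[n] = (M[test_mask] - sol.mean) / sol.scale
        all_solutions.append(solutions)

        X_train = select_features(train_blocks, solutions)
        X_test = select_features(test_blocks, solutions)
        if config.use_adasyn:
            balanced = adasyn_balance(
                X_train, y_train,
                beta=config.adasyn_beta, k=config.adasyn_k, seed=rng,
            )
            X_fit, y_fit = balanced.X, balanced.focal
        else:
            X_fit, y_fit = X_train, y_train

        clf = SVC(C=config.svm_c, kernel="rbf", gamma=config.svm_gamma)
        clf.fit(X_fit, y_fit)
        pred = clf.predict(X_test).astype(bool)

        fold_df = rows[test_mask].copy()
        fold_df["fold"] = fold_i
        fold_df["predicted"] = pred
        pred_rows.append(fold_df)

        fold_counts = (
            fold_df.assign(det=fold_df["predicted"].astype(int))
            .groupby("channel_index")["det"].sum()
        )
        fold_soz = fold_df.groupby("channel_index")["label"].first()
        try:
            fold_aucs.append(
                channel_auc(fold_counts.to_numpy(), fold_soz.to_numpy(dtype=bool))
            )
        except ValueError:
            warnings.warn(f"fold {fold_i}: single-class channels, AUC skipped")

    predictions = pd.concat(pred_rows, ignore_index=True)
    c = confusion(predictions["predicted"], predictions["label"])
    det = (
        predictions.assign(det=predictions["predicted"].astype(int))
        .groupby(["channel_index", "channel"], sort=True)
        .agg(soz=("label", "first"), detected=("det", "sum"))
        .reset_index()
    )
    return CVResult(
        predictions=predictions,
        confusion=c,
        metrics=segment_metrics(c),
        detection_counts=det,
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)) if fold_aucs else float("nan"),
        solutions=all_solutions,
    )


def detection_report(result: CVResult, out_dir: str | Path) -> dict[str, Path]:
    """Write the evaluation artifacts as TSV.

    ``detections.tsv``: channel x segment binary detection matrix;
    ``channel_counts.tsv``: per-channel detected-focal counts with SOZ flag;
    ``segment_metrics.tsv``: the summary metrics (2-decimal convention);
    ``channel_auc.tsv``: per-fold and mean channel AUC.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mat = result.predictions.pivot_table(
        index="channel", columns="segment", values="predicted", aggfunc="first"
    ).astype(int)
    paths["detections"] = out / "detections.tsv"
    mat.to_csv(paths["detections"], sep="\t")

    paths["channel_counts"] = out / "channel_counts.tsv"
    result.detection_counts.to_csv(paths["channel_counts"], sep="\t", index=False)

    m = result.metrics
    summary = pd.DataFrame(
        [
            {
                "sen": round(m.sen, 2), "spe": round(m.spe, 2),
                "ppv": round(m.ppv, 2), "fpr": round(m.fpr, 2),
                "f1": round(m.f1, 2), "plr": round(m.plr, 2),
                "tp": result.confusion.tp, "fn": result.confusion.fn,
                "fp": result.confusion.fp, "tn": result.confusion.tn,
            }
        ]
    )
    paths["segment_metrics"] = out / "segment_metrics.tsv"
    summary.to_csv(paths["segment_metrics"], sep="\t", index=False)

    auc = pd.DataFrame(
        {"fold": list(range(len(result.fold_aucs))) + ["mean"],
         "auc": [round(a, 4) for a in result.fold_aucs] + [round(result.mean_auc, 4)]}
    )
    paths["channel_auc"] = out / "channel_auc.tsv"
    auc.to_csv(paths["channel_auc"], sep="\t", index=False)
    return paths
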