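"""Multi-label evaluation metrics and the repeated-CV harness.

Example-based metrics compare, per protein, the true location set M with
the predicted set M-hat: accuracy is the mean Jaccard overlap
|M n M^| / |M u M^| and F1 the mean Dice overlap 2|M n M^| / (|M| + |M^|).
Location-based metrics come in two flavors: the adapted multilabel
precision/recall (overlap ratios averaged over the proteins predicted at /
truly in a location) and the standard binary precision/recall from
TP/FP/FN counts.  F1-label is the macro average over locations of the
harmonic mean of the adapted precision and recall.

The cross-validation harness runs R complete k-fold rounds with
label-combination-stratified splits, evaluates both the Bayesian network
collection and the raw SVM indicator baseline on the pooled held-out
predictions of each round, and reports per-run values with mean and
sample standard deviation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from .config import TrainConfig
from .dataset import LocationVocabulary, MultiLocDataset, split_stratified
from .predictor import baseline_predict, predict, train

__all__ = [
    "LabelSetPair",
    "EvalReport",
    "multilabel_accuracy",
    "multilabel_f1",
    "multilabel_pre_rec",
    "f1_label",
    "standard_pre_rec",
    "evaluate_predictions",
    "cross_validate",
]

logger = logging.getLogger("locnet")


@dataclass(frozen=True)
class LabelSetPair:
    """True and predicted location sets for one protein."""

    true: frozenset
    pred: frozenset


def _as_matrices(y_true, y_pred):
    Yt = np.asarray(y_true, dtype=bool)
    Yp = np.asarray(y_pred, dtype=bool)
    if Yt.shape != Yp.shape or Yt.ndim != 2:
        raise ValueError("true/predicted indicator matrices must share shape (m, q)")
    if len(Yt) == 0:
        raise ValueError("metrics need at least one evaluated protein")
    if (Yt.sum(axis=1) == 0).any():
        raise ValueError("every evaluated protein needs >= 1 true location")
    return Yt, Yp


def pairs_to_matrices(pairs, vocabulary: LocationVocabulary):
    """Convert LabelSetPair lists to 0/1 indicator matrices."""
    Yt = np.zeros((len(pairs), len(vocabulary)), dtype=np.int8)
    Yp = np.zeros_like(Yt)
    for i, p in enumerate(pairs):
        Yt[i] = vocabulary.encode(p.true)
        Yp[i] = vocabulary.encode(p.pred)
    return Yt, Yp


def multilabel_accuracy(y_true, y_pred) -> float:
    """Mean per-protein Jaccard overlap |M n M^| / |M u M^|."""
    Yt, Yp = _as_matrices(y_true, y_pred)
    inter = (Yt & Yp).sum(axis=1)
    union = (Yt | Yp).sum(axis=1)
    return float((inter / union).mean())


def multilabel_f1(y_true, y_pred) -> float:
    """Mean per-protein Dice overlap 2|M n M^| / (|M| + |M^|)."""
    Yt, Yp = _as_matrices(y_true, y_pred)
    inter = (Yt & Yp).sum(axis=1)
    tot = Yt.sum(axis=1) + Yp.sum(axis=1)
    return float((2.0 * inter / tot).mean())


def multilabel_pre_rec(y_true, y_pred, location: int) -> tuple[float, float]:
    """Adapted multilabel precision and recall for one location.

    Precision averages |M n M^| / |M^| over proteins *predicted* at the
    location; recall averages |M n M^| / |M| over proteins *truly* at it.
    An empty conditioning set yields NaN (undefined).
    """
    Yt, Yp = _as_matrices(y_true, y_pred)
    inter = (Yt & Yp).sum(axis=1)
    pred_here = Yp[:, location]
    true_here = Yt[:, location]
    pre = (
        float((inter[pred_here] / Yp[pred_here].sum(axis=1)).mean())
        if pred_here.any()
        else float("nan")
    )
    rec = (
        float((inter[true_here] / Yt[true_here].sum(axis=1)).mean())
        if true_here.any()
        else float("nan")
    )
    return pre, rec


def f1_label(y_true, y_pred) -> float:
    """Macro average over locations of 2 Pre Rec / (Pre + Rec).

    Averages over the locations with at least one true member; a location
    whose precision is undefined (never predicted) or with Pre + Rec = 0
    contributes 0.
    """
    Yt, Yp = _as_matrices(y_true, y_pred)
    present = np.where(Yt.any(axis=0))[0]
    terms = []
    for i in present:
        pre, rec = multilabel_pre_rec(Yt, Yp, i)
        if np.isnan(pre) or np.isnan(rec) or pre + rec == 0:
            terms.append(0.0)
        else:
            terms.append(2.0 * pre * rec / (pre + rec))
    return float(np.mean(terms))


def standard_pre_rec(y_true, y_pred, location: int):
    """Standard binary precision/recall and the TP/FP/FN counts."""
    Yt, Yp = _as_matrices(y_true, y_pred)
    t = Yt[:, location]
    p = Yp[:, location]
    tp = int((t & p).sum())
    fp = int((~t & p).sum())
    fn = int((t & ~p).sum())
    pre = tp / (tp + fp) if tp + fp else float("nan")
    rec = tp / (tp + fn) if tp + fn else float("nan")
    return pre, rec, tp, fp, fn


def evaluate_predictions(y_true, y_pred, vocabulary: LocationVocabulary) -> dict:
    """All metrics for one pooled set of predictions."""
    out = {
        "acc": multilabel_accuracy(y_true, y_pred),
        "f1": multilabel_f1(y_true, y_pred),
        "f1_label": f1_label(y_true, y_pred),
        "per_location": {},
    }
    for i, name in enumerate(vocabulary.names):
        pre, rec = multilabel_pre_rec(y_true, y_pred, i)
        pre_std, rec_std, tp, fp, fn = standard_pre_rec(y_true, y_pred, i)
        out["per_location"][name] = {
            "pre": pre, "rec": rec,
            "pre_std": pre_std, "rec_std": rec_std,
            "tp": tp, "fp": fp, "fn": fn,
        }
    return out


# -- repeated stratified cross-validation ----------------------------------


@dataclass
class EvalReport:
    """Per-run metrics for the BN system and the SVM baseline."""

    vocabulary: LocationVocabulary
    runs: int
    folds: int
    seed: int
    bn_runs: list[dict] = field(default_factory=list)
    svm_runs: list[dict] = field(default_factory=list)

    @staticmethod
    def _mean_sd(values) -> tuple[float, float]:
        v = np.asarray(values, dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            return float("nan"), float("nan")
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        return float(v.mean()), sd

    def summary(self, system: str = "bn") -> dict:
        """Mean and sample SD of each scalar metric across runs."""
        runs = self.bn_runs if system == "bn" else self.svm_runs
        out = {}
        for key in ("acc", "f1", "f1_label"):
            out[key] = self._mean_sd([r[key] for r in runs])
        out["per_location"] = {}
        for name in self.vocabulary.names:
            out["per_location"][name] = {
                m: self._mean_sd([r["per_location"][name][m] for r in runs])
                for m in ("pre", "rec", "pre_std", "rec_std")
            }
        return out

    def to_tsv(self) -> str:
        lines = ["system\tmetric\t" + "\t".join(
            f"run{r + 1}" for r in range(self.runs)) + "\tmean\tsd"]
        for system, runs in (("bn", self.bn_runs), ("svm", self.svm_runs)):
            for key in ("acc", "f1", "f1_label"):
                vals = [r[key] for r in runs]
                mean, sd = self._mean_sd(vals)
                row = "\t".join(f"{v:.4f}" for v in vals)
                lines.append(f"{system}\t{key}\t{row}\t{mean:.4f}\t{sd:.4f}")
        lines.append("")
        lines.append("system\tlocation\tmetric\tmean\tsd")
        for system in ("bn", "svm"):
            s = self.summary(system)
            for name in self.vocabulary.names:
                for m in ("pre_std", "rec_std", "pre", "rec"):
                    mean, sd = s["per_location"][name][m]
                    lines.append(
                        f"{system}\t{name}\t{m}\t{mean:.4f}\t{sd:.4f}"
                    )
        return "\n".join(lines) + "\n"


def _run_seed(seed: int, r: int) -> int:
    # distinct deterministic sub-seeds per CV round, kept below 2**31
    return int((seed * 100003 + 7919 * r + 1) % (2**31 - 1))


def cross_validate(
    dataset: MultiLocDataset,
    runs: int,
    folds: int,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """R complete rounds of stratified k-fold CV for BN system and baseline.

    For each round, the dataset is split with a round-specific seed, a
    model is trained on each k-1 fold union and applied to the held-out
    fold, and all held-out predictions of the round are pooled before
    computing metrics.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = config or TrainConfig()
    report = EvalReport(dataset.vocabulary, runs, folds, seed)
    for r in range(runs):
        rs = _run_seed(seed, r)
        fold_idx = split_stratified(dataset, folds, rs)
        y_pred_bn = np.zeros_like(dataset.Y)
        y_pred_svm = np.zeros_like(dataset.Y)
        for f, held in enumerate(fold_idx):
            train_idx = np.concatenate(
                [fold_idx[g] for g in range(folds) if g != f]
            )
            try:
                model = train(dataset.subset(train_idx), config.with_seed(rs))
                held_ds = dataset.subset(held)
                y_pred_bn[held] = predict(model, held_ds)
                y_pred_svm[held] = baseline_predict(model, held_ds)
            except Exception as exc:
                raise RuntimeError(
                    f"cross-validation run {r}, fold {f} failed: {exc}"
                ) from exc
        report.bn_runs.append(
            evaluate_predictions(dataset.Y, y_pred_bn, dataset.vocabulary)
        )
        report.svm_runs.append(
            evaluate_predictions(dataset.Y, y_pred_svm, dataset.vocabulary)
        )
        logger.info(
            "run %d/%d: bn f1=%.3f, svm f1=%.3f",
            r + 1, runs, report.bn_runs[-1]["f1"], report.svm_runs[-1]["f1"],
        )
    return report
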