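"""Discriminant-analysis classification of folding kinetics with grouped CV.

Proteins are labelled two-state (TS) or multi-state (MS) and carry a
homology-group identifier.  Performance of a feature subset is assessed
by k-fold cross-validation in which all members of a homology group are
kept in the same fold (otherwise homologs in train and test would
inflate the score), re-randomised over many resamplings; the report
carries the mean and standard deviation over resamplings of the overall
and per-class accuracies and of the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

which is +1 for perfect prediction, 0 for random guessing and -1 for
total disagreement, and is robust to class imbalance.

The per-fold classifier is Gaussian discriminant analysis — linear
(pooled covariance) or quadratic (per-class covariance, the default) —
with class priors taken from training frequencies.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)

from .errors import ConfigurationError, PcnfoldError, ValidationError

#: ridge fraction used to regularise per-class covariances in tiny folds
COV_RIDGE = 1e-9


@dataclass(frozen=True)
class LabeledDataset:
    """Feature vectors with TS/MS labels and homology groups.

    ``features`` is a DataFrame indexed like ``ids``; ``labels`` and
    ``groups`` are aligned sequences.  Homology groups may be singletons
    but every protein must belong to one.
    """

    ids: tuple
    features: pd.DataFrame
    labels: tuple
    groups: tuple

    def __post_init__(self):
        ids = tuple(str(i) for i in self.ids)
        labels = tuple(str(l) for l in self.labels)
        groups = tuple(str(g) for g in self.groups)
        feats = pd.DataFrame(self.features)
        if not (len(ids) == len(labels) == len(groups) == len(feats)):
            raise ValidationError("ids, features, labels, groups must align")
        if feats.isna().any().any():
            bad = feats.columns[feats.isna().any()].tolist()
            raise ValidationError(f"missing feature values in columns {bad}")
        if len(set(labels)) != 2:
            raise ValidationError("exactly two class labels are required")
        feats = feats.copy()
        feats.index = list(ids)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "features", feats)

    def __len__(self):
        return len(self.ids)

    @property
    def classes(self) -> tuple:
        return tuple(sorted(set(self.labels)))

    def subset(self, indices) -> "LabeledDataset":
        idx = list(indices)
        return LabeledDataset(
            ids=[self.ids[i] for i in idx],
            features=self.features.iloc[idx],
            labels=[self.labels[i] for i in idx],
            groups=[self.groups[i] for i in idx],
        )


@dataclass
class ClassificationReport:
    """Grouped-CV performance summary (means and sds over resamplings)."""

    overall_accuracy: tuple  # (mean %, sd %)
    per_class_accuracy: dict  # label -> (mean %, sd %)
    mcc: tuple  # (mean, sd)
    confusion_totals: dict  # TP/TN/FP/FN summed over folds and resamplings
    n_resamplings: int
    seed: int
    k: int = 10
    feature_names: tuple = ()
    positive_label: str = ""
    mode: str = "quadratic"
    per_resampling: Optional[pd.DataFrame] = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mode": self.mode,
            "k": self.k,
            "n_resamplings": self.n_resamplings,
            "seed": self.seed,
            "positive_label": self.positive_label,
            "overall_accuracy_mean_pct": self.overall_accuracy[0],
            "overall_accuracy_sd_pct": self.overall_accuracy[1],
            "per_class_accuracy": {
                lab: {"mean_pct": m, "sd_pct": s}
                for lab, (m, s) in self.per_class_accuracy.items()
            },
            "mcc_mean": self.mcc[0],
            "mcc_sd": self.mcc[1],
            "confusion_totals": dict(self.confusion_totals),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def __str__(self) -> str:
        feats = ", ".join(self.feature_names) or "(all)"
        lines = [
            f"features: {feats}   [{self.mode} DA, {self.k}-fold CV, "
            f"{self.n_resamplings} resamplings, seed {self.seed}]",
            f"  overall : {self.overall_accuracy[0]:6.2f}% "
            f"± {self.overall_accuracy[1]:.2f}%",
        ]
        for lab, (m, s) in sorted(self.per_class_accuracy.items()):
            lines.append(f"  {lab:7s}: {m:6.2f}% ± {s:.2f}%")
        lines.append(f"  MCC     : {self.mcc[0]:.2f} ± {self.mcc[1]:.2f}")
        return "\n".join(lines)


def matthews_cc(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 by convention on a zero factor."""
    tp, tn, fp, fn = (float(v) for v in (tp, tn, fp, fn))
    if min(tp, tn, fp, fn) < 0:
        raise ValidationError("confusion counts must be nonnegative")
    if tp + tn + fp + fn == 0:
        raise PcnfoldError("MCC undefined: all confusion counts are zero")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def fit_discriminant(train: LabeledDataset, feature_names: Sequence[str],
                     mode: str = "quadratic"):
    """Fit a Gaussian discriminant model (priors = training frequencies).

    ``mode`` is ``"linear"`` (pooled covariance) or ``"quadratic"``
    (per-class covariance).  Returns a fitted scikit-learn estimator.
    """
    feature_names = list(feature_names)
    missing = set(feature_names) - set(train.features.columns)
    if missing:
        raise ConfigurationError(f"unknown feature column(s): {sorted(missing)}")
    X = train.features[feature_names].to_numpy(dtype=float)
    y = np.asarray(train.labels)
    counts = pd.Series(y).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise PcnfoldError("need at least 2 training samples per class")
    if mode == "linear":
        model = LinearDiscriminantAnalysis()
    elif mode == "quadratic":
        model = QuadraticDiscriminantAnalysis(reg_param=COV_RIDGE)
    else:
        raise ConfigurationError(f"unknown discriminant mode {mode!r}")
    try:
        model.fit(X, y)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
        raise PcnfoldError(f"singular covariance after regularisation: {exc}")
    return model


def _assign_folds(groups: Sequence[str], k: int, rng: np.random.Generator):
    """Randomised group-level fold assignment, balanced by protein count.

    Groups are shuffled and greedily placed into the currently smallest
    fold, so no homology group ever spans two folds.
    """
    unique = list(dict.fromkeys(groups))
    if len(unique) < k:
        raise ConfigurationError(
            f"{len(unique)} homology groups but k={k} folds requested"
        )
    sizes = pd.Series(groups).value_counts().to_dict()
    order = [unique[i] for i in rng.permutation(len(unique))]
    fold_of_group = {}
    load = np.zeros(k, dtype=int)
    for g in order:
        f = int(np.argmin(load))
        fold_of_group[g] = f
        load[f] += sizes[g]
    return np.array([fold_of_group[g] for g in groups])


def grouped_kfold_cv(data: LabeledDataset, feature_names: Sequence[str],
                     k: int = 10, n_resamplings: int = 10000,
                     seed: int = 0, mode: str = "quadratic",
                     positive_label: Optional[str] = None,
                     keep_per_resampling: bool = False) -> ClassificationReport:
    """Homology-grouped k-fold CV, re-randomised ``n_resamplings`` times.

    Each resampling redraws the group-to-fold assignment, pools the
    predictions of the k test folds, and contributes one value of each
    performance statistic; the report carries means and standard
    deviations over resamplings and is bit-reproducible from ``seed``.
    """
    feature_names = list(feature_names)
    classes = data.classes
    positive = positive_label or classes[0]
    negative = [c for c in classes if c != positive][0]
    rng = np.random.default_rng(seed)
    X_all = data.features[feature_names].to_numpy(dtype=float)
    y_all = np.asarray(data.labels)

    acc = np.empty(n_resamplings)
    acc_class = {c: np.empty(n_resamplings) for c in classes}
    mccs = np.empty(n_resamplings)
    totals = {"TP": 0, "TN": 0, "FP": 0, "FN": 0}

    for r in range(n_resamplings):
        folds = _assign_folds(data.groups, k, rng)
        pred = np.empty(len(data), dtype=y_all.dtype)
        for f in range(k):
            test = folds == f
            if not test.any():
                continue
            model = fit_discriminant(data.subset(np.flatnonzero(~test)),
                                     feature_names, mode=mode)
            pred[test] = model.predict(X_all[test])
        correct = pred == y_all
        acc[r] = 100.0 * correct.mean()
        for c in classes:
            mask = y_all == c
            acc_class[c][r] = 100.0 * correct[mask].mean()
        tp = int(((pred == positive) & (y_all == positive)).sum())
        tn = int(((pred == negative) & (y_all == negative)).sum())
        fp = int(((pred == positive) & (y_all == negative)).sum())
        fn = int(((pred == negative) & (y_all == positive)).sum())
        totals["TP"] += tp
        totals["TN"] += tn
        totals["FP"] += fp
        totals["FN"] += fn
        mccs[r] = matthews_cc(tp, tn, fp, fn)

    def _ms(v):
        return (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0)

    per_res = None
    if keep_per_resampling:
        per_res = pd.DataFrame({"accuracy_pct": acc, "mcc": mccs,
                                **{f"accuracy_{c}_pct": acc_class[c]
                                   for c in classes}})
    return ClassificationReport(
        overall_accuracy=_ms(acc),
        per_class_accuracy={c: _ms(acc_class[c]) for c in classes},
        mcc=_ms(mccs),
        confusion_totals=totals,
        n_resamplings=n_resamplings,
        seed=seed,
        k=k,
        feature_names=tuple(feature_names),
        positive_label=positive,
        mode=mode,
        per_resampling=per_res,
    )
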