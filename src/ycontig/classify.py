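"""Contig classification from the two k-mer features.

Three modes, mirroring how a user works with the feature scatter plot:

* ``female_only`` — a contig is Y iff its proportion shared with female is
  strictly below a threshold (the k-mer "genome scan" strategy);
* ``female_male`` — Y iff it falls strictly below both a female-proportion
  threshold and a male-depth threshold; the depth ceiling rejects autosomal
  repeats that are under-represented in the female reference;
* ``best`` — a linear separator learned with a linear support vector
  classifier on a labeled subset (train 16% / test 4% / validation 80%),
  applied as a sign rule.

The estimators follow scikit-learn conventions (``fit``/``predict``,
``get_params``, trailing-underscore fitted attributes) and accept either a
feature DataFrame (columns ``proportion_female`` and, where needed,
``male_depth``) or a plain (n, 2) array in that column order. Contigs with
undefined features (NaN) are always labeled non-Y.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Thresholds",
    "ThresholdClassifier",
    "LinearSeparatorClassifier",
    "ClassificationResult",
    "classify_female_only",
    "classify_female_male",
    "fit_best_separator",
    "classify_best",
    "scatter_plot",
    "Y_LABEL",
    "NONY_LABEL",
]

Y_LABEL = "Y"
NONY_LABEL = "non-Y"


@dataclass(frozen=True)
class Thresholds:
    """Classification ceilings: Y iff strictly below both."""
    p_thresh: float
    c_thresh: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_thresh <= 1.0:
            raise ValueError(f"p_thresh must be in [0, 1], got {self.p_thresh}")
        if self.c_thresh is not None and not self.c_thresh > 0:
            raise ValueError(f"c_thresh must be > 0, got {self.c_thresh}")


def _feature_matrix(X, need_depth: bool) -> tuple[np.ndarray, np.ndarray]:
    """Return (proportion, depth-or-nan) arrays from DataFrame or ndarray."""
    if isinstance(X, pd.DataFrame):
        if "proportion_female" not in X.columns:
            raise ValueError("feature table lacks a 'proportion_female' column")
        p = X["proportion_female"].to_numpy(dtype=float)
        if "male_depth" in X.columns:
            c = X["male_depth"].to_numpy(dtype=float)
        elif need_depth:
            raise ValueError(
                "feature table lacks a 'male_depth' column; recompute features "
                "with male read counts, or use female_only mode")
        else:
            c = np.full(p.shape, np.nan)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (1, 2):
            raise ValueError("expected an (n, 1) or (n, 2) feature array "
                             "[proportion_female, male_depth]")
        p = arr[:, 0]
        if arr.shape[1] == 2:
            c = arr[:, 1]
        elif need_depth:
            raise ValueError("male_depth feature column required but absent; "
                             "use female_only mode")
        else:
            c = np.full(p.shape, np.nan)
    return p, c


class ThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Rule-based classifier: Y iff features fall strictly below ceilings.

    Parameters
    ----------
    p_max : float
        Female-proportion ceiling in [0, 1].
    depth_max : float or None
        Male-depth ceiling; None disables the depth rule (female-only mode).
    """

    def __init__(self, p_max: float = 0.5, depth_max: float | None = None):
        self.p_max = p_max
        self.depth_max = depth_max

    def fit(self, X=None, y=None) -> "ThresholdClassifier":
        Thresholds(self.p_max, self.depth_max)  # validates
        self.classes_ = np.array([NONY_LABEL, Y_LABEL])
        self.is_fitted_ = True
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "is_fitted_")
        p, c = _feature_matrix(X, need_depth=self.depth_max is not None)
        with np.errstate(invalid="ignore"):
            is_y = p < self.p_max
            if self.depth_max is not None:
                is_y &= c < self.depth_max
        is_y &= ~np.isnan(p)  # undefined features -> non-Y
        return np.where(is_y, Y_LABEL, NONY_LABEL)


class LinearSeparatorClassifier(BaseEstimator, ClassifierMixin):
    """Learned linear separator over (proportion_female, male_depth).

    Features are standardized (zero mean, unit variance on the training
    data) and a hinge-loss linear SVC is fit. The decision rule is
    ``weight_p_ * p' + weight_c_ * c' + intercept_ < 0  =>  Y`` on
    standardized features; a point exactly on the boundary is non-Y.

    Attributes (after ``fit``)
    --------------------------
    weight_p_, weight_c_, intercept_ : float
        Separator coefficients in the "< 0 means Y" convention.
    scale_mean_, scale_std_ : ndarray
        Per-feature standardization parameters learned on the training data.
    """

    def __init__(self, C: float = 1.0, random_state: int = 42,
                 max_iter: int = 20000):
        self.C = C
        self.random_state = random_state
        self.max_iter = max_iter

    def fit(self, X, y) -> "LinearSeparatorClassifier":
        p, c = _feature_matrix(X, need_depth=True)
        y = np.asarray(y)
        is_y = (y == Y_LABEL) | (y == True)  # noqa: E712 - accepts bool labels
        if len(np.unique(is_y)) < 2:
            raise ValueError("training labels contain a single class; "
                             "a linear separator needs both Y and non-Y contigs")
        mask = ~(np.isnan(p) | np.isnan(c))
        feats = np.column_stack([p[mask], c[mask]])
        self._scaler = StandardScaler().fit(feats)
        self._svc = LinearSVC(C=self.C, loss="hinge",
                              random_state=self.random_state,
                              max_iter=self.max_iter)
        self._svc.fit(self._scaler.transform(feats), is_y[mask])
        # svc decision_function > 0 <=> Y; negate into the "< 0 => Y" form
        self.weight_p_ = float(-self._svc.coef_[0, 0])
        self.weight_c_ = float(-self._svc.coef_[0, 1])
        self.intercept_ = float(-self._svc.intercept_[0])
        self.scale_mean_ = self._scaler.mean_.copy()
        self.scale_std_ = self._scaler.scale_.copy()
        self.classes_ = np.array([NONY_LABEL, Y_LABEL])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed distance in the "< 0 means Y" convention (NaN -> NaN)."""
        check_is_fitted(self, "weight_p_")
        p, c = _feature_matrix(X, need_depth=True)
        ps = (p - self.scale_mean_[0]) / self.scale_std_[0]
        cs = (c - self.scale_mean_[1]) / self.scale_std_[1]
        return self.weight_p_ * ps + self.weight_c_ * cs + self.intercept_

    def predict(self, X) -> np.ndarray:
        value = self.decision_function(X)
        with np.errstate(invalid="ignore"):
            is_y = value < 0  # strict: boundary points are non-Y
        is_y &= ~np.isnan(value)
        return np.where(is_y, Y_LABEL, NONY_LABEL)

    def boundary_line(self) -> tuple[float, float, float]:
        """(a, b, d) with a*p + b*c + d = 0 in original feature units."""
        check_is_fitted(self, "weight_p_")
        a = self.weight_p_ / self.scale_std_[0]
        b = self.weight_c_ / self.scale_std_[1]
        d = (self.intercept_
             - self.weight_p_ * self.scale_mean_[0] / self.scale_std_[0]
             - self.weight_c_ * self.scale_mean_[1] / self.scale_std_[1])
        return a, b, d


@dataclass
class ClassificationResult:
    """Per-contig Y / non-Y calls plus the mode and parameters used."""
    labels: pd.DataFrame  # columns: contig_id, label, undefined
    mode: str
    params: dict = field(default_factory=dict)

    @property
    def y_ids(self) -> list[str]:
        return self.labels.loc[self.labels["label"] == Y_LABEL,
                               "contig_id"].tolist()

    def save(self, path: str | os.PathLike) -> None:
        self.labels[["contig_id", "label"]].to_csv(path, sep="\t", index=False)


def _result(features: pd.DataFrame, labels: np.ndarray, mode: str,
            params: dict) -> ClassificationResult:
    if "contig_id" not in features.columns:
        raise ValueError("feature table lacks a 'contig_id' column")
    undefined = features["undefined"].to_numpy(dtype=bool) \
        if "undefined" in features.columns \
        else features["proportion_female"].isna().to_numpy()
    frame = pd.DataFrame({"contig_id": features["contig_id"].to_numpy(),
                          "label": labels, "undefined": undefined})
    return ClassificationResult(frame, mode, params)


def classify_female_only(features: pd.DataFrame,
                         p_thresh: float) -> ClassificationResult:
    """Y iff proportion_female < p_thresh (strict)."""
    clf = ThresholdClassifier(p_max=p_thresh).fit()
    labels = clf.predict(features)
    return _result(features, labels, "female_only", {"p_thresh": p_thresh})


def classify_female_male(features: pd.DataFrame,
                         thresholds: Thresholds) -> ClassificationResult:
    """Y iff proportion_female < p_thresh and male_depth < c_thresh."""
    if thresholds.c_thresh is None:
        raise ValueError("female_male mode requires both p_thresh and c_thresh")
    clf = ThresholdClassifier(p_max=thresholds.p_thresh,
                              depth_max=thresholds.c_thresh).fit()
    labels = clf.predict(features)
    return _result(features, labels, "female_male",
                   {"p_thresh": thresholds.p_thresh,
                    "c_thresh": thresholds.c_thresh})


def fit_best_separator(features: pd.DataFrame,
                       truth_labels: Mapping[str, str] | pd.Series,
                       split: Sequence[float] = (0.16, 0.04, 0.80),
                       seed: int = 42,
                       C: float = 1.0,
                       ) -> tuple[LinearSeparatorClassifier, dict]:
    """Learn the best-fit linear separator from labeled contigs.

    Contigs are randomly partitioned into training (16%), test (4%) and
    validation (80%) sets; the separator is fit on the training set only and
    accuracy is reported on all three. Returns ``(separator, report)``.
    """
    split = tuple(float(s) for s in split)
    if len(split) != 3 or not math.isclose(sum(split), 1.0, abs_tol=1e-9):
        raise ValueError(f"split fractions must be three values summing to 1, "
                         f"got {split}")
    if isinstance(truth_labels, pd.Series):
        truth_labels = truth_labels.to_dict()
    missing = [cid for cid in features["contig_id"] if cid not in truth_labels]
    if missing:
        raise ValueError(f"contigs without truth labels: {missing[:5]}"
                         f"{'...' if len(missing) > 5 else ''}")
    labeled = features[~features.get("undefined",
                                     pd.Series(False, index=features.index))
                       .astype(bool)].reset_index(drop=True)
    n = len(labeled)
    if n < 10:
        raise ValueError(f"need at least 10 labeled contigs to fit a "
                         f"separator, got {n}")
    y = np.array([Y_LABEL if truth_labels[cid] == Y_LABEL else NONY_LABEL
                  for cid in labeled["contig_id"]])
    if len(np.unique(y)) < 2:
        raise ValueError("truth labels contain a single class; cannot fit "
                         "a linear separator")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_test = int(round(split[1] * n))
    idx_train = order[:n_train]
    idx_test = order[n_train:n_train + n_test]
    idx_val = order[n_train + n_test:]
    if len(np.unique(y[idx_train])) < 2:
        raise ValueError("random training split contains a single class; "
                         "re-run with a different seed or more labeled data")

    sep = LinearSeparatorClassifier(C=C, random_state=seed)
    sep.fit(labeled.iloc[idx_train], y[idx_train])

    def acc(idx: np.ndarray) -> float:
        if len(idx) == 0:
            return math.nan
        return float((sep.predict(labeled.iloc[idx]) == y[idx]).mean())

    report = {
        "n": n, "n_train": len(idx_train), "n_test": len(idx_test),
        "n_validation": len(idx_val), "seed": seed,
        "train_accuracy": acc(idx_train),
        "test_accuracy": acc(idx_test),
        "validation_accuracy": acc(idx_val),
        "weight_p": sep.weight_p_, "weight_c": sep.weight_c_,
        "intercept": sep.intercept_,
    }
    return sep, report


def classify_best(features: pd.DataFrame,
                  separator: LinearSeparatorClassifier) -> ClassificationResult:
    """Apply a fitted linear separator; boundary points are non-Y."""
    labels = separator.predict(features)
    return _result(features, labels, "best",
                   {"weight_p": separator.weight_p_,
                    "weight_c": separator.weight_c_,
                    "intercept": separator.intercept_})


def scatter_plot(features: pd.DataFrame, path: str | os.PathLike,
                 labels: Mapping[str, str] | pd.Series | None = None,
                 separator: LinearSeparatorClassifier | None = None,
                 title: str | None = None) -> None:
    """Diagnostic plot: one point per contig, x = proportion shared with
    female, y = male depth of coverage, with log-scaled marginal histograms
    and (optionally) the learned decision boundary as a dashed black line.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = features["proportion_female"].to_numpy(dtype=float) \
        if "proportion_female" in features.columns else np.empty(0)
    c = features["male_depth"].to_numpy(dtype=float) \
        if "male_depth" in features.columns else np.zeros_like(p)
    ok = ~(np.isnan(p) | np.isnan(c))
    p, c = p[ok], c[ok]

    if labels is not None:
        if isinstance(labels, pd.Series):
            labels = labels.to_dict()
        ids = features.loc[ok, "contig_id"] if "contig_id" in features.columns \
            else pd.Series([str(i) for i in range(len(p))])
        group = np.array([str(labels.get(cid, "unlabeled")) for cid in ids])
    else:
        group = np.array(["contig"] * len(p))

    fig = plt.figure(figsize=(7, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(5, 1), height_ratios=(1, 5),
                          wspace=0.05, hspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)

    for name in sorted(set(group)):
        sel = group == name
        ax.scatter(p[sel], c[sel], s=8, alpha=0.6, label=name)
    if len(p):
        bins_p = np.linspace(0, 1, 41)
        bins_c = np.linspace(0, max(float(c.max()), 1.0), 41)
        ax_top.hist([p[group == g] for g in sorted(set(group))],
                    bins=bins_p, stacked=True)
        ax_top.set_yscale("log")
        ax_right.hist([c[group == g] for g in sorted(set(group))],
                      bins=bins_c, stacked=True,
                      orientation="horizontal")
        ax_right.set_xscale("log")
        ax.legend(fontsize=7, loc="upper left")
    if separator is not None:
        a, b, d = separator.boundary_line()
        xs = np.linspace(0, 1, 200)
        if abs(b) > 1e-12:
            ys = -(a * xs + d) / b
            ax.plot(xs, ys, "k--", linewidth=1.2)
        else:
            ax.axvline(-d / a if abs(a) > 1e-12 else 0.0, color="k",
                       linestyle="--", linewidth=1.2)
    ax.set_xlabel("proportion shared with female")
    ax.set_ylabel("male depth of coverage")
    ax.set_xlim(-0.02, 1.02)
    if len(c):
        ax.set_ylim(-0.02 * c.max() - 0.1, 1.1 * c.max() + 1)
    plt.setp(ax_top.get_xticklabels(), visible=False)
    plt.setp(ax_right.get_yticklabels(), visible=False)
    if title:
        ax_top.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
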