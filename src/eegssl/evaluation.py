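"""Downstream emotion-classification evaluation.

Implements the evaluation protocol used throughout the package:
10-fold cross-validation with trial-level grouping (windows of one
trial never straddle folds — window-level splits leak within-trial
autocorrelation and inflate scores), accuracy and macro-F1 metrics,
valence/arousal quadrant labels for DEAP-style data, and Wilcoxon
signed-rank comparison of per-fold scores between methods with
Bonferroni correction.

The central object is :class:`LinearProbeEvaluation`: built from
per-window features (or raw windows plus a frozen encoder) and
labels, ``fit()`` runs the cross-validation and returns an
:class:`EvalReport` with per-fold metrics and a ``summary()`` table.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold

from .encoders import WindowEncoder

__all__ = [
    "EvalConfig", "EvalReport", "accuracy", "f1_per_class", "f1_macro",
    "make_va_labels", "LinearProbeEvaluation", "crossval_evaluate",
    "random_baseline_crossval", "permute_trial_labels", "wilcoxon_compare",
    "compare_methods",
]


# ---------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------

def _check_labels(pred, true):
    pred = np.asarray(pred).ravel()
    true = np.asarray(true).ravel()
    if pred.size == 0 or pred.size != true.size:
        raise ValueError("prediction and truth must be equal-length, non-empty")
    return pred, true


def accuracy(pred_labels, true_labels) -> float:
    """Fraction of correct predictions, (TP+TN)/(TP+TN+FP+FN) in the
    binary case."""
    pred, true = _check_labels(pred_labels, true_labels)
    return float(np.mean(pred == true))


def f1_per_class(pred_labels, true_labels, c) -> float:
    """One-vs-rest F1 = 2TP / (2TP + FP + FN) for class ``c``.

    When the class appears in neither truth nor prediction the ratio
    is 0/0; it is pinned to 0.0 (flagged by :func:`f1_macro` callers
    through the per-class vector).
    """
    pred, true = _check_labels(pred_labels, true_labels)
    tp = np.sum((pred == c) & (true == c))
    fp = np.sum((pred == c) & (true != c))
    fn = np.sum((pred != c) & (true == c))
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom > 0 else 0.0


def f1_macro(pred_labels, true_labels, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all ``n_classes`` classes."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    return float(np.mean([f1_per_class(pred_labels, true_labels, c)
                          for c in range(n_classes)]))


def make_va_labels(valence, arousal, threshold: float = 5.0):
    """Quadrant class from 0-10 valence/arousal ratings.

    ``class = 2 * [valence >= threshold] + [arousal >= threshold]``,
    i.e. 0 = low-V/low-A, 1 = low-V/high-A, 2 = high-V/low-A,
    3 = high-V/high-A. Ties (score == threshold) count as high.
    """
    v = np.asarray(valence, dtype=float)
    a = np.asarray(arousal, dtype=float)
    if np.any((v < 0) | (v > 10) | (a < 0) | (a > 10)):
        raise ValueError("valence/arousal scores must lie in [0, 10]")
    out = 2 * (v >= threshold).astype(int) + (a >= threshold).astype(int)
    return out if out.ndim else int(out)


def _fold_f1(pred, true) -> float:
    """Macro F1 over the classes observed in this fold.

    Small trial-grouped test folds need not contain every class;
    averaging over globally-defined classes would charge a perfect
    classifier a zero for each class the fold simply lacks. The
    per-fold macro therefore averages over classes present in the
    fold's truth or predictions.
    """
    classes = np.union1d(np.unique(pred), np.unique(true))
    return float(np.mean([f1_per_class(pred, true, c) for c in classes]))


# ---------------------------------------------------------------------
# cross-validated probing
# ---------------------------------------------------------------------

@dataclass
class EvalConfig:
    """Cross-validation protocol settings.

    ``label_fraction`` < 1 simulates scarce annotation: only that
    fraction of each fold's training windows (stratified by class)
    keeps its label for fitting the probe.
    """

    mode: str = "linear_probe"           # or "fine_tune"
    n_folds: int = 10
    label_scheme: str = "three_class"    # or "four_class_va"
    va_threshold: float = 5.0
    label_fraction: float = 1.0
    probe_c: float = 1.0                 # inverse L2 strength of the probe
    fine_tune_epochs: int = 10
    fine_tune_lr: float = 5e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not (0 < self.label_fraction <= 1):
            raise ValueError("label_fraction must be in (0, 1]")
        if self.mode not in ("linear_probe", "fine_tune"):
            raise ValueError(f"unknown mode {self.mode!r}")

    def fingerprint(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class EvalReport:
    """Per-fold downstream metrics for one method."""

    method: str
    fold_accuracy: np.ndarray    # percent
    fold_f1_macro: np.ndarray    # percent
    config_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.fold_accuracy = np.asarray(self.fold_accuracy, dtype=float)
        self.fold_f1_macro = np.asarray(self.fold_f1_macro, dtype=float)
        for arr in (self.fold_accuracy, self.fold_f1_macro):
            if np.any((arr < 0) | (arr > 100)):
                raise ValueError("per-fold metrics must lie in [0, 100]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracy.mean())

    @property
    def std_accuracy(self) -> float:
        return float(self.fold_accuracy.std(ddof=1))

    @property
    def mean_f1_macro(self) -> float:
        return float(self.fold_f1_macro.mean())

    @property
    def std_f1_macro(self) -> float:
        return float(self.fold_f1_macro.std(ddof=1))

    def summary(self) -> str:
        return "\n".join([
            f"Downstream evaluation: {self.method}",
            "=" * 40,
            f"folds                 {len(self.fold_accuracy)}",
            f"accuracy mean/std     {self.mean_accuracy:.2f} / "
            f"{self.std_accuracy:.2f} %",
            f"F1-macro mean/std     {self.mean_f1_macro:.2f} / "
            f"{self.std_f1_macro:.2f} %",
        ])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "fold_accuracy": self.fold_accuracy.tolist(),
            "fold_f1_macro": self.fold_f1_macro.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_f1_macro": self.mean_f1_macro,
            "std_f1_macro": self.std_f1_macro,
            "config_fingerprint": self.config_fingerprint,
        }


def _grouped_folds(y, groups, n_folds, seed):
    """Trial-grouped, class-stratified fold indices; audited for leaks."""
    y = np.asarray(y)
    groups = np.asarray(groups)
    # stratify on the trial's label, not the window's, so every fold's
    # training part contains all classes whenever trials allow it
    splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                    random_state=seed)
    folds = list(splitter.split(np.zeros_like(y), y, groups))
    for train_idx, test_idx in folds:
        overlap = set(groups[train_idx]) & set(groups[test_idx])
        if overlap:
            raise AssertionError(f"trials straddle folds: {sorted(overlap)}")
        if set(np.unique(y[train_idx])) != set(np.unique(y)):
            raise ValueError(
                "a class is absent from some training fold; use more "
                "trials per class or fewer folds")
    return folds


def _subsample_labels(idx, y, fraction, rng):
    if fraction >= 1.0:
        return idx
    keep = []
    for c in np.unique(y[idx]):
        c_idx = idx[y[idx] == c]
        n_keep = max(int(round(fraction * c_idx.size)), 1)
        keep.append(rng.choice(c_idx, size=n_keep, replace=False))
    return np.sort(np.concatenate(keep))


class LinearProbeEvaluation:
    """Cross-validated downstream classification of window features.

    Parameters
    ----------
    features : ndarray (n_windows, F) or raw windows (n, C, T)
        Precomputed features, or raw windows if ``encoder`` is given
        (the encoder then embeds every window; it stays frozen in
        ``linear_probe`` mode).
    labels : ndarray (n_windows,)
        Integer class labels per window.
    groups : ndarray (n_windows,)
        Trial identifier per window; folds never split a trial.
    config : EvalConfig
    encoder : WindowEncoder, optional
    method : str
        Name recorded in the report.
    """

    def __init__(self, features, labels, groups,
                 config: EvalConfig | None = None,
                 encoder: WindowEncoder | None = None,
                 method: str = "probe"):
        self.config = config or EvalConfig()
        self.labels = np.asarray(labels)
        self.groups = np.asarray(groups)
        self.method = method
        self.encoder = encoder
        self.raw = None
        if encoder is not None:
            self.raw = np.asarray(features, dtype=float)
            feats = encoder.encode_array(self.raw)
        else:
            if self.config.mode == "fine_tune":
                raise ValueError("fine_tune mode requires an encoder")
            feats = np.asarray(features, dtype=float)
            if feats.ndim != 2:
                raise ValueError("precomputed features must be 2-D")
        self.features = feats
        if not (len(self.features) == len(self.labels) == len(self.groups)):
            raise ValueError("features, labels, groups lengths differ")

    def _fine_tune_fold(self, train_idx, test_idx, rng) -> np.ndarray:
        """Unfreeze the encoder: clone it, train with a softmax head."""
        from .encoders import WindowEncoder as _WE
        from .nn.autodiff import Tensor
        from .nn.optim import Adam

        cfg = self.config
        classes = np.unique(self.labels)
        K = classes.size
        enc = _WE(self.encoder.config, self.encoder.input_shape)
        enc.load_state_dict(self.encoder.state_dict())
        D = enc.embedding_dim
        Wh = Tensor(np.zeros((K, D)), requires_grad=True)
        bh = Tensor(np.zeros((K, 1)), requires_grad=True)
        opt = Adam(enc.parameters() + [Wh, bh], lr=cfg.fine_tune_lr)
        y_local = np.searchsorted(classes, self.labels[train_idx])
        onehot = np.eye(K)[y_local].T                       # (K, n)
        order = np.arange(train_idx.size)
        for _ in range(cfg.fine_tune_epochs):
            rng.shuffle(order)
            for lo in range(0, order.size, 64):
                sel = order[lo:lo + 64]
                z = enc.forward(self.raw[train_idx[sel]])   # (D, B)
                logits = Wh @ z + bh                        # (K, B)
                ce = (logits.logsumexp(axis=0)
                      - (logits * Tensor(onehot[:, sel])).sum(axis=0)).mean()
                opt.zero_grad()
                ce.backward()
                opt.step()
        z_test = enc.encode_array(self.raw[test_idx])       # (m, D)
        scores = z_test @ Wh.data.T + bh.data.ravel()
        return classes[np.argmax(scores, axis=1)]

    def fit(self) -> EvalReport:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        folds = _grouped_folds(self.labels, self.groups, cfg.n_folds,
                               cfg.seed)
        acc, f1 = [], []
        for train_idx, test_idx in folds:
            train_idx = _subsample_labels(train_idx, self.labels,
                                          cfg.label_fraction, rng)
            if cfg.mode == "fine_tune":
                pred = self._fine_tune_fold(train_idx, test_idx, rng)
            else:
                clf = LogisticRegression(max_iter=2000, C=cfg.probe_c)
                clf.fit(self.features[train_idx], self.labels[train_idx])
                pred = clf.predict(self.features[test_idx])
            acc.append(100.0 * accuracy(pred, self.labels[test_idx]))
            f1.append(100.0 * _fold_f1(pred, self.labels[test_idx]))
        return EvalReport(method=self.method,
                          fold_accuracy=np.array(acc),
                          fold_f1_macro=np.array(f1),
                          config_fingerprint=cfg.fingerprint())


def crossval_evaluate(features, labels, groups,
                      config: EvalConfig | None = None,
                      encoder: WindowEncoder | None = None,
                      method: str = "probe") -> EvalReport:
    """Functional wrapper around :class:`LinearProbeEvaluation`."""
    return LinearProbeEvaluation(features, labels, groups, config,
                                 encoder, method).fit()


def random_baseline_crossval(labels, groups, n_classes: int,
                             config: EvalConfig | None = None,
                             seed: int = 0) -> EvalReport:
    """Uniform-random prediction through the same folds and metrics.

    This is the chance baseline: for balanced K-class data the mean
    CV accuracy converges to 100/K percent.
    """
    config = config or EvalConfig()
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    folds = _grouped_folds(labels, groups, config.n_folds, config.seed)
    acc, f1 = [], []
    for _, test_idx in folds:
        pred = rng.integers(0, n_classes, size=test_idx.size)
        acc.append(100.0 * accuracy(pred, labels[test_idx]))
        f1.append(100.0 * _fold_f1(pred, labels[test_idx]))
    return EvalReport(method="random-baseline",
                      fold_accuracy=np.array(acc),
                      fold_f1_macro=np.array(f1),
                      config_fingerprint=config.fingerprint())


def permute_trial_labels(labels, groups, rng: np.random.Generator
                         ) -> np.ndarray:
    """Permute labels between trials (constant within each trial).

    The permutation null: any model evaluated against these labels
    should score at chance.
    """
    labels = np.asarray(labels)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    trial_labels = np.array([labels[groups == g][0] for g in uniq])
    permuted = rng.permutation(trial_labels)
    out = np.empty_like(labels)
    for g, lab in zip(uniq, permuted):
        out[groups == g] = lab
    return out


# ---------------------------------------------------------------------
# method comparison
# ---------------------------------------------------------------------

def wilcoxon_compare(per_fold_scores_a, per_fold_scores_b
                     ) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired fold scores."""
    a = np.asarray(per_fold_scores_a, dtype=float)
    b = np.asarray(per_fold_scores_b, dtype=float)
    if a.size != b.size or a.size < 5:
        raise ValueError("need equal-length score vectors of length >= 5")
    if np.allclose(a, b):
        raise ValueError("degenerate comparison: all paired differences zero")
    stat, p = spstats.wilcoxon(a, b, alternative="two-sided")
    return float(stat), float(p)


def compare_methods(reports: dict[str, EvalReport],
                    metric: str = "fold_accuracy"):
    """All pairwise Wilcoxon tests with Bonferroni correction.

    Returns a pandas DataFrame (method_a, method_b, statistic, p,
    p_bonferroni). Pairs that cannot be tested (fewer than 5 folds,
    or all paired differences zero) are reported with NaN statistics
    rather than aborting the comparison table.
    """
    import pandas as pd

    names = list(reports)
    rows = []
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for a, b in pairs:
        try:
            stat, p = wilcoxon_compare(getattr(reports[a], metric),
                                       getattr(reports[b], metric))
        except ValueError:
            stat, p = float("nan"), float("nan")
        rows.append({"method_a": a, "method_b": b,
                     "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_bonferroni"] = np.minimum(df["p"] * len(df), 1.0)
    return df
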