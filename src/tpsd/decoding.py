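"""Time-resolved bootstrapped decoding of trial class from binned lick counts.

For every 0.067 s time bin, the lick count in that bin is the sole predictor
of a binary trial class (preferred vs nonpreferred stimulus, or FA vs CR
outcome).  An RBF-kernel support-vector classifier (scikit-learn defaults, no
hyperparameter tuning) is refit on many stratified 80/20 train/test splits to
produce a bootstrap distribution of test accuracies per bin per mouse, which
is pooled across mice into one grand distribution.  Chance is defined
empirically by a shuffled-label null: the same procedure with labels permuted
uniformly before each replicate.  Class imbalance is deliberately not
rebalanced, so the null concentrates near the majority-class fraction.

Because the per-bin feature takes only a handful of integer values, each fit
is run on the deduplicated (value, label) pairs with sample weights equal to
their multiplicities and gamma fixed to scikit-learn's 'scale' value computed
on the replicated training set.  This is mathematically the identical SVC
estimator (the dual problems coincide), just much faster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .performance import BEST_WINDOW_TRIALS, best_window_trials, score_session
from .records import SessionRecord, TrialRecord

__all__ = [
    "AccuracySummary",
    "DecodingResult",
    "bin_lick_counts",
    "decode_time_bin",
    "shuffled_null",
    "decode_session",
    "decoding_frame",
]

DEFAULT_BIN_WIDTH_S = 0.067
DEFAULT_EPOCH = (0.0, 3.0)
DEFAULT_N_BOOT = 10_000
DEFAULT_TRAIN_FRACTION = 0.8


def bin_lick_counts(
    trials: list[TrialRecord],
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial lick counts in uniform half-open bins.

    Returns a [trial x bin] integer matrix and the bin edges.  Row sums equal
    the number of in-epoch licks per trial (counts are conserved).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lo, hi = epoch
    n_bins = max(int(np.floor((hi - lo) / bin_width + 1e-9)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    mat = np.zeros((len(trials), n_bins), dtype=int)
    for i, t in enumerate(trials):
        x = t.lick_times
        x = x[(x >= edges[0]) & (x < edges[-1])]
        idx = np.floor((x - lo) / bin_width).astype(int)
        np.add.at(mat[i], np.clip(idx, 0, n_bins - 1), 1)
    return mat, edges


@dataclass(frozen=True)
class AccuracySummary:
    """Bootstrap accuracy distribution for one time bin."""

    mean: float
    q025: float
    q975: float
    accuracies: np.ndarray


def _svc_predict(x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray) -> np.ndarray:
    # Weighted-deduplication fit: exactly equivalent to SVC(kernel='rbf') on
    # the replicated points (duplicate points aggregate their box constraints).
    var = x_train.var()
    gamma = 1.0 / var if var > 0 else 1.0
    key = x_train * 2 + y_train
    uniq, counts = np.unique(key, return_counts=True)
    xu = (uniq // 2).astype(float).reshape(-1, 1)
    yu = uniq % 2
    if np.unique(yu).size < 2:
        # Single-class training set cannot occur with stratified splits, but
        # guard anyway: predict the lone class.
        return np.full(x_test.size, yu[0])
    clf = SVC(kernel="rbf", gamma=gamma)
    clf.fit(xu, yu, sample_weight=counts.astype(float))
    return clf.predict(x_test.astype(float).reshape(-1, 1))


def _stratified_split(
    idx0: np.ndarray, idx1: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for idx in (idx0, idx1):
        n = idx.size
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return np.concatenate(train_parts), np.concatenate(test_parts)


def _boot_accuracies(
    feature: np.ndarray,
    labels: np.ndarray,
    n_boot: int,
    train_fraction: float,
    rng: np.random.Generator,
    shuffle: bool,
) -> np.ndarray:
    x = np.asarray(feature)
    y = np.asarray(labels).astype(np.int64)
    if x.ndim != 1 or x.size != y.size:
        raise ValueError("feature and labels must be 1-D arrays of equal length")
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    if min(np.count_nonzero(y == 0), np.count_nonzero(y == 1)) < 2:
        raise ValueError("need >= 2 trials per class")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    x = x.astype(np.int64)

    acc = np.empty(n_boot)
    for b in range(n_boot):
        yb = rng.permutation(y) if shuffle else y
        idx0 = np.flatnonzero(yb == 0)
        idx1 = np.flatnonzero(yb == 1)
        tr, te = _stratified_split(idx0, idx1, train_fraction, rng)
        pred = _svc_predict(x[tr], yb[tr], x[te])
        acc[b] = np.mean(pred == yb[te])
    return acc


def _summarize(acc: np.ndarray) -> AccuracySummary:
    return AccuracySummary(
        mean=float(acc.mean()),
        q025=float(np.quantile(acc, 0.025)),
        q975=float(np.quantile(acc, 0.975)),
        accuracies=acc,
    )


def decode_time_bin(
    feature: np.ndarray,
    labels: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> AccuracySummary:
    """Bootstrap accuracy distribution of the per-bin RBF-SVC decoder.

    Each replicate draws a class-stratified train/test split (so every test
    set contains both classes), fits the classifier on the scalar feature,
    and records test accuracy.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    return _summarize(_boot_accuracies(feature, labels, n_boot, train_fraction, rng, False))


def shuffled_null(
    feature: np.ndarray,
    labels: np.ndarray,
    n_boot: int = DEFAULT_N_BOOT,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> AccuracySummary:
    """Shuffled-label chance distribution: labels permuted before each replicate."""
    rng = np.random.default_rng(seed)
    return _summarize(_boot_accuracies(feature, labels, n_boot, train_fraction, rng, True))


@dataclass(frozen=True)
class DecodingResult:
    """Grand (across-mouse pooled) per-bin accuracy and null distributions."""

    bin_centers: np.ndarray
    accuracy_mean: np.ndarray
    acc_q025: np.ndarray
    acc_q975: np.ndarray
    null_mean: np.ndarray
    null_q025: np.ndarray
    null_q975: np.ndarray
    n_boot: int
    train_fraction: float
    outcome_variable: str
    n_mice: int
    classifier_params: dict = field(default_factory=dict)


def _labels_for(trials: list[TrialRecord], outcome_variable: str):
    if outcome_variable == "stimulus_type":
        keep = trials
        labels = np.array([t.stimulus_type == "preferred" for t in keep])
    elif outcome_variable == "trial_outcome":
        # Binary reduction: FA vs CR on nonpreferred trials.
        keep = [t for t in trials if t.stimulus_type == "nonpreferred"]
        labels = np.array([t.outcome == "FA" for t in keep])
    else:
        raise ValueError("outcome_variable must be 'stimulus_type' or 'trial_outcome'")
    return keep, labels


def decode_session(
    sessions: list[SessionRecord],
    outcome_variable: str = "stimulus_type",
    bin_width: float = DEFAULT_BIN_WIDTH_S,
    epoch: tuple[float, float] = DEFAULT_EPOCH,
    n_boot: int = DEFAULT_N_BOOT,
    train_fraction: float = DEFAULT_TRAIN_FRACTION,
    seed: int = 0,
    use_best_window: bool = True,
    window: int = BEST_WINDOW_TRIALS,
) -> DecodingResult:
    """Per-bin decoding for an ensemble of mice (one session each).

    Runs :func:`decode_time_bin` and :func:`shuffled_null` independently per
    bin per mouse and pools the bootstrap accuracies across mice into the
    grand per-bin distribution.  Mice missing one of the two classes are
    skipped with a warning.
    """
    root = np.random.SeedSequence(seed)
    per_mouse: list[tuple[np.ndarray, np.ndarray]] = []  # (features matrix, labels)
    edges = None
    for s in sessions:
        if not s.is_scored:
            score_session(s)
        trials = s.trials
        if use_best_window and len({t.stimulus_type for t in trials}) == 2:
            trials = best_window_trials(trials, window=window)
        keep, labels = _labels_for(trials, outcome_variable)
        if labels.size == 0 or min((~labels).sum(), labels.sum()) < 2:
            warnings.warn(f"mouse {s.mouse_id}: missing a class; skipped", stacklevel=2)
            continue
        mat, edges = bin_lick_counts(keep, bin_width, epoch)
        per_mouse.append((mat, labels))
    if not per_mouse:
        raise ValueError("no mouse has both classes; cannot decode")
    n_bins = per_mouse[0][0].shape[1]

    acc_mean = np.empty(n_bins); acc_lo = np.empty(n_bins); acc_hi = np.empty(n_bins)
    nul_mean = np.empty(n_bins); nul_lo = np.empty(n_bins); nul_hi = np.empty(n_bins)
    streams = [child.spawn(2 * n_bins) for child in root.spawn(len(per_mouse))]
    for b in range(n_bins):
        pooled_acc, pooled_nul = [], []
        for (mat, labels), sub in zip(per_mouse, streams):
            pooled_acc.append(
                _boot_accuracies(mat[:, b], labels, n_boot, train_fraction,
                                 np.random.default_rng(sub[2 * b]), False)
            )
            pooled_nul.append(
                _boot_accuracies(mat[:, b], labels, n_boot, train_fraction,
                                 np.random.default_rng(sub[2 * b + 1]), True)
            )
        acc = np.concatenate(pooled_acc)
        nul = np.concatenate(pooled_nul)
        acc_mean[b], acc_lo[b], acc_hi[b] = acc.mean(), *np.quantile(acc, [0.025, 0.975])
        nul_mean[b], nul_lo[b], nul_hi[b] = nul.mean(), *np.quantile(nul, [0.025, 0.975])

    return DecodingResult(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        accuracy_mean=acc_mean, acc_q025=acc_lo, acc_q975=acc_hi,
        null_mean=nul_mean, null_q025=nul_lo, null_q975=nul_hi,
        n_boot=n_boot, train_fraction=train_fraction,
        outcome_variable=outcome_variable, n_mice=len(per_mouse),
        classifier_params={"kernel": "rbf", "C": 1.0, "gamma": "scale"},
    )


def decoding_frame(result: DecodingResult) -> pd.DataFrame:
    """Tidy per-bin decoding table."""
    c = result.bin_centers
    width = c[1] - c[0] if c.size > 1 else DEFAULT_BIN_WIDTH_S
    return pd.DataFrame(
        {
            "bin_start": c - 0.5 * width,
            "accuracy_mean": result.accuracy_mean,
            "acc_q025": result.acc_q025,
            "acc_q975": result.acc_q975,
            "null_mean": result.null_mean,
            "null_q025": result.null_q025,
            "null_q975": result.null_q975,
            "n_mice": result.n_mice,
        }
    )
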