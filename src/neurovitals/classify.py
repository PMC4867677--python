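"""Expert-independent response verification with a radial-kernel SVM.

Single-run, trial-averaged waveforms from all three scalp electrodes are
concatenated into one feature vector per condition per run. A two-class
SVM (RBF kernel) is trained to separate the stimulus conditions
(standard vs deviant tones for N100/P300; congruent vs incongruent
targets for N400) under stratified 10-fold cross-validation: 90% of the
data train the classifier, the held-out 10% test it, rotating until
every observation has been tested exactly once. Accuracy, true/false
positive rates, sensitivity and specificity come from the pooled
confusion matrix, and significance from a permutation test that
redistributes the class labels in the training sets.

Leakage controls: per-feature standardization is fit on training folds
only, and the two observations of one run always share a fold (their
residual noise is correlated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ERPWaveform, SCALP_CHANNELS

#: Conditions of each classification problem, ordered (negative, positive).
PROBLEMS = {
    "tones": ("standard", "deviant"),
    "words": ("congruent", "incongruent"),
}
#: The rare / violation condition counts as "positive" in the confusion matrix.
POSITIVE_LABELS = {"deviant", "incongruent"}

DEFAULT_DECIMATE = 5


@dataclass
class FeatureObservation:
    """One run's trial-averaged waveform for one condition, flattened."""

    vector: np.ndarray
    label: str
    participant: str
    run: int

    @property
    def group_key(self) -> tuple[str, int]:
        return (self.participant, self.run)


@dataclass
class ClassificationResult:
    confusion: np.ndarray  # rows true (neg, pos), cols predicted (neg, pos)
    accuracy: float  # percent
    tp_rate: float
    fp_rate: float
    sensitivity: float
    specificity: float
    fold_assignments: dict[tuple[str, int], int]
    permutation_p: float | None = None
    labels: tuple[str, str] = ("negative", "positive")

    def to_dict(self) -> dict:
        return {
            "accuracy_percent": self.accuracy,
            "true_positive": self.tp_rate,
            "false_positive": self.fp_rate,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": self.confusion.tolist(),
            "labels": list(self.labels),
            "permutation_p": self.permutation_p,
        }


def build_features(
    run_averages: list[tuple[str, int, dict[str, ERPWaveform]]],
    problem: str = "tones",
    decimate: int = DEFAULT_DECIMATE,
) -> list[FeatureObservation]:
    """Flatten per-run conditional averages into labelled feature vectors.

    ``run_averages`` holds (participant, run, {condition: waveform}).
    Runs missing either condition contribute no observations. Channel
    order is fixed Fz, Cz, Pz; decimation keeps every ``decimate``-th
    sample (501 samples at factor 5 -> 101 per channel).
    """
    if problem not in PROBLEMS:
        raise ValueError(f"unknown problem {problem!r}")
    if decimate < 1:
        raise ValueError("decimate must be >= 1")
    neg, pos = PROBLEMS[problem]
    obs: list[FeatureObservation] = []
    for participant, run, averages in run_averages:
        if neg not in averages or pos not in averages:
            continue
        for label in (neg, pos):
            wave = averages[label]
            parts = [wave.get(ch)[::decimate] for ch in SCALP_CHANNELS]
            obs.append(
                FeatureObservation(
                    vector=np.concatenate(parts),
                    label=label,
                    participant=participant,
                    run=run,
                )
            )
    lengths = {o.vector.size for o in obs}
    if len(lengths) > 1:
        raise ValueError("inconsistent feature vector lengths across runs")
    return obs


def _assign_folds(
    observations: list[FeatureObservation], folds: int, rng: np.random.Generator
) -> dict[tuple[str, int], int]:
    """Round-robin runs into folds after a seeded shuffle.

    Because every run contributes exactly one observation per class,
    grouping by run yields folds that are both disjoint and
    class-balanced (stratified).
    """
    keys = sorted({o.group_key for o in observations})
    order = rng.permutation(len(keys))
    return {keys[idx]: int(i % folds) for i, idx in enumerate(order)}


def _prepare_folds(observations, folds, rng):
    """Precompute standardized train/test matrices per fold.

    Standardization parameters are label-independent and fit on the
    training folds only, so they can be shared across label permutations.
    """
    assignment = _assign_folds(observations, folds, rng)
    X = np.stack([o.vector for o in observations])
    y = np.array([1 if o.label in POSITIVE_LABELS else 0 for o in observations])
    fold_of = np.array([assignment[o.group_key] for o in observations])
    prepared = []
    for f in range(folds):
        test = fold_of == f
        train = ~test
        if not test.any():
            continue
        if len(np.unique(y[train])) < 2:
            raise ValueError("degenerate fold: single-class training set")
        scaler = StandardScaler().fit(X[train])
        prepared.append(
            {
                "Xtr": scaler.transform(X[train]),
                "Xte": scaler.transform(X[test]),
                "ytr": y[train],
                "yte": y[test],
            }
        )
    return assignment, prepared, y


def _pooled_confusion(prepared, C: float, permute_rng=None) -> np.ndarray:
    """Train per fold, test on held-out data, pool the confusion matrix.

    When ``permute_rng`` is given, training labels are shuffled within
    each fold's training set (the permutation-test null).
    """
    conf = np.zeros((2, 2), dtype=int)
    for fold in prepared:
        ytr = fold["ytr"]
        if permute_rng is not None:
            ytr = permute_rng.permutation(ytr)
        clf = SVC(kernel="rbf", C=C, gamma="scale")
        clf.fit(fold["Xtr"], ytr)
        pred = clf.predict(fold["Xte"])
        for truth, p in zip(fold["yte"], pred):
            conf[truth, p] += 1
    return conf


def _metrics(conf: np.ndarray) -> dict[str, float]:
    tn, fp = conf[0]
    fn, tp = conf[1]
    total = conf.sum()
    return {
        "accuracy": 100.0 * (tp + tn) / total,
        "sensitivity": tp / (tp + fn) if (tp + fn) else float("nan"),
        "specificity": tn / (tn + fp) if (tn + fp) else float("nan"),
        "fp_rate": fp / (fp + tn) if (fp + tn) else float("nan"),
    }


def crossval_svm(
    observations: list[FeatureObservation],
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """Stratified k-fold cross-validated SVM classification."""
    _check_observations(observations, folds)
    rng = np.random.default_rng(seed)
    assignment, prepared, _ = _prepare_folds(observations, folds, rng)
    conf = _pooled_confusion(prepared, C)
    m = _metrics(conf)
    neg, pos = _label_pair(observations)
    return ClassificationResult(
        confusion=conf,
        accuracy=m["accuracy"],
        tp_rate=m["sensitivity"],
        fp_rate=m["fp_rate"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        fold_assignments=assignment,
        labels=(neg, pos),
    )


def permutation_test(
    observations: list[FeatureObservation],
    n_perm: int = 1000,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, float, np.ndarray]:
    """Permutation significance of the cross-validated accuracy.

    Each permutation redistributes class labels within the training sets
    (fold structure and test labels untouched), yielding a null accuracy
    distribution. Returns (p, observed accuracy %, null accuracies %)
    with the +1 Monte-Carlo correction:
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    _check_observations(observations, folds)
    rng = np.random.default_rng(seed)
    _, prepared, _ = _prepare_folds(observations, folds, rng)
    observed = _metrics(_pooled_confusion(prepared, C))["accuracy"]
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _metrics(_pooled_confusion(prepared, C, permute_rng=rng))["accuracy"]
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return float(p), float(observed), null


def classify_with_permutation(
    observations: list[FeatureObservation],
    folds: int = 10,
    n_perm: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationResult:
    """Cross-validated classification plus permutation p, sharing folds."""
    result = crossval_svm(observations, folds=folds, seed=seed, C=C)
    p, _, _ = permutation_test(observations, n_perm=n_perm, folds=folds, seed=seed, C=C)
    result.permutation_p = p
    return result


def _label_pair(observations) -> tuple[str, str]:
    labels = sorted({o.label for o in observations})
    pos = [l for l in labels if l in POSITIVE_LABELS]
    neg = [l for l in labels if l not in POSITIVE_LABELS]
    if len(labels) != 2 or len(pos) != 1:
        raise ValueError(f"expected one positive and one negative label, got {labels}")
    return neg[0], pos[0]


def _check_observations(observations, folds):
    if not observations:
        raise ValueError("no observations")
    _label_pair(observations)  # validates the label alphabet
    per_class = min(
        sum(o.label in POSITIVE_LABELS for o in observations),
        sum(o.label not in POSITIVE_LABELS for o in observations),
    )
    if per_class < folds:
        raise ValueError(f"need >= {folds} observations per class, have {per_class}")
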