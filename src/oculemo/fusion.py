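"""Feature-level / decision-level fusion, classification and evaluation.

Feature-level fusion (FLF) concatenates the time-frequency vector with the
11 time-domain features and trains one polynomial-kernel SVM.  Decision-
level fusion (DLF) trains four SVMs — one per feature group (time-frequency,
saccade, fixation, pupil) — and combines their calibrated per-class
posteriors with the *maximal rule*: the predicted class is the one whose
maximum posterior across classifiers is largest.

Evaluation uses repeated k-fold cross-validation (default 10 repetitions of
6 folds): each repetition freshly shuffles the samples into equally sized
segments and every segment serves once as the test set.  Reported metrics
are the mean accuracy over repetitions, the pooled confusion matrix and the
macro-averaged F1 score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ValidationError
from .oculomotor import TimeDomainFeatures
from .types import EMOTIONS, Emotion

CLASS_ORDER = tuple(e.value for e in EMOTIONS)
_CLASS_INDEX = {label: i for i, label in enumerate(CLASS_ORDER)}

#: DLF feature groups: slices into the concatenated (tf + 11 td) layout.
DLF_GROUPS = ("tf", "saccade", "fixation", "pupil")


@dataclass
class TrialSample:
    """One trial's features and label."""

    tf: np.ndarray
    td: TimeDomainFeatures | np.ndarray
    label: Emotion | str
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.tf = np.asarray(self.tf, dtype=float).ravel()
        if isinstance(self.td, TimeDomainFeatures):
            self.td = self.td.vector()
        self.td = np.asarray(self.td, dtype=float).ravel()
        if self.td.size != 11:
            raise ValidationError(f"expected 11 time-domain values, got {self.td.size}")
        self.label = Emotion.coerce(self.label)

    @property
    def y(self) -> int:
        return _CLASS_INDEX[self.label.value]


def flf_concat(sample: TrialSample) -> np.ndarray:
    """Concatenate time-frequency then time-domain features (tf first)."""
    return np.concatenate([sample.tf, sample.td])


def validate_posteriors(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.size == 0:
        raise ValidationError("posterior matrix must be a nonempty Q x k matrix")
    if np.any(probs < -1e-12) or np.any(probs > 1 + 1e-12):
        raise ValidationError("posterior entries must lie in [0, 1]")
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValidationError("each classifier's posteriors must sum to 1")
    return probs


def dlf_maximal(posteriors: np.ndarray) -> int:
    """Maximal-rule fusion: argmax over classes of the per-class maximum
    posterior across classifiers; ties break toward the lowest class index."""
    probs = validate_posteriors(posteriors)
    return int(np.argmax(probs.max(axis=0)))


def _group_matrix(samples: list[TrialSample], group: str) -> np.ndarray:
    if group == "tf":
        return np.stack([s.tf for s in samples])
    sl = {"saccade": slice(0, 4), "fixation": slice(4, 8), "pupil": slice(8, 11)}[group]
    return np.stack([s.td[sl] for s in samples])


@dataclass
class ClassifierBundle:
    """Fitted model bundle for one fusion mode."""

    mode: str
    models: dict[str, Pipeline]

    def predict(self, samples: list[TrialSample]) -> np.ndarray:
        if self.mode == "flf":
            X = np.stack([flf_concat(s) for s in samples])
            return self.models["flf"].predict(X)
        post = self.posteriors(samples)
        return np.array([dlf_maximal(p) for p in post])

    def posteriors(self, samples: list[TrialSample]) -> np.ndarray:
        """(n_samples, Q, k) calibrated posteriors (DLF bundles only)."""
        if self.mode != "dlf":
            raise ValidationError("posteriors are only defined for DLF bundles")
        n, k = len(samples), len(CLASS_ORDER)
        out = np.zeros((n, len(DLF_GROUPS), k))
        for qi, group in enumerate(DLF_GROUPS):
            model = self.models[group]
            probs = model.predict_proba(_group_matrix(samples, group))
            # align predict_proba columns with the canonical class order
            for ci, cls in enumerate(model.classes_):
                out[:, qi, int(cls)] = probs[:, ci]
        # classes absent from training keep probability 0; renormalize
        out /= out.sum(axis=2, keepdims=True)
        return out


def fit_classifiers(
    train: list[TrialSample],
    mode: str = "flf",
    degree: int = 3,
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierBundle:
    """Fit the FLF classifier or the four DLF group classifiers.

    The SVMs use the inhomogeneous polynomial kernel (gamma x.y + 1)^degree;
    features are standardized with train-set statistics inside each
    pipeline.  DLF classifiers expose calibrated posteriors (pairwise
    sigmoid coupling fitted on the training fold).
    """
    if mode not in ("flf", "dlf"):
        raise ValidationError(f"mode must be 'flf' or 'dlf', got {mode!r}")
    y = np.array([s.y for s in train])
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain at least 2 classes")

    def make_svc(probability: bool) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        kernel="poly",
                        degree=degree,
                        C=C,
                        gamma="scale",
                        coef0=1.0,
                        probability=probability,
                        random_state=seed,
                    ),
                ),
            ]
        )

    if mode == "flf":
        model = make_svc(probability=False)
        model.fit(np.stack([flf_concat(s) for s in train]), y)
        return ClassifierBundle("flf", {"flf": model})
    models = {}
    with warnings.catch_warnings():
        # sklearn >= 1.9 deprecates SVC(probability=True) in favour of an
        # external calibrator; the pairwise-coupled sigmoid fit is exactly
        # the calibration we want, so silence the migration notice.
        warnings.simplefilter("ignore", FutureWarning)
        for group in DLF_GROUPS:
            model = make_svc(probability=True)
            model.fit(_group_matrix(train, group), y)
            models[group] = model
    return ClassifierBundle("dlf", models)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------

def make_folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Shuffle ``n`` indices into ``folds`` equal segments (remainder
    distributed round-robin over the first folds)."""
    if folds < 2 or folds > n:
        raise ValidationError(f"need 2 <= folds <= n, got folds={folds}, n={n}")
    perm = rng.permutation(n)
    sizes = np.full(folds, n // folds)
    sizes[: n % folds] += 1
    return list(np.split(perm, np.cumsum(sizes)[:-1]))


def macro_f1(confusion: np.ndarray) -> float:
    """Unweighted mean over classes of the per-class F1.

    precision_i = TP_i / column sum, recall_i = TP_i / row sum (rows are
    actual classes); a class with zero precision + recall contributes 0.
    """
    confusion = np.asarray(confusion, dtype=float)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(confusion.sum(axis=1) == 0):
        raise ValidationError("every class needs at least one actual sample")
    f1s = []
    for i in range(confusion.shape[0]):
        tp = confusion[i, i]
        col, row = confusion[:, i].sum(), confusion[i, :].sum()
        precision = tp / col if col > 0 else 0.0
        recall = tp / row
        if precision + recall == 0:
            f1s.append(0.0)
        else:
            f1s.append(2 * precision * recall / (precision + recall))
    return float(np.mean(f1s))


@dataclass
class CVReport:
    """Repeated k-fold cross-validation results."""

    mode: str
    accuracy_mean: float
    accuracy_per_rep: list[float]
    confusion: np.ndarray  # pooled counts over all repetitions
    macro_f1: float

    @property
    def confusion_row_percent(self) -> np.ndarray:
        totals = self.confusion.sum(axis=1, keepdims=True).astype(float)
        return 100.0 * self.confusion / np.where(totals == 0, 1, totals)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "accuracy_mean": self.accuracy_mean,
            "accuracy_per_rep": self.accuracy_per_rep,
            "macro_f1": self.macro_f1,
            "classes": list(CLASS_ORDER),
            "confusion_counts": self.confusion.tolist(),
            "confusion_row_percent": self.confusion_row_percent.round(2).tolist(),
        }

    def summary(self) -> str:
        lines = [
            f"{self.mode.upper()} repeated-CV report",
            f"  mean accuracy : {self.accuracy_mean:.4f}",
            f"  macro F1      : {self.macro_f1:.4f}",
            "  confusion (rows = actual, % of row):",
        ]
        pct = self.confusion_row_percent
        header = "            " + "".join(f"{c:>10}" for c in CLASS_ORDER)
        lines.append(header)
        for i, cls in enumerate(CLASS_ORDER):
            lines.append(
                f"  {cls:>10}" + "".join(f"{pct[i, j]:>10.2f}" for j in range(len(CLASS_ORDER)))
            )
        return "\n".join(lines)


def evaluate_cv(
    samples: list[TrialSample],
    mode: str = "flf",
    repetitions: int = 10,
    folds: int = 6,
    seed: int = 0,
    degree: int = 3,
    C: float = 1.0,
    _predictor=None,
) -> CVReport:
    """Repeated k-fold cross-validation of a fusion mode.

    Each repetition re-shuffles the samples (seeded) into ``folds`` equal
    segments; every segment serves once as the test set while the others
    train the bundle.  ``_predictor`` optionally replaces the fitted bundle
    with a callable ``(train, test) -> predicted indices`` (used for oracle
    and null-model checks).

    Returns a :class:`CVReport` with per-repetition accuracies, the pooled
    confusion matrix (rows = actual class) and its macro-F1.
    """
    n, k = len(samples), len(CLASS_ORDER)
    if folds > n:
        raise ValidationError(f"folds={folds} exceeds sample count {n}")
    confusion = np.zeros((k, k), dtype=int)
    acc_per_rep = []
    for rep in range(repetitions):
        rng = np.random.default_rng([int(seed), rep])
        correct = total = 0
        for test_idx in make_folds(n, folds, rng):
            test_mask = np.zeros(n, dtype=bool)
            test_mask[test_idx] = True
            train = [samples[i] for i in np.flatnonzero(~test_mask)]
            test = [samples[i] for i in test_idx]
            if _predictor is not None:
                pred = np.asarray(_predictor(train, test))
            else:
                bundle = fit_classifiers(train, mode, degree=degree, C=C, seed=seed)
                pred = bundle.predict(test)
            truth = np.array([s.y for s in test])
            for a, p in zip(truth, pred):
                confusion[a, p] += 1
            correct += int((pred == truth).sum())
            total += len(test)
        acc_per_rep.append(correct / total)
    return CVReport(
        mode=mode,
        accuracy_mean=float(np.mean(acc_per_rep)),
        accuracy_per_rep=[float(a) for a in acc_per_rep],
        confusion=confusion,
        macro_f1=macro_f1(confusion),
    )


def stimulus_score(ratings: list[float] | np.ndarray) -> float:
    """Normalized stimulus score: mean / sample standard deviation.

    Used to rank candidate emotion-induction clips by rater agreement-
    weighted intensity; scale-invariant by construction.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 1 or ratings.size < 2:
        raise ValidationError("need at least 2 ratings")
    sd = ratings.std(ddof=1)
    if sd == 0:
        raise ValidationError("ratings have zero standard deviation")
    return float(ratings.mean() / sd)
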