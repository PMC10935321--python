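"""Classifier training and evaluation protocols.

Three conventional models (SVM with RBF kernel, k-nearest neighbours,
random forest) evaluated under three protocols:

* ``loocv`` - leave-one-out cross-validation;
* ``holdout30`` - repeated stratified 70:30 hold-out ("T30"): 70% of each
  condition trains the model, the rest tests it, re-randomised 20 times;
  metrics are reported as mean +/- SD over repeats;
* ``subject_out_holdout`` - one subject is excluded entirely, the remaining
  subjects supply the 70:30 partition, and the held-out subject serves as
  genuinely new data (one fold per subject).

Problems: binary fear-happy (FH), fear-neutral (FN), happy-neutral (HN),
and the three-class HNF.  Feature scaling is always fit on the training
partition only (no leakage); partitions are shared across models for a
given seed so model comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import LeaveOneOut, StratifiedShuffleSplit
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

PROBLEMS = {"FH": ("fear", "happy"), "FN": ("fear", "neutral"),
            "HN": ("happy", "neutral"),
            "HNF": ("happy", "neutral", "fear")}
MODELS = ("svm", "knn", "rfo")


@dataclass
class EvalProtocol:
    scheme: str = "holdout30"     # loocv | holdout30 | subject_out_holdout
    repeats: int = 20
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class EvalResult:
    problem: str
    model: str
    scheme: str
    accuracy_mean: float          # percent
    accuracy_sd: float
    f1_mean: float                # percent, macro-averaged
    f1_sd: float
    confusion: np.ndarray         # summed over repeats/folds
    classes: list[str] = field(default_factory=list)
    per_fold_accuracy: np.ndarray = field(default_factory=lambda: np.empty(0))

    def as_dict(self) -> dict:
        return {
            "problem": self.problem, "model": self.model, "scheme": self.scheme,
            "accuracy_mean": self.accuracy_mean, "accuracy_sd": self.accuracy_sd,
            "f1_mean": self.f1_mean, "f1_sd": self.f1_sd,
            "classes": self.classes, "confusion": self.confusion.tolist(),
        }


def make_model(name: str, seed: int = 0):
    """Default hyperparameters, all overridable by constructing directly:
    SVM = RBF, C=1, gamma scaled by n_features*Var(x); KNN = 5 neighbours,
    Euclidean; RFO = 100 trees, sqrt(N) features per split."""
    name = name.lower()
    if name == "svm":
        clf = SVC(kernel="rbf", C=1.0, gamma="scale")
    elif name == "knn":
        clf = KNeighborsClassifier(n_neighbors=5)
    elif name == "rfo":
        clf = RandomForestClassifier(n_estimators=100, max_features="sqrt",
                                     random_state=seed)
    else:
        raise ValueError(f"unknown model {name!r}; use one of {MODELS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _subset(fm, selected, problem):
    classes = PROBLEMS[problem]
    mask = np.isin(fm.labels, classes)
    x = fm.df.loc[mask, list(selected)].to_numpy()
    y = fm.labels[mask]
    subjects = fm.obs.loc[mask, "subject_id"].to_numpy()
    return x, y, subjects, sorted(classes)


def _metrics(y_true, y_pred, classes):
    acc = 100.0 * accuracy_score(y_true, y_pred)
    f1 = 100.0 * f1_score(y_true, y_pred, labels=classes, average="macro",
                          zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    return acc, f1, cm


def evaluate(fm, selected, model: str = "rfo",
             protocol: EvalProtocol | None = None,
             problem: str = "HNF") -> EvalResult:
    """Evaluate one model under ``loocv`` or ``holdout30``."""
    protocol = protocol or EvalProtocol()
    if problem not in PROBLEMS:
        raise ValueError(f"unknown problem {problem!r}")
    x, y, _, classes = _subset(fm, selected, problem)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    missing = [c for c in PROBLEMS[problem] if c not in set(y)]
    if missing:
        raise ValueError(f"classes missing from the data: {missing}")

    if protocol.scheme == "loocv":
        preds = np.empty(y.shape, dtype=y.dtype)
        for tr, te in LeaveOneOut().split(x):
            clf = make_model(model, protocol.seed)
            clf.fit(x[tr], y[tr])
            preds[te] = clf.predict(x[te])
        acc, f1, cm = _metrics(y, preds, classes)
        return EvalResult(problem, model, "loocv", acc, 0.0, f1, 0.0, cm,
                          classes, np.array([acc]))

    if protocol.scheme != "holdout30":
        raise ValueError("use subject_out_evaluate for subject_out_holdout")
    accs, f1s = [], []
    cm_total = np.zeros((len(classes), len(classes)), int)
    splitter = StratifiedShuffleSplit(
        n_splits=protocol.repeats, train_size=protocol.train_fraction,
        random_state=protocol.seed)
    for tr, te in splitter.split(x, y):
        clf = make_model(model, protocol.seed)
        clf.fit(x[tr], y[tr])
        pred = clf.predict(x[te])
        a, f, cm = _metrics(y[te], pred, classes)
        accs.append(a)
        f1s.append(f)
        cm_total += cm
    accs, f1s = np.asarray(accs), np.asarray(f1s)
    return EvalResult(problem, model, "holdout30",
                      float(accs.mean()), float(accs.std()),
                      float(f1s.mean()), float(f1s.std()),
                      cm_total, classes, accs)


def subject_out_evaluate(fm, selected, model: str = "rfo",
                         protocol: EvalProtocol | None = None,
                         problem: str = "HNF") -> EvalResult:
    """Leave-one-subject-out variant of the hold-out test.

    For each held-out subject the remaining subjects supply a stratified
    70:30 partition (the 30% is simply not used for training, matching the
    protocol); the trained model is then tested on the held-out subject.
    Metrics are the mean +/- SD across subjects.
    """
    protocol = protocol or EvalProtocol(scheme="subject_out_holdout")
    x, y, subjects, classes = _subset(fm, selected, problem)
    uniq = np.unique(subjects)
    if uniq.size < 2:
        raise ValueError("subject-out evaluation needs >= 2 subjects")
    accs, f1s = [], []
    cm_total = np.zeros((len(classes), len(classes)), int)
    for k, subj in enumerate(uniq):
        test = subjects == subj
        xr, yr = x[~test], y[~test]
        seed = protocol.seed + k
        for attempt in range(10):
            sss = StratifiedShuffleSplit(n_splits=1,
                                         train_size=protocol.train_fraction,
                                         random_state=seed + 1000 * attempt)
            tr, _ = next(sss.split(xr, yr))
            if set(yr[tr]) == set(classes):
                break
        clf = make_model(model, protocol.seed)
        clf.fit(xr[tr], yr[tr])
        pred = clf.predict(x[test])
        a, f, cm = _metrics(y[test], pred, classes)
        accs.append(a)
        f1s.append(f)
        cm_total += cm
    accs, f1s = np.asarray(accs), np.asarray(f1s)
    return EvalResult(problem, model, "subject_out_holdout",
                      float(accs.mean()), float(accs.std()),
                      float(f1s.mean()), float(f1s.std()),
                      cm_total, classes, accs)


def results_table(results: list[EvalResult]) -> "pd.DataFrame":
    """Mean +/- SD grid (models x problems), mirroring a results table."""
    import pandas as pd

    rows = {}
    for r in results:
        rows.setdefault(r.model.upper(), {})[f"{r.problem} ({r.scheme})"] = \
            f"{r.accuracy_mean:.1f}±{r.accuracy_sd:.1f}"
    return pd.DataFrame.from_dict(rows, orient="index")
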