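"""Two-state classification and ground-truth artifact-removal metrics.

Classification follows the common vigilance protocol: per frequency band,
epochs from the alert and decrement windows are classified with five
standard classifiers (KNN, linear Discriminant Analysis, Gaussian Naive
Bayes, Decision Tree, RBF-SVM) under randomized, stratified 10-fold
cross-validation, reporting accuracy, sensitivity (recall on the
decrement class) and specificity (recall on the alert class) as mean +/-
sd over folds.  Feature standardization is fit on training folds only.

Removal metrics score a cleaned recording against simulator ground truth:
RMSE and mean per-channel correlation to the true neural mixture, the
fraction of artifact power left in the residual, and per-band PSD
distortion relative to the true neural spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import DEFAULT_BANDS, LabeledDataset
from .preproc import Recording
from .synthgen import SyntheticGroundTruth

CLASSIFIER_NAMES = ("KNN", "DA", "NB", "DT", "SVM")


class EvaluationError(ValueError):
    """Raised for invalid classification or scoring requests."""


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the five study classifiers with its fixed hyperparameters."""
    if name == "KNN":
        return KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    if name == "DA":
        return LinearDiscriminantAnalysis()
    if name == "NB":
        return GaussianNB()
    if name == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale")
    raise EvaluationError(f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}")


@dataclass
class CVReport:
    """Cross-validated two-state performance of one classifier on one band."""

    classifier: str
    band: str
    accuracy_mean: float
    accuracy_sd: float
    sensitivity_mean: float
    sensitivity_sd: float
    specificity_mean: float
    specificity_sd: float
    n_folds: int
    seed: int


def crossval_classify(
    ds: LabeledDataset, classifier: str = "SVM", k: int = 10, seed: int = 0
) -> CVReport:
    """Randomized stratified k-fold CV; every epoch is tested exactly once."""
    classes, counts = np.unique(ds.y, return_counts=True)
    if classes.size < 2:
        raise EvaluationError("dataset contains a single class; cannot cross-validate")
    if counts.min() < k:
        raise EvaluationError(
            f"need at least k={k} epochs per class, got {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    acc, sens, spec = [], [], []
    for train_idx, test_idx in skf.split(ds.x, ds.y):
        model = Pipeline(
            [("scale", StandardScaler()), ("clf", make_classifier(classifier, seed))]
        )
        model.fit(ds.x[train_idx], ds.y[train_idx])
        pred = model.predict(ds.x[test_idx])
        truth = ds.y[test_idx]
        acc.append(np.mean(pred == truth))
        pos = truth == 1
        neg = truth == 0
        sens.append(np.mean(pred[pos] == 1) if pos.any() else np.nan)
        spec.append(np.mean(pred[neg] == 0) if neg.any() else np.nan)
    acc, sens, spec = (100.0 * np.asarray(v, dtype=float) for v in (acc, sens, spec))
    return CVReport(
        classifier=classifier,
        band=ds.band.name,
        accuracy_mean=float(np.mean(acc)),
        accuracy_sd=float(np.std(acc, ddof=1)),
        sensitivity_mean=float(np.nanmean(sens)),
        sensitivity_sd=float(np.nanstd(sens, ddof=1)),
        specificity_mean=float(np.nanmean(spec)),
        specificity_sd=float(np.nanstd(spec, ddof=1)),
        n_folds=k,
        seed=seed,
    )


def run_all(
    datasets: dict[str, LabeledDataset],
    classifiers=CLASSIFIER_NAMES,
    k: int = 10,
    seed: int = 0,
) -> list[CVReport]:
    """Cross-validate the full band x classifier grid."""
    return [
        crossval_classify(datasets[band], clf, k=k, seed=seed)
        for band in datasets
        for clf in classifiers
    ]


def report_table(reports: list[CVReport]) -> pd.DataFrame:
    """Arrange reports as a metric x classifier table with one column per band."""
    bands = list(dict.fromkeys(r.band for r in reports))
    rows = []
    for metric in ("accuracy", "specificity", "sensitivity"):
        for r_clf in dict.fromkeys(r.classifier for r in reports):
            row = {"metric": metric, "classifier": r_clf}
            for band in bands:
                match = [r for r in reports if r.classifier == r_clf and r.band == band]
                if match:
                    m = match[0]
                    mean = getattr(m, f"{metric}_mean")
                    sd = getattr(m, f"{metric}_sd")
                    row[band] = f"{mean:.1f} +/- {sd:.1f}"
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ground-truth removal metrics
# ---------------------------------------------------------------------------

@dataclass
class RemovalMetrics:
    """How well a cleaned recording matches the simulator's true neural part."""

    method: str  # "ica_zero" | "wica" | free text
    rmse_to_neural: float  # microvolts
    corr_to_neural: float  # mean per-channel Pearson r
    residual_artifact_power_fraction: float  # ||cleaned - neural||^2 / ||artifact||^2
    band_psd_distortion: dict[str, float] = field(default_factory=dict)


def _mean_channel_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = np.sum(a * b, axis=1)
    den = np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
    valid = den > 0
    return float(np.mean(num[valid] / den[valid])) if valid.any() else 0.0


def score_removal(
    cleaned: Recording,
    truth: SyntheticGroundTruth,
    method: str = "",
    neural_reference: Recording | None = None,
    artifact_reference: Recording | None = None,
    bands=DEFAULT_BANDS,
) -> RemovalMetrics:
    """Score ``cleaned`` against ground truth.

    ``neural_reference``/``artifact_reference`` override the raw truth
    tracks when the comparison target should be the *filtered* (and
    edge-trimmed) mixtures — the cleaned data has been notch/band-pass
    filtered, so the fair reference is the same treatment applied to the
    true tracks.
    """
    neural = truth.neural if neural_reference is None else neural_reference
    artifact = truth.artifact if artifact_reference is None else artifact_reference
    if cleaned.data.shape != neural.data.shape:
        raise EvaluationError(
            f"shape mismatch: cleaned {cleaned.data.shape} vs neural {neural.data.shape}"
        )
    if cleaned.fs != neural.fs:
        raise EvaluationError("sampling-rate mismatch between cleaned and truth")
    resid = cleaned.data - neural.data
    rmse = float(np.sqrt(np.mean(resid**2)))
    corr = _mean_channel_corr(cleaned.data, neural.data)
    artifact_power = float(np.sum(artifact.data**2))
    residual_fraction = float(np.sum(resid**2) / artifact_power) if artifact_power > 0 else 0.0

    nper = min(neural.n_samples, 4096)
    f, p_clean = sp_signal.welch(cleaned.data, fs=cleaned.fs, nperseg=nper, axis=1)
    _, p_true = sp_signal.welch(neural.data, fs=neural.fs, nperseg=nper, axis=1)
    distortion = {}
    for band in bands:
        mask = (f >= band.lo) & (f < band.hi)
        true_power = p_true[:, mask].sum()
        if true_power > 0:
            distortion[band.name] = float(
                abs(p_clean[:, mask].sum() - true_power) / true_power
            )
    return RemovalMetrics(
        method=method,
        rmse_to_neural=rmse,
        corr_to_neural=corr,
        residual_artifact_power_fraction=residual_fraction,
        band_psd_distortion=distortion,
    )
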