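"""Locomotor classification bench.

Six classifier families (LDA, pruned CART, KNN, Gaussian naive Bayes,
linear-kernel SVM, random forest) are trained on extant specimens and
scored by repeated leave-group-out cross-validation: 200 stratified
75/25 train/test splits, recording overall accuracy and Cohen's Kappa
per repeat.  The best model per feature set is refitted on all extant
data and emits posterior locomotor-class probabilities for fossils.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CvSpec",
    "ClassifierReport",
    "FossilPrediction",
    "MODEL_FAMILIES",
    "DEFAULT_GRIDS",
    "make_model",
    "cohens_kappa",
    "lgocv_evaluate",
    "tune_svm_cost",
    "tune_rf",
    "fit_final_model",
    "predict_fossils",
]

MODEL_FAMILIES = ("LDA", "CART", "KNN", "NB", "SVM_linear", "RF")

# per-family default tuning grids; the SVM cost ladder and the RF grid
# are swept more widely by the dedicated tuning helpers
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "LDA": [{}],
    "CART": [{"ccp_alpha": a} for a in (0.0, 0.01, 0.02)],
    "KNN": [{"n_neighbors": k} for k in (3, 5, 7, 9)],
    "NB": [{}],
    "SVM_linear": [{"C": c} for c in (0.25, 0.5, 1.0, 2.0)],
    "RF": [{"n_estimators": 200, "max_features": m} for m in (2, 3)],
}

SVM_COST_LADDER = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0)
RF_TREE_GRID = (100, 200, 500, 1000, 2000)
RF_MTRY_GRID = (2, 3, 4, 5, 6)


@dataclass
class CvSpec:
    """Leave-group-out cross-validation settings: repeated random
    stratified splits into a 75% modelling and 25% prediction set."""

    repeats: int = 200
    train_fraction: float = 0.75
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.repeats < 1:
            raise ValueError("repeats must be positive")


@dataclass
class ClassifierReport:
    model_name: str
    best_params: dict
    accuracy_mean: float
    accuracy_ci95: tuple[float, float]
    kappa_mean: float
    kappa_ci95: tuple[float, float]
    per_repeat_metrics: np.ndarray  # repeats x 2 (accuracy, kappa)
    grid_results: list[dict] = field(default_factory=list)


@dataclass
class FossilPrediction:
    specimen_id: str
    posterior: dict[str, float]
    predicted_class: str


def make_model(model_name: str, params: dict, seed: int | None = None):
    """Instantiate one of the six classifier families."""
    if model_name == "LDA":
        return LinearDiscriminantAnalysis(**params)
    if model_name == "CART":
        return DecisionTreeClassifier(random_state=seed, **params)
    if model_name == "KNN":
        return KNeighborsClassifier(**params)
    if model_name == "NB":
        return GaussianNB(**params)
    if model_name == "SVM_linear":
        return SVC(kernel="linear", random_state=seed, **params)
    if model_name == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(f"unknown model family: {model_name!r}")


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's Kappa from a g x g confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed agreement and
    p_e the chance agreement from the marginals; if p_e = 1 (all mass
    in a single row/column pair) kappa is defined as 0 with a warning.
    """
    confusion = np.asarray(confusion, dtype=float)
    if np.any(confusion < 0):
        raise ValueError("confusion counts must be nonnegative")
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain observations")
    p_o = np.trace(confusion) / total
    p_e = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / total**2
    if p_e >= 1.0:
        warnings.warn("chance agreement is 1; kappa defined as 0", stacklevel=2)
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes)}
    m = np.zeros((classes.size, classes.size))
    for t, p in zip(y_true, y_pred):
        m[idx[t], idx[p]] += 1
    return m


def _splits(y: np.ndarray, cv: CvSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    n = y.shape[0]
    n_train = round(cv.train_fraction * n)
    if cv.stratified:
        splitter = StratifiedShuffleSplit(
            n_splits=cv.repeats, train_size=n_train, random_state=cv.seed
        )
        return [(tr, te) for tr, te in splitter.split(np.zeros(n), y)]
    rng = np.random.default_rng(cv.seed)
    classes = np.unique(y)
    out = []
    made = 0
    while made < cv.repeats:
        perm = rng.permutation(n)
        tr, te = perm[:n_train], perm[n_train:]
        if np.unique(y[tr]).size < classes.size:
            warnings.warn("training split missing a class; resampled", stacklevel=2)
            continue
        out.append((tr, te))
        made += 1
    return out


def lgocv_evaluate(
    x: np.ndarray,
    y,
    model_name: str,
    param_grid: list[dict] | None = None,
    cv: CvSpec | None = None,
) -> ClassifierReport:
    """Repeated leave-group-out evaluation of one classifier family.

    Every grid point is fitted on each of the ``cv.repeats`` stratified
    train splits and scored on the held-out quarter; the grid point
    with the highest mean accuracy wins and its per-repeat accuracy and
    Cohen's Kappa are reported with 95% percentile intervals.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    cv = cv or CvSpec()
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[model_name]
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise ValueError("every class needs at least two members")
    splits = _splits(y, cv)
    grid_results = []
    best = None
    for gi, params in enumerate(grid):
        metrics = np.empty((len(splits), 2))
        for si, (tr, te) in enumerate(splits):
            model = make_model(model_name, params, seed=cv.seed + 7919 * gi + si)
            model.fit(x[tr], y[tr])
            pred = model.predict(x[te])
            conf = _confusion(y[te], pred, classes)
            metrics[si, 0] = np.trace(conf) / conf.sum()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                metrics[si, 1] = cohens_kappa(conf)
        rec = {
            "params": params,
            "accuracy_mean": float(metrics[:, 0].mean()),
            "kappa_mean": float(metrics[:, 1].mean()),
        }
        grid_results.append(rec)
        if best is None or rec["accuracy_mean"] > best[0]["accuracy_mean"]:
            best = (rec, metrics)
    rec, metrics = best
    acc, kap = metrics[:, 0], metrics[:, 1]
    return ClassifierReport(
        model_name=model_name,
        best_params=rec["params"],
        accuracy_mean=float(acc.mean()),
        accuracy_ci95=(float(np.percentile(acc, 2.5)), float(np.percentile(acc, 97.5))),
        kappa_mean=float(kap.mean()),
        kappa_ci95=(float(np.percentile(kap, 2.5)), float(np.percentile(kap, 97.5))),
        per_repeat_metrics=metrics,
        grid_results=grid_results,
    )


def tune_svm_cost(
    x: np.ndarray,
    y,
    costs=SVM_COST_LADDER,
    cv: CvSpec | None = None,
) -> tuple[float, ClassifierReport]:
    """Sweep the linear-SVM cost ladder; ties go to the smaller cost."""
    costs = tuple(costs)
    if len(costs) < 2:
        raise ValueError("need at least two candidate costs")
    if any(c <= 0 for c in costs):
        raise ValueError("costs must be positive")
    report = lgocv_evaluate(
        x, y, "SVM_linear", [{"C": float(c)} for c in sorted(costs)], cv
    )
    return float(report.best_params["C"]), report


def tune_rf(
    x: np.ndarray,
    y,
    n_trees=RF_TREE_GRID,
    m_try=RF_MTRY_GRID,
    cv: CvSpec | None = None,
) -> tuple[dict, ClassifierReport]:
    """Full random-forest grid over tree count and per-split candidate
    variables; ties go to fewer trees, then smaller m_try."""
    x = np.asarray(x, dtype=float)
    if max(m_try) > x.shape[1]:
        raise ValueError("m_try exceeds the number of features")
    grid = [
        {"n_estimators": int(t), "max_features": int(m)}
        for t in sorted(n_trees)
        for m in sorted(m_try)
    ]
    report = lgocv_evaluate(x, y, "RF", grid, cv)
    return dict(report.best_params), report


def fit_final_model(x: np.ndarray, y, model_name: str, params: dict, seed: int = 0):
    """Refit the chosen family on all extant data, with class
    probabilities available.

    SVM posteriors come from Platt-style sigmoid calibration fitted by
    internal cross-validation; tree/forest posteriors are vote
    fractions; the rest expose probabilities natively.
    """
    model = make_model(model_name, params, seed=seed)
    if model_name == "SVM_linear":
        model = CalibratedClassifierCV(model, method="sigmoid", cv=5)
    model.fit(np.asarray(x, dtype=float), np.asarray(y))
    return model


def predict_fossils(fitted_model, fossil_features: np.ndarray, specimen_ids=None) -> list[FossilPrediction]:
    """Posterior locomotor-class probabilities for fossil specimens.

    Fossil features must already be in the training-time feature space
    (same transform metadata as the extant rows).
    """
    f = np.asarray(fossil_features, dtype=float)
    if f.ndim == 1:
        f = f[None, :]
    n_features = getattr(fitted_model, "n_features_in_", f.shape[1])
    if f.shape[1] != n_features:
        raise ValueError(
            f"fossil features have {f.shape[1]} columns; model expects {n_features}"
        )
    proba = fitted_model.predict_proba(f)
    classes = [str(c) for c in fitted_model.classes_]
    if specimen_ids is None:
        specimen_ids = [f"fossil_{i}" for i in range(f.shape[0])]
    out = []
    for sid, p in zip(specimen_ids, proba):
        posterior = {c: float(v) for c, v in zip(classes, p)}
        out.append(
            FossilPrediction(
                specimen_id=str(sid),
                posterior=posterior,
                predicted_class=classes[int(np.argmax(p))],
            )
        )
    return out
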