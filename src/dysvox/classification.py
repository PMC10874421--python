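"""Supervector fusion, PCA, SVM grid search and repeated stratified CV.

Evaluation protocol: stratified 10-fold cross-validation repeated 10 times.
Inside every training fold the supervectors are z-score normalized (train
statistics only), optionally PCA-reduced to 90% cumulative variance, and an
RBF-kernel SVM is grid-searched over C and gamma by inner 5-fold accuracy
before being refit on the whole training fold.  Accuracy is reported as
mean +/- SD over the repetitions; the selected hyperparameters are the mode
over all folds and repetitions, ties broken toward the smaller C and then
the smaller gamma.  The mixture size M is selected by an outer sweep that
keeps the best mean accuracy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .adaptation import FUSION_ORDER, Supervector

C_GRID = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0, 500.0, 1000.0)
GAMMA_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
M_GRID = (2, 4, 8, 16, 32, 64, 128)


@dataclass
class ExperimentSpec:
    """Configuration of one classification experiment."""

    task: str = "biclass"
    C_grid: tuple = C_GRID
    gamma_grid: tuple = GAMMA_GRID
    M_grid: tuple = M_GRID
    folds: int = 10
    repetitions: int = 10
    inner_folds: int = 5
    use_pca: bool = False
    var_kept: float = 0.90
    positive_class: str | None = None  # bi-class positive label (e.g. "PD")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (self.C_grid and self.gamma_grid and self.M_grid):
            raise ValueError("hyperparameter grids must be non-empty")


@dataclass
class CVResult:
    """Aggregated outcome of one repeated stratified CV experiment."""

    accuracy_mean: float  # %
    accuracy_sd: float  # % over repetitions
    sensitivity: float  # %
    specificity: float  # %
    confusion: np.ndarray  # pooled counts, rows = true classes
    classes: list[str]
    selected_C: float
    selected_gamma: float
    selected_M: int | None = None
    rep_accuracies: np.ndarray | None = None  # % per repetition
    scores: np.ndarray | None = None  # (reps, n) or (reps, n, n_classes)
    n_excluded: int = 0


# ---------------------------------------------------------------------------
# fusion and transforms
# ---------------------------------------------------------------------------

def fuse_supervectors(svs: dict[str, Supervector]) -> np.ndarray:
    """Early fusion: concatenate one recording's per-dimension supervectors
    in the fixed order articulation | phonation | prosody."""
    missing = [d for d in FUSION_ORDER if d not in svs]
    if missing:
        raise KeyError(f"missing dimension(s) for fusion: {missing}")
    return np.concatenate([svs[d].values for d in FUSION_ORDER])


def zscore_fit_apply(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize columns with training statistics; constant columns map to 0."""
    scaler = StandardScaler().fit(train)
    return scaler.transform(train), scaler.transform(test)


def pca_reduce(
    train: np.ndarray, test: np.ndarray, var_kept: float = 0.90
) -> tuple[np.ndarray, np.ndarray]:
    """Project onto the fewest train-fitted components reaching ``var_kept``
    cumulative explained variance."""
    n_max = min(train.shape[0], train.shape[1])
    pca = PCA(n_components=min(var_kept, 0.9999), svd_solver="full").fit(train)
    return pca.transform(train), pca.transform(test)


# ---------------------------------------------------------------------------
# SVM machinery (precomputed RBF kernels keep the full grid affordable)
# ---------------------------------------------------------------------------

def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    d = (A**2).sum(1)[:, None] - 2.0 * A @ B.T + (B**2).sum(1)[None, :]
    return np.maximum(d, 0.0)


def _make_svc(C: float, n_classes: int):
    svc = SVC(C=C, kernel="precomputed")
    return OneVsRestClassifier(svc) if n_classes > 2 else svc


def _grid_search(
    X: np.ndarray,
    y: np.ndarray,
    spec: ExperimentSpec,
    seed: int,
) -> tuple[float, float]:
    """Best (C, gamma) by mean inner-CV accuracy; ties -> smaller C, gamma.

    Inner scoring uses libsvm's native multiclass voting (a single fit per
    candidate), which ranks candidates identically in the binary case; the
    final per-fold model is refit one-vs-rest.
    """
    inner = StratifiedKFold(spec.inner_folds, shuffle=True, random_state=seed)
    splits = [
        (tr, te, y[tr], y[te]) for tr, te in inner.split(X, y)
    ]
    sq = _sq_dists(X, X)
    Cs = sorted(spec.C_grid)
    gammas = sorted(spec.gamma_grid)
    acc = np.zeros((len(Cs), len(gammas)))
    for j, gamma in enumerate(gammas):
        K = np.exp(-gamma * sq)
        kernels = [(K[np.ix_(tr, tr)], K[np.ix_(te, tr)]) for tr, te, *_ in splits]
        for i, C in enumerate(Cs):
            scores = []
            for (Ktr, Kte), (_, _, ytr, yte) in zip(kernels, splits):
                clf = SVC(C=C, kernel="precomputed")
                clf.fit(Ktr, ytr)
                scores.append(np.mean(clf.predict(Kte) == yte))
            acc[i, j] = np.mean(scores)
    best = np.argwhere(acc >= acc.max() - 1e-12)
    i, j = min(map(tuple, best))  # smallest C index, then smallest gamma index
    return Cs[i], gammas[j]


@dataclass
class SVMModel:
    """A fitted z-score (+ optional PCA) + RBF-SVM model for one training set."""

    scaler: StandardScaler
    pca: PCA | None
    clf: object
    X_ref: np.ndarray  # transformed training data (kernel reference)
    gamma: float
    classes: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(X)
        return self.pca.transform(Z) if self.pca is not None else Z

    def _kernel(self, X: np.ndarray) -> np.ndarray:
        return np.exp(-self.gamma * _sq_dists(self.transform(X), self.X_ref))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict(self._kernel(X))

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed distances to the separating hyperplane(s).

        Binary models return one score per sample whose sign matches the
        predicted class; multi-class models return one-vs-rest scores per
        class."""
        return self.clf.decision_function(self._kernel(X))


def fit_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    gamma: float,
    use_pca: bool = False,
    var_kept: float = 0.90,
) -> SVMModel:
    y = np.asarray(y)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = None
    if use_pca:
        pca = PCA(n_components=min(var_kept, 0.9999), svd_solver="full").fit(Z)
        Z = pca.transform(Z)
    clf = _make_svc(C, len(np.unique(y)))
    clf.fit(np.exp(-gamma * _sq_dists(Z, Z)), y)
    return SVMModel(scaler, pca, clf, Z, gamma, np.unique(y))


def decision_scores(model: SVMModel, X: np.ndarray) -> np.ndarray:
    return model.decision_scores(X)


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

def run_experiment(X: np.ndarray, y, spec: ExperimentSpec) -> CVResult:
    """Repeated stratified k-fold evaluation with per-fold nested selection.

    All transforms (z-score, PCA) and the (C, gamma) grid search are fitted
    strictly on each training fold.  Accuracy mean/SD are over repetitions;
    the confusion matrix pools every held-out prediction.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    counts = {c: int(np.sum(y == c)) for c in classes}
    for c, n in counts.items():
        if n < spec.folds:
            raise ValueError(f"class {c!r} has {n} samples, fewer than {spec.folds} folds")

    import sklearn

    rng = np.random.default_rng(spec.seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=spec.repetitions)
    rep_acc = np.zeros(spec.repetitions)
    pooled = np.zeros((len(classes), len(classes)), dtype=int)
    chosen: list[tuple[float, float]] = []
    n_classes = len(classes)
    binary = n_classes == 2
    scores = (
        np.zeros((spec.repetitions, len(y)))
        if binary
        else np.zeros((spec.repetitions, len(y), n_classes))
    )

    with sklearn.config_context(assume_finite=True):
        for r in range(spec.repetitions):
            skf = StratifiedKFold(
                spec.folds, shuffle=True, random_state=int(rep_seeds[r])
            )
            y_pred = np.empty(len(y), dtype=y.dtype)
            for f, (tr, te) in enumerate(skf.split(X, y)):
                Ztr, Zte = zscore_fit_apply(X[tr], X[te])
                if spec.use_pca:
                    Ztr, Zte = pca_reduce(Ztr, Zte, spec.var_kept)
                fold_seed = int((rep_seeds[r] + 7919 * f) % (2**31 - 1))
                C, gamma = _grid_search(Ztr, y[tr], spec, fold_seed)
                chosen.append((C, gamma))
                clf = _make_svc(C, n_classes)
                Ktr = np.exp(-gamma * _sq_dists(Ztr, Ztr))
                clf.fit(Ktr, y[tr])
                Kte = np.exp(-gamma * _sq_dists(Zte, Ztr))
                y_pred[te] = clf.predict(Kte)
                scores[r, te] = clf.decision_function(Kte)
            rep_acc[r] = 100.0 * np.mean(y_pred == y)
            pooled += confusion_matrix(y, y_pred, labels=classes)

    mode = _modal_params(chosen)
    sens, spec_pct = _sens_spec(pooled, classes, spec.positive_class)
    return CVResult(
        accuracy_mean=float(rep_acc.mean()),
        accuracy_sd=float(rep_acc.std(ddof=1)) if spec.repetitions > 1 else 0.0,
        sensitivity=sens,
        specificity=spec_pct,
        confusion=pooled,
        classes=classes,
        selected_C=mode[0],
        selected_gamma=mode[1],
        rep_accuracies=rep_acc,
        scores=scores,
    )


def _modal_params(chosen: list[tuple[float, float]]) -> tuple[float, float]:
    counts = Counter(chosen)
    top = max(counts.values())
    return min(p for p, c in counts.items() if c == top)


def sweep_m(
    X_by_m: dict[int, np.ndarray], y, spec: ExperimentSpec
) -> tuple[CVResult, dict[int, CVResult]]:
    """Run the experiment for each mixture size; keep the best mean accuracy."""
    results = {}
    for M in sorted(X_by_m):
        res = run_experiment(X_by_m[M], y, spec)
        res.selected_M = M
        results[M] = res
    best = max(results.values(), key=lambda r: (r.accuracy_mean, -r.selected_M))
    return best, results


# ---------------------------------------------------------------------------
# metrics and projections
# ---------------------------------------------------------------------------

def metrics_from_confusion(
    cm: np.ndarray, positive_index: int = 0
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) in % from a confusion matrix.

    Rows are true classes, columns predictions.  Binary matrices use the
    declared positive row; larger matrices report macro-averaged
    one-vs-rest sensitivity and specificity.
    """
    cm = np.asarray(cm, dtype=np.float64)
    if cm.size == 0:
        raise ValueError("empty confusion matrix")
    total = cm.sum()
    accuracy = 100.0 * np.trace(cm) / total
    if cm.shape[0] == 2:
        p, n = positive_index, 1 - positive_index
        sens = 100.0 * cm[p, p] / cm[p].sum() if cm[p].sum() else 0.0
        spec = 100.0 * cm[n, n] / cm[n].sum() if cm[n].sum() else 0.0
        return accuracy, sens, spec
    sens_list, spec_list = [], []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        sens_list.append(tp / (tp + fn) if tp + fn else 0.0)
        spec_list.append(tn / (tn + fp) if tn + fp else 0.0)
    return accuracy, 100.0 * np.mean(sens_list), 100.0 * np.mean(spec_list)


def _sens_spec(
    cm: np.ndarray, classes: list[str], positive_class: str | None
) -> tuple[float, float]:
    if len(classes) == 2:
        pos = classes.index(positive_class) if positive_class in classes else 0
        _, sens, spec = metrics_from_confusion(cm, positive_index=pos)
    else:
        _, sens, spec = metrics_from_confusion(cm)
    return sens, spec


def lda_project(X: np.ndarray, y) -> np.ndarray:
    """2-D linear-discriminant embedding for visualization.

    Two-class problems give one discriminant axis; the second coordinate is
    padded with zeros.  A singular within-class scatter falls back to the
    eigen solver with automatic shrinkage.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_classes = len(np.unique(y))
    n_comp = min(2, n_classes - 1)
    try:
        lda = LinearDiscriminantAnalysis(n_components=n_comp, solver="svd")
        Z = lda.fit_transform(X, y)
    except np.linalg.LinAlgError:
        lda = LinearDiscriminantAnalysis(
            n_components=n_comp, solver="eigen", shrinkage="auto"
        )
        Z = lda.fit_transform(X, y)
    if Z.shape[1] < 2:
        Z = np.hstack([Z, np.zeros((Z.shape[0], 2 - Z.shape[1]))])
    return Z


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_score_histogram(scores: np.ndarray, y, path) -> None:
    """Per-class histogram of SVM decision scores (binary models)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for c in np.unique(y):
        ax.hist(np.asarray(scores)[y == c], bins=25, alpha=0.6, label=str(c))
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("distance to the SVM hyperplane")
    ax.set_ylabel("count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_lda_scatter(coords: np.ndarray, y, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y)
    fig, ax = plt.subplots(figsize=(5, 4))
    for c in np.unique(y):
        pts = np.asarray(coords)[y == c]
        ax.scatter(pts[:, 0], pts[:, 1], s=14, alpha=0.7, label=str(c))
    ax.set_xlabel("LD 1")
    ax.set_ylabel("LD 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
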