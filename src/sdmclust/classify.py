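"""Classifiers and validation protocols for lymphocyte/lymphoblast calls.

Single models: the MLP of :mod:`sdmclust.mlp` and an RBF-kernel SVM
whose scaling factor sigma and soft-margin constant Co are tuned by
grid search over exponentially growing sequences with stratified 10-fold
cross-validation on the training partition only.  Ensembles combine
identically configured MLP base models (diversified by weight seed and
bootstrap resampling of the training rows) under nine fixed or trained
combination rules, including Dempster-Shafer evidence fusion.

Validation: class-balanced holdout at 75:25 / 50:50 / 25:75, stratified
k-fold cross-validation, and the .632 bootstrap
(acc_boot = mean_i [0.632 * acc_test_i + 0.368 * acc_orig_i]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from sdmclust.mlp import MlpConfig, MlpModel, train_mlp

COMBINERS = (
    "majority_voting",
    "min_probability",
    "max_probability",
    "distribution_summation",
    "average_of_probabilities",
    "product_of_probabilities",
    "bayesian_combination",
    "decision_templates",
    "dempster_shafer",
)


@dataclass
class SvmConfig:
    """RBF-kernel SVM; ``gamma = 1 / (2 sigma^2)`` links the kernel scaling
    factor sigma to the scikit-learn parameterisation."""

    sigma_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-4, 7))
    co_grid: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16))
    sigma: float | None = None
    co: float | None = None


@dataclass
class EnsembleConfig:
    n_base: int = 5
    base: MlpConfig = field(default_factory=lambda: MlpConfig(trainer="momentum_sgd"))
    combiner: str = "dempster_shafer"
    uncertainty_floor: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_base < 1:
            raise ValueError("n_base must be >= 1")
        if self.combiner not in COMBINERS:
            raise ValueError(f"unknown combiner {self.combiner!r}")


@dataclass
class BootstrapReport:
    b: int
    acc_test: np.ndarray
    acc_orig: np.ndarray
    acc_boot: float
    oob_fraction: float


# ---------------------------------------------------------------------------
# single models
# ---------------------------------------------------------------------------

def make_svm(sigma: float, co: float) -> SVC:
    return SVC(kernel="rbf", C=co, gamma=1.0 / (2.0 * sigma ** 2))


def grid_search_svm(X: np.ndarray, y: np.ndarray, cfg: SvmConfig | None = None,
                    folds: int = 10, seed: int = 0
                    ) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive (sigma, Co) search by stratified k-fold CV accuracy on the
    training rows only; ties resolved toward smaller Co, then smaller sigma."""
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel()
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("grid search needs two classes")
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few samples per class for cross-validation")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    rows = []
    for sigma in cfg.sigma_grid:
        for co in cfg.co_grid:
            accs = []
            for tr, va in splits:
                model = make_svm(sigma, co).fit(X[tr], y[tr])
                accs.append(float(np.mean(model.predict(X[va]) == y[va])))
            rows.append({"sigma": float(sigma), "co": float(co),
                         "cv_accuracy": float(np.mean(accs))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["cv_accuracy", "co", "sigma"],
                             ascending=[False, True, True]).iloc[0]
    return float(best["sigma"]), float(best["co"]), table


class SvmClassifier:
    """SVM with per-fit hyper-parameter tuning (unless fixed in the config)."""

    def __init__(self, cfg: SvmConfig | None = None, seed: int = 0, tune_folds: int = 10):
        self.cfg = cfg or SvmConfig()
        self.seed = seed
        self.tune_folds = tune_folds
        self.model: SVC | None = None
        self.sigma_: float | None = None
        self.co_: float | None = None

    def fit(self, X, y):
        if self.cfg.sigma is not None and self.cfg.co is not None:
            self.sigma_, self.co_ = self.cfg.sigma, self.cfg.co
        else:
            self.sigma_, self.co_, _ = grid_search_svm(
                X, y, self.cfg, folds=self.tune_folds, seed=self.seed)
        self.model = make_svm(self.sigma_, self.co_).fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict(X)


# ---------------------------------------------------------------------------
# combination rules
# ---------------------------------------------------------------------------

def _bpa_from_proba(p: np.ndarray, floor: float = 0.0) -> tuple[np.ndarray, float]:
    """Basic probability assignment of one model: singleton masses
    ``p_c * (1 - u)`` plus uncertainty mass ``u = 1 - max_c p_c``."""
    u = max(1.0 - float(np.max(p)), floor)
    return p * (1.0 - u), u


def dempster_fuse(bpas: list[tuple[np.ndarray, float]]) -> tuple[np.ndarray, float]:
    """Fuse BPAs over singleton classes + the frame Theta by Dempster's
    rule with conflict normalisation."""
    m, u = bpas[0]
    m = np.asarray(m, dtype=np.float64).copy()
    for m2, u2 in bpas[1:]:
        m2 = np.asarray(m2, dtype=np.float64)
        fused = m * m2 + m * u2 + u * m2
        fused_u = u * u2
        conflict = float(m.sum() * m2.sum() - np.sum(m * m2))
        norm = 1.0 - conflict
        if norm <= 0:
            raise ValueError("total conflict between evidence sources")
        m, u = fused / norm, fused_u / norm
    return m, u


def combine(probas: np.ndarray, combiner: str,
            confusions: np.ndarray | None = None,
            templates: np.ndarray | None = None,
            uncertainty_floor: float = 0.0) -> tuple[int, np.ndarray]:
    """Combine per-model class-probability vectors for one sample.

    ``probas`` has shape (n_models, n_classes), rows summing to 1.
    ``bayesian_combination`` needs per-model confusion matrices
    (n_models, n_classes, n_classes), indexed [predicted, true];
    ``decision_templates`` needs class templates
    (n_classes, n_models, n_classes).  Returns (decision, scores).
    """
    probas = np.asarray(probas, dtype=np.float64)
    if probas.ndim != 2:
        raise ValueError("probas must be (n_models, n_classes)")
    n_models, n_classes = probas.shape
    if combiner == "majority_voting":
        votes = np.bincount(np.argmax(probas, axis=1), minlength=n_classes).astype(float)
        top = votes == votes.max()
        scores = np.where(top, probas.sum(axis=0), -np.inf) if top.sum() > 1 else votes
        return int(np.argmax(scores)), votes / n_models
    if combiner == "min_probability":
        scores = probas.min(axis=0)
    elif combiner == "max_probability":
        scores = probas.max(axis=0)
    elif combiner == "distribution_summation":
        scores = probas.sum(axis=0)
    elif combiner == "average_of_probabilities":
        scores = probas.mean(axis=0)
    elif combiner == "product_of_probabilities":
        scores = probas.prod(axis=0)
    elif combiner == "bayesian_combination":
        if confusions is None:
            raise ValueError("bayesian_combination requires confusion matrices")
        preds = np.argmax(probas, axis=1)
        scores = np.ones(n_classes)
        for mi in range(n_models):
            cond = confusions[mi][preds[mi]].astype(np.float64)
            total = cond.sum()
            scores = scores * (cond / total if total > 0 else np.full(n_classes, 1.0 / n_classes))
    elif combiner == "decision_templates":
        if templates is None:
            raise ValueError("decision_templates requires class templates")
        dists = np.array([np.linalg.norm(probas - templates[c]) for c in range(n_classes)])
        scores = -dists
    elif combiner == "dempster_shafer":
        bpas = [_bpa_from_proba(probas[mi], uncertainty_floor) for mi in range(n_models)]
        masses, _ = dempster_fuse(bpas)
        scores = masses
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return int(np.argmax(scores)), scores


class EnsembleClassifier:
    """Bagged MLP ensemble with a pluggable combination rule.

    All base models share one topology; diversity comes from per-member
    weight seeds and bootstrap resampling of the training rows.  Fitting
    also records per-member training confusion matrices (for Bayesian
    combination) and class decision templates.
    """

    def __init__(self, cfg: EnsembleConfig | None = None):
        self.cfg = cfg or EnsembleConfig()
        self.members: list[MlpModel] = []
        self.confusions_: np.ndarray | None = None
        self.templates_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel().astype(int)
        root = np.random.SeedSequence(self.cfg.seed)
        member_seeds = root.generate_state(self.cfg.n_base) >> 1
        rng = np.random.default_rng(root.spawn(1)[0])
        n = X.shape[0]
        self.members = []
        for mi in range(self.cfg.n_base):
            if self.cfg.n_base > 1:
                while True:  # bootstrap resample keeping both classes
                    idx = rng.integers(0, n, size=n)
                    if np.unique(y[idx]).size == np.unique(y).size:
                        break
            else:
                idx = np.arange(n)
            cfg = MlpConfig(**{**self.cfg.base.__dict__, "seed": int(member_seeds[mi])})
            self.members.append(train_mlp(X[idx], y[idx], cfg))
        profiles = self._profiles(X)  # (n, n_models, 2)
        preds = np.argmax(profiles, axis=2)
        self.confusions_ = np.stack([
            confusion_matrix(preds[:, mi], y, labels=[0, 1]) for mi in range(self.cfg.n_base)
        ])
        self.templates_ = np.stack([profiles[y == c].mean(axis=0) for c in (0, 1)])
        return self

    def _profiles(self, X) -> np.ndarray:
        return np.stack([m.predict_proba(X) for m in self.members], axis=1)

    def predict(self, X) -> np.ndarray:
        profiles = self._profiles(np.asarray(X, dtype=np.float64))
        out = np.empty(profiles.shape[0], dtype=int)
        for i in range(profiles.shape[0]):
            out[i], _ = combine(profiles[i], self.cfg.combiner,
                                confusions=self.confusions_, templates=self.templates_,
                                uncertainty_floor=self.cfg.uncertainty_floor)
        return out


# ---------------------------------------------------------------------------
# model factory
# ---------------------------------------------------------------------------

def make_model(kind: str, seed: int = 0, **kwargs):
    """Factory used by the validation protocols: ``mlp``, ``svm`` or ``ds``
    (Dempster-Shafer MLP ensemble).  Extra kwargs feed the model config."""
    if kind == "mlp":
        cfg = kwargs.pop("cfg", None) or MlpConfig(seed=seed, **kwargs)
        return _FunctionalModel(lambda X, y: train_mlp(X, y, cfg))
    if kind == "svm":
        cfg = kwargs.pop("cfg", None) or SvmConfig(**kwargs)
        return SvmClassifier(cfg, seed=seed)
    if kind == "ds":
        cfg = kwargs.pop("cfg", None) or EnsembleConfig(seed=seed, combiner="dempster_shafer",
                                                        **kwargs)
        return EnsembleClassifier(cfg)
    raise ValueError(f"unknown model kind {kind!r}")


class _FunctionalModel:
    def __init__(self, fit_fn):
        self._fit_fn = fit_fn
        self._model = None

    def fit(self, X, y):
        self._model = self._fit_fn(X, y)
        return self

    def predict(self, X):
        return self._model.predict(X)


# ---------------------------------------------------------------------------
# validation protocols
# ---------------------------------------------------------------------------

SCHEMES = {"75:25": 0.75, "50:50": 0.50, "25:75": 0.25}


def holdout_eval(X: np.ndarray, y: np.ndarray, scheme: str, model_factory,
                 seed: int = 0) -> dict:
    """Class-balanced holdout: each class contributes the same train
    fraction; accuracy measured on the held-out rows."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    frac = SCHEMES[scheme]
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel().astype(int)
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        n_tr = int(round(frac * idx.size))
        if n_tr == 0 or n_tr == idx.size:
            raise ValueError(
                f"scheme {scheme} impossible for class {c} with {idx.size} samples; "
                f"achievable train sizes are 1..{idx.size - 1}")
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_tr])
        test_idx.extend(perm[n_tr:])
    train_idx, test_idx = np.array(train_idx), np.array(test_idx)
    model = model_factory(seed).fit(X[train_idx], y[train_idx])
    acc = float(np.mean(model.predict(X[test_idx]) == y[test_idx]))
    return {"scheme": scheme, "accuracy": acc,
            "n_train": int(train_idx.size), "n_test": int(test_idx.size)}


def kfold_cv(X: np.ndarray, y: np.ndarray, model_factory, k: int = 10,
             seed: int = 0) -> dict:
    """Stratified k-fold cross-validation accuracy."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel().astype(int)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class size {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_fold = []
    for fi, (tr, te) in enumerate(skf.split(X, y)):
        model = model_factory(seed + fi).fit(X[tr], y[tr])
        per_fold.append(float(np.mean(model.predict(X[te]) == y[te])))
    return {"k": k, "mean_accuracy": float(np.mean(per_fold)), "per_fold": per_fold}


def bootstrap_632(X: np.ndarray, y: np.ndarray, model_factory, b: int = 500,
                  seed: int = 0) -> BootstrapReport:
    """.632 bootstrap: n draws with replacement form the training set, the
    out-of-bag rows the test set; resamples with an empty out-of-bag set
    or a single-class training set are redrawn.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel().astype(int)
    n = X.shape[0]
    if n < 10:
        raise ValueError("bootstrap validation needs at least 10 samples")
    rng = np.random.default_rng(seed)
    acc_test = np.empty(b)
    acc_orig = np.empty(b)
    oob_sizes = np.empty(b)
    n_classes = np.unique(y).size
    for i in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 0 and np.unique(y[idx]).size == n_classes:
                break
        model = model_factory(seed + i).fit(X[idx], y[idx])
        acc_test[i] = float(np.mean(model.predict(X[oob]) == y[oob]))
        acc_orig[i] = float(np.mean(model.predict(X) == y))
        oob_sizes[i] = oob.size
    acc_boot = float(np.mean(0.632 * acc_test + 0.368 * acc_orig))
    return BootstrapReport(b=b, acc_test=acc_test, acc_orig=acc_orig,
                           acc_boot=acc_boot, oob_fraction=float(oob_sizes.mean() / n))
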