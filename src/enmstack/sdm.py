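"""Per-species niche models: four algorithm families behind one contract.

Presence cells are contrasted against uniformly drawn background cells, split
80/20 (stratified) into calibration and evaluation sets. Each algorithm
returns a suitability score in [0, 1]. Models are scored on the held-out 20%
by AUC (threshold-independent) and by TSS at the sensitivity–specificity
equality threshold; models with AUC < 0.75 or TSS < 0.3 — skill comparable to
a random prediction — are excluded from the downstream ensemble.

Algorithms: GLM = binomial logistic regression on linear + quadratic terms
(a linear logit cannot express the unimodal responses typical of climatic
niches); BRT = stagewise boosted shallow trees; RF = bagged randomized trees
with class-probability output; SVM = RBF-kernel classifier with Platt-scaled
probabilities. Hyperparameters are fixed, documented defaults — no per-species
tuning, so hundreds of species receive an identical treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC

from .climate import ClimateStack, OccurrenceSet

__all__ = [
    "ALGORITHMS",
    "ModelSpec",
    "EvalMetrics",
    "SuitabilityModel",
    "filter_rare_species",
    "make_background",
    "split_train_test",
    "fit_model",
    "auc",
    "tss",
    "equality_threshold",
    "evaluate",
]

ALGORITHMS = ("glm", "brt", "rf", "svm")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "glm": {"degree": 2, "max_iter": 2000},
    "brt": {"n_estimators": 300, "learning_rate": 0.05, "max_depth": 3},
    "rf": {"n_estimators": 500, "min_samples_leaf": 2},
    "svm": {"C": 1.0, "gamma": "scale"},
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm_id: str
    seed: int = 0
    hyperparams: tuple = ()  # (key, value) pairs; recorded, not tuned

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm_id!r}; choose from {ALGORITHMS}")

    def params(self) -> dict:
        p = dict(DEFAULT_HYPERPARAMS[self.algorithm_id])
        p.update(dict(self.hyperparams))
        return p


@dataclass
class EvalMetrics:
    auc: float
    tss: float
    threshold_eq: float
    passed: bool


class SuitabilityModel:
    """A fitted predictor mapping covariate vectors to scores in [0, 1]."""

    def __init__(self, spec: ModelSpec, estimator) -> None:
        self.spec = spec
        self._est = estimator

    def predict(self, x: np.ndarray) -> np.ndarray:
        scores = self._est.predict_proba(np.asarray(x, dtype=float))[:, 1]
        return np.clip(scores, 0.0, 1.0)

    def predict_raster(self, clim: ClimateStack, variables: list[str]) -> np.ndarray:
        return self.predict(clim.as_matrix(variables)).reshape(clim.grid_shape)


def filter_rare_species(occurrences: dict[str, OccurrenceSet], clim: ClimateStack,
                        min_records: int = 5) -> tuple[list[str], pd.DataFrame]:
    """Drop species with fewer than ``min_records`` unique presence cells.

    Records are collapsed to raster cells first, so the rule counts
    informative cells, not raw coordinates. Returns the retained species ids
    and a per-species log of counts.
    """
    if not occurrences:
        warnings.warn("no species supplied to filter_rare_species")
        return [], pd.DataFrame(columns=["species_id", "n_records", "n_cells", "retained"])
    rows = []
    retained = []
    for sid, occ in occurrences.items():
        cells = clim.coords_to_cells(occ.presences)
        n_cells = len(np.unique(cells, axis=0)) if len(cells) else 0
        keep = n_cells >= min_records
        rows.append({"species_id": sid, "n_records": occ.n_presence,
                     "n_cells": n_cells, "retained": keep})
        if keep:
            retained.append(sid)
    return retained, pd.DataFrame(rows)


def make_background(clim: ClimateStack, presences: np.ndarray, n_background: int,
                    seed: int = 0) -> np.ndarray:
    """Uniform random non-presence cells, without replacement.

    Returns (x_km, y_km) coordinates of the sampled cell centers.
    """
    if n_background < 0:
        raise ValueError("n_background must be >= 0")
    if n_background == 0:
        return np.empty((0, 2))
    pres_cells = clim.coords_to_cells(np.asarray(presences).reshape(-1, 2))
    mask = np.zeros(clim.grid_shape, dtype=bool)
    if len(pres_cells):
        mask[pres_cells[:, 0], pres_cells[:, 1]] = True
    candidates = np.flatnonzero(~mask.ravel())
    if len(candidates) < n_background:
        raise ValueError(
            f"only {len(candidates)} non-presence cells available, "
            f"{n_background} background points requested")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(candidates, size=n_background, replace=False)
    cells = np.column_stack(np.unravel_index(chosen, clim.grid_shape))
    return clim.cell_centers_km(cells)


def split_train_test(n: int, labels: np.ndarray, test_fraction: float = 0.2,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Single stratified random split: 80% calibration / 20% evaluation."""
    idx = np.arange(n)
    train, test = train_test_split(idx, test_size=test_fraction, random_state=seed,
                                   stratify=np.asarray(labels))
    return np.sort(train), np.sort(test)


def _build_estimator(spec: ModelSpec):
    p = spec.params()
    if spec.algorithm_id == "glm":
        return make_pipeline(
            StandardScaler(),
            PolynomialFeatures(degree=p["degree"], include_bias=False),
            LogisticRegression(penalty=None, max_iter=p["max_iter"]),
        )
    if spec.algorithm_id == "brt":
        return GradientBoostingClassifier(
            n_estimators=p["n_estimators"], learning_rate=p["learning_rate"],
            max_depth=p["max_depth"], random_state=spec.seed)
    if spec.algorithm_id == "rf":
        return RandomForestClassifier(
            n_estimators=p["n_estimators"], min_samples_leaf=p["min_samples_leaf"],
            random_state=spec.seed, n_jobs=1)
    if spec.algorithm_id == "svm":
        return make_pipeline(
            StandardScaler(),
            SVC(C=p["C"], gamma=p["gamma"], kernel="rbf", probability=True,
                random_state=spec.seed))
    raise AssertionError(spec.algorithm_id)


def fit_model(spec: ModelSpec, x: np.ndarray, y: np.ndarray) -> SuitabilityModel:
    """Fit one algorithm on presence(1)/background(0) training data."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training data contain a single class ({classes.tolist()}); "
            "both presences and background are required")
    est = _build_estimator(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # perfect-separation convergence chatter
        est.fit(x, y)
    return SuitabilityModel(spec, est)


def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) AUC; ties count one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if len(sp) == 0 or len(sb) == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(len(sp)), np.zeros(len(sb))])
    s = np.concatenate([sp, sb])
    if np.all(s == s[0]):
        return 0.5
    return float(roc_auc_score(y, s))


def tss(tp: int, fn: int, tn: int, fp: int) -> float:
    """True skill statistic: sensitivity + specificity - 1."""
    if tp + fn <= 0 or tn + fp <= 0:
        raise ValueError("need at least one observation in each class")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens + spec - 1.0


def _sens_spec(scores: np.ndarray, labels: np.ndarray, threshold: float) -> tuple[float, float]:
    pred = scores >= threshold
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    return sens, spec


def equality_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Score cutoff at which sensitivity and specificity are (most nearly)
    equal.

    Candidates are the sorted unique scores plus midpoints between
    consecutive unique scores. Ties on |sens - spec| break by larger TSS,
    then by smaller threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required to compute the equality threshold")
    uniq = np.unique(scores)
    if len(uniq) == 1:
        warnings.warn("constant scores; equality threshold is degenerate")
        return float(uniq[0])
    candidates = np.sort(np.concatenate([uniq, (uniq[:-1] + uniq[1:]) / 2.0]))
    best_t, best_gap, best_tss = None, np.inf, -np.inf
    for t in candidates:
        sens, spec = _sens_spec(scores, labels, t)
        gap = abs(sens - spec)
        t_tss = sens + spec - 1.0
        if (gap < best_gap - 1e-12
                or (abs(gap - best_gap) <= 1e-12 and t_tss > best_tss + 1e-12)):
            best_t, best_gap, best_tss = float(t), gap, t_tss
    return best_t


def evaluate(model: SuitabilityModel, x_test: np.ndarray, y_test: np.ndarray,
             auc_min: float = 0.75, tss_min: float = 0.3) -> EvalMetrics:
    """Held-out evaluation: AUC, equality threshold, TSS at that threshold,
    and the pass/fail flag for ensemble membership."""
    y_test = np.asarray(y_test, dtype=int)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set must contain both classes")
    scores = model.predict(x_test)
    a = auc(scores[y_test == 1], scores[y_test == 0])
    thr = equality_threshold(scores, y_test)
    pred = scores >= thr
    tp = int(np.sum(pred & (y_test == 1)))
    fn = int(np.sum(~pred & (y_test == 1)))
    tn = int(np.sum(~pred & (y_test == 0)))
    fp = int(np.sum(pred & (y_test == 0)))
    t = tss(tp, fn, tn, fp)
    return EvalMetrics(auc=a, tss=t, threshold_eq=thr,
                       passed=bool(a >= auc_min and t >= tss_min))
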