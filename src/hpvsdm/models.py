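"""Single-model fitting, TSS/ROC evaluation and ensemble construction.

Seven presence/absence algorithms are fitted per predictor-set variant:
random forest (RF), gradient boosting (GBM), a single classification tree
(CTA), a small feed-forward neural network (ANN), an adaptive hinge-basis
regression (MARS), a discriminant analysis on the same hinge basis (FDA)
and a surface range envelope (SRE). Every model is scored with the true
skill statistic, TSS = sensitivity + specificity - 1, maximized over a
fine threshold grid, and with the rank-based ROC AUC. Single models whose
TSS reaches the ensemble gate (0.7 by default) are combined into six
ensemble statistics: mean, TSS-weighted mean, median, committee averaging,
and the lower/upper bounds of the normal-approximation confidence interval
of the member mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .design import ModelMatrix

logger = logging.getLogger("hpvsdm")

ALGORITHMS = ("ANN", "CTA", "FDA", "GBM", "MARS", "RF", "SRE")

ENSEMBLE_METHODS = ("mean", "weighted_mean", "median", "committee_avg",
                    "ci_inf", "ci_sup")

#: TSS threshold a single model must reach to join an ensemble.
DEFAULT_ENSEMBLE_GATE = 0.7

#: Threshold grid for TSS optimization: 0, 0.001, ..., 1.
TSS_THRESHOLDS = np.round(np.linspace(0.0, 1.0, 1001), 3)


class EmptyEnsembleError(RuntimeError):
    """No single model passed the ensemble quality gate."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """One algorithm and its hyperparameters."""

    name: str
    hyperparameters: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.name!r}; "
                             f"choose from {ALGORITHMS}")
        hp = dict(self.hyperparameters)
        if self.name == "SRE":
            alpha = hp.get("alpha", 0.025)
            if not (0.0 <= alpha < 0.5):
                raise ValueError("SRE quantile alpha must be in [0, 0.5)")

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


@dataclass(frozen=True)
class ModelResult:
    """Evaluation record of one fitted (single or ensemble) model."""

    variant_label: str
    algorithm: str
    pa_set: int
    repetition: int
    group: str  # "single" | "ensemble"
    tss: float
    roc_auc: float
    threshold: float
    ensemble_method: str | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (-1.0 <= self.tss <= 1.0):
            raise ValueError(f"tss {self.tss} outside [-1, 1]")
        if not (0.0 <= self.roc_auc <= 1.0):
            raise ValueError(f"roc_auc {self.roc_auc} outside [0, 1]")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError(f"threshold {self.threshold} outside [0, 1]")


# ---------------------------------------------------------------------------
# Evaluation statistics
# ---------------------------------------------------------------------------

def _check_two_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("labels contain a single class; evaluation undefined")
    return labels


def evaluate_tss(scores, labels) -> tuple[float, float]:
    """Maximum TSS over the threshold grid and its (smallest) argmax.

    A case is predicted present when its score is >= the threshold.
    TSS(t) = sensitivity(t) + specificity(t) - 1.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    pred = scores[:, None] >= TSS_THRESHOLDS[None, :]
    tp = (pred & pos[:, None]).sum(axis=0)
    fp = (pred & ~pos[:, None]).sum(axis=0)
    tss = tp / n_pos + (n_neg - fp) / n_neg - 1.0
    best = int(np.argmax(tss))  # first (= smallest threshold) on ties
    return float(tss[best]), float(TSS_THRESHOLDS[best])


def evaluate_roc(scores, labels) -> float:
    """ROC AUC by the rank (Mann-Whitney) formulation, ties averaged."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    ranks = rankdata(scores)
    n_pos = int((labels == 1).sum())
    n_neg = len(labels) - n_pos
    rank_sum = float(ranks[labels == 1].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def classify_tss_quality(tss: float) -> str:
    """Verbal quality class of a TSS value.

    Below 0.4 is moderate at best, 0.4-0.6 good, above 0.6 very good, and
    from 0.7 the model qualifies for ensemble membership.
    """
    if not (-1.0 <= tss <= 1.0):
        raise ValueError(f"tss {tss} outside [-1, 1]")
    if tss < 0.4:
        return "moderate or below"
    if tss <= 0.6:
        return "good"
    if tss < 0.7:
        return "very good"
    return "ensemble-eligible"


# ---------------------------------------------------------------------------
# Single-model algorithms
# ---------------------------------------------------------------------------

@dataclass
class SREModel:
    """Surface range envelope: per-predictor presence quantile box.

    Predicts 1 iff every predictor value lies inside its envelope
    ``[q_alpha, q_(1-alpha)]`` of the training-presence values.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        inside = (X >= self.lower[None, :]) & (X <= self.upper[None, :])
        return inside.all(axis=1).astype(float)


def fit_sre(presence_X: np.ndarray, alpha: float = 0.025) -> SREModel:
    """Fit the envelope from presence rows only."""
    presence_X = np.asarray(presence_X, dtype=float)
    if presence_X.ndim != 2 or len(presence_X) < 2:
        raise ValueError("SRE needs at least 2 presence rows")
    if not (0.0 <= alpha < 0.5):
        raise ValueError("alpha must be in [0, 0.5)")
    lower = np.quantile(presence_X, alpha, axis=0)
    upper = np.quantile(presence_X, 1.0 - alpha, axis=0)
    return SREModel(lower, upper)


def _hinge_basis(X: np.ndarray, knots: list[np.ndarray]) -> np.ndarray:
    """Hinge expansion max(x-k, 0), max(k-x, 0) per feature and knot."""
    cols = [X]
    for j, ks in enumerate(knots):
        xj = X[:, j][:, None]
        cols.append(np.maximum(xj - ks[None, :], 0.0))
        cols.append(np.maximum(ks[None, :] - xj, 0.0))
    return np.hstack(cols)


@dataclass
class _BasisModel:
    """Linear model on a fixed hinge basis (MARS / FDA stand-ins)."""

    knots: list[np.ndarray]
    scaler: StandardScaler
    estimator: object

    def __call__(self, X: np.ndarray) -> np.ndarray:
        B = _hinge_basis(self.scaler.transform(np.asarray(X, float)), self.knots)
        return self.estimator.predict_proba(B)[:, 1]


@dataclass
class _SkModel:
    scaler: StandardScaler | None
    estimator: object

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class FittedModel:
    """A fitted scorer plus its bookkeeping."""

    spec: AlgorithmSpec
    scorer: object  # callable X -> probabilities in [0, 1]
    converged: bool = True
    result: ModelResult | None = None

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.scorer(X), 0.0, 1.0)


def fit_algorithm(spec: AlgorithmSpec, X: np.ndarray, y: np.ndarray
                  ) -> FittedModel:
    """Fit one algorithm and return a probability scorer.

    All stochastic learners are seeded from ``spec.seed``. A model that
    fails to converge is returned flagged (``converged=False``) so that
    ensemble construction can exclude it.
    """
    X = np.asarray(X, dtype=float)
    y = _check_two_classes(y)
    hp = spec.params
    seed = spec.seed
    converged = True

    if spec.name == "SRE":
        model = fit_sre(X[y == 1], alpha=hp.get("alpha", 0.025))
        return FittedModel(spec, model)

    if spec.name == "RF":
        est = RandomForestClassifier(
            **{"n_estimators": 200, "min_samples_leaf": 2, **hp},
            random_state=seed, n_jobs=1)
        est.fit(X, y)
        return FittedModel(spec, _SkModel(None, est))

    if spec.name == "GBM":
        est = GradientBoostingClassifier(
            **{"n_estimators": 150, "learning_rate": 0.1, "max_depth": 3,
               **hp}, random_state=seed)
        est.fit(X, y)
        return FittedModel(spec, _SkModel(None, est))

    if spec.name == "CTA":
        est = DecisionTreeClassifier(
            **{"min_samples_leaf": 10, **hp}, random_state=seed)
        est.fit(X, y)
        return FittedModel(spec, _SkModel(None, est))

    if spec.name == "ANN":
        scaler = StandardScaler().fit(X)
        est = MLPClassifier(
            **{"hidden_layer_sizes": (16,), "max_iter": 2000,
               "solver": "lbfgs", **hp},
            random_state=seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(scaler.transform(X), y)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught)
        if not converged:
            logger.warning("ANN did not converge; flagged for exclusion "
                           "from ensembles")
        return FittedModel(spec, _SkModel(scaler, est), converged=converged)

    # MARS / FDA: hinge-basis expansion, then a linear classifier
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    qs = hp.get("knot_quantiles", (0.25, 0.5, 0.75))
    knots = [np.unique(np.quantile(Xs[:, j], qs)) for j in range(X.shape[1])]
    B = _hinge_basis(Xs, knots)
    if spec.name == "MARS":
        est = LogisticRegression(C=hp.get("C", 1.0), max_iter=2000)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(B, y)
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught)
    else:  # FDA
        est = LinearDiscriminantAnalysis()
        est.fit(B, y)
    return FittedModel(spec, _BasisModel(knots, scaler, est),
                       converged=converged)


# ---------------------------------------------------------------------------
# Cross-validated fitting
# ---------------------------------------------------------------------------

@dataclass
class RepetitionFit:
    """Models and held-out evaluation data of one calibration split."""

    repetition: int
    train_idx: np.ndarray
    eval_idx: np.ndarray
    models: dict[str, FittedModel]


@dataclass
class CrossValidation:
    """All repetitions of one variant x pseudoabsence-set fit."""

    variant_label: str
    matrix: ModelMatrix
    pa_set: int
    repetitions: list[RepetitionFit]

    @property
    def results(self) -> list[ModelResult]:
        out = []
        for rep in self.repetitions:
            out.extend(m.result for m in rep.models.values()
                       if m.result is not None)
        return out


def cross_validate(variant_label: str, matrix: ModelMatrix,
                   algorithms=ALGORITHMS, n_repetitions: int = 3,
                   eval_fraction: float = 0.2, seed: int = 0,
                   pa_set: int = 0,
                   hyperparameters: dict | None = None) -> CrossValidation:
    """Stratified split / fit / held-out evaluation, repeated.

    For each repetition the cases are split into calibration and
    evaluation fractions stratified by the response; every algorithm is
    fitted on the calibration part and scored with TSS and ROC AUC on the
    held-out part.
    """
    if not (0.0 < eval_fraction <= 0.5):
        raise ValueError("eval_fraction must be in (0, 0.5]")
    X, y = matrix.X, matrix.y
    hyperparameters = hyperparameters or {}
    rng = np.random.default_rng(seed)
    reps: list[RepetitionFit] = []
    for rep in range(n_repetitions):
        split_seed = int(rng.integers(2 ** 31))
        idx_train, idx_eval = train_test_split(
            np.arange(len(y)), test_size=eval_fraction, stratify=y,
            random_state=split_seed)
        models: dict[str, FittedModel] = {}
        for name in algorithms:
            spec = AlgorithmSpec(
                name, tuple(sorted(hyperparameters.get(name, {}).items())),
                seed=int(rng.integers(2 ** 31)))
            fitted = fit_algorithm(spec, X[idx_train], y[idx_train])
            scores = fitted(X[idx_eval])
            tss, thr = evaluate_tss(scores, y[idx_eval])
            roc = evaluate_roc(scores, y[idx_eval])
            fitted.result = ModelResult(
                variant_label=variant_label, algorithm=name, pa_set=pa_set,
                repetition=rep, group="single", tss=tss, roc_auc=roc,
                threshold=thr, converged=fitted.converged)
            models[name] = fitted
        reps.append(RepetitionFit(rep, idx_train, idx_eval, models))
    return CrossValidation(variant_label, matrix, pa_set, reps)


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Combination of gate-passing single models by one statistic."""

    method: str
    members: list[FittedModel]

    def __post_init__(self) -> None:
        if self.method not in ENSEMBLE_METHODS:
            raise ValueError(f"unknown ensemble method {self.method!r}")
        if not self.members:
            raise EmptyEnsembleError("ensemble with zero members")

    def member_scores(self, X: np.ndarray) -> np.ndarray:
        return np.stack([m(X) for m in self.members])  # (m, n)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        S = self.member_scores(X)
        m = S.shape[0]
        if self.method == "mean":
            return S.mean(axis=0)
        if self.method == "weighted_mean":
            w = np.array([mm.result.tss for mm in self.members], dtype=float)
            w = w / w.sum()
            return np.einsum("m,mn->n", w, S)
        if self.method == "median":
            return np.median(S, axis=0)
        if self.method == "committee_avg":
            thr = np.array([mm.result.threshold for mm in self.members])
            return (S >= thr[:, None]).mean(axis=0)
        sd = S.std(axis=0, ddof=1) if m > 1 else np.zeros(S.shape[1])
        half = 1.96 * sd / np.sqrt(m)
        if self.method == "ci_inf":
            return np.clip(S.mean(axis=0) - half, 0.0, 1.0)
        return np.clip(S.mean(axis=0) + half, 0.0, 1.0)


def build_ensemble(cv: CrossValidation, gate: float = DEFAULT_ENSEMBLE_GATE,
                   methods=ENSEMBLE_METHODS
                   ) -> tuple[list[ModelResult], dict[tuple[int, str], EnsembleModel]]:
    """Build and evaluate the six ensemble statistics per repetition.

    Members are the converged single models of each repetition whose
    held-out TSS is >= ``gate``. Each ensemble is evaluated on the same
    held-out cases as its members. Raises :class:`EmptyEnsembleError` when
    no repetition has any gate-passing member.
    """
    results: list[ModelResult] = []
    ensembles: dict[tuple[int, str], EnsembleModel] = {}
    any_members = False
    X, y = cv.matrix.X, cv.matrix.y
    for rep in cv.repetitions:
        members = [m for m in rep.models.values()
                   if m.converged and m.result is not None
                   and m.result.tss >= gate]
        if not members:
            logger.info("variant %s repetition %d: no member passed the "
                        "TSS >= %.2f gate", cv.variant_label, rep.repetition,
                        gate)
            continue
        any_members = True
        Xe, ye = X[rep.eval_idx], y[rep.eval_idx]
        for method in methods:
            ens = EnsembleModel(method, members)
            scores = ens(Xe)
            tss, thr = evaluate_tss(scores, ye)
            roc = evaluate_roc(scores, ye)
            results.append(ModelResult(
                variant_label=cv.variant_label, algorithm=method,
                pa_set=cv.pa_set, repetition=rep.repetition,
                group="ensemble", tss=tss, roc_auc=roc, threshold=thr,
                ensemble_method=method))
            ensembles[(rep.repetition, method)] = ens
    if not any_members:
        raise EmptyEnsembleError(
            f"variant {cv.variant_label}: no single model reached the "
            f"TSS >= {gate} ensemble gate in any repetition")
    return results, ensembles


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Long-format results table, one row per ModelResult."""
    return pd.DataFrame([{
        "variant": r.variant_label, "algorithm": r.algorithm,
        "pa_set": r.pa_set, "repetition": r.repetition, "group": r.group,
        "ensemble_method": r.ensemble_method or "",
        "tss": r.tss, "roc_auc": r.roc_auc, "threshold": r.threshold,
        "converged": r.converged,
    } for r in results])
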