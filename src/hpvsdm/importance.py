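"""Meta-modelling of what drives model quality, via shadow features.

The long table of model evaluations is annotated with the attributes of
each predictor-set variant (algorithm, information capacity, minimal
recentness, number of time periods, single/ensemble group) and the TSS is
z-scored within the single and ensemble groups. A shadow-feature
random-forest procedure then classifies each attribute as Confirmed,
Tentative or Rejected: at every iteration a permuted "shadow" copy of
every attribute is appended, a random-forest regressor is fitted, and an
attribute scores a hit when its importance Z-score beats the best shadow;
hit counts are tested against Binomial(iterations, 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from sklearn.tree import DecisionTreeRegressor

from .history import VariantSpec
from .models import ModelResult, results_to_frame

logger = logging.getLogger("hpvsdm")

#: The meta-model candidate attributes, in registry order.
ATTRIBUTES = ("algorithm", "capacity_code", "minimal_recentness",
              "n_periods", "group")


@dataclass(frozen=True)
class AttributeImportance:
    name: str
    mean_z: float
    hits: int
    status: str  # Confirmed | Tentative | Rejected


@dataclass(frozen=True)
class ImportanceReport:
    attributes: tuple[AttributeImportance, ...]
    n_iterations: int
    p_value: float

    def status_of(self, name: str) -> str:
        for a in self.attributes:
            if a.name == name:
                return a.status
        raise KeyError(name)

    def mean_z_of(self, name: str) -> float:
        for a in self.attributes:
            if a.name == name:
                return a.mean_z
        raise KeyError(name)


def melt_results(results: list[ModelResult] | pd.DataFrame,
                 registry: dict[str, VariantSpec] | None = None
                 ) -> pd.DataFrame:
    """Annotate evaluations with variant attributes and standardize TSS.

    Returns one row per evaluation with columns ``tss``, the five
    attributes, and ``tss_std`` — the TSS z-scored separately within the
    single-model and ensemble groups.
    """
    table = results if isinstance(results, pd.DataFrame) \
        else results_to_frame(results)
    if registry is None:
        registry = {}
    rows = []
    for _, r in table.iterrows():
        label = r["variant"]
        spec = registry.get(label) or VariantSpec.parse(label)
        rows.append({
            "tss": float(r["tss"]),
            "algorithm": r["algorithm"],
            "capacity_code": spec.capacity_code,
            "minimal_recentness": str(spec.minimal_recentness),
            "n_periods": str(spec.n_periods),
            "group": r["group"],
        })
    melted = pd.DataFrame(rows)
    melted["tss_std"] = melted.groupby("group")["tss"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=0))
    return melted


def _one_hot(table: pd.DataFrame, attributes) -> tuple[np.ndarray, list[str]]:
    """Encode attributes for the forest: numeric pass through as single
    columns, categoricals are one-hot expanded. Returns (matrix, column
    owners) where owners maps each column back to its attribute."""
    blocks, owners = [], []
    for attr in attributes:
        col = table[attr]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.to_numpy(dtype=float)[:, None])
            owners.append(attr)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=attr)
            blocks.append(dummies.to_numpy(dtype=float))
            owners.extend([attr] * dummies.shape[1])
    return np.hstack(blocks), owners


def _forest_importance_z(X: np.ndarray, y: np.ndarray, n_trees: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Per-feature Z-scores from a bagged regression forest.

    Each tree is fitted on a bootstrap sample; its importance for a
    feature is the increase in out-of-bag mean squared error when that
    feature's column is permuted among the out-of-bag rows (a mean
    decrease in accuracy for regression). The Z-score is the mean over
    trees divided by the standard deviation over trees — so a feature
    unrelated to the response scores near zero, not merely low.
    """
    n, k = X.shape
    imps = []
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob_mask = np.ones(n, dtype=bool)
        oob_mask[boot] = False
        oob = np.flatnonzero(oob_mask)
        if len(oob) < 10:
            continue
        tree = DecisionTreeRegressor(
            max_features=max(1, k // 3), min_samples_leaf=5,
            random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[boot], y[boot])
        Xo, yo = X[oob], y[oob]
        m = len(oob)
        base = np.mean((yo - tree.predict(Xo)) ** 2)
        perm = rng.permutation(m)
        # one batched predict over all k single-feature permutations
        big = np.repeat(Xo[None, :, :], k, axis=0)
        for j in range(k):
            big[j, :, j] = Xo[perm, j]
        preds = tree.predict(big.reshape(k * m, k)).reshape(k, m)
        imps.append(np.mean((yo[None, :] - preds) ** 2, axis=1) - base)
    imp = np.asarray(imps)
    mean = imp.mean(axis=0)
    sd = imp.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(sd > 0, mean / sd, 0.0)


def boruta_importance(table: pd.DataFrame, response: str = "tss_std",
                      p: float = 0.01, max_iter: int = 100, seed: int = 0,
                      attributes=ATTRIBUTES, n_estimators: int = 100
                      ) -> ImportanceReport:
    """Shadow-feature importance analysis of the melted results.

    Per iteration: permute a shadow copy of every attribute (rows permuted
    jointly within an attribute, so its marginal distribution is kept but
    any association with the response is destroyed), fit a bagged
    regression forest on real + shadow features, and compute per-feature
    Z-scores from the per-tree out-of-bag permutation importances. An
    attribute's importance is the maximum Z over its one-hot columns; a
    hit means it exceeded every shadow's Z. Hits over iterations are
    compared with Binomial(max_iter, 1/2) two-sided at ``p``:
    significantly many hits → Confirmed, significantly few → Rejected,
    otherwise Tentative.
    """
    attributes = [a for a in attributes if a in table.columns
                  and table[a].nunique() > 1]
    if len(attributes) < 2:
        raise ValueError("need at least 2 candidate attributes with variation")
    if len(table) < 50:
        raise ValueError("table too small for a forest meta-model (< 50 rows)")
    y = table[response].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("response has zero variance")

    X_real, owners = _one_hot(table, attributes)
    n, k = X_real.shape
    rng = np.random.default_rng(seed)
    hits = {a: 0 for a in attributes}
    z_sums = {a: 0.0 for a in attributes}

    # pad shadows to at least 5 so the max-shadow reference is stable even
    # for small attribute sets
    n_copies = max(1, -(-5 // len(attributes)))

    for _ in range(max_iter):
        shadows = []
        # permute per attribute block so shadow columns stay internally
        # consistent
        for _copy in range(n_copies):
            X_shadow = np.empty_like(X_real)
            for attr in attributes:
                cols = [j for j, o in enumerate(owners) if o == attr]
                perm = rng.permutation(n)
                X_shadow[:, cols] = X_real[perm][:, cols]
            shadows.append(X_shadow)
        X = np.hstack([X_real, *shadows])
        z = _forest_importance_z(X, y, n_estimators, rng)
        z_real, z_shadow = z[:k], z[k:]
        best_shadow = z_shadow.max()
        for attr in attributes:
            cols = [j for j, o in enumerate(owners) if o == attr]
            z_attr = float(z_real[cols].max())
            z_sums[attr] += z_attr
            if z_attr > best_shadow:
                hits[attr] += 1

    out = []
    for attr in attributes:
        test = binomtest(hits[attr], max_iter, 0.5, alternative="two-sided")
        if test.pvalue < p:
            status = "Confirmed" if hits[attr] > max_iter / 2 else "Rejected"
        else:
            status = "Tentative"
        out.append(AttributeImportance(attr, z_sums[attr] / max_iter,
                                       hits[attr], status))
    return ImportanceReport(tuple(out), max_iter, p)


def attribute_ranking(report: ImportanceReport) -> pd.DataFrame:
    """Attributes sorted by mean Z-score (descending; name breaks ties)."""
    rows = sorted(report.attributes, key=lambda a: (-a.mean_z, a.name))
    return pd.DataFrame([{
        "attribute": a.name, "mean_z": a.mean_z, "hits": a.hits,
        "status": a.status,
    } for a in rows])
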