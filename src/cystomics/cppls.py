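"""Canonical powered PLS discriminant analysis with VIP elimination.

Components are extracted sequentially.  For each component the loading
weights blend two ingredients computed on the current (deflated) data:
the per-molecule standard deviation and the correlation of each
molecule with the dominant direction of the dummy-coded class
responses.  A power parameter ``p`` in (0, 1) controls the blend,

    w_j(p)  ~  sign(rho_j) * (|rho_j| / max|rho|)^(p / (1 - p))
                           * (s_j / max s)^((1 - p) / p)

so ``p = 0.5`` reduces to the ordinary PLS covariance weight, ``p -> 1``
weights by correlation alone and ``p -> 0`` by standard deviation
alone.  The power is chosen per component from a grid by maximizing
the canonical correlation between the resulting X-score and the space
spanned by the centered class-indicator responses.  Class prediction
runs a linear discriminant on the score matrix; its class posterior
probability is the continuous score used for ROC curves.

Feature selection follows a recursive scheme: record leave-one-out
cross-validated performance, rank molecules by their Variable
Importance in Projection (VIP) on an all-samples fit, discard the
lowest 5%, and repeat while the model remains identifiable; the feature
set with the best cross-validated balanced accuracy wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .matrix import ValidationError
from .metrics import auc_score, balanced_accuracy, sensitivity_specificity

__all__ = [
    "CpplsModel",
    "VipRanking",
    "ClassificationReport",
    "DEFAULT_POWER_GRID",
    "fit_cppls",
    "vip_scores",
    "loocv_evaluate",
    "recursive_elimination",
]

#: p = 0.05, 0.10, ..., 0.95
DEFAULT_POWER_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass
class CpplsModel:
    """A fitted CPPLS-DA model."""

    loading_weights: np.ndarray     # (m, A), unit-norm columns
    scores: np.ndarray              # (n, A)
    x_loadings: np.ndarray          # (m, A)
    y_loadings: np.ndarray          # (K, A)
    powers: tuple[float, ...]       # chosen power per component
    classes_: np.ndarray
    x_mean: np.ndarray              # (m,) training centering
    classifier: LinearDiscriminantAnalysis
    feature_names: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loading_weights.shape[1]

    @property
    def rotation(self) -> np.ndarray:
        """W (P'W)^-1: maps centered X rows to scores."""
        W, P = self.loading_weights, self.x_loadings
        return W @ np.linalg.inv(P.T @ W)

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.x_mean) @ self.rotation

    def predict(self, X) -> np.ndarray:
        return self.classifier.predict(self.transform(X))

    def predict_proba(self, X) -> np.ndarray:
        """Class posterior probabilities, columns ordered as classes_."""
        return self.classifier.predict_proba(self.transform(X))

    def explained_y_variance(self) -> np.ndarray:
        """Per-component sum of squares of Y explained (SS_a)."""
        tt = (self.scores**2).sum(axis=0)
        qq = (self.y_loadings**2).sum(axis=0)
        return tt * qq


@dataclass
class VipRanking:
    """VIP scores with ranks and (optionally) elimination bookkeeping."""

    table: pd.DataFrame   # columns: vip, rank, dropped_at_step


@dataclass
class ClassificationReport:
    """LOO-CV performance per one-vs-rest task, plus elimination trace."""

    per_task: pd.DataFrame          # task, auc, sensitivity, specificity, ba
    n_components: int
    trace: pd.DataFrame = field(default_factory=pd.DataFrame)
    selected_features: list = field(default_factory=list)
    predictions: pd.DataFrame = field(default_factory=pd.DataFrame)


def _dummy_code(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(y)
    Y = (y[:, None] == classes[None, :]).astype(float)
    return classes, Y


def _powered_weights(rho: np.ndarray, s: np.ndarray, power: float) -> np.ndarray:
    """Blend correlation and standard-deviation terms at the given power."""
    abs_rho = np.abs(rho)
    max_rho = abs_rho.max()
    max_s = s.max()
    if max_rho == 0.0 or max_s == 0.0:
        return np.zeros_like(rho)
    e_rho = power / (1.0 - power)
    e_s = (1.0 - power) / power
    w = (
        np.sign(rho)
        * (abs_rho / max_rho) ** e_rho
        * np.where(s > 0, (s / max_s) ** e_s, 0.0)
    )
    return w


def _canonical_fit(t: np.ndarray, Yc: np.ndarray) -> float:
    """Canonical correlation between a single score and span(Yc)."""
    denom = t @ t
    if denom <= 0:
        return -np.inf
    coef, *_ = np.linalg.lstsq(Yc, t, rcond=None)
    proj = Yc @ coef
    return float(np.sqrt((proj @ proj) / denom))


def fit_cppls(
    X,
    y,
    n_components: int = 2,
    power_grid=DEFAULT_POWER_GRID,
    feature_names=None,
) -> CpplsModel:
    """Fit a CPPLS-DA model on a samples x molecules matrix.

    Raises
    ------
    ValidationError
        For single-class labels or too many requested components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, m = X.shape
    classes, Ydum = _dummy_code(y)
    if classes.size < 2:
        raise ValidationError("need at least 2 classes")
    if n_components > min(n - 1, m):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n-1, m)="
            f"{min(n - 1, m)}"
        )
    for p in power_grid:
        if not 0.0 < p < 1.0:
            raise ValidationError("powers must lie in the open interval (0,1)")

    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    Yc = Ydum - Ydum.mean(axis=0)

    W = np.empty((m, n_components))
    T = np.empty((n, n_components))
    P = np.empty((m, n_components))
    Q = np.empty((classes.size, n_components))
    powers = []
    for comp in range(n_components):
        s = Xd.std(axis=0, ddof=1)
        sy = Yc.std(axis=0, ddof=1)
        cov = Xd.T @ Yc / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            R = np.where(
                (s[:, None] > 0) & (sy[None, :] > 0),
                cov / (s[:, None] * sy[None, :]),
                0.0,
            )
        # dominant response direction (first right singular vector)
        _, _, vt = np.linalg.svd(R, full_matrices=False)
        a_vec = vt[0]
        if a_vec[np.argmax(np.abs(a_vec))] < 0:  # deterministic sign
            a_vec = -a_vec
        rho = R @ a_vec

        best = (-np.inf, None, None)
        for p in power_grid:
            w = _powered_weights(rho, s, p)
            norm = np.linalg.norm(w)
            if norm == 0:
                continue
            w = w / norm
            t = Xd @ w
            crit = _canonical_fit(t, Yc)
            if crit > best[0]:
                best = (crit, float(p), w)
        if best[1] is None:
            raise ValidationError(
                "no informative direction left; reduce n_components"
            )
        _, p_star, w = best
        t = Xd @ w
        tt = t @ t
        p_load = Xd.T @ t / tt
        q_load = Yc.T @ t / tt
        Xd = Xd - np.outer(t, p_load)
        W[:, comp] = w
        T[:, comp] = t
        P[:, comp] = p_load
        Q[:, comp] = q_load
        powers.append(p_star)

    lda = LinearDiscriminantAnalysis()
    lda.fit(T, y)
    return CpplsModel(
        loading_weights=W,
        scores=T,
        x_loadings=P,
        y_loadings=Q,
        powers=tuple(powers),
        classes_=classes,
        x_mean=x_mean,
        classifier=lda,
        feature_names=None if feature_names is None else np.asarray(feature_names),
    )


def vip_scores(model: CpplsModel) -> VipRanking:
    """Variable importance in projection for a fitted model.

    ``VIP_j = sqrt(m * sum_a SS_a w_ja^2 / sum_a SS_a)`` with unit-norm
    weight columns, so the mean squared VIP over molecules is exactly 1.
    """
    ss = model.explained_y_variance()
    total = ss.sum()
    if total <= 0:
        raise ValidationError("no explained Y variance in any component")
    m = model.loading_weights.shape[0]
    vip = np.sqrt(m * (model.loading_weights**2 @ ss) / total)
    names = (
        model.feature_names
        if model.feature_names is not None
        else np.array([f"var_{j}" for j in range(m)])
    )
    table = pd.DataFrame({"vip": vip}, index=pd.Index(names, name="molecule"))
    table["rank"] = (
        table["vip"].rank(ascending=False, method="first").astype(int)
    )
    table["dropped_at_step"] = pd.NA
    return VipRanking(table=table.sort_values("rank"))


def _prior_rule_prediction(y_train: np.ndarray, classes: np.ndarray):
    """Fallback when a training fold lost a class entirely."""
    vals, counts = np.unique(y_train, return_counts=True)
    pred = vals[np.argmax(counts)]
    proba = np.zeros(classes.size)
    for v, c in zip(vals, counts):
        proba[np.flatnonzero(classes == v)[0]] = c / counts.sum()
    return pred, proba


def loocv_evaluate(
    X,
    y,
    n_components: int = 2,
    power_grid=DEFAULT_POWER_GRID,
) -> ClassificationReport:
    """Leave-one-out cross-validated CPPLS-DA performance.

    Each sample is predicted by a model fitted on the remaining n - 1;
    held-out labels and class probabilities are aggregated into
    sensitivity, specificity, balanced accuracy and AUC per one-vs-rest
    task.  Fully deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes = np.unique(y)
    if n < classes.size + 2:
        raise ValidationError("too few samples for leave-one-out evaluation")
    preds = np.empty(n, dtype=y.dtype)
    probas = np.empty((n, classes.size))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        y_tr = y[keep]
        if np.unique(y_tr).size < 2:
            warnings.warn(
                f"training fold {i} lost a class; prior-frequency rule used",
                stacklevel=2,
            )
            preds[i], probas[i] = _prior_rule_prediction(y_tr, classes)
            continue
        model = fit_cppls(X[keep], y_tr, n_components, power_grid)
        preds[i] = model.predict(X[i : i + 1])[0]
        p = model.predict_proba(X[i : i + 1])[0]
        # training fold may expose fewer classes than the full label set
        row = np.zeros(classes.size)
        for cls, val in zip(model.classes_, p):
            row[np.flatnonzero(classes == cls)[0]] = val
        probas[i] = row
    rows = []
    for ci, cls in enumerate(classes):
        sens, spec = sensitivity_specificity(y, preds, positive=cls)
        rows.append(
            {
                "task": f"{cls} vs All",
                "auc": auc_score(y, probas[:, ci], positive=cls),
                "sensitivity": sens,
                "specificity": spec,
                "balanced_accuracy": balanced_accuracy(sens, spec),
            }
        )
    predictions = pd.DataFrame(
        {"true": y, "predicted": preds}
        | {f"proba_{c}": probas[:, i] for i, c in enumerate(classes)}
    )
    return ClassificationReport(
        per_task=pd.DataFrame(rows),
        n_components=n_components,
        predictions=predictions,
    )


def _mean_balanced_accuracy(report: ClassificationReport) -> float:
    return float(report.per_task["balanced_accuracy"].mean())


def select_n_components(
    X, y, power_grid=DEFAULT_POWER_GRID, max_components: int = 8
) -> int:
    """Pick the component count maximizing LOO-CV balanced accuracy."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    upper = min(max_components, n - 2, m)
    best_a, best_ba = 1, -np.inf
    for a in range(1, upper + 1):
        ba = _mean_balanced_accuracy(loocv_evaluate(X, y, a, power_grid))
        if ba > best_ba:
            best_a, best_ba = a, ba
    return best_a


def recursive_elimination(
    X,
    y,
    drop_fraction: float = 0.05,
    n_components: int | None = None,
    power_grid=DEFAULT_POWER_GRID,
    max_components: int = 8,
    feature_names=None,
) -> tuple[ClassificationReport, VipRanking]:
    """VIP-guided recursive feature elimination with LOO-CV scoring.

    At every step the LOO-CV performance of the current feature set is
    recorded, an all-samples model is fitted, and the ``max(1,
    floor(drop_fraction * m))`` molecules with the lowest VIP are
    discarded (VIP ties drop the alphabetically-last IDs).  The loop
    stops once fewer than ``n_components + 1`` molecules would remain;
    the feature set with the highest cross-validated balanced accuracy
    is selected, ties resolved toward the smaller set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    m = X.shape[1]
    names = (
        np.asarray(feature_names)
        if feature_names is not None
        else np.array([f"var_{j:05d}" for j in range(m)])
    )
    if n_components is None:
        n_components = select_n_components(X, y, power_grid, max_components)

    active = np.arange(m)
    dropped_at: dict = {}
    vip_last: dict = {}
    trace_rows = []
    step_reports: list[tuple[int, np.ndarray, ClassificationReport]] = []
    step = 0
    while active.size >= n_components + 1:
        report = loocv_evaluate(X[:, active], y, n_components, power_grid)
        ba = _mean_balanced_accuracy(report)
        trace_rows.append(
            {"step": step, "n_molecules": active.size, "balanced_accuracy": ba}
        )
        step_reports.append((step, active.copy(), report))
        model = fit_cppls(
            X[:, active], y, n_components, power_grid,
            feature_names=names[active],
        )
        vip = vip_scores(model).table["vip"]
        for mol in vip.index:
            vip_last[mol] = float(vip.loc[mol])
        n_drop = max(1, int(np.floor(drop_fraction * active.size)))
        order = sorted(
            range(active.size),
            key=lambda idx: (
                vip.loc[names[active[idx]]],
                # alphabetically-last IDs go first at equal VIP
                tuple(-ord(ch) for ch in str(names[active[idx]])),
            ),
        )
        to_drop = order[:n_drop]
        for idx in to_drop:
            dropped_at[names[active[idx]]] = step
        keep_mask = np.ones(active.size, dtype=bool)
        keep_mask[to_drop] = False
        active = active[keep_mask]
        step += 1

    trace = pd.DataFrame(trace_rows)
    best_ba = trace["balanced_accuracy"].max()
    # ties resolve to the earliest step (largest feature set): once peak
    # performance is reached, further pruning is not rewarded
    best_step = int(
        trace[trace["balanced_accuracy"] == best_ba]["step"].iloc[0]
    )
    _, best_active, best_report = step_reports[best_step]
    best_report.trace = trace
    best_report.selected_features = list(names[best_active])

    table = pd.DataFrame(
        {"vip": pd.Series(vip_last)}, index=pd.Index(list(vip_last), name="molecule")
    )
    table["rank"] = table["vip"].rank(ascending=False, method="first").astype(int)
    table["dropped_at_step"] = pd.Series(dropped_at, dtype="Int64").reindex(
        table.index
    )
    return best_report, VipRanking(table=table.sort_values("rank"))
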