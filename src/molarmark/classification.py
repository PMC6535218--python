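"""Stepwise Wilks'-lambda discriminant analysis with leave-one-out validation.

The selection criterion is Wilks' lambda, det(W)/det(T), where W and T are
the within-group and total corrected cross-product matrices of the current
variable set.  Variables enter greedily (largest partial F, i.e. the largest
drop in lambda) while F-to-enter >= 3.84, and already-entered variables are
removed while their F-to-remove < 2.71 — the classical SPSS defaults.  The
partial-F statistics use the standard identities

    F_enter  = (n - g - p) / (g - 1) * (L_p / L_{p+1} - 1)
    F_remove = (n - g - p + 1) / (g - 1) * (L_{p-1} / L_p - 1)

with p variables currently entered, n specimens and g groups.

Canonical discriminant functions come from the generalized eigenproblem
B v = lambda W v; coefficients are scaled so the pooled within-group variance
of every canonical score is 1.  Classification assigns each specimen to the
group with the highest ln(prior) - d^2/2 in canonical space (nearest group
centroid under equal priors).  Leave-one-out cross-validation refits the
canonical functions on n-1 specimens while keeping the variable set selected
on the full sample (SPSS semantics); ``selection_inside_loop=True`` re-runs
selection per fold for a stricter generalization estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import CollinearityError, UsageError

logger = logging.getLogger(__name__)

F_ENTER_DEFAULT = 3.84
F_REMOVE_DEFAULT = 2.71


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    variable: str
    wilks_lambda: float
    f_statistic: float


@dataclass(frozen=True)
class StepwiseTrace:
    steps: tuple[StepwiseStep, ...]

    @property
    def selected(self) -> tuple[str, ...]:
        current: list[str] = []
        for s in self.steps:
            if s.action == "enter":
                current.append(s.variable)
            else:
                current.remove(s.variable)
        return tuple(current)


@dataclass(frozen=True)
class DFAModel:
    selected_variables: tuple[str, ...]
    canonical_coefficients: np.ndarray  # (p, m): variables x functions
    constants: np.ndarray               # (m,)
    eigenvalues: np.ndarray             # (m,)
    percent_variance_per_function: np.ndarray
    group_centroids: np.ndarray         # (g, m) in canonical space
    priors: np.ndarray                  # (g,)
    group_labels: tuple[str, ...]
    wilks_lambda: float

    @property
    def n_functions(self) -> int:
        return self.canonical_coefficients.shape[1]

    def canonical_scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.canonical_coefficients + self.constants


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: pd.DataFrame  # true group (rows) x predicted group (columns)
    accuracy_percent: float
    mode: str  # "original" | "cross_validated"
    flagged_folds: tuple[int, ...] = field(default=())


# ---------------------------------------------------------------------------
# data wrangling


def _design(X, labels, variables=None):
    """Return (values (n, p), variable names, label array, sorted group labels)."""
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if variables is None else list(variables)
        values = X[names].to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim != 2:
            raise UsageError("X must be 2-dimensional")
        all_names = [f"v{i}" for i in range(values.shape[1])]
        if variables is None:
            names = all_names
        else:
            names = list(variables)
            values = values[:, [all_names.index(v) for v in names]]
    labels = np.asarray(labels)
    if len(labels) != len(values):
        raise UsageError("labels and X disagree in length")
    groups = tuple(sorted(pd.unique(labels).tolist()))
    if len(groups) < 2:
        raise UsageError("need at least 2 groups")
    return values, names, labels, groups


def _sscp(values: np.ndarray, labels: np.ndarray, groups) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) corrected cross-product matrices."""
    grand = values.mean(axis=0)
    dev_total = values - grand
    T = dev_total.T @ dev_total
    W = np.zeros_like(T)
    for g in groups:
        sub = values[labels == g]
        dev = sub - sub.mean(axis=0)
        W += dev.T @ dev
    return W, T


# ---------------------------------------------------------------------------
# Wilks' lambda and stepwise selection


def wilks_lambda(X, labels, variables=None) -> float:
    """Wilks' lambda det(W)/det(T) for the given variable set."""
    values, names, labels, groups = _design(X, labels, variables)
    n, p = values.shape
    if n <= p + len(groups) - 1:
        raise UsageError(
            f"too few specimens ({n}) for {p} variables and {len(groups)} groups"
        )
    W, T = _sscp(values, labels, groups)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise CollinearityError(
            f"total cross-product matrix is singular for variables {names}"
        )
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def _lambda_of(values, labels, groups, cols) -> float:
    if not cols:
        return 1.0
    W, T = _sscp(values[:, cols], labels, groups)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        return np.nan
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0:
        return 0.0
    return float(np.exp(logdet_w - logdet_t))


def stepwise_select(
    X,
    labels,
    f_enter: float = F_ENTER_DEFAULT,
    f_remove: float = F_REMOVE_DEFAULT,
    max_steps: int = 100,
) -> StepwiseTrace:
    """Greedy SPSS-style stepwise variable selection on Wilks' lambda.

    At each step the candidate with the largest partial F (equivalently the
    smallest resulting lambda) enters if F >= f_enter; then entered variables
    whose F-to-remove falls below f_remove are removed one at a time.
    ``f_enter`` must exceed ``f_remove`` to rule out cycling.
    """
    if f_enter <= f_remove:
        raise UsageError("f_enter must be greater than f_remove")
    values, names, labels, groups = _design(X, labels)
    n, n_vars = values.shape
    g = len(groups)
    steps: list[StepwiseStep] = []
    included: list[int] = []

    for _ in range(max_steps):
        changed = False
        p = len(included)
        lam_now = _lambda_of(values, labels, groups, included)
        # --- entry phase
        if n - g - p > 0:
            best_f, best_j, best_lam = -np.inf, None, None
            for j in range(n_vars):
                if j in included:
                    continue
                lam_new = _lambda_of(values, labels, groups, included + [j])
                if not np.isfinite(lam_new):
                    continue  # collinear with entered set (singular T)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = lam_now / lam_new if lam_new > 0 else np.inf
                f = (n - g - p) / (g - 1) * (ratio - 1.0)
                if np.isfinite(lam_now) and lam_now == 0.0:
                    continue  # already perfect separation; nothing to gain
                if f > best_f:
                    best_f, best_j, best_lam = f, j, lam_new
            if best_j is not None and best_f >= f_enter:
                included.append(best_j)
                steps.append(
                    StepwiseStep("enter", names[best_j], best_lam, float(best_f))
                )
                changed = True
        # --- removal phase
        while len(included) > 1:
            p = len(included)
            lam_now = _lambda_of(values, labels, groups, included)
            worst_f, worst_j, worst_lam = np.inf, None, None
            for j in included:
                rest = [k for k in included if k != j]
                lam_without = _lambda_of(values, labels, groups, rest)
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = lam_without / lam_now if lam_now > 0 else np.inf
                f = (n - g - p + 1) / (g - 1) * (ratio - 1.0)
                if f < worst_f:
                    worst_f, worst_j, worst_lam = f, j, lam_without
            if worst_j is not None and worst_f < f_remove:
                included.remove(worst_j)
                steps.append(
                    StepwiseStep("remove", names[worst_j], worst_lam, float(worst_f))
                )
                changed = True
            else:
                break
        if not changed:
            break

    if not included:
        warnings.warn(
            "no variable passed the entry threshold; model is empty "
            "(classification falls back to priors)",
            UserWarning,
            stacklevel=2,
        )
    return StepwiseTrace(steps=tuple(steps))


# ---------------------------------------------------------------------------
# canonical discriminant functions


def _resolve_priors(priors, groups, labels) -> np.ndarray:
    g = len(groups)
    if priors is None or priors == "equal":
        return np.full(g, 1.0 / g)
    if priors == "proportional":
        counts = np.array([(labels == grp).sum() for grp in groups], dtype=float)
        return counts / counts.sum()
    arr = np.array([priors[grp] for grp in groups], dtype=float)
    if np.any(arr < 0) or arr.sum() <= 0:
        raise UsageError("priors must be non-negative and sum to a positive value")
    return arr / arr.sum()


def fit_lda(X, labels, variables=None, priors="equal") -> DFAModel:
    """Fit canonical discriminant functions on the given variable set."""
    values, names, labels, groups = _design(X, labels, variables)
    n, p = values.shape
    g = len(groups)
    if p == 0:
        raise UsageError("cannot fit a model with no variables")
    if n <= g + p:
        raise UsageError("too few specimens for the requested model")
    W, T = _sscp(values, labels, groups)
    B = T - W
    try:
        # B v = lambda W v with W symmetric positive definite
        eigvals, eigvecs = scipy.linalg.eigh(B, W)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise CollinearityError(
            f"within-group matrix singular for variables {names}: {exc}"
        ) from exc
    order = np.argsort(eigvals)[::-1]
    m = min(g - 1, p)
    eigvals = np.clip(eigvals[order][:m], 0.0, None)
    vecs = eigvecs[:, order][:, :m]
    # eigh normalizes v^T W v = 1; rescale so pooled within-group variance
    # of each canonical score is 1: v^T (W / (n - g)) v = 1
    coef = vecs * np.sqrt(n - g)
    grand = values.mean(axis=0)
    constants = -grand @ coef
    group_means = np.stack([values[labels == grp].mean(axis=0) for grp in groups])
    centroids = (group_means - grand) @ coef
    total = eigvals.sum()
    percent = 100.0 * eigvals / total if total > 0 else np.zeros_like(eigvals)
    sign_t, logdet_t = np.linalg.slogdet(T)
    sign_w, logdet_w = np.linalg.slogdet(W)
    lam = float(np.exp(logdet_w - logdet_t)) if sign_t > 0 and sign_w > 0 else 0.0
    return DFAModel(
        selected_variables=tuple(names),
        canonical_coefficients=coef,
        constants=constants,
        eigenvalues=eigvals,
        percent_variance_per_function=percent,
        group_centroids=centroids,
        priors=_resolve_priors(priors, groups, labels),
        group_labels=groups,
        wilks_lambda=lam,
    )


def predict(model: DFAModel, X) -> np.ndarray:
    """Assign each specimen to the group maximizing ln(prior) - d^2/2 in
    canonical space.  Ties break toward the earlier group label (logged)."""
    if isinstance(X, pd.DataFrame):
        values = X[list(model.selected_variables)].to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
    scores = model.canonical_scores(values)
    d2 = ((scores[:, None, :] - model.group_centroids[None, :, :]) ** 2).sum(axis=2)
    decision = np.log(np.where(model.priors > 0, model.priors, 1e-300)) - 0.5 * d2
    best = np.argmax(decision, axis=1)
    ties = (decision == decision[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if np.any(ties):
        logger.info(
            "%d tie(s) in nearest-centroid classification broken by label order",
            int(ties.sum()),
        )
    return np.array([model.group_labels[i] for i in best])


def _confusion(true_labels, predicted, groups, mode, flagged=()) -> ConfusionMatrix:
    counts = pd.DataFrame(0, index=list(groups), columns=list(groups), dtype=int)
    for t, p in zip(true_labels, predicted):
        counts.loc[t, p] += 1
    total = counts.to_numpy().sum()
    accuracy = 100.0 * np.trace(counts.to_numpy()) / total if total else 0.0
    return ConfusionMatrix(
        counts=counts,
        accuracy_percent=float(accuracy),
        mode=mode,
        flagged_folds=tuple(flagged),
    )


def classification_report(model: DFAModel, X, labels) -> ConfusionMatrix:
    """Resubstitution confusion matrix (original grouped cases)."""
    labels = np.asarray(labels)
    unknown = set(pd.unique(labels)) - set(model.group_labels)
    if unknown:
        raise UsageError(f"labels absent from the model: {sorted(unknown)}")
    predicted = predict(model, X)
    return _confusion(labels, predicted, model.group_labels, "original")


def loo_crossvalidate(
    X,
    labels,
    variables=None,
    priors="equal",
    selection_inside_loop: bool = False,
    f_enter: float = F_ENTER_DEFAULT,
    f_remove: float = F_REMOVE_DEFAULT,
) -> ConfusionMatrix:
    """Leave-one-out cross-validated confusion matrix.

    By default the variable set is fixed (selected beforehand on the full
    sample) and only the canonical functions are refit per fold.  A fold whose
    holdout empties a group is computed on the remaining groups and flagged.
    """
    values, names, label_arr, groups = _design(X, labels, variables)
    for grp in groups:
        if (label_arr == grp).sum() < 2:
            raise UsageError(f"group {grp!r} has fewer than 2 specimens")
    n = len(values)
    predicted = np.empty(n, dtype=object)
    flagged = []
    frame = pd.DataFrame(values, columns=names)
    for i in range(n):
        keep = np.arange(n) != i
        sub = frame.iloc[keep]
        sub_labels = label_arr[keep]
        if len(pd.unique(sub_labels)) < len(groups):
            flagged.append(i)
        fold_vars = names
        if selection_inside_loop:
            trace = stepwise_select(sub, sub_labels, f_enter=f_enter, f_remove=f_remove)
            fold_vars = list(trace.selected) or names
        fold_model = fit_lda(sub, sub_labels, variables=fold_vars, priors=priors)
        predicted[i] = predict(fold_model, frame.iloc[[i]])[0]
    return _confusion(label_arr, predicted, groups, "cross_validated", flagged)


def stepwise_dfa(
    X,
    labels,
    priors="equal",
    f_enter: float = F_ENTER_DEFAULT,
    f_remove: float = F_REMOVE_DEFAULT,
):
    """Convenience pipeline: stepwise selection, fit, resubstitution and LOO.

    Returns (trace, model, original ConfusionMatrix, cross-validated
    ConfusionMatrix).
    """
    trace = stepwise_select(X, labels, f_enter=f_enter, f_remove=f_remove)
    selected = list(trace.selected)
    if not selected:
        raise UsageError("stepwise selection produced an empty model")
    model = fit_lda(X, labels, variables=selected, priors=priors)
    original = classification_report(model, X, labels)
    crossval = loo_crossvalidate(X, labels, variables=selected, priors=priors)
    return trace, model, original, crossval
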