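"""Two-class PLS (NIPALS) with cross-validated component tuning and VIP selection.

The supervised differential-feature step: a PLS1 regression of the centered
log-intensity matrix on the centered +/-1 culture label, component count tuned
by stratified cross-validated classification accuracy, and features ranked by
Variable Importance in Projection

    VIP_j = sqrt( p * sum_a SS_a * (w_ja / ||w_a||)^2 / sum_a SS_a )

where SS_a is the response variance explained by component a.  Features whose
VIP exceeds the empirical 0.95 quantile (type-7/linear interpolation) of the
VIP distribution are selected; mean(VIP^2) = 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, ValidationError


@dataclass
class PlsModel:
    """Fitted PLS1 model: normalized weights W, loadings P, scores T, response
    loadings q, and per-component explained response variance ss."""

    W: np.ndarray   # p x A, each column unit norm
    P: np.ndarray   # p x A
    T: np.ndarray   # n x A, mutually orthogonal
    q: np.ndarray   # A
    ss: np.ndarray  # A: response variance explained per component
    x_mean: np.ndarray
    y_mean: float

    @property
    def n_components(self) -> int:
        return self.W.shape[1]


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PlsModel:
    """Sequential NIPALS extraction for a single response.

    Each component takes w_a proportional to X'y on the deflated matrices,
    scores t_a = X w_a, then deflates X by t_a p_a' and y by q_a t_a.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValidationError("X and y disagree on sample count")
    if np.unique(y).size < 2:
        raise DegenerateDataError("single-class response; nothing to discriminate")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValidationError(
            f"n_components={n_components} outside 1..min(n_samples-1, n_features)"
            f"={min(n - 1, p)}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    if not (Xc.std(axis=0) > 0).any():
        raise DegenerateDataError("zero-variance X matrix")
    yc = y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    T = np.empty((n, n_components))
    q = np.empty(n_components)
    ss = np.empty(n_components)
    for a in range(n_components):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm <= 1e-12 * max(1.0, np.abs(Xc).max()):
            raise DegenerateDataError(
                f"rank exhausted at component {a + 1}; requested {n_components}"
            )
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 0:
            raise DegenerateDataError(f"degenerate score vector at component {a + 1}")
        p_vec = Xc.T @ t / tt
        q_a = float(yc @ t / tt)
        Xc = Xc - np.outer(t, p_vec)
        yc = yc - q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_vec, t, q_a
        ss[a] = q_a ** 2 * tt
    return PlsModel(W=W, P=P, T=T, q=q, ss=ss, x_mean=x_mean, y_mean=y_mean)


def predict_components(model: PlsModel, X: np.ndarray) -> np.ndarray:
    """Predictions using 1..A components: returns an (n, A) matrix.

    Column a-1 is the fitted response with the first a components
    (y_mean + Xc @ B_a with B_a = W_a (P_a' W_a)^-1 q_a).
    """
    X = np.asarray(X, dtype=float)
    Xc = X - model.x_mean
    A = model.n_components
    out = np.empty((X.shape[0], A))
    for a in range(1, A + 1):
        Wa, Pa, qa = model.W[:, :a], model.P[:, :a], model.q[:a]
        B = Wa @ np.linalg.solve(Pa.T @ Wa, qa)
        out[:, a - 1] = model.y_mean + Xc @ B
    return out


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    return predict_components(model, X)[:, -1]


def stratified_folds(y: np.ndarray, folds: int, seed: int = 0) -> list[np.ndarray]:
    """Class-balanced fold assignment that tolerates classes smaller than the
    fold count (e.g. 8-vs-4 samples, 5 folds -> fold sizes {2,2,2,1,1}).

    Members of each class are shuffled and dealt round-robin across folds with
    a running offset, so every training complement retains both classes as
    long as each class has >= 2 members.
    """
    n = y.size
    if folds < 2 or folds > n:
        raise ValidationError(
            f"folds={folds} infeasible for {n} samples; "
            "use leave-one-out (folds = n_samples) at most"
        )
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValidationError(
            "each class needs >= 2 samples so every training fold retains both classes"
        )
    rng = np.random.default_rng(seed)
    assignment = [[] for _ in range(folds)]
    offset = 0
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, s in enumerate(idx):
            assignment[(offset + i) % folds].append(int(s))
        offset += len(idx)
    return [np.sort(np.array(a, dtype=int)) for a in assignment if a]


def tune_ncomp(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> int:
    """Pick the component count by stratified CV classification accuracy.

    Held-out samples are classified by the sign of the predicted response;
    A* maximizes mean accuracy over 1..min(max_components, rank bound), ties
    broken toward the smaller count.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateDataError("single-class response")
    fold_sets = stratified_folds(y, folds, seed=seed)
    folds = len(fold_sets)
    all_idx = np.arange(y.size)
    n, p = X.shape
    cap = 0
    acc_sums: np.ndarray | None = None
    fold_counts: np.ndarray | None = None
    for test in fold_sets:
        train = np.setdiff1d(all_idx, test)
        a_max = min(max_components, min(len(train) - 1, p))
        model = fit_pls(X[train], y[train], a_max)
        preds = predict_components(model, X[test])
        correct = (np.sign(preds) == np.sign(y[test])[:, None]).sum(axis=0)
        if acc_sums is None:
            acc_sums = np.zeros(max_components)
            fold_counts = np.zeros(max_components)
        acc_sums[:a_max] += correct / len(test)
        fold_counts[:a_max] += 1
        cap = max(cap, a_max)
    assert acc_sums is not None and fold_counts is not None
    mean_acc = np.full(max_components, -np.inf)
    usable = fold_counts == folds  # only component counts evaluable in every fold
    mean_acc[usable] = acc_sums[usable] / folds
    best = float(mean_acc[:cap].max())
    return int(np.flatnonzero(mean_acc[:cap] >= best - 1e-12)[0]) + 1


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable Importance in Projection; satisfies sum(VIP^2) = n_features."""
    total = float(model.ss.sum())
    if total <= 0:
        raise DegenerateDataError("model explains no response variance")
    p = model.W.shape[0]
    # W columns are unit norm already
    contrib = (model.W ** 2) @ model.ss
    return np.sqrt(p * contrib / total)


@dataclass
class SelectionResult:
    selected: list[str]
    vip: pd.Series
    threshold: float
    direction: pd.Series            # per selected feature: '<class>-enriched'
    n_components: int
    classes: tuple[str, str]        # (negative label, positive label)
    dropped_zero_variance: list[str] = field(default_factory=list)


def select_features(
    X: pd.DataFrame,
    labels,
    components: int = 5,
    tune_length: int = 10,
    quantile: float = 0.95,
    folds: int = 5,
    seed: int = 0,
) -> SelectionResult:
    """Differential-feature selection for one two-class contrast.

    ``X`` is a sample x feature matrix of transformed intensities; ``labels``
    is a two-level vector (e.g. culture 'mono'/'co').  The component count is
    tuned over 1..tune_length by CV, then capped at ``components``; VIP is
    computed on the final all-sample fit and features above the empirical
    ``quantile`` VIP quantile are selected.  Direction of each selected
    feature is the sign of its class mean difference.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    lab = pd.Series(list(labels), index=X.index)
    classes = sorted(lab.unique().tolist())
    if len(classes) != 2:
        raise DegenerateDataError(f"need exactly 2 classes, got {classes}")
    # canonical orientation: 'co' is the positive class when present
    if "co" in classes:
        classes = [c for c in classes if c != "co"] + ["co"]
    y = np.where(lab == classes[1], 1.0, -1.0)

    variances = X.var(axis=0, ddof=0)
    dropped = list(X.columns[variances == 0])
    if dropped:
        warnings.warn(f"dropped {len(dropped)} zero-variance feature(s)", stacklevel=2)
    Xs = X.loc[:, variances > 0]
    if Xs.shape[1] == 0:
        raise DegenerateDataError("all features have zero variance")
    Xmat = Xs.to_numpy(dtype=float)

    a_star = tune_ncomp(Xmat, y, max_components=tune_length, folds=folds, seed=seed)
    a_star = min(a_star, components, min(Xmat.shape[0] - 1, Xmat.shape[1]))
    model = fit_pls(Xmat, y, a_star)
    vip = pd.Series(vip_scores(model), index=Xs.columns, name="VIP")
    threshold = float(np.quantile(vip.to_numpy(), quantile))  # type-7 linear
    selected = list(vip.index[vip > threshold])
    mean_pos = Xs.loc[lab == classes[1]].mean(axis=0)
    mean_neg = Xs.loc[lab == classes[0]].mean(axis=0)
    diff = mean_pos - mean_neg
    direction = pd.Series(
        np.where(diff.loc[selected] > 0, f"{classes[1]}-enriched", f"{classes[0]}-enriched"),
        index=pd.Index(selected, name="feature_id"),
        name="direction",
    )
    return SelectionResult(
        selected=selected,
        vip=vip,
        threshold=threshold,
        direction=direction,
        n_components=a_star,
        classes=(classes[0], classes[1]),
        dropped_zero_variance=dropped,
    )
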