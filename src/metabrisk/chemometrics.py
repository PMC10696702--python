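"""Latent-variable discriminant modelling: PCA, PLS-DA and OPLS-DA with VIP.

OPLS-DA splits the systematic variation of a (scaled) feature matrix ``X``
into a single component predictive of a two-class response and a set of
components orthogonal to it.  The fit is the classic single-``y`` NIPALS
sequence: for each orthogonal component the ``y``-predictive weight
``w = X'y / ||X'y||`` is computed, the loading of the current score is
decomposed into its ``w``-parallel and ``w``-orthogonal parts, and the
orthogonal part is deflated from ``X``; the final predictive component is
extracted from the deflated matrix.  With zero orthogonal components the
model degenerates exactly to one-component PLS-DA.  No RNG is involved:
with a single response the weight vectors are closed-form, so fitting is
deterministic.

Model quality is summarised by R²X (cumulative fraction of X variance
captured), R²Y (fraction of class variance explained by the predictive
component) and Q² (cross-validated predictive fraction, 1 - PRESS/SS over
stratified folds).  Feature influence is the VIP score over the predictive
component, normalised so the mean squared VIP is exactly 1; VIP > 1 is the
conventional influence threshold.  Model significance uses a label
permutation test reported both in the raw "k/n exceedances" convention and
as the add-one permutation p-value (k+1)/(n+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PcaResult:
    explained_fraction: np.ndarray   # per-component fraction of total variance
    scores: np.ndarray               # n × k
    loadings: np.ndarray             # p × k
    mean: np.ndarray


@dataclass
class OplsModel:
    """Fitted OPLS-DA model (one predictive component, >=0 orthogonal)."""

    w_pred: np.ndarray               # predictive weights (unit norm), p
    t_pred: np.ndarray               # predictive scores, n
    p_pred: np.ndarray               # predictive loadings, p
    c_pred: float                    # y-loading
    w_orth: np.ndarray               # n_orth × p orthogonal weights
    t_orth: np.ndarray               # n × n_orth orthogonal scores
    p_orth: np.ndarray               # n_orth × p orthogonal loadings
    x_mean: np.ndarray
    y_mean: float
    classes: tuple                   # (negative class, positive class)
    r2x: float
    r2x_pred: float
    r2x_orth: float
    r2y: float
    vip: np.ndarray
    n_orth: int
    residual_ss: float
    total_ss_x: float

    @property
    def n_components(self) -> tuple[int, int]:
        return (1, self.n_orth)

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Predictive and orthogonal scores for new observations."""
        Xr = np.asarray(X, dtype=float) - self.x_mean
        t_o = np.zeros((Xr.shape[0], self.n_orth))
        for a in range(self.n_orth):
            t = Xr @ self.w_orth[a]
            Xr = Xr - np.outer(t, self.p_orth[a])
            t_o[:, a] = t
        return Xr @ self.w_pred, t_o

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        t, _ = self.transform(X)
        return t * self.c_pred + self.y_mean

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class labels by the sign of the decision value."""
        yhat = self.decision_values(X)
        return np.where(yhat >= 0, self.classes[1], self.classes[0])


@dataclass
class PermutationResult:
    n_permutations: int
    n_exceeding: int
    observed: float
    statistic: str
    p_value: float = field(init=False)       # add-one convention
    p_value_raw: float = field(init=False)   # raw k/n ratio

    def __post_init__(self) -> None:
        assert 0 <= self.n_exceeding <= self.n_permutations
        self.p_value = (self.n_exceeding + 1) / (self.n_permutations + 1)
        self.p_value_raw = self.n_exceeding / self.n_permutations

    @property
    def label(self) -> str:
        """The conventional "k/n" exceedance report, e.g. ``0/100``."""
        return f"{self.n_exceeding}/{self.n_permutations}"


def _encode_labels(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if "case" in classes:  # case-control studies: cases are the positive class
        classes = [c for c in classes if c != "case"] + ["case"]
    return np.where(y == classes[1], 1.0, -1.0), tuple(classes)


def fit_pca(X: np.ndarray, k: int) -> PcaResult:
    """PCA by SVD of the column-centered matrix.

    Explained fractions are non-increasing and the full set of components
    reconstructs the centered matrix exactly.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(n-1, p)={min(n - 1, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    frac = s**2 / (s**2).sum()
    return PcaResult(explained_fraction=frac[:k], scores=(U * s)[:, :k],
                     loadings=Vt[:k].T, mean=mean)


def fit_oplsda(X: np.ndarray, y, n_orth: int = 1) -> OplsModel:
    """Fit OPLS-DA with one predictive and ``n_orth`` orthogonal components.

    ``X`` is expected already scaled (e.g. log + Pareto); it is centered here.
    ``y`` may be any two-valued labelling; internally it is coded -1/+1 and
    centered.  If the data cannot support the requested number of orthogonal
    components (no y-orthogonal variation left), fewer are extracted.
    """
    X = np.asarray(X, dtype=float)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("X must be a matrix with at least 4 rows")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("constant feature column; scale/filter X upstream")
    y_pm, classes = _encode_labels(y)

    x_mean = X.mean(axis=0)
    Xr = X - x_mean
    y_mean = float(y_pm.mean())
    yc = y_pm - y_mean
    ssy = float(yc @ yc)
    ssx_total = float((Xr**2).sum())

    w_orth, t_orth, p_orth = [], [], []
    for _ in range(n_orth):
        w = Xr.T @ yc
        w /= np.linalg.norm(w)
        t = Xr @ w
        p = Xr.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm_wo = np.linalg.norm(wo)
        if norm_wo < 1e-10:
            break  # no y-orthogonal variation left
        wo /= norm_wo
        to = Xr @ wo
        po = Xr.T @ to / (to @ to)
        Xr = Xr - np.outer(to, po)
        w_orth.append(wo)
        t_orth.append(to)
        p_orth.append(po)

    w = Xr.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("X carries no covariance with the class labels")
    w /= nw
    t = Xr @ w
    p = Xr.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    ss_pred = float((t @ t) * (p @ p))
    ss_orth = float(sum((to @ to) * (po @ po)
                        for to, po in zip(t_orth, p_orth)))
    residual = Xr - np.outer(t, p)
    r2y = float(c**2 * (t @ t) / ssy)

    n_feat = X.shape[1]
    vip = np.sqrt(n_feat) * np.abs(w)   # single predictive component

    return OplsModel(
        w_pred=w, t_pred=t, p_pred=p, c_pred=c,
        w_orth=np.array(w_orth).reshape(len(w_orth), n_feat),
        t_orth=np.array(t_orth).T.reshape(X.shape[0], len(t_orth)),
        p_orth=np.array(p_orth).reshape(len(p_orth), n_feat),
        x_mean=x_mean, y_mean=y_mean, classes=classes,
        r2x=(ss_pred + ss_orth) / ssx_total,
        r2x_pred=ss_pred / ssx_total, r2x_orth=ss_orth / ssx_total,
        r2y=r2y, vip=vip, n_orth=len(w_orth),
        residual_ss=float((residual**2).sum()), total_ss_x=ssx_total)


def compute_vip(model: OplsModel) -> np.ndarray:
    """Variable importance in the projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) with unit-norm
    weights; with a single predictive component this is sqrt(p) * |w_j| and
    the squared VIPs always sum to the number of features.
    """
    return model.vip


def _stratified_folds(y_pm: np.ndarray, folds: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (round-robin within class)."""
    assign = np.empty(len(y_pm), dtype=int)
    for cls in (-1.0, 1.0):
        idx = np.flatnonzero(y_pm == cls)
        assign[idx] = np.arange(len(idx)) % folds
    return [np.flatnonzero(assign == f) for f in range(folds)]


def cross_validated_q2(X: np.ndarray, y, folds: int = 7, n_orth: int = 1) -> float:
    """Q² = 1 - PRESS/SS over stratified cross-validation folds.

    Each training fold refits the OPLS-DA model from scratch (X is assumed
    already scaled; no re-scaling inside folds) and predicts the held-out
    decision values; SS is taken against the training-fold class mean.
    """
    X = np.asarray(X, dtype=float)
    y_pm, _ = _encode_labels(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, int((y_pm == 1).sum()), int((y_pm == -1).sum()))
    press = 0.0
    ss = 0.0
    for test_idx in _stratified_folds(y_pm, folds):
        train = np.ones(len(y_pm), dtype=bool)
        train[test_idx] = False
        if len(np.unique(y_pm[train])) < 2:
            raise ValueError("a training fold lost a class; reduce folds")
        model = fit_oplsda(X[train], y_pm[train], n_orth=n_orth)
        yhat = model.decision_values(X[test_idx])
        y_true = y_pm[test_idx]
        press += float(((y_true - yhat)**2).sum())
        ss += float(((y_true - y_pm[train].mean())**2).sum())
    return 1.0 - press / ss


def choose_n_orth(X: np.ndarray, y, max_orth: int = 5, folds: int = 7) -> int:
    """Number of orthogonal components maximising cross-validated Q²."""
    best_k, best_q2 = 0, -np.inf
    for k in range(max_orth + 1):
        q2 = cross_validated_q2(X, y, folds=folds, n_orth=k)
        if q2 > best_q2 + 1e-12:
            best_k, best_q2 = k, q2
    return best_k


def permutation_test(X: np.ndarray, y, n_perm: int = 100,
                     statistic: str = "q2", n_orth: int = 1, folds: int = 7,
                     seed: int | np.random.Generator = 0) -> PermutationResult:
    """Label-permutation significance of an OPLS-DA fit.

    ``statistic`` is ``"q2"`` (cross-validated) or ``"r2y"`` (apparent).  The
    observed statistic is compared with the same statistic recomputed under
    uniformly random label permutations; the exceedance count k yields both
    the raw k/n report and the add-one p-value (k+1)/(n+1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic not in ("q2", "r2y"):
        raise ValueError("statistic must be 'q2' or 'r2y'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    y_pm, _ = _encode_labels(y)

    def stat(labels: np.ndarray) -> float:
        if statistic == "q2":
            return cross_validated_q2(X, labels, folds=folds, n_orth=n_orth)
        return fit_oplsda(X, labels, n_orth=n_orth).r2y

    observed = stat(y_pm)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(y_pm)
        if len(np.unique(perm)) < 2:  # cannot happen for two-class y, defensive
            continue
        if stat(perm) >= observed:
            exceed += 1
    return PermutationResult(n_permutations=n_perm, n_exceeding=exceed,
                             observed=observed, statistic=statistic)
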