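"""Supervised multivariate modelling (chemometrics).

The modelling core of the pipeline: PCA with Hotelling-T2 outlier screening,
NIPALS PLS-DA, OPLS-DA (orthogonal signal correction with one predictive
component), Maximum Margin Criterion (MMC) projections, grouped
cross-validation with Q2 and accuracy, ROC/AUC, and the FDR-coloured
pseudo-loadings ANOVA used to read discriminatory variables off a model.

All decompositions are deterministic: NIPALS components are initialized from
the dominant covariance direction (SVD of X'Y) and every direction's sign is
fixed so its largest-magnitude element is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PcaModel",
    "SupervisedModel",
    "CvResult",
    "RocCurve",
    "fit_pca",
    "remove_outliers",
    "fit_plsda",
    "fit_oplsda",
    "fit_mmc",
    "cross_validate",
    "roc_auc",
    "pseudo_loadings_anova",
    "q2_score",
]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Flip a direction so its largest-magnitude element is positive."""
    i = int(np.argmax(np.abs(v)))
    return -v if v[i] < 0 else v


def _dummy_code(labels: Sequence) -> tuple[np.ndarray, list]:
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    lab = np.asarray(labels)
    Y = np.column_stack([(lab == c).astype(float) for c in classes])
    return Y, classes


# ----------------------------------------------------------------------- PCA


@dataclass
class PcaModel:
    loadings: np.ndarray          # components x variables, orthonormal rows
    scores: np.ndarray            # samples x components
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    hotelling_t2: np.ndarray
    t2_limit: float
    confidence: float


def fit_pca(X: np.ndarray, n_components: int, confidence: float = 0.95) -> PcaModel:
    """Centred SVD-based PCA with a Hotelling T2 outlier limit.

    T2 is computed from the first ``n_components`` scores; the limit is the
    standard F-distribution bound
    ``k (n^2 - 1) / (n (n - k)) * F_{confidence}(k, n - k)``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    k = n_components
    loadings = np.array([_fix_sign(v) for v in Vt[:k]])
    scores = Xc @ loadings.T
    var = (s[:k] ** 2) / (n - 1)
    total_var = (s**2).sum() / (n - 1)
    t2 = ((scores**2) / var).sum(axis=1)
    if n - k <= 0:
        raise ValueError("need n > n_components for a T2 limit")
    f_crit = stats.f.ppf(confidence, k, n - k)
    limit = k * (n**2 - 1) / (n * (n - k)) * f_crit
    return PcaModel(
        loadings=loadings,
        scores=scores,
        explained_variance=var,
        explained_variance_ratio=var / total_var,
        mean=mean,
        hotelling_t2=t2,
        t2_limit=float(limit),
        confidence=confidence,
    )


def remove_outliers(
    X: np.ndarray, model: PcaModel, sample_ids: Sequence | None = None
) -> tuple[np.ndarray, list]:
    """Drop rows whose Hotelling T2 exceeds the model's limit.

    Returns the reduced matrix and the identifiers (or indices) removed.
    Refuses to act when every row is flagged.
    """
    X = np.asarray(X, dtype=float)
    flagged = model.hotelling_t2 > model.t2_limit
    if flagged.all():
        raise ValueError("every sample exceeds the T2 limit; refusing to remove all rows")
    ids = list(sample_ids) if sample_ids is not None else list(range(X.shape[0]))
    removed = [ids[i] for i in np.flatnonzero(flagged)]
    return X[~flagged], removed


# ------------------------------------------------------------------- PLS-DA


@dataclass
class SupervisedModel:
    """A fitted discriminant projection (PLS-DA, OPLS-DA or MMC).

    ``weights`` maps centred data to predictive scores (for PLS this is
    R = W (P'W)^-1 under the NIPALS deflation convention, so
    ``scores = Xc @ weights``).  OPLS models additionally store the
    orthogonal weights/loadings/scores used to filter new data before
    scoring.
    """

    kind: str
    classes: list
    weights: np.ndarray               # variables x n_components
    loadings: np.ndarray | None       # variables x n_components (P)
    y_loadings: np.ndarray | None     # classes x n_components (Q)
    scores: np.ndarray                # training predictive scores
    x_mean: np.ndarray
    y_mean: np.ndarray | None
    n_components: int
    n_orthogonal: int = 0
    orthogonal_weights: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    orthogonal_scores: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    # -- projection -------------------------------------------------------
    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        if self.n_orthogonal and self.orthogonal_weights is not None:
            Xc = Xc.copy()
            for a in range(self.n_orthogonal):
                w_o = self.orthogonal_weights[:, a]
                p_o = self.orthogonal_loadings[:, a]
                t_o = Xc @ w_o
                Xc -= np.outer(t_o, p_o)
        return Xc

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Predictive scores of new samples."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        return self._filter(Xc) @ self.weights

    def predict_y(self, X: np.ndarray) -> np.ndarray:
        """Predicted dummy-Y (class indicator) values."""
        T = self.transform(X)
        if self.y_loadings is not None:
            return T @ self.y_loadings.T + self.y_mean
        # projection-only models (MMC): regress training Y on training scores
        B = self.extras["score_to_y"]
        return T @ B + self.y_mean

    def predict_classes(self, X: np.ndarray) -> np.ndarray:
        """Nearest class mean in predictive-score space."""
        T = self.transform(X)
        means = self.extras["class_score_means"]
        d = np.stack([np.linalg.norm(T - means[c], axis=1) for c in self.classes])
        return np.asarray(self.classes, dtype=object)[np.argmin(d, axis=0)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Scalar score for ROC: predicted indicator of the last (sorted) class."""
        return self.predict_y(X)[:, -1]


def _class_score_means(T: np.ndarray, labels: np.ndarray, classes: list) -> dict:
    return {c: T[labels == c].mean(axis=0) for c in classes}


def fit_plsda(X: np.ndarray, labels: Sequence, n_components: int = 2) -> SupervisedModel:
    """NIPALS PLS2 regression of dummy-coded class labels on X.

    Standard X/Y deflation; each component's weight vector is initialized
    from the dominant left singular vector of the current X'Y, giving a
    deterministic fit.
    """
    X = np.asarray(X, dtype=float)
    Y, classes = _dummy_code(labels)
    lab = np.asarray(labels)
    x_mean, y_mean = X.mean(axis=0), Y.mean(axis=0)
    Xa, Ya = X - x_mean, Y - y_mean
    n, p = Xa.shape
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds data rank bound")
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((Y.shape[1], n_components))
    T = np.zeros((n, n_components))
    for a in range(n_components):
        C = Xa.T @ Ya
        u_left, _, _ = np.linalg.svd(C, full_matrices=False)
        w = _fix_sign(u_left[:, 0])
        t = Xa @ w
        for _ in range(_NIPALS_MAX_ITER):
            q = Ya.T @ t / (t @ t)
            u = Ya @ q / (q @ q)
            w_new = Xa.T @ u
            nrm = np.linalg.norm(w_new)
            if nrm == 0:
                break
            w_new = _fix_sign(w_new / nrm)
            t_new = Xa @ w_new
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                w, t = w_new, t_new
                break
            w, t = w_new, t_new
        tt = t @ t
        if tt == 0:
            raise ValueError("degenerate component (zero score variance)")
        p_a = Xa.T @ t / tt
        q_a = Ya.T @ t / tt
        Xa = Xa - np.outer(t, p_a)
        Ya = Ya - np.outer(t, q_a)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, p_a, q_a, t
    R = W @ np.linalg.pinv(P.T @ W)
    model = SupervisedModel(
        kind="plsda",
        classes=classes,
        weights=R,
        loadings=P,
        y_loadings=Q,
        scores=T,
        x_mean=x_mean,
        y_mean=y_mean,
        n_components=n_components,
        extras={"W": W},
    )
    model.extras["class_score_means"] = _class_score_means(T, lab, classes)
    return model


# ------------------------------------------------------------------ OPLS-DA


def fit_oplsda(
    X: np.ndarray, labels: Sequence, n_predictive: int = 1, n_orthogonal: int = 1
) -> SupervisedModel:
    """OPLS-DA: orthogonal signal correction + one predictive component.

    Binary labels only (wrap one-vs-rest for multi-class).  Per orthogonal
    component the X-loading is stripped of its projection onto the predictive
    weight, and the resulting class-orthogonal variation is deflated from X
    before the final predictive component is extracted.
    """
    if n_predictive != 1:
        raise ValueError("OPLS-DA uses a single predictive component")
    X = np.asarray(X, dtype=float)
    Y, classes = _dummy_code(labels)
    if len(classes) != 2:
        raise ValueError("OPLS-DA requires binary labels; use one-vs-rest for multi-class")
    lab = np.asarray(labels)
    y = Y[:, 1]
    x_mean, y_mean_s = X.mean(axis=0), y.mean()
    Xa = X - x_mean
    yc = y - y_mean_s
    n, p = Xa.shape
    if n_orthogonal >= min(n - 1, p):
        raise ValueError(f"n_orthogonal={n_orthogonal} too large for rank bound")
    w = Xa.T @ yc
    w = _fix_sign(w / np.linalg.norm(w))
    W_o = np.zeros((p, n_orthogonal))
    P_o = np.zeros((p, n_orthogonal))
    T_o = np.zeros((n, n_orthogonal))
    for a in range(n_orthogonal):
        t = Xa @ w
        p_load = Xa.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:
            W_o = W_o[:, :a]
            P_o = P_o[:, :a]
            T_o = T_o[:, :a]
            n_orthogonal = a
            break
        w_o = _fix_sign(w_o / nrm)
        t_o = Xa @ w_o
        p_o = Xa.T @ t_o / (t_o @ t_o)
        Xa = Xa - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o
    t = Xa @ w
    p_pred = Xa.T @ t / (t @ t)
    c = yc @ t / (t @ t)
    # dummy-Y loadings for both indicator columns (second = 1 - first)
    Q = np.array([[-c], [c]])
    y_mean = np.array([1.0 - y_mean_s, y_mean_s])
    model = SupervisedModel(
        kind="oplsda",
        classes=classes,
        weights=w[:, None],
        loadings=p_pred[:, None],
        y_loadings=Q,
        scores=t[:, None],
        x_mean=x_mean,
        y_mean=y_mean,
        n_components=1,
        n_orthogonal=n_orthogonal,
        orthogonal_weights=W_o,
        orthogonal_loadings=P_o,
        orthogonal_scores=T_o,
    )
    model.extras["class_score_means"] = _class_score_means(t[:, None], lab, classes)
    return model


# ---------------------------------------------------------------------- MMC


def fit_mmc(
    X: np.ndarray,
    labels: Sequence,
    n_components: int = 2,
    pca_variance: float = 0.95,
    regularize: float = 0.0,
) -> SupervisedModel:
    """Maximum Margin Criterion projection.

    Projects onto the top eigenvectors of ``S_between - S_within`` computed
    from class means and the pooled within-class scatter.  When variables
    outnumber samples the scatter matrices are formed in a PCA subspace
    retaining ``pca_variance`` of the variance, which stabilizes them; the
    returned directions are mapped back to (and orthonormal in) the original
    variable space.
    """
    X = np.asarray(X, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(set(lab))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    counts = {c: int((lab == c).sum()) for c in classes}
    if min(counts.values()) < 2 and regularize <= 0:
        bad = [c for c, k in counts.items() if k < 2]
        raise ValueError(
            f"classes {bad} have a single sample; within-class scatter undefined "
            "(set regularize > 0 to proceed)"
        )
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    n, p = Xc.shape
    basis = None
    Z = Xc
    if p > n - 1:
        U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        var = s**2
        keep = max(
            int(np.searchsorted(np.cumsum(var) / var.sum(), pca_variance) + 1),
            min(n - 1, n_components + 1),
        )
        keep = min(keep, int((s > s[0] * 1e-12).sum()))
        basis = Vt[:keep]
        Z = Xc @ basis.T
    d = Z.shape[1]
    if n_components > d:
        raise ValueError(f"n_components={n_components} exceeds usable dimension {d}")
    overall = Z.mean(axis=0)
    Sb = np.zeros((d, d))
    Sw = np.zeros((d, d))
    for c in classes:
        Zc = Z[lab == c]
        mu = Zc.mean(axis=0)
        diff = mu - overall
        Sb += len(Zc) * np.outer(diff, diff)
        R = Zc - mu
        Sw += R.T @ R
    Sb /= n
    Sw /= n
    if regularize > 0:
        Sw += regularize * np.eye(d)
    M = Sb - Sw
    M = (M + M.T) / 2.0
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    dirs = np.column_stack([_fix_sign(evecs[:, i]) for i in order[:n_components]])
    if basis is not None:
        dirs_full = basis.T @ dirs
    else:
        dirs_full = dirs
    T = Xc @ dirs_full
    Y, _ = _dummy_code(lab)
    y_mean = Y.mean(axis=0)
    B, *_ = np.linalg.lstsq(T, Y - y_mean, rcond=None)
    model = SupervisedModel(
        kind="mmc",
        classes=classes,
        weights=dirs_full,
        loadings=None,
        y_loadings=None,
        scores=T,
        x_mean=x_mean,
        y_mean=y_mean,
        n_components=n_components,
        extras={"eigenvalues": evals[order][:n_components], "score_to_y": B},
    )
    model.extras["class_score_means"] = _class_score_means(T, lab, classes)
    return model


def _fit_by_spec(spec: Mapping, X: np.ndarray, labels: Sequence) -> SupervisedModel:
    kind = spec["kind"]
    params = {k: v for k, v in spec.items() if k != "kind"}
    if kind == "plsda":
        return fit_plsda(X, labels, **params)
    if kind == "oplsda":
        return fit_oplsda(X, labels, **params)
    if kind == "mmc":
        return fit_mmc(X, labels, **params)
    raise ValueError(f"unknown model kind {kind!r}")


# ----------------------------------------------------------- cross-validate


@dataclass
class CvResult:
    scheme: str
    q2: float
    accuracy: float
    predictions: pd.DataFrame        # per-sample predicted class + decision score
    y_pred: np.ndarray               # pooled CV dummy-Y predictions
    y_true: np.ndarray
    classes: list


def q2_score(Y: np.ndarray, Y_pred: np.ndarray) -> float:
    """Q2 = 1 - PRESS / TSS on (dummy) response values."""
    Y = np.asarray(Y, dtype=float)
    press = ((Y - Y_pred) ** 2).sum()
    tss = ((Y - Y.mean(axis=0)) ** 2).sum()
    return 1.0 - press / tss


def cross_validate(
    model_spec: Mapping,
    X: np.ndarray,
    labels: Sequence,
    groups: Sequence | None = None,
    scheme: str = "leave-one-sample-out",
    scale: bool = True,
) -> CvResult:
    """Grouped cross-validation with per-fold refitting of preprocessing.

    ``scheme`` is ``"leave-one-sample-out"`` or ``"leave-one-patient-out"``
    (the latter requires ``groups``; all rows of a patient are held out
    together, which is essential when replicate inserts share a patient).
    Per fold, column means/sds (when ``scale``) are estimated on training
    rows only and applied to the held-out rows.  Q2 = 1 - PRESS/TSS on the
    pooled dummy-Y predictions; accuracy is nearest-class-mean in predictive
    score space.
    """
    X = np.asarray(X, dtype=float)
    lab = np.asarray(labels)
    Y, classes = _dummy_code(lab)
    n = X.shape[0]
    if scheme in ("leave-one-sample-out", "loo"):
        folds = [np.array([i]) for i in range(n)]
        scheme = "leave-one-sample-out"
    elif scheme in ("leave-one-patient-out", "lopo"):
        if groups is None:
            raise ValueError("leave-one-patient-out requires group ids")
        groups = np.asarray(groups)
        folds = [np.flatnonzero(groups == g) for g in pd.unique(groups)]
        scheme = "leave-one-patient-out"
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    y_pred = np.full_like(Y, np.nan, dtype=float)
    pred_class = np.empty(n, dtype=object)
    decision = np.zeros(n)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        if len(set(lab[train_idx])) < 2:
            raise ValueError("a training fold contains a single class")
        X_tr, X_te = X[train_idx], X[test_idx]
        if scale:
            mu = X_tr.mean(axis=0)
            sd = X_tr.std(axis=0, ddof=1)
            sd = np.where(sd <= 0, 1.0, sd)
            X_tr = (X_tr - mu) / sd
            X_te = (X_te - mu) / sd
        model = _fit_by_spec(model_spec, X_tr, lab[train_idx])
        y_hat = model.predict_y(X_te)
        # align fold class columns with the global class list
        for j, c in enumerate(classes):
            if c in model.classes:
                y_pred[test_idx, j] = y_hat[:, model.classes.index(c)]
            else:
                y_pred[test_idx, j] = 0.0
        pred_class[test_idx] = model.predict_classes(X_te)
        decision[test_idx] = y_pred[test_idx, -1]
    assert not np.isnan(y_pred).any()
    q2 = q2_score(Y, y_pred)
    accuracy = float((pred_class == lab).mean())
    predictions = pd.DataFrame(
        {"label": lab, "predicted": pred_class, "decision_score": decision}
    )
    return CvResult(
        scheme=scheme,
        q2=float(q2),
        accuracy=accuracy,
        predictions=predictions,
        y_pred=y_pred,
        y_true=Y,
        classes=classes,
    )


# ------------------------------------------------------------------ ROC/AUC


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores: np.ndarray, labels: Sequence, positive=None) -> RocCurve:
    """ROC curve by threshold sweep over unique scores; AUC by trapezoid.

    Tied scores move together along the sweep, which averages ties (all-equal
    scores give AUC 0.5).
    """
    lab = np.asarray(labels)
    classes = sorted(set(lab))
    if len(classes) != 2:
        raise ValueError("ROC requires exactly two classes present")
    positive = classes[-1] if positive is None else positive
    y = (lab == positive).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("one class absent")
    fpr, tpr, thr = _sk_roc_curve(y, np.asarray(scores, dtype=float),
                                  drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


# --------------------------------------------------- pseudo-loadings ANOVA


def pseudo_loadings_anova(
    X,
    labels: Sequence,
    scores: np.ndarray | None = None,
    class_of_interest=None,
    variable_names: Sequence | None = None,
) -> pd.DataFrame:
    """Per-variable one-way ANOVA with BH-FDR and signed covariance loading.

    For every variable: one-way ANOVA p across classes (constant variables
    get p = 1 by convention), Benjamini-Hochberg q, a direction sign (mean in
    the class of interest minus mean in the reference class) and a magnitude
    equal to the covariance of the variable with the model's predictive score
    (a pseudo-loading).  ``X`` may be a 2-D array or an object with ``.X``
    and ``.bins`` (a spectral matrix), in which case bins name the variables.
    """
    if hasattr(X, "X"):
        if variable_names is None:
            variable_names = [f"{b:.5f}" for b in X.bins]
        X = X.X
    X = np.asarray(X, dtype=float)
    lab = np.asarray(labels)
    classes = sorted(set(lab))
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    interest = classes[-1] if class_of_interest is None else class_of_interest
    reference = classes[0] if interest != classes[0] else classes[-1]
    groups = [X[lab == c] for c in classes]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=0)
        p = np.asarray(res.pvalue, dtype=float)
    const = X.std(axis=0) <= 0
    p[~np.isfinite(p)] = 1.0
    p[const] = 1.0
    q = multipletests(p, method="fdr_bh")[1]
    diff = X[lab == interest].mean(axis=0) - X[lab == reference].mean(axis=0)
    sign = np.sign(diff).astype(int)
    sign[const] = 0
    if scores is None:
        n_comp = 1 if len(classes) == 2 else 2
        scores = fit_mmc(X, lab, n_components=n_comp).scores[:, 0]
    s = np.asarray(scores, dtype=float).ravel()
    sc = s - s.mean()
    magnitude = (X - X.mean(axis=0)).T @ sc / (len(s) - 1)
    out = pd.DataFrame(
        {
            "sign": sign,
            "magnitude": magnitude,
            "p_anova": p,
            "q_fdr": q,
        }
    )
    if variable_names is not None:
        out.index = list(variable_names)
    return out
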