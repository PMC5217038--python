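"""Two-class PLS-DA with the full chemometric validation surface.

The model is PLS1 on a single 0/1 class dummy, fitted by NIPALS with
sequential deflation on unit-variance-scaled data.  Reported alongside the
fit: R2X and R2Y (fractions of X- and class-variance explained), Q2 from
stratified k-fold cross-validation (scaling re-estimated inside each
training fold, so no leakage), VIP scores (whose mean square is 1 by
construction), an n-permutation label-shuffling validation with a +1/+1
empirical p-value, and the axis-aligned Hotelling T^2 confidence ellipse
for the 2-component score plot.

Conventions: Y is the single dummy column for the lexicographically larger
class (S = 1 when classes are P/S); the first nonzero element of every
weight vector is forced positive so refits are bit-identical; NIPALS stops
at a relative score change below 1e-10 or 500 iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataio import FeatureMatrix, SampleSheet

logger = logging.getLogger("stemomics")

__all__ = [
    "autoscale",
    "PLSDAModel",
    "fit_plsda",
    "predict_scores",
    "predict_y",
    "cross_validate_q2",
    "vip_scores",
    "select_discriminant",
    "PermutationRecord",
    "permutation_validate",
    "hotelling_ellipse",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAX_ITER = 500


def autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Mean-center and scale each column to unit variance (sd with n-1).

    Returns ``(X_scaled, mu, sigma, kept)`` where ``kept`` is a boolean mask
    over columns; constant columns are excluded with a warning (their sigma
    would be 0).
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=1)
    kept = ~np.isclose(sigma, 0)
    if not kept.all():
        logger.warning("autoscale: excluding %d constant feature(s)",
                       int((~kept).sum()))
    Xs = (X[:, kept] - mu[kept]) / sigma[kept]
    return Xs, mu[kept], sigma[kept], kept


def _encode_classes(y) -> tuple[np.ndarray, dict[str, int]]:
    labels = [str(v) for v in y]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly 2 classes, got {classes}")
    encoding = {classes[0]: 0, classes[1]: 1}
    yv = np.array([encoding[v] for v in labels], dtype=float)
    for c in classes:
        if labels.count(c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    return yv, encoding


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, n_components: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sequential NIPALS on centered/scaled X and centered y.

    Returns (W, P, T, q): unit-norm weights, X-loadings, scores and
    y-loadings per extracted component.  With a single Y column the NIPALS
    inner iteration converges in one pass (u is fixed at the y-residual),
    so each component is extracted in closed form; the generic tolerance
    (relative score change < 1e-10, <= 500 iterations) only matters for a
    multi-column Y and is kept as the documented contract.  Extraction
    stops early, with a warning, when X or its covariance with y is
    numerically exhausted (rank of X reached).
    """
    X = Xs.copy()
    u = yc.copy()
    W, P, T, q = [], [], [], []
    for a in range(n_components):
        wv = X.T @ u
        norm = np.linalg.norm(wv)
        if norm < 1e-12:
            logger.warning("NIPALS: X exhausted after %d component(s); "
                           "truncating", a)
            break
        wv = wv / norm
        # deterministic sign: first nonzero weight element positive
        nz = np.nonzero(~np.isclose(wv, 0))[0]
        if nz.size and wv[nz[0]] < 0:
            wv = -wv
        t = X @ wv
        tt = float(t @ t)
        if tt < 1e-12:
            logger.warning("NIPALS: degenerate score at component %d; "
                           "truncating", a)
            break
        pa = (X.T @ t) / tt
        qa = float(u @ t) / tt
        X = X - np.outer(t, pa)
        u = u - t * qa
        W.append(wv)
        P.append(pa)
        T.append(t)
        q.append(qa)
    if not W:
        raise ValueError("NIPALS could not extract any component")
    return (np.column_stack(W), np.column_stack(P), np.column_stack(T),
            np.array(q))


@dataclass
class PLSDAModel:
    """Fitted two-class PLS-DA: weights/loadings/scores per component plus
    scaling, fit statistics and (optionally) cross-validated Q2."""

    weights: np.ndarray        # p_kept x A, unit-norm columns
    x_loadings: np.ndarray     # p_kept x A
    scores: np.ndarray         # n x A
    y_loadings: np.ndarray     # A
    mu: np.ndarray
    sigma: np.ndarray
    kept: np.ndarray           # mask over input features
    y_mean: float
    feature_names: list[str]
    class_encoding: dict[str, int]
    R2X: float
    R2Y: float
    Q2: float | None = None
    permutation: "PermutationRecord | None" = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def vip(self) -> np.ndarray:
        return vip_scores(self)


def _prepare_xy(X, y, sheet: SampleSheet | None):
    """Accept a FeatureMatrix (features x samples) + sheet, or a plain
    samples x features array + labels."""
    if isinstance(X, FeatureMatrix):
        names = list(X.features)
        Xmat = X.values.T
        if y is None:
            if sheet is None:
                raise ValueError("a sample sheet or labels are required")
            cond = dict(zip(sheet.sample_id, sheet.condition))
            y = [cond[s] for s in X.samples]
    else:
        Xmat = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xmat.shape[1])]
        if y is None:
            raise ValueError("labels y are required for array input")
    if np.isnan(Xmat).any():
        raise ValueError("PLS-DA input contains missing values")
    return Xmat, list(y), names


def fit_plsda(X, y=None, n_components: int = 2, *,
              sheet: SampleSheet | None = None) -> PLSDAModel:
    """Fit a two-class PLS-DA model on unit-variance-scaled data.

    ``X`` is either a :class:`FeatureMatrix` (with labels taken from
    ``sheet`` conditions) or a samples x features array with explicit ``y``.
    ``n_components`` beyond the rank of X is truncated with a warning.
    """
    Xmat, labels, names = _prepare_xy(X, y, sheet)
    yv, encoding = _encode_classes(labels)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Xs, mu, sigma, kept = autoscale(Xmat)
    y_mean = yv.mean()
    yc = yv - y_mean
    W, P, T, q = _nipals_pls1(Xs, yc, n_components)
    ssx = float((Xs ** 2).sum())
    ssy = float((yc ** 2).sum())
    r2x = float(sum((T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a])
                    for a in range(W.shape[1])) / ssx)
    r2y = float(sum((q[a] ** 2) * (T[:, a] @ T[:, a])
                    for a in range(W.shape[1])) / ssy)
    return PLSDAModel(
        weights=W, x_loadings=P, scores=T, y_loadings=q,
        mu=mu, sigma=sigma, kept=kept, y_mean=float(y_mean),
        feature_names=[n for n, k in zip(names, kept) if k],
        class_encoding=encoding, R2X=r2x, R2Y=r2y,
    )


def _regression_vector(model: PLSDAModel) -> np.ndarray:
    W, P, q = model.weights, model.x_loadings, model.y_loadings
    return W @ np.linalg.solve(P.T @ W, q)


def predict_scores(model: PLSDAModel, Xnew: np.ndarray) -> np.ndarray:
    """Project new samples (raw feature space) onto the model's components."""
    Xs = (np.asarray(Xnew, dtype=float)[:, model.kept] - model.mu) / model.sigma
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    return Xs @ R


def predict_y(model: PLSDAModel, Xnew: np.ndarray) -> np.ndarray:
    """Predicted class dummy (continuous); >= 0.5 classifies as class 1."""
    Xs = (np.asarray(Xnew, dtype=float)[:, model.kept] - model.mu) / model.sigma
    return Xs @ _regression_vector(model) + model.y_mean


def _stratified_folds(yv: np.ndarray, folds: int) -> np.ndarray:
    """Deterministic stratified fold assignment: samples ordered by class,
    then dealt round-robin; folds = n reduces to leave-one-out."""
    order = np.concatenate([np.nonzero(yv == c)[0] for c in (0.0, 1.0)])
    fold_of = np.empty(len(yv), dtype=int)
    for counter, idx in enumerate(order):
        fold_of[idx] = counter % folds
    return fold_of


def cross_validate_q2(X, y=None, n_components: int = 2, folds: int = 7, *,
                      sheet: SampleSheet | None = None) -> float:
    """Q2 = 1 - PRESS/TSS by stratified k-fold CV.

    Scaling (and the y offset) are re-estimated inside each training fold;
    PRESS accumulates squared prediction error over held-out samples only.
    """
    Xmat, labels, _ = _prepare_xy(X, y, sheet)
    yv, _ = _encode_classes(labels)
    n = len(yv)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    folds = min(folds, n)
    fold_of = _stratified_folds(yv, folds)
    press = 0.0
    for k in range(folds):
        test = fold_of == k
        train = ~test
        if len(set(yv[train])) < 2:
            raise ValueError(
                f"fold {k} leaves a single-class training set; reduce folds"
            )
        Xs, mu, sigma, kept = autoscale(Xmat[train])
        y_mean = yv[train].mean()
        W, P, T, q = _nipals_pls1(Xs, yv[train] - y_mean, n_components)
        B = W @ np.linalg.solve(P.T @ W, q)
        Xt = (Xmat[test][:, kept] - mu) / sigma
        yhat = Xt @ B + y_mean
        press += float(((yv[test] - yhat) ** 2).sum())
    tss = float(((yv - yv.mean()) ** 2).sum())
    return 1.0 - press / tss


def vip_scores(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt( p * sum_a SSY_a w_ja^2 / sum_a SSY_a ) with
    SSY_a = q_a^2 t_a.t_a (class variance explained by component a) and
    unit-norm weights, so sum_j VIP_j^2 = p exactly.
    """
    W, T, q = model.weights, model.scores, model.y_loadings
    p = W.shape[0]
    ssy = np.array([(q[a] ** 2) * (T[:, a] @ T[:, a])
                    for a in range(W.shape[1])])
    total = ssy.sum()
    if total <= 0:
        raise ValueError("model explains no class variance; VIP undefined")
    return np.sqrt(p * (W ** 2 @ ssy) / total)


def select_discriminant(model: PLSDAModel, p_values, *,
                        vip_threshold: float = 1.0,
                        p_threshold: float = 0.05) -> list[str]:
    """Features with VIP > 1 and univariate p < 0.05 (both configurable).

    ``p_values`` is either a mapping keyed by feature name (dict or Series)
    or an array aligned with ``model.feature_names``.
    """
    vip = vip_scores(model)
    if isinstance(p_values, (dict,)) or hasattr(p_values, "loc"):
        pv = np.asarray([float(p_values[n]) for n in model.feature_names])
    else:
        pv = np.asarray(p_values, dtype=float)
    if pv.shape != vip.shape:
        raise ValueError("p_values do not align with model features")
    return [n for n, v, p in zip(model.feature_names, vip, pv)
            if v > vip_threshold and p < p_threshold]


@dataclass
class PermutationRecord:
    """Label-permutation null for R2Y/Q2 with the +1/+1 empirical p-value."""

    n_perm: int
    permuted_R2Y: np.ndarray
    permuted_Q2: np.ndarray
    observed_R2Y: float
    observed_Q2: float
    empirical_p_Q2: float
    n_failed: int = 0


def permutation_validate(X, y=None, n_components: int = 2,
                         n_perm: int = 100, seed: int | None = None, *,
                         folds: int = 7,
                         sheet: SampleSheet | None = None) -> PermutationRecord:
    """Repeated permutation test: refit R2Y and Q2 under shuffled labels.

    empirical_p_Q2 = (1 + #{permuted Q2 >= observed Q2}) / (n_ok + 1), so a
    model beating all permutations reports 1/(n_perm + 1), never 0.  Rounds
    whose refit fails (e.g. a degenerate permutation) are excluded and
    counted.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    Xmat, labels, _ = _prepare_xy(X, y, sheet)
    rng = np.random.default_rng(seed)
    obs_model = fit_plsda(Xmat, labels, n_components)
    obs_q2 = cross_validate_q2(Xmat, labels, n_components, folds)
    perm_r2y, perm_q2 = [], []
    n_failed = 0
    labels_arr = np.asarray(labels)
    for _ in range(n_perm):
        perm = labels_arr[rng.permutation(len(labels_arr))]
        try:
            m = fit_plsda(Xmat, perm, n_components)
            q2 = cross_validate_q2(Xmat, perm, n_components, folds)
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        perm_r2y.append(m.R2Y)
        perm_q2.append(q2)
    perm_q2_arr = np.asarray(perm_q2)
    p = (1 + int((perm_q2_arr >= obs_q2).sum())) / (len(perm_q2_arr) + 1)
    if n_failed:
        logger.warning("permutation_validate: %d/%d rounds failed and were "
                       "excluded", n_failed, n_perm)
    return PermutationRecord(
        n_perm=n_perm,
        permuted_R2Y=np.asarray(perm_r2y),
        permuted_Q2=perm_q2_arr,
        observed_R2Y=obs_model.R2Y,
        observed_Q2=obs_q2,
        empirical_p_Q2=float(p),
        n_failed=n_failed,
    )


def hotelling_ellipse(t1, t2, alpha: float = 0.05) -> tuple[float, float]:
    """Semi-axes of the axis-aligned (1 - alpha) Hotelling T^2 ellipse for a
    2-component score plot.

    semi_a = sd(t_a) * sqrt( 2 (n-1) / (n-2) * F_{2, n-2}(1 - alpha) ).
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    n = len(t1)
    if len(t2) != n:
        raise ValueError("score vectors differ in length")
    if n < 3:
        raise ValueError("Hotelling ellipse needs >= 3 samples")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(1.0 - alpha, 2, n - 2)
    return (
        float(t1.std(ddof=1) * np.sqrt(crit)),
        float(t2.std(ddof=1) * np.sqrt(crit)),
    )
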