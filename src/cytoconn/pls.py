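"""Orthogonalized partial least squares for cytokine signatures.

This module implements, from scratch, the latent-variable modelling used to
link regional cytokine panels to age (PLS regression) or genotype (PLS
discriminant analysis):

* NIPALS PLS with a univariate response,
* O-PLS style orthogonalization that concentrates all response-predictive
  covariance on the first latent variable while leaving predictions unchanged,
* Wold VIP scores (mean squared VIP equals 1 by construction),
* repeated k-fold cross-validation for latent-variable selection
  (k = 3 when n > 30, else k = 5; 100 random repartitions; candidates 1-3 LVs),
* permutation significance: the response is shuffled, the cross-validated
  statistic recomputed, and the observed statistic standardised against the
  null as Z = (x_model - mu_null) / sigma_null with a normal-tail p-value.

The response is age in months for regression models and a -1/+1 class code
for discriminant models (two-group designs throughout).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "CVResult",
    "PermutationResult",
    "zscore_fit",
    "zscore_apply",
    "zscore_fit_apply",
    "fit_pls",
    "predict",
    "orthogonalize",
    "vip_scores",
    "choose_k",
    "cross_validate",
    "permutation_test",
    "z_and_p",
    "signature_report",
]

_NIPALS_TOL = 1e-10
_NIPALS_MAXITER = 500


# ---------------------------------------------------------------------------
# scaling

def zscore_fit(X: np.ndarray, names: list[str] | None = None):
    """Column means and SDs of a training matrix; constant columns raise."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        labels = [names[i] for i in bad] if names else list(bad)
        raise ValueError(f"constant training columns: {labels}")
    return mu, sd


def zscore_apply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - mu) / sd


def zscore_fit_apply(X_train: np.ndarray, X_apply: np.ndarray | None = None,
                     names: list[str] | None = None):
    """Z-score using training statistics; apply the same scaling elsewhere."""
    mu, sd = zscore_fit(X_train, names)
    Zt = zscore_apply(X_train, mu, sd)
    if X_apply is None:
        return Zt, (mu, sd)
    return Zt, zscore_apply(X_apply, mu, sd), (mu, sd)


# ---------------------------------------------------------------------------
# core model

@dataclass
class PLSModel:
    """Fitted (optionally orthogonalized) PLS model with a univariate response.

    ``W, T, P`` hold per-LV weights, scores and X-loadings; ``q`` the y
    loadings.  For orthogonalized models the response-orthogonal components
    live in ``W_orth / T_orth / P_orth`` and the single predictive component
    occupies the first (only) column of ``W/T/P``.  Training data are stored
    in z-scored form together with the centring/scaling parameters so the
    model can be re-expressed or orthogonalized after the fact.
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    n_components: int
    mode: str                      # "regression" | "da"
    names: list[str]
    X_train: np.ndarray            # z-scored training matrix
    y_train: np.ndarray
    W_orth: np.ndarray | None = None
    T_orth: np.ndarray | None = None
    P_orth: np.ndarray | None = None

    @property
    def is_orthogonalized(self) -> bool:
        return self.W_orth is not None

    def coefficients(self) -> np.ndarray:
        """Regression vector b such that yhat = Xz @ b + y_mean."""
        PtW = self.P.T @ self.W
        return self.W @ np.linalg.solve(PtW, self.q)


def _nipals(X: np.ndarray, y: np.ndarray, A: int):
    """NIPALS decomposition for a single response column.

    Returns weights W (unit norm), scores T, X-loadings P and y-loadings q.
    With one response the inner loop converges after one pass; the iteration
    is retained for robustness and capped at 500 passes / 1e-10 change.
    """
    n, p = X.shape
    Xa = X.copy()
    ya = y.astype(float).copy()
    W = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    for a in range(A):
        w = Xa.T @ ya
        nrm = np.linalg.norm(w)
        if nrm < 1e-14:
            raise np.linalg.LinAlgError(
                f"no X-y covariance left at component {a + 1}")
        w = w / nrm
        for _ in range(_NIPALS_MAXITER):
            t = Xa @ w
            qa = float(ya @ t) / float(t @ t)
            w_new = Xa.T @ (ya * qa)
            w_new /= np.linalg.norm(w_new)
            delta = np.linalg.norm(w_new - w)
            w = w_new
            if delta < _NIPALS_TOL:
                break
        t = Xa @ w
        tt = float(t @ t)
        p_a = Xa.T @ t / tt
        q_a = float(ya @ t) / tt
        Xa = Xa - np.outer(t, p_a)
        ya = ya - t * q_a
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    return W, T, P, q


def fit_pls(X: np.ndarray, y: np.ndarray, A: int, mode: str = "regression",
            names: list[str] | None = None, scale: bool = True) -> PLSModel:
    """Fit an A-component PLS model.

    ``X`` is raw (unscaled) and is z-scored internally (column mean 0, SD 1);
    ``y`` is age in months for regression or a two-level label / -1,+1 code
    for discriminant analysis, and is mean-centred.  Components are oriented
    so the first y-loading is positive (loadings then read as up/down with
    the response).
    """
    X = np.asarray(X, dtype=float)
    y = _encode_response(y, mode)
    n, p = X.shape
    if not 1 <= A <= min(n - 1, p):
        raise ValueError(f"A={A} out of range for a {n} x {p} matrix")
    names = list(names) if names is not None else [f"x{i}" for i in range(p)]
    if scale:
        mu, sd = zscore_fit(X, names)
    else:
        mu, sd = np.zeros(p), np.ones(p)
    Xz = zscore_apply(X, mu, sd)
    y_mean = float(np.mean(y))
    W, T, P, q = _nipals(Xz, y - y_mean, A)
    flip = np.where(q >= 0, 1.0, -1.0)
    W, T, P, q = W * flip, T * flip, P * flip, q * flip
    return PLSModel(W=W, T=T, P=P, q=q, x_mean=mu, x_sd=sd, y_mean=y_mean,
                    n_components=A, mode=mode, names=names,
                    X_train=Xz, y_train=y - y_mean)


def _encode_response(y, mode: str) -> np.ndarray:
    y = np.asarray(y)
    if mode == "regression":
        return y.astype(float)
    if mode != "da":
        raise ValueError("mode must be 'regression' or 'da'")
    levels = np.unique(y)
    if len(levels) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {levels}")
    return np.where(y == levels[-1], 1.0, -1.0)


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted response (continuous) for new raw observations."""
    Xz = zscore_apply(np.atleast_2d(np.asarray(X_new, float)),
                      model.x_mean, model.x_sd)
    if model.is_orthogonalized:
        for a in range(model.W_orth.shape[1]):
            t_o = Xz @ model.W_orth[:, a]
            Xz = Xz - np.outer(t_o, model.P_orth[:, a])
    yhat = Xz @ model.coefficients() + model.y_mean
    return yhat


def classify(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Class code (-1/+1) by sign of the predicted response."""
    return np.where(predict(model, X_new) >= 0, 1.0, -1.0)


def orthogonalize(model: PLSModel) -> PLSModel:
    """O-PLS re-expression: A-1 response-orthogonal components + 1 predictive.

    Response-orthogonal variation is peeled off the training matrix one
    component at a time (weights orthogonal to the X-y covariance direction),
    then a single predictive component is fitted to the filtered matrix.  For
    a univariate response this re-expression leaves predictions numerically
    identical to the original A-component model.
    """
    if model.is_orthogonalized:
        return model
    A = model.n_components
    Xc = model.X_train.copy()
    y = model.y_train
    w = Xc.T @ y
    w = w / np.linalg.norm(w)
    W_o, T_o, P_o = [], [], []
    for _ in range(A - 1):
        t = Xc @ w
        p_a = Xc.T @ t / float(t @ t)
        w_o = p_a - float(w @ p_a) * w
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12:       # nothing orthogonal left to remove
            break
        w_o = w_o / nrm
        t_o = Xc @ w_o
        p_o = Xc.T @ t_o / float(t_o @ t_o)
        Xc = Xc - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    Wp, Tp, Pp, qp = _nipals(Xc, y, 1)
    if qp[0] < 0:
        Wp, Tp, Pp, qp = -Wp, -Tp, -Pp, -qp
    stack = (lambda cols: np.column_stack(cols) if cols else None)
    return PLSModel(W=Wp, T=Tp, P=Pp, q=qp, x_mean=model.x_mean,
                    x_sd=model.x_sd, y_mean=model.y_mean, n_components=A,
                    mode=model.mode, names=model.names, X_train=model.X_train,
                    y_train=model.y_train, W_orth=stack(W_o),
                    T_orth=stack(T_o), P_orth=stack(P_o))


def vip_scores(model: PLSModel) -> np.ndarray:
    """Wold variable-importance-in-projection scores.

        VIP_f = sqrt( p * sum_a SSY_a (w_fa / ||w_a||)^2 / sum_a SSY_a )

    where SSY_a = q_a^2 t_a' t_a is the response variance explained by
    component a.  Because weights have unit norm, mean(VIP^2) = 1.  For an
    orthogonalized model the VIP is computed from the predictive plus
    orthogonal components of the underlying decomposition of X-y covariance,
    i.e. from the original (non-orthogonalized) fit when available.
    """
    if model.is_orthogonalized:
        base = fit_pls(
            model.X_train, model.y_train + model.y_mean, model.n_components,
            mode="regression", names=model.names, scale=False)
        return vip_scores(base)
    p = model.W.shape[0]
    ssy = model.q ** 2 * np.einsum("ia,ia->a", model.T, model.T)
    wn = model.W / np.linalg.norm(model.W, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2 @ ssy) / ssy.sum())


# ---------------------------------------------------------------------------
# model selection and significance

@dataclass
class CVResult:
    """Repeated k-fold cross-validation over candidate component counts."""

    statistics: np.ndarray          # repeats x candidates
    candidates: tuple[int, ...]
    chosen_A: int
    k: int
    mode: str
    n_reshuffled: int = 0

    @property
    def mean_statistic(self) -> np.ndarray:
        return self.statistics.mean(axis=0)

    def chosen_statistic(self) -> float:
        return float(self.mean_statistic[self.candidates.index(self.chosen_A)])


@dataclass
class PermutationResult:
    """Permutation-null standardisation of the cross-validated statistic."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_permutations: int
    mode: str
    null_values: np.ndarray = field(repr=False, default=None)


def choose_k(n: int) -> int:
    """Fold count rule: 3 folds when n > 30, else 5 (n = 30 -> 5)."""
    if n < 6:
        raise ValueError("need at least 6 samples for cross-validation")
    return 3 if n > 30 else 5


def _cv_statistic(X, y_enc, A, k, mode, rng, max_reshuffle=20,
                  global_scaling=False):
    """One CV repeat: random k-fold partition, z-scoring refit per training fold.

    ``global_scaling=True`` z-scores once on the full matrix instead
    (compatibility with pipelines that scaled before splitting; leaks scale
    information across folds and is off by default).
    """
    n = len(y_enc)
    for _ in range(max_reshuffle):
        perm = rng.permutation(n)
        folds = np.array_split(perm, k)
        if mode != "da" or all(len(np.unique(y_enc[np.setdiff1d(perm, f)])) == 2
                               for f in folds):
            break
    else:
        raise RuntimeError("could not build folds with both classes in training")
    if global_scaling:
        mu, sd = zscore_fit(X)
        X = zscore_apply(X, mu, sd)
    preds = np.empty(n)
    for f in folds:
        train = np.setdiff1d(perm, f)
        m = fit_pls(X[train], y_enc[train], A, mode="regression",
                    scale=not global_scaling)
        preds[f] = predict(m, X[f])
    if mode == "da":
        return float(np.mean(np.where(preds >= 0, 1.0, -1.0) == y_enc))
    return float(np.sqrt(np.mean((preds - y_enc) ** 2)))


def cross_validate(X: np.ndarray, y: np.ndarray, mode: str = "regression",
                   candidates: tuple[int, ...] = (1, 2, 3), repeats: int = 100,
                   seed: int | np.random.Generator = 0,
                   global_scaling: bool = False) -> CVResult:
    """Repeated random k-fold CV to pick the latent-variable count.

    Every repeat draws a fresh random partition; per candidate A the model is
    refitted on each training fold (z-scoring refit inside the fold) and the
    held-out samples predicted.  The statistic per repeat is RMSECV
    ``sqrt(mean((pred - y)^2))`` for regression or classification accuracy
    for discriminant analysis.  The chosen A minimises mean RMSECV
    (maximises mean accuracy); ties break toward fewer components.
    ``global_scaling`` z-scores once on the full matrix instead of per
    training fold (compatibility option; leaks scale across folds).
    """
    X = np.asarray(X, dtype=float)
    y_enc = _encode_response(y, mode)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = choose_k(len(y_enc))
    stat = np.empty((repeats, len(candidates)))
    for r in range(repeats):
        # one partition per repeat, shared across candidates
        seed_r = int(rng.integers(2 ** 31))
        for c, A in enumerate(candidates):
            stat[r, c] = _cv_statistic(X, y_enc, A, k, mode,
                                       np.random.default_rng(seed_r),
                                       global_scaling=global_scaling)
    mean = stat.mean(axis=0)
    if mode == "da":
        best = int(np.argmax(np.round(mean, 12)))
    else:
        best = int(np.argmin(np.round(mean, 12)))
    return CVResult(statistics=stat, candidates=tuple(candidates),
                    chosen_A=candidates[best], k=k, mode=mode)


def z_and_p(observed: float, null_mean: float, null_sd: float, mode: str):
    """Standardised permutation statistic and its normal-tail p-value.

    Z = (observed - null_mean) / null_sd.  The p-value is one-tailed in the
    favourable direction: lower RMSECV is better for regression
    (p = Phi(Z)), higher accuracy is better for discriminant analysis
    (p = 1 - Phi(Z)).  A degenerate null (sd = 0) yields NaN.
    """
    if null_sd == 0 or not np.isfinite(null_sd):
        return float("nan"), float("nan")
    z = (observed - null_mean) / null_sd
    p = stats.norm.cdf(z) if mode == "regression" else stats.norm.sf(z)
    return float(z), float(p)


def permutation_test(X: np.ndarray, y: np.ndarray, chosen_A: int,
                     mode: str = "regression", n_perm: int = 1000,
                     cv_repeats: int = 10,
                     seed: int | np.random.Generator = 0) -> PermutationResult:
    """Permutation significance of the cross-validated model.

    Each permutation shuffles the response against the covariate rows and
    recomputes the cross-validated statistic at the chosen component count.
    The observed statistic is recomputed with the same number of CV repeats
    (``cv_repeats``) so observed and null values are exchangeable under the
    null hypothesis.  ``cv_repeats`` defaults to 10 (rather than the 100 used
    for component selection) because the statistic enters only through its
    null standardisation.
    """
    X = np.asarray(X, dtype=float)
    y_enc = _encode_response(y, mode)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = choose_k(len(y_enc))

    def stat_for(y_use):
        vals = [_cv_statistic(X, y_use, chosen_A, k, mode,
                              np.random.default_rng(rng.integers(2 ** 31)))
                for _ in range(cv_repeats)]
        return float(np.mean(vals))

    observed = stat_for(y_enc)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = stat_for(rng.permutation(y_enc))
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    z, p = z_and_p(observed, mu, sd, mode)
    return PermutationResult(observed=observed, null_mean=mu, null_sd=sd,
                             z=z, p=p, n_permutations=n_perm, mode=mode,
                             null_values=null)


def signature_report(model: PLSModel, threshold: float = 1.0):
    """Analytes with VIP above threshold, ranked, with signed LV1 loadings.

    Positive loadings mark analytes that rise with the response (the model is
    oriented so the first y-loading is positive); requires an orthogonalized
    model so LV1 carries all predictive covariance.
    """
    import pandas as pd
    if not model.is_orthogonalized and model.n_components > 1:
        raise ValueError("signature_report expects an orthogonalized model")
    vip = vip_scores(model)
    lv1 = model.P[:, 0]
    df = pd.DataFrame({"analyte": model.names, "vip": vip, "lv1_loading": lv1,
                       "direction": np.where(lv1 >= 0, "up", "down")})
    df = df[df["vip"] > threshold].sort_values("vip", ascending=False)
    return df.reset_index(drop=True)
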