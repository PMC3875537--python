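"""Two-class OPLS-DA: NIPALS with built-in orthogonal signal correction.

A single predictive latent variable captures the between-class covariance,
while ``n_ortho`` orthogonal components absorb systematic within-class
variation uncorrelated with the 0/1 class response.  The fitted model
reports R2X / R2Y (explained X and Y sum of squares), cross-validated
Q2Y = 1 - PRESS/SS, and a CV-ANOVA F-test for model significance.

Algorithm (on column-centered X, mean-centered y):

    w  = X'y / ||X'y||                      predictive weights (unit norm)
    repeat n_ortho times:
        t   = X w
        p   = X't / t't
        w_o = (p - (w'p) w) / ||.||         weights of Y-orthogonal variation
        t_o = X w_o ;  p_o = X't_o / t_o't_o
        X  <- X - t_o p_o'                  orthogonal signal correction
    t  = X w ;  p = X't / t't
    b  = t'y / t't                          inner regression coefficient

The predictive score ``t`` is orthogonal to every ``t_o``, and each ``t_o``
is uncorrelated with ``y``.  ``w`` is oriented so the positive class (coded
1) has positive mean score, which makes S-plot signs interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

_CENTERING_TOL = 1e-8


class DegenerateModelError(ValueError):
    """X carries no covariance with the class response."""


class RankError(ValueError):
    """More orthogonal components requested than X's rank supports."""


class FoldCompositionError(ValueError):
    """A cross-validation fold's training part contains a single class."""


@dataclass
class DummyResponse:
    """0/1 class coding for a two-group contrast.

    ``values[i] == 1`` for samples of ``positive_class``, 0 otherwise.
    """

    values: np.ndarray
    positive_class: str
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        codes = set(np.unique(self.values).tolist())
        if not codes <= {0.0, 1.0} or len(codes) != 2:
            raise ValueError(f"dummy response must contain exactly the codes 0 and 1, got {sorted(codes)}")
        n1 = int(self.values.sum())
        n0 = self.values.size - n1
        if min(n0, n1) < 2:
            raise ValueError(f"both classes need >= 2 samples (got {n0} vs {n1})")

    @property
    def y_mean(self) -> float:
        return float(self.values.mean())

    @property
    def centered(self) -> np.ndarray:
        return self.values - self.values.mean()


def dummy_response(labels: Sequence[str], positive_class: str,
                   sample_ids: Sequence[str] | None = None) -> DummyResponse:
    """Code *labels* as 1 for ``positive_class`` and 0 for everything else."""
    labels = list(labels)
    if positive_class not in labels:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    y = np.array([1.0 if c == positive_class else 0.0 for c in labels])
    return DummyResponse(values=y, positive_class=positive_class,
                         sample_ids=list(sample_ids) if sample_ids is not None else None)


@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model (one predictive component)."""

    w: np.ndarray                 # predictive weights, unit norm (n_genes,)
    t: np.ndarray                 # predictive scores (n_samples,)
    p: np.ndarray                 # predictive loadings (n_genes,)
    W_o: np.ndarray               # orthogonal weights (n_genes, n_ortho)
    T_o: np.ndarray               # orthogonal scores (n_samples, n_ortho)
    P_o: np.ndarray               # orthogonal loadings (n_genes, n_ortho)
    b: float                      # inner regression coefficient, ŷ = b·t + y_mean
    n_ortho: int
    x_means: np.ndarray           # training column means (for projecting new data)
    y_mean: float
    r2x: float
    r2y: float
    positive_class: str
    gene_ids: list[str] | None = None
    q2y: float | None = None
    press: float | None = None
    ss: float | None = None

    @property
    def s_t(self) -> float:
        """Sample standard deviation of the predictive score."""
        return float(np.std(self.t, ddof=1))


def _check_centered(X: np.ndarray) -> None:
    if X.shape[0] and np.abs(X.mean(axis=0)).max() > _CENTERING_TOL:
        raise ValueError(
            "X must be column-centered (max |column mean| = "
            f"{np.abs(X.mean(axis=0)).max():.3g})"
        )


def fit_opls(X: np.ndarray, y: DummyResponse, n_ortho: int = 0, *,
             x_means: np.ndarray | None = None,
             gene_ids: Sequence[str] | None = None) -> OplsModel:
    """Fit OPLS-DA on a column-centered sample x gene matrix.

    Parameters
    ----------
    X:
        Samples in rows, genes in columns, each column mean-centered
        (tolerance 1e-8).
    y:
        0/1 class coding; its mean is removed internally.
    n_ortho:
        Number of Y-orthogonal components to strip before extracting the
        predictive component.
    x_means:
        The gene means that were subtracted to center X, kept so new data
        can be projected; defaults to zeros (X already in centered units).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x genes)")
    n, p_genes = X.shape
    if n != y.values.size:
        raise ValueError(f"X has {n} rows but y has {y.values.size} samples")
    if n < 4:
        raise ValueError("need at least 4 samples")
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if n_ortho >= min(n, p_genes):
        raise RankError(f"n_ortho={n_ortho} >= min(X.shape)={min(n, p_genes)}")
    _check_centered(X)

    yc = y.centered
    x_norm2 = float(np.sum(X * X))

    cov = X.T @ yc
    cov_norm = float(np.linalg.norm(cov))
    scale = float(np.linalg.norm(X, ord="fro")) * float(np.linalg.norm(yc))
    if scale == 0 or cov_norm < 1e-10 * scale:
        raise DegenerateModelError("X carries no covariance with the class response")
    w = cov / cov_norm

    Xd = X.copy()
    Wo = np.zeros((p_genes, n_ortho))
    To = np.zeros((n, n_ortho))
    Po = np.zeros((p_genes, n_ortho))
    for k in range(n_ortho):
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-12 * max(x_norm2, 1.0):
            raise RankError(f"predictive direction vanished after {k} deflations")
        pvec = Xd.T @ t / tt
        w_o = pvec - float(w @ pvec) * w
        nw_o = float(np.linalg.norm(w_o))
        if nw_o < 1e-10 * max(float(np.linalg.norm(pvec)), 1e-30):
            raise RankError(
                f"no Y-orthogonal variation left for component {k + 1} "
                f"(requested n_ortho={n_ortho})"
            )
        w_o = w_o / nw_o
        t_o = Xd @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < 1e-12 * max(x_norm2, 1.0):
            raise RankError(f"orthogonal score {k + 1} vanished: rank exhausted")
        p_o = Xd.T @ t_o / tt_o
        Xd = Xd - np.outer(t_o, p_o)
        Wo[:, k], To[:, k], Po[:, k] = w_o, t_o, p_o

    t = Xd @ w
    tt = float(t @ t)
    if tt < 1e-12 * max(x_norm2, 1.0):
        raise RankError("predictive score vanished after orthogonal deflation")
    pvec = Xd.T @ t / tt
    b = float(t @ yc) / tt

    # orient so the positive class sits on the positive side of t
    if b < 0:
        w, t, pvec, b = -w, -t, -pvec, -b
        # t_o p_o' deflations are unaffected

    resid = yc - b * t
    ss_y = float(yc @ yc)
    r2y = 1.0 - float(resid @ resid) / ss_y
    explained = tt * float(pvec @ pvec) + sum(
        float(To[:, k] @ To[:, k]) * float(Po[:, k] @ Po[:, k]) for k in range(n_ortho)
    )
    r2x = explained / x_norm2 if x_norm2 > 0 else 0.0

    if x_means is None:
        x_means = np.zeros(p_genes)
    else:
        x_means = np.asarray(x_means, dtype=float)
        if x_means.shape != (p_genes,):
            raise ValueError("x_means length must match gene count")

    return OplsModel(
        w=w, t=t, p=pvec, W_o=Wo, T_o=To, P_o=Po, b=b, n_ortho=n_ortho,
        x_means=x_means, y_mean=y.y_mean, r2x=r2x, r2y=r2y,
        positive_class=y.positive_class,
        gene_ids=list(gene_ids) if gene_ids is not None else None,
    )


def predict(model: OplsModel, X_new: np.ndarray,
            gene_ids: Sequence[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Project new samples and predict their class score.

    *X_new* is sample x gene in the same (log10) units the training means
    were computed in.  Returns ``(y_hat, t_new)``; ``y_hat`` is unbounded,
    values above 0.5 lean toward the positive class.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.w.size:
        raise KeyError(
            f"X_new has {X_new.shape[1]} genes, model expects {model.w.size}"
        )
    if gene_ids is not None and model.gene_ids is not None:
        if list(gene_ids) != model.gene_ids:
            raise KeyError("gene ids of X_new do not match the model's training genes")
    Xc = X_new - model.x_means
    for k in range(model.n_ortho):
        t_o = Xc @ model.W_o[:, k]
        Xc = Xc - np.outer(t_o, model.P_o[:, k])
    t_new = Xc @ model.w
    y_hat = model.b * t_new + model.y_mean
    return y_hat, t_new


# -- cross-validation ------------------------------------------------------

@dataclass
class Q2Result:
    q2y: float
    press: float
    ss: float
    n_folds: int
    scheme: str
    n_ortho: int
    fold_sizes: list[int] = field(default_factory=list)


def _fold_assignment(n: int, n_folds: int, scheme: str, seed: int | None) -> np.ndarray:
    if scheme == "venetian_blind":
        return np.arange(n) % n_folds
    if scheme == "contiguous":
        return np.repeat(np.arange(n_folds), np.diff(np.linspace(0, n, n_folds + 1).astype(int)))
    if scheme == "random":
        rng = np.random.default_rng(seed)
        return rng.permutation(np.arange(n) % n_folds)
    raise ValueError(f"unknown CV scheme {scheme!r}")


def cross_validate(X: np.ndarray, y: DummyResponse, n_ortho: int = 0,
                   n_folds: int = 7, scheme: str = "venetian_blind",
                   seed: int | None = None) -> Q2Result:
    """Cross-validated predictive ability Q2Y = 1 - PRESS/SS.

    Each fold is refit from scratch: the fold's training columns are
    re-centered on their own means (no leakage from held-out samples), the
    held-out responses are predicted, and squared errors accumulate into
    PRESS.  SS is the total response sum of squares about the full-data
    mean.  The default venetian-blind scheme (sample i -> fold i mod
    n_folds) is deterministic, so Q2 needs no seed.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must be in [2, {n}], got {n_folds}")
    folds = _fold_assignment(n, n_folds, scheme, seed)

    y_all = y.values
    press = 0.0
    fold_sizes = []
    for f in range(n_folds):
        test = folds == f
        train = ~test
        if not test.any():
            continue
        y_tr = y_all[train]
        if len(np.unique(y_tr)) < 2 or min((y_tr == 0).sum(), (y_tr == 1).sum()) < 2:
            raise FoldCompositionError(
                f"fold {f}: training part lacks two classes with >= 2 samples each; "
                "use fewer folds or a stratified scheme"
            )
        x_means = X[train].mean(axis=0)
        Xtr = X[train] - x_means
        y_fold = DummyResponse(values=y_tr, positive_class=y.positive_class)
        model = fit_opls(Xtr, y_fold, n_ortho=n_ortho, x_means=x_means)
        y_hat, _ = predict(model, X[test])
        press += float(np.sum((y_all[test] - y_hat) ** 2))
        fold_sizes.append(int(test.sum()))

    ss = float(np.sum((y_all - y_all.mean()) ** 2))
    return Q2Result(q2y=1.0 - press / ss, press=press, ss=ss,
                    n_folds=n_folds, scheme=scheme, n_ortho=n_ortho,
                    fold_sizes=fold_sizes)


def select_n_ortho(X: np.ndarray, y: DummyResponse, max_ortho: int = 5,
                   gain_threshold: float = 0.01, n_folds: int = 7,
                   scheme: str = "venetian_blind", seed: int | None = None) -> int:
    """Pick the orthogonal-component count by cross-validated gain.

    Starts at 0 and accepts another orthogonal component while Q2Y improves
    by more than ``gain_threshold``; deterministic for deterministic fold
    schemes.
    """
    if max_ortho < 0:
        raise ValueError("max_ortho must be >= 0")
    best = cross_validate(X, y, n_ortho=0, n_folds=n_folds, scheme=scheme, seed=seed).q2y
    chosen = 0
    for k in range(1, max_ortho + 1):
        try:
            q2 = cross_validate(X, y, n_ortho=k, n_folds=n_folds,
                                scheme=scheme, seed=seed).q2y
        except RankError:
            break
        if q2 > best + gain_threshold:
            best, chosen = q2, k
        else:
            break
    return chosen


def cv_anova(q2_result: Q2Result, n_samples: int,
             n_components: int) -> tuple[float, float]:
    """CV-ANOVA significance of a cross-validated model.

    Compares the reduction of the response sum of squares achieved by the
    cross-validated predictions against the residual predictive error:

        F = ((SS - PRESS) / d1) / (PRESS / d2)

    with d1 degrees of freedom spent on the extracted components (here one
    per component: 1 predictive + n_ortho) and d2 = n_samples - d1 - 1.
    A negative F (PRESS > SS, i.e. the model predicts worse than the mean)
    maps to p = 1.
    """
    press, ss = q2_result.press, q2_result.ss
    if press <= 0:
        raise ValueError("PRESS must be positive")
    d1 = n_components
    d2 = n_samples - d1 - 1
    if d2 <= 0:
        raise ValueError(
            f"insufficient samples: n={n_samples} leaves d2={d2} residual DoF"
        )
    f_stat = ((ss - press) / d1) / (press / d2)
    if f_stat < 0:
        return f_stat, 1.0
    p = float(stats.f.sf(f_stat, d1, d2))
    return float(f_stat), p


# -- matrix-level convenience ---------------------------------------------

def fit_opls_da(m: ExpressionMatrix, positive_class: str,
                n_ortho: int | str = "auto", max_ortho: int = 5,
                n_folds: int = 7, scheme: str = "venetian_blind",
                seed: int | None = None) -> OplsModel:
    """Fit OPLS-DA from an :class:`ExpressionMatrix` in log10 or centered state.

    Columns (samples) become rows; gene means over these samples are removed
    and stored on the model so test data can be projected.  With
    ``n_ortho="auto"`` the component count comes from :func:`select_n_ortho`,
    and the returned model carries the corresponding Q2Y/PRESS/SS.
    """
    m.require_state("log10", "centered")
    X_raw = m.values.T  # samples x genes
    x_means = X_raw.mean(axis=0)
    X = X_raw - x_means
    y = dummy_response(m.label_vector(), positive_class, sample_ids=m.sample_ids)
    if n_ortho == "auto":
        k = select_n_ortho(X, y, max_ortho=max_ortho, n_folds=n_folds,
                           scheme=scheme, seed=seed)
    else:
        k = int(n_ortho)
    model = fit_opls(X, y, n_ortho=k, x_means=x_means, gene_ids=m.gene_ids)
    cv = cross_validate(X, y, n_ortho=k, n_folds=n_folds, scheme=scheme, seed=seed)
    model.q2y, model.press, model.ss = cv.q2y, cv.press, cv.ss
    return model
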