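"""PCA and NIPALS PLS2-DA: the unconstrained latent-variable engine.

One NIPALS code path serves both plain PLS2-DA and the orthogonally
constrained variant: the latter injects a projection of the weight vector
after each weight update (see :mod:`terroirpls.ocpls`). NIPALS rather than a
kernel or SIMPLS formulation is used precisely so that this injection point
exists; all model variants share the same deflation and bookkeeping.

Sign convention: every component is flipped so that the largest-magnitude
entry of its weight vector is positive, making outputs reproducible across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ClassResponse

__all__ = [
    "LatentModel",
    "ConfoundedConstraintError",
    "fit_pca",
    "fit_pls2da",
    "predict",
    "classify",
]

CONV_TOL = 1e-10
MAX_ITER = 500


class ConfoundedConstraintError(ValueError):
    """Raised when the class structure lies entirely inside the forbidden span."""


@dataclass
class LatentModel:
    """Scores, loadings and weights of a fitted projection model.

    Attributes
    ----------
    kind
        One of ``pca``, ``pls2da``, ``ocpls2da``, ``oplsda``.
    A
        Number of (predictive) latent components.
    W, P, T
        X-weights (features x A), X-loadings (features x A) and scores
        (samples x A). For PCA, W is equal to P.
    C
        Y-loadings (classes x A); ``None`` for PCA.
    y_mean
        Column means of Y removed before fitting (Y is centered, never
        scaled, inside the fit).
    W_o, P_o, T_o
        Orthogonal-component blocks (OPLS-DA only).
    """

    kind: str
    A: int
    W: np.ndarray
    P: np.ndarray
    T: np.ndarray
    C: np.ndarray | None = None
    classes: list = field(default_factory=list)
    y_mean: np.ndarray | None = None
    r2x_per_component: np.ndarray | None = None
    r2y_cumulative: np.ndarray | None = None
    W_o: np.ndarray | None = None
    P_o: np.ndarray | None = None
    T_o: np.ndarray | None = None
    sample_ids: list | None = None
    feature_ids: list | None = None

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def rotation(self) -> np.ndarray:
        """W* = W (P'W)^-1, mapping centered X to scores: T = X W*."""
        return self.W @ np.linalg.inv(self.P.T @ self.W)

    def coefficients(self) -> np.ndarray:
        """Regression coefficients B with Yhat_centered = X_centered B."""
        if self.C is None:
            raise ValueError("model has no Y block")
        return self.rotation() @ self.C.T


def _sign_flip(w: np.ndarray) -> float:
    s = np.sign(w[np.argmax(np.abs(w))])
    return 1.0 if s == 0 else float(s)


def fit_pca(X: np.ndarray, A: int) -> LatentModel:
    """PCA of a centered matrix via singular value decomposition.

    Successive components maximize explained variance; scores are orthogonal
    and per-component explained-variance fractions are reported.
    """
    X = np.asarray(X, dtype=float)
    if A < 1:
        raise ValueError("A must be >= 1")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if A > rank:
        raise ValueError(f"A={A} exceeds rank {rank} of X")
    P = Vt[:A].T
    flips = np.array([_sign_flip(P[:, a]) for a in range(A)])
    P = P * flips
    T = U[:, :A] * s[:A] * flips
    ssx = float(np.sum(X**2))
    r2x = (s[:A] ** 2) / ssx
    return LatentModel(
        kind="pca", A=A, W=P.copy(), P=P, T=T, r2x_per_component=r2x
    )


def _nipals_pls2(
    X: np.ndarray,
    Yc: np.ndarray,
    A: int,
    Z: np.ndarray | None = None,
    conv_tol: float = CONV_TOL,
    max_iter: int = MAX_ITER,
):
    """Shared NIPALS loop; Z (centered constraint block) may be None/empty.

    Per component: u -> w = X'u/(u'u) -> [project w off the span of X'Z]
    -> normalize -> t = Xw -> c = Y't/(t't) -> u = Yc/(c'c), iterated until
    the score stabilizes; X is then deflated by t p' and Y by t c'.
    """
    Xd = X.copy()
    Yd = Yc.copy()
    n, p = Xd.shape
    constrained = Z is not None and Z.size > 0 and Z.shape[1] > 0
    rank = np.linalg.matrix_rank(X)
    if A > rank:
        raise ValueError(f"A={A} exceeds rank {rank} of X")
    ssx = float(np.sum(X**2))
    ssy = float(np.sum(Yc**2))
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    C = np.empty((Yc.shape[1], A))
    r2x = np.empty(A)
    r2y = np.empty(A)
    for a in range(A):
        if constrained:
            A0 = Xd.T @ Z  # p x c, the forbidden span for this component
            proj = np.linalg.pinv(A0.T @ A0, rcond=1e-12) @ A0.T
        # initialize u along the dominant singular direction of the
        # (projected) X'Y block: the NIPALS fixed point, so the power
        # iteration converges in a couple of steps even when trailing
        # singular values are nearly degenerate
        M = Xd.T @ Yd
        if constrained:
            M = M - A0 @ (proj @ M)
        _, sM, VtM = np.linalg.svd(M, full_matrices=False)
        if sM.size == 0 or sM[0] <= 0:
            raise ValueError(
                f"component {a + 1}: no response covariance left to model"
            )
        u = Yd @ VtM[0]
        if np.linalg.norm(u) == 0:
            u = Yd[:, np.argmax(np.sum(Yd**2, axis=0))].copy()
        t_old = None
        for _ in range(max_iter):
            w = Xd.T @ u / (u @ u)
            if constrained:
                w_norm_before = np.linalg.norm(w)
                w = w - A0 @ (proj @ w)
                if np.linalg.norm(w) < 1e-8 * w_norm_before:
                    raise ConfoundedConstraintError(
                        f"component {a + 1}: class structure confounded with "
                        "constraint (projected weight vanishes)"
                    )
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(f"component {a + 1}: zero weight vector")
            w = w / nw
            t = Xd @ w
            c = Yd.T @ t / (t @ t)
            u = Yd @ c / (c @ c)
            if t_old is not None and np.linalg.norm(t - t_old) <= conv_tol * np.linalg.norm(t):
                break
            t_old = t
        else:
            raise RuntimeError(
                f"NIPALS did not converge within {max_iter} iterations at "
                f"component {a + 1}"
            )
        flip = _sign_flip(w)
        w, t, c = w * flip, t * flip, c * flip
        pvec = Xd.T @ t / (t @ t)
        Xd -= np.outer(t, pvec)
        Yd -= np.outer(t, c)
        W[:, a], P[:, a], T[:, a], C[:, a] = w, pvec, t, c
        r2x[a] = (t @ t) * (pvec @ pvec) / ssx
        r2y[a] = 1.0 - float(np.sum(Yd**2)) / ssy
    return W, P, T, C, r2x, r2y


def fit_pls2da(X: np.ndarray, Y: ClassResponse, A: int) -> LatentModel:
    """NIPALS PLS2 discriminant analysis on a centered X and dummy-coded Y."""
    X = np.asarray(X, dtype=float)
    if A < 1:
        raise ValueError("A must be >= 1")
    y_mean = Y.Y.mean(axis=0)
    Yc = Y.Y - y_mean
    W, P, T, C, r2x, r2y = _nipals_pls2(X, Yc, A)
    return LatentModel(
        kind="pls2da",
        A=A,
        W=W,
        P=P,
        T=T,
        C=C,
        classes=list(Y.classes),
        y_mean=y_mean,
        r2x_per_component=r2x,
        r2y_cumulative=r2y,
    )


def predict(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted responses Yhat (original dummy scale) for preprocessed X_new.

    X_new must already be transformed with the model's stored preprocessing
    parameters (the cross-validation machinery takes care of this).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model has {model.n_features}, "
            f"X_new has {X_new.shape[1]}"
        )
    if model.kind == "oplsda":
        from .opls import filter_orthogonal

        X_new = filter_orthogonal(model, X_new)
    return X_new @ model.coefficients() + model.y_mean


def classify(Yhat: np.ndarray, classes: list) -> np.ndarray:
    """Assign each row to the class of its maximal predicted response.

    Ties are broken toward the earlier class in the stored class order.
    """
    Yhat = np.atleast_2d(Yhat)
    if Yhat.shape[1] < 2:
        raise ValueError("need >=2 response columns to classify")
    idx = np.argmax(Yhat, axis=1)  # argmax takes the first maximum
    return np.asarray(classes, dtype=object)[idx]
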