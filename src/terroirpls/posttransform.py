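"""Post-transformation: rotate a fitted PLS-DA/oCPLS2-DA model so that all
class-discriminating variation is concentrated in N-1 predictive components.

A fitted model with A components discriminating N classes generically
spreads the between-class structure over all A score directions. The
post-transformation finds an orthogonal rotation G of the score (and
weight) space such that only the first ``n_predictive = rank(Yc'T)`` rotated
components carry class information, while the remaining rotated scores are
exactly uncorrelated with the centered response. Because G is orthogonal and
acts inside the fitted score space, fitted and new-sample predictions are
unchanged.

Construction: singular value decomposition of M = Yc'T (N x A). The right
singular vectors with nonzero singular value span the predictive directions
(ordered by decreasing singular value); the null-space vectors span the
orthogonal directions, reordered by decreasing rotated-score variance so the
leading orthogonal component is the most interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import ClassResponse
from .latent import LatentModel

__all__ = ["PostTransformedModel", "post_transform", "predict_posttransformed"]

RANK_TOL = 1e-10  # relative singular-value cutoff for rank(Yc'T)


@dataclass
class PostTransformedModel:
    """A fitted latent model plus the orthogonal rotation splitting its
    score space into predictive and response-orthogonal blocks."""

    base: LatentModel
    G: np.ndarray  # A x A orthogonal, [G_pred | G_orth]
    n_predictive: int
    T_pred: np.ndarray
    T_orth: np.ndarray
    W_pred: np.ndarray
    W_orth: np.ndarray

    @property
    def C_rot(self) -> np.ndarray:
        """Y-loadings in the rotated basis (zero on the orthogonal block)."""
        return self.base.C @ self.G


def post_transform(model: LatentModel, Y: ClassResponse) -> PostTransformedModel:
    """Rotate the weight/score space of ``model`` around the response.

    Returns a model whose first ``n_predictive <= N-1`` rotated components
    hold all the class structure; the rest satisfy Yc'T_orth = 0.
    Emits a warning when A < N-1 (nothing to split off).
    """
    if model.C is None:
        raise ValueError("post-transformation needs a supervised model")
    A = model.A
    N = Y.n_classes
    Yc = Y.Y - Y.Y.mean(axis=0)
    M = Yc.T @ model.T  # N x A
    U, s, Vt = np.linalg.svd(M)
    smax = s[0] if s.size else 0.0
    r = int(np.sum(s > RANK_TOL * smax)) if smax > 0 else 0
    r = min(r, A)
    if A < N - 1:
        warnings.warn(
            f"model has A={A} < N-1={N - 1} components; rotation is "
            "identity-like and all components stay predictive",
            stacklevel=2,
        )
    G_pred = Vt[:r].T  # ordered by decreasing singular value of M
    G_orth = Vt[r:A].T
    if G_orth.shape[1] > 1:
        var = np.var(model.T @ G_orth, axis=0)
        G_orth = G_orth[:, np.argsort(var)[::-1]]
    G = np.hstack([G_pred, G_orth])
    return PostTransformedModel(
        base=model,
        G=G,
        n_predictive=r,
        T_pred=model.T @ G_pred,
        T_orth=model.T @ G_orth,
        W_pred=model.W @ G_pred,
        W_orth=model.W @ G_orth,
    )


def predict_posttransformed(pt: PostTransformedModel, X_new: np.ndarray) -> np.ndarray:
    """Predict through the rotated representation.

    Scores of new samples are rotated by G and combined with the rotated
    Y-loadings; algebraically identical to the base model's predictions
    (G Gᵀ = I), exposed so the invariance is directly checkable.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    t_new = X_new @ pt.base.rotation()
    return (t_new @ pt.G) @ pt.C_rot.T + pt.base.y_mean
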