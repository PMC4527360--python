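"""Orthogonal constrained PLS2-DA (oCPLS2-DA).

PLS-DA run on data whose dominant variation is a nuisance factor (here:
vintage) absorbs that factor into its latent space, so site ("terroir") and
vintage effects confound each other in the scores. oCPLS2-DA removes the
nuisance from the model by constraining every latent score to be orthogonal
to a centered dummy block Z coding the nuisance levels.

The constraint is enforced inside the PLS maximization itself: after each
NIPALS weight update the weight vector w is replaced by Q w, where
Q = I - A0 (A0'A0)^+ A0' projects onto the null space of A0' with
A0 = X'Z (X the currently deflated block). Since t = X w, w ⟂ col(A0)
implies t'Z = w'A0 = 0 exactly, for every component. A0 is recomputed from
the deflated X at each component because deflation changes the forbidden
span.

A simpler alternative — pre-projecting X itself onto the orthocomplement of
Z — is provided as :func:`project_out_constraint` for comparison; it removes
Z-related variance from the loadings as well and is a different estimator,
not the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ClassResponse, ConstraintBlock
from .latent import LatentModel, _nipals_pls2, fit_pls2da

__all__ = [
    "fit_ocpls2da",
    "project_out_constraint",
    "score_constraint_r2",
    "compare_confounding",
    "ConfoundingReport",
]


def fit_ocpls2da(
    X: np.ndarray,
    Y: ClassResponse,
    Z: ConstraintBlock | None,
    A: int,
) -> LatentModel:
    """Fit PLS2-DA with scores constrained orthogonal to the block Z.

    With ``Z`` absent or empty the code path is exactly that of plain
    PLS2-DA (the projector degenerates to the identity).

    Raises
    ------
    ConfoundedConstraintError
        If the class-predictive direction lies entirely inside the span
        forbidden by the constraint.
    """
    X = np.asarray(X, dtype=float)
    if A < 1:
        raise ValueError("A must be >= 1")
    Zmat = None
    if Z is not None:
        Zmat = np.asarray(Z.Z, dtype=float)
        if Zmat.ndim != 2 or Zmat.shape[0] != X.shape[0]:
            raise ValueError("constraint block row count must match X")
        colsum = np.abs(Zmat.sum(axis=0))
        if Zmat.size and colsum.max() > 1e-8 * max(1.0, np.abs(Zmat).max()):
            raise ValueError("constraint columns must be centered")
        if Zmat.shape[1] == 0:
            Zmat = None
    y_mean = Y.Y.mean(axis=0)
    Yc = Y.Y - y_mean
    W, P, T, C, r2x, r2y = _nipals_pls2(X, Yc, A, Z=Zmat)
    return LatentModel(
        kind="ocpls2da" if Zmat is not None else "pls2da",
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


def project_out_constraint(X: np.ndarray, Z: ConstraintBlock) -> np.ndarray:
    """Remove the constraint subspace from X itself: X - Z (Z'Z)^+ Z' X.

    Documented utility for comparison with the default weight-projection
    estimator; removes nuisance variance from loadings too.
    """
    Zmat = np.asarray(Z.Z, dtype=float)
    return X - Zmat @ (np.linalg.pinv(Zmat.T @ Zmat, rcond=1e-12) @ (Zmat.T @ X))


def score_constraint_r2(T: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """R-squared of each constraint column regressed on the score matrix T.

    Quantifies how much nuisance information the latent space retains;
    ordinary least squares per column.
    """
    T = np.atleast_2d(T)
    coef, *_ = np.linalg.lstsq(T, Z, rcond=None)
    resid = Z - T @ coef
    ssz = np.sum((Z - Z.mean(axis=0)) ** 2, axis=0)
    out = np.empty(Z.shape[1])
    for j in range(Z.shape[1]):
        out[j] = 1.0 - np.sum(resid[:, j] ** 2) / ssz[j] if ssz[j] > 0 else 0.0
    return out


@dataclass
class ConfoundingReport:
    """Side-by-side confounding diagnostics for PLS-DA vs oCPLS2-DA."""

    plsda_score_on_z_r2: np.ndarray | None
    ocpls_score_on_z_r2: np.ndarray | None
    plsda_cv_accuracy: float
    ocpls_cv_accuracy: float | None
    A: int
    n_folds: int
    arms: tuple = ("pls2da",)
    extras: dict = field(default_factory=dict)


def compare_confounding(
    X: np.ndarray,
    Y: ClassResponse,
    Z: ConstraintBlock | None,
    A: int,
    n_folds: int = 7,
    seed: int | None = None,
    preprocess: tuple = (),
    X_raw: np.ndarray | None = None,
) -> ConfoundingReport:
    """Fit PLS-DA and oCPLS2-DA on the same data and quantify confounding.

    Reports, for each arm, the R-squared of every constraint column
    regressed on the model scores, and the cross-validated classification
    accuracy. ``X`` is the preprocessed (centered) matrix used for the
    full-data fits; ``X_raw`` (defaulting to ``X``) feeds cross-validation,
    which re-applies ``preprocess`` per training fold.
    """
    from .validation import ModelRecipe, crossval_accuracy

    labels = Y.labels()
    if X_raw is None:
        X_raw = X
    pls = fit_pls2da(X, Y, A)
    rec_pls = ModelRecipe(method="pls2da", preprocess=preprocess)
    acc_pls = crossval_accuracy(rec_pls, X_raw, labels, A, n_folds, seed=seed)
    if Z is None:
        return ConfoundingReport(
            plsda_score_on_z_r2=None,
            ocpls_score_on_z_r2=None,
            plsda_cv_accuracy=acc_pls,
            ocpls_cv_accuracy=None,
            A=A,
            n_folds=n_folds,
            arms=("pls2da",),
        )
    oc = fit_ocpls2da(X, Y, Z, A)
    # each centered-dummy row peaks at its own level, so argmax recovers labels
    z_labels = np.argmax(Z.Z, axis=1)
    rec_oc = ModelRecipe(
        method="ocpls2da", preprocess=preprocess, constraint=z_labels
    )
    acc_oc = crossval_accuracy(rec_oc, X_raw, labels, A, n_folds, seed=seed)
    return ConfoundingReport(
        plsda_score_on_z_r2=score_constraint_r2(pls.T, Z.Z),
        ocpls_score_on_z_r2=score_constraint_r2(oc.T, Z.Z),
        plsda_cv_accuracy=acc_pls,
        ocpls_cv_accuracy=acc_oc,
        A=A,
        n_folds=n_folds,
        arms=("pls2da", "ocpls2da"),
    )
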