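"""OPLS-DA: orthogonal-filtered PLS discriminant analysis.

Structured X-variation uncorrelated with the class response is peeled off
into ``n_orth`` orthogonal components before min(N-1, rank) predictive
components are fitted on the filtered matrix. Per orthogonal component: the
current predictive weight w gives a provisional score t = Xw and loading
p = X't/(t't); the part of p outside the response-predictive span is the
orthogonal weight, t_o = X w_o its score, and X is deflated by t_o p_o'.

For a two-class response this is the classical single-y construction
(w_o = p - (w'p/w'w) w). With N > 2 classes the predictive span has N-1
directions, so p is projected off an orthonormal basis of col(X'Yc) rather
than off the single w; this keeps T_o'Yc = 0 exact for any N.

The models behind the terroir-feature battery (altitude, soil pH, training
system, ... classifications) are OPLS-DA models validated by 7-fold Q2 and a
permutation test; a model is flagged reliable only when Q2 > 0.5 and the
permutation test passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import orth

from .io import ClassResponse, StudyDesign, dummy_code
from .latent import LatentModel, _nipals_pls2

__all__ = ["fit_oplsda", "filter_orthogonal", "feature_model_battery"]


def fit_oplsda(X: np.ndarray, Y: ClassResponse, n_orth: int) -> LatentModel:
    """Fit OPLS-DA with ``n_orth`` Y-orthogonal components.

    The returned model has A = min(N-1, rank of filtered X) predictive
    components in W/P/T/C and the orthogonal block in W_o/P_o/T_o.
    """
    X = np.asarray(X, dtype=float)
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    N = Y.n_classes
    rank = np.linalg.matrix_rank(X)
    n_pred = min(N - 1, rank)
    if n_orth > rank - n_pred:
        raise ValueError(
            f"n_orth={n_orth} exceeds rank {rank} minus {n_pred} predictive "
            "components"
        )
    y_mean = Y.Y.mean(axis=0)
    Yc = Y.Y - y_mean
    Xd = X.copy()
    n, p = X.shape
    W_o = np.empty((p, n_orth))
    P_o = np.empty((p, n_orth))
    T_o = np.empty((n, n_orth))
    for k in range(n_orth):
        S = Xd.T @ Yc  # p x N, the response-predictive span
        V = orth(S)
        # dominant predictive weight: first left singular vector of S
        u_, _, _ = np.linalg.svd(S, full_matrices=False)
        w = u_[:, 0]
        t = Xd @ w
        pvec = Xd.T @ t / (t @ t)
        w_o = pvec - V @ (V.T @ pvec)
        nrm = np.linalg.norm(w_o)
        if nrm < 1e-12 * np.linalg.norm(pvec):
            raise ValueError(
                f"orthogonal component {k + 1}: no Y-orthogonal structured "
                "variation left in X"
            )
        w_o = w_o / nrm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        W_o[:, k], P_o[:, k], T_o[:, k] = w_o, p_o, t_o
    W, P, T, C, r2x, r2y = _nipals_pls2(Xd, Yc, n_pred)
    return LatentModel(
        kind="oplsda",
        A=n_pred,
        W=W,
        P=P,
        T=T,
        C=C,
        classes=list(Y.classes),
        y_mean=y_mean,
        r2x_per_component=r2x,
        r2y_cumulative=r2y,
        W_o=W_o,
        P_o=P_o,
        T_o=T_o,
    )


def filter_orthogonal(model: LatentModel, X_new: np.ndarray) -> np.ndarray:
    """Remove the fitted orthogonal components from new (centered) data."""
    if model.W_o is None:
        return X_new
    Xf = np.array(X_new, dtype=float, copy=True)
    for k in range(model.W_o.shape[1]):
        t_o = Xf @ model.W_o[:, k]
        Xf -= np.outer(t_o, model.P_o[:, k])
    return Xf


@dataclass
class BatteryRow:
    name: str
    classes: list
    estimable: bool
    n_orth: int | None = None
    q2: float | None = None
    perm_p: float | None = None
    reliable: bool = False
    note: str = ""


def feature_model_battery(
    X_raw: np.ndarray,
    design: StudyDesign,
    feature_classifications: list,
    preprocess: tuple = ("center",),
    n_folds: int = 7,
    n_perm: int = 400,
    max_orth: int = 3,
    q2_threshold: float = 0.5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run a battery of OPLS-DA models, one per candidate classification.

    ``feature_classifications`` is a list of ``(name, labels)`` pairs, each
    labelling every sample (for instance by thresholding a vineyard feature
    such as altitude or soil pH). For each classification the number of
    orthogonal components is chosen by the first maximum of 7-fold Q2, a
    permutation test is run, and the model is flagged *reliable* when
    Q2 > ``q2_threshold`` and the permutation test passes. Classifications
    with an empty or single class are marked not-estimable and skipped;
    the run continues.
    """
    from .validation import ModelRecipe, crossval_q2, permutation_test

    rows = []
    for name, labels in feature_classifications:
        labels = np.asarray(labels)
        classes = list(pd.unique(labels))
        if len(classes) < 2 or min((labels == c).sum() for c in classes) == 0:
            rows.append(
                BatteryRow(name, classes, estimable=False, note="degenerate classes")
            )
            continue
        rec = ModelRecipe(method="oplsda", preprocess=preprocess)
        q2s = []
        for k in range(max_orth + 1):
            try:
                q2s.append(
                    crossval_q2(rec, X_raw, labels, A=k, n_folds=n_folds, seed=seed)
                )
            except ValueError:
                break
            if len(q2s) >= 2 and q2s[-2] >= q2s[-1]:
                break
        if not q2s:
            rows.append(
                BatteryRow(name, classes, estimable=False, note="model not estimable")
            )
            continue
        best_k = int(np.argmax(q2s)) if len(q2s) > 1 else 0
        # first local maximum: smallest k with Q2(k) >= Q2(k+1)
        best_k = len(q2s) - 1
        for k in range(len(q2s) - 1):
            if q2s[k] >= q2s[k + 1]:
                best_k = k
                break
        perm = permutation_test(
            rec, X_raw, labels, A=best_k, n_perm=n_perm, n_folds=n_folds, seed=seed
        )
        rows.append(
            BatteryRow(
                name,
                classes,
                estimable=True,
                n_orth=best_k,
                q2=q2s[best_k],
                perm_p=perm.p_value,
                reliable=bool(q2s[best_k] > q2_threshold and perm.passed),
            )
        )
    return pd.DataFrame(
        [
            {
                "model": r.name,
                "classes": "/".join(str(c) for c in r.classes),
                "estimable": r.estimable,
                "n_orth": r.n_orth,
                "q2": r.q2,
                "perm_p": r.perm_p,
                "reliable": r.reliable,
                "note": r.note,
            }
            for r in rows
        ]
    )
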