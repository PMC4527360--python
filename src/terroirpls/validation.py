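"""Model validation: N-fold full cross-validation Q2, permutation testing
and component selection.

"Full" cross-validation partitions the samples into N groups so that every
sample is held out exactly once (N = 6, 7, 8 are the schemes used for the
reported models; 7-fold drives component selection). Fold assignment is
deterministic and class-stratified: samples are ordered by (class, stable
index) and dealt round-robin into the folds, in the spirit of the venetian
blinds default of commercial chemometrics software; a seed only shuffles
within class when requested.

Preprocessing parameters (MFC reference, centers, scales) are re-estimated
inside each training fold and applied to the held-out rows, so no held-out
information leaks into the model.

Q2 = 1 - PRESS/SS with PRESS accumulated over all samples exactly once and
SS the squared norm of held-out responses centered with training-fold means.
The permutation test permutes the class labels, recomputes the 7-fold Q2,
and uses the add-one p-value estimator p = (1 + #{Q2_perm >= Q2_obs}) /
(n_perm + 1), so p is never exactly zero. The number of latent components is
the first local maximum of Q2(A) under the constraint that the selected
model passes the permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .io import ClassResponse, build_constraint_block, dummy_code
from .latent import LatentModel, classify, fit_pls2da, predict
from .preprocess import Preprocessor

__all__ = [
    "ModelRecipe",
    "ValidationReport",
    "PermutationRecord",
    "assign_folds",
    "crossval_q2",
    "crossval_accuracy",
    "permutation_test",
    "select_components",
    "r2y",
    "validate_model",
]


@dataclass
class ModelRecipe:
    """Bundle of preprocessing + model choice, refit per training fold.

    ``method`` is one of ``pls2da``, ``ocpls2da``, ``oplsda``. For
    ``ocpls2da`` the full-length per-sample nuisance labels go in
    ``constraint``; the constraint block is rebuilt (and recentered) on the
    training rows of each fold. For ``oplsda`` the component count passed to
    the cross-validation functions is the number of *orthogonal* components
    (the predictive count is fixed at N-1).
    """

    method: str = "pls2da"
    preprocess: tuple = ()
    constraint: np.ndarray | None = None
    epsilon: float = 1.0

    def fit(self, X_train_raw, labels_train, A, classes, constraint_train=None):
        prep = Preprocessor(tuple(self.preprocess) + ("center",), self.epsilon) \
            if "center" not in self.preprocess and "autoscale" not in self.preprocess \
            else Preprocessor(tuple(self.preprocess), self.epsilon)
        Xp = prep.fit_transform(np.asarray(X_train_raw, dtype=float))
        Y = _dummy_with_classes(labels_train, classes)
        if self.method == "pls2da":
            model = fit_pls2da(Xp, Y, A)
        elif self.method == "ocpls2da":
            from .ocpls import fit_ocpls2da

            if constraint_train is None:
                raise ValueError("ocpls2da recipe needs constraint labels")
            levels = pd.unique(np.asarray(constraint_train))
            Z = (
                build_constraint_block(constraint_train)
                if len(levels) >= 2
                else None
            )
            model = fit_ocpls2da(Xp, Y, Z, A)
        elif self.method == "oplsda":
            from .opls import fit_oplsda

            model = fit_oplsda(Xp, Y, n_orth=A)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return prep, model


def _dummy_with_classes(labels, classes) -> ClassResponse:
    """Dummy-code against a fixed, full class list (CV folds share columns)."""
    labels = np.asarray(labels)
    Y = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        Y[labels == cls, k] = 1.0
    return ClassResponse(list(classes), Y)


def assign_folds(
    labels, n_folds: int, seed: int | None = None
) -> np.ndarray:
    """Deterministic stratified fold assignment (round-robin within class).

    Returns an integer fold id per sample; every sample lands in exactly one
    fold. A seed shuffles sample order within each class before dealing.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > len(labels):
        raise ValueError("more folds than samples")
    classes = list(pd.unique(labels))
    rng = np.random.default_rng(seed) if seed is not None else None
    order = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if rng is not None:
            idx = rng.permutation(idx)
        order.extend(idx.tolist())
    folds = np.empty(len(labels), dtype=int)
    for pos, sample in enumerate(order):
        folds[sample] = pos % n_folds
    return folds


def _cv_loop(recipe, X_raw, labels, A, n_folds, seed, collect):
    X_raw = np.asarray(X_raw, dtype=float)
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("discrimination needs >=2 classes")
    folds = assign_folds(labels, n_folds, seed=seed)
    for f in range(n_folds):
        test = folds == f
        train = ~test
        for cls in classes:
            if not np.any(labels[train] == cls):
                raise ValueError(
                    f"fold {f} holds out every sample of class {cls!r}; "
                    "use fewer folds or stratify a larger class"
                )
        ctrain = (
            np.asarray(recipe.constraint)[train]
            if recipe.constraint is not None
            else None
        )
        prep, model = recipe.fit(
            X_raw[train], labels[train], A, classes, constraint_train=ctrain
        )
        X_test = prep.transform(X_raw[test])
        Yhat = predict(model, X_test)
        collect(f, test, train, model, Yhat, classes)


def crossval_q2(
    recipe: ModelRecipe,
    X_raw: np.ndarray,
    labels,
    A: int,
    n_folds: int = 7,
    seed: int | None = None,
) -> float:
    """Cross-validated Q2 = 1 - PRESS/SS for an A-component model."""
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    Yfull = _dummy_with_classes(labels, classes).Y
    acc = {"press": 0.0, "ss": 0.0}

    def collect(f, test, train, model, Yhat, classes_):
        Ytest = Yfull[test]
        ytrain_mean = Yfull[train].mean(axis=0)
        acc["press"] += float(np.sum((Ytest - Yhat) ** 2))
        acc["ss"] += float(np.sum((Ytest - ytrain_mean) ** 2))

    _cv_loop(recipe, X_raw, labels, A, n_folds, seed, collect)
    return 1.0 - acc["press"] / acc["ss"]


def crossval_accuracy(
    recipe: ModelRecipe,
    X_raw: np.ndarray,
    labels,
    A: int,
    n_folds: int = 7,
    seed: int | None = None,
) -> float:
    """Cross-validated classification accuracy (max-response rule)."""
    labels = np.asarray(labels)
    acc = {"correct": 0, "total": 0}

    def collect(f, test, train, model, Yhat, classes_):
        pred = classify(Yhat, classes_)
        acc["correct"] += int(np.sum(pred == labels[test]))
        acc["total"] += int(test.sum())

    _cv_loop(recipe, X_raw, labels, A, n_folds, seed, collect)
    return acc["correct"] / acc["total"]


@dataclass
class PermutationRecord:
    n_perm: int
    observed_q2: float
    null_q2: np.ndarray
    p_value: float
    passed: bool
    seed: int | None = None


def permutation_test(
    recipe: ModelRecipe,
    X_raw: np.ndarray,
    labels,
    A: int,
    n_perm: int = 400,
    n_folds: int = 7,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PermutationRecord:
    """Permutation test on the class response.

    The class labels are permuted ``n_perm`` times; each permutation's
    7-fold Q2 forms the null distribution. Constraint labels (if any) stay
    attached to the samples — only the response is shuffled.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    q2_obs = crossval_q2(recipe, X_raw, labels, A, n_folds, seed=None)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(len(labels))
        null[i] = crossval_q2(recipe, X_raw, labels[perm], A, n_folds, seed=None)
    p = (1 + int(np.sum(null >= q2_obs))) / (n_perm + 1)
    return PermutationRecord(
        n_perm=n_perm,
        observed_q2=q2_obs,
        null_q2=null,
        p_value=p,
        passed=bool(p < alpha),
        seed=seed,
    )


@dataclass
class SelectionResult:
    selected_A: int | None
    status: str  # "accepted" | "accepted_at_max" | "rejected"
    q2_sequence: list
    permutation: PermutationRecord | None = None


def select_components(
    recipe: ModelRecipe,
    X_raw: np.ndarray,
    labels,
    max_A: int,
    n_folds: int = 7,
    n_perm: int = 400,
    seed: int | None = None,
    cv: Callable | None = None,
) -> SelectionResult:
    """Choose the component count at the first maximum of 7-fold Q2,
    under the constraint that the selected model passes the permutation test.

    ``cv`` may override the Q2 engine (used by tests to inject a fixed Q2
    sequence). If Q2 increases strictly through ``max_A``, the maximum is
    taken with a warning in the status; if no candidate passes the
    permutation test the model is rejected.
    """
    if max_A < 1:
        raise ValueError("max_A must be >= 1")
    cv = cv or (lambda A: crossval_q2(recipe, X_raw, labels, A, n_folds, seed=seed))
    q2 = []
    for A in range(1, max_A + 1):
        try:
            q2.append(cv(A))
        except ValueError:
            break
    if not q2:
        return SelectionResult(None, "rejected", [])
    candidates = [
        a + 1 for a in range(len(q2) - 1) if q2[a] >= q2[a + 1]
    ]
    at_max = not candidates
    if at_max:
        candidates = [len(q2)]
    # drop shadowed later maxima only when trying after a permutation failure
    for rank_i, A_cand in enumerate(candidates):
        perm = permutation_test(
            recipe, X_raw, labels, A_cand, n_perm=n_perm, n_folds=n_folds, seed=seed
        )
        if perm.passed:
            status = "accepted_at_max" if at_max else "accepted"
            return SelectionResult(A_cand, status, q2, perm)
    return SelectionResult(None, "rejected", q2, perm)


def r2y(model: LatentModel, Y: ClassResponse) -> float:
    """Fraction of centered-response variance explained by the fitted model."""
    Yc = Y.Y - Y.Y.mean(axis=0)
    ss = float(np.sum(Yc**2))
    if ss == 0:
        raise ValueError("response has zero variance")
    Yhat_c = model.T @ model.C.T
    return 1.0 - float(np.sum((Yc - Yhat_c) ** 2)) / ss


@dataclass
class ValidationReport:
    """R2, per-scheme Q2, selected component count and permutation record."""

    r2y: float
    q2_by_scheme: dict
    selected_A: int | None
    permutation: PermutationRecord | None
    status: str
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "r2y": self.r2y,
            "q2_by_scheme": {str(k): v for k, v in self.q2_by_scheme.items()},
            "selected_A": self.selected_A,
            "status": self.status,
            "p_value": self.permutation.p_value if self.permutation else None,
            "seed": self.seed,
        }


def validate_model(
    recipe: ModelRecipe,
    X_raw: np.ndarray,
    labels,
    max_A: int,
    schemes: tuple = (6, 7, 8),
    n_perm: int = 400,
    seed: int | None = None,
) -> ValidationReport:
    """Full validation protocol: select A at the first Q2 maximum (7-fold),
    then report R2 and Q2 under every fold scheme plus the permutation record."""
    sel = select_components(
        recipe, X_raw, labels, max_A, n_folds=7, n_perm=n_perm, seed=seed
    )
    if sel.selected_A is None:
        return ValidationReport(
            r2y=float("nan"),
            q2_by_scheme={},
            selected_A=None,
            permutation=sel.permutation,
            status="rejected",
            seed=seed,
        )
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    ctr = np.asarray(recipe.constraint) if recipe.constraint is not None else None
    prep, model = recipe.fit(
        X_raw, labels, sel.selected_A, classes, constraint_train=ctr
    )
    q2s = {
        n: crossval_q2(recipe, X_raw, labels, sel.selected_A, n_folds=n, seed=seed)
        for n in schemes
    }
    return ValidationReport(
        r2y=r2y(model, _dummy_with_classes(labels, classes)),
        q2_by_scheme=q2s,
        selected_A=sel.selected_A,
        permutation=sel.permutation,
        status=sel.status,
        seed=seed,
    )
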