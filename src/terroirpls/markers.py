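"""Correlation loadings (pq(corr)), marker extraction and chemical-class
aggregation.

A correlation loading plot places every X-variable at its Pearson
correlations with two predictive scores (the "p(corr)" part) and every
class-response column at its correlations with the same scores ("q(corr)").
Features close to the unit circle and to a class point are candidate
markers of that class. A feature becomes a marker when |p(corr)| exceeds a
threshold on at least one predictive component; it is assigned to the class
whose q(corr) points the same way on that component, and flagged negative
when it points the opposite way (low abundance characterizes the class).

The aggregation step averages normalized intensities of the member features
of each marker group (e.g. a chemical class such as "anthocyanin") per
vineyard and vintage, the data behind per-vineyard bar summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .io import ClassResponse, FeatureAnnotation, FeatureTable, StudyDesign
from .posttransform import PostTransformedModel

__all__ = [
    "correlation_loadings",
    "CorrelationLoadings",
    "extract_markers",
    "aggregate_marker_groups",
]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


@dataclass
class CorrelationLoadings:
    """p(corr) per feature and q(corr) per class, per predictive component."""

    p_corr: pd.DataFrame  # features x components
    q_corr: pd.DataFrame  # classes x components

    @property
    def components(self) -> list:
        return list(self.p_corr.columns)


def correlation_loadings(
    model: PostTransformedModel,
    X: np.ndarray,
    Y: ClassResponse,
    feature_ids=None,
) -> CorrelationLoadings:
    """Pearson correlations of features and class responses with the
    predictive scores of a post-transformed model.

    ``X`` must be the preprocessed training matrix the model was fitted on.
    Zero-variance features get NaN loadings (flagged, not fatal).
    """
    T = model.T_pred
    if T.shape[1] == 0:
        raise ValueError("model has no predictive components")
    X = np.asarray(X, dtype=float)
    Yc = Y.Y - Y.Y.mean(axis=0)
    comp = [f"t{a + 1}" for a in range(T.shape[1])]
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    zero_var = np.flatnonzero(X.std(axis=0) == 0)
    if len(zero_var):
        warnings.warn(
            f"{len(zero_var)} zero-variance feature(s); pq(corr) recorded as "
            "missing",
            stacklevel=2,
        )
    p = np.empty((X.shape[1], T.shape[1]))
    q = np.empty((Y.n_classes, T.shape[1]))
    for a in range(T.shape[1]):
        for j in range(X.shape[1]):
            p[j, a] = _corr(X[:, j], T[:, a])
        for k in range(Y.n_classes):
            q[k, a] = _corr(Yc[:, k], T[:, a])
    return CorrelationLoadings(
        pd.DataFrame(p, index=feature_ids, columns=comp),
        pd.DataFrame(q, index=list(Y.classes), columns=comp),
    )


def extract_markers(
    loadings: CorrelationLoadings,
    annotation: FeatureAnnotation | None = None,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Features exceeding |p(corr)| >= threshold on >= 1 predictive component.

    Each marker is assigned to the class whose q(corr) is largest in
    magnitude on the feature's strongest component; the marker is positive
    when feature and class point the same way, negative otherwise.
    Raising the threshold never adds markers.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    p = loadings.p_corr
    q = loadings.q_corr
    rows = []
    for feat, prow in p.iterrows():
        if prow.isna().all():
            continue
        a = prow.abs().idxmax()
        if abs(prow[a]) < threshold:
            continue
        k = q[a].abs().idxmax()
        sign = np.sign(prow[a] * q.loc[k, a])
        rows.append(
            {
                "feature": feat,
                "component": a,
                "pq_corr": prow[a],
                "class": k,
                "direction": "positive" if sign >= 0 else "negative",
            }
        )
    out = pd.DataFrame(
        rows, columns=["feature", "component", "pq_corr", "class", "direction"]
    ).set_index("feature")
    if annotation is not None and len(out):
        ann = annotation.table.reindex(out.index)
        out["chemical_class"] = ann["chemical_class"]
        out["marker_group"] = ann["marker_group"]
    return out


def aggregate_marker_groups(
    table: FeatureTable,
    markers: pd.DataFrame,
    design: StudyDesign,
    group_col: str = "marker_group",
) -> pd.DataFrame:
    """Mean normalized intensity per marker group, vineyard and vintage.

    Averages over member features and over the replicate samples of each
    vineyard-vintage combination (arbitrary units). The mean, not the sum,
    keeps group size from inflating the bars. Groups without member
    features present in the table are omitted with a warning. Long-format
    output: (group, vineyard, vintage, value).
    """
    if group_col not in markers.columns:
        raise KeyError(f"markers table lacks a {group_col!r} column")
    vineyard = design.factor("vineyard")
    vintage = design.factor("vintage")
    recs = []
    for group, members in markers.groupby(group_col, dropna=True):
        feats = [f for f in members.index if f in table.data.columns]
        if not feats:
            warnings.warn(f"marker group {group!r} has no member features",
                          stacklevel=2)
            continue
        sub = table.data[feats].to_numpy()
        for vy in pd.unique(vineyard):
            for vt in pd.unique(vintage):
                sel = (vineyard == vy) & (vintage == vt)
                if not sel.any():
                    continue
                recs.append(
                    {
                        "group": group,
                        "vineyard": vy,
                        "vintage": vt,
                        "value": float(sub[sel].mean()),
                    }
                )
    return pd.DataFrame(recs, columns=["group", "vineyard", "vintage", "value"])
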