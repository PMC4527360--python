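"""Normalization and scaling chain for LC-MS and GC-MS feature tables.

Two standard recipes are supported:

* LC-MS: median fold change (MFC) normalization -> natural log -> mean
  centering;
* GC-MS: internal-standard normalization per compound class -> autoscaling.

All steps come in two forms: functions on :class:`~terroirpls.io.FeatureTable`
for one-shot use, and the :class:`Preprocessor` fit/transform object used by
cross-validation, which re-estimates its parameters (MFC reference profile,
column means, column standard deviations) on training rows only and applies
them unchanged to held-out rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureAnnotation, FeatureState, FeatureTable, INTERNAL_STANDARDS

__all__ = [
    "internal_standard_normalize",
    "median_fold_change_normalize",
    "mfc_factors",
    "log_transform",
    "mean_center",
    "autoscale",
    "Preprocessor",
]


def internal_standard_normalize(
    table: FeatureTable,
    annotation: FeatureAnnotation,
    is_areas: pd.DataFrame,
) -> FeatureTable:
    """Divide each intensity by its sample's designated internal-standard area.

    Monoterpenes/sesquiterpenes are referred to alpha-copaene, norisoprenoids
    to d3-b-ionone and all remaining compounds to d13-hexanol; the per-feature
    assignment comes from ``annotation.internal_standard_key``.

    Parameters
    ----------
    is_areas
        Sample x internal-standard peak-area table; index must cover the
        table's samples and columns the three IS names. Areas must be
        strictly positive.
    """
    keys = annotation.internal_standard_for(table.features)
    missing = [s for s in table.samples if s not in is_areas.index]
    if missing:
        raise ValueError(f"IS areas missing for sample(s): {missing[:5]}")
    areas = is_areas.loc[table.samples]
    for is_name in set(keys):
        col = areas[is_name]
        bad = col[col <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive {is_name} area for sample {bad.index[0]!r}"
            )
    denom = areas[keys.to_numpy()].to_numpy(dtype=float)  # n x p
    return table.with_values(table.values / denom, FeatureState.NORMALIZED)


def mfc_factors(X: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Per-sample median fold change factors against a reference profile.

    The factor of a sample is the median, over features positive in both the
    sample and the reference, of intensity / reference.
    """
    factors = np.empty(X.shape[0])
    for i, row in enumerate(X):
        ok = (row > 0) & (reference > 0)
        if not ok.any():
            raise ValueError(
                f"sample index {i} shares no positive feature with the "
                "reference profile; MFC factor undefined"
            )
        factors[i] = np.median(row[ok] / reference[ok])
    return factors


def median_fold_change_normalize(
    table: FeatureTable, reference: np.ndarray | None = None
) -> tuple[FeatureTable, pd.Series]:
    """Median fold change normalization, removing per-sample dilution.

    The reference profile defaults to the per-feature median across all
    samples of the table. Each sample is divided by its median ratio to the
    reference. Returns the normalized table and the per-sample factors.
    """
    X = table.values
    if (X < 0).any():
        raise ValueError("MFC normalization requires non-negative intensities")
    if reference is None:
        reference = np.median(X, axis=0)
    factors = mfc_factors(X, reference)
    out = table.with_values(X / factors[:, None], FeatureState.NORMALIZED)
    return out, pd.Series(factors, index=table.samples, name="mfc_factor")


def log_transform(table: FeatureTable, epsilon: float = 1.0) -> FeatureTable:
    """Natural log transform x -> ln(x + epsilon).

    ``epsilon`` (default 1 raw-intensity unit) keeps zero intensities finite;
    it must be positive. Any log base differs only by a constant factor that
    centering/autoscaling absorbs.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    X = table.values
    if (X < 0).any():
        i, j = np.argwhere(X < 0)[0]
        raise ValueError(
            f"negative intensity at sample {table.samples[i]!r}, "
            f"feature {table.features[j]!r}"
        )
    return table.with_values(np.log(X + epsilon), FeatureState.LOGGED)


def mean_center(table: FeatureTable) -> tuple[FeatureTable, pd.Series]:
    """Subtract per-feature means; returns the centered table and the means."""
    if table.shape[0] < 2:
        raise ValueError("centering needs >=2 samples")
    X = table.values
    means = X.mean(axis=0)
    out = table.with_values(X - means, FeatureState.CENTERED)
    return out, pd.Series(means, index=table.features, name="mean")


def autoscale(
    table: FeatureTable,
) -> tuple[FeatureTable, pd.Series, pd.Series]:
    """Center and scale each feature to unit (sample, n-1) standard deviation."""
    if table.shape[0] < 2:
        raise ValueError("autoscaling needs >=2 samples")
    X = table.values
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    zero = np.asarray(table.features, dtype=object)[sds == 0]
    if len(zero):
        raise ValueError(
            f"zero-variance feature(s) under autoscaling: {list(zero[:10])}"
        )
    out = table.with_values((X - means) / sds, FeatureState.AUTOSCALED)
    return (
        out,
        pd.Series(means, index=table.features, name="mean"),
        pd.Series(sds, index=table.features, name="sd"),
    )


@dataclass
class Preprocessor:
    """Ordered preprocessing chain with stored (training) parameters.

    ``steps`` is an ordered subset of ``{"mfc", "log", "center",
    "autoscale"}``; ``center`` and ``autoscale`` are mutually exclusive.
    ``fit`` estimates the MFC reference profile and column means/sds on the
    given matrix; ``transform`` applies the stored parameters, so held-out
    samples are processed with training-fold statistics only.
    """

    steps: tuple = ("mfc", "log", "center")
    epsilon: float = 1.0
    reference_: np.ndarray | None = field(default=None, repr=False)
    means_: np.ndarray | None = field(default=None, repr=False)
    sds_: np.ndarray | None = field(default=None, repr=False)

    KNOWN = ("mfc", "log", "center", "autoscale")

    def __post_init__(self) -> None:
        unknown = [s for s in self.steps if s not in self.KNOWN]
        if unknown:
            raise ValueError(f"unknown preprocessing step(s): {unknown}")
        if "center" in self.steps and "autoscale" in self.steps:
            raise ValueError("center and autoscale are mutually exclusive")

    def fit(self, X: np.ndarray) -> "Preprocessor":
        X = np.asarray(X, dtype=float)
        for step in self.steps:
            if step == "mfc":
                self.reference_ = np.median(X, axis=0)
                X = X / mfc_factors(X, self.reference_)[:, None]
            elif step == "log":
                X = np.log(X + self.epsilon)
            elif step == "center":
                self.means_ = X.mean(axis=0)
                self.sds_ = None
                X = X - self.means_
            elif step == "autoscale":
                self.means_ = X.mean(axis=0)
                self.sds_ = X.std(axis=0, ddof=1)
                if (self.sds_ == 0).any():
                    raise ValueError("zero-variance feature under autoscaling")
                X = (X - self.means_) / self.sds_
        self.X_fitted_ = X
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        for step in self.steps:
            if step == "mfc":
                if self.reference_ is None:
                    raise RuntimeError("Preprocessor not fitted")
                X = X / mfc_factors(X, self.reference_)[:, None]
            elif step == "log":
                X = np.log(X + self.epsilon)
            elif step in ("center", "autoscale"):
                if self.means_ is None:
                    raise RuntimeError("Preprocessor not fitted")
                X = X - self.means_
                if step == "autoscale":
                    X = X / self.sds_
        return X

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        self.fit(X)
        return self.X_fitted_
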