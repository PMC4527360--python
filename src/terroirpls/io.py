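"""Domain types and delimited-text I/O for feature tables, study designs and models.

The package works on three aligned tables:

* a sample x feature intensity matrix (:class:`FeatureTable`),
* a per-sample factor table (:class:`StudyDesign`) carrying vineyard,
  macrozone, vintage, developmental stage and replicate,
* an optional per-feature annotation (:class:`FeatureAnnotation`) carrying
  chemical class, marker group and internal-standard assignment.

All files are plain CSV (UTF-8, one header row); no binary formats.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureState",
    "FeatureTable",
    "StudyDesign",
    "FeatureAnnotation",
    "ClassResponse",
    "ConstraintBlock",
    "MACROZONE_OF_VINEYARD",
    "read_feature_table",
    "write_feature_table",
    "read_design",
    "read_annotation",
    "dummy_code",
    "build_constraint_block",
    "write_model_tables",
]

#: Fixed vineyard -> macrozone map of the seven-vineyard, three-macrozone design.
MACROZONE_OF_VINEYARD = {
    "BA": "LakeGarda",
    "CS": "LakeGarda",
    "BM": "Valpolicella",
    "FA": "Valpolicella",
    "MN": "Valpolicella",
    "AM": "Soave",
    "PM": "Soave",
}

#: Names of the three spiked internal standards used for GC-MS normalization.
INTERNAL_STANDARDS = ("alpha-copaene", "d3-b-ionone", "d13-hexanol")


class FeatureState(enum.Enum):
    """Processing state of a feature table.

    Transitions only move forward: raw -> normalized -> logged ->
    centered/autoscaled.
    """

    RAW = 0
    NORMALIZED = 1
    LOGGED = 2
    CENTERED = 3
    AUTOSCALED = 3.5

    def __lt__(self, other: "FeatureState") -> bool:
        return self.value < other.value


@dataclass
class FeatureTable:
    """Sample x feature intensity matrix with aligned identifiers.

    ``data`` holds samples in rows and features in columns; identifiers are
    the DataFrame index/columns and must be unique. Intensities are
    non-negative until the log transform, real-valued afterwards.
    """

    data: pd.DataFrame
    state: FeatureState = FeatureState.RAW

    def __post_init__(self) -> None:
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValueError("empty feature table")
        dup_s = self.data.index[self.data.index.duplicated()].unique().tolist()
        if dup_s:
            raise ValueError(f"duplicate sample id(s): {dup_s}")
        dup_f = self.data.columns[self.data.columns.duplicated()].unique().tolist()
        if dup_f:
            raise ValueError(f"duplicate feature id(s): {dup_f}")
        if self.data.isna().any().any():
            r, c = np.argwhere(self.data.isna().values)[0]
            raise ValueError(
                f"missing value at sample {self.data.index[r]!r}, "
                f"feature {self.data.columns[c]!r}"
            )

    @property
    def samples(self) -> list:
        return list(self.data.index)

    @property
    def features(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_values(self, values: np.ndarray, state: FeatureState) -> "FeatureTable":
        """Return a copy with new values and a (forward) state transition."""
        if state < self.state:
            raise ValueError(
                f"illegal state transition {self.state.name} -> {state.name}"
            )
        df = pd.DataFrame(values, index=self.data.index, columns=self.data.columns)
        return FeatureTable(df, state)


@dataclass
class StudyDesign:
    """Per-sample factor table: vineyard, macrozone, vintage, stage, replicate.

    Macrozone is a function of vineyard; it is filled from
    :data:`MACROZONE_OF_VINEYARD` when absent.
    """

    table: pd.DataFrame  # indexed by sample id

    REQUIRED = ("vineyard", "vintage", "stage", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design missing column(s): {missing}")
        if "macrozone" not in self.table.columns:
            unknown = sorted(
                set(self.table["vineyard"]) - set(MACROZONE_OF_VINEYARD)
            )
            if unknown:
                raise ValueError(
                    f"unknown vineyard code(s) {unknown}: cannot derive macrozone"
                )
            self.table = self.table.assign(
                macrozone=self.table["vineyard"].map(MACROZONE_OF_VINEYARD)
            )

    @property
    def samples(self) -> list:
        return list(self.table.index)

    def factor(self, name: str) -> np.ndarray:
        """Per-sample labels of a design column, in table order."""
        if name not in self.table.columns:
            raise KeyError(f"no design factor {name!r}")
        return self.table[name].to_numpy()

    def subset(self, mask: np.ndarray) -> "StudyDesign":
        return StudyDesign(self.table.loc[np.asarray(mask)])


@dataclass
class FeatureAnnotation:
    """Per-feature chemical class, marker group and internal-standard key."""

    table: pd.DataFrame  # indexed by feature id

    def __post_init__(self) -> None:
        if "chemical_class" not in self.table.columns:
            raise ValueError("annotation requires a chemical_class column")
        if "marker_group" not in self.table.columns:
            self.table = self.table.assign(marker_group=pd.NA)
        if "internal_standard_key" not in self.table.columns:
            self.table = self.table.assign(internal_standard_key="none")

    def internal_standard_for(self, features: Sequence) -> pd.Series:
        missing = [f for f in features if f not in self.table.index]
        if missing:
            raise KeyError(f"feature(s) without annotation: {missing[:5]}")
        keys = self.table.loc[list(features), "internal_standard_key"]
        bad = keys[~keys.isin(INTERNAL_STANDARDS)]
        if len(bad):
            raise ValueError(
                "internal_standard_key required for every feature before "
                f"IS normalization; offending feature(s): {list(bad.index[:5])}"
            )
        return keys


@dataclass
class ClassResponse:
    """Dummy-coded class response Y for discriminant analysis.

    Each row of ``Y`` has exactly one 1; column order follows first
    appearance of each label so component signs are reproducible.
    """

    classes: list
    Y: np.ndarray  # n x N
    source_factor: str = ""

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def labels(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[np.argmax(self.Y, axis=1)]


@dataclass
class ConstraintBlock:
    """Centered dummy codes of a nuisance factor (the constraint matrix Z).

    All levels are kept, so Z is rank-deficient by one; downstream
    projectors use pseudo-inverses and tolerate this.
    """

    Z: np.ndarray  # n x c, columns sum to zero
    source_factor: str = ""
    levels: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def read_feature_table(
    path, orientation: str = "samples_in_rows"
) -> FeatureTable:
    """Read a CSV intensity table.

    The default layout has one header row of feature ids and one leading
    column of sample ids; ``orientation="features_in_rows"`` reads the
    transposed layout (MZmine-style exports).
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    dups = sorted({h for h in header if header.count(h) > 1})
    if dups:
        raise ValueError(f"duplicate identifier(s) in header: {dups}")
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table in {path}")
    dup_idx = df.index[df.index.duplicated()].unique().tolist()
    if dup_idx:
        raise ValueError(f"duplicate identifier(s): {dup_idx}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = df.notna() & numeric.isna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell {df.iat[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().values)[0]
        raise ValueError(
            f"missing cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if orientation == "features_in_rows":
        numeric = numeric.T
    return FeatureTable(numeric.astype(float))


def write_feature_table(
    table: FeatureTable, path, orientation: str = "samples_in_rows"
) -> None:
    df = table.data if orientation == "samples_in_rows" else table.data.T
    df.to_csv(path, float_format="%.12g")


def read_design(path, samples: Sequence) -> StudyDesign:
    """Read the design CSV and check it covers exactly the given samples."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    wanted = [str(s) for s in samples]
    missing = [s for s in wanted if s not in df.index]
    if missing:
        raise ValueError(f"design missing sample(s): {missing}")
    return StudyDesign(df.loc[wanted])


def read_annotation(path) -> FeatureAnnotation:
    return FeatureAnnotation(pd.read_csv(path, index_col=0))


def dummy_code(labels: Sequence, source_factor: str = "") -> ClassResponse:
    """Dummy-code class labels in first-appearance order."""
    labels = np.asarray(labels)
    classes = list(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("discrimination needs >=2 classes")
    Y = np.zeros((len(labels), len(classes)))
    for k, cls in enumerate(classes):
        Y[labels == cls, k] = 1.0
    return ClassResponse(classes, Y, source_factor)


def build_constraint_block(
    labels: Sequence, source_factor: str = ""
) -> ConstraintBlock:
    """Centered dummy codes of a nuisance factor (all levels kept)."""
    labels = np.asarray(labels)
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValueError(
            "constraint factor has a single level; pass no constraint instead"
        )
    D = np.zeros((len(labels), len(levels)))
    for k, lev in enumerate(levels):
        D[labels == lev, k] = 1.0
    Z = D - D.mean(axis=0)
    return ConstraintBlock(Z, source_factor, levels)


def write_model_tables(model, out_dir, prefix: str = "model") -> dict:
    """Write scores/loadings/weights (and Y-loadings) of a fitted model as CSV.

    Values are written with 12 significant digits so they round-trip within
    1e-10. Returns the mapping of table name -> written path.
    """
    T = getattr(model, "T", None)
    if T is None or getattr(model, "A", 0) < 1:
        raise ValueError("model is not fitted")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp = [f"t{a + 1}" for a in range(model.A)]
    written = {}

    def _write(name, matrix, index, columns):
        p = out_dir / f"{prefix}_{name}.csv"
        pd.DataFrame(matrix, index=index, columns=columns).to_csv(
            p, float_format="%.12g"
        )
        written[name] = p

    sample_ids = getattr(model, "sample_ids", None)
    feature_ids = getattr(model, "feature_ids", None)
    n, p_ = model.T.shape[0], model.W.shape[0]
    _write("scores", model.T, sample_ids or range(n), comp)
    _write("loadings", model.P, feature_ids or range(p_), comp)
    _write("weights", model.W, feature_ids or range(p_), comp)
    if getattr(model, "C", None) is not None:
        _write("y_loadings", model.C, model.classes, comp)
    if getattr(model, "T_o", None) is not None and model.T_o.shape[1]:
        comp_o = [f"to{a + 1}" for a in range(model.T_o.shape[1])]
        _write("orthogonal_scores", model.T_o, sample_ids or range(n), comp_o)
    return written
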