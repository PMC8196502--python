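"""Canonical feature schema for 2D-STE strain tables.

The data model covers the 71 predictors used for CHD screening: 64
speckle-tracking strain features (peak systolic strain, systolic strain
rate and time-to-peak over the AHA 17-segment model; radial global strain
at three short-axis levels times three myocardial layers; layer-specific
global longitudinal peak strain; and the peak standard deviation of
time-to-peak) plus age and six binary clinical risk factors.

Column names are canonical to this package (``PSS_seg01`` ... ``PSD``,
``age``, ``smoke``, ...); arbitrary CSV headers can be bound to the schema
through a user-supplied column mapping, since vendor exports do not share
a naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSchema",
    "FeatureTable",
    "CohortSummary",
    "default_schema",
    "read_feature_table",
    "write_feature_table",
    "count_predictors",
    "summarize_cohort",
    "SchemaError",
    "ValidationError",
]

#: AHA 17-segment model, standard numbering (basal 1-6, mid 7-12,
#: apical 13-16, apex 17).
AHA_SEGMENTS = tuple(f"seg{i:02d}" for i in range(1, 18))

#: Segments at the apical/apex levels (13-17); the remaining twelve are
#: basal/mid. The distinction matters because apical strain values are
#: strongly inter-correlated.
APICAL_SEGMENTS = tuple(f"seg{i:02d}" for i in range(13, 18))

SHORT_AXIS_LEVELS = ("MV", "PM", "AP")  # mitral valve, papillary muscle, apical
MYOCARDIAL_LAYERS = ("ENDO", "MID", "EPI")


class SchemaError(ValueError):
    """A table does not structurally match the schema (missing columns...)."""


class ValidationError(ValueError):
    """A table matches the schema structurally but violates its contracts."""


@dataclass(frozen=True)
class FeatureSchema:
    """Names and grouping of the predictor columns plus the label column.

    Parameters
    ----------
    ste_blocks
        Mapping from 17-segment block name (``PSS``, ``SSR``, ``TP``) to
        the ordered list of its segment feature names.
    radial_gs
        Radial global-strain feature names (level x layer).
    glps
        Layer-specific global longitudinal peak strain feature names.
    psd
        Peak-standard-deviation feature names (a single dispersion index
        in the default schema).
    clinical_numeric, clinical_binary
        Clinical covariate names.
    label_name
        Name of the binary outcome column (1 = CHD positive).
    """

    ste_blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)
    radial_gs: tuple[str, ...] = ()
    glps: tuple[str, ...] = ()
    psd: tuple[str, ...] = ()
    clinical_numeric: tuple[str, ...] = ()
    clinical_binary: tuple[str, ...] = ()
    #: numeric columns derived by the pipeline (e.g. PC scores); not 2D-STE
    #: measurements themselves
    derived: tuple[str, ...] = ()
    label_name: str = "CHD"

    def __post_init__(self) -> None:
        for block, names in self.ste_blocks.items():
            if len(names) != 17:
                raise SchemaError(
                    f"block {block!r} must list 17 segment features, got {len(names)}"
                )
            if len(set(names)) != 17:
                raise SchemaError(f"block {block!r} has duplicate feature names")
        all_names = self.feature_names
        if len(set(all_names)) != len(all_names):
            dupes = sorted({n for n in all_names if all_names.count(n) > 1})
            raise SchemaError(f"duplicate feature names across schema: {dupes}")
        if self.label_name in all_names:
            raise SchemaError("label column cannot also be a predictor")

    @property
    def ste_names(self) -> list[str]:
        """All 2D-STE feature names, in schema order."""
        names: list[str] = []
        for block_names in self.ste_blocks.values():
            names.extend(block_names)
        names.extend(self.radial_gs)
        names.extend(self.glps)
        names.extend(self.psd)
        return names

    @property
    def feature_names(self) -> list[str]:
        """All predictor names: 2D-STE features, derived columns, clinical."""
        return (self.ste_names + list(self.derived)
                + list(self.clinical_numeric) + list(self.clinical_binary))

    @property
    def numeric_names(self) -> list[str]:
        return self.ste_names + list(self.derived) + list(self.clinical_numeric)

    def restrict(self, names: list[str]) -> "FeatureSchema":
        """Schema containing only the named predictors (label kept)."""
        keep = set(names)
        unknown = keep - set(self.feature_names)
        if unknown:
            raise SchemaError(f"unknown feature names: {sorted(unknown)}")
        return FeatureSchema(
            ste_blocks={
                b: tuple(n for n in ns)
                for b, ns in self.ste_blocks.items()
                if all(n in keep for n in ns)
            },
            radial_gs=tuple(n for n in self.radial_gs if n in keep),
            glps=tuple(n for n in self.glps if n in keep),
            psd=tuple(n for n in self.psd if n in keep),
            clinical_numeric=tuple(n for n in self.clinical_numeric if n in keep),
            clinical_binary=tuple(n for n in self.clinical_binary if n in keep),
            derived=tuple(n for n in self.derived if n in keep),
            label_name=self.label_name,
        )

    def to_dict(self) -> dict:
        return {
            "ste_blocks": {b: list(ns) for b, ns in self.ste_blocks.items()},
            "radial_gs": list(self.radial_gs),
            "glps": list(self.glps),
            "psd": list(self.psd),
            "clinical_numeric": list(self.clinical_numeric),
            "clinical_binary": list(self.clinical_binary),
            "derived": list(self.derived),
            "label_name": self.label_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        return cls(
            ste_blocks={b: tuple(ns) for b, ns in d.get("ste_blocks", {}).items()},
            radial_gs=tuple(d.get("radial_gs", ())),
            glps=tuple(d.get("glps", ())),
            psd=tuple(d.get("psd", ())),
            clinical_numeric=tuple(d.get("clinical_numeric", ())),
            clinical_binary=tuple(d.get("clinical_binary", ())),
            derived=tuple(d.get("derived", ())),
            label_name=d.get("label_name", "CHD"),
        )


def default_schema() -> FeatureSchema:
    """The canonical 71-predictor schema (64 2D-STE + 7 clinical)."""
    return FeatureSchema(
        ste_blocks={
            "PSS": tuple(f"PSS_{s}" for s in AHA_SEGMENTS),
            "SSR": tuple(f"SSR_{s}" for s in AHA_SEGMENTS),
            "TP": tuple(f"TP_{s}" for s in AHA_SEGMENTS),
        },
        radial_gs=tuple(
            f"GS_{lvl}_{lay}" for lvl in SHORT_AXIS_LEVELS for lay in MYOCARDIAL_LAYERS
        ),
        glps=tuple(f"GLPS_{lay}" for lay in MYOCARDIAL_LAYERS),
        psd=("PSD",),
        clinical_numeric=("age",),
        clinical_binary=(
            "gender",
            "hypertension",
            "diabetes",
            "hyperlipemia",
            "smoke",
            "family_history",
        ),
    )


@dataclass
class FeatureTable:
    """A validated subjects-by-features table with a binary CHD label.

    ``features`` is a DataFrame whose columns follow ``schema`` order;
    ``labels`` is an int array with 1 = CHD positive.
    """

    subject_ids: list
    features: pd.DataFrame
    labels: np.ndarray
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        n = len(self.subject_ids)
        if len(self.features) != n or len(self.labels) != n:
            raise ValidationError(
                f"row-count mismatch: {n} ids, {len(self.features)} feature rows, "
                f"{len(self.labels)} labels"
            )
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids")
        validate_features(self.features, self.schema)
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")
        self.labels = self.labels.astype(int)
        # normalize column order to schema order
        self.features = self.features[self.schema.feature_names]

    def __len__(self) -> int:
        return len(self.subject_ids)

    @property
    def X(self) -> np.ndarray:
        return self.features.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels

    def subset(self, idx) -> "FeatureTable":
        """Row subset by positional indices (copy)."""
        idx = np.asarray(idx)
        return FeatureTable(
            subject_ids=[self.subject_ids[i] for i in idx],
            features=self.features.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            schema=self.schema,
        )

    def select_features(self, names: list[str]) -> "FeatureTable":
        """Restrict to a subset of predictors (schema restricted to match)."""
        return FeatureTable(
            subject_ids=list(self.subject_ids),
            features=self.features[names].copy(),
            labels=self.labels.copy(),
            schema=self.schema.restrict(names),
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out.insert(0, "subject_id", self.subject_ids)
        out[self.schema.label_name] = self.labels
        return out


def validate_features(features: pd.DataFrame, schema: FeatureSchema) -> None:
    """Raise if ``features`` violates the schema contracts."""
    missing = [c for c in schema.feature_names if c not in features.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    for col in schema.numeric_names:
        if not np.issubdtype(features[col].dtype, np.number):
            bad_rows = features.index[
                pd.to_numeric(features[col], errors="coerce").isna()
            ].tolist()
            raise ValidationError(
                f"non-numeric values in column {col!r} at rows {bad_rows[:5]}"
            )
    na_cols = [c for c in schema.feature_names if features[c].isna().any()]
    if na_cols:
        raise ValidationError(
            f"missing values in columns {na_cols}; imputation is not performed"
        )
    for col in schema.clinical_binary:
        vals = set(pd.unique(features[col]))
        if not vals <= {0, 1}:
            raise ValidationError(
                f"binary column {col!r} contains values outside {{0, 1}}: "
                f"{sorted(v for v in vals if v not in (0, 1))[:5]}"
            )


#: Accepted text encodings for binary clinical columns, normalized on read.
_BINARY_CODES = {"Y": 1, "N": 0, "M": 1, "F": 0, "1": 1, "0": 0,
                 "YES": 1, "NO": 0, "TRUE": 1, "FALSE": 0}


def _normalize_binary(series: pd.Series, col: str) -> pd.Series:
    if np.issubdtype(series.dtype, np.number):
        return series
    out = series.astype(str).str.strip().str.upper().map(_BINARY_CODES)
    if out.isna().any():
        bad = series[out.isna()].unique()[:5]
        raise ValidationError(
            f"cannot interpret values in binary column {col!r}: {list(bad)}"
        )
    return out.astype(int)


def read_feature_table(
    path,
    schema: FeatureSchema | None = None,
    column_map: dict[str, str] | None = None,
    id_column: str = "subject_id",
) -> FeatureTable:
    """Read and validate a CSV feature table.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8, ``.`` decimal separator).
    schema
        Target schema; default is :func:`default_schema`.
    column_map
        Optional mapping ``{csv header -> canonical name}`` so arbitrary
        vendor exports can be bound to the schema.
    id_column
        Header of the subject-id column; if absent, row numbers are used.
    """
    schema = schema or default_schema()
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    if id_column in df.columns:
        subject_ids = df[id_column].tolist()
        df = df.drop(columns=[id_column])
    else:
        subject_ids = list(range(len(df)))
    if schema.label_name not in df.columns:
        raise SchemaError(f"missing label column {schema.label_name!r}")
    missing = [c for c in schema.feature_names if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    labels = _normalize_binary(df[schema.label_name], schema.label_name).to_numpy()
    feats = df[schema.feature_names].copy()
    for col in schema.clinical_binary:
        feats[col] = _normalize_binary(feats[col], col)
    for col in schema.numeric_names:
        if not np.issubdtype(feats[col].dtype, np.number):
            coerced = pd.to_numeric(feats[col], errors="coerce")
            if coerced.isna().any():
                bad = feats.index[coerced.isna()].tolist()
                raise ValidationError(
                    f"non-numeric values in column {col!r} at rows {bad[:5]}"
                )
            feats[col] = coerced
    return FeatureTable(subject_ids=subject_ids, features=feats,
                        labels=labels, schema=schema)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as CSV such that a read round-trips bit-exactly."""
    table.to_frame().to_csv(path, index=False)


def count_predictors(schema: FeatureSchema) -> tuple[int, int]:
    """(total predictor count, 2D-STE-only count), computed from block sizes."""
    return len(schema.feature_names), len(schema.ste_names)


@dataclass
class CohortSummary:
    """Per-class descriptive statistics in the style of a baseline table.

    ``numeric`` maps feature -> {class -> (mean, sd)} with the n-1 SD;
    ``binary`` maps feature -> {class -> proportion}.
    """

    class_counts: dict[int, int]
    numeric: dict[str, dict[int, tuple[float, float]]]
    binary: dict[str, dict[int, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat, per_class in self.numeric.items():
            row = {"feature": feat, "kind": "numeric"}
            for cls, (m, s) in per_class.items():
                row[f"class{cls}_mean"] = m
                row[f"class{cls}_sd"] = s
            rows.append(row)
        for feat, per_class in self.binary.items():
            row = {"feature": feat, "kind": "binary"}
            for cls, p in per_class.items():
                row[f"class{cls}_prop"] = p
            rows.append(row)
        return pd.DataFrame(rows)


def summarize_cohort(table: FeatureTable) -> CohortSummary:
    """Per-class means/SDs for numeric features and proportions for binary."""
    classes = (0, 1)
    counts = {c: int((table.labels == c).sum()) for c in classes}
    if min(counts.values()) == 0:
        raise ValidationError("both classes must be present to summarize")
    numeric: dict[str, dict[int, tuple[float, float]]] = {}
    for col in table.schema.numeric_names:
        numeric[col] = {}
        for c in classes:
            vals = table.features.loc[table.labels == c, col].to_numpy(float)
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            numeric[col][c] = (float(np.mean(vals)), sd)
    binary: dict[str, dict[int, float]] = {}
    for col in table.schema.clinical_binary:
        binary[col] = {
            c: float(table.features.loc[table.labels == c, col].mean())
            for c in classes
        }
    return CohortSummary(class_counts=counts, numeric=numeric, binary=binary)
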