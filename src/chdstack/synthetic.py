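"""Synthetic CHD cohort generator.

Emulates the statistical structure the screening pipeline assumes: the
clinical marginals of a suspected-CHD angiography cohort (424 subjects,
217 CHD positive), a block-correlation structure among the 64 strain
features, and a class-effect pattern in which the longitudinal measures
(PSS, SSR, GLPS) separate the classes while the radial global strains,
time-to-peak and PSD carry essentially no signal.

Strain features are multivariate Gaussian. The correlation model is a
two-level block design per 17-segment block: segments at the apical/apex
levels are highly inter-correlated, basal/mid segments moderately so,
with a configurable coupling between the PSS and SSR blocks and a higher
uniform correlation inside TP. These are generator parameters describing
qualitative observations, not estimates of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .schema import (
    APICAL_SEGMENTS,
    FeatureSchema,
    FeatureTable,
    default_schema,
)

__all__ = [
    "BlockCorr",
    "GeneratorParams",
    "default_params",
    "generate_cohort",
    "effect_pattern_check",
    "FEATURE_GROUPS",
]


@dataclass(frozen=True)
class BlockCorr:
    """Within-block correlation of a 17-segment block.

    ``high`` applies within the apical/apex segments (13-17), ``low``
    within the basal/mid segments (1-12), ``between`` across the two
    groups. Setting all three equal gives an exchangeable block.
    """

    high: float
    low: float
    between: float

    def __post_init__(self) -> None:
        for v in (self.high, self.low, self.between):
            if not -1.0 < v < 1.0:
                raise ValueError(f"correlation {v} outside (-1, 1)")


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the cohort generator; defaults mirror the study design."""

    n_subjects: int = 424
    prevalence: float = 217 / 424
    #: per-class (mean, SD) of age: (positive, negative)
    clinical_numeric_params: dict[str, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=lambda: {"age": ((64.39, 9.79), (64.11, 9.52))}
    )
    #: per-class prevalence (positive, negative) of each binary factor
    clinical_binary_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "gender": (0.765, 0.7432),
            "hypertension": (0.662, 0.678),
            "diabetes": (0.30, 0.4174),
            "hyperlipemia": (0.726, 0.686),
            "smoke": (0.525, 0.28),
            "family_history": (0.361, 0.325),
        }
    )
    block_corr: dict[str, BlockCorr] = field(
        default_factory=lambda: {
            "PSS": BlockCorr(high=0.70, low=0.50, between=0.35),
            "SSR": BlockCorr(high=0.70, low=0.35, between=0.25),
            "TP": BlockCorr(high=0.60, low=0.60, between=0.60),
        }
    )
    #: uniform correlation between any PSS segment and any SSR segment
    cross_corr_pss_ssr: float = 0.20
    #: correlation among radial GS layers within one short-axis level /
    #: across levels
    radial_within_level: float = 0.50
    radial_between_level: float = 0.10
    #: correlation among the three GLPS layers
    glps_corr: float = 0.80
    #: positive-class mean shift per feature group, in units of the group SD
    class_effect: dict[str, float] = field(
        default_factory=lambda: {
            "PSS": 0.25,
            "SSR": 0.22,
            "TP": 0.0,
            "GLPS": 0.30,
            "GS_MV": 0.0,
            "GS_PM": 0.0,
            "GS_AP": 0.0,
            "PSD": 0.0,
        }
    )
    #: per-block marginal (mean, SD) on the raw measurement scale
    feature_location: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "PSS": (-18.0, 4.0),    # % longitudinal shortening
            "SSR": (-1.10, 0.30),   # 1/s
            "TP": (380.0, 40.0),    # ms
            "GS": (40.0, 12.0),     # % radial thickening
            "GLPS": (-19.0, 3.5),   # %
            "PSD": (40.0, 15.0),    # ms
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        for name, v in [("cross_corr_pss_ssr", self.cross_corr_pss_ssr),
                        ("radial_within_level", self.radial_within_level),
                        ("radial_between_level", self.radial_between_level),
                        ("glps_corr", self.glps_corr)]:
            if not -1.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (-1, 1)")


def default_params(**overrides) -> GeneratorParams:
    """Default generator parameters, optionally overridden field-by-field."""
    return replace(GeneratorParams(), **overrides)


#: Feature groups used for effect assignment and group-level screening.
def feature_groups(schema: FeatureSchema) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {b: list(ns) for b, ns in schema.ste_blocks.items()}
    for lvl in ("MV", "PM", "AP"):
        names = [n for n in schema.radial_gs if f"_{lvl}_" in n]
        if names:
            groups[f"GS_{lvl}"] = names
    if schema.glps:
        groups["GLPS"] = list(schema.glps)
    if schema.psd:
        groups["PSD"] = list(schema.psd)
    return groups


FEATURE_GROUPS = feature_groups(default_schema())


def _segment_block_corr(bc: BlockCorr) -> np.ndarray:
    """17x17 correlation with the two-level apical/basal-mid structure."""
    hi = np.array([s in APICAL_SEGMENTS for s in
                   (f"seg{i:02d}" for i in range(1, 18))])
    R = np.where(np.outer(hi, hi), bc.high,
                 np.where(np.outer(~hi, ~hi), bc.low, bc.between))
    np.fill_diagonal(R, 1.0)
    return R


def build_correlation(params: GeneratorParams) -> tuple[np.ndarray, list[str]]:
    """Assemble the 64x64 strain-feature correlation matrix.

    Raises ``ValueError`` if the implied matrix is not positive definite;
    an invalid configuration is never silently repaired.
    """
    schema = default_schema()
    names = schema.ste_names
    p = len(names)
    R = np.eye(p)

    def idx(block_names):
        return [names.index(n) for n in block_names]

    pss = idx(schema.ste_blocks["PSS"])
    ssr = idx(schema.ste_blocks["SSR"])
    tp = idx(schema.ste_blocks["TP"])
    for block, ix in (("PSS", pss), ("SSR", ssr), ("TP", tp)):
        R[np.ix_(ix, ix)] = _segment_block_corr(params.block_corr[block])
    R[np.ix_(pss, ssr)] = params.cross_corr_pss_ssr
    R[np.ix_(ssr, pss)] = params.cross_corr_pss_ssr

    for lvl in ("MV", "PM", "AP"):
        ix = idx([n for n in schema.radial_gs if f"_{lvl}_" in n])
        R[np.ix_(ix, ix)] = params.radial_within_level
        for i in ix:
            R[i, i] = 1.0
    for lvl_a in ("MV", "PM", "AP"):
        for lvl_b in ("MV", "PM", "AP"):
            if lvl_a == lvl_b:
                continue
            ia = idx([n for n in schema.radial_gs if f"_{lvl_a}_" in n])
            ib = idx([n for n in schema.radial_gs if f"_{lvl_b}_" in n])
            R[np.ix_(ia, ib)] = params.radial_between_level

    gl = idx(list(schema.glps))
    R[np.ix_(gl, gl)] = params.glps_corr
    for i in gl:
        R[i, i] = 1.0

    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "configured correlations imply a non-positive-definite covariance"
        ) from exc
    return R, names


def _group_of(name: str) -> str:
    for group, members in FEATURE_GROUPS.items():
        if name in members:
            return group
    raise KeyError(name)


def _block_of(name: str) -> str:
    """Marginal-location block for a feature name."""
    if name.startswith("GS_"):
        return "GS"
    return name.split("_")[0]


def generate_cohort(params: GeneratorParams | None = None,
                    seed: int | None = None) -> FeatureTable:
    """Draw one synthetic cohort; byte-identical for a given seed.

    Labels hit the exact count ``round(n * prevalence)`` (the fixed
    case/control design), strain features come from one multivariate
    Gaussian per configuration with the class effect added to
    positive-class means, and clinical covariates are drawn per class.
    """
    params = params or GeneratorParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    schema = default_schema()
    n = params.n_subjects
    n_pos = int(np.floor(n * params.prevalence + 0.5))
    if not 0 < n_pos < n:
        raise ValueError("prevalence leaves one class empty")

    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    labels = labels[rng.permutation(n)]
    pos = labels == 1

    R, ste_names = build_correlation(params)
    chol = np.linalg.cholesky(R)
    Z = rng.standard_normal((n, len(ste_names))) @ chol.T

    data: dict[str, np.ndarray] = {}
    for j, name in enumerate(ste_names):
        mean, sd = params.feature_location[_block_of(name)]
        shift = params.class_effect.get(_group_of(name), 0.0) * sd
        col = mean + sd * Z[:, j]
        col[pos] += shift
        data[name] = col

    for feat, ((m1, s1), (m0, s0)) in params.clinical_numeric_params.items():
        col = np.empty(n)
        col[pos] = rng.normal(m1, s1, pos.sum())
        col[~pos] = rng.normal(m0, s0, (~pos).sum())
        data[feat] = col
    for feat, (p1, p0) in params.clinical_binary_params.items():
        col = np.empty(n, dtype=int)
        col[pos] = rng.binomial(1, p1, pos.sum())
        col[~pos] = rng.binomial(1, p0, (~pos).sum())
        data[feat] = col

    features = pd.DataFrame(data)[schema.feature_names]
    return FeatureTable(
        subject_ids=[f"S{i:05d}" for i in range(n)],
        features=features,
        labels=labels,
        schema=schema,
    )


def effect_pattern_check(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Which feature groups separate the classes, by a group-mean Welch test.

    Each group of strain features is collapsed to its per-subject mean and
    compared between classes with a two-sided Welch t-test; a group is
    flagged when p <= alpha. Returns a DataFrame indexed by group with
    columns ``t``, ``p`` and ``flagged``.
    """
    y = table.labels
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("both classes with >= 2 subjects required")
    rows = []
    for group, members in feature_groups(table.schema).items():
        score = table.features[members].mean(axis=1).to_numpy()
        t, p = stats.ttest_ind(score[y == 1], score[y == 0], equal_var=False)
        rows.append({"group": group, "t": float(t), "p": float(p),
                     "flagged": bool(p <= alpha)})
    return pd.DataFrame(rows).set_index("group")
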