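"""Feature screening, block-wise PCA, and the stratified split architecture.

The pipeline screens individual strain features with a two-sample t-test
(Welch by default), reduces each 17-segment strain block (PSS, SSR, TP) to
a few principal components, and partitions subjects into a testing set, a
second-step validation set ("validation 0"), and K paired first-step
train/validation splits of the remaining training pool — all stratified
by the CHD label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .schema import FeatureSchema, FeatureTable

__all__ = [
    "ttest_screen",
    "PCAModel",
    "fit_block_pca",
    "choose_components",
    "apply_reduction",
    "fit_default_reduction",
    "SplitPlan",
    "make_split_plan",
    "DEFAULT_COMPONENT_COUNTS",
]

#: Retained principal components per strain block under the fixed rule.
DEFAULT_COMPONENT_COUNTS = {"PSS": 3, "SSR": 3, "TP": 2}


# ---------------------------------------------------------------------------
# t-test screen


def ttest_screen(
    table: FeatureTable,
    features: list[str] | None = None,
    alpha: float = 0.05,
    variant: str = "welch",
) -> pd.DataFrame:
    """Two-sided two-sample t-test of each feature between classes.

    Parameters
    ----------
    features
        Feature names to test; defaults to all numeric predictors.
    variant
        ``"welch"`` (unequal variances, default) or ``"pooled"``.

    Returns a DataFrame indexed by feature with columns ``t``, ``p``,
    ``flagged`` (p <= alpha) and ``degenerate`` (both classes had zero
    variance, in which case p is defined as 1).
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    features = list(features) if features is not None else table.schema.numeric_names
    y = table.labels
    a_mask, b_mask = y == 1, y == 0
    if a_mask.sum() < 2 or b_mask.sum() < 2:
        raise ValueError("each class needs >= 2 subjects for a t-test")
    rows = []
    for name in features:
        x = table.features[name].to_numpy(float)
        a, b = x[a_mask], x[b_mask]
        degenerate = np.var(a) == 0.0 and np.var(b) == 0.0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
            t, p = float(t), float(p)
        rows.append({"feature": name, "t": t, "p": p,
                     "flagged": bool(p <= alpha), "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# block PCA


@dataclass
class PCAModel:
    """A PCA fitted to one strain block on training subjects only.

    Loadings are orthonormal columns (features x components); each column's
    sign is fixed so its largest-magnitude element is positive, making
    fitted models reproducible across runs. ``scale`` holds per-feature
    SDs when the model was fitted on the correlation matrix (default) and
    ones for covariance PCA.
    """

    block: str
    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    n_components: int

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        missing = [n for n in self.feature_names if n not in features.columns]
        if missing:
            raise ValueError(f"block {self.block!r}: table lacks columns {missing}")
        X = features[self.feature_names].to_numpy(float)
        Z = (X - self.mean) / self.scale
        return Z @ self.loadings[:, : self.n_components]

    @property
    def component_names(self) -> list[str]:
        return [f"{self.block}_PC{i + 1}" for i in range(self.n_components)]


def fit_block_pca(
    table: FeatureTable,
    block: str | list[str],
    n_components: int,
    standardize: bool = True,
) -> PCAModel:
    """Fit PCA to one feature block on the given (training) subjects.

    ``block`` is either a schema block name (``"PSS"``) or an explicit
    feature-name list. With ``standardize`` (default) the decomposition is
    of the correlation matrix — appropriate because strain blocks mix
    measurement scales — otherwise of the covariance matrix.
    """
    if isinstance(block, str):
        names = list(table.schema.ste_blocks[block])
        block_name = block
    else:
        names = list(block)
        block_name = names[0].split("_")[0] if names else "block"
    if n_components > len(names):
        raise ValueError(
            f"n_components={n_components} exceeds block size {len(names)}"
        )
    X = table.features[names].to_numpy(float)
    if X.shape[0] < n_components + 1:
        raise ValueError("need at least n_components + 1 subjects")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            raise ValueError("zero-variance feature; cannot standardize")
    else:
        scale = np.ones(X.shape[1])
    Z = (X - mean) / scale
    cov = (Z.T @ Z) / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|.| element of each loading positive
    flip = np.sign(eigvecs[np.argmax(np.abs(eigvecs), axis=0),
                           np.arange(eigvecs.shape[1])])
    flip[flip == 0] = 1.0
    eigvecs = eigvecs * flip
    return PCAModel(
        block=block_name,
        feature_names=names,
        mean=mean,
        scale=scale,
        eigenvalues=eigvals,
        loadings=eigvecs,
        n_components=n_components,
    )


def choose_components(
    eigenvalues,
    rule: str = "fixed",
    block: str | None = None,
    fixed_counts: dict[str, int] | None = None,
) -> int:
    """Number of PCs to retain for a block.

    ``fixed`` returns the configured per-block count (defaults: PSS and
    SSR keep 3, TP keeps 2). ``elbow`` returns argmax_j lambda_j /
    lambda_{j+1}, the largest relative drop in the scree plot.
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    if eigenvalues.size == 0:
        raise ValueError("empty eigenvalue list")
    if np.any(np.diff(eigenvalues) > 1e-12):
        raise ValueError("eigenvalues must be non-increasing")
    if rule == "fixed":
        counts = fixed_counts or DEFAULT_COMPONENT_COUNTS
        if block is None or block not in counts:
            raise ValueError(f"no fixed count configured for block {block!r}")
        return counts[block]
    if rule == "elbow":
        if eigenvalues.size == 1:
            return 1
        tail = np.where(eigenvalues[1:] > 0, eigenvalues[1:], np.finfo(float).tiny)
        ratios = eigenvalues[:-1] / tail
        return int(np.argmax(ratios)) + 1
    raise ValueError(f"unknown rule {rule!r}")


def fit_default_reduction(
    table: FeatureTable,
    rule: str = "fixed",
    standardize: bool = True,
    fixed_counts: dict[str, int] | None = None,
) -> list[PCAModel]:
    """Fit one PCA per 17-segment block of the table's schema."""
    models = []
    for block in table.schema.ste_blocks:
        probe = fit_block_pca(table, block, n_components=1, standardize=standardize)
        k = choose_components(probe.eigenvalues, rule=rule, block=block,
                              fixed_counts=fixed_counts)
        probe.n_components = k
        models.append(probe)
    return models


def apply_reduction(table: FeatureTable, models: list[PCAModel]) -> FeatureTable:
    """Replace each 17-segment block by its retained PC scores.

    Non-block features pass through unchanged. With the default component
    counts a 71-predictor table becomes a 28-predictor table
    (71 - 3x17 + 3 + 3 + 2).
    """
    schema = table.schema
    by_block = {m.block: m for m in models}
    unknown = set(by_block) - set(schema.ste_blocks)
    if unknown:
        raise ValueError(f"models for blocks not in schema: {sorted(unknown)}")
    new_cols: dict[str, np.ndarray] = {}
    new_blocks: dict[str, tuple[str, ...]] = {}
    for block, names in schema.ste_blocks.items():
        if block not in by_block:
            for n in names:
                new_cols[n] = table.features[n].to_numpy()
            new_blocks[block] = names
            continue
        model = by_block[block]
        if list(names) != model.feature_names:
            raise ValueError(f"block {block!r} feature names do not match model")
        scores = model.transform(table.features)
        for i, cname in enumerate(model.component_names):
            new_cols[cname] = scores[:, i]
    passthrough = (
        list(schema.radial_gs) + list(schema.glps) + list(schema.psd)
        + list(schema.derived)
        + list(schema.clinical_numeric) + list(schema.clinical_binary)
    )
    for n in passthrough:
        new_cols[n] = table.features[n].to_numpy()

    score_names = [c for m in models for c in m.component_names]
    reduced_schema = FeatureSchema(
        ste_blocks=new_blocks,
        radial_gs=schema.radial_gs,
        glps=schema.glps,
        psd=schema.psd,
        clinical_numeric=schema.clinical_numeric,
        clinical_binary=schema.clinical_binary,
        derived=tuple(score_names) + schema.derived,
        label_name=schema.label_name,
    )
    features = pd.DataFrame(new_cols)[reduced_schema.feature_names]
    return FeatureTable(
        subject_ids=list(table.subject_ids),
        features=features,
        labels=table.labels.copy(),
        schema=reduced_schema,
    )


# ---------------------------------------------------------------------------
# split architecture


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _stratified_take(rng: np.random.Generator, idx_by_class: dict[int, np.ndarray],
                     frac: float,
                     require_all_strata: bool = True,
                     ) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Split each stratum by ``frac`` with round-half-up per stratum, then
    reconcile the total to round-half-up of the overall target by adjusting
    the largest stratum.

    With ``require_all_strata`` every class must land in both the taken and
    the remaining part (the named architecture parts); the resampled
    first-step splits relax this so the size arithmetic always holds.
    """
    total = sum(len(v) for v in idx_by_class.values())
    target = _round_half_up(total * frac)
    counts = {c: _round_half_up(len(v) * frac) for c, v in idx_by_class.items()}
    largest = max(idx_by_class, key=lambda c: len(idx_by_class[c]))
    counts[largest] += target - sum(counts.values())
    lo = 1 if require_all_strata else 0
    for c, k in counts.items():
        if not lo <= k <= len(idx_by_class[c]) - lo:
            raise ValueError(
                f"stratum {c} too small to populate every part "
                f"(size {len(idx_by_class[c])}, needs {k} plus remainder)"
            )
    if not 0 < sum(counts.values()) < total:
        raise ValueError("a split part would be empty")
    taken, rest = {}, {}
    for c, pool in idx_by_class.items():
        perm = rng.permutation(len(pool))
        taken[c] = np.sort(pool[perm[: counts[c]]])
        rest[c] = np.sort(pool[perm[counts[c]:]])
    return taken, rest


def _concat(d: dict[int, np.ndarray]) -> np.ndarray:
    return np.sort(np.concatenate(list(d.values())))


@dataclass
class SplitPlan:
    """Subject-index partition for the two-step architecture.

    ``test_idx`` and ``validation0_idx`` are held out once; the remaining
    training pool is re-split K times into paired first-step
    (train, validation) sets. All parts are stratified by label.
    """

    test_idx: np.ndarray
    validation0_idx: np.ndarray
    train_pool_idx: np.ndarray
    first_step_splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def K(self) -> int:
        return len(self.first_step_splits)

    def to_json(self, path) -> None:
        doc = {
            "seed": self.seed,
            "params": self.params,
            "test": self.test_idx.tolist(),
            "validation0": self.validation0_idx.tolist(),
            "train_pool": self.train_pool_idx.tolist(),
            "first_step": [
                {"train": tr.tolist(), "validation": va.tolist()}
                for tr, va in self.first_step_splits
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            test_idx=np.asarray(doc["test"]),
            validation0_idx=np.asarray(doc["validation0"]),
            train_pool_idx=np.asarray(doc["train_pool"]),
            first_step_splits=[
                (np.asarray(s["train"]), np.asarray(s["validation"]))
                for s in doc["first_step"]
            ],
            seed=doc["seed"],
            params=doc.get("params", {}),
        )


def make_split_plan(
    labels,
    test_frac: float = 0.15,
    val_frac: float = 0.20,
    first_val_frac: float = 0.20,
    K: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Stratified test / validation-0 / K first-step splits.

    With 424 labels (217/207) at the default fractions this yields a test
    set of 64, a second-step validation set of 72, a training pool of 288,
    and K first-step (230, 58) pairs. Per-stratum sizes use round-half-up
    and are reconciled to the round-half-up overall target by adjusting
    the larger stratum, which reproduces that arithmetic exactly.
    """
    labels = np.asarray(labels)
    for name, f in (("test_frac", test_frac), ("val_frac", val_frac),
                    ("first_val_frac", first_val_frac)):
        if not 0.0 < f < 1.0:
            raise ValueError(f"{name} must be in (0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("labels must contain both classes")
    rng = np.random.default_rng(seed)
    by_class = {int(c): np.flatnonzero(labels == c) for c in classes}

    test, rest = _stratified_take(rng, by_class, test_frac)
    val0, pool = _stratified_take(rng, rest, val_frac)
    first_steps = []
    for _ in range(K):
        val_k, train_k = _stratified_take(rng, pool, first_val_frac,
                                          require_all_strata=False)
        first_steps.append((_concat(train_k), _concat(val_k)))
    return SplitPlan(
        test_idx=_concat(test),
        validation0_idx=_concat(val0),
        train_pool_idx=_concat(pool),
        first_step_splits=first_steps,
        seed=seed,
        params={
            "test_frac": test_frac,
            "val_frac": val_frac,
            "first_val_frac": first_val_frac,
            "K": K,
        },
    )
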