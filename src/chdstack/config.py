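"""Run configuration and reproducibility manifests.

One base seed governs a full pipeline run; every stage derives its own
seed by a fixed offset, so two runs from the same config are byte-identical
in all CSV/JSON outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ensemble import EnsembleConfig

__all__ = ["RunConfig", "RunManifest", "SEED_OFFSETS"]

#: Fixed per-stage seed offsets from the base seed.
SEED_OFFSETS = {"generate": 0, "split": 1, "learners": 2, "evaluate": 3}


@dataclass
class RunConfig:
    """Everything a full generate -> train -> evaluate run needs."""

    # input: either a CSV path or generator settings
    data_csv: str | None = None
    n_subjects: int = 424
    prevalence: float = 217 / 424
    # preprocessing
    pca: str = "fixed"  # fixed | elbow | off
    ttest_variant: str = "welch"
    alpha: float = 0.05
    test_frac: float = 0.15
    val_frac: float = 0.20
    first_val_frac: float = 0.20
    # ensemble
    L: int = 14
    K: int = 10
    stack_on: str = "labels"
    meta_trees: int = 500
    tune: bool = False
    # evaluation
    methods: tuple[str, ...] = ("two_step_stacking", "traditional_stacking",
                                "weighted_voting")
    replicates: int = 5
    # bookkeeping
    base_seed: int = 0
    out_dir: str = "chdstack_run"

    def ensemble_config(self, seed: int | None = None) -> EnsembleConfig:
        return EnsembleConfig(
            L=self.L, K=self.K, stack_on=self.stack_on,
            meta_trees=self.meta_trees, tune=self.tune,
            seed=self.base_seed if seed is None else seed,
        )

    def seed_for(self, stage: str) -> int:
        return self.base_seed + SEED_OFFSETS[stage]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in doc.items()})
        if isinstance(cfg.methods, list):
            cfg.methods = tuple(cfg.methods)
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one pipeline run: config snapshot, artifacts, timings."""

    config: dict
    artifacts: dict[str, str] = field(default_factory=dict)  # name -> path
    checksums: dict[str, str] = field(default_factory=dict)
    timings_s: dict[str, float] = field(default_factory=dict)
    version: str = ""

    def add_artifact(self, name: str, path) -> None:
        p = Path(path)
        self.artifacts[name] = str(p)
        self.checksums[name] = _checksum(p)

    def time_stage(self, name: str):
        manifest = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                manifest.timings_s[name] = round(time.perf_counter() - self.t0, 3)
                return False

        return _Timer()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config,
                    "artifacts": self.artifacts,
                    "checksums": self.checksums,
                    "timings_s": self.timings_s,
                    "version": self.version,
                },
                fh,
                indent=1,
            )
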