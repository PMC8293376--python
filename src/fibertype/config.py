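"""Run configuration shared across pipeline stages.

Defaults reproduce the analysis settings the pipeline implements: 200 ng
total protein per sample, 50% minimum valid values, downshifted-normal
imputation with width 0.3 and downshift 1.8, 300 k-means pre-clusters with
at most 10 iterations cut into 4 final clusters, RFE dropping 20% of
peptides per round, 5-fold x 10-repeat stratified cross-validation, and a
minimum confirmation class size of 4.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    total_ng: float = 200.0
    loess_span: float = 0.7
    loess_iterations: int = 3
    min_valid_fraction: float = 0.5
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    k_pre: int = 300
    max_iter: int = 10
    n_final: int = 4
    drop_fraction: float = 0.2
    cv_folds: int = 5
    cv_repeats: int = 10
    n_trees: int = 500
    min_class_n: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.total_ng <= 0:
            raise ValueError("total_ng must be positive")
        if not 0 < self.min_valid_fraction <= 1:
            raise ValueError("min_valid_fraction must lie in (0, 1]")
        if self.impute_width <= 0:
            raise ValueError("impute_width must be positive")
        if not 0 < self.drop_fraction < 1:
            raise ValueError("drop_fraction must lie in (0, 1)")
        for name in ("k_pre", "max_iter", "n_final", "cv_folds", "cv_repeats",
                     "n_trees", "min_class_n"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a flat key=value file ('#' starts a comment)."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown setting {key!r}")
            caster = float if fields[key] == "float" else int
            kwargs[key] = caster(value)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def log_effective(self) -> None:
        """Log the full effective configuration (reproducibility contract)."""
        for f in dataclasses.fields(self):
            log.info("config %s = %r", f.name, getattr(self, f.name))
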