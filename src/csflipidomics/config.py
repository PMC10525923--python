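"""Pipeline configuration.

All thresholds that govern the analysis live in one dataclass so that a run
is fully described by a config + a seed.  Defaults follow the study design
the pipeline implements: two-sided Grubbs screening at alpha = 0.05, sample
exclusion above a 20 % outlier burden, a descriptive-power cutoff of 2.5,
and Benjamini-Hochberg control at a 10 % false discovery rate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and switches for an end-to-end analysis run.

    Parameters
    ----------
    grubbs_alpha
        Two-sided significance level of the per-compound Smirnov-Grubbs
        outlier test.
    sample_exclusion_fraction
        A biological sample whose flagged-outlier fraction strictly exceeds
        this value is excluded from the whole analysis (the ">20 %" rule).
    descriptive_power_threshold
        Compounds with descriptive power (sd of experimental samples over sd
        of QC samples, on the normalized scale) below this value are excluded
        from the statistical comparisons; DP equal to the threshold is kept.
    fdr_q
        Benjamini-Hochberg adjusted-p cutoff (strict: p_adj < q).
    min_group_size
        Lipid main classes with fewer members than this are pooled into the
        "small group collection".
    random_seed
        Seed for every stochastic step of a pipeline run.
    grubbs_log_scale
        Screen log-transformed intensities (default).  Intensities are
        multiplicative, so the Grubbs normality assumption is only tenable on
        the log scale; raw-scale screening is available for comparison.
    screen_normalized
        If True, outlier screening runs on QC-normalized values instead of
        raw intensities (the screening stage then follows normalization).
    max_outliers_per_compound
        Optional cap on iterated Grubbs removals per compound per group
        (None = iterate until clean).
    pca_center, pca_scale
        Column centering / unit-variance scaling of the PCA input.
    fold_change_means
        "arithmetic" (default) or "geometric" cohort means for log2 fold
        changes.
    """

    grubbs_alpha: float = 0.05
    sample_exclusion_fraction: float = 0.20
    descriptive_power_threshold: float = 2.5
    fdr_q: float = 0.10
    min_group_size: int = 4
    random_seed: int = 0
    grubbs_log_scale: bool = True
    screen_normalized: bool = False
    max_outliers_per_compound: int | None = None
    pca_center: bool = True
    pca_scale: bool = False
    fold_change_means: str = "arithmetic"

    def __post_init__(self) -> None:
        if not 0.0 < self.grubbs_alpha < 1.0:
            raise ValueError(f"grubbs_alpha must be in (0, 1), got {self.grubbs_alpha}")
        for name in ("sample_exclusion_fraction", "descriptive_power_threshold", "fdr_q"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fdr_q >= 1.0:
            raise ValueError(f"fdr_q must be < 1, got {self.fdr_q}")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.fold_change_means not in ("arithmetic", "geometric"):
            raise ValueError("fold_change_means must be 'arithmetic' or 'geometric'")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
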