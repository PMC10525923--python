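"""Synthetic LC-MS lipidomics feature tables with known ground truth.

The generator emulates the statistical design the analysis assumes: two
biological cohorts (control / case) plus repeated injections of a pooled QC
sample, per-compound lognormal intensities with multiplicative biological
noise, QC values scattered tightly around the pooled (geometric-mean) level,
optional case-vs-control fold changes on chosen compounds, sporadic outlier
cells, and missing measurements.  Every generated table ships with a
:class:`GroundTruth` recording what was injected, so downstream stages can be
tested for recovery rather than merely for not crashing.

Defaults mirror the cohort design the pipeline targets: 9 control and 12
case subjects (the post-exclusion cohort sizes), 15 pooled-QC injections,
~250 compounds in ~20 main classes with a long-tailed class-size
distribution so that a handful of classes fall below the 4-member merge
threshold.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .io_annotation import (
    FeatureTable,
    ROLE_CASE,
    ROLE_CONTROL,
    ROLE_QC,
)

log = logging.getLogger(__name__)


def _cv_to_sigma(cv: float) -> float:
    """Log-scale sd of a lognormal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


@dataclass
class SimulationSpec:
    """Parameters of a synthetic feature table.

    ``biological_cv`` and ``technical_cv_qc`` are coefficients of variation
    on the intensity scale; internally they become log-scale standard
    deviations of the lognormal noise.  ``log_mean_range`` bounds the
    per-compound baseline log-intensity (natural log of instrument units).
    ``fold_changes`` is cycled over the ``n_differential`` spiked compounds.
    ``outlier_magnitude_sd`` is the size of an injected outlier in units of
    the compound's biological log-sd (applied multiplicatively with random
    sign).  ``class_effect_sd`` turns on a shared per-(class, sample)
    log-scale factor inducing intra-class correlation (off by default).
    """

    n_compounds: int = 250
    n_classes: int = 20
    class_weights: Sequence[float] | None = None
    n_control: int = 9
    n_case: int = 12
    n_qc: int = 15
    log_mean_range: tuple[float, float] = (math.log(1e4), math.log(1e7))
    biological_cv: float = 0.4
    technical_cv_qc: float = 0.08
    n_differential: int = 0
    fold_changes: Sequence[float] = (8.0,)
    outlier_rate: float = 0.0
    outlier_magnitude_sd: float = 8.0
    missing_rate: float = 0.0
    class_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_classes", "n_control", "n_case", "n_qc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.biological_cv <= 0 or self.technical_cv_qc <= 0:
            raise ValueError("coefficients of variation must be > 0")
        if any(fc <= 0 for fc in self.fold_changes):
            raise ValueError("fold changes must be > 0")
        for name in ("outlier_rate", "missing_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_differential < 0:
            raise ValueError("n_differential must be >= 0")
        if self.n_differential > self.n_compounds:
            raise ValueError(
                f"n_differential ({self.n_differential}) exceeds n_compounds "
                f"({self.n_compounds})"
            )
        if self.class_weights is not None and len(self.class_weights) != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")

    @property
    def sigma_biological(self) -> float:
        return _cv_to_sigma(self.biological_cv)

    @property
    def sigma_qc(self) -> float:
        return _cv_to_sigma(self.technical_cv_qc)

    def to_dict(self) -> dict[str, Any]:
        d = self.__dict__.copy()
        d["log_mean_range"] = list(self.log_mean_range)
        d["fold_changes"] = list(self.fold_changes)
        if d["class_weights"] is not None:
            d["class_weights"] = list(d["class_weights"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationSpec":
        data = dict(data)
        if "log_mean_range" in data:
            data["log_mean_range"] = tuple(data["log_mean_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    """What was injected into a generated table.

    ``differential_compounds`` maps compound id -> true fold change;
    ``outlier_cells`` lists (compound_id, sample_id) pairs whose value was
    perturbed; ``excluded_sample_targets`` names samples seeded with enough
    outlier burden to trip the sample-exclusion rule.
    """

    differential_compounds: dict[str, float] = field(default_factory=dict)
    outlier_cells: set[tuple[str, str]] = field(default_factory=set)
    excluded_sample_targets: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "differential_compounds": self.differential_compounds,
            "outlier_cells": sorted(list(c) for c in self.outlier_cells),
            "excluded_sample_targets": sorted(self.excluded_sample_targets),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            differential_compounds=dict(payload["differential_compounds"]),
            outlier_cells={tuple(c) for c in payload["outlier_cells"]},
            excluded_sample_targets=set(payload["excluded_sample_targets"]),
        )


def _default_class_weights(n_classes: int) -> np.ndarray:
    # long-tailed (Zipf-like) class sizes: a few dominant classes, several
    # classes small enough to fall under the merge threshold
    w = 1.0 / np.arange(1, n_classes + 1)
    return w / w.sum()


def generate(spec: SimulationSpec) -> tuple[FeatureTable, GroundTruth]:
    """Generate a feature table plus ground truth; same seed, same table.

    Biological intensities are lognormal per compound around a baseline drawn
    from ``log_mean_range``; case samples of differential compounds are
    multiplied by their fold change; QC injections scatter around the
    geometric mean of all biological samples (the pooled-aliquot
    construction) with ``technical_cv_qc``; outlier cells are multiplied by
    exp(+/- outlier_magnitude_sd * sigma_log).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds

    compound_ids = [f"C{i + 1:04d}" for i in range(n)]
    class_names = [f"class_{k + 1:02d}" for k in range(spec.n_classes)]
    weights = (
        np.asarray(spec.class_weights, dtype=float)
        if spec.class_weights is not None
        else _default_class_weights(spec.n_classes)
    )
    weights = weights / weights.sum()
    class_idx = rng.choice(spec.n_classes, size=n, p=weights)

    control_ids = [f"CTRL{i + 1:02d}" for i in range(spec.n_control)]
    case_ids = [f"CASE{i + 1:02d}" for i in range(spec.n_case)]
    qc_ids = [f"QC{i + 1:02d}" for i in range(spec.n_qc)]
    bio_ids = control_ids + case_ids
    n_bio = len(bio_ids)

    mu = rng.uniform(*spec.log_mean_range, size=n)
    sigma = spec.sigma_biological

    log_bio = mu[:, None] + rng.normal(0.0, sigma, size=(n, n_bio))
    if spec.class_effect_sd > 0:
        factor = rng.normal(0.0, spec.class_effect_sd, size=(spec.n_classes, n_bio))
        log_bio = log_bio + factor[class_idx, :]

    truth = GroundTruth()
    if spec.n_differential > 0:
        diff_idx = rng.choice(n, size=spec.n_differential, replace=False)
        fcs = [spec.fold_changes[i % len(spec.fold_changes)]
               for i in range(spec.n_differential)]
        case_cols = np.arange(spec.n_control, n_bio)
        for idx, fc in zip(diff_idx, fcs):
            log_bio[idx, case_cols] += math.log(fc)
            truth.differential_compounds[compound_ids[idx]] = float(fc)

    # pooled QC: geometric mean of the biological samples, technical scatter
    log_pool = log_bio.mean(axis=1)
    log_qc = log_pool[:, None] + rng.normal(0.0, spec.sigma_qc, size=(n, spec.n_qc))

    bio = np.exp(log_bio)
    qc = np.exp(log_qc)

    if spec.outlier_rate > 0:
        mask = rng.random(size=(n, n_bio)) < spec.outlier_rate
        signs = rng.choice([-1.0, 1.0], size=(n, n_bio))
        bump = np.exp(signs * spec.outlier_magnitude_sd * sigma)
        bio = np.where(mask, bio * bump, bio)
        rows, cols = np.nonzero(mask)
        for r, c in zip(rows, cols):
            truth.outlier_cells.add((compound_ids[r], bio_ids[c]))

    values = np.concatenate([bio, qc], axis=1)
    if spec.missing_rate > 0:
        miss = rng.random(size=values.shape) < spec.missing_rate
        values = np.where(miss, np.nan, values)

    sample_ids = bio_ids + qc_ids
    intensities = pd.DataFrame(values, index=compound_ids, columns=sample_ids)
    intensities.index.name = "compound_id"

    ages = rng.integers(40, 78, size=n_bio).astype(float)
    sexes = rng.choice(["F", "M"], size=n_bio)
    samples = pd.DataFrame(
        {
            "role": [ROLE_CONTROL] * spec.n_control
            + [ROLE_CASE] * spec.n_case
            + [ROLE_QC] * spec.n_qc,
            "age": list(ages) + [np.nan] * spec.n_qc,
            "sex": list(sexes) + [None] * spec.n_qc,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    compounds = pd.DataFrame(
        {
            "name": compound_ids,
            "main_class": [class_names[k] for k in class_idx],
            "annotation_level": "1",
            "is_biological": True,
            "total_carbons": np.nan,
            "total_double_bonds": np.nan,
        },
        index=pd.Index(compound_ids, name="compound_id"),
    )

    return FeatureTable(intensities, samples, compounds), truth


def seed_sample_outlier_burden(
    table: FeatureTable,
    sample_id: str,
    fraction: float,
    spec: SimulationSpec,
    truth: GroundTruth | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FeatureTable, GroundTruth]:
    """Inject outliers into ceil(fraction * n_compounds) cells of one sample.

    Used to test the sample-exclusion rule: a burden above the exclusion
    fraction should get the sample removed.  QC samples are refused (the
    exclusion rule applies to patient samples only).  Returns a perturbed
    copy of the table and the updated ground truth, with the sample recorded
    in ``excluded_sample_targets``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if sample_id not in table.samples.index:
        raise ValueError(f"unknown sample {sample_id!r}")
    if table.samples.at[sample_id, "role"] == ROLE_QC:
        raise ValueError("cannot seed outlier burden into a qc sample")

    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    truth = truth if truth is not None else GroundTruth()

    n_cells = math.ceil(fraction * table.n_compounds)
    chosen = rng.choice(table.n_compounds, size=n_cells, replace=False)
    sigma = spec.sigma_biological
    out = table.copy()
    col = out.intensities.columns.get_loc(sample_id)
    for idx in chosen:
        sign = rng.choice([-1.0, 1.0])
        out.intensities.iat[idx, col] *= math.exp(sign * spec.outlier_magnitude_sd * sigma)
        truth.outlier_cells.add((table.compound_ids[idx], sample_id))
    truth.excluded_sample_targets.add(sample_id)
    log.info("seeded %d outlier cells into sample %s", n_cells, sample_id)
    return out, truth


def write_simulation(
    spec: SimulationSpec, out_dir: str | Path, prefix: str = "synthetic"
) -> dict[str, Path]:
    """Generate and write the three CSVs plus ground-truth JSON."""
    from .io_annotation import write_feature_table

    table, truth = generate(spec)
    paths = write_feature_table(table, out_dir, prefix=prefix)
    truth_path = Path(out_dir) / f"{prefix}_ground_truth.json"
    truth.to_json(truth_path)
    paths["ground_truth"] = truth_path
    return paths
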