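"""Smirnov-Grubbs outlier screening and sample exclusion.

Each compound is screened within each biological cohort separately (QC
injections are never screened) with a two-sided Grubbs test, iterated until
no further value exceeds the critical bound.  Per sample, the fraction of
evaluable compounds flagged as outliers is accumulated; samples whose
fraction strictly exceeds the exclusion threshold (default 20 %) are removed
from the rest of the analysis.

Screening operates on log-transformed intensities by default: abundances
carry multiplicative noise, so normality — the Grubbs test's working
assumption — only holds on the log scale, and a value suppressed by a
multiplicative factor is as detectable as one inflated by it.  Raw-scale
screening is available via ``PipelineConfig.grubbs_log_scale = False``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io_annotation import FeatureTable, ROLE_QC

log = logging.getLogger(__name__)


@lru_cache(maxsize=4096)
def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value for a sample of size n.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n-2+t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError(f"Grubbs test undefined for n < 3 (got {n})")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_flag(
    values: Iterable[float],
    alpha: float = 0.05,
    max_outliers: int | None = None,
) -> set[int]:
    """Iterated two-sided Grubbs test; returns indices of flagged values.

    At each round the most extreme remaining value (max |x - mean| / sd) is
    tested against the critical bound for the current sample size; if it
    exceeds the bound it is flagged and removed, and the test repeats.
    Stops when the extreme value passes, fewer than 3 values remain, or the
    remaining values are constant.  Missing values (NaN) are ignored; with
    fewer than 3 non-missing values nothing is flagged (logged skip).
    """
    x = np.asarray(list(values), dtype=float)
    alive = np.flatnonzero(np.isfinite(x))
    if alive.size < 3:
        log.debug("grubbs_flag skipped: only %d non-missing values", alive.size)
        return set()

    flagged: set[int] = set()
    while alive.size >= 3:
        if max_outliers is not None and len(flagged) >= max_outliers:
            break
        sub = x[alive]
        mean = sub.mean()
        sd = sub.std(ddof=1)
        if sd == 0.0:
            break  # constant data has no outliers
        dev = np.abs(sub - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        if g > grubbs_critical_value(alive.size, alpha):
            flagged.add(int(alive[j]))
            alive = np.delete(alive, j)
        else:
            break
    return flagged


@dataclass
class OutlierReport:
    """Outcome of screening one feature table.

    ``flags`` holds (compound_id, sample_id) pairs; ``per_sample_fraction``
    is flagged count over evaluable compounds for each biological sample;
    ``excluded_samples`` are those whose fraction strictly exceeds the
    configured threshold.
    """

    flags: set[tuple[str, str]] = field(default_factory=set)
    per_sample_fraction: dict[str, float] = field(default_factory=dict)
    evaluable_counts: dict[str, int] = field(default_factory=dict)
    excluded_samples: set[str] = field(default_factory=set)
    exclusion_fraction: float = 0.20

    def flags_frame(self) -> pd.DataFrame:
        rows = sorted(self.flags)
        return pd.DataFrame(rows, columns=["compound_id", "sample_id"])

    def sample_summary(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "outlier_fraction": self.per_sample_fraction[s],
                "evaluable_compounds": self.evaluable_counts.get(s, 0),
                "excluded": s in self.excluded_samples,
            }
            for s in self.per_sample_fraction
        ]
        return pd.DataFrame(rows)


def _screen_values(table: FeatureTable, config: PipelineConfig) -> pd.DataFrame:
    vals = table.intensities
    if config.grubbs_log_scale:
        arr = vals.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logged = np.where(arr > 0, np.log(np.where(arr > 0, arr, 1.0)), np.nan)
        n_nonpos = int(((arr <= 0) & np.isfinite(arr)).sum())
        if n_nonpos:
            log.info("%d non-positive cells excluded from log-scale screening", n_nonpos)
        return pd.DataFrame(logged, index=vals.index, columns=vals.columns)
    return vals


def screen_table(table: FeatureTable, config: PipelineConfig | None = None) -> OutlierReport:
    """Grubbs-screen every compound within each biological cohort.

    Each cohort (control, case) is screened independently per compound; QC
    samples are never screened.  The per-sample outlier fraction denominator
    counts that sample's evaluable compounds: those with at least 3
    non-missing values in the sample's cohort (an undefined test can count
    neither way).  Samples with fraction > ``sample_exclusion_fraction`` are
    marked excluded.
    """
    config = config or PipelineConfig()
    groups = {
        role: table.sample_ids(role)
        for role in ("control", "case")
        if table.sample_ids(role)
    }
    for role, ids in groups.items():
        if len(ids) < 3:
            raise ValueError(f"cohort {role!r} has {len(ids)} samples; need >= 3 to screen")

    values = _screen_values(table, config)
    report = OutlierReport(exclusion_fraction=config.sample_exclusion_fraction)
    flag_counts = {s: 0 for ids in groups.values() for s in ids}
    evaluable = {s: 0 for s in flag_counts}

    for role, ids in groups.items():
        sub = values[ids].to_numpy(dtype=float)
        n_ok = np.isfinite(sub).sum(axis=1)
        for i, cid in enumerate(table.compound_ids):
            if n_ok[i] < 3:
                continue
            for s in ids:
                evaluable[s] += 1
            flagged = grubbs_flag(
                sub[i], config.grubbs_alpha, config.max_outliers_per_compound
            )
            for j in flagged:
                sid = ids[j]
                report.flags.add((cid, sid))
                flag_counts[sid] += 1

    for s, n_eval in evaluable.items():
        frac = flag_counts[s] / n_eval if n_eval else 0.0
        report.per_sample_fraction[s] = frac
        report.evaluable_counts[s] = n_eval
        if frac > config.sample_exclusion_fraction:
            report.excluded_samples.add(s)
    if report.excluded_samples:
        log.info(
            "excluded %d samples over the %.0f%% outlier-burden rule: %s",
            len(report.excluded_samples),
            100 * config.sample_exclusion_fraction,
            sorted(report.excluded_samples),
        )
    return report


def apply_exclusions(
    table: FeatureTable,
    report: OutlierReport,
    mode: str = "drop_samples",
) -> FeatureTable:
    """Apply an outlier report: drop excluded samples, optionally mask cells.

    ``drop_samples`` removes the excluded samples entirely; ``mask_cells``
    additionally sets every flagged (compound, sample) cell of the retained
    samples to missing — the "without outliers" surface the per-lipid and
    per-class statistics run on.
    """
    if mode not in ("drop_samples", "mask_cells"):
        raise ValueError(f"mode must be 'drop_samples' or 'mask_cells', got {mode!r}")
    out = table.drop_samples(report.excluded_samples) if report.excluded_samples else table.copy()

    for role in ("control", "case"):
        if table.sample_ids(role) and not out.sample_ids(role):
            raise ValueError(f"exclusion removed every sample of cohort {role!r}")

    if mode == "mask_cells" and report.flags:
        kept = set(out.samples.index)
        n_masked = 0
        for cid, sid in report.flags:
            if sid in kept:
                out.intensities.at[cid, sid] = np.nan
                n_masked += 1
        log.info("masked %d flagged cells", n_masked)
    return out
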