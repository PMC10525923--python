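"""QC-pool geometric-mean normalization and the descriptive-power filter.

Each compound's intensities are divided by the geometric mean of its pooled-QC
injections, putting every compound on a dimensionless scale where the QC
level is 1.  The descriptive power of a compound is then the ratio of the
standard deviation of its normalized experimental (control + case) values to
that of its normalized QC values: a compound whose biological spread barely
exceeds technical noise carries no usable signal and is excluded from the
statistical comparisons (default cutoff 2.5; a value exactly at the cutoff
is retained).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_annotation import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class NormalizedTable(FeatureTable):
    """A FeatureTable on the QC-geomean scale, plus per-compound descriptive power.

    ``descriptive_power`` is populated by :func:`descriptive_power`; it is
    NaN for compounds with fewer than 2 experimental or 2 QC values and
    +inf where the QC sd is zero.
    """

    descriptive_power: pd.Series | None = None

    def copy(self) -> "NormalizedTable":
        dp = None if self.descriptive_power is None else self.descriptive_power.copy()
        return NormalizedTable(
            self.intensities.copy(), self.samples.copy(), self.compounds.copy(), dp
        )


def qc_geomean_normalize(table: FeatureTable) -> NormalizedTable:
    """Divide each compound row by the geometric mean of its QC values.

    The geomean is exp(mean(log x)) over the compound's positive, non-missing
    QC values; zeros and missing QC entries are omitted (logged count) rather
    than pseudocounted, so the normalized QC geomean is exactly 1.  Compounds
    with no usable QC value are dropped with a logged list.
    """
    qc_ids = table.qc_ids
    if not qc_ids:
        raise ValueError("normalization requires qc samples")
    if len(qc_ids) < 2:
        raise ValueError(f"normalization requires >= 2 qc samples, got {len(qc_ids)}")

    qc = table.intensities[qc_ids].to_numpy(dtype=float)
    usable = np.isfinite(qc) & (qc > 0)
    n_omitted = int((np.isfinite(qc) & ~usable).sum() + (~np.isfinite(qc)).sum())
    if n_omitted:
        log.info("%d zero/missing qc cells omitted from geomean computation", n_omitted)

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, qc, 1.0)), np.nan)
    n_usable = usable.sum(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-qc-missing rows
        geomean = np.exp(np.nanmean(np.where(usable, logs, np.nan), axis=1))

    keep = n_usable >= 1
    dropped = [cid for cid, k in zip(table.compound_ids, keep) if not k]
    if dropped:
        log.warning("dropped %d compounds with no usable qc value: %s", len(dropped), dropped)
    if not keep.any():
        raise ValueError("no compound has a usable qc value")

    kept_ids = [cid for cid, k in zip(table.compound_ids, keep) if k]
    normalized = table.intensities.loc[kept_ids].div(
        pd.Series(geomean[keep], index=kept_ids), axis=0
    )
    return NormalizedTable(
        normalized, table.samples.copy(), table.compounds.loc[kept_ids].copy()
    )


def descriptive_power(table: NormalizedTable) -> pd.Series:
    """Per-compound sd(experimental) / sd(qc) on the normalized scale.

    "Experimental" pools control and case samples.  Sample standard
    deviations (ddof=1) on the normalized arithmetic scale.  Compounds with
    fewer than 2 non-missing values on either side get NaN; sd(qc) = 0
    yields +inf (maximally informative relative to technical noise, logged).
    The result is also stored on ``table.descriptive_power``.
    """
    exp_ids = table.control_ids + table.case_ids
    qc_ids = table.qc_ids
    exp = table.intensities[exp_ids].to_numpy(dtype=float)
    qc = table.intensities[qc_ids].to_numpy(dtype=float)

    def _sd(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = np.isfinite(a).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sd = np.where(n >= 2, np.nanstd(a, axis=1, ddof=1), np.nan)
        return sd, n

    sd_exp, n_exp = _sd(exp)
    sd_qc, n_qc = _sd(qc)

    dp = np.full(table.n_compounds, np.nan)
    ok = (n_exp >= 2) & (n_qc >= 2)
    zero_qc = ok & (sd_qc == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dp[ok] = sd_exp[ok] / sd_qc[ok]
    dp[zero_qc] = np.inf
    if zero_qc.any():
        log.info("%d compounds with zero qc sd set to infinite descriptive power",
                 int(zero_qc.sum()))
    series = pd.Series(dp, index=table.intensities.index, name="descriptive_power")
    table.descriptive_power = series
    return series


def filter_by_dp(table: NormalizedTable, threshold: float) -> NormalizedTable:
    """Retain compounds with descriptive power >= threshold.

    Compounds with undefined (NaN) descriptive power are dropped with a log
    message.  Raises if nothing survives.  Idempotent.
    """
    dp = table.descriptive_power
    if dp is None:
        dp = descriptive_power(table)
    keep = dp >= threshold  # NaN compares False, so undefined DP is dropped
    n_undefined = int(dp.isna().sum())
    if n_undefined:
        log.info("%d compounds with undefined descriptive power dropped", n_undefined)
    if not keep.any():
        raise ValueError(f"descriptive-power filter at {threshold} retained no compounds")
    kept = list(dp.index[keep])
    log.info("descriptive-power filter (threshold %g): %d of %d compounds retained",
             threshold, len(kept), table.n_compounds)
    return NormalizedTable(
        table.intensities.loc[kept].copy(),
        table.samples.copy(),
        table.compounds.loc[kept].copy(),
        dp.loc[kept].copy(),
    )
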