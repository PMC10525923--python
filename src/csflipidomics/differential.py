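"""Differential abundance: Welch's t-tests with Benjamini-Hochberg control.

Per-lipid comparisons on the normalized scale (the volcano surface),
per-class comparisons of group totals, within-class analyses with the BH
family restricted to each class, an overall-abundance comparison, and the
pooled-variance Student's t used for cohort demographics.

Statistical engines are scipy (Welch / Student t) and statsmodels (BH
step-up); the wrappers here own missing-value handling, degenerate-variance
cases, vectorization across compounds, and the significance flags
(strict p_adj < q; "suggestive" = raw p < 0.05 without surviving BH).
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .io_annotation import GroupScheme
from .normalization import NormalizedTable

log = logging.getLogger(__name__)

RAW_P_CUTOFF = 0.05


class TTestResult(NamedTuple):
    t_stat: float
    df: float
    p_value: float


def _clean(v: Sequence[float]) -> np.ndarray:
    a = np.asarray(list(v), dtype=float)
    return a[np.isfinite(a)]


def _degenerate(x: np.ndarray, y: np.ndarray) -> TTestResult | None:
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        df = float(len(x) + len(y) - 2)
        if x.mean() == y.mean():
            return TTestResult(0.0, df, 1.0)
        warnings.warn("both groups have zero variance but unequal means; p set to 0")
        return TTestResult(np.inf if x.mean() > y.mean() else -np.inf, df, 0.0)
    return None


def welch_t(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Two-sided Welch's t-test (unequal variances, Satterthwaite df).

    Missing values are dropped per side; each side needs >= 2 values.  If
    both variances are zero: p = 1 for equal means, p = 0 (with a warning)
    otherwise.
    """
    xa, ya = _clean(x), _clean(y)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("welch_t needs >= 2 non-missing values per side")
    deg = _degenerate(xa, ya)
    if deg is not None:
        return deg
    res = stats.ttest_ind(xa, ya, equal_var=False)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def demographics_test(values_a: Sequence[float], values_b: Sequence[float]) -> TTestResult:
    """Unpaired Student's t-test with pooled variance (cohort demographics)."""
    xa, ya = _clean(values_a), _clean(values_b)
    if len(xa) < 2 or len(ya) < 2:
        raise ValueError("demographics_test needs >= 2 non-missing values per side")
    deg = _degenerate(xa, ya)
    if deg is not None:
        return deg
    res = stats.ttest_ind(xa, ya, equal_var=True)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries stay NaN and do not count toward the family size m.
    """
    p = np.asarray(list(p_values), dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if not ok.any():
        return out
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _welch_matrix(
    case: np.ndarray, ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized row-wise Welch test: (t, df, p, testable mask).

    Rows with fewer than 2 values on either side, or zero variance on both
    sides, are marked untestable (NaN statistics).
    """
    def moments(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        n = np.isfinite(a).sum(axis=1).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(a, axis=1)
            var = np.where(n >= 2, np.nanvar(a, axis=1, ddof=1), np.nan)
        return mean, var, n

    m1, v1, n1 = moments(case)
    m0, v0, n0 = moments(ctrl)
    testable = (n1 >= 2) & (n0 >= 2) & ((v1 > 0) | (v0 > 0))

    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v0 / n0
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    t = np.where(testable, t, np.nan)
    df = np.where(testable, df, np.nan)
    p = np.where(testable, p, np.nan)
    return t, df, p, testable


def _differential_frame(
    values: pd.DataFrame,
    control_ids: Sequence[str],
    case_ids: Sequence[str],
    config: PipelineConfig,
    family: str,
) -> pd.DataFrame:
    """Welch + BH over the rows of ``values`` (one BH family)."""
    ctrl = values[list(control_ids)].to_numpy(dtype=float)
    case = values[list(case_ids)].to_numpy(dtype=float)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_ctrl = np.nanmean(ctrl, axis=1)
        mean_case = np.nanmean(case, axis=1)

    if config.fold_change_means == "geometric":
        def gmean(a: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                la = np.where(a > 0, np.log(np.where(a > 0, a, 1.0)), np.nan)
                return np.exp(np.nanmean(la, axis=1))
        fc_ctrl, fc_case = gmean(ctrl), gmean(case)
    else:
        fc_ctrl, fc_case = mean_ctrl, mean_case

    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(
            (fc_ctrl > 0) & (fc_case > 0),
            np.log2(np.where(fc_ctrl > 0, fc_case, 1.0)
                    / np.where(fc_ctrl > 0, fc_ctrl, 1.0)),
            np.nan,
        )
    n_bad_fc = int(np.isnan(log2fc).sum())
    if n_bad_fc:
        log.info("%d units with non-positive cohort mean: fold change undefined", n_bad_fc)

    t, df, p, testable = _welch_matrix(case, ctrl)
    if (~testable).any():
        log.info("%d of %d units untestable (too few values or zero variance) "
                 "in family %r", int((~testable).sum()), len(values), family)
    p_adj = bh_adjust(p)

    frame = pd.DataFrame(
        {
            "mean_control": mean_ctrl,
            "mean_case": mean_case,
            "log2fc": log2fc,
            "t_stat": t,
            "df_welch": df,
            "p_raw": p,
            "p_adj": p_adj,
        },
        index=values.index,
    )
    frame["significant"] = frame["p_adj"] < config.fdr_q
    frame["suggestive"] = (frame["p_raw"] < RAW_P_CUTOFF) & ~frame["significant"]
    frame["bh_family"] = family
    log.info("BH family %r: m = %d, %d significant at q = %g",
             family, int(np.isfinite(p).sum()), int(frame["significant"].sum()),
             config.fdr_q)
    return frame


def volcano_table(table: NormalizedTable, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-lipid Welch + BH across all lipids in the table (one family).

    Run this on the descriptive-power-filtered, outlier-masked normalized
    table; log2 fold change is case over control on cohort means.
    """
    config = config or PipelineConfig()
    return _differential_frame(
        table.intensities, table.control_ids, table.case_ids, config,
        family="all_lipids",
    )


def class_total_comparison(
    totals: pd.DataFrame,
    samples: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Welch + BH across lipid-group totals (samples x groups input)."""
    config = config or PipelineConfig()
    roles = samples.loc[totals.index, "role"]
    ctrl = list(roles.index[roles == "control"])
    case = list(roles.index[roles == "case"])
    return _differential_frame(totals.T, ctrl, case, config, family="class_totals")


def within_class_tests(
    table: NormalizedTable,
    scheme: GroupScheme,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-lipid Welch tests with the BH family restricted to each class.

    Each lipid group is analyzed in isolation: the member lipids are tested
    and adjusted only against each other.  Classes with no member present in
    the table are skipped with a log message.
    """
    config = config or PipelineConfig()
    assignment = scheme.assign(table.compounds)
    frames = []
    for group in scheme.groups:
        members = [c for c in table.compound_ids if assignment.get(c) == group]
        if not members:
            log.info("class %r has no members in the filtered table; skipped", group)
            continue
        sub = table.intensities.loc[members]
        frame = _differential_frame(
            sub, table.control_ids, table.case_ids, config, family=group
        )
        frame.insert(0, "group", group)
        frames.append(frame)
    if not frames:
        raise ValueError("no class had a testable lipid")
    return pd.concat(frames)


class OverallComparison(NamedTuple):
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    t_stat: float
    df: float
    p_value: float


def overall_abundance_comparison(table: NormalizedTable) -> OverallComparison:
    """Total normalized abundance per subject, compared between cohorts.

    Each sample's values are summed over all lipids (missing cells contribute
    zero); cohort mean +/- sd and the Welch p-value are returned.
    """
    totals = table.intensities.sum(axis=0, skipna=True)
    ctrl = totals[table.control_ids].to_numpy(dtype=float)
    case = totals[table.case_ids].to_numpy(dtype=float)
    res = welch_t(case, ctrl)
    return OverallComparison(
        mean_case=float(case.mean()), sd_case=float(case.std(ddof=1)),
        mean_control=float(ctrl.mean()), sd_control=float(ctrl.std(ddof=1)),
        t_stat=res.t_stat, df=res.df, p_value=res.p_value,
    )
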