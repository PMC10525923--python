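"""Lipid class/group-level summaries.

Count enrichment (how many detected lipids fall in each group, as a share of
all classified lipids), abundance enrichment (per-group totals of normalized
values averaged over a cohort, as a share of the summed group means),
per-subject group totals feeding the class-level statistics, and group
abundance as a function of subject age.
"""

from __future__ import annotations

import logging
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .io_annotation import FeatureTable, GroupScheme, ROLE_CASE, ROLE_CONTROL
from .normalization import NormalizedTable

log = logging.getLogger(__name__)


def round_share(value: float, ndigits: int = 1) -> float:
    """Half-up rounding for reported percentage shares (43/244 -> 17.6)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def count_enrichment(scheme: GroupScheme, compounds: pd.DataFrame) -> pd.DataFrame:
    """Member counts and percentage shares of classified lipids per group.

    Returns a DataFrame indexed by group with ``member_count``,
    ``count_share`` (exact) and ``count_share_rounded`` (one decimal,
    half-up, the reporting precision).  Shares are percentages of the
    retained/classified total and sum to 100.
    """
    assignment = scheme.assign(compounds)
    counts = assignment.value_counts()
    total = int(counts.sum())
    out = pd.DataFrame({"member_count": counts})
    out["count_share"] = 100.0 * out["member_count"] / total
    out["count_share_rounded"] = out["count_share"].map(round_share)
    out.index.name = "group"
    return out.sort_values("member_count", ascending=False)


def subject_group_totals(
    table: NormalizedTable | FeatureTable, scheme: GroupScheme
) -> pd.DataFrame:
    """Per-sample total normalized abundance of each group (samples x groups).

    Totals sum the normalized values of a group's member lipids per
    biological sample; missing (including masked) cells contribute zero to
    the sum, with the skipped-cell count logged.
    """
    assignment = scheme.assign(table.compounds)
    ids = [c for c in table.compound_ids if c in assignment.index]
    bio = table.biological_ids
    sub = table.intensities.loc[ids, bio]
    n_missing = int(sub.isna().sum().sum())
    if n_missing:
        log.info("%d missing/masked cells contribute 0 to group totals", n_missing)
    totals = sub.groupby(assignment.loc[ids]).sum(min_count=0).T
    totals.index.name = "sample_id"
    totals.columns.name = "group"
    return totals


def abundance_enrichment(
    table: NormalizedTable | FeatureTable,
    scheme: GroupScheme,
    cohort: str,
) -> pd.DataFrame:
    """Cohort-mean group totals and their percentage shares.

    For each group, the total normalized abundance per sample is averaged
    over the cohort's samples; the abundance share is that mean divided by
    the sum of all group means, times 100.  Shares sum to 100.
    """
    if cohort not in (ROLE_CONTROL, ROLE_CASE):
        raise ValueError(f"cohort must be 'control' or 'case', got {cohort!r}")
    ids = table.sample_ids(cohort)
    if not ids:
        raise ValueError(f"no samples in cohort {cohort!r}")
    totals = subject_group_totals(table, scheme)
    means = totals.loc[ids].mean(axis=0)
    out = pd.DataFrame({"mean_abundance": means})
    out["abundance_share"] = 100.0 * out["mean_abundance"] / out["mean_abundance"].sum()
    out["abundance_share_rounded"] = out["abundance_share"].map(round_share)
    out.index.name = "group"
    return out.sort_values("mean_abundance", ascending=False)


def enrichment_table(
    table: NormalizedTable | FeatureTable, scheme: GroupScheme, cohort: str
) -> pd.DataFrame:
    """Joined count + abundance enrichment for one cohort."""
    counts = count_enrichment(scheme, table.compounds)
    abundance = abundance_enrichment(table, scheme, cohort)
    return counts.join(abundance, how="outer")


def age_trajectory(totals: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Group abundance as a function of subject age.

    ``totals`` is the samples x groups matrix from
    :func:`subject_group_totals`; samples sharing an age are averaged with
    the subject count recorded.  Samples with missing age are dropped with a
    log message.  Returns a tidy frame (group, age, mean_total, n_subjects)
    with ages strictly increasing within each group.
    """
    ages = pd.to_numeric(samples.loc[totals.index, "age"], errors="coerce")
    missing = list(ages.index[ages.isna()])
    if missing:
        log.info("dropped %d samples without age from trajectories: %s",
                 len(missing), missing)
    keep = ages.dropna()
    rows = []
    for group in totals.columns:
        series = totals.loc[keep.index, group]
        grouped = series.groupby(keep).agg(["mean", "size"]).sort_index()
        for age, (mean, n) in grouped.iterrows():
            rows.append(
                {"group": group, "age": float(age),
                 "mean_total": float(mean), "n_subjects": int(n)}
            )
    return pd.DataFrame(rows, columns=["group", "age", "mean_total", "n_subjects"])
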