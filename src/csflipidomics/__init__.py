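"""Untargeted CSF lipidomics feature-table analysis.

A tested re-usable pipeline for annotated LC-MS lipid feature tables:
pooled-QC geometric-mean normalization, iterated two-sided Smirnov-Grubbs
outlier screening with per-sample exclusion, lipid shorthand parsing and
class curation, descriptive-power filtering, class enrichment summaries,
PCA ordination, and Welch / Benjamini-Hochberg differential abundance —
plus a synthetic feature-table generator with ground truth so every stage
is testable for recovery.
"""

__version__ = "0.1.0"

from .config import PipelineConfig
from .io_annotation import (
    FeatureTable,
    GroupScheme,
    LipidAnnotation,
    SMALL_GROUP,
    curate_classes,
    parse_lipid_name,
    read_feature_table,
    register_lipid_class,
    write_feature_table,
)
from .synthetic import GroundTruth, SimulationSpec, generate, seed_sample_outlier_burden
from .qc_outliers import (
    OutlierReport,
    apply_exclusions,
    grubbs_critical_value,
    grubbs_flag,
    screen_table,
)
from .normalization import (
    NormalizedTable,
    descriptive_power,
    filter_by_dp,
    qc_geomean_normalize,
)
from .enrichment import (
    abundance_enrichment,
    age_trajectory,
    count_enrichment,
    enrichment_table,
    round_share,
    subject_group_totals,
)
from .differential import (
    bh_adjust,
    class_total_comparison,
    demographics_test,
    overall_abundance_comparison,
    volcano_table,
    welch_t,
    within_class_tests,
)
from .ordination import PCAResult, pca_profiles, select_component_pair
from .pipeline import PipelineResult, RunManifest, run_analysis, run_pipeline

__all__ = [
    "PipelineConfig",
    "FeatureTable", "GroupScheme", "LipidAnnotation", "SMALL_GROUP",
    "curate_classes", "parse_lipid_name", "read_feature_table",
    "register_lipid_class", "write_feature_table",
    "GroundTruth", "SimulationSpec", "generate", "seed_sample_outlier_burden",
    "OutlierReport", "apply_exclusions", "grubbs_critical_value",
    "grubbs_flag", "screen_table",
    "NormalizedTable", "descriptive_power", "filter_by_dp", "qc_geomean_normalize",
    "abundance_enrichment", "age_trajectory", "count_enrichment",
    "enrichment_table", "round_share", "subject_group_totals",
    "bh_adjust", "class_total_comparison", "demographics_test",
    "overall_abundance_comparison", "volcano_table", "welch_t",
    "within_class_tests",
    "PCAResult", "pca_profiles", "select_component_pair",
    "PipelineResult", "RunManifest", "run_analysis", "run_pipeline",
]
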