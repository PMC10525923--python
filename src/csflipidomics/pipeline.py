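"""End-to-end orchestration with a run manifest.

Stage order follows the analysis design: curate classes -> outlier screen and
sample exclusion -> QC-geomean normalization -> descriptive-power filter (for
the statistical surfaces) -> enrichment summaries -> PCA -> differential
tests.  Identical config + seed gives byte-identical outputs; every stage
records its in/out record counts in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .differential import (
    class_total_comparison,
    overall_abundance_comparison,
    volcano_table,
    within_class_tests,
)
from .enrichment import (
    abundance_enrichment,
    age_trajectory,
    count_enrichment,
    subject_group_totals,
)
from .io_annotation import FeatureTable, ROLE_CASE, ROLE_CONTROL, curate_classes, read_feature_table
from .normalization import descriptive_power, filter_by_dp, qc_geomean_normalize
from .ordination import pca_profiles, select_component_pair
from .qc_outliers import apply_exclusions, screen_table
from .synthetic import SimulationSpec, generate

log = logging.getLogger(__name__)


@dataclass
class StageRecord:
    stage: str
    n_compounds_in: int
    n_compounds_out: int
    n_samples_in: int
    n_samples_out: int
    notes: str = ""


@dataclass
class RunManifest:
    """Everything needed to audit or repeat a run."""

    config: dict[str, Any]
    seed: int
    software_version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: list[StageRecord] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    status: str = "ok"
    failure: str | None = None
    extras: dict[str, Any] = field(default_factory=dict)

    def record(self, stage: str, before: FeatureTable, after: FeatureTable,
               notes: str = "") -> None:
        self.stages.append(StageRecord(
            stage, before.n_compounds, after.n_compounds,
            before.n_samples, after.n_samples, notes,
        ))

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        d["stages"] = [StageRecord(**s) for s in d["stages"]]
        return cls(**d)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class PipelineResult:
    """In-memory results of a full run (the CSV outputs' data)."""

    manifest: RunManifest
    table: FeatureTable
    scheme: Any
    outlier_report: Any
    normalized: Any
    filtered: Any
    counts: pd.DataFrame
    abundance_control: pd.DataFrame
    abundance_case: pd.DataFrame
    totals: pd.DataFrame
    trajectory: pd.DataFrame
    pca: Any
    pair_selection: Any
    volcano: pd.DataFrame
    class_tests: pd.DataFrame
    within_class: pd.DataFrame
    overall: Any


def run_analysis(
    table: FeatureTable,
    config: PipelineConfig | None = None,
    manifest: RunManifest | None = None,
) -> PipelineResult:
    """Run every analysis stage on an already-loaded feature table."""
    config = config or PipelineConfig()
    manifest = manifest or RunManifest(config=config.to_dict(), seed=config.random_seed)

    # 1. class curation: keep biological, classified, level 1/2 compounds
    scheme = curate_classes(table.compounds, config)
    curated = table.subset_compounds(scheme.retained_compounds)
    manifest.record("curate_classes", table, curated,
                    notes=f"{len(scheme.groups)} groups, "
                          f"{len(scheme.small_group_members)} classes merged")

    # 2. outlier screening (raw scale by default) and sample exclusion
    screen_input = curated
    if config.screen_normalized:
        screen_input = qc_geomean_normalize(curated)
    report = screen_table(screen_input, config)
    screened = apply_exclusions(curated, report, mode="drop_samples")
    manifest.record("outlier_screen", curated, screened,
                    notes=f"{len(report.flags)} flags, "
                          f"{len(report.excluded_samples)} samples excluded")

    # 3. QC-geomean normalization
    normalized = qc_geomean_normalize(screened)
    manifest.record("qc_geomean_normalize", screened, normalized)

    # 4. descriptive power + filter (statistics/PCA surface)
    descriptive_power(normalized)
    filtered = filter_by_dp(normalized, config.descriptive_power_threshold)
    manifest.record("descriptive_power_filter", normalized, filtered,
                    notes=f"threshold {config.descriptive_power_threshold}")

    # 5. enrichment summaries on all retained lipids
    counts = count_enrichment(scheme, normalized.compounds)
    abundance_control = abundance_enrichment(normalized, scheme, ROLE_CONTROL)
    abundance_case = abundance_enrichment(normalized, scheme, ROLE_CASE)
    totals = subject_group_totals(normalized, scheme)
    trajectory_controls = totals.loc[[s for s in totals.index
                                      if normalized.samples.at[s, "role"] == ROLE_CONTROL]]
    trajectory = age_trajectory(trajectory_controls, normalized.samples)

    # 6. PCA on the DP-filtered profiles
    pca = pca_profiles(filtered, center=config.pca_center, scale=config.pca_scale)
    cohort_labels = filtered.samples.loc[pca.scores.index, "role"]
    pair_sel = select_component_pair(pca, cohort_labels)
    pca.component_pair_plotted = pair_sel.pair

    # 7. differential testing on masked ("without outliers") normalized data
    masked = apply_exclusions(normalized, report, mode="mask_cells")
    masked_filtered = masked.subset_compounds(filtered.compound_ids)
    volcano = volcano_table(
        _as_normalized(masked_filtered), config
    )
    masked_totals = subject_group_totals(masked, scheme)
    class_tests = class_total_comparison(masked_totals, masked.samples, config)
    within = within_class_tests(_as_normalized(masked_filtered), scheme, config)
    overall = overall_abundance_comparison(_as_normalized(masked))

    manifest.extras.update({
        "n_significant_lipids": int(volcano["significant"].sum()),
        "significant_lipids": sorted(volcano.index[volcano["significant"]]),
        "n_significant_classes": int(class_tests["significant"].sum()),
        "component_pair": list(pair_sel.pair),
        "overall_abundance": {
            "mean_case": overall.mean_case, "sd_case": overall.sd_case,
            "mean_control": overall.mean_control, "sd_control": overall.sd_control,
            "p_value": overall.p_value,
        },
    })

    return PipelineResult(
        manifest=manifest, table=table, scheme=scheme, outlier_report=report,
        normalized=normalized, filtered=filtered, counts=counts,
        abundance_control=abundance_control, abundance_case=abundance_case,
        totals=totals, trajectory=trajectory, pca=pca, pair_selection=pair_sel,
        volcano=volcano, class_tests=class_tests, within_class=within,
        overall=overall,
    )


def _as_normalized(table: FeatureTable):
    from .normalization import NormalizedTable

    if isinstance(table, NormalizedTable):
        return table
    return NormalizedTable(table.intensities, table.samples, table.compounds)


def write_outputs(result: PipelineResult, output_dir: str | Path,
                  plots: bool = False) -> list[Path]:
    """Write every stage's CSV outputs (and optional figures) plus the manifest."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _csv(frame: pd.DataFrame, name: str, **kwargs: Any) -> None:
        path = out / name
        frame.to_csv(path, float_format="%.10g", **kwargs)
        written.append(path)

    _csv(result.outlier_report.flags_frame(), "outlier_flags.csv", index=False)
    _csv(result.outlier_report.sample_summary(), "sample_summary.csv", index=False)
    _csv(result.normalized.intensities, "normalized_intensities.csv")
    dp = result.normalized.descriptive_power
    if dp is not None:
        _csv(dp.to_frame(), "descriptive_power.csv")
    _csv(result.counts, "count_enrichment.csv")
    _csv(result.abundance_control, "abundance_enrichment_control.csv")
    _csv(result.abundance_case, "abundance_enrichment_case.csv")
    _csv(result.totals, "subject_group_totals.csv")
    _csv(result.trajectory, "age_trajectory_control.csv", index=False)
    _csv(result.pca.scores, "pca_scores.csv")
    _csv(result.pca.loadings, "pca_loadings.csv")
    _csv(pd.DataFrame({
        "component": [f"PC{i + 1}" for i in range(result.pca.n_components)],
        "explained_variance_ratio": result.pca.explained_variance_ratio,
    }), "pca_explained_variance.csv", index=False)
    _csv(result.volcano, "volcano.csv")
    _csv(result.class_tests, "class_total_tests.csv")
    _csv(result.within_class, "within_class_tests.csv")

    if plots:
        from . import plots as _plots

        written.append(_plots.enrichment_bars(
            result.counts, out / "count_enrichment.svg"))
        written.append(_plots.enrichment_bars(
            result.abundance_control, out / "abundance_enrichment_control.svg",
            column="abundance_share", ylabel="% of abundance"))
        written.append(_plots.age_trajectory_lines(
            result.trajectory, out / "age_trajectory.svg"))
        labels = result.filtered.samples.loc[result.pca.scores.index, "role"]
        written.append(_plots.pca_scatter(
            result.pca.scores, labels, result.pca.component_pair_plotted,
            result.pca.explained_variance_ratio, out / "pca_cohorts.svg"))
        written.append(_plots.volcano_plot(
            result.volcano, result.manifest.config["fdr_q"], out / "volcano.svg"))

    result.manifest.outputs = [str(p.name) for p in written]
    manifest_path = out / "manifest.json"
    result.manifest.save(manifest_path)
    written.append(manifest_path)
    return written


def run_pipeline(
    config_path: str | Path | None,
    output_dir: str | Path,
    config: PipelineConfig | None = None,
    inputs: dict[str, str] | None = None,
    simulate: SimulationSpec | dict[str, Any] | None = None,
    plots: bool = False,
) -> RunManifest:
    """Load (or simulate) a feature table, run the full analysis, write outputs.

    The YAML config may carry pipeline keys at top level plus either an
    ``inputs:`` mapping (intensities / samples / compounds paths) or a
    ``simulate:`` mapping of :class:`SimulationSpec` fields.  Explicit
    keyword arguments override the file.  Any stage failure is recorded in
    the manifest (status "failed") and re-raised.
    """
    import yaml

    file_cfg: dict[str, Any] = {}
    if config_path is not None:
        with open(config_path) as fh:
            file_cfg = yaml.safe_load(fh) or {}
    inputs = inputs or file_cfg.pop("inputs", None)
    sim_cfg = simulate if simulate is not None else file_cfg.pop("simulate", None)
    if config is None:
        config = PipelineConfig.from_dict(file_cfg)

    manifest = RunManifest(config=config.to_dict(), seed=config.random_seed)
    try:
        if inputs is not None:
            table = read_feature_table(
                inputs["intensities"], inputs["samples"], inputs["compounds"]
            )
            manifest.input_digests = {k: _digest(v) for k, v in inputs.items()}
        elif sim_cfg is not None:
            spec = (sim_cfg if isinstance(sim_cfg, SimulationSpec)
                    else SimulationSpec.from_dict({**sim_cfg, "seed": sim_cfg.get("seed", config.random_seed)}))
            table, _truth = generate(spec)
            manifest.input_digests = {"simulated": f"seed={spec.seed}"}
        else:
            raise ValueError("config must provide 'inputs' paths or a 'simulate' block")

        result = run_analysis(table, config, manifest)
        write_outputs(result, output_dir, plots=plots)
    except Exception as exc:
        manifest.status = "failed"
        manifest.failure = f"{type(exc).__name__}: {exc}"
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest.save(out / "manifest.json")
        raise
    return result.manifest
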