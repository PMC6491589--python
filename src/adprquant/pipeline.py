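"""End-to-end orchestration of the two published analyses.

Both runs share the same spine: parse proteinGroups → quality filters →
TMM + log2-per-million → design matrix → per-protein OLS → empirical-Bayes
variance moderation → moderated t-tests with BH adjustment → annotated
result tables and plot-ready exports.  The cofactor run tests the single
cofactor-preference coefficient; the inhibitor run tests the inhibitor
preference and the inhibition effect separately (each BH-adjusted on its
own), debiases intensities for the response scatter, and summarises
dose–response profiles across all five doses.

For the inhibitor experiment the intermediate doses are carried through
normalization and debiasing (they occupy TMT channels and contribute to
library sizes) but excluded at the design-matrix stage.

Every step is deterministic: identical inputs and config produce
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import debias as _debias
from . import design as _design
from . import eb_stats as _eb
from . import io_maxquant as _io
from . import normalization as _norm
from .layout import COFACTOR, INHIBITOR, ExperimentLayout

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative settings for one analysis run."""

    experiment_type: str                      # "cofactor" | "inhibitor"
    layout: ExperimentLayout
    input_path: str | None = None
    min_peptides: int = 2
    trim_m: float = 0.30
    trim_a: float = 0.05
    span: float = 0.5
    trend: bool = True
    alpha: float = 0.01
    reference_path: str | None = None
    output_dir: str | None = None
    volcano_ceiling: float = 16.0

    def __post_init__(self) -> None:
        if self.experiment_type not in (COFACTOR, INHIBITOR):
            raise ValueError(f"unknown experiment type {self.experiment_type!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["layout"] = ExperimentLayout.from_dict(raw["layout"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layout"] = self.layout.to_dict()
        return d


@dataclass
class ResultsBundle:
    """Everything a run produced, with optional on-disk mirrors."""

    config: RunConfig
    filter_report: _io.FilterReport
    normalization: _norm.NormalizationResult
    fit: _eb.FitResult
    prior: _eb.VariancePrior
    stats: dict[str, _eb.ModeratedStats]
    results: pd.DataFrame
    exports: dict[str, pd.DataFrame] = field(default_factory=dict)


def _load_records(config: RunConfig, table: pd.DataFrame | None):
    if table is not None:
        return _io.table_to_records(table, config.layout)
    if config.input_path is None:
        raise ValueError("either an input path or an in-memory table is required")
    return _io.read_protein_groups(config.input_path, config.layout)


def _known_targets(config: RunConfig, meta: pd.DataFrame) -> pd.Series:
    if config.reference_path is None:
        return pd.Series(False, index=meta.index)
    reference = _io.load_reference_accessions(config.reference_path)
    ids = [tuple(s.split(";")) for s in meta["protein_ids"]]
    return pd.Series(_io.annotate_known_targets(ids, reference), index=meta.index)


def _prepare(config: RunConfig, table: pd.DataFrame | None):
    records = _load_records(config, table)
    kept, report = _io.apply_quality_filters(records, min_peptides=config.min_peptides)
    logger.info("quality filters: kept %d of %d proteins", report.n_kept, report.n_input)
    if not kept:
        raise ValueError("no proteins survive the quality filters")
    matrix, meta = _io.records_to_matrix(kept, config.layout)
    norm = _norm.normalize(matrix, trim_m=config.trim_m, trim_a=config.trim_a)
    return report, matrix, meta, norm


def _write_bundle(bundle: ResultsBundle) -> None:
    out = Path(bundle.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.results.to_csv(out / "results.tsv", sep="\t")
    for name, frame in bundle.exports.items():
        frame.to_csv(out / f"{name}.tsv", sep="\t")
    (out / "filter_report.json").write_text(bundle.filter_report.to_json())
    run_info = {
        "config": bundle.config.to_dict(),
        "tmm_factors": list(map(float, bundle.normalization.tmm_factors)),
        "library_sizes": list(map(float, bundle.normalization.library_sizes)),
        "prior_df": float(bundle.prior.prior_df),
        "residual_df": int(bundle.fit.residual_df),
    }
    (out / "run_info.json").write_text(json.dumps(run_info, indent=2))


def run_cofactor_analysis(
    config: RunConfig,
    table: pd.DataFrame | None = None,
) -> ResultsBundle:
    """The 2YnAd/6YnAd cofactor-preference analysis."""
    if config.experiment_type != COFACTOR:
        raise ValueError("config.experiment_type must be 'cofactor'")
    report, _matrix, meta, norm = _prepare(config, table)

    design = _design.cofactor_design(config.layout)
    fit = _eb.fit_linear_models(norm.matrix_log2pm, design)
    prior = _eb.estimate_variance_prior(fit, trend=config.trend, span=config.span)
    stats = _eb.moderated_t_test(fit, prior, "cofactor", alpha=config.alpha)

    known = _known_targets(config, meta)
    results = stats.to_frame()
    results.insert(0, "gene_name", meta["gene_name"])
    results["mean_log2pm"] = fit.mean_log_intensity
    results["known_target"] = known

    volcano = _debias.export_volcano(
        stats, gene_names=meta["gene_name"], known_targets=known,
        ceiling=config.volcano_ceiling,
    )
    bundle = ResultsBundle(
        config=config,
        filter_report=report,
        normalization=norm,
        fit=fit,
        prior=prior,
        stats={"cofactor": stats},
        results=results,
        exports={"volcano": volcano},
    )
    if config.output_dir:
        _write_bundle(bundle)
    return bundle


def run_inhibitor_analysis(
    config: RunConfig,
    table: pd.DataFrame | None = None,
) -> ResultsBundle:
    """The Olaparib/Rucaparib PARP-inhibitor response analysis."""
    if config.experiment_type != INHIBITOR:
        raise ValueError("config.experiment_type must be 'inhibitor'")
    report, _matrix, meta, norm = _prepare(config, table)

    design = _design.inhibitor_design(config.layout)
    fit = _eb.fit_linear_models(norm.matrix_log2pm, design)
    prior = _eb.estimate_variance_prior(fit, trend=config.trend, span=config.span)
    stats = {
        name: _eb.moderated_t_test(fit, prior, name, alpha=config.alpha)
        for name in ("preference", "inhibited")
    }

    known = _known_targets(config, meta)
    results = pd.DataFrame({"gene_name": meta["gene_name"]}, index=meta.index)
    for name, st in stats.items():
        frame = st.to_frame().add_prefix(f"{name}_")
        results = results.join(frame)
    results["mean_log2pm"] = fit.mean_log_intensity
    results["known_target"] = known

    debiased = _debias.remove_bias(norm.matrix_log2pm, fit)
    scatter = _debias.inhibitor_responses(debiased, config.layout, dose=25.0)
    scatter["significant"] = (
        stats["preference"].significant | stats["inhibited"].significant
    )
    scatter["known_target"] = known

    significant_ids = results.index[scatter["significant"]]
    profiles = []
    for pid in significant_ids:
        prof = _debias.dose_response_profile(pid, debiased, config.layout)
        prof.insert(0, "protein", pid)
        profiles.append(prof)
    dose_profiles = (
        pd.concat(profiles, ignore_index=True)
        if profiles
        else pd.DataFrame(columns=["protein", "label", "concentration", "mean_log2", "n_replicates"])
    )

    volcano = _debias.export_volcano(
        stats["preference"], gene_names=meta["gene_name"], known_targets=known,
        ceiling=config.volcano_ceiling,
    )
    bundle = ResultsBundle(
        config=config,
        filter_report=report,
        normalization=norm,
        fit=fit,
        prior=prior,
        stats=stats,
        results=results,
        exports={
            "volcano_preference": volcano,
            "response_scatter": scatter,
            "dose_response": dose_profiles.set_index("protein")
            if len(dose_profiles)
            else dose_profiles,
        },
    )
    if config.output_dir:
        _write_bundle(bundle)
    return bundle


def run_analysis(config: RunConfig, table: pd.DataFrame | None = None) -> ResultsBundle:
    """Dispatch on the configured experiment type."""
    if config.experiment_type == COFACTOR:
        return run_cofactor_analysis(config, table)
    return run_inhibitor_analysis(config, table)
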