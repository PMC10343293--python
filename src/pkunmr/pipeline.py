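"""End-to-end driver: simulate -> bin -> classify -> compare -> stratify -> report."""
from __future__ import annotations

import logging
from dataclasses import asdict, replace
from pathlib import Path

from . import __version__
from .classifier import mccv
from .io import PipelineConfig, RunReport, read_concentration_table, write_concentration_table
from .phenotype import flag_inconsistencies, group_summary, stratify_gpv, write_metadata_csv
from .spectral_binning import assemble_bucket_table
from .synthetic_cohort import (
    generate_concentrations,
    generate_metadata,
    load_default_panel,
    synthesize_spectrum,
)
from .targeted_stats import compare_groups, comparison_to_frame

logger = logging.getLogger("pkunmr")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order and write the report plus CSV artifacts.

    Deterministic under a fixed seed; any stage failure propagates with the
    stage context attached by the originating module.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    shapes: dict = {}

    cohort = config.cohort
    if not cohort.panel:
        cohort = cohort.with_panel(load_default_panel())
    if config.seed != 0 and cohort.seed == 0:
        cohort = replace(cohort, seed=config.seed)

    if config.simulate:
        logger.info("simulating cohort: %d case / %d control, %d metabolites",
                    cohort.n_case, cohort.n_control, len(cohort.panel))
        table, labels = generate_concentrations(cohort)
        records = generate_metadata(cohort)
        write_concentration_table(table, labels, outdir / "concentrations.csv")
        write_metadata_csv(records, outdir / "metadata.csv")
    else:
        if not config.concentration_table:
            raise FileNotFoundError("simulate=false requires concentration_table")
        table, labels = read_concentration_table(config.concentration_table)
        records = []
        if config.metadata_table:
            from .phenotype import read_metadata_csv

            records = read_metadata_csv(config.metadata_table)
    shapes["concentrations"] = list(table.shape)

    confusion = None
    accuracy = None
    if config.run_classifier:
        logger.info("synthesizing and binning spectra")
        spectra = [
            synthesize_spectrum(table.iloc[i].fillna(0.0), cohort.panel,
                                noise_sd=cohort.noise_sd, seed=cohort.seed + 1000 + i)
            for i in range(len(table))
        ] if config.simulate else None
        if spectra is not None:
            buckets = assemble_bucket_table(spectra, config.binning,
                                            sample_ids=list(table.index))
            buckets.to_csv(outdir / "buckets.csv")
            shapes["buckets"] = list(buckets.values.shape)
            result = mccv(buckets, labels.to_numpy(), config.classifier)
        else:
            result = mccv(table.fillna(0.0).to_numpy(), labels.to_numpy(), config.classifier)
        confusion = result.confusion.to_dict()
        accuracy = result.confusion.accuracy
        logger.info("MCCV accuracy: %.1f%%", accuracy)

    rows = compare_groups(table, labels, config.stats)
    comparison_to_frame(rows).to_csv(outdir / "comparison.csv", index=False)
    shapes["comparison"] = [len(rows), 10]

    pheno_summary = {}
    if records:
        warnings_log.extend(flag_inconsistencies(records, config.phenotype))
        for rec in records:
            derived = stratify_gpv(rec, config.phenotype)
            if rec.phenotype == "undetermined":
                rec.phenotype = derived
        pheno_summary = {
            "phe_serum": group_summary(records, "phe_serum"),
            "protein_intake": group_summary(records, "protein_intake"),
        }

    report = RunReport(
        version=__version__,
        config=config.to_dict(),
        seed=cohort.seed,
        stage_shapes=shapes,
        comparison_table=[asdict(r) for r in rows],
        confusion=confusion,
        accuracy_percent=accuracy,
        phenotype_summary=pheno_summary,
        warnings=warnings_log,
    )
    report.to_json(outdir / "report.json")
    return report
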