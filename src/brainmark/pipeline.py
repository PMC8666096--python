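"""End-to-end orchestration of the discovery and verification stages.

``RunConfig`` gathers every threshold of the pipeline in one serialisable
place, with defaults equal to the study's stated values.  ``run_simulate``
writes a complete synthetic input bundle; ``run_discovery`` chains PSM
filtering -> redundancy clustering -> differential screen -> brain
enrichment and writes TSV/JSON reports; ``run_verification`` chains
calibration -> duplicate QC -> censoring -> group comparison, with the
processing-time sensitivity re-run.  Reports are plain text so runs diff
cleanly; the config used is embedded in each run's summary for provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assay, brain, cluster, differential, identfilter, synthetic

log = logging.getLogger("brainmark")

__all__ = ["RunConfig", "run_simulate", "run_discovery", "run_verification"]


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the study's stated values."""

    # identification acceptance
    min_probability: float = 0.95
    min_mowse: float = 35.0
    min_charge: int = 2
    min_spectra_per_peptide: int = 2
    require_manual_validation: bool = False
    # redundancy clustering
    identity_threshold: float = 0.90
    # differential screen
    min_samples: int = 2
    high_cut: float = 2.0
    low_cut: float = 0.5
    round_digits: int = 1
    # brain enrichment
    fold_cut: float = 10.0
    presence_cut: float = 1.0
    max_other_tissues: int = 2
    min_total: int = 1
    # immunoassay verification
    cv_threshold: float = 20.0
    lloq: float = 0.039
    lod: float = 0.012
    max_days: int = 4
    below_lod_policy: str = "half_lod"
    # simulation
    seed: int = 0
    n_sci_pos: int = 7
    n_sci_neg: int = 8
    n_control: int = 6
    n_proteins: int = 30

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, set):
            return sorted(o)
        if isinstance(o, float) and math.isinf(o):
            return "inf"
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def run_simulate(config: RunConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic input bundle plus the planted-truth key."""
    spec = synthetic.CohortSpec(
        config.n_sci_pos, config.n_sci_neg, config.n_control, seed=config.seed
    )
    log.info("simulate: cohort %d/%d/%d, %d proteins, seed %d",
             spec.n_sci_pos, spec.n_sci_neg, spec.n_control,
             config.n_proteins, config.seed)
    return synthetic.write_bundle(outdir, spec, n_proteins=config.n_proteins)


def run_discovery(
    config: RunConfig,
    psm_path,
    cohort_path,
    fasta_path,
    compendium_path,
    accession_to_gene_path,
    outdir,
) -> dict:
    """Identification filtering through brain-protein reporting.

    Writes protein-evidence, differential, Venn and brain-protein reports to
    ``outdir`` and returns the machine-readable summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotations = pd.read_csv(cohort_path, sep="\t", dtype={"sample_id": str})

    log.info("discovery: filtering PSMs from %s", psm_path)
    psms = identfilter.read_psm_table(psm_path)
    accepted = identfilter.filter_psms(
        psms, config.min_probability, config.min_mowse, config.min_charge
    )
    evidence = identfilter.assemble_proteins(
        accepted,
        config.min_spectra_per_peptide,
        require_manual_validation=config.require_manual_validation,
    )

    log.info("discovery: clustering %s at %.0f%% identity",
             fasta_path, 100 * config.identity_threshold)
    records = cluster.read_fasta(fasta_path)
    clusters = cluster.cluster_sequences(records, config.identity_threshold)
    collapsed = cluster.collapse_evidence(evidence, clusters)
    cluster.write_clstr(clusters, outdir / "clusters.clstr")
    pd.DataFrame(
        [
            {"accession": m, "representative": cl.representative}
            for cl in clusters
            for m in cl.members
        ]
    ).to_csv(outdir / "cluster_map.tsv", sep="\t", index=False)
    identfilter.evidence_to_frame(collapsed).to_csv(
        outdir / "protein_evidence.tsv", sep="\t", index=False
    )

    sets = differential.detection_sets(collapsed, annotations)
    venn = differential.venn_partition(
        sets["sci_pos"], sets["sci_neg"], sets["control"]
    )
    diff_records = differential.fold_change_screen(
        differential.records_from_evidence(collapsed, annotations),
        config.min_samples,
        config.high_cut,
        config.low_cut,
        config.round_digits,
    )
    diff_frame = differential.differential_to_frame(diff_records)
    diff_frame.to_csv(outdir / "differential.tsv", sep="\t", index=False)
    _write_json(venn.report(), outdir / "venn.json")

    compendium = pd.read_csv(compendium_path, sep="\t")
    brain_list = brain.build_brain_list(
        compendium,
        config.min_total,
        fold_cut=config.fold_cut,
        presence_cut=config.presence_cut,
        max_other_tissues=config.max_other_tissues,
    )
    mapping_df = pd.read_csv(accession_to_gene_path, sep="\t")
    mapping = dict(zip(mapping_df["accession"], mapping_df["gene"]))
    brain_tables = brain.filter_plasma_brain(
        sets, brain_list, mapping, evidence=collapsed, annotations=annotations
    )
    for name, table in brain_tables.items():
        table.to_csv(outdir / f"brain_{name}.tsv", sep="\t", index=False)

    summary = {
        "config": config.to_dict(),
        "n_psms": len(psms),
        "n_accepted_psms": len(accepted),
        "n_proteins": len(evidence),
        "n_clusters": len(clusters),
        "venn": venn.report(),
        "n_passing_fold_change": int(sum(r.passes_filter for r in diff_records)),
        "brain_list_size": len(brain_list),
        "n_brain_scd_not_control": int(len(brain_tables["scd_not_control"])),
        "n_brain_control_not_scd": int(len(brain_tables["control_not_scd"])),
    }
    _write_json(summary, outdir / "discovery_summary.json")
    return summary


def run_verification(config: RunConfig, plate_path, standards_path, outdir) -> dict:
    """Calibration -> QC -> censoring -> group comparisons, with the
    processing-time sensitivity re-run; writes per-subject concentrations
    and the comparison report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    standards = pd.read_csv(standards_path, sep="\t")
    plate = pd.read_csv(plate_path, sep="\t")
    log.info("verification: fitting calibration from %s", standards_path)
    curve = assay.fit_calibration(standards, lloq=config.lloq, lod=config.lod)
    measurements = assay.process_plate(
        plate, curve, config.cv_threshold, config.below_lod_policy
    )
    assay.to_long_format(measurements).to_csv(
        outdir / "concentrations.tsv", sep="\t", index=False
    )

    def comparison(ms) -> dict | None:
        scd = [
            m.concentration
            for m in ms
            if m.group in ("sci_pos", "sci_neg") and m.concentration is not None
        ]
        ctrl = [
            m.concentration
            for m in ms
            if m.group == "control" and m.concentration is not None
        ]
        if len(scd) < 2 or len(ctrl) < 2:
            log.warning("comparison skipped: too few samples (%d vs %d)",
                        len(scd), len(ctrl))
            return None
        c = assay.compare_groups(scd, ctrl)
        return {
            "n_scd": c.n_a,
            "n_control": c.n_b,
            "median_scd": c.median_a,
            "median_control": c.median_b,
            "iqr_scd": list(c.iqr_a),
            "iqr_control": list(c.iqr_b),
            "statistic": c.statistic,
            "p_value": c.p_value,
        }

    primary = comparison(measurements)
    retained = assay.sensitivity_filter(measurements, config.max_days)
    sensitivity = comparison(retained)
    summary = {
        "config": config.to_dict(),
        "calibration": {
            "lower": curve.lower,
            "upper": curve.upper,
            "inflection": curve.inflection,
            "slope": curve.slope,
        },
        "n_measurements": len(measurements),
        "n_repeat_flagged": int(sum(m.repeat_required for m in measurements)),
        "censor_counts": {
            state: int(sum(m.censor_state == state for m in measurements))
            for state in ("quantified", "between_lod_lloq", "below_lod")
        },
        "primary_comparison": primary,
        "n_retained_sensitivity": len(retained),
        "sensitivity_comparison": sensitivity,
    }
    _write_json(summary, outdir / "verification_summary.json")
    return summary
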