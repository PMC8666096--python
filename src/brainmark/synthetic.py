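"""Synthetic study-data generators with planted ground truth.

The discovery study's raw mass-spectrometry and immunoassay data are not
public, so every input the pipeline consumes can be simulated here with a
known answer key: a cohort annotation table (two SCD groups and healthy
controls), protein sequences with planted identity clusters, a scored PSM
table with group-specific detection and negative-binomial spectral counts, a
28-tissue expression compendium with planted brain-enriched genes, and
immunoassay plates (4PL standards, duplicate noise, detection-limit
censoring).  All generators are pure functions of their arguments: the same
seed gives byte-identical output.

Defaults follow the study conditions: discovery cohort 7 SCI-positive /
8 SCI-negative / 6 controls; sample processing times of 0-6 days; standards
spanning 40 down to 0.055 ng/mL by 3-fold serial dilution; assay group
medians 0.28 ng/mL (SCD) vs 0.12 ng/mL (control).  Spectral counts are drawn
negative-binomial — the standard overdispersed model for count-based
label-free quantification — with configurable dispersion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import SequenceRecord
from .differential import GROUPS

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "generate_cohort",
    "generate_sequences",
    "generate_psm_table",
    "generate_expression_compendium",
    "generate_assay_plates",
    "default_truth",
    "write_bundle",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: 4PL parameters of the synthetic electro-chemiluminescent response
STANDARD_CURVE = {"lower": 50.0, "upper": 30000.0, "inflection": 2.0, "slope": 1.0}
#: 3-fold serial dilution from the top standard: 40 / 3**6 = 0.0549 ng/mL
STANDARD_TOP = 40.0
STANDARD_DILUTION = 3.0
N_STANDARDS = 7


@dataclass(frozen=True)
class CohortSpec:
    """Sizes of the three study groups plus the master seed."""

    n_sci_pos: int = 7
    n_sci_neg: int = 8
    n_control: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sci_pos", "n_sci_neg", "n_control"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class PlantedTruth:
    """Answer key for parameter-recovery tests.

    ``fold_map`` holds the true expected SCI-negative / SCI-positive
    spectral-count ratio per accession; ``scd_only_set`` accessions are never
    emitted in control samples; ``assay_group_medians`` are the true group
    medians (ng/mL) of the simulated analyte.
    """

    brain_gene_set: set[str] = field(default_factory=set)
    scd_only_set: set[str] = field(default_factory=set)
    fold_map: dict[str, float] = field(default_factory=dict)
    assay_group_medians: dict[str, float] = field(
        default_factory=lambda: {"sci_pos": 0.28, "sci_neg": 0.28, "control": 0.12}
    )

    def __post_init__(self) -> None:
        bad = {a: f for a, f in self.fold_map.items() if f <= 0}
        if bad:
            raise ValueError(f"fold_map values must be > 0: {bad}")


def default_truth(n_proteins: int = 30) -> PlantedTruth:
    """A convenient answer key over accessions PROT_000..PROT_{n-1}:
    the first two proteins carry planted folds (6.5 up, 0.4 down), the next
    two are SCD-only, and genes GENE_00..GENE_04 are brain-enriched."""
    accs = [f"PROT_{i:03d}" for i in range(n_proteins)]
    return PlantedTruth(
        brain_gene_set={f"GENE_{i:02d}" for i in range(5)},
        scd_only_set=set(accs[2:4]),
        fold_map={accs[0]: 6.5, accs[1]: 0.4},
    )


# ---------------------------------------------------------------- cohort


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample annotation table: one row per sample with id, group, age in
    months, sex, and pre-freeze processing time in days (0-6)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    # group mean ages (months) echo the study populations: ~9.4 y for SCD
    # children, ~11.5 y for controls
    age_mean = {"sci_pos": 118.0, "sci_neg": 108.0, "control": 138.0}
    sizes = {
        "sci_pos": spec.n_sci_pos,
        "sci_neg": spec.n_sci_neg,
        "control": spec.n_control,
    }
    for group in GROUPS:
        for i in range(sizes[group]):
            rows.append(
                {
                    "sample_id": f"{group.upper()}_{i + 1:02d}",
                    "group": group,
                    "age_months": int(
                        np.clip(rng.normal(age_mean[group], 30.0), 24, 216)
                    ),
                    "sex": str(rng.choice(["M", "F"])),
                    "processing_days": int(rng.integers(0, 7)),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "age_months", "sex", "processing_days"]
    )


# ------------------------------------------------------------- sequences


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def generate_sequences(
    n_clusters: int,
    variants_per_cluster: int,
    length_range: tuple[int, int] = (100, 200),
    within_identity: float = 0.95,
    seed: int = 0,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Sequence set with planted identity clusters.

    Each cluster is a random base sequence plus point-substituted variants
    whose identity to the base (and pairwise, by the triangle of shared
    positions) stays >= ``within_identity``; sequences from different
    clusters have independent random composition, so between-cluster
    identity is far below the clustering threshold.  Returns the records and
    a map accession -> planted cluster index.
    """
    if not 0.9 <= within_identity <= 1.0:
        raise ValueError(
            f"within_identity {within_identity} must be in [0.9, 1.0]"
        )
    lo, hi = length_range
    if lo < 20:
        raise ValueError("sequence lengths must be >= 20")
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    labels: dict[str, int] = {}
    for c in range(n_clusters):
        length = int(rng.integers(lo, hi + 1))
        base = _random_sequence(rng, length)
        # substitutions are split across variants so any two variants still
        # share >= within_identity of their positions
        max_mut = int((1.0 - within_identity) * length) // 2
        for v in range(variants_per_cluster):
            acc = f"SEQ_C{c:02d}_V{v:02d}"
            if v == 0:
                seq = base
            else:
                n_mut = int(rng.integers(0, max_mut + 1))
                seq = list(base)
                for pos in rng.choice(length, size=n_mut, replace=False):
                    current = seq[pos]
                    choices = [a for a in AMINO_ACIDS if a != current]
                    seq[pos] = str(rng.choice(choices))
                seq = "".join(seq)
            records.append(SequenceRecord(acc, seq))
            labels[acc] = c
    return records, labels


# ------------------------------------------------------------- PSM table


def _peptides_for(rng: np.random.Generator, n: int = 4) -> list[str]:
    # tryptic-looking peptides: 8-15 residues ending in K/R
    peps = []
    for _ in range(n):
        body = _random_sequence(rng, int(rng.integers(7, 15)))
        peps.append(body + str(rng.choice(["K", "R"])))
    return peps


def generate_psm_table(
    cohort: pd.DataFrame,
    proteins: list[str],
    truth: PlantedTruth,
    detection_prob: dict[str, float] | None = None,
    mean_sc: dict[str, float] | None = None,
    dispersion: float = 5.0,
    fail_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Scored PSM table with group-specific detection and planted folds.

    Per sample and protein: the protein is detected with the group's
    detection probability; if detected, its accepted-quality spectral count
    is drawn from a negative binomial with mean ``mean_sc[group]`` times the
    planted fold factor (applied to the SCI-negative group), floored at 1.
    On top of the accepted-quality rows, roughly ``fail_fraction`` extra rows
    are emitted that each violate exactly one acceptance rule (probability
    <= 0.95, Mowse <= 35, or charge 1).  Accessions in ``truth.scd_only_set``
    are never emitted for control samples.
    """
    detection_prob = detection_prob or {g: 0.9 for g in GROUPS}
    mean_sc = mean_sc or {g: 8.0 for g in GROUPS}
    if dispersion <= 0:
        raise ValueError(f"dispersion must be > 0, got {dispersion}")
    for g, p in detection_prob.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"detection_prob[{g}]={p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    pep_pool = {acc: _peptides_for(rng) for acc in proteins}
    rows = []
    spectrum_counter = 0

    def emit(sample: str, acc: str, good: bool) -> None:
        nonlocal spectrum_counter
        spectrum_counter += 1
        if good:
            prob = float(rng.uniform(0.951, 1.0))
            mowse = float(rng.uniform(35.5, 90.0))
            charge = int(rng.choice([2, 3]))
        else:
            mode = rng.integers(0, 3)
            prob = float(rng.uniform(0.5, 0.95)) if mode == 0 else float(rng.uniform(0.951, 1.0))
            mowse = float(rng.uniform(10.0, 35.0)) if mode == 1 else float(rng.uniform(35.5, 90.0))
            charge = 1 if mode == 2 else int(rng.choice([2, 3]))
        rows.append(
            {
                "sample_id": sample,
                "accession": acc,
                "peptide": str(rng.choice(pep_pool[acc])),
                "charge": charge,
                "probability": round(prob, 4),
                "mowse": round(mowse, 1),
                "spectrum_id": f"spec_{spectrum_counter:07d}",
            }
        )

    for row in cohort.itertuples(index=False):
        group = row.group
        for acc in proteins:
            if group == "control" and acc in truth.scd_only_set:
                continue
            if rng.random() >= detection_prob[group]:
                continue
            fold = truth.fold_map.get(acc, 1.0) if group == "sci_neg" else 1.0
            mean = mean_sc[group] * fold
            r = dispersion
            k = int(rng.negative_binomial(r, r / (r + mean)))
            k = max(k, 1)
            for _ in range(k):
                emit(row.sample_id, acc, good=True)
            n_bad = int(rng.binomial(k, fail_fraction))
            for _ in range(n_bad):
                emit(row.sample_id, acc, good=False)
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "accession",
            "peptide",
            "charge",
            "probability",
            "mowse",
            "spectrum_id",
        ],
    )


# ------------------------------------------------------------ compendium


def generate_expression_compendium(
    genes: list[str],
    brain_gene_set: set[str],
    n_other_tissues: int = 27,
    partial_genes: dict[str, set[str]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format compendium (gene, source, tissue, value) for the three
    sources (microarray, est, sage) over brain + ``n_other_tissues`` tissues.

    Planted brain genes satisfy all three enrichment criteria; genes in
    ``partial_genes`` satisfy exactly the listed sources; all other genes
    satisfy none.  Planted and partial sets must not overlap.
    """
    if n_other_tissues < 1:
        raise ValueError("need at least one non-brain tissue")
    partial_genes = partial_genes or {}
    overlap = brain_gene_set & set(partial_genes)
    if overlap:
        raise ValueError(f"genes both planted and partial: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    tissues = [f"tissue_{i:02d}" for i in range(1, n_other_tissues + 1)]
    rows = []
    for gene in genes:
        if gene in brain_gene_set:
            satisfied = {"microarray", "est", "sage"}
        else:
            satisfied = partial_genes.get(gene, set())
        # microarray intensities
        others = rng.uniform(8.0, 12.0, size=n_other_tissues)
        if "microarray" in satisfied:
            brain_val = 15.0 * float(np.median(others)) + float(rng.uniform(0, 50))
        else:
            brain_val = float(rng.uniform(8.0, 12.0))
        rows.append({"gene": gene, "source": "microarray", "tissue": "brain", "value": round(brain_val, 3)})
        rows += [
            {"gene": gene, "source": "microarray", "tissue": t, "value": round(float(v), 3)}
            for t, v in zip(tissues, others)
        ]
        # tag-count sources
        for source in ("est", "sage"):
            tags = np.zeros(n_other_tissues)
            if source in satisfied:
                brain_tags = float(rng.integers(5, 20))
                n_leak = int(rng.integers(0, 2))  # 0 or 1 other tissue
            else:
                brain_tags = float(rng.integers(1, 10))
                n_leak = int(rng.integers(5, n_other_tissues + 1))
            leak_idx = rng.choice(n_other_tissues, size=n_leak, replace=False)
            tags[leak_idx] = rng.integers(1, 10, size=n_leak)
            rows.append({"gene": gene, "source": source, "tissue": "brain", "value": brain_tags})
            rows += [
                {"gene": gene, "source": source, "tissue": t, "value": float(v)}
                for t, v in zip(tissues, tags)
            ]
    return pd.DataFrame(rows, columns=["gene", "source", "tissue", "value"])


# ----------------------------------------------------------- assay plates


def _standards_table(
    rng: np.random.Generator, duplicate_cv: float
) -> pd.DataFrame:
    from .assay import four_pl

    concs = [STANDARD_TOP / STANDARD_DILUTION**k for k in range(N_STANDARDS)]
    rows = []
    for c in concs:
        mu = float(four_pl(c, **STANDARD_CURVE))
        s1 = mu * (1.0 + duplicate_cv * float(rng.standard_normal()))
        s2 = mu * (1.0 + duplicate_cv * float(rng.standard_normal()))
        rows.append(
            {"concentration": c, "signal_1": round(s1, 3), "signal_2": round(s2, 3)}
        )
    return pd.DataFrame(rows)


def generate_assay_plates(
    cohort: pd.DataFrame,
    truth: PlantedTruth,
    duplicate_cv: float = 0.05,
    lloq: float = 0.039,
    lod: float = 0.012,
    timepoints: tuple = (0,),
    log_sigma: dict[str, float] | None = None,
    below_lloq_fraction: float = 0.0,
    below_lod_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(plate table, standards table) for an immunoassay verification run.

    Subject concentrations are log-normal around the planted group median
    (the log-scale spread defaults mirror the study's reported IQRs: wide in
    SCD, narrow in controls); duplicates perturb the 4PL signal at
    ``duplicate_cv``; configurable fractions of subject-visits are planted
    in the LOD-LLOQ window or below the LOD.
    """
    if lod >= lloq:
        raise ValueError(f"LOD {lod} must be below LLOQ {lloq}")
    if duplicate_cv < 0:
        raise ValueError("duplicate_cv must be >= 0")
    from .assay import four_pl

    log_sigma = log_sigma or {"sci_pos": 1.3, "sci_neg": 1.3, "control": 0.35}
    rng = np.random.default_rng(seed)
    standards = _standards_table(rng, duplicate_cv)
    rows = []
    for row in cohort.itertuples(index=False):
        median = truth.assay_group_medians[row.group]
        base = float(
            np.exp(rng.normal(np.log(median), log_sigma[row.group]))
        )
        for month in timepoints:
            conc = base * float(np.exp(rng.normal(0.0, 0.1)))
            u = rng.random()
            if u < below_lod_fraction:
                conc = float(rng.uniform(lod * 0.1, lod))
            elif u < below_lod_fraction + below_lloq_fraction:
                conc = float(rng.uniform(lod * 1.01, lloq * 0.99))
            mu = float(four_pl(conc, **STANDARD_CURVE))
            s1 = mu * (1.0 + duplicate_cv * float(rng.standard_normal()))
            s2 = mu * (1.0 + duplicate_cv * float(rng.standard_normal()))
            rows.append(
                {
                    "subject_id": row.sample_id,
                    "group": row.group,
                    "visit_month": month,
                    "dup_signal_1": round(s1, 3),
                    "dup_signal_2": round(s2, 3),
                    "processing_days": row.processing_days,
                }
            )
    plate = pd.DataFrame(
        rows,
        columns=[
            "subject_id",
            "group",
            "visit_month",
            "dup_signal_1",
            "dup_signal_2",
            "processing_days",
        ],
    )
    return plate, standards


# ---------------------------------------------------------------- bundle


def write_bundle(
    outdir,
    cohort_spec: CohortSpec,
    n_proteins: int = 30,
    truth: PlantedTruth | None = None,
) -> dict[str, Path]:
    """Write a full simulated input bundle (FASTA, TSVs, truth JSON) that
    the discovery and verification stages can consume end to end."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = truth or default_truth(n_proteins)
    seed = cohort_spec.seed

    cohort = generate_cohort(cohort_spec)
    records, labels = generate_sequences(
        n_clusters=n_proteins, variants_per_cluster=1, seed=seed + 1
    )
    # rename singleton-cluster sequences onto the protein accessions
    accs = [f"PROT_{i:03d}" for i in range(n_proteins)]
    records = [
        SequenceRecord(acc, rec.sequence) for acc, rec in zip(accs, records)
    ]
    psms = generate_psm_table(cohort, accs, truth, seed=seed + 2)
    genes = [f"GENE_{i:02d}" for i in range(n_proteins)]
    compendium = generate_expression_compendium(
        genes, truth.brain_gene_set, seed=seed + 3
    )
    acc_to_gene = pd.DataFrame({"accession": accs, "gene": genes})
    plate, standards = generate_assay_plates(cohort, truth, seed=seed + 4)

    paths = {
        "cohort": outdir / "cohort.tsv",
        "psms": outdir / "psms.tsv",
        "fasta": outdir / "proteins.fasta",
        "compendium": outdir / "compendium.tsv",
        "accession_to_gene": outdir / "accession_to_gene.tsv",
        "plate": outdir / "plate.tsv",
        "standards": outdir / "standards.tsv",
        "truth": outdir / "planted_truth.json",
    }
    cohort.to_csv(paths["cohort"], sep="\t", index=False)
    psms.to_csv(paths["psms"], sep="\t", index=False)
    with open(paths["fasta"], "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")
    compendium.to_csv(paths["compendium"], sep="\t", index=False)
    acc_to_gene.to_csv(paths["accession_to_gene"], sep="\t", index=False)
    plate.to_csv(paths["plate"], sep="\t", index=False)
    standards.to_csv(paths["standards"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "brain_gene_set": sorted(truth.brain_gene_set),
                "scd_only_set": sorted(truth.scd_only_set),
                "fold_map": truth.fold_map,
                "assay_group_medians": truth.assay_group_medians,
            },
            fh,
            indent=2,
        )
    return paths
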