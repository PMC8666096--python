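"""Brain-enrichment scoring from a 28-tissue expression compendium.

Each gene is scored 0-3 from three independent transcript-expression data
sources measured across human brain plus 27 other normal tissues:

* **microarray** — 1 point when brain intensity exceeds ten-fold the
  baseline, where baseline is the median of the non-brain tissues (robust to
  co-expression in one or two other tissues; configurable to the mean);
* **EST** and **SAGE** tag counts — 1 point each when tags are present in
  brain and in fewer than two other tissues (presence = at least one tag).

The composite brain list (default: any point, i.e. total >= 1) is then
intersected with the detected plasma proteome, per group, to report brain
proteins circulating in plasma of the SCD groups but absent from controls,
and vice versa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import round_half_up
from .identfilter import ProteinEvidence

__all__ = [
    "SOURCES",
    "TissueProfile",
    "BrainScore",
    "score_microarray",
    "score_tag_presence",
    "composite_score",
    "build_brain_list",
    "score_table",
    "filter_plasma_brain",
]

SOURCES = ("microarray", "est", "sage")
BRAIN = "brain"


@dataclass(frozen=True)
class TissueProfile:
    """Per-gene expression across brain + other tissues for one source."""

    gene: str
    source: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if BRAIN not in self.values:
            raise ValueError(f"{self.gene}/{self.source}: no brain entry")
        if len(self.values) < 2:
            raise ValueError(f"{self.gene}/{self.source}: no non-brain tissue")
        if any(v < 0 for v in self.values.values()):
            raise ValueError(f"{self.gene}/{self.source}: negative expression")

    @property
    def brain(self) -> float:
        return self.values[BRAIN]

    @property
    def others(self) -> list[float]:
        return [v for t, v in self.values.items() if t != BRAIN]


@dataclass(frozen=True)
class BrainScore:
    gene: str
    microarray_point: int
    est_point: int
    sage_point: int

    @property
    def total(self) -> int:
        return self.microarray_point + self.est_point + self.sage_point


def score_microarray(
    profile: TissueProfile, fold_cut: float = 10.0, baseline: str = "median"
) -> int:
    """1 iff brain intensity is strictly more than ``fold_cut`` times the
    non-brain baseline.  A zero baseline with nonzero brain signal scores 1;
    an all-zero profile scores 0 (with a warning)."""
    if profile.source != "microarray":
        raise ValueError(f"expected a microarray profile, got {profile.source}")
    base = float(np.median(profile.others) if baseline == "median" else np.mean(profile.others))
    if profile.brain == 0 and base == 0:
        warnings.warn(f"{profile.gene}: all-zero microarray profile", stacklevel=2)
        return 0
    if base == 0:
        return 1
    return int(profile.brain > fold_cut * base)


def score_tag_presence(
    profile: TissueProfile,
    presence_cut: float = 1.0,
    max_other_tissues: int = 2,
) -> int:
    """1 iff tags are present in brain and in fewer than ``max_other_tissues``
    non-brain tissues (presence = value >= presence_cut)."""
    if profile.source not in ("est", "sage"):
        raise ValueError(f"expected an est/sage profile, got {profile.source}")
    n_other = sum(v >= presence_cut for v in profile.others)
    return int(profile.brain >= presence_cut and n_other < max_other_tissues)


def composite_score(
    gene: str,
    profiles: dict[str, TissueProfile],
    fold_cut: float = 10.0,
    presence_cut: float = 1.0,
    max_other_tissues: int = 2,
) -> BrainScore:
    """Combine available per-source profiles into the 0-3 score; a missing
    source contributes 0."""
    if not profiles:
        raise ValueError(f"{gene}: no expression profile in any source")
    pts = {s: 0 for s in SOURCES}
    if "microarray" in profiles:
        pts["microarray"] = score_microarray(profiles["microarray"], fold_cut)
    for s in ("est", "sage"):
        if s in profiles:
            pts[s] = score_tag_presence(profiles[s], presence_cut, max_other_tissues)
    return BrainScore(gene, pts["microarray"], pts["est"], pts["sage"])


def _profiles_by_gene(compendium: pd.DataFrame) -> dict[str, dict[str, TissueProfile]]:
    """Long compendium (gene, source, tissue, value) -> nested profiles."""
    out: dict[str, dict[str, TissueProfile]] = {}
    for (gene, source), sub in compendium.groupby(["gene", "source"], sort=True):
        values = dict(zip(sub["tissue"], sub["value"].astype(float)))
        out.setdefault(str(gene), {})[str(source)] = TissueProfile(
            str(gene), str(source), values
        )
    return out


def score_table(compendium: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Score every gene in a long-format compendium; one row per gene with
    per-source points and the total, sorted by gene."""
    rows = []
    for gene, profiles in sorted(_profiles_by_gene(compendium).items()):
        s = composite_score(gene, profiles, **kwargs)
        rows.append(
            {
                "gene": gene,
                "microarray_point": s.microarray_point,
                "est_point": s.est_point,
                "sage_point": s.sage_point,
                "total": s.total,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "microarray_point", "est_point", "sage_point", "total"]
    )


def build_brain_list(
    compendium: pd.DataFrame, min_total: int = 1, **kwargs
) -> set[str]:
    """Genes whose composite score reaches ``min_total`` (1, 2 or 3)."""
    if min_total not in (1, 2, 3):
        raise ValueError("min_total must be 1, 2 or 3")
    if compendium.empty:
        return set()
    table = score_table(compendium, **kwargs)
    return set(table.loc[table["total"] >= min_total, "gene"])


def filter_plasma_brain(
    detected_sets: dict[str, set[str]],
    brain_list: set[str],
    accession_to_gene: dict[str, str],
    evidence: list[ProteinEvidence] | None = None,
    annotations: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Intersect detected plasma proteomes with the brain-enriched gene list.

    Returns two tables: ``scd_not_control`` — brain proteins detected in
    either SCD group but never in controls — and ``control_not_scd`` — brain
    proteins seen only in controls.  When evidence is supplied each row also
    carries the average spectral count over detected samples (across the
    relevant groups) and the single-peptide flag.
    """
    unmapped = (
        set().union(*detected_sets.values()) - set(accession_to_gene)
        if detected_sets
        else set()
    )
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} detected accession(s) lack a gene mapping and "
            "cannot match the brain list",
            stacklevel=2,
        )

    def is_brain(acc: str) -> bool:
        return accession_to_gene.get(acc) in brain_list

    scd = detected_sets.get("sci_pos", set()) | detected_sets.get("sci_neg", set())
    ctrl = detected_sets.get("control", set())
    scd_brain = sorted(acc for acc in scd - ctrl if is_brain(acc))
    ctrl_brain = sorted(acc for acc in ctrl - scd if is_brain(acc))

    ev_by_acc = {ev.accession: ev for ev in (evidence or [])}

    def table(accessions: list[str], groups: tuple[str, ...]) -> pd.DataFrame:
        rows = []
        for acc in accessions:
            row: dict[str, object] = {
                "accession": acc,
                "gene": accession_to_gene.get(acc),
            }
            ev = ev_by_acc.get(acc)
            if ev is not None and annotations is not None:
                group_of = dict(
                    zip(annotations["sample_id"].astype(str), annotations["group"])
                )
                counts = [
                    sc
                    for s, sc in ev.sc_by_sample.items()
                    if sc > 0 and group_of.get(s) in groups
                ]
                row["avg_sc"] = (
                    round_half_up(sum(counts) / len(counts), 2) if counts else 0.0
                )
                row["single_peptide_flag"] = ev.single_peptide_flag
            rows.append(row)
        return pd.DataFrame(rows)

    return {
        "scd_not_control": table(scd_brain, ("sci_pos", "sci_neg")),
        "control_not_scd": table(ctrl_brain, ("control",)),
    }
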