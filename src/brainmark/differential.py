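"""Group-wise presence/absence algebra and spectral-count fold-change screen.

Proteins are compared between the SCI-positive, SCI-negative and healthy
control proteomes in two ways: (i) a three-set detection partition ("which
groups was the protein ever seen in"), reported as a seven-region Venn
breakdown with percentages of the SCD-detected proteome, and (ii) a
fold-change screen on average spectral counts between the two SCD groups.

Conventions that matter for reproducing reported values:

* The per-group average spectral count is taken over the samples in which
  the protein was *detected* (SC > 0), not over the whole group.
* The SCI-negative / SCI-positive ratio is rounded half-up to one decimal
  *before* it is compared with the cut-offs, and the cut-offs are inclusive
  (>= 2.0 or <= 0.5).  This is the only convention under which boundary
  proteins (e.g. a ratio of 1.9935 printing as 2.0) screen in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .identfilter import ProteinEvidence

__all__ = [
    "GROUPS",
    "DifferentialRecord",
    "VennPartition",
    "round_half_up",
    "detection_sets",
    "venn_partition",
    "average_sc",
    "fold_change_screen",
    "differential_to_frame",
]

#: canonical group labels used throughout the pipeline
GROUPS = ("sci_pos", "sci_neg", "control")


def round_half_up(x: float, digits: int = 1) -> float:
    """Decimal round-half-up (0.25 -> 0.3 at one digit), unlike banker's
    rounding.  Infinities pass through."""
    x = float(x)
    if math.isinf(x):
        return x
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class DifferentialRecord:
    accession: str
    n_detected: dict[str, int]
    avg_sc: dict[str, float]
    ratio: float  # SCI-negative avg / SCI-positive avg, rounded
    passes_filter: bool


@dataclass
class VennPartition:
    """Counts for the seven regions of the three-set detection diagram."""

    pos_only: int
    neg_only: int
    control_only: int
    pos_neg_only: int      # both SCD groups, not control
    pos_control_only: int
    neg_control_only: int
    triple: int

    @property
    def scd_total(self) -> int:
        """Proteins detected in either SCD group."""
        return (
            self.pos_only
            + self.neg_only
            + self.pos_neg_only
            + self.pos_control_only
            + self.neg_control_only
            + self.triple
        )

    @property
    def union_total(self) -> int:
        return self.scd_total + self.control_only

    def report(self) -> dict[str, float]:
        """Headline counts and integer percentages of the SCD proteome."""
        tot = self.scd_total

        def pct(k: int) -> int:
            return int(round_half_up(100.0 * k / tot, 0)) if tot else 0

        return {
            "scd_total": tot,
            "unique_sci_pos": self.pos_only,
            "unique_sci_pos_pct": pct(self.pos_only),
            "unique_sci_neg": self.neg_only,
            "unique_sci_neg_pct": pct(self.neg_only),
            "common_scd_not_control": self.pos_neg_only,
            "common_scd_not_control_pct": pct(self.pos_neg_only),
            "control_only": self.control_only,
        }


def _group_of(annotations: pd.DataFrame) -> dict[str, str]:
    return dict(zip(annotations["sample_id"].astype(str), annotations["group"]))


def detection_sets(
    evidence: list[ProteinEvidence], annotations: pd.DataFrame
) -> dict[str, set[str]]:
    """Accessions detected (SC > 0 in >= 1 sample) per group."""
    group_of = _group_of(annotations)
    sets: dict[str, set[str]] = {g: set() for g in GROUPS}
    for ev in evidence:
        for sample, sc in ev.sc_by_sample.items():
            if sc <= 0:
                continue
            if sample not in group_of:
                raise ValueError(f"sample {sample!r} has no group annotation")
            sets[group_of[sample]].add(ev.accession)
    return sets


def venn_partition(
    set_pos: set[str], set_neg: set[str], set_control: set[str]
) -> VennPartition:
    return VennPartition(
        pos_only=len(set_pos - set_neg - set_control),
        neg_only=len(set_neg - set_pos - set_control),
        control_only=len(set_control - set_pos - set_neg),
        pos_neg_only=len((set_pos & set_neg) - set_control),
        pos_control_only=len((set_pos & set_control) - set_neg),
        neg_control_only=len((set_neg & set_control) - set_pos),
        triple=len(set_pos & set_neg & set_control),
    )


def average_sc(
    ev: ProteinEvidence, group: str, annotations: pd.DataFrame
) -> float:
    """Mean spectral count over the group's samples where the protein was
    detected (SC > 0); 0.0 if never detected in the group."""
    group_of = _group_of(annotations)
    counts = [
        sc
        for sample, sc in ev.sc_by_sample.items()
        if sc > 0 and group_of.get(sample) == group
    ]
    return sum(counts) / len(counts) if counts else 0.0


def _ratio(avg_neg: float, avg_pos: float) -> float:
    if avg_pos == 0.0:
        return math.inf if avg_neg > 0 else 0.0
    return avg_neg / avg_pos


def fold_change_screen(
    records: list[dict],
    min_samples: int = 2,
    high_cut: float = 2.0,
    low_cut: float = 0.5,
    round_digits: int = 1,
) -> list[DifferentialRecord]:
    """Flag proteins whose rounded SC ratio clears the two-fold screen.

    ``records`` rows need ``accession``, ``n_detected`` (group -> int) and
    ``avg_sc`` (group -> float).  A protein passes when it was detected in at
    least ``min_samples`` samples of *each* SCD group and its SCI-neg/SCI-pos
    average-SC ratio, rounded half-up to ``round_digits``, is >= high_cut or
    <= low_cut.  An infinite ratio (never detected in SCI-pos) can only pass
    the high side.
    """
    if high_cut <= 1.0 or not math.isclose(low_cut, 1.0 / high_cut):
        raise ValueError("expected high_cut > 1 and low_cut = 1/high_cut")
    out = []
    for rec in records:
        n_det = rec["n_detected"]
        avg = rec["avg_sc"]
        ratio = round_half_up(_ratio(avg["sci_neg"], avg["sci_pos"]), round_digits)
        enough = (
            n_det.get("sci_neg", 0) >= min_samples
            and n_det.get("sci_pos", 0) >= min_samples
        )
        passes = enough and (ratio >= high_cut or ratio <= low_cut)
        out.append(
            DifferentialRecord(
                accession=rec["accession"],
                n_detected=dict(n_det),
                avg_sc=dict(avg),
                ratio=ratio,
                passes_filter=passes,
            )
        )
    return out


def records_from_evidence(
    evidence: list[ProteinEvidence], annotations: pd.DataFrame
) -> list[dict]:
    """Build fold_change_screen input rows from assembled evidence."""
    group_of = _group_of(annotations)
    rows = []
    for ev in evidence:
        n_det = {g: 0 for g in GROUPS}
        for sample, sc in ev.sc_by_sample.items():
            if sc > 0:
                n_det[group_of[sample]] += 1
        rows.append(
            {
                "accession": ev.accession,
                "n_detected": n_det,
                "avg_sc": {g: average_sc(ev, g, annotations) for g in GROUPS},
            }
        )
    return rows


def differential_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Tabular report mirroring the discovery screen's published layout."""
    rows = [
        {
            "accession": r.accession,
            "n_samples_sci_neg": r.n_detected.get("sci_neg", 0),
            "n_samples_sci_pos": r.n_detected.get("sci_pos", 0),
            "avg_sc_sci_neg": round_half_up(r.avg_sc.get("sci_neg", 0.0), 1),
            "avg_sc_sci_pos": round_half_up(r.avg_sc.get("sci_pos", 0.0), 1),
            "sc_ratio_neg_over_pos": r.ratio,
            "passes_filter": r.passes_filter,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
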