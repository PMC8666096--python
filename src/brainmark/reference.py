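"""Published reference values from the sickle-cell silent-infarct discovery
cohort, packaged as plain-text tables.

These are inputs, not outputs: the raw mass-spectrometry data behind them
are not publicly available, so the per-group average spectral counts of the
23 differentially detected proteins, the 25-protein brain panel, and the
detection-overlap (Venn) region counts of the 1172-protein SCD plasma
proteome are carried as reported, and the pipeline's arithmetic is exercised
against them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_fold_change_reference",
    "load_brain_panel",
    "VENN_REGIONS",
    "CONTROL_BRAIN_PROTEINS",
]

#: detection-overlap counts of the discovery proteomes. The three regions of
#: the SCD proteome outside the control set and the control-only region are
#: reported individually; the 400 SCD proteins shared with controls are only
#: reported in aggregate and are carried as a single pooled region here.
VENN_REGIONS = {
    "pos_only": 289,
    "neg_only": 335,
    "pos_neg_only": 148,
    "control_only": 239,
    "scd_and_control": 400,  # 1172 - 289 - 335 - 148
    "scd_total": 1172,
}

#: brain-enriched proteins detected only in the healthy control proteome
CONTROL_BRAIN_PROTEINS = {"O75096": "LRP4", "Q9Y2J0": "RPH3A"}


def _load(name: str) -> pd.DataFrame:
    with resources.files("brainmark.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_fold_change_reference() -> pd.DataFrame:
    """The 23-protein differential screen: per-group detection counts,
    average spectral counts, and the reported SCI-neg/SCI-pos ratio."""
    return _load("discovery_fold_change.tsv")


def load_brain_panel() -> pd.DataFrame:
    """The 25 brain-enriched proteins detected in SCD plasma, with cellular
    component and average spectral count."""
    return _load("brain_panel.tsv")
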