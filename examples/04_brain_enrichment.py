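"""Score genes for brain-enriched expression and intersect with plasma.

Generates a 28-tissue compendium with three planted brain-enriched genes
and one partially enriched gene, scores each gene 0-3 (one point per data
source meeting its criterion), and filters a toy detected plasma proteome
against the resulting brain list.
"""

from brainmark.brain import build_brain_list, filter_plasma_brain, score_table
from brainmark.synthetic import generate_expression_compendium

genes = [f"G{i:02d}" for i in range(8)]
compendium = generate_expression_compendium(
    genes, brain_gene_set={"G00", "G01", "G02"},
    partial_genes={"G03": {"microarray"}}, seed=3,
)
print(score_table(compendium).to_string(index=False))

brain_list = build_brain_list(compendium, min_total=1)
detected = {"sci_pos": {"P00", "P03", "P07"}, "sci_neg": {"P01"}, "control": {"P02"}}
mapping = {f"P{i:02d}": f"G{i:02d}" for i in range(8)}
tables = filter_plasma_brain(detected, brain_list, mapping)
print("\nbrain proteins in SCD plasma, absent from controls:",
      list(tables["scd_not_control"]["accession"]))
print("brain proteins only in control plasma:",
      list(tables["control_not_scd"]["accession"]))
# G02 maps to P02, detected only in controls -> reported on the control side.
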