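"""Filter a scored PSM table and assemble per-sample spectral counts.

Builds a small synthetic identification table (some rows deliberately fail
the probability > 0.95 / Mowse > 35 / charge >= 2 rules), filters it, and
tallies per-protein spectral counts.
"""

from brainmark import identfilter, synthetic

cohort = synthetic.generate_cohort(synthetic.CohortSpec(3, 3, 2, seed=1))
truth = synthetic.default_truth(n_proteins=5)
accs = [f"PROT_{i:03d}" for i in range(5)]
table = synthetic.generate_psm_table(cohort, accs, truth, fail_fraction=0.2, seed=1)

psms = identfilter.psms_from_frame(table)
accepted = identfilter.filter_psms(psms)
evidence = identfilter.assemble_proteins(accepted, require_manual_validation=False)

print(f"{len(psms)} PSMs scored, {len(accepted)} accepted by the thresholds")
print(f"{len(evidence)} proteins with spectral-count evidence:")
for ev in evidence:
    print(f"  {ev.accession}: total SC {ev.total_sc}, "
          f"{ev.n_peptides} peptides, detected in {len(ev.sc_by_sample)} samples")
# The accepted/scored gap reflects the planted failure fraction; each
# protein's total SC is its label-free abundance proxy summed over samples.
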