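# Methods

## Scope and data model

The package reconstructs a plasma biomarker workflow with two stages. The
*discovery* stage consumes a scored peptide-identification table (one row
per peptide-spectrum match: sample, protein accession, peptide, charge,
identification probability, Mowse score, spectrum id), protein sequences
(FASTA), a sample annotation table (SCI-positive / SCI-negative / control),
a 28-tissue expression compendium (gene × source × tissue, long format),
and an accession→gene map. The *verification* stage consumes immunoassay
plate tables (duplicate signals per subject-visit plus pre-freeze
processing time in days) and a standards table. All I/O is TSV/FASTA/JSON;
reports are plain text so runs diff cleanly.

The raw study data behind the workflow are not publicly available. Two
packaged plain-text tables carry the study's *reported summaries* — the
23-protein differential screen (per-group detection counts and average
spectral counts) and the 25-protein brain panel (cellular component,
average spectral count) — and are treated as inputs for re-computation, not
as outputs of this package.

## Identification filtering

A PSM is accepted iff probability > 0.95 AND Mowse > 35 AND charge ≥ 2.
The probability and Mowse comparisons are strict, following the "greater
than" phrasing of the acceptance rules. "Charge > +2" is ambiguous between
≥ 2 and ≥ 3; the default is ≥ 2 because doubly protonated tryptic peptides
dominate real identifications and a ≥ 3 rule would discard most of them.
All three thresholds are configurable.

The spectral count of a protein in a sample is the number of accepted PSMs
for that (protein, sample) pair; no normalisation is applied (none is part
of the workflow being modelled). A peptide is *confirmed* when ≥ 2 accepted
spectra match it across all samples. A protein supported only by a single
peptide seen in a single spectrum is routed to a manual-validation path: by
default (`require_manual_validation`) it is dropped unless its accession is
supplied in a validated set; the pipeline default disables the requirement
because synthetic data have no manual reviewer. Single-peptide proteins are
always flagged, since low-level single-peptide hits are exactly what a
brain protein in plasma is expected to look like.

## Redundancy clustering

Sequences are clustered greedily at an identity threshold (default 0.90):
sorted by descending length (ties: lexicographic accession), each sequence
joins the first existing cluster whose representative it matches at ≥ the
threshold, else founds a new cluster. The output is a deterministic
partition; the representative is the longest member.

Identity follows the CD-HIT convention: identical aligned residue pairs in
an optimal global alignment (match 1, mismatch 0, linear gap −1) divided by
the shorter sequence length. Because the mismatch score is zero the optimal
alignment is highly degenerate, and the identity of "an" optimal traceback
depends on which one an aligner happens to report — it is not even
symmetric in its arguments. The package therefore defines identity via the
*maximum* match count over all optimal-score alignments, a well-defined
symmetric quantity, computed exactly by dynamic programming (the DP packs
(score, matches) into one integer so the lexicographic maximum is an
ordinary maximum; rows vectorise with a prefix maximum). Exact DP with no
k-mer prescreen is adequate at the scale this package targets (hundreds of
sequences of a few hundred residues).

Collapsing evidence sums per-sample spectral counts over cluster members
under the representative accession (total SC is conserved; asserted in
tests) and unions peptide sets. Evidence accessions without a sequence pass
through unclustered.

## Differential screen

A protein is *detected* in a group iff SC > 0 in at least one sample of the
group. The three detection sets yield a seven-region Venn partition;
headline percentages (unique to each SCD group, common to both SCD groups
outside controls) are reported against the SCD-detected total, rounded to
the nearest integer.

The per-group average SC is the mean over *detected* samples only, not the
whole group — the only reading consistent with reported high averages at
low detection counts (e.g. an average of 21.0 from 2 samples). A switch
(`average_over_all_samples` semantics via the records interface) is not
needed by any supported analysis and was not carried; the averaging base is
documented here instead.

The screen passes a protein iff it is detected in ≥ 2 samples of each SCD
group and the SCI-negative/SCI-positive average-SC ratio, **rounded half-up
to one decimal before comparison**, is ≥ 2.0 or ≤ 0.5. Rounding before
thresholding is deliberate and load-bearing: a ratio of 1.9935 (305.0/153.0)
must screen in, and boundary values of exactly 2.0 and 0.5 are members of
the reference screen. An infinite ratio (zero SCI-positive average) passes
only the high side. Two reference rows (L-selectin, protein Z-dependent
protease inhibitor) print ratios one final-decimal step away from what
their printed one-decimal averages yield under any rounding convention;
they were evidently computed from unrounded averages. The re-computation
tests assert exact agreement on the other 21 rows and one-decimal-step
agreement on those two; membership of all 23 in the passing set is exact.

## Brain-enrichment scoring

Each gene receives one point per data source meeting its criterion, total
0–3:

* **microarray** — brain intensity strictly greater than 10× baseline.
  "Baseline" is not defined by the source workflow; the package uses the
  *median* of the 27 non-brain tissues (robust to co-expression in one or
  two tissues), configurable to the mean. A zero baseline with nonzero
  brain signal scores 1; an all-zero profile scores 0 with a warning.
* **EST / SAGE** — tags present in brain and in fewer than two other
  tissues; presence is ≥ 1 tag (`presence_cut` configurable for noisy
  compendia).

Missing sources contribute 0. The composite brain list admits genes with
total ≥ `min_total`; the default is 1 (any evidence level), matching a
panel that mixes evidence strengths, with 2 or 3 available for stricter
lists. The plasma intersection reports brain-listed proteins detected in
either SCD group but never in controls, and vice versa, each with average
SC over detected samples and the single-peptide flag. Membrane association
in the packaged panel is counted from the cellular-component annotation
equal to "Membrane" (a protein annotated "Membrane; Cytoplasm" or
"Endoplasmic reticulum membrane" is not counted), which is the only
convention consistent with the panel's reported 11/25 membrane fraction.

## Immunoassay verification

Standards spanning 40 down to 0.055 ng/mL (a 3-fold serial dilution:
40/3⁶ ≈ 0.055) are fitted by least squares to the four-parameter logistic
signal = d + (a − d)/(1 + (c/c₀)^b). Gross non-monotonicity of the
standards (rank correlation between concentration and mean signal below
0.9 in magnitude, e.g. a corrupted standard) is a hard error; small
adjacent inversions from duplicate noise on the flat ends of the curve are
tolerated, but the *fitted* curve must be strictly monotone over the
standard range. Unknowns are inverted in closed form; signals at or outside
the asymptotes are not invertible and censor low.

Duplicate QC takes CV% = 100·sd/mean (sample sd) of the two back-calculated
concentrations; CV% strictly above 20 flags the well for repeat, otherwise
the duplicate mean is carried forward. Censoring: values ≥ LLOQ
(0.039 ng/mL) are quantified; values between LOD (0.012 ng/mL) and LLOQ are
recorded as LLOQ/2 = 0.0195; values at or below LOD are recorded as LOD/2
by default (`below_lod_policy="half_lod"`, preserving sample size symmetry
with the half-LLOQ rule) or excluded under `"exclude"`. Censoring is
idempotent (property-tested).

Groups are summarised by median and 25–75% IQR (linear-interpolation
quantiles, the common convention; the original analysis software's default
is unknowable) and compared with the two-sided Wilcoxon rank-sum test —
exact when the pooled sample has ≤ 30 observations and no ties, otherwise
the tie-corrected normal approximation. The nonparametric test is the
primary comparison because medians and IQRs are the reported summaries; a
t-test on covariates such as age is available through scipy directly.
Spearman correlation uses average ranks with the t-approximation p-value;
constant input is undefined and returns NaN. The sensitivity filter
withholds samples whose pre-freeze processing time was 4 days or more
(strictly less than `max_days` retained); samples with unknown processing
time are retained. Longitudinal modelling (multi-level mixed-effects
regression) is out of scope; `to_long_format` exports a tidy subject-visit
table for external fitting.

## Synthetic data

The generators emulate the study conditions and carry an explicit answer
key (`PlantedTruth`):

* **Cohort** — default 7 SCI-positive / 8 SCI-negative / 6 controls; ages
  drawn around the group means of the modelled populations (~9–9.8 years
  SCD, ~11.5 years controls); processing times uniform integers 0–6 days.
* **Sequences** — per cluster, a random base sequence (uniform residues)
  plus point-substituted variants budgeted so any two members stay at or
  above the within-cluster identity floor (≥ 0.9 enforced); between-cluster
  identity is far below threshold by construction and asserted in tests.
* **PSM tables** — per sample × protein, detection is Bernoulli per group;
  detected proteins draw their accepted-quality spectral count from a
  negative binomial (the standard overdispersed model for spectral counts;
  the source workflow states no generative model) with mean
  `mean_sc[group] × fold` (fold applied to the SCI-negative group, so the
  planted SC ratio equals the fold when group means are equal), dispersion
  default 5. About `fail_fraction` extra rows violate exactly one
  acceptance rule each; SCD-only accessions are never emitted for controls.
* **Compendium** — planted brain genes satisfy all three criteria,
  designated "partial" genes satisfy exactly the listed sources,
  everything else satisfies none.
* **Assay plates** — subject concentrations are log-normal around the
  planted group median (0.28 ng/mL SCD, 0.12 control, i.e. the reported
  verification medians) with log-scale spread defaults of 1.3 (SCD) and
  0.35 (control), mirroring the wide and narrow reported IQRs; visit-level
  jitter is 10% on the log scale; duplicate signals perturb the known 4PL
  response at the configured CV (default 5%); optional fractions are
  planted in the LOD–LLOQ window or below LOD.

Every generator is a pure function of its arguments: identical seeds give
byte-identical files. What the synthetic data do **not** model: raw
spectra, chromatography or search-engine score covariance; shared peptides
between proteins (each accession has its own peptide pool); plate-position
effects or inter-plate drift; longitudinal trends in analyte concentration.
Passing recovery tests therefore demonstrates the correctness of the
statistical pipeline under its stated assumptions, not robustness to those
real-data complications.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale: reference-table
re-computations are instantaneous; planted-cluster recovery uses 10–15
sequences of 30–200 residues; fold-recovery and verification Monte-Carlos
use 200 replicates (8 vs 8 samples for spectral counts; 100 vs 25 subjects
for the assay stage), sizes at which the Monte-Carlo means are stable to
well under the asserted tolerances. 4PL fitting initialises asymptotes from
the observed signal extremes, the inflection from the median standard
concentration and slope 1, which converges on all tested inputs; the
back-calculation round trip is exact to 1e-9 relative. Ratio rounding uses
decimal half-up (not banker's rounding) throughout reporting.

## Known limitations

* The reference proteome lists (1172 proteins, 524 brain-enriched genes)
  cannot be regenerated — they depend on unavailable raw data and retired
  public databases; only their construction rules are implemented.
* The fold-change screen has no significance model; at 7–8 samples per
  group, null proteins pass occasionally by sampling noise (visible in
  end-to-end runs on synthetic bundles). This reproduces the screening
  rule as specified rather than improving on it.
* Isoform-level curation (peptides unique to a specific isoform) and
  pathway-network analysis are manual/proprietary steps and are out of
  scope.
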