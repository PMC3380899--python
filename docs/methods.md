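# Methods

## Mass chemistry

All masses are monoisotopic. Residue masses come from the standard table
(`pyteomics.mass.std_aa_mass`); water is 18.010565 Da and the proton
1.00728 Da, so `[M+H]+ = Σ residues + water + Σ modification deltas +
1.00728` and `m/z(z) = (M + z·1.00728)/z`. The modification registry
carries exactly the workflow's set — GG +114.0429, methyl +14.0156,
dimethyl +28.0313, Met oxidation +15.9949, SILAC Lys8 +8.01420 and Arg10
+10.00827 — plus `dialkyl` (+114.0429 on K), the iodoacetamide-derived
pseudo-GG adduct that is mass-identical to the true ubiquitin remnant and
underlies the external-reference validation strategy.

Shipped reference masses reproduce within one unit in the fourth decimal
for the dialkylated standards and within 2×10⁻⁴ Da for the methylation-site
rows; the printed sources mix rounding and truncation, so tests compare at
those bands rather than digit equality.

Trypsin cleaves after K/R but not before P. The proline exception is the
standard convention; the original search's behavior on this point is not
documented, and the choice does not affect any shipped reference value. A
K/R carrying a cleavage-blocking modification (GG, dialkyl, dimethyl) never
terminates a peptide and does not consume the missed-cleavage budget —
this is what makes the K145 site observable on the spanning peptide
TGHSKGFGFVR. `trypticity="partial"` requires one tryptic terminus;
digestion is validated against an independent substring enumerator.

Inclusion-list centers sit 0.50 m/z above the monoisotopic 2+ m/z with a
1.7 m/z window, reverse-engineered from the published method centers (four
of six match exactly at 2 dp, two differ by 0.01–0.02, hence the ±0.03
validation band). Peptides are taken in the order given (elution order);
retention prediction is out of scope.

## Target-decoy filtering

The FDR estimator is `2·nd/nt` (decoy matches double-counted to stand in
for false target matches), 0 on empty input. PSMs are grouped by
trypticity (full/partial) × charge (2+, 3+, 4+); other charges go to a
logged reject bin. Each group is gated at |Δm| ≤ 15 ppm and then searched
on a threshold grid — Xcorr from 1.0 in steps of 0.1, ΔCn from 0.05 in
steps of 0.01 — for the pair maximizing accepted target PSMs subject to a
working FDR, with deterministic tie-breaks (lower Xcorr, then lower ΔCn).
"Protein FDR" is operationalized as `2·(all-decoy families)/(families)`
after protein-family grouping (proteins sharing any accepted peptide are
merged transitively). If the protein-level FDR exceeds the 1% target, the
working per-group rate is halved and the search repeats (up to 20 rounds);
an infeasible input yields an empty acceptance with a diagnostic, never an
exception. Families supported by a single distinct peptide are flagged in
the report — the automated stand-in for manual spectrum inspection.

## SILAC quantification and significance

The protein-level statistic is the median of peptide log2(light/heavy)
across peptides and gel regions (robust to outlier peptides; the original
software's rollup rule is unpublished). Records with a nonpositive channel
are rejected and counted. Differences between conditions are formed within
replicate and averaged across the two replicates, then recentered by
subtracting the population means (reported in the run log). Cutoffs are
`1.64 × sample SD` of the recentered differences — the one-tailed 95%
normal quantile — computed only from proteins quantified in all three
conditions in both replicates; other proteins keep partial calls.

Classification: group 1 if both mock-relative differences exceed their
cutoffs with the same sign; group 2 if only the S6−Mock difference does;
group 3 if only the 43−Mock difference; the "lost in TDP-S6" mark uses the
signed one-tailed condition `Δlog2(S6−43) < −cutoff` and attaches in
addition to groups 1–3 (mirroring the dual marking of the source table).
Direction follows the sign of the triggering difference. Fold changes are
`2^Δ`, presentation-rounded to integers at ≥ 2. The triple-map y-axis
defaults to the recentered S6−43 difference and is configurable to
S6−Mock; the choice is recorded in output metadata because the original
figure's axis annotation is ambiguous.

## PTM stoichiometry

For each modification site: `ratio_cond = light/heavy`,
`unnorm%(cond) = 100·ratio_cond/ratio_mock`, and
`norm%(cond) = 100·unnorm%/unmodified%(cond)` where the unmodified percent
is `100·2^Δ` from the protein rollup over **unmodified** peptides only (all
accepted unmodified peptides, replicate-averaged — the exact peptide set
behind the published unmodified percentages is not specified, so this is
configurable in principle and documented here as the default). Reporting is
at 3 significant figures with full precision retained internally. Site
labels are 1-based on the protein sequence (K145-GG, R291-Me2); a peptide
with two modified residues yields two site records sharing the PSM. GG
sites are labeled generically: NEDD8/ISG15 leave the same remnant, and the
ubiquitin interpretation is metadata, not computation.

## Targeted quantification

A scan contributes only if **every** required fragment has a peak within
±0.5 m/z (ion-trap MS/MS tolerance); each fragment takes its closest peak
and the matched intensities are summed. The sum is multiplied by
`150 ms/(ion inject time)` to cancel automatic gain control; of a
peptide/sample's passing scans the apex (maximum corrected) intensity is
kept. Reference peptides are quantified from precursor XIC traces (not
subject to AGC) as the apex within the elution window; peak area is a
possible alternative the implementation does not default to. For each
reference × replicate, the normalized ratio is
`(target/ref)_exp / (target/ref)_ctl`; the summary is the mean log2 over
those k values with `ci95 = t₀.₉₇₅,k₋₁·SD/√k` (a normal-quantile mode is
available; whether the published interval spans replicates only or
replicates × normalizers is not stated, so both are supported and the
t-based replicates × references form is the default). Percent change is
`100·(2^mean − 1)`.

## Synthetic experiments

The generator emulates the study design: three transfection conditions
(mock, TDP-43, TDP-S6) × heavy internal standard × two replicates over a
default 585-protein population. Null log2 differences are drawn from a
correlated bivariate Gaussian with SDs 0.55/0.54 and difference-SD 0.40
(matching the population widths implied by the published cutoffs); 35 up
and 6 down spiked changers replace their null draw with an effect drawn
uniformly from 1.2–3.0 log2 units, split among both/S6-only/43-only
patterns — sized like the reported changers, truncated at the low end so
the planted truth is in principle recoverable. Peptides are real tryptic
peptides of the generated proteome (human-like residue frequencies, ≥3
fully tryptic peptides per protein), with log-normal base intensities,
peptide-level ratio noise of 0.35 log2 units, and a 1% missing-channel
rate. PSM scores follow separate target and decoy distributions with a 1%
planted false-target rate; decoy entries use reversed peptides under
`REV_` identifiers. PTM sites are placed by digesting with the
modification applied (so blocking is honored) and the heavy standard
carries mock stoichiometry. Targeted scans obey
`inject = min(150 ms, C/flux)` and per-sample loading factors that must
cancel under reference normalization. Everything is driven by one seeded
generator and recorded in `truth.json`.

What the generator does **not** emulate: chromatographic drift and
retention time, isotope envelopes and interference, ratio compression,
shared/degenerate peptides across homologous proteins, and
intensity-dependent missingness. Passing tests therefore demonstrate the
statistics and bookkeeping on idealized inputs, not robustness to every
artifact of real LC-MS/MS data.

## Problem sizes and numerics

The default simulated experiment (585 proteins, ~8 peptides/protein, 2
replicates, 3 conditions) runs end to end in a few seconds; repeated-seed
calibration checks use 12–60-protein configurations and 20 seeds. Reported
percentages and ratios use 3 significant figures; masses 4 decimals;
internal computation is double precision throughout. Degenerate inputs are
defined: empty acceptance for infeasible FDR targets, `None` for
non-quantifiable ratios or absent fragments, explicit partial significance
calls when a comparison is missing.

## Known limitations

Xcorr/ΔCn are consumed, never computed; no spectrum-level site
localization scores; no mzML/RAW parsing (documented TSV dialects
instead); the headline biological counts of the original study depend on
unreleased raw data and are emulated structurally, not asserted
numerically.
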