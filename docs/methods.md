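# Methods

This note documents the models, numerical choices, and open design
decisions behind `isopull`, at the level of detail a maintainer needs to
judge whether a result can be trusted and where the model ends and the
data begins.

## Experimental design model

The unit of analysis is a *run*: one mixed light/heavy sample measured
once. A full design crosses growth conditions × crosslinker (FA) levels ×
three sample types (`WT_WT`, `BAIT_WT`, `BAIT_BAIT`) × biological
replicates; the light and heavy pellets of a sample always share a
replicate index. The canonical layout (2 × 2 × 3 × 4 = 48 runs) is what
`enumerate_samples` produces with both conditions and both FA levels. The
FA level is metadata only — nothing in the statistics depends on it
beyond stratification. A label-swap flag exists for reciprocal designs
but defaults to off: when channels are mixed before purification, both
isotopologues see identical handling and a swap doubles instrument time
without improving accuracy.

## Ratio normalization

Ratios are ingested in the search engine's H/L orientation and inverted
once (`ratio_lh = 1/ratio_hl`), keeping the light channel — the channel
carrying the tagged strain in the experiment mix — in the numerator.
Non-finite or non-positive ratios never enter the pipeline; ingest
rejects and counts them. The idealized "infinite" ratio of a bait peptide
absent from the heavy channel is represented in data (and in the
simulator) as a large finite ratio produced by a heavy-channel noise
floor.

Each run is normalized by a median over a QC set, in three steps:

1. a **provisional factor**: the median L/H over peptides passing the
   identification q-value filter alone;
2. an **ion-CV screen** on the provisionally centered ratios: for each
   peptide ion, the coefficient of variation (sample sd / mean, n−1
   denominator) across the biological replicates of one
   (sample type, condition, FA) stratum; ions with CV ≥ the threshold, or
   with fewer than two observations, leave the QC set;
3. the **final factor**: the provisional factor times the median of
   centered ratios over the surviving QC set.

Step 1 exists because a CV computed on *raw* ratios couples the screen to
the run-level mixing errors: it preferentially keeps ions whose noise
happens to cancel the mixing differences between replicates, and a median
over that selection is biased toward 1 rather than toward the run's true
mixing factor. Centering first makes the screen's selection independent
of the run effects. The construction also makes the post-normalization
median over the QC set equal 1 exactly (up to one floating rounding), and
on simulated data with mixing errors of log2 sd 0.2 the injected factors
are recovered within about 1% from ≳2000 background ions per run.

Normalization divides *every* row, including QC failures — QC status is
carried as a flag, never by deletion, so downstream filters remain
auditable. Medians of even-sized sets are the mean of the central pair.
Re-normalizing already-normalized data yields factors of 1 up to QC-set
membership churn at the CV boundary (exactly 1 when no ion sits on the
threshold).

## Stringent filters

Defaults: control-deviation fold 2, q ≤ 0.01, ion CV < 0.2, completeness
1.0 (all replicates), coverage > 40%, ≥ 2 distinct peptides. Boundary
conventions follow each parameter's description — CV "must be smaller"
and coverage "must be greater" are strict; the q cutoff and the peptide
count minimum are inclusive; the control-fold rule is strict. These
conventions matter at the tuning grid: a bait with ion CV 0.28 and
coverage exactly 35% tunes to (0.3, 30), not (0.3, 35).

The ion filters (q, CV on the normalized ratio) are conjunctive, so
application order cannot change the survivor set. The **control
consistency filter** marks a peptide ion untrusted when any confidently
identified observation of it in a control sample type deviates from 1 by
more than the fold cutoff on the log scale; the verdict is global per
ion but is consumed only by the experiment (`BAIT_WT`) aggregation.
Control sample types aggregate without it, deliberately: the classifier's
exclusion logic needs the control-enrichment evidence that this filter
would otherwise delete, and a control channel cannot be both the
detector of an artifact and the eraser of its signal.

Protein-level rules per (protein, sample type, condition, FA): detected
(≥ 1 surviving peptide observation) in at least
⌈completeness × n_replicates⌉ replicates; ≥ the minimum number of
distinct surviving peptide sequences; sequence coverage above the
threshold. Coverage is an identification property and is computed from
the q-passing peptides of the stratum — exact substring matching against
the FASTA entry, all occurrences, unioned residue positions, I/L kept
distinct, integer-first arithmetic (`covered·100/length`) so that e.g.
70/200 residues is exactly 35.0. A report-supplied coverage column can be
trusted instead via configuration.

**Filter tuning** walks (coverage, CV) threshold pairs from most to least
stringent — coverage descending in the outer loop, CV ascending inside,
so coverage stringency is surrendered last — and returns the first pair
under which the bait passes every filter in all `BAIT_WT` replicates,
with a trace of every pair tried and the failing filter. Grid points are
evaluated at fixed normalization (computed once under the initial
parameters); re-normalizing per grid point would couple the QC set to the
candidate CV threshold for a negligible change in factors.

## Aggregation and moderated statistics

Protein ratio per run = median over all surviving peptide observations
(duplicate rows of one sequence each contribute; the distinct-sequence
count is reported separately), then log2. No imputation: proteins missing
from a replicate after the completeness filter simply never reach the
test.

The one-sample moderated t-test and its empirical-Bayes variance prior
are as described in the README. Numerical details:

* The prior fit solves ψ′(d₀/2) = var(e) − mean(ψ′(dᵍ/2)) by Brent root
  finding on the bracket [10⁻³, 10⁷] with xtol 10⁻¹⁰ (ψ′ is monotone, so
  the root is unique); s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)). When the
  observed log-variance dispersion does not exceed sampling noise, d₀ is
  set to the cap 10⁶ ("effectively infinite shrinkage"). The fit matches
  Bioconductor limma's `squeezeVar` to ~10⁻¹² relative on shared inputs
  (cross-checked in the test suite via Rscript).
* Zero sample variances carry no log-scale information and are set aside
  by the fit; a fully degenerate input (fewer than two positive
  variances) falls back to (d₀ = cap, s₀² = 0), under which noiseless
  data produce t = 0, p = 1 at zero means and |t| = ∞, p = 0 otherwise —
  the correct limits for exact data.
* One joint prior is fitted per (condition, FA) analysis with residual
  variances pooled across all three sample-type groups (each group
  contributes its own dᵍ = n−1), mirroring a single linear-model fit with
  one coefficient per group; a per-group fit is available behind a flag.
* BH correction is applied within each sample type's p-value vector —
  each volcano panel is its own multiplicity universe. The step-up is
  implemented directly from its definition (sorted cumulative minimum of
  p·m/rank, capped at 1).
* Two-sided p-values; directionality enters through the fold threshold
  on positive enrichment. Significance = adj. p ≤ α (default 0.001) and
  linear fold ≥ 2.

The two-condition contrast uses the difference of group means with a
pooled moderated variance, s²_post = (d₀s₀² + d_A s²_A + d_B s²_B) /
(d₀ + d_A + d_B), the prior refit on the combined variance set, df =
d₀ + d_A + d_B, and BH within the contrast vector; proteins present in
one condition only are flagged, not tested.

## Interactor classification

Decision table over the union of proteins in the three result tables,
first match wins: configured bait → `bait`; significantly enriched in
`WT_WT` → `excluded_wt_control`; in `BAIT_BAIT` → `excluded_bait_control`;
in `BAIT_WT` → `candidate`; otherwise `not_significant`. "Significantly
enriched in a control" reuses the experiment's own significance rule
(optionally with a separate control α) — the sources describe the
control exclusions visually, so a symmetric quantitative rule is this
package's determinization. Detection in a control at ratio ≈ 1 (the
signature of nonspecific binders such as biotinylated carboxylases) never
excludes. Control exclusion is checked before candidate status so that a
protein enriched everywhere is reported as a control problem, not a hit.

## The simulator

`simulate_experiment` generates, per run, observed log2 L/H =
true log2 fold (protein, sample type, condition) + run mixing error +
N(0, peptide noise sd), stored as H/L. Structure (sequences, peptides)
comes from one stream keyed on the seed; each run draws from its own
stream keyed on (seed, sample id), so extending a design never perturbs
existing runs and a fixed seed reproduces files byte for byte.

What it emulates: background at ratio 1 everywhere; a bait (default
256-fold) and interactors (defaults at 38/37/22/5.2/3.5/2.4-fold, the
tier spectrum of a polymerase-subunit pull-down) enriched only in
`BAIT_WT` and absent from `WT_WT` entirely (the untagged strain purifies
no bait); always-detected nonspecific binders at ratio 1; control decoys
enriched in the experiment *and* one designated control — the profile
the exclusion logic must catch; per-ion i.i.d. missingness (default 5%);
a fraction of observations drawn above the q cutoff (default 2%);
log-normal peptide noise (default log2 sd 0.3) and shared per-run mixing
error (default log2 sd 0.2). Emitted FASTA sequences embed the simulated
peptides as true substrings at recorded positions; protein length is set
by peptide content over a target coverage drawn in 45–75% (typical for
detected proteins in DIA), within configurable bounds, so simulated
proteins clear the default coverage filter and filter tests probe what
they intend to.

What it does not emulate: spectra, retention time, interference,
crosslink chemistry, incomplete ¹⁵N incorporation (idealized to 100%;
real labeling reaches >98%), intensity-dependent noise, correlated
missingness, or shared-peptide ambiguity. Passing tests therefore
demonstrate the statistical pipeline's correctness under its own model
assumptions, not robustness to every instrument artifact.

Default noise magnitudes are calibration choices: no published values
exist for them, and they were fixed once at levels that make the ion-CV
filter genuinely binding (log2 sd 0.3 implies a linear ion CV ≈ 0.21
against the 0.2 threshold — the regime in which real analyses end up
relaxing the CV threshold to 0.3 for the bait's sake).

## Isotope mass arithmetic

Per-residue nitrogen counts cover exactly the 20 canonical residues
(K/Q/N/W = 2, H = 3, R = 4, the rest 1, backbone amide included). The
heavy-channel shift uses the exact ¹⁵N–¹⁴N mass difference 0.9970349 Da
per nitrogen; the "integer 1 Da per nitrogen" picture is an approximation
that holds to < 0.2 Da over a 38-nitrogen peptide and is verified as a
property, not hard-coded. Heavy m/z = light m/z + shift/charge (the
proton count is channel-invariant). Fragment-ion channels and
partial-labeling envelopes are out of scope.

## Problem sizes used by the acceptance script

Simulations are sized to be decisive yet quick: 150 background proteins
(~2300 ions) for normalization recovery; 5000 variance draws for prior
recovery; 2000 proteins for the null false-positive rate; 200 planted
interactors against 1800 background per enrichment tier; 10 control
decoys. The full script completes in well under a minute on one CPU.

## Known limitations

* Peptide-to-protein assignment is taken from the report as-is; shared
  peptides are counted for every protein that claims them.
* The q-value column is treated as ion-level confidence; whether a
  vendor export provides precursor- or protein-level q-values must be
  resolved by the user's column mapping.
* Exclusion verdicts are binary; no CRAPome-style frequency scoring.
* `compare_conditions` assumes both analyses used identical filter
  parameters; it does not re-harmonize them.
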