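# Methods

`mscarray` implements the computational arm of a paired study design that
asks whether heparin, added as an anticoagulant during bone-marrow sampling,
changes the transcriptome or in-vitro phenotype of the mesenchymal stromal
cells (MSCs) later isolated from that marrow.  Each donor's marrow is split
into aliquots processed with and without heparin, so every comparison is a
matched pair within one donor; the readouts are one-color microarray
expression, confirmatory qRT-PCR, and culture metrics (doubling times,
GAG/DNA, mineralization).

## Microarray processing model

**Replicate aggregation.**  Each probe is printed five times on the array.
The replicate population is collapsed to the geometric mean of its
processed green-channel signals (gPS) after excluding features that (i) are
manually flagged, (ii) are flagged as outliers by the extraction software,
(iii) lie outside `median ± 1.42 × IQR` of the probe's replicate signal
population, or (iv) have a pixel-intensity CV above 0.5.  The rules form an
independent union; a feature can trip several and counts in each tally.
Numerical choices for rule iii: the interval is centred on the population
median, computed on the raw replicate signals with linear-interpolation
quantiles (the numpy/R default), and boundary values are kept (exclusion is
strictly outside).  A surviving replicate with signal exactly zero cannot
enter a geometric mean; it is dropped with a warning, and if nothing
survives the probe is reported missing.  One surviving replicate suffices
for a value (`min_surviving_replicates = 1`).

**Global linear scaling.**  Every aggregated array is multiplied by
`1500 / p75(array)`, pinning the 75th percentile of its non-control,
non-missing values to a series-wide reference of 1500 signal units.  The
percentile is computed after removing probes that aggregated to missing.

**Surrogate floor.**  Normalized values below 15 units — the platform's
reliable detection limit, set from the negative-control intensity
distribution — are replaced by 15.  Flooring is idempotent and always
applied after scaling, never before; an optional recalibration mode
(the 95th percentile of scaled negative controls) exists but the fixed
published value is the default.

**Paired fold-change screen.**  Per donor, fold change = heparin sample /
no-heparin sample on floored values.  A gene is called up-regulated when
every one of its probes satisfies: (1) at least two pairs at or above
2-fold (inclusive); (2) if a pair falls short of 2-fold, it must still
change in the same direction (ratio > 1) and the geometric mean of all
pairs' ratios must then exceed 2 strictly — when every pair clears 2-fold
on its own, no geometric-mean condition applies; (3) the heparin-side
normalized signal exceeds 100 units in every pair, which suppresses calls
near the detection limit.  Down-regulation mirrors this (ratios ≤ 0.5,
geometric mean < 0.5, the 100-unit floor applied to the no-heparin side).
The differing boundary semantics (inclusive per-pair, strict geometric
mean) reflect "at least twofold" versus "more than twofold".  For genes
with several probes, all probes must pass, and the reported per-pair fold
changes come from the probe with the highest mean normalized signal across
all samples.  A gene with a missing probe value in any pair is rejected as
`incomplete` rather than judged on the remaining pairs.  The intensity
criterion is enforced per pair (each counted pair must clear 100); an
averaged reading would be laxer and is not offered as a default.
The screen is deliberately fold-change/intensity based: no p-values or
multiple-testing machinery, matching the confirmatory-qPCR workflow it
feeds.

**qPCR concordance.**  Duplicate CTs are averaged on the cycle scale
(not on linearized expression), then `ΔCT = CT(gene) − CT(RPS29)` and
relative expression `2^−ΔCT`.  A twofold expression ratio between
conditions — inclusive, either direction — is called "regulated".  The
concordance table compares, per donor × gene, the twofold call on the
microarray fold change with the twofold qPCR call; the summary is the
fraction of assessable cells that agree.  Undetermined CTs (no
amplification) make a cell "not assessable" and it is excluded from the
fraction, as are genes present in only one assay.

## Culture metrics

Population doubling time assumes exponential growth between passages:
`PDT = Δt · ln 2 / ln(N₂/N₁)` (hours).  Cultures with `N₂ ≤ N₁` raise a
no-net-growth signal instead of returning a number.  GAG/DNA is a plain
ratio of calibrated masses (linear signal→mass calibrations, identity by
default).  Mineralization is called when calcium *and* phosphate both
strictly exceed 1 mM.  Marker summaries use arithmetic means with sample
(n−1) standard deviations; a single-donor group has no SD.

## Synthetic-study generator

The generator is first-class, tested code: it defines the conditions every
recovery claim is made under.

* **Expression.**  Gene baselines are log-normal (`baseline_log_mean =
  ln 500`, `baseline_log_sd = 1.0`), shared across donors; each donor
  applies a gene-wise multiplicative jitter (log-SD 0.1) identical across
  that donor's conditions, so it cancels in paired fold changes.  This
  reproduces the >100-fold intensity spread of real arrays without
  asserting any particular biological distribution.  10% of genes are drawn
  near the detection limit (around 1/300 of the typical signal), emulating
  the large background fraction of a whole-genome array and guaranteeing
  the surrogate floor has work.
* **Effects.**  Regulated genes multiply their baseline by the configured
  fold (up) or its reciprocal (down) in non-baseline conditions; a
  regulated gene's baseline can be pinned so that effects sit well clear of
  the intensity floor and of the scaling percentile.
* **Noise.**  Replicates get multiplicative log-normal noise with CV 0.05
  (log-sigma `√ln(1+cv²)`, median-unbiased so geometric means are
  recovered).  The published study reports no noise magnitudes; 5% is a
  plausible within-array replicate CV chosen for testability.
* **Contamination.**  Single replicates receive 50–200× spikes at rate
  0.01; 90% of spikes carry the software-outlier flag (extraction software
  catches most gross artifacts), the unflagged residue being exactly what
  the IQR rule exists for.  Manual and (independent) software flags appear
  at rate 0.005 with values distorted 0.1–10×, so ignoring the flags would
  corrupt results.  Pixel CVs above the 0.5 cap appear at rate 0.01, also
  with distorted values.  Negative controls are drawn around 1/500 of the
  typical signal, far below the floor after scaling.
* **Matched assays.**  qPCR CTs are generated from the same true
  expression (`CT = 20 − log₂(e/1000)` plus 0.2 cycles of noise per
  replicate, housekeeping constant at 20), so `2^−ΔCT` reproduces true
  relative expression.  Growth records follow exact exponential curves
  with doubling times drawn in 40–80 h over 72–144 h intervals; assay
  records carry their own ground-truth ratios and mineralization classes.
* **Streams.**  One RNG stream per donor × condition (plus separate
  streams for baselines, jitter, qPCR, growth, assays) derived from the
  master seed, so enlarging a study never perturbs existing samples, and a
  fixed seed reproduces byte-identical tables.

**What the generator does not emulate:** probe-sequence and dye effects,
spatial artifacts, background subtraction, cross-hybridization, donor
biology beyond a scalar jitter, and any correlation structure between
genes.  Passing recovery tests therefore demonstrates that the pipeline's
logic is correct under its stated assumptions, not that the thresholds are
optimal for real arrays.

## Verification scale and determinism

The test suite checks exact identities at zero noise (replicate values,
fold changes, concordance 1.0), hand-computed examples for every closed
form, equivalence of the screen with a brute-force criterion-by-criterion
oracle on 200 random instances of up to 200 genes × 3 pairs, and full
recovery (all ten 4-fold spikes, zero false calls) on twenty independent
1000-gene studies at default noise — sizes chosen to exercise every rule
while keeping the whole suite around a minute.  Property tests
(hypothesis) are derandomized.  `scripts/acceptance.py` re-runs the
1000-gene spiked study end-to-end from a command-line seed and reports the
normalized 75th percentile, the floored matrix minimum, spike recovery and
false-call counts, the qPCR concordance fraction, and two closed forms.

## Known limitations

* The deposited-series reproduction route (`geo-reproduce`) is exercised
  against series-matrix files written by this package; running it on the
  actual deposited study requires downloading that series matrix and
  supplying the donor/condition sample mapping.
* Rule iii has a ~40% breakdown point (two coincident gross spikes in a
  quintuplicate can shield each other); the software-outlier flag is the
  realistic first line of defence against such features.
* The PDT formula assumes a single exponential phase between the two
  passages; lag or plateau phases bias it upward.
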