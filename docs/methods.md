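# Methods

## Quantification model

A stable-isotope-dilution MRM measurement of one peptide in one replicate
consists of ≥2 transitions recorded for both the endogenous (light) peptide
and the spiked heavy-labeled internal standard. The pipeline:

1. **Interference screen.** A transition is trusted only when the light and
   heavy signals agree in retention time and in within-label fragment-area
   proportion. For each fragment shared between labels we compute
   `rt_delta = |RT_light − RT_heavy|` and
   `prop_delta = |p_light − p_heavy|`, where `p` is the fragment's share of
   the summed area within its label. A fragment is flagged interfered when
   either delta exceeds its tolerance. Defaults: 0.2 min and 0.20
   (absolute). The agreement criterion is fixed; the numeric tolerances
   are configurable and recorded in run metadata, because chromatographic
   peak widths and fragment count vary by platform. If fewer than two
   clean shared transitions remain, the measurement is marked
   unquantifiable (with reason), never silently dropped or zeroed.
2. **Summation.** Total intensity per label =
   Σ over clean transitions of (peak area + background). The background
   term is added once per transition. Whether an exported "total area"
   column already folds in background varies by report template; this
   package always sums the two explicit columns, and the reader maps
   dialect aliases onto them.
3. **Ratio.** PAR = light/heavy by default; heavy/light for response
   curves, where the spiked heavy amount is the independent variable. The
   two orientations are exact reciprocals. A zero or missing denominator
   yields a missing PAR with a reason code — zeros would corrupt every CV
   and regression downstream, so absence of signal always propagates as
   missing.
4. **Amount inference.** Endogenous amount (fmol) =
   PAR(light/heavy) × spiked heavy fmol, with the spike amount taken from
   the sample annotations (200 fmol/sample in all default designs).
5. **LLOQ filter.** Measurements are retained only when the inferred
   amount is *strictly* greater than the peptide's LLOQ in that matrix.
   Peptides without a characterized LLOQ are dropped conservatively, with
   a warning.

## Response curves

Design: heavy standard spiked at 2000, 200, 20, 8, 3.2, 1.28, 0.512,
0.205 fmol into background matrix (light peptide constant at 200 fmol),
process triplicate per level plus triplicate blanks.

- **Fit**: ordinary least squares of log2(mean PAR) on log2(fmol) over the
  points in the quantifiable range; slope, intercept, Pearson r and R² are
  all reported.
- **LLOQ**: scan from the lowest concentration upward; accept the first
  point whose triplicate CV < 20% while (a) the fit over all points at and
  above it keeps linear correlation ≥ 0.98 and (b) every higher point also
  keeps CV < 20%. The published rule names a "linear correlation
  coefficient" without specifying r or R²; we default to Pearson r and
  expose `use_r_squared`. "Maintained" precision is read as a property of
  the whole region above the LLOQ (strict mode, default); a
  single-point mode is available. The LLOQ is by construction always one
  of the designed concentrations.
- **ULOQ**: starting from all points ≥ LLOQ, the top point is dropped
  while the fit that includes it fails R² ≥ 0.98 or its studentized
  residual exceeds 3. When the curve stays linear to the top of the
  design, the ULOQ equals the highest designed concentration and is
  flagged a minimum estimate — the true upper limit was not reached.
- **Dynamic range** = log10(ULOQ/LLOQ).
- **Blanks** never enter the curve; they yield a mean + 3·sd
  limit-of-detection diagnostic reported alongside.

## Precision, stability, validation calls

CVs use the sample (n−1) standard deviation and are computed on the
untransformed PAR (log2 is reserved for comparative statistics): intra =
unweighted mean over days of the within-day %CV; inter = %CV of the
per-day means. Days with <2 usable replicates are skipped with a warning.
When every replicate value is bitwise identical the CV is returned as
exactly 0 rather than the ~1e−14 residue that floating-point mean/std of
identical values can produce.

Stability = 100·(mean stored − mean fresh)/mean fresh over process
triplicates, for 24 h autosampler storage and 2× freeze–thaw.

A peptide fails validation in a matrix when ≥2 (spike level ×
intra/inter) conditions exceed 20% CV ("multiple" read as at least two;
configurable); exactly one exceedance is a pass-with-flag, and reasons
always enumerate the offending conditions.

## Sequential enrichment

Per panel and enrichment position, triplicate medians of light area, heavy
area and PAR are computed for peptides above the LLOQ (sub-LLOQ peptides
drop out pairwise, not listwise). Concordance is Pearson correlation of
log10 medians between position pairs: areas span orders of magnitude, so
log scale is appropriate, and a uniform depletion between positions then
shifts the intercept without touching r. Spearman and linear-scale options
exist; the choice is recorded in output metadata.

## Detection profiling and minimum input

Detection: per peptide, the number of cohort samples whose inferred amount
exceeds the LLOQ, plus the panel histogram of peptides by detecting-sample
count.

Minimum input: with r_i = log2(amount_i/LLOQ) over the samples of one
tissue site, the one-sided 95% lower bound of the mean is
`lb = mean(r) − t_{0.95, n−1}·sd(r)/√n`. The analyte is confidently above
the LLOQ when lb > 0, and linear-scale dilution gives
`min_input = 500 µg / 2^lb` — the input at which the confident lower
bound lands exactly on the LLOQ. The reported CI maps the two-sided
t-interval on the mean through the same relation. The test is performed on
the log2 ratio so the null (at LLOQ) is 0 and lognormal-like abundance
noise is symmetric; a linear-scale alternative is a documented
convention, not a claim about the original analysis. Sites with n = 1
yield no result. Predicted-detection counts at an input grid (default 10,
50, 200, 500 µg) count analytes with min_input ≤ m; the CI brackets the
count using the analytes whose interval straddles m. Counts are monotone
in input mass by construction.

## Peptide selection

Fully tryptic digestion cleaves after K/R except before P, with zero
missed cleavages; the peptides tile the protein exactly. Hard exclusions:
non-uniqueness (exact substring over the proteome; Ile/Leu kept
distinct), NG/NP motifs (deamidation), N-terminal Q (pyroglutamate),
protein N-terminal peptide, length outside 5–30, hydrophobicity outside
10–40, overlap with a variant at MAF > 1% (strictly greater), and
annotated frequent PTM sites. Deprioritizations (rank penalties, never
exclusions): Cys, Met, ragged ends (a second K/R immediately inside either
cleavage boundary), protein C-terminal peptide. Ranking: observation count
desc, median intensity desc, deprioritization count asc, sequence asc as
the deterministic tiebreak. The composite ordering is this package's
declared convention — published selection guidelines rank by observation
frequency and intensity without giving weights.

The hydrophobicity index is an additive sequence-specific retention model
on the 100 Å/TFA C18 scale (Krokhin-style coefficients):
`H = KL·[Σ RC(aa_i) + Σ_{j≤3} w_j·(RC_NT(aa_j) − RC(aa_j))]` with
N-terminal attenuation weights (0.42, 0.22, 0.05), length scaling
`KL = 1 − 0.055·(10−N)` for N < 10 and `KL = 1/(1 + 0.027·(N−20))` for
N > 20, and 30% compression of the scale above 38. The residue coefficient
column is the published 100 Å TFA scale; the N-terminal column is an
approximation packaged as a versioned data module
(`iomrm._ssrcalc_data`, version `100A-tfa-v1`) so a recalibrated table can
be swapped in without code changes. The 10–40 selection window applies to
this scale.

## Synthetic-data generator

The generator emulates the characterization designs, not raw
chromatography. For one measurement of peptide p:

- expected label intensity = response_factor_p × amount × process effect,
  the process effect being lognormal (σ_process, log2 domain) and shared
  by light and heavy within a replicate — the internal standard is added
  before digestion, so processing variation cancels in the PAR;
- the PAR itself carries a between-day lognormal effect (σ_inter) and a
  within-day replicate effect (σ_intra), applied to the light label;
- the label intensity splits across transitions by fixed per-peptide
  Dirichlet proportions; each transition gets additive detector noise
  N(0, noise_floor) truncated at 0 and a small positive background;
- an interfered transition receives a co-eluting contaminant (extra area,
  +0.5 min apparent RT) in the light label only;
- sub-threshold intensities are emitted as missing when dropout is
  enabled (off by default so design row counts are exact).

Defaults (chosen once, as the package's standing study conditions):

| parameter | default | rationale |
|---|---|---|
| panel_size | 43 peptides | panel scale of the characterized assay |
| transitions/peptide | 3 | ≥2 required; 3 is typical |
| σ_intra | 0.072 log2 (~5% CV) | within-day precision regime of a well-behaved immuno-MRM panel |
| σ_inter | 0.058 log2 (~4%) | between-day component; day-mean CV ≈ 5% |
| σ_process | 0.25 log2 (~19%) | complete-process replicate variation; cancels in the PAR |
| noise_floor | 110 counts (tissue), ×0.45 plasma | places the CV=20% crossing mid-dilution-series for a median-response peptide |
| response factor | median 2000 counts/fmol, log2 sd 2.0 | MRM responses span orders of magnitude between peptides |
| endogenous tissue | median 30 fmol/500 µg, log2 sd 2.2 | most analytes detectable, a tail near the LLOQ |
| endogenous plasma | median 0.2 fmol/100 µL, log2 sd 3.0 | circulating levels of tissue-selected targets: roughly half the panel effectively absent |
| stability shift | −3% median, 5% log2 sd | small storage losses |
| heavy spike | 200 fmol/sample | standard spike level of the designs |

The `expected_lloq` ground truth is the smallest designed level whose
predicted PAR CV — √(CV_mult² + Σ_labels (noise_floor·√k/(rf·amount))²),
with CV_mult the multiplicative CV implied by σ_intra and k the transition
count — is below 20%. Parameter-recovery tests check that the pipeline's
detected LLOQ lands within one dilution step of this truth for ≥90% of
peptides across 100 seeds, that estimated intra/inter CVs recover the
configured components within 25% relative (the mean-of-day-CVs estimator
carries the usual small-n sample-sd bias, c₄(3) ≈ 0.89, well inside that
band), and that slope ≈ 1 on proportional response.

**What the generator does not emulate** — and hence what green tests do
not certify on real data: chromatographic peak-shape and integration
quality, matrix-dependent ionization suppression beyond a scalar noise
floor, antibody capture efficiency differences between matrices,
heavy-standard purity/calibration error, carryover mechanisms (the
sequential design models depletion as a scalar per position), and
correlated inter-peptide structure within a multiplexed run. Headline
medians computed on synthetic data describe the configured regime, not
any particular instrument.

## Numerical and degenerate-input conventions

- Missing ≠ zero everywhere; every missing value carries a reason code.
- Exact ties return CV = 0 (see above); zero-variance simulations
  therefore reproduce CV = 0, slope = 1, R² = 1, LLOQ = lowest designed
  level, and min_input = 500·LLOQ/amount exactly.
- All stage outputs are sorted on their group keys, making results
  invariant to input row order and replicate naming.
- Medians use the standard midpoint convention for even counts.
- Panel-level summaries exclude unquantifiable peptides (no LLOQ), with an
  inclusion toggle for sensitivity analysis.
- The characterization writer emits 6 significant digits and the
  write→read round trip is lossless at that precision.

## Known limitations

- No nonlinear (4PL/5PL) calibration: the characterization is linear on
  log-log by design.
- Precision uses the two-level mean-CV scheme, not a mixed-effects
  variance decomposition.
- The endogenous repeatability statistic is the PAR (not back-calculated
  fmol); recorded in run metadata.
- Vendor raw files and Skyline documents are out of scope; the pipeline
  consumes exported integrated transition areas, and the reader's alias
  map is meant to be extended on first contact with new report dialects.
- The N-terminal column of the packaged hydrophobicity table is an
  approximation; indices are consistent within this package and the
  selection window is applied on this scale.
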