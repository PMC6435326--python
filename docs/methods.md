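# Methods

## Ratio quantification and the empirical null

A glycopeptide PSM is quantified as r = log10(light/medium), light being
the mutant channel (formaldehyde dimethyl label) and medium the control
(deuterated formaldehyde). Unpaired records — spectra with a single
precursor and no isotope partner, or a missing/non-positive intensity —
are *unquantifiable*, which the API keeps distinct from a ratio of zero:
`compute_log_ratio` raises, the vectorised path yields NaN, and such
records never enter ratio statistics. They are still counted for
glycoform-class and site tallies and reported separately. No pseudo-count
imputation is applied.

The null is fitted on flow-through (non-glycosylated) peptide ratios from
the same lectin-enrichment run: μ and σ are the sample mean and SD
(≥ 30 finite values required, zero variance rejected), and the candidate
cutoff is z·σ with z the two-sided normal quantile of the coverage
parameter. Coverage defaults to 0.9973 = 2Φ(3) − 1, which makes the
default cutoff exactly 3σ; at a flow-through scale of σ = 0.55/3 this
reproduces the ±0.55 interval containing 99.7% of null ratios.
Candidate selection is strict (|r − μ| > cutoff): values exactly on the
boundary are not candidates.

## Classification and aggregation

Fold-change categories use literal thresholds t3 = log10 3 ≈ 0.477 and
t10 = 1 with inclusive boundaries (|r| = t3 is a 3× change), while
candidate selection uses the empirical-null cutoff; since 10^0.55 ≈ 3.55×
these differ, and the report surfaces the cutoff's fold-equivalent so the
two scales are never conflated. Both thresholds are parameters.

A glycosite is keyed by (protein accession, 1-based position in the
protein, residue letter); a helper maps peptide-relative positions given
the peptide start. Two different residue letters at one (protein,
position) raise a data-integrity error. PSMs aggregate to a site ×
glycoform ratio as the **median** of PSM log ratios — robust to a single
outlier PSM; the site's glycoform class (Tn-only / T-only / both) is the
union of observed glycoforms, counting unpaired records too. Proteins
aggregate over sites: the protein category comes from the site ratio of
largest magnitude across both glycoforms; the class is Tn-only or T-only
only when every site is, otherwise both. The direct-target flag is true
iff some site's category is down3/down10 while a *different* site is
unchanged or increased; it therefore implies at least two sites.

Report percentages use largest-remainder rounding so every axis sums to
exactly 100 (integer precision, residue composition at 0.1%).

The glycosite-multiplicity comparison (do altered proteins carry more
sites than the glycoproteome at large?) is a two-sided Mann–Whitney U
test with normal approximation and tie correction; counts are heavily
tied, so the asymptotic tie-corrected form is the appropriate one. A
brute-force permutation test serves as its oracle in the test suite.

## Trajectory metrics

Tracks are ordered 3D positions in µm at uniform frame spacing (the
simulator defaults to the 40 s two-photon frame interval). Instantaneous
speed is |Δp|/Δt converted to µm/min; a condition's speed is the mean of
per-track means (each trajectory one vote), with SE across tracks (NaN
for a single track). Directionality splits a trajectory into consecutive
non-overlapping 10-frame segments — a sliding step-1 window is available
as an option, and the choice is echoed in the CLI output metadata — and
scores each segment as net displacement over summed path length; a
zero-path (stationary) segment scores 0 by definition. Trailing frames
short of a full window are dropped from directionality but kept for
speed; tracks shorter than one window are excluded from condition
averages rather than erroring.

Germband entry time is T1 − T0 in minutes, where T0 is the earliest time
any nucleus satisfies the caller-supplied edge predicate and T1 the
earliest time any nucleus (possibly from a different track) satisfies
the interior predicate; the boundary is declared (e.g. a planar
threshold via `axis_threshold`), never inferred from images. Percent
speed reduction rounds half away from zero to an integer.

## Image quantification

Pearson colocalization is the plain sample correlation over unmasked
pixels — no Costes-style auto-thresholding — and errors on a constant
channel rather than returning a value. Arbitrary-unit normalization
subtracts each ROI pair's background from its signal individually, then
divides by the mean background-subtracted signal of the same imaging
day's control ROIs, so the control mean is 1 per day and any per-day
laser-gain factor cancels; a day without controls requires an explicit
reference divisor. ROI geometry is the caller's job: this module
consumes ROI means. Line profiles sample n equidistant points between
two endpoints given in µm (pixel (r, c) sits at physical
(c·px, r·px); origin at the top-left pixel centre) with bilinear
interpolation, so an axis-aligned line through pixel centres reproduces
raw pixel values exactly. Border-cell migration percent is the scalar
projection of (current − origin) onto the origin→target axis as a
fraction of the full distance; negative values (movement away) are
clamped to 0 with a flag, overshoot beyond 100 is reported as-is.

## Synthetic data: what it emulates, and what it does not

The generators produce every input the pipeline consumes, with ground
truth in separate tables.

- **Flow-through ratios**: N(0, σ) with σ = 0.55/3 by default — the
  distributional shape the cutoff calibration assumes.
- **Glycopeptide tables**: defaults emulate the measured embryo
  glycoproteome — 270 proteins; a sites-per-protein distribution with
  P(1) = 0.44, P(2) = 0.20 and a geometric tail capped at 27; site
  classes 74/4/22% Tn-only/T-only/both; residues 78.5/21.2/0.3% T/S/Y;
  10% of sites spiked with effects from {−log10 50, −1, +1}; 30% of
  PSMs singletons (the study reports singletons as frequent without a
  number; 30% is a realistic choice, fixed here once). Channel
  intensities are log-normal (log10 medium ~ N(6, 0.5)) — standard for
  MS intensities, and only the ratio matters downstream. Each paired
  PSM's log ratio is exactly the site effect plus null noise.
- **Tracks**: fixed-step persistent random walks; each step has length
  speed·dt and heading normalize(p·previous + (1 − p)·fresh) with fresh
  uniform on the sphere. p → 1 gives straight lines, p = 0 an isotropic
  walk; speed ground truth is exact by construction, persistence ground
  truth is ordinal (higher p ⇒ higher directionality).
- **Image pairs**: correlated Gaussian fields with exact target
  correlation in expectation; Pearson is invariant to the affine
  intensity rescaling applied.

Not emulated: raw spectra, chromatography, retention time or charge
states; intensity-dependent ratio variance; embryo morphology beyond a
planar boundary; cell shape or segmentation noise; spatial structure in
the image fields (pixels are i.i.d.). Passing tests therefore establish
the correctness of the computations on data matching the stated
statistical assumptions, not robustness to the full messiness of real
acquisitions.

## Numerical and scale choices

One `numpy` Generator per simulation, seeded explicitly; no global RNG.
All test simulations are sized to run the whole suite in well under a
minute: 2×10⁵ draws for null-coverage and false-positive-rate checks
(3·binomial-SE tolerances), 10³ tracks × 60 frames against a 10⁵-sample
Monte-Carlo oracle for random-walk directionality (2% relative), and
512² pixels for correlation round-trips (±0.05). Exact-recovery checks
use a null σ of 0.05–0.1 so spiked ±1 effects sit ≥ 8σ from the null and
recovery is deterministic. `fit_null_model` uses the unbiased sample SD
(ddof = 1). Tables are TSV (CSV accepted by extension), UTF-8, decimal
point; glycosite coordinates 1-based, pixels 0-based.

## Known limitations

The candidate cutoff assumes a normal null; heavy-tailed flow-through
distributions would need a robust scale estimate. Site aggregation has
no within-site variance model, so a site quantified by one PSM weighs
like one quantified by ten. The direct-target rule is purely
categorical and inherits the 3× threshold's arbitrariness. Entry-time
detection depends entirely on the supplied boundary predicates.
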