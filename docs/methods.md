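# Methods

This note documents the models, defaults and design decisions behind
`hramsst`, in the order data flows through the package.

## Theoretical masses

Monoisotopic masses are sums of most-abundant-isotope atomic masses
over the molecular formula. The embedded element table (C, H, N, O, F,
Na, Si, P, S, Cl, K, Br, I) carries 8–9 significant decimals from the
AME2020 / NIST atomic-mass compilations; four-decimal agreement of an
adduct *m/z* with published reference values requires at least five to
six decimals per element, so the table must not be truncated further.

Adducts are modelled as proton transfer only: [M+H]⁺ adds and [M−H]⁻
subtracts the proton mass 1.00727646 u, with |z| = 1. This convention
(rather than hydrogen-atom transfer with separate electron bookkeeping)
reproduces curated reference masses to all four printed decimals.
Multiply charged species, isotopologues and electron-mass corrections
are out of scope — they are not needed for a suitability panel of
singly protonated/deprotonated small molecules.

The bundled panel ships as data (`data/reference_panel.csv`), not code,
so laboratories can substitute their own standards. One bundled entry,
perfluoropentanoic acid, carries an erratum flag: its curated *m/z*
262.9760 corresponds to C5HF9O2, not the recorded formula C6HF9O2
(274.9761). The curated value is retained as the scoring target and
`validate_panel` reports the inconsistency as an advisory rather than
an error, because the measured instrument peak is matched against the
curated mass. Acetaminophen ionizes in both polarities; the panel
carries it with its protonated adduct so that each polarity's scored
set (8 positive, 5 negative) matches the masses evaluated in routine
use. Panel validation is purely advisory: interior coverage gaps wider
than 200 u per polarity, uncovered spans longer than 75 u at either
scan-range edge (a stricter rule, since range ends are where calibrant
coverage is thinnest), out-of-range compounds and duplicate masses.

## Spectral measurement

Runs are centroided MS1 mzML. The reader is a focused implementation
of the mzML 1.1 subset this workflow needs — spectrum elements with
ms-level, centroid/profile and polarity cvParams, scan start time in
minutes or seconds, and 32/64-bit float binary arrays with optional
zlib compression. Profile data is rejected with a distinct error
rather than centroided internally: the apex read-out below is only
meaningful for centroided peaks. The writer (used by the simulator and
for fixture export) emits uncompressed 64-bit arrays; the test suite
cross-checks it against Bioconductor's mzR reader.

Per compound, an EIC is extracted in a ±10 ppm window (default) around
the theoretical *m/z*: per scan, window intensities are summed and the
most intense centroid's *m/z* recorded. The window is deliberately
wider than the 3 ppm pass threshold so a drifted-but-failing peak is
still measured instead of silently vanishing. The apex is the scan
with maximal summed intensity (ties broken toward earlier retention
time), and the observed *m/z* is the most intense centroid at that scan
— the closest equivalent to reading the apex value in vendor software.
An intensity-weighted mean across the peak top (scans contiguous with
the apex above half its intensity) is available as `mz_mode="weighted"`.
Detection requires apex intensity ≥ 1e4 counts (a typical Orbitrap
noise-floor scale; configurable). No retention-time library is used:
the chromatography of a suitability mix is intentionally generic and
column/mobile-phase dependent, so each compound is located as the
global EIC maximum, optionally narrowed by an rt window.

## Verdict criteria

* **Threshold**: default semantics `each` — a compound fails if any
  replicate exceeds 3 ppm in absolute value, the strict reading of a
  maximum-deviation criterion. `mean` mode holds only the replicate
  mean to the threshold.
* **Bias randomness**: per-compound mean errors should be randomly
  signed. This is operationalized as an exact two-sided sign test on
  the signs of the means (zeros dropped): p = 2·P(Bin(n,½) ≥ max(k,
  n−k)), capped at 1, flagged when p < 0.05. The sign test is
  distribution-free, needs no variance estimate at n ≤ 13, and is
  conservative due to discreteness (at n = 13 it fires only for ≥ 11
  same-sign means, actual level ≈ 0.022). With fewer than five usable
  means the check is inconclusive and never flags. A one-sample t-test
  would be the parametric alternative; it was not chosen because the
  per-compound means share no common scale across masses.
* **Missing compounds**: a panel member undetected in any replicate
  fails the verdict — silent non-detection is itself a suitability
  failure. An allowlist exempts intentionally skipped compounds.
* **Two-injection protocol**: with n = 2, a third injection is
  requested when any compound breaches the threshold, is detected only
  once, or differs between the two replicates by more than 1.5 ppm.
  The 1.5 ppm gap default is roughly twice the typical pooled replicate
  standard deviation (~0.7 ppm) of a healthy instrument; "outlier" has
  no canonical definition in this setting, so the gap is configurable.
* Recommendation: RECALIBRATE on threshold or bias failure;
  THIRD_INJECTION when n = 2 and the adaptive rule demands it;
  missing-compound failures with ≥ 3 replicates also map to
  RECALIBRATE, as the operator must intervene before acquisition.

## Longitudinal models

The history is a long-format CSV (one row per compound per replicate
injection) keyed by (batch, phase, polarity, replicate, compound), with
batch covariates: real-sample injection count, calibration type,
calibration rms error, days since calibration. Replicate-level rows —
not batch means — are the modelling unit, matching how the underlying
injections are acquired. Derived quantities: batch hours = injections
× 20 min (a display convention; models regress on the measured
injection count), calibration quality flag GOOD iff rms ≤ 0.3 ppm.
The flag enters the models as a binary covariate rather than the
continuous rms, because 0.3 ppm is the operational accept/reject line
for a calibration.

Both models are ordinary least squares via statsmodels, with a rank
check that names constant/collinear columns before fitting, and
two-sided t-tests (n − p dof) for the coefficients. P-values are
unadjusted; no multiple-testing correction is applied across
compounds. The per-mass error model is

    error ~ 1 + phase_post + n_injections + phase_post:n_injections

whose interaction estimates the within-batch drift rate in ppm per
injection (the pre-batch intercept and slope absorb between-batch
structure). An optional `max_hours` filter restricts to short batches
(the < 33 h stratification). The calibration model regresses the
absolute error:

    |error| ~ 1 + calmix_only + poor_cal + days_since_cal
              + days_since_cal:poor_cal

By default, CalMix-only calibrations older than 7 days are excluded:
that stratum is typically sparse and leverages the type × age cells of
the design; the 7-day cutoff is this package's choice and is logged by
the report command. The drift analysis computes Δ = (mean post-batch
error − mean pre-batch error) per batch and polarity, stratified by
calibration quality, with a per-stratum linear trend of Δ against
batch hours (fitted when a stratum has ≥ 3 batches with varying
length). Batch-length advisories fire beyond 100 injections (~33 h at
20 min/injection) in general, and beyond 20 h (~60 injections) when
the calibration flag is POOR — drift onset is earlier under suboptimal
calibration.

## Synthetic data

The run generator emulates one centroided injection: matching-polarity
panel compounds elute as Gaussian peaks (σ = 0.06 min, height 1e6)
spread over the middle of a 7-minute generic gradient, scanned every
2 s. Each centroid's *m/z* is displaced by (bias + N(0, noise sd)) ppm
— mass noise is modelled in ppm, not daltons, because that is the scale
on which accuracy is specified and thresholded. Decoy centroids 80 ppm
from each target (15 ppm in adversarial tests) and a sparse random
baseline exercise window extraction. The generator does not emulate
isotope patterns, adduct clusters, ion suppression or profile peaks;
passing tests therefore demonstrate correctness of extraction, apex
picking and scoring, not robustness to convolved real-world spectra.

The history generator draws replicate errors as

    base  ~ N(μ_c + slope · n_injections · 1[post-batch],  sd_polarity)
    error = sign(base) · (|base| + poor_penalty·1[POOR]
            + calmix_penalty·1[CALMIX] + day slopes · days)

with default spreads 0.7 ppm (positive) / 0.5 ppm (negative), the
magnitudes seen on a well-behaved instrument over months of operation.
Calibration effects inflate the error magnitude additively and leave
the sign untouched, so the absolute-error calibration model recovers
the configured penalties as linear coefficients in expectation, while
sign-test behaviour is unaffected. Batch covariates are sampled
independently (default 5–120 injections per batch, 20% poor
calibrations, 30% CalMix-only, calibration age uniform on 0–14 days).
All randomness flows from NumPy's PCG64 `default_rng`; a fixed seed
reproduces every artifact bit for bit across platforms.

## Problem sizes and numerical choices

Simulation-backed tests use sizes chosen to make their statistical
assertions sharp at interactive runtimes: 50-batch histories with 5
replicates per phase for parameter recovery, 200 seeded replications
for confidence-interval coverage (bound ≥ 90% for nominal 95%
intervals), 100–1000 replications for type-I-rate checks with explicit
Monte-Carlo margins. OLS correctness is asserted against an explicit
normal-equation solve at 1e−8 relative tolerance on 50 random small
designs; degenerate random designs (e.g. a single poorly calibrated
batch, which collinearizes the age × quality interaction) raise a
rank-deficiency error by design and are skipped by the comparison.
EIC window arithmetic treats the boundary as closed; at ppm widths the
open/closed distinction is below float resolution. Apex ties break
toward earlier retention time deterministically.

## Known limitations

* Only proton-transfer adducts and |z| = 1; no isotopologue scoring.
* mzML subset reader: indexed wrappers are tolerated but the index is
  ignored; vendor raw formats are not read.
* The longitudinal models are plain linear models; no mixed effects or
  time-series structure, so repeated measures within a batch are
  treated as independent (standard errors are accordingly optimistic
  for strongly clustered data).
* Intensity and retention-time stability are deliberately not part of
  the verdict: this is a mass-accuracy suitability test, not a full
  system suitability test.
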