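# hramsst

High-resolution accurate mass system suitability testing (HRAM-SST) for
LC-HRMS laboratories.

Screening workflows on high-resolution instruments (Orbitrap-class
analyzers in particular) stand or fall with mass accuracy: molecular
formula assignment, suspect matching and data-dependent precursor
selection all assume that observed *m/z* values stay within a few ppm of
the truth. Calibration routines do not guarantee this — an instrument
can accept a mediocre calibration without complaint, and accuracy
drifts between calibrations with temperature and field instabilities.
`hramsst` implements the complementary check: replicate injections of a
known reference-standard mixture **before and after** every sample
batch, scored against explicit suitability criteria, with the results
accumulated into a longitudinal record that supports statistical
analysis of drift and calibration effects over months of operation.

## What it computes

For each reference compound with formula *M* and a proton-transfer
adduct ([M+H]⁺ or [M−H]⁻), the theoretical mass-to-charge ratio is

```
m/z_theo = ( Σ_e  n_e · m_e  ±  m_p ) / |z|,    m_p = 1.00727646 u
```

with monoisotopic element masses *m_e*. The suitability statistic per
compound and injection is the signed relative error of the observed
apex *m/z* of its extracted ion chromatogram (EIC):

```
δ [ppm] = (m/z_obs − m/z_theo) / m/z_theo × 10⁶
```

A replicate set (2–5 injections per polarity) **passes** when

1. every |δ| ≤ 3 ppm (threshold criterion), and
2. the per-compound mean errors show no systematic sign bias — tested
   with an exact two-sided sign test at α = 0.05 (randomness criterion), and
3. every panel compound of the run polarity is detected.

With only two injections, an adaptive rule requests a third whenever
the pair disagrees by more than 1.5 ppm for any compound, breaches the
threshold, or misses a detection.

Longitudinally, two ordinary-least-squares models are fit per mass:

* `error ~ phase + n_injections + phase:n_injections` — the interaction
  is the within-batch drift rate (ppm per injection; phase is
  pre- vs post-batch);
* `|error| ~ cal_type + cal_quality + days_since_cal +
  days_since_cal:cal_quality` — calibration type (CalMix only vs
  CalMix + FlexMix), a 0.3 ppm-rms quality flag, and calibration age.

The bundled default panel contains 13 stable reference standards
(8 positive mode, 5 negative mode) spanning *m/z* 152–716, acidic
perfluorinated compounds to basic pharmaceuticals. Users supply their
own panel as a CSV (`name,formula,adduct,...`); `panel validate` gives
advisory coverage checks (one compound per 100–200 *m/z* is the
recommended density over a 100–1000 scan range).

## Worked example

Simulate three replicate injections carrying a uniform +1.2 ppm mass
bias (0.1 ppm noise), then evaluate them:

```
$ for s in 1 2 3; do hramsst simulate run --out sst_$s.mzML \
      --bias-ppm 1.2 --noise-sd-ppm 0.1 --seed $s; done
$ hramsst evaluate sst_1.mzML sst_2.mzML sst_3.mzML \
      --polarity pos --phase pre --out-dir out
## SST verdict — POS / PRE

**Result:** FAIL — recommendation **RECALIBRATE** (3 replicates)

Bias check: p = 0.007812 (flagged, positive bias)

| compound | n | mean ppm | sd ppm | status |
| --- | ---: | ---: | ---: | --- |
| Acetaminophen | 3 | 1.156 | 0.116 | ok |
| Anhydro erythromycin | 3 | 1.161 | 0.127 | ok |
| Caffeine | 3 | 1.275 | 0.048 | ok |
| Carbamazepine | 3 | 1.264 | 0.133 | ok |
| Clindamycin sulfoxide | 3 | 1.249 | 0.069 | ok |
| Fexofenadine | 3 | 1.254 | 0.095 | ok |
| Oxazepam | 3 | 1.136 | 0.137 | ok |
| Verapamil | 3 | 1.260 | 0.058 | ok |
$ echo $?
3
```

Every compound is comfortably inside the 3 ppm threshold, yet the
verdict is FAIL: all eight mean errors are positive, and the exact sign
test (p = 2·(½)⁸ ≈ 0.0078 < 0.05) flags a systematic positive bias —
precisely the situation where an instrument should be recalibrated even
though no single mass "looks bad". With unbiased runs the same command
prints `PASS — recommendation PROCEED` and exits 0. Exit codes are
stable (0 = proceed, 2 = third injection needed, 3 = recalibrate,
1 = error), so batch submission can be gated in shell pipelines.

`hramsst report --history history.csv` summarizes an accumulated
history: per-mass mean/sd tables for 5- and first-2-replicate
evaluation, both model fits per compound, a per-batch drift table
(post- minus pre-batch mean error against batch duration, stratified by
calibration quality) and batch-length advisories (warnings beyond ~100
injections ≈ 33 h, or ~20 h under a poor calibration).

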