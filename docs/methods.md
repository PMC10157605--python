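# Methods

## The statistic

Two centroided MS/MS spectra that derive from isomeric analytes can share
every fragment m/z and differ only in fragment intensities.  `specdiff`
reduces such a pair to a single number and a p-value as follows.

1. **Channel matching.**  Peaks of the two (scan-averaged) spectra are
   paired greedily by smallest m/z gap within a tolerance (default 10 ppm;
   an absolute-Th mode serves ion-trap data).  Only channels present in
   *both* spectra are kept — the statistic is defined on common ions — and
   a zero-fill mode is available but not default.
2. **Fractional abundance (FA).**  Within the matched panel, each channel's
   intensity is divided by the panel's summed intensity, so each FA vector
   sums to 1 and raw intensity scale cancels.
3. **Normalized differences.**  Per channel, `|fa_a - fa_b|` is divided by
   the channel's mean FA, `(fa_a + fa_b)/2`.  The per-fragment
   normalization weights the *relative* change of each peak, balancing
   small and large fragments; each normalized value lies in [0, 2].
4. **Observed mean.**  The mean of the normalized values over channels.

Because both FA vectors sum to 1, the signed differences sum to zero
(numerically to ~1e-15): abundance lost by one dissociation channel
reappears in others.  This near-zero-sum behaviour is why signed means are
uninformative and the absolute, normalized form is used.

The normalization is deliberately **per fragment**, not pooled over the
spectrum: a pooled reading ("divide all absolute differences by the grand
mean FA") would reduce to a rescaling of the unnormalized mean and lose the
small-peak/large-peak balancing that motivates the normalization.

## Hypothesis testing

The sampling unit is one normalized difference per matched channel.  With
`n` channels, the one-sample, one-tailed t-test computes
`t = (observed_mean − μ0) · √n / s` with `n − 1` degrees of freedom, where
`μ0` is the **hypothesized mean** — the observed-mean level expected from
replicate variation alone.  Two rules construct it:

* `mean_plus_3sd` (default): mean of replicate observed means plus 3 sample
  standard deviations (n−1 denominator); conservatively high, so replicate
  noise is almost never called significant.
* `upper_quartile`: 75th percentile (type-7 linear interpolation) of
  single-peak edge means in LC–MS data, robust when some apparently single
  peaks hide isomers and would inflate a mean-plus-SD rule.

Tests are one-sided ("greater") only: two spectra cannot be meaningfully
*more* similar than replicates.  Verdicts use α = 0.05 by default with
stars at 0.05/0.01/0.001.  A two-sample Welch variant compares an isomer
difference set directly against a matched replicate difference set
(unequal-variance form; nothing suggests pooled variances are safe here).
A Wilcoxon signed-rank check (exact null for ≤ 25 nonzero differences,
normal approximation with continuity correction above; sign-test fallback
for heavily tied data) is provided as the non-parametric confirmation.  No
multiple-testing correction is applied by default; a Benjamini–Hochberg
helper exists for all-vs-all LC comparisons.

Degenerate inputs are flagged rather than hidden: zero variance across
channels yields p = 0 or 1 by the sign of the mean with a
"degenerate variance" flag; a Wilcoxon with no nonzero differences raises.

## Mixture calibration

For binary mixtures, the observed mean between a mixture and a pure
endpoint reference grows monotonically — and to good approximation
linearly — with the minor-isomer fraction.  `fit_calibration` fits an
unweighted OLS line through (fraction, observed mean) points (≥ 3 points
spanning ≥ 0.2 of the unit interval; duplicate runs fitted jointly to
preserve residual degrees of freedom), and `predict_fraction` inverts it
with the first-order inverse-prediction standard error, clipping estimates
to [0, 1] with an extrapolation flag.  The reference is the pure
0%-composition isomer by default (configurable to either endpoint).

The response is not exactly linear: the per-channel normalization
denominator `(fa_mix + fa_ref)/2` itself moves with composition, giving a
mild convexity (≲ 7% at the far endpoint for the default effect).  Donor
and acceptor channels curve in opposite directions and largely cancel in
the mean, which is why synthetic curves fit with R² ≳ 0.98 and held-out
compositions are recovered to about one percentage point (mean absolute
error ≈ 0.9 points under the default generator; see
`scripts/acceptance.py`).

## LC–MS screening

All extractions in a run use one scan window: ⌊min(scan count over
peaks)/2⌋, so every comparison averages an equal number of scans (a run
whose narrowest peak has 144 MS2 scans uses 72-scan windows).  Each peak's
leading and trailing `window` scans are averaged and compared (edge
comparison); single-elution peaks' edge means feed the hypothesized-mean
rule; apex-centred windows (even windows biased one scan left) of every
same-peptide peak pair are then compared against μ0.  Outcomes follow a
decision table:

| elution pattern | test | p ≥ α | p < α |
|---|---|---|---|
| single peak | own edges | non-isomer | co-eluting isomers |
| peak pair | centre windows | unconfirmed isomer | confirmed isomer |

The global (not per-peptide) minimum scan window keeps scan counts equal
across *all* comparisons, including those that set μ0.  Peak boundaries
are taken as input (TSV peak table); `detect_peaks` offers only a thin
contiguous-precursor-run finder, since real chromatographic peak picking is
a separate problem.  Cross comparisons are computed once per unordered
pair (the statistic is symmetric).

## The synthetic generator

The generator emulates the statistical structure the method assumes, not
fragmentation chemistry; channels are abstract m/z slots 25 Th apart.

* **Noise model**: per scan, total ion count ~ log-normal with configurable
  mean and RSD (source drift), allocated to channels by a multinomial draw
  (competition between dissociation channels).  This reproduces the
  near-zero-sum FA behaviour and makes the replicate floor of the observed
  mean scale like 1/√TIC, with a wide stability plateau in ion count.
* **Isomers**: a zero-sum perturbation moving a total abundance
  `effect_size` from donor channels to acceptor channels (equal shares,
  donors drawn among channels that can afford their share).
* **Defaults**: 20 channels, Dirichlet(5) base spectrum, TIC 10⁶, TIC RSD
  10% (inside the 15% spray-stability gate), 100 scans per acquisition,
  effect 0.05 over 4 channels.  These mirror a stable direct-infusion
  experiment: 100 collected scans, drift below the acceptance gate, and an
  isomer effect small enough that spectra look nearly identical by eye.
* **Chromatograms**: Gaussian elution envelopes modulate per-scan TIC;
  declared co-eluting pairs share one scan block whose per-scan FA is the
  envelope-weighted mixture of the two components (apexes offset within
  the block), so the leading and trailing edges sample different mixtures.

What the generator does **not** model: electronic/detector noise floors,
profile peak shapes, mass-accuracy drift, deisotoping artefacts, real
peptide fragment mass lists, or between-run retention shifts.  Passing
tests on this generator therefore demonstrate the statistical machinery
under the stated noise model, not instrument-specific robustness.

## Sparse-signal saturation (a known limitation)

With the default generator the isomer effect is confined to exactly 4 of
20 channels.  The one-sample t-statistic of a panel whose signal lives on
`k` of `n` channels is bounded above by `√(k(n−1)/(n−k))` — about 2.18 for
k = 4, n = 20 — regardless of effect size, because the channel-to-channel
standard deviation grows with the same outlying values that raise the
mean.  Detection under the defaults is therefore reliable at α = 0.05
(p typically 0.02–0.05) but cannot reach p < 0.001, and the Wilcoxon
signed-rank test, which discounts a shift carried by few channels, often
stays near p ≈ 0.5 where the t-test rejects.  Real isomeric spectra
repartition intensity across many fragments at varying magnitude, which is
the regime where very small p-values and parametric/non-parametric
agreement are observed; a denser synthetic perturbation would reproduce
that regime, but the sparse default is kept because it is the harder,
clearly-specified case.  Practical guidance follows: the statistical
confidence attainable from a comparison depends not only on the size of
the spectral difference but on how many fragment channels carry it.

## Numerical choices

* FA vectors must sum to 1 within 1e-9 at construction; generated vectors
  are accurate to ~1e-15.  0/0 channels define a normalized difference of
  0 (possible only under zero-fill matching).
* Scan averaging uses the arithmetic mean with absent channels counted as
  zero, making the averaged spectrum — and everything downstream —
  invariant to the number of scans averaged; channel m/z is the
  intensity-weighted mean of merged peaks.
* Channel matching is greedy by smallest m/z gap, each peak used at most
  once; matching is symmetric up to swapping the two intensity columns.
* Default fragment panel: the 25 most abundant peaks outside a ±2 Th
  precursor exclusion window.  The count is a conservative configurable
  default; published workflows rarely state one.
* Quantiles use type-7 (linear interpolation), numpy's default.
* Exact Wilcoxon is used for ≤ 25 nonzero differences, falling back to the
  corrected normal approximation when ties preclude the exact null.
* "Within 5%" for mixture recovery is read as percentage points of
  composition, the stricter reading at mid-range compositions.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run entirely on the synthetic
generator at its default sizes: 100-scan acquisitions at TIC 10⁶, 500
replicate-pair simulations for the false-positive rate, 200 isomer pairs
for power, 11-point calibration curves with 3 held-out compositions over
20 seeds, and 20 seeded LC runs of 7 observed peaks (~1 200 scans each).
These sizes give stable rates (binomial SE below 1 percentage point for
the error-rate estimates) while completing in a few seconds each.
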