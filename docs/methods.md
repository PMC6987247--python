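# Methods

This note documents the models, numerical choices and limitations of
`kciq`. It is the companion to the code, not a results report: every number
quoted here is recomputed by the test suite or by `scripts/acceptance.py`.

## Wavefront representation and pupil rescaling

Wavefronts are represented by OSA/ANSI double-indexed Zernike coefficients
with unit-variance normalization, in micrometres. Under this normalization a
coefficient equals the RMS wavefront contribution of its term, so the
higher-order RMS is simply HORMS = √Σ c(n,m)² over n ≥ 3, and Parseval's
identity ties the sampled wavefront RMS to the coefficient vector (verified
to 0.2% on 256-sample grids).

Aberrometer measurements taken over a natural pupil larger than the 5 mm
analysis pupil are rescaled by *restriction and re-projection*: the original
wavefront is evaluated at radius s·ρ′ (s = target/source ≤ 1) on a
Gauss–Legendre × uniform-azimuth quadrature grid and projected onto the same
Zernike order set. Because the restricted wavefront is itself a polynomial
within the quadrature degree, the projection is exact to machine precision;
the analytic single-term identities (pure defocus scales by s², pure
spherical aberration by s⁴ with a √15·s²(s²−1) defocus leakage) hold to
1e-6 and the operation is linear and composes. The piston offset created by
restriction is discarded as optically irrelevant. Upscaling is refused —
coefficients carry no information outside the measured pupil. Replicate
measurements of one eye are averaged term-wise; replicates must agree on
pupil diameter within 5% (the instrument protocol repeats measurements over
the same dilated pupil, so larger discrepancies indicate an acquisition
problem rather than noise).

Defocus in diopters maps to the Z(2,0) coefficient as ΔZ(2,0) =
V·(d/2)²/(4√3). Positive vergence is *labeled* induced myopia on the
through-focus axis. The opposite aberrometry sign convention would only
mirror the axis labels; note that under the convention implemented here the
negative spherical aberration of unaided keratoconic eyes drives best focus
toward the negative (hyperopia-labeled) side, i.e. the published
myopic-unaided/hyperopic-RGP shift appears with mirrored labels. Nothing
else in the analysis depends on this choice.

## PSF and the Neural Sharpness metric

The monochromatic PSF at 555 nm is |FFT of A·exp(i2πW/λ)|², computed from a
pupil grid of 256 samples across the diameter zero-padded 8× (defaults;
both config-exposed), giving 0.048 arcmin per pixel at 5 mm — comfortably
below the 0.25 arcmin needed to resolve a 1-arcmin neural weighting. A
Nyquist guard rejects wavefronts whose phase changes by more than π between
adjacent pupil samples; rather than silently folding energy, the pipeline
then re-evaluates that vergence point on a doubled pupil grid (up to 1024
samples). Mild keratoconic eyes never trigger this; severe eyes do at the
±3–4 D extremes of the sweep.

Neural Sharpness is the peak of the Gaussian-smoothed PSF (SD 1 arcmin)
normalized by the diffraction-limited equivalent. Taking the maximum over
position makes NS invariant to the prismatic PSF displacement that coma
induces; the published variants of this metric family differ in whether the
weighting is centered on the peak, centroid or chief ray, which is not
recoverable from the study protocol — the translation-invariant choice is
the default and the only one exercised by the tests. Values satisfy
NS ∈ (0, 1], logNS = log₁₀NS ≤ 0, with logNS = 0 for the aberration-free
pupil by construction.

For through-focus sweeps the smoothed-PSF peak is evaluated through the
pupil autocorrelation (OTF) rather than the padded PSF grid: the OTF has
support of twice the pupil sample count regardless of padding, so the
smoothed PSF is synthesized by one inverse FFT of the Gaussian-windowed
autocorrelation. This is algebraically identical to the direct route (the
test suite asserts agreement to 1e-9) and about seven times faster, which is
what makes the 95-eye study sweep a minutes-scale computation.

## Through-focus curves and their summary

The sweep spans −4…+4 D in 0.5 D steps (17 samples). The baseline Z(2,0)
and both astigmatism terms Z(2,±2) are zeroed first: the analysis models IQ
under full sphero-cylindrical correction with HOAs untouched. Astigmatic
(sphero-cylindrical) through-focus surfaces are out of scope. A cubic spline
through the 17 samples, evaluated at 0.01 D, provides the fine curve; peak
and best focus are read from it, with a guard asserting the spline never
overshoots the sampled maximum by more than 0.05 logNS. If the maximum is a
plateau (within 1e-6), the plateau point closest to 0 D is reported —
deterministic and favoring emmetropia.

The DOF threshold "above 70% of peak IQ" is applied on the **linear NS
scale** by default: NS ≥ 0.7·NS_peak, i.e. logNS ≥ peak − log₁₀(1/0.7) ≈
peak − 0.155. Applying 70% multiplicatively on the log scale is degenerate
(0.7 × a negative peak lies *above* the peak), so the config-exposed
`logns` alternative divides instead (floor = peak/0.7). The DOF is the
single contiguous super-threshold interval containing the best focus, with
endpoints refined below the fine-grid spacing by local linear inversion;
disjoint super-threshold islands — which occur on the flat multimodal
curves of severe unaided eyes — are reported in a diagnostic field but
excluded from the width. Censoring flags mark intervals that reach ±4 D.

## Synthetic cohorts

The generator emulates the published summary statistics of three groups
(controls n=20; bilateral keratoconus n=12; very asymmetric ectasia n=9,
one ectatic + one non-ectatic eye, the latter with no RGP condition), each
eye described at 5 mm / 555 nm. Five key terms — both trefoils, vertical
and horizontal coma, spherical aberration — are drawn from piecewise-linear
inverse CDFs pinned to the published per-eye 25th/50th/75th percentiles,
with exponential tails of decay length = IQR/2. Remaining fourth-order
terms are zero-mean Gaussian; fifth/sixth-order terms are sampled at a
tenth of that scale (the study found them clinically insignificant). The
two eyes of a subject are coupled by a Gaussian copula (default ρ = 0.5);
with the final sampler this yields a median signed interocular HORMS
difference of ≈ 0.4 µm in the bilateral cohort, within the published
interquartile range for that statistic.

Two knobs are calibrated per eye, at generator-construction time, against
the published per-eye median HORMS (common random numbers + bisection, so
calibration is deterministic):

* the **residual fourth-order SD** is raised from zero when the key terms
  alone fall short of the target (controls, RGP conditions);
* where the key terms alone already overshoot the target — the published
  marginal quantile spreads of the most dispersed ectatic eyes are not
  jointly attainable with the published HORMS median if terms are sampled
  independently within an eye — a **spread-shrink factor** γ ∈ (0,1]
  contracts the quantile deviations about each term median instead.
  Medians are preserved exactly; the sampled IQRs of those eyes are
  narrower than the printed ones, which is the explicit reconciliation of
  the two published tables under independence.

Within-eye dependence between coma, trefoil and SA is unknown (only
marginal summaries are published) and is not modeled; conditions (unaided
vs RGP) are likewise drawn independently per subject, so paired contrasts
test pairing machinery, not a measured within-subject correlation. These
are the main senses in which passing tests do *not* certify behavior on
real clinical data.

## Statistics

Medians with 25th–75th IQRs per cohort × condition; Shapiro-Wilk as a
normality screen; Wilcoxon signed-rank for paired contrasts (unaided vs RGP
within eyes, ectatic vs fellow within subjects), Mann-Whitney U against
controls, Kruskal-Wallis across the three KCE-related groups; Spearman rank
correlations of best focus and DOF against peak IQ, pooled and per
subgroup. Two-sided p-values, α = 0.05, and — as a faithful-reproduction
choice, not a statistical endorsement — no multiple-comparison correction.
The inter-subject variability of best focus is summarized by a
moving-window 10th/90th quantile envelope across peak-IQ-sorted eyes
(window max(9, n/5), step 1; window parameters config-exposed — no
estimator is canonical for this construction, any smooth quantile estimator
with the same monotone-convergence behavior is equivalent for the
qualitative claim).

## Problem sizes and determinism

The synthetic study comprises 95 eye-conditions (24 + 24 KCE, 18 + 9 VAE,
20 control right eyes). Study-level sweeps (tests and the acceptance
script) run at 256 pupil samples with 4× padding, which the convergence
gate shows agrees with the 8× default to better than 0.01 logNS while
keeping the ~1600-point sweep to a few minutes; per-point escalation to 512
or 1024 samples engages automatically for severe eyes at large defocus.
Generator-recovery quantities are reported as the median over 15 replicate
study-size cohorts to damp the sampling noise of an n=9–20 median. All
randomness flows from a single master seed through named seed sequences;
repeated runs are bit-identical.

## Known limitations

Monochromatic, single-metric, spherical-equivalent analysis: no chromatic
or Stiles–Crawford effects, no astigmatic through-focus surface, no acuity
prediction, no binocular modeling, no cone topography or disease
progression. The generator matches marginal summaries, not joint
distributions, and controls' left/right eyes are statistically exchangeable
rather than anatomically mirror-symmetric.
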