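# Methods

## Signal model and analysis window

A urodynamic study is modelled as a uniformly sampled multichannel
recording: vesical pressure P_ves and abdominal pressure P_abd (cm-H₂O),
infused and voided volume (ml), optionally detrusor pressure
P_det = P_ves − P_abd and flow. The canonical analysis rate is 10 Hz;
exports at other rates are linearly interpolated onto a 10 Hz grid. No
anti-alias filter is applied on downsampling: the analysis band ends at
0.1 Hz, far below the Nyquist frequency of any plausible export rate.

The analysis window (ROI) is exactly **2048 samples** (204.8 s), a power
of two so that the DFT bin width — 10·60/2048 ≈ 0.293 cycles/min — is
identical for every study and the spectral thresholds remain comparable.
The window ends 0, 30, or 60 s before void onset; three offsets are
analyzed because voiding contractions can leak backwards into a window
ending at the void, and flowmeter transit delays blur the onset estimate.

Void onset is the first sample at which voided volume exceeds a 1 ml
threshold and stays above it; the sustained-exceedance rule rejects
isolated flowmeter jitter. With a smooth physiologic ramp the threshold
crossing necessarily trails the true ramp start (≈1.6 s for a 30-s
raised-cosine ramp to 300 ml); this bias is far below the 30/60-s offset
granularity. For studies with no void the window is anchored at the
recording end — the only landmark available. Recordings with less than
420 s of filling, or with more than one void event (a second rise of
>10 ml after >30 s of flat volume — a leak-then-void or double-void
signature), are excluded, because the window arithmetic assumes a single
fill–void cycle.

## Conditioning and spectrum

Each ROI channel passes through, in order:

1. **minimum subtraction** — removes the arbitrary pressure offset;
2. **10-point moving average** — suppresses sample-level noise. The
   window is centered with shrunken edges; an even 10-point mask cannot
   be exactly symmetric, so sample *i* averages indices *i−4 … i+5*,
   a half-sample group delay with no effect on amplitude spectra. The
   passband loss in the analysis band is the discrete boxcar gain
   (0.998 at 2 cycles/min, 0.985 at 6 cycles/min);
3. **symmetric Hanning window** 0.5·(1 − cos 2πn/(N−1)) — forces the
   segment endpoints to zero so the DFT's periodic extension has no
   discontinuity. The periodic-vs-symmetric convention difference is
   <0.1% at N = 2048.

The single-sided amplitude spectrum is A_k = 2|X_k|/N for k ≥ 1 (DC is
|X₀|/N and excluded from all band queries). **No window-gain
compensation is applied**: a Hanning-windowed sine of amplitude A shows
≈A/2 at its bin. Consequently a detected rhythm's physical peak-to-peak
amplitude is **4·A_k** — a factor 2 undoing the window's coherent gain
and a factor 2 converting amplitude to peak-to-peak — and all amplitude
thresholds are stated in these normalized units. The acceptance script
verifies the 4× relation end-to-end; the measured ratio is ≈4.01, the
excess over 4 being exactly the moving-average passband loss.

## Detection rules

Within 1.75–6.0 cycles/min (bins 6–20 inclusive at the canonical grid;
band edges inclusive), the three largest **local maxima** of the P_ves
spectrum are evaluated — local maxima rather than largest bins, since a
single broad peak should not occupy several ranks. A plateau of equal
bins counts once, at its lowest-frequency bin; amplitude ties rank the
lower frequency first. Neighbor lookups use the full spectrum, so a
band-edge peak is compared against its out-of-band neighbors.

**Significance** (both must hold):

- amplitude: A_peak > 0.45 normalized units (strict inequality). This
  equals the 1.8 cm-H₂O floor in model peak-to-peak units (4 × 0.45).
- prominence: on each side, at least one of the two nearest neighbors
  must lie on or below a line descending from the peak at 20% of the
  peak amplitude per bin (≤ 0.8·A at distance 1, ≤ 0.6·A at distance 2).
  "At or below" is chosen over "strictly below" — a measure-zero
  difference on real data. A peak whose side neighbors fall outside the
  spectrum fails that side, and the report records the reason.

**Independence** of a significant peak, with a = A_peak, b0 the P_abd
amplitude at the same bin and bL, bR its nearest neighbors:

- rule A: a > 1.5·max(b0, bL, bR)
- rule B: b0 < 1.33·max(bL, bR) (P_abd relatively flat — no sharp
  abdominal peak at that frequency)
- rule C: a > 2.0·max(b0, bL, bR) (vesical dominance, regardless of
  abdominal peak shape)

independent = (A AND B) OR C. All comparisons are strict, as the rules
are stated. A study is **S&I** if any of its top three peaks is
significant and independent; the reported rhythm is the slowest S&I
frequency with its 4× sine model. Per-offset results are combined into
an "any-offset" flag by logical OR.

## Cohort statistics

The S&I flag is cross-tabulated against the clinician DO label.
Sensitivity = S&I∩DO / DO, specificity = notS&I∩notDO / notDO, reported
to 4 decimals. Association is tested with a **two-sided Fisher exact
test** computed from first principles: hypergeometric point
probabilities via log-factorials, summing all same-margin tables whose
probability is at most the observed one (point-probability rule, the
convention of mainstream statistics tools). A relative tolerance of
1e-12 treats numerically equal probabilities as ties; for tables with
N ≤ 40 the spacing between distinct exact probabilities exceeds this by
orders of magnitude, and the implementation agrees with an exact-integer
enumeration on every such table within 1e-10. Group comparisons of
continuous covariates use a two-tailed pooled-variance t-test; zero
pooled variance returns p = 1 for equal means and p = 0 otherwise.
Subgroup descriptives are mean ± standard error (sd/√n); a single
observation reports SE = 0 with an explicit flag rather than NaN.

## Synthetic data

`synthgen` emulates the qualitative morphology of filling-phase UDS
traces. Defaults: 600 s duration, 42 ml/min fill rate, baselines 10/8
cm-H₂O (vesical/abdominal), compliance-related vesical drift of 2 cm-H₂O
per 100 ml infused, Gaussian sensor noise of 1 cm-H₂O sd, void onset at
520 s with a 30-s raised-cosine ramp to 300 ml plus a 40 cm-H₂O voiding
contraction. LARC is injected as a pure sine (rhythms are modelled as
ideal sines throughout), either vesical-only or translated identically
into both channels; respiration is a shared sinusoid constrained to
≥10 cycles/min, above the analysis band. Coughs and Valsalva are
raised-cosine transients written to both pressure channels; rectal
contractions are longer smooth bumps in the abdominal channel only.
Cohorts are generated from a category mix (vesical rhythm / translated
rhythm / no rhythm) with a stated label rule: all rhythm-bearing studies
are labelled DO, plus a configurable fraction of rhythm-free studies
(sporadic, non-rhythmic contractions the spectral detector is
deliberately blind to), which makes specificity-1, sensitivity-below-1
cohorts constructible.

What the generator does **not** emulate: non-sinusoidal or
amplitude-modulated rhythms, non-stationary drift, catheter movement
artifacts, pump-stop intervals, EMG cross-talk, or correlated
physiological noise. Passing the synthetic suite therefore demonstrates
the algorithm's correctness against its own definitions and its
separation of the three scenario classes — not clinical performance on
real recordings.

## Numerical and design choices

- Interpolation is linear everywhere; the ROI is a pure slice, never
  padded or interpolated.
- The canonical export dialect is tab-delimited text with a header row
  and time in seconds, written at fixed 6-decimal precision so
  write→read→write round trips are byte-stable; a column-mapping YAML
  adapts other dialects.
- Thresholds (0.45 units, 20% slope, 1.5/1.33/2.0, band 1.75–6.0) are
  configuration with those defaults, not fitted quantities; the package
  does no threshold learning.
- Determinism: generators take explicit integer seeds; identical inputs
  give byte-identical reports.
- Test problem sizes: the ground-truth suite uses 50 studies per
  scenario at 600 s each with study parameters drawn from frequency
  2.0–5.5 cycles/min, peak-to-peak 8–14 cm-H₂O, noise sd 0.5–2 — a
  regime where a rhythm is clearly present yet far from artifact
  amplitudes. The ROI-placement property (a rhythm stopping 90 s before
  the void is caught more often by the earlier window) is tested at
  peak-to-peak 3 cm-H₂O, near the 1.8 cm-H₂O floor, because stronger
  rhythms remain detectable even when the window truncates them and the
  contrast between offsets vanishes.

## Known limitations

- The detector is frequency-domain only: non-stationary or intermittent
  rhythms dilute into neighboring bins and can fail prominence; sporadic
  single contractions are invisible by design.
- Frequency resolution is one bin (0.293 cycles/min); reported
  frequencies are bin centers.
- The no-void window anchor (recording end) is a convention; if a
  recording continues long after infusion stops, the analyzed window may
  sit outside the physiologically interesting region.
- Amplitude recovery is biased low by a few percent (smoothing, leakage,
  start/stop truncation of real rhythms).
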