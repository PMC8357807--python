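# Methods

This note documents the models and procedures implemented in
`macroscreen`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where
the design was genuinely open.

## Color scoring

A well's redox state is read from its mean center color. The normalized
yellow intensity is the projection of the white-referenced color onto the
white-referenced saturated-yellow axis:

y = (C⃗ − W⃗₀)·(Y⃗₀ − W⃗₀) / |Y⃗₀ − W⃗₀|², with
Y⃗₀ = (225, 153, 0), W⃗₀ = (255, 255, 255), |Y⃗₀ − W⃗₀|² = 76329.

The value is deliberately **not clipped** to [0, 1]: the formula is a
projection, and off-axis colors (stains, condensation, debris) can land
outside the segment. Clipping would hide exactly the wells a QC pass
should notice. Bounds are guaranteed only for colors on the white-yellow
segment, where the display-color map W⃗₀ + y·(Y⃗₀ − W⃗₀) inverts the
score to machine precision.

Well colors are sampled as the mean RGB over a disc centered on the
predicted well center with radius 30% of the well pitch (config
`radius_frac`). The mean (not median) matches the mean-well-center-color
definition of the score; with ≥100 pixels per disc, per-channel shot
noise of a few gray levels averages to ≲0.3 levels.

## Plate identification and registration

Plates carry a fixed-width 1-D barcode (custom symbology: 8-bit start
frame, length byte, ASCII payload up to 10 characters, checksum byte,
asymmetric stop frame; one module per bit) flanked by two filled
registration discs. Both the writer and the reader live in this package,
so a self-describing fixed-width code was chosen over a commercial
symbology: the decoder can locate every module center from geometry
alone, and the checksum plus asymmetric framing rejects misreads rather
than guessing.

The two discs are deliberately **unequal in radius** (left larger).
A similarity transform (rotation, isotropic scale, translation) fitted to
the two disc centroids maps canonical plate coordinates to image
coordinates; identifying "left" with the larger blob makes the transform
unambiguous under a 180° rotation of the photograph, which two identical
discs could not disambiguate. Mark centroids are localized to sub-pixel
precision by connected-component center of mass; discs are separated from
barcode bars by near-square bounding box and ≥0.6 fill fraction.

Images whose marks or barcode cannot be read are flagged
`barcode_unreadable`, logged, and skipped. They are never interpolated:
absent data must not fabricate a phenotype.

## Growth-plate QC

Turbidity score = Euclidean RGB distance of the well mean color from the
blank-media reference color. The growth threshold is median +
3·(1.4826·MAD) of the catalogued-empty wells' scores, floored at a
configurable minimum (default 20 gray levels), which also serves alone on
plates without empty wells. The robust center/spread was chosen over
mean/SD because a contaminated blank well would otherwise inflate the
very threshold that should flag it. Growth in a catalogued-empty well is
a `contamination` event; no growth in a catalogued-occupied well is a
`growth_failure` event, and such wells are excluded from hit calling.

## Hit calling

Replicate traces are averaged (interpolated onto the first replicate's
time grid) before feature extraction; per-replicate behavior is
diagnostic only. The calling statistic is t₅₀, the first
linear-interpolated crossing of half the initial mean intensity.

* **eliminated** — no crossing within the observation window (~40 h of
  imaging). This is a robustness choice: at late times the trace is
  noise-dominated and a rate cutoff would be fragile.
* **slowed** — t₅₀ > mean + k·SD of the quasi-wild-type controls' t₅₀
  (default k = 3). The threshold is control-referenced because the
  screen provides quasi-wild-type controls for exactly this purpose; at
  least 8 usable controls are required or calling refuses outright.
* **excluded_growth_failure** — any of the mutant's wells flagged by QC.

The hit set is monotone non-increasing in k by construction. Oxidation
rates are reported as the |OLS slope| of the mean curve over its
20–80% dynamic-range window (the operationalization of "the linear
portion" of the decline; window fractions are config-exposed), bounded by
the first crossings of the two window levels. Curves with dynamic range
< 0.1 get rate 0 and a `no_decline` flag.

Cross-assay bookkeeping is pure set algebra over test mutants (controls
never enter partitions); mutants assayed in only one acceptor are counted
there with a warning. Category triage maps hits through an annotation
table; unannotated hits fall in the "unknown" bucket, which is the
validation shortlist.

## Chronoamperometry

Steady-state current = arithmetic mean of the final 100 samples of a
segment; a shorter segment is an error, never a silent shrink.
Biological current = steady state of the pre-inhibitor segment minus
steady state of the post-inhibitor segment, the latter starting 60 s
(config `settle_s`) after the addition so the step transient is excluded.
Cathodic currents are negative throughout, so cathode-active strains give
negative biological currents; the estimator cancels any whole-trace
current offset exactly.

## Cyclic voltammetry

Each scan is split into a forward (descending, +222 → −322 mV vs SHE by
default) and reverse branch on the analysis window (config-exposed; the
hardware scan range may be wider). Per branch: penalized cubic smoothing
spline of current vs potential, evaluation on a uniform 1 mV grid,
centered finite-difference derivative, and the potential of maximum
|dI/dE| as the wave inflection. The midpoint (formal) potential is the
mean of the two branch inflections, which cancels symmetric scan
hysteresis exactly.

Smoothing is parameterized by `spar_equiv ∈ [0, 1]`, mapped linearly to a
target effective degrees of freedom, edf = 2 + 20·(1 − spar_equiv)
(default 0.70 ↦ edf 8, config-exposed); the penalty λ is solved from the
target edf by bisection on the trace of the smoother matrix (computed in
one vectorized fit of the identity matrix, cached per potential grid).
This is a smoothing-*level* convention of this package: it reproduces the
behavior of common spar-style knobs qualitatively, and no claim is made
of numerically replicating any particular ecosystem's spar mapping —
midpoint recovery is insensitive to moderate smoothing differences
(planted-truth RMSE ≈ 1 mV at 2% amplitude noise, against a 5 mV
acceptance bound).

Reading the inflection from the **derivative maximum** (rather than the
smoothed-current maximum) is deliberate: for a sigmoidal uptake wave the
raw current maximum always sits at a scan boundary and carries no
midpoint information. A branch whose derivative peaks at the window
boundary, or has no prominent peak at all (peak − median < 50% of peak —
the signature of a purely capacitive, featureless branch), yields an
`edge_inflection` flag and no midpoint. This prominence heuristic is
aimed at degenerate noiseless scans; a noise-only scan may still pass it.

Potentials are stored in mV vs SHE; `to_she` converts Ag/AgCl-referenced
input with a declared offset (default 222 mV for 1 M KCl).

## Strain statistics

Per-strain replicate biological currents (≥3 replicates required;
under-replicated strains are excluded with a warning) are fitted to
`current ~ strain` by OLS; a type-II ANOVA gives the panel F and p, and
Tukey's HSD gives adjusted p for every pair. A strain is flagged as a
reduced-uptake phenotype when its contrast against the reference has
adjusted p < α (default 0.05) **and** its mean current magnitude is below
the reference's — significance alone can also mean *more* current. The
Tukey table is built from the estimator's raw attributes, not its
rounded display summary (µA-scale differences vanish at 4 decimals).

## Synthetic data: what it emulates, what it does not

The generator replaces unpublished raw data with ground-truthed
stand-ins; its defaults are the study conditions the analysis is tested
under.

* **Oxidation kinetics**: y(t) = y₀·exp(−k·max(0, t − lag)), the simplest
  forward model producing orange→clear trajectories with a closed form
  for tests. Defaults: y₀ = 1, normal mutants k ~ N(1.0, 0.1) h⁻¹
  (half-time ≈ 42 min, comfortably resolved by sub-hourly early imaging),
  slowed mutants k = 0.2 h⁻¹, eliminated mutants and no-cell blanks
  k = 0. Intensity noise sd 0.02 per well and timepoint, plus per-pixel
  channel noise sd 2 (clipped to [0, 255]). Each 4-plate run carries 2
  blanks and 3 quasi-wild-type controls per plate.
* **CA traces**: plateau at the baseline current until the inhibitor
  addition, cubic-smoothstep relaxation to the abiotic current over
  3·`step_sharpness` seconds placed entirely *after* the addition time
  (so the pre-segment is exactly on baseline and the noiseless pre/post
  difference is exact), additive Gaussian noise. Defaults: −10 µA
  baseline, −2 µA abiotic, 1 Hz sampling, addition at 600 s of 800 s,
  noise sd 0.05 µA; between-replicate biofilm variability in the
  end-to-end pipeline is N(0, 0.5 µA) on the plateau.
* **CV scans**: logistic wave I(E) = offset + A·σ((E − E_infl)/w) on each
  branch, with the forward/reverse inflections at E° ∓ h/2 so their mean
  recovers the formal potential exactly. Defaults: A = 5 µA, w = 13 mV
  (≈ RT/nF for a two-electron couple), hysteresis 20 mV, E° = −184 mV vs
  SHE (an AQDS-like couple), 2 mV grid over −322 … +222 mV, noise 2% of
  amplitude.
* **Growth plates**: turbid wells at a fixed tan color, blank media
  near-white, channel noise sd 2.

Not emulated, by design: camera optics (vignetting, specular highlights,
mirror flip), white-balance/exposure drift, dye chemistry (extinction,
pH), electrode double-layer physics, plate-edge effects, non-96-well
formats. Passing tests therefore demonstrate correctness of the analysis
chain under ideal constant illumination and the stated noise models —
they say nothing about robustness to real photographic artifacts.

## Problem sizes and numerical choices

The test suite validates at these scales: planted-hit recovery on
4-plate runs (384 wells, 12 timepoints, full render→decode→sample→call
path) pooled over 20 seeds; the well-recovery round-trip invariant on 384
wells at a ≥99% bar; CV midpoint RMSE over 200 scans; biological-current
calibration over 500 seeds; Tukey family-wise null calibration over 1000
simulated panels (6 strains × 4 replicates). Determinism: every
stochastic stage takes an explicit integer seed, and identical seeds give
bit-identical outputs (the end-to-end report is byte-identical across
reruns).

Degenerate inputs are handled explicitly rather than silently: empty
traces, flat traces, sub-window CA segments, sparse CV branches,
featureless voltammograms, under-replicated strains, unreadable
barcodes, zero-plate configs.
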