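# Methods

## Scope and model

`fusionmode` quantifies single-vesicle exocytosis in TIRF time-lapse movies
acquired with a pH-sensitive lumenal reporter (pHluorin-type), an optional
pH-insensitive ligand channel, and an optional tether-marker channel. The
measurement chain follows the standard circle-annulus protocol: events are
excised as 4 × 4 µm ministacks centred on the brightest pixel, the
per-frame signal is mean(1.3 µm circle) − mean(1.3/2.4 µm annulus), traces
are fusion-aligned, baseline-subtracted over the last 10 s before onset and
normalised to the maximum during fusion, and ensembles are averaged per
cell before averaging across cells (SEM over the averaging units). Events
within the first 50 or last 100 frames of a recording are excluded from
averages because their baseline or post-fusion course is truncated.

Three fusion modes are distinguished:

* **Full fusion (FF)** — the pore dilates; cargo spreads laterally by 2D
  diffusion so Gaussian line-profile widths grow as
  σ²(t) = σ_psf² + 2·D·(t − t_fus), and the receptor signal decays quickly
  as it dilutes into the plasma membrane.
* **Kiss-and-run (KR)** — the pore reseals after a transient opening; the
  lumen reacidifies (first order, rate k_acid) and the vesicle departs
  axially ("runs") through the exponentially decaying evanescent field,
  so the reporter decays to baseline with no lateral spread.
* **Kiss-and-stay (KS)** — the pore reseals but the vesicle remains
  tethered at the membrane. Under high (100 mM) extracellular HEPES the
  buffer that entered through the open pore retards reacidification, so a
  stuck vesicle's reporter signal stays elevated — a late plateau.

## Classification rules

Per event we compute: `half_decay_time` (first interpolated 0.5-crossing of
the normalised reporter after its peak; censored if never), `plateau` (mean
normalised reporter over 30–60 s post onset), `width_slope` (error-weighted
least-squares slope of σ²(t) from line-profile Gaussian fits over the first
5 s post onset; averaged over the three central rows/columns of the
ministack), and tether persistence when a marker channel exists. Rules fire
in order:

1. plateau > 0.3, or persistent tether signal → **KS**;
2. the condition-appropriate FF criterion → **FF**: under high HEPES a fast
   reporter decay (half-decay < 2 s — KR decay there is dominated by the
   slow axial departure); under low HEPES a significant positive width
   slope (> 3 SE — the reporter decay is confounded by reacidification).
   When the primary feature is censored the other acts as fallback;
3. otherwise → **KR**. Events with all features censored are left
   unclassified and are excluded from per-cell frequencies.

The thresholds are configuration-exposed defaults chosen to sit far from
the simulator's mode separatrices, not biologically calibrated constants:
the underlying experimental classification is descriptive (decay speed,
spread, plateau, buffer sensitivity) and publishes no thresholds.

## Synthetic data generator

Because no experimental movies are distributed, the package ships a forward
model that renders ground-truth kinetics into realistic movies; every
pipeline stage is validated against the generator's ground truth.

Reporter photophysics: brightness(pH) = r + (1 − r)·f(pH)/f(7.4) with
f(pH) = 1/(1 + 10^(pKa − pH)), pKa 7.1, normalised to 1 at external pH 7.4;
r is the residual (incompletely quenched) fraction, 0 for the pHluorin-like
default and 0.15 for a pHTomato-like reporter. A vesicle contributes
photons_per_vesicle × brightness(pH) × exp(−z/d) photons per frame
(evanescent penetration depth d), rendered as a 2D Gaussian of width
sqrt(σ_psf² + spread²) integrated exactly over pixel areas. The camera
applies Poisson shot noise, linear gain, Gaussian read noise and 16-bit
clipping; EMCCD excess noise is deliberately omitted (a simple
Poisson × gain model is sufficient to exercise the analysis and is exactly
verifiable: with gain 1 the rendered variance equals the mean).

Default conditions (all configurable): 0.18 µm pixels, 2 Hz frames,
512 × 512 field (tests and the acceptance script use 192 × 192 crops of the
same optics to keep runs fast — a size choice of this package), σ_psf
0.2 µm, penetration depth 0.15 µm, 2000 photons per dequenched vesicle over
50 background photons/pixel. Kinetics: exponential tethering dwells with
means 8/15/20 s for FF/KR/KS (kissing vesicles tether longer than fully
fusing ones), pore open 2 s for KR/KS, k_acid 0.15 s⁻¹ (lumen pH time
constant ≈ 7 s, in the range reported for endosomal/synaptic vesicle
reacidification), D = 0.05 µm²/s for post-FF cargo spread, 0.02 µm/s axial
departure for KR, and an extra 0.5 s⁻¹ receptor dilution decay after FF.

High HEPES is modelled as a single multiplicative slowdown of k_acid. The
package default is buffer_factor 20: raising the lumenal buffer capacity by
roughly the 100 mM/25 mM concentration step makes reacidification slow on
the minutes scale, which is what produces the KS signature of a reporter
plateau persisting through the 30–60 s window. Any factor > 1 preserves
the strict ordering of KR half-decay times between conditions, and the
HEPES-contrast check deliberately uses a conservative factor of 4.

What the generator does **not** emulate: EMCCD excess noise and pixel
cross-talk, focal drift, photobleaching (optional flag off by default),
lateral vesicle drift during tethering (off by default; when enabled it
reproduces the known underestimation of long dwells by fixed-ROI
measurement), repeated kissing at one site beyond step-like re-activation,
and any optogenetic photochemistry — light-dose effects enter only through
user-chosen mode probabilities and dwells. Passing tests therefore
demonstrate correctness of the measurement chain under the stated forward
model, not robustness to every property of real recordings.

## Detection

The experimental protocol calls events by eye; the package substitutes a
quantified rule: onset is the first frame whose lightly smoothed intensity
exceeds its rolling 10 s pre-frame baseline by k = 5 SD at a spatial local
maximum, confirmed on the following frame against the same baseline.
The per-pixel rolling SD is floored at (a) the frame-median SD and (b) the
shot-noise SD implied by the local mean (Poisson counts propagated through
the smoothing kernel, exact at unit gain). The floors matter: a locally
under-estimated rolling SD otherwise inflates both consecutive z-scores
together and fires false onsets, and in noise-free renders any arbitrarily
small step (a dim tethered vesicle arriving) would otherwise be infinitely
significant. Detections within 2.4 µm merge (brightest wins); a site is
refractory for one baseline window after its onset, and later
re-activations of the same site share a site id (repeated kissing).

With the defaults, a fusion event (~70 SD) is unmissable while a tethered
pHTomato-like vesicle arriving (~3 SD) stays below threshold, matching the
intent that time zero is pore opening, not arrival.

## Tethering metrics

The tether-marker ensemble is normalised to its pre-fusion maximum and
integrated over [−50, 0) s (Riemann sum × frame interval, units s). The
interpolated half-rise time before fusion is reported separately; the
integral and the half-rise capture the same dwell information only for
step-like traces, and both are emitted without a claim that either is the
canonical "tethering half-time".

## Membrane morphometry

Per frame: Otsu threshold on a 256-bin histogram over the frame's min–max
range (exhaustive between-class-variance maximisation, term-for-term
identical to the brute-force definition so oracle equality is exact; ties
take the lowest boundary; foreground is intensity ≥ threshold), then the
largest 8-connected component (configurable to 4; holes kept unless
`fill_holes` is set). Area = pixel count × pixel area. The signed
expansion map is last-mask minus first-mask; by construction
expansion − contraction = area(last) − area(first) exactly. Automatic
thresholds are sanity-checked (mask fraction within [1 %, 95 %] of the
frame); failures fall back to a single manual global threshold, mirroring
the original semi-automated protocol. The displacement summary is the net
area change from a post-retraction baseline (mean over 5–10 s, skipping the
light-induced retraction of the first ~10 s) to the final 10 s mean — this
definition is declared by this package, since the plotted quantity it
echoes is not formally defined anywhere.

## Numerical choices and degenerate inputs

* Pixel membership in circle/annulus uses the pixel-centre test (circle
  d ≤ r, annulus r_in < d ≤ r_out) with pixel centres at (i + 0.5)·pixel
  size; no partial-pixel weighting, so exhaustive enumeration is an exact
  oracle.
* Ministack side = round(4 µm / pixel size) forced odd (0.18 µm → 23 px),
  so the event pixel is exactly central; edge-proximal events are flagged
  and skipped, not cropped.
* Interpolated crossings (half-decay, half-rise) are linear between frames;
  ties resolve to the earliest crossing.
* Constant traces, empty masks, constant frames, all-excluded ensembles and
  zero-variance t-tests raise typed errors rather than returning NaNs; the
  one deliberate exception is two identical constant groups, where t = 0,
  p = 1.
* Ensemble time bins with fewer than two contributing units are masked NaN.
* All randomness flows from a single master seed through
  `numpy.random.SeedSequence` spawning, so every simulated dataset and every
  CLI run is bit-reproducible from (inputs + resolved config + seed).

## Known limitations

* The detector assumes an approximately uniform background cell footprint;
  strong intracellular structure would call for a local background model.
* Width-slope estimation degrades for spots dimmer than ~10 photons/pixel
  at peak; the classifier treats such fits as censored rather than guessing.
* At 0.2 Hz acquisition the 2 s pore openings are under-sampled; decay
  features remain usable but onset timing carries the full 5 s frame
  quantisation.
* The KS plateau criterion presumes the high-HEPES condition; in low HEPES
  KS detection relies on a tether-marker channel being present.
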