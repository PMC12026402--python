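# Methods

## The problem

Megakaryocytes (MKs) are rare, very large, polyploid bone-marrow cells;
micromegakaryocytes (7–15 µm) are a dysplasia marker in myelodysplastic
neoplasms.  Identifying MKs by flow cytometry is confounded by their
size (they overlap doublets in area-based singlet gates) and by CD41⁺
platelets adhering to unrelated cells, which then display an MK-like
immunophenotype.  Imaging flow cytometry (IFC) records a multichannel
image of every event, so immunophenotypic gating can be combined with
morphometry and image classification.  `mkflow` implements that analysis
end to end: feature extraction, a hierarchical gating cascade, a linear
discriminant singlet gate, a CNN that rejects platelet-adhesion false
positives, and a two-class evaluation stack — exercised on a synthetic,
ground-truth-labeled event-image generator, because MK IFC image data
are not publicly deposited.

## Data model

An *event* is a set of co-registered per-channel rasters (120×120 px at
0.5 µm/px by default — a 60 µm field of view, the geometry of a 40x IFC
objective, which still accommodates the largest ~51 µm MKs).  Channels
are addressed by marker role through `PanelConfig`; the default layout
puts brightfield (BF) in Ch01, CD41 in Ch03, SSC in Ch06, CD45 in Ch08,
the dump pool (CD3/CD19/CD15/CD64) in Ch10, the DNA dye in Ch11 and the
viability dye in Ch12.  Pixels are 12-bit (0–4095) by default; the raw
bit depth of the instrument is not published, but the conventional
saturation cut at 4030 counts implies a 12-bit range, and the depth
remains configurable.  Vendor file formats are not parsed; galleries are
interchanged as multipage TIFF plus a plain `index.csv`
(`object_id,time_s,channel,file,page`), and feature tables export to CSV
and FCS 3.1.

## Morphometric features

Vendor feature formulas are unpublished; the definitions below are this
package's normative ones, chosen so the conventional thresholds keep
their meaning.

* **Default mask**: Otsu threshold on the σ=1 smoothed raster, hole
  fill, largest connected component.  A contrast guard rejects the
  "mask" of a signal-free raster (where Otsu merely splits noise and the
  pseudo-foreground percolates): the foreground mean must exceed the
  background mean by ≥ 4 background SDs.  **Morphology mask**: the
  default mask closed (disk 2) and eroded by 1 px — a tight boundary
  for size features.
* **Area** (µm²), **diameter** = 2·√(area/π) (µm; exact identity with
  area by construction), **aspect ratio** = minor/major axis of the
  second-moment ellipse ∈ (0, 1].
* **Raw max pixel**: maximum *uncompensated* pixel over the frame —
  saturation is a property of the raw acquisition, so this feature is
  never compensated.
* **Intensity**: background-subtracted sum over a 3-px dilation of the
  default BF mask (the dilation captures membrane spots sitting on the
  perimeter); background is the *median* of pixels outside the dilated
  mask, robust to stray platelet spots in the frame.  Floored at 0.
* **Gradient RMS**: RMS of central-difference gradients of the raster
  rescaled to [0, 100] by bit depth, averaged over the mask.  Constant
  rasters score 0; Gaussian blur strictly lowers it.  The [0, 100]
  scale is calibrated (through the synthetic BF texture, below) so the
  in-focus/defocused boundary sits near the conventional threshold 55.

## Synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Classes and mixture** (defaults): mk 0.35, micro_mk 0.05,
  platelet_adherent 0.15, lymphocyte 0.20, dead 0.08, anucleate 0.07,
  doublet 0.10.
* **Geometry**: MK diameters log-normal with median 22.5 µm (log-SD
  0.32) truncated to [10.5, 51.5] µm — the size statistics reported for
  enriched human marrow MKs; micro-MKs uniform on [7, 15] µm;
  lymphocytes 8–11 µm; other mononuclear hosts 9–16 µm; doublets are two
  touching discs with components drawn around 15 µm so the pair fits the
  field of view.
* **CD41 signal**: true membranes carry 8–24 spots (σ ≈ 1.5 px ≈ 2 µm
  spot size) on the mask-boundary annulus; platelet-adherent events
  carry 1–4 *brighter* off-perimeter spots (per-spot amplitude 3×
  membrane spots) — bright puncta are the visual signature of adherent
  platelets.
* **BF texture**: a phase-randomized period-4 XOR checker at near-full
  contrast.  A period-4 square wave has |central difference| = A/2 at
  every pixel, and XOR-ing two orthogonal waves makes both gradient
  components full amplitude, so in-focus events score gradient RMS ≈ 60
  while σ=3 defocus erases the period-4 component to RMS ≈ 3.  This is
  the calibration that places the focus boundary near 55; it was fixed
  once, before any acceptance run.
* **Immunophenotype amplitudes** (counts/pixel; no physical units are
  published for any channel, so these are free parameters documented
  here): gate-defining markers differ by ≥ 30× between the populations a
  gate must separate, because integrated intensities also scale with the
  ~25× spread in cell area.  Lymphocytes: CD45 2000, SSC 30, dump 600;
  MK classes: CD45 30, SSC 400, dump 1; dead: viability 1500 vs 4 for
  viable cells; nuclei: DNA 900 on a disc of 0.55× the cell radius
  (absent for anucleate events).  A shared per-event log-normal
  brightness jitter (σ = 0.25) correlates channels as staining
  efficiency does.
* **Camera model**: Poisson shot noise on signal + background (30
  counts) plus Gaussian read noise (SD 3), clipped to the bit depth.
  Saturated events receive a forced 3×3 patch at the ceiling; the
  ground-truth `is_saturated` flag is *recomputed from the final
  rasters*, so it is consistent with the pixels by construction.
* **Timeline**: 300 s acquisition; unstable-flow events are crammed
  into a 10 s window (elevated rate) while stable events avoid it, so
  the stable-flow gate has a genuine density anomaly to find.

What the generator does **not** emulate: real optics (no PSF), spectral
overlap at the pixel level, chromatin texture, ploidy-dependent DNA
content, cell debris, or the continuum of staining quality found in
patient samples.  Passing tests therefore demonstrate that the pipeline
machinery is correct and self-consistent under controlled conditions —
not that the specific thresholds would transfer to an instrument without
recalibration.

## Gating cascade

Gates run in the conventional order: stable flow → non-saturated → live
→ nucleated → lymphocyte exclusion → CD41⁺dump⁻ → singlet → focus → CNN.
(Live and nucleated are reported as separate stages of the one
live-nucleated criterion, giving per-cause attrition.)  Every gate's
criterion is evaluated for every event and the cascade is the running
intersection — so independent gates commute and the per-stage fractions
re-multiply exactly to the terminal fraction.

The original workflow placed most gates by visual inspection; `mkflow`
parameterizes each one in `GateConfig`:

* **Stable flow** (auto): origin-aligned 5 s bins; a bin is stable when
  its count is within 3 robust SDs (1.4826·MAD, floored at √median —
  the Poisson counting floor, so a flat stream is never fragmented) of
  the median; the largest contiguous run of stable bins is kept.  An
  explicit time window may be supplied instead.
* **Saturation**: keep events with raw max pixel strictly below 4030 in
  *every* used channel ("below 4030" is read as a strict inequality).
* **Intensity gates** (viability ≤ t, DNA > t, CD41 > t, dump ≤ t,
  CD45/SSC exclusion rectangle): "auto" thresholds use Otsu's method on
  log1p intensities with two safeguards.  First, a split only counts as
  bimodal when the two Otsu class means differ by ≥ 2 log units —
  integrated intensities of a *single* population already span more
  than a decade because cell areas vary ~25×, and without the guard an
  all-MK sample would be cut in half; when unimodal, the gate keeps
  everything.  Second, the threshold is placed at the geometric midpoint
  of the two class means (mid-gap) rather than at the raw Otsu cut,
  which for very unbalanced modes hugs the minority mode's edge.  Auto
  thresholds are frozen once, on the population surviving the
  saturation gate, then applied as fixed values.  The lymphocyte gate
  also accepts a percentile mode (75th CD45 / 25th SSC) for analysts
  who prefer that convention, but Otsu is the default: a percentile cut
  at 75% can never capture ≥ 90% of a subpopulation that exceeds 25%
  prevalence.
* **Singlet**: keep discriminant score ≥ 0 (below).
* **Focus**: keep BF gradient RMS > 55 (default).
* **CNN**: keep events the model calls CD41-membrane-positive; the
  stage is optional (skipped when no model is supplied).

An *oracle mode* drives every gate from the ground-truth table instead;
it validates the cascade plumbing and expresses the generator's
separability budget: on the constructed 100-event fixture (each event
failing exactly one gate) the survivor counts are exactly
90 → 80 → 70 → 60 → 45 → 35 → 25 → 15 → 5.

## Singlet/doublet discriminant

Large MKs overlap aggregates in a BF-area × aspect-ratio gate, so
singlets are separated from doublets by Fisher LDA over ten features —
{area, aspect ratio, diameter, gradient RMS, intensity} × {BF, CD41}.
(The exact feature list used by the original instrument software is not
published; this list is the package's documented, configurable choice.)
Features are standardized; the pooled within-class covariance is
ridge-regularized with λ = 10⁻³·tr(S)/p; the weight vector is
S⁻¹(μ_s − μ_d).  The offset puts the standardized class-mean midpoint
exactly at score 0, the sign convention makes singlets positive, and
the score is divided by the pooled within-class SD of training scores,
so the "keep score ≥ 0" gate is affine-invariant and scale-free.
Degenerate inputs (a class with < 2 distinct events, a zero-variance
feature) are errors, not silent fits.

## Platelet-rejection CNN

Architecture (64×64×2 input → three 3×3 conv blocks of 16/32/64 filters
with ReLU and 2×2 max-pooling → global average pooling → dense-2
softmax; ~23k parameters) is small by design: it trains on hundreds of
crops in minutes on one CPU.  Forward/backward passes are implemented
directly in NumPy (im2col convolutions, Adam, lr 3·10⁻³, batch 32);
training is a pure function of (data, spec, seed) and identical seeds
reproduce identical weights bit for bit.

Crops are the BF+CD41 pair, padded square (edge mode), resampled to
64×64 and min-max normalized per channel per crop — the CNN judges the
*pattern* of the CD41 signal; size is handled by morphometry.  Flips
and 90° rotations augment training by default, since flow-cell
orientation is physically arbitrary; loss weighting by inverse class
frequency is available.

Splitting is stratified per class with largest-remainder rounding (an
exact 80/10/10 is not generally achievable; realized fractions are
reported — e.g. a 610/92/92 partition of 794 objects realizes
76.8/11.6/11.6%).  Training stops when the train and validation
accuracy curves have stayed within 0.02 of each other for `patience`
(5) consecutive epochs, or validation accuracy has stalled for
`patience` epochs, whichever first — but not before `min_epochs` (10):
at initialization both curves sit together at chance, and a literal
"curves agree" rule would stop immediately.  The returned model carries
the best-validation-epoch weights.

## Evaluation

Two-class confusion matrices with exact integer counts; accuracy,
precision, recall and F1 as percentages; per-class rows plus
support-weighted averages (weighted on *unrounded* values — rounding is
presentation only, half-up, 1 dp in tables and additionally 2 dp for
accuracy); row-normalized (recall) and column-normalized (precision)
matrix views.  Metrics with zero denominators are reported as missing,
never as 0, so weighted averages are never silently inflated.

## Compensation

Spillover entry (i, j) is the zero-intercept least-squares slope of
channel-j on channel-i total intensity over single-stained control-i
events (≥ 30 required), clamped non-negative, diagonal 1.  Compensation
right-multiplies per-event intensity vectors by the matrix inverse; it
acts on scalar intensities, not pixels, because the gates consume
intensities — and raw max pixel is never compensated.  The exact "best
fit" convention of instrument software is unpublished; plain zero-
intercept least squares is the documented choice here.

## Problem sizes

Defaults used by the test suite and the acceptance script: galleries of
100–500 events (one 2000-event draw for the diameter-distribution
check), a 794-crop CNN benchmark (412 positive / 382 negative,
stratified 80/10/10), 28/52 singlet/doublet training events with 100
held-out doublets, and 500-event compensation controls.

## Known limitations

* The FCS writer/reader covers the list-mode float32 subset of FCS 3.1
  only; no installed library provides an independent FCS implementation,
  so the round-trip check exercises this package's own reader.
* Feature-mode auto thresholds assume each gated marker is either
  genuinely bimodal or absent; pathological mixtures (e.g. a sample that
  is *all* dump-positive) would be kept wholesale by the unimodality
  guard.
* The stable-flow rule keeps a single contiguous span; a burst in the
  middle of an acquisition costs the shorter good side as well.
* Synthetic separations are cleaner than patient data; published
  real-data accuracies are reproduced arithmetically from their printed
  counts, not re-measured on images, because no image data are deposited.
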