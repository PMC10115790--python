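# Methods

## Fragment chemistry and nomenclature

Double-bond positions are methyl-referenced (*n*-x) and bonds are indexed
from the methyl end; conversion from carboxyl-referenced Δ positions is
x = C − Δ. For a site (index *i*, position *n*-x) the aldehyde-channel
neutral loss from the intact precursor ion is C(x−1)H(2x−4−2(i−1)) — the
methyl-terminal C(x−1) hydrocarbon carrying i+1 degrees of unsaturation —
and the criegee-channel loss is one oxygen lighter (the fragment ion gains
the ozone-derived O). Because the aldehyde loss contains no oxygen, the
criegee loss cannot be expressed as a non-negative formula; neutral losses
are therefore represented internally as *signed* element deltas (the
criegee delta carries O: −1) while fragment and precursor formulas remain
strictly non-negative. Fragments retain the full adduct; adduct-loss
channels are not modeled. Pairs from different chains that collide in m/z
within 0.01 Da are flagged `chain-ambiguous`, never merged.

Candidate sites are enumerated per unsaturated chain with defaults
x_min = 2, minimum spacing 3 carbons (methylene-interrupted), deepest
position ≤ C − 2. For index *i* of *d* bonds the range is
[x_min + s(i−1), C − 2 − s(d−i)]; the test suite checks this against a
brute-force enumeration over all legal bond placements. Spacing 2 admits
conjugated systems and both are configurable (`min_spacing`, `x_min`).

Formula assembly: glycerophospholipid classes are head-group-alcohol cores
plus one fatty acid minus one water per ester; sphingolipids condense a
sphingoid base (d = dihydroxy, t = trihydroxy) with one N-acyl amide, plus
phosphocholine for SM. Deuterium labels ([Dy]- prefix) are tracked as a
count only and applied as an H→D substitution of the assembled formula —
the labeled standards carry the label on head group/backbone, outside the
chains OzID cleaves, and the count-only model keeps every mass relation
exact. Atomic masses are hard-coded from the IUPAC table at 6 decimals and
the electron mass is included in m/z (sub-mDa correctness at QTOF
accuracy).

## Isotope model

Theoretical M/M+1/M+2 abundances come from a multinomial expansion over
per-atom isotope choices restricted to ¹³C (1.07%), ¹⁵N (0.364%), ¹⁸O
(0.205%), ³³S (0.75%) and ³⁴S (4.25%); ²H/¹⁷O and shifts beyond +2 are
excluded, and label deuteriums are fixed atoms, not sampled. The
implementation convolves per-element shift polynomials truncated at +2,
which is exact for the reported triplet; the tests compare it against an
independent exhaustive isotopologue enumeration (relative error < 1e-6 for
lipid-scale formulas). Abundances are normalized to the largest of the
three isotopes (for lipid-scale formulas that is always M). M+1/M+2 m/z
values are abundance-weighted centroids of the contributing isotopologues,
matching what a centroiding QTOF reports; a charge of |z| divides the
spacing.

## Signal extraction

Chromatographic and spectral peaks are single Gaussians fitted by least
squares (scipy `curve_fit`), seeded at the local maximum nearest the
expected position with ties broken toward the higher maximum. Peak shape
was deliberately kept Gaussian rather than exponentially-modified Gaussian:
one fewer parameter, stable on sparse scans, and the cosine scores compare
shapes rather than depending on tail fidelity. An XIC with no positive
signal returns a distinct `no-peak` result; non-convergence returns `fail`
with the seed retained. Abundance is peak *height*, not area.

Saturation is detected by an intensity threshold (default 1e6 counts,
configurable — the mechanism matters more than the value, which is
instrument-specific). Unsaturated precursors take the MS1 window
mean ± k·σ (k = 1); saturated ones take the leading edge
[mean − 2σ, mean − σ], where the detector still responds linearly. On
simulated clipped peaks this reduces the median isotope-ratio error from
~40% to ~1% (the acceptance script recomputes this).

Default tolerances (all in the config, flat key=value file): XIC extraction
±0.02 Da, isotope-fit centroid acceptance ±0.05 Da, broad precursor RT
window ±2 min.

## Scoring and assignment

Both score axes are cosine distances (1 − cosine similarity) on
non-negative vectors, so they are scale-invariant; an all-zero vector
scores 1 by convention.

* Chromatographic: fragment and precursor XICs linearly resampled onto the
  union of their RT samples over [fit mean ± 3σ].
* Spectral: the raw RT-selected MS1 spectrum over M−1.5…M+2.5,
  interpolated onto a 0.01 Da grid (grid points farther than 0.02 Da from
  any observed point are zeroed so interpolation never bridges empty
  regions), against a theoretical spectrum of three Gaussians whose width
  comes from the fitted observed M peak (fallback 0.05 Da FWHM). Comparing
  the raw spectrum rather than re-fitted peak heights is deliberate:
  interfering peaks inside the window (e.g. the isotopes of a *different*
  fragment ~1 Da away) then count against the match instead of being
  fitted away, which is what kills one family of near-miss decoys.

A site is accepted when all four components (two axes × aldehyde and
criegee) are ≤ the cutoff (default 0.25), partial when exactly one
fragment passes both its components (flagged `criegee-missing` /
`aldehyde-missing` — partials are reported but never merged with full
acceptances), rejected otherwise. The composite ranking score is the mean
of available components plus 0.5 per wholly missing fragment; it is a
documented package choice (no canonical formula exists) and is isolated in
one function. Candidates are ranked per (chain, index) by ascending
composite, ties broken by ascending n-position. Precursor validation
reuses the spectral axis with the same cutoff (separately overridable).

## CNN classifier

Each candidate is rendered as a 3-channel pseudo-RGB image: channel 0
precursor, 1 aldehyde, 2 criegee; x = m/z over each ion's own M−1.5…M+2.5
window, y = RT over fit RT ± 2.5 min; sparse scans are 2D-linearly
interpolated to a uniform grid and each channel max-normalized to [0, 1].
Default image size is 32×32 — sufficient for the 3-peak × 1-peak structure
being classified and sized for CPU training — and configurable.

Augmentation resamples the RT axis only (shifts ±0.25/±0.5 min, width
scales ×0.7/0.85/1.15/1.3, one combined variant): 9 variants + the source
= 10 images per example, emulating shifted/narrower/broader peaks. The
train/validation split is 4:1, stratified by label at the *source* level,
with all variants of a source kept on one side (leakage guard).

The network is the classic 18-weighted-layer residual design (3×3 stem,
four stages of two basic blocks, global average pooling, 2-node head) at
width 8, implemented directly on numpy with im2col convolutions and
hand-written backprop (checked against numerical gradients in the tests).
Initialization is random (He); no pretrained weights are used or needed at
these image sizes. Training: Adam, learning rate 1e-3, batch 128, 8
epochs, cross-entropy weighted by inverse class frequency; the parameter
set with minimal validation loss is kept. Because only ~100–200 optimizer
steps occur, momentum-averaged batch-norm running statistics lag the
trained distribution and eval-mode inference collapses; the trainer
therefore recomputes the running statistics exactly over training batches
after every epoch (precise BN) before validating. Checkpoints are an
`.npz` parameter blob plus a key=value text sidecar. The DL decision is
reported alongside the heuristic (modes `heuristic`, `dl`, `both`), never
silently substituted.

## Simulator

`simulate_run` renders each planted lipid as a Gaussian elution
(FWHM 0.25 min) sampled at 2 Hz, with every ion's theoretical isotope
triplet drawn as Gaussian m/z profiles (FWHM 0.03 Da on a 0.005 Da grid).
True double-bond sites contribute co-eluting aldehyde (5% of precursor
apex by default; OzID yields are instrument-dependent) and criegee (×0.8)
signals at exactly the m/z the fragment predictor computes — the simulator
calls the same code path, asserted by test. Interference presets:

* `rt-shift-decoys` — decoy-site fragment pairs with correct envelopes but
  RT shifted 3–6σ (fails the chromatographic axis only);
* `isotope-decoys` — co-eluting interferers whose envelope sits one
  nominal mass low, so their M+1 feeds the decoy XIC while the spectral
  window shows a dominant wrong peak (fails the spectral axis only);
* `realistic` — 25% of decoy sites receive one of rt-shift / offset-envelope
  / ratio-scrambled interference (the last is a deliberate near-miss that
  produces honest false accepts), plus Poisson counting noise and uniform
  chemical-noise spikes.

Detector saturation is simulated by clipping at a configured level. A
fixed seed determines the run completely, down to the bytes of the HDF5
file (datasets are written without timestamps).

What the simulator does **not** emulate: tailing/fronting peak shapes,
ion-mobility profiles (a drift dimension is summed on read if present),
correlated chemical backgrounds, co-eluting isomer mixtures, secondary
ozonolysis products, and electronic noise structure. Passing tests
therefore demonstrate the pipeline's correctness and its decision logic
under controlled interference — not instrument-grade performance; the
realistic-preset accuracy is a property of these synthetic conditions.

## Validation workloads and problem sizes

The benchmarks module (used by tests and `scripts/acceptance.py`) runs:
fragment chemistry over 50 random species; isotope model vs enumeration
over 100 random lipid-scale formulas; fit recovery over 100 Poisson-noised
peaks at SNR ≥ 20 (median RT error < 0.02 min, median worst-isotope ratio
error < 3%); leading-edge vs apex windows over 50 clipped replicates; a
noise-free standard run (exactly the 3 planted sites accepted, 0 decoys);
a 10-lipid realistic-interference panel with 210 candidate sites
(heuristic accuracy ≥ 85% at the 0.25 cutoff); and CNN training on a
250-source corpus (2500 images after augmentation, ≥ 95% validation
accuracy after 8 epochs on one CPU). These sizes keep the full validation
run to a few CPU-minutes while exercising every stage.

## Known limitations

* Lipid-class registry covers PC, PE, PG, PI, PS, PA, DG, TG, LPC, LPE,
  Cer, SM; ether/oxidized subclasses, sn-position and cis/trans geometry
  are out of scope.
* Deuterium positions are not tracked (count only); a chain-attributed
  label would change fragment m/z for chain-labeled standards.
* No multi-peak deconvolution of co-eluting isomers — on instruments that
  is the role of the ion-mobility dimension, which this package collapses.
* MS2 scans and vendor raw formats are not read; inputs are mzML or the
  documented HDF5 run-store.
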