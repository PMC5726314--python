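# Methods

This note records the models, conventions and numerical choices behind
`twocolor_sfx`, in the order data flows through the pipeline.

## Geometry and conventions

The detector is a flat multi-panel stack read out as one assembled frame of
shape `(n_panels × 1024, 512)`; the deposited 8-panel frame is `{8192, 512}`.
Pixel coordinates are 0-based `(slow, fast)` with integer coordinates at
pixel centres. The lab frame has `z` along the incident beam, `x` along fast,
`y` along slow; the detector plane sits at `z = distance`. Panel offsets
default to a gapless stack (the real MPCCD has inter-panel gaps that are not
documented in the emulated schema) but are configurable in the geometry file.
Defaults: pixel size 0.05 mm (typical MPCCD scale; not stated in the source
schema), distance 51.03 mm, beam centre at the stack centre.

Scattering vectors use the crystallographic convention without the 2π factor:
`q = (ŝ − ẑ)/λ`, so `|q| = 2 sinθ/λ = 1/d`. The reciprocal basis `B` has
columns `a*, b*, c*` with `q_crystal = B·(h,k,l)`; an orientation `R` (proper
rotation, `R Rᵀ = I`, det +1) maps crystal to lab frame. Energy–wavelength
conversion uses `hc = 12.3984193 keV·Å`.

Orientations are only identifiable modulo the lattice point group: 422
(8 proper rotations) for tetragonal, 432 (24) for cubic. Reported
orientations are canonicalized to the symmetry-class representative with
maximal trace (lexicographic tie-break), and misorientations are always the
minimum over the group.

## Peak finding

A candidate is a local maximum above `threshold`. Its signal is integrated
over a fixed disc of radius `nms_radius` (default 3 px); the local background
is the median of an annulus (inner 4, outer 8 px) with a robust sigma of
1.4826 × MAD, giving

    SNR = (Σ disc − n_disc · bg_median) / (bg_σ · √n_disc).

The SNR criterion is conventionally named but rarely defined in processing
summaries; this integrated form with a threshold-independent disc was chosen
so that peak counts are provably monotone non-increasing in both `threshold`
and `min_snr` (a property the tests check). Positions are intensity-weighted
centroids of the background-subtracted disc; `min_pixels = 2` rejects
single-pixel noise; peaks are ordered by integrated intensity with
lexicographic position tie-breaks for determinism. A frame with strictly
more than 20 peaks is a hit.

Interest points serve features too faint to threshold (high-order powder
rings). Per panel, the image is Gaussian-smoothed (σ = 1 px, suppressing
single-pixel shot noise), a local background is taken as a 15 px box mean
(larger than a ring's width so the crest stands out), and every smoothed
local maximum with positive contrast is scored by difference (signal −
background) and ratio (signal / background). In the default `both` mode a
candidate's score is the *worse* of its two ranks, so the accepted set
exceeds the dynamic cut — the score of the rank-n candidate — in both
criteria simultaneously; exactly `n_per_panel` points are returned per panel
where contrast allows, with shortfalls flagged. A relative contrast floor
(10⁻⁹ of the panel's dynamic range) keeps numerical dirt from the separable
filters out of the candidate pool on noise-free images. The original
dynamic-acceptance rule is defined in an external supplement; this rank-based
formulation is this package's own documented choice.

Peak subtraction removes every candidate within `match_radius` (default 4 px,
between the matching scale and the 6 px integration radius; the removal
radius is not stated in the source) of any member of the removal set, in one
pass — idempotent, order-preserving, non-mutating.

## Spectral chain

The wide-range spectrometer camera (1024 dispersive × 512 non-dispersive
pixels) is collapsed by summation over the non-dispersive axis (any linear
scale is absorbed by the fitted amplitudes). The profile model is a constant
plus two Lorentzians; widths are FWHM — deposited width fields may follow
another convention, so this is stated prominently. The fit is
Levenberg–Marquardt least squares initialised from the two highest local
maxima separated by ≥ 30 px (prominence ≥ 5% of the dynamic range), with
`Peak1 < Peak2` enforced on output; fewer than two resolvable maxima trigger
a single-Lorentzian fallback reported with `converged = False`.

Calibration points pair the median wide-range line position of all shots
sharing one narrow-range reading (readings grouped after rounding to a 1 eV
quantum, reflecting the narrow spectrometer's coarser resolving power) with
that reading's energy; an ordinary least-squares line `E = c₀ + c₁·x` per
colour branch, with its validity range, converts fitted positions to
energies. Colour 1 is the lower-energy (~7 keV) branch, colour 2 the ~9 keV
branch, so `E₁ < E₂` always. Calibration shots are assumed single-colour.

## Powder distance

Ring radii follow `r = D·tan(2θ)`, `sinθ = λ/2d`, valid for `λ < 2d` and
`2θ < 90°` (a forward flat detector cannot record back-scattered rings;
spacings that violate either bound are recorded as absent). Silicon
d-spacings derive from `a = 5.431 Å` with diamond-structure extinctions
(111, 220, 311, 400, …). Interest-point radii are histogrammed in 2 px bins
around the configured beam centre (the centre is an input, not jointly
fitted); the `n_rings` most prominent modes with ≥ 20 supporting points are
refined by the median radial distance within ± one bin. Because `r` is linear
in `D` at fixed `(d, λ)`, each contiguous ring-to-spacing alignment has the
closed-form solution `D = Σ rᵢtᵢ / Σ tᵢ²` with `tᵢ = tan(2θᵢ)`; the
alignment with the smallest relative residual wins, alignments all leaving
> 20% residual raise a matching error, and the uncertainty is propagated
from the fit residuals.

## Reflection prediction and known-cell indexing

Prediction enumerates all `(h, k, l)` with `d ≥ resolution_cutoff`
(default 1.9 Å, the data's stated resolution) whose relative excitation
error `(|q + k_in| − k)/k` lies within `bandwidth_tolerance` (default 0.3%,
a typical SASE bandwidth), then intersects scattered rays with the detector
plane; an exhaustive hkl-box oracle checks this in the tests. The index
bound per axis uses the duality relation `h = a·q`, so `|h| ≤ |a|·q_max`.

Indexing against the known cell works on the strongest ≤ 40 peaks mapped to
scattering vectors. Candidate orientations come from *pairs* of observed
vectors matched to reciprocal-lattice vectors by length (tolerance: the
bandwidth plus a q-space equivalent of the 4 px match radius) and mutual
angle; pair seeds are chosen by farthest-point sampling in direction space
(8 peaks, up to 15 pairs) so near-collinear pairs never arise, and the
anchor side of each pair is restricted to one representative per symmetry
orbit. Candidates are scored by how many observed vectors land within the
q-tolerance of a lattice point (a two-stage count with a 12-observation
prefilter); a candidate explaining ≥ 80% of observations stops the pair
search — the bar is deliberately above the ~50% a pseudo-symmetric
near-miss can reach. The best-scoring candidates, spaced ≥ `coarse_step`
(3°) apart modulo symmetry, are refined by iterated nearest-lattice-point
assignment and closed-form Kabsch alignment (≤ 50 iterations, 10⁻⁴ °
convergence), then polished in *detector* space: observed vectors sit
exactly on the Ewald sphere while predictions are off it by the excitation
error, so pure q-space alignment is slightly biased; a soft-L1
least-squares rotation update on matched position residuals (scale 1 px,
two rounds with re-matching) removes it. Final scoring is a greedy
one-to-one peak↔prediction match within `match_radius`, deterministic under
(distance, peak index, prediction index) ordering; the tests bound its gap
to the optimal assignment.

Two safeguards make failure a value rather than a wrong answer. First, a
chance-match verification: a random or contaminated peak list accumulates
`μ = n_peaks · n_preds · πr²/area` matches by accident, so solutions scoring
below `max(min_matched, 4μ)` are rejected (with `min_matched = 10`).
Second, indexing-ambiguity resolution: the lysozyme cell has `c = 39.1 Å`
within 0.2% of `a/2`, so a 90°-rotated lattice explains about half the
observations within tolerance — a classic special-ratio ambiguity. Rotations
approximately mapping the reciprocal lattice onto itself are computed once
per cell (by matching the reciprocal basis vectors against equal-length
lattice vectors and keeping operations where ≥ 25% of a low-resolution shell
coincides); the winning solution is re-refined through each partner and the
one explaining the most peaks is kept.

This candidate-generation strategy replaces a quasi-uniform 3° grid over
the 422 asymmetric domain: covering SO(3)/8 at 3° dispersion needs on the
order of 10⁵ orientations, and scoring each by full Ewald prediction is
hours per event in vectorised numpy, whereas pair matching proposes
orientations only where the data supports them. The 3° figure survives as
the spacing of candidates carried into refinement.

## Two-colour processing

Step 1 finds peaks at strong settings and indexes them at *both* colours;
the higher-scoring colour is declared strong (score is the robust proxy for
"brighter": the brighter pattern is the one the indexer can explain; a
raw-intensity choice would be misled by the colour-blind peak list). Step 2
finds peaks at weak settings and subtracts everything within 4 px of the
strong solution's predicted reflections. Step 3 indexes the residual at the
other colour with the match radius widened to the 6 px integration radius.
Statuses are `none` / `strong_only` / `both`; the residual is recorded (and
written as `residual_points_7keV/9keV`) whether or not step 3 succeeds.
With `subtract=False` step 3 runs on the unsubtracted weak-settings list —
the ablation baseline, where the search list is dominated by the strong
pattern and the weak colour mostly fails honestly (the verification gate is
what keeps it from "succeeding" spuriously there). The brighter colour is
decided per event; whether the original processing fixed it per run is
ambiguous, and per-event is the stricter reading.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions: the tetragonal lysozyme cell,
7/9 keV colours with 0.3% bandwidth and 0.05% per-event energy jitter, one
shared random (Haar-uniform) orientation per event, anti-correlated
amplitudes `a₁ + a₂ = 12000 ± 5%` counts with the split fraction uniform on
(0.3, 0.7) — both colours usually indexable, the dimmer one needing the
lowered thresholds, mirroring that roughly half the 9 keV-indexable deposit
yielded a second colour — Gaussian spots of σ = 1.2 px whose integrated
intensities are amplitude × Exp(1) draws (Wilson-like, fixed per `(h,k,l)`
per event via a splitmix-style hash so renders are reproducible
vector-wise), Poisson background of 5 counts/pixel, silicon rings of crest
intensity 50 with σ = 1.5 px, and spectra placed on the camera through the
inverses of the canonical calibration lines. The 12000-count budget and
5-count background were chosen so the published thresholds (200/SNR 5,
150/SNR 3) sit meaningfully between typical strong and weak spot amplitudes;
all were fixed a priori as the package's study conditions.

Not modelled: real structure factors, polarization and absorption, detector
gain maps and panel gaps, twinning, multi-crystal shots, the physical
dispersion of the spectrometer optics, and the true anti-correlation law of
the split undulator (the linear-sum model is a labelled stand-in). Passing
tests therefore demonstrate the *processing logic* — recovery of known
truth under realistic counting statistics — not detector-calibration
fidelity on real frames. Desk-scale runs use a 2-panel (2048 × 512) centred
subset of the detector for the two-colour batches and the full 8-panel
frame wherever a count depends on it (interest-point totals, powder rings);
batch sizes are 200 events for the two-colour study, 100 spectra, and 50
seeds for the powder Monte-Carlo.

## File formats

Event files are single-event HDF5 with the deposited field names (`data`,
`photon_energy_ev[_color1/2]`, `photon_wavelength_A[_color1/2]`, `poi`,
`pca_peaks/<n>`, `residual_points_7keV/9keV` as `{n, 3}` slow/fast/intensity
arrays); peak coordinates are assembled-frame (the deposit does not state
panel-local vs assembled; assembled is this package's convention,
documented here). Spectra files carry `spectrum {n, 1024}`, the seven fit
parameters and `tags` linking rows to event identifiers. Scalars are true
HDF5 scalars. Multi-event containers group events under `/events/<tag>`
(the deposit's internal grouping is not specified; a plugin reader can
replace `split_events` for the real format), and synthetic ground truth
lives in a separate `.truth.h5` sidecar, never mixed into the emulated
schema. All event-file writes go through a temp-file-then-rename so partial
failures never corrupt an event. Geometry and cell descriptions are
key = value text files; pipeline configuration is YAML.

## Known limitations

* The indexer assumes the cell is known; cell refinement is out of scope.
* Flat, untilted detector only; no ellipse fitting for tilted geometries,
  no per-panel distances.
* The beam centre is trusted from the geometry file in the powder fit;
  joint centre+distance refinement is not enabled.
* Greedy matching is near-optimal, not optimal (the tests bound the gap).
* The ambiguity search probes pairs of reciprocal basis vectors; ambiguity
  operations that move *no* basis vector near a lattice vector would be
  missed (none exist for the cells used here).
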