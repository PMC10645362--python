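# Methods

`crscreen` implements the quantitative core of a genome-scale colony-array
screen for *E. coli* mutants deficient in sub-MIC antibiotic biofilm
stimulation, read out as Congo Red (CR) binding of pinned colonies, together
with the plate-reader and disc-diffusion calculations used to follow up
screen hits. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic data do and do not establish.

## The screen statistic

Each plate carries a pinned array (by default 1536-density, 32 x 48) of
single-gene knockouts on CR agar with a sub-MIC antibiotic. Two per-colony
quantities are measured from an RGB scan:

* **growth** — colony density: background-subtracted mean foreground
  intensity weighted by the colony's effective area relative to the nominal
  colony footprint pi*r^2 (equivalently, integrated background-subtracted
  intensity over the measurement window divided by pi*r^2). This is
  monotone in both colony size and opacity.
* **red_intensity** — mean red-channel value inside the colony mask, minus
  the plate background: the CR-binding readout.

Positional artifacts (edge effects, pinning pressure) are modelled as
separable multiplicative row x column factors and removed by
interquartile-mean (IQM) normalization: each value is divided by the IQM of
its column, then by the row IQM of the column-normalized values, applied
identically to growth and red intensity. The IQM is the fractional-weight
25%-trimmed mean — sort, discard n/4 observations from each end, giving
fractional weight to the boundary observations when n is not divisible by
4 — and is robust to exactly the low-CR mutants the screen seeks. For
separable multiplicative effects the two-pass correction cancels the
gradients identically (verified to 1e-9); a typical colony lands at
normalized growth ~ 1 and normalized CR ~ 1.

The per-strain statistic is the **enrichment value** = normalized CR /
normalized growth. Hits require concordance of two independent replicates
under either rule:

* **sd rule** — enrichment at least k = 2 sample standard deviations below
  the replicate mean, in both replicates. Mean and sd are computed per
  replicate across all non-excluded strains plate-set-wide (global rather
  than per-plate; configurable).
* **threshold rule** — enrichment below 0.5 in both replicates; strains
  with normalized growth below 0.2 are excluded as small-colony false
  positives. The exclusion triggers on *either* replicate by default (the
  conservative reading; `growth_rule="both"` gives the alternative).

Strains missing a colony in either replicate are reported as no-call,
never as hits. Multi-antibiotic hit lists are intersected with exclusive
Venn semantics (region counts sum to the union). The replica plot omits
points with enrichment above 4 in either replicate *from the display
only*; the written table and all statistics are uncapped.

### A note on idempotence

The normalization is a single column-then-row pass, matching the described
procedure. After the pass, row IQMs are exactly 1 but column IQMs are not
(the row division perturbs them), so re-normalizing a generic plate is not
an exact no-op; it is exact on plates whose positional structure is
separable (including every plate the generator produces). The test suite
asserts exact idempotence in the separable case and a strong contraction
(second-pass changes well under half the first-pass correction) in general.

## Synthetic data

The generators produce every input the pipeline consumes, with ground
truth, under a single integer seed (bit-reproducible).

**Colony arrays** (`PlateSpec`): flat-top disks with a 1-px anti-aliased
edge on a constant agar background (default 30/255) — the simplest shape
whose integrated intensity is analytically the disk area times the plateau
value, which is what makes quantification exactly checkable. Defaults:
spacing 20 px, colony radius 7 px, colony green/blue level
background + 150, red level background + 170, separable row/column
gradient factors, planted stimulation-deficient mutants as
(redness_multiplier, growth_multiplier) pairs, Bernoulli missing
colonies, additive Gaussian pixel noise. Replicate pairs share planted-hit
identities but draw noise and missing colonies independently (seeds are
SeedSequence children), mirroring a duplicate screen pinned from two
source plates. For multi-plate screens at realistic scale (3,808 strains
across three 1536 plates) a value-level generator emits ColonyTable pairs
directly with multiplicative measurement noise (default CV 10%) and
per-plate gradients uniform in [1/1.5, 1.5] — the regime used for the
planted-hit recovery benchmark (60 plants at true enrichment 0.3, 30
seeds), which runs in seconds where full rendering would add nothing to
what the single-plate image tests already establish.

**Dose responses** (`DoseSpec`): a 2x serial dilution series (8 dilutions,
top dose 2 x MIC) with growth declining as a Hill sigmoid with midpoint at
the MIC (slope 4) and biofilm following
`b0 * (1 + A * exp(-(log2(c / (peak_frac * mic)))^2 / (2 * stim_width^2)))`
— a log-concentration Gaussian peaking at `peak_frac * MIC` (default 1/4)
with fold increase `A = 3` and width one dilution, reproducing the
sub-MIC stimulation pattern in which biofilm peaks where planktonic growth
has barely begun to fall. A nitrate flag multiplies `A` by
`nitrate_suppression` (default 0.2). Tables include vehicle wells and a
sterile-media row H, with media blank offsets on every readout, laid out
as a 96-well plate with technical triplicates.

**Disc-diffusion plates** (`DiscSpec`): radially symmetric green channel —
bright paper disk, near-zero zone of inhibition out to `zoi_radius_px`,
lawn outside, and an optional Gaussian dark ring (depth 60, sigma 6 px)
centered at `ring_radius_px`, placed just beyond the ZOI periphery where
surviving cells at sub-MIC exposure upshift respiration and deposit
formazan. `ring_depth = 0` models a drug that never produces the ring.

What the generators deliberately do **not** model: colony morphology
(texture, domes, sectors), agar artifacts (bubbles, glare, uneven
illumination beyond a scalar background), optical blur, plate-to-plate
focus differences, non-separable positional effects, or antibiotic
chemistry. Passing tests therefore demonstrate that the *calculations* are
correct and that the pipeline recovers known signal under controlled
noise; they do not certify segmentation robustness on real scanner output.

## Image analysis choices

* **Grid finding**: foreground intensity is projected onto each axis;
  periodic peaks are detected, refined by local centroids, and a regular
  line spacing is fitted by least squares, so individual missing colonies
  inherit interpolated centers. A blank or drastically under-grown plate
  raises `GridNotFound`.
* **Thresholding**: per-position windows (colony radius + 2 px) are
  thresholded by Otsu when the window shows real contrast; otherwise the
  midpoint between plate background and window maximum, floored several
  noise sigmas above background so pixel noise cannot fabricate colonies.
  Presence requires 5% of the window above threshold. Intensity means use
  the mask eroded by 1 px to avoid anti-aliased edge dilution; colony area
  is coverage-weighted (integrated intensity over plateau level), which
  recovers the true disk area rather than the binary pixel count.
* **Background**: median of the inter-colony agar region, per channel;
  its MAD sets the noise floor.
* **Growth's area term** is referenced to the nominal colony footprint
  pi*r^2 (not the window area): referenced to the window it would be a
  constant geometry factor carrying no information, and noise-free
  recovery of the generator's planted values would be biased by exactly
  that factor.
* **Radial profiles**: green channel; rolling-ball-style background
  removal implemented as greyscale opening with a large flat structuring
  element (separable min/max filters, default half-width 150 px — removes
  offsets and smooth illumination without touching ring-scale features);
  linear contrast stretch saturating 0.35% of pixels; annular averaging in
  1-px bins from the disk edge (a single-ray mode is provided for direct
  comparison with line-profile measurements). The first 2 px beyond the
  disk edge are skipped so the disk's bright rim does not contaminate the
  profile. The ZOI boundary is the first distance where intensity exceeds
  half the far-field plateau (median of the outer 20% of bins); the
  formazan ring is the interior local minimum beyond the boundary with the
  greatest depth below the plateau, requiring at least 10 intensity units.
  Depth is measured against the plateau rather than as two-sided peak
  prominence because a ring hugging the ZOI periphery — the constructed
  regime — has its inner flank swallowed by the inhibition step.
* Scanner resolution is configurable (`px_per_cm`); distances are reported
  in pixels unless it is supplied.

## Plate-reader calculations

Sterility (uninoculated media) well means are subtracted per condition;
negative corrected values clamp to zero with a warning. Percent of control
is the treated mean divided by the matched vehicle mean times 100, per
concentration, separately for growth (OD600) and biofilm (crystal violet
A600); "matched" means same strain, same condition/nitrate status. Maximum
stimulation is the concentration with the highest mean biofilm percent
(ties break toward the lower concentration — sub-MIC-conservative; ties do
not occur in practice). The nitrate fold change divides the nitrate-treated
maximum by the no-nitrate maximum. Reporter normalizations: RFU =
sterility-corrected GFP / OD600; relative change = RFU over the
promoterless strain's RFU in condition- and concentration-matched wells;
NADH signal = GFP / (mCherry x OD600), computed on raw values by default
(blank subtraction for this ratiometric reporter is opt-in, since the
ratio largely cancels additive offsets and the protocol for it does not
specify subtraction); nitrate-reduction index = sterility-corrected A546 /
corrected OD600. Significance testing (ANOVA with multiple-comparison
corrections) is out of scope and left to standard statistical tools.

## Known limitations

* Bit-compatibility with the original ImageJ macro is not claimed; the
  thresholding and background operations are documented choices, not a
  port.
* Pixel values clip at 255: gradients times base levels exceeding the
  8-bit range break multiplicativity by construction, so quantitative
  image tests use base levels that keep the brightest colony in range.
* The published screen's supplementary data table is not redistributable;
  the hit-overlap reproduction against it runs only when the user places
  the file under `data/` (see README), and the corresponding test fails
  with an explanatory message otherwise.
* The grid finder assumes an axis-aligned array; rotated scans should be
  deskewed upstream.
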