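# Methods

## Problem and model

During serial femtosecond crystallography, a micro-jet of mother liquor
carries crystals through the focus of an X-ray free-electron laser. A side
microscope watches the jet in backlit (shadowgraph) geometry at ~10 Hz, one
frame per pulse train. When a pulse intersects the jet it blows a visible
gap in the liquid column near the interaction point; when it misses, the
column runs unbroken from the nozzle until its natural Rayleigh breakup into
droplets much farther downstream. `jetvision` classifies each frame as
*hit* or *miss* from that signature, with five deterministic stages:

1. **Nozzle localisation.** The nozzle silhouette is the one stable
   landmark, so it is located by template matching. Similarity is the
   zero-normalised cross-correlation coefficient (ZNCC): template and image
   window are mean-subtracted and scaled by their standard deviations, which
   makes the score invariant to affine intensity changes and hence robust to
   illumination drift. Ties break to the first maximum in row-major order.
   Because nozzle and background stay put over a run while the jet moves,
   the match from the first frame is cached and reused
   (`rematch_every = k` re-runs it every k frames if wanted).
2. **Region of interest.** A box anchored at the matched tip — default
   400 px downstream and ±100 px laterally — is cropped out; all later
   stages see only the crop. The default is deliberately much larger than
   typical breakup lengths so one setting serves many nozzles.
3. **Binarisation.** Each ROI pixel is compared to the Gaussian-weighted
   mean of its W×W neighbourhood minus an offset C (defaults W = 13, C = 7
   on the 16-bit scale). The *local* threshold absorbs slow illumination
   non-uniformity. Polarity: the raw jet is dark on a bright background, so
   with the default `dark_jet` setting a pixel is jet (mask value 1) when it
   is darker than its local mean by more than C.
4. **Break scan.** Row 0 of the mask is the nozzle tip row. A row "contains
   jet" when it holds at least `min_run` (default 2) contiguous jet pixels —
   single salt-noise pixels do not count. A maximal band of jet-free rows is
   a *break* iff it is bounded by jet rows above and below, spans at most
   `max_gap_px` rows (default 20) and its upstream edge lies within
   `max_break_distance_um` of the tip (default 200 µm). The distance rule is
   what rejects the spontaneous droplet region, which in addition is never
   bounded from below. A frame with no jet rows at all is flagged `no_jet`
   and classified miss (calling it a hit would turn every unstable-jet frame
   into a false positive).
5. **Instance decisions.** Frame verdicts are pooled over a sliding
   first-in-first-out window of `sma_window` frames (default 10, i.e. 1 s at
   10 Hz): any hit in the window marks the instance as hit. Decisions are
   causal (frame k uses only frames ≤ k); before the buffer fills, the
   partial window is used, preserving "any hit ⇒ hit" from frame 0. A
   `tumbling` mode emits one decision per disjoint 10-frame block instead.

Evaluation forms TP/TN/FP/FN against manually- or synthetically-labelled
truth and summarises agreement with the Dice coefficient
`2TP/(2TP+FP+FN)`, which ignores true negatives by design. Instance-level
scoring applies the same trailing-OR window to both series first. The
degenerate all-negative case returns 1.0 (perfect agreement) with a
warning. Run summaries use the sample standard deviation (n−1) and linearly
interpolated quartiles.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `pixel_size_um` | — (required) | µm/px | converts the 200 µm rule to rows; no sane default exists, so it must be supplied |
| `threshold_window` W | 13 | px | local-mean window; odd |
| `threshold_offset` C | 7 | counts (16-bit) | margin below the local mean that defines "jet"; see below |
| `threshold_sigma` | 0.3·((W−1)/2−1)+0.8 | px | Gaussian width of the weights; the conventional window-to-sigma mapping of imaging toolkits, stated here so results are reproducible |
| `max_gap_px` | 20 | px | tallest band accepted as a beam-induced break |
| `max_break_distance_um` | 200 | µm | upstream-edge distance limit that excludes droplet breakup |
| `min_run` | 2 | px | contiguous jet pixels needed for a row to count as jet |
| `sma_window` | 10 | frames | FIFO width; 1 s at 10 Hz |
| `roi_length_px` / `roi_halfwidth_px` | 400 / 100 | px | ROI extent downstream / lateral |

**Choosing C.** C must exceed the noise floor of `pixel − local mean`
(approximately the per-pixel noise sd, since the Gaussian mean is much less
noisy) while staying far below the jet contrast. C = 7 suits low-noise
16-bit imagery; for noisier data a 3-sigma rule `C ≈ 3·noise_sd` keeps the
per-pixel false-jet probability near 10⁻³ without touching real jet pixels,
whose contrast is typically tens of thousands of counts. The noisy
synthetic runs in the test suite and acceptance script use exactly that
rule (noise sd = 3 % of full scale ⇒ C ≈ 5900), fixed a priori from the
known noise level.

Numerical choices: the local mean is a separable float64 correlation with
half-sample symmetric ("reflect") borders — the edge row/column is
repeated, avoiding spurious edge breaks. ZNCC is computed with an FFT
numerator and integral-image window sums; window sums can go slightly
negative from roundoff and are clipped at zero, and windows whose sum of
squared deviations falls below `eps · image_size · max²` are treated as
flat and scored 0 (a flat window carries no evidence either way). Scores
are clipped to [−1, 1]. The 200 µm rule is applied to the gap's *upstream*
edge, the conservative reading. A clipped ROI smaller than max(W, 32) in
either dimension is a location error rather than a silent degenerate crop.

## Synthetic scenes

No experimental imagery ships with the method, so the generator renders the
phenomenology end to end: a dark tapering nozzle silhouette (the same
raster used by the default matching template, so a noiseless render matches
it with score exactly 1), a dark jet column of a few pixels' width with a
configurable angle, spontaneous droplet breakup beyond `breakup_length_um`
(default 350 µm at 1 µm/px), and, on hit frames, a full-width gap of
`break_gap_px` rows centred `break_center_um` below the tip plus optional
splatter speckle. Nuisance effects: a linear illumination ramp and additive
Gaussian noise. Sequences support exact label control (a literal pattern,
or a hit fraction realised as exactly `round(f·n)` hits placed by a seeded
shuffle) and per-frame jitter of jet angle and lateral nozzle position.
Identical parameters and seed render bit-identical frames.

Two modelling choices are worth flagging. Splatter is a seeded speckle of
dark 3×3 dots in a disc around the break, *excluding* the gap band itself —
a phenomenological stand-in for material ejected out of the void, which
also guarantees the rendered gap survives binarisation and the break scan
on noiseless frames. And the droplet pattern is part of each frame's seeded
random stream, so zero-jitter sequences are identical only above the
breakup point.

What the generator does **not** emulate: real explosion hydrodynamics,
partial hits ("necking" at the jet edge), unstable jets with collapsing
breakup length, motion blur, vignetting or structured camera noise.
Passing tests on these scenes therefore demonstrate the correctness of the
decision rules and their composition, not field performance on beamline
data; partial-hit and unstable-jet sub-classification are out of scope
here.

## Problem sizes and conditions in the checks

The end-to-end checks use 400-frame sequences at 448×320 px, 50 % hits,
1 µm/px: one noiseless run under the default settings (expected Dice
exactly 1.0, zero FP/FN), one with noise sd = 3 % of full scale plus jet
jitter (angle sd 1°, lateral sd 2 px) under the 3-sigma offset rule
(expected Dice ≥ 0.95), and a 100-frame "beam-off" run whose breakup length
is 260 µm — beyond the 200 µm rule — where any detected hit would be a
false positive (expected: none). Stage-level checks compare against
independent brute-force oracles: per-pixel thresholding on 100 random
64×64 images, ZNCC argmax on 50 rendered scenes (plus a 2 %-noise
localisation tolerance of ±1 px), a 30×30 gap-width × distance boundary
grid plus 1000 random profiles, and all 2¹⁰ ten-frame patterns plus 100
random length-200 streams for the FIFO window.

## Known limitations

- The optical scale (µm/px) of the original instrument is not public; all
  µm-valued defaults assume the user supplies their own `pixel_size_um`.
- Exact Gaussian sigma and border handling of the original implementation
  are unstated; the choices above are fixed and documented instead.
- The scan axis is rows (vertical jet); `scan_axis: columns` transposes
  incoming frames, and expects a template oriented for the transposed view.
- Throughput is logged but not guaranteed; real-time behaviour depends on
  hardware.
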