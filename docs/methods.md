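# Methods

## The measurement model

A ratiometric FRET experiment observes, per cell and per acquisition cycle,
two fluorescence images — donor emission and acceptor emission — and reduces
them to a single dimensionless number. `multifret` implements the simplest
and most widely used estimator:

1. **ROI mean.** For a signal region of interest (one cell) with pixel set
   {xᵢ, i = 1..n}: F̄ = (1/n) Σ xᵢ. Sums are accumulated in float64
   regardless of camera bit depth.
2. **Background correction and ratio.** With a background ROI measured on
   the same frame in each channel,
   FRET = (F̄_donor − F̄_donor bg) / (F̄_acceptor − F̄_acceptor bg).
   The acceptor/donor orientation is the reciprocal arrangement; the config
   must state one, because sensors differ (Epac-family sensors lose FRET on
   cAMP binding, AKAP79-CUTie gains it).
3. **Plateaus.** P_base is the mean of the last `window` (default 10)
   defined ratio points strictly before the first stimulant addition;
   P_stim for each stimulant uses the boundary of the next addition, and the
   final stimulant uses the tail of the trace.
4. **Change and normalization.** C = (P_base − P_stim)/P_base;
   % FRET shift = 100 · C_stim / C_max, with C_max from the designated
   maximizer event.

### Conventions and their rationale

* **Background is a per-channel ROI re-measured every frame**, not a fixed
  scalar. This absorbs slow lamp drift and constant camera offset; the
  subtraction makes the ratio exactly invariant to adding a constant to all
  pixels of one channel (tested property).
* **"Before adding" is strict** (`time < event time`): the addition frame
  may already contain response.
* **Plateau windows count defined points only.** A transiently lost or
  degenerate frame becomes a missing value (NaN) and does not silently
  shrink the 10-point average; a shortfall is logged with the count used.
* **The final plateau uses the trace tail.** The protocol ends on the
  maximizer plateau; no terminating marker is required.
* **Degenerate frames do not abort a run.** A non-positive corrected
  denominator yields a missing value plus a warning (a transient artifact
  must not kill an hour-long live acquisition); a negative corrected
  numerator is computed as-is with a warning.
* **Maximizer shift is exactly 100.** The shift is computed as
  `100 * (C_stim / C_max)`, so for the maximizer the quotient is the IEEE
  exact 1.0.
* **Saturated pixels** (at the integer bit-depth maximum) are included in
  means but counted; a per-ROI saturation fraction above a threshold
  (default 1 %) triggers a warning, since a silently clipped mean is worse
  than a warned one.

## Beam-splitter geometry and registration

Full camera frames are partitioned into half-open quadrant blocks, indexed
row-major from the top-left; ROI masks live in sub-image (post-split,
post-registration) coordinates so they need no quadrant bookkeeping.
Channel registration is **integer-pixel only**: sub-pixel registration
would interpolate raw counts before averaging, biasing the ratio. Offsets
are undone by an integer shift, and all channels are cropped symmetrically
by the maximum offset magnitudes so they share one size. The offset
estimator is an exhaustive normalized cross-correlation over a small search
window (default ±16 px), with ties broken toward the smallest displacement;
it exists as an optional aid and the default offsets are (0, 0).

Pre-split acquisitions (separate per-channel stacks) bypass the splitter
entirely, including registration.

## Streaming ≡ batch

Live analysis extends every trace by one point per stage cycle.
`compute_traces` is implemented as repeated single-cycle `update_traces`
calls, so batch and streaming run the identical floating-point code path
and produce bitwise-identical traces — a structural property, not a
tolerance. A cycle must cover all positions and arrive in order; the `watch`
command tolerates corrupt frames by recording missing values.

## File formats

* **Stacks**: three declared dialects — one multipage TIFF per position
  (`stack`), one OME-TIFF with a series per position (`ome`), or a
  directory per position with one TIFF per frame (`frames`, what `watch`
  polls). The dialect is always declared in config, never guessed.
* **Timestamps**: an optional `timestamps.json` sidecar (position →
  seconds) is preferred; otherwise timestamps are synthesized as
  `frame_index × interval`. Non-monotonic timestamps are an error naming
  the offending frames.
* **Events**: CSV `label,time_seconds,is_maximizer`. If no row is flagged,
  the last event becomes the maximizer with a warning (the saturating dose
  is conventionally added last).
* **ROIs**: JSON per position; rectangles (`row0,col0,height,width`,
  half-open) or run-length masks, signal ROIs named per cell plus one
  background ROI per channel or a shared one.
* **Traces**: one CSV per position with time plus five columns per ROI
  (donor mean, donor background, acceptor mean, acceptor background,
  ratio), written with 17-significant-digit formatting so stored doubles
  round-trip exactly.
* **Workbook**: xlsx with one raw sheet per position plus a summary sheet.
  With a template, only the reserved raw-data sheet is cleared and refilled
  (stacked positions, a position column) and the summary sheet rewritten;
  all other sheets — user formulas, charts — are untouched.

## The simulator

The simulator emulates what the analysis needs from real data and nothing
more: elliptical cells (~100 px, jittered geometry and brightness) on a
uniform background, a designed ratio trajectory

r(t) = baseline_ratio · Π over past events e of (1 + Δₑ·(1 − exp(−(t − tₑ)/τ)))

with mono-exponential transitions (τ = 0, the default, gives instant
steps — the analysis consumes plateaus only), reciprocal donor/acceptor
modulation (donor up, acceptor down, or acceptor-only via a flag),
per-pixel Poisson or Gaussian noise, optional photobleaching that
attenuates both channels equally (and therefore, by design, cancels in the
ratio), and a constant background offset.

Default conditions: 2 positions × 3 cells × 60 frames at 10 s intervals,
background 100 counts, acceptor amplitude 900 counts (≈1000-count cell
pixels, typical of a 16-bit sCMOS exposure), baseline ratio 2.0, ISO-like
event Δ = −0.2 at 200 s and an IBMX-like maximizer Δ = −0.375 at 400 s, so
the designed ISO response is 40 % of maximal.

Noiseless renders store continuous expected intensities as float64 TIFF
pages rather than quantized integers, so the zero-noise round trip through
the full pipeline recovers r(t) to floating-point rounding; noisy renders
quantize to uint16 as a real camera would. The trace-only fast path applies
noise to the four stored channel means (Gaussian σ in counts, or the
shot-noise standard error √(λ/n) for the Poisson model) and then computes
the ratio from those means, so even noisy traces satisfy the invariant that
the stored ratio is recomputable from the stored means.

Ground truth records both the designed asymptotic % shifts and the shifts
obtained by applying the pipeline's own plateau rule to the noiseless
trajectory; recovery experiments score against the latter, which isolates
the effect of noise when τ > 0 leaves residual kinetics inside the
averaging window.

**What the simulator does not emulate** — and what passing tests therefore
do not demonstrate about real data: optical point-spread, focus drift, cell
movement and shape change, spectral bleed-through between channels,
flat-field inhomogeneity, and autofluorescence. The pipeline itself applies
background correction only; bleed-through and flat-field corrections are
out of scope by design.

## Problem sizes in validation

The validation suite uses deliberately small scenes chosen to exercise
every code path while keeping runs fast: 64×64 quadrants, ~100 px cells,
60-frame runs, 25 positions for the streaming-equivalence check (the
throughput scale the tool targets), 50 seeds for the Poisson recovery
experiment and 12 paired seeds per level of the noise-monotonicity grid.
The statistics do not depend on image size beyond ROI pixel counts.

## Known limitations

* Registration is integer-pixel; sub-pixel misalignment contributes a small
  bias the estimator cannot remove (deliberate, see above).
* The plateau rule is purely positional (last N points); no slope test
  guards against an unsettled plateau. A too-short inter-stimulant interval
  with τ > 0 biases P_stim toward the transition.
* The `ome` dialect reads positions as separate series; per-plane
  acquisition-time metadata inside OME-XML is not parsed (use the
  `timestamps.json` sidecar for non-uniform timing).
* Backgrounds measured from a small ROI are themselves noisy; with very
  small background regions this noise propagates into the ratio.
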