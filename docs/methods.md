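# Methods

This note documents the models, conventions and numerical choices behind
`gaitpipe`, and what the synthetic-data tests do and do not demonstrate.

## Data model and units

A trial is ingested from C3D into an `AcquisitionData`: marker trajectories
(frames × 3, acquisition length unit, normally mm), analog channels in
physical units (all scale factors and offsets applied on load), force-plate
descriptors from the FORCE_PLATFORM group, and events. A point sample is
occluded when its residual is negative *or* all three coordinates are
exactly zero — both dialects occur in exported files. Internal canonical
units are mm for stored lengths (converted to metres where the mechanics
needs SI), N, N·m, seconds. Frames are 1-based; an event at time *t* maps to
video frame ⌊t·rate⌋ for window starts / heel strikes and ⌈t·rate⌉ for
stops / toe offs, with a small snap tolerance because C3D stores event times
as float32.

The C3D codec (`gaitpipe._c3d`) is a purpose-built reader/writer covering
the subset the pipeline needs: Intel byte order, float or int16 data on
read, float on write, POINT/ANALOG/FORCE_PLATFORM/EVENT groups. It sits
behind one ingestion function so a different backend could be substituted.

## Force plates

Moments of types 1/2/4 are interpreted about the transducer origin located
by the ORIGIN vector (surface centre → transducer, plate axes); labs whose
plates report moments about the surface centre simply set ORIGIN = 0. The
type-3 channel order is fixed as (fx12, fx34, fy14, fy23, fz1..fz4) with
transducer numbering 1 = +x+y, 2 = −x+y, 3 = −x−y, 4 = +x−y and sensor
offsets a (x) and b (y) in metres from the lab configuration; labs that
differ reorder the channel map in the configuration. Type-1 plates report
CoP directly; the pipeline synthesises transducer-origin moments from the
reported CoP/Tz via M = (p−o)×F + Tz·ẑ so that a single
filter → threshold → invert path serves all four types, and the inversion
returns exactly the device-reported CoP (the raw values are also retained on
the wrench).

CoP and free torque are computed only on frames where |Fz| ≥ a threshold
(default 20 N, configurable); the paper-style "thresholded" guard prevents
division by near-zero vertical force. Off-contact frames carry placeholders
(CoP at the plate surface centre, zero force/torque in the exported series)
because downstream dynamics tools reject NaN. Plates measure the
subject-on-plate action; the exported wrench is negated to the reaction on
the subject at the global-frame transform, controlled by a per-lab flag.

Plate pose comes from the CORNERS quadrilateral: centre = corner mean,
local x along the corner 1→2 edge, z by the right-hand rule around the
winding, y = z×x. Lab→model axes are declared per lab (with per-plate
overrides) as a signed permutation, validated to determinant +1.

## Filtering and gaps

All smoothing uses a second-order Butterworth applied forward and backward
(zero phase). The nominal cutoff is passed straight to the single-pass
design — no double-pass warping correction — matching common motion-lab
practice; the effective −6 dB (gain 0.5) point therefore sits at the nominal
cutoff, which the tests assert. Edge transients use odd-reflection padding
of 3× the filter order. Marker filtering runs after gap filling,
independently per contiguous valid segment; segments still missing are never
filtered across, and segments too short to pad are left raw and reported.

Gap interpolation uses monotone shape-preserving piecewise cubic Hermite
(PCHIP) rather than a natural spline, because occlusions near trajectory
extrema must not overshoot. Only interior gaps of length ≤ max_gap (default
10 frames) are filled; max_gap = 0 disables interpolation entirely; boundary
gaps have no bracketing data and are always skipped. Every gap becomes one
log line. The GRF filter is applied to the assembled six-component wrench,
not to raw channels (for type 3 the two orders are equivalent up to the
linear combination; filtering the assembled wrench keeps one code path).

## Events and windows

The threshold detector marks a contact as a maximal run of |Fz| ≥ threshold
lasting at least min_contact (default 0.05 s, a debounce against noise
spikes; the cited detector's exact parameters are not public). Inside the
orchestrated pipeline, detection runs on the filtered Fz — thresholding raw
noisy data chatters — which can shift window edges by a few milliseconds of
filter smear; the detector itself, tested on unfiltered assembled series, is
sample-exact. When several plates are configured the elaboration selects
which plate(s) define the window; the window spans the first heel strike to
the last toe off. No constraint ties the window to exactly one gait cycle.

## EMG

Envelope = zero-lag high-pass (default 30 Hz) → |·| → zero-lag low-pass
(default 6 Hz); defaults are conventional for gait EMG and configurable.
Per-muscle maxima are taken as the maximum instantaneous envelope value over
the user-selected trial set, computed on the exported representation
(analysis window, video-rate time base) so the normalized maximum over that
set is exactly 1 in the files written. Muscles are normalized per recorded
channel (no left/right pairing). A trial outside the selection set may
exceed 1; it is flagged in the log, never clipped. Envelopes are decimated
to the video rate after the low-pass (safe: the passband is far below the
decimated Nyquist) so all exported columns share one time base.

## Joint centers

The pelvis frame is pinned as: origin mid-ASIS, z toward the right ASIS,
x anterior (mid-PSIS → mid-ASIS orthogonalized against z), y = z×x. The
Harrington regression (combined adult+child coefficients; the constants live
in one table, `joints.HARRINGTON_COEFFS`, so swapping the adult-only variant
is a one-line change) maps pelvic width/depth to the HJC offset in that
frame. All other joints are landmark midpoints chosen in the static
configuration. Static means use only frames where the landmark is valid;
landmarks with fewer than 10 valid frames are rejected as untrustworthy.
All constructions are equivariant under rigid motions, which the tests check
to 1e-9 mm.

## Writers

`.trc`, `.mot` (datacolumns/datarows/range dialect) and `.sto`
(nRows=/nColumns= dialect) are emitted with six decimal places, tab
delimiters and "." decimals regardless of locale, so outputs are bit-stable
across platforms; the bundled parsers accept both time-series dialects and
back the round-trip tests. TRC is exported in mm; GRF `.mot` columns are
force (N), CoP point (m) and torque (N·m) per plate, model frame, one file
per trial containing all plates. Occluded TRC samples are empty fields.

## Orchestration

Configuration is schema-validated XML (three files: acquisition /
elaboration / static); unknown elements are rejected and errors quote the
element and line. Outputs mirror the input tree
(`InputData/...` → `ElaboratedData/...`) under
`dynamicElaborations/<identifier>/` and `staticElaborations/<identifier>/`,
with a copy of the governing configuration files beside every elaboration
and extracted-trial summaries cached (regenerably) under `sessionData/`.
Log content contains no timestamps, so identical configuration reproduces
every data file byte for byte. Per-trial failures are logged and skipped;
only configuration errors abort. Plot failures are warnings. The command
line replaces interactive configuration: `validate-config`, `run-dynamic`,
`run-static`, `make-fixtures`.

## Synthetic sessions: what they emulate

The generator fabricates a 2.4 s walking trial at 100 Hz video / 1000 Hz
analog with two plates (types 2 and 3 by default; all four types are
constructible) and one static standing trial. Its design targets
*identifiable* structure, not physiology:

- vertical GRF is a double-hump (two Gaussian bumps) that is identically
  zero outside the true contact interval and ≥ ~50 N at its edges — a sharp
  heel-strike onset — so threshold crossings are sample-exact for any
  threshold between the noise floor and the in-contact minimum;
- raw plate channels come from the exact forward model of each plate type,
  so assembly + inversion recovering the truth checks the documented
  combinations, not a tautology of one code path (the channel decompositions
  are written independently of the assembly formulas);
- EMG is a constant-amplitude band-limited (50–350 Hz) noise carrier —
  amplitude flattened via the analytic signal — gated by stance-locked
  Gaussian bursts, making the expected rectified-mean envelope exactly
  (2/π)·A·g(t); real EMG has fluctuating amplitude, so real-data envelope
  peaks are noisier than the tests suggest;
- markers follow smooth sinusoidally-oscillating walking curves with gaps
  injected at recorded frames; real occlusions correlate with fast motion.

Default noise levels (0.2 mm marker, 0.5 N per channel, 2 % EMG baseline)
are typical of a calibrated optical system and modern plates; zero-noise
variants are used where a check is about numerical identity. All randomness
flows from a single seed through one generator, and noise enters as fixed
standard-normal draws scaled by the level, so recovery error is monotone in
each level by construction. Problem sizes throughout (3 trials, 240 frames,
1000 random wrenches per plate type in the oracle checks) keep the full
suite and the acceptance script in the seconds-to-a-minute range while
exercising every branch.

Passing tests demonstrate correctness of the mechanics, signal processing,
geometry and formats on data whose generating process is exactly the
pipeline's model. They do not demonstrate robustness to soft-tissue
artefact, marker relabeling, plate crosstalk or non-stationary EMG, none of
which the generator emulates.

## Known limitations

- No pattern-based or rigid-body gap filling from neighbouring markers.
- No functional (movement-based) joint-centre methods.
- No plate re-calibration or CoP error-correction maps; instrumented
  treadmills are out of scope.
- C3D writing exists for fixture generation only; the pipeline does not
  export C3D.
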