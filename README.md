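# gaitpipe

Elaboration of gait-lab motion data into inputs for neuromusculoskeletal
modeling and simulation software (OpenSim-style workflows).

Motion-analysis laboratories record synchronized 3D marker trajectories,
force-plate analog channels, and surface EMG into C3D files, but
musculoskeletal modeling tools need something quite different: filtered
marker files in the model's global frame, ground-reaction **wrenches**
(force, centre of pressure, free torque) per plate, normalized EMG linear
envelopes, and subject-specific joint centers for model scaling. `gaitpipe`
performs that elaboration, driven entirely by three declarative XML
configuration files, so the same processing runs identically across labs
with different instrumentation — and stores a copy of the governing
configuration beside every output for provenance.

## What it computes

**Ground reaction.** Raw plate channels are assembled into a plate-local
wrench for any of the four standard plate output types (type 1: forces +
CoP; type 2: six force/moment channels; type 3: eight piezoelectric channels
combined as Fx = fx12+fx34, Fy = fy14+fy23, Fz = Σfz_i, Mx = b(fz1+fz2−fz3−fz4),
My = a(−fz1+fz2+fz3−fz4), Mz = b(−fx12+fx34)+a(fy14−fy23); type 4: channels
premultiplied by a 6×6 calibration matrix). After zero-lag low-pass
filtering and thresholding on |Fz|, the centre of pressure and free torque
follow from the moment balance about the transducer origin *o*:

    CoPx = ox + (−My − oz·Fx)/Fz        Tz = Mz − (CoPx−ox)·Fy + (CoPy−oy)·Fx
    CoPy = oy + ( Mx − oz·Fy)/Fz

**Signals.** Markers and GRFs are filtered with a zero-lag (forward–backward)
second-order Butterworth filter; occlusion gaps up to a configurable length
are restored by shape-preserving piecewise-cubic interpolation and logged.

**Events and windows.** The analysis window comes from C3D events, from a
|Fz|-threshold detector (heel strike = first sample of a sustained
supra-threshold run, toe off = first sample after it), or from manual
frames.

**EMG.** High-pass filter → full-wave rectification → low-pass filter gives
the linear envelope; each muscle is normalized by its maximum instantaneous
envelope value over a user-selected set of trials, and the maxima are
logged.

**Joint centers.** The hip joint centre uses the Harrington pelvic
regression (offsets −0.24·PD−9.9, −0.30·PW−10.9, ±(0.33·PW+7.3) mm in a
pelvis frame built from the ASIS/PSIS landmarks); knee, ankle, elbow,
shoulder and wrist are landmark midpoints. Centers are appended to the
static marker file as virtual markers.

Everything is written as tab-delimited text: `.trc` markers, `.mot`/`.sto`
time series, plain-text logs, plus diagnostic plots.

A synthetic-session generator (`gaitpipe.synthetic`) fabricates complete
sessions — C3D files, configuration XMLs, and the generating ground truth —
so the whole pipeline is testable without any laboratory data.

## Worked example

```sh
gaitpipe make-fixtures demo --seed 7 --trials 1
gaitpipe run-dynamic demo/InputData/subject01/session1 \
    -a demo/InputData/subject01/session1/acquisition.xml \
    -e demo/InputData/subject01/session1/elaboration.xml
gaitpipe run-static demo/InputData/subject01/session1 \
    -a demo/InputData/subject01/session1/acquisition.xml \
    -s demo/InputData/subject01/session1/static.xml
```

This creates `demo/ElaboratedData/subject01/session1/` mirroring the input
tree, with `dynamicElaborations/run1/` holding per-trial `trial1.trc`,
`trial1_grf.mot`, `trial1_emg.mot`, logs and plots. The run log shows the
analysis window chosen by GRF thresholding:

    elaboration run1
    ok [trial1]: window 49-161 (grf-threshold)

i.e. the trial was cropped to video frames 49–161, spanning the first heel
strike to the last toe off. The gap log records what happened to each
marker occlusion:

    RKNE  frames 61-65    interpolated
    LHEE  frames 151-175  skipped-too-long

and `maxemg.txt` lists each muscle's reference maximum (volts) and the
trial attaining it, e.g. `gastrocnemius_r  0.000692441  trial1`. The GRF
file carries nine columns per plate (reaction force in N, CoP point in m,
torque in N·m, model frame), so two plates give `datacolumns 19`. The
static run writes `staticElaborations/static1/static.trc` with HJC/KJC/AJC
virtual markers and a `joint_centers.txt` such as

    HJC_R  harrington  521.529531  -86.495297  873.790298

(millimetres, acquisition frame).

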