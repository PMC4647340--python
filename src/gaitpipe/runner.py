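"""Orchestration: config-driven dynamic and static elaborations.

A session directory holds the trials of one acquisition session (one C3D per
trial). ``run_dynamic_elaboration`` drives the full dynamic pipeline over
the configured trials:

    load -> assemble/filter plate wrenches -> CoP + free torque
         -> gap-fill + filter markers -> analysis window -> crop
         -> rotate to the model global frame -> EMG envelopes
         -> per-muscle maxima over the max-selection trials -> normalize
         -> write .trc / .mot + gap log + maxima log + plots

Outputs land under ``dynamicElaborations/<identifier>/`` in a tree mirroring
the input tree (``InputData/...`` maps onto ``ElaboratedData/...``); static
results go to ``staticElaborations/<identifier>/``. A copy of the governing
configuration files is stored beside every elaboration for provenance, and
extracted-trial summaries are cached under ``sessionData/`` (regenerable).

Per-trial failures are logged and the trial skipped; only configuration
errors abort a run. Log content is deterministic (no timestamps), so
re-running an elaboration with identical configuration reproduces every
data file byte for byte.
"""

from __future__ import annotations

import json
import shutil
import traceback
from pathlib import Path

import numpy as np

from . import emg as emg_mod
from . import events as events_mod
from . import joints as joints_mod
from . import writers
from .acquisition import (AcquisitionData, load_acquisition,
                          merge_lab_plate_info, validate_against_lab)
from .config import (ConfigError, ElabConfig, LabConfig, StaticConfig,
                     load_elab_config, load_lab_config, load_static_config)
from .forceplate import (PlateWrench, assemble_wrench, compute_cop_and_torque,
                         zero_off_contact)
from .frames import grf_to_global, rotate_markers, rotation_from_spec
from .signals import fill_gaps, filter_trajectory, write_gap_log, zero_lag_butterworth


def mirror_output_root(session_dir: Path) -> Path:
    """Map an input session path onto its elaborated-data twin.

    ``.../InputData/<subject>/<session>`` mirrors to
    ``.../ElaboratedData/<subject>/<session>``; paths without an InputData
    component get an ``ElaboratedData`` folder beside the session.
    """
    session_dir = Path(session_dir).resolve()
    parts = list(session_dir.parts)
    if "InputData" in parts:
        parts[parts.index("InputData")] = "ElaboratedData"
        return Path(*parts)
    return session_dir / "ElaboratedData"


def _copy_configs(dest: Path, *paths) -> None:
    for p in paths:
        if p is not None:
            shutil.copyfile(p, dest / Path(p).name)


def _resolve_configs(lab, elab_or_static, loader):
    lab_path = None
    if not isinstance(lab, LabConfig):
        lab_path = Path(lab)
        lab = load_lab_config(lab_path)
    other_path = None
    if isinstance(elab_or_static, (str, Path)):
        other_path = Path(elab_or_static)
        elab_or_static = loader(other_path)
    return lab, lab_path, elab_or_static, other_path


def _cache_extraction(session_out: Path, acq: AcquisitionData) -> None:
    info = {
        "trial": acq.name, "frames": acq.nframes,
        "video_rate": acq.video_rate, "analog_rate": acq.analog_rate,
        "markers": [m.label for m in acq.markers],
        "analog_channels": [c.label for c in acq.analog],
        "plates": [{"index": p.index, "type": p.type} for p in acq.plates],
        "events": [list(e) for e in acq.events],
    }
    out = session_out / "sessionData"
    out.mkdir(parents=True, exist_ok=True)
    (out / f"{acq.name}.json").write_text(json.dumps(info, indent=1, sort_keys=True))


def _grf_pipeline(acq: AcquisitionData, lab: LabConfig, elab: ElabConfig):
    """Assembled, filtered, inverted per-plate GRF series (plate-local)."""
    grfs = []
    mm = acq.units.lower().startswith("mm")
    for spec in acq.plates:
        raw = acq.plate_channels(spec)
        w = assemble_wrench(raw, spec, length_unit_mm=mm)
        if elab.grf_cutoff:
            w = PlateWrench(
                F=zero_lag_butterworth(w.F, acq.analog_rate, elab.grf_cutoff),
                M=zero_lag_butterworth(w.M, acq.analog_rate, elab.grf_cutoff),
                valid=w.valid, cop_direct=w.cop_direct, tz_direct=w.tz_direct)
        grfs.append(compute_cop_and_torque(
            w, np.asarray(spec.origin, dtype=float) * 0.001,
            fz_threshold=elab.window.threshold, plate_index=spec.index))
    return grfs


def _define_window(acq: AcquisitionData, elab: ElabConfig, grfs) -> events_mod.AnalysisWindow:
    w = elab.window
    if w.method == "manual":
        return events_mod.manual_window(w.start, w.stop, acq.nframes)
    if w.method == "events":
        return events_mod.window_from_events(
            acq.events, acq.video_rate, acq.nframes,
            start_label=w.start_label, stop_label=w.stop_label)
    wanted = set(w.plates) if w.plates else {g.plate_index for g in grfs}
    contacts = []
    for g in grfs:
        if g.plate_index in wanted:
            contacts.extend(events_mod.detect_contacts(
                g, acq.analog_rate, acq.video_rate,
                threshold=w.threshold, min_contact=w.min_contact))
    return events_mod.window_from_contacts(contacts, acq.nframes)


def _process_trial(acq: AcquisitionData, lab: LabConfig, elab: ElabConfig,
                   trial_out: Path, lab_rotation: np.ndarray):
    """Everything except EMG normalization (which needs all trials first)."""
    merge_lab_plate_info(acq, lab)
    ratio = acq.rate_ratio

    grfs = _grf_pipeline(acq, lab, elab)
    window = _define_window(acq, elab, grfs)

    out_labels = elab.output_markers or lab.marker_protocol or \
        [m.label for m in acq.markers]
    gap_entries, notes = [], []
    processed = {}
    raw_markers = {}
    for label in out_labels:
        traj = acq.marker(label)
        raw_markers[label] = traj
        filled, entries = fill_gaps(traj, elab.max_gap)
        gap_entries.extend(entries)
        if elab.marker_cutoff:
            filled, seg_notes = filter_trajectory(filled, acq.video_rate,
                                                  elab.marker_cutoff)
            notes.extend(seg_notes)
        processed[label] = filled

    # crop + rotate markers to the model frame (exported in mm)
    trc_markers, trc_masks = {}, {}
    for label, traj in processed.items():
        pos = events_mod.crop_frames(traj.positions, window)
        mask = events_mod.crop_frames(traj.mask, window)
        trc_markers[label] = rotate_markers(np.nan_to_num(pos), lab_rotation)
        trc_masks[label] = mask

    # crop + rotate GRFs; zero the exported wrench outside contact
    global_grfs = []
    for g, spec in zip(grfs, acq.plates):
        cropped = events_mod.crop_grf(zero_off_contact(g), window, ratio)
        global_grfs.append(grf_to_global(cropped, spec.corners, lab_rotation,
                                         reaction=lab.reaction))

    # EMG envelopes over the full trial, then cropped and decimated to the
    # video rate so every exported column shares one time base
    emg_windowed = {}
    raw_emg = {}
    for ch_idx, muscle in sorted(lab.emg_map.items()):
        sig = acq.channel(ch_idx).samples
        raw_emg[muscle] = events_mod.crop_analog(sig, window, ratio)
        env = emg_mod.envelope(sig, acq.analog_rate, elab.emg_hp, elab.emg_lp)
        emg_windowed[muscle] = emg_mod.resample_to_video(
            events_mod.crop_analog(env, window, ratio), ratio)

    trial_out.mkdir(parents=True, exist_ok=True)
    writers.write_trc(trc_markers, acq.video_rate,
                      trial_out / f"{acq.name}.trc", units="mm",
                      masks=trc_masks, start_frame=window.start, name=acq.name)
    if global_grfs:
        writers.write_grf_mot(global_grfs, acq.analog_rate,
                              trial_out / f"{acq.name}_grf.mot", name=acq.name)
    write_gap_log(gap_entries, notes, trial_out / "gaps.log")

    return dict(window=window, grfs=grfs, global_grfs=global_grfs,
                emg=emg_windowed, raw_emg=raw_emg, raw_markers=raw_markers,
                processed_markers=processed, gap_entries=gap_entries,
                _acq=acq, _video_rate=acq.video_rate)


def run_dynamic_elaboration(session_dir, lab, elab, out_root=None,
                            plots: bool = True) -> Path:
    """Run the configured dynamic elaboration; returns the output folder."""
    session_dir = Path(session_dir)
    lab, lab_path, elab, elab_path = _resolve_configs(lab, elab, load_elab_config)
    if elab.max_emg_trials and not lab.emg_map:
        raise ConfigError(
            "elaboration selects EMG max-peak trials but the acquisition "
            "configuration declares no EMG protocol")
    lab_rotation = rotation_from_spec(lab.axes)
    session_out = Path(out_root) if out_root else mirror_output_root(session_dir)
    run_out = session_out / "dynamicElaborations" / elab.identifier
    run_out.mkdir(parents=True, exist_ok=True)
    _copy_configs(run_out, lab_path, elab_path)

    log_lines: list[str] = [f"elaboration {elab.identifier}"]
    results: dict[str, dict] = {}
    for trial in elab.trials:
        path = session_dir / f"{trial}.c3d"
        try:
            acq = load_acquisition(path, name=trial)
            for report in validate_against_lab(acq, lab):
                log_lines.append(f"warning [{trial}]: {report}")
            results[trial] = _process_trial(acq, lab, elab, run_out / trial,
                                            lab_rotation)
            log_lines.append(
                f"ok [{trial}]: window {results[trial]['window'].start}-"
                f"{results[trial]['window'].stop} "
                f"({results[trial]['window'].source})")
        except ConfigError:
            raise
        except Exception as exc:  # per-trial failure: log and continue
            log_lines.append(f"failed [{trial}]: {exc}")
            log_lines.append("".join(traceback.format_exception_only(exc)).strip())

    # EMG normalization: maxima over the selected trials, on the exported
    # (windowed, video-rate) time base
    if lab.emg_map and results:
        max_trials = [t for t in (elab.max_emg_trials or elab.trials)
                      if t in results]
        per_muscle: dict[str, list[tuple[str, np.ndarray]]] = {}
        for t in max_trials:
            for muscle, env in results[t]["emg"].items():
                per_muscle.setdefault(muscle, []).append((t, env))
        maxima, log = emg_mod.max_over_trials(per_muscle)
        for trial, res in results.items():
            normalized = {}
            for muscle, env in res["emg"].items():
                mx = maxima.get(muscle, 0.0)
                if mx <= 0:
                    log.append(f"# muscle {muscle} skipped in {trial}: zero maximum")
                    continue
                normalized[muscle] = env / mx
                peak = float(np.max(normalized[muscle]))
                if peak > 1.0 + 1e-12:
                    log.append(f"# {muscle} exceeds reference maximum in {trial} "
                               f"(normalized peak {peak:.4f})")
            res["normalized"] = normalized
            if normalized:
                writers.write_emg_mot(
                    normalized, res["_video_rate"],
                    run_out / trial / f"{trial}_emg.{elab.emg_format}",
                    fmt=elab.emg_format, name=f"{trial} emg")
        (run_out / "maxemg.txt").write_text(
            "# muscle\tmax_value_V\ttrial\n" + "\n".join(log) + "\n")

    for trial, res in results.items():
        _cache_extraction(session_out, res["_acq"])
        if plots:
            try:
                emit_plots(res, run_out / trial / "plots", trial)
            except Exception as exc:   # plots never abort a run
                log_lines.append(f"warning [{trial}]: plotting failed: {exc}")

    (run_out / "run.log").write_text("\n".join(log_lines) + "\n")
    return run_out


def run_static_elaboration(session_dir, lab, static_cfg, identifier: str = "static1",
                           trial: str = "static", out_root=None) -> Path:
    """Static pipeline: mean pose, joint centers, augmented .trc."""
    session_dir = Path(session_dir)
    lab, lab_path, static_cfg, static_path = _resolve_configs(
        lab, static_cfg, load_static_config)
    lab_rotation = rotation_from_spec(lab.axes)
    session_out = Path(out_root) if out_root else mirror_output_root(session_dir)
    run_out = session_out / "staticElaborations" / identifier
    run_out.mkdir(parents=True, exist_ok=True)
    _copy_configs(run_out, lab_path, static_path)

    acq = load_acquisition(session_dir / f"{trial}.c3d", name=trial)
    pose = joints_mod.mean_pose(acq)
    centers = joints_mod.compute_centers(pose, static_cfg)

    markers = {m.label: rotate_markers(np.nan_to_num(m.positions), lab_rotation)
               for m in acq.markers}
    masks = {m.label: m.mask for m in acq.markers}
    n = acq.nframes
    for c in centers:
        markers[c.label] = np.tile((lab_rotation @ c.position)[None, :], (n, 1))
        masks[c.label] = np.zeros(n, dtype=bool)
    writers.write_trc(markers, acq.video_rate, run_out / f"{trial}.trc",
                      units=acq.units, masks=masks, name=trial)
    lines = [f"{c.label}\t{c.method}\t"
             + "\t".join(f"{v:.6f}" for v in c.position) for c in centers]
    (run_out / "joint_centers.txt").write_text(
        "# label\tmethod\tx_mm\ty_mm\tz_mm (acquisition frame)\n"
        + "\n".join(lines) + "\n")
    return run_out


# ---------------------------------------------------------------------------
# diagnostic plots
# ---------------------------------------------------------------------------

def emit_plots(res: dict, out_dir: Path, trial: str) -> list[Path]:
    """Per-trial inspection plots; failures are warnings upstream, never fatal."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    made: list[Path] = []
    window = res["window"]

    for muscle, raw in res.get("raw_emg", {}).items():
        fig, ax = plt.subplots(figsize=(7, 3))
        t = np.arange(len(raw))
        ax.plot(t, raw, lw=0.4, label="raw")
        env = res.get("normalized", {}).get(muscle)
        if env is None:
            env = res["emg"].get(muscle)
        if env is not None:
            ax2 = ax.twinx()
            ratio = max(1, len(raw) // max(1, len(env)))
            ax2.plot(np.arange(len(env)) * ratio, env, color="C2", label="envelope")
        ax.axvspan(0, len(raw), alpha=0.08, color="C3")
        ax.set_title(f"{trial}: {muscle} (window {window.start}-{window.stop})")
        fig.tight_layout()
        p = out_dir / f"emg_{muscle}.png"
        fig.savefig(p, dpi=72)
        plt.close(fig)
        made.append(p)

    for g in res.get("global_grfs", []):
        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 5), sharex=True)
        t = np.arange(g.F.shape[0])
        for k, lbl in enumerate("xyz"):
            ax1.plot(t, g.F[:, k], label=f"F{lbl}")
        ax1.legend(loc="upper right")
        ax1.set_title(f"{trial}: plate {g.plate_index} GRF (model frame)")
        ax2.plot(g.cop[g.contact, 0], g.cop[g.contact, 2], ".", ms=2)
        ax2.set_title("CoP trace (contact frames)")
        fig.tight_layout()
        p = out_dir / f"grf_plate{g.plate_index}.png"
        fig.savefig(p, dpi=72)
        plt.close(fig)
        made.append(p)

    filled_any = {e.marker for e in res.get("gap_entries", [])
                  if e.action == "interpolated"}
    for label in sorted(filled_any):
        before = res["raw_markers"][label]
        after = res["processed_markers"][label]
        fig, ax = plt.subplots(figsize=(7, 3))
        ax.plot(after.positions[:, 2], label="after", color="C1")
        ax.plot(np.where(before.mask, np.nan, before.positions[:, 2]),
                label="before", color="C0", lw=0.8)
        ax.legend()
        ax.set_title(f"{trial}: gap fill {label} (z)")
        fig.tight_layout()
        p = out_dir / f"gapfill_{label}.png"
        fig.savefig(p, dpi=72)
        plt.close(fig)
        made.append(p)
    return made
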