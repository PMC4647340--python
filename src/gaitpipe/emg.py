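"""EMG processing: linear envelopes, per-muscle maxima, normalization.

Raw surface EMG is high-pass filtered (removing offset and movement
artefact), full-wave rectified, and low-pass filtered into a linear
envelope — a smooth, activation-like signal. Envelopes are normalized by
the maximum instantaneous envelope value the muscle reached over a set of
trials chosen for that purpose, so normalized activity is dimensionless and
comparable across sessions. The per-muscle maxima and the trial attaining
each are logged to a text file.

Default cutoffs: 30 Hz high-pass, 6 Hz low-pass, both second-order zero-lag
Butterworth (both configurable). A muscle may legitimately exceed 1.0 in a
trial outside the max-selection set; such excursions are flagged, not
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import FilterSpec, zero_lag_butterworth

DEFAULT_HP_CUTOFF = 30.0
DEFAULT_LP_CUTOFF = 6.0


class EmgError(ValueError):
    """EMG parameters or inputs are unusable."""


@dataclass
class EmgSet:
    """Processed EMG of one trial, keyed by muscle name."""

    raw: dict[str, np.ndarray] = field(default_factory=dict)          # V
    envelopes: dict[str, np.ndarray] = field(default_factory=dict)    # V
    maxima: dict[str, float] = field(default_factory=dict)            # V
    normalized: dict[str, np.ndarray] = field(default_factory=dict)   # dimensionless
    rate: float = 0.0
    hp_cutoff: float = DEFAULT_HP_CUTOFF
    lp_cutoff: float = DEFAULT_LP_CUTOFF


def envelope(raw: np.ndarray, rate: float,
             hp_cutoff: float = DEFAULT_HP_CUTOFF,
             lp_cutoff: float = DEFAULT_LP_CUTOFF) -> np.ndarray:
    """Linear envelope: zero-lag high-pass, rectify, zero-lag low-pass.

    The result is non-negative up to filter ringing near sharp transients.
    Invariant to a sign flip of the raw signal (rectification symmetry).
    """
    if rate <= 2.0 * hp_cutoff:
        raise EmgError(
            f"sampling rate {rate} Hz must exceed twice the high-pass cutoff "
            f"{hp_cutoff} Hz")
    hp = zero_lag_butterworth(raw, rate, FilterSpec(hp_cutoff), btype="highpass")
    return zero_lag_butterworth(np.abs(hp), rate, FilterSpec(lp_cutoff))


def max_over_trials(envelopes: dict[str, list[tuple[str, np.ndarray]]],
                    ) -> tuple[dict[str, float], list[str]]:
    """Per-muscle maximum instantaneous envelope value across trials.

    ``envelopes`` maps muscle -> list of (trial_id, envelope series). Returns
    the maxima and the text-log lines (muscle, max value in V, attaining
    trial). Raises when a muscle has no trial.
    """
    maxima: dict[str, float] = {}
    lines: list[str] = []
    for muscle, series in envelopes.items():
        if not series:
            raise EmgError(f"muscle {muscle!r} absent from every max-selection trial")
        best_trial, best = max(
            ((trial, float(np.max(env))) for trial, env in series),
            key=lambda p: p[1])
        maxima[muscle] = best
        lines.append(f"{muscle}\t{best:.6g}\t{best_trial}")
    return maxima, lines


def normalize(env: np.ndarray, mx: float) -> np.ndarray:
    """Pointwise division by the reference maximum (must be positive)."""
    if mx <= 0:
        raise EmgError("normalization maximum must be positive")
    return np.asarray(env, dtype=np.float64) / mx


def process_trial(raw: dict[str, np.ndarray], rate: float,
                  hp_cutoff: float = DEFAULT_HP_CUTOFF,
                  lp_cutoff: float = DEFAULT_LP_CUTOFF) -> EmgSet:
    """Envelope every muscle of one trial (normalization happens later)."""
    out = EmgSet(raw=dict(raw), rate=rate, hp_cutoff=hp_cutoff, lp_cutoff=lp_cutoff)
    for muscle, sig in raw.items():
        out.envelopes[muscle] = envelope(sig, rate, hp_cutoff, lp_cutoff)
    return out


def normalize_set(emg: EmgSet, maxima: dict[str, float],
                  trial_id: str = "") -> list[str]:
    """Normalize a trial's envelopes in place; returns warning lines.

    Muscles whose reference maximum is zero are skipped with a warning;
    normalized values above 1 (a peak beyond the max-selection set) are
    flagged but kept.
    """
    warnings: list[str] = []
    for muscle, env in emg.envelopes.items():
        mx = maxima.get(muscle, 0.0)
        if mx <= 0:
            warnings.append(
                f"muscle {muscle!r} skipped in trial {trial_id!r}: "
                "reference maximum is zero")
            continue
        emg.maxima[muscle] = mx
        emg.normalized[muscle] = normalize(env, mx)
        peak = float(np.max(emg.normalized[muscle]))
        if peak > 1.0 + 1e-12:
            warnings.append(
                f"muscle {muscle!r} in trial {trial_id!r} exceeds its reference "
                f"maximum (normalized peak {peak:.3f})")
    return warnings


def resample_to_video(env: np.ndarray, ratio: int) -> np.ndarray:
    """Decimate an envelope to the video rate (safe after the low-pass)."""
    if ratio < 1:
        raise EmgError("rate ratio must be >= 1")
    return np.asarray(env)[::ratio].copy()
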