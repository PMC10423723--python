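"""Gaze angular velocity, fixation detection and dwell accounting.

Angular velocity is computed per eye from consecutive unit gaze
directions (arccos of their dot product over the frame interval) and
smoothed with an asymptotic filter that relaxes exponentially toward the
instantaneous velocity.  Fixations are maximal runs below a velocity
threshold (I-VT style); dwell time per target ball is accumulated from
the tracker's fixated-ball label channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidSampleError

FIXATION_THRESHOLD_DPS = 30.0
MIN_FIXATION_MS = 100.0
ASYMPTOTIC_ALPHA = 0.6
DWELL_LABELS = ("Up", "Down", "Left", "Right", "nan")


@dataclass
class VelocityTrace:
    """Per-eye angular velocity: raw and asymptotically smoothed (deg/s).

    ``valid_mask`` is False where a velocity could not be computed (first
    sample, or either endpoint of the frame pair missing); no velocity is
    ever computed across an excluded gap.
    """

    t: np.ndarray
    omega_raw: np.ndarray
    omega_asym: np.ndarray
    valid_mask: np.ndarray


@dataclass
class FixationSet:
    """Detected fixations for one eye."""

    segments: list[tuple[float, float]]
    count: int


def angular_change(dir_a: np.ndarray, dir_b: np.ndarray) -> float:
    """Angle between two unit gaze directions, degrees.

    The dot product is clamped into [-1, 1] so float noise at parallel
    vectors cannot produce NaN.
    """
    a = np.asarray(dir_a, dtype=float)
    b = np.asarray(dir_b, dtype=float)
    if np.linalg.norm(a) < 1e-12 or np.linalg.norm(b) < 1e-12:
        raise InvalidSampleError("zero-length gaze vector")
    dot = float(np.dot(a / np.linalg.norm(a), b / np.linalg.norm(b)))
    return float(np.degrees(np.arccos(np.clip(dot, -1.0, 1.0))))


def asymptotic_velocity(
    t: np.ndarray,
    dirs: np.ndarray,
    valid: np.ndarray | None = None,
    smoothing_alpha: float = ASYMPTOTIC_ALPHA,
) -> VelocityTrace:
    """Angular velocity trace with asymptotic smoothing.

    omega_raw[i] is the angular change from frame i-1 to i divided by
    the frame interval; omega_asym relaxes toward omega_raw with
    per-frame rate ``smoothing_alpha``::

        omega_asym[i] = omega_asym[i-1] + alpha * (omega_raw[i] - omega_asym[i-1])

    The recurrence restarts (from the instantaneous value) after every
    gap, so no velocity or smoothing state crosses excluded samples.
    """
    t = np.asarray(t, dtype=float)
    dirs = np.asarray(dirs, dtype=float)
    n = len(t)
    if valid is None:
        valid = np.all(np.isfinite(dirs), axis=1)
    valid = np.asarray(valid, dtype=bool)

    omega_raw = np.full(n, np.nan)
    omega_asym = np.full(n, np.nan)
    vmask = np.zeros(n, dtype=bool)

    # Vectorized raw velocity over consecutive valid pairs.
    pair_ok = valid[1:] & valid[:-1]
    if np.any(pair_ok):
        a = dirs[:-1][pair_ok]
        b = dirs[1:][pair_ok]
        dots = np.clip(np.einsum("ij,ij->i", a, b), -1.0, 1.0)
        ang = np.degrees(np.arccos(dots))
        dt = np.diff(t)[pair_ok]
        idx = np.nonzero(pair_ok)[0] + 1
        omega_raw[idx] = ang / dt
        vmask[idx] = True

    prev = np.nan
    for i in range(n):
        if not vmask[i]:
            prev = np.nan  # smoothing state does not survive a gap
            continue
        if np.isnan(prev):
            omega_asym[i] = omega_raw[i]
        else:
            omega_asym[i] = prev + smoothing_alpha * (omega_raw[i] - prev)
        prev = omega_asym[i]
    return VelocityTrace(t=t, omega_raw=omega_raw, omega_asym=omega_asym, valid_mask=vmask)


def detect_fixations(
    trace: VelocityTrace,
    threshold_dps: float = FIXATION_THRESHOLD_DPS,
    min_duration_ms: float = MIN_FIXATION_MS,
) -> FixationSet:
    """Velocity-threshold fixation detection.

    Maximal runs of valid samples with smoothed velocity below
    ``threshold_dps`` that last at least ``min_duration_ms`` become
    fixations.
    """
    below = trace.valid_mask & (trace.omega_asym < threshold_dps)
    segments: list[tuple[float, float]] = []
    n = len(below)
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        if (trace.t[j] - trace.t[i]) * 1000.0 >= min_duration_ms:
            segments.append((float(trace.t[i]), float(trace.t[j])))
        i = j + 1
    return FixationSet(segments=segments, count=len(segments))


def durations_by_target(
    labels: np.ndarray, t: np.ndarray, dwell_labels: tuple[str, ...] = DWELL_LABELS
) -> dict[str, float]:
    """Total dwell time per fixated-ball label (seconds).

    Each sample contributes its frame interval dt to the label it
    carries; the final sample contributes the median dt.  Labels outside
    ``dwell_labels`` (including missing) count toward 'nan'.
    """
    t = np.asarray(t, dtype=float)
    labels = np.asarray(labels, dtype=object)
    dts = np.diff(t)
    dts = np.append(dts, np.median(dts) if len(dts) else 0.0)
    out = {lab: 0.0 for lab in dwell_labels}
    for lab, dt in zip(labels, dts):
        key = str(lab) if str(lab) in dwell_labels else "nan"
        out[key] += float(dt)
    return out
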