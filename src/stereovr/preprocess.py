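"""Eye-tracking signal cleaning.

Raw per-frame logs carry blinks, tracker dropouts and pupil artifacts.
Cleaning proceeds in fixed order: blink masking from the eye-openness
channel, four per-eye pupil validity filters (physiological range,
dilation-speed outliers, trend-line deviation, isolated clusters),
merging of the two eyes into one mean-pupil signal with shape-preserving
piecewise-cubic (PCHIP) gap interpolation, and gap-limited linear
interpolation of the gaze-direction vectors.

The filter cascade follows the staged pupillometry pipeline of Kret &
Sjak-Shie; thresholds the source left unstated use that pipeline's
defaults and are exposed as parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .errors import InsufficientDataError

PUPIL_RANGE_MM = (1.5, 9.0)
BLINK_OPENNESS_THRESHOLD = 0.1
#: MAD multiplier of the speed / trend-deviation outlier filters.
MAD_MULTIPLIER = 16.0
MIN_CLUSTER_MS = 50.0
#: Absolute floor (mm) of the trend-deviation threshold: residuals this
#: small are physiologically negligible and never flagged, which keeps
#: the MAD threshold from rejecting structure in near-noiseless signals.
TREND_FLOOR_MM = 0.05
MAX_CLUSTER_SEP_MS = 40.0
MAX_GAZE_GAP_SAMPLES = 10


@dataclass
class EyeSampleLog:
    """Time-ordered raw eye-tracking channels for one trial run.

    ``t`` is in seconds on the renderer's ~90 Hz grid; pupil diameters in
    mm (NaN where the tracker reported no value); ``dir_*`` are unit gaze
    vectors (rows of NaN where invalid); ``fixated_*`` hold the fixated
    ball label per sample ('Up'/'Down'/'Left'/'Right' or 'nan').
    ``events`` is the per-stimulus (onset_t, offset_t, stimulus_index)
    list; ``idle_start_t`` marks the beginning of the pre-trial idle
    phase.
    """

    t: np.ndarray
    pupil_l: np.ndarray
    pupil_r: np.ndarray
    open_l: np.ndarray
    open_r: np.ndarray
    origin_l: np.ndarray
    origin_r: np.ndarray
    dir_l: np.ndarray
    dir_r: np.ndarray
    fixated_l: np.ndarray
    fixated_r: np.ndarray
    events: list[tuple[float, float, int]] = field(default_factory=list)
    idle_start_t: float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise InsufficientDataError("timestamps must be strictly increasing, length >= 2")


@dataclass
class PupilFilterStages:
    """Boolean validity mask after each filter stage (True = valid)."""

    blink: np.ndarray
    range: np.ndarray
    speed: np.ndarray
    trend: np.ndarray
    cluster: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.cluster

    def rejected_counts(self) -> dict[str, int]:
        """Samples newly rejected at each stage (QC bookkeeping)."""
        stages = [self.blink, self.range, self.speed, self.trend, self.cluster]
        names = ["blink", "range", "speed", "trend", "cluster"]
        counts = {}
        prev = np.ones_like(self.blink, dtype=bool)
        for name, mask in zip(names, stages):
            counts[name] = int(np.sum(prev & ~mask))
            prev = mask
        return counts


@dataclass
class CleanSignals:
    """Artifact-masked, interpolated signals ready for feature extraction."""

    t: np.ndarray
    pupil_mean: np.ndarray
    pupil_valid_mask: np.ndarray
    stages_l: PupilFilterStages
    stages_r: PupilFilterStages
    dir_l: np.ndarray
    dir_r: np.ndarray
    gaze_valid_l: np.ndarray
    gaze_valid_r: np.ndarray
    blink_mask: np.ndarray


def detect_blinks(
    open_l: np.ndarray, open_r: np.ndarray, threshold: float = BLINK_OPENNESS_THRESHOLD
) -> np.ndarray:
    """Blink mask: True where either eye's openness drops below threshold.

    Blinks are excluded from both the pupil and the gaze stream; beyond
    that the blink events themselves are not processed further.
    """
    open_l = np.asarray(open_l, dtype=float)
    open_r = np.asarray(open_r, dtype=float)
    return (open_l < threshold) | (open_r < threshold)


def _mad_threshold(values: np.ndarray, k: float) -> float:
    med = np.nanmedian(values)
    mad = np.nanmedian(np.abs(values - med))
    return float(med + k * mad)


def _dilation_speed(d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Max of backward/forward normalized sample-to-sample change rate.

    A blink edge or tracker glitch produces a change far faster than any
    physiological dilation; taking the max of the two one-sided speeds
    flags both edges of a discontinuity.
    """
    n = len(d)
    speed = np.full(n, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        back = np.abs(np.diff(d) / np.diff(t))
    fwd = np.concatenate([back, [np.nan]])
    bwd = np.concatenate([[np.nan], back])
    speed = np.fmax(fwd, bwd)
    return speed


def _trend_line(t: np.ndarray, d: np.ndarray, valid: np.ndarray, win_s: float = 0.3) -> np.ndarray:
    """Smoothed trend through the provisionally valid samples.

    PCHIP through the valid samples, then a Savitzky-Golay smoother with
    a ~win_s window (quadratic, polynomial boundary handling — a plain
    moving average is biased at the run's edges); residuals from this
    trend expose samples the speed filter missed (e.g. slow drifts into
    artifact).
    """
    tv, dv = t[valid], d[valid]
    if len(tv) < 2:
        return np.full_like(d, np.nan)
    interp = PchipInterpolator(tv, dv, extrapolate=False)
    filled = interp(t)
    filled[t < tv[0]] = dv[0]
    filled[t > tv[-1]] = dv[-1]
    dt = np.median(np.diff(t))
    win = max(5, int(round(win_s / dt)))
    if win % 2 == 0:
        win += 1
    if win >= len(filled):
        win = len(filled) - 1 if len(filled) % 2 == 0 else len(filled)
        win = max(win - 2, 3)
    return savgol_filter(filled, win, polyorder=2, mode="interp")


def _cluster_filter(
    t: np.ndarray, valid: np.ndarray, min_cluster_ms: float, max_sep_ms: float
) -> np.ndarray:
    """Drop temporally isolated short runs of valid samples.

    A valid run shorter than ``min_cluster_ms`` whose gaps to the
    neighbouring valid data exceed ``max_sep_ms`` on both sides is more
    likely a mid-artifact glitch than signal.
    """
    out = valid.copy()
    n = len(valid)
    i = 0
    while i < n:
        if not valid[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and valid[j + 1]:
            j += 1
        run_ms = (t[j] - t[i]) * 1000.0
        # Temporal separation from the previous/next valid sample.
        prev_valid = np.nonzero(valid[:i])[0]
        next_valid = j + 1 + np.nonzero(valid[j + 1 :])[0]
        sep_prev = (t[i] - t[prev_valid[-1]]) * 1000.0 if len(prev_valid) else np.inf
        sep_next = (t[next_valid[0]] - t[j]) * 1000.0 if len(next_valid) else np.inf
        if run_ms < min_cluster_ms and sep_prev > max_sep_ms and sep_next > max_sep_ms:
            out[i : j + 1] = False
        i = j + 1
    return out


def filter_pupil(
    t: np.ndarray,
    pupil: np.ndarray,
    blink_mask: np.ndarray,
    pupil_range_mm: tuple[float, float] = PUPIL_RANGE_MM,
    mad_multiplier: float = MAD_MULTIPLIER,
    min_cluster_ms: float = MIN_CLUSTER_MS,
    max_sep_ms: float = MAX_CLUSTER_SEP_MS,
    trend_floor_mm: float = TREND_FLOOR_MM,
) -> PupilFilterStages:
    """Staged validity filtering of one eye's pupil-diameter series.

    Stages, each only ever removing validity:

    1. physiological range — diameters outside [1.5, 9.0] mm rejected;
    2. dilation speed — normalized sample-to-sample change rates above
       median + k·MAD rejected (blink edges, glitches);
    3. trend deviation — residuals from a smoothed trend line above
       median + k·MAD rejected;
    4. isolated clusters — short valid runs surrounded by large gaps
       rejected.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(pupil, dtype=float)
    blink_ok = ~np.asarray(blink_mask, dtype=bool) & np.isfinite(d)
    if np.sum(blink_ok) < 2:
        raise InsufficientDataError("fewer than 2 valid pupil samples after blink masking")

    lo, hi = pupil_range_mm
    range_ok = blink_ok & (d >= lo) & (d <= hi)
    _require(range_ok, "range")

    dv = np.where(range_ok, d, np.nan)
    speed = _dilation_speed(dv, t)
    thr = _mad_threshold(speed[range_ok], mad_multiplier)
    speed_ok = range_ok & ~(speed > thr)  # NaN speed (isolated) passes here
    _require(speed_ok, "speed")

    trend = _trend_line(t, d, speed_ok)
    resid = np.abs(d - trend)
    thr = max(_mad_threshold(resid[speed_ok], mad_multiplier), trend_floor_mm)
    trend_ok = speed_ok & ~(resid > thr)
    _require(trend_ok, "trend")

    cluster_ok = _cluster_filter(t, trend_ok, min_cluster_ms, max_sep_ms)
    _require(cluster_ok, "cluster")

    return PupilFilterStages(
        blink=blink_ok, range=range_ok, speed=speed_ok, trend=trend_ok, cluster=cluster_ok
    )


def _require(mask: np.ndarray, stage: str) -> None:
    if np.sum(mask) < 2:
        raise InsufficientDataError(f"fewer than 2 valid pupil samples after {stage} filter")


def merge_and_interpolate_pupil(
    t: np.ndarray,
    pupil_l: np.ndarray,
    pupil_r: np.ndarray,
    valid_l: np.ndarray,
    valid_r: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-pupil signal with all gaps filled.

    Per sample, the mean of whichever eyes are valid (single-eye
    fallback).  Remaining gaps are filled with a shape-preserving
    piecewise-cubic (PCHIP) interpolant — monotone across gaps, no
    spline overshoot — and leading/trailing gaps take the nearest valid
    value.  Returns (pupil_mean, had_data_mask).
    """
    t = np.asarray(t, dtype=float)
    dl = np.where(valid_l, np.asarray(pupil_l, dtype=float), np.nan)
    dr = np.where(valid_r, np.asarray(pupil_r, dtype=float), np.nan)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.vstack([dl, dr]), axis=0)
    have = np.isfinite(mean)
    if not np.any(have):
        raise InsufficientDataError("no valid pupil samples in either eye")
    if np.sum(have) == 1:
        return np.full_like(t, mean[have][0]), have
    interp = PchipInterpolator(t[have], mean[have], extrapolate=False)
    out = np.where(have, mean, interp(t))
    first, last = np.nonzero(have)[0][[0, -1]]
    out[:first] = mean[first]
    out[last + 1 :] = mean[last]
    return out, have


def interpolate_gaze(
    dirs: np.ndarray,
    valid: np.ndarray,
    max_gap_samples: int = MAX_GAZE_GAP_SAMPLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Fill short gaps in a unit gaze-direction series linearly.

    Gaps of at most ``max_gap_samples`` samples are filled by
    componentwise linear interpolation and re-normalized to unit length
    (during a short dropout the gaze change is expected to be directed,
    hence close to a straight path).  Longer gaps stay missing and are
    excluded from velocity computation.  Returns (filled_dirs,
    valid_after_fill).
    """
    dirs = np.array(dirs, dtype=float, copy=True)
    valid = np.asarray(valid, dtype=bool).copy()
    n = len(valid)
    idx_valid = np.nonzero(valid)[0]
    if len(idx_valid) == 0:
        return dirs, valid
    out_valid = valid.copy()
    for a, b in zip(idx_valid[:-1], idx_valid[1:]):
        gap = b - a - 1
        if gap == 0 or gap > max_gap_samples:
            continue
        w = np.linspace(0.0, 1.0, gap + 2)[1:-1, None]
        seg = (1.0 - w) * dirs[a] + w * dirs[b]
        norms = np.linalg.norm(seg, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        dirs[a + 1 : b] = seg / norms
        out_valid[a + 1 : b] = True
    return dirs, out_valid


def clean(log: EyeSampleLog, **filter_kwargs) -> CleanSignals:
    """Run the full cleaning cascade on one raw log."""
    blink = detect_blinks(log.open_l, log.open_r, filter_kwargs.pop("blink_threshold", BLINK_OPENNESS_THRESHOLD))
    max_gap = filter_kwargs.pop("max_gap_samples", MAX_GAZE_GAP_SAMPLES)
    stages_l = filter_pupil(log.t, log.pupil_l, blink, **filter_kwargs)
    stages_r = filter_pupil(log.t, log.pupil_r, blink, **filter_kwargs)
    pupil_mean, have = merge_and_interpolate_pupil(
        log.t, log.pupil_l, log.pupil_r, stages_l.final, stages_r.final
    )
    raw_valid_l = ~blink & np.all(np.isfinite(log.dir_l), axis=1)
    raw_valid_r = ~blink & np.all(np.isfinite(log.dir_r), axis=1)
    dir_l, valid_l = interpolate_gaze(log.dir_l, raw_valid_l, max_gap)
    dir_r, valid_r = interpolate_gaze(log.dir_r, raw_valid_r, max_gap)
    return CleanSignals(
        t=np.asarray(log.t, dtype=float),
        pupil_mean=pupil_mean,
        pupil_valid_mask=have,
        stages_l=stages_l,
        stages_r=stages_r,
        dir_l=dir_l,
        dir_r=dir_r,
        gaze_valid_l=valid_l,
        gaze_valid_r=valid_r,
        blink_mask=blink,
    )
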