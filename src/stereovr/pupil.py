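"""Pupil-diameter metrics: LHIPA and per-stimulus regression slopes.

The Low/High Index of Pupillary Activity (LHIPA) quantifies pupil
oscillation as a proxy for cognitive load.  The mean-pupil signal is
wavelet-decomposed; the elementwise ratio of the low-frequency detail
band (level ⌊maxlevel/2⌋) to the high-frequency band (level 1) is formed,
its modulus maxima are thresholded with the universal threshold, and the
surviving maxima are counted per second of signal.  A *lower* LHIPA means
relatively more high-frequency oscillation, i.e. higher load.

The per-stimulus slope features split each stimulus segment at its
temporal midpoint and fit an ordinary least-squares line to each half:
the first half can still carry the delayed pupil response to the
*previous* stimulus, so the second-half slope is the cleaner readout of
the response to the current one.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pywt

from .errors import InsufficientDataError

#: Default wavelet for the LHIPA decomposition.  A short symlet keeps
#: two distinct frequency bands available on second-scale stimulus
#: segments at 90 Hz (sym4 needs >= 112 samples for the low band to
#: separate from level 1; a 32-tap symlet would need >= 496).
LHIPA_WAVELET = "sym4"

DEFAULT_DISPARITIES = (275.0, 550.0, 1100.0)
BASELINE_WINDOW_S = 1.0


def _modulus_maxima(x: np.ndarray) -> np.ndarray:
    """Keep strict local maxima of |x|, zero elsewhere."""
    m = np.abs(x)
    out = np.zeros_like(m)
    for i in range(len(m)):
        left = m[i - 1] if i >= 1 else m[i]
        right = m[i + 1] if i < len(m) - 1 else m[i]
        if left <= m[i] >= right and (left < m[i] or m[i] > right):
            out[i] = m[i]
    return out


def lhipa(t: np.ndarray, d: np.ndarray, wavelet: str = LHIPA_WAVELET) -> float:
    """Low/High Index of Pupillary Activity of one pupil segment.

    Raises :class:`InsufficientDataError` when the segment is too short
    for the wavelet to separate a low band (level ⌊maxlevel/2⌋) from the
    level-1 high band — with coincident bands the ratio is constant and
    the index carries no information, so it is treated as missing rather
    than reported as a degenerate number.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(d) < 2 or len(t) != len(d):
        raise InsufficientDataError("LHIPA needs an aligned segment of >= 2 samples")
    w = pywt.Wavelet(wavelet)
    maxlevel = pywt.dwt_max_level(len(d), filter_len=w.dec_len)
    hif, lof = 1, maxlevel // 2
    if lof <= hif:
        raise InsufficientDataError(
            f"segment of {len(d)} samples gives no distinct low band with {wavelet} "
            f"(max level {maxlevel})"
        )
    cD_H = pywt.downcoef("d", d, wavelet, "periodization", level=hif) / math.sqrt(2.0**hif)
    cD_L = pywt.downcoef("d", d, wavelet, "periodization", level=lof) / math.sqrt(2.0**lof)
    # Elementwise LF:HF ratio; the HF band is sampled at the LF band's
    # stride so corresponding coefficients cover the same time span.
    stride = 2 ** (lof - hif)
    idx = np.minimum((np.arange(len(cD_L)) * stride).astype(int), len(cD_H) - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = cD_L / cD_H[idx]
    ratio[~np.isfinite(ratio)] = 0.0
    maxima = _modulus_maxima(ratio)
    lam = float(np.std(maxima)) * math.sqrt(2.0 * np.log2(max(len(maxima), 2)))
    kept = pywt.threshold(maxima, lam, mode="less")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise InsufficientDataError("segment has zero duration")
    return float(np.count_nonzero(kept)) / duration


def segment_signal(
    t: np.ndarray,
    d: np.ndarray,
    events: list[tuple[float, float, int]],
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Cut the mean-pupil signal into per-stimulus segments.

    Returns (stimulus_index, t_seg, d_seg) for every event whose
    onset→offset window contains at least two samples.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    out = []
    for onset, offset, idx in events:
        sel = (t >= onset) & (t <= offset)
        if np.sum(sel) >= 2:
            out.append((idx, t[sel], d[sel]))
    return out


def lhipa_features(
    t: np.ndarray,
    pupil_mean: np.ndarray,
    events: list[tuple[float, float, int]],
    disparity_by_index: dict[int, float],
    disparities: tuple[float, ...] = DEFAULT_DISPARITIES,
    wavelet: str = LHIPA_WAVELET,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> dict[str, float]:
    """Baseline LHIPA plus one mean LHIPA per disparity (4 features).

    The baseline is computed on the idle-phase window of
    ``baseline_window_s`` seconds ending at the first stimulus onset.
    Per-disparity values average the per-segment LHIPA over all segments
    sharing that disparity; segments too short to decompose are skipped.
    """
    t = np.asarray(t, dtype=float)
    out: dict[str, float] = {}

    baseline = np.nan
    if events:
        first_onset = min(e[0] for e in events)
        sel = (t >= first_onset - baseline_window_s) & (t <= first_onset)
        if np.sum(sel) >= 2:
            try:
                baseline = lhipa(t[sel], np.asarray(pupil_mean)[sel], wavelet)
            except InsufficientDataError:
                warnings.warn("baseline window too short for LHIPA; feature set missing")
        else:
            warnings.warn("missing idle window; baseline LHIPA set missing")
    out["LHIPA_Baseline"] = baseline

    per_disp: dict[float, list[float]] = {disp: [] for disp in disparities}
    for idx, ts, ds in segment_signal(t, pupil_mean, events):
        disp = disparity_by_index.get(idx)
        if disp not in per_disp:
            continue
        try:
            per_disp[disp].append(lhipa(ts, ds, wavelet))
        except InsufficientDataError:
            continue
    for disp in disparities:
        vals = per_disp[disp]
        out[f"LHIPA_{disp:.1f}"] = float(np.mean(vals)) if vals else np.nan
    return out


def split_slopes(t: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    """OLS slopes (mm/s) of the two temporal halves of one segment.

    The segment is split at its temporal midpoint: first half t < mid,
    second half t >= mid.  A half with fewer than 2 samples (or no
    temporal spread) yields NaN.
    """
    t = np.asarray(t, dtype=float)
    d = np.asarray(d, dtype=float)
    if len(t) < 4:
        raise InsufficientDataError("split slopes need >= 4 samples")
    mid = (t[0] + t[-1]) / 2.0
    slopes = []
    for mask in (t < mid, t >= mid):
        th, dh = t[mask], d[mask]
        if len(th) < 2 or th[-1] == th[0]:
            slopes.append(np.nan)
        else:
            slopes.append(float(np.polyfit(th, dh, 1)[0]))
    return slopes[0], slopes[1]


def slope_features(
    t: np.ndarray,
    pupil_mean: np.ndarray,
    events: list[tuple[float, float, int]],
    disparity_by_index: dict[int, float],
    disparities: tuple[float, ...] = DEFAULT_DISPARITIES,
) -> dict[str, float]:
    """Per-disparity mean first/second-half slopes (6 features)."""
    per_disp: dict[float, list[tuple[float, float]]] = {disp: [] for disp in disparities}
    for idx, ts, ds in segment_signal(t, pupil_mean, events):
        disp = disparity_by_index.get(idx)
        if disp not in per_disp:
            continue
        try:
            per_disp[disp].append(split_slopes(ts, ds))
        except InsufficientDataError:
            continue
    out: dict[str, float] = {}
    for disp in disparities:
        pairs = per_disp[disp]
        if pairs:
            arr = np.asarray(pairs, dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                s1 = float(np.nanmean(arr[:, 0]))
                s2 = float(np.nanmean(arr[:, 1]))
        else:
            warnings.warn(f"no usable segments for disparity {disp}; slope features missing")
            s1 = s2 = np.nan
        out[f"Slope1_{disp:.1f}"] = s1
        out[f"Slope2_{disp:.1f}"] = s2
    return out
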