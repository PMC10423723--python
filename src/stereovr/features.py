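"""Assembly of the 73-feature vector for one participant run.

Three blocks: stereopsis performance (29 features from the 81 stimulus
responses), pupil diameter (18 features from the cleaned mean-pupil
signal) and gaze behavior (26 features from the per-eye velocity traces,
fixations and dwell labels).

Moment conventions, fixed for reproducibility: population (n-denominator)
standard deviation and variance; skewness and kurtosis are the biased
moment estimators, kurtosis as excess (Fisher).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import gaze as gaze_mod
from . import pupil as pupil_mod
from .errors import StereoVRError
from .preprocess import CleanSignals, EyeSampleLog, clean

DISPARITIES = (275.0, 550.0, 1100.0)
STAT_NAMES = ("Maximum", "Minimum", "Mean", "Median", "SD", "Variance", "Skewness", "Kurtosis")
N_STEREO, N_PUPIL, N_GAZE = 29, 18, 26
N_FEATURES = N_STEREO + N_PUPIL + N_GAZE


@dataclass(frozen=True)
class ResponseRecord:
    """One stimulus response: reaction time and correctness."""

    stimulus_index: int
    disparity_arcsec: float
    position_label: str
    reaction_time_s: float
    correct: bool

    def __post_init__(self) -> None:
        if self.reaction_time_s <= 0:
            raise StereoVRError(f"reaction time must be positive, got {self.reaction_time_s}")


@dataclass
class FeatureVector:
    """Named 73-feature map with group tags ('stereo'/'pupil'/'gaze')."""

    values: dict[str, float]
    groups: dict[str, str]
    missing: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != N_FEATURES:
            raise StereoVRError(f"expected {N_FEATURES} features, got {len(self.values)}")
        counts = {g: sum(1 for v in self.groups.values() if v == g) for g in ("stereo", "pupil", "gaze")}
        if (counts["stereo"], counts["pupil"], counts["gaze"]) != (N_STEREO, N_PUPIL, N_GAZE):
            raise StereoVRError(f"bad block partition: {counts}")

    def as_array(self, names: list[str] | None = None) -> np.ndarray:
        names = names or list(self.values)
        return np.array([self.values[n] for n in names], dtype=float)


def _moments(x: np.ndarray) -> dict[str, float]:
    """The eight descriptive statistics; degenerate shape moments -> NaN."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return {s: np.nan for s in STAT_NAMES}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sd = float(np.std(x))
        out = {
            "Maximum": float(np.max(x)),
            "Minimum": float(np.min(x)),
            "Mean": float(np.mean(x)),
            "Median": float(np.median(x)),
            "SD": sd,
            "Variance": float(np.var(x)),
            "Skewness": float(sps.skew(x)) if sd > 0 else np.nan,
            "Kurtosis": float(sps.kurtosis(x)) if sd > 0 else np.nan,
        }
    return out


def gain(median_hard_s: float, median_easy_s: float) -> float:
    """Reaction-time gain: median(harder) − median(easiest disparity).

    Positive gain = slowing on the harder task; subtracting the easiest
    disparity's median cancels the individual base response time.
    """
    return median_hard_s - median_easy_s


def stereo_features(
    responses: list[ResponseRecord], disparities: tuple[float, ...] = DISPARITIES
) -> dict[str, float]:
    """29 stereopsis-performance features.

    Per disparity: the eight reaction-time statistics on *correct*
    responses only, plus accuracy = correct / tested at that disparity
    (9 × 3 = 27).  Two gains on medians: 275″ vs 1100″ and 550″ vs 1100″.
    A disparity with < 2 correct responses leaves its moment features
    missing (imputed downstream); accuracy is always computed.
    """
    out: dict[str, float] = {}
    medians: dict[float, float] = {}
    for disp in disparities:
        all_resp = [r for r in responses if r.disparity_arcsec == disp]
        rts = np.array([r.reaction_time_s for r in all_resp if r.correct])
        if len(rts) >= 2:
            moms = _moments(rts)
        else:
            moms = {s: np.nan for s in STAT_NAMES}
        for stat in STAT_NAMES:
            out[f"{stat}_{disp:.1f}"] = moms[stat]
        medians[disp] = moms["Median"]
        out[f"Accuracy_{disp:.1f}"] = (
            sum(r.correct for r in all_resp) / len(all_resp) if all_resp else np.nan
        )
    easiest = max(disparities)
    for disp in sorted(disparities)[:-1]:
        out[f"Gain_{disp:.1f}"] = gain(medians[disp], medians[easiest])
    return out


def pupil_features(
    signals: CleanSignals,
    events: list[tuple[float, float, int]],
    disparity_by_index: dict[int, float],
    disparities: tuple[float, ...] = DISPARITIES,
    wavelet: str = pupil_mod.LHIPA_WAVELET,
) -> dict[str, float]:
    """18 pupil features: 8 run-level statistics + 4 LHIPA + 6 slopes.

    All computed from the merged mean-pupil signal, never per eye.
    """
    out = {f"{s}_Pupil": v for s, v in _moments(signals.pupil_mean).items()}
    out.update(
        pupil_mod.lhipa_features(
            signals.t, signals.pupil_mean, events, disparity_by_index, disparities, wavelet
        )
    )
    out.update(
        pupil_mod.slope_features(signals.t, signals.pupil_mean, events, disparity_by_index, disparities)
    )
    return out


def gaze_features(
    signals: CleanSignals,
    fixated_l: np.ndarray,
    fixated_r: np.ndarray,
    threshold_dps: float = gaze_mod.FIXATION_THRESHOLD_DPS,
    min_duration_ms: float = gaze_mod.MIN_FIXATION_MS,
    smoothing_alpha: float = gaze_mod.ASYMPTOTIC_ALPHA,
) -> dict[str, float]:
    """26 gaze features.

    Per eye: number of fixations (2), seven angular-velocity statistics
    — the minimum is excluded, it is zero for everyone — (14), and dwell
    time on each of the four balls plus the background ('nan') (10).
    """
    out: dict[str, float] = {}
    labels = {"Left": (signals.dir_l, signals.gaze_valid_l, fixated_l),
              "Right": (signals.dir_r, signals.gaze_valid_r, fixated_r)}
    for eye, (dirs, valid, fixated) in labels.items():
        trace = gaze_mod.asymptotic_velocity(signals.t, dirs, valid, smoothing_alpha)
        fixations = gaze_mod.detect_fixations(trace, threshold_dps, min_duration_ms)
        out[f"Number_Fixations_{eye}"] = float(fixations.count)
        omega = trace.omega_asym[trace.valid_mask]
        moms = _moments(omega) if len(omega) else {s: np.nan for s in STAT_NAMES}
        for stat in STAT_NAMES:
            if stat == "Minimum":
                continue
            out[f"{stat}_{eye}"] = moms[stat]
        dwell = gaze_mod.durations_by_target(fixated, signals.t)
        for lab in gaze_mod.DWELL_LABELS:
            out[f"{lab}_Fixation_Duration_{eye}"] = dwell[lab]
    return out


def assemble(
    stereo: dict[str, float], pupil: dict[str, float], gaze: dict[str, float]
) -> FeatureVector:
    """Canonical 73-entry feature vector with group tags."""
    values: dict[str, float] = {}
    groups: dict[str, str] = {}
    for block, tag in ((stereo, "stereo"), (pupil, "pupil"), (gaze, "gaze")):
        for name, val in block.items():
            if name in values:
                raise StereoVRError(f"duplicate feature name {name!r}")
            values[name] = float(val)
            groups[name] = tag
    missing = [n for n, v in values.items() if not np.isfinite(v)]
    return FeatureVector(values=values, groups=groups, missing=missing)


def extract_features(
    log: EyeSampleLog,
    responses: list[ResponseRecord],
    disparities: tuple[float, ...] = DISPARITIES,
    **params,
) -> FeatureVector:
    """Full extraction for one participant run: clean, then all blocks."""
    signals = clean(log, **{k: v for k, v in params.items() if k in
                            ("blink_threshold", "max_gap_samples", "mad_multiplier",
                             "min_cluster_ms", "max_sep_ms", "pupil_range_mm")})
    disparity_by_index = {r.stimulus_index: r.disparity_arcsec for r in responses}
    stereo = stereo_features(responses, disparities)
    pupil = pupil_features(
        signals, log.events, disparity_by_index, disparities,
        wavelet=params.get("wavelet", pupil_mod.LHIPA_WAVELET),
    )
    gz = gaze_features(
        signals, log.fixated_l, log.fixated_r,
        threshold_dps=params.get("threshold_dps", gaze_mod.FIXATION_THRESHOLD_DPS),
        min_duration_ms=params.get("min_duration_ms", gaze_mod.MIN_FIXATION_MS),
        smoothing_alpha=params.get("smoothing_alpha", gaze_mod.ASYMPTOTIC_ALPHA),
    )
    return assemble(stereo, pupil, gz)


def feature_group(name: str) -> str:
    """Group tag of a canonical feature name."""
    if name.startswith(("LHIPA", "Slope")) or name.endswith("_Pupil"):
        return "pupil"
    if "Fixation" in name or name.endswith(("_Left", "_Right")):
        return "gaze"
    return "stereo"
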