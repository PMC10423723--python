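"""Synthetic-cohort generator.

Produces raw ~90 Hz eye-tracking logs, stimulus event markers and
response records for control-like and Post-COVID-like participants.  The
group contrasts mirror the clinically reported direction of effects:
patients respond more slowly (especially at small disparities), less
accurately, move their eyes more slowly, hold fixations longer and show
a more oscillatory pupil signal at the hardest disparity.  Ground-truth
generating parameters are stored with every participant so recovery
tests can close the loop.

The generator is the single source of truth for the raw-log schema: it
emits exactly the channels the preprocessing module consumes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .features import ResponseRecord
from .geometry import HeadsetSpec, StimulusSpec, TrialSchedule, build_trial_schedule
from .preprocess import EyeSampleLog

IDLE_DURATION_S = 2.0
INTER_STIMULUS_S = 0.8
SACCADE_PEAK_DPS = 250.0
FIXATION_DWELL_S = 0.30
FIXATION_JITTER_DEG = 0.05
BLINK_DURATION_RANGE_S = (0.12, 0.25)
#: Frequency band of the stylized fast pupil oscillation (Hz).  Placed
#: inside the level-1 wavelet band at 90 Hz so the oscillatory-load
#: contrast is identifiable on second-scale stimulus segments.
HF_FREQ_RANGE_HZ = (23.0, 28.0)
HF_BASE_AMP_MM = 0.01
DRIFT_AMP_MM = 0.15
DRIFT_FREQ_HZ = 0.05

_DIFFICULTY_STEP = {1100.0: 0, 550.0: 1, 275.0: 2}


@dataclass(frozen=True)
class EffectProfile:
    """Group-level generating parameters.

    Reaction time is lognormal: the median at the easiest disparity is
    ``rt_base_s`` and grows ``rt_disparity_slope_s`` per difficulty step
    (1100″ → 550″ → 275″), plus ``rt_group_shift_s`` for the clinical
    group; ``rt_sigma`` is the log-scale spread.  ``velocity_scale``
    multiplies every gaze speed (saccades and fixational jitter);
    ``fixation_prolongation`` multiplies fixation dwell times.
    ``hf_oscillation_gain`` is the amplitude (mm) of the high-frequency
    pupil oscillation during 275″ stimuli — the hardest task, where
    cognitive load bites.
    """

    rt_base_s: float = 1.6
    rt_disparity_slope_s: float = 0.3
    rt_group_shift_s: float = 0.0
    rt_sigma: float = 0.25
    accuracy_by_disparity: dict[float, float] = field(
        default_factory=lambda: {275.0: 0.80, 550.0: 0.90, 1100.0: 0.97}
    )
    velocity_scale: float = 1.0
    fixation_prolongation: float = 1.0
    pupil_base_mm: float = 4.2
    pupil_noise_sd: float = 0.02
    hf_oscillation_gain: float = 0.012
    blink_rate_hz: float = 0.2
    missingness_rate: float = 0.01

    def __post_init__(self) -> None:
        assert all(0.0 <= p <= 1.0 for p in self.accuracy_by_disparity.values())
        assert self.rt_sigma >= 0 and self.pupil_noise_sd >= 0
        assert self.velocity_scale > 0 and self.fixation_prolongation > 0


CONTROL_PROFILE = EffectProfile()
POSTCOVID_PROFILE = EffectProfile(
    rt_group_shift_s=0.35,
    accuracy_by_disparity={275.0: 0.66, 550.0: 0.82, 1100.0: 0.92},
    velocity_scale=0.75,
    fixation_prolongation=1.35,
    hf_oscillation_gain=0.05,
)


@dataclass
class SyntheticParticipant:
    """One simulated run plus the ground truth that generated it."""

    id: str
    label: str  # 'control' | 'postcovid'
    schedule: TrialSchedule
    log: EyeSampleLog
    responses: list[ResponseRecord]
    truth: dict


def _individualize(profile: EffectProfile, rng: np.random.Generator) -> EffectProfile:
    """Draw per-participant random effects around the group profile."""
    rt_mult = float(np.exp(rng.normal(0.0, 0.08)))
    vel_mult = float(np.exp(rng.normal(0.0, 0.05)))
    acc = {
        d: float(np.clip(p + rng.normal(0.0, 0.02), 0.05, 1.0))
        for d, p in profile.accuracy_by_disparity.items()
    }
    return dataclasses.replace(
        profile,
        rt_base_s=profile.rt_base_s * rt_mult,
        rt_group_shift_s=profile.rt_group_shift_s * rt_mult,
        accuracy_by_disparity=acc,
        velocity_scale=profile.velocity_scale * vel_mult,
        pupil_base_mm=float(np.clip(profile.pupil_base_mm + rng.normal(0.0, 0.3), 2.5, 7.0)),
    )


def simulate_responses(
    schedule: TrialSchedule, profile: EffectProfile, rng: np.random.Generator | int | None = None
) -> list[ResponseRecord]:
    """Seeded responses: lognormal RTs, Bernoulli correctness.

    The RT median decreases with disparity (275″ slowest) and carries
    the group shift; correctness follows the profile's per-disparity
    accuracy.
    """
    rng = np.random.default_rng(rng)
    out = []
    for stim in schedule.stimuli:
        step = _DIFFICULTY_STEP.get(stim.disparity_arcsec, 0)
        median = profile.rt_base_s + step * profile.rt_disparity_slope_s + profile.rt_group_shift_s
        rt = float(median * np.exp(rng.normal(0.0, profile.rt_sigma)))
        acc = profile.accuracy_by_disparity.get(stim.disparity_arcsec, 0.9)
        out.append(
            ResponseRecord(
                stimulus_index=stim.index,
                disparity_arcsec=stim.disparity_arcsec,
                position_label=stim.position_label,
                reaction_time_s=max(rt, 0.2),
                correct=bool(rng.random() < acc),
            )
        )
    return out


def _slerp(a: np.ndarray, b: np.ndarray, w: float) -> np.ndarray:
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    ang = np.arccos(dot)
    if ang < 1e-9:
        return a
    return (np.sin((1 - w) * ang) * a + np.sin(w * ang) * b) / np.sin(ang)


def _gaze_script_for_stimulus(
    stim: StimulusSpec,
    response: ResponseRecord,
    t_on: float,
    profile: EffectProfile,
    rng: np.random.Generator,
) -> list[tuple[float, float, np.ndarray, str]]:
    """Fixation plan (t0, t1, 3-D point, label) covering onset→response.

    The participant scans balls in random order and ends on the ball
    they answer with (the near target if correct, another otherwise);
    saccade times between fixations come out of the same budget.
    """
    balls = stim.ball_positions()
    t_off = t_on + response.reaction_time_s
    if response.correct:
        final = stim.target_ball
    else:
        others = [b for b in balls if b != stim.target_ball]
        final = others[rng.integers(len(others))]
    segs: list[tuple[float, float, np.ndarray, str]] = []
    t = t_on
    current = None
    while t < t_off:
        remaining = t_off - t
        candidates = [b for b in balls if b != current]
        ball = candidates[rng.integers(len(candidates))]
        dwell = FIXATION_DWELL_S * profile.fixation_prolongation * float(
            np.exp(rng.normal(0.0, 0.25))
        )
        if remaining < dwell * 1.5:
            ball, dwell = final, remaining
        segs.append((t, min(t + dwell, t_off), balls[ball], ball))
        t += dwell + 0.04  # nominal saccade budget; real timing set at rasterization
        current = ball
    return segs


def simulate_eye_log(
    schedule: TrialSchedule,
    responses: list[ResponseRecord],
    profile: EffectProfile,
    rng: np.random.Generator | int | None = None,
    refresh_hz: float = 90.0,
    ipd_cm: float = 6.3,
) -> EyeSampleLog:
    """Frame-by-frame synthetic eye-tracking channels for one run."""
    rng = np.random.default_rng(rng)

    # --- timeline & fixation script -------------------------------------
    events: list[tuple[float, float, int]] = []
    script: list[tuple[float, float, np.ndarray, str]] = []
    t_cursor = IDLE_DURATION_S
    script.append((0.0, t_cursor, np.array([200.0, 0.0, 0.0]), "nan"))
    resp_by_idx = {r.stimulus_index: r for r in responses}
    for stim in schedule.stimuli:
        center = np.asarray(stim.center_xyz)
        script.append((t_cursor, t_cursor + INTER_STIMULUS_S, center, "nan"))
        t_on = t_cursor + INTER_STIMULUS_S
        resp = resp_by_idx[stim.index]
        script.extend(_gaze_script_for_stimulus(stim, resp, t_on, profile, rng))
        t_off = t_on + resp.reaction_time_s
        events.append((t_on, t_off, stim.index))
        t_cursor = t_off
    total = t_cursor + 0.5

    dt = 1.0 / refresh_hz
    n = int(np.ceil(total / dt))
    t = np.arange(n) * dt

    # --- rasterize gaze --------------------------------------------------
    origin_l = np.array([0.0, -ipd_cm / 2.0, 0.0])
    origin_r = np.array([0.0, +ipd_cm / 2.0, 0.0])
    seg_start = np.array([s[0] for s in script])
    seg_idx = np.clip(np.searchsorted(seg_start, t, side="right") - 1, 0, len(script) - 1)

    dir_l = np.empty((n, 3))
    dir_r = np.empty((n, 3))
    labels = np.empty(n, dtype=object)
    saccade_speed = SACCADE_PEAK_DPS * profile.velocity_scale
    jitter_deg = FIXATION_JITTER_DEG * profile.velocity_scale

    # Per-frame rotation is capped at the saccade peak velocity, so
    # transitions between fixation points unfold as saccade-like sweeps.
    max_step = np.radians(saccade_speed * dt)
    prev_dl = None
    prev_dr = None
    for i in range(n):
        _, _, point, lab = script[seg_idx[i]]
        tl = point - origin_l
        tr = point - origin_r
        tl = tl / np.linalg.norm(tl)
        tr = tr / np.linalg.norm(tr)
        if prev_dl is None:
            dl, dr, lab_i = tl, tr, lab
        else:
            ang = np.arccos(np.clip(np.dot(prev_dl, tl), -1.0, 1.0))
            if ang > max_step:
                w = max_step / ang
                dl = _slerp(prev_dl, tl, w)
                dr = _slerp(prev_dr, tr, w)
                lab_i = "nan"  # mid-saccade: no ball fixated
            else:
                dl, dr, lab_i = tl, tr, lab
        # fixational jitter
        noise = rng.normal(0.0, np.radians(jitter_deg), size=3)
        dl = dl + np.cross(noise, dl)
        dr = dr + np.cross(noise, dr)
        dl /= np.linalg.norm(dl)
        dr /= np.linalg.norm(dr)
        dir_l[i] = dl
        dir_r[i] = dr
        labels[i] = lab_i
        prev_dl, prev_dr = dl, dr

    # --- pupil signal ----------------------------------------------------
    base = profile.pupil_base_mm
    drift = DRIFT_AMP_MM * np.sin(2 * np.pi * DRIFT_FREQ_HZ * t + rng.uniform(0, 2 * np.pi))
    pupil = base + drift

    # stimulus-evoked dilation transients (delayed ramp, slow decay)
    for (t_on, t_off, idx), stim in zip(events, schedule.stimuli):
        step = _DIFFICULTY_STEP.get(stim.disparity_arcsec, 0)
        amp = 0.08 + 0.04 * step
        during = (t >= t_on) & (t < t_off)
        pupil[during] += amp * (1.0 - np.exp(-(t[during] - t_on) / 0.4))
        after = (t >= t_off) & (t < t_off + 3.0)
        level = amp * (1.0 - np.exp(-(t_off - t_on) / 0.4))
        pupil[after] += level * np.exp(-(t[after] - t_off) / 0.8)

    # fast narrow-band oscillation (shared between eyes): a small base
    # amplitude during every stimulus, boosted at the hardest disparity
    for (t_on, t_off, idx), stim in zip(events, schedule.stimuli):
        sel = (t >= t_on) & (t < t_off)
        amp = (
            profile.hf_oscillation_gain
            if stim.disparity_arcsec == 275.0
            else HF_BASE_AMP_MM
        )
        freq = rng.uniform(*HF_FREQ_RANGE_HZ)
        pupil[sel] += amp * np.sin(2 * np.pi * freq * t[sel] + rng.uniform(0, 2 * np.pi))

    pupil_l = pupil + 0.04 + rng.normal(0.0, profile.pupil_noise_sd, n)
    pupil_r = pupil - 0.04 + rng.normal(0.0, profile.pupil_noise_sd, n)

    # --- blinks and dropouts ---------------------------------------------
    open_l = np.clip(0.95 + rng.normal(0.0, 0.02, n), 0.0, 1.0)
    open_r = np.clip(0.95 + rng.normal(0.0, 0.02, n), 0.0, 1.0)
    n_blinks = rng.poisson(profile.blink_rate_hz * total)
    blink_truth = []
    for _ in range(n_blinks):
        bt = rng.uniform(0.0, total)
        bd = rng.uniform(*BLINK_DURATION_RANGE_S)
        sel = (t >= bt) & (t < bt + bd)
        if not np.any(sel):
            continue
        open_l[sel] = 0.02
        open_r[sel] = 0.02
        pupil_l[sel] = np.nan
        pupil_r[sel] = np.nan
        dir_l[sel] = np.nan
        dir_r[sel] = np.nan
        blink_truth.append((bt, bt + bd))

    if profile.missingness_rate > 0:
        drop = rng.random(n) < profile.missingness_rate
        pupil_l[drop] = np.nan
        pupil_r[drop] = np.nan
        dir_l[drop] = np.nan
        dir_r[drop] = np.nan

    fixated_l = labels.copy()
    fixated_r = labels.copy()
    invalid_gaze = ~np.isfinite(dir_l[:, 0])
    fixated_l[invalid_gaze] = "nan"
    fixated_r[invalid_gaze] = "nan"

    log = EyeSampleLog(
        t=t,
        pupil_l=pupil_l,
        pupil_r=pupil_r,
        open_l=open_l,
        open_r=open_r,
        origin_l=np.tile(origin_l, (n, 1)),
        origin_r=np.tile(origin_r, (n, 1)),
        dir_l=dir_l,
        dir_r=dir_r,
        fixated_l=fixated_l,
        fixated_r=fixated_r,
        events=events,
        idle_start_t=0.0,
    )
    log.blink_truth = blink_truth  # ground truth for recovery tests
    return log


def simulate_participant(
    pid: str,
    label: str,
    profile: EffectProfile,
    seed_seq: np.random.SeedSequence,
    headset: HeadsetSpec | None = None,
) -> SyntheticParticipant:
    """One participant: schedule, responses and raw log from one seed."""
    rng = np.random.default_rng(seed_seq)
    schedule_seed = int(rng.integers(0, 2**31 - 1))
    indiv = _individualize(profile, rng)
    headset = headset or HeadsetSpec()
    schedule = build_trial_schedule(seed=schedule_seed, headset=headset)
    responses = simulate_responses(schedule, indiv, rng)
    log = simulate_eye_log(schedule, responses, indiv, rng, refresh_hz=headset.refresh_hz)
    truth = {
        "profile": {
            k: (v if not isinstance(v, dict) else {str(kk): vv for kk, vv in v.items()})
            for k, v in dataclasses.asdict(indiv).items()
        },
        "schedule_seed": schedule_seed,
        "n_blinks": len(getattr(log, "blink_truth", [])),
    }
    return SyntheticParticipant(
        id=pid, label=label, schedule=schedule, log=log, responses=responses, truth=truth
    )


def simulate_cohort(
    n_control: int = 15,
    n_postcovid: int = 20,
    profiles: dict[str, EffectProfile] | None = None,
    seed: int = 0,
) -> list[SyntheticParticipant]:
    """Independent participants around the two group profiles.

    Default sizes mirror a 15-control / 20-patient pilot cohort.  The
    whole cohort is reproducible from (profiles, seed).
    """
    assert n_control >= 1 and n_postcovid >= 1
    profiles = profiles or {"control": CONTROL_PROFILE, "postcovid": POSTCOVID_PROFILE}
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_control + n_postcovid)
    cohort = []
    for i in range(n_control):
        cohort.append(
            simulate_participant(f"C{i:02d}", "control", profiles["control"], children[i])
        )
    for j in range(n_postcovid):
        cohort.append(
            simulate_participant(
                f"P{j:02d}", "postcovid", profiles["postcovid"], children[n_control + j]
            )
        )
    return cohort
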