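"""Stereoscopic stimulus geometry.

The stimulus is a rhombus of four balls floating 200 cm in front of the
observer; one ball is rendered nearer than the others so that the depth
offset corresponds to a requested binocular disparity *difference* Θ
(arcseconds).  This module quantizes Θ to the headset's pixel grid, places
the stimulus in spherical coordinates, solves the near-ball viewing
distance D from Θ, applies the monocular-cue corrections (size scaling,
per-ball positional jitter) and builds randomized trial schedules.

Coordinate convention: x-forward, y-right, z-up (the rendering engine's
frame).  All internal trigonometry is in radians; arcseconds convert via
the exact factor 1″ = π/648000 rad.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    GeometryInfeasibleError,
    InvalidConfigError,
    InvalidDisparityError,
    NotRenderableError,
)

ARCSEC_TO_RAD = math.pi / 648000.0
RAD_TO_ARCSEC = 1.0 / ARCSEC_TO_RAD

#: The nine test positions.  Peripheral labels are listed in the azimuth
#: order φ = 0°, 45°, ..., 315°; ``Central`` has θ = φ = 0.
PERIPHERAL_LABELS = (
    "Down",
    "LowerRight",
    "Right",
    "UpperRight",
    "Up",
    "UpperLeft",
    "Left",
    "LowerLeft",
)
POSITION_LABELS = ("Central",) + PERIPHERAL_LABELS

TARGET_BALLS = ("Up", "Down", "Left", "Right")

#: Horizontal/vertical distance of each ball from the stimulus center (cm).
BALL_OFFSET_CM = 25.0
#: Ball diameter (cm); a sphere scaled to resemble a small football.
BALL_DIAMETER_CM = 25.0

#: Unit offsets of the four balls in the stimulus plane, (right, up) order.
_BALL_PLANE_OFFSETS = {
    "Up": (0.0, 1.0),
    "Down": (0.0, -1.0),
    "Left": (-1.0, 0.0),
    "Right": (1.0, 0.0),
}


@dataclass(frozen=True)
class HeadsetSpec:
    """Display properties that bound the renderable disparities.

    Parameters
    ----------
    fov_deg : float
        Horizontal field of view (degrees).
    h_pixels : int
        Horizontal resolution per eye (pixels).
    refresh_hz : float
        Render / eye-tracking sampling rate (Hz).
    ipd_cm : float
        Interpupillary distance ``a`` (cm).  The mean human value of
        6.3 cm is a sufficient stand-in because the viewing distance is
        much larger than any interindividual IPD variation.
    """

    fov_deg: float = 110.0
    h_pixels: int = 1440
    refresh_hz: float = 90.0
    ipd_cm: float = 6.3

    def __post_init__(self) -> None:
        if self.fov_deg <= 0 or self.h_pixels < 1 or self.ipd_cm <= 0 or self.refresh_hz <= 0:
            raise InvalidConfigError(
                f"invalid headset spec: fov={self.fov_deg}, h_pixels={self.h_pixels}, "
                f"refresh={self.refresh_hz}, ipd={self.ipd_cm}"
            )


@dataclass(frozen=True)
class GeometrySolution:
    """Solved viewing geometry for one disparity difference.

    Attributes mirror the quantities of the two-object disparity model:
    Θ (``theta_dd_arcsec``) is the disparity difference, Φ_A / Φ_B the
    disparities of the near and far object, D the solved distance of the
    near object, Δd the depth offset to the far object at ``D_total``,
    e the horizontal shift of the near object, and l1/l2 the horizontal
    eye–object distances.  ``scale_s`` is the size correction D/D_total
    applied to the near ball to cancel the size monocular cue.
    """

    theta_dd_arcsec: float
    phi_A_rad: float
    phi_B_rad: float
    D_cm: float
    delta_d_cm: float
    e_cm: float
    l1_cm: float
    l2_cm: float
    c1: float
    c2: float
    c3: float
    scale_s: float


def min_disparity_difference(headset: HeadsetSpec) -> float:
    """Smallest renderable disparity difference (arcsec per pixel).

    One pixel of horizontal image-point disparity on a display of
    ``h_pixels`` across ``fov_deg`` subtends fov/h_pixels degrees, i.e.
    ``fov_deg / h_pixels * 3600`` arcseconds.
    """
    return headset.fov_deg / headset.h_pixels * 3600.0


def quantize_disparity(requested_arcsec: float, headset: HeadsetSpec) -> float:
    """Snap a requested disparity difference to the pixel-grid quantum.

    Only integer multiples of :func:`min_disparity_difference` are
    renderable.  Requests below half a quantum would round to zero and
    are rejected.
    """
    if requested_arcsec <= 0:
        raise NotRenderableError(f"disparity must be positive, got {requested_arcsec}")
    dd_min = min_disparity_difference(headset)
    k = round(requested_arcsec / dd_min)
    if k < 1:
        raise NotRenderableError(
            f"requested {requested_arcsec}″ is below half the quantum {dd_min}″"
        )
    return k * dd_min


def stimulus_position(
    r_cm: float, theta_deg: float, phi_deg: float, formula: str = "corrected"
) -> np.ndarray:
    """Cartesian stimulus-center position from spherical test coordinates.

    ``formula="printed"`` evaluates r·(cosθ, sinφ·cosθ, −cosφ·sinθ), the
    rotated spherical transform as originally printed; its y-term mixes a
    cosθ factor that inflates ‖p‖ beyond r for azimuths off the x–z
    plane.  ``formula="corrected"`` (default) uses r·(cosθ, sinφ·sinθ,
    −cosφ·sinθ), which keeps every test position at distance r from the
    observer — the stated intent (all stimuli at 200 cm).
    """
    if r_cm <= 0:
        raise InvalidConfigError(f"radius must be positive, got {r_cm}")
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    if formula == "printed":
        vec = (math.cos(th), math.sin(ph) * math.cos(th), -math.cos(ph) * math.sin(th))
    elif formula == "corrected":
        vec = (math.cos(th), math.sin(ph) * math.sin(th), -math.cos(ph) * math.sin(th))
    else:
        raise InvalidConfigError(f"unknown placement formula {formula!r}")
    return r_cm * np.array(vec)


def position_angles(label: str, theta_deg: float = 10.0) -> tuple[float, float]:
    """(inclination θ, azimuth φ) in degrees for a named test position."""
    if label == "Central":
        return 0.0, 0.0
    try:
        idx = PERIPHERAL_LABELS.index(label)
    except ValueError:
        raise InvalidConfigError(f"unknown position label {label!r}") from None
    return theta_deg, 45.0 * idx


def disparity_of_far_object(ipd_cm: float, D_total_cm: float) -> float:
    """Disparity Φ_B (radians) of the unshifted object at distance D_total.

    Φ_B = 2·atan(a / (2·D_total)) for interpupillary distance a.
    """
    if D_total_cm <= 0:
        raise InvalidConfigError(f"D_total must be positive, got {D_total_cm}")
    return 2.0 * math.atan(ipd_cm / (2.0 * D_total_cm))


def size_scale(D_cm: float, D_total_cm: float) -> float:
    """Size correction s = D / D_total for the near ball.

    Scaling the near ball down by s cancels the retinal-size monocular
    cue a nearer object would otherwise give away.
    """
    if not (0 < D_cm <= D_total_cm):
        raise InvalidConfigError(f"need 0 < D <= D_total, got D={D_cm}, D_total={D_total_cm}")
    return D_cm / D_total_cm


def solve_target_distance(
    theta_arcsec: float,
    ipd_cm: float = 6.3,
    D_total_cm: float = 200.0,
    e_cm: float = 0.0,
) -> GeometrySolution:
    """Distance D of the near object producing disparity difference Θ.

    With l1 = |e| and l2 = |e| + |a| the horizontal eye–object distances,
    the near object's disparity is Φ_A = atan(l2/D) − atan(l1/D) and
    Θ = Φ_A − Φ_B.  Applying the tangent subtraction identity turns this
    into the quadratic c1·D² + c2·D + c3 = 0 with c1 = tan(Θ + Φ_B),
    c2 = l1 − l2 and c3 = c1·l1·l2.  Of the two roots only the one with
    0 < D < D_total corresponds to an object nearer than the reference.
    """
    if theta_arcsec < 0:
        raise InvalidDisparityError(f"disparity difference must be >= 0, got {theta_arcsec}")
    if e_cm < 0:
        e_cm = abs(e_cm)
    phi_B = disparity_of_far_object(ipd_cm, D_total_cm)
    theta_rad = theta_arcsec * ARCSEC_TO_RAD
    angle = theta_rad + phi_B
    if angle >= math.pi / 2:
        raise InvalidDisparityError(
            f"disparity {theta_arcsec}″ puts Θ+Φ_B past 90°; tangent overflows"
        )
    l1 = abs(e_cm)
    l2 = abs(e_cm) + abs(ipd_cm)
    c1 = math.tan(angle)
    c2 = l1 - l2
    c3 = c1 * l1 * l2

    if theta_arcsec == 0:
        # Θ = 0 leaves the near object at the reference distance.
        D = D_total_cm
    elif c1 == 0.0:
        raise GeometryInfeasibleError("degenerate geometry: tan(Θ+Φ_B) = 0")
    else:
        disc = c2 * c2 - 4.0 * c1 * c3
        if disc < 0:
            raise GeometryInfeasibleError(
                f"no real root for Θ={theta_arcsec}″ (discriminant {disc:.3g})"
            )
        sq = math.sqrt(disc)
        roots = [(-c2 + sq) / (2.0 * c1), (-c2 - sq) / (2.0 * c1)]
        valid = [d for d in roots if 0.0 < d < D_total_cm]
        if not valid:
            raise GeometryInfeasibleError(
                f"no root in (0, {D_total_cm}) for Θ={theta_arcsec}″; roots={roots}"
            )
        # Both roots rarely land in range; prefer the larger (continuity
        # with the Θ -> 0 limit where D -> D_total).
        D = max(valid)

    phi_A = math.atan(l2 / D) - math.atan(l1 / D)
    return GeometrySolution(
        theta_dd_arcsec=theta_arcsec,
        phi_A_rad=phi_A,
        phi_B_rad=phi_B,
        D_cm=D,
        delta_d_cm=D_total_cm - D,
        e_cm=e_cm,
        l1_cm=l1,
        l2_cm=l2,
        c1=c1,
        c2=c2,
        c3=c3,
        scale_s=size_scale(D, D_total_cm),
    )


def recovered_disparity_arcsec(sol: GeometrySolution) -> float:
    """Recompute Θ (arcsec) from a solved geometry — round-trip check."""
    return (sol.phi_A_rad - sol.phi_B_rad) * RAD_TO_ARCSEC


def jitter_ball_offsets(rng: np.random.Generator | int | None = None) -> dict[str, float]:
    """Per-ball random positional jitter (cm), the linear-perspective veil.

    Each of the four balls receives an independent offset drawn uniformly
    from [0, 2] cm with a random sign — applied horizontally to the
    Left/Right balls and vertically to the Up/Down balls — so that no two
    stimuli present the same perspective lines.
    """
    rng = np.random.default_rng(rng)
    magnitudes = rng.uniform(0.0, 2.0, size=4)
    signs = rng.choice([-1.0, 1.0], size=4)
    return dict(zip(TARGET_BALLS, magnitudes * signs))


@dataclass(frozen=True)
class StimulusSpec:
    """One stereoscopic task: where the stimulus sits and which ball is near."""

    index: int
    disparity_arcsec: float
    position_label: str
    azimuth_deg: float
    inclination_deg: float
    radius_cm: float
    center_xyz: tuple[float, float, float]
    target_ball: str
    geometry: GeometrySolution
    jitter_cm: dict[str, float] = field(default_factory=dict)

    def ball_positions(self) -> dict[str, np.ndarray]:
        """World positions of the four balls (cm), jitter applied.

        The ball plane is perpendicular to the viewing direction; its
        right/up axes derive from the world up vector.  The target ball
        is pulled onto the solved near distance D and the others stay at
        the full radius.
        """
        center = np.asarray(self.center_xyz)
        fwd = center / np.linalg.norm(center)
        up_world = np.array([0.0, 0.0, 1.0])
        right = np.cross(fwd, up_world)
        nr = np.linalg.norm(right)
        if nr < 1e-12:  # looking straight up/down; cannot happen for θ ≤ 10°
            right = np.array([0.0, 1.0, 0.0])
        else:
            right = right / nr
        up = np.cross(right, fwd)
        out: dict[str, np.ndarray] = {}
        for ball, (dr, du) in _BALL_PLANE_OFFSETS.items():
            jitter = self.jitter_cm.get(ball, 0.0)
            dr_cm = dr * BALL_OFFSET_CM + (jitter if dr != 0.0 else 0.0)
            du_cm = du * BALL_OFFSET_CM + (jitter if du != 0.0 else 0.0)
            pos = center + dr_cm * right + du_cm * up
            if ball == self.target_ball:
                # Near ball: same visual direction, distance D instead of r.
                pos = pos / np.linalg.norm(pos) * self.geometry.D_cm
            out[ball] = pos
        return out


@dataclass(frozen=True)
class TrialSchedule:
    """Seeded factorial schedule of stereoscopic tasks for one trial run."""

    stimuli: tuple[StimulusSpec, ...]
    seed: int
    disparities: tuple[float, ...]
    positions: tuple[str, ...]
    repetitions: int

    def __len__(self) -> int:
        return len(self.stimuli)


def build_trial_schedule(
    disparities: tuple[float, ...] = (275.0, 550.0, 1100.0),
    positions: tuple[str, ...] = POSITION_LABELS,
    repetitions: int = 3,
    seed: int = 0,
    headset: HeadsetSpec | None = None,
    r_cm: float = 200.0,
    theta_deg: float = 10.0,
    e_cm: float = 0.0,
    placement_formula: str = "corrected",
) -> TrialSchedule:
    """Full factorial (disparity × position) × repetitions, seeded order.

    Every disparity is first quantized to the headset's pixel grid; the
    resulting cells are repeated ``repetitions`` times, shuffled with a
    seeded permutation, and each stimulus draws its near-target ball
    uniformly and its per-ball jitter independently.
    """
    if not disparities or not positions:
        raise InvalidConfigError("factor lists must be non-empty")
    if repetitions < 1:
        raise InvalidConfigError(f"repetitions must be >= 1, got {repetitions}")
    headset = headset or HeadsetSpec()
    rng = np.random.default_rng(seed)

    quantized = [quantize_disparity(d, headset) for d in disparities]
    solutions = {
        d: solve_target_distance(d, headset.ipd_cm, r_cm, e_cm) for d in quantized
    }
    cells = [(d, p) for d in quantized for p in positions for _ in range(repetitions)]
    order = rng.permutation(len(cells))

    stimuli = []
    for index, cell_idx in enumerate(order):
        d, label = cells[cell_idx]
        theta, phi = position_angles(label, theta_deg)
        center = stimulus_position(r_cm, theta, phi, placement_formula)
        target = TARGET_BALLS[rng.integers(0, 4)]
        jitter = jitter_ball_offsets(rng)
        stimuli.append(
            StimulusSpec(
                index=index,
                disparity_arcsec=d,
                position_label=label,
                azimuth_deg=phi,
                inclination_deg=theta,
                radius_cm=r_cm,
                center_xyz=tuple(center),
                target_ball=target,
                geometry=solutions[d],
                jitter_cm=jitter,
            )
        )
    return TrialSchedule(
        stimuli=tuple(stimuli),
        seed=seed,
        disparities=tuple(quantized),
        positions=tuple(positions),
        repetitions=repetitions,
    )
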