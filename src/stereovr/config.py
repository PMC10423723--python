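"""Validated run configuration.

Defaults equal the study-protocol values where those are stated
(110° FoV / 1440 px / 90 Hz headset, 6.3 cm IPD, 200 cm viewing
distance, 10° inclination, disparities {275, 550, 1100}″ × 9 positions
× 3 repetitions, openness threshold 0.1, pupil range 1.5–9.0 mm,
10-sample gaze gap limit, seed 0); the rest are implementation defaults,
marked as such by ``provenance()``.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HeadsetConfig(_Strict):
    fov_deg: float = Field(110.0, gt=0)
    h_pixels: int = Field(1440, ge=1)
    refresh_hz: float = Field(90.0, gt=0)
    ipd_cm: float = Field(6.3, gt=0)


class GeometryConfig(_Strict):
    r_cm: float = Field(200.0, gt=0)
    theta_deg: float = 10.0
    disparities: list[float] = [275.0, 550.0, 1100.0]
    repetitions: int = Field(3, ge=1)
    e_cm: float = Field(0.0, ge=0)
    placement_formula: str = "corrected"


class PreprocessConfig(_Strict):
    blink_threshold: float = 0.1
    pupil_range_mm: tuple[float, float] = (1.5, 9.0)
    mad_multiplier: float = 16.0
    min_cluster_ms: float = 50.0
    max_sep_ms: float = 40.0
    max_gap_samples: int = 10
    blink_padding_samples: int = 0


class MetricsConfig(_Strict):
    fixation_threshold_dps: float = 30.0
    min_fixation_ms: float = 100.0
    smoothing_alpha: float = 0.6
    lhipa_wavelet: str = "sym4"
    baseline_window_s: float = 1.0


class BenchConfig(_Strict):
    classifiers: list[str] = ["svm_linear", "svm_rbf", "knn", "rf"]
    groups: list[str] = ["stereo", "pupil", "gaze", "all"]
    rf_n_estimators: int = 300


class CohortConfig(_Strict):
    n_control: int = Field(15, ge=1)
    n_postcovid: int = Field(20, ge=1)


class RunConfig(_Strict):
    headset: HeadsetConfig = HeadsetConfig()
    geometry: GeometryConfig = GeometryConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    metrics: MetricsConfig = MetricsConfig()
    bench: BenchConfig = BenchConfig()
    cohort: CohortConfig = CohortConfig()
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def provenance(self) -> dict[str, str]:
        """Which defaults are protocol values vs implementation choices."""
        protocol = {
            "headset.fov_deg", "headset.h_pixels", "headset.refresh_hz", "headset.ipd_cm",
            "geometry.r_cm", "geometry.theta_deg", "geometry.disparities",
            "geometry.repetitions", "preprocess.blink_threshold",
            "preprocess.pupil_range_mm", "preprocess.max_gap_samples",
            "bench.classifiers", "bench.rf_n_estimators",
            "cohort.n_control", "cohort.n_postcovid", "seed",
        }
        out = {}
        for section, model in self.model_dump().items():
            if isinstance(model, dict):
                for key in model:
                    dotted = f"{section}.{key}"
                    out[dotted] = "protocol" if dotted in protocol else "implementation default"
            else:
                out[section] = "protocol" if section in protocol else "implementation default"
        return out
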