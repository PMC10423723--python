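"""End-to-end pipeline: simulate → preprocess → features → bench → report."""

from __future__ import annotations

import logging
from pathlib import Path

from . import classify, io
from .config import RunConfig
from .features import extract_features
from .simulate import simulate_cohort

log = logging.getLogger("stereovr")


def extract_cohort_features(cohort, config: RunConfig | None = None):
    """Feature vectors for every participant; returns (vectors, labels)."""
    config = config or RunConfig()
    vectors, labels = {}, {}
    for part in cohort:
        vec = extract_features(
            part.log,
            part.responses,
            disparities=tuple(config.geometry.disparities),
            blink_threshold=config.preprocess.blink_threshold,
            max_gap_samples=config.preprocess.max_gap_samples,
            mad_multiplier=config.preprocess.mad_multiplier,
            min_cluster_ms=config.preprocess.min_cluster_ms,
            max_sep_ms=config.preprocess.max_sep_ms,
            pupil_range_mm=config.preprocess.pupil_range_mm,
            wavelet=config.metrics.lhipa_wavelet,
            threshold_dps=config.metrics.fixation_threshold_dps,
            min_duration_ms=config.metrics.min_fixation_ms,
            smoothing_alpha=config.metrics.smoothing_alpha,
        )
        vectors[part.id] = vec
        labels[part.id] = part.label
        log.info(
            "features %s: %d entries, %d missing", part.id, len(vec.values), len(vec.missing)
        )
    return vectors, labels


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute all stages and write the artifacts; returns the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = simulate_cohort(
        config.cohort.n_control, config.cohort.n_postcovid, seed=config.seed
    )
    for part in cohort:
        io.write_responses(part.responses, out / f"{part.id}_responses.csv")
    vectors, labels = extract_cohort_features(cohort, config)
    df = io.write_feature_matrix(vectors, labels, out / "features.csv")

    X, y, names, tags = io.read_feature_matrix(out / "features.csv")
    spaces = {
        "rf": classify.SearchSpace.default("rf", rf_n_estimators=config.bench.rf_n_estimators)
    }
    report = classify.run_bench(
        X, y, names, tags,
        groups=config.bench.groups,
        classifiers=config.bench.classifiers,
        seed=config.seed,
        spaces=spaces,
    )
    io.write_json(report, out / "ncv_report.json")
    return report
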