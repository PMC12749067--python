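"""Reproducible end-to-end experiments on synthetic phantom datasets.

These functions glue the generator, the feature extractors and the
evaluation harness together while streaming scans one at a time (a full
scan is ~20 MB; ensembles of hundreds must never be held in memory).
The CLI, the test suite and the results-reproduction script all call
these entry points.
"""

from __future__ import annotations

import numpy as np

from .estimators import FFTFeatureExtractor
from .ml_eval import (
    ClassifierSpec,
    DetectionReport,
    EvalReport,
    SplitPlan,
    density_stratified_detection,
    evaluate,
)
from .synthetic import (
    GeneratorConfig,
    estimate_spatial_moments,
    generate_scan,
    iter_dataset,
)

__all__ = [
    "spatial_moment_ensemble",
    "extract_dataset_features",
    "density_classification_experiment",
    "detection_experiment",
]


def spatial_moment_ensemble(
    density: str,
    n_scans: int,
    seed: int,
    config: GeneratorConfig | None = None,
    freqs_hz=(4.0e9, 6.0e9),
    health: str = "healthy",
) -> dict:
    """Across-receiver |S21| moments of an ensemble of generated scans.

    Returns ``{f_hz: {"mean": array, "std": array, "cv": array}}`` with one
    entry per scan; per-scan seeds derive from the master seed.  Scans are
    generated, reduced and discarded one at a time.
    """
    config = config or GeneratorConfig()
    child = np.random.SeedSequence(seed).generate_state(n_scans, dtype=np.uint32)
    out = {f: {"mean": [], "std": [], "cv": []} for f in freqs_hz}
    for i in range(n_scans):
        scan = generate_scan(density, health, int(child[i]), config)
        for f in freqs_hz:
            m = estimate_spatial_moments(scan, f)
            out[f]["mean"].append(m.mean)
            out[f]["std"].append(m.std)
            out[f]["cv"].append(m.cv)
    return {f: {k: np.asarray(v) for k, v in d.items()} for f, d in out.items()}


def extract_dataset_features(
    n_per_cell: int,
    seed: int,
    config: GeneratorConfig | None = None,
    extractor=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    """Generate a 2x2 (density x health) dataset and extract features, streaming.

    Returns ``(features, density_labels, health_labels, feature_names)``.
    """
    extractor = extractor or FFTFeatureExtractor()
    rows, density, health = [], [], []
    fitted = False
    for scan in iter_dataset(n_per_cell, seed, config):
        if not fitted:
            extractor.fit([scan])
            fitted = True
        rows.append(extractor.transform([scan])[0])
        density.append(scan.density_label)
        health.append(scan.health_label)
    return (
        np.vstack(rows),
        np.asarray(density),
        np.asarray(health),
        tuple(extractor.feature_names_),
    )


def density_classification_experiment(
    n_per_cell: int = 50,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    extractor=None,
) -> EvalReport:
    """LD-vs-HD classification on a generated dataset (end-to-end pipeline)."""
    X, density, _, _ = extract_dataset_features(n_per_cell, seed, config, extractor)
    return evaluate(
        X, density, spec=spec or ClassifierSpec("svm_rbf"), plan=plan, positive_label="LD"
    )


def detection_experiment(
    n_per_cell: int = 40,
    seed: int = 0,
    config: GeneratorConfig | None = None,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    extractor=None,
) -> tuple[DetectionReport, DetectionReport]:
    """Healthy / non-healthy detection with and without the density prior.

    Returns ``(stratified_report, pooled_report)`` evaluated on identical
    splits of the same generated dataset.
    """
    spec = spec or ClassifierSpec("naive_bayes")
    X, density, health, _ = extract_dataset_features(n_per_cell, seed, config, extractor)
    stratified = density_stratified_detection(
        X, density, health, spec=spec, plan=plan, use_density_prior=True
    )
    pooled = density_stratified_detection(
        X, density, health, spec=spec, plan=plan, use_density_prior=False
    )
    return stratified, pooled
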