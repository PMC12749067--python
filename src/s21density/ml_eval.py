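"""Evaluation harness: Monte-Carlo x k-fold splitting, classifier sweep,
balance rate, sub-band search and density-stratified cancer detection.

The protocol mirrors common practice for modest clinical cohorts: in each
Monte-Carlo run a stratified 20% test split is held out, 4-fold
cross-validation inside the remaining 80% provides validation metrics, the
model is refitted on the full 80% and scored on the held-out 20%.  All
reported numbers are means +/- stds across runs.  Feature standardization is
fitted inside each training split only (no test leakage).

The balance rate BR = (2 - (sensitivity + specificity)) + |sensitivity -
specificity| summarises a binary classifier in [0, 2]: 0 only for a perfect
balanced classifier, 2 at the degenerate corners; it penalises both low and
*unbalanced* class-wise performance, which matters in screening settings.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .preprocess import SubBandMask

__all__ = [
    "balance_rate",
    "SplitPlan",
    "ClassifierSpec",
    "EvalReport",
    "DetectionReport",
    "evaluate",
    "subband_search",
    "subband_search_features",
    "density_stratified_detection",
    "TABLE_MASKS",
]

METRIC_KEYS = ("total_accuracy", "sensitivity", "specificity", "balance_rate")

# The 19 sub-band combinations examined in the frequency-selection study:
# the eight single bands plus eleven hand-picked unions.
TABLE_MASKS: tuple[str, ...] = (
    "1000 0000",
    "0100 0000",
    "0010 0000",
    "0001 0000",
    "0000 1000",
    "0000 0100",
    "0000 0010",
    "0000 0001",
    "1010 1010",
    "0101 0101",
    "0011 1100",
    "1100 0000",
    "0000 0011",
    "1100 0011",
    "1111 0000",
    "0000 1111",
    "1001 1100",
    "1011 1100",
    "1111 1111",
)


def balance_rate(sensitivity: float, specificity: float) -> float:
    """Balance rate of a binary classifier; lower is better, 0 is perfect.

    ``(2 - (sensitivity + specificity)) + |sensitivity - specificity|``.
    Symmetric in its arguments; equals 2 at (1,0), (0,1) and (0,0).
    """
    s, p = float(sensitivity), float(specificity)
    if not (0.0 <= s <= 1.0 and 0.0 <= p <= 1.0):
        raise ValueError(f"rates must lie in [0, 1], got ({s}, {p})")
    return (2.0 - (s + p)) + abs(s - p)


@dataclass(frozen=True)
class SplitPlan:
    """Monte-Carlo x k-fold split protocol."""

    n_monte_carlo: int = 5
    test_fraction: float = 0.2
    n_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_monte_carlo < 1:
            raise ValueError("n_monte_carlo must be >= 1")


def _builders():
    return {
        "knn": lambda hp, rs: KNeighborsClassifier(n_neighbors=int(hp.get("k", 5))),
        "naive_bayes": lambda hp, rs: GaussianNB(**hp),
        "svm_rbf": lambda hp, rs: SVC(
            kernel="rbf", C=float(hp.get("C", 1.0)), gamma=hp.get("gamma", "scale"),
            random_state=rs,
        ),
        "svm_linear": lambda hp, rs: SVC(
            kernel="linear", C=float(hp.get("C", 1.0)), random_state=rs
        ),
        "decision_tree": lambda hp, rs: DecisionTreeClassifier(random_state=rs, **hp),
        "random_forest": lambda hp, rs: RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)), random_state=rs
        ),
        "adaboost": lambda hp, rs: AdaBoostClassifier(
            n_estimators=int(hp.get("n_estimators", 50)), random_state=rs
        ),
        "xgboost": _build_xgboost,
        "majority": lambda hp, rs: DummyClassifier(strategy="most_frequent"),
    }


def _build_xgboost(hp, rs):
    try:
        from xgboost import XGBClassifier
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("the 'xgboost' classifier family requires the xgboost package") from exc
    return XGBClassifier(random_state=rs, **hp)


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus hyperparameters (library defaults otherwise)."""

    family: str = "svm_rbf"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _builders():
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"known: {sorted(_builders())}"
            )

    def build(self, random_state: int | None = None):
        return _builders()[self.family](dict(self.hyperparameters), random_state)


def _default_positive(classes) -> str:
    """Which class plays the sensitivity slot (BR is symmetric, so the
    assignment only affects reporting labels)."""
    s = set(classes)
    if s == {"LD", "HD"}:
        return "LD"
    if s == {"healthy", "non-healthy"}:
        return "non-healthy"
    return sorted(classes)[0]


def _metrics(y_true, y_pred, positive, negative) -> dict:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == positive
    neg = y_true == negative
    sens = float((y_pred[pos] == positive).mean()) if pos.any() else np.nan
    spec = float((y_pred[neg] == negative).mean()) if neg.any() else np.nan
    return {
        "total_accuracy": float((y_pred == y_true).mean()),
        "sensitivity": sens,
        "specificity": spec,
        "balance_rate": balance_rate(sens, spec),
    }


def _make_pipeline(spec: ClassifierSpec, random_state: int):
    return Pipeline(
        [("scale", StandardScaler()), ("clf", spec.build(random_state=random_state))]
    )


def _aggregate(run_dicts) -> dict:
    out = {}
    for key in METRIC_KEYS:
        vals = np.array([r[key] for r in run_dicts], dtype=float)
        out[key] = {
            "mean": float(np.nanmean(vals)),
            "std": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return out


@dataclass
class EvalReport:
    """Per-run and aggregate metrics of one evaluation."""

    runs: list
    aggregate: dict
    classes: tuple[str, str]  # (sensitivity slot, specificity slot)
    n_samples: int
    classifier: str

    def to_json(self, path=None) -> str:
        payload = {
            "classifier": self.classifier,
            "classes": {"sensitivity": self.classes[0], "specificity": self.classes[1]},
            "n_samples": self.n_samples,
            "runs": self.runs,
            "aggregate": self.aggregate,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_row(self) -> dict:
        row = {}
        for split in ("validation", "test"):
            for key in METRIC_KEYS:
                agg = self.aggregate[split][key]
                row[f"{split}_{key}_mean"] = agg["mean"]
                row[f"{split}_{key}_std"] = agg["std"]
        return row


def evaluate(
    X,
    y,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    positive_label: str | None = None,
) -> EvalReport:
    """Monte-Carlo x k-fold evaluation of one feature matrix.

    For each run: stratified ``test_fraction`` hold-out; ``n_folds``-fold CV
    inside the training part (validation metrics); refit on the full training
    part and score on the hold-out (test metrics).  Standardization is fitted
    per training split inside the pipeline.
    """
    spec = spec or ClassifierSpec()
    plan = plan or SplitPlan()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("evaluation needs at least 2 classes")
    positive = positive_label or _default_positive(classes)
    if positive not in classes:
        raise ValueError(f"positive label {positive!r} not among classes {classes}")
    negative = [c for c in classes if c != positive][0]

    sss = StratifiedShuffleSplit(
        n_splits=plan.n_monte_carlo, test_size=plan.test_fraction, random_state=plan.seed
    )
    runs = []
    for r, (train_idx, test_idx) in enumerate(sss.split(X, y)):
        X_tr, y_tr = X[train_idx], y[train_idx]
        X_te, y_te = X[test_idx], y[test_idx]
        fold_seed = (plan.seed + 7919 * (r + 1)) % (2**31)
        skf = StratifiedKFold(n_splits=plan.n_folds, shuffle=True, random_state=fold_seed)
        fold_metrics = []
        for f, (fit_idx, val_idx) in enumerate(skf.split(X_tr, y_tr)):
            pipe = _make_pipeline(spec, (fold_seed + f) % (2**31))
            pipe.fit(X_tr[fit_idx], y_tr[fit_idx])
            fold_metrics.append(_metrics(y_tr[val_idx], pipe.predict(X_tr[val_idx]), positive, negative))
        val = {k: float(np.nanmean([m[k] for m in fold_metrics])) for k in METRIC_KEYS}
        pipe = _make_pipeline(spec, fold_seed)
        pipe.fit(X_tr, y_tr)
        test = _metrics(y_te, pipe.predict(X_te), positive, negative)
        runs.append({"run": r, "validation": val, "test": test})

    aggregate = {
        "validation": _aggregate([r["validation"] for r in runs]),
        "test": _aggregate([r["test"] for r in runs]),
    }
    return EvalReport(
        runs=runs,
        aggregate=aggregate,
        classes=(str(positive), str(negative)),
        n_samples=int(len(y)),
        classifier=spec.family,
    )


# ---------------------------------------------------------------------------
# sub-band search
# ---------------------------------------------------------------------------


def _band_columns_from_names(names) -> dict[int, np.ndarray]:
    """Column indices per 1-based band, parsed from per-band feature names."""
    bands: dict[int, list[int]] = {}
    for j, name in enumerate(names):
        parts = name.split("_")
        tag = parts[1]
        if not tag.startswith("sb"):
            raise ValueError(f"feature {name!r} is not a per-band feature")
        bands.setdefault(int(tag[2:]), []).append(j)
    return {b: np.asarray(cols) for b, cols in bands.items()}


def subband_search_features(
    features: np.ndarray,
    feature_names,
    y,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    masks=None,
    positive_label: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rank sub-band masks given a precomputed all-band per-band feature matrix.

    Splits depend only on the plan seed and labels, so every mask is
    evaluated on identical partitions and rows are directly comparable.
    Ranking: ascending test balance rate, then descending test accuracy.
    """
    masks = [SubBandMask.coerce(m) for m in (masks or TABLE_MASKS)]
    unique, seen = [], set()
    for m in masks:
        if m.bits in seen:
            warnings.warn(f"duplicate sub-band mask {m} dropped", stacklevel=2)
            continue
        seen.add(m.bits)
        unique.append(m)
    band_cols = _band_columns_from_names(feature_names)
    available = set(band_cols)
    reports: dict[str, EvalReport] = {}
    rows = []
    for mask in unique:
        missing = set(mask.selected_bands) - available
        if missing:
            raise ValueError(f"mask {mask} selects band(s) {sorted(missing)} absent from features")
        cols = np.concatenate([band_cols[b] for b in mask.selected_bands])
        rep = evaluate(features[:, cols], y, spec=spec, plan=plan, positive_label=positive_label)
        reports[mask.to_string()] = rep
        rows.append({"mask": mask.to_string(), "n_bands": mask.n_selected, **rep.summary_row()})
    table = pd.DataFrame(rows).sort_values(
        by=["test_balance_rate_mean", "test_total_accuracy_mean"],
        ascending=[True, False],
        kind="stable",
    )
    return table.reset_index(drop=True), reports


def subband_search(
    scans,
    y,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    masks=None,
    n_components: int = 40,
    positive_label: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Extract all-band per-band features once, then rank the given masks."""
    from .estimators import FFTFeatureExtractor

    ext = FFTFeatureExtractor(
        n_components=n_components, mode="per_band", mask=SubBandMask.all_bands()
    ).fit(scans)
    F = ext.transform(scans)
    return subband_search_features(
        F, ext.feature_names_, y, spec=spec, plan=plan, masks=masks,
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# density-stratified cancer detection
# ---------------------------------------------------------------------------


@dataclass
class DetectionReport:
    """Per-density-stratum sensitivity/specificity of cancer detection."""

    per_stratum: dict  # stratum -> {"runs": [...], "aggregate": {...}}
    use_density_prior: bool
    classifier: str

    def aggregate_numbers(self) -> dict:
        """The 4 headline numbers: (sens, spec) x (LD, HD), as means."""
        out = {}
        for stratum, rep in self.per_stratum.items():
            for key in ("sensitivity", "specificity"):
                out[f"{stratum}_{key}"] = rep["aggregate"][key]["mean"]
        return out

    def to_json(self, path=None) -> str:
        payload = {
            "use_density_prior": self.use_density_prior,
            "classifier": self.classifier,
            "per_stratum": self.per_stratum,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def density_stratified_detection(
    X,
    density,
    health,
    spec: ClassifierSpec | None = None,
    plan: SplitPlan | None = None,
    use_density_prior: bool = True,
) -> DetectionReport:
    """Healthy / non-healthy detection, reported per density stratum.

    ``use_density_prior=True``: one detector per density stratum, fitted on
    that stratum's training samples; test samples are routed by their density
    label.  ``use_density_prior=False``: a single pooled detector, metrics
    still reported per stratum.  Sensitivity is non-healthy recall,
    specificity healthy recall.
    """
    spec = spec or ClassifierSpec("naive_bayes")
    plan = plan or SplitPlan()
    X = np.asarray(X, dtype=float)
    density = np.asarray(density)
    health = np.asarray(health)
    if len(set(density)) < 2 or len(set(health)) < 2:
        raise ValueError("detection needs both density strata and both health classes")
    combo = np.char.add(np.char.add(density.astype(str), "|"), health.astype(str))
    strata = sorted(set(density))

    sss = StratifiedShuffleSplit(
        n_splits=plan.n_monte_carlo, test_size=plan.test_fraction, random_state=plan.seed
    )
    per_stratum: dict[str, dict] = {s: {"runs": []} for s in strata}
    for r, (train_idx, test_idx) in enumerate(sss.split(X, combo)):
        rs = (plan.seed + 7919 * (r + 1)) % (2**31)
        models: dict[str, object] = {}
        if use_density_prior:
            for s in strata:
                sel = train_idx[density[train_idx] == s]
                counts = pd.Series(health[sel]).value_counts()
                if len(counts) < 2 or counts.min() < 2:
                    warnings.warn(
                        f"stratum {s!r} skipped: fewer than 2 training samples of a health class",
                        stacklevel=2,
                    )
                    continue
                pipe = _make_pipeline(spec, rs)
                pipe.fit(X[sel], health[sel])
                models[s] = pipe
        else:
            pipe = _make_pipeline(spec, rs)
            pipe.fit(X[train_idx], health[train_idx])
            models = {s: pipe for s in strata}
        for s in strata:
            if s not in models:
                continue
            sel = test_idx[density[test_idx] == s]
            if sel.size == 0:
                continue
            m = _metrics(health[sel], models[s].predict(X[sel]), "non-healthy", "healthy")
            per_stratum[s]["runs"].append({"run": r, **m})

    for s in strata:
        runs = per_stratum[s]["runs"]
        per_stratum[s]["aggregate"] = _aggregate(runs) if runs else {}
    return DetectionReport(
        per_stratum=per_stratum, use_density_prior=use_density_prior, classifier=spec.family
    )
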