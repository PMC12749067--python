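"""Dual-domain FFT features and baseline feature families.

For each per-transmitter block the complex S21 sub-matrix is Fourier
transformed along both axes:

* ``rf_spectral`` -- DFT along the frequency axis of each receiver row,
  describing how the transmission response oscillates across the measurement
  band (dielectric dispersion);
* ``spatial`` -- DFT along the receiver-angle axis of each frequency column,
  describing angular heterogeneity of the transmitted wavefront (scattering
  richness).

Both transforms are the plain unnormalised forward DFT with kernel
``exp(-j*2*pi*k*n/N)``.  The first K coefficients (K=40 by default) are kept,
split into magnitude and phase, and summarised by the mean and population
standard deviation pooled over all retained entries -- eight numbers per
block, concatenated over transmitters (and over sub-bands in per-band mode)
into the final feature vector.

Baselines: classical per-block statistics (mean, std, min, max, median,
range, Shannon index) and per-block PCA scores of the flattened |S21|.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler

from .preprocess import SubBandMask, remove_dc_bias, subband_slice
from .s21_io import S21Scan, TxBlock, split_by_transmitter

__all__ = [
    "CoefficientBlock",
    "PolarBlock",
    "FeatureConfig",
    "FeatureBlock",
    "FeatureVector",
    "Standardizer",
    "fft_along",
    "polar_decompose",
    "block_features",
    "extract_features",
    "feature_vector_length",
    "fit_standardizer",
    "apply_standardizer",
    "stack_features",
    "sf_features",
    "SF_STAT_NAMES",
    "pca_features",
]

DOMAINS = ("rf_spectral", "spatial")

# order of the eight per-block statistics
STAT_NAMES = (
    ("rf_spectral", "mag", "mean"),
    ("rf_spectral", "mag", "std"),
    ("rf_spectral", "phase", "mean"),
    ("rf_spectral", "phase", "std"),
    ("spatial", "mag", "mean"),
    ("spatial", "mag", "std"),
    ("spatial", "phase", "mean"),
    ("spatial", "phase", "std"),
)


@dataclass
class CoefficientBlock:
    """DFT coefficients of one block along one domain."""

    values: np.ndarray
    domain: str

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"domain must be one of {DOMAINS}, got {self.domain!r}")

    @property
    def transform_axis(self) -> int:
        # rf_spectral transforms each row over frequency (axis 1);
        # spatial transforms each column over receivers (axis 0)
        return 1 if self.domain == "rf_spectral" else 0

    @property
    def n_components_available(self) -> int:
        return self.values.shape[self.transform_axis]


@dataclass
class PolarBlock:
    """Magnitude and phase of truncated DFT coefficients."""

    magnitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must have identical shapes")


def fft_along(block: TxBlock, domain: str) -> CoefficientBlock:
    """Unnormalised forward DFT of a block along one domain.

    ``rf_spectral``: for each receiver row i,
    ``C[i,k] = sum_n S21[i,n] exp(-j*2*pi*k*n/F)``, k = 0..F-1.
    ``spatial``: for each frequency column j,
    ``C[k,j] = sum_n S21[n,j] exp(-j*2*pi*k*n/R)``, k = 0..R-1.
    """
    if domain not in DOMAINS:
        raise ValueError(f"domain must be one of {DOMAINS}, got {domain!r}")
    if block.values.size == 0:
        raise ValueError("cannot transform an empty block")
    axis = 1 if domain == "rf_spectral" else 0
    return CoefficientBlock(values=np.fft.fft(block.values, axis=axis), domain=domain)


def polar_decompose(coeffs: CoefficientBlock, n_components: int) -> PolarBlock:
    """Magnitude and phase of the first ``n_components`` coefficients.

    Truncation keeps k = 0..K-1 along the transform axis.  Phase is the
    two-argument arctangent in (-pi, pi]; the phase of an exactly-zero
    coefficient is 0.
    """
    avail = coeffs.n_components_available
    if not 1 <= n_components <= avail:
        raise ValueError(f"n_components={n_components} outside 1..{avail}")
    sl = (slice(None), slice(0, n_components))
    if coeffs.transform_axis == 0:
        sl = (slice(0, n_components), slice(None))
    kept = coeffs.values[sl]
    phase = np.angle(kept)
    phase[phase == -np.pi] = np.pi  # principal value in (-pi, pi]
    return PolarBlock(magnitude=np.abs(kept), phase=phase)


@dataclass(frozen=True)
class FeatureConfig:
    """Configuration of the dual-domain FFT feature family.

    ``mode="whole_band"`` processes each full-band block directly;
    ``mode="per_band"`` slices the selected sub-bands first and processes each
    independently (DC removal recomputed within each band), concatenating the
    per-band statistics.
    """

    n_components: int = 40
    use_magnitude: bool = True
    use_phase: bool = True
    mask: SubBandMask = field(default_factory=SubBandMask.all_bands)
    mode: str = "whole_band"

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", SubBandMask.coerce(self.mask))
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not (self.use_magnitude or self.use_phase):
            raise ValueError("at least one of use_magnitude/use_phase must be set")
        if self.mode not in ("whole_band", "per_band"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "per_band" and self.mask.n_selected == 0:
            raise ValueError("per_band mode needs a non-empty sub-band mask")

    @property
    def stat_keys(self) -> tuple[tuple[str, str, str], ...]:
        return tuple(
            (dom, qty, st)
            for (dom, qty, st) in STAT_NAMES
            if (qty == "mag" and self.use_magnitude) or (qty == "phase" and self.use_phase)
        )


@dataclass
class FeatureBlock:
    """The eight per-block statistics, in canonical order."""

    stats: dict

    def as_array(self, config: FeatureConfig) -> np.ndarray:
        return np.array([self.stats[k] for k in config.stat_keys], dtype=float)


@dataclass
class FeatureVector:
    """Flat feature vector with a (tx, band, domain, quantity, statistic) layout."""

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if len(self.names) != self.values.size:
            raise ValueError("one name per feature required")


def block_features(block: TxBlock, config: FeatureConfig) -> FeatureBlock:
    """Mean/std of magnitude and phase of both truncated DFTs of one block.

    Expects the block to be DC-removed already.  Statistics pool over all
    retained entries (rows x K components); std is the population standard
    deviation.
    """
    stats: dict = {}
    for domain in DOMAINS:
        polar = polar_decompose(fft_along(block, domain), config.n_components)
        for qty, arr in (("mag", polar.magnitude), ("phase", polar.phase)):
            flat = arr.ravel()
            stats[(domain, qty, "mean")] = float(flat.mean())
            stats[(domain, qty, "std")] = float(flat.std())
    return FeatureBlock(stats=stats)


def _feature_names(n_tx: int, config: FeatureConfig) -> tuple[str, ...]:
    names = []
    bands = ("full",) if config.mode == "whole_band" else tuple(
        f"sb{b}" for b in config.mask.selected_bands
    )
    for t in range(n_tx):
        for band in bands:
            for dom, qty, st in config.stat_keys:
                dom_short = "spec" if dom == "rf_spectral" else "spat"
                names.append(f"tx{t:02d}_{band}_{dom_short}_{qty}_{st}")
    return tuple(names)


def feature_vector_length(n_tx: int, config: FeatureConfig) -> int:
    """Expected feature count: (#stats) * n_tx * n_bands."""
    n_bands = 1 if config.mode == "whole_band" else config.mask.n_selected
    return len(config.stat_keys) * n_tx * n_bands


def extract_features(scan: S21Scan, config: FeatureConfig | None = None) -> FeatureVector:
    """Dual-domain FFT feature vector of one scan.

    Whole-band: per transmitter block, remove DC then compute the block
    statistics.  Per-band: slice the selected sub-bands first, remove DC
    within each band, then compute per-band statistics; concatenation is
    (transmitter, band) lexicographic.
    """
    config = config or FeatureConfig()
    pieces = []
    for block in split_by_transmitter(scan):
        if config.mode == "whole_band":
            sub_blocks = [block]
        else:
            sub_blocks = subband_slice(block, config.mask)
        for sub in sub_blocks:
            pieces.append(block_features(remove_dc_bias(sub), config).as_array(config))
    return FeatureVector(
        values=np.concatenate(pieces), names=_feature_names(scan.geometry.n_tx, config)
    )


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def stack_features(features) -> np.ndarray:
    """Stack FeatureVectors (or rows) into an (n_samples, n_features) matrix."""
    rows = [f.values if isinstance(f, FeatureVector) else np.asarray(f, float) for f in features]
    return np.vstack([r.reshape(1, -1) for r in rows])


class Standardizer:
    """Per-feature z-scoring fitted on training samples only.

    Thin wrapper over :class:`sklearn.preprocessing.StandardScaler`
    (population std).  Features that are constant on the training set map to
    zero and are flagged in ``zero_variance_mask_``.
    """

    def __init__(self) -> None:
        self._scaler: StandardScaler | None = None

    def fit(self, features) -> "Standardizer":
        X = stack_features(features)
        if X.shape[0] < 2:
            raise ValueError("standardizer needs at least 2 training vectors")
        self._scaler = StandardScaler().fit(X)
        self.mean_ = self._scaler.mean_
        self.scale_ = self._scaler.scale_
        self.zero_variance_mask_ = self._scaler.var_ == 0.0
        return self

    def transform(self, features):
        if self._scaler is None:
            raise ValueError("standardizer is not fitted")
        if isinstance(features, FeatureVector):
            vals = self.transform([features])[0]
            return FeatureVector(values=vals, names=features.names)
        Z = self._scaler.transform(stack_features(features))
        Z[:, self.zero_variance_mask_] = 0.0  # constants map to exactly 0
        return Z


def fit_standardizer(train_features) -> Standardizer:
    return Standardizer().fit(train_features)


def apply_standardizer(params: Standardizer, features):
    return params.transform(features)


# ---------------------------------------------------------------------------
# baseline feature families
# ---------------------------------------------------------------------------

SF_STAT_NAMES = ("mean", "std", "min", "max", "median", "range", "shannon")


def sf_features(block: TxBlock) -> np.ndarray:
    """Classical statistics of the flattened |S21| entries of one block.

    Returns [mean, std, min, max, median, range, Shannon index].  The Shannon
    index is H = -sum p_i ln p_i with p_i = |x_i| / sum |x_j| (zero terms
    contribute 0; an all-zero block has H = 0).  Std is population std.
    """
    a = np.abs(block.values).ravel()
    if a.size == 0:
        raise ValueError("cannot compute statistics of an empty block")
    total = a.sum()
    if total == 0.0:
        shannon = 0.0
    else:
        p = a / total
        p = p[p > 0]
        shannon = float(-(p * np.log(p)).sum())
    return np.array(
        [a.mean(), a.std(), a.min(), a.max(), np.median(a), a.max() - a.min(), shannon],
        dtype=float,
    )


def pca_features(train_scans, test_scans, n_pcs: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-block PCA scores of flattened |S21|, concatenated over transmitters.

    Components are fitted on the training scans only (one PCA per transmitter
    position); test scans are projected with the training loadings.  Thin
    wrapper over :class:`~s21density.estimators.BlockPCAExtractor`.
    """
    from .estimators import BlockPCAExtractor

    ext = BlockPCAExtractor(n_pcs=n_pcs).fit(train_scans)
    return ext.transform(train_scans), ext.transform(test_scans)
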