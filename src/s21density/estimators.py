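"""scikit-learn style feature extractors operating on lists of scans.

Each extractor is a ``TransformerMixin`` whose ``transform`` maps a sequence
of :class:`~s21density.s21_io.S21Scan` to a dense ``(n_scans, n_features)``
matrix, so the extractors compose with sklearn pipelines and model
selection.  The dual-domain FFT and SF extractors are stateless; the
block-PCA extractor learns its loadings from the training scans.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from .features import (
    SF_STAT_NAMES,
    FeatureConfig,
    extract_features,
    sf_features,
)
from .preprocess import SubBandMask
from .s21_io import split_by_transmitter

__all__ = ["FFTFeatureExtractor", "StatisticalFeatureExtractor", "BlockPCAExtractor"]


def _as_scan_list(X):
    scans = list(X)
    if not scans:
        raise ValueError("need at least one scan")
    return scans


class FFTFeatureExtractor(TransformerMixin, BaseEstimator):
    """Dual-domain FFT statistics of each scan (the primary feature family).

    Parameters
    ----------
    n_components:
        Number of DFT coefficients kept per domain (k = 0..K-1).
    use_magnitude, use_phase:
        Which polar quantities contribute statistics.
    mode:
        ``"whole_band"`` (one block per transmitter) or ``"per_band"``
        (independent processing of each selected 1 GHz sub-band).
    mask:
        Sub-band selection, as a :class:`SubBandMask` or its string form
        (only consulted in per-band mode).
    """

    def __init__(
        self,
        n_components: int = 40,
        use_magnitude: bool = True,
        use_phase: bool = True,
        mode: str = "whole_band",
        mask="1111 1111",
    ):
        self.n_components = n_components
        self.use_magnitude = use_magnitude
        self.use_phase = use_phase
        self.mode = mode
        self.mask = mask

    def _config(self) -> FeatureConfig:
        return FeatureConfig(
            n_components=self.n_components,
            use_magnitude=self.use_magnitude,
            use_phase=self.use_phase,
            mode=self.mode,
            mask=SubBandMask.coerce(self.mask),
        )

    def fit(self, X, y=None):
        scans = _as_scan_list(X)
        cfg = self._config()
        first = extract_features(scans[0], cfg)
        self.feature_names_ = first.names
        self.n_features_out_ = first.values.size
        return self

    def transform(self, X) -> np.ndarray:
        cfg = self._config()
        return np.vstack([extract_features(s, cfg).values for s in _as_scan_list(X)])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


class StatisticalFeatureExtractor(TransformerMixin, BaseEstimator):
    """Classical per-block statistics of |S21| (SF baseline): 7 per transmitter."""

    def fit(self, X, y=None):
        scans = _as_scan_list(X)
        n_tx = scans[0].geometry.n_tx
        self.feature_names_ = tuple(
            f"tx{t:02d}_{name}" for t in range(n_tx) for name in SF_STAT_NAMES
        )
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        rows = []
        for scan in _as_scan_list(X):
            rows.append(
                np.concatenate([sf_features(b) for b in split_by_transmitter(scan)])
            )
        return np.vstack(rows)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)


class BlockPCAExtractor(TransformerMixin, BaseEstimator):
    """Per-transmitter PCA of flattened |S21|, scores concatenated.

    One PCA is fitted per transmitter position on the training scans'
    flattened magnitude vectors; ``transform`` projects with the training
    loadings.  Raises if ``n_pcs`` exceeds the rank of the centred training
    data.
    """

    def __init__(self, n_pcs: int = 10):
        self.n_pcs = n_pcs

    @staticmethod
    def _block_matrix(scans, t: int) -> np.ndarray:
        return np.vstack(
            [np.abs(split_by_transmitter(s)[t].values).ravel() for s in scans]
        )

    def fit(self, X, y=None):
        scans = _as_scan_list(X)
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")
        n_tx = scans[0].geometry.n_tx
        self.pcas_ = []
        for t in range(n_tx):
            A = self._block_matrix(scans, t)
            rank = np.linalg.matrix_rank(A - A.mean(axis=0, keepdims=True))
            if self.n_pcs > rank:
                raise ValueError(
                    f"n_pcs={self.n_pcs} exceeds training rank {rank} at transmitter {t}"
                )
            self.pcas_.append(PCA(n_components=self.n_pcs, svd_solver="full").fit(A))
        self.feature_names_ = tuple(
            f"tx{t:02d}_pc{k}" for t in range(n_tx) for k in range(self.n_pcs)
        )
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        scans = _as_scan_list(X)
        scores = [
            pca.transform(self._block_matrix(scans, t)) for t, pca in enumerate(self.pcas_)
        ]
        return np.hstack(scores)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
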