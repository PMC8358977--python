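"""Classical decoding path: band-power features -> PCA -> linear SVM.

Per epoch and channel, power is extracted in the delta (1-4 Hz), theta
(4-8 Hz) and alpha (8-12 Hz) bands from a Hann-windowed periodogram
(0.5 Hz resolution for 2-s epochs at 100 Hz), yielding 3 x n_channels
features (180 for 60 channels). Features are log-transformed and
standardised on training statistics, reduced to 30 principal components
fit on the training fold only, and classified with a linear-kernel
maximum-margin SVM whose signed decision values feed the ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .containers import EpochSet, labels_to_int

#: Canonical frequency bands, half-open [low, high) Hz.
DEFAULT_BANDS = (("delta", 1.0, 4.0), ("theta", 4.0, 8.0), ("alpha", 8.0, 12.0))


@dataclass
class FeatureMatrix:
    """Per-epoch band-power features (microvolts squared)."""

    values: np.ndarray  # (n_epochs, n_features)
    feature_names: list

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def bandpower_features(
    epochs: EpochSet | np.ndarray,
    bands=DEFAULT_BANDS,
    rate: float | None = None,
    channel_labels: list | None = None,
) -> FeatureMatrix:
    """Band power per epoch and channel; features ordered channel-major."""
    if isinstance(epochs, EpochSet):
        data, fs = epochs.data, epochs.rate
    else:
        data = np.asarray(epochs)
        if rate is None:
            raise ValueError("rate required when passing a raw array")
        fs = rate
    if data.ndim != 3:
        raise ValueError("expected (epochs, channels, samples)")
    nyq = fs / 2.0
    for name, lo, hi in bands:
        if hi > nyq:
            raise ValueError(f"band {name} [{lo}, {hi}) exceeds Nyquist {nyq}")
    freqs, psd = periodogram(data, fs=fs, window="hann", axis=-1, scaling="density")
    n_e, n_c = data.shape[:2]
    feats = np.empty((n_e, n_c, len(bands)))
    for b, (_, lo, hi) in enumerate(bands):
        mask = (freqs >= lo) & (freqs < hi)
        feats[:, :, b] = psd[:, :, mask].sum(axis=-1)
    labels = channel_labels or (
        epochs.__dict__.get("channel_labels") if isinstance(epochs, EpochSet) else None
    )
    if labels is None:
        labels = [f"ch{c}" for c in range(n_c)]
    names = [f"{labels[c]}_{bands[b][0]}" for c in range(n_c) for b in range(len(bands))]
    return FeatureMatrix(feats.reshape(n_e, n_c * len(bands)), names)


def pca_reduce(
    train_features: np.ndarray, test_features: np.ndarray, k: int = 30
) -> tuple[np.ndarray, np.ndarray, PCA]:
    """Rank-k PCA fit on the training features only, applied to both sets."""
    train = np.asarray(train_features)
    test = np.asarray(test_features)
    if k > min(train.shape):
        raise ValueError(f"k={k} exceeds min(n_train, n_features)={min(train.shape)}")
    pca = PCA(n_components=k, svd_solver="full")
    return pca.fit_transform(train), pca.transform(test), pca


@dataclass
class SVMConfig:
    C: float = 1.0
    n_components: int = 30
    log_transform: bool = True
    standardize: bool = True
    bands: tuple = DEFAULT_BANDS


class SVMPipeline:
    """Frozen-on-train pipeline: log -> z-score -> PCA -> linear SVM.

    Operates on band-power feature matrices; every statistic (log offsets,
    means, SDs, principal axes, support vectors) is fit on the training
    fold only.
    """

    def __init__(self, config: SVMConfig | None = None):
        self.cfg = config or SVMConfig()
        self._mu = None
        self._sd = None
        self._pca = None
        self._svc = None

    def _pretransform(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=np.float64)
        if self.cfg.log_transform:
            F = np.log10(F + 1e-12)
        return F

    def fit(self, features: np.ndarray, labels) -> "SVMPipeline":
        y = labels_to_int(np.asarray(labels))
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        F = self._pretransform(features)
        if self.cfg.standardize:
            self._mu = F.mean(axis=0)
            sd = F.std(axis=0)
            self._sd = np.where(sd == 0, 1.0, sd)
            F = (F - self._mu) / self._sd
        k = min(self.cfg.n_components, min(F.shape))
        self._pca = PCA(n_components=k, svd_solver="full")
        Z = self._pca.fit_transform(F)
        self._svc = SVC(kernel="linear", C=self.cfg.C)
        self._svc.fit(Z, y)
        return self

    def _reduce(self, features: np.ndarray) -> np.ndarray:
        F = self._pretransform(features)
        if self.cfg.standardize:
            F = (F - self._mu) / self._sd
        return self._pca.transform(F)

    def predict_score(self, features: np.ndarray) -> np.ndarray:
        """Signed distances to the separating hyperplane."""
        if self._svc is None:
            raise ValueError("pipeline not fitted")
        return self._svc.decision_function(self._reduce(features))

    def predict(self, features: np.ndarray) -> np.ndarray:
        return (self.predict_score(features) > 0).astype(int)


def train_svm(train_reduced: np.ndarray, labels, C: float = 1.0) -> SVC:
    """Linear-kernel maximum-margin classifier on already-reduced features."""
    y = labels_to_int(np.asarray(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    svc = SVC(kernel="linear", C=C)
    svc.fit(np.asarray(train_reduced), y)
    return svc


def predict_score(classifier: SVC, test_reduced: np.ndarray) -> np.ndarray:
    """Signed decision values (distances to the hyperplane) per epoch."""
    return classifier.decision_function(np.asarray(test_reduced))
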