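"""Linear spectrogram decoding under non-shuffled 10-fold cross-validation.

The decoding model per fold: z-score the stacked high-gamma features with
training-fold statistics, compress to the first 50 principal components
(estimated on the training fold only), and map components to the 23
log-mel bands by ordinary least squares with intercept. Folds are
contiguous temporal blocks — no shuffling — so temporal autocorrelation
cannot leak between train and test. The decode path contains no
randomness: identical inputs give identical results.

``SpectrogramDecoder`` is the model object (built from arrays or straight
from a :class:`~neurovoc.session.RecordingSession`); ``fit()`` returns a
:class:`DecodingResults` carrying per-fold/per-bin correlations, the
assembled predicted spectrogram, per-fold explained variance, fitted fold
parameters, a ``summary()`` table and plotting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .audio_features import LogMelSpectrogram, compute_log_mel
from .errors import DimensionError
from .evaluation import BaselineDistribution, compare_to_baseline, pearson_per_bin
from .neural_features import NeuralFeatureMatrix, Normalizer, extract_features

__all__ = [
    "FoldSpec",
    "PCAModel",
    "LinearDecoder",
    "FoldFit",
    "DecodingResults",
    "SpectrogramDecoder",
    "make_folds",
    "fit_pca",
    "apply_pca",
    "fit_linear",
    "predict",
    "run_cv",
]

logger = logging.getLogger(__name__)

N_COMPONENTS = 50
N_FOLDS = 10


@dataclass(frozen=True)
class FoldSpec:
    """One contiguous evaluation block of the temporal k-fold split."""

    fold_id: int
    train_rows: np.ndarray
    test_rows: np.ndarray


def make_folds(n_rows: int, k: int = N_FOLDS) -> list[FoldSpec]:
    """k contiguous blocks; block b covers rows [floor(b*n/k), floor((b+1)*n/k))."""
    if n_rows < k:
        raise ValueError(f"cannot split {n_rows} rows into {k} folds")
    bounds = [(b * n_rows) // k for b in range(k + 1)]
    all_rows = np.arange(n_rows)
    folds = []
    for b in range(k):
        test = all_rows[bounds[b] : bounds[b + 1]]
        train = np.concatenate([all_rows[: bounds[b]], all_rows[bounds[b + 1] :]])
        folds.append(FoldSpec(fold_id=b + 1, train_rows=train, test_rows=test))
    return folds


@dataclass
class PCAModel:
    """Principal-component compression fitted on one training fold."""

    components: np.ndarray  # (n_features, n_kept)
    mean: np.ndarray
    explained_variance_ratio: np.ndarray
    n_requested: int

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def fit_pca(train: np.ndarray, n_components: int = N_COMPONENTS) -> PCAModel:
    """PCA by full SVD of the centered training matrix (deterministic).

    The retained count is capped at min(n_components, n_features,
    n_rows - 1); a cap is logged, not an error.
    """
    train = np.asarray(train, dtype=float)
    n_rows, n_features = train.shape
    n_keep = min(n_components, n_features, n_rows - 1)
    if n_keep < n_components:
        logger.warning(
            "PCA capped at %d components (requested %d) for a %dx%d matrix",
            n_keep, n_components, n_rows, n_features,
        )
    p = PCA(n_components=n_keep, svd_solver="full")
    p.fit(train)
    return PCAModel(
        components=p.components_.T.copy(),
        mean=p.mean_.copy(),
        explained_variance_ratio=p.explained_variance_ratio_.copy(),
        n_requested=n_components,
    )


def apply_pca(model: PCAModel, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.shape[1] != model.mean.shape[0]:
        raise DimensionError(
            f"data has {data.shape[1]} features, PCA fitted on {model.mean.shape[0]}"
        )
    return (data - model.mean) @ model.components


@dataclass
class LinearDecoder:
    """OLS weights (n_components + 1, n_bins); first row is the intercept."""

    weights: np.ndarray

    @property
    def n_inputs(self) -> int:
        return self.weights.shape[0] - 1


def fit_linear(trainX: np.ndarray, trainY: np.ndarray) -> LinearDecoder:
    """Least-squares fit with intercept; min-norm solution if rank-deficient."""
    trainX = np.asarray(trainX, dtype=float)
    trainY = np.asarray(trainY, dtype=float)
    if trainX.shape[0] != trainY.shape[0]:
        raise DimensionError("X and Y row counts differ")
    X1 = np.column_stack([np.ones(trainX.shape[0]), trainX])
    W, _, rank, _ = np.linalg.lstsq(X1, trainY, rcond=None)
    if rank < X1.shape[1]:
        logger.warning("rank-deficient design (rank %d of %d): minimum-norm solution",
                       rank, X1.shape[1])
    return LinearDecoder(weights=W)


def predict(dec: LinearDecoder, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != dec.n_inputs:
        raise DimensionError(f"X has {X.shape[1]} columns, decoder expects {dec.n_inputs}")
    return np.column_stack([np.ones(X.shape[0]), X]) @ dec.weights


@dataclass
class FoldFit:
    """Everything fitted on one training fold (for leakage audits)."""

    spec: FoldSpec
    normalizer: Normalizer
    pca: PCAModel
    regression: LinearDecoder
    correlations: np.ndarray  # (n_bins,) held-out per-bin r
    cumulative_explained_variance: float


@dataclass
class DecodingResults:
    """Cross-validated reconstruction of the log-mel spectrogram."""

    fold_fits: list[FoldFit]
    predicted: np.ndarray  # (n_rows, n_bins), each row predicted exactly once
    fold_correlations: np.ndarray  # (k, n_bins)
    n_components: int
    n_folds: int

    @property
    def per_bin_mean_r(self) -> np.ndarray:
        return self.fold_correlations.mean(axis=0)

    @property
    def mean_correlation(self) -> float:
        """Mean r across all bins and folds — the headline score."""
        return float(self.fold_correlations.mean())

    @property
    def std_correlation(self) -> float:
        return float(self.fold_correlations.mean(axis=1).std())

    @property
    def explained_variance(self) -> np.ndarray:
        """Cumulative explained variance of the retained PCs, per fold."""
        return np.array([f.cumulative_explained_variance for f in self.fold_fits])

    def compare_to_baseline(self, base: BaselineDistribution) -> tuple[int, bool]:
        return compare_to_baseline(self.mean_correlation, base)

    def summary(self) -> str:
        lines = [
            "Linear spectrogram decoding - cross-validation summary",
            "=" * 56,
            f"folds: {self.n_folds} (contiguous, non-shuffled)   "
            f"components: {self.n_components}",
            f"mean r (bins x folds): {self.mean_correlation:.4f}   "
            f"sd over folds: {self.std_correlation:.4f}",
            f"PC cumulative explained variance: "
            f"{self.explained_variance.mean():.1%} "
            f"(range {self.explained_variance.min():.1%}-{self.explained_variance.max():.1%})",
            "-" * 56,
            " fold   mean r    min bin r   max bin r",
        ]
        for f in self.fold_fits:
            r = f.correlations
            lines.append(
                f"  {f.spec.fold_id:3d}   {r.mean():7.4f}    {r.min():7.4f}     {r.max():7.4f}"
            )
        return "\n".join(lines)

    def plot_correlations(self, ax=None, baseline: BaselineDistribution | None = None):
        """Per-bin mean r with per-fold spread (and baseline max, if given)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        bins = np.arange(self.fold_correlations.shape[1])
        mean = self.per_bin_mean_r
        sem = self.fold_correlations.std(axis=0) / np.sqrt(self.n_folds)
        ax.fill_between(bins, mean - sem, mean + sem, alpha=0.3)
        ax.plot(bins, mean, label="decoded")
        if baseline is not None:
            ax.plot(bins, baseline.draws_per_bin.max(axis=0), "--",
                    label="baseline max")
        ax.set_xlabel("mel bin")
        ax.set_ylabel("Pearson r")
        ax.legend()
        return ax


def run_cv(
    features: NeuralFeatureMatrix | np.ndarray,
    mel: LogMelSpectrogram | np.ndarray,
    k: int = N_FOLDS,
    n_components: int = N_COMPONENTS,
) -> DecodingResults:
    """Non-shuffled k-fold CV of normalize -> PCA -> OLS, per fold.

    All three stages are fitted on training rows only; test rows are only
    ever transformed and predicted. The assembled spectrogram has every
    row predicted exactly once.
    """
    X = np.asarray(getattr(features, "values", features), dtype=float)
    Y = np.asarray(getattr(mel, "values", mel), dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise DimensionError(
            f"features have {X.shape[0]} rows, target has {Y.shape[0]}: "
            "align the mel rows to the stacked feature rows first"
        )
    folds = make_folds(X.shape[0], k)
    predicted = np.empty_like(Y)
    fold_fits: list[FoldFit] = []
    for fs in folds:
        norm = Normalizer().fit(X[fs.train_rows], fold=f"fold-{fs.fold_id}")
        Xtr = norm.transform(X[fs.train_rows])
        pca = fit_pca(Xtr, n_components)
        reg = fit_linear(apply_pca(pca, Xtr), Y[fs.train_rows])
        Yhat = predict(reg, apply_pca(pca, norm.transform(X[fs.test_rows])))
        predicted[fs.test_rows] = Yhat
        r = pearson_per_bin(Y[fs.test_rows], Yhat)
        fold_fits.append(
            FoldFit(
                spec=fs,
                normalizer=norm,
                pca=pca,
                regression=reg,
                correlations=r,
                cumulative_explained_variance=float(pca.explained_variance_ratio.sum()),
            )
        )
    return DecodingResults(
        fold_fits=fold_fits,
        predicted=predicted,
        fold_correlations=np.vstack([f.correlations for f in fold_fits]),
        n_components=n_components,
        n_folds=k,
    )


class SpectrogramDecoder:
    """Model object: stacked high-gamma features -> log-mel spectrogram.

    Parameters
    ----------
    features, targets
        Aligned feature matrix and log-mel target (equal row counts).
    n_components, n_folds
        PCA size and CV fold count; defaults 50 and 10.
    """

    def __init__(self, features, targets, n_components: int = N_COMPONENTS,
                 n_folds: int = N_FOLDS):
        self.features = features
        self.targets = targets
        self.n_components = n_components
        self.n_folds = n_folds

    @classmethod
    def from_session(cls, session, n_components: int = N_COMPONENTS,
                     n_folds: int = N_FOLDS) -> "SpectrogramDecoder":
        """Extract both feature streams from a session and align them.

        The context stacking drops 20 frames at each end of the neural
        stream; the same rows are dropped from the mel target.
        """
        feats = extract_features(session.neural, session.neural_rate,
                                 channel_names=list(session.channel_names))
        mel = compute_log_mel(session.audio, session.audio_rate)
        lo = feats.first_valid_frame
        hi = lo + feats.n_frames
        if mel.n_frames < hi:
            raise DimensionError(
                f"mel target has {mel.n_frames} frames, need {hi}: "
                "audio and neural durations disagree"
            )
        target = mel.values[lo:hi]
        return cls(feats, target, n_components=n_components, n_folds=n_folds)

    def fit(self) -> DecodingResults:
        return run_cv(self.features, self.targets, k=self.n_folds,
                      n_components=self.n_components)
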