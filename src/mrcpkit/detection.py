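"""Single-trial MRCP-vs-idle detection (offline BCI performance estimate).

Pre-processing: 0.1-30 Hz order-4 zero-phase Butterworth on all channels,
then a large Laplacian spatial filter centered on Cz producing a single
surrogate channel:

    surrogate = Cz - (F3 + Fz + F4 + C3 + C4 + P3 + Pz + P4) / 8

Two-second epochs (-2 s to the movement onset) are cut from the surrogate,
idle epochs are drawn at random from the preprocessed idle recording (same
count as MRCP epochs), and 29 features are extracted per epoch:

* 5 temporal: the four 0.5-s window means and the first-half minus
  second-half mean difference,
* 23 spectral: Welch PSD (1-s Hamming segments, 0.5-s overlap) in 1-Hz
  bins from 8 to 30 Hz,
* 1 template: zero-lag normalized cross-correlation with the average of
  the MRCP-class training epochs.

Classification is leave-one-out: for every held-out epoch the template,
the feature standardization (LDA/kNN), and the classifier are recomputed
from the remaining epochs only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

from .data import ContinuousRecording, EventSeries, EpochSet
from .filters import bandpass_recording
from .morphology import extract_epochs, reject_artifacts, ARTIFACT_LIMIT

log = logging.getLogger(__name__)

DETECTION_BAND = (0.1, 30.0)
DETECTION_WINDOW = (-2.0, 0.0)
SURROGATE_CENTER = "Cz"
SURROGATE_NEIGHBORS = ("F3", "Fz", "F4", "C3", "C4", "P3", "Pz", "P4")
SPECTRAL_BINS = np.arange(8, 31)  # Hz, 23 one-Hz bins

TEMPORAL_NAMES = ["mean_m2_m15", "mean_m15_m1", "mean_m1_m05", "mean_m05_0", "half_diff"]
FEATURE_NAMES = TEMPORAL_NAMES + [f"psd_{f}Hz" for f in SPECTRAL_BINS] + ["template_xcorr"]


def surrogate_channel(eeg: ContinuousRecording) -> np.ndarray:
    """Large Laplacian surrogate channel (Cz minus the mean of 8 neighbors).

    FP1 and FCz do not enter the computation.
    """
    cz = eeg.channel(SURROGATE_CENTER)
    return cz - np.mean([eeg.channel(c) for c in SURROGATE_NEIGHBORS], axis=0)


def preprocess_detection(eeg: ContinuousRecording) -> ContinuousRecording:
    """0.1-30 Hz zero-phase bandpass on all channels, then the Laplacian."""
    filt = bandpass_recording(eeg, *DETECTION_BAND, order=4)
    return ContinuousRecording(
        surrogate_channel(filt)[None, :], eeg.fs, ("surrogate",), eeg.start_offset
    )


def extract_detection_epochs(
    surrogate: ContinuousRecording, onsets: EventSeries
) -> EpochSet:
    """Two-second MRCP epochs on the surrogate channel, artifact-rejected."""
    epochs = extract_epochs(surrogate, onsets, window=DETECTION_WINDOW, label="mrcp")
    return reject_artifacts(epochs, ARTIFACT_LIMIT)


def sample_idle_epochs(
    idle_surrogate: ContinuousRecording, n: int, seed: int,
    limit: float = ARTIFACT_LIMIT, max_tries: int = 50,
) -> EpochSet:
    """`n` random clean 2-s epochs from the idle surrogate channel.

    Start times are uniform over the recording; epochs exceeding ±limit µV
    are redrawn, up to `max_tries * n` draws.  Deterministic under `seed`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    fs = idle_surrogate.fs
    x = idle_surrogate.data[0]
    m = int(round(-DETECTION_WINDOW[0] * fs))  # 2 s
    if len(x) < m:
        raise ValueError("idle recording shorter than one 2-s epoch")
    rng = np.random.default_rng(seed)
    out, tries = [], 0
    while len(out) < n and tries < max_tries * n:
        start = rng.integers(0, len(x) - m + 1)
        seg = x[start : start + m]
        tries += 1
        if np.max(np.abs(seg)) <= limit:
            out.append(seg)
    if len(out) < n:
        raise ValueError(
            f"could only draw {len(out)} of {n} clean idle epochs "
            f"within the retry cap"
        )
    t = np.arange(-m, 0) / fs
    return EpochSet(
        np.asarray(out)[:, None, :], t, fs, ("surrogate",),
        labels=np.array(["idle"] * n),
    )


def temporal_features(epoch: np.ndarray, fs: float) -> np.ndarray:
    """Five window-mean features of a 2-s pre-movement epoch.

    f1..f4 are the means over [-2,-1.5), [-1.5,-1), [-1,-0.5), [-0.5,0) s;
    f5 is mean[-2,-1) minus mean[-1,0).
    """
    n = len(epoch)
    if n != int(round(2 * fs)):
        raise ValueError(f"expected a 2-s epoch ({int(2*fs)} samples), got {n}")
    q = n // 4
    quarters = [epoch[i * q : (i + 1) * q].mean() for i in range(4)]
    half_diff = epoch[: n // 2].mean() - epoch[n // 2 :].mean()
    return np.array(quarters + [half_diff])


def spectral_features(epoch: np.ndarray, fs: float) -> np.ndarray:
    """Welch PSD at the 23 integer frequencies 8..30 Hz.

    1-s Hamming segments with 0.5-s overlap give exact 1-Hz bins; the
    sampling rate must therefore be an integer number of Hz.
    """
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"1-Hz PSD bins require an integer sampling rate, got {fs}")
    nper = int(round(fs))
    f, p = welch(epoch, fs=fs, window="hamming", nperseg=nper, noverlap=nper // 2)
    # f is exactly 0,1,2,... Hz here
    return p[SPECTRAL_BINS]


def build_template(epochs: np.ndarray) -> np.ndarray:
    """Pointwise mean of the MRCP-class training epochs (the held-out epoch
    must not be among them — enforced by the caller)."""
    epochs = np.atleast_2d(epochs)
    if epochs.shape[0] == 0:
        raise ValueError("cannot build a template from zero training epochs")
    return epochs.mean(axis=0)


def template_feature(epoch: np.ndarray, template: np.ndarray,
                     normalize: bool = True) -> float:
    """Zero-lag cross-correlation between an epoch and the template.

    Normalized by default (value in [-1, 1], scale-invariant); set
    ``normalize=False`` for the plain inner product.
    """
    if len(epoch) != len(template):
        raise ValueError("epoch and template lengths differ")
    num = float(np.dot(epoch, template))
    if not normalize:
        return num
    denom = np.sqrt(np.dot(epoch, epoch) * np.dot(template, template))
    if denom == 0:
        raise ValueError("zero-energy epoch or template")
    return num / denom


@dataclass
class FeatureMatrix:
    """Per-epoch features with labels; carries the raw epochs so the
    template feature can be recomputed per cross-validation fold."""

    static: np.ndarray          # (n, 28): temporal + spectral
    epochs: np.ndarray          # (n, n_samples) surrogate epochs
    labels: np.ndarray          # "mrcp" | "idle"
    fs: float
    session: str = ""
    normalize_template: bool = True

    @classmethod
    def from_epochs(cls, mrcp: EpochSet, idle: EpochSet, session: str = "",
                    normalize_template: bool = True) -> "FeatureMatrix":
        a, b = mrcp.kept(), idle.kept()
        if a.n_epochs != b.n_epochs:
            raise ValueError(
                f"class imbalance: {a.n_epochs} MRCP vs {b.n_epochs} idle epochs"
            )
        ep = np.vstack([a.epochs[:, 0, :], b.epochs[:, 0, :]])
        labels = np.concatenate([a.labels, b.labels])
        fs = mrcp.fs
        static = np.array([
            np.concatenate([temporal_features(e, fs), spectral_features(e, fs)])
            for e in ep
        ])
        return cls(static, ep, labels, fs, session, normalize_template)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def with_template(self, template: np.ndarray) -> np.ndarray:
        """Full 29-column matrix for a given template (column order fixed
        as FEATURE_NAMES)."""
        tf = np.array([
            template_feature(e, template, self.normalize_template) for e in self.epochs
        ])
        return np.column_stack([self.static, tf])


@dataclass
class ClassifierSpec:
    """Fixed-hyperparameter classifier choice: random forest (512 trees),
    LDA, or k-nearest neighbors (k=5)."""

    kind: str = "random_forest"   # random_forest | lda | knn
    trees: int = 512
    k: int = 5
    seed: int = 0
    standardize: bool | None = None  # default: True for lda/knn, False for RF

    def make(self):
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=self.trees, random_state=self.seed, n_jobs=1
            )
        if self.kind == "lda":
            return LinearDiscriminantAnalysis()
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.k)
        raise ValueError(f"unknown classifier kind {self.kind!r}")

    @property
    def wants_standardization(self) -> bool:
        if self.standardize is not None:
            return self.standardize
        return self.kind in ("lda", "knn")


@dataclass
class DetectionResult:
    """LOOCV outcome for one session and classifier."""

    accuracy: float             # percent correct over all folds
    predictions: np.ndarray
    labels: np.ndarray
    n_folds: int
    classifier: str = ""
    session: str = ""


def fold_template(features: FeatureMatrix, held_out: int) -> np.ndarray:
    """Template for one LOOCV fold: mean of the MRCP-class epochs with the
    held-out epoch excluded, whatever its class."""
    train = np.ones(features.n_epochs, dtype=bool)
    train[held_out] = False
    return build_template(features.epochs[train & (features.labels == "mrcp")])


def loocv_classify(features: FeatureMatrix, spec: ClassifierSpec) -> DetectionResult:
    """Leave-one-out cross-validation with per-fold template recomputation.

    For every fold the MRCP-class template, the z-scoring (when used), and
    the classifier are fit on the remaining epochs only; the held-out epoch
    never influences its own fold's model.
    """
    n = features.n_epochs
    labels = features.labels
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"two-class problem expected, got classes {classes}")
    n_a, n_b = (labels == classes[0]).sum(), (labels == classes[1]).sum()
    if n_a != n_b:
        raise ValueError(f"balanced classes required ({n_a} vs {n_b})")
    if min(n_a, n_b) < 2:
        raise ValueError("need at least 2 epochs per class")

    preds = np.empty(n, dtype=labels.dtype)
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        template = fold_template(features, i)
        X = features.with_template(template)
        Xtr, ytr, Xte = X[train], labels[train], X[~train]
        if spec.wants_standardization:
            mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
            keep = sd > 0
            if not keep.all():
                log.info("fold %d: dropping %d zero-variance feature(s)",
                         i, int((~keep).sum()))
            Xtr = (Xtr[:, keep] - mu[keep]) / sd[keep]
            Xte = (Xte[:, keep] - mu[keep]) / sd[keep]
        clf = spec.make()
        clf.fit(Xtr, ytr)
        preds[i] = clf.predict(Xte)[0]

    acc = 100.0 * np.mean(preds == labels)
    return DetectionResult(
        accuracy=float(acc), predictions=preds, labels=labels.copy(),
        n_folds=n, classifier=spec.kind, session=features.session,
    )


def session_detection(
    eeg: ContinuousRecording,
    idle: ContinuousRecording,
    onsets: EventSeries,
    specs,
    idle_seed: int = 0,
    session: str = "",
) -> list:
    """Full detection stage for one session: preprocess, epoch, balance,
    and run LOOCV for each classifier spec."""
    sur = preprocess_detection(eeg)
    sur_idle = preprocess_detection(idle)
    mrcp_epochs = extract_detection_epochs(sur, onsets)
    n = int(mrcp_epochs.kept_mask.sum())
    idle_epochs = sample_idle_epochs(sur_idle, n, seed=idle_seed)
    fm = FeatureMatrix.from_epochs(mrcp_epochs, idle_epochs, session=session)
    return [loocv_classify(fm, spec) for spec in specs]
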