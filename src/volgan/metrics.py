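"""Generative-model validation: Frechet distance, precision/recall manifolds,
per-sample realism, and visual-grading-based dataset filtering.

The Frechet distance between the Gaussian summaries of two feature sets is

    FID = ||mu_A - mu_B||^2 + tr(Sigma_A + Sigma_B - 2 (Sigma_A Sigma_B)^(1/2))

computed with a principal matrix square root; tiny negative eigenvalues from
near-singular covariances are clamped.  Zero means the two feature
distributions agree.

Feature extraction is a pluggable contract so the same metric code serves a
2D-slice route (the classic Inception-style protocol: two random axial slices
per volume), a direct volumetric route, and features from a visual-grading
classifier trained on graded volumes.  No pre-trained third-party weights are
shipped; the provided extractors are synthetic stand-ins (random-weight or
phantom-trained) that exercise the identical contracts.

Precision is the fraction of generated features inside the union of k-NN
balls around the real features; recall is the symmetric quantity.  The
realism score of a generated feature is ``max_r radius_k(r) / dist(g, r)``
over real features ``r`` — large when the sample sits deep inside the real
manifold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.spatial.distance import cdist
from skimage.transform import resize

from . import autodiff as ad
from .autodiff import Tensor
from .nn import Adam, Conv3, Dense, Module
from .phantoms import GradedVolume

__all__ = [
    "FeatureSet", "GaussianSummary", "MetricsReport",
    "gaussian_summary", "fid", "fid_from_summaries",
    "precision_recall", "realism_scores",
    "RandomProjectionSliceExtractor", "RandomConvVolumeExtractor",
    "VGSClassifier", "train_vgs_classifier", "filter_vgs",
    "extract_slice_features", "extract_volume_features", "evaluate",
]

REALISM_CAP = 1e6


@dataclass
class FeatureSet:
    features: np.ndarray          # (n, d)
    extractor_id: str = "unknown"
    source: str = "real"

    def __post_init__(self):
        self.features = np.atleast_2d(np.asarray(self.features, dtype=np.float64))

    def __len__(self):
        return self.features.shape[0]


@dataclass
class GaussianSummary:
    mean: np.ndarray
    cov: np.ndarray


@dataclass
class MetricsReport:
    fid: float
    precision: float
    recall: float
    realism: np.ndarray
    n_real: int
    n_gen: int
    extractor_id: str


def gaussian_summary(fs: FeatureSet) -> GaussianSummary:
    x = fs.features
    if x.shape[0] < 2:
        raise ValueError("need at least 2 feature vectors for a covariance")
    return GaussianSummary(mean=x.mean(axis=0), cov=np.cov(x, rowvar=False))


def fid_from_summaries(a: GaussianSummary, b: GaussianSummary,
                       eps: float = 1e-10) -> float:
    """Frechet distance between two Gaussian summaries.

    The trace term uses ``sqrt(Sigma_A) Sigma_B sqrt(Sigma_A)`` — similar to
    ``Sigma_A Sigma_B`` but symmetric, so an eigendecomposition with
    negative-eigenvalue clamping is enough.
    """
    mu_d = a.mean - b.mean
    ca = np.atleast_2d(a.cov)
    cb = np.atleast_2d(b.cov)
    wa, va = scipy.linalg.eigh(ca)
    sa = (va * np.sqrt(np.clip(wa, 0.0, None))) @ va.T
    m = sa @ cb @ sa
    wm = scipy.linalg.eigvalsh((m + m.T) / 2.0)
    wm = np.clip(wm, 0.0, None)
    tr_term = float(np.trace(ca) + np.trace(cb) - 2.0 * np.sqrt(wm + eps**2).sum())
    return float(mu_d @ mu_d) + tr_term


def fid(a: FeatureSet, b: FeatureSet) -> float:
    if len(a) == 0 or len(b) == 0:
        raise ValueError("feature sets must be nonempty")
    if a.features.shape[1] != b.features.shape[1]:
        raise ValueError("feature lengths differ")
    return fid_from_summaries(gaussian_summary(a), gaussian_summary(b))


def _knn_radii(x: np.ndarray, k: int) -> np.ndarray:
    """Distance of each point to its k-th nearest neighbour among ``x``
    (self excluded)."""
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    return np.sort(d, axis=1)[:, k - 1]


def precision_recall(real: FeatureSet, gen: FeatureSet, k: int = 3) -> tuple:
    """k-NN manifold precision and recall between feature sets."""
    if k >= len(real) or k >= len(gen):
        raise ValueError("k must be smaller than both set sizes")
    xr, xg = real.features, gen.features
    rr = _knn_radii(xr, k)
    rg = _knn_radii(xg, k)
    d_gr = cdist(xg, xr)
    precision = float((d_gr <= rr[None, :]).any(axis=1).mean())
    recall = float((d_gr.T <= rg[None, :]).any(axis=1).mean())
    return precision, recall


def realism_scores(real: FeatureSet, gen: FeatureSet, k: int = 3) -> np.ndarray:
    """Per-generated-sample realism ``max_r radius_k(r) / ||g - r||``, capped
    at ``1e6`` for coincident points."""
    if k >= len(real):
        raise ValueError("k must be smaller than the real set size")
    rr = _knn_radii(real.features, k)
    d = cdist(gen.features, real.features)
    with np.errstate(divide="ignore"):
        ratios = rr[None, :] / d
    ratios[~np.isfinite(ratios)] = REALISM_CAP
    return np.minimum(ratios.max(axis=1), REALISM_CAP)


# ---------------------------------------------------------------------------
# feature extractors
# ---------------------------------------------------------------------------

class RandomProjectionSliceExtractor:
    """2D slice features: resize to a fixed frame, then a fixed random
    two-layer projection.  A synthetic stand-in for an ImageNet classifier
    backbone; deterministic given its seed."""

    mode = "slice2d"

    def __init__(self, feature_dim: int = 64, frame: tuple = (64, 64), seed: int = 0):
        self.feature_dim = feature_dim
        self.frame = frame
        rng = np.random.default_rng(seed)
        n_in = int(np.prod(frame))
        self.w1 = rng.standard_normal((n_in, 256)) / np.sqrt(n_in)
        self.w2 = rng.standard_normal((256, feature_dim)) / np.sqrt(256)
        self.extractor_id = f"slice2d-rp{feature_dim}-s{seed}"

    def apply_slices(self, slices: np.ndarray) -> np.ndarray:
        out = np.empty((len(slices), self.feature_dim))
        for i, sl in enumerate(slices):
            fr = resize(sl.astype(np.float64), self.frame, order=1,
                        anti_aliasing=True)
            h = np.maximum(fr.ravel() @ self.w1, 0.0)
            out[i] = h @ self.w2
        return out


class RandomConvVolumeExtractor:
    """Volumetric features from a random-weight 3D CNN (three strided
    convolutions, global average pooling).  Stand-in for a medical-image
    ResNet backbone."""

    mode = "volume3d"

    def __init__(self, feature_dim: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.feature_dim = feature_dim
        widths = (1, 8, 16, feature_dim)
        self.convs = [Conv3(widths[i], widths[i + 1], rng, stride=2)
                      for i in range(3)]
        self.extractor_id = f"volume3d-randcnn{feature_dim}-s{seed}"

    def apply_volumes(self, volumes: np.ndarray) -> np.ndarray:
        out = []
        with ad.no_grad():
            for vol in volumes:
                x = Tensor(np.asarray(vol, dtype=np.float32)[None, None])
                for c in self.convs:
                    x = ad.leaky_relu(c(x))
                out.append(x.data.mean(axis=(2, 3, 4))[0])
        return np.asarray(out, dtype=np.float64)


class VGSClassifier(Module):
    """Small volumetric CNN predicting the 1-5 visual grading score.

    The penultimate dense activations double as the grading-aware feature
    route for FID.
    """

    mode = "volume3d"

    def __init__(self, input_shape: tuple, rng: np.random.Generator,
                 width: int = 8, feature_dim: int = 32):
        self.input_shape = tuple(input_shape)
        self.feature_dim = feature_dim
        self.conv1 = Conv3(1, width, rng, stride=2)
        self.conv2 = Conv3(width, 2 * width, rng, stride=2)
        self.conv3 = Conv3(2 * width, 4 * width, rng, stride=2)
        flat = 4 * width
        self.fc_feat = Dense(flat, feature_dim, rng)
        self.fc_out = Dense(feature_dim, 5, rng, gain=1.0)
        self.extractor_id = f"vgs-cnn{feature_dim}"

    def features_t(self, x: Tensor) -> Tensor:
        h = ad.leaky_relu(self.conv1(x))
        h = ad.leaky_relu(self.conv2(h))
        h = ad.leaky_relu(self.conv3(h))
        h = ad.tmean(h, axis=(2, 3, 4))
        return ad.leaky_relu(self.fc_feat(h))

    def logits(self, x: Tensor) -> Tensor:
        return self.fc_out(self.features_t(x))

    def predict(self, volumes: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            lg = self.logits(Tensor(np.asarray(volumes, dtype=np.float32)[:, None]))
        return lg.data.argmax(axis=1) + 1

    def apply_volumes(self, volumes: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            f = self.features_t(Tensor(np.asarray(volumes, dtype=np.float32)[:, None]))
        return f.data.astype(np.float64)


def _softmax_xent(logits: Tensor, labels: np.ndarray) -> Tensor:
    shift = Tensor(logits.data.max(axis=1, keepdims=True))
    z = logits - shift
    lse = ad.log(ad.tsum(ad.exp(z), axis=1))
    picked = ad.tsum(z * Tensor(np.eye(z.shape[1])[labels]), axis=1)
    return ad.tmean(lse - picked)


def train_vgs_classifier(graded: list, rng: np.random.Generator | None = None,
                         steps: int = 400, batch: int = 8, lr: float = 5e-3,
                         width: int = 8, feature_dim: int = 32) -> VGSClassifier:
    """Train the grading classifier on graded volumes (grades 1-5).

    Volumes must share one shape.  Raises on single-class data.
    """
    rng = rng or np.random.default_rng(0)
    vols = np.stack([g.volume.data for g in graded]).astype(np.float32)
    labels = np.array([g.vgs - 1 for g in graded])
    if np.unique(labels).size < 2:
        raise ValueError("need at least two distinct grades to train")
    clf = VGSClassifier(vols.shape[1:], rng, width=width, feature_dim=feature_dim)
    opt = Adam(clf.parameters(), lr=lr)
    params = clf.parameters()
    for _ in range(steps):
        idx = rng.integers(0, len(vols), size=batch)
        logits = clf.logits(Tensor(vols[idx][:, None]))
        loss = _softmax_xent(logits, labels[idx])
        opt.step(ad.grad(loss, params))
    return clf


def filter_vgs(graded: list) -> list:
    """Drop motion-degraded volumes: keep grades 1-3 only."""
    for g in graded:
        if g.vgs not in (1, 2, 3, 4, 5):
            raise ValueError(f"invalid grade {g.vgs}")
    return [g for g in graded if g.vgs <= 3]


# ---------------------------------------------------------------------------
# extraction drivers
# ---------------------------------------------------------------------------

def extract_slice_features(volumes, extractor, rng: np.random.Generator,
                           slices_per_volume: int = 2,
                           source: str = "real") -> FeatureSet:
    """Features from randomly positioned axial slices, two per volume by
    default (the slice-based FID protocol)."""
    if extractor.mode != "slice2d":
        raise ValueError("extractor must operate on 2D slices")
    slices = []
    for vol in volumes:
        data = vol.data if hasattr(vol, "data") else np.asarray(vol)
        if data.shape[0] < 1:
            raise ValueError("volume has no axial slices")
        picks = rng.integers(0, data.shape[0], size=slices_per_volume)
        slices.extend(data[p] for p in picks)
    feats = extractor.apply_slices(np.asarray(slices))
    return FeatureSet(feats, extractor.extractor_id, source)


def extract_volume_features(volumes, extractor, source: str = "real") -> FeatureSet:
    if extractor.mode != "volume3d":
        raise ValueError("extractor must operate on volumes")
    # volumes may have heterogeneous shapes; extractors see them one by one
    arrs = [v.data if hasattr(v, "data") else np.asarray(v) for v in volumes]
    return FeatureSet(extractor.apply_volumes(arrs), extractor.extractor_id, source)


def evaluate(real: FeatureSet, gen: FeatureSet, k: int = 3) -> MetricsReport:
    """One-stop report: FID, precision, recall and per-sample realism."""
    p, r = precision_recall(real, gen, k)
    return MetricsReport(fid=fid(real, gen), precision=p, recall=r,
                         realism=realism_scores(real, gen, k),
                         n_real=len(real), n_gen=len(gen),
                         extractor_id=real.extractor_id)
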