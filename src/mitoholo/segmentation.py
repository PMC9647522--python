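"""Pixel classification of RI frames into mitochondrion vs background.

Two routes produce per-frame binary maps:

* a supervised pixel classifier — a random forest over a fixed multiscale
  filter bank, trained from user scribbles, yielding a per-pixel
  mitochondrion probability that is then thresholded; and
* an unsupervised fallback (``threshold_segment``) — background
  subtraction, a robust global threshold (Otsu guarded by a noise floor)
  and a connected-component size filter.

Both end in the same binarization rule: keep pixels at or above threshold,
drop 8-connected components smaller than ``min_object_px``.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import remove_small_objects
from sklearn.ensemble import RandomForestClassifier

FILTER_KINDS = ("gaussian", "gradient_magnitude", "laplacian", "hessian_eigen", "dog")

#: default multiscale filter bank: (kind, scale in pixels)
DEFAULT_FEATURES: tuple[tuple[str, float], ...] = (
    ("gaussian", 1.0),
    ("gaussian", 2.0),
    ("gradient_magnitude", 1.5),
    ("laplacian", 1.5),
    ("hessian_eigen", 1.5),
    ("dog", 1.0),
)

DEFAULT_MIN_OBJECT_PX = 10

CLASSIFIER_FORMAT_VERSION = 1


def compute_features(frame: np.ndarray, feature_spec=DEFAULT_FEATURES) -> np.ndarray:
    """Multiscale filter responses: one (H, W) plane per (kind, scale).

    ``hessian_eigen`` emits the larger-magnitude Hessian eigenvalue;
    ``dog`` is a difference of Gaussians at scales (s, 1.6 s).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    planes = []
    for kind, scale in feature_spec:
        if scale <= 0:
            raise ValueError("feature scales must be > 0")
        if kind == "gaussian":
            planes.append(ndi.gaussian_filter(frame, scale))
        elif kind == "gradient_magnitude":
            planes.append(ndi.gaussian_gradient_magnitude(frame, scale))
        elif kind == "laplacian":
            planes.append(ndi.gaussian_laplace(frame, scale))
        elif kind == "hessian_eigen":
            H = hessian_matrix(frame, sigma=scale, order="rc", use_gaussian_derivatives=False)
            eig = hessian_matrix_eigvals(H)
            planes.append(np.where(np.abs(eig[0]) >= np.abs(eig[1]), eig[0], eig[1]))
        elif kind == "dog":
            planes.append(ndi.gaussian_filter(frame, scale) - ndi.gaussian_filter(frame, 1.6 * scale))
        else:
            raise ValueError(f"unknown filter kind {kind!r}; valid kinds: {FILTER_KINDS}")
    return np.stack(planes)


@dataclass
class PixelClassifier:
    feature_spec: tuple
    model: RandomForestClassifier
    train_summary: dict = field(default_factory=dict)


def train_pixel_classifier(
    frames,
    scribbles,
    feature_spec=DEFAULT_FEATURES,
    seed: int = 0,
    holdout_fraction: float = 0.2,
) -> PixelClassifier:
    """Train a random-forest pixel classifier from scribble labels.

    Parameters
    ----------
    frames : 2-D array or sequence of 2-D arrays
    scribbles : matching label image(s); 0 = unlabeled, 1 = mitochondrion,
        2 = background.
    seed : controls both the holdout split and the forest; training twice
        with the same seed gives identical predictions.

    A random 20% of the scribbled pixels is held out and its accuracy
    reported in ``train_summary``.
    """
    if isinstance(frames, np.ndarray) and frames.ndim == 2:
        frames = [frames]
        scribbles = [scribbles]
    X_parts, y_parts = [], []
    for frame, scrib in zip(frames, scribbles):
        scrib = np.asarray(scrib)
        feats = compute_features(frame, feature_spec)
        sel = scrib > 0
        X_parts.append(feats[:, sel].T)
        y_parts.append(scrib[sel])
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("scribbles must label at least one pixel in each class (1=mito, 2=background)")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_hold = max(1, int(round(holdout_fraction * len(y))))
    hold, train = order[:n_hold], order[n_hold:]
    if len(np.unique(y[train])) < 2:  # tiny scribble sets: train on everything
        train = order
    model = RandomForestClassifier(n_estimators=50, random_state=int(seed), n_jobs=1)
    model.fit(X[train], y[train])
    acc = float(np.mean(model.predict(X[hold]) == y[hold]))
    summary = dict(
        class_counts={int(c): int(n) for c, n in zip(classes, counts)},
        holdout_accuracy=acc,
        n_train=int(len(train)),
        n_holdout=int(len(hold)),
    )
    return PixelClassifier(feature_spec=tuple(feature_spec), model=model, train_summary=summary)


def predict_probability(classifier: PixelClassifier, frame: np.ndarray) -> np.ndarray:
    """Per-pixel probability of the mitochondrion class, in [0, 1]."""
    feats = compute_features(frame, classifier.feature_spec)
    if feats.shape[0] != classifier.model.n_features_in_:
        raise ValueError(
            f"feature_spec mismatch: classifier expects {classifier.model.n_features_in_} "
            f"features, got {feats.shape[0]}"
        )
    X = feats.reshape(feats.shape[0], -1).T
    proba = classifier.model.predict_proba(X)
    mito_col = list(classifier.model.classes_).index(1)
    return proba[:, mito_col].reshape(frame.shape)


def save_classifier(classifier: PixelClassifier, path) -> None:
    payload = dict(
        format_version=CLASSIFIER_FORMAT_VERSION,
        feature_spec=classifier.feature_spec,
        model=classifier.model,
        train_summary=classifier.train_summary,
    )
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_classifier(path) -> PixelClassifier:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != CLASSIFIER_FORMAT_VERSION:
        raise ValueError(f"unsupported classifier file version: {payload.get('format_version')}")
    return PixelClassifier(
        feature_spec=payload["feature_spec"],
        model=payload["model"],
        train_summary=payload["train_summary"],
    )


# ---------------------------------------------------------------------------
# binarization

def binarize(
    prob_map_or_frame: np.ndarray,
    threshold: float = 0.5,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    is_probability: bool = True,
) -> np.ndarray:
    """Threshold at ``value >= threshold`` and drop small 8-connected components."""
    img = np.asarray(prob_map_or_frame, dtype=float)
    if is_probability and not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1) for probability maps")
    mask = img >= threshold
    if min_object_px > 1:
        # keep components of at least min_object_px pixels
        mask = remove_small_objects(mask, connectivity=2, max_size=min_object_px - 1)
    return mask


def _robust_sd(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def threshold_segment(
    frame: np.ndarray,
    bg_sigma: float = 15.0,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    polarity: str = "bright",
    noise_floor_k: float = 3.0,
) -> np.ndarray:
    """Unsupervised segmentation of a single RI frame.

    Large-scale background is removed by Gaussian smoothing; the residual is
    thresholded with Otsu's between-class-variance criterion, guarded by a
    noise floor of ``noise_floor_k`` robust standard deviations so that a
    frame containing no organelles (the Otsu failure mode on a unimodal
    histogram) yields an empty mask rather than half the noise pixels.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    resid = frame - ndi.gaussian_filter(frame, bg_sigma)
    if polarity == "dark":
        resid = -resid
    if np.ptp(resid) == 0:
        warnings.warn("constant frame: returning empty mask", stacklevel=2)
        return np.zeros(frame.shape, dtype=bool)
    thr = threshold_otsu(resid)
    floor = noise_floor_k * _robust_sd(resid)
    return binarize(resid, max(thr, floor), min_object_px, is_probability=False)


@dataclass
class MitoMaskStack:
    """Per-frame binary mitochondrion maps for one movie."""

    masks: np.ndarray  # (T, H, W) bool
    min_object_px: int
    source: str  # {"classifier", "threshold"}

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]


def segment_stack(
    ri_stack,
    classifier: PixelClassifier | None = None,
    threshold: float = 0.5,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
    **threshold_kwargs,
) -> MitoMaskStack:
    """Segment every frame independently (no temporal smoothing).

    Uses the supervised classifier when one is provided, else the
    unsupervised threshold fallback.
    """
    frames = np.asarray(ri_stack.pixels, dtype=float)
    masks = np.empty(frames.shape, dtype=bool)
    if classifier is not None:
        for t in range(frames.shape[0]):
            prob = predict_probability(classifier, frames[t])
            masks[t] = binarize(prob, threshold, min_object_px)
        source = "classifier"
    else:
        for t in range(frames.shape[0]):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                masks[t] = threshold_segment(frames[t], min_object_px=min_object_px, **threshold_kwargs)
        source = "threshold"
    return MitoMaskStack(masks=masks, min_object_px=min_object_px, source=source)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A∩B| / (|A| + |B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
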