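"""Trainable pre-diagnosis and segmentation models, and the hierarchy rule.

The screening hierarchy: a pre-diagnosis classifier produces an initial
glaucoma probability from the whole image (label threshold 0.8, ties to
glaucoma); segmentation then extracts the optic disc, optic cup and RNFLD
masks, with the cup segmenter *selected by the pre-diagnosis* -- a
glaucoma-specific cup model (trained on referable eyes only) when the
pre-diagnosis says glaucoma, a general cup model otherwise.

Models are scikit-learn estimators.  The classifier is a small multilayer
perceptron over a downsampled copy of the image; each segmenter is a
per-pixel multilayer perceptron over a multi-scale intensity / position
feature stack evaluated on a reduced working grid and upsampled back to
the input resolution.  An ``oracle_mode`` bundle bypasses the trained
models and returns ground-truth masks, which lets the downstream geometry
and decision layers be tested independently of segmentation error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import downscale_local_mean, resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .geometry import MaskSet

__all__ = [
    "FundusImage",
    "TrainConfig",
    "FundusClassifier",
    "FundusSegmenter",
    "NetworkBundle",
    "train_prediagnosis",
    "pre_diagnose",
    "train_segmenter",
    "train_bundle",
    "segment_eye",
    "rnfld_present",
]

INGEST_SIZE = 512

#: softmax threshold on the pre-diagnosis glaucoma probability
PREDIAG_THRESHOLD = 0.8

SEG_TARGETS = ("disc", "cup_general", "cup_glaucoma", "rnfld")


@dataclass
class FundusImage:
    """An RGB fundus photograph, resized to 512x512 on ingestion."""

    pixels: np.ndarray
    laterality: str = "unknown"
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("expected an RGB raster of shape (H, W, 3)")
        if px.shape[:2] != (INGEST_SIZE, INGEST_SIZE):
            px = resize(px, (INGEST_SIZE, INGEST_SIZE), order=1,
                        preserve_range=True, anti_aliasing=True)
        self.pixels = px.astype(np.uint8)


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by the trainable models.

    ``network_depth`` and ``base_channels`` set the hidden-layer layout of
    the perceptrons (layer i has ``base_channels * 2**(depth-1-i)`` units);
    ``binarization_threshold`` binarizes segmentation probability maps.
    """

    epochs: int = 60
    batch_size: int = 64
    learning_rate: float = 1e-3
    network_depth: int = 2
    base_channels: int = 16
    seed: int = 0
    binarization_threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.network_depth, self.base_channels) < 1:
            raise ValueError("counts must all be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.binarization_threshold < 1:
            raise ValueError("binarization_threshold must lie in (0, 1)")

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return tuple(
            self.base_channels * 2 ** (self.network_depth - 1 - i)
            for i in range(self.network_depth)
        )


def _as_pixel_array(image) -> np.ndarray:
    if isinstance(image, FundusImage):
        return image.pixels
    return np.asarray(image)


def _downsample(px: np.ndarray, size: int) -> np.ndarray:
    """Downsample an image to size x size (local mean when factors align)."""
    h, w = px.shape[:2]
    if h == w == size:
        return px
    if h == w and h % size == 0:
        f = h // size
        factors = (f, f) if px.ndim == 2 else (f, f, 1)
        return downscale_local_mean(px, factors)
    return resize(px, (size, size), order=1, preserve_range=True, anti_aliasing=True)


def _upsample_mask(mask: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour upsample of a binary working-grid mask."""
    h, w = shape
    if mask.shape == (h, w):
        return mask
    if h % mask.shape[0] == 0 and w % mask.shape[1] == 0:
        return np.repeat(np.repeat(mask, h // mask.shape[0], axis=0), w // mask.shape[1], axis=1)
    return resize(mask.astype(float), (h, w), order=0,
                  preserve_range=True, anti_aliasing=False) > 0.5


class FundusClassifier(ClassifierMixin, BaseEstimator):
    """Pre-diagnosis classifier: glaucoma probability from the whole image.

    The image is downsampled to ``input_size`` squared, flattened,
    standardized, and fed to a small MLP.  ``predict`` applies the
    screening threshold (default 0.8) with ties going to glaucoma.
    """

    def __init__(self, input_size: int = 32, threshold: float = PREDIAG_THRESHOLD,
                 config: TrainConfig | None = None):
        self.input_size = input_size
        self.threshold = threshold
        self.config = config

    def _features(self, images) -> np.ndarray:
        rows = []
        for img in images:
            px = _as_pixel_array(img).astype(float) / 255.0
            rows.append(_downsample(px, self.input_size).ravel())
        return np.asarray(rows)

    def fit(self, images, y) -> "FundusClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training cohort must contain both classes")
        cfg = self.config or TrainConfig(network_depth=1, base_channels=64)
        X = self._features(images)
        self.scaler_ = StandardScaler().fit(X)
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=cfg.hidden_layer_sizes,
            max_iter=cfg.epochs,
            batch_size=min(cfg.batch_size, X.shape[0]),
            learning_rate_init=cfg.learning_rate,
            random_state=cfg.seed,
            solver="adam",
        )
        _fit_for_epoch_budget(self.mlp_, self.scaler_.transform(X), y)
        self.classes_ = self.mlp_.classes_
        self.loss_curve_ = list(self.mlp_.loss_curve_)
        return self

    def predict_proba(self, images) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        return self.mlp_.predict_proba(self.scaler_.transform(self._features(images)))

    def glaucoma_probability(self, images) -> np.ndarray:
        proba = self.predict_proba(images)
        return proba[:, list(self.classes_).index(1)]

    def predict(self, images) -> np.ndarray:
        return (self.glaucoma_probability(images) >= self.threshold).astype(int)


def _fit_for_epoch_budget(mlp: MLPClassifier, X: np.ndarray, y: np.ndarray) -> None:
    """Fit an MLP whose ``max_iter`` is an epoch budget, not a tolerance."""
    from sklearn.exceptions import ConvergenceWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        mlp.fit(X, y)


def _sample_pixel_indices(rng: np.random.Generator, labels: np.ndarray, k: int) -> np.ndarray:
    """Class-balanced pixel subsample: up to k/2 positives, rest negatives."""
    pos = np.nonzero(labels)[0]
    neg = np.nonzero(~labels)[0]
    n_pos = min(pos.size, k // 2)
    n_neg = min(neg.size, k - n_pos)
    return np.concatenate([
        rng.choice(pos, size=n_pos, replace=False) if n_pos else np.empty(0, int),
        rng.choice(neg, size=n_neg, replace=False) if n_neg else np.empty(0, int),
    ])


def _feature_stack(px_small: np.ndarray, sigmas=(0.0, 2.0, 4.0)) -> np.ndarray:
    """Per-pixel features on the working grid.

    Multi-scale RGB, a local-contrast channel (medium-scale brightness
    minus large-scale surround, which distinguishes broad dark RNFLD
    wedges from thin vessels and slow illumination gradients), and
    normalised position.
    """
    w = px_small.shape[0]
    channels = []
    for sigma in sigmas:
        if sigma == 0:
            blurred = px_small
        else:
            blurred = ndimage.gaussian_filter(px_small, sigma=(sigma, sigma, 0.0))
        channels.extend(blurred[..., c] for c in range(3))
    gray = px_small.mean(axis=-1)
    contrast = ndimage.gaussian_filter(gray, 2.0) - ndimage.gaussian_filter(gray, 10.0)
    rr, cc = np.mgrid[0:w, 0:w].astype(float) / (w - 1)
    radial = np.hypot(rr - 0.5, cc - 0.5)
    channels.extend([contrast, rr, cc, radial])
    return np.stack(channels, axis=-1).reshape(w * w, -1)


class FundusSegmenter(BaseEstimator):
    """Per-pixel segmentation model for one anatomical target.

    Works on a reduced ``working_res`` grid: multi-scale colour and
    position features feed a small MLP; the probability map is binarized at
    the configured threshold, optionally reduced to its largest connected
    component (disc and cup are single structures), and upsampled to the
    input resolution.
    """

    def __init__(self, target: str = "disc", working_res: int = 128,
                 pixels_per_image: int = 1200, largest_component: bool | None = None,
                 min_component_px: int = 64, config: TrainConfig | None = None):
        self.target = target
        self.working_res = working_res
        self.pixels_per_image = pixels_per_image
        self.largest_component = largest_component
        self.min_component_px = min_component_px
        self.config = config

    def _keep_largest(self) -> bool:
        if self.largest_component is not None:
            return self.largest_component
        return self.target != "rnfld"

    def _image_features(self, image) -> np.ndarray:
        px = _as_pixel_array(image).astype(float) / 255.0
        return _feature_stack(_downsample(px, self.working_res))

    def _mask_small(self, mask: np.ndarray) -> np.ndarray:
        return _downsample(np.asarray(mask, float), self.working_res) > 0.5

    def fit(self, images, masks, features=None) -> "FundusSegmenter":
        """Fit on images + target masks.

        ``features`` optionally carries precomputed per-image feature
        stacks (from :meth:`_image_features`); the stacks only depend on
        the image and working resolution, so they can be shared between
        the segmenters of one bundle.
        """
        if len(images) == 0:
            raise ValueError("cannot train a segmenter on an empty cohort")
        cfg = self.config or TrainConfig()
        rng = np.random.default_rng(cfg.seed)
        if features is None:
            features = (self._image_features(img) for img in images)
        xs, ys = [], []
        for feats, mask in zip(features, masks):
            labels = self._mask_small(np.asarray(mask, bool)).ravel()
            take = _sample_pixel_indices(rng, labels, self.pixels_per_image)
            xs.append(np.asarray(feats)[take])
            ys.append(labels[take])
        return self._fit_arrays(np.concatenate(xs), np.concatenate(ys).astype(int), cfg)

    def _fit_arrays(self, X: np.ndarray, y: np.ndarray, cfg: TrainConfig) -> "FundusSegmenter":
        self.scaler_ = StandardScaler().fit(X)
        self.mlp_ = MLPClassifier(
            hidden_layer_sizes=cfg.hidden_layer_sizes,
            max_iter=cfg.epochs,
            batch_size=min(cfg.batch_size * 4, X.shape[0]),
            learning_rate_init=cfg.learning_rate,
            random_state=cfg.seed,
            solver="adam",
        )
        _fit_for_epoch_budget(self.mlp_, self.scaler_.transform(X), y)
        self.threshold_ = cfg.binarization_threshold
        self.loss_curve_ = list(self.mlp_.loss_curve_)
        return self

    def predict_proba_map(self, image, features=None) -> np.ndarray:
        check_is_fitted(self, "mlp_")
        if features is None:
            features = self._image_features(image)
        feats = self.scaler_.transform(features)
        if 1 in self.mlp_.classes_:
            col = list(self.mlp_.classes_).index(1)
            proba = self.mlp_.predict_proba(feats)[:, col]
        else:  # trained on a cohort where the structure never appears
            proba = np.zeros(feats.shape[0])
        return proba.reshape(self.working_res, self.working_res)

    def predict(self, image, features=None) -> np.ndarray:
        proba = self.predict_proba_map(image, features=features)
        mask = proba >= self.threshold_
        if mask.any():
            labeled, n = ndimage.label(mask, structure=np.ones((3, 3), int))
            sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
            if self._keep_largest():
                mask = labeled == (1 + int(np.argmax(sizes)))
            else:
                # multi-component target: drop speckle far smaller than any
                # real structure at the working resolution
                keep = 1 + np.nonzero(sizes >= self.min_component_px)[0]
                mask = np.isin(labeled, keep)
        h, w = _as_pixel_array(image).shape[:2]
        return _upsample_mask(mask, (h, w))


@dataclass
class NetworkBundle:
    """All trained models of the hierarchy, or an oracle stand-in."""

    prediag: FundusClassifier | None = None
    seg_disc: FundusSegmenter | None = None
    seg_cup_general: FundusSegmenter | None = None
    seg_cup_glaucoma: FundusSegmenter | None = None
    seg_rnfld: FundusSegmenter | None = None
    oracle_mode: bool = False

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(f"bundle is missing model(s): {', '.join(missing)}")


def train_prediagnosis(cohort, config: TrainConfig | None = None) -> FundusClassifier:
    """Train the pre-diagnosis classifier on a simulated cohort."""
    y = np.asarray(cohort.referable_labels, dtype=int)
    clf = FundusClassifier(config=config or TrainConfig(network_depth=1, base_channels=64))
    return clf.fit(cohort.images, y)


def pre_diagnose(image, model: FundusClassifier,
                 threshold: float = PREDIAG_THRESHOLD) -> tuple[float, str]:
    """Pre-diagnosis of one image: (glaucoma probability, label).

    The label is ``"glaucoma"`` iff the probability reaches the threshold;
    an exact tie goes to glaucoma.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    check_is_fitted(model, "mlp_")
    p_pre = float(model.glaucoma_probability([image])[0])
    return p_pre, ("glaucoma" if p_pre >= threshold else "normal")


def train_segmenter(cohort, target: str, config: TrainConfig | None = None) -> FundusSegmenter:
    """Train one segmentation model.

    ``cup_glaucoma`` trains on the referable-GON subset only (the
    glaucoma-specific cup model); all other targets use the full cohort.
    """
    if target not in SEG_TARGETS:
        raise ValueError(f"unknown segmentation target {target!r}")
    eyes = cohort.eyes
    if target == "cup_glaucoma":
        eyes = [e for e in eyes if e.referable]
        if not eyes:
            raise ValueError("no referable eyes available to train the glaucoma-specific cup model")
    attr = {"disc": "disc", "cup_general": "cup", "cup_glaucoma": "cup", "rnfld": "rnfld"}[target]
    images = [e.image for e in eyes]
    masks = [getattr(e.masks, attr) for e in eyes]
    seg = FundusSegmenter(target="rnfld" if target == "rnfld" else attr, config=config)
    return seg.fit(images, masks)


def train_bundle(cohort, config: TrainConfig | None = None,
                 prediag_config: TrainConfig | None = None) -> NetworkBundle:
    """Train the full hierarchy on one cohort with a single feature pass.

    Per-pixel features are computed once per image and shared by all four
    segmenters; the glaucoma-specific cup model sees only referable eyes.
    """
    cfg = config or TrainConfig()
    if prediag_config is None:
        prediag_config = TrainConfig(epochs=max(cfg.epochs, 60), seed=cfg.seed,
                                     network_depth=1, base_channels=64)
    prediag = train_prediagnosis(cohort, prediag_config)
    if not any(e.referable for e in cohort.eyes):
        raise ValueError("no referable eyes available to train the glaucoma-specific cup model")
    attr_map = {"disc": "disc", "cup_general": "cup", "cup_glaucoma": "cup", "rnfld": "rnfld"}
    segs = {
        t: FundusSegmenter(target="rnfld" if t == "rnfld" else attr_map[t], config=cfg)
        for t in SEG_TARGETS
    }
    rngs = {t: np.random.default_rng(cfg.seed) for t in SEG_TARGETS}
    xs = {t: [] for t in SEG_TARGETS}
    ys = {t: [] for t in SEG_TARGETS}
    probe = segs["disc"]
    for eye in cohort.eyes:
        feats = probe._image_features(eye.image)
        smalls = {
            attr: probe._mask_small(getattr(eye.masks, attr)).ravel()
            for attr in ("disc", "cup", "rnfld")
        }
        for t in SEG_TARGETS:
            if t == "cup_glaucoma" and not eye.referable:
                continue
            labels = smalls[attr_map[t]]
            take = _sample_pixel_indices(rngs[t], labels, segs[t].pixels_per_image)
            xs[t].append(feats[take])
            ys[t].append(labels[take])
    for t in SEG_TARGETS:
        segs[t]._fit_arrays(np.concatenate(xs[t]), np.concatenate(ys[t]).astype(int), cfg)
    return NetworkBundle(
        prediag=prediag,
        seg_disc=segs["disc"],
        seg_cup_general=segs["cup_general"],
        seg_cup_glaucoma=segs["cup_glaucoma"],
        seg_rnfld=segs["rnfld"],
    )


def segment_eye(image, bundle: NetworkBundle, pre_label: str,
                oracle_masks: MaskSet | None = None,
                laterality: str | None = None) -> MaskSet:
    """Segment disc, cup and RNFLD, selecting the cup model by pre-diagnosis.

    In oracle mode the ground-truth masks are returned (with provenance
    noting the selection the hierarchy *would* have made).
    """
    if pre_label not in ("glaucoma", "normal"):
        raise ValueError("pre_label must be 'glaucoma' or 'normal'")
    cup_model = "glaucoma-specific" if pre_label == "glaucoma" else "general"
    if bundle.oracle_mode:
        if oracle_masks is None:
            raise ValueError("oracle_mode requires the ground-truth masks")
        return MaskSet(
            disc=oracle_masks.disc, cup=oracle_masks.cup, rnfld=oracle_masks.rnfld,
            laterality=oracle_masks.laterality,
            provenance={"source": "oracle", "cup_model": cup_model},
        )
    bundle.require("seg_disc", "seg_rnfld",
                   "seg_cup_glaucoma" if pre_label == "glaucoma" else "seg_cup_general")
    feats = bundle.seg_disc._image_features(image)
    disc = bundle.seg_disc.predict(image, features=feats)
    cup_net = bundle.seg_cup_glaucoma if pre_label == "glaucoma" else bundle.seg_cup_general
    cup = cup_net.predict(image, features=feats)
    rnfld = bundle.seg_rnfld.predict(image, features=feats)
    if laterality is None:
        laterality = image.laterality if isinstance(image, FundusImage) else "right"
    if laterality == "unknown":
        laterality = "right"
    return MaskSet(
        disc=disc, cup=cup, rnfld=rnfld, laterality=laterality,
        provenance={"source": "network", "cup_model": cup_model},
    )


def rnfld_present(rnfld_mask: np.ndarray, min_area: int = 50) -> bool:
    """True iff the largest 8-connected RNFLD component has >= min_area pixels."""
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(rnfld_mask, bool)
    if not mask.any():
        return False
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    return bool(sizes.max() >= min_area)
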