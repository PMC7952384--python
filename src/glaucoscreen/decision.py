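"""Final diagnosis layer: decision line, decision tree, fusion, confidence.

A linear support-vector machine fitted on the two interpretable rim
features (MCDR, ISNT score) yields a classification line in the feature
plane; its signed margin is mapped to a glaucoma probability p1 by
Platt-style logistic calibration.  The final label follows a two-step
decision tree: an RNFL defect forces a glaucoma call; otherwise the side
of the line decides, with points on the line called normal.  The fused
probability is p = (1 + p1) / 2 when an RNFLD is present and p = p1
otherwise, and confidence regions (reliable glaucoma / reliable normal /
suspicious) are thresholds on p.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .geometry import (
    BaselineVector,
    MaskSet,
    RimFeatures,
    compute_cdr_profile,
    isnt_score,
    mean_cdr,
)
from .models import NetworkBundle, pre_diagnose, rnfld_present, segment_eye

__all__ = [
    "LinearBoundary",
    "Diagnosis",
    "DecisionLine",
    "fit_decision_line",
    "classify_final",
    "glaucoma_probability",
    "confidence_region",
    "extract_rim_features",
    "diagnose",
]

REGIONS = ("reliable_glaucoma", "reliable_normal", "suspicious")

REGION_LOW = 0.2
REGION_HIGH = 0.8


@dataclass(frozen=True)
class LinearBoundary:
    """Classification line in the (MCDR, ISNT score) plane.

    The signed margin ``weight_mcdr * mcdr + weight_isnt * isnt + bias`` is
    positive on the glaucoma side; with data where a high ISNT score marks
    normal rims, ``weight_isnt`` comes out negative, so increasing the ISNT
    score at fixed MCDR moves a point toward the normal side.  The
    calibration maps the margin to p1 through a fitted logistic function.
    """

    weight_mcdr: float
    weight_isnt: float
    bias: float
    platt_slope: float
    platt_intercept: float

    def __post_init__(self) -> None:
        if self.weight_mcdr == 0.0 and self.weight_isnt == 0.0:
            raise ValueError("boundary weights must not both be zero")

    def margin(self, mcdr, isnt) -> np.ndarray:
        return self.weight_mcdr * np.asarray(mcdr) + self.weight_isnt * np.asarray(isnt) + self.bias

    def p1(self, mcdr, isnt) -> np.ndarray:
        """Calibrated glaucoma probability from the signed margin."""
        return expit(self.platt_slope * self.margin(mcdr, isnt) + self.platt_intercept)


class DecisionLine(ClassifierMixin, BaseEstimator):
    """Linear SVM on (MCDR, ISNT score) with Platt-calibrated probabilities."""

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y) -> "DecisionLine":
        X = np.asarray(X, float)
        y = np.asarray(y, int)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): columns MCDR, ISNT score")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present to fit the decision line")
        if self.C <= 0:
            raise ValueError("regularization parameter C must be positive")
        self.svm_ = SVC(kernel="linear", C=self.C, random_state=0)
        self.svm_.fit(X, y)
        margins = self.svm_.decision_function(X)
        self.platt_ = LogisticRegression(C=1.0, tol=1e-10, max_iter=10_000)
        self.platt_.fit(margins[:, None], y)
        self.classes_ = self.svm_.classes_
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "svm_")
        return self.svm_.decision_function(np.asarray(X, float))

    def predict(self, X) -> np.ndarray:
        """Glaucoma (1) iff strictly on the positive-margin side of the line."""
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "platt_")
        p1 = self.platt_.predict_proba(self.decision_function(X)[:, None])
        return p1

    def as_boundary(self) -> LinearBoundary:
        check_is_fitted(self, "svm_")
        (w_mcdr, w_isnt), b = self.svm_.coef_[0], float(self.svm_.intercept_[0])
        return LinearBoundary(
            weight_mcdr=float(w_mcdr),
            weight_isnt=float(w_isnt),
            bias=b,
            platt_slope=float(self.platt_.coef_[0, 0]),
            platt_intercept=float(self.platt_.intercept_[0]),
        )


def fit_decision_line(points, labels, regularization: float = 1.0) -> LinearBoundary:
    """Fit the classification line on (MCDR, ISNT) points with referable labels."""
    line = DecisionLine(C=regularization).fit(np.asarray(points, float), labels)
    return line.as_boundary()


def classify_final(features: RimFeatures, boundary: LinearBoundary) -> str:
    """The two-step decision tree for the final label.

    An RNFL defect is called glaucoma outright; otherwise points on the
    normal side of the line -- or exactly on it -- are called normal and
    points strictly on the glaucoma side are called glaucoma.
    """
    if features.rnfld_present:
        return "glaucoma"
    margin = float(boundary.margin(features.mcdr, features.isnt_score))
    return "glaucoma" if margin > 0 else "normal"


def glaucoma_probability(p1: float, rnfld_present: bool) -> float:
    """Fused glaucoma probability: (1 + p1)/2 with an RNFLD, p1 without."""
    if not 0.0 <= p1 <= 1.0:
        raise ValueError("p1 must lie in [0, 1]")
    return (1.0 + p1) / 2.0 if rnfld_present else float(p1)


def confidence_region(p: float, low: float = REGION_LOW, high: float = REGION_HIGH) -> str:
    """Assign the fused probability to a confidence region.

    p >= high: reliable glaucoma (red); p <= low: reliable normal (green);
    in between: suspicious (yellow).
    """
    if not 0.0 < low < high < 1.0:
        raise ValueError("thresholds must satisfy 0 < low < high < 1")
    if p >= high:
        return "reliable_glaucoma"
    if p <= low:
        return "reliable_normal"
    return "suspicious"


def extract_rim_features(masks: MaskSet, baseline: BaselineVector,
                         min_rnfld_area: int = 50) -> RimFeatures:
    """MCDR, ISNT score and RNFLD presence from one eye's masks."""
    profile = compute_cdr_profile(masks)
    return RimFeatures(
        mcdr=mean_cdr(profile),
        isnt_score=isnt_score(profile, baseline),
        rnfld_present=rnfld_present(masks.rnfld, min_area=min_rnfld_area),
    )


def compute_training_features(cohort, bundle: NetworkBundle, baseline: BaselineVector,
                              *, threshold: float = 0.8, min_rnfld_area: int = 50,
                              oracle: bool = False) -> np.ndarray:
    """(MCDR, ISNT score) for every eye, as the trained hierarchy sees them.

    Running the training cohort back through the fitted networks keeps the
    decision line and its probability calibration on the same feature
    distribution that evaluation eyes will produce; ``oracle`` short-cuts
    to the ground-truth masks instead.
    """
    feats = []
    for eye in cohort.eyes:
        if oracle or bundle.oracle_mode:
            masks = eye.masks
        else:
            _, pre_label = pre_diagnose(eye.image, bundle.prediag, threshold)
            masks = segment_eye(eye.image, bundle, pre_label,
                                laterality=eye.masks.laterality)
        rf = extract_rim_features(masks, baseline, min_rnfld_area=min_rnfld_area)
        feats.append((rf.mcdr, rf.isnt_score))
    return np.asarray(feats)


@dataclass
class Diagnosis:
    """Full record of one eye's pass through the hierarchy."""

    id: str
    p_pre: float
    pre_label: str
    mcdr: float
    isnt_score: float
    rnfld_present: bool
    p1: float
    p: float
    final_label: str
    region: str
    mask_provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def diagnose(image, bundle: NetworkBundle, boundary: LinearBoundary,
             baseline: BaselineVector, *, threshold: float = 0.8,
             region_low: float = REGION_LOW, region_high: float = REGION_HIGH,
             min_rnfld_area: int = 50, oracle_masks: MaskSet | None = None,
             laterality: str | None = None, eye_id: str = "") -> Diagnosis:
    """Run the whole hierarchy on one image and record every intermediate.

    Pre-diagnosis selects the cup segmenter; the resulting masks yield the
    rim features; the decision tree and fusion produce the final label, the
    fused probability p and its confidence region.
    """
    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            try:
                wrapped = type(exc)(f"[{name}] {exc}")
            except Exception:
                wrapped = RuntimeError(f"[{name}] {exc}")
            raise wrapped from exc

    if bundle.oracle_mode and bundle.prediag is None:
        p_pre, pre_label = 1.0, "glaucoma"
    else:
        bundle.require("prediag")
        p_pre, pre_label = stage(
            "pre-diagnosis", lambda: pre_diagnose(image, bundle.prediag, threshold)
        )
    masks = stage(
        "segmentation",
        lambda: segment_eye(image, bundle, pre_label, oracle_masks=oracle_masks,
                            laterality=laterality),
    )
    features = stage(
        "rim-features",
        lambda: extract_rim_features(masks, baseline, min_rnfld_area=min_rnfld_area),
    )
    p1 = float(boundary.p1(features.mcdr, features.isnt_score))
    final_label = classify_final(features, boundary)
    p = stage("fusion", lambda: glaucoma_probability(p1, features.rnfld_present))
    region = stage("confidence", lambda: confidence_region(p, low=region_low, high=region_high))
    return Diagnosis(
        id=eye_id,
        p_pre=p_pre,
        pre_label=pre_label,
        mcdr=features.mcdr,
        isnt_score=features.isnt_score,
        rnfld_present=features.rnfld_present,
        p1=p1,
        p=p,
        final_label=final_label,
        region=region,
        mask_provenance=dict(masks.provenance),
    )
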