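"""Shared fixtures: small seeded cohorts and a lightly trained bundle.

Unit tests run on reduced canvases and cohort sizes to stay fast; the
geometric oracles in the acceptance tests use the full 512 canvas.
"""

import numpy as np
import pytest

import glaucoscreen as gs

MIX = {"unlikely": 0.5, "probable": 0.25, "definite": 0.25}


def circle_mask(n: int, center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ellipse_mask(n: int, center: tuple[float, float], a: float, b: float) -> np.ndarray:
    """Axis-aligned ellipse with horizontal semi-axis a, vertical b."""
    rr, cc = np.mgrid[0:n, 0:n]
    return ((cc - center[1]) / a) ** 2 + ((rr - center[0]) / b) ** 2 <= 1.0


@pytest.fixture(scope="session")
def small_train_cohort() -> gs.Cohort:
    return gs.generate_dataset(60, MIX, 11, config=gs.RenderConfig(canvas_size=256, seed=11))


@pytest.fixture(scope="session")
def small_eval_cohort() -> gs.Cohort:
    return gs.generate_dataset(40, MIX, 12, config=gs.RenderConfig(canvas_size=256, seed=12))


@pytest.fixture(scope="session")
def trained_bundle(small_train_cohort) -> gs.NetworkBundle:
    return gs.train_bundle(small_train_cohort, gs.TrainConfig(epochs=30, seed=0))


@pytest.fixture(scope="session")
def small_baseline(small_train_cohort) -> gs.BaselineVector:
    profiles = [
        gs.compute_cdr_profile(e.masks)
        for e in small_train_cohort.eyes
        if e.truth.grade.category == "unlikely"
    ]
    return gs.build_baseline(profiles)


@pytest.fixture(scope="session")
def fitted_boundary(small_train_cohort, small_baseline) -> gs.LinearBoundary:
    feats = []
    for e in small_train_cohort.eyes:
        p = gs.compute_cdr_profile(e.masks)
        feats.append((gs.mean_cdr(p), gs.isnt_score(p, small_baseline)))
    return gs.fit_decision_line(np.asarray(feats), small_train_cohort.referable_labels)
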