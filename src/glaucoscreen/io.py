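"""File formats, configuration and report figures.

Images and masks travel as 8-bit PNG (masks 0/255, one file per structure
with suffixes _disc/_cup/_rnfld), cohort manifests as CSV, profiles and
baselines as CSV with a JSON sidecar, diagnoses as JSON lines, pipeline
configuration as YAML, and model checkpoints as joblib files with a JSON
manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import joblib
import numpy as np
import pandas as pd
import yaml

from .decision import Diagnosis, LinearBoundary, confidence_region, glaucoma_probability
from .geometry import BaselineVector, MaskSet
from .simulate import Cohort, EyeRecord

MASK_SUFFIXES = ("disc", "cup", "rnfld")


@dataclass
class PipelineConfig:
    """Run-wide configuration; round-trips through YAML unchanged."""

    data_dir: str = "data"
    model_dir: str = "models"
    baseline_path: str = "baseline.csv"
    report_dir: str = "reports"
    prediag_threshold: float = 0.8
    region_low: float = 0.2
    region_high: float = 0.8
    rnfld_min_area: int = 50
    master_seed: int = 0
    train: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in (self.prediag_threshold, self.region_low, self.region_high):
            if not 0.0 < t < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.region_low >= self.region_high:
            raise ValueError("region_low must be below region_high")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return np.asarray(iio.imread(path)) > 127


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write images, masks and the manifest of a simulated cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for eye in cohort.eyes:
        iio.imwrite(out / f"{eye.id}.png", eye.image)
        for suffix in MASK_SUFFIXES:
            write_mask(out / f"{eye.id}_{suffix}.png", getattr(eye.masks, suffix))
    manifest_path = out / "manifest.csv"
    cohort.manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(in_dir) -> Cohort:
    """Read a cohort written by :func:`write_cohort` (truths are not recoverable)."""
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    eyes = []
    for row in manifest.itertuples():
        image = np.asarray(iio.imread(in_dir / f"{row.id}.png"))
        masks = MaskSet(
            disc=read_mask(in_dir / f"{row.id}_disc.png"),
            cup=read_mask(in_dir / f"{row.id}_cup.png"),
            rnfld=read_mask(in_dir / f"{row.id}_rnfld.png"),
            laterality=row.laterality,
            provenance={"source": "files"},
        )
        eyes.append(EyeRecord(id=row.id, image=image, masks=masks, truth=None,
                              seed=int(row.seed), referable_label=bool(row.referable)))
    return Cohort(eyes=eyes, manifest=manifest)


def write_profile(path, values: np.ndarray, meta: dict) -> None:
    """Profile or baseline to CSV (degree,value) plus a JSON sidecar."""
    df = pd.DataFrame({"degree": np.arange(360), "value": np.asarray(values, float)})
    df.to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_baseline(path) -> BaselineVector:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return BaselineVector(values=df["value"].to_numpy(), n_source_eyes=int(meta["n_source_eyes"]))


def write_baseline(path, baseline: BaselineVector) -> None:
    write_profile(
        path, baseline.values,
        {
            "n_source_eyes": baseline.n_source_eyes,
            "convention": "canonical-right-eye, 0deg=superior, clockwise",
            "standardized": True,
        },
    )


def write_diagnoses(path, diagnoses: list[Diagnosis]) -> None:
    with open(path, "w") as fh:
        for d in diagnoses:
            fh.write(json.dumps(d.to_dict(), sort_keys=True) + "\n")


def read_diagnoses(path) -> list[Diagnosis]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(Diagnosis(**json.loads(line)))
    return out


def save_model(path, model, manifest: dict) -> None:
    joblib.dump(model, path)
    Path(str(path) + ".json").write_text(json.dumps(manifest, sort_keys=True, default=str))


def load_model(path):
    return joblib.load(path)


def save_boundary(path, boundary: LinearBoundary) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(boundary), sort_keys=True))


def load_boundary(path) -> LinearBoundary:
    return LinearBoundary(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# report figures

REGION_COLORS = {
    "reliable_glaucoma": (0.85, 0.25, 0.25),
    "reliable_normal": (0.30, 0.70, 0.35),
    "suspicious": (0.95, 0.85, 0.30),
}


def overlay_figure(path, image: np.ndarray, masks: MaskSet) -> None:
    """Fundus image with disc/cup/RNFLD contours drawn on top."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image)
    for mask, color, label in (
        (masks.disc, "deepskyblue", "disc"),
        (masks.cup, "orange", "cup"),
        (masks.rnfld, "magenta", "RNFLD"),
    ):
        if mask.any():
            ax.contour(mask.astype(float), levels=[0.5], colors=color, linewidths=1.5)
            ax.plot([], [], color=color, label=label)
    ax.legend(loc="lower right", fontsize=8)
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plane_figure(path, boundary: LinearBoundary, point: tuple[float, float] | None = None,
                 region_low: float = 0.2, region_high: float = 0.8,
                 grid_size: int = 200) -> None:
    """The (MCDR, ISNT) plane shaded by confidence region.

    Each grid point is pushed through the calibrated probability (with no
    RNFLD) and coloured red / green / yellow by the region rule; the
    evaluated eye, if given, is drawn as a point.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mcdr = np.linspace(0.0, 1.0, grid_size)
    isnt = np.linspace(-1.0, 1.0, grid_size)
    mm, ii = np.meshgrid(mcdr, isnt)
    rgb = np.zeros(mm.shape + (3,))
    p1 = boundary.p1(mm, ii)
    for r in range(grid_size):
        for c in range(grid_size):
            p = glaucoma_probability(float(p1[r, c]), False)
            rgb[r, c] = REGION_COLORS[confidence_region(p, region_low, region_high)]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.imshow(rgb, origin="lower", extent=(0, 1, -1, 1), aspect="auto")
    if point is not None:
        ax.plot(point[0], point[1], "ko", markersize=8, markerfacecolor="white")
    ax.set_xlabel("MCDR")
    ax.set_ylabel("ISNT score")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
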