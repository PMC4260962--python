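"""Synthetic H&E-like ROI cohorts with known ground truth.

Each ROI is rendered by placing non-overlapping elliptical nuclei on a
background, assigning each stain an optical-density field — hematoxylin
high inside nuclei with a smooth random chromatin texture, eosin low and
mildly textured in the background — and converting OD to RGB through the
Beer-Lambert law using the *same* stain matrix the analysis pipeline uses
for deconvolution.  That shared matrix makes stain recovery an exact
round-trip oracle (up to 8-bit quantization).

The two diagnosis-like classes differ along the axes that distinguish
malignant from benign intraductal proliferations: the DCIS-like class has
larger mean nuclear radius, larger radius spread (pleomorphism), and
coarser, stronger chromatin texture than the UDH-like class.  Default
cohort sizes mirror a two-institution study: a training set of 80 + 36
patients and a validation set of 20 + 31, with 1-4 ROIs per patient.

The generator makes no claim of histologic realism: no stroma, ducts,
necrosis or cribriform architecture — only the statistical features the
downstream pipeline measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .color import od_to_rgb
from .config import PipelineConfig

# nuclei must land inside the 200-4000 px size filter: r in ~[8.3, 34]
_R_MIN, _R_MAX = 8.5, 34.0


@dataclass
class ClassParams:
    """Per-class nucleus population parameters (pixel units, OD unitless)."""

    mean_radius: float = 11.0        # equivalent radius of the ellipse (px)
    radius_sd: float = 1.2
    aspect_max: float = 1.4          # major/minor ratio drawn in [1, aspect_max]
    chromatin_amp: float = 0.15      # relative OD amplitude of the texture field
    chromatin_scale: float = 2.0     # Gaussian correlation length (px)
    hematoxylin_od: float = 0.65     # base nuclear hematoxylin OD


@dataclass
class CohortSpec:
    """Generator parameters for a two-dataset, two-class cohort."""

    class0: ClassParams = field(default_factory=ClassParams)  # UDH-like
    class1: ClassParams = field(default_factory=lambda: ClassParams(
        mean_radius=15.0, radius_sd=2.5, aspect_max=1.8,
        chromatin_amp=0.30, chromatin_scale=4.0, hematoxylin_od=0.70))
    nuclei_per_roi: int = 16
    rois_per_patient: int = 2        # must lie in 1..4
    roi_size: int = 224
    # patients per (dataset, class): two-institution template
    patients: dict = field(default_factory=lambda: {
        "train": (36, 80), "validation": (31, 20)})  # (n_class0, n_class1)
    eosin_od: float = 0.22
    background_hematoxylin_od: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.rois_per_patient <= 4):
            raise ValueError("rois_per_patient must lie in 1..4")
        if self.nuclei_per_roi < 1 or self.roi_size < 4 * _R_MAX:
            pass  # small ROIs allowed; placement may fail and raise below


@dataclass
class GroundTruth:
    """Planted geometry of one ROI."""

    labels: np.ndarray               # H x W int label map, 0 = background
    centers: np.ndarray              # (n, 2) row/col
    axes: np.ndarray                 # (n, 2) semi-major, semi-minor
    orientations: np.ndarray         # (n,) radians
    hematoxylin_od: np.ndarray       # planted H x W OD field


@dataclass
class Cohort:
    """A generated cohort: manifest plus in-memory images and ground truth."""

    manifest: pd.DataFrame           # patient_id, label, dataset_id, roi_path
    images: dict[str, np.ndarray]    # roi_path -> uint8 RGB
    ground_truth: dict[str, GroundTruth]
    spec: CohortSpec


def _smooth_field(shape: tuple[int, int], scale: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean, unit-variance smoothed white noise (correlation length ~scale)."""
    noise = rng.standard_normal(shape)
    f = ndi.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def render_roi(spec: CohortSpec, class_label: int,
               rng: np.random.Generator) -> tuple[np.ndarray, GroundTruth]:
    """Render one ROI of the given class; returns (uint8 RGB image, truth)."""
    params = spec.class1 if class_label == 1 else spec.class0
    size = spec.roi_size
    labels = np.zeros((size, size), dtype=np.int32)
    centers, axes, angles = [], [], []
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    max_tries = 200 * spec.nuclei_per_roi
    tries = 0
    while len(centers) < spec.nuclei_per_roi:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.nuclei_per_roi} non-overlapping nuclei "
                f"in a {size}x{size} ROI after {max_tries} tries")
        r_eq = float(np.clip(rng.normal(params.mean_radius, params.radius_sd),
                             _R_MIN, _R_MAX))
        q = float(rng.uniform(1.0, params.aspect_max))
        a, b = r_eq * np.sqrt(q), r_eq / np.sqrt(q)
        margin = a + 2.0
        cy = rng.uniform(margin, size - margin)
        cx = rng.uniform(margin, size - margin)
        if any((cy - y) ** 2 + (cx - x) ** 2 < (a + aa + 2.0) ** 2
               for (y, x), (aa, _) in zip(centers, axes)):
            continue
        theta = rng.uniform(0.0, np.pi)
        ct, st = np.cos(theta), np.sin(theta)
        u = (rows - cy) * ct + (cols - cx) * st
        v = -(rows - cy) * st + (cols - cx) * ct
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        labels[inside] = len(centers) + 1
        centers.append((cy, cx))
        axes.append((a, b))
        angles.append(theta)

    nuclear = labels > 0
    chromatin = _smooth_field((size, size), params.chromatin_scale, rng)
    h_od = np.where(
        nuclear,
        np.clip(params.hematoxylin_od * (1.0 + params.chromatin_amp * chromatin), 0.05, None),
        spec.background_hematoxylin_od,
    )
    bg_tex = _smooth_field((size, size), 8.0, rng)
    e_od = np.where(nuclear, 0.05,
                    np.clip(spec.eosin_od * (1.0 + 0.15 * bg_tex), 0.02, None))

    cfg = PipelineConfig()
    stains = cfg.stain_matrix  # rows: hematoxylin, eosin
    od_rgb = h_od[..., None] * stains[0] + e_od[..., None] * stains[1]
    img = od_to_rgb(od_rgb)
    truth = GroundTruth(labels=labels, centers=np.array(centers),
                        axes=np.array(axes), orientations=np.array(angles),
                        hematoxylin_od=h_od)
    return img, truth


def generate_cohort(spec: CohortSpec | None = None,
                    out_dir: str | Path | None = None) -> Cohort:
    """Generate the full two-dataset cohort; optionally write it to disk.

    When ``out_dir`` is given, ROI PNGs, ``manifest.csv`` and a
    ``ground_truth.csv`` of planted nucleus geometry are written there and
    the manifest's ``roi_path`` entries point at the files.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    rows, images, truths = [], {}, {}
    for dataset_id, (n0, n1) in spec.patients.items():
        for class_label, n_patients in ((0, n0), (1, n1)):
            for i in range(n_patients):
                pid = f"{dataset_id}_c{class_label}_p{i:03d}"
                for r in range(spec.rois_per_patient):
                    key = f"{pid}_roi{r}.png"
                    img, truth = render_roi(spec, class_label, rng)
                    images[key] = img
                    truths[key] = truth
                    rows.append({"patient_id": pid, "label": class_label,
                                 "dataset_id": dataset_id, "roi_path": key})
    manifest = pd.DataFrame(rows)
    cohort = Cohort(manifest=manifest, images=images, ground_truth=truths, spec=spec)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, img in images.items():
            iio.imwrite(out / key, img)
        manifest_disk = manifest.copy()
        manifest_disk["roi_path"] = [str(out / k) for k in manifest["roi_path"]]
        manifest_disk.to_csv(out / "manifest.csv", index=False)
        gt_rows = []
        for key, t in truths.items():
            for j, ((cy, cx), (a, b), th) in enumerate(
                    zip(t.centers, t.axes, t.orientations), start=1):
                gt_rows.append({"roi_path": key, "nucleus": j, "row": cy, "col": cx,
                                "semi_major": a, "semi_minor": b, "orientation": th})
        pd.DataFrame(gt_rows).to_csv(out / "ground_truth.csv", index=False)
        cohort.manifest = manifest_disk
        cohort.images = {str(out / k): v for k, v in images.items()}
        cohort.ground_truth = {str(out / k): v for k, v in truths.items()}
    return cohort


def effect_preset(effect: str, seed: int = 0) -> CohortSpec:
    """Cohort specs for the named class-separation levels.

    ``strong`` is the default spec; ``weak`` shrinks the class contrasts;
    ``none`` gives both classes identical (benign-like) parameters.
    """
    base = CohortSpec(seed=seed)
    if effect == "strong":
        return base
    if effect == "weak":
        return replace(base, class1=ClassParams(
            mean_radius=12.2, radius_sd=1.6, aspect_max=1.5,
            chromatin_amp=0.20, chromatin_scale=2.5, hematoxylin_od=0.66))
    if effect == "none":
        return replace(base, class1=ClassParams())
    raise ValueError(f"unknown effect preset: {effect}")


def effect_size_report(cohort: Cohort) -> pd.DataFrame:
    """Standardized mean differences of planted per-patient parameters.

    Computed from the ground-truth geometry (not from the pipeline), per
    parameter: mean nucleus area, within-patient SD of area, and the
    chromatin amplitude parameter; enables calibrated AUC expectations.
    """
    per_patient = []
    for _, grp in cohort.manifest.groupby("patient_id"):
        areas = []
        for path in grp["roi_path"]:
            t = cohort.ground_truth[path]
            areas.extend(np.pi * t.axes[:, 0] * t.axes[:, 1])
        areas = np.asarray(areas)
        label = int(grp["label"].iloc[0])
        params = cohort.spec.class1 if label == 1 else cohort.spec.class0
        per_patient.append({"label": label, "mean_area": areas.mean(),
                            "sd_area": areas.std(ddof=1),
                            "chromatin_amp": params.chromatin_amp})
    df = pd.DataFrame(per_patient)
    rows = []
    for col in ("mean_area", "sd_area", "chromatin_amp"):
        g0, g1 = df.loc[df.label == 0, col], df.loc[df.label == 1, col]
        pooled = np.sqrt((g0.var(ddof=1) + g1.var(ddof=1)) / 2.0)
        smd = 0.0 if pooled == 0 else float((g1.mean() - g0.mean()) / pooled)
        rows.append({"parameter": col, "class0_mean": g0.mean(),
                     "class1_mean": g1.mean(), "effect_size": smd})
    return pd.DataFrame(rows)
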