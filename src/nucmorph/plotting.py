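"""Case-panel and model plots (binary overlay, ellipse approximations,
feature scatter with kernel-density contours, probability rank plot)."""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Ellipse
from scipy.stats import gaussian_kde

from .segment import NucleusObject
from .shape import fit_ellipse_moments

logger = logging.getLogger("nucmorph")


def plot_case_panels(
    image: np.ndarray,
    labels: np.ndarray,
    records: pd.DataFrame,
    objects: list[NucleusObject],
    out_prefix: str | Path,
    features: tuple[str, str] = ("Perim", "Circ"),
) -> list[Path]:
    """Write the three per-case panels; returns the paths written.

    (a) the binary segmentation overlaid on the ROI, (b) elliptical
    approximations of the nuclei, (c) a scatter of two per-nucleus
    features with kernel-density contours.  With fewer than two nuclei
    the density panel is skipped with a logged warning.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(image)
    ax.contour(labels > 0, levels=[0.5], colors="yellow", linewidths=0.8)
    ax.set_axis_off()
    ax.set_title("segmentation")
    p = prefix.with_name(prefix.name + "_binary.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(np.ones_like(image) * 255)
    for obj in objects:
        if obj.area_px < 2:
            continue
        major, minor, theta = fit_ellipse_moments(obj.mask)
        rr, cc = obj.global_coords
        ax.add_patch(Ellipse((cc.mean(), rr.mean()), width=minor, height=major,
                             angle=np.degrees(theta), fill=False, color="navy", lw=0.8))
    ax.set_xlim(0, image.shape[1])
    ax.set_ylim(image.shape[0], 0)
    ax.set_aspect("equal")
    ax.set_title("elliptical approximations")
    p = prefix.with_name(prefix.name + "_ellipses.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    fx, fy = features
    fig, ax = plt.subplots(figsize=(5, 5))
    x, y = records[fx].to_numpy(float), records[fy].to_numpy(float)
    ax.scatter(x, y, s=12, c="black")
    if len(records) >= 2 and np.ptp(x) > 0 and np.ptp(y) > 0:
        try:
            kde = gaussian_kde(np.vstack([x, y]))
            xi = np.linspace(x.min(), x.max(), 80)
            yi = np.linspace(y.min(), y.max(), 80)
            xx, yy = np.meshgrid(xi, yi)
            zz = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
            ax.contour(xx, yy, zz, levels=6, colors="tab:blue", linewidths=0.8)
        except np.linalg.LinAlgError:
            logger.warning("plot: singular covariance, density contour skipped")
    else:
        logger.warning("plot: < 2 nuclei or degenerate spread, density contour skipped")
    ax.set_xlabel(fx)
    ax.set_ylabel(fy)
    p = prefix.with_name(prefix.name + "_density.png")
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written


def plot_rank(table: pd.DataFrame, out_path: str | Path) -> Path:
    """Ranked probability-of-UDH plot; DCIS-like cases red, UDH-like black."""
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = np.where(table["label"].to_numpy() == 1, "red", "black")
    ax.scatter(table["rank"], table["prob_udh"], c=colors, s=18)
    ax.set_xlabel("case rank")
    ax.set_ylabel("probability of UDH")
    ax.set_ylim(-0.02, 1.02)
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def plot_cv_curve(lambdas, auc, out_path: str | Path,
                  lambda_max_auc: float | None = None,
                  lambda_1se: float | None = None) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(np.log(lambdas), auc, marker=".", ms=3)
    for lam, style in ((lambda_max_auc, "--"), (lambda_1se, ":")):
        if lam is not None:
            ax.axvline(np.log(lam), color="grey", ls=style)
    ax.set_xlabel("log(lambda)")
    ax.set_ylabel("cross-validated AUC")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out
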