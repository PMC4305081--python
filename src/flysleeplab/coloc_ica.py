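"""Intensity-correlation (PDM) colocalization for two-channel confocal data.

The pixel-wise colocalization statistic is the product of the
differences from the mean, PDM = (R - mean R) * (G - mean G): positive
where the two channels' intensities covary above or below their means
together (colocalized structure), negative where they anti-covary.
Unlike overlap of absolute intensities, PDM is insensitive to a
constant offset in either channel and to inter-channel staining
intensity differences up to scale.

Stacks are background-subtracted per slice (rolling-ball) and collapsed
to 2-D by sum or maximum Z-projection before the PDM map is computed;
channel means are taken over the analysis mask on the projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.restoration import rolling_ball

__all__ = [
    "TwoChannelImage",
    "PDMMap",
    "subtract_background",
    "z_project",
    "compute_pdm",
    "pdm_summary",
    "render_pdm",
]

DEFAULT_BALL_RADIUS = 50.0


@dataclass
class TwoChannelImage:
    """Two aligned 2-D intensity arrays plus an optional analysis mask."""

    channel_r: np.ndarray
    channel_g: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.channel_r = np.asarray(self.channel_r, dtype=float)
        self.channel_g = np.asarray(self.channel_g, dtype=float)
        if self.channel_r.shape != self.channel_g.shape:
            raise ValueError("channel shapes differ")
        if self.channel_r.ndim != 2:
            raise ValueError("channels must be 2-D (project stacks first)")
        for name, ch in (("R", self.channel_r), ("G", self.channel_g)):
            if not np.all(np.isfinite(ch)):
                raise ValueError(f"channel {name} has non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.channel_r.shape:
                raise ValueError("mask shape differs from channels")

    def effective_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.channel_r.shape, dtype=bool)
        return self.mask


@dataclass
class PDMMap:
    """Per-pixel PDM values (NaN outside the mask) and channel means."""

    pdm: np.ndarray
    mean_r: float
    mean_g: float
    mask: np.ndarray
    degenerate: bool = False  # a channel was constant over the mask


def subtract_background(stack: np.ndarray, radius: float = DEFAULT_BALL_RADIUS) -> np.ndarray:
    """Rolling-ball background subtraction per slice, clipped at zero.

    Accepts a (z, y, x) stack or a single 2-D image; radius is the ball
    radius in pixels and must be positive and smaller than the image.
    """
    a = np.asarray(stack, dtype=float)
    if radius <= 0:
        raise ValueError("radius must be positive")
    squeeze = a.ndim == 2
    if squeeze:
        a = a[None]
    if a.ndim != 3:
        raise ValueError("expected a 2-D image or 3-D stack")
    if radius >= max(a.shape[1], a.shape[2]):
        raise ValueError(
            f"radius {radius} >= image extent {a.shape[1:]}"
        )
    out = np.empty_like(a)
    for i, plane in enumerate(a):
        bg = rolling_ball(plane, radius=radius)
        out[i] = np.clip(plane - bg, 0.0, None)
    return out[0] if squeeze else out


def z_project(
    stack: np.ndarray,
    method: str = "sum",
    slice_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Sum or maximum intensity projection over selected slices.

    slice_range is a half-open (start, stop) into the z axis; default
    all slices.
    """
    a = np.asarray(stack, dtype=float)
    if a.ndim != 3:
        raise ValueError("z_project expects a (z, y, x) stack")
    if slice_range is not None:
        start, stop = slice_range
        if not (0 <= start < stop <= a.shape[0]):
            raise ValueError(
                f"slice_range {slice_range} invalid for {a.shape[0]} slices"
            )
        a = a[start:stop]
    if a.shape[0] == 0:
        raise ValueError("empty slice range")
    if method == "sum":
        return a.sum(axis=0)
    if method == "max":
        return a.max(axis=0)
    raise ValueError(f"unknown projection method {method!r}")


def compute_pdm(image: TwoChannelImage) -> PDMMap:
    """Product-of-differences-from-the-mean map over the analysis mask.

    pdm[x] = (r[x] - mean_r) * (g[x] - mean_g) with means over the
    mask; pixels outside the mask are NaN. The mean of the map over the
    mask equals the population covariance of the two channels. If
    either channel is constant over the mask the map is all zero and
    flagged degenerate.
    """
    mask = image.effective_mask()
    n = int(mask.sum())
    if n < 2:
        raise ValueError("mask must cover at least 2 pixels")
    r = image.channel_r
    g = image.channel_g
    mean_r = float(r[mask].mean())
    mean_g = float(g[mask].mean())
    degenerate = bool(
        np.all(r[mask] == r[mask].flat[0]) or np.all(g[mask] == g[mask].flat[0])
    )
    pdm = np.full(r.shape, np.nan)
    if degenerate:
        pdm[mask] = 0.0
    else:
        pdm[mask] = (r[mask] - mean_r) * (g[mask] - mean_g)
    return PDMMap(pdm=pdm, mean_r=mean_r, mean_g=mean_g, mask=mask,
                  degenerate=degenerate)


def pdm_summary(pdm_map: PDMMap) -> dict[str, float]:
    """Summary statistics of a PDM map over its mask.

    mean_pdm equals the masked channel covariance (population
    convention); fraction_positive is the share of masked pixels with
    strictly positive PDM.
    """
    vals = pdm_map.pdm[pdm_map.mask]
    return {
        "n_pixels": float(vals.size),
        "mean_pdm": float(vals.mean()),
        "fraction_positive": float(np.mean(vals > 0)),
        "min_pdm": float(vals.min()),
        "max_pdm": float(vals.max()),
    }


def render_pdm(pdm_map: PDMMap, out_path=None):
    """False-color rendering with a symmetric diverging scale.

    Color bounds are +/- max(|PDM|) so zero sits at the palette center,
    mirroring the conventional PDM>0 / PDM<0 display. Returns the
    matplotlib figure; saves a PNG when out_path is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = pdm_map.pdm[np.isfinite(pdm_map.pdm)]
    bound = float(np.max(np.abs(finite))) if finite.size else 1.0
    bound = bound or 1.0
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(pdm_map.pdm, cmap="PuOr_r", vmin=-bound, vmax=bound)
    fig.colorbar(im, ax=ax, label="PDM")
    ax.set_axis_off()
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
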