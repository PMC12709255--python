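"""Synthetic fluorescence microscopy and ROI selection.

Simulation frames (per-voxel unbleached counts) are projected along the
optical axis, resampled onto a 128 x 128 pixel grid covering the full axon
length, and convolved with a diffraction-limited Gaussian PSF.  The recovery
ROI is chosen exactly like the experimental analysis: threshold the
difference image between the pre-bleach frame and the first post-bleach
frame at mean + f*std, statistics taken over the whole image including the
dark background (f = 0.5 for bouton FRAP, f = 1.0 for axon FRAP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .geometry import VoxelGrid

DEFAULT_N_PIXELS = 128
DEFAULT_PSF_FWHM = 250.0      # nm, diffraction-limited GFP-like spot
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

ROI_THRESHOLD_SYNAPSE = 0.5
ROI_THRESHOLD_AXON = 1.0


@dataclass
class ImagingConfig:
    """Camera/optics model for synthetic images.

    The field of view spans the full axon length (pixel size = axon length /
    n_pixels, ~39 nm for the defaults); the PSF is an isotropic 2D Gaussian
    normalized to unit sum so total intensity is proportional to the number
    of unbleached proteins in view.  ``projection_axis`` is the optical
    axis, perpendicular to the axon, so the bleached cylinder projects to a
    disk.  Optional Poisson shot noise for robustness studies (off by
    default).
    """

    n_pixels: int = DEFAULT_N_PIXELS
    psf_fwhm: float = DEFAULT_PSF_FWHM        # nm
    pixel_size: Optional[float] = None        # nm; None -> axon_length/n_pixels
    projection_axis: int = 2
    poisson_noise: bool = False


@dataclass
class SyntheticImage:
    """One rendered frame plus its optics metadata."""

    data: np.ndarray          # (n_pixels, n_pixels), float64, a.u. >= 0
    pixel_size: float         # nm
    psf_fwhm: float           # nm

    @property
    def total(self) -> float:
        return float(self.data.sum())


@dataclass
class ImagePair:
    """Pre/post bleach frame pair; ``difference`` is the bleached footprint."""

    pre: np.ndarray
    post: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.pre - self.post


@dataclass
class ROISelection:
    mask: np.ndarray          # boolean (n_pixels, n_pixels)
    threshold: float
    degenerate: bool = False  # std of the difference image was zero

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


class Imager:
    """Renders frames of one grid; precomputes the voxel->pixel binning."""

    def __init__(self, grid: VoxelGrid, config: Optional[ImagingConfig] = None,
                 rng: Optional[np.random.Generator] = None):
        self.config = config or ImagingConfig()
        cfg = self.config
        self.grid = grid
        self.pixel_size = cfg.pixel_size or grid.axon_length / cfg.n_pixels
        self.sigma_px = cfg.psf_fwhm * FWHM_TO_SIGMA / self.pixel_size
        self.rng = rng

        axes = [ax for ax in range(3) if ax != cfg.projection_axis]
        self._axes = axes
        a = grid.voxel_edge
        coords = np.argwhere(grid.accessible_mask)
        # physical center of each voxel along the two image axes
        u = (coords[:, axes[0]] + 0.5) * a
        v = (coords[:, axes[1]] + 0.5) * a
        # center the transverse extent of the grid in the field of view
        fov = cfg.n_pixels * self.pixel_size
        shape = grid.labels.shape
        self._offsets = ((fov - shape[axes[0]] * a) / 2.0,
                         (fov - shape[axes[1]] * a) / 2.0)
        u = u + self._offsets[0]
        v = v + self._offsets[1]
        pu = np.floor(u / self.pixel_size).astype(np.int64)
        pv = np.floor(v / self.pixel_size).astype(np.int64)
        if (pu < 0).any() or (pu >= cfg.n_pixels).any() or \
           (pv < 0).any() or (pv >= cfg.n_pixels).any():
            raise ValueError("geometry does not fit in the imaging field of view")
        self._flat_pixel = pu * cfg.n_pixels + pv

    def render(self, frame: np.ndarray) -> SyntheticImage:
        """Project per-accessible-voxel counts into one synthetic image."""
        cfg = self.config
        if frame.shape[0] != self._flat_pixel.shape[0]:
            raise ValueError("frame is not aligned with the grid's accessible voxels")
        raw = np.bincount(self._flat_pixel, weights=frame,
                          minlength=cfg.n_pixels ** 2)
        img = raw.reshape(cfg.n_pixels, cfg.n_pixels)
        img = ndimage.gaussian_filter(img, self.sigma_px, mode="constant")
        if cfg.poisson_noise and self.rng is not None:
            img = self.rng.poisson(img).astype(float)
        return SyntheticImage(data=img, pixel_size=self.pixel_size,
                              psf_fwhm=cfg.psf_fwhm)

    def pixel_of(self, point) -> tuple:
        """Image pixel containing a physical (x, y, z) position in nm."""
        n = self.config.n_pixels
        pu = int((point[self._axes[0]] + self._offsets[0]) / self.pixel_size)
        pv = int((point[self._axes[1]] + self._offsets[1]) / self.pixel_size)
        return (min(max(pu, 0), n - 1), min(max(pv, 0), n - 1))

    def footprint_mask(self, region: np.ndarray) -> np.ndarray:
        """Pixel footprint of a voxel region (bool over accessible voxels)."""
        cfg = self.config
        hit = np.bincount(self._flat_pixel[region], minlength=cfg.n_pixels ** 2)
        return hit.reshape(cfg.n_pixels, cfg.n_pixels) > 0


def render_image(frame: np.ndarray, grid: VoxelGrid,
                 config: Optional[ImagingConfig] = None) -> SyntheticImage:
    """One-off rendering helper (builds a fresh :class:`Imager`)."""
    return Imager(grid, config).render(frame)


def select_roi(pair: ImagePair,
               threshold_factor: float = ROI_THRESHOLD_SYNAPSE,
               anchor: Optional[tuple] = None) -> ROISelection:
    """Threshold the difference image at mean + f*std over all pixels.

    With ``anchor`` (a pixel index) only the connected component of the
    thresholded mask containing that pixel is kept: the bleached area is a
    single enclosed region around the laser spot, and with finite protein
    numbers the global threshold also passes isolated shot-noise pixels
    elsewhere in the field.
    """
    if pair.pre.shape != pair.post.shape:
        raise ValueError("pre and post images differ in shape")
    diff = pair.difference
    mu = float(diff.mean())
    sd = float(diff.std())
    if sd == 0.0:
        return ROISelection(mask=np.zeros_like(diff, dtype=bool),
                            threshold=mu, degenerate=True)
    thr = mu + threshold_factor * sd
    mask = diff > thr
    if anchor is not None and mask.any():
        lab, _ = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        ai, aj = anchor
        target = lab[ai, aj]
        if target == 0:
            # anchor itself below threshold: take the nearest labeled pixel
            on = np.argwhere(lab > 0)
            d2 = ((on - np.array(anchor)) ** 2).sum(axis=1)
            target = lab[tuple(on[np.argmin(d2)])]
        mask = lab == target
    return ROISelection(mask=mask, threshold=thr)


def roi_timeseries(stack: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-frame sum of masked pixels over an image stack (F, H, W)."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("ROI mask is empty (degenerate image pair?)")
    stack = np.asarray(stack)
    return stack[:, mask].sum(axis=1)


def save_tiff(path, stack: np.ndarray) -> None:
    """Write an image stack as multi-page 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def save_roi(selection: ROISelection, png_path=None, csv_path=None,
             sidecar_path=None, **meta) -> None:
    """Persist an ROI as a binary PNG and/or a pixel-index CSV.

    ``meta`` (threshold factor, seed, protocol, ...) is echoed into an
    optional JSON sidecar together with the computed threshold.
    """
    if png_path is not None:
        from PIL import Image

        Image.fromarray((selection.mask * np.uint8(255))).save(png_path)
    if csv_path is not None:
        idx = np.argwhere(selection.mask)
        np.savetxt(csv_path, idx, fmt="%d", delimiter=",",
                   header="row,col", comments="")
    if sidecar_path is not None:
        import json

        meta.update(threshold=selection.threshold,
                    degenerate=selection.degenerate,
                    n_pixels=selection.n_pixels)
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
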