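"""Photobleaching protocols and acquisition schedules.

Three protocols are implemented:

* ``whole_synapse``  — instantaneous bleach of the entire bouton; the ROI is
  the bouton itself, so recovery is pure axonal influx.
* ``spot_instant``   — instantaneous bleach of a 400-nm-diameter cylinder at
  the bouton center (the laser path); the ROI is the same cylinder.
* ``spot_continuous``— the experimental protocol: the same cylinder is
  bleached for 80 ms, every protein entering the spot while the laser is on
  is flagged, and the ROI is found afterwards by thresholding the
  difference between the pre-bleach image and the first image taken 0.5 s
  after the start of the pulse.

Axon FRAP uses the continuous protocol with the spot centered on the axon
midway between the bouton and the periodic boundary and a stricter ROI
threshold (mean + 1.0 std).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .curves import RecoveryTrace
from .engine import (EquilibrationPolicy, KineticParams, LatticeIndex,
                     Simulation, equilibrate)
from .geometry import VoxelGrid
from .imaging import (ImagePair, Imager, ImagingConfig, ROISelection,
                      ROI_THRESHOLD_AXON, ROI_THRESHOLD_SYNAPSE, select_roi)

WHOLE_SYNAPSE = "whole_synapse"
SPOT_INSTANT = "spot_instant"
SPOT_CONTINUOUS = "spot_continuous"
MODES = (WHOLE_SYNAPSE, SPOT_INSTANT, SPOT_CONTINUOUS)


@dataclass
class BleachSpec:
    """Where, how and for how long the bleaching laser acts."""

    mode: str = SPOT_CONTINUOUS
    spot_diameter: float = 400.0      # nm
    duration: float = 0.080           # s; 0 for the instant modes
    center: Optional[tuple] = None    # physical nm; None -> bouton centroid
    axis: int = 2                     # cylinder/optical axis

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown bleach mode {self.mode!r}")
        if self.mode == SPOT_CONTINUOUS:
            if self.duration <= 0:
                raise ValueError("continuous bleaching needs duration > 0")
        else:
            self.duration = 0.0
        if self.mode != WHOLE_SYNAPSE and self.spot_diameter <= 0:
            raise ValueError("spot_diameter must be positive")


@dataclass
class AcquisitionSchedule:
    """Frame times in seconds relative to the start of the bleach pulse."""

    frame_times: np.ndarray
    pre_frame_time: float = -0.1

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0) or self.frame_times[0] <= 0:
            raise ValueError("frame times must be strictly increasing and positive")

    @classmethod
    def experimental(cls, max_time: float = 80.0) -> "AcquisitionSchedule":
        """The 80-s schedule used in the neuronal-culture FRAP experiments:
        0.5-s intervals to 12 s, 1-s intervals to 36 s, then 2-s intervals.
        ``max_time`` truncates the schedule for reduced-scale runs."""
        t = np.concatenate([np.arange(0.5, 12.0 + 1e-9, 0.5),
                            np.arange(13.0, 36.0 + 1e-9, 1.0),
                            np.arange(38.0, 80.0 + 1e-9, 2.0)])
        return cls(frame_times=t[t <= max_time + 1e-9])

    @classmethod
    def uniform(cls, dt: float = 0.1, duration: float = 200.0,
                first_frame: float = 0.5) -> "AcquisitionSchedule":
        t = np.arange(first_frame, duration + 1e-9, dt)
        return cls(frame_times=t)


def bleach_region(grid: VoxelGrid, spec: BleachSpec,
                  lattice: Optional[LatticeIndex] = None) -> np.ndarray:
    """Boolean mask over accessible voxels hit by the laser.

    Spot modes select accessible voxels whose centers lie inside the
    infinite cylinder of ``spot_diameter`` around the line through
    ``center`` along ``axis``; whole-bouton mode selects every accessible
    bouton voxel.
    """
    lat = lattice if lattice is not None else LatticeIndex(grid)
    if spec.mode == WHOLE_SYNAPSE:
        region = lat.in_synapse.copy()
    else:
        center = spec.center if spec.center is not None else grid.center
        a = grid.voxel_edge
        axes = [ax for ax in range(3) if ax != spec.axis]
        u = (lat.coords[:, axes[0]] + 0.5) * a - center[axes[0]]
        v = (lat.coords[:, axes[1]] + 0.5) * a - center[axes[1]]
        region = (u * u + v * v) <= (spec.spot_diameter / 2.0) ** 2
    if not region.any():
        raise ValueError("bleach region contains no accessible voxels")
    return region


@dataclass
class FRAPResult:
    """Everything one in silico FRAP run produced."""

    trace: RecoveryTrace
    fitted_region: np.ndarray            # bool over accessible voxels (laser)
    roi: ROISelection                    # pixel ROI used for the trace
    pre_image: np.ndarray
    first_post_image: np.ndarray
    images: Optional[np.ndarray] = None  # (F, H, W) stack when requested
    params: Optional[KineticParams] = None
    seed: Optional[int] = None
    n_proteins: int = 0
    equilibration_stationary: bool = True
    total_unbleached: Optional[np.ndarray] = None  # per frame, protein count
    roi_sums: Optional[np.ndarray] = None          # raw ROI intensity per frame

    def trace_frame(self):
        """Raw trace as a DataFrame (t, roi_sum, total_unbleached)."""
        import pandas as pd

        return pd.DataFrame({"t": self.trace.times, "roi_sum": self.roi_sums,
                             "total_unbleached": self.total_unbleached})


def run_frap(grid: VoxelGrid, params: KineticParams, spec: BleachSpec,
             schedule: AcquisitionSchedule, seed: int,
             n_proteins: int = 5000,
             roi_threshold: float = ROI_THRESHOLD_SYNAPSE,
             equilibration: Optional[EquilibrationPolicy] = None,
             imaging: Optional[ImagingConfig] = None,
             lattice: Optional[LatticeIndex] = None,
             keep_images: bool = False) -> FRAPResult:
    """Equilibrate, bleach, image, and record one recovery trace.

    Deterministic given ``seed``.  For the two instant protocols the ROI is
    the pixel footprint of the bleached region; for the continuous protocol
    it is selected from the difference image with ``roi_threshold``.
    """
    lat = lattice if lattice is not None else LatticeIndex(grid)
    sim = Simulation(grid, params, n_proteins=n_proteins, seed=seed,
                     lattice=lat)
    report = equilibrate(sim, equilibration)
    imager = Imager(grid, imaging, rng=sim.rng)

    pre_img = imager.render(sim.unbleached()).data
    region = bleach_region(grid, spec, lattice=lat)

    t0 = sim.time  # bleach pulse start
    if spec.mode == SPOT_CONTINUOUS:
        sim.run_continuous_bleach(region, spec.duration)
    else:
        sim.apply_instant_bleach(region)

    frame_times = schedule.frame_times
    images = [] if keep_images else None
    sums = np.empty(len(frame_times))
    total_unbleached = np.empty(len(frame_times))
    roi: Optional[ROISelection] = None
    for i, ft in enumerate(frame_times):
        sim.advance(t0 + ft)
        total_unbleached[i] = sim.unbleached().sum()
        img = imager.render(sim.unbleached()).data
        if i == 0:
            first_post = img
            if spec.mode == SPOT_CONTINUOUS:
                center = spec.center if spec.center is not None else grid.center
                roi = select_roi(ImagePair(pre=pre_img, post=img),
                                 threshold_factor=roi_threshold,
                                 anchor=imager.pixel_of(center))
                if roi.degenerate or not roi.mask.any():
                    raise ValueError("degenerate image pair: empty ROI")
            else:
                roi = ROISelection(mask=imager.footprint_mask(region),
                                   threshold=np.nan)
        sums[i] = img[roi.mask].sum()
        if keep_images:
            images.append(img)

    pre_value = float(pre_img[roi.mask].sum())
    if pre_value <= 0:
        raise ValueError("pre-bleach ROI intensity is zero; cannot normalize")
    trace = RecoveryTrace(times=frame_times, intensity=sums / pre_value,
                          pre_value=pre_value, protocol=spec.mode)
    return FRAPResult(trace=trace, fitted_region=region, roi=roi,
                      pre_image=pre_img, first_post_image=first_post,
                      images=np.array(images) if keep_images else None,
                      params=params, seed=seed, n_proteins=n_proteins,
                      equilibration_stationary=report.stationary,
                      total_unbleached=total_unbleached, roi_sums=sums)


def axon_spot_center(grid: VoxelGrid) -> tuple:
    """Spot center on the axon midway between the bouton pole and the
    periodic boundary."""
    cx, cy, cz = grid.center
    x = (cx - grid.semi_axes[0]) / 2.0
    return (x, cy, cz)


def run_axon_frap(grid: VoxelGrid, params: KineticParams,
                  schedule: AcquisitionSchedule, seed: int,
                  n_proteins: int = 5000,
                  spot_diameter: float = 400.0,
                  bleach_duration: float = 0.080,
                  **kwargs) -> FRAPResult:
    """Continuous-bleach FRAP on the axon shaft (ROI threshold mean + 1 std)."""
    spec = BleachSpec(mode=SPOT_CONTINUOUS, spot_diameter=spot_diameter,
                      duration=bleach_duration, center=axon_spot_center(grid))
    kwargs.setdefault("roi_threshold", ROI_THRESHOLD_AXON)
    return run_frap(grid, params, spec, schedule, seed,
                    n_proteins=n_proteins, **kwargs)
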