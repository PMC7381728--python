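"""Tumor volume and contrast-derived blood volume from stepped 2D sweeps.

A sweep is an ordered stack of 2D slices acquired at a fixed step along the
tumor (0.2 mm in the motivating protocol).  Each slice is treated as a slab of
thickness equal to the step, so the tumor volume (TV, mm^3) is the summed
in-mask pixel area times the step, and the 3D relative blood volume (RBV, in
arbitrary pixel units) is the summed supra-threshold linear contrast inside
the masks.  ``RBV/TV`` is the perfusion density used to compare tumors of
different sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SweepVolume:
    """Ordered 2D slices at a fixed step with per-slice tumor masks.

    ``slices`` holds the contrast (or B-mode) frames, shape
    (n_slices, rows, cols); ``tumor_masks`` the matching binary masks.
    """

    slices: np.ndarray
    step: float  # mm between slices
    pixel_spacing: tuple[float, float] = (0.1, 0.1)  # mm (row, col)
    tumor_masks: np.ndarray | None = None
    contrast_threshold: float = 0.0
    is_linear: bool = True

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("slices must be (n_slices, rows, cols)")
        if not self.step > 0:
            raise ValueError("step must be positive")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        if self.tumor_masks is not None:
            self.tumor_masks = np.asarray(self.tumor_masks).astype(bool)
            if self.tumor_masks.shape != self.slices.shape:
                raise ValueError(
                    f"tumor_masks shape {self.tumor_masks.shape} != "
                    f"slices {self.slices.shape}"
                )

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    @property
    def pixel_area(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass
class VolumetricsResult:
    TV: float  # mm^3
    RBV3d: float  # arbitrary pixel units
    normalized_rbv: float  # a.u. / mm^3
    contrast_threshold: float = 0.0
    mode: str = "intensity_sum"


def tumor_volume(sweep: SweepVolume) -> float:
    """TV = sum over slices of (mask pixel count * pixel area) * step, in mm^3.

    Additive over disjoint slice subsets and invariant to slice order.
    """
    if sweep.tumor_masks is None:
        raise ValueError("sweep has no tumor masks")
    n_pixels = int(sweep.tumor_masks.sum())
    return n_pixels * sweep.pixel_area * sweep.step


def contrast_blood_volume(
    sweep: SweepVolume,
    threshold: float | None = None,
    mode: str = "intensity_sum",
) -> float:
    """3D RBV: summed supra-threshold linear contrast inside the tumor masks.

    ``mode='pixel_count'`` instead counts the supra-threshold pixels, the
    alternative reading of 'arbitrary pixel units'.  Sub-threshold pixels
    contribute 0 either way.  Log-compressed sweeps must be linearized first.
    """
    if sweep.tumor_masks is None:
        raise ValueError("sweep has no tumor masks")
    if not sweep.is_linear:
        raise ValueError("sweep contrast is log-compressed; linearize it first")
    if mode not in {"intensity_sum", "pixel_count"}:
        raise ValueError(f"unknown mode {mode!r}")
    thr = sweep.contrast_threshold if threshold is None else threshold
    values = sweep.slices[sweep.tumor_masks]
    supra = values > thr
    if mode == "pixel_count":
        return float(np.count_nonzero(supra))
    return float(values[supra].sum())


def normalized_rbv(rbv3d: float, tv: float) -> float:
    """RBV3d / TV (a.u. per mm^3); errors when TV is 0."""
    if tv <= 0:
        raise ValueError("tumor volume must be positive to normalize RBV")
    return rbv3d / tv


def analyze_sweep(
    sweep: SweepVolume,
    threshold: float | None = None,
    mode: str = "intensity_sum",
) -> VolumetricsResult:
    """TV, 3D RBV and their ratio in one record, with the threshold stamped in."""
    tv = tumor_volume(sweep)
    rbv = contrast_blood_volume(sweep, threshold=threshold, mode=mode)
    thr = sweep.contrast_threshold if threshold is None else threshold
    return VolumetricsResult(
        TV=tv,
        RBV3d=rbv,
        normalized_rbv=normalized_rbv(rbv, tv),
        contrast_threshold=thr,
        mode=mode,
    )
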