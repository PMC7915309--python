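"""The VIT/RPE relative-intensity biomarker.

The mean pixel intensity of the vitreous, divided by the mean pixel
intensity of the RPE band, per b-scan; the eye-level value is the unweighted
mean over the b-scans of the session.  Using the RPE as an internal
reference makes the biomarker dimensionless and invariant to global
intensity scaling, so values are comparable across visits and devices
without contrast normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptyRegionError, ZeroRPESignalError
from .io import IntensityGrid
from .segmentation import RegionMasks


@dataclass(frozen=True)
class RelativeIntensityResult:
    """Per-b-scan vitreous and RPE means and their ratio."""

    vit_mean: float
    rpe_mean: float
    ratio: float


def bscan_relative_intensity(
    grid: IntensityGrid, masks: RegionMasks
) -> RelativeIntensityResult:
    """VIT/RPE relative intensity of one b-scan.

    The mean of each region is the average of the intensity of all pixels
    within the region mask; the ratio is ``vit_mean / rpe_mean``.

    Raises
    ------
    EmptyRegionError
        Either mask selects no pixels.
    ZeroRPESignalError
        The RPE mean is zero, leaving the ratio undefined.
    """
    if masks.vitreous.shape != grid.pixels.shape:
        raise EmptyRegionError(
            f"mask shape {masks.vitreous.shape} does not match grid "
            f"{grid.pixels.shape}"
        )
    n_vit = int(masks.vitreous.sum())
    n_rpe = int(masks.rpe.sum())
    if n_vit == 0:
        raise EmptyRegionError("vitreous mask is empty")
    if n_rpe == 0:
        raise EmptyRegionError("RPE mask is empty")
    vit_mean = float(grid.pixels[masks.vitreous].mean())
    rpe_mean = float(grid.pixels[masks.rpe].mean())
    if rpe_mean == 0.0:
        raise ZeroRPESignalError("RPE mean intensity is zero")
    return RelativeIntensityResult(
        vit_mean=vit_mean, rpe_mean=rpe_mean, ratio=vit_mean / rpe_mean
    )


def eye_relative_intensity(
    per_bscan: Sequence[RelativeIntensityResult],
    pooled: bool = False,
) -> float:
    """Eye-level VIT/RPE relative intensity.

    By definition the eye value is the unweighted arithmetic mean of the
    per-b-scan ratios.  ``pooled=True`` instead returns the ratio of the
    pooled region means (mean of vit_means over mean of rpe_means); it is
    exposed for sensitivity analyses and is not the default.
    """
    if not per_bscan:
        raise EmptyRegionError("no b-scan results to aggregate")
    if pooled:
        v = float(np.mean([r.vit_mean for r in per_bscan]))
        r = float(np.mean([r.rpe_mean for r in per_bscan]))
        if r == 0.0:
            raise ZeroRPESignalError("pooled RPE mean intensity is zero")
        return v / r
    return float(np.mean([r.ratio for r in per_bscan]))
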