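"""Retinal layer segmentation on single b-scans.

Four boundaries are traced per column, in depth order: the inner limiting
membrane (ILM), the outer border of the ILM-RNFL co-layer, and the inner and
outer borders of the retinal pigment epithelium (RPE).  They delimit the two
reference regions of the VIT/RPE biomarker -- the vitreous (everything above
the ILM) and the RPE band -- and the ILM-RNFL thickness measure.

Algorithm (per column, fully vectorised across columns):

1. Smooth the column profile with a moving average (default 7 rows).
2. Estimate the vitreous background level (median of the top rows) and its
   spread (MAD); the bright-tissue threshold is
   ``background + max(k * MAD, floor_frac * (column max - background))``.
3. Anchor on the RPE: the deepest row whose smoothed intensity is within a
   few percent of the column maximum (the RPE is the brightest sustained
   band; when several bands tie, the deepest wins).
4. ILM: the first row of a sustained bright run (>= 5 raw rows above
   threshold) that lies *below* the last dark gap above the RPE anchor.  A
   floating hyperreflective aggregate is bright but is followed by dark
   vitreous before the retina, so it sits above such a gap and is skipped;
   an aggregate resting on the ILM has no gap below it and is merged into
   the ILM-RNFL co-layer, which is the intended behaviour.
5. RNFL outer / RPE inner / RPE outer: crossings of the smoothed profile
   through the midpoint between the adjacent plateau levels.  For a
   symmetric smoothing window the midpoint crossing lands exactly on the
   step edge of a noiseless piecewise-constant profile.
6. Median-smooth each boundary trace across columns (default window 15) to
   suppress single-column outliers; failed columns are filled by linear
   interpolation from their neighbours.

A b-scan is rejected when more than ``max_failed_frac`` of its columns fail
detection; an image without any sustained bright band raises
:class:`~octquant.errors.NoRetinalBandError`.  All thresholds are defined
relative to robust image statistics, so segmentation is invariant under
global multiplicative intensity scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import (
    BScanRejectedError,
    GeometryMismatchError,
    NoRetinalBandError,
    OrderingViolationError,
)
from .io import IntensityGrid


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the boundary tracer.

    Attributes
    ----------
    smooth_rows
        Moving-average window (rows) for the column profile.
    column_median_window
        Median window (columns) applied to each boundary trace.
    background_rows
        Number of top rows used for the vitreous background estimate.
    k_mad
        Bright-tissue threshold offset in MAD units above background.
    rel_floor
        Threshold floor as a fraction of the column's dynamic range;
        keeps the threshold meaningful on noiseless images where MAD = 0.
    sustain_rows
        Minimum consecutive above-threshold raw rows for an ILM candidate.
    gap_rows
        Minimum consecutive dark smoothed rows that count as a vitreous gap.
    dark_frac
        A row is "dark" below background + dark_frac * (threshold - background).
    rpe_peak_frac
        Rows within this fraction of the column maximum are RPE-peak
        candidates; the deepest one is the anchor.
    band_sample_rows
        Rows sampled below the ILM to estimate the ILM-RNFL band level.
    max_failed_frac
        Reject the b-scan when more columns than this fraction fail.
    """

    smooth_rows: int = 7
    column_median_window: int = 15
    background_rows: int = 50
    k_mad: float = 4.0
    rel_floor: float = 0.1
    sustain_rows: int = 5
    gap_rows: int = 7
    dark_frac: float = 0.5
    rpe_peak_frac: float = 0.95
    band_sample_rows: int = 10
    max_failed_frac: float = 0.30


@dataclass
class LayerBoundaries:
    """Per-column row indices of the four traced boundaries.

    All indices are 0-based; regions are half-open ``[start, end)``.  The
    depth ordering ``ilm <= rnfl_outer <= rpe_inner <= rpe_outer`` holds for
    every column.  ``rpe_outer`` may equal ``n_rows`` when the RPE band
    touches the bottom of the scan.
    """

    ilm_row: np.ndarray
    rnfl_outer_row: np.ndarray
    rpe_inner_row: np.ndarray
    rpe_outer_row: np.ndarray
    n_rows: int

    def __post_init__(self) -> None:
        traces = [self.ilm_row, self.rnfl_outer_row,
                  self.rpe_inner_row, self.rpe_outer_row]
        arrs = [np.asarray(t, dtype=int) for t in traces]
        n = arrs[0].shape[0]
        if any(a.ndim != 1 or a.shape[0] != n for a in arrs):
            raise GeometryMismatchError("boundary traces must be 1-D and equal length")
        if any(a.min() < 0 for a in arrs):
            raise GeometryMismatchError("boundary indices must be >= 0")
        if max(a.max() for a in arrs[:3]) >= self.n_rows or arrs[3].max() > self.n_rows:
            raise GeometryMismatchError("boundary indices exceed grid rows")
        if not (np.all(arrs[0] <= arrs[1]) and np.all(arrs[1] <= arrs[2])
                and np.all(arrs[2] <= arrs[3])):
            raise OrderingViolationError("boundary depth ordering violated")
        self.ilm_row, self.rnfl_outer_row, self.rpe_inner_row, self.rpe_outer_row = arrs

    @property
    def n_cols(self) -> int:
        return self.ilm_row.shape[0]

    def to_tsv(self, path) -> None:
        """Export as a 4-row TSV (one value per column) for overlay checks."""
        arr = np.vstack([self.ilm_row, self.rnfl_outer_row,
                         self.rpe_inner_row, self.rpe_outer_row])
        np.savetxt(path, arr, fmt="%d", delimiter="\t")


@dataclass
class RegionMasks:
    """Boolean pixel masks of the vitreous and the RPE band."""

    vitreous: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        if self.vitreous.shape != self.rpe.shape:
            raise GeometryMismatchError("mask shapes differ")
        if np.any(self.vitreous & self.rpe):
            raise GeometryMismatchError("vitreous and RPE masks overlap")


def _sliding_all(mask: np.ndarray, w: int) -> np.ndarray:
    """True at row r where mask[r:r+w, c] is all True (False near the bottom)."""
    n = mask.shape[0]
    c = np.zeros((n + 1, mask.shape[1]), dtype=np.int32)
    np.cumsum(mask, axis=0, out=c[1:])
    out = np.zeros_like(mask)
    if n >= w:
        out[: n - w + 1] = (c[w:] - c[:-w]) == w
    return out


def _first_true(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per column: (row of first True, any True)."""
    has = mask.any(axis=0)
    return mask.argmax(axis=0), has


def _last_true(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    has = mask.any(axis=0)
    rev = mask[::-1].argmax(axis=0)
    return mask.shape[0] - 1 - rev, has


def segment_boundaries(
    grid: IntensityGrid,
    params: SegmentationParams | None = None,
) -> LayerBoundaries:
    """Trace the ILM, RNFL-outer and RPE inner/outer boundaries.

    Raises
    ------
    NoRetinalBandError
        No column contains a sustained bright band (e.g. a uniform image).
    BScanRejectedError
        More than ``params.max_failed_frac`` of the columns failed.
    OrderingViolationError
        Depth ordering could not be enforced after column smoothing.
    """
    p = params or SegmentationParams()
    pix = grid.pixels
    n_rows, n_cols = pix.shape
    rows = np.arange(n_rows)[:, None]

    smoothed = uniform_filter1d(pix, p.smooth_rows, axis=0, mode="nearest")

    nb = min(p.background_rows, max(8, n_rows // 3))
    background = np.median(pix[:nb], axis=0)
    mad = np.median(np.abs(pix[:nb] - background), axis=0)
    col_max = smoothed.max(axis=0)
    contrast = col_max - background
    threshold = background + np.maximum(p.k_mad * mad, p.rel_floor * contrast)

    scale = max(float(np.max(col_max)), 1.0)
    col_ok = contrast > 1e-9 * scale
    if not col_ok.any():
        raise NoRetinalBandError("no column shows contrast above background")

    # --- RPE anchor: deepest near-maximum row -------------------------------
    near_max = smoothed >= p.rpe_peak_frac * col_max[None, :]
    peak, _ = _last_true(near_max)   # every column has at least its argmax

    # --- ILM: first sustained bright run below the last vitreous gap --------
    above = pix > threshold[None, :]
    run = _sliding_all(above, p.sustain_rows)

    dark_level = background + p.dark_frac * (threshold - background)
    dark = smoothed < dark_level[None, :]
    gap = _sliding_all(dark, p.gap_rows)
    gap &= rows + p.gap_rows <= peak[None, :] - 5
    last_gap, has_gap = _last_true(gap)
    last_gap = np.where(has_gap, last_gap, -1)

    ilm_cand = run & (rows > last_gap[None, :]) & (rows < peak[None, :] - 2)
    ilm_cand &= col_ok[None, :]
    ilm, has_ilm = _first_true(ilm_cand)

    # --- level estimates ----------------------------------------------------
    cols = np.arange(n_cols)
    band_rows = np.clip(ilm[None, :] + np.arange(p.band_sample_rows)[:, None],
                        0, n_rows - 1)
    band_level = np.median(smoothed[band_rows, cols[None, :]], axis=0)

    inner = (rows > (ilm + 5)[None, :]) & (rows < (peak - 5)[None, :])
    tissue = np.where(inner, smoothed, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        retina_level = np.nanpercentile(tissue, 25, axis=0)
    has_level = np.isfinite(retina_level)
    retina_level = np.where(has_level, retina_level, band_level)

    rpe_level = smoothed[peak, cols]
    deep = np.where(rows > (peak + 10)[None, :], smoothed, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        below_level = np.nanmedian(deep, axis=0)
    below_level = np.where(np.isfinite(below_level), below_level, background)

    half = p.smooth_rows // 2

    # --- RNFL outer: midpoint crossing below the ILM band -------------------
    mid_band = 0.5 * (band_level + retina_level)
    cand = (smoothed < mid_band[None, :]) & (rows >= (ilm + half + 1)[None, :]) \
        & (rows <= peak[None, :])
    rnfl_outer, has_rnfl = _first_true(cand)

    # --- RPE inner: last sub-midpoint row above the anchor, plus one --------
    mid_in = 0.5 * (rpe_level + retina_level)
    cand = (smoothed < mid_in[None, :]) & (rows > rnfl_outer[None, :]) \
        & (rows <= peak[None, :])
    last_in, has_in = _last_true(cand)
    rpe_inner = last_in + 1

    # --- RPE outer: first sub-midpoint row below the anchor -----------------
    mid_out = 0.5 * (rpe_level + below_level)
    cand = (smoothed < mid_out[None, :]) & (rows > peak[None, :])
    first_out, has_out = _first_true(cand)
    rpe_outer = np.where(has_out, first_out, n_rows)

    # --- failed-column handling ---------------------------------------------
    failed = ~(col_ok & has_ilm & has_rnfl & has_in & has_level)
    n_failed = int(failed.sum())
    if n_failed == n_cols:
        raise NoRetinalBandError("boundary detection failed in every column")
    if n_failed > p.max_failed_frac * n_cols:
        raise BScanRejectedError(
            f"{n_failed}/{n_cols} columns failed boundary detection"
        )

    traces = np.vstack([ilm, rnfl_outer, rpe_inner, rpe_outer]).astype(float)
    if n_failed:
        good = ~failed
        xs = cols[good]
        for t in traces:
            t[failed] = np.interp(cols[failed], xs, t[good])

    # --- column smoothing and ordering enforcement --------------------------
    w = min(p.column_median_window, n_cols)
    traces = np.stack([
        median_filter(t, size=w, mode="nearest") for t in traces
    ])
    traces = np.rint(traces).astype(int)

    violated = (np.diff(traces, axis=0) < 0).any(axis=0)
    if violated.mean() > p.max_failed_frac:
        raise OrderingViolationError(
            f"depth ordering violated in {int(violated.sum())}/{n_cols} columns"
        )
    traces = np.maximum.accumulate(traces, axis=0)
    traces[:3] = np.clip(traces[:3], 0, n_rows - 1)
    traces[3] = np.clip(traces[3], 0, n_rows)

    return LayerBoundaries(
        ilm_row=traces[0], rnfl_outer_row=traces[1],
        rpe_inner_row=traces[2], rpe_outer_row=traces[3],
        n_rows=n_rows,
    )


def build_masks(boundaries: LayerBoundaries, dims: tuple[int, int]) -> RegionMasks:
    """Build the vitreous and RPE pixel masks for a grid of shape ``dims``.

    Vitreous = rows ``[0, ilm)`` per column (the space between the top of the
    b-scan and the ILM); RPE = rows ``[rpe_inner, rpe_outer)``.
    """
    n_rows, n_cols = dims
    if boundaries.n_cols != n_cols or boundaries.n_rows != n_rows:
        raise GeometryMismatchError(
            f"boundaries for {(boundaries.n_rows, boundaries.n_cols)} "
            f"do not match dims {dims}"
        )
    rows = np.arange(n_rows)[:, None]
    vitreous = rows < boundaries.ilm_row[None, :]
    rpe = (rows >= boundaries.rpe_inner_row[None, :]) \
        & (rows < boundaries.rpe_outer_row[None, :])
    return RegionMasks(vitreous=vitreous, rpe=rpe)


def ilm_rnfl_thickness(boundaries: LayerBoundaries, axial_pitch: float) -> float:
    """Mean ILM-RNFL co-layer thickness in um.

    The column-wise thickness is ``(rnfl_outer - ilm) * axial_pitch``; the
    scan value is its unweighted mean over columns.
    """
    d = (boundaries.rnfl_outer_row - boundaries.ilm_row).astype(float)
    return float(d.mean() * axial_pitch)
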