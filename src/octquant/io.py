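"""Reading and writing b-scan stacks and result tables.

The session data model mirrors how a spectral-domain OCT device exports a
posterior-pole acquisition: an ordered stack of cross-sectional b-scans per
eye per visit (61 scans of 1536 x 496 pixels on the rodent Spectralis
protocol, ~3 um per pixel).  The library operates on decoded frames only:
AVI exports are ingested as directories of pre-extracted frames, multi-page
TIFFs, or PNG directories.  Intensities are stored as read, with no contrast
adjustment -- every downstream statistic is ratio-based and scale-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ChannelCountError,
    FrameShapeMismatchError,
    MissingPathError,
    UnreadableFrameError,
    ZeroFramesError,
)

#: Rec. 601 luminance weights, the near-universal video-export convention.
_REC601 = np.array([0.299, 0.587, 0.114])

#: Device defaults: rodent posterior-pole protocol.
DEFAULT_N_ROWS = 496
DEFAULT_N_COLS = 1536
DEFAULT_N_BSCANS = 61
DEFAULT_AXIAL_PITCH_UM = 3.0
DEFAULT_LATERAL_PITCH_UM = 3.0

#: Printed-calibration area ratio: 2906 mm^2 over 761,856 pixels per image.
PRINTED_PIXEL_AREA_UM2 = 3815.0
#: Isotropic alternative implied by the 3 um/pixel pitch.
ISOTROPIC_PIXEL_AREA_UM2 = DEFAULT_AXIAL_PITCH_UM * DEFAULT_LATERAL_PITCH_UM

_FRAME_SUFFIXES = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


@dataclass(frozen=True)
class IntensityGrid:
    """One grayscale b-scan with its physical calibration.

    Parameters
    ----------
    pixels
        2-D float array, rows x cols, row 0 = top of the b-scan (deepest
        vitreous), rows increasing toward the choroid.
    axial_pitch, lateral_pitch
        Physical pixel pitch in um along rows / columns.
    pixel_area
        Effective area in um^2 per pixel used for aggregate quantification.
        Defaults to the printed device calibration (3815 um^2/pixel); an
        isotropic 3 um x 3 um grid gives 9 um^2/pixel instead.
    """

    pixels: np.ndarray
    axial_pitch: float = DEFAULT_AXIAL_PITCH_UM
    lateral_pitch: float = DEFAULT_LATERAL_PITCH_UM
    pixel_area: float = PRINTED_PIXEL_AREA_UM2

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"degenerate grid {px.shape}: need >= 8 rows and cols")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel intensities must be finite")
        if px.min() < 0:
            raise ValueError("pixel intensities must be >= 0")
        if not (self.pixel_area > 0):
            raise ValueError("pixel_area must be > 0")
        if not (self.axial_pitch > 0 and self.lateral_pitch > 0):
            raise ValueError("pixel pitches must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def scaled(self, c: float) -> "IntensityGrid":
        """Grid with all intensities multiplied by ``c`` (c > 0)."""
        return dataclasses.replace(self, pixels=self.pixels * float(c))


@dataclass
class ScanSession:
    """All b-scans of one eye at one follow-up week."""

    eye_id: str
    bscans: list[IntensityGrid]
    laterality: str = "RE"                 # RE | LE
    group: str = "treated"                 # treated | untreated_OHT | healthy_control
    week: float = 0.0

    def __post_init__(self) -> None:
        if self.week < 0:
            raise ValueError("week must be >= 0")
        if self.laterality not in ("RE", "LE"):
            raise ValueError(f"laterality must be RE or LE, got {self.laterality!r}")
        if not self.bscans:
            raise ValueError("session must contain at least one b-scan")
        ref = self.bscans[0]
        for i, g in enumerate(self.bscans):
            if (g.n_rows, g.n_cols) != (ref.n_rows, ref.n_cols):
                raise FrameShapeMismatchError(
                    f"b-scan {i} has shape {(g.n_rows, g.n_cols)}, "
                    f"expected {(ref.n_rows, ref.n_cols)}"
                )
            if (g.axial_pitch, g.lateral_pitch, g.pixel_area) != (
                ref.axial_pitch, ref.lateral_pitch, ref.pixel_area
            ):
                raise ValueError(f"b-scan {i} calibration differs from b-scan 0")

    @property
    def n_bscans(self) -> int:
        return len(self.bscans)

    @property
    def dims(self) -> tuple[int, int]:
        return self.bscans[0].n_rows, self.bscans[0].n_cols

    def metadata(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "laterality": self.laterality,
            "group": self.group,
            "week": self.week,
            "n_bscans": self.n_bscans,
            "n_rows": self.dims[0],
            "n_cols": self.dims[1],
            "axial_pitch_um": self.bscans[0].axial_pitch,
            "lateral_pitch_um": self.bscans[0].lateral_pitch,
            "pixel_area_um2": self.bscans[0].pixel_area,
        }


@dataclass
class EyeTimepointResult:
    """Per-eye-per-week metric bundle produced by the pipeline."""

    eye_id: str
    laterality: str
    group: str
    week: float
    vit_rpe_ratio: float
    vit_mean: float
    rpe_mean: float
    n_bscans: int
    n_rejected: int
    aggregate_count: int
    total_area_um2: float
    mean_area_um2: float
    ilm_rnfl_thickness_um: float
    pixel_area_um2: float = PRINTED_PIXEL_AREA_UM2
    calibration: str = "printed_ratio"

    #: fixed TSV column order
    COLUMNS = (
        "eye_id", "laterality", "group", "week",
        "vit_rpe_ratio", "vit_mean", "rpe_mean",
        "n_bscans", "n_rejected",
        "aggregate_count", "total_area_um2", "mean_area_um2",
        "ilm_rnfl_thickness_um", "pixel_area_um2", "calibration",
    )


def to_grayscale(
    frame: np.ndarray,
    axial_pitch: float = DEFAULT_AXIAL_PITCH_UM,
    lateral_pitch: float = DEFAULT_LATERAL_PITCH_UM,
    pixel_area: float = PRINTED_PIXEL_AREA_UM2,
) -> IntensityGrid:
    """Reduce a decoded frame to a single-channel :class:`IntensityGrid`.

    Three-channel frames are collapsed with the Rec. 601 luminance weights
    (0.299 R + 0.587 G + 0.114 B); single-channel frames pass through
    unchanged.  RGBA is accepted by dropping the alpha channel.
    """
    arr = np.asarray(frame, dtype=float)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 2:
        gray = arr
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = arr @ _REC601
    elif arr.ndim == 3 and arr.shape[2] == 1:
        gray = arr[:, :, 0]
    else:
        raise ChannelCountError(
            f"expected 1 or 3 channels, got frame shape {arr.shape}"
        )
    return IntensityGrid(
        pixels=gray,
        axial_pitch=axial_pitch,
        lateral_pitch=lateral_pitch,
        pixel_area=pixel_area,
    )


def _frame_files(path: Path) -> list[Path]:
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in _FRAME_SUFFIXES
    )
    return files


def load_bscan_stack(
    path: str | Path,
    format: str = "auto",
    *,
    eye_id: str = "eye",
    laterality: str = "RE",
    group: str = "treated",
    week: float = 0.0,
    axial_pitch: float = DEFAULT_AXIAL_PITCH_UM,
    lateral_pitch: float = DEFAULT_LATERAL_PITCH_UM,
    pixel_area: float = PRINTED_PIXEL_AREA_UM2,
) -> ScanSession:
    """Load an ordered b-scan stack into a :class:`ScanSession`.

    Parameters
    ----------
    path
        Directory of frame files (``avi_frames`` / ``png_dir``, sorted by
        filename = scan order) or a multi-page TIFF (``tiff_stack``).
    format
        ``avi_frames`` | ``png_dir`` | ``tiff_stack`` | ``auto`` (inferred
        from the path).  ``avi_frames`` and ``png_dir`` are synonymous: the
        library accepts decoded frames only; AVI decoding, when needed, is
        delegated to an external decoder by the CLI.

    Raises
    ------
    MissingPathError, ZeroFramesError, FrameShapeMismatchError,
    UnreadableFrameError
    """
    path = Path(path)
    if not path.exists():
        raise MissingPathError(f"no such stack: {path}")

    if format == "auto":
        format = "tiff_stack" if path.is_file() else "png_dir"

    frames: list[np.ndarray] = []
    if format in ("png_dir", "avi_frames"):
        if not path.is_dir():
            raise MissingPathError(f"{format} expects a directory: {path}")
        files = _frame_files(path)
        if not files:
            raise ZeroFramesError(f"zero frames in {path}")
        for f in files:
            try:
                frames.append(np.asarray(iio.imread(f)))
            except Exception as exc:   # plugin backends raise mixed types
                raise UnreadableFrameError(f"cannot decode {f}: {exc}") from exc
    elif format == "tiff_stack":
        if not path.is_file():
            raise MissingPathError(f"tiff_stack expects a file: {path}")
        try:
            stack = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise UnreadableFrameError(f"cannot decode {path}: {exc}") from exc
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.size == 0:
            raise ZeroFramesError(f"zero frames in {path}")
        frames = list(stack)
    else:
        raise ValueError(f"unknown stack format {format!r}")

    shapes = {f.shape[:2] for f in frames}
    if len(shapes) > 1:
        raise FrameShapeMismatchError(f"inconsistent frame dimensions: {sorted(shapes)}")

    grids = [
        to_grayscale(
            f,
            axial_pitch=axial_pitch,
            lateral_pitch=lateral_pitch,
            pixel_area=pixel_area,
        )
        for f in frames
    ]
    return ScanSession(
        eye_id=eye_id, bscans=grids,
        laterality=laterality, group=group, week=week,
    )


def save_bscan_stack(session: ScanSession, path: str | Path, format: str = "tiff_stack") -> Path:
    """Write a session losslessly (float64 TIFF pages or per-frame TIFFs).

    The inverse of :func:`load_bscan_stack` for synthetic sessions;
    round-trips pixel values exactly.
    """
    path = Path(path)
    stack = np.stack([g.pixels for g in session.bscans])
    if format == "tiff_stack":
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, stack)
        meta_path = path.with_suffix(".json")
    elif format in ("png_dir", "avi_frames"):
        # PNG cannot hold floats; store frame files as TIFF inside the dir
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack):
            tifffile.imwrite(path / f"frame_{i:04d}.tif", frame)
        meta_path = path / "session.json"
    else:
        raise ValueError(f"unknown stack format {format!r}")
    meta_path.write_text(json.dumps(session.metadata(), indent=1))
    return path


def write_results(results: Sequence[EyeTimepointResult], path: str | Path,
                  header_comment: str | None = None) -> Path:
    """Write per-eye-per-week results as a TSV with a fixed column order.

    Numeric values survive a write/read round trip to 6 significant digits.
    An optional ``# comment`` line (e.g. config hash + calibration mode) is
    placed above the header.
    """
    path = Path(path)
    cols = list(EyeTimepointResult.COLUMNS)
    rows = [{c: getattr(r, c) for c in cols} for r in results]
    df = pd.DataFrame(rows, columns=cols)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    return path


def read_results(path: str | Path) -> list[EyeTimepointResult]:
    """Read a TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for rec in df.to_dict("records"):
        rec["n_bscans"] = int(rec["n_bscans"])
        rec["n_rejected"] = int(rec["n_rejected"])
        rec["aggregate_count"] = int(rec["aggregate_count"])
        out.append(EyeTimepointResult(**rec))
    return out
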