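"""Reading and writing of contrast image sequences, ROI masks, configs and result tables.

The canonical on-disk form of a sequence is a multi-page TIFF next to a JSON
sidecar carrying the acquisition metadata (frame rate, pixel spacing, intensity
scale).  DICOM cine loops (multi-frame files or a directory of single-frame
instances) are supported read-only.  Log-compressed video intensities are
linearized with an amplitude (20*log10) mapping normalized so that the maximum
code maps to 1.0; the convention is recorded in the output metadata so results
stay auditable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for per-fit result rows
FIT_COLUMNS = [
    "subject", "roi", "phase", "A", "beta", "y0", "sse", "r2",
    "n_samples", "converged", "reason",
]


@dataclass(frozen=True)
class LogCompression:
    """Parameters of a logarithmic (dB) intensity compression.

    ``code = max_code * (1 + (20/dynamic_range) * log10(v / linear_ref))``,
    clipped to ``[0, max_code]``.  ``linear_ref`` is the linear intensity that
    maps to ``max_code`` (full scale).
    """

    dynamic_range: float  # dB
    max_code: float
    linear_ref: float | None = None

    def __post_init__(self) -> None:
        if self.dynamic_range <= 0:
            raise ValueError("dynamic_range must be positive (dB)")
        if self.max_code <= 0:
            raise ValueError("max_code must be positive")


@dataclass
class FrameSequence:
    """A time-ordered stack of 2D intensity frames with acquisition metadata.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, rows, cols)
        Pixel intensities in acquisition order.
    frame_rate : float
        Frames per second (Hz).
    pixel_spacing : (float, float)
        Physical size of one pixel, (row, col), in mm.
    acquisition_start : float
        Time of the first frame in seconds.
    compression : LogCompression or None
        ``None`` means the intensities are on the linear scale.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_spacing: tuple[float, float] = (0.1, 0.1)
    acquisition_start: float = 0.0
    compression: LogCompression | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (time, rows, cols) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.is_linear and self.frames.size and self.frames.min() < 0:
            raise ValueError("linear-scale intensities must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def is_linear(self) -> bool:
        return self.compression is None

    @property
    def intensity_scale(self) -> str:
        return "linear" if self.is_linear else "log_compressed"

    @property
    def times(self) -> np.ndarray:
        """Frame time stamps in seconds; frame i at start + i/frame_rate."""
        return self.acquisition_start + np.arange(self.n_frames) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    def copy(self) -> "FrameSequence":
        return FrameSequence(
            frames=self.frames.copy(),
            frame_rate=self.frame_rate,
            pixel_spacing=tuple(self.pixel_spacing),
            acquisition_start=self.acquisition_start,
            compression=self.compression,
        )


class RegionMaskSet(Mapping):
    """Named binary ROI masks sharing one frame shape.

    Reserved labels ``treated``, ``control`` and ``background`` carry the
    treated focal zone, the non-treated reference region and an optional
    background ROI used for signal subtraction.
    """

    def __init__(self, masks: Mapping[str, np.ndarray]):
        if not masks:
            raise ValueError("mask set must not be empty")
        self._masks: dict[str, np.ndarray] = {}
        shape = None
        for label, mask in masks.items():
            arr = np.asarray(mask).astype(bool)
            if arr.ndim != 2:
                raise ValueError(f"mask {label!r} must be 2D")
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"mask {label!r} shape {arr.shape} != {shape}"
                )
            self._masks[str(label)] = arr
        self.frame_shape = shape

    def __getitem__(self, label: str) -> np.ndarray:
        return self._masks[label]

    def __iter__(self):
        return iter(self._masks)

    def __len__(self) -> int:
        return len(self._masks)

    def require(self, label: str) -> np.ndarray:
        """Return a mask, insisting it exists and is nonempty."""
        if label not in self._masks:
            raise KeyError(
                f"unknown ROI label {label!r}; have {sorted(self._masks)}"
            )
        mask = self._masks[label]
        if not mask.any():
            raise ValueError(f"ROI {label!r} is empty")
        return mask


# ---------------------------------------------------------------------------
# sequence read/write


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a sequence as multi-page TIFF + JSON sidecar; returns the TIFF path."""
    import tifffile

    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        path = path.with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames)
    meta = {
        "frame_rate": seq.frame_rate,
        "acquisition_start": seq.acquisition_start,
        "pixel_spacing": list(seq.pixel_spacing),
        "intensity_scale": seq.intensity_scale,
    }
    if seq.compression is not None:
        meta["compression"] = dataclasses.asdict(seq.compression)
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _read_tiff_sequence(path: Path) -> FrameSequence:
    import tifffile

    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"metadata sidecar missing: {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "frame_rate" not in meta:
        raise ValueError(f"frame_rate missing from sidecar {sidecar}")
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    compression = None
    if meta.get("intensity_scale") == "log_compressed":
        comp = meta.get("compression")
        if comp is None or "dynamic_range" not in comp:
            raise ValueError("log_compressed sequence lacks dynamic_range metadata")
        compression = LogCompression(**comp)
    return FrameSequence(
        frames=frames,
        frame_rate=float(meta["frame_rate"]),
        pixel_spacing=tuple(meta.get("pixel_spacing", (0.1, 0.1))),
        acquisition_start=float(meta.get("acquisition_start", 0.0)),
        compression=compression,
    )


def _dicom_frame_rate(ds) -> float:
    """Frame rate (Hz) from cine attributes; hard error when absent."""
    ft = getattr(ds, "FrameTime", None)  # ms per frame
    if ft:
        return 1000.0 / float(ft)
    for attr in ("CineRate", "RecommendedDisplayFrameRate"):
        val = getattr(ds, attr, None)
        if val:
            return float(val)
    raise ValueError(
        "frame_rate missing: DICOM has none of FrameTime, CineRate, "
        "RecommendedDisplayFrameRate"
    )


def _dicom_spacing(ds) -> tuple[float, float]:
    sp = getattr(ds, "PixelSpacing", None)
    if sp is not None and len(sp) == 2:
        return float(sp[0]), float(sp[1])
    return (0.1, 0.1)


def _read_dicom_multiframe(path: Path) -> FrameSequence:
    import pydicom

    ds = pydicom.dcmread(path)
    frames = np.asarray(ds.pixel_array, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameSequence(
        frames=frames,
        frame_rate=_dicom_frame_rate(ds),
        pixel_spacing=_dicom_spacing(ds),
    )


def _read_dicom_series(path: Path) -> FrameSequence:
    """Directory of single-frame instances, ordered by InstanceNumber."""
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(p) for p in files]
    order = [int(getattr(ds, "InstanceNumber", i)) for i, ds in enumerate(datasets)]
    datasets = [ds for _, ds in sorted(zip(order, datasets), key=lambda t: t[0])]
    frames = [np.asarray(ds.pixel_array, dtype=np.float64) for ds in datasets]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"mixed frame shapes in DICOM series: {sorted(shapes)}")
    return FrameSequence(
        frames=np.stack(frames),
        frame_rate=_dicom_frame_rate(datasets[0]),
        pixel_spacing=_dicom_spacing(datasets[0]),
    )


def read_sequence(path: str | Path) -> FrameSequence:
    """Read a sequence from TIFF+sidecar, a multi-frame DICOM file, or a DICOM directory.

    Pixel values are returned untransformed; the intensity scale is recorded in
    the metadata, not applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        return _read_dicom_series(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return _read_tiff_sequence(path)
    return _read_dicom_multiframe(path)


# ---------------------------------------------------------------------------
# log-compression


def compress(
    seq: FrameSequence,
    dynamic_range: float = 60.0,
    max_code: float = 255.0,
    linear_ref: float | None = None,
) -> FrameSequence:
    """Log-compress a linear-scale sequence.

    ``linear_ref`` (the intensity mapping to full scale) defaults to the
    sequence maximum.  Codes are kept as floats; intensities below the dynamic
    range floor clip to code 0.
    """
    if not seq.is_linear:
        raise ValueError("sequence is already log-compressed")
    ref = float(seq.frames.max()) if linear_ref is None else float(linear_ref)
    if ref <= 0:
        raise ValueError("linear_ref must be positive")
    with np.errstate(divide="ignore"):
        codes = max_code * (1.0 + (20.0 / dynamic_range) * np.log10(seq.frames / ref))
    codes = np.clip(codes, 0.0, max_code)
    return FrameSequence(
        frames=codes,
        frame_rate=seq.frame_rate,
        pixel_spacing=tuple(seq.pixel_spacing),
        acquisition_start=seq.acquisition_start,
        compression=LogCompression(dynamic_range, max_code, linear_ref=ref),
    )


def linearize(seq: FrameSequence, restore_scale: bool = False) -> FrameSequence:
    """Invert log compression: ``v_lin = 10**((v/max_code - 1) * DR/20)``.

    The output is normalized so ``max_code`` maps to 1.0.  With
    ``restore_scale=True`` and a recorded ``linear_ref`` the original linear
    units are restored instead.  Idempotent on already-linear input (returns a
    copy and logs a no-op).
    """
    if seq.is_linear:
        logger.info("linearize: sequence already linear; no-op")
        return seq.copy()
    comp = seq.compression
    v_lin = 10.0 ** ((seq.frames / comp.max_code - 1.0) * comp.dynamic_range / 20.0)
    if restore_scale:
        if comp.linear_ref is None:
            raise ValueError("no linear_ref recorded; cannot restore absolute scale")
        v_lin = v_lin * comp.linear_ref
    return FrameSequence(
        frames=v_lin,
        frame_rate=seq.frame_rate,
        pixel_spacing=tuple(seq.pixel_spacing),
        acquisition_start=seq.acquisition_start,
        compression=None,
    )


# ---------------------------------------------------------------------------
# masks


def write_masks(masks: RegionMaskSet, path: str | Path) -> Path:
    """Write masks as an 8-bit label image (+ JSON label map). PNG or TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    label_img = np.zeros(masks.frame_shape, dtype=np.uint8)
    label_map: dict[str, int] = {}
    for value, (label, mask) in enumerate(masks.items(), start=1):
        if np.any(label_img[mask]):
            raise ValueError("overlapping masks cannot be stored as a label image")
        label_img[mask] = value
        label_map[label] = value
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, label_img)
    else:
        import imageio.v3 as iio

        iio.imwrite(path, label_img)
    path.with_suffix(".json").write_text(json.dumps(label_map, indent=2))
    return path


def read_masks(path: str | Path) -> RegionMaskSet:
    path = Path(path)
    map_path = path.with_suffix(".json")
    if not map_path.exists():
        raise FileNotFoundError(f"label map missing: {map_path}")
    label_map = json.loads(map_path.read_text())
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        label_img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        label_img = iio.imread(path)
    return RegionMaskSet({label: label_img == value for label, value in label_map.items()})


# ---------------------------------------------------------------------------
# result tables


def _as_record(rec) -> dict:
    if dataclasses.is_dataclass(rec) and not isinstance(rec, type):
        return dataclasses.asdict(rec)
    return dict(rec)


def write_results(records, path: str | Path, columns: list[str] | None = None) -> Path:
    """Write result records as CSV with a JSON mirror; one row per record.

    An empty record list produces a header-only CSV using ``columns`` (default:
    the per-fit result columns).
    """
    path = Path(path)
    if path.suffix.lower() != ".csv":
        path = path.with_suffix(".csv")
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [_as_record(r) for r in records]
    if rows:
        df = pd.DataFrame(rows)
    else:
        df = pd.DataFrame(columns=columns or FIT_COLUMNS)
    df.to_csv(path, index=False)
    path.with_suffix(".json").write_text(df.to_json(orient="records", indent=2))
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# configs


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration mapping."""
    import yaml

    path = Path(path)
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a mapping")
    return data


def save_config(config: dict, path: str | Path) -> Path:
    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config, sort_keys=False))
    return path
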