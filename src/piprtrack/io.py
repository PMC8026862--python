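"""File I/O: videos and frame directories, trace CSVs, config files.

The preferred fixture format is a directory of losslessly compressed frames
(PNG/TIFF) so that pixel-exact round trips are possible; multi-page TIFF
stacks and any container imageio can decode are also accepted (lossy codecs
round-trip only to codec tolerance).
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import FrameSequence, InvalidParameterError, PupilTrace, TraceFormatError
from .defaults import FRAME_RATE_HZ, RunConfig

__all__ = [
    "read_video",
    "write_video",
    "write_trace",
    "read_trace",
    "write_truth",
    "load_config",
    "dump_config",
    "load_manifest",
]

_IMAGE_EXTS = (".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp")

# Rec.601 luminance weights for colour -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])

TRACE_COLUMNS = [
    "frame",
    "time_s",
    "diameter_px",
    "diameter_mm",
    "center_x_px",
    "center_y_px",
    "measurement_used",
    "blink_flag",
]
_TRACE_HEADER = "# piprtrack-trace v1"


def _to_gray01(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame)
    if frame.ndim == 3:
        frame = frame[..., :3] @ _LUMA
    if np.issubdtype(frame.dtype, np.integer):
        frame = frame.astype(float) / np.iinfo(frame.dtype).max
    return np.clip(frame.astype(float), 0.0, 1.0)


def read_video(path: str | Path, frame_rate_hz: float | None = None) -> FrameSequence:
    """Read a frame directory, TIFF stack or video file as grayscale [0,1].

    ``frame_rate_hz`` overrides (or supplies, for frame directories) the
    sampling rate; the default is the protocol's 30 fps.
    """
    path = Path(path)
    fps = frame_rate_hz or FRAME_RATE_HZ
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not files:
            raise OSError(f"no image frames found in directory {path}")
        frames = [_to_gray01(iio.imread(f)) for f in files]
    elif path.suffix.lower() in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        frames = [_to_gray01(f) for f in stack]
    elif path.exists():
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # unreadable container
            raise OSError(f"cannot decode video {path}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = [_to_gray01(f) for f in raw]
    else:
        raise OSError(f"no such video or frame directory: {path}")
    if len(frames) == 0:
        raise OSError(f"zero frames decoded from {path}")
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise InvalidParameterError(f"frames differ in size: {sorted(shapes)}")
    return FrameSequence.from_frames(np.stack(frames), fps)


def write_video(frames: FrameSequence, path: str | Path) -> None:
    """Write frames losslessly: a PNG directory, or a TIFF stack if the
    path ends in .tif/.tiff.  Intensities are quantised to 16-bit."""
    path = Path(path)
    data = np.clip(frames.frames, 0.0, 1.0)
    u16 = np.round(data * np.iinfo(np.uint16).max).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, u16, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(u16):
            iio.imwrite(path / f"frame_{i:05d}.png", frame)


def write_trace(trace: PupilTrace, path: str | Path) -> None:
    """Serialize a trace as versioned CSV (floats at 12 significant digits)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cal = trace.calibration_px_per_mm
    df = pd.DataFrame(
        {
            "frame": np.arange(len(trace)),
            "time_s": trace.times_s,
            "diameter_px": trace.diameter_px,
            "diameter_mm": trace.diameter_mm if cal is not None
            else np.full(len(trace), np.nan),
            "center_x_px": trace.center_x_px,
            "center_y_px": trace.center_y_px,
            "measurement_used": trace.measurement_used.astype(int),
            "blink_flag": trace.blink_flag.astype(int),
        }
    )
    buf = _stdio.StringIO()
    cal_str = f"{cal:.12g}" if cal is not None else "none"
    buf.write(f"{_TRACE_HEADER} px_per_mm={cal_str}\n")
    df.to_csv(buf, index=False, float_format="%.12g")
    path.write_text(buf.getvalue())


def read_trace(path: str | Path) -> PupilTrace:
    """Read a trace CSV written by :func:`write_trace`.

    Columns are matched by header name, so column order is free; a missing
    column raises :class:`TraceFormatError` naming it.
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.exists() else ""
    cal: float | None = None
    if first.startswith(_TRACE_HEADER):
        tag = first.split("px_per_mm=")[-1].strip()
        cal = None if tag == "none" else float(tag)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"trace file {path} missing column(s): {missing}")
    return PupilTrace(
        times_s=df["time_s"].to_numpy(float),
        diameter_px=df["diameter_px"].to_numpy(float),
        center_x_px=df["center_x_px"].to_numpy(float),
        center_y_px=df["center_y_px"].to_numpy(float),
        measurement_used=df["measurement_used"].to_numpy(bool),
        blink_flag=df["blink_flag"].to_numpy(bool),
        calibration_px_per_mm=cal,
    )


def write_truth(times_s, diameter_mm, blink, path: str | Path) -> None:
    """Ground-truth CSV for a simulated trial: time_s, diameter_mm, blink."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "time_s": np.asarray(times_s, float),
            "diameter_mm": np.asarray(diameter_mm, float),
            "blink": np.asarray(blink).astype(int),
        }
    ).to_csv(path, index=False, float_format="%.12g")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration (missing path -> defaults)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def load_manifest(path: str | Path):
    """Read a cohort manifest CSV into SubjectRecords.

    One row per trial with columns: subject_id, group, age_years, ledd_mg,
    hy_grade, wavelength_nm, power_uw, onset_s, offset_s, trace_path
    (relative paths resolved against the manifest's directory).
    """
    from .stats import StimulusMeta, SubjectRecord, Trial

    path = Path(path)
    df = pd.read_csv(path)
    required = [
        "subject_id", "group", "wavelength_nm", "power_uw",
        "onset_s", "offset_s", "trace_path",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TraceFormatError(f"manifest missing column(s): {missing}")
    subjects: dict[str, SubjectRecord] = {}
    for _, row in df.iterrows():
        sid = str(row["subject_id"])
        if sid not in subjects:
            def _opt(col):
                v = row.get(col)
                return None if v is None or pd.isna(v) else float(v)

            subjects[sid] = SubjectRecord(
                subject_id=sid,
                group=str(row["group"]),
                trials=[],
                age_years=_opt("age_years"),
                ledd_mg=_opt("ledd_mg"),
                hy_grade=_opt("hy_grade"),
            )
        trace_path = Path(row["trace_path"])
        if not trace_path.is_absolute():
            trace_path = path.parent / trace_path
        subjects[sid].trials.append(
            Trial(
                trace=read_trace(trace_path),
                stim=StimulusMeta(
                    wavelength_nm=float(row["wavelength_nm"]),
                    power_uw=float(row["power_uw"]),
                    stim_onset_s=float(row["onset_s"]),
                    stim_offset_s=float(row["offset_s"]),
                ),
            )
        )
    return list(subjects.values())
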