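"""Extraction of mean-gray-value time signals from video frame stacks.

A beating-tissue video is reduced to a 1-D signal by averaging all pixel
gray values of each frame (optionally restricted to a rectangular ROI).
Contractions appear as downward dips on a bright baseline because
contracting tissue absorbs more light.  The signal keeps full floating
point precision; only the source pixels are 8-bit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FrameStack",
    "GrayTrace",
    "rgb_to_gray8",
    "mean_gray_per_frame",
    "read_trace_csv",
    "write_trace_csv",
    "read_frame_dir",
    "read_avi",
]


@dataclass
class FrameStack:
    """An ordered stack of 2-D 8-bit grayscale frames.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width), uint8
        Pixel gray values in [0, 255].
    frame_rate : float
        Acquisition rate in frames per second.
    roi : tuple (row0, col0, height, width), optional
        0-based, half-open rectangle to which averaging is restricted.
    """

    frames: np.ndarray
    frame_rate: float
    roi: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (n, h, w) array, got ndim={self.frames.ndim}"
            )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.roi is not None:
            r0, c0, h, w = self.roi
            nh, nw = self.frames.shape[1:]
            if r0 < 0 or c0 < 0 or h <= 0 or w <= 0 or r0 + h > nh or c0 + w > nw:
                raise ValueError(f"roi {self.roi} outside frame bounds {(nh, nw)}")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class GrayTrace:
    """A uniformly sampled mean-gray-value signal.

    ``values`` are dimensionless gray values in [0, 255] (floating point),
    ``sample_rate`` is in Hz.  ``meta`` carries free-form provenance tags.
    """

    values: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("trace must be a non-empty 1-D sequence")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 255:
            raise ValueError("gray values must lie in [0, 255]")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.values.size) / self.sample_rate


def rgb_to_gray8(frame: np.ndarray) -> np.ndarray:
    """Convert a 3-channel 8-bit frame to single-channel 8-bit gray.

    The camera used for these recordings is monochrome but stores RGB with
    (near-)identical channels, so the unweighted channel mean is used, not
    luminance weights.  The mean is rounded half up and clipped to [0, 255];
    identical-channel input therefore returns that channel unchanged.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected a (h, w, 3) array, got shape {frame.shape}")
    mean = frame.astype(np.float64).mean(axis=2)
    return np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)


def mean_gray_per_frame(stack: FrameStack) -> GrayTrace:
    """Average all (ROI) pixels of each frame into one gray value per frame.

    Returns a trace of the same length as the stack; value *i* is the
    arithmetic mean of the ROI pixels of frame *i*, kept in floating point.
    """
    if len(stack) == 0:
        raise ValueError("empty frame stack")
    frames = stack.frames
    if stack.roi is not None:
        r0, c0, h, w = stack.roi
        frames = frames[:, r0 : r0 + h, c0 : c0 + w]
    values = frames.astype(np.float64).mean(axis=(1, 2))
    return GrayTrace(values, stack.frame_rate, meta={"source": "frames"})


_RATE_RE = re.compile(r"#\s*sample_rate_hz\s*=\s*([0-9eE+.\-]+)")


def write_trace_csv(trace: GrayTrace, path: str | Path) -> None:
    """Write a trace as a one-column CSV with a sample-rate header comment."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz={trace.sample_rate!r}\n")
        fh.write("value\n")
        for v in trace.values:
            fh.write(f"{float(v)!r}\n")


def read_trace_csv(path: str | Path, sample_rate: Optional[float] = None) -> GrayTrace:
    """Read a trace written by :func:`write_trace_csv`.

    The sample rate is taken from the ``# sample_rate_hz=...`` header line
    unless overridden.  Values round-trip at full float precision.  Rows
    that do not parse as numbers raise with the offending line number;
    locale-style comma decimals are rejected explicitly.
    """
    path = Path(path)
    values: list[float] = []
    rate = sample_rate
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _RATE_RE.match(line)
                if m and rate is None:
                    rate = float(m.group(1))
                continue
            if line.lower() == "value":
                continue
            if "," in line:
                raise ValueError(
                    f"{path}:{lineno}: comma found ({line!r}); this reader expects "
                    "a single dot-decimal column, not comma decimals or multiple fields"
                )
            try:
                values.append(float(line))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from None
    if not values:
        raise ValueError(f"{path}: empty trace (header only or no rows)")
    if rate is None:
        raise ValueError(f"{path}: no '# sample_rate_hz=' header and no rate given")
    return GrayTrace(np.asarray(values), rate, meta={"source": str(path)})


def _numeric_key(p: Path) -> tuple:
    m = re.search(r"(\d+)", p.stem)
    return (int(m.group(1)) if m else -1, p.name)


def read_frame_dir(
    path: str | Path,
    frame_rate: float,
    roi: Optional[tuple[int, int, int, int]] = None,
    pattern: str = "*",
) -> FrameStack:
    """Load a directory of TIFF/PNG frames (zero-padded numeric names) as a stack."""
    import imageio.v3 as iio

    path = Path(path)
    files = sorted(
        (p for p in path.glob(pattern) if p.suffix.lower() in {".tif", ".tiff", ".png"}),
        key=_numeric_key,
    )
    if not files:
        raise FileNotFoundError(f"no TIFF/PNG frames under {path}")
    frames = []
    for p in files:
        img = np.asarray(iio.imread(p))
        if img.ndim == 3:
            img = rgb_to_gray8(img)
        frames.append(img.astype(np.uint8))
    return FrameStack(np.stack(frames), frame_rate, roi=roi)


def read_avi(path: str | Path, frame_rate: float, **kwargs) -> FrameStack:
    """Optional AVI ingest; requires an imageio ffmpeg backend.

    The canonical inputs are frame directories or trace CSVs; this reader is
    a convenience and raises a clear error when no codec backend is present.
    """
    try:
        import imageio.v3 as iio

        frames = [
            f if f.ndim == 2 else rgb_to_gray8(f)
            for f in iio.imiter(Path(path), plugin="pyav")
        ]
    except Exception as exc:  # pragma: no cover - backend-dependent
        raise RuntimeError(
            "AVI reading needs an imageio video backend (pyav/ffmpeg); "
            "convert the video to a frame directory or a trace CSV instead"
        ) from exc
    return FrameStack(np.stack(frames).astype(np.uint8), frame_rate, **kwargs)
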