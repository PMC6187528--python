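"""Image-sequence and results I/O.

All file-format handling for the rotation-analysis pipeline lives here:
reading grayscale image sequences (multi-page TIFF, numbered PNG/TIFF frame
directories or globs), writing sequences back out, and persisting rotation
estimates as CSV with a JSON configuration sidecar.
"""

from __future__ import annotations

import glob as _glob
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageSequence",
    "read_sequence",
    "write_sequence",
    "write_rotation_results",
    "read_rotation_results",
]

# Rec. 601 luma weights for RGB -> grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class ImageSequence:
    """An ordered stack of 2D grayscale frames plus frame-rate metadata.

    Frames are float64 arrays with intensities in [0, 1]; all frames share
    one height x width. ``fps`` is the camera sampling rate in frames per
    second and is always user-supplied, never inferred from files.
    """

    frames: np.ndarray  # (n, h, w) float64 in [0, 1]
    fps: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, h, w) stack, got shape {self.frames.shape}"
            )
        if self.fps is not None and self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, k: int) -> np.ndarray:
        return self.frames[k]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def usable_for_flow(self) -> bool:
        """Motion analysis needs at least two frames."""
        return len(self) >= 2


def _natural_key(name: str) -> list:
    """Sort key splitting digit runs so frame2 < frame10."""
    return [int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name)]


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an image array to float64 grayscale in [0, 1].

    Integer inputs are divided by their dtype maximum (255, 65535, ...),
    never min-max scaled per frame, so that relative brightness between
    frames is preserved. RGB(A) inputs are reduced with Rec. 601 luma
    weights. Float inputs are assumed to already be on [0, 1] and are
    clipped.
    """
    a = np.asarray(img)
    if a.ndim == 3:
        if a.shape[-1] in (3, 4):
            a = a[..., :3] @ _LUMA if np.issubdtype(a.dtype, np.floating) else (
                a[..., :3].astype(np.float64) @ _LUMA
            )
        else:
            raise ValueError(f"cannot interpret image of shape {np.asarray(img).shape}")
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        scale = float(np.iinfo(np.asarray(img).dtype).max)
        return np.asarray(a, dtype=np.float64) / scale
    return np.clip(np.asarray(a, dtype=np.float64), 0.0, 1.0)


def _frames_from_paths(paths: Sequence[str]) -> list[np.ndarray]:
    out = []
    for p in paths:
        if Path(p).suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(p)
        else:
            img = iio.imread(p)
        if img.ndim == 3 and img.shape[-1] not in (3, 4):
            # multi-page file inside a glob: take pages in order
            out.extend(to_grayscale(page) for page in img)
        else:
            out.append(to_grayscale(img))
    return out


def read_sequence(path_or_pattern: str | Path, fps: float | None = None) -> ImageSequence:
    """Read an image sequence from a multi-page TIFF, a directory of frames,
    or a glob of numbered PNG/TIFF files.

    Frames are ordered by TIFF page index or by natural-numeric filename
    sort (``frame2.png`` before ``frame10.png``). RGB inputs are converted
    to luminance, intensities scaled to [0, 1].

    Raises
    ------
    FileNotFoundError
        If the path resolves to nothing readable.
    ValueError
        If frames do not all share the same shape.
    """
    path = str(path_or_pattern)
    p = Path(path)
    if p.is_dir():
        paths = sorted(
            (str(f) for f in p.iterdir()
             if f.suffix.lower() in (".png", ".tif", ".tiff")),
            key=_natural_key,
        )
        if not paths:
            raise FileNotFoundError(f"no PNG/TIFF frames in directory {path}")
        frames = _frames_from_paths(paths)
    elif any(c in path for c in "*?["):
        paths = sorted(_glob.glob(path), key=_natural_key)
        if not paths:
            raise FileNotFoundError(f"glob {path!r} matched no files")
        frames = _frames_from_paths(paths)
    elif p.is_file():
        if p.suffix.lower() in (".tif", ".tiff"):
            stack = tifffile.imread(path)
            if stack.ndim == 2:
                frames = [to_grayscale(stack)]
            else:
                frames = [to_grayscale(page) for page in stack]
        else:
            frames = [to_grayscale(iio.imread(path))]
    else:
        raise FileNotFoundError(f"no such file, directory or glob: {path}")

    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent frame shapes in sequence: {sorted(shapes)}")
    return ImageSequence(np.stack(frames), fps=fps, source=path)


def write_sequence(seq: ImageSequence, path: str | Path) -> None:
    """Write a sequence as a float32 multi-page TIFF (``.tif``) or as
    numbered 16-bit PNG frames into a directory (any other path)."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(p), seq.frames.astype(np.float32),
                         photometric="minisblack")
    else:
        p.mkdir(parents=True, exist_ok=True)
        width = len(str(len(seq) - 1))
        for k in range(len(seq)):
            frame16 = np.round(np.clip(seq[k], 0, 1) * 65535).astype(np.uint16)
            iio.imwrite(str(p / f"frame{k:0{width}d}.png"), frame16)


def write_rotation_results(
    estimates: Iterable,
    path: str | Path,
    fps: float | None = None,
    config: dict | None = None,
) -> pd.DataFrame:
    """Persist per-frame-pair rotation estimates as CSV plus a JSON sidecar.

    Columns: frame_pair, axis_x/y/z, deg_per_frame, n_valid_pixels,
    residual, and — when ``fps`` is known — the derived rad_per_min and rpm.
    The JSON sidecar (``<path>.json``) echoes the analysis configuration.
    """
    from .sphere import to_angular_velocity

    estimates = list(estimates)
    if not estimates:
        raise ValueError("estimates must be nonempty")
    rows = []
    for k, est in enumerate(estimates):
        row = {
            "frame_pair": getattr(est, "frame_pair", f"{k}-{k + 1}"),
            "axis_x": est.axis[0],
            "axis_y": est.axis[1],
            "axis_z": est.axis[2],
            "deg_per_frame": est.deg_per_frame,
            "n_valid_pixels": est.n_valid_pixels,
            "residual": est.residual,
        }
        if fps is not None:
            rad_per_min, rpm = to_angular_velocity(est.deg_per_frame, fps)
            row["rad_per_min"] = rad_per_min
            row["rpm"] = rpm
        else:
            row["rad_per_min"] = np.nan
            row["rpm"] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = {"fps": fps, "n_estimates": len(estimates), "config": config or {}}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))
    return df


def read_rotation_results(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_rotation_results`."""
    return pd.read_csv(path)
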