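"""File round-trips: float TIFF, scaled 8/16-bit PNG, YOLO labels, detections."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "YoloRecord",
    "save_tiff",
    "load_tiff",
    "save_png",
    "load_png",
    "write_yolo",
    "read_yolo",
    "write_predictions",
    "read_predictions",
]


@dataclass(frozen=True)
class YoloRecord:
    """One labeled box: class index + center-form coordinates as frame fractions."""

    class_id: int
    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        tol = 1e-9
        for name in ("x_center", "y_center", "width", "height"):
            v = getattr(self, name)
            if not (0.0 - tol <= v <= 1.0 + tol):
                raise ValueError(f"{name} = {v} outside [0, 1]")
        if self.x_center - self.width / 2 < -tol or self.x_center + self.width / 2 > 1 + tol:
            raise ValueError("box extends past the left/right frame edge")
        if self.y_center - self.height / 2 < -tol or self.y_center + self.height / 2 > 1 + tol:
            raise ValueError("box extends past the top/bottom frame edge")

    def to_line(self) -> str:
        return (f"{self.class_id} {self.x_center:.6f} {self.y_center:.6f} "
                f"{self.width:.6f} {self.height:.6f}")

    @classmethod
    def from_line(cls, line: str) -> "YoloRecord":
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"expected 5 fields in YOLO line, got {len(parts)}: {line!r}")
        return cls(int(float(parts[0])), *(float(p) for p in parts[1:]))

    def corners(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) in frame fractions."""
        return (self.x_center - self.width / 2, self.y_center - self.height / 2,
                self.x_center + self.width / 2, self.y_center + self.height / 2)


def save_tiff(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a 2D map (real or the split complex parts) as 32-bit float TIFF."""
    arr = np.asarray(image)
    if np.iscomplexobj(arr):
        arr = np.stack([arr.real, arr.imag]).astype(np.float32)
    else:
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)


def load_tiff(path: str | os.PathLike) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 3 and arr.shape[0] == 2:
        return arr[0].astype(float) + 1j * arr[1].astype(float)
    return arr.astype(float)


def save_png(path: str | os.PathLike, image: np.ndarray, bit_depth: int = 16) -> float:
    """Write an intensity map as an 8- or 16-bit PNG, normalized by its maximum.

    Returns the scale factor (the pre-normalization maximum) so the caller
    can record it; the exported image always peaks at the full digital range.
    """
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = np.asarray(image, dtype=float)
    if np.any(arr < 0):
        raise ValueError("intensity map must be nonnegative for PNG export")
    peak = float(arr.max())
    norm = arr / peak if peak > 0 else arr
    top = 2**bit_depth - 1
    quant = np.round(norm * top)
    if bit_depth == 8:
        img = Image.fromarray(quant.astype(np.uint8), mode="L")
    else:
        img = Image.fromarray(quant.astype(np.uint16))
    img.save(str(path), format="PNG")
    return peak


def load_png(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale PNG back to floats in [0, 1]."""
    img = Image.open(str(path))
    arr = np.asarray(img, dtype=float)
    top = 65535.0 if img.mode in ("I;16", "I") else 255.0
    return arr / top


def write_yolo(path: str | os.PathLike, records: list[YoloRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


def read_yolo(path: str | os.PathLike) -> list[YoloRecord]:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                records.append(YoloRecord.from_line(line))
    return records


def write_predictions(path: str | os.PathLike, detections) -> None:
    """Write detections as 'class confidence xc yc w h' lines."""
    with open(path, "w") as fh:
        for det in detections:
            b = det.box
            fh.write(f"{det.class_id} {det.confidence:.6f} {b.x_center:.6f} "
                     f"{b.y_center:.6f} {b.width:.6f} {b.height:.6f}\n")


def read_predictions(path: str | os.PathLike):
    """Read 'class confidence xc yc w h' prediction lines."""
    from .detect_eval import Detection  # local import: avoid a cycle

    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(f"expected 6 fields in prediction line: {line!r}")
            cls = int(float(parts[0]))
            conf = float(parts[1])
            box = YoloRecord(cls, *(float(p) for p in parts[2:]))
            out.append(Detection(class_id=cls, box=box, confidence=conf))
    return out
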