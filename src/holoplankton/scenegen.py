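"""Procedural scene and dataset generation for hologram experiments.

Four visually distinct silhouette families stand in for real plankton
imagery: (0) an elongated body with a wiggly tail, (1) a radially
symmetric star, (2) a bell with hanging tentacles, and (3) a slender
curved rod.  Scenes place 5-10 of them (configurable) on an empty frame
with 90-degree rotations and flips, forbidding any overlap of their
silhouette supports, and record one bounding box per placement.

From each composed transmission object a four-frame hologram set is
synthesized; its two-step reconstruction becomes the training label.
Dataset builds are fully deterministic in the seed.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .gpsdh import HologramSet, two_step_reconstruct
from .io import YoloRecord, save_png, write_yolo
from .optics import (
    OpticalConfig,
    PlaneReference,
    TransmissionObject,
    fresnel_propagate,
    interfere,
    plane_wave,
    transmit,
)

__all__ = [
    "ShapeEntry",
    "ShapeBank",
    "Placement",
    "SceneSpec",
    "ScenePlacementError",
    "PROFILES",
    "profile_config",
    "make_shape",
    "make_shape_bank",
    "compose_scene",
    "synthesize_hologram_set",
    "split_indices",
    "build_dataset",
    "load_dataset",
]

N_CLASSES = 4

#: Transmission floor: fully opaque pixels are clipped here so the
#: absorption map -ln(t) stays finite.
T_FLOOR = 1e-3

#: Optical profiles.  "paper" mirrors the full-scale recording geometry
#: (512x512, 5 um pitch, 530 nm, z = 24 cm); "desk" is a reduced 64x64
#: geometry whose distance sits safely inside the alias-free range so
#: the whole pipeline runs in seconds.
PROFILES: dict[str, dict] = {
    "paper": {
        "config": dict(wavelength=530e-9, distance_z=0.24, pixel_pitch=5e-6,
                       grid_shape=(512, 512)),
        "count_range": (5, 10),
    },
    "desk": {
        "config": dict(wavelength=530e-9, distance_z=2.1e-3, pixel_pitch=5e-6,
                       grid_shape=(64, 64)),
        "count_range": (2, 4),
    },
    "desk128": {
        "config": dict(wavelength=530e-9, distance_z=4.3e-3, pixel_pitch=5e-6,
                       grid_shape=(128, 128)),
        "count_range": (3, 6),
    },
}


def profile_config(profile: str) -> OpticalConfig:
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    return OpticalConfig(**PROFILES[profile]["config"])


class ScenePlacementError(RuntimeError):
    """Could not place the minimum number of objects without overlap."""


@dataclass
class ShapeEntry:
    class_id: int
    mask: np.ndarray  # opacity in [0, 1], cropped to its support
    nominal_size: int


@dataclass
class ShapeBank:
    entries: list[ShapeEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.class_id not in range(N_CLASSES):
                raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {e.class_id}")
            if not np.any(e.mask > 0):
                raise ValueError("shape mask has empty support")

    def by_class(self, class_id: int) -> list[ShapeEntry]:
        return [e for e in self.entries if e.class_id == class_id]


@dataclass(frozen=True)
class Placement:
    entry_index: int
    class_id: int
    rotation_deg: int       # one of 0, 90, 180, 270
    flip: str               # one of "none", "horizontal", "vertical"
    top_left: tuple[int, int]  # (row, col)


@dataclass
class SceneSpec:
    placements: list[Placement]
    boxes: list[YoloRecord]
    frame_shape: tuple[int, int]
    seed: int


# ---------------------------------------------------------------------------
# silhouette families
# ---------------------------------------------------------------------------

def _tube(canvas: np.ndarray, pts: np.ndarray, width: float,
          strength: float = 1.0) -> None:
    """Stamp a soft tube of the given half-width along a polyline, in place.

    The width is floored at one pixel: sub-pixel strokes are below the
    resolving power of the small grids the shapes are stamped on.
    """
    width = max(width, 1.0)
    s = canvas.shape[0]
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    d2 = np.full((s, s), np.inf)
    for py, px in pts:
        d2 = np.minimum(d2, (yy - py) ** 2 + (xx - px) ** 2)
    np.maximum(canvas, strength * np.exp(-(d2 / width**2) ** 2), out=canvas)


def _ellipse(canvas: np.ndarray, cy: float, cx: float, ry: float, rx: float,
             strength: float = 1.0, hardness: float = 4.0) -> None:
    s = canvas.shape[0]
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    q = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    np.maximum(canvas, strength * np.exp(-(q**hardness)), out=canvas)


def _shape_elongated(s: int, rng: np.random.Generator) -> np.ndarray:
    m = np.zeros((s, s))
    c = s / 2.0
    body_ry = s * rng.uniform(0.10, 0.14)
    body_rx = s * rng.uniform(0.16, 0.22)
    _ellipse(m, c - s * 0.12, c, body_ry, body_rx)
    # wiggly tail trailing downward
    t = np.linspace(0, 1, 60)
    amp = s * rng.uniform(0.06, 0.12)
    freq = rng.uniform(1.5, 2.5)
    ys = (c - s * 0.12 + body_ry * 0.5) + t * s * 0.42
    xs = c + amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, np.pi))
    _tube(m, np.column_stack([ys, xs]), width=s * 0.035)
    return m


def _shape_radial(s: int, rng: np.random.Generator) -> np.ndarray:
    base = np.zeros((s, s))
    c = (s - 1) / 2.0
    n_arms_quadrant = rng.integers(1, 3)  # 4 or 8 arms after symmetrization
    for a in range(n_arms_quadrant):
        theta = rng.uniform(0, np.pi / 2) if n_arms_quadrant > 1 else rng.uniform(0.2, 1.3)
        length = s * rng.uniform(0.32, 0.44)
        t = np.linspace(0, 1, 40)
        ys = c + t * length * np.sin(theta)
        xs = c + t * length * np.cos(theta)
        _tube(base, np.column_stack([ys, xs]), width=s * rng.uniform(0.03, 0.05))
    _ellipse(base, c, c, s * 0.09, s * 0.09)
    # exact 4-fold symmetry by folding over the rotation group
    m = base
    for k in (1, 2, 3):
        m = np.maximum(m, np.rot90(base, k))
    return m


def _shape_bell(s: int, rng: np.random.Generator) -> np.ndarray:
    m = np.zeros((s, s))
    c = s / 2.0
    bell_ry = s * rng.uniform(0.13, 0.17)
    bell_rx = s * rng.uniform(0.20, 0.27)
    cy = c - s * 0.18
    _ellipse(m, cy, c, bell_ry, bell_rx)
    m[int(cy) + int(bell_ry * 0.6):, :] *= 0.0  # open the bell underside
    _ellipse(m, cy, c, bell_ry * 0.6, bell_rx * 0.95)
    n_tent = rng.integers(3, 6)
    for i in range(n_tent):
        x0 = c + bell_rx * np.linspace(-0.7, 0.7, n_tent)[i]
        t = np.linspace(0, 1, 50)
        amp = s * rng.uniform(0.02, 0.05)
        ys = cy + bell_ry * 0.5 + t * s * rng.uniform(0.30, 0.42)
        xs = x0 + amp * np.sin(2 * np.pi * rng.uniform(1.0, 2.0) * t)
        _tube(m, np.column_stack([ys, xs]), width=s * 0.02, strength=0.9)
    return m


def _shape_rod(s: int, rng: np.random.Generator) -> np.ndarray:
    m = np.zeros((s, s))
    c = s / 2.0
    t = np.linspace(-1, 1, 80)
    length = s * rng.uniform(0.38, 0.47)
    bow = s * rng.uniform(0.02, 0.08)
    ys = c + bow * (t**2 - 0.5)
    xs = c + t * length
    _tube(m, np.column_stack([ys, xs]), width=s * rng.uniform(0.025, 0.045))
    return m


_FAMILIES = {0: _shape_elongated, 1: _shape_radial, 2: _shape_bell, 3: _shape_rod}


def make_shape(class_id: int, rng: np.random.Generator,
               size: int = 32) -> ShapeEntry:
    """Generate one silhouette of the given family on a ``size`` px canvas.

    The opacity mask lies in [0, 1], has a single connected support
    component, and is cropped to its support.  Deterministic given
    (class_id, size, rng state).
    """
    if class_id not in _FAMILIES:
        raise ValueError(f"class_id must be in 0..{N_CLASSES - 1}, got {class_id}")
    m = _FAMILIES[class_id](size, rng)
    m = np.clip(m, 0.0, 1.0)
    m[m < 0.08] = 0.0
    # keep only the largest connected component (tails occasionally detach)
    labels, n = ndimage.label(m > 0)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(m), labels, index=range(1, n + 1))
        m[labels != (1 + int(np.argmax(sizes)))] = 0.0
    rows = np.any(m > 0, axis=1)
    cols = np.any(m > 0, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    return ShapeEntry(class_id=class_id, mask=m[r0:r1, c0:c1], nominal_size=size)


def make_shape_bank(rng: np.random.Generator, per_class: int = 3,
                    size: int = 32) -> ShapeBank:
    """A bank with ``per_class`` variants of each of the four families."""
    entries = [make_shape(cid, rng, size=size)
               for cid in range(N_CLASSES) for _ in range(per_class)]
    return ShapeBank(entries)


# ---------------------------------------------------------------------------
# scene composition
# ---------------------------------------------------------------------------

_FLIPS = ("none", "horizontal", "vertical")


def _transform_mask(mask: np.ndarray, rotation_deg: int, flip: str) -> np.ndarray:
    out = np.rot90(mask, rotation_deg // 90)
    if flip == "horizontal":
        out = out[:, ::-1]
    elif flip == "vertical":
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def _support_box(mask: np.ndarray, top: int, left: int,
                 frame_shape: tuple[int, int]) -> YoloRecord:
    """Tight box around the placed support, as a normalized center-form record."""
    rows = np.any(mask > 0, axis=1)
    cols = np.any(mask > 0, axis=0)
    r0 = top + int(np.argmax(rows))
    r1 = top + len(rows) - int(np.argmax(rows[::-1]))
    c0 = left + int(np.argmax(cols))
    c1 = left + len(cols) - int(np.argmax(cols[::-1]))
    R, C = frame_shape
    return YoloRecord(
        class_id=-1,  # caller overwrites
        x_center=(c0 + c1) / 2.0 / C,
        y_center=(r0 + r1) / 2.0 / R,
        width=(c1 - c0) / C,
        height=(r1 - r0) / R,
    )


def compose_scene(bank: ShapeBank, rng: np.random.Generator,
                  frame_shape: tuple[int, int] = (512, 512),
                  count_range: tuple[int, int] = (5, 10),
                  max_attempts: int = 200,
                  ) -> tuple[TransmissionObject, SceneSpec]:
    """Place silhouettes on an empty frame with pairwise-disjoint supports.

    Each placement draws a bank entry, a 90-degree rotation, and a flip at
    random, then rejection-samples a position.  After ``max_attempts``
    failures the target count is reduced by one; dropping below the
    minimum raises :class:`ScenePlacementError`.
    """
    if not bank.entries:
        raise ValueError("shape bank is empty")
    lo, hi = count_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid count_range {count_range}")
    target = int(rng.integers(lo, hi + 1))
    R, C = frame_shape
    opacity = np.zeros(frame_shape)
    occupied = np.zeros(frame_shape, dtype=bool)
    placements: list[Placement] = []
    boxes: list[YoloRecord] = []
    seed_marker = int(rng.integers(0, 2**31 - 1))

    while len(placements) < target:
        placed = False
        for _ in range(max_attempts):
            idx = int(rng.integers(len(bank.entries)))
            entry = bank.entries[idx]
            rot = int(rng.integers(4)) * 90
            flip = _FLIPS[int(rng.integers(3))]
            mask = _transform_mask(entry.mask, rot, flip)
            h, w = mask.shape
            if h > R or w > C:
                continue
            top = int(rng.integers(0, R - h + 1))
            left = int(rng.integers(0, C - w + 1))
            sup = mask > 0
            if np.any(occupied[top:top + h, left:left + w] & sup):
                continue
            occupied[top:top + h, left:left + w] |= sup
            np.maximum(opacity[top:top + h, left:left + w], mask,
                       out=opacity[top:top + h, left:left + w])
            box = _support_box(mask, top, left, frame_shape)
            boxes.append(YoloRecord(entry.class_id, box.x_center, box.y_center,
                                    box.width, box.height))
            placements.append(Placement(idx, entry.class_id, rot, flip, (top, left)))
            placed = True
            break
        if not placed:
            target -= 1
            if target < lo:
                raise ScenePlacementError(
                    f"could not place the minimum of {lo} objects on a "
                    f"{frame_shape} frame without overlap"
                )

    transmission = np.clip(1.0 - opacity, T_FLOOR, 1.0)
    obj = TransmissionObject(absorption=-np.log(transmission))
    spec = SceneSpec(placements=placements, boxes=boxes,
                     frame_shape=frame_shape, seed=seed_marker)
    return obj, spec


# ---------------------------------------------------------------------------
# hologram synthesis and dataset assembly
# ---------------------------------------------------------------------------

def synthesize_hologram_set(obj: TransmissionObject, config: OpticalConfig,
                            delta: float = np.pi / 2,
                            A_r: float = 1.0) -> HologramSet:
    """Simulate the four raw intensity frames for one transmission object.

    The incident illumination is a unit plane wave.  The returned frames
    are unnormalized floats so the algebraic inversion stays exact;
    normalization by the maximum happens at image export and the scale
    factor is recorded alongside.
    """
    incident = plane_wave(config.grid_shape)
    exit_wave = transmit(obj, incident)
    recording = fresnel_propagate(exit_wave, config.distance_z, config)
    I1 = interfere(recording, PlaneReference(A_r, 0.0))
    I2 = interfere(recording, PlaneReference(A_r, delta))
    Io = recording.intensity
    Ir = np.full(config.grid_shape, A_r**2)
    return HologramSet(I1=I1, I2=I2, Io=Io, Ir=Ir, delta=float(delta))


def split_indices(n_scenes: int, split_ratio: float,
                  rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Deterministic shuffled train/test partition; train gets round(n*ratio)."""
    if n_scenes < 2:
        raise ValueError(f"need at least 2 scenes to split, got {n_scenes}")
    if not (0.0 < split_ratio < 1.0):
        raise ValueError(f"split_ratio must lie in (0, 1), got {split_ratio}")
    perm = rng.permutation(n_scenes)
    n_train = int(round(n_scenes * split_ratio))
    n_train = min(max(n_train, 1), n_scenes - 1)
    return sorted(int(i) for i in perm[:n_train]), sorted(int(i) for i in perm[n_train:])


def build_dataset(n_scenes: int, split_ratio: float, seed: int,
                  out_dir: str | os.PathLike, profile: str = "desk",
                  delta: float | str = np.pi / 2,
                  count_range: tuple[int, int] | None = None,
                  bank_size: int | None = None,
                  bit_depth: int = 16,
                  manifest_only: bool = False) -> dict:
    """Build a labeled hologram dataset on disk and return its manifest.

    Layout: ``images/*.png`` (max-normalized interferograms I1),
    ``targets/*.png`` (two-step reconstructions used as labels),
    ``labels/*.txt`` (YOLO records), and ``manifest.yaml``.  Identical
    seeds produce byte-identical trees.

    ``delta`` may be a fixed step in radians or ``"random"`` for a step
    drawn uniformly from [0.3, 2.8] per scene.  ``manifest_only=True``
    writes just the manifest (with the full train/test partition), which
    exercises the split arithmetic at any ``n_scenes`` without paying for
    image synthesis.
    """
    config = profile_config(profile)
    if count_range is None:
        count_range = tuple(PROFILES[profile]["count_range"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    root_ss = np.random.SeedSequence(int(seed))
    bank_ss, split_ss, scenes_ss = root_ss.spawn(3)
    train_ids, test_ids = split_indices(n_scenes, split_ratio,
                                        np.random.default_rng(split_ss))

    manifest: dict = {
        "seed": int(seed),
        "n_scenes": int(n_scenes),
        "split_ratio": float(split_ratio),
        "profile": profile,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in PROFILES[profile]["config"].items()},
        "count_range": list(count_range),
        "delta_mode": "random" if delta == "random" else float(delta),
        "train": train_ids,
        "test": test_ids,
        "scenes": [],
    }

    if not manifest_only:
        for sub in ("images", "targets", "labels"):
            (out / sub).mkdir(exist_ok=True)
        if bank_size is None:
            bank_size = max(12, min(config.grid_shape) // 4)
        bank = make_shape_bank(np.random.default_rng(bank_ss), size=bank_size)
        scene_seeds = scenes_ss.spawn(n_scenes)
        for i in range(n_scenes):
            rng = np.random.default_rng(scene_seeds[i])
            obj, spec = compose_scene(bank, rng, config.grid_shape, count_range)
            d = float(rng.uniform(0.3, 2.8)) if delta == "random" else float(delta)
            holoset = synthesize_hologram_set(obj, config, delta=d)
            target = two_step_reconstruct(holoset, config)
            stem = f"{i:05d}"
            i1_scale = save_png(out / "images" / f"{stem}.png", holoset.I1,
                                bit_depth=bit_depth)
            t_scale = save_png(out / "targets" / f"{stem}.png", target,
                               bit_depth=bit_depth)
            write_yolo(out / "labels" / f"{stem}.txt", spec.boxes)
            manifest["scenes"].append({
                "id": i,
                "delta": d,
                "n_objects": len(spec.placements),
                "i1_scale": float(i1_scale),
                "target_scale": float(t_scale),
            })

    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def load_dataset(out_dir: str | os.PathLike):
    """Load a built dataset back as float arrays in [0, 1].

    Returns ``(x_train, y_train, x_test, y_test, manifest)`` where inputs
    are the normalized interferograms and targets the reconstruction
    labels, shaped (n, rows, cols).
    """
    from .io import load_png

    out = Path(out_dir)
    with open(out / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)

    def stack(ids):
        xs = [load_png(out / "images" / f"{i:05d}.png") for i in ids]
        ys = [load_png(out / "targets" / f"{i:05d}.png") for i in ids]
        return np.stack(xs), np.stack(ys)

    x_tr, y_tr = stack(manifest["train"])
    x_te, y_te = stack(manifest["test"])
    return x_tr, y_tr, x_te, y_te, manifest


def tree_digest(out_dir: str | os.PathLike) -> str:
    """SHA-256 over every file in a dataset tree (reproducibility checks)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    for p in sorted(out.rglob("*")):
        if p.is_file():
            h.update(str(p.relative_to(out)).encode())
            h.update(p.read_bytes())
    return h.hexdigest()
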