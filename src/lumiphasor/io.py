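"""File formats, channel splitting and run manifests.

The rig exports one multi-page grayscale TIFF per acquisition, each page a
frame holding the four channels as configurable rectangular quadrants
(sine-filtered, its reference, cosine-filtered, its reference). This module
splits such files into :class:`~lumiphasor.pipeline.FourChannelStack`
objects, writes derived images (phasor planes, fraction maps) as
floating-point multi-page TIFF, tables as CSV, and records every output in
a JSON run manifest with config, seeds, software version and input
checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import FormatError, ParameterError
from .pipeline import CHANNELS, FourChannelStack, PhasorImage

__all__ = [
    "Quadrant",
    "QuadrantLayout",
    "RunConfig",
    "read_raw",
    "write_raw",
    "write_phasor",
    "read_phasor",
    "write_outputs",
    "sha256_file",
]


@dataclass(frozen=True)
class Quadrant:
    """A channel's rectangle within the raw frame (0-based, row-major)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if min(self.row, self.col) < 0 or min(self.height, self.width) < 1:
            raise ParameterError(f"invalid quadrant geometry {self}")

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row, self.row + self.height), slice(self.col, self.col + self.width)


@dataclass(frozen=True)
class QuadrantLayout:
    """Placement of the four channels within a raw frame."""

    quadrants: dict[str, Quadrant]

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.quadrants)
        if missing:
            raise ParameterError(f"layout missing channels: {sorted(missing)}")
        boxes = []
        for name in CHANNELS:
            q = self.quadrants[name]
            boxes.append((name, q.row, q.col, q.row + q.height, q.col + q.width))
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                if a[1] < b[3] and b[1] < a[3] and a[2] < b[4] and b[2] < a[4]:
                    raise ParameterError(f"quadrants {a[0]!r} and {b[0]!r} overlap")

    @property
    def channel_shape(self) -> tuple[int, int]:
        shapes = {(q.height, q.width) for q in self.quadrants.values()}
        if len(shapes) != 1:
            raise ParameterError("quadrants have unequal shapes")
        return shapes.pop()

    @property
    def frame_shape(self) -> tuple[int, int]:
        """Minimal raw-frame shape containing all quadrants."""
        return (
            max(q.row + q.height for q in self.quadrants.values()),
            max(q.col + q.width for q in self.quadrants.values()),
        )

    @classmethod
    def two_by_two(cls, height: int, width: int) -> "QuadrantLayout":
        """Default layout: four equal quadrants in a 2x2 grid
        (SIN | INT_SIN on top, COS | INT_COS below)."""
        return cls(
            {
                "sin": Quadrant(0, 0, height, width),
                "int_sin": Quadrant(0, width, height, width),
                "cos": Quadrant(height, 0, height, width),
                "int_cos": Quadrant(height, width, height, width),
            }
        )

    def to_dict(self) -> dict:
        return {name: dataclasses.asdict(q) for name, q in self.quadrants.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "QuadrantLayout":
        return cls({name: Quadrant(**q) for name, q in d.items()})


@dataclass
class RunConfig:
    """Pipeline configuration: filter bounds, processing parameters, seeds.

    Serialized as flat ``key = value`` text; nested layout as JSON inline.
    """

    f_sin_min: float = 0.0
    f_sin_max: float = 1.0
    f_cos_min: float = 0.0
    f_cos_max: float = 1.0
    lambda_start: float = 400.0
    lambda_end: float = 700.0
    sigma: float = 1.0
    n_average: int = 20
    threshold: float = 0.0
    min_area: int = 1
    max_area: int = 10**9
    bins: int = 256
    seed: int = 0
    correction_mode: str = "multiply"
    median_size: int = 51
    layout: QuadrantLayout | None = None

    def __post_init__(self) -> None:
        if self.correction_mode not in ("multiply", "divide"):
            raise ParameterError(f"bad correction_mode {self.correction_mode!r}")
        for lo, hi, which in (
            (self.f_sin_min, self.f_sin_max, "sine"),
            (self.f_cos_min, self.f_cos_max, "cosine"),
        ):
            if not 0 <= lo < hi <= 1:
                raise ParameterError(f"{which} filter bounds ({lo}, {hi}) invalid")

    def to_file(self, path) -> None:
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "layout":
                v = json.dumps(v.to_dict()) if v is not None else "none"
            lines.append(f"{f.name} = {v}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in types:
                raise FormatError(f"unknown config key {key!r}")
            if key == "layout":
                kwargs[key] = None if value == "none" else QuadrantLayout.from_dict(json.loads(value))
            elif key in ("n_average", "min_area", "max_area", "bins", "seed", "median_size"):
                kwargs[key] = int(value)
            elif key == "correction_mode":
                kwargs[key] = value
            else:
                kwargs[key] = float(value)
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# raw stacks
# ---------------------------------------------------------------------------

def read_raw(path, layout: QuadrantLayout) -> FourChannelStack:
    """Split a multi-page grayscale TIFF into the four channels per
    ``layout``; pages are frames, pixel values are kept as counts."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError) as exc:
        raise FormatError(f"{path}: cannot read TIFF ({exc})") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise FormatError(
            f"{path}: expected multi-page grayscale TIFF, got array shape {frames.shape}"
        )
    fh, fw = layout.frame_shape
    if frames.shape[1] < fh or frames.shape[2] < fw:
        raise FormatError(
            f"{path}: layout needs frames of at least {fh}x{fw}, file has "
            f"{frames.shape[1]}x{frames.shape[2]}"
        )
    channels = {}
    for name in CHANNELS:
        rs, cs = layout.quadrants[name].slices()
        channels[name] = frames[:, rs, cs].astype(float)
    return FourChannelStack(**channels)


def write_raw(path, stack: FourChannelStack, layout: QuadrantLayout, dtype=np.uint16) -> None:
    """Assemble the four channels into quadrant frames and write a
    multi-page TIFF (inverse of :func:`read_raw`)."""
    fh, fw = layout.frame_shape
    n = stack.n_frames
    frames = np.zeros((n, fh, fw), dtype=float)
    for name in CHANNELS:
        rs, cs = layout.quadrants[name].slices()
        frames[:, rs, cs] = stack.channel(name)
    if np.issubdtype(np.dtype(dtype), np.integer):
        info = np.iinfo(dtype)
        frames = np.clip(np.rint(frames), info.min, info.max)
    tifffile.imwrite(path, frames.astype(dtype), photometric="minisblack")


# ---------------------------------------------------------------------------
# phasor images
# ---------------------------------------------------------------------------

_PHASOR_PAGES = ("g", "s", "intensity", "mask", "labels")


def write_phasor(path, phasor: PhasorImage) -> None:
    """Phasor image as a 5-page float32 TIFF (g, s, intensity, mask, labels)."""
    pages = np.stack(
        [
            phasor.g,
            phasor.s,
            phasor.intensity,
            phasor.mask.astype(float),
            phasor.labels.astype(float),
        ]
    ).astype(np.float32)
    tifffile.imwrite(path, pages, photometric="minisblack")


def read_phasor(path) -> PhasorImage:
    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim != 3 or pages.shape[0] != len(_PHASOR_PAGES):
        raise FormatError(f"{path}: expected {len(_PHASOR_PAGES)}-page phasor TIFF")
    return PhasorImage(
        g=pages[0],
        s=pages[1],
        intensity=pages[2],
        mask=pages[3] > 0.5,
        labels=np.rint(pages[4]).astype(np.int32),
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(
    out_dir,
    phasor: PhasorImage | None = None,
    images: dict[str, np.ndarray] | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    config: RunConfig | None = None,
    inputs: list = (),
    extra: dict | None = None,
) -> dict:
    """Write all results to ``out_dir`` and return (and save) the manifest.

    ``images`` are extra float32 single/multi-page TIFFs (e.g. fraction
    maps); ``tables`` CSVs; ``inputs`` paths whose sha256 checksums go into
    the manifest. Every file written is listed in the manifest; an empty
    result set still produces a manifest.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def record(name: str, path: Path) -> None:
        files[name] = path.name

    if phasor is not None:
        p = out_dir / "phasor.tif"
        write_phasor(p, phasor)
        record("phasor", p)
    for name, arr in (images or {}).items():
        p = out_dir / f"{name}.tif"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32), photometric="minisblack")
        record(name, p)
    for name, df in (tables or {}).items():
        p = out_dir / f"{name}.csv"
        df.to_csv(p, index=False)
        record(name, p)
    if config is not None:
        p = out_dir / "config.txt"
        config.to_file(p)
        record("config", p)

    manifest = {
        "software": "lumiphasor",
        "version": __version__,
        "files": files,
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "pixel_convention": "row-major, origin top-left, 0-based",
    }
    if config is not None:
        manifest["seed"] = config.seed
        manifest["correction_mode"] = config.correction_mode
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    missing = [f for f in files.values() if not (out_dir / f).exists()]
    if missing:  # pragma: no cover - defensive
        raise FormatError(f"manifest lists files that were not written: {missing}")
    return manifest
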