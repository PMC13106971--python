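"""Dark and bright calibration of the four-channel detection path.

Two calibration acquisitions characterize the cameras:

* a **dark** stack (shutter closed) measures the per-pixel offset and dark
  noise of each channel;
* a **bright** stack of a homogeneous lamp measures the effective light
  splitting between each filtered channel and its unfiltered reference.

Per channel *i* the dark image ``I_i_dark`` is the frame-averaged dark
stack smoothed with a large (default 51 x 51) median filter. From the
bright stack the two splitting-correction maps are

    R_COS = (I_COS_bright - I_COS_dark) / (I_INT(COS)_bright - I_INT(COS)_dark)
    R_SIN = (I_SIN_bright - I_SIN_dark) / (I_INT(SIN)_bright - I_INT(SIN)_dark)

and experiment frames are corrected channelwise:

    I_INT(SIN) = I_INT(SIN)_raw - I_INT(SIN)_dark        (reference: dark only)
    I_SIN      = (I_SIN_raw - I_SIN_dark) * R_SIN        (filtered: dark + R)

with the COS pair analogous. The multiplication by R above is the published
form and is the default (``mode="multiply"``); note however that since R is
itself a filtered/reference ratio, multiplying by it doubles rather than
cancels a splitting imbalance. ``mode="divide"`` divides the filtered
channel by R instead, which renders the downstream phasor exactly
independent of the splitter fractions when the bright acquisition is taken
without the encoding filters (the instrument protocol). Both modes coincide
for a balanced 50:50 splitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, ShapeError
from .pipeline import CHANNELS, FourChannelStack

__all__ = [
    "CalibrationFrames",
    "CalibrationModel",
    "build_dark",
    "build_bright",
    "build_calibration",
    "apply_correction",
    "save_calibration",
    "load_calibration",
]


@dataclass
class CalibrationFrames:
    """Dark and bright calibration stacks, one ``(frames, H, W)`` array per
    channel. Within each of dark/bright all four channels must agree in
    shape; dark and bright may have different frame counts."""

    dark: dict[str, np.ndarray]
    bright: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for group_name in ("dark", "bright"):
            group = getattr(self, group_name)
            if group is None:
                continue
            missing = set(CHANNELS) - set(group)
            if missing:
                raise ShapeError(f"{group_name} stacks missing channels: {sorted(missing)}")
            arrs = {}
            for name in CHANNELS:
                a = np.asarray(group[name], dtype=float)
                if a.ndim == 2:
                    a = a[None, ...]
                if a.ndim != 3:
                    raise ShapeError(f"{group_name}[{name!r}] must be (frames, H, W)")
                arrs[name] = a
            if len({a.shape for a in arrs.values()}) != 1:
                raise ShapeError(f"{group_name} stacks disagree in shape across channels")
            setattr(self, group_name, arrs)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.dark["sin"].shape[1:]


@dataclass
class CalibrationModel:
    """Per-channel dark images plus the R_SIN / R_COS splitting maps.

    ``valid`` is False on pixels where the bright calibration was
    degenerate (non-positive reference excess or non-positive R); those
    pixels are excluded from downstream phasor statistics. ``n_masked``
    counts them.
    """

    dark: dict[str, np.ndarray]
    r_sin: np.ndarray
    r_cos: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_masked: int = 0

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.r_sin.shape, dtype=bool)

    @classmethod
    def identity(cls, shape: tuple[int, int]) -> "CalibrationModel":
        """No-op calibration: zero dark, unit R."""
        zeros = {name: np.zeros(shape) for name in CHANNELS}
        return cls(dark=zeros, r_sin=np.ones(shape), r_cos=np.ones(shape))


def _median_smooth(image: np.ndarray, size: int) -> np.ndarray:
    if size <= 1:
        return image
    return ndimage.median_filter(image, size=size, mode="reflect")


def build_dark(frames: CalibrationFrames, median_size: int = 51) -> dict[str, np.ndarray]:
    """Per-channel dark images: frame average then a ``median_size`` square
    median filter (reflection borders) to remove high-frequency noise."""
    if median_size < 1:
        raise ParameterError("median_size must be >= 1")
    return {
        name: _median_smooth(stack.mean(axis=0), median_size)
        for name, stack in frames.dark.items()
    }


def build_bright(
    frames: CalibrationFrames,
    dark: dict[str, np.ndarray],
    median_size: int = 51,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Splitting-correction maps from the bright calibration stack.

    The bright stacks are frame-averaged and median-smoothed, the dark
    images subtracted, and the filtered/reference ratio computed pixelwise.
    Pixels with non-positive reference excess (or non-positive R) are masked.

    Returns ``(r_cos, r_sin, valid)``.
    """
    if frames.bright is None:
        raise ParameterError("calibration frames contain no bright stacks")
    bright = {
        name: _median_smooth(stack.mean(axis=0), median_size)
        for name, stack in frames.bright.items()
    }
    valid = np.ones(frames.image_shape, dtype=bool)
    maps = {}
    for filtered, reference in (("cos", "int_cos"), ("sin", "int_sin")):
        num = bright[filtered] - dark[filtered]
        den = bright[reference] - dark[reference]
        ok = den > 0
        r = np.zeros_like(num)
        np.divide(num, den, out=r, where=ok)
        ok &= r > 0
        valid &= ok
        maps[filtered] = r
    return maps["cos"], maps["sin"], valid


def build_calibration(frames: CalibrationFrames, median_size: int = 51) -> CalibrationModel:
    """Full calibration: :func:`build_dark` then :func:`build_bright`."""
    dark = build_dark(frames, median_size=median_size)
    r_cos, r_sin, valid = build_bright(frames, dark, median_size=median_size)
    return CalibrationModel(
        dark=dark,
        r_sin=r_sin,
        r_cos=r_cos,
        valid=valid,
        n_masked=int(np.count_nonzero(~valid)),
    )


def apply_correction(
    raw: FourChannelStack,
    cal: CalibrationModel,
    mode: str = "multiply",
    negative_tolerance: float = 0.0,
) -> FourChannelStack:
    """Dark-subtract all channels and undo splitting imbalance.

    Reference channels are dark-subtracted only; the filtered channels are
    dark-subtracted then combined with their R map according to ``mode``
    ("multiply" = published equations, "divide" = imbalance-cancelling
    form; see module docstring). Pixels whose corrected reference intensity
    falls below ``-negative_tolerance`` in any frame are masked as
    background; calibration-masked pixels propagate.
    """
    if mode not in ("multiply", "divide"):
        raise ParameterError(f"mode must be 'multiply' or 'divide', got {mode!r}")
    for name in CHANNELS:
        if cal.dark[name].shape != raw.image_shape:
            raise ShapeError(
                f"calibration shape {cal.dark[name].shape} does not match data {raw.image_shape}"
            )
    corrected: dict[str, np.ndarray] = {}
    valid = cal.valid.copy()
    if raw.valid is not None:
        valid &= raw.valid
    for name in ("int_sin", "int_cos"):
        sub = raw.channel(name) - cal.dark[name]
        valid &= (sub >= -negative_tolerance).all(axis=0)
        corrected[name] = sub
    for name, r in (("sin", cal.r_sin), ("cos", cal.r_cos)):
        sub = raw.channel(name) - cal.dark[name]
        if mode == "multiply":
            corrected[name] = sub * r
        else:
            out = np.zeros_like(sub)
            np.divide(sub, r[None, ...], out=out, where=(r != 0)[None, ...])
            corrected[name] = out
    return FourChannelStack(valid=valid, offsets=raw.offsets, **corrected)


# ---------------------------------------------------------------------------
# serialization: one float32 TIFF, pages = 4 dark images + R_SIN + R_COS +
# valid mask, with a small JSON metadata block in the description tag
# ---------------------------------------------------------------------------

_PAGE_ORDER = (*CHANNELS, "r_sin", "r_cos", "valid")


def save_calibration(path, model: CalibrationModel) -> None:
    import json

    import tifffile

    pages = np.stack(
        [model.dark[name] for name in CHANNELS]
        + [model.r_sin, model.r_cos, model.valid.astype(float)]
    ).astype(np.float32)
    meta = {"pages": list(_PAGE_ORDER), "n_masked": model.n_masked}
    tifffile.imwrite(path, pages, description=json.dumps(meta), photometric="minisblack")


def load_calibration(path) -> CalibrationModel:
    import tifffile

    pages = np.asarray(tifffile.imread(path), dtype=float)
    if pages.ndim != 3 or pages.shape[0] != len(_PAGE_ORDER):
        raise ParameterError(f"{path}: expected a {len(_PAGE_ORDER)}-page calibration TIFF")
    dark = {name: pages[i] for i, name in enumerate(CHANNELS)}
    valid = pages[6] > 0.5
    return CalibrationModel(
        dark=dark,
        r_sin=pages[4],
        r_cos=pages[5],
        valid=valid,
        n_masked=int(np.count_nonzero(~valid)),
    )
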