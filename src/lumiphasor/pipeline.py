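"""From corrected four-channel stacks to per-pixel phasor images.

The instrument records four channels on two cameras: on the "sine" camera a
beam splitter sends part of the light through a sinusoidal-transmission
filter (channel ``SIN``) and the rest to the sensor unfiltered (reference
channel ``INT_SIN``); the "cosine" camera is analogous (``COS`` /
``INT_COS``). After dark/bright calibration, the filtered-to-reference
intensity ratio of each camera measures the mean filter transmission of the
pixel's emission spectrum, which is an affine function of one Fourier
coefficient; the phasor coordinates follow pixelwise as

    g = 2 * (I_COS / I_INT(COS) - F_COS_min) / (F_COS_max - F_COS_min) - 1
    s = 2 * (I_SIN / I_INT(SIN) - F_SIN_min) / (F_SIN_max - F_SIN_min) - 1

with (F_min, F_max) the measured transmission bounds of each filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError, ShapeError

__all__ = [
    "CHANNELS",
    "FourChannelStack",
    "PhasorImage",
    "preprocess",
    "register_channels",
    "threshold_and_segment",
    "pixel_phasor",
    "phasor_histogram",
]

#: Channel order used throughout: sine-filtered, its reference, cosine-filtered, its reference.
CHANNELS = ("sin", "int_sin", "cos", "int_cos")


@dataclass
class FourChannelStack:
    """Registered frames of the four measured channels.

    Each channel is a ``(frames, height, width)`` float array (a single
    frame may be stored as ``(1, H, W)``). ``valid`` marks pixels usable in
    all four channels (False where registration shifted data out of frame or
    calibration masked a pixel). ``offsets`` records the integer (row, col)
    translation applied to each channel by :func:`register_channels`.
    """

    sin: np.ndarray
    int_sin: np.ndarray
    cos: np.ndarray
    int_cos: np.ndarray
    valid: np.ndarray | None = None
    offsets: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        arrays = []
        for name in CHANNELS:
            a = np.asarray(getattr(self, name), dtype=float)
            if a.ndim == 2:
                a = a[None, ...]
            if a.ndim != 3:
                raise ShapeError(f"channel {name!r} must be (frames, H, W), got {a.shape}")
            setattr(self, name, a)
            arrays.append(a)
        if len({a.shape for a in arrays}) != 1:
            raise ShapeError(
                "all four channels must share one shape, got "
                + ", ".join(f"{n}:{a.shape}" for n, a in zip(CHANNELS, arrays))
            )
        if arrays[0].shape[0] < 1:
            raise ShapeError("frame count must be >= 1")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != arrays[0].shape[1:]:
                raise ShapeError("valid mask must match the image shape")

    @property
    def n_frames(self) -> int:
        return self.sin.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.sin.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return getattr(self, name)

    def channels(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}

    def map_channels(self, func) -> "FourChannelStack":
        """New stack with ``func`` applied to every channel array."""
        return replace(self, **{name: func(getattr(self, name)) for name in CHANNELS})


@dataclass
class PhasorImage:
    """Per-pixel phasor coordinates with intensity, mask and segmentation.

    ``g``/``s`` are NaN off-mask; ``labels`` is a consecutive segment-id
    image (0 = background) and is nonzero only on the mask.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    mask: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.labels is None:
            self.labels = np.zeros(self.mask.shape, dtype=np.int32)
        shapes = {self.g.shape, self.s.shape, self.intensity.shape, self.mask.shape, self.labels.shape}
        if len(shapes) != 1:
            raise ShapeError(f"phasor planes disagree in shape: {shapes}")

    def points(self) -> np.ndarray:
        """Masked pixels as an ``(N, 2)`` array of (g, s) points."""
        return np.column_stack([self.g[self.mask], self.s[self.mask]])


# ---------------------------------------------------------------------------
# processing steps
# ---------------------------------------------------------------------------

def preprocess(
    stack: FourChannelStack, sigma: float = 1.0, n_average: int | None = None
) -> FourChannelStack:
    """Gaussian-smooth every frame of every channel, then average frames.

    ``sigma`` is the smoothing width in pixels (reflection borders);
    ``n_average`` averages the first n frames (None = all). Returns a
    single-frame stack.
    """
    n = stack.n_frames if n_average is None else int(n_average)
    if n < 1 or n > stack.n_frames:
        raise ParameterError(
            f"n_average={n_average} outside [1, {stack.n_frames}] available frames"
        )

    def smooth_and_average(frames: np.ndarray) -> np.ndarray:
        if sigma > 0:
            sm = ndimage.gaussian_filter(frames[:n], sigma=(0, sigma, sigma), mode="reflect")
        else:
            sm = frames[:n]
        return sm.mean(axis=0, keepdims=True)

    return stack.map_channels(smooth_and_average)


def _integer_shift(image: np.ndarray, shift: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Translate by integer pixels; returns (shifted, in-frame mask)."""
    dr, dc = int(shift[0]), int(shift[1])
    out = np.roll(image, (dr, dc), axis=(-2, -1))
    valid = np.ones(image.shape[-2:], dtype=bool)
    if dr > 0:
        out[..., :dr, :] = 0
        valid[:dr, :] = False
    elif dr < 0:
        out[..., dr:, :] = 0
        valid[dr:, :] = False
    if dc > 0:
        out[..., :, :dc] = 0
        valid[:, :dc] = False
    elif dc < 0:
        out[..., :, dc:] = 0
        valid[:, dc:] = False
    return out, valid


def _estimate_shift(
    reference: np.ndarray, moving: np.ndarray, max_shift: int
) -> tuple[tuple[int, int], float]:
    """Integer translation maximizing circular cross-correlation, restricted
    to shifts within ``max_shift``. Returns (shift to apply to ``moving``,
    normalized peak correlation)."""
    ref = reference - reference.mean()
    mov = moving - moving.mean()
    denom = np.linalg.norm(ref) * np.linalg.norm(mov)
    corr = np.fft.ifft2(np.fft.fft2(ref) * np.conj(np.fft.fft2(mov))).real
    offsets = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(offsets, offsets)]  # negative indices wrap
    idx = np.unravel_index(np.argmax(window), window.shape)
    shift = (int(offsets[idx[0]]), int(offsets[idx[1]]))
    peak = float(window[idx] / denom) if denom > 0 else 0.0
    return shift, peak


def register_channels(stack: FourChannelStack, max_shift: int = 10) -> FourChannelStack:
    """Estimate and apply integer-pixel translations aligning every channel
    to the ``INT_SIN`` reference channel.

    The shift is estimated on frame-averaged intensity by cross-correlation.
    A shift saturating ``max_shift`` or a weak correlation peak triggers a
    possible-registration-failure warning. Out-of-frame pixels are removed
    from the stack's ``valid`` mask.
    """
    if max_shift < 1:
        raise ParameterError("max_shift must be >= 1")
    ref = stack.int_sin.mean(axis=0)
    shifted: dict[str, np.ndarray] = {}
    offsets: dict[str, tuple[int, int]] = {}
    valid = np.ones(stack.image_shape, dtype=bool) if stack.valid is None else stack.valid.copy()
    for name in CHANNELS:
        frames = stack.channel(name)
        if name == "int_sin":
            shift = (0, 0)
        else:
            shift, peak = _estimate_shift(ref, frames.mean(axis=0), max_shift)
            if max(abs(shift[0]), abs(shift[1])) >= max_shift or peak < 0.2:
                warnings.warn(
                    f"channel {name!r}: possible registration failure "
                    f"(shift {shift}, normalized peak {peak:.3f})",
                    stacklevel=2,
                )
        shifted[name], in_frame = _integer_shift(frames, shift)
        valid &= in_frame
        offsets[name] = shift
    return FourChannelStack(valid=valid, offsets=offsets, **shifted)


def threshold_and_segment(
    intensity: np.ndarray,
    threshold: float,
    min_area: int = 1,
    max_area: int | float = np.inf,
) -> tuple[np.ndarray, np.ndarray]:
    """Global threshold plus connected-component segmentation.

    Pixels with ``intensity > threshold`` form the foreground mask;
    8-connected components with area outside ``[min_area, max_area]`` are
    discarded; surviving components are relabeled 1..K by decreasing area
    (ties broken by the top-left-most pixel in row-major order).

    Returns ``(mask, labels)``; an empty mask yields an all-zero labeling
    with a warning, not an error.
    """
    from skimage import measure

    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    if min_area < 1:
        raise ParameterError("min_area must be >= 1")
    intensity = np.asarray(intensity)
    mask = intensity > threshold
    if not mask.any():
        warnings.warn("threshold produced an empty foreground mask", stacklevel=2)
        return mask, np.zeros(intensity.shape, dtype=np.int32)
    raw = measure.label(mask, connectivity=2)
    components = []
    for lab in range(1, raw.max() + 1):
        pix = np.flatnonzero(raw == lab)
        if min_area <= pix.size <= max_area:
            components.append((-pix.size, pix[0], lab))
    components.sort()
    labels = np.zeros(intensity.shape, dtype=np.int32)
    for new, (_, _, lab) in enumerate(components, start=1):
        labels[raw == lab] = new
    mask = labels > 0
    return mask, labels


def pixel_phasor(
    stack: FourChannelStack,
    sin_bounds: tuple[float, float],
    cos_bounds: tuple[float, float],
    mask: np.ndarray | None = None,
) -> PhasorImage:
    """Pixelwise phasor coordinates from a corrected single-frame stack.

    ``sin_bounds``/``cos_bounds`` are the measured (F_min, F_max)
    transmission bounds of each encoding filter. ``g`` comes from the cosine
    camera ratio, ``s`` from the sine camera ratio. Masked-in pixels whose
    reference channel is not positive are dropped from the mask and counted
    in ``n_dropped``. Intensity is the sum of the two reference channels.
    """
    for lo, hi, which in (*sin_bounds, "sine"), (*cos_bounds, "cosine"):
        if not hi > lo:
            raise ParameterError(f"{which} filter bounds need F_max > F_min, got ({lo}, {hi})")
    if stack.n_frames != 1:
        raise ParameterError(
            f"pixel_phasor expects a single-frame (preprocessed) stack, got {stack.n_frames} frames"
        )
    int_sin = stack.int_sin[0]
    int_cos = stack.int_cos[0]
    if mask is None:
        mask = np.ones(stack.image_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool).copy()
    if stack.valid is not None:
        mask &= stack.valid
    ref_ok = (int_sin > 0) & (int_cos > 0)
    n_dropped = int(np.count_nonzero(mask & ~ref_ok))
    mask &= ref_ok

    g = np.full(stack.image_shape, np.nan)
    s = np.full(stack.image_shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_c = stack.cos[0] / int_cos
        ratio_s = stack.sin[0] / int_sin
    c_min, c_max = cos_bounds
    s_min, s_max = sin_bounds
    g[mask] = 2.0 * (ratio_c[mask] - c_min) / (c_max - c_min) - 1.0
    s[mask] = 2.0 * (ratio_s[mask] - s_min) / (s_max - s_min) - 1.0
    intensity = int_sin + int_cos
    return PhasorImage(g=g, s=s, intensity=intensity, mask=mask, n_dropped=n_dropped)


def phasor_histogram(
    phasor: PhasorImage, bins: int = 256
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of masked pixels over the phasor square [-1, 1]^2.

    Returns ``(counts, g_edges, s_edges)``; total mass equals the number of
    masked pixels (out-of-square pixels are clipped into the edge bins so
    mass is conserved).
    """
    if not phasor.mask.any():
        raise ParameterError("phasor histogram of an empty mask")
    pts = phasor.points()
    clipped = np.clip(pts, -1.0, 1.0)
    counts, ge, se = np.histogram2d(
        clipped[:, 0], clipped[:, 1], bins=bins, range=[[-1, 1], [-1, 1]]
    )
    return counts, ge, se
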