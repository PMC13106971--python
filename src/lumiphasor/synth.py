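"""Synthetic four-channel bioluminescence microscope.

Emulates the phasor-imaging rig end to end so every downstream stage can be
tested against known ground truth: scenes of reporter-expressing cells,
sinusoidal encoding filters, imperfect beam splitting, camera dark offset,
Gaussian read noise, and Poisson photon noise over repeated frames —
together with matching dark/bright calibration stacks.

Light model
-----------
Each pixel emits ``rate`` expected photons per frame toward each camera.
On the sine camera a splitter sends fraction ``split_sin`` through the sine
filter (channel ``SIN``) and the rest to the sensor unfiltered
(``INT_SIN``); the cosine camera is analogous. Expected counts per frame:

    E[SIN]      = gain * split_sin       * rate * <T_sin>   + offset
    E[INT_SIN]  = gain * (1 - split_sin) * rate             + offset

where ``<T>`` is the mean filter transmission under the pixel's
(area-normalized) emission spectrum, evaluated with the same trapezoidal
quadrature as :func:`lumiphasor.spectra.spectral_phasor` — which is what
makes the noiseless simulated pipeline agree with the direct spectral
transform to machine precision. Poisson noise acts on photon counts before
gain; read noise and offset are added per frame.

Depth / scattering surrogate
----------------------------
Imaging through tissue-like material broadens phasor signatures without
moving their center. :class:`SpectralBroadening` emulates this with a
per-pixel random spectral shift (zero-mean, ``shift_sd`` nm) whose optical
throughput is attenuated with the magnitude of the distortion
(``attenuation_sd`` nm): strongly scattered photons are both spectrally
distorted and strongly absorbed, so dim, heavily shifted pixels broaden the
phasor histogram while the intensity-weighted centroid stays put.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .calibration import CalibrationFrames
from .exceptions import ParameterError
from .pipeline import CHANNELS, FourChannelStack
from .spectra import (
    DEFAULT_WINDOW,
    EmissionSpectrum,
    ReporterModel,
    SpectralWindow,
    mix_bret,
    spectral_phasor,
    trapezoid_weights,
)

__all__ = [
    "FilterFunction",
    "CameraModel",
    "CellSpec",
    "Scene",
    "GroundTruth",
    "SpectralBroadening",
    "make_filters",
    "render_stack",
    "render_calibration",
    "library_spectra",
    "reference_phasors",
    "default_library",
]


@dataclass(frozen=True)
class FilterFunction:
    """Sinusoidal-transmission encoding filter.

    Transmission spans exactly one period of the spectral window:
    ``T(lambda) = F_min + (F_max - F_min) * (1 + trig(theta)) / 2`` with
    ``trig`` cos or sin and ``theta`` the window's angular coordinate, so
    ``T`` is bounded by ``[F_min, F_max]`` by construction.
    """

    kind: str  # "sine" | "cosine"
    f_min: float
    f_max: float
    window: SpectralWindow = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if self.kind not in ("sine", "cosine"):
            raise ParameterError(f"filter kind must be 'sine' or 'cosine', got {self.kind!r}")
        if not 0.0 <= self.f_min < self.f_max <= 1.0:
            raise ParameterError(
                f"need 0 <= F_min < F_max <= 1, got ({self.f_min}, {self.f_max})"
            )

    @property
    def bounds(self) -> tuple[float, float]:
        return self.f_min, self.f_max

    def transmission(self, wavelengths: np.ndarray) -> np.ndarray:
        theta = self.window.phase(wavelengths)
        trig = np.sin(theta) if self.kind == "sine" else np.cos(theta)
        return self.f_min + (self.f_max - self.f_min) * (1.0 + trig) / 2.0

    def mean_transmission(self, spectrum: EmissionSpectrum) -> float:
        """Spectrum-weighted mean transmission <T> (trapezoid quadrature)."""
        w = trapezoid_weights(spectrum.wavelengths) * spectrum.intensities
        total = w.sum()
        if total <= 0:
            raise ParameterError("mean transmission of a zero-intensity spectrum")
        return float(np.dot(w, self.transmission(spectrum.wavelengths)) / total)


def make_filters(
    window: SpectralWindow = DEFAULT_WINDOW, f_min: float = 0.0, f_max: float = 1.0
) -> tuple[FilterFunction, FilterFunction]:
    """The (sine, cosine) filter pair over one period of ``window``."""
    return (
        FilterFunction("sine", f_min, f_max, window),
        FilterFunction("cosine", f_min, f_max, window),
    )


@dataclass(frozen=True)
class CameraModel:
    """Camera/splitter imperfections corrected by calibration.

    ``dark_offset`` may be a scalar or a per-pixel map (counts);
    ``split_sin``/``split_cos`` are the fractions of each camera's light
    sent through the respective encoding filter.
    """

    dark_offset: float | np.ndarray = 100.0
    read_noise_sd: float = 1.5
    gain: float = 1.0
    split_sin: float = 0.5
    split_cos: float = 0.5

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.dark_offset) < 0):
            raise ParameterError("dark_offset must be >= 0")
        for name in ("split_sin", "split_cos"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ParameterError(f"{name} must be in (0, 1), got {v}")
        if self.gain <= 0:
            raise ParameterError("gain must be > 0")
        if self.read_noise_sd < 0:
            raise ParameterError("read_noise_sd must be >= 0")

    def offset_map(self, shape: tuple[int, int]) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.dark_offset, dtype=float), shape).copy()

    @classmethod
    def ideal(cls) -> "CameraModel":
        """Noise-free balanced camera: zero offset, unit gain, 50:50 splits."""
        return cls(dark_offset=0.0, read_noise_sd=0.0, gain=1.0)


@dataclass(frozen=True)
class CellSpec:
    """A disk-shaped cell: center (row, col), radius in pixels, the name of
    the expressed reporter, and its photon rate (expected photons per pixel
    per frame reaching each camera)."""

    center: tuple[float, float]
    radius: float
    reporter: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("photon rate must be >= 0")
        if self.radius <= 0:
            raise ParameterError("radius must be > 0")


@dataclass
class Scene:
    """A field of view: image size, cells, and a uniform background rate.

    Overlapping cells add photons, which is how per-pixel reporter mixtures
    are constructed (two co-centered disks with rates ``f*R`` and
    ``(1-f)*R`` give every interior pixel intensity fraction ``f``).
    """

    height: int
    width: int
    cells: list[CellSpec] = field(default_factory=list)
    background_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.background_rate < 0:
            raise ParameterError("background_rate must be >= 0")
        for cell in self.cells:
            r, c = cell.center
            if not (
                cell.radius <= r <= self.height - 1 - cell.radius
                and cell.radius <= c <= self.width - 1 - cell.radius
            ):
                raise ParameterError(
                    f"cell at {cell.center} with radius {cell.radius} exceeds "
                    f"image bounds {self.height}x{self.width}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.height, self.width

    def disk_mask(self, cell: CellSpec) -> np.ndarray:
        rr, cc = np.ogrid[: self.height, : self.width]
        return (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= cell.radius**2


@dataclass
class GroundTruth:
    """Noiseless truth for a rendered scene.

    ``labels`` is the cell-id map (0 = background; overlaps keep the last
    cell's id — mixtures are captured by ``fractions``); ``g``/``s`` are the
    per-pixel true phasor (NaN where flux is zero); ``flux`` the expected
    photons/pixel/frame; ``fractions`` maps reporter name to its per-pixel
    intensity fraction; ``cells`` is a per-cell table (id, reporter,
    geometry, rate, reference phasor, BRET efficiency where applicable).
    """

    labels: np.ndarray
    g: np.ndarray
    s: np.ndarray
    flux: np.ndarray
    fractions: dict[str, np.ndarray]
    cells: pd.DataFrame


@dataclass(frozen=True)
class SpectralBroadening:
    """Depth/scattering surrogate: per-pixel spectral shift with
    scattering-correlated attenuation (see module docstring).

    ``shift_sd``: sd of the zero-mean per-pixel wavelength shift (nm);
    ``attenuation_sd``: spectral-distortion scale of the Gaussian
    throughput penalty (nm); ``n_levels`` quantization levels of the shift.
    """

    shift_sd: float
    attenuation_sd: float = 5.0
    n_levels: int = 33
    max_sigmas: float = 2.5

    def __post_init__(self) -> None:
        if self.shift_sd < 0 or self.attenuation_sd <= 0:
            raise ParameterError("shift_sd must be >= 0 and attenuation_sd > 0")
        if self.n_levels < 3:
            raise ParameterError("n_levels must be >= 3")

    def level_shifts(self) -> np.ndarray:
        half = self.max_sigmas * self.shift_sd
        return np.linspace(-half, half, self.n_levels)

    def attenuation(self, delta: np.ndarray) -> np.ndarray:
        return np.exp(-np.asarray(delta) ** 2 / (2.0 * self.attenuation_sd**2))


# ---------------------------------------------------------------------------
# reporter libraries
# ---------------------------------------------------------------------------

def library_spectra(
    library: Mapping[str, EmissionSpectrum | ReporterModel]
) -> dict[str, EmissionSpectrum]:
    """Resolve a reporter library to unit-area emission spectra
    (:func:`mix_bret` is applied to BRET reporter models)."""
    out: dict[str, EmissionSpectrum] = {}
    for name, entry in library.items():
        spec = mix_bret(entry) if isinstance(entry, ReporterModel) else entry.normalized()
        out[name] = spec
    return out


def reference_phasors(
    library: Mapping[str, EmissionSpectrum | ReporterModel],
    window: SpectralWindow = DEFAULT_WINDOW,
) -> dict[str, tuple[float, float]]:
    """Reference (g, s) centroid per library entry."""
    return {
        name: spectral_phasor(spec, window)
        for name, spec in library_spectra(library).items()
    }


def default_library(window: SpectralWindow = DEFAULT_WINDOW) -> dict[str, object]:
    """A small synthetic reporter library.

    Gaussian stand-ins for common luciferases / fluorescent proteins
    (NanoLuc-blue through LumiScarlet-red) plus two BRET sensor models
    (caspase-9 protease sensor, NanoLuc->mNeonGreen; calcium sensor,
    NanoLuc->Venus). Spectral shapes are synthetic approximations chosen for
    realistic peak positions and widths, not measured curves.
    """
    grid = window.grid(601)
    gauss = lambda c, sd: EmissionSpectrum.gaussian(c, sd, grid)
    nanoluc = gauss(460.0, 40.0)
    mneon = gauss(518.0, 25.0)
    venus = gauss(528.0, 26.0)
    lib: dict[str, object] = {
        "NanoLuc": nanoluc,
        "mNeonGreen": mneon,
        "Venus": venus,
        "YeNL": gauss(530.0, 30.0),
        "LumiScarlet": gauss(600.0, 30.0),
        "C9-BRET": ReporterModel("C9-BRET", nanoluc, mneon, efficiency=0.8),
        "CaFluxVTN": ReporterModel("CaFluxVTN", nanoluc, venus, efficiency=0.5),
    }
    return lib


def demo_scene(kind: str = "demo", size: int = 96, rate: float = 500.0) -> Scene:
    """Packaged demonstration scenes.

    ``demo``: three well-separated pure-reporter cells (NanoLuc, YeNL,
    LumiScarlet). ``mixture``: two reporters plus co-centered disks mixing
    them at fractions 0.3/0.7. ``sensor``: cells expressing the caspase
    BRET sensor alongside pure donor/acceptor cells.
    """
    q = size / 4.0
    r = max(3.0, size / 10.0)
    if kind == "demo":
        cells = [
            CellSpec((q, q), r, "NanoLuc", rate),
            CellSpec((q, 3 * q), r, "YeNL", rate),
            CellSpec((3 * q, 2 * q), r, "LumiScarlet", rate),
        ]
    elif kind == "mixture":
        cells = [
            CellSpec((q, q), r, "NanoLuc", rate),
            CellSpec((q, 3 * q), r, "YeNL", rate),
            CellSpec((3 * q, 2 * q), r, "NanoLuc", 0.3 * rate),
            CellSpec((3 * q, 2 * q), r, "YeNL", 0.7 * rate),
        ]
    elif kind == "sensor":
        cells = [
            CellSpec((q, q), r, "NanoLuc", rate),
            CellSpec((q, 3 * q), r, "mNeonGreen", rate),
            CellSpec((3 * q, q), r, "C9-BRET", rate),
            CellSpec((3 * q, 3 * q), r, "CaFluxVTN", rate),
        ]
    else:
        raise ParameterError(f"unknown demo scene {kind!r}")
    return Scene(height=size, width=size, cells=cells)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BACKGROUND = "__background__"


def _reporter_rate_maps(
    scene: Scene, spectra: Mapping[str, EmissionSpectrum]
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-reporter photon-rate maps and the cell-id label map."""
    maps: dict[str, np.ndarray] = {}
    labels = np.zeros(scene.shape, dtype=np.int32)
    for cell_id, cell in enumerate(scene.cells, start=1):
        if cell.reporter not in spectra:
            raise KeyError(f"scene reporter {cell.reporter!r} not in library")
        disk = scene.disk_mask(cell)
        maps.setdefault(cell.reporter, np.zeros(scene.shape))[disk] += cell.rate
        labels[disk] = cell_id
    if scene.background_rate > 0:
        maps[_BACKGROUND] = np.full(scene.shape, scene.background_rate)
    return maps, labels


def _channel_coefficients(
    spectrum: EmissionSpectrum,
    filters: tuple[FilterFunction, FilterFunction],
    window: SpectralWindow,
) -> tuple[float, float, float, float]:
    """(t_sin, t_cos, g, s) of a unit-area spectrum: mean transmissions of
    the two filters and the true phasor."""
    sine, cosine = filters
    t_s = sine.mean_transmission(spectrum)
    t_c = cosine.mean_transmission(spectrum)
    g, s = spectral_phasor(spectrum, window)
    return t_s, t_c, g, s


def render_stack(
    scene: Scene,
    library: Mapping[str, EmissionSpectrum | ReporterModel],
    filters: tuple[FilterFunction, FilterFunction],
    camera: CameraModel,
    n_frames: int = 20,
    seed: int | None = None,
    noise: bool = True,
    broadening: SpectralBroadening | None = None,
) -> tuple[FourChannelStack, GroundTruth]:
    """Render a scene into a four-channel frame stack plus ground truth.

    One ``seed`` governs the whole render; independent sub-streams are
    derived deterministically for the broadening field and for every
    (frame, channel) pair, so renders are bit-reproducible. With
    ``noise=False`` every frame equals the expected image exactly.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    window = filters[0].window
    spectra = library_spectra(library)
    spectra[_BACKGROUND] = EmissionSpectrum.flat(window.grid(601)).normalized()
    rate_maps, labels = _reporter_rate_maps(scene, spectra)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    broadening_ss, noise_parent = ss.spawn(2)

    shape = scene.shape
    flux = np.zeros(shape)
    sin_photon = np.zeros(shape)
    cos_photon = np.zeros(shape)
    g_num = np.zeros(shape)
    s_num = np.zeros(shape)
    fractions_num: dict[str, np.ndarray] = {}

    if broadening is not None and broadening.shift_sd > 0:
        rng = np.random.default_rng(broadening_ss)
        delta = rng.normal(0.0, broadening.shift_sd, size=shape)
        half = broadening.max_sigmas * broadening.shift_sd
        delta = np.clip(delta, -half, half)
        shifts = broadening.level_shifts()
        level = np.abs(delta[..., None] - shifts).argmin(axis=-1)
        atten_levels = broadening.attenuation(shifts)
        for name, rate in rate_maps.items():
            base = spectra[name]
            coefs = np.array(
                [
                    _channel_coefficients(base.shifted(d).normalized(), filters, window)
                    for d in shifts
                ]
            )  # (n_levels, 4)
            t_s, t_c, g_r, s_r = (coefs[level, i] for i in range(4))
            eff_rate = rate * atten_levels[level]
            flux += eff_rate
            sin_photon += eff_rate * t_s
            cos_photon += eff_rate * t_c
            g_num += eff_rate * g_r
            s_num += eff_rate * s_r
            fractions_num[name] = eff_rate
    else:
        for name, rate in rate_maps.items():
            t_s, t_c, g_r, s_r = _channel_coefficients(spectra[name], filters, window)
            flux += rate
            sin_photon += rate * t_s
            cos_photon += rate * t_c
            g_num += rate * g_r
            s_num += rate * s_r
            fractions_num[name] = rate

    with np.errstate(invalid="ignore", divide="ignore"):
        g_true = np.where(flux > 0, g_num / np.where(flux > 0, flux, 1.0), np.nan)
        s_true = np.where(flux > 0, s_num / np.where(flux > 0, flux, 1.0), np.nan)
        fractions = {
            name: np.where(flux > 0, num / np.where(flux > 0, flux, 1.0), 0.0)
            for name, num in fractions_num.items()
            if name != _BACKGROUND
        }

    expected_photons = {
        "sin": camera.split_sin * sin_photon,
        "int_sin": (1.0 - camera.split_sin) * flux,
        "cos": camera.split_cos * cos_photon,
        "int_cos": (1.0 - camera.split_cos) * flux,
    }
    offset = camera.offset_map(shape)
    frames = {name: np.empty((n_frames,) + shape) for name in CHANNELS}
    frame_streams = noise_parent.spawn(n_frames)
    for f in range(n_frames):
        channel_streams = frame_streams[f].spawn(len(CHANNELS))
        for name, chan_ss in zip(CHANNELS, channel_streams):
            if noise:
                rng = np.random.default_rng(chan_ss)
                photons = rng.poisson(expected_photons[name]).astype(float)
                img = camera.gain * photons + offset
                if camera.read_noise_sd > 0:
                    img = img + rng.normal(0.0, camera.read_noise_sd, size=shape)
            else:
                img = camera.gain * expected_photons[name] + offset
            frames[name][f] = img

    stack = FourChannelStack(**frames)
    refs = reference_phasors(library, window)
    rows = []
    for cell_id, cell in enumerate(scene.cells, start=1):
        entry = library[cell.reporter]
        rows.append(
            {
                "cell_id": cell_id,
                "reporter": cell.reporter,
                "row": cell.center[0],
                "col": cell.center[1],
                "radius": cell.radius,
                "rate": cell.rate,
                "g_true": refs[cell.reporter][0],
                "s_true": refs[cell.reporter][1],
                "efficiency": entry.efficiency if isinstance(entry, ReporterModel) else np.nan,
            }
        )
    cells = pd.DataFrame(
        rows,
        columns=[
            "cell_id", "reporter", "row", "col", "radius", "rate",
            "g_true", "s_true", "efficiency",
        ],
    )
    truth = GroundTruth(
        labels=labels, g=g_true, s=s_true, flux=flux, fractions=fractions, cells=cells
    )
    return stack, truth


def render_calibration(
    camera: CameraModel,
    shape: tuple[int, int],
    filters: tuple[FilterFunction, FilterFunction] | None = None,
    n_frames: int = 100,
    bright_rate: float = 1.0e4,
    seed: int | None = None,
    noise: bool = True,
) -> CalibrationFrames:
    """Render dark and bright calibration stacks.

    The dark stack is offset plus read noise only (shutter closed). The
    bright stack images a homogeneous, spectrally flat lamp through the
    splitters; by the instrument protocol the encoding filters are removed
    (``filters=None``), so the bright filtered/reference ratio isolates the
    splitting imbalance. Pass the filter pair explicitly to model a bright
    acquisition with the filters left in the path, in which case the ratio
    additionally carries each filter's mean transmission ``(F_min+F_max)/2``.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be >= 1")
    offset = camera.offset_map(shape)
    if filters is None:
        t_s = t_c = 1.0
    else:
        sine, cosine = filters
        flat = EmissionSpectrum.flat(sine.window.grid(601))
        t_s = sine.mean_transmission(flat)
        t_c = cosine.mean_transmission(flat)
    bright_photons = {
        "sin": camera.split_sin * bright_rate * t_s,
        "int_sin": (1.0 - camera.split_sin) * bright_rate,
        "cos": camera.split_cos * bright_rate * t_c,
        "int_cos": (1.0 - camera.split_cos) * bright_rate,
    }
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    dark_parent, bright_parent = ss.spawn(2)
    dark = {name: np.empty((n_frames,) + shape) for name in CHANNELS}
    bright = {name: np.empty((n_frames,) + shape) for name in CHANNELS}
    dark_streams = dark_parent.spawn(n_frames)
    bright_streams = bright_parent.spawn(n_frames)
    for f in range(n_frames):
        d_chan = dark_streams[f].spawn(len(CHANNELS))
        b_chan = bright_streams[f].spawn(len(CHANNELS))
        for name, dss, bss in zip(CHANNELS, d_chan, b_chan):
            if noise:
                rng_d = np.random.default_rng(dss)
                dark_img = offset + (
                    rng_d.normal(0.0, camera.read_noise_sd, size=shape)
                    if camera.read_noise_sd > 0
                    else 0.0
                )
                rng_b = np.random.default_rng(bss)
                photons = rng_b.poisson(
                    np.full(shape, bright_photons[name])
                ).astype(float)
                bright_img = camera.gain * photons + offset
                if camera.read_noise_sd > 0:
                    bright_img = bright_img + rng_b.normal(0.0, camera.read_noise_sd, size=shape)
            else:
                dark_img = offset.copy()
                bright_img = camera.gain * np.full(shape, bright_photons[name]) + offset
            dark[name][f] = dark_img
            bright[name][f] = bright_img
    return CalibrationFrames(dark=dark, bright=bright)
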