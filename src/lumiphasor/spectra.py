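"""Emission spectra and the spectral-phasor transform.

The spectral phasor of an emission spectrum :math:`I(\\lambda)` over a
window :math:`[\\lambda_0, \\lambda_0 + L]` is the pair of normalized
harmonic-:math:`n` Fourier coefficients

.. math::

    g = \\frac{\\int I(\\lambda)\\cos(2\\pi n (\\lambda-\\lambda_0)/L)\\,d\\lambda}
             {\\int I(\\lambda)\\,d\\lambda},
    \\qquad
    s = \\frac{\\int I(\\lambda)\\sin(2\\pi n (\\lambda-\\lambda_0)/L)\\,d\\lambda}
             {\\int I(\\lambda)\\,d\\lambda}.

Because both coordinates are intensity-normalized linear functionals, the
phasor of a sum of spectra is the intensity-weighted mean of the component
phasors — mixtures lie on straight chords between pure-component phasors,
which is what makes phasor-space unmixing and BRET-trajectory readouts
linear. Integrals are evaluated by trapezoidal quadrature on the supplied
wavelength grid (uniform or not), and the same quadrature is used
consistently across the package so that the optical filter encoding and the
direct spectral transform agree to machine precision.

Conventions: phase increases with wavelength (a red-shift rotates the
phasor counter-clockwise by :math:`2\\pi\\,\\Delta\\lambda/L`); the default
window is 400–700 nm at harmonic 1, spanning the emission of the blue
(NanoLuc, ~460 nm) through red (LumiScarlet / Antares) reporters in one
full period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import DomainError, IllPosedError, ParameterError, UndefinedPhasorError

__all__ = [
    "SpectralWindow",
    "EmissionSpectrum",
    "ReporterModel",
    "DEFAULT_WINDOW",
    "spectral_phasor",
    "mix_bret",
    "bret_ratio",
    "spectral_decompose",
    "trapezoid_weights",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_spectra_long_csv",
]


def trapezoid_weights(x: np.ndarray) -> np.ndarray:
    """Trapezoidal quadrature weights for an ascending (possibly
    non-uniform) grid ``x``: ``sum(w * f(x))`` equals ``np.trapezoid(f(x), x)``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ParameterError("quadrature grid must be 1-D with at least 2 samples")
    w = np.empty_like(x)
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    return w


@dataclass(frozen=True)
class SpectralWindow:
    """Wavelength window and harmonic of the phasor transform.

    Parameters
    ----------
    lambda_start, lambda_end : float
        Window bounds in nm; one full period of the harmonic-1 transform.
    harmonic : int
        Harmonic number ``n`` (default 1).
    """

    lambda_start: float = 400.0
    lambda_end: float = 700.0
    harmonic: int = 1

    def __post_init__(self) -> None:
        if not self.lambda_end > self.lambda_start:
            raise ParameterError(
                f"lambda_end ({self.lambda_end}) must exceed lambda_start ({self.lambda_start})"
            )
        if int(self.harmonic) != self.harmonic or self.harmonic < 1:
            raise ParameterError(f"harmonic must be a positive integer, got {self.harmonic}")

    @property
    def length(self) -> float:
        """Window length ``L`` in nm."""
        return self.lambda_end - self.lambda_start

    def phase(self, wavelengths: np.ndarray) -> np.ndarray:
        """Angular coordinate ``2*pi*n*(lambda - lambda_start)/L`` in radians."""
        lam = np.asarray(wavelengths, dtype=float)
        return 2.0 * np.pi * self.harmonic * (lam - self.lambda_start) / self.length

    def grid(self, n: int = 601) -> np.ndarray:
        """Uniform wavelength grid with ``n`` samples spanning the window."""
        return np.linspace(self.lambda_start, self.lambda_end, n)


DEFAULT_WINDOW = SpectralWindow()


class EmissionSpectrum:
    """A sampled emission spectrum: wavelength (nm) vs photon rate.

    Wavelengths must be strictly ascending; intensities non-negative.
    Arithmetic (``+`` and scalar ``*``) acts on intensities so that photon
    mixing of co-located reporters is literal addition of spectra.
    """

    __slots__ = ("wavelengths", "intensities")

    def __init__(self, wavelengths: Iterable[float], intensities: Iterable[float]) -> None:
        lam = np.asarray(wavelengths, dtype=float)
        inten = np.asarray(intensities, dtype=float)
        if lam.ndim != 1 or inten.ndim != 1 or lam.size != inten.size:
            raise ParameterError("wavelengths and intensities must be 1-D and equal length")
        if lam.size < 2:
            raise ParameterError("a spectrum needs at least 2 samples")
        if np.any(np.diff(lam) <= 0):
            raise ParameterError("wavelengths must be strictly ascending")
        if np.any(inten < 0):
            raise ParameterError("intensities must be non-negative")
        self.wavelengths = lam
        self.intensities = inten

    # -- constructors -------------------------------------------------
    @classmethod
    def gaussian(
        cls,
        center: float,
        sd: float,
        grid: np.ndarray | None = None,
        amplitude: float = 1.0,
    ) -> "EmissionSpectrum":
        """Gaussian emission line with peak ``center`` nm and width ``sd`` nm."""
        lam = DEFAULT_WINDOW.grid() if grid is None else np.asarray(grid, dtype=float)
        inten = amplitude * np.exp(-0.5 * ((lam - center) / sd) ** 2)
        return cls(lam, inten)

    @classmethod
    def flat(cls, grid: np.ndarray | None = None, level: float = 1.0) -> "EmissionSpectrum":
        lam = DEFAULT_WINDOW.grid() if grid is None else np.asarray(grid, dtype=float)
        return cls(lam, np.full(lam.shape, float(level)))

    # -- basic quantities ---------------------------------------------
    @property
    def total(self) -> float:
        """Integrated intensity (trapezoid area) — total photon rate."""
        return float(np.trapezoid(self.intensities, self.wavelengths))

    def normalized(self) -> "EmissionSpectrum":
        """Unit-area copy."""
        a = self.total
        if a <= 0:
            raise UndefinedPhasorError("cannot normalize a zero-total-intensity spectrum")
        return EmissionSpectrum(self.wavelengths, self.intensities / a)

    def resample(self, grid: np.ndarray) -> "EmissionSpectrum":
        """Linear interpolation onto ``grid``; zero outside the support."""
        grid = np.asarray(grid, dtype=float)
        inten = np.interp(grid, self.wavelengths, self.intensities, left=0.0, right=0.0)
        return EmissionSpectrum(grid, inten)

    def shifted(self, delta: float) -> "EmissionSpectrum":
        """Spectrum translated by ``delta`` nm on the same grid (support
        leaving the grid is clipped to zero)."""
        inten = np.interp(
            self.wavelengths - delta, self.wavelengths, self.intensities, left=0.0, right=0.0
        )
        return EmissionSpectrum(self.wavelengths, inten)

    def band_integral(self, center: float, bandwidth: float) -> float:
        """Integrated intensity in ``[center - bw/2, center + bw/2]``."""
        lo, hi = center - bandwidth / 2.0, center + bandwidth / 2.0
        lam, inten = self.wavelengths, self.intensities
        if hi < lam[0] or lo > lam[-1]:
            return 0.0
        # integrate on a clipped grid with exact band endpoints
        inner = lam[(lam > lo) & (lam < hi)]
        grid = np.concatenate(([max(lo, lam[0])], inner, [min(hi, lam[-1])]))
        vals = np.interp(grid, lam, inten)
        return float(np.trapezoid(vals, grid))

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "EmissionSpectrum") -> "EmissionSpectrum":
        if not np.array_equal(self.wavelengths, other.wavelengths):
            other = other.resample(self.wavelengths)
        return EmissionSpectrum(self.wavelengths, self.intensities + other.intensities)

    def __mul__(self, factor: float) -> "EmissionSpectrum":
        return EmissionSpectrum(self.wavelengths, self.intensities * float(factor))

    __rmul__ = __mul__

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lam = self.wavelengths
        return (
            f"EmissionSpectrum({lam[0]:.0f}-{lam[-1]:.0f} nm, "
            f"{lam.size} samples, area={self.total:.3g})"
        )


@dataclass(frozen=True)
class ReporterModel:
    """A BRET reporter: luciferase donor plus fluorescent-protein acceptor.

    ``efficiency`` is the acceptor *photon fraction* of the area-normalized
    donor and acceptor components — the quantity observable from an emission
    spectrum — not a molar FRET efficiency. Spectra are resampled onto the
    donor's wavelength grid on construction.
    """

    name: str
    donor_spectrum: EmissionSpectrum
    acceptor_spectrum: EmissionSpectrum
    efficiency: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ParameterError(f"efficiency must be in [0, 1], got {self.efficiency}")
        if not np.array_equal(
            self.donor_spectrum.wavelengths, self.acceptor_spectrum.wavelengths
        ):
            object.__setattr__(
                self,
                "acceptor_spectrum",
                self.acceptor_spectrum.resample(self.donor_spectrum.wavelengths),
            )

    def with_efficiency(self, efficiency: float) -> "ReporterModel":
        return replace(self, efficiency=efficiency)


def spectral_phasor(
    spectrum: EmissionSpectrum, window: SpectralWindow = DEFAULT_WINDOW
) -> tuple[float, float]:
    """Spectral phasor (g, s) of a spectrum.

    Raises
    ------
    UndefinedPhasorError
        If the spectrum has zero total intensity.
    DomainError
        If the spectrum's support extends outside the window.
    """
    lam = spectrum.wavelengths
    support = lam[spectrum.intensities > 0]
    if support.size and (
        support[0] < window.lambda_start - 1e-9 or support[-1] > window.lambda_end + 1e-9
    ):
        raise DomainError(
            f"spectrum support [{support[0]:.1f}, {support[-1]:.1f}] nm outside "
            f"window [{window.lambda_start:.1f}, {window.lambda_end:.1f}] nm"
        )
    w = trapezoid_weights(lam) * spectrum.intensities
    total = w.sum()
    if total <= 0:
        raise UndefinedPhasorError("phasor of a zero-total-intensity spectrum is undefined")
    theta = window.phase(lam)
    g = float(np.dot(w, np.cos(theta)) / total)
    s = float(np.dot(w, np.sin(theta)) / total)
    return g, s


def mix_bret(model: ReporterModel) -> EmissionSpectrum:
    """Emission spectrum of a BRET reporter at its transfer efficiency.

    Returns the unit-area mixture ``(1-E) * donor_hat + E * acceptor_hat``
    of the area-normalized donor and acceptor spectra.
    """
    d = model.donor_spectrum.normalized()
    a = model.acceptor_spectrum.normalized()
    mix = (1.0 - model.efficiency) * d + model.efficiency * a
    return mix.normalized()


def bret_ratio(
    spectrum: EmissionSpectrum,
    donor_lambda: float = 460.0,
    acceptor_lambda: float = 518.0,
    bandwidth: float = 20.0,
) -> float:
    """Acceptor-band / donor-band intensity ratio of a spectrum.

    Band centers default to the NanoLuc donor (460 nm) and mNeonGreen
    acceptor (518 nm) emission peaks; each band is
    ``[center - bandwidth/2, center + bandwidth/2]``.
    """
    lam = spectrum.wavelengths
    for center, which in ((donor_lambda, "donor"), (acceptor_lambda, "acceptor")):
        if not lam[0] <= center <= lam[-1]:
            raise DomainError(f"{which} band center {center} nm outside spectrum support")
    donor = spectrum.band_integral(donor_lambda, bandwidth)
    acceptor = spectrum.band_integral(acceptor_lambda, bandwidth)
    if donor <= 0:
        raise DomainError("zero donor-band intensity: BRET ratio undefined")
    return acceptor / donor


def spectral_decompose(
    mixture: EmissionSpectrum,
    donor_ref: EmissionSpectrum,
    acceptor_ref: EmissionSpectrum,
) -> tuple[float, float, float]:
    """Two-component non-negative decomposition of a spectrum.

    Fits the mixture onto the two area-normalized reference spectra by
    non-negative least squares, then renormalizes the coefficients to
    fractions summing to 1.

    Returns
    -------
    (f_donor, f_acceptor, residual_norm)
        Photon fractions and the root-mean-square misfit of the NNLS fit.
    """
    from scipy.optimize import nnls

    grid = mixture.wavelengths
    d = donor_ref.resample(grid).normalized().intensities
    a = acceptor_ref.resample(grid).normalized().intensities
    dn, an = d / np.linalg.norm(d), a / np.linalg.norm(a)
    if np.linalg.norm(dn - an) < 1e-8:
        raise IllPosedError("donor and acceptor references are collinear")
    design = np.column_stack([d, a])
    coef, _ = nnls(design, mixture.intensities)
    total = coef.sum()
    if total <= 0:
        raise IllPosedError("NNLS returned all-zero coefficients")
    resid = design @ coef - mixture.intensities
    rms = float(np.sqrt(np.mean(resid**2)))
    return float(coef[0] / total), float(coef[1] / total), rms


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_spectrum_csv(path) -> EmissionSpectrum:
    """Read a 2-column (wavelength_nm, intensity) CSV with a header row."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ParameterError(f"{path}: expected 2 columns (wavelength_nm, intensity)")
    return EmissionSpectrum(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def write_spectrum_csv(path, spectrum: EmissionSpectrum) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectra_long_csv(path) -> dict[str, EmissionSpectrum]:
    """Read a long-format (reporter, wavelength_nm, intensity) CSV into a
    name -> spectrum mapping."""
    df = pd.read_csv(path)
    cols = list(df.columns[:3])
    out: dict[str, EmissionSpectrum] = {}
    for name, grp in df.groupby(cols[0], sort=False):
        grp = grp.sort_values(cols[1])
        out[str(name)] = EmissionSpectrum(grp[cols[1]].to_numpy(), grp[cols[2]].to_numpy())
    return out
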