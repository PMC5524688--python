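"""From solver populations to observable fluorescence.

Time-resolved: the ROH* and RO-* excited-state populations are weighted by
their radiative lifetimes and convolved with the instrument response
function (IRF) to produce what a TCSPC experiment records.  Steady-state:
the two emission bands (protonated ROH* blue, deprotonated RO-* red) are
synthesised as Gaussian bands whose area ratio is the RO-*/ROH* ratio, and
measured back by non-negative two-band unmixing.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "EmissionCurve",
    "IRF",
    "SteadyStateSpectrum",
    "BandModel",
    "apply_excited_state_decay",
    "gaussian_irf",
    "convolve_irf",
    "synth_spectrum",
    "measure_ratio",
    "UnderResolvedIRFError",
    "UnidentifiableModelError",
]

#: default radiative lifetimes (ns) for the protonated / deprotonated bands;
#: naphthol-family magnitudes, treated as known and fixed throughout.
DEFAULT_TAU_ROH = 8.0
DEFAULT_TAU_RO = 10.0


class UnderResolvedIRFError(ValueError):
    """IRF narrower than two channels cannot be represented on the grid."""


class UnidentifiableModelError(ValueError):
    """Band model degenerate: the two bands cannot be distinguished."""


@dataclass(frozen=True)
class EmissionCurve:
    """Relative emission intensity on a time grid (ns)."""

    times: np.ndarray
    intensity: np.ndarray
    species: str = "ROH*"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class IRF:
    """Discrete instrument response: normalized weights on a channel grid."""

    times: np.ndarray
    weights: np.ndarray
    fwhm: float
    t0: float

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("IRF weights must sum to 1 within 1e-9")
        if np.any(self.weights < 0):
            raise ValueError("IRF weights must be non-negative")


@dataclass(frozen=True)
class SteadyStateSpectrum:
    """Relative emission intensity on a wavelength grid (nm)."""

    wavelengths: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "intensity", np.asarray(self.intensity, dtype=float))
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be non-negative")


@dataclass(frozen=True)
class BandModel:
    """Two Gaussian emission bands (centers and widths in nm).

    Widths are Gaussian standard deviations.  ``bathochromic_shift`` moves
    the RO-* band to the red, the signature of a polarity change at the
    probe's binding site.
    """

    roh_center: float
    ro_center: float
    roh_width: float = 20.0
    ro_width: float = 20.0
    bathochromic_shift: float = 0.0

    def __post_init__(self):
        if self.roh_width <= 0 or self.ro_width <= 0:
            raise ValueError("band widths must be > 0")
        if self.ro_center <= self.roh_center:
            raise ValueError("RO-* band must lie to the red of the ROH* band")

    def shifted(self, extra_nm: float) -> "BandModel":
        return replace(self, bathochromic_shift=self.bathochromic_shift + extra_nm)

    def basis(self, wavelengths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Unit-area band profiles evaluated on the wavelength grid."""
        wl = np.asarray(wavelengths, dtype=float)
        ro_c = self.ro_center + self.bathochromic_shift
        for c, w in ((self.roh_center, self.roh_width), (ro_c, self.ro_width)):
            if not (wl[0] <= c <= wl[-1]):
                raise ValueError(f"band center {c} nm outside the wavelength grid")
        roh = np.exp(-0.5 * ((wl - self.roh_center) / self.roh_width) ** 2)
        ro = np.exp(-0.5 * ((wl - ro_c) / self.ro_width) ** 2)
        roh /= self.roh_width * np.sqrt(2.0 * np.pi)
        ro /= self.ro_width * np.sqrt(2.0 * np.pi)
        return roh, ro


def apply_excited_state_decay(trace, tau_roh: float = DEFAULT_TAU_ROH,
                              tau_ro: float = DEFAULT_TAU_RO):
    """Weight solver populations by the excited-state radiative decays.

    I_ROH(t) = P_bound(t) e^{-t/tau_roh};  I_RO(t) = (1 - P_bound) e^{-t/tau_ro}.
    Returns the (ROH*, RO-*) pair of :class:`EmissionCurve`.
    """
    if tau_roh <= 0 or tau_ro <= 0:
        raise ValueError("lifetimes must be > 0")
    t = np.asarray(trace.times, dtype=float)
    i_roh = trace.p_bound * np.exp(-t / tau_roh)
    i_ro = (1.0 - trace.p_bound) * np.exp(-t / tau_ro)
    return (
        EmissionCurve(times=t, intensity=np.clip(i_roh, 0.0, None), species="ROH*"),
        EmissionCurve(times=t, intensity=np.clip(i_ro, 0.0, None), species="RO-*"),
    )


def gaussian_irf(fwhm: float, t0: float, channel_width: float,
                 n_channels: int) -> IRF:
    """Discretised Gaussian IRF, renormalized to unit sum.

    Emulates the ~1 ns pulse of an LED excitation source sampled on the
    TCSPC channel grid.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be > 0")
    if fwhm < 2.0 * channel_width:
        raise UnderResolvedIRFError(
            f"fwhm {fwhm} ns under-resolved at channel width {channel_width} ns")
    times = np.arange(n_channels) * channel_width
    if not (times[0] <= t0 <= times[-1]):
        raise ValueError("t0 must lie inside the channel window")
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    w = np.exp(-0.5 * ((times - t0) / sigma) ** 2)
    w /= w.sum()
    return IRF(times=times, weights=w, fwhm=fwhm, t0=t0)


def convolve_irf(curve: EmissionCurve, irf: IRF) -> EmissionCurve:
    """Causal discrete convolution of an emission curve with the IRF.

    Grids must match channel-for-channel; a unit-sum IRF preserves the
    integrated intensity up to the tail truncated by the finite window.
    """
    if curve.times.shape != irf.times.shape or not np.allclose(
            curve.times, irf.times, rtol=0, atol=1e-9):
        raise ValueError("curve and IRF must share one channel grid")
    full = np.convolve(curve.intensity, irf.weights)
    out = full[: curve.times.size]
    return EmissionCurve(times=curve.times, intensity=np.clip(out, 0.0, None),
                         species=curve.species)


def synth_spectrum(ratio: float, bands: BandModel,
                   wavelengths: np.ndarray) -> SteadyStateSpectrum:
    """Two-band spectrum with RO-*/ROH* band-area ratio ``ratio``."""
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    wl = np.asarray(wavelengths, dtype=float)
    roh, ro = bands.basis(wl)
    return SteadyStateSpectrum(wavelengths=wl, intensity=roh + ratio * ro)


def measure_ratio(spectrum: SteadyStateSpectrum, bands: BandModel,
                  mode: str = "area") -> float:
    """RO-*/ROH* ratio by non-negative least-squares two-band unmixing.

    ``mode="area"`` returns the band-area ratio (the default convention);
    ``mode="peak"`` the apex-height ratio of the fitted bands.
    """
    wl = spectrum.wavelengths
    roh, ro = bands.basis(wl)
    if np.allclose(roh, ro, rtol=1e-12, atol=1e-15):
        raise UnidentifiableModelError("identical bands cannot be unmixed")
    design = np.column_stack([roh, ro])
    coef, _ = nnls(design, spectrum.intensity)
    a_roh, a_ro = coef
    if a_roh <= 0:
        return np.inf if a_ro > 0 else 0.0
    if mode == "area":
        return float(a_ro / a_roh)
    if mode == "peak":
        peak_roh = a_roh / (bands.roh_width * np.sqrt(2 * np.pi))
        peak_ro = a_ro / (bands.ro_width * np.sqrt(2 * np.pi))
        return float(peak_ro / peak_roh)
    raise ValueError(f"unknown mode {mode!r}")
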