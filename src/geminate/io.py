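"""Delimited-text readers and writers for decays, IRFs and spectra.

All files are two-column text ('#'-prefixed header lines; comma or
whitespace separated): ``time_ns  counts`` for TCSPC histograms and
``wavelength_nm  intensity`` for steady-state spectra.  Round trips are
lossless for integer counts and 1e-9-relative for spectra.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .signal_model import IRF, SteadyStateSpectrum
from .synthetic_data import TCSPCHistogram

__all__ = [
    "ParseError",
    "read_histogram",
    "write_histogram",
    "read_spectrum",
    "write_spectrum",
    "irf_from_histogram",
]


class ParseError(ValueError):
    """Malformed data file; carries the offending line number."""

    def __init__(self, path, line_no: int, message: str):
        self.path = str(path)
        self.line_no = line_no
        super().__init__(f"{path}:{line_no}: {message}")


def _read_two_columns(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    headers: list[str] = []
    xs: list[float] = []
    ys: list[float] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                headers.append(stripped)
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(path, line_no, f"expected 2 columns, got {len(parts)}")
            try:
                x, y = float(parts[0]), float(parts[1])
            except ValueError:
                raise ParseError(path, line_no, f"non-numeric value in {parts}") from None
            xs.append(x)
            ys.append(y)
    if not xs:
        raise ParseError(path, 0, "no data rows")
    return headers, np.asarray(xs), np.asarray(ys)


def _check_axis(path, x: np.ndarray, what: str):
    bad = np.nonzero(np.diff(x) <= 0)[0]
    if bad.size:
        raise ParseError(path, int(bad[0]) + 2, f"{what} axis not strictly increasing")


def read_histogram(path) -> TCSPCHistogram:
    """Read a TCSPC histogram (time_ns, counts); counts must be integers >= 0."""
    headers, t, c = _read_two_columns(path)
    _check_axis(path, t, "time")
    neg = np.nonzero(c < 0)[0]
    if neg.size:
        raise ParseError(path, int(neg[0]) + 1 + len(headers),
                         f"negative count {c[neg[0]]}")
    frac = np.nonzero(np.abs(c - np.rint(c)) > 1e-9)[0]
    if frac.size:
        raise ParseError(path, int(frac[0]) + 1 + len(headers),
                         f"non-integer count {c[frac[0]]}")
    hist = TCSPCHistogram(times=t, counts=c.astype(np.int64), irf=None,
                          peak_target=float(c.max()), seed=None)
    object.__setattr__(hist, "headers", headers)
    return hist


def write_histogram(hist: TCSPCHistogram, path, headers: list[str] | None = None):
    path = Path(path)
    if headers is None:
        headers = getattr(hist, "headers", None) or ["# time_ns counts"]
    with open(path, "w") as fh:
        for h in headers:
            fh.write(h.rstrip("\n") + "\n")
        for t, c in zip(hist.times, hist.counts):
            fh.write(f"{t:.6f} {int(c)}\n")


def read_spectrum(path) -> SteadyStateSpectrum:
    """Read a steady-state spectrum (wavelength_nm, intensity >= 0)."""
    headers, wl, inten = _read_two_columns(path)
    _check_axis(path, wl, "wavelength")
    neg = np.nonzero(inten < 0)[0]
    if neg.size:
        raise ParseError(path, int(neg[0]) + 1 + len(headers),
                         f"negative intensity {inten[neg[0]]}")
    spec = SteadyStateSpectrum(wavelengths=wl, intensity=inten)
    object.__setattr__(spec, "headers", headers)
    return spec


def write_spectrum(spectrum: SteadyStateSpectrum, path,
                   headers: list[str] | None = None):
    path = Path(path)
    if headers is None:
        headers = getattr(spectrum, "headers", None) or ["# wavelength_nm intensity"]
    with open(path, "w") as fh:
        for h in headers:
            fh.write(h.rstrip("\n") + "\n")
        for wl, y in zip(spectrum.wavelengths, spectrum.intensity):
            fh.write(f"{wl:.6f} {y:.12g}\n")


def irf_from_histogram(hist: TCSPCHistogram) -> IRF:
    """Build a normalized IRF from a measured scatter histogram.

    The FWHM is estimated by linear interpolation at half maximum and t0
    taken as the count-weighted centroid.
    """
    c = np.asarray(hist.counts, dtype=float)
    if c.sum() <= 0:
        raise ValueError("IRF histogram has no counts")
    w = c / c.sum()
    t = hist.times
    t0 = float(np.sum(t * w))
    half = c.max() / 2.0
    above = np.nonzero(c >= half)[0]
    fwhm = float(t[above[-1]] - t[above[0]]) if above.size > 1 else hist.channel_width
    fwhm = max(fwhm, 2.0 * hist.channel_width)
    return IRF(times=t, weights=w, fwhm=fwhm, t0=t0)
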