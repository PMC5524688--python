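"""Synthetic inputs for the whole pipeline.

The experimental observables are not deposited, so everything the analysis
consumes is generated here: TCSPC photon-count histograms with a measured-
style IRF and Poisson counting noise, two-band steady-state spectra at the
published RO-*/ROH* ratios, the four-photoacid parameter registry, and
sigmoidal amyloidogenesis ratio time-courses.

Every generator is a pure function of its arguments including the seed.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml
from scipy.optimize import least_squares

from .dse_core import SolverConfig
from .signal_model import BandModel, EmissionCurve, IRF, convolve_irf

__all__ = [
    "PhotoacidSpec",
    "TCSPCHistogram",
    "AmyloidTrace",
    "photoacid_registry",
    "make_tcspc",
    "amyloid_trace",
    "fit_amyloid_kinetics",
    "DEFAULT_CHANNEL_WIDTH",
    "DEFAULT_N_CHANNELS",
]

#: TCSPC acquisition window: 0-200 ns in 0.055 ns channels (~3640 channels),
#: wide enough that the t^{-d/2} tail is observable above a ~1 count/channel
#: background at 1e4 peak counts.
DEFAULT_CHANNEL_WIDTH = 0.055
DEFAULT_N_CHANNELS = 3640
DEFAULT_BACKGROUND = 1.0


@dataclass(frozen=True)
class PhotoacidSpec:
    """One photoacid of the 2-naphthol family.

    Holds the published kinetic parameter sets (free in buffer and bound to
    insulin fibrils), the steady-state band model and ratios, and the
    charge/acidity metadata.  ``k_PT_fast`` is the fast-component rate from
    the 3-exponential reconvolution where the direct estimate is
    IRF-limited (None when not applicable).
    """

    name: str
    anion_charge_Z1: int
    pKa: float
    pKa_star: float
    collection_wavelength_nm: float
    buffer: SolverConfig
    fibrils: SolverConfig
    bands: BandModel
    ratio_free: float
    ratio_bound: float
    bathochromic_shift_bound_nm: float
    k_PT_fast: float | None = None

    def config(self, condition: str) -> SolverConfig:
        if condition in ("buffer", "In pH7", "free"):
            return self.buffer
        if condition in ("fibrils", "+fibrils", "bound"):
            return self.fibrils
        raise KeyError(f"unknown condition {condition!r}")


def _load_table() -> dict:
    ref = importlib.resources.files("geminate.data") / "photoacid_parameters.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def _solver_config(row: dict, z1: int) -> SolverConfig:
    return SolverConfig(
        contact_radius_a=row["a"],
        debye_radius_RD=row["R_D"],
        D_cm2_per_s=row["D"],
        dimensionality_d=row["d"],
        k_PT=row["k_PT"],
        k_a=row["k_a"],
        anion_charge_Z1=z1,
        proton_charge_Z2=1,
    )


def photoacid_registry() -> dict[str, PhotoacidSpec]:
    """The four-photoacid registry (2N, 2N6S, 2N8S, 2N6,8S).

    Values are read from the checked-in parameter table
    (``data/photoacid_parameters.yaml``); the test suite asserts them
    against independently frozen constants, so any edit to the table
    breaks a test.
    """
    raw = _load_table()
    registry: dict[str, PhotoacidSpec] = {}
    for name, row in raw["photoacids"].items():
        z1 = int(row["anion_charge_Z1"])
        bands = BandModel(
            roh_center=float(row["collection_wavelength_nm"]),
            ro_center=float(row["ro_band_center_nm"]),
            roh_width=float(row["band_width_nm"]),
            ro_width=float(row["band_width_nm"]),
        )
        registry[name] = PhotoacidSpec(
            name=name,
            anion_charge_Z1=z1,
            pKa=float(row["pKa"]),
            pKa_star=float(row["pKa_star"]),
            collection_wavelength_nm=float(row["collection_wavelength_nm"]),
            buffer=_solver_config(row["buffer"], z1),
            fibrils=_solver_config(row["fibrils"], z1),
            bands=bands,
            ratio_free=float(row["ratio_free"]),
            ratio_bound=float(row["ratio_bound"]),
            bathochromic_shift_bound_nm=float(row["bathochromic_shift_bound_nm"]),
            k_PT_fast=float(row["k_PT_fast"]) if "k_PT_fast" in row else None,
        )
    if len(registry) != 4:
        raise RuntimeError("registry must hold exactly 4 photoacids")
    return registry


@dataclass(frozen=True)
class TCSPCHistogram:
    """A TCSPC decay: photon counts per channel, with its paired IRF."""

    times: np.ndarray
    counts: np.ndarray
    irf: IRF | None
    peak_target: float
    seed: int | None
    background: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        widths = np.diff(self.times)
        if widths.size and not np.allclose(widths, widths[0], rtol=1e-6):
            raise ValueError("channel width must be uniform")

    @property
    def channel_width(self) -> float:
        return float(self.times[1] - self.times[0])


def make_tcspc(curve: EmissionCurve, irf: IRF, peak_counts: float,
               background: float = DEFAULT_BACKGROUND, seed: int = 0,
               noise: bool = True) -> TCSPCHistogram:
    """Turn an emission curve into a photon-count histogram.

    The IRF-convolved curve is scaled so its expected peak equals
    ``peak_counts``; a flat background is added; counts are Poisson draws
    when ``noise`` is on and deterministically rounded expectations when
    off.  Reproducible for a fixed seed.
    """
    if peak_counts <= 0:
        raise ValueError("peak_counts must be > 0")
    model = convolve_irf(curve, irf).intensity
    top = model.max()
    if top <= 0:
        raise ValueError("emission curve convolves to zero signal")
    expected = (peak_counts - background) * model / top + background
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected)
    else:
        counts = np.rint(expected).astype(np.int64)
    return TCSPCHistogram(times=curve.times, counts=counts, irf=irf,
                          peak_target=peak_counts, seed=seed,
                          background=background)


@dataclass(frozen=True)
class AmyloidTrace:
    """RO-*/ROH* ratio of a probe followed through amyloid formation."""

    times: np.ndarray          # minutes
    values: np.ndarray         # dimensionless ratio
    ratio_free: float
    ratio_bound: float
    lag_min: float
    rate_per_min: float
    noise_sd: float
    seed: int | None


def _logistic(t, lower, upper, rate, t_mid):
    return lower + (upper - lower) / (1.0 + np.exp(-rate * (t - t_mid)))


def amyloid_trace(ratio_free: float, ratio_bound: float, lag_min: float,
                  rate_per_min: float, times: np.ndarray,
                  noise_sd: float = 0.0, seed: int = 0) -> AmyloidTrace:
    """Sigmoidal ratio time-course of amyloid formation.

    Logistic interpolation from the free-probe ratio to the fibril-bound
    ratio, with the inflection placed two rate constants after the lag
    time (so the lag phase ends where growth takes off), plus additive
    Gaussian noise.
    """
    if lag_min < 0:
        raise ValueError("lag must be >= 0")
    if rate_per_min <= 0:
        raise ValueError("rate must be > 0")
    t = np.asarray(times, dtype=float)
    t_mid = lag_min + 2.0 / rate_per_min
    y = _logistic(t, ratio_free, ratio_bound, rate_per_min, t_mid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return AmyloidTrace(times=t, values=y, ratio_free=ratio_free,
                        ratio_bound=ratio_bound, lag_min=lag_min,
                        rate_per_min=rate_per_min, noise_sd=noise_sd, seed=seed)


def fit_amyloid_kinetics(trace: AmyloidTrace, seed: int = 0) -> dict:
    """Four-parameter logistic fit of an amyloidogenesis trace.

    Returns lag time (t_mid - 2/rate), growth rate, the two plateau
    levels, approximate standard errors, and quality flags
    (``rate_unidentifiable`` for flat traces, ``poor_fit`` when the trace
    is not monotone beyond the fitted noise level).
    """
    t = trace.times
    y = trace.values
    if t.size < 6:
        raise ValueError("need at least 6 time points")
    span = y.max() - y.min()
    scale = max(span, 1e-12)
    first, last = float(y[0]), float(y[-1])

    def resid(p):
        return _logistic(t, p[0], p[1], p[2], p[3]) - y

    t_range = t[-1] - t[0]
    x0 = np.array([first, last, 4.0 / max(t_range, 1e-9), t[0] + 0.5 * t_range])
    lo = [y.min() - 2 * scale, y.min() - 2 * scale, 1e-6 / max(t_range, 1e-9), t[0] - t_range]
    hi = [y.max() + 2 * scale, y.max() + 2 * scale, 1e3, t[-1] + t_range]
    sol = least_squares(resid, x0, bounds=(lo, hi))
    lower, upper, rate, t_mid = sol.x
    res = sol.fun
    dof = max(t.size - 4, 1)
    noise_hat = float(np.sqrt(res @ res / dof))

    # approximate standard errors from the Jacobian at the optimum
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * noise_hat**2
        stderr = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        stderr = np.full(4, np.nan)

    flags: list[str] = []
    if abs(upper - lower) < 5.0 * max(noise_hat, 1e-12):
        flags.append("rate_unidentifiable")
    else:
        # monotonicity beyond noise: steps against the overall trend
        trend = np.sign(upper - lower)
        backward = trend * np.diff(y) < -5.0 * noise_hat
        if np.any(backward):
            flags.append("poor_fit")

    return {
        "lag_min": float(t_mid - 2.0 / rate),
        "rate_per_min": float(rate),
        "plateau_start": float(lower),
        "plateau_end": float(upper),
        "t_mid": float(t_mid),
        "noise_sd_hat": noise_hat,
        "stderr": {"plateau_start": float(stderr[0]), "plateau_end": float(stderr[1]),
                   "rate_per_min": float(stderr[2]), "t_mid": float(stderr[3])},
        "flags": flags,
        "converged": bool(sol.success),
    }
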