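"""Spherically-symmetric Debye-Smoluchowski solver for reversible geminate
proton recombination.

After photoexcitation a photoacid ROH* dissociates with rate ``k_PT`` into a
contact ion pair [RO-* ... H+].  The proton then diffuses in the attractive
Coulomb field of the anion, described by the Debye-Smoluchowski equation in a
(possibly fractional) dimensionality ``d``:

    dp/dt = r^(1-d) d/dr [ r^(d-1) D ( dp/dr + p dV/dr ) ],   V(r) = -R_D / r

with V in units of k_B T and R_D the Debye radius.  At the contact radius
``a`` the pair density is coupled to the bound state through the
back-reaction (radiation) boundary condition: the bound population P(t) obeys

    dP/dt = -k_PT P + k_a A_d(a) p(a, t)

where ``k_a`` is an intrinsic recombination velocity (Å/ns) and
A_d(a) = (2 pi^(d/2) / Gamma(d/2)) a^(d-1) is the generalized contact surface
measure.  The pair density is normalized per generalized volume
dV_d = A_d(r) dr, so that P(t) + integral p dV_d is conserved exactly for any
real d.  The outer boundary is reflecting and placed far enough to emulate an
unbounded medium.

Radiative (excited-state lifetime) decay is deliberately not part of the
solver; it is applied multiplicatively downstream so that probability
conservation remains a strict invariant of every run.

All lengths are Å and all times ns internally; diffusion coefficients are
accepted in cm^2/s and converted exactly once at construction
(1 cm^2/s = 1e7 Å^2/ns).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc

from ._kernels import brownian_bound_counts, evolve_cn

__all__ = [
    "MediumContext",
    "SolverConfig",
    "GridSpec",
    "KineticTrace",
    "debye_radius",
    "solve_dse",
    "asymptotic_roh",
    "smoluchowski_survival_oracle",
    "brownian_geminate_oracle",
    "DomainTooSmallError",
    "NumericalFailureError",
]

# CODATA 2018 exact/recommended values (SI)
ELEMENTARY_CHARGE = 1.602176634e-19  # C
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m
BOLTZMANN = 1.380649e-23  # J/K

CM2_PER_S_TO_A2_PER_NS = 1.0e7


class DomainTooSmallError(RuntimeError):
    """Significant pair density reached the outer (reflecting) boundary."""


class NumericalFailureError(RuntimeError):
    """Mass-balance defect exceeded the configured tolerance."""


@dataclass(frozen=True)
class MediumContext:
    """Dielectric medium for the Coulomb interaction.

    Defaults are water at 20 degC, the condition of the buffered
    measurements (relative permittivity 80.1, T = 293.15 K).
    """

    relative_permittivity: float = 80.1
    temperature: float = 293.15

    elementary_charge: float = ELEMENTARY_CHARGE
    vacuum_permittivity: float = VACUUM_PERMITTIVITY
    boltzmann: float = BOLTZMANN

    def __post_init__(self):
        if not (np.isfinite(self.relative_permittivity) and self.relative_permittivity > 0):
            raise ValueError("relative_permittivity must be finite and > 0")
        if not (np.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError("temperature must be finite and > 0")


def debye_radius(z1: int, z2: int, medium: MediumContext | None = None) -> float:
    """Debye radius |Z1 Z2| e^2 / (4 pi eps0 eps_r kB T), in Å.

    The distance at which the Coulomb attraction between the dissociated
    anion (charge ``z1`` in elementary units) and the proton (``z2``)
    equals the thermal energy.  Linear in |z1 z2|; zero if either charge
    is zero.
    """
    medium = medium or MediumContext()
    for z in (z1, z2):
        if not np.isfinite(z):
            raise ValueError("charges must be finite")
    e = medium.elementary_charge
    r_m = (
        abs(z1 * z2)
        * e**2
        / (4.0 * math.pi * medium.vacuum_permittivity * medium.relative_permittivity
           * medium.boltzmann * medium.temperature)
    )
    return r_m * 1e10


@dataclass(frozen=True)
class SolverConfig:
    """Physical parameters of the geminate recombination problem.

    Parameters
    ----------
    contact_radius_a : float
        Reaction-sphere radius a, Å.
    debye_radius_RD : float
        Debye radius R_D, Å (0 means no Coulomb potential).
    D_cm2_per_s : float
        Proton diffusion coefficient, cm^2/s (converted to Å^2/ns once,
        at construction; see :attr:`diffusion_D`).
    dimensionality_d : float
        Effective dimensionality of the proton's diffusion space,
        real in (0.5, 3].
    k_PT : float
        Excited-state proton-transfer (dissociation) rate, 1/ns.
    k_a : float
        Intrinsic contact recombination velocity, Å/ns; the total
        recombination flux is k_a * A_d(a) * p(a, t).
    anion_charge_Z1, proton_charge_Z2 : int
        Charges in elementary units (used for Debye-radius bookkeeping).
    """

    contact_radius_a: float
    debye_radius_RD: float
    D_cm2_per_s: float
    dimensionality_d: float
    k_PT: float
    k_a: float
    anion_charge_Z1: int = 1
    proton_charge_Z2: int = 1
    diffusion_D: float = field(init=False)  # Å^2/ns

    def __post_init__(self):
        if not self.contact_radius_a > 0:
            raise ValueError("contact_radius_a must be > 0")
        if self.debye_radius_RD < 0:
            raise ValueError("debye_radius_RD must be >= 0")
        if not self.D_cm2_per_s > 0:
            raise ValueError("D must be > 0")
        if not (0.5 < self.dimensionality_d <= 3.0):
            raise ValueError("dimensionality_d must lie in (0.5, 3]")
        if self.k_PT < 0 or self.k_a < 0:
            raise ValueError("rates must be >= 0")
        object.__setattr__(self, "diffusion_D", self.D_cm2_per_s * CM2_PER_S_TO_A2_PER_NS)

    @property
    def tau_PT(self) -> float:
        """Proton-transfer time 1/k_PT, ns (inf when k_PT = 0)."""
        return math.inf if self.k_PT == 0 else 1.0 / self.k_PT

    @property
    def tau_a(self) -> float:
        """Recombination time 1/k_a, ns/Å velocity inverse (inf when k_a = 0)."""
        return math.inf if self.k_a == 0 else 1.0 / self.k_a

    @classmethod
    def from_flat(cls, mapping: dict) -> "SolverConfig":
        """Build from the flat structured-text key set used by the pipeline."""
        return cls(
            contact_radius_a=float(mapping["a_angstrom"]),
            debye_radius_RD=float(mapping["R_D_angstrom"]),
            D_cm2_per_s=float(mapping["D_cm2_per_s"]),
            dimensionality_d=float(mapping["dimensionality_d"]),
            k_PT=float(mapping["k_PT_per_ns"]),
            k_a=float(mapping["k_a_angstrom_per_ns"]),
            anion_charge_Z1=int(mapping.get("Z1", 1)),
            proton_charge_Z2=int(mapping.get("Z2", 1)),
        )

    def to_flat(self) -> dict:
        """Flat key/value form (exact pipeline key names)."""
        return {
            "a_angstrom": self.contact_radius_a,
            "R_D_angstrom": self.debye_radius_RD,
            "D_cm2_per_s": self.D_cm2_per_s,
            "dimensionality_d": self.dimensionality_d,
            "k_PT_per_ns": self.k_PT,
            "k_a_angstrom_per_ns": self.k_a,
            "Z1": self.anion_charge_Z1,
            "Z2": self.proton_charge_Z2,
        }

    def contact_surface(self) -> float:
        """Generalized contact surface A_d(a) = sigma_d a^(d-1)."""
        d = self.dimensionality_d
        sigma = 2.0 * math.pi ** (d / 2.0) / math.gamma(d / 2.0)
        return sigma * self.contact_radius_a ** (d - 1.0)


def default_r_max(config: SolverConfig, t_max: float) -> float:
    """Outer-boundary radius emulating an unbounded medium."""
    return max(
        20.0 * config.debye_radius_RD,
        10.0 * math.sqrt(2.0 * config.diffusion_D * t_max),
        200.0,
    )


@dataclass(frozen=True)
class GridSpec:
    """Numerical grid: geometric radial mesh and a ramped time step.

    ``dt`` is the initial time step; steps grow geometrically with a
    per-step factor proportional to ``dt`` (g - 1 = 0.015 dt / 1e-4), so
    the local step is ~1.5% of elapsed time at the default resolution and
    halving ``dt`` halves the step everywhere.
    """

    r_max: float
    t_max: float
    output_times: np.ndarray
    n_r: int = 500
    dt: float = 1e-4

    def __post_init__(self):
        object.__setattr__(self, "output_times", np.asarray(self.output_times, dtype=float))
        if self.n_r < 100:
            raise ValueError("n_r must be >= 100")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if self.output_times.ndim != 1 or np.any(np.diff(self.output_times) <= 0):
            raise ValueError("output_times must be strictly increasing")
        if self.output_times[-1] > self.t_max * (1 + 1e-12):
            raise ValueError("output_times must not exceed t_max")

    @classmethod
    def auto(cls, config: SolverConfig, t_max: float,
             output_times: np.ndarray | None = None, n_r: int = 500,
             dt: float = 1e-4, r_max: float | None = None) -> "GridSpec":
        if output_times is None:
            output_times = np.geomspace(1e-3, t_max, 200)
        if r_max is None:
            r_max = default_r_max(config, t_max)
        if r_max <= config.contact_radius_a:
            raise ValueError("r_max must exceed the contact radius")
        return cls(r_max=r_max, t_max=t_max, output_times=output_times,
                   n_r=n_r, dt=dt)

    def refined(self) -> "GridSpec":
        """Grid with halved time step and doubled radial resolution."""
        return replace(self, n_r=2 * self.n_r, dt=self.dt / 2.0)


@dataclass(frozen=True)
class KineticTrace:
    """Solver output: bound-state survival and contact pair density.

    ``p_bound`` is the ROH* survival probability P(t); ``p_contact`` the
    pair density at the first radial cell (per generalized volume);
    ``separated_fraction`` is 1 - P(t).  ``stderr`` is populated only by
    the stochastic (Brownian) estimator.
    """

    times: np.ndarray
    p_bound: np.ndarray
    p_contact: np.ndarray
    separated_fraction: np.ndarray
    mass_balance_error: float
    config: SolverConfig
    stderr: np.ndarray | None = None


def _radial_faces(a: float, r_max: float, n_r: int) -> np.ndarray:
    """Geometric face positions clustered at the contact radius.

    First cell width scales as a/n_r so doubling n_r refines the contact
    region as well as the bulk.
    """
    h0 = a / n_r
    span = r_max - a
    n_cells = n_r

    def total(g):
        return h0 * (g**n_cells - 1.0) / (g - 1.0) - span

    if total(1.0 + 1e-12) > 0:  # uniform grid already wider than span
        return np.linspace(a, r_max, n_cells + 1)
    g = brentq(total, 1.0 + 1e-12, 2.0, xtol=1e-14)
    j = np.arange(n_cells + 1)
    faces = a + h0 * (np.power(g, j) - 1.0) / (g - 1.0)
    faces[-1] = r_max
    return faces


def _bernoulli(x: np.ndarray) -> np.ndarray:
    """B(x) = x / (exp(x) - 1), the exponential-fitting flux weight."""
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = x[nz] / np.expm1(x[nz])
    return out


def _build_operator(config: SolverConfig, faces: np.ndarray):
    """Tridiagonal generator L for [P, p_0 ... p_{N-1}] and volume weights.

    Interior fluxes use Scharfetter-Gummel exponential fitting so the
    discrete equilibrium is exactly the Boltzmann profile and the scheme
    stays stable for strong Coulomb attraction.
    """
    d = config.dimensionality_d
    sigma = 2.0 * math.pi ** (d / 2.0) / math.gamma(d / 2.0)
    centers = 0.5 * (faces[:-1] + faces[1:])
    vol = sigma * (faces[1:] ** d - faces[:-1] ** d) / d
    area_faces = sigma * faces ** (d - 1.0)
    area_a = sigma * config.contact_radius_a ** (d - 1.0)

    v = -config.debye_radius_RD / centers  # k_B T units
    dv = np.diff(v)
    c = config.diffusion_D * area_faces[1:-1] / np.diff(centers)
    # outward flux through a face: c * (B(dV) p_in - B(-dV) p_out), whose
    # discrete equilibrium is exactly the Boltzmann ratio p_out/p_in = e^{-dV}
    b_minus = _bernoulli(dv)   # weight of the inner cell
    b_plus = _bernoulli(-dv)   # weight of the outer cell

    n = centers.size
    m = n + 1
    low = np.zeros(m)
    diag = np.zeros(m)
    up = np.zeros(m)

    # bound state
    diag[0] = -config.k_PT
    up[0] = config.k_a * area_a
    # first cell: exchange with the bound state + flux through face 1
    low[1] = config.k_PT / vol[0]
    diag[1] = (-config.k_a * area_a - c[0] * b_minus[0]) / vol[0]
    up[1] = c[0] * b_plus[0] / vol[0]
    # interior cells
    i = np.arange(1, n - 1)
    low[i + 1] = c[i - 1] * b_minus[i - 1] / vol[i]
    diag[i + 1] = -(c[i - 1] * b_plus[i - 1] + c[i] * b_minus[i]) / vol[i]
    up[i + 1] = c[i] * b_plus[i] / vol[i]
    # last cell: reflecting outer face
    low[n] = c[n - 2] * b_minus[n - 2] / vol[n - 1]
    diag[n] = -c[n - 2] * b_plus[n - 2] / vol[n - 1]

    weights = np.concatenate(([1.0], vol))
    return low, diag, up, vol, centers, weights


def _time_steps(dt0: float, t_max: float) -> np.ndarray:
    growth = 1.0 + 0.015 * (dt0 / 1e-4)
    dts = []
    t = 0.0
    dt = dt0
    while t < t_max:
        dt = min(dt, t_max - t)
        dts.append(dt)
        t += dt
        dt *= growth
    return np.asarray(dts)


def solve_dse(config: SolverConfig, grid: GridSpec,
              initial: str | tuple[str, float] = "bound",
              mass_tolerance: float = 1e-4) -> KineticTrace:
    """Solve the back-reaction Debye-Smoluchowski problem.

    Parameters
    ----------
    initial : "bound" or ("delta", r0)
        "bound" starts fully associated (P(0) = 1), the photoexcitation
        condition.  ("delta", r0) starts with the pair at separation r0
        (used by the validation oracles).
    """
    a = config.contact_radius_a
    if initial == "bound" and config.k_PT == 0.0:
        # nothing ever dissociates: P == 1 identically
        t_out = grid.output_times
        ones = np.ones_like(t_out)
        return KineticTrace(times=t_out, p_bound=ones,
                            p_contact=np.zeros_like(t_out),
                            separated_fraction=np.zeros_like(t_out),
                            mass_balance_error=0.0, config=config)
    faces = _radial_faces(a, grid.r_max, grid.n_r)
    low, diag, up, vol, centers, weights = _build_operator(config, faces)

    m = centers.size + 1
    x0 = np.zeros(m)
    if initial == "bound":
        x0[0] = 1.0
    else:
        kind, r0 = initial
        if kind != "delta":
            raise ValueError(f"unknown initial condition {initial!r}")
        if r0 < a:
            raise ValueError("delta initial condition requires r0 >= a")
        j = int(np.searchsorted(centers, r0))
        j = min(max(j, 1), centers.size - 1)
        # split between neighbouring cells so the mean radius is exactly r0
        w_hi = (r0 - centers[j - 1]) / (centers[j] - centers[j - 1])
        w_hi = min(max(w_hi, 0.0), 1.0)
        x0[j] = (1.0 - w_hi) / vol[j - 1]
        x0[j + 1] = w_hi / vol[j]

    dts = _time_steps(grid.dt, grid.t_max)
    t_int, p_b, p_c, mass_err, x_final = evolve_cn(low, diag, up, x0, dts, weights)

    if mass_err > mass_tolerance:
        raise NumericalFailureError(
            f"mass-balance defect {mass_err:.3e} exceeds tolerance {mass_tolerance:.1e}")
    free_mass = float(np.dot(vol, x_final[1:]))
    edge_mass = float(np.dot(vol[-5:], x_final[1 + centers.size - 5:]))
    if free_mass > 0 and edge_mass > 1e-6 * (free_mass + x_final[0]):
        raise DomainTooSmallError(
            f"pair density at the outer boundary ({edge_mass:.2e}) exceeds "
            f"1e-6 of the total; increase r_max")

    t_out = grid.output_times
    p_bound = np.interp(t_out, t_int, p_b)
    p_contact = np.interp(t_out, t_int, p_c)
    return KineticTrace(
        times=t_out,
        p_bound=p_bound,
        p_contact=p_contact,
        separated_fraction=1.0 - p_bound,
        mass_balance_error=float(mass_err),
        config=config,
    )


def bound_population(config: SolverConfig, times: np.ndarray,
                     n_r: int = 500, dt: float = 1e-4,
                     r_max: float | None = None) -> np.ndarray:
    """P_bound sampled on an arbitrary increasing time grid (t >= 0).

    Convenience wrapper around :func:`solve_dse` used by the forward
    model of the reconvolution fits; times may start at 0.
    """
    times = np.asarray(times, dtype=float)
    t_max = float(times[-1])
    pos = times[times > 0]
    out = pos if pos.size else np.array([t_max])
    grid = GridSpec.auto(config, t_max=t_max, output_times=out, n_r=n_r,
                         dt=dt, r_max=r_max)
    trace = solve_dse(config, grid)
    p = np.interp(times, np.concatenate(([0.0], trace.times)),
                  np.concatenate(([1.0], trace.p_bound)))
    return p


def asymptotic_roh(t: float | np.ndarray, config: SolverConfig) -> float | np.ndarray:
    """Long-time power-law intensity of the ROH* band.

    Evaluates pi a^2 k_a exp(-R_D/a) / (2 k_PT (pi D t)^{d/2}): the
    t^{-d/2} asymptotic law whose exponent encodes the dimensionality of
    the proton's diffusion space.  Undefined for k_PT = 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    if config.k_PT <= 0:
        raise ValueError("asymptotic form undefined for k_PT = 0")
    a = config.contact_radius_a
    val = (
        math.pi * a**2 * config.k_a * math.exp(-config.debye_radius_RD / a)
        / (2.0 * config.k_PT * (math.pi * config.diffusion_D * t) ** (config.dimensionality_d / 2.0))
    )
    return val if val.shape else float(val)


def smoluchowski_survival_oracle(a: float, D: float, r0: float,
                                 t: float | np.ndarray) -> float | np.ndarray:
    """Closed-form survival for free 3D diffusion with an absorbing sphere.

    S(t | r0) = 1 - (a/r0) erfc[(r0 - a) / sqrt(4 D t)]; D in Å^2/ns.
    Independent analytic reference for the solver's absorbing limit.
    """
    if r0 < a:
        raise ValueError("r0 must be >= a")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore"):
        arg = np.where(t > 0, (r0 - a) / np.sqrt(4.0 * D * t), np.inf)
    s = 1.0 - (a / r0) * erfc(arg)
    return s if s.shape else float(s)


def brownian_geminate_oracle(config: SolverConfig, n_particles: int, seed: int,
                             output_times: np.ndarray | None = None,
                             dt: float = 2e-4) -> KineticTrace:
    """Stochastic reference for P_bound(t): Euler-Maruyama walkers.

    Radial walkers in the Coulomb field with exactly-sampled dissociation
    dwell times and first-order reactive encounters at contact.  Returns a
    :class:`KineticTrace` whose ``stderr`` holds binomial standard errors.
    Deterministic for a fixed seed.
    """
    if n_particles < 10_000:
        raise ValueError("n_particles must be >= 1e4 for a meaningful estimate")
    if output_times is None:
        output_times = np.linspace(0.5, 3.0, 6)
    output_times = np.asarray(output_times, dtype=float)
    p_react = config.k_a * math.sqrt(math.pi * dt / config.diffusion_D)
    if p_react > 0.01:
        raise ValueError(
            f"per-encounter reaction probability {p_react:.3f} > 1%; reduce dt")
    counts = brownian_bound_counts(
        config.contact_radius_a, config.debye_radius_RD, config.diffusion_D,
        config.dimensionality_d, config.k_PT, config.k_a, dt,
        output_times, n_particles, seed)
    p = counts / n_particles
    se = np.sqrt(np.clip(p * (1.0 - p), 0.0, None) / n_particles)
    return KineticTrace(
        times=output_times,
        p_bound=p,
        p_contact=np.full_like(p, np.nan),
        separated_fraction=1.0 - p,
        mass_balance_error=0.0,
        config=config,
        stderr=se,
    )
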