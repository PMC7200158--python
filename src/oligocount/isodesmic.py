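"""Isodesmic (equal stepwise-K) self-association equilibrium.

A protomer P assembles head-to-tail into linear oligomers P_n, with the
same dissociation constant K for every monomer-addition step:

    [P_n] = m * (m / K)**(n - 1),    m = [P_1]

Truncating the series at a maximum order N and imposing (i) conservation
of protomers, sum(n * c_n) = c_tot, and (ii) a measured number-average
mass, M1 * sum(n * c_n) / sum(c_n) = M_avg, fixes the whole distribution
and hence K.  This is the model used to turn a SEC-MALS average mass of a
small, concentration-dependent oligomer (such as the Axin DAX domain)
into a protomer-protomer dissociation constant, K_D = m**2 / [dimer].

The solve is reduced to one dimension: with x = m / K, the average-mass
constraint

    sum_{n=1..N} n x**(n-1) / sum_{n=1..N} x**(n-1) = M_avg / M1

depends only on x and is strictly increasing from 1 (x -> 0) to N
(x -> inf), so a bracketed root find gives the unique solution; m then
follows from conservation and K = m / x.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "IsodesmicSystem",
    "SpeciesDistribution",
    "KdEstimate",
    "MalsSeries",
    "InfeasibleMassError",
    "solve_isodesmic",
    "predict_average_mass",
    "infinite_limit_kd",
    "convergence_table",
    "oligomer_count",
    "fit_kd_to_series",
]

#: residual tolerance on the reduced (1-D) average-mass equation
_X_TOL = 1e-12


class InfeasibleMassError(ValueError):
    """The observed average mass lies outside what the model can produce."""


@dataclass(frozen=True)
class IsodesmicSystem:
    """Definition of a truncated isodesmic equilibrium problem.

    Parameters
    ----------
    total_protomer_conc : float
        Total concentration of protomers across all species, in nM.
    monomer_mass : float
        Protomer mass M1 in kDa.
    max_order : int
        Largest oligomer size N included in the truncated series.
    """

    total_protomer_conc: float
    monomer_mass: float
    max_order: int

    def __post_init__(self) -> None:
        if self.total_protomer_conc <= 0:
            raise ValueError("total_protomer_conc must be > 0 nM")
        if self.monomer_mass <= 0:
            raise ValueError("monomer_mass must be > 0 kDa")
        if int(self.max_order) != self.max_order or self.max_order < 1:
            raise ValueError("max_order must be an integer >= 1")


@dataclass(frozen=True)
class SpeciesDistribution:
    """Solved per-oligomer concentrations c_1..c_N (nM)."""

    concentrations: np.ndarray
    monomer_mass: float

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, len(self.concentrations) + 1)

    @property
    def protomer_sum(self) -> float:
        """sum(n * c_n), total protomers bound in all species (nM)."""
        return float(np.sum(self.orders * self.concentrations))

    @property
    def number_average_mass(self) -> float:
        """M1 * sum(n c_n) / sum(c_n), the species-number-average (kDa)."""
        c = self.concentrations
        return float(self.monomer_mass * np.sum(self.orders * c) / np.sum(c))

    @property
    def weight_average_mass(self) -> float:
        """M1 * sum(n^2 c_n) / sum(n c_n) (kDa); the MALS convention."""
        c = self.concentrations
        n = self.orders
        return float(self.monomer_mass * np.sum(n**2 * c) / np.sum(n * c))

    @property
    def monomer_fraction_of_protomers(self) -> float:
        return float(self.concentrations[0] / self.protomer_sum)

    @property
    def monomer_fraction_of_species(self) -> float:
        return float(self.concentrations[0] / np.sum(self.concentrations))


@dataclass(frozen=True)
class KdEstimate:
    """Inferred stepwise dissociation constant with solver diagnostics."""

    kd: float
    max_order: int
    residual: float
    monomer_fraction_of_protomers: float


@dataclass(frozen=True)
class MalsSeries:
    """A SEC-MALS concentration/average-mass series.

    ``detector_conc`` is the protomer concentration at the detector in uM
    (the directly measured quantity); ``average_mass`` in kDa.
    """

    detector_conc: np.ndarray
    average_mass: np.ndarray
    injected_conc: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.detector_conc, dtype=float)
        m = np.asarray(self.average_mass, dtype=float)
        object.__setattr__(self, "detector_conc", c)
        object.__setattr__(self, "average_mass", m)
        if c.shape != m.shape or c.ndim != 1 or c.size == 0:
            raise ValueError("series must be 1-D, non-empty and aligned")
        if np.any(c <= 0) or np.any(m <= 0):
            raise ValueError("concentrations and masses must be > 0")
        if len(np.unique(c)) != len(c):
            raise ValueError("detector_conc values must be unique")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MalsSeries":
        return cls(
            detector_conc=df["detector_conc_uM"].to_numpy(float),
            average_mass=df["average_mass_kDa"].to_numpy(float),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "detector_conc_uM": self.detector_conc,
                "average_mass_kDa": self.average_mass,
            }
        )


def _mass_ratio_of_x(x: float, max_order: int) -> float:
    """Number-average mass in monomer units for x = m/K, series to N."""
    n = np.arange(1, max_order + 1)
    with np.errstate(over="ignore"):
        xs = x ** (n - 1)
    s = xs.sum()
    if not np.isfinite(s):  # huge x: ratio saturates at N
        return float(max_order)
    return float((n * xs).sum() / s)


def _check_feasible(system: IsodesmicSystem, observed_avg_mass: float) -> None:
    m1, N = system.monomer_mass, system.max_order
    if observed_avg_mass <= m1:
        raise InfeasibleMassError(
            f"average mass {observed_avg_mass} kDa must exceed the monomer "
            f"mass {m1} kDa (pure monomer leaves K_D unbounded)"
        )
    if observed_avg_mass >= m1 * N:
        raise InfeasibleMassError(
            f"average mass {observed_avg_mass} kDa must be below the largest "
            f"included species mass {m1 * N} kDa (order {N})"
        )


def solve_isodesmic(
    system: IsodesmicSystem, observed_avg_mass: float
) -> tuple[SpeciesDistribution, KdEstimate]:
    """Solve the truncated isodesmic system for a measured average mass.

    Returns the species distribution satisfying protomer conservation,
    the number-average-mass constraint, and the equal stepwise-K law,
    together with K_D = m**2 / [dimer] in nM.

    Raises
    ------
    InfeasibleMassError
        If the observed mass is at or outside (M1, N*M1).
    """
    if system.max_order < 2:
        raise ValueError("max_order must be >= 2 to define a dissociation constant")
    _check_feasible(system, observed_avg_mass)

    target = observed_avg_mass / system.monomer_mass
    N = system.max_order

    def f(x: float) -> float:
        return _mass_ratio_of_x(x, N) - target

    # f is strictly increasing; bracket upward from x ~ 0
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 4.0
    x = brentq(f, lo, hi, xtol=_X_TOL, rtol=4*np.finfo(float).eps, maxiter=200)

    n = np.arange(1, N + 1)
    monomer = system.total_protomer_conc / float(np.sum(n * x ** (n - 1)))
    conc = monomer * x ** (n - 1)
    dist = SpeciesDistribution(concentrations=conc, monomer_mass=system.monomer_mass)
    kd = monomer**2 / conc[1]
    est = KdEstimate(
        kd=float(kd),
        max_order=N,
        residual=abs(f(x)),
        monomer_fraction_of_protomers=dist.monomer_fraction_of_protomers,
    )
    return dist, est


def predict_average_mass(
    kd: float,
    total_protomer_conc: float,
    monomer_mass: float,
    max_order: int,
) -> float:
    """Forward model: number-average mass (kDa) implied by a stepwise K_D.

    Solves conservation sum(n * m * (m/K)**(n-1)) = c_tot for the monomer
    concentration m (monotone in m, so bisection-safe), then evaluates the
    number-average mass of the implied distribution.
    """
    if kd <= 0 or total_protomer_conc <= 0 or monomer_mass <= 0:
        raise ValueError("kd, total_protomer_conc and monomer_mass must be > 0")
    if int(max_order) != max_order or max_order < 1:
        raise ValueError("max_order must be an integer >= 1")
    N = int(max_order)
    if N == 1:
        return float(monomer_mass)
    n = np.arange(1, N + 1)

    def bound_protomers(m: float) -> float:
        x = m / kd
        return float(np.sum(n * m * x ** (n - 1)))

    ctot = total_protomer_conc
    hi = ctot  # m <= c_tot always
    m = brentq(
        lambda v: bound_protomers(v) - ctot, 0.0, hi, xtol=1e-14 * ctot, rtol=4*np.finfo(float).eps
    )
    x = m / kd
    conc = m * x ** (n - 1)
    return float(monomer_mass * np.sum(n * conc) / np.sum(conc))


def infinite_limit_kd(
    observed_avg_mass: float, monomer_mass: float, total_protomer_conc: float
) -> float:
    """Closed-form K_D in the untruncated (N -> infinity) limit.

    With x = m/K < 1 the series sums in closed form and the number-average
    mass ratio is 1/(1-x); hence x = 1 - M1/M_avg and
    K = c_tot * (1-x)**2 / x.
    """
    if monomer_mass <= 0 or total_protomer_conc <= 0:
        raise ValueError("masses and concentrations must be > 0")
    if observed_avg_mass <= monomer_mass:
        raise InfeasibleMassError(
            "average mass must exceed the monomer mass for any association"
        )
    x = 1.0 - monomer_mass / observed_avg_mass
    return float(total_protomer_conc * (1.0 - x) ** 2 / x)


def convergence_table(
    total_protomer_conc: float,
    monomer_mass: float,
    observed_avg_mass: float,
    orders: list[int] | np.ndarray,
) -> pd.DataFrame:
    """K_D as a function of the truncation order N of the oligomer series.

    Returns a DataFrame with columns ``max_order`` and ``kd_nM``; K_D is
    non-decreasing in N for fixed feasible inputs and converges to
    :func:`infinite_limit_kd`.
    """
    orders = [int(N) for N in orders]
    if any(N < 2 for N in orders):
        raise ValueError("every order must be >= 2")
    if any(b <= a for a, b in zip(orders, orders[1:])):
        raise ValueError("orders must be strictly ascending")
    rows = []
    for N in orders:
        try:
            _, est = solve_isodesmic(
                IsodesmicSystem(total_protomer_conc, monomer_mass, N),
                observed_avg_mass,
            )
        except (InfeasibleMassError, ValueError) as exc:
            raise type(exc)(f"order {N}: {exc}") from exc
        rows.append({"max_order": N, "kd_nM": est.kd})
    return pd.DataFrame(rows)


def oligomer_count(average_mass: float, monomer_mass: float) -> float:
    """Average protomers per oligomer implied by an average mass."""
    if average_mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be > 0")
    return float(average_mass / monomer_mass)


def fit_kd_to_series(
    series: MalsSeries, monomer_mass: float, max_order: int
) -> KdEstimate:
    """Least-squares K_D over a concentration series of average masses.

    Each row's detector concentration (uM, converted to nM internally) is
    the total protomer concentration for the forward model; K_D minimizes
    the sum of squared (predicted - observed) mass residuals.  With a
    single row this coincides with :func:`solve_isodesmic`.
    """
    ctots_nM = series.detector_conc * 1000.0
    masses = series.average_mass

    feasible = masses > monomer_mass
    if not np.any(feasible):
        raise InfeasibleMassError(
            "every row is at or below the monomer mass; K_D is unidentifiable"
        )

    if len(ctots_nM) == 1:
        system = IsodesmicSystem(float(ctots_nM[0]), monomer_mass, max_order)
        return solve_isodesmic(system, float(masses[0]))[1]

    def sse(log10_kd: float) -> float:
        kd = 10.0**log10_kd
        pred = np.array(
            [predict_average_mass(kd, c, monomer_mass, max_order) for c in ctots_nM]
        )
        return float(np.sum((pred - masses) ** 2))

    res = minimize_scalar(
        sse, bounds=(-6.0, 12.0), method="bounded", options={"xatol": 1e-12}
    )
    kd = float(10.0**res.x)
    # diagnostics evaluated at the geometric-mean concentration row
    ref = float(np.exp(np.mean(np.log(ctots_nM))))
    n = np.arange(1, int(max_order) + 1)
    m = brentq(
        lambda v: float(np.sum(n * v * (v / kd) ** (n - 1))) - ref,
        0.0,
        ref,
        xtol=1e-14 * ref,
    )
    conc = m * (m / kd) ** (n - 1)
    return KdEstimate(
        kd=kd,
        max_order=int(max_order),
        residual=float(np.sqrt(res.fun / len(masses))),
        monomer_fraction_of_protomers=float(m / np.sum(n * conc)),
    )
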